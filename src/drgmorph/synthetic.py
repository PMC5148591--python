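"""Synthetic DRG neuron arbors: generation, rasterization, geometric oracle.

No image data accompanies the morphometry this package implements, so
every downstream stage is exercised against synthetic neurons whose
ground truth is known exactly.  A neuron is a large round soma (20–200 µm
diameter, the range seen in postnatal bovine DRG cultures) plus a rooted
tree of thin neurites grown by a discrete-step stochastic process: at
each step a growing tip branches into two children, terminates, or
elongates with a small heading jitter.  The tree can be rendered to an
8-bit grayscale image that emulates a thresholdable neurofilament-stained
confocal projection (binary foreground, Gaussian noise, debris blobs),
and an exact segment–circle intersection oracle provides the true Sholl
profile against which the image pipeline is validated.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import FrameTooSmallError, InvalidParameterError
from .sholl import ShollGrid, ShollProfile

_SWC_SOMA = 1
_SWC_NEURITE = 3


@dataclass(frozen=True)
class GrowthParams:
    """Parameters of the stochastic branch/terminate growth process.

    ``branch_prob`` and ``term_prob`` are per-step event probabilities
    for each growing tip; the remainder elongates the tip by
    ``step_len`` µm with Gaussian heading jitter of ``angle_sd`` rad.
    A branch replaces the tip by two children deflected by
    ``±branch_angle`` rad.  ``soma_diameter`` is in µm and stays inside
    the 20–200 µm range typical of the modelled neurons unless
    explicitly overridden via ``allow_soma_override``.
    """

    n_primary: int = 5
    step_len: float = 10.0
    branch_prob: float = 0.04
    term_prob: float = 0.02
    angle_sd: float = 0.15
    max_steps: int = 30
    soma_diameter: float = 60.0
    seed: int = 0
    branch_angle: float = 0.5
    allow_soma_override: bool = False

    def __post_init__(self) -> None:
        if self.n_primary < 0:
            raise InvalidParameterError("n_primary must be >= 0")
        if self.step_len <= 0:
            raise InvalidParameterError("step_len must be > 0")
        if not (0 <= self.branch_prob <= 1 and 0 <= self.term_prob <= 1):
            raise InvalidParameterError("probabilities must lie in [0, 1]")
        if self.branch_prob + self.term_prob > 1:
            raise InvalidParameterError("branch_prob + term_prob must be <= 1")
        if self.angle_sd < 0:
            raise InvalidParameterError("angle_sd must be >= 0")
        if self.max_steps < 1:
            raise InvalidParameterError("max_steps must be >= 1")
        if not self.allow_soma_override and not (20.0 <= self.soma_diameter <= 200.0):
            raise InvalidParameterError(
                "soma_diameter outside [20, 200] µm; set allow_soma_override to force")


@dataclass(frozen=True)
class Segment:
    """One neurite segment: a straight line in µm coordinates."""

    start: tuple[float, float]
    end: tuple[float, float]
    parent: int  # index of parent segment, -1 for a root segment
    depth: int   # 0 for root segments


@dataclass
class ArborTree:
    """Ground-truth neuron: soma disk plus a rooted tree of segments."""

    soma_center: tuple[float, float]
    soma_radius: float
    segments: list[Segment] = field(default_factory=list)

    @property
    def n_segments(self) -> int:
        return len(self.segments)

    def max_extent(self) -> float:
        """Largest distance from the soma centre to any point of the neuron (µm)."""
        cx, cy = self.soma_center
        extent = self.soma_radius
        for seg in self.segments:
            for x, y in (seg.start, seg.end):
                extent = max(extent, float(np.hypot(x - cx, y - cy)))
        return extent

    def translated(self, new_center: tuple[float, float]) -> "ArborTree":
        dx = new_center[0] - self.soma_center[0]
        dy = new_center[1] - self.soma_center[1]
        segs = [Segment((s.start[0] + dx, s.start[1] + dy),
                        (s.end[0] + dx, s.end[1] + dy), s.parent, s.depth)
                for s in self.segments]
        return ArborTree(soma_center=new_center, soma_radius=self.soma_radius,
                         segments=segs)


@dataclass(frozen=True)
class RasterConfig:
    """Rendering parameters for confocal-like 8-bit images."""

    pixel_size: float = 0.5   # µm / pixel, typical confocal sampling
    width: int = 1024
    height: int = 1024
    line_width: int = 3       # pixels
    noise_sd: float = 8.0     # grayscale units
    debris_count: int = 6
    debris_size: int = 8      # blob diameter, pixels
    foreground_level: int = 220
    background_level: int = 30

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise InvalidParameterError("pixel_size must be > 0")
        if self.line_width < 1:
            raise InvalidParameterError("line_width must be >= 1 pixel")
        if self.noise_sd < 0 or self.debris_count < 0:
            raise InvalidParameterError("noise_sd and debris_count must be >= 0")
        if not (0 <= self.background_level < self.foreground_level <= 255):
            raise InvalidParameterError(
                "need 0 <= background_level < foreground_level <= 255")


def grow_arbor(params: GrowthParams,
               soma_center: tuple[float, float] = (0.0, 0.0)) -> ArborTree:
    """Grow a neuron arbor by the discrete-step branch/terminate process.

    ``n_primary`` root segments leave the soma boundary at equally
    spaced angles heading radially outward.  At each of ``max_steps``
    growth steps every active tip, in creation order, terminates with
    probability ``term_prob``, branches into two children (headings
    deflected by ``±branch_angle``) with probability ``branch_prob``,
    and otherwise elongates with ``angle_sd`` heading jitter.  Fully
    deterministic for a fixed seed.
    """
    rng = np.random.default_rng(params.seed)
    r0 = params.soma_diameter / 2.0
    cx, cy = soma_center
    tree = ArborTree(soma_center=soma_center, soma_radius=r0)

    # active tips: (position, heading, parent segment index, depth)
    tips: list[tuple[tuple[float, float], float, int, int]] = []
    for k in range(params.n_primary):
        theta = 2.0 * np.pi * k / params.n_primary
        start = (cx + r0 * np.cos(theta), cy + r0 * np.sin(theta))
        tips.append((start, theta, -1, 0))

    for _ in range(params.max_steps):
        if not tips:
            break
        next_tips: list[tuple[tuple[float, float], float, int, int]] = []
        for pos, heading, parent, depth in tips:
            u = rng.random()
            if u < params.term_prob:
                continue
            if u < params.term_prob + params.branch_prob:
                for sign in (+1.0, -1.0):
                    h = heading + sign * params.branch_angle
                    end = (pos[0] + params.step_len * np.cos(h),
                           pos[1] + params.step_len * np.sin(h))
                    tree.segments.append(Segment(pos, end, parent, depth))
                    next_tips.append((end, h, len(tree.segments) - 1, depth + 1))
            else:
                h = heading
                if params.angle_sd > 0:
                    h += rng.normal(0.0, params.angle_sd)
                end = (pos[0] + params.step_len * np.cos(h),
                       pos[1] + params.step_len * np.sin(h))
                tree.segments.append(Segment(pos, end, parent, depth))
                next_tips.append((end, h, len(tree.segments) - 1, depth))
        tips = next_tips
    return tree


def oracle_sholl(tree: ArborTree, grid: ShollGrid) -> ShollProfile:
    """Exact Sholl profile of a ground-truth tree by segment–circle geometry.

    For each grid radius the number of transversal crossings between the
    circle and the union of segments is counted: a segment whose
    endpoint distances straddle the radius crosses once; a segment that
    dips across the circle and back (perpendicular foot inside the
    segment, closer than the radius, both endpoints outside) crosses
    twice; pure tangencies count zero.  An endpoint lying exactly on a
    circle is resolved by sign inheritance along the parent chain, so a
    chain that genuinely passes through the circle at a segment junction
    is counted exactly once and a tip that merely ends on the circle is
    not counted.  The soma disk itself is excluded (segments start on
    the soma boundary).
    """
    radii = grid.radii
    counts = np.zeros(grid.n_radii, dtype=int)
    if not tree.segments:
        return ShollProfile(radii=radii, counts=counts)

    cx, cy = tree.soma_center
    # effective sign of (distance - r) at each segment's end node, per radius;
    # zeros inherit the last non-zero sign along the chain toward the root
    eff_end_sign: list[np.ndarray] = []
    for seg in tree.segments:
        x0, y0 = seg.start
        x1, y1 = seg.end
        d0 = float(np.hypot(x0 - cx, y0 - cy))
        d1 = float(np.hypot(x1 - cx, y1 - cy))
        s0 = np.sign(d0 - radii)
        if seg.parent >= 0:
            parent_sign = eff_end_sign[seg.parent]
        else:
            # root start lies on the soma boundary: inside-or-on counts as inside
            parent_sign = -np.ones_like(radii)
        s0 = np.where(s0 == 0, parent_sign, s0)
        s1 = np.sign(d1 - radii)
        s1_eff = np.where(s1 == 0, s0, s1)
        eff_end_sign.append(s1_eff)

        counts += (s0 * s1_eff < 0).astype(int)

        # interior double crossing: both endpoints outside, perpendicular
        # foot strictly inside the segment and strictly closer than r
        vx, vy = x1 - x0, y1 - y0
        seg_len2 = vx * vx + vy * vy
        if seg_len2 > 0:
            t = ((cx - x0) * vx + (cy - y0) * vy) / seg_len2
            if 0.0 < t < 1.0:
                px_, py_ = x0 + t * vx, y0 + t * vy
                dperp = float(np.hypot(px_ - cx, py_ - cy))
                counts += 2 * ((d0 > radii) & (d1 > radii) & (dperp < radii)).astype(int)
    return ShollProfile(radii=radii, counts=counts)


def _draw_foreground(tree: ArborTree, cfg: RasterConfig) -> np.ndarray:
    """Boolean mask of pixels within line_width/2 of a segment or inside the soma."""
    px = cfg.pixel_size
    h, w = cfg.height, cfg.width
    mask = np.zeros((h, w), dtype=bool)
    half_w = cfg.line_width / 2.0  # pixels

    cx, cy = tree.soma_center[0] / px, tree.soma_center[1] / px
    r_soma = tree.soma_radius / px
    y0, y1 = int(np.floor(cy - r_soma)), int(np.ceil(cy + r_soma))
    x0, x1 = int(np.floor(cx - r_soma)), int(np.ceil(cx + r_soma))
    yy, xx = np.mgrid[max(0, y0):min(h, y1 + 1), max(0, x0):min(w, x1 + 1)]
    mask[yy, xx] |= (xx - cx) ** 2 + (yy - cy) ** 2 <= r_soma ** 2

    for seg in tree.segments:
        ax, ay = seg.start[0] / px, seg.start[1] / px
        bx, by = seg.end[0] / px, seg.end[1] / px
        lo_x = int(np.floor(min(ax, bx) - half_w)) - 1
        hi_x = int(np.ceil(max(ax, bx) + half_w)) + 1
        lo_y = int(np.floor(min(ay, by) - half_w)) - 1
        hi_y = int(np.ceil(max(ay, by) + half_w)) + 1
        yy, xx = np.mgrid[max(0, lo_y):min(h, hi_y + 1), max(0, lo_x):min(w, hi_x + 1)]
        vx, vy = bx - ax, by - ay
        seg_len2 = vx * vx + vy * vy
        if seg_len2 == 0:
            dist2 = (xx - ax) ** 2 + (yy - ay) ** 2
        else:
            t = np.clip(((xx - ax) * vx + (yy - ay) * vy) / seg_len2, 0.0, 1.0)
            dist2 = (xx - (ax + t * vx)) ** 2 + (yy - (ay + t * vy)) ** 2
        mask[yy, xx] |= dist2 <= half_w ** 2
    return mask


def rasterize(tree: ArborTree, cfg: RasterConfig, seed: int = 0) -> np.ndarray:
    """Render a tree to an 8-bit grayscale confocal-like image.

    Soma and segments are drawn at ``foreground_level`` without
    anti-aliasing (a noiseless image is exactly two-valued), Gaussian
    noise of ``noise_sd`` is added and clipped to [0, 255], and
    ``debris_count`` bright blobs are scattered away from the arbor.
    Deterministic for a fixed seed.
    """
    px = cfg.pixel_size
    margin = (cfg.line_width / 2.0 + 1.0) * px
    cx, cy = tree.soma_center
    ext = tree.max_extent() + margin
    if (cx - ext < 0 or cy - ext < 0
            or cx + ext > (cfg.width - 1) * px or cy + ext > (cfg.height - 1) * px):
        raise FrameTooSmallError(
            f"arbor extent {ext:.1f} µm around ({cx:.0f}, {cy:.0f}) exceeds the "
            f"{cfg.width}x{cfg.height} px frame at {px:g} µm/px")

    rng = np.random.default_rng(seed)
    fg = _draw_foreground(tree, cfg)

    if cfg.debris_count > 0:
        from scipy.ndimage import distance_transform_edt

        clearance = cfg.debris_size + cfg.line_width + 4.0
        dist_to_arbor = distance_transform_edt(~fg)
        r_blob = max(1.0, cfg.debris_size / 2.0)
        h, w = fg.shape
        placed = 0
        for _ in range(cfg.debris_count * 50):
            if placed == cfg.debris_count:
                break
            row = int(rng.integers(0, h))
            col = int(rng.integers(0, w))
            if dist_to_arbor[row, col] <= clearance:
                continue
            yy, xx = np.mgrid[max(0, row - int(r_blob) - 1):min(h, row + int(r_blob) + 2),
                              max(0, col - int(r_blob) - 1):min(w, col + int(r_blob) + 2)]
            fg = fg.copy()
            fg[yy, xx] |= (xx - col) ** 2 + (yy - row) ** 2 <= r_blob ** 2
            placed += 1

    image = np.where(fg, float(cfg.foreground_level), float(cfg.background_level))
    if cfg.noise_sd > 0:
        image = image + rng.normal(0.0, cfg.noise_sd, size=image.shape)
    return np.clip(np.rint(image), 0, 255).astype(np.uint8)


def write_swc(tree: ArborTree, path: str | Path, radius: float = 0.5) -> None:
    """Write the tree in standard 7-column SWC (id, type, x, y, z, radius, parent).

    Node 1 is the soma (type 1) at the soma centre with the soma radius;
    neurite nodes are type 3 with the given process radius in µm.
    """
    lines = ["# id type x y z radius parent"]
    cx, cy = tree.soma_center
    lines.append(f"1 {_SWC_SOMA} {cx:.4f} {cy:.4f} 0.0 {tree.soma_radius:.4f} -1")
    next_id = 2
    end_node_of: dict[int, int] = {}
    for idx, seg in enumerate(tree.segments):
        if seg.parent < 0:
            start_id = next_id
            next_id += 1
            lines.append(f"{start_id} {_SWC_NEURITE} {seg.start[0]:.4f} "
                         f"{seg.start[1]:.4f} 0.0 {radius:.4f} 1")
        else:
            start_id = end_node_of[seg.parent]
        end_id = next_id
        next_id += 1
        lines.append(f"{end_id} {_SWC_NEURITE} {seg.end[0]:.4f} "
                     f"{seg.end[1]:.4f} 0.0 {radius:.4f} {start_id}")
        end_node_of[idx] = end_id
    Path(path).write_text("\n".join(lines) + "\n")


def read_swc(path: str | Path) -> ArborTree:
    """Reconstruct an :class:`ArborTree` from an SWC file written by this package."""
    nodes: dict[int, tuple[int, float, float, float, int]] = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        nid, ntype, x, y, _z, radius, parent = line.split()
        nodes[int(nid)] = (int(ntype), float(x), float(y), float(radius), int(parent))
    soma_ids = [nid for nid, n in nodes.items() if n[0] == _SWC_SOMA]
    if len(soma_ids) != 1:
        raise InvalidParameterError(f"expected exactly one soma node in {path}")
    soma = nodes[soma_ids[0]]
    tree = ArborTree(soma_center=(soma[1], soma[2]), soma_radius=soma[3])

    seg_of_end_node: dict[int, int] = {}
    depth_of_end_node: dict[int, int] = {}
    for nid in sorted(nodes):
        ntype, x, y, _r, parent = nodes[nid]
        if ntype != _SWC_NEURITE or parent == soma_ids[0] or parent == -1:
            continue  # soma or a root-segment start point: no segment yet
        p_type, px_, py_, _pr, _pp = nodes[parent]
        parent_seg = seg_of_end_node.get(parent, -1)
        depth = depth_of_end_node.get(parent, -1) + 1 if parent in depth_of_end_node else 0
        tree.segments.append(Segment((px_, py_), (x, y), parent_seg, depth))
        seg_of_end_node[nid] = len(tree.segments) - 1
        depth_of_end_node[nid] = depth
    return tree


def auto_raster_config(params: GrowthParams, base: RasterConfig | None = None) -> RasterConfig:
    """A frame guaranteed to contain any arbor grown with ``params``."""
    base = base or RasterConfig()
    worst = params.soma_diameter / 2.0 + params.max_steps * params.step_len
    margin = (base.line_width / 2.0 + 2.0) * base.pixel_size
    side = int(np.ceil(2.0 * (worst + margin) / base.pixel_size)) + 3
    return dataclasses.replace(base, width=side, height=side)


def make_cohort(group_specs: list[tuple[str, GrowthParams, int]],
                cfg: RasterConfig, seed: int, outdir: str | Path,
                day: int = 1) -> pd.DataFrame:
    """Simulate a cohort: one TIFF + one SWC per neuron plus a manifest CSV.

    Per-neuron seeds are derived deterministically from the master seed
    via :class:`numpy.random.SeedSequence`, so the cohort is reproducible
    file-for-file.  Each neuron is centred in its frame.  Returns the
    manifest as a DataFrame (also written to ``manifest.csv``).
    """
    labels = [label for label, _p, _n in group_specs]
    if len(set(labels)) != len(labels):
        raise InvalidParameterError("duplicate group labels in cohort spec")
    for _label, _p, n in group_specs:
        if n < 1:
            raise InvalidParameterError("each group needs at least one neuron")

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    px = cfg.pixel_size
    center = ((cfg.width - 1) / 2.0 * px, (cfg.height - 1) / 2.0 * px)

    rows = []
    for g_idx, (label, params, n_neurons) in enumerate(group_specs):
        for j in range(n_neurons):
            sub_seed = int(np.random.SeedSequence([seed, g_idx, j]).generate_state(1)[0]
                           % (2 ** 31))
            p = dataclasses.replace(params, seed=sub_seed)
            tree = grow_arbor(p, soma_center=center)
            neuron_id = f"{label}_{j:03d}"
            tiff_path = outdir / f"{neuron_id}.tif"
            swc_path = outdir / f"{neuron_id}.swc"
            image = rasterize(tree, cfg, seed=sub_seed)
            tifffile.imwrite(tiff_path, image)
            write_swc(tree, swc_path, radius=cfg.line_width * px / 2.0)
            rows.append({
                "neuron_id": neuron_id, "group": label, "day": day,
                "tiff_path": tiff_path.name, "swc_path": swc_path.name,
                "soma_x_px": center[0] / px, "soma_y_px": center[1] / px,
                "pixel_size_um": px, "seed": sub_seed,
            })
    manifest = pd.DataFrame(rows)
    manifest.to_csv(outdir / "manifest.csv", index=False)
    return manifest
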