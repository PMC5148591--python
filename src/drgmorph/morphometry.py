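"""Per-neuron morphometry: soma-size classes, neurite presence, viability.

DRG cultures contain a heterogeneous neuron population; somas are split
at a 50 µm diameter cutoff into large and small classes, each neuron is
called neurite-bearing if its processes extend a minimum distance
beyond the soma boundary, and viability is the percentage of
calcein-stained (live) neurons among all neurons counted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import distance_transform_edt

from .branching import BranchingMetrics
from .errors import InvalidParameterError
from .image_prep import CleanMask, SomaSegment
from .sholl import ShollProfile

SIZE_CUTOFF_UM = 50.0
MIN_NEURITE_EXTENSION_UM = 20.0


@dataclass
class NeuronRecord:
    """Everything measured about one neuron."""

    neuron_id: str
    treatment: str
    day: int
    soma_diameter: float
    size_class: str
    neurite_bearing: bool
    viable: bool | None = None
    profile: ShollProfile | None = None
    metrics: BranchingMetrics | None = None


def classify_size(soma_diameter: float, cutoff: float = SIZE_CUTOFF_UM) -> str:
    """'large' if the soma diameter is >= cutoff (default 50 µm), else 'small'.

    A diameter of exactly 50 µm is assigned to the large class by
    convention.
    """
    if soma_diameter <= 0:
        raise InvalidParameterError("soma diameter must be positive")
    return "large" if soma_diameter >= cutoff else "small"


def classify_neurite_bearing(clean: CleanMask, soma: SomaSegment,
                             min_extension_um: float = MIN_NEURITE_EXTENSION_UM) -> bool:
    """True iff foreground reaches >= min_extension_um beyond the soma boundary.

    The criterion is the maximum, over foreground pixels outside the
    soma, of the Euclidean distance to the soma mask (in µm).  The
    default 20 µm is deliberately below the 50 µm Sholl start radius:
    a neuron can bear short neurites yet have an all-zero profile.
    """
    if not clean.mask.any():
        raise InvalidParameterError("empty mask: nothing to classify")
    outside = clean.mask & ~soma.mask
    if not outside.any():
        return False
    dist = distance_transform_edt(~soma.mask, sampling=clean.pixel_size)
    return bool(dist[outside].max() >= min_extension_um)


def viability_fraction(n_stained: int, n_total: int) -> float:
    """Viability as the percentage of calcein-stained neurons, 100·n_stained/n_total."""
    if n_total <= 0:
        raise InvalidParameterError("total neuron count must be positive")
    if not (0 <= n_stained <= n_total):
        raise InvalidParameterError("stained count must lie in [0, n_total]")
    return 100.0 * n_stained / n_total
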