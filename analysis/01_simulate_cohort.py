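"""Simulate a three-condition synthetic DRG cohort.

Emulates a growth-factor experiment: a control condition and two
supplemented conditions with progressively higher branching
probability, 30 neurons each (the per-treatment sample size used for
the branching-rate statistics).  Images and ground-truth SWC
reconstructions go to scratch/cohort/ (regenerable bulk data); the
manifest records every per-neuron seed so the cohort is reproducible
file-for-file.

Run from the repository root:  python analysis/01_simulate_cohort.py
"""

import drgmorph as dm

SEED = 20260921
OUTDIR = "scratch/cohort"

GROUPS = [
    ("control", dm.GrowthParams(branch_prob=0.02), 30),
    ("gf_low", dm.GrowthParams(branch_prob=0.04), 30),
    ("gf_high", dm.GrowthParams(branch_prob=0.06), 30),
]


def main() -> None:
    worst = max((p for _l, p, _n in GROUPS),
                key=lambda p: p.soma_diameter / 2 + p.max_steps * p.step_len)
    cfg = dm.auto_raster_config(worst, dm.RasterConfig())
    manifest = dm.make_cohort(GROUPS, cfg, seed=SEED, outdir=OUTDIR)
    print(f"wrote {len(manifest)} neurons "
          f"({manifest['group'].nunique()} groups) to {OUTDIR}")
    print(f"frame {cfg.width}x{cfg.height} px at {cfg.pixel_size} µm/px; "
          f"master seed {SEED}")


if __name__ == "__main__":
    main()
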