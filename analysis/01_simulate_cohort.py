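#!/usr/bin/env python
"""Simulate the default synthetic cohort under the study conditions.

Two groups of 16 subjects, 18 serial scans each (6 pre-injection), grid
32×32×8, SNR 40 Rician noise, and the treatment effect calibrated so the
noiseless cortical Sindex drops by 9% at plateau (hippocampus 1.3× that,
striatum untouched).  Writes NIfTI volumes, gradient tables, labels and the
manifest under scratch/cohort (large binary data stays out of results/).
"""

import argparse
from pathlib import Path

from dwimarkers.phantom import default_phantom_spec, simulate_cohort

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-per-group", type=int, default=16)
    ap.add_argument("--out", type=Path, default=ROOT / "scratch" / "cohort")
    args = ap.parse_args()

    spec = default_phantom_spec(seed=args.seed)
    dd, dk = spec.effect.plateau["cortex"]
    print(f"calibrated cortical plateau: Δd = {dd:.4g} mm²/s, Δk = {dk:.4g}")
    manifest = simulate_cohort(spec, args.out, n_per_group=args.n_per_group)
    print(
        f"wrote {len(manifest.rows)} scans for "
        f"{len(manifest.subjects)} subjects to {args.out}"
    )


if __name__ == "__main__":
    main()
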