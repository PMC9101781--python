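#!/usr/bin/env python
"""Simulate the study's spectral dataset: four rice varieties (two
saline-alkali-tolerant, two sensitive), 39 grains each, on the 200-3400 cm^-1
grid, and export the spectra as two-column ASCII (PRN) files with a manifest.

The spectra land under scratch/spectra/ (156 files of ~50 KB each); the
manifest is the hand-off point for 02_extract_features.py.
"""

import argparse
from pathlib import Path

from raman_rice.io import write_dataset
from raman_rice.synthetic import SyntheticConfig, generate_dataset

ROOT = Path(__file__).resolve().parent.parent


def main() -> None:
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=1)
    args = parser.parse_args()

    cfg = SyntheticConfig(seed=args.seed)
    spectra = generate_dataset(cfg)
    manifest = write_dataset(spectra, ROOT / "scratch" / "spectra")
    n_tol = sum(sp.variety_label for sp in spectra)
    print(f"generated {len(spectra)} spectra ({n_tol} tolerant, {len(spectra) - n_tol} sensitive)")
    print(f"grid: {spectra[0].shifts.size} points, {cfg.shift_min}-{cfg.shift_max} cm^-1 "
          f"at {cfg.step} cm^-1")
    print(f"manifest: {manifest}")


if __name__ == "__main__":
    main()
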