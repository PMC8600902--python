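#!/usr/bin/env python
"""Render the eight collagen-architecture archetypes and quantify them.

For each archetype this script renders replicate synthetic SHG ROIs,
runs the full 142-feature extractor, and tabulates the morphology that is
supposed to distinguish the patterns: curved wrapping fibers should have
the lowest straightness, the aligned pattern the highest orientation
concentration, the dense/sparse pair the extreme collagen area fractions,
and the reticular pattern the highest crosslink density.

Writes results/archetype_features.csv (one row per ROI, all 142 features)
and results/archetype_summary.csv (per-archetype means of the eight
morphological features).
"""

import argparse
import warnings
from pathlib import Path

import pandas as pd

from fiberscore import extract_features, simulate_tacs_archetype
from fiberscore.registry import FEATURE_NAMES, MORPH_NAMES

warnings.filterwarnings("ignore")


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=0)
    parser.add_argument("--replicates", type=int, default=8)
    parser.add_argument("--image-size", type=int, default=128)
    parser.add_argument("--out-dir", type=Path, default=Path("results"))
    args = parser.parse_args()
    args.out_dir.mkdir(parents=True, exist_ok=True)

    rows = []
    for pattern in range(1, 9):
        for rep in range(args.replicates):
            img, _, _ = simulate_tacs_archetype(
                pattern, seed=args.seed * 1000 + rep, image_size_px=args.image_size)
            vec = extract_features(img, patient_id=f"archetype{pattern}")
            row = {"archetype": pattern, "replicate": rep}
            row.update(dict(zip(FEATURE_NAMES, vec.values)))
            rows.append(row)
    df = pd.DataFrame(rows)
    df.to_csv(args.out_dir / "archetype_features.csv", index=False)

    summary = df.groupby("archetype")[list(MORPH_NAMES)].mean().round(4)
    summary.to_csv(args.out_dir / "archetype_summary.csv")
    print(summary.to_string())
    print()
    ms = summary["morph_straightness"]
    conc = summary["morph_orientation_concentration"]
    area = summary["morph_area_fraction"]
    xl = summary["morph_crosslink_density"]
    print(f"lowest straightness:            archetype {ms.idxmin()} ({ms.min():.3f})")
    print(f"highest orientation concentration: archetype {conc.idxmax()} ({conc.max():.3f})")
    print(f"area fraction dense vs sparse:  {area[7]:.3f} (7) vs {area[8]:.3f} (8)")
    print(f"highest crosslink density:      archetype {xl.idxmax()} ({xl.max():.3f} per 100 um^2)")


if __name__ == "__main__":
    main()
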