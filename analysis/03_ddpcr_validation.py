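#!/usr/bin/env python
"""Assay validation in silico: dilution linearity and admixture limit of
detection for the droplet digital PCR quantification.

Writes results/ddpcr/: the measured-vs-nominal admixture table with its
log-log regression, and per-fraction detection rates for the twofold series
from 50% down to ~0.01% tumor content (200 ng total input, ~25,704 droplets
per well, 100 replicates per fraction).
"""

import json
from pathlib import Path

import pandas as pd

import ctdna_monitor as cm

SEED = 20260103
OUT = Path("results/ddpcr")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)

    series = cm.admixture_measured_series(seed=SEED)
    fit = cm.dilution_linearity(series)
    pd.DataFrame(series, columns=["nominal_percent", "measured_percent"]).to_csv(
        OUT / "linearity.csv", index=False
    )
    (OUT / "linearity_fit.json").write_text(json.dumps(fit, indent=1))
    print(f"admixture linearity: slope {fit['slope']:.3f}, "
          f"R^2 {fit['r_squared']:.4f} over {fit['n_used']} points")

    det = cm.admixture_detection(replicates=100, seed=SEED + 1)
    pd.DataFrame(
        {"tumor_percent": det.as_percent(), "detection_rate": det.detection_rate}
    ).to_csv(OUT / "detection.csv", index=False)
    lod_pct = 100 * det.lod_fraction if det.lod_fraction else float("nan")
    print(f"limit of detection: {lod_pct:.4f}% tumor content detected in "
          f">=95% of {det.replicates} replicates "
          f"(~{lod_pct / 100 * 200e3 / 3.3:.1f} copies per reaction)")


if __name__ == "__main__":
    main()
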