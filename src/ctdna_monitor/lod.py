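"""Admixture limit-of-detection and dilution-linearity experiments.

Emulates the assay-validation design: tumor and normal DNA mixed at twofold
dilutions of tumor content from 50% down to ~0.01%, with total input fixed
at 200 ng (~60,600 haploid genomes at 3.3 pg each), one ddPCR well per
replicate.  The junction assay sees ``fraction x total`` target copies; the
copy number actually loaded into a well is Poisson around that expectation
(aliquot sampling), which is what limits detection at the bottom of the
series.  Quantification uses the reaction volume implied by the analyzed
droplets (v_r = T x v_d) so the round trip is unbiased.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .droplets import (
    DEFAULT_INTENSITY_MODEL,
    ng_to_copies,
    simulate_control_wells,
    simulate_droplets,
)
from .quant import call_positive, normalize_droplets, poisson_quantify


def admixture_series(start_fraction: float = 0.5, n_dilutions: int = 13) -> list[float]:
    """Twofold tumor-content dilution series, e.g. 0.5 ... 0.000122."""
    if not 0 < start_fraction <= 1 or n_dilutions < 1:
        raise ValueError("need 0 < start_fraction <= 1 and n_dilutions >= 1")
    return [start_fraction / 2**k for k in range(n_dilutions)]


@dataclass
class DetectionResult:
    fractions: list[float]  # tumor content per series member
    detection_rate: list[float]  # share of replicates with >= 1 positive droplet
    replicates: int
    lod_fraction: float | None  # smallest fraction detected in >= `criterion`

    def as_percent(self) -> list[float]:
        return [100.0 * f for f in self.fractions]


def admixture_detection(
    total_ng: float = 200.0,
    fractions: list[float] | None = None,
    n_droplets: int = 25_704,
    replicates: int = 100,
    threshold: float = 0.5,
    criterion: float = 0.95,
    intensity_model=DEFAULT_INTENSITY_MODEL,
    seed: int = 0,
) -> DetectionResult:
    """Detection rate (>= 1 positive droplet) per admixture fraction.

    Every replicate runs the full droplet path: simulate the well, normalize
    against per-fraction control wells, and call positives at ``threshold``.
    ``lod_fraction`` is the smallest fraction whose rate meets ``criterion``,
    provided every larger fraction meets it too.
    """
    if fractions is None:
        fractions = admixture_series()
    rng = np.random.default_rng(seed)
    total_copies = ng_to_copies(total_ng)
    rates = []
    for frac in fractions:
        controls = simulate_control_wells(
            "admix", n_droplets=n_droplets, intensity_model=intensity_model, seed=rng
        )
        mean_target = frac * total_copies
        detected = 0
        for _ in range(replicates):
            n_copies = int(rng.poisson(mean_target))
            n_bg = int(rng.poisson((1.0 - frac) * total_copies))
            ds = simulate_droplets(
                n_copies, n_bg, n_droplets, intensity_model, seed=rng, assay_id="admix"
            )
            P, _ = call_positive(normalize_droplets(ds, *controls), threshold)
            detected += P >= 1
        rates.append(detected / replicates)
    lod = None
    for frac, rate in zip(fractions, rates):  # largest -> smallest
        if rate >= criterion:
            lod = frac
        else:
            break
    return DetectionResult(list(fractions), rates, replicates, lod)


def admixture_measured_series(
    total_ng: float = 200.0,
    fractions: list[float] | None = None,
    n_droplets: int = 25_704,
    threshold: float = 0.5,
    intensity_model=DEFAULT_INTENSITY_MODEL,
    seed: int = 0,
) -> list[tuple[float, float]]:
    """One (nominal %, measured %) pair per fraction for linearity fits.

    The measured tumor percentage divides the junction-assay concentration by
    a total-DNA control assay run on the same input, mirroring how admixture
    content is quantified against a copy-number-stable region.
    """
    if fractions is None:
        fractions = admixture_series()
    rng = np.random.default_rng(seed)
    total_copies = ng_to_copies(total_ng)
    v_r = n_droplets * 0.91e-3  # reaction fully partitioned into droplets
    out = []
    controls = simulate_control_wells(
        "admix", n_droplets=n_droplets, intensity_model=intensity_model, seed=rng
    )
    ctrl_controls = simulate_control_wells(
        "total", n_droplets=n_droplets, intensity_model=intensity_model, seed=rng
    )
    for frac in fractions:
        target = simulate_droplets(
            int(rng.poisson(frac * total_copies)), 0, n_droplets,
            intensity_model, seed=rng, assay_id="admix",
        )
        total = simulate_droplets(
            int(rng.poisson(total_copies)), 0, n_droplets,
            intensity_model, seed=rng, assay_id="total",
        )
        Pt, Tt = call_positive(normalize_droplets(target, *controls), threshold)
        Pc, Tc = call_positive(normalize_droplets(total, *ctrl_controls), threshold)
        q_t = poisson_quantify(Pt, Tt, v_r=v_r, v_i=4.0, plasma_equiv_ml=None)
        q_c = poisson_quantify(Pc, Tc, v_r=v_r, v_i=4.0, plasma_equiv_ml=None)
        measured = 100.0 * q_t.c_vi / q_c.c_vi if q_c.c_vi > 0 and not q_c.saturated else 0.0
        out.append((100.0 * frac, measured))
    return out
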