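"""ddPCR analytics: normalization, positive calling, Poisson quantification.

Per-assay fluorescence is mapped to a nominal 0-1 scale anchored on the
negative-control median (-> 0) and the positive-control positive-cluster
median (-> 1).  Droplets at or above a relative threshold (default 0.5) are
positive.  The copy concentration per microliter of input circulating DNA is

    C_Vi = -ln(1 - P/T) * V_r / (V_d * V_i)

with P positive of T total droplets, droplet volume V_d (0.91e-3 ul),
reaction volume V_r and input volume V_i.  Replicate wells are pooled by
summing droplet counts (preserving Poisson statistics at low counts) and
quantified once with the summed input volume.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .droplets import DropletSet

V_DROPLET_UL = 0.91e-3
V_REACTION_UL = 20.0
V_INPUT_UL = 4.0
PLASMA_EQUIV_ML = 0.020
POSITIVE_THRESHOLD = 0.5


@dataclass
class NormalizedDroplets:
    """Relative intensities with the affine anchors that produced them."""

    assay_id: str
    sample_id: str
    rel_intensities: np.ndarray  # nominal 0-1 scale; values outside permitted
    neg_anchor: float
    pos_anchor: float

    def __post_init__(self) -> None:
        if not self.neg_anchor < self.pos_anchor:
            raise ValueError("neg_anchor must be below pos_anchor")

    def to_raw(self, rel: float) -> float:
        """Invert the affine normalization (for display/auditing)."""
        return self.neg_anchor + rel * (self.pos_anchor - self.neg_anchor)


def _positive_cluster_midpoint(intensities: np.ndarray) -> float:
    """Valley between the two modes of a bimodal well, by 1-D 2-median Lloyd."""
    lo, hi = float(np.min(intensities)), float(np.max(intensities))
    mid = 0.5 * (lo + hi)
    for _ in range(50):
        below = intensities[intensities < mid]
        above = intensities[intensities >= mid]
        if below.size == 0 or above.size == 0:
            break
        new_mid = 0.5 * (float(np.median(below)) + float(np.median(above)))
        if abs(new_mid - mid) < 1e-9:
            break
        mid = new_mid
    return mid


def normalize_droplets(
    sample: DropletSet, neg_control: DropletSet, pos_control: DropletSet
) -> NormalizedDroplets:
    """Scale a well's intensities so the control anchors map to 0 and 1.

    neg_anchor is the median of the negative-control well; pos_anchor is the
    median of the positive-control droplets above the valley between its two
    intensity modes.  Raises if the controls do not separate.
    """
    if not (sample.assay_id == neg_control.assay_id == pos_control.assay_id):
        raise ValueError("sample and controls must come from the same assay")
    neg_anchor = float(np.median(neg_control.intensities))
    mid = _positive_cluster_midpoint(pos_control.intensities)
    pos_cluster = pos_control.intensities[pos_control.intensities >= mid]
    pos_anchor = float(np.median(pos_cluster))
    if pos_anchor <= neg_anchor:
        raise ValueError(
            f"assay {sample.assay_id!r}: positive anchor does not exceed negative "
            "anchor; assay uninterpretable"
        )
    rel = (sample.intensities - neg_anchor) / (pos_anchor - neg_anchor)
    return NormalizedDroplets(sample.assay_id, sample.sample_id, rel, neg_anchor, pos_anchor)


def call_positive(norm: NormalizedDroplets, threshold: float = POSITIVE_THRESHOLD) -> tuple[int, int]:
    """Count droplets with relative intensity >= threshold (inclusive)."""
    rel = np.asarray(norm.rel_intensities)
    return int(np.count_nonzero(rel >= threshold)), int(rel.size)


@dataclass
class QuantResult:
    """Poisson-corrected quantification of one (possibly pooled) well."""

    P: int
    T: int
    lam: float  # mean copies per droplet
    c_vi: float  # copies per ul input circulating DNA
    copies_per_reaction: float
    copies_per_ml_plasma: float | None
    v_d: float
    v_r: float
    v_i: float
    plasma_equiv_ml: float | None = None
    saturated: bool = False

    def __post_init__(self) -> None:
        if not 0 <= self.P <= self.T:
            raise ValueError("need 0 <= P <= T")


def poisson_quantify(
    P: int,
    T: int,
    v_r: float = V_REACTION_UL,
    v_i: float = V_INPUT_UL,
    v_d: float = V_DROPLET_UL,
    plasma_equiv_ml: float | None = PLASMA_EQUIV_ML,
    saturation_correction: bool = False,
) -> QuantResult:
    """Poisson-correct positive/total droplet counts into concentrations.

    At saturation (P == T) the concentration is above the quantifiable range;
    the result is flagged and, with ``saturation_correction``, lambda is
    evaluated at the continuity-corrected bound P = T - 0.5.
    """
    if T <= 0:
        raise ValueError("total droplet count must be positive")
    if not 0 <= P <= T:
        raise ValueError("need 0 <= P <= T")
    if v_r <= 0 or v_i <= 0 or v_d <= 0:
        raise ValueError("volumes must be positive")
    saturated = P == T
    if saturated:
        lam = -math.log(0.5 / T) if saturation_correction else math.inf
    else:
        lam = -math.log1p(-P / T)
    c_vi = lam * v_r / (v_d * v_i)
    copies_rxn = lam * v_r / v_d
    per_ml = None
    if plasma_equiv_ml is not None:
        if plasma_equiv_ml <= 0:
            raise ValueError("plasma equivalent must be positive")
        per_ml = copies_rxn / plasma_equiv_ml
    return QuantResult(
        P, T, lam, c_vi, copies_rxn, per_ml, v_d, v_r, v_i,
        plasma_equiv_ml=plasma_equiv_ml, saturated=saturated,
    )


def copies_per_ml_plasma(q: QuantResult, plasma_equiv_ml: float = PLASMA_EQUIV_ML) -> float:
    """Copies per ml plasma from the per-reaction count; propagates saturation."""
    if plasma_equiv_ml <= 0:
        raise ValueError("plasma equivalent must be positive")
    return q.copies_per_reaction / plasma_equiv_ml


def pool_replicates(wells: list[tuple[int, int]]) -> tuple[int, int]:
    """Sum (P, T) over replicate wells of the same assay and sample."""
    if not wells:
        raise ValueError("cannot pool an empty replicate list")
    P = sum(int(p) for p, _ in wells)
    T = sum(int(t) for _, t in wells)
    if any(p < 0 or t <= 0 or p > t for p, t in wells):
        raise ValueError("each well needs 0 <= P <= T, T > 0")
    return P, T


def dilution_linearity(series: list[tuple[float, float]]) -> dict:
    """OLS fit of log(measured) on log(nominal) for a dilution series.

    Zero or negative measured values are dropped (with a count in the result)
    before the log transform.  Returns slope, intercept and R^2 on log-log
    axes, plus the number of points used.
    """
    if len(series) < 3:
        raise ValueError("need at least 3 dilution points")
    if any(nom <= 0 for nom, _ in series):
        raise ValueError("nominal inputs must be positive")
    kept = [(n, m) for n, m in series if m > 0]
    n_dropped = len(series) - len(kept)
    if len(kept) < 2:
        raise ValueError("fewer than 2 positive measurements; cannot fit")
    x = np.log10([n for n, _ in kept])
    y = np.log10([m for _, m in kept])
    slope, intercept = np.polyfit(x, y, 1)
    resid = y - (slope * x + intercept)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 if ss_tot == 0 else 1.0 - float(np.sum(resid**2)) / ss_tot
    return {
        "slope": float(slope),
        "intercept": float(intercept),
        "r_squared": float(r2),
        "n_used": len(kept),
        "n_dropped": n_dropped,
    }
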