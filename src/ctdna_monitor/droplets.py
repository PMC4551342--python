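"""Droplet digital PCR droplet-level simulation.

Target molecules are partitioned uniformly at random over droplets
(multinomial occupancy, equivalently Poisson per droplet for large droplet
counts).  A droplet fluoresces from the positive Gaussian component iff it
holds at least one amplifiable target after optional false-negative thinning;
otherwise it draws from the negative component.  There is no false-positive
mechanism by default: rearrangement junction assays show cleanly separated
clusters and zero positives in negative-control material, which the default
model reproduces (the negative component sits many SDs below the calling
threshold).  An optional "rain" mixture adds intermediate-intensity droplets
for robustness experiments.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: default two-component fluorescence model (RFU): mu_neg, sd_neg, mu_pos, sd_pos
DEFAULT_INTENSITY_MODEL = (1000.0, 30.0, 9000.0, 200.0)

#: average droplets analyzed per well and its SD, used by the cohort generator
DROPLETS_PER_WELL_MEAN = 25704.0
DROPLETS_PER_WELL_SD = 2320.0

#: mass of one haploid genome, pg; converts ng of input DNA to copies
HAPLOID_GENOME_PG = 3.3


@dataclass
class DropletSet:
    """Raw fluorescence intensities of one well, plus hidden simulation truth."""

    assay_id: str
    sample_id: str
    intensities: np.ndarray  # raw RFU, one per droplet
    role: str = "sample"  # sample | positive_control | negative_control | ntc
    n_target_copies: int | None = None  # hidden truth when simulated
    n_occupied: int | None = None

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)
        if self.role not in ("sample", "positive_control", "negative_control", "ntc"):
            raise ValueError(f"unknown well role {self.role!r}")
        if not np.all(np.isfinite(self.intensities)):
            raise ValueError("droplet intensities must be finite")

    @property
    def n_droplets(self) -> int:
        return int(self.intensities.size)


def simulate_droplets(
    n_target_copies: int,
    n_background_copies: int = 0,
    n_droplets: int = 25704,
    intensity_model: tuple[float, float, float, float] = DEFAULT_INTENSITY_MODEL,
    false_negative_rate: float = 0.0,
    rain_fraction: float = 0.0,
    seed: int | np.random.Generator = 0,
    assay_id: str = "assay",
    sample_id: str = "sample",
    role: str = "sample",
) -> DropletSet:
    """Simulate one well of droplets containing ``n_target_copies`` molecules.

    Background (non-target) copies partition into droplets too but never
    amplify under the default model, so they only matter when ``rain_fraction``
    is nonzero.  A per-copy false-negative thinning removes targets before
    partitioning.  ``seed`` may be an integer or a Generator.
    """
    if n_target_copies < 0 or n_background_copies < 0:
        raise ValueError("copy counts must be non-negative")
    if n_droplets <= 0:
        raise ValueError("need a positive droplet count")
    mu_neg, sd_neg, mu_pos, sd_pos = intensity_model
    if mu_pos <= mu_neg:
        raise ValueError("positive component mean must exceed negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)

    n_amp = n_target_copies
    if false_negative_rate > 0 and n_amp > 0:
        n_amp = int(rng.binomial(n_amp, 1.0 - false_negative_rate))
    intensities = rng.normal(mu_neg, sd_neg, size=n_droplets)
    occupied = np.array([], dtype=int)
    if n_amp > 0:
        occupied = np.unique(rng.integers(0, n_droplets, size=n_amp))
        intensities[occupied] = rng.normal(mu_pos, sd_pos, size=occupied.size)
    if rain_fraction > 0:
        # intermediate 'rain' droplets drawn uniformly between the components
        n_rain = int(rng.binomial(n_droplets, rain_fraction))
        where = rng.choice(n_droplets, size=n_rain, replace=False)
        intensities[where] = rng.uniform(mu_neg, mu_pos, size=n_rain)
    return DropletSet(
        assay_id,
        sample_id,
        intensities,
        role=role,
        n_target_copies=n_target_copies,
        n_occupied=int(occupied.size),
    )


def expected_occupied(n_copies: int, n_droplets: int) -> float:
    """Expected number of occupied droplets: T * (1 - (1 - 1/T)^N)."""
    return n_droplets * (1.0 - (1.0 - 1.0 / n_droplets) ** n_copies)


def ng_to_copies(nanograms: float) -> float:
    """Convert a DNA mass to haploid genome copies (3.3 pg per haploid genome)."""
    if nanograms < 0:
        raise ValueError("mass must be non-negative")
    return nanograms * 1e3 / HAPLOID_GENOME_PG


def simulate_control_wells(
    assay_id: str,
    n_droplets: int = 25704,
    intensity_model: tuple[float, float, float, float] = DEFAULT_INTENSITY_MODEL,
    positive_copies: int = 20000,
    seed: int | np.random.Generator = 0,
) -> tuple[DropletSet, DropletSet]:
    """Simulate the (negative, positive) control wells run with each assay."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    neg = simulate_droplets(
        0, 0, n_droplets, intensity_model, seed=rng,
        assay_id=assay_id, sample_id="neg_ctrl", role="negative_control",
    )
    pos = simulate_droplets(
        positive_copies, 0, n_droplets, intensity_model, seed=rng,
        assay_id=assay_id, sample_id="pos_ctrl", role="positive_control",
    )
    return neg, pos
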