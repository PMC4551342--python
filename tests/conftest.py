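import numpy as np
import pytest

import ctdna_monitor as cm


@pytest.fixture(scope="session")
def toy_genome():
    return cm.make_toy_genome(3, 60_000, seed=11)


@pytest.fixture(scope="session")
def planted(toy_genome):
    """Six planted events (2 each of t/del/inv) and the donor genome."""
    events = cm.random_rearrangements(
        toy_genome,
        ["translocation", "deletion", "inversion",
         "translocation", "deletion", "inversion"],
        seed=7,
    )
    donor = cm.plant_rearrangements(toy_genome, events)
    return events, donor


@pytest.fixture(scope="session")
def tumor_reads(planted):
    _, donor = planted
    return cm.simulate_read_pairs(donor.genome, 10.0, 100, 500.0, seed=3)


@pytest.fixture(scope="session")
def normal_reads(toy_genome):
    return cm.simulate_read_pairs(toy_genome, 10.0, 100, 500.0, seed=4, id_prefix="n")


@pytest.fixture(scope="session")
def small_cohort():
    """Reduced-droplet cohort for fast monitoring tests.

    The reaction volume is matched to the droplet count (v_r = T * v_d) so
    the scaled-down wells still analyze the full reaction contents and the
    cohort keeps the full-scale detection behaviour.
    """
    spec = cm.CohortSpec(
        seed=5, droplets_mean=4000.0, droplets_sd=200.0, v_r=4000.0 * 0.91e-3
    )
    return cm.simulate_cohort(spec)


@pytest.fixture(scope="session")
def small_records(small_cohort):
    return cm.quantify_cohort(small_cohort)


def canonical_truth_sides(event):
    """Truth junction as the caller's canonically ordered (side1, side2).

    Maps the generator's strand convention onto junction-side directions:
    side A '+' -> fused segment left of the breakpoint, side B '+' -> right.
    """
    d1 = "left" if event.strand_a == "+" else "right"
    d2 = "right" if event.strand_b == "+" else "left"
    s1 = (event.chrom_a, event.pos_a, d1)
    s2 = (event.chrom_b, event.pos_b, d2)
    return (s1, s2) if (s1[0], s1[1]) <= (s2[0], s2[1]) else (s2, s1)
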