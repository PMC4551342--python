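"""Paired-end read simulation from a donor genome.

Fragments are drawn uniformly along the genome with log-normal lengths around
the configured median insert size; the two mates are read convergently from
the fragment ends (one from each strand).  Base-call errors are i.i.d.
substitutions.  No attempt is made to model platform-specific error profiles,
GC bias or mappability.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .genome import ToyGenome, revcomp

_BASES = "ACGT"


@dataclass
class ReadPairSet:
    """A list of (read1, read2, fragment_id) with the library parameters."""

    pairs: list[tuple[str, str, str]]
    read_length: int
    insert_median: float
    insert_spread: float  # SD of the fragment-length distribution, bp

    def __len__(self) -> int:
        return len(self.pairs)

    def physical_coverage(self, genome_length: int) -> float:
        """Fragments x median insert / genome length."""
        return len(self.pairs) * self.insert_median / genome_length


def simulate_read_pairs(
    genome: ToyGenome,
    coverage: float,
    read_length: int = 100,
    insert_median: float = 500.0,
    insert_log_sd: float = 0.1,
    error_rate: float = 0.0,
    seed: int = 0,
    id_prefix: str = "frag",
) -> ReadPairSet:
    """Simulate paired-end reads at the given fold sequence coverage.

    The number of fragments is Poisson with mean
    ``coverage * genome_length / (2 * read_length)``.  ``insert_log_sd`` is
    the SD of log fragment length (the distribution is log-normal with median
    ``insert_median``); fragments shorter than ``2 * read_length`` are clipped
    up so mates never overlap the same junction twice from opposite ends.
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if insert_median <= 2 * read_length:
        raise ValueError("insert_median must exceed twice the read length")
    rng = np.random.default_rng(seed)
    # separate stream for base-call errors so fragment coordinates are
    # identical across error rates at a fixed seed
    err_rng = np.random.default_rng((int(seed), 7))
    names = genome.names()
    lengths = np.array([len(genome[c]) for c in names], dtype=float)
    total = lengths.sum()
    n_frags = int(rng.poisson(coverage * total / (2 * read_length)))
    chrom_idx = rng.choice(len(names), size=n_frags, p=lengths / total)
    frag_lens = np.maximum(
        np.round(insert_median * np.exp(rng.normal(0.0, insert_log_sd, size=n_frags))),
        2 * read_length,
    ).astype(int)
    flips = rng.random(n_frags) < 0.5
    # empirical spread of the realized fragment lengths
    spread = float(frag_lens.std()) if n_frags > 1 else insert_median * insert_log_sd

    pairs: list[tuple[str, str, str]] = []
    for i in range(n_frags):
        chrom = names[chrom_idx[i]]
        seq = genome[chrom]
        flen = min(int(frag_lens[i]), len(seq))
        start = int(rng.integers(0, len(seq) - flen + 1))
        frag = seq[start : start + flen]
        r1 = frag[:read_length]
        r2 = revcomp(frag[-read_length:])
        if flips[i]:
            r1, r2 = r2, r1
        if error_rate > 0:
            r1 = _mutate(r1, error_rate, err_rng)
            r2 = _mutate(r2, error_rate, err_rng)
        pairs.append((r1, r2, f"{id_prefix}{i}"))
    return ReadPairSet(pairs, read_length, insert_median, spread)


def _mutate(read: str, rate: float, rng: np.random.Generator) -> str:
    hits = np.flatnonzero(rng.random(len(read)) < rate)
    if hits.size == 0:
        return read
    out = list(read)
    for i in hits:
        out[i] = _BASES[(_BASES.index(out[i]) + int(rng.integers(1, 4))) % 4]
    return "".join(out)
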