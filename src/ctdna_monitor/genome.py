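"""Toy reference genomes and planted somatic rearrangements.

A :class:`ToyGenome` is an ordered set of random uniform-base chromosomes that
stands in for a reference assembly at a scale where an exact k-mer aligner is
practical.  Somatic structural variants (translocations, deletions,
inversions) are planted by :func:`plant_rearrangements`, which builds a donor
(tumor) genome and a ground-truth table of junctions.

Breakpoint convention
---------------------
All coordinates are 0-based half-open.  A junction has two sides; each side
carries a strand: ``+`` means the fused segment lies on the reference forward
strand *left* of the breakpoint for side A (respectively *right* of the
breakpoint for side B), ``-`` means the reverse-complemented flank is used.
With that convention the fusion sequence around a junction is::

    flank_a + flank_b

where ``flank_a = ref_a[pos_a-L:pos_a]`` for ``strand_a == '+'`` (else the
reverse complement of ``ref_a[pos_a:pos_a+L]``) and ``flank_b =
ref_b[pos_b:pos_b+L]`` for ``strand_b == '+'`` (else the reverse complement of
``ref_b[pos_b-L:pos_b]``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T(/N) string."""
    return "".join(_COMP[b] for b in reversed(seq))


@dataclass
class ToyGenome:
    """Ordered map of chromosome name -> uppercase A/C/G/T sequence."""

    chromosomes: dict[str, str]

    def __post_init__(self) -> None:
        if not self.chromosomes:
            raise ValueError("genome must contain at least one chromosome")
        for name, seq in self.chromosomes.items():
            if not seq:
                raise ValueError(f"chromosome {name!r} is empty")
            if set(seq) - set("ACGT"):
                raise ValueError(f"chromosome {name!r} contains non-ACGT characters")

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.chromosomes.values())

    def __getitem__(self, name: str) -> str:
        return self.chromosomes[name]

    def names(self) -> list[str]:
        return list(self.chromosomes)


@dataclass
class PlantedRearrangement:
    """A single planted somatic junction with reproducible fusion sequence."""

    chrom_a: str
    pos_a: int
    strand_a: str
    chrom_b: str
    pos_b: int
    strand_b: str
    svtype: str  # 'translocation' | 'deletion' | 'inversion'
    fusion_sequence: str = ""

    def __post_init__(self) -> None:
        if self.svtype not in ("translocation", "deletion", "inversion"):
            raise ValueError(f"unknown svtype {self.svtype!r}")
        if self.svtype in ("deletion", "inversion"):
            if self.chrom_a != self.chrom_b:
                raise ValueError(f"{self.svtype} must be intra-chromosomal")
            if not self.pos_a < self.pos_b:
                raise ValueError(f"{self.svtype} requires pos_a < pos_b")
        if self.strand_a not in "+-" or self.strand_b not in "+-":
            raise ValueError("strands must be '+' or '-'")


def make_toy_genome(n_chromosomes: int, lengths, seed: int) -> ToyGenome:
    """Generate a deterministic random genome of i.i.d. uniform bases.

    ``lengths`` may be a single int (applied to every chromosome) or a
    sequence of per-chromosome lengths.  Chromosomes are named chr1..chrN.
    """
    if n_chromosomes < 1:
        raise ValueError("need at least one chromosome")
    if isinstance(lengths, (int, np.integer)):
        lengths = [int(lengths)] * n_chromosomes
    lengths = [int(x) for x in lengths]
    if len(lengths) != n_chromosomes:
        raise ValueError("one length per chromosome required")
    if any(x <= 0 for x in lengths):
        raise ValueError("chromosome lengths must be positive")
    rng = np.random.default_rng(seed)
    chroms = {}
    for i, length in enumerate(lengths, start=1):
        idx = rng.integers(0, 4, size=length)
        chroms[f"chr{i}"] = _BASES[idx].tobytes().decode()
    return ToyGenome(chroms)


def fusion_sequence(
    genome: ToyGenome, event: PlantedRearrangement, flank: int = 100
) -> str:
    """Reconstruct the junction-spanning sequence from reference flanks."""
    ref_a = genome[event.chrom_a]
    ref_b = genome[event.chrom_b]
    if event.strand_a == "+":
        fa = ref_a[max(0, event.pos_a - flank) : event.pos_a]
    else:
        fa = revcomp(ref_a[event.pos_a : event.pos_a + flank])
    if event.strand_b == "+":
        fb = ref_b[event.pos_b : event.pos_b + flank]
    else:
        fb = revcomp(ref_b[max(0, event.pos_b - flank) : event.pos_b])
    return fa + fb


def _junction_homology(genome: ToyGenome, event: PlantedRearrangement) -> int:
    """Length of micro-homology at the junction (0 = unambiguous breakpoint).

    Measures how far the fused side-B sequence coincides with the reference
    continuation of side A (and symmetrically to the left); any positive value
    makes the breakpoint position ambiguous within the homology tract.
    """
    fus = fusion_sequence(genome, event, flank=30)
    mid = len(fus) // 2
    ref_a = genome[event.chrom_a]
    ref_b = genome[event.chrom_b]
    # continuation of side A beyond its breakpoint, in junction orientation
    if event.strand_a == "+":
        cont_a = ref_a[event.pos_a : event.pos_a + 30]
    else:
        cont_a = revcomp(ref_a[max(0, event.pos_a - 30) : event.pos_a])
    # sequence preceding side B's breakpoint, in junction orientation
    if event.strand_b == "+":
        prev_b = ref_b[max(0, event.pos_b - 30) : event.pos_b]
    else:
        prev_b = revcomp(ref_b[event.pos_b : event.pos_b + 30])
    right = 0
    while right < min(len(cont_a), len(fus) - mid) and fus[mid + right] == cont_a[right]:
        right += 1
    left = 0
    while left < min(len(prev_b), mid) and fus[mid - 1 - left] == prev_b[-1 - left]:
        left += 1
    return left + right


@dataclass
class DonorGenome:
    """A rearranged (tumor) genome plus the truth table of planted junctions.

    For inversions the truth table records both novel junctions (left and
    right edge of the inverted segment); each refers back to the originating
    event by index.
    """

    genome: ToyGenome
    events: list[PlantedRearrangement]
    junctions: list[PlantedRearrangement] = field(default_factory=list)


def plant_rearrangements(
    genome: ToyGenome,
    events: list[PlantedRearrangement],
    flank: int = 100,
    min_end_distance: int = 1000,
) -> DonorGenome:
    """Build a donor genome containing each event's fusion sequence once.

    Deletions and inversions rewrite their chromosome in place; a
    translocation adds a derivative contig ``der_<chromA>_<chromB>_<i>``
    joining the two reference arms (the intact reference chromosomes are kept,
    as in a tumor retaining normal homologues).  Events must be pairwise
    non-overlapping and keep ``min_end_distance`` bp clear of chromosome ends.
    """
    spans: dict[str, list[tuple[int, int]]] = {}
    for ev in events:
        for chrom, pos in ((ev.chrom_a, ev.pos_a), (ev.chrom_b, ev.pos_b)):
            if chrom not in genome.chromosomes:
                raise ValueError(f"unknown chromosome {chrom!r}")
            if not min_end_distance <= pos <= len(genome[chrom]) - min_end_distance:
                raise ValueError(
                    f"breakpoint {chrom}:{pos} closer than {min_end_distance} bp to an end"
                )
        if ev.svtype in ("deletion", "inversion"):
            spans.setdefault(ev.chrom_a, []).append((ev.pos_a, ev.pos_b))
        else:
            spans.setdefault(ev.chrom_a, []).append((ev.pos_a, ev.pos_a + 1))
            spans.setdefault(ev.chrom_b, []).append((ev.pos_b, ev.pos_b + 1))
    for chrom, ivals in spans.items():
        ivals.sort()
        for (s1, e1), (s2, e2) in zip(ivals, ivals[1:]):
            if s2 < e1 + 2 * flank:
                raise ValueError(f"overlapping or abutting events on {chrom}")

    chroms = dict(genome.chromosomes)
    junctions: list[PlantedRearrangement] = []
    # in-place events right-to-left so earlier coordinates stay valid
    inplace = [e for e in events if e.svtype in ("deletion", "inversion")]
    for ev in sorted(inplace, key=lambda e: -e.pos_a):
        seq = chroms[ev.chrom_a]
        if ev.svtype == "deletion":
            chroms[ev.chrom_a] = seq[: ev.pos_a] + seq[ev.pos_b :]
        else:
            chroms[ev.chrom_a] = (
                seq[: ev.pos_a] + revcomp(seq[ev.pos_a : ev.pos_b]) + seq[ev.pos_b :]
            )
    for i, ev in enumerate(events):
        if ev.svtype == "translocation":
            der = genome[ev.chrom_a][: ev.pos_a] + genome[ev.chrom_b][ev.pos_b :]
            chroms[f"der_{ev.chrom_a}_{ev.chrom_b}_{i}"] = der
        ev.fusion_sequence = fusion_sequence(genome, ev, flank=flank)
        if ev.svtype == "inversion":
            left = PlantedRearrangement(
                ev.chrom_a, ev.pos_a, "+", ev.chrom_b, ev.pos_b, "-", "inversion"
            )
            right = PlantedRearrangement(
                ev.chrom_a, ev.pos_a, "-", ev.chrom_b, ev.pos_b, "+", "inversion"
            )
            left.fusion_sequence = fusion_sequence(genome, left, flank=flank)
            right.fusion_sequence = fusion_sequence(genome, right, flank=flank)
            junctions.extend([left, right])
        else:
            junctions.append(ev)
    return DonorGenome(ToyGenome(chroms), events, junctions)


def random_rearrangements(
    genome: ToyGenome,
    svtypes: list[str],
    seed: int,
    min_end_distance: int = 2000,
    min_event_size: int = 5000,
    max_event_size: int = 20000,
) -> list[PlantedRearrangement]:
    """Draw non-overlapping events with micro-homology-free junctions.

    Breakpoints are resampled until every novel junction has zero
    micro-homology, which keeps planted breakpoints well defined at base
    precision.
    """
    rng = np.random.default_rng(seed)
    names = genome.names()
    events: list[PlantedRearrangement] = []

    def clashes(cand: PlantedRearrangement) -> bool:
        try:
            plant_rearrangements(
                genome, events + [cand], min_end_distance=min_end_distance
            )
        except ValueError:
            return True
        return False

    for svtype in svtypes:
        for _ in range(200):
            if svtype == "translocation":
                if len(names) < 2:
                    raise ValueError("translocation needs two chromosomes")
                ca, cb = rng.choice(len(names), size=2, replace=False)
                ca, cb = names[ca], names[cb]
                pa = int(rng.integers(min_end_distance, len(genome[ca]) - min_end_distance))
                pb = int(rng.integers(min_end_distance, len(genome[cb]) - min_end_distance))
                cand = PlantedRearrangement(ca, pa, "+", cb, pb, "+", svtype)
                probes = [cand]
            else:
                ca = names[int(rng.integers(len(names)))]
                size = int(rng.integers(min_event_size, max_event_size))
                hi = len(genome[ca]) - min_end_distance - size
                if hi <= min_end_distance:
                    continue
                pa = int(rng.integers(min_end_distance, hi))
                cand = PlantedRearrangement(ca, pa, "+", ca, pa + size, "+", svtype)
                if svtype == "inversion":
                    probes = [
                        PlantedRearrangement(ca, pa, "+", ca, pa + size, "-", svtype),
                        PlantedRearrangement(ca, pa, "-", ca, pa + size, "+", svtype),
                    ]
                else:
                    probes = [cand]
            if clashes(cand):
                continue
            if any(_junction_homology(genome, p) > 0 for p in probes):
                continue
            events.append(cand)
            break
        else:
            raise RuntimeError(f"could not place a {svtype} event")
    return events
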