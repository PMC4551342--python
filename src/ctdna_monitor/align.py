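"""Exact-seed read alignment against a toy reference.

A unique k-mer index (default k = 21) anchors reads; anchored seeds are
extended by exact character matching.  Reads whose two ends anchor to
disparate loci with abutting read intervals are reported as split reads,
which is the base-precision evidence for rearrangement junctions.  Seeds that
occur more than once in the reference mark a read as ambiguous and exclude it
from downstream calling.  This is toy-scale plumbing, not a production
aligner: no indels, no base qualities, mismatch tolerance only for
full-length placements.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .genome import ToyGenome, revcomp
from .reads import ReadPairSet

AMBIG = ("*", -1)


@dataclass
class AlignedBlock:
    """One gapless aligned block of a read."""

    chrom: str
    ref_start: int  # 0-based half-open on the reference forward strand
    ref_end: int
    strand: str  # read maps to '+' (as-is) or '-' (reverse complement)
    read_start: int  # offsets within the read as sequenced
    read_end: int

    @property
    def length(self) -> int:
        return self.read_end - self.read_start


@dataclass
class ReadAlignment:
    read_id: str
    mate: int  # 1 or 2
    status: str  # 'aligned' | 'split' | 'unaligned' | 'ambiguous'
    blocks: list[AlignedBlock] = field(default_factory=list)

    @property
    def is_split(self) -> bool:
        return self.status == "split"

    @property
    def primary(self) -> AlignedBlock | None:
        return self.blocks[0] if self.blocks else None


class KmerIndex:
    """Unique-position k-mer lookup over the reference forward strand."""

    def __init__(self, genome: ToyGenome, k: int = 21):
        if k < 8:
            raise ValueError("seed length too short to be reliably unique")
        self.k = k
        self.genome = genome
        index: dict[str, tuple[str, int]] = {}
        for chrom, seq in genome.chromosomes.items():
            for i in range(len(seq) - k + 1):
                kmer = seq[i : i + k]
                if kmer in index:
                    index[kmer] = AMBIG
                else:
                    index[kmer] = (chrom, i)
        self.index = index

    def lookup(self, kmer: str) -> tuple[str, int, str] | None | str:
        """Return (chrom, pos, strand), 'ambiguous', or None."""
        fwd = self.index.get(kmer)
        rev = self.index.get(revcomp(kmer))
        if fwd is AMBIG or rev is AMBIG or (fwd and rev):
            return "ambiguous"
        if fwd:
            return fwd[0], fwd[1], "+"
        if rev:
            return rev[0], rev[1], "-"
        return None


def _extend(read: str, ref: str, anchor_read: int, anchor_ref: int, k: int, strand: str):
    """Maximal exact extension of a seed hit; returns read/ref intervals."""
    L = len(read)
    if strand == "+":
        off = anchor_ref - anchor_read  # ref index = read index + off
        a = anchor_read
        while a > 0 and 0 <= a - 1 + off < len(ref) and ref[a - 1 + off] == read[a - 1]:
            a -= 1
        b = anchor_read + k
        while b < L and 0 <= b + off < len(ref) and ref[b + off] == read[b]:
            b += 1
        return a, b, a + off, b + off
    # '-': read index t maps to ref index c - t
    c = anchor_ref + k - 1 + anchor_read
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    a = anchor_read
    while a > 0 and 0 <= c - (a - 1) < len(ref) and ref[c - (a - 1)] == comp.get(read[a - 1], "N"):
        a -= 1
    b = anchor_read + k
    while b < L and 0 <= c - b < len(ref) and ref[c - b] == comp.get(read[b], "N"):
        b += 1
    return a, b, c - (b - 1), c - a + 1


def align_read(
    read: str,
    index: KmerIndex,
    read_id: str = "read",
    mate: int = 1,
    max_mismatches: int = 2,
) -> ReadAlignment:
    """Place one read: unique full-length, split across a junction, or neither."""
    k = index.k
    L = len(read)
    if L < k:
        return ReadAlignment(read_id, mate, "unaligned")

    hit_l = index.lookup(read[:k])
    hit_r = index.lookup(read[L - k :])
    if hit_l == "ambiguous" or hit_r == "ambiguous":
        return ReadAlignment(read_id, mate, "ambiguous")

    block_l = block_r = None
    if hit_l is not None:
        chrom, pos, strand = hit_l
        a, b, ra, rb = _extend(read, index.genome[chrom], 0, pos, k, strand)
        block_l = AlignedBlock(chrom, ra, rb, strand, a, b)
    if hit_r is not None:
        chrom, pos, strand = hit_r
        a, b, ra, rb = _extend(read, index.genome[chrom], L - k, pos, k, strand)
        block_r = AlignedBlock(chrom, ra, rb, strand, a, b)

    for blk in (block_l, block_r):
        if blk is not None and blk.length == L:
            return ReadAlignment(read_id, mate, "aligned", [blk])

    # mismatch-tolerant full placement anchored on either seed
    for hit in (hit_l, hit_r):
        if hit is None:
            continue
        chrom, pos, strand = hit
        anchor_read = 0 if hit is hit_l else L - k
        placed = _full_with_mismatches(
            read, index.genome[chrom], anchor_read, pos, k, strand, max_mismatches
        )
        if placed is not None:
            ra, rb = placed
            return ReadAlignment(
                read_id, mate, "aligned", [AlignedBlock(chrom, ra, rb, strand, 0, L)]
            )

    if block_l is not None and block_r is not None and block_l.read_end == block_r.read_start:
        disparate = (block_l.chrom, block_l.strand) != (block_r.chrom, block_r.strand)
        if not disparate:
            if block_l.strand == "+":
                disparate = block_r.ref_start != block_l.ref_end
            else:
                disparate = block_l.ref_start != block_r.ref_end
        if disparate:
            return ReadAlignment(read_id, mate, "split", [block_l, block_r])
    return ReadAlignment(read_id, mate, "unaligned")


def _full_with_mismatches(read, ref, anchor_read, anchor_ref, k, strand, max_mm):
    L = len(read)
    comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
    if strand == "+":
        start = anchor_ref - anchor_read
        if start < 0 or start + L > len(ref):
            return None
        mm = sum(1 for i in range(L) if ref[start + i] != read[i])
        return (start, start + L) if mm <= max_mm else None
    c = anchor_ref + k - 1 + anchor_read
    start = c - (L - 1)
    if start < 0 or c + 1 > len(ref):
        return None
    mm = sum(1 for i in range(L) if ref[c - i] != comp.get(read[i], "N"))
    return (start, c + 1) if mm <= max_mm else None


def align_reads(
    reads: ReadPairSet, reference: ToyGenome, k: int = 21, max_mismatches: int = 2
) -> list[tuple[ReadAlignment, ReadAlignment]]:
    """Align every pair; returns [(alignment mate 1, alignment mate 2), ...]."""
    index = KmerIndex(reference, k=k)
    out = []
    for r1, r2, frag_id in reads.pairs:
        a1 = align_read(r1, index, read_id=frag_id, mate=1, max_mismatches=max_mismatches)
        a2 = align_read(r2, index, read_id=frag_id, mate=2, max_mismatches=max_mismatches)
        out.append((a1, a2))
    return out
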