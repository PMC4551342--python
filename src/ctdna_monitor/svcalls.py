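"""Somatic rearrangement calling from discordant pairs and split reads.

The scan mirrors the classic paired-end logic: a fragment is discordant when
its mates map to different chromosomes, imply a fragment length far outside
the library distribution, or have inconsistent orientation.  Discordant
fragments (including fragments whose read spans the junction and aligns
split) are clustered by their two junction sides; clusters with at least two
supporting fragments become calls; split reads refine breakpoints to base
precision by majority vote and let the junction-spanning fusion sequence be
reconstructed from reference flanks.  Calls seen in matched normal reads are
removed as germline.

Each junction side carries a *direction*: ``left`` means the fused segment
occupies the reference forward strand left of the breakpoint (reads on that
side map '+'), ``right`` means it continues rightward (reads map '-').  The
direction pair determines the cytogenetic-style label: inter-chromosomal
pairs are ``t``, intra-chromosomal (left,right) is ``del``, equal directions
are ``inv``.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

from .align import ReadAlignment
from .genome import ToyGenome, revcomp

MIN_SUPPORT = 2


@dataclass(frozen=True)
class JunctionSide:
    chrom: str
    pos: int
    direction: str  # 'left' | 'right'


@dataclass
class SupportFragment:
    """One fragment's evidence for a junction (pair-level or split-read)."""

    frag_id: str
    side1: JunctionSide
    side2: JunctionSide
    exact: bool  # True when derived from a split read
    kind: str  # inter_chromosomal | deletion_like | inversion_like | other


@dataclass
class RearrangementCall:
    chrom1: str
    pos1: int
    dir1: str
    chrom2: str
    pos2: int
    dir2: str
    svtype: str  # 't' | 'del' | 'inv' | 'other'
    n_supporting_fragments: int
    split_read_support: int
    fusion_sequence: str | None
    ci_bp: int  # half-width of the breakpoint confidence interval
    exact: bool
    flags: list[str] = field(default_factory=list)
    fragments: list[SupportFragment] = field(default_factory=list)

    def key(self) -> tuple:
        return (self.chrom1, self.pos1, self.chrom2, self.pos2, self.dir1, self.dir2)


# ------------------------------------------------------------ pair classification


def classify_pair(
    a1: ReadAlignment,
    a2: ReadAlignment,
    insert_median: float,
    insert_spread: float,
    n_sd: float = 4.0,
) -> str:
    """Label one fragment: concordant, or the flavour of discordance."""
    b1, b2 = a1.primary, a2.primary
    if b1 is None or b2 is None:
        raise ValueError("both mates must be aligned")
    if b1.chrom != b2.chrom:
        return "inter_chromosomal"
    if b1.strand == b2.strand:
        return "inversion_like"
    left, right = (b1, b2) if b1.ref_start <= b2.ref_start else (b2, b1)
    if left.strand != "+":  # divergent (outward-facing) orientation
        return "other"
    implied = right.ref_end - left.ref_start
    lo = insert_median - n_sd * insert_spread
    hi = insert_median + n_sd * insert_spread
    if implied > hi:
        return "deletion_like"
    if implied < lo:
        return "other"
    return "concordant"


def _side_from_block(block) -> JunctionSide:
    if block.strand == "+":
        return JunctionSide(block.chrom, block.ref_end, "left")
    return JunctionSide(block.chrom, block.ref_start, "right")


def _ordered(s1: JunctionSide, s2: JunctionSide) -> tuple[JunctionSide, JunctionSide]:
    return (s1, s2) if (s1.chrom, s1.pos) <= (s2.chrom, s2.pos) else (s2, s1)


def _split_sides(aln: ReadAlignment) -> tuple[JunctionSide, JunctionSide]:
    bl, br = aln.blocks  # read-order: junction at bl.read_end == br.read_start
    s1 = (
        JunctionSide(bl.chrom, bl.ref_end, "left")
        if bl.strand == "+"
        else JunctionSide(bl.chrom, bl.ref_start, "right")
    )
    s2 = (
        JunctionSide(br.chrom, br.ref_start, "right")
        if br.strand == "+"
        else JunctionSide(br.chrom, br.ref_end, "left")
    )
    return _ordered(s1, s2)


def _kind_from_sides(s1: JunctionSide, s2: JunctionSide) -> str:
    if s1.chrom != s2.chrom:
        return "inter_chromosomal"
    if s1.direction == s2.direction:
        return "inversion_like"
    if s1.direction == "left":
        return "deletion_like"
    return "other"


def extract_support_fragments(
    alignment_pairs: list[tuple[ReadAlignment, ReadAlignment]],
    insert_median: float,
    insert_spread: float,
    n_sd: float = 4.0,
) -> tuple[list[SupportFragment], dict]:
    """Turn aligned pairs into junction evidence; returns (fragments, counts)."""
    frags: list[SupportFragment] = []
    counts = Counter()
    for a1, a2 in alignment_pairs:
        split = next((a for a in (a1, a2) if a.is_split), None)
        if split is not None:
            s1, s2 = _split_sides(split)
            frags.append(
                SupportFragment(split.read_id, s1, s2, True, _kind_from_sides(s1, s2))
            )
            counts["split"] += 1
            continue
        if a1.status != "aligned" or a2.status != "aligned":
            counts["excluded_unaligned_or_ambiguous"] += 1
            continue
        kind = classify_pair(a1, a2, insert_median, insert_spread, n_sd=n_sd)
        counts[kind] += 1
        if kind == "concordant":
            continue
        s1, s2 = _ordered(_side_from_block(a1.primary), _side_from_block(a2.primary))
        frags.append(SupportFragment(a1.read_id, s1, s2, False, kind))
    return frags, dict(counts)


# ---------------------------------------------------------------------- clustering


def cluster_discordant(
    fragments: list[SupportFragment],
    window: int = 500,
    min_support: int = MIN_SUPPORT,
) -> list[RearrangementCall]:
    """Merge compatible fragments and emit calls with >= min_support fragments.

    Fragments merge when chromosomes and side directions agree and both side
    positions fall within ``window`` of the cluster's running means.  The
    candidate breakpoint of a discordant-only cluster is the innermost
    compatible position per side (interval precision, CI +- window).
    """
    calls: list[RearrangementCall] = []
    groups: dict[tuple, list[list[SupportFragment]]] = {}
    key = lambda f: (f.side1.chrom, f.side2.chrom, f.side1.direction, f.side2.direction)
    ordered = sorted(fragments, key=lambda f: key(f) + (f.side1.pos, f.side2.pos))
    for frag in ordered:
        merged = False
        for cluster in groups.setdefault(key(frag), []):
            m1 = sum(f.side1.pos for f in cluster) / len(cluster)
            m2 = sum(f.side2.pos for f in cluster) / len(cluster)
            if abs(frag.side1.pos - m1) <= window and abs(frag.side2.pos - m2) <= window:
                cluster.append(frag)
                merged = True
                break
        if not merged:
            groups[key(frag)].append([frag])

    for (c1, c2, d1, d2), clusters in groups.items():
        for members in clusters:
            if len(members) < min_support:
                continue
            pos1 = (
                max(f.side1.pos for f in members)
                if d1 == "left"
                else min(f.side1.pos for f in members)
            )
            pos2 = (
                max(f.side2.pos for f in members)
                if d2 == "left"
                else min(f.side2.pos for f in members)
            )
            s1, s2 = JunctionSide(c1, pos1, d1), JunctionSide(c2, pos2, d2)
            svtype = {
                "inter_chromosomal": "t",
                "deletion_like": "del",
                "inversion_like": "inv",
                "other": "other",
            }[_kind_from_sides(s1, s2)]
            calls.append(
                RearrangementCall(
                    c1, pos1, d1, c2, pos2, d2, svtype,
                    n_supporting_fragments=len(members),
                    split_read_support=sum(f.exact for f in members),
                    fusion_sequence=None,
                    ci_bp=window,
                    exact=False,
                    fragments=members,
                )
            )
    calls.sort(key=RearrangementCall.key)
    return calls


# ---------------------------------------------------------- fusion reconstruction


def junction_sequence(
    reference: ToyGenome,
    s1: JunctionSide,
    s2: JunctionSide,
    flank: int = 100,
) -> str:
    """Reference-derived sequence spanning the junction, side1 then side2."""
    ref1, ref2 = reference[s1.chrom], reference[s2.chrom]
    f1 = (
        ref1[max(0, s1.pos - flank) : s1.pos]
        if s1.direction == "left"
        else revcomp(ref1[s1.pos : s1.pos + flank])
    )
    f2 = (
        ref2[s2.pos : s2.pos + flank]
        if s2.direction == "right"
        else revcomp(ref2[max(0, s2.pos - flank) : s2.pos])
    )
    return f1 + f2


def reconstruct_fusion(
    call: RearrangementCall,
    reference: ToyGenome,
    window: int = 500,
    flank: int = 100,
) -> RearrangementCall:
    """Refine a call to base precision from its split-read members.

    The breakpoint pair is the most frequent split-read junction (ties break
    to the smallest coordinates); disagreement beyond ``window`` flags the
    call unresolved.  Without split reads the interval-precision call is
    returned unchanged.
    """
    exact_pairs = [
        (f.side1.pos, f.side2.pos) for f in call.fragments if f.exact
    ]
    if not exact_pairs:
        return call
    spread1 = max(p for p, _ in exact_pairs) - min(p for p, _ in exact_pairs)
    spread2 = max(p for _, p in exact_pairs) - min(p for _, p in exact_pairs)
    if spread1 > window or spread2 > window:
        call.flags.append("unresolved_split_disagreement")
        return call
    counts = Counter(exact_pairs)
    top = max(counts.values())
    pos1, pos2 = min(p for p, c in counts.items() if c == top)
    call.pos1, call.pos2 = int(pos1), int(pos2)
    call.exact = True
    call.ci_bp = 0
    s1 = JunctionSide(call.chrom1, call.pos1, call.dir1)
    s2 = JunctionSide(call.chrom2, call.pos2, call.dir2)
    call.fusion_sequence = junction_sequence(reference, s1, s2, flank=flank)
    return call


# ------------------------------------------------------------------ germline filter


def filter_germline(
    calls: list[RearrangementCall],
    normal_fragments: list[SupportFragment] | None,
    window: int = 500,
) -> tuple[list[RearrangementCall], int]:
    """Drop tumor calls supported by any matched-normal fragment.

    Returns (somatic calls, number removed).  With no normal data every call
    passes through carrying a ``no_normal_filter`` flag.
    """
    if normal_fragments is None:
        for call in calls:
            if "no_normal_filter" not in call.flags:
                call.flags.append("no_normal_filter")
        return calls, 0
    somatic = []
    removed = 0
    for call in calls:
        hit = any(
            f.side1.chrom == call.chrom1
            and f.side2.chrom == call.chrom2
            and f.side1.direction == call.dir1
            and f.side2.direction == call.dir2
            and abs(f.side1.pos - call.pos1) <= window
            and abs(f.side2.pos - call.pos2) <= window
            for f in normal_fragments
        )
        if hit:
            removed += 1
        else:
            somatic.append(call)
    return somatic, removed


# --------------------------------------------------------------- candidate selection


def select_candidates(
    calls: list[RearrangementCall], k: int = 5
) -> tuple[list[RearrangementCall], str | None]:
    """Pick k calls spanning the range of supporting-fragment counts.

    Calls are ranked by support, split into k contiguous rank strata, and the
    call with the highest split-read support (then smallest breakpoint
    coordinates) is taken from each stratum; monitoring assays are chosen
    this way so a range of apparent copy-number states is represented.
    Returns (selection, shortfall notice or None).
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(calls) <= k:
        notice = (
            f"only {len(calls)} calls available for k={k}" if len(calls) < k else None
        )
        return list(calls), notice
    ranked = sorted(
        calls, key=lambda c: (-c.n_supporting_fragments,) + c.key()
    )
    strata = [ranked[i * len(ranked) // k : (i + 1) * len(ranked) // k] for i in range(k)]
    chosen = [
        min(stratum, key=lambda c: (-c.split_read_support,) + c.key())
        for stratum in strata
        if stratum
    ]
    return chosen, None
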