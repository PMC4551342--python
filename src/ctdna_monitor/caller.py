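"""End-to-end rearrangement calling: reads in, somatic junction calls out."""

from __future__ import annotations

from dataclasses import dataclass, field

from .align import align_reads
from .genome import ToyGenome
from .reads import ReadPairSet
from .svcalls import (
    MIN_SUPPORT,
    RearrangementCall,
    SupportFragment,
    cluster_discordant,
    extract_support_fragments,
    filter_germline,
    reconstruct_fusion,
)


@dataclass
class CallingResult:
    calls: list[RearrangementCall]
    n_germline_removed: int
    pair_counts: dict
    window: int
    alignment_pairs: list = field(repr=False, default_factory=list)


def call_rearrangements(
    reads: ReadPairSet,
    reference: ToyGenome,
    normal_reads: ReadPairSet | None = None,
    k: int = 21,
    min_support: int = MIN_SUPPORT,
    window: int | None = None,
    n_sd: float = 4.0,
    fusion_flank: int = 100,
) -> CallingResult:
    """Align, classify, cluster, refine and germline-filter in one pass.

    ``window`` defaults to the library's median insert size, the natural
    scale of breakpoint uncertainty for pair-level evidence.
    """
    if window is None:
        window = int(reads.insert_median)
    if window < reads.insert_median:
        raise ValueError("clustering window must be at least the median insert size")
    pairs = align_reads(reads, reference, k=k)
    frags, counts = extract_support_fragments(
        pairs, reads.insert_median, reads.insert_spread, n_sd=n_sd
    )
    calls = cluster_discordant(frags, window=window, min_support=min_support)
    calls = [reconstruct_fusion(c, reference, window=window, flank=fusion_flank) for c in calls]

    normal_frags: list[SupportFragment] | None = None
    if normal_reads is not None:
        normal_pairs = align_reads(normal_reads, reference, k=k)
        normal_frags, _ = extract_support_fragments(
            normal_pairs, normal_reads.insert_median, normal_reads.insert_spread, n_sd=n_sd
        )
    calls, removed = filter_germline(calls, normal_frags, window=window)
    return CallingResult(calls, removed, counts, window, alignment_pairs=pairs)
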