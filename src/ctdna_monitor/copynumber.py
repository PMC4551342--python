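"""Read-depth copy-number track from fragment midpoints."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .align import ReadAlignment
from .genome import ToyGenome


@dataclass
class CopyNumberTrack:
    bin_size: int
    counts: dict[str, np.ndarray]  # per-chromosome fragment midpoint counts
    log2_ratio: dict[str, np.ndarray]  # vs genome-wide median count; NaN in empty bins
    empty: dict[str, np.ndarray]  # True where the bin holds no fragments

    @property
    def total_fragments(self) -> int:
        return int(sum(c.sum() for c in self.counts.values()))


def copy_number_track(
    alignment_pairs: list[tuple[ReadAlignment, ReadAlignment]],
    reference: ToyGenome,
    bin_size: int = 1000,
) -> CopyNumberTrack:
    """Bin fragment midpoints and normalize to the genome-wide median.

    A fragment is assigned to the bin of its midpoint: the span of both mates
    when both align to one chromosome, otherwise the span of the first
    aligned block.  Empty bins are flagged instead of carrying -inf ratios.
    """
    if bin_size < 1:
        raise ValueError("bin_size must be positive")
    counts = {
        chrom: np.zeros(max(1, -(-len(seq) // bin_size)), dtype=int)
        for chrom, seq in reference.chromosomes.items()
    }
    for a1, a2 in alignment_pairs:
        blocks = [a.primary for a in (a1, a2) if a.status == "aligned"]
        if not blocks:
            continue
        if len(blocks) == 2 and blocks[0].chrom == blocks[1].chrom:
            lo = min(b.ref_start for b in blocks)
            hi = max(b.ref_end for b in blocks)
            chrom = blocks[0].chrom
        else:
            chrom, lo, hi = blocks[0].chrom, blocks[0].ref_start, blocks[0].ref_end
        mid = (lo + hi) // 2
        counts[chrom][min(mid // bin_size, counts[chrom].size - 1)] += 1

    allc = np.concatenate(list(counts.values()))
    med = float(np.median(allc[allc > 0])) if np.any(allc > 0) else np.nan
    log2 = {}
    empty = {}
    for chrom, c in counts.items():
        empty[chrom] = c == 0
        with np.errstate(divide="ignore"):
            r = np.where(c > 0, np.log2(np.maximum(c, 1) / med), np.nan)
        log2[chrom] = r
    return CopyNumberTrack(bin_size, counts, log2, empty)
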