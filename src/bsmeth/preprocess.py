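"""Read quality statistics and adapter/quality trimming.

QC summarises per-cycle quality and base composition, the read-GC
distribution and exact-duplicate overrepresented sequences.  Trimming
removes a 3' adapter (prefix-overlap match) and low-quality bases from
both ends, then short reads (or read pairs with one short mate) are
dropped.  Trimming only ever removes bases, never modifies them, and is
idempotent.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np

from .types import Read


@dataclass
class QcReport:
    per_position_quality: list[float]       # mean quality by cycle
    base_composition: list[dict[str, float]]  # A/C/G/T/N fraction by cycle
    gc_histogram: tuple[np.ndarray, np.ndarray]  # (counts, bin edges) over [0,1]
    overrepresented: list[tuple[str, float]]  # (sequence, frequency)
    n_reads: int
    n_bases: int


def qc_report(reads, overrep_min_frac: float = 0.001, gc_bins: int = 20) -> QcReport:
    """Per-cycle and per-read quality statistics for one FASTQ file."""
    qual_sum: list[float] = []
    qual_n: list[int] = []
    comp: list[Counter] = []
    gcs: list[float] = []
    seq_counts: Counter = Counter()
    n_reads = 0
    n_bases = 0
    for r in reads:
        n_reads += 1
        n_bases += len(r)
        if len(r) > len(qual_sum):
            extra = len(r) - len(qual_sum)
            qual_sum.extend([0.0] * extra)
            qual_n.extend([0] * extra)
            comp.extend(Counter() for _ in range(extra))
        for i, (b, q) in enumerate(zip(r.seq, r.qual)):
            qual_sum[i] += q
            qual_n[i] += 1
            comp[i][b] += 1
        if len(r):
            gcs.append((r.seq.count("G") + r.seq.count("C")) / len(r))
        seq_counts[r.seq] += 1
    per_pos = [s / n if n else float("nan") for s, n in zip(qual_sum, qual_n)]
    composition = []
    for c in comp:
        tot = sum(c.values())
        composition.append({b: c.get(b, 0) / tot for b in "ACGTN"})
    counts, edges = np.histogram(gcs, bins=gc_bins, range=(0.0, 1.0))
    over = [
        (seq, cnt / n_reads)
        for seq, cnt in seq_counts.most_common()
        if n_reads and cnt / n_reads >= overrep_min_frac
    ]
    return QcReport(per_pos, composition, (counts, edges), over, n_reads, n_bases)


def _find_adapter(seq: str, adapter: str, min_overlap: int, max_mismatch_frac: float) -> int:
    """Leftmost position where a 3' suffix matches the adapter prefix.

    Returns len(seq) when no acceptable match exists.  An overlap
    shorter than min_overlap is only accepted if it covers the whole
    adapter (short adapters are matched in full).
    """
    required = min(min_overlap, len(adapter))
    for i in range(len(seq) - required + 1):
        ov = min(len(seq) - i, len(adapter))
        if ov < required:
            break
        mism = sum(a != b for a, b in zip(seq[i : i + ov], adapter[:ov]))
        if mism <= int(max_mismatch_frac * ov):
            return i
    return len(seq)


def trim_read(
    read: Read,
    adapter: str | None = None,
    qual_threshold: int = 20,
    min_overlap: int = 5,
    max_mismatch_frac: float = 0.1,
) -> Read:
    """Remove a 3' adapter and low-quality bases from both ends.

    Adapter and quality trimming are iterated to a fixed point, which
    makes the operation idempotent.  May return an empty read; length
    filtering is a separate step (:func:`filter_short`).
    """
    seq, qual = read.seq, list(read.qual)
    while True:
        n0 = len(seq)
        if adapter:
            cut = _find_adapter(seq, adapter, min_overlap, max_mismatch_frac)
            seq, qual = seq[:cut], qual[:cut]
        lo, hi = 0, len(seq)
        while lo < hi and qual[lo] < qual_threshold:
            lo += 1
        while hi > lo and qual[hi - 1] < qual_threshold:
            hi -= 1
        seq, qual = seq[lo:hi], qual[lo:hi]
        if len(seq) == n0:
            break
    return Read(read.id, seq, tuple(qual), read.mate, read.richness)


def filter_short(read: Read, min_len: int = 36) -> bool:
    """Keep (True) iff the trimmed read reaches the minimum length."""
    return len(read) >= min_len


def trim_pairs(
    pairs,
    adapter: str | None = None,
    qual_threshold: int = 20,
    min_len: int = 36,
):
    """Trim mate pairs; a pair is dropped if either mate becomes short."""
    kept = []
    n_dropped = 0
    for r1, r2 in pairs:
        t1 = trim_read(r1, adapter, qual_threshold)
        t2 = trim_read(r2, adapter, qual_threshold)
        if filter_short(t1, min_len) and filter_short(t2, min_len):
            kept.append((t1, t2))
        else:
            n_dropped += 1
    return kept, n_dropped


def trim_reads(
    reads,
    adapter: str | None = None,
    qual_threshold: int = 20,
    min_len: int = 36,
):
    """Trim single-end reads, dropping those shorter than min_len."""
    kept = []
    n_dropped = 0
    for r in reads:
        t = trim_read(r, adapter, qual_threshold)
        if filter_short(t, min_len):
            kept.append(t)
        else:
            n_dropped += 1
    return kept, n_dropped
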