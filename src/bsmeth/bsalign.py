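"""Three-letter bisulfite alignment and post-alignment filtering.

Reads are reduced to a three-letter alphabet (T-rich reads: C->T;
A-rich reads: G->A) and searched against the two converted reference
texts (all-C->T and all-G->A).  For a directional library each read has
exactly two legitimate placements:

========  =================  ==============  ===================
richness  searched pattern   searched text   reported site strand
========  =================  ==============  ===================
T-rich    converted read     C->T genome     ``+`` (Watson Cs)
T-rich    revcomp(conv)      G->A genome     ``-`` (Crick Cs)
A-rich    revcomp(conv)      C->T genome     ``+``
A-rich    converted read     G->A genome     ``-``
========  =================  ==============  ===================

In every legitimate placement the strand the read aligns against had
its cytosines converted for a T-rich read (``conversion_used == "CT"``)
and its guanines converted for an A-rich read (``"GA"``); records
violating this are wrong-strand hits and are discarded.

Post-alignment filtering discards, in order: (1) multi-hit reads,
(2) wrong-strand hits, (3) reads retaining C over a reference T
(A-rich: G over A) - evidence the read cannot come from a bisulfite
fragment at this locus - and optionally (4) PCR duplicates.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, NamedTuple

import numpy as np

from .types import A_RICH, T_RICH, Genome, Read, revcomp

_C, _G, _T, _A = (ord(b) for b in "CGTA")


@dataclass
class ConvertedRead:
    """A read after three-letter conversion, with marked positions."""

    original: Read
    converted_seq: str
    marked: frozenset[int]


def convert_read(read: Read, mark_quality: int = 5) -> ConvertedRead:
    """Replace C->T (T-rich) or G->A (A-rich); mark confident replacements.

    A replaced position is marked when its base quality exceeds
    ``mark_quality``; marks are carried as an audit tag only and do not
    affect counting.
    """
    target = "C" if read.richness == T_RICH else "G"
    sub = "T" if read.richness == T_RICH else "A"
    marked = frozenset(
        i for i, (b, q) in enumerate(zip(read.seq, read.qual))
        if b == target and q > mark_quality
    )
    return ConvertedRead(read, read.seq.replace(target, sub), marked)


def convert_reference(genome: Genome) -> tuple[Genome, Genome]:
    """The two fully converted reference genomes (C->T and G->A)."""
    ct = {c: s.replace("C", "T") for c, s in genome.sequences.items()}
    ga = {c: s.replace("G", "A") for c, s in genome.sequences.items()}
    return (
        Genome(ct, lambda_name=genome.lambda_name),
        Genome(ga, lambda_name=genome.lambda_name),
    )


@dataclass
class AlignmentRecord:
    """A placed read, expressed along Watson coordinates.

    ``strand`` is the bisulfite strand whose cytosines the read reports
    ('+' = Watson, '-' = Crick).  ``watson_seq`` is the original
    (unconverted) read sequence oriented along Watson, so methylation
    counting and mismatch restoration read straight off the reference.
    """

    read_id: str
    richness: str
    chrom: str
    pos: int
    strand: str
    conversion_used: str  # CT | GA: conversion of the strand aligned against
    mapq: int
    cigar: str
    n_hits: int
    mismatches_restored: tuple[tuple[str, str, int], ...]
    watson_seq: str
    watson_qual: tuple[int, ...]
    span: int | None = None  # mate-pair span for PE duplicate keys

    def __len__(self) -> int:
        return len(self.watson_seq)


class BuiltinAligner:
    """Exhaustive seeded Hamming-distance aligner for small genomes.

    Uses k+1 disjoint exact seeds (pigeonhole), so every placement with
    <= max_mismatches mismatches is found whenever the read is at least
    ``index_kmer * (max_mismatches + 1)`` bp long.  Intended for
    genomes up to ~1 Mb; larger runs should go through an external
    aligner and the SAM adapter.
    """

    def __init__(self, genome: Genome, max_mismatches: int = 3, index_kmer: int = 12):
        self.genome = genome
        self.max_mismatches = max_mismatches
        self.index_kmer = index_kmer
        ref_ct, ref_ga = convert_reference(genome)
        self._texts = {
            "CT": {c: np.frombuffer(s.encode(), np.uint8) for c, s in ref_ct.sequences.items()},
            "GA": {c: np.frombuffer(s.encode(), np.uint8) for c, s in ref_ga.sequences.items()},
        }
        self._index = {conv: self._build_index(texts) for conv, texts in self._texts.items()}

    def _build_index(self, texts):
        k = self.index_kmer
        index: dict[bytes, list] = {}
        for chrom, arr in texts.items():
            b = arr.tobytes()
            for p in range(len(b) - k + 1):
                index.setdefault(b[p : p + k], []).append((chrom, p))
        return index

    def _search(self, pattern: str, conv: str):
        """All placements of pattern in the converted text, Hamming <= k."""
        k = self.index_kmer
        kmax = self.max_mismatches
        L = len(pattern)
        pat = np.frombuffer(pattern.encode(), np.uint8)
        hits = []
        if L < k:
            return hits
        n_seeds = min(kmax + 1, L // k)
        block = L // n_seeds
        index = self._index[conv]
        texts = self._texts[conv]
        seen = set()
        pbytes = pattern.encode()
        for s in range(n_seeds):
            off = s * block
            for chrom, p in index.get(pbytes[off : off + k], ()):  # noqa: E203
                start = p - off
                if start < 0 or (chrom, start) in seen:
                    continue
                seen.add((chrom, start))
                text = texts[chrom]
                if start + L > len(text):
                    continue
                d = int(np.count_nonzero(text[start : start + L] != pat))
                if d <= kmax:
                    hits.append((d, chrom, start))
        return hits

    def align_read(self, read: Read, converted: ConvertedRead | None = None) -> AlignmentRecord | None:
        conv = converted or convert_read(read)
        fwd = conv.converted_seq
        rev = revcomp(fwd)
        if read.richness == T_RICH:
            combos = [(fwd, "CT", "+", False), (rev, "GA", "-", True)]
            used = "CT"
        else:
            combos = [(rev, "CT", "+", True), (fwd, "GA", "-", False)]
            used = "GA"
        hits = []
        for pattern, text_conv, bstrand, flip in combos:
            for d, chrom, p in self._search(pattern, text_conv):
                hits.append((d, chrom, p, bstrand, flip))
        if not hits:
            return None
        hits.sort(key=lambda h: (h[0], h[1], h[2], h[3]))
        best_d = hits[0][0]
        n_hits = sum(1 for h in hits if h[0] == best_d)
        d, chrom, pos, bstrand, flip = hits[0]
        if flip:
            wseq = revcomp(read.seq)
            wqual = tuple(reversed(read.qual))
        else:
            wseq, wqual = read.seq, read.qual
        ref = self.genome[chrom][pos : pos + len(wseq)]
        mism = tuple(
            (rb, fb, pos + i)
            for i, (rb, fb) in enumerate(zip(wseq, ref))
            if rb != fb
        )
        return AlignmentRecord(
            read_id=read.id,
            richness=read.richness,
            chrom=chrom,
            pos=pos,
            strand=bstrand,
            conversion_used=used,
            mapq=0 if n_hits > 1 else 40,
            cigar=f"{len(wseq)}M",
            n_hits=n_hits,
            mismatches_restored=mism,
            watson_seq=wseq,
            watson_qual=wqual,
        )


def align(
    reads: Iterable[Read],
    genome: Genome | None = None,
    aligner: BuiltinAligner | None = None,
    max_mismatches: int = 3,
) -> Iterator[AlignmentRecord]:
    """Align reads with the built-in aligner (or a prebuilt one)."""
    if aligner is None:
        if genome is None:
            raise ValueError("provide a genome or a prebuilt aligner")
        aligner = BuiltinAligner(genome, max_mismatches=max_mismatches)
    for read in reads:
        rec = aligner.align_read(read)
        if rec is not None:
            yield rec


# ---------------------------------------------------------------------------
# the four discard rules
# ---------------------------------------------------------------------------

def _rule3_offences(rec: AlignmentRecord) -> int:
    """Unconvertible bases: read C over ref T (+) / read G over ref A (-)."""
    if rec.strand == "+":
        return sum(1 for rb, fb, _ in rec.mismatches_restored if rb == "C" and fb == "T")
    return sum(1 for rb, fb, _ in rec.mismatches_restored if rb == "G" and fb == "A")


def filter_alignments(
    records: Iterable[AlignmentRecord],
    dedup: bool = False,
    max_ct_mismatch: int = 0,
) -> tuple[list[AlignmentRecord], dict[str, int]]:
    """Apply the post-alignment discard rules.

    1. multi-hit reads (n_hits > 1);
    2. wrong-strand hits for a strand-specific library (a T-rich read
       must align against a C->T-converted strand, an A-rich read
       against a G->A-converted strand);
    3. reads with more than ``max_ct_mismatch`` positions retaining C
       over a reference T (A-rich mirror: G over A);
    4. optional PCR-duplicate removal keyed on (chrom, pos, strand)
       (plus mate span when present); the record with the highest
       summed quality wins, ties broken by read id.
    """
    counts = {"multi_hit": 0, "wrong_strand": 0, "unconverted_c": 0, "duplicate": 0}
    kept: list[AlignmentRecord] = []
    for rec in records:
        if rec.n_hits > 1:
            counts["multi_hit"] += 1
            continue
        valid = (rec.richness == T_RICH and rec.conversion_used == "CT") or (
            rec.richness == A_RICH and rec.conversion_used == "GA"
        )
        if not valid:
            counts["wrong_strand"] += 1
            continue
        if _rule3_offences(rec) > max_ct_mismatch:
            counts["unconverted_c"] += 1
            continue
        kept.append(rec)
    if dedup:
        best: dict[tuple, AlignmentRecord] = {}
        for rec in kept:
            key = (rec.chrom, rec.pos, rec.strand, rec.span)
            prev = best.get(key)
            if prev is None:
                best[key] = rec
            else:
                counts["duplicate"] += 1
                a = (sum(rec.watson_qual), rec.read_id)
                b = (sum(prev.watson_qual), prev.read_id)
                # highest summed quality wins; ties to lexicographically
                # smaller read id -> order-independent
                if (a[0], ) > (b[0], ) or (a[0] == b[0] and a[1] < b[1]):
                    best[key] = rec
        kept = sorted(best.values(), key=lambda r: (r.chrom, r.pos, r.strand, r.read_id))
    return kept, counts


class NonconversionRate(NamedTuple):
    rate: float
    n_unconverted: int  # read C over lambda reference C
    n_total: int        # read C + read T over lambda reference C


def nonconversion_rate(records: Iterable[AlignmentRecord], genome: Genome) -> NonconversionRate:
    """Bisulfite non-conversion rate from the unmethylated lambda control.

    p-hat = (#read C at lambda reference-C positions) /
            (#read C + #read T at lambda reference-C positions),
    computed strand-aware.  Raises if the control is absent or
    uncovered, in which case p must be supplied by the user.
    """
    lam = genome.lambda_name
    if lam is None:
        raise ValueError(
            "no lambda control chromosome in the reference; "
            "supply the error probability p manually"
        )
    from .mcall import methylation_counts

    lam_records = [r for r in records if r.chrom == lam]
    arrays = methylation_counts(lam_records, genome, chroms=[lam])
    m_p, n_p, m_m, n_m = arrays[lam]
    n_unconv = int(m_p.sum() + m_m.sum())
    n_total = int(n_p.sum() + n_m.sum())
    if n_total == 0:
        raise ValueError(
            "lambda control has no informative coverage; "
            "supply the error probability p manually"
        )
    return NonconversionRate(n_unconv / n_total, n_unconv, n_total)


# ---------------------------------------------------------------------------
# SAM adapter
# ---------------------------------------------------------------------------

def write_sam(records: Iterable[AlignmentRecord], genome: Genome, path: str) -> int:
    """Write records as SAM with XR/XC/XH/XM audit tags."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [{"SN": c, "LN": genome.chrom_length(c)} for c in genome.chroms()],
    }
    n = 0
    with pysam.AlignmentFile(path, "w", header=header) as fh:
        for rec in records:
            a = pysam.AlignedSegment(fh.header)
            a.query_name = rec.read_id
            a.query_sequence = rec.watson_seq
            a.query_qualities = pysam.qualitystring_to_array(
                "".join(chr(q + 33) for q in rec.watson_qual)
            )
            a.flag = 16 if rec.strand == "-" else 0
            a.reference_name = rec.chrom
            a.reference_start = rec.pos
            a.mapping_quality = rec.mapq
            a.cigarstring = rec.cigar
            a.set_tag("XR", rec.richness)
            a.set_tag("XC", rec.conversion_used)
            a.set_tag("XH", rec.n_hits)
            a.set_tag(
                "XM",
                ",".join(f"{rb}>{fb}@{p}" for rb, fb, p in rec.mismatches_restored) or "-",
            )
            fh.write(a)
            n += 1
    return n


def read_sam(path: str, genome: Genome) -> list[AlignmentRecord]:
    """Read SAM (built-in or external aligner) back into records.

    Richness/conversion/hit-count come from the XR/XC/XH tags when
    present; mismatches are restored against the unconverted genome.
    """
    import pysam

    out = []
    with pysam.AlignmentFile(path, "r") as fh:
        for a in fh:
            if a.is_unmapped:
                continue
            strand = "-" if a.is_reverse else "+"
            wseq = a.query_sequence.upper()
            ref = genome[a.reference_name][a.reference_start : a.reference_start + len(wseq)]
            mism = tuple(
                (rb, fb, a.reference_start + i)
                for i, (rb, fb) in enumerate(zip(wseq, ref))
                if rb != fb
            )
            richness = a.get_tag("XR") if a.has_tag("XR") else T_RICH
            conv = a.get_tag("XC") if a.has_tag("XC") else ("CT" if richness == T_RICH else "GA")
            n_hits = int(a.get_tag("XH")) if a.has_tag("XH") else 1
            out.append(
                AlignmentRecord(
                    read_id=a.query_name,
                    richness=richness,
                    chrom=a.reference_name,
                    pos=a.reference_start,
                    strand=strand,
                    conversion_used=conv,
                    mapq=a.mapping_quality,
                    cigar=a.cigarstring or f"{len(wseq)}M",
                    n_hits=n_hits,
                    mismatches_restored=mism,
                    watson_seq=wseq,
                    watson_qual=tuple(a.query_qualities or [40] * len(wseq)),
                )
            )
    return out
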