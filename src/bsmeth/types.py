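"""Shared domain types and coordinate conventions.

Conventions used throughout the package:

* Coordinates are 0-based, half-open internally.  Emitted tables are
  1-based inclusive and the matching readers convert back, so a
  write/read round trip is the identity.
* A cytosine on the minus strand is represented by the position of the
  G on the Watson (plus) sequence with strand ``"-"``; its sequence
  context is read on the reverse complement.
* Reads from a directional (strand-specific) bisulfite library are
  classified by richness: mate 1 derives from the converted strand and
  is C-depleted ("T-rich"); mate 2 is its complement ("A-rich").
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

VALID_BASES = frozenset("ACGTN")
T_RICH = "T-rich"
A_RICH = "A-rich"
CONTEXTS = ("CG", "CHG", "CHH", "CN")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")
_COMP1 = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (N self-complements)."""
    return seq.translate(_COMPLEMENT)[::-1]


def complement(base: str) -> str:
    return _COMP1[base]


def context_of(seq: str, pos: int, strand: str) -> str:
    """Cytosine context (CG/CHG/CHH/CN) at ``pos`` on ``strand``.

    ``seq`` is the Watson sequence.  A minus-strand cytosine appears as
    G on Watson; its context is read on the reverse complement.  Flanks
    that run off the contig, or that contain N, give CN.
    """
    if strand == "+":
        b1 = seq[pos + 1] if pos + 1 < len(seq) else "N"
        b2 = seq[pos + 2] if pos + 2 < len(seq) else "N"
    elif strand == "-":
        b1 = _COMP1[seq[pos - 1]] if pos - 1 >= 0 else "N"
        b2 = _COMP1[seq[pos - 2]] if pos - 2 >= 0 else "N"
    else:
        raise ValueError(f"invalid strand {strand!r}")
    if b1 == "G":
        return "CG"
    if b1 == "N":
        return "CN"
    if b2 == "G":
        return "CHG"
    if b2 == "N":
        return "CN"
    return "CHH"


@dataclass
class Genome:
    """A reference genome: chromosome name -> uppercase DNA string.

    ``lambda_name`` optionally designates an unmethylated spike-in
    control chromosome (conventionally ``"chrLam"``) used to estimate
    the bisulfite non-conversion rate.
    """

    sequences: dict[str, str]
    lambda_name: str | None = None

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            bad = set(seq) - VALID_BASES
            if bad:
                raise ValueError(
                    f"chromosome {name!r} contains invalid characters {sorted(bad)}"
                )
        if self.lambda_name is not None and self.lambda_name not in self.sequences:
            raise ValueError(
                f"lambda control {self.lambda_name!r} is not a chromosome"
            )

    def __getitem__(self, chrom: str) -> str:
        return self.sequences[chrom]

    def __contains__(self, chrom: str) -> bool:
        return chrom in self.sequences

    def chroms(self) -> list[str]:
        return list(self.sequences)

    def chrom_length(self, chrom: str) -> int:
        return len(self.sequences[chrom])

    @property
    def total_length(self) -> int:
        return sum(len(s) for s in self.sequences.values())


@dataclass
class Read:
    """A sequencing read with per-base Phred qualities."""

    id: str
    seq: str
    qual: tuple[int, ...]
    mate: int = 0  # 0 = single-end, 1/2 = paired mates
    richness: str = T_RICH

    def __post_init__(self) -> None:
        if len(self.seq) != len(self.qual):
            raise ValueError(
                f"read {self.id!r}: sequence and quality lengths differ "
                f"({len(self.seq)} vs {len(self.qual)})"
            )
        if self.richness not in (T_RICH, A_RICH):
            raise ValueError(f"invalid richness {self.richness!r}")

    def __len__(self) -> int:
        return len(self.seq)


@dataclass(frozen=True)
class GenomicInterval:
    """A 0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int
    strand: str = "."
    label: str = ""

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def contains(self, chrom: str, pos: int) -> bool:
        return chrom == self.chrom and self.start <= pos < self.end

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GeneModel:
    """A gene model: strand-oriented exon chain on one chromosome.

    Exons are stored in ascending genomic order; orientation-dependent
    views (first/last exon, introns, promoter) honour ``strand``.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: tuple[GenomicInterval, ...]

    def __post_init__(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"gene {self.gene_id!r}: invalid strand")
        if not self.exons:
            raise ValueError(f"gene {self.gene_id!r}: no exons")
        exons = tuple(sorted(self.exons, key=lambda e: e.start))
        for a, b in zip(exons, exons[1:]):
            if a.end > b.start:
                raise ValueError(f"gene {self.gene_id!r}: overlapping exons")
        object.__setattr__(self, "exons", exons)

    @property
    def start(self) -> int:
        return self.exons[0].start

    @property
    def end(self) -> int:
        return self.exons[-1].end

    @property
    def tss(self) -> int:
        """0-based position of the transcription start site base."""
        return self.start if self.strand == "+" else self.end - 1

    @property
    def tes(self) -> int:
        """0-based position of the transcription end site base."""
        return self.end - 1 if self.strand == "+" else self.start

    def body(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.start, self.end, self.strand, self.gene_id)

    def oriented_exons(self) -> tuple[GenomicInterval, ...]:
        return self.exons if self.strand == "+" else tuple(reversed(self.exons))

    def introns(self) -> tuple[GenomicInterval, ...]:
        """Introns in ascending genomic order."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end < b.start:
                out.append(GenomicInterval(self.chrom, a.end, b.start, self.strand))
        return tuple(out)

    def oriented_introns(self) -> tuple[GenomicInterval, ...]:
        ins = self.introns()
        return ins if self.strand == "+" else tuple(reversed(ins))

    def promoter(self, flank_len: int) -> GenomicInterval | None:
        """The ``flank_len`` bp immediately 5' of the TSS (clipped at 0)."""
        if self.strand == "+":
            s, e = self.start - flank_len, self.start
        else:
            s, e = self.end, self.end + flank_len
        s = max(s, 0)
        if s >= e:
            return None
        return GenomicInterval(self.chrom, s, e, self.strand, self.gene_id)

    upstream = promoter

    def downstream(self, flank_len: int) -> GenomicInterval | None:
        """The ``flank_len`` bp immediately 3' of the TES (clipped at 0)."""
        if self.strand == "+":
            s, e = self.end, self.end + flank_len
        else:
            s, e = self.start - flank_len, self.start
        s = max(s, 0)
        if s >= e:
            return None
        return GenomicInterval(self.chrom, s, e, self.strand, self.gene_id)


@dataclass
class CytosineSite:
    """One reference cytosine with methylation evidence.

    ``m`` counts reads showing C over the reference C (methylated);
    ``n`` is the informative depth (read C + read T).  ``pos`` is the
    0-based Watson coordinate of the C (plus strand) or of the G whose
    Crick partner is the C (minus strand).
    """

    chrom: str
    pos: int
    strand: str
    context: str
    m: int
    n: int
    pvalue: float | None = None
    qvalue: float | None = None
    called: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.m <= self.n):
            raise ValueError(f"site {self.chrom}:{self.pos}: need 0 <= m <= n")
        if self.strand not in "+-":
            raise ValueError(f"site {self.chrom}:{self.pos}: invalid strand")

    @property
    def level(self) -> float | None:
        """Methylation level m/n, or None when uncovered."""
        return self.m / self.n if self.n > 0 else None

    def key(self) -> tuple[str, int, str]:
        return (self.chrom, self.pos, self.strand)
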