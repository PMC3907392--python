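"""Readers and writers for the standard formats the pipeline touches.

FASTA/FASTQ go through Biopython; tables through pandas; gene models
through gffutils (GTF/GFF3) or a BED12 reader.  All writers emit
1-based inclusive coordinates; all readers restore the internal 0-based
half-open convention, so round trips are lossless.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
from Bio import SeqIO

from .types import (
    A_RICH,
    T_RICH,
    CytosineSite,
    GeneModel,
    Genome,
    GenomicInterval,
    Read,
)

SITE_COLUMNS = [
    "chrom", "pos", "strand", "context", "m", "n",
    "level", "pvalue", "qvalue", "called",
]

# Ambiguity codes other than N are collapsed to N so the Genome
# invariant (A/C/G/T/N only) holds for arbitrary input FASTA.
_NON_ACGTN = str.maketrans({c: "N" for c in "RYSWKMBDHVU"})


def read_fasta(path: str | Path, lambda_name: str | None = None) -> Genome:
    """Load a (multi-)FASTA into a :class:`Genome`, uppercased, N preserved."""
    sequences: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in sequences:
            raise ValueError(f"duplicate chromosome name {rec.id!r} in {path}")
        sequences[rec.id] = str(rec.seq).upper().translate(_NON_ACGTN)
    if not sequences:
        raise ValueError(f"no FASTA records in {path}")
    if lambda_name is None and "chrLam" in sequences:
        lambda_name = "chrLam"
    return Genome(sequences, lambda_name=lambda_name)


def write_fasta(genome: Genome, path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fastq(path: str | Path, mate: int = 0, richness: str | None = None) -> Iterator[Read]:
    """Stream Phred+33 FASTQ as :class:`Read` objects.

    Richness defaults by mate: single-end and mate 1 are T-rich, mate 2
    is A-rich (directional library convention).
    """
    if richness is None:
        richness = A_RICH if mate == 2 else T_RICH
    for rec in SeqIO.parse(str(path), "fastq"):
        yield Read(
            id=rec.id,
            seq=str(rec.seq).upper(),
            qual=tuple(rec.letter_annotations["phred_quality"]),
            mate=mate,
            richness=richness,
        )


def write_fastq(reads: Iterable[Read], path: str | Path) -> int:
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.qual)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")
            n += 1
    return n


# ---------------------------------------------------------------------------
# per-cytosine site table (the package's canonical output schema)
# ---------------------------------------------------------------------------

def write_site_table(sites: Iterable[CytosineSite], path: str | Path) -> None:
    """Write the canonical TSV site table (positions 1-based).

    Input must be sorted by (chrom, pos); level/pvalue/qvalue are NA
    when undefined.  Round-trips losslessly through
    :func:`read_site_table`.
    """
    sites = list(sites)
    keys = [(s.chrom, s.pos) for s in sites]
    if keys != sorted(keys):
        raise ValueError("site table must be sorted by (chrom, pos)")
    rows = []
    for s in sites:
        rows.append(
            (
                s.chrom, s.pos + 1, s.strand, s.context, s.m, s.n,
                s.level if s.n > 0 else None,
                s.pvalue, s.qvalue, int(s.called),
            )
        )
    df = pd.DataFrame(rows, columns=SITE_COLUMNS)
    df.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_site_table(path: str | Path) -> list[CytosineSite]:
    df = pd.read_csv(path, sep="\t", na_values=["NA"], keep_default_na=False)
    out = []
    for row in df.itertuples(index=False):
        out.append(
            CytosineSite(
                chrom=str(row.chrom),
                pos=int(row.pos) - 1,
                strand=row.strand,
                context=row.context,
                m=int(row.m),
                n=int(row.n),
                pvalue=None if _isna(row.pvalue) else float(row.pvalue),
                qvalue=None if _isna(row.qvalue) else float(row.qvalue),
                called=bool(int(row.called)),
            )
        )
    return out


def _isna(x) -> bool:
    return x is None or (isinstance(x, float) and math.isnan(x))


def sites_to_frame(sites: Iterable[CytosineSite]) -> pd.DataFrame:
    """Tabular (0-based) view of a site list for vectorized analyses."""
    return pd.DataFrame(
        {
            "chrom": [s.chrom for s in sites],
            "pos": [s.pos for s in sites],
            "strand": [s.strand for s in sites],
            "context": [s.context for s in sites],
            "m": [s.m for s in sites],
            "n": [s.n for s in sites],
            "called": [s.called for s in sites],
        }
    )


# ---------------------------------------------------------------------------
# intervals and gene models
# ---------------------------------------------------------------------------

def read_bed(path: str | Path) -> list[GenomicInterval]:
    """Read BED3-BED6 into intervals (BED is already 0-based half-open)."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            out.append(
                GenomicInterval(
                    chrom=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    strand=f[5] if len(f) > 5 else ".",
                    label=f[3] if len(f) > 3 else "",
                )
            )
    return out


def write_bed(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(
                f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.label or '.'}\t0\t{iv.strand}\n"
            )


def read_gene_models(path: str | Path) -> list[GeneModel]:
    """Load gene models from GTF/GFF3 (exons grouped by gene_id) or BED12."""
    path = Path(path)
    if path.suffix.lower() == ".bed":
        return _read_bed12(path)
    return _read_gxf(path)


def _read_gxf(path: Path) -> list[GeneModel]:
    import gffutils

    db = gffutils.create_db(
        str(path),
        ":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )
    grouped: dict[str, list] = {}
    meta: dict[str, tuple[str, str]] = {}
    for feat in db.features_of_type("exon"):
        gid = feat.attributes.get("gene_id", feat.attributes.get("Parent", ["?"]))[0]
        grouped.setdefault(gid, []).append(feat)
        meta[gid] = (feat.seqid, feat.strand)
    genes = []
    for gid, feats in grouped.items():
        chrom, strand = meta[gid]
        exons = _merge_exons(
            [(f.start - 1, f.end) for f in feats], chrom, strand
        )
        genes.append(GeneModel(gid, chrom, strand, exons))
    genes.sort(key=lambda g: (g.chrom, g.start))
    return genes


def _read_bed12(path: Path) -> list[GeneModel]:
    genes = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            chrom, start, name, strand = f[0], int(f[1]), f[3], f[5]
            sizes = [int(x) for x in f[10].rstrip(",").split(",")]
            offs = [int(x) for x in f[11].rstrip(",").split(",")]
            exons = tuple(
                GenomicInterval(chrom, start + o, start + o + s, strand)
                for o, s in zip(offs, sizes)
            )
            genes.append(GeneModel(name, chrom, strand, exons))
    return genes


def _merge_exons(spans, chrom, strand) -> tuple[GenomicInterval, ...]:
    """Union overlapping exon spans (multiple transcripts per gene)."""
    spans = sorted(spans)
    merged: list[list[int]] = []
    for s, e in spans:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return tuple(GenomicInterval(chrom, s, e, strand) for s, e in merged)


def write_gtf(genes: Iterable[GeneModel], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            for ex in g.exons:
                fh.write(
                    f"{g.chrom}\tbsmeth\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f'{g.strand}\t.\tgene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1";\n'
                )


def read_two_column_table(path: str | Path, value_type=float) -> dict:
    """Read a 2-column TSV (gene -> value); tolerates an optional header."""
    out: dict = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, val = line.split("\t")[:2]
            if i == 0:
                try:
                    value_type(val)
                except ValueError:
                    continue  # header line
            out[key] = value_type(val)
    return out


def read_expression_table(path: str | Path) -> dict[str, float]:
    return read_two_column_table(path, float)


def read_class_map(path: str | Path) -> dict[str, str]:
    return read_two_column_table(path, str)
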