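"""Methylation annotation analyses.

Covers sequence-context classification, the genic/repeat distribution
of methylcytosines, methylated CpG islands and their regional
statistics, gene methylation classes with functional-class counts, the
TE methylation-level distribution, local sequence-preference matrices,
and expression-stratified methylation metaplots (5 expression groups x
20 positional bins per region).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .mcall import region_level
from .types import CytosineSite, GeneModel, Genome, GenomicInterval, context_of

GENIC_LABELS = (
    "upstream", "first exon", "first intron", "internal exons",
    "internal introns", "last exon", "downstream",
)
ISLAND_LABELS = ("promoter", "gene body", "downstream", "intergenic")

_C, _G = ord("C"), ord("G")


def classify_context(genome: Genome, chrom: str, pos: int, strand: str) -> str:
    """CG/CHG/CHH/CN context of the cytosine at (chrom, pos, strand)."""
    seq = genome[chrom]
    base = seq[pos]
    sense = "C" if strand == "+" else "G"
    if base != sense:
        raise ValueError(
            f"{chrom}:{pos}({strand}) is {base}, not a cytosine on that strand"
        )
    return context_of(seq, pos, strand)


# ---------------------------------------------------------------------------
# site indexing (shared by the region analyses)
# ---------------------------------------------------------------------------

class SiteIndex:
    """Per-(chrom, context) sorted position arrays with m/n prefix sums."""

    def __init__(self, sites, contexts=None):
        buckets: dict = {}
        for s in sites:
            if contexts is not None and s.context not in contexts:
                continue
            buckets.setdefault((s.chrom, s.context), []).append((s.pos, s.m, s.n))
        self._idx = {}
        for key, rows in buckets.items():
            rows.sort()
            pos = np.array([r[0] for r in rows])
            m = np.concatenate([[0], np.cumsum([r[1] for r in rows])])
            n = np.concatenate([[0], np.cumsum([r[2] for r in rows])])
            self._idx[key] = (pos, m, n)

    def counts(self, chrom: str, start: int, end: int, contexts) -> tuple[int, int]:
        """(sum m, sum n) over sites of the given contexts in [start, end)."""
        m_tot = n_tot = 0
        for ctx in contexts:
            entry = self._idx.get((chrom, ctx))
            if entry is None:
                continue
            pos, m, n = entry
            i = np.searchsorted(pos, start, "left")
            j = np.searchsorted(pos, end, "left")
            m_tot += int(m[j] - m[i])
            n_tot += int(n[j] - n[i])
        return m_tot, n_tot

    def level(self, chrom: str, start: int, end: int, contexts) -> float:
        m, n = self.counts(chrom, start, end, contexts)
        return m / n if n > 0 else float("nan")


# ---------------------------------------------------------------------------
# genic / repeat distribution of methylcytosines
# ---------------------------------------------------------------------------

@dataclass
class RegionProfileResult:
    genic: pd.DataFrame      # region x context: n_sites, mean_level
    repeats: pd.DataFrame    # context: n_sites, mean_level
    n_unassigned: int        # called mCs outside all genes/flanks


def _genic_label(gene: GeneModel, pos: int) -> str | None:
    """Label of a position inside the gene body, else None."""
    if not (gene.start <= pos < gene.end):
        return None
    exons = gene.oriented_exons()
    for i, ex in enumerate(exons):
        if ex.start <= pos < ex.end:
            if i == 0:
                return "first exon"
            if i == len(exons) - 1:
                return "last exon"
            return "internal exons"
    introns = gene.oriented_introns()
    for i, iv in enumerate(introns):
        if iv.start <= pos < iv.end:
            return "first intron" if i == 0 else "internal introns"
    return None


def genic_region_profile(
    sites,
    genes,
    flank_len: int = 2000,
    repeats=None,
) -> RegionProfileResult:
    """Distribution of called methylcytosines over genic regions.

    Each called mC receives at most one label.  Gene-body labels
    (exon/intron, strand-oriented) take precedence over upstream/
    downstream flanks; the first matching gene (genomic order) wins.
    Sites in supplied repeat intervals are tallied separately (a site
    may be both genic and repeat-associated).
    """
    genes = sorted(genes, key=lambda g: (g.chrom, g.start))
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    tally: dict[tuple[str, str], list] = {}
    n_unassigned = 0
    called = [s for s in sites if s.called]
    for s in called:
        label = None
        cands = by_chrom.get(s.chrom, [])
        for g in cands:
            label = _genic_label(g, s.pos)
            if label:
                break
        if label is None:
            for g in cands:
                up = g.promoter(flank_len)
                if up and up.start <= s.pos < up.end:
                    label = "upstream"
                    break
                down = g.downstream(flank_len)
                if down and down.start <= s.pos < down.end:
                    label = "downstream"
                    break
        if label is None:
            n_unassigned += 1
            continue
        tally.setdefault((label, s.context), []).append(s.level)
    rows = [
        {
            "region": lab,
            "context": ctx,
            "n_sites": len(levels),
            "mean_level": float(np.mean(levels)),
        }
        for (lab, ctx), levels in sorted(
            tally.items(), key=lambda kv: (GENIC_LABELS.index(kv[0][0]), kv[0][1])
        )
    ]
    genic = pd.DataFrame(rows, columns=["region", "context", "n_sites", "mean_level"])

    rep_rows = []
    if repeats:
        rep_tally: dict[str, list] = {}
        for s in called:
            if any(iv.contains(s.chrom, s.pos) for iv in repeats):
                rep_tally.setdefault(s.context, []).append(s.level)
        rep_rows = [
            {"context": ctx, "n_sites": len(v), "mean_level": float(np.mean(v))}
            for ctx, v in sorted(rep_tally.items())
        ]
    rep_df = pd.DataFrame(rep_rows, columns=["context", "n_sites", "mean_level"])
    return RegionProfileResult(genic, rep_df, n_unassigned)


# ---------------------------------------------------------------------------
# methylated CpG islands
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class MethylatedIsland:
    """A CpG island whose CG methylation level exceeds the threshold."""

    interval: GenomicInterval
    gc_frac: float
    obs_exp_cpg: float
    level: float


def _island_stats(cum_gc, cum_c, cum_g, cum_cpg, cum_m, cum_n, a: int, b: int):
    L = b - a
    gc = (cum_gc[b] - cum_gc[a]) / L
    n_c = cum_c[b] - cum_c[a]
    n_g = cum_g[b] - cum_g[a]
    n_cpg = cum_cpg[b] - cum_cpg[a]
    oe = n_cpg * L / (n_c * n_g) if n_c > 0 and n_g > 0 else 0.0
    n_cov = cum_n[b] - cum_n[a]
    level = (cum_m[b] - cum_m[a]) / n_cov if n_cov > 0 else None
    return gc, oe, level


def find_methylated_islands(
    genome: Genome,
    sites,
    min_len: int = 200,
    gc_min: float = 0.5,
    oe_min: float = 0.6,
    level_min: float = 0.7,
) -> list[MethylatedIsland]:
    """Methylated CpG islands: >= min_len bp, GC > gc_min, CpG
    observed/expected > oe_min and CG methylation level > level_min.

    Scans min_len-bp windows stepping 1 bp; overlapping passing windows
    are merged and the merged interval must itself satisfy all four
    criteria (windows passing individually but diluting on merge are
    dropped).  The observed/expected ratio follows Gardiner-Garden:
    (N_CpG * L) / (N_C * N_G); the level is the coverage-weighted CG
    level over both strands.
    """
    idx = SiteIndex(sites, contexts={"CG"})
    islands: list[MethylatedIsland] = []
    for chrom in genome.chroms():
        seq = genome[chrom]
        L = len(seq)
        if L < min_len:
            continue
        arr = np.frombuffer(seq.encode(), np.uint8)
        is_c = arr == _C
        is_g = arr == _G
        cpg = np.zeros(L, bool)
        cpg[:-1] = is_c[:-1] & is_g[1:]
        m_arr = np.zeros(L)
        n_arr = np.zeros(L)
        entry = idx._idx.get((chrom, "CG"))
        if entry is not None:
            pos, m_cum, n_cum = entry
            m_arr[pos] = np.diff(m_cum)
            n_arr[pos] = np.diff(n_cum)
        cum = lambda x: np.concatenate([[0], np.cumsum(x)])
        cum_gc = cum(is_c | is_g)
        cum_c = cum(is_c)
        cum_g = cum(is_g)
        cum_cpg = cum(cpg)
        cum_m = cum(m_arr)
        cum_n = cum(n_arr)

        starts = np.arange(0, L - min_len + 1)
        ends = starts + min_len
        gc_w = (cum_gc[ends] - cum_gc[starts]) / min_len
        n_c = cum_c[ends] - cum_c[starts]
        n_g = cum_g[ends] - cum_g[starts]
        with np.errstate(divide="ignore", invalid="ignore"):
            oe_w = np.where(
                (n_c > 0) & (n_g > 0),
                (cum_cpg[ends] - cum_cpg[starts]) * min_len / (n_c * n_g),
                0.0,
            )
        n_w = cum_n[ends] - cum_n[starts]
        with np.errstate(divide="ignore", invalid="ignore"):
            lvl_w = np.where(n_w > 0, (cum_m[ends] - cum_m[starts]) / np.maximum(n_w, 1), 0.0)
        passing = (gc_w > gc_min) & (oe_w > oe_min) & (n_w > 0) & (lvl_w > level_min)
        # merge overlapping passing windows, then re-check the union
        idxs = np.flatnonzero(passing)
        i = 0
        while i < len(idxs):
            a = int(starts[idxs[i]])
            b = a + min_len
            j = i + 1
            while j < len(idxs) and starts[idxs[j]] <= b:
                b = int(starts[idxs[j]]) + min_len
                j += 1
            gc, oe, level = _island_stats(cum_gc, cum_c, cum_g, cum_cpg, cum_m, cum_n, a, b)
            if (
                b - a >= min_len
                and gc > gc_min
                and oe > oe_min
                and level is not None
                and level > level_min
            ):
                islands.append(
                    MethylatedIsland(
                        GenomicInterval(chrom, a, b, ".", "island"),
                        float(gc), float(oe), float(level),
                    )
                )
            i = j
    return islands


def island_region_stats(
    islands, genes, promoter_len: int = 2000
) -> pd.DataFrame:
    """Counts/percentages of methylated islands per functional region.

    Each island is assigned one label by its midpoint with precedence
    promoter > gene body > downstream > intergenic.
    """
    counts = {lab: 0 for lab in ISLAND_LABELS}
    genes = list(genes)
    for isl in islands:
        mid = isl.interval.midpoint
        chrom = isl.interval.chrom
        label = "intergenic"
        for want in ("promoter", "gene body", "downstream"):
            hit = False
            for g in genes:
                if g.chrom != chrom:
                    continue
                if want == "promoter":
                    iv = g.promoter(promoter_len)
                    hit = iv is not None and iv.start <= mid < iv.end
                elif want == "gene body":
                    hit = g.start <= mid < g.end
                else:
                    iv = g.downstream(promoter_len)
                    hit = iv is not None and iv.start <= mid < iv.end
                if hit:
                    break
            if hit:
                label = want
                break
        counts[label] += 1
    total = sum(counts.values())
    return pd.DataFrame(
        {
            "region": list(ISLAND_LABELS),
            "n_islands": [counts[lab] for lab in ISLAND_LABELS],
            "percent": [
                100.0 * counts[lab] / total if total else 0.0 for lab in ISLAND_LABELS
            ],
        }
    )


# ---------------------------------------------------------------------------
# gene methylation classes
# ---------------------------------------------------------------------------

@dataclass
class GeneClassResult:
    high_genes: list[str]
    low_genes: list[str]
    histogram: pd.DataFrame     # class, n_high, n_low
    uncovered_genes: list[str]  # no informative CG coverage
    gene_levels: dict[str, float]


def gene_methylation_classes(
    genes,
    sites,
    class_map: dict[str, str] | None = None,
    high_threshold: float = 0.7,
    low_threshold: float = 0.3,
) -> GeneClassResult:
    """High (>70%) / low (<30%) CG-methylation gene sets with per-class counts.

    The gene level is the coverage-weighted CG level over the gene
    body; genes without covered CG sites are excluded and reported.
    ``class_map`` is a user-supplied gene -> functional-class table.
    """
    idx = SiteIndex(sites, contexts={"CG"})
    high, low, uncovered = [], [], []
    levels: dict[str, float] = {}
    for g in genes:
        lvl = idx.level(g.chrom, g.start, g.end, ["CG"])
        if np.isnan(lvl):
            uncovered.append(g.gene_id)
            continue
        levels[g.gene_id] = lvl
        if lvl > high_threshold:
            high.append(g.gene_id)
        elif lvl < low_threshold:
            low.append(g.gene_id)
    rows = []
    if class_map:
        classes = sorted(set(class_map.values()))
        for cls in classes:
            rows.append(
                {
                    "class": cls,
                    "n_high": sum(1 for gid in high if class_map.get(gid) == cls),
                    "n_low": sum(1 for gid in low if class_map.get(gid) == cls),
                }
            )
    hist = pd.DataFrame(rows, columns=["class", "n_high", "n_low"])
    return GeneClassResult(high, low, hist, uncovered, levels)


# ---------------------------------------------------------------------------
# TE methylation distribution
# ---------------------------------------------------------------------------

@dataclass
class TeProfile:
    counts: np.ndarray
    bin_edges: np.ndarray
    levels: dict[str, float]  # per-TE weighted level
    n_uncovered: int


def te_methylation_profile(sites, te_intervals, n_bins: int = 20) -> TeProfile:
    """Histogram of per-TE coverage-weighted methylation levels (all contexts)."""
    idx = SiteIndex(sites)
    contexts = ["CG", "CHG", "CHH", "CN"]
    levels: dict[str, float] = {}
    n_uncov = 0
    for i, te in enumerate(te_intervals):
        lvl = idx.level(te.chrom, te.start, te.end, contexts)
        if np.isnan(lvl):
            n_uncov += 1
        else:
            levels[te.label or f"te{i}"] = lvl
    counts, edges = np.histogram(list(levels.values()), bins=n_bins, range=(0.0, 1.0))
    return TeProfile(counts, edges, levels, n_uncov)


# ---------------------------------------------------------------------------
# sequence preference around methylcytosines
# ---------------------------------------------------------------------------

@dataclass
class PreferenceMatrix:
    """Base x position counts of the -k..+k flank around called mCs."""

    context: str  # mCG | mCHG | mCHH
    k: int
    counts: pd.DataFrame  # rows A/C/G/T, columns -k..+k
    n_sites: int
    n_skipped: int  # too close to a contig edge, or N in the flank


def context_preference_matrix(sites, genome: Genome, k: int = 4) -> dict[str, PreferenceMatrix]:
    """Strand-oriented flanking-base counts per methylation context.

    For each called mC the -k..+k genomic window (read 5'->3' on the
    site's strand) is tallied; flanks crossing a contig edge or
    containing N are skipped and counted.
    """
    from .types import revcomp

    out = {}
    for ctx, name in (("CG", "mCG"), ("CHG", "mCHG"), ("CHH", "mCHH")):
        cols = list(range(-k, k + 1))
        counts = pd.DataFrame(0, index=list("ACGT"), columns=cols)
        n_sites = n_skipped = 0
        for s in sites:
            if not s.called or s.context != ctx:
                continue
            seq = genome[s.chrom]
            if s.pos - k < 0 or s.pos + k >= len(seq):
                n_skipped += 1
                continue
            flank = seq[s.pos - k : s.pos + k + 1]
            if s.strand == "-":
                flank = revcomp(flank)
            if "N" in flank:
                n_skipped += 1
                continue
            for offset, base in zip(cols, flank):
                counts.loc[base, offset] += 1
            n_sites += 1
        out[name] = PreferenceMatrix(name, k, counts, n_sites, n_skipped)
    return out


# ---------------------------------------------------------------------------
# expression / methylation metaplots
# ---------------------------------------------------------------------------

def expression_methylation_curves(
    genes,
    expression: dict[str, float],
    sites,
    promoter_len: int = 2000,
    n_groups: int = 5,
    n_bins: int = 20,
    contexts=("CG", "CHG", "CHH"),
) -> dict[tuple[str, str], pd.DataFrame]:
    """Average methylation across genes stratified by expression.

    Genes with expression values are sorted ascending and split into
    ``n_groups`` equal groups (remainder to the last); group 1 has the
    lowest expression.  Each promoter and gene body is divided into
    ``n_bins`` equal-width strand-oriented bins; the bin level is
    sum(m)/sum(n), and the group curve averages gene bins with
    coverage.  Returns {(region, context): DataFrame n_groups x n_bins}.
    """
    genes = [g for g in genes if g.gene_id in expression]
    if len(genes) < n_groups:
        raise ValueError(
            f"need at least {n_groups} genes with expression values, got {len(genes)}"
        )
    genes.sort(key=lambda g: (expression[g.gene_id], g.gene_id))
    size = len(genes) // n_groups
    groups = [genes[i * size : (i + 1) * size] for i in range(n_groups - 1)]
    groups.append(genes[(n_groups - 1) * size :])

    idx = SiteIndex(sites)
    out: dict[tuple[str, str], pd.DataFrame] = {}
    for region in ("promoter", "gene_body"):
        for ctx in contexts:
            mat = np.full((n_groups, n_bins), np.nan)
            for gi, grp in enumerate(groups):
                bins = np.full((len(grp), n_bins), np.nan)
                for gj, g in enumerate(grp):
                    iv = g.promoter(promoter_len) if region == "promoter" else g.body()
                    if iv is None:
                        continue
                    span = iv.end - iv.start
                    for b in range(n_bins):
                        lo = iv.start + round(b * span / n_bins)
                        hi = iv.start + round((b + 1) * span / n_bins)
                        if hi <= lo:
                            continue
                        # orient bin 0 at the gene-proximal 5' side
                        col = b if g.strand == "+" else n_bins - 1 - b
                        lvl = idx.level(g.chrom, lo, hi, [ctx])
                        bins[gj, col] = lvl
                with np.errstate(invalid="ignore"):
                    have = ~np.all(np.isnan(bins), axis=0)
                    mat[gi, have] = np.nanmean(bins[:, have], axis=0)
            df = pd.DataFrame(
                mat,
                index=[f"group{i + 1}" for i in range(n_groups)],
                columns=[f"bin{j + 1}" for j in range(n_bins)],
            )
            out[(region, ctx)] = df
    return out
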