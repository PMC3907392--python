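"""Differentially methylated region (DMR) detection.

Two window schemes over the cytosines shared (covered in both samples)
between two per-site methylation tables:

* **static**: windows of fixed genomic length anchored on successive
  methylcytosines (one mC per step); runs of at least ``n_adjacent``
  consecutive significant, same-sign windows merge into one DMR.
* **dynamic**: seed windows of a fixed number of sites that, once
  significant, extend site-by-site 3'-ward while the re-test stays
  significant, then likewise 5'-ward from the original window.

A window is tested only when both samples have sufficient coverage and
the weighted levels differ by at least ``delta_min`` (default 0.2);
significance uses the paired Wilcoxon signed-rank test over per-site
levels at shared positions (exact null for n <= 25, midranks for ties;
normal approximation above), optionally under BH FDR correction.
Context classes: CN = all cytosines, CG, CH = CHG + CHH (static only
for CH).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import stats

from .types import CytosineSite, GeneModel, GenomicInterval

CONTEXT_CLASSES = {
    "CN": {"CG", "CHG", "CHH", "CN"},
    "CG": {"CG"},
    "CH": {"CHG", "CHH"},
}


@dataclass
class WindowStat:
    """One tested window over shared covered sites."""

    interval: GenomicInterval
    context_class: str
    level_a: float
    level_b: float
    delta: float
    pvalue: float
    n_shared: int


@dataclass
class Dmr:
    """A merged differentially methylated region."""

    interval: GenomicInterval  # first to last contributing mC
    context_class: str
    mean_delta: float
    min_pvalue: float
    qvalue: float | None
    n_windows: int
    linked_genes: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# Wilcoxon signed-rank test
# ---------------------------------------------------------------------------

def _exact_signed_rank_p(d: np.ndarray) -> float:
    """Two-sided exact signed-rank p over all 2^n sign assignments.

    Ties get midranks; the null distribution of W+ (sum of ranks of
    positive differences) is built by convolution over doubled ranks,
    which enumerates all sign assignments exactly.
    """
    n = len(d)
    ranks = stats.rankdata(np.abs(d))
    r2 = np.rint(2 * ranks).astype(int)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        new = dist.copy()
        new[r:] += dist[: total + 1 - r]
        dist = new
    w = int(r2[d > 0].sum())
    denom = 2.0 ** n
    p_ge = dist[w:].sum() / denom
    p_le = dist[: w + 1].sum() / denom
    return min(1.0, 2.0 * min(p_ge, p_le))


def wilcoxon_window_test(levels_a, levels_b, method: str = "signed-rank") -> float:
    """Two-sided Wilcoxon p-value comparing paired per-site levels.

    Zero differences are dropped (Wilcoxon convention); if nothing
    remains the window is non-informative and p = 1.  The paired
    signed-rank test is the default; ``method="rank-sum"`` switches to
    the unpaired Mann-Whitney variant.
    """
    a = np.asarray(levels_a, float)
    b = np.asarray(levels_b, float)
    if method == "rank-sum":
        if len(a) == 0 or len(b) == 0:
            return 1.0
        return float(stats.mannwhitneyu(a, b, alternative="two-sided").pvalue)
    if len(a) != len(b):
        raise ValueError("paired test needs equal-length level vectors")
    d = a - b
    d = d[d != 0]
    if len(d) == 0:
        return 1.0
    if len(d) <= 25:
        return _exact_signed_rank_p(d)
    res = stats.wilcoxon(d, correction=False, method="approx")
    return float(res.pvalue)


# ---------------------------------------------------------------------------
# shared-site tables
# ---------------------------------------------------------------------------

def _shared_table(sites_a, sites_b, contexts):
    """Per-chromosome arrays of sites covered in both samples."""
    da = {s.key(): s for s in sites_a if s.n > 0 and s.context in contexts}
    db = {s.key(): s for s in sites_b if s.n > 0 and s.context in contexts}
    shared = sorted(set(da) & set(db))
    by_chrom: dict[str, dict] = {}
    for key in shared:
        chrom = key[0]
        by_chrom.setdefault(chrom, []).append(key)
    out = {}
    for chrom, keys in by_chrom.items():
        keys.sort(key=lambda k: (k[1], k[2]))
        sa = [da[k] for k in keys]
        sb = [db[k] for k in keys]
        out[chrom] = {
            "pos": np.array([k[1] for k in keys]),
            "ma": np.array([s.m for s in sa], float),
            "na": np.array([s.n for s in sa], float),
            "mb": np.array([s.m for s in sb], float),
            "nb": np.array([s.n for s in sb], float),
        }
    return out


def _window_stat(tab, idx, min_coverage, min_covered_frac):
    """Delta/levels over covered sites of a window; None if coverage fails."""
    na, nb = tab["na"][idx], tab["nb"][idx]
    covered = (na >= min_coverage) & (nb >= min_coverage)
    if len(idx) == 0 or covered.mean() < min_covered_frac or covered.sum() == 0:
        return None
    sub = idx[covered]
    ma, na = tab["ma"][sub], tab["na"][sub]
    mb, nb = tab["mb"][sub], tab["nb"][sub]
    level_a = ma.sum() / na.sum()
    level_b = mb.sum() / nb.sum()
    la = ma / na
    lb = mb / nb
    return level_a, level_b, la, lb, sub


# ---------------------------------------------------------------------------
# static windows
# ---------------------------------------------------------------------------

def static_window_dmrs(
    sites_a,
    sites_b,
    context_class: str = "CG",
    window_len: int = 1000,
    n_adjacent: int = 3,
    min_coverage: int = 4,
    min_covered_frac: float = 0.8,
    delta_min: float = 0.2,
    alpha: float = 0.05,
    use_fdr: bool = False,
    return_windows: bool = False,
):
    """Fixed-length windows advancing one mC per step.

    A window anchored at a shared site spans ``window_len`` bp; it is
    tested when both samples reach ``min_coverage`` at
    ``min_covered_frac`` of its shared sites and the weighted levels
    differ by at least ``delta_min``.  Runs of >= ``n_adjacent``
    consecutive significant windows with the same delta sign merge into
    one DMR spanning the first to last contributing mC.
    """
    if context_class not in CONTEXT_CLASSES:
        raise ValueError(f"unknown context class {context_class!r}")
    contexts = CONTEXT_CLASSES[context_class]
    tables = _shared_table(sites_a, sites_b, contexts)
    windows: list[tuple[str, int, int, WindowStat]] = []  # (chrom, anchor, last_idx, stat)
    for chrom, tab in sorted(tables.items()):
        pos = tab["pos"]
        for i in range(len(pos)):
            j = int(np.searchsorted(pos, pos[i] + window_len, "left"))
            idx = np.arange(i, j)
            res = _window_stat(tab, idx, min_coverage, min_covered_frac)
            if res is None:
                continue
            level_a, level_b, la, lb, sub = res
            delta = level_a - level_b
            if abs(delta) < delta_min:
                continue
            p = wilcoxon_window_test(la, lb)
            stat = WindowStat(
                GenomicInterval(chrom, int(pos[sub[0]]), int(pos[sub[-1]]) + 1),
                context_class, float(level_a), float(level_b), float(delta),
                float(p), int(len(sub)),
            )
            windows.append((chrom, i, int(sub[-1]), stat))
    qvals = [None] * len(windows)
    if use_fdr and windows:
        from statsmodels.stats.multitest import multipletests

        _, q, _, _ = multipletests([w[3].pvalue for w in windows], method="fdr_bh")
        qvals = list(q)
    sig = [
        (qvals[k] if use_fdr else windows[k][3].pvalue) < alpha
        for k in range(len(windows))
    ]

    dmrs: list[Dmr] = []
    k = 0
    while k < len(windows):
        if not sig[k]:
            k += 1
            continue
        chrom, anchor, _, stat = windows[k]
        sign = np.sign(stat.delta)
        run = [k]
        j = k + 1
        while (
            j < len(windows)
            and sig[j]
            and windows[j][0] == chrom
            and windows[j][1] == windows[j - 1][1] + 1
            and np.sign(windows[j][3].delta) == sign
        ):
            run.append(j)
            j += 1
        if len(run) >= n_adjacent:
            stats_run = [windows[r][3] for r in run]
            start = min(s.interval.start for s in stats_run)
            end = max(s.interval.end for s in stats_run)
            qs = [qvals[r] for r in run if qvals[r] is not None]
            dmrs.append(
                Dmr(
                    GenomicInterval(chrom, start, end, ".", context_class),
                    context_class,
                    float(np.mean([s.delta for s in stats_run])),
                    float(min(s.pvalue for s in stats_run)),
                    float(min(qs)) if qs else None,
                    len(run),
                )
            )
        k = j
    if return_windows:
        return dmrs, [w[3] for w in windows]
    return dmrs


# ---------------------------------------------------------------------------
# dynamic windows
# ---------------------------------------------------------------------------

def dynamic_window_dmrs(
    sites_a,
    sites_b,
    context_class: str = "CG",
    n_sites: int = 10,
    step: int = 2,
    min_coverage: int = 4,
    delta_min: float = 0.2,
    alpha: float = 0.05,
):
    """Fixed-site-count seed windows with bidirectional extension.

    Supported context classes: CN and CG.  A seed of ``n_sites``
    covered shared sites that tests significant is extended 3'-ward by
    ``step`` sites while the re-test (coverage, delta, p < alpha) stays
    significant, then 5'-ward likewise from the original window; the
    maximal extent is reported.  Overlapping same-sign results merge.
    """
    if context_class not in ("CN", "CG"):
        raise ValueError(
            f"dynamic windows support context classes CN and CG, not {context_class!r}"
        )
    if n_sites < 3:
        raise ValueError("n_sites must be >= 3")
    contexts = CONTEXT_CLASSES[context_class]
    tables = _shared_table(sites_a, sites_b, contexts)
    raw: list[tuple[str, int, int, float, float]] = []  # chrom, lo, hi, delta, p
    for chrom, tab in sorted(tables.items()):
        # dynamic windows count covered sites, so pre-filter on coverage
        covered = (tab["na"] >= min_coverage) & (tab["nb"] >= min_coverage)
        sub = {k: v[covered] for k, v in tab.items()}
        N = len(sub["pos"])
        done_until = -1
        for i in range(0, N - n_sites + 1):
            if i <= done_until:
                continue
            res = _test_span(sub, i, i + n_sites, delta_min)
            if res is None or res[1] >= alpha:
                continue
            delta0, p0 = res
            sign = np.sign(delta0)
            lo, hi = i, i + n_sites
            best = (delta0, p0)
            while hi < N:
                nxt = min(hi + step, N)
                r = _test_span(sub, lo, nxt, delta_min)
                if r is None or r[1] >= alpha or np.sign(r[0]) != sign:
                    break
                hi, best = nxt, r
            while lo > 0:
                nxt = max(lo - step, 0)
                r = _test_span(sub, nxt, hi, delta_min)
                if r is None or r[1] >= alpha or np.sign(r[0]) != sign:
                    break
                lo, best = nxt, r
            raw.append((chrom, lo, hi, best[0], best[1]))
            done_until = hi - 1
        tables[chrom] = sub  # keep filtered view for interval lookup below
    # merge overlapping same-sign windows
    dmrs: list[Dmr] = []
    raw.sort(key=lambda r: (r[0], r[1]))
    i = 0
    while i < len(raw):
        chrom, lo, hi, delta, p = raw[i]
        deltas, ps, n_win = [delta], [p], 1
        j = i + 1
        while (
            j < len(raw)
            and raw[j][0] == chrom
            and raw[j][1] < hi
            and np.sign(raw[j][3]) == np.sign(delta)
        ):
            hi = max(hi, raw[j][2])
            deltas.append(raw[j][3])
            ps.append(raw[j][4])
            n_win += 1
            j += 1
        pos = tables[chrom]["pos"]
        dmrs.append(
            Dmr(
                GenomicInterval(chrom, int(pos[lo]), int(pos[hi - 1]) + 1, ".", context_class),
                context_class,
                float(np.mean(deltas)),
                float(min(ps)),
                None,
                n_win,
            )
        )
        i = j
    return dmrs


def _test_span(tab, lo, hi, delta_min):
    """(delta, p) for covered shared sites [lo, hi); None if delta too small."""
    ma, na = tab["ma"][lo:hi], tab["na"][lo:hi]
    mb, nb = tab["mb"][lo:hi], tab["nb"][lo:hi]
    if na.sum() == 0 or nb.sum() == 0:
        return None
    delta = ma.sum() / na.sum() - mb.sum() / nb.sum()
    if abs(delta) < delta_min:
        return None
    p = wilcoxon_window_test(ma / na, mb / nb)
    return float(delta), float(p)


# ---------------------------------------------------------------------------
# DMR -> gene annotation
# ---------------------------------------------------------------------------

def annotate_dmrs(dmrs, genes, promoter_len: int = 2000) -> list[Dmr]:
    """Link each DMR to genes whose promoter or body overlaps it.

    ``linked_genes`` holds (gene_id, overlap_class) pairs; a DMR
    spanning both promoter and body of a gene records both classes.
    """
    out = []
    for d in dmrs:
        links = []
        for g in genes:
            if g.chrom != d.interval.chrom:
                continue
            prom = g.promoter(promoter_len)
            if prom is not None and prom.overlaps(d.interval):
                links.append((g.gene_id, "promoter"))
            if g.body().overlaps(d.interval):
                links.append((g.gene_id, "gene body"))
        out.append(replace(d, linked_genes=links))
    return out


def write_dmr_bed(dmrs, path) -> None:
    """BED6+ with context class, delta, p, q, window count and links."""
    with open(path, "w") as fh:
        for i, d in enumerate(dmrs):
            direction = "hyper" if d.mean_delta > 0 else "hypo"
            links = ";".join(f"{gid}:{cls}" for gid, cls in d.linked_genes) or "."
            fh.write(
                "\t".join(
                    [
                        d.interval.chrom,
                        str(d.interval.start),
                        str(d.interval.end),
                        f"dmr{i + 1}_{direction}",
                        "0",
                        ".",
                        d.context_class,
                        f"{d.mean_delta:.4f}",
                        f"{d.min_pvalue:.3e}",
                        "NA" if d.qvalue is None else f"{d.qvalue:.3e}",
                        str(d.n_windows),
                        links,
                    ]
                )
                + "\n"
            )
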