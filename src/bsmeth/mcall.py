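"""Binomial methylation-site calling.

For each reference cytosine the informative depth n counts read C + T
(plus strand; G + A mirror on the minus strand) and m counts retained
Cs.  Under the null of no methylation, m ~ Binomial(n, p) with p the
error rate (non-conversion plus sequencing error), estimated from the
unmethylated lambda spike-in or supplied by the user.  Sites are called
when the one-sided upper-tail p-value survives Benjamini-Hochberg
control at FDR 0.01 (strict q < fdr).

RRBS mode additionally masks the artifactual cytosine filled in during
end repair at MspI fragment 3' termini.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .types import CytosineSite, Genome, GenomicInterval, context_of

_C, _G, _T, _A = (ord(b) for b in "CGTA")


@dataclass(frozen=True)
class ErrorModel:
    """Null probability of reading C at an unmethylated reference C."""

    p: float
    source: str = "user-supplied"  # or "lambda-estimate"

    def __post_init__(self) -> None:
        if not (0.0 < self.p < 1.0):
            raise ValueError(f"error probability must be in (0,1), got {self.p}")


def binomial_pvalue(m: int, n: int, p: float) -> float:
    """One-sided upper tail P(X >= m), X ~ Binomial(n, p).

    Computed through the regularized incomplete beta function (exact to
    machine precision; no normal approximation).
    """
    if not (0 <= m <= n):
        raise ValueError(f"need 0 <= m <= n, got m={m}, n={n}")
    if not (0.0 < p < 1.0):
        raise ValueError(f"need 0 < p < 1, got {p}")
    if m == 0:
        return 1.0
    return float(stats.binom.sf(m - 1, n, p))


def methylation_counts(records, genome: Genome, chroms=None, mask_fn=None):
    """Per-position methylation counts from filtered alignments.

    Returns dict chrom -> (m_plus, n_plus, m_minus, n_minus) int arrays
    over the chromosome.  Plus-strand sites live at Watson C positions
    (read C counts m, read T completes n); minus-strand sites at Watson
    G positions (read G / read A).  ``mask_fn(record)`` may return
    Watson positions to exclude (RRBS end repair).
    """
    chroms = list(chroms) if chroms is not None else genome.chroms()
    ref = {c: np.frombuffer(genome[c].encode(), np.uint8) for c in chroms}
    is_c = {c: ref[c] == _C for c in chroms}
    is_g = {c: ref[c] == _G for c in chroms}
    out = {
        c: tuple(np.zeros(len(ref[c]), np.int32) for _ in range(4)) for c in chroms
    }
    for rec in records:
        if rec.chrom not in out:
            continue
        arr = np.frombuffer(rec.watson_seq.encode(), np.uint8)
        L = len(arr)
        sl = slice(rec.pos, rec.pos + L)
        keep = np.ones(L, bool)
        if mask_fn is not None:
            for wpos in mask_fn(rec):
                off = wpos - rec.pos
                if 0 <= off < L:
                    keep[off] = False
        m_p, n_p, m_m, n_m = out[rec.chrom]
        if rec.strand == "+":
            sites = is_c[rec.chrom][sl] & keep
            m_p[sl] += (arr == _C) & sites
            n_p[sl] += ((arr == _C) | (arr == _T)) & sites
        else:
            sites = is_g[rec.chrom][sl] & keep
            m_m[sl] += (arr == _G) & sites
            n_m[sl] += ((arr == _G) | (arr == _A)) & sites
    return out


def pileup_cytosines(
    records,
    genome: Genome,
    rrbs_fragments=None,
    include_uncovered: bool = False,
    exclude_lambda: bool = True,
) -> list[CytosineSite]:
    """Per-cytosine m/n counts from filtered alignment records.

    With ``rrbs_fragments`` (the MspI fragment map) the end-repair mask
    is applied per record.  The lambda control chromosome is excluded
    from the site list by default (it is used for the error model, not
    for methylation calls).
    """
    mask_fn = None
    if rrbs_fragments is not None:
        fragmap = _fragment_map(rrbs_fragments)

        def mask_fn(rec):
            return rrbs_end_repair_mask(rec, fragmap)

    chroms = [
        c for c in genome.chroms()
        if not (exclude_lambda and c == genome.lambda_name)
    ]
    counts = methylation_counts(records, genome, chroms=chroms, mask_fn=mask_fn)
    sites: list[CytosineSite] = []
    for chrom in chroms:
        seq = genome[chrom]
        m_p, n_p, m_m, n_m = counts[chrom]
        pos_p = np.flatnonzero(n_p) if not include_uncovered else np.flatnonzero(
            np.frombuffer(seq.encode(), np.uint8) == _C
        )
        pos_m = np.flatnonzero(n_m) if not include_uncovered else np.flatnonzero(
            np.frombuffer(seq.encode(), np.uint8) == _G
        )
        merged = [(int(p), "+") for p in pos_p] + [(int(p), "-") for p in pos_m]
        merged.sort()
        for p, strand in merged:
            m, n = (m_p[p], n_p[p]) if strand == "+" else (m_m[p], n_m[p])
            sites.append(
                CytosineSite(chrom, p, strand, context_of(seq, p, strand), int(m), int(n))
            )
    return sites


def call_methylation(
    sites: Sequence[CytosineSite], error_model: ErrorModel, fdr: float = 0.01
) -> list[CytosineSite]:
    """Binomial test + Benjamini-Hochberg over all covered sites.

    Sites with n == 0 keep missing p/q and called=False and are
    excluded from the BH family.  Calls are a prefix of the
    p-value-sorted list and do not depend on input order.
    """
    sites = list(sites)
    tested = [s for s in sites if s.n > 0]
    if not tested:
        return sites
    pvals = np.array([binomial_pvalue(s.m, s.n, error_model.p) for s in tested])
    _, qvals, _, _ = multipletests(pvals, alpha=fdr, method="fdr_bh")
    for s, p, q in zip(tested, pvals, qvals):
        s.pvalue = float(p)
        s.qvalue = float(q)
        s.called = bool(q < fdr)
    return sites


# ---------------------------------------------------------------------------
# RRBS end repair
# ---------------------------------------------------------------------------

def _fragment_map(fragments) -> dict:
    if isinstance(fragments, dict):
        return fragments
    out: dict = {}
    for f in fragments:
        out.setdefault(f.chrom, []).append(f)
    return out


def rrbs_end_repair_mask(record, fragment_map) -> frozenset[int]:
    """Watson positions to exclude from counting for one RRBS record.

    End repair of an MspI fragment fills in an unmethylated cytosine at
    the fragment's 3' terminal CCGG (Watson fragment: the second C of
    the downstream CCGG; Crick fragment: the mirror position at the
    upstream CCGG).  That artifact is masked only when the read's
    terminal positions reach it.  The 5' read start (the genuine C of
    the fragment-start CGG) is never masked.  Outside any fragment (or
    in WGBS mode, with an empty map) the mask is empty.
    """
    frags = _fragment_map(fragment_map).get(record.chrom, [])
    start, end = record.pos, record.pos + len(record.watson_seq)
    masked = set()
    for f in frags:
        if f.strand not in ("+", "-") or f.strand != record.strand:
            continue
        if f.end <= start or end <= f.start:
            continue
        if record.strand == "+":
            fill = f.end - 3  # second C of the 3'-terminal CCGG
        else:
            fill = f.start + 2  # mirror: Crick C at the upstream CCGG
        if start <= fill < end:
            masked.add(fill)
    return frozenset(masked)


# ---------------------------------------------------------------------------
# region-level summaries
# ---------------------------------------------------------------------------

def region_level(
    sites: Iterable[CytosineSite],
    interval: GenomicInterval,
    contexts=None,
) -> float | None:
    """Coverage-weighted methylation level sum(m)/sum(n) in an interval.

    ``contexts`` restricts to the given context set (None = all).
    Returns None (missing) when no informative coverage exists.
    """
    if contexts is not None:
        contexts = set(contexts)
    m_tot = n_tot = 0
    for s in sites:
        if s.chrom != interval.chrom or not (interval.start <= s.pos < interval.end):
            continue
        if contexts is not None and s.context not in contexts:
            continue
        m_tot += s.m
        n_tot += s.n
    return m_tot / n_tot if n_tot > 0 else None
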