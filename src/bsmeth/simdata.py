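"""Synthetic WGBS and RRBS data with per-cytosine ground truth.

The simulators emulate a directional (strand-specific) bisulfite
library.  Every reference cytosine is assigned a binary methylation
state from per-context probabilities; an unmethylated cytosine survives
bisulfite as C with probability ``nonconversion`` (modelling incomplete
conversion), otherwise it is read as T.  Sequencing errors are i.i.d.
substitutions, and a configurable fraction of uniform-random reads is
appended to emulate contaminating sequence.

The ground truth (:class:`SimTruth`) records each site's state and each
read's origin, enabling parameter-recovery tests downstream.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

import numpy as np

from .types import CytosineSite, Genome, GenomicInterval, GeneModel, Read, T_RICH, A_RICH, revcomp

_A, _C, _G, _T = (ord(b) for b in "ACGT")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass(frozen=True)
class TruthModel:
    """Ground-truth methylation model.

    Defaults emulate a vertebrate-like methylome: dense CpG methylation
    and sparse non-CpG methylation, with a 0.5% non-conversion rate
    typical of a good bisulfite treatment.
    """

    p_mCG: float = 0.7
    p_mCHG: float = 0.02
    p_mCHH: float = 0.02
    nonconversion: float = 0.005
    seed: int = 1

    def __post_init__(self) -> None:
        for name in ("p_mCG", "p_mCHG", "p_mCHH", "nonconversion"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must be in [0,1], got {v}")


class SimTruth:
    """Per-site truth states and per-read origins of a simulation.

    ``site_states`` maps (chrom, pos, strand) -> methylated bool for
    every reference cytosine; ``read_origins`` maps read id ->
    (chrom, watson_start, bisulfite_strand) or the string ``"RANDOM"``.
    """

    def __init__(self, site_states: dict, read_origins: dict) -> None:
        self.site_states = site_states
        self.read_origins = read_origins

    def truth_fraction(self, genome: Genome, context: str) -> float:
        """Fraction of methylated cytosines among sites of ``context``.

        Restricted to chromosomes present in ``genome``, so passing a
        genome without the lambda control excludes the (forced
        unmethylated) spike-in from the truth summary.
        """
        from .types import context_of

        tot = meth = 0
        for (chrom, pos, strand), state in self.site_states.items():
            if chrom not in genome:
                continue
            if context_of(genome[chrom], pos, strand) == context:
                tot += 1
                meth += bool(state)
        if tot == 0:
            raise ValueError(f"no sites of context {context}")
        return meth / tot

    def truth_sites(self, genome: Genome) -> list[CytosineSite]:
        """Truth states as fully methylated/unmethylated site records."""
        from .types import context_of

        out = []
        for (chrom, pos, strand), state in sorted(self.site_states.items()):
            ctx = context_of(genome[chrom], pos, strand)
            out.append(CytosineSite(chrom, pos, strand, ctx, int(bool(state)), 1))
        return out


# ---------------------------------------------------------------------------
# toy inputs
# ---------------------------------------------------------------------------

def make_toy_genome(
    length: int,
    gc_frac: float = 0.4,
    n_islands: int = 2,
    island_len: int = 300,
    seed: int = 1,
    name: str = "chr1",
) -> Genome:
    """A random chromosome with embedded CpG-island-like blocks.

    The background is i.i.d. with the requested GC fraction; islands
    are i.i.d. with GC 0.65 (an i.i.d. sequence has CpG obs/exp near 1,
    so islands satisfy GC >= 0.6 and obs/exp >= 0.6 in expectation).
    Deterministic for a fixed seed.
    """
    if n_islands > 0 and length < n_islands * island_len:
        raise ValueError("genome too short for the requested islands")
    rng = np.random.default_rng([seed, 0x67656e])  # distinct stream per consumer
    at = (1.0 - gc_frac) / 2.0
    gc = gc_frac / 2.0
    seq = rng.choice(_BASES, size=length, p=[at, gc, gc, at])
    if n_islands > 0:
        seg = length // n_islands
        for i in range(n_islands):
            off = int(rng.integers(0, max(1, seg - island_len)))
            s = i * seg + off
            island = rng.choice(_BASES, size=island_len, p=[0.175, 0.325, 0.325, 0.175])
            seq[s : s + island_len] = island
    return Genome({name: seq.tobytes().decode()})


def add_lambda_control(
    genome: Genome, length: int = 48502, gc_frac: float = 0.5, seed: int = 7
) -> Genome:
    """Append an unmethylated control chromosome named chrLam."""
    if "chrLam" in genome.sequences:
        raise ValueError("genome already contains chrLam")
    rng = np.random.default_rng([seed, 0x6c616d])
    at = (1.0 - gc_frac) / 2.0
    gc = gc_frac / 2.0
    lam = rng.choice(_BASES, size=length, p=[at, gc, gc, at]).tobytes().decode()
    seqs = dict(genome.sequences)
    seqs["chrLam"] = lam
    return Genome(seqs, lambda_name="chrLam")


def make_toy_genes(
    genome: Genome,
    n_genes: int = 10,
    n_exons: int = 3,
    exon_len: int = 200,
    intron_len: int = 150,
    margin: int = 2500,
    seed: int = 1,
) -> list[GeneModel]:
    """Evenly spaced multi-exon genes on alternating strands."""
    rng = np.random.default_rng(seed)
    chrom = genome.chroms()[0]
    L = genome.chrom_length(chrom)
    gene_len = n_exons * exon_len + (n_exons - 1) * intron_len
    if n_genes * (gene_len + margin) > L:
        raise ValueError("genome too short for the requested genes")
    seg = L // n_genes
    genes = []
    for i in range(n_genes):
        start = i * seg + int(rng.integers(0, max(1, seg - gene_len - margin))) + margin // 2
        strand = "+" if i % 2 == 0 else "-"
        exons = []
        pos = start
        for _ in range(n_exons):
            exons.append(GenomicInterval(chrom, pos, pos + exon_len, strand))
            pos += exon_len + intron_len
        genes.append(GeneModel(f"gene{i + 1}", chrom, strand, tuple(exons)))
    return genes


def make_toy_tes(
    genome: Genome, n: int = 20, te_len: int = 150, seed: int = 2
) -> list[GenomicInterval]:
    rng = np.random.default_rng(seed)
    chrom = genome.chroms()[0]
    L = genome.chrom_length(chrom)
    starts = sorted(int(s) for s in rng.integers(0, L - te_len, size=n))
    return [
        GenomicInterval(chrom, s, s + te_len, ".", f"TE{i + 1}")
        for i, s in enumerate(starts)
    ]


def make_toy_expression(genes, seed: int = 3) -> dict[str, float]:
    rng = np.random.default_rng(seed)
    return {g.gene_id: float(rng.lognormal(2.0, 1.0)) for g in genes}


def make_toy_class_map(genes, n_classes: int = 4, seed: int = 4) -> dict[str, str]:
    rng = np.random.default_rng(seed)
    return {g.gene_id: f"class{int(rng.integers(1, n_classes + 1))}" for g in genes}


# ---------------------------------------------------------------------------
# truth states
# ---------------------------------------------------------------------------

def _context_prob_arrays(seq: str, truth: TruthModel):
    """Per-position context probabilities for Watson Cs and Gs (Crick Cs)."""
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    L = len(arr)
    is_c = arr == _C
    is_g = arr == _G
    nxt = np.full(L, ord("N"), np.uint8)
    nxt[:-1] = arr[1:]
    nxt2 = np.full(L, ord("N"), np.uint8)
    nxt2[:-2] = arr[2:]
    prv = np.full(L, ord("N"), np.uint8)
    prv[1:] = arr[:-1]
    prv2 = np.full(L, ord("N"), np.uint8)
    prv2[2:] = arr[:-2]

    p_plus = np.zeros(L)
    p_minus = np.zeros(L)
    # plus strand: C followed by G -> CG; C,N -> CN; C,H,G -> CHG; C,H,H -> CHH
    cg = is_c & (nxt == _G)
    cn = is_c & ~cg & ((nxt == ord("N")) | ((nxt2 == ord("N")) & (nxt != _G)))
    chg = is_c & ~cg & ~cn & (nxt2 == _G)
    chh = is_c & ~cg & ~cn & ~chg
    p_plus[cg] = truth.p_mCG
    p_plus[chg] = truth.p_mCHG
    p_plus[chh] = truth.p_mCHH
    # minus strand: site at Watson G; next base on Crick is complement of prv
    gc = is_g & (prv == _C)  # CpG on Crick
    gn = is_g & ~gc & ((prv == ord("N")) | ((prv2 == ord("N")) & (prv != _C)))
    ghg = is_g & ~gc & ~gn & (prv2 == _C)
    ghh = is_g & ~gc & ~gn & ~ghg
    p_minus[gc] = truth.p_mCG
    p_minus[ghg] = truth.p_mCHG
    p_minus[ghh] = truth.p_mCHH
    return is_c, is_g, p_plus, p_minus


def draw_truth_states(genome: Genome, truth: TruthModel):
    """Bernoulli methylation state for every reference cytosine.

    Returns dict chrom -> (meth_plus, meth_minus) full-length bool
    arrays (meaningful at Watson C / Watson G positions).  The lambda
    control chromosome, if present, is forced fully unmethylated.
    """
    rng = np.random.default_rng([truth.seed, 0x747275])
    out = {}
    for chrom, seq in genome.sequences.items():
        is_c, is_g, p_plus, p_minus = _context_prob_arrays(seq, truth)
        if chrom == genome.lambda_name:
            p_plus[:] = 0.0
            p_minus[:] = 0.0
        u = rng.random(len(seq))
        v = rng.random(len(seq))
        out[chrom] = ((u < p_plus) & is_c, (v < p_minus) & is_g)
    return out


def _states_to_dict(genome: Genome, states) -> dict:
    site_states = {}
    for chrom, seq in genome.sequences.items():
        arr = np.frombuffer(seq.encode(), dtype=np.uint8)
        mp, mm = states[chrom]
        for pos in np.flatnonzero(arr == _C):
            site_states[(chrom, int(pos), "+")] = bool(mp[pos])
        for pos in np.flatnonzero(arr == _G):
            site_states[(chrom, int(pos), "-")] = bool(mm[pos])
    return site_states


def _bisulfite_convert(
    frag: np.ndarray, meth: np.ndarray, nonconversion: float, rng
) -> np.ndarray:
    """Convert a fragment-strand sequence: unmethylated C -> T.

    ``frag`` and ``meth`` are oriented 5'->3' along the fragment strand;
    an unmethylated C is retained with probability ``nonconversion``.
    """
    out = frag.copy()
    is_c = frag == _C
    survive = meth | (rng.random(len(frag)) < nonconversion)
    out[is_c & ~survive] = _T
    return out


def _inject_errors(seq: np.ndarray, error_rate: float, rng) -> np.ndarray:
    if error_rate <= 0:
        return seq
    hit = np.flatnonzero(rng.random(len(seq)) < error_rate)
    if hit.size:
        seq = seq.copy()
        # substitute with a uniformly chosen *different* base
        shift = rng.integers(1, 4, size=hit.size)
        idx = (np.searchsorted(_BASES, seq[hit]) + shift) % 4
        seq[hit] = _BASES[idx]
    return seq


def _revcomp_arr(arr: np.ndarray) -> np.ndarray:
    comp = np.full(256, ord("N"), np.uint8)
    for a, b in zip(b"ACGTN", b"TGCAN"):
        comp[a] = b
    return comp[arr][::-1]


# ---------------------------------------------------------------------------
# WGBS simulation
# ---------------------------------------------------------------------------

def simulate_wgbs(
    genome: Genome,
    truth: TruthModel,
    coverage: float = 10.0,
    read_len: int = 80,
    error_rate: float = 0.005,
    random_frac: float = 0.05,
    insert_mean: float = 250.0,
    insert_sd: float = 30.0,
    seed: int = 1,
) -> tuple[list[Read], list[Read], SimTruth]:
    """Simulate a paired-end directional WGBS run.

    Fragments are sampled uniformly from both strands with
    normal(insert_mean, insert_sd) insert sizes (truncated at
    read_len).  Mate 1 reads the converted fragment strand (T-rich,
    C->T); mate 2 is the reverse complement of the fragment 3' end, so
    conversions appear as G->A (A-rich).  ``floor(random_frac *
    n_pairs)`` pairs of uniform-random DNA are appended and tagged
    RANDOM in the truth.
    """
    if genome.total_length == 0 or not genome.sequences:
        raise ValueError("empty genome")
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    rng = np.random.default_rng([seed, 0x776762])
    states = draw_truth_states(genome, truth)
    chroms = genome.chroms()
    lengths = np.array([genome.chrom_length(c) for c in chroms], float)
    arrs = {c: np.frombuffer(genome[c].encode(), np.uint8) for c in chroms}

    n_pairs = int(round(coverage * genome.total_length / (2 * read_len)))
    chrom_idx = rng.choice(len(chroms), size=n_pairs, p=lengths / lengths.sum())
    mates1: list[Read] = []
    mates2: list[Read] = []
    origins: dict = {}
    q40 = tuple([40] * read_len)
    for i in range(n_pairs):
        chrom = chroms[int(chrom_idx[i])]
        L = int(lengths[int(chrom_idx[i])])
        insert = int(round(rng.normal(insert_mean, insert_sd)))
        insert = max(read_len, min(insert, L))
        start = int(rng.integers(0, L - insert + 1))
        strand = "+" if rng.random() < 0.5 else "-"
        wslice = arrs[chrom][start : start + insert]
        mp, mm = states[chrom]
        if strand == "+":
            frag = wslice
            meth = mp[start : start + insert]
        else:
            frag = _revcomp_arr(wslice)
            meth = mm[start : start + insert][::-1]
        conv = _bisulfite_convert(frag, meth, truth.nonconversion, rng)
        m1 = _inject_errors(conv[:read_len], error_rate, rng)
        m2 = _inject_errors(_revcomp_arr(conv[-read_len:]), error_rate, rng)
        rid = f"sim{i}"
        mates1.append(Read(f"{rid}/1", m1.tobytes().decode(), q40, 1, T_RICH))
        mates2.append(Read(f"{rid}/2", m2.tobytes().decode(), q40, 2, A_RICH))
        if strand == "+":
            origins[f"{rid}/1"] = (chrom, start, "+")
            origins[f"{rid}/2"] = (chrom, start + insert - read_len, "+")
        else:
            origins[f"{rid}/1"] = (chrom, start + insert - read_len, "-")
            origins[f"{rid}/2"] = (chrom, start, "-")

    n_rand = int(random_frac * n_pairs)
    for j in range(n_rand):
        rid = f"rand{j}"
        for mate, store, rich in ((1, mates1, T_RICH), (2, mates2, A_RICH)):
            seq = rng.choice(_BASES, size=read_len).tobytes().decode()
            store.append(Read(f"{rid}/{mate}", seq, q40, mate, rich))
            origins[f"{rid}/{mate}"] = "RANDOM"

    return mates1, mates2, SimTruth(_states_to_dict(genome, states), origins)


# ---------------------------------------------------------------------------
# RRBS simulation
# ---------------------------------------------------------------------------

_CCGG = re.compile(r"(?=CCGG)")


def enumerate_mspi_fragments(genome: Genome) -> list[GenomicInterval]:
    """In-silico MspI digestion with 40-220 bp size selection.

    Reports, per strand, every interval spanning two successive CCGG
    occurrences whose start-to-start distance d satisfies 40 <= d <=
    220 (the interval covers both CCGG sites).  CCGG is palindromic, so
    Crick fragments mirror Watson ones; both are scanned explicitly.
    """
    if not genome.sequences:
        raise ValueError("empty genome")
    out: list[GenomicInterval] = []
    for chrom, seq in genome.sequences.items():
        L = len(seq)
        starts = [m.start() for m in _CCGG.finditer(seq)]
        for s, t in zip(starts, starts[1:]):
            d = t - s
            if 40 <= d <= 220:
                out.append(GenomicInterval(chrom, s, t + 4, "+", f"d={d}"))
        crick = revcomp(seq)
        cstarts = [m.start() for m in _CCGG.finditer(crick)]
        for s, t in zip(cstarts, cstarts[1:]):
            d = t - s
            if 40 <= d <= 220:
                # Crick [s, t+4) maps to Watson [L-t-4, L-s)
                out.append(GenomicInterval(chrom, L - t - 4, L - s, "-", f"d={d}"))
    out.sort(key=lambda iv: (iv.chrom, iv.start, iv.strand))
    return out


def simulate_rrbs(
    genome: Genome,
    truth: TruthModel,
    reads_per_fragment: int = 10,
    read_len: int = 36,
    error_rate: float = 0.005,
    random_frac: float = 0.05,
    seed: int = 1,
) -> tuple[list[Read], SimTruth]:
    """Simulate single-end directional RRBS reads.

    Each size-selected MspI fragment yields ``reads_per_fragment``
    reads of ``read_len`` bp starting at the fragment 5' cut, whose
    first three reference bases are CGG (the CCGG minus the cut-off C).
    Bisulfite conversion follows the truth model; errors are i.i.d.;
    ``floor(random_frac * n)`` uniform-random reads are appended.
    """
    fragments = enumerate_mspi_fragments(genome)
    if not fragments:
        raise ValueError("no MspI fragments in the 40-220 bp size window")
    rng = np.random.default_rng([seed, 0x726273])
    states = draw_truth_states(genome, truth)
    arrs = {c: np.frombuffer(genome[c].encode(), np.uint8) for c in genome.chroms()}
    reads: list[Read] = []
    origins: dict = {}
    qconst = tuple([40] * read_len)
    i = 0
    for frag in fragments:
        arr = arrs[frag.chrom]
        mp, mm = states[frag.chrom]
        if frag.strand == "+":
            ws = frag.start + 1  # skip the cut-off C of CCGG
            if ws + read_len > len(arr):
                continue
            region = arr[ws : ws + read_len]
            meth = mp[ws : ws + read_len]
            oriented = region
            meth_or = meth
        else:
            # Crick read: last cut is at the interval 3' (Watson-left) end
            we = frag.end - 1  # skip cut-off C (Watson G at frag.end-1)
            ws = we - read_len
            if ws < 0:
                continue
            region = arr[ws:we]
            oriented = _revcomp_arr(region)
            meth_or = mm[ws:we][::-1]
        for _ in range(reads_per_fragment):
            conv = _bisulfite_convert(oriented.copy(), meth_or, truth.nonconversion, rng)
            conv = _inject_errors(conv, error_rate, rng)
            rid = f"rrbs{i}"
            reads.append(Read(rid, conv.tobytes().decode(), qconst, 0, T_RICH))
            origins[rid] = (frag.chrom, ws, frag.strand)
            i += 1
    n_rand = int(random_frac * len(reads))
    for j in range(n_rand):
        rid = f"rand{j}"
        seq = rng.choice(_BASES, size=read_len).tobytes().decode()
        reads.append(Read(rid, seq, qconst, 0, T_RICH))
        origins[rid] = "RANDOM"
    return reads, SimTruth(_states_to_dict(genome, states), origins)
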