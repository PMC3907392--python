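"""Simulate a small WGBS run and call methylation sites.

Builds a 30-kb toy genome with a lambda spike-in, simulates 10x
directional paired-end reads, aligns with the built-in aligner, applies
the discard rules, estimates the non-conversion rate from the spike-in
and calls sites with the binomial test at FDR 0.01.
"""

import bsmeth as b
from bsmeth.mcall import ErrorModel, call_methylation, pileup_cytosines

genome = b.add_lambda_control(b.make_toy_genome(30_000, n_islands=2, seed=1), length=20_000)
truth = b.TruthModel(p_mCG=0.7, p_mCHG=0.02, p_mCHH=0.02, nonconversion=0.005, seed=1)

m1, m2, sim = b.simulate_wgbs(genome, truth, coverage=10, seed=1)
print(f"simulated {len(m1)} read pairs over {genome.total_length / 1e3:.0f} kb")

aligner = b.BuiltinAligner(genome, max_mismatches=3)
kept, counts = b.filter_alignments(list(b.align(m1 + m2, aligner=aligner)))
print(f"kept {len(kept)} alignments; discards by rule: {counts}")

est = b.nonconversion_rate(kept, genome)
print(f"lambda non-conversion estimate: {est.rate:.5f} "
      f"({est.n_unconverted}/{est.n_total} retained Cs)")

sites = call_methylation(pileup_cytosines(kept, genome), ErrorModel(est.rate), fdr=0.01)
cg = [s for s in sites if s.context == "CG"]
called_cg = sum(s.called for s in cg)
level = sum(s.m for s in cg) / sum(s.n for s in cg)
print(f"{len(cg)} covered CG sites, {called_cg} called methylated")
print(f"global CG level: {level:.3f} (truth fraction "
      f"{sim.truth_fraction(b.Genome({'chr1': genome['chr1']}), 'CG'):.3f})")
# The called fraction tracks p_mCG; the level estimate should sit within
# a point or two of the simulated truth.
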