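"""In-silico MspI digestion and RRBS simulation.

Scans a toy genome for CCGG sites, keeps fragments whose adjacent-site
distance falls in the 40-220 bp size-selection window, then simulates
36-bp single-end reads starting at the fragment cut sites (first three
reference bases CGG) and shows how the CGG start reads out methylation.
"""

import numpy as np

import bsmeth as b

# a CpG-dense genome so MspI sites are frequent
genome = b.make_toy_genome(50_000, gc_frac=0.55, n_islands=5, island_len=400, seed=3)
frags = b.enumerate_mspi_fragments(genome)
watson = [f for f in frags if f.strand == "+"]
sizes = [f.length for f in watson]
print(f"{len(watson)} Watson-strand fragments in the 40-220 bp window")
print(f"fragment span: min {min(sizes)} bp, median {int(np.median(sizes))} bp, "
      f"max {max(sizes)} bp")

truth = b.TruthModel(p_mCG=0.7, nonconversion=0.005, seed=1)
reads, sim = b.simulate_rrbs(genome, truth, reads_per_fragment=5, seed=2)
genuine = [r for r in reads if sim.read_origins[r.id] != "RANDOM"]
starts_cgg = sum(r.seq.startswith("CGG") for r in genuine)
starts_tgg = sum(r.seq.startswith("TGG") for r in genuine)
print(f"{len(reads)} reads ({len(reads) - len(genuine)} random contaminants)")
print(f"read starts: CGG {starts_cgg} (methylated CpG retained), "
      f"TGG {starts_tgg} (unmethylated, converted)")
frac = starts_cgg / (starts_cgg + starts_tgg)
print(f"fraction starting CGG: {frac:.3f} ~ p_mCG = {truth.p_mCG}")
# Each read begins at a fragment cut; its first base is the CpG cytosine
# of the CCGG site, so the CGG/TGG split directly reads out methylation.
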