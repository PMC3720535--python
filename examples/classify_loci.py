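"""Full locus discovery and mutant-dependency classification.

Simulates a default panel, maps every library, clusters alignments into
proximity-defined loci (gap <= 200 bp), computes per-library normalized
abundances, and assigns each exonic locus to ex-siRNA class I-IV from its
pattern of >= 3-fold drops (log2 fold change <= -1.6, wild-type abundance
>= 50 per million) across the dicer/rdrp knockouts.
"""

from exsirna import SimConfig, analyze_panel, simulate
from exsirna.pipeline import score_recovery

sim = simulate(SimConfig(seed=42))
result = analyze_panel(sim.libraries, sim.genome, sim.annotation)

print(f"discovered loci: {len(result.locus_table)} "
      f"({(result.locus_table['category'] == 'exon').sum()} exonic, "
      f"rest intergenic background)")
print()
print("class summary (count and mean ago-1 vs WT log2 fold change):")
print(result.class_summary.to_string(index=False))
print()
metrics = score_recovery(sim.truth, result)
print(f"planted-class recovery accuracy: {metrics['class_accuracy']:.3f} "
      f"over {metrics['n_eligible']} loci passing the abundance filter")
print()
print("Each row mirrors the per-class dependency table: class I loci are")
print("dcl-2 dependent only, class II adds rdrp-1, class III needs the")
print("dicer double knockout plus both rdrps, class IV depends on dcl-1.")
print("The ago-1 mutant depresses every locus uniformly, and per-million")
print("normalization is scale-free, so its fold-change column sits near")
print("zero at this panel size (see docs/methods.md).")
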