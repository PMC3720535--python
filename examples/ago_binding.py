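"""Ago-1 binding calls from immunoprecipitation libraries.

The IP pair (Ago-1 pulldown from wild type vs the same fractions from the
ago-1 mutant) is length-filtered to 21-24 nt, mapped, and compared per locus:
a locus is Ago-1-bound when its normalized abundance is >= 3-fold higher in
the wild-type pulldown (log2 fold change >= 1.6) and clears the abundance
floor. Bound loci are cross-tabulated with the ex-siRNA classes.
"""

from exsirna import SimConfig, analyze_panel, simulate

sim = simulate(SimConfig(seed=42))
result = analyze_panel(sim.libraries, sim.genome, sim.annotation)

print("binding crosstab (per class: members, bound, percent, mean log2 fc):")
print(result.binding_summary.to_string(index=False))
print()
comp = result.fp_composition["bound"]
print("5' nucleotide composition of Ago-1-bound reads:")
print("  " + "  ".join(f"{b}: {comp[b]:.3f}" for b in "UACG"))
comp3 = result.fp_composition["class_III"]
print("5' composition of class III reads (not bound):")
print("  " + "  ".join(f"{b}: {comp3[b]:.3f}" for b in "UACG"))
print()
print("Classes I/II are bound (planted 16-fold IP enrichment) and show the")
print("5'-U preference typical of Argonaute cargo; class III reads favour")
print("5'-A and stay at background in the pulldown.")
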