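"""Transformation silencing-frequency tables.

Recomputes the percent of silenced (albino) transformants from the bundled
colony counts for silencing-reporter plasmids introduced into wild-type and
argonaute-mutant M. circinelloides strains. A colony with any albino patch
counts as albino; frequency = 100 x albino / total, one decimal.
"""

from exsirna.report import (format_frequency, load_transformation_counts,
                            transformation_table)

table = transformation_table(load_transformation_counts())
table["silencing frequency (%)"] = table["silencing_frequency_pct"].map(
    format_frequency)
cols = ["plasmid", "construct", "strain", "albino", "bright_yellow",
        "total", "silencing frequency (%)"]
print(table[cols].to_string(index=False))
print()
print("The hpRNA trigger silences ~76-95% of wild-type transformants, the")
print("sense transgene 34-53%; the ago-1 knockout abolishes silencing")
print("entirely (0%) and the ago-1+ complementation restores it (93.5%).")
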