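# Methods

## The analysis

`exsirna` reimplements, as a tested pipeline, the discovery and
classification of endogenous exonic short interfering RNAs (ex-siRNAs) from
deep sequencing of small RNAs in a fungal RNAi genotype panel: wild type,
the dicer knockouts *dcl-1⁻*, *dcl-2⁻* and the *dcl-1⁻/dcl-2⁻* double, the
RNA-dependent-RNA-polymerase knockouts *rdrp-1⁻* and *rdrp-2⁻*, the
argonaute knockout *ago-1⁻*, and an Ago-1 immunoprecipitation (IP) pair
(pulldown from wild type vs the equivalent fractions from *ago-1⁻*).

The stages are:

1. **Ingestion** (`libio`). Reads are collapsed to distinct sequences with
   counts (U stored as T; sequences containing N dropped). Genotype-panel
   libraries keep 18–25 nt; the 21–24 nt filter is applied only to the IP
   pair, upstream of mapping. Abundance is expressed in reads per million
   genome-matching reads.
2. **Mapping** (`mapper`). Exact (0-mismatch) placement of each collapsed
   read on both strands, via a k-mer seed index (default k = 12) with full
   verification of every candidate. Multi-mapping reads split their count
   evenly across placements by default (`all` and `unique` policies are
   selectable).
3. **Locus definition** (`loci`). Alignments pooled across the genotype
   panel are merged single-linkage along each scaffold: two alignments join
   one locus iff the gap between them (next.start − prev.end on half-open
   intervals) is ≤ 200 bp, transitively; both strands pool into one locus.
   Each locus is categorised exon > transposon > intergenic by ≥ 1 bp
   overlap with the annotation, and described by strand bias
   (S − A)/(S + A) relative to the mRNA orientation, a length histogram
   over 18–25 nt, and the 5′-nucleotide composition, all weighted by
   normalized abundance (a distinct-sequence mode can be had by passing
   unit weights).
4. **Classification** (`classify`). Per locus and mutant,
   log₂((mutant + 1)/(wt + 1)); a locus is *down* in a mutant when its
   wild-type abundance is ≥ 50 per million and the fold change is
   ≤ −1.6 (both boundaries inclusive; 1.6, the conventional rounding, not
   log₂3 ≈ 1.585). The flag pattern assigns the class:
   dcl-2 down & rdrp-1 not → **I**; dcl-2 down & rdrp-1 down → **II**;
   neither single dicer down & double down & both rdrps down → **III**;
   dcl-1 down & dcl-2 not & both rdrps down → **IV**; anything else is
   unclassified. The *ago-1⁻* fold change is carried through as an outcome
   but never used for assignment.
5. **Binding** (`agobind`). A locus is Ago-1-bound when the IP-WT
   normalized abundance is ≥ 50 and the log₂ enrichment over the *ago-1⁻*
   IP control is ≥ 1.6. By default binding is evaluated on the
   panel-defined loci joined by id; re-clustering the IP alignments de novo
   is available through the same clustering API.
6. **Autolysis** (`lysis`). Plate scans are converted to 8-bit gray with
   ITU-R 601 luma weights (rounded half-up), banded into lysed area
   (gray 1–112) and mycelium (113–255), and summarised as
   100 × lysis / (lysis + mycelium) by default, or per plate area.
7. **Reporting** (`report`). Silencing frequency = 100 × albino / total
   transformants, rounded to one decimal; all percentages are recomputed
   from integer counts at render time, never from stored floats.

## The synthetic data generator

`simdata` is first-class, tested code, not a fixture. It emulates the
statistical structure the analysis assumes, with a ground-truth table so
every stage is verifiable without external downloads.

Default study conditions (all `SimConfig` fields):

| parameter | default | meaning |
|---|---|---|
| `n_scaffolds`, `scaffold_length` | 5 × 100 kb | random uniform ACGT genome |
| `loci_per_class` | I 9, II 20, III 20, IV 5 | class II scaled down from the full-scale 222 for desk-scale runs |
| `locus_length` | 300–800 bp uniform | exon length |
| `base_abundance` | log-normal(μ=8.2, σ=0.6) reads | expected WT reads per locus; the panel sums to ≈ 2×10⁵ reads per library, a free choice since source depths are unstated |
| `down_factor` | 0.05 | multiplier in dependent-mutant libraries; < 1/3 guarantees the planted drop exceeds the threefold call threshold; 1.0 gives the null panel |
| `noise_dispersion` | 0 | Poisson counts; > 0 switches to negative binomial (var = m + d·m²) |
| `length_profile` | I/II peaked at 23–24 nt, III/IV uniform 18–25 | |
| `strand_profile` | I/II 0.5, III 1.0 (all sense), IV 0.5 | probability a read is sense to the mRNA |
| `fp_profile` | I/II 5′-U 0.79, III 5′-A 0.79, IV uniform | |
| `background_fraction` | 0.001 | intergenic background reads, uniform over intergenic space on both strands |
| `ip_enrichment` | 16 | class I/II multiplier, IP-WT vs IP-control |
| `ip_background_fraction` | 0.8 | nonspecific carryover mass in both IP libraries |
| `min_locus_separation` | 3000 bp | pairwise gap between planted loci |

Class-specific biases are imposed by weighting the enumerated genomic
windows of each locus — weight ∝ P(length)·P(strand)·P(5′ base), normalised
within each (length, strand, base) cell so the marginals are exact — never
by editing sequence, so every read is an exact substring of the genome or
its reverse complement. A class profile that is unsatisfiable within a
locus (positive target probability on a cell with no windows, e.g. no 5′-U
window on a forced strand) raises an error naming the locus.

Dependency patterns follow the per-class table literally: class I drops in
*dcl-2⁻*; II in *dcl-2⁻* and *rdrp-1⁻*; III in the double dicer knockout
and both rdrps; IV in *dcl-1⁻* and both rdrps; *ago-1⁻* depresses all four.
The single-dicer libraries are left at full expectation for classes I/II
even in the double-knockout's components' classes — the classifier never
consults the double-mutant flag for classes I/II, so generator and decision
rule stay consistent.

### Design choices that required judgement

**Background density.** Single-linkage clustering with a 200 bp gap chains
any read set whose typical spacing falls below the gap. Because loci are
defined from the *pooled* panel (seven libraries), the uniform intergenic
background must stay sparse after pooling: at the default 0.001, pooled
background spacing is ≈ 270 bp, background forms hundreds of small
low-abundance loci (which the ≥ 50 abundance floor removes — the filter has
real work to do), and the chance of chaining a 3 kb corridor between two
planted loci is negligible. Much denser uniform background would merge
whole scaffolds into single loci; real libraries escape this because their
background is concentrated, not uniform.

**IP carryover.** With only ~54 planted loci, enriching classes I/II
16-fold and then normalizing per million would cancel most of the planted
enrichment (the enriched loci dominate the library total). Real IP
libraries are dominated by nonspecific carryover, so the generator gives
both IP libraries an 80% carryover mass emitted from ~40 discrete
intergenic hotspots (abundant degradation fragments co-purifying with the
protein fraction), identical in expectation in both libraries and placed
≥ 1 kb clear of planted loci. This keeps the library totals comparable,
leaves the planted threefold enrichment visible after normalization
(effective enrichment ≈ 4-fold, log₂ ≈ 2.0 after the 21–24 nt filter), and
adds nothing to locus envelopes.

**What the generator does not reproduce.** The *ago-1⁻* panel library
depresses every planted locus uniformly; per-million normalization is
scale-free, so at desk scale the measured *ago-1⁻* fold changes sit near
zero rather than at the planted log₂ 0.05 ≈ −4.3. This is exactly why the
full-scale per-class mean *ago-1⁻* fold changes are not recoverable without
the real libraries, where ex-siRNA loci are a small fraction of the
sequenced pool; the dicer/rdrp patterns, which move only part of the
library mass, are recovered essentially perfectly. Also not modelled:
sequencing error, adapters, quality scores, transposon-derived read
classes, and non-uniform genome composition.

## Numerical and policy choices

- Coordinates are 0-based half-open internally; GFF3 (1-based inclusive)
  is converted at the file boundary.
- Both dependency and binding calls use the same pseudocount (1 normalized
  unit) and inclusive thresholds, keeping the two threefold rules
  symmetric.
- The wild-type abundance floor (≥ 50) applies to all dependency calls and
  to the binding call, as a single global stringency filter.
- Ties in clustering cannot arise (single linkage over sorted intervals);
  ordering of alignments is canonicalised to (scaffold, start, strand), so
  identical inputs give byte-identical outputs.
- The reference lysis/mycelium gray bands overlap at 107–112; the overlap is given
  to lysis (mycelium effectively starts at 113) so the two masks partition
  gray 1–255; gray 0 stays unassigned background. The policy and both band
  edges are configurable.
- The autolysis denominator defaults to the colony area
  (lysis + mycelium); the plate-area variant is exposed.
- Intergenic loci take '+' as the strand-bias reference, flagged as a
  convention.
- Statistics weight reads by normalized abundance rather than distinct
  sequences; unit weights give the distinct-sequence variant.

## Problem sizes

Tests and the acceptance script run the default panel (5 × 100 kb genome,
54 planted loci, ≈ 2×10⁵ reads × 9 libraries) over 20 seeds for the
recovery experiments and 20 for the null, a deliberate desk-scale choice:
one panel simulates and analyses in roughly ten seconds, and the recovery
rates are estimated over ≈ 1000 planted loci. Oracle equivalence checks run
on ≤ 500-alignment clustering instances and ≤ 20 kb genomes where the
brute-force references are exact and fast.

## Known limitations

- Exact matching only; the original analysis allowed the aligner's (unstated)
  mismatch settings. A mismatch knob exists but defaults to 0-equivalent
  behaviour and no gapped or quality-aware mode is provided.
- The de-novo IP clustering mode shares the panel clustering code but is
  not exercised by the recovery experiments (the joined-loci mode is).
- Silencing-frequency tables carry no statistical test, mirroring the
  source tables, which report none.
- The plate segmenter assumes the scanner background maps to gray 0; no
  colony detection or registration across time points is attempted.
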