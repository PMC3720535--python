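"""Synthetic genomes and multi-genotype small-RNA libraries with planted loci.

The generator emulates the statistical structure the downstream analysis
assumes: a multi-scaffold random genome carrying non-overlapping exonic
sRNA-producing loci of four classes, each class with its own genotype
dependency pattern, read-length profile, strand preference and 5'-nucleotide
bias; plus uniform intergenic background reads, and a pair of Ago-1
immunoprecipitation libraries in which classes I and II are enriched over
the ago-1-mutant control.

Class dependency patterns (which mutant libraries see the planted drop):

  I    dcl-2
  II   dcl-2, rdrp-1
  III  dcl-1/dcl-2 double, rdrp-1, rdrp-2
  IV   dcl-1, rdrp-1, rdrp-2

and the ago-1 mutant depresses all four classes.

Reads are always exact substrings of the genome (or its reverse complement):
per-class biases are imposed by weighting the enumerated genomic windows of
each locus, never by editing sequence. Identical configurations (including
the seed) reproduce byte-identical outputs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .annotation import Annotation, write_gff3
from .libio import Library, write_collapsed_fasta

GENOTYPE_LIBRARIES = ("wt", "dcl1", "dcl2", "dcl1dcl2", "rdrp1", "rdrp2", "ago1")
IP_LIBRARIES = ("ip_wt", "ip_ago1")
ALL_LIBRARIES = GENOTYPE_LIBRARIES + IP_LIBRARIES

#: Mutant libraries in which each class's loci receive the planted drop.
DOWN_IN = {
    "I": frozenset({"dcl2", "ago1"}),
    "II": frozenset({"dcl2", "rdrp1", "ago1"}),
    "III": frozenset({"dcl1dcl2", "rdrp1", "rdrp2", "ago1"}),
    "IV": frozenset({"dcl1", "rdrp1", "rdrp2", "ago1"}),
}

READ_LENGTHS = tuple(range(18, 26))

_PEAKED = {18: 0.01, 19: 0.01, 20: 0.02, 21: 0.05, 22: 0.11,
           23: 0.40, 24: 0.35, 25: 0.05}
_UNIFORM_LEN = {n: 1.0 / len(READ_LENGTHS) for n in READ_LENGTHS}
_U_BIASED = {"T": 0.79, "A": 0.07, "C": 0.07, "G": 0.07}
_A_BIASED = {"A": 0.79, "C": 0.07, "G": 0.07, "T": 0.07}
_UNIFORM_FP = {"A": 0.25, "C": 0.25, "G": 0.25, "T": 0.25}

_BASES = "ACGT"
_COMP_IDX = np.array([3, 2, 1, 0])  # A<->T, C<->G on base indices


def _default_length_profile():
    return {"I": dict(_PEAKED), "II": dict(_PEAKED),
            "III": dict(_UNIFORM_LEN), "IV": dict(_UNIFORM_LEN)}


def _default_strand_profile():
    return {"I": 0.5, "II": 0.5, "III": 1.0, "IV": 0.5}


def _default_fp_profile():
    return {"I": dict(_U_BIASED), "II": dict(_U_BIASED),
            "III": dict(_A_BIASED), "IV": dict(_UNIFORM_FP)}


@dataclass
class SimConfig:
    """Study conditions for one synthetic panel.

    ``base_abundance`` gives the (mu, sigma) of the log-normal draw of
    expected wild-type reads per locus; with the default class sizes the
    panel sums to roughly 2e5 reads per library. ``down_factor`` multiplies
    a locus's expected count in its dependent-mutant libraries; values below
    1/3 guarantee the planted drop exceeds the threefold call threshold
    (1.0 gives a null panel with no planted effects). ``ip_background_
    fraction`` models the nonspecific carryover that dominates real IP
    libraries; without it, per-million normalization would cancel most of
    the planted IP enrichment. Carryover is emitted from a set of discrete
    intergenic hotspots (abundant degradation fragments co-purifying with
    the protein fraction), identical in expectation in both IP libraries.
    """

    seed: int = 0
    n_scaffolds: int = 5
    scaffold_length: int = 100_000
    loci_per_class: dict[str, int] = field(
        default_factory=lambda: {"I": 9, "II": 20, "III": 20, "IV": 5})
    locus_length: tuple[int, int] = (300, 800)
    base_abundance: tuple[float, float] = (8.2, 0.6)
    down_factor: float = 0.05
    noise_dispersion: float = 0.0
    length_profile: dict[str, dict[int, float]] = field(
        default_factory=_default_length_profile)
    strand_profile: dict[str, float] = field(
        default_factory=_default_strand_profile)
    fp_profile: dict[str, dict[str, float]] = field(
        default_factory=_default_fp_profile)
    background_fraction: float = 0.001
    ip_enrichment: float = 16.0
    ip_background_fraction: float = 0.8
    ip_carryover_loci: int = 40
    ip_carryover_length: tuple[int, int] = (80, 200)
    min_locus_separation: int = 3000

    def validate(self) -> None:
        if any(n < 0 for n in self.loci_per_class.values()):
            raise ValueError("loci_per_class counts must be >= 0")
        if not 0.0 < self.down_factor <= 1.0:
            raise ValueError("down_factor must lie in (0, 1]")
        if not 0.0 <= self.background_fraction < 1.0:
            raise ValueError("background_fraction must lie in [0, 1)")
        if not 0.0 <= self.ip_background_fraction < 1.0:
            raise ValueError("ip_background_fraction must lie in [0, 1)")
        if self.noise_dispersion < 0:
            raise ValueError("noise_dispersion must be >= 0")
        for cls, prof in self.length_profile.items():
            if abs(sum(prof.values()) - 1.0) > 1e-9:
                raise ValueError(f"length_profile[{cls}] must sum to 1")
        for cls, prof in self.fp_profile.items():
            if abs(sum(prof.values()) - 1.0) > 1e-9:
                raise ValueError(f"fp_profile[{cls}] must sum to 1")
        for cls, p in self.strand_profile.items():
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"strand_profile[{cls}] must lie in [0, 1]")


TRUTH_COLUMNS = [
    "locus_id", "scaffold", "start", "end", "class", "strand",
    "sense_fraction", "fp_A", "fp_C", "fp_G", "fp_T", "base_reads",
] + [f"exp_{lib}" for lib in ALL_LIBRARIES]


def generate_genome(config: SimConfig
                    ) -> tuple[dict[str, str], Annotation, pd.DataFrame]:
    """Random genome, exon annotation, and truth table of planted loci.

    Loci are placed uniformly at random subject to pairwise separation of at
    least ``min_locus_separation`` bp (so proximity clustering cannot merge
    neighbours through a short bridge); an error names that constraint when
    the requested loci cannot be placed.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    scaffolds = [f"scaffold_{i + 1}" for i in range(config.n_scaffolds)]
    codes = {s: rng.integers(0, 4, size=config.scaffold_length).astype(np.uint8)
             for s in scaffolds}
    genome = {s: "".join(_BASES[b] for b in codes[s]) for s in scaffolds}

    n_total = sum(config.loci_per_class.values())
    lo, hi = config.locus_length
    demand = n_total * (hi + config.min_locus_separation)
    capacity = config.n_scaffolds * config.scaffold_length
    if n_total and demand > capacity:
        raise ValueError(
            "requested loci do not fit without overlap: "
            f"{n_total} loci x ~{hi + config.min_locus_separation} bp "
            f"exceed genome of {capacity} bp")

    placed: dict[str, list[tuple[int, int]]] = {s: [] for s in scaffolds}
    rows = []
    idx = 0
    for cls in ("I", "II", "III", "IV"):
        for _ in range(config.loci_per_class.get(cls, 0)):
            length = int(rng.integers(lo, hi + 1))
            for attempt in range(1000):
                scaffold = scaffolds[int(rng.integers(len(scaffolds)))]
                start = int(rng.integers(0, config.scaffold_length - length))
                end = start + length
                sep = config.min_locus_separation
                if all(start - e >= sep or s - end >= sep
                       for s, e in placed[scaffold]):
                    break
            else:
                raise ValueError(
                    "requested loci do not fit without overlap at "
                    f"min_locus_separation={config.min_locus_separation}")
            placed[scaffold].append((start, end))
            strand = "+" if rng.random() < 0.5 else "-"
            base = float(rng.lognormal(*config.base_abundance))
            fp = config.fp_profile[cls]
            rows.append({
                "locus_id": f"planted_{idx:04d}", "scaffold": scaffold,
                "start": start, "end": end, "class": cls, "strand": strand,
                "sense_fraction": config.strand_profile[cls],
                **{f"fp_{b}": fp.get(b, 0.0) for b in _BASES},
                "base_reads": base,
            })
            idx += 1

    truth = pd.DataFrame(rows, columns=[c for c in TRUTH_COLUMNS
                                        if not c.startswith("exp_")])
    truth = _add_expectations(truth, config)

    features = pd.DataFrame(
        [(r.scaffold, "exon", r.start, r.end, r.strand, r.locus_id)
         for r in truth.itertuples(index=False)],
        columns=["scaffold", "type", "start", "end", "strand", "feature_id"])
    annotation = Annotation(features,
                            {s: config.scaffold_length for s in scaffolds})
    return genome, annotation, truth


def _add_expectations(truth: pd.DataFrame, config: SimConfig) -> pd.DataFrame:
    """Per-library expected locus counts implied by the dependency patterns."""
    truth = truth.copy()
    base = truth["base_reads"].to_numpy() if len(truth) else np.array([])
    for lib in GENOTYPE_LIBRARIES:
        factor = np.array([
            config.down_factor if lib in DOWN_IN[c] else 1.0
            for c in truth["class"]])
        truth[f"exp_{lib}"] = base * factor
    # IP model: both IP libraries carry heavy nonspecific background; the
    # specific fraction is proportional to base expression, multiplied by
    # ip_enrichment for classes I/II in the wild-type pulldown only.
    total = base.sum()
    depth = total / (1.0 - config.background_fraction) if total else 0.0
    specific = (1.0 - config.ip_background_fraction) * depth
    scale = specific / total if total else 0.0
    truth["exp_ip_ago1"] = base * scale
    enrich = np.array([
        config.ip_enrichment if c in ("I", "II") else 1.0
        for c in truth["class"]])
    truth["exp_ip_wt"] = base * scale * enrich
    return truth


def expected_background(truth: pd.DataFrame, config: SimConfig,
                        library: str) -> float:
    """Expected background read count for one library."""
    total = truth["base_reads"].sum() if len(truth) else 0.0
    depth = total / (1.0 - config.background_fraction)
    if library in IP_LIBRARIES:
        return config.ip_background_fraction * depth
    return config.background_fraction * depth


# ---------------------------------------------------------------------------
# Window enumeration and sampling
# ---------------------------------------------------------------------------

class _LocusWindows:
    """All genomic read windows of one locus with class-profile weights."""

    __slots__ = ("scaffold", "pos", "length", "strand", "probs")

    def __init__(self, locus_row, codes: dict[str, np.ndarray],
                 config: SimConfig, profiles=None):
        cls = locus_row["class"]
        scaffold = locus_row["scaffold"]
        s0, e0 = int(locus_row["start"]), int(locus_row["end"])
        mrna = locus_row["strand"]
        code = codes[scaffold]
        if profiles is not None:
            p_len, p_sense, p_fp = profiles
        else:
            p_len = config.length_profile[cls]
            p_sense = config.strand_profile[cls]
            p_fp = config.fp_profile[cls]

        pos_l, len_l, strand_l, base_l = [], [], [], []
        for length in READ_LENGTHS:
            n_pos = e0 - s0 - length + 1
            if n_pos <= 0:
                continue
            starts = np.arange(s0, s0 + n_pos)
            # read strand '+' => first base at start; '-' => complement of last
            for strand, first in (("+", code[starts]),
                                  ("-", _COMP_IDX[code[starts + length - 1]])):
                pos_l.append(starts)
                len_l.append(np.full(n_pos, length))
                strand_l.append(np.full(n_pos, strand == "+"))
                base_l.append(first)
        self.scaffold = scaffold
        self.pos = np.concatenate(pos_l)
        self.length = np.concatenate(len_l)
        self.strand = np.concatenate(strand_l)  # True == '+'
        base = np.concatenate(base_l)

        # cell = (length, read strand, 5' base); weights put the exact class
        # marginals on each factor by normalising within cells
        len_idx = self.length - READ_LENGTHS[0]
        cell = (len_idx * 2 + self.strand.astype(int)) * 4 + base
        n_cells = len(READ_LENGTHS) * 2 * 4
        counts = np.bincount(cell, minlength=n_cells)
        target = np.zeros(n_cells)
        for li, length in enumerate(READ_LENGTHS):
            for si, is_plus in enumerate((False, True)):
                # sense means read strand equals the mRNA strand
                sense = (mrna == "+") == is_plus
                ps = p_sense if sense else 1.0 - p_sense
                for bi, b in enumerate(_BASES):
                    c = (li * 2 + int(is_plus)) * 4 + bi
                    target[c] = p_len.get(length, 0.0) * ps * p_fp.get(b, 0.0)
        unsatisfiable = (target > 0) & (counts == 0)
        if unsatisfiable.any():
            c = int(np.argmax(unsatisfiable))
            b = _BASES[c % 4]
            raise ValueError(
                f"class profile unsatisfiable within locus "
                f"{locus_row['locus_id']}: no window with 5' base {b}")
        with np.errstate(divide="ignore", invalid="ignore"):
            per_window = np.where(counts > 0, target / counts, 0.0)
        self.probs = per_window[cell]
        self.probs = self.probs / self.probs.sum()

    def draw(self, total: int, rng: np.random.Generator,
             genome: dict[str, str]) -> dict[str, int]:
        """Multinomial draw of ``total`` reads over the windows."""
        if total <= 0:
            return {}
        counts = rng.multinomial(total, self.probs)
        nz = np.nonzero(counts)[0]
        seq = genome[self.scaffold]
        out: dict[str, int] = {}
        for i in nz:
            p, n = int(self.pos[i]), int(self.length[i])
            read = seq[p:p + n]
            if not self.strand[i]:
                read = _revcomp(read)
            out[read] = out.get(read, 0) + int(counts[i])
        return out


_COMP_TABLE = str.maketrans("ACGT", "TGCA")


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP_TABLE)[::-1]


def _intergenic_intervals(config: SimConfig, truth: pd.DataFrame,
                          scaffolds: list[str]) -> list[tuple[str, int, int]]:
    out = []
    for scaffold in scaffolds:
        loci = sorted(
            (int(r.start), int(r.end))
            for r in truth.itertuples(index=False) if r.scaffold == scaffold)
        prev = 0
        for s, e in loci:
            if s > prev:
                out.append((scaffold, prev, s))
            prev = max(prev, e)
        if prev < config.scaffold_length:
            out.append((scaffold, prev, config.scaffold_length))
    return out


def _draw_background(total: int, intervals: list[tuple[str, int, int]],
                     genome: dict[str, str], rng: np.random.Generator
                     ) -> dict[str, int]:
    """Uniform background reads from intergenic space, both strands."""
    if total <= 0 or not intervals:
        return {}
    out: dict[str, int] = {}
    lengths = rng.integers(READ_LENGTHS[0], READ_LENGTHS[-1] + 1, size=total)
    strands = rng.random(total) < 0.5
    for length in np.unique(lengths):
        n = int((lengths == length).sum())
        valid = np.array([max(0, e - s - int(length) + 1)
                          for _, s, e in intervals])
        if valid.sum() == 0:
            continue
        cum = np.cumsum(valid)
        offsets = rng.integers(0, cum[-1], size=n)
        ividx = np.searchsorted(cum, offsets, side="right")
        sub_strands = strands[lengths == length]
        for off, ii, plus in zip(offsets, ividx, sub_strands):
            scaffold, s, _e = intervals[ii]
            start = s + int(off) - (int(cum[ii - 1]) if ii else 0)
            read = genome[scaffold][start:start + int(length)]
            if not plus:
                read = _revcomp(read)
            out[read] = out.get(read, 0) + 1
    return out


def _draw_total(mean: float, dispersion: float,
                rng: np.random.Generator) -> int:
    """Poisson count, or negative binomial when overdispersed
    (variance = mean + dispersion * mean^2)."""
    if mean <= 0:
        return 0
    if dispersion > 0:
        n = 1.0 / dispersion
        p = n / (n + mean)
        return int(rng.negative_binomial(n, p))
    return int(rng.poisson(mean))


def simulate_libraries(genome: dict[str, str], truth: pd.DataFrame,
                       config: SimConfig) -> dict[str, Library]:
    """Collapsed-read libraries for the genotype panel and the IP pair.

    Every emitted read is an exact substring of the genome or its reverse
    complement. Per-locus totals are Poisson (or negative-binomial) around
    the truth table's per-library expectations; within a locus, reads are
    drawn from the enumerated windows under the class profiles.
    """
    config.validate()
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    scaffolds = sorted(genome)
    codes = {s: np.frombuffer(genome[s].encode(), dtype=np.uint8)
             for s in scaffolds}
    lut = np.zeros(256, dtype=np.uint8)
    for i, b in enumerate(_BASES):
        lut[ord(b)] = i
    codes = {s: lut[c] for s, c in codes.items()}

    windows = [_LocusWindows(row, codes, config)
               for _, row in truth.iterrows()]
    intervals = _intergenic_intervals(config, truth, scaffolds)
    hot_windows, hot_means = _carryover_hotspots(
        genome, codes, truth, intervals, config, rng)

    libraries: dict[str, Library] = {}
    for lib in ALL_LIBRARIES:
        reads: dict[str, int] = {}
        exp = truth[f"exp_{lib}"].to_numpy() if len(truth) else np.array([])
        for w, mean in zip(windows, exp):
            for seq, n in w.draw(
                    _draw_total(mean, config.noise_dispersion, rng),
                    rng, genome).items():
                reads[seq] = reads.get(seq, 0) + n
        if len(truth) and lib in IP_LIBRARIES:
            for w, mean in zip(hot_windows, hot_means):
                for seq, n in w.draw(_draw_total(mean, 0.0, rng),
                                     rng, genome).items():
                    reads[seq] = reads.get(seq, 0) + n
        elif len(truth):
            bg_total = _draw_total(
                expected_background(truth, config, lib), 0.0, rng)
            for seq, n in _draw_background(bg_total, intervals,
                                           genome, rng).items():
                reads[seq] = reads.get(seq, 0) + n
        genotype = lib.replace("ip_", "")
        libraries[lib] = Library(name=lib, genotype=genotype, reads=reads)
    return libraries


_BG_PROFILES = (dict(_UNIFORM_LEN), 0.5, dict(_UNIFORM_FP))


def _carryover_hotspots(genome, codes, truth, intervals, config,
                        rng) -> tuple[list[_LocusWindows], np.ndarray]:
    """Discrete intergenic hotspots emitting the nonspecific IP carryover.

    Hotspots sit well clear of planted loci so carryover cannot leak into
    locus envelopes; expected emission is shared by both IP libraries, with
    log-normal rate variation across hotspots.
    """
    n_hot = config.ip_carryover_loci
    if n_hot <= 0 or len(truth) == 0:
        return [], np.array([])
    lo, hi = config.ip_carryover_length
    margin = 1000
    usable = [(s, a + margin, b - margin - hi) for s, a, b in intervals
              if b - a > 2 * margin + hi]
    if not usable:
        return [], np.array([])
    spans = np.array([b - a for _, a, b in usable], dtype=float)
    probs = spans / spans.sum()
    rows = []
    for j in range(n_hot):
        scaffold, a, b = usable[int(rng.choice(len(usable), p=probs))]
        start = int(rng.integers(a, b))
        length = int(rng.integers(lo, hi + 1))
        rows.append({"class": "_carryover", "scaffold": scaffold,
                     "start": start, "end": start + length, "strand": "+",
                     "locus_id": f"carryover_{j:03d}"})
    weights = rng.lognormal(0.0, 1.0, size=n_hot)
    total = expected_background(truth, config, "ip_wt")
    means = total * weights / weights.sum()
    hot = [_LocusWindows(r, codes, config, profiles=_BG_PROFILES)
           for r in rows]
    return hot, means


@dataclass
class SimResult:
    config: SimConfig
    genome: dict[str, str]
    annotation: Annotation
    truth: pd.DataFrame
    libraries: dict[str, Library]


def simulate(config: SimConfig) -> SimResult:
    """Convenience wrapper: genome + annotation + truth + all libraries."""
    genome, annotation, truth = generate_genome(config)
    libraries = simulate_libraries(genome, truth, config)
    return SimResult(config, genome, annotation, truth, libraries)


def write_outputs(result: SimResult, outdir: str | Path) -> None:
    """Write genome FASTA, GFF3, truth TSV and collapsed library FASTAs."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    with open(outdir / "genome.fa", "w") as fh:
        for scaffold in sorted(result.genome):
            fh.write(f">{scaffold}\n")
            seq = result.genome[scaffold]
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    write_gff3(result.annotation, outdir / "annotation.gff3")
    result.truth.to_csv(outdir / "truth.tsv", sep="\t", index=False,
                        float_format="%.6g")
    for name in sorted(result.libraries):
        write_collapsed_fasta(result.libraries[name],
                              outdir / f"{name}.fa")
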