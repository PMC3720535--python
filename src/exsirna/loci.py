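"""Proximity-defined sRNA loci and their descriptive statistics.

Alignments lying within a maximum gap (default 200 bp, inclusive) of each
other along a scaffold are merged transitively into loci, pooling both
strands. Each locus is then categorised against the annotation (exon beats
transposon beats intergenic) and described by its strand bias relative to the
mRNA orientation, its read-length histogram over 18-25 nt, and the nucleotide
composition at the 5' position, all weighted by read abundance.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .annotation import Annotation

log = logging.getLogger(__name__)

DEFAULT_MAX_GAP = 200
SIZE_RANGE = range(18, 26)

#: Categories in precedence order; a locus takes the first one it overlaps.
CATEGORY_PRECEDENCE = ("exon", "transposon")


def cluster_alignments(alignments: pd.DataFrame,
                       max_gap: int = DEFAULT_MAX_GAP) -> pd.DataFrame:
    """Single-linkage merge of alignments into loci along each scaffold.

    Two alignments join one locus iff the gap between them
    (next.start - prev.end) is <= max_gap, transitively; strands are pooled.
    Returns the input table with a ``locus`` id column added, ordered by
    (scaffold, start).
    """
    if max_gap < 0:
        raise ValueError("max_gap must be >= 0")
    if len(alignments) == 0:
        out = alignments.copy()
        out["locus"] = pd.Series(dtype=str)
        return out
    df = alignments.sort_values(["scaffold", "start", "end"],
                                kind="stable").reset_index(drop=True)
    ids = np.empty(len(df), dtype=np.int64)
    counter = 0
    for _, grp in df.groupby("scaffold", sort=True):
        starts = grp["start"].to_numpy()
        ends = grp["end"].to_numpy()
        running_end = np.maximum.accumulate(ends)
        # a new locus starts where the gap to everything before exceeds max_gap
        new_locus = np.ones(len(grp), dtype=bool)
        new_locus[1:] = starts[1:] - running_end[:-1] > max_gap
        grp_ids = np.cumsum(new_locus) - 1 + counter
        counter = int(grp_ids[-1]) + 1
        ids[grp.index] = grp_ids
    labels = np.array([f"locus_{i:05d}" for i in range(counter)], dtype=object)
    df["locus"] = labels[ids]
    return df


def locus_envelopes(clustered: pd.DataFrame) -> pd.DataFrame:
    """Per-locus envelope intervals (min start, max end) from clustered reads."""
    env = clustered.groupby("locus").agg(
        scaffold=("scaffold", "first"),
        start=("start", "min"),
        end=("end", "max"),
    ).reset_index()
    return env.sort_values(["scaffold", "start"], kind="stable").reset_index(drop=True)


def assign_category(scaffold: str, start: int, end: int,
                    annotation: Annotation) -> tuple[str, str]:
    """(category, sense_strand) of a locus interval.

    Category is ``exon`` if the locus overlaps any exon feature by >= 1 bp,
    else ``transposon`` if it overlaps a transposon, else ``intergenic``.
    The sense reference strand is the strand of the best-overlapping feature
    of the winning type; intergenic loci use '+' by convention (flagged in
    output as convention-dependent).
    """
    hits = annotation.overlapping(scaffold, start, end)
    for wanted in CATEGORY_PRECEDENCE:
        for ftype, strand, _fid, _ov in hits:
            if ftype == wanted:
                return wanted, strand
    return "intergenic", "+"


def strand_bias(sense_mass: float, antisense_mass: float) -> float:
    """(S - A) / (S + A); +1 all sense, 0 balanced, -1 all antisense.

    Undefined (NaN) when the locus carries no weighted reads.
    """
    total = sense_mass + antisense_mass
    if total <= 0:
        return float("nan")
    return (sense_mass - antisense_mass) / total


def size_distribution(lengths: np.ndarray, weights: np.ndarray) -> pd.Series:
    """Abundance-weighted histogram over 18-25 nt.

    Lengths outside the range are pooled into the nearest edge bin with a
    warning. An empty locus yields an all-zero histogram.
    """
    hist = pd.Series(0.0, index=list(SIZE_RANGE))
    if len(lengths) == 0:
        return hist
    lengths = np.asarray(lengths)
    weights = np.asarray(weights, dtype=float)
    if (lengths < SIZE_RANGE.start).any() or (lengths > SIZE_RANGE.stop - 1).any():
        log.warning("size_distribution: lengths outside 18-25 pooled into edge bins")
    clipped = np.clip(lengths, SIZE_RANGE.start, SIZE_RANGE.stop - 1)
    for length, w in zip(clipped, weights):
        hist[int(length)] += w
    return hist


def five_prime_composition(sequences, weights=None) -> dict[str, float]:
    """Abundance-weighted fraction of A/C/G/U at the 5' position.

    T is reported as U (reads are RNA stored in DNA alphabet). Returns an
    empty dict for an empty read set (composition undefined).
    """
    sequences = list(sequences)
    if not sequences:
        return {}
    if weights is None:
        weights = np.ones(len(sequences))
    totals = {"A": 0.0, "C": 0.0, "G": 0.0, "U": 0.0}
    for seq, w in zip(sequences, weights):
        base = seq[0].upper().replace("T", "U")
        totals[base] += w
    grand = sum(totals.values())
    return {b: v / grand for b, v in totals.items()}


def naive_cluster(intervals: list[tuple[int, int]], max_gap: int) -> list[set[int]]:
    """Transitive-closure clustering oracle: O(n^2) pairwise merging.

    Intervals i, j are linked iff the gap between them (start of the later
    minus end of the earlier, or any overlap) is <= max_gap; clusters are the
    connected components. Used only to validate ``cluster_alignments``.
    """
    n = len(intervals)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i, j):
        parent[find(i)] = find(j)

    for i in range(n):
        si, ei = intervals[i]
        for j in range(i + 1, n):
            sj, ej = intervals[j]
            gap = max(si, sj) - min(ei, ej)
            if gap <= max_gap:
                union(i, j)
    groups: dict[int, set[int]] = {}
    for i in range(n):
        groups.setdefault(find(i), set()).add(i)
    return list(groups.values())


# ---------------------------------------------------------------------------
# Locus table assembly
# ---------------------------------------------------------------------------

def build_locus_table(clustered: pd.DataFrame,
                      annotation: Annotation,
                      total_mapped: dict[str, float],
                      stats_library: str | None = None) -> pd.DataFrame:
    """Assemble the per-locus table from clustered multi-library alignments.

    ``clustered`` must carry ``library``, ``locus``, ``weight`` columns (one
    row per alignment placement per library). Per-library abundance is the
    summed placement weight normalised to reads per million mapped in that
    library. Descriptive statistics (strand bias, size histogram, 5'
    composition) are computed from ``stats_library`` (default: the library
    named 'wt' if present, else all libraries pooled).
    """
    from .libio import normalize_abundance

    env = locus_envelopes(clustered)
    cats = [assign_category(r.scaffold, r.start, r.end, annotation)
            for r in env.itertuples(index=False)]
    env["category"] = [c[0] for c in cats]
    env["sense_strand"] = [c[1] for c in cats]

    # per-library normalized abundance
    mass = clustered.groupby(["locus", "library"])["weight"].sum().unstack(
        fill_value=0.0)
    for lib in total_mapped:
        if lib not in mass.columns:
            mass[lib] = 0.0
    abundance = pd.DataFrame(
        {lib: [normalize_abundance(v, total_mapped[lib]) for v in mass[lib]]
         for lib in sorted(total_mapped)},
        index=mass.index,
    )
    abundance.columns = [f"ab_{c}" for c in abundance.columns]
    env = env.merge(abundance, left_on="locus", right_index=True, how="left")
    env[abundance.columns] = env[abundance.columns].fillna(0.0)

    if stats_library is None:
        stats_library = "wt" if (clustered["library"] == "wt").any() else None
    stats_rows = (clustered if stats_library is None else
                  clustered[clustered["library"] == stats_library]).copy()

    # vectorised per-locus statistics, all weighted by placement weight
    sense_ref = env.set_index("locus")["sense_strand"]
    stats_rows["is_sense"] = (
        stats_rows["strand"] == stats_rows["locus"].map(sense_ref))
    mass_by_strand = stats_rows.groupby(["locus", "is_sense"])["weight"].sum(
        ).unstack(fill_value=0.0).reindex(columns=[True, False], fill_value=0.0)
    env["strand_bias"] = env["locus"].map(
        (mass_by_strand[True] - mass_by_strand[False])
        / (mass_by_strand[True] + mass_by_strand[False]))

    stats_rows["read_len"] = (stats_rows["end"] - stats_rows["start"]).clip(
        SIZE_RANGE.start, SIZE_RANGE.stop - 1)
    hist = stats_rows.groupby(["locus", "read_len"])["weight"].sum().unstack(
        fill_value=0.0).reindex(columns=list(SIZE_RANGE), fill_value=0.0)
    for length in SIZE_RANGE:
        env[f"len_{length}"] = env["locus"].map(hist[length])
    env["peak_length"] = env["locus"].map(hist.idxmax(axis=1))

    stats_rows["fp"] = stats_rows["read"].str[0].replace("T", "U")
    comp = stats_rows.groupby(["locus", "fp"])["weight"].sum().unstack(
        fill_value=0.0).reindex(columns=list("ACGU"), fill_value=0.0)
    comp = comp.div(comp.sum(axis=1), axis=0)
    env["fp_U"] = env["locus"].map(comp["U"])
    env["fp_A"] = env["locus"].map(comp["A"])
    return env
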