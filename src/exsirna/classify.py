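"""Mutant-dependency classification of exonic siRNA loci.

Each exonic locus is compared between every biogenesis mutant and the wild
type on the log2 scale. A locus counts as down-regulated in a mutant when the
wild-type abundance clears a stringency floor (normalized count >= 50) and
the log2 fold change is at or below -1.6 (the conventional round threefold
threshold, not log2(3)). The pattern of down flags across the dicer / rdrp
genotypes
assigns the locus to ex-siRNA class I-IV:

  I    dcl-2 dependent, rdrp-1 independent
  II   dcl-2 and rdrp-1 dependent
  III  redundant dicers (down only in the dcl-1/dcl-2 double), rdrp-1 and
       rdrp-2 dependent
  IV   dcl-1 dependent (dcl-2 independent), rdrp-1 and rdrp-2 dependent

The ago-1 mutant is carried through the fold-change table but is an outcome
reported per class, not a classification input.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

#: Biogenesis genotypes consulted by the decision rule, in evaluation order.
PANEL_GENOTYPES = ("dcl1", "dcl2", "dcl1dcl2", "rdrp1", "rdrp2", "ago1")
CLASS_LABELS = ("I", "II", "III", "IV")
UNCLASSIFIED = "unclassified"


@dataclass(frozen=True)
class Thresholds:
    """Dependency-call thresholds shared by the down and binding rules."""

    fold_log2: float = 1.6
    min_wt_abundance: float = 50.0
    pseudocount: float = 1.0

    def __post_init__(self):
        if self.fold_log2 <= 0:
            raise ValueError("fold_log2 must be > 0")
        if self.min_wt_abundance < 0:
            raise ValueError("min_wt_abundance must be >= 0")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")


def log2_fold_change(mutant_ab: float, wt_ab: float,
                     pseudocount: float = 1.0) -> float:
    """log2((mutant + pseudocount) / (wt + pseudocount))."""
    if mutant_ab < 0 or wt_ab < 0:
        raise ValueError("abundances must be >= 0")
    return math.log2((mutant_ab + pseudocount) / (wt_ab + pseudocount))


def call_down(fc: float, wt_ab: float,
              thresholds: Thresholds = Thresholds()) -> bool:
    """Down-regulated iff WT abundance clears the floor and fc <= -fold_log2.

    Both boundaries are inclusive: fc == -1.6 at wt == 50 is a call.
    """
    return wt_ab >= thresholds.min_wt_abundance and fc <= -thresholds.fold_log2


def assign_class(down: dict[str, bool]) -> str:
    """Class label from the per-genotype down flags.

    Ordered decision rule; branches for classes I/II consult only dcl-2 and
    rdrp-1 (the dcl-2 fold change separates the classes), III/IV additionally
    require both rdrp genes and discriminate on which dicer context is down.
    """
    for g in ("dcl1", "dcl2", "dcl1dcl2", "rdrp1", "rdrp2"):
        if g not in down:
            raise KeyError(f"missing down flag for genotype: {g}")
    dcl1, dcl2 = down["dcl1"], down["dcl2"]
    double, rdrp1, rdrp2 = down["dcl1dcl2"], down["rdrp1"], down["rdrp2"]
    if dcl2 and not rdrp1:
        return "I"
    if dcl2 and rdrp1:
        return "II"
    if not dcl2 and not dcl1 and double and rdrp1 and rdrp2:
        return "III"
    if dcl1 and not dcl2 and rdrp1 and rdrp2:
        return "IV"
    return UNCLASSIFIED


def classify_loci(locus_table: pd.DataFrame,
                  thresholds: Thresholds = Thresholds(),
                  category: str | None = "exon") -> pd.DataFrame:
    """Fold changes, down flags and class labels for loci of one category.

    Expects per-library abundance columns ``ab_wt``, ``ab_dcl1`` ... as built
    by :func:`exsirna.loci.build_locus_table`. Loci whose wild-type abundance
    is below the stringency floor are excluded entirely,
    as are loci outside the requested category (default exonic).
    """
    df = locus_table
    if category is not None:
        df = df[df["category"] == category]
    df = df[df["ab_wt"] >= thresholds.min_wt_abundance].copy()
    for g in PANEL_GENOTYPES:
        df[f"fc_{g}"] = [
            log2_fold_change(m, w, thresholds.pseudocount)
            for m, w in zip(df[f"ab_{g}"], df["ab_wt"])]
        df[f"down_{g}"] = [
            call_down(fc, w, thresholds)
            for fc, w in zip(df[f"fc_{g}"], df["ab_wt"])]
    df["class"] = [
        assign_class({g: row[f"down_{g}"] for g in PANEL_GENOTYPES})
        for _, row in df.iterrows()]
    return df


def summarize_classes(class_calls: pd.DataFrame) -> pd.DataFrame:
    """Per-class locus count and mean ago-1 vs WT log2 fold change.

    One row per class I-IV (count 0 and missing mean for empty classes) plus
    an 'unclassified' row when any locus fell through the rule.
    """
    rows = []
    labels = list(CLASS_LABELS)
    if (class_calls["class"] == UNCLASSIFIED).any():
        labels.append(UNCLASSIFIED)
    for label in labels:
        members = class_calls[class_calls["class"] == label]
        rows.append({
            "class": label,
            "n_loci": len(members),
            "mean_fc_ago1": members["fc_ago1"].mean() if len(members) else np.nan,
        })
    return pd.DataFrame(rows)
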