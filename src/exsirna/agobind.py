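"""Ago-1 binding calls from immunoprecipitation (IP) libraries.

A locus is called Ago-1-bound when its normalized abundance in the Ago-1
fraction purified from the wild type shows at least a threefold increase over
the equivalent fraction from the ago-1 mutant (log2 fold change >= 1.6,
boundary inclusive) and clears the same wild-type abundance floor used for
the dependency calls. IP libraries are length-filtered to 21-24 nt upstream
of mapping.

By default binding is evaluated on the loci defined from the genotype panel
(joined by locus id); a de-novo mode re-clusters the IP alignments instead.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .classify import Thresholds, log2_fold_change, CLASS_LABELS, UNCLASSIFIED
from .loci import five_prime_composition

log = logging.getLogger(__name__)

IP_MIN_NT = 21
IP_MAX_NT = 24


def call_bound(ip_wt_ab: float, ip_ago_ab: float,
               thresholds: Thresholds = Thresholds()) -> bool:
    """Bound iff IP-WT abundance >= floor and log2 enrichment >= fold_log2."""
    fc = log2_fold_change(ip_wt_ab, ip_ago_ab, thresholds.pseudocount)
    return ip_wt_ab >= thresholds.min_wt_abundance and fc >= thresholds.fold_log2


def binding_table(locus_table: pd.DataFrame,
                  thresholds: Thresholds = Thresholds(),
                  ip_wt: str = "ab_ip_wt",
                  ip_ago: str = "ab_ip_ago1") -> pd.DataFrame:
    """Per-locus IP abundances, enrichment fold change and bound flag."""
    df = locus_table[["locus", ip_wt, ip_ago]].copy()
    df["fc_ip"] = [log2_fold_change(w, a, thresholds.pseudocount)
                   for w, a in zip(df[ip_wt], df[ip_ago])]
    df["bound"] = [call_bound(w, a, thresholds)
                   for w, a in zip(df[ip_wt], df[ip_ago])]
    return df


def crosstab_classes(binding: pd.DataFrame,
                     class_calls: pd.DataFrame) -> pd.DataFrame:
    """Per-class bound counts, percentage (2 decimals) and mean enrichment.

    Percentages are computed from integer counts at output time; a class with
    no bound members reports 0% and a missing mean fold change.
    """
    merged = class_calls[["locus", "class"]].merge(binding, on="locus")
    rows = []
    labels = list(CLASS_LABELS)
    if (merged["class"] == UNCLASSIFIED).any():
        labels.append(UNCLASSIFIED)
    for label in labels:
        members = merged[merged["class"] == label]
        bound = members[members["bound"]]
        pct = round(100.0 * len(bound) / len(members), 2) if len(members) else np.nan
        rows.append({
            "class": label,
            "n_loci": len(members),
            "n_bound": len(bound),
            "pct_bound": pct,
            "mean_fc_bound": bound["fc_ip"].mean() if len(bound) else np.nan,
        })
    return pd.DataFrame(rows)


def denovo_binding_table(ip_alignments: pd.DataFrame,
                         total_mapped: dict[str, float],
                         annotation,
                         thresholds: Thresholds = Thresholds(),
                         max_gap: int | None = None) -> pd.DataFrame:
    """Binding calls on loci re-clustered from the IP alignments themselves.

    The alternative to joining panel-defined loci by id: the IP pair's own
    alignments (already 21-24 nt filtered and mapped, with a ``library``
    column naming ``ip_wt`` / ``ip_ago1``) define the locus set, and every
    de-novo locus gets an enrichment call. Returns the locus table with the
    ``fc_ip`` and ``bound`` columns appended.
    """
    from .loci import DEFAULT_MAX_GAP, build_locus_table, cluster_alignments

    clustered = cluster_alignments(
        ip_alignments, DEFAULT_MAX_GAP if max_gap is None else max_gap)
    table = build_locus_table(clustered, annotation, total_mapped,
                              stats_library="ip_wt")
    calls = binding_table(table, thresholds)[["locus", "fc_ip", "bound"]]
    return table.merge(calls, on="locus")


def bound_fp_composition(binding: pd.DataFrame,
                         clustered: pd.DataFrame,
                         library: str = "ip_wt") -> dict[str, float]:
    """5' nucleotide composition over reads of bound loci in an IP library.

    Delegates to the locus-level composition statistic; returns an empty dict
    with a warning when no locus is bound.
    """
    bound_ids = set(binding.loc[binding["bound"], "locus"])
    if not bound_ids:
        log.warning("bound_fp_composition: no bound loci")
        return {}
    rows = clustered[(clustered["library"] == library)
                     & clustered["locus"].isin(bound_ids)]
    return five_prime_composition(rows["read"].tolist(),
                                  rows["weight"].to_numpy())
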