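"""End-to-end analysis: libraries -> alignments -> loci -> classes -> binding.

The genotype panel (wild type plus six biogenesis mutants) defines the locus
set: alignments from those libraries are pooled and clustered by proximity.
The IP pair is length-filtered to 21-24 nt, mapped, and its reads are
assigned to the panel-defined loci for the binding comparison (a de-novo
clustering of IP reads is available separately).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import agobind, classify, loci, mapper, report
from .annotation import Annotation
from .libio import Library, length_filter
from .simdata import (GENOTYPE_LIBRARIES, IP_LIBRARIES, SimConfig, SimResult,
                      simulate)


@dataclass
class PanelResult:
    """Everything the pipeline computes for one panel."""

    locus_table: pd.DataFrame
    class_calls: pd.DataFrame
    class_summary: pd.DataFrame
    binding: pd.DataFrame
    binding_summary: pd.DataFrame
    fp_composition: dict[str, dict[str, float]]
    clustered: pd.DataFrame
    ip_clustered: pd.DataFrame       # IP placements assigned to panel loci
    ip_alignments: pd.DataFrame      # all IP placements, pre-assignment
    total_mapped: dict[str, float] = field(default_factory=dict)


def _assign_to_loci(alignments: pd.DataFrame,
                    envelopes: pd.DataFrame) -> pd.DataFrame:
    """Label alignments with the panel locus whose envelope contains them.

    An alignment belongs to a locus when its interval overlaps the locus
    envelope; alignments hitting no locus get a missing label.
    """
    out = alignments.copy()
    out["locus"] = None
    for scaffold, env in envelopes.groupby("scaffold"):
        sel = out["scaffold"] == scaffold
        if not sel.any():
            continue
        starts = env["start"].to_numpy()
        ends = env["end"].to_numpy()
        ids = env["locus"].to_numpy()
        a_start = out.loc[sel, "start"].to_numpy()
        a_end = out.loc[sel, "end"].to_numpy()
        idx = np.searchsorted(starts, a_start, side="right") - 1
        labels = np.empty(len(a_start), dtype=object)
        labels[:] = None
        ok = idx >= 0
        ok[ok] &= a_start[ok] < ends[idx[ok]]
        labels[ok] = ids[idx[ok]]
        # an alignment may also start in a gap but overlap the next locus
        nxt = np.clip(idx + 1, 0, len(starts) - 1)
        more = (~ok) & (a_end > starts[nxt]) & (a_start < ends[nxt])
        labels[more] = ids[nxt[more]]
        out.loc[sel, "locus"] = labels
    return out[out["locus"].notna()].copy()


def analyze_panel(libraries: dict[str, Library],
                  genome: dict[str, str],
                  annotation: Annotation,
                  thresholds: classify.Thresholds = classify.Thresholds(),
                  max_gap: int = loci.DEFAULT_MAX_GAP,
                  seed_k: int = mapper.DEFAULT_SEED_K,
                  multi: str = "split") -> PanelResult:
    """Run the full analysis on an already-simulated or loaded panel."""
    index = mapper.build_index(genome, seed_k)

    panel_tables = []
    total_mapped: dict[str, float] = {}
    for name in GENOTYPE_LIBRARIES:
        if name not in libraries:
            raise ValueError(f"missing genotype library: {name}")
        table = mapper.map_library(libraries[name], index, multi=multi)
        table["library"] = name
        panel_tables.append(table)
        total_mapped[name] = libraries[name].total_mapped
    panel = pd.concat(panel_tables, ignore_index=True)

    clustered = loci.cluster_alignments(panel, max_gap)
    envelopes = loci.locus_envelopes(clustered)

    # IP pair: 21-24 nt filter upstream of mapping, then join to panel loci
    ip_tables = []
    for name in IP_LIBRARIES:
        if name not in libraries:
            continue
        lib = libraries[name]
        filtered = Library(name=lib.name, genotype=lib.genotype,
                           reads=length_filter(lib.reads, agobind.IP_MIN_NT,
                                               agobind.IP_MAX_NT))
        table = mapper.map_library(filtered, index, multi=multi)
        table["library"] = name
        ip_tables.append(table)
        total_mapped[name] = filtered.total_mapped
    ip_alignments = (pd.concat(ip_tables, ignore_index=True) if ip_tables
                     else pd.DataFrame(columns=panel.columns))
    ip_clustered = (_assign_to_loci(ip_alignments, envelopes) if ip_tables
                    else pd.DataFrame(columns=clustered.columns))

    all_rows = pd.concat([clustered, ip_clustered], ignore_index=True)
    locus_table = loci.build_locus_table(all_rows, annotation, total_mapped)
    for name in IP_LIBRARIES:  # absent IP libraries appear as zero columns
        col = f"ab_{name}"
        if col not in locus_table.columns:
            locus_table[col] = 0.0

    class_calls = classify.classify_loci(locus_table, thresholds)
    class_summary = classify.summarize_classes(class_calls)
    binding = agobind.binding_table(
        locus_table[locus_table["locus"].isin(class_calls["locus"])],
        thresholds)
    binding_summary = agobind.crosstab_classes(binding, class_calls)

    fp_comp = {"bound": agobind.bound_fp_composition(binding, ip_clustered)}
    class3 = class_calls.loc[class_calls["class"] == "III", "locus"]
    rows3 = clustered[(clustered["library"] == "wt")
                      & clustered["locus"].isin(set(class3))]
    fp_comp["class_III"] = loci.five_prime_composition(
        rows3["read"].tolist(), rows3["weight"].to_numpy())

    return PanelResult(
        locus_table=locus_table, class_calls=class_calls,
        class_summary=class_summary, binding=binding,
        binding_summary=binding_summary, fp_composition=fp_comp,
        clustered=clustered, ip_clustered=ip_clustered,
        ip_alignments=ip_alignments,
        total_mapped=total_mapped)


def run_synthetic(config: SimConfig,
                  thresholds: classify.Thresholds = classify.Thresholds(),
                  outdir: str | Path | None = None
                  ) -> tuple[SimResult, PanelResult]:
    """Simulate a panel under ``config`` and analyze it end to end.

    When ``outdir`` is given, the consolidated report bundle is written
    there; identical (config, thresholds) reproduce byte-identical bundles.
    """
    sim = simulate(config)
    result = analyze_panel(sim.libraries, sim.genome, sim.annotation,
                           thresholds)
    if outdir is not None:
        report.render_reports(
            outdir,
            locus_table=result.locus_table,
            class_calls=result.class_calls,
            class_summary=result.class_summary,
            binding_summary=result.binding_summary,
            fp_composition=result.fp_composition,
            manifest={"seed": config.seed,
                      "n_loci_planted": int(len(sim.truth)),
                      "thresholds": {
                          "fold_log2": thresholds.fold_log2,
                          "min_wt_abundance": thresholds.min_wt_abundance,
                          "pseudocount": thresholds.pseudocount}})
    return sim, result


# ---------------------------------------------------------------------------
# Truth scoring (synthetic panels only)
# ---------------------------------------------------------------------------

def match_truth(truth: pd.DataFrame, locus_table: pd.DataFrame) -> pd.DataFrame:
    """Map each planted locus to the discovered locus overlapping it."""
    rows = []
    for _, t in truth.iterrows():
        hits = locus_table[(locus_table["scaffold"] == t["scaffold"])
                           & (locus_table["start"] < t["end"])
                           & (locus_table["end"] > t["start"])]
        rows.append({
            "locus_id": t["locus_id"],
            "class_true": t["class"],
            "locus": hits.iloc[0]["locus"] if len(hits) else None,
        })
    return pd.DataFrame(rows)


def score_recovery(truth: pd.DataFrame, result: PanelResult,
                   thresholds: classify.Thresholds = classify.Thresholds()
                   ) -> dict[str, float]:
    """Class-recovery and binding-recovery rates against the truth table.

    Recovery is scored over planted loci whose discovered wild-type
    abundance clears the classification floor (the stringency filter the
    method itself applies).
    """
    matched = match_truth(truth, result.locus_table)
    calls = matched.merge(result.class_calls[["locus", "class"]],
                          on="locus", how="left")
    wt_ab = result.locus_table.set_index("locus")["ab_wt"]
    calls["ab_wt"] = calls["locus"].map(wt_ab)
    eligible = calls[calls["ab_wt"] >= thresholds.min_wt_abundance]
    correct = (eligible["class"] == eligible["class_true"]).sum()

    bound = result.binding.set_index("locus")["bound"]
    calls["bound"] = calls["locus"].map(bound)
    elig_bind = calls[calls["ab_wt"].notna()]
    cls12 = elig_bind[elig_bind["class_true"].isin(["I", "II"])]
    cls34 = elig_bind[elig_bind["class_true"].isin(["III", "IV"])]
    return {
        "n_eligible": int(len(eligible)),
        "class_accuracy": correct / len(eligible) if len(eligible) else np.nan,
        "bound_rate_class12":
            cls12["bound"].fillna(False).mean() if len(cls12) else np.nan,
        "bound_rate_class34":
            cls34["bound"].fillna(False).mean() if len(cls34) else np.nan,
    }


def down_call_rate(result: PanelResult) -> float:
    """Fraction of (locus, genotype) pairs called down across the panel
    mutants (ago-1 included); the null-simulation false-positive metric."""
    cols = [f"down_{g}" for g in classify.PANEL_GENOTYPES]
    calls = result.class_calls[cols]
    if calls.size == 0:
        return float("nan")
    return float(calls.to_numpy().mean())
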