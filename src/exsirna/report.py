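"""Derived statistics tables and consolidated pipeline reports.

Covers the transformation silencing-frequency arithmetic (percent of
transformants with the silenced, albino phenotype) and the writer that
consolidates all pipeline stage outputs into a TSV/JSON bundle. All
percentages are recomputed from integer counts at render time.
"""

from __future__ import annotations

import json
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__


def silencing_frequency(albino: int, total: int) -> float:
    """Percent of silenced (albino) transformants, rounded to 1 decimal."""
    if total <= 0:
        raise ValueError("total transformant count must be > 0")
    if not 0 <= albino <= total:
        raise ValueError("albino count must lie in [0, total]")
    return round(100.0 * albino / total, 1)


def format_frequency(value: float) -> str:
    """Display form: one decimal with trailing .0 dropped (34.0 -> '34')."""
    return f"{value:.1f}".rstrip("0").rstrip(".")


def transformation_table(counts: pd.DataFrame) -> pd.DataFrame:
    """Add totals and silencing frequencies to a transformant-count table.

    Expects columns plasmid, strain, albino, bright_yellow; colonies with
    mixed albino/wild-type patches are counted as albino upstream.
    """
    df = counts.copy()
    df["total"] = df["albino"] + df["bright_yellow"]
    df["silencing_frequency_pct"] = [
        silencing_frequency(a, t) for a, t in zip(df["albino"], df["total"])]
    return df


def load_transformation_counts() -> pd.DataFrame:
    """Bundled transformant colour counts for silencing-reporter plasmids
    introduced into wild-type and argonaute-mutant M. circinelloides strains."""
    with resources.files("exsirna.data").joinpath(
            "transformation_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def load_binding_class_counts() -> pd.DataFrame:
    """Bundled per-class ex-siRNA locus counts and Ago-1-bound locus counts
    from the full-scale M. circinelloides study (class sizes 9/222/88/5)."""
    with resources.files("exsirna.data").joinpath(
            "ago1_binding_counts.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


# ---------------------------------------------------------------------------
# Consolidated bundle
# ---------------------------------------------------------------------------

#: Bundle file names, fixed so re-runs are byte-comparable.
BUNDLE_FILES = (
    "silencing_frequencies.tsv",
    "locus_table.tsv",
    "class_summary.tsv",
    "binding_summary.tsv",
    "fp_composition.tsv",
    "manifest.json",
)


def _write_tsv(df: pd.DataFrame, path: Path) -> None:
    df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def render_reports(outdir: str | Path,
                   locus_table: pd.DataFrame,
                   class_calls: pd.DataFrame,
                   class_summary: pd.DataFrame,
                   binding_summary: pd.DataFrame,
                   fp_composition: dict[str, dict[str, float]],
                   transformation_counts: pd.DataFrame | None = None,
                   lysis_timeseries: pd.DataFrame | None = None,
                   manifest: dict | None = None) -> list[Path]:
    """Write the consolidated report bundle; returns the files written.

    Raises ValueError naming the missing stage when a required upstream
    output is absent. Identical inputs produce byte-identical files.
    """
    stages = {
        "loci": locus_table, "classify": class_calls,
        "class summary": class_summary, "ago-bind": binding_summary,
    }
    for stage, obj in stages.items():
        if obj is None:
            raise ValueError(f"missing upstream output from stage: {stage}")
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written = []

    if transformation_counts is None:
        transformation_counts = load_transformation_counts()
    path = outdir / "silencing_frequencies.tsv"
    _write_tsv(transformation_table(transformation_counts), path)
    written.append(path)

    path = outdir / "locus_table.tsv"
    merged = locus_table.merge(
        class_calls[["locus", "class"]], on="locus", how="left")
    merged["class"] = merged["class"].fillna("-")
    _write_tsv(merged, path)
    written.append(path)

    path = outdir / "class_summary.tsv"
    _write_tsv(class_summary, path)
    written.append(path)

    path = outdir / "binding_summary.tsv"
    _write_tsv(binding_summary, path)
    written.append(path)

    path = outdir / "fp_composition.tsv"
    comp = pd.DataFrame(
        [{"group": g, **{b: f.get(b, np.nan) for b in "UACG"}}
         for g, f in sorted(fp_composition.items())])
    _write_tsv(comp, path)
    written.append(path)

    if lysis_timeseries is not None:
        path = outdir / "lysis_timeseries.tsv"
        _write_tsv(lysis_timeseries, path)
        written.append(path)

    path = outdir / "manifest.json"
    payload = {"package": "exsirna", "version": __version__}
    payload.update(manifest or {})
    path.write_text(json.dumps(payload, indent=2, sort_keys=True) + "\n")
    written.append(path)
    return written
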