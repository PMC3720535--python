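"""Genome feature annotation: GFF3 in/out and interval lookup.

Features live in a pandas table with 0-based half-open coordinates; GFF3's
1-based inclusive convention is converted at the file boundary. Only feature
types the locus categoriser consults (exon, transposon) need to be present;
anything not covered by them is intergenic by definition.
"""

from __future__ import annotations

import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import gffutils
import pandas as pd
from intervaltree import IntervalTree

FEATURE_COLUMNS = ["scaffold", "type", "start", "end", "strand", "feature_id"]


@dataclass
class Annotation:
    """Feature table plus the scaffold universe it refers to."""

    features: pd.DataFrame
    scaffold_lengths: dict[str, int] = field(default_factory=dict)
    _trees: dict[str, IntervalTree] = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if self.features is None or len(self.features) == 0:
            self.features = pd.DataFrame(columns=FEATURE_COLUMNS)
        for scaffold, grp in self.features.groupby("scaffold"):
            tree = IntervalTree()
            for row in grp.itertuples(index=False):
                tree.addi(row.start, row.end, (row.type, row.strand, row.feature_id))
            self._trees[str(scaffold)] = tree

    def overlapping(self, scaffold: str, start: int, end: int) -> list[tuple]:
        """(type, strand, feature_id, overlap_bp) of features hitting [start, end)."""
        if self.scaffold_lengths and scaffold not in self.scaffold_lengths:
            raise KeyError(f"unknown scaffold: {scaffold!r}")
        tree = self._trees.get(scaffold)
        if tree is None:
            return []
        out = []
        for iv in tree.overlap(start, end):
            overlap = min(end, iv.end) - max(start, iv.begin)
            ftype, strand, fid = iv.data
            out.append((ftype, strand, fid, overlap))
        return sorted(out, key=lambda t: (-t[3], t[2]))


def read_gff3(path: str | Path,
              scaffold_lengths: dict[str, int] | None = None) -> Annotation:
    """Parse a GFF3 file into an Annotation (coordinates converted to 0-based)."""
    db = gffutils.create_db(str(path), dbfn=":memory:", force=True,
                            keep_order=True, merge_strategy="create_unique")
    rows = []
    for feat in db.all_features():
        rows.append((feat.seqid, feat.featuretype, feat.start - 1, feat.end,
                     feat.strand, feat.id))
    features = pd.DataFrame(rows, columns=FEATURE_COLUMNS)
    lengths = dict(scaffold_lengths or {})
    if not lengths:
        lengths = _sequence_regions(path)
    return Annotation(features, lengths)


def _sequence_regions(path: str | Path) -> dict[str, int]:
    lengths: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith("##sequence-region"):
                _, scaffold, _start, end = line.split()
                lengths[scaffold] = int(end)
            elif not line.startswith("#"):
                break
    return lengths


def write_gff3(annotation: Annotation, path: str | Path,
               source: str = "exsirna") -> None:
    """Write features as GFF3 (1-based inclusive), with sequence-region pragmas."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for scaffold in sorted(annotation.scaffold_lengths):
            fh.write(f"##sequence-region {scaffold} 1 "
                     f"{annotation.scaffold_lengths[scaffold]}\n")
        feats = annotation.features.sort_values(
            ["scaffold", "start", "feature_id"], kind="stable")
        for row in feats.itertuples(index=False):
            fh.write("\t".join([
                str(row.scaffold), source, str(row.type),
                str(row.start + 1), str(row.end), ".", row.strand, ".",
                f"ID={row.feature_id}",
            ]) + "\n")
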