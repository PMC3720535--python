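"""Small-RNA library ingestion: collapsing, length filtering, normalization.

Libraries arrive as FASTA/FASTQ of raw reads or as collapsed FASTA
(``>id_count=N`` headers). Internally a library is a mapping from a distinct
uppercase DNA sequence (U stored as T) to its raw read count, plus the
bookkeeping needed to express per-read abundance in reads per million
genome-matching reads.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

from Bio import SeqIO

log = logging.getLogger(__name__)

#: Sanity bounds applied at ingestion; anything outside cannot be a small RNA
#: read and is dropped with a log message.
MIN_INGEST_NT = 15
MAX_INGEST_NT = 40

_COUNT_RE = re.compile(r"_count=(\d+)$")
_VALID_RE = re.compile(r"^[ACGT]+$")


@dataclass(frozen=True)
class CollapsedRead:
    """A distinct read sequence with its per-library raw count."""

    sequence: str
    count: int

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass
class Library:
    """A collapsed small-RNA library for one genotype.

    ``total_mapped`` is filled in by the mapper; until then normalized
    abundances are undefined.
    """

    name: str
    genotype: str = ""
    reads: dict[str, int] = field(default_factory=dict)
    total_mapped: int | float | None = None

    @property
    def total_raw(self) -> int:
        return sum(self.reads.values())

    def records(self) -> Iterator[CollapsedRead]:
        for seq in sorted(self.reads):
            yield CollapsedRead(seq, self.reads[seq])

    def __len__(self) -> int:
        return len(self.reads)


def _clean(seq: str) -> str | None:
    """Uppercase, U->T; return None for sequences to drop (N, bad length)."""
    s = seq.upper().replace("U", "T")
    if not _VALID_RE.match(s):
        return None
    if not MIN_INGEST_NT <= len(s) <= MAX_INGEST_NT:
        return None
    return s


def collapse_reads(raw: Iterable[str]) -> dict[str, int]:
    """Collapse raw read sequences into distinct-sequence counts.

    Sequences containing any character outside A/C/G/T/U (notably N) are
    dropped and logged; counts of the survivors sum to the number of clean
    input reads. An empty input yields an empty mapping.
    """
    counts: dict[str, int] = {}
    dropped = 0
    for seq in raw:
        s = seq.upper().replace("U", "T")
        if not _VALID_RE.match(s):
            dropped += 1
            continue
        counts[s] = counts.get(s, 0) + 1
    if dropped:
        log.info("collapse_reads: dropped %d reads with non-ACGTU characters", dropped)
    return counts


def collapse_counts(weighted: Iterable[tuple[str, int]]) -> dict[str, int]:
    """Collapse (sequence, count) pairs, merging duplicates and cleaning."""
    counts: dict[str, int] = {}
    dropped = 0
    for seq, n in weighted:
        s = _clean(seq)
        if s is None:
            dropped += 1
            continue
        counts[s] = counts.get(s, 0) + int(n)
    if dropped:
        log.info("collapse_counts: dropped %d records outside sanity bounds", dropped)
    return counts


def length_filter(reads: dict[str, int], min_nt: int, max_nt: int) -> dict[str, int]:
    """Keep reads with min_nt <= length <= max_nt (both ends inclusive)."""
    if min_nt > max_nt:
        raise ValueError(f"min_nt ({min_nt}) must not exceed max_nt ({max_nt})")
    return {s: c for s, c in reads.items() if min_nt <= len(s) <= max_nt}


def normalize_abundance(count: float, total_mapped: float) -> float:
    """Reads per million mapped: count / total_mapped * 1e6."""
    if total_mapped is None or total_mapped <= 0:
        raise ValueError("empty mapped library: total_mapped must be > 0")
    return count / total_mapped * 1e6


# ---------------------------------------------------------------------------
# File I/O
# ---------------------------------------------------------------------------

def load_library(path: str | Path, name: str | None = None,
                 genotype: str = "") -> Library:
    """Load a FASTA/FASTQ (raw or collapsed) file into a Library.

    Headers matching ``..._count=N`` are treated as pre-collapsed records
    contributing N reads; all other records contribute one read each.
    FASTQ qualities are ignored.
    """
    path = Path(path)
    fmt = "fastq" if path.suffix.lower() in {".fastq", ".fq"} else "fasta"
    pairs: list[tuple[str, int]] = []
    for rec in SeqIO.parse(str(path), fmt):
        m = _COUNT_RE.search(rec.id)
        n = int(m.group(1)) if m else 1
        pairs.append((str(rec.seq), n))
    lib = Library(name=name or path.stem, genotype=genotype)
    lib.reads = collapse_counts(pairs)
    return lib


def write_collapsed_fasta(library: Library, path: str | Path) -> None:
    """Write a library as collapsed FASTA with ``>read<i>_count=N`` headers."""
    with open(path, "w") as fh:
        for i, rec in enumerate(library.records()):
            fh.write(f">read{i}_count={rec.count}\n{rec.sequence}\n")


def library_summary(library: Library) -> dict[str, float]:
    """Per-library summary used in the TSV report."""
    return {
        "library": library.name,
        "genotype": library.genotype,
        "distinct_sequences": len(library),
        "total_raw": library.total_raw,
        "total_mapped": library.total_mapped if library.total_mapped is not None else float("nan"),
    }
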