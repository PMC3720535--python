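"""Exact-match placement of collapsed reads on both genome strands.

A k-mer seed index over the forward genome drives candidate lookup; each
candidate is verified by direct string comparison, so reported hits are exact
(0-mismatch) occurrences. A read's reverse complement found on the forward
sequence is reported as a minus-strand hit in forward coordinates.

Multi-mapping reads are handled by a selectable policy; the default splits a
read's count evenly across its genomic placements (weight = count / n_hits).
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .libio import Library

DEFAULT_SEED_K = 12

_COMP = str.maketrans("ACGT", "TGCA")
_DIGIT = {"A": 0, "C": 1, "G": 2, "T": 3}
_LUT = np.zeros(256, dtype=np.int64)
for _b, _d in _DIGIT.items():
    _LUT[ord(_b)] = _d

ALIGNMENT_COLUMNS = [
    "read", "scaffold", "start", "end", "strand", "n_hits", "count", "weight",
]


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


@dataclass(frozen=True)
class Alignment:
    """One exact genomic placement of a read (0-based half-open interval)."""

    read: str
    scaffold: str
    start: int
    end: int
    strand: str
    n_hits: int = 1


class KmerIndex:
    """Positions of every k-mer of the forward genome sequence.

    Scaffolds are concatenated internally and k-mers packed into base-4
    integers held in sorted arrays; windows crossing a scaffold boundary are
    excluded. Candidate positions from the seed are verified against the
    full query before a hit is reported, so lookups are exact.
    """

    def __init__(self, genome: dict[str, str], k: int = DEFAULT_SEED_K):
        if k < 4:
            raise ValueError("seed too short: k must be >= 4")
        self.k = k
        self.genome = genome
        self.scaffolds = sorted(genome)
        lengths = [len(genome[s]) for s in self.scaffolds]
        self._offsets = np.concatenate([[0], np.cumsum(lengths)]).astype(np.int64)
        self._offsets_list = [int(o) for o in self._offsets]
        self._concat = "".join(genome[s] for s in self.scaffolds)

        arr = _LUT[np.frombuffer(self._concat.encode(), dtype=np.uint8)]
        n = len(arr) - k + 1
        if n <= 0:
            self._uniq = np.empty(0, dtype=np.int64)
            self._bounds = np.zeros(1, dtype=np.int64)
            self._pos = np.empty(0, dtype=np.int64)
            return
        codes = np.zeros(n, dtype=np.int64)
        for j in range(k):
            codes = codes * 4 + arr[j:j + n]
        pos = np.arange(n, dtype=np.int64)
        scaf = np.searchsorted(self._offsets, pos, side="right") - 1
        valid = pos + k <= self._offsets[scaf + 1]
        codes, pos = codes[valid], pos[valid]
        order = np.argsort(codes, kind="stable")
        codes, self._pos = codes[order], pos[order]
        self._uniq, starts = np.unique(codes, return_index=True)
        self._bounds = np.concatenate([starts, [len(codes)]]).astype(np.int64)

    def encode(self, seed: str) -> int:
        code = 0
        for ch in seed:
            code = code * 4 + _DIGIT[ch]
        return code

    def _positions_for_code(self, code: int) -> np.ndarray | None:
        i = int(np.searchsorted(self._uniq, code))
        if i >= len(self._uniq) or self._uniq[i] != code:
            return None
        return self._pos[self._bounds[i]:self._bounds[i + 1]]

    def lookup(self, kmer: str) -> list[tuple[str, int]]:
        """(scaffold, position) of every occurrence of a k-mer."""
        positions = self._positions_for_code(self.encode(kmer))
        if positions is None:
            return []
        out = []
        for gp in positions:
            gp = int(gp)
            si = bisect_right(self._offsets_list, gp) - 1
            out.append((self.scaffolds[si], gp - self._offsets_list[si]))
        return out

    def occurrences(self, query: str) -> list[tuple[int, int]]:
        """(scaffold index, local start) of exact forward occurrences."""
        positions = self._positions_for_code(self.encode(query[:self.k]))
        return self._verify(query, positions)

    def _verify(self, query: str,
                positions: np.ndarray | None) -> list[tuple[int, int]]:
        if positions is None:
            return []
        concat = self._concat
        offsets = self._offsets_list
        n = len(query)
        hits = []
        for gp in positions:
            gp = int(gp)
            if concat.startswith(query, gp):
                si = bisect_right(offsets, gp) - 1
                if gp + n <= offsets[si + 1]:
                    hits.append((si, gp - offsets[si]))
        return hits


def build_index(genome: dict[str, str], k: int = DEFAULT_SEED_K) -> KmerIndex:
    """Build a seed index of all genomic k-mers (forward sequence)."""
    return KmerIndex(genome, k)


def _placements(read: str, index: KmerIndex) -> list[tuple[int, int, str]]:
    if len(read) < index.k:
        raise ValueError(f"read shorter than seed k={index.k}: {read!r}")
    placements = [(si, p, "+") for si, p in index.occurrences(read)]
    placements += [(si, p, "-") for si, p in index.occurrences(revcomp(read))]
    placements.sort()
    return placements


def map_read(read: str, index: KmerIndex,
             genome: dict[str, str] | None = None) -> list[Alignment]:
    """All exact placements of a read on either strand.

    Plus-strand hits are occurrences of the read itself; minus-strand hits
    are occurrences of its reverse complement, reported in forward
    coordinates. Alignments are ordered by (scaffold, start, strand) and
    each carries the total placement count ``n_hits``.
    """
    placements = _placements(read, index)
    n_hits = len(placements)
    n = len(read)
    return [Alignment(read, index.scaffolds[si], p, p + n, strand, n_hits)
            for si, p, strand in placements]


def _batch_seed_codes(seqs: list[str], k: int) -> np.ndarray:
    """Base-4 codes of the first k characters of every sequence."""
    buf = "".join(s[:k] for s in seqs).encode()
    mat = _LUT[np.frombuffer(buf, dtype=np.uint8)].reshape(len(seqs), k)
    powers = 4 ** np.arange(k - 1, -1, -1, dtype=np.int64)
    return mat @ powers


def map_library(library: Library, index: KmerIndex,
                multi: str = "split") -> pd.DataFrame:
    """Map every collapsed read of a library; sets ``library.total_mapped``.

    Returns an alignment table with one row per placement. ``total_mapped``
    is the summed raw count of reads with at least one genomic hit. The
    ``multi`` policy sets per-placement weights: ``split`` = count / n_hits,
    ``all`` = full count at every placement, ``unique`` = discard
    multi-mapping reads.
    """
    if multi not in {"split", "all", "unique"}:
        raise ValueError(f"unknown multi-hit policy: {multi!r}")
    seqs = sorted(library.reads)
    if not seqs:
        library.total_mapped = 0
        return pd.DataFrame(columns=ALIGNMENT_COLUMNS)
    if min(len(s) for s in seqs) < index.k:
        raise ValueError(f"library contains reads shorter than seed k={index.k}")
    rcs = [revcomp(s) for s in seqs]
    k = index.k
    codes_f = _batch_seed_codes(seqs, k)
    codes_r = _batch_seed_codes(rcs, k)
    uniq = index._uniq
    idx_f = np.searchsorted(uniq, codes_f).clip(0, max(len(uniq) - 1, 0))
    idx_r = np.searchsorted(uniq, codes_r).clip(0, max(len(uniq) - 1, 0))
    found_f = len(uniq) > 0 and (uniq[idx_f] == codes_f)
    found_r = len(uniq) > 0 and (uniq[idx_r] == codes_r)

    scaffolds = index.scaffolds
    pos_arr, bounds = index._pos, index._bounds
    col_read, col_scaf, col_start, col_strand = [], [], [], []
    col_nhits, col_count, col_weight, col_end = [], [], [], []
    total_mapped = 0
    reads = library.reads
    verify = index._verify
    for i, seq in enumerate(seqs):
        placements = []
        if found_f[i]:
            j = idx_f[i]
            for si, p in verify(seq, pos_arr[bounds[j]:bounds[j + 1]]):
                placements.append((si, p, "+"))
        if found_r[i]:
            j = idx_r[i]
            for si, p in verify(rcs[i], pos_arr[bounds[j]:bounds[j + 1]]):
                placements.append((si, p, "-"))
        n_hits = len(placements)
        if n_hits == 0:
            continue
        count = reads[seq]
        total_mapped += count
        if multi == "unique" and n_hits > 1:
            continue
        if n_hits > 1:
            placements.sort()
        weight = count / n_hits if multi == "split" else float(count)
        n = len(seq)
        for si, p, strand in placements:
            col_read.append(seq)
            col_scaf.append(scaffolds[si])
            col_start.append(p)
            col_end.append(p + n)
            col_strand.append(strand)
            col_nhits.append(n_hits)
            col_count.append(count)
            col_weight.append(weight)
    library.total_mapped = total_mapped
    return pd.DataFrame({
        "read": col_read, "scaffold": col_scaf,
        "start": np.array(col_start, dtype=np.int64),
        "end": np.array(col_end, dtype=np.int64),
        "strand": col_strand,
        "n_hits": np.array(col_nhits, dtype=np.int64),
        "count": np.array(col_count, dtype=np.int64),
        "weight": np.array(col_weight, dtype=float),
    })


def naive_map_read(read: str, genome: dict[str, str]) -> list[Alignment]:
    """Brute-force both-strand scan; the oracle the index is tested against."""
    placements: list[tuple[str, int, str]] = []
    rc = revcomp(read)
    for scaffold in sorted(genome):
        seq = genome[scaffold]
        for query, strand in ((read, "+"), (rc, "-")):
            start = seq.find(query)
            while start != -1:
                placements.append((scaffold, start, strand))
                start = seq.find(query, start + 1)
    placements.sort()
    n_hits = len(placements)
    return [Alignment(read, s, p, p + len(read), strand, n_hits)
            for s, p, strand in placements]


def write_alignments(alignments: pd.DataFrame, path) -> None:
    alignments.to_csv(path, sep="\t", index=False)


def write_bed(alignments: pd.DataFrame, path) -> None:
    """BED6 output (0-based half-open, score = n_hits)."""
    bed = alignments[["scaffold", "start", "end", "read", "n_hits", "strand"]]
    bed.to_csv(path, sep="\t", index=False, header=False)
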