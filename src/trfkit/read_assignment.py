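"""Read collapsing and sequential, priority-ordered, edit-tiered category assignment.

Each distinct read sequence is tried at increasing edit tiers; within a tier
the reference categories are tried in their fixed priority order and the first
category with at least one sense-strand hit claims the read.  Tier 0 is an
exact substring match; tier 1 allows one edit (substitution, insertion or
deletion); tiers 2 and 3 allow two and three substitutions only — the asymmetry
is deliberate and mirrors the original mapping protocol.
"""
from __future__ import annotations

import gzip
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import edlib
import numpy as np
import pandas as pd
from Bio import SeqIO

from .reference_model import ReferenceCategory, normalize_nt

logger = logging.getLogger(__name__)

UNASSIGNED = "unassigned"
_ACGT = frozenset("ACGT")


@dataclass
class ReadSet:
    """Collapsed small-RNA reads (sequence -> count) for one library."""

    library_id: str
    stage: str
    fraction: str
    reads: dict[str, int]
    total_input_reads: int

    @property
    def total_reads(self) -> int:
        return sum(self.reads.values())

    @property
    def n_distinct(self) -> int:
        return len(self.reads)


def _open_text(path: str | Path):
    path = str(path)
    if path.endswith(".gz"):
        return gzip.open(path, "rt")
    return open(path)


def trim_adapter(seq: str, adapter: str, min_overlap: int = 6) -> str:
    """Trim a 3' adapter by exact-prefix search.

    The leftmost full occurrence of the adapter wins; otherwise the longest
    adapter prefix (>= ``min_overlap``) found at the read's 3' end is removed.
    """
    idx = seq.find(adapter)
    if idx >= 0:
        return seq[:idx]
    for k in range(min(len(adapter), len(seq)) - 1, min_overlap - 1, -1):
        if seq.endswith(adapter[:k]):
            return seq[: len(seq) - k]
    return seq


def _collapse(
    sequences: Iterable[tuple[str, int]],
    library_id: str,
    stage: str,
    fraction: str,
    adapter: str | None,
    min_overlap: int,
    total_input: int,
) -> ReadSet:
    reads: dict[str, int] = {}
    dropped = 0
    for seq, count in sequences:
        seq = normalize_nt(seq)
        if adapter:
            seq = trim_adapter(seq, normalize_nt(adapter), min_overlap)
        if not seq or set(seq) - _ACGT:
            dropped += count
            continue
        reads[seq] = reads.get(seq, 0) + count
    if dropped:
        logger.info("%s: dropped %d reads (empty after trimming or non-ACGT)", library_id, dropped)
    return ReadSet(library_id, stage, fraction, reads, total_input)


def from_fastq(
    path: str | Path,
    library_id: str,
    stage: str = "other",
    fraction: str = "Total",
    adapter: str | None = None,
    min_overlap: int = 6,
) -> ReadSet:
    """Collapse a FASTQ file (optionally gzip-compressed) into a :class:`ReadSet`."""
    with _open_text(path) as fh:
        raw = [(str(rec.seq), 1) for rec in SeqIO.parse(fh, "fastq")]
    return _collapse(raw, library_id, stage, fraction, adapter, min_overlap, len(raw))


def from_collapsed_fasta(
    path: str | Path,
    library_id: str,
    stage: str = "other",
    fraction: str = "Total",
    adapter: str | None = None,
    min_overlap: int = 6,
) -> ReadSet:
    """Collapse a pre-collapsed FASTA with ``id_count`` headers (e.g. ``seq12_345``)."""
    raw: list[tuple[str, int]] = []
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            try:
                count = int(rec.id.rsplit("_", 1)[1])
            except (IndexError, ValueError):
                raise ValueError(f"collapsed FASTA header {rec.id!r} lacks an _count suffix")
            raw.append((str(rec.seq), count))
    total = sum(c for _, c in raw)
    return _collapse(raw, library_id, stage, fraction, adapter, min_overlap, total)


def length_filter(readset: ReadSet, min_len: int = 15, max_len: int = 29) -> ReadSet:
    """Retain reads with min_len <= length <= max_len (bounds inclusive)."""
    if min_len > max_len:
        raise ValueError(f"min_len {min_len} > max_len {max_len}")
    kept = {s: c for s, c in readset.reads.items() if min_len <= len(s) <= max_len}
    n_removed = readset.total_reads - sum(kept.values())
    logger.info(
        "%s: length filter [%d, %d] kept %d/%d reads (%d distinct)",
        readset.library_id, min_len, max_len, sum(kept.values()), readset.total_reads, len(kept),
    )
    if n_removed == 0 and len(kept) == len(readset.reads):
        return replace(readset, reads=dict(readset.reads))
    return replace(readset, reads=kept)


@dataclass(frozen=True)
class CategoryAssignment:
    """Resolved category for one distinct read sequence.

    ``gene_hits`` lists every sense-strand hit within the claiming category as
    (gene_id, start, end), 1-based closed; ``edit_tier`` is None for unassigned
    sequences.
    """

    sequence: str
    category: str
    gene_hits: tuple[tuple[str, int, int], ...] = ()
    edit_tier: int | None = None


def _exact_hits(seq: str, sequences: Mapping[str, str]) -> list[tuple[str, int, int]]:
    hits = []
    n = len(seq)
    for gid, ref in sequences.items():
        start = ref.find(seq)
        while start >= 0:
            hits.append((gid, start + 1, start + n))
            start = ref.find(seq, start + 1)
    return hits


def _edit1_hits(seq: str, sequences: Mapping[str, str]) -> list[tuple[str, int, int]]:
    hits = []
    for gid, ref in sequences.items():
        res = edlib.align(seq, ref, mode="HW", task="locations", k=1)
        if res["editDistance"] < 0:
            continue
        for s0, e0 in res["locations"]:
            hits.append((gid, (s0 or 0) + 1, e0 + 1))
    return hits


def _hamming_hits(seq: str, sequences: Mapping[str, str], k: int) -> list[tuple[str, int, int]]:
    hits = []
    q = np.frombuffer(seq.encode(), dtype=np.uint8)
    n = len(seq)
    for gid, ref in sequences.items():
        if len(ref) < n:
            continue
        arr = np.frombuffer(ref.encode(), dtype=np.uint8)
        windows = np.lib.stride_tricks.sliding_window_view(arr, n)
        mism = (windows != q).sum(axis=1)
        for s0 in np.flatnonzero(mism <= k):
            hits.append((gid, int(s0) + 1, int(s0) + n))
    return hits


def _hits_at_tier(seq: str, category: ReferenceCategory, tier: int) -> list[tuple[str, int, int]]:
    if tier == 0:
        return _exact_hits(seq, category.sequences)
    if tier == 1:
        return _edit1_hits(seq, category.sequences)
    return _hamming_hits(seq, category.sequences, tier)


def assign_sequences(
    sequences: Iterable[str],
    categories: Sequence[ReferenceCategory],
    max_tier: int = 0,
) -> dict[str, CategoryAssignment]:
    """Assign each distinct sequence to its claiming category and tier.

    Tiers are tried in increasing order; within a tier, categories in priority
    order; the first category with >= 1 hit claims the sequence.
    """
    if not 0 <= max_tier <= 3:
        raise ValueError("max_tier must be between 0 and 3")
    if list(categories) != sorted(categories, key=lambda c: c.priority):
        raise ValueError("categories must be supplied in priority order")
    out: dict[str, CategoryAssignment] = {}
    for seq in sequences:
        assignment = CategoryAssignment(seq, UNASSIGNED)
        for tier in range(max_tier + 1):
            claimed = False
            for category in categories:
                hits = _hits_at_tier(seq, category, tier)
                if hits:
                    assignment = CategoryAssignment(seq, category.name, tuple(hits), tier)
                    claimed = True
                    break
            if claimed:
                break
        out[seq] = assignment
    return out


def assign_reads(
    readset: ReadSet,
    categories: Sequence[ReferenceCategory],
    max_tier: int = 0,
    cache: dict[str, CategoryAssignment] | None = None,
) -> list[CategoryAssignment]:
    """Assign every distinct sequence of a library; see :func:`assign_sequences`.

    ``cache`` (sequence -> assignment) lets multiple libraries against the same
    references share work.
    """
    if cache is None:
        cache = {}
    missing = [s for s in readset.reads if s not in cache]
    cache.update(assign_sequences(missing, categories, max_tier))
    return [cache[s] for s in readset.reads]


def mapped_total(assignments: Iterable[CategoryAssignment], readset: ReadSet) -> int:
    """Total count of reads assigned to any category (the RPM denominator)."""
    return sum(
        readset.reads[a.sequence] for a in assignments if a.category != UNASSIGNED
    )


def category_totals(assignments: Iterable[CategoryAssignment], readset: ReadSet) -> dict[str, int]:
    """Read counts per claiming category, including ``unassigned``."""
    totals: dict[str, int] = {}
    for a in assignments:
        totals[a.category] = totals.get(a.category, 0) + readset.reads[a.sequence]
    return totals


def assignments_to_frame(
    assignments: Iterable[CategoryAssignment], readset: ReadSet
) -> pd.DataFrame:
    """Long-format assignment table (sequence, count, category, tier, hits)."""
    rows = []
    for a in assignments:
        rows.append(
            {
                "sequence": a.sequence,
                "count": readset.reads[a.sequence],
                "category": a.category,
                "edit_tier": -1 if a.edit_tier is None else a.edit_tier,
                "gene_hits": ";".join(f"{g}:{s}-{e}" for g, s, e in a.gene_hits),
            }
        )
    return pd.DataFrame(
        rows, columns=["sequence", "count", "category", "edit_tier", "gene_hits"]
    )
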