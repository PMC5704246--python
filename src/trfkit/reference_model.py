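"""Reference sequence sets, tRNA gene models and the coordinate systems they define.

Mature tRNAs are handled on a 1-based, fully closed coordinate system with the
universal 3'-CCA appended, so that 3'-fragment reads align.  Two derived
coordinate systems are built per gene:

* a three-way *region partition* — 5' (positions 1-26), middle, and 3' (last 26
  positions) — used to place fragments on the body of the tRNA, and
* a 15-segment *cloverleaf* address (acceptor stem strands, D arm, anticodon
  arm, variable loop, T arm, discriminator+CCA), used to express 3' cleavage
  sites in structural rather than linear coordinates.

Cloverleaf addresses are rendered "offset;segment", e.g. ``"2;7"`` for the
second nucleotide of the anticodon-stem 5' strand.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

from Bio import SeqIO

logger = logging.getLogger(__name__)

#: Fixed priority order in which reference categories claim reads.
CATEGORY_PRIORITY: tuple[str, ...] = (
    "rRNA",
    "hairpin",
    "tRNA",
    "miscRNA",
    "ncRNA",
    "transposon",
    "transcript",
    "intron",
    "pseudogene",
    "intergenic",
)

_VALID_NT = frozenset("ACGTN")

#: Length of the 5' region and of the 3' region of the partition, in nt.
REGION_WIDTH = 26


class CloverleafError(ValueError):
    """Raised when a structure string cannot be parsed as a canonical cloverleaf."""


def normalize_nt(seq: str) -> str:
    """Uppercase a nucleotide string and convert RNA U to DNA T."""
    return seq.upper().replace("U", "T")


@dataclass(frozen=True)
class ReferenceCategory:
    """A named reference set (e.g. rRNA) holding id -> sequence."""

    name: str
    sequences: dict[str, str]

    @property
    def priority(self) -> int:
        return CATEGORY_PRIORITY.index(self.name)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sequences)


def _validate_category(name: str, sequences: Mapping[str, str]) -> ReferenceCategory:
    if name not in CATEGORY_PRIORITY:
        raise ValueError(f"unknown reference category {name!r}; known: {CATEGORY_PRIORITY}")
    if not sequences:
        raise ValueError(f"reference category {name!r} is empty")
    cleaned: dict[str, str] = {}
    for sid, seq in sequences.items():
        if sid in cleaned:
            raise ValueError(f"duplicate sequence id {sid!r} in category {name!r}")
        seq = normalize_nt(seq)
        bad = set(seq) - _VALID_NT
        if bad:
            raise ValueError(f"invalid characters {sorted(bad)} in {name}/{sid}")
        cleaned[sid] = seq
    return ReferenceCategory(name, cleaned)


def references_from_dict(categories: Mapping[str, Mapping[str, str]]) -> list[ReferenceCategory]:
    """Build validated :class:`ReferenceCategory` objects, returned in priority order."""
    unknown = set(categories) - set(CATEGORY_PRIORITY)
    if unknown:
        raise ValueError(f"unknown reference categories {sorted(unknown)}")
    out = []
    for name in CATEGORY_PRIORITY:
        if name in categories:
            out.append(_validate_category(name, dict(categories[name])))
    return out


def load_references(category_fastas: Mapping[str, str | Path]) -> list[ReferenceCategory]:
    """Load one FASTA per category and return categories in fixed priority order.

    U is normalized to T; duplicate ids within a category and empty files are
    rejected.
    """
    unknown = set(category_fastas) - set(CATEGORY_PRIORITY)
    if unknown:
        raise ValueError(f"unknown reference categories {sorted(unknown)}")
    raw: dict[str, dict[str, str]] = {}
    for name, path in category_fastas.items():
        seqs: dict[str, str] = {}
        for rec in SeqIO.parse(str(path), "fasta"):
            if rec.id in seqs:
                raise ValueError(f"duplicate sequence id {rec.id!r} in {path}")
            seqs[rec.id] = str(rec.seq)
        if not seqs:
            raise ValueError(f"no FASTA records in {path} (category {name!r})")
        raw[name] = seqs
    return references_from_dict(raw)


@dataclass(frozen=True)
class TRNAGene:
    """A mature tRNA reference sequence with 3'-CCA appended.

    ``structure`` is a dot-bracket string of the same length as ``sequence``;
    position 1 is the mature 5' nucleotide. ``anticodon_start`` (1-based) is
    optional but, when present, anchors the anticodon validation.
    """

    gene_id: str
    amino_acid: str
    anticodon: str
    sequence: str
    structure: str
    is_mitochondrial: bool = False
    anticodon_start: int | None = None

    @property
    def length(self) -> int:
        return len(self.sequence)


def build_trna_genes(rows: Iterable[Mapping[str, object]], append_cca: bool = True) -> list[TRNAGene]:
    """Build validated :class:`TRNAGene` objects from structure-table rows.

    Each row supplies gene_id, amino_acid, anticodon, sequence and structure
    (plus optional is_mitochondrial / anticodon_start).  When ``append_cca`` is
    set and the sequence does not already end in CCA, CCA is appended and the
    structure padded with three unpaired positions.  Idempotent on sequences
    already carrying CCA.
    """
    genes: list[TRNAGene] = []
    for row in rows:
        gid = str(row["gene_id"])
        seq = normalize_nt(str(row["sequence"]))
        struct = str(row["structure"])
        if append_cca and not seq.endswith("CCA"):
            seq += "CCA"
            struct += "..."
        if len(struct) != len(seq):
            raise ValueError(
                f"gene {gid}: structure length {len(struct)} != sequence length {len(seq)}"
            )
        anticodon = normalize_nt(str(row["anticodon"]))
        ac_start = row.get("anticodon_start")
        ac_start = int(ac_start) if ac_start not in (None, "") else None
        if ac_start is not None:
            if seq[ac_start - 1 : ac_start + 2] != anticodon:
                raise ValueError(
                    f"gene {gid}: anticodon {anticodon} not found at annotated position {ac_start}"
                )
        elif anticodon not in seq:
            raise ValueError(f"gene {gid}: anticodon {anticodon} not found in sequence")
        genes.append(
            TRNAGene(
                gene_id=gid,
                amino_acid=str(row["amino_acid"]),
                anticodon=anticodon,
                sequence=seq,
                structure=struct,
                is_mitochondrial=bool(int(row.get("is_mitochondrial", 0) or 0)),
                anticodon_start=ac_start,
            )
        )
    return genes


_STRUCTURE_COLUMNS = (
    "gene_id",
    "amino_acid",
    "anticodon",
    "anticodon_start",
    "is_mitochondrial",
    "sequence",
    "structure",
)


def read_structure_table(path: str | Path) -> list[dict[str, object]]:
    """Parse a tRNA structure table (tRNAscan-SE-style tabular + dot-bracket).

    Strict layout: a tab-separated file whose header line names the columns
    ``gene_id  amino_acid  anticodon  anticodon_start  is_mitochondrial
    sequence  structure``.  Fallback: header-less whitespace-delimited rows in
    the same column order.
    """
    rows: list[dict[str, object]] = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip() and not ln.startswith("#")]
    if not lines:
        raise ValueError(f"empty structure table {path}")
    first = lines[0].split("\t")
    if "gene_id" in first:
        cols = [c.strip() for c in first]
        for ln in lines[1:]:
            parts = ln.split("\t")
            rows.append(dict(zip(cols, parts)))
    else:
        logger.info("structure table %s has no header; using permissive whitespace parser", path)
        for ln in lines:
            parts = ln.split()
            if len(parts) < len(_STRUCTURE_COLUMNS):
                raise ValueError(f"structure table row has {len(parts)} fields: {ln!r}")
            rows.append(dict(zip(_STRUCTURE_COLUMNS, parts)))
    return rows


def write_structure_table(rows: Sequence[Mapping[str, object]], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(_STRUCTURE_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "")) for c in _STRUCTURE_COLUMNS) + "\n")


@dataclass(frozen=True)
class RegionPartition:
    """5' / middle / 3' partition of a tRNA of length ``length``.

    Regions are 1-based closed intervals; ``middle`` is ``None`` when the gene
    is exactly 52 nt (the two terminal regions abut).
    """

    length: int
    five: tuple[int, int]
    middle: tuple[int, int] | None
    three: tuple[int, int]

    def spans(self) -> dict[str, tuple[int, int] | None]:
        return {"FIVE": self.five, "MID": self.middle, "THREE": self.three}


def partition_regions(gene: TRNAGene | int) -> RegionPartition:
    """Partition a tRNA into 5' (1-26), middle, and 3' (last 26) regions.

    Raises for genes shorter than 52 nt, where the terminal regions would
    overlap.
    """
    if isinstance(gene, TRNAGene):
        length, gid = gene.length, gene.gene_id
    else:
        length, gid = int(gene), "<anonymous>"
    if length < 2 * REGION_WIDTH:
        raise ValueError(
            f"gene {gid} is {length} nt; region partition requires >= {2 * REGION_WIDTH} nt"
        )
    middle = (REGION_WIDTH + 1, length - REGION_WIDTH)
    return RegionPartition(
        length=length,
        five=(1, REGION_WIDTH),
        middle=middle if middle[0] <= middle[1] else None,
        three=(length - REGION_WIDTH + 1, length),
    )


class CloverleafCoordinate(NamedTuple):
    segment: int
    offset: int


def format_coordinate(coord: CloverleafCoordinate) -> str:
    """Render an address as ``"offset;segment"`` (e.g. ``"2;7"``)."""
    return f"{coord.offset};{coord.segment}"


SEGMENT_NAMES: tuple[str, ...] = (
    "acceptor stem 5' strand",
    "linker",
    "D-stem 5' strand",
    "D loop",
    "D-stem 3' strand",
    "linker",
    "anticodon-stem 5' strand",
    "anticodon loop",
    "anticodon-stem 3' strand",
    "variable loop",
    "T-stem 5' strand",
    "T loop",
    "T-stem 3' strand",
    "acceptor stem 3' strand",
    "discriminator + CCA",
)


@dataclass(frozen=True)
class CloverleafMap:
    """Bijective map from tRNA positions to 15-segment cloverleaf addresses.

    ``segments[k]`` is the closed interval of segment k+1; empty segments are
    stored as ``None``.
    """

    gene_id: str
    length: int
    segments: tuple[tuple[int, int] | None, ...]
    _by_position: dict[int, CloverleafCoordinate] = field(repr=False, hash=False, default_factory=dict)

    def coordinate(self, position: int) -> CloverleafCoordinate:
        try:
            return self._by_position[position]
        except KeyError:
            raise ValueError(f"position {position} outside gene {self.gene_id} (1..{self.length})")

    def positions(self) -> dict[int, CloverleafCoordinate]:
        return dict(self._by_position)


def _pair_table(structure: str) -> list[tuple[int, int]]:
    stack: list[int] = []
    pairs: list[tuple[int, int]] = []
    for i, ch in enumerate(structure, start=1):
        if ch in "(<[{":
            stack.append(i)
        elif ch in ")>]}":
            if not stack:
                raise CloverleafError(f"unbalanced structure at position {i}")
            pairs.append((stack.pop(), i))
    if stack:
        raise CloverleafError("unbalanced structure: unclosed pairs")
    return sorted(pairs)


def _helices(pairs: list[tuple[int, int]]) -> list[list[tuple[int, int]]]:
    """Group base pairs into stacked helices (runs of (i+1, j-1) continuation)."""
    helices: list[list[tuple[int, int]]] = []
    for p in pairs:
        if helices and p[0] == helices[-1][-1][0] + 1 and p[1] == helices[-1][-1][1] - 1:
            helices[-1].append(p)
        else:
            helices.append([p])
    return helices


def assign_cloverleaf_coordinates(gene: TRNAGene) -> CloverleafMap:
    """Parse the gene's dot-bracket structure into the 15-segment cloverleaf map.

    The structure must contain exactly four helices nested as acceptor stem
    around D, anticodon and T stems (5'->3'); anything else (e.g. a degenerate
    mitochondrial fold missing an arm) raises :class:`CloverleafError` naming
    the gene.
    """
    length = gene.length
    pairs = _pair_table(gene.structure)
    if not pairs:
        raise CloverleafError(f"gene {gene.gene_id}: no base pairs in structure")
    helices = _helices(pairs)
    if len(helices) != 4:
        raise CloverleafError(
            f"gene {gene.gene_id}: expected 4 helices (acceptor, D, anticodon, T), "
            f"found {len(helices)} — not a canonical cloverleaf"
        )
    acceptor, d_stem, ac_stem, t_stem = helices
    # the acceptor stem must enclose the three arms
    if not (acceptor[0][0] < d_stem[0][0] and acceptor[0][1] > t_stem[0][1]):
        raise CloverleafError(f"gene {gene.gene_id}: helices are not nested as a cloverleaf")

    a5 = (acceptor[0][0], acceptor[-1][0])
    a3 = (acceptor[-1][1], acceptor[0][1])
    d5, d3 = (d_stem[0][0], d_stem[-1][0]), (d_stem[-1][1], d_stem[0][1])
    c5, c3 = (ac_stem[0][0], ac_stem[-1][0]), (ac_stem[-1][1], ac_stem[0][1])
    t5, t3 = (t_stem[0][0], t_stem[-1][0]), (t_stem[-1][1], t_stem[0][1])
    if a5[0] != 1:
        raise CloverleafError(f"gene {gene.gene_id}: acceptor stem does not start at position 1")
    if t3[1] + 1 != a3[0]:
        raise CloverleafError(
            f"gene {gene.gene_id}: T-stem 3' strand not contiguous with acceptor 3' strand"
        )
    if a3[1] >= length:
        raise CloverleafError(f"gene {gene.gene_id}: no discriminator/CCA after acceptor stem")

    bounds = [
        a5,
        (a5[1] + 1, d5[0] - 1),
        d5,
        (d5[1] + 1, d3[0] - 1),
        d3,
        (d3[1] + 1, c5[0] - 1),
        c5,
        (c5[1] + 1, c3[0] - 1),
        c3,
        (c3[1] + 1, t5[0] - 1),
        t5,
        (t5[1] + 1, t3[0] - 1),
        t3,
        a3,
        (a3[1] + 1, length),
    ]
    segments: list[tuple[int, int] | None] = []
    cursor = 1
    for k, (s, e) in enumerate(bounds, start=1):
        if e < s:
            segments.append(None)
            continue
        if s != cursor:
            raise CloverleafError(
                f"gene {gene.gene_id}: segment {k} starts at {s}, expected {cursor}"
            )
        segments.append((s, e))
        cursor = e + 1
    if cursor != length + 1:
        raise CloverleafError(f"gene {gene.gene_id}: segments do not tile 1..{length}")

    by_position: dict[int, CloverleafCoordinate] = {}
    for k, span in enumerate(segments, start=1):
        if span is None:
            continue
        for off, pos in enumerate(range(span[0], span[1] + 1), start=1):
            by_position[pos] = CloverleafCoordinate(segment=k, offset=off)
    return CloverleafMap(
        gene_id=gene.gene_id,
        length=length,
        segments=tuple(segments),
        _by_position=by_position,
    )


def cloverleaf_maps(genes: Iterable[TRNAGene]) -> tuple[dict[str, CloverleafMap], list[str]]:
    """Map every parseable gene; return (maps, ids of genes excluded with a warning)."""
    maps: dict[str, CloverleafMap] = {}
    skipped: list[str] = []
    for gene in genes:
        try:
            maps[gene.gene_id] = assign_cloverleaf_coordinates(gene)
        except CloverleafError as exc:
            logger.warning("excluding %s from cloverleaf mapping: %s", gene.gene_id, exc)
            skipped.append(gene.gene_id)
    return maps, skipped
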