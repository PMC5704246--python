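"""tRF quantification: species tables, per-nucleotide profiles, region assignment
and per-tRNA fragmentation classes.

A *tRF species* is a distinct (gene, start, end) fragment on the CCA-appended
mature tRNA.  Abundances are expressed in RPM (reads per million
category-assigned reads of the library).  Fragments are placed into the 5' /
middle / 3' region whose overlap covers at least 2/3 of the fragment
(inclusive), SPANNING otherwise, and each tRNA is classified from the
rpm-weighted mix of its fragments' regions.
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from fractions import Fraction
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .read_assignment import CategoryAssignment, ReadSet
from .reference_model import RegionPartition, TRNAGene

logger = logging.getLogger(__name__)

#: minimum fragment/region overlap share for a region call
REGION_OVERLAP_SHARE = Fraction(2, 3)


class RegionLabel(str, enum.Enum):
    FIVE = "FIVE"
    MID = "MID"
    THREE = "THREE"
    SPANNING = "SPANNING"


class TRNAClass(str, enum.Enum):
    FIVE = "FIVE"
    MID = "MID"
    THREE = "THREE"
    COMBINATION = "COMBINATION"
    LOW_RPM = "LOW_RPM"
    RANDOM = "RANDOM"
    NONE = "NONE"


SPECIES_COLUMNS = ["gene_id", "start", "end", "length", "count", "rpm"]


def build_species_table(
    assignments: Iterable[CategoryAssignment],
    readset: ReadSet,
    denominator: int,
    min_len: int = 15,
    max_len: int = 29,
    multi_gene: str = "each",
    category: str = "tRNA",
) -> pd.DataFrame:
    """Aggregate category-claimed reads into a per-(gene, start, end) species table.

    ``multi_gene`` controls how a read hitting several genes of the claiming
    category is counted: ``"each"`` gives the full count to every gene
    (isodecoders share sequence), ``"fractional"`` splits it evenly.  Category
    totals and RPM denominators are unaffected by this choice.
    """
    if multi_gene not in ("each", "fractional"):
        raise ValueError("multi_gene must be 'each' or 'fractional'")
    if denominator <= 0:
        raise ValueError("RPM denominator must be positive")
    acc: dict[tuple[str, int, int], float] = {}
    for a in assignments:
        if a.category != category or not a.gene_hits:
            continue
        count = readset.reads[a.sequence]
        weight = count / len(a.gene_hits) if multi_gene == "fractional" else count
        for gid, start, end in a.gene_hits:
            if not (min_len <= end - start + 1 <= max_len):
                continue
            key = (gid, start, end)
            acc[key] = acc.get(key, 0.0) + weight
    rows = [
        {
            "gene_id": gid,
            "start": start,
            "end": end,
            "length": end - start + 1,
            "count": count,
            "rpm": count * 1e6 / denominator,
        }
        for (gid, start, end), count in sorted(acc.items())
    ]
    return pd.DataFrame(rows, columns=SPECIES_COLUMNS)


def pool_species_tables(
    tables: Sequence[pd.DataFrame], denominators: Sequence[int]
) -> tuple[pd.DataFrame, int]:
    """Pool species counts across libraries; RPM uses the summed denominator."""
    if len(tables) != len(denominators):
        raise ValueError("one denominator per table required")
    denom = int(sum(denominators))
    merged = pd.concat(tables, ignore_index=True) if tables else pd.DataFrame(columns=SPECIES_COLUMNS)
    if merged.empty:
        return pd.DataFrame(columns=SPECIES_COLUMNS), denom
    pooled = (
        merged.groupby(["gene_id", "start", "end", "length"], as_index=False)["count"].sum()
    )
    pooled["rpm"] = pooled["count"] * 1e6 / denom
    return pooled[SPECIES_COLUMNS].sort_values(["gene_id", "start", "end"]).reset_index(drop=True), denom


def assign_region(start: int, end: int, partition: RegionPartition) -> RegionLabel:
    """Place one fragment using the inclusive 2/3-overlap rule.

    At most one disjoint region can reach the 2/3 threshold (asserted); a
    fragment reaching it nowhere is SPANNING.
    """
    if not (1 <= start <= end <= partition.length):
        raise ValueError(
            f"fragment [{start},{end}] outside tRNA of length {partition.length}"
        )
    length = end - start + 1
    winners = []
    for label, span in partition.spans().items():
        if span is None:
            continue
        overlap = min(end, span[1]) - max(start, span[0]) + 1
        if overlap > 0 and Fraction(overlap, length) >= REGION_OVERLAP_SHARE:
            winners.append(RegionLabel[label])
    assert len(winners) <= 1, "disjoint regions cannot both cover >= 2/3 of a fragment"
    return winners[0] if winners else RegionLabel.SPANNING


def add_regions(
    species: pd.DataFrame, partitions: Mapping[str, RegionPartition]
) -> pd.DataFrame:
    """Return a copy of the species table with a ``region`` column."""
    species = species.copy()
    species["region"] = [
        assign_region(int(s), int(e), partitions[g]).value
        for g, s, e in zip(species["gene_id"], species["start"], species["end"])
    ]
    return species


@dataclass(frozen=True)
class TRFProfile:
    """Per-nucleotide coverage of one tRNA.

    ``rpm[p-1]`` sums the rpm of every species covering position p;
    ``density[p-1]`` spreads each species' rpm uniformly over its length
    (rpm/length per covered position), so the density sums to the total
    species rpm of the gene.
    """

    gene_id: str
    rpm: np.ndarray
    density: np.ndarray


def build_profiles(
    species: pd.DataFrame, gene_lengths: Mapping[str, int]
) -> dict[str, TRFProfile]:
    profiles: dict[str, TRFProfile] = {}
    for gid, sub in species.groupby("gene_id"):
        length = gene_lengths[gid]
        rpm = np.zeros(length)
        density = np.zeros(length)
        for row in sub.itertuples():
            rpm[row.start - 1 : row.end] += row.rpm
            density[row.start - 1 : row.end] += row.rpm / row.length
        profiles[str(gid)] = TRFProfile(str(gid), rpm, density)
    return profiles


def superpose_on_representative(profiles: Mapping[str, TRFProfile]) -> np.ndarray:
    """Sum per-position rpm over genes, aligned at the 5' end (index 0 = position 1)."""
    if not profiles:
        raise ValueError("at least one profile required")
    max_len = max(p.rpm.size for p in profiles.values())
    out = np.zeros(max_len)
    for p in profiles.values():
        out[: p.rpm.size] += p.rpm
    return out


def five_prime_fraction(
    species: pd.DataFrame, window_end: int = 28, weight: str = "rpm", containment: str = "full"
) -> float:
    """RPM-weighted share of fragments lying within [1, window_end].

    ``containment="full"`` (default) counts only fragments entirely inside the
    window; ``"overlap"`` credits partial overlaps proportionally.
    """
    if window_end < 1:
        raise ValueError("window_end must be >= 1")
    total = float(species[weight].sum())
    if total <= 0:
        raise ValueError("zero total mass: five-prime fraction undefined")
    if containment == "full":
        inside = species[(species["start"] >= 1) & (species["end"] <= window_end)]
        return float(inside[weight].sum()) / total
    if containment == "overlap":
        overlap = (
            np.minimum(species["end"], window_end) - np.maximum(species["start"], 1) + 1
        ).clip(lower=0)
        return float((species[weight] * overlap / species["length"]).sum()) / total
    raise ValueError("containment must be 'full' or 'overlap'")


def length_distribution(species: pd.DataFrame, weight: str = "rpm") -> dict[int, float]:
    """Share of mass per fragment length; shares sum to 1."""
    if species.empty:
        raise ValueError("at least one species required")
    totals = species.groupby("length")[weight].sum()
    shares = totals / totals.sum()
    return {int(k): float(v) for k, v in shares.items()}


def classify_trna(
    gene_species: pd.DataFrame,
    rpm_threshold: float = 50.0,
    random_mass_share: float = 0.5,
    minor_share: float = 0.2,
) -> TRNAClass:
    """Classify one tRNA from its region-labelled species list.

    Order of the decision rule: no species -> NONE; total rpm below the
    threshold -> LOW_RPM; SPANNING mass at or above ``random_mass_share`` ->
    RANDOM; otherwise the set of regions holding at least ``minor_share`` of
    the total mass gives the label (COMBINATION when several regions qualify).
    Invariant to species order and to rescaling rpm together with the
    threshold.
    """
    if rpm_threshold < 0:
        raise ValueError("rpm_threshold must be >= 0")
    if gene_species.empty:
        return TRNAClass.NONE
    if "region" not in gene_species.columns:
        raise ValueError("species table lacks a 'region' column; call add_regions first")
    total = float(gene_species["rpm"].sum())
    if total < rpm_threshold:
        return TRNAClass.LOW_RPM
    by_region = gene_species.groupby("region")["rpm"].sum() / total
    if by_region.get(RegionLabel.SPANNING.value, 0.0) >= random_mass_share:
        return TRNAClass.RANDOM
    regional = by_region.drop(RegionLabel.SPANNING.value, errors="ignore")
    qualifying = regional[regional >= minor_share]
    if len(qualifying) >= 2:
        return TRNAClass.COMBINATION
    if len(qualifying) == 1:
        return TRNAClass[qualifying.index[0]]
    # nothing reaches the minor share (heavy spanning mass below the random
    # cutoff): fall back to the largest regional share
    return TRNAClass[regional.idxmax()]


def tabulate_classes(
    gene_ids: Iterable[str],
    species: pd.DataFrame,
    rpm_threshold: float = 50.0,
    random_mass_share: float = 0.5,
    minor_share: float = 0.2,
) -> pd.DataFrame:
    """Per-gene classes plus a class -> (count, gene list) summary.

    Genes absent from the species table are NONE; counts sum to the number of
    genes.
    """
    gene_ids = list(gene_ids)
    grouped = dict(tuple(species.groupby("gene_id"))) if not species.empty else {}
    empty = species.iloc[0:0]
    per_gene = {
        gid: classify_trna(
            grouped.get(gid, empty), rpm_threshold, random_mass_share, minor_share
        ).value
        for gid in gene_ids
    }
    rows = []
    for cls in TRNAClass:
        members = sorted(g for g, c in per_gene.items() if c == cls.value)
        rows.append(
            {
                "trna_class": cls.value,
                "n_genes": len(members),
                "genes": ";".join(members),
            }
        )
    table = pd.DataFrame(rows)
    assert int(table["n_genes"].sum()) == len(gene_ids)
    table.attrs["per_gene"] = per_gene
    return table


def gene_rpm_totals(species: pd.DataFrame) -> pd.Series:
    """Total rpm per gene (an aggregate feature vector for differential analysis)."""
    if species.empty:
        return pd.Series(dtype=float)
    return species.groupby("gene_id")["rpm"].sum()
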