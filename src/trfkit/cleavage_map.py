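"""3' cleavage-site profiles in linear and cloverleaf coordinates.

The cleavage site of a fragment is its last aligned nucleotide (the position
5' of the scissile bond).  Profiles default to 5'-region fragments (tRF-5s),
whose processing site is the object of interest; a flag widens them to all
fragments.  Linear profiles index the 3'-end position relative to the tRNA 5'
end; structural profiles translate the same position into the 15-segment
cloverleaf address, skipping (and counting) genes without a parseable
cloverleaf.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import pandas as pd

from .reference_model import CloverleafMap, format_coordinate

logger = logging.getLogger(__name__)

DEFAULT_REGIONS: tuple[str, ...] = ("FIVE",)


def _restrict(species: pd.DataFrame, regions: Sequence[str] | None) -> pd.DataFrame:
    if regions is None:
        return species
    if "region" not in species.columns:
        raise ValueError("species table lacks a 'region' column; call add_regions first")
    return species[species["region"].isin(list(regions))]


def linear_cleavage_profile(
    species: pd.DataFrame,
    regions: Sequence[str] | None = DEFAULT_REGIONS,
    weight: str = "rpm",
) -> pd.Series:
    """Mass accumulated at each fragment 3'-end position (relative to the 5' end)."""
    sub = _restrict(species, regions)
    if sub.empty:
        return pd.Series(dtype=float, name=weight)
    prof = sub.groupby("end")[weight].sum().sort_index()
    prof.index.name = "position"
    return prof


@dataclass
class StructuralCleavageProfile:
    """Per-(segment, offset) cleavage mass, plus the genes skipped for lack of structure."""

    table: pd.DataFrame
    skipped_genes: tuple[str, ...] = ()
    skipped_mass: float = 0.0

    @property
    def total(self) -> float:
        return float(self.table["rpm"].sum()) if not self.table.empty else 0.0

    def segment_totals(self) -> pd.Series:
        if self.table.empty:
            return pd.Series(dtype=float)
        return self.table.groupby("segment")["rpm"].sum()


def structural_cleavage_profile(
    species: pd.DataFrame,
    maps: Mapping[str, CloverleafMap],
    regions: Sequence[str] | None = DEFAULT_REGIONS,
    weight: str = "rpm",
) -> StructuralCleavageProfile:
    """Translate 3' ends into cloverleaf addresses and accumulate mass per address.

    Total mass equals the linear profile's total for genes with a cloverleaf
    annotation; genes without one are skipped with a logged count.
    """
    sub = _restrict(species, regions)
    acc: dict[tuple[int, int], float] = {}
    skipped: dict[str, float] = {}
    for row in sub.itertuples():
        cmap = maps.get(row.gene_id)
        mass = getattr(row, weight)
        if cmap is None:
            skipped[row.gene_id] = skipped.get(row.gene_id, 0.0) + mass
            continue
        coord = cmap.coordinate(int(row.end))
        acc[(coord.segment, coord.offset)] = acc.get((coord.segment, coord.offset), 0.0) + mass
    if skipped:
        logger.info(
            "structural cleavage profile skipped %d genes without cloverleaf structure",
            len(skipped),
        )
    rows = [
        {
            "segment": seg,
            "offset": off,
            "address": format_coordinate_tuple(seg, off),
            "rpm": mass,
        }
        for (seg, off), mass in sorted(acc.items())
    ]
    return StructuralCleavageProfile(
        table=pd.DataFrame(rows, columns=["segment", "offset", "address", "rpm"]),
        skipped_genes=tuple(sorted(skipped)),
        skipped_mass=float(sum(skipped.values())),
    )


def format_coordinate_tuple(segment: int, offset: int) -> str:
    from .reference_model import CloverleafCoordinate

    return format_coordinate(CloverleafCoordinate(segment=segment, offset=offset))


@dataclass(frozen=True)
class CleavageComparison:
    modal_a: int
    modal_b: int

    @property
    def separation(self) -> int:
        return self.modal_b - self.modal_a


def compare_cleavage_modes(profile_a: pd.Series, profile_b: pd.Series) -> CleavageComparison:
    """Modal 3'-end position of two linear profiles and their separation in nt.

    Typically ``profile_a`` holds the short tRFs and ``profile_b`` the longer
    tRNA halves, so a positive separation means the halves are cleaved further
    3'.
    """
    if profile_a.empty or profile_b.empty:
        raise ValueError("both cleavage profiles must be non-empty")
    return CleavageComparison(
        modal_a=int(profile_a.idxmax()), modal_b=int(profile_b.idxmax())
    )
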