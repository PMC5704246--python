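"""Stage / fraction differential quantitation of tRF abundances.

The libraries were pooled before sequencing, so there is no replicate-level
variance to fit: the analysis deliberately stops at pseudocounted fold
changes, fraction-distribution shares and a permutation-friendly rank
concordance — no p-values are fabricated.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

TOTAL_FRACTION = "Total"
DEFAULT_FRACTIONS: tuple[str, ...] = ("mRNP", "60S", "monosome", "polysome")


@dataclass
class AbundanceMatrix:
    """Feature x library RPM matrix with (stage, fraction) column metadata.

    ``counts`` and per-column ``denominators`` are retained so pooled columns
    (e.g. a derived unfractionated Total) can be computed on the count scale.
    """

    rpm: pd.DataFrame
    counts: pd.DataFrame
    denominators: pd.Series

    @property
    def stages(self) -> list[str]:
        return sorted({s for s, _ in self.rpm.columns})

    def column(self, stage: str, fraction: str) -> pd.Series:
        key = (stage, fraction)
        if key not in self.rpm.columns:
            raise KeyError(f"missing library column (stage={stage!r}, fraction={fraction!r})")
        return self.rpm[key]


def build_abundance_matrix(
    feature_counts: Mapping[str, pd.Series],
    metadata: Mapping[str, tuple[str, str]],
    denominators: Mapping[str, int],
    derive_total: bool = True,
) -> AbundanceMatrix:
    """Assemble per-library feature counts into an :class:`AbundanceMatrix`.

    ``feature_counts`` maps library_id -> Series (feature -> raw count);
    ``metadata`` maps library_id -> (stage, fraction).  When ``derive_total``
    is set and a stage has no Total column, one is synthesized by pooling that
    stage's fraction libraries (counts and denominators summed).
    """
    if set(feature_counts) != set(metadata) or set(feature_counts) != set(denominators):
        raise ValueError("feature_counts, metadata and denominators must share library ids")
    counts = pd.DataFrame(
        {metadata[lib]: ser for lib, ser in feature_counts.items()}
    ).fillna(0.0)
    counts.columns = pd.MultiIndex.from_tuples(counts.columns, names=["stage", "fraction"])
    denom = pd.Series({metadata[lib]: float(denominators[lib]) for lib in denominators})
    denom.index = pd.MultiIndex.from_tuples(denom.index, names=["stage", "fraction"])
    if derive_total:
        for stage in {s for s, _ in counts.columns}:
            if (stage, TOTAL_FRACTION) in counts.columns:
                continue
            frac_cols = [c for c in counts.columns if c[0] == stage]
            counts[(stage, TOTAL_FRACTION)] = counts[frac_cols].sum(axis=1)
            denom[(stage, TOTAL_FRACTION)] = float(denom[frac_cols].sum())
    counts = counts.sort_index(axis=1)
    denom = denom.sort_index()
    rpm = counts / denom * 1e6
    return AbundanceMatrix(rpm=rpm, counts=counts, denominators=denom)


@dataclass(frozen=True)
class FoldChangeRecord:
    feature: str
    rpm_a: float
    rpm_b: float
    fold: float
    direction: str


def stage_fold_changes(
    matrix: AbundanceMatrix,
    stage_a: str,
    stage_b: str,
    fraction: str = TOTAL_FRACTION,
    pseudocount: float = 1.0,
) -> pd.DataFrame:
    """Per-feature fold change max(a,b)/min(a,b) between two stages of one fraction.

    Folds are computed on pseudocounted rpm and are always >= 1, with the
    direction recorded; the table is sorted by fold, descending.  fold(a,b)
    equals fold(b,a) with the direction flipped, and with pseudocount 0 the
    fold is invariant to rescaling both columns by a common factor.
    """
    a = matrix.column(stage_a, fraction) + pseudocount
    b = matrix.column(stage_b, fraction) + pseudocount
    if ((a <= 0) | (b <= 0)).any():
        raise ValueError("non-positive pseudocounted rpm; use a positive pseudocount")
    fold = np.maximum(a, b) / np.minimum(a, b)
    direction = np.where(a > b, "up_in_a", np.where(b > a, "up_in_b", "unchanged"))
    out = pd.DataFrame(
        {
            "rpm_a": matrix.column(stage_a, fraction),
            "rpm_b": matrix.column(stage_b, fraction),
            "fold": fold,
            "direction": direction,
        }
    )
    out.index.name = "feature"
    return out.sort_values("fold", ascending=False)


def fraction_distribution(
    matrix: AbundanceMatrix,
    stage: str,
    fractions: Sequence[str] = DEFAULT_FRACTIONS,
) -> tuple[pd.DataFrame, pd.Series]:
    """Per-feature rpm shares across gradient fractions, plus the aggregate share.

    Shares sum to 1 for every feature with nonzero total; features with zero
    total across the fractions are dropped.
    """
    cols = pd.DataFrame({f: matrix.column(stage, f) for f in fractions})
    totals = cols.sum(axis=1)
    shares = cols[totals > 0].div(totals[totals > 0], axis=0)
    aggregate = cols.sum(axis=0)
    aggregate = aggregate / aggregate.sum()
    return shares, aggregate


def ratio_concordance(
    matrix: AbundanceMatrix,
    stage_a: str,
    stage_b: str,
    fractions: Sequence[str] = DEFAULT_FRACTIONS,
    pseudocount: float = 1.0,
    rpm_floor: float = 50.0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stage log2-ratios per column and their rank concordance with Total.

    Features are restricted to those whose Total rpm reaches ``rpm_floor`` in
    at least one of the two stages.  Returns (per-feature log-ratio table,
    per-fraction Spearman concordance with the Total log-ratios).
    """
    total_a = matrix.column(stage_a, TOTAL_FRACTION)
    total_b = matrix.column(stage_b, TOTAL_FRACTION)
    keep = (total_a >= rpm_floor) | (total_b >= rpm_floor)
    ratios = pd.DataFrame(index=matrix.rpm.index[keep])
    ratios[TOTAL_FRACTION] = np.log2(
        (total_a[keep] + pseudocount) / (total_b[keep] + pseudocount)
    )
    for f in fractions:
        a = matrix.column(stage_a, f)[keep] + pseudocount
        b = matrix.column(stage_b, f)[keep] + pseudocount
        ratios[f] = np.log2(a / b)
    rows = []
    for f in fractions:
        if len(ratios) > 2:
            rho = float(stats.spearmanr(ratios[TOTAL_FRACTION], ratios[f]).statistic)
        else:
            rho = float("nan")
        rows.append({"fraction": f, "n_features": len(ratios), "spearman_rho": rho})
    return ratios, pd.DataFrame(rows)
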