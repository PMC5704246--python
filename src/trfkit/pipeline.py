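"""End-to-end orchestration: assignment -> quantification -> cleavage -> differential.

``analyze`` is the in-memory engine (references + read sets in, result object
out); ``run_pipeline`` wraps it with file IO, a run log, a config echo and
TSV outputs whose headers record the tool version, a config hash and the RPM
denominators.  Intermediates are plain TSV so any stage is inspectable.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import yaml

from . import __version__
from .cleavage_map import (
    CleavageComparison,
    StructuralCleavageProfile,
    compare_cleavage_modes,
    linear_cleavage_profile,
    structural_cleavage_profile,
)
from .differential import (
    AbundanceMatrix,
    build_abundance_matrix,
    fraction_distribution,
    ratio_concordance,
    stage_fold_changes,
)
from .read_assignment import (
    CategoryAssignment,
    ReadSet,
    assign_reads,
    category_totals,
    from_collapsed_fasta,
    from_fastq,
    mapped_total,
)
from .reference_model import (
    CloverleafMap,
    ReferenceCategory,
    TRNAGene,
    build_trna_genes,
    cloverleaf_maps,
    load_references,
    partition_regions,
    read_structure_table,
)
from .trf_quantify import (
    add_regions,
    build_profiles,
    build_species_table,
    five_prime_fraction,
    gene_rpm_totals,
    length_distribution,
    pool_species_tables,
    superpose_on_representative,
    tabulate_classes,
)

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid run configuration (CLI exit code 2)."""


class InputError(ValueError):
    """Missing or malformed input (CLI exit code 3)."""


@dataclass
class AnalysisParams:
    """Thresholds of the analysis, all exposed and echoed into output headers."""

    min_len: int = 15
    max_len: int = 29
    half_min_len: int = 33
    half_max_len: int = 40
    max_tier: int = 0
    rpm_threshold: float = 50.0
    random_mass_share: float = 0.5
    minor_share: float = 0.2
    window_end: int = 28
    pseudocount: float = 1.0
    rpm_floor: float = 50.0
    multi_gene: str = "each"
    stage_a: str = "0-1h"
    stage_b: str = "7-8h"

    def validate(self) -> None:
        if not (1 <= self.min_len <= self.max_len):
            raise ConfigError("invalid tRF length bounds")
        if not (0 <= self.max_tier <= 3):
            raise ConfigError("max_tier must be 0..3")
        if self.rpm_threshold < 0 or not (0 < self.random_mass_share <= 1) or not (
            0 < self.minor_share <= 1
        ):
            raise ConfigError("thresholds out of documented range")


@dataclass
class LibraryResult:
    readset: ReadSet
    assignments: list[CategoryAssignment]
    mapped: int
    category_counts: dict[str, int]
    species: pd.DataFrame  # region-labelled tRF species, lengths within [min_len, max_len]
    half_species: pd.DataFrame


@dataclass
class PipelineResult:
    params: AnalysisParams
    genes: list[TRNAGene]
    maps: dict[str, CloverleafMap]
    unfoldable_genes: list[str]
    libraries: dict[str, LibraryResult]
    pooled_species: pd.DataFrame
    pooled_denominator: int
    pooled_half_species: pd.DataFrame
    superposition: pd.Series
    five_prime_fraction: float
    length_shares: dict[int, float]
    class_table: pd.DataFrame
    linear_cleavage: pd.Series
    structural_cleavage: StructuralCleavageProfile
    half_linear_cleavage: pd.Series
    cleavage_comparison: CleavageComparison | None
    matrix: AbundanceMatrix | None
    fold_changes: pd.DataFrame | None
    fraction_shares: pd.DataFrame | None
    fraction_aggregate: pd.Series | None
    log_ratios: pd.DataFrame | None
    concordance: pd.DataFrame | None

    @property
    def n_genes_tested(self) -> int:
        return len(self.genes)

    @property
    def n_genes_folded(self) -> int:
        return len(self.maps)


def analyze(
    categories: Sequence[ReferenceCategory],
    genes: Sequence[TRNAGene],
    readsets: Sequence[ReadSet],
    params: AnalysisParams | None = None,
) -> PipelineResult:
    """Run the full analysis in memory.

    Assignment happens once per distinct sequence across all libraries (shared
    cache); the RPM denominator of each library is its total category-assigned
    read count, taken before any length windowing.
    """
    params = params or AnalysisParams()
    params.validate()
    if not readsets:
        raise InputError("no read libraries supplied")
    gene_lengths = {g.gene_id: g.length for g in genes}
    partitions = {g.gene_id: partition_regions(g) for g in genes}
    maps, unfoldable = cloverleaf_maps(genes)

    cache: dict[str, CategoryAssignment] = {}
    lib_results: dict[str, LibraryResult] = {}
    any_trna = False
    for rs in readsets:
        assignments = assign_reads(rs, categories, params.max_tier, cache=cache)
        mapped = mapped_total(assignments, rs)
        totals = category_totals(assignments, rs)
        if mapped == 0:
            logger.warning("%s: no reads assigned to any category", rs.library_id)
            species = pd.DataFrame(columns=["gene_id", "start", "end", "length", "count", "rpm", "region"])
            halves = species.copy()
        else:
            species = add_regions(
                build_species_table(
                    assignments, rs, mapped, params.min_len, params.max_len, params.multi_gene
                ),
                partitions,
            )
            halves = add_regions(
                build_species_table(
                    assignments, rs, mapped, params.half_min_len, params.half_max_len, params.multi_gene
                ),
                partitions,
            )
        any_trna = any_trna or not species.empty
        lib_results[rs.library_id] = LibraryResult(rs, assignments, mapped, totals, species, halves)
    if not any_trna:
        logger.warning("no tRNA-assigned reads in any library; downstream tables will be empty")

    pooled, pooled_denom = pool_species_tables(
        [r.species for r in lib_results.values()],
        [r.mapped for r in lib_results.values()],
    )
    pooled = add_regions(pooled, partitions) if not pooled.empty else pooled
    pooled_half, _ = pool_species_tables(
        [r.half_species for r in lib_results.values()],
        [r.mapped for r in lib_results.values()],
    )
    pooled_half = add_regions(pooled_half, partitions) if not pooled_half.empty else pooled_half

    if pooled.empty:
        superposition = pd.Series(dtype=float)
        fp_fraction = float("nan")
        length_shares: dict[int, float] = {}
    else:
        profiles = build_profiles(pooled, gene_lengths)
        arr = superpose_on_representative(profiles)
        superposition = pd.Series(arr, index=range(1, arr.size + 1), name="rpm")
        fp_fraction = five_prime_fraction(pooled, params.window_end)
        length_shares = length_distribution(pooled)
    class_table = tabulate_classes(
        [g.gene_id for g in genes],
        pooled,
        params.rpm_threshold,
        params.random_mass_share,
        params.minor_share,
    )
    linear = linear_cleavage_profile(pooled) if not pooled.empty else pd.Series(dtype=float)
    structural = structural_cleavage_profile(pooled, maps) if not pooled.empty else StructuralCleavageProfile(
        pd.DataFrame(columns=["segment", "offset", "address", "rpm"])
    )
    half_linear = (
        linear_cleavage_profile(pooled_half, regions=None) if not pooled_half.empty else pd.Series(dtype=float)
    )
    comparison = (
        compare_cleavage_modes(linear, half_linear) if not linear.empty and not half_linear.empty else None
    )

    matrix = fold = shares = aggregate = ratios = concordance = None
    stages = {r.readset.stage for r in lib_results.values()}
    try:
        matrix = build_abundance_matrix(
            {lid: gene_rpm_totals(r.species) * r.mapped / 1e6 for lid, r in lib_results.items()},
            {lid: (r.readset.stage, r.readset.fraction) for lid, r in lib_results.items()},
            {lid: r.mapped for lid, r in lib_results.items()},
        )
        if {params.stage_a, params.stage_b} <= stages:
            fold = stage_fold_changes(matrix, params.stage_a, params.stage_b, pseudocount=params.pseudocount)
            fractions = tuple(
                f
                for f in ("mRNP", "60S", "monosome", "polysome")
                if (params.stage_a, f) in matrix.rpm.columns
            )
            if len(fractions) == 4:
                shares, aggregate = fraction_distribution(matrix, params.stage_a, fractions)
            if fractions:
                ratios, concordance = ratio_concordance(
                    matrix,
                    params.stage_a,
                    params.stage_b,
                    fractions,
                    params.pseudocount,
                    params.rpm_floor,
                )
        else:
            logger.warning(
                "stages %s/%s not both present; differential stage skipped", params.stage_a, params.stage_b
            )
    except (KeyError, ValueError) as exc:
        logger.warning("differential stage skipped: %s", exc)

    return PipelineResult(
        params=params,
        genes=list(genes),
        maps=maps,
        unfoldable_genes=unfoldable,
        libraries=lib_results,
        pooled_species=pooled,
        pooled_denominator=pooled_denom,
        pooled_half_species=pooled_half,
        superposition=superposition,
        five_prime_fraction=fp_fraction,
        length_shares=length_shares,
        class_table=class_table,
        linear_cleavage=linear,
        structural_cleavage=structural,
        half_linear_cleavage=half_linear,
        cleavage_comparison=comparison,
        matrix=matrix,
        fold_changes=fold,
        fraction_shares=shares,
        fraction_aggregate=aggregate,
        log_ratios=ratios,
        concordance=concordance,
    )


# ---------------------------------------------------------------------------
# file-based run


@dataclass
class RunConfig:
    """File-level pipeline configuration; round-trips losslessly to YAML."""

    references: dict[str, str] = field(default_factory=dict)  # category -> FASTA path
    structure_path: str = ""
    metadata_path: str = ""  # TSV: library_id, stage, fraction, path, format
    outdir: str = "trfkit_out"
    adapter: str | None = None
    params: AnalysisParams = field(default_factory=AnalysisParams)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        try:
            with open(path) as fh:
                raw = yaml.safe_load(fh) or {}
        except FileNotFoundError as exc:
            raise ConfigError(f"config file not found: {path}") from exc
        params = AnalysisParams(**raw.pop("params", {}))
        try:
            return cls(params=params, **raw)
        except TypeError as exc:
            raise ConfigError(f"invalid run config: {exc}") from exc

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(data, fh, sort_keys=False)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(asdict(self), sort_keys=True).encode()).hexdigest()[:12]


def _load_inputs(config: RunConfig) -> tuple[list[ReferenceCategory], list[TRNAGene], list[ReadSet]]:
    for name, path in {**config.references, "structure": config.structure_path,
                       "metadata": config.metadata_path}.items():
        if not path or not Path(path).exists():
            raise InputError(f"missing input file for {name!r}: {path!r}")
    categories = load_references(config.references)
    genes = build_trna_genes(read_structure_table(config.structure_path), append_cca=True)
    if "tRNA" not in config.references:
        # the tRNA category is built from the structure table (CCA appended)
        from .reference_model import references_from_dict

        cats = {c.name: dict(c.sequences) for c in categories}
        cats["tRNA"] = {g.gene_id: g.sequence for g in genes}
        categories = references_from_dict(cats)
    meta = pd.read_csv(config.metadata_path, sep="\t")
    required = {"library_id", "stage", "fraction", "path"}
    if not required <= set(meta.columns):
        raise InputError(f"metadata table must have columns {sorted(required)}")
    readsets = []
    for row in meta.itertuples():
        fmt = getattr(row, "format", "collapsed_fasta")
        reader = from_fastq if fmt == "fastq" else from_collapsed_fasta
        if not Path(row.path).exists():
            raise InputError(f"library file not found: {row.path}")
        readsets.append(
            reader(row.path, row.library_id, row.stage, row.fraction, adapter=config.adapter)
        )
    return categories, genes, readsets


def _write_tsv(df: pd.DataFrame, path: Path, header_lines: list[str], index: bool = False) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(f"# {line}\n")
        df.to_csv(fh, sep="\t", index=index)


def write_outputs(result: PipelineResult, config: RunConfig, outdir: Path) -> None:
    outdir.mkdir(parents=True, exist_ok=True)
    denoms = {lid: r.mapped for lid, r in result.libraries.items()}
    header = [
        f"trfkit {__version__}",
        f"config_hash={config.config_hash()}",
        "rpm_denominator=category-assigned reads per library: "
        + ",".join(f"{k}:{v}" for k, v in denoms.items()),
        f"params={json.dumps(asdict(result.params))}",
    ]
    for lid, r in result.libraries.items():
        from .read_assignment import assignments_to_frame

        _write_tsv(assignments_to_frame(r.assignments, r.readset), outdir / f"assignments_{lid}.tsv", header)
        _write_tsv(r.species, outdir / f"species_{lid}.tsv", header)
    summary = pd.DataFrame(
        [
            {"library_id": lid, "category": cat, "reads": n}
            for lid, r in result.libraries.items()
            for cat, n in sorted(r.category_counts.items())
        ]
    )
    _write_tsv(summary, outdir / "category_summary.tsv", header)
    _write_tsv(result.pooled_species, outdir / "species_pooled.tsv", header)
    _write_tsv(result.class_table, outdir / "trna_classes.tsv", header)
    _write_tsv(result.superposition.rename_axis("position").reset_index(), outdir / "superposition.tsv", header)
    _write_tsv(
        result.linear_cleavage.rename_axis("position").reset_index(), outdir / "cleavage_linear.tsv", header
    )
    _write_tsv(result.structural_cleavage.table, outdir / "cleavage_structural.tsv", header)
    _write_tsv(
        result.half_linear_cleavage.rename_axis("position").reset_index(),
        outdir / "cleavage_halves_linear.tsv",
        header,
    )
    if result.fold_changes is not None:
        _write_tsv(result.fold_changes.reset_index(), outdir / "stage_fold_changes.tsv", header)
    if result.fraction_shares is not None:
        _write_tsv(result.fraction_shares.rename_axis("feature").reset_index(), outdir / "fraction_shares.tsv", header)
    if result.concordance is not None:
        _write_tsv(result.concordance, outdir / "ratio_concordance.tsv", header)
    run_info = {
        "version": __version__,
        "config_hash": config.config_hash(),
        "n_genes_tested": result.n_genes_tested,
        "n_genes_folded": result.n_genes_folded,
        "unfoldable_genes": result.unfoldable_genes,
        "denominators": denoms,
        "five_prime_fraction": result.five_prime_fraction,
    }
    with open(outdir / "run_manifest.json", "w") as fh:
        json.dump(run_info, fh, indent=2, sort_keys=True)
    config.to_yaml(outdir / "config_echo.yaml")


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Load inputs per the run config, analyze, and write all output TSVs."""
    categories, genes, readsets = _load_inputs(config)
    result = analyze(categories, genes, readsets, config.params)
    write_outputs(result, config, Path(config.outdir))
    return result
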