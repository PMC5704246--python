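"""Synthetic references, libraries and ground-truth manifests.

The generator emulates the structure of fractionated embryonic small-RNA
libraries: 15-29 nt tRNA fragments dominated by 5'-anchored species whose 3'
ends are enriched at positions 26-28, a minority of longer (33-40 nt) tRNA
halves, background reads from rRNA/miRNA-hairpin/transcript/intergenic
references, a small unmappable remainder, and stage- and fraction-dependent
abundance differences (mRNP-skewed tRFs; designated species with fixed
expected rpm fold changes between stages).

Key design properties, relied upon by the recovery tests:

* every expressing gene distributes its tRF mass over fragment lengths with
  exactly the configured length weights, so the expected pooled length
  distribution equals the configured one regardless of the class mix;
* the tRF / half / background / unmatched block shares of every library are
  fixed, so expected RPM values, fraction shares (80/15/3/2 across
  mRNP/60S/monosome/polysome by default) and stage folds are exact;
* stage multipliers are calibrated against the compositional closure of RPM,
  so the *expected rpm fold* of a designated species equals the configured
  value;
* all randomness flows from the single seed.
"""
from __future__ import annotations

import json
import gzip
from dataclasses import dataclass, field, asdict, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .read_assignment import ReadSet
from .reference_model import (
    ReferenceCategory,
    TRNAGene,
    build_trna_genes,
    partition_regions,
    references_from_dict,
    write_structure_table,
)
from .trf_quantify import RegionLabel, TRNAClass, assign_region

_NT = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMPLEMENT = str.maketrans("ACGT", "TGCA")

# fixed 5'-side cloverleaf geometry (nt) so that linear 3'-end positions map to
# stable structural addresses across genes; only the variable loop varies
ACC_STEM = 7
LINKER1 = 2
D_STEM = 3
D_LOOP = 8
LINKER2 = 1
AC_STEM = 5
AC_LOOP = 7
T_STEM = 5
T_LOOP = 7

KMER_SCREEN = 15  # background refs and tRNA genes share no 15-mer


def _revcomp(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _random_nt(rng: np.random.Generator, n: int) -> str:
    return bytes(_NT[rng.integers(0, 4, size=n)]).decode()


def default_length_weights() -> dict[int, float]:
    """Fragment-length weights: 0.251/0.183/0.176 at 28/27/26, rest uniform 15-25,29."""
    head = {28: 0.251, 27: 0.183, 26: 0.176}
    rest = [l for l in range(15, 30) if l not in head]
    share = (1.0 - sum(head.values())) / len(rest)
    return {l: head.get(l, share) for l in range(15, 30)}


def default_half_end_weights() -> dict[int, float]:
    return {33: 0.10, 34: 0.10, 35: 0.25, 36: 0.15, 37: 0.10, 38: 0.10, 39: 0.10, 40: 0.10}


@dataclass(frozen=True)
class SpecialGeneSpec:
    """A designated tRNA with a fixed expected rpm fold change between stages."""

    gene_id: str
    amino_acid: str
    anticodon: str  # actual triplet placed in the anticodon loop
    weight: float  # pre-normalization share of tRF mass
    stage_fold: dict[str, float] = field(default_factory=dict)  # stage -> fold vs other stage
    mitochondrial: bool = False


def default_special_genes() -> tuple[SpecialGeneSpec, ...]:
    return (
        SpecialGeneSpec("tRNA-Pro-AGG-1", "Pro", "AGG", 0.02, {"0-1h": 3.7}),
        SpecialGeneSpec("tRNA-Gly-GCC-1", "Gly", "GCC", 0.02, {"7-8h": 4.6}),
        SpecialGeneSpec("mt:tRNA-Ser-AGY-1", "Ser", "GCT", 0.004, {"7-8h": 18.9}, True),
    )


AA_ANTICODONS: tuple[tuple[str, str], ...] = (
    ("Ala", "AGC"), ("Arg", "ACG"), ("Asn", "GTT"), ("Asp", "GTC"), ("Cys", "GCA"),
    ("Gln", "TTG"), ("Glu", "TTC"), ("Gly", "GCC"), ("His", "GTG"), ("Ile", "AAT"),
    ("Leu", "TAG"), ("Lys", "CTT"), ("Met", "CAT"), ("Phe", "GAA"), ("Pro", "AGG"),
    ("Ser", "AGA"), ("Thr", "AGT"), ("Trp", "CCA"), ("Tyr", "GTA"), ("Val", "CAC"),
)


@dataclass(frozen=True)
class LibrarySpec:
    library_id: str
    stage: str
    fraction: str
    depth: int


@dataclass
class SimulationConfig:
    """Full specification of a synthetic scenario; all randomness flows from ``seed``."""

    seed: int = 0
    n_trna_genes: int = 111
    class_counts: dict[str, int] = field(
        default_factory=lambda: {
            "FIVE": 50, "MID": 7, "THREE": 14, "COMBINATION": 16,
            "LOW_RPM": 20, "RANDOM": 2, "NONE": 2,
        }
    )
    n_degenerate_structures: int = 8  # genes kept for region analyses, unfoldable as cloverleafs
    special_genes: tuple[SpecialGeneSpec, ...] = field(default_factory=default_special_genes)
    length_weights: dict[int, float] = field(default_factory=default_length_weights)
    half_end_weights: dict[int, float] = field(default_factory=default_half_end_weights)
    var_loop_range: tuple[int, int] = (4, 5)
    # pre-normalization tRF mass budget per class
    five_mass: float = 0.93
    combination_mass: float = 0.045
    mid_gene_weight: float = 8e-4
    three_gene_weight: float = 8e-4
    random_gene_weight: float = 2e-3
    low_rpm_gene_weight: float = 1e-4
    lognormal_sigma: float = 0.8
    combo_five_share: float = 0.6
    random_spanning_share: float = 0.7
    five_prime_window_mass: float | None = None  # exact in-window mass target (window preset)
    window_end: int = 28
    calibrate_compositional: bool = True
    # library design
    stages: tuple[str, str] = ("0-1h", "7-8h")
    fractions: tuple[str, ...] = ("mRNP", "60S", "monosome", "polysome")
    depth: int = 50_000
    libraries: tuple[LibrarySpec, ...] | None = None
    trf_share: dict[str, float] = field(
        default_factory=lambda: {
            "mRNP": 0.48, "60S": 0.09, "monosome": 0.018, "polysome": 0.012, "Total": 0.15,
        }
    )
    half_share: dict[str, float] = field(
        default_factory=lambda: {
            "mRNP": 0.08, "60S": 0.015, "monosome": 0.003, "polysome": 0.002, "Total": 0.025,
        }
    )
    unmatched_share: float = 0.04
    background_split: dict[str, float] = field(
        default_factory=lambda: {"rRNA": 0.5, "hairpin": 0.2, "transcript": 0.2, "intergenic": 0.1}
    )
    background_read_lengths: tuple[int, int] = (18, 28)
    unmatched_read_lengths: tuple[int, int] = (20, 24)
    collision_decoys: bool = False
    error_rate: float = 0.0

    def library_specs(self) -> tuple[LibrarySpec, ...]:
        if self.libraries is not None:
            return tuple(self.libraries)
        return tuple(
            LibrarySpec(f"{stage}_{fraction}", stage, fraction, self.depth)
            for stage in self.stages
            for fraction in self.fractions
        )


def default_scenario(seed: int = 0) -> SimulationConfig:
    """The headline scenario: 111 genes, 8 fractionated libraries of 50k reads."""
    return SimulationConfig(seed=seed)


def window_scenario(seed: int = 0, window_mass: float = 0.95) -> SimulationConfig:
    """A single-library scenario with exactly ``window_mass`` of expected tRF
    mass generated inside [1, 28]."""
    return SimulationConfig(
        seed=seed,
        n_trna_genes=30,
        class_counts={"FIVE": 30},
        n_degenerate_structures=0,
        special_genes=(),
        five_mass=1.0,
        combination_mass=0.0,
        five_prime_window_mass=window_mass,
        libraries=(LibrarySpec("window_Total", "0-1h", "Total", 50_000),),
        trf_share={"Total": 0.5},
        half_share={"Total": 0.02},
    )


def small_scenario(seed: int = 0) -> SimulationConfig:
    """A fast scenario for unit tests and examples."""
    return SimulationConfig(
        seed=seed,
        n_trna_genes=12,
        class_counts={"FIVE": 5, "MID": 1, "THREE": 2, "COMBINATION": 2, "RANDOM": 1, "NONE": 1},
        n_degenerate_structures=1,
        five_mass=0.9,
        combination_mass=0.06,
        mid_gene_weight=5e-3,
        three_gene_weight=5e-3,
        random_gene_weight=8e-3,
        depth=5_000,
    )


# ---------------------------------------------------------------------------
# reference generation


@dataclass
class GeneSpec:
    gene_id: str
    amino_acid: str
    anticodon: str
    trna_class: str
    weight: float
    mitochondrial: bool = False
    degenerate: bool = False
    stage_fold: dict[str, float] = field(default_factory=dict)


@dataclass
class References:
    """Synthetic reference sets: background categories plus tRNA genes."""

    background: dict[str, dict[str, str]]
    trna_rows: list[dict[str, object]]
    genes: list[TRNAGene]
    gene_specs: list[GeneSpec]

    def reference_categories(self) -> list[ReferenceCategory]:
        cats: dict[str, dict[str, str]] = {k: dict(v) for k, v in self.background.items()}
        cats["tRNA"] = {g.gene_id: g.sequence for g in self.genes}
        return references_from_dict(cats)


def _gene_structure(var_loop: int, degenerate: bool) -> str:
    d_arm = "(" * D_STEM + "." * D_LOOP + ")" * D_STEM
    if degenerate:
        d_arm = "." * len(d_arm)
    return (
        "(" * ACC_STEM
        + "." * LINKER1
        + d_arm
        + "." * LINKER2
        + "(" * AC_STEM
        + "." * AC_LOOP
        + ")" * AC_STEM
        + "." * var_loop
        + "(" * T_STEM
        + "." * T_LOOP
        + ")" * T_STEM
        + ")" * ACC_STEM
        + "."  # discriminator
    )


def _gene_sequence(rng: np.random.Generator, anticodon: str, var_loop: int) -> str:
    acc5 = _random_nt(rng, ACC_STEM)
    link1 = _random_nt(rng, LINKER1)
    d5 = _random_nt(rng, D_STEM)
    dloop = _random_nt(rng, D_LOOP)
    link2 = _random_nt(rng, LINKER2)
    ac5 = _random_nt(rng, AC_STEM)
    loop = _random_nt(rng, 2) + anticodon + _random_nt(rng, AC_LOOP - 5)
    var = _random_nt(rng, var_loop)
    t5 = _random_nt(rng, T_STEM)
    tloop = _random_nt(rng, T_LOOP)
    disc = _random_nt(rng, 1)
    return (
        acc5 + link1 + d5 + dloop + _revcomp(d5) + link2
        + ac5 + loop + _revcomp(ac5) + var
        + t5 + tloop + _revcomp(t5) + _revcomp(acc5) + disc
    )


#: 1-based start of the anticodon on the gene body (fixed 5'-side geometry)
ANTICODON_START = ACC_STEM + LINKER1 + 2 * D_STEM + D_LOOP + LINKER2 + AC_STEM + 3  # = 32


def _kmers(seq: str, k: int = KMER_SCREEN) -> set[str]:
    return {seq[i : i + k] for i in range(len(seq) - k + 1)}


def _build_gene_specs(config: SimulationConfig, rng: np.random.Generator) -> list[GeneSpec]:
    counts = dict(config.class_counts)
    if sum(counts.values()) != config.n_trna_genes:
        raise ValueError("class_counts must sum to n_trna_genes")
    specs: list[GeneSpec] = []
    for sp in config.special_genes:
        if counts.get("FIVE", 0) <= 0:
            raise ValueError("special genes require FIVE class slots")
        counts["FIVE"] -= 1
        specs.append(
            GeneSpec(sp.gene_id, sp.amino_acid, sp.anticodon, "FIVE", sp.weight,
                     sp.mitochondrial, False, dict(sp.stage_fold))
        )
    used = {s.gene_id for s in specs}
    cycle = 0
    idx = 0
    remaining = [(cls, counts[cls]) for cls in ("FIVE", "MID", "THREE", "COMBINATION", "RANDOM", "LOW_RPM", "NONE") if counts.get(cls, 0) > 0]
    flat = [cls for cls, n in remaining for _ in range(n)]
    for cls in flat:
        while True:
            aa, ac = AA_ANTICODONS[idx % len(AA_ANTICODONS)]
            cycle = idx // len(AA_ANTICODONS) + 1
            idx += 1
            gid = f"tRNA-{aa}-{ac}-{cycle}"
            if gid not in used:
                used.add(gid)
                break
        specs.append(GeneSpec(gid, aa, ac, cls, 0.0))

    # per-class weights (pre-normalization)
    five = [s for s in specs if s.trna_class == "FIVE" and not s.stage_fold]
    special_mass = sum(s.weight for s in specs if s.stage_fold)
    if five:
        draws = rng.lognormal(mean=0.0, sigma=config.lognormal_sigma, size=len(five))
        scale = max(config.five_mass - special_mass, 0.0) / draws.sum()
        for s, d in zip(five, draws):
            s.weight = float(d * scale)
    combos = [s for s in specs if s.trna_class == "COMBINATION"]
    if combos:
        draws = rng.lognormal(mean=0.0, sigma=config.lognormal_sigma, size=len(combos))
        scale = config.combination_mass / draws.sum()
        for s, d in zip(combos, draws):
            s.weight = float(d * scale)
    fixed = {"MID": config.mid_gene_weight, "THREE": config.three_gene_weight,
             "RANDOM": config.random_gene_weight, "LOW_RPM": config.low_rpm_gene_weight}
    for s in specs:
        if s.trna_class in fixed:
            s.weight = fixed[s.trna_class]

    # mark degenerate (unfoldable) structures among non-special FIVE genes
    degenerate_pool = [s for s in specs if s.trna_class == "FIVE" and not s.stage_fold]
    for s in degenerate_pool[-config.n_degenerate_structures:] if config.n_degenerate_structures else []:
        s.degenerate = True
        s.mitochondrial = True
        s.gene_id = f"mt:{s.gene_id}"
    return specs


def generate_references(config: SimulationConfig) -> References:
    """Random tRNA genes with valid canonical cloverleaf structures plus decoy
    background categories, mutually screened for shared 15-mers."""
    rng = np.random.default_rng(config.seed)
    specs = _build_gene_specs(config, rng)

    rows: list[dict[str, object]] = []
    gene_kmers: set[str] = set()
    for spec in specs:
        while True:
            var_loop = int(rng.integers(config.var_loop_range[0], config.var_loop_range[1] + 1))
            seq = _gene_sequence(rng, spec.anticodon, var_loop)
            if not (_kmers(seq) & gene_kmers):
                break
        gene_kmers |= _kmers(seq)
        rows.append(
            {
                "gene_id": spec.gene_id,
                "amino_acid": spec.amino_acid,
                "anticodon": spec.anticodon,
                "anticodon_start": ANTICODON_START,
                "is_mitochondrial": int(spec.mitochondrial),
                "sequence": seq,
                "structure": _gene_structure(var_loop, spec.degenerate),
            }
        )
    genes = build_trna_genes(rows, append_cca=True)
    gene_kmers |= set().union(*(_kmers(g.sequence) for g in genes))

    def clean_random(n: int) -> str:
        while True:
            seq = _random_nt(rng, n)
            if not (_kmers(seq) & gene_kmers):
                return seq

    background: dict[str, dict[str, str]] = {
        "rRNA": {
            "rRNA_18S_frag": clean_random(1500),
            "rRNA_28S_frag": clean_random(900),
            "rRNA_2S": clean_random(120),
        },
        "hairpin": {f"hairpin_mir_{i}": clean_random(90) for i in range(1, 11)},
        "transcript": {f"transcript_{i}": clean_random(600) for i in range(1, 5)},
        "intergenic": {f"intergenic_{i}": clean_random(500) for i in range(1, 5)},
    }
    if config.collision_decoys:
        planted_gene = genes[0]
        planted = planted_gene.sequence[0:26]
        background["rRNA"]["rRNA_decoy_tRF"] = clean_random(40) + planted + clean_random(40)
    return References(background, rows, genes, specs)


# ---------------------------------------------------------------------------
# ground-truth species table


def _spanning_start(length: int, frag_len: int) -> int:
    """Smallest start making [start, start+frag_len-1] SPANNING under the 2/3 rule."""
    partition = partition_regions(length)
    for start in range(1, length - frag_len + 2):
        if assign_region(start, start + frag_len - 1, partition) == RegionLabel.SPANNING:
            return start
    raise ValueError(f"no spanning placement for fragment of {frag_len} nt on {length} nt tRNA")


def _mid_start(length: int) -> int:
    return 27


def build_truth_species(config: SimulationConfig, refs: References) -> pd.DataFrame:
    """Expected (gene, start, end) fragment table with normalized base masses.

    ``kind`` separates 15-29 nt tRFs from 33-40 nt halves; each block's masses
    sum to 1.  ``region`` is the ground-truth region label of the fragment.
    """
    lw = config.length_weights
    if abs(sum(lw.values()) - 1.0) > 1e-9:
        raise ValueError("length weights must sum to 1")
    rows: list[dict[str, object]] = []

    def add(gene: TRNAGene, start: int, end: int, mass: float, kind: str) -> None:
        partition = partition_regions(gene)
        rows.append(
            {
                "gene_id": gene.gene_id,
                "start": start,
                "end": end,
                "length": end - start + 1,
                "kind": kind,
                "mass": mass,
                "region": assign_region(start, end, partition).value,
            }
        )

    genes_by_id = {g.gene_id: g for g in refs.genes}
    for spec in refs.gene_specs:
        gene = genes_by_id[spec.gene_id]
        L = gene.length
        w = spec.weight
        if spec.trna_class == "NONE" or w <= 0:
            continue
        if config.five_prime_window_mass is not None:
            target = config.five_prime_window_mass
            inside = {l: p for l, p in lw.items() if l <= config.window_end}
            z = sum(inside.values())
            for l, p in inside.items():
                add(gene, 1, l, w * target * p / z, "trf")
            for l, p in lw.items():
                add(gene, L - l + 1, L, w * (1.0 - target) * p, "trf")
            continue
        if spec.trna_class in ("FIVE", "LOW_RPM"):
            for l, p in lw.items():
                add(gene, 1, l, w * p, "trf")
        elif spec.trna_class == "MID":
            for l, p in lw.items():
                add(gene, _mid_start(L), _mid_start(L) + l - 1, w * p, "trf")
        elif spec.trna_class == "THREE":
            for l, p in lw.items():
                add(gene, L - l + 1, L, w * p, "trf")
        elif spec.trna_class == "COMBINATION":
            for l, p in lw.items():
                add(gene, 1, l, w * config.combo_five_share * p, "trf")
                add(gene, L - l + 1, L, w * (1.0 - config.combo_five_share) * p, "trf")
        elif spec.trna_class == "RANDOM":
            for l, p in lw.items():
                s = _spanning_start(L, l)
                add(gene, s, s + l - 1, w * config.random_spanning_share * p, "trf")
                add(gene, 1, l, w * (1.0 - config.random_spanning_share) * p, "trf")
        else:  # pragma: no cover - defensive
            raise ValueError(f"unknown class {spec.trna_class}")

    # tRNA halves from 5'-fragment-producing genes, proportional to tRF weight
    half_sources = [s for s in refs.gene_specs if s.trna_class == "FIVE" and s.weight > 0]
    for spec in half_sources:
        gene = genes_by_id[spec.gene_id]
        for end, p in config.half_end_weights.items():
            add(gene, 1, end, spec.weight * p, "half")

    df = pd.DataFrame(rows)
    for kind in ("trf", "half"):
        mask = df["kind"] == kind
        total = df.loc[mask, "mass"].sum()
        if total > 0:
            df.loc[mask, "mass"] = df.loc[mask, "mass"] / total
    return df


# ---------------------------------------------------------------------------
# stage calibration and library simulation


def _stage_multipliers(
    config: SimulationConfig, refs: References, species: pd.DataFrame
) -> dict[str, dict[str, float]]:
    """Per-gene per-stage mass multipliers.

    With ``calibrate_compositional`` the configured folds are treated as
    *expected rpm folds*: a fixed-point iteration absorbs the renormalization
    of the closed rpm scale so that the expected fold equals the configured
    value exactly.
    """
    stages = list(config.stages)
    mult: dict[str, dict[str, float]] = {
        s.gene_id: {stage: 1.0 for stage in stages} for s in refs.gene_specs
    }
    folds = {s.gene_id: s.stage_fold for s in refs.gene_specs if s.stage_fold}
    if not folds:
        return mult
    if len(stages) != 2:
        raise ValueError("stage folds require exactly two stages")
    for gid, stage_fold in folds.items():
        for stage, phi in stage_fold.items():
            mult[gid][stage] = float(phi)
    if not config.calibrate_compositional:
        return mult
    trf = species[species["kind"] == "trf"]
    base_mass = trf.groupby("gene_id")["mass"].sum()
    for _ in range(80):
        w = {
            stage: float(sum(base_mass.get(g, 0.0) * mult[g][stage] for g in mult))
            for stage in stages
        }
        for gid, stage_fold in folds.items():
            for stage, phi in stage_fold.items():
                other = stages[1] if stage == stages[0] else stages[0]
                mult[gid][stage] = phi * w[stage] / w[other]
    return mult


@dataclass
class TruthManifest:
    """Ground truth for a simulated scenario: per-gene classes and weights,
    per-species expected rpm per library, and per-library composition."""

    genes: pd.DataFrame
    species: pd.DataFrame  # includes expected_rpm:<library_id> columns
    libraries: pd.DataFrame
    expected: dict[str, object]
    config: SimulationConfig

    def gene_classes(self) -> dict[str, str]:
        return dict(zip(self.genes["gene_id"], self.genes["trna_class"]))


@dataclass
class Scenario:
    config: SimulationConfig
    references: References
    categories: list[ReferenceCategory]
    genes: list[TRNAGene]
    readsets: list[ReadSet]
    manifest: TruthManifest


def _library_block_shares(config: SimulationConfig, fraction: str) -> tuple[float, float, float, float]:
    try:
        t = config.trf_share[fraction]
        h = config.half_share[fraction]
    except KeyError:
        raise ValueError(f"no tRF/half share configured for fraction {fraction!r}")
    u = config.unmatched_share
    b = 1.0 - t - h - u
    if b < 0:
        raise ValueError(f"block shares for fraction {fraction!r} exceed 1")
    return t, h, b, u


def _species_probabilities(
    config: SimulationConfig,
    species: pd.DataFrame,
    mult: Mapping[str, Mapping[str, float]],
    spec: LibrarySpec,
) -> np.ndarray:
    t, h, _, _ = _library_block_shares(config, spec.fraction)
    m = np.array([mult[g][spec.stage] for g in species["gene_id"]])
    mass = species["mass"].to_numpy() * m
    p = np.zeros(len(species))
    for kind, share in (("trf", t), ("half", h)):
        mask = (species["kind"] == kind).to_numpy()
        block = mass * mask
        total = block.sum()
        if total > 0 and share > 0:
            p += share * block / total
    return p


def _mutate_reads(reads: dict[str, int], rate: float, rng: np.random.Generator) -> dict[str, int]:
    out: dict[str, int] = {}
    nts = "ACGT"
    for seq, count in reads.items():
        n_mut = int(rng.binomial(count, min(1.0, rate * len(seq))))
        if count - n_mut > 0:
            out[seq] = out.get(seq, 0) + count - n_mut
        for _ in range(n_mut):
            pos = int(rng.integers(0, len(seq)))
            base = nts[(nts.index(seq[pos]) + int(rng.integers(1, 4))) % 4]
            mutated = seq[:pos] + base + seq[pos + 1 :]
            out[mutated] = out.get(mutated, 0) + 1
    return out


def simulate_library(
    config: SimulationConfig,
    refs: References,
    species: pd.DataFrame,
    mult: Mapping[str, Mapping[str, float]],
    spec: LibrarySpec,
    rng: np.random.Generator,
) -> ReadSet:
    """Draw one library multinomially from the species table plus background."""
    t, h, b, u = _library_block_shares(config, spec.fraction)
    p_species = _species_probabilities(config, species, mult, spec)
    bg_names = list(config.background_split)
    bg_p = np.array([config.background_split[c] for c in bg_names])
    bg_p = b * bg_p / bg_p.sum()
    p = np.concatenate([p_species, bg_p, [u]])
    p = p / p.sum()
    counts = rng.multinomial(spec.depth, p) if spec.depth > 0 else np.zeros(len(p), dtype=int)

    genes_by_id = {g.gene_id: g for g in refs.genes}
    reads: dict[str, int] = {}
    for row, n in zip(species.itertuples(), counts[: len(species)]):
        if n == 0:
            continue
        seq = genes_by_id[row.gene_id].sequence[row.start - 1 : row.end]
        reads[seq] = reads.get(seq, 0) + int(n)

    lo, hi = config.background_read_lengths
    for cat, n in zip(bg_names, counts[len(species) : len(species) + len(bg_names)]):
        if n == 0:
            continue
        ids = list(refs.background.get(cat, {}))
        if not ids:
            raise ValueError(f"background category {cat!r} has no references")
        seqs = [refs.background[cat][i] for i in ids]
        wts = np.array([len(s) for s in seqs], dtype=float)
        wts /= wts.sum()
        ref_idx = rng.choice(len(ids), size=int(n), p=wts)
        lengths = rng.integers(lo, hi + 1, size=int(n))
        offsets = rng.random(int(n))
        for ri, length, off in zip(ref_idx, lengths, offsets):
            ref = seqs[int(ri)]
            length = int(min(length, len(ref)))
            start = int(off * (len(ref) - length + 1))
            frag = ref[start : start + length]
            reads[frag] = reads.get(frag, 0) + 1

    n_unmatched = int(counts[-1])
    if n_unmatched:
        all_refs = [s for cat in refs.background.values() for s in cat.values()]
        all_refs += [g.sequence for g in refs.genes]
        ulo, uhi = config.unmatched_read_lengths
        made = 0
        while made < n_unmatched:
            seq = _random_nt(rng, int(rng.integers(ulo, uhi + 1)))
            if any(seq in r for r in all_refs):
                continue
            reads[seq] = reads.get(seq, 0) + 1
            made += 1

    if config.error_rate > 0:
        reads = _mutate_reads(reads, config.error_rate, rng)
    return ReadSet(spec.library_id, spec.stage, spec.fraction, reads, spec.depth)


def simulate_scenario(config: SimulationConfig) -> Scenario:
    """Generate references, all libraries and the ground-truth manifest."""
    refs = generate_references(config)
    species = build_truth_species(config, refs)
    mult = _stage_multipliers(config, refs, species)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))

    lib_specs = config.library_specs()
    readsets = []
    manifest_species = species.copy()
    lib_rows = []
    for spec in lib_specs:
        p = _species_probabilities(config, species, mult, spec)
        manifest_species[f"expected_rpm:{spec.library_id}"] = (
            p / (1.0 - config.unmatched_share) * 1e6
        )
        t, h, b, u = _library_block_shares(config, spec.fraction)
        lib_rows.append(
            {
                "library_id": spec.library_id,
                "stage": spec.stage,
                "fraction": spec.fraction,
                "depth": spec.depth,
                "trf_share": t,
                "half_share": h,
                "background_share": b,
                "unmatched_share": u,
            }
        )
        readsets.append(simulate_library(config, refs, species, mult, spec, rng))

    genes_df = pd.DataFrame(
        [
            {
                "gene_id": s.gene_id,
                "amino_acid": s.amino_acid,
                "anticodon": s.anticodon,
                "trna_class": s.trna_class,
                "weight": s.weight,
                "mitochondrial": s.mitochondrial,
                "degenerate_structure": s.degenerate,
                **{f"multiplier:{stage}": mult[s.gene_id][stage] for stage in config.stages},
            }
            for s in refs.gene_specs
        ]
    )
    trf_mask = manifest_species["kind"] == "trf"
    rpm_cols = [c for c in manifest_species.columns if c.startswith("expected_rpm:")]
    pooled = manifest_species.loc[trf_mask, rpm_cols].sum(axis=1)
    in_window = (
        (manifest_species.loc[trf_mask, "start"] >= 1)
        & (manifest_species.loc[trf_mask, "end"] <= config.window_end)
    )
    expected = {
        "configured_stage_folds": {
            s.gene_id: s.stage_fold for s in refs.gene_specs if s.stage_fold
        },
        "fraction_shares": {
            f: config.trf_share[f] / sum(config.trf_share[x] for x in config.fractions)
            for f in config.fractions
            if f in config.trf_share
        },
        "length_weights": {int(k): v for k, v in config.length_weights.items()},
        "five_prime_window_mass": float(pooled[in_window].sum() / pooled.sum())
        if pooled.sum() > 0
        else float("nan"),
        "expected_gene_rpm_pooled": {
            gid: float(v)
            for gid, v in manifest_species.loc[trf_mask]
            .groupby("gene_id")[rpm_cols]
            .sum()
            .mean(axis=1)
            .items()
        },
    }
    manifest = TruthManifest(
        genes=genes_df,
        species=manifest_species,
        libraries=pd.DataFrame(lib_rows),
        expected=expected,
        config=config,
    )
    return Scenario(config, refs, refs.reference_categories(), refs.genes, readsets, manifest)


# ---------------------------------------------------------------------------
# file emission


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    opener = gzip.open if str(path).endswith(".gz") else open
    with opener(path, "wt") as fh:
        for sid, seq in sequences.items():
            fh.write(f">{sid}\n{seq}\n")


def write_library(readset: ReadSet, path: str | Path, fmt: str = "fasta") -> None:
    """Emit a library as collapsed FASTA (``id_count`` headers) or expanded FASTQ."""
    opener = gzip.open if str(path).endswith(".gz") else open
    items = sorted(readset.reads.items())
    with opener(path, "wt") as fh:
        if fmt == "fasta":
            for i, (seq, count) in enumerate(items, start=1):
                fh.write(f">seq{i}_{count}\n{seq}\n")
        elif fmt == "fastq":
            n = 0
            for seq, count in items:
                for _ in range(count):
                    n += 1
                    fh.write(f"@read{n}\n{seq}\n+\n{'I' * len(seq)}\n")
        else:
            raise ValueError(f"unknown library format {fmt!r}")


def write_scenario(scenario: Scenario, outdir: str | Path, fmt: str = "fasta") -> Path:
    """Write references, structure table, libraries, metadata and manifest files."""
    outdir = Path(outdir)
    (outdir / "references").mkdir(parents=True, exist_ok=True)
    (outdir / "libraries").mkdir(exist_ok=True)
    (outdir / "manifest").mkdir(exist_ok=True)
    ref_paths = {}
    for cat, seqs in scenario.references.background.items():
        p = outdir / "references" / f"{cat}.fasta"
        write_fasta(seqs, p)
        ref_paths[cat] = str(p)
    write_structure_table(scenario.references.trna_rows, outdir / "references" / "trna_structure.tsv")

    ext = "fasta" if fmt == "fasta" else "fastq"
    meta_rows = []
    for rs in scenario.readsets:
        p = outdir / "libraries" / f"{rs.library_id}.{ext}"
        write_library(rs, p, fmt)
        meta_rows.append(
            {
                "library_id": rs.library_id,
                "stage": rs.stage,
                "fraction": rs.fraction,
                "path": str(p),
                "format": "collapsed_fasta" if fmt == "fasta" else "fastq",
            }
        )
    pd.DataFrame(meta_rows).to_csv(outdir / "metadata.tsv", sep="\t", index=False)

    m = scenario.manifest
    m.genes.to_csv(outdir / "manifest" / "genes.tsv", sep="\t", index=False)
    m.species.to_csv(outdir / "manifest" / "species.tsv", sep="\t", index=False)
    m.libraries.to_csv(outdir / "manifest" / "libraries.tsv", sep="\t", index=False)
    with open(outdir / "manifest" / "expected.json", "w") as fh:
        json.dump(m.expected, fh, indent=2)
    with open(outdir / "config.yaml", "w") as fh:
        cfg = asdict(scenario.config)
        cfg["special_genes"] = [asdict(s) for s in scenario.config.special_genes]
        cfg["libraries"] = (
            [asdict(l) for l in scenario.config.libraries]
            if scenario.config.libraries is not None
            else None
        )
        yaml.safe_dump(cfg, fh, sort_keys=False)
    return outdir
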