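import numpy as np
import pandas as pd
import pytest

from trfkit.pipeline import analyze
from trfkit.reference_model import build_trna_genes
from trfkit.synthetic import (
    _gene_sequence,
    _gene_structure,
    default_scenario,
    simulate_scenario,
    window_scenario,
)


@pytest.fixture(scope="session")
def default_run():
    """The headline scenario (111 genes, 8 libraries of 50k reads) analyzed once."""
    scenario = simulate_scenario(default_scenario(seed=11))
    result = analyze(scenario.categories, scenario.genes, scenario.readsets)
    return scenario, result


@pytest.fixture(scope="session")
def window_run():
    """Single-library scenario with exactly 95% of expected tRF mass in [1, 28]."""
    scenario = simulate_scenario(window_scenario(seed=12))
    result = analyze(scenario.categories, scenario.genes, scenario.readsets)
    return scenario, result


@pytest.fixture
def toy_gene():
    """One canonical cloverleaf tRNA (73 nt with CCA) built from the generator geometry."""
    rng = np.random.default_rng(7)
    row = {
        "gene_id": "tRNA-Gly-GCC-toy",
        "amino_acid": "Gly",
        "anticodon": "GCC",
        "anticodon_start": 32,
        "sequence": _gene_sequence(rng, "GCC", 4),
        "structure": _gene_structure(4, degenerate=False),
    }
    return build_trna_genes([row])[0]


def make_species(rows, columns=("gene_id", "start", "end", "length", "count", "rpm", "region")):
    """Helper: build a species table from (gene, start, end, rpm[, region]) tuples."""
    out = []
    for row in rows:
        gene_id, start, end, rpm = row[:4]
        region = row[4] if len(row) > 4 else None
        rec = {
            "gene_id": gene_id,
            "start": start,
            "end": end,
            "length": end - start + 1,
            "count": rpm,
            "rpm": float(rpm),
        }
        if region is not None:
            rec["region"] = region
        out.append(rec)
    return pd.DataFrame(out)


@pytest.fixture
def species_factory():
    return make_species
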