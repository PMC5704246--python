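"""Species tables, profiles, region rule and per-tRNA classification."""
import numpy as np
import pandas as pd
import pytest

from trfkit.read_assignment import CategoryAssignment, ReadSet
from trfkit.reference_model import partition_regions
from trfkit.trf_quantify import (
    RegionLabel,
    TRNAClass,
    add_regions,
    assign_region,
    build_profiles,
    build_species_table,
    classify_trna,
    five_prime_fraction,
    length_distribution,
    pool_species_tables,
    superpose_on_representative,
    tabulate_classes,
)


def oracle_region(start, end, length):
    """Independent per-nucleotide membership count of the 2/3 rule."""
    five = set(range(1, 27))
    three = set(range(length - 25, length + 1))
    mid = set(range(27, length - 25))
    frag = set(range(start, end + 1))
    winners = [
        name
        for name, region in (("FIVE", five), ("MID", mid), ("THREE", three))
        if 3 * len(frag & region) >= 2 * len(frag)
    ]
    assert len(winners) <= 1
    return winners[0] if winners else "SPANNING"


class TestAssignRegion:
    P75 = partition_regions(75)

    @pytest.mark.parametrize(
        "start,end,expected",
        [
            (1, 28, RegionLabel.FIVE),  # 26/28 overlap with the 5' region
            (20, 46, RegionLabel.MID),  # 20/27 in the middle
            (18, 44, RegionLabel.MID),  # exactly 2/3 in the middle: inclusive
            (10, 39, RegionLabel.SPANNING),  # no region reaches 2/3
            (50, 75, RegionLabel.THREE),
        ],
    )
    def test_examples(self, start, end, expected):
        assert assign_region(start, end, self.P75) == expected
        assert oracle_region(start, end, 75) == expected.value

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            assign_region(0, 10, self.P75)
        with pytest.raises(ValueError):
            assign_region(70, 80, self.P75)

    def test_matches_oracle_on_random_triples(self):
        rng = np.random.default_rng(0)
        for _ in range(2000):
            length = int(rng.integers(53, 121))
            start = int(rng.integers(1, length + 1))
            end = int(rng.integers(start, length + 1))
            got = assign_region(start, end, partition_regions(length))
            assert got.value == oracle_region(start, end, length)


class TestSpeciesTable:
    def _inputs(self):
        rs = ReadSet("lib", "0-1h", "Total", {"A" * 20: 10, "C" * 20: 4}, 14)
        assignments = [
            CategoryAssignment("A" * 20, "tRNA", (("g1", 1, 20),), 0),
            CategoryAssignment("C" * 20, "tRNA", (("g1", 5, 24), ("g2", 5, 24)), 0),
        ]
        return rs, assignments

    def test_counts_and_rpm(self):
        rs, assignments = self._inputs()
        table = build_species_table(assignments, rs, denominator=14)
        by_key = {(r.gene_id, r.start, r.end): r for r in table.itertuples()}
        assert by_key[("g1", 1, 20)].count == 10
        assert by_key[("g1", 1, 20)].rpm == pytest.approx(10 * 1e6 / 14)
        # multi-gene hit: full count to each gene under the default policy
        assert by_key[("g1", 5, 24)].count == 4
        assert by_key[("g2", 5, 24)].count == 4

    def test_fractional_multi_gene(self):
        rs, assignments = self._inputs()
        table = build_species_table(assignments, rs, denominator=14, multi_gene="fractional")
        by_key = {(r.gene_id, r.start, r.end): r for r in table.itertuples()}
        assert by_key[("g1", 5, 24)].count == pytest.approx(2.0)
        assert by_key[("g2", 5, 24)].count == pytest.approx(2.0)

    def test_length_window(self):
        rs, assignments = self._inputs()
        table = build_species_table(assignments, rs, denominator=14, min_len=21, max_len=40)
        assert table.empty

    def test_pooling(self):
        rs, assignments = self._inputs()
        t1 = build_species_table(assignments, rs, denominator=100)
        t2 = build_species_table(assignments, rs, denominator=300)
        pooled, denom = pool_species_tables([t1, t2], [100, 300])
        assert denom == 400
        row = pooled[(pooled.gene_id == "g1") & (pooled.start == 1)].iloc[0]
        assert row["count"] == 20
        assert row["rpm"] == pytest.approx(20 * 1e6 / 400)


class TestProfiles:
    def test_single_species_profile(self, species_factory):
        sp = species_factory([("g1", 1, 26, 100.0)])
        profiles = build_profiles(sp, {"g1": 75})
        prof = profiles["g1"]
        assert np.all(prof.rpm[:26] == 100.0)
        assert np.all(prof.rpm[26:] == 0.0)
        assert prof.density.sum() == pytest.approx(100.0)
        assert np.all(prof.rpm >= prof.density)

    def test_density_sums_to_species_rpm(self, species_factory):
        sp = species_factory([("g1", 1, 26, 100.0), ("g1", 5, 24, 40.0), ("g1", 50, 75, 7.0)])
        prof = build_profiles(sp, {"g1": 75})["g1"]
        assert prof.density.sum() == pytest.approx(147.0)

    def test_superposition_additivity_and_padding(self, species_factory):
        profiles = build_profiles(
            species_factory([("g1", 1, 26, 100.0), ("g2", 40, 66, 25.0)]),
            {"g1": 70, "g2": 80},
        )
        total = superpose_on_representative(profiles)
        assert total.size == 80
        assert total[0] == 100.0
        assert total[45] == 25.0
        assert total.sum() == pytest.approx(100.0 * 26 + 25.0 * 27)

    def test_superposition_requires_profiles(self):
        with pytest.raises(ValueError):
            superpose_on_representative({})


class TestFivePrimeFraction:
    def test_saturation(self, species_factory):
        sp = species_factory([("g1", 1, 26, 10.0), ("g1", 1, 28, 30.0)])
        assert five_prime_fraction(sp, 28) == 1.0

    def test_weighted_ratio(self, species_factory):
        sp = species_factory([("g1", 1, 26, 75.0), ("g1", 40, 66, 25.0)])
        assert five_prime_fraction(sp, 28) == pytest.approx(0.75)

    def test_zero_mass_rejected(self, species_factory):
        with pytest.raises(ValueError, match="zero total"):
            five_prime_fraction(species_factory([("g1", 1, 26, 0.0)]), 28)

    def test_overlap_mode_credits_partial(self, species_factory):
        sp = species_factory([("g1", 15, 42, 100.0)])  # 28-mer, 14 nt inside the window
        assert five_prime_fraction(sp, 28, containment="full") == 0.0
        assert five_prime_fraction(sp, 28, containment="overlap") == pytest.approx(0.5)


class TestLengthDistribution:
    def test_degenerate(self, species_factory):
        assert length_distribution(species_factory([("g1", 1, 26, 5.0)])) == {26: 1.0}

    def test_symmetry(self, species_factory):
        shares = length_distribution(
            species_factory([("g1", 1, 26, 5.0), ("g1", 1, 28, 5.0)])
        )
        assert shares == {26: 0.5, 28: 0.5}


class TestClassify:
    def _sp(self, species_factory, rows):
        return add_regions(species_factory(rows), {"g1": partition_regions(75)})

    def test_none_without_species(self, species_factory):
        assert classify_trna(species_factory([]).reindex(columns=["rpm", "region"])) == TRNAClass.NONE

    def test_low_rpm(self, species_factory):
        sp = self._sp(species_factory, [("g1", 1, 26, 30.0)])
        assert classify_trna(sp, rpm_threshold=50) == TRNAClass.LOW_RPM

    def test_single_region_and_combination(self, species_factory):
        five_dominant = self._sp(species_factory, [("g1", 1, 26, 90.0), ("g1", 27, 46, 10.0)])
        assert classify_trna(five_dominant) == TRNAClass.FIVE
        combo = self._sp(species_factory, [("g1", 1, 26, 60.0), ("g1", 50, 75, 40.0)])
        assert classify_trna(combo) == TRNAClass.COMBINATION

    def test_random_from_spanning_mass(self, species_factory):
        sp = self._sp(species_factory, [("g1", 10, 39, 70.0), ("g1", 1, 26, 30.0)])
        assert classify_trna(sp) == TRNAClass.RANDOM

    def test_order_and_scale_invariance(self, species_factory):
        rows = [("g1", 1, 26, 60.0), ("g1", 50, 75, 40.0), ("g1", 27, 46, 5.0)]
        sp = self._sp(species_factory, rows)
        shuffled = self._sp(species_factory, rows[::-1])
        assert classify_trna(sp) == classify_trna(shuffled)
        scaled = sp.copy()
        scaled["rpm"] *= 10
        assert classify_trna(scaled, rpm_threshold=500) == classify_trna(sp, rpm_threshold=50)


class TestTabulate:
    def test_counts_sum_and_none_genes(self, species_factory):
        sp = add_regions(
            species_factory([("g1", 1, 26, 100.0), ("g2", 1, 26, 100.0), ("g3", 1, 26, 100.0)]),
            {g: partition_regions(75) for g in ("g1", "g2", "g3")},
        )
        table = tabulate_classes(["g1", "g2", "g3", "g4"], sp)
        by_class = dict(zip(table["trna_class"], table["n_genes"]))
        assert by_class["FIVE"] == 3
        assert by_class["NONE"] == 1
        assert table["n_genes"].sum() == 4
        assert table.attrs["per_gene"]["g4"] == "NONE"
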