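"""Reference loading, CCA handling, region partition and cloverleaf coordinates."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from trfkit.reference_model import (
    CATEGORY_PRIORITY,
    CloverleafError,
    assign_cloverleaf_coordinates,
    build_trna_genes,
    cloverleaf_maps,
    format_coordinate,
    load_references,
    partition_regions,
    read_structure_table,
    references_from_dict,
    write_structure_table,
)
from trfkit.synthetic import _gene_sequence, _gene_structure


def _write_fasta(path, records):
    path.write_text("".join(f">{sid}\n{seq}\n" for sid, seq in records))


class TestLoadReferences:
    def test_counts_order_and_u_normalization(self, tmp_path):
        rrna = tmp_path / "rrna.fa"
        trna = tmp_path / "trna.fa"
        _write_fasta(rrna, [("r1", "ACGUACGU"), ("r2", "GGGUUU")])
        _write_fasta(trna, [("t1", "acgtacgt")])
        cats = load_references({"tRNA": trna, "rRNA": rrna})
        assert [c.name for c in cats] == ["rRNA", "tRNA"]  # priority order, not input order
        assert len(cats[0].sequences) == 2
        assert cats[0].sequences["r1"] == "ACGTACGT"
        assert cats[1].sequences["t1"] == "ACGTACGT"

    def test_unknown_category_rejected(self, tmp_path):
        f = tmp_path / "x.fa"
        _write_fasta(f, [("a", "ACGT")])
        with pytest.raises(ValueError, match="unknown reference categor"):
            load_references({"mystery": f})

    def test_duplicate_id_rejected(self, tmp_path):
        f = tmp_path / "dup.fa"
        _write_fasta(f, [("a", "ACGT"), ("a", "TTTT")])
        with pytest.raises(ValueError, match="duplicate"):
            load_references({"rRNA": f})

    def test_empty_fasta_rejected(self, tmp_path):
        f = tmp_path / "empty.fa"
        f.write_text("")
        with pytest.raises(ValueError, match="no FASTA records"):
            load_references({"rRNA": f})

    def test_priority_is_total_and_unique(self):
        assert len(set(CATEGORY_PRIORITY)) == len(CATEGORY_PRIORITY) == 10


class TestBuildTRNAGenes:
    def _row(self, **overrides):
        rng = np.random.default_rng(1)
        row = {
            "gene_id": "g1",
            "amino_acid": "Gly",
            "anticodon": "GCC",
            "anticodon_start": 32,
            "sequence": _gene_sequence(rng, "GCC", 4),
            "structure": _gene_structure(4, degenerate=False),
        }
        row.update(overrides)
        return row

    def test_cca_appended_and_structure_padded(self):
        row = self._row()
        (gene,) = build_trna_genes([row])
        assert gene.sequence.endswith("CCA")
        assert gene.length == len(row["sequence"]) + 3
        assert len(gene.structure) == gene.length
        assert gene.structure.endswith("...")

    def test_idempotent_on_cca_terminated_input(self):
        (gene,) = build_trna_genes([self._row()])
        again = {
            "gene_id": gene.gene_id,
            "amino_acid": gene.amino_acid,
            "anticodon": gene.anticodon,
            "anticodon_start": 32,
            "sequence": gene.sequence,
            "structure": gene.structure,
        }
        (gene2,) = build_trna_genes([again])
        assert gene2.sequence == gene.sequence
        assert gene2.structure == gene.structure

    def test_structure_length_mismatch_rejected(self):
        row = self._row(structure=self._row()["structure"][:-5])
        with pytest.raises(ValueError, match="structure length"):
            build_trna_genes([row])

    def test_anticodon_position_validated(self):
        row = self._row(anticodon="AAA" if "AAA" != self._row()["sequence"][31:34] else "CCC")
        with pytest.raises(ValueError, match="anticodon"):
            build_trna_genes([row])

    def test_structure_table_roundtrip(self, tmp_path):
        row = self._row()
        path = tmp_path / "structure.tsv"
        write_structure_table([row], path)
        parsed = read_structure_table(path)
        genes = build_trna_genes(parsed)
        assert genes[0].gene_id == "g1"
        # permissive whitespace fallback (no header line)
        headerless = tmp_path / "plain.tsv"
        fields = [row["gene_id"], row["amino_acid"], row["anticodon"],
                  str(row["anticodon_start"]), "0", row["sequence"], row["structure"]]
        headerless.write_text(" ".join(fields) + "\n")
        genes2 = build_trna_genes(read_structure_table(headerless))
        assert genes2[0].sequence == genes[0].sequence
        assert genes2[0].is_mitochondrial is False


class TestRegionPartition:
    def test_standard_length(self):
        p = partition_regions(75)
        assert (p.five, p.middle, p.three) == ((1, 26), (27, 49), (50, 75))

    def test_boundary_52(self):
        p = partition_regions(52)
        assert p.five == (1, 26)
        assert p.middle is None
        assert p.three == (27, 52)

    def test_short_gene_rejected(self):
        with pytest.raises(ValueError, match="region partition requires"):
            partition_regions(40)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(length=st.integers(min_value=52, max_value=300))
    def test_partition_tiles_exactly_once(self, length):
        p = partition_regions(length)
        covered = []
        for span in (p.five, p.middle, p.three):
            if span is not None:
                covered.extend(range(span[0], span[1] + 1))
        assert sorted(covered) == list(range(1, length + 1))
        assert len(covered) == len(set(covered))


class TestCloverleaf:
    def test_known_addresses(self, toy_gene):
        cmap = assign_cloverleaf_coordinates(toy_gene)
        assert cmap.coordinate(1) == (1, 1)
        # position 26 is the 2nd nt of the anticodon-stem 5' strand
        coord = cmap.coordinate(26)
        assert (coord.segment, coord.offset) == (7, 2)
        assert format_coordinate(coord) == "2;7"
        last = cmap.coordinate(toy_gene.length)
        assert last.segment == 15
        span = cmap.segments[14]
        assert last.offset == span[1] - span[0] + 1 == 4  # discriminator + CCA

    def test_bijection_and_segment_order(self, toy_gene):
        cmap = assign_cloverleaf_coordinates(toy_gene)
        positions = cmap.positions()
        assert sorted(positions) == list(range(1, toy_gene.length + 1))
        assert len(set(positions.values())) == toy_gene.length
        # concatenating segments in order reproduces the position sequence
        concat = [
            p
            for span in cmap.segments
            if span is not None
            for p in range(span[0], span[1] + 1)
        ]
        assert concat == list(range(1, toy_gene.length + 1))

    def test_missing_arm_rejected_and_skipped(self):
        rng = np.random.default_rng(3)
        rows = [
            {
                "gene_id": "mt:tRNA-X-1",
                "amino_acid": "Ser",
                "anticodon": "GCT",
                "anticodon_start": 32,
                "sequence": _gene_sequence(rng, "GCT", 4),
                "structure": _gene_structure(4, degenerate=True),
            },
            {
                "gene_id": "tRNA-Y-1",
                "amino_acid": "Gly",
                "anticodon": "GCC",
                "anticodon_start": 32,
                "sequence": _gene_sequence(rng, "GCC", 5),
                "structure": _gene_structure(5, degenerate=False),
            },
        ]
        genes = build_trna_genes(rows)
        with pytest.raises(CloverleafError, match="mt:tRNA-X-1"):
            assign_cloverleaf_coordinates(genes[0])
        maps, skipped = cloverleaf_maps(genes)
        assert skipped == ["mt:tRNA-X-1"]
        assert set(maps) == {"tRNA-Y-1"}

    def test_references_from_dict_validates_alphabet(self):
        with pytest.raises(ValueError, match="invalid characters"):
            references_from_dict({"rRNA": {"r1": "ACGTX"}})
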