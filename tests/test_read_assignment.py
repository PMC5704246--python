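"""Read collapsing, adapter trimming and priority/tier assignment semantics."""
import numpy as np
import pytest

from trfkit.read_assignment import (
    ReadSet,
    UNASSIGNED,
    assign_reads,
    assign_sequences,
    category_totals,
    from_collapsed_fasta,
    from_fastq,
    length_filter,
    mapped_total,
    trim_adapter,
)
from trfkit.reference_model import references_from_dict


def make_readset(reads, library_id="lib", stage="0-1h", fraction="Total"):
    return ReadSet(library_id, stage, fraction, dict(reads), sum(reads.values()))


class TestIO:
    def test_trim_adapter(self):
        adapter = "TGGAATTCTCGG"
        assert trim_adapter("ACGTACGT" + adapter, adapter) == "ACGTACGT"
        assert trim_adapter("ACGTACGT" + adapter[:7], adapter) == "ACGTACGT"  # partial 3' prefix
        assert trim_adapter("ACGTACGT" + adapter[:4], adapter) == "ACGTACGT" + adapter[:4]

    def test_from_fastq_collapses_and_drops_n(self, tmp_path):
        fq = tmp_path / "lib.fastq"
        adapter = "TGGAATTCTCGG"
        reads = ["ACGTACGTACGTACG", "ACGTACGTACGTACG", "ACGNACGTACGTACG", "TTTTTTTTTTTTTTT"]
        fq.write_text("".join(f"@r{i}\n{s}{adapter}\n+\n{'I'*(len(s)+len(adapter))}\n" for i, s in enumerate(reads)))
        rs = from_fastq(fq, "lib", adapter=adapter)
        assert rs.total_input_reads == 4
        assert rs.reads == {"ACGTACGTACGTACG": 2, "TTTTTTTTTTTTTTT": 1}

    def test_from_collapsed_fasta(self, tmp_path):
        fa = tmp_path / "lib.fasta"
        fa.write_text(">seq1_10\nACGTACGTACGTACG\n>seq2_3\nTTTTTTTTTTTTTTT\n")
        rs = from_collapsed_fasta(fa, "lib")
        assert rs.reads["ACGTACGTACGTACG"] == 10
        assert rs.total_input_reads == 13

    def test_collapsed_fasta_bad_header(self, tmp_path):
        fa = tmp_path / "bad.fasta"
        fa.write_text(">readone\nACGT\n")
        with pytest.raises(ValueError, match="_count suffix"):
            from_collapsed_fasta(fa, "lib")


class TestLengthFilter:
    def test_bounds_inclusive(self):
        rs = make_readset({"A" * 14: 1, "C" * 15: 2, "G" * 29: 3, "T" * 30: 4})
        kept = length_filter(rs, 15, 29)
        assert {len(s) for s in kept.reads} == {15, 29}
        assert kept.reads["C" * 15] == 2  # counts preserved

    def test_empty_identity(self):
        assert length_filter(make_readset({})).reads == {}

    def test_half_mode(self):
        rs = make_readset({"A" * 28: 1, "C" * 35: 1, "G" * 40: 1, "T" * 41: 1})
        kept = length_filter(rs, 35, 40)
        assert {len(s) for s in kept.reads} == {35, 40}

    def test_invalid_bounds(self):
        with pytest.raises(ValueError):
            length_filter(make_readset({}), 29, 15)


def _categories(with_decoy, trf):
    pad = "GGCCTTAAGGCCTTAAGGCC"
    rrna = {"r1": pad + "ATATATATATATATATAT" + pad}
    if with_decoy:
        rrna["r_decoy"] = pad + trf + pad
    trna = {"t1": trf + "CTCTCTCTCTCTCTCTCTCTCTCTCTCTCTCTCTCTCTCTCTCTCCA"}
    return references_from_dict({"rRNA": rrna, "tRNA": trna})


class TestPriorityAndTiers:
    TRF = "ACGTTGCAACGGTACCGGTTACCAAG"

    def test_priority_dominance(self):
        rs = make_readset({self.TRF: 5, "ATATATATATATATATAT": 2})
        with_decoy = assign_reads(rs, _categories(True, self.TRF))
        by_seq = {a.sequence: a for a in with_decoy}
        assert by_seq[self.TRF].category == "rRNA"
        assert by_seq[self.TRF].edit_tier == 0
        without = {a.sequence: a for a in assign_reads(rs, _categories(False, self.TRF))}
        assert without[self.TRF].category == "tRNA"
        assert without[self.TRF].gene_hits == (("t1", 1, len(self.TRF)),)
        # the other read is unaffected by the decoy
        assert by_seq["ATATATATATATATATAT"].category == without["ATATATATATATATATAT"].category

    def test_unassigned_after_exhaustion(self):
        rs = make_readset({"CCCCCCCCCCCCCCCCCCCCCC": 1})
        (a,) = assign_reads(rs, _categories(False, self.TRF), max_tier=3)
        assert a.category == UNASSIGNED
        assert a.edit_tier is None

    def test_tier1_substitution(self):
        mutated = "A" + ("G" if self.TRF[1] != "G" else "C") + self.TRF[2:]
        cats = _categories(False, self.TRF)
        (a0,) = assign_sequences([mutated], cats, max_tier=0).values()
        assert a0.category == UNASSIGNED
        (a1,) = assign_sequences([mutated], cats, max_tier=1).values()
        assert a1.category == "tRNA"
        assert a1.edit_tier == 1

    def test_category_order_enforced(self):
        cats = _categories(True, self.TRF)
        with pytest.raises(ValueError, match="priority order"):
            assign_sequences(["ACGT"], list(reversed(cats)))

    def test_mapped_total_and_partition(self):
        rs = make_readset({self.TRF: 5, "ATATATATATATATATAT": 2, "CCCCCCCCCCCCCCCC": 3})
        assignments = assign_reads(rs, _categories(False, self.TRF))
        totals = category_totals(assignments, rs)
        assert sum(totals.values()) == rs.total_reads == 10
        assert mapped_total(assignments, rs) == 7
        assert totals[UNASSIGNED] == 3


# --- brute-force oracle for the edit tiers ---------------------------------


def _infix_edit_distance(query, ref):
    prev = [0] * (len(ref) + 1)
    for i, qc in enumerate(query, 1):
        cur = [i] + [0] * len(ref)
        for j, rc in enumerate(ref, 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (qc != rc))
        prev = cur
    return min(prev)


def _min_hamming(query, ref):
    best = len(query) + 1
    for s in range(len(ref) - len(query) + 1):
        best = min(best, sum(a != b for a, b in zip(query, ref[s : s + len(query)])))
    return best


def _oracle(seq, categories, max_tier):
    for tier in range(max_tier + 1):
        for cat in categories:
            for ref in cat.sequences.values():
                if tier == 0:
                    hit = seq in ref
                elif tier == 1:
                    hit = _infix_edit_distance(seq, ref) <= 1
                else:
                    hit = _min_hamming(seq, ref) <= tier
                if hit:
                    return cat.name, tier
    return UNASSIGNED, None


class TestTierOracle:
    @pytest.mark.parametrize("max_tier", [0, 1, 2, 3])
    def test_matches_brute_force(self, max_tier):
        rng = np.random.default_rng(42)
        nts = "ACGT"

        def rand(n):
            return "".join(rng.choice(list(nts), size=n))

        cats = references_from_dict(
            {"rRNA": {"r1": rand(80)}, "tRNA": {"t1": rand(70), "t2": rand(70)}}
        )
        refs = [s for c in cats for s in c.sequences.values()]
        queries = []
        for _ in range(12):
            ref = refs[rng.integers(len(refs))]
            start = int(rng.integers(0, len(ref) - 20))
            frag = ref[start : start + 20]
            queries.append(frag)  # exact
            pos = int(rng.integers(0, 20))
            sub = frag[:pos] + nts[(nts.index(frag[pos]) + 1) % 4] + frag[pos + 1 :]
            queries.append(sub)  # one substitution
            queries.append(frag[:pos] + frag[pos + 1 :])  # one deletion
            queries.append(frag[:pos] + "A" + frag[pos:])  # one insertion
            queries.append(rand(20))  # random
        result = assign_sequences(queries, cats, max_tier=max_tier)
        for q in queries:
            want_cat, want_tier = _oracle(q, cats, max_tier)
            assert (result[q].category, result[q].edit_tier) == (want_cat, want_tier), q

    def test_tier_monotonicity(self):
        rng = np.random.default_rng(7)
        nts = "ACGT"
        cats = references_from_dict(
            {"tRNA": {"t1": "".join(rng.choice(list(nts), size=70))}}
        )
        queries = ["".join(rng.choice(list(nts), size=18)) for _ in range(40)]
        ref = next(iter(cats[0].sequences.values()))
        queries += [ref[i : i + 18] for i in range(0, 40, 7)]
        n_assigned = []
        for tier in range(4):
            res = assign_sequences(queries, cats, max_tier=tier)
            n_assigned.append(sum(a.category != UNASSIGNED for a in res.values()))
        assert n_assigned == sorted(n_assigned)
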