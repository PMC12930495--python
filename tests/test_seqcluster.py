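"""Clustering, grouping, enzyme-site rewriting and synthesis benchmarking."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from synchar import seqcluster as sc
from synchar import synthdata as sd

from conftest import dp_levenshtein

DNA = st.text(alphabet="ACGT", max_size=40)


# ---------------------------------------------------------------------------
# input parsing
# ---------------------------------------------------------------------------


class TestReadParts:
    def test_csv_roundtrip(self, tmp_path):
        p = tmp_path / "parts.csv"
        p.write_text("Name,Sequence\nP1,ACGT\nP2,tttt\n")
        parts = sc.read_parts(p)
        assert [x.name for x in parts] == ["P1", "P2"]
        assert parts[1].sequence == "TTTT"  # case-normalized

    def test_missing_column_named_in_error(self, tmp_path):
        p = tmp_path / "bad.csv"
        p.write_text("Name,Seq\nP1,ACGT\n")
        with pytest.raises(sc.PartFormatError, match="Sequence"):
            sc.read_parts(p)

    def test_fasta_order_preserved(self, tmp_path):
        p = tmp_path / "parts.fasta"
        p.write_text(">a\nACGT\n>b\nGGGG\n>c\nTTTT\n")
        assert [x.name for x in sc.read_parts(p)] == ["a", "b", "c"]

    def test_duplicate_names_rejected(self, tmp_path):
        p = tmp_path / "dup.csv"
        p.write_text("Name,Sequence\nP1,ACGT\nP1,GGGG\n")
        with pytest.raises(sc.PartFormatError, match="duplicate"):
            sc.read_parts(p)

    def test_bad_alphabet_reports_position(self):
        with pytest.raises(sc.PartFormatError, match="position 2"):
            sc.PartSequence("P1", "ACXT")


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


class TestLevenshtein:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ("ACGT", "ACGT", 0),
            ("", "ACGT", 4),
            ("ACGT", "", 4),
            ("", "", 0),
            ("GATTACA", "GACTATA", 2),  # frozen from the DP oracle
        ],
    )
    def test_known_values(self, a, b, expected):
        assert sc.levenshtein(a, b) == expected

    def test_matches_dp_oracle_on_random_pairs(self, rng):
        for _ in range(500):
            a = "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(0, 41)))
            b = "".join("ACGT"[i] for i in rng.integers(0, 4, rng.integers(0, 41)))
            assert sc.levenshtein(a, b) == dp_levenshtein(a, b)

    @given(DNA, DNA)
    @settings(max_examples=100, deadline=None)
    def test_symmetry_and_identity(self, a, b):
        assert sc.levenshtein(a, b) == sc.levenshtein(b, a)
        assert sc.levenshtein(a, a) == 0

    @given(DNA, DNA, DNA)
    @settings(max_examples=100, deadline=None)
    def test_triangle_inequality(self, a, b, c):
        assert sc.levenshtein(a, c) <= sc.levenshtein(a, b) + sc.levenshtein(b, c)


class TestPairwiseDistances:
    def test_single_part_zero_matrix(self):
        dm = sc.pairwise_distances([sc.PartSequence("p", "ACGT")])
        assert dm.matrix.shape == (1, 1) and dm.matrix[0, 0] == 0

    def test_identical_sequences_zero_offdiagonal(self):
        parts = [sc.PartSequence("a", "ACGTACGT"), sc.PartSequence("b", "ACGTACGT")]
        assert sc.pairwise_distances(parts).matrix[0, 1] == 0

    def test_matches_bruteforce(self, small_parts):
        parts = small_parts[:5]
        dm = sc.pairwise_distances(parts)
        for i, j in itertools.product(range(5), repeat=2):
            assert dm.matrix[i, j] == dp_levenshtein(
                parts[i].sequence, parts[j].sequence
            )
        assert np.array_equal(dm.matrix, dm.matrix.T)
        assert np.all(np.diag(dm.matrix) == 0)


# ---------------------------------------------------------------------------
# clustering
# ---------------------------------------------------------------------------


class TestClusterParts:
    def test_single_part_is_own_exemplar(self):
        dm = sc.pairwise_distances([sc.PartSequence("p", "ACGT")])
        asg = sc.cluster_parts(dm)
        assert asg.labels == {"p": 0} and asg.exemplars[0] == "p"

    def test_identical_parts_one_cluster(self):
        parts = [sc.PartSequence(f"p{i}", "ACGTACGTACGT") for i in range(5)]
        asg = sc.cluster_parts(sc.pairwise_distances(parts))
        assert asg.n_clusters == 1

    def test_recovers_ground_truth_families(self, family_parts):
        parts, labels = family_parts
        asg = sc.cluster_parts(sc.pairwise_distances(parts))
        # every family maps to exactly one cluster and clusters do not mix
        by_family = {}
        for part, fam in zip(parts, labels):
            by_family.setdefault(fam, set()).add(asg.labels[part.name])
        found = [cl for s in by_family.values() for cl in s]
        assert all(len(s) == 1 for s in by_family.values())
        assert len(set(found)) == len(by_family)

    def test_deterministic(self, family_parts):
        parts, _ = family_parts
        dm = sc.pairwise_distances(parts)
        a1, a2 = sc.cluster_parts(dm), sc.cluster_parts(dm)
        assert a1.labels == a2.labels and a1.exemplars == a2.exemplars

    def test_exemplars_belong_to_their_clusters(self, small_parts):
        asg = sc.cluster_parts(sc.pairwise_distances(small_parts))
        for label, exemplar in asg.exemplars.items():
            assert asg.labels[exemplar] == label


# ---------------------------------------------------------------------------
# grouping
# ---------------------------------------------------------------------------


def _partition_ok(groups, parts):
    names = [m for g in groups for m in g.members]
    return sorted(names) == sorted(p.name for p in parts)


class TestFormGroups:
    def test_single_part(self):
        parts = [sc.PartSequence("p", "ACGT")]
        asg = sc.ClusterAssignment({"p": 0}, {0: "p"})
        groups = sc.form_groups(asg, parts)
        assert len(groups) == 1 and groups[0].members == ["p"]

    def test_three_balanced_clusters_give_three_triplets(self):
        parts = [sc.PartSequence(f"c{c}_{i}", "ACGT" * (c + 2)) for c in range(3) for i in range(3)]
        labels = {p.name: int(p.name[1]) for p in parts}
        asg = sc.ClusterAssignment(labels, {c: f"c{c}_0" for c in range(3)})
        groups = sc.form_groups(asg, parts)
        assert len(groups) == 3
        for g in groups:
            assert len(g) == 3
            assert len({labels[m] for m in g.members}) == 3
        assert _partition_ok(groups, parts)

    def test_members_always_from_distinct_clusters(self, small_parts):
        asg = sc.cluster_parts(sc.pairwise_distances(small_parts))
        groups = sc.form_groups(asg, small_parts)
        for g in groups:
            assert len(g) <= 3
            assert len({asg.labels[m] for m in g.members}) == len(g)
        assert _partition_ok(groups, small_parts)

    def test_aggressive_merges_singletons(self):
        # two clusters of two -> one pair per round, then the leftovers are
        # singletons; construct 1 cluster of 2 + 2 singleton clusters instead
        parts = [sc.PartSequence(n, s) for n, s in
                 [("a1", "ACGTACGT"), ("a2", "ACGTACGA"), ("b", "TTTTTTTT"), ("c", "GGGGGGGG")]]
        labels = {"a1": 0, "a2": 0, "b": 1, "c": 2}
        asg = sc.ClusterAssignment(labels, {0: "a1", 1: "b", 2: "c"})
        plain = sc.form_groups(asg, parts, aggressive=False)
        singles = [g for g in plain if len(g) == 1]
        merged = sc.form_groups(asg, parts, aggressive=True)
        if len(singles) > 1:
            assert len(merged) < len(plain)
        assert _partition_ok(merged, parts)
        assert all(len(g) <= 3 for g in merged)

    def test_aggressive_on_all_singletons_chunks_by_three(self):
        parts = [sc.PartSequence(f"p{i}", "ACGT" * (i + 1)) for i in range(7)]
        labels = {p.name: i for i, p in enumerate(parts)}
        asg = sc.ClusterAssignment(labels, {i: p.name for i, p in enumerate(parts)})
        merged = sc.form_groups(asg, parts, aggressive=True)
        sizes = sorted(len(g) for g in merged)
        assert sizes == [1, 3, 3]
        assert _partition_ok(merged, parts)


# ---------------------------------------------------------------------------
# rewriting and digestion
# ---------------------------------------------------------------------------


class TestRewriteAndDigest:
    def test_group_of_one_keeps_bsmbi_unchanged(self, small_parts):
        g = sc.rewrite_enzyme_sites(sc.SynthesisGroup([small_parts[0].name]), small_parts)
        assert g.sequence == small_parts[0].sequence
        assert g.enzymes[0].name == "BsmBI"

    def test_group_of_three_site_counts(self, small_parts):
        g = sc.rewrite_enzyme_sites(
            sc.SynthesisGroup([p.name for p in small_parts[:3]]), small_parts
        )
        assert sc.count_sites(g.sequence, sc.BSMBI) == 2
        assert sc.count_sites(g.sequence, sc.BBSI) == 2
        assert sc.count_sites(g.sequence, sc.BSPMI) == 2

    def test_digestion_roundtrip_every_member(self, small_parts):
        group = sc.SynthesisGroup([p.name for p in small_parts[:3]])
        rewritten = sc.rewrite_enzyme_sites(group, small_parts)
        by_name = {p.name: p for p in small_parts}
        for member, enzyme in zip(rewritten.members, rewritten.enzymes):
            original = sc.digest(by_name[member].sequence, sc.BSMBI)
            released = sc.digest(rewritten.sequence, enzyme)
            assert released.sequence == original.sequence
            assert released.left_overhang == original.left_overhang
            assert released.right_overhang == original.right_overhang

    def test_wrong_site_count_raises_naming_part(self):
        bad = sc.PartSequence("noflank", "ACGTACGTACGTACGT")
        with pytest.raises(sc.StructuralError, match="noflank"):
            sc.rewrite_enzyme_sites(sc.SynthesisGroup(["noflank"]), [bad])

    def test_oversized_group_rejected(self, small_parts):
        with pytest.raises(sc.RewriteError, match="unloading enzymes"):
            sc.rewrite_enzyme_sites(
                sc.SynthesisGroup([p.name for p in small_parts[:4]]), small_parts
            )


# ---------------------------------------------------------------------------
# padding and benchmarking
# ---------------------------------------------------------------------------


class TestNaivePadding:
    def test_short_part_padded_to_minimum(self):
        part = sd.simulate_parts(sd.PartSimSpec(n_parts=1, core_length_range=(98, 98), seed=0))[0]
        assert len(part) == 120  # 98-nt core + two 11-nt entry flanks
        padded = sc.pad_naive(part, min_length=300, rng=0)
        assert len(padded) == 300
        assert padded.startswith(part.sequence)

    @pytest.mark.parametrize("core", [278, 390])
    def test_long_part_unchanged(self, core):
        part = sd.simulate_parts(
            sd.PartSimSpec(n_parts=1, core_length_range=(core, core), seed=0)
        )[0]
        assert len(part) >= 300
        assert sc.pad_naive(part, min_length=300, rng=0) == part.sequence

    def test_filler_introduces_no_sites(self):
        part = sd.simulate_parts(sd.PartSimSpec(n_parts=1, core_length_range=(60, 60), seed=5))[0]
        padded = sc.pad_naive(part, min_length=400, rng=42)
        for enzyme in sc.DEFAULT_ENZYMES:
            assert sc.count_sites(padded, enzyme) == sc.count_sites(part.sequence, enzyme)


class TestSynthesisReport:
    def test_single_part_identical_across_strategies(self):
        part = sd.simulate_parts(sd.PartSimSpec(n_parts=1, seed=0))[0]
        rep = sc.synthesis_report([part], seed=0)
        totals = {r.total_bases for r in rep.results.values()}
        assert len(totals) == 1

    def test_naive_total_is_forced_by_padding_rule(self):
        parts = sd.simulate_parts(
            sd.PartSimSpec(n_parts=3, core_length_range=(78, 78), seed=1)
        )
        assert all(len(p) == 100 for p in parts)
        rep = sc.synthesis_report(parts, strategies=("naive",), min_length=300, seed=0)
        naive = rep.results["naive"]
        assert naive.total_bases == 900
        assert naive.filler_bases == 600

    def test_clustering_beats_naive_on_short_parts(self, small_parts):
        rep = sc.synthesis_report(small_parts, seed=2)
        r = rep.results
        assert r["clustered"].total_bases <= r["naive"].total_bases
        assert r["aggressive"].total_bases <= r["clustered"].total_bases

    def test_random_strategy_seeded(self, small_parts):
        rep1 = sc.synthesis_report(small_parts, strategies=("random",), seed=9)
        rep2 = sc.synthesis_report(small_parts, strategies=("random",), seed=9)
        assert [g.members for g in rep1.results["random"].fragments] == [
            g.members for g in rep2.results["random"].fragments
        ]
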