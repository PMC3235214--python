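"""Diameter-rule clustering, query assignment, abundance tables."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from hetavar import align, subfamily
from hetavar.align import DistanceMatrix
from hetavar.errors import AnalysisError
from hetavar.seq_io import SequenceRecord

from oracles import scipy_complete_linkage


def dm_from(ids, entries):
    n = len(ids)
    data = np.zeros((n, n))
    for (a, b), d in entries.items():
        i, j = ids.index(a), ids.index(b)
        data[i, j] = data[j, i] = d
    return DistanceMatrix(list(ids), data)


class TestCompleteLinkagePartition:
    def test_two_blocks(self):
        ids = ["a1", "a2", "b1", "b2"]
        entries = {("a1", "a2"): 0.05, ("b1", "b2"): 0.05,
                   ("a1", "b1"): 0.20, ("a1", "b2"): 0.20,
                   ("a2", "b1"): 0.20, ("a2", "b2"): 0.20}
        part = subfamily.complete_linkage_partition(dm_from(ids, entries))
        assert part.n_subfamilies == 2
        assert part.labels["a1"] == part.labels["a2"]
        assert part.labels["b1"] == part.labels["b2"]

    def test_all_beyond_threshold_gives_singletons(self):
        ids = ["x", "y", "z"]
        entries = {p: 0.15 for p in itertools.combinations(ids, 2)}
        part = subfamily.complete_linkage_partition(dm_from(ids, entries))
        assert part.n_subfamilies == 3

    def test_chain_respects_diameter_rule(self):
        # A,B merge first at 0.08; C stays out because d(A,C)=0.12 > 0.10
        ids = ["A", "B", "C"]
        entries = {("A", "B"): 0.08, ("B", "C"): 0.08, ("A", "C"): 0.12}
        part = subfamily.complete_linkage_partition(dm_from(ids, entries))
        assert part.labels["A"] == part.labels["B"]
        assert part.labels["C"] != part.labels["A"]

    def test_undefined_distance_blocks_merge(self):
        ids = ["a", "b"]
        data = np.array([[0.0, np.nan], [np.nan, 0.0]])
        part = subfamily.complete_linkage_partition(DistanceMatrix(ids, data))
        assert part.n_subfamilies == 2

    def test_empty_matrix_rejected(self):
        with pytest.raises(AnalysisError):
            subfamily.complete_linkage_partition(
                DistanceMatrix([], np.zeros((0, 0)))
            )

    def test_labels_by_descending_size(self):
        ids = ["q1", "q2", "q3", "r1"]
        entries = {("q1", "q2"): 0.02, ("q1", "q3"): 0.02, ("q2", "q3"): 0.02,
                   ("q1", "r1"): 0.5, ("q2", "r1"): 0.5, ("q3", "r1"): 0.5}
        part = subfamily.complete_linkage_partition(dm_from(ids, entries))
        assert part.labels["q1"] == "A"
        assert part.labels["r1"] == "B"

    @given(st.integers(0, 10_000))
    def test_matches_scipy_complete_linkage(self, seed):
        """Oracle equivalence on random tie-free matrices (n <= 8)."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        d = rng.uniform(0.01, 0.3, size=(n, n))
        d = np.triu(d, 1)
        d = d + d.T
        ids = [f"s{i}" for i in range(n)]
        dm = DistanceMatrix(ids, d)
        ours = {frozenset(dm.ids[i] for i, r in enumerate(ids)
                          if part.labels[r] == lab)
                for part in [subfamily.complete_linkage_partition(dm, 0.10)]
                for lab in part.subfamilies}
        theirs = scipy_complete_linkage(ids, d, 0.10)
        assert ours == theirs

    @given(st.integers(0, 10_000))
    def test_diameter_rule_and_threshold_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 9))
        d = rng.uniform(0.0, 0.3, size=(n, n))
        d = np.triu(d, 1)
        d = d + d.T
        dm = DistanceMatrix([f"s{i}" for i in range(n)], d)
        low = subfamily.complete_linkage_partition(dm, 0.08)
        high = subfamily.complete_linkage_partition(dm, 0.15)
        # diameter rule is asserted internally; re-check externally here
        for part in (low, high):
            for lab in part.subfamilies:
                members = part.members(lab)
                for a, b in itertools.combinations(members, 2):
                    assert dm[a, b] <= part.threshold + 1e-12
        assert high.n_subfamilies <= low.n_subfamilies

    def test_label_stability_under_permutation(self, rng):
        n = 7
        d = rng.uniform(0.0, 0.3, size=(n, n))
        d = np.triu(d, 1)
        d = d + d.T
        ids = [f"s{i}" for i in range(n)]
        dm = DistanceMatrix(ids, d)
        part1 = subfamily.complete_linkage_partition(dm)
        perm = list(rng.permutation(n))
        dm2 = DistanceMatrix([ids[i] for i in perm], d[np.ix_(perm, perm)])
        part2 = subfamily.complete_linkage_partition(dm2)
        assert part1.labels == part2.labels


class TestReferenceRelabelling:
    def _partition(self):
        ids = ["new1", "new2", "ref_old", "lone"]
        entries = {("new1", "new2"): 0.03, ("new1", "ref_old"): 0.04,
                   ("new2", "ref_old"): 0.05, ("new1", "lone"): 0.4,
                   ("new2", "lone"): 0.4, ("ref_old", "lone"): 0.4}
        return subfamily.complete_linkage_partition(dm_from(ids, entries))

    def test_cluster_adopts_prior_letter(self):
        part = self._partition()
        out = subfamily.relabel_with_references(part, {"ref_old": "D"})
        assert out.labels["new1"] == "D"
        assert out.labels["lone"] != "D"

    def test_conflicting_references_rejected(self):
        part = self._partition()
        part2 = subfamily.SubfamilyPartition(
            part.threshold, dict(part.labels)
        )
        with pytest.raises(AnalysisError):
            subfamily.relabel_with_references(
                part2, {"ref_old": "D", "new1": "B"}
            )


class TestAssignQueries:
    @pytest.fixture
    def small_partition(self):
        a = "ACGTACGTACGTACGTACGTACGTACGTACGT"
        b = "TGCATGCATGCATGCATGCATGCATGCATGCA"
        genomic = [SequenceRecord("gA1", a), SequenceRecord("gA2", a),
                   SequenceRecord("gB1", b)]
        dm = align.distance_matrix(genomic)
        part = subfamily.complete_linkage_partition(dm)
        return part, genomic, a, b

    def test_identical_query_assigned_at_zero(self, small_partition):
        part, genomic, a, _ = small_partition
        res = subfamily.assign_queries(part, genomic, [SequenceRecord("q", a)])
        assert res.labels["q"] == part.labels["gA1"]
        assert res.distances["q"] == 0.0

    def test_distant_query_unassigned(self, small_partition):
        part, genomic, _, _ = small_partition
        far = "GGGGGGGGGGGGGGGGCCCCCCCCCCCCCCCC"
        res = subfamily.assign_queries(part, genomic, [SequenceRecord("q", far)])
        assert res.labels["q"] == subfamily.UNASSIGNED

    def test_id_collision_rejected(self, small_partition):
        part, genomic, a, _ = small_partition
        with pytest.raises(AnalysisError):
            subfamily.assign_queries(part, genomic, [SequenceRecord("gA1", a)])

    def test_synthetic_transcripts_recover_their_subfamily(self):
        from hetavar import synthetic_data as sd

        cfg = sd.GeneratorConfig(n_subfamilies=3, members_per_subfamily=3,
                                 region_length=300, seed=5)
        genomes, truth = sd.generate_subfamily_genomes(cfg)
        tr, tt = sd.generate_transcripts(
            genomes, truth, {"S1": 10, "S2": 10, "S3": 10}, "sense",
            seed=6, error_rate=0.001,
        )
        dm = align.distance_matrix(genomes)
        part = subfamily.complete_linkage_partition(dm)
        res = subfamily.assign_queries(part, genomes, tr)
        fam_label = {
            fam: part.labels[truth.genomic_members(fam)[0]]
            for fam in ("S1", "S2", "S3")
        }
        truthmap = dict(zip(tt.records.record_id, tt.records.subfamily))
        correct = sum(
            res.labels[t.record_id] == fam_label[truthmap[t.record_id]]
            for t in tr
        )
        assert correct >= 0.99 * len(tr)


class TestAbundanceTable:
    def _records(self, n, strain="Oregon-R", material="RNA", strand="antisense"):
        return [
            SequenceRecord(f"t{i}", "ACGT", strain=strain, region="3UTR",
                           material=material, strand=strand)
            for i in range(n)
        ]

    def test_even_split(self):
        recs = self._records(4)
        labels = {"t0": "A", "t1": "A", "t2": "B", "t3": "B"}
        tab = subfamily.abundance_table(labels, recs)
        props = tab.set_index("subfamily")["proportion"]
        assert props["A"] == pytest.approx(0.5)
        assert props["B"] == pytest.approx(0.5)

    def test_dominant_subfamily_share(self):
        recs = self._records(100)
        labels = {f"t{i}": ("C" if i < 60 else "H") for i in range(100)}
        tab = subfamily.abundance_table(labels, recs)
        assert tab.set_index("subfamily")["proportion"]["C"] == pytest.approx(0.60)

    def test_zero_rows_for_absent_subfamilies(self):
        recs = self._records(2)
        labels = {"t0": "A", "t1": "A"}
        tab = subfamily.abundance_table(labels, recs, all_subfamilies=["A", "J"])
        j_row = tab[tab["subfamily"] == "J"].iloc[0]
        assert j_row["count"] == 0
        assert j_row["proportion"] == 0.0

    def test_proportions_sum_to_one_per_stratum(self):
        recs = (self._records(3) +
                [SequenceRecord("g0", "ACGT", strain="GIII", region="3UTR",
                                material="genomic", strand="na")])
        labels = {"t0": "A", "t1": "B", "t2": "B", "g0": "A"}
        tab = subfamily.abundance_table(labels, recs)
        sums = tab.groupby(subfamily.STRATUM_KEYS)["proportion"].sum()
        assert np.allclose(sums.values, 1.0)
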