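"""Intron calling, variant classification, PWM scoring, usage tables."""

import collections

import numpy as np
import pytest

from hetavar import splicing
from hetavar.errors import AnalysisError
from hetavar.seq_io import SequenceRecord


def plant_junctions(seq: str, introns) -> str:
    """Force canonical GT..AG at the given intervals of a sequence."""
    s = list(seq)
    for d, a in introns:
        s[d:d + 2] = "GT"
        s[a - 2:a] = "AG"
    return "".join(s)


@pytest.fixture
def consensus(make_seq):
    return plant_junctions(make_seq(400), [(100, 180), (250, 340)])


class TestCallIntrons:
    def test_identical_transcript_has_no_introns(self, consensus):
        assert splicing.call_introns(consensus, consensus) == []

    def test_single_planted_intron_recovered(self, consensus):
        transcript = splicing.excise(consensus, [(100, 180)])
        calls = splicing.call_introns(transcript, consensus)
        assert len(calls) == 1
        call = calls[0]
        assert call.interval == (100, 180)
        assert call.canonical
        assert call.donor_dinucleotide == "GT"
        assert call.acceptor_dinucleotide == "AG"

    def test_two_planted_introns_sorted(self, consensus):
        transcript = splicing.excise(consensus, [(100, 180), (250, 340)])
        calls = splicing.call_introns(transcript, consensus)
        assert [c.interval for c in calls] == [(100, 180), (250, 340)]
        assert all(c.canonical for c in calls)

    def test_short_deletions_are_not_introns(self, consensus):
        # a 20 nt deletion is indel polymorphism, not splicing
        transcript = consensus[:200] + consensus[220:]
        assert splicing.call_introns(transcript, consensus) == []

    def test_min_intron_length_is_the_switch_point(self, consensus):
        transcript = consensus[:200] + consensus[250:]
        calls = splicing.call_introns(transcript, consensus,
                                      min_intron_length=50)
        assert len(calls) == 1
        assert splicing.call_introns(transcript, consensus,
                                     min_intron_length=60) == []

    def test_transcript_mismatches_tolerated(self, consensus, rng):
        transcript = list(splicing.excise(consensus, [(100, 180)]))
        for pos in rng.choice(len(transcript), size=6, replace=False):
            transcript[pos] = "ACGT"[(("ACGT".index(transcript[pos])) + 1) % 4]
        calls = splicing.call_introns("".join(transcript), consensus)
        assert [c.interval for c in calls] == [(100, 180)]

    def test_overlong_transcript_rejected(self, consensus):
        with pytest.raises(AnalysisError):
            splicing.call_introns(consensus + consensus, consensus)

    def test_reconstruction_by_excision(self, consensus):
        """Excising the called introns from the reference reproduces the
        transcript (clean case)."""
        for introns in ([(100, 180)], [(100, 180), (250, 340)]):
            transcript = splicing.excise(consensus, introns)
            calls = splicing.call_introns(transcript, consensus)
            rebuilt = splicing.excise(consensus,
                                      [c.interval for c in calls])
            assert rebuilt == transcript


class TestJunctionSliding:
    def test_ambiguous_placement_slides_to_canonical(self, make_seq):
        # repeat around the junction makes naive placement ambiguous
        ref = plant_junctions(make_seq(300), [(100, 180)])
        transcript = splicing.excise(ref, [(100, 180)])
        calls = splicing.call_introns(transcript, ref)
        assert calls[0].canonical
        assert calls[0].interval == (100, 180)


class TestClassifyVariants:
    def _call(self, tid, introns):
        return [
            splicing.IntronCall(tid, "cons", d, a, "GT", "AG", True)
            for d, a in introns
        ]

    def test_identical_single_intron_one_variant(self):
        calls = {f"t{i}": self._call(f"t{i}", [(100, 180)]) for i in range(10)}
        catalogue, labels = splicing.classify_variants(calls)
        assert len(catalogue) == 1
        assert catalogue[0].variant_id == "SV1"
        assert catalogue[0].n_members == 10
        assert set(labels.values()) == {"SV1"}

    def test_jitter_within_tolerance_merges(self):
        calls = {"t0": self._call("t0", [(100, 180)]),
                 "t1": self._call("t1", [(102, 182)]),
                 "t2": self._call("t2", [(99, 179)])}
        catalogue, _ = splicing.classify_variants(calls, position_tolerance=3)
        assert len(catalogue) == 1

    def test_beyond_tolerance_separates(self):
        calls = {"t0": self._call("t0", [(100, 180)]),
                 "t1": self._call("t1", [(110, 190)])}
        catalogue, _ = splicing.classify_variants(calls, position_tolerance=3)
        assert len(catalogue) == 2

    def test_unspliced_reserved_label(self):
        calls = {"t0": [], "t1": self._call("t1", [(100, 180)])}
        _, labels = splicing.classify_variants(calls)
        assert labels["t0"] == splicing.UNSPLICED

    def test_variant_rank_by_frequency(self):
        calls = {}
        for i in range(3):
            calls[f"a{i}"] = self._call(f"a{i}", [(200, 260)])
        for i in range(7):
            calls[f"b{i}"] = self._call(f"b{i}", [(100, 180)])
        catalogue, _ = splicing.classify_variants(calls)
        assert catalogue[0].variant_id == "SV1"
        assert catalogue[0].introns == ((100, 180),)
        assert catalogue[1].introns == ((200, 260),)

    def test_four_variant_recovery_with_diagonal_confusion(self):
        from hetavar import synthetic_data as sd
        from hetavar import align

        specs = [sd.SpliceVariantSpec("V1", [(60, 140)]),
                 sd.SpliceVariantSpec("V2", [(60, 140), (200, 290)]),
                 sd.SpliceVariantSpec("V3", [(60, 160)]),
                 sd.SpliceVariantSpec("V4", [(200, 290)])]
        cfg = sd.GeneratorConfig(n_subfamilies=3, members_per_subfamily=4,
                                 region_length=400, seed=21, indel_rate=0.002)
        genomes, truth = sd.generate_subfamily_genomes(cfg, specs)
        tr, tt = sd.generate_transcripts(
            genomes, truth, {"S1": 24, "S2": 24, "S3": 24}, "antisense",
            variant_mixture={"V1": 0.4, "V2": 0.25, "V3": 0.15, "V4": 0.1,
                             "unspliced": 0.1},
            seed=5,
        )
        msa = align.progressive_msa(genomes)
        cons = align.consensus_sequence(msa)
        calls = {r.record_id: splicing.call_introns(r, cons) for r in tr}
        catalogue, labels = splicing.classify_variants(calls)
        assert len(catalogue) == 4
        truthmap = dict(zip(tt.records.record_id, tt.records.variant))
        confusion = collections.defaultdict(set)
        for tid, lab in labels.items():
            confusion[truthmap[tid]].add(lab)
        # each true variant maps to exactly one catalogue label and the
        # mapping is a bijection (diagonal confusion up to relabelling)
        assert all(len(v) == 1 for v in confusion.values())
        assigned = [next(iter(v)) for k, v in confusion.items()
                    if k != "unspliced"]
        assert len(set(assigned)) == 4
        assert confusion["unspliced"] == {splicing.UNSPLICED}


class TestSpliceSitePWM:
    def _calls_at(self, consensus, positions):
        out = []
        for i, (d, a) in enumerate(positions):
            out.append(splicing.IntronCall(f"t{i}", "cons", d, a,
                                           consensus[d:d + 2],
                                           consensus[a - 2:a],
                                           consensus[d:d + 2] == "GT"
                                           and consensus[a - 2:a] == "AG"))
        return out

    @pytest.fixture
    def varied_sites(self, make_seq):
        positions = [(50 + 60 * k, 90 + 60 * k) for k in range(5)]
        cons = plant_junctions(make_seq(400), positions)
        return cons, positions

    def test_needs_two_canonical_calls(self, varied_sites):
        cons, positions = varied_sites
        with pytest.raises(AnalysisError):
            splicing.build_splice_pwm(cons, self._calls_at(cons, positions[:1]))

    def test_true_window_scores_maximal_when_training_identical(self, varied_sites):
        cons, positions = varied_sites
        calls = self._calls_at(cons, [positions[0]] * 4)
        pwm = splicing.build_splice_pwm(cons, calls)
        true_win = splicing.donor_window_seq(cons, calls[0])
        true_score = splicing.score_splice_site(pwm.donor, true_win)
        best = pwm.donor.max(axis=0).sum()
        assert true_score == pytest.approx(best)

    def test_uniform_training_gives_zero_logodds(self):
        # every base equally frequent in windows and background
        cons = "ACGT" * 25
        calls = []
        for i, d in enumerate((8, 13, 18, 23)):
            calls.append(splicing.IntronCall(f"t{i}", "c", d, d + 60,
                                             "GT", "AG", True))
        pwm = splicing.build_splice_pwm(cons, calls, donor_window=(-4, 4),
                                        acceptor_window=(-4, 4))
        # windows tile the same 4-periodic sequence at 4 nt offsets: every
        # column sees each base once -> probabilities equal background
        assert np.allclose(pwm.donor, 0.0, atol=1e-9)

    def test_planted_gt_positions_carry_most_information(self, varied_sites):
        cons, positions = varied_sites
        calls = self._calls_at(cons, positions)
        assert all(c.canonical for c in calls)
        pwm = splicing.build_splice_pwm(cons, calls)
        ic = pwm.information_content("donor")
        # window (-3,+6): offsets 0,1 are the invariant G,T
        top_two = set(np.argsort(ic)[-2:])
        assert top_two == {3, 4}

    def test_true_sites_outrank_random_windows(self, varied_sites, rng):
        cons, positions = varied_sites
        calls = self._calls_at(cons, positions)
        pwm = splicing.build_splice_pwm(cons, calls)
        wins = [splicing.donor_window_seq(cons, c) for c in calls]
        true_scores = [splicing.score_splice_site(pwm.donor, w) for w in wins]
        width = pwm.donor.shape[1]
        better = 0
        trials = 200
        for _ in range(trials):
            start = int(rng.integers(0, len(cons) - width))
            w = cons[start:start + width]
            if splicing.score_splice_site(pwm.donor, w) < min(true_scores):
                better += 1
        assert better / trials >= 0.95

    def test_window_length_mismatch_rejected(self, varied_sites):
        cons, positions = varied_sites
        pwm = splicing.build_splice_pwm(cons, self._calls_at(cons, positions))
        with pytest.raises(AnalysisError):
            splicing.score_splice_site(pwm.donor, "ACGT")


class TestUsageTables:
    def _records(self, n, strain):
        return [
            SequenceRecord(f"{strain}-t{i}", "ACGT", strain=strain,
                           region="3UTR", material="RNA", strand="antisense")
            for i in range(n)
        ]

    def test_spliced_fraction_per_strain(self):
        recs = self._records(100, "GIII") + self._records(100, "Oregon-R")
        labels = {}
        for i in range(100):
            labels[f"GIII-t{i}"] = "SV1" if i < 91 else splicing.UNSPLICED
            labels[f"Oregon-R-t{i}"] = "SV1" if i < 74 else splicing.UNSPLICED
        subfam = {tid: "A" for tid in labels}
        tables = splicing.usage_tables(labels, subfam, recs)
        frac = tables["spliced_fraction"].set_index("strain")["spliced_percent"]
        assert frac["GIII"] == pytest.approx(91.0)
        assert frac["Oregon-R"] == pytest.approx(74.0)

    def test_variant_share_of_all_transcripts(self):
        recs = self._records(100, "GIII")
        labels = {f"GIII-t{i}": ("SV1" if i < 70 else splicing.UNSPLICED)
                  for i in range(100)}
        tables = splicing.usage_tables(labels, {t: "C" for t in labels}, recs)
        usage = tables["variant_usage"]
        row = usage[(usage["strain"] == "GIII") & (usage["variant"] == "SV1")]
        assert row["percent_of_all"].iloc[0] == pytest.approx(70.0)
        assert row["percent_of_spliced"].iloc[0] == pytest.approx(100.0)

    def test_all_unspliced_pool(self):
        recs = self._records(5, "Oregon-R")
        labels = {r.record_id: splicing.UNSPLICED for r in recs}
        tables = splicing.usage_tables(labels, {t: "A" for t in labels}, recs)
        assert tables["spliced_fraction"]["spliced_percent"].iloc[0] == 0.0
        assert (tables["variant_usage"]["variant"] == splicing.UNSPLICED).all()

    def test_variant_by_subfamily_counts(self):
        recs = self._records(4, "GIII")
        labels = {"GIII-t0": "SV1", "GIII-t1": "SV1",
                  "GIII-t2": "SV2", "GIII-t3": splicing.UNSPLICED}
        subfam = {"GIII-t0": "C", "GIII-t1": "H", "GIII-t2": "C",
                  "GIII-t3": "C"}
        tab = splicing.usage_tables(labels, subfam, recs)["variant_by_subfamily"]
        lookup = tab.set_index(["variant", "subfamily"])["count"]
        assert lookup[("SV1", "C")] == 1
        assert lookup[("SV1", "H")] == 1
        assert lookup[("SV2", "C")] == 1
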