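"""Marker-identity computation, greedy species clustering and the
ANI-gap threshold benchmark."""

import numpy as np
import pytest

from phagedyn.clustering import (
    AniBenchmarkPair,
    SequenceRecord,
    benchmark_threshold,
    dereplicate,
    dereplicate_and_cluster,
    pairwise_identity,
)


def _mutate(seq: str, positions, rng=None) -> str:
    swap = {"A": "C", "C": "G", "G": "T", "T": "A"}
    out = list(seq)
    for p in positions:
        out[p] = swap[out[p]]
    return "".join(out)


def _random_seq(rng, n) -> str:
    return "".join(rng.choice(list("ACGT"), size=n))


class TestPairwiseIdentity:
    def test_identical_sequences_are_100_percent(self, rng):
        s = _random_seq(rng, 100)
        assert pairwise_identity(SequenceRecord("a", s), SequenceRecord("b", s)) == 100.0

    def test_two_mismatches_in_100_bp_is_98(self, rng):
        s = _random_seq(rng, 100)
        m = _mutate(s, [10, 60])
        assert pairwise_identity(SequenceRecord("a", s), SequenceRecord("b", m)) == pytest.approx(98.0)

    def test_symmetry_over_random_pairs(self, rng):
        for _ in range(50):
            a = SequenceRecord("a", _random_seq(rng, int(rng.integers(30, 80))))
            b = SequenceRecord("b", _random_seq(rng, int(rng.integers(30, 80))))
            assert pairwise_identity(a, b) == pytest.approx(pairwise_identity(b, a))

    def test_n_counts_as_mismatch_even_against_n(self):
        a = SequenceRecord("a", "ACGTNACGT")
        b = SequenceRecord("b", "ACGTNACGT")
        # 8 of 9 columns match: N-N is forced to mismatch
        assert pairwise_identity(a, b) == pytest.approx(100 * 8 / 9)

    def test_masked_interval_removed_before_comparison(self, rng):
        s = _random_seq(rng, 60)
        insert = s[:20] + "A" * 10 + s[20:]
        a = SequenceRecord("a", s)
        b = SequenceRecord("b", insert)
        masked = pairwise_identity(a, b, mask_intervals=None)
        # removing the insertion interval from b restores perfect identity
        b_masked = SequenceRecord("b", insert[:20] + insert[30:])
        assert pairwise_identity(a, b_masked) == 100.0
        assert masked < 100.0

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            SequenceRecord("a", "")


class TestClustering:
    def test_two_identical_sequences_form_one_cluster(self, rng):
        s = _random_seq(rng, 120)
        clusters = dereplicate_and_cluster(
            [SequenceRecord("a", s), SequenceRecord("b", s)], threshold=0.98
        )
        assert len(clusters) == 1
        assert sorted(clusters[0].member_ids) == ["a", "b"]

    def test_near_and_far_variants_split_at_98(self, rng):
        a = _random_seq(rng, 200)
        b = _mutate(a, [5])  # 99.5% identity
        c = _mutate(a, list(range(0, 40, 2)))  # 20 mismatches, 90%
        clusters = dereplicate_and_cluster(
            [SequenceRecord("A", a), SequenceRecord("B", b), SequenceRecord("C", c)],
            threshold=0.98,
        )
        sets = sorted(sorted(cl.member_ids) for cl in clusters)
        assert sets == [["A", "B"], ["C"]]

    def test_threshold_one_gives_singletons_after_dereplication(self, rng):
        a = _random_seq(rng, 80)
        records = [
            SequenceRecord("a", a),
            SequenceRecord("b", _mutate(a, [3])),
            SequenceRecord("c", _mutate(a, [7])),
        ]
        clusters = dereplicate_and_cluster(records, threshold=1.0)
        assert sorted(len(c.member_ids) for c in clusters) == [1, 1, 1]

    def test_empty_input_gives_empty_output(self):
        assert dereplicate_and_cluster([], threshold=0.98) == []

    def test_dereplication_is_idempotent(self, rng):
        s = _random_seq(rng, 50)
        records = [SequenceRecord(i, s) for i in ("x", "y", "z")]
        first = dereplicate(records)
        assert first == {"x": ["x", "y", "z"]}
        again = dereplicate([SequenceRecord("x", s)])
        assert again == {"x": ["x"]}

    def test_greedy_matches_brute_force_on_small_inputs(self, rng):
        """Point-mutated sequences (no indels) let a hamming-identity greedy
        oracle reproduce the expected assignment independently of the
        alignment machinery."""
        for trial in range(20):
            base = _random_seq(rng, 100)
            records = []
            for i in range(int(rng.integers(3, 10))):
                k = int(rng.integers(0, 15))
                pos = rng.choice(100, size=k, replace=False)
                records.append(SequenceRecord(f"s{i:02d}", _mutate(base, pos)))

            def hamming_identity(x, y):
                return 100.0 * np.mean([p == q for p, q in zip(x, y)])

            # oracle: same ordering rule, independent identity computation
            dedup = {}
            for r in records:
                dedup.setdefault(r.seq, []).append(r.id)
            reps = {min(ids): sorted(ids) for ids in dedup.values()}
            rec_by_id = {r.id: r for r in records}
            order = sorted(reps, key=lambda i: (-len(rec_by_id[i].seq), i))
            expected = []
            for sid in order:
                for cl in expected:
                    if hamming_identity(rec_by_id[cl[0]].seq, rec_by_id[sid].seq) >= 98.0:
                        cl.extend(reps[sid])
                        break
                else:
                    expected.append([sid, *[m for m in reps[sid] if m != sid]])
            got = dereplicate_and_cluster(records, threshold=0.98)
            assert sorted(sorted(c.member_ids) for c in got) == sorted(
                sorted(set(c)) for c in expected
            )

    def test_members_match_centroid_at_threshold(self, rng):
        base = _random_seq(rng, 150)
        records = [SequenceRecord(f"s{i}", _mutate(base, rng.choice(150, size=i, replace=False)))
                   for i in range(8)]
        clusters = dereplicate_and_cluster(records, threshold=0.97)
        rec = {r.id: r for r in records}
        for cl in clusters:
            for mid in cl.member_ids:
                assert pairwise_identity(rec[cl.centroid_id], rec[mid]) >= 97.0


class TestBenchmark:
    def test_paper_style_gap_contains_98(self):
        pairs = [AniBenchmarkPair(mi, 99.0) for mi in (99.0, 99.5, 100.0)] + [
            AniBenchmarkPair(mi, 80.0) for mi in (85.0, 88.0, 90.0)
        ]
        rep = benchmark_threshold(pairs, candidate_threshold=98.0)
        assert rep.gap == (90.0, 99.0)
        assert rep.threshold_inside_gap is True

    def test_overlapping_classes_flag_gap_undefined(self):
        pairs = [AniBenchmarkPair(95.0, 99.0), AniBenchmarkPair(96.0, 80.0)]
        with pytest.warns(UserWarning):
            rep = benchmark_threshold(pairs, candidate_threshold=98.0)
        assert not rep.gap_defined and rep.gap is None

    def test_uniform_bands_recover_band_edges(self, rng):
        intra = rng.uniform(98.5, 100.0, size=200)
        inter = rng.uniform(80.0, 91.0, size=200)
        pairs = [AniBenchmarkPair(v, 99.0) for v in intra] + [
            AniBenchmarkPair(v, 85.0) for v in inter
        ]
        rep = benchmark_threshold(pairs)
        assert rep.min_intra == pytest.approx(intra.min())
        assert rep.max_inter == pytest.approx(inter.max())

    def test_single_class_flagged(self):
        with pytest.warns(UserWarning):
            rep = benchmark_threshold([AniBenchmarkPair(99.0, 99.0)])
        assert not rep.gap_defined
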