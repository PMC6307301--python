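"""Isolate-to-amplicon recruitment: alignment identity and count tabulation."""

import numpy as np
import pandas as pd
import pytest

from enrichseq._align import semiglobal_align
from enrichseq.io import ConsistencyError, CountMatrix
from enrichseq.recruitment import (
    IsolateSeq,
    pairwise_identity,
    recruit,
    _prefilter_is_lossless,
)

from oracles import dp_identity_oracle


def _random_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


class TestPairwiseIdentity:
    def test_identical_sequences_full_identity(self, rng):
        seq = _random_seq(rng, 500)
        identity, overlap = pairwise_identity(seq, seq)
        assert identity == 1.0
        assert overlap == 500

    def test_single_interior_mismatch(self, rng):
        a = _random_seq(rng, 100)
        pos = 50
        other = next(c for c in "ACGT" if c != a[pos])
        b = a[:pos] + other + a[pos + 1 :]
        identity, overlap = pairwise_identity(a, b)
        assert identity == pytest.approx(0.99)
        assert overlap == 100

    def test_terminal_overhangs_are_free(self, rng):
        core = _random_seq(rng, 300)
        identity, overlap = pairwise_identity("TTTT" + core, core + "GGGG")
        assert identity == 1.0
        assert overlap == 300

    def test_n_never_counts_as_match(self):
        a = "ACGTACGTACGTACGTACGT"
        b = a[:10] + "N" + a[11:]
        identity, overlap = pairwise_identity(a, b)
        assert overlap == 20
        assert identity == pytest.approx(19 / 20)
        # even N against N is not a match
        identity_nn, _ = pairwise_identity(b, b)
        assert identity_nn == pytest.approx(19 / 20)

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            pairwise_identity("", "ACGT")

    def test_matches_independent_dp_oracle(self):
        """50 random 30-nt pairs (unrelated, mutated and indel'd) agree with
        a top-down memoised DP oracle."""
        rng = np.random.default_rng(1234)
        for case in range(50):
            a = _random_seq(rng, 30)
            if case % 2:  # related pair: substitutions, sometimes a deletion
                b = list(a)
                for s in rng.choice(30, size=rng.integers(1, 5), replace=False):
                    b[s] = "ACGT"[rng.integers(0, 4)]
                b = "".join(b)
                if case % 4 == 1:
                    cut = int(rng.integers(0, 28))
                    b = b[:cut] + b[cut + 2 :]
            else:
                b = _random_seq(rng, 30)
            score, matches, columns = semiglobal_align(a, b)
            o_score, o_identity, o_columns = dp_identity_oracle(a, b)
            assert score == o_score
            assert columns == o_columns
            identity = matches / columns if columns else 0.0
            assert identity == pytest.approx(o_identity)

    def test_score_matches_biopython_optimum(self, rng):
        """Optimal score agrees with Biopython's free-end-gap aligner."""
        from Bio import Align

        aligner = Align.PairwiseAligner()
        aligner.mode = "global"
        aligner.match_score = 1
        aligner.mismatch_score = -1
        aligner.open_gap_score = -3
        aligner.extend_gap_score = -1
        aligner.query_end_gap_score = 0
        aligner.target_end_gap_score = 0
        for _ in range(20):
            a = _random_seq(rng, 40)
            b = _random_seq(rng, 35)
            score, _, _ = semiglobal_align(a, b)
            assert score == aligner.score(a, b)

    def test_symmetry(self):
        rng = np.random.default_rng(77)
        for _ in range(25):
            a = _random_seq(rng, 60)
            b = list(a)
            for s in rng.choice(60, size=rng.integers(1, 5), replace=False):
                b[s] = "ACGT"[rng.integers(0, 4)]
            b = "".join(b)[: int(rng.integers(55, 61))]
            assert pairwise_identity(a, b) == pairwise_identity(b, a)


def _feature_setup(rng, n_features=3, length=400):
    features = {f"f{i}": _random_seq(rng, length) for i in range(n_features)}
    counts = pd.DataFrame(
        rng.integers(0, 50, size=(n_features, 2)),
        index=list(features),
        columns=["s1", "s2"],
    )
    return features, CountMatrix(counts)


class TestRecruit:
    def test_exact_match_recovers_printed_abundance(self, rng):
        features, _ = _feature_setup(rng)
        counts = CountMatrix(
            pd.DataFrame(
                {"day0": [0, 3, 7], "day30": [251, 2, 9]}, index=list(features)
            )
        )
        isolate = IsolateSeq("iso", features["f0"])
        profile = recruit(isolate, features, counts)
        assert profile.matched_feature_ids == {"f0"}
        assert profile.counts_per_sample == {"day0": 0, "day30": 251}

    def test_below_threshold_yields_empty_profile(self, rng):
        features, counts = _feature_setup(rng, length=400)
        seq = features["f0"]
        # ~5% divergence: well below the 99% identity gate
        sites = rng.choice(400, size=20, replace=False)
        mutated = list(seq)
        for s in sites:
            mutated[s] = next(c for c in "ACGT" if c != mutated[s])
        profile = recruit(IsolateSeq("iso", "".join(mutated)), features, counts)
        assert profile.matched_feature_ids == set()
        assert all(v == 0 for v in profile.counts_per_sample.values())

    def test_multiple_matches_are_summed(self, rng):
        base = _random_seq(rng, 400)
        variant = base[:200] + ("A" if base[200] != "A" else "C") + base[201:]
        features = {"fa": base, "fb": variant, "fc": _random_seq(rng, 400)}
        counts = CountMatrix(
            pd.DataFrame({"s": [3, 4, 11]}, index=["fa", "fb", "fc"])
        )
        profile = recruit(IsolateSeq("iso", base), features, counts)
        assert profile.matched_feature_ids == {"fa", "fb"}
        assert profile.counts_per_sample["s"] == 7

    def test_id_mismatch_raises(self, rng):
        features, counts = _feature_setup(rng)
        features["extra"] = _random_seq(rng, 400)
        with pytest.raises(ConsistencyError):
            recruit(IsolateSeq("iso", features["f0"]), features, counts)

    def test_monotone_in_identity_threshold(self, rng):
        features, counts = _feature_setup(rng, n_features=5)
        base = features["f0"]
        sites = rng.choice(400, size=3, replace=False)
        seq = list(base)
        for s in sites:
            seq[s] = next(c for c in "ACGT" if c != seq[s])
        isolate = IsolateSeq("iso", "".join(seq))
        previous = None
        for threshold in (0.95, 0.99, 0.995, 1.0):
            profile = recruit(
                isolate, features, counts, min_identity=threshold,
                use_prefilter=False,
            )
            total = sum(profile.counts_per_sample.values())
            if previous is not None:
                assert total <= previous
            previous = total

    def test_prefilter_is_behavior_invisible(self, rng):
        features, counts = _feature_setup(rng, n_features=4)
        seq = list(features["f1"])
        for s in rng.choice(400, size=2, replace=False):
            seq[s] = next(c for c in "ACGT" if c != seq[s])
        isolate = IsolateSeq("iso", "".join(seq))
        with_f = recruit(isolate, features, counts, use_prefilter=True)
        without = recruit(isolate, features, counts, use_prefilter=False)
        assert with_f.matched_feature_ids == without.matched_feature_ids
        assert with_f.counts_per_sample == without.counts_per_sample

    def test_prefilter_guarantee_logic(self):
        assert _prefilter_is_lossless(0.99, 200, 12)
        assert not _prefilter_is_lossless(0.90, 200, 12)

    def test_divergence_sandwich_on_synthetic_sequences(self, rng):
        """Isolates at 0.5% divergence recruit their source taxon; at 3%
        they recruit nothing at the 99% identity gate."""
        from enrichseq.synthetic import generate_sequences

        for divergence, expect_match in ((0.005, True), (0.03, False)):
            refs, isolates, iso_to_taxon = generate_sequences(
                4, seq_length=1000, isolate_divergence=divergence, rng_seed=42
            )
            counts = CountMatrix(
                pd.DataFrame({"s": [5] * len(refs)}, index=list(refs))
            )
            for iso_id, seq in isolates.items():
                profile = recruit(IsolateSeq(iso_id, seq), refs, counts)
                if expect_match:
                    assert profile.matched_feature_ids == {iso_to_taxon[iso_id]}
                else:
                    assert profile.matched_feature_ids == set()


class TestIsolateSeq:
    def test_rejects_short_sequence(self):
        with pytest.raises(ValueError):
            IsolateSeq("iso", "ACGT" * 50)  # 200 nt < 300

    def test_rejects_bad_alphabet(self):
        with pytest.raises(ValueError):
            IsolateSeq("iso", "ACGU" * 100)

    def test_accepts_n_and_lowercase(self):
        iso = IsolateSeq("iso", "acgtn" * 80)
        assert set(iso.sequence) <= set("ACGTN")
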