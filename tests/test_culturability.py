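"""Enrichment and activity ratios, classification boundaries, aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from enrichseq.culturability import (
    activity_ratio,
    aggregate_activity,
    classify_active,
    classify_enrichment,
    enrichment_ratio,
    proportion_active,
)
from enrichseq.io import ConsistencyError, CountMatrix
from enrichseq.recruitment import RecruitmentProfile
from enrichseq.synthetic import SimParams, sample_counts, simulate_dataset
from test_synthetic import TestSampleCounts


class TestRatios:
    @pytest.mark.parametrize(
        "a_t, a_0, expected, enriched",
        [
            (0, 0, 1.0, False),      # pseudocount floor
            (251, 0, 252.0, True),   # bloom from undetected
            (3, 7, 0.5, False),
            (9, 9, 1.0, False),      # boundary is strictly > 1
        ],
    )
    def test_enrichment_ratio_values(self, a_t, a_0, expected, enriched):
        ratio = enrichment_ratio(a_t, a_0)
        assert ratio == pytest.approx(expected)
        assert (ratio > 1.0) is enriched

    @pytest.mark.parametrize(
        "rna, dna, expected, active",
        [
            (0, 0, 1.0, False),
            (10, 4, 2.2, True),
            (5, 5, 1.0, False),
        ],
    )
    def test_activity_ratio_values(self, rna, dna, expected, active):
        ratio = activity_ratio(rna, dna)
        assert ratio == pytest.approx(expected)
        assert classify_active(ratio) is active

    def test_negative_counts_rejected(self):
        with pytest.raises(ValueError):
            enrichment_ratio(-1, 0)
        with pytest.raises(ValueError):
            activity_ratio(0, -1)

    @settings(max_examples=60, derandomize=True)
    @given(
        a=st.integers(min_value=0, max_value=10_000),
        b=st.integers(min_value=0, max_value=10_000),
    )
    def test_enrichment_ratio_monotonicity(self, a, b):
        assert enrichment_ratio(a + 1, b) > enrichment_ratio(a, b)
        assert enrichment_ratio(a, b + 1) < enrichment_ratio(a, b)
        assert activity_ratio(a, a) == 1.0


def _profile(iso, counts):
    return RecruitmentProfile(iso, set(), counts)


def _meta(days, source="s1", molecule="DNA"):
    ids = [f"{source}_d{d}_{molecule}" for d in days]
    return pd.DataFrame(
        {"source": source, "day": days, "molecule": molecule}, index=ids
    )


class TestClassifyEnrichment:
    def test_flat_time_course_is_never_enriched(self):
        sample_meta = _meta([0, 5, 12])
        profiles = [
            _profile("isoA", {"s1_d0_DNA": 4, "s1_d5_DNA": 4, "s1_d12_DNA": 4}),
            _profile("isoB", {"s1_d0_DNA": 0, "s1_d5_DNA": 0, "s1_d12_DNA": 0}),
        ]
        iso_meta = pd.DataFrame(
            {"source": ["s1", "s1"], "isolation_day": [5, 12]},
            index=["isoA", "isoB"],
        )
        records, summary = classify_enrichment(profiles, iso_meta, sample_meta)
        assert summary["frac_not_enriched"] == 1.0
        assert all(r.ratio_t[r.isolation_day] == 1.0 for r in records)

    def test_day0_isolates_excluded_from_fraction(self):
        sample_meta = _meta([0, 5])
        profiles = [
            _profile("direct", {"s1_d0_DNA": 10, "s1_d5_DNA": 1}),
            _profile("late", {"s1_d0_DNA": 1, "s1_d5_DNA": 50}),
        ]
        iso_meta = pd.DataFrame(
            {"source": ["s1", "s1"], "isolation_day": [0, 5]},
            index=["direct", "late"],
        )
        records, summary = classify_enrichment(profiles, iso_meta, sample_meta)
        assert summary["n_species"] == 2
        assert summary["n_isolated_after_enrichment"] == 1
        assert summary["frac_not_enriched"] == 0.0

    def test_missing_day0_sample_raises(self):
        sample_meta = _meta([5, 12])
        profiles = [_profile("iso", {"s1_d5_DNA": 1, "s1_d12_DNA": 2})]
        iso_meta = pd.DataFrame(
            {"source": ["s1"], "isolation_day": [5]}, index=["iso"]
        )
        with pytest.raises(ConsistencyError):
            classify_enrichment(profiles, iso_meta, sample_meta)

    def test_planted_enriched_fraction_recovered_under_deep_sampling(self):
        """30% of taxa double by day 12, the rest halve; with deep multinomial
        sampling the recovered enriched fraction lands within 5 points."""
        rng = np.random.default_rng(42)
        n = 100
        p0 = np.full(n, 1.0 / n)
        p1 = p0 * np.where(np.arange(n) < 30, 2.0, 0.5)
        p1 /= p1.sum()
        depth = 100_000
        c0 = rng.multinomial(depth, p0)
        c1 = rng.multinomial(depth, p1)
        profiles = [
            _profile(f"iso{i}", {"s1_d0_DNA": int(c0[i]), "s1_d12_DNA": int(c1[i])})
            for i in range(n)
        ]
        iso_meta = pd.DataFrame(
            {"source": "s1", "isolation_day": 12}, index=[f"iso{i}" for i in range(n)]
        )
        _, summary = classify_enrichment(profiles, iso_meta, _meta([0, 12]))
        enriched_fraction = 1.0 - summary["frac_not_enriched"]
        assert enriched_fraction == pytest.approx(0.30, abs=0.05)


class TestAggregateActivity:
    def test_otu_rank_reduces_to_per_feature_ratios(self, toy_counts):
        table = aggregate_activity(toy_counts, toy_counts, rank="otu")
        row = table[(table["taxon"] == "f1") & (table["day"] == 0)].iloc[0]
        assert row["ratio"] == pytest.approx(activity_ratio(4, 10))

    def test_family_sum_then_ratio(self):
        counts = pd.DataFrame(
            {"s_d0_DNA": [1, 10], "s_d0_RNA": [5, 0]}, index=["o1", "o2"]
        )
        meta = pd.DataFrame(
            {"source": ["s", "s"], "day": [0, 0], "molecule": ["DNA", "RNA"]},
            index=counts.columns,
        )
        cm = CountMatrix(counts, meta)
        taxonomy = pd.DataFrame(
            {"family": ["FamX", "FamX"]}, index=["o1", "o2"]
        ).reindex(columns=["domain", "phylum", "class", "order", "family",
                           "genus", "species"])
        taxonomy["family"] = ["FamX", "FamX"]
        table = aggregate_activity(cm, cm, taxonomy, rank="family")
        fam = table[table["taxon"] == "FamX"].iloc[0]
        assert fam["ratio"] == pytest.approx((5 + 0 + 1) / (1 + 10 + 1))
        assert not fam["active"]

    def test_aggregation_consistency_with_marginals(self, study_dataset):
        """Sum-then-ratio at family rank equals the ratio of family-summed
        marginal counts, exactly."""
        ds = study_dataset
        table = aggregate_activity(
            ds.counts_rna, ds.counts_dna, ds.taxonomy, rank="family"
        )
        fam = ds.taxonomy["family"]
        rna_marg = ds.counts_rna.counts.groupby(fam).sum()
        dna_marg = ds.counts_dna.counts.groupby(fam).sum()
        sub = table[(table["source"] == "src1") & (table["day"] == 5)]
        for _, row in sub.iterrows():
            expected = (rna_marg.loc[row["taxon"], "src1_d5_RNA"] + 1) / (
                dna_marg.loc[row["taxon"], "src1_d5_DNA"] + 1
            )
            assert row["ratio"] == pytest.approx(expected)

    def test_unpaired_sample_raises(self, toy_counts):
        rna_only = toy_counts.subset_samples(["s1_d0_RNA", "s1_d12_RNA"])
        dna_partial = toy_counts.subset_samples(["s1_d0_DNA"])
        with pytest.raises(ConsistencyError):
            aggregate_activity(rna_only, dna_partial, rank="otu")

    def test_planted_active_order_shows_positive_log_ratio(self, study_dataset):
        """Taxa planted active at a day have median log10 ratio > 0 across
        sources, dormant taxa < 0 (at detectable abundance)."""
        ds = study_dataset
        table = aggregate_activity(ds.counts_rna, ds.counts_dna, rank="otu")
        merged = table.merge(
            ds.truth.true_active.stack().rename("truth"),
            left_on=["taxon", "day"], right_index=True,
        )
        present = merged[(merged["dna"] >= 20)]
        active_med = present[present["truth"]]["log10_ratio"].median()
        dormant_med = present[~present["truth"]]["log10_ratio"].median()
        assert active_med > 0 > dormant_med


class TestProportionActive:
    def test_all_dormant_gives_zero(self):
        table = pd.DataFrame(
            {
                "taxon": list("abc"),
                "source": "s",
                "day": 0,
                "rna": [0, 1, 2],
                "dna": [5, 5, 5],
                "ratio": [1 / 6, 2 / 6, 3 / 6],
                "active": [False] * 3,
            }
        )
        out = proportion_active(table)
        assert (out["proportion_active"] == 0).all()

    def test_simple_fraction(self):
        table = pd.DataFrame(
            {
                "taxon": [f"t{i}" for i in range(12)],
                "source": "s",
                "day": 5,
                "rna": [2] * 12,
                "dna": [1] * 12,
                "ratio": [1.5] * 3 + [0.5] * 9,
                "active": [True] * 3 + [False] * 9,
            }
        )
        out = proportion_active(table)
        assert out["proportion_active"].iloc[0] == pytest.approx(0.25)

    def test_empty_raises(self):
        empty = pd.DataFrame(
            columns=["taxon", "source", "day", "rna", "dna", "ratio", "active"]
        )
        with pytest.raises(ValueError):
            proportion_active(empty)

    def test_shrinking_active_set_yields_decreasing_proportion(self, study_dataset):
        ds = study_dataset
        table = aggregate_activity(ds.counts_rna, ds.counts_dna, rank="otu")
        props = proportion_active(table)
        means = props[props["source"] == "mean"].sort_values("day")
        assert means["proportion_active"].is_monotonic_decreasing


class TestDormantRecovery:
    def test_dormant_taxa_called_not_active_in_95pct_of_runs(self):
        """At >= 1% abundance and depth 10^4, a taxon with activity factor
        0.2 is classified not active in at least 95% of simulations."""
        ids = [f"t{i}" for i in range(50)]
        latent = np.full((50, 1, 1), 0.02)
        factors = np.where(np.arange(50)[:, None] < 25, 4.0, 0.2)
        truth = TestSampleCounts._truth(ids, [0], factors)
        n_runs, correct_dormant, correct_active = 100, 0, 0
        for rep in range(n_runs):
            dna = sample_counts(
                latent, 10_000, "DNA", truth, 31 + rep,
                taxon_ids=ids, source_ids=["s"], days=[0],
            )
            rna = sample_counts(
                latent, 10_000, "RNA", truth, 62_000 + rep,
                taxon_ids=ids, source_ids=["s"], days=[0],
            )
            ratios = (rna.counts["s_d0_RNA"] + 1) / (dna.counts["s_d0_DNA"] + 1)
            correct_dormant += (ratios.iloc[25:] <= 1).all()
            correct_active += (ratios.iloc[:25] > 1).all()
        assert correct_dormant / n_runs >= 0.95
        assert correct_active / n_runs >= 0.95
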