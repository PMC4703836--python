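"""Fold-change preprocessing, CDF/KS statistics and the derepression test."""

import numpy as np
import pytest

from sipivot.enrichment import (
    FoldChangeProfile,
    OffTargetEnrichment,
    bonferroni,
    derepression_binomial,
    empirical_cdf,
    filter_coding,
    ks_two_sample,
    run_enrichment,
    subset_significant,
)
from sipivot.sites import SiteClassAssignment


def profile(entries, name="exp"):
    return FoldChangeProfile(name, entries)


class TestFilterCoding:
    def test_prefix_rule(self):
        p = profile({"NM_0001": {"log2fc": -1.0}, "NR_0002": {"log2fc": -2.0}})
        assert set(filter_coding(p).entries) == {"NM_0001"}

    def test_empty(self):
        assert len(filter_coding(profile({}))) == 0

    def test_counts(self):
        entries = {f"NM_{i:04d}": {"log2fc": 0.0} for i in range(100)}
        entries |= {f"NR_{i:04d}": {"log2fc": 0.0} for i in range(50)}
        assert len(filter_coding(profile(entries))) == 100


class TestSubsetSignificant:
    def test_pvalue_threshold(self):
        p = profile({"a": {"log2fc": 0, "pvalue": 0.04}, "b": {"log2fc": 0, "pvalue": 0.06}})
        assert set(subset_significant(p, 0.05).entries) == {"a"}

    def test_flags_override(self):
        p = profile({"a": {"log2fc": 0, "significant": True},
                     "b": {"log2fc": 0, "significant": True}})
        assert len(subset_significant(p)) == 2

    def test_missing_fields_rejected(self):
        with pytest.raises(ValueError):
            subset_significant(profile({"a": {"log2fc": 0}}))

    def test_uniform_pvalues_retain_about_alpha(self, rng):
        pv = rng.uniform(size=1000)
        p = profile({f"t{i}": {"log2fc": 0.0, "pvalue": float(v)} for i, v in enumerate(pv)})
        kept = len(subset_significant(p, 0.05))
        assert 25 <= kept <= 80  # binomial(1000, 0.05) tolerance


class TestEmpiricalCdf:
    def test_fraction_at_value(self):
        c = empirical_cdf([-2, -1, 0, 1])
        assert c(0) == 0.75

    def test_single_value_step(self):
        c = empirical_cdf([3.0])
        assert c(2.999) == 0.0 and c(3.0) == 1.0

    def test_final_fraction_is_one_and_monotone(self, rng):
        c = empirical_cdf(rng.normal(size=500))
        assert c.fractions[-1] == 1.0
        assert np.all(np.diff(c.fractions) >= 0)

    def test_large_sample_matches_normal_median(self, rng):
        c = empirical_cdf(rng.normal(size=10_000))
        assert abs(c(0.0) - 0.5) < 0.02

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            empirical_cdf([])


class TestKs:
    def test_identical_samples(self):
        d, p = ks_two_sample([1, 2, 3], [1, 2, 3])
        assert d == 0.0 and p == 1.0

    def test_disjoint_supports(self):
        d, _ = ks_two_sample([0, 0, 0, 0], [1, 1, 1, 1])
        assert d == 1.0

    def test_undersized_sample_rejected(self):
        with pytest.raises(ValueError):
            ks_two_sample([1.0], [1, 2, 3])

    def test_power_against_location_shift(self, rng):
        ps = []
        for _ in range(200):
            ps.append(ks_two_sample(rng.normal(0, 1, 50), rng.normal(0.5, 1, 50))[1])
        assert np.median(ps) < 0.05


class TestBonferroni:
    @pytest.mark.parametrize(
        "p,n,expect", [(0.01, 5, 0.05), (0.5, 7, 1.0), (7.4e-5, 7, 5.18e-4)]
    )
    def test_values(self, p, n, expect):
        assert bonferroni(p, n) == pytest.approx(expect)

    def test_invalid_inputs(self):
        with pytest.raises(ValueError):
            bonferroni(1.5, 2)
        with pytest.raises(ValueError):
            bonferroni(0.5, 0)


def make_truth_assignments(n_seed, n_nuc, n_nosite):
    assigns, ids = [], {"Seed": [], "Nuc": [], "NoSite": []}
    i = 0
    for cls, n in (("Seed", n_seed), ("Nuc", n_nuc), ("NoSite", n_nosite)):
        for _ in range(n):
            tid = f"NM_{i:06d}"
            assigns.append(SiteClassAssignment(tid, cls,
                                               int(cls == "Seed"), int(cls == "Nuc")))
            ids[cls].append(tid)
            i += 1
    return assigns, ids


class TestRunEnrichment:
    def test_planted_shift_detected(self, rng):
        assigns, ids = make_truth_assignments(300, 0, 3000)
        entries = {t: {"log2fc": float(rng.normal(-0.4, 0.5))} for t in ids["Seed"]}
        entries |= {t: {"log2fc": float(rng.normal(0, 0.5))} for t in ids["NoSite"]}
        res = {r.site_class: r for r in run_enrichment(profile(entries), assigns)}
        assert res["Seed"].p_raw < 0.01
        assert res["Seed"].median_shift < 0
        assert res["Seed"].p_adjusted >= res["Seed"].p_raw

    def test_all_nosite_not_testable(self):
        assigns, ids = make_truth_assignments(0, 0, 10)
        entries = {t: {"log2fc": 0.1} for t in ids["NoSite"]}
        res = run_enrichment(profile(entries), assigns)
        assert all(not r.testable for r in res)

    def test_invariant_to_ordering_and_concatenation(self, rng):
        assigns, ids = make_truth_assignments(50, 50, 200)
        entries = {
            a.transcript_id: {"log2fc": float(rng.normal(0, 1))} for a in assigns
        }
        p1 = profile(entries, "a")
        shuffled = dict(reversed(list(entries.items())))
        p2 = profile(shuffled, "a")
        r1 = run_enrichment(p1, assigns)
        r2 = run_enrichment(p2, list(reversed(assigns)))
        for a, b in zip(r1, r2):
            assert a == b
        # experiment concatenation order
        r12 = run_enrichment([p1, p2], [assigns, assigns])
        r21 = run_enrichment([p2, p1], [assigns, assigns])
        for a, b in zip(r12, r21):
            assert a.ks_D == pytest.approx(b.ks_D)
            assert a.p_raw == pytest.approx(b.p_raw)

    def test_control_total_uses_all_observations(self, rng):
        assigns, ids = make_truth_assignments(50, 0, 100)
        entries = {a.transcript_id: {"log2fc": float(rng.normal())} for a in assigns}
        res = {r.site_class: r for r in run_enrichment(profile(entries), assigns,
                                                       control="total")}
        assert res["Seed"].n_control == 150

    def test_model_results_summary(self, rng):
        assigns, ids = make_truth_assignments(30, 30, 100)
        entries = {a.transcript_id: {"log2fc": float(rng.normal())} for a in assigns}
        res = OffTargetEnrichment(profile(entries), assigns).fit()
        tab = res.summary()
        assert list(tab["site_class"]) == ["Seed", "Nuc"]
        cdf = res.cdf_frame()
        assert set(cdf["site_class"]) == {"Seed", "Nuc", "NoSite"}
        assert len(cdf) == 160


class TestDerepressionBinomial:
    def test_closed_form_all_restored(self):
        wt = profile(
            {f"t{i}": {"log2fc": -1.0, "significant": True} for i in range(10)}, "wt"
        )
        mod = profile({f"t{i}": {"log2fc": 0.5} for i in range(10)}, "mod")
        n, k, p, shift = derepression_binomial(wt, mod)
        assert (n, k) == (10, 0)
        assert p == pytest.approx(2 * 0.5**10)
        assert shift == pytest.approx(1.5)

    def test_identical_profiles_maximal_asymmetry(self):
        entries = {f"t{i}": {"log2fc": -1.0, "significant": True} for i in range(8)}
        wt = profile(entries, "wt")
        mod = profile({t: {"log2fc": e["log2fc"]} for t, e in entries.items()}, "mod")
        n, k, p, shift = derepression_binomial(wt, mod)
        assert (n, k) == (8, 8)
        assert shift == 0.0

    def test_no_selected_transcripts_rejected(self):
        wt = profile({"t": {"log2fc": 1.0, "significant": True}}, "wt")
        mod = profile({"t": {"log2fc": 1.0}}, "mod")
        with pytest.raises(ValueError):
            derepression_binomial(wt, mod)

    def test_pvalue_fallback_selection(self):
        wt = profile(
            {"a": {"log2fc": -1.0, "pvalue": 0.01}, "b": {"log2fc": -1.0, "pvalue": 0.5}},
            "wt",
        )
        mod = profile({"a": {"log2fc": -0.2}, "b": {"log2fc": -0.2}}, "mod")
        n, k, _, _ = derepression_binomial(wt, mod)
        assert (n, k) == (1, 1)
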