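import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2_contingency

from longmicro.association import (
    association_frame,
    bh_adjust,
    fit_association,
    select_case_control,
    transform_pathway,
    transform_taxon,
    two_proportion_test,
)
from longmicro.simulate import (
    PATHWAY_CASE,
    PATHWAY_NULL,
    CohortConfig,
    generate_cohort,
)


class TestTransforms:
    def test_taxon_closed_forms(self):
        assert transform_taxon(0.0) == 0.0
        assert transform_taxon(1.0) == pytest.approx(np.pi / 2)
        assert transform_taxon(0.25) == pytest.approx(np.pi / 6)

    def test_pathway_closed_forms(self):
        assert transform_pathway(0.0) == 6.0
        assert transform_pathway(64.0) == 7.0
        assert transform_pathway(192.0) == 8.0

    def test_domain_checks(self):
        with pytest.raises(ValueError):
            transform_taxon(1.5)
        with pytest.raises(ValueError):
            transform_pathway(-1.0)

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(st.floats(0, 1, exclude_max=True), st.floats(1e-12, 1))
    def test_transforms_strictly_increasing(self, x, eps):
        hi = min(x + eps, 1.0)
        if hi > x:
            assert transform_taxon(hi) > transform_taxon(x)
        assert transform_pathway(1000 * x + 1) > transform_pathway(1000 * x)


class TestBH:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.04])[0] == pytest.approx(0.04)

    def test_equal_ps_unchanged(self):
        assert np.allclose(bh_adjust([0.2, 0.2, 0.2]), 0.2)

    def test_hand_step_up(self):
        # p = (0.01, 0.02, 0.03), m=3: cummin over p*m/rank from the top
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03]), [0.03, 0.03, 0.03])

    def test_monotone_in_p_rank(self):
        rng = np.random.default_rng(1)
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-15).all()

    def test_reapplication_preserves_order_and_bounds(self):
        rng = np.random.default_rng(2)
        q = bh_adjust(rng.uniform(size=30))
        q2 = bh_adjust(q)
        assert (q2 <= 1).all()
        # order-preserving: re-adjusting never reorders (ties may remain ties)
        order = np.argsort(q, kind="stable")
        assert (np.diff(q2[order]) >= -1e-15).all()

    @settings(deadline=None, max_examples=200, derandomize=True)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 40))
    def test_matches_bruteforce_definition(self, seed, m):
        rng = np.random.default_rng(seed)
        p = rng.uniform(size=m)
        order = np.argsort(p, kind="stable")
        brute = np.empty(m)
        running = 1.0
        for rank in range(m, 0, -1):
            running = min(running, p[order[rank - 1]] * m / rank)
            brute[order[rank - 1]] = running
        assert np.allclose(bh_adjust(p), brute, atol=1e-12)


class TestTwoProportion:
    def test_spec_worked_example(self):
        # 30/40 vs 10/40: Yates statistic 18.05, p ~ 2.2e-5
        stat, p = two_proportion_test(30, 40, 10, 40)
        assert stat == pytest.approx(18.05, abs=1e-10)
        assert p == pytest.approx(2.1518e-5, rel=1e-3)

    def test_equal_proportions_p_one(self):
        _, p = two_proportion_test(10, 20, 10, 20)
        assert p == pytest.approx(1.0)

    def test_degenerate_margins(self):
        _, p = two_proportion_test(0, 10, 0, 10)
        assert p == 1.0

    @settings(deadline=None, max_examples=150, derandomize=True)
    @given(st.integers(0, 2**31 - 1))
    def test_matches_contingency_chi2(self, seed):
        rng = np.random.default_rng(seed)
        n1, n2 = int(rng.integers(2, 200)), int(rng.integers(2, 200))
        k1, k2 = int(rng.integers(0, n1 + 1)), int(rng.integers(0, n2 + 1))
        table = np.array([[k1, n1 - k1], [k2, n2 - k2]])
        if table.sum(axis=0).min() == 0 or table.sum(axis=1).min() == 0:
            return
        for corr in (True, False):
            stat, p = two_proportion_test(k1, n1, k2, n2, correction=corr)
            ref = chi2_contingency(table, correction=corr)
            assert stat == pytest.approx(ref.statistic, abs=1e-10)
            assert p == pytest.approx(ref.pvalue, abs=1e-10)


class TestCaseControlSelection:
    def test_unknown_breastfeeding_pair_excluded(self):
        cfg = CohortConfig(n_subjects=60, max_age_days=240,
                           unknown_breastfeeding_prob=0.3, seed=9)
        records, _, _, _ = generate_cohort(cfg)
        kept = select_case_control(records, "IA")
        assert all(r.breastfeeding_known for r in kept)
        # partners of unknown-status subjects are gone too
        bad_pairs = {r.pair_id for r in records
                     if not r.breastfeeding_known and r.pair_id}
        assert not any(r.pair_id in bad_pairs for r in kept)

    def test_other_endpoint_pairs_excluded(self):
        cfg = CohortConfig(n_subjects=60, max_age_days=240, seed=10)
        records, _, _, _ = generate_cohort(cfg)
        kept = select_case_control(records, "T1D")
        assert {r.outcome for r in kept} <= {"control", "T1D"}
        pair_outcomes = {}
        for r in kept:
            pair_outcomes.setdefault(r.pair_id, set()).add(r.outcome)
        assert all({"control", "T1D"} == o for o in pair_outcomes.values())


class TestFitAssociation:
    def test_planted_pathway_minimises_q(self):
        cfg = CohortConfig(n_subjects=100, max_age_days=365, seed=42)
        records, _, table, truth = generate_cohort(cfg)
        feats = [PATHWAY_CASE] + PATHWAY_NULL
        res = fit_association(table.community[feats], records, cohort="IA")
        frame = association_frame(res)
        best = frame.loc[frame["q"].idxmin(), "feature_id"]
        assert best == truth.case_effect_feature
        planted = frame[frame.feature_id == PATHWAY_CASE].iloc[0]
        # effect was planted as a positive control shift, so the case
        # coefficient is near -case_effect on the log2 scale
        assert planted.coefficient == pytest.approx(-cfg.case_effect, abs=0.35)
        assert planted.reportable

    def test_constant_feature_skipped(self):
        cfg = CohortConfig(n_subjects=40, max_age_days=240, seed=43)
        records, _, table, _ = generate_cohort(cfg)
        X = table.community[[PATHWAY_CASE]].copy()
        X["FLAT"] = 123.0
        res = fit_association(X, records, cohort="IA")
        assert "FLAT" not in {r.feature_id for r in res}

    def test_low_prevalence_feature_filtered(self):
        cfg = CohortConfig(n_subjects=40, max_age_days=240, seed=44)
        records, _, table, _ = generate_cohort(cfg)
        X = table.community[[PATHWAY_CASE]].copy()
        rare = np.zeros(len(X))
        rare[:3] = 50.0
        X["RARE"] = rare
        res = fit_association(X, records, cohort="IA", prevalence_min=0.10)
        assert "RARE" not in {r.feature_id for r in res}

    def test_per_centre_scope_drops_centre_term(self):
        cfg = CohortConfig(n_subjects=60, max_age_days=300, seed=45)
        records, _, table, _ = generate_cohort(cfg)
        centre = records[0].centre
        recs = [r for r in records if r.centre == centre]
        ids = [r.sample_id for r in recs]
        res = fit_association(
            table.community.loc[ids, [PATHWAY_CASE]], recs,
            cohort="IA", scope="per-centre",
        )
        assert res and res[0].centre_scope.startswith("per_centre")
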