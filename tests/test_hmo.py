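import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from longmicro.hmo import (
    PRESENCE_CPM,
    call_presence,
    carriage_heatmap_table,
    differential_prevalence,
    filter_hits,
)
from longmicro.io import HomologyHit, read_homology_hits
from longmicro.simulate import (
    CohortConfig,
    generate_cohort,
    generate_homology_hits,
)
from longmicro.io import write_homology_hits


def _hit(fam="G1", sp="B_longum", ident=60.0, cq=0.9, cs=0.9):
    return HomologyHit(
        query_id="q", gene_family_id=fam, carrier_species=sp,
        pct_identity=ident, coverage_query=cq, coverage_subject=cs,
    )


class TestFilterHits:
    def test_inclusive_boundaries_kept(self):
        assert filter_hits([_hit(ident=50.0, cq=0.80, cs=0.80)]) != []

    def test_below_identity_dropped(self):
        assert filter_hits([_hit(ident=49.9)]) == []

    def test_one_sided_coverage_insufficient(self):
        # mutual coverage: both sides must pass
        assert filter_hits([_hit(cq=0.9, cs=0.7)]) == []

    def test_duplicates_keep_best_identity(self):
        kept = filter_hits([_hit(ident=60.0), _hit(ident=70.0)])
        assert len(kept) == 1 and kept[0].pct_identity == 70.0

    @settings(deadline=None, max_examples=100, derandomize=True)
    @given(
        st.floats(0, 100), st.floats(0, 1),
        st.integers(0, 2**31 - 1),
    )
    def test_tightening_thresholds_monotone(self, ident_thr, cov_thr, seed):
        rng = np.random.default_rng(seed)
        hits = [
            _hit(fam=f"G{i}", ident=rng.uniform(0, 100),
                 cq=rng.uniform(0, 1), cs=rng.uniform(0, 1))
            for i in range(25)
        ]
        loose = len(filter_hits(hits, min_identity=ident_thr / 2,
                                min_coverage=cov_thr / 2))
        tight = len(filter_hits(hits, min_identity=ident_thr,
                                min_coverage=cov_thr))
        assert tight <= loose


class TestPresence:
    def test_threshold_is_strict(self, tiny_cohort):
        _, records, _, table, _ = tiny_cohort
        t = table.stratified.copy()
        gene = ("UniRef90_HMO0000", "Bifidobacterium_longum")
        t[gene] = PRESENCE_CPM  # exactly 10^0.1
        table2 = type(table)(table.community, t, table.tokens)
        calls, _ = call_presence(table2, [_hit(*gene)], records,
                                 min_breastfed_samples=1)
        assert not calls["present"].any()
        t[gene] = 1.26  # just above
        calls2, _ = call_presence(
            type(table)(table.community, t, table.tokens),
            [_hit(*gene)], records, min_breastfed_samples=1,
        )
        assert calls2["present"].all()

    def test_eligibility_count_matches_hand_count(self, tiny_cohort):
        _, records, tax, table, _ = tiny_cohort
        gene = ("UniRef90_HMO0000", "Bifidobacterium_longum")
        calls, eligible = call_presence(table, [_hit(*gene)], records,
                                        min_breastfed_samples=5)
        by_id = {r.sample_id: r for r in records}
        hand = sum(
            bool(row.present)
            and by_id[row.sample_id].breastfeeding is True
            for row in calls.itertuples(index=False)
        )
        assert (gene in eligible) == (hand >= 5)

    def test_unquantified_gene_never_present(self, tiny_cohort):
        _, records, _, table, _ = tiny_cohort
        calls, eligible = call_presence(
            table, [_hit("UniRef90_NOPE", "Enterococcus_faecalis")], records,
            min_breastfed_samples=1,
        )
        assert not calls["present"].any() and eligible == []


class TestDifferentialPrevalence:
    def test_recovers_planted_contrast_on_cohort(self):
        cfg = CohortConfig(n_subjects=80, max_age_days=365, seed=17)
        records, tax, table, truth = generate_cohort(cfg)
        hits = [
            _hit(g, cfg.hmo_carrier_species) for g in cfg.hmo_genes
        ]
        calls, eligible = call_presence(table, hits, records,
                                        min_breastfed_samples=20)
        res = differential_prevalence(calls, eligible, tax, records)
        flagged = {r.gene_family_id for r in res if r.significant}
        assert flagged == set(truth.planted_hmo_genes)
        for r in res:
            assert r.p_adj >= r.p_raw
            assert r.prev_bf == pytest.approx(r.k_bf / r.n_bf)

    def test_empty_group_skipped(self, tiny_cohort):
        _, records, tax, table, _ = tiny_cohort
        # force everyone breastfeeding: the weaned group is empty
        recs = [r for r in records]
        for r in recs:
            r.breastfeeding = True
            r.weaned_age_days = 10**6
        gene = ("UniRef90_HMO0000", "Bifidobacterium_longum")
        calls, _ = call_presence(table, [_hit(*gene)], recs,
                                 min_breastfed_samples=1)
        res = differential_prevalence(calls, [gene], tax, recs)
        assert res == []


class TestHeatmap:
    def test_normalisation_by_carrier_fraction(self, tiny_cohort):
        cfg, records, tax, table, _ = tiny_cohort
        genes = cfg.hmo_genes[:3]
        hm = carriage_heatmap_table(table, tax, genes, min_species_abund=10.0)
        sample = hm.columns[0]
        gene = hm.index[0]
        frac = tax.data.loc[sample, "Bifidobacterium_longum"] / 100.0
        raw = table.stratified.loc[sample, (gene, "Bifidobacterium_longum")]
        assert hm.loc[gene, sample] == pytest.approx(raw / frac, rel=1e-12)

    def test_clustering_order_deterministic(self, tiny_cohort):
        cfg, records, tax, table, _ = tiny_cohort
        genes = cfg.hmo_genes
        h1 = carriage_heatmap_table(table, tax, genes)
        h2 = carriage_heatmap_table(table, tax, genes)
        assert list(h1.index) == list(h2.index)
        assert list(h1.columns) == list(h2.columns)

    def test_no_qualifying_sample_raises(self, tiny_cohort):
        cfg, records, tax, table, _ = tiny_cohort
        with pytest.raises(ValueError):
            carriage_heatmap_table(table, tax, cfg.hmo_genes,
                                   min_species_abund=100.0)


def test_synthetic_hits_table_round_trips_and_filters(tmp_path):
    cfg = CohortConfig(n_subjects=4, max_age_days=200, seed=5)
    df = generate_homology_hits(cfg)
    p = tmp_path / "hits.tsv"
    write_homology_hits(df, p)
    hits = read_homology_hits(p)
    kept = filter_hits(hits)
    fams = {h.gene_family_id for h in kept}
    assert set(cfg.hmo_genes) <= fams
    assert not any(f.startswith("UniRef90_DECOY") for f in fams)
    # the duplicate carrier-species hit collapses to one record per gene
    assert (
        sum(1 for h in kept if h.gene_family_id == cfg.hmo_genes[0]
            and h.carrier_species == cfg.hmo_carrier_species) == 1
    )
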