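"""Strain-level human-milk-oligosaccharide (HMO) gene-carriage analysis.

Specialised *Bifidobacterium longum* strains carry a cluster of HMO
utilisation genes; their presence in a metagenome marks milk-adapted strain
carriage. The pipeline stages are:

1. filter translated-search homology hits to >=50% alignment identity and
   >=80% *mutual* coverage (both query and subject sides),
2. call a gene present in a sample when its species-stratified abundance
   satisfies log10(CPM) > 0.1, keeping genes detectable in at least 50
   breastfeeding samples (configurable floor for small data sets),
3. compare gene prevalence between samples collected during breastfeeding
   and after weaning - restricted to samples where the carrier species
   itself exceeds 1% relative abundance - with a continuity-corrected
   two-sample proportion test and BH adjustment across genes.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import pdist

from .association import bh_adjust, two_proportion_test
from .io import HomologyHit, SampleRecord, StratifiedTable, TaxProfile

logger = logging.getLogger("longmicro.hmo")

#: presence threshold: log10(CPM) strictly greater than 0.1
PRESENCE_LOG10_CPM = 0.1
PRESENCE_CPM = 10.0 ** PRESENCE_LOG10_CPM


def filter_hits(
    hits: list[HomologyHit],
    min_identity: float = 50.0,
    min_coverage: float = 0.8,
) -> list[HomologyHit]:
    """Hits with identity >= ``min_identity`` and both coverages >= ``min_coverage``.

    Bounds are inclusive. (gene family, carrier species) duplicates collapse
    to the best-identity hit.
    """
    best: dict[tuple[str, str], HomologyHit] = {}
    for h in hits:
        if h.pct_identity < min_identity:
            continue
        if h.coverage_query < min_coverage or h.coverage_subject < min_coverage:
            continue
        key = (h.gene_family_id, h.carrier_species)
        if key not in best or h.pct_identity > best[key].pct_identity:
            best[key] = h
    return list(best.values())


@dataclass
class PresenceCall:
    sample_id: str
    gene_family_id: str
    carrier_species: str
    cpm: float
    present: bool


def _is_breastfeeding(r: SampleRecord) -> bool | None:
    """Sample feeding state: True during breastfeeding, False after weaning,
    None when the subject's status is unknown."""
    if not r.breastfeeding_known:
        return None
    if r.breastfeeding:
        return True
    if r.weaned_age_days is not None and r.age_days >= r.weaned_age_days:
        return False
    return None  # not breastfeeding yet unweaned: contradictory, exclude


def call_presence(
    table: StratifiedTable,
    hits: list[HomologyHit],
    records: list[SampleRecord],
    min_breastfed_samples: int = 50,
) -> tuple[pd.DataFrame, list[tuple[str, str]]]:
    """Per-sample presence calls plus the genes eligible for testing.

    A (gene, carrier species) pair is eligible when it is present in at
    least ``min_breastfed_samples`` samples collected during breastfeeding.
    Returns a frame of :class:`PresenceCall` rows and the eligible pairs.
    """
    state_by_sample = {r.sample_id: _is_breastfeeding(r) for r in records}
    strat = table.stratified
    bf_mask = np.array(
        [state_by_sample.get(s) is True for s in strat.index], dtype=bool
    )
    frames = []
    eligible = []
    for h in hits:
        key = (h.gene_family_id, h.carrier_species)
        if key in strat.columns:
            cpm = strat[key].to_numpy(dtype=float)
        else:
            cpm = np.zeros(len(strat.index))
        present = cpm > PRESENCE_CPM
        if int((present & bf_mask).sum()) >= min_breastfed_samples:
            eligible.append(key)
        frames.append(
            pd.DataFrame(
                {
                    "sample_id": list(strat.index),
                    "gene_family_id": h.gene_family_id,
                    "carrier_species": h.carrier_species,
                    "cpm": cpm,
                    "present": present,
                }
            )
        )
    calls = (
        pd.concat(frames, ignore_index=True)
        if frames
        else pd.DataFrame(
            columns=["sample_id", "gene_family_id", "carrier_species", "cpm", "present"]
        )
    )
    return calls, eligible


@dataclass
class PrevalenceTest:
    gene_family_id: str
    carrier_species: str
    n_bf: int
    k_bf: int
    n_wean: int
    k_wean: int
    prev_bf: float
    prev_wean: float
    p_raw: float
    p_adj: float
    significant: bool


def differential_prevalence(
    calls: pd.DataFrame,
    eligible: list[tuple[str, str]],
    tax: TaxProfile,
    records: list[SampleRecord],
    min_species_abund: float = 1.0,
    correction: bool = True,
    alpha: float = 0.001,
) -> list[PrevalenceTest]:
    """Test each eligible gene for breastfeeding-contrasted prevalence.

    Denominators are the samples in which the carrier species exceeds
    ``min_species_abund`` percent relative abundance and the feeding state is
    known; the proportion compared is the fraction of those samples carrying
    the gene. P-values come from the (Yates-corrected by default)
    two-proportion test, BH-adjusted across all tested genes; genes are
    flagged significant at ``p_adj < alpha``.
    """
    state_by_sample = {
        r.sample_id: _is_breastfeeding(r) for r in records
    }
    results: list[PrevalenceTest] = []
    for gene, species in eligible:
        sub = calls[
            (calls["gene_family_id"] == gene)
            & (calls["carrier_species"] == species)
        ]
        if species in tax.data.columns:
            abund = tax.data[species].reindex(sub["sample_id"]).to_numpy()
        else:
            abund = np.zeros(len(sub))
        state = np.array(
            [state_by_sample.get(s) for s in sub["sample_id"]], dtype=object
        )
        usable = (abund > min_species_abund) & (state != None)  # noqa: E711
        present = sub["present"].to_numpy()[usable]
        is_bf = state[usable].astype(bool)
        n = {True: int(is_bf.sum()), False: int((~is_bf).sum())}
        k = {
            True: int(present[is_bf].sum()),
            False: int(present[~is_bf].sum()),
        }
        if n[True] == 0 or n[False] == 0:
            logger.info(
                "gene %s|%s skipped: empty group (bf n=%d, weaned n=%d)",
                gene, species, n[True], n[False],
            )
            continue
        _, p = two_proportion_test(k[True], n[True], k[False], n[False], correction)
        results.append(
            PrevalenceTest(
                gene_family_id=gene,
                carrier_species=species,
                n_bf=n[True],
                k_bf=k[True],
                n_wean=n[False],
                k_wean=k[False],
                prev_bf=k[True] / n[True],
                prev_wean=k[False] / n[False],
                p_raw=p,
                p_adj=float("nan"),
                significant=False,
            )
        )
    if results:
        q = bh_adjust(np.array([r.p_raw for r in results]))
        for r, qi in zip(results, q):
            r.p_adj = float(qi)
            r.significant = bool(qi < alpha)
    return results


def prevalence_frame(results: list[PrevalenceTest]) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in results])


def carriage_heatmap_table(
    table: StratifiedTable,
    tax: TaxProfile,
    genes: list[str],
    species: str = "Bifidobacterium_longum",
    min_species_abund: float = 10.0,
) -> pd.DataFrame:
    """Gene x sample matrix of carrier-normalised abundances for display.

    Columns are samples where the carrier species exceeds
    ``min_species_abund`` percent; each gene's CPM is divided by the carrier
    species' relative-abundance fraction so values are comparable between
    samples. Rows and columns order by complete-linkage hierarchical
    clustering of Euclidean distance on log10(1 + x).
    """
    frac = tax.data[species] / 100.0
    samples = [
        s
        for s in table.stratified.index
        if s in frac.index and tax.data.loc[s, species] > min_species_abund
    ]
    if not samples:
        raise ValueError("no samples pass the carrier-abundance filter")
    cols = [(g, species) for g in genes if (g, species) in table.stratified.columns]
    mat = table.stratified.loc[samples, cols]
    mat.columns = [g for g, _ in cols]
    norm = mat.div(frac.loc[samples], axis=0).T  # genes x samples

    logx = np.log10(1.0 + norm.to_numpy())

    def order(m):
        if m.shape[0] < 3:
            return list(range(m.shape[0]))
        return list(leaves_list(linkage(pdist(m, metric="euclidean"),
                                        method="complete")))

    row_order = order(logx)
    col_order = order(logx.T)
    return norm.iloc[row_order, col_order]
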