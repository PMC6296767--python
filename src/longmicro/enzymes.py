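"""Ranking enzyme families by the consistency of within-subject change
between two ages, and species-stratified contribution matrices.

"Consistency" is operationalised as the sign-consistency score: with one
community-total abundance per subject at each of two target ages,

    score = (n_up - n_down) / n_subjects,

where a subject counts as "up" only when its later-minus-earlier difference
is strictly positive (exact zeros count in neither direction). The score
lies in [-1, 1]; ties in the top-k rankings break by |median difference|
descending, then feature id.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from scipy.spatial.distance import squareform
from scipy.stats import spearmanr

from .io import SampleRecord, StratifiedTable, UNCLASSIFIED


def closest_sample_per_subject(
    records: list[SampleRecord], target_age_days: int, tol_days: int = 45
) -> dict[str, str]:
    """Map subject -> sample id of the collection closest to ``target_age_days``.

    Ties in distance resolve to the earlier sample; subjects with no sample
    within ``tol_days`` are excluded.
    """
    best: dict[str, tuple[int, int, str]] = {}
    for r in sorted(records, key=lambda r: (r.subject_id, r.age_days, r.sample_id)):
        dist = abs(r.age_days - target_age_days)
        if dist > tol_days:
            continue
        key = (dist, r.age_days)
        if r.subject_id not in best or key < best[r.subject_id][:2]:
            best[r.subject_id] = (dist, r.age_days, r.sample_id)
    return {subj: sid for subj, (_, _, sid) in best.items()}


def subject_timepoint_abundance(
    table: StratifiedTable,
    records: list[SampleRecord],
    target_age_days: int,
    tol_days: int = 45,
) -> pd.DataFrame:
    """Subject x feature community-total CPM at the sample closest to a target age."""
    chosen = closest_sample_per_subject(records, target_age_days, tol_days)
    chosen = {s: sid for s, sid in chosen.items() if sid in table.community.index}
    out = table.community.loc[list(chosen.values())].copy()
    out.index = list(chosen.keys())
    out.index.name = "subject_id"
    return out.sort_index()


@dataclass
class ConsistencyScore:
    feature_id: str
    n_subjects: int
    n_up: int
    n_down: int
    score: float
    median_delta: float


def consistency_scores(m3: pd.DataFrame, y1: pd.DataFrame) -> pd.DataFrame:
    """Sign-consistency score per feature over the shared subjects."""
    subjects = m3.index.intersection(y1.index)
    if len(subjects) == 0:
        raise ValueError("no shared subjects between the two timepoints")
    features = [f for f in m3.columns if f in y1.columns]
    delta = y1.loc[subjects, features] - m3.loc[subjects, features]
    n = len(subjects)
    n_up = (delta > 0).sum(axis=0)
    n_down = (delta < 0).sum(axis=0)
    return pd.DataFrame(
        {
            "feature_id": features,
            "n_subjects": n,
            "n_up": n_up.to_numpy(),
            "n_down": n_down.to_numpy(),
            "score": ((n_up - n_down) / n).to_numpy(),
            "median_delta": delta.median(axis=0).to_numpy(),
        }
    ).reset_index(drop=True)


def consistency_ranking(
    m3: pd.DataFrame, y1: pd.DataFrame, top_k: int = 20
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Top-k most consistent increases and decreases between two timepoints."""
    scores = consistency_scores(m3, y1)
    scores["abs_median_delta"] = scores["median_delta"].abs()
    inc = scores.sort_values(
        ["score", "abs_median_delta", "feature_id"],
        ascending=[False, False, True],
    ).head(top_k)
    dec = scores.sort_values(
        ["score", "abs_median_delta", "feature_id"],
        ascending=[True, False, True],
    ).head(top_k)
    cols = ["feature_id", "n_subjects", "n_up", "n_down", "score", "median_delta"]
    return inc[cols].reset_index(drop=True), dec[cols].reset_index(drop=True)


@dataclass
class ContributionMatrix:
    """Mean species contribution (CPM) per feature at one timepoint.

    ``data`` rows are features, columns the top contributing species plus an
    ``other`` pool; row/column orders come from hierarchical clustering of
    rank-correlation distance and can be imposed from an earlier timepoint.
    """

    data: pd.DataFrame
    feature_order: list[str]
    species_order: list[str]

    def ordered(self) -> pd.DataFrame:
        return self.data.loc[self.feature_order, self.species_order]


def _cluster_order(frame: pd.DataFrame, axis: int) -> list[str]:
    mat = frame.to_numpy() if axis == 0 else frame.to_numpy().T
    labels = list(frame.index if axis == 0 else frame.columns)
    if len(labels) < 3:
        return labels
    rho = spearmanr(mat, axis=1).statistic
    rho = np.atleast_2d(rho)
    dist = 1.0 - np.nan_to_num(rho, nan=0.0)
    np.fill_diagonal(dist, 0.0)
    dist = np.clip((dist + dist.T) / 2.0, 0.0, None)
    order = leaves_list(linkage(squareform(dist, checks=False), method="average"))
    return [labels[i] for i in order]


def contribution_matrix(
    table: StratifiedTable,
    records: list[SampleRecord],
    features: list[str],
    age_days: int,
    top_species: int = 15,
    tol_days: int = 45,
    order_from: "ContributionMatrix | None" = None,
) -> ContributionMatrix:
    """Mean stratified CPM per (feature, species) over one timepoint's samples.

    Species rank by their total contribution across the selected features;
    the top ``top_species`` are kept and the remainder (including
    unclassified mass) pools into ``other``, so per-feature contributions
    still sum to the community mean. Orders come from clustering at this
    timepoint unless ``order_from`` imposes an earlier timepoint's orders.
    """
    chosen = closest_sample_per_subject(records, age_days, tol_days)
    sample_ids = [s for s in chosen.values() if s in table.stratified.index]
    if not sample_ids:
        raise ValueError("no samples at the requested timepoint")
    strat = table.stratified.loc[sample_ids]
    comm = table.community.loc[sample_ids]

    present = set(strat.columns.get_level_values(0))
    feats = list(dict.fromkeys(f for f in features if f in present))
    mean_by = {}
    for f in feats:
        mean_by[f] = strat[f].mean(axis=0)  # species -> mean CPM
    wide = pd.DataFrame(mean_by).T.fillna(0.0)  # features x species
    wide.index.name = "feature"
    named = [s for s in wide.columns if s != UNCLASSIFIED]
    totals = wide[named].sum(axis=0).sort_values(ascending=False)
    top = list(totals.index[:top_species])
    rest = [s for s in wide.columns if s not in top]

    out = wide[top].copy()
    comm_mean = comm.reindex(columns=feats).mean(axis=0)
    # pool the remainder against the community mean so rows stay additive
    out["other"] = comm_mean.loc[out.index] - out.sum(axis=1)
    out["other"] = out["other"].clip(lower=0.0)
    if rest:
        pass  # anything not in `top` is inside `other` by construction

    if order_from is not None:
        feature_order = [f for f in order_from.feature_order if f in out.index]
        feature_order += [f for f in out.index if f not in feature_order]
        species_order = [s for s in order_from.species_order if s in out.columns]
        species_order += [s for s in out.columns if s not in species_order]
    else:
        feature_order = _cluster_order(out, axis=0)
        cols = [c for c in out.columns if c != "other"]
        species_order = _cluster_order(out[cols], axis=1) + ["other"]
    return ContributionMatrix(out, feature_order, species_order)


def contribution_long_table(cm: ContributionMatrix) -> pd.DataFrame:
    """Heat-map-ready long-format (feature, species, mean_cpm) frame."""
    df = cm.ordered().stack().rename("mean_cpm").reset_index()
    df.columns = ["feature_id", "species", "mean_cpm"]
    return df
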