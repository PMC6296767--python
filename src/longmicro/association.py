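"""Case-control association of microbial features, plus shared statistics.

Features enter after a variance-stabilising transform: taxa as
arcsin(sqrt(relative abundance)) on the fraction scale, pathways as
log2(CPM + 2^6). Each feature is then fitted with a linear mixed model -
subject random intercept; age, delivery mode, clinical centre (cohort-wide
runs only), breastfeeding status, solid-food status, log10 sequencing reads
and case-control outcome as fixed effects - and the per-feature outcome
p-values are Benjamini-Hochberg adjusted within the run. Features with
q < 0.25 are flagged reportable.

The module also hosts the shared primitives used elsewhere in the pipeline:
the BH step-up adjustment and the two-sample proportion test with optional
Yates continuity correction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2

from .io import SampleRecord, records_to_frame

logger = logging.getLogger("longmicro.association")

PSEUDOCOUNT_CPM = 2.0 ** 6


def transform_taxon(relabund):
    """Arcsin-square-root transform of relative abundance on the [0, 1] scale."""
    x = np.asarray(relabund, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("taxon abundances must be fractions in [0, 1]")
    return np.arcsin(np.sqrt(x))


def transform_pathway(cpm, pseudocount: float = PSEUDOCOUNT_CPM):
    """log2(CPM + pseudocount); the 2^6 pseudocount stabilises sparse pathways."""
    x = np.asarray(cpm, dtype=float)
    if np.any(x < 0):
        raise ValueError("CPM values must be nonnegative")
    return np.log2(x + pseudocount)


def bh_adjust(p) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values).

    q_(i) = min_{j >= i} min(1, p_(j) * m / j) in the sort order of p.
    """
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a vector")
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = len(p)
    if m == 0:
        return p.copy()
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum(1.0, np.minimum.accumulate(ranked[::-1])[::-1])
    q = np.empty(m)
    q[order] = q_sorted
    return q


def two_proportion_test(
    k1: int, n1: int, k2: int, n2: int, correction: bool = True
) -> tuple[float, float]:
    """Chi-squared test of equal proportions on a 2x2 table.

    With ``correction`` (the default, mirroring the classical R behaviour)
    the Yates-corrected statistic

        X^2 = n (|ad - bc| - n/2)^2 / ((a+b)(c+d)(a+c)(b+d))

    is used, with the correction capped so it cannot overshoot zero.
    Returns ``(statistic, two-sided p)``; degenerate margins give p = 1.
    """
    if not (0 <= k1 <= n1 and 0 <= k2 <= n2):
        raise ValueError("need 0 <= k <= n in both groups")
    a, b = float(k1), float(n1 - k1)
    c, d = float(k2), float(n2 - k2)
    n = a + b + c + d
    denom = (a + b) * (c + d) * (a + c) * (b + d)
    if denom == 0 or n == 0:
        return 0.0, 1.0
    diff = abs(a * d - b * c)
    if correction:
        diff = max(0.0, diff - n / 2.0)
    stat = n * diff ** 2 / denom
    return float(stat), float(chi2.sf(stat, df=1))


# ---------------------------------------------------------------------------
# mixed-model association
# ---------------------------------------------------------------------------


@dataclass
class AssociationResult:
    feature_id: str
    feature_type: str
    coefficient: float
    std_error: float
    p_raw: float
    q: float
    n_obs: int
    n_subjects: int
    centre_scope: str
    reportable: bool


def select_case_control(
    records: list[SampleRecord], cohort: str = "IA"
) -> list[SampleRecord]:
    """Samples entering a case-control run for one end point.

    Keeps controls and the chosen end point's cases; drops subjects with
    unknown breastfeeding together with their matched pairs (unknown feeding
    status would confound every model), and drops pairs without a valid
    control member (the stand-in for pairs whose control later progressed).
    """
    if cohort not in {"IA", "T1D"}:
        raise ValueError("cohort must be 'IA' or 'T1D'")
    keep_outcomes = {"control", cohort}
    recs = [r for r in records if r.outcome in keep_outcomes]

    bad_pairs = {
        r.pair_id for r in recs if r.pair_id and not r.breastfeeding_known
    }
    bad_subjects = {r.subject_id for r in recs if not r.breastfeeding_known}

    by_pair: dict[str, set[str]] = {}
    for r in recs:
        if r.pair_id:
            by_pair.setdefault(r.pair_id, set()).add(r.outcome)
    for pid, outcomes in by_pair.items():
        if "control" not in outcomes or cohort not in outcomes:
            bad_pairs.add(pid)

    return [
        r
        for r in recs
        if r.subject_id not in bad_subjects and (r.pair_id or "") not in bad_pairs
    ]


def fit_association(
    features: pd.DataFrame,
    records: list[SampleRecord],
    feature_type: str = "pathway",
    cohort: str = "IA",
    scope: str = "cohort",
    prevalence_min: float = 0.10,
    q_threshold: float = 0.25,
    transform: bool = True,
) -> list[AssociationResult]:
    """Per-feature subject random-intercept models of case-control outcome.

    ``features`` is samples x features on the raw scale: percent relative
    abundance for ``feature_type='taxon'``, CPM for ``'pathway'``. Features
    nonzero in fewer than ``prevalence_min`` of the analysed samples are
    skipped, as are zero-variance features. ``scope='cohort'`` keeps the
    clinical-centre fixed effect; per-centre runs drop it.
    """
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    recs = select_case_control(records, cohort)
    meta = records_to_frame(recs)
    ids = [s for s in features.index if s in meta.index]
    if not ids:
        raise ValueError("no analysable samples after case-control selection")
    meta = meta.loc[ids].copy()
    X = features.loc[ids]
    meta["case"] = (meta["outcome"] != "control").astype(int)
    meta["breastfeeding"] = meta["breastfeeding"].astype(bool)
    meta["age_years"] = meta["age_days"] / 365.0

    fixed = ["age_years", "C(delivery_mode)", "breastfeeding", "solid_food",
             "log10_reads", "case"]
    if scope == "cohort" and meta["centre"].nunique() > 1:
        fixed.insert(2, "C(centre)")
    formula_rhs = " + ".join(fixed)

    results = []
    pvals = []
    for feat in X.columns:
        raw = X[feat].to_numpy(dtype=float)
        prevalence = float((raw > 0).mean())
        if prevalence < prevalence_min:
            logger.info("feature %s below prevalence filter (%.2f)", feat, prevalence)
            continue
        if transform:
            vals = (
                transform_taxon(raw / 100.0)
                if feature_type == "taxon"
                else transform_pathway(raw)
            )
        else:
            vals = raw
        if np.isclose(np.var(vals), 0.0):
            logger.info("feature %s has zero variance; skipped", feat)
            continue
        df = meta.copy()
        df["y"] = vals
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            fit = smf.mixedlm(
                "y ~ " + formula_rhs, df, groups=df["subject_id"]
            ).fit(reml=True)
        coef = float(fit.fe_params["case"])
        se = float(fit.bse_fe["case"])
        p = float(fit.pvalues["case"])
        results.append(
            AssociationResult(
                feature_id=str(feat),
                feature_type=feature_type,
                coefficient=coef,
                std_error=se,
                p_raw=p,
                q=float("nan"),
                n_obs=int(len(df)),
                n_subjects=int(df["subject_id"].nunique()),
                centre_scope="cohort_wide" if scope == "cohort"
                else f"per_centre:{meta['centre'].iloc[0]}",
                reportable=False,
            )
        )
        pvals.append(p)

    if results:
        qs = bh_adjust(np.array(pvals))
        for r, q in zip(results, qs):
            r.q = float(q)
            r.reportable = bool(q < q_threshold)
    return results


def association_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Tidy frame of association results (Supplementary-Table-style columns)."""
    return pd.DataFrame([r.__dict__ for r in results])
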