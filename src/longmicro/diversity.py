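"""Alpha/beta diversity, dominance classification, stability windows and
single-term PERMANOVA.

The stability analysis follows the design of the longitudinal comparison it
reimplements: Bray-Curtis dissimilarities of all sample pairs co-occurring in
three-month age windows advanced in two-month increments, stratified into
within-subject, within-centre and between-centre pairs, summarised by the
median and a seeded percentile-bootstrap 99% confidence interval.

PERMANOVA is the single-term partition of the squared-dissimilarity sums of
squares (the adonis decomposition), with significance from label
permutations; an optional ``strata`` argument restricts permutations within
blocks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .io import SampleRecord

#: the four mutually exclusive early-life dominance targets
DOMINANCE_TAXA = (
    "Bifidobacterium_longum",
    "Bifidobacterium_breve",
    "Bifidobacterium_bifidum",
    "Proteobacteria",
)

#: species of the panel belonging to the Proteobacteria phylum (used when a
#: dominance target is a phylum rather than a single species)
PROTEOBACTERIA_SPECIES = (
    "Escherichia_coli",
    "Klebsiella_pneumoniae",
    "Enterobacter_cloacae",
)

STRATA = ("within_subject", "within_centre", "between_centre")


def shannon(abundances) -> float:
    """Shannon diversity (natural log) of one abundance vector (percent scale).

    Nonzero entries are renormalised to fractions; an all-zero vector has no
    defined diversity and returns NaN with a warning.
    """
    x = np.asarray(abundances, dtype=float)
    if (x < 0).any():
        raise ValueError("negative abundance")
    total = x.sum()
    if total <= 0:
        warnings.warn("all-zero abundance vector: Shannon diversity undefined")
        return float("nan")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


def bray_curtis(x, y) -> float:
    """Bray-Curtis dissimilarity 1 - 2*sum(min)/(sum(x)+sum(y)) in [0, 1]."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("vectors must share the species index")
    if (x < 0).any() or (y < 0).any():
        raise ValueError("negative abundance")
    denom = x.sum() + y.sum()
    if denom == 0:
        return float("nan")
    return float(1.0 - 2.0 * np.minimum(x, y).sum() / denom)


@dataclass
class DissimilarityMatrix:
    """Symmetric sample-by-sample Bray-Curtis matrix with zero diagonal."""

    ids: list[str]
    data: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=float)
        if d.shape != (len(self.ids), len(self.ids)):
            raise ValueError("matrix shape does not match id count")
        if not np.allclose(d, d.T, atol=1e-12):
            raise ValueError("dissimilarity matrix must be symmetric")
        if not np.allclose(np.diag(d), 0.0, atol=1e-12):
            raise ValueError("dissimilarity matrix must have zero diagonal")
        if np.nanmin(d) < -1e-12 or np.nanmax(d) > 1 + 1e-12:
            raise ValueError("Bray-Curtis values must lie in [0, 1]")
        self.data = d

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, ids) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.ids)}
        return np.array([pos[s] for s in ids], dtype=int)

    def submatrix(self, idx: np.ndarray) -> np.ndarray:
        return self.data[np.ix_(idx, idx)]


def bray_curtis_matrix(profile) -> DissimilarityMatrix:
    """All-pairs Bray-Curtis matrix of a :class:`~longmicro.io.TaxProfile`."""
    values = profile.data.to_numpy(dtype=float)
    dm = squareform(pdist(values, metric="braycurtis"))
    return DissimilarityMatrix(list(profile.data.index), dm)


def target_taxon_fractions(
    profile_row: pd.Series, taxa=DOMINANCE_TAXA
) -> dict[str, float]:
    """Fraction-scale abundance of each dominance target for one sample.

    ``profile_row`` is a percent-scale species row; phylum-level targets sum
    their member species.
    """
    out = {}
    for t in taxa:
        if t == "Proteobacteria":
            members = [s for s in PROTEOBACTERIA_SPECIES if s in profile_row.index]
            out[t] = float(profile_row[members].sum()) / 100.0
        else:
            out[t] = float(profile_row.get(t, 0.0)) / 100.0
    return out


def classify_dominance(fractions, taxa=DOMINANCE_TAXA) -> str:
    """Label of the unique target taxon with fraction strictly > 0.5, else ``mixed``.

    Accepts either a mapping taxon -> fraction or a percent-scale species row
    (aggregated through :func:`target_taxon_fractions`).
    """
    if isinstance(fractions, pd.Series) and not set(taxa) <= set(fractions.index):
        fractions = target_taxon_fractions(fractions, taxa)
    for t in taxa:
        if float(fractions[t]) > 0.5:
            return t
    return "mixed"


# ---------------------------------------------------------------------------
# stability windows
# ---------------------------------------------------------------------------


def stability_windows(
    dm: DissimilarityMatrix,
    records: list[SampleRecord],
    window_days: int = 90,
    step_days: int = 60,
    n_boot: int = 1000,
    ci: float = 99.0,
    min_pairs: int = 5,
    seed: int = 0,
) -> pd.DataFrame:
    """Median Bray-Curtis per age window and stratum, with bootstrap CIs.

    Windows ``[t, t + window_days)`` start at age 0 and advance by
    ``step_days`` regardless of when sampling begins, so early windows may be
    empty (reported with ``n_pairs`` 0). A pair contributes to every window
    containing both collection ages; each pair belongs to exactly one stratum
    (same subject, else same centre, else between centres). Strata with fewer
    than ``min_pairs`` pairs get NaN confidence bounds.
    """
    if window_days <= 0:
        raise ValueError("window_days must be positive")
    if step_days <= 0:
        raise ValueError("step_days must be positive")
    by_id = {r.sample_id: r for r in records}
    missing = [s for s in dm.ids if s not in by_id]
    if missing:
        raise ValueError(f"samples without metadata: {missing[:5]}")
    ages = np.array([by_id[s].age_days for s in dm.ids])
    subjects = np.array([by_id[s].subject_id for s in dm.ids])
    centres = np.array([by_id[s].centre for s in dm.ids])
    rng = np.random.default_rng(seed)
    lo_q, hi_q = (100 - ci) / 2, 100 - (100 - ci) / 2

    rows = []
    max_age = int(ages.max()) if len(ages) else 0
    for start in range(0, max_age + 1, step_days):
        idx = np.flatnonzero((ages >= start) & (ages < start + window_days))
        sub = dm.data[np.ix_(idx, idx)]
        same_subj = subjects[idx][:, None] == subjects[idx][None, :]
        same_centre = centres[idx][:, None] == centres[idx][None, :]
        iu = np.triu_indices(len(idx), k=1)
        d = sub[iu]
        in_subj = same_subj[iu]
        in_centre = same_centre[iu] & ~in_subj
        between = ~same_subj[iu] & ~same_centre[iu]
        for stratum, mask in zip(STRATA, (in_subj, in_centre, between)):
            vals = d[mask]
            vals = vals[~np.isnan(vals)]
            n = len(vals)
            if n == 0:
                med = lo = hi = float("nan")
            else:
                med = float(np.median(vals))
                if n >= min_pairs:
                    boots = np.median(
                        rng.choice(vals, size=(n_boot, n), replace=True), axis=1
                    )
                    lo = float(np.percentile(boots, lo_q))
                    hi = float(np.percentile(boots, hi_q))
                else:
                    lo = hi = float("nan")
            rows.append(
                {
                    "window_start_days": start,
                    "window_center_days": start + window_days / 2,
                    "stratum": stratum,
                    "median_bc": med,
                    "ci99_low": lo,
                    "ci99_high": hi,
                    "n_pairs": n,
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------


@dataclass
class PermanovaResult:
    term: str
    sum_of_squares: float
    r_squared: float
    pseudo_f: float
    p_value: float
    n_permutations: int
    n_samples: int
    n_groups: int


def _ss_within(d2: np.ndarray, codes: np.ndarray, k: int) -> float:
    ss = 0.0
    for g in range(k):
        idx = np.flatnonzero(codes == g)
        if len(idx) > 1:
            ss += d2[np.ix_(idx, idx)].sum() / (2.0 * len(idx))
    return ss


def permanova(
    dm: DissimilarityMatrix,
    groups,
    n_perm: int = 1000,
    seed: int = 0,
    term: str = "group",
    strata=None,
) -> PermanovaResult:
    """Single-term PERMANOVA on a dissimilarity matrix.

    SS_total = sum_{i<j} d_ij^2 / n; SS_within pools the analogous quantity
    per group; R^2 = (SS_total - SS_within) / SS_total and the pseudo-F uses
    (k - 1, n - k) degrees of freedom. The p-value is
    ``(1 + #{F_perm >= F_obs}) / (1 + n_perm)`` under seeded label
    permutations, optionally restricted within ``strata`` blocks.
    """
    labels = np.asarray(groups)
    n = dm.n
    if len(labels) != n:
        raise ValueError("group vector length must match matrix size")
    uniq, codes = np.unique(labels, return_inverse=True)
    k = len(uniq)
    if k < 2:
        raise ValueError("PERMANOVA needs at least two groups")
    d2 = dm.data ** 2
    ss_total = d2.sum() / (2.0 * n)
    if ss_total <= 0:
        return PermanovaResult(term, 0.0, float("nan"), float("nan"), float("nan"),
                               n_perm, n, k)
    ss_within = _ss_within(d2, codes, k)
    ss_between = ss_total - ss_within
    r2 = ss_between / ss_total
    f_obs = (ss_between / (k - 1)) / (ss_within / (n - k)) if ss_within > 0 else np.inf

    rng = np.random.default_rng(seed)
    if strata is not None:
        strata = np.asarray(strata)
        if len(strata) != n:
            raise ValueError("strata length must match matrix size")
        blocks = [np.flatnonzero(strata == b) for b in np.unique(strata)]
    count = 0
    perm = np.arange(n)
    for _ in range(n_perm):
        if strata is None:
            rng.shuffle(perm)
        else:
            for b in blocks:
                perm[b] = rng.permutation(b)
        pc = codes[perm]
        ss_w = _ss_within(d2, pc, k)
        ss_b = ss_total - ss_w
        f = (ss_b / (k - 1)) / (ss_w / (n - k)) if ss_w > 0 else np.inf
        if f >= f_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return PermanovaResult(term, ss_between, r2, f_obs, p, n_perm, n, k)
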