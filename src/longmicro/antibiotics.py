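"""Antibiotic perturbation statistics on consecutive within-subject samples.

Two analyses:

* stability comparison of consecutive sample pairs (< 50 days apart, first
  three years) with versus without an antibiotic course starting between the
  two collections, summarised by LOESS curves against age with
  permutation-based pointwise confidence bands, and
* per-species bootstrapped mean log2 fold change across antibiotic pairs in
  which the species was present in the first sample.

A course "between" two samples is keyed on its start day falling in the open
interval between the two collection ages, so a course already running at the
first collection does not count.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import mannwhitneyu
from statsmodels.nonparametric.smoothers_lowess import lowess

from .diversity import DissimilarityMatrix
from .io import SampleRecord, TaxProfile


@dataclass
class ConsecutivePair:
    subject_id: str
    sample_before: str
    sample_after: str
    gap_days: int
    abx_between: bool
    age_at_first: int


@dataclass
class FoldChangeResult:
    species: str
    n_pairs: int
    mean_log2fc: float
    sd_log2fc: float
    pseudo_abundance: float
    seed: int


def consecutive_pairs(
    records: list[SampleRecord],
    max_gap_days: int = 50,
    max_age_days: int = 1095,
) -> list[ConsecutivePair]:
    """Adjacent same-subject sample pairs with gap strictly below ``max_gap_days``.

    Both collection ages must be at most ``max_age_days``; a pair is an
    antibiotic pair when any recorded course starts strictly between the two
    collection ages.
    """
    by_subject: dict[str, list[SampleRecord]] = {}
    for r in records:
        by_subject.setdefault(r.subject_id, []).append(r)
    pairs: list[ConsecutivePair] = []
    for subject in sorted(by_subject):
        samples = sorted(by_subject[subject], key=lambda r: (r.age_days, r.sample_id))
        for before, after in zip(samples, samples[1:]):
            gap = after.age_days - before.age_days
            if gap <= 0 or gap >= max_gap_days:
                continue
            if after.age_days > max_age_days:
                continue
            abx = any(
                before.age_days < start < after.age_days
                for start, _, _ in before.antibiotic_courses
            )
            pairs.append(
                ConsecutivePair(
                    subject_id=subject,
                    sample_before=before.sample_id,
                    sample_after=after.sample_id,
                    gap_days=gap,
                    abx_between=abx,
                    age_at_first=before.age_days,
                )
            )
    return pairs


@dataclass
class PairStabilitySummary:
    """LOESS fits of pair Bray-Curtis against age, per antibiotic stratum."""

    grid: np.ndarray
    fit_abx: np.ndarray | None
    fit_no_abx: np.ndarray | None
    ci_abx: np.ndarray | None        # (2, len(grid)) pointwise 2.5/97.5 perc.
    ci_no_abx: np.ndarray | None
    median_abx: float
    median_no_abx: float
    mw_p_early: float
    mw_p_late: float
    n_abx: int
    n_no_abx: int


def _pair_bc(pairs, dm: DissimilarityMatrix) -> np.ndarray:
    i = dm.index_of([p.sample_before for p in pairs])
    j = dm.index_of([p.sample_after for p in pairs])
    return dm.data[i, j]


def pair_stability_summary(
    pairs: list[ConsecutivePair],
    dm: DissimilarityMatrix,
    n_perm: int = 999,
    frac: float = 0.5,
    n_grid: int = 25,
    seed: int = 0,
) -> PairStabilitySummary:
    """Compare pair-to-pair Bray-Curtis with and without intervening antibiotics.

    Confidence bands come from permuting the antibiotic labels over pairs and
    taking pointwise 2.5/97.5 percentiles of the refitted curves; the
    Mann-Whitney comparisons split pairs at the median first-collection age.
    """
    if not pairs:
        raise ValueError("no pairs supplied")
    bc = _pair_bc(pairs, dm)
    ages = np.array([p.age_at_first for p in pairs], dtype=float)
    is_abx = np.array([p.abx_between for p in pairs])
    keep = ~np.isnan(bc)
    bc, ages, is_abx = bc[keep], ages[keep], is_abx[keep]
    grid = np.linspace(ages.min(), ages.max(), n_grid)
    rng = np.random.default_rng(seed)

    def fit(mask):
        if mask.sum() < 5:
            return None
        return lowess(bc[mask], ages[mask], frac=frac, xvals=grid)

    fit_abx = fit(is_abx)
    fit_no = fit(~is_abx)
    if fit_abx is None:
        warnings.warn("antibiotic stratum too small for a LOESS curve")
    if fit_no is None:
        warnings.warn("no-antibiotic stratum too small for a LOESS curve")

    ci_abx = ci_no = None
    if fit_abx is not None and fit_no is not None and n_perm > 0:
        perm_abx = np.empty((n_perm, len(grid)))
        perm_no = np.empty((n_perm, len(grid)))
        labels = is_abx.copy()
        for b in range(n_perm):
            rng.shuffle(labels)
            perm_abx[b] = lowess(bc[labels], ages[labels], frac=frac, xvals=grid)
            perm_no[b] = lowess(bc[~labels], ages[~labels], frac=frac, xvals=grid)
        ci_abx = np.percentile(perm_abx, [2.5, 97.5], axis=0)
        ci_no = np.percentile(perm_no, [2.5, 97.5], axis=0)

    split = float(np.median(ages))
    early, late = ages <= split, ages > split

    def mw(mask):
        a, b = bc[mask & is_abx], bc[mask & ~is_abx]
        if len(a) < 2 or len(b) < 2:
            return float("nan")
        return float(mannwhitneyu(a, b, alternative="two-sided").pvalue)

    return PairStabilitySummary(
        grid=grid,
        fit_abx=fit_abx,
        fit_no_abx=fit_no,
        ci_abx=ci_abx,
        ci_no_abx=ci_no,
        median_abx=float(np.median(bc[is_abx])) if is_abx.any() else float("nan"),
        median_no_abx=float(np.median(bc[~is_abx])) if (~is_abx).any() else float("nan"),
        mw_p_early=mw(early),
        mw_p_late=mw(late),
        n_abx=int(is_abx.sum()),
        n_no_abx=int((~is_abx).sum()),
    )


def species_fold_change(
    pairs: list[ConsecutivePair],
    tax: TaxProfile,
    species: str,
    n_boot: int = 1000,
    seed: int = 0,
) -> FoldChangeResult:
    """Bootstrapped mean log2 fold change of one species across antibiotic pairs.

    Only pairs with an antibiotic course between them and the species present
    (relative abundance strictly > 0) in the first sample are eligible. The
    per-pair statistic is ``log2((after + delta) / (before + delta))`` with
    ``delta`` half the smallest nonzero abundance of the species in the whole
    dataset (its detection floor), which keeps zero-after pairs finite. The
    reported mean and s.d. are taken over ``n_boot`` bootstrap resamples of
    the eligible pairs.
    """
    if species not in tax.data.columns:
        raise KeyError(f"species {species!r} not in taxonomic profile")
    col = tax.data[species]
    nonzero = col[col > 0]
    delta = float(nonzero.min()) / 2.0 if len(nonzero) else 0.5
    eligible = [
        p
        for p in pairs
        if p.abx_between and float(col.get(p.sample_before, 0.0)) > 0
    ]
    if not eligible:
        return FoldChangeResult(species, 0, float("nan"), float("nan"), delta, seed)
    before = col.loc[[p.sample_before for p in eligible]].to_numpy(dtype=float)
    after = col.loc[[p.sample_after for p in eligible]].to_numpy(dtype=float)
    lfc = np.log2((after + delta) / (before + delta))
    rng = np.random.default_rng(seed)
    n = len(lfc)
    boot_means = rng.choice(lfc, size=(n_boot, n), replace=True).mean(axis=1)
    return FoldChangeResult(
        species=species,
        n_pairs=n,
        mean_log2fc=float(boot_means.mean()),
        sd_log2fc=float(boot_means.std(ddof=0)),
        pseudo_abundance=delta,
        seed=seed,
    )


def fold_change_table(
    pairs, tax: TaxProfile, species_list, n_boot: int = 1000, seed: int = 0
) -> pd.DataFrame:
    """`species_fold_change` over a species panel, as a tidy frame."""
    rows = []
    for i, sp in enumerate(species_list):
        r = species_fold_change(pairs, tax, sp, n_boot=n_boot, seed=seed + i)
        rows.append(
            {
                "species": r.species,
                "n_pairs": r.n_pairs,
                "mean_log2fc": r.mean_log2fc,
                "sd_log2fc": r.sd_log2fc,
                "pseudo_abundance": r.pseudo_abundance,
            }
        )
    return pd.DataFrame(rows)
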