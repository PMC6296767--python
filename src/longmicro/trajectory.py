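"""Sigmoid longitudinal trend for alpha diversity plus residual mixed models.

Alpha diversity in early life accrues along a saturating, age-dependent
curve. The trend is modelled by a four-parameter logistic

    D(t) = d_min + (d_max - d_min) / (1 + exp(-k (t - t_mid)))

fitted by least squares from multiple starts (t_mid initialised at age
quantiles). Covariate effects are then assessed on the residuals with a
subject random-intercept linear mixed model, which accounts for repeated
measurements per child.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .io import SampleRecord, records_to_frame

_EXP_CLIP = 500.0


def sigmoid_curve(t, d_min, d_max, k, t_mid):
    z = np.clip(-k * (np.asarray(t, dtype=float) - t_mid), -_EXP_CLIP, _EXP_CLIP)
    return d_min + (d_max - d_min) / (1.0 + np.exp(z))


@dataclass
class SigmoidFit:
    d_min: float
    d_max: float
    k: float
    t_mid: float
    rss: float
    converged: bool
    fallback_coef: tuple[float, float] | None = None  # (slope, intercept)

    def predict(self, ages) -> np.ndarray:
        if not self.converged and self.fallback_coef is not None:
            m, b = self.fallback_coef
            return m * np.asarray(ages, dtype=float) + b
        return sigmoid_curve(ages, self.d_min, self.d_max, self.k, self.t_mid)

    def residuals(self, ages, diversity) -> np.ndarray:
        return np.asarray(diversity, dtype=float) - self.predict(ages)

    @property
    def diversity_range(self) -> float:
        return self.d_max - self.d_min


def fit_sigmoid(ages, diversity) -> SigmoidFit:
    """Least-squares four-parameter logistic fit with multi-start initialisation.

    Needs at least 10 observations over at least 2 distinct ages. Starting
    points place ``t_mid`` at the 0.25/0.5/0.75 age quantiles and try slow,
    moderate and steep rates; the best residual sum of squares wins. If no
    start converges the result falls back to a straight-line fit
    (``converged`` is False) whose residuals remain usable downstream.
    """
    t = np.asarray(ages, dtype=float)
    y = np.asarray(diversity, dtype=float)
    mask = ~(np.isnan(t) | np.isnan(y))
    t, y = t[mask], y[mask]
    if len(t) < 10:
        raise ValueError("need at least 10 observations")
    if len(np.unique(t)) < 2:
        raise ValueError("need at least 2 distinct ages")

    span = max(t.max() - t.min(), 1.0)
    y_lo, y_hi = float(y.min()), float(y.max())
    pad = max(y_hi - y_lo, 0.1)
    bounds = (
        [y_lo - 2 * pad, y_lo - 2 * pad, 1e-6, t.min() - 2 * span],
        [y_hi + 2 * pad, y_hi + 2 * pad, 5.0, t.max() + 2 * span],
    )

    def resid(theta):
        return sigmoid_curve(t, *theta) - y

    best = None
    for q in (0.25, 0.5, 0.75):
        for k0 in (2.0 / span, 8.0 / span, 30.0 / span):
            x0 = [y_lo, y_hi, min(k0, 4.9), float(np.quantile(t, q))]
            try:
                sol = least_squares(resid, x0, bounds=bounds, method="trf")
            except Exception:  # pragma: no cover - optimiser edge cases
                continue
            if not sol.success:
                continue
            rss = float(2 * sol.cost)
            if best is None or rss < best[0]:
                best = (rss, sol.x)

    if best is None:
        warnings.warn("sigmoid fit failed from all starts; using linear fallback")
        m, b = np.polyfit(t, y, 1)
        rss = float(((m * t + b - y) ** 2).sum())
        return SigmoidFit(float("nan"), float("nan"), float("nan"), float("nan"),
                          rss, False, fallback_coef=(float(m), float(b)))

    rss, (d_min, d_max, k, t_mid) = best
    if d_max < d_min:  # canonical orientation: mirror the curve
        d_min, d_max, k = d_max, d_min, -k
    return SigmoidFit(float(d_min), float(d_max), float(k), float(t_mid), rss, True)


@dataclass
class ResidualAssociation:
    covariate: str
    coefficient: float
    std_error: float
    p_value: float
    n_obs: int
    n_subjects: int


def residual_mixed_model(
    residuals,
    records: list[SampleRecord],
    covariates: list[str],
) -> list[ResidualAssociation]:
    """Subject random-intercept model of sigmoid residuals on covariates.

    ``residuals`` is indexed like ``records`` (one value per sample, in
    order). Covariates name columns of
    :func:`~longmicro.io.records_to_frame`, e.g. ``breastfeeding``,
    ``delivery_mode``, ``abx30d``, ``solid_food``. Samples with unknown
    breastfeeding are dropped when that covariate is requested; covariates
    with a single observed level are dropped with a warning. Wald p-values
    are reported per fixed-effect coefficient.
    """
    import statsmodels.formula.api as smf
    from statsmodels.tools.sm_exceptions import ConvergenceWarning

    df = records_to_frame(records).reset_index()
    resid = np.asarray(residuals, dtype=float)
    if len(resid) != len(df):
        raise ValueError("residual vector length must match records")
    if np.isclose(np.var(resid), 0.0):
        raise ValueError("zero residual variance: nothing to model")
    df["resid"] = resid
    if "breastfeeding" in covariates:
        df = df[df["breastfeeding_known"]].copy()
        df["breastfeeding"] = df["breastfeeding"].astype(bool)

    kept = []
    for c in covariates:
        if c not in df.columns:
            raise KeyError(f"unknown covariate {c!r}")
        if df[c].nunique() < 2:
            warnings.warn(f"covariate {c!r} has a single level; dropped")
            continue
        kept.append(c)
    if not kept:
        raise ValueError("no usable covariates")

    terms = [
        f"C({c})" if df[c].dtype == object else c for c in kept
    ]
    formula = "resid ~ " + " + ".join(terms)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", ConvergenceWarning)
        model = smf.mixedlm(formula, df, groups=df["subject_id"])
        fit = model.fit(reml=True)

    out = []
    for name in fit.fe_params.index:
        if name == "Intercept":
            continue
        out.append(
            ResidualAssociation(
                covariate=name,
                coefficient=float(fit.fe_params[name]),
                std_error=float(fit.bse_fe[name]),
                p_value=float(fit.pvalues[name]),
                n_obs=int(len(df)),
                n_subjects=int(df["subject_id"].nunique()),
            )
        )
    return out


def shannon_trajectory(records, tax) -> pd.DataFrame:
    """Per-sample age and Shannon diversity, ready for :func:`fit_sigmoid`."""
    from .diversity import shannon

    by_id = {r.sample_id: r for r in records}
    rows = []
    for sid in tax.data.index:
        if sid not in by_id:
            continue
        rows.append(
            {
                "sample_id": sid,
                "subject_id": by_id[sid].subject_id,
                "age_days": by_id[sid].age_days,
                "shannon": shannon(tax.data.loc[sid].to_numpy()),
            }
        )
    return pd.DataFrame(rows).set_index("sample_id")
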