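"""Nonlinear developmental trajectories of spectral features.

Each feature is modeled across age with a fixed-degrees-of-freedom
natural cubic spline (basis dimension 4), sex as an ordered-factor
(±0.5) contrast, study as a nuisance factor, and per-subject random
effects (random intercept + random age slope) to account for repeated
visits.  A second model adds a by-sex difference smooth; the two are
compared by a likelihood-ratio ANOVA and the interaction model is kept
only when p < 0.05.  Term p-values are corrected across measures within
an ROI by Benjamini-Hochberg FDR.  Trajectory extrema are located on the
daily prediction grid with a ±``order``-day dominance window, and a
standardized rate of change (day-to-day difference divided by the SD of
the modeled values) summarizes developmental velocity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from scipy.signal import argrelextrema
from statsmodels.regression.mixed_linear_model import MixedLM
from statsmodels.stats.multitest import multipletests
from statsmodels.tools.sm_exceptions import ConvergenceWarning

__all__ = [
    "TrajectoryFit",
    "RoiEffect",
    "validate_cohort_table",
    "fit_trajectory",
    "select_model",
    "fdr_adjust",
    "roi_contrast",
    "trajectory_extrema",
    "standardized_rate_of_change",
]

AGE_SCALE = 365.0  # days per year, used to condition the design matrix


def _fit_mixed(endog, exog, groups, exog_re):
    """MixedLM(ML) fit with an OLS fallback for degenerate data.

    Zero-residual or otherwise singular inputs make the mixed-model
    likelihood collapse; the fixed-effects OLS solution is then the
    correct limit and is returned in a duck-typed wrapper.
    """
    import statsmodels.api as sm

    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            warnings.simplefilter("ignore", RuntimeWarning)
            warnings.simplefilter("ignore", UserWarning)
            res = MixedLM(endog, exog, groups=groups, exog_re=exog_re).fit(
                reml=False, method="lbfgs", maxiter=200
            )
        if np.all(np.isfinite(np.asarray(res.fe_params))):
            return res
    except (np.linalg.LinAlgError, ValueError, ZeroDivisionError):
        pass
    ols = sm.OLS(endog, exog).fit()

    class _OlsShim:
        fe_params = np.asarray(ols.params)
        llf = float(ols.llf)
        converged = True
        bse_fe = np.asarray(ols.bse)

        @staticmethod
        def cov_params():
            return np.asarray(ols.cov_params())

    return _OlsShim()


def natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural cubic spline basis (without the constant column).

    With K knots the full natural-spline space has dimension K including
    the constant; the returned matrix holds the K-1 non-constant columns
    [x, d_1 - d_{K-1}, ..., d_{K-2} - d_{K-1}] with
    d_j(x) = ((x - k_j)^3_+ - (x - k_K)^3_+) / (k_K - k_j).
    """
    x = np.asarray(x, dtype=float)
    knots = np.sort(np.asarray(knots, dtype=float))
    K = len(knots)

    def d(j: int) -> np.ndarray:
        return (
            np.clip(x - knots[j], 0, None) ** 3
            - np.clip(x - knots[K - 1], 0, None) ** 3
        ) / (knots[K - 1] - knots[j])

    cols = [x]
    dK2 = d(K - 2)
    for j in range(K - 2):
        cols.append(d(j) - dK2)
    return np.column_stack(cols)


def _sex_contrast(sex: pd.Series) -> np.ndarray:
    """Ordered-factor sex as a ±0.5 contrast (F=+0.5, M=-0.5)."""
    s = sex.astype(str).str.upper().str[0]
    bad = ~s.isin(["F", "M"])
    if bad.any():
        raise ValueError(f"unrecognized sex values: {sorted(sex[bad].unique())}")
    return np.where(s == "F", 0.5, -0.5)


def validate_cohort_table(table: pd.DataFrame) -> pd.DataFrame:
    """Check the longitudinal cohort schema and invariants."""
    required = {"subject_id", "age_days", "sex", "study", "roi", "measure", "value"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"cohort table missing columns: {sorted(missing)}")
    if (table["age_days"] <= 0).any():
        raise ValueError("age_days must be positive")
    dup = table.duplicated(["subject_id", "age_days", "roi", "measure"])
    if dup.any():
        raise ValueError("duplicate (subject, age, roi, measure) rows")
    return table


@dataclass
class TrajectoryFit:
    """One fitted age-trajectory model for one measure."""

    measure: str
    with_interaction: bool
    params: pd.Series
    llf: float
    n_fixed: int
    n_obs: int
    knots: np.ndarray
    study_levels: list[str]
    daily_predictions: pd.DataFrame  # columns: age_days, male, female
    age_smooth_fvalue: float = np.nan
    age_smooth_pvalue: float = np.nan
    interaction_pvalue: float | None = None
    converged: bool = True

    @property
    def extrema_days(self) -> dict[str, np.ndarray]:
        ages = self.daily_predictions["age_days"].to_numpy()
        return {
            sex: ages[trajectory_extrema(self.daily_predictions[sex].to_numpy())]
            for sex in ("male", "female")
        }

    def std_rate_of_change(self, sex: str = "male") -> np.ndarray:
        return standardized_rate_of_change(self.daily_predictions[sex].to_numpy())


def _design(
    age_days: np.ndarray,
    sex_c: np.ndarray,
    study: pd.Series,
    knots: np.ndarray,
    study_levels: list[str],
    with_interaction: bool,
) -> tuple[np.ndarray, list[str]]:
    a = np.asarray(age_days, dtype=float) / AGE_SCALE
    S = natural_spline_basis(a, knots)
    cols = [np.ones_like(a), sex_c]
    names = ["intercept", "sex"]
    for lev in study_levels[1:]:
        cols.append((study == lev).to_numpy(dtype=float))
        names.append(f"study[{lev}]")
    for j in range(S.shape[1]):
        cols.append(S[:, j])
        names.append(f"s_age{j}")
    if with_interaction:
        for j in range(S.shape[1]):
            cols.append(sex_c * S[:, j])
            names.append(f"s_age{j}:sex")
    return np.column_stack(cols), names


def fit_trajectory(
    table: pd.DataFrame,
    measure: str,
    with_interaction: bool = False,
    roi: str | None = None,
    k: int = 4,
    random_slope: bool = True,
) -> TrajectoryFit:
    """Fit one smooth-age mixed model for ``measure``.

    Additive form: sex contrast + study factor + fixed-df natural spline
    of age (k=4 -> 3 non-constant columns) + per-subject random intercept
    and age slope.  The interaction form adds sex x spline columns (a
    difference smooth).  Daily predictions per sex are computed at the
    reference study level with random effects at zero.
    """
    table = validate_cohort_table(table)
    sub = table[table["measure"] == measure]
    if roi is not None:
        sub = sub[sub["roi"] == roi]
    if sub.empty:
        raise ValueError(f"no rows for measure '{measure}'")
    if sub["sex"].nunique() < 2:
        raise ValueError("both sexes must be present")

    age = sub["age_days"].to_numpy(dtype=float)
    a = age / AGE_SCALE
    knots = np.unique(np.quantile(a, [0.0, 1 / 3, 2 / 3, 1.0]))
    if len(knots) < 4:
        raise ValueError("not enough distinct ages for a k=4 spline")
    sex_c = _sex_contrast(sub["sex"])
    study_levels = sorted(sub["study"].astype(str).unique())
    if len(study_levels) == 1:
        # constant factor would be rank-deficient with the intercept
        warnings.warn("single study level; dropping the study factor", stacklevel=2)
    exog, names = _design(age, sex_c, sub["study"].astype(str), knots,
                          study_levels, with_interaction)

    exog_re = np.column_stack([np.ones_like(a), a]) if random_slope else np.ones((len(a), 1))
    res = _fit_mixed(
        sub["value"].to_numpy(dtype=float),
        exog,
        sub["subject_id"].to_numpy(),
        exog_re,
    )

    # daily predictions, reference study, random effects zero
    days = np.arange(int(np.floor(age.min())), int(np.ceil(age.max())) + 1)
    preds = {}
    for sex_name, sc in (("male", -0.5), ("female", 0.5)):
        ex, _ = _design(
            days.astype(float),
            np.full(len(days), sc),
            pd.Series([study_levels[0]] * len(days)),
            knots,
            study_levels,
            with_interaction,
        )
        preds[sex_name] = ex @ np.asarray(res.fe_params)
    daily = pd.DataFrame({"age_days": days, "male": preds["male"], "female": preds["female"]})

    # joint Wald test of the age-smooth columns
    smooth_ix = [i for i, nm in enumerate(names) if nm.startswith("s_age") and not nm.endswith(":sex")]
    fval, pval = np.nan, np.nan
    try:
        beta = np.asarray(res.fe_params)[smooth_ix]
        cov = np.asarray(res.cov_params())[np.ix_(smooth_ix, smooth_ix)]
        chi2 = float(beta @ np.linalg.solve(cov, beta))
        fval = chi2 / len(smooth_ix)
        pval = float(stats.chi2.sf(chi2, len(smooth_ix)))
    except np.linalg.LinAlgError:  # singular covariance on degenerate fits
        pass

    return TrajectoryFit(
        measure=measure,
        with_interaction=with_interaction,
        params=pd.Series(np.asarray(res.fe_params), index=names),
        llf=float(res.llf),
        n_fixed=len(names),
        n_obs=len(sub),
        knots=knots,
        study_levels=study_levels,
        daily_predictions=daily,
        age_smooth_fvalue=fval,
        age_smooth_pvalue=pval,
        converged=bool(res.converged),
    )


def select_model(
    fit_additive: TrajectoryFit, fit_interaction: TrajectoryFit, alpha: float = 0.05
) -> TrajectoryFit:
    """Likelihood-ratio ANOVA between nested forms; strict p < alpha keeps
    the interaction model."""
    if fit_additive.measure != fit_interaction.measure:
        raise ValueError("fits are for different measures")
    if fit_additive.n_obs != fit_interaction.n_obs:
        raise ValueError("fits use different data")
    df = fit_interaction.n_fixed - fit_additive.n_fixed
    if df <= 0 or fit_additive.with_interaction or not fit_interaction.with_interaction:
        raise ValueError("models are not nested additive/interaction forms")
    lr = 2.0 * (fit_interaction.llf - fit_additive.llf)
    p = float(stats.chi2.sf(max(lr, 0.0), df))
    fit_additive.interaction_pvalue = p
    fit_interaction.interaction_pvalue = p
    return fit_interaction if p < alpha else fit_additive


def fdr_adjust(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class RoiEffect:
    roi: str
    effect: float
    statistic: float
    pvalue: float
    qvalue: float


def roi_contrast(
    table: pd.DataFrame,
    measure: str,
    reference: str = "posterior",
    random_slope: bool = True,
) -> list[RoiEffect]:
    """Per-ROI offsets relative to the posterior reference ROI.

    Single model with the ROI factor added to the additive form; each
    non-reference ROI's coefficient is its adjusted offset vs. posterior,
    reported with a Wald statistic, p-value, and BH q-value.
    """
    table = validate_cohort_table(table)
    sub = table[table["measure"] == measure]
    rois = sorted(sub["roi"].astype(str).unique())
    if reference not in rois:
        raise ValueError(f"reference ROI '{reference}' absent (have {rois})")
    if len(rois) < 2:
        raise ValueError("need at least 2 ROIs")

    age = sub["age_days"].to_numpy(dtype=float)
    a = age / AGE_SCALE
    knots = np.unique(np.quantile(a, [0.0, 1 / 3, 2 / 3, 1.0]))
    sex_c = _sex_contrast(sub["sex"])
    study_levels = sorted(sub["study"].astype(str).unique())
    exog, names = _design(age, sex_c, sub["study"].astype(str), knots,
                          study_levels, with_interaction=False)
    others = [r for r in rois if r != reference]
    roi_cols = np.column_stack(
        [(sub["roi"].astype(str) == r).to_numpy(dtype=float) for r in others]
    )
    exog = np.column_stack([exog, roi_cols])
    names = names + [f"roi[{r}]" for r in others]

    exog_re = np.column_stack([np.ones_like(a), a]) if random_slope else np.ones((len(a), 1))
    res = _fit_mixed(
        sub["value"].to_numpy(dtype=float),
        exog,
        sub["subject_id"].to_numpy(),
        exog_re,
    )

    k0 = len(names) - len(others)
    effects, zs, ps = [], [], []
    bse = np.asarray(res.bse_fe)
    fe = np.asarray(res.fe_params)
    for i, r in enumerate(others):
        beta = float(fe[k0 + i])
        se = float(bse[k0 + i])
        z = beta / se if se > 0 else np.nan
        effects.append(beta)
        zs.append(z)
        ps.append(float(2 * stats.norm.sf(abs(z))))
    qs = fdr_adjust(ps)
    return [
        RoiEffect(r, effects[i], zs[i], ps[i], float(qs[i]))
        for i, r in enumerate(others)
    ]


def trajectory_extrema(daily_predictions: np.ndarray, order: int = 100) -> np.ndarray:
    """Indices that are strict extrema vs. all neighbors within ±order days.

    Endpoints are excluded.  Series shorter than the dominance window
    return an empty list with a warning.
    """
    y = np.asarray(daily_predictions, dtype=float)
    if len(y) <= 2 * order:
        warnings.warn(
            f"series of length {len(y)} shorter than the ±{order}-day window",
            stacklevel=2,
        )
        return np.array([], dtype=int)
    maxima = argrelextrema(y, np.greater, order=order, mode="clip")[0]
    minima = argrelextrema(y, np.less, order=order, mode="clip")[0]
    out = np.sort(np.concatenate([maxima, minima]))
    return out[(out > 0) & (out < len(y) - 1)]


def standardized_rate_of_change(daily_predictions: np.ndarray) -> np.ndarray:
    """(f(t+1) - f(t)) / SD(f) over the full age range; length n-1."""
    y = np.asarray(daily_predictions, dtype=float)
    if len(y) < 2:
        raise ValueError("need at least 2 daily values")
    sd = float(np.std(y))
    if sd == 0:
        warnings.warn("constant series: standardized rate defined as zero", stacklevel=2)
        return np.zeros(len(y) - 1)
    return np.diff(y) / sd
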