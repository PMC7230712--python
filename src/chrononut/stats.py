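"""Statistical layer: goodness-of-fit chi-square with arbitrary expected
weights, Welch's t from group summaries, the Watson-Williams circular
ANOVA, mixed-effects day-type models with pairwise contrasts, and
Benjamini-Hochberg adjustment.
"""

from __future__ import annotations

import itertools
import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

HOURS_PER_DAY = 24.0


@dataclass
class TestResult:
    statistic: float
    df: object  # float or (df1, df2)
    p_raw: float
    p_adj: Optional[float] = None
    family_id: str = ""
    effect_label: str = ""


def chi_square_gof(
    observed: Sequence[float], expected_weights: Sequence[float]
) -> TestResult:
    """Pearson goodness-of-fit test with expected counts proportional to
    ``expected_weights`` and scaled to the observed total.

    ``statistic = sum((obs - exp)^2 / exp)`` with ``df = k - 1``.
    """
    obs = np.asarray(observed, dtype=float)
    w = np.asarray(expected_weights, dtype=float)
    if obs.shape != w.shape or obs.size < 2:
        raise ValueError("observed and expected_weights must share a length >= 2")
    if obs.sum() <= 0 or w.sum() <= 0:
        raise ValueError("observed and weight totals must be positive")
    if (w < 0).any():
        raise ValueError("negative expected weights")
    expected = obs.sum() * w / w.sum()
    if (expected == 0).any():
        raise ValueError("zero expected count")
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = obs.size - 1
    p = float(sps.chi2.sf(stat, df))
    return TestResult(stat, df, p, effect_label="chi_square_gof")


def welch_t(
    mean1: float, sd1: float, n1: int, mean2: float, sd2: float, n2: int
) -> TestResult:
    """Welch's unequal-variance t test from group summaries.

    Uses the Welch-Satterthwaite degrees of freedom and a two-sided p.
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("group SDs must be positive")
    v1 = sd1**2 / n1
    v2 = sd2**2 / n2
    t = (mean1 - mean2) / math.sqrt(v1 + v2)
    df = (v1 + v2) ** 2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    p = float(2.0 * sps.t.sf(abs(t), df))
    return TestResult(float(t), float(df), p, effect_label="welch_t")


# --- circular helpers -------------------------------------------------------

def kappa_ml(rbar: float, tol: float = 1e-6) -> float:
    """Approximate maximum-likelihood von Mises concentration from a mean
    resultant length, via the standard three-piece inversion.
    """
    r = float(rbar)
    if not 0.0 <= r <= 1.0:
        raise ValueError("mean resultant length must be in [0, 1]")
    if r < 0.53:
        kappa = 2 * r + r**3 + 5 * r**5 / 6
    elif r < 0.85:
        kappa = -0.4 + 1.39 * r + 0.43 / (1 - r)
    else:
        denom = r**3 - 4 * r**2 + 3 * r
        kappa = 1.0 / max(denom, tol)
    return max(kappa, tol)


def circ_mean_resultant(angles: np.ndarray, weights: Optional[np.ndarray] = None):
    """(mean direction, resultant length R, total weight) of angles in radians."""
    a = np.asarray(angles, dtype=float)
    w = np.ones_like(a) if weights is None else np.asarray(weights, dtype=float)
    C = float(np.sum(w * np.cos(a)))
    S = float(np.sum(w * np.sin(a)))
    R = math.hypot(C, S)
    mu = math.atan2(S, C) % (2 * math.pi)
    return mu, R, float(w.sum())


def circ_se_h(times_h: Sequence[float]) -> float:
    """Approximate circular standard error (hours) of the mean direction
    of unweighted clock times: ``1 / sqrt(n * rbar * kappa_hat)`` radians.
    """
    a = 2 * np.pi * (np.asarray(times_h, dtype=float) % HOURS_PER_DAY) / HOURS_PER_DAY
    _, R, n = circ_mean_resultant(a)
    rbar = R / n
    if rbar <= 0:
        return math.inf
    se_rad = 1.0 / math.sqrt(n * rbar * kappa_ml(rbar))
    return se_rad * HOURS_PER_DAY / (2 * np.pi)


def watson_williams(groups: Sequence[Sequence[float]], unit: str = "hours") -> TestResult:
    """Watson-Williams high-concentration F test for equality of mean
    directions across k groups.

    ``F = c * ((N - k)(sum R_i - R)) / ((k - 1)(N - sum R_i))`` with
    correction ``c = 1 + 3/(8 kappa_hat)`` and kappa estimated from the
    pooled within-group mean resultant length.  p comes from
    ``F(k - 1, N - k)``.

    Parameters
    ----------
    groups : sequence of angle vectors
        Clock times in hours (``unit='hours'``) or radians
        (``unit='radians'``); each group needs n >= 2.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    rad_groups = []
    for g in groups:
        a = np.asarray(g, dtype=float)
        if a.size < 2:
            raise ValueError("each group needs n >= 2")
        if unit == "hours":
            a = 2 * np.pi * (a % HOURS_PER_DAY) / HOURS_PER_DAY
        elif unit != "radians":
            raise ValueError(f"unknown unit {unit!r}")
        rad_groups.append(a)

    k = len(rad_groups)
    N = sum(a.size for a in rad_groups)
    Rs = []
    for a in rad_groups:
        _, R_i, _ = circ_mean_resultant(a)
        if R_i < 1e-12:
            logger.warning("a group has zero resultant length; data fully dispersed")
        Rs.append(R_i)
    all_angles = np.concatenate(rad_groups)
    _, R_total, _ = circ_mean_resultant(all_angles)

    sum_R = float(np.sum(Rs))
    rbar_w = sum_R / N
    if rbar_w < 0.45:
        logger.warning(
            "pooled mean resultant length %.3f below 0.45: Watson-Williams "
            "approximation unreliable", rbar_w,
        )
    kappa = kappa_ml(rbar_w)
    correction = 1.0 + 3.0 / (8.0 * kappa)
    denom = N - sum_R
    if denom <= 0:
        # perfectly concentrated groups
        stat = 0.0 if sum_R - R_total <= 1e-12 else math.inf
    else:
        stat = correction * ((N - k) * (sum_R - R_total)) / ((k - 1) * denom)
    stat = max(stat, 0.0)
    p = float(sps.f.sf(stat, k - 1, N - k)) if math.isfinite(stat) else 0.0
    return TestResult(float(stat), (k - 1, N - k), p, effect_label="watson_williams")


# --- multiplicity -----------------------------------------------------------

def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted = np.minimum(adjusted, 1.0)
    out = np.empty(m)
    out[order] = adjusted
    return out


def apply_bh(results: list[TestResult]) -> list[TestResult]:
    """BH-adjust a family of results in place (grouped by ``family_id``)."""
    by_family: dict[str, list[TestResult]] = {}
    for r in results:
        by_family.setdefault(r.family_id, []).append(r)
    for fam in by_family.values():
        adj = bh_adjust([r.p_raw for r in fam])
        for r, a in zip(fam, adj):
            r.p_adj = float(a)
    return results


# --- mixed-effects day-type models ------------------------------------------

@dataclass
class ModelSpec:
    outcome: str
    fixed: tuple[str, ...] = ("day_type", "sex", "age_years")
    random_group: str = "subject_id"
    reml: bool = True
    family_id: str = ""


@dataclass
class ModelFit:
    omnibus: TestResult
    contrasts: list[TestResult]
    converged: bool
    fallback_ols: bool


def fit_day_type_model(table: pd.DataFrame, spec: ModelSpec) -> ModelFit:
    """REML mixed-effects model of a metric on day type with sex and age
    covariates and a subject random intercept.

    Returns the omnibus Wald F test for the day-type factor and pairwise
    estimated-marginal contrasts between day types (differences of
    day-type coefficients under treatment coding), BH-adjusted within the
    contrast family.  Falls back to OLS with a warning on a singular or
    non-converging fit.
    """
    import statsmodels.formula.api as smf

    df = table.dropna(subset=[spec.outcome]).copy()
    levels = sorted(df["day_type"].unique())
    if len(levels) < 2:
        raise ValueError("need at least two day types")
    n_subjects = df[spec.random_group].nunique()
    if n_subjects < 2:
        raise ValueError("need at least two subjects with repeated measures")

    terms = []
    for f in spec.fixed:
        if f == "day_type":
            terms.append("C(day_type)")
        elif f in ("sex",):
            terms.append("C(sex)")
        else:
            terms.append(f)
    formula = f"{spec.outcome} ~ " + " + ".join(terms)

    fallback = False
    fit = None
    last_exc: Optional[Exception] = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for method in ("lbfgs", "powell"):
            try:
                model = smf.mixedlm(formula, df, groups=df[spec.random_group])
                cand = model.fit(reml=spec.reml, method=method)
                if not cand.converged or np.any(~np.isfinite(cand.bse_fe)):
                    raise RuntimeError("singular or non-converged mixed model")
                fit = cand
                break
            except Exception as exc:  # noqa: BLE001 - try the next optimizer
                last_exc = exc
        if fit is None:
            logger.warning("mixed model failed (%s); falling back to OLS", last_exc)
            fallback = True
            fit = smf.ols(formula, df).fit()

    exog_names = list(fit.model.exog_names)
    day_cols = [i for i, n in enumerate(exog_names) if n.startswith("C(day_type)")]
    k_fixed = len(exog_names)
    df_denom = max(len(df) - k_fixed - (0 if fallback else n_subjects), 2)

    # omnibus Wald F for the day-type coefficients
    L = np.zeros((len(day_cols), len(fit.params)))
    for r, c in enumerate(day_cols):
        L[r, c] = 1.0
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        wt = fit.wald_test(L, use_f=True, scalar=False)
    f_stat = float(np.squeeze(wt.statistic))
    df1 = len(day_cols)
    p_omni = float(sps.f.sf(f_stat, df1, df_denom))
    omnibus = TestResult(
        f_stat, (df1, df_denom), p_omni,
        family_id=spec.family_id, effect_label=f"{spec.outcome}~day_type",
    )

    # pairwise contrasts between day-type levels (treatment coding:
    # baseline level has implicit coefficient zero)
    coef_index = {levels[0]: None}
    for i, name in enumerate(exog_names):
        for lev in levels[1:]:
            if name == f"C(day_type)[T.{lev}]":
                coef_index[lev] = i
    params = np.asarray(fit.params, dtype=float)
    cov = np.asarray(fit.cov_params(), dtype=float)[: len(params), : len(params)]
    contrasts = []
    for a, b in itertools.combinations(levels, 2):
        vec = np.zeros(len(params))
        if coef_index[a] is not None:
            vec[coef_index[a]] += 1.0
        if coef_index[b] is not None:
            vec[coef_index[b]] -= 1.0
        est = float(vec @ params)
        se = float(math.sqrt(max(vec @ cov @ vec, 0.0)))
        if se == 0:
            t_stat, p = 0.0, 1.0
        else:
            t_stat = est / se
            p = float(2 * sps.t.sf(abs(t_stat), df_denom))
        contrasts.append(TestResult(
            t_stat, float(df_denom), p,
            family_id=f"{spec.family_id or spec.outcome}:contrasts",
            effect_label=f"{spec.outcome}:{a}-{b}",
        ))
    apply_bh(contrasts)
    return ModelFit(omnibus, contrasts, converged=not fallback, fallback_ols=fallback)


def results_to_frame(results: Sequence[TestResult]) -> pd.DataFrame:
    rows = []
    for r in results:
        if isinstance(r.df, tuple):
            df_repr = f"{r.df[0]:g},{r.df[1]:g}"
        else:
            df_repr = f"{r.df:g}"
        rows.append({
            "family_id": r.family_id,
            "effect": r.effect_label,
            "statistic": r.statistic,
            "df": df_repr,
            "p_raw": r.p_raw,
            "p_adj": r.p_adj,
        })
    return pd.DataFrame(rows, columns=["family_id", "effect", "statistic", "df", "p_raw", "p_adj"])
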