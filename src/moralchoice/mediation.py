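"""Moderated mediation with cluster bootstrap inference.

The mediator model regresses the harm-framing report M on IH, the decision
context code DC, their interaction, and the IB/EC covariates; the reduced
outcome model regresses relative harm sensitivity Y on IH, M, DC, IB, EC.
With DC coded 1 = gain / 0 = loss, the context-specific IH -> M paths are
a_gain = b1 + b3 and a_loss = b1, the mediator path b is the M coefficient
of the reduced outcome model, and the indirect effects are ab = a * b per
context with moderation index delta_ab = ab_gain - ab_loss.

Inference resamples *subjects* (keeping their paired context rows together)
to respect the repeated-measures structure; CIs are percentile by default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "MediationResult",
    "fit_model_M",
    "fit_model_Y",
    "mediation_indices",
    "bootstrap_mediation",
]

M_TERMS = ("intercept", "IH", "DC", "IH:DC", "IB", "EC")
Y_FULL_TERMS = ("intercept", "IH", "M", "DC", "IH:DC", "M:DC", "IB", "EC")
Y_REDUCED_TERMS = ("intercept", "IH", "M", "DC", "IB", "EC")

_STATS = ("a_gain", "a_loss", "b", "c_prime", "ab_gain", "ab_loss", "delta_ab")


@dataclass(frozen=True)
class MediationResult:
    """Point estimates, bootstrap CIs and p-values of the mediation indices."""

    estimates: dict  # stat -> point estimate on the observed data
    ci: dict  # stat -> (lo, hi)
    p: dict  # stat -> two-sided sign-proportion bootstrap p
    B: int
    seed: int
    ci_level: float
    model_m: pd.DataFrame  # term, beta, se, t
    model_y: pd.DataFrame


def _ols(X: np.ndarray, y: np.ndarray, terms: tuple[str, ...]) -> tuple[np.ndarray, pd.DataFrame]:
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError("rank-deficient mediation design matrix")
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    sigma2 = float(resid @ resid) / df if df > 0 else np.nan
    se = np.sqrt(np.diag(sigma2 * np.linalg.inv(X.T @ X)))
    table = pd.DataFrame({"term": terms, "beta": beta, "se": se, "t": beta / se})
    return beta, table


def _design_M(data: pd.DataFrame) -> tuple[np.ndarray, np.ndarray]:
    ih = data["IH"].to_numpy(float)
    dc = data["context"].to_numpy(float)
    X = np.column_stack(
        [np.ones(len(data)), ih, dc, ih * dc,
         data["IB"].to_numpy(float), data["EC"].to_numpy(float)]
    )
    return X, data["M"].to_numpy(float)


def _design_Y(data: pd.DataFrame, reduced: bool) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    ih = data["IH"].to_numpy(float)
    m = data["M"].to_numpy(float)
    dc = data["context"].to_numpy(float)
    cols = [np.ones(len(data)), ih, m, dc]
    terms: tuple[str, ...] = Y_REDUCED_TERMS
    if not reduced:
        cols += [ih * dc, m * dc]
        terms = Y_FULL_TERMS
    cols += [data["IB"].to_numpy(float), data["EC"].to_numpy(float)]
    return np.column_stack(cols), data["Y"].to_numpy(float), terms


def fit_model_M(data: pd.DataFrame) -> pd.DataFrame:
    """OLS mediator model: M ~ IH + DC + IH:DC + IB + EC."""
    X, y = _design_M(data)
    _, table = _ols(X, y, M_TERMS)
    return table


def fit_model_Y(data: pd.DataFrame, reduced: bool = True) -> pd.DataFrame:
    """OLS outcome model: Y ~ IH + M + DC [+ IH:DC + M:DC] + IB + EC."""
    X, y, terms = _design_Y(data, reduced)
    _, table = _ols(X, y, terms)
    return table


def mediation_indices(model_m: pd.DataFrame, model_y: pd.DataFrame) -> dict:
    """Paths and indirect effects from fitted M and (reduced) Y tables."""
    cm = model_m.set_index("term")["beta"]
    cy = model_y.set_index("term")["beta"]
    a_loss = float(cm["IH"])
    a_gain = float(cm["IH"] + cm["IH:DC"])
    b = float(cy["M"])
    c_prime = float(cy["IH"])
    return {
        "a_gain": a_gain,
        "a_loss": a_loss,
        "b": b,
        "c_prime": c_prime,
        "ab_gain": a_gain * b,
        "ab_loss": a_loss * b,
        "delta_ab": a_gain * b - a_loss * b,
    }


def _indices_from_arrays(Xm, ym, Xy, yy) -> dict:
    bm = np.linalg.solve(Xm.T @ Xm, Xm.T @ ym)
    by = np.linalg.solve(Xy.T @ Xy, Xy.T @ yy)
    a_loss, a_gain = bm[1], bm[1] + bm[3]
    b, c_prime = by[2], by[1]
    return {
        "a_gain": a_gain,
        "a_loss": a_loss,
        "b": b,
        "c_prime": c_prime,
        "ab_gain": a_gain * b,
        "ab_loss": a_loss * b,
        "delta_ab": (a_gain - a_loss) * b,
    }


def _indices_fast(data: pd.DataFrame) -> dict:
    Xm, ym = _design_M(data)
    Xy, yy, _ = _design_Y(data, reduced=True)
    return _indices_from_arrays(Xm, ym, Xy, yy)


def bootstrap_mediation(
    data: pd.DataFrame,
    B: int = 5000,
    seed: int = 0,
    ci_level: float = 0.95,
    bias_corrected: bool = False,
) -> MediationResult:
    """Cluster bootstrap of the moderated mediation indices.

    ``data`` holds one row per subject x context with columns subject_id,
    context (1 = gain / 0 = loss or the labels), IH, IB, EC, M, Y.  Each
    bootstrap draw resamples whole subjects with replacement, refits models
    M and Y', and recomputes the indices.  Percentile CIs (bias-corrected
    behind the flag) and two-sided sign-proportion p-values.
    """
    if B < 100:
        raise ValueError("B < 100 gives unstable percentile intervals")
    data = data.copy()
    if data["context"].dtype == object:
        data["context"] = data["context"].map({"gain": 1, "loss": 0})
    subjects = data["subject_id"].unique()
    if len(subjects) < 10:
        raise ValueError("need at least 10 subjects")
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    Xm, ym = _design_M(data)
    Xy, yy, _ = _design_Y(data, reduced=True)
    point = _indices_from_arrays(Xm, ym, Xy, yy)
    sub_ids = data["subject_id"].to_numpy()
    row_idx = {s: np.flatnonzero(sub_ids == s) for s in subjects}

    draws = {k: np.empty(B) for k in _STATS}
    n_sub = len(subjects)
    for i in range(B):
        picked = subjects[rng.integers(0, n_sub, size=n_sub)]
        rows = np.concatenate([row_idx[s] for s in picked])
        try:
            idx = _indices_from_arrays(Xm[rows], ym[rows], Xy[rows], yy[rows])
        except np.linalg.LinAlgError:  # pragma: no cover - singular resample
            idx = point
        for k in _STATS:
            draws[k][i] = idx[k]

    alpha = 1.0 - ci_level
    ci: dict = {}
    p: dict = {}
    for k in _STATS:
        d = draws[k]
        if bias_corrected:
            from scipy.stats import norm

            z0 = norm.ppf(np.clip(np.mean(d < point[k]), 1e-6, 1 - 1e-6))
            lo_q = norm.cdf(2 * z0 + norm.ppf(alpha / 2))
            hi_q = norm.cdf(2 * z0 + norm.ppf(1 - alpha / 2))
        else:
            lo_q, hi_q = alpha / 2, 1 - alpha / 2
        ci[k] = (float(np.quantile(d, lo_q)), float(np.quantile(d, hi_q)))
        frac_le = np.mean(d <= 0.0)
        frac_ge = np.mean(d >= 0.0)
        p[k] = float(min(1.0, 2.0 * min(frac_le, frac_ge)))

    return MediationResult(
        estimates={k: float(point[k]) for k in _STATS},
        ci=ci,
        p=p,
        B=B,
        seed=seed,
        ci_level=ci_level,
        model_m=fit_model_M(data),
        model_y=fit_model_Y(data, reduced=True),
    )
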