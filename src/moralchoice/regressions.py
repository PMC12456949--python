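"""Choice-sensitivity and trait regressions.

Two-stage approach: per-subject, per-cell penalized logistic regressions of
choice on the money and shock differences give each subject's sensitivities;
recipient differences of those coefficients ("relative harm/money
sensitivity") are then analyzed at the group level with paired tests and an
8-term trait-by-context ordinary least squares model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.special import expit

__all__ = [
    "CellLogit",
    "TraitRegResult",
    "subject_cell_logit",
    "fit_cell_logits",
    "relative_sensitivities",
    "paired_group_test",
    "trait_regression",
]

_RIDGE = 1e-4
_SEP_NORM = 10.0  # coefficient magnitude beyond which we call it separation

TRAIT_TERMS = (
    "intercept",
    "EC",
    "IH",
    "IB",
    "context",
    "EC:context",
    "IH:context",
    "IB:context",
)


@dataclass(frozen=True)
class CellLogit:
    """Penalized-ML logistic fit of one subject x condition cell."""

    beta0: float
    beta_dm: float
    beta_ds: float
    se_dm: float
    se_ds: float
    converged: bool
    separated: bool
    n: int


@dataclass(frozen=True)
class TraitRegResult:
    """OLS trait-interaction regression in the layout of the trait tables."""

    table: pd.DataFrame  # term, beta, se, t, p
    r_squared: float
    n: int
    df_resid: int

    def coef(self, term: str) -> float:
        return float(self.table.set_index("term").loc[term, "beta"])


def subject_cell_logit(
    choice: np.ndarray,
    delta_m: np.ndarray,
    delta_s: np.ndarray,
    ridge: float = _RIDGE,
) -> CellLogit:
    """Logistic regression of choice on (1, delta_m, delta_s) by Newton.

    A small ridge penalty on the two slopes keeps estimates finite under
    complete separation (flagged, never silently dropped).  Iterates to
    gradient norm < 1e-8.
    """
    y = np.asarray(choice, dtype=float)
    if len(y) < 10:
        raise ValueError("need at least 10 trials in a cell")
    X = np.column_stack(
        [np.ones_like(y), np.asarray(delta_m, float), np.asarray(delta_s, float)]
    )
    pen = np.diag([0.0, ridge, ridge])
    beta = np.zeros(3)
    converged = False
    for _ in range(200):
        eta = X @ beta
        p = expit(eta)
        g = X.T @ (p - y) + pen @ beta
        if np.linalg.norm(g) < 1e-8:
            converged = True
            break
        w = np.clip(p * (1.0 - p), 1e-10, None)
        H = (X * w[:, None]).T @ X + pen
        step = np.linalg.solve(H, g)
        # dampen overshoot on near-separated data
        while np.max(np.abs(step)) > 20.0:
            step /= 2.0
        beta = beta - step
    eta = X @ beta
    p = expit(eta)
    w = np.clip(p * (1.0 - p), 1e-10, None)
    H = (X * w[:, None]).T @ X + pen
    cov = np.linalg.inv(H)
    separated = bool(np.max(np.abs(beta)) > _SEP_NORM)
    return CellLogit(
        beta0=float(beta[0]),
        beta_dm=float(beta[1]),
        beta_ds=float(beta[2]),
        se_dm=float(np.sqrt(cov[1, 1])),
        se_ds=float(np.sqrt(cov[2, 2])),
        converged=converged,
        separated=separated,
        n=len(y),
    )


def fit_cell_logits(choices: pd.DataFrame) -> pd.DataFrame:
    """Per-(subject, treatment, context, recipient) logistic sensitivities."""
    keys = [k for k in ("subject_id", "treatment", "context", "recipient") if k in choices]
    rows = []
    for key, grp in choices.groupby(keys, sort=True):
        fit = subject_cell_logit(
            grp["choice"].to_numpy(), grp["delta_m"].to_numpy(), grp["delta_s"].to_numpy()
        )
        row = dict(zip(keys, key))
        row.update(
            beta_dm=fit.beta_dm,
            beta_ds=fit.beta_ds,
            se_dm=fit.se_dm,
            se_ds=fit.se_ds,
            separated=fit.separated,
            converged=fit.converged,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def relative_sensitivities(cell_logits: pd.DataFrame) -> pd.DataFrame:
    """Recipient contrasts per subject x context (x treatment).

    ``rel_harm_sens``  = other beta_ds - self beta_ds;
    ``rel_money_sens`` = other beta_dm - self beta_dm.
    Subjects missing either recipient cell are skipped.
    """
    keys = [k for k in ("subject_id", "treatment", "context") if k in cell_logits]
    rows = []
    for key, grp in cell_logits.groupby(keys, sort=True):
        g = grp.set_index("recipient")
        if not {"self", "other"}.issubset(g.index):
            continue
        row = dict(zip(keys, key))
        row.update(
            beta_dm_self=float(g.loc["self", "beta_dm"]),
            beta_dm_other=float(g.loc["other", "beta_dm"]),
            beta_ds_self=float(g.loc["self", "beta_ds"]),
            beta_ds_other=float(g.loc["other", "beta_ds"]),
            flags=bool(g["separated"].any() or not g["converged"].all()),
        )
        row["rel_harm_sens"] = row["beta_ds_other"] - row["beta_ds_self"]
        row["rel_money_sens"] = row["beta_dm_other"] - row["beta_dm_self"]
        rows.append(row)
    return pd.DataFrame(rows)


def paired_group_test(values: np.ndarray) -> dict:
    """One-sample t of per-subject contrasts against zero."""
    v = np.asarray(values, dtype=float)
    t, p = sps.ttest_1samp(v, 0.0)
    return {"mean": float(v.mean()), "t": float(t), "p": float(p), "df": len(v) - 1, "n": len(v)}


def _name_collinear(X: np.ndarray, names: tuple[str, ...]) -> list[str]:
    bad = []
    for j in range(X.shape[1]):
        others = np.delete(X, j, axis=1)
        resid = X[:, j] - others @ np.linalg.lstsq(others, X[:, j], rcond=None)[0]
        if np.linalg.norm(resid) < 1e-8 * max(1.0, np.linalg.norm(X[:, j])):
            bad.append(names[j])
    return bad


def trait_regression(data: pd.DataFrame, outcome: str) -> TraitRegResult:
    """OLS of a per-subject-per-context outcome on traits and their context
    interactions.

    ``data`` needs one row per subject x context with columns EC, IH, IB,
    ``context`` coded 1 = gain / 0 = loss, and the outcome column.  The
    design is the fixed 8-term layout (intercept, EC, IH, IB, context and
    the three trait x context products); classical SEs, two-tailed p from
    the t distribution with n - 8 df.
    """
    ctx = data["context"]
    if ctx.dtype == object:
        ctx = ctx.map({"gain": 1, "loss": 0})
    c = ctx.to_numpy(dtype=float)
    y = data[outcome].to_numpy(dtype=float)
    X = np.column_stack(
        [
            np.ones(len(data)),
            data["EC"].to_numpy(float),
            data["IH"].to_numpy(float),
            data["IB"].to_numpy(float),
            c,
            data["EC"].to_numpy(float) * c,
            data["IH"].to_numpy(float) * c,
            data["IB"].to_numpy(float) * c,
        ]
    )
    if np.linalg.matrix_rank(X) < X.shape[1]:
        raise ValueError(
            "rank-deficient trait design; collinear columns: "
            + ", ".join(_name_collinear(X, TRAIT_TERMS))
        )
    beta, _, _, _ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    df = len(y) - X.shape[1]
    if df <= 0:
        raise ValueError("not enough rows for the 8-term design")
    sigma2 = float(resid @ resid) / df
    cov = sigma2 * np.linalg.inv(X.T @ X)
    se = np.sqrt(np.diag(cov))
    t = beta / se
    p = 2.0 * sps.t.sf(np.abs(t), df)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - float(resid @ resid) / tss if tss > 0 else 0.0
    table = pd.DataFrame(
        {"term": TRAIT_TERMS, "beta": beta, "se": se, "t": t, "p": p}
    )
    return TraitRegResult(table=table, r_squared=r2, n=len(y), df_resid=df)
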