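"""Classical statistics reported by the pipeline.

Within-subject ANOVA for fully crossed two-level factors (each effect tested
against its own effect-by-subject error term, so df are (1, n-1)
throughout), simple effects, tie-corrected Friedman tests with Bonferroni
pairwise follow-ups, Cohen's f-squared, and noncentral-F post-hoc power for
multiple-regression F tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "AnovaResult",
    "PowerResult",
    "rm_anova",
    "simple_effect",
    "friedman_test",
    "pairwise_wilcoxon",
    "cohen_f2",
    "regression_posthoc_power",
    "simulated_regression_power",
]


@dataclass(frozen=True)
class AnovaResult:
    table: pd.DataFrame  # effect, ss_effect, ss_error, df1, df2, F, p, partial_eta_sq
    n_subjects: int

    def effect(self, name: str) -> pd.Series:
        return self.table.set_index("effect").loc[name]


@dataclass(frozen=True)
class PowerResult:
    f2: float
    n_predictors: int
    N: int
    alpha: float
    noncentrality: float
    power: float


def _cells_matrix(
    data: pd.DataFrame, dv: str, factors: list[str], subject: str
) -> tuple[np.ndarray, list[tuple], list]:
    """Subjects x cells matrix for a complete, balanced within design."""
    levels = []
    for f in factors:
        lv = sorted(data[f].unique())
        if len(lv) != 2:
            raise ValueError(f"factor {f!r} must have exactly 2 levels, got {lv}")
        levels.append(lv)
    cells = [()]
    for lv in levels:
        cells = [c + (v,) for c in cells for v in lv]
    subjects = sorted(data[subject].unique())
    piv = data.set_index([subject] + factors)[dv]
    mat = np.empty((len(subjects), len(cells)))
    for i, s in enumerate(subjects):
        for j, cell in enumerate(cells):
            try:
                v = piv.loc[(s, *cell)]
            except KeyError:
                raise ValueError(f"missing cell {cell} for subject {s}")
            if np.ndim(v) > 0:
                raise ValueError(f"multiple rows for subject {s}, cell {cell}")
            mat[i, j] = v
    return mat, cells, levels


def rm_anova(
    data: pd.DataFrame,
    dv: str,
    factors: list[str],
    subject: str = "subject_id",
) -> AnovaResult:
    """Repeated-measures ANOVA over 2 or 3 two-level within-subject factors.

    ``data`` holds one value per subject per cell.  For each effect (every
    non-empty factor subset) the per-subject orthogonal contrast is tested
    against its subject-interaction error; partial eta-squared is
    SS_effect / (SS_effect + SS_error).
    """
    if not 1 <= len(factors) <= 3:
        raise ValueError("supports 1-3 within-subject factors")
    mat, cells, levels = _cells_matrix(data, dv, factors, subject)
    n, n_cells = mat.shape
    rows = []
    for r in range(1, len(factors) + 1):
        for combo in combinations(range(len(factors)), r):
            w = np.ones(n_cells)
            for j, cell in enumerate(cells):
                for f in combo:
                    # +1 for the second (higher) level, -1 for the first
                    w[j] *= 1.0 if cell[f] == levels[f][1] else -1.0
            theta_i = mat @ w / n_cells  # per-subject effect contrast
            theta = theta_i.mean()
            ss_eff = n * n_cells * theta**2
            ss_err = n_cells * float(((theta_i - theta) ** 2).sum())
            df1, df2 = 1, n - 1
            F = (ss_eff / df1) / (ss_err / df2) if ss_err > 0 else np.inf
            p = float(sps.f.sf(F, df1, df2))
            rows.append(
                {
                    "effect": " x ".join(factors[f] for f in combo),
                    "ss_effect": ss_eff,
                    "ss_error": ss_err,
                    "df1": df1,
                    "df2": df2,
                    "F": F,
                    "p": p,
                    "partial_eta_sq": ss_eff / (ss_eff + ss_err),
                }
            )
    return AnovaResult(table=pd.DataFrame(rows), n_subjects=n)


def simple_effect(
    data: pd.DataFrame,
    dv: str,
    factor: str,
    within: tuple[str, object],
    subject: str = "subject_id",
) -> pd.Series:
    """Effect of ``factor`` inside one level of a moderator.

    ``within`` is (moderator_name, level).  The subset is analyzed as a
    one-factor repeated-measures ANOVA, so F = paired-t^2 with df (1, n-1).
    """
    mod, level = within
    sub = data[data[mod] == level]
    res = rm_anova(sub, dv, [factor], subject=subject)
    return res.effect(factor)


def friedman_test(ratings: np.ndarray) -> tuple[float, int, float]:
    """Tie-corrected Friedman test on a subjects x conditions matrix."""
    X = np.asarray(ratings, dtype=float)
    n, k = X.shape
    if k < 2:
        raise ValueError("need at least 2 conditions")
    if np.isnan(X).any():
        raise ValueError("incomplete rows are not allowed")
    R = np.apply_along_axis(sps.rankdata, 1, X)
    col_sums = R.sum(axis=0)
    num = (k - 1) * float(((col_sums - n * (k + 1) / 2.0) ** 2).sum())
    den = float((R**2).sum()) - n * k * (k + 1) ** 2 / 4.0
    if den == 0:  # all ranks tied everywhere
        return 0.0, k - 1, 1.0
    chi2 = num / den
    df = k - 1
    return float(chi2), df, float(sps.chi2.sf(chi2, df))


def pairwise_wilcoxon(
    ratings: np.ndarray, bonferroni: bool = True
) -> pd.DataFrame:
    """Wilcoxon signed-rank follow-ups for every condition pair."""
    X = np.asarray(ratings, dtype=float)
    k = X.shape[1]
    n_pairs = k * (k - 1) // 2
    rows = []
    for i, j in combinations(range(k), 2):
        d = X[:, i] - X[:, j]
        if np.all(d == 0):
            stat, p = 0.0, 1.0
        else:
            stat, p = sps.wilcoxon(X[:, i], X[:, j], zero_method="wilcox")
        p_adj = min(1.0, p * n_pairs) if bonferroni else p
        rows.append({"i": i, "j": j, "statistic": float(stat), "p": float(p), "p_adj": p_adj})
    return pd.DataFrame(rows)


def cohen_f2(r_squared: float) -> float:
    """Cohen's effect size f^2 = R^2 / (1 - R^2)."""
    if not 0.0 <= r_squared < 1.0:
        raise ValueError("R^2 must lie in [0, 1)")
    return r_squared / (1.0 - r_squared)


def regression_posthoc_power(
    f2: float, n_predictors: int, N: int, alpha: float = 0.05
) -> PowerResult:
    """Achieved power of a multiple-regression F test via the noncentral F.

    df1 = number of tested predictors, df2 = N - n_predictors - 1,
    noncentrality = f2 * N; power is the probability a noncentral-F variate
    exceeds the central-F critical value at ``alpha``.
    """
    if f2 < 0:
        raise ValueError("f2 must be >= 0")
    df1 = n_predictors
    df2 = N - n_predictors - 1
    if df1 < 1 or df2 < 1:
        raise ValueError("invalid degrees of freedom")
    lam = f2 * N
    crit = sps.f.ppf(1.0 - alpha, df1, df2)
    power = float(sps.ncf.sf(crit, df1, df2, lam)) if lam > 0 else alpha
    return PowerResult(
        f2=f2, n_predictors=n_predictors, N=N, alpha=alpha,
        noncentrality=lam, power=power,
    )


def simulated_regression_power(
    f2: float,
    n_predictors: int,
    N: int,
    alpha: float = 0.05,
    n_sims: int = 100_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo cross-check of :func:`regression_posthoc_power`.

    Simulates Gaussian regressions on a fixed random design whose signal is
    scaled so the exact noncentrality equals f2 * N, and returns the
    rejection rate of the overall F test.
    """
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    df1 = n_predictors
    df2 = N - n_predictors - 1
    X = rng.standard_normal((N, n_predictors))
    Xc = X - X.mean(axis=0)
    beta = rng.standard_normal(n_predictors)
    mu = Xc @ beta
    # scale the signal so ||mu||^2 / sigma^2 equals the target noncentrality
    lam = f2 * N
    if lam > 0:
        mu *= np.sqrt(lam / float(mu @ mu))
    else:
        mu = np.zeros(N)
    Q, _ = np.linalg.qr(np.column_stack([np.ones(N), Xc]))
    crit = sps.f.ppf(1.0 - alpha, df1, df2)
    hits = 0
    chunk = 20_000
    for start in range(0, n_sims, chunk):
        m = min(chunk, n_sims - start)
        Y = mu + rng.standard_normal((m, N))
        fitted = (Y @ Q) @ Q.T
        rss = ((Y - fitted) ** 2).sum(axis=1)
        tss = ((Y - Y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
        F = ((tss - rss) / df1) / (rss / df2)
        hits += int((F > crit).sum())
    return hits / n_sims
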