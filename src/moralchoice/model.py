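"""Softmax harm-aversion choice model and per-subject maximum likelihood.

The model weighs the shock difference against the money difference between
the two options of a trial with a single aversion weight ``kappa`` per
condition cell and maps the weighted value difference to a choice
probability through a logistic with consistency ``gamma``:

    P(less painful option) = 1 / (1 + exp(-gamma * (kappa*ds - (1-kappa)*dm)))

so higher ``kappa`` means more willingness to forgo money to avoid shocks.
Fitting is bounded multi-start MLE (kappa in [0,1], gamma in (0, gamma_max]).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import expit

__all__ = [
    "ModelSpec",
    "FitResult",
    "delta_value",
    "p_less_painful",
    "neg_log_lik",
    "fit_subject",
    "fit_all_subjects",
    "compare_specs",
    "hyperaltruism_index",
]

_CELLS = (
    ("gain", "self"),
    ("gain", "other"),
    ("loss", "self"),
    ("loss", "other"),
)
_PCLIP = 1e-12
_DEFAULT_GAMMA_MAX = 50.0
_BOUNDARY_TOL = 1e-4


@dataclass(frozen=True)
class ModelSpec:
    """How kappa and gamma vary over the condition cells.

    ``kappa_partition`` is fixed to one kappa per (context, recipient) cell
    — the main model.  ``gamma_partition`` is one of ``single`` (the winning
    variant), ``per-context``, or ``per-condition``.
    """

    gamma_partition: str = "single"
    name: str = ""

    def __post_init__(self) -> None:
        if self.gamma_partition not in ("single", "per-context", "per-condition"):
            raise ValueError(f"unknown gamma partition {self.gamma_partition!r}")
        if not self.name:
            object.__setattr__(self, "name", f"kappa-per-cell/gamma-{self.gamma_partition}")

    @property
    def n_gamma(self) -> int:
        return {"single": 1, "per-context": 2, "per-condition": 4}[self.gamma_partition]

    def gamma_index(self, context: np.ndarray, recipient: np.ndarray) -> np.ndarray:
        if self.gamma_partition == "single":
            return np.zeros(len(context), dtype=int)
        if self.gamma_partition == "per-context":
            return (context == "loss").astype(int)
        return np.array(
            [_CELLS.index((c, r)) for c, r in zip(context, recipient)], dtype=int
        )


@dataclass(frozen=True)
class FitResult:
    """Best multi-start MLE solution for one subject (one session)."""

    kappa_hat: dict[tuple[str, str], float]
    gamma_hat: tuple[float, ...]
    neg_log_lik: float
    n_trials: int
    n_params: int
    n_restarts: int
    best_start_index: int
    boundary_flags: dict[str, bool]
    spec: ModelSpec = field(default_factory=ModelSpec)

    @property
    def gamma(self) -> float:
        """Single-gamma convenience accessor."""
        if len(self.gamma_hat) != 1:
            raise ValueError("fit has multiple gamma parameters")
        return self.gamma_hat[0]

    @property
    def aic(self) -> float:
        return 2.0 * self.neg_log_lik + 2.0 * self.n_params

    @property
    def bic(self) -> float:
        return 2.0 * self.neg_log_lik + self.n_params * float(np.log(self.n_trials))

    @property
    def any_boundary(self) -> bool:
        return any(self.boundary_flags.values())


def delta_value(kappa: float, delta_m, delta_s):
    """Value difference of the more painful option: (1-kappa)*dm - kappa*ds."""
    if not 0.0 <= kappa <= 1.0:
        raise ValueError("kappa must lie in [0, 1]")
    return (1.0 - kappa) * np.asarray(delta_m) - kappa * np.asarray(delta_s)


def p_less_painful(kappa: float, gamma: float, delta_m, delta_s):
    """Probability of choosing the less painful option.

    Equals ``expit(gamma * (kappa*ds - (1-kappa)*dm))``; numerically stable
    for arbitrarily large |gamma * value difference|.
    """
    return expit(-gamma * delta_value(kappa, delta_m, delta_s))


def _unpack(choices: pd.DataFrame, spec: ModelSpec):
    dm = choices["delta_m"].to_numpy(dtype=float)
    ds = choices["delta_s"].to_numpy(dtype=float)
    y = choices["choice"].to_numpy(dtype=float)
    ctx = choices["context"].to_numpy()
    rec = choices["recipient"].to_numpy()
    kidx = np.array([_CELLS.index((c, r)) for c, r in zip(ctx, rec)], dtype=int)
    gidx = spec.gamma_index(ctx, rec)
    return dm, ds, y, kidx, gidx


def _nll_and_grad(params, dm, ds, y, kidx, gidx, n_kappa):
    kappa = params[kidx]
    gamma = params[n_kappa + gidx]
    # z = gamma * (kappa*(ds+dm) - dm); p = expit(z)
    sm = ds + dm
    z = gamma * (kappa * sm - dm)
    p = expit(z)
    pc = np.clip(p, _PCLIP, 1.0 - _PCLIP)
    nll = -np.sum(y * np.log(pc) + (1.0 - y) * np.log(1.0 - pc))
    dz = p - y  # d nll / d z
    g = np.zeros_like(params)
    np.add.at(g, kidx, dz * gamma * sm)
    np.add.at(g, n_kappa + gidx, dz * (kappa * sm - dm))
    return nll, g


def neg_log_lik(
    params: np.ndarray, choices: pd.DataFrame, spec: ModelSpec | None = None
) -> float:
    """Negative log likelihood of a (kappa..., gamma...) parameter vector.

    ``params`` holds the four cell kappas in the order gain-self, gain-other,
    loss-self, loss-other, followed by the gamma block of ``spec``.
    Probabilities are clipped to [1e-12, 1 - 1e-12] before the logs.
    """
    spec = spec or ModelSpec()
    if len(choices) == 0:
        raise ValueError("empty choice data")
    params = np.asarray(params, dtype=float)
    dm, ds, y, kidx, gidx = _unpack(choices, spec)
    nll, _ = _nll_and_grad(params, dm, ds, y, kidx, gidx, 4)
    return float(nll)


def fit_subject(
    choices: pd.DataFrame,
    spec: ModelSpec | None = None,
    n_restarts: int = 300,
    rng: np.random.Generator | None = None,
    gamma_max: float = _DEFAULT_GAMMA_MAX,
) -> FitResult:
    """Multi-start bounded MLE for one subject's choices.

    Starts are uniform in the parameter box; the best local solution over
    all restarts is kept.  Parameters landing within tolerance of a bound
    (e.g. for subjects who always choose one option type) are flagged in
    ``boundary_flags`` — excluding such subjects is the caller's policy.
    """
    spec = spec or ModelSpec()
    rng = rng or np.random.default_rng()
    if len(choices) == 0:
        raise ValueError("empty choice data")
    cells_present = {
        (c, r) for c, r in zip(choices["context"], choices["recipient"])
    }
    dm, ds, y, kidx, gidx = _unpack(choices, spec)
    n_kappa = 4
    active_k = np.unique(kidx)
    n_params = len(active_k) + spec.n_gamma

    lo = np.concatenate([np.zeros(n_kappa), np.full(spec.n_gamma, 1e-6)])
    hi = np.concatenate([np.ones(n_kappa), np.full(spec.n_gamma, gamma_max)])
    bounds = list(zip(lo, hi))

    best = None
    best_idx = -1
    for i in range(n_restarts):
        x0 = rng.uniform(lo, hi)
        res = minimize(
            _nll_and_grad,
            x0,
            args=(dm, ds, y, kidx, gidx, n_kappa),
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"ftol": 1e-12, "gtol": 1e-10, "maxiter": 500},
        )
        if best is None or res.fun < best.fun - 0.0:
            best, best_idx = res, i

    x = np.clip(best.x, lo, hi)
    kappa_hat = {
        cell: float(x[j]) for j, cell in enumerate(_CELLS) if cell in cells_present
    }
    gamma_hat = tuple(float(v) for v in x[n_kappa:])
    flags: dict[str, bool] = {}
    for j, cell in enumerate(_CELLS):
        if cell in cells_present:
            flags[f"kappa_{cell[0]}_{cell[1]}"] = bool(
                x[j] <= _BOUNDARY_TOL or x[j] >= 1.0 - _BOUNDARY_TOL
            )
    for j in range(spec.n_gamma):
        v = x[n_kappa + j]
        flags[f"gamma_{j}"] = bool(v <= 1e-6 + _BOUNDARY_TOL or v >= gamma_max - _BOUNDARY_TOL)

    return FitResult(
        kappa_hat=kappa_hat,
        gamma_hat=gamma_hat,
        neg_log_lik=float(best.fun),
        n_trials=len(choices),
        n_params=n_params,
        n_restarts=n_restarts,
        best_start_index=best_idx,
        boundary_flags=flags,
        spec=spec,
    )


def fit_all_subjects(
    choices: pd.DataFrame,
    spec: ModelSpec | None = None,
    n_restarts: int = 300,
    seed: int = 0,
    gamma_max: float = _DEFAULT_GAMMA_MAX,
) -> pd.DataFrame:
    """Fit every (subject, treatment) session in a long choice table.

    Treatments are separate sessions and are fitted independently.  Returns
    one row per session with kappas, gamma, NLL, AIC/BIC and boundary flags.
    """
    spec = spec or ModelSpec()
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    rows = []
    keys = ["subject_id", "treatment"] if "treatment" in choices else ["subject_id"]
    for key, grp in choices.groupby(keys, sort=True):
        fit = fit_subject(grp, spec, n_restarts=n_restarts, rng=rng, gamma_max=gamma_max)
        row = dict(zip(keys, key if isinstance(key, tuple) else (key,)))
        for (c, r), v in fit.kappa_hat.items():
            row[f"kappa_{c}_{r}"] = v
        row.update(
            gamma=fit.gamma_hat[0] if spec.n_gamma == 1 else np.nan,
            nll=fit.neg_log_lik,
            aic=fit.aic,
            bic=fit.bic,
            n_trials=fit.n_trials,
            boundary=fit.any_boundary,
        )
        rows.append(row)
    return pd.DataFrame(rows)


def compare_specs(
    choices: pd.DataFrame,
    specs: list[ModelSpec],
    n_restarts: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Fit several model variants and rank them by summed BIC (then AIC).

    Returns one row per spec with aggregate criteria over all sessions,
    ranked ascending by total BIC.
    """
    if len(specs) < 1:
        raise ValueError("need at least one spec")
    rows = []
    for spec in specs:
        fits = fit_all_subjects(choices, spec, n_restarts=n_restarts, seed=seed)
        rows.append(
            {
                "spec": spec.name,
                "gamma_partition": spec.gamma_partition,
                "total_bic": float(fits["bic"].sum()),
                "total_aic": float(fits["aic"].sum()),
                "total_nll": float(fits["nll"].sum()),
                "n_sessions": len(fits),
            }
        )
    out = pd.DataFrame(rows).sort_values(
        ["total_bic", "total_aic"], kind="stable"
    )
    out["rank"] = np.arange(1, len(out) + 1)
    return out.reset_index(drop=True)


def hyperaltruism_index(fit: FitResult) -> dict[str, float]:
    """Per-context moral preference: kappa_other - kappa_self."""
    out = {}
    for context in ("gain", "loss"):
        try:
            out[context] = fit.kappa_hat[(context, "other")] - fit.kappa_hat[(context, "self")]
        except KeyError as e:
            raise ValueError(f"fit missing cell for context {context!r}") from e
    return out
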