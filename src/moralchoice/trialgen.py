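"""Stimulus construction for the money-pain trade-off task.

Each trial opposes a *more painful* option (more electric shocks, better
money) to a *less painful* option (fewer shocks, worse money).  Trials are
built from a pool of (shock-difference, money-difference) pairs laid out on
fixed grids; a per-condition grid of desired trade-off ratios
``delta_m / (delta_s + delta_m)`` picks the closest pool pair for every
trial.  Loss-context trials are derived from gain-form trials by a
sign-flip-and-swap of the money amounts.

Money is handled internally as integer counts of 0.2-yuan units so that all
grid arithmetic is exact; public fields expose conventional floats.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "MONEY_UNIT",
    "PairPool",
    "DesignTrial",
    "TrialSet",
    "TrialGenConfig",
    "CalibrationCurve",
    "build_pair_pool",
    "ratio_grid",
    "select_pair",
    "instantiate_options",
    "to_loss",
    "build_trialset",
    "fit_rating_curve",
    "intensity_for_rating",
]

#: Smallest money increment, in yuan.
MONEY_UNIT = 0.2

#: Inclusive shock-count bound for either option.
MAX_SHOCKS = 20
#: Inclusive money-magnitude bound for either option, in 0.2-yuan units.
MAX_MONEY_UNITS = 100

CONTEXTS = ("gain", "loss")
RECIPIENTS = ("self", "other")


@dataclass(frozen=True)
class PairPool:
    """Exhaustive pool of candidate (delta_s, delta_m) difference pairs.

    ``delta_m_units`` holds the money difference in 0.2-yuan units
    (1..99, i.e. 0.2..19.8 yuan); ``delta_s`` the shock difference (1..19).
    """

    delta_s: np.ndarray
    delta_m_units: np.ndarray

    def __len__(self) -> int:
        return self.delta_s.size

    @property
    def delta_m(self) -> np.ndarray:
        """Money differences in yuan."""
        return self.delta_m_units * MONEY_UNIT

    @property
    def ratios(self) -> np.ndarray:
        """Trade-off ratio delta_m / (delta_s + delta_m) of every pair."""
        dm = self.delta_m_units / 5.0  # exact: units/5 == units*0.2 on grid
        return dm / (self.delta_s + dm)


@dataclass(frozen=True)
class DesignTrial:
    """One two-option choice trial.

    ``money_*_units`` are signed integer counts of 0.2-yuan units; the
    ``money_more``/``money_less`` properties expose yuan floats.  In the gain
    context both amounts are positive and the more painful option pays more;
    in the loss context both are non-positive and the more painful option
    loses less.
    """

    context: str
    recipient: str
    shocks_more: int
    shocks_less: int
    money_more_units: int
    money_less_units: int
    delta_s: int
    delta_m_units: int
    desired_ratio: float
    side_more: str = "left"

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ValueError(f"unknown context {self.context!r}")
        if self.recipient not in RECIPIENTS:
            raise ValueError(f"unknown recipient {self.recipient!r}")
        if self.shocks_more - self.shocks_less != self.delta_s:
            raise ValueError("shock difference does not match delta_s")
        if self.money_more_units - self.money_less_units != self.delta_m_units:
            raise ValueError("money difference does not match delta_m")
        if not (1 <= self.shocks_less and self.shocks_more <= MAX_SHOCKS):
            raise ValueError("shock counts out of bounds")
        if max(abs(self.money_more_units), abs(self.money_less_units)) > MAX_MONEY_UNITS:
            raise ValueError("money magnitude out of bounds")
        if self.context == "gain" and self.money_less_units < 1:
            raise ValueError("gain-context money must be positive")
        if self.context == "loss" and self.money_more_units > 0:
            raise ValueError("loss-context money must be non-positive")

    @property
    def money_more(self) -> float:
        return self.money_more_units * MONEY_UNIT

    @property
    def money_less(self) -> float:
        return self.money_less_units * MONEY_UNIT

    @property
    def delta_m(self) -> float:
        return self.delta_m_units * MONEY_UNIT


@dataclass(frozen=True)
class TrialGenConfig:
    """Knobs for one session's trial set.

    ``spread_tol`` widens pair selection to near-closest pairs (see
    :func:`select_pair_spread`); ``max_corr`` bounds the realized
    |corr(delta_s, delta_m)| of a generated set via seeded regeneration.
    """

    n_per_cell: int = 60
    ratio_lo: float = 0.01
    ratio_hi: float = 0.99
    spread_tol: float = 0.02
    max_corr: float = 0.1
    max_attempts: int = 60


@dataclass(frozen=True)
class TrialSet:
    """An ordered full-session collection of trials plus its provenance."""

    trials: tuple[DesignTrial, ...]
    seed: int
    config: TrialGenConfig = field(default_factory=TrialGenConfig)
    block_order: tuple[str, ...] = ("gain", "loss")

    def __len__(self) -> int:
        return len(self.trials)

    def to_frame(self) -> pd.DataFrame:
        """Long-format trial table (one row per trial)."""
        rows = []
        for i, t in enumerate(self.trials):
            rows.append(
                {
                    "trial_id": i,
                    "block": self.block_order.index(t.context),
                    "context": t.context,
                    "recipient": t.recipient,
                    "money_more": round(t.money_more, 1),
                    "money_less": round(t.money_less, 1),
                    "shocks_more": t.shocks_more,
                    "shocks_less": t.shocks_less,
                    "delta_m": round(t.delta_m, 1),
                    "delta_s": t.delta_s,
                    "desired_ratio": t.desired_ratio,
                    "side_more": t.side_more,
                }
            )
        return pd.DataFrame(rows)


def build_pair_pool() -> PairPool:
    """Enumerate the full Cartesian grid of difference pairs.

    Shock differences run over 1..19 and money differences over
    0.2..19.8 yuan in 0.2 steps, giving 19 x 99 = 1881 distinct pairs,
    ordered delta_s-major then delta_m.
    """
    ds = np.repeat(np.arange(1, 20), 99)
    dm_units = np.tile(np.arange(1, 100), 19)
    return PairPool(delta_s=ds, delta_m_units=dm_units)


def ratio_grid(n: int, lo: float = 0.01, hi: float = 0.99) -> np.ndarray:
    """``n`` evenly spaced desired trade-off ratios from ``lo`` to ``hi``."""
    if n < 2:
        raise ValueError("need at least 2 grid points")
    if not (0 <= lo < hi <= 1):
        raise ValueError("require 0 <= lo < hi <= 1")
    return np.linspace(lo, hi, n)


def select_pair(
    ratio: float, pool: PairPool, rng: np.random.Generator
) -> tuple[int, int]:
    """Pick the pool pair whose trade-off ratio is closest to ``ratio``.

    Exact-distance ties (e.g. ratio 0.5, matched by every pair with
    delta_m == delta_s) are broken by a uniform draw from the tied set.
    Returns ``(delta_s, delta_m_units)``.
    """
    if len(pool) == 0:
        raise ValueError("empty pair pool")
    dist = np.abs(pool.ratios - ratio)
    tied = np.flatnonzero(dist == dist.min())
    idx = tied[0] if tied.size == 1 else rng.choice(tied)
    return int(pool.delta_s[idx]), int(pool.delta_m_units[idx])


def select_pair_spread(
    ratio: float, pool: PairPool, rng: np.random.Generator, tol: float = 0.02
) -> tuple[int, int]:
    """Draw a pair uniformly from the near-closest set, spread over delta_s.

    All pairs whose trade-off ratio lies within ``tol`` of the best
    achievable distance qualify; a qualifying delta_s level is drawn
    uniformly first, then a qualifying delta_m within it.  The
    stratification stops high-resolution delta_s rows from dominating, so
    stimulus magnitudes vary across trials and delta_s stays nearly
    uncorrelated with delta_m over a session (``tol=0`` reduces to
    :func:`select_pair`).
    """
    if len(pool) == 0:
        raise ValueError("empty pair pool")
    if tol <= 0:
        return select_pair(ratio, pool, rng)
    # pool is delta_s-major: rows are the 19 delta_s levels
    n_ds = np.unique(pool.delta_s).size
    dist = np.abs(pool.ratios - ratio).reshape(n_ds, -1)
    ok = dist <= dist.min() + tol
    rows = np.flatnonzero(ok.any(axis=1))
    i = int(rows[rng.integers(len(rows))])
    cols = np.flatnonzero(ok[i])
    j = int(cols[rng.integers(len(cols))])
    flat = i * dist.shape[1] + j
    return int(pool.delta_s[flat]), int(pool.delta_m_units[flat])


def instantiate_options(
    pair: tuple[int, int],
    context: str,
    rng: np.random.Generator,
    recipient: str = "self",
    desired_ratio: float = float("nan"),
) -> DesignTrial:
    """Draw concrete option magnitudes for a difference pair.

    The less painful option's shock count is uniform on the integers with
    ``shocks_less + delta_s <= 20`` and its money amount uniform on the
    0.2-grid with ``money_less + delta_m <= 20`` (the bounds are inclusive
    so the extreme pairs of the pool stay realizable); the more painful
    option is computed additively.  Loss trials are built in gain form and
    passed through :func:`to_loss`.
    """
    ds, dm_units = pair
    s_hi = MAX_SHOCKS - ds
    m_hi = MAX_MONEY_UNITS - dm_units
    if s_hi < 1 or m_hi < 1:
        raise ValueError(f"pair {pair} leaves no feasible option magnitudes")
    s_less = int(rng.integers(1, s_hi + 1))
    m_less_units = int(rng.integers(1, m_hi + 1))
    trial = DesignTrial(
        context="gain",
        recipient=recipient,
        shocks_more=s_less + ds,
        shocks_less=s_less,
        money_more_units=m_less_units + dm_units,
        money_less_units=m_less_units,
        delta_s=ds,
        delta_m_units=dm_units,
        desired_ratio=desired_ratio,
    )
    if context == "loss":
        trial = to_loss(trial)
    elif context != "gain":
        raise ValueError(f"unknown context {context!r}")
    return trial


def to_loss(trial: DesignTrial) -> DesignTrial:
    """Gain -> loss transform: negate money amounts, then swap them.

    Shocks are untouched and (delta_s, delta_m) are preserved, so e.g.
    [+15.0 & 10 shocks; +10.0 & 5 shocks] becomes
    [-10.0 & 10 shocks; -15.0 & 5 shocks].
    """
    if trial.context != "gain":
        raise ValueError("to_loss expects a gain-context trial")
    return replace(
        trial,
        context="loss",
        money_more_units=-trial.money_less_units,
        money_less_units=-trial.money_more_units,
    )


def build_trialset(
    config: TrialGenConfig | None = None, seed: int = 0
) -> TrialSet:
    """Generate one full session: ``n_per_cell`` trials per context x recipient.

    Per cell, the desired-ratio grid drives pair selection; trial order and
    the screen side of the more painful option are randomized within each
    block, and block order (gain/loss first) is randomized per seed.  Fully
    reproducible: identical ``(config, seed)`` gives an identical set.
    """
    config = config or TrialGenConfig()
    pool = build_pair_pool()
    ratios = ratio_grid(config.n_per_cell, config.ratio_lo, config.ratio_hi)

    # seeded regeneration until delta_s/delta_m are decorrelated enough;
    # each attempt uses an independent child stream of the same seed
    best_blocks, best_rng, best_corr = None, None, np.inf
    for attempt in range(config.max_attempts):
        rng = np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(attempt,)))
        blocks: dict[str, list[DesignTrial]] = {c: [] for c in CONTEXTS}
        for context in CONTEXTS:
            for recipient in RECIPIENTS:
                for r in ratios:
                    pair = select_pair_spread(r, pool, rng, tol=config.spread_tol)
                    blocks[context].append(
                        instantiate_options(
                            pair, context, rng, recipient=recipient, desired_ratio=float(r)
                        )
                    )
        all_trials = [t for b in blocks.values() for t in b]
        corr = abs(
            np.corrcoef(
                [t.delta_s for t in all_trials], [t.delta_m_units for t in all_trials]
            )[0, 1]
        )
        if corr < best_corr:
            best_blocks, best_rng, best_corr = blocks, rng, corr
        if corr <= config.max_corr:
            break
    blocks, rng = best_blocks, best_rng

    block_order = ("gain", "loss") if rng.random() < 0.5 else ("loss", "gain")
    trials: list[DesignTrial] = []
    for context in block_order:
        block = blocks[context]
        order = rng.permutation(len(block))
        sides = rng.integers(0, 2, size=len(block))
        for j, k in enumerate(order):
            trials.append(
                replace(block[k], side_more="left" if sides[j] == 0 else "right")
            )
    return TrialSet(
        trials=tuple(trials), seed=seed, config=config, block_order=block_order
    )


@dataclass(frozen=True)
class CalibrationCurve:
    """Fitted pain-rating sigmoid: rating = ceiling / (1 + exp(-(x - midpoint)/width))."""

    midpoint: float
    width: float
    rating_ceiling: float = 10.0
    converged: bool = True


def _sigmoid(x: np.ndarray, midpoint: float, width: float, ceiling: float) -> np.ndarray:
    return ceiling / (1.0 + np.exp(-(x - midpoint) / width))


def fit_rating_curve(
    intensities: Sequence[float], ratings: Sequence[float], ceiling: float = 10.0
) -> CalibrationCurve:
    """Least-squares fit of the rating sigmoid to calibration data.

    Degenerate data (fit failure / non-finite estimates) yields a result
    flagged ``converged=False`` rather than a silent fallback.
    """
    x = np.asarray(intensities, dtype=float)
    y = np.asarray(ratings, dtype=float)
    if np.unique(x).size < 4:
        raise ValueError("need ratings at >= 4 distinct intensities")
    if np.any((y < 0) | (y > ceiling)):
        raise ValueError(f"ratings must lie in [0, {ceiling}]")
    span = max(x.max() - x.min(), 1e-6)
    p0 = (float(np.median(x)), span / 4.0)
    try:
        popt, _ = curve_fit(
            lambda xx, m, w: _sigmoid(xx, m, w, ceiling),
            x,
            y,
            p0=p0,
            bounds=([x.min() - 10 * span, 1e-8], [x.max() + 10 * span, 100 * span]),
            maxfev=10000,
        )
        midpoint, width = float(popt[0]), float(popt[1])
        ok = np.isfinite(midpoint) and np.isfinite(width) and width > 0
    except RuntimeError:
        midpoint, width, ok = p0[0], p0[1], False
    return CalibrationCurve(
        midpoint=midpoint, width=width, rating_ceiling=ceiling, converged=ok
    )


def intensity_for_rating(curve: CalibrationCurve, level: float) -> float:
    """Invert the fitted sigmoid: stimulus intensity giving ``level``."""
    c = curve.rating_ceiling
    if not (0 < level < c):
        raise ValueError(f"level must lie strictly inside (0, {c})")
    return curve.midpoint + curve.width * float(np.log(level / (c - level)))
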