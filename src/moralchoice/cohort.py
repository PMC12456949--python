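"""Synthetic cohorts with the study's statistical structure.

Generates trait profiles, per-subject generative parameters (harm-aversion
weights, choice consistency, harm-framing reports), and simulated choice
tables, so the whole downstream pipeline is exercisable without any real
data.  The default configuration encodes the qualitative target pattern:

* hyperaltruism (kappa_other > kappa_self) in the gain context under
  placebo, absent in the loss context, restored in the loss context under
  oxytocin;
* an IH -> harm-framing -> relative-harm-sensitivity mediation chain whose
  IH path is active in the gain context under placebo and in both contexts
  under oxytocin (moderated mediation).

All randomness flows from one master seed through named child streams
(traits, truth, trials, choices) so each component can be regenerated
independently.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .trialgen import TrialGenConfig, TrialSet, build_trialset

__all__ = [
    "TraitConfig",
    "CohortConfig",
    "TraitProfile",
    "SubjectTruth",
    "StudyData",
    "sample_traits",
    "sample_subject_truth",
    "simulate_choices",
    "generate_study",
]

TREATMENTS = ("placebo", "oxytocin")
_STREAMS = ("traits", "truth", "trials", "choices")


@dataclass(frozen=True)
class TraitConfig:
    """Marginal moments, scale bounds and correlations of the trait battery.

    IH and IB are 1-7 item averages, EC a 1-5 item average; draws come from
    a truncated multivariate normal respecting the bounds.
    """

    ih_mean: float = 3.4
    ih_sd: float = 1.0
    ib_mean: float = 3.6
    ib_sd: float = 0.9
    ec_mean: float = 3.6
    ec_sd: float = 0.55
    corr_ec_ih: float = -0.35
    corr_ec_ib: float = 0.35
    corr_ih_ib: float = -0.10

    def correlation(self) -> np.ndarray:
        """Order: (IH, IB, EC)."""
        return np.array(
            [
                [1.0, self.corr_ih_ib, self.corr_ec_ih],
                [self.corr_ih_ib, 1.0, self.corr_ec_ib],
                [self.corr_ec_ih, self.corr_ec_ib, 1.0],
            ]
        )


@dataclass(frozen=True)
class CohortConfig:
    """Generative parameters for a synthetic cohort.

    ``framing_intercept`` sets the mean harm-framing report per
    (context, treatment); ``framing_ih_slope`` is the IH path, active only
    where ``ih_path_active`` says so (gain under placebo; both contexts
    under oxytocin).  ``kappa_framing_slope`` carries framing into the
    other-vs-self kappa gap, making the mediation chain recoverable by
    construction.
    """

    n_subjects: int = 46
    study: str = "study2"  # "study1": single session; "study2": two sessions
    traits: TraitConfig = field(default_factory=TraitConfig)

    kappa_self_logit_mean: float = -0.4  # kappa_self ~ 0.40 on average
    kappa_self_logit_sd: float = 0.5
    kappa_other_noise_sd: float = 0.04

    framing_intercept: dict = field(
        default_factory=lambda: {
            ("gain", "placebo"): 1.5,
            ("loss", "placebo"): 0.0,
            ("gain", "oxytocin"): 1.8,
            ("loss", "oxytocin"): 1.5,
        }
    )
    framing_ih_slope: float = -0.75
    ih_path_active: dict = field(
        default_factory=lambda: {
            ("gain", "placebo"): 1.0,
            ("loss", "placebo"): 0.0,
            ("gain", "oxytocin"): 1.0,
            ("loss", "oxytocin"): 1.0,
        }
    )
    framing_noise_sd: float = 1.0
    kappa_framing_slope: float = 0.04

    gamma_log_mean: float = 0.0  # lognormal: median gamma = 1
    gamma_log_sd: float = 0.3

    trialgen: TrialGenConfig = field(default_factory=TrialGenConfig)

    def __post_init__(self) -> None:
        if self.study not in ("study1", "study2"):
            raise ValueError(f"unknown study mode {self.study!r}")
        for sd in (
            self.kappa_self_logit_sd,
            self.kappa_other_noise_sd,
            self.framing_noise_sd,
            self.gamma_log_sd,
        ):
            if sd < 0:
                raise ValueError("noise SDs must be >= 0")

    @property
    def treatments(self) -> tuple[str, ...]:
        return ("placebo",) if self.study == "study1" else TREATMENTS

    @classmethod
    def null(cls, **kw) -> "CohortConfig":
        """A no-effect configuration: every downstream effect centred on zero."""
        zero_i = {k: 0.0 for k in (("gain", "placebo"), ("loss", "placebo"),
                                   ("gain", "oxytocin"), ("loss", "oxytocin"))}
        base = dict(
            framing_intercept=dict(zero_i),
            ih_path_active=dict(zero_i),
            framing_ih_slope=0.0,
            kappa_framing_slope=0.0,
            traits=TraitConfig(corr_ec_ih=0.0, corr_ec_ib=0.0, corr_ih_ib=0.0),
        )
        base.update(kw)
        return cls(**base)


@dataclass(frozen=True)
class TraitProfile:
    IH: float
    IB: float
    EC: float


@dataclass(frozen=True)
class SubjectTruth:
    """A simulated subject's generative parameters."""

    subject_id: int
    traits: TraitProfile
    kappa: dict  # (context, recipient, treatment) -> kappa in [0, 1]
    gamma: dict  # treatment -> gamma > 0
    framing: dict  # (context, treatment) -> int in [-4, 4]


@dataclass(frozen=True)
class StudyData:
    """All tables for one simulated study, cross-referenced by subject_id."""

    config: CohortConfig
    seed: int
    trialsets: dict  # (subject_id, treatment) -> TrialSet
    choices: pd.DataFrame
    traits: pd.DataFrame
    framing: pd.DataFrame
    truth: pd.DataFrame


def _streams(seed: int) -> dict[str, np.random.Generator]:
    children = np.random.SeedSequence(seed).spawn(len(_STREAMS))
    return {name: np.random.default_rng(ss) for name, ss in zip(_STREAMS, children)}


def sample_traits(
    n: int, config: TraitConfig, rng: np.random.Generator
) -> list[TraitProfile]:
    """Draw trait profiles from a bounds-truncated multivariate normal."""
    corr = config.correlation()
    eig = np.linalg.eigvalsh(corr)
    if eig.min() < -1e-10:
        raise ValueError("trait correlation matrix is not positive semidefinite")
    if n == 0:
        return []
    sds = np.array([config.ih_sd, config.ib_sd, config.ec_sd])
    means = np.array([config.ih_mean, config.ib_mean, config.ec_mean])
    cov = corr * np.outer(sds, sds)
    lo = np.array([1.0, 1.0, 1.0])
    hi = np.array([7.0, 7.0, 5.0])
    out = np.empty((0, 3))
    while out.shape[0] < n:
        draw = rng.multivariate_normal(means, cov, size=max(2 * n, 16), method="svd")
        ok = np.all((draw >= lo) & (draw <= hi), axis=1)
        out = np.vstack([out, draw[ok]])
    out = out[:n]
    return [TraitProfile(IH=float(r[0]), IB=float(r[1]), EC=float(r[2])) for r in out]


def sample_subject_truth(
    subject_id: int,
    traits: TraitProfile,
    config: CohortConfig,
    rng: np.random.Generator,
) -> SubjectTruth:
    """Draw one subject's kappas, gamma(s) and framing reports.

    Framing is generated before kappa_other (the mediator is causally
    upstream): framing = clamp(round(intercept + slope*centred_IH*active
    + noise), -4, 4); then kappa_other = clamp(kappa_self +
    slope_F*framing + noise, 0, 1).
    """
    ih_c = traits.IH - config.traits.ih_mean
    kappa: dict = {}
    framing: dict = {}
    gamma: dict = {}
    for treatment in config.treatments:
        gamma[treatment] = float(
            np.exp(rng.normal(config.gamma_log_mean, config.gamma_log_sd))
        )
        for context in ("gain", "loss"):
            key = (context, treatment)
            f = (
                config.framing_intercept[key]
                + config.framing_ih_slope * ih_c * config.ih_path_active[key]
                + rng.normal(0.0, config.framing_noise_sd)
            )
            f_int = int(np.clip(np.round(f), -4, 4))
            framing[key] = f_int
            k_self = float(
                expit(rng.normal(config.kappa_self_logit_mean, config.kappa_self_logit_sd))
            )
            k_other = float(
                np.clip(
                    k_self
                    + config.kappa_framing_slope * f_int
                    + rng.normal(0.0, config.kappa_other_noise_sd),
                    0.0,
                    1.0,
                )
            )
            kappa[(context, "self", treatment)] = k_self
            kappa[(context, "other", treatment)] = k_other
    return SubjectTruth(
        subject_id=subject_id, traits=traits, kappa=kappa, gamma=gamma, framing=framing
    )


def simulate_choices(
    subject: SubjectTruth,
    trialset: TrialSet,
    treatment: str,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Bernoulli choice simulation of one session.

    choice = 1 codes the less painful option, drawn with
    P = expit(gamma * (kappa*ds - (1-kappa)*dm)) per trial.
    """
    g = subject.gamma[treatment]
    rows = trialset.to_frame()
    kappa = np.array(
        [subject.kappa[(c, r, treatment)] for c, r in zip(rows["context"], rows["recipient"])]
    )
    dm = rows["delta_m"].to_numpy(float)
    ds = rows["delta_s"].to_numpy(float)
    p = expit(g * (kappa * ds - (1.0 - kappa) * dm))
    rows = rows[["trial_id", "context", "recipient", "delta_m", "delta_s"]].copy()
    rows.insert(0, "treatment", treatment)
    rows.insert(0, "subject_id", subject.subject_id)
    rows["choice"] = (rng.random(len(rows)) < p).astype(int)
    return rows


def generate_study(config: CohortConfig | None = None, seed: int = 0) -> StudyData:
    """Simulate a full study: trials, truths, choices, trait/framing tables.

    Study-2 mode produces two sessions per subject (placebo, oxytocin) with
    session order counterbalanced by subject parity; each session gets its
    own randomly generated trial set.  Byte-reproducible from ``seed``.
    """
    config = config or CohortConfig()
    rngs = _streams(seed)
    n = config.n_subjects
    traits = sample_traits(n, config.traits, rngs["traits"])
    truths = [
        sample_subject_truth(i, t, config, rngs["truth"]) for i, t in enumerate(traits)
    ]

    trial_seeds = rngs["trials"].integers(0, 2**31 - 1, size=(n, len(config.treatments)))
    trialsets: dict = {}
    choice_frames = []
    for i, subj in enumerate(truths):
        order = list(config.treatments)
        if config.study == "study2" and i % 2 == 1:
            order = order[::-1]
        for j, treatment in enumerate(order):
            ts = build_trialset(config.trialgen, seed=int(trial_seeds[i, j]))
            trialsets[(subj.subject_id, treatment)] = ts
            choice_frames.append(
                simulate_choices(subj, ts, treatment, rngs["choices"])
            )
    choices = pd.concat(choice_frames, ignore_index=True)

    trait_rows = [
        {"subject_id": s.subject_id, "IH": s.traits.IH, "IB": s.traits.IB, "EC": s.traits.EC}
        for s in truths
    ]
    framing_rows = [
        {
            "subject_id": s.subject_id,
            "treatment": tr,
            "context": ctx,
            "framing": s.framing[(ctx, tr)],
        }
        for s in truths
        for (ctx, tr) in s.framing
    ]
    truth_rows = []
    for s in truths:
        for tr in config.treatments:
            row = {
                "subject_id": s.subject_id,
                "treatment": tr,
                "gamma": s.gamma[tr],
            }
            for ctx in ("gain", "loss"):
                for rec in ("self", "other"):
                    row[f"kappa_{ctx}_{rec}"] = s.kappa[(ctx, rec, tr)]
            truth_rows.append(row)

    return StudyData(
        config=config,
        seed=seed,
        trialsets=trialsets,
        choices=choices,
        traits=pd.DataFrame(trait_rows),
        framing=pd.DataFrame(framing_rows),
        truth=pd.DataFrame(truth_rows),
    )
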