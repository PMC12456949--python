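"""Pipeline orchestration: config (de)serialization, table validation,
stage execution and the run manifest.

Stage order mirrors the analysis chain: trials -> simulated choices ->
per-session model fits -> sensitivity logits -> trait regressions ->
moderated mediation -> within-subject ANOVA / Friedman / power report.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__, cohort, mediation, model, regressions, stats
from .trialgen import TrialGenConfig

__all__ = [
    "PipelineConfig",
    "RunManifest",
    "load_config",
    "save_config",
    "config_to_dict",
    "config_from_dict",
    "validate_tables",
    "run_pipeline",
]

log = logging.getLogger("moralchoice")

_PROFILES = {"ci": {"restarts": 50, "bootstrap_B": 1000},
             "full": {"restarts": 300, "bootstrap_B": 5000}}


@dataclass(frozen=True)
class PipelineConfig:
    """Everything needed for one reproducible end-to-end run."""

    cohort: cohort.CohortConfig = field(default_factory=cohort.CohortConfig)
    restarts: int = 50
    gamma_max: float = 50.0
    bootstrap_B: int = 1000
    seed: int = 0
    profile: str = "ci"

    @classmethod
    def with_profile(cls, profile: str, **kw) -> "PipelineConfig":
        if profile not in _PROFILES:
            raise ValueError(f"unknown profile {profile!r}")
        merged = dict(_PROFILES[profile], profile=profile)
        merged.update(kw)
        return cls(**merged)


@dataclass(frozen=True)
class RunManifest:
    config_hash: str
    version: str
    seed: int
    checksums: dict
    started: float
    finished: float


def _key_str(k: tuple[str, str]) -> str:
    return f"{k[0]}:{k[1]}"


def _key_tuple(s: str) -> tuple[str, str]:
    a, b = s.split(":")
    return a, b


def config_to_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    cc = d["cohort"]
    for key in ("framing_intercept", "ih_path_active"):
        cc[key] = {_key_str(k): v for k, v in cc[key].items()}
    return d


def config_from_dict(d: dict) -> PipelineConfig:
    d = dict(d)
    cc = dict(d.pop("cohort", {}))
    for key in ("framing_intercept", "ih_path_active"):
        if key in cc:
            cc[key] = {_key_tuple(k): float(v) for k, v in cc[key].items()}
    if "traits" in cc:
        cc["traits"] = cohort.TraitConfig(**cc["traits"])
    if "trialgen" in cc:
        cc["trialgen"] = TrialGenConfig(**cc["trialgen"])
    return PipelineConfig(cohort=cohort.CohortConfig(**cc), **d)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config_to_dict(cfg), sort_keys=True))


def load_config(path: str | Path) -> PipelineConfig:
    return config_from_dict(yaml.safe_load(Path(path).read_text()))


def _config_hash(cfg: PipelineConfig) -> str:
    blob = json.dumps(config_to_dict(cfg), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# validation

_RANGE_CHECKS = {
    "choices.csv": {
        "choice": (0, 1),
        "delta_s": (1, 19),
        "delta_m": (0.2, 19.8),
    },
    "traits.csv": {"IH": (1, 7), "IB": (1, 7), "EC": (1, 5)},
    "framing.csv": {"framing": (-4, 4)},
    "fits.csv": {
        "kappa_gain_self": (0, 1),
        "kappa_gain_other": (0, 1),
        "kappa_loss_self": (0, 1),
        "kappa_loss_other": (0, 1),
    },
}

_REQUIRED_COLUMNS = {
    "choices.csv": ["subject_id", "trial_id", "context", "recipient", "delta_m", "delta_s", "choice"],
    "traits.csv": ["subject_id", "IH", "IB", "EC"],
    "framing.csv": ["subject_id", "context", "framing"],
}


def validate_tables(out_dir: str | Path) -> list[dict]:
    """Schema, range and referential-integrity checks over a run directory.

    Returns a list of violation records (empty when everything passes);
    each names the file, column and offending row numbers.
    """
    out_dir = Path(out_dir)
    violations: list[dict] = []
    frames: dict[str, pd.DataFrame] = {}
    for name in ("choices.csv", "traits.csv", "framing.csv", "fits.csv"):
        path = out_dir / name
        if not path.exists():
            if name != "fits.csv":
                violations.append({"file": name, "error": "missing file"})
            continue
        df = pd.read_csv(path)
        frames[name] = df
        for col in _REQUIRED_COLUMNS.get(name, []):
            if col not in df.columns:
                violations.append({"file": name, "column": col, "error": "missing column"})
        for col, (lo, hi) in _RANGE_CHECKS.get(name, {}).items():
            if col not in df.columns:
                continue
            bad = df.index[(df[col] < lo) | (df[col] > hi) | df[col].isna()].tolist()
            if bad:
                violations.append(
                    {"file": name, "column": col, "error": f"out of range [{lo}, {hi}]",
                     "rows": bad[:20], "n_bad": len(bad)}
                )
    if "choices.csv" in frames and "traits.csv" in frames:
        known = set(frames["traits.csv"]["subject_id"])
        bad = frames["choices.csv"].index[
            ~frames["choices.csv"]["subject_id"].isin(known)
        ].tolist()
        if bad:
            violations.append(
                {"file": "choices.csv", "column": "subject_id",
                 "error": "references unknown subject", "rows": bad[:20], "n_bad": len(bad)}
            )
    return violations


# ---------------------------------------------------------------------------
# stages


def _mediation_data(
    sens: pd.DataFrame, traits: pd.DataFrame, framing: pd.DataFrame, treatment: str
) -> pd.DataFrame:
    sens = sens[~sens["flags"]]  # separated/degenerate cells flagged upstream
    s = sens[sens["treatment"] == treatment] if "treatment" in sens else sens
    f = framing[framing["treatment"] == treatment] if "treatment" in framing else framing
    merged = s.merge(f, on=["subject_id", "context"]).merge(traits, on="subject_id")
    out = merged[["subject_id", "context", "IH", "IB", "EC"]].copy()
    out["M"] = merged["framing"].astype(float)
    out["Y"] = merged["rel_harm_sens"]
    out["context"] = out["context"].map({"gain": 1, "loss": 0})
    return out


def run_pipeline(config: PipelineConfig, out_dir: str | Path) -> RunManifest:
    """Execute all stages and write every output table plus the manifest.

    Deterministic given (config, seed): rerunning into a fresh directory
    reproduces identical file checksums.
    """
    t0 = time.time()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    cc = config.cohort

    log.info("stage 1/6: simulating cohort (n=%d, %s)", cc.n_subjects, cc.study)
    study = cohort.generate_study(cc, seed=config.seed)
    study.choices.to_csv(out / "choices.csv", index=False)
    study.traits.to_csv(out / "traits.csv", index=False)
    study.framing.to_csv(out / "framing.csv", index=False)
    study.truth.to_csv(out / "truth.csv", index=False)

    log.info("stage 2/6: fitting harm-aversion model (%d restarts)", config.restarts)
    fits = model.fit_all_subjects(
        study.choices, n_restarts=config.restarts, seed=config.seed + 1,
        gamma_max=config.gamma_max,
    )
    fits.to_csv(out / "fits.csv", index=False)

    log.info("stage 3/6: sensitivity logits")
    cell_logits = regressions.fit_cell_logits(study.choices)
    sens = regressions.relative_sensitivities(cell_logits)
    sens.to_csv(out / "sensitivities.csv", index=False)

    log.info("stage 4/6: trait regressions")
    fits_long = fits.melt(
        id_vars=[c for c in ("subject_id", "treatment") if c in fits],
        value_vars=[c for c in fits.columns if c.startswith("kappa_")],
    )
    parts = fits_long["variable"].str.split("_", expand=True)
    fits_long["context"], fits_long["recipient"] = parts[1], parts[2]
    kap = fits_long.pivot_table(
        index=[c for c in ("subject_id", "treatment", "context") if c in fits_long],
        columns="recipient", values="value",
    ).reset_index()
    kap["hyperaltruism"] = kap["other"] - kap["self"]

    trait_reg: dict = {}
    for treatment in cc.treatments:
        h = kap[kap["treatment"] == treatment] if "treatment" in kap else kap
        h = h.merge(study.traits, on="subject_id")
        s = sens[sens["treatment"] == treatment] if "treatment" in sens else sens
        s = s[~s["flags"]].merge(study.traits, on="subject_id")
        trait_reg[treatment] = {
            "hyperaltruism": regressions.trait_regression(h, "hyperaltruism"),
            "rel_harm_sens": regressions.trait_regression(s, "rel_harm_sens"),
            "rel_money_sens": regressions.trait_regression(s, "rel_money_sens"),
        }
    (out / "trait_regressions.json").write_text(
        json.dumps(
            {
                tr: {
                    k: {"table": v.table.to_dict("records"), "r_squared": v.r_squared, "n": v.n}
                    for k, v in d.items()
                }
                for tr, d in trait_reg.items()
            },
            indent=2,
        )
    )

    log.info("stage 5/6: moderated mediation (B=%d)", config.bootstrap_B)
    med_results: dict = {}
    if cc.study == "study2":
        for treatment in cc.treatments:
            data = _mediation_data(sens, study.traits, study.framing, treatment)
            res = mediation.bootstrap_mediation(
                data, B=config.bootstrap_B, seed=config.seed + 2
            )
            med_results[treatment] = res
            (out / f"mediation_{treatment}.json").write_text(
                json.dumps(
                    {
                        "estimates": res.estimates,
                        "ci": {k: list(v) for k, v in res.ci.items()},
                        "p": res.p,
                        "B": res.B,
                        "seed": res.seed,
                        "model_M": res.model_m.to_dict("records"),
                        "model_Y_reduced": res.model_y.to_dict("records"),
                    },
                    indent=2,
                )
            )

    log.info("stage 6/6: ANOVA / Friedman / power report")
    report: dict = {"n_subjects": cc.n_subjects, "study": cc.study}
    factors = ["context", "recipient"] + (["treatment"] if cc.study == "study2" else [])
    kappa_long = fits_long.rename(columns={"value": "kappa"})
    anova = stats.rm_anova(kappa_long, "kappa", factors)
    report["anova_kappa"] = anova.table.to_dict("records")
    hyper_means = (
        kap.groupby([c for c in ("treatment", "context") if c in kap])["hyperaltruism"]
        .agg(["mean", "count"])
        .reset_index()
    )
    report["hyperaltruism_mean"] = hyper_means.to_dict("records")
    if cc.study == "study2":
        piv = study.framing.pivot_table(
            index="subject_id", columns=["treatment", "context"], values="framing"
        )
        chi2, df_, p_ = stats.friedman_test(piv.to_numpy())
        report["friedman_framing"] = {"chi2": chi2, "df": df_, "p": p_}
        report["power"] = {}
        for treatment in cc.treatments:
            r2 = trait_reg[treatment]["rel_harm_sens"].r_squared
            f2 = stats.cohen_f2(r2)
            pw = stats.regression_posthoc_power(f2, 7, cc.n_subjects, 0.05)
            report["power"][treatment] = {"r_squared": r2, "f2": f2, "power": pw.power}
        report["mediation_sign_pattern"] = {
            tr: {k: med_results[tr].estimates[k] for k in ("ab_gain", "ab_loss", "delta_ab")}
            for tr in med_results
        }
    (out / "stats_report.json").write_text(json.dumps(report, indent=2))

    checksums = {
        p.name: _sha256(p)
        for p in sorted(out.iterdir())
        if p.suffix in (".csv", ".json") and p.name != "manifest.json"
    }
    manifest = RunManifest(
        config_hash=_config_hash(config),
        version=__version__,
        seed=config.seed,
        checksums=checksums,
        started=t0,
        finished=time.time(),
    )
    (out / "manifest.json").write_text(
        json.dumps(dataclasses.asdict(manifest), indent=2)
    )
    violations = validate_tables(out)
    if violations:
        raise RuntimeError(f"output validation failed: {violations[:3]}")
    return manifest
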