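"""File formats, run configuration and the staged pipeline.

Everything on disk is plain text: trial data and all tabular artifacts as
UTF-8 CSV with '.' decimals, configuration as YAML key-value files.  The
trial CSV schema is::

    participant_id, group, trial, pair, choice, rt, reward

with choice in {optimal, suboptimal, none}; rt and reward are empty on
non-response trials.
"""

from __future__ import annotations

import json
import logging
import sys
import time
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import diagnostics, inference, recovery, task
from .models import RAW_COLUMNS, enumerate_model_space, get_model, preprocess_rts

log = logging.getLogger("rlddm")


def read_trials(path) -> pd.DataFrame:
    """Read and validate a trial CSV."""
    df = pd.read_csv(path, dtype={"participant_id": str, "group": str, "choice": str})
    missing = [c for c in RAW_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"trial file {path} is missing columns: {missing}")
    bad = set(df["choice"].unique()) - {"optimal", "suboptimal", "none"}
    if bad:
        raise ValueError(f"unknown choice labels: {sorted(bad)}")
    responded = df["choice"] != "none"
    if (df.loc[responded, "rt"] <= 0).any() or df.loc[responded, "rt"].isna().any():
        raise ValueError("responded trials must have a positive rt")
    if df.loc[~responded, "rt"].notna().any():
        raise ValueError("choice 'none' must have an empty rt")
    rew = df.loc[responded, "reward"]
    if not rew.isin([0, 1]).all():
        raise ValueError("reward must be 0 or 1 on responded trials (empty otherwise)")
    if df.loc[~responded, "reward"].notna().any():
        raise ValueError("choice 'none' must have an empty reward")
    return df


def write_trials(df: pd.DataFrame, path) -> None:
    df.to_csv(path, index=False, columns=list(RAW_COLUMNS) + [c for c in df.columns if c not in RAW_COLUMNS])


def write_group_params(params: task.GroupParams, path) -> None:
    Path(path).write_text(yaml.safe_dump({"mu": params.mu, "sigma": params.sigma}, sort_keys=True))


def read_group_params(path) -> task.GroupParams:
    raw = yaml.safe_load(Path(path).read_text())
    return task.GroupParams(mu=raw["mu"], sigma=raw["sigma"])


@dataclass
class RunConfig:
    """Settings of one pipeline run; defaults reproduce the full study setup."""

    n_trials: int = 60
    n_pairs: int = 2
    rate_optimal: float = 0.80
    rate_suboptimal: float = 0.20
    deadline: float = 3.0
    groups: tuple = ("control", "gambling")
    n_subjects: int = 23
    generating_model: str = "RLDDM8"
    models: tuple = tuple(m.name for m in enumerate_model_space())
    chains: int = 2
    burn: int = 50_000
    thin: int = 2
    keep: int = 10_000
    ppc_bin_width: int = 10
    ppc_draws: int = 1000
    recovery_sims: int = 10
    model_recovery_sims: int = 20
    seed: int = 1
    stages: tuple = ("simulate", "preprocess", "fit", "compare", "ppc", "report")

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        cfg = cls(**raw)
        for key in ("groups", "models", "stages"):
            setattr(cfg, key, tuple(getattr(cfg, key)))
        return cfg

    def to_yaml(self, path) -> None:
        data = asdict(self)
        for key in ("groups", "models", "stages"):
            data[key] = list(data[key])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    @property
    def mcmc(self) -> inference.MCMCConfig:
        return inference.MCMCConfig(chains=self.chains, burn=self.burn, thin=self.thin, keep=self.keep)

    @property
    def schedule(self) -> task.TaskSchedule:
        return task.generate_task_schedule(
            self.n_trials, self.n_pairs, self.rate_optimal, self.rate_suboptimal,
            self.deadline, seed=self.seed,
        )


def _setup_logging(outdir: Path):
    log.setLevel(logging.INFO)
    log.handlers.clear()
    for handler in (logging.StreamHandler(sys.stderr), logging.FileHandler(outdir / "run.log")):
        handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
        log.addHandler(handler)


def _warn_convergence(fit):
    bad = {k: v for k, v in fit.rhat.items() if not 1.0 <= v <= 1.01}
    if bad:
        worst = max(bad.values())
        log.warning("%s: %d parameters with R-hat outside [1, 1.01] (worst %.3f)",
                    fit.model, len(bad), worst)


def run_pipeline(config: RunConfig, outdir) -> Path:
    """Execute the requested stages, writing artifacts and a config echo.

    Stage failures write a machine-readable `status.json` and re-raise.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    _setup_logging(out)
    config.to_yaml(out / "config_echo.yaml")
    status = {"stages": {}, "ok": True}
    rng = np.random.default_rng(config.seed)
    spec_gen = get_model(config.generating_model)
    schedule = config.schedule
    data = fd = None
    fits = {}

    def _stage(name, fn):
        t0 = time.time()
        log.info("stage %s started (seed %d)", name, config.seed)
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - recorded then re-raised
            status["stages"][name] = {"ok": False, "error": str(exc)}
            status["ok"] = False
            (out / "status.json").write_text(json.dumps(status, indent=2))
            log.error("stage %s failed: %s", name, exc)
            raise
        status["stages"][name] = {"ok": True, "seconds": round(time.time() - t0, 2)}

    def do_simulate():
        nonlocal data
        frames = []
        for grp in config.groups:
            params = task.group_presets(grp)
            d, truth = task.simulate_group(
                params, config.n_subjects, spec_gen, schedule,
                seed=int(rng.integers(0, 2**31 - 1)), group=grp,
            )
            frames.append(d)
            truth.to_csv(out / f"generating_params_{grp}.csv", index=False)
            write_group_params(params, out / f"generating_group_{grp}.yaml")
        data = pd.concat(frames, ignore_index=True)
        write_trials(data, out / "trials.csv")

    def do_preprocess():
        nonlocal fd
        fd = preprocess_rts(data)
        fd.to_csv(out / "trials_filtered.csv", index=False)

    def do_fit():
        for grp in config.groups:
            gd = fd[fd["group"] == grp]
            for name in config.models:
                fit = inference.fit_hierarchical(
                    get_model(name), gd, mcmc=config.mcmc,
                    seed=int(rng.integers(0, 2**31 - 1)),
                )
                _warn_convergence(fit)
                fit.save(out / "fits" / grp / name)
                fits[(grp, name)] = fit

    def do_compare():
        for grp in config.groups:
            table = inference.compare_models([fits[(grp, m)] for m in config.models])
            table.to_csv(out / f"comparison_{grp}.csv", index=False)

    def do_recover():
        report = recovery.parameter_recovery(
            task.group_presets(config.groups[0]), spec_gen,
            n_sims=config.recovery_sims, n_subjects=config.n_subjects,
            schedule=schedule, mcmc=config.mcmc, seed=int(rng.integers(0, 2**31 - 1)),
        )
        report.correlations.to_csv(out / "recovery_correlations.csv", index=False)
        report.coverage.to_csv(out / "recovery_coverage.csv", index=False)
        report.convergence.to_csv(out / "recovery_convergence.csv", index=False)

    def do_ppc():
        for grp in config.groups:
            gd = data[data["group"] == grp]
            for name in config.models:
                if (grp, name) not in fits:
                    continue
                summary = diagnostics.posterior_predictive_bins(
                    fits[(grp, name)], get_model(name), gd,
                    bin_width=config.ppc_bin_width,
                    n_draws=min(config.ppc_draws, config.chains * config.keep),
                    seed=int(rng.integers(0, 2**31 - 1)),
                    rate_optimal=config.rate_optimal,
                    rate_suboptimal=config.rate_suboptimal,
                    deadline=config.deadline,
                )
                summary.table.to_csv(out / f"ppc_{grp}_{name}.csv", index=False)

    def do_report():
        diagnostics.model_agnostic_summary(data).to_csv(out / "behavior_summary.csv", index=False)
        best = config.models[-1]
        if len(config.groups) == 2 and (config.groups[0], best) in fits:
            diff = diagnostics.group_difference_summary(
                fits[(config.groups[0], best)], fits[(config.groups[1], best)],
            )
            diff.to_csv(out / f"group_differences_{best}.csv", index=False)

    stage_fns = {"simulate": do_simulate, "preprocess": do_preprocess, "fit": do_fit,
                 "compare": do_compare, "recover": do_recover, "ppc": do_ppc, "report": do_report}
    for name in config.stages:
        if name not in stage_fns:
            raise ValueError(f"unknown stage {name!r}")
        _stage(name, stage_fns[name])
    (out / "status.json").write_text(json.dumps(status, indent=2))
    return out
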