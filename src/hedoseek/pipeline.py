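"""Pipeline orchestration: simulate -> fit -> compare -> recover -> rope ->
report, seed-controlled and logged, with descriptive behavioural summaries.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .inference.fit import SamplerConfig, fit_hierarchical, diagnostics, point_estimates
from .model_comparison import compare_models, posterior_predictive_check
from .recovery_rope import (
    hdi,
    pooled_update_sd,
    rope_decision,
    rope_interval,
)
from .synthetic_cohort import CohortSpec, generate_exp1, generate_exp2

logger = logging.getLogger("hedoseek")

CHOICE_MODELS = ["accpos", "acc", "pos", "tiebreak"]
BELIEF_MODELS = ["full", "nopos"]


@dataclass
class RunConfig:
    """Configuration of one end-to-end run."""

    experiment: int = 1
    models: list[str] = field(default_factory=lambda: list(CHOICE_MODELS))
    n_participants: int = 20
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    comparison_method: str = "tis"
    out_dir: str = "hedoseek_run"
    seed: int = 0
    log_level: str = "INFO"
    generating_model: str | None = None

    def config_hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    @classmethod
    def from_file(cls, path: str | Path, **overrides) -> "RunConfig":
        """Load a YAML run configuration; keyword arguments (CLI flags)
        override file values.  The ``sampler`` key nests SamplerConfig
        fields."""
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        raw.update({k: v for k, v in overrides.items() if v is not None})
        sampler = raw.pop("sampler", None)
        cfg = cls(**raw)
        if sampler:
            cfg.sampler = SamplerConfig(**sampler)
        return cfg


def descriptive_summaries(dataset: pd.DataFrame) -> pd.DataFrame:
    """Choice proportions per participant and pooled.

    - equal-accuracy trials: proportion choosing the more positive source;
    - unequal-accuracy trials: proportion choosing the more accurate source,
      split by whether the more accurate source was also the more positive.

    Categories without trials are reported as missing.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    df = dataset.copy()
    eq = df["nAccA"] == df["nAccB"]
    pos_a = df["nPosA"] > df["nPosB"]
    acc_a = df["nAccA"] > df["nAccB"]
    more_pos_of_acc = np.where(acc_a, df["nPosA"] > df["nPosB"], df["nPosB"] > df["nPosA"])
    chose_a = df["chose_A"].to_numpy(int)
    df["_chose_positive"] = np.where(pos_a, chose_a, 1 - chose_a)
    df["_chose_accurate"] = np.where(acc_a, chose_a, 1 - chose_a)
    df["_aligned"] = more_pos_of_acc

    def summarise(g: pd.DataFrame) -> pd.Series:
        eq_g = g[(g["nAccA"] == g["nAccB"]) & (g["nPosA"] != g["nPosB"])]
        uneq = g[g["nAccA"] != g["nAccB"]]
        return pd.Series(
            {
                "positivity_pref_equal_acc": eq_g["_chose_positive"].mean()
                if len(eq_g) else np.nan,
                "accuracy_pref_aligned": uneq[uneq["_aligned"]]["_chose_accurate"].mean()
                if len(uneq[uneq["_aligned"]]) else np.nan,
                "accuracy_pref_opposed": uneq[~uneq["_aligned"]]["_chose_accurate"].mean()
                if len(uneq[~uneq["_aligned"]]) else np.nan,
                "n_trials": float(len(g)),
            }
        )

    per = df.groupby("participant_id").apply(summarise, include_groups=False)
    pooled = summarise(df)
    pooled.name = "pooled"
    per.loc["pooled"] = pooled
    return per


def _write_json(path: Path, payload: dict, config: RunConfig) -> None:
    payload = dict(payload)
    payload["config_hash"] = config.config_hash()
    payload["master_seed"] = config.seed
    path.write_text(json.dumps(payload, indent=2, default=str))


def run_pipeline(config: RunConfig) -> dict:
    """Execute the configured stages, writing versioned artifacts.

    Returns a report bundle (paths plus key results).  Any stage failure
    aborts with a stage-tagged error; artifacts written so far are retained.
    """
    logging.basicConfig(level=config.log_level)
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"out_dir": str(out), "config_hash": config.config_hash()}
    stage = "configure"
    try:
        if config.experiment == 1:
            models = config.models or CHOICE_MODELS
            gen_model = config.generating_model or "accpos"
        else:
            models = config.models or BELIEF_MODELS
            gen_model = config.generating_model or "full"
        for m in models:
            valid = CHOICE_MODELS if config.experiment == 1 else BELIEF_MODELS
            if m not in valid:
                raise ValueError(f"model {m!r} invalid for experiment {config.experiment}")

        stage = "simulate"
        spec = CohortSpec(
            n_participants=config.n_participants, experiment=config.experiment,
            model=gen_model, seed=config.seed,
        )
        gen = generate_exp1 if config.experiment == 1 else generate_exp2
        dataset, truth, offsets = gen(spec)
        dataset.to_csv(out / "dataset.csv", index=False)
        truth.to_csv(out / "true_parameters.csv", index=False)
        _write_json(out / "simulate.json", {
            "generating_model": gen_model,
            "n_participants": config.n_participants,
            "centering_offsets": offsets,
        }, config)
        logger.info("simulate: %d trials, %d participants", len(dataset), config.n_participants)

        if config.experiment == 1:
            stage = "describe"
            descriptive_summaries(dataset).to_csv(out / "descriptives.csv")

        stage = "fit"
        posteriors = {}
        for m in models:
            posteriors[m] = fit_hierarchical(m, dataset, config.sampler)
            posteriors[m].save(out / f"posterior_{m}")
            table, hyper = point_estimates(posteriors[m])
            table.to_csv(out / f"estimates_{m}.csv", index=False)
            hyper.to_csv(out / f"hyper_{m}.csv", index=False)
            logger.info("fit %s: max rhat %.3f, %d divergences", m,
                        diagnostics(posteriors[m])["max_rhat"],
                        posteriors[m].divergences)

        stage = "compare"
        comparison = compare_models(
            models, dataset, method=config.comparison_method,
            config=config.sampler, seed=config.seed,
        )
        _write_json(out / "comparison.json", comparison.to_dict(), config)
        comparison.table().to_csv(out / "comparison_table.csv")

        stage = "ppc"
        best = comparison.summary["elpd"].idxmax()
        ppc = posterior_predictive_check(best, posteriors[best], dataset, seed=config.seed)
        ppc.to_csv(out / "ppc.csv", index=False)

        bundle["comparison"] = comparison.table().to_dict()
        bundle["best_model"] = str(best)

        if config.experiment == 2:
            stage = "rope"
            sd = pooled_update_sd(dataset)
            full_post = posteriors.get("full") or fit_hierarchical("full", dataset, config.sampler)
            flat = full_post.stacked()
            rope_report = {"sd_DV": sd}
            for kind, hyper_name in (("accuracy", "mu_kAcc"), ("positivity", "mu_kPos")):
                rope = rope_interval(kind, sd)
                interval = hdi(flat[hyper_name], 0.95)
                rope_report[hyper_name] = {
                    "rope": [rope.lower, rope.upper],
                    "hdi": list(interval),
                    "decision": rope_decision(interval, rope),
                }
            _write_json(out / "rope.json", rope_report, config)
            bundle["rope"] = rope_report

        stage = "report"
        _write_json(out / "manifest.json", {
            "stages": "simulate,fit,compare,ppc" + (",rope" if config.experiment == 2 else ""),
            "models": models,
            "files": sorted(p.name for p in out.iterdir()),
        }, config)
    except Exception as err:
        raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err
    return bundle
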