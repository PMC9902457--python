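"""Model recovery, parameter recovery, and ROPE/HDI assessment.

The ROPE (region of practical equivalence) bound is the parameter value at
which the maximum change in the predictor produces a 0.1 standard-deviation
change in the dependent variable: the maximum raw difference is 5 for
positivity (five win- vs five loss-predictions) and 1 for accuracy (four vs
three accurate predictions).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference.fit import PosteriorSamples, SamplerConfig, fit_hierarchical, point_estimates
from .model_comparison import participant_elpd, pointwise_loglik, waic
from .synthetic_cohort import CohortSpec, generate_exp1, generate_exp2

ROPE_DELTA_MAX = {"positivity": 5.0, "accuracy": 1.0}


@dataclass
class RecoveryResult:
    """Confusion matrix of generating vs best-fitting model, plus (for
    parameter recovery) true-vs-recovered pairs and their correlations."""

    confusion: pd.DataFrame | None = None
    pairs: dict[str, pd.DataFrame] = field(default_factory=dict)
    correlations: dict[str, float] = field(default_factory=dict)
    hyper_summary: pd.DataFrame | None = None
    posterior: PosteriorSamples | None = None


@dataclass(frozen=True)
class RopeInterval:
    lower: float
    upper: float
    delta_max: float
    sd_dv: float

    def __post_init__(self) -> None:
        if self.upper <= 0 or self.lower != -self.upper:
            raise ValueError("ROPE must be symmetric about 0 with upper > 0")

    def contains(self, lo: float, hi: float) -> bool:
        return self.lower <= lo and hi <= self.upper

    def disjoint(self, lo: float, hi: float) -> bool:
        return hi < self.lower or lo > self.upper


def rope_interval(kind: str, sd_DV: float) -> RopeInterval:
    """ROPE bound b = 0.1 * sd_DV / delta_max, symmetric about zero."""
    if kind not in ROPE_DELTA_MAX:
        raise ValueError(f"kind must be one of {sorted(ROPE_DELTA_MAX)}")
    if sd_DV <= 0:
        raise ValueError("sd_DV must be > 0")
    b = 0.1 * sd_DV / ROPE_DELTA_MAX[kind]
    return RopeInterval(lower=-b, upper=b, delta_max=ROPE_DELTA_MAX[kind], sd_dv=sd_DV)


def hdi(samples: np.ndarray, mass: float = 0.95) -> tuple[float, float]:
    """Narrowest contiguous interval holding the requested posterior mass
    (sliding window over sorted draws; unimodal assumption)."""
    s = np.sort(np.asarray(samples, dtype=float).ravel())
    n = s.size
    if n < 100:
        raise ValueError("hdi requires at least 100 samples")
    if not (0.0 < mass <= 1.0):
        raise ValueError("mass must lie in (0, 1]")
    k = int(np.ceil(mass * n))
    if k >= n:
        return float(s[0]), float(s[-1])
    widths = s[k - 1 + np.arange(n - k + 1)] - s[np.arange(n - k + 1)]
    i = int(np.argmin(widths))
    return float(s[i]), float(s[i + k - 1])


def rope_decision(hdi_interval: tuple[float, float], rope: RopeInterval) -> str:
    """'practically_zero' iff HDI inside the ROPE; 'meaningfully_nonzero' iff
    disjoint; otherwise 'undecided'."""
    lo, hi = hdi_interval
    if rope.contains(lo, hi):
        return "practically_zero"
    if rope.disjoint(lo, hi):
        return "meaningfully_nonzero"
    return "undecided"


def pooled_update_sd(dataset: pd.DataFrame) -> float:
    """Pooled empirical standard deviation of the quantified updates."""
    return float(dataset["update"].astype(float).std(ddof=1))


# ---------------------------------------------------------------------------
# recovery analyses

_CHOICE_SET = ("accpos", "acc", "pos", "tiebreak")


def _generate(spec: CohortSpec):
    if spec.experiment == 1:
        return generate_exp1(spec)
    return generate_exp2(spec)


def model_recovery(
    model_set: tuple[str, ...] = _CHOICE_SET,
    n_participants: int = 15,
    n_sims: int = 2,
    config: SamplerConfig = SamplerConfig(),
    spec_factory=None,
    classifier: str = "elpd",
    n_inner: int = 100,
    seed: int = 0,
) -> RecoveryResult:
    """Simulate cohorts from each model, fit every candidate, classify by
    summed participant-wise elpd (or WAIC), and tally the confusion matrix."""
    if n_sims < 1:
        raise ValueError("n_sims must be >= 1")
    if classifier not in ("elpd", "waic"):
        raise ValueError("classifier must be 'elpd' or 'waic'")
    experiment = 1 if model_set[0] in _CHOICE_SET else 2
    confusion = pd.DataFrame(
        0.0, index=list(model_set), columns=list(model_set)
    )
    sim_seed = seed
    for gen_model in model_set:
        for s in range(n_sims):
            sim_seed += 1
            if spec_factory is not None:
                spec = spec_factory(gen_model, sim_seed)
            else:
                spec = CohortSpec(
                    n_participants=n_participants, experiment=experiment,
                    model=gen_model, seed=sim_seed,
                )
            dataset, _, _ = _generate(spec)
            posteriors = {
                m: fit_hierarchical(m, dataset, SamplerConfig(
                    n_chains=config.n_chains, n_warmup=config.n_warmup,
                    n_draws=config.n_draws, seed=config.seed + sim_seed,
                    max_treedepth=config.max_treedepth,
                    target_accept=config.target_accept,
                ))
                for m in model_set
            }
            if classifier == "elpd":
                elpd = participant_elpd(
                    posteriors, dataset, method="tis",
                    n_inner=n_inner, seed=sim_seed,
                )
                best = elpd.sum(axis=0).idxmax()
            else:
                scores = {
                    m: waic(pointwise_loglik(m, posteriors[m], dataset)).waic
                    for m in model_set
                }
                best = min(scores, key=scores.get)
            confusion.loc[gen_model, best] += 1
    return RecoveryResult(confusion=confusion)


def parameter_recovery(
    model: str = "accpos",
    spec: CohortSpec | None = None,
    config: SamplerConfig = SamplerConfig(),
    seed: int = 0,
) -> RecoveryResult:
    """Simulate one cohort from stated hyperparameters, fit, and correlate
    true vs recovered individual parameters."""
    if spec is None:
        spec = CohortSpec(n_participants=30, experiment=1, model=model, seed=seed)
    if spec.n_participants < 10:
        raise ValueError("parameter recovery needs a cohort of >= 10")
    dataset, truth, _ = _generate(spec)
    posterior = fit_hierarchical(model, dataset, config)
    table, hyper = point_estimates(posterior)
    result = RecoveryResult()
    for col in table.columns:
        if col == "participant_id" or col not in truth.columns:
            continue
        pairs = pd.DataFrame({"true": truth[col].to_numpy(),
                              "recovered": table[col].to_numpy()})
        result.pairs[col] = pairs
        if pairs["true"].std() > 0:
            result.correlations[col] = float(
                np.corrcoef(pairs["true"], pairs["recovered"])[0, 1]
            )
    result.hyper_summary = hyper
    result.posterior = posterior
    return result
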