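"""Posterior sampling front end: configuration, draws container, diagnostics.

``fit_hierarchical`` runs one NUTS chain per configured chain (sequentially,
single process), transforms the draws to the constrained, named parameter
space, and wraps them with convergence diagnostics computed via ArviZ.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import arviz as az
import numpy as np
import pandas as pd

from .models import build_posterior, ChoicePosterior
from .nuts import sample_nuts, ChainStats

PAPER_SCALE = dict(n_chains=4, n_warmup=1500, n_draws=5000)


@dataclass(frozen=True)
class SamplerConfig:
    """MCMC run configuration.  Paper-scale defaults: 4 chains, 1500 warm-up,
    5000 retained draws per chain."""

    n_chains: int = 4
    n_warmup: int = 1500
    n_draws: int = 5000
    seed: int = 0
    rhat_threshold: float = 1.01
    max_treedepth: int = 10
    target_accept: float = 0.8

    def __post_init__(self) -> None:
        if self.n_chains < 2:
            raise ValueError("n_chains must be >= 2 for convergence diagnostics")
        if self.n_warmup < 0 or self.n_draws <= 0:
            raise ValueError("sample counts must be positive")


TEST_SCALE = SamplerConfig(n_chains=2, n_warmup=400, n_draws=400)


@dataclass
class PosteriorSamples:
    """Constrained posterior draws with chain structure and diagnostics."""

    model: str
    draws: dict[str, np.ndarray]          # (chain, draw) or (chain, draw, n)
    participant_ids: np.ndarray
    config: SamplerConfig
    dataset_fingerprint: str
    chain_stats: list[ChainStats] = field(default_factory=list)
    posterior: object = None              # the log-density object (not saved)

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    @property
    def n_draws(self) -> int:
        return next(iter(self.draws.values())).shape[1]

    @property
    def divergences(self) -> int:
        return int(sum(s.divergences for s in self.chain_stats))

    def stacked(self) -> dict[str, np.ndarray]:
        """Draws with chains flattened: (chain*draw,) or (chain*draw, n)."""
        return {
            k: v.reshape(v.shape[0] * v.shape[1], *v.shape[2:])
            for k, v in self.draws.items()
        }

    def to_arviz(self) -> az.InferenceData:
        mapped = {}
        for k, v in self.draws.items():
            mapped[k] = v
        return az.from_dict(posterior=mapped)

    def save(self, directory: str | Path) -> None:
        """Columnar-text draw store plus a JSON diagnostics sidecar."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        cols: dict[str, np.ndarray] = {}
        nc, nd = self.n_chains, self.n_draws
        cols["chain"] = np.repeat(np.arange(nc), nd)
        cols["draw"] = np.tile(np.arange(nd), nc)
        for k, v in self.draws.items():
            if v.ndim == 2:
                cols[k] = v.reshape(-1)
            else:
                for j in range(v.shape[2]):
                    cols[f"{k}[{self.participant_ids[j]}]"] = v[:, :, j].reshape(-1)
        pd.DataFrame(cols).to_csv(directory / "draws.csv", index=False)
        report = diagnostics(self)
        meta = {
            "model": self.model,
            "dataset_fingerprint": self.dataset_fingerprint,
            "config": {
                "n_chains": self.config.n_chains,
                "n_warmup": self.config.n_warmup,
                "n_draws": self.config.n_draws,
                "seed": self.config.seed,
            },
            "diagnostics": report,
        }
        (directory / "diagnostics.json").write_text(json.dumps(meta, indent=2))


def fingerprint_dataset(df: pd.DataFrame) -> str:
    h = hashlib.sha256()
    h.update(pd.util.hash_pandas_object(df, index=False).values.tobytes())
    return h.hexdigest()[:16]


def fit_hierarchical(
    model: str,
    dataset: pd.DataFrame,
    config: SamplerConfig = SamplerConfig(),
) -> PosteriorSamples:
    """Sample the joint posterior of the named model on the given dataset.

    Datasets must already carry centred covariates (``center_covariates``).
    Non-convergence (R-hat above threshold, divergences) is flagged in the
    diagnostics report, never silently dropped.
    """
    post = build_posterior(model, dataset)
    seeds = np.random.SeedSequence(config.seed).spawn(config.n_chains)
    per_chain: list[np.ndarray] = []
    stats: list[ChainStats] = []
    for seq in seeds:
        rng = np.random.default_rng(seq)
        x0 = post.initial_point(rng)
        draws, st = sample_nuts(
            post.logp_grad, x0, config.n_warmup, config.n_draws, rng,
            max_treedepth=config.max_treedepth,
            target_accept=config.target_accept,
        )
        per_chain.append(draws)
        stats.append(st)
    named: dict[str, np.ndarray] = {}
    for c, draws in enumerate(per_chain):
        cons = post.constrain(draws)
        for k, v in cons.items():
            if k not in named:
                named[k] = np.empty((config.n_chains, *v.shape))
            named[k][c] = v
    return PosteriorSamples(
        model=model,
        draws=named,
        participant_ids=post.data.participant_ids,
        config=config,
        dataset_fingerprint=fingerprint_dataset(dataset),
        chain_stats=stats,
        posterior=post,
    )


def diagnostics(posterior: PosteriorSamples) -> dict:
    """Split-R-hat, effective sample size and divergence counts per parameter,
    with a pass/fail verdict against the configured R-hat threshold."""
    if posterior.n_chains < 2:
        raise ValueError("diagnostics require at least two chains")
    nonempty = {k: v for k, v in posterior.draws.items() if v.size}
    idata = az.from_dict(posterior=nonempty)
    rhat = az.rhat(idata)
    ess = az.ess(idata)
    report: dict = {"params": {}, "divergences": posterior.divergences}
    worst = 1.0
    for k in nonempty:
        r = float(np.nanmax(np.asarray(rhat[k])))
        e = float(np.nanmin(np.asarray(ess[k])))
        report["params"][k] = {"rhat": r, "ess": e}
        worst = max(worst, r)
    report["max_rhat"] = worst
    report["rhat_threshold"] = posterior.config.rhat_threshold
    report["converged"] = bool(
        worst <= posterior.config.rhat_threshold and posterior.divergences == 0
    )
    return report


def point_estimates(
    posterior: PosteriorSamples, stat: str = "mean"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-participant posterior point estimates and hyperparameter summaries.

    ``stat`` is "mean" (default) or "median".
    """
    if stat not in ("mean", "median"):
        raise ValueError("stat must be 'mean' or 'median'")
    reduce = np.mean if stat == "mean" else np.median
    flat = posterior.stacked()
    indiv = {k: v for k, v in flat.items() if v.ndim == 2}
    hyper = {k: v for k, v in flat.items() if v.ndim == 1}
    table = pd.DataFrame({"participant_id": posterior.participant_ids})
    for k, v in indiv.items():
        table[k] = reduce(v, axis=0)
    rows = []
    for k, v in hyper.items():
        rows.append(
            dict(
                parameter=k,
                estimate=float(reduce(v)),
                sd=float(np.std(v)),
                q2_5=float(np.quantile(v, 0.025)),
                q97_5=float(np.quantile(v, 0.975)),
            )
        )
    return table, pd.DataFrame(rows)
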