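"""Participant-wise cross-validated elpd, WAIC, Bayesian stacking and
posterior predictive checks.

Out-of-sample fit is measured per participant: the held-out participant's
individual parameters are integrated over the group-level distribution
inferred from the remaining data.  Two estimators are provided:

- ``exact_refit``: refit the model once per fold (gold standard, slow);
- ``tis``: reuse the full-data posterior with truncated importance sampling
  (raw weights capped at mean * sqrt(S) over S draws).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.special import logsumexp

from .inference.fit import PosteriorSamples, SamplerConfig, fit_hierarchical
from .inference.models import build_posterior

DEFAULT_N_INNER = 100


@dataclass
class PointwiseLogLik:
    """Log-likelihood of every observation at every retained posterior draw."""

    matrix: np.ndarray            # (draws, observations)
    participant_of_obs: np.ndarray

    def __post_init__(self) -> None:
        if not np.all(np.isfinite(self.matrix)):
            raise ValueError("pointwise log-likelihood contains non-finite entries")
        if self.matrix.shape[1] != len(self.participant_of_obs):
            raise ValueError("grouping map must cover every observation exactly once")


def pointwise_loglik(
    model: str, posterior: PosteriorSamples, dataset: pd.DataFrame
) -> PointwiseLogLik:
    """Evaluate the model's per-observation log-likelihood at every draw."""
    post = build_posterior(model, dataset)
    if list(post.data.participant_ids) != list(posterior.participant_ids):
        raise ValueError("dataset participants do not match the posterior")
    flat = posterior.stacked()
    mat = post.pointwise_loglik(flat)
    return PointwiseLogLik(
        matrix=mat,
        participant_of_obs=dataset["participant_id"].to_numpy(),
    )


@dataclass
class WaicResult:
    waic: float
    se: float                     # per-participant convention
    lppd: float
    p_waic: float
    pointwise: np.ndarray         # per-observation -2*(lppd_n - p_n)


def waic(pointwise: PointwiseLogLik) -> WaicResult:
    """WAIC = -2 (lppd - p_waic); smaller is better (deviance scale)."""
    m = pointwise.matrix
    if m.shape[0] < 2:
        raise ValueError("WAIC requires at least two posterior draws")
    lppd_n = logsumexp(m, axis=0) - np.log(m.shape[0])
    p_n = np.var(m, axis=0, ddof=1)
    contrib = -2.0 * (lppd_n - p_n)
    groups = pd.Series(contrib).groupby(pointwise.participant_of_obs).sum()
    n_p = len(groups)
    se = float(np.sqrt(n_p * groups.var(ddof=1))) if n_p > 1 else float("nan")
    return WaicResult(
        waic=float(contrib.sum()),
        se=se,
        lppd=float(lppd_n.sum()),
        p_waic=float(p_n.sum()),
        pointwise=contrib,
    )


def _elpd_tis(
    posterior: PosteriorSamples,
    dataset: pd.DataFrame,
    n_inner: int,
    rng: np.random.Generator,
) -> pd.Series:
    """Leave-one-participant-out elpd from the full-data posterior via
    truncated importance sampling (cap: mean weight * sqrt(S))."""
    post = posterior.posterior or build_posterior(posterior.model, dataset)
    flat = posterior.stacked()
    out = {}
    for pid, df_i in dataset.groupby("participant_id"):
        # log p(y_i | hypers_s), marginal over individual parameters
        l = post.loglik_new_participant(flat, df_i, n_inner, rng)
        S = len(l)
        lw = -l                                   # raw weights 1 / p_hat
        cap = (logsumexp(lw) - np.log(S)) + 0.5 * np.log(S)
        lw = np.minimum(lw, cap)
        out[pid] = float(logsumexp(lw + l) - logsumexp(lw))
    return pd.Series(out)


def _elpd_exact(
    model: str,
    dataset: pd.DataFrame,
    config: SamplerConfig,
    n_inner: int,
    rng: np.random.Generator,
) -> pd.Series:
    """Leave-one-participant-out elpd by refitting per fold (oracle)."""
    pids = np.unique(dataset["participant_id"].to_numpy())
    if len(pids) < 2:
        raise ValueError("exact refit needs >= 2 participants (no training data otherwise)")
    out = {}
    for k, pid in enumerate(pids):
        train = dataset[dataset["participant_id"] != pid]
        held = dataset[dataset["participant_id"] == pid]
        fold_cfg = SamplerConfig(
            n_chains=config.n_chains, n_warmup=config.n_warmup,
            n_draws=config.n_draws, seed=config.seed + 1000 + k,
            rhat_threshold=config.rhat_threshold,
            max_treedepth=config.max_treedepth,
            target_accept=config.target_accept,
        )
        posterior = fit_hierarchical(model, train, fold_cfg)
        flat = posterior.stacked()
        post = posterior.posterior
        l = post.loglik_new_participant(flat, held, n_inner, rng)
        out[pid] = float(logsumexp(l) - np.log(len(l)))
    return pd.Series(out)


def participant_elpd(
    models: list[str] | dict[str, PosteriorSamples],
    dataset: pd.DataFrame,
    method: str = "tis",
    config: SamplerConfig = SamplerConfig(),
    n_inner: int = DEFAULT_N_INNER,
    seed: int = 0,
) -> pd.DataFrame:
    """Per-participant leave-one-out elpd matrix (participants x models).

    ``models`` is either a list of model ids (posteriors are fitted here) or,
    for ``method="tis"``, a mapping of model id to an existing full-data
    posterior.
    """
    if len(np.unique(dataset["participant_id"])) < 2:
        raise ValueError("participant-wise cross-validation needs >= 2 participants")
    if method not in ("tis", "exact_refit"):
        raise ValueError("method must be 'tis' or 'exact_refit'")
    rng = np.random.default_rng(seed)
    cols = {}
    if isinstance(models, dict):
        items = models.items()
    else:
        items = [(m, None) for m in models]
    for model, posterior in items:
        if method == "exact_refit":
            cols[model] = _elpd_exact(model, dataset, config, n_inner, rng)
        else:
            if posterior is None:
                posterior = fit_hierarchical(model, dataset, config)
            cols[model] = _elpd_tis(posterior, dataset, n_inner, rng)
    return pd.DataFrame(cols)


def elpd_summary(elpd_matrix: pd.DataFrame) -> pd.DataFrame:
    """Summed elpd, its standard error (sqrt(n * var) over participant
    contributions) and the difference from the best model."""
    total = elpd_matrix.sum(axis=0)
    n = len(elpd_matrix)
    se = np.sqrt(n * elpd_matrix.var(axis=0, ddof=1)) if n > 1 else np.nan
    best = total.max()
    d = total - best
    d_se = {}
    best_model = total.idxmax()
    for m in elpd_matrix.columns:
        diff = elpd_matrix[m] - elpd_matrix[best_model]
        d_se[m] = float(np.sqrt(n * diff.var(ddof=1))) if n > 1 else np.nan
    return pd.DataFrame(
        {"elpd": total, "se": se, "delta_elpd": d, "delta_se": pd.Series(d_se)}
    )


def stacking_weights(elpd_matrix: pd.DataFrame | np.ndarray, tol: float = 1e-10) -> np.ndarray:
    """Simplex weights maximising the summed log pointwise predictive density
    of the weighted model mixture."""
    m = np.asarray(elpd_matrix, dtype=float)
    if m.ndim != 2 or m.shape[1] < 1:
        raise ValueError("elpd matrix must be 2-D with >= 1 model")
    if not np.all(np.isfinite(m)):
        raise ValueError("elpd matrix contains non-finite entries")
    n, k = m.shape
    if k == 1:
        return np.array([1.0])
    if np.allclose(m, m[:, [0]]):
        return np.full(k, 1.0 / k)       # flat objective: uniform by convention
    shifted = m - m.max(axis=1, keepdims=True)   # objective invariant per row
    dens = np.exp(shifted)

    def neg_obj(w):
        mix = dens @ w
        return -float(np.sum(np.log(np.maximum(mix, 1e-300))))

    def grad(w):
        mix = np.maximum(dens @ w, 1e-300)
        return -(dens / mix[:, None]).sum(axis=0)

    w0 = np.full(k, 1.0 / k)
    res = minimize(
        neg_obj, w0, jac=grad, method="SLSQP",
        bounds=[(0.0, 1.0)] * k,
        constraints=[{"type": "eq", "fun": lambda w: w.sum() - 1.0,
                      "jac": lambda w: np.ones(k)}],
        options={"ftol": tol, "maxiter": 2000},
    )
    w = np.clip(res.x, 0.0, None)
    return w / w.sum()


def best_model_proportions(elpd_matrix: pd.DataFrame) -> pd.Series:
    """Per-participant argmax labels tallied into proportions; exact ties are
    split equally."""
    m = elpd_matrix.to_numpy(float)
    counts = np.zeros(m.shape[1])
    for row in m:
        winners = np.flatnonzero(row == row.max())
        counts[winners] += 1.0 / len(winners)
    props = counts / m.shape[0]
    return pd.Series(props, index=elpd_matrix.columns)


@dataclass
class ComparisonResult:
    """Table-1-style comparison across models."""

    elpd_matrix: pd.DataFrame
    summary: pd.DataFrame
    waic: pd.Series
    waic_se: pd.Series
    stacking: pd.Series
    proportions: pd.Series

    def table(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "elpd": self.summary["elpd"],
                "elpd_se": self.summary["se"],
                "delta_elpd": self.summary["delta_elpd"],
                "waic": self.waic,
                "waic_se": self.waic_se,
                "stacking_weight": self.stacking,
                "prop_best": self.proportions,
            }
        )

    def to_dict(self) -> dict:
        return {
            "elpd_matrix": {
                m: self.elpd_matrix[m].to_dict() for m in self.elpd_matrix.columns
            },
            "table": {m: self.table().loc[m].to_dict() for m in self.table().index},
        }


def compare_models(
    models: list[str],
    dataset: pd.DataFrame,
    method: str = "tis",
    config: SamplerConfig = SamplerConfig(),
    n_inner: int = DEFAULT_N_INNER,
    seed: int = 0,
) -> ComparisonResult:
    """Fit every model, estimate participant-wise elpd, WAIC, stacking
    weights and best-model proportions."""
    posteriors = {m: fit_hierarchical(m, dataset, config) for m in models}
    elpd = participant_elpd(
        posteriors if method == "tis" else models,
        dataset, method=method, config=config, n_inner=n_inner, seed=seed,
    )
    waics, waic_ses = {}, {}
    for m in models:
        res = waic(pointwise_loglik(m, posteriors[m], dataset))
        waics[m], waic_ses[m] = res.waic, res.se
    w = stacking_weights(elpd)
    return ComparisonResult(
        elpd_matrix=elpd,
        summary=elpd_summary(elpd),
        waic=pd.Series(waics),
        waic_se=pd.Series(waic_ses),
        stacking=pd.Series(w, index=elpd.columns),
        proportions=best_model_proportions(elpd),
    )


def posterior_predictive_check(
    model: str,
    posterior: PosteriorSamples,
    dataset: pd.DataFrame,
    n_reps: int = 200,
    seed: int = 0,
) -> pd.DataFrame:
    """Observed summary statistics against their replicated distribution.

    Choice models: proportion choosing the more positive source on
    equal-accuracy trials and the more accurate source on unequal-accuracy
    trials.  Belief models: mean update after win- and loss-direction
    predictions.
    """
    if len(dataset) == 0:
        raise ValueError("empty dataset")
    rng = np.random.default_rng(seed)
    post = posterior.posterior or build_posterior(model, dataset)
    flat = posterior.stacked()
    S = next(iter(flat.values())).shape[0]
    take = rng.choice(S, size=min(n_reps, S), replace=False)
    sub = {k: v[take] for k, v in flat.items()}

    rows = []
    if model in ("accpos", "acc", "pos", "tiebreak"):
        d = post.data
        dv = np.zeros((len(take), len(d.pid)))
        if post.has_acc:
            dv += sub["k_Acc"][:, d.pid] * d.d_acc
        if post.has_pos:
            dv += sub["k_Pos"][:, d.pid] * post._dp
        eta = sub["beta"][:, d.pid] * dv
        p_a = 1.0 / (1.0 + np.exp(-np.clip(eta, -700, 700)))
        rep = (rng.random(p_a.shape) < p_a).astype(float)
        obs = dataset["chose_A"].to_numpy(float)
        eq = dataset["EQ"].to_numpy(int) == 1
        pos_a_more = dataset["nPosA_c"].to_numpy(float) > dataset["nPosB_c"].to_numpy(float)
        acc_a_more = dataset["nAccA_c"].to_numpy(float) > dataset["nAccB_c"].to_numpy(float)

        def chose_positive(c):
            rel = eq & (dataset["nPosA_c"].to_numpy(float) != dataset["nPosB_c"].to_numpy(float))
            return np.mean(np.where(pos_a_more[rel], c[..., rel], 1 - c[..., rel]), axis=-1)

        def chose_accurate(c):
            rel = ~eq
            return np.mean(np.where(acc_a_more[rel], c[..., rel], 1 - c[..., rel]), axis=-1)

        for name, fn in (("positivity_choice_equal_acc", chose_positive),
                         ("accuracy_choice_unequal_acc", chose_accurate)):
            o = float(fn(obs))
            r = fn(rep)
            rows.append(dict(statistic=name, observed=o,
                             rep_lo=float(np.quantile(r, 0.025)),
                             rep_hi=float(np.quantile(r, 0.975)),
                             rep_mean=float(np.mean(r))))
    else:
        d = post.data
        linear = sub["k_Cons"][:, d.pid] + sub["k_Acc"][:, d.pid] * d.acc
        if post.has_pos:
            linear = linear + sub["k_Pos"][:, d.pid] * d.pos
        mult = 1.0 + (sub["k_Sym"][:, d.pid] - 1.0) * d.direction
        mu = linear * mult
        rep = rng.normal(mu, sub["sigma_U"][:, d.pid])
        for name, mask in (("mean_update_win_dir", d.direction == 1),
                           ("mean_update_loss_dir", d.direction == 0)):
            o = float(np.mean(d.u[mask]))
            r = np.mean(rep[:, mask], axis=1)
            rows.append(dict(statistic=name, observed=o,
                             rep_lo=float(np.quantile(r, 0.025)),
                             rep_hi=float(np.quantile(r, 0.975)),
                             rep_mean=float(np.mean(r))))
    df = pd.DataFrame(rows)
    df["inside_95"] = (df["observed"] >= df["rep_lo"]) & (df["observed"] <= df["rep_hi"])
    return df
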