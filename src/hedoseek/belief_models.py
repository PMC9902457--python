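"""Belief-update quantification and Gaussian update models for Experiment 2.

A belief rating on the 0-100 scale is converted to a signed update ``U``
relative to the 50-point indifference level, signed toward the source's
own-lottery prediction.  The mean update is a linear function of the source's
centred accuracy/positivity, multiplied by an asymmetry factor ``k_Sym`` on
win-direction trials:

    mu_U = (k_Cons + k_Acc * nAcc_c [+ k_Pos * nPos_c]) * (1 + (k_Sym - 1) * Dir)
    U ~ Normal(mu_U, sigma_U)

Model ``full`` includes the positivity term; ``nopos`` omits it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

BELIEF_MODELS = ("full", "nopos")

_LOG2PI = float(np.log(2.0 * np.pi))


@dataclass(frozen=True)
class BeliefParams:
    """Per-participant free parameters of the belief-update models."""

    k_Cons: float = 0.0
    k_Acc: float = 0.0
    k_Pos: float = 0.0
    k_Sym: float = 1.0
    sigma_U: float = 1.0

    def __post_init__(self) -> None:
        if self.sigma_U <= 0:
            raise ValueError("sigma_U must be > 0")


@dataclass(frozen=True)
class BeliefHyperParams:
    """Group-level locations and scales for the belief-model hierarchy.

    ``mu_kSym`` must be positive: its log carries the Normal(0, 1) hyperprior.
    """

    mu_kCons: float = 0.0
    sigma_kCons: float = 1.0
    mu_kAcc: float = 0.0
    sigma_kAcc: float = 1.0
    mu_kPos: float = 0.0
    sigma_kPos: float = 1.0
    mu_kSym: float = 1.0
    sigma_kSym: float = 1.0

    def __post_init__(self) -> None:
        if self.mu_kSym <= 0:
            raise ValueError("mu_kSym must be > 0 (log-normal hyperprior)")
        for name in ("sigma_kCons", "sigma_kAcc", "sigma_kPos", "sigma_kSym"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def quantify_update(rating, Dir):
    """Signed update relative to indifference (50), toward the prediction.

    U = rating - 50 when a win was predicted (Dir=1); U = 50 - rating when a
    loss was predicted (Dir=0).  E.g. a loss prediction followed by a rating
    of 10 is a 40-point update; a rating of 60 is a -10-point update.
    """
    rating = np.asarray(rating, dtype=float)
    if np.any(rating < 0) or np.any(rating > 100):
        raise ValueError("rating must lie in [0, 100]")
    Dir = np.asarray(Dir)
    u = np.where(Dir == 1, rating - 50.0, 50.0 - rating)
    return float(u) if u.ndim == 0 else u


def predict_mean_update(model: str, params: BeliefParams, nAcc_c, nPos_c, Dir):
    """Mean update mu_U under the given model variant."""
    if model == "full":
        linear = params.k_Cons + params.k_Acc * np.asarray(nAcc_c, float) \
            + params.k_Pos * np.asarray(nPos_c, float)
    elif model == "nopos":
        linear = params.k_Cons + params.k_Acc * np.asarray(nAcc_c, float)
        linear = linear + 0.0 * np.asarray(nPos_c, float)  # broadcast shape
    else:
        raise ValueError(f"unknown belief model {model!r}")
    mult = 1.0 + (params.k_Sym - 1.0) * np.asarray(Dir, float)
    out = linear * mult
    return float(out) if np.ndim(out) == 0 else out


def belief_loglik(
    model: str, params: BeliefParams, dataset: pd.DataFrame
) -> tuple[float, np.ndarray]:
    """Gaussian log-likelihood of quantified updates, total and per trial.

    ``dataset`` must carry centred covariates, ``dir_prediction`` and the
    quantified ``update`` column.
    """
    if params.sigma_U <= 0:
        raise ValueError("sigma_U must be > 0")
    mu = predict_mean_update(
        model, params,
        dataset["nAccA_c"].to_numpy(float),
        dataset["nPosA_c"].to_numpy(float),
        dataset["dir_prediction"].to_numpy(int),
    )
    u = dataset["update"].to_numpy(float)
    z = (u - mu) / params.sigma_U
    per_trial = -0.5 * z**2 - np.log(params.sigma_U) - 0.5 * _LOG2PI
    return float(per_trial.sum()), per_trial


def simulate_ratings(
    model: str,
    params: BeliefParams,
    schedule: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Generative counterpart of the belief likelihood.

    Draws U ~ Normal(mu_U, sigma_U), reconstructs the 0-100 rating, clips to
    the response scale (clip events recorded in ``clipped``) and re-quantifies
    the update from the stored rating so the dataset is self-consistent.
    """
    df = schedule.copy()
    d = df["dir_prediction"].to_numpy(int)
    mu = predict_mean_update(
        model, params,
        df["nAccA_c"].to_numpy(float),
        df["nPosA_c"].to_numpy(float),
        d,
    )
    u = rng.normal(mu, params.sigma_U)
    rating = np.where(d == 1, 50.0 + u, 50.0 - u)
    clipped = (rating < 0) | (rating > 100)
    rating = np.clip(rating, 0.0, 100.0)
    df["rating"] = rating
    df["clipped"] = clipped.astype(int)
    df["update"] = quantify_update(rating, d)
    return df
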