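"""Two-source choice models: linear source values entered into a softmax.

Four variants of the same structure differ in which covariates carry weight:

- ``accpos``    value = k_Acc * nAcc_c + k_Pos * nPos_c
- ``acc``       value = k_Acc * nAcc_c
- ``pos``       value = k_Pos * nPos_c
- ``tiebreak``  value = k_Acc * nAcc_c + k_Pos * nPos_c * EQ, where EQ = 1
  only when both sources are equally accurate (positivity as a tiebreaker).

All covariates are centred (dataset-wide mean over every presented source
subtracted) before entering the models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .task_design import TrialSpecExp1, sample_own_prediction, PsychicProfile

CHOICE_MODELS = ("accpos", "acc", "pos", "tiebreak")

BETA_MAX = 5.0


@dataclass(frozen=True)
class ChoiceParams:
    """Per-participant free parameters of the choice models."""

    k_Acc: float = 0.0
    k_Pos: float = 0.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.beta <= BETA_MAX):
            raise ValueError(f"beta must lie in [0, {BETA_MAX}], got {self.beta}")


@dataclass(frozen=True)
class ChoiceHyperParams:
    """Group-level locations and scales for the choice-model hierarchy."""

    mu_kAcc: float = 0.0
    sigma_kAcc: float = 1.0
    mu_kPos: float = 0.0
    sigma_kPos: float = 1.0
    mu_beta: float = 1.0
    sigma_beta: float = 1.0

    def __post_init__(self) -> None:
        for name in ("sigma_kAcc", "sigma_kPos", "sigma_beta"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


def center_covariates(schedule: pd.DataFrame) -> tuple[pd.DataFrame, dict[str, float]]:
    """Centre nAcc and nPos over every presented source in the dataset.

    Returns a copy with added columns ``nAccA_c, nPosA_c`` (and the B
    counterparts where present) plus ``EQ``, and the offsets that were
    subtracted so raw values remain recoverable.
    """
    if len(schedule) == 0:
        raise ValueError("cannot centre an empty schedule")
    df = schedule.copy()
    two_source = "nAccB" in df.columns and df["nAccB"].notna().any()
    if two_source:
        acc_mean = float(pd.concat([df["nAccA"], df["nAccB"]]).astype(float).mean())
        pos_mean = float(pd.concat([df["nPosA"], df["nPosB"]]).astype(float).mean())
    else:
        acc_mean = float(df["nAccA"].astype(float).mean())
        pos_mean = float(df["nPosA"].astype(float).mean())
    df["nAccA_c"] = df["nAccA"].astype(float) - acc_mean
    df["nPosA_c"] = df["nPosA"].astype(float) - pos_mean
    if two_source:
        df["nAccB_c"] = df["nAccB"].astype(float) - acc_mean
        df["nPosB_c"] = df["nPosB"].astype(float) - pos_mean
        df["EQ"] = (df["nAccA"] == df["nAccB"]).astype(int)
    offsets = {"nAcc": acc_mean, "nPos": pos_mean}
    return df, offsets


def source_value(
    model: str,
    params: ChoiceParams,
    nAcc_c: np.ndarray | float,
    nPos_c: np.ndarray | float,
    EQ: np.ndarray | float = 0.0,
) -> np.ndarray | float:
    """Linear value of a source under the given model variant."""
    if model == "accpos":
        return params.k_Acc * nAcc_c + params.k_Pos * nPos_c
    if model == "acc":
        return params.k_Acc * nAcc_c
    if model == "pos":
        return params.k_Pos * nPos_c
    if model == "tiebreak":
        return params.k_Acc * nAcc_c + params.k_Pos * nPos_c * EQ
    raise ValueError(f"unknown choice model {model!r}")


def choice_probability(valueX, valueY, beta):
    """Softmax probability of choosing X over Y (log-sum-exp stable)."""
    beta = np.asarray(beta, dtype=float)
    if np.any(beta < 0) or np.any(beta > BETA_MAX):
        raise ValueError(f"beta must lie in [0, {BETA_MAX}]")
    d = beta * (np.asarray(valueX, dtype=float) - np.asarray(valueY, dtype=float))
    # expit computed via where-split to stay stable for large |d|
    out = np.where(d >= 0, 1.0 / (1.0 + np.exp(-np.abs(d))),
                   np.exp(-np.abs(d)) / (1.0 + np.exp(-np.abs(d))))
    return out if out.ndim else float(out)


def choice_loglik(
    model: str, params: ChoiceParams, dataset: pd.DataFrame
) -> tuple[float, np.ndarray]:
    """Total and per-trial log-likelihood of the observed choices.

    ``dataset`` must carry centred covariates (``center_covariates``) and a
    binary ``chose_A`` column.
    """
    if "chose_A" not in dataset.columns or dataset["chose_A"].isna().any():
        raise ValueError("dataset must contain complete 'chose_A' observations")
    eq = dataset["EQ"].to_numpy(float) if "EQ" in dataset.columns else 0.0
    vA = source_value(model, params, dataset["nAccA_c"].to_numpy(float),
                      dataset["nPosA_c"].to_numpy(float), eq)
    vB = source_value(model, params, dataset["nAccB_c"].to_numpy(float),
                      dataset["nPosB_c"].to_numpy(float), eq)
    c = dataset["chose_A"].to_numpy(int)
    sign = np.where(c == 1, 1.0, -1.0)
    d = sign * params.beta * (np.asarray(vA) - np.asarray(vB))
    per_trial = -np.logaddexp(0.0, -d)  # log expit(d), stable
    return float(per_trial.sum()), per_trial


def simulate_choices(
    model: str,
    params: ChoiceParams,
    schedule: pd.DataFrame,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Generative counterpart of the choice likelihood.

    Draws a Bernoulli choice per trial from the softmax probability and a
    shown own-lottery prediction from the chosen source's positivity
    (P(win) = nPos / 5).  ``schedule`` must carry centred covariates.
    """
    df = schedule.copy()
    eq = df["EQ"].to_numpy(float) if "EQ" in df.columns else 0.0
    vA = source_value(model, params, df["nAccA_c"].to_numpy(float),
                      df["nPosA_c"].to_numpy(float), eq)
    vB = source_value(model, params, df["nAccB_c"].to_numpy(float),
                      df["nPosB_c"].to_numpy(float), eq)
    pA = choice_probability(vA, vB, params.beta)
    chose_A = (rng.random(len(df)) < pA).astype(int)
    df["chose_A"] = chose_A
    nacc_chosen = np.where(chose_A == 1, df["nAccA"].to_numpy(int),
                           df["nAccB"].to_numpy(int))
    npos_chosen = np.where(chose_A == 1, df["nPosA"].to_numpy(int),
                           df["nPosB"].to_numpy(int))
    df["shown_prediction"] = [
        sample_own_prediction(PsychicProfile(int(na), int(np_)), rng)
        for na, np_ in zip(nacc_chosen, npos_chosen)
    ]
    return df
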