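"""Synthetic cohorts with the statistical structure the analyses assume.

The behavioural data of the original cohorts are available only on request,
so every analysis in this package runs on cohorts generated here: individual
parameters drawn from group-level Normals at stated hyperparameter values,
schedules built by :mod:`hedoseek.task_design`, and responses generated by
the choice / belief models.

Default generating hyperparameters qualitatively mirror the published
findings (accuracy weight > positivity weight > 0; update asymmetry > 1);
they are illustrative, not estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ndtr, ndtri

from .belief_models import BeliefHyperParams, BeliefParams, simulate_ratings
from .choice_models import (
    BETA_MAX,
    ChoiceHyperParams,
    ChoiceParams,
    center_covariates,
    simulate_choices,
)
from .task_design import (
    build_exp1_schedule,
    build_exp2_schedule,
    default_exp1_combos,
    default_exp2_combos,
    schedule_to_frame,
)

DEFAULT_CHOICE_HYPERS = ChoiceHyperParams(
    mu_kAcc=2.0, sigma_kAcc=0.8,
    mu_kPos=0.7, sigma_kPos=0.5,
    mu_beta=2.0, sigma_beta=1.0,
)

DEFAULT_BELIEF_HYPERS = BeliefHyperParams(
    mu_kCons=6.0, sigma_kCons=8.0,
    mu_kAcc=4.0, sigma_kAcc=1.5,
    mu_kPos=1.0, sigma_kPos=0.5,
    mu_kSym=1.3, sigma_kSym=0.2,
)


@dataclass(frozen=True)
class CohortSpec:
    """Recipe for one synthetic cohort."""

    n_participants: int
    experiment: int                      # 1 or 2
    model: str                           # generating model id
    hypers: ChoiceHyperParams | BeliefHyperParams = None
    random_responder_fraction: float = 0.0
    seed: int = 0
    sigma_U: float | None = 3.0          # None: draw from the Gamma(1, 0.5) prior
    n_blocks: int = 4

    def __post_init__(self) -> None:
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if not (0.0 <= self.random_responder_fraction <= 1.0):
            raise ValueError("random_responder_fraction must lie in [0, 1]")
        if self.experiment not in (1, 2):
            raise ValueError("experiment must be 1 or 2")
        if self.hypers is None:
            default = DEFAULT_CHOICE_HYPERS if self.experiment == 1 else DEFAULT_BELIEF_HYPERS
            object.__setattr__(self, "hypers", default)


def _truncnorm(rng, mu, sigma, lo, hi, size):
    a, b = ndtr((lo - mu) / sigma), ndtr((hi - mu) / sigma)
    u = rng.uniform(a, b, size=size)
    return np.clip(mu + sigma * ndtri(np.clip(u, 1e-12, 1 - 1e-12)), lo, hi)


def draw_participants(spec: CohortSpec, rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Individual parameters drawn from the group-level distributions.

    The inverse temperature is drawn from a Normal truncated to [0, 5]; a
    ``random_responder_fraction`` of participants (the leading ones) get
    beta = 0 (Experiment 1) regardless.
    """
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(1)[0])
    n = spec.n_participants
    h = spec.hypers
    if spec.experiment == 1:
        k_acc = rng.normal(h.mu_kAcc, h.sigma_kAcc, n)
        k_pos = rng.normal(h.mu_kPos, h.sigma_kPos, n)
        beta = _truncnorm(rng, h.mu_beta, h.sigma_beta, 0.0, BETA_MAX, n)
        if spec.model == "acc":
            k_pos = np.zeros(n)
        elif spec.model == "pos":
            k_acc = np.zeros(n)
        n_random = int(round(spec.random_responder_fraction * n))
        beta[:n_random] = 0.0
        return pd.DataFrame(
            dict(participant_id=np.arange(n), k_Acc=k_acc, k_Pos=k_pos, beta=beta)
        )
    k_cons = rng.normal(h.mu_kCons, h.sigma_kCons, n)
    k_acc = rng.normal(h.mu_kAcc, h.sigma_kAcc, n)
    k_pos = rng.normal(h.mu_kPos, h.sigma_kPos, n)
    k_sym = rng.normal(h.mu_kSym, h.sigma_kSym, n)
    if spec.model == "nopos":
        k_pos = np.zeros(n)
    if spec.sigma_U is None:
        sigma_u = rng.gamma(shape=1.0, scale=2.0, size=n)  # Gamma(1, rate 0.5)
    else:
        sigma_u = np.full(n, float(spec.sigma_U))
    return pd.DataFrame(
        dict(
            participant_id=np.arange(n), k_Cons=k_cons, k_Acc=k_acc,
            k_Pos=k_pos, k_Sym=k_sym, sigma_U=sigma_u,
        )
    )


def generate_exp1(
    spec: CohortSpec, combos=None
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """Full Experiment-1 dataset: schedules, softmax choices, shown
    predictions, and block-level win estimates / confidence ratings.

    The block-level estimate and confidence generators are NOT part of the
    published models — they are plumbing to exercise the end-to-end pipeline
    (estimate: shown wins pulled toward the 8-win expectation plus noise;
    confidence: increasing in shown wins).

    Returns (trial dataset with centred covariates, true parameter table,
    centring offsets).
    """
    if spec.experiment != 1:
        raise ValueError("spec.experiment must be 1")
    if combos is None:
        combos = default_exp1_combos()
    seqs = np.random.SeedSequence(spec.seed).spawn(spec.n_participants + 1)
    params = draw_participants(spec, np.random.default_rng(seqs[0]))
    frames = []
    for i in range(spec.n_participants):
        rng_i = np.random.default_rng(seqs[i + 1])
        trials = build_exp1_schedule(combos, spec.n_blocks, rng_i)
        frames.append((schedule_to_frame(trials, participant_id=i), rng_i))
    pooled = pd.concat([f for f, _ in frames], ignore_index=True)
    pooled, offsets = center_covariates(pooled)
    out = []
    for i in range(spec.n_participants):
        rng_i = frames[i][1]
        sub = pooled[pooled["participant_id"] == i].copy()
        row = params.iloc[i]
        p = ChoiceParams(k_Acc=row.k_Acc, k_Pos=row.k_Pos, beta=row.beta)
        sim = simulate_choices(spec.model, p, sub, rng_i)
        # invented block-level plumbing: anchored win estimates and confidence
        for blk, g in sim.groupby("block"):
            shown = int(g["shown_prediction"].sum())
            est = int(np.clip(round(8 + 0.5 * (shown - 8) + rng_i.normal(0, 1.5)), 0, 16))
            conf = float(np.clip(50 + 3 * (shown - 8) + rng_i.normal(0, 10), 0, 100))
            sim.loc[sim["block"] == blk, "win_estimate"] = est
            sim.loc[sim["block"] == blk, "confidence"] = conf
        out.append(sim)
    dataset = pd.concat(out, ignore_index=True)
    return dataset, params, offsets


def generate_exp2(
    spec: CohortSpec, combos=None
) -> tuple[pd.DataFrame, pd.DataFrame, dict[str, float]]:
    """Full Experiment-2 dataset: balanced-direction schedules and ratings
    from the generating belief model, with updates pre-quantified."""
    if spec.experiment != 2:
        raise ValueError("spec.experiment must be 2")
    if combos is None:
        combos = default_exp2_combos()
    seqs = np.random.SeedSequence(spec.seed).spawn(spec.n_participants + 1)
    params = draw_participants(spec, np.random.default_rng(seqs[0]))
    frames = []
    for i in range(spec.n_participants):
        rng_i = np.random.default_rng(seqs[i + 1])
        trials = build_exp2_schedule(combos, rng_i)
        frames.append((schedule_to_frame(trials, participant_id=i), rng_i))
    pooled = pd.concat([f for f, _ in frames], ignore_index=True)
    pooled, offsets = center_covariates(pooled)
    out = []
    for i in range(spec.n_participants):
        rng_i = frames[i][1]
        sub = pooled[pooled["participant_id"] == i].copy()
        row = params.iloc[i]
        p = BeliefParams(
            k_Cons=row.k_Cons, k_Acc=row.k_Acc, k_Pos=row.k_Pos,
            k_Sym=row.k_Sym, sigma_U=row.sigma_U,
        )
        out.append(simulate_ratings(spec.model, p, sub, rng_i))
    dataset = pd.concat(out, ignore_index=True)
    return dataset, params, offsets
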