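"""Unconstrained log-posterior densities (with analytic gradients) for the
six hierarchical models, plus transforms between sampler space and the named
parameter space.

Conventions
-----------
- Individual weights use the non-centred parameterisation
  ``k_i = mu + sigma * z_i`` with ``z_i ~ Normal(0, 1)``.
- Scales carry Gamma(1, 0.5) (= Exponential(rate 0.5)) priors and are
  sampled as logs.
- The choice-model inverse temperature is mapped to [0, 5] by a scaled
  logistic transform; its Normal(mu_beta, sigma_beta) prior is normalised
  over the interval (proper truncated density).
- Belief-model hyper-location ``mu_kSym`` is sampled as its log, which
  carries the Normal(0, 1) hyperprior.

Hyperpriors: mu_k* ~ Normal(0, 1); mu_beta ~ Normal(0, 2);
all sigma ~ Gamma(1, 0.5); log(mu_kSym) ~ Normal(0, 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit as _expit, log_expit, log_ndtr, ndtri

BETA_MAX = 5.0
_LOG2PI = float(np.log(2.0 * np.pi))
_HALF_LOG2PI = 0.5 * _LOG2PI


# ---------------------------------------------------------------------------
# numerics helpers

def _truncnorm_logz(mu: float, sig: float, lo: float = 0.0, hi: float = BETA_MAX):
    """log Z = log(Phi(hi') - Phi(lo')) and its gradients wrt mu and sigma."""
    a = (lo - mu) / sig
    g = (hi - mu) / sig
    la, lg_ = log_ndtr(a), log_ndtr(g)
    # log(exp(lg) - exp(la)) with lg >= la
    diff = la - lg_
    logz = lg_ + np.log(-np.expm1(diff)) if diff < -1e-12 else lg_ + np.log(1e-300)
    lpdf_a = -0.5 * a * a - _HALF_LOG2PI
    lpdf_g = -0.5 * g * g - _HALF_LOG2PI
    ra = np.exp(lpdf_a - logz)
    rg = np.exp(lpdf_g - logz)
    dmu = (ra - rg) / sig
    dsig = (a * ra - g * rg) / sig
    return float(logz), float(dmu), float(dsig)


def _exp_prior_logp_grad(sig: float):
    """Gamma(1, 0.5) prior on sigma, parameterised by log sigma (with
    Jacobian): returns (logp, d logp / d log sigma)."""
    return np.log(0.5) - 0.5 * sig + np.log(sig), 1.0 - 0.5 * sig


# ---------------------------------------------------------------------------
# data containers

@dataclass
class ChoiceData:
    """Trial-level arrays for the two-source choice likelihood."""

    pid: np.ndarray          # participant index per trial (0..n-1)
    d_acc: np.ndarray        # centred accuracy difference A - B
    d_pos: np.ndarray        # centred positivity difference A - B
    eq: np.ndarray           # 1 if equally accurate
    chose_a: np.ndarray      # observed choice
    n_participants: int
    participant_ids: np.ndarray

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "ChoiceData":
        required = {"participant_id", "nAccA_c", "nPosA_c", "nAccB_c", "nPosB_c",
                    "EQ", "chose_A"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"choice dataset missing columns: {sorted(missing)}")
        ids = np.unique(df["participant_id"].to_numpy())
        lookup = {v: i for i, v in enumerate(ids)}
        pid = df["participant_id"].map(lookup).to_numpy(int)
        return cls(
            pid=pid,
            d_acc=df["nAccA_c"].to_numpy(float) - df["nAccB_c"].to_numpy(float),
            d_pos=df["nPosA_c"].to_numpy(float) - df["nPosB_c"].to_numpy(float),
            eq=df["EQ"].to_numpy(float),
            chose_a=df["chose_A"].to_numpy(int),
            n_participants=len(ids),
            participant_ids=ids,
        )


@dataclass
class BeliefData:
    """Trial-level arrays for the Gaussian belief-update likelihood."""

    pid: np.ndarray
    acc: np.ndarray          # centred accuracy of the single source
    pos: np.ndarray          # centred positivity
    direction: np.ndarray    # Dir in {0, 1}
    u: np.ndarray            # quantified update
    n_participants: int
    participant_ids: np.ndarray

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "BeliefData":
        required = {"participant_id", "nAccA_c", "nPosA_c", "dir_prediction", "update"}
        missing = required - set(df.columns)
        if missing:
            raise ValueError(f"belief dataset missing columns: {sorted(missing)}")
        ids = np.unique(df["participant_id"].to_numpy())
        lookup = {v: i for i, v in enumerate(ids)}
        return cls(
            pid=df["participant_id"].map(lookup).to_numpy(int),
            acc=df["nAccA_c"].to_numpy(float),
            pos=df["nPosA_c"].to_numpy(float),
            direction=df["dir_prediction"].to_numpy(float),
            u=df["update"].to_numpy(float),
            n_participants=len(ids),
            participant_ids=ids,
        )


# ---------------------------------------------------------------------------
# choice-model posterior

class ChoicePosterior:
    """Joint log density of one choice model on the unconstrained scale."""

    def __init__(self, model: str, data: ChoiceData):
        if model not in ("accpos", "acc", "pos", "tiebreak"):
            raise ValueError(f"unknown choice model {model!r}")
        self.model = model
        self.data = data
        self.has_acc = model in ("accpos", "acc", "tiebreak")
        self.has_pos = model in ("accpos", "pos", "tiebreak")
        n = data.n_participants
        self._dp = data.d_pos * data.eq if model == "tiebreak" else data.d_pos
        self._sign = np.where(data.chose_a == 1, 1.0, -1.0)
        # layout: hyper locations, log hyper scales, then per-participant blocks
        names = []
        if self.has_acc:
            names.append("mu_kAcc")
        if self.has_pos:
            names.append("mu_kPos")
        names.append("mu_beta")
        if self.has_acc:
            names.append("log_sigma_kAcc")
        if self.has_pos:
            names.append("log_sigma_kPos")
        names.append("log_sigma_beta")
        self.hyper_names = names
        self.n_hyper = len(names)
        blocks = (int(self.has_acc) + int(self.has_pos) + 1)
        self.dim = self.n_hyper + blocks * n

    # -- layout helpers -----------------------------------------------------
    def _split(self, theta: np.ndarray):
        n = self.data.n_participants
        h = theta[: self.n_hyper]
        rest = theta[self.n_hyper:]
        i = 0
        z_acc = z_pos = None
        if self.has_acc:
            z_acc = rest[i * n:(i + 1) * n]; i += 1
        if self.has_pos:
            z_pos = rest[i * n:(i + 1) * n]; i += 1
        y_beta = rest[i * n:(i + 1) * n]
        return h, z_acc, z_pos, y_beta

    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        return 0.5 * rng.uniform(-1, 1, size=self.dim)

    # -- density ------------------------------------------------------------
    def logp_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        d = self.data
        n = d.n_participants
        h, z_acc, z_pos, y_beta = self._split(theta)
        hv = dict(zip(self.hyper_names, h))
        grad = np.zeros_like(theta)
        gh = np.zeros(self.n_hyper)
        logp = 0.0

        sig = {k[10:]: float(np.exp(v)) for k, v in hv.items() if k.startswith("log_sigma")}

        # hyperpriors
        for j, name in enumerate(self.hyper_names):
            v = float(hv[name])
            if name == "mu_beta":
                logp += -0.5 * (v / 2.0) ** 2 - np.log(2.0) - _HALF_LOG2PI
                gh[j] += -v / 4.0
            elif name.startswith("mu_"):
                logp += -0.5 * v * v - _HALF_LOG2PI
                gh[j] += -v
            else:  # log sigma
                lp, g = _exp_prior_logp_grad(sig[name[10:]])
                logp += lp
                gh[j] += g

        # individual parameters
        k_acc = k_pos = None
        g_zacc = g_zpos = None
        if self.has_acc:
            k_acc = hv["mu_kAcc"] + sig["kAcc"] * z_acc
            logp += float(-0.5 * np.dot(z_acc, z_acc) - n * _HALF_LOG2PI)
        if self.has_pos:
            k_pos = hv["mu_kPos"] + sig["kPos"] * z_pos
            logp += float(-0.5 * np.dot(z_pos, z_pos) - n * _HALF_LOG2PI)

        s_b = _expit(y_beta)
        beta = BETA_MAX * s_b
        mu_b, sig_b = float(hv["mu_beta"]), sig["beta"]
        e_b = (beta - mu_b) / sig_b**2
        logz, dlogz_dmu, dlogz_dsig = _truncnorm_logz(mu_b, sig_b)
        logp += float(
            np.sum(-0.5 * ((beta - mu_b) / sig_b) ** 2 - np.log(sig_b) - _HALF_LOG2PI)
            - n * logz
            + np.sum(np.log(BETA_MAX) + log_expit(y_beta) + log_expit(-y_beta))
        )

        # likelihood
        dv = np.zeros(len(d.pid))
        if self.has_acc:
            dv += k_acc[d.pid] * d.d_acc
        if self.has_pos:
            dv += k_pos[d.pid] * self._dp
        beta_t = beta[d.pid]
        eta = self._sign * beta_t * dv
        logp += float(np.sum(log_expit(eta)))
        q = self._sign * _expit(-eta)          # d loglik / d eta

        # gradients: likelihood -> individual params
        g_beta_lik = np.bincount(d.pid, weights=q * dv, minlength=n)
        if self.has_acc:
            g_kacc = np.bincount(d.pid, weights=q * beta_t * d.d_acc, minlength=n)
        if self.has_pos:
            g_kpos = np.bincount(d.pid, weights=q * beta_t * self._dp, minlength=n)

        # chain rules to unconstrained space
        idx = {name: j for j, name in enumerate(self.hyper_names)}
        if self.has_acc:
            gh[idx["mu_kAcc"]] += float(np.sum(g_kacc))
            gh[idx["log_sigma_kAcc"]] += sig["kAcc"] * float(np.dot(g_kacc, z_acc))
            g_zacc = g_kacc * sig["kAcc"] - z_acc
        if self.has_pos:
            gh[idx["mu_kPos"]] += float(np.sum(g_kpos))
            gh[idx["log_sigma_kPos"]] += sig["kPos"] * float(np.dot(g_kpos, z_pos))
            g_zpos = g_kpos * sig["kPos"] - z_pos

        g_beta_total = g_beta_lik - e_b        # + prior term d/d beta_i
        g_y = g_beta_total * BETA_MAX * s_b * (1 - s_b) + (1 - 2 * s_b)
        gh[idx["mu_beta"]] += float(np.sum(e_b)) - n * dlogz_dmu
        gh[idx["log_sigma_beta"]] += (
            float(np.sum(((beta - mu_b) / sig_b) ** 2 - 1.0))
            - n * sig_b * dlogz_dsig
        )

        grad[: self.n_hyper] = gh
        pieces = []
        if self.has_acc:
            pieces.append(g_zacc)
        if self.has_pos:
            pieces.append(g_zpos)
        pieces.append(g_y)
        if n:
            grad[self.n_hyper:] = np.concatenate(pieces)
        return float(logp), grad

    # -- transforms ---------------------------------------------------------
    def constrain(self, draws: np.ndarray) -> dict[str, np.ndarray]:
        """Map (S, dim) unconstrained draws to named constrained arrays."""
        draws = np.atleast_2d(draws)
        n = self.data.n_participants
        out: dict[str, np.ndarray] = {}
        for j, name in enumerate(self.hyper_names):
            col = draws[:, j]
            if name.startswith("log_sigma"):
                out["sigma_" + name[10:]] = np.exp(col)
            else:
                out[name] = col.copy()
        rest = draws[:, self.n_hyper:]
        i = 0
        if self.has_acc:
            z = rest[:, i * n:(i + 1) * n]; i += 1
            out["k_Acc"] = out["mu_kAcc"][:, None] + out["sigma_kAcc"][:, None] * z
        if self.has_pos:
            z = rest[:, i * n:(i + 1) * n]; i += 1
            out["k_Pos"] = out["mu_kPos"][:, None] + out["sigma_kPos"][:, None] * z
        y = rest[:, i * n:(i + 1) * n]
        out["beta"] = BETA_MAX * _expit(y)
        return out

    def pointwise_loglik(self, constrained: dict[str, np.ndarray]) -> np.ndarray:
        """(S, T) log-likelihood of every observation at every draw."""
        d = self.data
        dv = np.zeros((next(iter(constrained.values())).shape[0], len(d.pid)))
        if self.has_acc:
            dv += constrained["k_Acc"][:, d.pid] * d.d_acc
        if self.has_pos:
            dv += constrained["k_Pos"][:, d.pid] * self._dp
        eta = self._sign * constrained["beta"][:, d.pid] * dv
        return -np.logaddexp(0.0, -eta)

    def loglik_new_participant(
        self,
        constrained: dict[str, np.ndarray],
        df_i: pd.DataFrame,
        n_inner: int,
        rng: np.random.Generator,
    ) -> np.ndarray:
        """log p(participant data | hypers) per draw, marginalising the
        individual parameters by Monte Carlo over the group distribution."""
        d_acc = df_i["nAccA_c"].to_numpy(float) - df_i["nAccB_c"].to_numpy(float)
        d_pos = df_i["nPosA_c"].to_numpy(float) - df_i["nPosB_c"].to_numpy(float)
        if self.model == "tiebreak":
            d_pos = d_pos * df_i["EQ"].to_numpy(float)
        sign = np.where(df_i["chose_A"].to_numpy(int) == 1, 1.0, -1.0)
        S = next(iter(constrained.values())).shape[0]
        dv = np.zeros((S, n_inner, len(sign)))
        if self.has_acc:
            k = constrained["mu_kAcc"][:, None] + constrained["sigma_kAcc"][:, None] \
                * rng.standard_normal((S, n_inner))
            dv += k[:, :, None] * d_acc
        if self.has_pos:
            k = constrained["mu_kPos"][:, None] + constrained["sigma_kPos"][:, None] \
                * rng.standard_normal((S, n_inner))
            dv += k[:, :, None] * d_pos
        # truncated-normal beta draws via inverse CDF
        mu_b = constrained["mu_beta"][:, None]
        sig_b = constrained["sigma_beta"][:, None]
        from scipy.special import ndtr
        lo = ndtr((0.0 - mu_b) / sig_b)
        hi = ndtr((BETA_MAX - mu_b) / sig_b)
        u = rng.random((S, n_inner))
        beta = mu_b + sig_b * ndtri(np.clip(lo + u * (hi - lo), 1e-12, 1 - 1e-12))
        beta = np.clip(beta, 0.0, BETA_MAX)
        eta = sign * beta[:, :, None] * dv
        ll = np.sum(-np.logaddexp(0.0, -eta), axis=2)     # (S, n_inner)
        from scipy.special import logsumexp
        return logsumexp(ll, axis=1) - np.log(n_inner)


# ---------------------------------------------------------------------------
# belief-model posterior

class BeliefPosterior:
    """Joint log density of one belief-update model, unconstrained scale."""

    def __init__(self, model: str, data: BeliefData):
        if model not in ("full", "nopos"):
            raise ValueError(f"unknown belief model {model!r}")
        self.model = model
        self.data = data
        self.has_pos = model == "full"
        n = data.n_participants
        names = ["mu_kCons", "mu_kAcc"]
        if self.has_pos:
            names.append("mu_kPos")
        names.append("log_mu_kSym")
        names += ["log_sigma_kCons", "log_sigma_kAcc"]
        if self.has_pos:
            names.append("log_sigma_kPos")
        names.append("log_sigma_kSym")
        self.hyper_names = names
        self.n_hyper = len(names)
        blocks = 4 + int(self.has_pos)  # zCons, zAcc, (zPos), zSym, log_sigU
        self.dim = self.n_hyper + blocks * n

    def _split(self, theta: np.ndarray):
        n = self.data.n_participants
        h = theta[: self.n_hyper]
        rest = theta[self.n_hyper:]
        i = 0
        z_cons = rest[i * n:(i + 1) * n]; i += 1
        z_acc = rest[i * n:(i + 1) * n]; i += 1
        z_pos = None
        if self.has_pos:
            z_pos = rest[i * n:(i + 1) * n]; i += 1
        z_sym = rest[i * n:(i + 1) * n]; i += 1
        log_sigu = rest[i * n:(i + 1) * n]
        return h, z_cons, z_acc, z_pos, z_sym, log_sigu

    def initial_point(self, rng: np.random.Generator) -> np.ndarray:
        x = 0.5 * rng.uniform(-1, 1, size=self.dim)
        n = self.data.n_participants
        if n and len(self.data.u):
            sd = max(float(np.std(self.data.u)), 1.0)
            x[-n:] = np.log(sd) + 0.1 * rng.uniform(-1, 1, size=n)
        return x

    def logp_grad(self, theta: np.ndarray) -> tuple[float, np.ndarray]:
        d = self.data
        n = d.n_participants
        h, z_cons, z_acc, z_pos, z_sym, log_sigu = self._split(theta)
        hv = dict(zip(self.hyper_names, h))
        idx = {name: j for j, name in enumerate(self.hyper_names)}
        gh = np.zeros(self.n_hyper)
        logp = 0.0

        sig = {k[10:]: float(np.exp(v)) for k, v in hv.items() if k.startswith("log_sigma")}
        mu_sym = float(np.exp(hv["log_mu_kSym"]))

        # hyperpriors: locations N(0,1); log mu_kSym N(0,1); scales Exp(0.5)
        for j, name in enumerate(self.hyper_names):
            v = float(hv[name])
            if name.startswith("mu_") or name == "log_mu_kSym":
                logp += -0.5 * v * v - _HALF_LOG2PI
                gh[j] += -v
            else:
                lp, g = _exp_prior_logp_grad(sig[name[10:]])
                logp += lp
                gh[j] += g

        # non-centred individual parameters
        k_cons = hv["mu_kCons"] + sig["kCons"] * z_cons
        k_acc = hv["mu_kAcc"] + sig["kAcc"] * z_acc
        k_sym = mu_sym + sig["kSym"] * z_sym
        logp += float(-0.5 * (np.dot(z_cons, z_cons) + np.dot(z_acc, z_acc)
                              + np.dot(z_sym, z_sym)) - 3 * n * _HALF_LOG2PI)
        if self.has_pos:
            k_pos = hv["mu_kPos"] + sig["kPos"] * z_pos
            logp += float(-0.5 * np.dot(z_pos, z_pos) - n * _HALF_LOG2PI)

        sig_u = np.exp(log_sigu)
        # Gamma(1, 0.5) prior on each sigma_U with log-transform Jacobian
        logp += float(np.sum(np.log(0.5) - 0.5 * sig_u + log_sigu))
        g_logsigu = 1.0 - 0.5 * sig_u

        # likelihood
        linear = k_cons[d.pid] + k_acc[d.pid] * d.acc
        if self.has_pos:
            linear = linear + k_pos[d.pid] * d.pos
        mult = 1.0 + (k_sym[d.pid] - 1.0) * d.direction
        mu_t = linear * mult
        s_t = sig_u[d.pid]
        resid = d.u - mu_t
        z_t = resid / s_t
        logp += float(np.sum(-0.5 * z_t**2 - log_sigu[d.pid] - _HALF_LOG2PI))

        r = resid / s_t**2
        g_cons = np.bincount(d.pid, weights=r * mult, minlength=n)
        g_acc = np.bincount(d.pid, weights=r * mult * d.acc, minlength=n)
        g_sym = np.bincount(d.pid, weights=r * linear * d.direction, minlength=n)
        g_logsigu = g_logsigu + np.bincount(d.pid, weights=z_t**2 - 1.0, minlength=n)

        gh[idx["mu_kCons"]] += float(np.sum(g_cons))
        gh[idx["log_sigma_kCons"]] += sig["kCons"] * float(np.dot(g_cons, z_cons))
        g_zcons = g_cons * sig["kCons"] - z_cons
        gh[idx["mu_kAcc"]] += float(np.sum(g_acc))
        gh[idx["log_sigma_kAcc"]] += sig["kAcc"] * float(np.dot(g_acc, z_acc))
        g_zacc = g_acc * sig["kAcc"] - z_acc
        gh[idx["log_mu_kSym"]] += mu_sym * float(np.sum(g_sym))
        gh[idx["log_sigma_kSym"]] += sig["kSym"] * float(np.dot(g_sym, z_sym))
        g_zsym = g_sym * sig["kSym"] - z_sym
        pieces = [g_zcons, g_zacc]
        if self.has_pos:
            g_pos = np.bincount(d.pid, weights=r * mult * d.pos, minlength=n)
            gh[idx["mu_kPos"]] += float(np.sum(g_pos))
            gh[idx["log_sigma_kPos"]] += sig["kPos"] * float(np.dot(g_pos, z_pos))
            pieces.append(g_pos * sig["kPos"] - z_pos)
        pieces += [g_zsym, g_logsigu]

        grad = np.zeros_like(theta)
        grad[: self.n_hyper] = gh
        if n:
            grad[self.n_hyper:] = np.concatenate(pieces)
        return float(logp), grad

    def constrain(self, draws: np.ndarray) -> dict[str, np.ndarray]:
        draws = np.atleast_2d(draws)
        n = self.data.n_participants
        out: dict[str, np.ndarray] = {}
        for j, name in enumerate(self.hyper_names):
            col = draws[:, j]
            if name.startswith("log_sigma"):
                out["sigma_" + name[10:]] = np.exp(col)
            elif name == "log_mu_kSym":
                out["mu_kSym"] = np.exp(col)
            else:
                out[name] = col.copy()
        rest = draws[:, self.n_hyper:]
        i = 0
        out["k_Cons"] = out["mu_kCons"][:, None] + out["sigma_kCons"][:, None] \
            * rest[:, i * n:(i + 1) * n]; i += 1
        out["k_Acc"] = out["mu_kAcc"][:, None] + out["sigma_kAcc"][:, None] \
            * rest[:, i * n:(i + 1) * n]; i += 1
        if self.has_pos:
            out["k_Pos"] = out["mu_kPos"][:, None] + out["sigma_kPos"][:, None] \
                * rest[:, i * n:(i + 1) * n]; i += 1
        out["k_Sym"] = out["mu_kSym"][:, None] + out["sigma_kSym"][:, None] \
            * rest[:, i * n:(i + 1) * n]; i += 1
        out["sigma_U"] = np.exp(rest[:, i * n:(i + 1) * n])
        return out

    def pointwise_loglik(self, constrained: dict[str, np.ndarray]) -> np.ndarray:
        d = self.data
        linear = constrained["k_Cons"][:, d.pid] + constrained["k_Acc"][:, d.pid] * d.acc
        if self.has_pos:
            linear = linear + constrained["k_Pos"][:, d.pid] * d.pos
        mult = 1.0 + (constrained["k_Sym"][:, d.pid] - 1.0) * d.direction
        mu = linear * mult
        s = constrained["sigma_U"][:, d.pid]
        return -0.5 * ((d.u - mu) / s) ** 2 - np.log(s) - _HALF_LOG2PI

    def loglik_new_participant(
        self,
        constrained: dict[str, np.ndarray],
        df_i: pd.DataFrame,
        n_inner: int,
        rng: np.random.Generator,
    ) -> np.ndarray:
        acc = df_i["nAccA_c"].to_numpy(float)
        pos = df_i["nPosA_c"].to_numpy(float)
        direction = df_i["dir_prediction"].to_numpy(float)
        u = df_i["update"].to_numpy(float)
        S = next(iter(constrained.values())).shape[0]
        shape = (S, n_inner)
        k_cons = constrained["mu_kCons"][:, None] + constrained["sigma_kCons"][:, None] \
            * rng.standard_normal(shape)
        k_acc = constrained["mu_kAcc"][:, None] + constrained["sigma_kAcc"][:, None] \
            * rng.standard_normal(shape)
        k_sym = constrained["mu_kSym"][:, None] + constrained["sigma_kSym"][:, None] \
            * rng.standard_normal(shape)
        linear = k_cons[:, :, None] + k_acc[:, :, None] * acc
        if self.has_pos:
            k_pos = constrained["mu_kPos"][:, None] + constrained["sigma_kPos"][:, None] \
                * rng.standard_normal(shape)
            linear = linear + k_pos[:, :, None] * pos
        mult = 1.0 + (k_sym[:, :, None] - 1.0) * direction
        mu = linear * mult
        sig_u = rng.exponential(2.0, size=shape)[:, :, None]  # Gamma(1, 0.5) prior
        ll = np.sum(-0.5 * ((u - mu) / sig_u) ** 2 - np.log(sig_u) - _HALF_LOG2PI, axis=2)
        from scipy.special import logsumexp
        return logsumexp(ll, axis=1) - np.log(n_inner)


def build_posterior(model: str, dataset: pd.DataFrame):
    """Factory: choice models get a ChoicePosterior, belief models a
    BeliefPosterior."""
    if model in ("accpos", "acc", "pos", "tiebreak"):
        return ChoicePosterior(model, ChoiceData.from_frame(dataset))
    if model in ("full", "nopos"):
        return BeliefPosterior(model, BeliefData.from_frame(dataset))
    raise ValueError(f"unknown model {model!r}")
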