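"""Trial-structure enumeration, validation and scheduling for both experiments.

An information source ("psychic") is summarised by the pair ``(nAcc, nPos)``:
of the five example-lottery predictions it made, how many were correct and how
many were "win" predictions.  Not every pair is realisable for a given number
of true wins ``w`` among the five example lotteries — the combinatorics live
here, together with schedule builders for the two experiments.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

N_EXAMPLES = 5
MIN_ACCURACY = 3

__all__ = [
    "PsychicProfile",
    "TrialSpecExp1",
    "TrialSpecExp2",
    "enumerate_profiles",
    "enumerate_pair_combinations",
    "validate_trial",
    "default_exp1_combos",
    "default_exp2_combos",
    "build_exp1_schedule",
    "build_exp2_schedule",
    "sample_own_prediction",
    "schedule_to_frame",
]


@dataclass(frozen=True, order=True)
class PsychicProfile:
    """Summary of one source's five example predictions.

    Parameters
    ----------
    nAcc : int
        Number of correct example predictions.  The task's minimum-accuracy
        rule (>= 3) is enforced by ``validate_trial`` and the enumeration
        functions, not by the constructor, so that invalid designs can be
        represented and reported.
    nPos : int
        Number of "win" example predictions.
    pattern : tuple, optional
        Ordered (prediction, outcome) pairs with entries in {"win", "loss"};
        must be consistent with (nAcc, nPos) when given.
    """

    nAcc: int
    nPos: int
    pattern: tuple | None = field(default=None, compare=False)

    def __post_init__(self) -> None:
        if not (0 <= self.nPos <= N_EXAMPLES):
            raise ValueError(f"nPos must be in [0, {N_EXAMPLES}], got {self.nPos}")
        if not (0 <= self.nAcc <= N_EXAMPLES):
            raise ValueError(f"nAcc must be in [0, {N_EXAMPLES}], got {self.nAcc}")
        if self.pattern is not None:
            if len(self.pattern) != N_EXAMPLES:
                raise ValueError("pattern must have length 5")
            n_acc = sum(p == o for p, o in self.pattern)
            n_pos = sum(p == "win" for p, _ in self.pattern)
            if (n_acc, n_pos) != (self.nAcc, self.nPos):
                raise ValueError(
                    f"pattern implies ({n_acc}, {n_pos}), "
                    f"profile says ({self.nAcc}, {self.nPos})"
                )

    def as_tuple(self) -> tuple[int, int]:
        return (self.nAcc, self.nPos)


@dataclass(frozen=True)
class TrialSpecExp1:
    """One two-source trial: true-win count, the two profiles, block, layout."""

    w: int
    profileA: PsychicProfile
    profileB: PsychicProfile
    block: int = 1
    sideOfA: str = "left"

    def __post_init__(self) -> None:
        if self.sideOfA not in ("left", "right"):
            raise ValueError("sideOfA must be 'left' or 'right'")


@dataclass(frozen=True)
class TrialSpecExp2:
    """One single-source trial with an own-lottery prediction direction."""

    w: int
    profile: PsychicProfile
    Dir: int
    repetition: int = 1
    block: int = 1

    def __post_init__(self) -> None:
        if self.Dir not in (0, 1):
            raise ValueError("Dir must be 0 or 1")


def _feasible(w: int, nAcc: int, nPos: int) -> bool:
    """Feasibility of (nAcc, nPos) under w true wins.

    A wrong prediction on a loss lottery is necessarily a "win" prediction, so
    with x = number of correctly predicted win lotteries:
    nPos = x + (5 - w - (nAcc - x))  =>  nAcc + nPos + w must be odd and
    x = (nAcc + nPos + w - 5) / 2 must satisfy
    max(0, nAcc + w - 5) <= x <= min(nAcc, w).
    """
    if (nAcc + nPos + w) % 2 == 0:
        return False
    x2 = nAcc + nPos + w - N_EXAMPLES
    if x2 % 2 != 0:
        return False
    x = x2 // 2
    return max(0, nAcc + w - N_EXAMPLES) <= x <= min(nAcc, w)


def enumerate_profiles(w: int) -> list[PsychicProfile]:
    """All feasible profiles for ``w`` true wins, sorted by (nAcc, nPos).

    Realisable (nAcc, nPos) pairs over binary prediction patterns on five
    lotteries with ``w`` win outcomes, subject to nAcc >= 3.
    """
    if not (0 <= w <= N_EXAMPLES):
        raise ValueError(f"w must be in [0, {N_EXAMPLES}], got {w}")
    out = [
        PsychicProfile(nAcc, nPos)
        for nAcc in range(MIN_ACCURACY, N_EXAMPLES + 1)
        for nPos in range(N_EXAMPLES + 1)
        if _feasible(w, nAcc, nPos)
    ]
    return sorted(out)


def enumerate_pair_combinations() -> list[tuple[int, tuple[PsychicProfile, PsychicProfile]]]:
    """All (w, unordered pair of distinct feasible profiles), for w in 0..5.

    The pair is returned sorted so each unordered pair appears exactly once.
    The total count across w is asserted to equal 56, the number of admissible
    trial configurations in the two-source task.
    """
    combos: list[tuple[int, tuple[PsychicProfile, PsychicProfile]]] = []
    for w in range(N_EXAMPLES + 1):
        profs = enumerate_profiles(w)
        for a, b in itertools.combinations(profs, 2):
            combos.append((w, (a, b)))
    assert len(combos) == 56, f"expected 56 trial combinations, got {len(combos)}"
    return combos


def validate_trial(spec: TrialSpecExp1 | TrialSpecExp2) -> list[str]:
    """Report every violated design invariant; an empty list means valid."""
    problems: list[str] = []
    if not (0 <= spec.w <= N_EXAMPLES):
        problems.append(f"w={spec.w} outside [0, {N_EXAMPLES}]")
        return problems
    if isinstance(spec, TrialSpecExp1):
        for label, p in (("A", spec.profileA), ("B", spec.profileB)):
            if p.nAcc < MIN_ACCURACY:
                problems.append(
                    f"profile {label} nAcc={p.nAcc} below minimum accuracy {MIN_ACCURACY}"
                )
            elif (p.nAcc + p.nPos + spec.w) % 2 == 0:
                problems.append(
                    f"profile {label} ({p.nAcc},{p.nPos}) violates parity for w={spec.w}"
                )
            elif not _feasible(spec.w, p.nAcc, p.nPos):
                problems.append(
                    f"profile {label} ({p.nAcc},{p.nPos}) infeasible for w={spec.w}"
                )
        if spec.profileA.as_tuple() == spec.profileB.as_tuple():
            problems.append("profiles A and B are identical")
    else:
        p = spec.profile
        if p.nAcc < MIN_ACCURACY:
            problems.append(
                f"profile nAcc={p.nAcc} below minimum accuracy {MIN_ACCURACY}"
            )
        elif (p.nAcc + p.nPos + spec.w) % 2 == 0:
            problems.append(
                f"profile ({p.nAcc},{p.nPos}) violates parity for w={spec.w}"
            )
        elif not _feasible(spec.w, p.nAcc, p.nPos):
            problems.append(f"profile ({p.nAcc},{p.nPos}) infeasible for w={spec.w}")
    return problems


def default_exp1_combos() -> list[tuple[int, tuple[PsychicProfile, PsychicProfile]]]:
    """Default stratified 16-combination subset of the 56 admissible trials.

    The published 16-trial selection is not reproducible from the article text,
    so the default is a documented stratified sample: for every w it includes
    (when available, in deterministic sorted order)

    1. one equal-accuracy pair (profiles differing only in positivity),
    2. one unequal-accuracy pair where the more accurate source is also the
       more positive,
    3. one unequal-accuracy pair where the more accurate source is the less
       positive,

    then tops up deterministically with further equal-accuracy pairs to reach
    16.  The result covers all w, both equal- and unequal-accuracy pairs, and
    both positivity orderings.
    """
    buckets: dict[int, list[list[tuple[PsychicProfile, PsychicProfile]]]] = {}
    for w in range(N_EXAMPLES + 1):
        profs = enumerate_profiles(w)
        pairs = list(itertools.combinations(profs, 2))
        eq = [p for p in pairs if p[0].nAcc == p[1].nAcc]
        # positivity aligned / opposed with accuracy among unequal-accuracy pairs
        aligned = [
            p for p in pairs
            if p[0].nAcc != p[1].nAcc
            and (p[0].nAcc - p[1].nAcc) * (p[0].nPos - p[1].nPos) > 0
        ]
        opposed = [
            p for p in pairs
            if p[0].nAcc != p[1].nAcc
            and (p[0].nAcc - p[1].nAcc) * (p[0].nPos - p[1].nPos) < 0
        ]
        buckets[w] = [eq, aligned, opposed]
    picks: list[tuple[int, tuple[PsychicProfile, PsychicProfile]]] = []
    for w in range(N_EXAMPLES + 1):
        for bucket in buckets[w]:
            if bucket:
                picks.append((w, bucket.pop(0)))
    # w=0 and w=5 each fill a single bucket, leaving 14 picks; top up with
    # extra equal-accuracy pairs (they carry the positivity signal) from the
    # middle w values, in deterministic order
    for w in (2, 3, 1, 4):
        if len(picks) >= 16:
            break
        if buckets[w][0]:
            picks.append((w, buckets[w][0].pop(0)))
    picks.sort(key=lambda c: (c[0], c[1][0].as_tuple(), c[1][1].as_tuple()))
    assert len(picks) == 16
    return picks


def default_exp2_combos() -> list[tuple[int, PsychicProfile]]:
    """All feasible (w, profile) with w in {2, 3} and nAcc in {3, 4}."""
    out = [
        (w, p)
        for w in (2, 3)
        for p in enumerate_profiles(w)
        if p.nAcc in (3, 4)
    ]
    return out


def build_exp1_schedule(
    combos: Sequence[tuple[int, tuple[PsychicProfile, PsychicProfile]]],
    n_blocks: int,
    rng: np.random.Generator,
) -> list[TrialSpecExp1]:
    """Blocked schedule: each combo once per block, order and sides randomised."""
    if n_blocks < 1:
        raise ValueError("n_blocks must be >= 1")
    for w, (a, b) in combos:
        report = validate_trial(TrialSpecExp1(w=w, profileA=a, profileB=b))
        if report:
            raise ValueError(f"invalid combo (w={w}, {a.as_tuple()}, {b.as_tuple()}): {report}")
    trials: list[TrialSpecExp1] = []
    for block in range(1, n_blocks + 1):
        order = rng.permutation(len(combos))
        sides = rng.integers(0, 2, size=len(combos))
        for j, idx in enumerate(order):
            w, (a, b) = combos[idx]
            trials.append(
                TrialSpecExp1(
                    w=w,
                    profileA=a,
                    profileB=b,
                    block=block,
                    sideOfA="left" if sides[j] == 0 else "right",
                )
            )
    return trials


def build_exp2_schedule(
    combos: Sequence[tuple[int, PsychicProfile]],
    rng: np.random.Generator,
) -> list[TrialSpecExp2]:
    """Four repetitions per combo: two win- and two loss-predictions, with two
    repetitions pseudo-randomised into blocks 1-2 and two into blocks 3-4."""
    for w, p in combos:
        if w not in (2, 3):
            raise ValueError(f"Exp2 requires w in {{2, 3}}, got {w}")
        if p.nAcc not in (3, 4):
            raise ValueError(f"Exp2 requires nAcc in {{3, 4}}, got {p.nAcc}")
        report = validate_trial(TrialSpecExp2(w=w, profile=p, Dir=0))
        if report:
            raise ValueError(f"invalid combo (w={w}, {p.as_tuple()}): {report}")
    # per combo: assign the four (Dir, half) cells — one win and one loss
    # prediction in each experiment half
    per_block: dict[int, list[TrialSpecExp2]] = {1: [], 2: [], 3: [], 4: []}
    for w, p in combos:
        for half, blocks in ((0, (1, 2)), (1, (3, 4))):
            dirs = [0, 1]
            rng.shuffle(dirs)
            blk = list(blocks)
            rng.shuffle(blk)
            for rep_in_half, (d, b) in enumerate(zip(dirs, blk)):
                per_block[b].append(
                    TrialSpecExp2(
                        w=w, profile=p, Dir=d,
                        repetition=2 * half + rep_in_half + 1, block=b,
                    )
                )
    trials: list[TrialSpecExp2] = []
    for b in (1, 2, 3, 4):
        order = rng.permutation(len(per_block[b]))
        trials.extend(per_block[b][i] for i in order)
    return trials


def sample_own_prediction(profile: PsychicProfile, rng: np.random.Generator) -> int:
    """Own-lottery prediction direction: P(win predicted) = nPos / 5."""
    return int(rng.random() < profile.nPos / N_EXAMPLES)


def schedule_to_frame(
    trials: Iterable[TrialSpecExp1 | TrialSpecExp2],
    participant_id: int = 0,
) -> pd.DataFrame:
    """Tabular form of a schedule (one row per trial, shared Exp1/Exp2 layout)."""
    rows = []
    for i, t in enumerate(trials):
        if isinstance(t, TrialSpecExp1):
            rows.append(
                dict(
                    participant_id=participant_id, experiment=1, block=t.block,
                    trial_index=i, w=t.w,
                    nAccA=t.profileA.nAcc, nPosA=t.profileA.nPos,
                    nAccB=t.profileB.nAcc, nPosB=t.profileB.nPos,
                    side_of_A=t.sideOfA, dir_prediction=pd.NA,
                )
            )
        else:
            rows.append(
                dict(
                    participant_id=participant_id, experiment=2, block=t.block,
                    trial_index=i, w=t.w,
                    nAccA=t.profile.nAcc, nPosA=t.profile.nPos,
                    nAccB=pd.NA, nPosB=pd.NA,
                    side_of_A=pd.NA, dir_prediction=t.Dir,
                )
            )
    return pd.DataFrame(rows)
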