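"""Number-needed-to-genotype (NNG) and genotyping-cost modelling.

A two-group risk model splits a drug-exposed population into carriers of a
high-risk CYP2C9 phenotype (frequency f) with event probability q1 and
non-carriers with probability q0, constrained so the mixture reproduces the
overall event probability q:

    f * q1 + (1 - f) * q0 = q

The effect size links q1 to q0 either as a risk ratio (q1 = RR * q0, the
default) or as an odds ratio (odds1 = OR * odds0).  The number needed to
treat among carriers is NNT = 1 / (q1 - q0), and the number needed to
genotype to prevent one additional adverse event is NNG = NNT / f.

Because the meta-analytic (q, effect) inputs are configuration rather than
constants, a calibration utility recovers them from two published
(f, NNG) anchor points by nested bracketed root-finding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence, Tuple

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "InfeasibleParametersError",
    "CalibrationError",
    "RiskModelParams",
    "NNGResult",
    "baseline_risks",
    "nng",
    "calibrate",
    "genotyping_cost",
]

MODE_RISK_RATIO = "risk-ratio"
MODE_ODDS_RATIO = "odds-ratio"
_MODES = (MODE_RISK_RATIO, MODE_ODDS_RATIO)


class InfeasibleParametersError(ValueError):
    """No (q0, q1) in (0,1) satisfies the mixture constraint."""


class CalibrationError(RuntimeError):
    """No (q, effect) inside the search brackets reproduces the anchors."""


@dataclass(frozen=True)
class RiskModelParams:
    """Overall event probability q and carrier effect size, with its scale."""

    q: float
    effect: float
    mode: str = MODE_RISK_RATIO

    def __post_init__(self):
        if not (0.0 < self.q < 1.0):
            raise InfeasibleParametersError(f"q must lie in (0,1), got {self.q}")
        if self.effect <= 0:
            raise InfeasibleParametersError(f"effect must be positive, got {self.effect}")
        if self.mode not in _MODES:
            raise ValueError(f"mode must be one of {_MODES}, got {self.mode!r}")


@dataclass(frozen=True)
class NNGResult:
    """Risk decomposition and the NNT/NNG it implies at carrier frequency f."""

    f: float
    q0: float
    q1: float
    risk_difference: float
    nnt: float
    nng: float

    @property
    def nng_rounded(self) -> int:
        return int(round(self.nng))


def baseline_risks(f: float, params: RiskModelParams) -> Tuple[float, float]:
    """Solve the mixture constraint for (q0, q1) at carrier frequency f.

    Risk-ratio mode has the closed form q0 = q / (1 + f*(RR-1)); odds-ratio
    mode brackets q0 in (0, 1) and root-solves the constraint to 1e-12.
    """
    if not (0.0 < f < 1.0):
        raise InfeasibleParametersError(f"carrier frequency f must lie in (0,1), got {f}")
    q, effect = params.q, params.effect
    if params.mode == MODE_RISK_RATIO:
        q0 = q / (1.0 + f * (effect - 1.0))
        q1 = effect * q0
        if not (0.0 < q0 < 1.0 and 0.0 < q1 < 1.0):
            raise InfeasibleParametersError(
                f"risk-ratio solution outside (0,1): q0={q0}, q1={q1}"
            )
        return q0, q1

    def q1_of(q0: float) -> float:
        odds1 = effect * q0 / (1.0 - q0)
        return odds1 / (1.0 + odds1)

    def constraint(q0: float) -> float:
        return f * q1_of(q0) + (1.0 - f) * q0 - q

    eps = 1e-15
    lo, hi = eps, 1.0 - eps
    if constraint(lo) > 0 or constraint(hi) < 0:
        raise InfeasibleParametersError("no q0 in (0,1) satisfies the mixture constraint")
    q0 = brentq(constraint, lo, hi, xtol=1e-12, rtol=8.9e-16)
    return q0, q1_of(q0)


def nng(f: float, params: RiskModelParams) -> NNGResult:
    """NNG = 1 / (f * (q1 - q0)) under the two-group risk model.

    A null effect (effect = 1) yields an infinite NNG.
    """
    q0, q1 = baseline_risks(f, params)
    rd = q1 - q0
    nnt = math.inf if rd == 0 else 1.0 / rd
    value = math.inf if rd == 0 else 1.0 / (f * rd)
    return NNGResult(f=f, q0=q0, q1=q1, risk_difference=rd, nnt=nnt, nng=value)


_Q_BRACKET = (1e-6, 0.5)
_EFFECT_BRACKET = (1.0 + 1e-6, 20.0)


def calibrate(anchors: Sequence[Tuple[float, float]], mode: str = MODE_RISK_RATIO) -> RiskModelParams:
    """Recover (q, effect) from two published (f, NNG) anchor points.

    For a fixed effect size, NNG is strictly decreasing in q, so the inner
    solve brackets q on (1e-6, 0.5) against the first anchor; the outer
    solve brackets the effect on (1+1e-6, 20) against the second.  The
    returned parameters reproduce both anchors within 0.5 individuals.
    """
    if len(anchors) != 2:
        raise CalibrationError("exactly two (f, NNG) anchors are required")
    (f1, t1), (f2, t2) = anchors
    if f1 == f2:
        raise CalibrationError("anchors must have distinct carrier frequencies")
    for f, t in anchors:
        if not (0.0 < f < 1.0) or t <= 0:
            raise CalibrationError(f"invalid anchor (f={f}, NNG={t})")

    def solve_q(effect: float) -> float | None:
        def g(q: float) -> float:
            return nng(f1, RiskModelParams(q=q, effect=effect, mode=mode)).nng - t1

        lo, hi = _Q_BRACKET
        try:
            if g(lo) < 0 or g(hi) > 0:
                return None
            return brentq(g, lo, hi, xtol=1e-14, rtol=8.9e-16)
        except (InfeasibleParametersError, ValueError):
            return None

    def residual(effect: float) -> float | None:
        q = solve_q(effect)
        if q is None:
            return None
        return nng(f2, RiskModelParams(q=q, effect=effect, mode=mode)).nng - t2

    # scan for a sign change of the outer residual, then refine by brentq
    grid = np.linspace(_EFFECT_BRACKET[0], _EFFECT_BRACKET[1], 256)
    prev_e, prev_r = None, None
    bracket = None
    for e in grid:
        r = residual(e)
        if r is None:
            prev_e, prev_r = None, None
            continue
        if prev_r is not None and prev_r * r <= 0:
            bracket = (prev_e, e)
            break
        prev_e, prev_r = e, r
    if bracket is None:
        raise CalibrationError(
            f"no (q, effect) in q∈{_Q_BRACKET}, effect∈{_EFFECT_BRACKET} fits the anchors"
        )
    effect = brentq(lambda e: residual(e), bracket[0], bracket[1], xtol=1e-12)
    q = solve_q(effect)
    params = RiskModelParams(q=q, effect=effect, mode=mode)
    for f, t in anchors:
        if abs(nng(f, params).nng - t) > 0.5:
            raise CalibrationError("calibration failed to reproduce an anchor within 0.5")
    return params


def genotyping_cost(nng_value: float, cost_per_sample: float, batch_size: int = 10) -> dict:
    """Total reagent/disposable cost of genotyping NNG individuals.

    cost_per_sample is a configuration input (it embeds an exchange rate);
    batch_size is carried as metadata only.
    """
    if nng_value <= 0:
        raise ValueError("nng must be positive")
    if cost_per_sample <= 0:
        raise ValueError("cost_per_sample must be positive")
    if batch_size <= 0:
        raise ValueError("batch_size must be positive")
    return {
        "nng": nng_value,
        "cost_per_sample": cost_per_sample,
        "batch_size": batch_size,
        "total_cost": nng_value * cost_per_sample,
    }
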