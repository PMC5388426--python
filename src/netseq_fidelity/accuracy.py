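"""Experimental-error propagation: how much of the signal is real?

Library preparation and sequencing superimpose errors on the nascent RNA:
reverse transcription (no proofreading, ~1e-4 to 1e-5 per base), PCR
(~1e-7 per base per cycle) and sequencing miscalls (1 in 1000 after a Phred
30 filter). Composing these additively (all rates are small, so second-order
terms fall below reporting precision) gives an expected observed mismatch
rate for any true misincorporation rate; inverting it estimates the fraction
of observed mismatches that are genuine.

A genuine mismatch hit by a superimposed error has a two-in-three chance of
remaining mismatched (the error lands on one of the three non-template
bases, one of which is the template); that retention factor is exposed for
sensitivity analysis.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np


def phred_accuracy_percent(q: float) -> float:
    """Base-call accuracy implied by a Phred score, in percent (Q30 = 99.9)."""
    return 100.0 * (1.0 - 10.0 ** (-q / 10.0))


@dataclass
class ErrorBudget:
    """Per-base error rates of the experimental layers.

    Defaults: RT 1e-4 per base, PCR 4e-7 per base per cycle over 15 cycles,
    sequencing miscalls 1e-3 (the residual rate after a Phred>=30 filter),
    retention factor 2/3.
    """

    p_rt: float = 1e-4
    p_pcr: float = 4e-7
    n_cycles: int = 15
    p_seq: float = 1e-3
    f_retain: float = 2.0 / 3.0

    def __post_init__(self) -> None:
        for name in ("p_rt", "p_pcr", "p_seq", "f_retain"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.n_cycles < 0:
            raise ValueError("n_cycles must be >= 0")
        if self.p_exp >= 1.0:
            raise ValueError("combined experimental error rate must be < 1")

    @property
    def p_exp(self) -> float:
        """Combined experimental error probability per base (additive)."""
        return self.p_rt + self.n_cycles * self.p_pcr + self.p_seq


@dataclass
class AccuracyEstimate:
    r_obs: float  # observed mismatch rate at an offset (fraction, not %)
    r_true: float  # inferred true misincorporation rate
    tp_fraction_percent: float  # % of observed mismatches that are genuine

    def __post_init__(self) -> None:
        if not 0.0 <= self.tp_fraction_percent <= 100.0:
            raise ValueError("tp_fraction outside [0, 100]")


def expected_observed_rate(r_true: float, budget: ErrorBudget) -> float:
    """Observed mismatch rate produced by a true rate under the error budget.

    A truly mismatched base stays observed-mismatched unless a superimposed
    error reverts it (probability p_exp * (1 - f_retain)); a truly matched
    base becomes observed-mismatched with probability p_exp.
    """
    if not 0.0 <= r_true <= 1.0:
        raise ValueError("r_true outside [0, 1]")
    p = budget.p_exp
    return r_true * (1.0 - p * (1.0 - budget.f_retain)) + (1.0 - r_true) * p


def true_positive_fraction(r_obs: float, budget: ErrorBudget) -> AccuracyEstimate:
    """Invert the propagation model: which part of ``r_obs`` is genuine?

    When the observed rate sits at or below the pure-noise floor ``p_exp``
    the true rate is clipped to 0 (with a warning) and the true-positive
    fraction is 0%.
    """
    if r_obs < 0:
        raise ValueError("r_obs must be >= 0")
    p = budget.p_exp
    retained = 1.0 - p * (1.0 - budget.f_retain)
    r_true = (r_obs - p) / (retained - p)
    if r_true < 0:
        if r_obs < p:
            warnings.warn(
                f"observed rate {r_obs:.3g} below the experimental noise floor "
                f"{p:.3g}; true rate clipped to 0",
                stacklevel=2,
            )
        r_true = 0.0
    tp = 100.0 * r_true * retained / r_obs if r_obs > 0 else 0.0
    return AccuracyEstimate(r_obs, r_true, min(tp, 100.0))


def accuracy_report(
    total_rate_percent: np.ndarray, budget: ErrorBudget
) -> list[dict]:
    """Per-offset accuracy estimates from a positional rate table (in %)."""
    report = []
    for k, rate in enumerate(total_rate_percent):
        if np.isnan(rate):
            report.append({"offset": -k, "r_obs": None, "r_true": None, "tp_fraction_percent": None})
            continue
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            est = true_positive_fraction(rate / 100.0, budget)
        report.append(
            {
                "offset": -k,
                "r_obs": est.r_obs,
                "r_true": est.r_true,
                "tp_fraction_percent": est.tp_fraction_percent,
            }
        )
    return report


def simulate_error_layers(
    r_true: float,
    budget: ErrorBudget,
    n_bases: int,
    rng: np.random.Generator,
) -> float:
    """Monte-Carlo cross-check of the additive propagation model.

    Simulates the base identity of ``n_bases`` positions through RT, PCR
    (one Bernoulli at cycles x per-cycle rate) and sequencing layers; each
    error replaces the base with a uniform choice among the other three.
    Returns the observed mismatch fraction.
    """
    # state 0 = template base; 1..3 = the three wrong bases
    state = np.where(rng.random(n_bases) < r_true, 0, -1)
    state[state == 0] = rng.integers(1, 4, size=int((state == 0).sum()))
    state[state == -1] = 0
    for rate in (budget.p_rt, budget.n_cycles * budget.p_pcr, budget.p_seq):
        if rate <= 0:
            continue
        hit = rng.random(n_bases) < rate
        shifts = rng.integers(1, 4, size=int(hit.sum()))
        state[hit] = (state[hit] + shifts) % 4
    return float((state != 0).mean())
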