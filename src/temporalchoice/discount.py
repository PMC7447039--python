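"""Delay-discounting value models and the softmax choice rule.

Three discount families map an objective larger-later (LL) reward and its
delay onto a subjective value:

* quasi-hyperbolic ("beta-delta"):  ``SV = reward * beta * delta**delay``
* one-parameter hyperbolic:         ``SV = reward / (1 + k*delay)``
* generalized hyperbolic:           ``SV = reward / (1 + k*delay)**s``

Choices between the LL option and a fixed smaller-sooner (SS) amount are
modelled with a logistic (softmax) rule on the value difference.  Delays are
expressed in days throughout, so ``k`` carries units of 1/day.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.special import expit

__all__ = [
    "MODELS",
    "SS_AMOUNT",
    "PROB_FLOOR",
    "ChoiceTrial",
    "DiscountParams",
    "sv_quasi_hyperbolic",
    "sv_hyperbolic",
    "sv_generalized_hyperbolic",
    "subjective_value",
    "choice_prob",
    "log_likelihood",
    "auc_discount_curve",
    "auc_closed_form",
    "read_choice_table",
    "write_choice_table",
]

MODELS = ("quasi_hyperbolic", "hyperbolic", "generalized_hyperbolic")

#: Fixed smaller-sooner amount (CHF, delivered today).
SS_AMOUNT = 10.0

#: Per-trial choice probabilities are clamped to [PROB_FLOOR, 1 - PROB_FLOOR]
#: before taking logs, so extreme inverse temperatures cannot produce -inf
#: log-likelihoods during sampling.
PROB_FLOOR = 1e-12

CHOICE_TABLE_COLUMNS = [
    "participant_id",
    "group",
    "session",
    "run",
    "reward_ll",
    "delay",
    "choice",
]


def _require(cond: bool, name: str, msg: str) -> None:
    if not cond:
        raise ValueError(f"{name}: {msg}")


@dataclass(frozen=True)
class ChoiceTrial:
    """One intertemporal decision between a fixed SS amount and an LL offer."""

    participant_id: str
    group: str  # "rTPJ" or "vertex"
    session: str  # "pre" or "post"
    run: int
    reward_ll: float
    delay: float
    choice: str  # "LL" or "SS"

    def __post_init__(self) -> None:
        _require(self.group in ("rTPJ", "vertex"), "group", f"unknown group {self.group!r}")
        _require(self.session in ("pre", "post"), "session", f"unknown session {self.session!r}")
        _require(self.choice in ("LL", "SS"), "choice", f"unknown choice {self.choice!r}")
        _require(self.reward_ll > 0, "reward_ll", "must be positive")
        _require(self.delay >= 0, "delay", "must be non-negative")


@dataclass
class DiscountParams:
    """Parameter set for one discount model.

    Only the fields that belong to ``model`` may be set; all others must stay
    ``None``.  Bounds: ``k > 0``, ``s > 0``, ``beta_temp > 0``,
    ``0 < beta <= 1``, ``0 < delta <= 1``.
    """

    model: str
    k: float | None = None
    s: float | None = None
    beta: float | None = None
    delta: float | None = None
    beta_temp: float | None = None

    _FIELDS = {
        "quasi_hyperbolic": ("beta", "delta", "beta_temp"),
        "hyperbolic": ("k", "beta_temp"),
        "generalized_hyperbolic": ("k", "s", "beta_temp"),
    }

    def __post_init__(self) -> None:
        _require(self.model in MODELS, "model", f"unknown model {self.model!r}")
        wanted = self._FIELDS[self.model]
        for name in ("k", "s", "beta", "delta", "beta_temp"):
            value = getattr(self, name)
            if name in wanted:
                _require(value is not None, name, f"required for model {self.model!r}")
            else:
                _require(value is None, name, f"not a parameter of model {self.model!r}")
        if self.k is not None:
            _require(self.k > 0, "k", "must be > 0")
        if self.s is not None:
            _require(self.s > 0, "s", "must be > 0")
        if self.beta is not None:
            _require(0 < self.beta <= 1, "beta", "must be in (0, 1]")
        if self.delta is not None:
            _require(0 < self.delta <= 1, "delta", "must be in (0, 1]")
        if self.beta_temp is not None:
            _require(self.beta_temp > 0, "beta_temp", "must be > 0")

    @property
    def param_names(self) -> tuple[str, ...]:
        return self._FIELDS[self.model]

    def to_dict(self) -> dict:
        out = {"model": self.model}
        out.update({name: getattr(self, name) for name in self.param_names})
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "DiscountParams":
        return cls(**data)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "DiscountParams":
        return cls.from_dict(json.loads(text))


def sv_quasi_hyperbolic(reward, delay, beta: float, delta: float):
    """Quasi-hyperbolic subjective value ``reward * beta * delta**delay``.

    ``beta`` is the present-bias weight (the discount fraction at delay 0)
    and ``delta`` the per-day exponential decay.
    """
    _require(np.all(np.asarray(reward) > 0), "reward", "must be > 0")
    _require(np.all(np.asarray(delay) >= 0), "delay", "must be >= 0")
    _require(0 < beta <= 1, "beta", "must be in (0, 1]")
    _require(0 < delta <= 1, "delta", "must be in (0, 1]")
    return np.asarray(reward, dtype=float) * beta * delta ** np.asarray(delay, dtype=float)


def sv_hyperbolic(reward, delay, k: float):
    """One-parameter hyperbolic subjective value ``reward / (1 + k*delay)``."""
    _require(np.all(np.asarray(reward) > 0), "reward", "must be > 0")
    _require(np.all(np.asarray(delay) >= 0), "delay", "must be >= 0")
    _require(k > 0, "k", "must be > 0")
    return np.asarray(reward, dtype=float) / (1.0 + k * np.asarray(delay, dtype=float))


def sv_generalized_hyperbolic(reward, delay, k: float, s: float):
    """Generalized hyperbolic subjective value ``reward / (1 + k*delay)**s``.

    The exponent ``s`` scales discounting strength, most visibly at long
    delays; ``s = 1`` reduces to :func:`sv_hyperbolic`.
    """
    _require(np.all(np.asarray(reward) > 0), "reward", "must be > 0")
    _require(np.all(np.asarray(delay) >= 0), "delay", "must be >= 0")
    _require(k > 0, "k", "must be > 0")
    _require(s > 0, "s", "must be > 0")
    return np.asarray(reward, dtype=float) / (1.0 + k * np.asarray(delay, dtype=float)) ** s


def subjective_value(params: DiscountParams, reward, delay):
    """Dispatch to the subjective-value function selected by ``params.model``."""
    if params.model == "quasi_hyperbolic":
        return sv_quasi_hyperbolic(reward, delay, params.beta, params.delta)
    if params.model == "hyperbolic":
        return sv_hyperbolic(reward, delay, params.k)
    return sv_generalized_hyperbolic(reward, delay, params.k, params.s)


def choice_prob(sv_ll, beta_temp: float, ss_amount: float = SS_AMOUNT):
    """Softmax probability of choosing the LL option.

    ``P(LL) = 1 / (1 + exp(-beta_temp * (sv_ll - ss_amount)))``, evaluated
    with a numerically stable logistic so arguments of magnitude up to ~700
    neither overflow nor underflow to exactly 0/1 prematurely.
    """
    _require(beta_temp > 0, "beta_temp", "must be > 0")
    return expit(beta_temp * (np.asarray(sv_ll, dtype=float) - ss_amount))


def log_likelihood(
    params: DiscountParams,
    trials: Sequence[ChoiceTrial] | pd.DataFrame,
) -> tuple[float, np.ndarray]:
    """Bernoulli log-likelihood of observed choices under ``params``.

    Returns ``(total, pointwise)`` where ``pointwise`` holds one
    log-probability per trial (needed downstream for leave-one-out scores)
    and ``total`` is exactly ``pointwise.sum()``.  Probabilities are clamped
    to ``[PROB_FLOOR, 1 - PROB_FLOOR]`` before the log.
    """
    rewards, delays, chose_ll = trials_to_arrays(trials)
    if rewards.size == 0:
        raise ValueError("trials: must be non-empty")
    sv = subjective_value(params, rewards, delays)
    p_ll = np.clip(choice_prob(sv, params.beta_temp), PROB_FLOOR, 1.0 - PROB_FLOOR)
    pointwise = np.where(chose_ll, np.log(p_ll), np.log1p(-p_ll))
    return float(pointwise.sum()), pointwise


def trials_to_arrays(
    trials: Sequence[ChoiceTrial] | pd.DataFrame,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Extract ``(rewards, delays, chose_ll)`` arrays from trials.

    Accepts either a sequence of :class:`ChoiceTrial` or a DataFrame with
    ``reward_ll``/``delay``/``choice`` columns; ``chose_ll`` is boolean.
    """
    if isinstance(trials, pd.DataFrame):
        rewards = trials["reward_ll"].to_numpy(dtype=float)
        delays = trials["delay"].to_numpy(dtype=float)
        chose_ll = (trials["choice"].to_numpy() == "LL")
    else:
        rewards = np.array([t.reward_ll for t in trials], dtype=float)
        delays = np.array([t.delay for t in trials], dtype=float)
        chose_ll = np.array([t.choice == "LL" for t in trials], dtype=bool)
    return rewards, delays, chose_ll


def auc_discount_curve(params: DiscountParams, max_delay: float = 180.0) -> float:
    """Normalized area under the generalized hyperbolic discount curve.

    Both axes are normalized — delay by ``max_delay`` and subjective value by
    the reward — so the result lies in (0, 1], equals 1 for a flat curve, and
    decreases as either ``k`` or ``s`` grows.  Computed by adaptive
    quadrature; see :func:`auc_closed_form` for the analytic counterpart.
    """
    _require(params.model == "generalized_hyperbolic", "model",
             "AUC is defined for the generalized hyperbolic model")
    _require(max_delay > 0, "max_delay", "must be > 0")
    k, s = params.k, params.s
    # break the interval at the curve's characteristic scale so steep
    # curves (huge k) do not trip the adaptive quadrature
    breaks = [min(1.0 / k, max_delay / 2)] if k > 1 else None
    value, _ = integrate.quad(lambda d: (1.0 + k * d) ** (-s), 0.0, max_delay,
                              limit=200, points=breaks)
    return value / max_delay


def auc_closed_form(k: float, s: float, max_delay: float = 180.0) -> float:
    """Analytic normalized AUC of ``(1 + k d)^-s`` over ``[0, max_delay]``.

    Antiderivative ``((1+kd)^(1-s) - 1) / (k (1-s))`` for ``s != 1`` and
    ``ln(1+kd)/k`` for ``s = 1``.
    """
    kD = k * max_delay
    if s == 1.0:
        return float(np.log1p(kD) / kD)
    return float(((1.0 + kD) ** (1.0 - s) - 1.0) / (k * (1.0 - s) * max_delay))


def write_choice_table(trials: Iterable[ChoiceTrial] | pd.DataFrame, path) -> None:
    """Write a choice table as CSV with the canonical column order."""
    if not isinstance(trials, pd.DataFrame):
        trials = pd.DataFrame([vars(t) for t in trials])
    trials[CHOICE_TABLE_COLUMNS].to_csv(path, index=False)


def read_choice_table(path) -> pd.DataFrame:
    """Read a choice-table CSV, validating the schema."""
    df = pd.read_csv(path, dtype={"participant_id": str})
    missing = set(CHOICE_TABLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"choice table {path} missing columns: {sorted(missing)}")
    bad = set(df["choice"].unique()) - {"LL", "SS"}
    if bad:
        raise ValueError(f"choice column contains unknown codes: {sorted(bad)}")
    return df
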