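"""Q-learning value updating and the softmax baseline choice rule.

Each stimulus pair holds one optimal (80% reinforced) and one suboptimal
(20% reinforced) option.  The value Q of the chosen option is updated with a
delta rule, ``Q <- Q + eta * (r - Q)``, with rewards coded 0/1 and Q-values
initialized at 0.5 (the unit-scale midpoint).  Dual-learning-rate variants
apply ``eta_plus`` to positive and ``eta_minus`` to negative prediction
errors.  Learning rates live in standard-normal space ``[-3, 3]`` during
estimation and map to (0, 1) through the standard-normal CDF (the usual
probit device).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

Q_INIT = 0.5


def transform_learning_rate(eta_raw):
    """Map a learning rate from standard-normal space to (0, 1) via Phi.

    Strictly increasing; 0 maps to 0.5.
    """
    arr = np.asarray(eta_raw, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("eta_raw must be finite")
    out = 0.5 * (1.0 + np.vectorize(math.erf)(arr / math.sqrt(2.0)))
    return float(out) if arr.ndim == 0 else out


@dataclass
class LearningRates:
    """Learning rates in raw (standard-normal) space; probabilities derived."""

    eta_raw_plus: float
    eta_raw_minus: float | None = None

    def __post_init__(self):
        if self.eta_raw_minus is None:
            self.eta_raw_minus = self.eta_raw_plus

    @property
    def eta_plus(self) -> float:
        return transform_learning_rate(self.eta_raw_plus)

    @property
    def eta_minus(self) -> float:
        return transform_learning_rate(self.eta_raw_minus)


@dataclass
class QState:
    """Per-pair option values; column 0 optimal, column 1 suboptimal."""

    n_pairs: int = 2
    q: np.ndarray = field(default=None)
    last_delta: float = 0.0

    def __post_init__(self):
        if self.q is None:
            self.q = np.full((self.n_pairs, 2), Q_INIT, dtype=float)

    def q_diff(self, pair: int) -> float:
        """Q(optimal) - Q(suboptimal) for one pair."""
        return float(self.q[pair, 0] - self.q[pair, 1])


def q_update(state: QState, pair: int, choice: str, reward: int, rates: LearningRates):
    """Delta-rule update of the chosen option of the presented pair, in place.

    Returns the prediction error ``delta = r - Q_chosen``.  Unchosen options
    and the pair not shown are untouched; a zero prediction error leaves the
    state unchanged without selecting a learning-rate branch.
    """
    if not 0 <= pair < state.n_pairs:
        raise KeyError(f"unknown pair id {pair}")
    if choice not in ("optimal", "suboptimal"):
        raise ValueError(f"choice must be 'optimal' or 'suboptimal', got {choice!r}")
    col = 0 if choice == "optimal" else 1
    delta = float(reward) - state.q[pair, col]
    if delta > 0:
        state.q[pair, col] += rates.eta_plus * delta
    elif delta < 0:
        state.q[pair, col] += rates.eta_minus * delta
    state.last_delta = delta
    return delta


def softmax_prob(q_optimal: float, q_suboptimal: float, beta: float) -> float:
    """Probability of choosing the optimal option under softmax action selection.

    ``P = 1 / (1 + exp(-beta * (Q_opt - Q_sub)))``; beta = 0 gives random
    choice, larger beta makes choices track the value difference more sharply.
    """
    if beta < 0:
        raise ValueError("inverse temperature beta must be non-negative")
    return 1.0 / (1.0 + math.exp(-beta * (q_optimal - q_suboptimal)))


def q_trajectory(trials, rates: LearningRates, n_pairs: int = 2) -> np.ndarray:
    """Forward pass over a trial sequence; returns per-trial (q_opt, q_sub, delta).

    ``trials`` is an iterable of (pair, choice, reward) with choice in
    {'optimal', 'suboptimal', 'none'}; non-response trials leave values
    unchanged and record delta = nan.  Useful for exporting model-based
    regressors.
    """
    state = QState(n_pairs=n_pairs)
    rows = np.empty((len(trials), 3), dtype=float)
    for i, (pair, choice, reward) in enumerate(trials):
        rows[i, 0] = state.q[pair, 0]
        rows[i, 1] = state.q[pair, 1]
        if choice == "none":
            rows[i, 2] = np.nan
        else:
            rows[i, 2] = q_update(state, pair, choice, reward, rates)
    return rows
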