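"""Single-pass ("running") statistics that never retain the series.

The accumulator keeps six scalars — count, min, max, mean, and two
central-moment auxiliaries — and updates them recursively on every
incoming value.  After any number of pushes the state is all that exists:
no sample is stored, which is the point.  The disposable nature of the
accumulator is what lets a monitoring device summarise a person's
movement without ever holding the raw trace.

Recursions (for a state holding ``n`` values receiving ``x``):

    min' = min(min, x)                       (first push sets min = max = x)
    max' = max(max, x)
    mu'  = mu + (x - mu) / (n + 1)
    V'   = V + (x - mu') (x - mu)            carries  sum_i (x_i - mu)^2
    T'   = T - 3 (mu' - mu) V + (V' - V) [x - mu' - (mu' - mu)]
                                             carries  sum_i (x_i - mu)^3

Derived statistics use the unbiased conventions: sample variance
``V / (n - 1)`` and the adjusted Fisher–Pearson sample skewness
``n T / ((n - 1)(n - 2) sigma^3)``.  The deltas ``mu' - mu`` and
``V' - V`` are computed once per push and reused, so a push costs a
handful of flops.

The empty state carries no min/max: seeding them with zero would poison
all-negative or all-positive data, so the first observation defines both.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np
from scipy import stats as _stats

from .errors import ParameterError

__all__ = ["RunningState", "RunningSummary", "push", "summarize", "fold", "batch_oracle"]


@dataclass
class RunningSummary:
    """Derived statistics of everything pushed so far.

    ``sample_sd`` is absent (None) below 2 values, ``sample_skewness``
    below 3 values or for a degenerate (zero-variance) stream.
    """

    n: int
    min_v: Optional[float]
    max_v: Optional[float]
    mean: Optional[float]
    sample_sd: Optional[float]
    sample_skewness: Optional[float]

    def as_dict(self) -> dict:
        return {
            "n": self.n,
            "min": self.min_v,
            "max": self.max_v,
            "mean": self.mean,
            "sample_sd": self.sample_sd,
            "sample_skewness": self.sample_skewness,
        }


@dataclass
class RunningState:
    """The disposable six-field accumulator.

    Fields: count ``n``, running extrema, running mean ``mu``, second
    central moment auxiliary ``V`` and third central moment auxiliary
    ``T``.  Nothing else survives a push.
    """

    n: int = 0
    min_v: Optional[float] = None
    max_v: Optional[float] = None
    mu: float = 0.0
    V: float = 0.0
    T: float = 0.0

    def push(self, x: float) -> "RunningState":
        """Fold one value into the state (mutates and returns self)."""
        if not math.isfinite(x):
            raise ParameterError(
                f"non-finite value {x!r} rejected at stream index {self.n} "
                "(values must be finite reals)"
            )
        n1 = self.n + 1
        if self.n == 0:
            self.min_v = self.max_v = float(x)
            self.mu = float(x)
            self.n = 1
            return self
        self.min_v = min(self.min_v, x)
        self.max_v = max(self.max_v, x)
        mu_new = self.mu + (x - self.mu) / n1
        d_mu = mu_new - self.mu
        V_new = self.V + (x - mu_new) * (x - self.mu)
        d_V = V_new - self.V
        self.T = self.T - 3.0 * d_mu * self.V + d_V * (x - mu_new - d_mu)
        self.mu, self.V = mu_new, V_new
        self.n = n1
        return self

    def summary(self) -> RunningSummary:
        return summarize(self)


def push(state: RunningState, x: float) -> RunningState:
    """Functional alias for :meth:`RunningState.push`."""
    return state.push(x)


def summarize(state: RunningState) -> RunningSummary:
    """Derive min/max/mean/SD/skewness from the six state fields only."""
    n = state.n
    if n == 0:
        return RunningSummary(0, None, None, None, None, None)
    sd = None
    skew = None
    if n >= 2:
        sd = math.sqrt(max(state.V, 0.0) / (n - 1))
    if n >= 3:
        if sd is not None and sd > 0.0:
            skew = n * state.T / ((n - 1) * (n - 2) * sd**3)
        else:
            skew = None  # zero-variance stream: skewness undefined
    return RunningSummary(n, state.min_v, state.max_v, state.mu, sd, skew)


def fold(values: Iterable[float]) -> RunningState:
    """Push a whole iterable through a fresh accumulator."""
    st = RunningState()
    for x in values:
        st.push(x)
    return st


def batch_oracle(values) -> RunningSummary:
    """Non-recursive reference: same statistics from the full series.

    Exists as the independent check for the recursive path — it sees the
    whole array at once and leans on numpy/scipy (``scipy.stats.skew``
    with ``bias=False`` is the same adjusted Fisher–Pearson estimator).
    """
    v = np.asarray(list(values), dtype=float)
    n = v.size
    if n == 0:
        return RunningSummary(0, None, None, None, None, None)
    sd = float(np.std(v, ddof=1)) if n >= 2 else None
    skew = None
    if n >= 3 and sd is not None and sd > 0.0:
        skew = float(_stats.skew(v, bias=False))
    return RunningSummary(
        int(n), float(v.min()), float(v.max()), float(v.mean()), sd, skew
    )
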