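"""Risk-driven privacy quantification with a sigmoidal fuzzy membership.

Privacy risk is modelled as a fuzzy degree in [0, 1] that grows with the
percentage ``x`` of personal data disclosed in a given data context
(storage, transmission, ...).  The membership function is the logistic
sigmoid

    sig(x; s, p) = 1 / (1 + exp(-(x - p) / s)),   1 <= s <= 10, 0 < p < 100,

where ``p`` is the context's objective sensitivity — the inflection
point at which risk reaches 0.5 — and ``s`` the user's subjective
sensitivity (smaller s = steeper transition).  Per-context privacy is
the complement ``P = 1 - sig``, with hard boundary overrides: disclosing
nothing is recognised as privacy exactly 1, disclosing everything as
exactly 0 (the sigmoid alone would give e.g. 0.998 at x = 0).  Privacy
across independent contexts multiplies, treating the contexts as
orthogonal dimensions:

    P = prod_k P_k.

The two shipped contexts model a home-care deployment: data *storage*
stays at the user side, so sensitivity s = 8 and inflection p = 50;
data *transmission* leaves the user's control, so the maximal
sensitivity s = 10 and an earlier inflection p = 30.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .errors import ParameterError

__all__ = [
    "PrivacyContext",
    "PrivacyScore",
    "STORAGE_CONTEXT",
    "TRANSMISSION_CONTEXT",
    "risk",
    "dimension_privacy",
    "combined_privacy",
    "dnd_privacy",
    "scenario_matrix",
]


@dataclass(frozen=True)
class PrivacyContext:
    """One data context's sensitivity parameters.

    s: subjective privacy sensitivity, in [1, 10].
    p: objective inflection point, percent disclosure in (0, 100).
    """

    name: str
    s: float
    p: float

    def __post_init__(self):
        if not 1.0 <= self.s <= 10.0:
            raise ParameterError(
                f"context {self.name!r}: subjective sensitivity s={self.s} "
                "outside [1, 10]"
            )
        if not 0.0 < self.p < 100.0:
            raise ParameterError(
                f"context {self.name!r}: inflection point p={self.p} "
                "outside (0, 100)"
            )


#: Defaults for the home-care case: stored data stay at the user side.
STORAGE_CONTEXT = PrivacyContext("storage", s=8.0, p=50.0)
#: Transmitted data leave the user's control: maximal sensitivity.
TRANSMISSION_CONTEXT = PrivacyContext("transmission", s=10.0, p=30.0)


@dataclass(frozen=True)
class PrivacyScore:
    """Risk degree and its complement for one evaluated context."""

    risk: float
    privacy: float


def _check_disclosure(x: float) -> float:
    x = float(x)
    if not 0.0 <= x <= 100.0:
        raise ParameterError(f"disclosure x={x} outside [0, 100] percent")
    return x


def risk(x: float, ctx: PrivacyContext) -> float:
    """Fuzzy privacy-risk degree for disclosing ``x`` percent of data."""
    x = _check_disclosure(x)
    return 1.0 / (1.0 + math.exp(-(x - ctx.p) / ctx.s))


def dimension_privacy(x: float, ctx: PrivacyContext) -> float:
    """Per-context privacy ``1 - risk``, clamped at the boundaries.

    Disclosing 0% is recognised as privacy exactly 1 and disclosing
    100% as exactly 0, overriding the sigmoid's asymptotic values.
    """
    x = _check_disclosure(x)
    if x == 0.0:
        return 1.0
    if x == 100.0:
        return 0.0
    return 1.0 - risk(x, ctx)


def score(x: float, ctx: PrivacyContext) -> PrivacyScore:
    """Risk and privacy of one context in a single call."""
    p = dimension_privacy(x, ctx)
    return PrivacyScore(risk=1.0 - p, privacy=p)


def combined_privacy(scores: Iterable[float]) -> float:
    """Product of per-dimension privacies; empty product is 1."""
    out = 1.0
    for pk in scores:
        if not 0.0 <= pk <= 1.0:
            raise ParameterError(f"dimension privacy {pk} outside [0, 1]")
        out *= pk
    return out


def dnd_privacy(
    x_store: float,
    x_trans: float,
    store_ctx: PrivacyContext = STORAGE_CONTEXT,
    trans_ctx: PrivacyContext = TRANSMISSION_CONTEXT,
) -> float:
    """Combined storage x transmission privacy of one disclosure policy."""
    return combined_privacy(
        [dimension_privacy(x_store, store_ctx), dimension_privacy(x_trans, trans_ctx)]
    )


def scenario_matrix(
    store_levels: Sequence[float],
    trans_levels: Sequence[float],
    store_ctx: PrivacyContext = STORAGE_CONTEXT,
    trans_ctx: PrivacyContext = TRANSMISSION_CONTEXT,
) -> np.ndarray:
    """Full storage x transmission privacy grid.

    Rows follow ``store_levels``, columns ``trans_levels``.  With the
    canonical levels {0, 30, 100} x {0, 10, 30, 100} this is the twelve-
    scenario grid of the home-care case study.
    """
    if len(store_levels) == 0 or len(trans_levels) == 0:
        raise ParameterError("scenario_matrix: level lists must be non-empty")
    grid = np.empty((len(store_levels), len(trans_levels)), dtype=float)
    for i, xs in enumerate(store_levels):
        for j, xt in enumerate(trans_levels):
            grid[i, j] = dnd_privacy(xs, xt, store_ctx, trans_ctx)
    return grid
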