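"""Interpretation of the sparse equations: term dynamics and rankings.

Each active term of a governing equation contributes
``coefficient * basis_function(x(t), drivers(t))`` to the derivative at
every time point. Because the analysis runs on z-scored data, the sign of
a contribution depends on the signs of both the coefficient and the basis
value: a negative coefficient times a below-average (negative) z-score is
a growth contribution. Bloom growth phases are the periods where the
Chl-a z-score is positive and increasing; integrating each term over such
a window and normalising within the positive and negative groups gives
the ranked "strongest growth / strongest loss" tables.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .sindy import BasisLibrary, DerivativeSample, SparseModel, evaluate_library

#: minimum window length (days) kept by the growth-window scan
MIN_WINDOW_DAYS = 5

#: proportions closer than this are reported as a near-tie
NEAR_TIE = 0.01


@dataclass
class TermContribution:
    """Time series of one term's coefficient*basis value in one equation."""

    term: str
    equation: int
    t: np.ndarray
    values: np.ndarray

    def __post_init__(self):
        if len(self.t) != len(self.values):
            raise ValueError("series length must equal grid length")


@dataclass(frozen=True)
class GrowthWindow:
    """Inclusive day-of-year interval of a growing, above-average bloom."""

    start: float
    end: float

    def __post_init__(self):
        if not (1 <= self.start <= self.end <= 366):
            raise ValueError(f"invalid growth window [{self.start}, {self.end}]")


@dataclass
class SignGroupRanking:
    """Ranked contributions of one sign group within one window."""

    terms: list[str]
    proportions: np.ndarray
    top: list[str]                       # argmax, plus near-ties within 0.01


@dataclass
class ContributionRanking:
    """Per-window strongest positive and negative contributors."""

    window: GrowthWindow
    positive: SignGroupRanking
    negative: SignGroupRanking


def term_timeseries(model: SparseModel, sample: DerivativeSample,
                    library: BasisLibrary, equation: int = 0) -> list[TermContribution]:
    """Contribution series of every active term along the base trajectory.

    The sum over all returned terms equals the fitted derivative of that
    equation at every grid point (exact reconstruction by construction).
    """
    base = sample.base()
    theta = evaluate_library(library, base.Z)
    names = library.names
    out = []
    for j in np.flatnonzero(model.coef[equation]):
        out.append(TermContribution(
            term=names[j], equation=equation, t=base.t,
            values=model.coef[equation, j] * theta[:, j],
        ))
    return out


def classify_term(coefficient_sign: int, basis_value_sign: int) -> str:
    """Growth/loss/neutral classification by the product-sign rule.

    (+,+) and (-,-) are growth, (+,-) and (-,+) are loss, any zero factor
    is neutral.
    """
    product = np.sign(coefficient_sign) * np.sign(basis_value_sign)
    if product > 0:
        return "growth"
    if product < 0:
        return "loss"
    return "neutral"


def detect_growth_windows(chla, chla_derivative, t=None,
                          min_days: float = MIN_WINDOW_DAYS) -> list[GrowthWindow]:
    """Maximal runs where Chl-a is above average (z>0) and increasing.

    Runs shorter than ``min_days`` are discarded as numerical sign
    flicker. Returns disjoint, sorted windows.
    """
    chla = np.asarray(chla, dtype=float)
    dchla = np.asarray(chla_derivative, dtype=float)
    if chla.shape != dchla.shape:
        raise ValueError("chla and derivative grids must match")
    t = np.arange(1.0, len(chla) + 1.0) if t is None else np.asarray(t, dtype=float)
    active = (chla > 0) & (dchla > 0)
    windows = []
    start = None
    for i, flag in enumerate(active):
        if flag and start is None:
            start = i
        elif not flag and start is not None:
            if t[i - 1] - t[start] >= min_days:
                windows.append(GrowthWindow(start=t[start], end=t[i - 1]))
            start = None
    if start is not None and t[-1] - t[start] >= min_days:
        windows.append(GrowthWindow(start=t[start], end=t[-1]))
    return windows


def rank_contributions(terms: list[TermContribution],
                       windows: list[GrowthWindow]) -> list[ContributionRanking]:
    """Integrate each term over each growth window and rank by sign group.

    Trapezoidal integration on the day grid; within the positive and the
    negative group, a term's proportion is |integral| / sum(|integrals|),
    so proportions in each group sum to one. The strongest term of each
    group is reported; a term within 0.01 of the maximum proportion is
    listed alongside it (near-tie).
    """
    if not windows:
        raise ValueError("need at least one growth window")
    if not terms:
        raise ValueError("need at least one term contribution")
    t = terms[0].t
    rankings = []
    for w in windows:
        mask = (t >= w.start) & (t <= w.end)
        integrals = {}
        for term in terms:
            if not np.array_equal(term.t, t):
                raise ValueError("all term series must share one grid")
            integrals[term.term] = float(np.trapezoid(term.values[mask], t[mask]))
        pos = {k: v for k, v in integrals.items() if v > 0}
        neg = {k: -v for k, v in integrals.items() if v < 0}
        rankings.append(ContributionRanking(
            window=w,
            positive=_rank_group(pos),
            negative=_rank_group(neg),
        ))
    return rankings


def _rank_group(magnitudes: dict[str, float]) -> SignGroupRanking:
    if not magnitudes:
        return SignGroupRanking(terms=[], proportions=np.array([]), top=[])
    total = sum(magnitudes.values())
    items = sorted(magnitudes.items(), key=lambda kv: -kv[1])
    names = [k for k, _ in items]
    props = np.array([v / total for _, v in items])
    top = [names[i] for i in range(len(names)) if props[0] - props[i] <= NEAR_TIE]
    return SignGroupRanking(terms=names, proportions=props, top=top)


# -- tabular exports ---------------------------------------------------------

def contributions_frame(terms: list[TermContribution]) -> pd.DataFrame:
    """Long-format (day, term, contribution) table for heatmap plotting."""
    frames = [pd.DataFrame({"day": c.t, "term": c.term, "contribution": c.values})
              for c in terms]
    return pd.concat(frames, ignore_index=True)


def ranking_frame(rankings: list[ContributionRanking], pattern: str = "") -> pd.DataFrame:
    """Tidy table (pattern, window, sign group, term, proportion)."""
    rows = []
    for i, r in enumerate(rankings, start=1):
        for group_name, group in (("positive", r.positive), ("negative", r.negative)):
            for term, prop in zip(group.terms, group.proportions):
                rows.append({
                    "pattern": pattern, "window": i,
                    "window_start": r.window.start, "window_end": r.window.end,
                    "sign_group": group_name, "term": term,
                    "proportion": prop, "top": term in group.top,
                })
    return pd.DataFrame(rows)
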