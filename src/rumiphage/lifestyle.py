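"""Phage lifestyle stratification from continuous virulence scores.

Scores in [0, 1] (higher = more virulent) map onto four categories:
temperate (score <= 0.3), uncertain temperate (0.3 < score < 0.5),
uncertain virulent (0.5 <= score <= 0.7), and virulent (score > 0.7).
A phage is called lytic iff its score is >= 0.5, i.e. the virulent and
uncertain-virulent categories combined.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.special import gammaincc

from .catalog import PhageRecord, proportion

CATEGORIES = ("temperate", "uncertain_temperate", "uncertain_virulent", "virulent")
LYTIC_THRESHOLD = 0.5


@dataclass(frozen=True)
class LifestyleSummary:
    group: str
    n: int
    counts: dict[str, int]
    lytic_pct: float


def classify_lifestyle(score: float) -> str:
    """Map a score in [0, 1] to one of the four lifestyle categories."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score {score} outside [0, 1]")
    if score <= 0.3:
        return "temperate"
    if score < 0.5:
        return "uncertain_temperate"
    if score <= 0.7:
        return "uncertain_virulent"
    return "virulent"


def is_lytic(score: float) -> bool:
    """Lytic iff score >= 0.5 (virulent or uncertain virulent)."""
    if not 0.0 <= score <= 1.0:
        raise ValueError(f"score {score} outside [0, 1]")
    return score >= LYTIC_THRESHOLD


def lytic_fraction(
    records: Iterable[PhageRecord], group_by: str = "none"
) -> list[LifestyleSummary]:
    """Per-group category counts and lytic percentage.

    ``group_by`` is one of ``animal_host``, ``git_site``, or ``none``
    (a single group labelled ``all``).
    """
    if group_by not in ("animal_host", "git_site", "none"):
        raise ValueError(f"unknown group_by {group_by!r}")
    groups: dict[str, list[PhageRecord]] = {}
    for r in records:
        key = "all" if group_by == "none" else getattr(r, group_by)
        groups.setdefault(key, []).append(r)
    if not groups:
        raise ValueError("no records to summarize")

    out = []
    for group in sorted(groups):
        members = groups[group]
        counts = {c: 0 for c in CATEGORIES}
        for r in members:
            counts[classify_lifestyle(r.lifestyle_score)] += 1
        n = len(members)
        lytic = counts["uncertain_virulent"] + counts["virulent"]
        out.append(
            LifestyleSummary(
                group=group, n=n, counts=counts, lytic_pct=proportion(lytic, n)
            )
        )
    return out


def chi_square(table: Sequence[Sequence[float]]) -> tuple[float, int, float]:
    """Pearson chi-square test of independence on an r x c count table.

    No continuity correction. The p-value is the upper tail of the
    chi-square distribution, computed via the regularized incomplete
    gamma function Q(df/2, X2/2). A warning is emitted when any expected
    count falls below 5, but the computation proceeds.
    """
    obs = np.asarray(table, dtype=np.float64)
    if obs.ndim != 2 or obs.shape[0] < 2 or obs.shape[1] < 2:
        raise ValueError("table must be at least 2 x 2")
    if (obs < 0).any():
        raise ValueError("counts must be non-negative")
    rows = obs.sum(axis=1)
    cols = obs.sum(axis=0)
    if (rows == 0).any() or (cols == 0).any():
        raise ValueError("zero row or column margin")
    expected = np.outer(rows, cols) / obs.sum()
    if (expected < 5).any():
        warnings.warn(
            "expected count below 5; chi-square approximation may be poor",
            stacklevel=2,
        )
    stat = float(((obs - expected) ** 2 / expected).sum())
    df = (obs.shape[0] - 1) * (obs.shape[1] - 1)
    p = float(gammaincc(df / 2.0, stat / 2.0))
    return stat, df, p
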