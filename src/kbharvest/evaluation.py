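"""Evaluation statistics: Wilson interval sampling, Fleiss' kappa, planted P/R.

Precision of a harvested KB is estimated by sequentially sampling facts
for human (or, here, ledger-based) judgment until the two-sided Wilson
score interval at significance ``alpha`` is narrower than a target width;
an exhausted finite population is reported as a census (width 0 by
convention).  Inter-annotator agreement over a rating matrix uses the
standard Fleiss' kappa.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Iterator

import numpy as np
from statsmodels.stats.inter_rater import fleiss_kappa as _sm_fleiss_kappa
from statsmodels.stats.proportion import proportion_confint


@dataclass
class SampleState:
    n: int
    k: int
    alpha: float
    width_target: float
    census: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.k <= self.n):
            raise ValueError("need 0 <= k <= n")
        if not (0.0 < self.alpha < 1.0):
            raise ValueError("alpha must be in (0, 1)")

    def interval(self) -> tuple[float, float]:
        return wilson_interval(self.k, self.n, self.alpha)

    @property
    def width(self) -> float:
        """Interval width; 0 by convention when the whole population was judged."""
        if self.census:
            return 0.0
        low, high = self.interval()
        return high - low


def wilson_interval(k: int, n: int, alpha: float = 0.05) -> tuple[float, float]:
    """Two-sided Wilson score interval for a binomial proportion."""
    if n < 1:
        raise ValueError("wilson interval requires n >= 1")
    if not (0 <= k <= n):
        raise ValueError("need 0 <= k <= n")
    low, high = proportion_confint(k, n, alpha=alpha, method="wilson")
    return float(low), float(high)


def sample_until_width(
    judgments: Iterable[bool] | Iterator[bool],
    alpha: float = 0.05,
    width_target: float = 0.05,
    population_size: int | None = None,
) -> SampleState:
    """Consume judgments until the Wilson interval is narrower than the target.

    When the stream is exhausted first, the state is flagged as a census
    (``width`` then reports 0, the convention for a fully evaluated set).
    """
    n = k = 0
    for judgment in judgments:
        n += 1
        k += int(bool(judgment))
        low, high = wilson_interval(k, n, alpha)
        if high - low < width_target:
            return SampleState(n, k, alpha, width_target)
    census = population_size is None or n >= population_size
    return SampleState(n, k, alpha, width_target, census=census)


def fleiss_kappa(matrix: np.ndarray | list[list[int]]) -> float:
    """Fleiss' kappa for a (items x categories) count matrix.

    Every row must sum to the same number of raters.  Raises on the
    degenerate case where chance agreement equals 1 (a single category
    used throughout), for which kappa is undefined.
    """
    table = np.asarray(matrix, dtype=float)
    if table.ndim != 2 or table.shape[0] < 2 or table.shape[1] < 2:
        raise ValueError("rating matrix must be at least 2 items x 2 categories")
    raters = table.sum(axis=1)
    if raters[0] < 2 or not np.all(raters == raters[0]):
        raise ValueError("every item must be rated by the same >= 2 raters")
    p_cat = table.sum(axis=0) / table.sum()
    p_e = float(np.sum(p_cat**2))
    if 1.0 - p_e < 1e-12:
        raise ValueError("chance agreement is 1; kappa undefined")
    return float(_sm_fleiss_kappa(table, method="fleiss"))


def precision_recall_on_planted(
    kb: Iterable, truth: Iterable[tuple[str, str, str]]
) -> tuple[float, float]:
    """Set-level precision/recall of harvested triples against planted truth.

    ``kb`` may hold :class:`~kbharvest.kb.Fact` objects or raw
    (relation, left, right) triples.
    """
    kb_keys = {getattr(f, "key", f) for f in kb}
    truth_set = set(truth)
    if not kb_keys:
        raise ValueError("cannot compute precision of an empty KB")
    hits = len(kb_keys & truth_set)
    recall = hits / len(truth_set) if truth_set else 1.0
    return hits / len(kb_keys), recall
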