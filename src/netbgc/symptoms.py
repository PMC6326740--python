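"""CES-D scoring, handedness laterality, and score normalization.

The Center for Epidemiologic Studies Depression scale (CES-D) has 20 items
rated 0-3 for symptom frequency over the past week.  Four positively worded
items are reverse-scored (3 minus the response) before summing, giving a
total in 0-60.  Three factor subscores — somatic symptoms, negative affect
and anhedonia — are sums over configurable item subsets; the default map
assigns the four reverse-scored items to anhedonia and splits the remaining
items between somatic and negative-affect sets following the three-factor
literature.  The exact item-factor assignment is a documented default, not
a fixed property of the scale, and callers with a preferred map should pass
their own.

CES-D totals in community samples are right-skewed, so before Pearson-based
inference the package tests normality with a one-sample Kolmogorov-Smirnov
test and applies a Box-Cox power transform, y -> (y^lambda - 1)/lambda
(log y at lambda = 0), with a +1 shift because the minimum score is 0.
The KS flavor here estimates mean and SD from the sample, standardizes and
tests against N(0,1) without a Lilliefors correction; this is the common
default but is anti-conservative, so its p-values are diagnostics rather
than strict gates.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

__all__ = [
    "DEFAULT_REVERSE_ITEMS",
    "DEFAULT_FACTOR_MAP",
    "CesdScores",
    "BoxCoxResult",
    "score_cesd",
    "laterality_quotient",
    "ks_normality",
    "boxcox_normalize",
]

#: 1-based indices of the positively worded, reverse-scored CES-D items.
DEFAULT_REVERSE_ITEMS = (4, 8, 12, 16)

#: Default item-factor map (1-based item indices).  Anhedonia comprises the
#: four reverse-scored items; the remaining items are split between somatic
#: and negative-affect sets.  A documented default, configurable per study.
DEFAULT_FACTOR_MAP: Mapping[str, tuple] = {
    "somatic": (1, 2, 5, 7, 11, 13, 20),
    "negative_affect": (3, 6, 9, 10, 14, 15, 17, 18, 19),
    "anhedonia": (4, 8, 12, 16),
}

#: Handedness answer labels and their scores.
HANDEDNESS_SCORES = {
    "always_right": 2,
    "usually_right": 1,
    "no_preference": 0,
    "usually_left": -1,
    "always_left": -2,
}


@dataclass(frozen=True)
class CesdScores:
    total: int
    factors: Mapping[str, int]


@dataclass(frozen=True)
class BoxCoxResult:
    transformed: np.ndarray
    lmbda: float
    shift: float
    ks_p_before: float
    ks_p_after: float


def score_cesd(
    items: Sequence[int],
    reverse_items: Sequence[int] = DEFAULT_REVERSE_ITEMS,
    factor_map: Mapping[str, Sequence[int]] = DEFAULT_FACTOR_MAP,
) -> CesdScores:
    """Total and factor scores from 20 raw item responses.

    ``reverse_items`` and the values of ``factor_map`` are 1-based item
    indices.  Reverse items are scored ``3 - response``; the total is the
    sum of all 20 scored items and each factor score the sum over its
    items.  Factor sets must not overlap.
    """
    arr = np.asarray(items)
    if arr.shape != (20,):
        raise ValueError("expected exactly 20 item responses")
    if not np.all(np.isin(arr, [0, 1, 2, 3])):
        raise ValueError("item responses must be integers in {0,1,2,3}")
    rev = set(reverse_items)
    if not rev <= set(range(1, 21)):
        raise ValueError("reverse_items must be 1-based indices in 1..20")
    assigned: set = set()
    for name, idx in factor_map.items():
        s = set(idx)
        if not s <= set(range(1, 21)):
            raise ValueError(f"factor {name!r} has out-of-range items")
        if assigned & s:
            raise ValueError(f"factor {name!r} overlaps another factor")
        assigned |= s
    scored = np.array(
        [3 - arr[i - 1] if i in rev else arr[i - 1] for i in range(1, 21)]
    )
    factors = {
        name: int(sum(scored[i - 1] for i in idx))
        for name, idx in factor_map.items()
    }
    return CesdScores(int(scored.sum()), factors)


def laterality_quotient(answers: Sequence) -> float:
    """Handedness laterality quotient from 11 preference answers.

    Answers may be labels (``always_right`` ... ``always_left``) or the
    integer scores 2, 1, 0, -1, -2.  LQ = 100 * (sum of scores) / 22, so
    all-right gives +100 and all-left -100.
    """
    if len(answers) != 11:
        raise ValueError("expected exactly 11 handedness answers")
    total = 0
    for a in answers:
        if isinstance(a, str):
            if a not in HANDEDNESS_SCORES:
                raise ValueError(f"unknown handedness answer {a!r}")
            total += HANDEDNESS_SCORES[a]
        else:
            if a not in (2, 1, 0, -1, -2):
                raise ValueError(f"handedness score {a!r} not in -2..2")
            total += int(a)
    return 100.0 * total / 22.0


def ks_normality(x: Sequence[float]) -> tuple[float, float]:
    """One-sample KS test of standardized data against the standard normal.

    Returns (statistic, asymptotic two-sided p).  Mean and SD are estimated
    from the sample, which makes the test anti-conservative.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 observations")
    sd = x.std(ddof=1)
    if sd == 0:
        raise ValueError("degenerate (constant) sample")
    z = (x - x.mean()) / sd
    res = stats.kstest(z, "norm", mode="asymp")
    return float(res.statistic), float(res.pvalue)


def boxcox_normalize(
    x: Sequence[float],
    shift: float = 1.0,
    lmbda: float | None = None,
) -> BoxCoxResult:
    """Box-Cox transform with profile-likelihood lambda on a fixed grid.

    ``x + shift`` must be strictly positive (the default +1 accommodates
    CES-D's minimum of 0).  Lambda is chosen on the grid [-5, 5] in steps
    of 0.01 by maximizing the Box-Cox log-likelihood unless ``lmbda`` is
    given explicitly.  The transform is strictly increasing, so subject
    ordering is preserved.  KS normality p-values before and after are
    reported as diagnostics.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 5:
        raise ValueError("need at least 5 observations")
    y = x + shift
    if np.any(y <= 0):
        raise ValueError("shifted values must be strictly positive")
    if np.ptp(x) == 0:
        raise ValueError("constant input cannot be normalized")
    if lmbda is None:
        grid = np.round(np.arange(-5.0, 5.0 + 1e-9, 0.01), 2)
        llf = np.array([stats.boxcox_llf(l, y) for l in grid])
        lmbda = float(grid[int(np.argmax(llf))])
    lmbda = float(lmbda)
    if lmbda == 0.0:
        transformed = np.log(y)
    else:
        transformed = (np.power(y, lmbda) - 1.0) / lmbda
    _, p_before = ks_normality(x)
    _, p_after = ks_normality(transformed)
    return BoxCoxResult(transformed, lmbda, float(shift), p_before, p_after)
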