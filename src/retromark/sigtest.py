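"""Significance test for retroposon insertion support patterns.

A retroposon marker that is present in a candidate clade and absent outside it
supports one particular resolution of the local branching order.  Under the
null hypothesis of a hard polytomy each marker independently supports one of
the three possible resolutions of a rooted triplet with probability 1/3.  For
``k`` conflict-free markers (no marker supporting either alternative) the
probability of the observed pattern is therefore ``(1/3)**k``; three or more
conflict-free markers reach significance at ``alpha = 0.05``.

For conflicting patterns ``[k l m]`` an exact enumeration test on the support
margin ``k - max(l, m)`` is provided.  It reduces to the closed form when
``l = m = 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .markers import SupportPattern

ALPHA = 0.05


@dataclass(frozen=True)
class TestResult:
    """Outcome of the insertion significance test for one internal edge."""

    pattern: SupportPattern
    p_value: float
    significant: bool


def conflict_free_p(k: int) -> float:
    """Trichotomy-null p-value for ``k`` conflict-free supporting markers.

    Each marker picks one of three resolutions with probability 1/3, so the
    chance that all ``k`` markers land on the one pre-specified topology is
    ``(1/3)**k``.  ``k = 0`` carries no information and returns 1.
    """
    if k < 0:
        raise ValueError(f"marker count must be non-negative, got {k}")
    return (1.0 / 3.0) ** k


def multinomial_p(pattern: SupportPattern) -> float:
    """Exact enumeration p-value for a (possibly conflicting) support pattern.

    Under the trinomial null (n = k+l+m markers, cells equiprobable) the test
    statistic is the support margin of the best edge, ``a - max(b, c)``.  The
    p-value sums the null probabilities of all outcomes whose margin is at
    least the observed ``k - max(l, m)``.  For conflict-free patterns this
    equals :func:`conflict_free_p` exactly.
    """
    k, l, m = pattern.k, pattern.l, pattern.m
    if min(k, l, m) < 0:
        raise ValueError("pattern counts must be non-negative")
    if k < max(l, m):
        raise ValueError(
            f"hypothesis edge is not best supported: [{k} {l} {m}]"
        )
    n = k + l + m
    if n == 0:
        return 1.0
    observed_margin = k - max(l, m)
    total = 0.0
    base = (1.0 / 3.0) ** n
    for a in range(n + 1):
        for b in range(n - a + 1):
            c = n - a - b
            if a - max(b, c) >= observed_margin:
                total += math.comb(n, a) * math.comb(n - a, b) * base
    return min(total, 1.0)


def evaluate_pattern(pattern: SupportPattern, alpha: float = ALPHA) -> TestResult:
    """Run the significance test appropriate for ``pattern``.

    Conflict-free patterns use the closed form; conflicting ones the
    enumeration test.
    """
    if pattern.l == 0 and pattern.m == 0:
        p = conflict_free_p(pattern.k)
    else:
        p = multinomial_p(pattern)
    return TestResult(pattern=pattern, p_value=p, significant=p < alpha)
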