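"""Hypergeometric comparison of hit frequency across library categories.

Drawing K hits from a library of N factors, a category of size n expects
n*K/N hits.  The observed count k is tested with the exact one-sided
hypergeometric tail in the observed direction: a lower tail
P(X <= k) when the category is depleted (k <= expected) and an upper tail
P(X >= k) when enriched.  Tail probabilities are exact integer-arithmetic
sums of the hypergeometric pmf -- no normal approximation -- so they agree
with subset enumeration to the last bit.

Three hit definitions are exposed: recruited to either structure, or
selective for the test / reference structure only.  No multiple-testing
correction is applied across the (three) categories.
"""

from __future__ import annotations

import dataclasses
from math import comb
from typing import Callable, Sequence

from .differential_scoring import Classification, ScreenResult
from .screen_model import Category, LibraryAnnotation

HIT_DEFINITIONS: dict[str, Callable[[Classification], bool]] = {
    "recruited_any": lambda c: c is not Classification.NOT_RECRUITED,
    "test_selective": lambda c: c is Classification.TEST_SELECTIVE,
    "reference_selective": lambda c: c is Classification.REFERENCE_SELECTIVE,
}


def _check_params(N: int, K: int, n: int) -> tuple[int, int]:
    if not (0 <= K <= N and 0 <= n <= N):
        raise ValueError(f"invalid hypergeometric parameters N={N}, K={K}, n={n}")
    return max(0, n + K - N), min(n, K)


def hypergeom_pmf(N: int, K: int, n: int, k: int) -> float:
    """P(X = k) for X ~ Hypergeometric(N, K, n), exact."""
    lo, hi = _check_params(N, K, n)
    if not lo <= k <= hi:
        return 0.0
    return comb(K, k) * comb(N - K, n - k) / comb(N, n)


def hypergeom_tail(N: int, K: int, n: int, k: int, tail: str = "lower") -> float:
    """Exact hypergeometric tail probability.

    ``tail="lower"`` gives P(X <= k), ``"upper"`` gives P(X >= k), for X the
    number of marked items (K of N) in a draw of n.  k must lie in the
    support [max(0, n+K-N), min(n, K)].  Computed by exact integer summation
    of binomial coefficients, divided once at the end.
    """
    lo, hi = _check_params(N, K, n)
    if not lo <= k <= hi:
        raise ValueError(
            f"k={k} outside hypergeometric support [{lo}, {hi}] "
            f"for N={N}, K={K}, n={n}"
        )
    if tail == "lower":
        ks = range(lo, k + 1)
    elif tail == "upper":
        ks = range(k, hi + 1)
    else:
        raise ValueError(f"tail must be 'lower' or 'upper', got {tail!r}")
    numerator = sum(comb(K, j) * comb(N - K, n - j) for j in ks)
    return numerator / comb(N, n)


@dataclasses.dataclass(frozen=True)
class EnrichmentResult:
    """Hit-frequency comparison for one annotation category."""

    category: str
    hit_definition: str
    N: int  # library size
    K: int  # total hits
    n: int  # category size
    k: int  # hits in category
    expected: float  # n*K/N
    direction: str  # "depleted" | "enriched"
    p_value: float


def category_enrichment(
    result: ScreenResult,
    library: Sequence[LibraryAnnotation],
    hit_definition: str = "recruited_any",
) -> list[EnrichmentResult]:
    """One exact one-sided test per non-empty category.

    Direction is chosen by the observed count against its expectation
    (a tie counts as depleted by convention), and the tail is taken in that
    direction.  Dedicated control lysates never enter the universe.
    """
    try:
        is_hit = HIT_DEFINITIONS[hit_definition]
    except KeyError:
        raise ValueError(
            f"unknown hit definition {hit_definition!r}; "
            f"choose from {sorted(HIT_DEFINITIONS)}"
        ) from None

    categories = {a.factor_id: a.category for a in library}
    scores = result.tallied_scores()
    N = len(scores)
    if N == 0:
        raise ValueError("no tallied factors to test")
    K = sum(1 for s in scores if is_hit(s.classification))

    out: list[EnrichmentResult] = []
    for cat in Category:
        members = [s for s in scores if categories.get(s.factor_id) is cat]
        n = len(members)
        if n == 0:
            continue
        k = sum(1 for s in members if is_hit(s.classification))
        expected = n * K / N
        direction = "enriched" if k > expected else "depleted"
        p = hypergeom_tail(N, K, n, k, "upper" if direction == "enriched" else "lower")
        out.append(
            EnrichmentResult(
                category=cat.value,
                hit_definition=hit_definition,
                N=N,
                K=K,
                n=n,
                k=k,
                expected=expected,
                direction=direction,
                p_value=p,
            )
        )
    return out
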