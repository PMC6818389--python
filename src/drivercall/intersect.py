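"""Exact significance of multi-way gene-set intersections.

Six driver-calling strategies rarely agree, and the genes they do agree on
are the most trustworthy calls — provided the agreement exceeds chance. The
null model here: each strategy's predicted set A_i is an independent uniform
random subset of size n_i drawn from a background universe of N
protein-coding genes. The distribution of |A_1 ∩ ... ∩ A_m| is computed
exactly by sequential conditioning — after intersecting with set i+1, the
overlap z given the current overlap y is hypergeometric with population N,
y successes, and n_{i+1} draws:

    P(z | y) = C(y, z) C(N - y, n_{i+1} - z) / C(N, n_{i+1}).

For m = 2 this reduces to the classical hypergeometric overlap test; for
larger m it generalizes it (the model behind multi-set intersection
statistics). The upper-tail p-value P(X >= observed) measures enrichment of
the observed overlap. Probabilities are carried in log space so that deeply
significant intersections (p ~ 1e-300 and below) survive to the reported
-log10 p.

The background size N is a required input — the set of all protein-coding
genes under consideration — and predicted genes outside the background are
an error, since silently growing N would bias every p-value.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
from scipy.special import logsumexp
from scipy.stats import hypergeom

__all__ = [
    "IntersectionSpec",
    "IntersectionResult",
    "intersection_pmf",
    "intersection_pvalue",
    "expected_intersection",
    "all_subset_intersections",
]


@dataclass(frozen=True)
class IntersectionSpec:
    """A multi-set overlap test: background N, set sizes, observed overlap."""

    background_size: int
    set_sizes: tuple[int, ...]
    observed: int

    def __post_init__(self) -> None:
        _validate_sizes(self.background_size, self.set_sizes)
        if not 0 <= self.observed <= min(self.set_sizes):
            raise ValueError(
                f"observed overlap {self.observed} outside [0, min set size "
                f"{min(self.set_sizes)}]"
            )


@dataclass(frozen=True)
class IntersectionResult:
    """Observed vs expected overlap and exact tail p-value for one subset."""

    subset_label: tuple[str, ...]
    observed: int
    expected: float
    fold_enrichment: float
    p_value: float
    neg_log10_p: float

    @property
    def degree(self) -> int:
        return len(self.subset_label)


def _validate_sizes(n_background: int, sizes: Sequence[int]) -> None:
    if n_background < 1:
        raise ValueError(f"background size must be positive, got {n_background}")
    for n in sizes:
        if not 0 <= n <= n_background:
            raise ValueError(
                f"set size {n} outside [0, background size {n_background}]"
            )


def _log_pmf(n_background: int, sizes: Sequence[int]) -> np.ndarray:
    """Log-pmf of the intersection size over support 0..min(sizes)."""
    sizes = list(sizes)
    support_max = min(sizes)
    # Start from the first set: the running intersection is the set itself.
    log_pmf = np.full(sizes[0] + 1, -np.inf)
    log_pmf[sizes[0]] = 0.0
    for draw in sizes[1:]:
        y = np.arange(log_pmf.size)  # current overlap sizes
        z = np.arange(min(log_pmf.size - 1, draw) + 1)  # next overlap sizes
        # transition[yi, zi] = log P(Hypergeom(N, y, draw) = z)
        transition = hypergeom.logpmf(z[None, :], n_background, y[:, None], draw)
        log_pmf = logsumexp(log_pmf[:, None] + transition, axis=0)
    # Pad/trim to the full support 0..min(sizes).
    out = np.full(support_max + 1, -np.inf)
    out[: log_pmf.size] = log_pmf[: support_max + 1]
    return out


def intersection_pmf(n_background: int, sizes: Sequence[int]) -> np.ndarray:
    """Exact pmf of |A_1 ∩ ... ∩ A_m| over overlap sizes 0..min(sizes).

    Each A_i is an independent uniform random subset of size ``sizes[i]``
    from a background of ``n_background`` genes; requires m >= 2.
    """
    if len(sizes) < 2:
        raise ValueError("intersection model needs at least 2 sets")
    _validate_sizes(n_background, sizes)
    return np.exp(_log_pmf(n_background, sizes))


def intersection_pvalue(spec: IntersectionSpec) -> float:
    """Upper-tail P(X >= observed) under the intersection null; 1 at observed 0."""
    if spec.observed == 0:
        return 1.0
    log_pmf = _log_pmf(spec.background_size, spec.set_sizes)
    return float(min(1.0, math.exp(logsumexp(log_pmf[spec.observed :]))))


def _log_pvalue(spec: IntersectionSpec) -> float:
    if spec.observed == 0:
        return 0.0
    log_pmf = _log_pmf(spec.background_size, spec.set_sizes)
    return float(min(0.0, logsumexp(log_pmf[spec.observed :])))


def expected_intersection(n_background: int, sizes: Sequence[int]) -> float:
    """Expected overlap N * Π(n_i / N) under independent uniform subsets."""
    _validate_sizes(n_background, sizes)
    expected = float(n_background)
    for n in sizes:
        expected *= n / n_background
    return expected


def all_subset_intersections(
    named_sets: Mapping[str, frozenset[str] | set[str]],
    n_background: int,
    background: frozenset[str] | set[str] | None = None,
) -> list[IntersectionResult]:
    """Test every combination of >= 2 named sets (2^m - m - 1 results).

    Results are ordered by subset size then lexicographic label. When the
    ``background`` membership is supplied, genes outside it are rejected;
    either way a set larger than ``n_background`` is an error.
    """
    names = sorted(named_sets)
    if not 2 <= len(names) <= 12:
        raise ValueError(f"need between 2 and 12 sets, got {len(names)}")
    sets = {name: frozenset(named_sets[name]) for name in names}
    for name, members in sets.items():
        if len(members) > n_background:
            raise ValueError(
                f"set {name!r} has {len(members)} genes, more than the "
                f"background size {n_background}"
            )
        if background is not None:
            stray = members - frozenset(background)
            if stray:
                raise ValueError(
                    f"set {name!r} contains {len(stray)} genes absent from the "
                    f"background universe (e.g. {sorted(stray)[0]!r})"
                )

    results: list[IntersectionResult] = []
    for degree in range(2, len(names) + 1):
        for label in combinations(names, degree):
            members = [sets[name] for name in label]
            observed = len(frozenset.intersection(*members))
            sizes = tuple(len(m) for m in members)
            expected = expected_intersection(n_background, sizes)
            if expected > 0:
                fold = observed / expected
            else:
                fold = math.inf if observed > 0 else 0.0
            spec = IntersectionSpec(
                background_size=n_background, set_sizes=sizes, observed=observed
            )
            log_p = _log_pvalue(spec)
            results.append(
                IntersectionResult(
                    subset_label=label,
                    observed=observed,
                    expected=expected,
                    fold_enrichment=fold,
                    p_value=math.exp(log_p),
                    neg_log10_p=max(0.0, -log_p / math.log(10)),
                )
            )
    return results
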