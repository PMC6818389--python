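"""Top-N evaluation of driver-gene rankings: precision and nDCG.

Two complementary views of how good a predicted ranking is:

* **Top-N-Precision** against a membership reference (CGC-style): the
  fraction of the top n predicted genes that are in the reference set. When
  the predicted list is shorter than n, the denominator is the number of
  genes actually evaluated, so short lists are not penalized twice.

* **Top-N-nDCG** against a weighted reference (IntOGen-style): each
  predicted gene's gain is its reference weight w_i (0 outside the
  reference), cumulated with a logarithmic position discount,

      CG_n   = Σ_{i=1..n} w_i
      DCG_n  = w_1 + Σ_{i=2..n} w_i / log2(i)
      IDCG_n = DCG_n of the reference's own descending-weight ordering
      nDCG_n = DCG_n / IDCG_n  (0 when IDCG_n = 0),

  so nDCG is 1 exactly when the prediction reproduces the reference order
  and decays as high-weight genes slip down the list. By the rearrangement
  inequality nDCG always lies in [0, 1].

Pan-cancer summaries average the per-cancer-type values of either metric at
a fixed depth (conventionally n = 100); the denominator is the number of
cancer types actually evaluated, never a hard-coded constant.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

from .references import ReferenceGeneSet, WeightedReference, weight_of_gene

__all__ = [
    "EvaluationResult",
    "PanCancerSummary",
    "top_n_precision",
    "dcg_curve",
    "idcg",
    "top_n_ndcg",
    "evaluate_ranking",
    "pan_cancer_summary",
]

DEFAULT_DEPTH = 100


@dataclass(frozen=True)
class EvaluationResult:
    """Per-depth precision and (n)DCG curves for one predicted ranking."""

    n_values: tuple[int, ...]
    precision_at: Mapping[int, float]
    cg_at: Mapping[int, float]
    dcg_at: Mapping[int, float]
    idcg_at: Mapping[int, float]
    ndcg_at: Mapping[int, float]


@dataclass(frozen=True)
class PanCancerSummary:
    """Cross-cohort averages of precision and nDCG at one depth."""

    per_type: Mapping[str, EvaluationResult]
    depth: int
    average_precision: float
    average_ndcg: float
    sum_precision: float


def top_n_precision(
    predicted: Sequence[str], reference: ReferenceGeneSet | frozenset[str] | set[str], n: int
) -> float:
    """Fraction of the top-n predicted genes found in the reference set.

    The denominator is min(n, len(predicted)) — the genes actually evaluated.
    """
    if n < 1:
        raise ValueError(f"evaluation depth n must be >= 1, got {n}")
    if not predicted:
        raise ValueError("predicted list must contain at least one gene")
    members = reference.members if isinstance(reference, ReferenceGeneSet) else reference
    top = predicted[: min(n, len(predicted))]
    return sum(1 for g in top if g in members) / len(top)


def _dcg_terms(weights: Sequence[float]) -> list[float]:
    """Per-position discounted gains: w_1, then w_i / log2(i) for i >= 2."""
    return [
        w if i == 1 else w / math.log2(i) for i, w in enumerate(weights, start=1)
    ]


def dcg_curve(
    predicted: Sequence[str], ref: WeightedReference, n_max: int
) -> tuple[dict[int, float], dict[int, float]]:
    """Cumulative gain CG_n and discounted cumulative gain DCG_n for n <= n_max.

    Gains are the reference weights of the predicted genes (0 outside the
    reference). Returns (cg_at, dcg_at) with an entry for every n in
    1..n_max; depths beyond the list length accumulate nothing further.
    """
    if n_max < 1:
        raise ValueError(f"n_max must be >= 1, got {n_max}")
    weights = [weight_of_gene(g, ref) for g in predicted[:n_max]]
    terms = _dcg_terms(weights)
    cg_at: dict[int, float] = {}
    dcg_at: dict[int, float] = {}
    cg = dcg = 0.0
    for n in range(1, n_max + 1):
        if n <= len(weights):
            cg += weights[n - 1]
            dcg += terms[n - 1]
        cg_at[n] = cg
        dcg_at[n] = dcg
    return cg_at, dcg_at


def idcg(ref: WeightedReference, n: int) -> float:
    """DCG_n of the ideal (descending-weight) ordering of the reference itself."""
    if n < 1:
        raise ValueError(f"evaluation depth n must be >= 1, got {n}")
    ideal = ref.ideal_order()[:n]
    return sum(_dcg_terms([ref.weight_of[g] for g in ideal]))


def top_n_ndcg(predicted: Sequence[str], ref: WeightedReference, n: int) -> float:
    """Normalized DCG at depth n: DCG_n / IDCG_n, or 0 for a degenerate reference."""
    if n < 1:
        raise ValueError(f"evaluation depth n must be >= 1, got {n}")
    _, dcg_at = dcg_curve(predicted, ref, n)
    ideal = idcg(ref, n)
    if ideal == 0.0:
        return 0.0
    return dcg_at[n] / ideal


def evaluate_ranking(
    predicted: Sequence[str],
    reference_set: ReferenceGeneSet,
    weighted_ref: WeightedReference,
    n_max: int = DEFAULT_DEPTH,
) -> EvaluationResult:
    """Full per-depth evaluation of one ranking against both reference kinds."""
    cg_at, dcg_at = dcg_curve(predicted, weighted_ref, n_max)
    idcg_at = {n: idcg(weighted_ref, n) for n in range(1, n_max + 1)}
    ndcg_at = {
        n: (dcg_at[n] / idcg_at[n] if idcg_at[n] > 0 else 0.0)
        for n in range(1, n_max + 1)
    }
    precision_at = {
        n: top_n_precision(predicted, reference_set, n) for n in range(1, n_max + 1)
    }
    return EvaluationResult(
        n_values=tuple(range(1, n_max + 1)),
        precision_at=precision_at,
        cg_at=cg_at,
        dcg_at=dcg_at,
        idcg_at=idcg_at,
        ndcg_at=ndcg_at,
    )


def pan_cancer_summary(
    results: Mapping[str, EvaluationResult], n: int
) -> PanCancerSummary:
    """Average precision and nDCG at depth n across cancer types.

    The denominator is the number of supplied cancer types.
    """
    if not results:
        raise ValueError("pan-cancer summary requires at least one cancer type")
    precisions = [res.precision_at[n] for res in results.values()]
    ndcgs = [res.ndcg_at[n] for res in results.values()]
    return PanCancerSummary(
        per_type=dict(results),
        depth=n,
        average_precision=sum(precisions) / len(precisions),
        average_ndcg=sum(ndcgs) / len(ndcgs),
        sum_precision=sum(precisions),
    )
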