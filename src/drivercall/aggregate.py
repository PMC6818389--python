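"""Robust rank aggregation (RRA) of discordant driver-gene rankings.

Each driver-calling strategy contributes an ordered, possibly truncated list
of candidate genes over a shared universe of n protein-coding genes. A gene
found at 1-based position p in a list gets the normalized rank p / n; lists
that do not report the gene contribute nothing (this is what makes the
method robust to incomplete rankings — a missing prediction is no evidence,
not worst-case evidence).

Under the null hypothesis that every strategy ranks genes uniformly at
random, the j-th smallest of a gene's K normalized ranks behaves like the
j-th order statistic of K independent Uniform(0,1) draws, which follows a
Beta(j, K - j + 1) distribution. The RRA score is

    rho(r) = min_{j = 1..k} P( Beta(j, K - j + 1) <= r_(j) ),

the strongest order-statistic evidence that the gene sits higher than chance
across lists. A Bonferroni factor K over the order-statistic positions turns
rho into a conservative p-value: p = min(1, K * rho). The consensus list
orders genes by ascending rho.

Beta CDFs are evaluated with the regularized incomplete beta function
(scipy.special.betainc); no simulation is used in the production path.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence, TextIO

import numpy as np
import pandas as pd
from scipy import special

__all__ = [
    "RankedList",
    "AggregationResult",
    "normalized_ranks",
    "rho_score",
    "aggregate",
    "load_ranked_list",
]


@dataclass(frozen=True)
class RankedList:
    """One strategy's ordered gene predictions over a stated universe.

    ``genes`` are distinct symbols, best first; ``universe_size`` is the
    total number of genes the strategy considered (>= len(genes)).
    """

    strategy: str
    genes: tuple[str, ...]
    universe_size: int

    def __post_init__(self) -> None:
        if len(set(self.genes)) != len(self.genes):
            seen: set[str] = set()
            dup = next(g for g in self.genes if g in seen or seen.add(g))  # type: ignore[func-returns-value]
            raise ValueError(f"duplicate gene {dup!r} in ranked list {self.strategy!r}")
        if self.universe_size < len(self.genes):
            raise ValueError(
                f"universe_size {self.universe_size} < list length {len(self.genes)}"
            )

    def position_of(self, gene: str) -> int | None:
        """1-based rank of ``gene`` in this list, or None if absent."""
        try:
            return self.genes.index(gene) + 1
        except ValueError:
            return None


@dataclass(frozen=True)
class AggregationResult:
    """Consensus ranking with per-gene rho scores and corrected p-values."""

    table: pd.DataFrame  # columns: consensus_rank, gene, rho, p_corrected, n_lists_supporting
    k_lists: int

    @property
    def genes(self) -> list[str]:
        return list(self.table["gene"])

    def to_tsv(self, destination: str | Path | TextIO) -> None:
        out = self.table.copy()
        out["rho"] = out["rho"].map("{:.6e}".format)
        out["p_corrected"] = out["p_corrected"].map("{:.6e}".format)
        out.to_csv(destination, sep="\t", index=False)


def normalized_ranks(
    gene: str, lists: Iterable[RankedList], universe: frozenset[str] | set[str]
) -> list[float]:
    """Ascending normalized ranks of ``gene`` across the lists that report it.

    Each list containing the gene at 1-based position p contributes
    p / universe_size; other lists contribute nothing. Raises if any list
    contains a gene outside the universe.
    """
    ranks: list[float] = []
    for ranked in lists:
        missing = next((g for g in ranked.genes if g not in universe), None)
        if missing is not None:
            raise ValueError(
                f"gene {missing!r} in list {ranked.strategy!r} is absent from the universe"
            )
        pos = ranked.position_of(gene)
        if pos is not None:
            ranks.append(pos / ranked.universe_size)
    return sorted(ranks)


def rho_score(r: Sequence[float], k_lists: int) -> float:
    """RRA order-statistic score of an ascending normalized rank vector.

    rho = min over j of P(Beta(j, K - j + 1) <= r_(j)); an empty vector
    (gene unranked everywhere) scores 1.
    """
    r = np.asarray(r, dtype=float)
    if r.size == 0:
        return 1.0
    if np.any(r <= 0) or np.any(r > 1):
        raise ValueError("normalized ranks must lie in (0, 1]")
    if np.any(np.diff(r) < 0):
        raise ValueError("normalized ranks must be sorted ascending")
    if r.size > k_lists:
        raise ValueError(f"{r.size} ranks supplied but only {k_lists} lists")
    j = np.arange(1, r.size + 1, dtype=float)
    return float(np.min(special.betainc(j, k_lists - j + 1, r)))


def _rho_scores_batch(rank_matrix: np.ndarray, counts: np.ndarray, k_lists: int) -> np.ndarray:
    """Vectorized rho over a (genes x K) matrix of ascending ranks.

    ``rank_matrix`` holds each gene's sorted normalized ranks left-justified
    and NaN-padded; ``counts`` gives the number of valid ranks per gene.
    """
    n_genes, width = rank_matrix.shape
    j = np.arange(1, width + 1, dtype=float)
    with np.errstate(invalid="ignore"):
        probs = special.betainc(j[None, :], k_lists - j[None, :] + 1, rank_matrix)
    probs = np.where(np.isnan(probs), np.inf, probs)
    rho = np.min(probs, axis=1)
    rho[counts == 0] = 1.0
    return rho


def aggregate(
    lists: Sequence[RankedList], universe: frozenset[str] | set[str]
) -> AggregationResult:
    """Aggregate K ranked lists into a consensus ranking.

    Scores every gene appearing in at least one list; corrected p-values are
    min(1, K * rho). The consensus is ordered by ascending rho, ties broken
    by descending support count then lexicographic gene symbol.
    """
    lists = list(lists)
    if not lists:
        raise ValueError("aggregate requires at least one ranked list")
    k = len(lists)
    universe = frozenset(universe)
    for ranked in lists:
        if ranked.universe_size != len(universe):
            raise ValueError(
                f"list {ranked.strategy!r} states universe_size {ranked.universe_size} "
                f"but the shared universe has {len(universe)} genes"
            )
        missing = next((g for g in ranked.genes if g not in universe), None)
        if missing is not None:
            raise ValueError(
                f"gene {missing!r} in list {ranked.strategy!r} is absent from the universe"
            )

    scored = sorted({g for ranked in lists for g in ranked.genes})
    index = {g: i for i, g in enumerate(scored)}
    n = len(universe)

    rank_matrix = np.full((len(scored), k), np.nan)
    counts = np.zeros(len(scored), dtype=int)
    for ranked in lists:
        for pos, gene in enumerate(ranked.genes, start=1):
            i = index[gene]
            rank_matrix[i, counts[i]] = pos / n
            counts[i] += 1
    rank_matrix.sort(axis=1)  # NaNs sort to the end, leaving ranks ascending

    rho = _rho_scores_batch(rank_matrix, counts, k)
    p_corrected = np.minimum(1.0, rho * k)

    frame = pd.DataFrame(
        {
            "gene": scored,
            "rho": rho,
            "p_corrected": p_corrected,
            "n_lists_supporting": counts,
        }
    )
    frame = frame.sort_values(
        by=["rho", "n_lists_supporting", "gene"],
        ascending=[True, False, True],
        kind="stable",
    ).reset_index(drop=True)
    frame.insert(0, "consensus_rank", np.arange(1, len(frame) + 1))
    return AggregationResult(table=frame, k_lists=k)


def load_ranked_list(
    source: str | Path | TextIO,
    strategy: str,
    universe_size: int,
    score_ascending: bool | None = None,
) -> RankedList:
    """Read a per-strategy ranking from a 2-column TSV with header.

    The first column is the gene symbol. When the second column is a rank
    (default), genes are ordered by ascending value; pass
    ``score_ascending=False`` for score files where larger is better.
    """
    table = pd.read_csv(source, sep="\t", comment="#")
    if table.shape[1] < 2:
        raise ValueError("ranked list TSV needs (gene, rank-or-score) columns")
    gene_col, value_col = table.columns[:2]
    ascending = True if score_ascending is None else score_ascending
    table = table.sort_values(value_col, ascending=ascending, kind="stable")
    genes = tuple(str(g).strip() for g in table[gene_col])
    return RankedList(strategy=strategy, genes=genes, universe_size=universe_size)
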