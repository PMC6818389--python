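"""Reference driver-gene resources: membership sets and weighted rankings.

Driver-gene predictions are benchmarked against two kinds of curated
resources. A membership set (CGC-style: the Cancer Gene Census and similar
catalogues) is just a set of gene symbols and supports precision-type
metrics. A weighted reference (IntOGen-style) additionally carries per-gene
driver-mutation counts, from which each reference gene g receives the weight

    w(g) = (count(g) / total_count) * (G - rank(g)),

where G is the number of reference genes and rank(g) is g's 1-based position
when the reference is ordered by descending count (ties broken
lexicographically by symbol). The proportion factor rewards mutation burden
and the (G - rank) factor rewards position, so the bottom-ranked gene always
has weight exactly 0. Genes outside the reference have weight 0 by
definition. These weights are the gains used by the nDCG evaluation in
:mod:`drivercall.metrics`.

G is always computed from the supplied reference file; the published IntOGen
snapshot (version 2014.12) this scheme was designed around contains 459
driver genes, but no constant is hard-coded here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, TextIO

import pandas as pd

__all__ = [
    "ReferenceGeneSet",
    "WeightedReference",
    "load_gene_set",
    "load_weighted_reference",
    "build_weighted_reference",
    "weight_of_gene",
    "annotate_genes",
]


@dataclass(frozen=True)
class ReferenceGeneSet:
    """A named, unweighted set of reference gene symbols."""

    name: str
    members: frozenset[str]

    def __post_init__(self) -> None:
        if any(not g for g in self.members):
            raise ValueError("ReferenceGeneSet members must be non-empty strings")

    def __contains__(self, gene: str) -> bool:
        return gene in self.members

    def __len__(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class WeightedReference:
    """A mutation-count-weighted reference ranking.

    Attributes
    ----------
    counts
        Gene symbol -> positive driver-mutation count.
    total_count
        Sum of all counts.
    n_genes
        Number of reference genes, G.
    rank_of
        Gene -> 1-based rank by descending count (lexicographic tie-break).
    weight_of
        Gene -> (count/total) * (G - rank); always >= 0, exactly 0 for the
        bottom-ranked gene.
    """

    counts: Mapping[str, int]
    total_count: int
    n_genes: int
    rank_of: Mapping[str, int]
    weight_of: Mapping[str, float]

    def ideal_order(self) -> list[str]:
        """Reference genes ordered by ascending rank (descending weight)."""
        return sorted(self.rank_of, key=self.rank_of.__getitem__)


def load_gene_set(source: str | Path | TextIO, name: str) -> ReferenceGeneSet:
    """Load a gene set from a one-symbol-per-line or TSV-first-column file.

    Duplicates are collapsed and blank lines skipped; an empty result is
    valid but triggers a warning.
    """
    if isinstance(source, (str, Path)):
        with open(source, "r", encoding="utf-8") as fh:
            lines = fh.readlines()
    else:
        lines = source.readlines()
    members = set()
    for raw in lines:
        line = raw.strip()
        if not line or line.startswith("#"):
            continue
        symbol = line.split("\t")[0].strip()
        if symbol:
            members.add(symbol)
    if not members:
        warnings.warn(f"gene set {name!r} is empty after parsing", stacklevel=2)
    return ReferenceGeneSet(name=name, members=frozenset(members))


def load_weighted_reference(source: str | Path | TextIO) -> WeightedReference:
    """Load a (gene, count) TSV with header and build the weighted reference."""
    table = pd.read_csv(source, sep="\t", comment="#")
    if table.shape[1] < 2:
        raise ValueError("weighted reference TSV needs at least (gene, count) columns")
    gene_col, count_col = table.columns[:2]
    counts = {
        str(row[gene_col]).strip(): int(row[count_col]) for _, row in table.iterrows()
    }
    return build_weighted_reference(counts)


def build_weighted_reference(counts: Mapping[str, int]) -> WeightedReference:
    """Build a :class:`WeightedReference` from per-gene driver-mutation counts.

    Ranks are assigned by descending count with lexicographic tie-breaking,
    and weights follow w(g) = (count/total) * (G - rank). All counts must be
    positive integers.

    Examples
    --------
    >>> ref = build_weighted_reference({"A": 100, "B": 60, "C": 40})
    >>> ref.weight_of["A"], ref.weight_of["B"], ref.weight_of["C"]
    (1.0, 0.3, 0.0)
    """
    if not counts:
        raise ValueError("weighted reference requires at least one gene")
    for gene, count in counts.items():
        if count < 1:
            raise ValueError(f"count for gene {gene!r} must be >= 1, got {count}")
    total = sum(counts.values())
    g = len(counts)
    ordered = sorted(counts, key=lambda sym: (-counts[sym], sym))
    rank_of = {sym: i for i, sym in enumerate(ordered, start=1)}
    weight_of = {
        sym: (counts[sym] / total) * (g - rank_of[sym]) for sym in ordered
    }
    return WeightedReference(
        counts=dict(counts),
        total_count=total,
        n_genes=g,
        rank_of=rank_of,
        weight_of=weight_of,
    )


def weight_of_gene(gene: str, ref: WeightedReference) -> float:
    """The reference weight of ``gene``, or exactly 0 if it is not in the reference."""
    return ref.weight_of.get(gene, 0.0)


def annotate_genes(
    genes: Sequence[str], sets: Iterable[ReferenceGeneSet]
) -> pd.DataFrame:
    """Flag each gene's membership in each reference set.

    Returns a DataFrame with one row per input gene (order preserved), a
    ``gene`` column and one boolean column per set, named after the set.
    """
    sets = list(sets)
    data: dict[str, object] = {"gene": list(genes)}
    for ref in sets:
        data[ref.name] = [g in ref.members for g in genes]
    return pd.DataFrame(data)


def write_weighted_reference(ref: WeightedReference, destination: str | Path) -> None:
    """Write a weighted reference back out as a (gene, count) TSV."""
    frame = pd.DataFrame(
        {"gene": list(ref.counts), "count": list(ref.counts.values())}
    ).sort_values("gene", kind="stable")
    frame.to_csv(destination, sep="\t", index=False)


__all__.append("write_weighted_reference")
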