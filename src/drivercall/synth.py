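"""Seeded synthetic fixtures with planted driver genes.

Real driver-calling benchmarks need TCGA cohorts and curated databases; this
module generates miniature stand-ins with the same statistical structure so
the whole pipeline is exercisable offline:

* **Rankings.** Gene g's score under strategy k is
  s_{g,k} = beta_k * [g is driver] + eps_{g,k}, eps ~ N(0, 1) independent.
  Each strategy ranks the universe by descending score and truncates to its
  top L — emulating callers that only emit significant genes, which is
  exactly the incomplete-ranking regime robust rank aggregation targets.
  beta_k = 0 gives a uniformly random ranking; heterogeneous beta_k across
  strategies emulates the complementary power of frequency-, clustering-,
  network-based (etc.) callers.

* **Cohorts.** ``simulate_maf`` produces exactly M mutation records across
  exactly S distinct sample barcodes, with a prescribed fraction of records
  hitting planted drivers — enough structure for cohort summaries and
  frequency rankings, with no pretense of realistic mutational signatures.

* **References.** A membership reference samples a subset of the planted
  drivers (an imperfect catalogue, like any real one); a weighted reference
  draws per-gene counts from geometric distributions whose mean is tilted
  upward for drivers, so reference weight correlates with the planted truth
  without copying it.

All generators take explicit seeds and use one fresh numpy Generator per
call; identical configuration and seed give bitwise-identical output.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .aggregate import RankedList
from .maf_io import MafRecord
from .references import (
    ReferenceGeneSet,
    WeightedReference,
    build_weighted_reference,
)

__all__ = [
    "SimulationConfig",
    "SyntheticTruth",
    "simulate_rankings",
    "simulate_maf",
    "simulate_weighted_reference",
    "simulate_reference_set",
    "planted_driver_benchmark",
]

#: Default per-strategy signal strengths: six callers of complementary,
#: unequal power, the strongest clearly informative and the weakest barely so.
DEFAULT_EFFECTS = (2.5, 2.0, 2.0, 1.5, 1.5, 1.0)

_VARIANT_CLASSES = (
    "Missense_Mutation",
    "Silent",
    "Nonsense_Mutation",
    "Splice_Site",
    "Frame_Shift_Del",
)


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of a planted-driver simulation.

    ``universe_size`` genes, of which ``n_drivers`` are planted drivers;
    ``n_strategies`` rankings truncated to ``list_length``; ``driver_effect``
    gives each strategy's signal strength (standard deviations of score
    separation between drivers and passengers).
    """

    universe_size: int = 2000
    n_drivers: int = 30
    n_strategies: int = 6
    list_length: int = 200
    driver_effect: tuple[float, ...] = DEFAULT_EFFECTS
    seed: int = 0
    reference_fraction: float = 0.8

    def __post_init__(self) -> None:
        if self.universe_size < 1:
            raise ValueError(f"universe_size must be positive, got {self.universe_size}")
        if not 1 <= self.n_drivers <= self.universe_size:
            raise ValueError(
                f"n_drivers must be in [1, universe_size], got {self.n_drivers}"
            )
        if not 1 <= self.list_length <= self.universe_size:
            raise ValueError(
                f"list_length must be in [1, universe_size], got {self.list_length}"
            )
        if self.n_strategies < 1:
            raise ValueError(f"n_strategies must be positive, got {self.n_strategies}")
        if len(self.driver_effect) != self.n_strategies:
            raise ValueError(
                f"driver_effect has {len(self.driver_effect)} entries for "
                f"{self.n_strategies} strategies"
            )
        if any(b < 0 for b in self.driver_effect):
            raise ValueError("driver_effect entries must be non-negative")
        if not 0 < self.reference_fraction <= 1:
            raise ValueError(
                f"reference_fraction must be in (0, 1], got {self.reference_fraction}"
            )


@dataclass(frozen=True)
class SyntheticTruth:
    """A simulated benchmark: planted drivers, rankings, and references."""

    universe: tuple[str, ...]
    driver_genes: frozenset[str]
    rankings: tuple[RankedList, ...]
    reference_set: ReferenceGeneSet
    weighted_reference: WeightedReference


def _gene_names(universe_size: int) -> tuple[str, ...]:
    width = len(str(universe_size - 1))
    return tuple(f"G{i:0{width}d}" for i in range(universe_size))


def simulate_rankings(config: SimulationConfig) -> SyntheticTruth:
    """Generate K noisy rankings over a universe with planted drivers.

    Strategy k scores every gene as beta_k * [driver] + N(0, 1) noise, ranks
    by descending score, and keeps its top ``list_length`` genes. The
    accompanying references are generated from the same truth with
    seed offsets, so one config describes a complete benchmark instance.
    """
    rng = np.random.default_rng(config.seed)
    genes = _gene_names(config.universe_size)
    driver_idx = rng.choice(config.universe_size, size=config.n_drivers, replace=False)
    is_driver = np.zeros(config.universe_size, dtype=bool)
    is_driver[driver_idx] = True
    drivers = frozenset(genes[i] for i in driver_idx)

    rankings = []
    for k, beta in enumerate(config.driver_effect):
        scores = beta * is_driver + rng.standard_normal(config.universe_size)
        order = np.argsort(-scores, kind="stable")[: config.list_length]
        rankings.append(
            RankedList(
                strategy=f"strategy_{k + 1}",
                genes=tuple(genes[i] for i in order),
                universe_size=config.universe_size,
            )
        )

    reference_set = simulate_reference_set(
        drivers, fraction=config.reference_fraction, seed=config.seed + 1
    )
    weighted_reference = simulate_weighted_reference(
        universe=genes, drivers=drivers, concentration=8.0, seed=config.seed + 2
    )
    return SyntheticTruth(
        universe=genes,
        driver_genes=drivers,
        rankings=tuple(rankings),
        reference_set=reference_set,
        weighted_reference=weighted_reference,
    )


def simulate_reference_set(
    drivers: frozenset[str] | set[str], fraction: float, seed: int
) -> ReferenceGeneSet:
    """Sample a membership reference covering a fraction of the true drivers."""
    if not 0 < fraction <= 1:
        raise ValueError(f"fraction must be in (0, 1], got {fraction}")
    rng = np.random.default_rng(seed)
    ordered = sorted(drivers)
    size = max(1, round(fraction * len(ordered)))
    chosen = rng.choice(len(ordered), size=size, replace=False)
    return ReferenceGeneSet(
        name="synthetic_reference",
        members=frozenset(ordered[i] for i in chosen),
    )


def simulate_weighted_reference(
    universe: Sequence[str],
    drivers: frozenset[str] | set[str],
    concentration: float,
    seed: int,
    n_noise_genes: int | None = None,
) -> WeightedReference:
    """Draw a mutation-count-weighted reference tilted toward the drivers.

    Counts are geometric (support >= 1). Driver genes draw with mean
    ``concentration`` times the passenger mean of 2, so larger concentration
    pushes drivers toward the top of the reference ranking. The reference
    contains every driver plus ``n_noise_genes`` passengers (default: as
    many as there are drivers).
    """
    if concentration <= 0:
        raise ValueError(f"concentration must be positive, got {concentration}")
    rng = np.random.default_rng(seed)
    drivers = sorted(drivers)
    passengers = sorted(set(universe) - set(drivers))
    if n_noise_genes is None:
        n_noise_genes = len(drivers)
    n_noise_genes = min(n_noise_genes, len(passengers))
    noise_idx = rng.choice(len(passengers), size=n_noise_genes, replace=False)

    base_mean = 2.0
    counts: dict[str, int] = {}
    for gene in drivers:
        counts[gene] = int(rng.geometric(1.0 / (base_mean * concentration)))
    for i in sorted(noise_idx):
        counts[passengers[i]] = int(rng.geometric(1.0 / base_mean))
    return build_weighted_reference(counts)


def simulate_maf(
    n_samples: int,
    n_mutations: int,
    universe: Sequence[str],
    driver_fraction: float,
    drivers: frozenset[str] | set[str],
    seed: int,
) -> list[MafRecord]:
    """Simulate a cohort with exact sample and mutation totals.

    Produces exactly ``n_mutations`` records over exactly ``n_samples``
    distinct barcodes (each barcode used at least once when M >= S); a
    ``driver_fraction`` share of records (rounded) hits driver genes, the
    rest hit passengers uniformly.
    """
    if not 0 <= driver_fraction <= 1:
        raise ValueError(f"driver_fraction must be in [0, 1], got {driver_fraction}")
    if n_samples < 0 or n_mutations < 0:
        raise ValueError("n_samples and n_mutations must be non-negative")
    if n_mutations == 0 and n_samples == 0:
        return []
    if n_samples == 0:
        raise ValueError("cannot place mutations in a cohort of 0 samples")
    if n_mutations < n_samples:
        raise ValueError(
            f"need n_mutations >= n_samples to use every barcode, got "
            f"{n_mutations} < {n_samples}"
        )

    rng = np.random.default_rng(seed)
    drivers = sorted(set(drivers))
    passengers = sorted(set(universe) - set(drivers))
    if not passengers and driver_fraction < 1:
        raise ValueError("universe has no non-driver genes for passenger mutations")
    if not drivers and driver_fraction > 0:
        raise ValueError("driver_fraction > 0 but no driver genes supplied")

    width = len(str(max(n_samples - 1, 1)))
    barcodes = [f"SAMPLE_{i:0{width}d}" for i in range(n_samples)]
    # Every barcode appears at least once; the remainder are uniform.
    assignment = np.concatenate(
        [
            np.arange(n_samples),
            rng.integers(0, n_samples, size=n_mutations - n_samples),
        ]
    )
    rng.shuffle(assignment)

    n_driver_hits = round(driver_fraction * n_mutations)
    is_driver_hit = np.zeros(n_mutations, dtype=bool)
    is_driver_hit[rng.choice(n_mutations, size=n_driver_hits, replace=False)] = True

    records = []
    for i in range(n_mutations):
        pool = drivers if is_driver_hit[i] else passengers
        gene = pool[int(rng.integers(0, len(pool)))]
        records.append(
            MafRecord(
                hugo_symbol=gene,
                sample_barcode=barcodes[int(assignment[i])],
                variant_classification=_VARIANT_CLASSES[
                    int(rng.integers(0, len(_VARIANT_CLASSES)))
                ],
            )
        )
    return records


def planted_driver_benchmark(
    config: SimulationConfig | None = None,
    n_seeds: int = 20,
    depth: int = 50,
    base_seed: int = 0,
):
    """Compare the consensus ranking with each individual strategy.

    Runs ``n_seeds`` independent planted-driver simulations (seeds
    ``base_seed .. base_seed + n_seeds - 1`` applied on top of the config's
    own seed), aggregates each one into a consensus, and reports the mean
    Top-``depth``-Precision against the planted drivers and the mean
    Top-``depth``-nDCG against the synthetic weighted reference, per
    strategy and for the consensus.

    Returns a pandas DataFrame with columns (strategy, mean_precision,
    mean_ndcg), the consensus row last.
    """
    import pandas as pd

    from .aggregate import aggregate
    from .metrics import top_n_ndcg, top_n_precision

    if config is None:
        config = SimulationConfig()
    if n_seeds < 1:
        raise ValueError(f"n_seeds must be positive, got {n_seeds}")

    names = [rl_name for rl_name in (f"strategy_{k + 1}" for k in range(config.n_strategies))]
    precision: dict[str, list[float]] = {name: [] for name in names + ["consensus"]}
    ndcg: dict[str, list[float]] = {name: [] for name in names + ["consensus"]}

    for offset in range(n_seeds):
        seeded = SimulationConfig(
            universe_size=config.universe_size,
            n_drivers=config.n_drivers,
            n_strategies=config.n_strategies,
            list_length=config.list_length,
            driver_effect=config.driver_effect,
            seed=config.seed + 1000 * (base_seed + offset),
            reference_fraction=config.reference_fraction,
        )
        truth = simulate_rankings(seeded)
        universe = frozenset(truth.universe)
        consensus = aggregate(truth.rankings, universe)
        rankings = {rl.strategy: list(rl.genes) for rl in truth.rankings}
        rankings["consensus"] = consensus.genes
        for name, genes in rankings.items():
            precision[name].append(top_n_precision(genes, truth.driver_genes, depth))
            ndcg[name].append(top_n_ndcg(genes, truth.weighted_reference, depth))

    return pd.DataFrame(
        {
            "strategy": names + ["consensus"],
            "mean_precision": [
                float(np.mean(precision[name])) for name in names + ["consensus"]
            ],
            "mean_ndcg": [float(np.mean(ndcg[name])) for name in names + ["consensus"]],
        }
    )
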