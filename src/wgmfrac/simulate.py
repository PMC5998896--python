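"""Forward simulator of multiplication, fractionation and divergence.

Generates ground-truth datasets for every other module: a gene forest
from the synchronized birth-and-death process (each litter's survivor
count drawn from the event's survival distribution, support 1..r), the
partition of surviving paralog pairs by originating event, and pair
similarities drawn as Binomial(G, p_i)/G for the originating event's
age — the pair-level model, since similarity here is a property of a
pair, not of a sequence.

All randomness flows through a single numpy Generator (PCG64); datasets
are reproducible bit-for-bit from their seed.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass
import numpy as np
import pandas as pd

from .birthdeath import EventSchedule
from .fit import ObservedHistogram
from .mixture import DivergenceParams, similarity_from_age
from .tuples import PairRecord

__all__ = [
    "GeneForest",
    "SimulatedDataset",
    "simulate_forest",
    "count_pairs_by_event",
    "simulate_similarities",
    "simulate_dataset",
]

_RNG_ALGORITHM = "numpy PCG64 (default_rng)"


@dataclass(frozen=True)
class GeneForest:
    """Surviving genes with full multiplication ancestry.

    ``roots[g]`` is gene g's ancestral gene; ``paths[g, i]`` is the
    surviving-sibling slot gene g's lineage took at event i+1.  Two
    genes with the same root form a t_i-pair exactly when their paths
    first differ at event i — every surviving same-root pair has one
    originating event.
    """

    roots: np.ndarray
    paths: np.ndarray
    schedule: EventSchedule
    seed: int | None = None

    @property
    def n_genes(self) -> int:
        return len(self.roots)

    @property
    def n_unpaired(self) -> int:
        _, counts = np.unique(self.roots, return_counts=True)
        return int(np.sum(counts == 1))


def _rng(seed_or_rng) -> np.random.Generator:
    if isinstance(seed_or_rng, np.random.Generator):
        return seed_or_rng
    return np.random.default_rng(seed_or_rng)


def simulate_forest(schedule: EventSchedule, seed=None) -> GeneForest:
    """Run the birth-and-death process forward once."""
    rng = _rng(seed)
    roots = np.arange(schedule.m1, dtype=np.int64)
    paths = np.empty((schedule.m1, 0), dtype=np.int64)
    for i, r in enumerate(schedule.ploidies):
        u = np.asarray(schedule.survival[i], dtype=float)
        j = rng.choice(np.arange(1, r + 1), size=len(roots), p=u / u.sum())
        roots = np.repeat(roots, j)
        paths = np.repeat(paths, j, axis=0)
        starts = np.repeat(np.cumsum(j) - j, j)
        slots = np.arange(int(j.sum()), dtype=np.int64) - starts
        paths = np.column_stack([paths, slots])
    return GeneForest(
        roots=roots,
        paths=paths,
        schedule=schedule,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )


def _group_pair_sum(keys: np.ndarray) -> int:
    _, counts = np.unique(keys, axis=0, return_counts=True)
    return int(np.sum(counts * (counts - 1) // 2))


def count_pairs_by_event(forest: GeneForest) -> np.ndarray:
    """Number of surviving pairs originating at each event.

    A pair's originating event is where its two path prefixes first
    split, so the count at event i is the number of pairs sharing a
    prefix through i-1 minus those still together through i.  Totals
    satisfy sum_i d_i = sum_roots C(k_root, 2).
    """
    n_events = forest.schedule.n_events
    d = np.empty(n_events, dtype=np.int64)
    keys = forest.roots.reshape(-1, 1)
    prev = _group_pair_sum(keys)
    for i in range(n_events):
        keys = np.column_stack([keys, forest.paths[:, i]])
        cur = _group_pair_sum(keys)
        d[i] = prev - cur
        prev = cur
    return d


def _pair_indices(forest: GeneForest) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """All same-root gene index pairs with their originating event (1-based)."""
    order = np.argsort(forest.roots, kind="stable")
    roots = forest.roots[order]
    paths = forest.paths[order]
    ia, ib, ev = [], [], []
    boundaries = np.flatnonzero(np.diff(roots)) + 1
    for grp in np.split(np.arange(len(roots)), boundaries):
        if len(grp) < 2:
            continue
        sub = paths[grp]
        for a, b in itertools.combinations(range(len(grp)), 2):
            ia.append(order[grp[a]])
            ib.append(order[grp[b]])
            ev.append(int(np.argmax(sub[a] != sub[b])) + 1)
    return (
        np.asarray(ia, dtype=np.int64),
        np.asarray(ib, dtype=np.int64),
        np.asarray(ev, dtype=np.int64),
    )


def _gene_names(indices: np.ndarray) -> pd.Series:
    return "g" + pd.Series(indices).astype(str)


def _region_labels(forest: GeneForest) -> tuple[pd.Series, pd.Series]:
    """Synthetic region / region-tuple labels from event lineage.

    Genes sharing a full path (across all roots) lie in the same
    subgenome copy, i.e. the same synthetic region; regions sharing all
    but the last event's slot form one region-tuple of the most recent
    event.  A simulated genome whose last event was a triplication then
    shows the classic signature: high-similarity pairs among the
    regions of a tuple, none within a region or across tuples.
    """
    paths = forest.paths
    region = pd.Series(["R" + "".join(map(str, row)) for row in paths])
    if paths.shape[1] > 1:
        tup = pd.Series(["T" + "".join(map(str, row[:-1])) for row in paths])
    else:
        tup = pd.Series(["T"] * len(paths))
    return region, tup


@dataclass(frozen=True)
class SimulatedDataset:
    """Pair list with similarities, unpaired count and the generating truth."""

    pairs: pd.DataFrame  # gene_a, gene_b, similarity, event, region_a, region_b
    n_genes: int
    n_unpaired: int
    schedule: EventSchedule
    divergence: DivergenceParams
    seed: int | None
    rng_algorithm: str = _RNG_ALGORITHM

    def to_histogram(self, k_min: int = 1, k_max: int = 100) -> ObservedHistogram:
        return ObservedHistogram.from_similarities(
            self.pairs["similarity"].to_numpy(), f_star=self.n_unpaired,
            k_min=k_min, k_max=k_max,
        )

    def pair_records(self) -> list[PairRecord]:
        return [
            PairRecord(
                gene_a=row.gene_a,
                gene_b=row.gene_b,
                similarity=row.similarity,
                region_a=row.region_a,
                region_b=row.region_b,
            )
            for row in self.pairs.itertuples()
        ]

    def region_map(self) -> dict[str, tuple[str, str]]:
        out: dict[str, tuple[str, str]] = {}
        for row in self.pairs.itertuples():
            out[row.gene_a] = (row.region_a, row.tuple_a)
            out[row.gene_b] = (row.region_b, row.tuple_b)
        return out

    def write_pairs_tsv(self, path) -> None:
        self.pairs[["gene_a", "gene_b", "similarity"]].to_csv(
            path, sep="\t", index=False, header=False
        )

    def truth(self) -> dict:
        return {
            "schedule": json.loads(self.schedule.to_json()),
            "lam": self.divergence.lam,
            "G": self.divergence.G,
            "n_genes": self.n_genes,
            "n_unpaired": self.n_unpaired,
            "seed": self.seed,
            "rng_algorithm": self.rng_algorithm,
        }


def simulate_similarities(
    forest: GeneForest, div: DivergenceParams, seed=None
) -> SimulatedDataset:
    """Draw each pair's similarity from Binomial(G, p_i)/G.

    ``p_i`` is the expected identity for the pair's originating event
    age; G is rounded to an integer site count for exact binomial
    sampling.
    """
    rng = _rng(seed)
    schedule = forest.schedule
    G = int(round(div.G))
    if G < 1:
        raise ValueError("G must round to a positive integer site count")
    ia, ib, ev = _pair_indices(forest)
    p_event = np.array(
        [similarity_from_age(div.lam, schedule.event_age(i)) for i in range(1, schedule.n_events + 1)]
    )
    if len(ev):
        sims = rng.binomial(G, p_event[ev - 1]) / G
    else:
        sims = np.empty(0)
    region, tup = _region_labels(forest)
    pairs = pd.DataFrame(
        {
            "gene_a": _gene_names(ia),
            "gene_b": _gene_names(ib),
            "similarity": sims,
            "event": ev,
            "region_a": region.iloc[ia].to_numpy(),
            "region_b": region.iloc[ib].to_numpy(),
            "tuple_a": tup.iloc[ia].to_numpy(),
            "tuple_b": tup.iloc[ib].to_numpy(),
        }
    )
    return SimulatedDataset(
        pairs=pairs,
        n_genes=forest.n_genes,
        n_unpaired=forest.n_unpaired,
        schedule=schedule,
        divergence=div,
        seed=seed if isinstance(seed, (int, np.integer)) else forest.seed,
    )


def simulate_dataset(
    schedule: EventSchedule, div: DivergenceParams, seed=None
) -> SimulatedDataset:
    """Forest plus similarities in one call, from a single seed."""
    rng = _rng(seed)
    forest = simulate_forest(schedule, rng)
    ds = simulate_similarities(forest, div, rng)
    if isinstance(seed, (int, np.integer)):
        object.__setattr__(ds, "seed", int(seed))
    return ds
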