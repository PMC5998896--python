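"""Counting high-similarity pairs, triples and higher tuples.

The ploidy of the most recent multiplication leaves a direct
combinatorial trace that the similarity histogram hides: a recent
triplication produces many *triples* of highly similar genes spread
across the three regions of a region-triple, while a recent duplication
produces pairs but almost no triples.  This module parses self-synteny
pair lists (SynMap-like TSV output), builds the graph of
high-similarity pairs, and reports components by size together with the
region-level signature counts.
"""

from __future__ import annotations

import logging
from bisect import bisect_right
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import networkx as nx

__all__ = [
    "PairRecord",
    "TupleReport",
    "Region",
    "SignatureSummary",
    "read_pairs",
    "read_regions",
    "assign_genes_to_regions",
    "high_similarity_tuples",
    "signature_summary",
    "share_high_similarity",
    "percent_share",
]

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class PairRecord:
    """One paralog pair; gene order is canonical (lexicographic)."""

    gene_a: str
    gene_b: str
    similarity: float
    region_a: str | None = None
    region_b: str | None = None

    def __post_init__(self):
        if self.gene_a == self.gene_b:
            raise ValueError(f"self-pair {self.gene_a!r}")
        if not 0 <= self.similarity <= 1:
            raise ValueError(f"similarity {self.similarity} outside [0, 1]")
        if self.gene_b < self.gene_a:
            a, b = self.gene_a, self.gene_b
            ra, rb = self.region_a, self.region_b
            object.__setattr__(self, "gene_a", b)
            object.__setattr__(self, "gene_b", a)
            object.__setattr__(self, "region_a", rb)
            object.__setattr__(self, "region_b", ra)


def read_pairs(
    path,
    gene_cols: tuple[int, int] = (0, 1),
    similarity_col: int = 2,
    comment: str = "#",
) -> list[PairRecord]:
    """Parse a tab-separated pair list into canonical, deduplicated records.

    Similarity values above 1 are interpreted as percentages.  Duplicate
    rows for one gene pair keep the maximum similarity (logged).  A line
    that cannot be parsed raises with its line number.
    """
    seen: dict[tuple[str, str], float] = {}
    conflicts = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or (comment and line.startswith(comment)):
                continue
            fields = line.split("\t")
            try:
                a = fields[gene_cols[0]].strip()
                b = fields[gene_cols[1]].strip()
                sim = float(fields[similarity_col])
            except (IndexError, ValueError) as e:
                raise ValueError(f"{path}: cannot parse line {lineno}: {line!r}") from e
            if sim > 1.0:
                sim /= 100.0
            if not 0 <= sim <= 1:
                raise ValueError(f"{path}: similarity out of range on line {lineno}")
            if a == b:
                raise ValueError(f"{path}: self-pair on line {lineno}")
            key = (a, b) if a < b else (b, a)
            if key in seen:
                if seen[key] != sim:
                    conflicts += 1
                seen[key] = max(seen[key], sim)
            else:
                seen[key] = sim
    if conflicts:
        logger.info("%s: %d duplicated pairs with conflicting similarity; kept the maximum",
                    path, conflicts)
    return [PairRecord(a, b, s) for (a, b), s in seen.items()]


@dataclass(frozen=True)
class TupleReport:
    """High-similarity component census at one threshold.

    ``components_by_size[k]`` counts connected components of exactly k
    genes in the graph of pairs at or above the threshold.  ``triples``
    are components of exactly 3 genes (hence never part of a larger
    tuple); ``clique_triples`` additionally require all three pairwise
    edges, since a synteny census may or may not demand the third edge.
    """

    threshold: float
    n_pairs_total: int
    n_pairs_high: int
    components_by_size: dict[int, int]
    triples: int
    clique_triples: int
    four_tuples_and_higher: int
    unpaired: int | None = None

    @property
    def pair_components(self) -> int:
        return self.components_by_size.get(2, 0)


def high_similarity_tuples(
    pairs: Sequence[PairRecord],
    threshold: float = 0.81,
    total_genes: int | None = None,
) -> TupleReport:
    """Census of connected components among pairs at/above a threshold.

    When ``total_genes`` is given, ``unpaired`` counts roster genes that
    appear in no input pair at all (at any similarity), matching how an
    unpaired-gene count is derived from a synteny screen.
    """
    if not 0 < threshold <= 1:
        raise ValueError("threshold must lie in (0, 1]")
    graph = nx.Graph()
    genes_in_any_pair: set[str] = set()
    n_high = 0
    for rec in pairs:
        genes_in_any_pair.add(rec.gene_a)
        genes_in_any_pair.add(rec.gene_b)
        if rec.similarity >= threshold:
            graph.add_edge(rec.gene_a, rec.gene_b)
            n_high += 1
    by_size: dict[int, int] = defaultdict(int)
    clique_triples = 0
    for comp in nx.connected_components(graph):
        by_size[len(comp)] += 1
        if len(comp) == 3 and graph.subgraph(comp).number_of_edges() == 3:
            clique_triples += 1
    unpaired = None
    if total_genes is not None:
        if total_genes < len(genes_in_any_pair):
            raise ValueError("total_genes is smaller than the number of genes in pairs")
        unpaired = total_genes - len(genes_in_any_pair)
    return TupleReport(
        threshold=threshold,
        n_pairs_total=len(pairs),
        n_pairs_high=n_high,
        components_by_size=dict(sorted(by_size.items())),
        triples=by_size.get(3, 0),
        clique_triples=clique_triples,
        four_tuples_and_higher=sum(c for k, c in by_size.items() if k >= 4),
        unpaired=unpaired,
    )


# ---------------------------------------------------------------------------
# Region annotations and the multiplication signature
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Region:
    """A syntenic region and the region-tuple it belongs to (0-based half-open)."""

    region_id: str
    tuple_id: str
    chrom: str
    start: int
    end: int


def read_regions(path) -> list[Region]:
    """BED-like TSV: chrom, start, end, region_id, tuple_id."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.split("\t")
            try:
                chrom, start, end, region_id, tuple_id = fields[:5]
                out.append(Region(region_id, tuple_id, chrom, int(start), int(end)))
            except (IndexError, ValueError) as e:
                raise ValueError(f"{path}: cannot parse line {lineno}: {line!r}") from e
    return out


def assign_genes_to_regions(
    regions: Sequence[Region], gene_locations: Mapping[str, tuple[str, int]]
) -> dict[str, tuple[str, str]]:
    """Map genes to (region_id, tuple_id) by genomic position."""
    by_chrom: dict[str, list[tuple[int, int, str, str]]] = defaultdict(list)
    for r in regions:
        by_chrom[r.chrom].append((r.start, r.end, r.region_id, r.tuple_id))
    for intervals in by_chrom.values():
        intervals.sort()
    out: dict[str, tuple[str, str]] = {}
    for gene, (chrom, pos) in gene_locations.items():
        intervals = by_chrom.get(chrom, [])
        i = bisect_right(intervals, (pos, float("inf"), "", "")) - 1
        if i >= 0 and intervals[i][0] <= pos < intervals[i][1]:
            out[gene] = (intervals[i][2], intervals[i][3])
    return out


@dataclass(frozen=True)
class SignatureSummary:
    """High-similarity pair counts sorted into the three signature clauses.

    A recent triplication should show pairs *among* the regions of one
    region-tuple vastly outnumbering pairs *within* a single region and
    pairs *between* different tuples.
    """

    threshold: float
    among_tuple: int
    within_region: int
    cross_tuple: int
    unassigned: int
    ratio_threshold: float

    @property
    def satisfied(self) -> bool:
        return (
            self.among_tuple > 0
            and self.among_tuple >= self.ratio_threshold * self.within_region
            and self.among_tuple >= self.ratio_threshold * self.cross_tuple
        )


def signature_summary(
    pairs: Sequence[PairRecord],
    regions: Mapping[str, tuple[str, str]],
    threshold: float = 0.81,
    ratio_threshold: float = 10.0,
) -> SignatureSummary:
    """Classify high-similarity pairs by region membership.

    ``regions`` maps gene id to (region_id, tuple_id).  Pairs whose
    genes lack an assignment are counted in the ``unassigned`` bucket,
    never dropped.
    """
    among = within = cross = unassigned = 0
    for rec in pairs:
        if rec.similarity < threshold:
            continue
        ra = regions.get(rec.gene_a)
        rb = regions.get(rec.gene_b)
        if ra is None or rb is None:
            unassigned += 1
        elif ra[0] == rb[0]:
            within += 1
        elif ra[1] == rb[1]:
            among += 1
        else:
            cross += 1
    return SignatureSummary(
        threshold=threshold,
        among_tuple=among,
        within_region=within,
        cross_tuple=cross,
        unassigned=unassigned,
        ratio_threshold=ratio_threshold,
    )


def percent_share(qualifying: int, total: int) -> int:
    """Integer-percent share, the reporting convention for pair censuses."""
    if total <= 0:
        raise ValueError("total must be positive")
    if not 0 <= qualifying <= total:
        raise ValueError("qualifying count must lie in [0, total]")
    return int(round(100.0 * qualifying / total))


def share_high_similarity(
    pairs: Sequence[PairRecord],
    threshold: float = 0.81,
    regions: Mapping[str, tuple[str, str]] | None = None,
) -> int:
    """Percent of pairs that are high-similarity (and cross two regions).

    When region information is available — via ``regions`` or labels on
    the records — a qualifying pair must also join two *different*
    regions; without any region information the criterion is similarity
    alone.
    """
    if not pairs:
        raise ValueError("cannot compute a share of an empty pair list")
    qualifying = 0
    for rec in pairs:
        if rec.similarity < threshold:
            continue
        ra, rb = rec.region_a, rec.region_b
        if regions is not None:
            ga = regions.get(rec.gene_a)
            gb = regions.get(rec.gene_b)
            ra = ga[0] if ga else None
            rb = gb[0] if gb else None
            if ra is None or rb is None or ra == rb:
                continue
        elif ra is not None and rb is not None and ra == rb:
            continue
        qualifying += 1
    return percent_share(qualifying, len(pairs))
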