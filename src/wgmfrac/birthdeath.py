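"""Synchronized birth-and-death process with fractionation.

A genome starts with ``m1`` genes at time ``t_1``.  At each event time
``t_i`` (i = 1 .. n-1) every gene is replaced by ``r_i`` progeny
(tetraploidy r=2, hexaploidy r=3, ...), of which at least one and at most
``r_i`` survive until the next time point, with probabilities
``u_1^(i) .. u_{r_i}^(i)``.  Lineages with zero survivors leave no trace
and are excluded by construction.  Observation happens at ``t_n``.

This module provides the probability of an evolutionary history, an
exhaustive enumeration of all histories for small instances (the test
oracle), and closed-form expectations for gene counts, paralog-pair
counts per originating event, and unpaired genes.  Expected values use
linearity of expectation across independent lineages, so they stay cheap
where the naive sum over histories explodes combinatorially.

Event indices are 1-based throughout (event ``i`` happens at time
``t_i``), matching the standard notation for these models.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import dataclass
from math import comb, fsum
from typing import Sequence

from .errors import EnumerationCapError, InvalidHistoryError, ScheduleError

__all__ = [
    "EventSchedule",
    "History",
    "HistoryRecord",
    "PairExpectations",
    "multiplicity_after_event",
    "history_probability",
    "enumerate_histories",
    "enumeration_expectations",
    "expected_gene_count",
    "expected_pairs_created",
    "expected_pairs_observed",
    "expected_unpaired",
    "pair_expectations",
]

_SUM_TOL = 1e-12


@dataclass(frozen=True)
class EventSchedule:
    """Times, ploidies and per-event survival distributions of a model.

    Parameters
    ----------
    times
        Strictly increasing sequence ``t_1 < ... < t_n``; ``t_n`` is the
        observation time.  Units are arbitrary (the divergence rate
        absorbs them).
    ploidies
        ``r_1 .. r_{n-1}``, each an integer >= 2.
    survival
        One probability vector per event; ``survival[i-1][j-1]`` is
        ``u_j^(i)``, the probability that exactly j of the r_i progeny
        survive to the next time point.  Each vector sums to 1.
    m1
        Initial gene count (>= 1).  All expectations scale linearly in
        it; the default 1 gives per-ancestral-gene rates.
    """

    times: tuple[float, ...]
    ploidies: tuple[int, ...]
    survival: tuple[tuple[float, ...], ...]
    m1: int = 1

    def __post_init__(self):
        object.__setattr__(self, "times", tuple(float(t) for t in self.times))
        object.__setattr__(self, "ploidies", tuple(int(r) for r in self.ploidies))
        object.__setattr__(
            self, "survival", tuple(tuple(float(u) for u in v) for v in self.survival)
        )
        n = len(self.times)
        if n < 1:
            raise ScheduleError("need at least one time point")
        if any(b <= a for a, b in zip(self.times, self.times[1:])):
            raise ScheduleError("times must be strictly increasing")
        if len(self.ploidies) != n - 1:
            raise ScheduleError("need exactly n-1 ploidies for n time points")
        if any(r < 2 for r in self.ploidies):
            raise ScheduleError("every ploidy must be an integer >= 2")
        if len(self.survival) != n - 1:
            raise ScheduleError("need one survival vector per event")
        for i, (r, u) in enumerate(zip(self.ploidies, self.survival), start=1):
            if len(u) != r:
                raise ScheduleError(
                    f"survival vector for event {i} must have length r_{i}={r}"
                )
            if any(x < 0 for x in u):
                raise ScheduleError(f"survival probabilities of event {i} must be >= 0")
            if abs(sum(u) - 1.0) > _SUM_TOL:
                raise ScheduleError(f"survival vector of event {i} must sum to 1")
        if int(self.m1) != self.m1 or self.m1 < 1:
            raise ScheduleError("m1 must be an integer >= 1")
        object.__setattr__(self, "m1", int(self.m1))

    @property
    def n(self) -> int:
        """Number of time points (events are 1 .. n-1)."""
        return len(self.times)

    @property
    def n_events(self) -> int:
        return len(self.ploidies)

    def mean_survivors(self, event: int) -> float:
        """Expected number of surviving progeny per gene at ``event``."""
        self._check_event(event)
        u = self.survival[event - 1]
        return fsum((j + 1) * x for j, x in enumerate(u))

    def event_age(self, event: int) -> float:
        """Time elapsed between ``event`` and the observation time t_n."""
        self._check_event(event)
        return self.times[-1] - self.times[event - 1]

    def max_population(self) -> int:
        return self.m1 * math.prod(self.ploidies)

    def _check_event(self, event: int) -> None:
        if not 1 <= event <= self.n_events:
            raise ScheduleError(f"event index must be in 1..{self.n_events}")

    # --- JSON round trip -------------------------------------------------
    def to_json(self) -> str:
        return json.dumps(
            {
                "times": list(self.times),
                "ploidies": list(self.ploidies),
                "survival": [list(v) for v in self.survival],
                "m1": self.m1,
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "EventSchedule":
        try:
            doc = json.loads(text)
        except json.JSONDecodeError as e:
            raise ScheduleError(f"not valid JSON: {e}") from e
        if not isinstance(doc, dict):
            raise ScheduleError("schedule document must be a JSON object")
        missing = {"times", "ploidies", "survival"} - doc.keys()
        if missing:
            raise ScheduleError(f"schedule document missing keys: {sorted(missing)}")
        return cls(
            times=tuple(doc["times"]),
            ploidies=tuple(doc["ploidies"]),
            survival=tuple(tuple(v) for v in doc["survival"]),
            m1=int(doc.get("m1", 1)),
        )


@dataclass(frozen=True)
class History:
    """One evolutionary outcome: ``a[i-1][j-1]`` genes at event i kept j copies."""

    a: tuple[tuple[int, ...], ...]

    def __post_init__(self):
        object.__setattr__(self, "a", tuple(tuple(int(x) for x in v) for v in self.a))
        if not self.a:
            raise InvalidHistoryError("history must cover at least one event")
        for v in self.a:
            if not v or any(x < 0 for x in v):
                raise InvalidHistoryError("survivor counts must be non-negative")

    @property
    def gene_counts(self) -> tuple[int, ...]:
        """Gene counts ``m_i`` at each covered time point (length = events + 1)."""
        m = [sum(self.a[0])]
        for v in self.a:
            m.append(sum((j + 1) * x for j, x in enumerate(v)))
        return tuple(m)

    def validate(self, schedule: EventSchedule, from_event: int = 1) -> None:
        events = range(from_event, from_event + len(self.a))
        if events.stop - 1 > schedule.n_events:
            raise InvalidHistoryError("history covers more events than the schedule")
        for i, v in zip(events, self.a):
            if len(v) != schedule.ploidies[i - 1]:
                raise InvalidHistoryError(
                    f"event {i}: expected {schedule.ploidies[i - 1]} survivor "
                    f"categories, got {len(v)}"
                )
        m = self.gene_counts
        if from_event == 1 and m[0] != schedule.m1:
            raise InvalidHistoryError(
                f"history starts with {m[0]} genes but the schedule has m1={schedule.m1}"
            )
        for i, v in zip(events, self.a):
            if sum(v) != m[i - from_event]:
                raise InvalidHistoryError(f"event {i}: survivor categories do not sum to m_i")


def multiplicity_after_event(a_vector: Sequence[int]) -> int:
    """Gene count after an event from its survivor-category counts.

    ``a_vector[j-1]`` genes kept exactly j copies, so the population
    becomes ``sum_j j * a_j``.  E.g. (2, 1, 1, 1) under a ploidy-4 event
    gives 2*1 + 1*2 + 1*3 + 1*4 = 11 genes.
    """
    a = tuple(int(x) for x in a_vector)
    if not a:
        raise InvalidHistoryError("survivor-count vector is empty")
    if any(x < 0 for x in a):
        raise InvalidHistoryError("survivor counts must be non-negative")
    if all(x == 0 for x in a):
        raise InvalidHistoryError("at least one gene must survive the event")
    return sum((j + 1) * x for j, x in enumerate(a))


def history_probability(
    schedule: EventSchedule,
    history: History,
    from_event: int = 1,
    to_event: int | None = None,
) -> float:
    """Probability of an evolutionary history between two time points.

    The product over events i of a multinomial coefficient
    ``(m_i; a_1 .. a_r)`` and ``prod_j u_j^(i) ** a_j^(i)``.  The full
    range (1, n) gives the probability measure over complete histories.
    """
    if to_event is None:
        to_event = schedule.n
    if not 1 <= from_event < to_event <= schedule.n:
        raise InvalidHistoryError("need 1 <= from_event < to_event <= n")
    if len(history.a) != to_event - from_event:
        raise InvalidHistoryError(
            f"history covers {len(history.a)} events but the range has "
            f"{to_event - from_event}"
        )
    history.validate(schedule, from_event)
    prob = 1.0
    m = sum(history.a[0])
    for i, avec in zip(range(from_event, to_event), history.a):
        u = schedule.survival[i - 1]
        coeff = math.factorial(m)
        for x in avec:
            coeff //= math.factorial(x)
        term = coeff
        for uj, aj in zip(u, avec):
            if aj:
                term *= uj**aj
        prob *= term
        m = sum((j + 1) * x for j, x in enumerate(avec))
    return prob


# ---------------------------------------------------------------------------
# Exhaustive enumeration (the oracle)
# ---------------------------------------------------------------------------

# A single-gene outcome entering event i carries:
#   prob     probability of everything below this gene
#   desc     number of surviving descendants at t_n
#   created  tuple over all events: pairs created at t_{k+1} (d^(k,k+1) terms)
#   observed tuple over all events: descendant pairs at t_n with MRCA at event k
#   avec     tuple over all events of survivor-category count vectors
_Outcome = tuple  # (prob, desc, created, observed, avec)


def _zero_counts(schedule: EventSchedule) -> tuple[tuple[int, ...], ...]:
    return tuple((0,) * r for r in schedule.ploidies)


def _add_vecs(a, b):
    return tuple(tuple(x + y for x, y in zip(va, vb)) for va, vb in zip(a, b))


def _single_gene_outcomes(schedule: EventSchedule, event: int, cache: dict) -> list:
    """All outcomes of one gene entering ``event`` (1-based), recursively."""
    if event in cache:
        return cache[event]
    E = schedule.n_events
    if event > E:
        out = [(1.0, 1, (0,) * E, (0,) * E, _zero_counts(schedule))]
        cache[event] = out
        return out
    r = schedule.ploidies[event - 1]
    u = schedule.survival[event - 1]
    deeper = _single_gene_outcomes(schedule, event + 1, cache)
    out = []
    for j in range(1, r + 1):
        uj = u[j - 1]
        for children in itertools.product(deeper, repeat=j):
            prob = uj
            desc = 0
            created = [0] * E
            observed = [0] * E
            avec = _zero_counts(schedule)
            descs = []
            for cprob, cdesc, ccre, cobs, cavec in children:
                prob *= cprob
                desc += cdesc
                descs.append(cdesc)
                created = [x + y for x, y in zip(created, ccre)]
                observed = [x + y for x, y in zip(observed, cobs)]
                avec = _add_vecs(avec, cavec)
            created[event - 1] += comb(j, 2)
            # pairs whose most recent common multiplication is this event:
            # one member descends from each of two distinct siblings
            cross = (desc * desc - sum(d * d for d in descs)) // 2
            observed[event - 1] += cross
            new_avec = list(list(v) for v in avec)
            new_avec[event - 1][j - 1] += 1
            out.append(
                (prob, desc, tuple(created), tuple(observed), tuple(tuple(v) for v in new_avec))
            )
    cache[event] = out
    return out


def _forest_outcomes(schedule: EventSchedule, gene_cap: int):
    """Exhaustive labeled enumeration over all m1 root lineages."""
    required = schedule.max_population()
    if required > gene_cap:
        raise EnumerationCapError(required, gene_cap)
    roots = _single_gene_outcomes(schedule, 1, {})
    for combo in itertools.product(roots, repeat=schedule.m1):
        prob = 1.0
        desc = 0
        unpaired = 0
        created = (0,) * schedule.n_events
        observed = (0,) * schedule.n_events
        avec = _zero_counts(schedule)
        for cprob, cdesc, ccre, cobs, cavec in combo:
            prob *= cprob
            desc += cdesc
            unpaired += cdesc == 1
            created = tuple(x + y for x, y in zip(created, ccre))
            observed = tuple(x + y for x, y in zip(observed, cobs))
            avec = _add_vecs(avec, cavec)
        yield prob, desc, unpaired, created, observed, avec


@dataclass(frozen=True)
class HistoryRecord:
    """One aggregate history with its probability and pair bookkeeping.

    ``pairs_created[i-1]`` (exact for the history) counts t_i-pairs alive
    at t_{i+1}.  Pair counts at observation time and the unpaired count
    depend on which lineages the later losses hit, which the aggregate
    survivor-category counts do not pin down, so those fields are
    conditional expectations given the history.
    """

    history: History
    probability: float
    m_n: int
    pairs_created: tuple[int, ...]
    expected_pairs_observed: tuple[float, ...]
    expected_unpaired: float


def enumerate_histories(schedule: EventSchedule, gene_cap: int = 12) -> list[HistoryRecord]:
    """Exhaustive, duplicate-free catalogue of aggregate histories.

    Enumerates every labeled forest (each gene's survivor count at each
    event), then groups forests sharing the same survivor-category
    counts ``a_j^(i)``; the grouped probabilities reproduce the
    multinomial history measure.  Refuses instances whose maximal
    population ``m1 * prod(r_i)`` exceeds ``gene_cap``.
    """
    groups: dict = {}
    for prob, desc, unpaired, created, observed, avec in _forest_outcomes(schedule, gene_cap):
        rec = groups.get(avec)
        if rec is None:
            groups[avec] = [prob, desc, created, [p * prob for p in observed], unpaired * prob]
        else:
            rec[0] += prob
            rec[3] = [x + p * prob for x, p in zip(rec[3], observed)]
            rec[4] += unpaired * prob
    out = []
    for avec, (prob, desc, created, obs_w, unp_w) in sorted(groups.items()):
        out.append(
            HistoryRecord(
                history=History(avec),
                probability=prob,
                m_n=desc,
                pairs_created=created,
                expected_pairs_observed=tuple(
                    (x / prob if prob > 0 else 0.0) for x in obs_w
                ),
                expected_unpaired=unp_w / prob if prob > 0 else 0.0,
            )
        )
    return out


def enumeration_expectations(schedule: EventSchedule, gene_cap: int = 12) -> "PairExpectations":
    """Expectations by brute-force enumeration (test oracle, small instances)."""
    probs, m_n, unp = [], [], []
    created = [[] for _ in range(schedule.n_events)]
    observed = [[] for _ in range(schedule.n_events)]
    for prob, desc, unpaired, cre, obs, _ in _forest_outcomes(schedule, gene_cap):
        probs.append(prob)
        m_n.append(prob * desc)
        unp.append(prob * unpaired)
        for k in range(schedule.n_events):
            created[k].append(prob * cre[k])
            observed[k].append(prob * obs[k])
    total = fsum(probs)
    if abs(total - 1.0) > 1e-9:
        raise AssertionError(f"enumeration probabilities sum to {total}, not 1")
    return PairExpectations(
        pairs_created=tuple(fsum(c) for c in created),
        pairs_observed=tuple(fsum(o) for o in observed),
        unpaired=fsum(unp),
        total_genes=fsum(m_n),
    )


# ---------------------------------------------------------------------------
# Closed-form expectations
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PairExpectations:
    """Expected pair counts per originating event, unpaired and total genes."""

    pairs_created: tuple[float, ...]
    pairs_observed: tuple[float, ...]
    unpaired: float
    total_genes: float


def expected_gene_count(
    schedule: EventSchedule,
    from_time: int = 1,
    to_time: int | None = None,
    m_start: float | None = None,
) -> float:
    """Expected gene count at ``t_to`` starting from ``t_from``.

    Linearity of expectation across independent lineages gives
    ``m_start * prod_i E[survivors per gene at event i]``; the brute-force
    sum over histories (Eqs. over the full history measure) agrees
    exactly, without its combinatorial cost.  ``m_start`` defaults to m1
    when starting at t_1 and to 1 (a per-gene rate) otherwise.
    """
    if to_time is None:
        to_time = schedule.n
    if not 1 <= from_time <= to_time <= schedule.n:
        raise ScheduleError("need 1 <= from_time <= to_time <= n")
    if m_start is None:
        m_start = schedule.m1 if from_time == 1 else 1.0
    out = float(m_start)
    for i in range(from_time, to_time):
        out *= schedule.mean_survivors(i)
    return out


def expected_pairs_created(schedule: EventSchedule, event: int) -> float:
    """Expected t_i-pairs alive at t_{i+1}: E(m_i) * sum_{j>=2} C(j,2) u_j^(i)."""
    schedule._check_event(event)
    u = schedule.survival[event - 1]
    per_gene = fsum(comb(j, 2) * u[j - 1] for j in range(2, len(u) + 1))
    return expected_gene_count(schedule, 1, event) * per_gene


def expected_pairs_observed(schedule: EventSchedule, event: int) -> float:
    """Expected t_i-pairs among the genes at observation time t_n.

    Each member of a pair created at event i founds an independent
    lineage, so the pair count is inflated by the squared per-gene
    expected descendant count from t_{i+1} to t_n.
    """
    schedule._check_event(event)
    growth = expected_gene_count(schedule, event + 1, schedule.n, m_start=1.0)
    return expected_pairs_created(schedule, event) * growth**2


def expected_unpaired(schedule: EventSchedule) -> float:
    """Expected genes with no surviving paralog: m1 * prod_i u_1^(i)."""
    out = float(schedule.m1)
    for u in schedule.survival:
        out *= u[0]
    return out


def pair_expectations(schedule: EventSchedule) -> PairExpectations:
    """Closed-form pair/gene expectations for a schedule."""
    events = range(1, schedule.n_events + 1)
    return PairExpectations(
        pairs_created=tuple(expected_pairs_created(schedule, i) for i in events),
        pairs_observed=tuple(expected_pairs_observed(schedule, i) for i in events),
        unpaired=expected_unpaired(schedule),
        total_genes=expected_gene_count(schedule),
    )
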