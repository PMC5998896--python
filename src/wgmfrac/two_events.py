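"""Closed-form algebra for the two competing two-event models.

Two histories that are hard to tell apart from a similarity histogram:

* **dup-first** — a whole-genome duplication at t_1 followed by a
  triplication at t_2, with fractionation parameters
  ``w`` (both t_1 duplicates survive to t_2), ``u`` (all three t_2
  triplicates survive to t_3) and ``v`` (exactly two survive);
* **trip-first** — the triplication precedes the duplication, with
  ``p3``/``p2`` (three / exactly two t_1 triplicates survive to t_2)
  and ``z`` (both t_2 duplicates survive to t_3).

Per ancestral gene, each model yields an observable triple
(expected t_1-pairs, expected t_2-pairs, expected unpaired genes):

    dup-first:  ( (2u+v+1)^2 w,  (3u+v)(1+w),  (1-w)(1-u-v) )
    trip-first: ( (3*p3+p2)(1+z)^2,  z(1+2*p3+p2),  (1-z)(1-p3-p2) )

Because the likelihood of a histogram depends only on this triple (and
the component locations), equating the two triples defines a polynomial
correspondence between the parameter cubes; inside a bounded volume of
the (u, v, w) cube each point has a valid (x, y, z) counterpart with an
*identical* likelihood, which is exactly why ploidy cannot be read off a
similarity histogram alone.

A note on printed symbols: in the source convention for the trip-first
model the equations are consistent only with ``y`` = P(3 survive) and
``x`` = P(2 survive), although the accompanying prose swaps them.  The
types here use the unambiguous names ``p3``/``p2``;
:func:`trip_first_expectations_xy` evaluates the printed formulas
``(x+3y)(1+z)^2`` etc. under the mapping x = p2, y = p3, and the tree
enumeration is the ground truth for both.
"""

from __future__ import annotations

import itertools
import math
from collections import Counter
from dataclasses import dataclass
from math import comb
from typing import Iterable, NamedTuple

import numpy as np
from numpy.polynomial import polynomial as npoly
from scipy.optimize import fsolve

__all__ = [
    "DupFirstParams",
    "TripFirstParams",
    "ExpectationTriple",
    "TreeRecord",
    "Monomial",
    "CorrespondenceRoot",
    "CorrespondenceResult",
    "ConstrainedMatch",
    "ScanResult",
    "dup_first_expectations",
    "trip_first_expectations",
    "trip_first_expectations_xy",
    "enumerate_two_event_trees",
    "catalogue_expectations",
    "correspondence_solve",
    "dup_to_trip",
    "trip_to_dup",
    "valid_region_scan",
    "constrained_reparam",
    "constrained_reparam_inverse",
    "constrained_trip_reparam",
    "constrained_correspondence",
    "constrained_correspondence_inverse",
    "unpaired_difference_grid",
    "unpaired_per_ancestral_gene",
    "unpaired_ratio",
]

_EPS = 1e-6  # boundary epsilon for valid-model classification
_RESIDUAL_TOL = 1e-10


@dataclass(frozen=True)
class DupFirstParams:
    """Fractionation parameters of the duplication-then-triplication model."""

    w: float
    u: float
    v: float

    def __post_init__(self):
        if not 0 < self.w < 1:
            raise ValueError("w must lie in (0, 1)")
        if not 0 < self.u < 1:
            raise ValueError("u must lie in (0, 1)")
        if not 0 <= self.v < 1:
            raise ValueError("v must lie in [0, 1)")
        if not self.u + self.v < 1:
            raise ValueError("u + v must be < 1")


@dataclass(frozen=True)
class TripFirstParams:
    """Fractionation parameters of the triplication-then-duplication model.

    ``p3``/``p2`` are the probabilities that three / exactly two of the
    t_1 triplicates survive; in printed symbols y = p3 and x = p2.
    """

    z: float
    p3: float
    p2: float

    def __post_init__(self):
        if not 0 < self.z < 1:
            raise ValueError("z must lie in (0, 1)")
        if self.p3 < 0 or self.p2 < 0:
            raise ValueError("p3 and p2 must be >= 0")
        if not self.p3 + self.p2 < 1:
            raise ValueError("p3 + p2 must be < 1")


class ExpectationTriple(NamedTuple):
    t1_pairs: float
    t2_pairs: float
    unpaired: float


def dup_first_expectations(params: DupFirstParams) -> ExpectationTriple:
    """Per-ancestral-gene observable triple of the dup-first model."""
    u, v, w = params.u, params.v, params.w
    return ExpectationTriple(
        t1_pairs=(4 * u * u + 4 * u * v + 4 * u + v * v + 2 * v + 1) * w,
        t2_pairs=3 * w * u + w * v + 3 * u + v,
        unpaired=(1 - w) * (1 - u - v),
    )


def trip_first_expectations(params: TripFirstParams) -> ExpectationTriple:
    """Per-ancestral-gene observable triple of the trip-first model."""
    z, p3, p2 = params.z, params.p3, params.p2
    return ExpectationTriple(
        t1_pairs=(3 * p3 + p2) * (1 + z) ** 2,
        t2_pairs=z * (1 + 2 * p3 + p2),
        unpaired=(1 - z) * (1 - p3 - p2),
    )


def trip_first_expectations_xy(x: float, y: float, z: float) -> ExpectationTriple:
    """Printed-symbol form of the trip-first triple (x = p2, y = p3)."""
    return ExpectationTriple(
        t1_pairs=(x + 3 * y) * (1 + z) ** 2,
        t2_pairs=2 * y * z + x * z + z,
        unpaired=(1 - z) * (1 - x - y),
    )


# ---------------------------------------------------------------------------
# Paralog-tree catalogues (the oracle for the closed forms)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Monomial:
    """A probability monomial like 2*w*v*u: integer coefficient and factors."""

    coeff: int
    factors: tuple[tuple[str, int], ...]

    def evaluate(self, values: dict[str, float]) -> float:
        out = float(self.coeff)
        for name, power in self.factors:
            out *= values[name] ** power
        return out

    def __str__(self) -> str:
        parts = [str(self.coeff)] if self.coeff != 1 else []
        for name, power in self.factors:
            parts.append(name if power == 1 else f"{name}^{power}")
        return "*".join(parts) or "1"


@dataclass(frozen=True)
class TreeRecord:
    """One paralog-tree shape with its multiplicity and pair counts."""

    structure: str
    multiplicity: int
    monomial: Monomial
    t1_pairs: int
    t2_pairs: int
    unpaired: int


def _monomial(coeff: int, names: Iterable[str]) -> Monomial:
    counts = Counter(names)
    return Monomial(coeff=coeff, factors=tuple(sorted(counts.items())))


_DUP_FACTOR = {1: "1-u-v", 2: "v", 3: "u"}
_TRIP_FACTOR = {1: "1-x-y", 2: "x", 3: "y"}  # printed symbols: y = P(3 survive)
_Z_FACTOR = {1: "1-z", 2: "z"}


def enumerate_two_event_trees(order: str) -> list[TreeRecord]:
    """Exhaustive catalogue of paralog trees for a two-event model.

    ``order`` is ``"dup_first"`` or ``"trip_first"``.  Each record
    carries the tree shape (survivor counts per surviving t_2 lineage),
    the number of colour-permuted versions of the shape (its
    multiplicity, absorbed into the monomial coefficient), and the
    t_1-pair, t_2-pair and unpaired-gene counts of the shape.  Summing
    count x probability over the catalogue reproduces the closed-form
    expectation triples.
    """
    records = []
    if order == "dup_first":
        # first event: 1 or 2 of the duplicates survive to t_2
        for ks in _survivor_profiles(max_lineages=2, litter_choices=(1, 2, 3)):
            j = len(ks)
            first = ["w"] if j == 2 else ["1-w"]
            mult = _profile_multiplicity(ks)
            names = first + [_DUP_FACTOR[k] for k in ks]
            records.append(
                TreeRecord(
                    structure=f"dup:{'+'.join(map(str, ks))}",
                    multiplicity=mult,
                    monomial=_monomial(mult, names),
                    t1_pairs=_cross_pairs(ks),
                    t2_pairs=sum(comb(k, 2) for k in ks),
                    unpaired=int(j == 1 and ks[0] == 1),
                )
            )
    elif order == "trip_first":
        for ks in _survivor_profiles(max_lineages=3, litter_choices=(1, 2)):
            j = len(ks)
            first = [_TRIP_FACTOR[j]]
            mult = _profile_multiplicity(ks)
            names = first + [_Z_FACTOR[k] for k in ks]
            records.append(
                TreeRecord(
                    structure=f"trip:{'+'.join(map(str, ks))}",
                    multiplicity=mult,
                    monomial=_monomial(mult, names),
                    t1_pairs=_cross_pairs(ks),
                    t2_pairs=sum(comb(k, 2) for k in ks),
                    unpaired=int(j == 1 and ks[0] == 1),
                )
            )
    else:
        raise ValueError("order must be 'dup_first' or 'trip_first'")
    return records


def _survivor_profiles(max_lineages: int, litter_choices: tuple[int, ...]):
    """Sorted survivor-count profiles (k_1 <= ... <= k_j) for j = 1..max."""
    for j in range(1, max_lineages + 1):
        for ks in itertools.combinations_with_replacement(litter_choices, j):
            yield ks


def _profile_multiplicity(ks: tuple[int, ...]) -> int:
    """Number of ordered lineage assignments producing a sorted profile."""
    counts = Counter(ks)
    mult = math.factorial(len(ks))
    for c in counts.values():
        mult //= math.factorial(c)
    return mult


def _cross_pairs(ks: tuple[int, ...]) -> int:
    return sum(a * b for a, b in itertools.combinations(ks, 2))


def _factor_values(order: str, params) -> dict[str, float]:
    if order == "dup_first":
        return {
            "w": params.w,
            "1-w": 1 - params.w,
            "u": params.u,
            "v": params.v,
            "1-u-v": 1 - params.u - params.v,
        }
    return {
        "z": params.z,
        "1-z": 1 - params.z,
        "y": params.p3,
        "x": params.p2,
        "1-x-y": 1 - params.p3 - params.p2,
    }


def catalogue_expectations(order: str, params) -> ExpectationTriple:
    """Expectation triple summed over the tree catalogue (oracle path)."""
    values = _factor_values(order, params)
    t1 = t2 = unp = 0.0
    for rec in enumerate_two_event_trees(order):
        p = rec.monomial.evaluate(values)
        t1 += p * rec.t1_pairs
        t2 += p * rec.t2_pairs
        unp += p * rec.unpaired
    return ExpectationTriple(t1, t2, unp)


# ---------------------------------------------------------------------------
# The correspondence system
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CorrespondenceRoot:
    """One root of the correspondence system with its classification."""

    raw: tuple[complex, complex, complex]
    classification: str  # "valid" | "invalid" | "complex"
    residual: float
    params: object | None = None  # DupFirstParams / TripFirstParams when valid


@dataclass(frozen=True)
class CorrespondenceResult:
    source: object
    roots: tuple[CorrespondenceRoot, ...]

    @property
    def valid(self) -> tuple:
        return tuple(r.params for r in self.roots if r.classification == "valid")


def _trip_residual(triple: ExpectationTriple, x: float, y: float, z: float) -> float:
    got = trip_first_expectations_xy(x, y, z)
    return max(abs(a - b) for a, b in zip(triple, got))


def _dup_residual(triple: ExpectationTriple, u: float, v: float, w: float) -> float:
    got = ExpectationTriple(
        (4 * u * u + 4 * u * v + 4 * u + v * v + 2 * v + 1) * w,
        3 * w * u + w * v + 3 * u + v,
        (1 - w) * (1 - u - v),
    )
    return max(abs(a - b) for a, b in zip(triple, got))


def dup_to_trip(params: DupFirstParams, polish: bool = True) -> CorrespondenceResult:
    """Solve the correspondence for (x, y, z) given a dup-first point.

    Eliminating x and y leaves a quartic in z: with the target triple
    (A, B, C), ``T = x + 3y = A/(1+z)^2``, ``S = x + y = 1 - C/(1-z)``
    and the t_2-pair equation ``z (2 + T + S) = 2B`` combine into

        z [3(1+z)^2(1-z) + A(1-z) - C(1+z)^2] - 2B(1+z)^2(1-z) = 0.

    Real roots are back-substituted, optionally Newton-polished, and
    classified as valid (inside the trip-first parameter region),
    invalid (real but outside), or complex.
    """
    A, B, C = dup_first_expectations(params)
    coeffs = [  # ascending in z
        -2 * B,
        3 + A - C - 2 * B,
        3 - A - 2 * C + 2 * B,
        -3 - C + 2 * B,
        -3.0,
    ]
    roots = []
    for z in npoly.polyroots(coeffs):
        if abs(z.imag) > 1e-8:
            roots.append(
                CorrespondenceRoot(raw=(math.nan, math.nan, z), classification="complex",
                                   residual=math.inf)
            )
            continue
        z = float(z.real)
        if abs(1 - z) < 1e-12 or abs(1 + z) < 1e-12:
            continue
        T = A / (1 + z) ** 2
        S = 1 - C / (1 - z)
        y = (T - S) / 2
        x = (3 * S - T) / 2
        if polish:
            sol, info, ok, _ = fsolve(
                lambda q: np.array(trip_first_expectations_xy(*q)) - np.array([A, B, C]),
                [x, y, z],
                full_output=True,
            )
            if ok == 1:
                x, y, z = map(float, sol)
        residual = _trip_residual(ExpectationTriple(A, B, C), x, y, z)
        valid = (
            residual < _RESIDUAL_TOL
            and _EPS < z < 1 - _EPS
            and x > -1e-12
            and y > -1e-12
            and x + y < 1 - _EPS
        )
        trip = None
        if valid:
            trip = TripFirstParams(z=z, p3=max(y, 0.0), p2=max(x, 0.0))
        roots.append(
            CorrespondenceRoot(
                raw=(x, y, z),
                classification="valid" if valid else "invalid",
                residual=residual,
                params=trip,
            )
        )
    return CorrespondenceResult(source=params, roots=tuple(roots))


def trip_to_dup(params: TripFirstParams, polish: bool = True) -> CorrespondenceResult:
    """Solve the correspondence for (u, v, w) given a trip-first point.

    With target triple (A, B, C) and ``P = 2u+v``, ``Q = 3u+v``,
    ``S = u+v``, the system reduces to ``P = sqrt(A/w) - 1``,
    ``Q = B/(1+w)``, ``S = 1 - C/(1-w)`` and the identity 2P = Q + S;
    squaring out the radical leaves the quintic

        4A(1-w^2)^2 = w [3(1-w^2) + B(1-w) - C(1+w)]^2.

    Squaring can introduce spurious roots; every candidate is filtered
    by the residual of the original three equations.
    """
    A, B, C = trip_first_expectations(params)
    pm = np.array([1.0, 0.0, -1.0])  # 1 - w^2, ascending
    inner = 3 * pm + B * np.array([1.0, -1.0, 0.0]) + (-C) * np.array([1.0, 1.0, 0.0])
    poly = npoly.polysub(
        4 * A * npoly.polymul(pm, pm),
        npoly.polymul(np.array([0.0, 1.0]), npoly.polymul(inner, inner)),
    )
    roots = []
    for w in npoly.polyroots(poly):
        if abs(w.imag) > 1e-8:
            roots.append(
                CorrespondenceRoot(raw=(math.nan, math.nan, w), classification="complex",
                                   residual=math.inf)
            )
            continue
        w = float(w.real)
        if w <= 0 or abs(1 - w) < 1e-12:
            roots.append(
                CorrespondenceRoot(raw=(math.nan, math.nan, w), classification="invalid",
                                   residual=math.inf)
            )
            continue
        P = math.sqrt(A / w) - 1
        Q = B / (1 + w)
        u = Q - P
        v = 3 * P - 2 * Q
        if polish:
            sol, info, ok, _ = fsolve(
                lambda q: np.array(
                    [
                        (4 * q[0] ** 2 + 4 * q[0] * q[1] + 4 * q[0] + q[1] ** 2 + 2 * q[1] + 1)
                        * q[2]
                        - A,
                        3 * q[2] * q[0] + q[2] * q[1] + 3 * q[0] + q[1] - B,
                        (1 - q[2]) * (1 - q[0] - q[1]) - C,
                    ]
                ),
                [u, v, w],
                full_output=True,
            )
            if ok == 1:
                u, v, w = map(float, sol)
        residual = _dup_residual(ExpectationTriple(A, B, C), u, v, w)
        valid = (
            residual < _RESIDUAL_TOL
            and _EPS < w < 1 - _EPS
            and _EPS < u < 1 - _EPS
            and v > -1e-12
            and u + v < 1 - _EPS
        )
        dup = None
        if valid:
            dup = DupFirstParams(w=w, u=u, v=max(v, 0.0))
        roots.append(
            CorrespondenceRoot(
                raw=(u, v, w),
                classification="valid" if valid else "invalid",
                residual=residual,
                params=dup,
            )
        )
    return CorrespondenceResult(source=params, roots=tuple(roots))


def correspondence_solve(source) -> CorrespondenceResult:
    """Dispatch on the source model's parameter type."""
    if isinstance(source, DupFirstParams):
        return dup_to_trip(source)
    if isinstance(source, TripFirstParams):
        return trip_to_dup(source)
    raise TypeError("source must be DupFirstParams or TripFirstParams")


@dataclass(frozen=True)
class ScanResult:
    """Classification lattice over the valid dup-first parameter region."""

    points: np.ndarray  # (N, 3) columns u, v, w
    has_counterpart: np.ndarray  # (N,) bool
    step: float

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "u": self.points[:, 0],
                "v": self.points[:, 1],
                "w": self.points[:, 2],
                "has_counterpart": self.has_counterpart,
            }
        )


def valid_region_scan(grid_step: float = 0.01, polish: bool = False) -> ScanResult:
    """Label each valid (u, v, w) lattice point by counterpart existence.

    The region with a valid trip-first counterpart is strictly smaller
    than the valid cube — the volume between the bounding sheets where
    the two models are genuinely indistinguishable by likelihood.
    """
    if not 0 < grid_step <= 0.1:
        raise ValueError("grid_step must lie in (0, 0.1]")
    axis = np.arange(grid_step, 1.0 - grid_step / 2, grid_step)
    v_axis = np.arange(0.0, 1.0 - grid_step / 2, grid_step)
    points = []
    labels = []
    for u in axis:
        for v in v_axis:
            if u + v >= 1:
                continue
            for w in axis:
                params = DupFirstParams(w=float(w), u=float(u), v=float(v))
                res = dup_to_trip(params, polish=polish)
                points.append((u, v, w))
                labels.append(len(res.valid) > 0)
    return ScanResult(
        points=np.array(points), has_counterpart=np.array(labels, dtype=bool), step=grid_step
    )


# ---------------------------------------------------------------------------
# Constrained one-parameter fractionation
# ---------------------------------------------------------------------------


def _ds(s: float) -> float:
    return 3.0 * (1.0 - s) + s * s


def constrained_reparam(s: float) -> tuple[float, float]:
    """(u, v) of a triplication whose copies survive i.i.d. with probability s.

    Conditioning three independent survivals on at least one survivor
    gives u = s^2/(3(1-s)+s^2) and v = 3s(1-s)/(3(1-s)+s^2).
    """
    if not 0 < s < 1:
        raise ValueError("s must lie in (0, 1)")
    d = _ds(s)
    return s * s / d, 3 * s * (1 - s) / d


def constrained_reparam_inverse(u: float, v: float) -> float:
    """Recover s from a (u, v) pair on the constrained curve."""
    if u <= 0 or v < 0:
        raise ValueError("need u > 0 and v >= 0")
    s = 3 * u / (v + 3 * u)
    uu, vv = constrained_reparam(s) if 0 < s < 1 else (math.nan, math.nan)
    if not (abs(uu - u) < 1e-9 and abs(vv - v) < 1e-9):
        raise ValueError("(u, v) does not lie on the constrained curve")
    return s


def constrained_trip_reparam(h: float) -> tuple[float, float]:
    """(p3, p2) for the constrained trip-first model with per-copy survival h."""
    if not 0 < h < 1:
        raise ValueError("h must lie in (0, 1)")
    d = _ds(h)
    return h * h / d, 3 * h * (1 - h) / d


def _constrained_dup_triple(s: float, w: float) -> ExpectationTriple:
    d = _ds(s)
    return ExpectationTriple(
        t1_pairs=9 * w / d**2,
        t2_pairs=3 * s * (1 + w) / d,
        unpaired=3 * (1 - w) * (1 - s) ** 2 / d,
    )


def _constrained_trip_triple(h: float, z: float) -> ExpectationTriple:
    d = _ds(h)
    return ExpectationTriple(
        t1_pairs=3 * h * (1 + z) ** 2 / d,
        t2_pairs=3 * z / d,
        unpaired=3 * (1 - z) * (1 - h) ** 2 / d,
    )


@dataclass(frozen=True)
class ConstrainedMatch:
    """A matched constrained point and its unpaired-gene disagreement.

    ``valid`` marks whether the matched (h, z) lies inside the open unit
    square; outside a bounded region of (s, w) the algebraic branch
    strays past z = 1, in which case the match is still the analytic
    continuation used for the difference surface but not a probability
    model.
    """

    s: float
    w: float
    h: float
    z: float
    unpaired_difference: float
    residual: float
    valid: bool = True


def constrained_correspondence(s: float, w: float, polish: bool = True) -> ConstrainedMatch:
    """Map a constrained dup-first point (s, w) to its trip-first twin (h, z).

    Matching the two pair expectations (the first two correspondence
    equations; with only two parameters per model the third cannot also
    be imposed) gives ``h = A z / (B (1+z)^2)`` and the quintic

        3 B^2 (1+z)^4 - 3 A B z (1+z)^2 + A^2 z^2 - 3 B z (1+z)^4 = 0

    with A, B the dup-first t_1- and t_2-pair expectations.  The
    returned ``unpaired_difference`` (dup-first minus trip-first
    expected unpaired genes) is generally nonzero — the lever that
    breaks the likelihood tie between the models.  Raises when no real
    positive root exists at all.
    """
    if not (0 < s < 1 and 0 < w < 1):
        raise ValueError("(s, w) must lie in (0, 1)^2")
    A, B, _ = _constrained_dup_triple(s, w)
    p4 = np.array([1.0, 4.0, 6.0, 4.0, 1.0])  # (1+z)^4 ascending
    coeffs = 3 * B * B * np.append(p4, 0.0)
    coeffs = coeffs - 3 * A * B * np.array([0.0, 1.0, 2.0, 1.0, 0.0, 0.0])
    coeffs = coeffs + A * A * np.array([0.0, 0.0, 1.0, 0.0, 0.0, 0.0])
    coeffs = coeffs - 3 * B * np.concatenate([[0.0], p4])
    best = None
    for z in npoly.polyroots(coeffs):
        if abs(z.imag) > 1e-8:
            continue
        z = float(z.real)
        if z <= 0:
            continue
        h = A * z / (B * (1 + z) ** 2)
        if h <= 0:
            continue
        resid = _constrained_residual(A, B, h, z)
        inside = 0 < z < 1 and 0 < h < 1
        key = (not inside, resid)
        if best is None or key < best[0]:
            best = (key, h, z, resid, inside)
    if best is None:
        raise RuntimeError(
            f"no real constrained counterpart found for (s, w)=({s}, {w})"
        )
    _, h, z, resid, inside = best
    if polish:
        sol, info, ok, _ = fsolve(
            lambda q: [
                _constrained_trip_triple(q[0], q[1]).t1_pairs - A,
                _constrained_trip_triple(q[0], q[1]).t2_pairs - B,
            ],
            [h, z],
            full_output=True,
        )
        if ok == 1 and sol[0] > 0 and sol[1] > 0:
            h, z = map(float, sol)
            resid = _constrained_residual(A, B, h, z)
            inside = 0 < z < 1 and 0 < h < 1
    diff = _constrained_dup_triple(s, w).unpaired - _constrained_trip_triple(h, z).unpaired
    return ConstrainedMatch(
        s=s, w=w, h=h, z=z, unpaired_difference=diff, residual=resid, valid=inside
    )


def _constrained_residual(A: float, B: float, h: float, z: float) -> float:
    got = _constrained_trip_triple(h, z)
    return max(abs(got.t1_pairs - A), abs(got.t2_pairs - B))


def constrained_correspondence_inverse(h: float, z: float, polish: bool = True) -> tuple[float, float]:
    """Recover the constrained dup-first point (s, w) matching (h, z).

    Accepts z >= 1 so the analytic continuation returned by the forward
    map round-trips.
    """
    if not (0 < h < 1 and z > 0):
        raise ValueError("need h in (0, 1) and z > 0")
    A, B, _ = _constrained_trip_triple(h, z)
    # A s (3 - 3s + s^2)^2 - 3 B (3 - 3s + s^2) + 9 s = 0
    ds = np.array([3.0, -3.0, 1.0])
    ds2 = npoly.polymul(ds, ds)
    poly = A * npoly.polymul(np.array([0.0, 1.0]), ds2) - 3 * B * np.pad(ds, (0, 3)) + np.array(
        [0.0, 9.0, 0.0, 0.0, 0.0, 0.0]
    )
    best = None
    for s in npoly.polyroots(poly):
        if abs(s.imag) > 1e-8:
            continue
        s = float(s.real)
        if not 0 < s < 1:
            continue
        w = B * _ds(s) / (3 * s) - 1
        if w <= 0:
            continue
        got = _constrained_dup_triple(s, w)
        resid = max(abs(got.t1_pairs - A), abs(got.t2_pairs - B))
        key = (not w < 1, resid)
        if best is None or key < (not best[1] < 1, best[2]):
            best = (s, w, resid)
    if best is None:
        raise RuntimeError(f"no constrained dup-first point matches (h, z)=({h}, {z})")
    s, w, _ = best
    if polish:
        sol, info, ok, _ = fsolve(
            lambda q: [
                _constrained_dup_triple(q[0], q[1]).t1_pairs - A,
                _constrained_dup_triple(q[0], q[1]).t2_pairs - B,
            ],
            [s, w],
            full_output=True,
        )
        if ok == 1 and 0 < sol[0] < 1 and 0 < sol[1] < 1:
            s, w = map(float, sol)
    return s, w


def unpaired_difference_grid(
    grid_step: float = 0.01,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Unpaired-gene disagreement between matched constrained models.

    Returns meshgrid arrays (S, W, D): D[i, j] is the dup-first minus
    trip-first expected unpaired genes at the matched pair for
    (s, w) = (S[i, j], W[i, j]).  Its zero contour is the only locus
    where the two constrained models agree on unpaired genes.
    """
    axis = np.arange(grid_step, 1.0, grid_step)
    S, W = np.meshgrid(axis, axis, indexing="ij")
    D = np.empty_like(S)
    for i in range(S.shape[0]):
        for j in range(S.shape[1]):
            D[i, j] = constrained_correspondence(
                float(S[i, j]), float(W[i, j]), polish=False
            ).unpaired_difference
    return S, W, D


def unpaired_per_ancestral_gene(order: str, params) -> float:
    """Expected currently-unpaired genes per ancestral gene for a model."""
    if order == "dup_first":
        return dup_first_expectations(params).unpaired
    if order == "trip_first":
        return trip_first_expectations(params).unpaired
    raise ValueError("order must be 'dup_first' or 'trip_first'")


def unpaired_ratio(observed_unpaired: float, ancestral_genes: float) -> float:
    """Observed unpaired genes per assumed ancestral gene (the diagnostic)."""
    if ancestral_genes <= 0:
        raise ValueError("ancestral gene count must be positive")
    if observed_unpaired < 0:
        raise ValueError("observed unpaired count must be >= 0")
    return observed_unpaired / ancestral_genes
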