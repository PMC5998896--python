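"""Predicted paralog-similarity distributions.

Under a Jukes-Cantor substitution process, the expected proportion of
identical sites between two paralogs that diverged an age ``t`` ago is
``p = 1/4 + (3/4) exp(-lambda t)``, decaying from 1 toward the
saturation value 1/4.  For an effective gene length of ``G`` sites the
observed similarity of one pair is Binomial(G, p)/G, approximated by a
normal with mean ``p`` and variance ``p(1-p)/G``.

A multiplication/fractionation schedule then predicts a mixture: each
event contributes a normal component weighted by its expected surviving
pair count at observation time, plus an atom of unpaired genes.  The
mixture is discretized onto percent-similarity bins by normal-CDF
differences, with tail mass folded into the edge bins, so the binned
vector together with the unpaired atom is an exact probability vector.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm

from .birthdeath import EventSchedule, expected_pairs_observed, expected_unpaired

__all__ = [
    "DivergenceParams",
    "MixtureComponent",
    "PredictedDistribution",
    "similarity_from_age",
    "age_from_similarity",
    "component_moments",
    "components",
    "default_bins",
    "predict_distribution",
]


@dataclass(frozen=True)
class DivergenceParams:
    """Divergence rate ``lam`` (per unit time) and effective gene length ``G``."""

    lam: float
    G: float

    def __post_init__(self):
        if not self.lam > 0:
            raise ValueError("divergence rate lam must be > 0")
        if not self.G > 0:
            raise ValueError("gene length G must be > 0")


def similarity_from_age(lam: float, t: float) -> float:
    """Expected site identity of a pair that diverged ``t`` time units ago."""
    if t < 0:
        raise ValueError("age must be >= 0")
    if lam <= 0:
        raise ValueError("divergence rate must be > 0")
    return 0.25 + 0.75 * math.exp(-lam * t)


def age_from_similarity(lam: float, p: float) -> float:
    """Invert the similarity decay: the age at which identity equals ``p``."""
    if not 0.25 < p <= 1.0:
        raise ValueError("similarity must lie in (1/4, 1]")
    return math.log(3.0 / (4.0 * p - 1.0)) / lam


def component_moments(p: float, G: float) -> tuple[float, float]:
    """Mean and standard deviation of one similarity component.

    Proportion scale: mean ``p``, sd ``sqrt(p(1-p)/G)`` — the moments of
    Binomial(G, p)/G.
    """
    if not 0 < p <= 1:
        raise ValueError("p must lie in (0, 1]")
    if not G > 0:
        raise ValueError("G must be > 0")
    return p, math.sqrt(p * (1.0 - p) / G)


@dataclass(frozen=True)
class MixtureComponent:
    """One event's similarity component: location, spread and pair weight."""

    event: int
    p: float
    mean: float
    sd: float
    weight: float


def components(schedule: EventSchedule, div: DivergenceParams) -> list[MixtureComponent]:
    """Per-event mixture components for a schedule.

    Component ``i`` sits at ``p_i = 1/4 + 3/4 exp(-lam * (t_n - t_i))``
    and carries weight equal to the expected number of t_i-pairs among
    the observed genes.
    """
    out = []
    for i in range(1, schedule.n_events + 1):
        p = similarity_from_age(div.lam, schedule.event_age(i))
        mean, sd = component_moments(p, div.G)
        out.append(
            MixtureComponent(
                event=i, p=p, mean=mean, sd=sd, weight=expected_pairs_observed(schedule, i)
            )
        )
    return out


def default_bins(k_min: int = 1, k_max: int = 100) -> np.ndarray:
    """Integer-percent bin edges: bin k covers [k - 0.5, k + 0.5)."""
    return np.arange(k_min - 0.5, k_max + 0.6, 1.0)


@dataclass(frozen=True)
class PredictedDistribution:
    """Binned similarity probabilities ``q`` plus the unpaired atom ``q_star``."""

    edges: np.ndarray
    q: np.ndarray
    q_star: float

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.edges[:-1] + self.edges[1:])

    def to_csv(self, path) -> None:
        import pandas as pd

        rows = pd.DataFrame({"bin_center": self.centers, "q": self.q})
        rows = pd.concat(
            [rows, pd.DataFrame({"bin_center": ["unpaired"], "q": [self.q_star]})],
            ignore_index=True,
        )
        rows.to_csv(path, index=False)


def _bin_masses(mean_pct: float, sd_pct: float, edges: np.ndarray) -> np.ndarray:
    """Normal mass per bin, tails folded into the edge bins (total mass 1)."""
    if sd_pct == 0.0:
        masses = np.zeros(len(edges) - 1)
        k = int(np.clip(np.searchsorted(edges, mean_pct, side="right") - 1, 0, len(masses) - 1))
        masses[k] = 1.0
        return masses
    cdf = norm.cdf(edges, loc=mean_pct, scale=sd_pct)
    masses = np.diff(cdf)
    masses[0] += cdf[0]
    masses[-1] += 1.0 - cdf[-1]
    return masses


def predict_distribution(
    schedule: EventSchedule,
    div: DivergenceParams,
    bins: np.ndarray | None = None,
) -> PredictedDistribution:
    """Predict the binned similarity distribution plus unpaired-gene mass.

    The relative frequencies are the event pair weights and the expected
    unpaired count, jointly normalized, so ``q_star + sum(q) == 1``.
    Warns (but proceeds) when a component presses against 100% identity
    closely enough that the normal approximation to the binomial is
    visibly truncated.
    """
    edges = default_bins() if bins is None else np.asarray(bins, dtype=float)
    if edges.ndim != 1 or len(edges) < 2 or np.any(np.diff(edges) <= 0):
        raise ValueError("bins must be a strictly increasing 1-D edge array")
    comps = components(schedule, div)
    m_star = expected_unpaired(schedule)
    total = m_star + sum(c.weight for c in comps)
    q = np.zeros(len(edges) - 1)
    for c in comps:
        if c.p < 1.0 and c.mean * 100 + 2 * c.sd * 100 > edges[-1]:
            warnings.warn(
                f"component at p={c.p:.4f} presses against the upper bin edge; "
                "the normal approximation to the binomial is degraded",
                stacklevel=2,
            )
        q += c.weight * _bin_masses(c.mean * 100.0, c.sd * 100.0, edges)
    return PredictedDistribution(edges=edges, q=q / total, q_star=m_star / total)
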