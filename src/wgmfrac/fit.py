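"""Multinomial maximum-likelihood fitting of similarity histograms.

The data are integer-percent binned pair-similarity counts ``f(k)``,
optionally with an unpaired-gene count ``f*``.  A model template fixes
the number of events and their ploidies; the free parameters are the
per-event expected similarities ``p_i`` (ordered, oldest smallest), the
per-event fractionation parameters, and the effective gene length G.
The log-likelihood (up to an additive constant) is

    f* log q* + sum_k f(k) log q(k),

with ``(q, q*)`` the model's predicted relative frequencies.  Because
the likelihood depends on the parameters only through ``(q, q*)``, fits
of models with different event ploidies can land on ridges of equal
likelihood; ``fit_mle`` therefore runs a seeded multi-start bounded
optimizer and reports *all* local optima within a small log-likelihood
band of the best, instead of a single point.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .birthdeath import EventSchedule
from .errors import BinMismatchError, FitError
from .mixture import (
    DivergenceParams,
    PredictedDistribution,
    age_from_similarity,
    predict_distribution,
)

__all__ = [
    "ObservedHistogram",
    "ModelTemplate",
    "Optimum",
    "FitResult",
    "log_likelihood",
    "fit_mle",
    "standard_errors",
    "binomial_survival",
]

_BIG = 1e12


@dataclass(frozen=True)
class ObservedHistogram:
    """Integer-percent similarity counts ``f(k)`` for k in [k_min, k_max].

    ``f_star`` is the unpaired-gene count; when absent the unpaired term
    is excluded from the likelihood and the pair bins are renormalized.
    """

    k_min: int
    k_max: int
    counts: np.ndarray
    f_star: int | None = None
    bin_width: float = 1.0

    def __post_init__(self):
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "counts", counts)
        if self.k_min > self.k_max:
            raise ValueError("k_min must be <= k_max")
        if len(counts) != self.k_max - self.k_min + 1:
            raise ValueError("counts length must match k_min..k_max")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if self.f_star is not None and self.f_star < 0:
            raise ValueError("f_star must be non-negative")

    @property
    def ks(self) -> np.ndarray:
        return np.arange(self.k_min, self.k_max + 1)

    @property
    def n_pairs(self) -> float:
        return float(self.counts.sum())

    @classmethod
    def from_similarities(
        cls,
        similarities: Sequence[float],
        f_star: int | None = None,
        k_min: int = 1,
        k_max: int = 100,
    ) -> "ObservedHistogram":
        """Bin raw similarity proportions into integer-percent bins.

        Values land in bin ``k = round(100 * s)``; anything outside
        [k_min, k_max] is dropped (the trimming used to exclude noise at
        the low end and heterozygosity artifacts at the high end).
        """
        k = np.rint(np.asarray(similarities, dtype=float) * 100.0).astype(int)
        k = k[(k >= k_min) & (k <= k_max)]
        counts = np.bincount(k - k_min, minlength=k_max - k_min + 1)
        return cls(k_min=k_min, k_max=k_max, counts=counts, f_star=f_star)

    def to_csv(self, path) -> None:
        rows = pd.DataFrame({"k": self.ks, "count": self.counts.astype(int)})
        if self.f_star is not None:
            rows = pd.concat(
                [rows, pd.DataFrame({"k": ["unpaired"], "count": [self.f_star]})],
                ignore_index=True,
            )
        rows.to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "ObservedHistogram":
        rows = pd.read_csv(path, dtype={"k": str})
        star = rows[rows["k"] == "unpaired"]
        f_star = int(star["count"].iloc[0]) if len(star) else None
        rows = rows[rows["k"] != "unpaired"]
        ks = rows["k"].astype(int).to_numpy()
        order = np.argsort(ks)
        ks, counts = ks[order], rows["count"].to_numpy()[order]
        if np.any(np.diff(ks) != 1):
            raise ValueError("histogram bins must be consecutive integers")
        return cls(k_min=int(ks[0]), k_max=int(ks[-1]), counts=counts, f_star=f_star)


def log_likelihood(
    hist: ObservedHistogram,
    pred: PredictedDistribution,
    renormalize_pairs: bool | None = None,
    floor: float = 0.0,
) -> float:
    """Multinomial log-likelihood of a predicted distribution (constant dropped).

    ``renormalize_pairs`` defaults to True exactly when the histogram has
    no unpaired count, in which case ``q`` is renormalized over the pair
    bins and the ``q*`` term is dropped.  A bin with observations but
    zero predicted mass yields ``-inf``; the optimizer instead passes a
    tiny ``floor`` so far-off starts see a steep but finite surface.
    """
    centers = pred.centers
    idx = np.searchsorted(centers, hist.ks - 1e-9)
    if np.any(idx >= len(centers)) or np.any(np.abs(centers[np.minimum(idx, len(centers) - 1)] - hist.ks) > 1e-6):
        raise BinMismatchError(
            f"predicted bins do not cover histogram bins {hist.k_min}..{hist.k_max}"
        )
    q = pred.q[idx]
    q_star = pred.q_star
    if floor > 0:
        q = np.maximum(q, floor)
        q_star = max(q_star, floor)
    if renormalize_pairs is None:
        renormalize_pairs = hist.f_star is None
    ll = 0.0
    if renormalize_pairs:
        total = q.sum()
        if total <= 0:
            return -math.inf
        q = q / total
    else:
        if hist.f_star:
            if q_star <= 0:
                return -math.inf
            ll += hist.f_star * math.log(q_star)
    pos = hist.counts > 0
    if np.any(q[pos] <= 0):
        return -math.inf
    ll += float(np.sum(hist.counts[pos] * np.log(q[pos])))
    return ll


# ---------------------------------------------------------------------------
# Model templates and the parameter map
# ---------------------------------------------------------------------------


def binomial_survival(r: int, s: float) -> tuple[float, ...]:
    """Per-litter survival vector from a single per-copy parameter.

    Each of the r copies survives independently with probability ``s``,
    conditioned on at least one survivor:
    ``u_j = C(r,j) s^j (1-s)^(r-j) / (1 - (1-s)^r)``.  For r = 3 this is
    the one-parameter fractionation law u = s^2/(3(1-s)+s^2),
    v = 3s(1-s)/(3(1-s)+s^2).
    """
    if not 0 < s < 1:
        raise ValueError("per-copy survival must lie in (0, 1)")
    denom = 1.0 - (1.0 - s) ** r
    return tuple(math.comb(r, j) * s**j * (1 - s) ** (r - j) / denom for j in range(1, r + 1))


@dataclass(frozen=True)
class ModelTemplate:
    """Fixed structure of a fit: event ploidies and survival parametrization.

    ``survival_modes[i]`` is ``"free"`` (full survival vector; one
    parameter for ploidy 2, a stick-breaking pair for ploidy 3) or
    ``"binomial"`` (single per-copy survival parameter).  ``fixed`` pins
    named natural parameters, e.g. ``{"G": 1000.0}`` or ``{"p1": 0.7}``.
    """

    ploidies: tuple[int, ...]
    survival_modes: tuple[str, ...] = ()
    fixed: Mapping[str, float] = field(default_factory=dict)
    p_bounds: tuple[float, float] = (0.2501, 0.995)
    G_bounds: tuple[float, float] = (10.0, 1e5)

    def __post_init__(self):
        object.__setattr__(self, "ploidies", tuple(int(r) for r in self.ploidies))
        modes = self.survival_modes or ("free",) * len(self.ploidies)
        if len(modes) != len(self.ploidies):
            raise ValueError("need one survival mode per event")
        for m in modes:
            if m not in ("free", "binomial"):
                raise ValueError(f"unknown survival mode {m!r}")
        object.__setattr__(self, "survival_modes", tuple(modes))
        object.__setattr__(self, "fixed", dict(self.fixed))

    @property
    def n_events(self) -> int:
        return len(self.ploidies)

    # -- internal optimization-space layout -------------------------------
    def _param_layout(self) -> list[tuple[str, tuple[float, float]]]:
        eps = 1e-4
        layout: list[tuple[str, tuple[float, float]]] = []
        for i, (r, mode) in enumerate(zip(self.ploidies, self.survival_modes), start=1):
            if mode == "binomial":
                if f"s_e{i}" not in self.fixed:
                    layout.append((f"s_e{i}", (eps, 1 - eps)))
            elif r == 2:
                if f"u2_e{i}" not in self.fixed:
                    layout.append((f"u2_e{i}", (eps, 1 - eps)))
            elif r == 3:
                fixed_here = f"u2_e{i}" in self.fixed and f"u3_e{i}" in self.fixed
                if (f"u2_e{i}" in self.fixed) != (f"u3_e{i}" in self.fixed):
                    raise ValueError(f"fix both u2_e{i} and u3_e{i} or neither")
                if not fixed_here:
                    layout.append((f"stick_total_e{i}", (eps, 1 - eps)))
                    layout.append((f"stick_top_e{i}", (eps, 1 - eps)))
            else:
                raise NotImplementedError(
                    "free survival mode is implemented for ploidies 2 and 3; "
                    "use the binomial mode for higher ploidies"
                )
        if "p1" not in self.fixed:
            layout.append(("p1", self.p_bounds))
        for i in range(2, self.n_events + 1):
            if f"p{i}" not in self.fixed:
                layout.append((f"dp{i}", (1e-4, 0.74)))
        if "G" not in self.fixed:
            layout.append(("log10G", tuple(math.log10(b) for b in self.G_bounds)))
        return layout

    def natural_params(self, x: np.ndarray) -> dict[str, float]:
        """Map an optimization vector to named natural parameters."""
        vals = dict(zip((name for name, _ in self._param_layout()), x))
        out: dict[str, float] = {}
        for i, (r, mode) in enumerate(zip(self.ploidies, self.survival_modes), start=1):
            if mode == "binomial":
                out[f"s_e{i}"] = self.fixed.get(f"s_e{i}", vals.get(f"s_e{i}"))
            elif r == 2:
                out[f"u2_e{i}"] = self.fixed.get(f"u2_e{i}", vals.get(f"u2_e{i}"))
            else:
                if f"u2_e{i}" in self.fixed:
                    out[f"u2_e{i}"] = self.fixed[f"u2_e{i}"]
                    out[f"u3_e{i}"] = self.fixed[f"u3_e{i}"]
                else:
                    total = vals[f"stick_total_e{i}"]
                    top = vals[f"stick_top_e{i}"]
                    out[f"u3_e{i}"] = total * top
                    out[f"u2_e{i}"] = total * (1 - top)
        p = self.fixed.get("p1", vals.get("p1"))
        out["p1"] = p
        for i in range(2, self.n_events + 1):
            if f"p{i}" in self.fixed:
                p = self.fixed[f"p{i}"]
            else:
                p = min(p + vals[f"dp{i}"], 0.9999)
            out[f"p{i}"] = p
        out["G"] = self.fixed.get("G", 10 ** vals.get("log10G", math.nan))
        return out

    def build_model(self, params: Mapping[str, float]) -> tuple[EventSchedule, DivergenceParams]:
        """Schedule and divergence parameters from natural parameter values.

        The rate and the times enter only through the products
        ``lam * (t_n - t_i)``, so the canonical parametrization fixes
        lam = 1 and recovers event ages by inverting the similarity
        decay at each ``p_i``.
        """
        ages = [age_from_similarity(1.0, params[f"p{i}"]) for i in range(1, self.n_events + 1)]
        t_n = ages[0]
        times = [t_n - a for a in ages] + [t_n]
        survival = []
        for i, (r, mode) in enumerate(zip(self.ploidies, self.survival_modes), start=1):
            if mode == "binomial":
                survival.append(binomial_survival(r, params[f"s_e{i}"]))
            elif r == 2:
                u2 = params[f"u2_e{i}"]
                survival.append((1.0 - u2, u2))
            else:
                u2, u3 = params[f"u2_e{i}"], params[f"u3_e{i}"]
                survival.append((1.0 - u2 - u3, u2, u3))
        schedule = EventSchedule(
            times=tuple(times), ploidies=self.ploidies, survival=tuple(survival)
        )
        return schedule, DivergenceParams(lam=1.0, G=params["G"])


@dataclass(frozen=True)
class Optimum:
    params: dict[str, float]
    x: np.ndarray
    log_likelihood: float
    converged: bool
    trajectory: tuple[float, ...]


@dataclass(frozen=True)
class FitResult:
    """All near-best local optima of a multi-start fit, best first."""

    optima: tuple[Optimum, ...]
    template: ModelTemplate
    seed: int

    @property
    def best(self) -> Optimum:
        return self.optima[0]

    @property
    def log_likelihood(self) -> float:
        return self.best.log_likelihood


def _objective(template: ModelTemplate, hist: ObservedHistogram):
    import warnings as _warnings

    def nll(x: np.ndarray) -> float:
        try:
            params = template.natural_params(x)
            with _warnings.catch_warnings():
                _warnings.simplefilter("ignore")
                schedule, div = template.build_model(params)
                pred = predict_distribution(schedule, div)
            ll = log_likelihood(hist, pred, floor=1e-300)
        except (ValueError, FloatingPointError):
            return _BIG
        if not math.isfinite(ll):
            return _BIG
        return -ll

    return nll


def fit_mle(
    hist: ObservedHistogram,
    template: ModelTemplate,
    *,
    seed: int = 0,
    n_starts: int = 50,
    extra_starts: Sequence[Mapping[str, float]] | None = None,
    keep_within: float = 0.01,
    maxiter: int = 500,
) -> FitResult:
    """Seeded multi-start bounded maximum-likelihood fit.

    Runs ``n_starts`` L-BFGS-B starts drawn uniformly inside the bounds
    (plus any ``extra_starts`` given as natural-parameter dicts, e.g.
    points mapped across the two-event model correspondence), polishes
    the best candidates with Nelder-Mead, and returns every distinct
    local optimum whose log-likelihood is within ``keep_within`` of the
    best — surfacing the underdetermination ridge rather than hiding it.
    """
    layout = template._param_layout()
    if not layout:
        raise FitError("template has no free parameters")
    names = [name for name, _ in layout]
    bounds = [b for _, b in layout]
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    nll = _objective(template, hist)
    rng = np.random.default_rng(seed)

    starts = [lo + (hi - lo) * rng.random(len(bounds)) for _ in range(n_starts)]
    for extra in extra_starts or []:
        x0 = _natural_to_x(template, extra, names)
        starts.append(np.clip(x0, lo, hi))

    candidates = []
    for x0 in starts:
        traj: list[float] = []
        res = minimize(
            nll,
            x0,
            method="L-BFGS-B",
            bounds=bounds,
            callback=lambda xk: traj.append(nll(xk)),
            options={"maxiter": maxiter, "ftol": 1e-12, "gtol": 1e-8},
        )
        if res.fun < _BIG:
            candidates.append((res.fun, res.x, bool(res.success), tuple(traj)))
    if not candidates:
        raise FitError("no start produced a valid optimum inside the constraints")

    candidates.sort(key=lambda c: c[0])
    polished = []
    for fun, x, ok, traj in candidates[:5]:
        res = minimize(
            nll,
            x,
            method="Nelder-Mead",
            options={"fatol": 1e-10, "xatol": 1e-9, "maxiter": 20000, "maxfev": 20000},
        )
        if res.fun <= fun and np.all(res.x >= lo - 1e-12) and np.all(res.x <= hi + 1e-12):
            polished.append((res.fun, np.clip(res.x, lo, hi), ok, traj))
        else:
            polished.append((fun, x, ok, traj))
    candidates = sorted(polished + candidates[5:], key=lambda c: c[0])

    best_fun = candidates[0][0]
    optima: list[Optimum] = []
    for fun, x, ok, traj in candidates:
        if fun > best_fun + keep_within:
            break
        if any(np.allclose(x, o.x, atol=1e-4) for o in optima):
            continue
        optima.append(
            Optimum(
                params=template.natural_params(x),
                x=x,
                log_likelihood=-fun,
                converged=ok,
                trajectory=traj,
            )
        )
    return FitResult(optima=tuple(optima), template=template, seed=seed)


def _natural_to_x(
    template: ModelTemplate, params: Mapping[str, float], names: Sequence[str]
) -> np.ndarray:
    """Invert the natural-parameter map for use as a warm start."""
    vals: dict[str, float] = {}
    for i in range(1, template.n_events + 1):
        if f"s_e{i}" in params:
            vals[f"s_e{i}"] = params[f"s_e{i}"]
        if f"u2_e{i}" in params and f"u3_e{i}" in params:
            total = params[f"u2_e{i}"] + params[f"u3_e{i}"]
            vals[f"stick_total_e{i}"] = total
            vals[f"stick_top_e{i}"] = params[f"u3_e{i}"] / total if total > 0 else 0.5
        elif f"u2_e{i}" in params:
            vals[f"u2_e{i}"] = params[f"u2_e{i}"]
    if "p1" in params:
        vals["p1"] = params["p1"]
    for i in range(2, template.n_events + 1):
        if f"p{i}" in params:
            vals[f"dp{i}"] = params[f"p{i}"] - params[f"p{i - 1}"]
    if "G" in params:
        vals["log10G"] = math.log10(params["G"])
    missing = [n for n in names if n not in vals]
    if missing:
        raise ValueError(f"warm start missing parameters: {missing}")
    return np.array([vals[n] for n in names])


def standard_errors(
    hist: ObservedHistogram,
    template: ModelTemplate,
    optimum: Optimum,
    step: float = 1e-4,
) -> dict[str, float]:
    """Asymptotic standard errors from the observed information matrix.

    Central-difference Hessian of the negative log-likelihood at the
    optimum (in optimization space), inverted and pushed through the
    Jacobian of the natural-parameter map.
    """
    nll = _objective(template, hist)
    x = np.asarray(optimum.x, dtype=float)
    k = len(x)
    h = step * np.maximum(1.0, np.abs(x))
    H = np.empty((k, k))
    f0 = nll(x)
    for a in range(k):
        for b in range(a, k):
            ea = np.zeros(k)
            eb = np.zeros(k)
            ea[a] = h[a]
            eb[b] = h[b]
            if a == b:
                H[a, a] = (nll(x + ea) - 2 * f0 + nll(x - ea)) / h[a] ** 2
            else:
                H[a, b] = H[b, a] = (
                    nll(x + ea + eb) - nll(x + ea - eb) - nll(x - ea + eb) + nll(x - ea - eb)
                ) / (4 * h[a] * h[b])
    cov = np.linalg.pinv(H)

    nat_names = sorted(optimum.params)
    J = np.empty((len(nat_names), k))
    for b in range(k):
        e = np.zeros(k)
        e[b] = h[b]
        up = template.natural_params(x + e)
        dn = template.natural_params(x - e)
        for a, name in enumerate(nat_names):
            J[a, b] = (up[name] - dn[name]) / (2 * h[b])
    var = np.einsum("ab,bc,ac->a", J, cov, J)
    return {name: math.sqrt(max(v, 0.0)) for name, v in zip(nat_names, var)}
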