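"""Null models for ROC score distributions.

A null model is a pair of continuous score distributions: ``F`` for the
true positives (cases) and ``G`` for the true negatives (controls).  The
canonical choice is the equal-variance *binormal* model, where both scores
are normal with unit variance and the TP mean exceeds the TN mean by
``delta``; its population AUC is ``Phi(delta / sqrt(2))``.

Tabulated models carry densities on a shared grid; their CDFs are rebuilt
from the densities by cumulative trapezoid integration so that density and
CDF are always internally consistent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy import integrate, stats

__all__ = [
    "NullModel",
    "BinormalModel",
    "TabulatedModel",
    "IntegrationGrid",
    "default_grid",
]

#: grid points used when the caller does not supply a grid
DEFAULT_GRID_POINTS = 4001
#: half-width of the default grid in standard deviations around the means
DEFAULT_GRID_SPAN = 9.0


@dataclass(frozen=True)
class IntegrationGrid:
    """Strictly increasing abscissae for trapezoid integration."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 1 or pts.size < 3:
            raise ValueError("grid needs at least 3 points")
        if not np.all(np.diff(pts) > 0):
            raise ValueError("grid points must be strictly increasing")
        object.__setattr__(self, "points", pts)

    @property
    def count(self) -> int:
        return int(self.points.size)

    def refined(self, factor: int = 2) -> "IntegrationGrid":
        """Grid with ``factor`` times the resolution over the same span."""
        n = (self.count - 1) * factor + 1
        return IntegrationGrid(np.linspace(self.points[0], self.points[-1], n))


class NullModel:
    """Abstract pair of TP / TN score distributions.

    Subclasses provide densities ``f`` (TP) and ``g`` (TN), CDFs ``F`` and
    ``G``, samplers, and a default integration grid covering the support.
    """

    family: str = "abstract"

    def pdf_tp(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def pdf_tn(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def cdf_tp(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def cdf_tn(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def sample_tp(self, n: int, rng: np.random.Generator) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def sample_tn(self, m: int, rng: np.random.Generator) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError

    def default_grid(self, n_points: int = DEFAULT_GRID_POINTS) -> IntegrationGrid:
        raise NotImplementedError

    def swapped(self) -> "NullModel":
        """Model with the roles of TP and TN exchanged (lower-tail symmetry)."""
        raise NotImplementedError

    @property
    def population_auc(self) -> float:
        """P(TP score > TN score) for independent draws."""
        raise NotImplementedError


@dataclass(frozen=True)
class BinormalModel(NullModel):
    """Equal-variance binormal model: TP ~ N(delta, 1), TN ~ N(0, 1).

    ``delta`` is the difference in means (TP minus TN); the population AUC
    is ``Phi(delta / sqrt(2))``.  ``mu_tn`` shifts both distributions and
    never changes the AUC distribution (rank invariance).
    """

    delta: float = 1.0
    mu_tn: float = 0.0
    family: str = field(default="binormal", init=False)

    @property
    def mu_tp(self) -> float:
        return self.mu_tn + self.delta

    def pdf_tp(self, x):
        return stats.norm.pdf(x, loc=self.mu_tp)

    def pdf_tn(self, x):
        return stats.norm.pdf(x, loc=self.mu_tn)

    def cdf_tp(self, x):
        return stats.norm.cdf(x, loc=self.mu_tp)

    def cdf_tn(self, x):
        return stats.norm.cdf(x, loc=self.mu_tn)

    def sample_tp(self, n, rng):
        return rng.standard_normal(n) + self.mu_tp

    def sample_tn(self, m, rng):
        return rng.standard_normal(m) + self.mu_tn

    def default_grid(self, n_points: int = DEFAULT_GRID_POINTS) -> IntegrationGrid:
        lo = min(self.mu_tp, self.mu_tn) - DEFAULT_GRID_SPAN
        hi = max(self.mu_tp, self.mu_tn) + DEFAULT_GRID_SPAN
        return IntegrationGrid(np.linspace(lo, hi, n_points))

    def swapped(self) -> "BinormalModel":
        return BinormalModel(delta=-self.delta, mu_tn=self.mu_tp)

    @property
    def population_auc(self) -> float:
        return float(stats.norm.cdf(self.delta / math.sqrt(2.0)))


def binormal_for_auc(target_auc: float) -> BinormalModel:
    """Binormal model whose population AUC equals ``target_auc``.

    Inverts AUC = Phi(delta / sqrt(2)); used to realise benchmark nulls
    such as "on par with a predicate test of AUC 0.88".
    """
    if not 0.0 < target_auc < 1.0:
        raise ValueError("target_auc must lie strictly inside (0, 1)")
    return BinormalModel(delta=math.sqrt(2.0) * float(stats.norm.ppf(target_auc)))


class TabulatedModel(NullModel):
    """Score distributions given by densities tabulated on a shared grid.

    Densities are linearly interpolated between grid points and must each
    integrate to 1 within ``norm_tol`` by the trapezoid rule.  CDFs are the
    cumulative trapezoid integrals of the tabulated densities.
    """

    family = "tabulated"

    def __init__(self, grid: np.ndarray, f: np.ndarray, g: np.ndarray,
                 norm_tol: float = 1e-6):
        grid = np.asarray(grid, dtype=float)
        f = np.asarray(f, dtype=float)
        g = np.asarray(g, dtype=float)
        if grid.ndim != 1 or f.shape != grid.shape or g.shape != grid.shape:
            raise ValueError("grid, f and g must be 1-D arrays of equal length")
        if not np.all(np.diff(grid) > 0):
            raise ValueError("grid must be strictly increasing")
        if np.any(f < 0) or np.any(g < 0):
            raise ValueError("densities must be non-negative")
        for name, dens in (("f", f), ("g", g)):
            total = float(np.trapezoid(dens, grid))
            if abs(total - 1.0) > norm_tol:
                raise ValueError(
                    f"density {name} integrates to {total:.8f}, not 1 within {norm_tol}")
        self.grid = grid
        self.f = f
        self.g = g
        self.F = integrate.cumulative_trapezoid(f, grid, initial=0.0)
        self.G = integrate.cumulative_trapezoid(g, grid, initial=0.0)

    def pdf_tp(self, x):
        return np.interp(x, self.grid, self.f, left=0.0, right=0.0)

    def pdf_tn(self, x):
        return np.interp(x, self.grid, self.g, left=0.0, right=0.0)

    def cdf_tp(self, x):
        return np.interp(x, self.grid, self.F, left=0.0, right=self.F[-1])

    def cdf_tn(self, x):
        return np.interp(x, self.grid, self.G, left=0.0, right=self.G[-1])

    def _inverse_sample(self, cdf: np.ndarray, size: int,
                        rng: np.random.Generator) -> np.ndarray:
        u = rng.uniform(cdf[0], cdf[-1], size)
        return np.interp(u, cdf, self.grid)

    def sample_tp(self, n, rng):
        return self._inverse_sample(self.F, n, rng)

    def sample_tn(self, m, rng):
        return self._inverse_sample(self.G, m, rng)

    def default_grid(self, n_points: int = DEFAULT_GRID_POINTS) -> IntegrationGrid:
        return IntegrationGrid(np.linspace(self.grid[0], self.grid[-1], n_points))

    def swapped(self) -> "TabulatedModel":
        return TabulatedModel(self.grid, self.g, self.f)

    @property
    def population_auc(self) -> float:
        # P(X > Y) = int f(x) G(x) dx on the shared grid
        return float(np.trapezoid(self.f * self.G, self.grid))


def default_grid(model: NullModel, n_points: int = DEFAULT_GRID_POINTS,
                 coverage_warn: float = 1e-15) -> IntegrationGrid:
    """Default grid for ``model`` with a coverage sanity check."""
    grid = model.default_grid(n_points)
    ends = grid.points[[0, -1]]
    dens = np.maximum(model.pdf_tp(ends), model.pdf_tn(ends))
    if np.any(dens > coverage_warn):
        import warnings

        warnings.warn(
            "integration grid may not cover the score distributions' support; "
            "tail density at a grid end exceeds %g" % coverage_warn,
            RuntimeWarning,
        )
    return grid
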