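"""Discrete concentration grids and normalized drug-response surfaces.

A drug cocktail is a point on a finite Cartesian grid: drug ``n`` takes one
of ``M_n`` pre-specified concentrations. The response surface maps each grid
point to a normalized efficacy ``f`` in ``[0, 1]`` (0 = ineffective, 1 = grid
optimum). This module provides the grid/combination containers, min--max
normalization over the grid, a registry of built-in analytic benchmark
surfaces, and a CSV loader for tabulated experimental surfaces.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GridError",
    "SurfaceError",
    "ConcentrationGrid",
    "Combination",
    "ResponseSurface",
    "make_grid",
    "normalize_minmax",
    "builtin_surface",
    "builtin_surface_names",
    "load_tabular_surface",
]


class GridError(ValueError):
    """Invalid concentration-grid specification."""


class SurfaceError(ValueError):
    """Invalid or degenerate response-surface data."""


@dataclass(frozen=True)
class ConcentrationGrid:
    """Per-drug ordered concentration sets defining the discrete search space.

    ``drugs[n]`` is the strictly increasing concentration vector of drug
    ``n`` (units arbitrary: nM, µM, ...). The search space is the Cartesian
    product of the per-drug sets.
    """

    drugs: tuple

    def __post_init__(self) -> None:
        if len(self.drugs) < 1:
            raise GridError("a grid needs at least one drug")
        frozen = []
        for n, axis in enumerate(self.drugs):
            arr = np.asarray(axis, dtype=float)
            if arr.ndim != 1 or arr.size < 2:
                raise GridError(f"drug {n}: need at least 2 concentration levels")
            if not np.all(np.diff(arr) > 0):
                raise GridError(f"drug {n}: concentrations must be strictly increasing")
            arr.flags.writeable = False
            frozen.append(arr)
        object.__setattr__(self, "drugs", tuple(frozen))

    @property
    def n_drugs(self) -> int:
        return len(self.drugs)

    @property
    def shape(self) -> tuple:
        """Levels per drug ``(M_1, ..., M_N)``."""
        return tuple(len(axis) for axis in self.drugs)

    @property
    def size(self) -> int:
        """Total number of combinations ``M``."""
        return int(np.prod(self.shape))

    def validate_levels(self, levels: Sequence[int]) -> tuple:
        levels = tuple(int(k) for k in levels)
        if len(levels) != self.n_drugs:
            raise GridError(f"expected {self.n_drugs} level indices, got {len(levels)}")
        for n, (k, m) in enumerate(zip(levels, self.shape)):
            if not 0 <= k < m:
                raise GridError(f"drug {n}: level index {k} outside [0, {m - 1}]")
        return levels

    def concentrations(self, levels: Sequence[int]) -> np.ndarray:
        """Real concentration vector for 0-based level indices."""
        levels = self.validate_levels(levels)
        return np.array([axis[k] for axis, k in zip(self.drugs, levels)])

    def nearest_levels(self, concentrations: Sequence[float]) -> tuple:
        """Level indices of the grid point closest (per axis) to ``concentrations``."""
        if len(concentrations) != self.n_drugs:
            raise GridError("concentration vector length mismatch")
        return tuple(
            int(np.argmin(np.abs(axis - c)))
            for axis, c in zip(self.drugs, concentrations)
        )

    def median_levels(self) -> tuple:
        """Per-drug median level index, lower middle for even ``M_n``.

        This is the fixed reference concentration of the Gur Game automaton.
        """
        return tuple((m - 1) // 2 for m in self.shape)

    def random_levels(self, rng: np.random.Generator) -> tuple:
        """Uniformly random combination on the grid."""
        return tuple(int(rng.integers(0, m)) for m in self.shape)


@dataclass(frozen=True)
class Combination:
    """A point in the combination space: one 0-based level index per drug."""

    grid: ConcentrationGrid
    levels: tuple

    def __post_init__(self) -> None:
        object.__setattr__(self, "levels", self.grid.validate_levels(self.levels))

    def concentrations(self) -> np.ndarray:
        return self.grid.concentrations(self.levels)


def normalize_minmax(values: np.ndarray) -> np.ndarray:
    """Min--max normalize raw responses over the full grid to span ``[0, 1]``.

    Raises :class:`SurfaceError` on a constant surface, for which the
    normalization is undefined.
    """
    values = np.asarray(values, dtype=float)
    if not np.all(np.isfinite(values)):
        raise SurfaceError("raw surface contains non-finite values")
    lo, hi = float(values.min()), float(values.max())
    if hi == lo:
        raise SurfaceError("degenerate surface: all raw responses are equal")
    return (values - lo) / (hi - lo)


class ResponseSurface:
    """Deterministic normalized response ``f`` over a concentration grid.

    The full response table is evaluated once at construction; lookups during
    a search are plain array indexing. Normalized surfaces span exactly
    ``[0, 1]`` over the grid; pre-normalized tables (``normalize=False``) must
    lie within ``[0, 1]`` but need not attain both endpoints.
    """

    def __init__(
        self,
        grid: ConcentrationGrid,
        table: np.ndarray,
        name: str = "surface",
        raw_fn: Callable | None = None,
    ) -> None:
        table = np.asarray(table, dtype=float)
        if table.shape != grid.shape:
            raise SurfaceError(
                f"table shape {table.shape} does not match grid shape {grid.shape}"
            )
        if table.min() < 0.0 or table.max() > 1.0:
            raise SurfaceError("normalized responses must lie in [0, 1]")
        table.flags.writeable = False
        self.grid = grid
        self.table = table
        self.name = name
        self._raw_fn = raw_fn

    @property
    def optimum_response(self) -> float:
        """Maximum of ``f`` over the grid (1.0 for min--max normalized surfaces)."""
        return float(self.table.max())

    def response(self, levels: Sequence[int]) -> float:
        """Normalized true response at a combination given by level indices."""
        levels = self.grid.validate_levels(levels)
        return float(self.table[levels])

    def raw(self, concentrations: Sequence[float]) -> float:
        """Raw (un-normalized) response at real concentrations, if defined."""
        if self._raw_fn is None:
            raise SurfaceError(f"surface {self.name!r} has no raw functional form")
        return float(self._raw_fn(*np.asarray(concentrations, dtype=float)))

    def potent_fraction(self, threshold: float = 0.95) -> float:
        """Fraction of grid combinations with ``f >= threshold``."""
        return float(np.mean(self.table >= threshold))

    @classmethod
    def from_function(
        cls,
        grid: ConcentrationGrid,
        fn: Callable,
        name: str = "surface",
        invert: bool = False,
    ) -> "ResponseSurface":
        """Evaluate ``fn`` on the full grid and min--max normalize.

        With ``invert=True`` the response is ``1 - minmax(raw)``, turning a
        minimization benchmark into a maximized "drug response" whose optimum
        sits at the benchmark's minimum.
        """
        axes = np.meshgrid(*grid.drugs, indexing="ij")
        raw = np.asarray(fn(*axes), dtype=float)
        raw = np.broadcast_to(raw, grid.shape)
        table = normalize_minmax(raw)
        if invert:
            table = 1.0 - table
        return cls(grid, table, name=name, raw_fn=fn)

    @classmethod
    def from_table(
        cls,
        grid: ConcentrationGrid,
        values: np.ndarray,
        name: str = "surface",
        normalize: bool = True,
    ) -> "ResponseSurface":
        values = np.asarray(values, dtype=float)
        if normalize:
            values = normalize_minmax(values)
        return cls(grid, values, name=name)


def make_grid(spec: Sequence) -> ConcentrationGrid:
    """Build a grid from per-drug specifications.

    Each per-drug entry is either a ``(low, high, n_levels)`` *tuple* --
    ``n_levels`` evenly spaced concentrations including both endpoints, level
    ``k`` mapping to ``low + k (high - low)/(n_levels - 1)`` -- or an explicit
    *list/array* of strictly increasing concentrations. The tuple/list
    distinction disambiguates a 3-tuple range spec from a 3-level explicit set.
    """
    axes = []
    for n, item in enumerate(spec):
        if isinstance(item, tuple):
            if len(item) != 3:
                raise GridError(f"drug {n}: range spec must be (low, high, n_levels)")
            low, high, n_levels = item
            n_levels = int(n_levels)
            if n_levels < 2:
                raise GridError(f"drug {n}: n_levels must be >= 2")
            if not low < high:
                raise GridError(f"drug {n}: need low < high")
            axes.append(np.linspace(float(low), float(high), n_levels))
        else:
            axes.append(np.asarray(item, dtype=float))
    return ConcentrationGrid(tuple(axes))


# ---------------------------------------------------------------------------
# Built-in benchmark surfaces
# ---------------------------------------------------------------------------

def peaks(x1, x2):
    """MATLAB ``peaks`` function: three Gaussians mixed with polynomials."""
    return (
        3.0 * (1.0 - x1) ** 2 * np.exp(-(x1**2) - (x2 + 1.0) ** 2)
        - 10.0 * (x1 / 5.0 - x1**3 - x2**5) * np.exp(-(x1**2) - x2**2)
        - (1.0 / 3.0) * np.exp(-((x1 + 1.0) ** 2) - x2**2)
    )


def rosenbrock(x1, x2):
    """Second De Jong function (Rosenbrock's saddle); global minimum 0 at (1, 1)."""
    return 100.0 * (x1**2 - x2) ** 2 + (1.0 - x1) ** 2


def _f3a(x1, x2, x3):
    return x1**2 * np.sin(x2) ** 2 * np.cos(x3) ** 2


def _f3b(x1, x2, x3):
    return peaks(x1, x2) * x3


def _f4a(x1, x2, x3, x4):
    return x1 * np.exp(-(x1**2 + x2**2 + x3**2 + x4**2))


def _f4b(x1, x2, x3, x4):
    return np.cos(0.3 * x1) ** 2 * np.sin(0.3 * x2) * np.tan(0.1 * x3) * x4


def _f5a(x1, x2, x3, x4, x5):
    return np.exp(-x1) * np.cos(x2) ** 2 * x3**2 * np.exp(
        -((x4 + 2.0) ** 2) - (x5 + 3.0) ** 2
    ) + np.exp(-((x4 - 2.0) ** 2) - (x5 - 3.0) ** 2)


def _f5b(x1, x2, x3, x4, x5):
    return 0.5 * peaks(x1, x2) * np.cos(0.5 * x3) * np.sin(0.5 * x4) * x5**2


def _f6a(x1, x2, x3, x4, x5, x6):
    return np.exp(-0.75 * x1) * np.sin(x2) ** 2 + np.cos(x3) * np.exp(
        -0.75 * (x4**2 + x5**2)
    ) * x6


def _f6b(x1, x2, x3, x4, x5, x6):
    return (
        np.exp(-0.1 * (x1**2 - x2**2) - 0.1 * (x3**2 + x4**2))
        * np.cos(0.2 * x5**3) ** 2
        * np.sin(0.2 * x6**3)
    )


# name -> (grid spec, raw function, invert)
_BUILTINS: dict = {
    "dejong2": ([(-2.0, 2.0, 21)] * 2, rosenbrock, False),
    "f3a": ([(-2.5, 2.5, 11)] * 3, _f3a, False),
    "f3b": ([(-3.0, 3.0, 11)] * 3, _f3b, False),
    "f4a": ([(-2.0, 2.0, 11)] * 2 + [(-3.0, 3.0, 11)] * 2, _f4a, False),
    "f4b": ([(-3.0, 3.0, 11)] * 4, _f4b, False),
    "f5a": ([(-2.0, 2.0, 11)] * 2 + [(-4.5, 4.5, 11)] * 3, _f5a, False),
    "f5b": ([(-3.0, 3.0, 11)] * 5, _f5b, False),
    "f6a": ([(-2.5, 2.5, 11)] * 6, _f6a, False),
    "f6b": ([(-2.5, 2.5, 11)] * 6, _f6b, False),
}

_SURFACE_CACHE: dict = {}


def builtin_surface_names() -> tuple:
    return tuple(_BUILTINS)


def builtin_surface(name: str, invert: bool | None = None) -> ResponseSurface:
    """Return a built-in benchmark surface by name.

    ``dejong2`` is Rosenbrock's saddle on a 21x21 grid over [-2, 2]^2,
    min--max normalized as-is, so the response to be maximized peaks at the
    corners where the saddle is largest and the response is below 0.5 over
    most of the grid (the over-normalized regime in which the Gur Game's
    fixed automaton fails). Pass ``invert=True`` to flip the orientation so
    the optimizer seeks the Rosenbrock valley at (1, 1) instead. The
    hypothetical 3-6 drug surfaces use 11 evenly spaced levels per drug on
    their stated ranges and plain min--max normalization.
    """
    if name not in _BUILTINS:
        raise KeyError(
            f"unknown surface {name!r}; choose from {sorted(_BUILTINS)}"
        )
    spec, fn, default_invert = _BUILTINS[name]
    do_invert = default_invert if invert is None else invert
    key = (name, do_invert)
    if key not in _SURFACE_CACHE:
        grid = make_grid(spec)
        _SURFACE_CACHE[key] = ResponseSurface.from_function(
            grid, fn, name=name, invert=do_invert
        )
    return _SURFACE_CACHE[key]


def load_tabular_surface(path, normalize: bool = True) -> ResponseSurface:
    """Load a tabulated surface from CSV.

    Layout: a header row (drug names, then a response column), one data row
    per combination. The grid is inferred from the distinct sorted values of
    each concentration column; the rows must enumerate the complete Cartesian
    grid exactly once, in any order. With ``normalize=True`` the response
    column is min--max normalized over the grid.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise SurfaceError("CSV needs at least one concentration column and a response")
    for col in df.columns:
        numeric = pd.to_numeric(df[col], errors="coerce")
        if numeric.isna().any():
            row = int(numeric.isna().idxmax()) + 2  # +1 header, +1 one-based
            raise SurfaceError(f"non-numeric cell in column {col!r} at file row {row}")
        df[col] = numeric
    conc = df.iloc[:, :-1].to_numpy(dtype=float)
    resp = df.iloc[:, -1].to_numpy(dtype=float)
    axes = tuple(np.unique(conc[:, j]) for j in range(conc.shape[1]))
    grid = ConcentrationGrid(axes)
    if len(df) != grid.size:
        raise SurfaceError(
            f"incomplete grid: {len(df)} rows but the inferred grid has "
            f"{grid.size} combinations"
        )
    table = np.full(grid.shape, np.nan)
    for i in range(conc.shape[0]):
        levels = tuple(
            int(np.searchsorted(axis, c)) for axis, c in zip(axes, conc[i])
        )
        if not np.isnan(table[levels]):
            raise SurfaceError(f"duplicate combination at file row {i + 2}")
        table[levels] = resp[i]
    # complete-row-count + no-duplicates implies no holes, but be explicit
    if np.isnan(table).any():
        raise SurfaceError("rows do not cover the full Cartesian grid")
    return ResponseSurface.from_table(
        grid, table, name=str(path), normalize=normalize
    )
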