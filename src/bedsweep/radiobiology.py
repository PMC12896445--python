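"""Linear-quadratic (LQ) biologically effective dose computation.

The biologically effective dose of a fractionated scheme delivering ``n``
fractions of ``d`` Gy each, for a tissue with fractionation-sensitivity
parameter ``alpha_beta`` (the α/β ratio, in Gy), is

    BED = n * d * (1 + d / alpha_beta)

BED puts heterogeneous fractionation schemes (single-fraction radiosurgery
through 10-fraction hypofractionated courses) on one biological scale.  The
inverse problem — which dose per fraction over ``n`` fractions is
isoeffective with a given BED target — has the closed-form positive root

    d = (-ab + sqrt(ab**2 + 4 * ab * BED / n)) / 2

of the quadratic ``n*d**2/ab + n*d - BED = 0``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import EmptyInputError, InvalidParameterError

__all__ = [
    "TreatmentScheme",
    "AlphaBetaGrid",
    "BedMatrix",
    "compute_bed",
    "isoeffective_dose_per_fraction",
    "bed_matrix",
]


@dataclass(frozen=True)
class TreatmentScheme:
    """One tumor's fractionation: ``n_fractions`` fractions of
    ``dose_per_fraction`` Gy each."""

    n_fractions: int
    dose_per_fraction: float

    def __post_init__(self) -> None:
        if int(self.n_fractions) != self.n_fractions or self.n_fractions < 1:
            raise InvalidParameterError(
                f"n_fractions must be a positive integer, got {self.n_fractions!r}"
            )
        if not (self.dose_per_fraction > 0) or not math.isfinite(self.dose_per_fraction):
            raise InvalidParameterError(
                f"dose_per_fraction must be a positive finite Gy value, "
                f"got {self.dose_per_fraction!r}"
            )

    @property
    def total_dose(self) -> float:
        """Total physical (marginal) dose in Gy."""
        return self.n_fractions * self.dose_per_fraction


@dataclass(frozen=True)
class AlphaBetaGrid:
    """Ordered grid of α/β ratios (Gy) over which BED is re-computed.

    Defaults to the integers 2–20 inclusive.  Arbitrary positive reals are
    accepted as long as they are strictly increasing.
    """

    values: tuple[float, ...] = field(default_factory=lambda: tuple(float(v) for v in range(2, 21)))

    def __post_init__(self) -> None:
        vals = tuple(float(v) for v in self.values)
        if len(vals) == 0:
            raise InvalidParameterError("alpha/beta grid must be non-empty")
        if any(not (v > 0) for v in vals):
            raise InvalidParameterError("alpha/beta values must all be positive")
        if any(b <= a for a, b in zip(vals, vals[1:])):
            raise InvalidParameterError("alpha/beta grid must be strictly increasing")
        object.__setattr__(self, "values", vals)

    def __len__(self) -> int:
        return len(self.values)

    def __iter__(self):
        return iter(self.values)


def compute_bed(scheme: TreatmentScheme, alpha_beta: float) -> float:
    """BED in Gy of ``scheme`` for a tissue with the given α/β ratio.

    Strictly increasing in dose per fraction and number of fractions,
    strictly decreasing in ``alpha_beta``.  When the dose per fraction
    equals α/β, BED is exactly twice the physical dose.
    """
    if not (alpha_beta > 0) or not math.isfinite(alpha_beta):
        raise InvalidParameterError(f"alpha_beta must be positive and finite, got {alpha_beta!r}")
    n, d = scheme.n_fractions, scheme.dose_per_fraction
    return n * d * (1.0 + d / alpha_beta)


def isoeffective_dose_per_fraction(
    target_bed: float, n_fractions: int, alpha_beta: float
) -> float:
    """Dose per fraction (Gy) whose ``n_fractions``-fraction scheme has the
    target BED at the given α/β ratio.

    Unique positive root of the LQ quadratic; satisfies the round trip
    ``compute_bed(TreatmentScheme(n, d), ab) == target_bed`` to ~1e-12 Gy.
    """
    if not (target_bed > 0) or not math.isfinite(target_bed):
        raise InvalidParameterError(f"target_bed must be positive, got {target_bed!r}")
    if int(n_fractions) != n_fractions or n_fractions < 1:
        raise InvalidParameterError(f"n_fractions must be a positive integer, got {n_fractions!r}")
    if not (alpha_beta > 0) or not math.isfinite(alpha_beta):
        raise InvalidParameterError(f"alpha_beta must be positive, got {alpha_beta!r}")
    ab = float(alpha_beta)
    return (-ab + math.sqrt(ab * ab + 4.0 * ab * target_bed / n_fractions)) / 2.0


@dataclass(frozen=True)
class BedMatrix:
    """Per-tumor BED tabulated over an α/β grid.

    ``values[i, j]`` is the BED (Gy) of tumor ``i`` at grid ratio ``j``;
    rows follow cohort order.  Every cell is positive and each row is
    strictly decreasing along the grid (BED falls as α/β rises).
    """

    values: np.ndarray
    grid: AlphaBetaGrid

    def to_frame(self, index: Sequence | None = None) -> pd.DataFrame:
        cols = [f"bed_ab{g:g}" for g in self.grid]
        return pd.DataFrame(self.values, columns=cols, index=index)

    def column(self, alpha_beta: float) -> np.ndarray:
        """BED scores of the whole cohort at one grid ratio."""
        for j, g in enumerate(self.grid):
            if g == alpha_beta:
                return self.values[:, j]
        raise InvalidParameterError(f"alpha_beta {alpha_beta!r} is not on the grid")


def bed_matrix(schemes: Iterable[TreatmentScheme], grid: AlphaBetaGrid | None = None) -> BedMatrix:
    """Tabulate :func:`compute_bed` for every (tumor, grid ratio) pair.

    ``schemes`` may be ``TreatmentScheme`` objects or any objects exposing a
    ``scheme`` attribute (e.g. cohort records).
    """
    if grid is None:
        grid = AlphaBetaGrid()
    schemes = [s if isinstance(s, TreatmentScheme) else s.scheme for s in schemes]
    if len(schemes) == 0:
        raise EmptyInputError("cannot build a BED matrix for an empty cohort")
    n = np.array([s.n_fractions for s in schemes], dtype=float)
    d = np.array([s.dose_per_fraction for s in schemes], dtype=float)
    ab = np.asarray(grid.values, dtype=float)
    values = (n * d)[:, None] * (1.0 + d[:, None] / ab[None, :])
    return BedMatrix(values=values, grid=grid)
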