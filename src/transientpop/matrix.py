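"""Construction of 18x18 age-structured population projection matrices.

The matrix A advances the binned female population by one five-year step,
n_{t+5} = A n_t.  Survival (progression) per bin is 1 - 5*deaths/population,
clamped below at zero, and sits on the subdiagonal for bins 0-4 through
80-84; the open 85+ class persists through a stasis term, the same survival
formula applied to the open class, in the bottom-right diagonal cell.
Survival of the first bin combines infant (age 0) and child (ages 1-4)
survival as 0.2*s(0) + 0.8*s(1-4), reflecting the concentration of
early-life deaths in infancy.  Fertility on the top row follows the
birth-flow approximation: the crude daughter rate 5*births/population
discounted by the square roots of maternal survival and newborn (0-4)
survival, since births occur continuously within the step and both mother
and newborn are exposed to mortality for half a step on average.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import DegenerateBinError, ValidationError
from .ingest import N_BINS, BinnedDemography

#: weight of infant (age-0) survival in the combined 0-4 survival
INFANT_WEIGHT = 0.2
#: weight of child (ages 1-4) survival in the combined 0-4 survival
CHILD_WEIGHT = 0.8
#: projection interval in years
TIMESTEP_YEARS = 5


@dataclass
class ProjectionMatrix:
    """An 18x18 Leslie-type matrix with country/year metadata.

    Nonzero entries are confined to the top row (fertility), the
    subdiagonal (survival/progression) and the bottom-right corner
    (85+ stasis).
    """

    entries: np.ndarray
    country: str = ""
    year: int = 0
    timestep_years: int = TIMESTEP_YEARS

    def __post_init__(self) -> None:
        A = np.asarray(self.entries, dtype=float)
        self.entries = A
        if A.shape != (N_BINS, N_BINS):
            raise ValidationError(f"matrix must be {N_BINS}x{N_BINS}, got {A.shape}")
        if np.any(A < 0):
            raise ValidationError("projection matrix entries must be nonnegative")
        mask = np.zeros_like(A, dtype=bool)
        mask[0, :] = True
        mask[np.arange(1, N_BINS), np.arange(N_BINS - 1)] = True
        mask[-1, -1] = True
        if np.any(A[~mask] != 0):
            raise ValidationError(
                "nonzero entries outside the top row, subdiagonal and "
                "85+ stasis cell"
            )
        sub = A[np.arange(1, N_BINS), np.arange(N_BINS - 1)]
        if np.any(sub > 1 + 1e-12) or A[-1, -1] > 1 + 1e-12:
            raise ValidationError("survival entries must not exceed 1")

    @property
    def key(self) -> tuple[str, int]:
        return (self.country, self.year)

    @property
    def survivals(self) -> np.ndarray:
        """Subdiagonal survival entries (bins 0-4 ... 80-84), length 17."""
        return self.entries[np.arange(1, N_BINS), np.arange(N_BINS - 1)].copy()

    @property
    def stasis(self) -> float:
        """Survival of the open 85+ class (bottom-right diagonal cell)."""
        return float(self.entries[-1, -1])

    @property
    def fertilities(self) -> np.ndarray:
        """Top-row fertility entries, length 18."""
        return self.entries[0].copy()


def survival_rate(deaths: float, population: float, *, country: str = "?",
                  year: int = 0, bin_index: int = -1) -> float:
    """Probability of surviving one five-year step: 1 - 5*deaths/population,
    clamped below at zero (quintupled deaths can exceed population)."""
    if population <= 0:
        raise DegenerateBinError(country, year, bin_index)
    if deaths < 0:
        raise ValidationError("deaths must be nonnegative")
    return max(0.0, 1.0 - 5.0 * deaths / population)


def combined_infant_child_survival(s0: float, s1_4: float) -> float:
    """Survival of the 0-4 bin: 0.2*s(0) + 0.8*s(1-4).

    Infant (under-1) and child (1-4) survival are computed separately
    because infant mortality dominates early-life deaths, then combined
    with fixed one-fifth / four-fifths exposure weights.
    """
    for name, s in (("s0", s0), ("s1_4", s1_4)):
        if not 0.0 <= s <= 1.0:
            raise ValidationError(f"{name} must lie in [0, 1], got {s}")
    return INFANT_WEIGHT * s0 + CHILD_WEIGHT * s1_4


def fertility_rate(
    female_births: float,
    population: float,
    s_maternal: float,
    s_04: float,
    *,
    country: str = "?",
    year: int = 0,
    bin_index: int = -1,
) -> float:
    """Daughters per female per step under the birth-flow approximation:
    (5*births/population) * sqrt(s_maternal) * sqrt(s_04)."""
    if population <= 0:
        raise DegenerateBinError(country, year, bin_index)
    for name, s in (("s_maternal", s_maternal), ("s_04", s_04)):
        if not 0.0 <= s <= 1.0:
            raise ValidationError(f"{name} must lie in [0, 1], got {s}")
    if female_births < 0:
        raise ValidationError("female_births must be nonnegative")
    crude = 5.0 * female_births / population
    return crude * np.sqrt(s_maternal) * np.sqrt(s_04)


def build_ppm(binned: BinnedDemography) -> ProjectionMatrix:
    """Build the projection matrix for one country-year.

    Subdiagonal: survival of bins 0-4 ... 80-84 (the first from the
    0.2/0.8 infant-child combination).  Corner: 85+ stasis.  Top row:
    fertility of each bin, using that bin's own survival as the maternal
    survival (the stasis value for the open class) and the combined 0-4
    survival for the newborns.
    """
    c, y = binned.country, binned.year
    s0 = survival_rate(binned.infant_deaths, binned.infant_population,
                       country=c, year=y, bin_index=0)
    s1_4 = survival_rate(binned.child_deaths, binned.child_population,
                         country=c, year=y, bin_index=0)
    s_04 = combined_infant_child_survival(s0, s1_4)

    survivals = np.empty(N_BINS - 1)
    survivals[0] = s_04
    for i in range(1, N_BINS - 1):
        survivals[i] = survival_rate(
            binned.deaths[i], binned.population[i], country=c, year=y, bin_index=i
        )
    stasis = survival_rate(
        binned.deaths[-1], binned.population[-1], country=c, year=y,
        bin_index=N_BINS - 1,
    )

    A = np.zeros((N_BINS, N_BINS))
    A[np.arange(1, N_BINS), np.arange(N_BINS - 1)] = survivals
    A[-1, -1] = stasis
    maternal = np.concatenate([survivals, [stasis]])
    for i in range(N_BINS):
        A[0, i] = fertility_rate(
            binned.female_births[i], binned.population[i], maternal[i], s_04,
            country=c, year=y, bin_index=i,
        )
    return ProjectionMatrix(entries=A, country=c, year=y)


def project(
    ppm: ProjectionMatrix | np.ndarray, n0: np.ndarray, steps: int
) -> np.ndarray:
    """Iterated projection n_0, A n_0, A^2 n_0, ...

    Returns an array of shape (steps + 1, 18) whose k-th row is A^k n_0.
    """
    A = ppm.entries if isinstance(ppm, ProjectionMatrix) else np.asarray(ppm, float)
    n = np.asarray(n0, dtype=float)
    if n.shape != (A.shape[0],):
        raise ValidationError(
            f"population vector length {n.shape} does not match matrix {A.shape}"
        )
    if steps < 0:
        raise ValidationError("steps must be >= 0")
    out = np.empty((steps + 1, A.shape[0]))
    out[0] = n
    for k in range(1, steps + 1):
        out[k] = A @ out[k - 1]
    return out


def write_matrix_csv(ppm: ProjectionMatrix, path: str | Path) -> None:
    """Persist one matrix as 18 header-less rows of comma-separated floats.

    Country/year metadata lives in the long-format bundle written by
    :func:`write_matrix_bundle`, or in a sidecar the caller manages.
    """
    np.savetxt(path, ppm.entries, delimiter=",")


def write_matrix_bundle(
    matrices: Sequence[ProjectionMatrix], path: str | Path
) -> None:
    """Stack all matrices into one long-format CSV:
    country, year, row, col, value (rows/cols are 1-based bins)."""
    records = []
    for m in matrices:
        rows, cols = np.nonzero(m.entries)
        for r, c in zip(rows, cols):
            records.append((m.country, m.year, r + 1, c + 1, m.entries[r, c]))
    frame = pd.DataFrame(
        records, columns=["country", "year", "row", "col", "value"]
    )
    frame.to_csv(path, index=False)


def read_matrix_csv(path: str | Path) -> np.ndarray:
    """Read a header-less matrix CSV back into an array."""
    return np.loadtxt(path, delimiter=",", ndmin=2)
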