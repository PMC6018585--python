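"""Eigendata and case-specific transient indices of projection matrices.

For a projection matrix A, the dominant eigenvalue lambda_1 is the
asymptotic per-step growth rate and its right eigenvector the stable age
structure.  Transient behaviour — what happens before the population
settles onto that structure — is summarised here by three quantities:

* the damping ratio lambda_1 / |lambda_2|, the asymptotic rate at which
  transient deviations decay (not their amplitude);
* case-specific reactivity ||A_hat n_0||_1, the relative population size
  one step after starting from the observed structure n_0, with growth
  factored out via the standardised matrix A_hat = A / lambda_1;
* inertia ||A_hat^h n_0||_1 at horizon h (default 100 steps, i.e. 500
  years), the lasting multiplicative offset in population size caused by
  the unstable initial structure.

Values below one are attenuation rather than amplification; both are
reported as-is.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import NonPerronError, TransientPopError, ValidationError
from .matrix import ProjectionMatrix

#: tolerance for discarding a numerically spurious imaginary part of lambda_1
IMAG_TOL = 1e-9
#: default transient horizon for inertia, in projection steps
DEFAULT_HORIZON = 100


def _as_array(A) -> np.ndarray:
    if isinstance(A, ProjectionMatrix):
        return A.entries
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValidationError(f"expected a square matrix, got shape {A.shape}")
    return A


@dataclass
class EigenData:
    """Full spectrum of a matrix, sorted by non-increasing magnitude.

    Ties in magnitude are broken by descending real part, then descending
    imaginary part; the damping ratio depends only on |lambda_2| and is
    tie-invariant.
    """

    eigenvalues: np.ndarray
    lambda1: float
    right_eigenvector_1: np.ndarray


def eigendata(A, *, imag_tol: float = IMAG_TOL) -> EigenData:
    """Eigendecomposition with the ordering and Perron checks applied.

    The dominant eigenvalue must be real (imaginary part <= ``imag_tol``,
    then discarded) and its eigenvector is returned rescaled to a
    nonnegative vector of unit one-norm.
    """
    M = _as_array(A)
    values, vectors = np.linalg.eig(M)
    order = np.lexsort((-values.imag, -values.real, -np.abs(values)))
    values = values[order]
    vectors = vectors[:, order]
    lam1 = values[0]
    if abs(lam1.imag) > imag_tol:
        raise NonPerronError(
            f"dominant eigenvalue {lam1} has non-negligible imaginary part"
        )
    w = vectors[:, 0].real
    total = w.sum()
    if total != 0:
        w = w / total
    return EigenData(
        eigenvalues=values,
        lambda1=float(lam1.real),
        right_eigenvector_1=w,
    )


def damping_ratio(ed: EigenData) -> float:
    """lambda_1 / |lambda_2|; infinity when the subdominant eigenvalue is
    zero (e.g. rank-one matrices)."""
    mag2 = abs(ed.eigenvalues[1])
    if mag2 == 0:
        return float("inf")
    return ed.lambda1 / mag2


def scale_matrix(A, lambda1: float) -> np.ndarray:
    """Standardised matrix A_hat = A / lambda_1, whose dominant eigenvalue
    is one; isolates transient from asymptotic dynamics."""
    if not np.isfinite(lambda1) or lambda1 <= 0:
        raise TransientPopError(
            f"cannot standardise: dominant eigenvalue {lambda1} is not positive"
        )
    return _as_array(A) / lambda1


def normalize_structure(n) -> np.ndarray:
    """Scale a nonnegative population vector to unit sum (proportions of
    the population in each age bin)."""
    n = np.asarray(n, dtype=float)
    if np.any(n < 0):
        raise ValidationError("population vector must be nonnegative")
    total = n.sum()
    if total <= 0:
        raise ValidationError("population vector must have positive sum")
    return n / total


def reactivity(A_hat: np.ndarray, n0: np.ndarray) -> float:
    """One-norm of A_hat n_0: relative population size after one step.

    ``n0`` must be normalised to unit sum and ``A_hat`` standardised;
    values below one are first-timestep attenuation, reported as-is.
    """
    return float(np.abs(np.asarray(A_hat) @ np.asarray(n0)).sum())


def inertia(
    A_hat: np.ndarray, n0: np.ndarray, horizon: int = DEFAULT_HORIZON
) -> float:
    """One-norm of A_hat^horizon n_0, by iterated multiplication.

    Repeated matrix-vector products are used rather than an explicit
    matrix power for numerical stability.  A non-finite result (possible
    if lambda_1 was misestimated) is returned as-is for the caller to flag.
    """
    if horizon < 1:
        raise ValidationError("horizon must be >= 1")
    v = np.asarray(n0, dtype=float)
    M = np.asarray(A_hat, dtype=float)
    for _ in range(horizon):
        v = M @ v
    return float(np.abs(v).sum())


@dataclass
class TransientRecord:
    """Per-matrix summary row: growth, transient indices and the six
    non-normality values (three metrics on the raw and standardised
    matrix).  ``flags`` collects non-finite or otherwise suspect values
    so the comparative layer can exclude them explicitly."""

    country: str
    year: int
    lambda1: float
    damping_ratio: float
    reactivity: float
    inertia: float
    nn_frobenius_raw: float = np.nan
    nn_henrici_raw: float = np.nan
    nn_ruhe_raw: float = np.nan
    nn_frobenius_scaled: float = np.nan
    nn_henrici_scaled: float = np.nan
    nn_ruhe_scaled: float = np.nan
    flags: list[str] = field(default_factory=list)

    COLUMNS = (
        "country", "year", "lambda1", "damping_ratio", "reactivity",
        "inertia", "nn_frobenius_raw", "nn_henrici_raw", "nn_ruhe_raw",
        "nn_frobenius_scaled", "nn_henrici_scaled", "nn_ruhe_scaled",
    )

    def as_row(self) -> tuple:
        return tuple(getattr(self, c) for c in self.COLUMNS)

    @property
    def is_finite(self) -> bool:
        return all(
            np.isfinite(v) for v in self.as_row()[2:]
        )


def transient_record(
    ppm: ProjectionMatrix,
    n0: np.ndarray | None = None,
    horizon: int = DEFAULT_HORIZON,
) -> TransientRecord:
    """Compute lambda_1, damping ratio, reactivity and inertia for one
    matrix.  Callers normally pass the observed binned population as
    ``n0`` (it is normalised here); if omitted the stable structure is
    used, which makes both transient indices exactly one."""
    ed = eigendata(ppm)
    A_hat = scale_matrix(ppm, ed.lambda1)
    if n0 is None:
        n0 = ed.right_eigenvector_1
    n0 = normalize_structure(n0)
    rec = TransientRecord(
        country=ppm.country,
        year=ppm.year,
        lambda1=ed.lambda1,
        damping_ratio=damping_ratio(ed),
        reactivity=reactivity(A_hat, n0),
        inertia=inertia(A_hat, n0, horizon),
    )
    if not np.isfinite(rec.damping_ratio):
        rec.flags.append("damping_ratio_infinite")
    if not np.isfinite(rec.inertia):
        rec.flags.append("inertia_nonfinite")
    return rec
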