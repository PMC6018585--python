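"""Scalar non-normality metrics.

A matrix is normal when it commutes with its conjugate transpose,
A*A = AA*; only then is its behaviour fully described by eigendata, and
only non-normal matrices can amplify transients that eigenvalues miss.
Three classical scalar measures of the departure from normality are
implemented, all based on the Frobenius norm:

* Frobenius metric: sqrt(||A*A - AA*||_F), the size of the commutator;
* Henrici metric: sqrt(||A||_F^2 - sum_k |lambda_k|^2), the "energy" of A
  not accounted for by its eigenvalues (zero iff A is normal, by Schur's
  inequality);
* Ruhe metric: max_k |sigma_k - |lambda_k||, the largest rank-paired gap
  between singular values and eigenvalue magnitudes (equal for normal
  matrices).

All three are positively homogeneous of degree one, so the value on the
standardised matrix A_hat = A/lambda_1 equals the raw value divided by
lambda_1 — standardising inflates non-normality exactly when lambda_1 < 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .errors import TransientPopError, ValidationError
from .matrix import ProjectionMatrix
from .transient import TransientRecord, scale_matrix

logger = logging.getLogger(__name__)

#: flooring beyond this magnitude in the Henrici metric is logged
_HENRICI_FLOOR_WARN = 1e-12


def _as_square(A) -> np.ndarray:
    if isinstance(A, ProjectionMatrix):
        return A.entries
    A = np.asarray(A, dtype=float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValidationError(f"expected a square matrix, got shape {A.shape}")
    return A


def frobenius_metric(A) -> float:
    """sqrt of the Frobenius norm of the commutator A*A - AA*."""
    M = _as_square(A)
    commutator = M.T @ M - M @ M.T
    return float(np.sqrt(np.linalg.norm(commutator, "fro")))


def henrici_metric(A) -> float:
    """sqrt(||A||_F^2 - sum |lambda|^2), with a machine-precision deadband.

    Schur's inequality guarantees the argument is nonnegative
    analytically.  The computed eigenvalues carry a backward error of
    order n*eps*||A||, so for a normal matrix the argument is rounding
    noise of order n^2*eps*||A||_F^2 rather than exactly zero; taking the
    square root would inflate that noise to ~1e-7.  Arguments inside the
    deadband n^2*eps*||A||_F^2 are therefore snapped to zero, and
    negative arguments beyond it are logged before flooring.
    """
    M = _as_square(A)
    fro2 = np.linalg.norm(M, "fro") ** 2
    arg = fro2 - np.sum(np.abs(np.linalg.eigvals(M)) ** 2)
    deadband = M.shape[0] ** 2 * np.finfo(float).eps * fro2
    if abs(arg) <= deadband:
        return 0.0
    if arg < -_HENRICI_FLOOR_WARN:
        logger.warning(
            "Henrici metric argument %.3e floored to zero (beyond rounding)", arg
        )
    return float(np.sqrt(max(arg, 0.0)))


def ruhe_metric(A) -> float:
    """Largest gap between rank-paired singular values and eigenvalue
    magnitudes, both sorted in descending order."""
    M = _as_square(A)
    sigma = np.linalg.svd(M, compute_uv=False)  # descending
    lam = np.sort(np.abs(np.linalg.eigvals(M)))[::-1]
    return float(np.max(np.abs(sigma - lam)))


@dataclass(frozen=True)
class NonNormalityTriple:
    """The three metric values for one matrix (raw A or standardised A_hat)."""

    frobenius: float
    henrici: float
    ruhe: float
    scaled: bool

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.frobenius, self.henrici, self.ruhe)


def metric_triple(A, scaled: bool = False) -> NonNormalityTriple:
    M = _as_square(A)
    return NonNormalityTriple(
        frobenius=frobenius_metric(M),
        henrici=henrici_metric(M),
        ruhe=ruhe_metric(M),
        scaled=scaled,
    )


def metric_suite(A, lambda1: float) -> tuple[NonNormalityTriple, NonNormalityTriple]:
    """Raw and standardised metric triples for one matrix.

    The standardised triple is computed on A_hat = A/lambda_1 (kept real;
    valid projection matrices are real to begin with).
    """
    if not np.isfinite(lambda1) or lambda1 <= 0:
        raise TransientPopError(f"lambda_1 must be positive, got {lambda1}")
    raw = metric_triple(A, scaled=False)
    scl = metric_triple(np.real(scale_matrix(A, lambda1)), scaled=True)
    return raw, scl


def fill_record(record: TransientRecord, A) -> TransientRecord:
    """Populate the six non-normality fields of a TransientRecord."""
    raw, scl = metric_suite(A, record.lambda1)
    record.nn_frobenius_raw = raw.frobenius
    record.nn_henrici_raw = raw.henrici
    record.nn_ruhe_raw = raw.ruhe
    record.nn_frobenius_scaled = scl.frobenius
    record.nn_henrici_scaled = scl.henrici
    record.nn_ruhe_scaled = scl.ruhe
    return record
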