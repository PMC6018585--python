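"""Multivariate comparison of transient and non-normality metrics.

Rank correlations (Spearman, mid-rank ties) describe pairwise monotone
association among the per-matrix metrics; principal component analysis on
the scaled-and-centred metrics table summarises their joint structure.
Component retention uses Horn's parallel analysis with a conservative
95th-percentile correction: observed correlation-matrix eigenvalues are
debiased by the amount the corresponding rank's eigenvalue exceeds one in
size-matched uncorrelated normal data, and components are retained while
the adjusted eigenvalue still exceeds one.  Per-year trend summaries
(mean, median, central 95% interval) replace smoother fits for
visualising change over time.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import ValidationError
from .transient import TransientRecord

#: the nine analysis variables of the comparison layer (raw-metric set);
#: the scaled set swaps the three non-normality columns
RAW_VARIABLES = (
    "year", "lambda1", "damping_ratio", "reactivity", "inertia",
    "nn_frobenius_raw", "nn_henrici_raw", "nn_ruhe_raw",
)
SCALED_VARIABLES = (
    "year", "lambda1", "damping_ratio", "reactivity", "inertia",
    "nn_frobenius_scaled", "nn_henrici_scaled", "nn_ruhe_scaled",
)


def records_to_frame(records: Sequence[TransientRecord]) -> pd.DataFrame:
    """Assemble TransientRecords into the metrics table, one row per
    country-year."""
    return pd.DataFrame(
        [r.as_row() for r in records], columns=list(TransientRecord.COLUMNS)
    )


def drop_nonfinite(frame: pd.DataFrame, columns: Sequence[str]) -> tuple[pd.DataFrame, int]:
    """Listwise-exclude rows with non-finite values in the given columns;
    returns the clean frame and the number of rows dropped."""
    values = frame[list(columns)].to_numpy(dtype=float)
    keep = np.isfinite(values).all(axis=1)
    return frame.loc[keep].reset_index(drop=True), int((~keep).sum())


@dataclass(frozen=True)
class SpearmanResult:
    rho: float
    p_value: float
    n: int

    def rounded(self) -> float:
        """Coefficient to two decimal places, the summary convention."""
        return round(self.rho, 2)


def spearman_rho(x, y) -> SpearmanResult:
    """Spearman rank correlation with mid-rank tie handling and a
    two-sided p-value from the large-sample t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValidationError("inputs must be equal-length vectors")
    if x.size < 3:
        raise ValidationError("need at least 3 observations")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValidationError("correlation undefined for constant input")
    rho, p = sps.spearmanr(x, y)
    return SpearmanResult(rho=float(rho), p_value=float(p), n=int(x.size))


def correlation_matrix(frame: pd.DataFrame, columns: Sequence[str]) -> pd.DataFrame:
    """Pairwise Spearman correlation matrix of the given columns."""
    cols = list(columns)
    clean, _ = drop_nonfinite(frame, cols)
    out = pd.DataFrame(np.eye(len(cols)), index=cols, columns=cols)
    for i, a in enumerate(cols):
        for j in range(i + 1, len(cols)):
            b = cols[j]
            try:
                r = spearman_rho(clean[a], clean[b]).rho
            except ValidationError:
                r = np.nan  # undefined (constant column); flagged as NaN
            out.iloc[i, j] = out.iloc[j, i] = r
    return out


@dataclass
class ParallelAnalysisResult:
    observed_eigenvalues: np.ndarray
    bias: np.ndarray
    adjusted_eigenvalues: np.ndarray
    n_retained: int
    quantile: float
    n_iter: int


def parallel_analysis(
    data: pd.DataFrame | np.ndarray,
    n_iter: int = 1000,
    quantile: float = 0.95,
    seed: int | None = None,
) -> ParallelAnalysisResult:
    """Horn's parallel analysis with conservative quantile correction.

    Correlation-matrix eigenvalues of uncorrelated standard-normal data of
    the same shape are simulated ``n_iter`` times; the bias at rank k is
    the chosen quantile of the simulated k-th eigenvalues minus one.
    Observed eigenvalues are debiased by that amount and components with
    adjusted eigenvalue above one are retained.
    """
    X = np.asarray(data, dtype=float)
    if X.ndim != 2:
        raise ValidationError("data must be two-dimensional")
    n, p = X.shape
    if n <= p:
        raise ValidationError(f"need more rows than columns, got {n}x{p}")
    if n_iter < 100:
        raise ValidationError("n_iter must be >= 100")
    if not np.isfinite(X).all():
        raise ValidationError("data must be finite")
    observed = np.sort(np.linalg.eigvalsh(np.corrcoef(X, rowvar=False)))[::-1]
    rng = np.random.default_rng(seed)
    sims = np.empty((n_iter, p))
    for it in range(n_iter):
        Z = rng.standard_normal((n, p))
        sims[it] = np.sort(np.linalg.eigvalsh(np.corrcoef(Z, rowvar=False)))[::-1]
    bias = np.quantile(sims, quantile, axis=0) - 1.0
    adjusted = observed - bias
    # retained components must be leading: stop at the first rank <= 1
    n_retained = 0
    for value in adjusted:
        if value > 1.0:
            n_retained += 1
        else:
            break
    return ParallelAnalysisResult(
        observed_eigenvalues=observed,
        bias=bias,
        adjusted_eigenvalues=adjusted,
        n_retained=n_retained,
        quantile=quantile,
        n_iter=n_iter,
    )


@dataclass
class PcaResult:
    variables: tuple[str, ...]
    loadings: np.ndarray  # variables x components (all p components)
    explained_variance_fraction: np.ndarray
    scores: np.ndarray  # rows x retained components
    n_retained: int

    def loading_report(self, threshold: float = 0.10) -> list[list[str]]:
        """Per retained component: variables whose absolute loading exceeds
        ``threshold`` of the axis (relative to the largest absolute
        loading), in order of decreasing importance."""
        report = []
        for k in range(self.n_retained):
            col = self.loadings[:, k]
            scale = np.abs(col).max()
            order = np.argsort(-np.abs(col))
            names = [
                f"{self.variables[i]}{'+' if col[i] >= 0 else '-'}"
                for i in order
                if abs(col[i]) > threshold * scale
            ]
            report.append(names)
        return report


def pca(
    data: pd.DataFrame, columns: Sequence[str], n_retained: int = 2
) -> PcaResult:
    """PCA on scaled-and-centred variables via eigendecomposition of the
    correlation matrix.

    Loadings are the (orthonormal) eigenvectors, sign-fixed so each
    component's largest-magnitude loading is positive; scores are the
    standardised data projected onto the retained components.
    """
    if n_retained < 1:
        raise ValidationError("n_retained must be >= 1")
    cols = list(columns)
    X = data[cols].to_numpy(dtype=float)
    sd = X.std(axis=0, ddof=1)
    zero_var = [c for c, s in zip(cols, sd) if s == 0 or not np.isfinite(s)]
    if zero_var:
        raise ValidationError(f"zero-variance columns: {zero_var}")
    Z = (X - X.mean(axis=0)) / sd
    corr = np.corrcoef(Z, rowvar=False)
    values, vectors = np.linalg.eigh(corr)
    order = np.argsort(values)[::-1]
    values = values[order]
    vectors = vectors[:, order]
    for k in range(vectors.shape[1]):
        pivot = np.argmax(np.abs(vectors[:, k]))
        if vectors[pivot, k] < 0:
            vectors[:, k] = -vectors[:, k]
    frac = values / values.sum()
    n_retained = min(n_retained, len(cols))
    return PcaResult(
        variables=tuple(cols),
        loadings=vectors,
        explained_variance_fraction=frac,
        scores=Z @ vectors[:, :n_retained],
        n_retained=n_retained,
    )


def summarise_trends(
    frame: pd.DataFrame, metrics: Sequence[str] | None = None
) -> pd.DataFrame:
    """Per-calendar-year mean, median and central 95% interval per metric.

    The attribute ``lambda1_below_1_year`` on the result records the first
    year whose annual mean lambda_1 drops below one (None if it never
    does).
    """
    if frame.empty:
        raise ValidationError("metrics table is empty")
    metrics = list(
        metrics
        if metrics is not None
        else [c for c in frame.columns if c not in ("country", "year")]
    )
    rows = []
    for year, group in frame.groupby("year", sort=True):
        for m in metrics:
            v = group[m].to_numpy(dtype=float)
            v = v[np.isfinite(v)]
            if v.size == 0:
                continue
            rows.append(
                (
                    int(year), m, float(np.mean(v)), float(np.median(v)),
                    float(np.quantile(v, 0.025)), float(np.quantile(v, 0.975)),
                )
            )
    out = pd.DataFrame(
        rows, columns=["year", "metric", "mean", "median", "q025", "q975"]
    )
    below = None
    if "lambda1" in metrics:
        lam = out[out["metric"] == "lambda1"].sort_values("year")
        hit = lam.loc[lam["mean"] < 1.0, "year"]
        below = int(hit.iloc[0]) if len(hit) else None
    out.attrs["lambda1_below_1_year"] = below
    return out


def write_frame(frame: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    frame.to_csv(path, index=index)
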