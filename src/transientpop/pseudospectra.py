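"""Pseudospectra of projection matrices.

The epsilon-pseudospectrum of A is the set of complex z with
sigma_min(zI - A) <= epsilon: equivalently, the union of the eigenvalues
of all perturbations A + E with ||E|| <= epsilon.  Where eigenvalues give
only the asymptotic picture, pseudospectra show how fragile that picture
is — eigenvalues of a non-normal matrix can move far under small
perturbations, and low-valued contours reaching far from the spectrum
signal proneness to transient amplification.  Age-structured projection
matrices have many zero eigenvalues (the post-reproductive tail), which
are highly perturbation-sensitive and produce the characteristic broad
pseudospectral plateau around the origin.

The grid stores sigma_min(zI - A) on an evenly spaced complex-plane
raster; since A is real the map is conjugate-symmetric, so only the upper
half-plane is computed and mirrored.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ValidationError
from .matrix import ProjectionMatrix

logger = logging.getLogger(__name__)

#: default points per axis of the raster
DEFAULT_RESOLUTION = 201
#: default fractional margin around the spectrum for the bounding box
DEFAULT_MARGIN = 0.2
#: default contour levels: powers of ten from 1e-8 up to 1
DEFAULT_LEVELS = tuple(10.0 ** k for k in range(-8, 1))


@dataclass(frozen=True)
class Box:
    """Axis-aligned bounding box in the complex plane."""

    re_min: float
    re_max: float
    im_min: float
    im_max: float


@dataclass
class PseudospectrumGrid:
    """sigma_min(zI - A) on an evenly spaced complex grid.

    ``sigma_min[i, j]`` corresponds to z = real_axis[j] + 1j*imag_axis[i].
    """

    real_axis: np.ndarray
    imag_axis: np.ndarray
    sigma_min: np.ndarray
    eigenvalues: np.ndarray
    levels: tuple[float, ...] = DEFAULT_LEVELS
    country: str = ""
    year: int = 0

    @property
    def inverse_height(self) -> np.ndarray:
        """1/sigma_min, the 'height' used in perspective plots (eigenvalues
        have infinite height)."""
        with np.errstate(divide="ignore"):
            return 1.0 / self.sigma_min


def grid_bounds(eigenvalues, margin: float = DEFAULT_MARGIN) -> Box:
    """Bounding box covering the spectrum, expanded by ``margin`` times the
    larger spectral extent and symmetric about the real axis."""
    lam = np.atleast_1d(np.asarray(eigenvalues, dtype=complex))
    if lam.size == 0:
        raise ValidationError("need at least one eigenvalue")
    re_lo, re_hi = lam.real.min(), lam.real.max()
    im_hi = np.abs(lam.imag).max()
    extent = max(re_hi - re_lo, 2 * im_hi)
    if extent == 0:
        # single (or fully degenerate) spectrum: fall back to a box of
        # nonzero area around the point
        extent = max(float(np.abs(lam).max()), 1.0)
    pad = margin * extent
    return Box(
        re_min=float(re_lo - pad),
        re_max=float(re_hi + pad),
        im_min=float(-(im_hi + pad)),
        im_max=float(im_hi + pad),
    )


def sigma_min_grid(
    A,
    box: Box | None = None,
    resolution: int = DEFAULT_RESOLUTION,
    levels: tuple[float, ...] = DEFAULT_LEVELS,
) -> PseudospectrumGrid:
    """Compute sigma_min(zI - A) over the raster.

    For real A the conjugate symmetry sigma_min(conj(z)) = sigma_min(z) is
    exploited: rows with negative imaginary part whose mirror row exists in
    the grid are copied rather than recomputed.
    """
    if resolution < 2:
        raise ValidationError("resolution must be >= 2")
    country = year = None
    if isinstance(A, ProjectionMatrix):
        country, year = A.country, A.year
        M = A.entries
    else:
        M = np.asarray(A, dtype=float)
        if M.ndim != 2 or M.shape[0] != M.shape[1]:
            raise ValidationError(f"expected a square matrix, got {M.shape}")
    lam = np.linalg.eigvals(M)
    if box is None:
        box = grid_bounds(lam)
    re = np.linspace(box.re_min, box.re_max, resolution)
    im = np.linspace(box.im_min, box.im_max, resolution)
    sig = np.full((resolution, resolution), np.nan)
    eye = np.eye(M.shape[0])

    # map each negative-imaginary row onto its mirror if present
    tol = 1e-12 * max(1.0, np.abs(im).max())
    mirror: dict[int, int] = {}
    for i, v in enumerate(im):
        if v < 0:
            j = np.argmin(np.abs(im + v))
            if abs(im[j] + v) <= tol:
                mirror[i] = int(j)

    for i, v in enumerate(im):
        if i in mirror:
            continue
        for j, u in enumerate(re):
            shifted = (u + 1j * v) * eye - M
            sig[i, j] = np.linalg.svd(shifted, compute_uv=False)[-1]
    for i, j in mirror.items():
        sig[i] = sig[j]
    return PseudospectrumGrid(
        real_axis=re,
        imag_axis=im,
        sigma_min=sig,
        eigenvalues=lam,
        levels=tuple(sorted(levels)),
        country=country or "",
        year=year or 0,
    )


@dataclass
class EncapsulationEntry:
    """Whether one eigenvalue's epsilon-sublevel component also contains
    another eigenvalue, on the rasterised grid."""

    eigenvalue: complex
    level: float
    shares_component: bool
    component_cells: int


def _nearest_cell(grid: PseudospectrumGrid, z: complex) -> tuple[int, int]:
    i = int(np.argmin(np.abs(grid.imag_axis - z.imag)))
    j = int(np.argmin(np.abs(grid.real_axis - z.real)))
    return i, j


def contour_summary(
    grid: PseudospectrumGrid, levels: tuple[float, ...] | None = None
) -> list[EncapsulationEntry]:
    """Per-eigenvalue encapsulation report.

    For each eigenvalue and each epsilon level, reports whether the
    connected sublevel region {sigma_min <= epsilon} containing that
    eigenvalue's nearest grid cell also contains another eigenvalue, and
    how many grid cells the region covers.  Levels below the grid's
    minimum produce an empty sublevel set and are skipped with a warning.
    """
    levels = tuple(sorted(levels if levels is not None else grid.levels))
    floor = float(np.nanmin(grid.sigma_min))
    cells = [_nearest_cell(grid, z) for z in grid.eigenvalues]
    out: list[EncapsulationEntry] = []
    for eps in levels:
        mask = grid.sigma_min <= eps
        if not mask.any():
            warnings.warn(
                f"level {eps:g} below the grid floor {floor:g}; skipped",
                stacklevel=2,
            )
            continue
        labels, _ = ndimage.label(mask)
        comp = [labels[i, j] for (i, j) in cells]
        counts = np.bincount(labels.ravel())
        for k, z in enumerate(grid.eigenvalues):
            c = comp[k]
            if c == 0:
                # the eigenvalue's nearest cell is above the level (grid
                # too coarse for this epsilon); report no component
                out.append(EncapsulationEntry(complex(z), eps, False, 0))
                continue
            shared = any(
                comp[m] == c for m in range(len(comp)) if m != k
            )
            out.append(
                EncapsulationEntry(complex(z), eps, shared, int(counts[c]))
            )
    return out


def render_grid(
    grid: PseudospectrumGrid,
    contour_path: str | Path | None = None,
    perspective_path: str | Path | None = None,
) -> None:
    """Render the grid as a contour plot and/or a perspective surface of
    1/sigma_min (eigenvalues appear as dots / infinite peaks)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if contour_path is not None:
        fig, ax = plt.subplots(figsize=(6, 5))
        cs = ax.contour(
            grid.real_axis, grid.imag_axis, grid.sigma_min,
            levels=list(grid.levels),
        )
        ax.clabel(cs, inline=True, fontsize=7, fmt="%.0e")
        ax.plot(grid.eigenvalues.real, grid.eigenvalues.imag, "k.", ms=4)
        ax.set_xlabel("Re(z)")
        ax.set_ylabel("Im(z)")
        ax.set_title(r"$\sigma_{\min}(zI - A)$")
        fig.savefig(contour_path, dpi=150, bbox_inches="tight")
        plt.close(fig)

    if perspective_path is not None:
        fig = plt.figure(figsize=(6, 5))
        ax = fig.add_subplot(projection="3d")
        rr, ii = np.meshgrid(grid.real_axis, grid.imag_axis)
        height = np.minimum(grid.inverse_height, np.nanmax(
            np.where(np.isfinite(grid.inverse_height), grid.inverse_height, 0)
        ))
        ax.plot_surface(rr, ii, height, cmap="viridis", linewidth=0)
        ax.set_xlabel("Re(z)")
        ax.set_ylabel("Im(z)")
        ax.set_zlabel(r"$1/\sigma_{\min}$")
        fig.savefig(perspective_path, dpi=150, bbox_inches="tight")
        plt.close(fig)


def write_grid_csv(grid: PseudospectrumGrid, path: str | Path) -> None:
    """Export the grid in long format (re, im, sigma_min) plus a sidecar
    '<path>.levels' file with one contour level per line."""
    rr, ii = np.meshgrid(grid.real_axis, grid.imag_axis)
    frame = pd.DataFrame(
        {"re": rr.ravel(), "im": ii.ravel(), "sigma_min": grid.sigma_min.ravel()}
    )
    frame.to_csv(path, index=False)
    Path(str(path) + ".levels").write_text(
        "\n".join(f"{lvl:g}" for lvl in grid.levels) + "\n"
    )
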