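"""Spectral unmixing of multichannel brightfield stain images.

A transmitted-light image of chromogen-stained tissue follows Beer-Lambert
behaviour: optical density ``OD = log10(blank / I)`` is, per pixel and
wavelength band, a linear combination of stain concentrations weighted by
each stain's absorbance spectrum.  Unmixing inverts that model: given the
per-band absorbance spectra of the stains, solve a non-negative least-squares
problem per pixel for the stain concentrations.

Two solver modes are provided:

* fixed spectra (default): the spectra are held constant and the problem
  separates into one small NNLS solve per pixel -- deterministic and direct;
* alternating refinement: spectra and concentrations are alternately
  re-estimated under non-negativity, for when the supplied spectra are only
  approximate.

Concentrations are never renormalised: per-pixel sums are unconstrained.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls

__all__ = [
    "SpectralCube",
    "StainSpectrum",
    "ConcentrationMaps",
    "to_optical_density",
    "mcr_als_unmix",
]

logger = logging.getLogger(__name__)

#: intensity floor (camera counts) applied before the log transform
INTENSITY_FLOOR = 1.0


@dataclass
class SpectralCube:
    """A wavelength-indexed image stack.

    Parameters
    ----------
    data
        ``(rows, cols, bands)`` float array.  Raw camera intensities for an
        acquired cube, or optical densities after :func:`to_optical_density`.
    wavelengths
        Band-centre wavelengths in nm, strictly increasing, one per band.
    blank_reference
        Per-band blank-slide intensity used for calibration: either a
        ``(bands,)`` vector or a full ``(rows, cols, bands)`` image.
        ``None`` for OD-valued cubes.
    is_od
        Whether ``data`` holds optical densities rather than intensities.
    """

    data: np.ndarray
    wavelengths: np.ndarray
    blank_reference: np.ndarray | None = None
    is_od: bool = False
    n_clamped: int = 0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        self.wavelengths = np.asarray(self.wavelengths, dtype=float)
        if self.data.ndim != 3:
            raise ValueError("cube data must be (rows, cols, bands)")
        if self.data.shape[2] != self.wavelengths.size:
            raise ValueError(
                f"band count {self.data.shape[2]} != wavelength count "
                f"{self.wavelengths.size}"
            )
        if self.wavelengths.size > 1 and not np.all(np.diff(self.wavelengths) > 0):
            raise ValueError("wavelengths must be strictly increasing")
        if self.blank_reference is not None:
            self.blank_reference = np.asarray(self.blank_reference, dtype=float)
            if self.blank_reference.ndim not in (1, 3):
                raise ValueError("blank_reference must be per-band vector or image")
            if self.blank_reference.shape[-1] != self.n_bands:
                raise ValueError("blank_reference band count mismatch")

    @property
    def n_bands(self) -> int:
        return self.data.shape[2]

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape[:2]


@dataclass
class StainSpectrum:
    """Per-band absorbance coefficients of one stain.

    Absorbances are normalised to unit maximum on construction; the scale
    indeterminacy of the bilinear model is thereby pushed entirely into the
    concentrations.
    """

    name: str
    absorbance: np.ndarray

    def __post_init__(self) -> None:
        a = np.asarray(self.absorbance, dtype=float)
        if a.ndim != 1:
            raise ValueError(f"spectrum {self.name!r}: absorbance must be 1-D")
        if np.any(a < 0):
            raise ValueError(f"spectrum {self.name!r}: negative absorbance")
        peak = a.max()
        if peak <= 0:
            raise ValueError(f"spectrum {self.name!r}: all-zero absorbance")
        self.absorbance = a / peak


@dataclass
class ConcentrationMaps:
    """Per-stain concentration images plus model diagnostics."""

    stains: list[str]
    maps: dict[str, np.ndarray]
    residual: np.ndarray
    n_iterations: int
    converged: bool
    spectra: dict[str, np.ndarray] = field(default_factory=dict)

    def __getitem__(self, stain: str) -> np.ndarray:
        return self.maps[stain]

    def stack(self) -> np.ndarray:
        """Concentrations as a ``(rows, cols, n_stains)`` array in stain order."""
        return np.stack([self.maps[s] for s in self.stains], axis=-1)


def to_optical_density(cube: SpectralCube, floor: float = INTENSITY_FLOOR) -> SpectralCube:
    """Convert raw intensities to optical density against the blank reference.

    ``OD(p, b) = log10(blank(b) / I(p, b))``.  Intensities at or below
    ``floor`` are clamped up to it (their count is recorded on the returned
    cube and logged); OD is floored at 0 where intensity exceeds the blank,
    since negative absorbance is physically meaningless for chromogens.
    """
    if cube.is_od:
        raise ValueError("cube is already OD-valued")
    if cube.blank_reference is None:
        raise ValueError("blank reference required for optical-density conversion")
    if floor <= 0:
        raise ValueError("intensity floor must be positive")
    intensity = cube.data
    n_clamped = int(np.count_nonzero(intensity < floor))
    if n_clamped:
        logger.warning("clamped %d non-positive/low intensities to %g", n_clamped, floor)
    intensity = np.maximum(intensity, floor)
    blank = cube.blank_reference
    if blank.ndim == 1:
        blank = blank[np.newaxis, np.newaxis, :]
    od = np.log10(np.maximum(blank, floor) / intensity)
    np.maximum(od, 0.0, out=od)
    return SpectralCube(
        data=od,
        wavelengths=cube.wavelengths,
        blank_reference=None,
        is_od=True,
        n_clamped=n_clamped,
    )


def _spectra_matrix(spectra: list[StainSpectrum], n_bands: int) -> np.ndarray:
    S = np.stack([sp.absorbance for sp in spectra])  # (n_stains, n_bands)
    if S.shape[1] != n_bands:
        raise ValueError(
            f"spectra have {S.shape[1]} bands but cube has {n_bands}"
        )
    if np.linalg.matrix_rank(S) < S.shape[0]:
        # locate the most collinear pair for the error message
        G = S @ S.T
        norms = np.sqrt(np.diag(G))
        cos = G / np.outer(norms, norms)
        np.fill_diagonal(cos, 0.0)
        i, j = np.unravel_index(np.argmax(np.abs(cos)), cos.shape)
        raise ValueError(
            "stain spectra are rank deficient; most collinear pair: "
            f"{spectra[i].name!r} and {spectra[j].name!r}"
        )
    return S


def _nnls_pixels(X: np.ndarray, S: np.ndarray) -> np.ndarray:
    """Non-negative least squares ``min ||x - c @ S||`` for each row of X.

    Fast path: the unconstrained solution is accepted wherever it is already
    non-negative (it then coincides with the NNLS optimum); remaining pixels
    fall back to an active-set solve.
    """
    C, *_ = np.linalg.lstsq(S.T, X.T, rcond=None)
    C = C.T  # (npix, n_stains)
    bad = np.any(C < 0, axis=1)
    if np.any(bad):
        idx = np.flatnonzero(bad)
        ST = S.T
        for k in idx:
            C[k], _ = nnls(ST, X[k])
    np.maximum(C, 0.0, out=C)
    return C


def mcr_als_unmix(
    od: SpectralCube,
    spectra: list[StainSpectrum],
    max_iter: int = 50,
    tol: float = 1e-6,
    refine_spectra: bool = False,
) -> ConcentrationMaps:
    """Decompose an OD cube into per-stain concentration maps.

    With ``refine_spectra=False`` (default) the supplied spectra are held
    fixed and each pixel is an independent NNLS solve — direct and
    deterministic.  With ``refine_spectra=True`` the spectra themselves are
    alternately re-estimated under non-negativity, starting from the supplied
    spectra, until the relative residual change falls below ``tol``.

    Returns
    -------
    ConcentrationMaps
        Non-negative concentration image per stain, per-pixel residual norm
        ``||OD_pixel - c @ S||``, iteration count and convergence flag.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    if not np.all(np.isfinite(od.data)):
        raise ValueError("OD cube contains non-finite values")
    S = _spectra_matrix(spectra, od.n_bands)
    rows, cols, bands = od.data.shape
    X = od.data.reshape(-1, bands)

    if not refine_spectra:
        C = _nnls_pixels(X, S)
        n_iter, converged = 1, True
    else:
        C = _nnls_pixels(X, S)
        prev = np.linalg.norm(X - C @ S)
        converged = False
        n_iter = 0
        for n_iter in range(1, max_iter + 1):
            # re-estimate spectra rows under non-negativity, then renormalise
            # to unit maximum, folding the scale back into the concentrations
            S_new = _nnls_pixels(X.T, C.T)  # (bands, n_stains) -> transpose
            S_new = S_new.T
            peaks = S_new.max(axis=1)
            peaks[peaks <= 0] = 1.0
            S = S_new / peaks[:, None]
            C = _nnls_pixels(X, S)
            res = np.linalg.norm(X - C @ S)
            norm_x = np.linalg.norm(X)
            if res <= tol * max(norm_x, 1e-300) or (
                prev > 0 and abs(prev - res) / prev < tol
            ):
                converged = True
                break
            prev = res

    residual = np.linalg.norm(X - C @ S, axis=1).reshape(rows, cols)
    names = [sp.name for sp in spectra]
    maps = {name: C[:, k].reshape(rows, cols) for k, name in enumerate(names)}
    return ConcentrationMaps(
        stains=names,
        maps=maps,
        residual=residual,
        n_iterations=n_iter,
        converged=converged,
        spectra={name: S[k].copy() for k, name in enumerate(names)},
    )
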