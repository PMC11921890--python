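"""ROI spectral analysis, region-restricted PCA and characteristic-wavelength
selection.

The hyperspectral cube is far too redundant for real-time detection, so a
small number of characteristic wavelengths is chosen to represent a whole
spectral region.  The procedure: gather regions of interest (ROIs) per
material, smooth their mean reflectance curves with a cubic smoothing
spline, run covariance PCA on the bands inside a chosen region, form the
per-wavelength weight-coefficient curve of one principal component
(eigenvalue x loading), and pick wavelengths at widely separated extrema of
that curve.  On the study's own cubes this yields 580, 680 and 850 nm.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.interpolate import make_smoothing_spline

from .cube import SpectralCube
from .synth import MATERIAL_NAMES


@dataclasses.dataclass
class ROISet:
    """Per-material pixel-spectra matrices plus (smoothed) mean curves."""

    spectra: dict[str, np.ndarray]  # material -> (n_pixels, B)
    wavelengths: np.ndarray
    min_pixels: int = 0  # configurable lower bound; 8000 for full-size scenes

    def __post_init__(self) -> None:
        for name, mat in self.spectra.items():
            if mat.ndim != 2 or mat.shape[1] != self.wavelengths.size:
                raise ValueError(f"ROI {name!r}: spectra must be (n_pixels, B)")
            if mat.shape[0] < self.min_pixels:
                raise ValueError(
                    f"ROI {name!r}: {mat.shape[0]} pixels < required {self.min_pixels}"
                )

    def mean_curve(self, material: str) -> np.ndarray:
        return self.spectra[material].mean(axis=0)

    def smoothed_mean_curve(self, material: str) -> np.ndarray:
        return smooth_curve(self.mean_curve(material), self.wavelengths)

    def pooled(self, materials=None) -> np.ndarray:
        """Stacked pixel spectra over the given materials (default: all)."""
        keys = materials if materials is not None else list(self.spectra)
        return np.concatenate([self.spectra[k] for k in keys], axis=0)


def build_roiset(scenes, materials=MATERIAL_NAMES, max_pixels_per_roi=30000,
                 min_pixels=0, seed: int = 0) -> ROISet:
    """Extract per-material ROIs from synthetic scenes' label maps.

    Pools pixels of each material over all scenes (post-occlusion label
    maps), subsampling to at most ``max_pixels_per_roi`` — mirroring manual
    ROI extraction bounded at 8,000-30,000 pixels on full-size frames.
    """
    rng = np.random.default_rng(seed)
    spectra: dict[str, list[np.ndarray]] = {m: [] for m in materials}
    wavelengths = None
    for scene in scenes:
        if scene.cube is None or scene.label_map is None:
            raise ValueError("build_roiset needs scenes rendered with cubes")
        wavelengths = scene.cube.wavelengths
        flat = scene.cube.data.reshape(-1, scene.cube.n_bands)
        lab = scene.label_map.reshape(-1)
        for idx, m in enumerate(MATERIAL_NAMES):
            if m in spectra:
                spectra[m].append(flat[lab == idx])
    out = {}
    for m, chunks in spectra.items():
        mat = np.concatenate(chunks, axis=0)
        if mat.shape[0] > max_pixels_per_roi:
            sel = rng.choice(mat.shape[0], size=max_pixels_per_roi, replace=False)
            mat = mat[sel]
        out[m] = mat
    return ROISet(out, wavelengths, min_pixels=min_pixels)


def smooth_curve(curve: np.ndarray, wavelengths: np.ndarray | None = None,
                 max_rms: float | None = None) -> np.ndarray:
    """Cubic smoothing-spline fit of a reflectance curve on its own grid.

    Uses a GCV-selected smoothing parameter, which reproduces constant and
    linear inputs exactly and attenuates band-to-band noise otherwise.
    ``max_rms`` optionally asserts a residual bound.
    """
    curve = np.asarray(curve, dtype=np.float64)
    if curve.ndim != 1 or curve.size < 10:
        raise ValueError("curve must be a vector with at least 10 bands")
    if not np.all(np.isfinite(curve)):
        raise ValueError("curve contains non-finite values")
    x = (np.arange(curve.size, dtype=np.float64)
         if wavelengths is None else np.asarray(wavelengths, dtype=np.float64))
    smoothed = make_smoothing_spline(x, curve)(x)
    if max_rms is not None:
        rms = float(np.sqrt(np.mean((smoothed - curve) ** 2)))
        if rms > max_rms:
            raise ValueError(f"spline residual RMS {rms:.4g} exceeds bound {max_rms}")
    return smoothed


@dataclasses.dataclass
class PCAResult:
    """Covariance PCA of mean-centered spectra restricted to one region."""

    region: tuple[float, float]
    wavelengths: np.ndarray      # region wavelengths, length m
    eigenvalues: np.ndarray      # descending, length m
    loadings: np.ndarray         # (m, m); row i = unit-norm eigenvector of PC i+1
    scores: np.ndarray           # (n_pixels, m) centered data projected on loadings
    image_shape: tuple[int, int] | None = None  # set when built from a cube

    def score_image(self, pc: int) -> np.ndarray:
        """H x W score plane of 1-based component ``pc`` (cube input only)."""
        if self.image_shape is None:
            raise ValueError("PCA was not computed from a cube")
        return self.scores[:, pc - 1].reshape(self.image_shape)

    @property
    def n_components(self) -> int:
        return self.eigenvalues.size


def pca_region(data, wavelengths=None, region=(450.0, 850.0)) -> PCAResult:
    """Covariance-matrix PCA on the bands inside ``region`` (inclusive, nm).

    ``data`` is either a :class:`SpectralCube` or an (n_pixels, B) matrix
    with ``wavelengths`` supplied.  Spectra are mean-centered but not
    standardized (bands share reflectance units).  Requires more pixel
    samples than region bands.
    """
    image_shape = None
    if isinstance(data, SpectralCube):
        wavelengths = data.wavelengths
        image_shape = data.shape[:2]
        X = data.data.reshape(-1, data.n_bands).astype(np.float64)
    else:
        if wavelengths is None:
            raise ValueError("wavelengths required with matrix input")
        X = np.asarray(data, dtype=np.float64)
        wavelengths = np.asarray(wavelengths, dtype=np.float64)
    lo, hi = region
    if lo < 400.0 - 1e-9 or hi > 900.0 + 1e-9 or lo >= hi:
        raise ValueError(f"region {region} must lie within [400, 900] nm")
    sel = (wavelengths >= lo - 1e-9) & (wavelengths <= hi + 1e-9)
    wl = wavelengths[sel]
    Xr = X[:, sel]
    n, m = Xr.shape
    if n <= m:
        raise ValueError(f"rank-deficient sample: {n} pixels for {m} bands")
    Xc = Xr - Xr.mean(axis=0)
    cov = (Xc.T @ Xc) / (n - 1)
    evals, evecs = np.linalg.eigh(cov)
    order = np.argsort(evals)[::-1]
    evals = np.clip(evals[order], 0.0, None)
    loadings = evecs[:, order].T  # rows = eigenvectors
    scores = Xc @ loadings.T
    return PCAResult((float(lo), float(hi)), wl, evals, loadings, scores, image_shape)


def weight_curve(pca: PCAResult, pc: int) -> np.ndarray:
    """Weight-coefficient curve of 1-based component ``pc``.

    gamma_j = alpha_pc * beta_{pc,j}: the component's eigenvalue scales its
    loading at each wavelength.  Extremum *locations* are invariant to any
    positive per-component rescaling of the eigenvalue (e.g. sqrt(alpha)),
    so wavelength selection does not depend on that convention.
    """
    if not 1 <= pc <= pca.n_components:
        raise ValueError(f"pc must be in 1..{pca.n_components}")
    return pca.eigenvalues[pc - 1] * pca.loadings[pc - 1]


def select_wavelengths(gamma: np.ndarray, wavelengths: np.ndarray, k: int = 3,
                       min_sep: float = 80.0) -> list[float]:
    """Pick ``k`` widely separated wavelengths at extrema of a weight curve.

    Candidates are the interior local extrema of ``gamma`` (sign changes of
    the first difference) plus the region endpoints.  Candidates are taken
    greedily in descending |gamma| (ties broken toward the lower
    wavelength), subject to pairwise separation >= ``min_sep`` nm; the
    selected wavelengths are returned sorted ascending.
    """
    gamma = np.asarray(gamma, dtype=np.float64)
    wavelengths = np.asarray(wavelengths, dtype=np.float64)
    if gamma.size != wavelengths.size:
        raise ValueError("gamma and wavelengths must have equal length")
    if gamma.size < 2 * k + 1:
        raise ValueError("curve too short for requested k")
    d = np.diff(gamma)
    sign = np.sign(d)
    # propagate through zero-difference plateaus
    for i in range(1, sign.size):
        if sign[i] == 0:
            sign[i] = sign[i - 1]
    interior = [i + 1 for i in range(sign.size - 1)
                if sign[i] != 0 and sign[i + 1] != 0 and sign[i] != sign[i + 1]]
    candidates = sorted(set(interior) | {0, gamma.size - 1})
    # descending |gamma|, ties toward lower wavelength
    candidates.sort(key=lambda i: (-abs(gamma[i]), wavelengths[i]))
    chosen: list[int] = []
    for i in candidates:
        if all(abs(wavelengths[i] - wavelengths[j]) >= min_sep for j in chosen):
            chosen.append(i)
        if len(chosen) == k:
            break
    if len(chosen) < k:
        raise ValueError(
            f"insufficient extrema: only {len(chosen)} admissible candidates "
            f"for k={k} at min_sep={min_sep} nm"
        )
    return sorted(float(wavelengths[i]) for i in chosen)


def select_characteristic_bands(data, wavelengths=None, region=(450.0, 850.0),
                                pc: int = 4, k: int = 3,
                                min_sep: float = 80.0) -> list[float]:
    """End-to-end: region PCA -> weight curve of ``pc`` -> wavelength triple.

    The component used for selection is configurable; the default (PC 4 of
    the 450-850 nm region) is the one whose score image best isolates
    contaminant contours on the study's belt scenes.
    """
    res = pca_region(data, wavelengths, region)
    gamma = weight_curve(res, pc)
    return select_wavelengths(gamma, res.wavelengths, k=k, min_sep=min_sep)
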