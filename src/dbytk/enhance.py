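"""Pseudo-color composition (PCC) and decorrelation contrast stretch (DCS).

The three characteristic bands become one 3-channel image in two ways:

* PCC — each band min-max scaled to 8-bit and assigned to R/G/B by
  descending wavelength (the NIR-as-red false-color convention);
* DCS — the channel covariance is whitened symmetrically
  (V diag(1/sqrt(lambda)) V^T, preserving channel identity), each output
  channel is rescaled to a target SD and re-centered at the original
  channel means, then clipped to 8-bit.  Whitening removes inter-channel
  correlation, which exaggerates the color differences between materials.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .cube import SpectralCube, band_slice, minmax_to_uint8


@dataclasses.dataclass
class EnhancedImage:
    """3-channel 8-bit enhanced image plus the parameters that made it."""

    pixels: np.ndarray
    kind: str  # "PCC" or "DCS"
    band_map: tuple[float, float, float] | None = None  # (R, G, B) wavelengths
    stretch_params: dict | None = None

    def __post_init__(self) -> None:
        if self.pixels.dtype != np.uint8 or self.pixels.ndim != 3 \
                or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be H x W x 3 uint8")
        if self.kind not in ("PCC", "DCS"):
            raise ValueError(f"unknown kind {self.kind!r}")


def pseudo_color(cube: SpectralCube, triple) -> EnhancedImage:
    """Compose a false-color image from three characteristic wavelengths.

    Bands are assigned to channels by descending wavelength -> (R, G, B),
    each independently min-max scaled to [0, 255] (a constant band maps to
    a zero channel).
    """
    triple = [float(t) for t in triple]
    if len(triple) != 3 or len(set(triple)) != 3:
        raise ValueError("need three distinct wavelengths")
    ordered = tuple(sorted(triple, reverse=True))
    channels = [minmax_to_uint8(band_slice(cube, lam)) for lam in ordered]
    return EnhancedImage(np.stack(channels, axis=-1), "PCC", band_map=ordered)


def _dcs_transform(img: np.ndarray, target_sd: float, ridge: float | None):
    """Float-valued DCS (no clipping); returns (out, params)."""
    x = np.asarray(img, dtype=np.float64)
    flat = x.reshape(-1, 3)
    mu = flat.mean(axis=0)
    cov = np.cov(flat, rowvar=False)
    tr = float(np.trace(cov))
    if tr <= 0.0:
        raise ValueError("degenerate covariance: image is constant")
    eps = 0.0 if ridge is None else (ridge if ridge > 0 else 0.0)
    if ridge == "auto" or (ridge is not None and ridge < 0):
        raise ValueError("ridge must be None or a non-negative float")
    cov_r = cov + eps * np.eye(3)
    evals, evecs = np.linalg.eigh(cov_r)
    if evals.min() <= tr * 1e-12:
        raise ValueError(
            "degenerate covariance: channels linearly dependent "
            "(enable ridge regularization)"
        )
    whiten = evecs @ np.diag(1.0 / np.sqrt(evals)) @ evecs.T
    y = (flat - mu) @ whiten.T
    y *= target_sd
    y += mu
    params = {
        "channel_means": mu,
        "covariance": cov,
        "eigenvalues": evals,
        "eigenvectors": evecs,
        "target_sd": target_sd,
        "ridge": eps,
    }
    return y.reshape(x.shape), params


def default_ridge(img: np.ndarray) -> float:
    """Default ridge: 1e-6 x trace(channel covariance) / 3."""
    flat = np.asarray(img, dtype=np.float64).reshape(-1, 3)
    return 1e-6 * float(np.trace(np.cov(flat, rowvar=False))) / 3.0


def decorrelation_stretch(
    img: np.ndarray,
    target_sd: float = 100.0,
    clip: tuple[float, float] = (0.0, 255.0),
    ridge: float | None = "default",
    return_float: bool = False,
):
    """Decorrelation-stretch a 3-channel image.

    After symmetric whitening each channel is white with unit SD; scaling by
    ``target_sd`` and re-centering at the original channel means yields an
    image whose pre-clip channels are uncorrelated with SD ``target_sd``.
    ``ridge`` regularizes the covariance (default 1e-6 x trace/3); pass
    ``ridge=None`` to disable, which raises on rank-deficient input.  With
    ``return_float`` the un-clipped float image is returned alongside.
    """
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("img must be H x W x 3")
    eps = default_ridge(img) if ridge == "default" else ridge
    y, params = _dcs_transform(img, float(target_sd), eps)
    pixels = np.clip(np.round(y), clip[0], clip[1]).astype(np.uint8)
    out = EnhancedImage(pixels, "DCS", stretch_params=params)
    if return_float:
        return out, y
    return out


def enhance_scene(scene, triple, target_sd: float = 100.0) -> None:
    """Attach PCC-composed + decorrelation-stretched image to a scene.

    The DCS image is computed from the PCC composite of the characteristic
    bands and stored on ``scene.dcs`` (``scene.pcc`` keeps the composite).
    """
    if scene.cube is None:
        raise ValueError("scene has no cube to enhance")
    pcc = pseudo_color(scene.cube, triple)
    dcs = decorrelation_stretch(pcc.pixels.astype(np.float64), target_sd=target_sd)
    dcs.band_map = pcc.band_map
    scene.pcc = pcc.pixels
    scene.dcs = dcs.pixels
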