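"""Beer-Lambert stain separation for hematoxylin + DAB brightfield IHC.

Chromogenic IHC images are absorbance mixtures: each stain attenuates
transmitted light multiplicatively, so in optical-density (OD) space the
stains add linearly and can be unmixed with a 3x3 stain matrix.  This module
converts 8-bit RGB pixels to base-10 OD, unmixes them into per-stain
concentration maps (hematoxylin marks nuclei, DAB marks the antigen), and
provides a reconstruction-error QC metric.

Stain vectors default to the Ruifrok-Johnston H-DAB constants; they can be
overridden per run (``stains.hematoxylin`` / ``stains.dab`` config keys).
"""

from __future__ import annotations

import numpy as np

from .exceptions import DegeneracyError, FormatError, ParameterError

#: Ruifrok-Johnston H-DAB absorbance vectors (unit length, RGB order).
HEMATOXYLIN = (0.650, 0.704, 0.286)
DAB = (0.268, 0.570, 0.776)

_MAX_CONDITION = 1e6


def rgb_to_od(img: np.ndarray, i0=255.0, eps_intensity: float = 1.0) -> np.ndarray:
    """Convert an 8-bit RGB image to base-10 optical density.

    ``OD_c = -log10(max(I_c, eps_intensity) / i0_c)``.  The intensity floor
    ``eps_intensity`` keeps saturated-dark pixels at a finite OD.

    Parameters
    ----------
    img : (H, W, 3) uint8 array
    i0 : scalar or length-3 white reference (transmitted intensity of clean
        glass), default 255 per channel.
    eps_intensity : intensity floor in (0, 1].

    Returns
    -------
    (H, W, 3) float64 array of non-negative optical densities.
    """
    img = np.asarray(img)
    if img.ndim != 3 or img.shape[2] != 3:
        raise FormatError(f"expected an (H, W, 3) RGB image, got shape {img.shape}")
    if img.dtype != np.uint8:
        raise FormatError(f"expected 8-bit input, got dtype {img.dtype}")
    i0 = np.broadcast_to(np.asarray(i0, dtype=float), (3,))
    if np.any(i0 <= 0):
        raise ParameterError("white reference i0 must be positive in every channel")
    if not (0.0 < eps_intensity <= 1.0):
        raise ParameterError("eps_intensity must lie in (0, 1]")
    intensity = np.maximum(img.astype(np.float64), eps_intensity)
    return -np.log10(intensity / i0)


def build_stain_matrix(h_vec=HEMATOXYLIN, d_vec=DAB) -> np.ndarray:
    """Assemble a 3x3 stain matrix (rows: hematoxylin, DAB, residual).

    Rows 1-2 are the normalized input vectors; the residual row is the
    normalized cross product, giving a complete basis so unmixing is an
    exact 3x3 solve.
    """
    h = np.asarray(h_vec, dtype=float)
    d = np.asarray(d_vec, dtype=float)
    if h.shape != (3,) or d.shape != (3,):
        raise FormatError("stain vectors must have 3 components")
    hn, dn = np.linalg.norm(h), np.linalg.norm(d)
    if hn == 0 or dn == 0:
        raise DegeneracyError("stain vectors must be non-zero")
    h, d = h / hn, d / dn
    r = np.cross(h, d)
    rn = np.linalg.norm(r)
    if rn < 1e-8:
        raise DegeneracyError("hematoxylin and DAB vectors are collinear")
    m = np.stack([h, d, r / rn])
    if np.linalg.cond(m) >= _MAX_CONDITION:
        raise DegeneracyError("stain matrix is ill-conditioned")
    return m


def deconvolve(od: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Unmix an OD image into per-stain concentration maps.

    Per pixel solves ``od = m.T @ conc`` and clamps negative components
    (out-of-gamut noise) to zero.  Channel order follows the matrix rows:
    hematoxylin, DAB, residual.
    """
    od = np.asarray(od, dtype=float)
    m = np.asarray(m, dtype=float)
    if od.shape[-1] != 3 or m.shape != (3, 3):
        raise FormatError("od must have 3 channels and m must be 3x3")
    if np.linalg.cond(m) >= _MAX_CONDITION:
        raise DegeneracyError("stain matrix is singular or ill-conditioned")
    conc = od @ np.linalg.inv(m)
    np.clip(conc, 0.0, None, out=conc)
    return conc


def compose(conc: np.ndarray, m: np.ndarray) -> np.ndarray:
    """Forward Beer-Lambert mixing: concentrations -> OD image."""
    return np.asarray(conc, dtype=float) @ np.asarray(m, dtype=float)


def reconstruction_error(od: np.ndarray, m: np.ndarray, conc: np.ndarray) -> float:
    """Max absolute per-pixel difference between ``od`` and the re-mixed ``conc``.

    A QC metric: large values mean the image contains color outside the span
    of the stain basis (or clamping destroyed signal).
    """
    od = np.asarray(od, dtype=float)
    conc = np.asarray(conc, dtype=float)
    if od.shape != conc.shape:
        raise FormatError(f"shape mismatch: od {od.shape} vs conc {conc.shape}")
    return float(np.max(np.abs(od - compose(conc, m)))) if od.size else 0.0
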