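"""Colour deconvolution of stained histology with corrective stain parameters.

Transmitted-light microscopy obeys the Beer-Lambert law: the optical density
``OD_c = -log10(I_c / I0_c)`` in each RGB channel is the sum of the per-stain
densities weighted by each stain's characteristic unit absorbance vector.
Colour deconvolution inverts that mixing: given a 3x3 matrix whose rows are
the stains' unit OD vectors, applying the matrix inverse per pixel recovers
per-stain coefficient (density) images.

When the assumed stain vectors mismatch the image's true mixing, deconvolution
produces physically impossible *negative* coefficients.  This module exposes
two corrective parameters, ``p1`` and ``p2``, that rotate the first and second
stain vectors within the plane the two base vectors span (0 = no change), and
quality measures ``m1``-``m6`` built from the negative coefficients of each
stain: their percentage, mean and standard deviation.  Sweeping ``p1``/``p2``
and inspecting ``m1``-``m6`` is how the optimality of a published stain matrix
can be interrogated.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .sweep import Plugin

__all__ = [
    "RUIFROK_JOHNSON_HEMATOXYLIN",
    "RUIFROK_JOHNSON_EOSIN",
    "StainModel",
    "rgb_to_od",
    "od_to_rgb",
    "build_deconv_matrix",
    "deconvolve",
    "negative_coefficient_stats",
    "reconstruct_stain_image",
    "DeconvolutionPlugin",
]

# Standard H&E absorbance vectors (Ruifrok & Johnson's calibration),
# normalised to unit length below.  Hematoxylin absorbs strongly in red and
# green (nuclei appear blue); eosin absorbs mostly green (tissue appears pink).
RUIFROK_JOHNSON_HEMATOXYLIN = (0.650, 0.704, 0.286)
RUIFROK_JOHNSON_EOSIN = (0.072, 0.990, 0.105)


def _unit(v: np.ndarray) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    n = np.linalg.norm(v)
    if n == 0:
        raise ValueError("zero stain vector")
    return v / n


@dataclass(frozen=True)
class StainModel:
    """Stain OD vectors plus corrective rotation angles.

    ``base_vectors`` holds two or three unit absorbance vectors in OD(R,G,B)
    space, one row per stain, with non-negative components.  ``p1`` and ``p2``
    (radians) rotate stain 1 and stain 2 respectively within the plane spanned
    by the first two base vectors; ``p1 = p2 = 0`` reproduces the base matrix
    unchanged.  ``background`` is the per-channel incident intensity I0.
    """

    base_vectors: tuple[tuple[float, float, float], ...] = (
        RUIFROK_JOHNSON_HEMATOXYLIN,
        RUIFROK_JOHNSON_EOSIN,
    )
    p1: float = 0.0
    p2: float = 0.0
    background: tuple[float, float, float] = (255.0, 255.0, 255.0)

    def __post_init__(self) -> None:
        if len(self.base_vectors) not in (2, 3):
            raise ValueError("StainModel requires 2 or 3 stain vectors")
        vecs = []
        for v in self.base_vectors:
            u = _unit(np.asarray(v, dtype=float))
            if np.any(u < 0):
                raise ValueError("stain vectors must have non-negative components")
            vecs.append(tuple(float(x) for x in u))
        object.__setattr__(self, "base_vectors", tuple(vecs))
        if np.any(np.asarray(self.background) <= 0):
            raise ValueError("background intensity must be positive per channel")

    @property
    def unit_vectors(self) -> np.ndarray:
        """Base stain vectors as a (n_stains, 3) unit-row array."""
        return np.asarray(self.base_vectors, dtype=float)


def rgb_to_od(image: np.ndarray, background: float | tuple | np.ndarray) -> np.ndarray:
    """Beer-Lambert optical density ``-log10(I / I0)`` per channel.

    Intensities are clamped to ``[eps, I0]`` with ``eps = I0/255`` (one count
    on the 8-bit scale) before the log, so fully dark pixels map to a large
    finite density instead of infinity.  ``OD(I0) = 0`` exactly.
    """
    i0 = np.broadcast_to(np.asarray(background, dtype=float), np.shape(image)[-1:] or (1,))
    if np.any(i0 <= 0):
        raise ValueError("background intensity I0 must be positive")
    image = np.asarray(image, dtype=float)
    if np.any(image < 0):
        raise ValueError("intensities must be non-negative")
    eps = i0 / 255.0
    clamped = np.clip(image, eps, i0)
    return -np.log10(clamped / i0)


def od_to_rgb(od: np.ndarray, background: float | tuple | np.ndarray) -> np.ndarray:
    """Inverse of :func:`rgb_to_od` (float result, not quantised)."""
    i0 = np.asarray(background, dtype=float)
    return i0 * np.power(10.0, -np.asarray(od, dtype=float))


def _rotate_in_plane(v: np.ndarray, e1: np.ndarray, e2: np.ndarray, angle: float) -> np.ndarray:
    """Rotate unit vector *v* by *angle* within the plane spanned by (e1, e2)."""
    a = float(v @ e1)
    b = float(v @ e2)
    out_of_plane = v - a * e1 - b * e2
    c, s = np.cos(angle), np.sin(angle)
    rotated = (a * c - b * s) * e1 + (a * s + b * c) * e2 + out_of_plane
    return _unit(rotated)


def build_deconv_matrix(model: StainModel) -> np.ndarray:
    """Deconvolution matrix: inverse of the corrected row-vector stain matrix.

    Stain 1 is rotated by ``p1`` and stain 2 by ``p2`` within the plane
    spanned by the two base vectors (then renormalised).  For a two-stain
    model the third row is the normalised cross product of the corrected
    rows, the standard complement for three-channel deconvolution.  With
    ``p1 = p2 = 0`` the result is exactly the inverse of the base matrix.
    """
    vecs = model.unit_vectors
    v1, v2 = vecs[0], vecs[1]
    cross = np.cross(v1, v2)
    if np.linalg.norm(cross) < 1e-6:
        raise np.linalg.LinAlgError("stain vectors are (nearly) collinear")
    e1 = v1
    e2 = _unit(v2 - (v2 @ e1) * e1)
    r1 = _rotate_in_plane(v1, e1, e2, model.p1)
    r2 = _rotate_in_plane(v2, e1, e2, model.p2)
    if len(model.base_vectors) == 3:
        r3 = vecs[2]
    else:
        r3 = _unit(np.cross(r1, r2))
    stain_matrix = np.vstack([r1, r2, r3])
    cond = np.linalg.cond(stain_matrix)
    if not np.isfinite(cond) or cond > 1e8:
        raise np.linalg.LinAlgError(
            f"corrected stain matrix is ill-conditioned (cond={cond:.3g})"
        )
    return np.linalg.inv(stain_matrix)


def deconvolve(od_image: np.ndarray, matrix: np.ndarray) -> np.ndarray:
    """Per-pixel stain coefficients: OD row vector times the deconvolution matrix.

    The result has the same shape as *od_image* with the channel axis holding
    per-stain coefficients; values may be negative when the matrix mismatches
    the image's true mixing.
    """
    od_image = np.asarray(od_image, dtype=float)
    matrix = np.asarray(matrix, dtype=float)
    if od_image.shape[-1] != matrix.shape[0]:
        raise ValueError(
            f"OD channel count {od_image.shape[-1]} != matrix rows {matrix.shape[0]}"
        )
    return od_image @ matrix


def negative_coefficient_stats(
    coeffs: np.ndarray, tol: float = 1e-12
) -> tuple[float, float, float]:
    """(percentage, mean, population sd) of the negative coefficients.

    The percentage is over all pixels; mean and standard deviation are over
    the negative coefficients only.  If no coefficient is negative, mean and
    sd are 0 by convention.  Values in ``[-tol, 0)`` are treated as zero:
    an exact forward mixture deconvolved with its own matrix leaves
    float-roundoff residue of order 1e-16 OD at zero-density pixels, which is
    numerical noise, not a negative stain contribution.
    """
    coeffs = np.asarray(coeffs, dtype=float)
    if coeffs.size == 0:
        raise ValueError("empty coefficient image")
    if not np.all(np.isfinite(coeffs)):
        raise ValueError("coefficient image contains non-finite values")
    neg = coeffs[coeffs < -tol]
    pct = 100.0 * neg.size / coeffs.size
    if neg.size == 0:
        return pct, 0.0, 0.0
    return pct, float(neg.mean()), float(neg.std())


def reconstruct_stain_image(
    coeff: np.ndarray, stain_vector: np.ndarray, background: float | tuple | np.ndarray
) -> np.ndarray:
    """Single-dye RGB viewable: re-expose one stain's density through Beer-Lambert.

    Coefficients are clamped to >= 0 for display only (the quality measures
    use the unclamped values).  Returns uint8 with round-half-up quantisation.
    """
    coeff = np.clip(np.asarray(coeff, dtype=float), 0.0, None)
    od = coeff[..., None] * np.asarray(stain_vector, dtype=float)
    rgb = od_to_rgb(od, background)
    return np.clip(np.floor(rgb + 0.5), 0, 255).astype(np.uint8)


class DeconvolutionPlugin(Plugin):
    """Sweepable two-stain colour deconvolution with corrective angles p1, p2.

    Measures per input image: ``m1``-``m3`` are the percentage, mean and
    standard deviation of negative stain-1 coefficients; ``m4``-``m6`` the
    same for stain 2.  Output channels are the two single-dye viewables.
    """

    name = "stain_deconvolution"
    measure_names = ("m1", "m2", "m3", "m4", "m5", "m6")
    n_output_channels = 2

    def __init__(self, model: StainModel | None = None) -> None:
        self.model = model if model is not None else StainModel()
        self.settings = {
            "base_vectors": [list(v) for v in self.model.base_vectors],
            "background": list(self.model.background),
            "correction": "in-plane rotation (radians)",
        }

    def run(
        self, image: np.ndarray, params: Mapping[str, float]
    ) -> tuple[dict[str, float], list[np.ndarray]]:
        model = StainModel(
            base_vectors=self.model.base_vectors,
            p1=float(params["p1"]),
            p2=float(params["p2"]),
            background=self.model.background,
        )
        od = rgb_to_od(image, model.background)
        matrix = build_deconv_matrix(model)
        coeffs = deconvolve(od, matrix)
        m1, m2, m3 = negative_coefficient_stats(coeffs[..., 0])
        m4, m5, m6 = negative_coefficient_stats(coeffs[..., 1])
        corrected = np.linalg.inv(matrix)  # corrected stain row vectors
        channels = [
            reconstruct_stain_image(coeffs[..., s], corrected[s], model.background)
            for s in range(2)
        ]
        measures = {"m1": m1, "m2": m2, "m3": m3, "m4": m4, "m5": m5, "m6": m6}
        return measures, channels
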