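"""Synthetic test inputs with known ground truth.

Two generators emulate the image classes the sweep tooling is exercised on:

* two-stain histology-like RGB images, produced by *forward* Beer-Lambert
  mixing of known per-stain density fields (so deconvolution quality can be
  scored against ground truth, which real slides never provide), and
* grayscale photomicrograph-like images of bright, non-overlapping disks on a
  dark background with a known object count, for the nuclei-detection fixture.

All generators are pure functions of their parameters and seed.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .stains import RUIFROK_JOHNSON_EOSIN, RUIFROK_JOHNSON_HEMATOXYLIN, _unit

__all__ = [
    "DensityField",
    "generate_structured_densities",
    "generate_two_stain_image",
    "generate_nuclei_image",
]


@dataclass(frozen=True)
class DensityField:
    """Known per-stain density images plus the mixing model that renders them.

    ``densities`` has shape ``(n_stains, H, W)`` with non-negative OD-unit
    values; ``stain_vectors`` are the unit absorbance rows used for forward
    mixing; ``noise_sd`` is additive Gaussian noise in intensity units.
    """

    densities: np.ndarray
    stain_vectors: tuple[tuple[float, float, float], ...] = (
        RUIFROK_JOHNSON_HEMATOXYLIN,
        RUIFROK_JOHNSON_EOSIN,
    )
    background: tuple[float, float, float] = (255.0, 255.0, 255.0)
    noise_sd: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        d = np.asarray(self.densities, dtype=float)
        if d.ndim != 3:
            raise ValueError("densities must have shape (n_stains, H, W)")
        if not np.all(np.isfinite(d)):
            raise ValueError("densities must be finite")
        if np.any(d < 0):
            raise ValueError("densities must be non-negative")
        object.__setattr__(self, "densities", d)
        vecs = tuple(tuple(float(x) for x in _unit(np.asarray(v))) for v in self.stain_vectors)
        if len(vecs) != d.shape[0]:
            raise ValueError("one stain vector per density field required")
        object.__setattr__(self, "stain_vectors", vecs)
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


def generate_two_stain_image(fieldspec: DensityField) -> tuple[np.ndarray, np.ndarray]:
    """Forward Beer-Lambert rendering of a density field.

    Per pixel and channel, ``I_c = I0_c * 10**(-sum_s D_s * v_{s,c})`` plus
    optional Gaussian noise, clipped to ``[0, I0_c]``.  Returns the float RGB
    image and the ground-truth densities (stains stacked on the last axis,
    matching the channel axis of deconvolved coefficients).
    """
    d = fieldspec.densities
    vecs = np.asarray(fieldspec.stain_vectors, dtype=float)  # (n_stains, 3)
    i0 = np.asarray(fieldspec.background, dtype=float)
    od = np.tensordot(np.moveaxis(d, 0, -1), vecs, axes=([-1], [0]))  # (H, W, 3)
    image = i0 * np.power(10.0, -od)
    if fieldspec.noise_sd > 0:
        rng = np.random.default_rng(fieldspec.seed)
        image = image + rng.normal(0.0, fieldspec.noise_sd, size=image.shape)
    image = np.clip(image, 0.0, i0)
    return image, np.moveaxis(d, 0, -1)


def _gaussian_bump(shape: tuple[int, int], center: np.ndarray, sigma: float) -> np.ndarray:
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    r2 = (yy - center[0]) ** 2 + (xx - center[1]) ** 2
    return np.exp(-r2 / (2.0 * sigma**2))

def generate_structured_densities(
    shape: tuple[int, int] = (256, 256),
    n_blobs_per_stain: tuple[int, ...] = (40, 12),
    seed: int = 0,
    amplitude: tuple[float, ...] = (0.9, 0.6),
    sigma: tuple[float, ...] = (4.0, 22.0),
    noise_sd: float = 0.0,
    stain_vectors: tuple[tuple[float, float, float], ...] = (
        RUIFROK_JOHNSON_HEMATOXYLIN,
        RUIFROK_JOHNSON_EOSIN,
    ),
) -> DensityField:
    """Smooth blob-structured density fields for a two-stain H&E-like slide.

    Stain 1 (hematoxylin-like) gets many small, dense bumps mimicking nuclei;
    stain 2 (eosin-like) gets fewer broad bumps mimicking cytoplasm and
    connective tissue.  Deterministic per seed.
    """
    if shape[0] <= 0 or shape[1] <= 0:
        raise ValueError("shape must be positive")
    rng = np.random.default_rng(seed)
    fields = []
    for n_blobs, amp, sig in zip(n_blobs_per_stain, amplitude, sigma):
        d = np.zeros(shape, dtype=float)
        for _ in range(n_blobs):
            center = rng.uniform([0, 0], shape)
            d += amp * rng.uniform(0.5, 1.0) * _gaussian_bump(shape, center, sig)
        # cap the peak at the stain's amplitude so overlapping bumps cannot
        # drive total OD beyond what transmitted light can still resolve
        peak = d.max()
        if peak > amp:
            d *= amp / peak
        fields.append(d)
    return DensityField(
        densities=np.stack(fields),
        stain_vectors=tuple(stain_vectors)[: len(fields)],
        noise_sd=noise_sd,
        seed=seed,
    )


def generate_nuclei_image(
    shape: tuple[int, int] = (256, 256),
    n_disks: int = 12,
    diameter: float = 10.0,
    intensity: float = 200.0,
    background: float = 20.0,
    noise_sd: float = 0.0,
    seed: int = 0,
    min_gap: float = 4.0,
    max_attempts: int = 10_000,
) -> tuple[np.ndarray, int, np.ndarray]:
    """Grayscale image of non-overlapping bright disks on a dark background.

    Disk centers are drawn by rejection sampling so disks neither overlap each
    other (separation >= diameter + *min_gap*) nor clip the image border.
    Returns ``(image, ground-truth count, centers)``; the image is float64 in
    intensity units with optional additive Gaussian noise.
    """
    if n_disks < 0:
        raise ValueError("n_disks must be >= 0")
    rng = np.random.default_rng(seed)
    radius = diameter / 2.0
    margin = radius + 1.0
    if n_disks > 0 and (shape[0] <= 2 * margin or shape[1] <= 2 * margin):
        raise ValueError(f"disks of diameter {diameter} do not fit in image of shape {shape}")
    centers: list[np.ndarray] = []
    attempts = 0
    while len(centers) < n_disks:
        if attempts >= max_attempts:
            raise RuntimeError(
                f"could not place {n_disks} non-overlapping disks in {shape} "
                f"after {max_attempts} attempts"
            )
        attempts += 1
        c = rng.uniform([margin, margin], [shape[0] - margin, shape[1] - margin])
        if all(np.linalg.norm(c - prev) >= diameter + min_gap for prev in centers):
            centers.append(c)

    image = np.full(shape, float(background))
    yy, xx = np.mgrid[0 : shape[0], 0 : shape[1]]
    for c in centers:
        mask = (yy - c[0]) ** 2 + (xx - c[1]) ** 2 <= radius**2
        image[mask] = float(intensity)
    if noise_sd > 0:
        image = image + rng.normal(0.0, noise_sd, size=shape)
    centers_arr = np.array(centers) if centers else np.empty((0, 2))
    return image, len(centers), centers_arr
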