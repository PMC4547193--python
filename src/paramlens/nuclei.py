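"""Parameterised nuclei detection on grayscale photomicrograph-like images.

A deliberately simple five-parameter detector in the CellProfiler mould:
smooth, threshold, fill holes, label connected components, and keep the
components whose equivalent diameter falls within a size window.  It exists
to exercise the sweep/table tooling on a detection task where object counts
are the output measures and outline overlays are the output images — not to
compete with real segmentation methods (touching nuclei are not declumped).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np
from skimage import filters, measure, morphology, segmentation

from .sweep import Plugin

__all__ = ["NucleiParams", "detect_nuclei", "NucleiPlugin"]


@dataclass(frozen=True)
class NucleiParams:
    """The detector's five tunables.

    smoothing_sigma : Gaussian pre-smoothing scale, px.
    lower_threshold : intensity above which pixels count as foreground.
    min_diameter, max_diameter : accepted equivalent-diameter window, px.
    hole_fill : largest hole diameter (px) filled inside foreground objects.
    """

    smoothing_sigma: float = 1.0
    lower_threshold: float = 100.0
    min_diameter: float = 6.0
    max_diameter: float = 30.0
    hole_fill: float = 4.0

    def __post_init__(self) -> None:
        for name in ("smoothing_sigma", "lower_threshold", "min_diameter", "max_diameter", "hole_fill"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.min_diameter > self.max_diameter:
            raise ValueError(
                f"min_diameter {self.min_diameter} > max_diameter {self.max_diameter}"
            )


def detect_nuclei(image: np.ndarray, params: NucleiParams) -> tuple[int, np.ndarray]:
    """Count nucleus-like objects and draw their outlines.

    Pipeline: Gaussian smooth -> threshold -> fill small holes -> 8-connected
    components -> keep components with equivalent diameter (diameter of the
    circle with the component's area) in ``[min_diameter, max_diameter]``.
    Returns the surviving-component count and a uint8 copy of the input with
    the 1-px inner boundaries of kept components set to 255.
    """
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError(f"detect_nuclei expects a single-channel image, got shape {image.shape}")

    if params.smoothing_sigma > 0:
        smoothed = filters.gaussian(image, sigma=params.smoothing_sigma, preserve_range=True)
    else:
        smoothed = image
    mask = smoothed >= params.lower_threshold
    if params.hole_fill > 0:
        hole_area = int(math.pi * (params.hole_fill / 2.0) ** 2)
        if hole_area >= 1:
            mask = morphology.remove_small_holes(mask, max_size=hole_area)

    labels = measure.label(mask, connectivity=2)
    kept = np.zeros_like(mask)
    count = 0
    for region in measure.regionprops(labels):
        if params.min_diameter <= region.equivalent_diameter_area <= params.max_diameter:
            count += 1
            kept[labels == region.label] = True

    outline = np.clip(np.floor(image + 0.5), 0, 255).astype(np.uint8)
    boundaries = segmentation.find_boundaries(kept, mode="inner")
    outline[boundaries] = 255
    return count, outline


class NucleiPlugin(Plugin):
    """Sweepable adapter around :func:`detect_nuclei`.

    One measure (``object_count``) and one outline channel per input image.
    """

    name = "nuclei_detection"
    measure_names = ("object_count",)
    n_output_channels = 1
    settings: dict = {}

    def run(
        self, image: np.ndarray, params: Mapping[str, float]
    ) -> tuple[dict[str, float], list[np.ndarray]]:
        p = NucleiParams(
            smoothing_sigma=float(params["smoothing_sigma"]),
            lower_threshold=float(params["lower_threshold"]),
            min_diameter=float(params["min_diameter"]),
            max_diameter=float(params["max_diameter"]),
            hole_fill=float(params["hole_fill"]),
        )
        count, outline = detect_nuclei(image, p)
        return {"object_count": float(count)}, [outline]
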