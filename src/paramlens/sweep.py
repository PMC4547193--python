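"""Cartesian parameter sweeps over image-processing plugins.

The engine expands a list of :class:`~paramlens.core.ParameterSpec` into the
full Cartesian grid (last parameter varying fastest), runs a plugin once per
(grid point x input image), and persists the results as a sweep directory.
Record ids are the row index in enumeration order, so re-running the same
configuration with the same seed reproduces ``records.csv`` byte for byte.
"""

from __future__ import annotations

import abc
import itertools
from pathlib import Path
from typing import Mapping, Sequence

import imageio.v3 as iio
import numpy as np

from .core import (
    DataRecord,
    ManifestError,
    MeasureSpec,
    ParameterSpec,
    SweepManifest,
    write_manifest,
)

__all__ = ["Plugin", "SweepError", "sample_parameter", "expand_grid", "run_sweep"]


class SweepError(RuntimeError):
    """A plugin failed during a sweep; carries the failing grid-point context."""


class Plugin(abc.ABC):
    """Contract for a sweepable image-processing algorithm.

    A plugin declares the measures it produces per input image and how many
    output image channels it emits, then computes both in :meth:`run`.
    ``run`` must be deterministic given ``(image, params)``; any internal
    randomness must be seeded from :attr:`seed`.
    """

    #: identifier recorded in the manifest
    name: str = "plugin"
    #: measure names produced for each input image, in column order
    measure_names: tuple[str, ...] = ()
    #: number of output images produced per input image
    n_output_channels: int = 0
    #: serialisable fixed settings, recorded in the manifest
    settings: Mapping[str, object] = {}
    seed: int = 0

    @abc.abstractmethod
    def run(
        self, image: np.ndarray, params: Mapping[str, float]
    ) -> tuple[dict[str, float], list[np.ndarray]]:
        """Process one input image at one grid point.

        Returns ``(measures, channels)`` where ``measures`` has exactly the
        declared :attr:`measure_names` as keys and ``channels`` has exactly
        :attr:`n_output_channels` uint8 image arrays.
        """

    def measure_specs(self, n_images: int) -> tuple[MeasureSpec, ...]:
        """Sweep-wide measure columns: per-image measures concatenated.

        The first image keeps the bare measure names; measures for image
        ``i >= 1`` are suffixed ``-<i>`` (so a second image's first measure
        renders as e.g. ``m1-1``).
        """
        specs = []
        for i in range(n_images):
            for name in self.measure_names:
                col = name if i == 0 else f"{name}-{i}"
                specs.append(MeasureSpec(name=col, input_image_index=i))
        return tuple(specs)


def sample_parameter(spec: ParameterSpec) -> np.ndarray:
    """Evenly spaced samples of *spec*'s interval, inclusive of both endpoints."""
    return spec.samples()


def expand_grid(specs: Sequence[ParameterSpec]) -> list[dict[str, float]]:
    """All combinations of sampled parameter values, last parameter fastest.

    The result has ``prod(n_samples)`` entries; its index order defines the
    canonical ``record_id`` assignment for a sweep.
    """
    if not specs:
        raise ValueError("expand_grid requires at least one parameter spec")
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError(f"duplicate parameter names: {names}")
    grids = [sample_parameter(s) for s in specs]
    return [
        dict(zip(names, (float(v) for v in combo))) for combo in itertools.product(*grids)
    ]


def _validate_plugin_output(
    plugin: Plugin, measures: Mapping[str, float], channels: Sequence[np.ndarray]
) -> None:
    if set(measures) != set(plugin.measure_names):
        raise SweepError(
            f"plugin {plugin.name!r} returned measures {sorted(measures)}, "
            f"declared {sorted(plugin.measure_names)}"
        )
    if len(channels) != plugin.n_output_channels:
        raise SweepError(
            f"plugin {plugin.name!r} returned {len(channels)} channels, "
            f"declared {plugin.n_output_channels}"
        )


def run_sweep(
    specs: Sequence[ParameterSpec],
    input_images: Sequence[np.ndarray],
    plugin: Plugin,
    seed: int,
    out_dir: str | Path,
    input_image_paths: Sequence[str] | None = None,
) -> SweepManifest:
    """Execute *plugin* over the full grid and persist a sweep directory.

    One :class:`DataRecord` is produced per grid combination, holding
    ``n_images * len(plugin.measure_names)`` measures and
    ``n_images * plugin.n_output_channels`` output images.  A plugin failure
    at any grid point aborts the sweep with the failing record id, image
    index and parameter values in the error message.
    """
    if not input_images:
        raise ValueError("run_sweep requires at least one input image")
    combos = expand_grid(specs)
    plugin.seed = int(seed)

    out = Path(out_dir)
    img_dir = out / "images"
    img_dir.mkdir(parents=True, exist_ok=True)

    records = []
    for rid, params in enumerate(combos):
        measure_values: dict[str, float] = {}
        refs: dict[tuple[int, int], str] = {}
        for i, image in enumerate(input_images):
            try:
                measures, channels = plugin.run(image, params)
                _validate_plugin_output(plugin, measures, channels)
            except Exception as exc:
                raise SweepError(
                    f"plugin {plugin.name!r} failed at record {rid}, input image {i}, "
                    f"params {params}: {exc}"
                ) from exc
            for name in plugin.measure_names:
                col = name if i == 0 else f"{name}-{i}"
                measure_values[col] = float(measures[name])
            for k, channel in enumerate(channels):
                ref = f"images/rec{rid}_in{i}_ch{k}.png"
                iio.imwrite(out / ref, np.asarray(channel, dtype=np.uint8))
                refs[(i, k)] = ref
        records.append(
            DataRecord(
                record_id=rid,
                param_values=params,
                measure_values=measure_values,
                output_image_refs=refs,
            )
        )

    if input_image_paths is None:
        # persist in-memory inputs so renderers can resolve them later
        (out / "inputs").mkdir(exist_ok=True)
        input_image_paths = []
        for i, image in enumerate(input_images):
            ref = f"inputs/input{i}.png"
            arr = np.asarray(image)
            if arr.dtype != np.uint8:
                arr = np.clip(np.floor(arr.astype(float) + 0.5), 0, 255).astype(np.uint8)
            iio.imwrite(out / ref, arr)
            input_image_paths.append(ref)
    manifest = SweepManifest(
        param_specs=tuple(specs),
        measure_specs=plugin.measure_specs(len(input_images)),
        input_image_paths=tuple(input_image_paths),
        plugin_name=plugin.name,
        plugin_settings=dict(plugin.settings),
        seed=int(seed),
        records=tuple(records),
    )
    write_manifest(manifest, out)
    return manifest
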