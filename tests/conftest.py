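import numpy as np
import pytest

from paramlens import (
    DataRecord,
    DeconvolutionPlugin,
    ParameterSpec,
    ResultTable,
    generate_structured_densities,
    generate_two_stain_image,
    run_sweep,
)


def quantise(image: np.ndarray) -> np.ndarray:
    """Round-half-up 8-bit quantisation, as used when writing PNGs."""
    return np.clip(np.floor(np.asarray(image, dtype=float) + 0.5), 0, 255).astype(np.uint8)


@pytest.fixture(scope="session")
def he_images() -> list[np.ndarray]:
    """Two small synthetic H&E-like uint8 images (known mixing model)."""
    images = []
    for seed in (0, 1):
        fieldspec = generate_structured_densities(shape=(48, 48), seed=seed)
        image, _ = generate_two_stain_image(fieldspec)
        images.append(quantise(image))
    return images


@pytest.fixture(scope="session")
def small_sweep(tmp_path_factory, he_images):
    """A 3x3 deconvolution sweep over two input images, persisted to disk."""
    out = tmp_path_factory.mktemp("sweep")
    specs = [
        ParameterSpec("p1", -0.2, 0.2, 3),
        ParameterSpec("p2", -0.2, 0.2, 3),
    ]
    manifest = run_sweep(specs, he_images, DeconvolutionPlugin(), seed=7, out_dir=out)
    return manifest, out


def make_table(
    param_values: dict[str, list[float]], measure_values: dict[str, list[float]]
) -> ResultTable:
    """Build a ResultTable directly from per-column value lists."""
    n = len(next(iter((param_values | measure_values).values())))
    records = [
        DataRecord(
            record_id=i,
            param_values={k: v[i] for k, v in param_values.items()},
            measure_values={k: v[i] for k, v in measure_values.items()},
        )
        for i in range(n)
    ]
    return ResultTable(
        records=records,
        param_columns=tuple(param_values),
        measure_columns=tuple(measure_values),
    )


def random_table(rng: np.random.Generator, max_rows: int = 200) -> ResultTable:
    """A random table with tie-heavy integer-valued columns."""
    n = int(rng.integers(2, max_rows + 1))
    n_params = int(rng.integers(1, 4))
    n_measures = int(rng.integers(1, 4))
    params = {f"p{j}": list(rng.integers(0, 5, size=n).astype(float)) for j in range(n_params)}
    measures = {f"m{j}": list(rng.normal(size=n)) for j in range(n_measures)}
    return make_table(params, measures)
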