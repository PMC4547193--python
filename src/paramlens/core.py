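"""Domain types shared across the package, and the on-disk sweep manifest.

A *sweep* evaluates an image-processing algorithm over a Cartesian grid of
input-parameter values and one or more input images.  Each grid point yields
one :class:`DataRecord`: the parameter values together with the scalar output
measures and output images produced for every input image.  A persisted sweep
lives in a directory::

    <sweep>/manifest.json    specs, provenance, seed, image references
    <sweep>/records.csv      one row per record: record_id, params..., measures...
    <sweep>/images/          rec<id>_in<i>_ch<k>.png output images

The JSON half is self-describing; the CSV half keeps parameters to the left of
measures, mirroring the column layout of the tabular view.
"""

from __future__ import annotations

import csv
import io
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Any, Iterator, Mapping, Sequence

import numpy as np

MANIFEST_VERSION = 1

__all__ = [
    "ParameterSpec",
    "MeasureSpec",
    "DataRecord",
    "ResultTable",
    "SweepManifest",
    "ManifestError",
    "write_manifest",
    "read_manifest",
]


class ManifestError(ValueError):
    """Raised when a sweep manifest cannot be written or read back."""


@dataclass(frozen=True)
class ParameterSpec:
    """One real-valued input parameter sampled on a closed interval.

    Parameters
    ----------
    name : str
        Column identifier, unique within a sweep.
    lo, hi : float
        Interval endpoints (inclusive), in the parameter's own units.
    n_samples : int
        Number of evenly spaced samples; both endpoints are included when
        ``n_samples >= 2``, and a single sample equals ``lo``.
    """

    name: str
    lo: float
    hi: float
    n_samples: int

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("parameter name must be non-empty")
        if not (math.isfinite(self.lo) and math.isfinite(self.hi)):
            raise ValueError(f"{self.name}: interval endpoints must be finite")
        if self.lo > self.hi:
            raise ValueError(f"{self.name}: lo={self.lo} > hi={self.hi}")
        if self.n_samples < 1:
            raise ValueError(f"{self.name}: n_samples must be >= 1, got {self.n_samples}")
        if self.n_samples > 1 and self.lo == self.hi:
            raise ValueError(f"{self.name}: degenerate interval with n_samples > 1")

    def samples(self) -> np.ndarray:
        """Evenly spaced samples, endpoint-inclusive.

        Computed as the convex combination ``lo*(1-t) + hi*t`` with
        ``t = i/(n-1)`` so that the endpoints are exact and a symmetric
        interval has an exactly-zero midpoint sample (the "no change" value
        of a corrective parameter sampled an odd number of times).
        """
        if self.n_samples == 1:
            return np.array([float(self.lo)])
        t = np.arange(self.n_samples) / (self.n_samples - 1)
        return self.lo * (1.0 - t) + self.hi * t


@dataclass(frozen=True)
class MeasureSpec:
    """A scalar output measure describing the output for one input image."""

    name: str
    input_image_index: int
    description: str = ""

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("measure name must be non-empty")
        if self.input_image_index < 0:
            raise ValueError(f"{self.name}: input_image_index must be >= 0")


@dataclass(frozen=True)
class DataRecord:
    """One sampled parameter combination with its outputs.

    ``output_image_refs`` maps ``(input_image_index, output_channel_index)``
    to an image path relative to the sweep directory.
    """

    record_id: int
    param_values: Mapping[str, float]
    measure_values: Mapping[str, float]
    output_image_refs: Mapping[tuple[int, int], str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "param_values", dict(self.param_values))
        object.__setattr__(self, "measure_values", dict(self.measure_values))
        object.__setattr__(
            self, "output_image_refs", {tuple(k): v for k, v in dict(self.output_image_refs).items()}
        )

    def value(self, column: str) -> float:
        if column in self.param_values:
            return self.param_values[column]
        if column in self.measure_values:
            return self.measure_values[column]
        raise KeyError(column)


@dataclass(frozen=True)
class SweepManifest:
    """Complete description of one executed sweep."""

    param_specs: tuple[ParameterSpec, ...]
    measure_specs: tuple[MeasureSpec, ...]
    input_image_paths: tuple[str, ...]
    plugin_name: str
    plugin_settings: Mapping[str, Any]
    seed: int
    records: tuple[DataRecord, ...]
    version: int = MANIFEST_VERSION

    def __post_init__(self) -> None:
        object.__setattr__(self, "param_specs", tuple(self.param_specs))
        object.__setattr__(self, "measure_specs", tuple(self.measure_specs))
        object.__setattr__(self, "input_image_paths", tuple(self.input_image_paths))
        object.__setattr__(self, "plugin_settings", dict(self.plugin_settings))
        object.__setattr__(self, "records", tuple(self.records))
        names = [m.name for m in self.measure_specs]
        if len(set(names)) != len(names):
            raise ValueError("measure names must be unique within a sweep")
        pnames = [p.name for p in self.param_specs]
        if len(set(pnames)) != len(pnames):
            raise ValueError("parameter names must be unique within a sweep")

    @property
    def param_columns(self) -> tuple[str, ...]:
        return tuple(p.name for p in self.param_specs)

    @property
    def measure_columns(self) -> tuple[str, ...]:
        return tuple(m.name for m in self.measure_specs)

    def validate(self) -> None:
        pcols, mcols = set(self.param_columns), set(self.measure_columns)
        for rec in self.records:
            if set(rec.param_values) != pcols:
                raise ManifestError(
                    f"record {rec.record_id}: param columns {sorted(rec.param_values)} "
                    f"!= declared {sorted(pcols)}"
                )
            if set(rec.measure_values) != mcols:
                raise ManifestError(
                    f"record {rec.record_id}: measure columns do not match declared measures"
                )


@dataclass(frozen=True)
class ResultTable:
    """A sweep's records plus the current view state of the tabular display.

    ``ordering`` is a permutation of all record positions; ``visible`` is the
    subset of positions that pass the active filters; ``selection`` is an
    ordered list of visible positions.  Parameter columns always render left
    of measure columns.
    """

    records: tuple[DataRecord, ...]
    param_columns: tuple[str, ...]
    measure_columns: tuple[str, ...]
    ordering: tuple[int, ...] | None = None
    visible: frozenset[int] | None = None  # None means "all visible"
    sort_keys: tuple[str, ...] = ()
    selection: tuple[int, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "records", tuple(self.records))
        object.__setattr__(self, "param_columns", tuple(self.param_columns))
        object.__setattr__(self, "measure_columns", tuple(self.measure_columns))
        n = len(self.records)
        ordering = tuple(self.ordering) if self.ordering is not None else tuple(range(n))
        visible = frozenset(self.visible) if self.visible is not None else frozenset(range(n))
        object.__setattr__(self, "ordering", ordering)
        object.__setattr__(self, "visible", visible)
        object.__setattr__(self, "sort_keys", tuple(self.sort_keys))
        object.__setattr__(self, "selection", tuple(self.selection))
        if sorted(ordering) != list(range(n)):
            raise ValueError("ordering must be a permutation of all record indices")
        if not visible <= set(range(n)):
            raise ValueError("visible must be a subset of record indices")
        if not set(self.selection) <= visible:
            raise ValueError("selection must be a subset of visible records")

    @classmethod
    def from_manifest(cls, manifest: SweepManifest) -> "ResultTable":
        return cls(
            records=manifest.records,
            param_columns=manifest.param_columns,
            measure_columns=manifest.measure_columns,
        )

    @property
    def columns(self) -> tuple[str, ...]:
        return self.param_columns + self.measure_columns

    def column_values(self, column: str) -> np.ndarray:
        """Values of *column* for all records, in record (not display) order."""
        if column not in self.columns:
            raise KeyError(f"unknown column {column!r}")
        return np.array([rec.value(column) for rec in self.records])

    def visible_ordering(self) -> tuple[int, ...]:
        """Current display order restricted to visible records (top to bottom)."""
        return tuple(i for i in self.ordering if i in self.visible)


# ---------------------------------------------------------------------------
# Manifest persistence


def _fmt(x: float) -> str:
    # repr() emits the shortest decimal string that round-trips the double
    return repr(float(x))


def write_manifest(manifest: SweepManifest, path: str | Path) -> None:
    """Persist *manifest* into directory *path* as ``manifest.json`` + ``records.csv``.

    Every output image referenced by a record must already exist relative to
    *path*; a dangling reference is an error naming the missing file.
    """
    manifest.validate()
    root = Path(path)
    root.mkdir(parents=True, exist_ok=True)
    missing = [
        ref
        for rec in manifest.records
        for ref in rec.output_image_refs.values()
        if not (root / ref).is_file()
    ]
    if missing:
        raise ManifestError(f"dangling output-image reference(s): {', '.join(sorted(set(missing)))}")

    doc = {
        "format": "paramlens-sweep",
        "version": manifest.version,
        "seed": manifest.seed,
        "plugin": {"name": manifest.plugin_name, "settings": manifest.plugin_settings},
        "parameters": [
            {"name": p.name, "lo": p.lo, "hi": p.hi, "n_samples": p.n_samples}
            for p in manifest.param_specs
        ],
        "measures": [
            {"name": m.name, "input_image_index": m.input_image_index, "description": m.description}
            for m in manifest.measure_specs
        ],
        "input_images": list(manifest.input_image_paths),
        "n_records": len(manifest.records),
        "record_images": [
            {
                "record_id": rec.record_id,
                "refs": {f"{i},{k}": ref for (i, k), ref in sorted(rec.output_image_refs.items())},
            }
            for rec in manifest.records
        ],
    }
    (root / "manifest.json").write_text(json.dumps(doc, indent=1, sort_keys=True) + "\n")

    header = ["record_id", *manifest.param_columns, *manifest.measure_columns]
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(header)
    for rec in manifest.records:
        writer.writerow(
            [rec.record_id]
            + [_fmt(rec.param_values[c]) for c in manifest.param_columns]
            + [_fmt(rec.measure_values[c]) for c in manifest.measure_columns]
        )
    (root / "records.csv").write_text(buf.getvalue())


def read_manifest(path: str | Path) -> SweepManifest:
    """Read a sweep directory written by :func:`write_manifest`."""
    root = Path(path)
    json_path = root / "manifest.json"
    csv_path = root / "records.csv"
    if not json_path.is_file():
        raise ManifestError(f"no manifest.json in {root}")
    try:
        doc = json.loads(json_path.read_text())
    except json.JSONDecodeError as exc:
        raise ManifestError(f"{json_path}: malformed JSON at line {exc.lineno}: {exc.msg}") from exc
    if doc.get("format") != "paramlens-sweep":
        raise ManifestError(f"{json_path}: not a paramlens sweep manifest")
    if doc.get("version") != MANIFEST_VERSION:
        raise ManifestError(
            f"{json_path}: manifest version {doc.get('version')} != supported {MANIFEST_VERSION}"
        )

    param_specs = tuple(
        ParameterSpec(p["name"], p["lo"], p["hi"], p["n_samples"]) for p in doc["parameters"]
    )
    measure_specs = tuple(
        MeasureSpec(m["name"], m["input_image_index"], m.get("description", ""))
        for m in doc["measures"]
    )
    pcols = [p.name for p in param_specs]
    mcols = [m.name for m in measure_specs]

    if not csv_path.is_file():
        raise ManifestError(f"no records.csv in {root}")
    with csv_path.open(newline="") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise ManifestError(f"{csv_path}: empty file") from None
        expected = ["record_id", *pcols, *mcols]
        if header != expected:
            raise ManifestError(f"{csv_path}: header {header} != expected {expected}")
        rows = list(reader)
    if len(rows) != doc["n_records"]:
        raise ManifestError(
            f"{csv_path}: {len(rows)} data rows but manifest.json declares {doc['n_records']} records"
        )
    ref_by_id: dict[int, dict[tuple[int, int], str]] = {}
    for entry in doc.get("record_images", []):
        refs = {
            tuple(int(s) for s in key.split(",")): ref for key, ref in entry.get("refs", {}).items()
        }
        ref_by_id[entry["record_id"]] = refs

    records = []
    for lineno, row in enumerate(rows, start=2):
        if len(row) != len(expected):
            raise ManifestError(f"{csv_path}: line {lineno}: {len(row)} fields, expected {len(expected)}")
        try:
            rid = int(row[0])
            values = [float(v) for v in row[1:]]
        except ValueError as exc:
            raise ManifestError(f"{csv_path}: line {lineno}: {exc}") from exc
        records.append(
            DataRecord(
                record_id=rid,
                param_values=dict(zip(pcols, values[: len(pcols)])),
                measure_values=dict(zip(mcols, values[len(pcols) :])),
                output_image_refs=ref_by_id.get(rid, {}),
            )
        )

    manifest = SweepManifest(
        param_specs=param_specs,
        measure_specs=measure_specs,
        input_image_paths=tuple(doc["input_images"]),
        plugin_name=doc["plugin"]["name"],
        plugin_settings=doc["plugin"]["settings"],
        seed=doc["seed"],
        records=tuple(records),
        version=doc["version"],
    )
    manifest.validate()
    return manifest
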