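"""File formats: multi-page TIFF stacks with JSON sidecars, mask TIFFs,
spectrum CSVs, feature tables and checksummed output manifests.

A hyperspectral stack travels as a multi-page TIFF (one page per wavenumber,
ascending) with a sidecar ``<name>.json`` carrying the wavenumber axis, pixel
size and provenance; masks are 16-bit integer TIFFs; spectra are two-column
CSVs (``wavenumber_cm1,intensity``, header required).
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .segmentation import AggregateLabelMask, CellLabelMask
from .spectra import Spectrum, WavenumberAxis
from .stack import HyperspectralStack
from .unmixing import ConcentrationMaps

__all__ = [
    "read_spectrum_csv",
    "write_spectrum_csv",
    "read_stack",
    "write_stack",
    "read_mask",
    "write_mask",
    "write_map",
    "write_outputs",
    "sha256_file",
]


def read_spectrum_csv(path, label: str | None = None) -> Spectrum:
    """Load a two-column ``wavenumber_cm1,intensity`` CSV (header required)."""
    df = pd.read_csv(path, float_precision="round_trip")
    required = {"wavenumber_cm1", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"{path}: expected columns {sorted(required)}, found {list(df.columns)}"
        )
    order = np.argsort(df["wavenumber_cm1"].to_numpy())
    return Spectrum(
        axis=WavenumberAxis(df["wavenumber_cm1"].to_numpy()[order]),
        intensity=df["intensity"].to_numpy()[order],
        label=label if label is not None else Path(path).stem,
    )


def write_spectrum_csv(s: Spectrum, path) -> None:
    pd.DataFrame(
        {"wavenumber_cm1": s.axis.values, "intensity": s.intensity}
    ).to_csv(path, index=False)


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_stack(stack: HyperspectralStack, path, meta: dict | None = None) -> None:
    """Write a lambda-x-y stack as multi-page TIFF plus sidecar JSON."""
    path = Path(path)
    tifffile.imwrite(path, stack.data, photometric="minisblack")
    sidecar = {
        "wavenumber_cm1": [float(v) for v in stack.axis.values],
        "pixel_size_um": stack.pixel_size,
    }
    if meta:
        sidecar.update(meta)
    _sidecar_path(path).write_text(json.dumps(sidecar, indent=1))


def read_stack(
    path,
    axis: WavenumberAxis | None = None,
    pixel_size: float | None = None,
) -> HyperspectralStack:
    """Read a multi-page TIFF stack; the wavenumber axis comes from the
    sidecar JSON unless given explicitly."""
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    if axis is None:
        sidecar = _sidecar_path(path)
        if not sidecar.exists():
            raise ValueError(
                f"{path}: no wavenumber axis given and sidecar {sidecar.name} is missing"
            )
        meta = json.loads(sidecar.read_text())
        axis = WavenumberAxis(np.asarray(meta["wavenumber_cm1"], float))
        if pixel_size is None:
            pixel_size = meta.get("pixel_size_um")
    if data.shape[0] != len(axis):
        raise ValueError(
            f"{path}: {data.shape[0]} pages but axis has {len(axis)} wavenumbers"
        )
    return HyperspectralStack(axis=axis, data=data, pixel_size=pixel_size)


def write_mask(labels: np.ndarray, path) -> None:
    labels = np.asarray(labels)
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for a 16-bit mask")
    tifffile.imwrite(Path(path), labels.astype(np.uint16), photometric="minisblack")


def read_mask(path) -> np.ndarray:
    arr = tifffile.imread(Path(path))
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D mask, got shape {arr.shape}")
    return arr.astype(np.int32)


def write_map(image: np.ndarray, path) -> None:
    tifffile.imwrite(Path(path), np.asarray(image, np.float32), photometric="minisblack")


def sha256_file(path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_outputs(
    outdir,
    maps: ConcentrationMaps | None = None,
    cells: CellLabelMask | None = None,
    aggregates: AggregateLabelMask | None = None,
    tables: dict[str, pd.DataFrame] | None = None,
    summaries: dict | None = None,
    extra_maps: dict[str, np.ndarray] | None = None,
) -> dict:
    """Write every artifact of a run and a checksummed manifest.

    Channel maps go out as 32-bit float TIFFs, masks as 16-bit integer TIFFs,
    tables as CSV, summaries as JSON.  Returns the manifest (also written as
    ``manifest.json``), listing each file with its SHA-256 checksum.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    if maps is not None:
        for i, name in enumerate(maps.names):
            p = outdir / f"map_{name}.tif"
            write_map(maps.maps[i], p)
            written.append(p)
        p = outdir / "map_residual_norm.tif"
        write_map(maps.residual_norm, p)
        written.append(p)
    for name, image in (extra_maps or {}).items():
        p = outdir / f"{name}.tif"
        write_map(image, p)
        written.append(p)
    if cells is not None:
        p = outdir / "mask_cells.tif"
        write_mask(cells.labels, p)
        written.append(p)
    if aggregates is not None:
        p = outdir / "mask_aggregates.tif"
        write_mask(aggregates.labels, p)
        written.append(p)
        p = outdir / "aggregate_parents.csv"
        pd.DataFrame(
            sorted(aggregates.parent.items()), columns=["aggregate_label", "cell_label"]
        ).to_csv(p, index=False)
        written.append(p)
    for name, table in (tables or {}).items():
        p = outdir / f"{name}.csv"
        table.to_csv(p, index=False)
        written.append(p)
    if summaries is not None:
        p = outdir / "summary.json"
        p.write_text(json.dumps(summaries, indent=1, sort_keys=True, default=float))
        written.append(p)

    manifest = {
        "files": [
            {"path": p.name, "sha256": sha256_file(p), "bytes": p.stat().st_size}
            for p in written
        ]
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
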