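"""End-to-end composition: simulate (optional) -> unmix -> segment -> quantify
-> colocalize (optional) -> write outputs.

Every stage is logged with its parameters; given a fixed seed the whole run is
deterministic and the written manifest is byte-for-byte reproducible.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import io as hio
from .colocalization import auto_threshold, mcc
from .quantify import extract_cell_features, population_summaries
from .segmentation import CellLabelMask, import_labels, segment_aggregates, segment_cells
from .spectra import DEFAULT_WINDOWS, window_sum
from .synthetic import SceneParams, default_references, generate_scene, render_fluorescence, render_stack
from .unmixing import ReferenceSet, UnmixConfig, estimate_background_spectrum, select_lambda, unmix_stack

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "demo_config"]


@dataclass
class RunConfig:
    """Everything a full run needs; CLI flags and YAML entries map 1:1 here."""

    outdir: str = "hsrskit_run"
    seed: int = 0
    # input: either simulate a scene or point at files
    simulate: bool = True
    scene: dict = field(default_factory=dict)  # SceneParams overrides
    stack_path: str | None = None
    refs_paths: list[str] = field(default_factory=list)
    background: str = "auto"  # 'auto' or a spectrum CSV path
    fluorescence: bool | str = True  # simulate / path / False
    cell_mask_path: str | None = None
    aggregate_mask_path: str | None = None
    # unmixing
    lam: float | str = 0.01  # or 'auto' for the residual-inflation rule
    nonnegative: bool = True
    normalize_refs: str = "max"
    # segmentation
    segmentation: dict = field(default_factory=dict)
    aggregates: dict = field(default_factory=dict)
    # quantification
    rich_threshold: float = 1.1
    location_mode: str = "centroid"
    # colocalization
    colocal_threshold: float | str = "auto"
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


def demo_config(outdir, seed: int = 0) -> RunConfig:
    """A small, fully simulated run that exercises every stage in seconds."""
    return RunConfig(
        outdir=str(outdir),
        seed=seed,
        simulate=True,
        scene={"image_shape": (384, 384), "n_cells": 40, "aggregate_probability": 0.5},
        fluorescence=True,
    )


def run_pipeline(config: RunConfig) -> dict:
    """Run the configured stages and return the output manifest."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    truth = None
    fluor = None
    stage = "setup"

    def _stage(name: str) -> None:
        nonlocal stage
        stage = name
        logger.info("stage: %s", name)

    try:
        if config.simulate:
            _stage("simulate")
            scene_params = SceneParams(**{"seed": config.seed, **config.scene})
            truth = generate_scene(scene_params)
            refs = default_references()
            stack, _ = render_stack(truth, refs, seed=config.seed + 1)
            if config.fluorescence is True:
                fluor = render_fluorescence(truth, seed=config.seed + 2)
        else:
            _stage("load")
            stack = hio.read_stack(config.stack_path)
            if config.refs_paths:
                spectra = tuple(hio.read_spectrum_csv(p) for p in config.refs_paths)
                refs = ReferenceSet(spectra=spectra)
            else:
                refs = default_references()
            if isinstance(config.fluorescence, str):
                import tifffile

                fluor = tifffile.imread(config.fluorescence).astype(float)

        _stage("background reference")
        if config.background == "auto":
            bg = estimate_background_spectrum(stack)
            spectra = list(refs.spectra)
            names = list(refs.names)
            if "background" in names:
                spectra[names.index("background")] = bg
            else:
                spectra.append(bg)
                names.append("background")
            refs = ReferenceSet(spectra=tuple(spectra), names=tuple(names))
        elif config.background:
            bg = hio.read_spectrum_csv(config.background, label="background")
            refs = ReferenceSet(
                spectra=tuple(list(refs.spectra) + [bg]),
                names=tuple(list(refs.names) + ["background"]),
            )

        _stage("unmix")
        if config.lam == "auto":
            lam = select_lambda(stack, refs, seed=config.seed)
            logger.info("selected lambda = %g", lam)
        else:
            lam = float(config.lam)
        cfg = UnmixConfig(
            lam=lam, nonnegative=config.nonnegative, normalize_refs=config.normalize_refs,
            resample_refs=True,
        )
        maps = unmix_stack(stack, refs, cfg)

        _stage("segment")
        summed = window_sum(stack, DEFAULT_WINDOWS["fingerprint"])
        if config.cell_mask_path:
            cells = import_labels(config.cell_mask_path, kind="cell",
                                  pixel_size=stack.pixel_size)
        else:
            cells = segment_cells(summed, **config.segmentation)
            cells = CellLabelMask(labels=cells.labels, pixel_size=stack.pixel_size)
        if config.aggregate_mask_path:
            aggs = import_labels(config.aggregate_mask_path, kind="aggregate",
                                 cells_for_parenting=cells)
        else:
            aggs = segment_aggregates(maps["limonene"], cells, **config.aggregates)

        _stage("quantify")
        in_cell_rest = (cells.labels > 0) & (aggs.labels == 0)
        cellbody = maps["cell_body"] if "cell_body" in maps.names else None
        norm = float(cellbody[in_cell_rest].mean()) if (
            cellbody is not None and in_cell_rest.any()
        ) else 1.0
        cell_table, agg_table = extract_cell_features(
            stack, maps, cells, aggs,
            fluorescence=fluor,
            location_mode=config.location_mode,
            rich_threshold=config.rich_threshold,
            control_cellbody_mean=norm if norm > 0 else 1.0,
        )
        summaries = population_summaries(cell_table, agg_table)
        summaries["seed"] = config.seed
        summaries["lam"] = lam
        summaries["rich_threshold"] = config.rich_threshold
        summaries["cellbody_norm"] = norm

        if fluor is not None:
            _stage("colocalize")
            in_cell = cells.labels > 0
            if config.colocal_threshold == "auto":
                thr = auto_threshold(fluor, "otsu", restrict_mask=in_cell)
            else:
                thr = float(config.colocal_threshold)
            result = mcc(maps["limonene"], fluor, thr, restrict_mask=in_cell)
            summaries["mcc"] = result.mcc
            summaries["mcc_threshold"] = result.threshold_used
            summaries["mcc_n_colocal_pixels"] = result.n_colocal_pixels
        else:
            logger.info("no fluorescence channel: colocalization skipped")

        _stage("write outputs")
        extra = {"summed_fingerprint": summed}
        if fluor is not None:
            extra["fluorescence"] = fluor
        tables = {"cell_features": cell_table, "aggregate_features": agg_table}
        if truth is not None:
            import pandas as pd

            tables["truth_aggregates"] = pd.DataFrame(
                [dataclasses.asdict(a) for a in truth.aggregates]
            )
        manifest = hio.write_outputs(
            outdir,
            maps=maps,
            cells=cells,
            aggregates=aggs,
            tables=tables,
            summaries=summaries,
            extra_maps=extra,
        )
        (outdir / "run_config.yaml").write_text(yaml.safe_dump(config.to_dict()))
        return manifest
    except Exception as exc:  # noqa: BLE001 - re-raise with stage context
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc
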