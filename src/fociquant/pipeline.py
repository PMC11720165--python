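"""End-to-end orchestration: simulate/load fields, segment, classify,
quantify, detect nodules and clusters, gate the cell cycle, and write the
result bundle (CSV tables, label-mask TIFFs, YAML manifest).

Identical configuration + seed reproduces byte-identical CSVs. No stage
mutates upstream outputs; every row is traceable to ``(image, cell_id)``.
"""
from __future__ import annotations

import logging
import time
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from . import __version__
from .exceptions import ConfigurationError, GateFittingError
from .types import ChannelStack
from . import cellcycle as cc
from . import classify as cls
from . import clusters as clu
from . import io as fio
from . import nodules as nod
from . import quantify as qf
from . import segmentation as seg
from .simulate import FieldConfig, generate_field
from .stats import anova_tukey, results_table

logger = logging.getLogger(__name__)

REQUIRED_ROLES = ("dna", "f_actin", "ha")


@dataclass
class RunConfig:
    """Validated run description (usually loaded from YAML)."""

    output_dir: str = "fociquant_out"
    seed: int = 0
    #: simulation request: number of fields plus FieldConfig overrides
    simulate: dict | None = None
    #: or: list of TIFF paths to analyze
    inputs: list[str] = dc_field(default_factory=list)
    roles: dict[str, int] = dc_field(default_factory=lambda: {"dna": 0, "f_actin": 1, "ha": 2})
    segmentation: dict = dc_field(default_factory=dict)
    classify: dict = dc_field(default_factory=dict)
    nodules: dict = dc_field(default_factory=dict)
    clusters: dict = dc_field(default_factory=dict)
    cellcycle: dict = dc_field(default_factory=dict)
    #: experiment/construct/treatment labels attached to every row
    group: dict = dc_field(default_factory=dict)
    save_masks: bool = True

    def validate(self) -> None:
        if self.simulate is None and not self.inputs:
            raise ConfigurationError("config needs either 'simulate' or 'inputs'")
        for role in REQUIRED_ROLES:
            if role not in self.roles:
                raise ConfigurationError(f"channel role {role!r} missing from config")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        cfg = cls(**data)
        cfg.validate()
        return cfg


def analyze_field(stack: ChannelStack, config: RunConfig,
                  image_id: str = "field_0") -> dict:
    """Run segmentation through nodule/cluster analysis on one stack.

    Returns a dict with the per-cell table, nodule and colocalization
    tables, optional cluster table, and the label masks. Cell-cycle gating
    needs the pooled per-cell table of a whole run and is applied in
    :func:`run_pipeline`.
    """
    seg_params = dict(config.segmentation)
    z = 0
    if stack.n_z > 1:
        z = fio.central_plane(
            stack, lambda img: seg.segment_nuclei(img, **seg_params))
        logger.info("%s: central plane z=%d of %d", image_id, z, stack.n_z)

    channels = {role: stack.channel(role, z=z) for role in stack.roles}
    nuclei = seg.segment_nuclei(channels["dna"], **seg_params)
    cells = seg.segment_cells(channels["f_actin"], nuclei)
    cells, nuclei = seg.exclude_border(cells, nuclei)

    df = qf.measure_field(channels, cells, nuclei)
    if df.empty:
        logger.warning("%s: no cells retained", image_id)
        return {"cells": df, "nodules": pd.DataFrame(),
                "nodule_coloc": pd.DataFrame(), "clusters": pd.DataFrame(),
                "masks": {"nuclei": nuclei, "cells": cells}}
    # NoBaselineError propagates: a field with no untransfected cell has no
    # background/normalization baseline and is unusable.
    df["transfected"] = cls.classify_transfected(
        df["ha_cell_mean"].to_numpy(), **config.classify)
    if (~df["transfected"]).any():
        df = cls.subtract_utf_background(df)
        df = qf.add_normalized_columns(df)
    df.insert(0, "image", image_id)
    df["ha_nuclear_fraction"] = qf.nuclear_fraction(df, "ha")

    nod_params = dict(config.nodules)
    channel_b_name = nod_params.pop("channel_b", "f_actin")
    tf_ids = df.loc[df["transfected"], "cell_id"].to_numpy()
    tf_nuclei = np.where(np.isin(nuclei, tf_ids), nuclei, 0)
    nodule_df, coloc_df = nod.nodule_tables(
        channels["ha"], channels[channel_b_name], tf_nuclei,
        channel_b_name=channel_b_name, **nod_params)
    nodule_df.insert(0, "image", image_id)
    coloc_df.insert(0, "image", image_id)

    cluster_df = pd.DataFrame()
    if "polii" in channels:
        cluster_df = clu.cluster_table(channels["polii"], nuclei, **config.clusters)
        cluster_df = clu.normalize_tf_utf(
            cluster_df,
            cluster_df["cell_id"].map(df.set_index("cell_id")["transfected"]))
        cluster_df.insert(0, "image", image_id)

    return {"cells": df, "nodules": nodule_df, "nodule_coloc": coloc_df,
            "clusters": cluster_df, "masks": {"nuclei": nuclei, "cells": cells}}


def simulate_fields(config: RunConfig) -> list[tuple[str, ChannelStack, object]]:
    """Generate the fields requested by ``config.simulate``."""
    sim = dict(config.simulate or {})
    n_fields = int(sim.pop("n_fields", 1))
    fields = []
    for i in range(n_fields):
        fc = FieldConfig(**sim, seed=int(config.seed) * 1000 + i)
        stack, truth = generate_field(fc)
        fields.append((f"field_{i}", stack, truth))
    return fields


def run_pipeline(config: RunConfig) -> dict:
    """Execute a full run and write the result bundle to ``output_dir``.

    Emits ``cells.csv``, ``nodules.csv``, ``nodule_coloc.csv``,
    ``clusters.csv`` (when a Pol II channel exists), ``phase_summary.csv``
    and ``stats.csv`` (when an EdU channel exists), label-mask TIFFs and a
    ``manifest.yaml`` capturing config, seed and package version.
    """
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)

    if config.simulate is not None:
        fields = [(fid, stack) for fid, stack, _truth in simulate_fields(config)]
    else:
        fields = [(Path(p).stem, fio.load_stack(p, config.roles))
                  for p in config.inputs]

    bundles = []
    image_ids = []
    for image_id, stack in fields:
        t0 = time.perf_counter()
        bundles.append(analyze_field(stack, config, image_id=image_id))
        image_ids.append(image_id)
        logger.info("%s analyzed in %.2fs", image_id, time.perf_counter() - t0)

    cells = pd.concat([b["cells"] for b in bundles], ignore_index=True)
    nodules = pd.concat([b["nodules"] for b in bundles], ignore_index=True)
    coloc = pd.concat([b["nodule_coloc"] for b in bundles], ignore_index=True)
    clusters_df = pd.concat([b["clusters"] for b in bundles], ignore_index=True)
    for key, value in config.group.items():
        cells[key] = value

    results: dict = {"cells": cells, "nodules": nodules,
                     "nodule_coloc": coloc, "clusters": clusters_df}

    if "edu" in config.roles and not cells.empty:
        try:
            gates = cc.fit_gates(cells["dna_nucleus_integrated"].to_numpy(),
                                 cells["edu_nucleus_mean"].to_numpy(),
                                 **config.cellcycle)
            cells["phase"] = cc.assign_phase(
                cells["dna_nucleus_integrated"], cells["edu_nucleus_mean"], gates).values
            classified = cells[cells["phase"].isin(cc.PHASES)]
            summary = cc.phase_summary(classified)
            results["phase_summary"] = summary
            results["gates"] = gates
            groups = {ph: sub["ha_nuclear_fraction"].dropna().to_numpy()
                      for ph, sub in classified.groupby("phase")}
            groups = {k: v for k, v in groups.items() if v.size >= 2}
            if len(groups) >= 3:
                results["stats"] = results_table(anova_tukey(groups))
        except GateFittingError as exc:
            logger.warning("cell-cycle gating skipped: %s", exc)

    _write_bundle(out, config, results, bundles, image_ids)
    return results


def _write_bundle(out: Path, config: RunConfig, results: dict, bundles,
                  image_ids: list[str]) -> None:
    float_fmt = "%.10g"  # stable text representation -> reproducible bytes
    results["cells"].to_csv(out / "cells.csv", index=False, float_format=float_fmt)
    for name in ("nodules", "nodule_coloc", "clusters"):
        df = results.get(name)
        if df is not None and not df.empty:
            df.to_csv(out / f"{name}.csv", index=False, float_format=float_fmt)
    if "phase_summary" in results:
        results["phase_summary"].to_csv(out / "phase_summary.csv", index=False,
                                        float_format=float_fmt)
        gates = results["gates"]
        with open(out / "gates.yaml", "w") as fh:
            yaml.safe_dump({"dapi_g1_window": list(gates.dapi_g1_window),
                            "dapi_g2_window": list(gates.dapi_g2_window),
                            "edu_cutoff": gates.edu_cutoff}, fh)
    if "stats" in results:
        results["stats"].to_csv(out / "stats.csv", index=False,
                                float_format=float_fmt)
    if config.save_masks:
        masks_dir = out / "masks"
        masks_dir.mkdir(exist_ok=True)
        for b, image_id in zip(bundles, image_ids):
            for kind, mask in b["masks"].items():
                tifffile.imwrite(masks_dir / f"{image_id}_{kind}.tif",
                                 mask.astype(np.uint16))
    manifest = {
        "fociquant_version": __version__,
        "seed": config.seed,
        "config": {k: v for k, v in vars(config).items()},
    }
    with open(out / "manifest.yaml", "w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)
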