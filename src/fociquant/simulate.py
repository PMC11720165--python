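"""Synthetic multi-channel fluorescence fields with full ground truth.

The generator emulates the statistical structure of sparse adherent
U2OS-like fields imaged by confocal microscopy:

* elliptical cells with a concentric elliptical nucleus, placed on a
  jittered grid so cells never overlap;
* a DAPI channel whose integrated nuclear intensity is proportional to DNA
  content (2N in G1, 4N in G2/M, intermediate in S);
* a phalloidin (F-actin) channel with bright cytoplasm and a dimmer nuclear
  pool whose level is scaled by ``factin_scale`` (emulating an Arp2/3
  inhibitor arm);
* an HA channel in which a Bernoulli subpopulation of "transfected" cells
  carries a strong signal split between nucleus and cytoplasm to realize a
  prescribed nuclear fraction, over a faint background in untransfected
  cells;
* intranuclear nodules whose HA and F-actin additions are drawn from a
  bivariate Gaussian with a prescribed Pearson correlation;
* optional RNA Pol II puncta and an EdU channel marking S-phase nuclei.

All randomness flows from a single :func:`numpy.random.default_rng` stream
seeded by ``FieldConfig.seed``, so identical configurations are
bit-reproducible. Noise-free channel renders and label masks are kept in
the :class:`GroundTruth` so recovery tests can compare pipeline output
against known truth.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError
from .types import ChannelStack

# Intensity model (arbitrary camera units on a 16-bit scale). These are the
# fixed photometric conventions of the simulation, not tunables: tests and
# recovery analyses depend only on ratios and correlations, never on the
# absolute levels.
_FACTIN_CYTO = 150.0          # phalloidin, cytoplasm
_FACTIN_NUC = 80.0            # phalloidin, nucleoplasm (before factin_scale)
_HA_UNTRANSFECTED = 30.0      # faint HA background inside untransfected cells
_HA_TOTAL = 4.0e5             # expected integrated HA per transfected cell
_HA_SCATTER = 0.25            # lognormal sigma of per-cell expression level
_DAPI_LEVEL = 150.0           # per-pixel DAPI for 2N at the reference area
_DAPI_REF_AREA = 350.0        # reference nucleus area (px) for DAPI scaling
_NODULE_HA_MU = 1500.0        # mean HA addition on nodule pixels
_NODULE_FA_MU = 800.0         # mean F-actin addition on nodule pixels
_NODULE_SD = 200.0            # sd of the bivariate nodule draw
_POLII_NUC_BG = 50.0          # Pol II nucleoplasm background
_POLII_PUNCTUM = 600.0        # mean Pol II addition on punctum pixels
_POLII_PUNCTUM_SD = 100.0
_EDU_S_MEAN = 400.0           # EdU nuclear level in S phase
_EDU_BG = 20.0                # EdU background in non-S nuclei

_CELL_R = (16, 21)            # semi-axis range of the cell ellipse, px
_NUC_R = (10, 13)              # semi-axis range of the nucleus ellipse, px
_GRID_PITCH = 52              # center-to-center pitch; no two cells overlap
_INTERIOR_MARGIN = 60         # interior centers at least this far from edges
_BORDER_OFFSET = 8            # border-cell centers this far from their edge

_PHASES = ("G1", "S", "G2M")


@dataclass
class FieldConfig:
    """Parameters of one synthetic field.

    All fractions live in [0, 1]; ``seed`` fully determines the output.
    """

    width: int = 512
    height: int = 512
    n_cells: int = 30
    p_transfected: float = 0.3
    ha_nuclear_fraction: float = 0.5
    #: per-cell biological scatter of the nuclear fraction (sd, clipped)
    ha_nuclear_fraction_sd: float = 0.05
    #: optional phase -> nuclear-fraction map; overrides the global mean
    ha_nuclear_fraction_by_phase: dict[str, float] | None = None
    p_nodule: float = 0.8
    nodules_per_cell: int = 2
    nodule_rho: float = 0.9
    factin_scale: float = 1.0
    #: mixture weights of the G1 (2N), S (EdU+) and G2/M (4N) populations
    phase_fractions: tuple[float, float, float] = (0.5, 0.3, 0.2)
    noise_sd: float = 10.0
    #: fraction of cells deliberately placed touching the image border
    p_border: float = 0.1
    include_polii: bool = False
    polii_mean_clusters: float = 8.0
    #: multiplier on the expected punctum count in transfected cells
    polii_tf_multiplier: float = 1.0
    include_edu: bool = False
    seed: int = 0

    def validate(self) -> None:
        for name in ("p_transfected", "ha_nuclear_fraction", "p_nodule", "p_border"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name}={v!r} must lie in [0, 1]")
        if not -1.0 <= self.nodule_rho <= 1.0:
            raise ConfigurationError(f"nodule_rho={self.nodule_rho!r} must lie in [-1, 1]")
        if self.n_cells < 0:
            raise ConfigurationError("n_cells must be >= 0")
        if self.width <= 0 or self.height <= 0:
            raise ConfigurationError("width and height must be positive")
        if self.noise_sd < 0:
            raise ConfigurationError("noise_sd must be >= 0")
        if self.factin_scale < 0:
            raise ConfigurationError("factin_scale must be >= 0")
        if self.nodules_per_cell < 0:
            raise ConfigurationError("nodules_per_cell must be >= 0")
        w = np.asarray(self.phase_fractions, dtype=float)
        if w.shape != (3,) or np.any(w < 0) or not math.isclose(w.sum(), 1.0, abs_tol=1e-6):
            raise ConfigurationError("phase_fractions must be 3 nonnegative weights summing to 1")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class GroundTruth:
    """Everything the generator knows about a rendered field.

    ``cells`` has one row per cell (geometry, transfection flag, phase, DNA
    content, the realized noise-free nuclear fraction and the border flag);
    ``nodules`` one row per nodule (parent cell, area, target and realized
    correlation). Label masks share the cell ids used in ``cells``; ``clean``
    holds the noise-free float render of every channel.
    """

    cells: pd.DataFrame
    nodules: pd.DataFrame
    cell_labels: np.ndarray
    nucleus_labels: np.ndarray
    nodule_labels: np.ndarray
    cluster_labels: np.ndarray
    clean: dict[str, np.ndarray] = field(default_factory=dict)

    def nodule_pixels(self, nodule_id: int) -> np.ndarray:
        return self.nodule_labels == nodule_id


def _ellipse_mask(shape: tuple[int, int], cy: float, cx: float,
                  ry: float, rx: float) -> np.ndarray:
    """Boolean mask of an axis-aligned ellipse, clipped to the image."""
    y0 = max(int(cy - ry) - 1, 0)
    y1 = min(int(cy + ry) + 2, shape[0])
    x0 = max(int(cx - rx) - 1, 0)
    x1 = min(int(cx + rx) + 2, shape[1])
    mask = np.zeros(shape, dtype=bool)
    if y1 <= y0 or x1 <= x0:
        return mask
    yy = np.arange(y0, y1)[:, None]
    xx = np.arange(x0, x1)[None, :]
    mask[y0:y1, x0:x1] = ((yy - cy) / ry) ** 2 + ((xx - cx) / rx) ** 2 <= 1.0
    return mask


def _place_centers(cfg: FieldConfig, rng: np.random.Generator):
    """Jittered-grid placement: interior slots plus border slots.

    Returns a list of ``(cy, cx, on_border)``. Grid pitch exceeds the cell
    diameter, so no two cells overlap; a ConfigurationError is raised when
    the field cannot hold ``n_cells``.
    """
    h, w = cfg.height, cfg.width
    interior = [
        (float(y), float(x))
        for y in range(_INTERIOR_MARGIN, h - _INTERIOR_MARGIN + 1, _GRID_PITCH)
        for x in range(_INTERIOR_MARGIN, w - _INTERIOR_MARGIN + 1, _GRID_PITCH)
    ]
    border: list[tuple[float, float]] = []
    for t in range(_INTERIOR_MARGIN, w - _INTERIOR_MARGIN + 1, _GRID_PITCH):
        border.append((float(_BORDER_OFFSET), float(t)))            # top edge
        border.append((float(h - 1 - _BORDER_OFFSET), float(t)))    # bottom edge
    for t in range(_INTERIOR_MARGIN, h - _INTERIOR_MARGIN + 1, _GRID_PITCH):
        border.append((float(t), float(_BORDER_OFFSET)))            # left edge
        border.append((float(t), float(w - 1 - _BORDER_OFFSET)))    # right edge

    n_border = int(round(cfg.p_border * cfg.n_cells))
    n_interior = cfg.n_cells - n_border
    if n_interior > len(interior) or n_border > len(border):
        raise ConfigurationError(
            f"field {w}x{h} cannot hold {cfg.n_cells} cells "
            f"({len(interior)} interior / {len(border)} border slots)")

    jitter = 3
    chosen = []
    for pool, n in ((interior, n_interior), (border, n_border)):
        idx = rng.permutation(len(pool))[:n]
        for i in idx:
            cy, cx = pool[i]
            chosen.append((cy + rng.uniform(-jitter, jitter),
                           cx + rng.uniform(-jitter, jitter),
                           pool is border))
    return chosen


def generate_field(config: FieldConfig) -> tuple[ChannelStack, GroundTruth]:
    """Render one synthetic field and its ground truth.

    Returns a 16-bit :class:`ChannelStack` (channels ``dna``, ``f_actin``,
    ``ha`` plus ``polii``/``edu`` when enabled) and the matching
    :class:`GroundTruth`. Identical ``config`` (including ``seed``) yields
    bit-identical output.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    shape = (config.height, config.width)

    roles = {"dna": 0, "f_actin": 1, "ha": 2}
    if config.include_polii:
        roles["polii"] = len(roles)
    if config.include_edu:
        roles["edu"] = len(roles)

    clean = {r: np.zeros(shape, dtype=np.float64) for r in roles}
    cell_labels = np.zeros(shape, dtype=np.int32)
    nucleus_labels = np.zeros(shape, dtype=np.int32)
    nodule_labels = np.zeros(shape, dtype=np.int32)
    cluster_labels = np.zeros(shape, dtype=np.int32)

    centers = _place_centers(config, rng)
    cell_rows: list[dict] = []
    nodule_rows: list[dict] = []
    fraction_map = config.ha_nuclear_fraction_by_phase
    nodule_id = 0

    for cell_id, (cy, cx, _on_border) in enumerate(centers, start=1):
        cell_ry = rng.uniform(*_CELL_R)
        cell_rx = rng.uniform(*_CELL_R)
        nuc_ry = min(rng.uniform(*_NUC_R), cell_ry - 4.0)
        nuc_rx = min(rng.uniform(*_NUC_R), cell_rx - 4.0)

        transfected = bool(rng.random() < config.p_transfected)
        phase = _PHASES[rng.choice(3, p=np.asarray(config.phase_fractions, dtype=float))]
        if phase == "G1":
            dna_content = 1.0
        elif phase == "G2M":
            dna_content = 2.0
        else:
            dna_content = rng.uniform(1.1, 1.9)

        if fraction_map is not None:
            target_fraction = float(fraction_map[phase])
        else:
            target_fraction = float(np.clip(
                rng.normal(config.ha_nuclear_fraction, config.ha_nuclear_fraction_sd),
                0.02, 0.98))

        cell_mask = _ellipse_mask(shape, cy, cx, cell_ry, cell_rx)
        nuc_mask = _ellipse_mask(shape, cy, cx, nuc_ry, nuc_rx) & cell_mask
        cyto_mask = cell_mask & ~nuc_mask
        nuc_area = int(nuc_mask.sum())
        cyto_area = int(cyto_mask.sum())
        if nuc_area == 0 or cyto_area == 0:  # fully cropped at a border
            continue
        cell_labels[cell_mask] = cell_id
        nucleus_labels[nuc_mask] = cell_id

        # DAPI: integrated nuclear intensity proportional to DNA content,
        # independent of the drawn nucleus area.
        clean["dna"][nuc_mask] = _DAPI_LEVEL * dna_content * _DAPI_REF_AREA / nuc_area

        # F-actin: bright cytoplasm; the whole nuclear pool (baseline plus any
        # nodule additions) is multiplied by factin_scale at the end so that
        # scaling it by s scales nuclear integrated F-actin by exactly s.
        clean["f_actin"][cyto_mask] = _FACTIN_CYTO
        nuclear_factin = np.full(nuc_area, _FACTIN_NUC, dtype=np.float64)

        # HA + nodules.
        nuc_idx = np.flatnonzero(nuc_mask.ravel())
        if transfected:
            total = _HA_TOTAL * rng.lognormal(0.0, _HA_SCATTER)
            nuclear_budget = target_fraction * total
            ha_nuc = np.zeros(nuc_area, dtype=np.float64)

            n_nodules = (config.nodules_per_cell
                         if config.nodules_per_cell > 0 and rng.random() < config.p_nodule
                         else 0)
            nodule_masks = _place_nodules(rng, shape, cy, cx, nuc_ry, nuc_rx,
                                          nuc_mask, n_nodules)
            if nodule_masks:
                flat = {int(i): k for k, i in enumerate(nuc_idx)}
                draws = []
                for nmask in nodule_masks:
                    npx = int(nmask.sum())
                    z = rng.standard_normal((2, npx))
                    ha_add = _NODULE_HA_MU + _NODULE_SD * z[0]
                    rho = config.nodule_rho
                    fa_add = _NODULE_FA_MU + _NODULE_SD * (
                        rho * z[0] + math.sqrt(max(0.0, 1.0 - rho * rho)) * z[1])
                    draws.append((nmask, np.clip(ha_add, 0.0, None),
                                  np.clip(fa_add, 0.0, None)))
                # Keep nodules within the nuclear HA budget so the rendered
                # nuclear fraction still equals the per-cell target.
                tot_nod = sum(d[1].sum() for d in draws)
                if tot_nod > 0.8 * nuclear_budget:
                    scale = 0.8 * nuclear_budget / tot_nod
                    draws = [(m, h * scale, f) for m, h, f in draws]
                for nmask, ha_add, fa_add in draws:
                    nodule_id += 1
                    nodule_labels[nmask] = nodule_id
                    pos = np.array([flat[int(i)] for i in np.flatnonzero(nmask.ravel())])
                    ha_nuc[pos] += ha_add
                    nuclear_factin[pos] += fa_add
                    r = (np.corrcoef(ha_add, fa_add)[0, 1]
                         if len(ha_add) >= 3 and ha_add.std() > 0 and fa_add.std() > 0
                         else np.nan)
                    nodule_rows.append({
                        "nodule_id": nodule_id, "cell_id": cell_id,
                        "area": int(nmask.sum()),
                        "target_rho": config.nodule_rho,
                        "set_correlation": r,
                    })
            # Spread the remaining nuclear budget uniformly over non-nodule
            # nucleus pixels.
            rest = nuclear_budget - ha_nuc.sum()
            free = ha_nuc == 0
            if free.any():
                ha_nuc[free] += max(rest, 0.0) / free.sum()
            clean["ha"].ravel()[nuc_idx] = ha_nuc
            clean["ha"][cyto_mask] = (1.0 - target_fraction) * total / cyto_area
        else:
            clean["ha"][cell_mask] = _HA_UNTRANSFECTED

        clean["f_actin"].ravel()[nuc_idx] = nuclear_factin * config.factin_scale

        # Optional marker channels.
        n_polii_true = 0
        if config.include_polii:
            clean["polii"][nuc_mask] = _POLII_NUC_BG
            lam = config.polii_mean_clusters * (
                config.polii_tf_multiplier if transfected else 1.0)
            n_polii_true = _render_puncta(rng, shape, cy, cx, nuc_ry, nuc_rx,
                                          nuc_mask, clean["polii"],
                                          cluster_labels, cell_id,
                                          int(rng.poisson(lam)))
        if config.include_edu:
            clean["edu"][nuc_mask] = _EDU_S_MEAN if phase == "S" else _EDU_BG

        ha_cell = clean["ha"][cell_mask].sum()
        cell_rows.append({
            "cell_id": cell_id, "cy": cy, "cx": cx,
            "cell_ry": cell_ry, "cell_rx": cell_rx,
            "nuc_ry": nuc_ry, "nuc_rx": nuc_rx,
            "transfected": transfected, "phase": phase,
            "dna_content": dna_content,
            "target_nuclear_fraction": target_fraction,
            "true_nuclear_fraction": (clean["ha"][nuc_mask].sum() / ha_cell
                                      if ha_cell > 0 else np.nan),
            "n_polii_true": n_polii_true,
            "border_touching": _touches_border(cell_mask),
        })

    cells = pd.DataFrame(cell_rows, columns=[
        "cell_id", "cy", "cx", "cell_ry", "cell_rx", "nuc_ry", "nuc_rx",
        "transfected", "phase", "dna_content", "target_nuclear_fraction",
        "true_nuclear_fraction", "n_polii_true", "border_touching"])
    nodules = pd.DataFrame(nodule_rows, columns=[
        "nodule_id", "cell_id", "area", "target_rho", "set_correlation"])

    pixels = np.stack([clean[r] for r in roles])
    if config.noise_sd > 0:
        pixels = pixels + rng.normal(0.0, config.noise_sd, size=pixels.shape)
    pixels = np.clip(np.rint(pixels), 0, 65535).astype(np.uint16)

    stack = ChannelStack(pixels[np.newaxis], roles)
    truth = GroundTruth(cells=cells, nodules=nodules,
                        cell_labels=cell_labels, nucleus_labels=nucleus_labels,
                        nodule_labels=nodule_labels, cluster_labels=cluster_labels,
                        clean=clean)
    return stack, truth


def _touches_border(mask: np.ndarray) -> bool:
    return bool(mask[0].any() or mask[-1].any() or mask[:, 0].any() or mask[:, -1].any())


def _place_nodules(rng, shape, cy, cx, nuc_ry, nuc_rx, nuc_mask, n):
    """Disjoint disc-shaped nodules inside the nucleus, >=1 px apart so
    they stay separate 8-connected components."""
    masks: list[np.ndarray] = []
    occupied = np.zeros(shape, dtype=bool)
    for _ in range(n):
        for _attempt in range(80):
            # shrink the disc if the nucleus is getting crowded
            r = rng.uniform(2.5, 3.6) if _attempt < 40 else rng.uniform(2.3, 2.8)
            theta = rng.uniform(0, 2 * math.pi)
            rad = rng.uniform(0, 0.95)
            ny = cy + rad * (nuc_ry - r - 1) * math.sin(theta)
            nx = cx + rad * (nuc_rx - r - 1) * math.cos(theta)
            m = _ellipse_mask(shape, ny, nx, r, r)
            if m.sum() >= 15 and not (m & ~nuc_mask).any() \
                    and not (_dilate(m) & occupied).any():
                masks.append(m)
                occupied |= m
                break
    return masks


def _dilate(mask: np.ndarray) -> np.ndarray:
    from scipy import ndimage
    return ndimage.binary_dilation(mask, structure=np.ones((3, 3), dtype=bool))


def _render_puncta(rng, shape, cy, cx, nuc_ry, nuc_rx, nuc_mask,
                   channel, cluster_labels, cell_id, n):
    """Small bright discs inside the nucleus; returns the number placed."""
    placed = 0
    occupied = np.zeros(shape, dtype=bool)
    for _ in range(n):
        for _attempt in range(40):
            r = rng.uniform(1.7, 2.2)
            theta = rng.uniform(0, 2 * math.pi)
            rad = rng.uniform(0, 0.95)
            py = cy + rad * (nuc_ry - r - 1) * math.sin(theta)
            px = cx + rad * (nuc_rx - r - 1) * math.cos(theta)
            m = _ellipse_mask(shape, py, px, r, r)
            if m.sum() >= 8 and not (m & ~nuc_mask).any() \
                    and not (_dilate(m) & occupied).any():
                channel[m] += max(rng.normal(_POLII_PUNCTUM, _POLII_PUNCTUM_SD), 100.0)
                cluster_labels[m] = cell_id * 1000 + placed + 1
                occupied |= m
                placed += 1
                break
    return placed


def match_labels(segmented: np.ndarray, reference: np.ndarray) -> dict[int, int]:
    """Map each segmented label to the reference label it overlaps most.

    Ground-truth utility for recovery tests: segmentation assigns arbitrary
    label ids, so object-level comparisons go through majority pixel
    overlap. Segmented objects overlapping only background map to 0.
    """
    segmented = np.asarray(segmented).ravel()
    reference = np.asarray(reference).ravel()
    keep = segmented > 0
    pairs, counts = np.unique(
        np.stack([segmented[keep], reference[keep]]), axis=1, return_counts=True)
    best: dict[int, tuple[int, int]] = {}
    for (s, r), c in zip(pairs.T, counts):
        if s not in best or c > best[s][1]:
            best[int(s)] = (int(r), int(c))
    return {s: r for s, (r, _c) in best.items()}
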