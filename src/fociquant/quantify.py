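"""Per-cell intensity measurements and the headline statistics.

The measurement table has one row per retained cell and, for every channel
and compartment (nucleus, cytoplasm, whole cell), the integrated and mean
intensity plus the compartment areas. The identities
``integrated == mean * area`` and ``nucleus_area + cytoplasm_area ==
cell_area`` hold exactly on each pixel set.

Headline statistics:

* **nuclear fraction** — integrated intensity of a channel in the nucleus
  divided by its integrated intensity in the whole cell (in [0, 1] when the
  whole-cell signal is positive; recorded as missing, never as 0, when it
  is not);
* **UTF normalization** — a transfected cell's value divided by the mean of
  the corresponding values over untransfected (UTF) cells, by default
  within the same image.
"""
from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import NoBaselineError

COMPARTMENTS = ("nucleus", "cytoplasm", "cell")


def integrated_intensity(pixel_set: np.ndarray, image: np.ndarray) -> float:
    """Sum of image values over a boolean pixel set (0 for an empty set)."""
    pixel_set = np.asarray(pixel_set, dtype=bool)
    if pixel_set.shape != image.shape:
        raise IndexError(f"pixel set shape {pixel_set.shape} does not match "
                         f"image shape {image.shape}")
    return float(np.asarray(image, dtype=np.float64)[pixel_set].sum())


def measure_field(channels: dict[str, np.ndarray],
                  cells: np.ndarray,
                  nuclei: np.ndarray) -> pd.DataFrame:
    """Per-cell measurement table for one field.

    ``channels`` maps role names to 2-D images aligned with the ``cells``
    and ``nuclei`` label masks. Column naming is
    ``{role}_{compartment}_{integrated|mean}``.
    """
    cells = np.asarray(cells)
    nuclei = np.asarray(nuclei)
    labels = np.unique(cells)
    labels = labels[labels > 0]
    n = int(cells.max()) + 1 if labels.size else 1
    cyto = np.where(nuclei > 0, 0, cells)

    rows: dict[str, np.ndarray] = {"cell_id": labels}
    comp_masks = {"nucleus": nuclei, "cytoplasm": cyto, "cell": cells}
    areas = {}
    for comp, lab in comp_masks.items():
        counts = np.bincount(lab.ravel(), minlength=n)[labels]
        areas[comp] = counts
        rows[f"{comp}_area"] = counts.astype(np.int64)
    for role, image in channels.items():
        image = np.asarray(image, dtype=np.float64)
        for comp, lab in comp_masks.items():
            sums = np.bincount(lab.ravel(), weights=image.ravel(),
                               minlength=n)[labels]
            rows[f"{role}_{comp}_integrated"] = sums
            with np.errstate(invalid="ignore", divide="ignore"):
                rows[f"{role}_{comp}_mean"] = np.where(
                    areas[comp] > 0, sums / np.maximum(areas[comp], 1), np.nan)
    return pd.DataFrame(rows)


def nuclear_fraction(df: pd.DataFrame, channel: str = "ha") -> pd.Series:
    """Nuclear integrated intensity over whole-cell integrated intensity.

    Cells with zero whole-cell signal get NaN (missing), never 0.
    """
    whole = df[f"{channel}_cell_integrated"]
    nuc = df[f"{channel}_nucleus_integrated"]
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(whole > 0, nuc / whole, np.nan)
    return pd.Series(frac, index=df.index, name=f"{channel}_nuclear_fraction")


def normalize_to_utf(tf_values, utf_values) -> np.ndarray:
    """Divide values by the mean of the untransfected-cell baseline.

    Raises :class:`NoBaselineError` when the baseline is empty or its mean
    is not positive.
    """
    utf_values = np.asarray(utf_values, dtype=np.float64)
    utf_values = utf_values[~np.isnan(utf_values)]
    if utf_values.size == 0:
        raise NoBaselineError("no untransfected cells available for normalization")
    baseline = utf_values.mean()
    if baseline <= 0:
        raise NoBaselineError(f"untransfected baseline mean is {baseline}, not positive")
    return np.asarray(tf_values, dtype=np.float64) / baseline


def add_normalized_columns(df: pd.DataFrame,
                           columns: tuple[str, ...] = (
                               "dna_nucleus_integrated",
                               "f_actin_nucleus_integrated"),
                           group_key: str | None = None) -> pd.DataFrame:
    """Append ``{col}_norm`` columns: each value over the UTF mean of its group.

    ``group_key`` selects the pooling level ("image id" column for per-image
    normalization, an experiment column for per-experiment pooling, or None
    to pool the whole table). Untransfected cells have expected normalized
    value 1 by construction.
    """
    df = df.copy()
    groups = df.groupby(group_key, sort=False) if group_key else [(None, df)]
    for col in columns:
        out = pd.Series(np.nan, index=df.index)
        for _, sub in groups:
            utf = sub.loc[~sub["transfected"], col]
            out.loc[sub.index] = normalize_to_utf(sub[col], utf)
        df[f"{col}_norm"] = out
    return df
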