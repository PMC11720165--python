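"""Transfection recognition and UTF background subtraction.

Transfected (TF) cells are recognized from their HA staining intensity over
the cell area: a cell is flagged when its whole-cell mean HA exceeds
``median + k * MAD`` of the per-cell mean HA values in the same field
(raw median absolute deviation, unscaled; default ``k = 3``). The rule is
robust to the transfected tail and invariant to positive rescaling of the
channel.

The specific HA intensity of a TF cell is obtained by subtracting, per
compartment (nucleus and cytoplasm), the average HA mean intensity of the
untransfected (UTF) cells in the same image, flooring at 0, and recomputing
the integrated value as corrected mean times compartment area.
"""
from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .exceptions import NoBaselineError

logger = logging.getLogger(__name__)


def median_mad(values: np.ndarray) -> tuple[float, float]:
    """Median and raw median absolute deviation."""
    values = np.asarray(values, dtype=np.float64)
    med = float(np.median(values))
    return med, float(np.median(np.abs(values - med)))


def classify_transfected(mean_ha: np.ndarray, k: float = 3.0) -> np.ndarray:
    """Boolean transfection flags from per-cell whole-cell mean HA.

    Fields with fewer than 3 cells are all flagged untransfected (with a
    warning); a field where every cell exceeds the cutoff raises
    :class:`NoBaselineError` because it lacks a UTF baseline.
    """
    mean_ha = np.asarray(mean_ha, dtype=np.float64)
    if mean_ha.size < 3:
        logger.warning("fewer than 3 cells in field; all flagged untransfected")
        return np.zeros(mean_ha.shape, dtype=bool)
    med, mad = median_mad(mean_ha)
    flags = mean_ha > med + k * mad
    if flags.all():
        raise NoBaselineError(
            "every cell exceeds the transfection cutoff; "
            "field has no untransfected baseline")
    return flags


def subtract_utf_background(df: pd.DataFrame,
                            channel: str = "ha") -> pd.DataFrame:
    """Background-corrected compartment intensities for one image's table.

    ``df`` must carry a boolean ``transfected`` column and the measurement
    columns of :func:`fociquant.quantify.measure_field`. Adds
    ``{channel}_{compartment}_mean_corr`` and ``..._integrated_corr`` for the
    nucleus and cytoplasm: raw mean minus the UTF average of that mean,
    floored at 0; integrated recomputed as corrected mean times area.
    """
    if "transfected" not in df:
        raise KeyError("dataframe needs a 'transfected' column")
    utf = df.loc[~df["transfected"]]
    if utf.empty:
        raise NoBaselineError("no untransfected cell in image; cannot subtract background")
    df = df.copy()
    for comp in ("nucleus", "cytoplasm"):
        baseline = float(utf[f"{channel}_{comp}_mean"].mean())
        corr = np.maximum(df[f"{channel}_{comp}_mean"] - baseline, 0.0)
        df[f"{channel}_{comp}_mean_corr"] = corr
        df[f"{channel}_{comp}_integrated_corr"] = corr * df[f"{comp}_area"]
    return df
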