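"""Image-cytometry cell-cycle gating from integrated DAPI and mean EdU.

DNA content per nucleus is read from integrated DAPI: the highest peak of
its histogram marks the 2N (G1) mode and the peak nearest twice that value
marks 4N (G2/M). Gating windows span mode × [0.75, 1.25]. EdU marks DNA
synthesis, so an EdU mean above ``median + 3 * MAD`` of the presumed
EdU-negative set (the lower-DAPI half) assigns S phase with precedence over
the DNA-content windows. Cells matching no gate are reported as
``unclassified``, never dropped.

The rule set is deterministic and invariant to a common positive rescaling
of the DAPI channel, replacing interactive scatter-plot gating with a
reproducible procedure; every constant is a parameter.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks

from .classify import median_mad
from .exceptions import GateFittingError

logger = logging.getLogger(__name__)

PHASES = ("G1", "S", "G2M")


@dataclass
class PhaseGates:
    """Fitted gates: DNA-content windows around the 2N and 4N modes plus the
    EdU positivity cutoff."""
    dapi_g1_window: tuple[float, float]
    dapi_g2_window: tuple[float, float]
    edu_cutoff: float

    def __post_init__(self) -> None:
        if not self.dapi_g1_window[1] < self.dapi_g2_window[0]:
            raise GateFittingError(
                f"G1 window {self.dapi_g1_window} overlaps G2 window "
                f"{self.dapi_g2_window}")


def fit_gates(dapi_integrated: np.ndarray, edu_mean: np.ndarray,
              n_bins: int = 128, window: float = 0.25,
              edu_k: float = 3.0) -> PhaseGates:
    """Fit 2N/4N windows and the EdU cutoff from per-cell values.

    Raises :class:`GateFittingError` when the DAPI histogram is unimodal
    (no secondary peak near twice the main mode). Fewer than 100 cells
    triggers a warning; the fit still runs.
    """
    dapi = np.asarray(dapi_integrated, dtype=np.float64)
    edu = np.asarray(edu_mean, dtype=np.float64)
    if dapi.size < 100:
        logger.warning("gate fitting on %d cells; >=100 recommended", dapi.size)
    if dapi.size == 0 or dapi.min() == dapi.max():
        raise GateFittingError("DAPI distribution is degenerate (constant)")

    hist, edges = np.histogram(dapi, bins=n_bins)
    smooth = gaussian_filter1d(hist.astype(np.float64), sigma=2.0)
    # zero-pad so modes at the data range limits still count as peaks
    padded = np.concatenate([[0.0], smooth, [0.0]])
    peaks, _ = find_peaks(padded, prominence=0.05 * smooth.max())
    peaks -= 1
    if peaks.size < 2:
        raise GateFittingError(
            f"DAPI histogram has {peaks.size} peak(s); need a 2N and a 4N mode")
    centers = 0.5 * (edges[:-1] + edges[1:])[peaks]
    heights = smooth[peaks]

    mode_2n = float(centers[np.argmax(heights)])
    others = centers[centers != mode_2n]
    cand = others[np.abs(others - 2.0 * mode_2n) < 0.75 * mode_2n]
    if cand.size == 0:
        raise GateFittingError(
            f"no secondary DAPI peak near twice the 2N mode ({mode_2n:.3g})")
    mode_4n = float(cand[np.argmin(np.abs(cand - 2.0 * mode_2n))])

    low_half = edu[dapi <= np.median(dapi)]
    med, mad = median_mad(low_half)
    return PhaseGates(
        dapi_g1_window=(mode_2n * (1 - window), mode_2n * (1 + window)),
        dapi_g2_window=(mode_4n * (1 - window), mode_4n * (1 + window)),
        edu_cutoff=float(med + edu_k * mad),
    )


def assign_phase(dapi_integrated, edu_mean, gates: PhaseGates) -> pd.Series:
    """Vectorized gate application; EdU positivity takes precedence."""
    dapi = np.asarray(dapi_integrated, dtype=np.float64)
    edu = np.asarray(edu_mean, dtype=np.float64)
    phase = np.full(dapi.shape, "unclassified", dtype=object)
    g1 = (dapi >= gates.dapi_g1_window[0]) & (dapi <= gates.dapi_g1_window[1])
    g2 = (dapi >= gates.dapi_g2_window[0]) & (dapi <= gates.dapi_g2_window[1])
    phase[g1] = "G1"
    phase[g2] = "G2M"
    phase[edu > gates.edu_cutoff] = "S"
    return pd.Series(phase, name="phase")


def phase_summary(df: pd.DataFrame,
                  fraction_col: str = "ha_nuclear_fraction",
                  phase_col: str = "phase") -> pd.DataFrame:
    """Counts and mean ± sd of the nuclear fraction per phase."""
    if df.empty:
        raise ValueError("no cells to summarize")
    g = df.groupby(phase_col, sort=True)[fraction_col]
    out = pd.DataFrame({
        "n": g.size(),
        "mean_nuclear_fraction": g.mean(),
        "sd_nuclear_fraction": g.std(ddof=1),
    }).reset_index()
    return out


def dapi_correlation(nuclear_fractions, dapi_integrated) -> float:
    """Coefficient of determination R² of nuclear fraction vs DNA content.

    Squared Pearson correlation; missing (NaN) for constant input or fewer
    than 3 cells.
    """
    x = np.asarray(nuclear_fractions, dtype=np.float64)
    y = np.asarray(dapi_integrated, dtype=np.float64)
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size < 3 or x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1] ** 2)
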