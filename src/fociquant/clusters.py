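"""RNA Pol II cluster detection and per-nucleus cluster metrics.

Clusters (puncta) are detected with the same outlier-above-nuclear-
background rule as nodules, with defaults suited to small puncta
(``k = 3``, ``min_area = 5``). Four metrics are reported per nucleus —
number, mean size (px), integrated intensity over the union of cluster
pixels and mean intensity over that union — each divided by the
untransfected-cell population mean of the same metric (per image) to give
the normalized variants.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .nodules import detect_blobs

METRICS = ("n_clusters", "mean_size", "integrated_intensity", "mean_intensity")


def detect_clusters(polii_image: np.ndarray, nucleus_pixels: np.ndarray,
                    k: float = 3.0, min_area: int = 5) -> list[np.ndarray]:
    """Cluster pixel sets within one nucleus (possibly empty)."""
    return detect_blobs(polii_image, nucleus_pixels, k=k, min_area=min_area)


@dataclass
class ClusterMetrics:
    """Per-nucleus cluster summary. Size and mean intensity are missing
    (NaN), not 0, when the nucleus has no cluster."""
    n_clusters: int
    mean_size: float
    integrated_intensity: float
    mean_intensity: float


def cluster_metrics(clusters: list[np.ndarray],
                    polii_image: np.ndarray) -> ClusterMetrics:
    """Count, mean component area, and union integrated/mean intensity."""
    if not clusters:
        return ClusterMetrics(0, float("nan"), 0.0, float("nan"))
    image = np.asarray(polii_image, dtype=np.float64)
    areas = np.array([int(m.sum()) for m in clusters])
    union = np.zeros(clusters[0].shape, dtype=bool)
    for m in clusters:
        union |= m
    integrated = float(image[union].sum())
    union_area = int(union.sum())
    return ClusterMetrics(
        n_clusters=len(clusters),
        mean_size=float(areas.mean()),
        integrated_intensity=integrated,
        mean_intensity=integrated / union_area,
    )


def cluster_table(polii_image: np.ndarray, nuclei: np.ndarray,
                  k: float = 3.0, min_area: int = 5) -> pd.DataFrame:
    """One row of cluster metrics per nucleus label."""
    nuclei = np.asarray(nuclei)
    labels = np.unique(nuclei)
    labels = labels[labels > 0]
    rows = []
    for lab in labels:
        m = cluster_metrics(detect_clusters(polii_image, nuclei == lab,
                                            k=k, min_area=min_area),
                            polii_image)
        rows.append({"cell_id": int(lab), "n_clusters": m.n_clusters,
                     "mean_size": m.mean_size,
                     "integrated_intensity": m.integrated_intensity,
                     "mean_intensity": m.mean_intensity})
    return pd.DataFrame(rows, columns=["cell_id", *METRICS])


def normalize_tf_utf(table: pd.DataFrame,
                     transfected: pd.Series | np.ndarray) -> pd.DataFrame:
    """Divide each metric by its untransfected-population mean (per image).

    ``transfected`` aligns with ``table`` rows. Metrics whose UTF mean is 0
    or undefined get missing normalized values.
    """
    transfected = np.asarray(transfected, dtype=bool)
    out = table.copy()
    out["transfected"] = transfected
    utf = table.loc[~transfected]
    for metric in METRICS:
        baseline = float(utf[metric].mean()) if not utf.empty else float("nan")
        if not np.isfinite(baseline) or baseline == 0:
            out[f"{metric}_norm"] = np.nan
        else:
            out[f"{metric}_norm"] = table[metric] / baseline
    return out
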