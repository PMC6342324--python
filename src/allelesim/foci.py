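"""Detection and allelic classification of bright RNA foci.

Xist RNA accumulates on the inactive X chromosome as a single bright
nuclear focus, so allelic identity is decided per focus rather than per
molecule.  Detection runs on the guide channel: background subtraction
(large-sigma Gaussian estimate), grayscale morphological opening, a
Laplacian-of-Gaussian filter to sharpen blobs, thresholding in robust
noise-SD units, connected components, then area / solidity / intensity
filters.  Each surviving focus is parametrized by the angle
``theta = atan2(I_jf1, I_bl6)`` of its background-subtracted,
scan-mean-normalized SNV-channel intensities; two-cluster k-means on theta
yields a critical angle separating BL6 (below) from JF1 (above).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure, morphology, segmentation
from sklearn.cluster import KMeans

__all__ = [
    "DetectionParams",
    "FociDetection",
    "detect_foci",
    "measure_snv_intensities",
    "classify_by_kmeans",
]


@dataclass(frozen=True)
class DetectionParams:
    """Tunable parameters of the focus-detection pipeline.

    ``background_sigma`` is the Gaussian scale (px) of the background
    estimate (default 10x the LoG scale); ``log_sigma`` the LoG blob scale;
    ``threshold_nsd`` the binarization threshold in robust noise-SD (MAD)
    units of the LoG response; the remaining fields are the component
    filters.  Intensity filters are expressed on the background-subtracted
    guide image.
    """

    log_sigma: float = 2.0
    background_sigma: float | None = None  # default: 10 * log_sigma
    threshold_nsd: float = 5.0
    min_intensity: float = 0.0
    min_solidity: float = 0.8
    min_area: float = 4.0
    max_area: float = 400.0
    opening_radius: int = 1
    clear_border: bool = True

    def __post_init__(self):
        if self.log_sigma <= 0:
            raise ValueError("log_sigma must be > 0")
        if self.background_sigma is not None and self.background_sigma <= 0:
            raise ValueError("background_sigma must be > 0")
        if self.min_area >= self.max_area:
            raise ValueError("min_area must be < max_area")

    @property
    def bg_sigma(self) -> float:
        return self.background_sigma if self.background_sigma else 10.0 * self.log_sigma


@dataclass
class FociDetection:
    """Detected foci plus the label image needed for intensity measurement."""

    table: pd.DataFrame
    labels: np.ndarray

    def __len__(self) -> int:
        return len(self.table)


def _mad_sd(x: np.ndarray) -> float:
    """Robust SD via the median absolute deviation (normal-consistent)."""
    med = np.median(x)
    return 1.4826 * float(np.median(np.abs(x - med)))


def detect_foci(image: np.ndarray, params: DetectionParams | None = None) -> FociDetection:
    """Detect bright foci in a single 2D guide-channel image.

    Returns a :class:`FociDetection` whose table has one row per surviving
    connected component with intensity-weighted centroid (x, y), area,
    solidity and mean guide intensity (background-subtracted).
    """
    if params is None:
        params = DetectionParams()
    image = np.asarray(image, dtype=float)
    if image.ndim != 2:
        raise ValueError("expected a single-plane 2D image")
    if image.size == 0:
        return FociDetection(_empty_table(), np.zeros_like(image, dtype=np.int32))

    background = ndimage.gaussian_filter(image, params.bg_sigma)
    sub = image - background
    if params.opening_radius > 0:
        sub = morphology.opening(sub, morphology.disk(params.opening_radius))
    # negated LoG: blobs brighter than their surround give positive response
    log = -ndimage.gaussian_laplace(sub, params.log_sigma) * params.log_sigma**2
    noise = _mad_sd(log)
    binary = log > params.threshold_nsd * max(noise, 1e-12)
    if params.clear_border:
        binary = segmentation.clear_border(binary)
    binary = morphology.remove_small_objects(binary, max_size=int(params.min_area) - 1)
    labels = measure.label(binary)

    rows = []
    keep_label = np.zeros(labels.max() + 1, dtype=bool)
    # clip for the weighted centroid: negative residuals would distort it
    for region in measure.regionprops(labels, intensity_image=np.clip(sub, 0, None)):
        if not (params.min_area <= region.area <= params.max_area):
            continue
        if region.solidity < params.min_solidity:
            continue
        if region.intensity_mean < params.min_intensity:
            continue
        cy, cx = region.centroid_weighted
        keep_label[region.label] = True
        rows.append(
            {
                "label": region.label,
                "x": cx,
                "y": cy,
                "area": float(region.area),
                "solidity": float(region.solidity),
                "guide_intensity": float(region.intensity_mean),
            }
        )
    labels[~keep_label[labels]] = 0
    table = pd.DataFrame(rows) if rows else _empty_table()
    return FociDetection(table=table, labels=labels)


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(
        columns=["label", "x", "y", "area", "solidity", "guide_intensity"]
    )


def measure_snv_intensities(
    detection: FociDetection,
    bl6_image: np.ndarray,
    jf1_image: np.ndarray,
    background_sigma: float = 20.0,
) -> pd.DataFrame:
    """Measure normalized SNV-channel intensities and the ratio angle theta.

    Per focus and channel: mean pixel intensity over the component mask,
    minus a local background estimate (large-sigma Gaussian blur of the
    channel sampled under the same mask), divided by the whole-image mean
    of that channel.  Negative net intensities are clipped to zero and
    ``theta = atan2(jf1, bl6)`` in [0, pi/2].
    """
    table = detection.table.copy()
    if len(table) == 0:
        for col in ("bl6_intensity", "jf1_intensity", "theta"):
            table[col] = pd.Series(dtype=float)
        return table
    labels = detection.labels
    idx = table["label"].to_numpy()
    for name, img in (("bl6", bl6_image), ("jf1", jf1_image)):
        img = np.asarray(img, dtype=float)
        bg = ndimage.gaussian_filter(img, background_sigma)
        mean_in = ndimage.mean(img, labels=labels, index=idx)
        mean_bg = ndimage.mean(bg, labels=labels, index=idx)
        net = np.clip(mean_in - mean_bg, 0.0, None)
        table[f"{name}_intensity"] = net / max(float(img.mean()), 1e-12)
    table["theta"] = np.arctan2(
        table["jf1_intensity"].to_numpy(), table["bl6_intensity"].to_numpy()
    )
    return table


def classify_by_kmeans(
    foci: pd.DataFrame, random_state: int = 0, n_init: int = 10
) -> tuple[pd.DataFrame, float]:
    """Two-cluster k-means on theta; returns labeled table + critical angle.

    The critical angle is the midpoint of the two cluster centers; foci
    with ``theta`` above it are called JF1 (the JF1 channel dominates),
    those at or below it BL6.  Deterministic under the fixed
    ``random_state`` with ``n_init`` restarts.
    """
    if "theta" not in foci.columns:
        raise ValueError("foci table lacks a 'theta' column; run "
                         "measure_snv_intensities first")
    theta = foci["theta"].to_numpy(dtype=float)
    if len(theta) < 2:
        raise ValueError("need at least 2 foci to classify")
    if np.ptp(theta) == 0:
        raise ValueError("all theta identical: single cluster; cannot classify")
    km = KMeans(n_clusters=2, n_init=n_init, random_state=random_state)
    km.fit(theta.reshape(-1, 1))
    centers = np.sort(km.cluster_centers_.ravel())
    critical = float(centers.mean())
    out = foci.copy()
    out["assignment"] = np.where(theta > critical, "JF1", "BL6")
    return out, critical
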