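"""Marker-positive vs negative cell classification from channel intensities.

In two-marker immunofluorescence exports the marker channel (green for an
epithelial/tumor marker) is typically bimodal across cells: a dim
marker-negative population and a bright marker-positive one.  Three
classifiers are provided over the per-cell mean intensities:

* ``cutoff`` — a fixed intensity threshold (strict ``>``; ties are negative);
* ``gmm`` — a seeded Gaussian mixture, positive = component with the higher
  mean on the marker channel;
* ``kmeans`` — seeded K-means with the same component-to-class mapping.

The GMM falls back to a midpoint cutoff (with a warning) when the fit is
degenerate: the data do not support the requested number of components
(a single-component fit scores an equal-or-better BIC) or a component
variance collapses to the regularization floor.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal, stats
from scipy.optimize import brentq
from sklearn.cluster import KMeans
from sklearn.mixture import GaussianMixture

from .errors import EmptyInputError, FitError
from .roi import RoiImage
from .segmentation import LabelMask

__all__ = [
    "TypingResult",
    "classify_cutoff",
    "classify_gmm",
    "classify_kmeans",
    "intensity_density_report",
    "annotate_snapshot",
]

_CHANNEL_COL = {"R": "mean_r", "G": "mean_g", "B": "mean_b"}


@dataclass
class TypingResult:
    """Outcome of a positive/negative cell classification."""

    method: str
    positive_channel: str
    threshold_used: float
    labels: np.ndarray  # per-cell, "positive" | "negative", cell-table order

    @property
    def n_total(self) -> int:
        return int(self.labels.size)

    @property
    def n_positive(self) -> int:
        return int(np.sum(self.labels == "positive"))

    @property
    def positive_fraction(self) -> float:
        return self.n_positive / self.n_total if self.n_total else float("nan")

    @property
    def positive_percent(self) -> str:
        """Positive fraction formatted as a percentage with two decimals."""
        return f"{self.positive_fraction * 100:.2f}%"

    def summary_text(self) -> str:
        """Annotation line: total cells, positive count, percentage."""
        return (
            f"Total cells: {self.n_total} | "
            f"Positive cells: {self.n_positive} ({self.positive_percent})"
        )


def _intensities(cells: pd.DataFrame, channel: str) -> np.ndarray:
    if len(cells) == 0:
        raise EmptyInputError("cell table is empty")
    return cells[_CHANNEL_COL[channel]].to_numpy(dtype=float)


def classify_cutoff(
    cells: pd.DataFrame, channel: str = "G", cutoff: float = 20.0
) -> TypingResult:
    """Label cells positive when mean intensity on ``channel`` exceeds ``cutoff``.

    Strict inequality: a cell sitting exactly at the cutoff is negative.
    """
    vals = _intensities(cells, channel)
    labels = np.where(vals > cutoff, "positive", "negative")
    return TypingResult(
        method="cutoff",
        positive_channel=channel,
        threshold_used=float(cutoff),
        labels=labels,
    )


def _gmm_is_degenerate(gm: GaussianMixture, X: np.ndarray) -> bool:
    var_floor = 10.0 * gm.reg_covar
    variances = np.array(
        [np.diag(np.atleast_2d(c)).min() for c in gm.covariances_]
    )
    if (variances <= var_floor).any():
        return True
    if gm.n_components >= 2:
        single = GaussianMixture(
            n_components=1, random_state=0, covariance_type=gm.covariance_type
        ).fit(X)
        if single.bic(X) <= gm.bic(X):
            return True
    return False


def classify_gmm(
    cells: pd.DataFrame,
    channels: tuple[str, ...] = ("G",),
    k: int = 2,
    seed: int = 0,
    positive_channel: str | None = None,
) -> TypingResult:
    """Gaussian-mixture classification on the selected intensity channels.

    The mixture is fitted on the columns named in ``channels`` (1-D on the
    marker channel by default, or e.g. ``("R", "G")``).  The component with
    the highest mean on ``positive_channel`` is the positive class.  For the
    1-D two-component case ``threshold_used`` is the intensity where the
    posterior responsibility crosses 0.5; otherwise it is NaN.
    """
    positive_channel = positive_channel or channels[0]
    X = np.column_stack([_intensities(cells, ch) for ch in channels])
    if len(X) < 2 * k:
        raise FitError(f"need at least {2 * k} cells to fit {k} components")
    gm = GaussianMixture(n_components=k, random_state=seed, n_init=3).fit(X)
    dim = channels.index(positive_channel)
    comp_means = gm.means_[:, dim]

    if _gmm_is_degenerate(gm, X):
        warnings.warn(
            "degenerate mixture fit; falling back to a cutoff at the midpoint "
            "of component means",
            stacklevel=2,
        )
        thr = float((comp_means.max() + comp_means.min()) / 2.0)
        labels = np.where(X[:, dim] > thr, "positive", "negative")
        return TypingResult("gmm", positive_channel, thr, labels)

    pos_comp = int(np.argmax(comp_means))
    assign = gm.predict(X)
    labels = np.where(assign == pos_comp, "positive", "negative")

    threshold = float("nan")
    if X.shape[1] == 1 and k == 2:
        lo, hi = float(comp_means.min()), float(comp_means.max())

        def margin(x: float) -> float:
            return gm.predict_proba(np.array([[x]]))[0, pos_comp] - 0.5

        try:
            threshold = float(brentq(margin, lo, hi))
        except ValueError:
            threshold = (lo + hi) / 2.0
    return TypingResult("gmm", positive_channel, threshold, labels)


def classify_kmeans(
    cells: pd.DataFrame,
    channels: tuple[str, ...] = ("G",),
    k: int = 2,
    seed: int = 0,
    positive_channel: str | None = None,
) -> TypingResult:
    """K-means classification; positive = cluster with the higher marker mean."""
    positive_channel = positive_channel or channels[0]
    X = np.column_stack([_intensities(cells, ch) for ch in channels])
    if k == 1:
        warnings.warn("k=1: all cells assigned to one (positive) class", stacklevel=2)
        return TypingResult(
            "kmeans",
            positive_channel,
            float("nan"),
            np.full(len(X), "positive", dtype=object),
        )
    if len(X) < 2 * k:
        raise FitError(f"need at least {2 * k} cells for {k} clusters")
    km = KMeans(n_clusters=k, random_state=seed, n_init=10).fit(X)
    dim = channels.index(positive_channel)
    centers = km.cluster_centers_[:, dim]
    pos_comp = int(np.argmax(centers))
    labels = np.where(km.labels_ == pos_comp, "positive", "negative")
    threshold = float("nan")
    if X.shape[1] == 1 and k == 2:
        threshold = float(centers.sum() / 2.0)  # 1-D decision boundary
    return TypingResult("kmeans", positive_channel, threshold, labels)


def _count_density_modes(vals: np.ndarray) -> int:
    """Number of modes of a Gaussian-KDE of ``vals`` (5% prominence)."""
    if np.ptp(vals) == 0 or len(vals) < 3:
        return 1
    kde = stats.gaussian_kde(vals)
    pad = 0.1 * np.ptp(vals)
    grid = np.linspace(vals.min() - pad, vals.max() + pad, 512)
    dens = kde(grid)
    peaks, _ = signal.find_peaks(dens, prominence=0.05 * dens.max())
    return max(1, len(peaks))


def intensity_density_report(
    cells: pd.DataFrame, out_dir: str | Path
) -> dict:
    """Write per-channel intensity density plots and a red-vs-green scatter.

    Returns a dict with the written file paths and a modality diagnostic:
    the number of kernel-density modes per channel (bimodality of the marker
    channel is what justifies a simple cutoff).
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if len(cells) == 0:
        warnings.warn("empty cell table: writing no density report", stacklevel=2)
        return {"files": [], "modes": {}}

    files: list[str] = []
    modes: dict[str, int] = {}
    colors = {"R": "tab:red", "G": "tab:green", "B": "tab:blue"}
    for ch, col in _CHANNEL_COL.items():
        vals = cells[col].to_numpy(dtype=float)
        modes[ch] = _count_density_modes(vals)
        fig, ax = plt.subplots(figsize=(4, 3))
        if np.ptp(vals) > 0:
            kde = stats.gaussian_kde(vals)
            grid = np.linspace(vals.min(), vals.max(), 256)
            ax.fill_between(grid, kde(grid), color=colors[ch], alpha=0.5)
        ax.hist(vals, bins=30, density=True, color=colors[ch], alpha=0.3)
        ax.set_xlabel(f"mean {ch} intensity")
        ax.set_ylabel("density")
        path = out_dir / f"density_{ch}.png"
        fig.savefig(path, dpi=100)
        plt.close(fig)
        files.append(str(path))

    fig, ax = plt.subplots(figsize=(4, 4))
    color = None
    if "class_label" in cells.columns:
        color = np.where(cells["class_label"] == "positive", "tab:green", "tab:gray")
    ax.scatter(cells["mean_r"], cells["mean_g"], s=8, c=color)
    ax.set_xlabel("mean R intensity")
    ax.set_ylabel("mean G intensity")
    path = out_dir / "scatter_red_green.png"
    fig.savefig(path, dpi=100)
    plt.close(fig)
    files.append(str(path))
    return {"files": files, "modes": modes}


def annotate_snapshot(
    img: RoiImage,
    mask: LabelMask,
    typing: TypingResult,
    out_path: str | Path,
) -> Path:
    """Write a side-by-side snapshot: original image and classified overlay.

    The overlay outlines positive cells in green and negative cells in gray
    and is titled with the total cell count, positive count and percentage
    (two decimals).  ``typing.labels[i]`` must correspond to mask label
    ``i + 1`` (the cell-table row order produced by feature extraction).
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from skimage.segmentation import find_boundaries

    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)

    overlay = img.pixels.copy()
    if mask.n_cells:
        pos_labels = np.flatnonzero(typing.labels == "positive") + 1
        is_pos = np.isin(mask.labels, pos_labels) & (mask.labels > 0)
        bounds = find_boundaries(mask.labels, mode="inner")
        overlay[bounds & is_pos] = (0, 255, 0)
        overlay[bounds & ~is_pos] = (160, 160, 160)

    fig, axes = plt.subplots(1, 2, figsize=(8, 4.4))
    axes[0].imshow(img.pixels)
    axes[0].set_title("original")
    axes[1].imshow(overlay)
    axes[1].set_title("classified cells")
    for ax in axes:
        ax.set_axis_off()
    fig.suptitle(typing.summary_text())
    fig.savefig(out_path, dpi=100)
    plt.close(fig)
    return out_path
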