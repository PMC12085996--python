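"""Synthetic fixture generators with machine-readable ground truth.

Three generators emulate the three input kinds of the pipeline:

* :func:`make_roi_image` — a rendered circular ROI on a white margin with
  two cell populations: blue (DNA-dye) nuclei in every cell and a green
  marker stain whose per-cell intensity is drawn from a class-specific
  normal distribution (bright marker-positive vs dim marker-negative).
  Channel intensities are additive, clipped at 255, and blurred with a 1 px
  Gaussian to emulate optical blur; the default geometry mirrors a ~1 µm/px
  export: 600x600 px image, 150 px ROI radius, 535 cells.
* :func:`make_pattern` — marked point patterns in a disc under three
  regimes: complete spatial randomness, attraction (negatives placed near
  random positives) and segregation (marks confined to opposite half-discs).
* :func:`make_expression` — probe-level count matrices with planted
  per-segment scale factors, planted gene-pair correlations (via shared
  latent factors on the log scale), low-detection segments and rarely
  detected genes, plus a matching ligand–target table.

Every generator is deterministic for a fixed seed and returns ground truth
alongside the data.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import NamedTuple

import numpy as np
import pandas as pd
from scipy import ndimage as ndi

from .spatial import MarkedPointPattern

__all__ = [
    "ImageFixtureSpec",
    "PatternFixtureSpec",
    "ImageFixture",
    "ExpressionFixture",
    "make_roi_image",
    "make_pattern",
    "make_expression",
]


# ---------------------------------------------------------------------------
# rendered ROI images
# ---------------------------------------------------------------------------


@dataclass
class ImageFixtureSpec:
    """Parameters of a rendered two-population ROI image.

    Defaults mirror a typical export: 600x600 px, ROI radius 150 px, 535
    cells of which 258 are marker-positive, green means 60 (positive) vs 8
    (negative).  ``overlap_allowed=False`` places cells on a jittered grid
    with a guaranteed gap (needed for segmentation-count ground truth) and
    supports fewer cells per unit area.
    """

    image_size_px: int = 600
    roi_radius_px: float = 150.0
    n_positive: int = 258
    n_negative: int = 277
    cell_radius_px: float = 4.0
    cell_radius_sd: float = 0.6
    green_positive: tuple[float, float] = (60.0, 8.0)
    green_negative: tuple[float, float] = (8.0, 2.0)
    red_positive: tuple[float, float] = (15.0, 5.0)
    red_negative: tuple[float, float] = (30.0, 8.0)
    blue: tuple[float, float] = (180.0, 20.0)
    nucleus_frac: float = 0.7
    overlap_allowed: bool = True
    min_gap_px: float = 4.0
    seed: int = 0


class ImageFixture(NamedTuple):
    image: np.ndarray  # (H, W, 3) uint8, ROI on white margin
    truth: pd.DataFrame  # one row per rendered cell


def _nonoverlap_centers(
    rng: np.random.Generator, spec: ImageFixtureSpec, n: int, r_cell_max: float
) -> np.ndarray:
    """Jittered-grid placement guaranteeing pairwise gaps >= min_gap_px / 2."""
    spacing = 2.0 * r_cell_max + spec.min_gap_px
    half = spec.image_size_px / 2.0
    margin = r_cell_max + 2.0
    coords = np.arange(-half + spacing, half - spacing, spacing)
    gx, gy = np.meshgrid(coords, coords)
    centers = np.column_stack([gx.ravel(), gy.ravel()])
    inside = np.hypot(centers[:, 0], centers[:, 1]) <= spec.roi_radius_px - margin
    centers = centers[inside]
    if len(centers) < n:
        raise ValueError(
            f"cannot place {n} non-overlapping cells of radius {r_cell_max:.1f} "
            f"in a radius-{spec.roi_radius_px:.0f} ROI; enlarge the ROI or "
            "shrink the cells"
        )
    rng.shuffle(centers)
    jitter = rng.uniform(-spec.min_gap_px / 4, spec.min_gap_px / 4, size=(n, 2))
    return centers[:n] + jitter


def _uniform_disc(rng: np.random.Generator, n: int, radius: float) -> np.ndarray:
    r = radius * np.sqrt(rng.uniform(size=n))
    theta = rng.uniform(0, 2 * np.pi, size=n)
    return np.column_stack([r * np.cos(theta), r * np.sin(theta)])


def make_roi_image(spec: ImageFixtureSpec | None = None) -> ImageFixture:
    """Render a synthetic ROI image and its ground-truth cell table.

    The truth table has one row per cell: ``label, x, y, radius, class,
    green, red, blue`` (x/y in image pixel coordinates, class in
    {"positive", "negative"}).
    """
    spec = spec or ImageFixtureSpec()
    rng = np.random.default_rng(spec.seed)
    size = spec.image_size_px
    n_total = spec.n_positive + spec.n_negative
    cx = cy = float(size // 2)

    r_cell_max = spec.cell_radius_px + 2.0 * spec.cell_radius_sd
    if spec.overlap_allowed:
        centers = _uniform_disc(
            rng, n_total, spec.roi_radius_px - (r_cell_max + 2.0)
        )
    else:
        centers = _nonoverlap_centers(rng, spec, n_total, r_cell_max)
    classes = np.array(
        ["positive"] * spec.n_positive + ["negative"] * spec.n_negative
    )
    rng.shuffle(classes)

    radii = np.clip(
        rng.normal(spec.cell_radius_px, spec.cell_radius_sd, size=n_total),
        1.5,
        r_cell_max,
    )
    ecc = rng.uniform(0.0, 0.25, size=n_total)
    theta = rng.uniform(0.0, np.pi, size=n_total)
    greens = np.where(
        classes == "positive",
        rng.normal(*spec.green_positive, size=n_total),
        rng.normal(*spec.green_negative, size=n_total),
    ).clip(0, 255)
    reds = np.where(
        classes == "positive",
        rng.normal(*spec.red_positive, size=n_total),
        rng.normal(*spec.red_negative, size=n_total),
    ).clip(0, 255)
    blues = rng.normal(*spec.blue, size=n_total).clip(0, 255)

    canvas = np.zeros((size, size, 3), dtype=np.float64)
    for i in range(n_total):
        x0, y0 = centers[i, 0] + cx, centers[i, 1] + cy
        a = radii[i] * (1 + ecc[i])
        b = radii[i] / (1 + ecc[i])
        _paint_ellipse(canvas, x0, y0, a, b, theta[i], reds[i], 0)
        _paint_ellipse(canvas, x0, y0, a, b, theta[i], greens[i], 1)
        _paint_ellipse(
            canvas,
            x0,
            y0,
            a * spec.nucleus_frac,
            b * spec.nucleus_frac,
            theta[i],
            blues[i],
            2,
        )

    for ch in range(3):
        canvas[..., ch] = ndi.gaussian_filter(canvas[..., ch], sigma=1.0)
    canvas = np.clip(canvas, 0, 255)

    yy, xx = np.ogrid[:size, :size]
    outside = (xx - cx) ** 2 + (yy - cy) ** 2 > spec.roi_radius_px**2
    canvas[outside] = 255.0
    image = np.round(canvas).astype(np.uint8)

    truth = pd.DataFrame(
        {
            "label": np.arange(1, n_total + 1),
            "x": centers[:, 0] + cx,
            "y": centers[:, 1] + cy,
            "radius": radii,
            "class": classes,
            "green": greens,
            "red": reds,
            "blue": blues,
        }
    )
    return ImageFixture(image=image, truth=truth)


def _paint_ellipse(
    canvas: np.ndarray,
    x0: float,
    y0: float,
    a: float,
    b: float,
    theta: float,
    value: float,
    channel: int,
) -> None:
    """Add ``value`` to ``channel`` over an ellipse (additive rendering)."""
    size = canvas.shape[0]
    rmax = max(a, b)
    xlo, xhi = int(max(0, x0 - rmax - 1)), int(min(size, x0 + rmax + 2))
    ylo, yhi = int(max(0, y0 - rmax - 1)), int(min(size, y0 + rmax + 2))
    if xhi <= xlo or yhi <= ylo:
        return
    yy, xx = np.mgrid[ylo:yhi, xlo:xhi]
    dx, dy = xx - x0, yy - y0
    ct, st = np.cos(theta), np.sin(theta)
    u = (dx * ct + dy * st) / a
    v = (-dx * st + dy * ct) / b
    member = u**2 + v**2 <= 1.0
    canvas[ylo:yhi, xlo:xhi, channel][member] += value


# ---------------------------------------------------------------------------
# marked point patterns
# ---------------------------------------------------------------------------


@dataclass
class PatternFixtureSpec:
    """Parameters of a simulated marked point pattern in a disc window.

    ``regime`` controls the dependence between the two marks: ``"csr"`` for
    two independent uniform populations, ``"attraction"`` (each negative
    within ``attraction_distance`` of a random positive) and
    ``"segregation"`` (marks folded onto opposite half-discs).
    """

    window_radius: float = 150.0
    n_positive: int = 200
    n_negative: int = 200
    regime: str = "csr"
    attraction_distance: float = 5.0
    seed: int = 0


def make_pattern(spec: PatternFixtureSpec | None = None) -> MarkedPointPattern:
    """Simulate a marked point pattern under the requested mixing regime."""
    spec = spec or PatternFixtureSpec()
    if spec.regime not in ("csr", "attraction", "segregation"):
        raise ValueError(f"unknown regime {spec.regime!r}")
    if spec.regime == "attraction" and not (
        0 < spec.attraction_distance < spec.window_radius
    ):
        raise ValueError("attraction_distance must be positive and within the window")
    rng = np.random.default_rng(spec.seed)
    R = spec.window_radius

    pos = _uniform_disc(rng, spec.n_positive, R)
    if spec.regime == "csr":
        neg = _uniform_disc(rng, spec.n_negative, R)
    elif spec.regime == "attraction":
        neg = np.empty((spec.n_negative, 2))
        filled = 0
        while filled < spec.n_negative:
            parents = pos[rng.integers(0, len(pos), size=spec.n_negative - filled)]
            offsets = _uniform_disc(
                rng, spec.n_negative - filled, spec.attraction_distance
            )
            cand = parents + offsets
            ok = np.hypot(cand[:, 0], cand[:, 1]) <= R
            nk = int(ok.sum())
            neg[filled : filled + nk] = cand[ok]
            filled += nk
    else:  # segregation: fold marks onto opposite half-discs
        pos[:, 0] = -np.abs(pos[:, 0])
        neg = _uniform_disc(rng, spec.n_negative, R)
        neg[:, 0] = np.abs(neg[:, 0])

    points = np.vstack([pos, neg])
    marks = np.array(["positive"] * spec.n_positive + ["negative"] * spec.n_negative)
    return MarkedPointPattern(
        points=points, marks=marks, window_center=(0.0, 0.0), window_radius=R
    )


# ---------------------------------------------------------------------------
# expression matrices
# ---------------------------------------------------------------------------


@dataclass
class ExpressionFixture:
    probe_matrix: pd.DataFrame  # probes x segments
    probe_to_gene: pd.Series  # probe id -> gene id
    table: pd.DataFrame  # ligand, target, source_kind
    truth: dict = field(default_factory=dict)


def make_expression(
    n_genes: int = 100,
    n_segments: int = 20,
    planted_scales: np.ndarray | None = None,
    planted_pairs: tuple[tuple[str, str, float], ...] = (),
    n_decoy_pairs: int = 5,
    n_ppi_pairs: int = 3,
    low_detection_segments: int = 0,
    rare_genes: int = 0,
    biological_sd: float = 0.5,
    probe_sd: float = 0.05,
    seed: int = 0,
) -> ExpressionFixture:
    """Generate a probe-level count fixture with planted structure.

    Baseline counts are log-normal (per-gene log2 mean uniform in [3, 9],
    biological log2 SD ``biological_sd``).  Planted ligand–target pairs get
    dedicated genes whose log2 values share a latent factor so their log-
    scale correlation equals the requested ``true_r``.  Each segment is
    multiplied by a scale factor (``planted_scales``, default log-normal with
    log2 SD 0.4); each gene is measured by 2–4 probes with log-normal
    efficiencies.  The last ``low_detection_segments`` segments keep only 2%
    of genes nonzero (below the 5% segment filter) and the last
    ``rare_genes`` regular genes are nonzero in a single segment (below the
    10% gene filter).

    Ground truth (``truth`` dict): ``scales`` (pd.Series per segment),
    ``pairs`` (list of (ligand, target, true_r)), ``dropped_segments``,
    ``dropped_genes``, ``surviving_genes``.
    """
    rng = np.random.default_rng(seed)
    pair_genes: list[str] = []
    for ligand, target, _ in planted_pairs:
        for g in (ligand, target):
            if g not in pair_genes:
                pair_genes.append(g)
    base_genes = [f"G{i:04d}" for i in range(n_genes)]
    genes = base_genes + pair_genes
    segments = [f"S{j:02d}" for j in range(n_segments)]

    mu = rng.uniform(3.0, 9.0, size=len(genes))
    log2 = mu[:, None] + rng.normal(0.0, biological_sd, size=(len(genes), n_segments))

    for ligand, target, true_r in planted_pairs:
        li, ti = genes.index(ligand), genes.index(target)
        z = rng.normal(size=n_segments)
        e2 = rng.normal(size=n_segments)
        log2[li] = mu[li] + biological_sd * z
        log2[ti] = mu[ti] + biological_sd * (
            true_r * z + np.sqrt(1 - true_r**2) * e2
        )

    values = np.power(2.0, log2)

    if planted_scales is None:
        planted_scales = np.power(2.0, rng.normal(0.0, 0.4, size=n_segments))
    planted_scales = np.asarray(planted_scales, dtype=float)
    values = values * planted_scales[None, :]

    # rarely detected genes: nonzero in exactly one segment
    dropped_genes: list[str] = []
    for gi in range(n_genes - rare_genes, n_genes):
        keep_seg = int(rng.integers(0, max(1, n_segments - low_detection_segments)))
        mask = np.ones(n_segments, dtype=bool)
        mask[keep_seg] = False
        values[gi, mask] = 0.0
        if 1.0 / n_segments < 0.10:
            dropped_genes.append(genes[gi])

    # low-detection segments: keep only ~2% of genes nonzero
    dropped_segments: list[str] = []
    n_keep = max(1, int(round(0.02 * len(genes))))
    for sj in range(n_segments - low_detection_segments, n_segments):
        keep_idx = rng.choice(len(genes), size=n_keep, replace=False)
        mask = np.ones(len(genes), dtype=bool)
        mask[keep_idx] = False
        values[mask, sj] = 0.0
        dropped_segments.append(segments[sj])

    gene_df = pd.DataFrame(values, index=genes, columns=segments)

    # probes
    probe_rows = []
    probe_ids = []
    probe_gene = []
    for gi, g in enumerate(genes):
        for p in range(int(rng.integers(2, 5))):
            eff = np.power(2.0, rng.normal(0.0, probe_sd))
            probe_rows.append(gene_df.iloc[gi].to_numpy() * eff)
            probe_ids.append(f"{g}_p{p}")
            probe_gene.append(g)
    probe_matrix = pd.DataFrame(probe_rows, index=probe_ids, columns=segments)
    probe_to_gene = pd.Series(probe_gene, index=probe_ids, name="gene")

    # ligand–target table: planted pairs (curated) + uncorrelated decoys +
    # ppi_prediction rows (never counted by the RL filter)
    rows = [
        {"ligand": l, "target": t, "source_kind": "curated"}
        for l, t, _ in planted_pairs
    ]
    candidates = [g for g in base_genes[: n_genes - rare_genes]]
    for _ in range(n_decoy_pairs):
        l, t = rng.choice(candidates, size=2, replace=False)
        rows.append({"ligand": l, "target": t, "source_kind": "curated"})
    for _ in range(n_ppi_pairs):
        l, t = rng.choice(candidates, size=2, replace=False)
        rows.append({"ligand": l, "target": t, "source_kind": "ppi_prediction"})
    table = pd.DataFrame(rows).drop_duplicates(subset=["ligand", "target"])

    surviving = [g for g in genes if g not in dropped_genes]
    truth = {
        "scales": pd.Series(planted_scales, index=segments, name="scale"),
        "pairs": list(planted_pairs),
        "dropped_segments": dropped_segments,
        "dropped_genes": dropped_genes,
        "surviving_genes": surviving,
    }
    return ExpressionFixture(
        probe_matrix=probe_matrix,
        probe_to_gene=probe_to_gene,
        table=table,
        truth=truth,
    )
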