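"""GeoMx-style ROI expression preprocessing.

The preprocessing pipeline, in fixed order:

1. :func:`aggregate_probes` — gene-level counts as the arithmetic mean of
   each gene's probes per segment;
2. :func:`filter_segments` — drop segments detecting fewer than 5% (strict
   ``<``) of the genes detected anywhere in the dataset;
3. :func:`filter_genes` — keep genes detected in at least 10% (``>=``) of the
   remaining segments;
4. :func:`q3_normalize` — upper-quartile normalization: each segment is
   divided by ``Q3_s / geomean(Q3)``, where ``Q3_s`` is the segment's 75th
   percentile over retained genes (linear interpolation between order
   statistics).  Referencing to the geometric mean keeps the matrix on its
   original count scale.

"Detected" is taken as input — a boolean matrix or a simple limit-of-
detection threshold (default: value > 0) — rather than re-deriving vendor
negative-probe models.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .errors import MappingError, NormalizationError, ParameterError

__all__ = [
    "ExpressionMatrix",
    "aggregate_probes",
    "filter_segments",
    "filter_genes",
    "q3_normalize",
    "preprocess",
]


@dataclass
class ExpressionMatrix:
    """Genes x segments expression values with detection calls and metadata."""

    values: pd.DataFrame  # genes (rows) x segments (columns)
    detected: pd.DataFrame  # same shape, boolean
    meta: pd.DataFrame | None = None  # indexed by segment id
    norm_factors: pd.Series | None = None  # set by q3_normalize
    history: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.detected.shape != self.values.shape:
            raise ParameterError("detected must have the same shape as values")
        if (self.values.to_numpy() < 0).any():
            raise ParameterError("expression values must be non-negative")
        if self.values.index.has_duplicates or self.values.columns.has_duplicates:
            raise ParameterError("gene and segment ids must be unique")

    @classmethod
    def from_counts(
        cls,
        values: pd.DataFrame,
        lod: float | pd.DataFrame = 0.0,
        meta: pd.DataFrame | None = None,
    ) -> "ExpressionMatrix":
        """Build from a count matrix; detection = value above the LOD."""
        if isinstance(lod, pd.DataFrame):
            detected = values > lod
        else:
            detected = values > float(lod)
        return cls(values=values.copy(), detected=detected, meta=meta)

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def segment_ids(self) -> pd.Index:
        return self.values.columns

    def _subset(self, genes: pd.Index, segments: pd.Index, note: str) -> "ExpressionMatrix":
        meta = None
        if self.meta is not None:
            meta = self.meta.loc[self.meta.index.intersection(segments)]
        return ExpressionMatrix(
            values=self.values.loc[genes, segments].copy(),
            detected=self.detected.loc[genes, segments].copy(),
            meta=meta,
            norm_factors=self.norm_factors,
            history=[*self.history, note],
        )


def aggregate_probes(
    probe_matrix: pd.DataFrame,
    probe_to_gene: "pd.Series | dict[str, str]",
    lod: float = 0.0,
    meta: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """Average each gene's probes per segment into a gene-level matrix.

    Every probe (row of ``probe_matrix``) must map to exactly one gene;
    unmapped probes raise :class:`MappingError` listing the offenders.
    """
    mapping = pd.Series(probe_to_gene)
    missing = probe_matrix.index.difference(mapping.index)
    if len(missing):
        raise MappingError(f"unmapped probes: {sorted(missing)}")
    genes = mapping.loc[probe_matrix.index]
    values = probe_matrix.groupby(genes.to_numpy()).mean()
    values.index.name = "gene"
    em = ExpressionMatrix.from_counts(values, lod=lod, meta=meta)
    em.history.append(
        f"aggregate_probes: {len(probe_matrix)} probes -> {len(values)} genes"
    )
    return em


def filter_segments(m: ExpressionMatrix, min_gene_frac: float = 0.05) -> ExpressionMatrix:
    """Drop segments detecting < ``min_gene_frac`` of genes detected anywhere.

    The denominator is the number of genes detected in at least one segment
    of the current matrix (not the panel size).  The comparison is strictly
    less-than, so a segment exactly at the threshold is kept.
    """
    total_detected = int(m.detected.any(axis=1).sum())
    if total_detected == 0:
        raise ParameterError("no gene is detected in any segment")
    frac = m.detected.sum(axis=0) / total_detected
    keep = frac[frac >= min_gene_frac].index
    dropped = sorted(m.segment_ids.difference(keep))
    return m._subset(
        m.gene_ids, keep, f"filter_segments(<{min_gene_frac}): dropped {dropped}"
    )


def filter_genes(m: ExpressionMatrix, min_roi_frac: float = 0.10) -> ExpressionMatrix:
    """Keep genes detected in >= ``min_roi_frac`` of the current segments."""
    frac = m.detected.sum(axis=1) / m.detected.shape[1]
    keep = frac[frac >= min_roi_frac].index
    dropped = sorted(m.gene_ids.difference(keep))
    return m._subset(
        keep, m.segment_ids, f"filter_genes(>={min_roi_frac}): dropped {dropped}"
    )


def q3_normalize(m: ExpressionMatrix) -> ExpressionMatrix:
    """Upper-quartile normalization referenced to the geometric mean of Q3s.

    Raises :class:`NormalizationError` naming any segment whose Q3 is zero
    (normalization undefined).
    """
    q3 = m.values.quantile(0.75, axis=0)  # linear interpolation
    zero = sorted(q3.index[q3 <= 0])
    if zero:
        raise NormalizationError(f"segments with zero upper quartile: {zero}")
    factors = q3 / gmean(q3.to_numpy())
    out = m._subset(m.gene_ids, m.segment_ids, "q3_normalize")
    out.values = out.values.div(factors, axis=1)
    out.norm_factors = factors
    return out


def preprocess(
    probe_matrix: pd.DataFrame,
    probe_to_gene: "pd.Series | dict[str, str]",
    min_gene_frac: float = 0.05,
    min_roi_frac: float = 0.10,
    lod: float = 0.0,
    meta: pd.DataFrame | None = None,
) -> ExpressionMatrix:
    """Full pipeline: aggregate -> filter segments -> filter genes -> Q3."""
    m = aggregate_probes(probe_matrix, probe_to_gene, lod=lod, meta=meta)
    m = filter_segments(m, min_gene_frac=min_gene_frac)
    m = filter_genes(m, min_roi_frac=min_roi_frac)
    return q3_normalize(m)
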