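"""Correlation-based ligand–target pair prediction.

Given a normalized expression matrix, a group of segments (e.g. the
``Mixture`` or ``Separative`` ROIs), and a curated ligand–target table in a
NicheNet-like schema, a pair is "predicted" in a group when the Pearson
correlation of ligand and target expression across the group's segments is
strictly greater than a threshold (default 0.75).  Table rows whose
provenance is protein–protein-interaction prediction (``ppi_prediction``)
are excluded; only curated regulatory links count.

Correlations are computed only for table-listed pairs — mathematically
identical to correlating all gene pairs and intersecting with the table
(the all-pairs route is kept as a test oracle) but tractable.  No multiple-
testing correction is applied: the procedure is a pure correlation filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import InsufficientReplicatesError, ParameterError
from .expression import ExpressionMatrix

__all__ = [
    "load_ligand_target_table",
    "predict_rl_pairs",
    "compare_groups",
    "RLPairResult",
    "ComparisonReport",
]

PAIR_COLUMNS = [
    "ligand",
    "target",
    "pearson_r",
    "n_segments",
    "mean_expr_ligand",
    "mean_expr_target",
]


@dataclass
class RLPairResult:
    """Predicted ligand–target pairs for one ROI group."""

    group: str
    pairs: pd.DataFrame  # columns PAIR_COLUMNS
    n_segments: int
    n_skipped_missing: int = 0
    n_skipped_degenerate: int = 0

    @property
    def pair_set(self) -> set[tuple[str, str]]:
        return set(zip(self.pairs["ligand"], self.pairs["target"]))


@dataclass
class ComparisonReport:
    """Pair counts and overlaps between two groups' predictions."""

    group_a: str
    group_b: str
    n_a: int
    n_b: int
    n_shared: int
    n_unique_a: int
    n_unique_b: int
    shared: set
    table: pd.DataFrame  # plot-ready: ligand, target, pearson_r, group


def load_ligand_target_table(
    path_or_df: "str | Path | pd.DataFrame",
    ligand_col: str = "ligand",
    target_col: str = "target",
    source_kind_col: str = "source_kind",
    source_col: str | None = None,
    ppi_sources: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Load a ligand–target table and normalize it to (ligand, target, source_kind).

    Accepts either a table that already carries a ``source_kind`` column with
    values including ``curated`` / ``ppi_prediction``, or a raw provenance
    column (``source_col``) plus the set of source names that count as PPI
    prediction.  Gene ids are uppercased and duplicate (ligand, target) rows
    dropped (first occurrence wins).
    """
    if isinstance(path_or_df, pd.DataFrame):
        df = path_or_df.copy()
    else:
        df = pd.read_csv(path_or_df, sep="\t")
    if source_kind_col not in df.columns:
        if source_col is None or source_col not in df.columns:
            raise ParameterError(
                "table has no source_kind column; pass source_col and ppi_sources"
            )
        df[source_kind_col] = np.where(
            df[source_col].isin(ppi_sources), "ppi_prediction", "curated"
        )
    out = pd.DataFrame(
        {
            "ligand": df[ligand_col].astype(str).str.upper(),
            "target": df[target_col].astype(str).str.upper(),
            "source_kind": df[source_kind_col].astype(str),
        }
    )
    return out.drop_duplicates(subset=["ligand", "target"], keep="first").reset_index(
        drop=True
    )


def predict_rl_pairs(
    m: ExpressionMatrix,
    group_segments: "list[str] | set[str]",
    table: pd.DataFrame,
    r_threshold: float = 0.75,
    group: str = "group",
) -> RLPairResult:
    """Predict co-regulated ligand–target pairs within one segment group.

    For every non-PPI table pair with both genes in the matrix, the Pearson
    correlation across the group's segments is computed on the (normalized)
    values; pairs with ``r > r_threshold`` (strict) are retained.  Pairs with
    a missing gene are silently skipped and counted; zero-variance genes are
    skipped with a warning.
    """
    if len(table) == 0:
        raise ParameterError("ligand–target table is empty")
    segs = [s for s in m.segment_ids if s in set(group_segments)]
    if len(segs) < 3:
        raise InsufficientReplicatesError(
            f"group {group!r} has {len(segs)} segment(s) in the matrix; need >= 3"
        )
    sub = m.values[segs]
    genes = set(sub.index)

    tab = table.loc[table["source_kind"] != "ppi_prediction", ["ligand", "target"]]
    tab = tab.drop_duplicates()

    rows = []
    n_missing = 0
    n_degenerate = 0
    for ligand, target in tab.itertuples(index=False):
        if ligand not in genes or target not in genes:
            n_missing += 1
            continue
        x = sub.loc[ligand].to_numpy(dtype=float)
        y = sub.loc[target].to_numpy(dtype=float)
        if np.std(x) == 0 or np.std(y) == 0:
            warnings.warn(
                f"constant expression for pair ({ligand}, {target}); "
                "correlation undefined, pair skipped",
                stacklevel=2,
            )
            n_degenerate += 1
            continue
        r = float(np.corrcoef(x, y)[0, 1])
        if r > r_threshold:
            rows.append(
                {
                    "ligand": ligand,
                    "target": target,
                    "pearson_r": r,
                    "n_segments": len(segs),
                    "mean_expr_ligand": float(x.mean()),
                    "mean_expr_target": float(y.mean()),
                }
            )
    pairs = pd.DataFrame(rows, columns=PAIR_COLUMNS)
    pairs = pairs.sort_values(["ligand", "target"]).reset_index(drop=True)
    return RLPairResult(
        group=group,
        pairs=pairs,
        n_segments=len(segs),
        n_skipped_missing=n_missing,
        n_skipped_degenerate=n_degenerate,
    )


def compare_groups(a: RLPairResult, b: RLPairResult) -> ComparisonReport:
    """Count shared and group-unique pairs; emit a plot-ready long table."""
    set_a, set_b = a.pair_set, b.pair_set
    shared = set_a & set_b
    table = pd.concat(
        [
            a.pairs[["ligand", "target", "pearson_r"]].assign(group=a.group),
            b.pairs[["ligand", "target", "pearson_r"]].assign(group=b.group),
        ],
        ignore_index=True,
    )
    return ComparisonReport(
        group_a=a.group,
        group_b=b.group,
        n_a=len(set_a),
        n_b=len(set_b),
        n_shared=len(shared),
        n_unique_a=len(set_a - set_b),
        n_unique_b=len(set_b - set_a),
        shared=shared,
        table=table,
    )
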