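"""Tissue expression profiling and qPCR relative quantification.

RNA-seq FPKM matrices are transformed elementwise to log2(FPKM+1) and
ordered for heatmap display by hierarchical clustering of the transformed
rows. qPCR data are reduced to fold changes by the Livak 2^-ddCT method:
per-replicate dCT = Ct(target) - Ct(reference); ddCT is the difference of
treated and control mean dCT, and significance comes from a two-sided
Welch t-test on the replicate dCT values (pooled-variance Student's test
available by option).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "HeatmapSpec",
    "RelExpressionResult",
    "transform_fpkm",
    "ddct_fold_change",
    "call_stress_response",
]

QPCR_COLUMNS = [
    "gene_id", "condition", "timepoint_h", "tissue", "replicate",
    "ct_target", "ct_reference",
]


@dataclass
class HeatmapSpec:
    matrix: pd.DataFrame  # log2(FPKM+1), genes x conditions
    row_order: list[str]
    col_order: list[str]
    linkage: np.ndarray
    color_anchors: tuple = ("green", "yellow", "red")

    def cut(self, k: int) -> dict[str, int]:
        """Cluster labels from cutting the row dendrogram into k groups."""
        from scipy.cluster.hierarchy import fcluster

        labels = fcluster(self.linkage, t=k, criterion="maxclust")
        return dict(zip(self.matrix.index, (int(x) for x in labels)))


def transform_fpkm(m: pd.DataFrame, linkage_method: str = "average") -> HeatmapSpec:
    """log2(FPKM+1) transform plus heatmap row ordering.

    Rows are ordered by hierarchical clustering (Euclidean distance on the
    transformed rows; average linkage by default) with scipy's standard
    recursive leaf ordering. Columns keep input order.
    """
    if (m.values < 0).any():
        raise ValueError("negative FPKM values")
    if not np.isfinite(m.values).all():
        raise ValueError("non-finite FPKM values")
    if m.columns.duplicated().any():
        raise ValueError("duplicate condition labels")
    t = np.log2(m + 1.0)
    if len(t) > 1:
        from scipy.cluster.hierarchy import leaves_list, linkage
        from scipy.spatial.distance import pdist

        z = linkage(pdist(t.values, metric="euclidean"), method=linkage_method)
        order = [t.index[i] for i in leaves_list(z)]
    else:
        z = np.empty((0, 4))
        order = list(t.index)
    return HeatmapSpec(t, order, list(t.columns), z)


@dataclass(frozen=True)
class RelExpressionResult:
    gene_id: str
    condition: str
    timepoint_h: float
    tissue: str
    fold_change: float
    ddct: float
    p_value: float
    n_treated: int
    n_control: int

    def direction(self, alpha: float = 0.05) -> str:
        if self.p_value <= alpha:
            return "up" if self.fold_change > 1.0 else "down"
        return "ns"


def ddct_fold_change(
    records: pd.DataFrame,
    control_label: str = "control",
    equal_var: bool = False,
) -> list[RelExpressionResult]:
    """2^-ddCT relative expression per gene x condition x timepoint x tissue.

    The control cell for a gene/tissue is its ``control_label`` condition
    (pooled over control timepoints). Welch's t-test by default
    (``equal_var=True`` for the pooled-variance Student's test).
    """
    from scipy import stats

    df = records.copy()
    missing = [c for c in QPCR_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"qPCR table missing columns {missing}")
    bad_ct = df[["ct_target", "ct_reference"]].apply(
        lambda s: (s <= 0) | (s >= 45)
    )
    if bad_ct.values.any():
        raise ValueError("Ct values must lie in (0, 45)")
    df["dct"] = df["ct_target"] - df["ct_reference"]
    results: list[RelExpressionResult] = []
    for (gene, tissue), sub in df.groupby(["gene_id", "tissue"], sort=True):
        control = sub[sub["condition"] == control_label]["dct"].to_numpy()
        if control.size == 0:
            raise ValueError(f"missing control cell for ({gene}, {tissue})")
        if control.size < 2:
            raise ValueError(f"<2 control replicates for ({gene}, {tissue})")
        treated = sub[sub["condition"] != control_label]
        for (cond, tp), cell in treated.groupby(["condition", "timepoint_h"], sort=True):
            vals = cell["dct"].to_numpy()
            if vals.size < 2:
                raise ValueError(
                    f"<2 replicates for ({gene}, {cond}, {tp}, {tissue})"
                )
            ddct = float(vals.mean() - control.mean())
            if np.allclose(vals.var(ddof=1) + control.var(ddof=1), 0.0):
                p = 1.0 if np.isclose(ddct, 0.0) else 0.0
            else:
                p = float(stats.ttest_ind(vals, control, equal_var=equal_var).pvalue)
            results.append(
                RelExpressionResult(
                    gene, cond, float(tp), tissue, 2.0 ** (-ddct), ddct, p,
                    int(vals.size), int(control.size),
                )
            )
    return results


def call_stress_response(
    results: list[RelExpressionResult], alpha: float = 0.05
) -> pd.DataFrame:
    """Per-cell up/down/ns calls plus induced/repressed counts per cell.

    'up' requires fold_change > 1 and p <= alpha; 'down' fold_change < 1
    and p <= alpha; otherwise 'ns'.
    """
    rows = [
        {
            "gene_id": r.gene_id,
            "condition": r.condition,
            "timepoint_h": r.timepoint_h,
            "tissue": r.tissue,
            "fold_change": r.fold_change,
            "p_value": r.p_value,
            "direction": r.direction(alpha),
            "significant_0.01": r.p_value <= 0.01,
        }
        for r in results
    ]
    calls = pd.DataFrame(rows)
    summary = (
        calls.groupby(["condition", "timepoint_h", "tissue"])["direction"]
        .value_counts()
        .unstack(fill_value=0)
        .reindex(columns=["up", "down", "ns"], fill_value=0)
        .reset_index()
    )
    summary = summary.rename(columns={"up": "n_induced", "down": "n_repressed", "ns": "n_ns"})
    calls.attrs["summary"] = summary
    return calls
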