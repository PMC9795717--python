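"""Fold changes, DEG calling, temporal clustering, and PPI screening.

The transcriptomic stage works on plain expression tables (genes ×
samples) with a sample sheet giving cell type (EC/MSC), condition
(mono/co) and timepoint.  Per cell type and timepoint, a co-culture vs
monoculture log2 fold change is computed; genes crossing |log2FC| > 1
at any timepoint are DEGs; DEG temporal profiles (z-normalized per
gene) are clustered with Ward linkage on cosine distances, cutting the
dendrogram at the smallest number of clusters whose mean within-cluster
pairwise Pearson correlation exceeds 0.6.  Candidate interactions are
then screened: an edge survives only if its database, experimental and
text-mining confidence scores all strictly exceed the threshold, its
endpoints are DEGs of *different* cell types, and neither endpoint is
differentially expressed in both cell types.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

DEG_UP_THRESHOLD = 1.0  # log2 fold change, strict
DEG_DOWN_THRESHOLD = -1.0
MIN_WITHIN_CORR = 0.6
PPI_SCORE_THRESHOLD = 0.9
SCORE_COLUMNS = ("db_score", "exp_score", "text_score")


# ---------------------------------------------------------------------------
# fold changes


@dataclass
class FoldChangeMatrix:
    """Per-cell-type log2 fold changes and z-normalized profiles.

    ``log2fc``: genes × timepoints, co vs mono control.
    ``zprofile``: the same profiles standardized per gene (mean 0,
    sd 1 across timepoints); constant profiles are left at 0.
    """

    cell_type: str
    log2fc: pd.DataFrame
    zprofile: pd.DataFrame


def _zscore_rows(df: pd.DataFrame) -> pd.DataFrame:
    vals = df.to_numpy(dtype=float)
    mu = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, keepdims=True)
    z = np.divide(vals - mu, sd, out=np.zeros_like(vals), where=sd > 0)
    return pd.DataFrame(z, index=df.index, columns=df.columns)


def fold_changes(
    expr: pd.DataFrame, samples: pd.DataFrame, pseudocount: float | None = None
) -> dict[str, FoldChangeMatrix]:
    """log2((co + ε) / (mono + ε)) per gene, cell type and timepoint.

    ``samples`` needs columns sample / cell_type / condition / time_h.
    ε defaults to 1 for integer (count-like) data, otherwise half the
    smallest positive value in the matrix.
    """
    required = {"sample", "cell_type", "condition", "time_h"}
    if not required.issubset(samples.columns):
        raise ValueError(f"sample sheet must have columns {sorted(required)}")
    if expr.index.hasnans or expr.index.duplicated().any():
        raise ValueError("expression matrix has missing or duplicated gene ids")
    if pseudocount is None:
        vals = expr.to_numpy()
        if np.allclose(vals, np.round(vals)):
            pseudocount = 1.0
        else:
            pos = vals[vals > 0]
            pseudocount = float(pos.min() / 2.0) if pos.size else 1.0

    out: dict[str, FoldChangeMatrix] = {}
    for ct, sub in samples.groupby("cell_type"):
        times = sorted(sub["time_h"].unique())
        cols = {}
        for t in times:
            mono = sub[(sub.condition == "mono") & (sub.time_h == t)]["sample"]
            co = sub[(sub.condition == "co") & (sub.time_h == t)]["sample"]
            if mono.empty or co.empty:
                raise ValueError(
                    f"missing {'control' if mono.empty else 'co-culture'} sample "
                    f"for cell type {ct} at {t} h"
                )
            mono_mean = expr[list(mono)].mean(axis=1)
            co_mean = expr[list(co)].mean(axis=1)
            cols[f"{t}h"] = np.log2((co_mean + pseudocount) / (mono_mean + pseudocount))
        fc = pd.DataFrame(cols, index=expr.index)
        out[ct] = FoldChangeMatrix(cell_type=ct, log2fc=fc, zprofile=_zscore_rows(fc))
    return out


# ---------------------------------------------------------------------------
# DEG calling


def call_degs(fc: FoldChangeMatrix) -> pd.DataFrame:
    """Call DEGs: any timepoint with log2FC strictly beyond ±1.

    The direction is taken from the timepoint of largest |log2FC|.
    Returns a DataFrame indexed by DEG gene with columns ``direction``
    ("up"/"down") and ``max_abs_fc``.
    """
    vals = fc.log2fc.to_numpy(dtype=float)
    hit = (vals > DEG_UP_THRESHOLD).any(axis=1) | (vals < DEG_DOWN_THRESHOLD).any(
        axis=1
    )
    idx_max = np.abs(vals).argmax(axis=1)
    peak = vals[np.arange(len(vals)), idx_max]
    df = pd.DataFrame(
        {
            "direction": np.where(peak > 0, "up", "down"),
            "max_abs_fc": np.abs(peak),
        },
        index=fc.log2fc.index,
    )
    return df[hit]


# ---------------------------------------------------------------------------
# clustering


@dataclass
class DEGClusterSet:
    """Cluster assignments of DEG temporal profiles for one cell type.

    Labels follow the <cell>-<U|D><rank> scheme, with rank ordered by
    the cluster-mean peak timepoint.  ``within_corr`` maps each label to
    its mean within-cluster pairwise Pearson correlation (NaN for
    singletons, which satisfy the criterion vacuously).
    """

    cell_type: str
    direction: str  # "up" or "down"
    assignments: pd.Series  # gene -> label
    within_corr: dict[str, float]
    k: int
    all_singletons: bool = False

    def genes(self, label: str) -> list[str]:
        return list(self.assignments.index[self.assignments == label])


def _mean_pairwise_pearson(X: np.ndarray) -> float:
    """Mean pairwise Pearson correlation among rows; NaN for < 2 rows.

    Pairs of identical profiles count as perfectly correlated even when
    the profiles are constant (where the textbook formula is 0/0).
    """
    n = len(X)
    if n < 2:
        return np.nan
    vals = []
    for i in range(n):
        for j in range(i + 1, n):
            a, b = X[i], X[j]
            if np.allclose(a, b):
                vals.append(1.0)
                continue
            sa, sb = a.std(), b.std()
            if sa == 0 or sb == 0:
                vals.append(0.0)
                continue
            vals.append(float(np.corrcoef(a, b)[0, 1]))
    return float(np.mean(vals))


def cluster_degs(
    profiles: pd.DataFrame,
    cell_type: str = "EC",
    direction: str = "up",
    min_within_corr: float = MIN_WITHIN_CORR,
) -> DEGClusterSet:
    """Ward-linkage clustering of DEG profiles on cosine distances.

    The dendrogram is cut at the smallest k such that every cluster's
    mean within-cluster pairwise Pearson correlation exceeds
    ``min_within_corr`` (singletons pass vacuously).  If no k < n
    satisfies the criterion an all-singleton clustering is returned
    with a warning.
    """
    if len(profiles) < 2:
        raise ValueError("need at least two DEG profiles to cluster")
    X = profiles.to_numpy(dtype=float)
    D = pdist(X, metric="cosine")
    D = np.clip(D, 0.0, None)  # guard tiny negative rounding
    Z = linkage(D, method="ward")

    n = len(X)
    chosen = None
    for k in range(1, n):
        labels = fcluster(Z, t=k, criterion="maxclust")
        ok = True
        for c in np.unique(labels):
            r = _mean_pairwise_pearson(X[labels == c])
            if not np.isnan(r) and r <= min_within_corr:
                ok = False
                break
        if ok:
            chosen = (k, labels)
            break
    all_singletons = False
    if chosen is None:
        warnings.warn(
            "within-cluster correlation criterion unreachable before k = n; "
            "returning singletons"
        )
        chosen = (n, np.arange(1, n + 1))
        all_singletons = True
    k, labels = chosen

    # rank clusters by peak-time of the cluster-mean profile, then magnitude
    order_keys = []
    for c in np.unique(labels):
        mean_prof = X[labels == c].mean(axis=0)
        order_keys.append((c, int(np.abs(mean_prof).argmax()), -np.abs(mean_prof).max()))
    order_keys.sort(key=lambda t: (t[1], t[2]))
    dir_letter = "U" if direction == "up" else "D"
    name_of = {
        c: f"{cell_type}-{dir_letter}{rank + 1}"
        for rank, (c, _, _) in enumerate(order_keys)
    }
    assign = pd.Series(
        [name_of[c] for c in labels], index=profiles.index, name="cluster"
    )
    within = {
        name_of[c]: _mean_pairwise_pearson(X[labels == c]) for c in np.unique(labels)
    }
    return DEGClusterSet(
        cell_type=cell_type,
        direction=direction,
        assignments=assign,
        within_corr=within,
        k=int(k),
        all_singletons=all_singletons,
    )


# ---------------------------------------------------------------------------
# PPI screening


def filter_ppis(
    candidates: pd.DataFrame,
    ec_degs: set[str] | list[str],
    msc_degs: set[str] | list[str],
    threshold: float = PPI_SCORE_THRESHOLD,
) -> pd.DataFrame:
    """Screen candidate interactions down to high-confidence cross edges.

    Retained rows have all three confidence scores strictly above
    ``threshold``, endpoints from different cell types with each gene a
    DEG of its own cell type, and no endpoint among genes that are DEGs
    in both cell types.
    """
    need = {"gene_a", "cell_type_a", "gene_b", "cell_type_b", *SCORE_COLUMNS}
    if not need.issubset(candidates.columns):
        raise ValueError(f"candidate table must have columns {sorted(need)}")
    for col in SCORE_COLUMNS:
        bad = candidates.index[
            (candidates[col] < 0) | (candidates[col] > 1) | candidates[col].isna()
        ]
        if len(bad):
            raise ValueError(f"score {col} outside [0, 1] at row {bad[0]}")

    ec = set(ec_degs)
    msc = set(msc_degs)
    shared = ec & msc

    def keep(row) -> bool:
        if not all(row[c] > threshold for c in SCORE_COLUMNS):
            return False
        if row.cell_type_a == row.cell_type_b:
            return False
        sets = {"EC": ec, "MSC": msc}
        if row.gene_a not in sets.get(row.cell_type_a, set()):
            return False
        if row.gene_b not in sets.get(row.cell_type_b, set()):
            return False
        if row.gene_a in shared or row.gene_b in shared:
            return False
        return True

    mask = candidates.apply(keep, axis=1) if len(candidates) else pd.Series(dtype=bool)
    return candidates[mask].reset_index(drop=True)


def network_from_edges(edges: pd.DataFrame) -> nx.Graph:
    """Build the interaction graph (node attribute: cell_type)."""
    G = nx.Graph()
    for _, row in edges.iterrows():
        G.add_node(row.gene_a, cell_type=row.cell_type_a)
        G.add_node(row.gene_b, cell_type=row.cell_type_b)
        G.add_edge(
            row.gene_a,
            row.gene_b,
            db_score=float(row.db_score),
            exp_score=float(row.exp_score),
            text_score=float(row.text_score),
        )
    return G
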