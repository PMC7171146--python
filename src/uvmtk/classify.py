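"""Pan-cancer transcriptomic classification by Spearman k-NN.

A query expression profile is compared against every sample of a labeled
reference panel by Spearman rank correlation over the shared gene set; the
label is decided by majority vote among the k best-correlated reference
samples (k = 6 by default).  Vote ties are broken by removing the worst
correlating member of the neighbor set and re-voting until the vote is
untied.  Because the statistic is rank-based, any strictly increasing
transform of the query leaves the prediction unchanged.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["spearman_profile", "knn_classify"]


def spearman_profile(query: pd.Series, panel: pd.DataFrame) -> pd.Series:
    """Spearman rho between the query and every reference sample.

    Computed over the intersection of the query's genes and the panel's
    rows (at least 3 shared genes required), with average ranks for ties.
    A constant query (zero rank variance) is an error.
    """
    genes = query.index.intersection(panel.index)
    if len(genes) < 3:
        raise ValueError(f"need >= 3 shared genes, got {len(genes)}")
    q = query.loc[genes].to_numpy(dtype=float)
    if np.ptp(q) == 0:
        raise ValueError("constant query profile: Spearman rho undefined")
    X = panel.loc[genes].to_numpy(dtype=float)
    qr = stats.rankdata(q)
    qr = qr - qr.mean()
    R = np.apply_along_axis(stats.rankdata, 0, X)
    R = R - R.mean(axis=0, keepdims=True)
    denom = np.sqrt((qr**2).sum() * (R**2).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        rho = (qr @ R) / denom
    return pd.Series(rho, index=panel.columns, name="rho")


def knn_classify(
    query: pd.Series,
    panel: pd.DataFrame,
    labels: pd.Series,
    k: int = 6,
) -> dict:
    """k-nearest-neighbor label by Spearman correlation.

    The k highest-rho reference samples vote; a tied vote is resolved by
    dropping the lowest-rho member of the neighbor set and re-voting,
    repeated until untied.  References whose rho is undefined (constant
    column) are excluded; equal rho at the k-th position admits all tied
    samples before the drop-worst loop (deterministic order by sample id).

    Returns a dict with ``label``, ``neighbors`` (rho-ordered Series) and
    ``votes`` for the final deciding set.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > panel.shape[1]:
        raise ValueError(f"k={k} exceeds panel size {panel.shape[1]}")
    rho = spearman_profile(query, panel).dropna()
    if rho.empty:
        raise ValueError("all reference correlations undefined")
    order = pd.DataFrame({"rho": rho}).sort_values(
        ["rho"], ascending=False, kind="mergesort"
    )
    # stable order among exact rho ties: by sample id
    order = order.reset_index().sort_values(
        ["rho", "index"], ascending=[False, True], kind="mergesort"
    ).set_index("index")
    kth_rho = order["rho"].iloc[min(k, len(order)) - 1]
    neighbors = order[order["rho"] >= kth_rho]
    current = list(neighbors.index)
    while True:
        votes = labels.loc[current].value_counts()
        top = votes[votes == votes.max()]
        if len(top) == 1 or len(current) == 1:
            label = top.index[0]
            break
        current = current[:-1]  # drop the worst correlating sample
    return {
        "label": label,
        "neighbors": neighbors["rho"],
        "votes": votes,
    }
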