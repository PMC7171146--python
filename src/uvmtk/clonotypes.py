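"""TIL clonotype QC and diversity.

Per-cell TCR chain assignments are cleaned with a chain-count doublet rule
and marker-based cell-type reclassification rules, then collapsed to
clonotype frequencies whose normalized Shannon entropy (H / ln U for U
unique clonotypes) summarizes repertoire diversity: 0 for a monoclonal
culture, 1 for a maximally even one.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ledger import FilterLedger

__all__ = [
    "flag_doublets",
    "reclassify",
    "normalized_entropy",
    "clonotype_frequencies",
    "diversity_per_sample",
]


def flag_doublets(
    table: pd.DataFrame, external_flags: pd.Series | None = None
) -> pd.Series:
    """Doublet call per cell.

    A cell is a doublet when externally flagged (e.g. by an expression-based
    doublet caller) or when it expresses more than two alpha or more than
    two beta chains.  Two alpha plus two beta chains alone do not trigger
    the rule (it is strictly > 2 per chain type).
    """
    doublet = (table["alpha_count"] > 2) | (table["beta_count"] > 2)
    doublet.name = "doublet"
    if external_flags is not None:
        ext = external_flags.reindex(table.index).fillna(False).astype(bool)
        doublet = doublet | ext
    return doublet


# default label vocabulary for the reclassification rules; any label set
# can be supplied instead
CD4_LABELS = {"CD4+ T naive", "CD4+ T memory", "CD4+ T regulatory"}
T_LABELS = CD4_LABELS | {"CD8+ T", "CD8+ T naive", "CD8+ T cytotoxic"}
DENDRITIC_LABELS = {"Dendritic"}
MEMORY_CD4_LABELS = {"CD4+ T memory"}


def _best_label(scores: pd.Series, allowed: set[str]) -> str | None:
    cand = scores[scores.index.isin(allowed)].dropna()
    if cand.empty:
        return None
    # deterministic: highest score, ties by label name
    return sorted(cand.items(), key=lambda kv: (-kv[1], kv[0]))[0][0]


def reclassify(
    table: pd.DataFrame,
    score_prefix: str = "score_",
    expr_threshold: float = 0.0,
    cd4_labels: set[str] = CD4_LABELS,
    memory_cd4_labels: set[str] = MEMORY_CD4_LABELS,
    t_labels: set[str] = T_LABELS,
    dendritic_labels: set[str] = DENDRITIC_LABELS,
    max_rounds: int = 3,
    ledger: FilterLedger | None = None,
) -> pd.Series:
    """Correct predicted cell-type labels with three marker rules.

    Applied in order, per cell, until stable:

    1. memory CD4 cells not expressing CD4 but expressing CD8A move to the
       best-scoring non-CD4 type;
    2. predicted non-T cells carrying any TCR chain move to the
       best-scoring T type;
    3. predicted dendritic cells expressing CD3G or NCAM1 move to the
       best-scoring non-dendritic type.

    "Expressing" means marker count > ``expr_threshold``; "best-scoring"
    uses the per-cell correlation score columns (``score_<type>``).  Cells
    with no allowed type remaining, or whose labels do not stabilize
    within ``max_rounds``, become "unassigned".
    """
    all_types = {
        c[len(score_prefix):] for c in table.columns if c.startswith(score_prefix)
    }
    labels = table["label"].astype(str).copy()
    n_changed = 0
    for cell in table.index:
        row = table.loc[cell]
        scores = pd.Series(
            {t: row.get(score_prefix + t, np.nan) for t in all_types},
            dtype=float,
        )
        label = str(row["label"])
        has_tcr = (row["alpha_count"] + row["beta_count"]) > 0
        for _ in range(max_rounds):
            new = label
            if (
                label in memory_cd4_labels
                and row.get("CD4", 0) <= expr_threshold
                and row.get("CD8A", 0) > expr_threshold
            ):
                best = _best_label(scores, all_types - cd4_labels)
                new = best if best is not None else "unassigned"
            elif label not in t_labels and label != "unassigned" and has_tcr:
                best = _best_label(scores, t_labels)
                new = best if best is not None else "unassigned"
            elif label in dendritic_labels and (
                row.get("CD3G", 0) > expr_threshold
                or row.get("NCAM1", 0) > expr_threshold
            ):
                best = _best_label(scores, all_types - dendritic_labels)
                new = best if best is not None else "unassigned"
            if new == label:
                break
            label = new
        else:
            label = "unassigned"  # rules cycled; no stable assignment
        if label != str(row["label"]):
            n_changed += 1
        labels.loc[cell] = label
    if ledger is not None:
        ledger.record("til_clonotypes", "reclassified", len(table),
                      len(table) - n_changed)
    return labels


def normalized_entropy(frequencies) -> float:
    """Shannon entropy of clonotype frequencies normalized by ln(U).

    ``frequencies`` must be positive and sum to 1 (within 1e-9).  Defined
    as 0 for a single clonotype (the monoclonal, zero-diversity case).
    """
    f = np.asarray(frequencies, dtype=float)
    if f.size == 0:
        raise ValueError("no clonotype frequencies")
    if (f <= 0).any():
        raise ValueError("frequencies must be positive")
    if abs(f.sum() - 1.0) > 1e-9:
        raise ValueError(f"frequencies sum to {f.sum()}, not 1")
    if f.size == 1:
        return 0.0
    h = float(-(f * np.log(f)).sum())
    return h / float(np.log(f.size))


def clonotype_frequencies(
    table: pd.DataFrame,
    exclude_doublets: bool = True,
    external_flags: pd.Series | None = None,
    label_filter: str | None = "CD8",
) -> pd.Series:
    """Clonotype frequency distribution from a per-cell table.

    Doublets are removed first; ``label_filter`` restricts to cells whose
    label contains the given substring (CD8 cells by default, matching how
    repertoire diversity is reported for cytotoxic infiltrates).  Pass
    ``label_filter=None`` to use all cells.
    """
    df = table
    if exclude_doublets:
        df = df[~flag_doublets(df, external_flags)]
    if label_filter is not None and "label" in df.columns:
        df = df[df["label"].astype(str).str.contains(label_filter, regex=False)]
    if df.empty:
        raise ValueError("no cells left after filtering")
    counts = df.groupby("clonotype").size()
    return (counts / counts.sum()).rename("frequency")


def diversity_per_sample(
    table: pd.DataFrame, sample_col: str = "sample", **kwargs
) -> pd.DataFrame:
    """Normalized clonotype entropy for each sample in a combined table."""
    rows = []
    for sample, grp in table.groupby(sample_col):
        freqs = clonotype_frequencies(grp, **kwargs)
        rows.append(
            {
                sample_col: sample,
                "n_cells": int(grp.shape[0]),
                "n_clonotypes": int(freqs.size),
                "normalized_entropy": normalized_entropy(freqs.values),
            }
        )
    return pd.DataFrame(rows)
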