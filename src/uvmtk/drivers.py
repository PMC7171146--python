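"""Ranking of genes inside recurrent broad copy-number events.

Candidate drivers are genes whose expression tracks their copy number
consistently in two cohorts (a metastatic cohort and a reference cohort).
Per cohort, expression (log2 RPKM + 1) is regressed on the gene's copy-
number status with tumor purity as an additive covariate; per-cohort p
values are combined with Fisher's method and BH-adjusted across all tested
genes.  Retained candidates (q < 0.05, both raw p < 0.05, dosage-consistent
slopes, alteration frequency at or above the per-event third quartile) are
ranked within their region by protein-protein interaction degree, then by a
consistent worse-survival association, then by combined q.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import PipelineConfig
from .ledger import FilterLedger

__all__ = [
    "NormalizedExpression",
    "rpkm_normalize",
    "purity_adjusted_association",
    "combine_fisher",
    "frequency_filter",
    "cox_univariate",
    "rank_candidates",
    "rank_drivers",
]


@dataclass
class NormalizedExpression:
    rpkm: pd.DataFrame          # genes x samples
    size_factors: pd.Series     # per sample, median-of-ratios
    effective_lib: pd.Series    # size factor x geometric-mean library size

    def log2(self) -> pd.DataFrame:
        return np.log2(self.rpkm + 1.0)


def median_ratio_size_factors(counts: pd.DataFrame) -> pd.Series:
    """Robust per-sample size factors by the median-of-ratios method.

    The reference is the per-gene geometric mean across samples; genes with
    a zero count in any sample are excluded from the factor computation.
    Falls back to raw library-size factors (scaled to geometric mean 1)
    with a warning when no gene has all-positive counts.
    """
    x = counts.to_numpy(dtype=float)
    positive = (x > 0).all(axis=1)
    if not positive.any():
        warnings.warn(
            "no gene with all-positive counts; falling back to library-size factors"
        )
        lib = x.sum(axis=0)
        if (lib <= 0).any():
            raise ValueError("sample with zero library size")
        sf = lib / np.exp(np.mean(np.log(lib)))
        return pd.Series(sf, index=counts.columns, name="size_factor")
    logs = np.log(x[positive])
    ref = logs.mean(axis=1, keepdims=True)  # log geometric mean per gene
    sf = np.exp(np.median(logs - ref, axis=0))
    return pd.Series(sf, index=counts.columns, name="size_factor")


def rpkm_normalize(counts: pd.DataFrame, lengths: pd.Series) -> NormalizedExpression:
    """RPKM with robust (median-of-ratios) effective library sizes.

    RPKM_gs = count_gs * 1e9 / (effective_lib_s * length_g), where the
    effective library size is the sample's size factor times the geometric
    mean of raw library sizes.  ``lengths`` is max mature transcript length
    per gene in bp.
    """
    lengths = lengths.reindex(counts.index)
    if lengths.isna().any():
        missing = list(counts.index[lengths.isna()])[:5]
        raise ValueError(f"transcript length missing for genes {missing}...")
    if (lengths <= 0).any():
        raise ValueError("transcript lengths must be positive")
    sf = median_ratio_size_factors(counts)
    lib = counts.sum(axis=0).astype(float)
    geo_lib = float(np.exp(np.mean(np.log(lib))))
    eff = sf * geo_lib
    rpkm = counts.div(eff, axis=1).div(lengths, axis=0) * 1e9
    return NormalizedExpression(
        rpkm=rpkm, size_factors=sf, effective_lib=eff.rename("effective_lib")
    )


def _ols_batch(Y: np.ndarray, CN: np.ndarray, purity: np.ndarray):
    """Per-gene OLS of y on [1, cn, purity]; returns slope, p, status.

    Y and CN are genes x samples; a constant purity column is dropped from
    the design (it would be collinear with the intercept).  Genes with zero
    variance in cn or y are flagged degenerate.
    """
    G, n = Y.shape
    use_purity = np.ptp(purity) > 0
    k = 3 if use_purity else 2
    slope = np.full(G, np.nan)
    pval = np.full(G, np.nan)
    status = np.full(G, "ok", dtype=object)
    if n < max(k, 3):
        status[:] = "dropped_few_samples"
        return slope, pval, status
    var_cn = CN.var(axis=1)
    var_y = Y.var(axis=1)
    degenerate = (var_cn <= 0) | (var_y <= 0)
    ok = ~degenerate
    status[degenerate] = "dropped_degenerate"
    if not ok.any():
        return slope, pval, status
    Yk = Y[ok]
    CNk = CN[ok]
    m = Yk.shape[0]
    X = np.empty((m, n, k))
    X[:, :, 0] = 1.0
    X[:, :, 1] = CNk
    if use_purity:
        X[:, :, 2] = purity[None, :]
    XtX = np.einsum("gni,gnj->gij", X, X)
    Xty = np.einsum("gni,gn->gi", X, Yk)
    try:
        beta = np.linalg.solve(XtX, Xty[..., None])[..., 0]
        inv = np.linalg.inv(XtX)
    except np.linalg.LinAlgError:
        # fall back to per-gene pinv on rare singular designs
        beta = np.empty((m, k))
        inv = np.empty((m, k, k))
        for i in range(m):
            inv[i] = np.linalg.pinv(XtX[i])
            beta[i] = inv[i] @ Xty[i]
    rss = np.einsum("gn,gn->g", Yk, Yk) - np.einsum("gi,gi->g", beta, Xty)
    rss = np.maximum(rss, 0.0)
    dof = n - k
    sigma2 = rss / dof
    se = np.sqrt(np.maximum(sigma2 * inv[:, 1, 1], 0.0))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = beta[:, 1] / se
    p = np.where(np.isinf(t), 0.0, 2.0 * stats.t.sf(np.abs(t), dof))
    p = np.where(np.isnan(t), np.nan, p)
    slope[ok] = beta[:, 1]
    pval[ok] = p
    status[ok & np.isnan(pval)] = "dropped_degenerate"
    return slope, pval, status


def purity_adjusted_association(
    expr: pd.DataFrame,
    cn: pd.DataFrame,
    purity: pd.Series,
    log_transform: bool = True,
    min_samples: int = 3,
    ledger: FilterLedger | None = None,
) -> pd.DataFrame:
    """Copy-number / expression association per gene, adjusted for purity.

    ``expr`` (RPKM; log2(x+1)-transformed internally unless
    ``log_transform=False``) and ``cn`` (signed log2 status) are genes x
    samples frames sharing gene index; ``purity`` indexes the shared
    samples.  Returns a frame with slope, p, n and a status column; genes
    with fewer than ``min_samples`` complete observations or a degenerate
    fit carry NaN statistics.
    """
    samples = expr.columns.intersection(cn.columns).intersection(purity.index)
    if len(samples) < min_samples:
        raise ValueError(f"need >= {min_samples} shared samples, got {len(samples)}")
    genes = expr.index.intersection(cn.index)
    E = expr.loc[genes, samples].to_numpy(dtype=float)
    if log_transform:
        E = np.log2(E + 1.0)
    C = cn.loc[genes, samples].to_numpy(dtype=float)
    pur = purity.loc[samples].to_numpy(dtype=float)
    complete = np.isfinite(E) & np.isfinite(C)
    slope = np.full(len(genes), np.nan)
    pval = np.full(len(genes), np.nan)
    status = np.full(len(genes), "dropped_few_samples", dtype=object)
    full = complete.all(axis=1)
    if full.any():
        s, p, st = _ols_batch(E[full], C[full], pur)
        slope[full], pval[full], status[full] = s, p, st
    for i in np.flatnonzero(~full):
        mask = complete[i]
        if mask.sum() < min_samples:
            continue
        s, p, st = _ols_batch(
            E[i, mask][None, :], C[i, mask][None, :], pur[mask]
        )
        slope[i], pval[i], status[i] = s[0], p[0], st[0]
    out = pd.DataFrame(
        {
            "slope": slope,
            "p": pval,
            "n": complete.sum(axis=1),
            "status": status,
        },
        index=genes,
    )
    if ledger is not None:
        ledger.record(
            "driver_ranking", "association_testable", len(out),
            int((out["status"] == "ok").sum()),
        )
    return out


def combine_fisher(p_a, p_b):
    """Fisher's method for two independent p values (chi-square, 4 df).

    Zero inputs are clamped to the smallest positive float with a warning.
    Accepts scalars or arrays; symmetric and monotone in each argument.
    """
    pa = np.asarray(p_a, dtype=float)
    pb = np.asarray(p_b, dtype=float)
    if ((pa < 0) | (pa > 1) | (pb < 0) | (pb > 1)).any():
        raise ValueError("p values must lie in [0, 1]")
    tiny = np.nextafter(0.0, 1.0)
    if (pa == 0).any() or (pb == 0).any():
        warnings.warn("zero p value clamped to smallest positive float")
    pa = np.clip(pa, tiny, 1.0)
    pb = np.clip(pb, tiny, 1.0)
    x2 = -2.0 * (np.log(pa) + np.log(pb))
    out = stats.chi2.sf(x2, df=4)
    if np.isscalar(p_a) and np.isscalar(p_b):
        return float(out)
    return out


def frequency_filter(
    statuses: pd.DataFrame,
    direction: str,
    config: PipelineConfig,
    ledger: FilterLedger | None = None,
) -> pd.DataFrame:
    """Per-event alteration-frequency filter.

    ``statuses`` is genes x samples of signed log2 values for the genes of
    one (arm, direction) event.  A sample counts as altered when its value
    reaches ``min_abs_log2`` in the event direction.  Genes at or above the
    ``freq_quantile`` (default third) quantile of the event's frequency
    distribution (type-7/linear quantile) are retained.
    """
    if direction not in ("gain", "loss"):
        raise ValueError("direction must be gain/loss")
    vals = statuses.to_numpy(dtype=float)
    with np.errstate(invalid="ignore"):
        if direction == "gain":
            altered = vals >= config.min_abs_log2
        else:
            altered = vals <= -config.min_abs_log2
    n_obs = np.isfinite(vals).sum(axis=1)
    freq = np.where(n_obs > 0, altered.sum(axis=1) / np.maximum(n_obs, 1), 0.0)
    cutoff = float(np.quantile(freq, config.freq_quantile))
    out = pd.DataFrame(
        {"frequency": freq, "retained": freq >= cutoff}, index=statuses.index
    )
    if ledger is not None:
        ledger.record(
            "driver_ranking", f"frequency_{direction}", len(out),
            int(out["retained"].sum()),
        )
    return out


def cox_univariate(
    expr_gene: pd.Series, survival: pd.DataFrame, min_events: int = 2
) -> dict:
    """Univariate Cox proportional-hazards fit of survival on expression.

    ``survival`` is indexed by sample with columns time and event; Efron
    tie handling; Wald p on the expression coefficient.  Returns a dict
    with coef, p and a testable flag (False when fewer than ``min_events``
    events or the fit fails/degenerates).
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    samples = expr_gene.index.intersection(survival.index)
    df = pd.DataFrame(
        {
            "time": survival.loc[samples, "time"].astype(float),
            "event": survival.loc[samples, "event"].astype(int),
            "x": expr_gene.loc[samples].astype(float),
        }
    ).dropna()
    if int(df["event"].sum()) < min_events or df["x"].nunique() < 2:
        return {"coef": np.nan, "p": np.nan, "testable": False}
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
    except (ConvergenceError, ValueError):
        return {"coef": np.nan, "p": np.nan, "testable": False}
    return {
        "coef": float(cph.params_["x"]),
        "p": float(cph.summary.loc["x", "p"]),
        "testable": True,
    }


def rank_candidates(candidates: pd.DataFrame) -> pd.DataFrame:
    """Order retained candidates within each region.

    Sort keys: PPI degree (descending), consistent worse-survival flag
    (flagged first), combined q (ascending), gene name.  Adds a 1-based
    ``rank`` column per (arm, direction) region.
    """
    df = candidates.copy()
    df["degree"] = df["degree"].fillna(0).astype(int)
    df = df.sort_values(
        ["arm", "direction", "degree", "survival_flag", "q", "gene"],
        ascending=[True, True, False, False, True, True],
        kind="mergesort",
    )
    df["rank"] = df.groupby(["arm", "direction"]).cumcount() + 1
    return df.reset_index(drop=True)


def _genes_in_region(gene_models: pd.DataFrame, arm: str) -> pd.Index:
    """Genes belonging to an event unit (an arm, or a whole chromosome)."""
    arms = gene_models["arm"].astype(str)
    if arm.endswith(("p", "q")):
        sel = arms == arm
    else:  # whole-chromosome unit matches both arms
        sel = arms.isin([arm, arm + "p", arm + "q"])
    return pd.Index(gene_models.loc[sel, "gene"])


def rank_drivers(
    counts_a: pd.DataFrame,
    cn_a: pd.DataFrame,
    purity_a: pd.Series,
    counts_b: pd.DataFrame,
    cn_b: pd.DataFrame,
    purity_b: pd.Series,
    regions: pd.DataFrame,
    gene_models: pd.DataFrame,
    ppi_degree: pd.Series,
    survival_b: pd.DataFrame,
    config: PipelineConfig,
    ledger: FilterLedger | None = None,
) -> pd.DataFrame:
    """End-to-end driver prioritization over a recurrent-region list.

    Cohort A is the metastatic cohort, B the reference cohort supplying the
    frequency filter and the survival data.  ``regions`` has columns arm and
    direction.  Returns one row per tested gene with per-cohort statistics,
    combined q, retention flag and (for retained genes) the within-region
    rank.
    """
    lengths = gene_models.set_index("gene")["max_tx_len"]
    expr_a = rpkm_normalize(
        counts_a, lengths.reindex(counts_a.index)
    ).log2()
    expr_b = rpkm_normalize(
        counts_b, lengths.reindex(counts_b.index)
    ).log2()

    frames = []
    for region in regions.itertuples(index=False):
        arm, direction = str(region.arm), str(region.direction)
        genes = _genes_in_region(gene_models, arm)
        genes = genes.intersection(expr_a.index).intersection(expr_b.index)
        genes = genes.intersection(cn_a.index).intersection(cn_b.index)
        if len(genes) == 0:
            continue
        # genes must carry both copy-number and expression values
        has_cn = cn_a.loc[genes].notna().any(axis=1) & cn_b.loc[genes].notna().any(axis=1)
        genes = genes[has_cn]
        if ledger is not None:
            ledger.record(
                "driver_ranking", f"{arm}_{direction}:cn_and_expr",
                int(has_cn.size), int(len(genes)),
            )
        if len(genes) == 0:
            continue
        freq = frequency_filter(
            cn_b.loc[genes], direction, config, ledger=ledger
        )
        kept = freq.index[freq["retained"]]
        if len(kept) == 0:
            continue
        assoc_a = purity_adjusted_association(
            expr_a.loc[kept], cn_a.loc[kept], purity_a,
            log_transform=False, ledger=ledger,
        )
        assoc_b = purity_adjusted_association(
            expr_b.loc[kept], cn_b.loc[kept], purity_b,
            log_transform=False, ledger=ledger,
        )
        df = pd.DataFrame(
            {
                "gene": kept,
                "arm": arm,
                "direction": direction,
                "frequency": freq.loc[kept, "frequency"].values,
                "slope_a": assoc_a["slope"].values,
                "p_a": assoc_a["p"].values,
                "slope_b": assoc_b["slope"].values,
                "p_b": assoc_b["p"].values,
            }
        )
        frames.append(df)

    if not frames:
        return pd.DataFrame(
            columns=[
                "gene", "arm", "direction", "frequency", "slope_a", "p_a",
                "slope_b", "p_b", "p_combined", "q", "retained", "degree",
                "survival_coef", "survival_p", "survival_flag", "rank",
            ]
        )
    all_genes = pd.concat(frames, ignore_index=True)
    testable = all_genes.dropna(subset=["p_a", "p_b"]).copy()
    testable["p_combined"] = combine_fisher(
        testable["p_a"].values, testable["p_b"].values
    )
    testable["q"] = np.nan
    testable["q"] = bh_over(testable["p_combined"].values)
    # dosage-consistent: expression moves with copy number in both cohorts
    consistent = (testable["slope_a"] > 0) & (testable["slope_b"] > 0)
    testable["retained"] = (
        (testable["q"] < config.q_threshold)
        & (testable["p_a"] < config.raw_p_threshold)
        & (testable["p_b"] < config.raw_p_threshold)
        & consistent
    )
    if ledger is not None:
        ledger.record(
            "driver_ranking", "candidate_retention", len(testable),
            int(testable["retained"].sum()),
        )

    testable["degree"] = (
        testable["gene"].map(ppi_degree).fillna(0).astype(int)
    )
    testable["survival_coef"] = np.nan
    testable["survival_p"] = np.nan
    testable["survival_flag"] = False
    retained_idx = testable.index[testable["retained"]]
    for i in retained_idx:
        gene = testable.loc[i, "gene"]
        direction = testable.loc[i, "direction"]
        fit = cox_univariate(expr_b.loc[gene], survival_b)
        testable.loc[i, "survival_coef"] = fit["coef"]
        testable.loc[i, "survival_p"] = fit["p"]
        if fit["testable"] and fit["p"] < 0.05:
            # worse survival consistent with the event: overexpression of a
            # gained gene (coef > 0) or loss of expression of a lost gene
            # (coef < 0)
            if (direction == "gain" and fit["coef"] > 0) or (
                direction == "loss" and fit["coef"] < 0
            ):
                testable.loc[i, "survival_flag"] = True

    ranked = rank_candidates(testable[testable["retained"]])
    out = testable.merge(
        ranked[["gene", "arm", "direction", "rank"]],
        on=["gene", "arm", "direction"],
        how="left",
    )
    return out.sort_values(
        ["arm", "direction", "rank", "q"], na_position="last"
    ).reset_index(drop=True)


def bh_over(pvals: np.ndarray) -> np.ndarray:
    from .enrichment import bh_adjust

    return bh_adjust(pvals)


def top_candidates(ranked: pd.DataFrame, n: int = 3) -> pd.DataFrame:
    """Top-n retained candidates per region (summary-table layout)."""
    sel = ranked[ranked["retained"] & (ranked["rank"] <= n)]
    return sel.sort_values(["arm", "direction", "rank"]).reset_index(drop=True)
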