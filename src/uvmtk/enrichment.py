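"""Cohort enrichment of arm-level copy-number events.

Each (arm, direction) event observed at least once in either cohort is
tested for differential frequency with a two-tailed Fisher's exact test and
BH-corrected across all tested events as one family.  The two-sided rule
sums hypergeometric probabilities <= that of the observed table, matching
R's ``fisher.test``.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import PipelineConfig

__all__ = ["fisher_exact_2x2", "bh_adjust", "enrich_arm_events"]


def fisher_exact_2x2(table) -> float:
    """Two-tailed Fisher's exact p for a 2x2 table of non-negative ints.

    Degenerate tables (a zero row or column margin) return p = 1.
    """
    t = np.asarray(table)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any():
        raise ValueError("table entries must be non-negative")
    if not np.issubdtype(t.dtype, np.integer):
        if not np.allclose(t, np.round(t)):
            raise ValueError("table entries must be integers")
        t = np.round(t).astype(int)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        return 1.0
    return float(stats.fisher_exact(t, alternative="two-sided")[1])


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q values, input order preserved."""
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise ValueError("p values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def enrich_arm_events(
    events_a: pd.DataFrame,
    events_b: pd.DataFrame,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Test every observed (arm, direction) event for cohort enrichment.

    ``events_a`` / ``events_b`` are boolean sample x (arm, direction)
    matrices (cohort A is the metastatic cohort, B the reference).  Events
    never observed in either cohort are excluded from the test family.

    Returns a frame sorted by q with columns arm, direction, the 2x2
    counts, frequencies, log odds ratio (descriptive, Haldane-corrected),
    p, q, ``enriched`` flag and the cohort of higher frequency.
    """
    n_a, n_b = len(events_a), len(events_b)
    if n_a == 0 or n_b == 0:
        raise ValueError("no samples: both cohorts must be non-empty")
    common = events_a.columns.union(events_b.columns)
    rows = []
    for arm, direction in common:
        pres_a = int(events_a.get((arm, direction), pd.Series(dtype=bool)).sum())
        pres_b = int(events_b.get((arm, direction), pd.Series(dtype=bool)).sum())
        if pres_a == 0 and pres_b == 0:
            continue  # untestable: never observed in either dataset
        table = [[pres_a, n_a - pres_a], [pres_b, n_b - pres_b]]
        p = fisher_exact_2x2(table)
        log_or = float(
            np.log((pres_a + 0.5) * (n_b - pres_b + 0.5))
            - np.log((n_a - pres_a + 0.5) * (pres_b + 0.5))
        )
        rows.append(
            {
                "arm": arm,
                "direction": direction,
                "present_a": pres_a,
                "absent_a": n_a - pres_a,
                "present_b": pres_b,
                "absent_b": n_b - pres_b,
                "freq_a": pres_a / n_a,
                "freq_b": pres_b / n_b,
                "log_odds_ratio": log_or,
                "p": p,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "arm", "direction", "present_a", "absent_a", "present_b",
                "absent_b", "freq_a", "freq_b", "log_odds_ratio", "p", "q",
                "enriched", "enriched_in",
            ]
        )
    out = pd.DataFrame(rows)
    out["q"] = bh_adjust(out["p"].values)
    out["enriched"] = out["q"] < config.q_threshold
    out["enriched_in"] = np.where(
        out["freq_a"] >= out["freq_b"], "A", "B"
    )
    out.loc[~out["enriched"], "enriched_in"] = ""
    return out.sort_values(["q", "p", "arm", "direction"]).reset_index(drop=True)
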