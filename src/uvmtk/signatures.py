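"""96-channel mutation catalogs, signature refitting and strand bias.

A sample's somatic SNVs are collapsed to the standard 96-channel
trinucleotide spectrum (pyrimidine-reference convention), which is then
explained as a non-negative linear combination of reference signature
profiles by solving min ||S w - m||_2 subject to w >= 0.  Relative
contributions are w / sum(w).  Transcriptional strand asymmetry of a
mutation class is tested with the exact conditional form of the two-sample
Poisson rate comparison: a two-sided binomial test at p = 1/2 on the
(transcribed, untranscribed) count pair.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .config import PipelineConfig
from .ledger import FilterLedger

__all__ = [
    "CHANNELS_96",
    "SUBSTITUTIONS",
    "channel_of",
    "filter_for_signatures",
    "build_96_vector",
    "SignatureFit",
    "fit_signatures",
    "strand_bias_test",
    "strand_bias_table",
]

SUBSTITUTIONS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
_BASES = "ACGT"
_COMP = str.maketrans("ACGT", "TGCA")

#: Canonical channel order: substitution class major, then 5' flank, then 3'.
CHANNELS_96 = [
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
]
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS_96)}

_AUTOSOMES = {str(i) for i in range(1, 23)} | {f"chr{i}" for i in range(1, 23)}


def _revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def channel_of(ref: str, alt: str, tri_context: str) -> str:
    """Map an SNV to its pyrimidine-reference channel key.

    Purine-reference mutations are reverse-complemented: T[G>T]T becomes
    A[C>A]A.  The context's middle base must equal the reference base.
    """
    if len(tri_context) != 3 or tri_context[1] != ref:
        raise ValueError(f"context {tri_context!r} inconsistent with ref {ref!r}")
    if ref == alt or ref not in _BASES or alt not in _BASES:
        raise ValueError(f"invalid substitution {ref}>{alt}")
    if ref in "AG":
        tri_context = _revcomp(tri_context)
        ref = ref.translate(_COMP)
        alt = alt.translate(_COMP)
    return f"{tri_context[0]}[{ref}>{alt}]{tri_context[2]}"


def filter_for_signatures(
    variants: pd.DataFrame,
    config: PipelineConfig,
    ledger: FilterLedger | None = None,
) -> pd.DataFrame:
    """Retain SNVs usable for signature analysis.

    Keeps autosomal variants absent from population variant resources and
    with alt-allele read support >= ``min_allele_support`` (synonymous
    mutations are deliberately kept; the spectrum uses all somatic SNVs).
    """
    n0 = len(variants)
    auto = variants[variants["chrom"].astype(str).isin(_AUTOSOMES)]
    n1 = len(auto)
    not_pop = auto[~auto["population_flag"].astype(bool)]
    n2 = len(not_pop)
    supported = not_pop[not_pop["alt_support"] >= config.min_allele_support]
    n3 = len(supported)
    if ledger is not None:
        ledger.record("signatures", "autosomal", n0, n1)
        ledger.record("signatures", "population_resource", n1, n2)
        ledger.record("signatures", "allele_support", n2, n3)
    return supported.reset_index(drop=True)


def build_96_vector(snvs: pd.DataFrame) -> pd.Series:
    """Collapse SNVs to 96-channel counts (sums to the number of SNVs)."""
    counts = np.zeros(96, dtype=int)
    for ref, alt, ctx in zip(snvs["ref"], snvs["alt"], snvs["tri_context"]):
        counts[_CHANNEL_INDEX[channel_of(ref, alt, ctx)]] += 1
    return pd.Series(counts, index=CHANNELS_96, name="count")


@dataclass
class SignatureFit:
    """Non-negative signature refit of one catalog."""

    absolute: pd.Series   # estimated mutation counts per signature (>= 0)
    relative: pd.Series   # absolute / sum(absolute); sums to 1
    residual: float       # ||S w - m||_2

    def __post_init__(self) -> None:
        if (self.absolute < -1e-12).any():
            raise ValueError("negative contribution")


def fit_signatures(catalog_vector, signatures: pd.DataFrame) -> SignatureFit:
    """Refit a 96-channel catalog against reference signatures by NNLS.

    ``signatures`` is a 96 x K column-stochastic matrix; the catalog vector
    is reindexed to its channel order when labeled.  Raises on an empty
    catalog (no mutations to explain).
    """
    if isinstance(catalog_vector, pd.Series):
        m = catalog_vector.reindex(signatures.index).to_numpy(dtype=float)
        if np.isnan(m).any():
            raise ValueError("catalog channels do not match signature channels")
    else:
        m = np.asarray(catalog_vector, dtype=float)
    if m.shape[0] != signatures.shape[0]:
        raise ValueError("catalog/signature channel mismatch")
    if m.sum() <= 0:
        raise ValueError("empty catalog: no mutations to fit")
    w, rnorm = optimize.nnls(signatures.to_numpy(dtype=float), m)
    absolute = pd.Series(w, index=signatures.columns, name="absolute")
    total = absolute.sum()
    relative = absolute / total if total > 0 else absolute * 0.0
    return SignatureFit(
        absolute=absolute,
        relative=relative.rename("relative"),
        residual=float(rnorm),
    )


def summarize_contributions(
    fit: SignatureFit, display_threshold: float = 0.30
) -> pd.Series:
    """Summary view of a refit: contributions below the display threshold
    (30% by default) are suppressed; the full fit keeps every value."""
    rel = fit.relative
    return rel[rel >= display_threshold].sort_values(ascending=False)


def strand_bias_test(transcribed: int, untranscribed: int) -> float:
    """Two-sided exact test of equal mutation rates on the two strands.

    Conditional on the total, equal Poisson rates make the transcribed
    count Binomial(n, 1/2); the returned p is the exact two-sided binomial
    p value.  Returns NaN (untestable) when both counts are zero.
    """
    x, y = int(transcribed), int(untranscribed)
    if x < 0 or y < 0:
        raise ValueError("counts must be non-negative")
    n = x + y
    if n == 0:
        return float("nan")
    return float(stats.binomtest(x, n, 0.5).pvalue)


def strand_bias_table(
    variants: pd.DataFrame, by: str = "substitution"
) -> pd.DataFrame:
    """Strand-bias tests per mutation class, BH-adjusted across classes.

    Variants must carry ``gene_strand`` labels (transcribed / untranscribed
    / intergenic; intergenic sites are ignored).  ``by`` groups either by
    the six substitution classes or by 96-channel.
    """
    from .enrichment import bh_adjust

    sel = variants[variants["gene_strand"].isin(["transcribed", "untranscribed"])]
    if by == "substitution":
        keys = [
            channel_of(r, a, c)[2:5]
            for r, a, c in zip(sel["ref"], sel["alt"], sel["tri_context"])
        ]
    elif by == "channel":
        keys = [
            channel_of(r, a, c)
            for r, a, c in zip(sel["ref"], sel["alt"], sel["tri_context"])
        ]
    else:
        raise ValueError("by must be 'substitution' or 'channel'")
    grp = pd.DataFrame({"key": keys, "strand": sel["gene_strand"].values})
    rows = []
    for key, g in grp.groupby("key", sort=True):
        t = int((g["strand"] == "transcribed").sum())
        u = int((g["strand"] == "untranscribed").sum())
        rows.append({"class": key, "transcribed": t, "untranscribed": u,
                     "p": strand_bias_test(t, u)})
    out = pd.DataFrame(rows)
    if len(out):
        testable = out["p"].notna()
        out["q"] = np.nan
        out.loc[testable, "q"] = bh_adjust(out.loc[testable, "p"].values)
    return out
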