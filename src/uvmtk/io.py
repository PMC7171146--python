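"""Readers and writers for all on-disk formats.

All genomic intervals on disk are 1-based inclusive (the SEG convention);
the in-memory representation is 0-based half-open.  This module is the only
place the translation happens.

Formats
-------
segments        SEG-like TSV: sample, chrom, start, end, value
gene models     BED-like TSV: chrom, start, end, gene, arm, max_tx_len
count matrix    TSV, genes x samples, first column ``gene``
purity          TSV: sample, purity
survival        TSV: sample, time, event (event: 1 = death observed)
PPI degree      TSV: gene, degree
signatures      TSV: channel ("A[C>A]A"...) x signature columns
MAF-lite        TSV: sample, chrom, pos, ref, alt, tri_context,
                gene_strand, population_flag, alt_support
clonotypes      TSV: cell, clonotype, alpha_count, beta_count, ... extras
regions         TSV: arm, direction
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .cn import SegmentedProfile, to_log2

__all__ = [
    "SegDialect",
    "read_segments",
    "write_segments",
    "read_gene_models",
    "write_gene_models",
    "read_count_matrix",
    "write_count_matrix",
    "read_purity",
    "read_survival",
    "read_ppi_degree",
    "read_signature_matrix",
    "write_signature_matrix",
    "read_maf_lite",
    "write_maf_lite",
    "read_clonotypes",
    "write_clonotypes",
    "write_arm_events",
    "read_arm_events",
    "read_regions",
]


@dataclass(frozen=True)
class SegDialect:
    """How to interpret a segment file.

    ``value_type`` is "log2" (value is a log2 ratio relative to diploid) or
    "absolute" (value is an absolute copy number, converted with the
    per-sample zero-replacement rule of :func:`uvmtk.cn.to_log2`).
    Coordinates on disk are 1-based inclusive.
    """

    value_type: str = "log2"

    def __post_init__(self) -> None:
        if self.value_type not in ("log2", "absolute"):
            raise ValueError(f"unknown value_type {self.value_type!r}")


def read_segments(
    path: str | Path,
    dialect: SegDialect = SegDialect(),
    purity: pd.Series | None = None,
) -> list[SegmentedProfile]:
    """Read a SEG-like TSV into validated per-sample profiles.

    Overlapping segments within a sample or end < start raise a validation
    error naming the offending rows.  ``purity`` optionally attaches
    per-sample purity estimates.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    required = ["sample", "chrom", "start", "end", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = df["end"] < df["start"]
    if bad.any():
        raise ValueError(f"{path}: segment end < start at rows {list(df.index[bad])}")
    profiles = []
    for sample, grp in df.groupby("sample", sort=True):
        seg = pd.DataFrame(
            {
                "chrom": grp["chrom"].values,
                "start": grp["start"].values - 1,  # to 0-based half-open
                "end": grp["end"].values,
                "log2": (
                    to_log2(grp["value"].values)
                    if dialect.value_type == "absolute"
                    else grp["value"].values.astype(float)
                ),
            }
        )
        pur = None
        if purity is not None and sample in purity.index:
            pur = float(purity.loc[sample])
        profiles.append(SegmentedProfile(sample=str(sample), segments=seg, purity=pur))
    return profiles


def write_segments(
    profiles: list[SegmentedProfile], path: str | Path
) -> None:
    """Write profiles back to SEG-like TSV (log2 values, 1-based inclusive)."""
    frames = []
    for p in profiles:
        seg = p.segments
        frames.append(
            pd.DataFrame(
                {
                    "sample": p.sample,
                    "chrom": seg["chrom"],
                    "start": seg["start"] + 1,
                    "end": seg["end"],
                    "value": seg["log2"],
                }
            )
        )
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)


def read_gene_models(path: str | Path) -> pd.DataFrame:
    """Gene models with arm assignment and max mature transcript length."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    required = ["chrom", "start", "end", "gene", "arm", "max_tx_len"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if (df["end"] < df["start"]).any():
        raise ValueError(f"{path}: gene end < start")
    if (df["max_tx_len"] <= 0).any():
        raise ValueError(f"{path}: non-positive transcript length")
    out = df.copy()
    out["start"] = out["start"] - 1
    return out


def write_gene_models(genes: pd.DataFrame, path: str | Path) -> None:
    out = genes.copy()
    out["start"] = out["start"] + 1
    out.to_csv(path, sep="\t", index=False)


def read_count_matrix(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "gene"
    if df.isna().any().any():
        raise ValueError(f"{path}: missing values in count matrix")
    return df


def write_count_matrix(counts: pd.DataFrame, path: str | Path) -> None:
    out = counts.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")


def read_purity(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    s = df.set_index("sample")["purity"].astype(float)
    if ((s <= 0) | (s > 1)).any():
        raise ValueError(f"{path}: purity values must lie in (0, 1]")
    return s


def read_survival(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample": str})
    required = ["sample", "time", "event"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if (df["time"] < 0).any():
        raise ValueError(f"{path}: negative survival time")
    if not df["event"].isin([0, 1]).all():
        raise ValueError(f"{path}: event must be 0/1")
    return df.set_index("sample")


def read_ppi_degree(path: str | Path) -> pd.Series:
    df = pd.read_csv(path, sep="\t")
    return df.set_index("gene")["degree"].astype(int)


def read_signature_matrix(path: str | Path) -> pd.DataFrame:
    """96-channel x K signature probability matrix (COSMIC-style layout)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index.name = "channel"
    if (df.values < 0).any():
        raise ValueError(f"{path}: negative signature probability")
    sums = df.sum(axis=0)
    if not np.allclose(sums, 1.0, atol=1e-6):
        bad = list(sums.index[~np.isclose(sums, 1.0, atol=1e-6)])
        raise ValueError(f"{path}: signature columns do not sum to 1: {bad}")
    return df


def write_signature_matrix(sigs: pd.DataFrame, path: str | Path) -> None:
    out = sigs.copy()
    out.index.name = "channel"
    out.to_csv(path, sep="\t")


MAF_COLUMNS = [
    "sample", "chrom", "pos", "ref", "alt", "tri_context",
    "gene_strand", "population_flag", "alt_support",
]


def read_maf_lite(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample": str})
    missing = [c for c in MAF_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    df["population_flag"] = df["population_flag"].astype(bool)
    bad_ctx = df["tri_context"].str.len() != 3
    if bad_ctx.any():
        raise ValueError(f"{path}: malformed tri_context at rows {list(df.index[bad_ctx])}")
    mid = df["tri_context"].str[1]
    if (mid != df["ref"]).any():
        raise ValueError(f"{path}: tri_context middle base does not match ref")
    return df


def write_maf_lite(variants: pd.DataFrame, path: str | Path) -> None:
    variants[MAF_COLUMNS].to_csv(path, sep="\t", index=False)


def read_clonotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"cell": str, "clonotype": str})
    required = ["cell", "clonotype", "alpha_count", "beta_count"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    if (df[["alpha_count", "beta_count"]] < 0).any().any():
        raise ValueError(f"{path}: negative chain count")
    return df


def write_clonotypes(table: pd.DataFrame, path: str | Path) -> None:
    table.to_csv(path, sep="\t", index=False)


def write_arm_events(events: pd.DataFrame, path: str | Path) -> None:
    """Boolean sample x (arm, direction) matrix, columns flattened to
    ``arm:direction``."""
    out = events.copy()
    out.columns = [f"{arm}:{direction}" for arm, direction in out.columns]
    out.astype(int).to_csv(path, sep="\t")


def read_arm_events(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0)
    cols = pd.MultiIndex.from_tuples(
        [tuple(c.split(":", 1)) for c in df.columns],
        names=["arm", "direction"],
    )
    df.columns = cols
    return df.astype(bool)


def read_regions(path: str | Path) -> pd.DataFrame:
    """Recurrent broad-event region list: columns arm, direction."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ["arm", "direction"] if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    bad = ~df["direction"].isin(["gain", "loss"])
    if bad.any():
        raise ValueError(f"{path}: direction must be gain/loss")
    return df
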