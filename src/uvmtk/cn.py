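"""Gene-level copy-number status and arm-level event calling.

A segmented copy-number profile is reduced in three steps:

1. ``gene_copy_status`` maps each gene to the signed log2 ratio of the
   overlapping segment with the largest absolute log2 (genes not covered by
   any segment are flagged missing and excluded downstream).
2. ``filter_changes`` removes changes that are too shallow (|log2| below a
   threshold, default 0.2 relative to diploid) or too narrow (width below a
   fraction, default one half, of the shortest autosome arm) to count as
   arm-level events.
3. ``call_arm_events`` turns retained changes into a per-sample boolean
   matrix over (arm, direction) event units; chromosome 3 is treated as a
   single unit because its recurrent events span the whole chromosome.

All coordinates are 0-based half-open internally; the readers/writers in
:mod:`uvmtk.io` translate from the 1-based inclusive on-disk convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import PipelineConfig
from .genome import GenomeModel
from .ledger import FilterLedger

__all__ = [
    "SegmentedProfile",
    "gene_copy_status",
    "to_log2",
    "recenter",
    "filter_changes",
    "call_arm_events",
]

SEGMENT_COLUMNS = ["chrom", "start", "end", "log2"]


@dataclass
class SegmentedProfile:
    """Per-sample genomic segments with log2 copy ratios.

    ``segments`` has columns chrom, start, end (0-based half-open) and
    log2 (ratio relative to diploid).  Segments must be sorted and
    non-overlapping within each chromosome.
    """

    sample: str
    segments: pd.DataFrame
    purity: float | None = None
    ploidy: float | None = None

    def __post_init__(self) -> None:
        seg = self.segments.reset_index(drop=True)
        missing = [c for c in SEGMENT_COLUMNS if c not in seg.columns]
        if missing:
            raise ValueError(f"sample {self.sample}: missing columns {missing}")
        seg = seg[SEGMENT_COLUMNS].copy()
        bad = seg["end"] <= seg["start"]
        if bad.any():
            raise ValueError(
                f"sample {self.sample}: segment end <= start at rows "
                f"{list(seg.index[bad])}"
            )
        if not np.isfinite(seg["log2"]).all():
            raise ValueError(f"sample {self.sample}: non-finite log2 value")
        seg = seg.sort_values(["chrom", "start"], kind="mergesort").reset_index(drop=True)
        for chrom, grp in seg.groupby("chrom", sort=False):
            overlap = grp["start"].values[1:] < grp["end"].values[:-1]
            if overlap.any():
                rows = grp.index[1:][overlap]
                raise ValueError(
                    f"sample {self.sample}: overlapping segments on {chrom} "
                    f"at rows {list(rows)}"
                )
        if self.purity is not None and not 0 < self.purity <= 1:
            raise ValueError(f"sample {self.sample}: purity must be in (0, 1]")
        self.segments = seg

    def validate_chromosomes(self, genome: GenomeModel) -> None:
        unknown = set(self.segments["chrom"]) - set(genome.chrom_lengths)
        if unknown:
            raise ValueError(
                f"sample {self.sample}: unknown chromosome(s) {sorted(unknown)}"
            )


def to_log2(copy_values: np.ndarray) -> np.ndarray:
    """Convert absolute copy numbers to log2 ratios relative to diploid.

    Zeros are replaced by the smallest observed non-zero copy value of the
    same sample before taking ``log2(value / 2)``, so homozygous deletions
    stay finite.

    Raises
    ------
    ValueError
        If any value is negative or all values are zero.
    """
    values = np.asarray(copy_values, dtype=float)
    if (values < 0).any():
        raise ValueError("copy values must be non-negative")
    nonzero = values[values > 0]
    if nonzero.size == 0:
        raise ValueError("all copy values are zero; cannot form log2 ratios")
    floor = nonzero.min()
    return np.log2(np.where(values == 0, floor, values) / 2.0)


def recenter(profile: SegmentedProfile, offset: float) -> SegmentedProfile:
    """Shift every segment's log2 value by a manual per-sample offset.

    Some segmentation profiles deviate globally from the diploid baseline
    (variable coverage, platform differences); re-centering subtracts the
    estimated global shift.  The offset is supplied manually — automated
    re-centering rules are deliberately not implemented.
    """
    seg = profile.segments.copy()
    seg["log2"] = seg["log2"] - float(offset)
    return SegmentedProfile(
        sample=profile.sample, segments=seg,
        purity=profile.purity, ploidy=profile.ploidy,
    )


def gene_copy_status(
    profile: SegmentedProfile, genes: pd.DataFrame
) -> pd.Series:
    """Signed log2 status per gene for one sample.

    For every gene overlapped by at least one segment, returns the *signed*
    log2 of the overlapping segment with the largest |log2|.  Ties between
    +x and -x are broken toward the segment covering more of the gene, then
    toward the loss, so the result is deterministic.  Genes with no
    overlapping segment are NaN (flagged missing; dropped downstream).

    ``genes`` needs columns gene, chrom, start, end (0-based half-open).
    """
    out = pd.Series(np.nan, index=genes["gene"].values, name=profile.sample)
    seg_by_chrom = dict(tuple(profile.segments.groupby("chrom", sort=False)))
    for chrom, grp in genes.groupby("chrom", sort=False):
        seg = seg_by_chrom.get(chrom)
        if seg is None:
            continue
        gs = grp["start"].to_numpy()[:, None]
        ge = grp["end"].to_numpy()[:, None]
        ss = seg["start"].to_numpy()[None, :]
        se = seg["end"].to_numpy()[None, :]
        cover = np.maximum(
            np.minimum(ge, se) - np.maximum(gs, ss), 0
        )  # bp of overlap, genes x segments
        log2 = seg["log2"].to_numpy()[None, :]
        overlaps = cover > 0
        # lexicographic preference: |log2| desc, coverage desc, loss first
        key = np.where(
            overlaps,
            np.abs(log2)
            + 1e-12 * cover / max(1, int(cover.max() or 1))
            + 1e-15 * (log2 < 0),
            -np.inf,
        )
        best = np.argmax(key, axis=1)
        has = overlaps.any(axis=1)
        vals = seg["log2"].to_numpy()[best]
        out.loc[grp.loc[has, "gene"].values] = vals[has]
    return out


def gene_copy_matrix(
    profiles: list[SegmentedProfile], genes: pd.DataFrame
) -> pd.DataFrame:
    """genes x samples matrix of signed log2 statuses (NaN = missing)."""
    cols = {p.sample: gene_copy_status(p, genes) for p in profiles}
    return pd.DataFrame(cols)


def filter_changes(
    profile: SegmentedProfile,
    genome: GenomeModel,
    config: PipelineConfig,
    ledger: FilterLedger | None = None,
) -> pd.DataFrame:
    """Retain copy-number changes that qualify as arm-level events.

    A change (any segment with log2 != 0) is kept when |log2| >=
    ``min_abs_log2`` and its width >= ``min_width_fraction`` x the shortest
    autosome arm.  Idempotent: the retained set passes the filter unchanged.
    """
    min_width = config.min_width_fraction * genome.shortest_arm_length()
    seg = profile.segments
    changes = seg[seg["log2"] != 0.0]
    amp_ok = changes["log2"].abs() >= config.min_abs_log2
    width_ok = (changes["end"] - changes["start"]) >= min_width
    retained = changes[amp_ok & width_ok].reset_index(drop=True)
    if ledger is not None:
        ledger.record(
            "cn_events", f"{profile.sample}:amplitude", len(changes),
            int(amp_ok.sum()),
        )
        ledger.record(
            "cn_events", f"{profile.sample}:width", int(amp_ok.sum()),
            len(retained),
        )
    return retained


def call_arm_events(
    profiles: list[SegmentedProfile],
    genome: GenomeModel,
    config: PipelineConfig,
    ledger: FilterLedger | None = None,
) -> pd.DataFrame:
    """Per-sample arm-level gain/loss calls.

    Returns a boolean DataFrame indexed by sample with a MultiIndex column
    (arm, direction).  A sample carries (arm, direction) when at least one
    retained change of that direction overlaps the arm unit by more than
    ``arm_cover_fraction`` of the arm length (default 0, i.e. any overlap).
    Only autosomes are considered; chromosome units configured as whole
    chromosomes (chromosome 3 by default) yield one event unit.
    """
    arms = genome.arms()
    arms = arms[arms["chrom"].isin(genome.autosomes())]
    units = list(arms.itertuples(index=False))
    columns = pd.MultiIndex.from_tuples(
        [(u.arm, d) for u in units for d in ("gain", "loss")],
        names=["arm", "direction"],
    )
    mat = pd.DataFrame(
        False, index=[p.sample for p in profiles], columns=columns
    )
    mat.index.name = "sample"
    units_by_chrom: dict[str, list] = {}
    for u in units:
        units_by_chrom.setdefault(u.chrom, []).append(u)
    for profile in profiles:
        profile.validate_chromosomes(genome)
        retained = filter_changes(profile, genome, config, ledger=ledger)
        for chrom, on_chrom in retained.groupby("chrom", sort=False):
            starts = on_chrom["start"].to_numpy()
            ends = on_chrom["end"].to_numpy()
            log2 = on_chrom["log2"].to_numpy()
            for u in units_by_chrom.get(str(chrom), []):
                cover = np.clip(
                    np.minimum(ends, u.end) - np.maximum(starts, u.start),
                    0, None,
                )
                if config.arm_cover_fraction > 0:
                    hit = cover >= config.arm_cover_fraction * u.length
                else:
                    hit = cover > 0
                if (hit & (log2 > 0)).any():
                    mat.loc[profile.sample, (u.arm, "gain")] = True
                if (hit & (log2 < 0)).any():
                    mat.loc[profile.sample, (u.arm, "loss")] = True
    return mat


def event_amplitudes(
    profiles: list[SegmentedProfile],
    genome: GenomeModel,
    config: PipelineConfig,
) -> pd.DataFrame:
    """Mean |log2| of retained changes supporting each called event."""
    records = []
    arms = genome.arms()
    arms = arms[arms["chrom"].isin(genome.autosomes())]
    for profile in profiles:
        retained = filter_changes(profile, genome, config)
        for u in arms.itertuples(index=False):
            on = retained[retained["chrom"] == u.chrom]
            on = on[(on["start"] < u.end) & (on["end"] > u.start)]
            for direction, sel in (
                ("gain", on[on["log2"] > 0]),
                ("loss", on[on["log2"] < 0]),
            ):
                if len(sel):
                    records.append(
                        (profile.sample, u.arm, direction,
                         float(sel["log2"].abs().mean()))
                    )
    return pd.DataFrame(
        records, columns=["sample", "arm", "direction", "mean_abs_log2"]
    )
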