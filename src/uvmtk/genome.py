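"""Chromosome-arm geometry.

Arm-level copy-number analysis needs, for every chromosome, the centromere
position that splits it into a p and a q arm, and the arm lengths that the
segment-width filter references (changes narrower than a fraction of the
shortest arm are discarded as focal noise).  A GRCh37 arm table is built in;
any organism or assembly can be supplied as a plain table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

__all__ = ["GenomeModel", "grch37_genome"]

# GRCh37 chromosome lengths and approximate centromere midpoints (bp),
# from the UCSC cytoband/gap tables.
_GRCH37 = [
    # chrom, length, centromere
    ("1", 249_250_621, 125_000_000),
    ("2", 243_199_373, 93_300_000),
    ("3", 198_022_430, 91_000_000),
    ("4", 191_154_276, 50_400_000),
    ("5", 180_915_260, 48_400_000),
    ("6", 171_115_067, 61_000_000),
    ("7", 159_138_663, 59_900_000),
    ("8", 146_364_022, 45_600_000),
    ("9", 141_213_431, 49_000_000),
    ("10", 135_534_747, 40_200_000),
    ("11", 135_006_516, 53_700_000),
    ("12", 133_851_895, 35_800_000),
    ("13", 115_169_878, 17_900_000),
    ("14", 107_349_540, 17_600_000),
    ("15", 102_531_392, 19_000_000),
    ("16", 90_354_753, 36_600_000),
    ("17", 81_195_210, 24_000_000),
    ("18", 78_077_248, 17_200_000),
    ("19", 59_128_983, 26_500_000),
    ("20", 63_025_520, 27_500_000),
    ("21", 48_129_895, 13_200_000),
    ("22", 51_304_566, 14_700_000),
    ("X", 155_270_560, 60_600_000),
    ("Y", 59_373_566, 12_500_000),
]

_AUTOSOMES = {str(i) for i in range(1, 23)}


@dataclass
class GenomeModel:
    """Arm decomposition of a genome.

    Parameters
    ----------
    chrom_lengths
        Mapping chromosome name -> length in bp.
    centromeres
        Mapping chromosome name -> centromere midpoint in bp.  The p arm is
        ``[0, centromere)`` and the q arm ``[centromere, length)`` in the
        internal 0-based half-open convention.
    whole_chrom_units
        Chromosomes treated as a single event unit instead of two arms
        (recurrent events on chromosome 3 in uveal melanoma span the whole
        chromosome, so both arms are collapsed into one unit named "3").
    """

    chrom_lengths: dict[str, int]
    centromeres: dict[str, int]
    whole_chrom_units: frozenset[str] = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        missing = set(self.chrom_lengths) - set(self.centromeres)
        if missing:
            raise ValueError(f"centromere position missing for: {sorted(missing)}")
        for chrom, length in self.chrom_lengths.items():
            cen = self.centromeres[chrom]
            if not (0 < cen < length):
                raise ValueError(
                    f"chromosome {chrom}: centromere {cen} outside (0, {length})"
                )

    # -- basic queries -----------------------------------------------------

    @property
    def chrom_names(self) -> list[str]:
        return list(self.chrom_lengths)

    def autosomes(self) -> list[str]:
        return [c for c in self.chrom_lengths if c in _AUTOSOMES]

    def arm_names(self, chrom: str) -> list[str]:
        """Event-unit names for a chromosome ("3" or ["3p", "3q"])."""
        if chrom in self.whole_chrom_units:
            return [chrom]
        return [chrom + "p", chrom + "q"]

    def arms(self) -> pd.DataFrame:
        """All event units as a table (arm, chrom, start, end, length).

        Coordinates are 0-based half-open.  For whole-chromosome units the
        single row spans the full chromosome.
        """
        rows = []
        for chrom, length in self.chrom_lengths.items():
            cen = self.centromeres[chrom]
            if chrom in self.whole_chrom_units:
                rows.append((chrom, chrom, 0, length))
            else:
                rows.append((chrom + "p", chrom, 0, cen))
                rows.append((chrom + "q", chrom, cen, length))
        df = pd.DataFrame(rows, columns=["arm", "chrom", "start", "end"])
        df["length"] = df["end"] - df["start"]
        return df

    def arm_interval(self, arm: str) -> tuple[str, int, int]:
        """(chrom, start, end) of an event unit, 0-based half-open."""
        table = self.arms().set_index("arm")
        if arm not in table.index:
            raise KeyError(f"unknown arm {arm!r}")
        row = table.loc[arm]
        return str(row["chrom"]), int(row["start"]), int(row["end"])

    def shortest_arm_length(self, autosomes_only: bool = True) -> int:
        """Length of the shortest p/q arm (always computed on true arms,
        even for chromosomes collapsed to whole-chromosome event units)."""
        best = None
        for chrom, length in self.chrom_lengths.items():
            if autosomes_only and chrom not in _AUTOSOMES:
                continue
            cen = self.centromeres[chrom]
            for arm_len in (cen, length - cen):
                if best is None or arm_len < best:
                    best = arm_len
        if best is None:
            raise ValueError("genome has no autosomes")
        return best


def grch37_genome(whole_chrom_3: bool = True) -> GenomeModel:
    """The built-in GRCh37 arm model.

    ``whole_chrom_3=True`` collapses chromosome 3 into a single event unit,
    matching how monosomy 3 presents in uveal melanoma (events span the
    entire chromosome rather than one arm).
    """
    lengths = {c: n for c, n, _ in _GRCH37}
    cens = {c: cen for c, _, cen in _GRCH37}
    units = frozenset({"3"}) if whole_chrom_3 else frozenset()
    return GenomeModel(chrom_lengths=lengths, centromeres=cens, whole_chrom_units=units)
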