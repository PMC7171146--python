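"""Mutant peptide window construction and neoantigen candidate filtering.

For each missense mutation a 17-mer peptide window centered on the mutant
residue is built (truncated, not padded, at protein termini) and scanned
into all 9-mers containing the mutant position.  Binding predictions and
transcript expression are inputs; retained candidates have predicted
affinity strictly below 500 nM and come from expressed transcripts.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .config import PipelineConfig
from .ledger import FilterLedger

__all__ = ["PeptideWindows", "build_windows", "filter_candidates", "count_per_sample"]

_AA = set("ACDEFGHIKLMNPQRSTVWY")


@dataclass
class PeptideWindows:
    window: str            # mutant peptide window (<= window_size residues)
    mutant_offset: int     # 0-based position of the mutant residue in window
    epitopes: list[str]    # all 9-mers containing the mutant residue


def build_windows(
    protein_seq: str,
    mutant_pos: int,
    mutant_aa: str,
    consequence: str = "missense",
    window_size: int = 17,
    epitope_length: int = 9,
) -> PeptideWindows:
    """Construct the mutant window and its epitope-length substrings.

    ``mutant_pos`` is 1-based within ``protein_seq``.  Only simple amino
    acid substitutions are accepted; synonymous, stop-gain and frameshift
    consequences are rejected with a reason.  An interior mutation (at
    least ``epitope_length - 1`` residues from both termini) yields exactly
    ``epitope_length`` epitopes.
    """
    if consequence != "missense":
        raise ValueError(
            f"rejected: consequence {consequence!r} is not a simple substitution"
        )
    if window_size % 2 == 0 or window_size < epitope_length:
        raise ValueError("window_size must be odd and >= epitope_length")
    if not 1 <= mutant_pos <= len(protein_seq):
        raise ValueError(
            f"mutant position {mutant_pos} outside protein of length {len(protein_seq)}"
        )
    if mutant_aa not in _AA:
        raise ValueError(f"invalid mutant residue {mutant_aa!r}")
    if protein_seq[mutant_pos - 1] == mutant_aa:
        raise ValueError("rejected: mutant residue equals reference (synonymous)")
    flank = window_size // 2
    lo = max(0, mutant_pos - 1 - flank)
    hi = min(len(protein_seq), mutant_pos + flank)
    mutated = (
        protein_seq[: mutant_pos - 1] + mutant_aa + protein_seq[mutant_pos:]
    )
    window = mutated[lo:hi]
    offset = mutant_pos - 1 - lo
    epitopes = [
        window[i : i + epitope_length]
        for i in range(0, len(window) - epitope_length + 1)
        if i <= offset < i + epitope_length
    ]
    return PeptideWindows(window=window, mutant_offset=offset, epitopes=epitopes)


def filter_candidates(
    candidates: pd.DataFrame,
    config: PipelineConfig,
    ledger: FilterLedger | None = None,
) -> pd.DataFrame:
    """Apply the binding and expression filters to peptide candidates.

    Keeps rows with ``affinity_nM`` strictly below the cutoff (500 nM by
    default) and ``expression`` strictly above ``min_expression`` (zero by
    default, i.e. any expressed transcript).  Idempotent and row-order
    independent.
    """
    required = ["affinity_nM", "expression"]
    missing = [c for c in required if c not in candidates.columns]
    if missing:
        raise ValueError(f"candidates missing columns {missing}")
    if (candidates["affinity_nM"] <= 0).any():
        raise ValueError("affinity must be positive")
    n0 = len(candidates)
    bound = candidates[candidates["affinity_nM"] < config.affinity_cutoff_nM]
    n1 = len(bound)
    expressed = bound[bound["expression"] > config.min_expression]
    if ledger is not None:
        ledger.record("neoantigen", "affinity", n0, n1)
        ledger.record("neoantigen", "expression", n1, len(expressed))
    return expressed.reset_index(drop=True)


def count_per_sample(retained: pd.DataFrame) -> pd.Series:
    """Retained neoantigen candidates per sample."""
    if "sample" not in retained.columns:
        raise ValueError("candidates need a 'sample' column")
    return retained.groupby("sample").size().rename("n_candidates")
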