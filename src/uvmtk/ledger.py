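"""Filter ledger: rows in / rows out for every filtering step.

Each analysis stage records how many records entered and survived each
filter, so a run can be audited without re-executing it.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd

__all__ = ["FilterLedger"]


class FilterLedger:
    def __init__(self) -> None:
        self._rows: list[tuple[str, str, int, int]] = []

    def record(self, stage: str, filter_name: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError(f"{stage}/{filter_name}: n_out {n_out} > n_in {n_in}")
        self._rows.append((stage, filter_name, int(n_in), int(n_out)))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self._rows, columns=["stage", "filter", "n_in", "n_out"]
        )

    def write(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    def __len__(self) -> int:
        return len(self._rows)

    def __repr__(self) -> str:
        return f"FilterLedger({len(self._rows)} entries)"
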