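"""Enzyme-assay arithmetic with detection-limit censoring.

Converts reaction rates measured in cell extracts into specific
activities (amount per minute per mg protein) and applies the assay's
detection limit: readings below it are reported as "< limit" rather than
as numbers, matching the reporting convention for Rubisco activities
(detection limit 0.2 nmol CO2/min/mg protein) and PRK activities
(micromol/min/mg protein).  Raw-signal processing (absorbance slopes,
scintillation counts) is out of scope; inputs are rates.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .errors import RubifluxError, SchemaError

__all__ = ["AssayResult", "specific_activity", "read_assay_table", "format_assay_report"]

ASSAY_COLUMNS = ["enzyme", "rate", "protein", "lod"]


@dataclass(frozen=True)
class AssayResult:
    """Specific activity of one enzyme measurement.

    ``specific_activity`` and ``detection_limit`` share whatever
    amount-per-minute unit the rate was supplied in, normalized per mg
    protein.  ``censored`` marks readings below the detection limit,
    reported as ``"< lod"``.
    """

    enzyme: str
    specific_activity: float
    detection_limit: float
    censored: bool

    def __post_init__(self) -> None:
        if self.detection_limit <= 0:
            raise RubifluxError("detection_limit must be positive")
        if self.specific_activity < 0:
            raise RubifluxError("specific_activity must be non-negative")

    def __str__(self) -> str:
        if self.censored:
            return f"< {self.detection_limit:g}"
        return f"{self.specific_activity:g}"


def specific_activity(
    rate: float, protein: float, lod: float, enzyme: str = ""
) -> AssayResult:
    """Specific activity = rate / protein, censored below the detection limit.

    ``rate`` in amount per minute, ``protein`` in mg, ``lod`` in the same
    units as the resulting activity.  Censoring is monotone: any reading
    at or below a censored one is censored too.
    """
    if protein <= 0:
        raise RubifluxError("protein amount must be positive")
    if rate < 0:
        raise RubifluxError("rate must be non-negative")
    activity = rate / protein
    return AssayResult(
        enzyme=enzyme,
        specific_activity=activity,
        detection_limit=lod,
        censored=activity < lod,
    )


def read_assay_table(path: str | Path) -> list[AssayResult]:
    """Read (enzyme, rate, protein, lod) rows from a TSV file."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ASSAY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    results = []
    for i, row in df.iterrows():
        try:
            results.append(
                specific_activity(
                    float(row["rate"]), float(row["protein"]), float(row["lod"]),
                    enzyme=str(row["enzyme"]),
                )
            )
        except (ValueError, RubifluxError) as exc:
            raise SchemaError(f"{path}: line {i + 2}: {exc}") from None
    return results


def format_assay_report(results: Sequence[AssayResult]) -> str:
    """Plain-text report, one ``enzyme<TAB>activity`` line per measurement."""
    lines = ["enzyme\tspecific_activity"]
    lines += [f"{r.enzyme}\t{r}" for r in results]
    return "\n".join(lines) + "\n"
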