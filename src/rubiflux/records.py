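"""Fermentation observations and derived summaries, plus their TSV schemas.

Raw records hold concentrations *as measured in the broth*; all
corrections (ethanol evaporation, unit conversions) belong to the
analysis layer.  Tables are tab-separated with a fixed, documented header
and are validated with line-numbered error messages.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .errors import RubifluxError, SchemaError

__all__ = [
    "ChemostatRecord",
    "BatchTimeSeries",
    "YieldSet",
    "ComparisonResult",
    "GrowthFit",
    "read_chemostat_table",
    "write_chemostat_table",
    "read_batch_table",
    "write_batch_table",
    "CHEMOSTAT_COLUMNS",
    "BATCH_COLUMNS",
]

CHEMOSTAT_COLUMNS = [
    "replicate_id",
    "dilution_rate",
    "glucose_in",
    "galactose_in",
    "glucose_residual",
    "galactose_residual",
    "biomass",
    "ethanol",
    "glycerol",
    "gas_flow",
    "co2_in",
    "co2_out",
]

BATCH_COLUMNS = ["replicate_id", "time", "biomass", "sugar", "ethanol", "glycerol"]


@dataclass(frozen=True)
class ChemostatRecord:
    """One steady state of an anaerobic, sugar-limited chemostat.

    Concentrations in g/l as measured; ``gas_flow`` in litres of sparging
    gas per hour per litre of broth; ``co2_in``/``co2_out`` as volume
    fractions of the inlet and outlet gas.
    """

    dilution_rate: float  # 1/h
    glucose_in: float
    galactose_in: float
    glucose_residual: float
    galactose_residual: float
    biomass: float
    ethanol: float
    glycerol: float
    gas_flow: float
    co2_in: float
    co2_out: float
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        if self.dilution_rate <= 0:
            raise RubifluxError("dilution_rate must be positive")
        for name in (
            "glucose_in", "galactose_in", "glucose_residual", "galactose_residual",
            "biomass", "ethanol", "glycerol", "gas_flow",
        ):
            if getattr(self, name) < 0:
                raise RubifluxError(f"{name} must be non-negative")
        if self.glucose_residual > self.glucose_in:
            raise RubifluxError("residual glucose exceeds inlet glucose")
        if self.galactose_residual > self.galactose_in:
            raise RubifluxError("residual galactose exceeds inlet galactose")
        for name in ("co2_in", "co2_out"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise RubifluxError(f"{name} must be a volume fraction in [0, 1]")

    @property
    def sugar_consumed(self) -> float:
        """Total hexose consumed, g/l of feed."""
        return (self.glucose_in - self.glucose_residual) + (
            self.galactose_in - self.galactose_residual
        )


@dataclass(frozen=True)
class BatchTimeSeries:
    """Sampled trajectory of an anaerobic batch culture (g/l vs h)."""

    time: np.ndarray
    biomass: np.ndarray
    sugar: np.ndarray
    ethanol: np.ndarray
    glycerol: np.ndarray
    replicate_id: str = "r1"

    def __post_init__(self) -> None:
        arrays = {
            "time": np.asarray(self.time, dtype=float),
            "biomass": np.asarray(self.biomass, dtype=float),
            "sugar": np.asarray(self.sugar, dtype=float),
            "ethanol": np.asarray(self.ethanol, dtype=float),
            "glycerol": np.asarray(self.glycerol, dtype=float),
        }
        n = arrays["time"].size
        for name, arr in arrays.items():
            if arr.size != n:
                raise RubifluxError(f"{name} length differs from time length")
            object.__setattr__(self, name, arr)
        if n < 4:
            raise RubifluxError("a batch series needs at least 4 samples")
        if np.any(np.diff(arrays["time"]) <= 0):
            raise RubifluxError("time must be strictly increasing")

    def __len__(self) -> int:
        return self.time.size

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "replicate_id": self.replicate_id,
                "time": self.time,
                "biomass": self.biomass,
                "sugar": self.sugar,
                "ethanol": self.ethanol,
                "glycerol": self.glycerol,
            }
        )


@dataclass(frozen=True)
class YieldSet:
    """Yields on consumed sugar with optional replicate spread.

    ``y_biomass`` in g/g; ``y_ethanol`` and ``y_glycerol`` in mol per mol
    hexose.  ``spread`` holds the mean deviation across replicates per
    yield (the replicate summary convention is "average +/- mean
    deviation", not standard deviation).
    """

    y_biomass: float
    y_ethanol: float
    y_glycerol: float
    spread: dict = field(default_factory=dict)
    evaporation_corrected: bool = False
    n_replicates: int = 1

    def __post_init__(self) -> None:
        if min(self.y_biomass, self.y_ethanol, self.y_glycerol) < 0:
            raise RubifluxError("yields must be non-negative")
        if self.y_ethanol > 2.0 + 1e-9:
            raise RubifluxError("ethanol yield cannot exceed 2 mol/mol hexose")
        if self.y_glycerol > 2.0 + 1e-9:
            raise RubifluxError("glycerol yield cannot exceed 2 mol/mol hexose")

    def as_dict(self) -> dict:
        return {
            "y_biomass": self.y_biomass,
            "y_ethanol": self.y_ethanol,
            "y_glycerol": self.y_glycerol,
            "spread": dict(self.spread),
            "evaporation_corrected": self.evaporation_corrected,
            "n_replicates": self.n_replicates,
        }


@dataclass(frozen=True)
class ComparisonResult:
    """Per-yield percent changes between two strains with significance.

    ``percent_change`` maps yield name to the full-precision percent
    change; ``percent_change_rounded`` to the nearest-integer headline
    value; ``p_value`` to the two-sided equal-variance t-test p-value.
    ``undefined`` lists yields whose reference mean is zero.
    """

    percent_change: dict
    percent_change_rounded: dict
    p_value: dict
    significant: dict
    alpha: float
    undefined: tuple = ()

    def as_dict(self) -> dict:
        return {
            "percent_change": dict(self.percent_change),
            "percent_change_rounded": dict(self.percent_change_rounded),
            "p_value": dict(self.p_value),
            "significant": dict(self.significant),
            "alpha": self.alpha,
            "undefined": list(self.undefined),
        }


@dataclass(frozen=True)
class GrowthFit:
    """Log-linear growth-rate fit on a batch series."""

    mu_max: float  # 1/h
    lag_time: float  # h
    window: tuple  # (t_start, t_end) of the fitted samples
    r_squared: float
    n_points: int

    def __post_init__(self) -> None:
        if self.mu_max < 0:
            raise RubifluxError("mu_max must be non-negative")


# ---------------------------------------------------------------------------
# delimited I/O


def _validate_frame(df: pd.DataFrame, columns: Sequence[str], path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
    extra = [c for c in df.columns if c not in columns]
    if extra:
        raise SchemaError(f"{path}: unexpected columns {extra}")
    numeric = [c for c in columns if c != "replicate_id"]
    for col in numeric:
        values = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[values.isna()]
        if len(bad):
            # +2: one for the header row, one for 1-based numbering
            raise SchemaError(
                f"{path}: non-numeric value in column {col!r} at line {bad[0] + 2}"
            )
        df[col] = values


def read_chemostat_table(path: str | Path) -> list[ChemostatRecord]:
    """Read chemostat steady states (one row per record) from TSV."""
    df = pd.read_csv(path, sep="\t", dtype={"replicate_id": str})
    _validate_frame(df, CHEMOSTAT_COLUMNS, path)
    records = []
    for i, row in df.iterrows():
        try:
            records.append(
                ChemostatRecord(**{c: row[c] for c in CHEMOSTAT_COLUMNS if c != "replicate_id"},
                                replicate_id=str(row["replicate_id"]))
            )
        except RubifluxError as exc:
            raise SchemaError(f"{path}: line {i + 2}: {exc}") from None
    if not records:
        raise SchemaError(f"{path}: no data rows")
    return records


def write_chemostat_table(records: Sequence[ChemostatRecord], path: str | Path) -> None:
    df = pd.DataFrame([{c: getattr(r, c) for c in CHEMOSTAT_COLUMNS} for r in records])
    df.to_csv(path, sep="\t", index=False)


def read_batch_table(path: str | Path) -> list[BatchTimeSeries]:
    """Read batch time series (one row per time point, grouped by replicate)."""
    df = pd.read_csv(path, sep="\t", dtype={"replicate_id": str})
    _validate_frame(df, BATCH_COLUMNS, path)
    series = []
    for rid, group in df.groupby("replicate_id", sort=False):
        g = group.sort_values("time")
        try:
            series.append(
                BatchTimeSeries(
                    time=g["time"].to_numpy(),
                    biomass=g["biomass"].to_numpy(),
                    sugar=g["sugar"].to_numpy(),
                    ethanol=g["ethanol"].to_numpy(),
                    glycerol=g["glycerol"].to_numpy(),
                    replicate_id=str(rid),
                )
            )
        except RubifluxError as exc:
            raise SchemaError(f"{path}: replicate {rid!r}: {exc}") from None
    if not series:
        raise SchemaError(f"{path}: no data rows")
    return series


def write_batch_table(series: Sequence[BatchTimeSeries], path: str | Path) -> None:
    pd.concat([s.to_frame() for s in series], ignore_index=True).to_csv(
        path, sep="\t", index=False
    )
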