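"""Bioaccessibility from simulated-digestion measurements.

Bioaccessibility (BA) is the fraction of a compound released from the food
matrix into the digestive fluid during a standardized static in vitro
digestion and hence available for intestinal absorption.  It is computed
from the mass balance of the digest,

    BA(%) = 100 · (C_d · V_d) / (C_s · V_s)

with ``C_d`` the compound concentration in the digest supernatant (ng/mL),
``V_d`` the digestion-mixture volume (mL), ``C_s`` the spiked concentration
in the food (ng/mL) and ``V_s`` the food sample volume (mL).  Measured
digest concentrations are corrected for procedural-blank contamination
before the ratio is formed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "DigestionSample",
    "SpikedFood",
    "BlankBatch",
    "BAResult",
    "CorrectedConcentration",
    "blank_correct",
    "compute_ba",
    "summarize_ba",
    "ba_from_tables",
    "read_digestion_table",
    "read_blank_table",
]


@dataclass(frozen=True)
class DigestionSample:
    """One replicate digest measurement for a compound × food pair."""

    compound: str
    food: str
    c_d_ng_ml: float
    v_d_ml: float
    replicate: int = 1
    blank_batch: str = ""

    def __post_init__(self) -> None:
        if self.c_d_ng_ml < 0:
            raise ValueError(f"digest concentration must be >= 0, got {self.c_d_ng_ml!r}")
        if not self.v_d_ml > 0:
            raise ValueError(f"digest volume must be > 0, got {self.v_d_ml!r}")


@dataclass(frozen=True)
class SpikedFood:
    """The spiked food sample entering digestion (denominator of BA)."""

    compound: str
    food: str
    c_s_ng_ml: float = 100.0
    v_s_ml: float = 5.0

    def __post_init__(self) -> None:
        if not self.c_s_ng_ml > 0:
            raise ValueError(f"spike concentration must be > 0, got {self.c_s_ng_ml!r}")
        if not self.v_s_ml > 0:
            raise ValueError(f"sample volume must be > 0, got {self.v_s_ml!r}")


@dataclass(frozen=True)
class BlankBatch:
    """Per-compound procedural-blank concentrations for one analytical batch."""

    batch_id: str
    blanks_ng_ml: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for compound, value in self.blanks_ng_ml.items():
            if value < 0:
                raise ValueError(f"blank for {compound} must be >= 0, got {value!r}")

    def blank_for(self, compound: str) -> float:
        if compound not in self.blanks_ng_ml:
            warnings.warn(
                f"no blank recorded for {compound!r} in batch {self.batch_id!r}; "
                "treating as 0",
                stacklevel=3,
            )
            return 0.0
        return self.blanks_ng_ml[compound]


class CorrectedConcentration(NamedTuple):
    value: float
    floored: bool


def blank_correct(
    measured_ng_ml: float, batch: BlankBatch, compound: str
) -> CorrectedConcentration:
    """Subtract the batch's procedural blank, flooring at zero.

    Returns the corrected concentration and whether the floor was applied
    (a measurement at or below background).  The correction never increases
    a concentration.
    """
    if measured_ng_ml < 0:
        raise ValueError(f"measured concentration must be >= 0, got {measured_ng_ml!r}")
    corrected = measured_ng_ml - batch.blank_for(compound)
    if corrected < 0:
        return CorrectedConcentration(0.0, True)
    return CorrectedConcentration(corrected, False)


def compute_ba(sample: DigestionSample, spike: SpikedFood) -> float:
    """BA(%) = 100·(C_d·V_d)/(C_s·V_s); > 100 permitted but warned about."""
    ba = 100.0 * (sample.c_d_ng_ml * sample.v_d_ml) / (spike.c_s_ng_ml * spike.v_s_ml)
    if ba > 100.0:
        warnings.warn(
            f"bioaccessibility {ba:.2f}% exceeds 100% "
            f"({sample.compound}/{sample.food}; measurement noise?)",
            stacklevel=2,
        )
    return ba


@dataclass(frozen=True)
class BAResult:
    """Replicate-aggregated bioaccessibility for one compound × food pair."""

    compound: str
    food: str
    ba_percent: float
    ba_sd: float
    n: int

    def __post_init__(self) -> None:
        if self.ba_percent < 0 or self.ba_sd < 0:
            raise ValueError("ba_percent and ba_sd must be non-negative")


def summarize_ba(
    replicate_ba: Sequence[float], compound: str = "", food: str = ""
) -> BAResult:
    """Mean ± sample standard deviation over replicate BA values."""
    values = np.asarray(replicate_ba, dtype=float)
    if values.size == 0:
        raise ValueError("at least one replicate is required")
    sd = float(values.std(ddof=1)) if values.size > 1 else 0.0
    return BAResult(
        compound=compound,
        food=food,
        ba_percent=float(values.mean()),
        ba_sd=sd,
        n=int(values.size),
    )


# ---------------------------------------------------------------------------
# tabular pipeline
# ---------------------------------------------------------------------------

def read_digestion_table(path) -> pd.DataFrame:
    """Read digest measurements: one row per replicate.

    Columns: ``compound, food, replicate, c_d_ng_ml, v_d_ml, c_s_ng_ml,
    v_s_ml, blank_batch``.
    """
    df = pd.read_csv(path)
    required = {
        "compound", "food", "replicate", "c_d_ng_ml",
        "v_d_ml", "c_s_ng_ml", "v_s_ml", "blank_batch",
    }
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    return df


def read_blank_table(path) -> dict[str, BlankBatch]:
    """Read procedural blanks (columns ``batch, compound, blank_ng_ml``)."""
    df = pd.read_csv(path)
    required = {"batch", "compound", "blank_ng_ml"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    batches = {}
    for batch_id, group in df.groupby("batch"):
        batches[str(batch_id)] = BlankBatch(
            batch_id=str(batch_id),
            blanks_ng_ml=dict(zip(group["compound"], group["blank_ng_ml"])),
        )
    return batches


def ba_from_tables(
    digestion: pd.DataFrame,
    blanks: Mapping[str, BlankBatch] | None = None,
) -> pd.DataFrame:
    """Blank-correct and aggregate a digestion table into per-pair BA.

    Returns one row per compound × food with ``ba_percent, ba_sd, n`` and
    ``n_floored`` (replicates floored at zero during blank correction).
    """
    records = []
    for (compound, food), group in digestion.groupby(["compound", "food"], sort=True):
        per_rep = []
        n_floored = 0
        for row in group.itertuples(index=False):
            c_d = float(row.c_d_ng_ml)
            batch = blanks.get(str(row.blank_batch)) if blanks is not None else None
            if batch is not None and str(compound) in batch.blanks_ng_ml:
                corrected = blank_correct(c_d, batch, str(compound))
                c_d = corrected.value
                n_floored += int(corrected.floored)
            sample = DigestionSample(
                compound=str(compound),
                food=str(food),
                c_d_ng_ml=c_d,
                v_d_ml=float(row.v_d_ml),
                replicate=int(row.replicate),
                blank_batch=str(row.blank_batch),
            )
            spike = SpikedFood(
                compound=str(compound),
                food=str(food),
                c_s_ng_ml=float(row.c_s_ng_ml),
                v_s_ml=float(row.v_s_ml),
            )
            per_rep.append(compute_ba(sample, spike))
        result = summarize_ba(per_rep, compound=str(compound), food=str(food))
        records.append(
            {
                "compound": result.compound,
                "food": result.food,
                "ba_percent": result.ba_percent,
                "ba_sd": result.ba_sd,
                "n": result.n,
                "n_floored": n_floored,
            }
        )
    return pd.DataFrame.from_records(records)
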