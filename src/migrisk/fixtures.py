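"""Packaged reference tables from the source migration/exposure study.

Three delimited-text tables ship with the package:

``rfd_table1``
    Oral reference doses (ng/kg bw/day) per compound.
``migration_params_table2``
    Fitted migration parameters (α, K_P/F, D, R²) for 5 compounds × 9 foods.
``edi_table3``
    Estimated daily intake (ng/kg bw/day) and the printed hazard quotient
    per compound × food for median and 95th-percentile consumption.

Values are preserved exactly as printed.  Known internal inconsistencies of
the printed exposure table are attached to the returned frame as errata
metadata (``df.attrs["errata"]``) and are never silently repaired; only the
self-consistent food blocks listed in :data:`ANCHOR_FOODS` should be used
as quantitative anchors.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

__all__ = ["FIXTURE_NAMES", "ANCHOR_FOODS", "load_fixture"]

FIXTURE_NAMES = ("rfd_table1", "migration_params_table2", "edi_table3")

#: foods whose printed EDI and HQ columns are mutually consistent
ANCHOR_FOODS = ("Eastern leaf", "Jasmine tea")

_EDI_TABLE_ERRATA = [
    "HQ columns are row-permuted against the EDI columns for three food "
    "pairs: Vinegar<->Soy milk, Beer<->Baijiu, Cooking wine<->Coconut milk "
    "(each printed HQ equals the other food's EDI/RfD).",
    "Soda water / TPhP / median: printed HQ 1.06e-4 is an exponent typo "
    "for EDI/RfD = 74.49/70000 = 1.06e-3.",
    "Narrative describing soy/coconut milk as highest-EDI foods matches the "
    "permuted ordering, not the printed EDI rows.",
    "Only the Eastern leaf and Jasmine tea blocks are fully self-consistent "
    "(recomputed HQ = EDI/RfD within printing precision for every row).",
]


def _read_packaged_csv(filename: str) -> pd.DataFrame:
    ref = resources.files("migrisk.data").joinpath(filename)
    with ref.open("r", encoding="utf-8") as handle:
        return pd.read_csv(handle)


def load_fixture(name: str) -> pd.DataFrame:
    """Load one packaged reference table by name.

    Returns a DataFrame with the printed values verbatim; for the exposure
    table the documented erratum list is attached as ``df.attrs["errata"]``.
    """
    if name == "rfd_table1":
        return _read_packaged_csv("rfd_table1.csv")
    if name == "migration_params_table2":
        return _read_packaged_csv("migration_params_table2.csv")
    if name == "edi_table3":
        df = _read_packaged_csv("edi_table3.csv")
        df.attrs["errata"] = list(_EDI_TABLE_ERRATA)
        df.attrs["anchor_foods"] = list(ANCHOR_FOODS)
        return df
    raise KeyError(f"unknown fixture {name!r}; available: {FIXTURE_NAMES}")
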