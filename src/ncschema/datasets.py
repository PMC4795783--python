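"""Packaged measurement fixture for the GH5 cellulase chimera study.

The table lists the two parents (P1 = GsCelA catalytic core, P2 = BsCel5A
catalytic core), the eight sampled chimeras C1–C8, and the five
model-designed chimeras C9–C13, with their 8-block parent-choice codes,
SCHEMA E and m, measured T50 and TA50 (°C, ± one s.d.) and relative specific
activity A_re (P2 = 1.00).
"""

from __future__ import annotations

import importlib.resources

import pandas as pd

from .chimera_library import parse_code
from .stability_model import StabilityRecord


def load_gh5_table() -> pd.DataFrame:
    ref = importlib.resources.files("ncschema.data").joinpath("gh5_chimeras.csv")
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, dtype={"code": str})
    return df


def gh5_records(groups: tuple[str, ...] = ("parent", "sampled")) -> list[StabilityRecord]:
    """Stability records for model training (default: parents + C1–C8)."""
    df = load_gh5_table()
    df = df[df["group"].isin(groups)]
    return [
        StabilityRecord(name=row["name"], code=parse_code(row["code"]),
                        t50=float(row["T50"]), ta50=float(row["TA50"]),
                        a_re=float(row["A_re"]) if pd.notna(row["A_re"]) else None)
        for _, row in df.iterrows()
    ]
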