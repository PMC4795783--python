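"""Additive-block linear models of chimera thermostability.

Each block contributes an additive temperature offset when inherited from P1
instead of P2, so a chimera's trait value is modelled as

    trait(code) = intercept + sum_b delta_b * [block b taken from P1]

with the intercept the P2 baseline. Fitting is ordinary least squares via
the Moore–Penrose pseudoinverse, which stays defined when the design matrix
is rank-deficient (small informative samples routinely are); r² is reported
on the training records, without cross-validation.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .chimera_library import Chimera, Code

TRAITS = ("T50", "TA50")


@dataclass(frozen=True)
class StabilityRecord:
    name: str
    code: Code
    t50: float | None = None
    ta50: float | None = None
    a_re: float | None = None

    def trait(self, trait: str) -> float | None:
        return {"T50": self.t50, "TA50": self.ta50}[trait]


@dataclass
class AdditiveStabilityModel:
    trait: str
    intercept: float
    delta_per_block: np.ndarray  # °C, effect of taking the block from P1
    r_squared: float
    training_names: list[str]

    @property
    def k(self) -> int:
        return len(self.delta_per_block)

    def to_dict(self) -> dict:
        return {
            "trait": self.trait,
            "intercept": self.intercept,
            "delta_per_block": [float(d) for d in self.delta_per_block],
            "r_squared": self.r_squared,
            "training_names": self.training_names,
        }


def design_matrix(codes: Sequence[Code]) -> np.ndarray:
    """Intercept column plus one indicator per block (1 = block from P1)."""
    k = len(codes[0])
    X = np.ones((len(codes), k + 1))
    for i, code in enumerate(codes):
        if len(code) != k:
            raise ValueError("codes of unequal length")
        X[i, 1:] = [1.0 if c == 1 else 0.0 for c in code]
    return X


def fit_additive_model(records: Sequence[StabilityRecord], trait: str) -> AdditiveStabilityModel:
    if trait not in TRAITS:
        raise ValueError(f"trait must be one of {TRAITS}")
    usable = [r for r in records if r.trait(trait) is not None]
    if len(usable) < 2:
        raise ValueError("need at least 2 records with measured trait values")
    y = np.array([r.trait(trait) for r in usable], float)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("all trait values identical; model is undefined")
    X = design_matrix([r.code for r in usable])
    beta = np.linalg.pinv(X) @ y
    resid = y - X @ beta
    r2 = 1.0 - float(resid @ resid) / ss_tot
    return AdditiveStabilityModel(
        trait=trait,
        intercept=float(beta[0]),
        delta_per_block=beta[1:].copy(),
        r_squared=r2,
        training_names=[r.name for r in usable],
    )


def predict(model: AdditiveStabilityModel, code: Code) -> float:
    if len(code) != model.k:
        raise ValueError(f"code length {len(code)} != k={model.k}")
    return float(model.intercept
                 + sum(d for d, c in zip(model.delta_per_block, code) if c == 1))


def block_contribution_table(model: AdditiveStabilityModel,
                             neutral_tol: float = 1e-9) -> pd.DataFrame:
    """Per-block effect of inheriting the block from P1, relative to P2."""
    import string
    labels = list(string.ascii_uppercase[:model.k])
    deltas = model.delta_per_block
    effect = ["stabilizing" if d > neutral_tol else
              "destabilizing" if d < -neutral_tol else "neutral" for d in deltas]
    return pd.DataFrame({"block": labels, "delta_C": deltas, "effect": effect})


def rank_candidates(model_t50: AdditiveStabilityModel,
                    model_ta50: AdditiveStabilityModel,
                    library: Sequence[Chimera],
                    E_ceiling: float = np.inf) -> pd.DataFrame:
    """Rank chimeras by predicted T50 (ties: predicted TA50, then lower E)."""
    rows = [c for c in library if c.E <= E_ceiling]
    if not rows:
        raise ValueError("no chimeras pass the E ceiling (empty library?)")
    df = pd.DataFrame({
        "name": [c.name for c in rows],
        "code": ["".join(map(str, c.code)) for c in rows],
        "E": [c.E for c in rows],
        "m": [c.m for c in rows],
        "pred_T50": [predict(model_t50, c.code) for c in rows],
        "pred_TA50": [predict(model_ta50, c.code) for c in rows],
    })
    df = df.sort_values(["pred_T50", "pred_TA50", "E", "name"],
                        ascending=[False, False, True, True], kind="mergesort")
    return df.reset_index(drop=True)
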