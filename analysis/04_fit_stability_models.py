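#!/usr/bin/env python
"""Fit the additive-block stability models to the measured chimera table.

Trains the T50 and TA50 ordinary-least-squares models on the two parents
plus the eight sampled chimeras (C1-C8), reports each block's contribution
relative to P2, checks the designed chimeras C9-C13 against their
predictions, and ranks the full 256-member library by predicted T50.
"""

import json
from pathlib import Path

from ncschema import datasets
from ncschema import stability_model as sm
from ncschema.chimera_library import Chimera, parse_code

OUT = Path(__file__).resolve().parents[1] / "results" / "models"


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    records = datasets.gh5_records()  # parents + C1-C8
    table = datasets.load_gh5_table()

    models = {}
    for trait in sm.TRAITS:
        model = sm.fit_additive_model(records, trait)
        models[trait] = model
        (OUT / f"model_{trait}.json").write_text(json.dumps(model.to_dict(), indent=2))
        contrib = sm.block_contribution_table(model)
        contrib.to_csv(OUT / f"blocks_{trait}.csv", index=False)
        stabilizing = "".join(contrib[contrib.effect == "stabilizing"]["block"])
        print(f"{trait}: training r^2 = {model.r_squared:.3f}, "
              f"intercept {model.intercept:.1f} degC, stabilizing blocks: {stabilizing}")

    # designed chimeras: measured vs predicted
    designed = table[table.group == "designed"]
    print("\ndesigned chimeras, measured vs predicted T50 (degC):")
    for _, row in designed.iterrows():
        pred = sm.predict(models["T50"], parse_code(row["code"]))
        print(f"  {row['name']:>4s} {row['code']}  measured {row['T50']:.0f}  "
              f"predicted {pred:.1f}")

    # rank every code of the 8-block library by predicted stability
    library = [Chimera(name=f"X{i:03d}", code=tuple(
        (i >> b) & 1 and 1 or 2 for b in range(8)), E=0.0, m=0) for i in range(256)]
    ranked = sm.rank_candidates(models["T50"], models["TA50"], library)
    ranked.to_csv(OUT / "ranked_candidates.csv", index=False)
    top = ranked.iloc[0]
    print(f"\ntop-ranked code {top['code']} (predicted T50 {top['pred_T50']:.1f} degC)"
          f" -> {OUT}")


if __name__ == "__main__":
    main()
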