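#!/usr/bin/env python
"""Correlate each nano-descriptor with cell viability and compare the
recovered directions against the generator's ground-truth effects.

Writes results/feature_effects.csv (per-descriptor Pearson r and, for
the six ground-truth effects, the expected sign) and prints whether
every effect direction is recovered — the negative drivers (PMAA ×
concentration, Cl doping, concentration/diameter) and the protective
ones (PEG coating, Fe3O4 core, Fe doping).
"""

from pathlib import Path

import numpy as np
import pandas as pd

import nanoqstr as nq

SEED = 1
OUT = Path(__file__).resolve().parent.parent / "results"


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = nq.study_config(seed=SEED)
    ds = nq.filter_by_diameter(nq.generate_dataset(cfg)).dataset
    matrix, _ = nq.build_feature_matrix(ds)
    y = ds.viability
    expected = nq.ground_truth_effects(cfg).feature_signs()
    rows = []
    for col in matrix.columns:
        x = matrix.frame[col].to_numpy()
        r = float(np.corrcoef(x, y)[0, 1]) if x.std() > 0 else float("nan")
        rows.append({
            "descriptor": col,
            "provenance": matrix.provenance[col],
            "pearson_r": round(r, 4),
            "expected_sign": expected.get(col, ""),
            "sign_recovered": (np.sign(r) == expected[col]) if col in expected else "",
        })
    table = pd.DataFrame(rows).sort_values("pearson_r")
    table.to_csv(OUT / "feature_effects.csv", index=False)
    print(table.to_string(index=False))
    hits = [r for r in rows if r["sign_recovered"] != ""]
    n_ok = sum(bool(r["sign_recovered"]) for r in hits)
    print(f"\neffect directions recovered: {n_ok}/{len(hits)}")


if __name__ == "__main__":
    main()
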