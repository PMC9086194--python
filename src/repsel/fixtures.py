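"""Small, fully synthetic fixture files for demos and tests.

Everything written here is generated programmatically: a hand-countable set of
toy AIRR rearrangement TSVs, a miniature benchmark feature matrix, and the
worked five-fold selection example used to illustrate the weighted relative
frequency.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .simulation import SimulationScenario, simulate_dataset

__all__ = ["make_fixtures", "toy_airr_frames", "WRF_EXAMPLE_FOLDS"]

#: the worked example: five CV-fold selections over features X1..X7
WRF_EXAMPLE_FOLDS = [
    ["X1", "X2"],
    ["X2", "X4", "X5"],
    ["X1", "X5"],
    ["X1"],
    ["X2", "X5", "X7"],
]


def toy_airr_frames(seed: int = 0) -> dict[str, pd.DataFrame]:
    """Six tiny per-sample rearrangement tables with hand-countable VJ tallies."""
    rng = np.random.default_rng(seed)
    v_genes = ["TRBV19", "TRBV20-1", "TRBV5-1", "TRBV6-4"]
    j_genes = ["TRBJ2-1", "TRBJ1-2", "TRBJ2-7"]
    frames = {}
    for s in range(6):
        n_rows = int(rng.integers(6, 13))
        rows = []
        for _ in range(n_rows):
            v = v_genes[rng.integers(len(v_genes))]
            j = j_genes[rng.integers(len(j_genes))]
            allele = rng.integers(1, 3)
            rows.append(
                {
                    "v_call": f"{v}*0{allele}",
                    "j_call": f"{j}*01",
                    "duplicate_count": int(rng.integers(1, 9)),
                }
            )
        frames[f"sample{s + 1}"] = pd.DataFrame(rows)
    return frames


def make_fixtures(out_dir, seed: int = 0) -> dict[str, Path]:
    """Write the fixture set under ``out_dir`` and return the paths.

    (a) six toy AIRR TSVs, (b) a 50 x 100 feature matrix + labels drawn from a
    miniature scenario (six groups of five, three causal), (c) the worked
    five-fold WRF example as JSON.  Byte-identical for identical seeds.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths: dict[str, Path] = {}

    airr_dir = out / "airr"
    airr_dir.mkdir(exist_ok=True)
    for name, df in toy_airr_frames(seed).items():
        p = airr_dir / f"{name}.tsv"
        df.to_csv(p, sep="\t", index=False)
        paths[name] = p

    sc = SimulationScenario(
        label="mini_n50_G100",
        n=50, G=100, prevalence=0.5, beta=(0.0, -9.0, 6.0, 3.0),
        group_sizes=(5, 5, 5, 5, 5, 5),
    )
    data = simulate_dataset(sc, seed=seed)
    xy = pd.DataFrame(data.X, columns=data.feature_names)
    xy.insert(0, "y", data.y)
    p = out / "mini_matrix.csv"
    xy.to_csv(p, index=False, float_format="%.10g")
    paths["mini_matrix"] = p
    manifest = {
        "scenario": sc.label,
        "seed": seed,
        "causal_features": [data.feature_names[i] for i in data.causal_indices],
    }
    p = out / "mini_manifest.json"
    p.write_text(json.dumps(manifest, indent=1))
    paths["mini_manifest"] = p

    p = out / "wrf_example.json"
    p.write_text(json.dumps({"folds": WRF_EXAMPLE_FOLDS}, indent=1))
    paths["wrf_example"] = p
    return paths
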