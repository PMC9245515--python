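"""Occupancy and microheterogeneity dynamics across regeneration timepoints.

Quantifies per-site modification-state occupancy from the simulated MS1
feature table (percent of extracted area per state, per condition and
replicate), runs one-way ANOVA across the four conditions, and compares the
recovered values against the planted truth.  Also demonstrates the
abundance-layer arithmetic (spectral-count normalization, fold change,
row-standardized heatmap scaling) on a small synthetic count matrix.
"""

import json
import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parents[1] / "src"))

import numpy as np
import pandas as pd

from colptm.quantitation import (
    fold_change,
    heatmap_matrix,
    normalize_spectral_counts,
    occupancy_table,
    site_occupancy,
)

ROOT = Path(__file__).resolve().parents[1]
DATA = ROOT / "results" / "synthetic_dataset"
RESULTS = ROOT / "results"


def main():
    features = pd.read_csv(DATA / "features.tsv", sep="\t",
                           keep_default_na=False, na_values=[""])
    features["states"] = features["states"].fillna("")
    config = json.loads((DATA / "config.json").read_text())
    chain_id = features["chain"].iloc[0]
    records = []
    for site in config["planted"]:
        records.extend(site_occupancy(features, chain_id, site["position"]))
    table = occupancy_table(records)
    table.to_csv(RESULTS / "occupancy.tsv", sep="\t", index=False)
    print("recovered occupancy (mean % per condition) vs planted:")
    for site in config["planted"]:
        pos = str(site["position"])
        for state, true_sham in site["occupancy"]["sham"].items():
            if state == "unmod":
                continue
            row = table[(table["site"] == pos) & (table["state"] == state)]
            got = row["sham_mean"].iloc[0] if not row.empty else float("nan")
            print(f"  {site['kind']}{pos} {state:7s} sham: planted {true_sham:6.2f}"
                  f"  recovered {got:6.2f}")
    sig = table[table["significant"] == "*"]
    print(f"{len(sig)} site-state trajectories significant by ANOVA (p < 0.05)")

    # abundance layer: collagen rows drop 0.68-fold at 7 DPA while a filler
    # protein absorbs the difference, so per-file totals stay comparable
    rng = np.random.default_rng(config["seed"])
    collagen = rng.integers(20, 60, size=3).astype(float)
    sham = np.concatenate([collagen, [200.0]])
    dpa7 = np.concatenate([collagen * 0.68, [200.0 + collagen.sum() * 0.32]])
    counts = pd.DataFrame(
        {"sham_r1": sham, "sham_r2": sham, "dpa7_r1": dpa7, "dpa7_r2": dpa7},
        index=["COL1A1a", "COL1A1b", "COL1A2", "other_ecm"],
    )
    norm = normalize_spectral_counts(counts)
    fc = fold_change(norm.loc[["COL1A1a", "COL1A1b", "COL1A2"]],
                     ["dpa7_r1", "dpa7_r2"], ["sham_r1", "sham_r2"])
    heatmap_matrix(norm).to_csv(RESULTS / "heatmap_matrix.tsv", sep="\t")
    print(f"planted 0.68-fold collagen decrease recovered as "
          f"{fc['percent_change'].mean():.1f}% decrease at 7 DPA")


if __name__ == "__main__":
    main()
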