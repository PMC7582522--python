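#!/usr/bin/env python
"""Passive membrane properties and astrocyte phenotypes per cohort.

Simulates voltage-step recordings for each group with the observed
nPA/PA mixture, recovers R_In / R_S / R_M from the −5 mV test step,
applies the 15 MΩ series-resistance QC, classifies the I/V phenotype,
and compares nPA/PA proportions of each deaf model against WT with χ².

Output: results/ephys_cohort.csv, results/ephys_stats.json.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import numpy as np
import pandas as pd

from astrotopo import (
    EphysGroundTruth,
    chi_square_distribution,
    compute_passive_properties,
    extract_iv_curve,
    generate_voltage_step_traces,
)
from astrotopo.io import write_json
from common import COHORTS, PHENOTYPE_SPLIT, RESULTS

SEED = 731
N_CELLS = {"WT": 63, "CaV1.3-KO": 21, "otoferlin-KO": 17}  # recorded cells


def main() -> None:
    rng = np.random.default_rng(SEED)
    rows = []
    for g_idx, (group, n) in enumerate(N_CELLS.items()):
        n_npa = int(round(PHENOTYPE_SPLIT[group] * n))
        for i in range(n):
            is_npa = i < n_npa
            truth = EphysGroundTruth(
                r_series=float(rng.uniform(2.0, 8.0)),
                r_membrane=float(np.clip(rng.normal(3.7, 2.0), 1.0, None)) + 5.0,
                phenotype="nPA" if is_npa else "PA",
                g_max_outward=float(rng.uniform(30.0, 80.0)) if is_npa else 0.0,
            )
            traces = generate_voltage_step_traces(
                truth, noise_sd_na=0.005, seed=SEED + 17 * i + 100_000 * g_idx
            )
            props = compute_passive_properties(traces)
            iv = extract_iv_curve(traces)
            rows.append(
                dict(
                    group=group, cell=i, true_phenotype=truth.phenotype,
                    r_in_mohm=props.r_in, r_s_mohm=props.r_s, r_m_mohm=props.r_m,
                    qc_pass=props.qc_pass, rectification_index=iv.rectification_index,
                    phenotype=iv.phenotype,
                )
            )
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "ephys_cohort.csv", index=False)

    agree = (df.phenotype == df.true_phenotype).mean()
    print(f"phenotype agreement with ground truth: {100 * agree:.1f}%")
    print(df.groupby("group")[["r_s_mohm", "r_m_mohm"]].mean().round(2))

    stats = {"phenotype_agreement": float(agree)}
    counts = {
        g: [int((df[df.group == g].phenotype == p).sum()) for p in ("nPA", "PA")]
        for g in N_CELLS
    }
    stats["phenotype_counts"] = counts
    for model in ("CaV1.3-KO", "otoferlin-KO"):
        stat, p = chi_square_distribution(counts["WT"], counts[model])
        stats[f"chi2_WT_vs_{model}"] = {"statistic": stat, "p_value": p}
        print(f"chi2 nPA/PA WT vs {model}: stat={stat:.2f}, p={p:.4g}")
    write_json(RESULTS / "ephys_stats.json", stats)


if __name__ == "__main__":
    main()
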