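#!/usr/bin/env python
"""Topography of every simulated network: anisotropy, orientation, class.

Reads the point tables written by 01_simulate_networks.py, runs the
rotation-scan / sinusoid-fit / classification chain on each network, and
compares the class distributions of the deaf models against WT with χ²
tests under Šidák correction (two model-vs-WT comparisons).

Outputs: results/topography.csv, results/topography_stats.json.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).parent))

import pandas as pd

from astrotopo import (
    CLASS_ISOTROPIC,
    CLASS_ORTHOGONAL,
    CLASS_PARALLEL,
    analyze_network,
    chi_square_distribution,
    sidak_thresholds,
    significance_stars,
)
from astrotopo.io import read_points, write_json
from common import COHORTS, RESULTS, network_dir

CLASS_ORDER = [CLASS_ORTHOGONAL, CLASS_ISOTROPIC, CLASS_PARALLEL]


def main() -> None:
    rows = []
    for group in COHORTS:
        for path in sorted(network_dir(group).glob("net_*.csv")):
            rec = analyze_network(read_points(path))
            rows.append(
                dict(
                    group=group, network=path.stem,
                    r_max=rec["fit"]["r_max"], alpha_deg=rec["fit"]["alpha_deg"],
                    omega=rec["fit"]["omega"], network_class=rec["network_class"],
                    n_cells=rec["metrics"]["n_cells"],
                    density_per_mm2=rec["metrics"]["density_per_mm2"],
                )
            )
    df = pd.DataFrame(rows)
    if df.empty:
        sys.exit("no point tables found - run 01_simulate_networks.py first")
    df.to_csv(RESULTS / "topography.csv", index=False)

    counts = {
        g: [int((df[df.group == g].network_class == c).sum()) for c in CLASS_ORDER]
        for g in COHORTS
    }
    print("class counts (orthogonal / isotropic / parallel):")
    for g, c in counts.items():
        total = sum(c)
        pct = ", ".join(f"{100 * x / total:.0f}%" for x in c)
        print(f"  {g:14s} {c}  ({pct})")

    stats = {"class_counts": counts, "sidak_thresholds_m2": sidak_thresholds(2)}
    for model in ("CaV1.3-KO", "otoferlin-KO"):
        stat, p = chi_square_distribution(counts["WT"], counts[model])
        stars = significance_stars(p, m=2)
        stats[f"chi2_WT_vs_{model}"] = {"statistic": stat, "p_value": p, "stars": stars}
        print(f"chi2 WT vs {model}: stat={stat:.2f}, p={p:.4g} {stars}")
    write_json(RESULTS / "topography_stats.json", stats)


if __name__ == "__main__":
    main()
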