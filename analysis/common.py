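"""Shared cohort definitions for the analysis scripts.

The synthetic cohorts emulate the study design: a normal-hearing (WT)
group whose tracer-coupled networks are mostly elongated dorsoventrally
(orthogonal to the tonotopic axis), and two congenitally deaf models
(CaV1.3-KO-like, otoferlin-KO-like) whose networks are mostly elongated
mediolaterally (parallel to the tonotopic axis).  Group sizes, cell-count
statistics and topography mixtures follow the study's reported cohorts.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

from astrotopo import SyntheticNetworkSpec

RESULTS = Path(__file__).resolve().parents[1] / "results"
SCRATCH = Path(__file__).resolve().parents[1] / "scratch"

# per-group: (n_networks, mean cell count, sd, topography mixture)
# mixture = (n orthogonal, n isotropic, n parallel) networks
COHORTS = {
    "WT": dict(n=24, cells_mean=64, cells_sd=15, mix=(17, 3, 4)),
    "CaV1.3-KO": dict(n=14, cells_mean=54, cells_sd=12, mix=(3, 4, 7)),
    "otoferlin-KO": dict(n=8, cells_mean=65, cells_sd=14, mix=(2, 2, 4)),
}

# observed nPA/PA percentages per group
PHENOTYPE_SPLIT = {"WT": 0.32, "CaV1.3-KO": 0.62, "otoferlin-KO": 0.53}


def cohort_specs(group: str, seed: int) -> list[SyntheticNetworkSpec]:
    """Per-network generator specs for one group, deterministically seeded."""
    cfg = COHORTS[group]
    rng = np.random.default_rng(seed)
    kinds = (
        ["orthogonal"] * cfg["mix"][0]
        + ["isotropic"] * cfg["mix"][1]
        + ["parallel"] * cfg["mix"][2]
    )
    assert len(kinds) == cfg["n"]
    specs = []
    for i, kind in enumerate(kinds):
        n_cells = max(15, int(round(rng.normal(cfg["cells_mean"], cfg["cells_sd"])))) - 1
        if kind == "isotropic":
            sig = 53.0  # preserves the 2:1 default's geometric-mean spread
            spec = SyntheticNetworkSpec(
                n_cells=n_cells, sigma_major=sig, sigma_minor=sig,
                alpha_true=0.0, seed=seed * 1000 + i,
            )
        else:
            alpha = 90.0 if kind == "orthogonal" else 0.0
            alpha = float((alpha + rng.normal(0.0, 12.0)) % 180.0)
            spec = SyntheticNetworkSpec(
                n_cells=n_cells, alpha_true=alpha, seed=seed * 1000 + i,
            )
        specs.append(dataclasses.replace(spec))
    return specs


def network_dir(group: str) -> Path:
    d = SCRATCH / "networks" / group
    d.mkdir(parents=True, exist_ok=True)
    return d
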