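"""Calibrate per-SNP statistics into significance calls: outlier q-values
from selection posteriors (directional outliers at q < 0.05, positive
alpha), GIF-adjusted association p-values and Storey q-values (significant
at q <= 0.001). Also screens genetic structure (allele-frequency PCs)
against the environmental factors, and prunes correlated factors."""

import numpy as np
import pandas as pd
from _config import CONFIG, SIM_DIR, TABLE_DIR

from convergescan import annotate_scan_table, prune_correlated, structure_env_correlation
from convergescan.envfactors import read_env_table
from convergescan.io import read_scan_table, write_scan_table

TABLE_DIR.mkdir(parents=True, exist_ok=True)
factors = CONFIG.factor_names
screen_rows = []
for sp in CONFIG.species_ids:
    table = read_scan_table(SIM_DIR / f"{sp}.filtered.tsv")
    annotated = annotate_scan_table(table, factors)
    write_scan_table(annotated, SIM_DIR / f"{sp}.annotated.tsv")
    n_out = int(annotated["outlier"].sum())
    n_assoc = {f: int(annotated[f"sig_{f}"].sum()) for f in factors}
    print(f"{sp}: {n_out} outlier SNPs; associations per factor: {n_assoc}")

    # structure screen: PCs of the population x SNP allele-frequency matrix
    af = annotated[[f"af_{i + 1}" for i in range(CONFIG.n_pops)]].to_numpy().T
    af = af - af.mean(axis=0)
    u, s, _ = np.linalg.svd(af, full_matrices=False)
    pcs = pd.DataFrame(
        (u[:, :2] * s[:2]), columns=["PC1", "PC2"],
        index=[f"pop{i + 1}" for i in range(CONFIG.n_pops)],
    )
    env = read_env_table(SIM_DIR / f"{sp}.env.tsv")
    screen = structure_env_correlation(pcs, env)
    screen.insert(0, "species", sp)
    screen_rows.append(screen)
    n_sig = int((screen["p"] < 0.05).sum())
    print(f"{sp}: structure-environment screen: {n_sig}/{len(screen)} correlations at p < .05")

pd.concat(screen_rows).to_csv(TABLE_DIR / "structure_env_screen.tsv", sep="\t", index=False)

env = read_env_table(SIM_DIR / f"{CONFIG.species_ids[0]}.env.tsv")
kept = prune_correlated(env, threshold=0.7)
print(f"factor pruning at |r| < 0.7 keeps {len(kept)}/{len(env.columns)}: {', '.join(kept)}")
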