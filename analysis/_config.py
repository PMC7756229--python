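"""Shared configuration for the analysis drivers.

The synthetic study is run at a reduced scale (about 2,400 annotated genes
per species with an 1,800-gene shared core, six SNPs per gene) so the full
pipeline executes in seconds; the convergence replication step (script 05)
additionally runs the resampling at the published full-scale set sizes,
which is cheap because it depends only on gene counts.
"""

from pathlib import Path

from convergescan import SimConfig

RESULTS = Path(__file__).resolve().parent.parent / "results"
SIM_DIR = RESULTS / "simulated"
TABLE_DIR = RESULTS / "tables"

MAX_COV = {"Aal": 130, "Aha": 130, "Cre": 130}

CONFIG = SimConfig(
    species_ids=("Aal", "Aha", "Cre"),
    annotated_sizes=(2400, 2500, 2450),
    shared_all=1800,
    n_pops=6,
    snps_per_gene=6.0,
    n_planted_convergent=50,
    planted_factor="PRECYY",
    effect_shift=6.0,
    null_outlier_rate=0.01,
    ns_fraction=0.5,
    seed=42,
)
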