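"""Environmental factor tables and correlation-based pruning.

Topoclimatic factors extracted for sampling sites are typically redundant;
the analysis keeps a subset in which no retained pair is highly correlated
(Pearson |r| below a threshold, 0.7 by default). The reduction rule is an
explicit greedy walk over a priority order, so it is deterministic and
reproducible.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Sequence

import numpy as np
import pandas as pd


def read_env_table(path) -> pd.DataFrame:
    """Read a populations x factors TSV (first column: population ID)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        raise ValueError("environment table contains missing values")
    return df


def write_env_table(env: pd.DataFrame, path) -> None:
    env.to_csv(path, sep="\t", index_label="population")


def correlation_matrix(env: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of the factor columns.

    Raises on zero-variance factors (their correlation is undefined),
    naming the offending factor.
    """
    if len(env) < 3:
        raise ValueError("need at least three populations")
    sd = env.std(ddof=0)
    dead = sd.index[sd == 0].tolist()
    if dead:
        raise ValueError(f"zero-variance factor(s): {', '.join(map(str, dead))}")
    return env.corr(method="pearson")


def prune_correlated(
    env: pd.DataFrame,
    threshold: float = 0.7,
    priority: Sequence[str] | None = None,
) -> List[str]:
    """Greedy reduction to factors with pairwise |r| strictly below threshold.

    Walk the priority order (default: column order); keep a factor iff its
    absolute correlation with every already-kept factor is < threshold. A
    pair at exactly the threshold is therefore not retained together.
    """
    order = list(priority) if priority is not None else list(env.columns)
    missing = set(env.columns) - set(order)
    if missing:
        raise ValueError(f"priority does not cover factors: {sorted(missing)}")
    corr = correlation_matrix(env)
    kept: List[str] = []
    for f in order:
        if all(abs(corr.loc[f, g]) < threshold for g in kept):
            kept.append(f)
    return kept
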