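"""Calibrated significance calls from raw per-SNP selection-scan outputs.

Two streams of evidence are consumed as-is from upstream model fits:

* Bayesian F-model outlier scans supply a per-locus posterior probability of
  selection plus the sign of the locus effect alpha. q-values are rebuilt
  from posterior error probabilities (PEP = 1 - posterior): ranking loci by
  PEP, q at rank i is the mean of the i smallest PEPs — the Bayesian FDR of
  calling the top-i loci. Outliers for directional selection are loci with
  q < 0.05 *and* positive alpha (balancing selection excluded).

* Latent-factor association models supply per-factor z-scores. These are
  recalibrated with a genomic inflation factor: lambda = median(z^2) divided
  by the chi-square(1) median (~0.4549), adjusted p = upper chi-square(1)
  tail of z^2/lambda. q-values then come from Benjamini-Hochberg, optionally
  rescaled by a Storey pi0 estimate; associations are significant at
  q <= 0.001.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: Median of the chi-square distribution with one degree of freedom.
CHI2_MEDIAN_1DF = float(stats.chi2.ppf(0.5, df=1))


@dataclass
class CalibrationResult:
    lambda_: float
    adjusted_p: np.ndarray


def pep_qvalues(posteriors: Sequence[float]) -> np.ndarray:
    """q-values from posterior probabilities of selection.

    q at PEP-rank i = mean of the i smallest posterior error probabilities;
    non-decreasing along the ranking; ties broken by input order; returned
    in input order.
    """
    post = np.asarray(posteriors, dtype=float)
    if post.size == 0:
        raise ValueError("no posteriors given")
    if np.any((post < 0) | (post > 1)) or np.any(~np.isfinite(post)):
        raise ValueError("posteriors must lie in [0, 1]")
    pep = 1.0 - post
    order = np.argsort(pep, kind="stable")
    q_sorted = np.cumsum(pep[order]) / np.arange(1, pep.size + 1)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q


def gif_calibrate(zscores: Sequence[float]) -> CalibrationResult:
    """Genomic-inflation-factor recalibration of association z-scores.

    lambda anchors the median of z^2 to the null chi-square(1) median;
    adjusted p-values are the chi-square(1) upper tail of z^2/lambda. With
    lambda = 1 this reduces to the two-sided normal p-value.
    """
    z = np.asarray(zscores, dtype=float)
    if z.size < 2 or np.any(~np.isfinite(z)):
        raise ValueError("need at least two finite z-scores")
    lam = float(np.median(z**2)) / CHI2_MEDIAN_1DF
    if lam == 0:
        raise ValueError("all z-scores are zero; lambda undefined")
    adjusted = stats.chi2.sf(z**2 / lam, df=1)
    return CalibrationResult(lambda_=lam, adjusted_p=adjusted)


def qvalues(pvalues: Sequence[float], method: str = "bh") -> np.ndarray:
    """FDR q-values by Benjamini-Hochberg or Storey's pi0-rescaled variant.

    ``storey`` scales the BH values by pi0 estimated at the single point
    lambda = 0.5: pi0 = min(1, #{p > 0.5} / (0.5 n)).
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ValueError("no p-values given")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    bh = multipletests(p, method="fdr_bh")[1]
    if method == "bh":
        return bh
    if method == "storey":
        pi0 = min(1.0, (p > 0.5).sum() / (0.5 * p.size))
        return np.minimum(bh * pi0, 1.0)
    raise ValueError(f"unknown method {method!r}")


def call_outliers(table: pd.DataFrame, fdr: float = 0.05) -> pd.Series:
    """Directional-selection outlier flags: q_outlier < fdr and alpha > 0.

    The inequality is strict (FDR < 0.05); loci with negative locus effect
    (candidates for balancing selection) are never flagged. A sub-threshold
    locus with missing effect sign is an error.
    """
    q = table["q_outlier"].to_numpy(dtype=float)
    sign = table["alpha_sign"]
    below = q < fdr
    if bool(sign[below].isna().any()):
        raise ValueError("missing alpha_sign on a locus below the FDR threshold")
    return pd.Series(below & (sign.fillna(0).to_numpy(dtype=float) > 0), index=table.index)


def call_associations(q_assoc, q_threshold: float = 0.001):
    """Association flags at q <= threshold (inclusive)."""
    if isinstance(q_assoc, pd.DataFrame):
        return q_assoc.le(q_threshold)
    return np.asarray(q_assoc, dtype=float) <= q_threshold


def annotate_scan_table(
    table: pd.DataFrame,
    factor_names: Sequence[str],
    outlier_fdr: float = 0.05,
    assoc_q: float = 0.001,
    assoc_method: str = "storey",
) -> pd.DataFrame:
    """Fill q-values and significance flags on a per-species scan table.

    Adds ``q_outlier`` (from ``posterior``), ``outlier`` (directional
    outlier flag), and per factor ``p_<f>``/``q_<f>``/``sig_<f>`` from the
    ``z_<f>`` columns via GIF calibration and q-values.
    """
    out = table.copy()
    out["q_outlier"] = pep_qvalues(out["posterior"].to_numpy())
    out["outlier"] = call_outliers(out, fdr=outlier_fdr).to_numpy()
    for f in factor_names:
        cal = gif_calibrate(out[f"z_{f}"].to_numpy())
        out[f"p_{f}"] = cal.adjusted_p
        out[f"q_{f}"] = qvalues(cal.adjusted_p, method=assoc_method)
        out[f"sig_{f}"] = call_associations(out[f"q_{f}"].to_numpy(), assoc_q)
    return out


def structure_env_correlation(
    pc_scores: pd.DataFrame, env: pd.DataFrame
) -> pd.DataFrame:
    """Pearson correlation of genetic-structure PCs with each environmental factor.

    Both frames are populations x variables and must share their population
    index. Returns one row per (component, factor) with r and the two-sided
    p from the t distribution on n-2 df; zero-variance columns yield missing
    values with a warning.
    """
    if len(pc_scores) != len(env) or set(pc_scores.index) != set(env.index):
        raise ValueError("population sets of PC scores and environment differ")
    if len(env) < 3:
        raise ValueError("need at least three populations")
    env = env.loc[pc_scores.index]
    rows = []
    for comp in pc_scores.columns:
        x = pc_scores[comp].to_numpy(dtype=float)
        for factor in env.columns:
            y = env[factor].to_numpy(dtype=float)
            if np.std(x) == 0 or np.std(y) == 0:
                warnings.warn(
                    f"zero variance in ({comp}, {factor}); correlation undefined"
                )
                rows.append({"component": comp, "factor": factor, "r": np.nan, "p": np.nan})
                continue
            r, p = stats.pearsonr(x, y)
            rows.append({"component": comp, "factor": factor, "r": r, "p": p})
    return pd.DataFrame(rows)
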