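"""Two-round Pool-Seq variant filtering with per-rule rejection accounting.

Round one (``highconf``) keeps any variant type passing quality, coverage and
alternative-allele-count thresholds; its survivors feed base-quality
recalibration upstream. Round two (``final``) keeps biallelic SNPs only,
adds a minimum pooled alternative allele frequency, and an allele-frequency
consistency rule: the caller's per-population frequency must not differ from
the read-count-based estimate by more than a tolerance (0.2) in any
population. All thresholds are inclusive on the passing side.

A record failing several rules is attributed to the first failing rule in
the fixed order qual -> biallelic -> min_cov -> max_cov -> alt_count /
alt_freq -> freq_tol, which makes reports deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Mapping, Tuple

import numpy as np
import pandas as pd

from .universe import ConfigurationError

RULE_ORDER = (
    "min_qual",
    "biallelic",
    "min_cov",
    "max_cov",
    "min_alt_count",
    "min_alt_freq",
    "freq_tol",
)


@dataclass(frozen=True)
class FilterProfile:
    """Threshold bundle for one filtering round.

    ``max_cov`` maps species label -> maximum total coverage (repeat and
    paralog guard); it must name every species present in the data.
    """

    name: str
    max_cov: Mapping[str, int]
    min_qual: float = 30.0
    min_cov: int = 20
    min_alt_count: int | None = None
    min_alt_freq: float | None = None
    freq_tol: float | None = None
    biallelic_only: bool = False

    def __post_init__(self):
        for s, mx in self.max_cov.items():
            if self.min_cov >= mx:
                raise ConfigurationError(
                    f"min_cov {self.min_cov} not below max_cov {mx} for {s}"
                )

    @classmethod
    def highconf(cls, max_cov: Mapping[str, int]) -> "FilterProfile":
        """First-round profile: qual >= 30, alt count >= 6, coverage 20..max."""
        return cls(name="highconf", max_cov=dict(max_cov), min_alt_count=6)

    @classmethod
    def final(cls, max_cov: Mapping[str, int]) -> "FilterProfile":
        """Second-round profile: biallelic SNPs, qual >= 30, alt freq >= 1%,
        coverage 20..max, per-population frequency consistency within 0.2."""
        return cls(
            name="final",
            max_cov=dict(max_cov),
            min_alt_freq=0.01,
            freq_tol=0.2,
            biallelic_only=True,
        )


@dataclass
class FilterReport:
    n_input: int
    n_passed: int
    rejected: Dict[str, int] = field(default_factory=dict)

    def __post_init__(self):
        assert self.n_passed + sum(self.rejected.values()) == self.n_input

    def to_dict(self) -> dict:
        return {
            "n_input": self.n_input,
            "n_passed": self.n_passed,
            "rejected": dict(self.rejected),
        }


def freq_consistency_ok(called_freq, count_freq, tol: float):
    """True iff |called - count| <= tol in every population.

    Accepts scalars, 1-D per-population vectors, or 2-D (records x
    populations) arrays; for 2-D input returns a boolean per record.
    """
    called = np.asarray(called_freq, dtype=float)
    count = np.asarray(count_freq, dtype=float)
    if np.any((called < 0) | (called > 1)) or np.any((count < 0) | (count > 1)):
        raise ValueError("frequencies must lie in [0, 1]")
    diff_ok = np.abs(called - count) <= tol
    if diff_ok.ndim <= 1:
        return bool(np.all(diff_ok))
    return diff_ok.all(axis=1)


def _is_snp(ref: pd.Series, alt: pd.Series) -> np.ndarray:
    """Biallelic SNP: one REF base, one single-base ALT allele."""
    one_alt = ~alt.str.contains(",", regex=False)
    return (
        (ref.str.len() == 1) & one_alt & (alt.str.len() == 1)
    ).to_numpy()


def filter_variants(
    records: pd.DataFrame, profile: FilterProfile
) -> Tuple[pd.DataFrame, FilterReport]:
    """Apply a filter profile; return passing records and per-rule rejections.

    Requires columns ``species``, ``ref``, ``alt``, ``qual``, ``coverage``,
    ``alt_count`` and per-population ``af_*`` (called) / ``cf_*``
    (count-based) frequency columns. The passed set is a subset of the
    input; passed + rejected counts conserve the input size.
    """
    present = set(records["species"].unique()) if len(records) else set()
    unknown = present - set(profile.max_cov)
    if unknown:
        raise ConfigurationError(
            f"no max_cov configured for species: {sorted(unknown)}"
        )
    n = len(records)
    if n == 0:
        return records.copy(), FilterReport(0, 0, {})

    af_cols = [c for c in records.columns if c.startswith("af_")]
    cf_cols = [c for c in records.columns if c.startswith("cf_")]
    fail = {}
    fail["min_qual"] = (records["qual"].to_numpy(dtype=float) < profile.min_qual)
    fail["biallelic"] = (
        ~_is_snp(records["ref"].astype(str), records["alt"].astype(str))
        if profile.biallelic_only
        else np.zeros(n, dtype=bool)
    )
    cov = records["coverage"].to_numpy(dtype=float)
    fail["min_cov"] = cov < profile.min_cov
    max_cov = records["species"].map(profile.max_cov).to_numpy(dtype=float)
    fail["max_cov"] = cov > max_cov
    fail["min_alt_count"] = (
        records["alt_count"].to_numpy(dtype=float) < profile.min_alt_count
        if profile.min_alt_count is not None
        else np.zeros(n, dtype=bool)
    )
    fail["min_alt_freq"] = (
        records[af_cols].to_numpy(dtype=float).mean(axis=1) < profile.min_alt_freq
        if profile.min_alt_freq is not None and af_cols
        else np.zeros(n, dtype=bool)
    )
    if profile.freq_tol is not None and af_cols and cf_cols:
        ok = freq_consistency_ok(
            records[af_cols].to_numpy(dtype=float),
            records[cf_cols].to_numpy(dtype=float),
            profile.freq_tol,
        )
        fail["freq_tol"] = ~np.atleast_1d(ok)
    else:
        fail["freq_tol"] = np.zeros(n, dtype=bool)

    attributed = np.zeros(n, dtype=bool)
    rejected: Dict[str, int] = {}
    for rule in RULE_ORDER:
        hit = fail[rule] & ~attributed
        if hit.any():
            rejected[rule] = int(hit.sum())
        attributed |= fail[rule]
    passed = records[~attributed].copy()
    return passed, FilterReport(n, len(passed), rejected)
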