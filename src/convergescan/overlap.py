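"""Resampling test for over-representation of shared adaptation signatures.

The question: do more orthologous genes carry a selection signature in *all*
members of a species subset than expected if each species' candidate genes
were a random draw from its own annotated background? The null is built by
resampling: per iteration, draw — independently for each species — a uniform
without-replacement subset of that species' full annotated gene list, with
size equal to the species' observed candidate count, and record the
cardinality of the cross-species intersection. The empirical p-value is the
fraction of null counts greater than or equal to the observed count (no
pseudo-count), and the over-representation ratio is the percent excess of
the observed count over the null mean, 100*(obs/mean - 1).

This resampling is preferred over a hypergeometric test because it extends
to more than two species and uses each species' own background; the
hypergeometric version is kept as a pairwise cross-check oracle.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
from scipy import stats

from .genes import CandidateSetCollection
from .universe import OrthologUniverse


@dataclass
class OverlapTestResult:
    analysis: str
    species_subset: Tuple[str, ...]
    observed: int
    null_counts: np.ndarray
    null_mean: float
    null_sd: float
    empirical_p: float
    over_representation: float | None  # percent; None when the null mean is 0
    n_iter: int
    seed: int

    @property
    def significant(self) -> bool:
        return self.empirical_p < 0.05

    def to_dict(self) -> dict:
        return {
            "analysis": self.analysis,
            "species_subset": list(self.species_subset),
            "observed": int(self.observed),
            "null_mean": float(self.null_mean),
            "null_sd": float(self.null_sd),
            "empirical_p": float(self.empirical_p),
            "over_representation": None
            if self.over_representation is None
            else float(self.over_representation),
            "n_iter": int(self.n_iter),
            "seed": int(self.seed),
        }


def resample_overlap(
    universe: OrthologUniverse,
    candidate_sizes: Mapping[str, int],
    species_subset: Sequence[str],
    n_iter: int = 10000,
    seed: int | Sequence[int] = 0,
) -> np.ndarray:
    """Null distribution of the shared-gene count for a species subset.

    Each iteration draws, independently per species, ``candidate_sizes[s]``
    genes uniformly without replacement from that species' annotated list and
    counts ortholog IDs present in every draw. Bit-reproducible for a fixed
    seed.
    """
    subset = tuple(species_subset)
    if len(subset) < 2:
        raise ValueError("need at least two species")
    for s in subset:
        n = candidate_sizes[s]
        if not 0 <= n <= universe.size(s):
            raise ValueError(
                f"candidate size {n} for {s} outside [0, {universe.size(s)}]"
            )
    all_genes = sorted(set().union(*(universe.annotated[s] for s in subset)))
    index = {g: i for i, g in enumerate(all_genes)}
    gids = [
        np.array([index[g] for g in universe.sorted_genes(s)], dtype=np.int64)
        for s in subset
    ]
    sizes = [candidate_sizes[s] for s in subset]
    rng = np.random.default_rng(seed)
    total = np.zeros(len(all_genes), dtype=np.uint8)
    k = len(subset)
    counts = np.empty(n_iter, dtype=np.int64)
    for it in range(n_iter):
        total[:] = 0
        for g, n in zip(gids, sizes):
            total[g[rng.choice(g.size, size=n, replace=False)]] += 1
        counts[it] = int((total == k).sum())
    return counts


def expected_overlap_analytic(
    shared_core: int, sizes: Sequence[int], universes: Sequence[int]
) -> float:
    """Exact resampling-null mean when all cross-species sharing sits in the core.

    Each core gene is drawn by species i with probability n_i/N_i,
    independently across species, so E[overlap] = S * prod(n_i/N_i). Genes
    outside the shared core are assumed species-private.
    """
    if len(sizes) != len(universes):
        raise ValueError("sizes and universes must align")
    out = float(shared_core)
    for n, big_n in zip(sizes, universes):
        if big_n == 0:
            raise ValueError("empty universe")
        if not 0 <= n <= big_n:
            raise ValueError(f"size {n} outside [0, {big_n}]")
        out *= n / big_n
    return out


def empirical_p(null_counts: Sequence[int], observed: int) -> float:
    """Fraction of null counts >= observed (no pseudo-count)."""
    null = np.asarray(null_counts)
    if null.size == 0:
        raise ValueError("empty null distribution")
    return float((null >= observed).mean())


def over_representation(observed: int, expected: float) -> float:
    """Percent excess of observed over expected: 100*(observed/expected - 1)."""
    if expected <= 0:
        raise ValueError("expected overlap must be positive")
    return 100.0 * (observed / expected - 1.0)


def overlap_test(
    universe: OrthologUniverse,
    candidate_sizes: Mapping[str, int],
    species_subset: Sequence[str],
    observed: int,
    n_iter: int = 10000,
    seed: int | Sequence[int] = 0,
    analysis: str = "",
) -> OverlapTestResult:
    """Run one resampling test and package all summary statistics."""
    null = resample_overlap(universe, candidate_sizes, species_subset, n_iter, seed)
    mean = float(null.mean())
    seed_int = seed if isinstance(seed, (int, np.integer)) else int(np.asarray(seed)[0])
    return OverlapTestResult(
        analysis=analysis,
        species_subset=tuple(species_subset),
        observed=int(observed),
        null_counts=null,
        null_mean=mean,
        null_sd=float(null.std(ddof=0)),
        empirical_p=empirical_p(null, observed),
        over_representation=over_representation(observed, mean) if mean > 0 else None,
        n_iter=int(n_iter),
        seed=int(seed_int),
    )


def run_convergence_suite(
    collection: CandidateSetCollection,
    universe: OrthologUniverse,
    n_iter: int = 10000,
    seed: int = 0,
) -> List[OverlapTestResult]:
    """Resampling tests for every analysis over the full species set and all pairs.

    Observed overlaps come from the candidate sets. Each (analysis, subset)
    cell uses an independent RNG substream derived from the master seed, so
    results do not depend on execution order.
    """
    sp = collection.species_ids
    subsets: List[Tuple[str, ...]] = [tuple(sp)]
    subsets += [tuple(c) for c in itertools.combinations(sp, 2)]
    results = []
    for ai, analysis in enumerate(collection.analyses):
        sizes = collection.sizes(analysis)
        for si, subset in enumerate(subsets):
            observed = len(collection.shared(analysis, subset))
            null = resample_overlap(
                universe, sizes, subset, n_iter=n_iter, seed=[seed, ai, si]
            )
            mean = float(null.mean())
            results.append(
                OverlapTestResult(
                    analysis=analysis,
                    species_subset=subset,
                    observed=observed,
                    null_counts=null,
                    null_mean=mean,
                    null_sd=float(null.std(ddof=0)),
                    empirical_p=empirical_p(null, observed),
                    over_representation=over_representation(observed, mean)
                    if mean > 0
                    else None,
                    n_iter=n_iter,
                    seed=seed,
                )
            )
    return results


def ns_enrichment_test(
    shared_candidates: int,
    shared_with_ns: int,
    universe_shared: int,
    universe_ns: int,
    n_iter: int = 10000,
    seed: int | Sequence[int] = 0,
) -> float:
    """Empirical p for nonsynonymous enrichment among shared candidate genes.

    Null: draw ``shared_candidates`` genes without replacement from the
    ``universe_shared`` genes shared by all species, of which ``universe_ns``
    contain nonsynonymous SNPs in all species; count draws hitting the NS
    set. Sampling uses the exact hypergeometric law of that draw. Returns
    the fraction of iterations with a count >= ``shared_with_ns``.
    """
    if not 0 <= shared_with_ns <= shared_candidates:
        raise ValueError("shared_with_ns outside [0, shared_candidates]")
    if not 0 <= universe_ns <= universe_shared:
        raise ValueError("universe_ns outside [0, universe_shared]")
    if shared_candidates > universe_shared:
        raise ValueError("shared_candidates exceeds universe_shared")
    rng = np.random.default_rng(seed)
    counts = rng.hypergeometric(
        universe_ns, universe_shared - universe_ns, shared_candidates, size=n_iter
    )
    return float((counts >= shared_with_ns).mean())


def hypergeom_pairwise(
    shared_universe: int,
    n1: int,
    n2: int,
    big_n1: int,
    big_n2: int,
):
    """Exact pairwise null as a comparison oracle for the resampling test.

    Species 1 draws ``n1`` of ``big_n1`` genes, species 2 independently
    ``n2`` of ``big_n2``; ``shared_universe`` genes are common to both
    backgrounds (the rest private). Returns ``(expected, tail)`` where
    ``tail(k) = P(overlap >= k)`` from the exact mixture-of-hypergeometrics
    distribution. Intended for small instances.
    """
    if not (0 <= n1 <= big_n1 and 0 <= n2 <= big_n2):
        raise ValueError("sizes must lie within universes")
    if shared_universe > min(big_n1, big_n2):
        raise ValueError("shared universe exceeds a species' background")
    s = shared_universe
    expected = s * (n1 / big_n1) * (n2 / big_n2)
    k1 = np.arange(0, min(s, n1) + 1)
    k2 = np.arange(0, min(s, n2) + 1)
    p1 = stats.hypergeom.pmf(k1, big_n1, s, n1)
    p2 = stats.hypergeom.pmf(k2, big_n2, s, n2)
    kmax = min(s, n1, n2)
    pmf = np.zeros(kmax + 1)
    ks = np.arange(kmax + 1)
    for i, a in enumerate(k1):
        # P(overlap = k | k1=a, k2=b) is hypergeometric: b draws from s
        # genes of which a are "marked".
        cond = stats.hypergeom.pmf(ks[None, :], s, a, k2[:, None])
        pmf += p1[i] * (p2[:, None] * cond).sum(axis=0)
    pmf = np.clip(pmf, 0.0, None)
    pmf /= pmf.sum()
    sf = np.concatenate([np.cumsum(pmf[::-1])[::-1], [0.0]])

    def tail(k: int) -> float:
        if k <= 0:
            return 1.0
        if k > kmax:
            return 0.0
        return float(sf[k])

    return expected, tail
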