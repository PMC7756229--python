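"""Synthetic multi-species inputs for the convergence pipeline.

Real inputs to the analysis are per-species Pool-Seq variant tables carrying
selection-scan statistics, gene models keyed by one-to-one ortholog IDs, and
an environment matrix over populations. This module generates stand-ins with
the statistical structure the pipeline assumes, so every downstream stage is
testable without any sequencing data:

* an ortholog universe with exact, configured intersection structure;
* per-species SNP tables in which null loci carry low selection posteriors
  and standard-normal association z-scores, while a configured set of
  *planted* convergent genes carries z-scores shifted for one factor in
  every species;
* gene models whose CDS bodies are built from fourfold-degenerate codon
  families, so that coding SNPs can be placed at sites with a guaranteed
  effect class (second-codon-position substitutions are always
  nonsynonymous; third positions of fourfold codons always synonymous) —
  the Bernoulli ``ns_fraction`` label and sequence-level re-classification
  therefore agree exactly;
* an environment matrix with a configurable population-level correlation
  structure.

All randomness flows from ``SimConfig.seed`` through per-species substreams,
so regenerating one species is unaffected by reconfiguration of the others.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd

from .genes import GeneModel
from .universe import ConfigurationError, OrthologUniverse

# Gene geometry (bp): 60 nt 5'UTR | 72 nt exon 1 | 100 nt intron | 78 nt
# exon 2 | 60 nt 3'UTR. CDS = ATG + 48 fourfold-family codons + TAA = 150 nt.
_UTR = 60
_E1 = 72
_INTRON = 100
_E2 = 78
_SPAN = 2 * _UTR + _E1 + _INTRON + _E2  # 370
_CDS_LEN = _E1 + _E2  # 150
_GENES_PER_CHROM = 50
_SLOT = 500  # span + intergenic gap
_CODING_P = _CDS_LEN / _SPAN

# Fourfold-degenerate codon families (any third base keeps the amino acid).
_FOURFOLD = ("CT", "GT", "TC", "CC", "AC", "GC", "CG", "GG")
_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_COMP = np.zeros(256, dtype=np.uint8)
for a, b in zip(b"ACGT", b"TGCA"):
    _COMP[a] = b
# _OTHER[i] = the three base codes different from base i (as uint8 codes).
_OTHER = np.array([[b for b in _BASES if b != a] for a in _BASES], dtype=np.uint8)
_BASE_INDEX = np.zeros(256, dtype=np.int64)
for i, a in enumerate(_BASES):
    _BASE_INDEX[a] = i

DEFAULT_FACTORS = (
    "ASPVAL", "PRECYY", "SFROYY", "SLP25", "SRADYY", "SWB", "TAVEYY", "TWI25SS",
)


@dataclass
class SimConfig:
    """Study-design parameters for the synthetic three-species dataset.

    Defaults mirror the study conditions: three Brassicaceae species with
    ~16,000 annotated one-to-one orthologs each, a 12,485-gene shared core,
    six populations per species and eight topoclimatic factors.
    """

    species_ids: Tuple[str, ...] = ("Aal", "Aha", "Cre")
    annotated_sizes: Tuple[int, ...] = (15909, 16088, 16047)
    shared_all: int = 12485
    pairwise_extra: Mapping[Tuple[str, str], int] = field(default_factory=dict)
    n_pops: int = 6
    factor_names: Tuple[str, ...] = DEFAULT_FACTORS
    snps_per_gene: float = 21.0
    n_planted_convergent: int = 0
    planted_factor: str = "PRECYY"
    effect_shift: float = 0.0
    null_outlier_rate: float = 0.01
    ns_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self):
        k = len(self.species_ids)
        if len(self.annotated_sizes) != k:
            raise ConfigurationError("annotated_sizes must match species_ids")
        for p in (self.null_outlier_rate, self.ns_fraction):
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"probability {p} outside [0,1]")
        if self.effect_shift < 0:
            raise ConfigurationError("effect_shift must be >= 0")
        if self.snps_per_gene < 1:
            raise ConfigurationError("snps_per_gene must be >= 1")
        extra_by_species = {s: 0 for s in self.species_ids}
        for (s1, s2), n in self.pairwise_extra.items():
            if s1 not in extra_by_species or s2 not in extra_by_species:
                raise ConfigurationError(f"pairwise_extra names unknown species ({s1},{s2})")
            if n < 0:
                raise ConfigurationError("pairwise_extra counts must be >= 0")
            extra_by_species[s1] += n
            extra_by_species[s2] += n
        for s, size in zip(self.species_ids, self.annotated_sizes):
            need = self.shared_all + extra_by_species[s]
            if need > size:
                raise ConfigurationError(
                    f"species {s}: shared_all + pairwise extras = {need} "
                    f"exceeds annotated size {size}"
                )


def _locus_id(n: int) -> str:
    """Synthetic TAIR-style locus identifier (AT<chr>G<number>)."""
    return f"AT{1 + n % 5}G{(n // 5 + 1) * 10:05d}"


def gen_ortholog_universe(config: SimConfig) -> OrthologUniverse:
    """Build per-species gene lists with exact configured intersections.

    The first ``shared_all`` IDs form the three-way (all-species) core;
    ``pairwise_extra`` genes are shared by exactly one pair; everything else
    is species-private. Fully determined by the configuration.
    """
    counter = itertools.count()
    core = [_locus_id(next(counter)) for _ in range(config.shared_all)]
    lists: Dict[str, List[str]] = {s: list(core) for s in config.species_ids}
    for (s1, s2), n in sorted(config.pairwise_extra.items()):
        extra = [_locus_id(next(counter)) for _ in range(n)]
        lists[s1].extend(extra)
        lists[s2].extend(extra)
    for s, size in zip(config.species_ids, config.annotated_sizes):
        n_private = size - len(lists[s])
        lists[s].extend(_locus_id(next(counter)) for _ in range(n_private))
    return OrthologUniverse(
        species_ids=tuple(config.species_ids),
        annotated={s: frozenset(v) for s, v in lists.items()},
    )


def gen_gene_models(
    universe: OrthologUniverse, config: SimConfig, species: str
) -> List[GeneModel]:
    """Deterministic gene models (coordinates, strand, CDS) for one species.

    Genes are laid out in sorted-ID order, 50 per scaffold; each carries a
    two-exon CDS whose body codons come from fourfold-degenerate families
    (no internal stops, guaranteed synonymous sites).
    """
    si = universe.species_ids.index(species)
    rng = np.random.default_rng([config.seed, 2000 + si])
    genes = universe.sorted_genes(species)
    n = len(genes)
    strands = rng.choice(np.array(["+", "-"]), size=n)
    pidx = rng.integers(0, len(_FOURFOLD), size=(n, 48))
    tidx = rng.integers(0, 4, size=(n, 48))
    pre = np.array([[ord(c) for c in p] for p in _FOURFOLD], dtype=np.uint8)
    body = np.empty((n, 48, 3), dtype=np.uint8)
    body[:, :, :2] = pre[pidx]
    body[:, :, 2] = _BASES[tidx]
    cds = np.empty((n, _CDS_LEN), dtype=np.uint8)
    cds[:, :3] = np.frombuffer(b"ATG", dtype=np.uint8)
    cds[:, 3:147] = body.reshape(n, 144)
    cds[:, 147:] = np.frombuffer(b"TAA", dtype=np.uint8)
    models = []
    for j in range(n):
        chrom = f"{species}_scaf{1 + j // _GENES_PER_CHROM}"
        start = 201 + (j % _GENES_PER_CHROM) * _SLOT
        seg1 = (start + _UTR, start + _UTR + _E1 - 1)
        seg2 = (seg1[1] + _INTRON + 1, seg1[1] + _INTRON + _E2)
        models.append(
            GeneModel(
                species=species,
                gene_id=genes[j],
                chrom=chrom,
                start=start,
                end=start + _SPAN - 1,
                strand=str(strands[j]),
                cds_segments=(seg1, seg2),
                cds_sequence=cds[j].tobytes().decode("ascii"),
            )
        )
    return models


def _planted_genes(universe: OrthologUniverse, config: SimConfig) -> np.ndarray:
    core = np.array(sorted(universe.shared_core))
    if config.n_planted_convergent > core.size:
        raise ConfigurationError(
            f"n_planted_convergent {config.n_planted_convergent} exceeds "
            f"shared core size {core.size}"
        )
    if config.n_planted_convergent == 0:
        return np.array([], dtype=core.dtype)
    rng = np.random.default_rng([config.seed, 1])
    return rng.choice(core, size=config.n_planted_convergent, replace=False)


def gen_scan_table(
    universe: OrthologUniverse, config: SimConfig
) -> Dict[str, pd.DataFrame]:
    """Per-species SNP tables with selection statistics and variant fields.

    Every gene receives at least one SNP (1 + Poisson counts). Null SNPs:
    selection posteriors Beta(1,20), association z-scores N(0,1) per factor.
    A fraction ``null_outlier_rate`` of SNPs carries Beta(20,1) posteriors
    (mostly with positive locus effect sign). All SNPs inside planted
    convergent genes get ``effect_shift`` added to the planted factor's
    z-score, in every species. Coding SNPs are nonsynonymous with probability
    ``ns_fraction`` and placed at codon positions that guarantee the label.
    """
    if not universe.species_ids:
        raise ConfigurationError("empty universe")
    if config.n_planted_convergent and config.planted_factor not in config.factor_names:
        raise ConfigurationError(
            f"planted_factor {config.planted_factor!r} not among factors"
        )
    planted = _planted_genes(universe, config)
    tables = {}
    for si, species in enumerate(universe.species_ids):
        tables[species] = _species_table(universe, config, species, si, planted)
    return tables


def _species_table(universe, config, species, si, planted):
    rng = np.random.default_rng([config.seed, 1000 + si])
    models = gen_gene_models(universe, config, species)
    n = len(models)
    genes = np.array([m.gene_id for m in models])
    starts = np.array([m.start for m in models])
    chroms = np.array([m.chrom for m in models])
    plus = np.array([m.strand == "+" for m in models])
    cds = np.frombuffer(
        "".join(m.cds_sequence for m in models).encode("ascii"), dtype=np.uint8
    ).reshape(n, _CDS_LEN)

    counts = 1 + rng.poisson(max(config.snps_per_gene - 1.0, 0.0), size=n)
    gi = np.repeat(np.arange(n), counts)
    m = gi.size

    coding = rng.random(m) < _CODING_P
    is_ns = rng.random(m) < config.ns_fraction
    # Coding sites: codons 1..48 (skip start/stop); position 1 (second base)
    # forces a nonsynonymous change, position 2 (fourfold third base) a
    # synonymous one.
    codon = rng.integers(1, 49, size=m)
    within = np.where(is_ns, 1, 2)
    ci = 3 * codon + within
    ref_spliced = cds[gi, ci]
    alt_spliced = _OTHER[_BASE_INDEX[ref_spliced], rng.integers(0, 3, size=m)]
    gen_off = np.where(plus[gi], ci, _CDS_LEN - 1 - ci)
    ref_cod = np.where(plus[gi], ref_spliced, _COMP[ref_spliced])
    alt_cod = np.where(plus[gi], alt_spliced, _COMP[alt_spliced])
    pos_cod = np.where(
        gen_off < _E1,
        starts[gi] + _UTR + gen_off,
        starts[gi] + _UTR + _E1 + _INTRON + (gen_off - _E1),
    )
    # Noncoding sites: uniform over UTRs and the intron.
    r = rng.integers(0, 2 * _UTR + _INTRON, size=m)
    off_nc = np.where(
        r < _UTR, r, np.where(r < _UTR + _INTRON, _UTR + _E1 + (r - _UTR), _SPAN - _UTR + (r - _UTR - _INTRON))
    )
    pos_nc = starts[gi] + off_nc
    ref_nc = _BASES[rng.integers(0, 4, size=m)]
    alt_nc = _OTHER[_BASE_INDEX[ref_nc], rng.integers(0, 3, size=m)]

    pos = np.where(coding, pos_cod, pos_nc)
    ref = np.where(coding, ref_cod, ref_nc)
    alt = np.where(coding, alt_cod, alt_nc)
    effect = np.where(
        coding, np.where(is_ns, "nonsynonymous", "synonymous"), "noncoding"
    )

    is_out = rng.random(m) < config.null_outlier_rate
    posterior = np.where(is_out, rng.beta(20, 1, size=m), rng.beta(1, 20, size=m))
    sign_null = rng.choice(np.array([1, -1]), size=m)
    sign_out = np.where(rng.random(m) < 0.9, 1, -1)
    alpha_sign = np.where(is_out, sign_out, sign_null)

    z = rng.standard_normal((m, len(config.factor_names)))
    if planted.size:
        in_planted = np.isin(genes[gi], planted)
        pf = config.factor_names.index(config.planted_factor)
        z[in_planted, pf] += config.effect_shift

    qual = np.round(rng.gamma(4.0, 20.0, size=m), 1)
    coverage = np.maximum(1, np.rint(rng.lognormal(np.log(60.0), 0.35, size=m))).astype(int)
    p0 = rng.beta(0.8, 0.8, size=m)
    af = np.clip(p0[:, None] + rng.normal(0, 0.08, size=(m, config.n_pops)), 0, 1)
    cf = af + rng.uniform(-0.08, 0.08, size=af.shape)
    bad = rng.random(af.shape) < 0.005
    cf = np.clip(cf + bad * rng.choice(np.array([0.3, -0.3]), size=af.shape), 0, 1)
    af = np.round(af, 4)
    cf = np.round(cf, 4)
    alt_count = np.maximum(1, np.rint(af.mean(axis=1) * coverage)).astype(int)
    biallelic = rng.random(m) < 0.98

    alt_str = _byte_str(alt)
    ref_str = _byte_str(ref)
    extra = _OTHER[_BASE_INDEX[alt], rng.integers(0, 3, size=m)]
    clash = extra == ref
    extra[clash] = _OTHER[_BASE_INDEX[alt[clash]], 0]
    clash = extra == ref
    extra[clash] = _OTHER[_BASE_INDEX[alt[clash]], 1]
    alt_full = np.where(
        biallelic, alt_str, np.char.add(np.char.add(alt_str, ","), _byte_str(extra))
    )

    df = pd.DataFrame(
        {
            "species": species,
            "chrom": chroms[gi],
            "pos": pos,
            "gene": genes[gi],
            "ref": ref_str,
            "alt": alt_full,
            "qual": qual,
            "coverage": coverage,
            "alt_count": alt_count,
            "effect": effect,
            "posterior": posterior,
            "alpha_sign": alpha_sign,
        }
    )
    for j, f in enumerate(config.factor_names):
        df[f"z_{f}"] = z[:, j]
    for p in range(config.n_pops):
        df[f"af_{p + 1}"] = af[:, p]
    for p in range(config.n_pops):
        df[f"cf_{p + 1}"] = cf[:, p]
    df = df.sort_values(["chrom", "pos"], kind="mergesort").reset_index(drop=True)
    return df


def _byte_str(b: np.ndarray) -> np.ndarray:
    return b.view("S1").astype("U1")


def default_target_correlation(k: int, rho: float = 0.3) -> np.ndarray:
    """Compound-symmetry correlation target (moderately correlated factors)."""
    t = np.full((k, k), rho)
    np.fill_diagonal(t, 1.0)
    return t


def gen_env_matrix(
    n_pops: int,
    factor_names: Sequence[str],
    target_correlation: np.ndarray | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Populations x factors matrix with a target correlation structure.

    Columns are Gaussian with (asymptotically) the requested correlation
    matrix, produced via an eigen-decomposition factor so rank-deficient
    (but PSD) targets — e.g. duplicated factors — are allowed.
    """
    k = len(factor_names)
    if target_correlation is None:
        target = np.eye(k)
    else:
        target = np.asarray(target_correlation, dtype=float)
    if target.shape != (k, k) or not np.allclose(target, target.T):
        raise ConfigurationError("target correlation must be symmetric k x k")
    if not np.allclose(np.diag(target), 1.0):
        raise ConfigurationError("target correlation must have unit diagonal")
    w, v = np.linalg.eigh(target)
    if w.min() < -1e-8:
        raise ConfigurationError(
            f"target correlation is not positive semi-definite (min eigenvalue {w.min():.3g})"
        )
    loading = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((n_pops, k)) @ loading.T
    return pd.DataFrame(
        x, index=[f"pop{i + 1}" for i in range(n_pops)], columns=list(factor_names)
    )
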