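"""Gene models, SNP-to-gene mapping, coding-effect triage and candidate sets.

A gene is a *candidate* for an analysis (the directional-selection outlier
scan, or one environmental factor) in one species iff it is annotated with a
one-to-one ortholog key and contains at least one SNP flagged significant
under that analysis. Candidate sets are the inputs to the cross-species
overlap resampling in :mod:`convergescan.overlap`.

Effect triage distinguishes only nonsynonymous / synonymous / noncoding:
the amino-acid level classes that the downstream enrichment statistics use.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from intervaltree import IntervalTree

from .universe import OrthologUniverse

OUTLIER_ANALYSIS = "outlier"

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


class DataError(ValueError):
    """Inconsistent input data (e.g. REF allele disagreeing with the CDS)."""


def _revcomp(s: str) -> str:
    return s.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GeneModel:
    """A gene with its coding structure on a 1-based, closed coordinate system.

    ``cds_segments`` are genomic intervals in ascending order; for minus-strand
    genes the spliced coding sequence is the reverse complement of their
    concatenation. ``cds_sequence`` is the spliced sequence on the coding
    strand, length divisible by 3.
    """

    species: str
    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str
    cds_segments: Tuple[Tuple[int, int], ...]
    cds_sequence: str

    def __post_init__(self):
        if self.start < 1 or self.end < self.start:
            raise DataError(f"{self.gene_id}: malformed span [{self.start},{self.end}]")
        if self.strand not in "+-":
            raise DataError(f"{self.gene_id}: strand must be + or -")
        if len(self.cds_sequence) % 3:
            raise DataError(f"{self.gene_id}: CDS length not divisible by 3")
        prev_end = 0
        total = 0
        for s, e in self.cds_segments:
            if s <= prev_end or e < s or s < self.start or e > self.end:
                raise DataError(f"{self.gene_id}: bad CDS segment ({s},{e})")
            prev_end = e
            total += e - s + 1
        if self.cds_segments and total != len(self.cds_sequence):
            raise DataError(
                f"{self.gene_id}: CDS segments cover {total} bp but sequence "
                f"has {len(self.cds_sequence)}"
            )

    def cds_offset(self, pos: int) -> int | None:
        """Spliced coding-strand index of genomic position, or None if noncoding."""
        off = 0
        for s, e in self.cds_segments:
            if s <= pos <= e:
                genomic = off + (pos - s)
                if self.strand == "+":
                    return genomic
                return len(self.cds_sequence) - 1 - genomic
            off += e - s + 1
        return None


def classify_effect(model: GeneModel, pos: int, ref: str, alt: str) -> str:
    """Triage a single-nucleotide substitution as NS / synonymous / noncoding.

    The affected codon is translated before and after the substitution,
    strand-aware. Raises :class:`DataError` when the REF allele contradicts
    the gene's CDS sequence.
    """
    if len(ref) != 1 or len(alt) != 1:
        raise DataError("only single-nucleotide substitutions are classified")
    ci = model.cds_offset(pos)
    if ci is None:
        return "noncoding"
    ref_c, alt_c = ref.upper(), alt.upper()
    if model.strand == "-":
        ref_c, alt_c = ref_c.translate(_COMPLEMENT), alt_c.translate(_COMPLEMENT)
    if model.cds_sequence[ci].upper() != ref_c:
        raise DataError(
            f"{model.gene_id}: REF {ref} at {model.chrom}:{pos} does not match "
            f"CDS base {model.cds_sequence[ci]}"
        )
    codon_i = ci // 3
    codon = model.cds_sequence[3 * codon_i : 3 * codon_i + 3].upper()
    within = ci % 3
    mutated = codon[:within] + alt_c + codon[within + 1 :]
    before = str(Seq(codon).translate())
    after = str(Seq(mutated).translate())
    return "synonymous" if before == after else "nonsynonymous"


def map_snps_to_genes(snps: pd.DataFrame, models: Sequence[GeneModel]) -> pd.DataFrame:
    """Assign each SNP to every gene whose span contains its position.

    Spans are 1-based closed, endpoints inclusive; a SNP inside two
    overlapping genes yields one output row per gene. SNPs outside all genes
    keep ``gene`` as missing. Requires columns ``chrom`` and ``pos``.
    """
    trees: Dict[str, IntervalTree] = {}
    for m in models:
        trees.setdefault(m.chrom, IntervalTree()).addi(m.start, m.end + 1, m.gene_id)
    out_idx: List[int] = []
    genes: List[object] = []
    chroms = snps["chrom"].to_numpy()
    positions = snps["pos"].to_numpy()
    for i in range(len(snps)):
        tree = trees.get(chroms[i])
        hits = sorted(iv.data for iv in tree[positions[i]]) if tree is not None else []
        if hits:
            for g in hits:
                out_idx.append(i)
                genes.append(g)
        else:
            out_idx.append(i)
            genes.append(pd.NA)
    out = snps.iloc[out_idx].reset_index(drop=True)
    out["gene"] = genes
    return out


@dataclass
class CandidateSetCollection:
    """Candidate ortholog sets per (analysis, species), with NS evidence.

    ``sets[(a, s)]`` — genes of species ``s`` that are candidates under
    analysis ``a``. ``flagged_ns[(a, s)]`` — the subset whose significant SNP
    under ``a`` is itself nonsynonymous. ``ns_genes[s]`` — all annotated genes
    of ``s`` containing at least one nonsynonymous SNP (any SNP, significant
    or not): the background notion used for NS enrichment.
    """

    species_ids: Tuple[str, ...]
    analyses: Tuple[str, ...]
    sets: Dict[Tuple[str, str], frozenset]
    flagged_ns: Dict[Tuple[str, str], frozenset]
    ns_genes: Dict[str, frozenset]
    n_unannotated: Dict[str, int] = field(default_factory=dict)

    def shared(self, analysis: str, subset: Iterable[str] | None = None) -> frozenset:
        subset = tuple(subset) if subset is not None else self.species_ids
        out = frozenset(self.sets[(analysis, subset[0])])
        for s in subset[1:]:
            out &= self.sets[(analysis, s)]
        return out

    def sizes(self, analysis: str) -> Dict[str, int]:
        return {s: len(self.sets[(analysis, s)]) for s in self.species_ids}


def build_candidate_sets(
    flagged: Mapping[str, pd.DataFrame],
    universe: OrthologUniverse,
    factor_names: Sequence[str],
) -> CandidateSetCollection:
    """Aggregate per-SNP significance flags into per-species candidate gene sets.

    Each species table needs columns ``gene``, ``effect``, ``outlier`` (bool)
    and one boolean ``sig_<factor>`` column per factor. SNPs whose gene is
    missing or not annotated in that species' universe are dropped (counted in
    ``n_unannotated``): candidacy requires functional annotation.
    """
    analyses = (OUTLIER_ANALYSIS,) + tuple(factor_names)
    sets: Dict[Tuple[str, str], frozenset] = {}
    flagged_ns: Dict[Tuple[str, str], frozenset] = {}
    ns_genes: Dict[str, frozenset] = {}
    n_unannot: Dict[str, int] = {}
    species_ids = tuple(universe.species_ids)
    for s in species_ids:
        df = flagged[s]
        annotated = universe.annotated[s]
        in_univ = df["gene"].notna() & df["gene"].isin(annotated)
        any_flag = df["outlier"].astype(bool).copy()
        for f in factor_names:
            any_flag |= df[f"sig_{f}"].astype(bool)
        n_unannot[s] = int((any_flag & ~in_univ).sum())
        df = df[in_univ]
        is_ns = df["effect"] == "nonsynonymous"
        ns_genes[s] = frozenset(df.loc[is_ns, "gene"])
        for a in analyses:
            col = df["outlier"] if a == OUTLIER_ANALYSIS else df[f"sig_{a}"]
            col = col.astype(bool)
            sets[(a, s)] = frozenset(df.loc[col, "gene"])
            flagged_ns[(a, s)] = frozenset(df.loc[col & is_ns, "gene"])
    return CandidateSetCollection(
        species_ids=species_ids,
        analyses=analyses,
        sets=sets,
        flagged_ns=flagged_ns,
        ns_genes=ns_genes,
        n_unannotated=n_unannot,
    )


def overlap_table(collection: CandidateSetCollection) -> pd.DataFrame:
    """Cross-species candidate overlap summary, one row per analysis.

    Columns: per-species candidate counts; every pairwise intersection; the
    all-species intersection; ``shared_with_ns`` (shared genes containing a
    nonsynonymous SNP in every species); ``shared_with_flagged_ns`` (shared
    genes whose NS SNP is itself significant under the analysis in every
    species — the per-analysis top candidates); plus a final ``unique`` row
    deduplicating genes across analyses.
    """
    sp = collection.species_ids
    if len(sp) < 2:
        raise ValueError("need at least two species")
    pairs = [(sp[i], sp[j]) for i in range(len(sp)) for j in range(i + 1, len(sp))]
    rows = []
    union_all: set = set()
    union_ns: set = set()
    union_topc: set = set()
    for a in collection.analyses:
        row: Dict[str, object] = {"analysis": a}
        for s in sp:
            row[s] = len(collection.sets[(a, s)])
        for s1, s2 in pairs:
            row[f"{s1}&{s2}"] = len(collection.shared(a, (s1, s2)))
        shared = collection.shared(a)
        with_ns = set(shared)
        for s in sp:
            with_ns &= collection.ns_genes[s]
        topc = set(shared)
        for s in sp:
            topc &= collection.flagged_ns[(a, s)]
        row["shared_all"] = len(shared)
        row["shared_with_ns"] = len(with_ns)
        row["shared_with_flagged_ns"] = len(topc)
        rows.append(row)
        union_all |= shared
        union_ns |= with_ns
        union_topc |= topc
    rows.append(
        {
            "analysis": "unique",
            "shared_all": len(union_all),
            "shared_with_ns": len(union_ns),
            "shared_with_flagged_ns": len(union_topc),
        }
    )
    return pd.DataFrame(rows)


def top_candidates(collection: CandidateSetCollection) -> pd.DataFrame:
    """Genes carrying, in every species, a significant nonsynonymous SNP
    under the same single analysis (one factor, or the outlier scan).

    Returns a deduplicated table (gene, analyses) with all qualifying
    analyses listed, sorted by gene.
    """
    hits: Dict[str, List[str]] = {}
    for a in collection.analyses:
        qualifying = collection.shared(a)
        for s in collection.species_ids:
            qualifying &= collection.flagged_ns[(a, s)]
        for g in qualifying:
            hits.setdefault(g, []).append(a)
    rows = [
        {"gene": g, "analyses": ";".join(a_list)} for g, a_list in sorted(hits.items())
    ]
    return pd.DataFrame(rows, columns=["gene", "analyses"])
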