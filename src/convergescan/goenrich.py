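"""GO-term over-representation of candidate genes with Fisher's exact test.

Annotations are propagated up the ontology (true-path rule: a gene annotated
to a term is annotated to all its ancestors) before testing. Each term with
a background gene count strictly between the size bounds (more than four,
fewer than 1,000 by default) gets a one-sided Fisher's exact p from the
2x2 table candidate/non-candidate x term/non-term; q-values are
Benjamini-Hochberg, and terms are enriched at q below the FDR level.

Per-term classic Fisher testing is used; decorrelating variants of
hierarchical GO testing (elim/weight) are deliberately not replicated.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Iterable, Mapping, Set

import networkx as nx
import obonet
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class GoAnnotationSet:
    dag: nx.DiGraph  # edges child -> parent
    direct: Dict[str, Set[str]]
    propagated: Dict[str, Set[str]]


def load_dag(path) -> nx.DiGraph:
    """Load an ontology as a child->parent DiGraph.

    Accepts an OBO file (``.obo``; ``is_a`` edges) or a two-column TSV of
    (child, parent) edges.
    """
    path = Path(path)
    if path.suffix == ".obo":
        multi = obonet.read_obo(path)
        dag = nx.DiGraph()
        dag.add_nodes_from(multi.nodes)
        dag.add_edges_from(
            (u, v) for u, v, k in multi.edges(keys=True) if k == "is_a"
        )
        return dag
    edges = pd.read_csv(path, sep="\t", header=None, names=["child", "parent"])
    dag = nx.DiGraph()
    dag.add_edges_from(edges.itertuples(index=False, name=None))
    return dag


def load_annotations(path) -> Dict[str, Set[str]]:
    """Two-column TSV (gene, term) -> gene -> set of directly annotated terms."""
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"])
    out: Dict[str, Set[str]] = {}
    for gene, term in df.itertuples(index=False, name=None):
        out.setdefault(str(gene), set()).add(str(term))
    return out


def propagate_annotations(
    direct: Mapping[str, Iterable[str]], dag: nx.DiGraph
) -> Dict[str, Set[str]]:
    """Close each gene's term set under ancestry (true-path rule)."""
    if not nx.is_directed_acyclic_graph(dag):
        raise ValueError("ontology graph contains a cycle")
    ancestors: Dict[str, Set[str]] = {}
    out: Dict[str, Set[str]] = {}
    for gene, terms in direct.items():
        closed: Set[str] = set()
        for t in terms:
            closed.add(t)
            if t in dag:
                if t not in ancestors:
                    # edges run child -> parent, so graph-descendants are
                    # ontology ancestors
                    ancestors[t] = nx.descendants(dag, t)
                closed |= ancestors[t]
        out[gene] = closed
    return out


def build_annotation_set(
    direct: Mapping[str, Iterable[str]], dag: nx.DiGraph
) -> GoAnnotationSet:
    direct_sets = {g: set(t) for g, t in direct.items()}
    return GoAnnotationSet(
        dag=dag, direct=direct_sets, propagated=propagate_annotations(direct_sets, dag)
    )


def go_scan(
    candidates: Iterable[str],
    background: Iterable[str],
    annotations: GoAnnotationSet,
    min_genes: int = 5,
    max_genes: int = 999,
    fdr: float = 0.01,
) -> pd.DataFrame:
    """Per-term Fisher enrichment of candidates against the background.

    Terms are tested iff their propagated background gene count lies in
    [min_genes, max_genes]. Returns a table sorted by p with columns term,
    n_candidates, n_background, candidates_in_term, background_in_term,
    p, q, enriched.
    """
    cand = set(candidates)
    bg = set(background)
    if not cand <= bg:
        raise ValueError("candidate genes must be a subset of the background")
    term_genes: Dict[str, Set[str]] = {}
    for gene in bg:
        for t in annotations.propagated.get(gene, ()):
            term_genes.setdefault(t, set()).add(gene)
    rows = []
    for term, genes in sorted(term_genes.items()):
        k_bg = len(genes)
        if not min_genes <= k_bg <= max_genes:
            continue
        k_cand = len(genes & cand)
        table = [
            [k_cand, len(cand) - k_cand],
            [k_bg - k_cand, len(bg) - len(cand) - (k_bg - k_cand)],
        ]
        _, p = stats.fisher_exact(table, alternative="greater")
        rows.append(
            {
                "term": term,
                "n_candidates": len(cand),
                "n_background": len(bg),
                "candidates_in_term": k_cand,
                "background_in_term": k_bg,
                "p": p,
            }
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "term", "n_candidates", "n_background", "candidates_in_term",
                "background_in_term", "p", "q", "enriched",
            ]
        )
    out = pd.DataFrame(rows)
    out["q"] = multipletests(out["p"].to_numpy(), method="fdr_bh")[1]
    out["enriched"] = out["q"] < fdr
    return out.sort_values(["p", "term"], kind="mergesort").reset_index(drop=True)
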