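"""miRNA target consolidation and GO over-representation analysis.

Targets of the DE miRNA set are consolidated by intersecting computationally
predicted interactions above a score threshold (aggregate P_CT > 0.9 by
default, strict inequality) with experimentally validated interactions; a
gene qualifies when at least one query miRNA predicts it above threshold and
at least one query miRNA validates it.

Over-representation of the consolidated gene list in each gene set uses the
one-sided upper-tail hypergeometric test — population N (background genes),
K successes (term genes in background), n draws (query genes) — with
Benjamini-Hochberg FDR across the tested terms and significance at
FDR < 0.05.  Term relatedness is summarized as a shared-gene graph and an
average-linkage dendrogram on 1 - Jaccard distance between term gene sets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy import stats

from ._cluster import average_linkage, leaf_order, to_newick
from .assay_stats import bh_adjust
from .core_io import GeneSetCollection, TargetTable, ValidationError


@dataclass
class TargetSelection:
    """Consolidated target genes with their supporting query miRNAs."""

    mirnas: list[str]
    threshold: float
    genes: list[str]
    support: dict[str, dict[str, list[str]]] = field(default_factory=dict)
    # support[gene] = {"predicted": [...mirnas], "validated": [...mirnas]}


@dataclass
class TermGraph:
    graph: nx.Graph
    dendrogram_newick: str
    leaf_order: list[str]


def consolidate_targets(
    mirnas: list[str],
    predicted: TargetTable,
    validated: TargetTable,
    threshold: float = 0.9,
) -> TargetSelection:
    """Intersect predicted (score strictly above threshold) and validated targets."""
    if not (0.0 <= threshold <= 1.0):
        raise ValidationError("consolidate_targets: threshold must be in [0, 1]")
    query = set(mirnas)
    pred = predicted.subset("predicted")
    pred = pred[pred["mirna"].isin(query) & (pred["score"] > threshold)]
    val = validated.subset("validated")
    val = val[val["mirna"].isin(query)]

    pred_by_gene = pred.groupby("gene")["mirna"].agg(sorted)
    val_by_gene = val.groupby("gene")["mirna"].agg(sorted)
    genes = sorted(set(pred_by_gene.index) & set(val_by_gene.index))
    support = {
        g: {"predicted": list(pred_by_gene[g]), "validated": list(val_by_gene[g])} for g in genes
    }
    return TargetSelection(
        mirnas=sorted(query), threshold=threshold, genes=genes, support=support
    )


def hypergeom_enrich(
    query: list[str] | set[str],
    gsc: GeneSetCollection,
    background: set[str] | None = None,
    fdr: float = 0.05,
) -> pd.DataFrame:
    """Hypergeometric over-representation of ``query`` in every term of ``gsc``.

    Returns one row per term: k (overlap), K (term size in background), n
    (query size), N (background size), p_hyper, fdr, significant, members.
    Sorted by fdr, then p, then term_id.
    """
    if background is None:
        background = set(gsc.background) if gsc.background is not None else set(gsc.union())
    background = set(background)
    if not background:
        raise ValidationError("hypergeom_enrich: empty background")
    query_set = set(query)
    stray = query_set - background
    if stray:
        raise ValidationError(
            f"hypergeom_enrich: query gene(s) {sorted(stray)[:5]} not in background"
        )
    N, n = len(background), len(query_set)
    rows = []
    for term, (name, genes) in gsc.sets.items():
        term_genes = genes & background
        K = len(term_genes)
        members = sorted(term_genes & query_set)
        k = len(members)
        # upper tail: P(X >= k) for X ~ Hypergeom(N, K, n)
        p = float(stats.hypergeom.sf(k - 1, N, K, n)) if k > 0 else 1.0
        p = min(p, 1.0)
        rows.append(
            {
                "term_id": term,
                "term_name": name,
                "k": k,
                "K": K,
                "n": n,
                "N": N,
                "p_hyper": p,
                "members": tuple(members),
            }
        )
    out = pd.DataFrame(rows).set_index("term_id")
    out["fdr"] = bh_adjust(out["p_hyper"].tolist()) if len(out) else []
    out["significant"] = out["fdr"] < fdr
    out = out.sort_values(["fdr", "p_hyper", "term_id"], kind="mergesort")
    return out


def top_terms(records: pd.DataFrame, n: int = 30) -> pd.DataFrame:
    """First ``n`` terms by ascending FDR (ties: ascending p, then term_id)."""
    ordered = records.sort_index(kind="mergesort").sort_values(
        ["fdr", "p_hyper"], kind="mergesort"
    )
    return ordered.head(n)


def term_graph(records: pd.DataFrame, min_shared: int = 1) -> TermGraph:
    """Shared-gene graph and similarity dendrogram over significant terms.

    Nodes carry the member-gene count and FDR; an edge joins two terms whose
    member-gene sets share at least ``min_shared`` genes, weighted by that
    count.  The dendrogram clusters terms by average linkage on 1 - Jaccard
    similarity of their member-gene sets.
    """
    sig = records[records["significant"]] if "significant" in records.columns else records
    graph = nx.Graph()
    terms = list(sig.index)
    member_sets = {t: set(sig.at[t, "members"]) for t in terms}
    for t in terms:
        graph.add_node(t, n_genes=len(member_sets[t]), fdr=float(sig.at[t, "fdr"]))
    for i, a in enumerate(terms):
        for b in terms[i + 1 :]:
            shared = len(member_sets[a] & member_sets[b])
            if shared >= min_shared:
                graph.add_edge(a, b, weight=shared)
    if len(terms) < 2:
        newick = f"{terms[0]};" if terms else ""
        return TermGraph(graph=graph, dendrogram_newick=newick, leaf_order=list(terms))

    m = len(terms)
    dist = np.zeros((m, m))
    for i in range(m):
        for j in range(i + 1, m):
            a, b = member_sets[terms[i]], member_sets[terms[j]]
            union = len(a | b)
            jac = len(a & b) / union if union else 0.0
            dist[i, j] = dist[j, i] = 1.0 - jac
    Z = average_linkage(dist)
    order = leaf_order(Z, m)
    return TermGraph(
        graph=graph,
        dendrogram_newick=to_newick(Z, terms),
        leaf_order=[terms[i] for i in order],
    )
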