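"""Hypergeometric term enrichment and kappa-statistic functional networks.

Terms from a GMT annotation are tested for over-representation in a query
gene set by the right-tailed hypergeometric test over an expressed-gene
universe, BH-corrected. Enriched terms become nodes of a network whose edges
join term pairs with Cohen's kappa (chance-corrected agreement of the two
binary membership vectors over the universe) at or above a threshold; the
connected components are merged into functional groups while two groups share
at least a given fraction of their gene sets, and each group is labeled by
its lowest-p member term.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests


def hypergeom_enrich(
    query: set[str],
    gmt: dict[str, set[str]],
    universe: set[str],
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Right-tailed hypergeometric enrichment of each GMT term in the query.

    Terms are intersected with the universe first; the query must be a subset
    of the universe. Columns: term, n_term, n_overlap, pvalue, padj, enriched.
    """
    if not set(query) <= set(universe):
        raise ValueError("query genes must be a subset of the universe")
    M = len(universe)
    N = len(query)
    rows = []
    for term, genes in gmt.items():
        annotated = genes & universe
        k = len(annotated & query)
        n = len(annotated)
        # right tail includes the observed overlap
        p = float(hypergeom.sf(k - 1, M, n, N)) if n else 1.0
        rows.append(
            dict(term=term, n_term=n, n_overlap=k,
                 overlap_genes=sorted(annotated & query), pvalue=min(p, 1.0))
        )
    out = pd.DataFrame(rows)
    if out.empty:
        return out.assign(padj=[], enriched=[])
    _, padj, _, _ = multipletests(out["pvalue"], method="fdr_bh")
    out["padj"] = padj
    out["enriched"] = out["padj"] <= alpha
    return out.sort_values("pvalue", kind="stable").reset_index(drop=True)


def kappa(term_a: set[str], term_b: set[str], universe: set[str]) -> float:
    """Cohen's kappa between two term memberships over the universe.

    With a = |A∩B|, b = |A\\B|, c = |B\\A|, d the rest of the universe:
    Po = (a+d)/|U|, Pe = ((a+b)(a+c) + (c+d)(b+d)) / |U|^2,
    kappa = (Po - Pe) / (1 - Pe); 1.0 when the memberships are identical.
    """
    U = len(universe)
    if U == 0:
        raise ValueError("universe must be non-empty")
    A = term_a & universe
    B = term_b & universe
    a = len(A & B)
    b = len(A - B)
    c = len(B - A)
    d = U - a - b - c
    po = (a + d) / U
    pe = ((a + b) * (a + c) + (c + d) * (b + d)) / (U * U)
    if pe == 1.0:
        return 1.0 if po == 1.0 else 0.0
    return (po - pe) / (1.0 - pe)


@dataclass
class KappaNetwork:
    graph: nx.Graph
    groups: pd.DataFrame  # term -> group id, group label
    edges: pd.DataFrame


def build_network(
    enrichment: pd.DataFrame,
    gmt: dict[str, set[str]],
    universe: set[str],
    kappa_threshold: float = 0.35,
    overlap_threshold: float = 0.5,
) -> KappaNetwork:
    """Kappa network over the enriched terms, with merged functional groups.

    Edges join enriched term pairs with kappa >= ``kappa_threshold``. Initial
    groups are the connected components; groups are then merged iteratively
    (term pairs processed in lexicographic order) while two groups share at
    least ``overlap_threshold`` of the smaller group's gene union. Each group
    is labeled with its member term of lowest enrichment p.
    """
    enriched = enrichment[enrichment["enriched"]] if len(enrichment) else enrichment
    terms = sorted(enriched["term"]) if len(enriched) else []
    pvals = dict(zip(enrichment.get("term", []), enrichment.get("pvalue", [])))
    sets = {t: gmt[t] & universe for t in terms}

    G = nx.Graph()
    G.add_nodes_from(terms)
    edge_rows = []
    for i, t1 in enumerate(terms):
        for t2 in terms[i + 1:]:
            k = kappa(sets[t1], sets[t2], universe)
            if k >= kappa_threshold:
                G.add_edge(t1, t2, kappa=k)
                edge_rows.append(dict(source=t1, target=t2, kappa=k))

    groups = [sorted(c) for c in nx.connected_components(G)]
    groups.sort()
    merged = True
    while merged and len(groups) > 1:
        merged = False
        for i in range(len(groups)):
            for j in range(i + 1, len(groups)):
                gi = set().union(*(sets[t] for t in groups[i])) if groups[i] else set()
                gj = set().union(*(sets[t] for t in groups[j])) if groups[j] else set()
                denom = min(len(gi), len(gj))
                if denom and len(gi & gj) / denom >= overlap_threshold:
                    groups[i] = sorted(set(groups[i]) | set(groups[j]))
                    del groups[j]
                    merged = True
                    break
            if merged:
                break
        groups.sort()

    rows = []
    for gid, members in enumerate(groups):
        label = min(members, key=lambda t: (pvals.get(t, 1.0), t))
        genes = set().union(*(sets[t] for t in members)) if members else set()
        for t in members:
            rows.append(dict(term=t, group=gid, group_label=label,
                             group_n_genes=len(genes)))
    return KappaNetwork(
        graph=G,
        groups=pd.DataFrame(rows, columns=["term", "group", "group_label", "group_n_genes"]),
        edges=pd.DataFrame(edge_rows, columns=["source", "target", "kappa"]),
    )
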