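"""Phenotype anchoring of gene BMCs and cross-chemical set logic.

A gene is phenotype-associated when it has a concentration response
(``has_cr``) and its BMC lies at or below the anchoring concentration — the
lowest tested concentration that elicits the phenotype. Phenotype-unique genes
are the associated genes minus any gene with a concentration response to a
comparator chemical. Multi-way overlaps (Venn regions) and comparisons with
external DEG tables complete the picture.
"""

from __future__ import annotations

from itertools import product

import pandas as pd

from .genebmc import GeneBMCRecord


def anchor_genes(records: list[GeneBMCRecord], anchor_uM: float) -> set[str]:
    """Genes with has_cr and BMC <= anchor_uM (boundary inclusive)."""
    return {
        r.gene
        for r in records
        if r.has_cr and r.bmc_uM is not None and r.bmc_uM <= anchor_uM
    }


def unique_filter(
    target_set: set[str], *comparator_records: list[GeneBMCRecord]
) -> set[str]:
    """Remove genes with a concentration response in ANY comparator chemical.

    The comparator's BMC value is irrelevant; its ``has_cr`` flag alone
    excludes the gene.
    """
    excluded: set[str] = set()
    for records in comparator_records:
        excluded |= {r.gene for r in records if r.has_cr}
    return set(target_set) - excluded


def multiway_overlap(named_sets: dict[str, set[str]]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Full Venn decomposition of k named sets.

    Returns (membership, regions): per-gene boolean membership vectors, and
    per-region counts over all 2^k regions with percentages relative to the
    union. Region keys are '&'-joined subsets of the set names ('none' for the
    empty pattern, which always counts 0 within the union).
    """
    names = list(named_sets)
    union = sorted(set().union(*named_sets.values()) if named_sets else set())
    membership = pd.DataFrame(
        {name: [g in named_sets[name] for g in union] for name in names},
        index=pd.Index(union, name="gene"),
    )
    rows = []
    for pattern in product([True, False], repeat=len(names)):
        if union:
            mask = pd.Series(True, index=membership.index)
            for name, inside in zip(names, pattern):
                mask &= membership[name] == inside
            count = int(mask.sum())
        else:
            count = 0
        label = "&".join(n for n, inside in zip(names, pattern) if inside) or "none"
        rows.append(
            dict(
                region=label,
                count=count,
                percent=100.0 * count / len(union) if union else 0.0,
            )
        )
    return membership, pd.DataFrame(rows)


def compare_external(
    gene_set: set[str], external: dict[str, pd.DataFrame]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Join a gene set against external DEG tables (gene, log2FC[, padj]).

    Identifiers are lowercased before joining. Returns (summary, log2fc):
    per-source shared/missing counts, and the log2FC matrix across sources for
    genes shared with at least one source. Genes in no source are "unique to
    bulk".
    """
    norm_set = {g.lower() for g in gene_set}
    summary_rows = []
    fc = pd.DataFrame(index=pd.Index(sorted(norm_set), name="gene"))
    for name, table in external.items():
        tab = table.copy()
        tab["gene"] = tab["gene"].astype(str).str.lower()
        tab = tab.drop_duplicates("gene").set_index("gene")
        shared = norm_set & set(tab.index)
        summary_rows.append(
            dict(
                source=name,
                n_external=len(tab),
                n_shared=len(shared),
                n_unique_to_bulk=len(norm_set - set(tab.index)),
            )
        )
        if "log2FC" in tab.columns:
            fc[name] = tab["log2FC"].reindex(fc.index)
    in_any = fc.notna().any(axis=1) if len(fc.columns) else pd.Series(False, index=fc.index)
    fc = fc[in_any]
    return pd.DataFrame(summary_rows), fc
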