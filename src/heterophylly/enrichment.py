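"""Hypergeometric term enrichment and target-based functional propagation.

Over-representation of a term among a selected gene set (e.g. the
trend-associated mRNAs) is tested with the upper-tail hypergeometric
distribution: with N genes in the universe, m annotated to the term, n
selected and k in the overlap, p = P(X >= k).  P-values are adjusted
across terms with the Benjamini-Hochberg procedure.

Non-coding RNAs have no direct annotation; their putative functions are the
union of the terms of the mRNAs they regulate — one silencing step away for
a miRNA, one ceRNA edge away for a lncRNA/circRNA decoy.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests


@dataclass
class AnnotationMap:
    """term id -> gene set annotation over a fixed gene universe."""

    terms: dict[str, set]
    universe: set

    def __post_init__(self) -> None:
        for term, genes in self.terms.items():
            extra = set(genes) - self.universe
            if extra:
                raise ValueError(
                    f"term {term!r} annotates genes outside the universe, "
                    f"e.g. {next(iter(extra))!r}"
                )


def hypergeom_enrich(selection: Iterable, annotation: AnnotationMap) -> pd.DataFrame:
    """Upper-tail hypergeometric enrichment of every term, BH-adjusted.

    Returns a DataFrame sorted by p-value with columns ``term_id``, ``k``
    (overlap), ``m`` (term size), ``n`` (selection size), ``N`` (universe
    size), ``pvalue`` and ``qvalue``.
    """
    selection = set(selection)
    outside = selection - annotation.universe
    if outside:
        raise ValueError(
            f"selection contains genes outside the universe: {sorted(outside)[:5]}"
        )
    N, n = len(annotation.universe), len(selection)
    rows = []
    for term, genes in annotation.terms.items():
        m = len(genes)
        k = len(genes & selection)
        # P(X >= k) for X ~ Hypergeom(N, m, n)
        p = float(stats.hypergeom.sf(k - 1, N, m, n))
        rows.append((term, k, m, n, N, p))
    out = pd.DataFrame(rows, columns=["term_id", "k", "m", "n", "N", "pvalue"])
    if len(out):
        out["qvalue"] = multipletests(out["pvalue"], method="fdr_bh")[1]
        out = out.sort_values("pvalue", kind="stable").reset_index(drop=True)
    else:
        out["qvalue"] = pd.Series(dtype=float)
    return out


def term_counts(selection: Iterable, annotation: AnnotationMap) -> pd.Series:
    """Raw per-term annotation counts within a selection (no testing)."""
    selection = set(selection)
    return pd.Series(
        {t: len(g & selection) for t, g in annotation.terms.items()}, name="count"
    ).sort_values(ascending=False)


def annotate_ncrna_by_targets(
    ncrna_id: str,
    network: nx.MultiDiGraph,
    mrna_annotations: Mapping[str, set],
) -> set:
    """Terms propagated to a non-coding RNA from its regulated mRNAs.

    For a miRNA: union over mRNAs one silencing edge away.  For a decoy
    (lncRNA/circRNA): union over mRNAs one ceRNA edge away.  mRNAs missing
    from ``mrna_annotations`` contribute nothing.
    """
    if ncrna_id not in network:
        raise ValueError(f"unknown RNA id {ncrna_id!r}")
    rna_class = network.nodes[ncrna_id].get("rna_class")
    wanted_kind = "silencing" if rna_class == "miRNA" else "ceRNA"
    terms: set = set()
    for _, nbr, data in network.out_edges(ncrna_id, data=True):
        if data.get("kind") != wanted_kind:
            continue
        if network.nodes[nbr].get("rna_class") == "mRNA":
            terms |= set(mrna_annotations.get(nbr, ()))
    return terms
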