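"""Competing-endogenous-RNA (ceRNA) pairing and the tripartite network.

Under the ceRNA hypothesis a lncRNA or circRNA that carries response
elements for the same miRNA as an mRNA can act as a decoy ("sponge"),
titrating the miRNA away and de-repressing the mRNA.  Two consequences are
used as calling rules:

* a candidate decoy-mRNA pair must share at least one targeting miRNA;
* the decoy and the mRNA should co-vary — here, carry the *same* trend
  label (both CLI or both OLI), neither ``none``.

Strict mode additionally demands that every shared miRNA carry the
*opposite* label, the pattern expected when the sponge is actually pulling
the miRNA down.  The assembled network is tripartite: miRNA silencing
edges point at mRNAs and decoys, ceRNA edges link decoys to mRNAs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

import networkx as nx

from .targeting import TargetPair

logger = logging.getLogger(__name__)

DECOY_CLASSES = ("lncRNA", "circRNA")


@dataclass(frozen=True)
class CeRNAEdge:
    """A called decoy-mRNA ceRNA interaction."""

    decoy_id: str
    mrna_id: str
    shared_mirna_ids: frozenset
    decoy_label: str
    mrna_label: str


def shared_mirna_pairs(
    pairs: Iterable[TargetPair],
    classes: Mapping[str, str],
    decoy_class: str | None = None,
) -> list[tuple[str, str, frozenset]]:
    """Candidate (decoy, mRNA) pairs sharing at least one targeting miRNA.

    ``classes`` maps transcript id -> RNA class; decoys are transcripts of
    class ``decoy_class`` (or any of lncRNA/circRNA when None), partners
    are mRNAs.  The attached miRNA set is exactly the intersection of the
    two transcripts' targeting-miRNA sets.
    """
    if decoy_class is not None and decoy_class not in DECOY_CLASSES:
        raise ValueError(f"decoy class must be one of {DECOY_CLASSES}")
    wanted = (decoy_class,) if decoy_class else DECOY_CLASSES
    by_transcript: dict[str, set[str]] = {}
    for p in pairs:
        by_transcript.setdefault(p.transcript_id, set()).add(p.small_rna_id)
    decoys = [t for t in by_transcript if classes.get(t) in wanted]
    mrnas = [t for t in by_transcript if classes.get(t) == "mRNA"]
    out = []
    for d in decoys:
        for y in mrnas:
            shared = by_transcript[d] & by_transcript[y]
            if shared:
                out.append((d, y, frozenset(shared)))
    return out


def cerna_edges(
    candidates: Iterable[tuple[str, str, frozenset]],
    labels: Mapping[str, str],
    strict: bool = False,
) -> list[CeRNAEdge]:
    """Call ceRNA edges from shared-miRNA candidates and trend labels.

    An edge is kept when decoy and mRNA carry the same non-``none`` trend
    label.  In strict mode every shared miRNA must in addition carry the
    opposite label; miRNAs failing that are removed from the shared set and
    the edge is dropped if none survive.
    """
    edges = []
    for decoy, mrna, shared in candidates:
        ld, lm = labels.get(decoy), labels.get(mrna)
        if ld is None or lm is None:
            logger.warning("dropping candidate (%s, %s): missing trend label", decoy, mrna)
            continue
        if ld != lm or ld == "none":
            continue
        kept = frozenset(shared)
        if strict:
            opposite = "OLI" if ld == "CLI" else "CLI"
            kept = frozenset(m for m in shared if labels.get(m) == opposite)
            if not kept:
                continue
        edges.append(CeRNAEdge(decoy, mrna, kept, ld, lm))
    return edges


def assemble_network(
    silencing_edges: Iterable[TargetPair],
    cerna: Iterable[CeRNAEdge],
    labels: Mapping[str, str],
    classes: Mapping[str, str],
) -> tuple[nx.MultiDiGraph, dict]:
    """Tripartite regulatory network plus a count summary.

    Nodes carry ``rna_class`` and ``trend``; edges carry ``kind`` —
    ``silencing`` (miRNA -> mRNA or miRNA -> decoy) or ``ceRNA``
    (decoy -> mRNA, with the shared miRNA ids).  Raises if an edge
    references an RNA with no known class.
    """
    g = nx.MultiDiGraph()

    def add_node(rna_id: str) -> None:
        if rna_id not in classes:
            raise ValueError(f"edge references RNA of unknown class: {rna_id!r}")
        g.add_node(
            rna_id, rna_class=classes[rna_id], trend=labels.get(rna_id, "none")
        )

    for p in silencing_edges:
        add_node(p.small_rna_id)
        add_node(p.transcript_id)
        g.add_edge(
            p.small_rna_id, p.transcript_id, kind="silencing", expectation=p.expectation
        )
    for e in cerna:
        add_node(e.decoy_id)
        add_node(e.mrna_id)
        g.add_edge(
            e.decoy_id, e.mrna_id, kind="ceRNA",
            shared_mirnas=",".join(sorted(e.shared_mirna_ids)),
        )
    node_counts: dict[str, int] = {}
    trend_counts: dict[str, int] = {}
    for _, data in g.nodes(data=True):
        node_counts[data["rna_class"]] = node_counts.get(data["rna_class"], 0) + 1
        trend_counts[data["trend"]] = trend_counts.get(data["trend"], 0) + 1
    edge_counts: dict[str, int] = {}
    for _, _, data in g.edges(data=True):
        edge_counts[data["kind"]] = edge_counts.get(data["kind"], 0) + 1
    summary = {
        "nodes": node_counts,
        "nodes_by_trend": trend_counts,
        "edges": edge_counts,
        "n_nodes": g.number_of_nodes(),
        "n_edges": g.number_of_edges(),
    }
    return g, summary
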