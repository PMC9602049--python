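"""Term enrichment and piRNA regulatory-network construction.

Enrichment of GO terms / KEGG-style pathways among target genes uses the
two-sided Fisher exact test on the 2x2 table (targeted vs background, in-term
vs not), significant at p < 0.05 (strict). Networks are tripartite: called
DEpiRNAs connect to their energy-gated target genes, and genes connect to the
pathway-category terms they are annotated to. Exports are Cytoscape-ready
SIF (tab-separated) and GraphML.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd
from scipy import stats

from .diffexpr import bh_adjust
from .targetscan import DuplexHit


@dataclass
class TermMap:
    """gene -> annotation terms, with term labels and namespaces."""

    gene2terms: dict[str, set[str]]
    labels: dict[str, str] = field(default_factory=dict)
    namespaces: dict[str, str] = field(default_factory=dict)

    def __post_init__(self):
        referenced = set().union(*self.gene2terms.values()) if self.gene2terms else set()
        for t in referenced:
            self.labels.setdefault(t, t)
            self.namespaces.setdefault(t, "pathway")

    def genes_with(self, term: str) -> set[str]:
        return {g for g, ts in self.gene2terms.items() if term in ts}

    def terms(self) -> list[str]:
        return sorted(set().union(*self.gene2terms.values()) if self.gene2terms else set())


def enrich_terms(
    targets: Iterable[str],
    background: Iterable[str],
    term_map: TermMap,
    alpha: float = 0.05,
    bh: bool = False,
) -> pd.DataFrame:
    """Per-term Fisher exact enrichment of targets against a background.

    Table per term: a = targeted genes in term, b = targeted not in term,
    c = background-only genes in term, d = background-only not in term.
    Significance is p < alpha, strict. Rows ordered by (p, term id).
    """
    targets = set(targets)
    background = set(background)
    if not background:
        raise ValueError("background gene set is empty")
    if not targets <= background:
        raise ValueError("targets must be a subset of the background")
    rest = background - targets
    rows = []
    for term in term_map.terms():
        in_term = term_map.genes_with(term)
        a = len(targets & in_term)
        b = len(targets) - a
        c = len(rest & in_term)
        d = len(rest) - c
        odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            {
                "term": term,
                "label": term_map.labels.get(term, term),
                "namespace": term_map.namespaces.get(term, "pathway"),
                "n_target_in": a,
                "n_target_out": b,
                "n_bg_in": c,
                "n_bg_out": d,
                "odds_ratio": odds,
                "p_value": p,
            }
        )
    out = pd.DataFrame(
        rows,
        columns=[
            "term", "label", "namespace", "n_target_in", "n_target_out",
            "n_bg_in", "n_bg_out", "odds_ratio", "p_value",
        ],
    )
    out = out.sort_values(["p_value", "term"], kind="mergesort").reset_index(drop=True)
    if bh:
        out["q_value"] = bh_adjust(out["p_value"].to_numpy())
    out["significant"] = out["p_value"] < alpha
    return out


def build_network(
    de_directions: Mapping[str, Mapping[str, str]],
    hits: Sequence[DuplexHit] | pd.DataFrame,
    term_map: TermMap,
    categories: Mapping[str, Sequence[str]],
    category: str | None = None,
) -> nx.DiGraph:
    """Construct the DEpiRNA -> gene -> pathway-category network.

    de_directions maps comparison name -> {pirna_id: "up"/"down"}; only these
    piRNAs enter the network. `hits` are energy-gated duplex hits. Genes are
    kept iff annotated to at least one configured pathway of the requested
    category (all categories when category is None). piRNA nodes are kept iff
    they retain at least one edge.
    """
    for cat, terms in categories.items():
        known = set(term_map.terms())
        missing = set(terms) - known
        if missing:
            raise ValueError(f"category {cat!r} names unknown terms: {sorted(missing)}")
    if category is not None:
        if category not in categories:
            raise ValueError(f"unknown category {category!r}")
        wanted = {category: categories[category]}
    else:
        wanted = dict(categories)
    term_category = {t: cat for cat, terms in wanted.items() for t in terms}

    if isinstance(hits, pd.DataFrame):
        hit_rows = [
            (r.pirna_id, r.transcript_id, float(r.delta_g)) for r in hits.itertuples(index=False)
        ]
    else:
        hit_rows = [(h.pirna_id, h.transcript_id, h.delta_g) for h in hits]

    pirna_info: dict[str, tuple[str, str]] = {}
    for comp, dirs in de_directions.items():
        for pid, direction in dirs.items():
            pirna_info[pid] = (comp, direction)

    G = nx.DiGraph()
    for pid, gene, dg in hit_rows:
        if pid not in pirna_info:
            continue
        gene_terms = term_map.gene2terms.get(gene, set())
        cats = {term_category[t] for t in gene_terms if t in term_category}
        if not cats:
            continue
        comp, direction = pirna_info[pid]
        G.add_node(pid, node_type="piRNA", comparison=comp, direction=direction)
        G.add_node(gene, node_type="gene")
        G.add_edge(pid, gene, delta_g=float(dg), comparison=comp, direction=direction)
        for t in gene_terms:
            if t in term_category:
                G.add_node(
                    t,
                    node_type="pathway",
                    category=term_category[t],
                    label=term_map.labels.get(t, t),
                )
                G.add_edge(gene, t)
    return G


def hub_stats(network: nx.DiGraph) -> pd.DataFrame:
    """Per-piRNA ranking by number of distinct target genes (desc, id asc)."""
    rows = []
    for node, data in network.nodes(data=True):
        if data.get("node_type") != "piRNA":
            continue
        genes = {
            nb for nb in network.successors(node)
            if network.nodes[nb].get("node_type") == "gene"
        }
        rows.append({"pirna_id": node, "n_target_genes": len(genes)})
    out = pd.DataFrame(rows, columns=["pirna_id", "n_target_genes"])
    return out.sort_values(
        ["n_target_genes", "pirna_id"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)


def network_summary(network: nx.DiGraph) -> dict[str, int]:
    types = [d.get("node_type") for _, d in network.nodes(data=True)]
    return {
        "n_pirna": types.count("piRNA"),
        "n_gene": types.count("gene"),
        "n_pathway": types.count("pathway"),
        "n_edges": network.number_of_edges(),
    }


def export_network(
    network: nx.DiGraph, sif_path: str | Path | None = None, graphml_path: str | Path | None = None
) -> None:
    """Write the network as SIF (source<TAB>relation<TAB>target) and GraphML.

    Tab-delimited SIF keeps node identifiers with internal whitespace intact;
    GraphML carries all node and edge attributes and round-trips through
    networkx.
    """
    if sif_path is not None:
        with open(sif_path, "w") as fh:
            for u, v in sorted(network.edges()):
                relation = (
                    "targets"
                    if network.nodes[u].get("node_type") == "piRNA"
                    else "annotated_to"
                )
                fh.write(f"{u}\t{relation}\t{v}\n")
    if graphml_path is not None:
        nx.write_graphml(network, str(graphml_path))


def read_sif(path: str | Path) -> set[tuple[str, str, str]]:
    out = set()
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            u, rel, v = line.split("\t")
            out.add((u, rel, v))
    return out
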