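"""Hypergeometric miRNA overtargeting and bipartite network assembly.

The triple filter: (1) per-gene overtargeting test — does a gene interact
with more differentially abundant miRNAs than expected under hypergeometric
sampling from the miRNA-target interaction universe; (2) restriction to a
cancer-gene-census list (genes somatically mutated in cancer tissue);
(3) plain hypergeometric gene-set enrichment of the retained genes. The
interaction universe is the intersection of two prediction sources plus
experimentally validated pairs, deduplicated.

The overtargeting statistic is formalized as a miRNA-draw hypergeometric:
population = all miRNAs in the universe (M), successes = DA miRNAs present
in it (K), draws = the miRNAs targeting the gene (n); the upper tail
P(X >= x) includes the observed count. An edge-draw alternative exists; the
miRNA-draw form is the standard reading and is locked in here. BH adjustment
runs separately within the up- and down-regulated screens (two families).

Identifier harmonization is exact string match after upper-casing; no alias
resolution.
"""

from __future__ import annotations

import logging
import warnings
from collections import defaultdict
from dataclasses import dataclass, field

import networkx as nx
import pandas as pd
from scipy.stats import hypergeom

from .core import InputError
from .da import bh_adjust

logger = logging.getLogger(__name__)

DEFAULT_P_CUT = 0.01
DEFAULT_FDR_CUT = 0.05


def harmonize(identifier: str) -> str:
    return str(identifier).strip().upper()


@dataclass
class InteractionUniverse:
    """Deduplicated (miRNA, gene, provenance) edge set.

    Provenance is ``predicted``, ``validated`` or ``both`` (the pair arises
    from prediction and validation). The miRNA and gene universes are the
    distinct endpoint sets.
    """

    edges: dict = field(default_factory=dict)  # (mirna, gene) -> provenance

    @classmethod
    def from_edges(cls, predicted: set, validated: set) -> "InteractionUniverse":
        predicted = {(harmonize(a), harmonize(b)) for a, b in predicted}
        validated = {(harmonize(a), harmonize(b)) for a, b in validated}
        edges = {}
        for pair in predicted | validated:
            if pair in predicted and pair in validated:
                edges[pair] = "both"
            elif pair in validated:
                edges[pair] = "validated"
            else:
                edges[pair] = "predicted"
        return cls(edges=edges)

    @property
    def mirna_universe(self) -> set:
        return {m for m, _ in self.edges}

    @property
    def gene_universe(self) -> set:
        return {g for _, g in self.edges}

    def targeting(self, gene: str) -> set:
        gene = harmonize(gene)
        return {m for (m, g) in self.edges if g == gene}

    def targeting_map(self) -> dict:
        out: dict = defaultdict(set)
        for m, g in self.edges:
            out[g].add(m)
        return dict(out)

    def __len__(self) -> int:
        return len(self.edges)


@dataclass
class OvertargetingResult:
    """Per-gene hypergeometric upper-tail test outcome."""

    gene_id: str
    n_targeting: int
    x_da: int
    K: int
    M: int
    pvalue: float
    fdr: float = 1.0
    direction: str = "up"


def build_universe(pred_a: set, pred_b: set, validated: set) -> InteractionUniverse:
    """Intersect two prediction sources and add validated pairs.

    edges = (pred_a AND pred_b) OR validated, with provenance per membership.
    """
    pred_a = {(harmonize(a), harmonize(b)) for a, b in pred_a}
    pred_b = {(harmonize(a), harmonize(b)) for a, b in pred_b}
    return InteractionUniverse.from_edges(predicted=pred_a & pred_b, validated=set(validated))


def overtargeting_test(
    u: InteractionUniverse, da_mirnas: set, gene: str, direction: str = "up"
) -> OvertargetingResult:
    """Upper-tail hypergeometric overtargeting test for one gene.

    With M miRNAs in the universe, K of them differentially abundant, and n
    miRNAs targeting the gene, p = P(X >= x_da) for
    X ~ Hypergeometric(M, K, n).
    """
    gene = harmonize(gene)
    if gene not in u.gene_universe:
        raise InputError(f"gene {gene!r} absent from the interaction universe")
    da = {harmonize(x) for x in da_mirnas} & u.mirna_universe
    targeting = u.targeting(gene)
    m_total = len(u.mirna_universe)
    k = len(da)
    n = len(targeting)
    x = len(targeting & da)
    p = float(hypergeom.sf(x - 1, m_total, k, n))
    return OvertargetingResult(
        gene_id=gene, n_targeting=n, x_da=x, K=k, M=m_total,
        pvalue=min(1.0, p), direction=direction,
    )


def _screen_one_direction(
    u: InteractionUniverse, da: set, direction: str, p_cut: float, fdr_cut: float
) -> list:
    da = {harmonize(x) for x in da} & u.mirna_universe
    if not da:
        warnings.warn(f"empty DA miRNA set for direction {direction!r} after "
                      "intersection with the universe; returning no results")
        return []
    m_total = len(u.mirna_universe)
    k = len(da)
    results = []
    for gene, targeting in sorted(u.targeting_map().items()):
        n = len(targeting)
        if n == 0:
            continue  # undefined draw
        x = len(targeting & da)
        p = float(min(1.0, hypergeom.sf(x - 1, m_total, k, n)))
        results.append(OvertargetingResult(gene, n, x, k, m_total, p, direction=direction))
    fdrs = bh_adjust([r.pvalue for r in results])
    for r, q in zip(results, fdrs):
        r.fdr = float(q)
    flagged = [r for r in results if r.pvalue < p_cut and r.fdr < fdr_cut]
    flagged.sort(key=lambda r: (r.pvalue, r.gene_id))
    return flagged


def screen_overtargeted(
    u: InteractionUniverse,
    da_up: set,
    da_down: set,
    p_cut: float = DEFAULT_P_CUT,
    fdr_cut: float = DEFAULT_FDR_CUT,
) -> tuple[list, list]:
    """Screen every gene in the universe against the up- and down-DA sets.

    BH adjustment is computed within each direction (two separate families);
    a gene is flagged when pvalue < p_cut and fdr < fdr_cut. Returns the
    flagged ``(up_results, down_results)`` sorted by p-value.
    """
    if not (0 < p_cut <= 1 and 0 < fdr_cut <= 1):
        raise InputError("p_cut and fdr_cut must lie in (0, 1]")
    up = _screen_one_direction(u, da_up, "up", p_cut, fdr_cut)
    down = _screen_one_direction(u, da_down, "down", p_cut, fdr_cut)
    return up, down


def census_filter(results: list, census_genes: set) -> list:
    """Keep results whose gene is in the cancer-gene-census list (order kept)."""
    census = {harmonize(g) for g in census_genes}
    return [r for r in results if r.gene_id in census]


def geneset_enrichment(query: set, collections: dict, background: set) -> pd.DataFrame:
    """Hypergeometric gene-set over-representation of ``query`` per collection.

    Each collection is intersected with the background; the upper-tail p is
    P(overlap >= observed) under sampling |query| genes from the background;
    BH across collections. Returns a DataFrame (set_name, set_size, overlap,
    pvalue, fdr) sorted by p-value.
    """
    background = {harmonize(g) for g in background}
    if not background:
        raise InputError("empty background")
    query = {harmonize(g) for g in query}
    stray = query - background
    if stray:
        raise InputError(f"query genes outside background: {sorted(stray)[:3]}")
    rows = []
    for name in sorted(collections):
        members = {harmonize(g) for g in collections[name]} & background
        overlap = len(members & query)
        p = float(min(1.0, hypergeom.sf(overlap - 1, len(background), len(members), len(query))))
        rows.append({"set_name": name, "set_size": len(members), "overlap": overlap, "pvalue": p})
    df = pd.DataFrame(rows, columns=["set_name", "set_size", "overlap", "pvalue"])
    df["fdr"] = bh_adjust(df["pvalue"]) if len(df) else []
    return df.sort_values(["pvalue", "set_name"], kind="stable").reset_index(drop=True)


# ---------------------------------------------------------------------------
# Bipartite network assembly and export

BipartiteNetwork = nx.Graph
HUB_DEGREE = 3


def build_network(
    u: InteractionUniverse,
    da_results: list,
    genes: list,
    category_map: dict | None = None,
) -> nx.Graph:
    """Assemble the bipartite miRNA-gene network for retained genes.

    Nodes are the retained overtargeted genes plus every DA miRNA with at
    least one universe edge to them; edges carry provenance
    (validated/predicted, thick vs thin in the usual rendering). Gene nodes
    carry their functional category and the expected tissue regulation —
    opposite to the circulating miRNA direction, since genes overtargeted by
    miRNAs that are up in the circulation are expected to be repressed in
    tissue. miRNA nodes get ``hub_flag`` when they target >= 3 genes within
    some category subnetwork.
    """
    category_map = {harmonize(g): c for g, c in (category_map or {}).items()}
    da_by_id = {harmonize(r.feature_id): r for r in da_results}
    g = nx.Graph()
    gene_dir = {}
    for res in genes:
        gid = harmonize(res.gene_id)
        if gid not in u.gene_universe:
            raise InputError(f"gene {gid!r} not in the interaction universe")
        gene_dir[gid] = res.direction
        g.add_node(
            gid,
            kind="gene",
            category=category_map.get(gid, ""),
            # expected regulation in target tissue opposes the miRNA direction
            regulation="down" if res.direction == "up" else "up",
        )
    for (mir, gene), provenance in sorted(u.edges.items()):
        if gene not in gene_dir or mir not in da_by_id:
            continue
        res = da_by_id[mir]
        if mir not in g:
            g.add_node(
                mir,
                kind="miRNA",
                regulation="up" if res.log2fc > 0 else "down",
                hub_flag=False,
            )
        g.add_edge(mir, gene, provenance=provenance)
    # hub flag: degree >= HUB_DEGREE within a category subnetwork
    categories = {d.get("category", "") for n, d in g.nodes(data=True) if d["kind"] == "gene"}
    for cat in categories:
        cat_genes = {n for n, d in g.nodes(data=True) if d["kind"] == "gene" and d.get("category", "") == cat}
        for mir in [n for n, d in g.nodes(data=True) if d["kind"] == "miRNA"]:
            deg = sum(1 for nb in g.neighbors(mir) if nb in cat_genes)
            if deg >= HUB_DEGREE:
                g.nodes[mir]["hub_flag"] = True
    return g


def _canonical(g: nx.Graph) -> nx.Graph:
    out = nx.Graph()
    for n in sorted(g.nodes):
        out.add_node(n, **{k: g.nodes[n][k] for k in sorted(g.nodes[n])})
    for a, b in sorted(tuple(sorted(e)) for e in g.edges):
        out.add_edge(a, b, **{k: g.edges[a, b][k] for k in sorted(g.edges[a, b])})
    return out


def export_network(g: nx.Graph, path, format: str = "graphml") -> None:
    """Write the network as GraphML (lossless round-trip) or SIF.

    SIF lines are ``mirna <provenance> gene`` with one line per edge; nodes
    and edges are emitted in canonical sorted order so exports are
    byte-stable.
    """
    canon = _canonical(g)
    if format == "graphml":
        nx.write_graphml(canon, path)
    elif format == "sif":
        with open(path, "w") as fh:
            for a, b in canon.edges:
                mir, gene = (a, b) if canon.nodes[a].get("kind") == "miRNA" else (b, a)
                fh.write(f"{mir}\t{canon.edges[a, b].get('provenance', 'predicted')}\t{gene}\n")
    else:
        raise InputError(f"unknown format {format!r}")


def import_network(path) -> nx.Graph:
    g = nx.read_graphml(path)
    return nx.relabel_nodes(g, {n: str(n) for n in g.nodes})
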