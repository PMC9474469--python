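"""Per-treatment co-occurrence networks and their comparison.

A network G(V, E) has the shared abundance-filtered OTU set as nodes —
isolated nodes are kept so densities are comparable across treatments —
and an edge for every OTU pair whose permutation p-value clears the
significance level.  Comparisons cover the global properties reported for
such networks: density, average path length over connected pairs, total
edges, exclusive edges, and modularity of a detected module partition.
"""

from __future__ import annotations

import itertools
from collections import Counter
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import networkx as nx
import pandas as pd

from .lsa import LsaResult
from .tables import ValidationError, taxon_for


def build_network(
    results: Sequence[LsaResult],
    nodes: Iterable[str],
    alpha: float = 0.05,
    treatment: str = "",
    taxonomy: Mapping[str, str] | None = None,
    rule: str = "standard",
) -> nx.Graph:
    """Threshold LSA results into a simple undirected graph.

    ``rule="standard"`` draws an edge iff p_value <= alpha.  The
    ``"inverted-upper"`` rule (edge iff the p-value upper bound exceeds
    alpha) reproduces a literal reading of thresholding the upper bound
    from above; it is degenerate at alpha = 1 and never the default.
    """
    if rule not in ("standard", "inverted-upper"):
        raise ValidationError(f"unknown edge rule {rule!r}")
    node_set = list(dict.fromkeys(nodes))
    g = nx.Graph(treatment=treatment, alpha=alpha)
    for v in node_set:
        g.add_node(v, taxon=taxon_for(taxonomy, v) if taxonomy else "unclassified")
    known = set(node_set)
    for r in results:
        if r.otu_a not in known or r.otu_b not in known:
            raise ValidationError(f"result pair ({r.otu_a}, {r.otu_b}) outside the node set")
        if rule == "standard":
            keep = r.p_value <= alpha
        else:
            keep = (r.p_upper if r.p_upper is not None else r.p_value) > alpha
        if keep:
            g.add_edge(
                r.otu_a, r.otu_b,
                ls_score=r.ls_score, sign=r.sign, delay=r.best_delay, p_value=r.p_value,
            )
    return g


def alpha_scan(
    results_by_treatment: Mapping[str, Sequence[LsaResult]],
    nodes: Iterable[str],
    alphas: Sequence[float],
) -> pd.DataFrame:
    """Network density per (treatment, alpha) — the significance-threshold
    robustness table.  Density is monotone nondecreasing in alpha."""
    if len(alphas) == 0:
        raise ValidationError("alpha list must be nonempty")
    node_list = list(dict.fromkeys(nodes))
    rows = []
    for treatment, results in results_by_treatment.items():
        for a in sorted(alphas):
            g = build_network(results, node_list, alpha=a, treatment=treatment)
            rows.append(
                {"treatment": treatment, "alpha": a,
                 "n_edges": g.number_of_edges(), "density": nx.density(g)}
            )
    return pd.DataFrame(rows).sort_values(["alpha", "treatment"]).reset_index(drop=True)


def degree_distribution(g: nx.Graph) -> pd.Series:
    """Exact degree histogram including degree-0 nodes (index: degree)."""
    counts = Counter(dict(g.degree()).values())
    degrees = range(0, (max(counts) if counts else 0) + 1)
    return pd.Series({d: counts.get(d, 0) for d in degrees}, name="n_nodes")


def degree_tail_count(g: nx.Graph, k: int) -> int:
    """Number of nodes with degree strictly greater than k."""
    return sum(1 for _, d in g.degree() if d > k)


@dataclass
class ModulePartition:
    """A node -> module assignment with its Newman-Girvan modularity."""

    assignment: dict[str, int]
    modularity: float
    module_sizes: dict[int, int]

    def members(self, module_id: int) -> set[str]:
        return {v for v, m in self.assignment.items() if m == module_id}


def detect_modules(g: nx.Graph, method: str = "greedy", seed: int = 0) -> ModulePartition:
    """Partition the network into modules by modularity maximization.

    ``greedy`` (Clauset-Newman-Moore, deterministic) is the default;
    ``louvain`` is seeded.  Module ids are assigned by descending module
    size.  Isolated nodes become singleton modules.  Raises on an edgeless
    graph, where modularity is undefined (division by zero edges).
    """
    if g.number_of_edges() == 0:
        raise ValidationError("modularity is undefined on an edgeless graph")
    if method == "greedy":
        communities = nx.community.greedy_modularity_communities(g)
    elif method == "louvain":
        communities = nx.community.louvain_communities(g, seed=seed)
    else:
        raise ValidationError(f"unknown method {method!r}; use 'greedy' or 'louvain'")
    communities = sorted((set(c) for c in communities), key=lambda c: (-len(c), min(c)))
    q = nx.community.modularity(g, communities)
    assignment = {v: i for i, c in enumerate(communities) for v in c}
    sizes = {i: len(c) for i, c in enumerate(communities)}
    return ModulePartition(assignment=assignment, modularity=float(q), module_sizes=sizes)


def largest_modules(
    partition: ModulePartition, g: nx.Graph, k: int = 2
) -> list[dict]:
    """The k largest modules with member taxa and within-module edge counts."""
    if k > len(partition.module_sizes):
        raise ValidationError(f"k={k} exceeds module count {len(partition.module_sizes)}")
    order = sorted(partition.module_sizes, key=lambda m: (-partition.module_sizes[m], m))
    out = []
    for mid in order[:k]:
        members = partition.members(mid)
        sub = g.subgraph(members)
        taxa = Counter(g.nodes[v].get("taxon", "unclassified") for v in members)
        out.append(
            {"module_id": mid, "nodes": members, "size": len(members),
             "within_edges": sub.number_of_edges(), "taxa": dict(taxa)}
        )
    return out


@dataclass
class GlobalProperties:
    density: float
    average_path_length: float  # over connected distinct pairs; nan if none
    total_edges: int
    excluded_pairs: int  # unordered node pairs with no connecting path
    n_nodes: int


def global_properties(g: nx.Graph) -> GlobalProperties:
    """Density, average path length and edge count of one network.

    Path length is averaged over connected, distinct node pairs only —
    these networks are routinely disconnected — and the number of excluded
    (unreachable) pairs is reported alongside.
    """
    n = g.number_of_nodes()
    if n < 2:
        raise ValidationError("need at least 2 nodes")
    total_pairs = n * (n - 1) // 2
    path_sum = 0
    connected_pairs = 0
    for component in nx.connected_components(g):
        sub = g.subgraph(component)
        cn = sub.number_of_nodes()
        if cn < 2:
            continue
        for _, lengths in nx.all_pairs_shortest_path_length(sub):
            path_sum += sum(lengths.values())
        connected_pairs += cn * (cn - 1) // 2
    apl = (path_sum / 2) / connected_pairs if connected_pairs else float("nan")
    return GlobalProperties(
        density=nx.density(g),
        average_path_length=apl,
        total_edges=g.number_of_edges(),
        excluded_pairs=total_pairs - connected_pairs,
        n_nodes=n,
    )


def exclusive_edges(a: nx.Graph, b: nx.Graph) -> int:
    """Edges present in ``a`` but absent in ``b`` (presence only, shared node set)."""
    if set(a.nodes) != set(b.nodes):
        raise ValidationError("networks must share the node set")
    ea = {frozenset(e) for e in a.edges}
    eb = {frozenset(e) for e in b.edges}
    return len(ea - eb)


def compare_networks(networks: Mapping[str, nx.Graph]) -> pd.DataFrame:
    """Global-property table plus pairwise exclusive-edge counts.

    One row per network with density / average path length / total edges,
    and one ``exclusive_vs_<other>`` column per other network.
    """
    labels = list(networks)
    rows = {}
    for lab in labels:
        p = global_properties(networks[lab])
        row = {
            "density": p.density,
            "average_path_length": p.average_path_length,
            "total_edges": p.total_edges,
            "excluded_pairs": p.excluded_pairs,
        }
        for other in labels:
            if other != lab:
                row[f"exclusive_vs_{other}"] = exclusive_edges(networks[lab], networks[other])
        rows[lab] = row
    return pd.DataFrame.from_dict(rows, orient="index")


def write_graphml(g: nx.Graph, path) -> None:
    """GraphML export with degree and module annotations when present."""
    h = g.copy()
    for v, d in h.degree():
        h.nodes[v]["degree"] = d
    nx.write_graphml(h, path)


def write_edge_list(g: nx.Graph, path) -> None:
    rows = [
        {"otu_a": min(u, v), "otu_b": max(u, v), **data}
        for u, v, data in g.edges(data=True)
    ]
    pd.DataFrame(rows, columns=["otu_a", "otu_b", "ls_score", "sign", "delay", "p_value"]).sort_values(
        ["otu_a", "otu_b"]
    ).to_csv(path, sep="\t", index=False)
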