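"""Signed distance-correlation tripartite networks with Leiden communities.

Associations between differential metabolites and the two explanatory node
classes — pharmacokinetic parameters and clinical/laboratory traits — are
measured by distance correlation (dCor), a dependence coefficient in [0, 1]
that is zero only under independence and is sensitive to monotone
non-linear relationships that Pearson's r misses. Because dCor is unsigned,
the direction of each association is read off the Pearson correlation of
the same pair.

Significance comes from a seeded permutation test of dCor (label
permutations of the parameter vector), BH-adjusted across the entire
metabolite × parameter grid of one timepoint. Edges are retained when
d > d_min (default 0.5) AND q < alpha (default 0.05), which keeps the graph
tripartite by construction: metabolites are the only connectors between PK
parameters and traits. Communities are found with the Leiden algorithm on
the d-weighted graph (sign kept as an edge attribute — modularity is only
defined for positive weights).

Note on permutation resolution: the smallest achievable p is 1/(B+1). With
hundreds of simultaneous tests, BH demands p below roughly alpha·k/m, so B
must comfortably exceed m/(alpha·k); the default B = 4999 resolves
q < 0.05 for as few as ~10 true edges among ~900 tests, where B = 999
could not.
"""

from __future__ import annotations

import json
import igraph as ig
import leidenalg
import networkx as nx
import numpy as np
import pandas as pd

from .diffabund import bh_adjust

__all__ = [
    "distance_correlation",
    "signed_association",
    "build_edges",
    "build_graph",
    "leiden_partition",
    "community_report",
    "graph_to_json",
    "write_graphml",
]


# ---------------------------------------------------------------------------
# distance correlation
# ---------------------------------------------------------------------------


def _centered_distances(x: np.ndarray) -> np.ndarray:
    """Double-centered Euclidean distance matrix of a 1-D sample."""
    x = np.asarray(x, dtype=float)
    d = np.abs(x[:, None] - x[None, :])
    row = d.mean(axis=1, keepdims=True)
    col = d.mean(axis=0, keepdims=True)
    return d - row - col + d.mean()


def distance_correlation(x: np.ndarray, y: np.ndarray) -> float:
    """Sample distance correlation of two 1-D samples (V-statistic form).

    dCov² = mean(A∘B) over the double-centered distance matrices A, B;
    dCor = dCov/√(dVarX·dVarY), defined as 0 when either dVar vanishes
    (constant input).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D arrays of equal length")
    if x.size < 4:
        raise ValueError("need at least 4 observations")
    A = _centered_distances(x)
    B = _centered_distances(y)
    dcov2 = (A * B).mean()
    dvarx2 = (A * A).mean()
    dvary2 = (B * B).mean()
    if dvarx2 <= 0 or dvary2 <= 0:
        return 0.0
    dcor2 = dcov2 / np.sqrt(dvarx2 * dvary2)
    return float(np.sqrt(max(dcor2, 0.0)))


def signed_association(
    metabolite: np.ndarray,
    parameter: np.ndarray,
    n_perms: int = 4999,
    rng: np.random.Generator | None = None,
) -> tuple[float, str, float, bool]:
    """(d, sign, p, ambiguous) for one metabolite–parameter pair.

    The sign is the sign of Pearson's r on the same values ('+' with an
    ambiguous flag when |r| < 1e-10); p is the permutation p-value
    (1 + #{d_perm ≥ d_obs})/(1 + B). Constant inputs give d = 0, p = 1,
    ambiguous sign.
    """
    rng = np.random.default_rng(0) if rng is None else rng
    x = np.asarray(metabolite, float)
    y = np.asarray(parameter, float)
    if np.std(x) == 0 or np.std(y) == 0:
        return 0.0, "+", 1.0, True
    d_obs = distance_correlation(x, y)
    A = _centered_distances(x)
    B = _centered_distances(y)
    dvarx = np.sqrt((A * A).mean())
    dvary = np.sqrt((B * B).mean())
    n = x.size
    count = 0
    for _ in range(n_perms):
        perm = rng.permutation(n)
        Bp = B[np.ix_(perm, perm)]
        dcov2 = (A * Bp).mean()
        d_perm = np.sqrt(max(dcov2, 0.0) / (dvarx * dvary))
        if d_perm >= d_obs - 1e-12:
            count += 1
    p = (1 + count) / (1 + n_perms)
    r = float(np.corrcoef(x, y)[0, 1])
    ambiguous = abs(r) < 1e-10
    sign = "+" if (ambiguous or r > 0) else "-"
    return d_obs, sign, p, ambiguous


def build_edges(
    metabolites: pd.DataFrame,
    parameters: pd.DataFrame,
    parameter_classes: dict,
    d_min: float = 0.5,
    alpha: float = 0.05,
    n_perms: int = 4999,
    seed: int = 0,
) -> pd.DataFrame:
    """Test every metabolite × parameter pair; BH across the whole grid.

    ``metabolites`` and ``parameters`` are subjects × variables tables with
    identical subject index; ``parameter_classes`` maps each parameter
    column to 'PK' or 'trait'. Returns the full edge table (one row per
    pair) with a ``retained`` flag for d > d_min AND q < alpha.

    Permutations are shared across metabolites for a given parameter (the
    permuted parameter's centered distance matrix is the expensive part),
    which keeps the test exact per pair and the run deterministic per seed.
    """
    common = metabolites.index.intersection(parameters.index)
    if len(common) < 4:
        raise ValueError("fewer than 4 subjects shared across inputs")
    M = metabolites.loc[common]
    P = parameters.loc[common]
    n = len(common)

    # centered distance matrices and dVars for every metabolite
    A_list, dvarx = {}, {}
    for m in M.columns:
        A = _centered_distances(M[m].to_numpy())
        A_list[m] = A
        dvarx[m] = np.sqrt(max((A * A).mean(), 0.0))

    rng = np.random.default_rng(seed)
    rows = []
    for pname in P.columns:
        y = P[pname].to_numpy(float)
        B = _centered_distances(y)
        dvary = np.sqrt(max((B * B).mean(), 0.0))
        perms = np.array([rng.permutation(n) for _ in range(n_perms)])
        Bstack = B[perms[:, :, None], perms[:, None, :]]  # (B, n, n)
        for m in M.columns:
            A = A_list[m]
            if dvarx[m] <= 0 or dvary <= 0:
                d_obs, p, r = 0.0, 1.0, 0.0
            else:
                dcov2 = (A * B).mean()
                d_obs = float(np.sqrt(max(dcov2, 0.0)) / np.sqrt(dvarx[m] * dvary))
                dcov2_perm = np.tensordot(Bstack, A, axes=([1, 2], [0, 1])) / (n * n)
                d_perm = np.sqrt(np.maximum(dcov2_perm, 0.0) / (dvarx[m] * dvary))
                p = float((1 + np.sum(d_perm >= d_obs - 1e-12)) / (1 + n_perms))
                r = float(np.corrcoef(M[m].to_numpy(float), y)[0, 1])
            ambiguous = abs(r) < 1e-10
            rows.append(
                {
                    "metabolite_id": m,
                    "parameter_name": pname,
                    "parameter_class": parameter_classes[pname],
                    "d": d_obs,
                    "sign": "+" if (ambiguous or r > 0) else "-",
                    "sign_ambiguous": ambiguous,
                    "p": p,
                }
            )
    edges = pd.DataFrame(rows)
    if len(edges) == 0:
        edges["q"] = []
        edges["retained"] = []
        return edges
    edges["q"] = bh_adjust(edges["p"].to_numpy())
    edges["retained"] = (edges["d"] > d_min) & (edges["q"] < alpha)
    return edges


# ---------------------------------------------------------------------------
# graph construction, communities, reports
# ---------------------------------------------------------------------------


def build_graph(edges: pd.DataFrame, retained_only: bool = True) -> nx.Graph:
    """Weighted tripartite graph from an edge table.

    Nodes carry ``node_class`` in {metabolite, PK, trait}; edges carry the
    dCor weight, sign and q. The tripartite constraint (metabolites as sole
    connectors) is validated structurally.
    """
    G = nx.Graph()
    sub = edges[edges["retained"]] if retained_only else edges
    for _, row in sub.iterrows():
        G.add_node(row["metabolite_id"], node_class="metabolite")
        G.add_node(row["parameter_name"], node_class=row["parameter_class"])
        G.add_edge(
            row["metabolite_id"],
            row["parameter_name"],
            weight=float(row["d"]),
            sign=row["sign"],
            q=float(row["q"]),
        )
    validate_tripartite(G)
    return G


def validate_tripartite(G: nx.Graph) -> None:
    """Raise unless metabolites are the only connectors between classes."""
    for u, v in G.edges:
        cu = G.nodes[u]["node_class"]
        cv = G.nodes[v]["node_class"]
        if "metabolite" not in (cu, cv) or cu == cv:
            raise ValueError(
                f"non-tripartite edge {u!r}({cu}) — {v!r}({cv}); metabolites "
                "must be the only connectors"
            )


def leiden_partition(
    G: nx.Graph, resolution: float = 1.0, seed: int = 0
) -> tuple[dict, float]:
    """Leiden communities of the d-weighted graph; returns (partition, Q).

    Q is the weighted Newman modularity of the partition (resolution 1).
    Isolated nodes are dropped before partitioning; module ids are
    renumbered by descending module size (ties by smallest member name) so
    reports are stable. Deterministic for a fixed seed.
    """
    H = G.subgraph([n for n in G.nodes if G.degree(n) > 0]).copy()
    if H.number_of_edges() == 0:
        return {}, float("nan")
    nodes = sorted(H.nodes)
    index = {n: i for i, n in enumerate(nodes)}
    edges = [(index[u], index[v]) for u, v in H.edges]
    weights = [float(H.edges[u, v].get("weight", 1.0)) for u, v in H.edges]
    g = ig.Graph(n=len(nodes), edges=edges)
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights=weights,
        resolution_parameter=resolution,
        seed=seed,
        n_iterations=-1,
    )
    membership = part.membership
    q = g.modularity(membership, weights=weights)
    groups: dict[int, list] = {}
    for node, mod in zip(nodes, membership):
        groups.setdefault(mod, []).append(node)
    ordered = sorted(groups.values(), key=lambda ns: (-len(ns), sorted(ns)[0]))
    partition = {n: i for i, ns in enumerate(ordered) for n in ns}
    return partition, float(q)


def community_report(G: nx.Graph, partition: dict) -> dict:
    """Per-module membership and the summary counts of a timepoint network."""
    modules: dict[int, dict] = {}
    for node, mod in partition.items():
        entry = modules.setdefault(
            mod, {"members": [], "metabolites": [], "PK": [], "trait": []}
        )
        entry["members"].append(node)
        cls = G.nodes[node]["node_class"]
        key = "metabolites" if cls == "metabolite" else cls
        entry[key].append(node)
    cross_module = 0
    for mod, entry in modules.items():
        entry["members"].sort()
        entry["metabolites"].sort()
        entry["PK"].sort()
        entry["trait"].sort()
        entry["n_within_edges"] = 0
    for u, v in G.edges:
        mu, mv = partition.get(u), partition.get(v)
        if mu is None or mv is None:
            continue
        if mu == mv:
            modules[mu]["n_within_edges"] += 1
        else:
            cross_module += 1
    classes = nx.get_node_attributes(G, "node_class")
    connected = [n for n in G.nodes if G.degree(n) > 0]
    return {
        "n_modules": len(modules),
        "n_edges": G.number_of_edges(),
        "n_cross_module_edges": cross_module,
        "n_metabolites": sum(1 for n in connected if classes[n] == "metabolite"),
        "n_pk_parameters": sum(1 for n in connected if classes[n] == "PK"),
        "n_traits": sum(1 for n in connected if classes[n] == "trait"),
        "modules": {int(k): modules[k] for k in sorted(modules)},
    }


def graph_to_json(G: nx.Graph, partition: dict, path=None) -> dict:
    """Serializable {nodes, edges, partition} payload; written when path given."""
    payload = {
        "nodes": [
            {"id": n, "node_class": G.nodes[n]["node_class"]}
            for n in sorted(G.nodes)
        ],
        "edges": [
            {
                "source": u,
                "target": v,
                "d": G.edges[u, v].get("weight"),
                "sign": G.edges[u, v].get("sign"),
                "q": G.edges[u, v].get("q"),
            }
            for u, v in sorted(G.edges)
        ],
        "partition": {str(k): int(v) for k, v in partition.items()},
    }
    if path is not None:
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1, sort_keys=True)
    return payload


def write_graphml(G: nx.Graph, path) -> None:
    nx.write_graphml(G, path)
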