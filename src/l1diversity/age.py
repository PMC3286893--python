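"""Age estimation of L1 subfamilies from sequence divergence.

Two estimators share the molecular-clock conversion ``age = divergence /
rate`` with the primate neutral rate 0.15%/site/myr as default:

* consensus divergence — each copy's mismatch proportion against the
  subfamily consensus is converted to a per-copy age; the subfamily age
  is the mean with its standard error (the headline method);
* network rho — a median-joining haplotype network is built per
  Bandelt-style iteration of minimum-spanning-network (MSN) construction
  with median (Steiner) vectors, and rho (the multiplicity-weighted mean
  mutational distance from the observed haplotypes to a root) is scaled
  by 1/(L x rate), with sigma estimated on the shortest-path tree.

Links established at any iteration are retained, so the final network
always contains the MSN over the observed haplotypes and spans them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .consensus import ColumnAlignment, majority_consensus
from .io import L1Element

__all__ = [
    "DivergenceEstimate",
    "AgeEstimate",
    "HaplotypeNetwork",
    "pairwise_divergence",
    "estimate_age_consensus",
    "build_mj_network",
    "estimate_age_rho",
    "component_age_table",
    "append_average_row",
    "age_table_wide",
]

DEFAULT_RATE = 0.0015  # substitutions / site / myr

_ACGT = frozenset("ACGT")


# ---------------------------------------------------------------------------
# Divergence


def pairwise_divergence(a: str, b: str) -> tuple[int, int, float]:
    """(mismatches, evaluable sites, proportion) between two gapped rows.

    Sites where either symbol is not A/C/G/T (gap, N) are excluded from
    both counts.  Zero evaluable sites is an error.
    """
    if len(a) != len(b):
        raise ValueError(f"unequal lengths: {len(a)} vs {len(b)}")
    mism = evaluable = 0
    for x, y in zip(a, b):
        if x in _ACGT and y in _ACGT:
            evaluable += 1
            if x != y:
                mism += 1
    if evaluable == 0:
        raise ValueError("no evaluable sites")
    return mism, evaluable, mism / evaluable


@dataclass
class DivergenceEstimate:
    """Per-copy divergences of an alignment against its consensus."""

    per_copy: list[tuple[str, int, int, float]]  # (id, mismatches, evaluable, proportion)
    mean_divergence: float
    se: float | None


@dataclass
class AgeEstimate:
    age_myr: float
    sd_myr: float | None  # None when undefined (single copy / root-only)
    method: str  # "consensus-divergence" or "network-rho"
    rate: float
    n: int = 0
    divergence: DivergenceEstimate | None = None


def estimate_age_consensus(
    alignment: ColumnAlignment, consensus: str, rate: float = DEFAULT_RATE
) -> AgeEstimate:
    """Divergence-clock age: mean per-copy divergence to consensus / rate.

    The reported sd is the standard error of the mean per-copy age;
    undefined (None) for a single copy.
    """
    if rate <= 0:
        raise ValueError("rate must be > 0")
    if len(consensus) != alignment.width:
        raise ValueError("consensus length != alignment width")
    per_copy = []
    for member_id, row in zip(alignment.member_ids, alignment.rows):
        mism, ev, prop = pairwise_divergence(row, consensus)
        per_copy.append((member_id, mism, ev, prop))
    props = np.array([p for _, _, _, p in per_copy])
    mean_div = float(props.mean())
    n = len(props)
    se = float(props.std(ddof=1) / np.sqrt(n)) if n > 1 else None
    ages = props / rate
    return AgeEstimate(
        age_myr=float(ages.mean()),
        sd_myr=float(ages.std(ddof=1) / np.sqrt(n)) if n > 1 else None,
        method="consensus-divergence",
        rate=rate,
        n=n,
        divergence=DivergenceEstimate(per_copy, mean_div, se),
    )


# ---------------------------------------------------------------------------
# Median-joining network


@dataclass
class HaplotypeNetwork:
    """Median-joining network over distinct haplotypes.

    ``graph`` is an undirected networkx graph whose nodes are haplotype
    strings with attributes ``observed`` (bool), ``multiplicity`` (int)
    and ``median`` (bool); edge weights are Hamming distances (>= 1).
    """

    graph: nx.Graph
    epsilon: int = 0
    L: int = 0

    @property
    def observed(self) -> list[str]:
        return [h for h, d in self.graph.nodes(data=True) if d["observed"]]

    @property
    def medians(self) -> list[str]:
        return [h for h, d in self.graph.nodes(data=True) if d["median"]]

    def multiplicity(self, hap: str) -> int:
        return self.graph.nodes[hap]["multiplicity"]


def _seq_matrix(haps: Sequence[str]) -> np.ndarray:
    return np.frombuffer("".join(haps).encode(), dtype=np.uint8).reshape(len(haps), -1)


def _hamming_rows(arr: np.ndarray) -> np.ndarray:
    n = arr.shape[0]
    D = np.zeros((n, n), dtype=np.int64)
    for i in range(n):
        D[i] = (arr != arr[i]).sum(axis=1)
    return D


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[max(ra, rb)] = min(ra, rb)


def _msn_links(D: np.ndarray, eps: int) -> list[tuple[int, int]]:
    """Minimum-spanning-network links with tolerance eps.

    T[i, j] is the smallest distance class at which i and j become
    connected when classes are processed in ascending order (Kruskal with
    whole-class merging); the link (i, j) is feasible iff
    ``D[i, j] <= T[i, j] + eps``.  At eps = 0 this is exactly the union of
    all minimum spanning trees.
    """
    n = D.shape[0]
    if n == 1:
        return []
    iu, ju = np.triu_indices(n, 1)
    dvals = D[iu, ju]
    T = np.zeros((n, n), dtype=np.int64)
    assigned = np.eye(n, dtype=bool)
    uf = _UnionFind(n)
    for d in np.unique(dvals):
        mask = dvals == d
        for a, b in zip(iu[mask], ju[mask]):
            uf.union(int(a), int(b))
        labels = np.fromiter((uf.find(x) for x in range(n)), dtype=np.int64, count=n)
        newly = (labels[:, None] == labels[None, :]) & ~assigned
        T[newly] = d
        assigned |= newly
        if assigned.all():
            break
    keep = dvals <= T[iu, ju] + eps
    return [(int(a), int(b)) for a, b in zip(iu[keep], ju[keep])]


def build_mj_network(
    haplotypes: Sequence[str],
    epsilon: int = 0,
    *,
    multiplicities: Sequence[int] | None = None,
    max_iterations: int = 25,
    max_medians_factor: int = 2,
) -> HaplotypeNetwork:
    """Median-joining network of a set of equal-length haplotypes.

    Identical sequences collapse to one node whose multiplicity is the
    number of copies.  The construction iterates: (1) compute the MSN with
    tolerance ``epsilon`` over the current node set; (2) for every triplet
    sharing at least two MSN links, compute its median (Steiner) vector —
    per-position majority, three-way ties taking the character of the
    lexicographically smallest triplet member — and its connection cost
    (sum of distances from the median to the triplet); (3) add all new
    medians within ``epsilon`` of the cheapest candidate.  Links
    established at any iteration are retained, and median vectors left
    with fewer than three links in the final MSN are pruned as obsolete.
    Tie-breaking is lexicographic throughout, so the result is
    deterministic regardless of input order.  ``max_iterations`` and
    ``max_medians_factor`` bound runtime on pathological inputs.
    """
    if not haplotypes:
        raise ValueError("no haplotypes")
    lengths = {len(h) for h in haplotypes}
    if len(lengths) != 1:
        raise ValueError(f"haplotypes have unequal lengths: {sorted(lengths)}")
    if multiplicities is None:
        multiplicities = [1] * len(haplotypes)
    mult: dict[str, int] = {}
    for hap, m in zip(haplotypes, multiplicities):
        mult[hap] = mult.get(hap, 0) + m

    nodes: list[str] = sorted(mult)  # insertion order: observed, then medians
    n_observed = len(nodes)
    is_median: list[bool] = [False] * n_observed
    arr = _seq_matrix(nodes)
    D = _hamming_rows(arr)

    links_acc: set[tuple[str, str]] = set()
    max_medians = max_medians_factor * n_observed + 8

    def record_links(links: list[tuple[int, int]]) -> None:
        for i, j in links:
            links_acc.add(tuple(sorted((nodes[i], nodes[j]))))

    for _ in range(max_iterations):
        links = _msn_links(D, epsilon)
        record_links(links)
        adjacency: dict[int, list[int]] = {}
        for i, j in links:
            adjacency.setdefault(i, []).append(j)
            adjacency.setdefault(j, []).append(i)
        triples = {
            tuple(sorted((u, v, w)))
            for u, neigh in adjacency.items()
            for v, w in itertools.combinations(sorted(neigh), 2)
        }
        if not triples:
            break
        # evaluate all triplet medians in one vectorized batch; the
        # majority is where(v == w, v, u) with the triple ordered so u is
        # the lexicographically smallest member
        node_set = set(nodes)
        candidates: dict[bytes, int] = {}
        tri = sorted(triples)
        order = sorted(range(len(nodes)), key=nodes.__getitem__)
        rank = np.empty(len(nodes), dtype=np.int64)
        rank[order] = np.arange(len(nodes))
        for chunk_start in range(0, len(tri), 512):
            chunk = np.array(tri[chunk_start : chunk_start + 512])
            ranks = rank[chunk]
            first = chunk[np.arange(len(chunk)), ranks.argmin(axis=1)]
            U = arr[first]
            V_idx, W_idx = [], []
            for row, f in zip(chunk, first):
                rest = [x for x in row if x != f]
                V_idx.append(rest[0])
                W_idx.append(rest[1])
            V, W = arr[V_idx], arr[W_idx]
            M = np.where(V == W, V, U)
            costs = (
                (M != U).sum(axis=1) + (M != V).sum(axis=1) + (M != W).sum(axis=1)
            )
            for row, cost in zip(M, costs):
                key = row.tobytes()
                if key.decode() in node_set:
                    continue
                if key not in candidates or cost < candidates[key]:
                    candidates[key] = int(cost)
        if not candidates or len(nodes) - n_observed >= max_medians:
            break
        lam = min(candidates.values())
        new = sorted(
            key.decode() for key, c in candidates.items() if c <= lam + epsilon
        )
        new_arr = _seq_matrix(new)
        # grow the distance matrix incrementally
        cross = np.stack([(arr != row).sum(axis=1) for row in new_arr], axis=1)
        inner = _hamming_rows(new_arr)
        D = np.block([[D, cross], [cross.T, inner]])
        nodes.extend(new)
        is_median.extend([True] * len(new))
        arr = np.vstack([arr, new_arr])

    # prune obsolete medians: fewer than 3 links in the current MSN
    while True:
        links = _msn_links(D, epsilon)
        record_links(links)
        degree = np.zeros(len(nodes), dtype=int)
        for i, j in links:
            degree[i] += 1
            degree[j] += 1
        obsolete = [
            i for i in range(len(nodes)) if is_median[i] and degree[i] < 3
        ]
        if not obsolete:
            break
        keep = np.ones(len(nodes), dtype=bool)
        keep[obsolete] = False
        nodes = [h for h, k in zip(nodes, keep) if k]
        is_median = [m for m, k in zip(is_median, keep) if k]
        arr = arr[keep]
        D = D[np.ix_(keep, keep)]

    index = {h: i for i, h in enumerate(nodes)}
    graph = nx.Graph()
    for h, med in zip(nodes, is_median):
        graph.add_node(h, observed=not med, median=med, multiplicity=mult.get(h, 0))
    for a, b in links_acc:
        if a in index and b in index:
            graph.add_edge(a, b, weight=int(D[index[a], index[b]]))
    return HaplotypeNetwork(graph=graph, epsilon=epsilon, L=len(nodes[0]))


def estimate_age_rho(
    network: HaplotypeNetwork,
    root: str,
    L: int,
    rate: float = DEFAULT_RATE,
) -> AgeEstimate:
    """rho-based network age: age = rho / (L x rate).

    rho is the multiplicity-weighted mean shortest-path distance (by edge
    weight, i.e. mutational steps) from each observed haplotype to the
    root.  sigma follows the branch-partition estimator on the shortest-
    path tree: sigma^2 = sum_e w_e (n_e / n)^2 with n_e the multiplicity
    carried through branch e.
    """
    if L <= 0 or rate <= 0:
        raise ValueError("L and rate must be > 0")
    G = network.graph
    if root not in G:
        raise ValueError("root haplotype is not a node of the network")
    pred, dist = nx.dijkstra_predecessor_and_distance(G, root, weight="weight")
    weighted = [
        (h, G.nodes[h]["multiplicity"])
        for h in G.nodes
        if G.nodes[h].get("observed") and G.nodes[h]["multiplicity"] > 0
    ]
    n_total = sum(m for _, m in weighted)
    if n_total == 0 or all(h == root for h, _ in weighted):
        return AgeEstimate(0.0, 0.0, "network-rho", rate, n=n_total)
    rho = sum(m * dist[h] for h, m in weighted) / n_total
    # shortest-path tree with deterministic parent choice
    parent = {
        h: min(pred[h]) for h in G.nodes if h != root and h in pred and pred[h]
    }
    carried: dict[tuple[str, str], float] = {}
    for h, m in weighted:
        node = h
        while node != root:
            p = parent[node]
            edge = (p, node)
            carried[edge] = carried.get(edge, 0.0) + m
            node = p
    sigma_sq = sum(
        G.edges[p, c]["weight"] * (m / n_total) ** 2 for (p, c), m in carried.items()
    )
    sigma = float(np.sqrt(sigma_sq))
    return AgeEstimate(
        age_myr=rho / (L * rate),
        sd_myr=sigma / (L * rate),
        method="network-rho",
        rate=rate,
        n=n_total,
    )


# ---------------------------------------------------------------------------
# Component x subfamily age table


def _group_by_subfamily(elements: Iterable[L1Element]) -> dict[str, list[L1Element]]:
    groups: dict[str, list[L1Element]] = {}
    for el in elements:
        key = el.subfamily if el.subfamily is not None else "unknown"
        groups.setdefault(key, []).append(el)
    return groups


def component_age_table(
    elements: Sequence[L1Element],
    rate: float = DEFAULT_RATE,
    *,
    epsilon: int = 0,
    include_network: bool = True,
    combined_component: tuple[str, int] | None = ("pORF2+3UTR", 662),
) -> pd.DataFrame:
    """Age estimates per (subfamily x component), with an Average row.

    Every element must carry all its component intervals.  When
    ``combined_component`` is given, a derived segment made of the last
    ``n`` bp of ORF2 plus the 3' UTR (the classic partial-ORF2 + 3' UTR
    dating segment, 662 + 202 = 864 bp by default) is dated as well.
    The Average row is the unweighted mean of the subfamily ages (and of
    their sds) per component and method.
    """
    groups = _group_by_subfamily(elements)
    comp_names = list(elements[0].components)
    records = []
    for sub in groups:
        members = groups[sub]
        slices: dict[str, list[str]] = {
            name: [el.component_seq(name) for el in members] for name in comp_names
        }
        if combined_component and "ORF2" in comp_names and "3UTR" in comp_names:
            label, porf2_len = combined_component
            seqs = []
            for el in members:
                o_start, o_end = el.components["ORF2"]
                u_start, u_end = el.components["3UTR"]
                seqs.append(el.sequence[o_end - porf2_len : o_end] + el.sequence[u_start:u_end])
            slices[label] = seqs
        for comp, seqs in slices.items():
            aln = ColumnAlignment(
                member_ids=[el.id for el in members], rows=seqs
            )
            cons = majority_consensus(aln)
            est = estimate_age_consensus(aln, cons, rate=rate)
            records.append(
                {
                    "subfamily": sub,
                    "component": comp,
                    "method": est.method,
                    "n": est.n,
                    "n_sites": len(cons),
                    "mean_divergence": est.divergence.mean_divergence,
                    "age_myr": est.age_myr,
                    "sd_myr": est.sd_myr,
                }
            )
            if include_network:
                haps = list(seqs)
                mults = [1] * len(haps)
                if cons not in set(haps):
                    # root the network at the consensus without letting it
                    # contribute to rho
                    haps.append(cons)
                    mults.append(0)
                net = build_mj_network(haps, epsilon=epsilon, multiplicities=mults)
                # the consensus roots the network; multiplicity 0 if unobserved
                rho_est = estimate_age_rho(net, cons, L=len(cons), rate=rate)
                records.append(
                    {
                        "subfamily": sub,
                        "component": comp,
                        "method": rho_est.method,
                        "n": rho_est.n,
                        "n_sites": len(cons),
                        "mean_divergence": np.nan,
                        "age_myr": rho_est.age_myr,
                        "sd_myr": rho_est.sd_myr,
                    }
                )
    return append_average_row(pd.DataFrame.from_records(records))


def append_average_row(df: pd.DataFrame) -> pd.DataFrame:
    """Append the per-(component, method) Average row: the unweighted mean
    of the subfamily ages (and of their sds), with copy counts summed."""
    body = df[df["subfamily"] != "Average"]
    averages = (
        body.groupby(["component", "method"], sort=False)
        .agg(
            n=("n", "sum"),
            n_sites=("n_sites", "first"),
            mean_divergence=("mean_divergence", "mean"),
            age_myr=("age_myr", "mean"),
            sd_myr=("sd_myr", "mean"),
        )
        .reset_index()
    )
    averages.insert(0, "subfamily", "Average")
    return pd.concat([body, averages], ignore_index=True)


def age_table_wide(df: pd.DataFrame, method: str = "consensus-divergence") -> pd.DataFrame:
    """Pivot the tidy age table to one row per subfamily (Table-style)."""
    sub = df[df["method"] == method]
    wide = sub.pivot(index="subfamily", columns="component", values="age_myr")
    order = [s for s in sub["subfamily"].unique() if s != "Average"] + ["Average"]
    return wide.loc[order]
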