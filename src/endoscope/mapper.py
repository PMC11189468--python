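"""Mapper (topological data analysis) over patients.

Builds a soft clustering of patients from variance-stabilized expression:

1. correlation distance between patient expression profiles;
2. two "neighborhood" lens coordinates per patient — the leading
   nontrivial eigenvectors of the symmetric normalized Laplacian of the
   mutual k-nearest-neighbor graph (a deterministic spectral surrogate for
   proprietary local-neighborhood lenses);
3. an overlapping 2-D cover of the lens plane (R intervals per axis,
   fractional overlap controlled by the gain g);
4. single-linkage clustering within each cover bin, cut at the first empty
   bar of a merge-height histogram (the classic mapper gap heuristic);
5. a graph whose nodes are bin-clusters and whose edges join nodes sharing
   patients;
6. endotype groups = communities of nodes under greedy modularity
   maximization, with a cap on the fraction of patients shared between
   groups; if the cap is exceeded the cover is re-searched over a small
   (R, g) grid.

Everything is deterministic given (data, config).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

logger = logging.getLogger(__name__)

FALLBACK_RESOLUTIONS = (10, 15, 20, 25)
FALLBACK_GAINS = (0.20, 0.30, 0.35, 0.40)


@dataclass(frozen=True)
class MapperConfig:
    k_neighbors: int = 15
    # ~n*(1+gain)^2/resolution^2 patients per 2-D bin: 8 per axis keeps bins
    # around 10-15 patients at cohort scale, which the single-linkage gap
    # heuristic needs; finer covers starve bins and fragment the graph
    resolution: int = 8           # intervals per lens axis
    gain: float = 0.35            # fractional overlap between adjacent intervals
    clustering_bins: int = 10     # histogram bins for the single-linkage gap heuristic
    min_node_size: int = 2
    overlap_cap: float = 0.10     # max fraction of patients shared between groups
    min_group_fraction: float = 0.05  # groups smaller than this fraction are dropped
    seed: int = 0

    def validate(self) -> None:
        if self.resolution < 1:
            raise ValueError("resolution must be >= 1")
        if not 0.0 < self.gain < 1.0:
            raise ValueError("gain must lie in (0, 1)")
        if not 0.0 < self.overlap_cap < 0.5:
            raise ValueError("overlap_cap must lie in (0, 0.5)")
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


class OverlapCapError(RuntimeError):
    """Raised when no cover setting satisfies the shared-membership cap."""

    def __init__(self, best_fraction: float):
        super().__init__(
            f"no (resolution, gain) setting met the overlap cap; best shared "
            f"fraction found: {best_fraction:.3f}"
        )
        self.best_fraction = best_fraction


@dataclass
class MapperNode:
    node_id: int
    patients: frozenset
    bin_index: tuple[int, int]


@dataclass
class MapperGraph:
    nodes: list[MapperNode]
    edges: list[tuple[int, int, int]]  # (node a, node b, shared patient count)

    def patient_union(self) -> set:
        out: set = set()
        for node in self.nodes:
            out |= node.patients
        return out

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        # insertion order: descending node size, id tiebreak (determinism)
        for node in sorted(self.nodes, key=lambda n: (-len(n.patients), n.node_id)):
            g.add_node(node.node_id, size=len(node.patients), bin=node.bin_index)
        for a, b, w in sorted(self.edges):
            g.add_edge(a, b, weight=w)
        return g


@dataclass
class EndotypeGroups:
    """Soft patient groups extracted from a mapper graph.

    ``groups`` maps group id -> patient set; ``exclusive`` maps patient ->
    its single group id, or "shared" for patients in more than one group.
    ``shared_fraction`` is shared patients over patients in >= 1 group.
    """

    groups: dict[str, set]
    exclusive: dict
    shared_fraction: float
    node_members: dict[str, list[int]] = field(default_factory=dict)
    node_graph: MapperGraph | None = None
    mortality: dict[str, float] = field(default_factory=dict)

    def exclusive_members(self, group_id: str) -> list:
        return sorted(p for p, g in self.exclusive.items() if g == group_id)

    def assigned_patients(self) -> set:
        out: set = set()
        for members in self.groups.values():
            out |= members
        return out

    def with_mortality(self, died: pd.Series) -> "EndotypeGroups":
        """Relabel groups t1..tK by descending mortality and record rates."""
        rates = {}
        for gid, members in self.groups.items():
            known = [p for p in members if p in died.index]
            rates[gid] = float(died.loc[known].mean()) if known else float("nan")
        order = sorted(self.groups, key=lambda g: (-rates[g], g))
        rename = {old: f"t{i + 1}" for i, old in enumerate(order)}
        return EndotypeGroups(
            groups={rename[g]: set(m) for g, m in self.groups.items()},
            exclusive={
                p: (rename[g] if g in rename else g) for p, g in self.exclusive.items()
            },
            shared_fraction=self.shared_fraction,
            node_members={rename[g]: list(n) for g, n in self.node_members.items()},
            node_graph=self.node_graph,
            mortality={rename[g]: rates[g] for g in self.groups},
        )


# --------------------------------------------------------------------------
# distance and lenses


def correlation_distance(expr) -> pd.DataFrame:
    """Pairwise 1 - Pearson r between patient expression profiles."""
    x = expr.values.to_numpy(dtype=float)
    sd = x.std(axis=0)
    flat = np.flatnonzero(sd == 0)
    if len(flat):
        raise ValueError(
            f"constant expression profile for patient(s): "
            f"{list(expr.patient_ids[flat])}"
        )
    r = np.corrcoef(x, rowvar=False)
    d = 1.0 - r
    np.fill_diagonal(d, 0.0)
    d = np.clip((d + d.T) / 2.0, 0.0, 2.0)
    return pd.DataFrame(d, index=expr.patient_ids, columns=expr.patient_ids)


def _mutual_knn_adjacency(dist: np.ndarray, k: int) -> np.ndarray:
    n = dist.shape[0]
    order = np.argsort(dist, axis=1, kind="stable")
    is_nn = np.zeros((n, n), dtype=bool)
    for i in range(n):
        neighbors = [j for j in order[i] if j != i][:k]
        is_nn[i, neighbors] = True
    return is_nn & is_nn.T


def neighborhood_lenses(
    dist: pd.DataFrame, k: int = 15, connect_mst: bool = True
) -> pd.DataFrame:
    """Two spectral lens coordinates per patient, each scaled to [0, 1].

    Coordinates are the two leading nontrivial eigenvectors of the
    symmetric normalized Laplacian of the mutual k-NN graph under the given
    distance.  With ``connect_mst`` (the default) the graph is augmented
    with the global minimum spanning tree of the distance matrix, which
    guarantees connectivity while leaving the local-neighborhood geometry
    dominated by the k-NN edges; well-separated patient groups then spread
    out along the lens axes instead of breaking the embedding.

    The eigenvector sign is fixed so the lexicographically smallest
    embedded patient id has non-negative raw coordinates.  Without MST
    augmentation, patients outside the largest connected component inherit
    the coordinates of their nearest embedded patient (with a warning);
    an error is raised if the largest component covers < 50% of patients.
    """
    n = dist.shape[0]
    if k <= 0:
        raise ValueError("k must be positive")
    if k >= n:
        raise ValueError("k must be smaller than the number of patients")
    d = dist.to_numpy(dtype=float)
    adj = _mutual_knn_adjacency(d, k)
    if connect_mst:
        from scipy.sparse.csgraph import minimum_spanning_tree

        mst = minimum_spanning_tree(d).toarray() > 0
        adj |= mst | mst.T

    g = nx.from_numpy_array(adj.astype(int))
    components = sorted(nx.connected_components(g), key=len, reverse=True)
    comp = sorted(components[0])
    if len(comp) < 0.5 * n:
        raise ValueError(
            f"mutual {k}-NN graph largest component covers only "
            f"{len(comp)}/{n} patients"
        )
    if len(comp) < n:
        logger.warning(
            "mutual k-NN graph disconnected; embedding largest component "
            "(%d/%d patients), mapping the rest to nearest neighbors",
            len(comp), n,
        )

    a = adj[np.ix_(comp, comp)].astype(float)
    deg = a.sum(axis=1)
    deg_isqrt = 1.0 / np.sqrt(np.maximum(deg, 1e-12))
    lap = np.eye(len(comp)) - deg_isqrt[:, None] * a * deg_isqrt[None, :]
    eigvals, eigvecs = np.linalg.eigh((lap + lap.T) / 2.0)
    vecs = eigvecs[:, 1:3]  # skip the trivial eigenvector

    # sign fix keyed to the smallest embedded patient id
    ids = dist.index.to_numpy()
    anchor = int(np.argmin([ids[i] for i in comp]))
    for axis in range(2):
        if vecs[anchor, axis] < 0:
            vecs[:, axis] = -vecs[:, axis]

    coords = np.zeros((n, 2))
    coords[comp] = vecs
    outside = [i for i in range(n) if i not in set(comp)]
    if outside:
        comp_arr = np.array(comp)
        for i in outside:
            nearest = comp_arr[np.argmin(d[i, comp_arr])]
            coords[i] = coords[nearest]

    # rank-scale to [0, 1]: equalizes cover-bin occupancy, robust to the
    # mass concentration typical of Laplacian eigenvectors
    from scipy.stats import rankdata

    for axis in range(2):
        coords[:, axis] = (rankdata(coords[:, axis]) - 1.0) / max(n - 1, 1)
    return pd.DataFrame(coords, index=dist.index, columns=["lens1", "lens2"])


# --------------------------------------------------------------------------
# cover, per-bin clustering, graph


def _axis_intervals(values: np.ndarray, resolution: int, gain: float):
    lo, hi = float(values.min()), float(values.max())
    if hi - lo <= 0:
        logger.warning("zero lens range on an axis; using a single full-range interval")
        return [(lo - 0.5, lo + 0.5)]
    span = hi - lo
    length = span * (1.0 + gain) / resolution
    intervals = []
    for i in range(resolution):
        center = lo + span * (i + 0.5) / resolution
        a, b = max(center - length / 2.0, lo), min(center + length / 2.0, hi)
        intervals.append((a, b))
    return intervals


def _in_interval(values: np.ndarray, interval, is_last: bool) -> np.ndarray:
    a, b = interval
    if is_last:
        return (values >= a) & (values <= b)
    return (values >= a) & (values < b)


def build_cover(lens: pd.DataFrame, resolution: int, gain: float) -> dict:
    """Overlapping 2-D cover: bin index (i, j) -> list of patient ids.

    Per axis, ``resolution`` equal-length intervals with centers evenly
    spaced over the data range and length range*(1+gain)/resolution,
    clipped to the range; intervals are half-open except the last (closed).
    Only non-empty bins are returned.
    """
    if not np.isfinite(lens.to_numpy()).all():
        raise ValueError("lens coordinates must be finite")
    axes = []
    for col in lens.columns[:2]:
        values = lens[col].to_numpy(dtype=float)
        intervals = _axis_intervals(values, resolution, gain)
        members = [
            _in_interval(values, iv, i == len(intervals) - 1)
            for i, iv in enumerate(intervals)
        ]
        axes.append(members)
    cover = {}
    ids = lens.index
    for i, mi in enumerate(axes[0]):
        for j, mj in enumerate(axes[1]):
            both = mi & mj
            if both.any():
                cover[(i, j)] = list(ids[both])
    return cover


def cluster_bin(members: list, dist: pd.DataFrame, clustering_bins: int = 10) -> list[list]:
    """Single-linkage clusters within one cover bin.

    The dendrogram is cut at the lower edge of the first empty bar in a
    ``clustering_bins``-bin histogram of merge heights; no gap (or all
    merge heights equal) leaves the bin as a single cluster.
    """
    members = list(members)
    if len(members) <= 1:
        return [members] if members else []
    sub = dist.loc[members, members].to_numpy(dtype=float)
    if len(members) == 2:
        return [members]
    heights = linkage(squareform(sub, checks=False), method="single")[:, 2]
    if np.ptp(heights) <= 0:
        return [members]
    hist, edges = np.histogram(heights, bins=clustering_bins)
    empty = np.flatnonzero(hist == 0)
    if len(empty) == 0:
        return [members]
    threshold = edges[empty[0]]
    labels = fcluster(
        linkage(squareform(sub, checks=False), method="single"),
        t=threshold,
        criterion="distance",
    )
    clusters: dict[int, list] = {}
    for member, lab in zip(members, labels):
        clusters.setdefault(int(lab), []).append(member)
    return [clusters[key] for key in sorted(clusters)]


def build_graph(bin_clusters: dict, min_node_size: int = 2) -> MapperGraph:
    """Node per bin-cluster with >= min_node_size patients; edge where two
    nodes share at least one patient, weighted by the shared count."""
    nodes: list[MapperNode] = []
    for bin_index in sorted(bin_clusters):
        for cluster in bin_clusters[bin_index]:
            if len(cluster) >= min_node_size:
                nodes.append(MapperNode(len(nodes), frozenset(cluster), bin_index))
    if not nodes:
        raise ValueError("mapper graph is empty (all clusters below min_node_size)")
    edges = []
    for i, na in enumerate(nodes):
        for nb in nodes[i + 1 :]:
            shared = len(na.patients & nb.patients)
            if shared:
                edges.append((na.node_id, nb.node_id, shared))
    return MapperGraph(nodes, edges)


# --------------------------------------------------------------------------
# group extraction


def extract_groups(graph: MapperGraph, cfg: MapperConfig) -> EndotypeGroups:
    """Partition nodes into groups by greedy modularity on the node graph
    (edge weight = shared patient count) and lift to patients.

    Communities smaller than ``min_group_fraction`` of assigned patients
    are dropped (their patients stay unassigned, logged).  Raises
    OverlapCapError when the shared fraction exceeds ``overlap_cap``.
    """
    if not graph.nodes:
        raise ValueError("empty mapper graph")
    g = graph.to_networkx()
    if g.number_of_edges() == 0:
        communities = [{n} for n in g.nodes]
    else:
        communities = [
            set(c)
            for c in nx.algorithms.community.greedy_modularity_communities(
                g, weight="weight"
            )
        ]
    communities = sorted(communities, key=lambda c: (-len(c), min(c)))

    node_by_id = {n.node_id: n for n in graph.nodes}
    total_assigned = len(graph.patient_union())
    floor = max(2, int(np.ceil(cfg.min_group_fraction * total_assigned)))

    groups: dict[str, set] = {}
    node_members: dict[str, list[int]] = {}
    for community in communities:
        patients: set = set()
        for nid in sorted(community):
            patients |= node_by_id[nid].patients
        if len(patients) < floor:
            logger.info(
                "extract_groups: dropping community of %d nodes / %d patients "
                "(below %d-patient floor)", len(community), len(patients), floor
            )
            continue
        gid = f"g{len(groups) + 1}"
        groups[gid] = patients
        node_members[gid] = sorted(community)
    if not groups:
        raise ValueError("no group passed the size floor")

    membership: dict = {}
    for gid, patients in groups.items():
        for p in patients:
            membership.setdefault(p, []).append(gid)
    exclusive = {
        p: (gids[0] if len(gids) == 1 else "shared") for p, gids in membership.items()
    }
    assigned = len(membership)
    shared = sum(1 for gids in membership.values() if len(gids) > 1)
    fraction = shared / assigned if assigned else 0.0

    result = EndotypeGroups(groups, exclusive, fraction, node_members, graph)
    if fraction > cfg.overlap_cap:
        raise OverlapCapError(fraction)
    return result


def build_mapper_groups(expr, cfg: MapperConfig) -> tuple[MapperGraph, EndotypeGroups]:
    """Full mapper stage: distance -> lenses -> cover -> clusters -> graph
    -> groups, re-searching (R, g) over a small grid when the default cover
    violates the shared-membership cap.

    The fallback grid picks the setting with the most groups of size
    >= min_group_fraction of patients, subject to the cap.
    """
    cfg.validate()
    dist = correlation_distance(expr)
    lens = neighborhood_lenses(dist, cfg.k_neighbors)

    def attempt(resolution: int, gain: float):
        cover = build_cover(lens, resolution, gain)
        bin_clusters = {
            b: cluster_bin(members, dist, cfg.clustering_bins)
            for b, members in cover.items()
        }
        graph = build_graph(bin_clusters, cfg.min_node_size)
        return graph, extract_groups(graph, cfg)

    try:
        return attempt(cfg.resolution, cfg.gain)
    except OverlapCapError as first:
        best_fraction = first.best_fraction
        logger.warning(
            "default cover (R=%d, g=%.2f) exceeds the overlap cap "
            "(shared fraction %.3f); searching fallback grid",
            cfg.resolution, cfg.gain, best_fraction,
        )

    best = None
    for resolution in FALLBACK_RESOLUTIONS:
        for gain in FALLBACK_GAINS:
            try:
                graph, groups = attempt(resolution, gain)
            except OverlapCapError as err:
                best_fraction = min(best_fraction, err.best_fraction)
                continue
            except ValueError:
                continue
            key = (len(groups.groups), -groups.shared_fraction)
            if best is None or key > best[0]:
                best = (key, graph, groups, resolution, gain)
    if best is None:
        raise OverlapCapError(best_fraction)
    _, graph, groups, resolution, gain = best
    logger.info(
        "fallback cover selected: R=%d, g=%.2f (%d groups, shared fraction %.3f)",
        resolution, gain, len(groups.groups), groups.shared_fraction,
    )
    return graph, groups


def merge_low_mortality(
    groups: EndotypeGroups, cohort: pd.DataFrame, min_deaths: int = 10
) -> EndotypeGroups:
    """Merge adjacent groups that each contain fewer than ``min_deaths``
    deaths, pairwise, until none remain or no candidate pair exists.

    Adjacency = sharing patients, or an edge between member nodes in the
    mapper graph.  Mortality is recomputed per merged group.
    """
    if "mortality_28d" not in cohort.columns:
        raise ValueError("cohort table must contain 'mortality_28d'")
    died = cohort["mortality_28d"]

    current = {g: set(m) for g, m in groups.groups.items()}
    node_members = {g: list(n) for g, n in groups.node_members.items()}
    edge_pairs = set()
    if groups.node_graph is not None:
        for a, b, _ in groups.node_graph.edges:
            edge_pairs.add((a, b))
            edge_pairs.add((b, a))

    def deaths(members: set) -> int:
        known = [p for p in members if p in died.index]
        return int(died.loc[known].sum())

    def adjacent(ga: str, gb: str) -> bool:
        if current[ga] & current[gb]:
            return True
        return any(
            (na, nb) in edge_pairs
            for na in node_members.get(ga, [])
            for nb in node_members.get(gb, [])
        )

    while True:
        low = sorted(g for g in current if deaths(current[g]) < min_deaths)
        candidate = None
        for i, ga in enumerate(low):
            for gb in low[i + 1 :]:
                if adjacent(ga, gb):
                    candidate = (ga, gb)
                    break
            if candidate:
                break
        if candidate is None:
            break
        ga, gb = candidate
        merged_id = f"{ga}-{gb}"
        current[merged_id] = current.pop(ga) | current.pop(gb)
        node_members[merged_id] = sorted(
            node_members.pop(ga, []) + node_members.pop(gb, [])
        )
        logger.info("merge_low_mortality: merged %s and %s into %s", ga, gb, merged_id)

    membership: dict = {}
    for gid, patients in current.items():
        for p in patients:
            membership.setdefault(p, []).append(gid)
    exclusive = {
        p: (gids[0] if len(gids) == 1 else "shared") for p, gids in membership.items()
    }
    shared = sum(1 for gids in membership.values() if len(gids) > 1)
    fraction = shared / len(membership) if membership else 0.0
    mortality = {
        g: float(died.loc[[p for p in m if p in died.index]].mean())
        for g, m in current.items()
    }
    return EndotypeGroups(
        current, exclusive, fraction, node_members, groups.node_graph, mortality
    )
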