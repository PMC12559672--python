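"""Bipartite species-patch networks and their structural metrics.

A metacommunity snapshot is represented as a bipartite graph: waterbird
species and habitat patches are the two node classes and a link records
that a species occurred in a patch during that period. Network-level
structure is summarized by connectance, NODF nestedness and Barber
bipartite modularity; node-level structure by degree (patch richness /
species spatial niche width), the node's nestedness contribution (cnodf,
a z-score against randomizations of the focal node's links) and the
coefficient of variation of those quantities across periods.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata

from ._errors import UndefinedMetricError, ValidationError
from .io_model import AbundanceMatrix

NodeKey = tuple[str, str]  # ("species" | "patch", node id)


@dataclass
class BipartiteNetwork:
    """Species-patch occurrence network for one period."""

    period: str
    species_nodes: frozenset[str]
    patch_nodes: frozenset[str]
    links: frozenset[tuple[str, str]]

    def __post_init__(self):
        self.species_nodes = frozenset(self.species_nodes)
        self.patch_nodes = frozenset(self.patch_nodes)
        self.links = frozenset(self.links)
        for s, p in self.links:
            if s not in self.species_nodes or p not in self.patch_nodes:
                raise ValidationError(
                    f"link ({s}, {p}) references a node outside the node sets")

    @property
    def n_links(self) -> int:
        return len(self.links)

    def degree(self, node: str) -> int:
        """Number of partners of *node* (searched in both classes)."""
        if node in self.species_nodes:
            return sum(1 for s, _ in self.links if s == node)
        if node in self.patch_nodes:
            return sum(1 for _, p in self.links if p == node)
        raise KeyError(f"node {node!r} not in network")

    def incidence(self) -> tuple[np.ndarray, list[str], list[str]]:
        """0/1 incidence matrix with sorted species rows and patch columns."""
        species = sorted(self.species_nodes)
        patches = sorted(self.patch_nodes)
        a = np.zeros((len(species), len(patches)), dtype=np.int8)
        si = {s: i for i, s in enumerate(species)}
        pj = {p: j for j, p in enumerate(patches)}
        for s, p in self.links:
            a[si[s], pj[p]] = 1
        return a, species, patches


def build_network(m: AbundanceMatrix, presence_threshold: int = 1,
                  keep_isolated: bool = False) -> BipartiteNetwork:
    """Binarize an abundance matrix into an occurrence network.

    A link (species, patch) exists iff the count reaches
    *presence_threshold* (default 1 individual). Nodes left without links
    are dropped unless *keep_isolated* is set (e.g., when a survey roster
    should keep empty-but-surveyed patches as nodes).
    """
    if presence_threshold < 1:
        raise ValidationError("presence_threshold must be >= 1")
    present = np.asarray(m.counts) >= presence_threshold
    links = {
        (m.species_ids[i], m.patch_ids[j])
        for i, j in zip(*np.nonzero(present))
    }
    if keep_isolated:
        species = set(m.species_ids)
        patches = set(m.patch_ids)
    else:
        species = {s for s, _ in links}
        patches = {p for _, p in links}
    return BipartiteNetwork(m.period, frozenset(species), frozenset(patches),
                            frozenset(links))


def connectance(n: BipartiteNetwork) -> float:
    """Realized fraction of possible species x patch links."""
    if not n.species_nodes or not n.patch_nodes:
        raise UndefinedMetricError("connectance undefined for empty node set")
    return len(n.links) / (len(n.species_nodes) * len(n.patch_nodes))


def _nodf_matrix(a: np.ndarray) -> float:
    """NODF (Almeida-Neto overlap & decreasing fill) of a 0/1 matrix.

    A pair contributes 100 * overlap / (fill of the poorer node) only when
    the richer node strictly exceeds the poorer; degree ties and empty
    nodes contribute 0. The score averages over all row pairs and all
    column pairs.
    """
    a = np.asarray(a, dtype=float)
    nr, nc = a.shape

    def class_sum(mat: np.ndarray) -> float:
        deg = mat.sum(axis=1)
        shared = mat @ mat.T
        richer = deg[:, None] > deg[None, :]
        poorer_pos = deg[None, :] > 0
        with np.errstate(divide="ignore", invalid="ignore"):
            contrib = np.where(richer & poorer_pos,
                               100.0 * shared / deg[None, :], 0.0)
        return float(contrib.sum())  # each unordered pair scores once

    n_pairs = nr * (nr - 1) // 2 + nc * (nc - 1) // 2
    return (class_sum(a) + class_sum(a.T)) / n_pairs


def nodf(n: BipartiteNetwork) -> float:
    """Network NODF nestedness in [0, 100]."""
    if len(n.species_nodes) < 2 or len(n.patch_nodes) < 2:
        raise UndefinedMetricError(
            "NODF needs at least 2 nodes in each class")
    a, _, _ = n.incidence()
    return _nodf_matrix(a)


def _barber_q(b: np.ndarray, e: int, row_labels: np.ndarray,
              col_labels: np.ndarray) -> float:
    same = row_labels[:, None] == col_labels[None, :]
    return float(b[same].sum()) / e


def modularity(n: BipartiteNetwork, seed: int = 0,
               restarts: int = 20) -> tuple[float, dict[NodeKey, int]]:
    """Maximize Barber bipartite modularity Q_B with a seeded local search.

    Q_B = (1/E) sum_{ij} (A_ij - k_i d_j / E) [same module], where k and d
    are species and patch degrees and E the number of links. Each restart
    shuffles the node sweep order and greedily moves single nodes to the
    adjacent module with the best gain until no move improves Q. The best
    partition over all restarts is returned; identical seeds give identical
    results.
    """
    if not n.links:
        raise UndefinedMetricError("modularity undefined without links")
    a, species, patches = n.incidence()
    a = a.astype(float)
    e = int(a.sum())
    k = a.sum(axis=1)
    d = a.sum(axis=0)
    b = a - np.outer(k, d) / e
    ns, np_ = len(species), len(patches)
    rng = np.random.default_rng(seed)

    best_q = -np.inf
    best = None
    for _ in range(max(1, restarts)):
        # start from singleton modules; species i gets label i, patch j label ns+j
        row_lab = np.arange(ns)
        col_lab = np.arange(ns, ns + np_)
        improved = True
        while improved:
            improved = False
            order = rng.permutation(ns + np_)
            for idx in order:
                if idx < ns:  # species node: score against patch labels
                    scores: dict[int, float] = {}
                    for lab in np.unique(col_lab):
                        scores[lab] = b[idx, col_lab == lab].sum()
                    current = scores.get(row_lab[idx], 0.0)
                    lab, val = max(scores.items(),
                                   key=lambda kv: (kv[1], -kv[0]))
                    if val > current + 1e-12:
                        row_lab[idx] = lab
                        improved = True
                else:
                    j = idx - ns
                    scores = {}
                    for lab in np.unique(row_lab):
                        scores[lab] = b[row_lab == lab, j].sum()
                    current = scores.get(col_lab[j], 0.0)
                    lab, val = max(scores.items(),
                                   key=lambda kv: (kv[1], -kv[0]))
                    if val > current + 1e-12:
                        col_lab[j] = lab
                        improved = True
        q = _barber_q(b, e, row_lab, col_lab)
        if q > best_q:
            best_q = q
            best = (row_lab.copy(), col_lab.copy())

    # a single module always achieves Q computed over the full matrix;
    # with B summing to 0 overall that baseline is 0
    if best_q < 0.0:
        best_q = 0.0
        best = (np.zeros(ns, dtype=int), np.zeros(np_, dtype=int))

    row_lab, col_lab = best
    relabel = {lab: i for i, lab in
               enumerate(dict.fromkeys([*row_lab, *col_lab]))}
    partition: dict[NodeKey, int] = {}
    for i, s in enumerate(species):
        partition[("species", s)] = relabel[row_lab[i]]
    for j, p in enumerate(patches):
        partition[("patch", p)] = relabel[col_lab[j]]
    return best_q, partition


def cnodf(n: BipartiteNetwork, node: str, n_random: int = 100,
          seed: int = 0) -> float:
    """Nestedness contribution of one node, as a z-score.

    The focal node's links are replaced by *n_random* uniform draws of the
    same number of partners; cnodf = (NODF_obs - mean NODF_null) / SD_null.
    A null SD of zero (e.g., the node is linked to every possible partner)
    yields 0. Fixed seeds give identical values.
    """
    if n_random < 2:
        raise ValidationError("n_random must be >= 2")
    a, species, patches = n.incidence()
    if node in n.species_nodes:
        axis_ids, is_row = species, True
    elif node in n.patch_nodes:
        axis_ids, is_row = patches, False
    else:
        raise KeyError(f"node {node!r} not in network")
    obs = _nodf_matrix(a)
    idx = axis_ids.index(node)
    mat = a if is_row else a.T
    degree = int(mat[idx].sum())
    n_partners = mat.shape[1]
    rng = np.random.default_rng(seed)
    nulls = np.empty(n_random)
    work = mat.copy()
    for r in range(n_random):
        partners = rng.choice(n_partners, size=degree, replace=False)
        work[idx] = 0
        work[idx, partners] = 1
        nulls[r] = _nodf_matrix(work if is_row else work.T)
    sd = float(nulls.std(ddof=1))
    if sd == 0.0:
        return 0.0
    return (obs - float(nulls.mean())) / sd


def _cv(values: list[float]) -> float | None:
    """Sample-SD / mean; None when fewer than two values or zero mean."""
    if len(values) < 2:
        return None
    arr = np.asarray(values, dtype=float)
    mean = arr.mean()
    if mean == 0:
        return None
    return float(arr.std(ddof=1) / mean)


@dataclass
class NodeMetricSeries:
    """Per-node degree and cnodf across periods, with temporal CVs."""

    node_id: str
    node_class: str  # "species" | "patch"
    degree_by_period: dict[str, int] = field(default_factory=dict)
    cnodf_by_period: dict[str, float] = field(default_factory=dict)
    cv_degree: float | None = None
    cv_cnodf: float | None = None


def node_metric_series(nets: list[BipartiteNetwork], n_random: int = 100,
                       seed: int = 0) -> list[NodeMetricSeries]:
    """Degree and cnodf per period for every node, plus their temporal CVs.

    CVs are computed over the periods in which the node is present (sample
    standard deviation over mean); nodes present in a single period, or
    with zero mean, get the undefined sentinel ``None``. cnodf is skipped
    for periods whose network is too small for NODF.
    """
    if len(nets) < 2:
        raise ValidationError("need at least 2 period networks")
    series: dict[NodeKey, NodeMetricSeries] = {}
    for t, net in enumerate(nets):
        nodf_ok = (len(net.species_nodes) >= 2 and len(net.patch_nodes) >= 2)
        for cls, nodes in (("species", net.species_nodes),
                           ("patch", net.patch_nodes)):
            for node in sorted(nodes):
                key = (cls, node)
                entry = series.setdefault(key, NodeMetricSeries(node, cls))
                entry.degree_by_period[net.period] = net.degree(node)
                if nodf_ok:
                    entry.cnodf_by_period[net.period] = cnodf(
                        net, node, n_random=n_random,
                        seed=seed + 7919 * t + len(entry.degree_by_period))
    out = []
    for key in sorted(series):
        entry = series[key]
        entry.cv_degree = _cv(list(entry.degree_by_period.values()))
        entry.cv_cnodf = _cv(list(entry.cnodf_by_period.values()))
        out.append(entry)
    return out


def rank_sum_compare(a, b) -> tuple[float, float, float]:
    """Two-sided Mann-Whitney U with normal approximation and tie correction.

    Returns (U for the first group, z, two-sided p). U counts pairs where an
    ``a`` value exceeds a ``b`` value, plus half the ties. Raises
    :class:`UndefinedMetricError` when all values in both groups are
    identical (zero rank variance).
    """
    x = np.asarray(a, dtype=float)
    y = np.asarray(b, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValidationError("both groups must be non-empty")
    n1, n2 = x.size, y.size
    combined = np.concatenate([x, y])
    ranks = rankdata(combined)
    u = float(ranks[:n1].sum() - n1 * (n1 + 1) / 2)
    big_n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float((tie_counts**3 - tie_counts).sum())
    var = n1 * n2 / 12.0 * ((big_n + 1) - tie_term / (big_n * (big_n - 1)))
    if var <= 0:
        raise UndefinedMetricError(
            "rank variance is zero: all values identical across groups")
    mu = n1 * n2 / 2.0
    diff = u - mu
    # continuity correction toward the mean
    z = (diff - 0.5 * np.sign(diff)) / np.sqrt(var)
    p = min(1.0, 2.0 * float(norm.sf(abs(z))))
    return u, float(z), p
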