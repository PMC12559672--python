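"""Temporal beta diversity of species-patch links and its partitions.

Between two period networks the link sets L1 and L2 are compared with the
Jaccard dissimilarity over links,

    beta_T = (b + c) / (a + b + c),

where a = |L1 ∩ L2| (shared links), b = |L1 \\ L2| (links lost) and
c = |L2 \\ L1| (links gained). Two exact partitions of beta_T are computed
from the same (a, b, c) tally in a single pass, so their additivity is
structural rather than numerical:

* extinction / colonization: beta_E = b/(a+b+c), beta_C = c/(a+b+c);
* local / regional / landscape / RL: each changed link is classified by
  whether its species and patch nodes persist (hold at least one link at
  both times). Both persist -> local dynamics (rewiring among persisting
  nodes); species turnover with a persisting patch -> regional; patch
  turnover with a persisting species -> landscape; neither persists -> RL.

Node persistence is defined from link incidence by default. A roster of
surveyed-but-empty patches may be supplied so such patches still count as
persistent landscape elements.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable

from ._errors import UndefinedMetricError
from .network import BipartiteNetwork

COMPONENT_NAMES = ("local", "regional", "landscape", "rl")


@dataclass(frozen=True)
class BetaPartition:
    """Temporal beta diversity between two periods and its six components."""

    pair: tuple[str, str]
    beta_temporal: float
    beta_extinction: float
    beta_colonization: float
    beta_local: float
    beta_regional: float
    beta_landscape: float
    beta_rl: float
    a_shared: int
    b_lost: int
    c_gained: int


def _link_tally(n1: BipartiteNetwork, n2: BipartiteNetwork):
    l1, l2 = n1.links, n2.links
    if not l1 and not l2:
        raise UndefinedMetricError(
            "temporal beta undefined: both networks are empty")
    shared = l1 & l2
    lost = l1 - l2
    gained = l2 - l1
    return shared, lost, gained


def beta_temporal(n1: BipartiteNetwork, n2: BipartiteNetwork) -> float:
    """Jaccard dissimilarity of the two link sets."""
    shared, lost, gained = _link_tally(n1, n2)
    return (len(lost) + len(gained)) / (len(shared) + len(lost) + len(gained))


def partition_extinction_colonization(
    n1: BipartiteNetwork, n2: BipartiteNetwork
) -> tuple[float, float]:
    """Split beta_T into link-loss (extinction) and link-gain (colonization)."""
    shared, lost, gained = _link_tally(n1, n2)
    denom = len(shared) + len(lost) + len(gained)
    return len(lost) / denom, len(gained) / denom


def _persistent_nodes(
    n1: BipartiteNetwork, n2: BipartiteNetwork,
    roster_patches: Iterable[str] | None = None,
) -> tuple[set[str], set[str]]:
    """Nodes holding >= 1 link at both times (plus rostered patches)."""
    sp1 = {s for s, _ in n1.links}
    sp2 = {s for s, _ in n2.links}
    pa1 = {p for _, p in n1.links}
    pa2 = {p for _, p in n2.links}
    persistent_patches = pa1 & pa2
    if roster_patches is not None:
        persistent_patches = persistent_patches | set(roster_patches)
    return sp1 & sp2, persistent_patches


def partition_components(
    n1: BipartiteNetwork, n2: BipartiteNetwork,
    roster_patches: Iterable[str] | None = None,
) -> tuple[float, float, float, float]:
    """Split beta_T into local, regional, landscape and RL components.

    Each link in the symmetric difference is assigned to exactly one
    component by the persistence of its endpoints; the classification is a
    partition, so the four values sum to beta_T exactly.
    """
    shared, lost, gained = _link_tally(n1, n2)
    denom = len(shared) + len(lost) + len(gained)
    sp_persist, pa_persist = _persistent_nodes(n1, n2, roster_patches)
    counts = dict.fromkeys(COMPONENT_NAMES, 0)
    for s, p in lost | gained:
        s_ok = s in sp_persist
        p_ok = p in pa_persist
        if s_ok and p_ok:
            counts["local"] += 1
        elif p_ok:
            counts["regional"] += 1
        elif s_ok:
            counts["landscape"] += 1
        else:
            counts["rl"] += 1
    return tuple(counts[k] / denom for k in COMPONENT_NAMES)


def beta_partition(
    n1: BipartiteNetwork, n2: BipartiteNetwork,
    roster_patches: Iterable[str] | None = None,
) -> BetaPartition:
    """All six beta components for one ordered period pair."""
    shared, lost, gained = _link_tally(n1, n2)
    a, b, c = len(shared), len(lost), len(gained)
    denom = a + b + c
    local, regional, landscape, rl = partition_components(
        n1, n2, roster_patches)
    return BetaPartition(
        pair=(n1.period, n2.period),
        beta_temporal=(b + c) / denom,
        beta_extinction=b / denom,
        beta_colonization=c / denom,
        beta_local=local,
        beta_regional=regional,
        beta_landscape=landscape,
        beta_rl=rl,
        a_shared=a,
        b_lost=b,
        c_gained=c,
    )


def beta_matrix(
    nets: list[BipartiteNetwork],
    roster_patches: Iterable[str] | None = None,
) -> list[BetaPartition]:
    """One :class:`BetaPartition` per ordered pair (t_i, t_j), i < j.

    Pairs follow the order in which the networks are supplied (normally the
    chronological period order), so four periods give six rows.
    """
    if len(nets) < 2:
        raise UndefinedMetricError("need at least 2 networks")
    return [
        beta_partition(nets[i], nets[j], roster_patches)
        for i, j in combinations(range(len(nets)), 2)
    ]
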