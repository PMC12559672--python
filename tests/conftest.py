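"""Shared fixtures and independent oracle implementations.

The oracles here deliberately re-derive every metric by brute force
(explicit pair loops, exhaustive enumeration of partitions or partner
sets) so they share no code path with the package implementations they
check.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
import pytest

from metapatch.network import BipartiteNetwork


def make_network(links, period="T", species=None, patches=None):
    """Build a BipartiteNetwork from an iterable of (species, patch) pairs."""
    links = set(links)
    sp = set(species) if species is not None else {s for s, _ in links}
    pa = set(patches) if patches is not None else {p for _, p in links}
    return BipartiteNetwork(period, frozenset(sp), frozenset(pa),
                            frozenset(links))


def random_network(rng, n_species=6, n_patches=6, p=0.4, period="T"):
    """A random occurrence network with at least one link.

    All drawn nodes are kept (isolated ones included) so the requested
    class sizes are honoured.
    """
    while True:
        mask = rng.random((n_species, n_patches)) < p
        if mask.any():
            break
    links = {(f"s{i}", f"p{j}") for i, j in zip(*np.nonzero(mask))}
    return make_network(links, period=period,
                        species={f"s{i}" for i in range(n_species)},
                        patches={f"p{j}" for j in range(n_patches)})


# ---------------------------------------------------------------- oracles

def oracle_nodf(net: BipartiteNetwork) -> float:
    """NODF by explicit loops over row pairs and column pairs."""
    species = sorted(net.species_nodes)
    patches = sorted(net.patch_nodes)
    rows = {s: {p for s2, p in net.links if s2 == s} for s in species}
    cols = {p: {s for s, p2 in net.links if p2 == p} for p in patches}

    def pair_score(a: set, b: set) -> float:
        # contributes only with strictly decreasing fill, poorer non-empty
        if len(a) == len(b):
            return 0.0
        rich, poor = (a, b) if len(a) > len(b) else (b, a)
        if not poor:
            return 0.0
        return 100.0 * len(rich & poor) / len(poor)

    total = 0.0
    n_pairs = 0
    for group in (list(rows.values()), list(cols.values())):
        for a, b in combinations(group, 2):
            total += pair_score(a, b)
            n_pairs += 1
    return total / n_pairs


def oracle_connectance(net: BipartiteNetwork) -> float:
    return len(net.links) / (len(net.species_nodes) * len(net.patch_nodes))


def _set_partitions(items):
    """All set partitions of a sequence (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for partition in _set_partitions(rest):
        for i in range(len(partition)):
            yield partition[:i] + [partition[i] + [first]] + partition[i + 1:]
        yield partition + [[first]]


def oracle_barber_q_max(net: BipartiteNetwork):
    """Maximum Barber modularity by exhaustive search over set partitions."""
    species = sorted(net.species_nodes)
    patches = sorted(net.patch_nodes)
    e = len(net.links)
    deg_s = {s: sum(1 for s2, _ in net.links if s2 == s) for s in species}
    deg_p = {p: sum(1 for _, p2 in net.links if p2 == p) for p in patches}

    def q_of(partition):
        modules = []
        for block in partition:
            mod_s = [n for n in block if n in net.species_nodes]
            mod_p = [n for n in block if n in net.patch_nodes]
            modules.append((mod_s, mod_p))
        total = 0.0
        for mod_s, mod_p in modules:
            for s in mod_s:
                for p in mod_p:
                    a = 1.0 if (s, p) in net.links else 0.0
                    total += a - deg_s[s] * deg_p[p] / e
        return total / e

    best = -np.inf
    for partition in _set_partitions(species + patches):
        best = max(best, q_of(partition))
    return best


def oracle_beta_components(links1, links2):
    """Independent set-algebra derivation of all six beta components."""
    l1, l2 = set(links1), set(links2)
    shared = l1 & l2
    changed = l1 ^ l2
    denom = len(l1 | l2)
    sp_both = {s for s, _ in l1} & {s for s, _ in l2}
    pa_both = {p for _, p in l1} & {p for _, p in l2}
    comp = {"local": 0, "regional": 0, "landscape": 0, "rl": 0}
    for s, p in changed:
        if s in sp_both and p in pa_both:
            comp["local"] += 1
        elif p in pa_both:
            comp["regional"] += 1
        elif s in sp_both:
            comp["landscape"] += 1
        else:
            comp["rl"] += 1
    return {
        "beta_temporal": len(changed) / denom,
        "beta_extinction": len(l1 - l2) / denom,
        "beta_colonization": len(l2 - l1) / denom,
        "beta_local": comp["local"] / denom,
        "beta_regional": comp["regional"] / denom,
        "beta_landscape": comp["landscape"] / denom,
        "beta_rl": comp["rl"] / denom,
        "a_shared": len(shared),
    }


def oracle_mannwhitney_u(a, b):
    """U for the first group by explicit pair counting (ties count half)."""
    u = 0.0
    for x in a:
        for y in b:
            if x > y:
                u += 1.0
            elif x == y:
                u += 0.5
    return u


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)
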