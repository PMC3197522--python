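"""Degree-preserving null models and small-world indices.

The null ensemble is built by Markov-chain double-edge swaps
(Maslov–Sneppen rewiring): two edges (a,b), (c,d) are replaced by
(a,c), (b,d) whenever that creates neither a self-loop nor a duplicate
edge.  Every node's degree — and hence the edge count — is preserved
exactly.  The default burn-in is 10 successful swaps per edge.

γ = C/C_rand and λ = L/L_rand compare the observed graph against the
ensemble means; σ = γ/λ summarises small-world-ness (σ > 1 with λ ≈ 1).
The classical closed forms C_rand ≈ k̄/N and L_rand ≈ ln N / ln k̄ are
exposed only as a sanity cross-check: the indices always use the
empirical ensemble, which respects the observed degree sequence.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from numba import njit

from .graph import BinaryGraph, GraphMetrics, graph_metrics

__all__ = [
    "NullEnsemble",
    "SmallWorldIndices",
    "rewire_preserving_degree",
    "small_world_indices",
    "theoretical_random",
]

log = logging.getLogger(__name__)

SWAP_FACTOR = 10          # successful swaps per edge
MAX_TRY_FACTOR = 100      # attempt budget per requested swap


class NullModelError(ValueError):
    pass


@dataclass
class NullEnsemble:
    m: int
    c_rand: float                 # ensemble mean clustering
    l_rand: float                 # ensemble mean path length
    per_network_c: list[float] = field(default_factory=list)
    per_network_l: list[float] = field(default_factory=list)


@dataclass
class SmallWorldIndices:
    gamma: float                  # C / C_rand
    lam: float                    # L / L_rand
    sigma: float                  # gamma / lam, identically


@njit(cache=True)
def _ms_rewire(adj, edges, n_swaps, max_tries, seed):  # pragma: no cover
    # xorshift64* generator inlined for speed; one draw per attempt
    state = np.uint64(seed) * np.uint64(6364136223846793005) + np.uint64(1)
    m = np.uint64(edges.shape[0])
    done = 0
    tries = 0
    while done < n_swaps and tries < max_tries:
        tries += 1
        state ^= state << np.uint64(13)
        state ^= state >> np.uint64(7)
        state ^= state << np.uint64(17)
        r = state * np.uint64(2685821657736338717)
        e1 = np.int64(r % m)
        e2 = np.int64((r >> np.uint64(21)) % m)
        if e1 == e2:
            continue
        a, b = edges[e1, 0], edges[e1, 1]
        c, d = edges[e2, 0], edges[e2, 1]
        if (r >> np.uint64(63)) & np.uint64(1):
            c, d = d, c
        if a == c or a == d or b == c or b == d:
            continue
        if adj[a, c] or adj[b, d]:
            continue
        adj[a, b] = False
        adj[b, a] = False
        adj[c, d] = False
        adj[d, c] = False
        adj[a, c] = True
        adj[c, a] = True
        adj[b, d] = True
        adj[d, b] = True
        edges[e1, 0], edges[e1, 1] = a, c
        edges[e2, 0], edges[e2, 1] = b, d
        done += 1
    return done


def rewire_preserving_degree(g: BinaryGraph, n_swaps: int | None = None,
                             seed: int = 0) -> BinaryGraph:
    """One randomized copy of ``g`` with the exact same degree sequence.

    ``n_swaps`` defaults to ``SWAP_FACTOR × E`` successful double-edge
    swaps.  If the graph admits no valid swap (e.g. a complete graph), the
    input adjacency is returned unchanged with a warning.

    For graphs denser than 50% the default-budget chain runs on the
    complement instead: complementation is a degree-respecting bijection
    on the set of graphs with a fixed degree sequence, so randomizing the
    complement randomizes the graph, and swap acceptance is far higher on
    the sparser side.  An explicit ``n_swaps`` always rewires the graph
    itself.
    """
    if int(g.adjacency.sum()) < 4:          # fewer than 2 edges
        raise NullModelError("rewiring needs ≥ 2 edges")
    n = g.n_nodes
    density = g.adjacency.sum() / (n * (n - 1))
    use_complement = n_swaps is None and density > 0.5
    adj = g.adjacency.copy()
    if use_complement:
        adj = ~adj
        np.fill_diagonal(adj, False)
    edges = np.argwhere(np.triu(adj, 1)).astype(np.int64)
    if len(edges) < 2:
        done = 0
    else:
        budget = SWAP_FACTOR * len(edges) if n_swaps is None else n_swaps
        done = _ms_rewire(adj, edges, budget, MAX_TRY_FACTOR * budget,
                          (seed % (2**32)) or 1)
    if done == 0:
        log.warning("graph admits no valid double-edge swap; "
                    "returning input unchanged")
        return BinaryGraph(adjacency=g.adjacency.copy(),
                           threshold=g.threshold, network=g.network,
                           subject_id=g.subject_id)
    if use_complement:
        adj = ~adj
        np.fill_diagonal(adj, False)
    return BinaryGraph(adjacency=adj, threshold=g.threshold,
                       network=g.network, subject_id=g.subject_id)


def small_world_indices(g: BinaryGraph, m: int = 30, seed: int = 0,
                        metrics: GraphMetrics | None = None,
                        n_swaps: int | None = None,
                        ) -> tuple[SmallWorldIndices, NullEnsemble]:
    """γ, λ, σ for one graph against an ``m``-member rewired ensemble.

    Each ensemble member is an independently seeded rewiring of ``g``;
    C and L (largest-component rule) are averaged over the ensemble.
    """
    if m < 1:
        raise NullModelError("ensemble size m must be ≥ 1")
    if metrics is None:
        metrics = graph_metrics(g)
    seeds = np.random.SeedSequence(seed).generate_state(m) % (2**31)
    cs, ls = [], []
    for k in range(m):
        rnd = rewire_preserving_degree(g, n_swaps=n_swaps, seed=int(seeds[k]))
        mk = graph_metrics(rnd)
        cs.append(mk.clustering)
        ls.append(mk.path_length)
    c_rand = float(np.mean(cs))
    l_rand = float(np.mean(ls))
    if c_rand <= 0 or l_rand <= 0:
        raise NullModelError("degenerate null ensemble (zero C or L)")
    gamma = metrics.clustering / c_rand
    lam = metrics.path_length / l_rand
    ens = NullEnsemble(m=m, c_rand=c_rand, l_rand=l_rand,
                       per_network_c=cs, per_network_l=ls)
    return SmallWorldIndices(gamma=gamma, lam=lam, sigma=gamma / lam), ens


def theoretical_random(n: int, k_mean: float) -> tuple[float, float]:
    """Closed-form random-graph baselines: (k̄/N, ln N / ln k̄).

    Valid for N > k̄ > 1; used only as a cross-check of the empirical
    ensemble, never inside γ/λ/σ.
    """
    if k_mean <= 1:
        raise NullModelError("k_mean must exceed 1")
    if n <= k_mean:
        raise NullModelError("n must exceed k_mean")
    return k_mean / n, float(np.log(n) / np.log(k_mean))
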