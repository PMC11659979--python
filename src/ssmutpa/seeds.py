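"""Per-sample local weighting of mutated seed genes.

A sample's mutated genes that are present in the PPI network are its seed
nodes. Each seed G_i gets a local weight from the excess of observed over
expected mutated neighbors: with N network genes, K seeds, M_i neighbors of
G_i and X_i mutated neighbors, the neighborhood mutation count follows a
hypergeometric law with expectation E(X_i) = M_i * K / N. The weight is

    w_i = X_i - E(X_i)
    W_i = log_alpha(w_i * I(w_i > 0) + alpha)

so W_i >= 1 always, with equality exactly when the excess is non-positive.
The default base alpha = 2.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import MutationProfile
from .network import PPINetwork

logger = logging.getLogger(__name__)

__all__ = ["NoSeedsError", "SeedWeights", "map_seeds", "hypergeom_neighbor_pmf", "local_weights"]


class NoSeedsError(ValueError):
    """A sample has no mutated genes mapping into the network."""


@dataclass
class SeedWeights:
    """Local weights and per-seed diagnostics for one sample.

    ``table`` is indexed by seed gene symbol (sorted) with columns
    ``degree`` (M_i), ``x_observed`` (X_i), ``expected`` (E(X_i)),
    ``excess`` (w_i) and ``weight`` (W_i).
    """

    sample_id: str | None
    table: pd.DataFrame
    n_seeds: int
    alpha: float

    @property
    def weights(self) -> dict[str, float]:
        return self.table["weight"].to_dict()

    def __len__(self) -> int:
        return self.n_seeds


def map_seeds(profile: MutationProfile, net: PPINetwork) -> tuple[str, ...]:
    """Intersect a sample's mutated genes with the network nodes.

    Returns the seed genes sorted; an empty tuple signals the no-seeds
    condition to the caller (handled downstream as an all-zero score column).
    """
    seeds = tuple(sorted(profile.genes & set(net.nodes)))
    n_unmapped = len(profile.genes) - len(seeds)
    if n_unmapped:
        logger.debug(
            "sample %s: %d mutated gene(s) not in the network",
            profile.sample_id,
            n_unmapped,
        )
    if not seeds:
        logger.warning("sample %s: no mutated genes map to the network", profile.sample_id)
    return seeds


def hypergeom_neighbor_pmf(x: int, m_i: int, k: int, n: int) -> float:
    """P(X_i = x): hypergeometric pmf for mutated-neighbor counts.

    ``m_i`` is the seed's degree, ``k`` the number of seeds, ``n`` the number
    of network genes. Provided for diagnostics; the weighting itself uses only
    the expectation M_i * K / N.
    """
    if not (0 <= m_i <= n and 0 <= k <= n):
        raise ValueError(f"require 0 <= M_i, K <= N; got M_i={m_i}, K={k}, N={n}")
    if not 0 <= x <= min(m_i, k):
        raise ValueError(f"require 0 <= x <= min(M_i, K); got x={x}")
    return float(stats.hypergeom.pmf(x, n, m_i, k))


def local_weights(
    seeds,
    net: PPINetwork,
    alpha: float = 2.0,
    sample_id: str | None = None,
) -> SeedWeights:
    """Compute local weights W_i for every seed gene.

    ``alpha`` is the logarithm base guaranteeing the floor W_i = 1; it must be
    strictly greater than 1 (default 2).
    """
    if alpha <= 1:
        raise ValueError(f"alpha must be > 1, got {alpha}")
    seeds = sorted(set(seeds))
    unknown = [g for g in seeds if g not in net.index]
    if unknown:
        raise ValueError(f"seed genes not in network: {unknown[:5]}")
    if not seeds:
        raise NoSeedsError("empty seed set")

    n = net.n_nodes
    k = len(seeds)
    indicator = np.zeros(n)
    seed_idx = np.array([net.index[g] for g in seeds])
    indicator[seed_idx] = 1.0
    mutated_neighbors = net.adjacency @ indicator  # no self-loops, so G_i excluded

    degrees = net.degrees[seed_idx]
    x_obs = mutated_neighbors[seed_idx]
    expected = degrees * k / n
    excess = x_obs - expected
    weight = np.log(np.where(excess > 0, excess, 0.0) + alpha) / math.log(alpha)

    table = pd.DataFrame(
        {
            "degree": degrees.astype(int),
            "x_observed": x_obs.astype(int),
            "expected": expected,
            "excess": excess,
            "weight": weight,
        },
        index=pd.Index(seeds, name="seed"),
    )
    return SeedWeights(sample_id=sample_id, table=table, n_seeds=k, alpha=alpha)
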