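"""Random walk with restart (RWR) for node prioritization.

Deterministic power iteration of

    p  <-  (1 - r) * W p  +  r * p0

where ``W`` is the column-normalized adjacency of the undirected network,
``p0`` is uniform over the seed nodes, and ``r`` is the restart
probability (default 0.7, common in network-medicine diffusion).  Mass
sitting on dangling (degree-0) nodes is redistributed to ``p0`` each step,
so the profile stays a probability distribution on disconnected graphs.
The stationary profile ranks every node by diffusion proximity to the
seeds.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
import pandas as pd

from .containers import ValidationError
from .topology import TripartiteNetwork


class ConvergenceError(RuntimeError):
    """Power iteration failed to reach tolerance; carries the last residual."""

    def __init__(self, residual: float, max_iter: int):
        super().__init__(
            f"RWR did not converge within {max_iter} iterations "
            f"(last L1 residual {residual:.3e})"
        )
        self.residual = residual
        self.max_iter = max_iter


@dataclass
class RWRProfile:
    """Converged restart-walk probabilities over all network nodes."""

    restart_prob: float
    seed_nodes: tuple[str, ...]
    tolerance: float
    max_iter: int
    probabilities: pd.Series  # indexed by node id, sums to 1
    iterations_used: int

    def ranked(self) -> pd.Series:
        """Probabilities sorted descending, ties by node id."""
        df = self.probabilities.rename("probability").reset_index()
        df = df.sort_values(
            by=["probability", "index"], ascending=[False, True]
        )
        return pd.Series(df["probability"].values, index=df["index"].values)


def random_walk_restart(
    network: TripartiteNetwork,
    seeds: Iterable[str],
    restart_prob: float = 0.7,
    tolerance: float = 1e-10,
    max_iter: int = 1000,
    use_weights: bool = False,
) -> RWRProfile:
    """Run RWR from ``seeds``; see the module docstring for the iteration.

    ``use_weights`` switches the adjacency to edge-weight magnitudes
    (attribute ``weight``, default 1) instead of the unweighted 0/1 matrix.
    """
    seeds = sorted(set(seeds))
    if not seeds:
        raise ValidationError("RWR needs a non-empty seed set")
    if not 0.0 < restart_prob <= 1.0:
        raise ValidationError(f"restart_prob must be in (0, 1], got {restart_prob}")
    if tolerance <= 0:
        raise ValidationError(f"tolerance must be > 0, got {tolerance}")
    if max_iter < 1:
        raise ValidationError(f"max_iter must be >= 1, got {max_iter}")
    g = network.graph
    nodes = sorted(g.nodes)
    unknown = [s for s in seeds if s not in g]
    if unknown:
        raise ValidationError(f"seed node(s) not in network: {unknown}")
    index = {n: i for i, n in enumerate(nodes)}
    n = len(nodes)

    A = np.zeros((n, n))
    for u, v, data in g.edges(data=True):
        w = abs(float(data.get("weight", 1.0))) if use_weights else 1.0
        A[index[u], index[v]] = w
        A[index[v], index[u]] = w
    colsum = A.sum(axis=0)
    dangling = colsum == 0.0
    W = A / np.where(dangling, 1.0, colsum)
    W[:, dangling] = 0.0

    p0 = np.zeros(n)
    p0[[index[s] for s in seeds]] = 1.0 / len(seeds)
    p = p0.copy()
    r = restart_prob
    for it in range(1, max_iter + 1):
        dangling_mass = p[dangling].sum()
        p_next = (1.0 - r) * (W @ p + dangling_mass * p0) + r * p0
        residual = float(np.abs(p_next - p).sum())
        p = p_next
        if residual < tolerance:
            return RWRProfile(
                restart_prob=r,
                seed_nodes=tuple(seeds),
                tolerance=tolerance,
                max_iter=max_iter,
                probabilities=pd.Series(p, index=nodes),
                iterations_used=it,
            )
    raise ConvergenceError(residual, max_iter)
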