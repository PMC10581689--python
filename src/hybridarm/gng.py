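"""Growing Neural Gas over joint-space postures.

A GNG is an incremental self-organizing graph: nodes carry positions in the
feature space (here the 7-D space of joint angles), edges carry ages. Samples
are presented one at a time; the nearest node and its topological neighbours
move toward each sample, edges age and are pruned, and a new node is inserted
in the highest-error region at a fixed insertion period. Growth stops when the
requested node budget is reached, so the budget is the tuning knob and the
remaining hyperparameters follow the canonical formulation.

The node positions summarise the region of configuration space a subject
actually visited, which is what makes them a source of guaranteed-reachable
targets once pushed through forward kinematics. Distances are plain Euclidean
over the 7-D angle vector in radians.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["GngParams", "GrowingNeuralGas", "gng_fit"]


@dataclass(frozen=True)
class GngParams:
    """Hyperparameters of the growing process.

    n_nodes : node budget; growth stops when reached.
    lambda_insert : samples presented between node insertions.
    eps_b, eps_n : winner / neighbour learning rates.
    alpha : error decay applied to the two nodes bracketing an insertion.
    beta : global per-step error decay.
    max_age : edge age beyond which an edge is pruned.
    max_passes : upper bound on passes through the data before growth is
        declared unachievable.
    seed : shuffling seed.
    """

    n_nodes: int = 200
    lambda_insert: int = 100
    eps_b: float = 0.2
    eps_n: float = 0.006
    alpha: float = 0.5
    beta: float = 0.995
    max_age: int = 50
    max_passes: int = 200
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_nodes < 2:
            raise ValueError("n_nodes must be at least 2")
        if self.lambda_insert < 1:
            raise ValueError("lambda_insert must be at least 1")
        for name in ("eps_b", "eps_n", "alpha", "beta"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must be in (0, 1), got {v}")


class GrowingNeuralGas:
    """Fritzke-style growing neural gas with a node-budget stopping rule.

    Nodes live in a (capacity, dim) array; the graph is an adjacency map
    ``node -> {neighbour: edge age}`` kept symmetric at all times.
    """

    def __init__(self, params: GngParams):
        self.params = params
        self._pos: np.ndarray | None = None  # (capacity, dim)
        self._err: np.ndarray | None = None
        self._alive: list[int] = []
        self._adj: dict[int, dict[int, int]] = {}

    @property
    def nodes(self) -> np.ndarray:
        """Positions of the live nodes, (n_live, dim)."""
        return self._pos[self._alive].copy()

    # -- graph bookkeeping --------------------------------------------------
    def _set_edge(self, a: int, b: int, age: int = 0) -> None:
        self._adj[a][b] = age
        self._adj[b][a] = age

    def _drop_edge(self, a: int, b: int) -> None:
        self._adj[a].pop(b, None)
        self._adj[b].pop(a, None)

    def _drop_node(self, i: int) -> None:
        for j in list(self._adj[i]):
            self._drop_edge(i, j)
        del self._adj[i]
        self._alive.remove(i)
        self._free.append(i)

    def _add_node(self, pos: np.ndarray, err: float) -> int:
        if self._free:
            i = self._free.pop()
        else:
            i = self._next
            self._next += 1
            if i >= self._pos.shape[0]:
                self._pos = np.vstack([self._pos, np.zeros_like(self._pos)])
                self._err = np.concatenate([self._err, np.zeros_like(self._err)])
        self._pos[i] = pos
        self._err[i] = err
        self._alive.append(i)
        self._adj[i] = {}
        return i

    # -- training ------------------------------------------------------------
    def fit(self, data: np.ndarray) -> np.ndarray:
        p = self.params
        data = np.asarray(data, dtype=float)
        if data.ndim != 2 or data.shape[0] < 2:
            raise ValueError("need at least 2 input samples")
        n_samples, dim = data.shape
        needed_steps = (p.n_nodes - 2) * p.lambda_insert
        if needed_steps > p.max_passes * n_samples:
            raise ValueError(
                f"cannot grow {p.n_nodes} nodes from {n_samples} samples with "
                f"lambda_insert={p.lambda_insert}: {needed_steps} presentation steps "
                f"needed but only {p.max_passes * n_samples} available within "
                f"{p.max_passes} passes; reduce n_nodes or lambda_insert, or "
                "provide more data"
            )

        rng = np.random.default_rng(p.seed)
        self._pos = np.zeros((p.n_nodes + 8, dim))
        self._err = np.zeros(p.n_nodes + 8)
        self._alive = []
        self._adj = {}
        self._free: list[int] = []
        self._next = 0
        first = rng.choice(n_samples, size=2, replace=False)
        a = self._add_node(data[first[0]], 0.0)
        b = self._add_node(data[first[1]], 0.0)
        self._set_edge(a, b)

        pos, err, adj = self._pos, self._err, self._adj
        step = 0
        passes = 0
        while True:
            order = rng.permutation(n_samples)
            for idx in order:
                x = data[idx]
                step += 1
                alive = self._alive
                diff = pos[alive] - x
                d2 = np.einsum("ij,ij->i", diff, diff)
                o1 = int(np.argmin(d2))
                s1 = alive[o1]
                d2[o1] = np.inf
                s2 = alive[int(np.argmin(d2))]

                err[s1] += float(np.dot(diff[o1], diff[o1]))
                pos[s1] += p.eps_b * (x - pos[s1])
                nbrs = adj[s1]
                for j in list(nbrs):
                    pos[j] += p.eps_n * (x - pos[j])
                    age = nbrs[j] + 1
                    if age > p.max_age and j != s2:
                        self._drop_edge(s1, j)
                        if not adj[j] and len(self._alive) > 2:
                            self._drop_node(j)
                    else:
                        self._set_edge(s1, j, age)
                self._set_edge(s1, s2, 0)

                if step % p.lambda_insert == 0 and len(self._alive) < p.n_nodes:
                    alive_arr = np.array(self._alive)
                    q = int(alive_arr[np.argmax(err[alive_arr])])
                    nbrs_q = adj[q]
                    if nbrs_q:
                        f = max(nbrs_q, key=lambda j: err[j])
                    else:
                        others = [i for i in self._alive if i != q]
                        f = max(others, key=lambda j: err[j])
                    err[q] *= p.alpha
                    err[f] *= p.alpha
                    r = self._add_node(0.5 * (pos[q] + pos[f]), err[q])
                    pos, err = self._pos, self._err  # may have been reallocated
                    self._drop_edge(q, f)
                    self._set_edge(q, r)
                    self._set_edge(f, r)

                err[self._alive] *= p.beta
            # complete passes: once the budget is reached the pass finishes as
            # pure adaptation, so even budget-sized starts get one full pass
            passes += 1
            if len(self._alive) >= p.n_nodes:
                break
            if passes >= p.max_passes:
                raise ValueError(
                    f"node budget {p.n_nodes} not reached after {p.max_passes} passes"
                )
        return self.nodes

    def quantization_error(self, data: np.ndarray) -> float:
        """Mean distance of samples to their nearest node."""
        data = np.asarray(data, dtype=float)
        nodes = self.nodes
        d = np.sqrt(((data[:, None, :] - nodes[None, :, :]) ** 2).sum(axis=2)).min(axis=1)
        return float(d.mean())


def gng_fit(postures: np.ndarray, params: GngParams | None = None) -> np.ndarray:
    """Fit a GNG to (n, 7) postures and return the (n_nodes, 7) node positions."""
    if params is None:
        params = GngParams()
    return GrowingNeuralGas(params).fit(np.asarray(postures, dtype=float))
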