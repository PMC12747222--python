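"""Admixture graphs: expected f-statistics, parameter fitting, randomized
topology search, and bootstrap model comparison.

An admixture graph is a rooted DAG whose drift edges carry lengths (f2
units) and whose admixture nodes have two parents mixed with weights
(gamma, 1 - gamma). Writing w_X(e) for the total admixture weight of paths
from leaf X through edge e, the linearized drift algebra gives

    f2(A, B) = sum_e c_e (w_A(e) - w_B(e))^2

and every f3/f4 follows from the f2 basis. Fitting minimizes the
inverse-variance-weighted squared deviation between expected and observed
f2 over all leaf pairs (block-jackknife variances, diagonal weighting),
with lengths constrained non-negative and gamma in [0, 1] by projection.
"""

from __future__ import annotations

import hashlib
import itertools
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize

from .fstats import F2BlockTable
from .jackknife import jackknife_mean_stat

__all__ = [
    "AdmixtureGraph",
    "GraphFit",
    "random_graph",
    "expected_f2_matrix",
    "fit_graph",
    "find_graphs",
    "compare_fits",
    "enumerate_trees",
]


@dataclass
class AdmixtureGraph:
    """Rooted DAG over population leaves.

    ``drift_edges``: list of (child, parent); each carries a length
    parameter. ``admix_nodes``: node -> (parent_a, parent_b); the node
    carries a weight gamma on parent_a. Leaves are the labeled populations.
    """

    leaves: list[str]
    drift_edges: list[tuple[str, str]]
    admix_nodes: dict[str, tuple[str, str]] = field(default_factory=dict)
    lengths: np.ndarray | None = None
    gammas: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.nodes = sorted(
            {n for e in self.drift_edges for n in e}
            | set(self.admix_nodes)
            | {p for ps in self.admix_nodes.values() for p in ps}
        )
        parents: dict[str, list[str]] = {n: [] for n in self.nodes}
        for c, p in self.drift_edges:
            parents[c].append(p)
        for c, (a, b) in self.admix_nodes.items():
            parents[c] += [a, b]
        self.parents = parents
        roots = [n for n in self.nodes if not parents[n]]
        if len(roots) != 1:
            raise ValueError(f"expected one root, found {roots}")
        self.root = roots[0]
        self._check_acyclic()
        reachable = self._reachable_from_root()
        for leaf in self.leaves:
            if leaf not in reachable:
                raise ValueError(f"leaf {leaf!r} not reachable from root")
        if self.lengths is None:
            self.lengths = np.zeros(len(self.drift_edges))
        if self.gammas is None:
            self.gammas = np.full(len(self.admix_nodes), 0.5)

    def _children(self) -> dict[str, list[str]]:
        ch: dict[str, list[str]] = {n: [] for n in self.nodes}
        for c, p in self.drift_edges:
            ch[p].append(c)
        for c, (a, b) in self.admix_nodes.items():
            ch[a].append(c)
            ch[b].append(c)
        return ch

    def _check_acyclic(self) -> None:
        state: dict[str, int] = {}

        def visit(n: str) -> None:
            state[n] = 1
            for p in self.parents[n]:
                if state.get(p) == 1:
                    raise ValueError("graph contains a cycle")
                if p not in state:
                    visit(p)
            state[n] = 2

        for n in self.nodes:
            if n not in state:
                visit(n)

    def _reachable_from_root(self) -> set[str]:
        ch = self._children()
        seen = {self.root}
        stack = [self.root]
        while stack:
            for c in ch[stack.pop()]:
                if c not in seen:
                    seen.add(c)
                    stack.append(c)
        return seen

    # -- parameterized quantities ------------------------------------------

    def edge_weights(self) -> np.ndarray:
        """w_X(e): admixture-weight mass of leaf-to-root paths through each
        drift edge; shape (n_leaves, n_drift_edges)."""
        gamma = {n: self.gammas[i] for i, n in enumerate(sorted(self.admix_nodes))}
        eidx = {e: i for i, e in enumerate(self.drift_edges)}
        W = np.zeros((len(self.leaves), len(self.drift_edges)))
        for li, leaf in enumerate(self.leaves):
            mass = {leaf: 1.0}
            order = self._upward_order(leaf)
            for node in order:
                m = mass.get(node, 0.0)
                if m == 0.0 or node == self.root:
                    continue
                if node in self.admix_nodes:
                    a, b = self.admix_nodes[node]
                    g = gamma[node]
                    mass[a] = mass.get(a, 0.0) + g * m
                    mass[b] = mass.get(b, 0.0) + (1 - g) * m
                else:
                    (p,) = [q for q in self.parents[node] if (node, q) in eidx]
                    W[li, eidx[(node, p)]] = m
                    mass[p] = mass.get(p, 0.0) + m
        return W

    def _upward_order(self, leaf: str) -> list[str]:
        # ancestors of the leaf, children before parents
        depth = {n: i for i, n in enumerate(self._topo_down())}
        anc = set()
        work = [leaf]
        while work:
            n = work.pop()
            if n in anc:
                continue
            anc.add(n)
            work += self.parents[n]
        return sorted(anc, key=lambda n: -depth[n])

    def _topo_down(self) -> list[str]:
        ch = self._children()
        indeg = {n: len(self.parents[n]) for n in self.nodes}
        order = [n for n in self.nodes if indeg[n] == 0]
        i = 0
        while i < len(order):
            for c in ch[order[i]]:
                indeg[c] -= 1
                if indeg[c] == 0:
                    order.append(c)
            i += 1
        return order

    def n_admix(self) -> int:
        return len(self.admix_nodes)

    def topology_hash(self) -> str:
        """Canonical topology identifier, invariant to node relabeling and
        to the orientation of admixture parents."""
        colors = {
            n: (f"leaf:{n}" if n in self.leaves else
                ("admix" if n in self.admix_nodes else "node"))
            for n in self.nodes
        }
        ch = self._children()
        for _ in range(len(self.nodes)):
            nxt = {}
            for n in self.nodes:
                down = sorted(colors[c] for c in ch[n])
                up = sorted(colors[p] for p in self.parents[n])
                nxt[n] = hashlib.sha1(
                    ("|".join([colors[n]] + down + ["^"] + up)).encode()
                ).hexdigest()[:16]
            colors = nxt
        edges = sorted(
            [(colors[c], colors[p], "d") for c, p in self.drift_edges]
            + [(colors[c], colors[p], "a")
               for c, ps in self.admix_nodes.items() for p in ps]
        )
        return hashlib.sha1(repr(edges).encode()).hexdigest()[:16]

    def with_params(self, lengths: np.ndarray, gammas: np.ndarray) -> "AdmixtureGraph":
        return replace(self, lengths=np.asarray(lengths, float),
                       gammas=np.asarray(gammas, float))

    def to_edge_list(self) -> list[tuple[str, str, str, float]]:
        out = [
            (c, p, "drift", float(self.lengths[i]))
            for i, (c, p) in enumerate(self.drift_edges)
        ]
        for i, (c, (a, b)) in enumerate(sorted(self.admix_nodes.items())):
            out.append((c, a, "admix", float(self.gammas[i])))
            out.append((c, b, "admix", float(1 - self.gammas[i])))
        return out


def expected_f2_matrix(graph: AdmixtureGraph) -> np.ndarray:
    """Expected f2 between all leaf pairs from the path-overlap algebra."""
    W = graph.edge_weights()
    diff = W[:, None, :] - W[None, :, :]
    return np.einsum("abe,abe,e->ab", diff, diff, graph.lengths)


def expected_f2(graph: AdmixtureGraph, a: str, b: str) -> float:
    m = expected_f2_matrix(graph)
    return float(m[graph.leaves.index(a), graph.leaves.index(b)])


@dataclass
class GraphFit:
    graph: AdmixtureGraph
    score: float
    worst_residual: float
    fitted_f2: np.ndarray
    observed_f2: np.ndarray
    converged: bool = True


def _observed_f2_stats(f2_blocks: F2BlockTable, leaves: list[str]):
    """Mean f2 matrix and per-pair jackknife variances for the leaf set."""
    idx = [f2_blocks.index(p) for p in leaves]
    k = len(leaves)
    obs = np.zeros((k, k))
    var = np.ones((k, k))
    bw = f2_blocks.weights
    for a in range(k):
        for b in range(a + 1, k):
            bv = f2_blocks.values[:, idx[a], idx[b]]
            est, se, _ = jackknife_mean_stat(bv, bw)
            obs[a, b] = obs[b, a] = est
            var[a, b] = var[b, a] = se**2
    # variance floor relative to the f2 scale keeps exact (noise-free)
    # inputs well-conditioned without touching noisy data
    floor = (1e-3 * max(np.abs(obs).max(), 1e-9)) ** 2
    var = np.maximum(var, floor)
    return obs, var


def _score(graph, lengths, gammas, obs, var, iu):
    g2 = graph.with_params(lengths, gammas)
    exp = expected_f2_matrix(g2)
    resid = (obs - exp)[iu]
    return float(np.sum(resid**2 / var[iu]))


def fit_graph(
    topology: AdmixtureGraph,
    f2_blocks: F2BlockTable,
    n_starts: int = 3,
    seed: int = 0,
) -> GraphFit:
    """Fit drift lengths and admixture weights to an observed f2 basis.

    Projected L-BFGS-B from ``n_starts`` random initializations; the score
    is the inverse-variance-weighted sum of squared f2 residuals and the
    worst residual is the largest |Z| over all f4 statistics implied by the
    fitted graph.
    """
    leaves = topology.leaves
    obs, var = _observed_f2_stats(f2_blocks, leaves)
    iu = np.triu_indices(len(leaves), k=1)
    ne, na = len(topology.drift_edges), topology.n_admix()
    rng = np.random.default_rng(seed)
    scale = max(obs.max(), 1e-4)

    def pack_obj(theta):
        return _score(topology, theta[:ne], theta[ne:], obs, var, iu)

    best = None
    bounds = [(0.0, None)] * ne + [(0.0, 1.0)] * na
    for s in range(n_starts):
        x0 = np.concatenate([
            rng.uniform(0, scale, ne),
            rng.uniform(0.2, 0.8, na),
        ])
        res = optimize.minimize(
            pack_obj, x0, method="L-BFGS-B", bounds=bounds,
            options={"ftol": 1e-15, "gtol": 1e-12, "maxiter": 1000},
        )
        if best is None or res.fun < best.fun:
            best = res
    fitted = topology.with_params(best.x[:ne], best.x[ne:])
    exp = expected_f2_matrix(fitted)

    worst = _worst_f4_residual(f2_blocks, fitted, exp)
    return GraphFit(
        graph=fitted, score=float(best.fun), worst_residual=worst,
        fitted_f2=exp, observed_f2=obs, converged=bool(best.success),
    )


def _worst_f4_residual(f2_blocks: F2BlockTable, graph: AdmixtureGraph,
                       exp_f2: np.ndarray) -> float:
    leaves = graph.leaves
    worst = 0.0
    li = {p: i for i, p in enumerate(leaves)}
    for a, b, c, d in itertools.combinations(leaves, 4):
        for (w, x, y, z) in ((a, b, c, d), (a, c, b, d), (a, d, b, c)):
            bv = f2_blocks.f4_blocks(w, x, y, z)
            est, se, _ = jackknife_mean_stat(bv, f2_blocks.weights)
            fit = 0.5 * (
                exp_f2[li[w], li[z]] + exp_f2[li[x], li[y]]
                - exp_f2[li[w], li[y]] - exp_f2[li[x], li[z]]
            )
            if se > 0:
                worst = max(worst, abs(est - fit) / se)
    return worst


# ---------------------------------------------------------------------------
# Topology generation and search


def _tree_edges(leaves: list[str], rng: np.random.Generator):
    """Random rooted binary tree via sequential random attachment."""
    leaves = list(leaves)
    rng.shuffle(leaves)
    counter = itertools.count()
    edges = [(leaves[0], "R"), (leaves[1], "R")]
    for leaf in leaves[2:]:
        c, p = edges[int(rng.integers(len(edges)))]
        mid = f"n{next(counter)}_{len(edges)}"
        edges.remove((c, p))
        edges += [(c, mid), (mid, p), (leaf, mid)]
    return edges


def random_graph(
    pops: list[str], n_admix: int, rng: np.random.Generator
) -> AdmixtureGraph:
    """Random topology with exactly ``n_admix`` admixture nodes."""
    for _ in range(200):
        edges = _tree_edges(pops, rng)
        admix: dict[str, tuple[str, str]] = {}
        ok = True
        for k in range(n_admix):
            g = AdmixtureGraph(leaves=pops, drift_edges=edges, admix_nodes=admix)
            cand = _admix_insertion(g, rng, tag=f"adm{k}")
            if cand is None:
                ok = False
                break
            edges, admix = cand
        if ok:
            return AdmixtureGraph(leaves=pops, drift_edges=edges, admix_nodes=admix)
    raise RuntimeError("failed to build a random graph")


def _descendants(edges, admix, node) -> set[str]:
    ch: dict[str, list[str]] = {}
    for c, p in edges:
        ch.setdefault(p, []).append(c)
    for c, (a, b) in admix.items():
        ch.setdefault(a, []).append(c)
        ch.setdefault(b, []).append(c)
    out = set()
    stack = [node]
    while stack:
        n = stack.pop()
        for c in ch.get(n, []):
            if c not in out:
                out.add(c)
                stack.append(c)
    return out


def _admix_insertion(graph: AdmixtureGraph, rng: np.random.Generator, tag: str):
    """Turn a drift edge's child into an admixture node fed from another edge."""
    edges = list(graph.drift_edges)
    admix = dict(graph.admix_nodes)
    if len(edges) < 3:
        return None
    for _ in range(50):
        (c, p) = edges[int(rng.integers(len(edges)))]
        desc = _descendants(edges, admix, c) | {c}
        others = [(u, v) for (u, v) in edges if u not in desc and v not in desc
                  and (u, v) != (c, p)]
        if not others:
            continue
        (u, v) = others[int(rng.integers(len(others)))]
        mid = f"{tag}_src"
        anode = f"{tag}"
        new_edges = [e for e in edges if e not in ((c, p), (u, v))]
        new_edges += [(u, mid), (mid, v), (c, anode)]
        new_admix = dict(admix)
        new_admix[anode] = (p, mid)
        try:
            AdmixtureGraph(leaves=graph.leaves, drift_edges=new_edges,
                           admix_nodes=new_admix)
        except ValueError:
            continue
        return new_edges, new_admix
    return None


def _propose(graph: AdmixtureGraph, rng: np.random.Generator):
    """One random topology move: subtree regraft, leaf swap, admixture-edge
    relocation, or admixture-orientation flip."""
    moves = ["regraft", "swap"]
    if graph.admix_nodes:
        moves += ["relocate", "flip"]
    move = moves[int(rng.integers(len(moves)))]
    edges = list(graph.drift_edges)
    admix = dict(graph.admix_nodes)
    try:
        if move == "swap":
            a, b = rng.choice(len(graph.leaves), 2, replace=False)
            la, lb = graph.leaves[a], graph.leaves[b]
            swap = {la: lb, lb: la}
            edges = [(swap.get(c, c), swap.get(p, p)) for c, p in edges]
            admix = {swap.get(c, c): tuple(swap.get(x, x) for x in ps)
                     for c, ps in admix.items()}
        elif move == "regraft":
            (c, p) = edges[int(rng.integers(len(edges)))]
            desc = _descendants(edges, admix, c) | {c}
            others = [(u, v) for (u, v) in edges
                      if u not in desc and (u, v) != (c, p)]
            if not others:
                return None
            (u, v) = others[int(rng.integers(len(others)))]
            mid = f"rg{int(rng.integers(10**9))}"
            edges.remove((c, p))
            edges.remove((u, v))
            edges += [(u, mid), (mid, v), (c, mid)]
            edges = _contract_passthrough(edges, admix, graph.leaves)
        elif move == "relocate":
            anode = list(admix)[int(rng.integers(len(admix)))]
            pa, pb = admix[anode]
            side = int(rng.integers(2))
            keep, drop = (pa, pb) if side else (pb, pa)
            desc = _descendants(edges, admix, anode) | {anode}
            cand = [(u, v) for (u, v) in edges if u not in desc and u != keep]
            if not cand:
                return None
            (u, v) = cand[int(rng.integers(len(cand)))]
            mid = f"rl{int(rng.integers(10**9))}"
            edges.remove((u, v))
            edges += [(u, mid), (mid, v)]
            admix[anode] = (keep, mid) if side else (mid, keep)
            edges = _contract_passthrough(edges, admix, graph.leaves)
        elif move == "flip":
            anode = list(admix)[int(rng.integers(len(admix)))]
            pa, pb = admix[anode]
            admix[anode] = (pb, pa)
        return AdmixtureGraph(leaves=graph.leaves, drift_edges=edges,
                              admix_nodes=admix)
    except (ValueError, KeyError):
        return None


def _contract_passthrough(edges, admix, leaves):
    """Remove internal tree nodes left with a single child and parent."""
    changed = True
    admix_parents = {p for ps in admix.values() for p in ps}
    while changed:
        changed = False
        nodes = {n for e in edges for n in e}
        for n in nodes:
            if n in leaves or n in admix or n in admix_parents:
                continue
            kids = [c for c, p in edges if p == n]
            pars = [p for c, p in edges if c == n]
            if len(kids) == 1 and len(pars) == 1:
                edges.remove((kids[0], n))
                edges.remove((n, pars[0]))
                edges.append((kids[0], pars[0]))
                changed = True
            elif len(kids) == 1 and len(pars) == 0:
                # degree-one root: drop the stalk
                edges.remove((kids[0], n))
                changed = True
    return edges


def find_graphs(
    f2_blocks: F2BlockTable,
    pops: list[str],
    n_admix: int,
    iterations: int = 100,
    seed: int = 0,
    max_moves: int = 60,
    patience: int = 20,
) -> list[dict]:
    """Randomized hill-climbing topology search.

    Each iteration starts from a random graph with exactly ``n_admix``
    admixture nodes and accepts strictly score-improving moves until
    ``patience`` consecutive proposals fail or ``max_moves`` are accepted.
    Results are deduplicated by topology hash; each record carries the
    hash, score, worst f4 residual and the fitted graph.
    """
    rng = np.random.default_rng(seed)
    results: dict[str, dict] = {}
    for it in range(iterations):
        graph = random_graph(pops, n_admix, rng)
        fit = fit_graph(graph, f2_blocks, n_starts=2, seed=int(rng.integers(2**31)))
        stalled = 0
        moves = 0
        while stalled < patience and moves < max_moves:
            prop = _propose(fit.graph, rng)
            if prop is None or prop.n_admix() != n_admix:
                stalled += 1
                continue
            pfit = fit_graph(prop, f2_blocks, n_starts=2,
                             seed=int(rng.integers(2**31)))
            if pfit.score < fit.score - 1e-10:
                fit = pfit
                moves += 1
                stalled = 0
            else:
                stalled += 1
        h = fit.graph.topology_hash()
        if h not in results or fit.score < results[h]["score"]:
            results[h] = {
                "hash": h, "score": fit.score,
                "worst_residual": fit.worst_residual, "graph": fit.graph,
                "fit": fit,
            }
    return sorted(results.values(), key=lambda r: r["score"])


def enumerate_trees(pops: list[str]) -> list[AdmixtureGraph]:
    """All labeled rooted binary tree topologies ((2n-3)!! of them)."""
    if len(pops) > 6:
        raise ValueError("exhaustive enumeration limited to 6 populations")
    if len(pops) < 2:
        raise ValueError("need at least 2 populations")
    counter = itertools.count()

    def root_of(edges):
        children = {c for c, _ in edges}
        parents = {p for _, p in edges}
        return (parents - children).pop()

    trees = [[(pops[0], "R0"), (pops[1], "R0")]]
    for leaf in pops[2:]:
        grown = []
        for t in trees:
            for (c, p) in t:  # insert on an existing edge
                mid = f"m{next(counter)}"
                grown.append(
                    [e for e in t if e != (c, p)]
                    + [(c, mid), (mid, p), (leaf, mid)]
                )
            new_root = f"m{next(counter)}"  # insert above the root
            grown.append(t + [(root_of(t), new_root), (leaf, new_root)])
        trees = grown
    seen = {}
    for edges in trees:
        g = AdmixtureGraph(leaves=list(pops), drift_edges=edges)
        seen.setdefault(g.topology_hash(), g)
    return list(seen.values())


def compare_fits(
    graph_a: AdmixtureGraph,
    graph_b: AdmixtureGraph,
    f2_blocks: F2BlockTable,
    n_boot: int = 500,
    seed: int = 0,
) -> dict:
    """Out-of-sample score comparison with SNP-block bootstrap.

    Blocks are split in half; both graphs are fitted on the fit half and
    scored per evaluation block; the two-sided p-value is the bootstrap
    tail probability of the mean score difference crossing zero.
    """
    nb = f2_blocks.values.shape[0]
    if nb < 10:
        raise ValueError("compare_fits requires at least 10 blocks")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(nb)
    fit_half, eval_half = perm[: nb // 2], perm[nb // 2:]

    def restrict(idx):
        return F2BlockTable(
            pops=f2_blocks.pops, values=f2_blocks.values[idx],
            weights=f2_blocks.weights[idx], n_snps=f2_blocks.n_snps,
        )

    fits = {}
    for name, g in (("a", graph_a), ("b", graph_b)):
        # seed derived from the topology: identical graphs fit identically
        gseed = (seed + int(g.topology_hash()[:8], 16)) % 2**31
        fits[name] = fit_graph(g, restrict(fit_half), n_starts=3, seed=gseed)

    leaves = graph_a.leaves
    if set(leaves) != set(graph_b.leaves):
        raise ValueError("graphs must share the same populations")
    idx = [f2_blocks.index(p) for p in leaves]
    iu = np.triu_indices(len(leaves), k=1)
    _, var = _observed_f2_stats(f2_blocks, leaves)

    diffs = np.zeros(eval_half.size)
    for name, sign in (("a", 1.0), ("b", -1.0)):
        exp = expected_f2_matrix(fits[name].graph)
        lidx = [leaves.index(p) for p in leaves]
        for bi, b in enumerate(eval_half):
            obs_b = f2_blocks.values[b][np.ix_(idx, idx)]
            resid = (obs_b - exp)[iu]
            diffs[bi] += sign * float(np.sum(resid**2 / var[iu]))

    if np.allclose(diffs, 0.0):
        return {"p": 1.0, "mean_diff": 0.0, "fit_a": fits["a"], "fit_b": fits["b"]}
    boot = rng.choice(diffs, size=(n_boot, diffs.size), replace=True).mean(axis=1)
    p_lo = (np.sum(boot <= 0) + 1) / (n_boot + 1)
    p_hi = (np.sum(boot >= 0) + 1) / (n_boot + 1)
    return {
        "p": float(min(1.0, 2 * min(p_lo, p_hi))),
        "mean_diff": float(diffs.mean()),
        "fit_a": fits["a"], "fit_b": fits["b"],
    }
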