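"""Discrete Bayesian belief network for driver identification.

The network is a directed acyclic graph whose nodes are discretized
landscape factors and ecosystem-service variables.  Each node carries a
conditional probability table (CPT) over its states given every parent
state configuration, estimated from co-registered cell data by Laplace-
smoothed counting.  Exact posterior marginals under evidence are computed
by variable elimination, with a full-joint enumeration oracle available for
verification on small networks.

Three analyses are built on inference:

* **variance reduction** — the sensitivity of an ES node Q to a factor F,
  ``VR = V(Q) - E_F[V(Q|F)]``, with node states mapped to numeric values
  (bin midpoints) so variance is defined;
* **scenario deltas** — clamp ES nodes to "high = 100%" / "low = 100%"
  states per a scenario design and record the change in every factor
  node-state probability (posterior minus prior);
* **driver identification** — a factor is a driver when any of its
  |posterior - prior| changes exceeds the 95th percentile of all pooled
  changes; the threshold's confidence interval comes from 10,000 bootstrap
  resamples of the pooled changes (percentile method).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "DiscreteNode",
    "DiscreteBayesNet",
    "ScenarioSpec",
    "DriverResult",
    "discretize_equal_frequency",
    "discretize_categorical",
    "learn_cpts",
    "infer_marginals",
    "joint_enumeration_oracle",
    "evaluate_network",
    "variance_reduction",
    "run_scenario",
    "identify_drivers",
    "scenarios_from_pairs",
    "random_network",
]

DEFAULT_STATE_LABELS = ("low", "medium", "high")


class ImpossibleEvidenceError(ValueError):
    """Evidence assigns zero probability under the network."""


@dataclass(frozen=True)
class DiscreteNode:
    """A named discrete variable with ordered states.

    ``bin_edges`` (for discretized continuous sources) are the interior
    boundaries plus outer range; ``midpoints`` maps each state to a numeric
    value for variance computations.  Categorical nodes (land use) have no
    edges; their numeric values default to the raw category codes.
    """

    name: str
    states: tuple
    bin_edges: tuple | None = None
    numeric_values: tuple | None = None

    def __post_init__(self):
        if len(self.states) < 2:
            raise ValueError(f"node {self.name!r} needs >= 2 states")
        if self.bin_edges is not None and not np.all(np.diff(self.bin_edges) > 0):
            raise ValueError(f"node {self.name!r} bin edges must strictly increase")

    @property
    def n_states(self) -> int:
        return len(self.states)

    def midpoints(self) -> np.ndarray:
        """Numeric value per state (bin midpoints for discretized nodes).

        Open-ended extreme bins are valued at the edge offset by half the
        adjacent bin width."""
        if self.numeric_values is not None:
            return np.asarray(self.numeric_values, dtype=float)
        if self.bin_edges is None:
            raise ValueError(f"node {self.name!r} has no numeric state mapping")
        e = np.asarray(self.bin_edges, dtype=float)
        return (e[:-1] + e[1:]) / 2.0

    def state_index(self, state) -> int:
        try:
            return self.states.index(state)
        except ValueError:
            raise KeyError(f"node {self.name!r} has no state {state!r}") from None


def discretize_equal_frequency(
    values: np.ndarray,
    n_states: int,
    name: str,
    labels=None,
) -> tuple[DiscreteNode, np.ndarray]:
    """Equal-frequency (quantile) discretization.

    Returns the node definition (with bin edges spanning the data range)
    and the per-value state indices.  Bin counts differ by at most one when
    the values are distinct; heavily tied data yields the feasible quantile
    partition (duplicate edges collapsed).
    """
    v = np.asarray(values, dtype=float)
    if np.ptp(v) == 0:
        raise ValueError(f"cannot discretize constant input for node {name!r}")
    if len(np.unique(v)) < n_states:
        raise ValueError(f"node {name!r}: fewer distinct values than states")
    qs = np.quantile(v, np.linspace(0, 1, n_states + 1))
    qs[0], qs[-1] = v.min(), v.max()
    edges = np.unique(qs)
    k = len(edges) - 1  # may be < n_states under heavy ties
    if labels is None:
        # extreme states are always named low/high so scenario clamps apply
        if k == 2:
            labels = ("low", "high")
        elif k == 3:
            labels = DEFAULT_STATE_LABELS
        else:
            labels = ("low",) + tuple(f"s{i}" for i in range(1, k - 1)) + ("high",)
    assignments = np.clip(np.searchsorted(edges, v, side="right") - 1, 0, k - 1)
    node = DiscreteNode(name=name, states=tuple(labels[:k]), bin_edges=tuple(edges))
    return node, assignments


def discretize_categorical(
    values: np.ndarray, name: str, categories
) -> tuple[DiscreteNode, np.ndarray]:
    """Map raw category codes to state indices over a fixed category list."""
    cats = list(categories)
    lookup = {c: i for i, c in enumerate(cats)}
    idx = np.array([lookup[v] for v in np.asarray(values).ravel()], dtype=np.int64)
    node = DiscreteNode(
        name=name,
        states=tuple(str(c) for c in cats),
        numeric_values=tuple(float(c) for c in cats),
    )
    return node, idx


@dataclass
class DiscreteBayesNet:
    """DAG + per-node CPT.  CPT for node X with parents (P1..Pk) is an
    ndarray of shape (|P1|, ..., |Pk|, |X|); each last-axis row sums to 1."""

    nodes: dict  # name -> DiscreteNode
    parents: dict  # name -> tuple of parent names (CPT axis order)
    cpts: dict = field(default_factory=dict)  # name -> ndarray

    def __post_init__(self):
        import networkx as nx

        g = nx.DiGraph()
        g.add_nodes_from(self.nodes)
        for child, pas in self.parents.items():
            for pa in pas:
                g.add_edge(pa, child)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("network structure contains a cycle")
        self.graph = g

    def validate_cpts(self, atol: float = 1e-12) -> None:
        for name, node in self.nodes.items():
            cpt = self.cpts[name]
            expected = tuple(self.nodes[p].n_states for p in self.parents[name]) + (
                node.n_states,
            )
            if cpt.shape != expected:
                raise ValueError(f"CPT shape mismatch for {name!r}: {cpt.shape} != {expected}")
            if not np.allclose(cpt.sum(axis=-1), 1.0, atol=atol):
                raise ValueError(f"CPT rows for {name!r} do not sum to 1")

    def children(self, name: str) -> list:
        return sorted(self.graph.successors(name))

    # -- serialization -------------------------------------------------
    def to_json(self) -> str:
        payload = {
            "nodes": {
                n: {
                    "states": list(node.states),
                    "bin_edges": list(node.bin_edges) if node.bin_edges else None,
                    "numeric_values": list(node.numeric_values)
                    if node.numeric_values
                    else None,
                }
                for n, node in self.nodes.items()
            },
            "parents": {n: list(p) for n, p in self.parents.items()},
            "cpts": {n: self.cpts[n].tolist() for n in self.nodes},
        }
        return json.dumps(payload)

    @classmethod
    def from_json(cls, text: str) -> "DiscreteBayesNet":
        d = json.loads(text)
        nodes = {
            n: DiscreteNode(
                name=n,
                states=tuple(spec["states"]),
                bin_edges=tuple(spec["bin_edges"]) if spec["bin_edges"] else None,
                numeric_values=tuple(spec["numeric_values"])
                if spec["numeric_values"]
                else None,
            )
            for n, spec in d["nodes"].items()
        }
        parents = {n: tuple(p) for n, p in d["parents"].items()}
        cpts = {n: np.asarray(d["cpts"][n], dtype=float) for n in nodes}
        return cls(nodes=nodes, parents=parents, cpts=cpts)


def learn_cpts(
    data: pd.DataFrame,
    nodes: dict,
    parents: dict,
    alpha: float = 1.0,
) -> DiscreteBayesNet:
    """Estimate CPTs by Laplace-smoothed counting from state-index data.

    ``data`` columns hold integer state indices per node.  For each parent
    configuration, ``P(s | pa) = (count_s + alpha) / (sum_counts + alpha*|S|)``;
    parent configurations never observed receive a uniform row (pure
    pseudocount).
    """
    net = DiscreteBayesNet(nodes=nodes, parents=parents)
    for name, node in nodes.items():
        pas = parents[name]
        pa_shape = tuple(nodes[p].n_states for p in pas)
        shape = pa_shape + (node.n_states,)
        counts = np.zeros(shape, dtype=float)
        cols = [data[p].to_numpy() for p in pas] + [data[name].to_numpy()]
        np.add.at(counts, tuple(cols), 1.0)
        if alpha > 0:
            counts = counts + alpha
        totals = counts.sum(axis=-1, keepdims=True)
        with np.errstate(invalid="ignore", divide="ignore"):
            cpt = counts / totals
        # alpha == 0 with an unseen configuration: fall back to uniform.
        empty = (totals == 0)[..., 0]
        if empty.any():
            cpt[empty] = 1.0 / node.n_states
        net.cpts[name] = cpt
    net.validate_cpts()
    return net


# ---------------------------------------------------------------------------
# Inference: variable elimination
# ---------------------------------------------------------------------------


def _cpt_factor(net: DiscreteBayesNet, name: str):
    return tuple(net.parents[name]) + (name,), net.cpts[name]


def _restrict(variables, table, evidence):
    """Slice a factor on evidence assignments."""
    keep, index = [], []
    for v in variables:
        if v in evidence:
            index.append(evidence[v])
        else:
            index.append(slice(None))
            keep.append(v)
    return tuple(keep), table[tuple(index)]


def _multiply(f1, f2):
    v1, t1 = f1
    v2, t2 = f2
    out_vars = list(v1) + [v for v in v2 if v not in v1]
    a1 = t1.reshape(t1.shape + (1,) * (len(out_vars) - len(v1)))
    # align t2's axes to out_vars
    perm_shape = []
    src_axes = {v: i for i, v in enumerate(v2)}
    expand = [src_axes[v] if v in src_axes else None for v in out_vars]
    t2e = t2
    # build t2 broadcast to out_vars order
    order = [a for a in expand if a is not None]
    t2e = np.transpose(t2, order) if order else t2
    shape = []
    it = iter(t2e.shape)
    for v in out_vars:
        shape.append(next(it) if v in src_axes else 1)
    t2e = t2e.reshape(shape)
    return tuple(out_vars), a1 * t2e


def _sum_out(factor, var):
    variables, table = factor
    ax = variables.index(var)
    return tuple(v for v in variables if v != var), table.sum(axis=ax)


def _eliminate(factors, elim_order):
    for var in elim_order:
        related = [f for f in factors if var in f[0]]
        if not related:
            continue
        factors = [f for f in factors if var not in f[0]]
        prod = related[0]
        for f in related[1:]:
            prod = _multiply(prod, f)
        factors.append(_sum_out(prod, var))
    return factors


def _normalize_evidence(net: DiscreteBayesNet, evidence) -> dict:
    ev = {}
    for name, state in (evidence or {}).items():
        node = net.nodes[name]
        ev[name] = state if isinstance(state, (int, np.integer)) else node.state_index(state)
    return ev


def infer_marginals(
    net: DiscreteBayesNet,
    evidence: dict | None = None,
    query: list | None = None,
) -> dict:
    """Posterior marginals (dict name -> probability vector) by variable
    elimination.  Raises :class:`ImpossibleEvidenceError` when the evidence
    has zero probability."""
    ev = _normalize_evidence(net, evidence)
    query = list(net.nodes) if query is None else list(query)
    base = []
    for name in net.nodes:
        variables, table = _cpt_factor(net, name)
        base.append(_restrict(variables, table, ev))
    # cheap min-degree-style static order: fewest states first
    out = {}
    for q in query:
        if q in ev:
            vec = np.zeros(net.nodes[q].n_states)
            vec[ev[q]] = 1.0
            out[q] = vec
            continue
        elim = [v for v in net.nodes if v != q and v not in ev]
        elim.sort(key=lambda v: net.nodes[v].n_states)
        factors = _eliminate(list(base), elim)
        prod = (tuple(), np.array(1.0))
        for f in factors:
            prod = _multiply(prod, f)
        variables, table = prod
        if variables != (q,):
            table = table.reshape(-1) if table.ndim else np.atleast_1d(table)
        z = table.sum()
        if z <= 0:
            raise ImpossibleEvidenceError(f"evidence has zero probability (query {q!r})")
        out[q] = table / z
    return out


def joint_enumeration_oracle(
    net: DiscreteBayesNet,
    evidence: dict | None = None,
    max_size: int = 10**6,
) -> dict:
    """Exact marginals by materializing the full joint table (test oracle)."""
    names = list(net.nodes)
    sizes = [net.nodes[n].n_states for n in names]
    if int(np.prod(sizes)) > max_size:
        raise ValueError("joint state space too large for enumeration")
    ev = _normalize_evidence(net, evidence)
    joint = np.ones(sizes, dtype=float)
    axis = {n: i for i, n in enumerate(names)}
    for name in names:
        variables, table = _cpt_factor(net, name)
        order = [axis[v] for v in variables]
        # expand the CPT to the full joint axes
        expanded = np.ones([1] * len(names))
        shape = [1] * len(names)
        for v, s in zip(variables, table.shape):
            shape[axis[v]] = s
        perm = np.argsort(order)
        expanded = np.transpose(table, perm).reshape(shape)
        joint = joint * expanded
    for name, s in ev.items():
        sel = [slice(None)] * len(names)
        keepmask = np.zeros(sizes[axis[name]])
        keepmask[s] = 1.0
        shape = [1] * len(names)
        shape[axis[name]] = sizes[axis[name]]
        joint = joint * keepmask.reshape(shape)
    z = joint.sum()
    if z <= 0:
        raise ImpossibleEvidenceError("evidence has zero probability")
    joint = joint / z
    out = {}
    for name in names:
        axes = tuple(i for i in range(len(names)) if i != axis[name])
        out[name] = joint.sum(axis=axes)
    return out


# ---------------------------------------------------------------------------
# Validation, sensitivity, scenarios, drivers
# ---------------------------------------------------------------------------


def _posterior_target_given_rest(net, name, data: pd.DataFrame) -> np.ndarray:
    """P(target | all other observed nodes), vectorized over data rows.

    With every non-target node observed, the posterior involves only the
    target's own CPT slice and its children's CPT slices (Markov blanket);
    this is exact and equal to variable elimination.
    """
    node = net.nodes[name]
    n = len(data)
    logp = np.zeros((n, node.n_states))
    # target's own CPT: index parents per row, vary target state
    pas = net.parents[name]
    idx = tuple(data[p].to_numpy() for p in pas)
    own = net.cpts[name][idx]  # (n, n_states)
    probs = own.copy()
    for child in net.children(name):
        cpas = net.parents[child]
        cpt = net.cpts[child]
        t_ax = cpas.index(name)
        # gather per-row probability of the observed child state for each
        # candidate target state
        gather = []
        for s in range(node.n_states):
            cols = tuple(
                np.full(n, s, dtype=np.int64) if p == name else data[p].to_numpy()
                for p in cpas
            ) + (data[child].to_numpy(),)
            gather.append(cpt[cols])
        probs = probs * np.stack(gather, axis=1)
    z = probs.sum(axis=1, keepdims=True)
    z[z == 0] = 1.0
    return probs / z


def evaluate_network(
    nodes: dict,
    parents: dict,
    data: pd.DataFrame,
    target_nodes,
    split: float = 0.7,
    seed: int = 0,
    alpha: float = 1.0,
) -> dict:
    """Error-matrix validation: random split, CPTs learned on the training
    fraction, each target predicted on the test rows as the arg-max
    posterior state given all non-target evidence.

    Returns {'net', 'per_target': {name: {'confusion', 'accuracy'}},
    'overall_accuracy'} with confusion[i, j] = count(true i, predicted j).
    """
    rng = np.random.default_rng(seed)
    n = len(data)
    perm = rng.permutation(n)
    n_train = int(round(split * n))
    if n_train == 0 or n_train == n:
        raise ValueError("split leaves an empty train or test set")
    train = data.iloc[perm[:n_train]].reset_index(drop=True)
    test = data.iloc[perm[n_train:]].reset_index(drop=True)
    net = learn_cpts(train, nodes, parents, alpha=alpha)
    per_target, accs = {}, []
    for name in target_nodes:
        post = _posterior_target_given_rest(net, name, test)
        pred = post.argmax(axis=1)
        true = test[name].to_numpy()
        k = nodes[name].n_states
        confusion = np.zeros((k, k), dtype=int)
        np.add.at(confusion, (true, pred), 1)
        acc = float((pred == true).mean())
        per_target[name] = {"confusion": confusion, "accuracy": acc}
        accs.append(acc)
    return {"net": net, "per_target": per_target, "overall_accuracy": float(np.mean(accs))}


def variance_reduction(net: DiscreteBayesNet, target: str, factor: str) -> float:
    """VR = V(Q) - E_F[V(Q|F)] with state values Xq from the target node's
    numeric mapping (bin midpoints)."""
    xq = net.nodes[target].midpoints()
    prior = infer_marginals(net, query=[target, factor])
    pq, pf = prior[target], prior[factor]
    eq = float(pq @ xq)
    vq = float(pq @ (xq - eq) ** 2)
    expected_cond_var = 0.0
    for s, p_f in enumerate(pf):
        if p_f <= 0:
            continue
        post = infer_marginals(net, evidence={factor: s}, query=[target])[target]
        e_c = float(post @ xq)
        expected_cond_var += p_f * float(post @ (xq - e_c) ** 2)
    return vq - expected_cond_var


@dataclass(frozen=True)
class ScenarioSpec:
    """A scenario clamps ES node states with probability 1.

    Types follow the four designs: I maximizes a synergistic set (all
    clamped high), II minimizes it (all low), III/IV set the two sides of a
    trade-off pair to opposite extremes."""

    name: str
    scenario_type: str  # I | II | III | IV
    clamped: tuple  # tuple of (node, state)

    def __post_init__(self):
        if self.scenario_type not in ("I", "II", "III", "IV"):
            raise ValueError("scenario_type must be one of I, II, III, IV")


def run_scenario(net: DiscreteBayesNet, scenario: ScenarioSpec) -> pd.DataFrame:
    """Posterior-minus-prior probability change for every non-clamped
    node state under the scenario's hard evidence."""
    evidence = {node: state for node, state in scenario.clamped}
    for node, state in evidence.items():
        if node not in net.nodes:
            raise KeyError(f"scenario clamps unknown node {node!r}")
    prior = infer_marginals(net)
    post = infer_marginals(net, evidence=evidence)
    rows = []
    clamped_names = set(evidence)
    for name, node in net.nodes.items():
        if name in clamped_names:
            continue
        for i, state in enumerate(node.states):
            rows.append(
                {
                    "scenario": scenario.name,
                    "scenario_type": scenario.scenario_type,
                    "node": name,
                    "state": state,
                    "prior": float(prior[name][i]),
                    "posterior": float(post[name][i]),
                    "delta": float(post[name][i] - prior[name][i]),
                }
            )
    return pd.DataFrame(rows)


def scenarios_from_pairs(pair_results, high_state="high", low_state="low") -> list:
    """Build scenario specs from a classified pair matrix.

    Every significant synergy pair contributes a Scenario I (both high) and
    II (both low); every trade-off pair a Scenario III (A high, B low) and
    IV (A low, B high)."""
    specs = []
    i = 0
    for pr in pair_results:
        a, b = pr.pair
        if pr.relation == "synergy":
            i += 1
            specs.append(ScenarioSpec(f"scenario{i}", "I", ((a, high_state), (b, high_state))))
            i += 1
            specs.append(ScenarioSpec(f"scenario{i}", "II", ((a, low_state), (b, low_state))))
        elif pr.relation == "trade-off":
            i += 1
            specs.append(ScenarioSpec(f"scenario{i}", "III", ((a, high_state), (b, low_state))))
            i += 1
            specs.append(ScenarioSpec(f"scenario{i}", "IV", ((a, low_state), (b, high_state))))
    return specs


@dataclass
class DriverResult:
    threshold: float
    ci95: tuple
    drivers: list
    deltas: pd.DataFrame
    percentile: float
    n_boot: int


def identify_drivers(
    deltas: pd.DataFrame,
    percentile: float = 95.0,
    n_boot: int = 10_000,
    seed: int = 0,
    factor_nodes=None,
) -> DriverResult:
    """Threshold the pooled |posterior - prior| changes at their
    ``percentile``-th percentile; a factor node is a driver when any of its
    changes strictly exceeds the threshold.  The threshold's 95% CI is the
    2.5/97.5 percentile range of the statistic over ``n_boot`` bootstrap
    resamples (with replacement) of the pooled changes."""
    import warnings

    if len(deltas) == 0:
        raise ValueError("empty delta table")
    if len(deltas) < 20:
        raise ValueError("need at least 20 delta values")
    if n_boot < 100:
        warnings.warn("n_boot < 100 gives an unreliable confidence interval")
    pool = deltas if factor_nodes is None else deltas[deltas["node"].isin(factor_nodes)]
    if len(pool) == 0:
        raise ValueError("no delta values for the requested factor nodes")
    values = np.abs(pool["delta"].to_numpy(dtype=float))
    threshold = float(np.percentile(values, percentile))
    rng = np.random.default_rng(seed)
    idx = rng.integers(0, len(values), size=(n_boot, len(values)))
    boot = np.percentile(values[idx], percentile, axis=1)
    ci = (float(np.percentile(boot, 2.5)), float(np.percentile(boot, 97.5)))
    exceed = pool[np.abs(pool["delta"].to_numpy()) > threshold]
    drivers = sorted(exceed["node"].unique())
    return DriverResult(
        threshold=threshold,
        ci95=ci,
        drivers=drivers,
        deltas=deltas,
        percentile=percentile,
        n_boot=n_boot,
    )


def random_network(
    seed: int = 0,
    max_nodes: int = 8,
    max_states: int = 3,
    edge_prob: float = 0.35,
) -> DiscreteBayesNet:
    """A random small DAG with Dirichlet CPT rows (testing utility)."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(2, max_nodes + 1))
    names = [f"n{i}" for i in range(n)]
    nodes = {
        name: DiscreteNode(
            name=name,
            states=tuple(f"s{j}" for j in range(int(rng.integers(2, max_states + 1)))),
            numeric_values=None,
        )
        for name in names
    }
    parents = {}
    for i, name in enumerate(names):
        pas = [names[j] for j in range(i) if rng.random() < edge_prob]
        parents[name] = tuple(pas[:3])  # cap fan-in
    net = DiscreteBayesNet(nodes=nodes, parents=parents)
    for name in names:
        shape = tuple(nodes[p].n_states for p in parents[name]) + (nodes[name].n_states,)
        cpt = rng.dirichlet(np.ones(shape[-1]), size=shape[:-1] or (1,))
        net.cpts[name] = cpt.reshape(shape)
    net.validate_cpts()
    return net
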