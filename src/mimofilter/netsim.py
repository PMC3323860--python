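"""Linear-Gaussian causal network simulator.

Generates the synthetic benchmark used to evaluate cause prioritization:
a 40-node directed acyclic graph with three indirect causes feeding five
direct causes, a latent (unobserved) disease node mediating all causal
influence on three observable targets, seventeen downstream effect nodes,
and eleven isolated irrelevant nodes. Every structural equation is linear
with weights drawn uniformly from [-2, 2] and additive Gaussian noise of
standard deviation sigma. The three target nodes are emitted as binary
classes (median split of their continuous values); the latent node is
never observed. All observed columns are standardized to zero mean and
unit variance so that sigma directly controls the relative noise level.

The key property of this construction: direct causes act on the targets
only through the latent node, so any pair of them forms a (hidden)
collider pattern with each target and their interaction information given
a target is negative, while pairs of downstream effects share the targets
as common causes and interact positively. The causal filter exploits
exactly this asymmetry.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .data import Dataset, FeatureMatrix, TargetSet

__all__ = [
    "ROLES",
    "NetworkSpec",
    "default_network",
    "simulate",
    "discretize_binary",
]

ROLES = frozenset(
    {
        "indirect_cause",
        "direct_cause",
        "latent",
        "primary_target",
        "secondary_target",
        "effect",
        "irrelevant",
    }
)

#: roles never emitted as observed feature columns
_UNOBSERVED = {"latent", "primary_target", "secondary_target"}


@dataclass
class NetworkSpec:
    """A DAG with node roles, fixed edge weights, and a noise level."""

    nodes: list[tuple[str, str]]  # (id, role)
    edges: list[tuple[str, str, float]]  # (parent, child, weight)
    noise_sd: float
    weight_range: tuple[float, float] = (-2.0, 2.0)

    def __post_init__(self) -> None:
        ids = [i for i, _ in self.nodes]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate node ids")
        for _, role in self.nodes:
            if role not in ROLES:
                raise ValueError(f"unknown role {role!r}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be > 0")
        known = set(ids)
        for p, c, _ in self.edges:
            if p not in known or c not in known:
                raise ValueError(f"edge ({p}, {c}) references an unknown node")

    def graph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        for node_id, role in self.nodes:
            g.add_node(node_id, role=role)
        for p, c, w in self.edges:
            g.add_edge(p, c, weight=w)
        if not nx.is_directed_acyclic_graph(g):
            raise ValueError("network specification contains a cycle")
        return g

    def roles(self) -> dict[str, str]:
        return dict(self.nodes)

    def to_json(self) -> str:
        return json.dumps(
            {
                "nodes": [{"id": i, "role": r} for i, r in self.nodes],
                "edges": [
                    {"parent": p, "child": c, "weight": w} for p, c, w in self.edges
                ],
                "noise_sd": self.noise_sd,
                "weight_range": list(self.weight_range),
            },
            indent=1,
        )

    @classmethod
    def from_json(cls, text: str) -> "NetworkSpec":
        obj = json.loads(text)
        return cls(
            nodes=[(d["id"], d["role"]) for d in obj["nodes"]],
            edges=[(d["parent"], d["child"], float(d["weight"])) for d in obj["edges"]],
            noise_sd=float(obj["noise_sd"]),
            weight_range=tuple(obj.get("weight_range", (-2.0, 2.0))),
        )


def default_network(seed: int, sigma: float) -> NetworkSpec:
    """The default 40-node benchmark topology.

    Nodes n1-n3 are indirect causes, each a parent of every direct cause
    n4-n8; the direct causes are the sole parents of the latent node n9;
    n9 is the sole parent of the targets n10 (primary), n11 and n12
    (secondary); effect nodes n13-n29 are each the child of exactly one
    target, assigned round-robin (n10, n11, n12, n10, ...); n30-n40 are
    isolated. Edge weights are drawn uniformly from [-2, 2] with a
    seed-reproducible generator.
    """
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    rng = np.random.default_rng(seed)
    lo, hi = -2.0, 2.0

    def ids(a: int, b: int) -> list[str]:
        return [f"n{k}" for k in range(a, b + 1)]

    nodes: list[tuple[str, str]] = []
    nodes += [(i, "indirect_cause") for i in ids(1, 3)]
    nodes += [(i, "direct_cause") for i in ids(4, 8)]
    nodes += [("n9", "latent")]
    nodes += [("n10", "primary_target")]
    nodes += [(i, "secondary_target") for i in ids(11, 12)]
    nodes += [(i, "effect") for i in ids(13, 29)]
    nodes += [(i, "irrelevant") for i in ids(30, 40)]

    edges: list[tuple[str, str, float]] = []

    def w() -> float:
        return float(rng.uniform(lo, hi))

    for parent in ids(1, 3):
        for child in ids(4, 8):
            edges.append((parent, child, w()))
    for parent in ids(4, 8):
        edges.append((parent, "n9", w()))
    targets = ["n10", "n11", "n12"]
    for t in targets:
        edges.append(("n9", t, w()))
    for k, eff in enumerate(ids(13, 29)):
        edges.append((targets[k % 3], eff, w()))

    return NetworkSpec(nodes=nodes, edges=edges, noise_sd=sigma, weight_range=(lo, hi))


def discretize_binary(values) -> np.ndarray:
    """Median split: 1 where value > sample median, else 0.

    Balanced within one sample for distinct values; invariant under
    monotone affine transforms of the input. Constant input is an error
    (no split exists).
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("need at least 2 values")
    if np.all(arr == arr[0]):
        raise ValueError("cannot binarize a constant vector")
    return (arr > np.median(arr)).astype(np.int8)


def simulate(spec: NetworkSpec, n_samples: int, seed: int) -> Dataset:
    """Draw a dataset from the structural model.

    Root nodes are standard normal; every other node is the weighted sum
    of its parents plus N(0, noise_sd^2) noise, evaluated in topological
    order. Effect nodes are children of the *continuous* target values;
    discretization applies only to the emitted classification targets.
    """
    if n_samples < 20:
        raise ValueError("n_samples must be >= 20")
    g = spec.graph()
    rng = np.random.default_rng(seed)
    values: dict[str, np.ndarray] = {}
    for node in nx.topological_sort(g):
        parents = list(g.predecessors(node))
        if not parents:
            values[node] = rng.standard_normal(n_samples)
        else:
            acc = np.zeros(n_samples)
            for p in parents:
                acc += g.edges[p, node]["weight"] * values[p]
            values[node] = acc + rng.normal(0.0, spec.noise_sd, n_samples)

    roles = spec.roles()
    observed = [i for i, r in spec.nodes if r not in _UNOBSERVED]
    raw = np.column_stack([values[i] for i in observed])
    features = FeatureMatrix.from_raw(raw, feature_ids=observed)

    primary = [i for i, r in spec.nodes if r == "primary_target"]
    secondary = [i for i, r in spec.nodes if r == "secondary_target"]
    if len(primary) != 1:
        raise ValueError("spec must define exactly one primary target")
    targets = TargetSet(
        primary=discretize_binary(values[primary[0]]),
        secondaries=[discretize_binary(values[s]) for s in secondary],
    )
    truth = {i: roles[i] for i in observed}
    return Dataset(features=features, targets=targets, truth=truth, name="simulated")
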