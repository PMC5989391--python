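"""MI/CMI-based PC-algorithm pruning of a complete variable graph.

The procedure starts from a completely connected undirected graph over
all variables (genes and CpG probes), then

1. scores every edge by mutual information with a permutation
   significance test and drops edges with p >= p_cutoff;
2. for every surviving edge (i, j), tests each common graph-neighbor k
   one at a time with the conditional mutual information CMI(i, j | k);
   if any k renders the edge non-significant the edge is declared
   indirect and removed (removals are deferred to the end of the sweep);
3. applies a mutual-information floor (default MI > 0.1 bits) to drop
   weak connections.

Permutation indices are derived from (seed, edge id), so results do not
depend on the order in which variables or edges are visited.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

from .containers import VariableVector
from .errors import DegenerateInputError, ValidationError
from .infotheory import (
    conditional_mutual_information,
    mutual_information,
    permutation_significance,
)

logger = logging.getLogger(__name__)


@dataclass
class PcParams:
    """Tuning knobs of the pruning pipeline.

    p_cutoff : permutation p-value below which an edge is significant.
    mi_floor_bits : edges with MI <= this (bits) are removed last.
    n_perm : permutations per significance test.
    seed : master seed; per-edge seeds are derived from it.
    max_conditioning : size of conditioning sets (only 1 is supported).
    iterate_cmi : repeat CMI sweeps until no edge is removed.
    """

    p_cutoff: float = 0.01
    mi_floor_bits: float = 0.1
    n_perm: int = 100
    seed: int = 0
    max_conditioning: int = 1
    iterate_cmi: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.p_cutoff < 1.0:
            raise ValidationError("p_cutoff must lie in (0, 1)")
        if self.mi_floor_bits < 0.0:
            raise ValidationError("mi_floor_bits must be >= 0")
        if self.max_conditioning != 1:
            raise ValidationError("only order-1 conditioning is supported")


@dataclass
class RegulatoryNetwork:
    """Undirected weighted graph over variables, plus the data behind it.

    ``graph`` edges carry mi_nats / mi_bits / normalized_mi / p_value
    once scored.  ``data`` maps variable id -> VariableVector.
    """

    graph: nx.Graph
    data: dict[str, VariableVector] = field(default_factory=dict)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    @property
    def edges(self) -> set[frozenset]:
        return {frozenset(e) for e in self.graph.edges}

    def edge_attrs(self, a: str, b: str) -> dict:
        return dict(self.graph.edges[a, b])

    def copy(self) -> "RegulatoryNetwork":
        return RegulatoryNetwork(self.graph.copy(), dict(self.data))


def edge_seed(base_seed: int, a: str, b: str, k: str = "") -> int:
    """Stable per-edge (and per-conditioner) seed, independent of order."""
    lo, hi = sorted((a, b))
    h = zlib.crc32(f"{lo}\t{hi}\t{k}".encode())
    return (int(base_seed) * 2654435761 + h) % (2**31 - 1)


def build_complete_graph(variables: list[VariableVector]) -> RegulatoryNetwork:
    """Complete graph over the variables; edge weights unset."""
    if len(variables) < 2:
        raise ValidationError("need at least 2 variables")
    ids = [v.id for v in variables]
    if len(set(ids)) != len(ids):
        dup = sorted({i for i in ids if ids.count(i) > 1})
        raise ValidationError(f"duplicate variable ids: {dup}")
    lengths = {len(v) for v in variables}
    if len(lengths) != 1:
        raise ValidationError("variables have unequal sample counts")
    g = nx.complete_graph(ids)
    return RegulatoryNetwork(graph=g, data={v.id: v for v in variables})


def prune_by_mi(net: RegulatoryNetwork, params: PcParams) -> RegulatoryNetwork:
    """Score every edge by MI + permutation test; drop non-significant ones."""
    out = net.copy()
    for a, b in list(out.graph.edges):
        va, vb = out.data[a], out.data[b]
        try:
            mi = mutual_information(va, vb)
            sig = permutation_significance(
                va, vb, n_perm=params.n_perm, seed=edge_seed(params.seed, a, b)
            )
        except DegenerateInputError as err:
            raise DegenerateInputError(
                f"edge ({a}, {b}): {err}", variable_ids=(a, b)
            ) from err
        if sig.p_value >= params.p_cutoff:
            out.graph.remove_edge(a, b)
        else:
            out.graph.edges[a, b].update(
                mi_nats=mi.raw_nats,
                mi_bits=mi.raw_bits,
                normalized_mi=mi.normalized,
                p_value=sig.p_value,
            )
    return out


def prune_by_cmi(net: RegulatoryNetwork, params: PcParams) -> RegulatoryNetwork:
    """Remove edges rendered non-significant by any single common neighbor.

    Each sweep tests every edge against all its common neighbors on the
    entering graph and applies removals only after the sweep, so output
    does not depend on edge iteration order.  With ``iterate_cmi`` sweeps
    repeat until a fixed point.
    """
    out = net.copy()
    while True:
        to_remove: list[tuple[str, str]] = []
        for a, b in list(out.graph.edges):
            common = sorted(set(out.graph[a]) & set(out.graph[b]))
            for k in common:
                va, vb, vk = out.data[a], out.data[b], out.data[k]
                try:
                    sig = permutation_significance(
                        va,
                        vb,
                        vk,
                        n_perm=params.n_perm,
                        seed=edge_seed(params.seed, a, b, k),
                    )
                except DegenerateInputError as err:
                    raise DegenerateInputError(
                        f"edge ({a}, {b}) | {k}: {err}", variable_ids=(a, b, k)
                    ) from err
                if sig.p_value >= params.p_cutoff:
                    to_remove.append((a, b))
                    break
        for a, b in to_remove:
            out.graph.remove_edge(a, b)
        if not to_remove or not params.iterate_cmi:
            break
    return out


def apply_mi_floor(net: RegulatoryNetwork, params: PcParams) -> RegulatoryNetwork:
    """Drop edges whose MI (bits) does not exceed the floor."""
    out = net.copy()
    for a, b in list(out.graph.edges):
        bits = out.graph.edges[a, b].get("mi_bits")
        if bits is None:
            raise ValidationError(f"edge ({a}, {b}) has no MI; run prune_by_mi first")
        if bits <= params.mi_floor_bits:
            out.graph.remove_edge(a, b)
    return out


def infer_network(
    variables: list[VariableVector], params: PcParams | None = None
) -> RegulatoryNetwork:
    """Full pipeline: complete graph -> MI prune -> CMI prune -> MI floor."""
    params = params or PcParams()
    net = build_complete_graph(variables)
    net = prune_by_mi(net, params)
    net = prune_by_cmi(net, params)
    net = apply_mi_floor(net, params)
    return net


def write_edges(net: RegulatoryNetwork, path) -> None:
    """Write the edge list as TSV: node_a, node_b, mi_bits, normalized_mi, p_value."""
    with open(path, "w") as fh:
        fh.write("node_a\tnode_b\tmi_bits\tnormalized_mi\tp_value\n")
        for a, b in sorted(tuple(sorted(e)) for e in net.graph.edges):
            attrs = net.graph.edges[a, b]
            fh.write(
                f"{a}\t{b}\t{attrs.get('mi_bits', float('nan')):.6g}"
                f"\t{attrs.get('normalized_mi', float('nan')):.6g}"
                f"\t{attrs.get('p_value', float('nan')):.6g}\n"
            )
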