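"""Core regulatory circuitry (CRC) and three-node network motifs.

CRC assembly: a TF is auto-regulated when one of its distal DREs overlaps
a super-enhancer and carries the TF's own binding motif within +/- 250 bp
of the probe; TF t1 cross-regulates t2 when such a DRE of t2 carries t1's
motif.  The CRC graph is the union of all auto- and cross-regulations.

Motif census: every weakly connected three-node induced subgraph of a
directed network (self-loops ignored) falls into exactly one of the 13
connected triad isomorphism classes.  The class table is built at import
time by exhaustive generation of all 64 labeled 3-node digraphs and
canonicalization over the 6 node permutations; class ids 1..13 order the
canonical forms by (edge count, canonical code) and are documented in
docs/methods.md.  Significance uses degree-preserving randomized networks
(directed double-edge swaps): Z_c = (obs_c - mean_c) / sd_c per class.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from itertools import permutations, product
from typing import Mapping, Sequence

import networkx as nx
import numpy as np

from .containers import AnnotationMap
from .dre import DrePair
from .enrichment import FLANK_BP, MotifHit, tf_binding_association
from .errors import ValidationError

logger = logging.getLogger(__name__)

# Ordered node pairs backing the 6-bit code of a labeled 3-node digraph.
_PAIRS = [(0, 1), (0, 2), (1, 0), (1, 2), (2, 0), (2, 1)]


def _canonical(code: int) -> int:
    """Smallest code among the 6 node relabelings of a 3-node digraph."""
    bits = {_PAIRS[i]: (code >> i) & 1 for i in range(6)}
    best = 1 << 6
    for perm in permutations(range(3)):
        c = 0
        for i, (u, v) in enumerate(_PAIRS):
            if bits[(perm[u], perm[v])]:
                c |= 1 << i
        best = min(best, c)
    return best


def _weakly_connected(code: int) -> bool:
    und = {frozenset(p) for i, p in enumerate(_PAIRS) if (code >> i) & 1}
    if len(und) < 2:
        return False
    # 3 nodes with >= 2 distinct undirected pairs covering all nodes
    nodes = set()
    for p in und:
        nodes |= p
    return nodes == {0, 1, 2}


def _build_class_table() -> tuple[dict[int, int], dict[int, str], dict[int, int]]:
    """canonical code -> class id (1..13), class id -> MAN name, code->class."""
    canon_forms = sorted(
        {_canonical(c) for c in range(64) if _weakly_connected(c)},
        key=lambda c: (bin(c).count("1"), c),
    )
    assert len(canon_forms) == 13  # the 13 connected triad classes
    canon_to_class = {c: i + 1 for i, c in enumerate(canon_forms)}
    names = {}
    for c, cls in canon_to_class.items():
        g = nx.DiGraph()
        g.add_nodes_from(range(3))
        g.add_edges_from(p for i, p in enumerate(_PAIRS) if (c >> i) & 1)
        names[cls] = nx.triad_type(g)
    code_to_class = {
        code: canon_to_class[_canonical(code)]
        for code in range(64)
        if _weakly_connected(code)
    }
    return canon_to_class, names, code_to_class


CANONICAL_CLASSES, CLASS_NAMES, _CODE_TO_CLASS = _build_class_table()
N_CLASSES = 13


@dataclass
class CrcGraph:
    """Directed TF-TF regulation graph with per-edge provenance."""

    graph: nx.DiGraph = field(default_factory=nx.DiGraph)
    auto_loops: set[str] = field(default_factory=set)

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edges(self) -> list[tuple[str, str]]:
        return list(self.graph.edges)


@dataclass(frozen=True)
class MotifProfile:
    """Counts (and optionally Z-scores) over the 13 connected triad classes."""

    counts: np.ndarray  # length 13, class id order
    z_scores: np.ndarray | None = None
    null_mean: np.ndarray | None = None
    null_sd: np.ndarray | None = None
    n_random: int = 0
    n_subgraphs: int = 0
    degenerate: tuple[int, ...] = ()  # classes with sd=0 but obs != mean


@dataclass(frozen=True)
class SeRegion:
    """Super-enhancer interval, 1-based inclusive."""

    id: str
    chrom: str
    start: int
    end: int


def assemble_crc(
    distal_dres: Sequence[DrePair],
    se_regions: Sequence[SeRegion],
    motif_hits: Sequence[MotifHit],
    tf_list: Sequence[str],
    annotations: AnnotationMap,
    flank_bp: int = FLANK_BP,
) -> CrcGraph:
    """Assemble auto/cross regulatory loops over SE-overlapping distal DREs."""
    if not tf_list:
        raise ValidationError("tf_list must be nonempty")
    crc = CrcGraph()
    if not se_regions:
        logger.warning("empty super-enhancer set: CRC graph is empty")
        return crc
    tf_set = set(tf_list)
    tf_pairs = [
        p for p in distal_dres
        if p.gene_id in tf_set and p.locus_class == "distal"
    ]
    if not tf_pairs:
        return crc

    def overlapping_se(probe_ann) -> str | None:
        for se in se_regions:
            if se.chrom == probe_ann.chrom and se.start <= probe_ann.position <= se.end:
                return se.id
        return None

    assoc = tf_binding_association(tf_pairs, motif_hits, annotations, flank_bp)
    for pair in tf_pairs:
        se_id = overlapping_se(annotations[pair.probe_id])
        if se_id is None:
            continue
        target = pair.gene_id
        for regulator in sorted(tf_set):
            if pair.probe_id not in assoc.get(regulator, ()):
                continue
            crc.graph.add_edge(
                regulator, target, dre=pair.probe_id, se=se_id
            )
            if regulator == target:
                crc.auto_loops.add(target)
    return crc


def _iter_connected_triples(g: nx.DiGraph):
    und = {n: (set(g.predecessors(n)) | set(g.successors(n))) - {n} for n in g}
    seen = set()
    for center, nbrs in und.items():
        ns = sorted(nbrs - {center})
        for i in range(len(ns)):
            for j in range(i + 1, len(ns)):
                trip = tuple(sorted((center, ns[i], ns[j])))
                if trip not in seen:
                    seen.add(trip)
                    yield trip


def _triple_code(g: nx.DiGraph, trip: tuple) -> int:
    code = 0
    for i, (u, v) in enumerate(_PAIRS):
        if g.has_edge(trip[u], trip[v]):
            code |= 1 << i
    return code


def triad_census(network: nx.DiGraph) -> np.ndarray:
    """Counts per connected triad class (length-13 array, class id order).

    Every weakly connected node triple is counted exactly once; self-loops
    are ignored.
    """
    g = nx.DiGraph(network)
    g.remove_edges_from(nx.selfloop_edges(g))
    counts = np.zeros(N_CLASSES, dtype=int)
    for trip in _iter_connected_triples(g):
        code = _triple_code(g, trip)
        cls = _CODE_TO_CLASS.get(code)
        if cls is not None:  # center-based enumeration only yields connected
            counts[cls - 1] += 1
    return counts


def _degree_preserving_randomization(
    g: nx.DiGraph, rng: np.random.Generator, n_attempts: int
) -> nx.DiGraph:
    """Directed double-edge swaps: (a->b, c->d) becomes (a->d, c->b)."""
    h = nx.DiGraph()
    h.add_nodes_from(g.nodes)
    h.add_edges_from(g.edges)
    edges = list(h.edges)
    m = len(edges)
    if m < 2:
        return h
    for _ in range(n_attempts):
        i, j = rng.integers(0, m, size=2)
        if i == j:
            continue
        a, b = edges[i]
        c, d = edges[j]
        if a == d or c == b or a == c or b == d:
            continue
        if h.has_edge(a, d) or h.has_edge(c, b):
            continue
        h.remove_edge(a, b)
        h.remove_edge(c, d)
        h.add_edge(a, d)
        h.add_edge(c, b)
        edges[i] = (a, d)
        edges[j] = (c, b)
    return h


def motif_zscores(
    network: nx.DiGraph,
    n_random: int = 200,
    seed: int = 0,
    swaps_per_edge: int = 10,
    scheme: str = "swap",
) -> MotifProfile:
    """Motif enrichment against randomized same-size networks.

    ``scheme='swap'`` (default) preserves each node's in- and out-degree
    via double-edge swaps; ``scheme='gnm'`` draws Erdos-Renyi digraphs
    with the same node and edge counts.  Z = 0 where sd = 0 and the
    observed count equals the null mean; classes where sd = 0 but counts
    differ are flagged in ``degenerate`` (Z set to +/- inf).
    """
    if n_random < 2:
        raise ValidationError("n_random must be >= 2")
    g = nx.DiGraph(network)
    g.remove_edges_from(nx.selfloop_edges(g))
    if g.number_of_nodes() < 3:
        raise ValidationError("network needs at least 3 nodes")
    obs = triad_census(g)
    rng = np.random.default_rng(seed)
    nulls = np.zeros((n_random, N_CLASSES), dtype=int)
    n_edges = g.number_of_edges()
    nodes = list(g.nodes)
    for r in range(n_random):
        if scheme == "swap":
            rand = _degree_preserving_randomization(
                g, rng, swaps_per_edge * max(n_edges, 1)
            )
        elif scheme == "gnm":
            rand = nx.gnm_random_graph(
                len(nodes), n_edges, directed=True,
                seed=int(rng.integers(0, 2**31 - 1)),
            )
        else:
            raise ValidationError(f"unknown randomization scheme {scheme!r}")
        nulls[r] = triad_census(rand)
    mean = nulls.mean(axis=0)
    sd = nulls.std(axis=0, ddof=1)
    z = np.zeros(N_CLASSES)
    degenerate = []
    for c in range(N_CLASSES):
        if sd[c] > 0:
            z[c] = (obs[c] - mean[c]) / sd[c]
        elif obs[c] != mean[c]:
            z[c] = np.inf if obs[c] > mean[c] else -np.inf
            degenerate.append(c + 1)
    return MotifProfile(
        counts=obs,
        z_scores=z,
        null_mean=mean,
        null_sd=sd,
        n_random=n_random,
        n_subgraphs=int(obs.sum()),
        degenerate=tuple(degenerate),
    )


def motif_profile_frame(profile: MotifProfile):
    """Tabular view: class, name, count, mean_random, sd_random, z."""
    import pandas as pd

    rows = []
    for c in range(N_CLASSES):
        rows.append({
            "class": c + 1,
            "name": CLASS_NAMES[c + 1],
            "count": int(profile.counts[c]),
            "mean_random": float(profile.null_mean[c])
            if profile.null_mean is not None else np.nan,
            "sd_random": float(profile.null_sd[c])
            if profile.null_sd is not None else np.nan,
            "z": float(profile.z_scores[c]) if profile.z_scores is not None
            else np.nan,
        })
    return pd.DataFrame(rows)
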