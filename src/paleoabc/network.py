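"""Statistical-parsimony haplotype networks per time point.

Haplotypes are connected in order of increasing mutational distance, with
unsampled intermediate nodes inserted on multi-step edges, up to the
statistical-parsimony connection limit: the largest number of steps at
which a connection is non-homoplastic with the requested confidence
(Templeton-Crandall-Sing style 95% criterion).  Per-time-point networks
are stacked into a temporal network by linking identical haplotypes found
in adjacent layers.

The probability-of-parsimony model treats substitutions at each site as
Poisson with a per-site intensity estimated from the observed divergence
(Jukes-Cantor plug-in); a connection of j steps is parsimonious when each
of the j differing sites experienced exactly one substitution.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .seqdata import HaplotypeTable, SerialAlignment, collapse_haplotypes

__all__ = [
    "HaplotypeNetwork",
    "LayeredNetwork",
    "parsimony_probability",
    "parsimony_limit",
    "build_network",
    "build_temporal_network",
    "write_graphml",
    "write_dot",
]

MISSING_CHARS = frozenset("NRYSWKMBDHV")


def parsimony_probability(j: int, L: int) -> float:
    """Probability that a j-step connection over L sites is non-homoplastic.

    Uses the Jukes-Cantor plug-in estimate of the per-site substitution
    intensity ``theta`` from the observed proportion of differing sites
    ``p = j/L`` and assumes Poisson substitution counts per site: each
    observed difference is parsimonious when its site experienced exactly
    one substitution, so ``P_j = [theta e^-theta / P(site differs)]^j``.
    """
    if j <= 0:
        return 1.0
    p = j / L
    if p >= 0.75:
        return 0.0
    theta = -0.75 * np.log1p(-4.0 * p / 3.0)
    p_diff = 0.75 * (1.0 - np.exp(-4.0 * theta / 3.0))
    p_single = theta * np.exp(-theta) / p_diff
    return float(p_single ** j)


def parsimony_limit(L: int, confidence: float = 0.95,
                    override: int | None = None) -> int:
    """Largest step count whose parsimony probability exceeds ``confidence``.

    ``override`` bypasses the computation (a user-chosen fixed limit).
    """
    if override is not None:
        return int(override)
    if L < 1:
        raise ValueError("alignment length must be >= 1")
    if not 0.0 < confidence < 1.0:
        raise ValueError("confidence must be in (0, 1)")
    limit = 0
    for j in range(1, L + 1):
        if j / L >= 0.75:
            # beyond the Jukes-Cantor correction's reach: every shorter
            # connection passed, so nothing constrains the network
            return L
        pj = parsimony_probability(j, L)
        if pj > confidence:
            limit = j
        else:
            break
    else:
        return L
    return limit


def _distance(a: str, b: str, gap_as_state: bool = True) -> int:
    """Mutational steps between two sequences.

    Ambiguity codes are treated as missing; gaps count as a fifth state by
    default (set ``gap_as_state=False`` to treat them as missing too).
    """
    missing = MISSING_CHARS if gap_as_state else MISSING_CHARS | {"-"}
    d = 0
    for x, y in zip(a, b):
        if x in missing or y in missing:
            continue
        if x != y:
            d += 1
    return d


@dataclass
class HaplotypeNetwork:
    """A parsimony network for one set of haplotypes.

    ``graph`` nodes are haplotype indices (ints, attributes ``counts``,
    ``freq``, ``kind="haplotype"``) or inferred intermediates (strings
    ``"u0", "u1", ...``, ``kind="intermediate"``); every edge is one
    mutational step.
    """

    graph: nx.Graph
    table: HaplotypeTable
    limit: int

    @property
    def n_components(self) -> int:
        return nx.number_connected_components(self.graph)

    def components(self):
        return list(nx.connected_components(self.graph))

    def steps_between(self, i: int, j: int) -> int:
        """Realized path length (mutational steps) between two haplotypes."""
        return nx.shortest_path_length(self.graph, i, j)


def build_network(table: HaplotypeTable, limit: int,
                  gap_as_state: bool = True) -> HaplotypeNetwork:
    """Connect haplotypes agglomeratively under the parsimony limit.

    Pairs are joined in order of increasing mutational distance (ties
    broken by higher combined haplotype frequency, then input order);
    multi-step connections insert unsampled intermediate nodes; pairs
    already connected through the partial network are skipped, and pairs
    beyond the limit stay in separate components.
    """
    k = table.k
    if k < 1:
        raise ValueError("need at least one haplotype")
    freq = [sum(c.values()) for c in table.counts]
    g = nx.Graph()
    for i in range(k):
        g.add_node(i, kind="haplotype", counts=dict(table.counts[i]),
                   freq=freq[i])

    pairs = []
    for i, j in itertools.combinations(range(k), 2):
        d = _distance(table.haplotypes[i], table.haplotypes[j], gap_as_state)
        pairs.append((d, -(freq[i] + freq[j]), i, j))
    pairs.sort()

    next_u = 0
    for d, _, i, j in pairs:
        if d > limit:
            break
        if nx.has_path(g, i, j):
            continue
        prev = i
        for _step in range(d - 1):
            u = f"u{next_u}"
            next_u += 1
            g.add_node(u, kind="intermediate", counts={}, freq=0)
            g.add_edge(prev, u, steps=1)
            prev = u
        g.add_edge(prev, j, steps=1)
    return HaplotypeNetwork(graph=g, table=table, limit=limit)


@dataclass
class LayeredNetwork:
    """Per-layer parsimony networks plus cross-layer identity links.

    ``layers`` are layer labels ordered oldest to youngest; ``links`` are
    ``(layer_a, hap_a, layer_b, hap_b)`` tuples connecting *identical*
    sequences in adjacent layers.  ``near_matches`` lists the closest
    non-identical cross-layer pairs (one step or more) for reporting; they
    are never linked.
    """

    layers: list[str]
    networks: dict[str, HaplotypeNetwork]
    links: list[tuple[str, int, str, int]]
    near_matches: list[tuple[str, int, str, int, int]] = field(default_factory=list)

    def layer_haplotype_counts(self) -> dict[str, int]:
        """Number of distinct haplotypes per layer, oldest to youngest."""
        return {lab: self.networks[lab].table.k for lab in self.layers}


def build_temporal_network(tables: dict[str, HaplotypeTable],
                           limit: int, gap_as_state: bool = True) -> LayeredNetwork:
    """Stack per-layer networks into a temporal network.

    ``tables`` maps layer label to its haplotype table, ordered oldest to
    youngest.  Identity links join exactly equal haplotype sequences in
    adjacent layers.
    """
    layers = list(tables)
    networks = {lab: build_network(tab, limit, gap_as_state)
                for lab, tab in tables.items()}
    links = []
    near = []
    for la, lb in zip(layers, layers[1:]):
        ta, tb = tables[la], tables[lb]
        index_b = {h: j for j, h in enumerate(tb.haplotypes)}
        for i, h in enumerate(ta.haplotypes):
            j = index_b.get(h)
            if j is not None:
                links.append((la, i, lb, j))
            else:
                best = min(range(tb.k), key=lambda jj: _distance(
                    h, tb.haplotypes[jj], gap_as_state))
                near.append((la, i, lb, best,
                             _distance(h, tb.haplotypes[best], gap_as_state)))
    return LayeredNetwork(layers=layers, networks=networks, links=links,
                          near_matches=near)


def network_from_alignment(aln: SerialAlignment, confidence: float = 0.95,
                           limit: int | None = None) -> LayeredNetwork:
    """Per-layer networks straight from a serial alignment (oldest first)."""
    lim = parsimony_limit(aln.length, confidence, override=limit)
    tables = {lab: collapse_haplotypes(aln.layer_slice(lab))
              for lab in aln.layers()}
    return build_temporal_network(tables, lim)


def _export_graph(net: HaplotypeNetwork | LayeredNetwork) -> nx.Graph:
    if isinstance(net, HaplotypeNetwork):
        g = net.graph.copy()
        for _, data in g.nodes(data=True):
            data["counts"] = str(data.get("counts", {}))
        return g
    g = nx.Graph()
    for lab in net.layers:
        for node, data in net.networks[lab].graph.nodes(data=True):
            g.add_node(f"{lab}:{node}", layer=lab, kind=data["kind"],
                       counts=str(data.get("counts", {})),
                       freq=data.get("freq", 0))
        for a, b, data in net.networks[lab].graph.edges(data=True):
            g.add_edge(f"{lab}:{a}", f"{lab}:{b}", steps=data.get("steps", 1),
                       kind="mutation")
    for la, i, lb, j in net.links:
        g.add_edge(f"{la}:{i}", f"{lb}:{j}", steps=0, kind="identity")
    return g


def write_graphml(net: HaplotypeNetwork | LayeredNetwork, path) -> None:
    nx.write_graphml(_export_graph(net), path)


def write_dot(net: HaplotypeNetwork | LayeredNetwork, path) -> None:
    """Minimal DOT export (plain text, no pydot dependency)."""
    g = _export_graph(net)
    with open(path, "w") as fh:
        fh.write("graph haplotypes {\n")
        for node, data in g.nodes(data=True):
            shape = "circle" if data.get("kind") == "haplotype" else "point"
            fh.write(f'  "{node}" [shape={shape}, label="{node} ({data.get("freq", 0)})"];\n')
        for a, b, data in g.edges(data=True):
            style = "dashed" if data.get("kind") == "identity" else "solid"
            fh.write(f'  "{a}" -- "{b}" [style={style}];\n')
        fh.write("}\n")
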