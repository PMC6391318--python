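"""Mutational-step networks over 7-locus STR haplotypes.

Distances between repeat-count vectors come in two conventions, both
first-class:

* ``locus_count`` — number of loci at which the two haplotypes differ
  (one change per locus regardless of size); the package default for
  founder dating, since a single stepwise mutation per changed locus is
  the typical regime over the timescales involved;
* ``stepwise_sum`` — total number of single-repeat steps,
  sum over loci of |r1 - r2|, the stepwise-mutation-model step count.

The ancestral haplotype of a lineage is the locus-wise modal vector;
ties at a locus are broken by preferring the allele minimizing the
total stepwise distance to the sample, then the numerically smallest
allele, and every applied tie-break is reported.  The network itself is
the union of all minimum spanning trees over the distinct haplotypes
(Kruskal with all co-minimal edges kept), which retains alternative
equally-parsimonious connections instead of forcing a tree.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import networkx as nx
from networkx.utils import UnionFind

from .haplotypes import StrHaplotype
from .markers import STR_LOCI

__all__ = [
    "DistanceMode",
    "ModalResult",
    "TieBreak",
    "HaplotypeNetwork",
    "NetworkError",
    "step_distance",
    "modal_haplotype",
    "build_network",
    "export_network",
]


class NetworkError(ValueError):
    pass


class DistanceMode(str, Enum):
    LOCUS_COUNT = "locus_count"
    STEPWISE_SUM = "stepwise_sum"


def _vec(h: Union[StrHaplotype, Sequence[int]]) -> Tuple[int, ...]:
    repeats = getattr(h, "repeats", None)
    return tuple(repeats) if repeats is not None else tuple(h)


def step_distance(
    h1: Union[StrHaplotype, Sequence[int]],
    h2: Union[StrHaplotype, Sequence[int]],
    mode: DistanceMode = DistanceMode.LOCUS_COUNT,
) -> int:
    """Mutational-step distance between two repeat-count vectors."""
    v1, v2 = _vec(h1), _vec(h2)
    if len(v1) != len(v2):
        raise NetworkError(f"length mismatch: {len(v1)} vs {len(v2)}")
    mode = DistanceMode(mode)
    if mode is DistanceMode.LOCUS_COUNT:
        return sum(a != b for a, b in zip(v1, v2))
    return sum(abs(a - b) for a, b in zip(v1, v2))


@dataclass(frozen=True)
class TieBreak:
    locus: str
    tied_alleles: Tuple[int, ...]
    chosen: int
    rule: str


@dataclass(frozen=True)
class ModalResult:
    haplotype: StrHaplotype
    ties: Tuple[TieBreak, ...]


def modal_haplotype(
    haps: Sequence[Union[StrHaplotype, Sequence[int]]],
    loci: Sequence[str] = STR_LOCI,
) -> ModalResult:
    """Locus-wise modal (ancestral) haplotype of a sample.

    At each locus the most frequent repeat count wins.  A frequency tie
    is resolved by the allele with the smallest total |step| distance to
    the sample at that locus, then by the smallest allele; applied
    tie-breaks are returned, never silent.
    """
    if not haps:
        raise NetworkError("empty haplotype list")
    vecs = [_vec(h) for h in haps]
    n_loci = len(vecs[0])
    if any(len(v) != n_loci for v in vecs):
        raise NetworkError("haplotypes of differing length")
    modal: List[int] = []
    ties: List[TieBreak] = []
    for k in range(n_loci):
        alleles = [v[k] for v in vecs]
        counts = Counter(alleles)
        top = max(counts.values())
        tied = sorted(a for a, c in counts.items() if c == top)
        if len(tied) == 1:
            modal.append(tied[0])
            continue
        # tie: minimize total per-locus stepwise distance, then smallest
        totals = {a: sum(abs(a - x) for x in alleles) for a in tied}
        best = min(totals.values())
        candidates = sorted(a for a, t in totals.items() if t == best)
        chosen = candidates[0]
        rule = (
            "min_total_distance"
            if len(candidates) == 1
            else "min_total_distance_then_smallest_allele"
        )
        locus_name = loci[k] if k < len(loci) else f"locus{k}"
        ties.append(TieBreak(locus_name, tuple(tied), chosen, rule))
        modal.append(chosen)
    return ModalResult(StrHaplotype(tuple(modal)) if n_loci == len(STR_LOCI)
                       else _AnyLengthHap(tuple(modal)), tuple(ties))


class _AnyLengthHap:
    """Minimal stand-in for non-7-locus vectors (property tests)."""

    def __init__(self, repeats: Tuple[int, ...]):
        self.repeats = repeats

    def __len__(self):
        return len(self.repeats)


@dataclass
class HaplotypeNetwork:
    """Minimum-spanning network over distinct STR haplotypes."""

    graph: nx.Graph  # nodes = repeat tuples; attrs: multiplicity, families
    ancestral_node: Tuple[int, ...]
    distance_mode: DistanceMode
    ties: Tuple[TieBreak, ...] = ()

    @property
    def n_nodes(self) -> int:
        return self.graph.number_of_nodes()

    @property
    def total_edge_weight(self) -> int:
        return sum(w for _, _, w in self.graph.edges.data("weight"))


def build_network(
    haps: Sequence[StrHaplotype],
    mode: DistanceMode = DistanceMode.LOCUS_COUNT,
    ancestral: Optional[Union[StrHaplotype, Sequence[int]]] = None,
) -> HaplotypeNetwork:
    """Build the union-of-MSTs network over the distinct haplotypes.

    Node sizes are sample multiplicities; the ancestral node is the
    locus-wise modal haplotype unless supplied.  Kruskal is run over
    sorted weight classes keeping every edge that joins two components
    still separate before its weight class — exactly the edges belonging
    to at least one minimum spanning tree — so equal-weight alternatives
    survive as cycles.
    """
    if not haps:
        raise NetworkError("empty haplotype list")
    mode = DistanceMode(mode)
    counts: Counter = Counter()
    families: Dict[Tuple[int, ...], List[str]] = {}
    for h in haps:
        v = _vec(h)
        counts[v] += 1
        fam = getattr(h, "source_family", "")
        if fam:
            families.setdefault(v, []).append(fam)
    if ancestral is None:
        modal = modal_haplotype(haps)
        anc, ties = _vec(modal.haplotype), modal.ties
    else:
        anc, ties = _vec(ancestral), ()

    g = nx.Graph()
    for v, c in sorted(counts.items()):
        g.add_node(v, multiplicity=c, families=",".join(sorted(families.get(v, []))),
                   ancestral=(v == anc))
    if anc not in g:
        g.add_node(anc, multiplicity=0, families="", ancestral=True)

    nodes = sorted(g.nodes)
    edges = sorted(
        (step_distance(u, v, mode), u, v)
        for i, u in enumerate(nodes)
        for v in nodes[i + 1 :]
    )
    uf = UnionFind(nodes)
    i = 0
    while i < len(edges):
        w = edges[i][0]
        group = []
        while i < len(edges) and edges[i][0] == w:
            group.append(edges[i])
            i += 1
        # membership in some MST is decided against components *before*
        # this weight class; merge only afterwards
        kept = [(u, v) for _, u, v in group if uf[u] != uf[v]]
        for u, v in kept:
            g.add_edge(u, v, weight=w)
        for u, v in kept:
            uf.union(u, v)
    return HaplotypeNetwork(g, anc, mode, ties)


def _node_label(v: Tuple[int, ...]) -> str:
    return "-".join(str(x) for x in v)


def export_network(
    net: HaplotypeNetwork, path: Union[str, Path], format: str = "graphml"
) -> None:
    """Write the network as GraphML (via networkx) or DOT (plain text)."""
    if net.graph.number_of_nodes() == 0:
        raise NetworkError("refusing to export an empty network")
    path = Path(path)
    if format == "graphml":
        g = nx.relabel_nodes(net.graph, _node_label, copy=True)
        nx.write_graphml(g, path)
        return
    if format == "dot":
        lines = ["graph haplotype_network {"]
        for v, data in sorted(net.graph.nodes(data=True)):
            shape = "doublecircle" if data.get("ancestral") else "circle"
            lines.append(
                f'  "{_node_label(v)}" [multiplicity={data.get("multiplicity", 0)}, '
                f"shape={shape}];"
            )
        for u, v, w in sorted(net.graph.edges.data("weight")):
            lines.append(f'  "{_node_label(u)}" -- "{_node_label(v)}" [label={w}];')
        lines.append("}")
        path.write_text("\n".join(lines) + "\n")
        return
    raise NetworkError(f"unknown export format {format!r}")
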