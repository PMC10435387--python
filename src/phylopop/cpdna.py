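"""Organelle variant calling, haplotype collapsing and median-joining
networks.

The network construction follows the classic median-joining scheme:
iterate a minimum-spanning network (epsilon-relaxed) over the current
vertex set, add majority-consensus median vectors for triplets when the
star connection is shorter than the triangle, and finally prune inferred
vertices that no longer shorten the network.  Candidate processing is in
lexicographic order so the output is deterministic.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np
import pandas as pd

from .simulate import CpPileup

__all__ = [
    "call_cp_variants",
    "apply_masks",
    "collapse_haplotypes",
    "parsimony_informative",
    "median_joining_network",
    "count_mutation_steps",
    "quadripartite_total",
    "hamming",
]

_BASE_CHARS = "ACGT"


def quadripartite_total(inverted_repeat: int, large_single_copy: int,
                        small_single_copy: int) -> int:
    """Total circular genome length: 2 x IR + LSC + SSC."""
    return 2 * inverted_repeat + large_single_copy + small_single_copy


# ----------------------------------------------------------------------
# variant calling from pileups
# ----------------------------------------------------------------------
def call_cp_variants(
    pileups: dict[str, CpPileup],
    min_variant_fraction: float = 0.5,
    min_coverage_fraction: float = 0.3,
) -> tuple[list[int], pd.DataFrame]:
    """Union of per-sample variable positions plus per-sample base calls.

    A position is variable for a sample iff its variant-read fraction is
    strictly > ``min_variant_fraction`` and its coverage strictly >
    ``min_coverage_fraction`` x that sample's median coverage.  Returns
    (sorted 1-based positions, samples x positions DataFrame of consensus
    bases).
    """
    if not pileups:
        raise ValueError("no pileups supplied")
    variable: set[int] = set()
    medians = {}
    for sample, p in pileups.items():
        if p.coverage.sum() == 0:
            raise ValueError(f"sample {sample!r} has zero coverage genome-wide")
        med = float(np.median(p.coverage))
        medians[sample] = med
        ref_idx = p.ref.astype(int)
        ref_reads = p.counts[np.arange(p.length), ref_idx]
        total = p.counts.sum(axis=1)
        variant_reads = total - ref_reads
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, variant_reads / np.maximum(total, 1), 0.0)
        hit = (frac > min_variant_fraction) & (p.coverage > min_coverage_fraction * med)
        variable.update((np.flatnonzero(hit) + 1).tolist())
    positions = sorted(variable)
    calls = {}
    for sample, p in pileups.items():
        row = []
        for pos in positions:
            counts = p.counts[pos - 1]
            row.append(_BASE_CHARS[int(np.argmax(counts))])
        calls[sample] = row
    table = pd.DataFrame.from_dict(calls, orient="index", columns=positions)
    return positions, table


def apply_masks(
    positions: Sequence[int],
    masks: Sequence[tuple[int, int, str]],
) -> tuple[list[int], dict[str, int]]:
    """Remove positions inside any 0-based half-open mask interval.

    Overlapping masks attribute a removed position to the first matching
    mask in input order.  Returns (retained positions, removals per mask
    label).
    """
    removed_by: dict[str, int] = {}
    retained = []
    for pos in positions:
        z = pos - 1
        hit = None
        for start, end, label in masks:
            if start <= z < end:
                hit = label
                break
        if hit is None:
            retained.append(pos)
        else:
            removed_by[hit] = removed_by.get(hit, 0) + 1
    return retained, removed_by


def collapse_haplotypes(
    sequences: dict[str, str],
    populations: Optional[dict[str, str]] = None,
) -> pd.DataFrame:
    """Collapse identical strings into a haplotype table.

    Rows are haplotypes (lexicographic), with total count, member samples
    and optional per-population counts.  Missing states ('N', '-', '?')
    raise with the offending sample and column.
    """
    lengths = {len(s) for s in sequences.values()}
    if len(lengths) > 1:
        raise ValueError("sequences have unequal lengths")
    for sample, seq in sorted(sequences.items()):
        for i, c in enumerate(seq):
            if c in "N-?":
                raise ValueError(f"missing state in sample {sample!r} at column {i}")
    groups: dict[str, list[str]] = {}
    for sample in sorted(sequences):
        groups.setdefault(sequences[sample], []).append(sample)
    rows = []
    for i, hap in enumerate(sorted(groups)):
        members = sorted(groups[hap])
        row = {"haplotype": hap, "count": len(members), "samples": ",".join(members)}
        if populations:
            pops: dict[str, int] = {}
            for m in members:
                pops[populations[m]] = pops.get(populations[m], 0) + 1
            for p, c in sorted(pops.items()):
                row[f"n_{p}"] = c
        rows.append(row)
    out = pd.DataFrame(rows)
    if populations:
        out = out.fillna(0)
    return out


def parsimony_informative(alignment: Sequence[str]) -> list[int]:
    """0-based columns with >= 2 states each occurring in >= 2 sequences."""
    if not alignment:
        return []
    length = len(alignment[0])
    if any(len(s) != length for s in alignment):
        raise ValueError("sequences have unequal lengths")
    keep = []
    for j in range(length):
        col = [s[j] for s in alignment]
        counts = pd.Series(col).value_counts()
        if (counts >= 2).sum() >= 2:
            keep.append(j)
    return keep


# ----------------------------------------------------------------------
# median-joining network
# ----------------------------------------------------------------------
def hamming(a: str, b: str) -> int:
    if len(a) != len(b):
        raise ValueError("unequal sequence lengths")
    return sum(x != y for x, y in zip(a, b))


def _minimax_distances(vertices: list[str]) -> dict[tuple[str, str], int]:
    """Max edge weight on the MST path between every vertex pair."""
    g = nx.Graph()
    for a, b in itertools.combinations(vertices, 2):
        g.add_edge(a, b, weight=hamming(a, b))
    mst = nx.minimum_spanning_tree(g, algorithm="kruskal")
    out: dict[tuple[str, str], int] = {}
    for src in vertices:
        # DFS over the MST tracking the max edge seen
        stack = [(src, 0)]
        seen = {src}
        while stack:
            node, mx = stack.pop()
            for nb in mst.neighbors(node):
                if nb not in seen:
                    seen.add(nb)
                    m2 = max(mx, mst[node][nb]["weight"])
                    out[(src, nb)] = m2
                    stack.append((nb, m2))
    return out


def _mst_length(vertices: list[str]) -> int:
    if len(vertices) < 2:
        return 0
    g = nx.Graph()
    for a, b in itertools.combinations(vertices, 2):
        g.add_edge(a, b, weight=hamming(a, b))
    mst = nx.minimum_spanning_tree(g, algorithm="kruskal")
    return int(sum(d["weight"] for _, _, d in mst.edges(data=True)))


def _spanning_network(vertices: list[str], epsilon: int) -> nx.Graph:
    """Epsilon-relaxed minimum spanning network under Hamming distance."""
    g = nx.Graph()
    g.add_nodes_from(vertices)
    if len(vertices) < 2:
        return g
    minimax = _minimax_distances(vertices)
    for a, b in itertools.combinations(sorted(vertices), 2):
        d = hamming(a, b)
        if d <= minimax[(a, b)] + epsilon:
            g.add_edge(a, b, weight=d)
    return g


def _median_vector(a: str, b: str, c: str) -> str:
    out = []
    for x, y, z in zip(a, b, c):
        if x == y or x == z:
            out.append(x)
        elif y == z:
            out.append(y)
        else:  # three-way tie: keep the lexicographically smallest state
            out.append(min(x, y, z))
    return "".join(out)


@dataclass
class HaplotypeNetwork:
    """Median-joining graph over observed haplotypes and inferred medians."""

    graph: nx.Graph
    observed: list[str]
    medians: list[str] = field(default_factory=list)
    epsilon: int = 0

    @property
    def total_length(self) -> int:
        return int(sum(d["weight"] for _, _, d in self.graph.edges(data=True)))

    def spanning_length(self) -> int:
        mst = nx.minimum_spanning_tree(self.graph, algorithm="kruskal")
        return int(sum(d["weight"] for _, _, d in mst.edges(data=True)))


def median_joining_network(
    haplotypes: Sequence[str], epsilon: int = 0, max_rounds: int = 50
) -> HaplotypeNetwork:
    """Build a deterministic median-joining network.

    Repeatedly: (a) form the epsilon-relaxed minimum spanning network over
    the current vertices, (b) for each triplet that is mutually linked
    through the network, add the majority-consensus median when the star
    through it is strictly shorter than spanning the triangle, (c) prune
    inferred vertices of degree <= 2 whose removal does not lengthen the
    network.
    """
    observed = sorted(set(haplotypes))
    if len(observed) < 2:
        g = nx.Graph()
        g.add_nodes_from(observed)
        return HaplotypeNetwork(graph=g, observed=observed, epsilon=epsilon)
    lengths = {len(h) for h in observed}
    if len(lengths) > 1:
        raise ValueError("haplotypes have unequal lengths")
    if epsilon not in (0, 1):
        raise ValueError("epsilon must be 0 or 1")

    vertices = list(observed)
    best = _mst_length(vertices)
    for _ in range(max_rounds):
        net = _spanning_network(vertices, epsilon)
        added = False
        # candidate medians come from triplets with >= 2 links in the
        # current network; each is kept only if it strictly shortens the
        # spanning length (a direct Steiner-point test), which makes the
        # spanning cost monotone non-increasing
        for u, v, w in itertools.combinations(sorted(vertices), 3):
            n_links = (
                net.has_edge(u, v) + net.has_edge(u, w) + net.has_edge(v, w)
            )
            if n_links < 2:
                continue
            m = _median_vector(u, v, w)
            if m in vertices or m in (u, v, w):
                continue
            with_m = _mst_length(vertices + [m])
            if with_m < best:
                vertices.append(m)
                vertices.sort()
                best = with_m
                added = True
        if not added:
            break

    net = _spanning_network(vertices, epsilon)
    # prune inferred vertices of low degree that no longer shorten the
    # network (removal must not increase the spanning length)
    changed = True
    while changed:
        changed = False
        for m in sorted(set(vertices) - set(observed)):
            if net.degree(m) > 2:
                continue
            without = [v for v in vertices if v != m]
            if _mst_length(without) <= best:
                vertices = without
                best = _mst_length(vertices)
                net = _spanning_network(vertices, epsilon)
                changed = True
                break
    return HaplotypeNetwork(
        graph=net,
        observed=observed,
        medians=sorted(set(vertices) - set(observed)),
        epsilon=epsilon,
    )


def count_mutation_steps(
    network: HaplotypeNetwork,
    group_a: Sequence[str],
    group_b: Sequence[str],
) -> tuple[int, float]:
    """(min Hamming distance, min network path weight) between two groups."""
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    min_h = min(hamming(a, b) for a in group_a for b in group_b)
    best = np.inf
    for a in group_a:
        if a not in network.graph:
            continue
        dist = nx.single_source_dijkstra_path_length(network.graph, a, weight="weight")
        for b in group_b:
            if b in dist:
                best = min(best, dist[b])
    return min_h, float(best)
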