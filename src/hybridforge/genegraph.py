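"""Biosynthetic gene graph: construction, trimming, and assembly-line traversal.

Nodes are the genes of a BGC region; a directed edge s -> t means gene t can
follow gene s in the final biosynthesis.  Edges are created by five rules
(communication-domain pairing, domain hand-off, genomic co-linearity,
release-domain attraction, singleton promiscuity), each edge remembering all
rules that fired.  After trimming, assembly lines are enumerated as simple
paths ending at a sink node with at most k genes left out.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import networkx as nx

from .errors import ConfigurationError
from .mining import Gene

DEFAULT_PATH_CAP = 10_000


@dataclass
class GeneGraph:
    """Directed gene graph with rule-provenance edge tags."""

    graph: nx.DiGraph
    genes: dict[str, Gene]
    k: int  # allowed inactive genes

    @property
    def n(self) -> int:
        return self.graph.number_of_nodes()

    def edges_with_rules(self) -> list[tuple[str, str, frozenset[str]]]:
        return [
            (s, t, frozenset(d["rules"])) for s, t, d in self.graph.edges(data=True)
        ]


@dataclass(frozen=True)
class AssemblyLine:
    """An ordered list of gene ids ending at the sink."""

    gene_ids: tuple[str, ...]

    def __len__(self) -> int:
        return len(self.gene_ids)


def _first_active_or_pcp(gene: Gene) -> str | None:
    """First biosynthetically meaningful domain class (skips N-COM)."""
    for d in gene.domains:
        if d.domain_class != "NCOM":
            return d.domain_class
    return None


def _last_core(gene: Gene) -> str | None:
    for d in reversed(gene.domains):
        if d.domain_class != "CCOM":
            return d.domain_class
    return None


def build_graph(genes: Sequence[Gene], k: int | None = None) -> GeneGraph:
    """Apply the five edge rules to an ordered gene list.

    R1: s ends with a C-terminal COM domain, t begins with an N-terminal COM
        domain.
    R2: s ends with a C-domain and t starts with an A-domain, or s ends with
        an A-domain and t starts with a PCP-domain.
    R3: t is downstream of s on the same strand.
    R4: t contains a release (thioesterase/thioreductase) domain — edge from
        every other gene.
    R5: s is a singleton (exactly one active domain) — edge to every other
        gene.

    ``k`` defaults to the number of singleton genes.
    """
    if not genes:
        raise ConfigurationError("at least one gene is required")
    g = nx.DiGraph()
    for gene in genes:
        g.add_node(gene.id)
    index = {gene.id: gene for gene in genes}

    def add_edge(s: str, t: str, rule: str) -> None:
        if s == t:
            return
        if g.has_edge(s, t):
            g[s][t]["rules"].add(rule)
        else:
            g.add_edge(s, t, rules={rule})

    ordered = sorted(genes, key=lambda x: (x.contig, x.start, x.end))
    for s in ordered:
        for t in ordered:
            if s.id == t.id:
                continue
            if s.ends_with_ccom and t.starts_with_ncom:
                add_edge(s.id, t.id, "R1")
            last, first = _last_core(s), _first_active_or_pcp(t)
            if (last == "C" and first == "A") or (last == "A" and first == "PCP"):
                add_edge(s.id, t.id, "R2")
            if (
                s.contig == t.contig
                and s.strand == t.strand
                and (t.start > s.start if s.strand == 1 else t.start < s.start)
            ):
                add_edge(s.id, t.id, "R3")
            if t.contains_release:
                add_edge(s.id, t.id, "R4")
            if s.is_singleton:
                add_edge(s.id, t.id, "R5")

    if k is None:
        k = sum(1 for gene in genes if gene.is_singleton)
    return GeneGraph(graph=g, genes=index, k=k)


def trim_graph(gg: GeneGraph) -> GeneGraph:
    """Remove (i) all outgoing edges of release-domain genes, then (ii)
    COM-mismatch edges into N-COM-starting genes, identifying all candidate
    removals first and keeping them only if removal would orphan the target."""
    g = gg.graph.copy()
    for gid, gene in gg.genes.items():
        if gene.contains_release:
            for succ in list(g.successors(gid)):
                g.remove_edge(gid, succ)
    for tid, tgene in gg.genes.items():
        if not tgene.starts_with_ncom:
            continue
        incoming = list(g.predecessors(tid))
        candidates = [s for s in incoming if not gg.genes[s].ends_with_ccom]
        if candidates and len(candidates) < len(incoming):
            for s in candidates:
                g.remove_edge(s, tid)
        # if every incoming edge is a candidate, all are retained to avoid
        # leaving t with no incoming edges
    return GeneGraph(graph=g, genes=gg.genes, k=gg.k)


def find_sink(gg: GeneGraph) -> str:
    """Node with minimal out-degree; ties prefer release-domain genes, then
    the lowest genomic coordinate."""
    def key(gid: str) -> tuple:
        gene = gg.genes[gid]
        return (
            gg.graph.out_degree(gid),
            0 if gene.contains_release else 1,
            gene.start,
            gid,
        )

    return min(gg.graph.nodes, key=key)


def enumerate_assembly_lines(
    gg: GeneGraph,
    k: int | None = None,
    cap: int = DEFAULT_PATH_CAP,
) -> tuple[list[AssemblyLine], bool]:
    """All simple paths ending at the sink with length >= n - k.

    Returns (lines, truncated).  Enumeration is an exhaustive reverse DFS from
    the sink; output order is deterministic (sorted by gene-id tuple).
    """
    if gg.n == 0:
        raise ConfigurationError("empty gene graph")
    if k is None:
        k = gg.k
    sink = find_sink(gg)
    min_len = max(1, gg.n - k)
    rev = gg.graph.reverse(copy=False)
    lines: list[tuple[str, ...]] = []
    truncated = False

    def dfs(node: str, path: list[str]) -> None:
        nonlocal truncated
        if truncated:
            return
        if len(path) >= min_len:
            lines.append(tuple(reversed(path)))
            if len(lines) >= cap:
                truncated = True
                return
        for pred in sorted(rev.successors(node)):
            if pred not in path:
                path.append(pred)
                dfs(pred, path)
                path.pop()

    dfs(sink, [sink])
    lines.sort()
    return [AssemblyLine(gene_ids=t) for t in lines], truncated


def graph_to_json(gg: GeneGraph, path: str | Path) -> None:
    obj = {
        "k": gg.k,
        "nodes": sorted(gg.graph.nodes),
        "edges": [
            {"source": s, "target": t, "rules": sorted(d["rules"])}
            for s, t, d in sorted(gg.graph.edges(data=True))
        ],
    }
    Path(path).write_text(json.dumps(obj, indent=1))


def graph_to_dot(gg: GeneGraph, path: str | Path) -> None:
    lines = ["digraph genegraph {"]
    for node in sorted(gg.graph.nodes):
        lines.append(f'  "{node}";')
    for s, t, d in sorted(gg.graph.edges(data=True)):
        tags = ",".join(sorted(d["rules"]))
        lines.append(f'  "{s}" -> "{t}" [label="{tags}"];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")


def lines_to_json(lines: Sequence[AssemblyLine], path: str | Path) -> None:
    Path(path).write_text(
        json.dumps([list(l.gene_ids) for l in lines], indent=1)
    )
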