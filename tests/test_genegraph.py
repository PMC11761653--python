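"""Gene-graph rules, trimming, sink selection and line enumeration."""

from itertools import permutations

import pytest

from hybridforge.errors import ConfigurationError
from hybridforge.genegraph import (
    build_graph,
    enumerate_assembly_lines,
    find_sink,
    graph_to_dot,
    graph_to_json,
    lines_to_json,
    trim_graph,
)
from hybridforge.mining import DomainHit, Gene


def _gene(gid, arch, start, strand=1, contig="c"):
    domains = []
    pos = start
    for cls in arch:
        domains.append(
            DomainHit(
                contig=contig, strand=strand, frame=0, domain_class=cls,
                prot_start=0, prot_end=10, start=pos, end=pos + 30,
                score=1.0, evalue=1e-10,
            )
        )
        pos += 40
    return Gene(
        id=gid, contig=contig, strand=strand, start=start,
        end=pos - 10, domains=domains,
    )


def test_rule_r1_com_pairing():
    a = _gene("a", ["A", "PCP", "CCOM"], 0)
    b = _gene("b", ["NCOM", "C", "A", "PCP"], 5000, strand=-1)
    gg = build_graph([a, b])
    rules = dict(((s, t), r) for s, t, r in gg.edges_with_rules())
    assert "R1" in rules[("a", "b")]
    assert ("b", "a") not in rules or "R1" not in rules.get(("b", "a"), set())


def test_rule_r2_domain_handoff():
    # s ends with C, t starts with A
    s = _gene("s", ["A", "PCP", "C"], 0, strand=-1)
    t = _gene("t", ["A", "PCP"], 5000)
    gg = build_graph([s, t])
    rules = dict(((u, v), r) for u, v, r in gg.edges_with_rules())
    assert "R2" in rules[("s", "t")]
    # s ends with A, t starts with PCP
    s2 = _gene("s2", ["C", "A"], 0, strand=-1)
    t2 = _gene("t2", ["PCP", "C"], 5000)
    gg2 = build_graph([s2, t2])
    rules2 = dict(((u, v), r) for u, v, r in gg2.edges_with_rules())
    assert "R2" in rules2[("s2", "t2")]


def test_rule_r2_skips_leading_ncom():
    s = _gene("s", ["C", "A", "PCP", "C"], 0, strand=-1)
    t = _gene("t", ["NCOM", "A", "PCP"], 5000)
    gg = build_graph([s, t])
    rules = dict(((u, v), r) for u, v, r in gg.edges_with_rules())
    assert "R2" in rules[("s", "t")]


def test_rule_r3_colinearity_strand_aware():
    a = _gene("a", ["C", "A", "PCP", "C"], 0)
    b = _gene("b", ["C", "A", "PCP"], 5000)
    c = _gene("c", ["C", "A", "PCP"], 10000, strand=-1)
    gg = build_graph([a, b, c])
    rules = dict(((u, v), r) for u, v, r in gg.edges_with_rules())
    assert "R3" in rules[("a", "b")]
    assert "R3" not in rules.get(("b", "a"), set())
    # opposite strands never get R3
    assert "R3" not in rules.get(("a", "c"), set())
    # on the minus strand downstream means smaller coordinate
    d = _gene("d", ["C", "A", "PCP"], 2000, strand=-1)
    gg2 = build_graph([c, d])
    rules2 = dict(((u, v), r) for u, v, r in gg2.edges_with_rules())
    assert "R3" in rules2[("c", "d")]
    assert "R3" not in rules2.get(("d", "c"), set())


def test_rule_r4_release_attraction():
    # multi-module genes so the singleton rule R5 cannot fire
    arch = ["C", "A", "PCP", "C", "A", "PCP"]
    a = _gene("a", arch, 0, strand=-1)
    b = _gene("b", arch, 5000, strand=-1)
    t = _gene("t", arch + ["TE"], 10000, strand=-1)
    gg = build_graph([a, b, t])
    rules = dict(((u, v), r) for u, v, r in gg.edges_with_rules())
    assert "R4" in rules[("a", "t")]
    assert "R4" in rules[("b", "t")]
    # nothing points away from the release gene by R4
    assert "R4" not in rules.get(("t", "a"), set())
    assert "R4" not in rules.get(("t", "b"), set())


def test_rule_r5_singleton_promiscuity_and_default_k():
    single = _gene("x", ["A", "PCP"], 0, strand=-1)
    other = _gene("y", ["C", "A", "PCP", "C", "A", "PCP"], 5000, strand=-1)
    gg = build_graph([single, other])
    rules = dict(((u, v), r) for u, v, r in gg.edges_with_rules())
    assert "R5" in rules[("x", "y")]
    assert "R5" not in rules.get(("y", "x"), set())
    assert gg.k == 1  # defaults to the singleton count


def test_trim_removes_release_outgoing_edges():
    a = _gene("a", ["A", "PCP"], 0)
    t = _gene("t", ["C", "A", "TE"], 5000)
    gg = trim_graph(build_graph([a, t]))
    assert gg.graph.out_degree("t") == 0
    assert gg.graph.has_edge("a", "t")


def test_trim_com_mismatch_removed_when_alternative_exists():
    ccom = _gene("ccom", ["A", "PCP", "CCOM"], 0)
    plain = _gene("plain", ["A", "PCP"], 5000)
    target = _gene("target", ["NCOM", "C", "A", "PCP"], 10000)
    gg = trim_graph(build_graph([ccom, plain, target]))
    assert gg.graph.has_edge("ccom", "target")
    assert not gg.graph.has_edge("plain", "target")


def test_trim_keeps_mismatches_when_removal_would_orphan():
    p1 = _gene("p1", ["A", "PCP"], 0)
    p2 = _gene("p2", ["C", "A"], 5000)
    target = _gene("target", ["NCOM", "C", "A", "PCP"], 10000)
    gg = trim_graph(build_graph([p1, p2, target]))
    # no C-COM predecessor exists: all incoming edges are retained
    assert gg.graph.in_degree("target") >= 2


def test_find_sink_prefers_release_on_ties():
    a = _gene("a", ["A", "PCP"], 0)
    t = _gene("t", ["C", "A", "TE"], 5000)
    gg = trim_graph(build_graph([a, t]))
    assert find_sink(gg) == "t"


def _bruteforce_lines(gg, k):
    """All simple paths over the trimmed graph ending at the sink with
    length >= n - k, by exhaustive permutation check."""
    sink = find_sink(gg)
    nodes = list(gg.graph.nodes)
    n = len(nodes)
    min_len = max(1, n - k)
    found = set()
    for size in range(min_len, n + 1):
        for perm in permutations(nodes, size):
            if perm[-1] != sink:
                continue
            if all(
                gg.graph.has_edge(u, v) for u, v in zip(perm, perm[1:])
            ):
                found.add(perm)
    return sorted(found)


@pytest.mark.parametrize("k", [0, 1, 2])
def test_enumeration_matches_bruteforce(k):
    genes = [
        _gene("g1", ["A", "PCP", "CCOM"], 0),
        _gene("g2", ["NCOM", "C", "A", "PCP", "CCOM"], 5000),
        _gene("g3", ["NCOM", "C", "A", "PCP"], 10000),
        _gene("g4", ["C", "A", "PCP", "TE"], 15000),
        _gene("g5", ["A", "PCP"], 20000, strand=-1),
    ]
    gg = trim_graph(build_graph(genes))
    lines, truncated = enumerate_assembly_lines(gg, k=k)
    assert not truncated
    assert [l.gene_ids for l in lines] == _bruteforce_lines(gg, k)


def test_enumeration_cap_truncates():
    genes = [
        _gene(f"g{i}", ["C", "A", "PCP", "C"], i * 5000, strand=-1)
        for i in range(6)
    ] + [_gene("te", ["C", "A", "TE"], 40000, strand=-1)]
    gg = trim_graph(build_graph(genes))
    lines, truncated = enumerate_assembly_lines(gg, k=len(genes), cap=5)
    assert truncated
    assert len(lines) == 5


def test_empty_graph_rejected():
    with pytest.raises(ConfigurationError):
        build_graph([])


def test_exports(tmp_path):
    genes = [
        _gene("a", ["A", "PCP", "CCOM"], 0),
        _gene("b", ["NCOM", "C", "A", "TE"], 5000),
    ]
    gg = trim_graph(build_graph(genes))
    lines, _ = enumerate_assembly_lines(gg)
    graph_to_json(gg, tmp_path / "g.json")
    graph_to_dot(gg, tmp_path / "g.dot")
    lines_to_json(lines, tmp_path / "l.json")
    assert (tmp_path / "g.json").stat().st_size > 0
    assert "digraph" in (tmp_path / "g.dot").read_text()
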