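"""Six-frame search, region merging, gene calling and domain annotation."""

import json

import numpy as np
import pytest
from Bio.Seq import Seq

from hybridforge import synth
from hybridforge.errors import ConfigurationError
from hybridforge.mining import (
    BGCRegion,
    DomainHit,
    annotate_adomains,
    annotate_atdomains,
    call_genes,
    find_domains,
    load_hmms,
    merge_regions,
    regions_to_gff3,
    regions_to_json,
    six_frame_translate,
)


def _hit(contig="c", strand=1, frame=0, cls="A", start=0, end=30, **kw):
    return DomainHit(
        contig=contig, strand=strand, frame=frame, domain_class=cls,
        prot_start=start // 3, prot_end=end // 3, start=start, end=end,
        score=1.0, evalue=1e-10, **kw,
    )


def test_six_frame_translation_and_coordinates():
    rng = np.random.default_rng(8)
    seq = "".join(rng.choice(list("ACGT"), size=301))
    frames = six_frame_translate("c1", seq)
    assert len(frames) == 6
    assert {(f.strand, f.frame) for f in frames} == {
        (s, f) for s in (1, -1) for f in range(3)
    }
    for fr in frames:
        # oracle: re-translate the genomic interval and compare
        p0, p1 = 3, min(20, len(fr.protein))
        g0, g1 = fr.to_genomic(p0, p1)
        sub = seq[g0:g1]
        if fr.strand == -1:
            sub = str(Seq(sub).reverse_complement())
        assert str(Seq(sub).translate()) == fr.protein[p0:p1]


def test_six_frame_rejects_bad_alphabet():
    with pytest.raises(ConfigurationError):
        six_frame_translate("c", "ACGU")
    with pytest.raises(ConfigurationError):
        six_frame_translate("c", "")


def test_find_domains_recovers_planted_layout(toy_bundle):
    genome = toy_bundle["genome"]
    frames = six_frame_translate(genome.contig_id, genome.sequence)
    hits = find_domains(frames, str(toy_bundle["dir"] / "domains.hmm"))
    truth = [h for g in genome.genes for h in g.domains]
    # every planted domain is found once with matching class/strand and
    # overlapping genomic coordinates
    for t in truth:
        matching = [
            h
            for h in hits
            if h.domain_class == t.domain_class
            and h.strand == t.strand
            and max(h.start, t.start) < min(h.end, t.end)
        ]
        assert matching, f"planted {t.domain_class} at {t.start} not found"
    assert len(hits) == len(truth)


def test_find_domains_threshold_and_empty(toy_bundle):
    genome = toy_bundle["genome"]
    frames = six_frame_translate(genome.contig_id, genome.sequence)
    hmms = load_hmms(str(toy_bundle["dir"] / "domains.hmm"))
    assert find_domains(frames, hmms, evalue=0.0) == []
    assert find_domains([], hmms) == []


def test_merge_regions_matches_naive_sweep():
    rng = np.random.default_rng(13)
    flank = 50
    L = 5000
    hits = []
    for _ in range(30):
        s = int(rng.integers(0, L - 60))
        cls = str(rng.choice(["A", "C", "TE"]))
        hits.append(_hit(cls=cls, start=s, end=s + 60))
    regions = merge_regions(hits, {"c": L}, flank=flank)
    # oracle: naive interval sweep
    intervals = sorted(
        ((max(0, h.start - flank), min(L, h.end + flank), h) for h in hits),
        key=lambda t: (t[0], t[1]),
    )
    merged = []
    for s, e, h in intervals:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
            merged[-1][2].append(h)
        else:
            merged.append([s, e, [h]])
    expected = [
        (s, e)
        for s, e, mem in merged
        if any(m.domain_class == "A" for m in mem)
    ]
    assert [(r.start, r.end) for r in regions] == expected
    with pytest.raises(ConfigurationError):
        merge_regions(hits, {"c": L}, flank=-1)


def test_regions_without_active_domain_dropped():
    hits = [_hit(cls="C", start=100, end=160)]
    assert merge_regions(hits, {"c": 1000}) == []


def test_call_genes_runs_and_strand_order():
    # two same-frame runs separated by >= 2 kb, plus one reverse-strand gene
    hits = [
        _hit(cls="A", start=0, end=30),
        _hit(cls="PCP", start=60, end=90),
        _hit(cls="C", start=3000, end=3030),
        _hit(cls="A", start=3060, end=3090),
        _hit(cls="TE", strand=-1, frame=1, start=601, end=631),
        _hit(cls="A", strand=-1, frame=1, start=502, end=532),
    ]
    region = BGCRegion(contig="c", start=0, end=4000, hits=hits)
    genes = call_genes(region)
    archs = {g.id: (g.strand, g.architecture) for g in genes}
    assert len(genes) == 3
    # reverse-strand translation order is reversed genomic order
    rev = [g for g in genes if g.strand == -1][0]
    assert rev.architecture == ["TE", "A"]
    fwd = sorted(
        (g for g in genes if g.strand == 1), key=lambda g: g.start
    )
    assert fwd[0].architecture == ["A", "PCP"]
    assert fwd[1].architecture == ["C", "A"]
    assert sorted(archs) == [f"c:g{i}" for i in (1, 2, 3)]


def test_toy_genome_gene_calling(toy_bundle):
    genome = toy_bundle["genome"]
    frames = six_frame_translate(genome.contig_id, genome.sequence)
    hits = find_domains(frames, str(toy_bundle["dir"] / "domains.hmm"))
    regions = merge_regions(hits, {genome.contig_id: len(genome.sequence)})
    assert len(regions) == 1
    got = [g.architecture for g in regions[0].genes]
    expected = [g.architecture for g in genome.genes]
    assert got == expected


def test_annotate_adomains_top1(toy_bundle, small_model, ref):
    genome = toy_bundle["genome"]
    frames = six_frame_translate(genome.contig_id, genome.sequence)
    hits = find_domains(frames, str(toy_bundle["dir"] / "domains.hmm"))
    regions = merge_regions(hits, {genome.contig_id: len(genome.sequence)})
    ann = annotate_adomains(regions[0], small_model, ref)
    assert set(ann) == set(genome.a_substrates)
    for key, preds in ann.items():
        assert len(preds) == 3
        assert preds[0][0] == genome.a_substrates[key]
        scores = [s for _, s in preds]
        assert scores == sorted(scores, reverse=True)


def test_annotate_atdomains(toy_bundle, at_model):
    genome = toy_bundle["genome"]
    frames = six_frame_translate(genome.contig_id, genome.sequence)
    hits = find_domains(frames, str(toy_bundle["dir"] / "domains.hmm"))
    regions = merge_regions(hits, {genome.contig_id: len(genome.sequence)})
    ann = annotate_atdomains(regions[0], at_model)
    assert set(ann) == set(genome.at_monomers)
    for key, preds in ann.items():
        assert preds[0][0] == genome.at_monomers[key]


def test_at_signature_and_fallback(at_model):
    for monomer in ("malonyl", "methylmalonyl"):
        seq = synth.at_sequence_for(monomer, at_model)
        sig = at_model.signature(seq)
        assert sig == at_model.monomer_signatures[monomer]
        name, prob, fallback = at_model.predict(seq)
        assert name == monomer
        assert prob > 0.5
        assert not fallback
    # unalignable garbage falls back to malonyl with the flag set
    name, prob, fallback = at_model.predict("W" * 5)
    assert (name, prob, fallback) == ("malonyl", 0.0, True)


def test_region_exports(tmp_path, toy_bundle):
    genome = toy_bundle["genome"]
    frames = six_frame_translate(genome.contig_id, genome.sequence)
    hits = find_domains(frames, str(toy_bundle["dir"] / "domains.hmm"))
    regions = merge_regions(hits, {genome.contig_id: len(genome.sequence)})
    gff = tmp_path / "r.gff3"
    js = tmp_path / "r.json"
    regions_to_gff3(regions, gff)
    regions_to_json(regions, js)
    text = gff.read_text()
    assert text.startswith("##gff-version 3")
    obj = json.loads(js.read_text())
    assert len(obj) == 1
    assert len(obj[0]["genes"]) == len(genome.genes)
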