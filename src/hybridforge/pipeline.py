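"""End-to-end genome -> products pipeline.

Wires together mining (HMM domain search and region calling), the A/AT
specificity models, gene-graph construction and trimming, assembly-line
enumeration, monomer assignment, core assembly, module tailoring and
combinatorial post-assembly modification.  All outputs are deterministic
given the inputs and the seed, and every result file carries a version stamp
with content hashes of the inputs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

from . import __version__ as _pkg_version
from .adomain import ReferenceAlignment, read_fasta
from .assembly import (
    DEFAULT_PRODUCT_CAP,
    MatureProduct,
    Modification,
    ModuleContext,
    Monomer,
    apply_module_tailoring,
    apply_postassembly,
    assemble_core,
    gate_preassembly,
    load_modifications,
    products_to_sdf,
    products_to_tsv,
    top_assignments,
)
from .errors import AssemblyError, ConfigurationError
from .genegraph import (
    DEFAULT_PATH_CAP,
    AssemblyLine,
    build_graph,
    enumerate_assembly_lines,
    lines_to_json,
    trim_graph,
)
from .mining import (
    DEFAULT_EVALUE,
    DEFAULT_FLANK,
    AtSpecificityModel,
    BGCRegion,
    annotate_adomains,
    annotate_atdomains,
    find_domains,
    load_hmms,
    merge_regions,
    regions_to_gff3,
    regions_to_json,
    six_frame_translate,
)
from .model import TrainedMaspr, load_model

#: domain classes that tailor the monomer of their own module
MODULE_TAILORING = {"MT", "F", "CY", "OX", "RED", "KR", "DH", "ER"}


@dataclass(frozen=True)
class RunConfig:
    """Configuration of one pipeline run (all paths are inputs)."""

    genome: str
    hmms: str
    model: str
    modifications: str | None = None
    reference: str | None = None
    evalue: float = DEFAULT_EVALUE
    flank: int = DEFAULT_FLANK
    topk: int = 3
    top_s: int = 25
    path_cap: int = DEFAULT_PATH_CAP
    product_cap: int = DEFAULT_PRODUCT_CAP
    backend: str = "onehot"
    seed: int = 0


@dataclass
class RegionResult:
    region: BGCRegion
    a_annotations: dict[str, list[tuple[str, float]]]
    at_annotations: dict[str, list[tuple[str, float]]]
    lines: list[AssemblyLine]
    lines_truncated: bool
    products: list[MatureProduct]
    products_truncated: bool
    graph_json: dict


@dataclass
class PipelineResult:
    config: RunConfig
    regions: list[RegionResult]
    stamp: dict

    @property
    def products(self) -> list[MatureProduct]:
        return [p for r in self.regions for p in r.products]


def _sha256_file(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def version_stamp(config: RunConfig) -> dict:
    """Provenance stamp: package version, config, and input content hashes."""
    cfg = dict(sorted(config.__dict__.items()))
    stamp = {
        "package": "hybridforge",
        "version": _pkg_version,
        "config": cfg,
        "config_hash": hashlib.sha256(
            json.dumps(cfg, sort_keys=True).encode()
        ).hexdigest(),
        "input_hashes": {},
    }
    for key in ("genome", "hmms", "model", "modifications", "reference"):
        value = getattr(config, key)
        if value and Path(value).exists():
            stamp["input_hashes"][key] = _sha256_file(value)
    return stamp


def _module_contexts(
    ordered_domains: Sequence[tuple[str, str]],
) -> list[ModuleContext]:
    """Attach tailoring domains to modules.

    ``ordered_domains`` is the (key, class) list of all domains along the
    assembly line in translation order.  A module is an active domain plus
    the tailoring-class domains that follow it up to the next active domain;
    tailoring domains preceding the first active domain join the first
    module.
    """
    active_positions = [
        i for i, (_k, cls) in enumerate(ordered_domains) if cls in ("A", "AT")
    ]
    contexts: list[ModuleContext] = []
    for mi, pos in enumerate(active_positions):
        end = (
            active_positions[mi + 1]
            if mi + 1 < len(active_positions)
            else len(ordered_domains)
        )
        classes = [
            cls
            for _k, cls in ordered_domains[pos + 1 : end]
            if cls in MODULE_TAILORING
        ]
        if mi == 0:
            classes = [
                cls for _k, cls in ordered_domains[:pos] if cls in MODULE_TAILORING
            ] + classes
        contexts.append(
            ModuleContext(
                monomer_index=mi,
                domain_classes=tuple(classes),
                n_terminal=(mi == 0),
            )
        )
    return contexts


def _line_products(
    region: BGCRegion,
    line: AssemblyLine,
    line_id: str,
    a_ann: dict[str, list[tuple[str, float]]],
    at_ann: dict[str, list[tuple[str, float]]],
    monomers: dict[str, Monomer],
    mods: Sequence[Modification],
    bgc_classes: set[str],
    top_s: int,
    product_cap: int,
) -> tuple[list[MatureProduct], bool]:
    gene_index = {g.id: g for g in region.genes}
    ordered: list[tuple[str, str]] = []
    for gid in line.gene_ids:
        gene = gene_index[gid]
        for j, hit in enumerate(gene.domains):
            ordered.append((f"{gid}:{hit.domain_class}{j}", hit.domain_class))

    # ranked monomer predictions per active domain, gated by the library;
    # domains without usable predictions contribute no monomer.
    predictions: list[list[tuple[str, float]]] = []
    active_keys: list[str] = []
    for key, cls in ordered:
        if cls == "A":
            preds = a_ann.get(key, [])
        elif cls == "AT":
            preds = at_ann.get(key, [])
        else:
            continue
        preds = [(n, s) for n, s in preds if n in monomers]
        if preds:
            predictions.append(preds)
            active_keys.append(key)
    if not predictions:
        return [], False

    # drop unusable active domains from the module layout too
    usable = set(active_keys)
    ordered = [
        (k, c) for k, c in ordered if c not in ("A", "AT") or k in usable
    ]
    contexts = _module_contexts(ordered)
    cyclize_variants = [False]
    if any(
        gene_index[gid].architecture.count("TE") for gid in line.gene_ids
    ):
        cyclize_variants.append(True)

    products: dict[str, MatureProduct] = {}
    truncated = False
    for ai, assignment in enumerate(top_assignments(predictions, s=top_s)):
        units = [monomers[name] for name in assignment.monomers]
        for cyclize in cyclize_variants:
            if cyclize and len(units) < 2:
                continue
            try:
                core = assemble_core(units, cyclize=cyclize)
                core = apply_module_tailoring(core, contexts)
            except AssemblyError:
                continue
            prods, trunc = apply_postassembly(
                core, mods, bgc_classes,
                cap=product_cap, line_id=line_id, assignment_id=f"a{ai + 1}",
            )
            truncated = truncated or trunc
            for p in prods:
                products.setdefault(p.smiles, p)
            if len(products) >= product_cap:
                truncated = True
                break
        if truncated and len(products) >= product_cap:
            break
    out = sorted(products.values(), key=lambda p: (len(p.modifications), p.smiles))
    return out[:product_cap], truncated


def run_pipeline(
    config: RunConfig,
    model: TrainedMaspr | None = None,
    at_model: AtSpecificityModel | None = None,
    ref: ReferenceAlignment | None = None,
    modifications: Sequence[Modification] | None = None,
) -> PipelineResult:
    """Mine a genome and predict its natural products.

    Heavy inputs (trained model, AT classifier, reference alignment,
    modification library) can be passed as objects to avoid re-loading; paths
    in ``config`` are used otherwise.
    """
    contigs = read_fasta(config.genome)
    if not contigs:
        raise ConfigurationError(f"no contigs in {config.genome}")
    if model is None:
        model = load_model(config.model)
    if ref is None:
        ref = (
            ReferenceAlignment.from_json(config.reference)
            if config.reference
            else ReferenceAlignment.default()
        )
    if modifications is None:
        modifications = (
            load_modifications(config.modifications) if config.modifications else []
        )
    hmms = load_hmms(config.hmms)

    frames = []
    lengths = {}
    for cid, seq in contigs:
        frames.extend(six_frame_translate(cid, seq))
        lengths[cid] = len(seq)
    hits = find_domains(frames, hmms, evalue=config.evalue)
    regions = merge_regions(hits, lengths, flank=config.flank)

    results: list[RegionResult] = []
    for region in regions:
        a_ann = annotate_adomains(
            region, model, ref, backend=config.backend, k=config.topk
        )
        at_ann = (
            annotate_atdomains(region, at_model) if at_model is not None else {}
        )
        bgc_classes = {h.domain_class for h in region.hits}
        monomers = {
            m.name: m for m in gate_preassembly(bgc_classes)
        }
        gg = trim_graph(build_graph(region.genes))
        lines, lines_trunc = enumerate_assembly_lines(gg, cap=config.path_cap)
        products: dict[str, MatureProduct] = {}
        prod_trunc = False
        for li, line in enumerate(lines):
            prods, trunc = _line_products(
                region, line, f"l{li + 1}", a_ann, at_ann, monomers,
                modifications, bgc_classes, config.top_s, config.product_cap,
            )
            prod_trunc = prod_trunc or trunc
            for p in prods:
                products.setdefault(p.smiles, p)
        graph_json = {
            "k": gg.k,
            "nodes": sorted(gg.graph.nodes),
            "edges": [
                {"source": s, "target": t, "rules": sorted(r)}
                for s, t, r in sorted(gg.edges_with_rules())
            ],
        }
        results.append(
            RegionResult(
                region=region,
                a_annotations=a_ann,
                at_annotations=at_ann,
                lines=lines,
                lines_truncated=lines_trunc,
                products=sorted(
                    products.values(),
                    key=lambda p: (len(p.modifications), p.smiles),
                )[: config.product_cap],
                products_truncated=prod_trunc,
                graph_json=graph_json,
            )
        )
    return PipelineResult(
        config=config, regions=results, stamp=version_stamp(config)
    )


def write_outputs(result: PipelineResult, outdir: str | Path) -> list[Path]:
    """Write all result files into ``outdir``; returns the written paths."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    regions = [r.region for r in result.regions]
    written: list[Path] = []

    def _w(path: Path) -> Path:
        written.append(path)
        return path

    regions_to_gff3(regions, _w(out / "regions.gff3"))
    regions_to_json(regions, _w(out / "regions.json"))
    annotations = []
    for i, rr in enumerate(result.regions):
        (out / f"graph_r{i + 1}.json").write_text(
            json.dumps(rr.graph_json, indent=1)
        )
        written.append(out / f"graph_r{i + 1}.json")
        lines_to_json(rr.lines, _w(out / f"lines_r{i + 1}.json"))
        for key in sorted(rr.a_annotations):
            for name, score in rr.a_annotations[key]:
                annotations.append((f"r{i + 1}", key, "A", name, f"{score:.6f}"))
        for key in sorted(rr.at_annotations):
            for name, score in rr.at_annotations[key]:
                annotations.append((f"r{i + 1}", key, "AT", name, f"{score:.6f}"))
    ann_lines = ["region\tdomain\tclass\tmonomer\tscore"]
    ann_lines += ["\t".join(row) for row in annotations]
    _w(out / "annotations.tsv").write_text("\n".join(ann_lines) + "\n")
    products = result.products
    products_to_tsv(products, _w(out / "products.tsv"))
    products_to_sdf(products, _w(out / "products.sdf"))
    summary = {
        "stamp": result.stamp,
        "n_regions": len(result.regions),
        "n_genes": sum(len(r.region.genes) for r in result.regions),
        "n_hits": sum(len(r.region.hits) for r in result.regions),
        "n_lines": sum(len(r.lines) for r in result.regions),
        "n_products": len(products),
        "lines_truncated": any(r.lines_truncated for r in result.regions),
        "products_truncated": any(r.products_truncated for r in result.regions),
    }
    _w(out / "summary.json").write_text(json.dumps(summary, indent=1))
    return written
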