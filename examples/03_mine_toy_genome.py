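"""Mine a toy hybrid NRPS-PKS genome end to end.

Builds every input from scratch (planted dataset, trained model, AT
classifier, profile HMMs, toy genome with known truth), runs the pipeline and
compares the annotations against the planted ground truth. Takes a few
minutes on one CPU.
"""

from pathlib import Path
from tempfile import TemporaryDirectory

from hybridforge import synth
from hybridforge.adomain import ReferenceAlignment
from hybridforge.model import TrainConfig, save_model, train
from hybridforge.pipeline import RunConfig, run_pipeline, write_outputs

SEED = 0

ref = ReferenceAlignment.default()
dataset = synth.make_adomain_dataset(
    synth.PlantedSpec(n_substrates=8, sequences_per_substrate=40, seed=SEED),
    ref,
)
model = train(
    dataset.featurized(ref), TrainConfig(epochs=80, seed=SEED),
    library=dataset.library,
)
at_model = synth.make_at_model(seed=SEED)

genome = synth.make_toy_genome(
    synth.acceptance_bgc_spec(seed=SEED),
    code_map=dataset.code_map,
    ref=ref,
    at_model=at_model,
)
print("planted cluster:")
for gene in genome.genes:
    print(f"  {gene.id} [{'+' if gene.strand == 1 else '-'}] "
          f"{'-'.join(gene.architecture)}")

with TemporaryDirectory() as tmp:
    tdir = Path(tmp)
    genome.write_fasta(tdir / "genome.fasta")
    synth.write_hmms(
        synth.build_fixture_hmms(genome.classes, ref=ref, seed=SEED),
        tdir / "domains.hmm",
    )
    synth.write_fixture_modifications(tdir / "modifications.tsv")
    save_model(model, tdir / "model.npz")

    cfg = RunConfig(
        genome=str(tdir / "genome.fasta"),
        hmms=str(tdir / "domains.hmm"),
        model=str(tdir / "model.npz"),
        modifications=str(tdir / "modifications.tsv"),
        seed=SEED,
    )
    result = run_pipeline(cfg, model=model, at_model=at_model, ref=ref)

region = result.regions[0]
print(f"\nmined 1 region with {len(region.region.genes)} genes, "
      f"{len(region.lines)} assembly lines, {len(region.products)} products")

print("\nA-domain annotations (predicted vs planted):")
for key, preds in sorted(region.a_annotations.items()):
    truth = genome.a_substrates[key]
    name, score = preds[0]
    flag = "ok" if name == truth else f"MISMATCH (truth {truth})"
    print(f"  {key}: {name} ({score:.3f}) {flag}")

print("\nAT-domain annotations:")
for key, preds in sorted(region.at_annotations.items()):
    print(f"  {key}: {preds[0][0]} ({preds[0][1]:.3f}) "
          f"truth {genome.at_monomers[key]}")

print("\nfirst products:")
for p in region.products[:5]:
    mods = ", ".join(m for m, _ in p.modifications) or "none"
    print(f"  {p.smiles}   [mods: {mods}]")

outdir = Path("mining_demo_out")
write_outputs(result, outdir)
print(f"\nall outputs written to {outdir}/")
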