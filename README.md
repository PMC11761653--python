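# hybridforge

Substrate-specificity prediction for NRPS adenylation domains and end-to-end
genome mining of nonribosomal peptide / polyketide (NRP-PK) hybrid natural
products.

The package has two faces:

- **`maspr`** — a specificity predictor that maps an adenylation (A-) domain's
  binding-pocket residues to a 296-entry chemical fingerprint of its substrate,
  then retrieves the nearest substrate in a learned latent space. Because the
  retrieval database is built from substrate *structures* (not training
  labels), the model can rank substrates it never saw during training
  (zero-shot).
- **`seq2hybrid`** — a mining engine that takes a genome FASTA, finds
  biosynthetic gene cluster (BGC) regions with profile HMMs over a six-frame
  translation, reconstructs candidate assembly lines from a rule-based gene
  graph, assigns monomers with the specificity model, assembles core
  molecules with RDKit chemistry, applies module tailoring (ketoreduction,
  methylation, heterocyclization, ...) and enumerates combinatorial
  post-assembly modifications.

Everything runs on one CPU with no network access. Synthetic fixture
generators (`hybridforge.synth`) produce planted-signal datasets and toy
genomes with coordinate-level ground truth, so the full pipeline is testable
offline.

## Quick start (CLI)

```bash
# generate a self-contained demo: planted A-domain dataset + toy genome
seq2hybrid fixtures --outdir demo --seed 0

# train the specificity model
maspr train --data demo/adomains.tsv --library demo/substrates.tsv \
            --out demo/model.npz --epochs 80 --seed 0

# predict substrates for A-domain protein sequences
maspr predict --model demo/model.npz --fasta queries.fasta --out preds.tsv

# mine a genome end to end
seq2hybrid run --genome demo/genome.fasta --hmms demo/domains.hmm \
               --model demo/model.npz --modifications demo/modifications.tsv \
               --outdir demo/out
```

`seq2hybrid run` writes `regions.gff3/json`, per-region gene graphs and
assembly lines, `annotations.tsv`, `products.tsv`/`products.sdf` and a
`summary.json` with a provenance stamp (package version, config hash, input
content hashes).

## Quick start (library)

```python
from hybridforge import synth
from hybridforge.adomain import ReferenceAlignment
from hybridforge.model import TrainConfig, train, predict_topk

ref = ReferenceAlignment.default()
ds = synth.make_adomain_dataset(synth.PlantedSpec(seed=0), ref)
model = train(ds.featurized(ref), TrainConfig(epochs=80, seed=0),
              library=ds.library)
record = ds.featurized(ref)[0][0]
print(predict_topk(record, model, k=3))
```

See `examples/` for narrative scripts covering training and evaluation
protocols, zero-shot retrieval, and a full mining run.

## Layout

- `src/hybridforge/chem.py` — 296-entry fingerprints (167 MACCS + 128 Morgan
  bits + mean partial charge), Tanimoto similarity, substrate library.
- `src/hybridforge/adomain.py` — alignment to a reference A-domain scaffold,
  Stachelhaus code (10 aa) and 8Å signature (34 aa) extraction, featurization
  backends (one-hot; pluggable protein-language-model interface).
- `src/hybridforge/nn.py`, `model.py` — numpy MLP stack with hand-written
  backprop/AdamW; fingerprint predictor, stop-gradient classifier head,
  embedding database, training loop, top-k retrieval.
- `src/hybridforge/evaluation.py` — LOSO / promiscuous / grouped / random
  splits, Hamming-distance bucket stratification, top-k accuracy.
- `src/hybridforge/mining.py` — six-frame translation, pyhmmer domain search,
  region merging, gene calling, A/AT-domain annotation.
- `src/hybridforge/genegraph.py` — gene-graph rules R1-R5, trimming, assembly
  line enumeration.
- `src/hybridforge/assembly.py` — monomer library, top-s assignment DP, core
  assembly, module tailoring, SMARTS post-assembly modifications.
- `src/hybridforge/pipeline.py` — one-call `run_pipeline` plus output writers.
- `src/hybridforge/synth.py` — synthetic fixture generators.

Methods details and design rationale: `docs/methods.md`.

## Tests and acceptance

```bash
pytest                                     # full suite
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

`scripts/acceptance.py` regenerates all fixtures from the given seed, trains
the models from scratch and reports the main quantities (planted-signal
top-1/top-5, zero-shot LOSO top-5, promiscuous-protocol top-1, mined
region/line/product counts, product Tanimoto statistics) as JSON.
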