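# Methods

This document describes what the package computes and why, stage by stage.

## 1. Substrate fingerprints

Substrates (amino acids, hydroxy acids, ketide extender units) are encoded as
a fixed 296-entry vector:

- entries 0-166: the 167 MACCS structural keys (RDKit),
- entries 167-294: a 128-bit Morgan fingerprint, radius 2,
- entry 295: the mean Gasteiger partial charge over heavy atoms.

SMILES are canonicalized with stereochemistry erased before fingerprinting,
so enantiomers share a fingerprint (A-domain specificity data rarely resolves
stereochemistry consistently). Tanimoto similarity used in reporting is the
explicit bit-set Jaccard index on 1024-bit radius-3 Morgan fingerprints, which
is independent of the model's feature space.

## 2. Binding-pocket codes

A query A-domain is globally aligned (Biopython PairwiseAligner, BLOSUM62,
gap open -10, extend -0.5) to a reference scaffold of length 520. From the
alignment we read off:

- the **Stachelhaus code**: 10 binding-pocket residues,
- the **8Å signature**: 34 residues (a superset of the 10), used for
  train/test distance stratification.

Alignments are rejected when the query is shorter than 100 residues or the
global identity — matches divided by the full alignment length, gap columns
included — is below 30%. Counting gap columns in the denominator matters: a
gappy alignment of an unrelated sequence can otherwise reach 30% identity on
its few matched columns.

The shipped reference scaffold is **synthetic** (generated, labelled as such
in `data/reference_adomain_synthetic.json`); a real reference can be supplied
through the same JSON schema (`ReferenceAlignment.from_json`).

Positions that align to a gap produce `-` in the code and an all-zero feature
row, so downstream layers see an explicit "missing residue" signal.

## 3. Featurization backends

Each of the 10 code residues becomes a feature row. Backends:

- `onehot` (default, offline): 20-dim one-hot per residue.
- `plm`: per-residue embeddings from a protein language model. The interface
  (`EmbeddingBackend`) is pluggable; the ESM backend raises a clear
  `BackendUnavailableError` when torch/fair-esm are not installed, pointing to
  one-hot mode. A deterministic mock backend exists for tests.

Features are cached on disk keyed by sequence hash and backend id.

## 4. Specificity model

Two numpy networks with hand-written backprop (`nn.py`: Linear, ELU, ReLU,
LayerNorm, Flatten, AdamW, cosine and cross-entropy losses):

- **Fingerprint predictor**: per-residue trunk (Linear 480 -> ELU -> LayerNorm
  -> Linear 240 -> ELU -> LayerNorm), flatten, then a 240-240 trunk to a
  296-dim output. Trained with batch-mean cosine distance to the substrate
  fingerprint (AdamW, lr 1e-4 decayed x0.8 every 10 epochs, weight decay
  0.01, batch 128, 80 epochs).
- **Classifier head** (latent mode): Linear(296, 296) initialized to the
  identity, ReLU, Linear to the label logits. Per predictor step the head
  takes **two** cross-entropy updates: one on the predicted fingerprint
  (gradient stopped at the predictor boundary) and one on the true target
  fingerprint. The counter invariant `head_updates == 2 * predictor_steps`
  is exposed on the trained model.

The **latent embedding** of a fingerprint is the head's post-ReLU first-layer
activation (296-dim, nonnegative). The **embedding database** maps each
library substrate's *structure* fingerprint to its latent vector; prediction
is nearest-neighbor retrieval by cosine distance. Because database entries
come from structures rather than training labels, substrates absent from
training remain retrievable (zero-shot).

Ablation modes: `fingerprint` (retrieve in raw fingerprint space, no head)
and `direct` (softmax classification over training labels, no retrieval).

## 5. Evaluation protocols

- **Random splits**: n seeded shuffles at a fixed test fraction.
- **LOSO** (leave-one-substrate-out): all pairs with the held-out substrate go
  to test; the embedding database still contains the substrate (that is the
  zero-shot claim being tested).
- **Promiscuous split**: for each sequence observed with >1 distinct
  substrate, exactly one (seeded-random) pair goes to train and the remaining
  n-1 to test.
- **Bucket stratification**: test items are grouped by minimum Hamming
  distance of their 34-residue signature to the train set (B0+, B3+, ...,
  nested), separating memorization from generalization.

Top-k accuracy accepts sets of truth labels (any observed substrate counts).

## 6. Genome mining

1. **Six-frame translation** with exact per-frame coordinate maps back to
   genomic space (verified by re-translation oracles in tests).
2. **Domain search**: pyhmmer hmmsearch of profile HMMs against the frame
   translations; default e-value 1e-5.
3. **Region merging**: hits padded by a 10 kb flank and merged by interval
   sweep; regions without an A or AT domain are dropped.
4. **Gene calling** (fixture-scale stand-in for a real gene caller): maximal
   runs of same-contig/strand/frame hits less than 2 kb apart; domains are
   ordered in translation order (reversed genomic order on the minus strand).
5. **A-domain annotation**: extract codes, featurize, top-k retrieval against
   the trained model. **AT-domain annotation**: hmmalign to the AT profile,
   read 24 match-state signature columns, random-forest classification; when
   more than half of the signature columns are gaps the domain falls back to
   malonyl with probability 0 and a fallback flag.

## 7. Gene graph and assembly lines

Directed graph over the region's genes; an edge s -> t means t can follow s:

- **R1**: s ends with a C-terminal COM domain and t starts with an N-terminal
  COM domain (communication pairing).
- **R2**: domain hand-off — s ends with C and t starts with A, or s ends with
  A and t starts with PCP.
- **R3**: t is downstream of s on the same strand.
- **R4**: t contains a release domain (TE/TR) — edge from every other gene.
- **R5**: s is a singleton (exactly one active domain) — edge to every gene.

Trimming removes outgoing edges of release genes and COM-mismatched incoming
edges when a COM-matched alternative exists (with protection against
orphaning a node). The sink is the node with minimal out-degree, ties broken
toward release-containing then start-position order. Assembly lines are all
simple paths ending at the sink with at least n-k genes, k defaulting to the
number of singleton genes; enumeration is capped (default 10000) with an
explicit truncation flag.

## 8. Monomers, core assembly, tailoring

Ranked monomer predictions per active domain feed a top-s assignment search
(exact beam DP, verified against exhaustive enumeration). For each
assignment:

- **Core assembly**: monomers are condensed head-to-tail, removing the
  carboxyl OH; amino heads give amides, hydroxy heads esters, ketide heads
  C-C bonds with a retained beta-keto group. A release domain also yields the
  macrocyclized variant.
- **Module tailoring**: KR reduces the module's beta-keto to a hydroxyl,
  KR+DH to an alkene, KR+DH+ER to a methylene — only at true ketone
  junctions (a carbon head atom); amide/ester carbonyls are never reduced.
  MT methylates the junction N (NRPS) or alpha-carbon (PKS); F formylates the
  N-terminal amine; CY closes thiazoline/oxazoline rings from Cys/Ser/Thr
  side chains.
- **Pre-assembly gating**: conditional monomers (e.g. beta-hydroxytyrosine)
  are only offered when their required enzyme classes occur in the BGC.

## 9. Post-assembly modifications

A modification is a SMARTS motif plus product template (`motif >> product`),
gated on enzyme domain classes present in the BGC (or constitutive). Matching
uses RDKit substructure search with symmetric-copy deduplication; the
combinatorial expansion applies every subset of pairwise atom-disjoint sites,
tracks modified atoms across reactions, deduplicates by canonical SMILES and
caps output with a truncation flag.

## 10. Determinism and provenance

All randomness flows from explicit seeds (numpy `default_rng`). Pipeline
results carry a version stamp: package version, full config, config hash and
SHA-256 content hashes of every input file. Reruns with identical inputs are
byte-identical.

## Synthetic fixtures

`hybridforge.synth` plants injective 10-residue codes at the Stachelhaus
positions of the reference scaffold (one code per substrate, 5% background
mutation), builds profile HMMs from mutated consensus variants, plants
24-column AT signatures, and encodes blueprint gene clusters into DNA with a
fixed codon table — yielding genomes whose domain coordinates, gene
architectures and monomer assignments are known exactly.
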