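# mhc2bind

Pan-specific prediction of peptide binding affinity to MHC class II
molecules, with binding-core calling, motif extraction and the evaluation
protocols used in this field — plus a synthetic planted-core benchmark
generator so every component is testable at desk scale without external
downloads.

## The problem and the model

MHC class II molecules present peptides to helper T cells; predicting which
peptides an allele binds is central to epitope discovery and vaccine
design. A peptide of length L binds through an unknown 9-residue *binding
core* that occupies the groove's nine pockets; each allele is represented
by its 34-residue *pseudo sequence* (the polymorphic contact residues).
IC50 affinities (nM) are normalized to [0, 1] by
`1 − log(IC50)/log(50 000)`; peptides with IC50 < 500 nM (normalized
affinity > 0.426) count as binders.

The model is an allele-conditioned convolutional network. Peptide and
pseudo sequence pass through residue embeddings (dimension d); for each
kernel of size M ∈ {9, 11, 13, 15} a learned matrix `W_k (M×34)` turns the
embedded pseudo sequence `Y` into an *allele-specific* kernel
`relu(W_k Y)`, which scans every candidate core window of the peptide:

    C_ik = relu( ⟨relu(W_k Y), X[i:i+M]⟩_F + b_k ),   i = 1 … L−8.

Kernels larger than 9 see flanking residues; symmetric padding keeps one
row per candidate core start. Fully connected layers, a masked max-pool
over candidate cores, and a sigmoid output give the affinity `ẑ ∈ (0,1)`.
Training minimizes mean squared error with Adadelta (batch 128); T models
with different initializations are averaged. Dropping the max-pool scores
each 9-mer start separately, which yields the binding core, sequence
motifs, and a per-pocket importance analysis of the kernel weights. The
network and its backward passes are implemented directly in numpy and
verified against finite differences and brute-force oracles.

## Worked example

From `examples/02_train_and_predict.py` — generate a 4-allele synthetic
benchmark with planted cores, train a small two-model ensemble, and score
records from a held-out fold whose peptides share no 9-mer with training:

```
960 training records, 240 held-out records
held-out Pearson correlation: 0.593 (1.0 = perfect affinity prediction, 0 = uninformative)
```

From `examples/03_core_calling_and_motif.py` — call binding cores on the
held-out fold and extract the allele's motif:

```
held-out core recovery: exact 0.37, within one position 0.70 (chance for exact: ~0.19)
e.g. peptide VRKSYEQGSMEG: called core RKSYEQGSM at start 2 (matches planted)

per-pocket information content of the SYN-01 motif (bits; anchors 1/4/6/9 are weighted 3x in the generator):
  P1=1.08  P2=0.39  P3=0.80  P4=0.53  P5=0.55  P6=0.57  P7=0.33  P8=0.28  P9=0.35
```

The correlation and above-chance core recovery show the network learning
the planted pocket preferences from affinity-only supervision; the motif's
information content concentrates at the anchor-weighted pockets as
training deepens. `examples/01_ic50_normalization.py` and
`examples/04_evaluation_protocols.py` cover the IC50 transform and the
evaluation toolbox (per-allele AUC/PCC, exact two-tailed binomial sign
test, cross-fold 9-mer redundancy).

## Command line

A thin CLI wraps the library for shell pipelines:

```sh
mhc2bind synth --seed 1 --outdir data/
mhc2bind train --data data/affinity.tsv --alleles data/alleles.tsv --outdir models/
mhc2bind predict --checkpoint models/model_00.npz ... --peptides peps.txt \
    --allele SYN-01 --alleles data/alleles.tsv --outdir out/
mhc2bind core / logo / eval ...   # core calling, motifs, CV/LOMO/ablation
```

Every command writes a `manifest.json` (config, seeds, input digests) so
runs are reproducible from the manifest alone.

## File formats

* affinity table: TSV `peptide<TAB>value<TAB>allele[<TAB>fold]` (value is
  normalized affinity, or raw IC50 nM with `--ic50`);
* allele registry: TSV `allele<TAB>pseudo_sequence` (34 residues);
* peptide lists: plain text or FASTA.

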