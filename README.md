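# ccvtyper

Alignment-free genotyping of nucleotide and protein sequence sets: complete
composition vectors for sequence comparison, affinity propagation for
cluster (genotype) assignment, and neighbour-joining trees for the familiar
phylogenetic view.

## Who this is for

Surveillance and molecular-epidemiology workflows that need to partition
hundreds of homologous sequences (e.g. influenza gene segments, bacterial
genomes, 16S surveys) into genotypes *without* a multiple sequence
alignment. Alignment-based pipelines must realign every time a sequence is
added and their cost grows quickly with sample count; a k-mer vector
representation gives each sequence a fixed embedding whose pairwise
distances never change as the dataset grows.

## The method

**Complete composition vector (CCV).** A sequence `S` of length `L` has
`L − k + 1` overlapping k-mers. For a k-mer `α`:

    p(α) = f(α) / (L − k + 1)

is its observed probability, and a second-order Markov model built from the
(k−1)- and (k−2)-mer statistics gives the expected probability

    q(α) = p(α₁…α_{k−1}) · p(α₂…α_k) / p(α₂…α_{k−1}).

The composition value

    π(α) = (p(α) − q(α)) / q(α)      (0 when q = 0)

measures the background-corrected deviation of observed from expected — the
signal of selective, rather than merely compositional, evolution. The CCV
concatenates the composition vectors for all k from 3 to M (default M = 9).

**Feature selection.** Each substring is scored by revised relative entropy
against the background vector Π (the CCV of the pooled dataset):

    RE(α) = Σᵢ π(α, i) · ln( π(α, i) / Π(α) )

and substrings with |RE| < 1.0 are discarded. Retained columns are z-score
normalized.

**Distances.** Cosine distance `D = (1 − cos θ) / 2 ∈ [0, 1]` (the default;
it tracks reference trees most linearly) or Euclidean distance.

**Genotyping.** Affinity propagation clusters the samples over similarities
(`s = 1 − D` for cosine, `s = −D` for Euclidean). The preference — the
self-similarity that controls how many exemplars emerge — is chosen by
sweeping four values spanning the minimum-to-median similarity and keeping
the run with the best mean silhouette `s(i) = (bᵢ − aᵢ)/max(aᵢ, bᵢ)`. For
segmented genomes, per-segment cluster labels combine into a composite
genotype "profile": samples sharing the whole label tuple share a genotype.

**Trees.** Canonical Saitou–Nei neighbour joining over the same distance
matrix, with PHYLIP-square and packed-row matrix interchange and Newick
output; patristic distances and the Adjusted Rand Index quantify agreement
with reference trees and expert-defined partitions.

## Worked example

Simulate three planted groups of five 800-bp sequences, genotype them with
the default settings (k = 3..9, |RE| ≥ 1.0, cosine distance, four-point
preference sweep), and validate:

```bash
$ ccvtyper simulate --out data --seed 7 --groups 3 --per-group 5 --length 800
$ ccvtyper genotype data/sim.fasta --out run
$ head -4 run/sim.clusters.tsv
sample  segment cluster exemplar silhouette
g1_s1   sim     0       0        0.735582
g1_s2   sim     0       1        0.739067
g1_s3   sim     0       0        0.663483
$ ccvtyper evaluate ari --pred run/sim.clusters.tsv --truth data/sim.truth.tsv
1.000000
$ ccvtyper evaluate patristic --tree-a run/sim.tree.nwk --tree-b data/sim.true_tree.nwk
0.996090
```

The run log narrates the pipeline:

```
INFO segment sim: 15 sequences, 2686/11764 substrings retained (0.09s)
INFO segment sim: K=3 (preference 0.2871, mean silhouette 0.753), total 0.11s
```

2686 of 11764 candidate substrings pass the |RE| ≥ 1.0 filter; the
preference sweep selects K = 3 clusters that match the planted groups
exactly (ARI = 1.0), and the neighbour-joining tree over cosine CCV
distances reproduces the generating tree's patristic structure almost
perfectly (Pearson r = 0.996).

Every stage is also available programmatically, sklearn-style:

```python
from ccvtyper import CCVVectorizer, PreferenceSweepAP, read_fasta

records = read_fasta("data/sim.fasta")
X = CCVVectorizer().fit_transform(records)          # samples x retained k-mers
model = PreferenceSweepAP(metric="cosine").fit(X, ids=[r.id for r in records])
print(model.labels_, model.mean_silhouette_)
```

## Layout

- `src/ccvtyper/seqio.py` — FASTA / label-table IO, alphabet canonicalization
- `src/ccvtyper/ccv.py` — k-mer statistics, composition vectors, RE selection, `CCVVectorizer`
- `src/ccvtyper/distance.py` — cosine/Euclidean matrices, PHYLIP square and packed-row formats
- `src/ccvtyper/cluster.py` — affinity propagation, silhouettes, preference sweep, composite genotypes
- `src/ccvtyper/tree.py` — neighbour joining, Newick IO, patristic distances
- `src/ccvtyper/evaluate.py` — Adjusted Rand Index, patristic tree comparison
- `src/ccvtyper/synthetic.py` — planted-structure sequence simulation
- `src/ccvtyper/pipeline.py`, `cli.py` — orchestration and the `ccvtyper` command

See `docs/methods.md` for the modelling assumptions, parameter choices and
known limitations.
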