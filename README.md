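# syntelog

Pairwise syntenic-ortholog detection for closely related genomes, built for
the comparative-genomics setting of Brassicaceae crops: a query genome (such
as *Brassica rapa*) descended from whole-genome triplication and heavy gene
loss, compared against a diploid-like reference (such as *Arabidopsis
thaliana*).  Because up to three query copies may legitimately descend from
one reference gene, reciprocal-best-hit orthology breaks down; `syntelog`
instead decides each homologous pair by the company it keeps.

## The method

Inputs are per-genome gene models (GFF3 or BED) and all-vs-all protein
homology in BLAST tabular format (`-outfmt 6`).  Genes are ranked 0..n−1
along each chromosome; all window arithmetic is in gene-rank units.
Four steps:

1. **Candidate pairs.** Keep gene pairs that are a best hit (highest
   bitscore) in either direction, or share any hit with e-value < 1e-20.
2. **Tandem collapsing.** Intra-genome runs of homologs (e-value < 1e-20,
   at most one intervening non-homolog between consecutive members) are
   tandem arrays; each is replaced by its first member before scoring, and
   results are copied back to every member afterwards.
3. **Flanking-gene vote.** For a candidate pair (q, s), take the
   `NumQ` = 20 genes on each side of q and the `NumR` = 100 genes on each
   side of s.  The support ratio is the fraction of q's flanking genes whose
   best hit lands inside s's window.  Pairs with ratio > `RatioQR` = 0.2 are
   potentially syntenic.  The vote is orientation-agnostic, so inverted
   syntenic fragments pass untouched.
4. **Best-pair resolution.** Per query gene, the subject with the highest
   support ratio wins; within 0.05 of the maximum, higher bitscore decides.
   Subjects may serve several query genes — that is the triplication signal.

Query genes left unassigned become *non-syntenic orthologs* when some hit
has identity > 70% and coverage > 60% of **both** proteins (the signature of
gene transposition), otherwise *none*.

A synthetic-genome generator (`syntelog.simulate`) produces genome pairs
with a known history — triplication, per-copy retention, inversions, tandem
arrays, transpositions, and a noisy hit table — so the whole pipeline is
testable against ground truth without running an aligner.

## Worked example

Simulate a pair (600 ancestral genes, triplicated query at 40% retention,
mild noise), then run the pipeline at the default parameters:

```sh
syntelog simulate --seed 7 --out-dir demo/sim --n-genes 600 --n-chromosomes 3
# wrote simulated pair to demo/sim (807 true ortholog pairs, 40 tandem
# arrays, 20 transposed genes)

syntelog run \
  --query-gff demo/sim/query.gff3 --ref-gff demo/sim/reference.gff3 \
  --hits demo/sim/query_vs_reference.blast6 \
  --query-lengths demo/sim/query.lengths.tsv \
  --ref-lengths demo/sim/reference.lengths.tsv \
  --query-intra demo/sim/query_intra.blast6 \
  --ref-intra demo/sim/reference_intra.blast6 \
  --out-dir demo/out
# classified 827 query genes: 793 syntenic, 9 non-syntenic orthologs,
# 25 without ortholog (95.9% detected synteny)
```

Every query gene gets exactly one row in `demo/out/synteny.tsv`:

```text
query_gene     query_chr  query_rank  subject_gene  ...  support_ratio  class     tandem_expanded
qry_c1_g00001  qchr1_1    0           ref_g00001    ...  0.95           syntenic  0
qry_c1_g00005  qchr1_1    1           ref_g00005    ...  0.952…         syntenic  0
```

`support_ratio` is the flanking-vote fraction behind the call; the 9
non-syntenic orthologs are (mostly) the planted transposed genes — similar
in sequence, but in the wrong neighbourhood.  `syntelog sweep` repeats the
run over NumQ/NumR/RatioQR grids and tabulates % detected synteny per
parameter triple; `syntelog tandems` dumps detected tandem arrays.

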