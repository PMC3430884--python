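# Methods

## Model and assumptions

`syntelog` treats synteny as a property of gene neighbourhoods, not of
sequence alone.  Two homologous genes q (query genome) and s (reference
genome) are a syntenic pair when the genes around q tend to have their own
best homologs around s.  This window-vote formulation makes three
assumptions: gene order is locally conserved between the genomes (true for
genomes sharing a recent ancestral karyotype); protein homology is
informative enough that per-gene best hits usually point at the true
ortholog; and duplication depth is asymmetric — the query genome may carry
several (e.g. three, after hexaploidy) copies per reference gene, while each
query gene has one best syntenic partner.  The method is protein-based and
cannot place genes without protein annotation.

All positional reasoning uses ordinal gene ranks (0..n−1 per chromosome,
sorted by start coordinate), never base pairs: what matters to the vote is
how many annotated genes separate two loci, which is robust to intergenic
size variation between genomes.  Ties on start are broken by end then
gene ID, so ranks are a pure function of the gene set.

## Parameters

| parameter | default | unit | meaning |
|---|---|---|---|
| `num_q` | 20 | genes/side | query flanking window |
| `num_r` | 100 | genes/side | reference flanking window |
| `ratio_qr` | 0.2 | fraction | support threshold, exceeded strictly |
| `evalue_cut` | 1e-20 | — | homology cut for candidates and tandem edges |
| `ratio_tie_margin` | 0.05 | fraction | near-tie band resolved by bitscore |
| `identity_min` | 70 | % | non-syntenic-ortholog identity floor |
| `coverage_min` | 0.60 | fraction | coverage floor, each protein separately |

`num_r` should exceed `num_q`: fractionation thins each query subgenome, so
~20 query flankers span a region whose reference image is several times
longer.  The defaults are the operating point at which detection is stable
for a triplicated, heavily fractionated query; the `sweep` command
reproduces that choice empirically on any input.

## Design choices where the design was open

* **Direction and denominator of the support ratio.** The numerator counts
  query-flank genes whose query→reference best hit falls in the reference
  window; the denominator is the query window actually used (truncated at
  chromosome ends).  Using the smaller, query-side window keeps ratios
  comparable near chromosome ends.  A symmetric mode (both directions must
  pass) is available via `SyntenyParams(symmetric=True)`.
* **Best hits are single-direction, not reciprocal.** Three retained query
  copies cannot all be reciprocal bests of one reference gene, so
  reciprocal-best would systematically discard two thirds of the
  triplication signal; `reciprocal_only=True` exposes the stricter mode.
* **Best-hit key is bitscore**, with e-value, identity and subject ID as
  tie-breaks; aligners' e-value rounding makes bitscore the stabler primary
  key.  Multiple HSPs per pair keep only the max-bitscore HSP (no
  summation).
* **Tandem arrays chain transitively** (connected components of the
  homology-plus-adjacency graph): A–B and B–C homologous joins all three
  even if the A–C hit is weak.  The one-interruption tolerance is applied
  per junction (rank gap ≤ 2 between consecutive members), not across the
  array span.
* **Pure argmax would never consult sequence homology** when resolving
  multiple surviving subjects; the 0.05 near-tie margin is what lets a
  clearly stronger alignment win among near-equal neighbourhood votes.
* **Exclusions:** the subject gene itself is not part of its own window, so
  a flank gene whose best hit is the subject does not vote.  No
  collinearity dynamic programming (DAGchainer/MCScan-style chaining) is
  performed — each pair is judged by its own window, which is what keeps
  all (up to three) duplicated copies rather than one chained path.

## Numerical and degenerate-input behaviour

Windows truncate at chromosome ends and the denominator shrinks; a gene
alone on its chromosome has window size 0 and support 0 (class `none`).
The threshold comparisons are strict (`>` for ratio, identity and
coverage; `<` for e-value).  Result tables serialise floats with `repr`, so
write→read round-trips are exact and reruns are byte-identical.  When
protein lengths are unavailable, coverage is unknown and non-syntenic-
ortholog classification is disabled with a warning; syntenic calls are
unaffected.

## What the generator emulates — and what it does not

`simulate_pair` builds an ancestral gene order, keeps the reference at that
order, and derives the query by whole-genome multiplication
(`ploidy_multiplier`, 3 by default) with independent per-copy gene retention
(0.4 by default — so copy number per reference gene is Binomial(3, 0.4)),
then local inversions (10 segments of 3–15 genes), tandem expansion (40
arrays of 2–5 members), and transposition of 20 genes to random positions.
The hit table gives every true homolog pair a high score (bitscore
~N(400, 50); e-values monotone in bitscore — only the ordering matters to
the algorithm), paralog pairs less (~N(330, 40)), spurious pairs least
(~N(250, 40), still below the candidate e-value cut so they exercise the
vote's rejection path), drops true hits at `missing_hit_rate` = 0.02 and
adds spurious ones at `spurious_hit_rate` = 0.02.  Noise applies to the
inter-genome table; the intra-genome tables that drive tandem detection are
emitted clean, and tandem detection is instead stress-tested against an
independent connected-components oracle on random layouts.

Not emulated: actual sequence evolution (no sequences exist), unbalanced or
erroneous annotation between the genomes, segmental (sub-chromosomal)
duplications, scaffold fragmentation, and gene-family expansions beyond
tandem arrays.  Passing tests therefore demonstrate correctness of the
algorithmic machinery under a realistic karyotype history, not robustness
to annotation artefacts in real genomes.

Scenario sizes used by the test suite and `scripts/acceptance.py`: the main
scenario uses 2,000 ancestral genes on 5 chromosomes (≈2,400-gene query
after retention); oracle-equivalence checks use 20 pairs of ≤300 genes;
monotonicity checks use a noisier 500-gene scenario.  These sizes give
binomial sampling errors small enough for 3σ histogram checks while keeping
a full run around a second.

## Known limitations

Genes on chromosomes shorter than the window are judged on whatever flank
exists, which inflates ratio variance there; per-query uniqueness is
enforced but subject-side uniqueness deliberately is not; candidate
selection admits best hits regardless of e-value, so a genome with no good
hits still yields (unsupported, hence rejected) candidates; and the tool
reports one direction per run — run it twice, swapping genomes, for both
tables.
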