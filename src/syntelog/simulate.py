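"""Synthetic genome pairs with known evolutionary history.

The generator emulates the comparative setting the pipeline targets: a
reference genome that kept the ancestral gene order, and a query genome
descended from the same ancestor through whole-genome multiplication
(``ploidy_multiplier`` copies, 3 = the hexaploidy/triplication case)
followed by per-copy fractionation (independent gene retention at
``retention_per_copy``), local inversions, tandem-array expansion and gene
transposition.  A matching noisy homology table is emitted alongside, with
bitscores/e-values/identities drawn so that true homolog pairs score high
and spurious pairs low — only the ordering matters to the algorithm.

No sequences are simulated; gene models, protein lengths and the hit table
are generated directly, in exactly the formats the io layer reads, together
with a ground-truth ortholog map so every pipeline stage can be scored
without an aligner.  A fixed seed yields byte-identical files.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Set, Tuple

import numpy as np

from .core import NONSYNTENIC_ORTHOLOG, SYNTENIC, SyntenyResult

GENE_SPACING = 2000      # bp between simulated gene starts
GENE_LENGTH = 999        # simulated gene span - 1


@dataclass(frozen=True)
class EvolutionScenario:
    """Parameters of one simulated divergence history.

    The defaults describe a triplicated query genome with heavy
    fractionation (retention 0.4 per copy), mild structural turnover and a
    lightly noisy hit table — the regime the method is designed for.
    """

    seed: int
    n_ancestor_genes: int = 2000
    n_chromosomes: int = 5
    ploidy_multiplier: int = 3
    retention_per_copy: float = 0.4
    n_inversions: int = 10
    inversion_span: Tuple[int, int] = (3, 15)
    n_tandem_arrays: int = 40
    tandem_size_range: Tuple[int, int] = (2, 5)
    n_ref_tandem_arrays: int = 0
    n_transpositions: int = 20
    missing_hit_rate: float = 0.02
    spurious_hit_rate: float = 0.02

    def __post_init__(self) -> None:
        for name in ("retention_per_copy", "missing_hit_rate",
                     "spurious_hit_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.ploidy_multiplier < 1:
            raise ValueError("ploidy_multiplier must be >= 1")


@dataclass
class GroundTruth:
    """What the generator actually did, for scoring pipeline output."""

    #: query gene -> reference gene, for every query gene descended from a
    #: shared ancestor gene in syntenic context (tandem duplicates included)
    ortholog_map: Dict[str, str] = field(default_factory=dict)
    #: planted query tandem arrays (member tuples, seed first)
    tandem_truth: List[Tuple[str, ...]] = field(default_factory=list)
    #: planted reference tandem arrays
    ref_tandem_truth: List[Tuple[str, ...]] = field(default_factory=list)
    #: query genes relocated out of syntenic context
    transposed_ids: Set[str] = field(default_factory=set)


@dataclass
class SimulationResult:
    """File paths plus ground truth for one simulated genome pair."""

    query_gff: Path
    ref_gff: Path
    query_lengths: Path
    ref_lengths: Path
    inter_hits: Path         # query -> reference, BLAST outfmt-6
    query_intra_hits: Path
    ref_intra_hits: Path
    truth_table: Path
    truth: GroundTruth


class _Gene:
    __slots__ = ("gid", "anc", "length", "strand")

    def __init__(self, gid: str, anc: int, length: int, strand: str = "+"):
        self.gid, self.anc, self.length, self.strand = gid, anc, length, strand


def _evalue(bitscore: float) -> float:
    # monotone map, roughly the aligner's score/e-value relationship
    return 10.0 ** (-bitscore / 10.0)


def simulate_pair(scenario: EvolutionScenario, outdir) -> SimulationResult:
    """Generate one genome pair plus hit tables and ground truth.

    Events are applied in a fixed order — fractionation, inversions, tandem
    expansion, transpositions — so inversions never split planted arrays.
    Chromosomes emptied by extreme fractionation are dropped with a warning.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(scenario.seed)
    n, n_chrom = scenario.n_ancestor_genes, scenario.n_chromosomes
    anc_lengths = rng.integers(120, 800, size=n)
    # contiguous ancestor chromosomes
    bounds = np.linspace(0, n, n_chrom + 1).astype(int)
    anc_chroms = [list(range(bounds[k], bounds[k + 1]))
                  for k in range(n_chrom)]

    # ---- reference genome: ancestral order (+ optional tandem arrays) ----
    ref_chroms: Dict[str, List[_Gene]] = {}
    for k, ancs in enumerate(anc_chroms):
        ref_chroms[f"rchr{k + 1}"] = [
            _Gene(f"ref_g{a:05d}", a, int(anc_lengths[a])) for a in ancs]
    truth = GroundTruth()
    ref_intra_pairs: List[Tuple[_Gene, _Gene]] = []
    if scenario.n_ref_tandem_arrays:
        _plant_tandems(ref_chroms, scenario.n_ref_tandem_arrays,
                       scenario.tandem_size_range, rng,
                       truth.ref_tandem_truth, ref_intra_pairs)

    # ---- query genome: multiply, fractionate, invert, tandems, transpose --
    qry_chroms: Dict[str, List[_Gene]] = {}
    for c in range(1, scenario.ploidy_multiplier + 1):
        for k, ancs in enumerate(anc_chroms):
            genes = []
            for a in ancs:
                if scenario.retention_per_copy >= 1.0 \
                        or rng.random() < scenario.retention_per_copy:
                    length = max(100, int(anc_lengths[a])
                                 + int(rng.integers(-10, 11)))
                    genes.append(_Gene(f"qry_c{c}_g{a:05d}", a, length))
            qry_chroms[f"qchr{k + 1}_{c}"] = genes

    for _ in range(scenario.n_inversions):
        chrom = _pick_chrom(qry_chroms, rng, min_len=2)
        if chrom is None:
            break
        genes = qry_chroms[chrom]
        span = int(rng.integers(scenario.inversion_span[0],
                                scenario.inversion_span[1] + 1))
        span = min(span, len(genes))
        start = int(rng.integers(0, len(genes) - span + 1))
        seg = genes[start:start + span][::-1]
        for g in seg:
            g.strand = "-" if g.strand == "+" else "+"
        genes[start:start + span] = seg

    qry_intra_pairs: List[Tuple[_Gene, _Gene]] = []
    if scenario.n_tandem_arrays:
        _plant_tandems(qry_chroms, scenario.n_tandem_arrays,
                       scenario.tandem_size_range, rng,
                       truth.tandem_truth, qry_intra_pairs)
    tandem_members = {m for arr in truth.tandem_truth for m in arr}

    movable = [(chrom, i) for chrom, genes in qry_chroms.items()
               for i, g in enumerate(genes) if g.gid not in tandem_members]
    n_move = min(scenario.n_transpositions, len(movable))
    if n_move:
        picked = rng.choice(len(movable), size=n_move, replace=False)
        moved: List[_Gene] = []
        to_remove: Dict[str, Set[int]] = {}
        for idx in sorted(picked):
            chrom, i = movable[idx]
            to_remove.setdefault(chrom, set()).add(i)
            moved.append(qry_chroms[chrom][i])
        for chrom, idxs in to_remove.items():
            qry_chroms[chrom] = [g for i, g in enumerate(qry_chroms[chrom])
                                 if i not in idxs]
        for g in moved:
            dest = _pick_chrom(qry_chroms, rng, min_len=0)
            pos = int(rng.integers(0, len(qry_chroms[dest]) + 1))
            qry_chroms[dest].insert(pos, g)
            truth.transposed_ids.add(g.gid)

    # dispersed paralogs: seeds of the same ancestor gene in other subgenomes
    seeds_by_anc: Dict[int, List[_Gene]] = {}
    for genes in qry_chroms.values():
        for g in genes:
            if "_t" not in g.gid:
                seeds_by_anc.setdefault(g.anc, []).append(g)
    for copies in seeds_by_anc.values():
        for i in range(len(copies)):
            for j in range(i + 1, len(copies)):
                qry_intra_pairs.append((copies[i], copies[j]))

    for chrom in [c for c, genes in qry_chroms.items() if not genes]:
        logging.getLogger(__name__).warning(
            "chromosome %s emptied by fractionation; dropped", chrom)
        del qry_chroms[chrom]

    # ---- ground-truth ortholog map ----
    ref_by_anc: Dict[int, str] = {}
    for genes in ref_chroms.values():
        for g in genes:
            if "_t" not in g.gid:
                ref_by_anc[g.anc] = g.gid
    for genes in qry_chroms.values():
        for g in genes:
            if g.gid not in truth.transposed_ids:
                truth.ortholog_map[g.gid] = ref_by_anc[g.anc]

    # ---- homology tables ----
    qry_genes = [g for genes in qry_chroms.values() for g in genes]
    ref_genes = [g for genes in ref_chroms.values() for g in genes]
    ref_by_anc_all: Dict[int, List[_Gene]] = {}
    for g in ref_genes:
        ref_by_anc_all.setdefault(g.anc, []).append(g)

    inter_rows: List[str] = []
    for q in sorted(qry_genes, key=lambda g: g.gid):
        for r in ref_by_anc_all[q.anc]:
            if rng.random() < scenario.missing_hit_rate:
                continue
            inter_rows.append(_hit_row(q, r, rng, true_pair=True))
    n_spurious = round(scenario.spurious_hit_rate * len(inter_rows))
    for _ in range(n_spurious):
        q = qry_genes[int(rng.integers(0, len(qry_genes)))]
        r = ref_genes[int(rng.integers(0, len(ref_genes)))]
        if r.anc == q.anc:
            continue
        inter_rows.append(_hit_row(q, r, rng, true_pair=False))

    qry_intra_rows = [_hit_row(a, b, rng, true_pair=True, paralog=True)
                      for a, b in qry_intra_pairs]
    ref_intra_rows = [_hit_row(a, b, rng, true_pair=True, paralog=True)
                      for a, b in ref_intra_pairs]

    # ---- write files ----
    paths = SimulationResult(
        query_gff=outdir / "query.gff3", ref_gff=outdir / "reference.gff3",
        query_lengths=outdir / "query.lengths.tsv",
        ref_lengths=outdir / "reference.lengths.tsv",
        inter_hits=outdir / "query_vs_reference.blast6",
        query_intra_hits=outdir / "query_intra.blast6",
        ref_intra_hits=outdir / "reference_intra.blast6",
        truth_table=outdir / "truth.tsv", truth=truth)
    _write_gff(paths.query_gff, qry_chroms)
    _write_gff(paths.ref_gff, ref_chroms)
    _write_lengths(paths.query_lengths, qry_genes)
    _write_lengths(paths.ref_lengths, ref_genes)
    for p, rows in ((paths.inter_hits, inter_rows),
                    (paths.query_intra_hits, qry_intra_rows),
                    (paths.ref_intra_hits, ref_intra_rows)):
        with open(p, "w") as fh:
            fh.writelines(rows)
    with open(paths.truth_table, "w") as fh:
        fh.write("kind\tquery_gene\tvalue\n")
        for q in sorted(truth.ortholog_map):
            fh.write(f"ortholog\t{q}\t{truth.ortholog_map[q]}\n")
        for arr in truth.tandem_truth:
            fh.write(f"tandem\t{arr[0]}\t{','.join(arr)}\n")
        for arr in truth.ref_tandem_truth:
            fh.write(f"ref_tandem\t{arr[0]}\t{','.join(arr)}\n")
        for t in sorted(truth.transposed_ids):
            fh.write(f"transposed\t{t}\t.\n")
    return paths


def _pick_chrom(chroms: Dict[str, List[_Gene]], rng,
                min_len: int) -> Optional[str]:
    names = sorted(c for c, genes in chroms.items() if len(genes) >= min_len)
    if not names:
        return None
    return names[int(rng.integers(0, len(names)))]


def _plant_tandems(chroms: Dict[str, List[_Gene]], n_arrays: int,
                   size_range: Tuple[int, int], rng,
                   truth_list: List[Tuple[str, ...]],
                   intra_pairs: List[Tuple[_Gene, _Gene]]) -> None:
    """Duplicate randomly chosen seed genes in place into adjacent runs."""
    eligible = [(chrom, g.gid) for chrom, genes in chroms.items()
                for g in genes]
    n_arrays = min(n_arrays, len(eligible))
    if not n_arrays:
        return
    picked = rng.choice(len(eligible), size=n_arrays, replace=False)
    chosen = sorted((eligible[i] for i in picked))
    for chrom, gid in chosen:
        genes = chroms[chrom]
        i = next(k for k, g in enumerate(genes) if g.gid == gid)
        seed = genes[i]
        size = int(rng.integers(size_range[0], size_range[1] + 1))
        dups = [_Gene(f"{seed.gid}_t{j}", seed.anc,
                      max(100, seed.length + int(rng.integers(-10, 11))),
                      seed.strand)
                for j in range(1, size)]
        genes[i + 1:i + 1] = dups
        members = [seed] + dups
        truth_list.append(tuple(m.gid for m in members))
        for a in range(len(members)):
            for b in range(a + 1, len(members)):
                intra_pairs.append((members[a], members[b]))


def _hit_row(q: _Gene, r: _Gene, rng, true_pair: bool,
             paralog: bool = False) -> str:
    """One 12-column BLAST tabular line with plausible statistics."""
    if true_pair and not paralog:
        bitscore = max(120.0, float(rng.normal(400.0, 50.0)))
        pident = float(rng.uniform(75.0, 95.0))
        cov = float(rng.uniform(0.80, 0.98))
    elif paralog:
        bitscore = max(110.0, float(rng.normal(330.0, 40.0)))
        pident = float(rng.uniform(70.0, 90.0))
        cov = float(rng.uniform(0.75, 0.95))
    else:  # spurious
        bitscore = max(50.0, float(rng.normal(250.0, 40.0)))
        pident = float(rng.uniform(30.0, 60.0))
        cov = float(rng.uniform(0.20, 0.50))
    aln = max(30, int(round(cov * min(q.length, r.length))))
    mismatch = int(round(aln * (1.0 - pident / 100.0)))
    evalue = _evalue(bitscore)
    return (f"{q.gid}\t{r.gid}\t{pident:.1f}\t{aln}\t{mismatch}\t0\t"
            f"1\t{aln}\t1\t{aln}\t{evalue:.3e}\t{bitscore:.1f}\n")


def _write_gff(path: Path, chroms: Dict[str, List[_Gene]]) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for chrom in sorted(chroms):
            for i, g in enumerate(chroms[chrom]):
                start = 1 + i * GENE_SPACING
                fh.write(f"{chrom}\tsim\tgene\t{start}\t"
                         f"{start + GENE_LENGTH}\t.\t{g.strand}\t.\t"
                         f"ID={g.gid}\n")


def _write_lengths(path: Path, genes: Sequence[_Gene]) -> None:
    with open(path, "w") as fh:
        for g in sorted(genes, key=lambda g: g.gid):
            fh.write(f"{g.gid}\t{g.length}\n")


# ---------------------------------------------------------------------------
# scoring pipeline output against the planted truth

@dataclass
class TruthMetrics:
    precision: float
    recall: float
    f1: float
    n_true_pairs: int
    n_predicted: int
    n_correct: int
    empty_predictions: bool
    #: how planted transposed genes ended up classified
    transposed_as_syntenic: int = 0
    transposed_as_nonsyntenic: int = 0
    transposed_as_none: int = 0


def score_against_truth(results: Sequence[SyntenyResult],
                        truth: GroundTruth) -> TruthMetrics:
    """Precision/recall/F1 of the syntenic pairs against the planted map.

    With an empty prediction set precision is reported as 1.0 with
    ``empty_predictions`` flagged.  Reference tandem members are normalised
    through their planted representative before comparison, matching how the
    pipeline reports subjects.
    """
    ref_rep = {m: arr[0] for arr in truth.ref_tandem_truth for m in arr}
    true_pairs = {(q, ref_rep.get(r, r))
                  for q, r in truth.ortholog_map.items()}
    predicted = {(r.query_id, r.subject_id) for r in results
                 if r.classification == SYNTENIC}
    correct = len(predicted & true_pairs)
    precision = correct / len(predicted) if predicted else 1.0
    recall = correct / len(true_pairs) if true_pairs else 1.0
    f1 = (2 * precision * recall / (precision + recall)
          if precision + recall else 0.0)
    m = TruthMetrics(precision=precision, recall=recall, f1=f1,
                     n_true_pairs=len(true_pairs), n_predicted=len(predicted),
                     n_correct=correct, empty_predictions=not predicted)
    by_query = {r.query_id: r for r in results}
    for t in truth.transposed_ids:
        r = by_query.get(t)
        if r is None:
            continue
        if r.classification == SYNTENIC:
            m.transposed_as_syntenic += 1
        elif r.classification == NONSYNTENIC_ORTHOLOG:
            m.transposed_as_nonsyntenic += 1
        else:
            m.transposed_as_none += 1
    return m


def syntenic_copy_number(results: Sequence[SyntenyResult]) -> Dict[str, int]:
    """Per reference gene, the number of distinct syntenic query copies
    (tandem-expanded members not double-counted)."""
    counts: Dict[str, int] = {}
    for r in results:
        if r.classification == SYNTENIC and not r.tandem_expanded:
            counts[r.subject_id] = counts.get(r.subject_id, 0) + 1
    return counts
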