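"""Shared fixtures: tiny hand-built genomes, simulation loaders, and
independent brute-force oracles the implementation is checked against."""
from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import pytest

import syntelog as sl
from syntelog.io import Gene, GenomeIndex, HomologyHit


# ---------------------------------------------------------------------------
# builders

def make_genome(gene_ids: Sequence[str], genome_id: str = "G",
                chromosome: str = "c1", spacing: int = 1000) -> GenomeIndex:
    """Genome with the given genes laid out in order on one chromosome."""
    genes = [Gene(gene_id=g, genome_id=genome_id, chromosome=chromosome,
                  start=1 + i * spacing, end=spacing - 100 + i * spacing)
             for i, g in enumerate(gene_ids)]
    return GenomeIndex(genome_id, genes)


def make_multichrom_genome(layout: Dict[str, Sequence[str]],
                           genome_id: str = "G") -> GenomeIndex:
    genes = []
    for chrom, ids in layout.items():
        for i, g in enumerate(ids):
            genes.append(Gene(gene_id=g, genome_id=genome_id,
                              chromosome=chrom, start=1 + i * 1000,
                              end=900 + i * 1000))
    return GenomeIndex(genome_id, genes)


def hit(q: str, s: str, bitscore: float = 400.0, evalue: float = 1e-40,
        pident: float = 90.0, aln: int = 200, qcov: Optional[float] = 0.9,
        scov: Optional[float] = 0.9) -> HomologyHit:
    return HomologyHit(query_id=q, subject_id=s, pident=pident,
                       aln_length=aln, evalue=evalue, bitscore=bitscore,
                       qcov=qcov, scov=scov)


def collinear_pair(n: int) -> Tuple[GenomeIndex, GenomeIndex,
                                    List[HomologyHit]]:
    """Two genomes with identical gene order and one-to-one hits."""
    qg = make_genome([f"q{i:03d}" for i in range(n)], "Q")
    rg = make_genome([f"r{i:03d}" for i in range(n)], "R")
    hits = [hit(f"q{i:03d}", f"r{i:03d}") for i in range(n)]
    return qg, rg, hits


def load_simulation(sim: sl.SimulationResult):
    """Read a generated pair back through the io layer."""
    qg = sl.read_gene_models(sim.query_gff, "gff3", "query")
    rg = sl.read_gene_models(sim.ref_gff, "gff3", "reference")
    lengths = {**sl.read_protein_lengths(sim.query_lengths),
               **sl.read_protein_lengths(sim.ref_lengths)}
    inter = sl.read_homology_table(sim.inter_hits, qg, rg,
                                   protein_lengths=lengths)
    qi = sl.read_homology_table(sim.query_intra_hits, qg, qg,
                                protein_lengths=lengths)
    ri = sl.read_homology_table(sim.ref_intra_hits, rg, rg,
                                protein_lengths=lengths)
    return qg, rg, inter, qi, ri


TRIPLICATION_SCENARIO = dict(n_ancestor_genes=2000, n_chromosomes=5,
                             ploidy_multiplier=3, retention_per_copy=0.4,
                             missing_hit_rate=0.02, spurious_hit_rate=0.02)


@pytest.fixture(scope="session")
def triplication_run(tmp_path_factory):
    """One full pipeline run on the triplicated, fractionated, noisy
    scenario, shared across tests (read-only)."""
    scenario = sl.EvolutionScenario(seed=42, **TRIPLICATION_SCENARIO)
    sim = sl.simulate_pair(scenario,
                           tmp_path_factory.mktemp("trip") / "sim")
    qg, rg, inter, qi, ri = load_simulation(sim)
    out = sl.run_pipeline(qg, rg, inter, qi, ri)
    return sim, qg, rg, inter, qi, ri, out


# ---------------------------------------------------------------------------
# independent oracles (deliberately naive re-implementations)

def oracle_best_hits(hits: Sequence[HomologyHit]) -> Dict[str, str]:
    """Brute-force scan: for each query, best subject by (bitscore,
    -evalue, pident, smallest subject_id)."""
    by_query: Dict[str, List[HomologyHit]] = {}
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
    out = {}
    for q, hs in by_query.items():
        best = None
        for h in hs:
            if best is None:
                best = h
                continue
            a = (h.bitscore, -h.evalue, h.pident)
            b = (best.bitscore, -best.evalue, best.pident)
            if a > b or (a == b and h.subject_id < best.subject_id):
                best = h
        out[q] = best.subject_id
    return out


def oracle_flanking_count(query_id: str, subject_id: str,
                          query_genome: GenomeIndex,
                          ref_genome: GenomeIndex,
                          best_map: Dict[str, str],
                          num_q: int, num_r: int) -> Tuple[int, int]:
    """Explicit window enumeration: build both window gene lists, then
    count query-window genes whose best hit is a member of the subject
    window.  Returns (supporting_count, query_window_size)."""
    qgene = query_genome[query_id]
    qchrom = query_genome.genes_on(qgene.chromosome)
    qwin = [g.gene_id for g in qchrom
            if g.gene_id != query_id and abs(g.rank - qgene.rank) <= num_q]
    sgene = ref_genome[subject_id]
    schrom = ref_genome.genes_on(sgene.chromosome)
    swin = {g.gene_id for g in schrom
            if g.gene_id != subject_id and abs(g.rank - sgene.rank) <= num_r}
    count = sum(1 for g in qwin if best_map.get(g) in swin)
    return count, len(qwin)


def oracle_tandem_arrays(genome: GenomeIndex,
                         intra_hits: Sequence[HomologyHit],
                         evalue_cut: float = 1e-20,
                         max_gap: int = 1) -> set:
    """Connected components of the explicit adjacency graph, via networkx."""
    import networkx as nx
    homolog = set()
    for h in intra_hits:
        if h.evalue < evalue_cut and h.query_id != h.subject_id:
            homolog.add(frozenset((h.query_id, h.subject_id)))
    g = nx.Graph()
    for chrom in genome.chromosomes:
        genes = genome.genes_on(chrom)
        for a in genes:
            for b in genes:
                if 0 < b.rank - a.rank <= max_gap + 1 \
                        and frozenset((a.gene_id, b.gene_id)) in homolog:
                    g.add_edge(a.gene_id, b.gene_id)
    return {frozenset(c) for c in nx.connected_components(g) if len(c) >= 2}
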