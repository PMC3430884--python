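"""Tandem gene array detection and collapsing (pipeline step 2).

A tandem array is a run of intra-genome homologs (e-value < 1e-20) along one
chromosome in which consecutive members may be separated by at most one
intervening non-homologous gene.  Arrays are the connected components of the
graph whose edges join homologous genes at rank distance <= max_gap + 1 on
the same chromosome; homology chains transitively (A-B and B-C homologous
joins A, B, C even if the A-C hit is weak), which is the conventional reading
of a tandem array in comparative genomics.

Before synteny scoring, each array is replaced by its first member (lowest
rank) and chromosome ranks are reassigned; a redirect map records where every
absorbed member went, so hits and final results can be translated back.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .io import Gene, GenomeIndex, HomologyHit
from .homology import DEFAULT_EVALUE_CUT, _hit_rank_key


@dataclass(frozen=True)
class TandemArray:
    genome_id: str
    chromosome: str
    member_ids: Tuple[str, ...]   # ascending rank
    representative_id: str        # first (lowest-rank) member

    def __len__(self) -> int:
        return len(self.member_ids)


@dataclass
class CollapsedGenome:
    """Genome with tandem arrays collapsed to their representatives.

    ``redirect`` maps every absorbed member to its representative; genes not
    in any array are absent from the map (resolve() treats them as identity).
    """

    genome: GenomeIndex
    redirect: Dict[str, str] = field(default_factory=dict)

    def resolve(self, gene_id: str) -> str:
        return self.redirect.get(gene_id, gene_id)


class _UnionFind:
    def __init__(self):
        self.parent: Dict[str, str] = {}

    def find(self, x: str) -> str:
        self.parent.setdefault(x, x)
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: str, b: str) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[ra] = rb


def detect_tandem_arrays(genome: GenomeIndex,
                         intra_hits: Iterable[HomologyHit],
                         evalue_cut: float = DEFAULT_EVALUE_CUT,
                         max_gap: int = 1) -> List[TandemArray]:
    """Find maximal tandem arrays on every chromosome.

    ``max_gap`` is the number of intervening non-homologous genes tolerated
    between consecutive members (default 1), applied per junction.
    """
    homolog = set()
    for h in intra_hits:
        if h.evalue < evalue_cut and h.query_id != h.subject_id:
            homolog.add((h.query_id, h.subject_id))
            homolog.add((h.subject_id, h.query_id))

    uf = _UnionFind()
    members = set()
    for chrom in genome.chromosomes:
        genes = genome.genes_on(chrom)
        for i, g in enumerate(genes):
            for j in range(i + 1, min(i + max_gap + 2, len(genes))):
                if (g.gene_id, genes[j].gene_id) in homolog:
                    uf.union(g.gene_id, genes[j].gene_id)
                    members.add(g.gene_id)
                    members.add(genes[j].gene_id)

    comps: Dict[str, List[Gene]] = {}
    for gid in members:
        comps.setdefault(uf.find(gid), []).append(genome[gid])

    arrays = []
    for comp in comps.values():
        comp.sort(key=lambda g: g.rank)
        arrays.append(TandemArray(
            genome_id=genome.genome_id,
            chromosome=comp[0].chromosome,
            member_ids=tuple(g.gene_id for g in comp),
            representative_id=comp[0].gene_id))
    arrays.sort(key=lambda a: (a.chromosome, genome[a.representative_id].rank))
    return arrays


def collapse_tandems(genome: GenomeIndex,
                     arrays: Sequence[TandemArray]) -> CollapsedGenome:
    """Replace each array by its first member; re-rank chromosomes."""
    redirect: Dict[str, str] = {}
    seen = set()
    for arr in arrays:
        for m in arr.member_ids:
            if m not in genome:
                raise ValueError(f"array member {m!r} not in genome")
            if m in seen:
                raise ValueError(f"gene {m!r} appears in more than one array")
            seen.add(m)
            if m != arr.representative_id:
                redirect[m] = arr.representative_id
    kept = [g for g in genome
            if g.gene_id not in redirect]
    collapsed = GenomeIndex(genome.genome_id,
                            [Gene(g.gene_id, g.genome_id, g.chromosome,
                                  g.start, g.end, g.strand) for g in kept])
    return CollapsedGenome(genome=collapsed, redirect=redirect)


def redirect_hits(hits: Iterable[HomologyHit],
                  query_redirect: Mapping[str, str],
                  subject_redirect: Optional[Mapping[str, str]] = None,
                  ) -> List[HomologyHit]:
    """Reassign hits of absorbed tandem members to their representatives,
    keeping the single best hit per resulting gene pair."""
    if subject_redirect is None:
        subject_redirect = {}
    best: Dict[Tuple[str, str], HomologyHit] = {}
    for h in hits:
        q = query_redirect.get(h.query_id, h.query_id)
        s = subject_redirect.get(h.subject_id, h.subject_id)
        redirected = HomologyHit(q, s, h.pident, h.aln_length, h.evalue,
                                 h.bitscore, h.qcov, h.scov) \
            if (q, s) != (h.query_id, h.subject_id) else h
        pair = (q, s)
        prev = best.get(pair)
        if prev is None or _hit_rank_key(redirected) > _hit_rank_key(prev):
            best[pair] = redirected
    return list(best.values())


def write_tandem_table(arrays: Sequence[TandemArray], path) -> None:
    """TSV dump: genome, chromosome, representative, comma-joined members."""
    with open(path, "w") as fh:
        fh.write("genome\tchromosome\trepresentative\tmembers\n")
        for a in arrays:
            fh.write(f"{a.genome_id}\t{a.chromosome}\t{a.representative_id}"
                     f"\t{','.join(a.member_ids)}\n")
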