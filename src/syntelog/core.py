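"""Flanking-gene support scoring and best-syntenic-pair resolution
(pipeline steps 3-4), plus the post-hoc classifications.

Whether a candidate homolog pair is syntenic is decided by a window vote:
take up to ``num_q`` genes on each side of the query gene and up to ``num_r``
genes on each side of the subject gene (rank units, chromosome ends
truncate).  Every query-window gene whose cross-genome best hit lands inside
the subject window is one supporting vote; the support ratio is
votes / |query window|.  A pair whose ratio exceeds ``ratio_qr`` (strictly)
is potentially syntenic.  The vote is orientation-agnostic, so an inverted
syntenic fragment supports exactly as a same-direction one does.

When several subjects survive for one query gene, the one with the highest
support ratio wins; within ``ratio_tie_margin`` of the maximum, sequence
homology (bitscore) breaks the near-tie.  Per-query uniqueness is enforced;
one subject may serve several query genes, which is what preserves the
triplication signal of a hexaploid-descended query genome.

Query genes left without a syntenic partner are classified non-syntenic
orthologs when some hit passes the similarity rule (identity > 70%, coverage
of each protein > 60%), and "none" otherwise.  Finally, results computed on
tandem representatives are copied back onto every absorbed array member.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple

from .io import GenomeIndex, HomologyHit
from .homology import (BestHitMap, CandidatePairSet, DEFAULT_EVALUE_CUT,
                       _hit_rank_key, compute_best_hits, flip_hits,
                       select_candidate_pairs)
from .tandem import (CollapsedGenome, TandemArray, collapse_tandems,
                     detect_tandem_arrays, redirect_hits)

log = logging.getLogger(__name__)

SYNTENIC = "syntenic"
NONSYNTENIC_ORTHOLOG = "nonsyntenic_ortholog"
NONE = "none"


@dataclass(frozen=True)
class SyntenyParams:
    """Window-vote parameters.

    num_q/num_r: flanking genes per side of the query/subject gene (rank
    units).  ratio_qr: support threshold, exceeded strictly.  ratio_tie_margin:
    candidates within this margin of the best support ratio are re-ranked by
    bitscore.  symmetric: also require the reverse-direction ratio (votes of
    subject flanks landing in the query window) to exceed ratio_qr.
    """

    num_q: int = 20
    num_r: int = 100
    ratio_qr: float = 0.2
    ratio_tie_margin: float = 0.05
    symmetric: bool = False

    def __post_init__(self) -> None:
        if self.num_q <= 0 or self.num_r <= 0:
            raise ValueError("num_q and num_r must be positive")
        if not 0 < self.ratio_qr <= 1:
            raise ValueError("ratio_qr must be in (0, 1]")
        if self.num_r < self.num_q:
            log.warning("num_r (%d) < num_q (%d); the subject window is "
                        "usually the larger one", self.num_r, self.num_q)


@dataclass(frozen=True)
class SyntenyCandidate:
    """A homologous gene pair annotated with its flanking support."""

    query_id: str
    subject_id: str
    support_ratio: float
    supporting_count: int
    window_size: int          # denominator actually used
    hit: Optional[HomologyHit] = None


@dataclass(frozen=True)
class SyntenyResult:
    """Final assignment for one query-genome gene."""

    query_id: str
    classification: str                  # syntenic / nonsyntenic_ortholog / none
    subject_id: Optional[str] = None
    support_ratio: Optional[float] = None
    hit: Optional[HomologyHit] = None
    tandem_expanded: bool = False


def flanking_support(query_id: str, subject_id: str,
                     query_genome: GenomeIndex, ref_genome: GenomeIndex,
                     best_hits: BestHitMap, params: SyntenyParams,
                     hit: Optional[HomologyHit] = None) -> SyntenyCandidate:
    """Score one candidate pair by its flanking-gene vote.

    Both genes must exist in their (collapsed) genomes — callers must first
    redirect absorbed tandem members to their representatives.  The window
    truncates at chromosome ends and the denominator shrinks accordingly.
    """
    if query_id not in query_genome:
        raise KeyError(f"{query_id!r} not in collapsed query genome "
                       f"(redirect tandem members first)")
    if subject_id not in ref_genome:
        raise KeyError(f"{subject_id!r} not in collapsed reference genome "
                       f"(redirect tandem members first)")
    subject = ref_genome[subject_id]
    window = query_genome.flanking(query_id, params.num_q)
    count = 0
    for g in window:
        partner = best_hits.map.get(g.gene_id)
        if partner is None or partner == subject_id:
            continue
        pg = ref_genome.get(partner)
        if pg is not None and pg.chromosome == subject.chromosome \
                and abs(pg.rank - subject.rank) <= params.num_r:
            count += 1
    n = len(window)
    ratio = count / n if n else 0.0
    return SyntenyCandidate(query_id=query_id, subject_id=subject_id,
                            support_ratio=ratio, supporting_count=count,
                            window_size=n, hit=hit)


def potential_syntenic_pairs(candidates: CandidatePairSet,
                             query_genome: GenomeIndex,
                             ref_genome: GenomeIndex,
                             best_hits: BestHitMap,
                             params: SyntenyParams,
                             best_hits_reverse: Optional[BestHitMap] = None,
                             ) -> List[SyntenyCandidate]:
    """Candidates whose support ratio strictly exceeds ``params.ratio_qr``.

    In symmetric mode the reverse-direction ratio (subject flanks voting into
    the query window) must also exceed the threshold; ``best_hits_reverse``
    is required then.
    """
    if params.symmetric and best_hits_reverse is None:
        raise ValueError("symmetric mode needs the reverse best-hit map")
    out = []
    for (q, s), hit in candidates:
        if q not in query_genome or s not in ref_genome:
            continue
        cand = flanking_support(q, s, query_genome, ref_genome, best_hits,
                                params, hit=hit)
        if cand.support_ratio <= params.ratio_qr:
            continue
        if params.symmetric:
            rev_params = replace(params, num_q=params.num_r,
                                 num_r=params.num_q, symmetric=False)
            rev = flanking_support(s, q, ref_genome, query_genome,
                                   best_hits_reverse, rev_params)
            if rev.support_ratio <= params.ratio_qr:
                continue
        out.append(cand)
    return out


def resolve_best_pairs(potentials: Iterable[SyntenyCandidate],
                       ratio_tie_margin: float = 0.05,
                       ) -> List[SyntenyCandidate]:
    """Keep exactly one subject per query gene.

    The maximal support ratio wins; candidates within ``ratio_tie_margin``
    of it are re-ranked by bitscore ("comparably higher sequence homology"),
    then lower e-value, then lexicographic subject ID.  Subjects may recur
    across query genes.
    """
    per_query: Dict[str, List[SyntenyCandidate]] = {}
    for c in potentials:
        per_query.setdefault(c.query_id, []).append(c)
    out = []
    for q in sorted(per_query):
        cands = per_query[q]
        top = max(c.support_ratio for c in cands)
        near = [c for c in cands if c.support_ratio >= top - ratio_tie_margin]
        near.sort(key=lambda c: (_hit_rank_key(c.hit) if c.hit is not None
                                 else (0.0, 0.0, 0.0, "")),
                  reverse=True)
        out.append(near[0])
    return out


def classify_nonsyntenic_orthologs(unassigned_query_genes: Iterable[str],
                                   hits: Iterable[HomologyHit],
                                   identity_min: float = 70.0,
                                   coverage_min: float = 0.60,
                                   ) -> List[SyntenyResult]:
    """Classify query genes without a syntenic partner.

    A gene becomes a non-syntenic ortholog when some hit has identity above
    ``identity_min`` (percent) and coverage of *each* protein above
    ``coverage_min``; the best such hit (bitscore) is recorded.  When no hit
    carries coverage (protein lengths unknown) the classification is
    disabled and every gene is reported as "none".
    """
    by_query: Dict[str, List[HomologyHit]] = {}
    any_coverage = False
    for h in hits:
        by_query.setdefault(h.query_id, []).append(h)
        if h.qcov is not None and h.scov is not None:
            any_coverage = True
    if by_query and not any_coverage:
        log.warning("no hit carries protein coverage; non-syntenic-ortholog "
                    "classification disabled (all unassigned genes -> none)")
    out = []
    for q in unassigned_query_genes:
        best: Optional[HomologyHit] = None
        if any_coverage:
            for h in by_query.get(q, ()):
                if h.qcov is None or h.scov is None:
                    continue
                if h.pident > identity_min and h.qcov > coverage_min \
                        and h.scov > coverage_min:
                    if best is None or _hit_rank_key(h) > _hit_rank_key(best):
                        best = h
        if best is not None:
            out.append(SyntenyResult(query_id=q,
                                     classification=NONSYNTENIC_ORTHOLOG,
                                     subject_id=best.subject_id, hit=best))
        else:
            out.append(SyntenyResult(query_id=q, classification=NONE))
    return out


def expand_tandem_synteny(results_on_representatives: Sequence[SyntenyResult],
                          query_redirect: Mapping[str, str],
                          ref_redirect: Optional[Mapping[str, str]] = None,
                          ) -> List[SyntenyResult]:
    """Copy each representative's result onto its absorbed tandem members.

    Members inherit the representative's class, subject and support with
    ``tandem_expanded`` set; subject IDs stay on reference representatives.
    """
    by_rep = {r.query_id: r for r in results_on_representatives}
    out = list(results_on_representatives)
    for member, rep in query_redirect.items():
        if rep not in by_rep:
            raise KeyError(f"tandem member {member!r} redirects to unknown "
                           f"representative {rep!r}")
        out.append(replace(by_rep[rep], query_id=member, tandem_expanded=True))
    return out


@dataclass
class PipelineOutput:
    """Everything one pairwise run produces."""

    results: List[SyntenyResult]
    params: SyntenyParams
    query_arrays: List[TandemArray]
    ref_arrays: List[TandemArray]
    query_collapsed: CollapsedGenome
    ref_collapsed: CollapsedGenome
    n_candidates: int
    n_potential: int

    def counts(self) -> Dict[str, int]:
        c = {SYNTENIC: 0, NONSYNTENIC_ORTHOLOG: 0, NONE: 0}
        for r in self.results:
            c[r.classification] += 1
        return c

    def syntenic_fraction(self) -> float:
        c = self.counts()
        total = sum(c.values())
        return c[SYNTENIC] / total if total else 0.0

    def syntenic_pairs(self) -> set:
        return {(r.query_id, r.subject_id) for r in self.results
                if r.classification == SYNTENIC}


def run_pipeline(query_genome: GenomeIndex, ref_genome: GenomeIndex,
                 inter_hits: Sequence[HomologyHit],
                 query_intra_hits: Sequence[HomologyHit] = (),
                 ref_intra_hits: Sequence[HomologyHit] = (),
                 params: SyntenyParams = SyntenyParams(),
                 evalue_cut: float = DEFAULT_EVALUE_CUT,
                 identity_min: float = 70.0,
                 coverage_min: float = 0.60,
                 reciprocal_only: bool = False) -> PipelineOutput:
    """Run the full pairwise synteny pipeline.

    Steps: detect and collapse tandem arrays in both genomes; redirect the
    inter-genome hits through the tandem representatives; compute best hits
    both directions; select candidate pairs; score each by flanking support
    and keep those above threshold; resolve one best subject per query gene;
    classify the remainder by raw similarity; expand results back onto
    absorbed tandem members.  Deterministic for identical inputs.

    ``inter_hits`` must be in query→reference direction; intra-genome hit
    tables (self-hits removed) drive tandem detection and may be empty, in
    which case no arrays are collapsed in that genome.
    """
    query_arrays = detect_tandem_arrays(query_genome, query_intra_hits,
                                        evalue_cut=evalue_cut)
    ref_arrays = detect_tandem_arrays(ref_genome, ref_intra_hits,
                                      evalue_cut=evalue_cut)
    qc = collapse_tandems(query_genome, query_arrays)
    rc = collapse_tandems(ref_genome, ref_arrays)

    hits = redirect_hits(inter_hits, qc.redirect, rc.redirect)
    best_qr = compute_best_hits(hits, query_genome.genome_id,
                                ref_genome.genome_id)
    best_rq = compute_best_hits(flip_hits(hits), ref_genome.genome_id,
                                query_genome.genome_id)
    candidates = select_candidate_pairs(hits, best_qr, best_rq,
                                        evalue_cut=evalue_cut,
                                        reciprocal_only=reciprocal_only)

    potentials = potential_syntenic_pairs(candidates, qc.genome, rc.genome,
                                          best_qr, params,
                                          best_hits_reverse=best_rq)
    winners = resolve_best_pairs(potentials,
                                 ratio_tie_margin=params.ratio_tie_margin)

    rep_results: Dict[str, SyntenyResult] = {}
    for w in winners:
        rep_results[w.query_id] = SyntenyResult(
            query_id=w.query_id, classification=SYNTENIC,
            subject_id=w.subject_id, support_ratio=w.support_ratio,
            hit=w.hit)
    unassigned = [g.gene_id for g in qc.genome
                  if g.gene_id not in rep_results]
    for r in classify_nonsyntenic_orthologs(unassigned, hits,
                                            identity_min=identity_min,
                                            coverage_min=coverage_min):
        rep_results[r.query_id] = r

    all_results = expand_tandem_synteny(
        sorted(rep_results.values(), key=lambda r: r.query_id),
        qc.redirect, rc.redirect)
    all_results.sort(key=lambda r: (query_genome[r.query_id].chromosome,
                                    query_genome[r.query_id].rank))
    return PipelineOutput(results=all_results, params=params,
                          query_arrays=query_arrays, ref_arrays=ref_arrays,
                          query_collapsed=qc, ref_collapsed=rc,
                          n_candidates=len(candidates),
                          n_potential=len(potentials))
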