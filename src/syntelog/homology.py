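"""Candidate ortholog pairs and per-gene best hits (pipeline step 1).

From the raw all-vs-all hit table, two things are derived:

* a best-hit map per direction — for every gene, its single highest-bitscore
  partner in the other genome (these best hits later act as the "votes" in
  flanking-gene support scoring);
* the candidate pair set — gene pairs that are a best hit in either direction
  or share any hit with e-value below the cut-off (default 1e-20).

Best-hit ranking uses bitscore as the primary key (e-value reporting
precision makes it the less stable key), with ties broken by lower e-value,
higher identity, then lexicographic subject ID for determinism.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Tuple

from .io import HomologyHit

DEFAULT_EVALUE_CUT = 1e-20


def _hit_rank_key(h: HomologyHit) -> tuple:
    # larger tuple = better hit
    return (h.bitscore, -h.evalue, h.pident, _NegStr(h.subject_id))


class _NegStr(str):
    """String whose ordering is reversed, so max() prefers the
    lexicographically smallest subject_id."""
    def __lt__(self, other):  # noqa: D105
        return str.__gt__(self, other)
    def __gt__(self, other):  # noqa: D105
        return str.__lt__(self, other)


@dataclass
class BestHitMap:
    """For each source gene, its single best hit in the target genome."""

    from_genome: str
    to_genome: str
    map: Dict[str, str] = field(default_factory=dict)
    hits: Dict[str, HomologyHit] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.map)

    def pairs(self) -> set:
        return set(self.map.items())


@dataclass
class CandidatePairSet:
    """Deduplicated candidate pairs, each carrying its max-bitscore hit."""

    pairs: Dict[Tuple[str, str], HomologyHit] = field(default_factory=dict)

    def __len__(self) -> int:
        return len(self.pairs)

    def __contains__(self, pair: Tuple[str, str]) -> bool:
        return pair in self.pairs

    def __iter__(self):
        return iter(self.pairs.items())


def flip_hits(hits: Iterable[HomologyHit]) -> List[HomologyHit]:
    """Swap query/subject roles (and coverages) of every hit."""
    return [HomologyHit(query_id=h.subject_id, subject_id=h.query_id,
                        pident=h.pident, aln_length=h.aln_length,
                        evalue=h.evalue, bitscore=h.bitscore,
                        qcov=h.scov, scov=h.qcov)
            for h in hits]


def compute_best_hits(hits: Iterable[HomologyHit], from_genome: str,
                      to_genome: str) -> BestHitMap:
    """Single-direction best hits: per query gene, the subject maximising
    bitscore (ties: lower e-value, higher identity, lexicographic subject)."""
    best = BestHitMap(from_genome=from_genome, to_genome=to_genome)
    best_key: Dict[str, tuple] = {}
    for h in hits:
        key = _hit_rank_key(h)
        if h.query_id not in best_key or key > best_key[h.query_id]:
            best_key[h.query_id] = key
            best.map[h.query_id] = h.subject_id
            best.hits[h.query_id] = h
    return best


def best_hit_per_pair(hits: Iterable[HomologyHit]
                      ) -> Dict[Tuple[str, str], HomologyHit]:
    """Collapse multiple HSPs per gene pair to the single max-bitscore one."""
    out: Dict[Tuple[str, str], HomologyHit] = {}
    for h in hits:
        pair = (h.query_id, h.subject_id)
        prev = out.get(pair)
        if prev is None or _hit_rank_key(h) > _hit_rank_key(prev):
            out[pair] = h
    return out


def select_candidate_pairs(hits: Iterable[HomologyHit],
                           best_qr: BestHitMap, best_rq: BestHitMap,
                           evalue_cut: float = DEFAULT_EVALUE_CUT,
                           *, reciprocal_only: bool = False,
                           ) -> CandidatePairSet:
    """Candidate ortholog pairs: best hit in either direction, or any hit
    with e-value below ``evalue_cut``.

    ``reciprocal_only=True`` switches the best-hit criterion to
    reciprocal-best (stricter; note that in a triplicated query genome three
    copies cannot all be reciprocal bests of one reference gene, so the
    default admits single-direction bests).
    """
    hits = list(hits)
    per_pair = best_hit_per_pair(hits)
    min_evalue: Dict[Tuple[str, str], float] = {}
    for h in hits:
        pair = (h.query_id, h.subject_id)
        if pair not in min_evalue or h.evalue < min_evalue[pair]:
            min_evalue[pair] = h.evalue
    bq = best_qr.pairs()
    br = {(s, q) for q, s in best_rq.map.items()}
    if reciprocal_only:
        best_pairs = bq & br
    else:
        best_pairs = bq | br
    out = CandidatePairSet()
    for pair, hit in per_pair.items():
        if pair in best_pairs or min_evalue[pair] < evalue_cut:
            out.pairs[pair] = hit
    return out
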