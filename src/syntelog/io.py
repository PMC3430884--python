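"""Gene models, homology tables and result tables.

This module establishes the ordinal gene-order coordinate system used by the
whole pipeline: genes on each chromosome are ranked 0..n-1 by ascending start
coordinate, and every notion of "flanking" downstream is measured in rank
units (gene counts), never in base pairs.

Coordinate conventions: GFF3 is 1-based inclusive, BED is 0-based half-open;
both are normalised to 1-based inclusive internally.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Dict, Iterable, Iterator, List, Mapping, Optional, Sequence

import pandas as pd
from gffutils.feature import feature_from_line

log = logging.getLogger(__name__)

#: Column names of 12-column BLAST tabular output (-outfmt 6).
BLAST6_COLUMNS = [
    "qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
    "qstart", "qend", "sstart", "send", "evalue", "bitscore",
]

#: Column order of the result table written by :func:`write_synteny_table`.
RESULT_COLUMNS = [
    "query_gene", "query_chr", "query_rank", "subject_gene", "subject_chr",
    "subject_rank", "support_ratio", "bitscore", "evalue", "class",
    "tandem_expanded",
]


@dataclass(frozen=True)
class Gene:
    """A positioned gene model with an ordinal rank along its chromosome."""

    gene_id: str
    genome_id: str
    chromosome: str
    start: int           # 1-based, inclusive
    end: int             # inclusive
    strand: str = "?"    # '+', '-' or '?'; stored but ignored by the core
    rank: int = -1       # assigned by GenomeIndex

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}")

    @property
    def span(self) -> int:
        return self.end - self.start + 1


@dataclass(frozen=True)
class HomologyHit:
    """One protein-aligner hit between two genes.

    ``qcov``/``scov`` are alignment length divided by the query/subject
    protein length; they are ``None`` when protein lengths are unknown, in
    which case coverage-based classification is disabled downstream.
    """

    query_id: str
    subject_id: str
    pident: float        # percent identity, 0-100
    aln_length: int      # aligned columns (aa)
    evalue: float
    bitscore: float
    qcov: Optional[float] = None
    scov: Optional[float] = None


class GenomeIndex:
    """Ordered gene models of one genome, ranked per chromosome.

    Iterating a chromosome yields genes in ascending rank.  Ties on start
    coordinate are broken by end coordinate, then gene_id, so ranks are a
    deterministic function of the gene set regardless of input line order.
    """

    def __init__(self, genome_id: str, genes: Iterable[Gene]):
        self.genome_id = genome_id
        by_chrom: Dict[str, List[Gene]] = {}
        for g in genes:
            by_chrom.setdefault(g.chromosome, []).append(g)
        self._by_chrom: Dict[str, List[Gene]] = {}
        self._by_id: Dict[str, Gene] = {}
        for chrom in sorted(by_chrom):
            ranked = sorted(by_chrom[chrom],
                            key=lambda g: (g.start, g.end, g.gene_id))
            ranked = [replace(g, genome_id=genome_id, rank=i)
                      for i, g in enumerate(ranked)]
            self._by_chrom[chrom] = ranked
            for g in ranked:
                if g.gene_id in self._by_id:
                    raise ValueError(
                        f"duplicate gene_id {g.gene_id!r} in genome "
                        f"{genome_id!r}")
                self._by_id[g.gene_id] = g

    @property
    def chromosomes(self) -> List[str]:
        return list(self._by_chrom)

    def genes_on(self, chromosome: str) -> List[Gene]:
        return self._by_chrom[chromosome]

    def __len__(self) -> int:
        return len(self._by_id)

    def __iter__(self) -> Iterator[Gene]:
        for chrom in self._by_chrom:
            yield from self._by_chrom[chrom]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._by_id

    def __getitem__(self, gene_id: str) -> Gene:
        return self._by_id[gene_id]

    def get(self, gene_id: str) -> Optional[Gene]:
        return self._by_id.get(gene_id)

    def flanking(self, gene_id: str, k: int) -> List[Gene]:
        """Up to ``k`` genes on each side of ``gene_id`` on its chromosome,
        excluding the gene itself; truncated at chromosome ends."""
        g = self._by_id[gene_id]
        chrom = self._by_chrom[g.chromosome]
        i = g.rank
        return chrom[max(0, i - k):i] + chrom[i + 1:i + 1 + k]


def read_gene_models(path, fmt: str, genome_id: str, *,
                     feature_type: str = "gene",
                     id_attribute: str = "ID",
                     parent_attribute: str = "Parent") -> GenomeIndex:
    """Read gene models from GFF3 or BED into a ranked :class:`GenomeIndex`.

    For GFF3, ``feature_type`` selects which features become genes.  With
    ``feature_type="mRNA"`` multiple isoforms sharing a parent gene are
    reduced to one representative locus spanning the longest isoform, and the
    parent ID becomes the gene_id.
    """
    path = Path(path)
    fmt = fmt.lower()
    if fmt == "gff3":
        genes = _read_gff3(path, genome_id, feature_type, id_attribute,
                           parent_attribute)
    elif fmt == "bed":
        genes = _read_bed(path, genome_id)
    else:
        raise ValueError(f"unknown gene-model format {fmt!r}")
    if not genes:
        raise ValueError(f"{path}: no gene models left after filtering "
                         f"for feature type {feature_type!r}")
    return GenomeIndex(genome_id, genes)


def _read_gff3(path: Path, genome_id: str, feature_type: str,
               id_attribute: str, parent_attribute: str) -> List[Gene]:
    records = []  # (gene_id, chrom, start, end, strand)
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            if len(line.rstrip("\n").split("\t")) != 9:
                raise ValueError(
                    f"{path}: malformed GFF3 at line {lineno}: "
                    f"expected 9 tab-separated fields")
            try:
                feat = feature_from_line(line)
            except Exception as exc:
                raise ValueError(
                    f"{path}: malformed GFF3 at line {lineno}: {exc}") from exc
            if feat.featuretype != feature_type:
                continue
            if feature_type == "mRNA":
                locus = (feat.attributes.get(parent_attribute)
                         or feat.attributes.get(id_attribute))
            else:
                locus = feat.attributes.get(id_attribute)
            if not locus:
                raise ValueError(
                    f"{path}: line {lineno}: feature lacks "
                    f"{id_attribute!r}/{parent_attribute!r} attribute")
            records.append((locus[0], feat.seqid, feat.start, feat.end,
                            feat.strand if feat.strand in "+-" else "?"))

    if feature_type == "mRNA":
        # one representative model per locus: the longest isoform's span
        best: Dict[str, tuple] = {}
        for gene_id, chrom, start, end, strand in records:
            prev = best.get(gene_id)
            if prev is None or (end - start) > (prev[3] - prev[2]):
                best[gene_id] = (gene_id, chrom, start, end, strand)
        records = list(best.values())
    else:
        seen = {}
        for rec in records:
            if rec[0] in seen:
                raise ValueError(
                    f"{path}: duplicate gene_id {rec[0]!r}")
            seen[rec[0]] = rec
        records = list(seen.values())

    return [Gene(gene_id=r[0], genome_id=genome_id, chromosome=r[1],
                 start=r[2], end=r[3], strand=r[4]) for r in records]


def _read_bed(path: Path, genome_id: str) -> List[Gene]:
    try:
        df = pd.read_csv(path, sep="\t", header=None, comment="#")
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] < 4:
        raise ValueError(f"{path}: BED needs at least 4 columns "
                         f"(chrom, start, end, name); got {df.shape[1]}")
    genes = []
    seen = set()
    for row in df.itertuples(index=False):
        chrom, start, end, name = row[0], row[1], row[2], row[3]
        strand = row[5] if len(row) > 5 and row[5] in ("+", "-") else "?"
        if name in seen:
            raise ValueError(f"{path}: duplicate gene_id {name!r}")
        seen.add(name)
        genes.append(Gene(gene_id=str(name), genome_id=genome_id,
                          chromosome=str(chrom), start=int(start) + 1,
                          end=int(end), strand=strand))
    return genes


def read_protein_lengths(path) -> Dict[str, int]:
    """Protein lengths from a FASTA file or a two-column ``id<TAB>length`` TSV."""
    path = Path(path)
    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        from Bio import SeqIO
        return {rec.id: len(rec.seq) for rec in SeqIO.parse(str(path), "fasta")}
    df = pd.read_csv(path, sep="\t", header=None, names=["gene_id", "length"])
    return dict(zip(df["gene_id"].astype(str), df["length"].astype(int)))


def read_homology_table(path, query_genome: GenomeIndex,
                        subject_genome: GenomeIndex,
                        protein_lengths: Optional[Mapping[str, int]] = None,
                        *, max_unresolved_frac: float = 0.05,
                        ) -> List[HomologyHit]:
    """Read a 12-column BLAST tabular file into :class:`HomologyHit` records.

    Hits whose gene IDs do not resolve against the given genomes are dropped
    and counted; more than ``max_unresolved_frac`` unresolved is an error
    (usually a sign that an ID-mapping step is missing).  Self-hits are
    removed when query and subject genome are the same.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep=r"\s+", header=None, comment="#",
                         float_precision="round_trip")
    except pd.errors.EmptyDataError:
        return []
    if df.shape[1] < 12:
        raise ValueError(
            f"{path}: expected 12-column BLAST tabular, got {df.shape[1]} "
            f"columns (line 1)")
    short = df[df.iloc[:, 11].isna()]
    if len(short):
        raise ValueError(
            f"{path}: line {short.index[0] + 1}: fewer than 12 columns")
    df = df.iloc[:, :12]
    df.columns = BLAST6_COLUMNS

    same_genome = query_genome.genome_id == subject_genome.genome_id
    hits: List[HomologyHit] = []
    unresolved = 0
    for row in df.itertuples(index=False):
        q, s = str(row.qseqid), str(row.sseqid)
        if same_genome and q == s:
            continue
        if q not in query_genome or s not in subject_genome:
            unresolved += 1
            continue
        qcov = scov = None
        if protein_lengths is not None:
            qlen = protein_lengths.get(q)
            slen = protein_lengths.get(s)
            if qlen:
                qcov = min(1.0, int(row.length) / qlen)
            if slen:
                scov = min(1.0, int(row.length) / slen)
        hits.append(HomologyHit(
            query_id=q, subject_id=s, pident=float(row.pident),
            aln_length=int(row.length), evalue=float(row.evalue),
            bitscore=float(row.bitscore), qcov=qcov, scov=scov))

    total = len(hits) + unresolved
    if total and unresolved / total > max_unresolved_frac:
        raise ValueError(
            f"{path}: {unresolved}/{total} hits reference unknown gene IDs; "
            f"check that gene-model and homology files use the same IDs "
            f"(or configure an ID mapping)")
    if unresolved:
        log.warning("%s: dropped %d hits with unresolvable gene IDs",
                    path, unresolved)
    return hits


def write_synteny_table(results: Sequence, path,
                        query_genome: GenomeIndex,
                        ref_genome: GenomeIndex) -> None:
    """Write final per-query-gene results as a TSV.

    Rows are ordered by query chromosome then rank, so output is
    deterministic for a given result set.  Floats are serialised with
    ``repr`` so a write→read round-trip is exact.
    """
    rows = []
    for r in results:
        qg = query_genome[r.query_id]
        if r.subject_id is not None:
            sg = ref_genome.get(r.subject_id)
            s_chr = sg.chromosome if sg else ""
            s_rank = sg.rank if sg else ""
        else:
            s_chr = s_rank = ""
        hit = r.hit
        rows.append((
            r.query_id, qg.chromosome, qg.rank,
            r.subject_id if r.subject_id is not None else "",
            s_chr, s_rank,
            repr(r.support_ratio) if r.support_ratio is not None else "",
            repr(hit.bitscore) if hit is not None else "",
            repr(hit.evalue) if hit is not None else "",
            r.classification,
            int(r.tandem_expanded),
        ))
    rows.sort(key=lambda t: (t[1], t[2]))
    with open(path, "w") as fh:
        fh.write("\t".join(RESULT_COLUMNS) + "\n")
        for row in rows:
            fh.write("\t".join(str(x) for x in row) + "\n")


def read_synteny_table(path) -> pd.DataFrame:
    """Read a result table back; inverse of :func:`write_synteny_table`."""
    df = pd.read_csv(path, sep="\t", dtype={"query_gene": str,
                                            "subject_gene": str,
                                            "class": str},
                     keep_default_na=False, float_precision="round_trip")
    for col in ("support_ratio", "bitscore", "evalue"):
        df[col] = pd.to_numeric(df[col].replace("", pd.NA), errors="raise")
    df["subject_rank"] = pd.to_numeric(df["subject_rank"].replace("", pd.NA),
                                       errors="raise")
    return df
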