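"""The two directional homology searches used for gene presence calling.

Direction 1: each reference CDS (nucleotide) against each target genome
assembly, both strands, E <= cutoff.
Direction 2: each target protein against the six-frame translation of the
reference genome, E <= cutoff plus >=50% identity and >=50% query coverage.

Both directions run a k-mer seeded Smith-Waterman (exact-word seeds clustered
by diagonal into candidate windows, full DP within each window), with an
``exhaustive`` flag that aligns against whole contigs instead — the guaranteed
fallback for small inputs and for validating the seeding.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from Bio.Seq import Seq

from .alignment import (LocalAlignment, ScoringScheme, _align_encoded,
                        _kmer_index, _seed_windows, bit_score, evalue,
                        iter_local_hits)
from .seqio import AnnotatedGenome

DEFAULT_MAX_E = 0.01


@dataclass
class HomologyHit:
    """One filtered local-alignment match of a query against a target genome."""

    query_id: str
    target_genome: str
    target_contig: str
    target_span: tuple  # 0-based half-open, nucleotide coordinates
    query_span: tuple  # 0-based half-open on the query as given
    strand_or_frame: str  # '+', '-' or '+0'..'-2'
    raw_score: int
    bit_score: float
    e_value: float
    pct_identity: float
    query_coverage: float

    def __post_init__(self):
        if not (0.0 <= self.pct_identity <= 100.0):
            raise ValueError("pct_identity out of [0, 100]")
        if not (0.0 <= self.query_coverage <= 1.0):
            raise ValueError("query_coverage out of [0, 1]")
        if self.e_value <= 0:
            raise ValueError("e_value must be positive")


@dataclass
class FrameTranslation:
    contig: str
    strand: str  # '+' or '-'
    frame: int  # 0, 1, 2
    protein: str
    contig_length: int

    def nt_span(self, p_start: int, p_end: int) -> tuple:
        """Map a protein span (0-based half-open) back to contig nucleotides."""
        lo = self.frame + 3 * p_start
        hi = self.frame + 3 * p_end
        if self.strand == "+":
            return lo, hi
        return self.contig_length - hi, self.contig_length - lo


def sixframe_translate(contig: str, contig_id: str = "contig") -> list:
    """All six reading-frame translations (genetic code 11), stops as '*'."""
    if len(contig) < 3:
        raise ValueError("contig shorter than one codon")
    out = []
    rc = str(Seq(contig).reverse_complement())
    for strand, seq in (("+", contig), ("-", rc)):
        for frame in range(3):
            sub = seq[frame:]
            sub = sub[:len(sub) - len(sub) % 3]
            prot = str(Seq(sub).translate(table=11))
            out.append(FrameTranslation(contig_id, strand, frame, prot,
                                        len(contig)))
    return out


def _min_score_for_e(max_e: float, m: int, n: int, s: ScoringScheme) -> int:
    """Smallest integer raw score with E <= max_e in an m x n space."""
    if max_e <= 0:
        raise ValueError("max_e must be positive")
    return max(1, math.ceil(math.log(s.K * m * n / max_e) / s.lam))


def _window_hits(q: np.ndarray, t: np.ndarray, s: ScoringScheme,
                 min_score: int, exhaustive: bool) -> list:
    """(LocalAlignment, target offset) pairs for one encoded query/target."""
    if len(q) < 1 or len(t) < 1:
        return []
    out = []
    if exhaustive or len(t) <= 4 * max(len(q), s.word_size):
        for aln in iter_local_hits(q, t, s, min_score):
            out.append((aln, 0))
        return out
    index = _kmer_index(t, s.word_size)
    for lo, hi, dlo, dhi in _seed_windows(q, t, index, s, min_score):
        for aln in iter_local_hits(q, t[lo:hi], s, min_score,
                                   dlo - lo, dhi - lo):
            out.append((aln, lo))
    return out


class GenomeIndex:
    """Precomputed k-mer index of one genome's contigs for repeated queries."""

    def __init__(self, genome: AnnotatedGenome, s: ScoringScheme):
        self.genome = genome
        self.scheme = s
        self.encoded = {cid: s.encode(seq) for cid, seq in genome.contigs.items()}
        self.indexes = {cid: _kmer_index(codes, s.word_size)
                        for cid, codes in self.encoded.items()}


def search_gene_vs_genome(query_id: str, query: str, genome: AnnotatedGenome,
                          s: ScoringScheme, max_e: float = DEFAULT_MAX_E,
                          exhaustive: bool = False,
                          index: GenomeIndex | None = None) -> list:
    """Nucleotide CDS query against a target assembly, both strands.

    Returns HomologyHit records with E <= max_e, sorted by ascending E.
    """
    if s.mode != "nucleotide":
        raise ValueError("nucleotide scoring scheme required")
    if not query:
        return []
    space_n = genome.total_length
    if space_n == 0:
        return []
    min_score = _min_score_for_e(max_e, len(query), space_n, s)
    queries = {"+": s.encode(query),
               "-": s.encode(str(Seq(query).reverse_complement()))}
    hits = []
    for cid, contig in genome.contigs.items():
        t = index.encoded[cid] if index is not None else s.encode(contig)
        for strand, q in queries.items():
            if exhaustive or index is None:
                pairs = _window_hits(q, t, s, min_score, exhaustive)
            else:
                pairs = []
                kidx = index.indexes[cid]
                for lo, hi, dlo, dhi in _seed_windows(q, t, kidx, s,
                                                      min_score):
                    for aln in iter_local_hits(q, t[lo:hi], s, min_score,
                                               dlo - lo, dhi - lo):
                        pairs.append((aln, lo))
            for aln, off in pairs:
                e = evalue(aln.score, len(query), space_n, s)
                if e > max_e:
                    continue
                ts, te = aln.target_span
                qs, qe = aln.query_span
                if strand == "-":  # map back to the forward query
                    qs, qe = len(query) - qe, len(query) - qs
                hits.append(HomologyHit(
                    query_id=query_id, target_genome=genome.strain,
                    target_contig=cid, target_span=(ts + off, te + off),
                    query_span=(qs, qe),
                    strand_or_frame=strand, raw_score=aln.score,
                    bit_score=bit_score(aln.score, s), e_value=e,
                    pct_identity=aln.pct_identity,
                    query_coverage=(qe - qs) / len(query)))
    hits.sort(key=lambda h: (h.e_value, -h.raw_score, h.target_contig,
                             h.target_span))
    return hits


class ReferenceFrameIndex:
    """Six-frame translations of a reference genome plus their k-mer indexes."""

    def __init__(self, reference: AnnotatedGenome, s: ScoringScheme):
        self.reference = reference
        self.scheme = s
        self.frames = []
        for cid, contig in reference.contigs.items():
            self.frames.extend(sixframe_translate(contig, cid))
        self.encoded = [s.encode(fr.protein) for fr in self.frames]
        self.indexes = [_kmer_index(codes, s.word_size)
                        for codes in self.encoded]
        self.space_n = sum(len(fr.protein) for fr in self.frames)


def search_protein_vs_reference(query_id: str, query: str,
                                reference: AnnotatedGenome | ReferenceFrameIndex,
                                s: ScoringScheme | None = None,
                                max_e: float = DEFAULT_MAX_E,
                                min_identity: float = 50.0,
                                min_coverage: float = 0.5,
                                exhaustive: bool = False) -> list:
    """Protein query against the six-frame translated reference genome.

    Hits must pass E <= max_e AND pct_identity >= min_identity AND
    query_coverage >= min_coverage (the direction-2 filters).
    """
    if isinstance(reference, ReferenceFrameIndex):
        ridx = reference
        s = ridx.scheme
    else:
        if s is None:
            s = ScoringScheme.protein()
        ridx = ReferenceFrameIndex(reference, s)
    if s.mode != "protein":
        raise ValueError("protein scoring scheme required")
    if not query:
        return []
    q = s.encode(query)
    min_score = _min_score_for_e(max_e, len(query), ridx.space_n, s)
    hits = []
    for fr, codes, kidx in zip(ridx.frames, ridx.encoded, ridx.indexes):
        if len(codes) == 0:
            continue
        if exhaustive:
            pairs = [(aln, 0) for aln in iter_local_hits(q, codes, s, min_score)]
        else:
            pairs = []
            for lo, hi, dlo, dhi in _seed_windows(q, codes, kidx, s,
                                                  min_score):
                for aln in iter_local_hits(q, codes[lo:hi], s, min_score,
                                           dlo - lo, dhi - lo):
                    pairs.append((aln, lo))
        for aln, off in pairs:
            e = evalue(aln.score, len(query), ridx.space_n, s)
            qs, qe = aln.query_span
            cov = (qe - qs) / len(query)
            if e > max_e or aln.pct_identity < min_identity or cov < min_coverage:
                continue
            ps, pe = aln.target_span[0] + off, aln.target_span[1] + off
            hits.append(HomologyHit(
                query_id=query_id, target_genome=ridx.reference.strain,
                target_contig=fr.contig, target_span=fr.nt_span(ps, pe),
                query_span=(qs, qe),
                strand_or_frame=f"{fr.strand}{fr.frame}",
                raw_score=aln.score, bit_score=bit_score(aln.score, s),
                e_value=e, pct_identity=aln.pct_identity, query_coverage=cov))
    hits.sort(key=lambda h: (h.e_value, -h.raw_score, h.target_contig,
                             h.target_span))
    return hits


def hits_to_tabular(hits: list) -> str:
    """Conventional 12-column tabular layout (outfmt-6 style), one hit per line.

    Columns: query, subject (genome:contig), %identity, alignment length,
    mismatches, gap opens, qstart, qend, sstart, send, evalue, bitscore.
    Coordinates are 1-based inclusive; minus-orientation hits have
    sstart > send.  Mismatch and gap-open counts are not tracked and are
    written as 0.
    """
    lines = []
    for h in hits:
        ts, te = h.target_span
        qs, qe = h.query_span
        if h.strand_or_frame.startswith("-"):
            sstart, send = te, ts + 1
        else:
            sstart, send = ts + 1, te
        cols = [h.query_id, f"{h.target_genome}:{h.target_contig}",
                f"{h.pct_identity:.2f}", "%d" % max(1, te - ts), "0", "0",
                "%d" % (qs + 1), "%d" % qe,
                "%d" % sstart, "%d" % send,
                f"{h.e_value:.3g}", f"{h.bit_score:.1f}"]
        lines.append("\t".join(cols))
    return "\n".join(lines) + ("\n" if lines else "")


def read_hits_tabular(path: str, query_lengths: dict | None = None) -> list:
    """Parse a 12-column tabular hit file back into HomologyHit records.

    The layout does not retain the query length, so query coverage is
    recomputed from ``query_lengths`` (query id -> length) when given and set
    to the filtered-at-search-time placeholder 1.0 otherwise.  Raw scores are
    not retained either and are reconstructed from the bit score.
    """
    hits = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) != 12:
                raise ValueError(f"expected 12 columns, got {len(f)}: {line!r}")
            genome, _, contig = f[1].partition(":")
            qs, qe = int(f[6]) - 1, int(f[7])
            sstart, send = int(f[8]), int(f[9])
            if sstart <= send:
                span, strand = (sstart - 1, send), "+"
            else:
                span, strand = (send - 1, sstart), "-"
            if query_lengths is not None:
                cov = (qe - qs) / query_lengths[f[0]]
            else:
                cov = 1.0
            hits.append(HomologyHit(
                query_id=f[0], target_genome=genome, target_contig=contig,
                target_span=span, query_span=(qs, qe), strand_or_frame=strand,
                raw_score=0, bit_score=float(f[11]), e_value=float(f[10]),
                pct_identity=float(f[2]), query_coverage=min(cov, 1.0)))
    return hits
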