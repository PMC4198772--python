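"""Local alignment and BLAST-style similarity statistics.

This module is the search core the screening pipeline runs on instead of an
external BLAST binary: scored Smith–Waterman local alignment of nucleotide
sequences, six-frame translated protein search of genomic contigs, and the
Karlin–Altschul conversion of raw scores into bit scores and E-values so that
thresholds such as ``E < 1e-5`` or ``bit score >= 100`` are meaningful.

Numeric parity with NCBI BLAST is a non-goal; the statistics use documented
built-in (lambda, K) constants per scoring scheme and are monotone-consistent:
the bit score is affine in the raw score and the E-value strictly decreasing
in the bit score.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Sequence

import numpy as np
from Bio import Align
from Bio.Align import substitution_matrices

from ._seq import revcomp, translate

__all__ = [
    "ScoringScheme",
    "AlignmentResult",
    "dna_scheme",
    "protein_scheme",
    "bit_score",
    "e_value",
    "local_align_nuc",
    "local_align_protein",
    "six_frame_segments",
    "translated_search",
    "hits_to_table",
    "write_hits_tsv",
]


@dataclass(frozen=True)
class ScoringScheme:
    """Alignment scoring parameters plus Karlin–Altschul constants.

    ``lam`` is in nats per raw-score unit and ``k`` is the dimensionless K
    constant; both must be positive.  For nucleotide schemes ``match`` /
    ``mismatch`` are used; for protein schemes ``matrix`` names a Biopython
    substitution matrix (e.g. ``"BLOSUM62"``).  Gap penalties are positive
    costs.
    """

    name: str
    gap_open: float
    gap_extend: float
    lam: float
    k: float
    match: float | None = None
    mismatch: float | None = None
    matrix: str | None = None

    def __post_init__(self) -> None:
        if self.lam <= 0 or self.k <= 0:
            raise ValueError("lambda and k must be positive")
        if (self.matrix is None) == (self.match is None):
            raise ValueError("specify either match/mismatch or a matrix name")


def dna_scheme(match: float = 1, mismatch: float = -2,
               gap_open: float = 5, gap_extend: float = 2) -> ScoringScheme:
    """Default nucleotide scheme (+1/−2, gaps 5/2) with its ungapped constants."""
    return ScoringScheme(name="dna+1-2", match=match, mismatch=mismatch,
                         gap_open=gap_open, gap_extend=gap_extend,
                         lam=1.33, k=0.621)


def protein_scheme(matrix: str = "BLOSUM62",
                   gap_open: float = 11, gap_extend: float = 1) -> ScoringScheme:
    """Default protein scheme: BLOSUM62 with gap open 11 / extend 1."""
    return ScoringScheme(name=matrix, matrix=matrix,
                         gap_open=gap_open, gap_extend=gap_extend,
                         lam=0.267, k=0.041)


@dataclass
class AlignmentResult:
    """One local alignment with BLAST-style statistics.

    Intervals are 1-based inclusive in the *original* (plus-strand) sequence
    coordinates.  ``frame`` is 0 for nucleotide alignments, otherwise a BLAST
    frame in −3..−1, +1..+3; for translated hits the subject interval is in
    genomic nucleotides.  ``coverage`` is the aligned fraction of the query.
    """

    query_id: str
    subject_id: str
    q_start: int
    q_end: int
    s_start: int
    s_end: int
    strand: str
    frame: int
    raw_score: float
    bit_score: float
    evalue: float
    identity: float
    coverage: float
    q_aln: str
    s_aln: str
    mismatches: int = 0
    gap_opens: int = 0

    @property
    def s_interval(self) -> tuple[int, int]:
        return (self.s_start, self.s_end)

    def subject_segment(self) -> str:
        """Ungapped aligned subject segment (aa for translated hits)."""
        return self.s_aln.replace("-", "")


def bit_score(raw: float, scheme: ScoringScheme) -> float:
    """Normalised score in bits: S' = (lambda*S - ln K) / ln 2."""
    return (scheme.lam * raw - math.log(scheme.k)) / math.log(2)


def e_value(bits: float, m: int, n: int) -> float:
    """Expected chance hits in an m x n search space: E = m*n*2^(-bits)."""
    if m < 1 or n < 1:
        raise ValueError("search-space dimensions must be >= 1")
    # 2^(-bits) underflows for strong hits; go through log space.
    log10_e = math.log10(m) + math.log10(n) - bits * math.log10(2)
    return 10.0 ** log10_e if log10_e > -320 else 0.0


def _nuc_matrix(scheme: ScoringScheme) -> substitution_matrices.Array:
    # N is scored as a mismatch against everything, including itself.
    alphabet = "ACGTN"
    m = substitution_matrices.Array(alphabet, dims=2)
    for a in alphabet:
        for b in alphabet:
            if a == b and a != "N":
                m[a, b] = scheme.match
            else:
                m[a, b] = scheme.mismatch
    return m


def _make_aligner(scheme: ScoringScheme, mode: str = "local") -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = mode
    if scheme.matrix is not None:
        aligner.substitution_matrix = substitution_matrices.load(scheme.matrix)
    else:
        aligner.substitution_matrix = _nuc_matrix(scheme)
    aligner.open_gap_score = -(scheme.gap_open + scheme.gap_extend)
    aligner.extend_gap_score = -scheme.gap_extend
    return aligner


def _stats_from_alignment(aln, query: str, scheme: ScoringScheme,
                          m: int | None = None, n: int | None = None):
    q_aln, s_aln = str(aln[0]), str(aln[1])
    # "N" is an ambiguity code only in nucleotide space (it is asparagine
    # in proteins), so the never-matches rule is nucleotide-specific
    ambiguous = "N" if scheme.matrix is None else ""
    matches = mismatches = gap_opens = 0
    in_gap = False
    for qa, sa in zip(q_aln, s_aln):
        if qa == "-" or sa == "-":
            if not in_gap:
                gap_opens += 1
            in_gap = True
        else:
            in_gap = False
            if qa == sa and qa != ambiguous:
                matches += 1
            else:
                mismatches += 1
    ncols = len(q_aln)
    identity = matches / ncols if ncols else 0.0
    qs, qe = aln.aligned[0][0][0], aln.aligned[0][-1][-1]
    coverage = (qe - qs) / len(query)
    bits = bit_score(aln.score, scheme)
    ev = e_value(bits, m or len(query), n or len(str(aln.sequences[1])))
    return q_aln, s_aln, identity, coverage, mismatches, gap_opens, bits, ev


def _zero_result(a: str, scheme: ScoringScheme, query_id: str,
                 subject_id: str, m: int | None, n: int | None,
                 n_len: int) -> AlignmentResult:
    bits = bit_score(0.0, scheme)
    return AlignmentResult(
        query_id=query_id, subject_id=subject_id, q_start=0, q_end=0,
        s_start=0, s_end=0, strand="+", frame=0, raw_score=0.0,
        bit_score=bits, evalue=e_value(bits, m or len(a), n or n_len),
        identity=0.0, coverage=0.0, q_aln="", s_aln="")


def local_align_nuc(a: str, b: str, scheme: ScoringScheme | None = None,
                    query_id: str = "query", subject_id: str = "subject",
                    m: int | None = None, n: int | None = None) -> AlignmentResult:
    """Optimal Smith–Waterman local alignment of two nucleotide sequences.

    ``N`` never counts as a match.  ``m``/``n`` override the search-space
    sizes used for the E-value (e.g. the full database length).  A pair
    with no positively scoring local alignment yields a zero-score result.
    """
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    scheme = scheme or dna_scheme()
    aligner = _make_aligner(scheme)
    try:
        aln = next(iter(aligner.align(a.upper(), b.upper())))
    except StopIteration:
        return _zero_result(a, scheme, query_id, subject_id, m, n, len(b))
    (q_aln, s_aln, identity, coverage,
     mismatches, gap_opens, bits, ev) = _stats_from_alignment(aln, a, scheme, m, n)
    return AlignmentResult(
        query_id=query_id, subject_id=subject_id,
        q_start=int(aln.aligned[0][0][0]) + 1, q_end=int(aln.aligned[0][-1][-1]),
        s_start=int(aln.aligned[1][0][0]) + 1, s_end=int(aln.aligned[1][-1][-1]),
        strand="+", frame=0, raw_score=float(aln.score), bit_score=bits,
        evalue=ev, identity=identity, coverage=coverage,
        q_aln=q_aln, s_aln=s_aln, mismatches=mismatches, gap_opens=gap_opens)


def local_align_protein(a: str, b: str, scheme: ScoringScheme | None = None,
                        query_id: str = "query", subject_id: str = "subject",
                        m: int | None = None, n: int | None = None) -> AlignmentResult:
    """Optimal local alignment of two protein sequences under ``scheme``."""
    if not a or not b:
        raise ValueError("sequences must be non-empty")
    scheme = scheme or protein_scheme()
    aligner = _make_aligner(scheme)
    try:
        aln = next(iter(aligner.align(a.upper(), b.upper())))
    except StopIteration:
        return _zero_result(a, scheme, query_id, subject_id, m, n, len(b))
    (q_aln, s_aln, identity, coverage,
     mismatches, gap_opens, bits, ev) = _stats_from_alignment(aln, a, scheme, m, n)
    return AlignmentResult(
        query_id=query_id, subject_id=subject_id,
        q_start=int(aln.aligned[0][0][0]) + 1, q_end=int(aln.aligned[0][-1][-1]),
        s_start=int(aln.aligned[1][0][0]) + 1, s_end=int(aln.aligned[1][-1][-1]),
        strand="+", frame=0, raw_score=float(aln.score), bit_score=bits,
        evalue=ev, identity=identity, coverage=coverage,
        q_aln=q_aln, s_aln=s_aln, mismatches=mismatches, gap_opens=gap_opens)


def six_frame_segments(contig: str, min_aa: int = 15):
    """Translate a contig in all six frames and segment at stop codons.

    Yields ``(frame, aa_segment, genomic_start)`` where ``genomic_start`` is
    the 1-based plus-strand position of the first nucleotide of the segment's
    first codon (for minus frames, of its last codon's last nucleotide the
    segment still maps to a plus-strand interval; see `_map_back`).  Frames
    follow the BLAST convention +1..+3, −1..−3.
    """
    if len(contig) < 3:
        raise ValueError("contig shorter than 3 nt cannot be translated")
    contig = contig.upper()
    rc = revcomp(contig)
    for frame_sign, seq in ((1, contig), (-1, rc)):
        for off in range(3):
            frame = frame_sign * (off + 1)
            aa = translate(seq[off:])
            pos = 0
            for seg in aa.split("*"):
                if len(seg) >= min_aa:
                    yield frame, seg, off, pos
                pos += len(seg) + 1


def _map_back(frame: int, off: int, aa_start0: int, aa_len: int,
              contig_len: int) -> tuple[int, int, str]:
    """Map an aa interval in a frame translation to 1-based genomic coords."""
    nt_start0 = off + 3 * aa_start0
    nt_end0 = nt_start0 + 3 * aa_len - 1
    if frame > 0:
        return nt_start0 + 1, nt_end0 + 1, "+"
    # coordinates were on the reverse complement
    s = contig_len - 1 - nt_end0
    e = contig_len - 1 - nt_start0
    return s + 1, e + 1, "-"


def translated_search(bait: str, contig: str, scheme: ScoringScheme | None = None,
                      query_id: str = "bait", subject_id: str = "contig",
                      min_segment_aa: int = 15, min_raw: float = 40,
                      db_len: int | None = None) -> list[AlignmentResult]:
    """tblastn-style search: protein bait vs all six reading frames of a contig.

    The translation of each frame is segmented at stop codons; the bait is
    locally aligned to every segment of at least ``min_segment_aa`` residues.
    Hits with raw score below ``min_raw`` are dropped.  Subject coordinates
    are mapped back to 1-based plus-strand genomic nucleotides.
    """
    if len(bait) < 30:
        raise ValueError("bait must be at least 30 aa")
    scheme = scheme or protein_scheme()
    aligner = _make_aligner(scheme)
    n_space = db_len if db_len is not None else len(contig)
    hits: list[AlignmentResult] = []
    for frame, seg, off, seg_aa0 in six_frame_segments(contig, min_segment_aa):
        score = aligner.score(bait, seg)
        if score < min_raw:
            continue
        aln = next(iter(aligner.align(bait, seg)))
        (q_aln, s_aln, identity, coverage,
         mismatches, gap_opens, bits, ev) = _stats_from_alignment(
            aln, bait, scheme, len(bait), n_space)
        s_aa0 = int(aln.aligned[1][0][0])
        s_aa_len = int(aln.aligned[1][-1][-1]) - s_aa0
        gs, ge, strand = _map_back(frame, off, seg_aa0 + s_aa0, s_aa_len, len(contig))
        hits.append(AlignmentResult(
            query_id=query_id, subject_id=subject_id,
            q_start=int(aln.aligned[0][0][0]) + 1, q_end=int(aln.aligned[0][-1][-1]),
            s_start=gs, s_end=ge, strand=strand, frame=frame,
            raw_score=float(aln.score), bit_score=bits, evalue=ev,
            identity=identity, coverage=coverage, q_aln=q_aln, s_aln=s_aln,
            mismatches=mismatches, gap_opens=gap_opens))
    hits.sort(key=lambda h: (-h.bit_score, h.s_start, h.frame))
    return hits


_TSV_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch", "gapopen",
                "qstart", "qend", "sstart", "send", "evalue", "bitscore", "frame"]


def hits_to_table(hits: Iterable[AlignmentResult]):
    """Hits as a pandas DataFrame in BLAST outfmt-6-like column order."""
    rows = []
    for h in hits:
        rows.append({
            "qseqid": h.query_id, "sseqid": h.subject_id,
            "pident": round(100 * h.identity, 2), "length": len(h.q_aln),
            "mismatch": h.mismatches, "gapopen": h.gap_opens,
            "qstart": h.q_start, "qend": h.q_end,
            "sstart": h.s_start, "send": h.s_end,
            "evalue": h.evalue, "bitscore": round(h.bit_score, 1),
            "frame": h.frame,
        })
    import pandas as pd
    return pd.DataFrame(rows, columns=_TSV_COLUMNS)


def write_hits_tsv(hits: Iterable[AlignmentResult], path) -> None:
    hits_to_table(hits).to_csv(path, sep="\t", index=False)
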