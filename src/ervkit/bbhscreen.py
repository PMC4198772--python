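"""Best-bidirectional-hit (BBH) screening for endogenous retroviral fragments.

The screen runs in two passes over a genome:

1. *forward*: every lentiviral Pol bait is searched against all six reading
   frames of every contig (tblastn-style); hits with E-value below the cutoff
   (default 1e-5) survive.  Baits attributed to a previously described
   endogenous element of the screened host species are excluded up front.
2. *backward*: the translated genomic segment of each surviving hit is
   aligned against a Pol panel spanning all retroviral genera (blastp-style);
   the panel entry with the best bit score classifies the hit.  A hit is a
   lentiviral candidate iff its backward best falls in the lentivirus genus;
   candidates with backward bit score below 100 are flagged low-confidence,
   mirroring the empirical false-positive band of genome-wide screens.

Overlapping hits on the same contig and strand are merged into loci, each
represented by its best-scoring record.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

from .panels import BaitPanel, PanelEntry
from .seqsearch import (AlignmentResult, ScoringScheme, local_align_protein,
                        protein_scheme, translated_search)

__all__ = ["ScreenConfig", "BBHRecord", "Locus", "ScreenReport",
           "forward_scan", "backward_classify", "screen_genome"]


@dataclass
class ScreenConfig:
    e_cut: float = 1e-5
    bit_threshold: float = 100.0
    target_genus: str = "lentivirus"
    min_backward_aa: int = 10
    host_species: str | None = None
    # hits this close on the same strand merge into one locus: nonsense
    # mutations segment one ancient ORF into several abutting hits
    merge_gap: int = 300
    scheme: ScoringScheme = field(default_factory=protein_scheme)


@dataclass
class BBHRecord:
    """A forward hit plus its backward classification."""

    hit: AlignmentResult
    backward_name: str | None
    backward_genus: str | None
    backward_bits: float
    backward_aln_len: int
    is_lentiviral_candidate: bool
    confidence: str                     # "high" | "low"


@dataclass
class Locus:
    """Merged per-locus record: overlapping same-strand hits collapsed."""

    contig: str
    start: int
    end: int
    strand: str
    best: BBHRecord
    n_hits: int
    hit_ids: list[str]

    @property
    def is_lentiviral_candidate(self) -> bool:
        return self.best.is_lentiviral_candidate


@dataclass
class ScreenReport:
    loci: list[Locus]
    n_forward_hits: int
    config: ScreenConfig

    @property
    def candidates(self) -> list[Locus]:
        return [l for l in self.loci if l.is_lentiviral_candidate]

    def summary(self) -> dict:
        return {
            "n_forward_hits": self.n_forward_hits,
            "n_loci": len(self.loci),
            "n_candidates": len(self.candidates),
            "n_high_confidence": sum(1 for l in self.candidates
                                     if l.best.confidence == "high"),
            "best_bit_score": max((l.best.backward_bits for l in self.loci),
                                  default=0.0),
        }


def forward_scan(contigs: dict[str, str], baits: BaitPanel,
                 e_cut: float = 1e-5, host_species: str | None = None,
                 scheme: ScoringScheme | None = None) -> list[AlignmentResult]:
    """Translated search of every bait against every contig; keep E < e_cut.

    The E-value search space is the bait length times the total genome
    length, so the cutoff behaves consistently across contigs.
    """
    entries = baits.baits_for(host_species)
    if not entries:
        raise ValueError("bait panel is empty after exclusion")
    db_len = sum(len(s) for s in contigs.values())
    scheme = scheme or protein_scheme()
    hits = []
    for cname, cseq in contigs.items():
        for bait in entries:
            for h in translated_search(bait.sequence, cseq, scheme,
                                       query_id=bait.name, subject_id=cname,
                                       db_len=db_len):
                if h.evalue < e_cut:
                    hits.append(h)
    hits.sort(key=lambda h: (-h.bit_score, h.subject_id, h.s_start))
    return hits


def backward_classify(hit: AlignmentResult, panel: list[PanelEntry],
                      bit_threshold: float = 100.0,
                      target_genus: str = "lentivirus",
                      min_backward_aa: int = 10,
                      scheme: ScoringScheme | None = None) -> BBHRecord:
    """Classify a forward hit by its best backward match in the Pol panel.

    Tie-break on equal bit scores: longer alignment, then lexicographically
    smaller panel name — deterministic.
    """
    segment = hit.subject_segment()
    if len(segment) < min_backward_aa:
        warnings.warn(
            f"hit segment of {len(segment)} aa is too short to classify",
            stacklevel=2)
        return BBHRecord(hit=hit, backward_name=None, backward_genus=None,
                         backward_bits=0.0, backward_aln_len=0,
                         is_lentiviral_candidate=False, confidence="low")
    scheme = scheme or protein_scheme()
    best = None
    for entry in panel:
        aln = local_align_protein(segment, entry.sequence, scheme,
                                  query_id="hit_segment", subject_id=entry.name)
        key = (-aln.bit_score, -len(aln.q_aln), entry.name)
        if best is None or key < best[0]:
            best = (key, entry, aln)
    _, entry, aln = best
    return BBHRecord(
        hit=hit, backward_name=entry.name, backward_genus=entry.genus,
        backward_bits=aln.bit_score, backward_aln_len=len(aln.q_aln),
        is_lentiviral_candidate=(entry.genus == target_genus),
        confidence="high" if aln.bit_score >= bit_threshold else "low")


def _merge_loci(records: list[BBHRecord], merge_gap: int = 300) -> list[Locus]:
    """Collapse same-contig, same-strand records whose genomic intervals
    overlap or sit within ``merge_gap`` nt of each other."""
    loci: list[Locus] = []
    by_key: dict[tuple[str, str], list[BBHRecord]] = {}
    for r in records:
        by_key.setdefault((r.hit.subject_id, r.hit.strand), []).append(r)
    for (contig, strand), recs in sorted(by_key.items()):
        recs.sort(key=lambda r: (r.hit.s_start, r.hit.s_end))
        cluster: list[BBHRecord] = []
        cur_end = -1
        for r in recs:
            if cluster and r.hit.s_start > cur_end + merge_gap:
                loci.append(_locus_from(contig, strand, cluster))
                cluster = []
                cur_end = -1
            cluster.append(r)
            cur_end = max(cur_end, r.hit.s_end)
        if cluster:
            loci.append(_locus_from(contig, strand, cluster))
    loci.sort(key=lambda l: (-l.best.hit.bit_score, l.contig, l.start))
    return loci


def _locus_from(contig: str, strand: str, cluster: list[BBHRecord]) -> Locus:
    best = max(cluster, key=lambda r: (r.hit.bit_score, -r.hit.s_start))
    return Locus(contig=contig,
                 start=min(r.hit.s_start for r in cluster),
                 end=max(r.hit.s_end for r in cluster),
                 strand=strand, best=best, n_hits=len(cluster),
                 hit_ids=[r.hit.query_id for r in cluster])


def screen_genome(contigs: dict[str, str], baits: BaitPanel,
                  panel: list[PanelEntry],
                  config: ScreenConfig | None = None) -> ScreenReport:
    """Run the full BBH screen on a contig set and return merged loci."""
    config = config or ScreenConfig()
    if not contigs:
        return ScreenReport(loci=[], n_forward_hits=0, config=config)
    hits = forward_scan(contigs, baits, config.e_cut, config.host_species,
                        config.scheme)
    records = [backward_classify(h, panel, config.bit_threshold,
                                 config.target_genus, config.min_backward_aa,
                                 config.scheme)
               for h in hits]
    return ScreenReport(loci=_merge_loci(records, config.merge_gap),
                        n_forward_hits=len(hits), config=config)
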