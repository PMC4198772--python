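"""Structural calling of proviruses, solo LTRs and empty integration sites.

A full provirus is recognised as a pair of similar direct repeats (the LTRs)
separated by an internal span of plausible size, anchored near a homology
hit.  Boundaries are refined jointly: candidate outer edges are scored by
repeat similarity *plus* agreement of the flanking target-site duplication
(TSD), because a matching TSD is the signature that both LTRs belong to the
original integrating element.  Solo LTRs are found by scanning a reference
LTR across the genome and keeping hits that pass the classical three-filter
rule (E-value, identity, query coverage), and putative insertions can be
checked against orthologous sequence for their empty pre-integration form.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import edlib

from ._seq import revcomp
from .seqsearch import ScoringScheme, dna_scheme, e_value, local_align_nuc

__all__ = ["StructConfig", "SoloFilters", "ProvirusCall", "SoloLTRCall",
           "TsdResult", "find_ltr_pairs", "detect_tsd", "scan_solo_ltrs",
           "check_preintegration_site"]


@dataclass
class StructConfig:
    """Provirus-calling parameters.

    The internal-span window brackets a ~10 kb provirus with indel slack;
    the minimum LTR-pair identity of 0.75 leaves margin for elements much
    older than the oldest that can still be dated reliably.
    """

    min_ltr: int = 100
    max_ltr: int = 1000
    min_ltr_identity: float = 0.75
    span_range: tuple[int, int] = (4000, 13000)
    window_half: int = 16500
    seed_k: int = 13
    min_seeds: int = 5
    snap_range: int = 15
    len_slack: int = 35
    tsd_bonus_weight: float = 1.0
    tsd_range: tuple[int, int] = (4, 6)
    tsd_allow_mismatch: bool = True
    scheme: ScoringScheme = field(default_factory=dna_scheme)


@dataclass
class SoloFilters:
    """The three conjunctive solo-LTR acceptance filters."""

    evalue_max: float = 1e-100
    min_identity: float = 0.80
    min_coverage: float = 0.50


@dataclass
class TsdResult:
    motif: str
    mismatches: int
    length: int


@dataclass
class ProvirusCall:
    contig: str
    start: int                       # 1-based inclusive, whole element
    end: int
    strand: str
    ltr5_interval: tuple[int, int]
    ltr3_interval: tuple[int, int]
    ltr_identity: float
    tsd: TsdResult | None = None
    source_hits: list[str] = field(default_factory=list)

    @property
    def internal_interval(self) -> tuple[int, int]:
        return (self.ltr5_interval[1] + 1, self.ltr3_interval[0] - 1)


@dataclass
class SoloLTRCall:
    contig: str
    start: int
    end: int
    strand: str
    identity_to_reference: float
    coverage_of_reference: float
    evalue: float
    aligned_len: int
    raw_score: float
    tsd: TsdResult | None = None


# ---------------------------------------------------------------------------
# TSD detection
# ---------------------------------------------------------------------------

def detect_tsd(contig: str, start: int, end: int,
               k_range: tuple[int, int] = (4, 6),
               allow_mismatch: bool = True) -> TsdResult | None:
    """Longest k in ``k_range`` whose copies flank the element [start, end].

    Perfect duplications are preferred at any length; with
    ``allow_mismatch`` a single mismatch is tolerated ("almost perfect"),
    again longest-first.  Returns None when no duplication is found or the
    element touches a contig edge.
    """
    kmin, kmax = k_range
    if start - 1 < kmin or end + kmin > len(contig):
        warnings.warn("element too close to contig edge for TSD detection",
                      stacklevel=2)
        return None
    for max_mm in ([0, 1] if allow_mismatch else [0]):
        for k in range(kmax, kmin - 1, -1):
            if start - 1 < k or end + k > len(contig):
                continue
            left = contig[start - 1 - k:start - 1]
            right = contig[end:end + k]
            mm = sum(a != b for a, b in zip(left, right))
            if mm <= max_mm:
                return TsdResult(motif=left, mismatches=mm, length=k)
    return None


# ---------------------------------------------------------------------------
# LTR-pair (full provirus) calling
# ---------------------------------------------------------------------------

def _seed_offset_clusters(window: str, cfg: StructConfig) -> list[tuple[int, int, int]]:
    """Direct-repeat seed detection: cluster k-mer pair offsets.

    Returns (offset, first_pos_min, first_pos_max) per cluster with enough
    seeds, most-supported first.  Positions are 0-based in ``window``.
    """
    k = cfg.seed_k
    lo = cfg.span_range[0] + cfg.min_ltr
    hi = cfg.span_range[1] + cfg.max_ltr
    occ: dict[str, list[int]] = {}
    for i in range(len(window) - k + 1):
        occ.setdefault(window[i:i + k], []).append(i)
    pairs: list[tuple[int, int]] = []           # (offset, first_pos)
    for positions in occ.values():
        if len(positions) > 25:                 # low-complexity guard
            continue
        for a in range(len(positions)):
            for b in range(a + 1, len(positions)):
                d = positions[b] - positions[a]
                if lo <= d <= hi:
                    pairs.append((d, positions[a]))
    pairs.sort()
    clusters = []
    i = 0
    while i < len(pairs):
        j = i
        while j + 1 < len(pairs) and pairs[j + 1][0] - pairs[i][0] <= 60:
            j += 1
        group = pairs[i:j + 1]
        if len(group) >= cfg.min_seeds:
            # one offset band can hold several distinct repeat pairs (e.g.
            # different solo LTRs at similar spacings): split by position
            by_pos = sorted(group, key=lambda dp: dp[1])
            sub: list[tuple[int, int]] = []
            for d, p_ in by_pos + [(0, 10 ** 12)]:
                if sub and p_ - sub[-1][1] > 500:
                    if len(sub) >= cfg.min_seeds:
                        offs = sorted(dd for dd, _ in sub)
                        ps = [pp for _, pp in sub]
                        clusters.append((len(sub), offs[len(offs) // 2],
                                         min(ps), max(ps) + k))
                    sub = []
                sub.append((d, p_))
        i = j + 1
    clusters.sort(reverse=True)
    return [(off, lo_p, hi_p) for _, off, lo_p, hi_p in clusters]


def _edit_dist(a: str, b: str) -> int:
    return edlib.align(a, b, task="distance")["editDistance"]


def _refine_pair(contig: str, s5: int, e3: int, l_est: int,
                 cfg: StructConfig) -> tuple[int, int, int, float]:
    """Jointly snap outer boundaries and the LTR length.

    Candidate (ds, de, L) triples are scored by repeat similarity
    (L − edit distance between the two implied LTR copies) plus a bonus for
    a perfect flanking TSD; a matching TSD pins both outer edges.  Returns
    0-based (s5, e3_inclusive, L, identity).
    """
    kmin, kmax = cfg.tsd_range
    best = None
    for ds in range(-cfg.snap_range, cfg.snap_range + 1):
        a = s5 + ds
        if a < kmax:
            continue
        for de in range(-cfg.snap_range, cfg.snap_range + 1):
            b = e3 + de
            if b + kmax >= len(contig):
                continue
            # perfect-duplication bonus only: mismatch-tolerant credit lets
            # chance motifs outbid the true boundary at zero divergence
            tsd_score = 0.0
            tsd_k = 0
            for k in range(kmax, kmin - 1, -1):
                if contig[a - k:a] == contig[b + 1:b + 1 + k]:
                    tsd_k = k
                    tsd_score = cfg.tsd_bonus_weight * k
                    break
            best_l = None
            for L in range(max(cfg.min_ltr, l_est - cfg.len_slack),
                           min(cfg.max_ltr, l_est + cfg.len_slack) + 1):
                if a + L > b + 1 - L:      # the two copies must not cross
                    break
                dist = _edit_dist(contig[a:a + L], contig[b + 1 - L:b + 1])
                sim = L - 3 * dist      # match +1, mismatch/indel −2
                if best_l is None or sim > best_l[0]:
                    best_l = (sim, L, dist)
            if best_l is None:
                continue
            sim, L, dist = best_l
            key = (sim + tsd_score, tsd_k, -(abs(ds) + abs(de)), -abs(ds), -abs(de))
            if best is None or key > best[0]:
                best = (key, a, b, L, dist)
    if best is None:
        raise ValueError("no boundary candidate")
    _, a, b, L, dist = best
    identity = 1.0 - dist / L
    return a, b, L, identity


def find_ltr_pairs(contig: str, anchor, cfg: StructConfig | None = None,
                   contig_name: str = "contig", strand_hint: str = "+",
                   source_hits: list[str] | None = None) -> list[ProvirusCall]:
    """Call full proviruses around an anchor locus.

    ``anchor`` is a 1-based position or (start, end) interval from screening
    or the user.  A window around it is searched for a pair of similar
    direct repeats separated by an internal span inside the configured
    range; calls are returned best-identity first.  No pair found is an
    empty list, not an error.
    """
    cfg = cfg or StructConfig()
    if isinstance(anchor, (tuple, list)):
        anchor_lo, anchor_hi = int(anchor[0]), int(anchor[1])
    else:
        anchor_lo = anchor_hi = int(anchor)
    center = (anchor_lo + anchor_hi) // 2
    ws = max(0, center - 1 - cfg.window_half)
    we = min(len(contig), center - 1 + cfg.window_half)
    window = contig[ws:we]
    calls: list[ProvirusCall] = []
    seen: set[tuple[int, int]] = set()
    candidates = []
    for off, p_lo, p_hi in _seed_offset_clusters(window, cfg):
        # The anchor is a protein-homology locus inside the element, so the
        # internal span between the two repeat copies must cover it; this
        # rejects pairs of nearby solo LTRs masquerading as a provirus.
        approx_internal = (ws + p_hi - 200, ws + p_lo + off + 200)
        if anchor_hi < approx_internal[0] or anchor_lo > approx_internal[1]:
            continue
        candidates.append((off, p_lo, p_hi))
    for off, p_lo, p_hi in candidates[:6]:
        pad = 600
        a_lo = max(0, p_lo - pad)
        a_hi = min(len(window), p_hi + pad)
        region_a = window[a_lo:a_hi]
        b_lo = max(0, a_lo + off)
        b_hi = min(len(window), a_hi + off)
        region_b = window[b_lo:b_hi]
        if len(region_a) < cfg.min_ltr or len(region_b) < cfg.min_ltr:
            continue
        aln = local_align_nuc(region_a, region_b, cfg.scheme)
        s5 = ws + a_lo + aln.q_start - 1          # 0-based genomic
        e3 = ws + b_lo + aln.s_end - 1            # 0-based inclusive
        l_est = aln.q_end - aln.q_start + 1
        if l_est < cfg.min_ltr // 2:
            continue
        try:
            a, b, L, identity = _refine_pair(contig, s5, e3,
                                             min(l_est, cfg.max_ltr), cfg)
        except ValueError:
            continue
        ltr5 = (a + 1, a + L)
        ltr3 = (b + 1 - L + 1, b + 1)
        span = ltr3[0] - ltr5[1] - 1
        if not (cfg.span_range[0] <= span <= cfg.span_range[1]):
            continue
        if anchor_hi < ltr5[1] or anchor_lo > ltr3[0]:
            continue  # anchor must fall inside the internal region
        if L < cfg.min_ltr or identity < cfg.min_ltr_identity:
            continue
        if (ltr5[0], ltr3[1]) in seen:
            continue
        seen.add((ltr5[0], ltr3[1]))
        tsd = detect_tsd(contig, ltr5[0], ltr3[1], cfg.tsd_range,
                         cfg.tsd_allow_mismatch)
        calls.append(ProvirusCall(
            contig=contig_name, start=ltr5[0], end=ltr3[1],
            strand=strand_hint, ltr5_interval=ltr5, ltr3_interval=ltr3,
            ltr_identity=identity, tsd=tsd,
            source_hits=list(source_hits or [])))
    # TSD agreement is the signature that both repeats belong to one
    # integrated element, so TSD-supported calls rank ahead of bare pairs
    calls.sort(key=lambda c: (c.tsd is None, -c.ltr_identity))
    return calls


# ---------------------------------------------------------------------------
# solo-LTR scanning
# ---------------------------------------------------------------------------

def _windows(length: int, window: int, step: int):
    if length <= window:
        yield 0, length
        return
    for s in range(0, length - window + step, step):
        yield s, min(length, s + window)


def scan_solo_ltrs(contigs: dict[str, str], reference_ltr: str,
                   filters: SoloFilters | None = None,
                   exclude: dict[str, list[tuple[int, int]]] | None = None,
                   scheme: ScoringScheme | None = None,
                   window: int = 2000, step: int = 1000,
                   with_tsd: bool = True) -> list[SoloLTRCall]:
    """Scan a reference LTR across a genome and apply the three filters.

    Every kept call satisfies ``E < evalue_max`` AND ``identity >=
    min_identity`` AND reference (query) coverage ``>= min_coverage``; hits
    overlapping an excluded interval (e.g. the LTRs of called full
    proviruses) are dropped.  Both strands are searched.  Output is sorted
    by (contig, start) and invariant to contig order.
    """
    if len(reference_ltr) < 100:
        raise ValueError("reference LTR must be >= 100 nt")
    filters = filters or SoloFilters()
    scheme = scheme or dna_scheme()
    db_len = sum(len(s) for s in contigs.values())
    queries = {"+": reference_ltr.upper(), "-": revcomp(reference_ltr.upper())}
    # conservative raw-score prefilter for a hit that could still pass
    m = scheme.match if scheme.match is not None else 1
    mm = scheme.mismatch if scheme.mismatch is not None else -2
    prefilter = 0.85 * filters.min_coverage * len(reference_ltr) * (
        filters.min_identity * m + (1 - filters.min_identity) * mm)
    from .seqsearch import _make_aligner  # aligner reused across windows
    aligner = _make_aligner(scheme)

    raw: list[SoloLTRCall] = []
    for cname in sorted(contigs):
        cseq = contigs[cname].upper()
        for wstart, wend in _windows(len(cseq), window, step):
            sub = cseq[wstart:wend]
            for strand, query in queries.items():
                if aligner.score(query, sub) < prefilter:
                    continue
                res = local_align_nuc(query, sub, scheme,
                                      m=len(reference_ltr), n=db_len)
                raw.append(SoloLTRCall(
                    contig=cname, start=wstart + res.s_start,
                    end=wstart + res.s_end, strand=strand,
                    identity_to_reference=res.identity,
                    coverage_of_reference=res.coverage,
                    evalue=res.evalue, aligned_len=len(res.q_aln),
                    raw_score=res.raw_score))
    # dedupe overlapping window hits: best raw score per overlap cluster
    raw.sort(key=lambda c: (c.contig, c.start, c.end))
    merged: list[SoloLTRCall] = []
    for c in raw:
        if merged and merged[-1].contig == c.contig and c.start <= merged[-1].end:
            if c.raw_score > merged[-1].raw_score:
                merged[-1] = c
        else:
            merged.append(c)
    out = []
    for c in merged:
        if exclude:
            skip = any(c.start <= b and c.end >= a
                       for a, b in exclude.get(c.contig, []))
            if skip:
                continue
        if (c.evalue < filters.evalue_max
                and c.identity_to_reference >= filters.min_identity
                and c.coverage_of_reference >= filters.min_coverage):
            if with_tsd:
                c.tsd = detect_tsd(contigs[c.contig], c.start, c.end)
            out.append(c)
    return out


# ---------------------------------------------------------------------------
# empty pre-integration site check
# ---------------------------------------------------------------------------

def check_preintegration_site(flank5: str, flank3: str, candidate_region: str,
                              scheme: ScoringScheme | None = None,
                              max_empty_gap: int = 25,
                              min_occupied_gap: int = 100,
                              min_score_frac: float = 0.3) -> str:
    """Classify an orthologous region as empty / occupied / ambiguous.

    Both flanks of a called insertion are locally aligned to the candidate.
    If they join across at most a TSD-sized gap the site is "empty" (the
    ortholog carries a single target-site copy and no element); an
    LTR-sized or larger intervening stretch means "occupied"; anything else
    — including unalignable flanks — is "ambiguous".
    """
    if len(flank5) < 50 or len(flank3) < 50:
        raise ValueError("flanks must be >= 50 nt")
    scheme = scheme or dna_scheme()
    m = scheme.match if scheme.match is not None else 1
    try:
        left = local_align_nuc(flank5, candidate_region, scheme)
        right = local_align_nuc(flank3, candidate_region, scheme)
    except ValueError:
        return "ambiguous"
    ok_l = left.raw_score >= min_score_frac * m * len(flank5)
    ok_r = right.raw_score >= min_score_frac * m * len(flank3)
    if not (ok_l and ok_r):
        return "ambiguous"
    gap = right.s_start - left.s_end - 1
    if -5 <= gap <= max_empty_gap:
        return "empty"
    if gap >= min_occupied_gap:
        return "occupied"
    return "ambiguous"
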