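"""Genome-organisation annotation of a provirus or consensus sequence.

Finds open reading frames on both strands, assigns the canonical retroviral
gene labels (gag, pol, env — with the gag/pol overlap in shifted frames that
marks ribosomal-frameshift translation, plus short accessory ORFs), and
locates the two reverse-transcription priming signals: the primer binding
site (PBS, complementary to a tRNA 3' tail just inside the 5' LTR) and the
polypurine tract (PPT, immediately upstream of the 3' LTR).

Gene labelling is positional and heuristic; homology evidence (e.g. aligning
candidate ORFs to reference proteins via :mod:`ervkit.seqsearch`) can be
layered on top but is not required.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from ._seq import PURINES, revcomp, translate
from .simgenome import TRNA_TAILS

__all__ = ["OrfCall", "FeatureCall", "find_orfs", "detect_frameshift_overlap",
           "locate_pbs_ppt", "annotate_provirus"]


@dataclass
class OrfCall:
    """An open reading frame, 1-based inclusive on the plus strand.

    The interval includes the initiator ATG and the terminal stop codon (or
    runs to the sequence end).  ``label`` is one of gag/pol/env/short_orf/
    long_orf; ``name`` carries the accessory-ORF analog (orf1/orf2/orf3)
    when positional rules assign one.
    """

    start: int
    end: int
    frame: int
    strand: str
    length_aa: int
    label: str = "short_orf"
    name: str | None = None

    def overlaps(self, other: "OrfCall") -> int:
        return max(0, min(self.end, other.end) - max(self.start, other.start) + 1)


@dataclass
class FeatureCall:
    kind: str                          # PBS | PPT | frameshift_overlap
    start: int
    end: int
    detail: dict = field(default_factory=dict)


def _orfs_one_strand(seq: str, strand: str, min_aa: int,
                     require_atg: bool) -> list[OrfCall]:
    L = len(seq)
    s = seq if strand == "+" else revcomp(seq)
    out = []
    for off in range(3):
        aa = translate(s[off:])
        start_idx = None
        for i, ch in enumerate(aa + "*"):
            at_end = i == len(aa)
            if start_idx is None:
                if (ch == "M" or (not require_atg and ch not in "*")) and not at_end:
                    start_idx = i
                continue
            if ch == "*" or at_end:
                length_aa = i - start_idx
                if length_aa >= min_aa:
                    nt_s = off + 3 * start_idx          # 0-based
                    nt_e = off + 3 * (i + (0 if at_end else 1)) - 1
                    nt_e = min(nt_e, len(s) - 1)
                    if strand == "+":
                        a, b = nt_s + 1, nt_e + 1
                    else:
                        a, b = L - nt_e, L - nt_s
                    out.append(OrfCall(start=a, end=b, frame=off + 1,
                                       strand=strand, length_aa=length_aa))
                start_idx = None
    return out


def find_orfs(seq: str, min_long_aa: int = 300, min_short_aa: int = 70,
              require_atg: bool = True) -> list[OrfCall]:
    """All ORFs of at least ``min_short_aa`` codons on both strands, with
    retroviral gene labels assigned on the strand carrying the long ORFs.

    The three longest non-nested long ORFs (>= ``min_long_aa``) become gag,
    pol and env in 5'→3' order; the pol label additionally requires an
    overlap with gag in a different frame (the frameshift signature).
    Short ORFs between pol and env become orf1/orf2 analogs in order; a
    short ORF overlapping the end of env becomes the orf3 analog.
    """
    orfs = (_orfs_one_strand(seq, "+", min_short_aa, require_atg)
            + _orfs_one_strand(seq, "-", min_short_aa, require_atg))
    for o in orfs:
        o.label = "long_orf" if o.length_aa >= min_long_aa else "short_orf"
    by_strand = {"+": [o for o in orfs if o.strand == "+" and o.label == "long_orf"],
                 "-": [o for o in orfs if o.strand == "-" and o.label == "long_orf"]}
    main = max("+-", key=lambda s: sum(o.length_aa for o in by_strand[s]))
    longs = sorted(by_strand[main], key=lambda o: -o.length_aa)
    chosen: list[OrfCall] = []
    for o in longs:
        if len(chosen) == 3:
            break
        if any(o.start >= c.start and o.end <= c.end for c in chosen):
            continue  # nested inside an already chosen ORF
        chosen.append(o)
    chosen.sort(key=lambda o: o.start if main == "+" else -o.end)
    gag = pol = env = None
    if chosen:
        gag = chosen[0]
        gag.label = "gag"
    if len(chosen) > 1:
        cand = chosen[1]
        if gag is not None and cand.overlaps(gag) > 0 and cand.frame != gag.frame:
            cand.label = "pol"
            pol = cand
        else:
            cand.label = "pol" if gag is None else "long_orf"
            pol = cand if cand.label == "pol" else pol
    if len(chosen) > 2:
        env = chosen[2]
        env.label = "env"
    if pol is not None and env is not None:
        shorts = [o for o in orfs if o.strand == main and o.label == "short_orf"]
        # accessory ORFs live between pol and env; allow overlap with the
        # pol tail (orf1-style) but not ORFs buried deep inside pol
        between = sorted(
            (o for o in shorts
             if o.start >= pol.end - 150 and o.end <= env.start + 30),
            key=lambda o: o.start)
        for o, nm in zip(between, ("orf1", "orf2")):
            o.name = nm
        for o in shorts:
            if o.start < env.end <= o.end:
                o.name = "orf3"
                break
    orfs.sort(key=lambda o: (o.start, o.end, o.strand))
    return orfs


def detect_frameshift_overlap(orf_a: OrfCall, orf_b: OrfCall) -> FeatureCall | None:
    """Frameshift-overlap feature if two same-strand ORFs overlap in
    different frames; ``detail['delta']`` is −1 or +1 (ribosomal slip)."""
    if orf_a.strand != orf_b.strand:
        return None
    ov = orf_a.overlaps(orf_b)
    if ov == 0 or orf_a.frame == orf_b.frame:
        return None
    first, second = sorted((orf_a, orf_b), key=lambda o: o.start)
    delta = (second.frame - first.frame) % 3
    delta = -1 if delta == 2 else +1
    return FeatureCall(kind="frameshift_overlap",
                       start=max(orf_a.start, orf_b.start),
                       end=min(orf_a.end, orf_b.end),
                       detail={"frames": (first.frame, second.frame),
                               "delta": delta, "overlap_len": ov})


def locate_pbs_ppt(seq: str, ltr5_end: int, ltr3_start: int,
                   trna_tails: dict[str, str] | None = None,
                   pbs_search: int = 30, pbs_min_matches_delta: int = 3,
                   ppt_min_len: int = 11, ppt_min_purine: float = 0.9,
                   ppt_max_gap: int = 10) -> list[FeatureCall]:
    """Locate the putative PBS and the PPT relative to known LTR boundaries.

    PBS: best reverse-complement match to any provided tRNA 3' tail within
    ``pbs_search`` nt downstream of the 5' LTR, tolerating up to
    ``pbs_min_matches_delta`` mismatches (>= 15/18 for an 18-nt tail).
    PPT: the longest window of >= ``ppt_min_len`` nt with purine fraction
    >= ``ppt_min_purine`` ending within ``ppt_max_gap`` nt of the 3' LTR.
    """
    if not (1 <= ltr5_end < ltr3_start <= len(seq)):
        raise ValueError("LTR boundaries missing or inconsistent")
    trna_tails = trna_tails if trna_tails is not None else TRNA_TAILS
    seq = seq.upper()
    feats: list[FeatureCall] = []

    best = None
    for name, tail in trna_tails.items():
        probe = revcomp(tail.upper())
        T = len(probe)
        region_start = ltr5_end            # 0-based start just after LTR5
        for s in range(region_start, min(region_start + pbs_search, len(seq) - T) + 1):
            matches = sum(a == b for a, b in zip(seq[s:s + T], probe))
            if matches >= T - pbs_min_matches_delta:
                key = (matches, -s)
                if best is None or key > best[0]:
                    best = (key, s, T, name, matches)
    if best is not None:
        _, s, T, name, matches = best
        feats.append(FeatureCall(kind="PBS", start=s + 1, end=s + T,
                                 detail={"trna": name, "matches": matches,
                                         "length": T, "putative": True}))

    lo = max(0, ltr3_start - 1 - ppt_max_gap - 50)
    hi = ltr3_start - 1                    # 0-based exclusive end limit
    best_ppt = None
    for a in range(lo, hi):
        for b in range(a + ppt_min_len, hi + 1):
            if hi - b > ppt_max_gap:
                continue
            window = seq[a:b]
            frac = sum(c in PURINES for c in window) / len(window)
            if frac >= ppt_min_purine:
                key = (b - a, frac, a)
                if best_ppt is None or key > best_ppt[0]:
                    best_ppt = (key, a, b, frac)
    if best_ppt is not None:
        _, a, b, frac = best_ppt
        feats.append(FeatureCall(kind="PPT", start=a + 1, end=b,
                                 detail={"purine_fraction": round(frac, 3),
                                         "length": b - a}))
    return feats


def annotate_provirus(seq: str, ltr_len: int,
                      min_long_aa: int = 300, min_short_aa: int = 70
                      ) -> dict[str, object]:
    """Convenience bundle: ORFs, gag/pol frameshift overlap, PBS and PPT for
    a full provirus whose LTRs span the first and last ``ltr_len`` nt."""
    orfs = find_orfs(seq, min_long_aa, min_short_aa)
    labelled = {o.label: o for o in orfs if o.label in ("gag", "pol", "env")}
    features: list[FeatureCall] = []
    if "gag" in labelled and "pol" in labelled:
        fs = detect_frameshift_overlap(labelled["gag"], labelled["pol"])
        if fs:
            features.append(fs)
    features.extend(locate_pbs_ppt(seq, ltr5_end=ltr_len,
                                   ltr3_start=len(seq) - ltr_len + 1))
    return {"orfs": orfs, "features": features}
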