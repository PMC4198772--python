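"""Molecular dating of insertions from LTR divergence.

A provirus integrates with byte-identical 5' and 3' LTRs; every difference
between them accrued afterwards at the host's neutral substitution rate mu.
With D substitution differences over L aligned sites, the expected per-LTR
divergence is D/(2L) and the insertion age is

    T = D / (2 * L * mu)

evaluated at both ends of a neutral-rate interval (default 2.2–4.5e-9 per
site per year, the mammalian range) to give [t_low, t_high].  The raw
difference count is used by default — no multiple-hit correction — matching
how such intervals are conventionally reported; a Jukes–Cantor-corrected
variant is available via a flag.  Segmental duplications containing the same
insertion give an independent *lower* bound: flanking-sequence divergence
between the duplicated copies dates the duplication, which the insertion
must predate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import edlib

from .seqsearch import local_align_nuc

__all__ = ["AgeEstimate", "RATE_LOW", "RATE_HIGH", "ltr_divergence",
           "estimate_age_range", "duplication_age_bound", "mya"]

RATE_LOW = 2.2e-9
RATE_HIGH = 4.5e-9


@dataclass
class AgeEstimate:
    d_count: int                       # substitution differences D
    aligned_len: int                   # sites L (gap columns excluded)
    rate_low: float
    rate_high: float
    t_low: float                       # years (at rate_high)
    t_high: float                      # years (at rate_low)
    method: str = "ltr_pair"
    jc_corrected: bool = False

    @property
    def t_low_mya(self) -> float:
        return mya(self.t_low)

    @property
    def t_high_mya(self) -> float:
        return mya(self.t_high)


def mya(t_years: float) -> float:
    """Years → MYA at the conventional 0.1 precision."""
    return round(t_years / 1e6, 1)


def ltr_divergence(ltr5: str, ltr3: str,
                   min_identity: float = 0.5) -> tuple[int, int, dict]:
    """Count substitution differences between the two LTRs of one provirus.

    The LTRs are globally aligned; L counts columns where both rows carry a
    base, D the mismatching ones — indel columns are excluded from both.
    Raises if identity over the base columns falls below ``min_identity``,
    which signals a probably non-orthologous pair.
    """
    if len(ltr5) < 100 or len(ltr3) < 100:
        raise ValueError("LTRs must be >= 100 nt")
    res = edlib.align(ltr5.upper(), ltr3.upper(), mode="NW", task="path")
    # unrelated sequences align at ~0.5 edits/site under unit costs, and a
    # unit-cost path then overstates column identity — gate on the raw
    # edit-distance ratio before counting columns
    if res["editDistance"] / max(len(ltr5), len(ltr3)) > min(0.45, 1 - min_identity):
        raise ValueError(
            "edit distance too high: probably not an orthologous 5'/3' pair")
    nice = edlib.getNiceAlignment(res, ltr5.upper(), ltr3.upper())
    a, b = nice["query_aligned"], nice["target_aligned"]
    L = D = 0
    for x, y in zip(a, b):
        if x != "-" and y != "-":
            L += 1
            if x != y:
                D += 1
    if L == 0 or 1 - D / L < min_identity:
        raise ValueError(
            f"LTR pair identity {1 - D / max(L, 1):.2f} below {min_identity}: "
            "probably not an orthologous 5'/3' pair")
    return D, L, {"aligned_5": a, "aligned_3": b}


def estimate_age_range(d_count: int, aligned_len: int,
                       rate_low: float = RATE_LOW,
                       rate_high: float = RATE_HIGH,
                       jc_correct: bool = False,
                       method: str = "ltr_pair") -> AgeEstimate:
    """Insertion-age interval from an LTR difference count.

    ``t_low = D/(2*L*rate_high)`` and ``t_high = D/(2*L*rate_low)`` in
    years.  With ``jc_correct`` the per-site divergence p = D/L is first
    mapped through the Jukes–Cantor distance −(3/4)·ln(1 − 4p/3).
    """
    if aligned_len <= 0:
        raise ValueError("aligned_len must be positive")
    if d_count < 0 or d_count > aligned_len:
        raise ValueError("need 0 <= D <= L")
    if rate_low >= rate_high:
        raise ValueError("rate_low must be < rate_high")
    if jc_correct:
        p = d_count / aligned_len
        if p >= 0.75:
            raise ValueError("divergence saturated under Jukes–Cantor")
        d = -0.75 * math.log(1 - 4 * p / 3)
    else:
        d = d_count / aligned_len
    return AgeEstimate(d_count=d_count, aligned_len=aligned_len,
                       rate_low=rate_low, rate_high=rate_high,
                       t_low=d / (2 * rate_high), t_high=d / (2 * rate_low),
                       method=method, jc_corrected=jc_correct)


def date_ltr_pair(ltr5: str, ltr3: str, rate_low: float = RATE_LOW,
                  rate_high: float = RATE_HIGH,
                  jc_correct: bool = False) -> AgeEstimate:
    """Convenience: ltr_divergence + estimate_age_range in one call."""
    D, L, _ = ltr_divergence(ltr5, ltr3)
    return estimate_age_range(D, L, rate_low, rate_high, jc_correct)


def duplication_age_bound(region_a: str, region_b: str, reference_ltr: str,
                          rate_low: float = RATE_LOW,
                          rate_high: float = RATE_HIGH,
                          min_hit_identity: float = 0.6,
                          min_hit_coverage: float = 0.5) -> AgeEstimate:
    """Lower bound on insertion age from a segmental-duplication pair.

    Both regions must contain the same solo-LTR insertion (located with the
    reference LTR); the insertion is excised and the flanking duplicated
    sequence dated with the standard two-branch clock.  The interval bounds
    the *duplication* age, hence a lower bound for the insertion.
    """
    hits = []
    for region in (region_a, region_b):
        h = local_align_nuc(reference_ltr, region)
        if h.identity < min_hit_identity or h.coverage < min_hit_coverage:
            raise ValueError("regions do not share a recognisable LTR insertion")
        hits.append(h)
    D = L = 0
    for side in ("left", "right"):
        parts = []
        for region, h in zip((region_a, region_b), hits):
            if side == "left":
                parts.append(region[:h.s_start - 1])
            else:
                parts.append(region[h.s_end:])
        fa, fb = parts
        if not fa or not fb:
            continue
        res = edlib.align(fa.upper(), fb.upper(), mode="NW", task="path")
        nice = edlib.getNiceAlignment(res, fa.upper(), fb.upper())
        for x, y in zip(nice["query_aligned"], nice["target_aligned"]):
            if x != "-" and y != "-":
                L += 1
                if x != y:
                    D += 1
    if L == 0:
        raise ValueError("no flanking sequence to date")
    return estimate_age_range(D, L, rate_low, rate_high,
                              method="duplication_bound")
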