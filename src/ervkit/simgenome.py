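"""Synthetic host genomes with implanted retroviral elements and full truth.

The simulator emulates what an ancient endogenous retrovirus leaves in a
present-day assembly:

* a neutral i.i.d. host background at configurable GC;
* full proviruses (``TSD + LTR + internal + LTR + TSD``) whose two LTRs are
  identical at insertion time and then accumulate independent neutral
  substitutions for the insertion's age — the basis of the LTR molecular
  clock; the internal region additionally suffers indels and nested
  retroelement (SINE/LINE-like) insertions;
* solo LTRs produced by LTR–LTR recombination (a single LTR between the two
  TSD copies);
* segmental-duplication pairs: a window containing a solo LTR copied
  elsewhere, both copies diverging since the duplication — yielding a lower
  bound on the insertion age;
* orthologous empty pre-integration sites (flank + one target-site copy +
  flank) as separate contigs.

Everything is driven by one seed and emitted together with a complete
machine-readable ground truth (`SimTruth` records, GFF3 + JSON writers).
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field

import numpy as np

from ._seq import NUCS, STOP_CODONS, random_dna, revcomp, translate

__all__ = [
    "ProvirusTemplate",
    "SimParams",
    "SimTruth",
    "TRNA_TAILS",
    "make_provirus_template",
    "mutate_neutral",
    "simulate_genome",
    "write_fasta",
    "read_fasta",
    "write_truth_gff3",
    "write_truth_json",
    "write_config",
    "read_config",
]

# Generic tRNA 3'-tail sequences (18 nt) used to implant / search a primer
# binding site.  Synthetic placeholder sequences, not database records; the
# PBS implanted by the simulator is the reverse complement of the first one.
TRNA_TAILS = {
    "tRNA-Lys": "TGGCGCCCGAACAGGGAC",
    "tRNA-Pro": "TGGGGGCTCGTCCGGGAT",
    "tRNA-Trp": "TGGTGACCCCGACGTGAT",
}

_CODON_TABLE: dict[str, list[str]] = {}


def _codons_for(aa: str) -> list[str]:
    if not _CODON_TABLE:
        for n1 in NUCS:
            for n2 in NUCS:
                for n3 in NUCS:
                    codon = n1 + n2 + n3
                    if codon in STOP_CODONS:
                        continue
                    _CODON_TABLE.setdefault(translate(codon), []).append(codon)
    return _CODON_TABLE[aa]


@dataclass(frozen=True)
class GeneInterval:
    """1-based inclusive gene interval on the full provirus, with its frame."""

    name: str
    start: int
    end: int
    frame: int


@dataclass
class ProvirusTemplate:
    """A full-length proviral element: LTR + internal region + identical LTR.

    Coordinates in ``gene_intervals``, ``pbs_interval`` and ``ppt_interval``
    are 1-based inclusive on the full provirus ``sequence``.  Gene intervals
    include the initiator ATG and the terminal stop codon.
    """

    name: str
    ltr_seq: str
    internal_seq: str
    gene_intervals: list[GeneInterval]
    pbs_interval: tuple[int, int]
    ppt_interval: tuple[int, int]

    @property
    def sequence(self) -> str:
        return self.ltr_seq + self.internal_seq + self.ltr_seq

    @property
    def l_ltr(self) -> int:
        return len(self.ltr_seq)

    @property
    def length(self) -> int:
        return 2 * len(self.ltr_seq) + len(self.internal_seq)

    def gene(self, name: str) -> GeneInterval:
        for g in self.gene_intervals:
            if g.name == name:
                return g
        raise KeyError(name)

    def protein(self, name: str) -> str:
        """Realized protein of a gene (terminal stop removed)."""
        g = self.gene(name)
        aa = translate(self.sequence[g.start - 1:g.end])
        return aa[:-1] if aa.endswith("*") else aa


class SizingError(ValueError):
    """Requested lengths cannot host the proviral gene layout."""


class PlacementError(RuntimeError):
    """Insertions could not be placed without overlap."""


@dataclass
class SimParams:
    """Simulation conditions.

    Rates are per site (or per provirus) per year.  The default substitution
    rate 3.0e-9 sits inside the 2.2–4.5e-9 mammalian neutral range used for
    dating; provirus default ages span the mid-Miocene window typical of
    ancient lentiviral endogenization (about 8–20 Myr).  ``tsd_len`` defaults
    to 5 nt (a free parameter of the simulator; integrase-dependent in
    reality).  ``seed`` fully determines the output.
    """

    seed: int = 0
    mu: float = 3.0e-9
    indel_rate: float = 2.0e-11
    indel_mean_len: float = 3.0
    ltr_indels: bool = False
    nested_insert_rate: float = 1.0e-7
    tsd_len: int = 5
    n_full: int = 3
    n_solo: int = 100
    n_dup_pairs: int = 7
    ages: list[float] | None = None
    solo_age_range: tuple[float, float] = (2.0e6, 15.0e6)
    genome_len: int = 400_000
    gc: float = 0.40
    minus_strand: bool = True
    empty_site_fraction: float = 0.5
    empty_site_divergence: float = 0.05
    flank_margin: int = 300
    contig_name: str = "contig_1"

    def __post_init__(self) -> None:
        if not (0 < self.mu < 1e-6):
            raise ValueError("mu must be in (0, 1e-6)")
        if self.tsd_len < 0:
            raise ValueError("tsd_len must be >= 0")
        if self.ages is None:
            self.ages = [7.7e6, 15.4e6, 20.1e6]


@dataclass
class SimTruth:
    """Ground truth for one implanted insertion (final contig coordinates)."""

    insertion_id: str
    type: str                      # "full" | "solo"
    contig: str
    position: int                  # 1-based start of the element (after 5' TSD)
    end: int                       # 1-based inclusive end of the element
    strand: str
    age_years: float
    tsd: str                       # pre-mutation target-site motif
    tsd5_interval: tuple[int, int] | None
    tsd3_interval: tuple[int, int] | None
    ltr_intervals: list[tuple[int, int]]
    internal_interval: tuple[int, int] | None = None
    nested_intervals: list[tuple[int, int]] = field(default_factory=list)
    duplication_partner: str | None = None
    duplication_age_years: float | None = None
    empty_site_contig: str | None = None


# ---------------------------------------------------------------------------
# template construction
# ---------------------------------------------------------------------------

def _paint_gene(seq: list[str], start0: int, n_codons: int,
                protein: str | None, rng: np.random.Generator) -> None:
    """Write ATG + body + stop at ``start0`` (0-based); body codons are either
    synonymous encodings of ``protein`` or random non-stop codons."""
    seq[start0:start0 + 3] = "ATG"
    for i in range(1, n_codons - 1):
        if protein is not None and i < len(protein):
            options = _codons_for(protein[i])
            codon = options[rng.integers(0, len(options))]
        else:
            codon = None
            while codon is None or codon in STOP_CODONS:
                codon = "".join(NUCS[j] for j in rng.integers(0, 4, 3))
        seq[start0 + 3 * i:start0 + 3 * i + 3] = codon
    seq[start0 + 3 * (n_codons - 1):start0 + 3 * n_codons] = "TAA"


def _repair_stops(seq: list[str], genes: list[tuple[int, int]],
                  locked: set[int], rng: np.random.Generator,
                  max_iter: int = 50_000) -> None:
    """Remove internal stop codons from every gene frame.

    ``genes`` holds 0-based (start, end_exclusive) intervals; the terminal
    codon of each gene is its sanctioned stop.  Locked positions (anchors,
    PBS, PPT) are never touched; each offending codon is fixed by mutating
    one of its unlocked nucleotides.
    """
    for _ in range(max_iter):
        violation = None
        for (s0, e0) in genes:
            for c in range(s0, e0 - 3, 3):
                if "".join(seq[c:c + 3]) in STOP_CODONS:
                    violation = c
                    break
            if violation is not None:
                break
        if violation is None:
            return
        free = [p for p in range(violation, violation + 3) if p not in locked]
        if not free:
            raise SizingError("gene layout over-constrained: cannot repair stop")
        p = free[rng.integers(0, len(free))]
        choices = NUCS.replace(seq[p], "")
        seq[p] = choices[rng.integers(0, len(choices))]
    raise SizingError("stop-codon repair did not converge")


def make_provirus_template(seed: int, l_ltr: int = 420, l_internal: int = 9200,
                           name: str = "template",
                           gag_protein: str | None = None,
                           pol_protein: str | None = None,
                           env_protein: str | None = None,
                           gc: float = 0.45,
                           pbs_tail: str = TRNA_TAILS["tRNA-Lys"],
                           ) -> ProvirusTemplate:
    """Build a deterministic proviral template with a lentivirus-like layout.

    The internal region carries gag, pol (overlapping gag in a −1 frame, as
    for ribosomal-frameshift translation), env, and three short accessory
    ORFs (orf1 overlapping the end of pol, orf2 between pol and env, orf3
    overlapping the end of env), plus a PBS just inside the 5' LTR boundary
    and a polypurine tract flush against the 3' LTR.  Gene proteins may be
    pinned (e.g. ``pol_protein``) so screening baits have a known target; in
    overlap regions a few residues may be adjusted to keep all frames open.
    """
    if l_ltr < 100:
        raise SizingError("l_ltr must be >= 100")
    rng = np.random.default_rng(seed)

    scale = l_internal / 9200.0
    gag_aa = len(gag_protein) if gag_protein else max(310, int(450 * scale))
    pol_aa = len(pol_protein) if pol_protein else max(380, int(1050 * scale))
    env_aa = len(env_protein) if env_protein else max(310, int(780 * scale))
    with_short = l_internal >= 6000
    orf1_aa, orf2_aa, orf3_aa = 272, 103, 83

    pbs_len = len(pbs_tail)
    leader = 150
    gag_start = pbs_len + leader + 1                       # internal 1-based
    gag_end = gag_start + 3 * (gag_aa + 1) - 1
    pol_start = gag_end - 200
    # enforce a -1 frameshift: (pol_start - gag_start) % 3 == 2
    pol_start += (2 - (pol_start - gag_start)) % 3
    pol_end = pol_start + 3 * (pol_aa + 1) - 1
    coords: list[tuple[str, int, int, str | None]] = [
        ("gag", gag_start, gag_end, gag_protein),
        ("pol", pol_start, pol_end, pol_protein),
    ]
    cursor = pol_end
    if with_short:
        orf1_start = pol_end - 100
        orf1_start += (1 - (orf1_start - pol_start)) % 3
        orf1_end = orf1_start + 3 * (orf1_aa + 1) - 1
        orf2_start = orf1_end + 40
        orf2_end = orf2_start + 3 * (orf2_aa + 1) - 1
        coords += [("orf1", orf1_start, orf1_end, None),
                   ("orf2", orf2_start, orf2_end, None)]
        cursor = orf2_end
    env_start = cursor + 60
    env_end = env_start + 3 * (env_aa + 1) - 1
    coords.append(("env", env_start, env_end, env_protein))
    tail_needed = env_end
    if with_short:
        orf3_start = env_end - 120
        orf3_start += (1 - (orf3_start - env_start)) % 3
        orf3_end = orf3_start + 3 * (orf3_aa + 1) - 1
        coords.append(("orf3", orf3_start, orf3_end, None))
        tail_needed = max(env_end, orf3_end)
    ppt_len = 13
    if tail_needed + 10 + ppt_len > l_internal:
        raise SizingError(
            f"l_internal={l_internal} too small for the gene layout "
            f"(needs >= {tail_needed + 10 + ppt_len})")

    internal = list(random_dna(rng, l_internal, gc))
    # PBS: reverse complement of the tRNA 3' tail, right after the 5' LTR
    internal[0:pbs_len] = revcomp(pbs_tail)
    # PPT: purine tract flush with the 3' LTR
    ppt = "".join("AG"[j] for j in rng.integers(0, 2, ppt_len))
    internal[l_internal - ppt_len:] = ppt

    locked: set[int] = set(range(pbs_len)) | set(range(l_internal - ppt_len, l_internal))
    gene_bounds: list[tuple[int, int]] = []
    for gname, start, end, protein in coords:
        s0 = start - 1
        n_codons = (end - start + 1) // 3
        _paint_gene(internal, s0, n_codons, protein, rng)
        gene_bounds.append((s0, end))
    # Later genes overwrite overlap regions (e.g. pol over gag's tail), so
    # re-force every anchor afterwards: an in-frame stop right before each
    # gene, its initiator ATG, and its terminal stop; then lock them all.
    for (gname, start, end, _), (s0, e0) in zip(coords, gene_bounds):
        if s0 - 3 >= 0:
            internal[s0 - 3:s0] = "TAA"
            locked.update(range(s0 - 3, s0))
        internal[s0:s0 + 3] = "ATG"
        internal[e0 - 3:e0] = "TAA"
        locked.update(range(s0, s0 + 3))           # ATG
        locked.update(range(e0 - 3, e0))           # terminal stop
    _repair_stops(internal, gene_bounds, locked, rng)

    ltr = random_dna(rng, l_ltr, gc)
    genes = [GeneInterval(gname, l_ltr + start, l_ltr + end,
                          ((l_ltr + start - 1) % 3) + 1)
             for gname, start, end, _ in coords]
    tpl = ProvirusTemplate(
        name=name, ltr_seq=ltr, internal_seq="".join(internal),
        gene_intervals=genes,
        pbs_interval=(l_ltr + 1, l_ltr + pbs_len),
        ppt_interval=(l_ltr + l_internal - ppt_len + 1, l_ltr + l_internal))
    for g in genes:
        aa = tpl.protein(g.name)
        assert "*" not in aa, f"internal stop left in {g.name}"
    return tpl


# ---------------------------------------------------------------------------
# neutral mutation
# ---------------------------------------------------------------------------

_IDX = {c: i for i, c in enumerate(NUCS)}


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.upper().encode(), dtype=np.uint8)
    out = np.full(arr.shape, 4, dtype=np.int8)
    for c, i in _IDX.items():
        out[arr == ord(c)] = i
    return out


def _decode(idx: np.ndarray) -> str:
    lut = np.frombuffer(b"ACGTN", dtype=np.uint8)
    return lut[idx].tobytes().decode()


def substitution_probability(mu: float, t: float) -> float:
    """Jukes–Cantor expected difference fraction after time t at rate mu."""
    return 0.75 * (1.0 - math.exp(-4.0 * mu * t / 3.0))


def mutate_neutral(seq: str, mu: float, t: float,
                   rng: np.random.Generator | int | None = None,
                   indel_rate: float = 0.0,
                   indel_mean_len: float = 3.0) -> str:
    """Age a sequence by ``t`` years of neutral Jukes–Cantor evolution.

    Substitutions are applied site-independently with the JC closed-form
    probability ``3/4*(1 - exp(-4*mu*t/3))``; optional indels arrive as a
    Poisson process (``indel_rate`` per site per year) with geometric lengths
    of the given mean, half insertions and half deletions.  Ambiguous (N)
    sites are never substituted.  Deterministic for a fixed generator/seed.
    """
    if t < 0:
        raise ValueError("t must be >= 0")
    if t == 0 or not seq:
        return seq
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    idx = _encode(seq)
    p = substitution_probability(mu, t)
    hit = (rng.random(idx.size) < p) & (idx < 4)
    # shift by 1..3 mod 4: uniform over the three other bases
    idx[hit] = (idx[hit] + rng.integers(1, 4, hit.sum())) % 4
    out = _decode(idx)
    if indel_rate > 0:
        n_events = rng.poisson(indel_rate * t * len(seq))
        for _ in range(n_events):
            pos = int(rng.integers(0, max(1, len(out))))
            length = int(rng.geometric(1.0 / indel_mean_len))
            if rng.random() < 0.5:
                out = out[:pos] + out[pos + length:]
            else:
                ins = random_dna(rng, length)
                out = out[:pos] + ins + out[pos:]
    return out


# ---------------------------------------------------------------------------
# genome assembly
# ---------------------------------------------------------------------------

def _make_repeat_library(rng: np.random.Generator, gc: float) -> dict[str, str]:
    return {"SINE": random_dna(rng, 300, gc), "LINE": random_dna(rng, 2500, gc)}


def _nest_insertions(internal: str, count: int, library: dict[str, str],
                     rng: np.random.Generator) -> tuple[str, list[tuple[int, int]]]:
    """Insert SINE/LINE-like fragments; returns sequence + 1-based intervals."""
    intervals: list[tuple[int, int]] = []
    for _ in range(count):
        if rng.random() < 0.5:
            src = library["SINE"]
            length = int(rng.integers(150, min(600, len(src)) + 1))
        else:
            src = library["LINE"]
            length = int(rng.integers(1000, min(3000, len(src)) + 1))
        start = int(rng.integers(0, len(src) - length + 1))
        frag = src[start:start + length]
        pos = int(rng.integers(50, max(51, len(internal) - 50)))
        internal = internal[:pos] + frag + internal[pos:]
        shifted = []
        for (a, b) in intervals:
            if a > pos:
                shifted.append((a + length, b + length))
            else:
                shifted.append((a, b))
        intervals = shifted + [(pos + 1, pos + length)]
    return internal, intervals


def simulate_genome(params: SimParams, template: ProvirusTemplate
                    ) -> tuple[dict[str, str], list[SimTruth]]:
    """Implant full proviruses, solo LTRs and duplication pairs into a
    neutral background and return (contigs, ground truth).

    Each insertion duplicates its target site (``tsd_len`` nt) on both
    flanks; the two TSD copies and both LTRs then age independently for the
    insertion's age, so a zero-age insertion has byte-identical LTRs and a
    perfect TSD.  Elements land on the minus strand with probability 0.5
    unless disabled.  Empty pre-integration contigs (flank + one TSD copy +
    flank, mildly diverged to emulate an orthologous species) are emitted
    for a configurable fraction of insertions.
    """
    p = params
    rng = np.random.default_rng(p.seed)
    library = _make_repeat_library(rng, p.gc)
    bg = random_dna(rng, p.genome_len, p.gc)

    # ---- plan the insertion roster -------------------------------------
    roster: list[dict] = []
    ages = list(p.ages or [])
    for i in range(p.n_full):
        roster.append({"id": f"full_{i + 1}", "type": "full",
                       "age": float(ages[i % len(ages)]) if ages else 10e6})
    lo, hi = p.solo_age_range
    for i in range(p.n_solo):
        roster.append({"id": f"solo_{i + 1}", "type": "solo",
                       "age": float(rng.uniform(lo, hi))})
    n_dup = min(p.n_dup_pairs, p.n_solo)
    dup_solo_idx = rng.choice(p.n_solo, size=n_dup, replace=False) if n_dup else []
    for j, k in enumerate(sorted(int(x) for x in np.atleast_1d(dup_solo_idx))):
        rec = roster[p.n_full + k]
        rec["type"] = "dup"
        rec["dup_age"] = float(rng.uniform(0.2, 0.8) * rec["age"])
        partner = {"id": rec["id"] + "b", "type": "dup_partner",
                   "age": rec["age"], "dup_age": rec["dup_age"],
                   "partner": rec["id"]}
        rec["partner"] = partner["id"]
        roster.append(partner)

    n = len(roster)
    if p.genome_len <= (n + 1) * (p.flank_margin + p.tsd_len):
        raise PlacementError(
            f"genome_len={p.genome_len} cannot host {n} insertions with "
            f"{p.flank_margin} nt margins")
    slack = p.genome_len - (n + 1) * (p.flank_margin + p.tsd_len)
    gaps = rng.multinomial(slack, [1.0 / (n + 1)] * (n + 1)) + p.flank_margin
    sites = np.cumsum(gaps + p.tsd_len)[:-1] - p.tsd_len  # bg coords, ascending
    order = rng.permutation(n)
    for idx, rec in zip(order, roster):
        rec["site"] = int(sites[idx])
    roster.sort(key=lambda r: r["site"])

    # ---- build element sequences ---------------------------------------
    for rec in roster:
        age = rec["age"]
        strand = "-" if (p.minus_strand and rng.random() < 0.5) else "+"
        rec["strand"] = strand
        if rec["type"] == "full":
            ltr5 = mutate_neutral(template.ltr_seq, p.mu, age, rng,
                                  p.indel_rate if p.ltr_indels else 0.0,
                                  p.indel_mean_len)
            ltr3 = mutate_neutral(template.ltr_seq, p.mu, age, rng,
                                  p.indel_rate if p.ltr_indels else 0.0,
                                  p.indel_mean_len)
            internal = mutate_neutral(template.internal_seq, p.mu, age, rng,
                                      p.indel_rate, p.indel_mean_len)
            n_nested = rng.poisson(p.nested_insert_rate * age)
            internal, nested = _nest_insertions(internal, int(n_nested), library, rng)
            rec.update(ltr_lens=(len(ltr5), len(ltr3)),
                       nested=nested, elem=ltr5 + internal + ltr3)
        elif rec["type"] in ("solo", "dup", "dup_partner"):
            if rec["type"] in ("dup", "dup_partner"):
                continue  # built pairwise below
            ltr = mutate_neutral(template.ltr_seq, p.mu, age, rng,
                                 p.indel_rate if p.ltr_indels else 0.0,
                                 p.indel_mean_len)
            rec.update(ltr_lens=(len(ltr),), nested=[], elem=ltr)
    # duplication pairs share history until the duplication event
    for rec in roster:
        if rec["type"] != "dup":
            continue
        partner = next(r for r in roster if r["id"] == rec.get("partner"))
        age, dup_age = rec["age"], rec["dup_age"]
        flank = 800
        site = rec["site"]
        tsd_src = bg[site:site + p.tsd_len]
        ltr_shared = mutate_neutral(template.ltr_seq, p.mu, age - dup_age, rng)
        window0 = (random_dna(rng, flank, p.gc) + tsd_src + ltr_shared
                   + tsd_src + random_dna(rng, flank, p.gc))
        for r in (rec, partner):
            copy = mutate_neutral(window0, p.mu, dup_age, rng)
            r.update(elem=copy, is_window=True, flank=flank,
                     ltr_lens=(len(ltr_shared),), nested=[], strand="+",
                     tsd_src=tsd_src)

    # ---- assemble the contig and truth ----------------------------------
    parts: list[str] = []
    truths: list[SimTruth] = []
    cursor_bg = 0
    final_pos = 0  # 0-based length emitted so far
    for rec in roster:
        site = rec["site"]
        elem = rec["elem"]
        if not rec.get("is_window"):
            if rec["strand"] == "-":
                elem = revcomp(elem)
            if rec["type"] == "full" and p.tsd_len > 0:
                # Nudge the site until the element boundary is identifiable:
                # coinciding edge nucleotides would make a (TSD, LTR)
                # assignment shifted by one base equally consistent with the
                # sequence, leaving the recorded truth ill-defined.
                l5 = rec["ltr_lens"][0] if rec["strand"] == "+" else rec["ltr_lens"][-1]
                l3 = rec["ltr_lens"][-1] if rec["strand"] == "+" else rec["ltr_lens"][0]
                for _ in range(50):
                    t = bg[site:site + p.tsd_len]
                    ok = (t[-1] != elem[len(elem) - l3 - 1]      # LTR3 pre-nt
                          and t[0] != elem[l5]                   # LTR5 post-nt
                          and bg[site + p.tsd_len] != elem[0]
                          and bg[site - 1] != elem[-1])
                    if ok:
                        break
                    site += 1
                rec["site"] = site
        parts.append(bg[cursor_bg:site])
        final_pos += site - cursor_bg
        if rec.get("is_window"):
            # segmental-duplication window: inserted as a plain block
            start0 = final_pos
            parts.append(elem)
            final_pos += len(elem)
            cursor_bg = site
            fl, tl = rec["flank"], p.tsd_len
            ltr_len = rec["ltr_lens"][0]
            ltr_start = start0 + fl + tl + 1
            truths.append(SimTruth(
                insertion_id=rec["id"], type="solo", contig=p.contig_name,
                position=ltr_start, end=ltr_start + ltr_len - 1,
                strand=rec["strand"], age_years=rec["age"],
                tsd=rec["tsd_src"],
                tsd5_interval=(start0 + fl + 1, start0 + fl + tl),
                tsd3_interval=(ltr_start + ltr_len, ltr_start + ltr_len + tl - 1),
                ltr_intervals=[(ltr_start, ltr_start + ltr_len - 1)],
                duplication_partner=rec.get("partner") or rec["id"].rstrip("b"),
                duplication_age_years=rec["dup_age"]))
            continue
        tsd_src = bg[site:site + p.tsd_len]
        left = mutate_neutral(tsd_src, p.mu, rec["age"], rng)
        right = mutate_neutral(tsd_src, p.mu, rec["age"], rng)
        tsd5 = (final_pos + 1, final_pos + p.tsd_len) if p.tsd_len else None
        parts.append(left)
        final_pos += len(left)
        elem_start = final_pos + 1
        parts.append(elem)
        final_pos += len(elem)
        elem_end = final_pos
        tsd3 = (final_pos + 1, final_pos + p.tsd_len) if p.tsd_len else None
        parts.append(right)
        final_pos += len(right)
        cursor_bg = site + p.tsd_len

        l5, *rest = rec["ltr_lens"]
        nested_ivs: list[tuple[int, int]] = []
        if rec["type"] == "full":
            l3 = rest[0]
            if rec["strand"] == "+":
                ltrs = [(elem_start, elem_start + l5 - 1),
                        (elem_end - l3 + 1, elem_end)]
            else:
                ltrs = [(elem_start, elem_start + l3 - 1),
                        (elem_end - l5 + 1, elem_end)]
            internal_iv = (ltrs[0][1] + 1, ltrs[1][0] - 1)
            elem_len = elem_end - elem_start + 1
            for (na, nb) in rec.get("nested", []):
                # nested coords are 1-based in the aged internal region
                if rec["strand"] == "+":
                    a0 = elem_start + l5 + na - 1
                    b0 = elem_start + l5 + nb - 1
                else:
                    b0 = elem_start + (elem_len - l5 - na)
                    a0 = elem_start + (elem_len - l5 - nb)
                nested_ivs.append((a0, b0))
        else:
            ltrs = [(elem_start, elem_end)]
            internal_iv = None
        truths.append(SimTruth(
            insertion_id=rec["id"], type=rec["type"], contig=p.contig_name,
            position=elem_start, end=elem_end, strand=rec["strand"],
            age_years=rec["age"], tsd=tsd_src,
            tsd5_interval=tsd5, tsd3_interval=tsd3,
            ltr_intervals=ltrs, internal_interval=internal_iv,
            nested_intervals=sorted(nested_ivs)))
    parts.append(bg[cursor_bg:])
    contigs = {p.contig_name: "".join(parts)}

    # ---- empty pre-integration contigs ----------------------------------
    for rec, truth in zip(roster, truths):
        if rec.get("is_window"):
            continue
        if rng.random() >= p.empty_site_fraction:
            continue
        site = rec["site"]
        fl_l = bg[max(0, site - 600):site]
        fl_r = bg[site + p.tsd_len:site + p.tsd_len + 600]
        if len(fl_l) < 50 or len(fl_r) < 50:
            continue
        empty = fl_l + bg[site:site + p.tsd_len] + fl_r
        if p.empty_site_divergence > 0:
            # convert the target ortholog divergence into a JC pseudo-time
            d = min(p.empty_site_divergence, 0.70)
            t_pseudo = -3.0 / (4.0 * p.mu) * math.log(1.0 - 4.0 * d / 3.0)
            empty = mutate_neutral(empty, p.mu, t_pseudo, rng)
        name = f"empty_{rec['id']}"
        contigs[name] = empty
        truth.empty_site_contig = name
    return contigs, truths


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def write_fasta(contigs: dict[str, str], path, width: int = 80) -> None:
    with open(path, "w") as fh:
        for name, seq in contigs.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_fasta(path) -> dict[str, str]:
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_truth_gff3(truths: list[SimTruth], path) -> None:
    """One feature line per element, LTR and TSD (GFF3, 1-based inclusive)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for t in truths:
            attrs = (f"ID={t.insertion_id};element_type={t.type};"
                     f"age_years={t.age_years:.0f};tsd={t.tsd}")
            fh.write("\t".join([t.contig, "ervkit_sim",
                                "provirus" if t.type == "full" else "solo_LTR",
                                str(t.position), str(t.end), ".", t.strand, ".",
                                attrs]) + "\n")
            for j, (a, b) in enumerate(t.ltr_intervals):
                fh.write("\t".join([t.contig, "ervkit_sim", "long_terminal_repeat",
                                    str(a), str(b), ".", t.strand, ".",
                                    f"Parent={t.insertion_id};ltr_index={j}"]) + "\n")
            for iv, tag in ((t.tsd5_interval, "tsd5"), (t.tsd3_interval, "tsd3")):
                if iv:
                    fh.write("\t".join([t.contig, "ervkit_sim",
                                        "target_site_duplication",
                                        str(iv[0]), str(iv[1]), ".", "+", ".",
                                        f"Parent={t.insertion_id};side={tag}"]) + "\n")


def write_truth_json(truths: list[SimTruth], path) -> None:
    with open(path, "w") as fh:
        json.dump([dataclasses.asdict(t) for t in truths], fh, indent=1)


def write_config(params: SimParams, path) -> None:
    with open(path, "w") as fh:
        for f in dataclasses.fields(params):
            fh.write(f"{f.name}={getattr(params, f.name)!r}\n")


def read_config(path) -> SimParams:
    import ast

    kv = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if line and not line.startswith("#"):
                k, v = line.split("=", 1)
                kv[k] = ast.literal_eval(v)
    return SimParams(**kv)
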