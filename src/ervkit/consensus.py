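"""Consensus reconstruction from multiple defective element copies.

Ancient proviruses are recovered as a handful of copies, each wrecked by a
*different* set of substitutions, indels and nested insertions; because the
defects are copy-specific, a column-wise majority over an alignment of the
copies recovers the ancestral element essentially exactly once three or more
copies are available.

The multiple alignment is a deterministic center-star: the member with the
highest summed pairwise identity is the center, every other member is
pairwise-aligned to it (fragments semi-globally, so their terminal gaps are
free), and the pairwise alignments are merged by gap propagation.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import edlib

__all__ = ["CopyMember", "CopySet", "Msa", "ConsensusResult",
           "build_msa", "majority_consensus", "reconstruct_consensus",
           "write_alignment_fasta", "write_support_tsv"]

_GAP = "-"


@dataclass(frozen=True)
class CopyMember:
    id: str
    sequence: str
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.weight <= 0:
            raise ValueError("weights must be positive")


@dataclass
class CopySet:
    members: list[CopyMember]
    anchor: str | None = None          # optional member id forced as center

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("CopySet needs at least one member")


@dataclass
class Msa:
    ids: list[str]
    rows: list[str]                    # aligned, equal length
    center_id: str

    @property
    def n_cols(self) -> int:
        return len(self.rows[0]) if self.rows else 0


@dataclass
class ConsensusResult:
    sequence: str
    support: list[float]               # per consensus column, in (0, 1]
    low_confidence: list[bool]
    column_map: list[dict[str, int | None]]  # consensus pos -> member pos (1-based)


def _identity(a: str, b: str) -> float:
    d = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - d / max(len(a), len(b))


def _pairwise_to_center(center: str, member: str) -> tuple[str, str]:
    """Align member to center; fragments get free terminal gaps."""
    fragment = len(member) < 0.8 * len(center)
    mode = "HW" if fragment else "NW"
    res = edlib.align(member, center, mode=mode, task="path")
    nice = edlib.getNiceAlignment(res, member, center)
    m_aln, c_aln = nice["query_aligned"], nice["target_aligned"]
    if mode == "HW":
        t0, t1 = res["locations"][0]
        m_aln = _GAP * t0 + m_aln + _GAP * (len(center) - t1 - 1)
        c_aln = center[:t0] + c_aln + center[t1 + 1:]
    return c_aln, m_aln


def build_msa(copies: CopySet) -> Msa:
    """Deterministic center-star multiple alignment of a copy set."""
    members = copies.members
    if len(members) == 1:
        return Msa(ids=[members[0].id], rows=[members[0].sequence],
                   center_id=members[0].id)
    if copies.anchor is not None:
        center_idx = next(i for i, m in enumerate(members)
                          if m.id == copies.anchor)
    else:
        sums = []
        for i, mi in enumerate(members):
            s = sum(_identity(mi.sequence, mj.sequence)
                    for j, mj in enumerate(members) if j != i)
            sums.append((-s, i))
        center_idx = min(sums)[1]
    center = members[center_idx]

    master = list(center.sequence)          # center row with accumulated gaps
    rows: dict[str, list[str]] = {center.id: list(center.sequence)}
    order = [center.id]
    for m in members:
        if m.id == center.id:
            continue
        c_aln, m_aln = _pairwise_to_center(center.sequence, m.sequence)
        new_master: list[str] = []
        new_row: list[str] = []
        grows: dict[str, list[str]] = {k: [] for k in rows}
        i = j = 0
        while i < len(master) or j < len(c_aln):
            mi = master[i] if i < len(master) else None
            cj = c_aln[j] if j < len(c_aln) else None
            if mi == _GAP and cj == _GAP:
                new_master.append(_GAP)
                for k in grows:
                    grows[k].append(rows[k][i])
                new_row.append(m_aln[j])
                i += 1
                j += 1
            elif mi == _GAP:
                new_master.append(_GAP)
                for k in grows:
                    grows[k].append(rows[k][i])
                new_row.append(_GAP)
                i += 1
            elif cj == _GAP:
                new_master.append(_GAP)
                for k in grows:
                    grows[k].append(_GAP)
                new_row.append(m_aln[j])
                j += 1
            else:
                new_master.append(mi)
                for k in grows:
                    grows[k].append(rows[k][i])
                new_row.append(m_aln[j])
                i += 1
                j += 1
        master = new_master
        rows = grows
        rows[m.id] = new_row
        order.append(m.id)
    id_order = [m.id for m in members]
    return Msa(ids=id_order, rows=["".join(rows[i]) for i in id_order],
               center_id=center.id)


_TIE_ORDER = {c: i for i, c in enumerate("ACGT")}
_IUPAC = {
    frozenset("AG"): "R", frozenset("CT"): "Y", frozenset("AC"): "M",
    frozenset("GT"): "K", frozenset("CG"): "S", frozenset("AT"): "W",
    frozenset("ACG"): "V", frozenset("ACT"): "H", frozenset("AGT"): "D",
    frozenset("CGT"): "B", frozenset("ACGT"): "N",
}


def majority_consensus(msa: Msa, min_support: float = 0.5,
                       weights: dict[str, float] | None = None,
                       ambiguity: bool = False) -> ConsensusResult:
    """Column-wise majority consensus of an alignment.

    The gap is an ordinary symbol but loses every tie; base ties break
    alphabetically (A<C<G<T), or emit an IUPAC ambiguity code when
    ``ambiguity`` is on.  Gap-majority columns are dropped.  Columns whose
    winner falls below ``min_support`` are kept but flagged low-confidence.
    """
    weights = weights or {}
    n = len(msa.rows)
    member_pos = [0] * n
    seq_chars: list[str] = []
    support: list[float] = []
    low: list[bool] = []
    column_map: list[dict[str, int | None]] = []
    total_w = sum(weights.get(i, 1.0) for i in msa.ids)
    for col in range(msa.n_cols):
        counts: dict[str, float] = {}
        col_pos: dict[str, int | None] = {}
        for r in range(n):
            ch = msa.rows[r][col].upper()
            w = weights.get(msa.ids[r], 1.0)
            counts[ch] = counts.get(ch, 0.0) + w
            if ch != _GAP:
                member_pos[r] += 1
                col_pos[msa.ids[r]] = member_pos[r]
            else:
                col_pos[msa.ids[r]] = None
        base_counts = {c: v for c, v in counts.items() if c != _GAP}
        gap_count = counts.get(_GAP, 0.0)
        if not base_counts or gap_count > max(base_counts.values()):
            continue  # gap-majority column dropped (gap loses exact ties)
        top = max(base_counts.values())
        winners = sorted((c for c, v in base_counts.items() if v == top),
                         key=lambda c: _TIE_ORDER.get(c, 99))
        if ambiguity and len(winners) > 1:
            ch = _IUPAC.get(frozenset(winners), winners[0])
        else:
            ch = winners[0]
        seq_chars.append(ch)
        support.append(top / total_w)
        low.append(top / total_w < min_support)
        column_map.append(col_pos)
    return ConsensusResult(sequence="".join(seq_chars), support=support,
                           low_confidence=low, column_map=column_map)


def reconstruct_consensus(copies: CopySet, rounds: int = 2,
                          min_support: float = 0.5,
                          ambiguity: bool = False) -> ConsensusResult:
    """Center-star consensus with iterative refinement.

    After the first majority consensus, members are re-aligned against it
    (as a non-voting center) and the majority is taken again.  This heals
    the center-star artefact where equivalent insertions from different
    members land in adjacent gap columns and are individually outvoted.
    """
    res = majority_consensus(build_msa(copies), min_support, ambiguity=ambiguity)
    for _ in range(max(0, rounds - 1)):
        members = [CopyMember("__center__", res.sequence)] + copies.members
        msa = build_msa(CopySet(members=members, anchor="__center__"))
        res = majority_consensus(msa, min_support,
                                 weights={"__center__": 1e-9},
                                 ambiguity=ambiguity)
    return res


def write_alignment_fasta(msa: Msa, path) -> None:
    with open(path, "w") as fh:
        for i, row in zip(msa.ids, msa.rows):
            fh.write(f">{i}\n{row}\n")


def write_support_tsv(result: ConsensusResult, path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tbase\tsupport\tlow_confidence\n")
        for i, (b, s, l) in enumerate(zip(result.sequence, result.support,
                                          result.low_confidence), 1):
            fh.write(f"{i}\t{b}\t{s:.3f}\t{int(l)}\n")
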