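"""End-to-end discovery workflow: simulate → screen → structure → consensus
→ annotate → date → phylo.

Each stage is a standalone function that reads its inputs from files in a
run directory and writes its outputs (plus an entry in ``manifest.json``)
back, so any stage can be re-run in isolation and reproduces its outputs
byte-for-byte for a fixed seed.  `run_discovery_pipeline` chains the enabled
stages; all thresholds default to the classical screen settings (forward
E < 1e-5, 100-bit confidence, solo filters E < 1e-100 / identity ≥ 0.80 /
coverage ≥ 0.50, neutral rates 2.2–4.5e-9 per site per year).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

from . import annotate as annotate_mod
from . import bbhscreen, consensus, ervstruct, ltrclock, panels, phylo
from . import simgenome as sim
from ._seq import revcomp, translate
from .seqsearch import write_hits_tsv

__all__ = ["RunConfig", "run_discovery_pipeline", "STAGES",
           "stage_simulate", "stage_screen", "stage_structure",
           "stage_consensus", "stage_annotate", "stage_date", "stage_phylo"]

STAGES = ("simulate", "screen", "structure", "consensus", "annotate",
          "date", "phylo")


@dataclass
class RunConfig:
    seed: int = 0
    stages: tuple[str, ...] = STAGES
    genome_fasta: str | None = None     # skip simulation, screen this instead
    sim_params: sim.SimParams | None = None
    e_cut: float = 1e-5
    bit_threshold: float = 100.0
    solo_filters: ervstruct.SoloFilters = field(default_factory=ervstruct.SoloFilters)
    struct_config: ervstruct.StructConfig = field(default_factory=ervstruct.StructConfig)
    rate_low: float = ltrclock.RATE_LOW
    rate_high: float = ltrclock.RATE_HIGH
    bootstrap_reps: int = 1000
    panel_seed: int = panels.DEFAULT_PANEL_SEED

    def __post_init__(self) -> None:
        bad = set(self.stages) - set(STAGES)
        if bad:
            raise ValueError(f"unknown stages: {sorted(bad)}")
        if self.sim_params is None:
            self.sim_params = sim.SimParams(seed=self.seed)


def _manifest_update(outdir: Path, stage: str, entry: dict) -> None:
    path = outdir / "manifest.json"
    manifest = json.loads(path.read_text()) if path.exists() else {"stages": {}}
    manifest["stages"][stage] = entry
    path.write_text(json.dumps(manifest, indent=1, sort_keys=True))


def _write_json(path: Path, obj) -> None:
    path.write_text(json.dumps(obj, indent=1, sort_keys=True))


# ---------------------------------------------------------------------------
# stages
# ---------------------------------------------------------------------------

def stage_simulate(outdir: Path, cfg: RunConfig) -> dict:
    """Generate the synthetic genome (template pol pinned to the bundled
    lentiviral representative so the screen has a real target)."""
    outdir.mkdir(parents=True, exist_ok=True)
    lenti_pol = panels.genus_representatives(cfg.panel_seed)["lentivirus"]
    template = sim.make_provirus_template(seed=cfg.seed, pol_protein=lenti_pol)
    contigs, truths = sim.simulate_genome(cfg.sim_params, template)
    sim.write_fasta(contigs, outdir / "genome.fasta")
    sim.write_fasta({"template": template.sequence,
                     "template_ltr": template.ltr_seq},
                    outdir / "template.fasta")
    sim.write_truth_gff3(truths, outdir / "truth.gff3")
    sim.write_truth_json(truths, outdir / "truth.json")
    sim.write_config(cfg.sim_params, outdir / "sim_config.txt")
    entry = {"outputs": ["genome.fasta", "template.fasta", "truth.gff3",
                         "truth.json", "sim_config.txt"],
             "seed": cfg.seed, "n_truth": len(truths), "status": "ok"}
    _manifest_update(outdir, "simulate", entry)
    return entry


def _load_genome(outdir: Path, cfg: RunConfig) -> dict[str, str]:
    if cfg.genome_fasta is not None:
        return sim.read_fasta(cfg.genome_fasta)
    return sim.read_fasta(outdir / "genome.fasta")


def stage_screen(outdir: Path, cfg: RunConfig) -> dict:
    contigs = _load_genome(outdir, cfg)
    baits = panels.make_lentivirus_baits(cfg.panel_seed)
    panel = panels.make_pol_panel(cfg.panel_seed)
    sc = bbhscreen.ScreenConfig(e_cut=cfg.e_cut, bit_threshold=cfg.bit_threshold)
    report = bbhscreen.screen_genome(contigs, baits, panel, sc)
    write_hits_tsv([l.best.hit for l in report.loci], outdir / "screen_hits.tsv")
    loci = [{"contig": l.contig, "start": l.start, "end": l.end,
             "strand": l.strand, "n_hits": l.n_hits,
             "candidate": l.is_lentiviral_candidate,
             "confidence": l.best.confidence,
             "backward_genus": l.best.backward_genus,
             "backward_bits": round(l.best.backward_bits, 1)}
            for l in report.loci]
    _write_json(outdir / "loci.json", loci)
    _write_json(outdir / "screen_summary.json", report.summary())
    entry = {"outputs": ["screen_hits.tsv", "loci.json", "screen_summary.json"],
             "thresholds": {"e_cut": cfg.e_cut, "bit": cfg.bit_threshold},
             "summary": report.summary(), "status": "ok"}
    _manifest_update(outdir, "screen", entry)
    return entry


def stage_structure(outdir: Path, cfg: RunConfig) -> dict:
    contigs = _load_genome(outdir, cfg)
    loci = json.loads((outdir / "loci.json").read_text())
    # merge nearby candidate loci first: nested insertions can split one
    # provirus's homology hits into several anchors
    anchors: list[dict] = []
    for l in sorted((l for l in loci if l["candidate"]),
                    key=lambda l: (l["contig"], l["strand"], l["start"])):
        prev = anchors[-1] if anchors else None
        if (prev and prev["contig"] == l["contig"]
                and prev["strand"] == l["strand"]
                and l["start"] - prev["end"] <= 5000):
            prev["end"] = max(prev["end"], l["end"])
        else:
            anchors.append(dict(l))
    scored: list[tuple] = []
    for a in anchors:
        found = ervstruct.find_ltr_pairs(
            contigs[a["contig"]], (a["start"], a["end"]), cfg.struct_config,
            contig_name=a["contig"], strand_hint=a["strand"])
        for c in found:
            # the protein-homology anchor must sit inside the internal
            # region of a genuine provirus; repeats that only straddle it
            # (e.g. paired nested elements) rank below and drop on overlap
            contains = (c.ltr5_interval[1] <= a["start"] + 50
                        and c.ltr3_interval[0] >= a["end"] - 50)
            scored.append((c, contains))
    scored.sort(key=lambda t: (not t[1], t[0].tsd is None,
                               -(t[0].end - t[0].start)))
    calls: list[ervstruct.ProvirusCall] = []
    for c, _ in scored:
        if any(k.contig == c.contig and c.start <= k.end and c.end >= k.start
               for k in calls):
            continue
        calls.append(c)
    calls.sort(key=lambda c: (c.contig, c.start))

    solo_calls: list[ervstruct.SoloLTRCall] = []
    ref_ltr = None
    if calls:
        best = max(calls, key=lambda c: c.ltr_identity)
        a, b = best.ltr5_interval
        ref_ltr = contigs[best.contig][a - 1:b]
        if best.strand == "-":
            ref_ltr = revcomp(ref_ltr)
        sim.write_fasta({"reference_ltr": ref_ltr}, outdir / "reference_ltr.fasta")
        exclude = {}
        for c in calls:
            exclude.setdefault(c.contig, []).extend(
                [c.ltr5_interval, c.ltr3_interval])
        solo_calls = ervstruct.scan_solo_ltrs(contigs, ref_ltr,
                                              cfg.solo_filters, exclude)
    _write_json(outdir / "provirus_calls.json", [
        {"contig": c.contig, "start": c.start, "end": c.end,
         "strand": c.strand, "ltr5": list(c.ltr5_interval),
         "ltr3": list(c.ltr3_interval),
         "ltr_identity": round(c.ltr_identity, 4),
         "tsd": dataclasses.asdict(c.tsd) if c.tsd else None}
        for c in calls])
    _write_json(outdir / "solo_calls.json", [
        {"contig": s.contig, "start": s.start, "end": s.end,
         "strand": s.strand, "identity": round(s.identity_to_reference, 4),
         "coverage": round(s.coverage_of_reference, 4),
         "evalue": s.evalue,
         "tsd": dataclasses.asdict(s.tsd) if s.tsd else None}
        for s in solo_calls])
    with open(outdir / "structure.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for i, c in enumerate(calls, 1):
            fh.write("\t".join([c.contig, "ervkit", "provirus", str(c.start),
                                str(c.end), ".", c.strand, ".",
                                f"ID=provirus_{i};ltr_identity={c.ltr_identity:.4f}"])
                     + "\n")
        for i, s in enumerate(solo_calls, 1):
            fh.write("\t".join([s.contig, "ervkit", "solo_LTR", str(s.start),
                                str(s.end), ".", s.strand, ".",
                                f"ID=solo_{i};identity={s.identity_to_reference:.4f}"])
                     + "\n")
    entry = {"outputs": ["provirus_calls.json", "solo_calls.json",
                         "structure.gff3"],
             "n_proviruses": len(calls), "n_solo": len(solo_calls),
             "solo_to_full_ratio": (round(len(solo_calls) / len(calls), 2)
                                    if calls else None),
             "status": "ok"}
    _manifest_update(outdir, "structure", entry)
    return entry


def stage_consensus(outdir: Path, cfg: RunConfig) -> dict:
    contigs = _load_genome(outdir, cfg)
    calls = json.loads((outdir / "provirus_calls.json").read_text())
    members = []
    for i, c in enumerate(calls, 1):
        seq = contigs[c["contig"]][c["start"] - 1:c["end"]]
        if c["strand"] == "-":
            seq = revcomp(seq)
        members.append(consensus.CopyMember(id=f"provirus_{i}", sequence=seq))
    if not members:
        entry = {"outputs": [], "status": "skipped: no provirus calls"}
        _manifest_update(outdir, "consensus", entry)
        return entry
    sim.write_fasta({m.id: m.sequence for m in members}, outdir / "copies.fasta")
    msa = consensus.build_msa(consensus.CopySet(members=members))
    res = consensus.majority_consensus(msa)
    consensus.write_alignment_fasta(msa, outdir / "alignment.fasta")
    sim.write_fasta({"consensus": res.sequence}, outdir / "consensus.fasta")
    consensus.write_support_tsv(res, outdir / "support.tsv")
    entry = {"outputs": ["copies.fasta", "alignment.fasta", "consensus.fasta",
                         "support.tsv"],
             "consensus_length": len(res.sequence),
             "n_copies": len(members), "status": "ok"}
    _manifest_update(outdir, "consensus", entry)
    return entry


def stage_annotate(outdir: Path, cfg: RunConfig) -> dict:
    cons = sim.read_fasta(outdir / "consensus.fasta")["consensus"]
    calls = json.loads((outdir / "provirus_calls.json").read_text())
    ltr_lens = [c["ltr5"][1] - c["ltr5"][0] + 1 for c in calls]
    ltr_len = round(sum(ltr_lens) / len(ltr_lens)) if ltr_lens else 420
    ann = annotate_mod.annotate_provirus(cons, ltr_len)
    _write_json(outdir / "annotation.json", {
        "ltr_len": ltr_len,
        "orfs": [dataclasses.asdict(o) for o in ann["orfs"]],
        "features": [dataclasses.asdict(f) for f in ann["features"]],
    })
    with open(outdir / "annotation.gff3", "w") as fh:
        fh.write("##gff-version 3\n")
        for o in ann["orfs"]:
            nm = o.name or o.label
            fh.write("\t".join(["consensus", "ervkit", "ORF", str(o.start),
                                str(o.end), ".", o.strand, ".",
                                f"Name={nm};label={o.label};aa={o.length_aa}"])
                     + "\n")
        for f in ann["features"]:
            fh.write("\t".join(["consensus", "ervkit", f.kind, str(f.start),
                                str(f.end), ".", "+", ".",
                                f"Name={f.kind}"]) + "\n")
    labels = sorted({o.label for o in ann["orfs"]
                     if o.label in ("gag", "pol", "env")})
    entry = {"outputs": ["annotation.json", "annotation.gff3"],
             "long_orfs": labels,
             "features": sorted({f.kind for f in ann["features"]}),
             "status": "ok"}
    _manifest_update(outdir, "annotate", entry)
    return entry


def stage_date(outdir: Path, cfg: RunConfig) -> dict:
    contigs = _load_genome(outdir, cfg)
    calls = json.loads((outdir / "provirus_calls.json").read_text())
    rows = []
    for i, c in enumerate(calls, 1):
        seq = contigs[c["contig"]]
        l5 = seq[c["ltr5"][0] - 1:c["ltr5"][1]]
        l3 = seq[c["ltr3"][0] - 1:c["ltr3"][1]]
        est = ltrclock.date_ltr_pair(l5, l3, cfg.rate_low, cfg.rate_high)
        rows.append({"provirus": f"provirus_{i}", "D": est.d_count,
                     "L": est.aligned_len, "t_low_mya": est.t_low_mya,
                     "t_high_mya": est.t_high_mya})
    _write_json(outdir / "ages.json", rows)
    with open(outdir / "ages.tsv", "w") as fh:
        fh.write("provirus\tD\tL\tt_low_mya\tt_high_mya\n")
        for r in rows:
            fh.write(f"{r['provirus']}\t{r['D']}\t{r['L']}\t"
                     f"{r['t_low_mya']}\t{r['t_high_mya']}\n")
    entry = {"outputs": ["ages.json", "ages.tsv"], "n_dated": len(rows),
             "rates": [cfg.rate_low, cfg.rate_high], "status": "ok"}
    _manifest_update(outdir, "date", entry)
    return entry


def _consensus_pol_protein(outdir: Path, cfg: RunConfig) -> str | None:
    """Pol protein of the consensus: the labelled ORF when intact, else the
    Pol region extracted by homology (translated search with the bundled
    lentiviral representative) — ancient elements usually carry nonsense
    defects, so the homology route is the common one."""
    ann = json.loads((outdir / "annotation.json").read_text())
    cons = sim.read_fasta(outdir / "consensus.fasta")["consensus"]
    for o in ann["orfs"]:
        if o["label"] == "pol":
            seq = cons[o["start"] - 1:o["end"]]
            if o["strand"] == "-":
                seq = revcomp(seq)
            aa = translate(seq)
            return aa[:-1] if aa.endswith("*") else aa
    from .seqsearch import translated_search

    rep = panels.genus_representatives(cfg.panel_seed)["lentivirus"]
    hits = translated_search(rep, cons, min_segment_aa=30)
    hits = [h for h in hits if len(h.subject_segment()) >= 100]
    if not hits:
        return None
    # stitch the translated segments of same-strand hits in genomic order
    strand = hits[0].strand
    picked = sorted((h for h in hits if h.strand == strand),
                    key=lambda h: h.s_start)
    merged: list = []
    for h in picked:
        if merged and h.s_start <= merged[-1].s_end:
            continue
        merged.append(h)
    return "".join(h.subject_segment() for h in merged)


def stage_phylo(outdir: Path, cfg: RunConfig) -> dict:
    """Place the recovered element's Pol among the all-genera panel and
    report inter-provirus nucleotide distances from the copies alignment."""
    pol = _consensus_pol_protein(outdir, cfg)
    entry: dict = {"outputs": [], "status": "ok"}
    if pol is not None:
        panel = panels.make_pol_panel(cfg.panel_seed, n_per_genus=2)
        members = ([consensus.CopyMember(id="candidate_element", sequence=pol)]
                   + [consensus.CopyMember(id=e.name, sequence=e.sequence)
                      for e in panel])
        msa = consensus.build_msa(consensus.CopySet(members=members))
        alignment = dict(zip(msa.ids, msa.rows))
        tree = phylo.bootstrap_support(alignment, model="poisson",
                                       n_reps=cfg.bootstrap_reps,
                                       seed=cfg.seed)
        (outdir / "tree.nwk").write_text(tree.newick())
        lenti = {e.name for e in panel if e.genus == "lentivirus"}
        mono, _ = phylo.check_monophyly(tree, lenti | {"candidate_element"})
        clade = lenti | {"candidate_element"}
        support = None
        for side, node in tree.bipartitions().items():
            if side == clade or frozenset(tree.leaves()) - side == clade:
                support = node.support
        entry["outputs"].append("tree.nwk")
        entry["lentivirus_clade_monophyletic"] = bool(mono)
        entry["lentivirus_clade_support"] = support
    aln_path = outdir / "alignment.fasta"
    if aln_path.exists():
        copies = sim.read_fasta(aln_path)
        if len(copies) >= 2:
            dm = phylo.distance_matrix(copies, model="p")
            with open(outdir / "distances.tsv", "w") as fh:
                fh.write("taxon\t" + "\t".join(dm.taxa) + "\n")
                for i, t in enumerate(dm.taxa):
                    fh.write(t + "\t" + "\t".join(
                        f"{dm.values[i, j]:.4f}" for j in range(len(dm.taxa)))
                        + "\n")
            off = dm.values[~(dm.values == 0)]
            entry["outputs"].append("distances.tsv")
            entry["interprovirus_distance_range"] = [
                round(float(off.min()), 4), round(float(off.max()), 4)]
    _manifest_update(outdir, "phylo", entry)
    return entry


_STAGE_FUNCS = {
    "simulate": stage_simulate,
    "screen": stage_screen,
    "structure": stage_structure,
    "consensus": stage_consensus,
    "annotate": stage_annotate,
    "date": stage_date,
    "phylo": stage_phylo,
}


def run_discovery_pipeline(cfg: RunConfig, outdir) -> dict:
    """Run the enabled stages in order; returns the final manifest dict.

    A stage failure marks the manifest and re-raises; outputs of completed
    stages are preserved.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    enabled = [s for s in STAGES if s in cfg.stages]
    if cfg.genome_fasta is not None:
        enabled = [s for s in enabled if s != "simulate"]
    for stage in enabled:
        try:
            _STAGE_FUNCS[stage](outdir, cfg)
        except Exception as exc:
            _manifest_update(outdir, stage,
                             {"status": f"failed: {exc}", "outputs": []})
            raise
    path = outdir / "manifest.json"
    return json.loads(path.read_text()) if path.exists() else {"stages": {}}
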