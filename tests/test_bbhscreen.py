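"""BBH screen: forward sensitivity, backward classification, locus merging."""

import numpy as np
import pytest

from ervkit import bbhscreen as bb
from ervkit import panels, simgenome as sg
from ervkit._seq import mutate_protein, random_dna, revcomp


@pytest.fixture(scope="module")
def lenti_genome(template):
    params = sg.SimParams(seed=31, n_full=1, n_solo=0, n_dup_pairs=0,
                          ages=[5e6], genome_len=30_000,
                          empty_site_fraction=0.0)
    return sg.simulate_genome(params, template)


class TestForwardScan:
    def test_implant_recovered(self, lenti_genome, bait_panel):
        contigs, truths = lenti_genome
        hits = bb.forward_scan(contigs, bait_panel, e_cut=1e-5)
        t = truths[0]
        assert any(h.s_start <= t.end and h.s_end >= t.position for h in hits)
        assert all(h.evalue < 1e-5 for h in hits)

    def test_background_only_clean(self, bait_panel):
        contigs = {"bg": random_dna(np.random.default_rng(0), 30_000, 0.4)}
        hits = bb.forward_scan(contigs, bait_panel, e_cut=1e-5)
        assert hits == []

    def test_host_species_bait_exclusion(self, lenti_genome, bait_panel):
        contigs, _ = lenti_genome
        all_hits = bb.forward_scan(contigs, bait_panel)
        excluded = bait_panel.exclusion_map["ferret"]
        hits = bb.forward_scan(contigs, bait_panel, host_species="ferret")
        assert any(h.query_id in excluded for h in all_hits)
        assert not any(h.query_id in excluded for h in hits)

    def test_empty_panel_rejected(self, lenti_genome):
        contigs, _ = lenti_genome
        with pytest.raises(ValueError):
            bb.forward_scan(contigs, panels.BaitPanel(entries=[]))


class TestBackwardClassify:
    def test_self_retrieval(self, pol_panel):
        from ervkit.seqsearch import AlignmentResult

        entry = pol_panel[0]
        segment = entry.sequence[100:300]
        hit = AlignmentResult(query_id="b", subject_id="c", q_start=1,
                              q_end=200, s_start=1, s_end=600, strand="+",
                              frame=1, raw_score=0, bit_score=0, evalue=0,
                              identity=1, coverage=1, q_aln=segment,
                              s_aln=segment)
        rec = bb.backward_classify(hit, pol_panel)
        assert rec.backward_name == entry.name
        assert rec.is_lentiviral_candidate == (entry.genus == "lentivirus")
        assert rec.confidence == "high"

    def test_gamma_segment_not_candidate(self, pol_panel, genus_reps):
        from ervkit.seqsearch import AlignmentResult

        seg = mutate_protein(np.random.default_rng(3),
                             genus_reps["gammaretrovirus"], 0.1)[50:400]
        hit = AlignmentResult(query_id="b", subject_id="c", q_start=1,
                              q_end=350, s_start=1, s_end=1050, strand="+",
                              frame=1, raw_score=0, bit_score=0, evalue=0,
                              identity=1, coverage=1, q_aln=seg, s_aln=seg)
        rec = bb.backward_classify(hit, pol_panel)
        assert rec.backward_genus == "gammaretrovirus"
        assert not rec.is_lentiviral_candidate

    def test_short_segment_low_confidence_with_warning(self, pol_panel):
        from ervkit.seqsearch import AlignmentResult

        hit = AlignmentResult(query_id="b", subject_id="c", q_start=1,
                              q_end=5, s_start=1, s_end=15, strand="+",
                              frame=1, raw_score=0, bit_score=0, evalue=0,
                              identity=1, coverage=1, q_aln="MKVLI",
                              s_aln="MKVLI")
        with pytest.warns(UserWarning):
            rec = bb.backward_classify(hit, pol_panel)
        assert rec.confidence == "low"
        assert not rec.is_lentiviral_candidate

    def test_tie_break_deterministic(self):
        from ervkit.seqsearch import AlignmentResult

        seg = "M" + "ACDEFGHIKL" * 20
        panel = [panels.PanelEntry("z_entry", "lentivirus", seg),
                 panels.PanelEntry("a_entry", "gammaretrovirus", seg)]
        hit = AlignmentResult(query_id="b", subject_id="c", q_start=1,
                              q_end=len(seg), s_start=1, s_end=3 * len(seg),
                              strand="+", frame=1, raw_score=0, bit_score=0,
                              evalue=0, identity=1, coverage=1, q_aln=seg,
                              s_aln=seg)
        rec = bb.backward_classify(hit, panel)
        assert rec.backward_name == "a_entry"  # lexicographic on exact tie


class TestScreenGenome:
    def test_single_candidate_locus(self, lenti_genome, bait_panel, pol_panel):
        contigs, truths = lenti_genome
        report = bb.screen_genome(contigs, bait_panel, pol_panel)
        cands = report.candidates
        assert len(cands) == 1
        t = truths[0]
        assert cands[0].start <= t.end and cands[0].end >= t.position
        assert cands[0].best.confidence == "high"

    def test_empty_genome(self, bait_panel, pol_panel):
        report = bb.screen_genome({}, bait_panel, pol_panel)
        assert report.loci == []
        assert report.summary()["n_candidates"] == 0

    def test_contig_order_and_strand_invariance(self, template, bait_panel,
                                                pol_panel):
        params = sg.SimParams(seed=37, n_full=1, n_solo=0, n_dup_pairs=0,
                              ages=[4e6], genome_len=22_000,
                              empty_site_fraction=0.0)
        contigs, _ = sg.simulate_genome(params, template)
        extra = {"decoy": random_dna(np.random.default_rng(4), 8000, 0.4)}
        g1 = dict(contigs, **extra)
        g2 = dict(extra, **contigs)
        r1 = bb.screen_genome(g1, bait_panel, pol_panel)
        r2 = bb.screen_genome(g2, bait_panel, pol_panel)
        key = lambda r: [(l.contig, l.start, l.end, l.is_lentiviral_candidate)
                         for l in sorted(r.loci, key=lambda x: (x.contig, x.start))]
        assert key(r1) == key(r2)
        flipped = {k: revcomp(v) for k, v in g1.items()}
        r3 = bb.screen_genome(flipped, bait_panel, pol_panel)
        assert ([l.is_lentiviral_candidate for l in r1.loci]
                == [l.is_lentiviral_candidate for l in r3.loci])
        assert len(r3.candidates) == len(r1.candidates)

    def test_abutting_hits_merge(self, pol_panel):
        # one implant split by a nonsense codon yields abutting hits that
        # must collapse into a single locus
        rng = np.random.default_rng(8)
        from ervkit._seq import AA20, random_protein

        prot = "M" + random_protein(rng, 400)
        tpl = sg.make_provirus_template(seed=4, l_ltr=150, l_internal=6500,
                                        pol_protein=prot)
        seq = list(tpl.sequence)
        pol = tpl.gene("pol")
        mid = pol.start - 1 + 3 * 200
        seq[mid:mid + 3] = "TAA"  # premature stop splits the ORF
        baits = panels.BaitPanel(
            entries=[panels.PanelEntry("bait", "lentivirus", prot)])
        report = bb.screen_genome({"c": "".join(seq)}, baits, pol_panel)
        assert report.n_forward_hits >= 2
        assert len([l for l in report.loci
                    if l.start <= pol.end and l.end >= pol.start]) == 1
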