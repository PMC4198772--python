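"""Simulator: template layout, neutral mutation, genome assembly and truth."""

import math

import numpy as np
import pytest

from ervkit import simgenome as sg
from ervkit._seq import random_dna, revcomp


class TestTemplate:
    def test_default_dimensions(self, template):
        assert template.l_ltr == 420
        assert len(template.internal_seq) == 9200
        assert template.length == 10_040
        assert template.sequence == (template.ltr_seq + template.internal_seq
                                     + template.ltr_seq)

    def test_deterministic(self, genus_reps):
        a = sg.make_provirus_template(seed=1, pol_protein=genus_reps["lentivirus"])
        b = sg.make_provirus_template(seed=1, pol_protein=genus_reps["lentivirus"])
        assert a.sequence == b.sequence
        assert a.gene_intervals == b.gene_intervals

    def test_gag_pol_frameshift_layout(self, template):
        gag, pol = template.gene("gag"), template.gene("pol")
        assert gag.frame != pol.frame
        overlap = min(gag.end, pol.end) - max(gag.start, pol.start) + 1
        assert overlap > 0
        # -1 ribosomal frameshift geometry
        assert (pol.start - gag.start) % 3 == 2

    def test_all_genes_are_open_frames(self, template):
        for g in template.gene_intervals:
            aa = template.protein(g.name)
            assert aa.startswith("M")
            assert "*" not in aa

    def test_pinned_pol_protein_mostly_preserved(self, genus_reps):
        pol = genus_reps["lentivirus"]
        tpl = sg.make_provirus_template(seed=7, pol_protein=pol)
        realized = tpl.protein("pol")
        assert len(realized) == len(pol)
        ident = sum(a == b for a, b in zip(realized, pol)) / len(pol)
        assert ident > 0.9  # overlap repairs may touch a few residues

    def test_sizing_error(self):
        with pytest.raises(sg.SizingError):
            sg.make_provirus_template(seed=0, l_ltr=420, l_internal=1000)
        with pytest.raises(sg.SizingError):
            sg.make_provirus_template(seed=0, l_ltr=50)


class TestMutateNeutral:
    def test_zero_time_identity(self, rng):
        s = random_dna(np.random.default_rng(0), 500)
        assert sg.mutate_neutral(s, 3e-9, 0.0, rng=1) == s

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            sg.mutate_neutral("ACGT" * 50, 3e-9, -1.0)

    def test_seed_determinism(self):
        s = random_dna(np.random.default_rng(2), 2000)
        assert (sg.mutate_neutral(s, 3e-9, 1e7, rng=5)
                == sg.mutate_neutral(s, 3e-9, 1e7, rng=5))

    def test_jukes_cantor_fraction(self):
        # closed form: p = 3/4 * (1 - exp(-4 mu t / 3)) ~ 0.0294
        L, mu, t = 100_000, 3e-9, 1e7
        s = random_dna(np.random.default_rng(0), L)
        out = sg.mutate_neutral(s, mu, t, rng=3)
        p_exp = sg.substitution_probability(mu, t)
        assert abs(p_exp - 0.0294) < 1e-3
        diff = sum(a != b for a, b in zip(s, out)) / L
        sd = math.sqrt(p_exp * (1 - p_exp) / L)
        assert abs(diff - p_exp) < 3 * sd

    def test_indels_change_length(self):
        s = random_dna(np.random.default_rng(1), 10_000)
        out = sg.mutate_neutral(s, 3e-9, 1e7, rng=4, indel_rate=1e-9)
        assert len(out) != len(s)


class TestSimulateGenome:
    def test_insertion_counts(self, template):
        p = sg.SimParams(seed=5, n_full=3, n_solo=100, n_dup_pairs=0,
                         genome_len=400_000, empty_site_fraction=0.0)
        _, truths = sg.simulate_genome(p, template)
        assert len(truths) == 103
        assert sum(t.type == "full" for t in truths) == 3

    def test_empty_simulation(self, template):
        p = sg.SimParams(seed=1, n_full=0, n_solo=0, n_dup_pairs=0,
                         genome_len=10_000, empty_site_fraction=0.0)
        contigs, truths = sg.simulate_genome(p, template)
        assert truths == []
        assert len(contigs["contig_1"]) == 10_000

    def test_zero_age_full_is_pristine(self, template):
        from conftest import zero_age_fixture

        contig, t = zero_age_fixture(template, seed=3)
        (a5, b5), (a3, b3) = t.ltr_intervals
        assert contig[a5 - 1:b5] == contig[a3 - 1:b3]
        assert contig[t.tsd5_interval[0] - 1:t.tsd5_interval[1]] == t.tsd
        assert contig[t.tsd3_interval[0] - 1:t.tsd3_interval[1]] == t.tsd
        elem = contig[t.position - 1:t.end]
        if t.strand == "-":
            elem = revcomp(elem)
        assert elem == template.sequence

    def test_truth_intervals_disjoint(self, small_sim):
        _, _, truths = small_sim
        ivs = sorted((t.position, t.end) for t in truths)
        for (a1, b1), (a2, b2) in zip(ivs, ivs[1:]):
            assert b1 < a2

    def test_seed_reproducibility(self, template):
        p = sg.SimParams(seed=17, n_full=1, n_solo=5, n_dup_pairs=1,
                         genome_len=60_000)
        c1, t1 = sg.simulate_genome(p, template)
        c2, t2 = sg.simulate_genome(p, template)
        assert c1 == c2
        assert t1 == t2

    def test_placement_error(self, template):
        p = sg.SimParams(seed=1, n_full=3, n_solo=50, genome_len=10_000)
        with pytest.raises(sg.PlacementError):
            sg.simulate_genome(p, template)

    def test_duplication_pairs_cross_reference(self, small_sim):
        _, _, truths = small_sim
        by_id = {t.insertion_id: t for t in truths}
        dups = [t for t in truths if t.duplication_partner]
        assert len(dups) == 4  # 2 pairs
        for t in dups:
            partner = by_id[t.duplication_partner]
            assert partner.duplication_partner == t.insertion_id
            assert partner.duplication_age_years == t.duplication_age_years
            assert t.duplication_age_years < t.age_years

    def test_empty_site_contigs_emitted(self, small_sim):
        _, contigs, truths = small_sim
        names = [t.empty_site_contig for t in truths if t.empty_site_contig]
        assert names
        for n in names:
            assert n in contigs

    def test_ltr_pair_divergence_matches_clock(self, template):
        # mean pairwise LTR difference over replicates ~ 2 * L * mu * T
        mu, T = 3e-9, 1e7
        rng = np.random.default_rng(123)
        ltr = random_dna(rng, 450)
        diffs = []
        for _ in range(200):
            a = sg.mutate_neutral(ltr, mu, T, rng)
            b = sg.mutate_neutral(ltr, mu, T, rng)
            diffs.append(sum(x != y for x, y in zip(a, b)))
        expected = 2 * 450 * mu * T
        assert abs(np.mean(diffs) - expected) / expected < 0.10


class TestIO:
    def test_fasta_roundtrip(self, small_sim, tmp_path):
        _, contigs, _ = small_sim
        sg.write_fasta(contigs, tmp_path / "g.fasta")
        back = sg.read_fasta(tmp_path / "g.fasta")
        assert back == contigs

    def test_truth_writers_and_config_roundtrip(self, small_sim, tmp_path):
        params, _, truths = small_sim
        sg.write_truth_gff3(truths, tmp_path / "t.gff3")
        sg.write_truth_json(truths, tmp_path / "t.json")
        text = (tmp_path / "t.gff3").read_text()
        assert text.startswith("##gff-version 3")
        assert text.count("\tprovirus\t") == 1
        sg.write_config(params, tmp_path / "cfg.txt")
        back = sg.read_config(tmp_path / "cfg.txt")
        assert back == params
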