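"""Structural calling: LTR pairs, TSDs, solo scanning, empty-site checks."""

import numpy as np
import pytest

from ervkit import ervstruct as es
from ervkit import simgenome as sg
from ervkit._seq import random_dna
from ervkit.seqsearch import local_align_nuc

from conftest import zero_age_fixture


class TestFindLtrPairs:
    @pytest.mark.parametrize("seed", range(10))
    def test_zero_age_exact_recovery(self, template, seed):
        contig, t = zero_age_fixture(template, seed=seed)
        calls = es.find_ltr_pairs(contig, (t.position, t.end))
        assert len(calls) >= 1
        call = calls[0]
        assert call.ltr5_interval == tuple(t.ltr_intervals[0])
        assert call.ltr3_interval == tuple(t.ltr_intervals[1])
        assert call.ltr_identity == 1.0
        assert call.tsd is not None
        assert call.tsd.motif == t.tsd and call.tsd.mismatches == 0

    @pytest.mark.parametrize("seed", range(505, 511))
    def test_aged_recovery_within_5nt(self, template, seed):
        params = sg.SimParams(seed=seed, n_full=1, n_solo=0, n_dup_pairs=0,
                              ages=[5e6], genome_len=26_000,
                              empty_site_fraction=0.0)
        contigs, truths = sg.simulate_genome(params, template)
        t = truths[0]
        calls = es.find_ltr_pairs(contigs["contig_1"], (t.position, t.end))
        assert len(calls) == 1
        call = calls[0]
        for got, want in zip(call.ltr5_interval + call.ltr3_interval,
                             tuple(t.ltr_intervals[0]) + tuple(t.ltr_intervals[1])):
            assert abs(got - want) <= 5

    def test_solo_ltr_yields_no_pair(self, template):
        params = sg.SimParams(seed=8, n_full=0, n_solo=1, n_dup_pairs=0,
                              genome_len=30_000, empty_site_fraction=0.0)
        contigs, truths = sg.simulate_genome(params, template)
        t = truths[0]
        calls = es.find_ltr_pairs(contigs["contig_1"], (t.position, t.end))
        assert calls == []


class TestDetectTsd:
    def test_implanted_perfect_tsd(self, template):
        contig, t = zero_age_fixture(template, seed=1)
        res = es.detect_tsd(contig, t.position, t.end)
        assert res is not None
        assert (res.motif, res.mismatches, res.length) == (t.tsd, 0, 5)

    def test_no_duplication_absent(self):
        rng = np.random.default_rng(0)
        contig = random_dna(rng, 500)
        # random flanks: require a perfect >=4-mer duplication
        res = es.detect_tsd(contig, 200, 300, allow_mismatch=False)
        if res is not None:  # extremely unlikely; make the check explicit
            assert contig[199 - res.length:199] == contig[300:300 + res.length]

    def test_one_mismatch_tolerated(self):
        core = "GGGGG" + "A" * 100 + "GGGGG"
        contig = "TTTTT" + "ACGTA" + core + "ACGTT" + "CCCCC"
        start, end = 11, 10 + len(core)
        assert es.detect_tsd(contig, start, end, allow_mismatch=False) is None
        res = es.detect_tsd(contig, start, end, allow_mismatch=True)
        assert res is not None and res.mismatches == 1 and res.length == 5

    def test_contig_edge_warns(self):
        with pytest.warns(UserWarning):
            assert es.detect_tsd("ACGTACGT", 1, 8) is None


class TestScanSoloLtrs:
    @pytest.fixture(scope="class")
    def solo_genome(self, template):
        params = sg.SimParams(seed=9, n_full=0, n_solo=30, n_dup_pairs=0,
                              genome_len=120_000, empty_site_fraction=0.0)
        return sg.simulate_genome(params, template)

    def test_recall_and_specificity(self, solo_genome, template):
        contigs, truths = solo_genome
        calls = es.scan_solo_ltrs(contigs, template.ltr_seq)
        matched = 0
        for c in calls:
            assert any(abs(c.start - t.position) < 60 and abs(c.end - t.end) < 60
                       for t in truths), "call on background"
            matched += 1
        assert matched >= 0.95 * len(truths)

    def test_filter_audit(self, solo_genome, template):
        # every accepted call re-satisfies the three predicates when the
        # alignment statistics are recomputed independently
        contigs, _ = solo_genome
        filters = es.SoloFilters()
        calls = es.scan_solo_ltrs(contigs, template.ltr_seq, filters)
        db_len = sum(len(s) for s in contigs.values())
        for c in calls:
            region = contigs[c.contig][max(0, c.start - 51):c.end + 50]
            query = (template.ltr_seq if c.strand == "+"
                     else sg.revcomp(template.ltr_seq))
            res = local_align_nuc(query, region, m=len(template.ltr_seq),
                                  n=db_len)
            assert res.evalue < filters.evalue_max
            assert res.identity >= filters.min_identity
            assert res.coverage >= filters.min_coverage

    def test_identity_below_threshold_rejected(self, template):
        # a 79%-identity copy of the reference LTR must not be called
        rng = np.random.default_rng(5)
        ltr = template.ltr_seq
        decayed = list(ltr)
        idx = rng.choice(len(ltr), size=int(0.21 * len(ltr)) + 1, replace=False)
        for i in idx:
            decayed[i] = "ACGT"[("ACGT".index(decayed[i]) + 1) % 4]
        contig = (random_dna(rng, 3000, 0.4) + "".join(decayed)
                  + random_dna(rng, 3000, 0.4))
        calls = es.scan_solo_ltrs({"c": contig}, ltr)
        assert calls == []

    def test_exclusion_of_provirus_ltrs(self, template):
        contig, t = zero_age_fixture(template, seed=12, genome_len=30_000)
        exclude = {"contig_1": [tuple(iv) for iv in t.ltr_intervals]}
        with_excl = es.scan_solo_ltrs({"contig_1": contig}, template.ltr_seq,
                                      exclude=exclude)
        without = es.scan_solo_ltrs({"contig_1": contig}, template.ltr_seq)
        assert len(without) == 2 and with_excl == []

    def test_contig_permutation_invariance(self, solo_genome, template):
        contigs, _ = solo_genome
        extra = {"aaa": random_dna(np.random.default_rng(7), 5000, 0.4)}
        g1 = dict(contigs, **extra)
        g2 = dict(extra, **contigs)
        c1 = es.scan_solo_ltrs(g1, template.ltr_seq)
        c2 = es.scan_solo_ltrs(g2, template.ltr_seq)
        assert [(c.contig, c.start, c.end) for c in c1] == \
               [(c.contig, c.start, c.end) for c in c2]

    def test_short_reference_rejected(self):
        with pytest.raises(ValueError):
            es.scan_solo_ltrs({"c": "ACGT" * 100}, "ACGT" * 10)


class TestPreintegrationSite:
    @pytest.fixture(scope="class")
    def site_case(self, template):
        params = sg.SimParams(seed=13, n_full=0, n_solo=3, n_dup_pairs=0,
                              genome_len=40_000, empty_site_fraction=1.0)
        contigs, truths = sg.simulate_genome(params, template)
        t = next(t for t in truths if t.empty_site_contig)
        c = contigs["contig_1"]
        f5 = c[t.tsd5_interval[0] - 1 - 300:t.tsd5_interval[0] - 1]
        f3 = c[t.tsd3_interval[1]:t.tsd3_interval[1] + 300]
        return contigs, t, c, f5, f3

    def test_empty_site_detected(self, site_case):
        contigs, t, _, f5, f3 = site_case
        assert es.check_preintegration_site(
            f5, f3, contigs[t.empty_site_contig]) == "empty"

    def test_own_locus_occupied(self, site_case):
        _, t, c, f5, f3 = site_case
        own = c[t.tsd5_interval[0] - 301:t.tsd3_interval[1] + 300]
        assert es.check_preintegration_site(f5, f3, own) == "occupied"

    def test_unrelated_sequence_ambiguous(self, site_case):
        _, _, _, f5, f3 = site_case
        rnd = random_dna(np.random.default_rng(2), 1200, 0.4)
        assert es.check_preintegration_site(f5, f3, rnd) == "ambiguous"

    def test_short_flanks_rejected(self):
        with pytest.raises(ValueError):
            es.check_preintegration_site("ACGT", "ACGT" * 20, "ACGT" * 100)
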