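"""Benchmark experiments that validate the pipeline on known ground truth.

Each function runs one self-contained experiment — simulate data with the
generator, run the relevant stage(s), score against the truth — and returns
a flat dict of metrics.  They power both the acceptance runner and the
acceptance test suite, so the numbers quoted in the documentation are always
recomputed, never stored.
"""

from __future__ import annotations

import numpy as np

from . import consensus as cns
from . import ervstruct as es
from . import ltrclock as lc
from . import panels, phylo
from . import simgenome as sg
from ._seq import mutate_protein, random_dna
from .seqsearch import dna_scheme, local_align_nuc

__all__ = [
    "dating_worked_example", "ltr_clock_recovery", "screen_benchmark",
    "structure_zero_age", "solo_filter_audit", "consensus_recovery",
    "smith_waterman_oracle", "nj_additive_recovery", "end_to_end",
]


def _sub_seed(seed: int, k: int) -> int:
    return (seed * 1009 + k * 7919 + 13) % (2 ** 31)


def dating_worked_example() -> dict:
    """The uncorrected two-rate clock on D=20 differences over L=440 sites."""
    est = lc.estimate_age_range(20, 440)
    return {"age_d20_l440_low_mya": est.t_low_mya,
            "age_d20_l440_high_mya": est.t_high_mya,
            "n": 440}


def ltr_clock_recovery(seed: int, n: int = 200, l_ltr: int = 450,
                       mu: float = 3e-9,
                       age_range: tuple[float, float] = (2e6, 15e6)) -> dict:
    """Simulate LTR pairs across an age range and score the clock.

    Reports the worst per-age-bin mean relative error of the point estimate
    D/(2*L*mu) and the fraction of replicates whose true age falls inside
    the 2.2–4.5e-9 rate interval.
    """
    rng = np.random.default_rng(_sub_seed(seed, 1))
    ltr = random_dna(rng, l_ltr)
    ages, rel_errs, covered = [], [], 0
    for _ in range(n):
        age = float(rng.uniform(*age_range))
        a = sg.mutate_neutral(ltr, mu, age, rng)
        b = sg.mutate_neutral(ltr, mu, age, rng)
        D, L, _ = lc.ltr_divergence(a, b)
        rel_errs.append((D / (2 * L * mu) - age) / age)
        est = lc.estimate_age_range(D, L)
        covered += est.t_low <= age <= est.t_high
        ages.append(age)
    ages = np.array(ages)
    rel_errs = np.array(rel_errs)
    # two bins of ~100 replicates: the bin-mean standard error (~2%) must
    # be able to resolve the 10% bound against the ~-5% JC bias
    bins = np.linspace(age_range[0], age_range[1], 3)
    bin_errs = []
    for lo, hi in zip(bins[:-1], bins[1:]):
        m = (ages >= lo) & (ages < hi + 1)
        if m.any():
            bin_errs.append(abs(float(rel_errs[m].mean())))
    return {"clock_max_bin_mean_error_pct": round(100 * max(bin_errs), 2),
            "clock_truth_in_interval_pct": round(100 * covered / n, 1),
            "n": n}


def _screen_genome_pair(seed: int, lenti_div: float, baits, panel) -> dict:
    """One genome carrying a lentiviral and a gammaretroviral implant."""
    from . import bbhscreen as bb

    reps = panels.genus_representatives()
    rng = np.random.default_rng(seed)
    fiv = next(e.sequence for e in baits.entries if e.name == "FIV")
    lenti_pol = "M" + mutate_protein(rng, fiv, lenti_div)[1:]
    gamma_pol = "M" + mutate_protein(rng, reps["gammaretrovirus"], 0.10)[1:]
    tpl_l = sg.make_provirus_template(seed=seed, l_ltr=300, l_internal=6500,
                                      pol_protein=lenti_pol)
    tpl_g = sg.make_provirus_template(seed=seed + 1, l_ltr=300,
                                      l_internal=6500, pol_protein=gamma_pol)
    p = dict(n_full=1, n_solo=0, n_dup_pairs=0, ages=[1e6],
             genome_len=18_000, empty_site_fraction=0.0)
    cl, tl = sg.simulate_genome(
        sg.SimParams(seed=seed + 2, contig_name="lenti_contig", **p), tpl_l)
    cg, tg = sg.simulate_genome(
        sg.SimParams(seed=seed + 3, contig_name="gamma_contig", **p), tpl_g)
    genome = {**cl, **cg}
    report = bb.screen_genome(genome, baits, panel)
    lt, gt = tl[0], tg[0]
    lenti_found = any(l.contig == "lenti_contig" and l.start <= lt.end
                      and l.end >= lt.position for l in report.candidates)
    gamma_mislabel = sum(l.contig == "gamma_contig" for l in report.candidates)
    return {"lenti_found": lenti_found, "gamma_mislabels": gamma_mislabel}


def screen_benchmark(seed: int, n_genomes: int = 20) -> dict:
    """Sensitivity/specificity of the BBH screen on paired-implant genomes.

    Every genome carries one lentiviral implant (0–~19% divergence from the
    FIV bait, spread across genomes) and one gammaretroviral implant; the
    screen must flag the former and never the latter.
    """
    baits = panels.make_lentivirus_baits()
    panel = panels.make_pol_panel()
    found = mislabels = 0
    for i in range(n_genomes):
        div = (i % 20) * 0.01
        r = _screen_genome_pair(_sub_seed(seed, 100 + i), div, baits, panel)
        found += r["lenti_found"]
        mislabels += r["gamma_mislabels"]
    return {"screen_sensitivity_pct": round(100 * found / n_genomes, 1),
            "screen_gamma_mislabels": mislabels,
            "n": n_genomes}


def structure_zero_age(seed: int, template=None, n: int = 100) -> dict:
    """Exact LTR-interval and TSD recovery on zero-age proviruses."""
    if template is None:
        template = sg.make_provirus_template(
            seed=1, pol_protein=panels.genus_representatives()["lentivirus"])
    exact = 0
    for i in range(n):
        p = sg.SimParams(seed=_sub_seed(seed, 200 + i), n_full=1, n_solo=0,
                         n_dup_pairs=0, ages=[0.0], genome_len=26_000,
                         empty_site_fraction=0.0)
        contigs, truths = sg.simulate_genome(p, template)
        t = truths[0]
        calls = es.find_ltr_pairs(contigs["contig_1"], (t.position, t.end))
        if not calls:
            continue
        c = calls[0]
        ok = (c.ltr5_interval == tuple(t.ltr_intervals[0])
              and c.ltr3_interval == tuple(t.ltr_intervals[1])
              and c.tsd is not None and c.tsd.motif == t.tsd
              and c.tsd.mismatches == 0)
        exact += ok
    return {"structure_zero_age_exact_pct": round(100 * exact / n, 1), "n": n}


def solo_filter_audit(seed: int, template=None, n_solo: int = 100) -> dict:
    """Accepted solo calls re-checked against the three filters, computed
    independently from the stored call statistics."""
    if template is None:
        template = sg.make_provirus_template(
            seed=1, pol_protein=panels.genus_representatives()["lentivirus"])
    p = sg.SimParams(seed=_sub_seed(seed, 300), n_full=0, n_solo=n_solo,
                     n_dup_pairs=0, genome_len=4000 * n_solo,
                     empty_site_fraction=0.0)
    contigs, truths = sg.simulate_genome(p, template)
    filters = es.SoloFilters()
    calls = es.scan_solo_ltrs(contigs, template.ltr_seq, filters)
    db_len = sum(len(s) for s in contigs.values())
    violations = background_calls = 0
    for c in calls:
        region = contigs[c.contig][max(0, c.start - 51):c.end + 50]
        query = (template.ltr_seq if c.strand == "+"
                 else sg.revcomp(template.ltr_seq))
        res = local_align_nuc(query, region, dna_scheme(),
                              m=len(template.ltr_seq), n=db_len)
        if not (res.evalue < filters.evalue_max
                and res.identity >= filters.min_identity
                and res.coverage >= filters.min_coverage):
            violations += 1
        if not any(abs(c.start - t.position) < 60 and abs(c.end - t.end) < 60
                   for t in truths):
            background_calls += 1
    return {"solo_recovered_count": len(calls),
            "solo_filter_violations": violations,
            "solo_background_calls": background_calls,
            "n": n_solo}


def consensus_recovery(seed: int, template=None, n_seeds: int = 50,
                       k_copies: int = 3, per_copy_divergence: float = 0.01
                       ) -> dict:
    """Mean consensus-vs-template identity for copies with independent,
    copy-specific defects (substitutions + indels) at ~1% of sites."""
    import edlib

    if template is None:
        template = sg.make_provirus_template(
            seed=1, pol_protein=panels.genus_representatives()["lentivirus"])
    mu = 3e-9
    t_years = per_copy_divergence / mu  # mu*t ~ divergence (small-p regime)
    idents = []
    for i in range(n_seeds):
        rng = np.random.default_rng(_sub_seed(seed, 400 + i))
        copies = cns.CopySet([
            cns.CopyMember(id=f"c{k}",
                           sequence=sg.mutate_neutral(template.sequence, mu,
                                                      t_years, rng,
                                                      indel_rate=2e-11))
            for k in range(k_copies)])
        res = cns.reconstruct_consensus(copies)
        d = edlib.align(res.sequence, template.sequence,
                        task="distance")["editDistance"]
        idents.append(1 - d / template.length)
    return {"consensus_mean_identity_pct": round(100 * float(np.mean(idents)), 3),
            "n": n_seeds}


def _brute_force_local(a: str, b: str, match=1, mismatch=-2,
                       gap_open=5, gap_extend=2) -> float:
    """Exhaustive affine-gap local DP (Gotoh), the independent oracle."""
    n, m = len(a), len(b)
    neg = -10 ** 9
    M = [[0.0] * (m + 1) for _ in range(n + 1)]
    X = [[neg] * (m + 1) for _ in range(n + 1)]
    Y = [[neg] * (m + 1) for _ in range(n + 1)]
    best = 0.0
    for i in range(1, n + 1):
        for j in range(1, m + 1):
            s = match if a[i - 1] == b[j - 1] and a[i - 1] != "N" else mismatch
            M[i][j] = max(0.0, max(M[i - 1][j - 1], X[i - 1][j - 1],
                                   Y[i - 1][j - 1]) + s)
            X[i][j] = max(M[i - 1][j] - gap_open - gap_extend,
                          X[i - 1][j] - gap_extend)
            Y[i][j] = max(M[i][j - 1] - gap_open - gap_extend,
                          Y[i][j - 1] - gap_extend)
            best = max(best, M[i][j])
    return best


def smith_waterman_oracle(seed: int, n_pairs: int = 1000,
                          max_len: int = 12) -> dict:
    """Alignment scores vs the exhaustive DP oracle on short random pairs."""
    rng = np.random.default_rng(_sub_seed(seed, 500))
    agree = 0
    for _ in range(n_pairs):
        a = random_dna(rng, int(rng.integers(1, max_len + 1)))
        b = random_dna(rng, int(rng.integers(1, max_len + 1)))
        agree += (local_align_nuc(a, b).raw_score == _brute_force_local(a, b))
    return {"sw_oracle_agreement_pct": round(100 * agree / n_pairs, 1),
            "n": n_pairs}


def _random_additive_matrix(rng: np.random.Generator, n: int) -> np.ndarray:
    d = np.zeros((n, n))
    groups = [[i] for i in range(n)]
    depth = [{i: 0.0} for i in range(n)]
    while len(groups) > 1:
        i, j = sorted(rng.choice(len(groups), 2, replace=False))
        bi, bj = rng.uniform(0.5, 5.0, 2)
        di = {k: v + bi for k, v in depth[i].items()}
        dj = {k: v + bj for k, v in depth[j].items()}
        for a in groups[i]:
            for b in groups[j]:
                d[a, b] = d[b, a] = di[a] + dj[b]
        groups = [g for k, g in enumerate(groups) if k not in (i, j)] \
            + [groups[i] + groups[j]]
        depth = [g for k, g in enumerate(depth) if k not in (i, j)] \
            + [{**di, **dj}]
    return d


def nj_additive_recovery(seed: int, n_trees: int = 100,
                         max_taxa: int = 8) -> dict:
    """NJ must reproduce random additive matrices exactly (path lengths)."""
    rng = np.random.default_rng(_sub_seed(seed, 600))
    exact = 0
    for _ in range(n_trees):
        n = int(rng.integers(4, max_taxa + 1))
        d = _random_additive_matrix(rng, n)
        taxa = [f"t{i}" for i in range(n)]
        tree = phylo.nj_tree(phylo.DistanceMatrix(taxa=taxa, values=d))
        pl = tree.path_lengths()
        order = [pl.taxa.index(t) for t in taxa]
        exact += np.allclose(pl.values[order][:, order], d, atol=1e-9)
    return {"nj_additive_recovery_pct": round(100 * exact / n_trees, 1),
            "n": n_trees}


def end_to_end(seed: int, n_solo: int = 100, genome_len: int = 400_000,
               bootstrap_reps: int = 500, workdir=None) -> dict:
    """Full discovery run on a synthetic genome at the default study
    conditions (3 proviruses at 7.7/15.4/20.1 Myr, ~100 solo LTRs)."""
    import json
    import tempfile
    from pathlib import Path

    from . import pipeline

    params = sg.SimParams(seed=_sub_seed(seed, 700), n_full=3, n_solo=n_solo,
                          genome_len=genome_len)
    cfg = pipeline.RunConfig(seed=_sub_seed(seed, 700), sim_params=params,
                             bootstrap_reps=bootstrap_reps)
    ctx = (tempfile.TemporaryDirectory() if workdir is None else None)
    out = Path(ctx.name if ctx else workdir)
    try:
        manifest = pipeline.run_discovery_pipeline(cfg, out)
        s = manifest["stages"]
        ages = json.loads((out / "ages.json").read_text())
        truth = json.loads((out / "truth.json").read_text())
        calls = json.loads((out / "provirus_calls.json").read_text())
        fulls = {t["position"]: t for t in truth if t["type"] == "full"}
        matched = ages_inside = 0
        for row, call in zip(ages, calls):
            t = next((v for k, v in fulls.items()
                      if abs(k - call["start"]) <= 5), None)
            if t is None:
                continue
            matched += 1
            ages_inside += (row["t_low_mya"] * 1e6 <= t["age_years"]
                            <= row["t_high_mya"] * 1e6)
        dist = s["phylo"].get("interprovirus_distance_range") or [0, 0]
        oldest = max(ages, key=lambda r: r["t_high_mya"]) if ages else None
        return {
            "provirus_calls": s["structure"]["n_proviruses"],
            "provirus_calls_at_truth": matched,
            "solo_ltr_calls": s["structure"]["n_solo"],
            "solo_to_full_ratio": s["structure"]["solo_to_full_ratio"] or 0,
            "consensus_length_bp": s["consensus"]["consensus_length"],
            "truth_age_in_interval_count": ages_inside,
            "oldest_age_low_mya": oldest["t_low_mya"] if oldest else 0,
            "oldest_age_high_mya": oldest["t_high_mya"] if oldest else 0,
            "interprovirus_distance_min": dist[0],
            "interprovirus_distance_max": dist[1],
            "lentivirus_clade_support": s["phylo"].get(
                "lentivirus_clade_support") or 0,
            "n": genome_len,
        }
    finally:
        if ctx:
            ctx.cleanup()
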