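"""Shared fixtures: templates, panels, and small simulated genomes.

Everything is generated programmatically at test time from fixed seeds, so
the suite needs no data files and is fully deterministic.
"""

import numpy as np
import pytest

from ervkit import panels, simgenome as sg


@pytest.fixture(scope="session")
def genus_reps():
    return panels.genus_representatives()


@pytest.fixture(scope="session")
def pol_panel():
    return panels.make_pol_panel()


@pytest.fixture(scope="session")
def bait_panel():
    return panels.make_lentivirus_baits()


@pytest.fixture(scope="session")
def template(genus_reps):
    """Default 10,040 nt proviral template with the Pol pinned to the
    bundled lentiviral representative (so screening baits have a target)."""
    return sg.make_provirus_template(seed=1, pol_protein=genus_reps["lentivirus"])


@pytest.fixture(scope="session")
def small_sim(template):
    """One aged provirus plus a handful of solo LTRs in a 60 kb contig."""
    params = sg.SimParams(seed=11, n_full=1, n_solo=8, n_dup_pairs=2,
                          ages=[8e6], genome_len=60_000,
                          empty_site_fraction=1.0)
    contigs, truths = sg.simulate_genome(params, template)
    return params, contigs, truths


def zero_age_fixture(template, seed, genome_len=26_000):
    """A single zero-age provirus: byte-identical LTRs and a perfect TSD."""
    params = sg.SimParams(seed=seed, n_full=1, n_solo=0, n_dup_pairs=0,
                          ages=[0.0], genome_len=genome_len,
                          empty_site_fraction=0.0)
    contigs, truths = sg.simulate_genome(params, template)
    return contigs["contig_1"], truths[0]


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(0)
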