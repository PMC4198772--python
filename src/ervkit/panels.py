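"""Bundled retroviral Pol panels and bait sets (synthetic placeholders).

The screening workflow needs two protein panels: a small set of lentiviral
Pol baits for the forward translated search, and an all-genera retroviral
Pol panel for the backward (classification) search.  Shipping real database
records is out of scope, so this module generates deterministic *synthetic*
stand-ins with a realistic divergence structure: all genus representatives
descend from one ancestral Pol (~45% inter-genus divergence), members within
a genus sit at ~15% divergence, and the six classically used lentiviral
baits are distinct variants of the lentiviral representative.  Users mining
real genomes should replace these with curated sequences; every function
downstream only sees ``(name, genus, sequence)`` triples.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ._seq import mutate_protein, random_protein

__all__ = ["GENERA", "PanelEntry", "BaitPanel", "genus_representatives",
           "make_pol_panel", "make_lentivirus_baits", "DEFAULT_PANEL_SEED"]

GENERA = (
    "alpharetrovirus", "betaretrovirus", "gammaretrovirus", "deltaretrovirus",
    "epsilonretrovirus", "lentivirus", "spumavirus",
)

DEFAULT_PANEL_SEED = 84

#: The six bait names used in classical endogenous-lentivirus screens, with
#: their host species (for the bait-exclusion rule) and the divergence of the
#: synthetic stand-in from the lentiviral genus representative.
_BAIT_SPECS = (
    ("HIV-1", None, 0.25),
    ("FIV", None, 0.20),
    ("Visna", None, 0.22),
    ("RELIK", "rabbit", 0.15),
    ("pSIVgml", "mouse_lemur", 0.18),
    ("ELVmpf", "ferret", 0.12),
)


@dataclass(frozen=True)
class PanelEntry:
    name: str
    genus: str
    sequence: str


@dataclass
class BaitPanel:
    """Forward-search baits plus a host-species exclusion map.

    ``exclusion_map`` maps a host genome label to bait names that must be
    skipped when screening that host (previously described endogenous
    elements would otherwise match themselves).
    """

    entries: list[PanelEntry]
    exclusion_map: dict[str, set[str]] = field(default_factory=dict)

    def __post_init__(self) -> None:
        known = set(GENERA)
        for e in self.entries:
            if e.genus not in known:
                raise ValueError(f"unknown retroviral genus: {e.genus}")

    def baits_for(self, host_species: str | None) -> list[PanelEntry]:
        excluded = self.exclusion_map.get(host_species, set()) if host_species else set()
        return [e for e in self.entries if e.name not in excluded]


def genus_representatives(seed: int = DEFAULT_PANEL_SEED,
                          length: int = 850) -> dict[str, str]:
    """One synthetic Pol protein per retroviral genus (deterministic)."""
    rng = np.random.default_rng(seed)
    ancestor = "M" + random_protein(rng, length - 1)
    reps = {}
    for genus in GENERA:
        reps[genus] = "M" + mutate_protein(rng, ancestor, 0.45)[1:]
    return reps


def make_pol_panel(seed: int = DEFAULT_PANEL_SEED, n_per_genus: int = 2,
                   length: int = 850) -> list[PanelEntry]:
    """All-genera backward-classification panel (synthetic placeholders)."""
    rng = np.random.default_rng(seed + 1)
    entries = []
    for genus, rep in genus_representatives(seed, length).items():
        for i in range(n_per_genus):
            div = 0.0 if i == 0 else 0.15
            seq = "M" + mutate_protein(rng, rep, div)[1:]
            entries.append(PanelEntry(f"{genus}_pol_{i + 1}", genus, seq))
    return entries


def make_lentivirus_baits(seed: int = DEFAULT_PANEL_SEED,
                          length: int = 850) -> BaitPanel:
    """The six-name lentiviral bait set with its host-exclusion map."""
    rng = np.random.default_rng(seed + 2)
    lenti = genus_representatives(seed, length)["lentivirus"]
    entries = []
    exclusion: dict[str, set[str]] = {}
    for name, host, div in _BAIT_SPECS:
        seq = "M" + mutate_protein(rng, lenti, div)[1:]
        entries.append(PanelEntry(name, "lentivirus", seq))
        if host is not None:
            exclusion.setdefault(host, set()).add(name)
    return BaitPanel(entries=entries, exclusion_map=exclusion)
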