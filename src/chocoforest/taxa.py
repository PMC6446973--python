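"""Synthetic taxonomy and wood-density lookup for the simulated inventory.

Builds a small fictitious flora per forest class whose species wood densities
centre on the class means (terra firme 0.60, wetland 0.49, mangrove
0.79 g cm^-3), together with the matching wood-density lookup table at
species, genus and family rank. Trees labelled at genus (family) level carry
a species (genus) name deliberately absent from the table, so the lookup
hierarchy species -> genus -> family -> plot mean resolves at the intended
rank.
"""

from __future__ import annotations

import numpy as np

__all__ = ["SyntheticTaxonomy"]

_CLASS_WD = {
    "terra_firme_intact": 0.60,
    "terra_firme_degraded": 0.60,
    "nonforest": 0.60,
    "wetland": 0.49,
    "mangrove": 0.79,
}

_LEVELS = ("species", "genus", "family", "unidentified")


class SyntheticTaxonomy:
    """A fictitious flora with a consistent wood-density table.

    Parameters
    ----------
    n_families, genera_per_family, species_per_genus
        Size of the flora generated for each forest class.
    wd_sd
        Between-species wood-density spread (g cm^-3) around the class mean.
    seed
        Determines the flora and its wood densities.
    """

    def __init__(
        self,
        n_families: int = 4,
        genera_per_family: int = 3,
        species_per_genus: int = 3,
        wd_sd: float = 0.05,
        seed: int = 12345,
    ) -> None:
        rng = np.random.default_rng(seed)
        self.entries: list[tuple[str, str, float]] = []  # (name, rank, wd)
        self._species: dict[str, list[tuple[str, str, str]]] = {}
        for cls_key, wd_mean in (
            ("tf", 0.60),
            ("wet", 0.49),
            ("man", 0.79),
        ):
            triples = []
            for fi in range(n_families):
                fam = f"{cls_key}_fam{fi}"
                fam_wds = []
                for gi in range(genera_per_family):
                    gen = f"{fam}_gen{gi}"
                    sp_wds = wd_mean + wd_sd * rng.standard_normal(species_per_genus)
                    sp_wds = np.clip(sp_wds, 0.15, 1.15)
                    for si, wd in enumerate(sp_wds):
                        sp = f"{gen}_sp{si}"
                        self.entries.append((sp, "species", float(wd)))
                        triples.append((sp, gen, fam))
                    self.entries.append((gen, "genus", float(sp_wds.mean())))
                    fam_wds.append(sp_wds.mean())
                self.entries.append((fam, "family", float(np.mean(fam_wds))))
            self._species[cls_key] = triples

    def _key(self, forest_class: str) -> str:
        return {"wetland": "wet", "mangrove": "man"}.get(forest_class, "tf")

    def draw_taxon(
        self, forest_class: str, level: int, rng: np.random.Generator
    ) -> tuple[str | None, str | None, str | None]:
        """Draw (species, genus, family) labels resolvable at ``level``.

        level 0: all three resolvable in the table; 1: species unknown to the
        table; 2: species and genus unknown; 3: fully unidentified.
        """
        triples = self._species[self._key(forest_class)]
        sp, gen, fam = triples[rng.integers(len(triples))]
        if level == 0:
            return sp, gen, fam
        if level == 1:
            return f"{sp}_novel", gen, fam
        if level == 2:
            return None, f"{gen}_novel", fam
        return None, None, None

    def wood_density_rows(self) -> list[tuple[str, str, float]]:
        """Rows (taxon name, rank, wd) for building a WoodDensityTable."""
        return list(self.entries)

    @staticmethod
    def class_mean_wd(forest_class: str) -> float:
        return _CLASS_WD[forest_class]
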