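"""Scenario recipes: what goes in the box.

A recipe counts molecules (diblock chains of each sign, porphyrins, added
salt pairs) in a cubic box of edge ``L`` filled with solvent to the
reference bead density ``rho = 3``.  Counterions are never user-set: each
A+ bead brings one CI-, each A- bead one CI+, each Pq+ bead one CI-, and
salt adds CI+/CI- in equal numbers, so every built system is electroneutral
by construction.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import yaml

from .templates import PORPHYRIN_ARM, PORPHYRIN_EDGE

#: reference DPD bead density
RHO_DEFAULT = 3.0


@dataclass
class ScenarioRecipe:
    n_plus: int = 0            # A_nA+ B_nB chains
    n_minus: int = 0           # A_nA- B_nB chains
    n_porphyrin: int = 0
    n_salt_pairs: int = 0
    L: float = 10.0
    rho: float = RHO_DEFAULT
    mode: str = "random"       # "random" | "preaggregated"
    seed: int = 0
    n_a: int = 10              # charged block length
    n_b: int = 25              # neutral block length
    porphyrin_edge: float = PORPHYRIN_EDGE
    porphyrin_arm: float = PORPHYRIN_ARM

    def __post_init__(self):
        if self.rho <= 0 or self.L <= 0:
            raise ValueError("rho and L must be positive")
        if self.mode not in ("random", "preaggregated"):
            raise ValueError(f"unknown mode {self.mode!r}")
        for key in ("n_plus", "n_minus", "n_porphyrin", "n_salt_pairs"):
            if getattr(self, key) < 0:
                raise ValueError(f"{key} must be non-negative")

    # -- derived counts -------------------------------------------------
    @property
    def n_total(self) -> int:
        return int(round(self.rho * self.L**3))

    @property
    def n_ci_minus(self) -> int:
        """One CI- per A+ bead and per Pq+ bead, plus salt anions."""
        return self.n_plus * self.n_a + 4 * self.n_porphyrin + self.n_salt_pairs

    @property
    def n_ci_plus(self) -> int:
        """One CI+ per A- bead, plus salt cations."""
        return self.n_minus * self.n_a + self.n_salt_pairs

    @property
    def n_polymer_beads(self) -> int:
        return (self.n_plus + self.n_minus) * (self.n_a + self.n_b)

    @property
    def n_nonsolvent(self) -> int:
        return (
            self.n_polymer_beads
            + 8 * self.n_porphyrin
            + self.n_ci_plus
            + self.n_ci_minus
        )

    @property
    def n_solvent(self) -> int:
        return self.n_total - self.n_nonsolvent

    @property
    def porphyrin_volume_fraction(self) -> float:
        """c_P+ in Vol%: porphyrin beads over all beads at uniform density."""
        return 100.0 * 8 * self.n_porphyrin / self.n_total

    def validate(self) -> None:
        if self.n_solvent < 0:
            raise ValueError(
                f"box too small: {self.n_nonsolvent} molecule/ion beads exceed "
                f"round(rho L^3) = {self.n_total}"
            )


def porphyrin_count_for_volume_fraction(c_vol_percent: float, L: float,
                                        rho: float = RHO_DEFAULT) -> int:
    """Number of porphyrin units giving volume fraction ``c_vol_percent``."""
    return max(1, int(round(c_vol_percent / 100.0 * rho * L**3 / 8.0)))


_RECIPE_KEYS = {
    "n_plus", "n_minus", "n_porphyrin", "n_salt_pairs", "L", "rho",
    "mode", "seed", "n_a", "n_b", "porphyrin_edge", "porphyrin_arm",
}


def recipe_to_yaml(recipe: ScenarioRecipe) -> str:
    return yaml.safe_dump(asdict(recipe), sort_keys=True)


def recipe_from_yaml(text: str) -> ScenarioRecipe:
    data = yaml.safe_load(text)
    if not isinstance(data, dict):
        raise ValueError("recipe file must be a mapping")
    unknown = set(data) - _RECIPE_KEYS
    if unknown:
        raise ValueError(f"unknown recipe key(s): {sorted(unknown)}")
    return ScenarioRecipe(**data)


def load_recipe(path) -> ScenarioRecipe:
    with open(path) as fh:
        return recipe_from_yaml(fh.read())


def save_recipe(recipe: ScenarioRecipe, path) -> None:
    with open(path, "w") as fh:
        fh.write(recipe_to_yaml(recipe))
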