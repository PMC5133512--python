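"""Pedigree container and extended-family construction.

A pedigree is an ordered collection of individuals with parent links.
Founders have no parents; every non-founder has both parents inside the
pedigree.  The container validates these invariants and exposes a
topological order (parents before children) used by the relationship-matrix
recursion and by gene dropping.
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, PedigreeError

MALE = "male"
FEMALE = "female"


@dataclass(frozen=True)
class Individual:
    iid: str
    father: str | None
    mother: str | None
    sex: str
    family: str

    @property
    def founder(self) -> bool:
        return self.father is None and self.mother is None


class Pedigree:
    """Validated set of individuals with parent links.

    Parameters
    ----------
    individuals
        Individuals in any order; a topological order is computed.  Each
        individual must either have both parents present in the pedigree
        (non-founder) or neither (founder).
    """

    def __init__(self, individuals: list[Individual]):
        if not individuals:
            raise PedigreeError("empty pedigree")
        self.individuals = list(individuals)
        self.ids = [ind.iid for ind in self.individuals]
        if len(set(self.ids)) != len(self.ids):
            raise PedigreeError("duplicate individual identifiers")
        self._index = {iid: k for k, iid in enumerate(self.ids)}
        n = len(self.individuals)
        self.father_idx = np.full(n, -1, dtype=int)
        self.mother_idx = np.full(n, -1, dtype=int)
        for k, ind in enumerate(self.individuals):
            if (ind.father is None) != (ind.mother is None):
                raise PedigreeError(
                    f"{ind.iid}: exactly one parent link set; founders have "
                    "neither parent, non-founders both"
                )
            if ind.father is not None:
                for pid, arr in ((ind.father, self.father_idx), (ind.mother, self.mother_idx)):
                    if pid not in self._index:
                        raise PedigreeError(f"{ind.iid}: parent {pid!r} not in pedigree")
                    arr[k] = self._index[pid]
        self._topo = self._topological_order()

    # -- structure ---------------------------------------------------------
    def _topological_order(self) -> np.ndarray:
        n = len(self.individuals)
        n_parents = (self.father_idx >= 0).astype(int) + (self.mother_idx >= 0).astype(int)
        children: list[list[int]] = [[] for _ in range(n)]
        for k in range(n):
            for p in (self.father_idx[k], self.mother_idx[k]):
                if p >= 0:
                    children[p].append(k)
        order, queue = [], [k for k in range(n) if n_parents[k] == 0]
        remaining = n_parents.copy()
        while queue:
            k = queue.pop(0)
            order.append(k)
            for c in children[k]:
                remaining[c] -= 1
                if remaining[c] == 0:
                    queue.append(c)
        if len(order) != n:
            raise PedigreeError("pedigree contains a parent-link cycle")
        return np.asarray(order, dtype=int)

    def __len__(self) -> int:
        return len(self.individuals)

    def index_of(self, iid: str) -> int:
        return self._index[iid]

    @property
    def topological_order(self) -> np.ndarray:
        return self._topo

    @property
    def founder_mask(self) -> np.ndarray:
        return self.father_idx < 0

    @property
    def founder_ids(self) -> list[str]:
        return [iid for iid, f in zip(self.ids, self.founder_mask) if f]

    @property
    def n_founders(self) -> int:
        return int(self.founder_mask.sum())

    @property
    def families(self) -> list[str]:
        seen: dict[str, None] = {}
        for ind in self.individuals:
            seen.setdefault(ind.family, None)
        return list(seen)

    def sex_mask_female(self) -> np.ndarray:
        return np.array([ind.sex == FEMALE for ind in self.individuals])


@dataclass(frozen=True)
class FamilyTemplate:
    """Shape of one extended family.

    ``generations`` counts generations including the founding couple;
    ``sibships[g]`` is the number of children born to each couple of
    generation ``g+1``.  Every child of a non-terminal generation marries a
    founder spouse who enters the pedigree, mirroring extended families in
    which spouses marry in.
    """

    generations: int = 3
    sibships: tuple[int, ...] = (4, 11)

    def __post_init__(self):
        if self.generations < 1:
            raise ConfigurationError("family template needs at least one generation")
        if len(self.sibships) != self.generations - 1:
            raise ConfigurationError(
                f"template with {self.generations} generations needs "
                f"{self.generations - 1} sibship sizes, got {len(self.sibships)}"
            )
        if any(s < 1 for s in self.sibships):
            raise ConfigurationError("sibship sizes must be positive")

    @property
    def family_size(self) -> int:
        size, couples = 2, 1
        for g, sib in enumerate(self.sibships):
            children = couples * sib
            size += children
            if g < len(self.sibships) - 1:
                size += children          # marrying-in spouses
                couples = children
        return size


def build_pedigree(
    n_families: int,
    template: FamilyTemplate = FamilyTemplate(),
    prop_female: float = 0.58,
    rng: np.random.Generator | None = None,
) -> Pedigree:
    """Construct ``n_families`` disjoint extended families from a template.

    Child sexes are Bernoulli(``prop_female``); marrying-in spouses take the
    opposite sex so every union is male-female.
    """
    if n_families < 1:
        raise ConfigurationError("n_families must be >= 1")
    if not 0.0 <= prop_female <= 1.0:
        raise ConfigurationError("prop_female must be in [0, 1]")
    rng = rng or np.random.default_rng(0)
    individuals: list[Individual] = []
    for f in range(1, n_families + 1):
        fam = f"FAM{f:03d}"
        counter = [0]

        def new_id() -> str:
            counter[0] += 1
            return f"{fam}_{counter[0]:03d}"

        pa, ma = new_id(), new_id()
        individuals.append(Individual(pa, None, None, MALE, fam))
        individuals.append(Individual(ma, None, None, FEMALE, fam))
        couples = [(pa, ma)]
        for g, sib in enumerate(template.sibships):
            next_couples = []
            for father, mother in couples:
                for _ in range(sib):
                    sex = FEMALE if rng.random() < prop_female else MALE
                    child = new_id()
                    individuals.append(Individual(child, father, mother, sex, fam))
                    if g < len(template.sibships) - 1:
                        spouse_sex = MALE if sex == FEMALE else FEMALE
                        spouse = new_id()
                        individuals.append(Individual(spouse, None, None, spouse_sex, fam))
                        pair = (child, spouse) if sex == MALE else (spouse, child)
                        next_couples.append(pair)
            couples = next_couples
    return Pedigree(individuals)
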