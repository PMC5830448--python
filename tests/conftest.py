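"""Shared fixtures: small hand-built pedigrees and random loop-free ones."""

from __future__ import annotations

import numpy as np
import pytest

from mendelscan.pedigree import Individual, Pedigree


@pytest.fixture
def trio() -> Pedigree:
    """Father, mother, child — the smallest non-trivial pedigree."""
    return Pedigree(
        family_id="T",
        members=(
            Individual("F1", "T", sex="male"),
            Individual("M1", "T", sex="female"),
            Individual("C1", "T", father_id="F1", mother_id="M1", sex="female"),
        ),
    )


def make_singletons(n: int, prefix: str = "S") -> list[Pedigree]:
    """n one-person families, each typed."""
    peds = []
    for i in range(n):
        ind = Individual(f"{prefix}{i}", f"fam_{prefix}{i}", sex="female")
        peds.append(
            Pedigree(family_id=ind.family_id, members=(ind,)).with_typed(
                (ind.individual_id,)
            )
        )
    return peds


def random_pedigree(rng: np.random.Generator, n_members: int, family_id: str = "R") -> Pedigree:
    """A random loop-free pedigree of exactly ``n_members``.

    Grown by repeatedly either adding a child to an existing couple or
    forming a new couple from an existing member and a fresh marry-in
    founder; marry-ins guarantee no consanguinity."""
    members: list[Individual] = []

    def add(father=None, mother=None, sex=None) -> Individual:
        if sex is None:
            sex = "female" if rng.random() < 0.5 else "male"
        # ids are namespaced by family so cohorts never collide
        ind = Individual(f"{family_id}_I{len(members)}", family_id, father, mother, sex)
        members.append(ind)
        return ind

    pa = add(sex="male")
    ma = add(sex="female")
    couples = [(pa, ma)]
    while len(members) < n_members:
        if rng.random() < 0.6 or len(members) + 2 > n_members:
            father, mother = couples[rng.integers(len(couples))]
            add(father=father.individual_id, mother=mother.individual_id)
        else:
            base = members[rng.integers(len(members))]
            spouse = add(sex="female" if base.sex == "male" else "male")
            pair = (base, spouse) if base.sex == "male" else (spouse, base)
            couples.append(pair)
    return Pedigree(family_id=family_id, members=tuple(members))


def random_typed_subset(
    rng: np.random.Generator, ped: Pedigree, max_size: int
) -> Pedigree:
    n = int(rng.integers(1, min(max_size, len(ped)) + 1))
    ids = list(ped.member_ids)
    chosen = sorted(rng.choice(len(ids), size=n, replace=False).tolist())
    return ped.with_typed(tuple(ids[i] for i in chosen))
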