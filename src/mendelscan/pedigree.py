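"""Pedigree and phenotype parsing, validation, and representation.

Pedigrees are the structural backbone of the segregation model: every
individual is either a founder (no parents in the pedigree, including
marry-in spouses) or has both parents present.  The file format follows the
PED/FAM convention: headerless, whitespace-delimited columns

    family_id  individual_id  father_id  mother_id  sex

with ``0`` for a missing parent and sex coded 1 = male, 2 = female,
0 = unknown.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "Individual",
    "Pedigree",
    "PhenotypeRecord",
    "PedigreeError",
    "parse_pedigrees",
    "write_pedigrees",
    "attach_typed_members",
    "parse_phenotypes",
]

_SEX_CODES = {"1": "male", "2": "female", "0": "unknown"}
_SEX_TO_CODE = {"male": "1", "female": "2", "unknown": "0"}


class PedigreeError(ValueError):
    """Raised for malformed or internally inconsistent pedigree input."""


@dataclass(frozen=True)
class Individual:
    """One pedigree member.  ``father_id``/``mother_id`` are ``None`` for founders."""

    individual_id: str
    family_id: str
    father_id: str | None = None
    mother_id: str | None = None
    sex: str = "unknown"

    def __post_init__(self) -> None:
        if (self.father_id is None) != (self.mother_id is None):
            raise PedigreeError(
                f"individual {self.individual_id!r}: parents must be both "
                "present or both missing"
            )
        if self.sex not in ("female", "male", "unknown"):
            raise PedigreeError(f"invalid sex {self.sex!r}")

    @property
    def is_founder(self) -> bool:
        return self.father_id is None


@dataclass
class Pedigree:
    """A single family: members in input order, parent links, typed subset.

    ``typed_members`` is the ordered tuple of member ids with methylation
    data, aligned to the columns of the methylation matrix; it is empty
    until :func:`attach_typed_members` is called.
    """

    family_id: str
    members: tuple[Individual, ...]
    typed_members: tuple[str, ...] = ()
    _by_id: dict[str, Individual] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        self._by_id = {m.individual_id: m for m in self.members}
        if len(self._by_id) != len(self.members):
            raise PedigreeError(
                f"family {self.family_id!r}: duplicate individual ids"
            )
        self._validate()

    def _validate(self) -> None:
        for m in self.members:
            for pid, role in ((m.father_id, "father"), (m.mother_id, "mother")):
                if pid is not None and pid not in self._by_id:
                    raise PedigreeError(
                        f"family {self.family_id!r}: {role} {pid!r} of "
                        f"{m.individual_id!r} is not a member"
                    )
        # acyclicity: walk parent links with an explicit stack
        state: dict[str, int] = {}  # 0 in-progress, 1 done

        def visit(start: str) -> None:
            stack = [(start, iter(self._parents(start)))]
            state[start] = 0
            while stack:
                node, parents = stack[-1]
                advanced = False
                for p in parents:
                    if state.get(p) == 0:
                        raise PedigreeError(
                            f"family {self.family_id!r}: individual {p!r} "
                            "is its own ancestor"
                        )
                    if p not in state:
                        state[p] = 0
                        stack.append((p, iter(self._parents(p))))
                        advanced = True
                        break
                if not advanced:
                    state[node] = 1
                    stack.pop()

        for m in self.members:
            if m.individual_id not in state:
                visit(m.individual_id)

    def _parents(self, individual_id: str) -> tuple[str, ...]:
        m = self._by_id[individual_id]
        if m.father_id is None:
            return ()
        return (m.father_id, m.mother_id)  # type: ignore[return-value]

    def __contains__(self, individual_id: str) -> bool:
        return individual_id in self._by_id

    def __len__(self) -> int:
        return len(self.members)

    def member(self, individual_id: str) -> Individual:
        return self._by_id[individual_id]

    @property
    def member_ids(self) -> tuple[str, ...]:
        return tuple(m.individual_id for m in self.members)

    @property
    def founders(self) -> tuple[str, ...]:
        return tuple(m.individual_id for m in self.members if m.is_founder)

    def children_of(self, individual_id: str) -> tuple[str, ...]:
        return tuple(
            m.individual_id
            for m in self.members
            if individual_id in (m.father_id, m.mother_id)
        )

    def with_typed(self, typed: Sequence[str]) -> "Pedigree":
        unknown = [t for t in typed if t not in self._by_id]
        if unknown:
            raise PedigreeError(
                f"family {self.family_id!r}: typed ids not members: {unknown}"
            )
        return replace(self, typed_members=tuple(typed))


@dataclass(frozen=True)
class PhenotypeRecord:
    """Disease outcome for one individual: affected flag and age at
    diagnosis (if affected) or censoring (if not), in years."""

    individual_id: str
    affected: bool
    event_or_censor_age: float
    sex: str = "unknown"

    def __post_init__(self) -> None:
        import math

        if not (math.isfinite(self.event_or_censor_age) and self.event_or_censor_age > 0):
            raise PedigreeError(
                f"individual {self.individual_id!r}: age must be finite and positive"
            )


def _parse_parent(raw: str) -> str | None:
    return None if raw == "0" else raw


def parse_pedigrees(path: str | Path) -> list[Pedigree]:
    """Parse a PED-style file into one :class:`Pedigree` per family.

    Families are returned in order of first appearance; members keep input
    order.  Errors name the offending row or individual.
    """
    rows: dict[str, list[Individual]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 5:
                raise PedigreeError(
                    f"{path}, line {lineno}: expected ≥5 columns, got {len(parts)}"
                )
            fam, ind, father, mother, sex = parts[:5]
            if sex not in _SEX_CODES:
                raise PedigreeError(
                    f"{path}, line {lineno}: invalid sex code {sex!r}"
                )
            try:
                individual = Individual(
                    individual_id=ind,
                    family_id=fam,
                    father_id=_parse_parent(father),
                    mother_id=_parse_parent(mother),
                    sex=_SEX_CODES[sex],
                )
            except PedigreeError as exc:
                raise PedigreeError(f"{path}, line {lineno}: {exc}") from exc
            rows.setdefault(fam, []).append(individual)
    return [Pedigree(family_id=fam, members=tuple(members)) for fam, members in rows.items()]


def write_pedigrees(pedigrees: Iterable[Pedigree], path: str | Path) -> None:
    """Write pedigrees back to PED format (inverse of :func:`parse_pedigrees`)."""
    with open(path, "w") as fh:
        for ped in pedigrees:
            for m in ped.members:
                fh.write(
                    "\t".join(
                        [
                            ped.family_id,
                            m.individual_id,
                            m.father_id or "0",
                            m.mother_id or "0",
                            _SEX_TO_CODE[m.sex],
                        ]
                    )
                    + "\n"
                )


def attach_typed_members(
    pedigrees: Sequence[Pedigree], sample_ids: Sequence[str]
) -> list[Pedigree]:
    """Mark the individuals with methylation data, in matrix column order.

    Every sample id must match a member of exactly one family; the typed
    ordering within each family follows ``sample_ids`` so that per-family
    M-value vectors can be sliced directly from the matrix.
    """
    owner: dict[str, str] = {}
    for ped in pedigrees:
        for m in ped.members:
            if m.individual_id in owner:
                raise PedigreeError(
                    f"individual id {m.individual_id!r} appears in families "
                    f"{owner[m.individual_id]!r} and {ped.family_id!r}"
                )
            owner[m.individual_id] = ped.family_id
    missing = [s for s in sample_ids if s not in owner]
    if missing:
        raise PedigreeError(f"sample ids not found in any pedigree: {missing}")
    typed_by_family: dict[str, list[str]] = {ped.family_id: [] for ped in pedigrees}
    for s in sample_ids:
        typed_by_family[owner[s]].append(s)
    return [ped.with_typed(typed_by_family[ped.family_id]) for ped in pedigrees]


def parse_phenotypes(path: str | Path) -> list[PhenotypeRecord]:
    """Read the phenotype TSV (header: individual_id, affected, age, sex)."""
    df = pd.read_csv(path, sep="\t", dtype={"individual_id": str})
    required = {"individual_id", "affected", "age"}
    if not required.issubset(df.columns):
        raise PedigreeError(
            f"phenotype file missing columns: {sorted(required - set(df.columns))}"
        )
    records = []
    for row in df.itertuples(index=False):
        sex = getattr(row, "sex", "unknown")
        if isinstance(sex, (int, float)):
            sex = _SEX_CODES.get(str(int(sex)), "unknown")
        records.append(
            PhenotypeRecord(
                individual_id=str(row.individual_id),
                affected=bool(int(row.affected)),
                event_or_censor_age=float(row.age),
                sex=str(sex),
            )
        )
    return records
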