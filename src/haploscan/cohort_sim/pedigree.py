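"""Pedigree construction.

The generator's sampling rules are part of its contract (tests replay them
independently):

* kindreds are generated in spec order with a single shared generator;
* within a kindred, generation by generation, couples in creation order:
  first one Poisson(``mean_sibship``) draw for the sibship size, then one
  ``integers(0, 2)`` draw per child for its sex;
* every child of a non-terminal generation marries a new founder spouse of
  the opposite sex (no draw);
* unrecorded link lineages are generated after all kindreds, one sex draw
  per hidden chain member.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..errors import PedigreeError
from .config import PedigreeSpec

MALE, FEMALE = 1, 2

__all__ = ["Member", "Pedigree", "build_pedigree", "meioses_between"]


@dataclass
class Member:
    id: str
    father: str | None
    mother: str | None
    sex: int
    fid: str = "0"
    recorded: bool = True

    @property
    def is_founder(self) -> bool:
        return self.father is None and self.mother is None


@dataclass
class Pedigree:
    """Acyclic family graph; members are stored parents-before-children."""

    members: list[Member] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._by_id = {m.id: m for m in self.members}
        if len(self._by_id) != len(self.members):
            raise PedigreeError("duplicate member ids")
        self.validate()

    def validate(self) -> None:
        seen: set[str] = set()
        for m in self.members:
            if (m.father is None) != (m.mother is None):
                raise PedigreeError(f"{m.id}: exactly one parent recorded")
            for parent, want_sex, role in (
                (m.father, MALE, "father"),
                (m.mother, FEMALE, "mother"),
            ):
                if parent is None:
                    continue
                if parent not in self._by_id:
                    raise PedigreeError(f"{m.id}: unknown {role} {parent!r}")
                if parent not in seen:
                    raise PedigreeError(
                        f"{m.id}: {role} {parent!r} does not precede child "
                        "(cycle or bad ordering)"
                    )
                if self._by_id[parent].sex != want_sex:
                    raise PedigreeError(f"{m.id}: {role} {parent!r} has wrong sex")
            seen.add(m.id)

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, member_id: str) -> bool:
        return member_id in self._by_id

    def get(self, member_id: str) -> Member:
        try:
            return self._by_id[member_id]
        except KeyError:
            raise PedigreeError(f"unknown member {member_id!r}") from None

    @property
    def ids(self) -> list[str]:
        return [m.id for m in self.members]

    @property
    def founders(self) -> list[Member]:
        return [m for m in self.members if m.is_founder]

    @property
    def recorded_members(self) -> list[Member]:
        return [m for m in self.members if m.recorded]

    def ancestor_depths(self, member_id: str) -> dict[str, int]:
        """Minimum number of meioses from ``member_id`` up to each ancestor
        (the member itself is at depth 0)."""
        depths: dict[str, int] = {}
        stack = [(member_id, 0)]
        while stack:
            mid, d = stack.pop()
            if mid in depths and depths[mid] <= d:
                continue
            depths[mid] = d
            m = self.get(mid)
            for parent in (m.father, m.mother):
                if parent is not None:
                    stack.append((parent, d + 1))
        return depths


def meioses_between(pedigree: Pedigree, id_a: str, id_b: str) -> int | None:
    """Length of the shortest up-down path through a common ancestor, in
    meioses; ``None`` when the two members share no ancestor."""
    da = pedigree.ancestor_depths(id_a)
    db = pedigree.ancestor_depths(id_b)
    common = set(da) & set(db)
    if not common:
        return None
    return min(da[c] + db[c] for c in common)


class _Namer:
    def __init__(self, fid: str) -> None:
        self.fid = fid
        self.n = 0

    def next(self) -> str:
        self.n += 1
        return f"{self.fid}-{self.n:03d}"


def _grow_kindred(spec, fid: str, rng: np.random.Generator) -> list[Member]:
    namer = _Namer(fid)
    members: list[Member] = []
    couples: list[tuple[Member, Member]] = []
    for _ in range(spec.n_founder_couples):
        father = Member(namer.next(), None, None, MALE, fid)
        mother = Member(namer.next(), None, None, FEMALE, fid)
        members += [father, mother]
        couples.append((father, mother))
    for gen in range(1, spec.generations):
        terminal = gen == spec.generations - 1
        next_couples: list[tuple[Member, Member]] = []
        n_total = 0
        for father, mother in couples:
            n_children = int(rng.poisson(spec.mean_sibship))
            n_total += n_children
            for _ in range(n_children):
                sex = MALE if rng.integers(0, 2) == 0 else FEMALE
                child = Member(namer.next(), father.id, mother.id, sex, fid)
                members.append(child)
                if not terminal:
                    spouse = Member(
                        namer.next(), None, None,
                        FEMALE if sex == MALE else MALE, fid,
                    )
                    members.append(spouse)
                    pair = (child, spouse) if sex == MALE else (spouse, child)
                    next_couples.append(pair)
        couples = next_couples
        if n_total == 0:
            break  # the kindred died out; a legitimate random outcome
    return members


def _hidden_chain(
    top: tuple[Member, Member],
    depth: int,
    namer: _Namer,
    rng: np.random.Generator,
) -> tuple[list[Member], tuple[Member, Member]]:
    """Unrecorded descent chain of ``depth - 1`` hidden generations below
    ``top``; returns the couple that will parent the link target."""
    members: list[Member] = []
    father, mother = top
    for _ in range(depth - 1):
        sex = MALE if rng.integers(0, 2) == 0 else FEMALE
        child = Member(namer.next(), father.id, mother.id, sex, namer.fid,
                       recorded=False)
        spouse = Member(namer.next(), None, None,
                        FEMALE if sex == MALE else MALE, namer.fid,
                        recorded=False)
        members += [child, spouse]
        father, mother = (child, spouse) if sex == MALE else (spouse, child)
    return members, (father, mother)


def build_pedigree(spec: PedigreeSpec, seed: int) -> Pedigree:
    """Generate a pedigree of recorded kindreds plus hidden link ancestry.

    Hidden link members come first in the member list (they are everyone's
    potential ancestors), then kindreds in spec order; the list is therefore
    topologically sorted.
    """
    spec.validate()
    rng = np.random.default_rng(seed)

    kindred_members = [
        _grow_kindred(ks, f"K{i + 1}", rng) for i, ks in enumerate(spec.kindreds)
    ]

    hidden: list[Member] = []
    if spec.n_unrecorded_links > 0:
        # Queue of link targets per kindred: founder fathers first, then
        # founder mothers.  A target founder acquires hidden parents and
        # stops being a true founder while staying recorded.
        queues: list[list[Member]] = []
        for members in kindred_members:
            founders = [m for m in members if m.is_founder]
            queues.append(
                [m for m in founders if m.sex == MALE]
                + [m for m in founders if m.sex == FEMALE]
            )

        def take_target(kindred_idx: int) -> Member:
            q = queues[kindred_idx]
            if not q:
                raise PedigreeError(
                    f"kindred {kindred_idx + 1} has no founder left to link"
                )
            return q.pop(0)

        n_kindreds = len(spec.kindreds)
        if spec.shared_ancestor:
            namer = _Namer("H0")
            apex_f = Member(namer.next(), None, None, MALE, "H0", recorded=False)
            apex_m = Member(namer.next(), None, None, FEMALE, "H0", recorded=False)
            hidden += [apex_f, apex_m]
            for j in range(spec.n_unrecorded_links):
                chain, couple = _hidden_chain(
                    (apex_f, apex_m), spec.link_meioses_per_side, namer, rng
                )
                hidden += chain
                target = take_target(j % n_kindreds)
                target.father, target.mother = couple[0].id, couple[1].id
        else:
            for j in range(spec.n_unrecorded_links):
                namer = _Namer(f"H{j + 1}")
                apex_f = Member(namer.next(), None, None, MALE, namer.fid,
                                recorded=False)
                apex_m = Member(namer.next(), None, None, FEMALE, namer.fid,
                                recorded=False)
                hidden += [apex_f, apex_m]
                for side in (0, 1):
                    chain, couple = _hidden_chain(
                        (apex_f, apex_m), spec.link_meioses_per_side, namer, rng
                    )
                    hidden += chain
                    target = take_target((2 * j + side) % n_kindreds)
                    target.father, target.mother = couple[0].id, couple[1].id

    members = hidden + [m for group in kindred_members for m in group]
    return Pedigree(members)
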