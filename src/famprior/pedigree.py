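"""Nuclear-pedigree model.

The study design this package targets is a two-generation multiplex family:
two founders and one sibship, with a subset of affected children (probands)
selected for sequencing.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional

__all__ = ["PedigreeMember", "Pedigree"]


@dataclass(frozen=True)
class PedigreeMember:
    member_id: str
    father_id: Optional[str]  # None for founders
    mother_id: Optional[str]
    sex: int  # 1 = male, 2 = female, 0 = unknown
    affected: bool


@dataclass
class Pedigree:
    """A two-founder nuclear family with a binary affection status."""

    family_id: str
    members: List[PedigreeMember] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [m.member_id for m in self.members]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise ValueError(f"duplicate member ids in pedigree: {dupes}")
        known = set(ids)
        for m in self.members:
            for pid in (m.father_id, m.mother_id):
                if pid is not None and pid not in known:
                    raise ValueError(
                        f"parent {pid!r} of member {m.member_id!r} is not in the pedigree"
                    )

    # -- views ---------------------------------------------------------------
    @property
    def by_id(self) -> Dict[str, PedigreeMember]:
        return {m.member_id: m for m in self.members}

    @property
    def founders(self) -> List[PedigreeMember]:
        return [m for m in self.members if m.father_id is None and m.mother_id is None]

    @property
    def children(self) -> List[PedigreeMember]:
        return [m for m in self.members if m.father_id is not None or m.mother_id is not None]

    @property
    def affected_children(self) -> List[PedigreeMember]:
        return [m for m in self.children if m.affected]

    @property
    def unaffected_children(self) -> List[PedigreeMember]:
        return [m for m in self.children if not m.affected]

    @property
    def probands(self) -> List[str]:
        """IDs of affected children, the sequenced subjects."""
        return [m.member_id for m in self.affected_children]

    def father_of(self, child_id: str) -> Optional[str]:
        return self.by_id[child_id].father_id

    def mother_of(self, child_id: str) -> Optional[str]:
        return self.by_id[child_id].mother_id

    def require_nuclear(self) -> tuple[str, str]:
        """Check the two-founder nuclear shape; return (father_id, mother_id).

        All children must share the same two parents, both of whom are
        founders in the pedigree.
        """
        founders = self.founders
        children = self.children
        if len(founders) != 2 or not children:
            raise ValueError(
                f"expected a two-founder nuclear family, got {len(founders)} founders "
                f"and {len(children)} children"
            )
        fathers = {c.father_id for c in children}
        mothers = {c.mother_id for c in children}
        if len(fathers) != 1 or len(mothers) != 1:
            raise ValueError("children do not share a single parental pair")
        father, mother = fathers.pop(), mothers.pop()
        if {father, mother} != {m.member_id for m in founders}:
            raise ValueError("children's parents are not the pedigree founders")
        return father, mother
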