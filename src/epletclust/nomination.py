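"""Nomination of driver eplets from clustered antibody-response groups.

The inference step: once beads are partitioned into response groups, each
group's allele set is the union of the alleles its beads carry (both chains
for DQ/DP heterodimer beads).  An eplet is *exclusive* to a group when every
tested allele expressing it lies inside that one group.  Exclusive eplets
are then filtered: those carried by fewer than ``min_allele_count`` tested
alleles cannot explain a correlated multi-bead response, and those with an
inadequate ElliPro category (Low / VeryLow by default) are poorly accessible
to antibody.  What survives is the driver list — the eplets nominated as
steering the group's clustered response.

Exclusivity is evaluated against the tested panel, not the full registry:
registry alleles absent from every group are ignored (with a logged count),
because the response groups can only contain tested alleles.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass
from typing import Iterable, Mapping

from .clustering import ClusterAssignment
from .panel import Panel
from .registry import ElliProCategory, EpletRegistry, LocusGroup

log = logging.getLogger(__name__)

__all__ = [
    "NominationError",
    "GroupAlleleSets",
    "ExclusiveEpletRow",
    "ExclusionReason",
    "FlaggedRow",
    "DriverReport",
    "group_alleles",
    "exclusive_eplets",
    "nominate_drivers",
    "chain_attribution",
    "DEFAULT_ALLOWED_SCORES",
]

#: ElliPro categories considered adequate for a driver eplet.  Unknown is
#: allowed through: a blank registry cell is not evidence of inaccessibility.
DEFAULT_ALLOWED_SCORES: frozenset[ElliProCategory] = frozenset(
    {ElliProCategory.HIGH, ElliProCategory.INTERMEDIATE, ElliProCategory.UNKNOWN}
)


class NominationError(ValueError):
    pass


@dataclass
class GroupAlleleSets:
    """Per-group union of the chain alleles carried by member beads."""

    locus_group: LocusGroup
    groups: dict[str, frozenset[str]]

    def __post_init__(self) -> None:
        self.locus_group = LocusGroup.coerce(self.locus_group)
        if not self.groups:
            raise NominationError("no groups")
        for gid, alleles in self.groups.items():
            if not alleles:
                raise NominationError(f"group {gid!r} has no alleles")

    @property
    def all_alleles(self) -> frozenset[str]:
        out: set[str] = set()
        for alleles in self.groups.values():
            out |= alleles
        return frozenset(out)


@dataclass(frozen=True)
class ExclusiveEpletRow:
    """One group-exclusive eplet with its panel-restricted expressing alleles."""

    eplet: str
    group: str
    alleles: tuple[str, ...]  # sorted, within-panel expressing alleles
    allele_count: int
    score: ElliProCategory
    chain_class: str


class ExclusionReason(str, enum.Enum):
    NONE = "none"
    SINGLE_ALLELE = "single_allele"
    LOW_SCORE = "low_score"


@dataclass(frozen=True)
class FlaggedRow:
    row: ExclusiveEpletRow
    reason: ExclusionReason


@dataclass
class DriverReport:
    rows: list[FlaggedRow]
    retained: list[str]
    min_allele_count: int
    allowed_scores: frozenset[ElliProCategory]


def group_alleles(
    groups: ClusterAssignment | Mapping[str, object],
    panel: Panel,
) -> GroupAlleleSets:
    """Union each group's bead alleles into a per-group allele set.

    ``groups`` maps bead id to group id (a :class:`ClusterAssignment` or any
    mapping; group ids are stringified).  Every bead must belong to a group
    in the panel, and every group must be non-empty.  For heterodimer beads
    both chain alleles join the set, so an alpha allele paired into several
    groups legitimately appears in all of them.
    """
    mapping = groups.assignment if isinstance(groups, ClusterAssignment) else groups
    panel_ids = set(panel.bead_ids)
    unknown = set(mapping) - panel_ids
    if unknown:
        raise NominationError(f"bead(s) {sorted(unknown)} not in the panel")
    unassigned = panel_ids - set(mapping)
    if unassigned:
        raise NominationError(f"bead(s) {sorted(unassigned)} have no group")
    sets: dict[str, set[str]] = {}
    for bead in panel.beads:
        gid = str(mapping[bead.bead_id])
        sets.setdefault(gid, set()).update(bead.alleles)
    return GroupAlleleSets(
        locus_group=panel.locus_group,
        groups={gid: frozenset(a) for gid, a in sets.items()},
    )


def _sort_group_key(gid: str):
    return (len(gid), gid)  # numeric-ish ids sort naturally, then lexicographic


def exclusive_eplets(
    gs: GroupAlleleSets, registry: EpletRegistry
) -> list[ExclusiveEpletRow]:
    """Eplets whose tested expressing alleles fall inside exactly one group.

    For eplet e with panel-restricted expressing set
    S(e) = alleles_expressing(e) intersect (union of all group sets),
    e is emitted iff S(e) is non-empty, is a subset of exactly one group's
    allele set, and is not a subset of any other group's set.  Rows are
    sorted by (group, eplet name).
    """
    if LocusGroup.coerce(gs.locus_group) is not LocusGroup.coerce(registry.locus_group):
        raise NominationError(
            f"locus mismatch: groups are {gs.locus_group.value}, "
            f"registry is {registry.locus_group.value}"
        )
    tested = gs.all_alleles
    untested = registry.alleles - tested
    if untested:
        log.info(
            "%d registry allele(s) absent from the tested panel are ignored",
            len(untested),
        )
    rows: list[ExclusiveEpletRow] = []
    for eplet in registry.eplets:
        s = registry.alleles_expressing(eplet) & tested
        if not s:
            continue
        containing = [gid for gid, alleles in gs.groups.items() if s <= alleles]
        if len(containing) != 1:
            continue
        record = registry.eplet_index[eplet]
        rows.append(
            ExclusiveEpletRow(
                eplet=eplet,
                group=containing[0],
                alleles=tuple(sorted(s)),
                allele_count=len(s),
                score=record.score,
                chain_class=record.chain_class,
            )
        )
    rows.sort(key=lambda r: (_sort_group_key(r.group), r.eplet))
    return rows


def nominate_drivers(
    rows: Iterable[ExclusiveEpletRow],
    min_allele_count: int = 2,
    allowed_scores: frozenset[ElliProCategory] = DEFAULT_ALLOWED_SCORES,
) -> DriverReport:
    """Filter exclusive eplets down to the nominated drivers.

    Flags are mutually exclusive with precedence ``single_allele`` over
    ``low_score``: an eplet failing both filters counts as single-allele.
    Row order is preserved; retained eplets are the unflagged rows.
    """
    allowed = frozenset(allowed_scores)
    flagged: list[FlaggedRow] = []
    for row in rows:
        if row.allele_count < min_allele_count:
            reason = ExclusionReason.SINGLE_ALLELE
        elif row.score not in allowed:
            reason = ExclusionReason.LOW_SCORE
        else:
            reason = ExclusionReason.NONE
        flagged.append(FlaggedRow(row=row, reason=reason))
    retained = [f.row.eplet for f in flagged if f.reason is ExclusionReason.NONE]
    return DriverReport(
        rows=flagged,
        retained=retained,
        min_allele_count=min_allele_count,
        allowed_scores=allowed,
    )


def chain_attribution(report: DriverReport) -> dict[str, int]:
    """Count retained driver eplets per chain class (alpha vs beta)."""
    counts = {"alpha": 0, "beta": 0}
    retained = set(report.retained)
    for f in report.rows:
        if f.row.eplet in retained and f.reason is ExclusionReason.NONE:
            counts[f.row.chain_class] += 1
    return counts
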