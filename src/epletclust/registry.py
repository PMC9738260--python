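"""Allele-to-eplet registries for the HLA class II loci.

An *eplet* is a small patch of polymorphic surface residues on an HLA
molecule that antibodies recognise.  Because many alleles carry the same
eplet, antibody responses cross-react within a locus; the registry records,
for one locus group (DRB, DQ or DP), which alleles express which eplets and
the ElliPro antibody-accessibility category of each eplet.

Registries are strictly per locus group: HLA class II cross-reactions are
essentially intralocus, so cross-locus queries are rejected at load time.
"""

from __future__ import annotations

import csv
import enum
import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

log = logging.getLogger(__name__)

__all__ = [
    "RegistryError",
    "LocusGroup",
    "ElliProCategory",
    "EpletRecord",
    "EpletRegistry",
    "chain_locus_of",
    "chain_class_of",
    "load_registry",
    "write_registry",
]


class RegistryError(ValueError):
    """Raised when a registry file or query violates the registry contract."""


class LocusGroup(str, enum.Enum):
    """The three HLA class II locus groups analysed separately."""

    DRB = "DRB"
    DQ = "DQ"
    DP = "DP"

    @classmethod
    def coerce(cls, value: "LocusGroup | str") -> "LocusGroup":
        if isinstance(value, cls):
            return value
        text = str(value).upper()
        if text == "DR":  # common shorthand for the DRB group
            text = "DRB"
        try:
            return cls(text)
        except ValueError:
            raise RegistryError(
                f"unknown locus group {value!r}; expected one of DRB/DR, DQ, DP"
            ) from None


#: chain loci whose alleles may appear in each locus group
CHAIN_LOCI: Mapping[LocusGroup, tuple[str, ...]] = {
    LocusGroup.DRB: ("DRB1", "DRB3", "DRB4", "DRB5"),
    LocusGroup.DQ: ("DQA1", "DQB1"),
    LocusGroup.DP: ("DPA1", "DPB1"),
}


class ElliProCategory(enum.Enum):
    """ElliPro antibody-accessibility category of an eplet.

    A closed enumeration; registry cells left blank map to ``UNKNOWN``, which
    downstream filters treat as *not* grounds for exclusion.
    """

    HIGH = "High"
    INTERMEDIATE = "Intermediate"
    LOW = "Low"
    VERY_LOW = "VeryLow"
    UNKNOWN = "Unknown"

    @classmethod
    def parse(cls, text: str) -> "ElliProCategory":
        stripped = text.strip()
        if not stripped:
            return cls.UNKNOWN
        for member in cls:
            if member.value == stripped:
                return member
        raise RegistryError(
            f"unknown ElliPro score label {text!r}; expected one of "
            f"{[m.value for m in cls]} or an empty cell"
        )


_ALLELE_RE = re.compile(r"^(DRB[1345]|DQA1|DQB1|DPA1|DPB1)\*\d{2,}(?::\d{2,})?$")


def chain_locus_of(allele: str) -> str:
    """Return the chain locus (e.g. ``DRB1``, ``DQA1``) of a WHO allele name."""
    m = _ALLELE_RE.match(allele)
    if m is None:
        raise RegistryError(
            f"malformed allele name {allele!r}; expected e.g. DRB1*01:01"
        )
    return m.group(1)


def chain_class_of(allele: str) -> str:
    """``alpha`` for A1-chain alleles, ``beta`` for B1/DRB-chain alleles."""
    locus = chain_locus_of(allele)
    return "alpha" if locus.endswith("A1") else "beta"


@dataclass(frozen=True)
class EpletRecord:
    """One eplet: its name, chain class, and ElliPro category."""

    name: str
    chain_class: str  # "alpha" or "beta"
    score: ElliProCategory


@dataclass
class EpletRegistry:
    """Per-locus-group map between alleles and the eplets they express."""

    locus_group: LocusGroup
    expression_map: dict[str, frozenset[str]]  # allele -> eplet names
    eplet_index: dict[str, EpletRecord] = field(repr=False)

    def __post_init__(self) -> None:
        self.locus_group = LocusGroup.coerce(self.locus_group)
        self.validate()

    # -- queries -----------------------------------------------------------

    def eplets_of(self, allele: str) -> frozenset[str]:
        """Eplets expressed by *allele*; raises for alleles not in the registry."""
        try:
            return self.expression_map[allele]
        except KeyError:
            raise RegistryError(
                f"allele {allele!r} is not in the {self.locus_group.value} registry"
            ) from None

    def alleles_expressing(self, eplet: str) -> frozenset[str]:
        """Alleles carrying *eplet*; raises for unknown eplets."""
        if eplet not in self.eplet_index:
            raise RegistryError(
                f"eplet {eplet!r} is not in the {self.locus_group.value} registry"
            )
        return self._inverse[eplet]

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset(self.expression_map)

    @property
    def eplets(self) -> frozenset[str]:
        return frozenset(self.eplet_index)

    def score_of(self, eplet: str) -> ElliProCategory:
        if eplet not in self.eplet_index:
            raise RegistryError(f"eplet {eplet!r} is not in the registry")
        return self.eplet_index[eplet].score

    # -- validation --------------------------------------------------------

    def validate(self) -> None:
        allowed = CHAIN_LOCI[LocusGroup.coerce(self.locus_group)]
        inverse: dict[str, set[str]] = {name: set() for name in self.eplet_index}
        for allele, eplets in self.expression_map.items():
            locus = chain_locus_of(allele)
            if locus not in allowed:
                raise RegistryError(
                    f"allele {allele} (locus {locus}) is not valid for "
                    f"locus group {LocusGroup.coerce(self.locus_group).value}"
                )
            if not eplets:
                raise RegistryError(f"allele {allele} expresses no eplets")
            for e in eplets:
                if e not in self.eplet_index:
                    raise RegistryError(
                        f"eplet {e} referenced by {allele} has no registry record"
                    )
                inverse[e].add(allele)
        for name, alleles in inverse.items():
            if not alleles:
                raise RegistryError(f"eplet {name} is expressed by no allele")
            classes = {chain_class_of(a) for a in alleles}
            if classes != {self.eplet_index[name].chain_class}:
                raise RegistryError(
                    f"eplet {name}: chain class {self.eplet_index[name].chain_class} "
                    f"inconsistent with expressing alleles {sorted(alleles)}"
                )
        self._inverse = {name: frozenset(a) for name, a in inverse.items()}


def load_registry(path: str | Path, locus_group: LocusGroup | str) -> EpletRegistry:
    """Load an (allele, eplet, score) table into a validated :class:`EpletRegistry`.

    The file is CSV/TSV with header ``allele,eplet,score``, one row per
    (allele, eplet) pair.  Duplicate rows are deduplicated with a warning;
    an empty score cell maps to :attr:`ElliProCategory.UNKNOWN`.
    """
    locus_group = LocusGroup.coerce(locus_group)
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    delimiter = "\t" if "\t" in text.splitlines()[0] else ","
    reader = csv.DictReader(text.splitlines(), delimiter=delimiter)
    required = {"allele", "eplet", "score"}
    if reader.fieldnames is None or not required.issubset(reader.fieldnames):
        raise RegistryError(
            f"{path}: expected header with columns {sorted(required)}, "
            f"found {reader.fieldnames}"
        )

    expression: dict[str, set[str]] = {}
    scores: dict[str, ElliProCategory] = {}
    seen: set[tuple[str, str]] = set()
    n_dupes = 0
    for i, row in enumerate(reader, start=2):
        allele = (row["allele"] or "").strip()
        eplet = (row["eplet"] or "").strip()
        if not allele or not eplet:
            raise RegistryError(f"{path}:{i}: empty allele or eplet cell")
        chain_locus_of(allele)  # raises on malformed names
        try:
            score = ElliProCategory.parse(row["score"] or "")
        except RegistryError as err:
            raise RegistryError(f"{path}:{i}: {err}") from None
        key = (allele, eplet)
        if key in seen:
            n_dupes += 1
            continue
        seen.add(key)
        expression.setdefault(allele, set()).add(eplet)
        if eplet in scores and scores[eplet] is not score:
            raise RegistryError(
                f"{path}:{i}: eplet {eplet} listed with conflicting scores"
            )
        scores[eplet] = score
    if n_dupes:
        log.warning("%s: %d duplicate (allele, eplet) rows deduplicated", path, n_dupes)
    if not scores:
        raise RegistryError(f"{path}: no eplets parsed (empty registry)")

    index: dict[str, EpletRecord] = {}
    for eplet, score in scores.items():
        carriers = [a for a, es in expression.items() if eplet in es]
        classes = {chain_class_of(a) for a in carriers}
        if len(classes) != 1:
            raise RegistryError(
                f"{path}: eplet {eplet} expressed by both alpha and beta chains"
            )
        index[eplet] = EpletRecord(eplet, classes.pop(), score)
    return EpletRegistry(
        locus_group=locus_group,
        expression_map={a: frozenset(es) for a, es in expression.items()},
        eplet_index=index,
    )


def write_registry(registry: EpletRegistry, path: str | Path) -> None:
    """Write a registry back to its CSV form (rows sorted for stable output)."""
    path = Path(path)
    rows: list[tuple[str, str, str]] = []
    for allele in sorted(registry.expression_map):
        for eplet in sorted(registry.expression_map[allele]):
            score = registry.eplet_index[eplet].score
            label = "" if score is ElliProCategory.UNKNOWN else score.value
            rows.append((allele, eplet, label))
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["allele", "eplet", "score"])
        writer.writerows(rows)
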