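"""Packaged reference fixtures: exclusive-eplet registries, panels, groups.

The shipped registries cover the group-exclusive eplet subsets of the DRB,
DQ and DP locus groups, transcribed with their ElliPro categories and the
explicit allele lists of each antibody-response group ("whole group"
shorthands are expanded to the member alleles).  They are not the full
epitope registry — locus-wide eplet totals are configuration constants in
``registry_totals.json``, not computable from these subsets.
"""

from __future__ import annotations

import csv
import json
from importlib import resources
from pathlib import Path

from .panel import Panel, load_panel
from .registry import EpletRegistry, LocusGroup, load_registry

__all__ = [
    "fixture_path",
    "load_reference_registry",
    "load_reference_panel",
    "load_reference_groups",
    "registry_total",
]

_REGISTRY_FILES = {
    LocusGroup.DRB: "drb_table1.csv",
    LocusGroup.DQ: "dq_table2.csv",
    LocusGroup.DP: "dp_table3.csv",
}
_PANEL_FILES = {
    LocusGroup.DRB: "panel_drb.csv",
    LocusGroup.DQ: "panel_dq.csv",
    LocusGroup.DP: "panel_dp.csv",
}
_GROUP_FILES = {
    LocusGroup.DRB: "groups_drb.csv",
    LocusGroup.DQ: "groups_dq.csv",
    LocusGroup.DP: "groups_dp.csv",
}


def fixture_path(name: str) -> Path:
    """Filesystem path of a packaged data file."""
    return Path(resources.files("epletclust.data") / name)


def load_reference_registry(locus_group: LocusGroup | str) -> EpletRegistry:
    """The exclusive-eplet registry fixture for one locus group."""
    lg = LocusGroup.coerce(locus_group)
    return load_registry(fixture_path(_REGISTRY_FILES[lg]), lg)


def load_reference_panel(locus_group: LocusGroup | str) -> Panel:
    """A bead panel covering the reference groups (one bead per DR allele,
    one per DQ/DP heterodimer pair)."""
    lg = LocusGroup.coerce(locus_group)
    return load_panel(fixture_path(_PANEL_FILES[lg]), lg)


def load_reference_groups(locus_group: LocusGroup | str) -> dict[str, str]:
    """The published bead -> response-group assignment for one locus group."""
    lg = LocusGroup.coerce(locus_group)
    with fixture_path(_GROUP_FILES[lg]).open(newline="", encoding="utf-8") as fh:
        return {row["bead_id"]: row["group"] for row in csv.DictReader(fh)}


def registry_total(locus_group: LocusGroup | str) -> int:
    """Locus-wide eplet total of the full epitope registry (metadata)."""
    lg = LocusGroup.coerce(locus_group)
    with fixture_path("registry_totals.json").open(encoding="utf-8") as fh:
        return int(json.load(fh)[lg.value])


def load_groups_file(path: str | Path) -> dict[str, str]:
    """Read an explicit bead -> group CSV (header ``bead_id,group``)."""
    with Path(path).open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or {"bead_id", "group"} - set(reader.fieldnames):
            raise ValueError(f"{path}: expected header bead_id,group")
        return {row["bead_id"]: row["group"] for row in reader}
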