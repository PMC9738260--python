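"""Single-antigen-bead (SAB) panels and raw-MFI matrices.

A Luminex SAB panel is a set of beads, each coated with one HLA class II
protein (DR) or an alpha/beta heterodimer (DQ, DP).  The assay readout is a
patients x beads matrix of raw Mean Fluorescence Intensities (MFI).  No
positivity threshold is applied anywhere in this package: all device values
enter the analysis, positive or negative, and only non-finite cells are
rejected.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .registry import CHAIN_LOCI, LocusGroup, chain_class_of, chain_locus_of

log = logging.getLogger(__name__)

__all__ = [
    "PanelError",
    "Bead",
    "Panel",
    "MFIMatrix",
    "StandardizedMatrix",
    "load_panel",
    "write_panel",
    "load_mfi",
    "write_mfi",
    "standardize",
]


class PanelError(ValueError):
    """Raised for structurally invalid panels or MFI matrices."""


@dataclass(frozen=True)
class Bead:
    """One bead: a single DR protein or a DQ/DP alpha+beta heterodimer."""

    bead_id: str
    alleles: tuple[str, ...]


@dataclass
class Panel:
    locus_group: LocusGroup
    beads: list[Bead]

    def __post_init__(self) -> None:
        self.locus_group = LocusGroup.coerce(self.locus_group)
        self.validate()

    def validate(self) -> None:
        if len(self.beads) < 2:
            raise PanelError("a panel needs at least 2 beads")
        ids = [b.bead_id for b in self.beads]
        if len(set(ids)) != len(ids):
            raise PanelError("bead ids are not unique")
        allowed = CHAIN_LOCI[self.locus_group]
        for bead in self.beads:
            loci = [chain_locus_of(a) for a in bead.alleles]
            for locus in loci:
                if locus not in allowed:
                    raise PanelError(
                        f"bead {bead.bead_id}: allele locus {locus} not valid "
                        f"for {self.locus_group.value}"
                    )
            if self.locus_group is LocusGroup.DRB:
                if len(bead.alleles) != 1:
                    raise PanelError(
                        f"bead {bead.bead_id}: DR beads carry exactly one allele"
                    )
            else:
                classes = sorted(chain_class_of(a) for a in bead.alleles)
                if len(bead.alleles) != 2 or classes != ["alpha", "beta"]:
                    raise PanelError(
                        f"bead {bead.bead_id}: {self.locus_group.value} beads carry "
                        f"one alpha and one beta allele, got {bead.alleles}"
                    )

    @property
    def bead_ids(self) -> list[str]:
        return [b.bead_id for b in self.beads]

    @property
    def alleles(self) -> frozenset[str]:
        return frozenset(a for b in self.beads for a in b.alleles)

    def bead(self, bead_id: str) -> Bead:
        for b in self.beads:
            if b.bead_id == bead_id:
                return b
        raise PanelError(f"no bead {bead_id!r} in panel")


@dataclass
class MFIMatrix:
    """Patients x beads matrix of raw MFI values (device units)."""

    data: pd.DataFrame  # index: patient ids; columns: bead ids

    def __post_init__(self) -> None:
        df = self.data
        if df.index.has_duplicates:
            raise PanelError("duplicate patient ids")
        if df.columns.has_duplicates:
            raise PanelError("duplicate bead ids")
        if not np.isfinite(df.to_numpy(dtype=float)).all():
            raise PanelError("MFI matrix contains non-finite values")
        self.data = df.astype(float)

    @property
    def patient_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def bead_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()


@dataclass
class StandardizedMatrix(MFIMatrix):
    """An MFI matrix whose columns have mean 0 and sample SD 1."""


def load_panel(path: str | Path, locus_group: LocusGroup | str) -> Panel:
    """Read a panel CSV (``bead_id,allele1,allele2``; allele2 empty for DR)."""
    locus_group = LocusGroup.coerce(locus_group)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    expected = ["bead_id", "allele1"]
    if list(df.columns[:2]) != expected:
        raise PanelError(f"{path}: expected columns {expected}[, allele2]")
    beads = []
    for _, row in df.iterrows():
        alleles = [row["allele1"].strip()]
        second = row.get("allele2", "")
        if isinstance(second, str) and second.strip():
            alleles.append(second.strip())
        beads.append(Bead(bead_id=row["bead_id"].strip(), alleles=tuple(alleles)))
    return Panel(locus_group=locus_group, beads=beads)


def write_panel(panel: Panel, path: str | Path) -> None:
    rows = []
    for b in panel.beads:
        rows.append(
            {
                "bead_id": b.bead_id,
                "allele1": b.alleles[0],
                "allele2": b.alleles[1] if len(b.alleles) > 1 else "",
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def load_mfi(path: str | Path, panel: Panel, missing: str = "drop") -> MFIMatrix:
    """Read a raw-MFI CSV (first column patient id, remaining columns beads).

    Columns are aligned to the panel bead order.  Patients with any missing
    bead value are dropped (with a warning reporting the count) under the
    default ``missing="drop"`` policy, or rejected under ``missing="error"``.
    """
    if missing not in {"drop", "error"}:
        raise PanelError(f"missing policy must be 'drop' or 'error', got {missing!r}")
    df = pd.read_csv(path, index_col=0, dtype=str, keep_default_na=False)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise PanelError(f"{path}: duplicate patient ids {dupes}")
    have, want = set(df.columns), set(panel.bead_ids)
    if have != want:
        raise PanelError(
            f"{path}: bead header mismatch with panel; "
            f"only in file: {sorted(have - want)}, only in panel: {sorted(want - have)}"
        )
    numeric = pd.DataFrame(index=df.index, columns=panel.bead_ids, dtype=float)
    for col in panel.bead_ids:
        raw = df[col].str.strip()
        blank = raw == ""
        parsed = pd.to_numeric(raw.where(~blank), errors="coerce")
        bad = parsed.isna() & ~blank
        if bad.any():
            patient = df.index[bad.to_numpy()][0]
            raise PanelError(
                f"{path}: non-numeric value {df.loc[patient, col]!r} "
                f"at patient {patient!r}, bead {col!r}"
            )
        numeric[col] = parsed
    incomplete = numeric.isna().any(axis=1)
    if incomplete.any():
        if missing == "error":
            raise PanelError(
                f"{path}: {int(incomplete.sum())} patients have missing bead values"
            )
        log.warning(
            "%s: %d patient(s) dropped for missing bead values",
            path,
            int(incomplete.sum()),
        )
        numeric = numeric.loc[~incomplete]
    return MFIMatrix(data=numeric)


def write_mfi(m: MFIMatrix, path: str | Path) -> None:
    """Write an MFI matrix to CSV at 10 significant digits (round-trip safe)."""
    m.data.to_csv(path, index_label="patient_id", float_format="%.10g")


def standardize(m: MFIMatrix, zero_variance: str = "error") -> StandardizedMatrix:
    """Center each bead column to mean 0 and scale to sample (n-1) SD 1.

    This is the sole transformation applied before ordination and distance
    computation.  Columns with zero sample variance cannot be scaled: the
    default policy raises naming the bead; ``zero_variance="drop"`` removes
    them with a warning instead.
    """
    if zero_variance not in {"error", "drop"}:
        raise PanelError(
            f"zero_variance policy must be 'error' or 'drop', got {zero_variance!r}"
        )
    df = m.data
    if len(df) < 2:
        raise PanelError("standardization needs at least 2 patients")
    sd = df.std(ddof=1)
    degenerate = sd[sd == 0.0].index.tolist()
    if degenerate:
        if zero_variance == "error":
            raise PanelError(f"zero-variance bead column(s): {degenerate}")
        log.warning("dropping %d zero-variance bead column(s): %s",
                    len(degenerate), degenerate)
        df = df.drop(columns=degenerate)
        sd = sd.drop(index=degenerate)
        if df.shape[1] < 2:
            raise PanelError("fewer than 2 bead columns left after dropping")
    out = (df - df.mean()) / sd
    return StandardizedMatrix(data=out)
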