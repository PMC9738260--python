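"""End-to-end locus-level analysis with config validation and report writing.

One run covers a single locus group: load registry/panel/MFI, standardize,
ordinate, compute antigenic distances, agglomerate, group beads (explicit
group file takes precedence over the dendrogram cut, since published group
assignments derive from reading the ordination, not from an automated cut),
and nominate driver eplets.  All artifacts are plain CSV/JSON/Newick and are
byte-stable across runs up to the run-summary timestamp.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path

import yaml

from . import __version__
from .clustering import (
    antigen_features,
    cut_tree,
    distances_frame,
    minkowski_distances,
    to_newick,
    ward_linkage,
)
from .datasets import load_groups_file
from .nomination import (
    DEFAULT_ALLOWED_SCORES,
    ExclusionReason,
    chain_attribution,
    exclusive_eplets,
    group_alleles,
    nominate_drivers,
)
from .ordination import biplot_table, pca, pca_summary
from .panel import Panel, load_mfi, load_panel, standardize
from .registry import ElliProCategory, LocusGroup, load_registry

log = logging.getLogger(__name__)

__all__ = ["ConfigError", "AnalysisConfig", "RunArtifacts", "validate_config", "run_analysis"]


class ConfigError(ValueError):
    pass


@dataclass
class AnalysisConfig:
    locus: str
    registry: Path
    panel: Path
    mfi: Path
    groups: Path | None = None
    minkowski_p: float = 2.0
    k: int = 3
    min_allele_count: int = 2
    allowed_scores: list[str] = field(
        default_factory=lambda: ["High", "Intermediate", "Unknown"]
    )
    missing: str = "drop"
    zero_variance: str = "error"
    out_dir: Path = Path("results")
    seed: int = 0

    def __post_init__(self) -> None:
        problems = []
        try:
            LocusGroup.coerce(self.locus)
        except Exception:
            problems.append(f"locus: unknown locus group {self.locus!r}")
        if self.minkowski_p < 1:
            problems.append(f"minkowski_p: must be >= 1, got {self.minkowski_p}")
        if self.k < 1:
            problems.append(f"k: must be >= 1, got {self.k}")
        if self.min_allele_count < 1:
            problems.append(
                f"min_allele_count: must be >= 1, got {self.min_allele_count}"
            )
        for label in self.allowed_scores:
            try:
                ElliProCategory.parse(label)
            except Exception:
                problems.append(f"allowed_scores: unknown category {label!r}")
        if self.missing not in {"drop", "error"}:
            problems.append(f"missing: must be 'drop' or 'error', got {self.missing!r}")
        if self.zero_variance not in {"error", "drop"}:
            problems.append(
                f"zero_variance: must be 'error' or 'drop', got {self.zero_variance!r}"
            )
        if problems:
            raise ConfigError("; ".join(problems))
        self.registry = Path(self.registry)
        self.panel = Path(self.panel)
        self.mfi = Path(self.mfi)
        self.groups = Path(self.groups) if self.groups else None
        self.out_dir = Path(self.out_dir)

    @property
    def locus_group(self) -> LocusGroup:
        return LocusGroup.coerce(self.locus)

    @property
    def score_set(self) -> frozenset[ElliProCategory]:
        return frozenset(ElliProCategory.parse(s) for s in self.allowed_scores)


def validate_config(path: str | Path, **overrides) -> AnalysisConfig:
    """Read a YAML config file into a fully-defaulted, range-checked config.

    Unknown keys are rejected; keyword overrides (e.g. from CLI flags) take
    precedence over file values.
    """
    raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: config must be a mapping")
    known = set(AnalysisConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigError(f"{path}: unknown config key(s) {sorted(unknown)}")
    raw.update({k: v for k, v in overrides.items() if v is not None})
    missing_required = {"locus", "registry", "panel", "mfi"} - set(raw)
    if missing_required:
        raise ConfigError(f"{path}: missing required key(s) {sorted(missing_required)}")
    try:
        return AnalysisConfig(**raw)
    except TypeError as err:
        raise ConfigError(f"{path}: {err}") from None


@dataclass
class RunArtifacts:
    files: list[Path]
    summary: dict


def run_analysis(cfg: AnalysisConfig) -> RunArtifacts:
    """Execute the full locus analysis and write all reports.

    On any stage failure the partially written artifacts are removed and the
    error re-raised with the stage name.
    """
    lg = cfg.locus_group
    for name in ("registry", "panel", "mfi"):
        p = getattr(cfg, name)
        if not Path(p).exists():
            raise ConfigError(f"{name} path does not exist: {p}")
    if cfg.groups is not None and not cfg.groups.exists():
        raise ConfigError(f"groups path does not exist: {cfg.groups}")

    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    def emit_csv(name: str, frame, **kwargs) -> None:
        path = out / name
        frame.to_csv(path, **kwargs)
        written.append(path)

    def emit_text(name: str, text: str) -> None:
        path = out / name
        path.write_text(text, encoding="utf-8")
        written.append(path)

    stage = "load"
    try:
        registry = load_registry(cfg.registry, lg)
        panel = load_panel(cfg.panel, lg)
        matrix = load_mfi(cfg.mfi, panel, missing=cfg.missing)
        n_loaded = len(matrix.patient_ids)

        stage = "standardize"
        std = standardize(matrix, zero_variance=cfg.zero_variance)

        stage = "pca"
        result = pca(std)
        emit_csv("pca_summary.csv", pca_summary(result), index=False,
                 float_format="%.10g")
        for i, j in ((1, 2), (2, 3)):
            if j <= result.n_components:
                emit_csv(f"biplot_dims_{i}_{j}.csv", biplot_table(result, i, j),
                         index=False, float_format="%.10g")
            else:
                log.info("skipping biplot dims (%d,%d): only %d component(s)",
                         i, j, result.n_components)

        stage = "distances"
        features = antigen_features(std)
        dm = minkowski_distances(features, p=cfg.minkowski_p)
        emit_csv(f"distances_{lg.value}.csv", distances_frame(dm),
                 float_format="%.10g")

        stage = "ward"
        tree = ward_linkage(dm)
        emit_text(f"dendrogram_{lg.value}.nwk", to_newick(tree) + "\n")

        stage = "grouping"
        if cfg.groups is not None:
            mapping: dict[str, str] = {
                b: g for b, g in load_groups_file(cfg.groups).items()
                if b in set(features.index)
            }
        else:
            mapping = {b: str(g) for b, g in cut_tree(tree, cfg.k).assignment.items()}
        group_rows = [{"bead_id": b, "group": mapping[b]} for b in features.index]
        import pandas as pd

        emit_csv(f"groups_{lg.value}.csv", pd.DataFrame(group_rows), index=False)

        stage = "nomination"
        kept_beads = set(features.index)
        subpanel = panel if kept_beads == set(panel.bead_ids) else Panel(
            locus_group=lg, beads=[b for b in panel.beads if b.bead_id in kept_beads]
        )
        gs = group_alleles(mapping, subpanel)
        rows = exclusive_eplets(gs, registry)
        report = nominate_drivers(
            rows,
            min_allele_count=cfg.min_allele_count,
            allowed_scores=cfg.score_set,
        )
        attribution = chain_attribution(report)
        driver_rows = [
            {
                "eplet": f.row.eplet,
                "group": f.row.group,
                "alleles": ";".join(f.row.alleles),
                "allele_count": f.row.allele_count,
                "score": f.row.score.value,
                "chain": f.row.chain_class,
                "exclusion_reason": f.reason.value,
            }
            for f in report.rows
        ]
        emit_csv(f"drivers_{lg.value}.csv", pd.DataFrame(
            driver_rows,
            columns=["eplet", "group", "alleles", "allele_count", "score",
                     "chain", "exclusion_reason"],
        ), index=False)
        counts = {
            "n_exclusive": len(report.rows),
            "n_single_allele": sum(
                1 for f in report.rows if f.reason is ExclusionReason.SINGLE_ALLELE
            ),
            "n_low_score": sum(
                1 for f in report.rows if f.reason is ExclusionReason.LOW_SCORE
            ),
            "n_retained": len(report.retained),
        }
        drivers_json = {
            **counts,
            "retained": report.retained,
            "chain_attribution": attribution,
            "min_allele_count": cfg.min_allele_count,
            "allowed_scores": sorted(s.value for s in cfg.score_set),
        }
        emit_text(f"drivers_{lg.value}.json",
                  json.dumps(drivers_json, indent=2) + "\n")

        stage = "summary"
        summary = {
            "locus": lg.value,
            "version": __version__,
            "timestamp_utc": datetime.now(timezone.utc).isoformat(),
            "parameters": {
                "minkowski_p": cfg.minkowski_p,
                "k": cfg.k,
                "min_allele_count": cfg.min_allele_count,
                "allowed_scores": sorted(s.value for s in cfg.score_set),
                "missing": cfg.missing,
                "zero_variance": cfg.zero_variance,
                "explicit_groups": cfg.groups is not None,
            },
            "counts": {
                "n_patients": n_loaded,
                "n_beads": len(features.index),
                "n_groups": len(set(mapping.values())),
                **counts,
            },
            "files": [p.name for p in written],
        }
        emit_text("run_summary.json", json.dumps(summary, indent=2) + "\n")
        return RunArtifacts(files=list(written), summary=summary)
    except Exception as err:
        for path in written:
            try:
                path.unlink()
            except OSError:
                pass
        err.args = (f"[stage: {stage}] {err}",)
        raise
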