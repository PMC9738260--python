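"""Synthetic SAB cohorts with eplet-driven correlated bead responses.

The generative mechanism mirrors the inference the analysis performs in
reverse: a sensitized patient's antibodies target *eplets*, and every bead
carrying an allele that expresses a targeted eplet lights up together.
Shared eplets therefore induce correlated bead columns — the structure the
PCA/dendrogram stack is designed to recover.

Model, per patient:

1. the patient is a responder with probability ``sensitization_prob``;
2. a responder draws ``1 + Poisson(exposures_per_responder - 1)`` exposure
   alleles uniformly (without replacement) from the panel alleles;
3. each eplet of an exposure allele enters the patient's sensitizing set
   with probability ``score_weights[ElliPro category]`` — higher-scoring
   (more antibody-accessible) eplets are more immunogenic;
4. each sensitized eplet contributes an independent log-normal reactivity
   (median ``exp(reactivity_log_mean)`` device units);
5. bead MFI = Gaussian background + sum of reactivities of sensitized
   eplets expressed by the bead's allele(s) + Gaussian noise, clipped to
   ``[0, saturation_cap]``.

Everything is driven by one seed, so cohorts are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.metrics import adjusted_rand_score

from .clustering import antigen_features, cut_tree, minkowski_distances, ward_linkage
from .nomination import (
    DEFAULT_ALLOWED_SCORES,
    exclusive_eplets,
    group_alleles,
    nominate_drivers,
)
from .panel import Bead, MFIMatrix, Panel, standardize
from .registry import ElliProCategory, EpletRecord, EpletRegistry, LocusGroup

__all__ = [
    "SimulationParams",
    "GroundTruth",
    "SimulatedCohort",
    "RecoveryResult",
    "simulate_cohort",
    "sensitize",
    "recovery_experiment",
    "block_design",
]

#: immunogenicity probability by ElliPro category
DEFAULT_SCORE_WEIGHTS: Mapping[ElliProCategory, float] = {
    ElliProCategory.HIGH: 0.9,
    ElliProCategory.INTERMEDIATE: 0.6,
    ElliProCategory.LOW: 0.2,
    ElliProCategory.VERY_LOW: 0.05,
    ElliProCategory.UNKNOWN: 0.6,
}


@dataclass
class SimulationParams:
    """Tunable cohort parameters; defaults give a clearly structured cohort.

    ``reactivity_log_mean/sd`` parameterize the underlying normal of the
    log-normal eplet reactivity (default median 5000 MFI, a strong positive
    reaction); background and noise are in the same device units.
    """

    n_patients: int = 300
    sensitization_prob: float = 0.6
    exposures_per_responder: float = 2.0  # mean of the shifted Poisson, min 1
    score_weights: Mapping[ElliProCategory, float] = field(
        default_factory=lambda: dict(DEFAULT_SCORE_WEIGHTS)
    )
    reactivity_log_mean: float = math.log(5000.0)
    reactivity_log_sd: float = 0.5
    background_mean: float = 100.0
    background_sd: float = 50.0
    noise_sd: float = 100.0
    saturation_cap: float = 25000.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_patients < 2:
            raise ValueError("n_patients must be >= 2")
        if not 0.0 <= self.sensitization_prob <= 1.0:
            raise ValueError("sensitization_prob must be in [0, 1]")
        if self.exposures_per_responder < 1:
            raise ValueError("exposures_per_responder must be >= 1")
        for cat, w in self.score_weights.items():
            if not 0.0 <= w <= 1.0:
                raise ValueError(f"score weight for {cat} must be in [0, 1]")
        for name in ("reactivity_log_sd", "background_sd", "noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if self.saturation_cap <= self.background_mean:
            raise ValueError("saturation_cap must exceed background_mean")


@dataclass
class GroundTruth:
    sensitizing: dict[str, frozenset[str]]  # patient -> eplets targeted
    exposures: dict[str, tuple[str, ...]]  # patient -> exposure alleles drawn

    @property
    def used_eplets(self) -> frozenset[str]:
        out: set[str] = set()
        for eplets in self.sensitizing.values():
            out |= eplets
        return frozenset(out)


@dataclass
class SimulatedCohort:
    mfi: MFIMatrix
    truth: GroundTruth
    params: SimulationParams


def _render_mfi(
    registry: EpletRegistry,
    panel: Panel,
    params: SimulationParams,
    sensitizing: dict[str, frozenset[str]],
    rng: np.random.Generator,
) -> MFIMatrix:
    """Turn per-patient sensitizing eplet sets into a raw-MFI matrix."""
    patients = list(sensitizing)
    bead_eplets = {
        b.bead_id: frozenset().union(*(registry.eplets_of(a) for a in b.alleles))
        for b in panel.beads
    }
    values = np.empty((len(patients), len(panel.beads)))
    for i, patient in enumerate(patients):
        eplets = sorted(sensitizing[patient])
        reactivity = {
            e: rng.lognormal(params.reactivity_log_mean, params.reactivity_log_sd)
            for e in eplets
        }
        for j, bead in enumerate(panel.beads):
            signal = sum(
                reactivity[e] for e in eplets if e in bead_eplets[bead.bead_id]
            )
            background = rng.normal(params.background_mean, params.background_sd)
            noise = rng.normal(0.0, params.noise_sd)
            values[i, j] = signal + background + noise
    np.clip(values, 0.0, params.saturation_cap, out=values)
    df = pd.DataFrame(values, index=patients, columns=panel.bead_ids)
    return MFIMatrix(data=df)


def simulate_cohort(
    registry: EpletRegistry, panel: Panel, params: SimulationParams
) -> SimulatedCohort:
    """Draw a full cohort under the eplet-driven response model."""
    params.validate()
    if LocusGroup.coerce(registry.locus_group) is not LocusGroup.coerce(
        panel.locus_group
    ):
        raise ValueError("registry and panel locus groups differ")
    panel_alleles = sorted(panel.alleles & registry.alleles)
    if not panel_alleles:
        raise ValueError("no panel allele is present in the registry")
    rng = np.random.default_rng(params.seed)
    sensitizing: dict[str, frozenset[str]] = {}
    exposures: dict[str, tuple[str, ...]] = {}
    for i in range(params.n_patients):
        patient = f"P{i + 1:04d}"
        if rng.random() >= params.sensitization_prob:
            sensitizing[patient] = frozenset()
            exposures[patient] = ()
            continue
        n_exp = 1 + rng.poisson(params.exposures_per_responder - 1.0)
        n_exp = min(n_exp, len(panel_alleles))
        drawn = rng.choice(len(panel_alleles), size=n_exp, replace=False)
        alleles = tuple(panel_alleles[j] for j in sorted(drawn))
        targeted: set[str] = set()
        for allele in alleles:
            for eplet in sorted(registry.eplets_of(allele)):
                weight = params.score_weights.get(registry.score_of(eplet), 0.0)
                if rng.random() < weight:
                    targeted.add(eplet)
        sensitizing[patient] = frozenset(targeted)
        exposures[patient] = alleles
    mfi = _render_mfi(registry, panel, params, sensitizing, rng)
    return SimulatedCohort(
        mfi=mfi,
        truth=GroundTruth(sensitizing=sensitizing, exposures=exposures),
        params=params,
    )


def sensitize(
    registry: EpletRegistry,
    panel: Panel,
    params: SimulationParams,
    assignments: Mapping[str, Sequence[str]],
) -> SimulatedCohort:
    """Direct-injection cohort: each patient's sensitizing eplets are given.

    Bypasses the random exposure draw (only the reactivity / background /
    noise draws remain stochastic), so deterministic propagation tests can
    pin exactly which eplets each patient targets.
    """
    params.validate()
    for patient, eplets in assignments.items():
        for e in eplets:
            registry.score_of(e)  # raises for eplets absent from the registry
    rng = np.random.default_rng(params.seed)
    sensitizing = {p: frozenset(e) for p, e in assignments.items()}
    mfi = _render_mfi(registry, panel, params, sensitizing, rng)
    truth = GroundTruth(
        sensitizing=sensitizing, exposures={p: () for p in assignments}
    )
    return SimulatedCohort(mfi=mfi, truth=truth, params=params)


@dataclass
class RecoveryResult:
    recall: float
    precision: float
    ari: float
    retained: list[str]
    assignment: dict[str, int]


def recovery_experiment(
    registry: EpletRegistry,
    panel: Panel,
    params: SimulationParams,
    k: int,
    min_allele_count: int = 2,
    allowed_scores: frozenset[ElliProCategory] = DEFAULT_ALLOWED_SCORES,
    minkowski_p: float = 2.0,
    true_blocks: Mapping[str, object] | None = None,
) -> RecoveryResult:
    """Simulate, run the full pipeline, and score recovery against truth.

    Recall and precision compare the retained driver eplets against the
    union of eplets the simulation actually sensitized patients to.  When
    ``true_blocks`` (bead id -> design block) is given, the Adjusted Rand
    Index of the k-group bead partition against that design is reported;
    otherwise ARI is NaN.
    """
    cohort = simulate_cohort(registry, panel, params)
    std = standardize(cohort.mfi, zero_variance="drop")
    features = antigen_features(std)
    dm = minkowski_distances(features, p=minkowski_p)
    tree = ward_linkage(dm)
    assignment = cut_tree(tree, k)
    gs = group_alleles(assignment, _subpanel(panel, list(features.index)))
    rows = exclusive_eplets(gs, registry)
    report = nominate_drivers(
        rows, min_allele_count=min_allele_count, allowed_scores=allowed_scores
    )
    retained = set(report.retained)
    used = set(cohort.truth.used_eplets)
    recall = len(retained & used) / len(used) if used else float("nan")
    precision = len(retained & used) / len(retained) if retained else float("nan")
    if true_blocks is not None:
        labels = list(assignment.assignment)
        ari = float(
            adjusted_rand_score(
                [str(true_blocks[b]) for b in labels],
                [assignment.assignment[b] for b in labels],
            )
        )
    else:
        ari = float("nan")
    return RecoveryResult(
        recall=recall,
        precision=precision,
        ari=ari,
        retained=sorted(retained),
        assignment=dict(assignment.assignment),
    )


def _subpanel(panel: Panel, bead_ids: list[str]) -> Panel:
    if set(bead_ids) == set(panel.bead_ids):
        return panel
    keep = [b for b in panel.beads if b.bead_id in set(bead_ids)]
    return Panel(locus_group=panel.locus_group, beads=keep)


def block_design(
    n_groups: int = 3,
    beads_per_group: int = 4,
) -> tuple[EpletRegistry, Panel, dict[str, int]]:
    """A DR-like toy design with disjoint per-group eplet blocks.

    Each block g has ``beads_per_group`` single-allele beads; three shared
    eplets per block (one on all alleles, one on the first half, one on the
    second half, all High) make every block eplet group-exclusive and
    multi-allele by construction.  Returns (registry, panel, bead -> block).
    """
    if beads_per_group < 4:
        raise ValueError("need at least 4 beads per group for the half-splits")
    expression: dict[str, set[str]] = {}
    index: dict[str, EpletRecord] = {}
    beads: list[Bead] = []
    blocks: dict[str, int] = {}
    for g in range(1, n_groups + 1):
        alleles = [f"DRB1*{g:02d}:{j:02d}" for j in range(1, beads_per_group + 1)]
        half = beads_per_group // 2
        eplets = {
            f"{g}ALL": alleles,
            f"{g}LO": alleles[:half],
            f"{g}HI": alleles[half:],
        }
        for name, carriers in eplets.items():
            index[name] = EpletRecord(name, "beta", ElliProCategory.HIGH)
            for a in carriers:
                expression.setdefault(a, set()).add(name)
        for a in alleles:
            bead_id = f"B-{a}"
            beads.append(Bead(bead_id=bead_id, alleles=(a,)))
            blocks[bead_id] = g
    registry = EpletRegistry(
        locus_group=LocusGroup.DRB,
        expression_map={a: frozenset(e) for a, e in expression.items()},
        eplet_index=index,
    )
    panel = Panel(locus_group=LocusGroup.DRB, beads=beads)
    return registry, panel, blocks
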