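"""Shared fixtures: reference data, random generators, independent oracles."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pandas as pd
import pytest

from epletclust import datasets
from epletclust.nomination import GroupAlleleSets
from epletclust.panel import MFIMatrix
from epletclust.registry import ElliProCategory, EpletRecord, EpletRegistry, LocusGroup


@pytest.fixture(scope="session")
def drb_registry():
    return datasets.load_reference_registry("DRB")


@pytest.fixture(scope="session")
def dq_registry():
    return datasets.load_reference_registry("DQ")


@pytest.fixture(scope="session")
def dp_registry():
    return datasets.load_reference_registry("DP")


@pytest.fixture(scope="session")
def drb_panel():
    return datasets.load_reference_panel("DRB")


@pytest.fixture(scope="session")
def dq_panel():
    return datasets.load_reference_panel("DQ")


@pytest.fixture(scope="session")
def drb_groups():
    return datasets.load_reference_groups("DRB")


@pytest.fixture(scope="session")
def dq_groups():
    return datasets.load_reference_groups("DQ")


def random_mfi(rng: np.random.Generator, n: int, p: int) -> MFIMatrix:
    values = rng.normal(size=(n, p)) * rng.uniform(10, 5000, size=p) + rng.uniform(
        0, 2000, size=p
    )
    return MFIMatrix(
        pd.DataFrame(
            values,
            index=[f"P{i}" for i in range(n)],
            columns=[f"B{j}" for j in range(p)],
        )
    )


# ---------------------------------------------------------------------------
# independent oracles
# ---------------------------------------------------------------------------


def ward_oracle(d: np.ndarray) -> list[tuple[int, int, float, int]]:
    """Brute-force Ward agglomerator.

    At every step the merge cost of every candidate pair is recomputed from
    scratch with the closed-form Ward objective increase expressed in the
    original pairwise squared dissimilarities (no Lance-Williams recursion),
    and the cheapest pair (lexicographic tie-break on node ids) merges.
    Heights are reported on the unsquared scale.
    """
    n = d.shape[0]
    d2 = d**2
    clusters: dict[int, list[int]] = {i: [i] for i in range(n)}
    merges = []
    nxt = n
    for _ in range(n - 1):
        best, best_val = None, math.inf
        for a, b in itertools.combinations(sorted(clusters), 2):
            A, B = clusters[a], clusters[b]
            na, nb = len(A), len(B)
            cross = sum(d2[i, j] for i in A for j in B) / (na * nb)
            within_a = sum(d2[i, j] for i in A for j in A) / (2 * na * na)
            within_b = sum(d2[i, j] for i in B for j in B) / (2 * nb * nb)
            val = 2 * (na * nb / (na + nb)) * (cross - within_a - within_b)
            if val < best_val - 1e-12:
                best_val, best = val, (a, b)
        a, b = best
        merges.append(
            (a, b, math.sqrt(max(best_val, 0.0)), len(clusters[a]) + len(clusters[b]))
        )
        clusters[nxt] = clusters.pop(a) + clusters.pop(b)
        nxt += 1
    return merges


def exclusivity_oracle(gs: GroupAlleleSets, registry: EpletRegistry) -> set[tuple[str, str]]:
    """Direct enumeration of (eplet, group) pairs satisfying exclusivity."""
    tested = frozenset().union(*gs.groups.values())
    out = set()
    for eplet in registry.eplets:
        s = registry.alleles_expressing(eplet) & tested
        if not s:
            continue
        for gid, alleles in gs.groups.items():
            if s <= alleles and not any(
                s <= other for g2, other in gs.groups.items() if g2 != gid
            ):
                out.add((eplet, gid))
    return out


def random_registry_and_groups(
    rng: np.random.Generator,
    max_alleles: int = 12,
    max_eplets: int = 20,
    max_groups: int = 4,
    disjoint: bool = False,
) -> tuple[EpletRegistry, GroupAlleleSets]:
    """A random small DRB registry plus random group allele sets.

    With ``disjoint=True`` the groups partition the alleles (the DR panel
    situation); otherwise groups may share alleles, as DQ/DP alpha chains do.
    """
    n_alleles = int(rng.integers(4, max_alleles + 1))
    alleles = [f"DRB1*{i + 1:02d}:01" for i in range(n_alleles)]
    n_groups = int(rng.integers(2, max_groups + 1))
    if disjoint:
        assignment = rng.integers(0, n_groups, size=n_alleles)
        while len(set(assignment.tolist())) < n_groups:
            assignment = rng.integers(0, n_groups, size=n_alleles)
        groups = {
            f"G{g + 1}": frozenset(
                a for a, ga in zip(alleles, assignment) if ga == g
            )
            for g in range(n_groups)
        }
    else:
        groups = {}
        for g in range(n_groups):
            size = int(rng.integers(1, n_alleles + 1))
            members = rng.choice(n_alleles, size=size, replace=False)
            groups[f"G{g + 1}"] = frozenset(alleles[i] for i in members)
    n_eplets = int(rng.integers(1, max_eplets + 1))
    cats = list(ElliProCategory)
    expression: dict[str, set[str]] = {}
    index: dict[str, EpletRecord] = {}
    for e in range(n_eplets):
        name = f"E{e + 1}"
        size = int(rng.integers(1, n_alleles + 1))
        members = rng.choice(n_alleles, size=size, replace=False)
        index[name] = EpletRecord(name, "beta", cats[int(rng.integers(len(cats)))])
        for i in members:
            expression.setdefault(alleles[i], set()).add(name)
    # alleles expressing nothing are dropped (registry invariant)
    registry = EpletRegistry(
        locus_group=LocusGroup.DRB,
        expression_map={a: frozenset(es) for a, es in expression.items()},
        eplet_index=index,
    )
    return registry, GroupAlleleSets(locus_group=LocusGroup.DRB, groups=groups)
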