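"""Burden-indicator coding and the random two-subgroup partition.

Collapsing replaces a subgroup of rare variants with a single 0/1 burden
indicator: an individual scores 1 when they carry a minor allele at any
member site.  Random collapsing draws, per gene and per repetition, a
uniform subgroup size ``S_k`` from ``{1, ..., M_k}``, assigns a random
subset of that size to the first subgroup and the remainder to the second,
yielding (at most) two indicators per gene.  Common variants are never
collapsed; they enter the design individually.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .data_model import GenotypeMatrix, VariantInfo


class PlanError(ValueError):
    """A collapse plan references variants it must not."""


@dataclass
class CollapsePlan:
    """Partition of one gene's rare variants into collapsed subgroups.

    ``subgroups`` are disjoint, non-empty, and jointly cover the gene's
    rare-variant set.  A degenerate draw (``S_k == M_k``) leaves a single
    subgroup: the gene collapses whole that repetition.
    """

    gene: str
    subgroups: list[list[str]]
    seed_state: str | None = None

    def __post_init__(self) -> None:
        self.subgroups = [list(s) for s in self.subgroups if len(s) > 0]
        if not self.subgroups:
            raise PlanError(f"plan for gene {self.gene!r} has no variants")
        flat = [v for s in self.subgroups for v in s]
        if len(flat) != len(set(flat)):
            raise PlanError(f"plan for gene {self.gene!r} has overlapping subgroups")

    @property
    def variant_ids(self) -> list[str]:
        return [v for s in self.subgroups for v in s]

    def to_json(self, repetition: int | None = None) -> str:
        d = {"gene": self.gene, "subgroups": self.subgroups}
        if repetition is not None:
            d["repetition"] = repetition
        if self.seed_state is not None:
            d["seed_state"] = self.seed_state
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, line: str) -> "CollapsePlan":
        d = json.loads(line)
        return cls(d["gene"], d["subgroups"], d.get("seed_state"))


@dataclass
class CollapsedDesign:
    """Design matrices for one repetition of the penalized selection.

    ``X`` holds the collapsed 0/1 indicators (one column per gene
    subgroup), ``U`` the uncollapsed common-variant carrier columns.
    ``column_map[j]`` names the gene and member variants behind ``X[:, j]``;
    ``u_column_map[c]`` names the common variant behind ``U[:, c]``.
    """

    X: np.ndarray
    column_map: list[tuple[str, tuple[str, ...]]]
    U: np.ndarray
    u_column_map: list[str]

    @property
    def n_individuals(self) -> int:
        return self.X.shape[0] if self.X.size else self.U.shape[0]

    @property
    def matrix(self) -> np.ndarray:
        """Concatenated [X | U] as float, X columns first."""
        parts = [m for m in (self.X, self.U) if m.shape[1] > 0]
        if not parts:
            raise ValueError("design has no columns")
        return np.hstack(parts).astype(float)


def random_partition(
    m_k: int, rng: np.random.Generator
) -> tuple[tuple[int, ...], tuple[int, ...]]:
    """Draw the two-subgroup random partition of ``{0, ..., m_k - 1}``.

    ``S_k`` is uniform on ``{1, ..., m_k}``; the first subgroup is a
    uniformly random subset of size ``S_k`` and the second its complement
    (empty when ``S_k == m_k``, in which case the gene collapses whole).
    Index subgroups are returned sorted for determinism.
    """
    if m_k < 1:
        raise ValueError("m_k must be >= 1")
    s_k = int(rng.integers(1, m_k + 1))
    if m_k == 1:
        return (0,), ()
    perm = rng.permutation(m_k)
    first = tuple(sorted(int(i) for i in perm[:s_k]))
    second = tuple(sorted(int(i) for i in perm[s_k:]))
    return first, second


def draw_plan(gene: str, rare_ids: Sequence[str], rng: np.random.Generator) -> CollapsePlan:
    """One random-collapsing plan for a gene's rare variants."""
    first, second = random_partition(len(rare_ids), rng)
    subgroups = [[rare_ids[i] for i in first]]
    if second:
        subgroups.append([rare_ids[i] for i in second])
    return CollapsePlan(gene, subgroups)


def collapse_indicator(g: GenotypeMatrix, subgroup: Sequence[str]) -> np.ndarray:
    """Burden indicator: 1 iff an individual carries a minor allele at any
    subgroup member site (logical OR across carrier columns)."""
    if g.coding != "carrier":
        raise ValueError("collapse_indicator requires carrier coding")
    if len(subgroup) == 0:
        raise ValueError("subgroup must be non-empty")
    idx = []
    pos = {v: j for j, v in enumerate(g.variant_ids)}
    for v in subgroup:
        if v not in pos:
            raise KeyError(f"unknown variant id {v!r}")
        idx.append(pos[v])
    return (g.values[:, idx].max(axis=1) > 0).astype(np.int8)


def build_design(
    g: GenotypeMatrix,
    plans: Mapping[str, CollapsePlan] | Iterable[CollapsePlan],
    common_ids: Sequence[str],
) -> CollapsedDesign:
    """Assemble the [X | U] design from per-gene plans and common variants.

    X columns are ordered by sorted gene id, then subgroup index within the
    plan; U columns follow ``common_ids`` input order.  A plan referencing
    a common variant is an error.
    """
    if g.coding != "carrier":
        raise ValueError("build_design requires carrier coding")
    if not isinstance(plans, Mapping):
        plans = {p.gene: p for p in plans}
    common_set = set(common_ids)

    cols: list[np.ndarray] = []
    column_map: list[tuple[str, tuple[str, ...]]] = []
    for gene in sorted(plans):
        plan = plans[gene]
        overlap = common_set.intersection(plan.variant_ids)
        if overlap:
            raise PlanError(
                f"plan for gene {gene!r} references common variant(s) {sorted(overlap)[:3]}"
            )
        for subgroup in plan.subgroups:
            cols.append(collapse_indicator(g, subgroup))
            column_map.append((gene, tuple(subgroup)))
    n = g.n_individuals
    X = np.column_stack(cols) if cols else np.empty((n, 0), dtype=np.int8)

    pos = {v: j for j, v in enumerate(g.variant_ids)}
    u_idx = [pos[v] for v in common_ids]
    U = g.values[:, u_idx].astype(np.int8) if u_idx else np.empty((n, 0), dtype=np.int8)
    return CollapsedDesign(X, column_map, U, list(common_ids))


def fixed_maf_partition(
    gene: str,
    variants: Sequence[VariantInfo],
    cut: float | None,
    rare_threshold: float = 0.05,
) -> CollapsePlan:
    """Deterministic MAF-threshold partition (the CMC-style predefined
    criterion).

    With ``cut=None`` the gene's rare variants form a single whole-gene
    subgroup; otherwise subgroup 1 holds variants with MAF < cut and
    subgroup 2 those with cut <= MAF < rare_threshold.  Empty subgroups
    are dropped.
    """
    rare = [v for v in variants if 0.0 < v.maf < rare_threshold]
    if not rare:
        raise PlanError(f"gene {gene!r} has no polymorphic rare variants")
    if cut is None:
        return CollapsePlan(gene, [[v.variant_id for v in rare]])
    if not 0.0 < cut < rare_threshold:
        raise ValueError("cut must lie in (0, rare_threshold)")
    low = [v.variant_id for v in rare if v.maf < cut]
    high = [v.variant_id for v in rare if v.maf >= cut]
    return CollapsePlan(gene, [s for s in (low, high) if s])


def write_plans_jsonl(path, plans_by_repetition: Sequence[Mapping[str, CollapsePlan]]) -> None:
    """Serialize the full plan sequence (audit/replay) to JSON lines."""
    with open(path, "w") as fh:
        for r, plans in enumerate(plans_by_repetition):
            for gene in sorted(plans):
                fh.write(plans[gene].to_json(repetition=r) + "\n")


def read_plans_jsonl(path) -> list[dict[str, CollapsePlan]]:
    """Read a plan sequence written by :func:`write_plans_jsonl`."""
    reps: dict[int, dict[str, CollapsePlan]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            d = json.loads(line)
            plan = CollapsePlan(d["gene"], d["subgroups"], d.get("seed_state"))
            reps.setdefault(int(d.get("repetition", 0)), {})[plan.gene] = plan
    return [reps[r] for r in sorted(reps)]
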