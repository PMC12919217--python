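"""Interspecies matrix comparison, sub-network aggregation and
two-group edge statistics.

Comparisons operate on Sinkhorn-balanced matrices only: balancing
removes modality- and scale-specific marginal effects, which is what
makes a tracer-derived matrix and a streamline-count matrix directly
comparable entry by entry.

Group differences use the classical pooled-variance two-sample t-test
per edge, with Bonferroni correction over the tested edge family;
Welch's variant is available behind a flag.  Both raw and adjusted
p-values are reported, since borderline effects are conventionally
shown before and after correction.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .types import LabeledMatrix

__all__ = [
    "SubNetworkMap",
    "EdgeTestResult",
    "default_subnetworks",
    "interspecies_delta",
    "subnetwork_profile",
    "group_edge_tests",
    "chord_export",
]


@dataclass
class SubNetworkMap:
    """Named cortico-subcortical edge sets (disease sub-networks)."""

    networks: dict  # name -> list of (cortical name, subcortical name)

    def __post_init__(self) -> None:
        if "DMN" in self.networks:
            raise ValueError(
                "the default-mode sub-network extends outside the prefrontal "
                "cortex and is not representable on this parcel roster"
            )

    def __getitem__(self, name: str) -> list:
        return self.networks[name]

    def names(self) -> list:
        return list(self.networks)


def default_subnetworks() -> SubNetworkMap:
    """The three prefrontal disease sub-networks on the 13-parcel roster.

    AN (affect), CMCN (cognitive motor control) and RMN
    (reward/maintenance) membership, restricted to parcels the toy
    roster carries (mediodorsal thalamus -> MD, SNr -> SN,
    ventrolateral thalamus -> VL; amygdala, hippocampus, accumbens,
    caudate and insula have no stand-in and are dropped).  The DMN is
    excluded: it extends outside the prefrontal cortex.
    """
    an_cortical = ["OFC", "vlPFC", "vACC"]
    cmcn_cortical = ["OFC", "vlPFC", "dmPFC", "dlPFC", "dACC", "vACC"]
    rmn_cortical = ["dlPFC", "dmPFC", "vlPFC", "OFC"]
    networks = {
        "AN": [(c, "MD") for c in an_cortical],
        "CMCN": [(c, s) for c in cmcn_cortical for s in ("STN", "SN", "RN", "VL")],
        "RMN": [(c, "VTA") for c in rmn_cortical],
    }
    return SubNetworkMap(networks)


@dataclass
class EdgeTestResult:
    edge: tuple
    t_value: float
    p_value: float
    p_adjusted: float
    significant: bool
    zero_variance: bool = False


def _require_balanced(m: LabeledMatrix, what: str) -> None:
    if m.normalization != "sinkhorn":
        raise ValueError(f"{what} requires Sinkhorn-balanced input, got {m.normalization!r}")


def interspecies_delta(a: LabeledMatrix, b: LabeledMatrix) -> LabeledMatrix:
    """Entrywise b - a on balanced matrices (direction a -> b).

    Differences are signed, so the result is a :class:`SignedMatrix`
    rather than a (nonnegative) :class:`LabeledMatrix`.
    """
    _require_balanced(a, "interspecies_delta")
    _require_balanced(b, "interspecies_delta")
    if a.row_labels != b.row_labels or a.col_labels != b.col_labels:
        raise ValueError("label mismatch between matrices")
    return SignedMatrix(b.values - a.values, list(a.row_labels), list(a.col_labels))


@dataclass
class SignedMatrix:
    """Signed entrywise differences between two balanced matrices."""

    values: np.ndarray
    row_labels: list
    col_labels: list

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.row_labels), len(self.col_labels)):
            raise ValueError("shape does not match labels")

    def loc(self, row: str, col: str) -> float:
        return float(self.values[self.row_labels.index(row), self.col_labels.index(col)])


def subnetwork_profile(m, netmap: SubNetworkMap):
    """Aggregate strength per sub-network plus the member-edge sub-matrix.

    Returns (aggregates, members) where aggregates maps network name ->
    sum of m over its member edges and members maps network name ->
    list of (cortical, subcortical, value) for chord plotting.
    """
    aggregates: dict = {}
    members: dict = {}
    for name in netmap.names():
        total = 0.0
        rows = []
        for (r, c) in netmap[name]:
            if r not in m.row_labels or c not in m.col_labels:
                raise KeyError(f"sub-network {name}: edge ({r}, {c}) absent from matrix")
            v = m.loc(r, c)
            total += v
            rows.append((r, c, v))
        aggregates[name] = total
        members[name] = rows
    return aggregates, members


def group_edge_tests(
    cohort: list,
    edges: list | None = None,
    alpha: float = 0.05,
    welch: bool = False,
) -> list:
    """Per-edge two-sample t-tests with Bonferroni correction.

    ``cohort`` is a list of (subject_id, group, LabeledMatrix) (or
    (group, LabeledMatrix)) with exactly two group labels.  ``edges``
    defaults to every (row, col) pair of the shared labels.  Pooled-
    variance (Student) t by default; ``welch=True`` drops the equal-
    variance assumption.  Edges with zero variance in both groups are
    flagged, not dropped.
    """
    normalized = []
    for item in cohort:
        if len(item) == 3:
            _, group, m = item
        else:
            group, m = item
        normalized.append((group, m))
    groups = sorted({g for g, _ in normalized})
    if len(groups) != 2:
        raise ValueError(f"need exactly 2 groups, got {groups}")
    ref = normalized[0][1]
    for _, m in normalized:
        if m.row_labels != ref.row_labels or m.col_labels != ref.col_labels:
            raise ValueError("all subject matrices must share labels")
    by_group = {g: [m for gg, m in normalized if gg == g] for g in groups}
    for g, ms in by_group.items():
        if len(ms) < 2:
            raise ValueError(f"group {g!r} has fewer than 2 subjects")
    if edges is None:
        edges = [(r, c) for r in ref.row_labels for c in ref.col_labels]
    n_tests = len(edges)
    results = []
    for (r, c) in edges:
        i, j = ref.row_labels.index(r), ref.col_labels.index(c)
        x = np.array([m.values[i, j] for m in by_group[groups[0]]])
        y = np.array([m.values[i, j] for m in by_group[groups[1]]])
        if x.var() == 0 and y.var() == 0:
            results.append(EdgeTestResult((r, c), float("nan"), float("nan"),
                                          float("nan"), False, zero_variance=True))
            continue
        t, p = sps.ttest_ind(x, y, equal_var=not welch)
        p_adj = min(1.0, float(p) * n_tests)
        results.append(
            EdgeTestResult((r, c), float(t), float(p), p_adj, p_adj < alpha)
        )
    return results


def chord_export(obj, path) -> str:
    """Export a matrix or edge-test results as chord-chart JSON.

    Nodes carry (name, role guess by position: rows first, cols second);
    edges carry (source, target, weight, sign).  For test results the
    weight is |t| and the sign is sign(t).
    """
    path = os.fspath(path)
    nodes: list = []
    edges: list = []

    def add_node(name: str, role: str) -> None:
        if not any(n["name"] == name for n in nodes):
            nodes.append({"name": name, "role": role})

    if isinstance(obj, (LabeledMatrix, SignedMatrix)):
        for r in obj.row_labels:
            add_node(r, "row")
        for c in obj.col_labels:
            add_node(c, "col")
        for i, r in enumerate(obj.row_labels):
            for j, c in enumerate(obj.col_labels):
                v = float(obj.values[i, j])
                if v == 0.0:
                    continue
                edges.append({"source": r, "target": c,
                              "weight": abs(v), "sign": int(np.sign(v))})
    else:  # list of EdgeTestResult
        for res in obj:
            r, c = res.edge
            add_node(r, "row")
            add_node(c, "col")
            t = res.t_value
            if np.isnan(t):
                continue
            edges.append({"source": r, "target": c, "weight": abs(float(t)),
                          "sign": int(np.sign(t)) if t != 0 else 0,
                          "p_value": res.p_value, "p_adjusted": res.p_adjusted,
                          "significant": bool(res.significant)})
    with open(path, "w") as fh:
        json.dump({"nodes": nodes, "edges": edges}, fh, indent=2)
    return path
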