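"""Consensus map construction by interval linear programming.

One linkage group at a time, component maps are merged on a physical-order
backbone. Every pair of markers at most K bin-ranks apart within a component
map contributes an interval constraint with that map's observed cM distance;
the consensus positions minimize the weighted sum of absolute deviations
from those distances, subject to monotonicity along the backbone and an
origin fixed at 0:

    minimize  sum_m sum_(i,j) w_m |(x_j - x_i) - d_ij^m|
    s.t.      x nondecreasing in backbone order, x_first = 0.

The whole merge is repeated for each K in a grid (default 1..4); candidates
are scored by the root-mean-square error between consensus and component
positions (both re-anchored at their first shared marker) and the K with the
lowest mean RMSE wins, ties going to the smallest K.

Among L1-optimal solutions the reported one re-minimizes the weighted sum of
*squared* residuals over the optimal face (characterized from the LP duals),
which sets each ambiguous position to the weight-averaged implied distance.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from collections import Counter
from scipy import sparse
from scipy.optimize import linprog

from . import _lsi
from .map_io import GeneticMap, LinkageGroupMap, MarkerRecord, PhysicalAnnotationSet
from .map_qc import bin_markers

logger = logging.getLogger(__name__)

# stage-2 refinement is skipped above this constraint count (LP vertex kept)
_LSI_MAX_CONSTRAINTS = 2000
_RIDGE = 1e-9


@dataclass(frozen=True)
class MergeConfig:
    """Parameters of the interval-LP merge."""

    K_grid: tuple[int, ...] = (1, 2, 3, 4)
    weights: Mapping[str, float] | None = None  # per component map; default 1.0
    solver_tol: float = 1e-8

    def __post_init__(self) -> None:
        if not self.K_grid or min(self.K_grid) < 1:
            raise ValueError("K_grid must contain integers >= 1")
        if self.weights is not None and any(w <= 0 for w in self.weights.values()):
            raise ValueError("weights must be > 0")

    def weight_of(self, map_name: str) -> float:
        if self.weights is None:
            return 1.0
        return float(self.weights.get(map_name, 1.0))


@dataclass(frozen=True)
class IntervalConstraint:
    """|x_j - x_i| should equal d (cM), by component map ``source``."""

    i: str  # backbone-earlier marker
    j: str  # backbone-later marker
    d: float
    weight: float
    source: str


@dataclass
class BackboneGroup:
    label: str
    order: list[str]
    method: dict[str, str]  # marker -> 'physical' | 'inferred'

    def rank(self) -> dict[str, int]:
        return {m: i for i, m in enumerate(self.order)}


@dataclass
class BackboneOrder:
    groups: dict[str, BackboneGroup] = field(default_factory=dict)


@dataclass
class ConsensusLG:
    """Consensus positions for one group, plus solve diagnostics."""

    label: str
    order: list[str]
    positions: dict[str, float]
    objective_cM: float
    refined: bool  # True if the squared-residual tie-break was applied


@dataclass
class RmseReport:
    """Per-(map, group) RMSE for each K, and the selected K."""

    rmse_by_K: dict[int, pd.DataFrame]
    overall_mean_by_K: dict[int, float]
    selected_K: int

    @property
    def selected_frame(self) -> pd.DataFrame:
        return self.rmse_by_K[self.selected_K]

    def per_map_mean(self) -> pd.Series:
        return self.selected_frame.mean(axis=1, skipna=True)


def _majority_chromosome(
    markers: Sequence[str], annotations: PhysicalAnnotationSet, label: str
) -> str:
    counts = Counter(
        annotations.chromosome_of(m) for m in markers if m in annotations
    )
    if not counts:
        raise ValueError(f"group {label}: no annotated marker to anchor the backbone")
    chrom, top = counts.most_common(1)[0]
    if 2 * top <= sum(counts.values()):
        raise ValueError(f"group {label}: no strict majority chromosome {dict(counts)}")
    return chrom


def build_backbone(
    maps: Sequence[GeneticMap], annotations: PhysicalAnnotationSet
) -> BackboneOrder:
    """Shared marker order per group: physical (bp) order, with unannotated
    markers inserted at their mean fractional rank between the nearest
    annotated neighbours over the component maps containing them."""
    out = BackboneOrder()
    labels: list[str] = []
    for m in maps:
        for label in m.groups:
            if label not in labels:
                labels.append(label)
    for label in labels:
        union: list[str] = []
        for m in maps:
            if label in m.groups:
                for r in m.groups[label].records:
                    if r.marker_id not in union:
                        union.append(r.marker_id)
        chrom = _majority_chromosome(union, annotations, label)
        annotated = [
            m for m in union
            if m in annotations and annotations.chromosome_of(m) == chrom
        ]
        annotated.sort(key=lambda m: (annotations.bp_of(m), m))
        rank = {m: float(i) for i, m in enumerate(annotated)}
        keys: dict[str, list[float]] = {}
        for gm in maps:
            if label not in gm.groups:
                continue
            records = gm.groups[label].records
            idx_of = {r.marker_id: p for p, r in enumerate(records)}
            ann_positions = [p for p, r in enumerate(records) if r.marker_id in rank]
            for r in records:
                if r.marker_id in rank:
                    continue
                p = idx_of[r.marker_id]
                left = max((q for q in ann_positions if q < p), default=None)
                right = min((q for q in ann_positions if q > p), default=None)
                if left is None and right is None:
                    continue
                if left is None:
                    key = rank[records[right].marker_id] - 0.5
                elif right is None:
                    key = rank[records[left].marker_id] + 0.5
                else:
                    ka = rank[records[left].marker_id]
                    kb = rank[records[right].marker_id]
                    lo, hi = min(ka, kb), max(ka, kb)
                    t = p - left  # 1-based rank among markers between the flanks
                    span = right - left  # = T + 1
                    key = lo + t * (hi - lo) / span if hi > lo else lo + t / span
                keys.setdefault(r.marker_id, []).append(key)
        unplaced = [m for m in union if m not in rank and m not in keys]
        if unplaced:
            raise ValueError(
                f"group {label}: marker(s) {sorted(unplaced)} have no annotated "
                "neighbour in any component map"
            )
        entries: list[tuple[float, int, str]] = [
            (rank[m], 0, m) for m in annotated
        ]
        for m, ks in keys.items():
            if len(set(round(k, 9) for k in ks)) > 1:
                logger.info(
                    "group %s: marker %s placed ambiguously between different "
                    "flank pairs (keys %s); using the mean", label, m, ks
                )
            entries.append((sum(ks) / len(ks), 1, m))
        entries.sort()
        out.groups[label] = BackboneGroup(
            label=label,
            order=[m for _, _, m in entries],
            method={m: ("physical" if f == 0 else "inferred") for _, f, m in entries},
        )
    return out


def extract_interval_constraints(
    lg: LinkageGroupMap,
    backbone_rank: Mapping[str, int],
    K: int,
    weight: float = 1.0,
    source: str | None = None,
) -> list[IntervalConstraint]:
    """Interval constraints of one component linkage group.

    Distances are taken between marker *bins* at most K ranks apart in the
    component's own bin order; co-segregating members are tied to their bin
    representative with a zero-length constraint. Constraint endpoints are
    oriented by backbone rank.
    """
    source = source or lg.label
    bins = bin_markers(lg)
    out: list[IntervalConstraint] = []

    def oriented(a: str, b: str, d: float) -> IntervalConstraint:
        if backbone_rank[a] > backbone_rank[b]:
            a, b = b, a
        return IntervalConstraint(a, b, abs(d), weight, source)

    reps: list[str] = []
    for b in bins:
        rep = min(b.member_ids, key=lambda m: backbone_rank[m])
        reps.append(rep)
        for member in b.member_ids:
            if member != rep:
                out.append(oriented(rep, member, 0.0))
    for p in range(len(bins)):
        for q in range(p + 1, min(p + K, len(bins) - 1) + 1):
            out.append(
                oriented(reps[p], reps[q], bins[q].position_cM - bins[p].position_cM)
            )
    return out


def _solve_l1(
    n: int,
    rows: np.ndarray,
    cols: np.ndarray,
    d: np.ndarray,
    w: np.ndarray,
    tol: float,
) -> tuple[np.ndarray, np.ndarray, float]:
    """L1 interval LP over gap variables g (length n-1). Returns (g, duals, f*).

    Constraint c couples backbone ranks rows[c] < cols[c]:
    sum(g[rows[c]:cols[c]]) - u_c + v_c = d[c]; minimize sum w (u + v).
    """
    m = d.size
    ng = n - 1
    data, ri, ci = [], [], []
    for c in range(m):
        for t in range(rows[c], cols[c]):
            data.append(1.0)
            ri.append(c)
            ci.append(t)
    B = sparse.csr_matrix((data, (ri, ci)), shape=(m, ng))
    A_eq = sparse.hstack(
        [B, -sparse.identity(m, format="csr"), sparse.identity(m, format="csr")],
        format="csr",
    )
    cvec = np.concatenate([np.zeros(ng), w, w])
    res = linprog(cvec, A_eq=A_eq, b_eq=d, bounds=(0, None), method="highs")
    if not res.success:  # pragma: no cover - monotone L1 LPs are always feasible
        raise RuntimeError(f"interval LP failed: {res.message}")
    g = res.x[:ng]
    duals = np.asarray(res.eqlin.marginals, dtype=float)
    return g, duals, float(res.fun)


def _refine_on_face(
    n: int,
    rows: np.ndarray,
    cols: np.ndarray,
    d: np.ndarray,
    w: np.ndarray,
    g_lp: np.ndarray,
    duals: np.ndarray,
    fstar: float,
    tol: float,
) -> tuple[np.ndarray, bool]:
    """Re-minimize sum w r^2 over the L1-optimal face; fall back to the vertex.

    The face is read off the LP duals y: |y_c| < w_c means r_c = 0 on every
    optimal solution; y_c at +-w_c constrains the residual sign; gaps with a
    nonzero reduced cost are pinned at 0.
    """
    ng = n - 1
    m = d.size
    B = np.zeros((m, ng))
    for c in range(m):
        B[c, rows[c] : cols[c]] = 1.0
    r_lp = B @ g_lp - d

    # dual sign convention: infer the factor linking sign(y) to sign(r)
    active = (np.abs(r_lp) > 1e-7) & (np.abs(duals) > 0.5 * w)
    if np.any(active):
        signs = np.sign(duals[active] * r_lp[active])
        if np.all(signs > 0):
            s = 1.0
        elif np.all(signs < 0):
            s = -1.0
        else:  # inconsistent duals; keep the vertex
            return g_lp, False
        y = s * duals
    else:
        y = duals  # no active residual: face == {r = 0 on flagged set}
    dtol = 1e-7 * max(1.0, float(w.max()))
    eq_res = np.abs(y) < w - dtol  # residual forced to 0
    pos_res = (~eq_res) & (y > 0)  # residual >= 0
    neg_res = (~eq_res) & (y < 0)  # residual <= 0
    bty = B.T @ y
    gap_fixed = np.abs(bty) > dtol  # gap pinned at 0 on the face

    sw = np.sqrt(w)
    A = np.vstack([sw[:, None] * B, np.sqrt(_RIDGE) * np.eye(ng)])
    b = np.concatenate([sw * d, np.zeros(ng)])

    # fast path: equality constraints only, then feasibility check
    E_rows = [B[eq_res]] if eq_res.any() else []
    e_rhs = [d[eq_res]] if eq_res.any() else []
    if gap_fixed.any():
        E_rows.append(np.eye(ng)[gap_fixed])
        e_rhs.append(np.zeros(int(gap_fixed.sum())))
    g_try: np.ndarray | None = None
    if E_rows:
        E = np.vstack(E_rows)
        e = np.concatenate(e_rhs)
        # minimize ||A g - b|| s.t. E g = e via nullspace elimination
        g0, *_ = np.linalg.lstsq(E, e, rcond=None)
        from scipy.linalg import null_space

        Z = null_space(E)
        if Z.size:
            q, *_ = np.linalg.lstsq(A @ Z, b - A @ g0, rcond=None)
            g_try = g0 + Z @ q
        else:
            g_try = g0
    else:
        g_try, *_ = np.linalg.lstsq(A, b, rcond=None)

    def feasible(g: np.ndarray) -> bool:
        if g.min() < -1e-7:
            return False
        r = B @ g - d
        if pos_res.any() and r[pos_res].min() < -1e-7:
            return False
        if neg_res.any() and r[neg_res].max() > 1e-7:
            return False
        return float(w @ np.abs(r)) <= fstar + max(tol, 1e-6) * (1 + abs(fstar))

    if g_try is not None and feasible(g_try):
        return np.clip(g_try, 0.0, None), True

    # exact path: full LSI with sign and nonnegativity constraints
    n_ineq = int(pos_res.sum() + neg_res.sum() + (~gap_fixed).sum())
    if m > _LSI_MAX_CONSTRAINTS or n_ineq > _LSI_MAX_CONSTRAINTS:
        return g_lp, False
    G_rows = [np.eye(ng)[~gap_fixed]]
    h_rhs = [np.zeros(int((~gap_fixed).sum()))]
    if pos_res.any():
        G_rows.append(B[pos_res])
        h_rhs.append(d[pos_res])
    if neg_res.any():
        G_rows.append(-B[neg_res])
        h_rhs.append(-d[neg_res])
    if eq_res.any():
        G_rows.extend([B[eq_res], -B[eq_res]])
        h_rhs.extend([d[eq_res], -d[eq_res]])
    if gap_fixed.any():
        I = np.eye(ng)[gap_fixed]
        G_rows.extend([I, -I])
        z = np.zeros(int(gap_fixed.sum()))
        h_rhs.extend([z, z])
    try:
        g_ref = _lsi.lsi(A, b, np.vstack(G_rows), np.concatenate(h_rhs))
    except _lsi.LsiInfeasible:  # pragma: no cover - face is nonempty by construction
        return g_lp, False
    if feasible(g_ref):
        return np.clip(g_ref, 0.0, None), True
    return g_lp, False


def merge_linkage_group(
    constraints: Sequence[IntervalConstraint],
    backbone_group: BackboneGroup | Sequence[str],
    config: MergeConfig | None = None,
) -> ConsensusLG:
    """Solve the monotone L1 interval problem for one linkage group."""
    config = config or MergeConfig()
    if isinstance(backbone_group, BackboneGroup):
        order = backbone_group.order
        label = backbone_group.label
    else:
        order = list(backbone_group)
        label = "LG"
    if not constraints:
        raise ValueError(f"group {label}: empty constraint set")
    rank = {mk: i for i, mk in enumerate(order)}
    n = len(order)
    if n == 1:
        return ConsensusLG(label, order, {order[0]: 0.0}, 0.0, False)
    rows = np.array([rank[c.i] for c in constraints], dtype=int)
    cols = np.array([rank[c.j] for c in constraints], dtype=int)
    if np.any(rows >= cols):
        raise ValueError("constraints must couple distinct backbone positions")
    d = np.array([c.d for c in constraints], dtype=float)
    w = np.array([c.weight for c in constraints], dtype=float)
    g, duals, fstar = _solve_l1(n, rows, cols, d, w, config.solver_tol)
    refined = False
    if fstar > n * 1e-9:  # ties only matter when the fit is not already exact
        g, refined = _refine_on_face(
            n, rows, cols, d, w, g, duals, fstar, config.solver_tol
        )
    g = np.clip(g, 0.0, None)
    x = np.concatenate([[0.0], np.cumsum(g)])
    positions = {mk: float(x[i]) for i, mk in enumerate(order)}
    return ConsensusLG(label, order, positions, fstar, refined)


def as_consensus_lg(lg: LinkageGroupMap) -> ConsensusLG:
    """View any linkage group as a ConsensusLG (for RMSE against e.g. truth)."""
    return ConsensusLG(
        label=lg.label,
        order=[r.marker_id for r in lg.records],
        positions={r.marker_id: r.position_cM for r in lg.records},
        objective_cM=0.0,
        refined=False,
    )


def compute_rmse(consensus: ConsensusLG, component: LinkageGroupMap) -> float:
    """RMSE between consensus and component positions over shared markers,
    both maps re-anchored at 0 at their first shared marker."""
    comp_pos = {r.marker_id: r.position_cM for r in component.records}
    shared = [m for m in consensus.order if m in comp_pos]
    if not shared:
        raise ValueError(
            f"group {consensus.label}: no marker shared with map {component.label}"
        )
    c0 = consensus.positions[shared[0]]
    p0 = comp_pos[shared[0]]
    sq = [
        ((consensus.positions[m] - c0) - (comp_pos[m] - p0)) ** 2 for m in shared
    ]
    return float(np.sqrt(np.mean(sq)))


def merge_all_groups(
    maps: Sequence[GeneticMap],
    backbone: BackboneOrder,
    K: int,
    config: MergeConfig,
) -> dict[str, ConsensusLG]:
    merged: dict[str, ConsensusLG] = {}
    for label, bg in backbone.groups.items():
        rank = bg.rank()
        constraints: list[IntervalConstraint] = []
        for gm in maps:
            if label in gm.groups and gm.groups[label].records:
                constraints.extend(
                    extract_interval_constraints(
                        gm.groups[label], rank, K, config.weight_of(gm.name), gm.name
                    )
                )
        merged[label] = merge_linkage_group(constraints, bg, config)
    return merged


def consensus_to_map(merged: dict[str, ConsensusLG], name: str) -> GeneticMap:
    groups = {}
    for label, clg in merged.items():
        records = [
            MarkerRecord(m, label, clg.positions[m]) for m in clg.order
        ]
        groups[label] = LinkageGroupMap(label, records)
    return GeneticMap(name, groups)


def select_consensus(
    maps: Sequence[GeneticMap],
    annotations: PhysicalAnnotationSet,
    config: MergeConfig | None = None,
) -> tuple[GeneticMap, RmseReport]:
    """Merge for every K in the grid and keep the lowest-mean-RMSE consensus."""
    if len(maps) < 2:
        raise ValueError("consensus construction requires at least 2 maps")
    config = config or MergeConfig()
    backbone = build_backbone(maps, annotations)
    labels = list(backbone.groups)
    rmse_by_K: dict[int, pd.DataFrame] = {}
    overall: dict[int, float] = {}
    merged_by_K: dict[int, dict[str, ConsensusLG]] = {}
    for K in sorted(set(config.K_grid)):
        merged = merge_all_groups(maps, backbone, K, config)
        merged_by_K[K] = merged
        frame = pd.DataFrame(index=[m.name for m in maps], columns=labels, dtype=float)
        for gm in maps:
            for label in labels:
                if label in gm.groups and gm.groups[label].records:
                    frame.loc[gm.name, label] = compute_rmse(
                        merged[label], gm.groups[label]
                    )
        rmse_by_K[K] = frame
        overall[K] = float(np.nanmean(frame.to_numpy(dtype=float)))
        logger.info("K=%d: mean RMSE %.4f cM", K, overall[K])
    selected = min(overall, key=lambda k: (overall[k], k))
    report = RmseReport(rmse_by_K, overall, selected)
    consensus = consensus_to_map(merged_by_K[selected], f"consensus_K{selected}")
    return consensus, report
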