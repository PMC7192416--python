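"""Map ensemble samples into criterion space.

x-criteria (per concentration profile): total metabolite concentration, draft
(intermediates over end product within each linear segment), thermodynamic
cost sum(1/(1-theta)) over the reversible reactions, and transition time
(total mass over pathway flux).  All are minimized.

k-criteria (per kinetic-order vector): steady-state sensitivities to rate
constants and logarithmic gains to independent variables, aggregated into the
seven pathway criteria APS, ISD, ISS (robustness, minimized) and PDG, FDG,
PSG, FSG (responsiveness, maximized).  The log-space steady-state algebra

    A = N diag(v0) F_d
    S_x = -A^{-1} N diag(v0)        (response of ln x_d to ln gamma)
    L_x = -A^{-1} N diag(v0) F_i    (response of ln x_d to ln x_i)
    S_v = F_d S_x + I,   L_v = F_d L_x + F_i

depends only on the kinetic orders and the flux *ratios* — never on the
concentration profile used for anchoring — which is what justifies screening
the k-subspace independently of the x-subspace.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd

from .ensembles import EnsembleTable, ThetaProfile
from .model import PathwayModel

__all__ = [
    "CriterionTable",
    "SensitivityResult",
    "x_criteria",
    "linear_segments",
    "sensitivities",
    "k_criteria",
    "k_criteria_table",
    "pathway_roles",
]

#: theta is capped here before evaluating the 1/(1-theta) cost
THETA_CAP = 1.0 - 1e-9

X_ORIENTATIONS = {"total": "min", "cost": "min", "transition_time": "min"}
K_ORIENTATIONS = {
    "APS": "min",
    "ISD": "min",
    "ISS": "min",
    "PDG": "max",
    "FDG": "max",
    "PSG": "max",
    "FSG": "max",
}


@dataclass
class CriterionTable:
    """Per-sample criterion values with per-criterion optimization orientation."""

    data: pd.DataFrame
    orientations: dict[str, str]
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        for col in self.data.columns:
            if col not in self.orientations:
                raise ValueError(f"criterion {col!r} has no orientation")
            if self.orientations[col] not in ("min", "max"):
                raise ValueError(f"bad orientation for {col!r}")

    def __len__(self) -> int:
        return len(self.data)

    def aligned(self, criteria=None) -> pd.DataFrame:
        """Criteria converted to uniform *minimization* (max columns negated)."""
        cols = list(criteria) if criteria is not None else list(self.data.columns)
        out = self.data[cols].copy()
        for c in cols:
            if self.orientations[c] == "max":
                out[c] = -out[c]
        return out

    def subset(self, mask) -> "CriterionTable":
        return CriterionTable(
            self.data.loc[mask].reset_index(drop=True), dict(self.orientations), dict(self.meta)
        )

    def with_column(self, name: str, values, orientation: str) -> "CriterionTable":
        data = self.data.copy()
        data[name] = np.asarray(values)
        orient = dict(self.orientations)
        orient[name] = orientation
        return CriterionTable(data, orient, dict(self.meta))

    def to_csv(self, path: str | Path) -> None:
        path = Path(path)
        header = "#orientation," + ",".join(f"{c}:{o}" for c, o in self.orientations.items())
        with open(path, "w") as fh:
            fh.write(header + "\n")
            self.data.to_csv(fh, index=False)

    @classmethod
    def from_csv(cls, path: str | Path) -> "CriterionTable":
        path = Path(path)
        with open(path) as fh:
            first = fh.readline().strip()
            if not first.startswith("#orientation,"):
                raise ValueError("missing orientation header line")
            orient = dict(p.split(":") for p in first.split(",")[1:])
            data = pd.read_csv(fh)
        return cls(data, orient)


@dataclass
class SensitivityResult:
    """The four steady-state response matrices for one kinetic-order vector."""

    model: PathwayModel
    S_x: np.ndarray  # (n, r): d ln x_d / d ln gamma
    S_v: np.ndarray  # (r, r): d ln v   / d ln gamma
    L_x: np.ndarray  # (n, m): d ln x_d / d ln x_i
    L_v: np.ndarray  # (r, m): d ln v   / d ln x_i

    def L(self, target: str, wrt: str) -> float:
        """Log-gain of a dependent species or reaction flux w.r.t. an independent species."""
        j = self.model.independent.index(wrt)
        if target in self.model.dependent:
            return float(self.L_x[self.model.dependent.index(target), j])
        return float(self.L_v[self.model.reaction_index(target), j])

    def S(self, target: str, wrt_reaction: str) -> float:
        """Sensitivity of a dependent species or flux w.r.t. a rate constant."""
        j = self.model.reaction_index(wrt_reaction)
        if target in self.model.dependent:
            return float(self.S_x[self.model.dependent.index(target), j])
        return float(self.S_v[self.model.reaction_index(target), j])


# ---------------------------------------------------------------------------
# x-criteria
# ---------------------------------------------------------------------------

def linear_segments(model: PathwayModel) -> list[list[str]]:
    """Ordered linear segments of the dependent-metabolite graph.

    Metabolites with connectivity greater than two (branch points) are removed;
    the connected components that remain are linear segments, ordered along the
    declared flux direction.
    """
    G = nx.Graph()
    D = nx.DiGraph()
    G.add_nodes_from(model.dependent)
    D.add_nodes_from(model.dependent)
    for j in range(model.r):
        col = model.N[:, j]
        consumed = [model.dependent[i] for i in np.where(col < 0)[0]]
        produced = [model.dependent[i] for i in np.where(col > 0)[0]]
        for a in consumed:
            for b in produced:
                G.add_edge(a, b)
                D.add_edge(a, b)
    keep = [sp for sp in model.dependent if G.degree(sp) <= 2]
    H = G.subgraph(keep)
    segments = []
    for comp in nx.connected_components(H):
        sub = D.subgraph(comp)
        starts = [s for s in comp if sub.in_degree(s) == 0]
        start = starts[0] if starts else sorted(comp, key=model.dependent.index)[0]
        order, node, seen = [start], start, {start}
        while True:
            nxt = [t for t in sub.successors(node) if t not in seen]
            if not nxt:
                break
            node = nxt[0]
            order.append(node)
            seen.add(node)
        segments.append(order)
    segments.sort(key=lambda seg: model.dependent.index(seg[0]))
    return segments


def x_criteria(
    model: PathwayModel,
    xens: EnsembleTable | pd.DataFrame,
    thetas: ThetaProfile,
    v0: float,
) -> CriterionTable:
    """Evaluate the concentration-profile criteria for feasible samples.

    ``v0`` is the pathway flux magnitude |v|_0 (mM/min) used for the
    transition time.  Samples must be pre-filtered to theta < 1; a sample with
    a zero end-product concentration has no defined draft and is dropped
    (recorded in the metadata).
    """
    data = xens.data if isinstance(xens, EnsembleTable) else xens
    th = thetas.values
    if np.any(th >= 1.0):
        raise ValueError("x_criteria requires thermodynamically feasible samples (theta < 1)")
    x = data[list(model.dependent)].to_numpy(dtype=float)
    segments = linear_segments(model)
    drop = np.zeros(len(data), dtype=bool)
    drafts = {}
    for si, seg in enumerate(segments):
        idx = [model.dependent.index(s) for s in seg]
        end = x[:, idx[-1]]
        bad = end == 0
        drop |= bad
        name = "draft" if len(segments) == 1 else f"draft_{si + 1}"
        with np.errstate(divide="ignore", invalid="ignore"):
            drafts[name] = x[:, idx[:-1]].sum(axis=1) / end if len(idx) > 1 else np.zeros(len(x))
    cost = (1.0 / (1.0 - np.minimum(th, THETA_CAP))).sum(axis=1)
    total = x.sum(axis=1)
    cols = {"total": total, **drafts, "cost": cost, "transition_time": total / float(v0)}
    frame = pd.DataFrame(cols)
    orient = dict(X_ORIENTATIONS)
    for name in drafts:
        orient[name] = "min"
    meta = {"v0": float(v0), "n_dropped_zero_product": int(drop.sum())}
    if drop.any():
        frame = frame.loc[~drop].reset_index(drop=True)
    return CriterionTable(frame, orient, meta)


# ---------------------------------------------------------------------------
# k-criteria
# ---------------------------------------------------------------------------

def _order_tensors(model: PathwayModel, K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Batched kinetic-order matrices F_d (s,r,n), F_i (s,r,m) from free-entry rows."""
    s = len(K)
    base = model.build_F(np.zeros(len(model.free_entries)))
    F = np.tile(base, (s, 1, 1))
    for col, (rxn, sp) in enumerate(model.free_entries):
        F[:, model.reaction_index(rxn), model.species_index(sp)] = K[:, col]
    return F[:, :, : model.n], F[:, :, model.n :]


def _sensitivity_arrays(model, K, fluxes=None):
    """Vectorized sensitivity algebra; singular designs yield NaN matrices."""
    K = np.atleast_2d(np.asarray(K, float))
    Fd, Fi = _order_tensors(model, K)
    v = np.full(model.r, 1.0) if fluxes is None else np.asarray(fluxes, float)
    NV = model.N * v[None, :]  # (n, r)
    A = np.einsum("ir,krj->kij", NV, Fd)
    dets = np.linalg.det(A)
    ok = np.abs(dets) > 1e-10 * max(np.abs(v).max(), 1.0) ** model.n
    A_safe = np.where(ok[:, None, None], A, np.eye(model.n)[None])
    S_x = -np.linalg.solve(A_safe, np.tile(NV, (len(K), 1, 1)))
    B = np.einsum("ir,krj->kij", NV, Fi)
    L_x = -np.linalg.solve(A_safe, B)
    S_v = np.einsum("krn,knj->krj", Fd, S_x) + np.eye(model.r)[None]
    L_v = np.einsum("krn,knj->krj", Fd, L_x) + Fi
    for arr in (S_x, L_x, S_v, L_v):
        arr[~ok] = np.nan
    return S_x, S_v, L_x, L_v, ok


def sensitivities(model: PathwayModel, k, fluxes=None) -> SensitivityResult:
    """Sensitivity and log-gain matrices for one kinetic-order vector.

    ``fluxes`` gives the steady-state flux distribution (only its ratios
    matter; defaults to equal fluxes, exact for an unbranched chain).
    Raises ``np.linalg.LinAlgError`` for a structurally degenerate design.
    """
    if isinstance(k, pd.Series) or isinstance(k, dict):
        k = [dict(k)[lab] for lab in model.free_labels]
    S_x, S_v, L_x, L_v, ok = _sensitivity_arrays(model, np.asarray(k, float)[None, :], fluxes)
    if not ok[0]:
        raise np.linalg.LinAlgError("steady-state system is singular for this design")
    return SensitivityResult(model, S_x[0], S_v[0], L_x[0], L_v[0])


def pathway_roles(model: PathwayModel) -> dict[str, str]:
    """Resolve the supply/demand/product roles used by the aggregate criteria.

    Explicit ``roles`` in the model config win; otherwise the demand reaction
    is the last purely-consuming reaction, the product is the species it
    consumes, the demand variable is the independent species acting on it, and
    the supply is the remaining independent species feeding the first reaction.
    """
    roles = dict(model.roles)
    if "demand_reaction" not in roles:
        for rxn in reversed(model.reactions):
            col = model.N[:, model.reaction_index(rxn)]
            if (col <= 0).all() and (col < 0).any():
                roles["demand_reaction"] = rxn
                break
        else:
            raise ValueError("no demand (sink) reaction found")
    dr = roles["demand_reaction"]
    if "product" not in roles:
        col = model.N[:, model.reaction_index(dr)]
        roles["product"] = model.dependent[int(np.where(col < 0)[0][0])]
    if "demand" not in roles:
        cands = [
            sp
            for sp in model.independent
            if (dr, sp) in model.orders_fixed or (dr, sp) in model.orders_free
        ]
        if not cands:
            raise ValueError("no independent demand variable acts on the sink reaction")
        roles["demand"] = cands[0]
    if "supply" not in roles:
        cands = [sp for sp in model.independent if sp != roles["demand"]]
        if not cands:
            raise ValueError("no independent supply species")
        roles["supply"] = cands[0]
    return roles


def _aggregate(model, S_x, L_x, L_v, roles):
    dep = list(model.dependent)
    product = roles["product"]
    inter = [i for i, sp in enumerate(dep) if sp != product]
    ip = dep.index(product)
    js = model.independent.index(roles["supply"])
    jd = model.independent.index(roles["demand"])
    jr = model.reaction_index(roles["demand_reaction"])
    # sensitivities to the rate constants of the pathway proper (sink step excluded)
    path_rxns = [j for j in range(model.r) if j != jr]
    APS = np.abs(S_x[:, inter][:, :, path_rxns]).sum(axis=(1, 2))
    ISD = np.abs(L_x[:, inter, jd].sum(axis=1))
    ISS = np.abs(L_x[:, inter, js].sum(axis=1))
    PDG = L_x[:, ip, jd]
    FDG = L_v[:, jr, jd]
    PSG = L_x[:, ip, js]
    FSG = L_v[:, jr, js]
    return {"APS": APS, "ISD": ISD, "ISS": ISS, "PDG": PDG, "FDG": FDG, "PSG": PSG, "FSG": FSG}


def k_criteria(model: PathwayModel, sens: SensitivityResult) -> CriterionTable:
    """The seven aggregate criteria for a single design's sensitivity result."""
    roles = pathway_roles(model)
    vals = _aggregate(model, sens.S_x[None], sens.L_x[None], sens.L_v[None], roles)
    frame = pd.DataFrame({k: v for k, v in vals.items()})
    return CriterionTable(frame, dict(K_ORIENTATIONS), {"roles": roles})


def k_criteria_table(
    model: PathwayModel,
    kens: EnsembleTable | pd.DataFrame,
    fluxes=None,
) -> tuple[CriterionTable, np.ndarray]:
    """Vectorized k-criteria over an ensemble.

    Returns the criterion table (rows aligned with the *valid* samples) and
    the boolean validity mask over the input rows; structurally degenerate
    designs (singular steady-state system) are dropped and counted in the
    table metadata.
    """
    data = kens.data if isinstance(kens, EnsembleTable) else kens
    K = data[list(model.free_labels)].to_numpy(dtype=float)
    S_x, S_v, L_x, L_v, ok = _sensitivity_arrays(model, K, fluxes)
    roles = pathway_roles(model)
    vals = _aggregate(model, S_x, L_x, L_v, roles)
    frame = pd.DataFrame(vals)
    frame = frame.loc[ok].reset_index(drop=True)
    meta = {"roles": roles, "n_dropped_singular": int((~ok).sum())}
    return CriterionTable(frame, dict(K_ORIENTATIONS), meta), ok
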