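"""Generalized Mass Action (GMA) pathway models anchored to a reference steady state.

A GMA model describes a reaction network by the mass balance

    dx_d/dt = N v(x_d, x_i),      v_i = gamma_i * prod_j x_j**f_{i,j}

where ``N`` is the stoichiometric matrix over the *dependent* species, the
kinetic orders ``f_{i,j}`` are real exponents (elasticities), and the rate
constants ``gamma_i`` are fixed by *anchoring*: given a reference flux
distribution ``v0`` and reference concentrations, gamma is chosen so that the
reference profile is exactly a steady state.  This module houses the model
representation, anchoring, rate/Jacobian evaluation and a numeric
steady-state re-solver used as an independent oracle elsewhere.

Species and reaction labels are 1-based in configs and reports (``v_1..v_r``,
subscripts taken from the declared species order starting at 0, matching the
conventional ``x_0`` precursor naming); internal arrays order dependent
species first, in declaration order, then independent species.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import yaml

__all__ = [
    "PathwayModel",
    "ReferenceState",
    "RateConstants",
    "build_pathway",
    "rate_constants",
    "evaluate_rates",
    "mass_balance_rhs",
    "jacobian",
    "solve_steady_state",
]


@dataclass(frozen=True)
class PathwayModel:
    """Structure of a GMA pathway: stoichiometry, kinetic-order spec, Keq.

    ``orders_fixed`` maps ``(reaction, species)`` to a fixed kinetic order;
    ``orders_free`` maps to a uniform sampling interval ``(lo, hi)``.  ``keq``
    holds dimensionless equilibrium constants for reversible reactions with a
    declared substrate -> product direction.
    """

    name: str
    dependent: tuple[str, ...]
    independent: tuple[str, ...]
    reactions: tuple[str, ...]
    N: np.ndarray  # (n, r) integer stoichiometry over dependent species
    orders_fixed: dict[tuple[str, str], float]
    orders_free: dict[tuple[str, str], tuple[float, float]]
    keq: dict[str, float] = field(default_factory=dict)
    substrates: dict[str, str] = field(default_factory=dict)
    products: dict[str, str] = field(default_factory=dict)
    independent_values: dict[str, float] = field(default_factory=dict)
    roles: dict[str, str] = field(default_factory=dict)

    # ---- shapes and orderings -------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.dependent)

    @property
    def m(self) -> int:
        return len(self.independent)

    @property
    def r(self) -> int:
        return len(self.reactions)

    @property
    def species(self) -> tuple[str, ...]:
        """All species, dependent first — the column order of the full F matrix."""
        return self.dependent + self.independent

    def species_index(self, name: str) -> int:
        return self.species.index(name)

    def reaction_index(self, name: str) -> int:
        return self.reactions.index(name)

    @property
    def free_entries(self) -> tuple[tuple[str, str], ...]:
        """Free kinetic-order entries in deterministic (reaction, species) order."""
        decl = sorted(self.species, key=lambda s: self._label_subscripts[s])
        out = []
        for rxn in self.reactions:
            for sp in decl:
                if (rxn, sp) in self.orders_free:
                    out.append((rxn, sp))
        return tuple(out)

    def entry_label(self, rxn: str, sp: str) -> str:
        """Conventional label ``f_{i,j}``: i = 1-based reaction, j = species subscript."""
        ri = self.reaction_index(rxn) + 1
        sj = self._label_subscripts[sp]
        return f"f_{ri},{sj}"

    @property
    def _label_subscripts(self) -> dict[str, int]:
        cache = self.__dict__.get("_label_cache")
        if cache is None:
            order = self.__dict__.get("_declaration_order") or list(self.species)
            cache = {s: i for i, s in enumerate(order)}
            object.__setattr__(self, "_label_cache", cache)
        return cache

    @property
    def free_labels(self) -> tuple[str, ...]:
        return tuple(self.entry_label(r, s) for r, s in self.free_entries)

    # ---- kinetic-order matrices ----------------------------------------------
    def build_F(self, k: Sequence[float] | Mapping[str, float]) -> np.ndarray:
        """Full kinetic-order matrix F (r x (n+m)) from a free-entry vector.

        ``k`` is either a sequence ordered like :attr:`free_entries` or a
        mapping from entry labels to values.
        """
        F = np.zeros((self.r, self.n + self.m))
        for (rxn, sp), val in self.orders_fixed.items():
            F[self.reaction_index(rxn), self.species_index(sp)] = val
        if isinstance(k, Mapping):
            k = [k[lab] for lab in self.free_labels]
        k = np.asarray(k, dtype=float)
        if k.shape != (len(self.free_entries),):
            raise ValueError(
                f"expected {len(self.free_entries)} free kinetic orders, got {k.shape}"
            )
        for (rxn, sp), val in zip(self.free_entries, k):
            F[self.reaction_index(rxn), self.species_index(sp)] = val
        return F

    def split_F(self, F: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Split full F into dependent (r x n) and independent (r x m) blocks."""
        return F[:, : self.n], F[:, self.n :]

    def default_x_i(self) -> np.ndarray:
        return np.array([self.independent_values[s] for s in self.independent])

    def __post_init__(self):
        if self.N.shape != (self.n, self.r):
            raise ValueError(f"N must be {self.n}x{self.r}, got {self.N.shape}")
        if self.n and not np.all(np.any(self.N != 0, axis=1)):
            raise ValueError("stoichiometric matrix has an all-zero row")
        declared = set(self.species)
        for (rxn, sp) in list(self.orders_fixed) + list(self.orders_free):
            if sp not in declared:
                raise ValueError(f"kinetic-order entry references undeclared species {sp!r}")
            if rxn not in self.reactions:
                raise ValueError(f"kinetic-order entry references undeclared reaction {rxn!r}")
        for rxn in self.keq:
            if rxn not in self.substrates or rxn not in self.products:
                raise ValueError(
                    f"Keq given for {rxn!r} without a substrate->product direction"
                )


@dataclass(frozen=True)
class ReferenceState:
    """Reference steady state: fluxes v0 (mM/min) and concentrations (mM).

    ``x_i0`` includes dimensionless placeholders such as a demand variable.
    All entries must be strictly positive and ``N @ v0`` must vanish.
    """

    v0: np.ndarray
    x_d0: np.ndarray
    x_i0: np.ndarray

    def __post_init__(self):
        for nm, arr in (("v0", self.v0), ("x_d0", self.x_d0), ("x_i0", self.x_i0)):
            a = np.asarray(arr, dtype=float)
            object.__setattr__(self, nm, a)
            if a.size and np.any(a <= 0):
                raise ValueError(f"{nm} must be strictly positive")

    def validate_steady(self, model: PathwayModel, rtol: float = 1e-9) -> None:
        resid = model.N @ self.v0
        scale = max(np.max(np.abs(self.v0)), 1.0)
        if np.max(np.abs(resid)) > rtol * scale:
            raise ValueError(f"v0 is not a steady-state flux: N@v0 = {resid}")

    def with_x_d(self, x_d: Sequence[float]) -> "ReferenceState":
        return replace(self, x_d0=np.asarray(x_d, dtype=float))


@dataclass(frozen=True)
class RateConstants:
    """Per-reaction positive rate constants gamma (units set by anchoring)."""

    gamma: np.ndarray

    def __post_init__(self):
        g = np.asarray(self.gamma, dtype=float)
        object.__setattr__(self, "gamma", g)
        if np.any(g <= 0) or not np.all(np.isfinite(g)):
            raise ValueError("rate constants must be finite and strictly positive")


# ---------------------------------------------------------------------------
# construction
# ---------------------------------------------------------------------------

def build_pathway(config: Mapping | str | Path) -> PathwayModel:
    """Build a validated :class:`PathwayModel` from a YAML/JSON-style document.

    The document declares ``species`` (name, role, optional value for
    independents), ``reactions`` (name, stoichiometry over dependent species,
    kinetic ``orders`` as fixed value or ``[lo, hi]`` interval, optional
    ``keq`` with ``substrate``/``product`` direction) and optional ``roles``.
    """
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            config = yaml.safe_load(fh)
    if not isinstance(config, Mapping):
        raise ValueError("model config must be a mapping")

    species_cfg = config.get("species") or []
    if not species_cfg:
        raise ValueError("config declares no species")
    dependent, independent, indep_values, decl = [], [], {}, []
    for sp in species_cfg:
        name, role = sp["name"], sp.get("role", "dependent")
        decl.append(name)
        if role == "dependent":
            dependent.append(name)
        elif role == "independent":
            independent.append(name)
            indep_values[name] = float(sp.get("value", 1.0))
        else:
            raise ValueError(f"unknown species role {role!r} for {name!r}")

    rxn_cfg = config.get("reactions") or []
    if not rxn_cfg:
        raise ValueError("config declares no reactions")
    reactions, keq, subs, prods = [], {}, {}, {}
    orders_fixed: dict[tuple[str, str], float] = {}
    orders_free: dict[tuple[str, str], tuple[float, float]] = {}
    N = np.zeros((len(dependent), len(rxn_cfg)), dtype=int)
    dep_index = {s: i for i, s in enumerate(dependent)}
    declared = set(decl)
    for j, rx in enumerate(rxn_cfg):
        name = rx.get("name", f"v{j + 1}")
        reactions.append(name)
        orders = rx.get("orders") or {}
        if not orders:
            raise ValueError(f"reaction {name!r} declares no kinetic orders")
        for sp, val in orders.items():
            if sp not in declared:
                raise ValueError(
                    f"reaction {name!r} references undeclared species {sp!r}"
                )
            if isinstance(val, (list, tuple)):
                if len(val) != 2:
                    raise ValueError(f"range for ({name},{sp}) must be [lo, hi]")
                lo, hi = val
                if not all(isinstance(b, (int, float)) for b in (lo, hi)):
                    raise ValueError(f"non-numeric range bounds for ({name},{sp})")
                orders_free[(name, sp)] = (float(lo), float(hi))
            else:
                if not isinstance(val, (int, float)):
                    raise ValueError(f"non-numeric kinetic order for ({name},{sp})")
                orders_fixed[(name, sp)] = float(val)
        for sp, coef in (rx.get("stoichiometry") or {}).items():
            if sp not in dep_index:
                raise ValueError(
                    f"stoichiometry of {name!r} references non-dependent species {sp!r}"
                )
            N[dep_index[sp], j] = int(coef)
        if "keq" in rx and rx["keq"] is not None:
            keq[name] = float(rx["keq"])
            if "substrate" not in rx or "product" not in rx:
                raise ValueError(f"reaction {name!r} has keq but no substrate/product")
        if "substrate" in rx:
            subs[name] = rx["substrate"]
        if "product" in rx:
            prods[name] = rx["product"]

    model = PathwayModel(
        name=config.get("name", "pathway"),
        dependent=tuple(dependent),
        independent=tuple(independent),
        reactions=tuple(reactions),
        N=N,
        orders_fixed=orders_fixed,
        orders_free=orders_free,
        keq=keq,
        substrates=subs,
        products=prods,
        independent_values=indep_values,
        roles=dict(config.get("roles") or {}),
    )
    # label subscripts follow the declaration order of the config
    object.__setattr__(model, "_declaration_order", decl)
    return model


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def _as_gamma(gamma) -> np.ndarray:
    return gamma.gamma if isinstance(gamma, RateConstants) else np.asarray(gamma, float)


def rate_constants(model: PathwayModel, ref: ReferenceState, k) -> RateConstants:
    """Anchor rate constants: gamma_i = v0_i / prod_j x_j0**f_{i,j}."""
    x_all = np.concatenate([ref.x_d0, ref.x_i0])
    if np.any(x_all <= 0):
        raise ValueError("reference concentrations must be strictly positive")
    F = model.build_F(k)
    gamma = np.asarray(ref.v0, float) / np.exp(F @ np.log(x_all))
    return RateConstants(gamma)


def evaluate_rates(model: PathwayModel, gamma, x_d, x_i, F: np.ndarray | None = None, k=None):
    """Power-law rates v_i = gamma_i * prod_j x_j**f_{i,j} over all species."""
    x_all = np.concatenate([np.asarray(x_d, float), np.asarray(x_i, float)])
    if np.any(x_all <= 0):
        raise ValueError("power-law rates are undefined at non-positive concentrations")
    if F is None:
        F = model.build_F(k)
    return _as_gamma(gamma) * np.exp(F @ np.log(x_all))


def mass_balance_rhs(model: PathwayModel, gamma, x_d, x_i, F=None, k=None) -> np.ndarray:
    """Time derivative of the dependent concentrations, N @ v."""
    return model.N @ evaluate_rates(model, gamma, x_d, x_i, F=F, k=k)


def jacobian(model: PathwayModel, gamma, x_d, x_i, F=None, k=None) -> np.ndarray:
    """Analytic Jacobian of the mass balance at (x_d, x_i).

    J = N diag(v) F_d diag(1/x_d), from d v_i/d x_j = v_i f_{i,j} / x_j.
    """
    if F is None:
        F = model.build_F(k)
    v = evaluate_rates(model, gamma, x_d, x_i, F=F)
    F_d, _ = model.split_F(F)
    x_d = np.asarray(x_d, float)
    return (model.N * v[None, :]) @ (F_d / x_d[None, :])


def solve_steady_state(
    model: PathwayModel,
    gamma,
    x_i,
    x_d_guess,
    tol: float = 1e-13,
    F: np.ndarray | None = None,
    k=None,
) -> np.ndarray:
    """Numerically re-solve N v(x_d) = 0 for x_d in log space.

    Independent oracle for the analytic sensitivity algebra: perturb gamma or
    x_i, re-solve, and difference the logs.
    """
    from scipy.optimize import root

    if F is None:
        F = model.build_F(k)
    g = np.log(_as_gamma(gamma))
    lxi = np.log(np.asarray(x_i, float))

    def fun(lx):
        x_all = np.concatenate([lx, lxi])
        v = np.exp(g + F @ x_all)
        return model.N @ v

    sol = root(fun, np.log(np.asarray(x_d_guess, float)), tol=tol)
    if not sol.success:
        raise RuntimeError(f"steady-state re-solve failed: {sol.message}")
    return np.exp(sol.x)
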