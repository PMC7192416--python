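"""Recombination of subspace selections, stability screening and step response.

After the v-, x- and k-ensembles have been screened separately, the surviving
members are recombined as a cartesian product of anchored full models.  Local
stability is decided from the eigenvalues of the analytic Jacobian at the
anchoring reference state (stable iff every real part < -tol; marginal cases
are conservatively counted unstable).  Step-response simulations integrate
the full nonlinear ODE, reporting concentrations and the demand flux
normalized to their reference values.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .criteria import pathway_roles
from .ensembles import EnsembleTable
from .model import (
    PathwayModel,
    RateConstants,
    ReferenceState,
    evaluate_rates,
    jacobian,
    rate_constants,
)

__all__ = [
    "StabilityReport",
    "StabilityScreen",
    "Trajectory",
    "RecombinedModel",
    "recombine",
    "stability",
    "stability_screen",
    "simulate_step",
]

#: a model is stable iff max Re(eig) < -STABILITY_TOL
STABILITY_TOL = 1e-9


class RecombinedModel(NamedTuple):
    """One member of the cartesian v-x-k product, anchored to its reference."""

    index: tuple[int, int, int]  # (x row, k row, v row)
    ref: ReferenceState
    k: np.ndarray
    gamma: RateConstants


@dataclass
class StabilityReport:
    stable: bool
    leading_real: float
    eigenvalues: np.ndarray


@dataclass
class StabilityScreen:
    """Vectorized stability results over a recombined ensemble."""

    stable: np.ndarray  # flat bool, k-major then x within v blocks
    leading_real: np.ndarray
    shape: tuple[int, int, int]  # (n_x, n_k, n_v)

    @property
    def unstable_fraction(self) -> float:
        return float(1.0 - self.stable.mean())

    def to_frame(self) -> pd.DataFrame:
        nx_, nk, nv = self.shape
        iv, ik, ix = np.unravel_index(np.arange(self.stable.size), (nv, nk, nx_))
        return pd.DataFrame(
            {
                "x_row": ix,
                "k_row": ik,
                "v_row": iv,
                "stable": self.stable,
                "leading_real": self.leading_real,
            }
        )


@dataclass
class Trajectory:
    """Normalized step-response trajectory of one model."""

    time: np.ndarray
    states: pd.DataFrame  # normalized dependent concentrations x_i(t)/x_i0
    flux: np.ndarray  # demand flux v(t)/v0
    perturbation: dict

    @property
    def intermediates(self) -> np.ndarray:
        """Sum of intermediate concentrations normalized to its reference value."""
        inter = self.perturbation["intermediates"]
        num = self.states[inter].to_numpy() @ self.perturbation["x_inter_0"]
        return num / self.perturbation["x_inter_0"].sum()

    def to_frame(self) -> pd.DataFrame:
        out = self.states.copy()
        out.insert(0, "time", self.time)
        out["flux"] = self.flux
        return out


# ---------------------------------------------------------------------------
# recombination
# ---------------------------------------------------------------------------

def recombine(
    model: PathwayModel,
    xsel: EnsembleTable,
    ksel: EnsembleTable,
    vsel: EnsembleTable,
    x_i=None,
) -> Iterator[RecombinedModel]:
    """Lazily yield the cartesian product of the three selections, anchored.

    The total number of yielded models is exactly
    ``len(xsel) * len(ksel) * len(vsel)``; the product is never materialized.
    """
    for tab in (xsel, ksel, vsel):
        if len(tab) == 0:
            raise ValueError("empty selection cannot be recombined")
    x_i0 = model.default_x_i() if x_i is None else np.asarray(x_i, float)
    X = xsel.data[list(model.dependent)].to_numpy(dtype=float)
    K = ksel.data[list(model.free_labels)].to_numpy(dtype=float)
    V = vsel.data[list(model.reactions)].to_numpy(dtype=float)
    for iv in range(len(V)):
        for ik in range(len(K)):
            for ix in range(len(X)):
                ref = ReferenceState(v0=V[iv], x_d0=X[ix], x_i0=x_i0)
                gamma = rate_constants(model, ref, K[ik])
                yield RecombinedModel((ix, ik, iv), ref, K[ik], gamma)


# ---------------------------------------------------------------------------
# stability
# ---------------------------------------------------------------------------

def stability(
    model: PathwayModel,
    gamma,
    ref: ReferenceState,
    k=None,
    F=None,
    tol: float = STABILITY_TOL,
) -> StabilityReport:
    """Eigenvalue stability of the anchored steady state."""
    J = jacobian(model, gamma, ref.x_d0, ref.x_i0, F=F, k=k)
    ev = np.linalg.eigvals(J)
    lead = float(ev.real.max())
    return StabilityReport(stable=lead < -tol, leading_real=lead, eigenvalues=ev)


def stability_screen(
    model: PathwayModel,
    xsel: EnsembleTable,
    ksel: EnsembleTable,
    vsel: EnsembleTable,
    tol: float = STABILITY_TOL,
    chunk: int = 200_000,
) -> StabilityScreen:
    """Vectorized eigenvalue screen over the recombined ensemble.

    At the anchored reference the Jacobian is N diag(v0) F_d diag(1/x_d), so
    per k-vector and flux row only the column scaling varies with the
    x-profile; the screen batches the small eigenproblems in chunks so even
    multi-million-model products stay within memory.
    """
    X = xsel.data[list(model.dependent)].to_numpy(dtype=float)
    K = ksel.data[list(model.free_labels)].to_numpy(dtype=float)
    V = vsel.data[list(model.reactions)].to_numpy(dtype=float)
    from .criteria import _order_tensors

    Fd, _ = _order_tensors(model, K)
    n_x, n_k, n_v = len(X), len(K), len(V)
    stable = np.empty(n_v * n_k * n_x, dtype=bool)
    leading = np.empty(n_v * n_k * n_x)
    pos = 0
    for iv in range(n_v):
        M = np.einsum("ir,krj->kij", model.N * V[iv][None, :], Fd)  # (n_k, n, n)
        x_per = max(1, chunk // max(n_k, 1))
        for start in range(0, n_x, x_per):
            xs = X[start : start + x_per]
            J = M[:, None, :, :] / xs[None, :, None, :]
            ev = np.linalg.eigvals(J.reshape(-1, model.n, model.n))
            lead = ev.real.max(axis=1)
            m = len(lead)
            stable[pos : pos + m] = lead < -tol
            leading[pos : pos + m] = lead
            pos += m
    return StabilityScreen(stable=stable, leading_real=leading, shape=(n_x, n_k, n_v))


# ---------------------------------------------------------------------------
# dynamic simulation
# ---------------------------------------------------------------------------

def simulate_step(
    model: PathwayModel,
    gamma,
    ref: ReferenceState,
    k=None,
    F=None,
    demand_factor: float = 2.0,
    t_step: float = 1.0,
    t_end: float = 50.0,
    demand_species: str | None = None,
    rtol: float = 1e-8,
    require_stable: bool = True,
    steady_tol: float = 1e-8,
) -> Trajectory:
    """Integrate the step response to a change in the demand variable.

    The model starts at its anchored reference steady state; at ``t_step``
    (minutes) the independent demand variable is multiplied by
    ``demand_factor``, and integration continues until a new steady state
    (``||dx/dt||_inf < steady_tol``) or ``t_end``.  All reported states are
    normalized to their reference values.
    """
    if F is None:
        F = model.build_F(k)
    roles = pathway_roles(model)
    demand_species = demand_species or roles["demand"]
    jd = model.independent.index(demand_species)
    jr = model.reaction_index(roles["demand_reaction"])
    if require_stable:
        rep = stability(model, gamma, ref, F=F)
        if not rep.stable:
            raise RuntimeError(
                f"model is locally unstable (leading Re = {rep.leading_real:.3g}); "
                "pass require_stable=False to simulate anyway"
            )

    def make_rhs(x_i):
        def rhs(t, x):
            x = np.maximum(x, 1e-300)
            return model.N @ evaluate_rates(model, gamma, x, x_i, F=F)

        return rhs

    def steady_event(x_i):
        f = make_rhs(x_i)

        def ev(t, x):
            return float(np.abs(f(t, x)).max()) - steady_tol

        ev.terminal = True
        ev.direction = -1
        return ev

    x_i_base = ref.x_i0.copy()
    x_i_step = x_i_base.copy()
    x_i_step[jd] *= demand_factor

    seg1 = solve_ivp(
        make_rhs(x_i_base),
        (0.0, t_step),
        ref.x_d0,
        method="LSODA",
        rtol=rtol,
        atol=1e-12,
        dense_output=True,
    )
    if not seg1.success:
        raise RuntimeError(f"integration failed before the step: {seg1.message}")
    seg2 = solve_ivp(
        make_rhs(x_i_step),
        (t_step, t_end),
        seg1.y[:, -1],
        method="LSODA",
        rtol=rtol,
        atol=1e-12,
        events=steady_event(x_i_step),
        dense_output=True,
    )
    if seg2.status == -1:
        raise RuntimeError(f"integration failed after the step: {seg2.message}")
    t = np.concatenate([seg1.t, seg2.t])
    Y = np.concatenate([seg1.y, seg2.y], axis=1).T  # (nt, n)
    norm = Y / ref.x_d0[None, :]
    states = pd.DataFrame(norm, columns=list(model.dependent))
    flux = np.empty(len(t))
    for i, (ti, y) in enumerate(zip(t, Y)):
        x_i = x_i_step if ti > t_step or (ti == t_step and i >= len(seg1.t)) else x_i_base
        flux[i] = evaluate_rates(model, gamma, np.maximum(y, 1e-300), x_i, F=F)[jr]
    flux /= ref.v0[jr]
    product = roles["product"]
    inter = [s for s in model.dependent if s != product]
    perturbation = {
        "demand_species": demand_species,
        "demand_factor": demand_factor,
        "t_step": t_step,
        "reached_steady": bool(seg2.status == 1),
        "intermediates": inter,
        "x_inter_0": ref.x_d0[[model.dependent.index(s) for s in inter]],
    }
    return Trajectory(time=t, states=states, flux=flux, perturbation=perturbation)
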