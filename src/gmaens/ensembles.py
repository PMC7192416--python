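"""Design-subspace ensembles (v-, x-, k-) and thermodynamic screening.

The design space of an anchored GMA model factorizes into three independent
subspaces — flux distributions (v), steady-state concentration profiles (x)
and kinetic orders (k) — each sampled and screened on its own.  The x-ensemble
is additionally subject to an *a priori* thermodynamic constraint: for a
reaction carrying flux in its declared direction, the mass-action ratio must
stay below the equilibrium constant, i.e. the distance to equilibrium
theta = (product/substrate)/Keq must satisfy theta < 1.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .model import PathwayModel

__all__ = [
    "EnsembleTable",
    "ThetaProfile",
    "sample_x",
    "sample_x_feasible",
    "theta",
    "feasible_filter",
    "sample_k",
    "v_ensemble",
]

#: numerical guard: a sample is feasible only if theta < 1 - FEASIBILITY_DELTA,
#: keeping the 1/(1-theta) cost finite.
FEASIBILITY_DELTA = 1e-6


@dataclass
class EnsembleTable:
    """Labeled sample matrix for one design subspace ('v', 'x' or 'k')."""

    tag: str
    data: pd.DataFrame
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.tag not in ("v", "x", "k"):
            raise ValueError(f"unknown subspace tag {self.tag!r}")
        if self.data.isna().any().any():
            raise ValueError("ensemble table contains missing values")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def to_csv(self, path: str | Path) -> None:
        """Write the samples as CSV plus a ``.meta.json`` sidecar."""
        path = Path(path)
        self.data.to_csv(path, index=False)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        sidecar.write_text(json.dumps({"tag": self.tag, **self.meta}, default=str, indent=1))

    @classmethod
    def from_csv(cls, path: str | Path) -> "EnsembleTable":
        path = Path(path)
        data = pd.read_csv(path)
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        meta = json.loads(sidecar.read_text()) if sidecar.exists() else {}
        tag = meta.pop("tag", "x")
        return cls(tag=tag, data=data, meta=meta)


@dataclass
class ThetaProfile:
    """Per-sample distance to equilibrium for each reversible reaction."""

    data: pd.DataFrame  # columns = reversible reaction names

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def feasible_mask(self, delta: float = FEASIBILITY_DELTA) -> np.ndarray:
        return (self.values < 1.0 - delta).all(axis=1)


# ---------------------------------------------------------------------------
# samplers
# ---------------------------------------------------------------------------

def sample_x(
    model: PathwayModel,
    n: int,
    conc_range: tuple[float, float] = (1e-4, 10.0),
    seed: int | None = None,
    log_uniform: bool = False,
) -> EnsembleTable:
    """Sample dependent concentration profiles i.i.d. uniform on [lo, hi] mM.

    The default range 0.1 uM - 10 mM spans realistic cytosolic metabolite
    levels.  ``log_uniform`` switches to uniform sampling of log-concentration
    (off by default; the linear scale is the study's convention).
    """
    lo, hi = conc_range
    if n <= 0:
        raise ValueError("n must be positive")
    if not (0 < lo < hi):
        raise ValueError(f"degenerate concentration range ({lo}, {hi})")
    rng = np.random.default_rng(seed)
    if log_uniform:
        x = np.exp(rng.uniform(np.log(lo), np.log(hi), size=(n, model.n)))
    else:
        x = rng.uniform(lo, hi, size=(n, model.n))
    data = pd.DataFrame(x, columns=list(model.dependent))
    meta = {"seed": seed, "range": [lo, hi], "distribution": "log-uniform" if log_uniform else "uniform"}
    return EnsembleTable(tag="x", data=data, meta=meta)


def theta(model: PathwayModel, xens: EnsembleTable | pd.DataFrame, x_i=None) -> ThetaProfile:
    """Distance to equilibrium theta_i = (product/substrate)/Keq per reversible reaction.

    ``x_i`` maps independent species to their concentrations; by default the
    model's declared independent values are used (the precursor level sets the
    feasibility of the first reaction).
    """
    data = xens.data if isinstance(xens, EnsembleTable) else xens
    vals = {}
    for sp in model.dependent:
        vals[sp] = data[sp].to_numpy(dtype=float)
    defaults = dict(model.independent_values)
    if x_i:
        defaults.update(x_i)
    n_rows = len(data)
    for sp in model.independent:
        vals[sp] = np.full(n_rows, float(defaults[sp]))
    cols = {}
    for rxn, K in model.keq.items():
        s, p = model.substrates[rxn], model.products[rxn]
        sub = vals[s]
        if np.any(sub <= 0):
            raise ValueError(f"zero substrate concentration for reaction {rxn!r}")
        cols[rxn] = (vals[p] / sub) / K
    return ThetaProfile(pd.DataFrame(cols, index=data.index))


def feasible_filter(
    xens: EnsembleTable,
    thetas: ThetaProfile,
    delta: float = FEASIBILITY_DELTA,
) -> tuple[EnsembleTable, ThetaProfile]:
    """Retain thermodynamically feasible samples (theta_i < 1 - delta for all).

    Idempotent; the retained fraction is recorded in the output metadata.
    """
    if len(thetas.data) != len(xens):
        raise ValueError("theta profile does not match the ensemble")
    mask = thetas.feasible_mask(delta)
    kept = xens.data.loc[mask].reset_index(drop=True)
    kept_theta = thetas.data.loc[mask].reset_index(drop=True)
    meta = dict(xens.meta)
    meta.update(
        {
            "feasibility_delta": delta,
            "n_before_filter": len(xens),
            "retained_fraction": float(mask.mean()) if len(mask) else 0.0,
        }
    )
    return EnsembleTable(tag="x", data=kept, meta=meta), ThetaProfile(kept_theta)


def sample_x_feasible(
    model: PathwayModel,
    n: int,
    conc_range: tuple[float, float] = (1e-4, 10.0),
    seed: int | None = None,
    x_i=None,
    delta: float = FEASIBILITY_DELTA,
    batch: int = 50_000,
) -> tuple[EnsembleTable, ThetaProfile]:
    """Rejection-sample until ``n`` thermodynamically feasible profiles are collected."""
    rng = np.random.default_rng(seed)
    frames, theta_frames, drawn = [], [], 0
    got = 0
    while got < n:
        sub_seed = int(rng.integers(0, 2**31 - 1))
        raw = sample_x(model, batch, conc_range=conc_range, seed=sub_seed)
        th = theta(model, raw, x_i=x_i)
        kept, kept_th = feasible_filter(raw, th, delta=delta)
        drawn += batch
        got += len(kept)
        frames.append(kept.data)
        theta_frames.append(kept_th.data)
    data = pd.concat(frames, ignore_index=True).iloc[:n].reset_index(drop=True)
    th = pd.concat(theta_frames, ignore_index=True).iloc[:n].reset_index(drop=True)
    meta = {
        "seed": seed,
        "range": list(conc_range),
        "distribution": "uniform",
        "feasibility_delta": delta,
        "n_raw_drawn": drawn,
        "retained_fraction": got / drawn,
    }
    return EnsembleTable(tag="x", data=data, meta=meta), ThetaProfile(th)


def sample_k(model: PathwayModel, n: int, seed: int | None = None) -> EnsembleTable:
    """Sample kinetic-order vectors i.i.d. uniform in each entry's declared interval."""
    if n <= 0:
        raise ValueError("n must be positive")
    entries = model.free_entries
    if not entries:
        raise ValueError("model has no free kinetic-order entries to sample")
    rng = np.random.default_rng(seed)
    cols = {}
    for (rxn, sp) in entries:
        lo, hi = model.orders_free[(rxn, sp)]
        cols[model.entry_label(rxn, sp)] = rng.uniform(lo, hi, size=n)
    data = pd.DataFrame(cols, columns=list(model.free_labels))
    meta = {
        "seed": seed,
        "ranges": {model.entry_label(r, s): list(model.orders_free[(r, s)]) for r, s in entries},
        "fixed": {model.entry_label(r, s): v for (r, s), v in model.orders_fixed.items()},
        "distribution": "uniform",
    }
    return EnsembleTable(tag="k", data=data, meta=meta)


def v_ensemble(model: PathwayModel, flux_spec) -> EnsembleTable:
    """Build the flux ensemble from a scalar (unbranched chain) or a table.

    A scalar assigns that flux to every reaction; every row is checked against
    the steady-state conservation N @ v = 0.  Flux sampling itself (FBA or
    thermodynamic approaches) is outside this package: distributions are
    assumed to have been selected upstream.
    """
    if np.isscalar(flux_spec):
        rows = np.full((1, model.r), float(flux_spec))
    else:
        arr = flux_spec.to_numpy() if isinstance(flux_spec, pd.DataFrame) else np.asarray(flux_spec, float)
        rows = np.atleast_2d(arr)
        if rows.shape[1] != model.r:
            raise ValueError(f"flux table must have {model.r} columns")
    resid = rows @ model.N.T
    scale = np.maximum(np.abs(rows).max(axis=1), 1.0)
    if np.any(np.abs(resid).max(axis=1) > 1e-9 * scale):
        raise ValueError("flux distribution violates N @ v = 0")
    data = pd.DataFrame(rows, columns=list(model.reactions))
    return EnsembleTable(tag="v", data=data, meta={"source": "scalar" if np.isscalar(flux_spec) else "table"})
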