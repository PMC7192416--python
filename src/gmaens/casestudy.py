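"""Built-in case study: a three-step unbranched pathway with end-product inhibition.

Precursor x0 feeds a chain x0 -> x1 -> x2 -> x3 whose final product x3 is
drained by a demand step modulated by the dimensionless demand variable x4
(first-order, f_{4,4} = 1).  The product inhibits the first reaction
(feedback order f_{1,3} in [-7, 0]; magnitudes beyond ~2 emulate longer
pathways with realistic coefficients).  Forward orders are sampled in [0, 1],
backward (product) orders in [-1, 0], all equilibrium constants default to 1,
and the reference flux is 31.5 mM/min on every reaction — a plausible
biosynthetic flux for a bacterium doubling every ~20 min.
"""

from __future__ import annotations

import copy

import numpy as np

from .model import PathwayModel, ReferenceState, build_pathway

__all__ = ["case_study_config", "case_study_model", "CASE_STUDY_FLUX"]

#: reference steady-state flux, mM/min, on every reaction of the chain
CASE_STUDY_FLUX = 31.5

_CASE_STUDY = {
    "name": "three-step chain with end-product inhibition",
    "species": [
        {"name": "x0", "role": "independent", "value": 10.0},
        {"name": "x1", "role": "dependent"},
        {"name": "x2", "role": "dependent"},
        {"name": "x3", "role": "dependent"},
        {"name": "x4", "role": "independent", "value": 1.0},
    ],
    "reactions": [
        {
            "name": "v1",
            "stoichiometry": {"x1": 1},
            "substrate": "x0",
            "product": "x1",
            "keq": 1.0,
            "orders": {"x0": [0.0, 1.0], "x1": [-1.0, 0.0], "x3": [-7.0, 0.0]},
        },
        {
            "name": "v2",
            "stoichiometry": {"x1": -1, "x2": 1},
            "substrate": "x1",
            "product": "x2",
            "keq": 1.0,
            "orders": {"x1": [0.0, 1.0], "x2": [-1.0, 0.0]},
        },
        {
            "name": "v3",
            "stoichiometry": {"x2": -1, "x3": 1},
            "substrate": "x2",
            "product": "x3",
            "keq": 1.0,
            "orders": {"x2": [0.0, 1.0], "x3": [-1.0, 0.0]},
        },
        {
            "name": "v4",
            "stoichiometry": {"x3": -1},
            "orders": {"x3": [0.0, 1.0], "x4": 1.0},
        },
    ],
    "reference": {"flux": CASE_STUDY_FLUX},
    "roles": {"supply": "x0", "demand": "x4", "product": "x3", "demand_reaction": "v4"},
}


def case_study_config(keq: dict[str, float] | None = None) -> dict:
    """A deep copy of the case-study model document (Keq overridable per reaction)."""
    cfg = copy.deepcopy(_CASE_STUDY)
    if keq:
        for rx in cfg["reactions"]:
            if rx["name"] in keq:
                rx["keq"] = float(keq[rx["name"]])
    return cfg


def case_study_model(
    keq: dict[str, float] | None = None,
    x_d0=(1.0, 1.0, 1.0),
) -> tuple[PathwayModel, ReferenceState]:
    """The built-in pathway and its reference state.

    ``x_d0`` is a placeholder anchoring profile (the pipeline re-anchors each
    sampled concentration profile); the flux is 31.5 mM/min on all reactions,
    x0 = 10 mM and the demand variable x4 = 1.
    """
    model = build_pathway(case_study_config(keq))
    ref = ReferenceState(
        v0=np.full(model.r, CASE_STUDY_FLUX),
        x_d0=np.asarray(x_d0, dtype=float),
        x_i0=model.default_x_i(),
    )
    ref.validate_steady(model)
    return model, ref
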