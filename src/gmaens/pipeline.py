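"""End-to-end workflow orchestration and test-fixture generation.

The pipeline mirrors the partitioned screening funnel: the x-ensemble is
sampled, filtered for thermodynamic feasibility and reduced to the exact
Pareto front of {total, draft, thermodynamic cost}; the k-ensemble is sampled,
mapped through the sensitivity criteria and reduced to behavioral classes
(robust / demand-driven / supply-driven) and fronts; the selections are then
recombined with the flux distribution and screened for stability.  Every
stage writes its tables as CSV and a structured entry into the run log.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import backmap as bm
from . import criteria as cr
from . import dynamics as dyn
from . import ensembles as ens
from . import selection as sel
from .casestudy import case_study_config, case_study_model
from .model import PathwayModel, ReferenceState, build_pathway

__all__ = ["RunConfig", "StageReport", "run_pipeline", "make_fixture"]


@dataclass
class RunConfig:
    """Parameters of one pipeline run (defaults reproduce the case study)."""

    model_path: str | None = None  # None -> built-in case study
    outdir: str = "run"
    n_x: int = 10_000  # feasible concentration profiles to collect
    n_k: int = 10_000  # kinetic-order vectors to sample
    flux: float = 31.5  # mM/min, applied to every reaction (unbranched)
    conc_range: tuple[float, float] = (1e-4, 10.0)  # mM
    seed_x: int = 11
    seed_k: int = 23
    seed_enrich: int = 37
    percentile: float = 50.0
    iss_exclusion: float = 0.03
    eps: float = 0.05
    keq: dict = field(default_factory=dict)
    n_enrich: int = 500
    run_backmap: bool = True
    run_stability: bool = True
    simulate: int = 0  # number of demand-front models to step-simulate

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(doc) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "conc_range" in doc:
            doc["conc_range"] = tuple(doc["conc_range"])
        return cls(**doc)

    def validate(self) -> None:
        if self.n_x <= 0 or self.n_k <= 0:
            raise ValueError("sample sizes must be positive")
        if not (0 <= self.iss_exclusion <= 1):
            raise ValueError("iss_exclusion must be in [0, 1]")
        if self.eps < 0:
            raise ValueError("eps must be non-negative")


@dataclass
class StageReport:
    stage: str
    n_in: int
    n_out: int
    seed: int | None
    elapsed: float
    params: dict = field(default_factory=dict)


class _Log:
    def __init__(self):
        self.reports: list[StageReport] = []

    def stage(self, name, n_in, n_out, seed=None, t0=None, **params):
        self.reports.append(
            StageReport(name, int(n_in), int(n_out), seed, time.perf_counter() - (t0 or 0), params)
        )


def _load_model(cfg: RunConfig) -> tuple[PathwayModel, ReferenceState]:
    if cfg.model_path:
        model = build_pathway(cfg.model_path)
        ref = ReferenceState(
            v0=np.full(model.r, cfg.flux),
            x_d0=np.ones(model.n),
            x_i0=model.default_x_i(),
        )
        ref.validate_steady(model)
        return model, ref
    return case_study_model(keq=cfg.keq or None)


def run_pipeline(cfg: RunConfig) -> list[StageReport]:
    """Execute the full screening workflow and write all outputs to cfg.outdir."""
    cfg.validate()
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    log = _Log()
    model, ref = _load_model(cfg)

    try:
        # ---- v-ensemble ----------------------------------------------------
        t0 = time.perf_counter()
        vens = ens.v_ensemble(model, cfg.flux)
        vens.to_csv(out / "v_ensemble.csv")
        log.stage("v_ensemble", 1, len(vens), t0=t0, flux=cfg.flux)

        # ---- x-ensemble: sample -> feasibility -> criteria -> front --------
        t0 = time.perf_counter()
        xens, thetas = ens.sample_x_feasible(
            model, cfg.n_x, conc_range=cfg.conc_range, seed=cfg.seed_x
        )
        xens.to_csv(out / "x_ensemble.csv")
        log.stage(
            "sample_x_feasible",
            xens.meta["n_raw_drawn"],
            len(xens),
            seed=cfg.seed_x,
            t0=t0,
            retained_fraction=xens.meta["retained_fraction"],
        )

        t0 = time.perf_counter()
        xcrit = cr.x_criteria(model, xens, thetas, cfg.flux)
        xcrit.to_csv(out / "x_criteria.csv")
        log.stage("x_criteria", len(xens), len(xcrit), t0=t0)

        t0 = time.perf_counter()
        xfront = sel.pareto_front(xcrit, ["total", "draft", "cost"])
        xsel = ens.EnsembleTable(
            tag="x",
            data=xens.data.iloc[xfront.indices].reset_index(drop=True),
            meta={"selection": "pareto {total,draft,cost}", "parent_rows": xfront.indices.tolist()},
        )
        xsel.to_csv(out / "x_selected.csv")
        log.stage("x_pareto_front", len(xcrit), len(xfront), t0=t0)

        # ---- k-ensemble: sample -> sensitivities -> classes -> fronts ------
        t0 = time.perf_counter()
        kens = ens.sample_k(model, cfg.n_k, seed=cfg.seed_k)
        kens.to_csv(out / "k_ensemble.csv")
        log.stage("sample_k", cfg.n_k, len(kens), seed=cfg.seed_k, t0=t0)

        t0 = time.perf_counter()
        kcrit, ok = cr.k_criteria_table(model, kens, fluxes=np.full(model.r, cfg.flux))
        kdata = kens.data.loc[ok].reset_index(drop=True)
        kens_valid = ens.EnsembleTable(tag="k", data=kdata, meta=dict(kens.meta))
        kcrit.to_csv(out / "k_criteria.csv")
        log.stage("k_criteria", len(kens), len(kcrit), t0=t0,
                  dropped_singular=kcrit.meta["n_dropped_singular"])

        t0 = time.perf_counter()
        robust = sel.behavioral_class(kcrit, ["APS", "ISS", "ISD"], cfg.percentile)
        demand = sel.behavioral_class(
            kcrit, ["APS", "ISS", "ISD", "PDG", "FDG"], cfg.percentile
        )
        supply = sel.behavioral_class(
            kcrit,
            ["APS", "ISD", "PSG", "FSG"],
            cfg.percentile,
            exclusion=("ISS", cfg.iss_exclusion),
        )
        classes = pd.DataFrame(
            {"robust": robust.mask, "demand": demand.mask, "supply": supply.mask}
        )
        classes.to_csv(out / "k_classes.csv", index=False)
        log.stage("behavioral_classes", len(kcrit), int(demand.mask.sum()), t0=t0,
                  robust=int(robust.mask.sum()), supply=int(supply.mask.sum()))

        # demand-performance composite axis and front (within the demand class)
        t0 = time.perf_counter()
        dcrit = kcrit.subset(demand.mask)
        gain_front = sel.pareto_front(dcrit, ["FDG", "PDG"])
        axis = sel.composite_axis(dcrit, ("FDG", "PDG"), gain_front)
        dcrit2 = dcrit.with_column(axis.name, axis.score, axis.orientation)
        dfront = sel.pareto_front(dcrit2, [axis.name, "ISD"])
        ddesigns = kens_valid.data.loc[demand.mask].reset_index(drop=True)

        def eval_k(designs: pd.DataFrame) -> cr.CriterionTable:
            tab, ok2 = cr.k_criteria_table(model, designs, fluxes=np.full(model.r, cfg.flux))
            if not ok2.all():  # keep row alignment for synthetic candidates
                raise RuntimeError("singular design generated during enrichment")
            ct = tab.with_column(
                axis.name,
                tab.data[axis.criteria].to_numpy() @ _axis_weights(axis, tab),
                axis.orientation,
            )
            return ct

        def _axis_weights(axis, tab):
            w = axis.weights.to_numpy().copy()
            for j, c in enumerate(axis.criteria):
                if tab.orientations[c] == "min":
                    w[j] = -w[j]
            return w

        enriched = sel.enrich_front(
            ddesigns, dcrit2, dfront, eval_k, cfg.n_enrich, seed=cfg.seed_enrich, eps=cfg.eps
        )
        front_designs = pd.concat(
            [ddesigns.iloc[dfront.indices], enriched.enriched_designs], ignore_index=True
        )
        front_designs.to_csv(out / "demand_front_designs.csv", index=False)
        log.stage("demand_front_enriched", len(dfront), len(front_designs),
                  seed=cfg.seed_enrich, t0=t0, eps=cfg.eps)

        # ---- recombination and stability -----------------------------------
        if cfg.run_stability:
            t0 = time.perf_counter()
            ksel_demand = ens.EnsembleTable(
                tag="k", data=kdata.loc[demand.mask].reset_index(drop=True), meta={}
            )
            screen = dyn.stability_screen(model, xsel, ksel_demand, vens)
            screen.to_frame().to_csv(out / "stability_demand.csv", index=False)
            log.stage("stability_demand", len(xsel) * len(ksel_demand) * len(vens),
                      int(screen.stable.sum()), t0=t0,
                      unstable_fraction=screen.unstable_fraction)

            t0 = time.perf_counter()
            ksel_supply = ens.EnsembleTable(
                tag="k", data=kdata.loc[supply.mask].reset_index(drop=True), meta={}
            )
            screen_s = dyn.stability_screen(model, xsel, ksel_supply, vens)
            screen_s.to_frame().to_csv(out / "stability_supply.csv", index=False)
            log.stage("stability_supply", len(xsel) * len(ksel_supply) * len(vens),
                      int(screen_s.stable.sum()), t0=t0,
                      unstable_fraction=screen_s.unstable_fraction)

        # ---- back-mapping ---------------------------------------------------
        if cfg.run_backmap:
            t0 = time.perf_counter()
            planes = bm.train_hyperplanes(kens_valid, kcrit, percentile=cfg.percentile)
            coefs = bm.coefficient_profile(planes)
            coefs.to_csv(out / "hyperplane_coefficients.csv")
            clust = bm.cluster_profiles(coefs)
            (out / "profile_clustering.json").write_text(
                json.dumps({"criterion_order": clust.row_order, "parameter_order": clust.col_order})
            )
            log.stage("backmap_hyperplanes", len(kcrit), len(planes), t0=t0)

            t0 = time.perf_counter()
            pca = bm.pca_front(front_designs)
            scores = pca.transform(front_designs.to_numpy(dtype=float))
            relations = bm.segment_regression(scores)
            synth = bm.synthesize_designs(
                pca,
                relations,
                n=100,
                model=model,
                evaluate=eval_k,
                front_crit=pd.concat(
                    [dcrit2.data.iloc[dfront.indices], enriched.enriched_criteria],
                    ignore_index=True,
                ),
                orientations=dcrit2.orientations,
                eps=max(cfg.eps, 0.02),
            )
            synth.designs.to_csv(out / "synthesized_designs.csv", index=False)
            log.stage("backmap_pca_synthesis", len(front_designs), len(synth.designs),
                      t0=t0, frac_efficient=synth.frac_efficient,
                      variance_share=[round(float(s), 4) for s in pca.variance_share[:4]])

        # ---- optional dynamic simulations ----------------------------------
        if cfg.simulate > 0:
            t0 = time.perf_counter()
            frames = []
            order = np.argsort(-dcrit2.data[axis.name].iloc[dfront.indices].to_numpy())
            picks = dfront.indices[order[: cfg.simulate]]
            for mi, row in enumerate(picks):
                kvec = ddesigns.iloc[row][list(model.free_labels)].to_numpy(dtype=float)
                x_row = xsel.data.iloc[0][list(model.dependent)].to_numpy(dtype=float)
                ref_i = ReferenceState(
                    v0=np.full(model.r, cfg.flux), x_d0=x_row, x_i0=model.default_x_i()
                )
                from .model import rate_constants

                gamma = rate_constants(model, ref_i, kvec)
                try:
                    traj = dyn.simulate_step(model, gamma, ref_i, k=kvec)
                except RuntimeError:
                    continue
                frame = traj.to_frame()
                frame.insert(0, "model", mi)
                frames.append(frame)
            if frames:
                pd.concat(frames, ignore_index=True).to_csv(out / "trajectories.csv", index=False)
            log.stage("simulate_step", len(picks), len(frames), t0=t0)

    except Exception as exc:
        _write_log(out, log, status="failed", error=f"{type(exc).__name__}: {exc}")
        raise

    _write_log(out, log, status="ok")
    return log.reports


def _write_log(out: Path, log: _Log, status: str, error: str | None = None) -> None:
    doc = {
        "status": status,
        "error": error,
        "stages": [asdict(r) for r in log.reports],
    }
    (out / "run_summary.json").write_text(json.dumps(doc, indent=1, default=str))


def file_digest(path: str | Path) -> str:
    """SHA256 of a file — used to assert byte-identical reruns."""
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def make_fixture(kind: str, params: dict | None = None, seed: int = 0, outdir=None):
    """Miniature models and datasets with known ground truth.

    kinds:
      ``chain-n``        a linear chain with ``n`` dependent metabolites
                         (n=1 is the closed-form sensitivity toy);
      ``no-feedback``    the case study with the feedback and backward orders
                         fixed at zero (triangular steady-state system);
      ``planted-signal`` a k-ensemble whose criterion equals one chosen
                         kinetic order plus noise, for hyperplane recovery.
    """
    params = dict(params or {})
    if kind == "chain-n":
        n = int(params.get("n", 1))
        species = [{"name": "x0", "role": "independent", "value": params.get("x0", 1.0)}]
        species += [{"name": f"x{i}", "role": "dependent"} for i in range(1, n + 1)]
        species += [{"name": f"x{n + 1}", "role": "independent", "value": 1.0}]
        reactions = []
        for j in range(1, n + 2):
            sub, prod = f"x{j - 1}", f"x{j}"
            orders = {sub: [0.0, 1.0]}
            stoich = {}
            if j <= n:
                orders[prod] = [-1.0, 0.0]
                stoich[prod] = 1
            if j > 1:
                stoich[sub] = stoich.get(sub, 0) - 1
            if j == n + 1:
                orders[f"x{n + 1}"] = 1.0
            reactions.append({"name": f"v{j}", "stoichiometry": stoich, "orders": orders})
        cfg = {
            "name": f"chain-{n}",
            "species": species,
            "reactions": reactions,
            "roles": {
                "supply": "x0",
                "demand": f"x{n + 1}",
                "product": f"x{n}",
                "demand_reaction": f"v{n + 1}",
            },
        }
        model = build_pathway(cfg)
        result = {"config": cfg, "model": model}
    elif kind == "no-feedback":
        cfg = case_study_config()
        for rx in cfg["reactions"]:
            for sp, val in list(rx["orders"].items()):
                if isinstance(val, list) and val[1] <= 0:  # backward/feedback entries
                    rx["orders"][sp] = 0.0
        model = build_pathway(cfg)
        result = {"config": cfg, "model": model}
    elif kind == "planted-signal":
        model = build_pathway(case_study_config())
        n = int(params.get("n", 2000))
        target = params.get("entry", "f_2,1")
        noise = float(params.get("noise", 0.05))
        kens = ens.sample_k(model, n, seed=seed)
        rng = np.random.default_rng(seed + 1)
        vals = kens.data[target].to_numpy() + noise * rng.standard_normal(n)
        crit = cr.CriterionTable(
            pd.DataFrame({"planted": vals}), {"planted": "max"}, {"entry": target}
        )
        result = {"model": model, "k_ensemble": kens, "criteria": crit, "entry": target}
    else:
        raise ValueError(f"unknown fixture kind {kind!r}")

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        if "config" in result:
            (outdir / f"{kind}.yaml").write_text(yaml.safe_dump(result["config"]))
        if "k_ensemble" in result:
            result["k_ensemble"].to_csv(outdir / "k_ensemble.csv")
        if "criteria" in result:
            result["criteria"].to_csv(outdir / "criteria.csv")
    return result
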