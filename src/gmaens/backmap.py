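"""Trace selected phenotypes back to design space.

Two linear, interpretable tools: per-criterion logistic hyperplanes whose
unit normals rank the kinetic orders by influence (with hierarchical
clustering of the coefficient profiles), and PCA of Pareto-efficient design
sets with segment-wise linear relations between principal components used to
synthesize new near-efficient designs.

Classification features are z-scored per column so coefficient magnitudes
are comparable across parameters; PCA is centered but not variance-scaled
because kinetic orders already share a natural scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.cluster.hierarchy import leaves_list, linkage
from sklearn.linear_model import LogisticRegression

from .criteria import CriterionTable
from .ensembles import EnsembleTable

__all__ = [
    "HyperplaneModel",
    "PCAModel",
    "ProfileClustering",
    "SegmentRelation",
    "SynthesisResult",
    "train_hyperplanes",
    "cluster_profiles",
    "pca_front",
    "segment_regression",
    "synthesize_designs",
]


@dataclass
class HyperplaneModel:
    """Separating hyperplane for one criterion's top-percentile class."""

    criterion: str
    features: list[str]
    coef: np.ndarray  # unit-norm normal, in standardized feature units
    intercept: float
    feature_mean: np.ndarray
    feature_scale: np.ndarray
    percentile: float
    accuracy: float

    def decision(self, X: np.ndarray) -> np.ndarray:
        Z = (np.asarray(X, float) - self.feature_mean) / self.feature_scale
        return Z @ self.coef + self.intercept


@dataclass
class PCAModel:
    """Centered (unscaled) PCA of a design set."""

    features: list[str]
    center: np.ndarray
    components: np.ndarray  # (k, d) orthonormal rows, ordered by variance
    variance_share: np.ndarray

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (np.asarray(X, float) - self.center) @ self.components.T

    def inverse_transform(self, scores: np.ndarray) -> np.ndarray:
        return np.asarray(scores, float) @ self.components + self.center


@dataclass
class ProfileClustering:
    row_order: list
    col_order: list
    row_linkage: np.ndarray
    col_linkage: np.ndarray | None


@dataclass
class SegmentRelation:
    """Per-segment linear relations PC_k = a*PC_1 + b (constants held at the mean)."""

    members: np.ndarray
    relations: dict[int, tuple[float, float]]  # pc index (0-based) -> (slope, intercept)
    constants: dict[int, float]  # pc index -> segment mean
    r2: dict[int, float]
    pc1_range: tuple[float, float]


@dataclass
class SynthesisResult:
    designs: pd.DataFrame
    scores: np.ndarray
    criteria: pd.DataFrame | None = None
    frac_efficient: float | None = None
    segment_of: np.ndarray | None = None


# ---------------------------------------------------------------------------
# logistic hyperplanes
# ---------------------------------------------------------------------------

def train_hyperplanes(
    kens: EnsembleTable | pd.DataFrame,
    crit: CriterionTable,
    criteria=None,
    percentile: float = 50.0,
    C: float = 1.0,
) -> dict[str, HyperplaneModel]:
    """Fit one L2-regularized logistic hyperplane per criterion.

    The positive class is the top ``percentile`` of *performers* for that
    criterion (orientation-aware: low values for minimized criteria).  The
    reported normal has unit Euclidean norm in standardized feature units.
    """
    X = (kens.data if isinstance(kens, EnsembleTable) else kens).to_numpy(dtype=float)
    features = list((kens.data if isinstance(kens, EnsembleTable) else kens).columns)
    if len(X) != len(crit):
        raise ValueError("ensemble and criterion table differ in length")
    mean = X.mean(axis=0)
    scale = X.std(axis=0)
    scale[scale == 0] = 1.0
    Z = (X - mean) / scale
    out: dict[str, HyperplaneModel] = {}
    for c in criteria if criteria is not None else list(crit.data.columns):
        vals = crit.data[c].to_numpy(dtype=float)
        if crit.orientations[c] == "min":
            y = vals <= np.percentile(vals, percentile)
        else:
            y = vals >= np.percentile(vals, 100 - percentile)
        if y.all() or not y.any():
            raise ValueError(f"degenerate class for criterion {c!r}")
        lr = LogisticRegression(C=C, max_iter=2000)  # L2 penalty (default)
        lr.fit(Z, y)
        w = lr.coef_[0]
        norm = np.linalg.norm(w)
        out[c] = HyperplaneModel(
            criterion=c,
            features=features,
            coef=w / norm if norm > 0 else w,
            intercept=float(lr.intercept_[0] / norm) if norm > 0 else float(lr.intercept_[0]),
            feature_mean=mean,
            feature_scale=scale,
            percentile=percentile,
            accuracy=float(lr.score(Z, y)),
        )
    return out


def coefficient_profile(models: dict[str, HyperplaneModel]) -> pd.DataFrame:
    """Criterion x parameter matrix of unit-normal coefficients."""
    rows = {c: m.coef for c, m in models.items()}
    any_model = next(iter(models.values()))
    return pd.DataFrame(rows, index=any_model.features).T


def cluster_profiles(coefs: pd.DataFrame) -> ProfileClustering:
    """Average-linkage (Euclidean) clustering of criterion and parameter profiles."""
    if len(coefs) < 2:
        raise ValueError("need at least 2 criterion profiles to cluster")
    row_link = linkage(coefs.to_numpy(), method="average", metric="euclidean")
    col_link = None
    col_order = list(coefs.columns)
    if coefs.shape[1] >= 2:
        col_link = linkage(coefs.to_numpy().T, method="average", metric="euclidean")
        col_order = [coefs.columns[i] for i in leaves_list(col_link)]
    row_order = [coefs.index[i] for i in leaves_list(row_link)]
    return ProfileClustering(row_order, col_order, row_link, col_link)


# ---------------------------------------------------------------------------
# PCA of fronts and segment synthesis
# ---------------------------------------------------------------------------

def pca_front(designs: pd.DataFrame) -> PCAModel:
    """Centered PCA of the designs of a (possibly enriched) Pareto front."""
    X = designs.to_numpy(dtype=float)
    if len(X) < 2:
        raise ValueError("need at least 2 front members for PCA")
    center = X.mean(axis=0)
    Xc = X - center
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    var = s**2
    share = var / var.sum() if var.sum() > 0 else var
    return PCAModel(
        features=list(designs.columns),
        center=center,
        components=vt,
        variance_share=share,
    )


def _two_piece_breakpoint(scores: np.ndarray) -> int:
    """Exhaustive two-piece least-squares scan along PC1 order.

    Returns the split position b (segment 1 = points[:b]) minimizing the total
    SSE of per-segment OLS fits of every other PC on PC1.
    """
    order = np.argsort(scores[:, 0])
    S = scores[order]
    n, k = S.shape

    def sse(seg):
        if len(seg) < 3:
            return np.inf
        x = seg[:, 0]
        X = np.stack([x, np.ones_like(x)], axis=1)
        coef, res, *_ = np.linalg.lstsq(X, seg[:, 1:], rcond=None)
        pred = X @ coef
        return float(((seg[:, 1:] - pred) ** 2).sum())

    best, best_b = np.inf, n // 2
    for b in range(3, n - 2):
        tot = sse(S[:b]) + sse(S[b:])
        if tot < best:
            best, best_b = tot, b
    return best_b


def segment_regression(
    scores: np.ndarray,
    segments=None,
    r2_threshold: float = 0.5,
) -> list[SegmentRelation]:
    """Per-segment OLS of each principal component on PC1.

    ``segments`` assigns each front member a segment id; if omitted, the
    front is split in two by an exhaustive two-piece least-squares scan along
    PC1.  A PC whose fit has R^2 below ``r2_threshold`` is held constant at
    the segment mean instead of varying with PC1.
    """
    scores = np.asarray(scores, float)
    n, k = scores.shape
    if segments is None:
        order = np.argsort(scores[:, 0])
        b = _two_piece_breakpoint(scores)
        seg_ids = np.zeros(n, dtype=int)
        seg_ids[order[b:]] = 1
    else:
        seg_ids = np.asarray(segments, dtype=int)
    out = []
    for sid in np.unique(seg_ids):
        members = np.where(seg_ids == sid)[0]
        if len(members) < 3:
            raise ValueError(f"segment {sid} has fewer than 3 members")
        S = scores[members]
        x = S[:, 0]
        X = np.stack([x, np.ones_like(x)], axis=1)
        relations, constants, r2s = {}, {}, {}
        for j in range(1, k):
            y = S[:, j]
            coef, *_ = np.linalg.lstsq(X, y, rcond=None)
            pred = X @ coef
            ss_res = float(((y - pred) ** 2).sum())
            ss_tot = float(((y - y.mean()) ** 2).sum())
            r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
            r2s[j] = r2
            if r2 >= r2_threshold:
                relations[j] = (float(coef[0]), float(coef[1]))
            else:
                constants[j] = float(y.mean())
        out.append(
            SegmentRelation(
                members=members,
                relations=relations,
                constants=constants,
                r2=r2s,
                pc1_range=(float(x.min()), float(x.max())),
            )
        )
    return out


def synthesize_designs(
    pca: PCAModel,
    relations: list[SegmentRelation],
    pc1_range=None,
    n: int = 100,
    model=None,
    evaluate=None,
    front_crit: pd.DataFrame | None = None,
    orientations: dict[str, str] | None = None,
    eps: float = 0.02,
) -> SynthesisResult:
    """Generate designs along the per-segment parametric PC relations.

    For each segment, PC1 runs on a grid over ``pc1_range`` (default: the
    segment's own range), dependent PCs follow their linear relations,
    constant PCs sit at the segment mean and all remaining PCs at the center.
    Scores are mapped back to kinetic orders, optionally clipped to the
    model's sampling intervals, and re-evaluated through ``evaluate``; if the
    original front's criteria are supplied the fraction of synthesized points
    that are epsilon-efficient against that front is reported.
    """
    if not relations:
        raise ValueError("no segment relations supplied")
    k = pca.components.shape[0]
    all_scores, seg_of = [], []
    for si, rel in enumerate(relations):
        lo, hi = pc1_range if pc1_range is not None else rel.pc1_range
        pc1 = np.linspace(lo, hi, n)
        S = np.zeros((n, k))
        S[:, 0] = pc1
        for j, (a, b) in rel.relations.items():
            S[:, j] = a * pc1 + b
        for j, m in rel.constants.items():
            S[:, j] = m
        all_scores.append(S)
        seg_of.append(np.full(n, si))
    scores = np.vstack(all_scores)
    X = pca.inverse_transform(scores)
    designs = pd.DataFrame(X, columns=pca.features)
    if model is not None:
        for (rxn, sp) in model.free_entries:
            lab = model.entry_label(rxn, sp)
            lo, hi = model.orders_free[(rxn, sp)]
            designs[lab] = designs[lab].clip(lo, hi)
    crit_df, frac = None, None
    if evaluate is not None:
        ct = evaluate(designs)
        crit_df = ct.data
        if front_crit is not None and orientations is not None:
            cols = list(front_crit.columns)
            A = front_crit.to_numpy(dtype=float).copy()
            B = crit_df[cols].to_numpy(dtype=float).copy()
            for j, c in enumerate(cols):
                if orientations[c] == "max":
                    A[:, j] = -A[:, j]
                    B[:, j] = -B[:, j]
            both = np.vstack([A, B])
            lo_, hi_ = both.min(axis=0), both.max(axis=0)
            span = np.where(hi_ > lo_, hi_ - lo_, 1.0)
            An, Bn = (A - lo_) / span, (B - lo_) / span
            eff = np.ones(len(Bn), dtype=bool)
            for i in range(len(Bn)):
                better = (An <= Bn[i] - eps).all(axis=1) & (An < Bn[i] - eps).any(axis=1)
                if better.any():
                    eff[i] = False
            frac = float(eff.mean())
    return SynthesisResult(
        designs=designs,
        scores=scores,
        criteria=crit_df,
        frac_efficient=frac,
        segment_of=np.concatenate(seg_of),
    )
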