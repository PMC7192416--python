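"""Design selection in criterion space.

Two complementary strategies: *behavioral classes* keep every design that
performs at or better than a percentile cutoff for each criterion in a set,
and *(epsilon-)Pareto fronts* keep the non-dominated designs under
simultaneous optimization.  Fronts can be enriched by convex combinations of
nearest-neighbor efficient designs, and a two-criterion front can be
collapsed into a composite performance axis orthogonal to its fitted line.

epsilon-dominance is additive in min-max normalized criterion units: each
criterion is scaled to [0,1] over the current table so a single epsilon is
meaningful across criteria, and a design is epsilon-dominated if another is
better by more than epsilon in every criterion (epsilon = 0 recovers exact
Pareto dominance).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .criteria import CriterionTable

__all__ = [
    "ParetoResult",
    "ClassMask",
    "CompositeAxis",
    "pareto_front",
    "epsilon_front",
    "enrich_front",
    "behavioral_class",
    "composite_axis",
]


@dataclass
class ParetoResult:
    """Efficient-sample indices plus any convex-combination enrichment."""

    indices: np.ndarray
    criteria: list[str]
    eps: float
    orientations: dict[str, str]
    duplicate_of: dict[int, int] = field(default_factory=dict)
    enriched_designs: pd.DataFrame | None = None
    enriched_criteria: pd.DataFrame | None = None

    def __len__(self) -> int:
        return len(self.indices)


@dataclass
class ClassMask:
    """Boolean class membership with the thresholds that defined it."""

    mask: np.ndarray
    criteria: list[str]
    percentile: float
    thresholds: dict[str, float]
    exclusion: tuple[str, float] | None = None

    def __len__(self) -> int:
        return len(self.mask)

    @property
    def indices(self) -> np.ndarray:
        return np.where(self.mask)[0]


@dataclass
class CompositeAxis:
    """A linear combination of two criteria orthogonal to the front's fitted line."""

    name: str
    criteria: list[str]
    weights: pd.Series  # over orientation-aligned (larger-is-better) criteria
    score: np.ndarray
    orientation: str = "max"


# ---------------------------------------------------------------------------
# dominance
# ---------------------------------------------------------------------------

def _non_dominated_mask(C: np.ndarray) -> np.ndarray:
    """Exact non-dominated mask of a minimization matrix (first duplicate kept)."""
    n = len(C)
    order = np.lexsort(C.T[::-1])  # sort by col 0, ties broken by later cols
    Cs = C[order]
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        if not keep[i]:
            continue
        ci = Cs[i]
        later = Cs[i + 1 :]
        dom = (ci <= later).all(axis=1)  # sorted: ci[0] <= later[0] always
        strict = (ci < later).any(axis=1)
        dup = dom & ~strict  # exact duplicates: keep only the first occurrence
        keep[i + 1 :] &= ~(dom & strict)
        keep[i + 1 :] &= ~dup
    mask = np.zeros(n, dtype=bool)
    mask[order[keep]] = True
    return mask


def _duplicates(C: np.ndarray, mask: np.ndarray) -> dict[int, int]:
    """Map a dropped exact-duplicate row to the front member it duplicates."""
    out: dict[int, int] = {}
    front = np.where(mask)[0]
    view = {tuple(C[i]): i for i in front}
    for i in np.where(~mask)[0]:
        j = view.get(tuple(C[i]))
        if j is not None:
            out[i] = j
    return out


def pareto_front(crit: CriterionTable, criteria=None) -> ParetoResult:
    """Exact non-dominated set under the selected criteria (orientation-aware)."""
    if len(crit) == 0:
        raise ValueError("empty criterion table")
    cols = list(criteria) if criteria is not None else list(crit.data.columns)
    C = crit.aligned(cols).to_numpy(dtype=float)
    mask = _non_dominated_mask(C)
    return ParetoResult(
        indices=np.where(mask)[0],
        criteria=cols,
        eps=0.0,
        orientations={c: crit.orientations[c] for c in cols},
        duplicate_of=_duplicates(C, mask),
    )


def _normalize(C: np.ndarray) -> np.ndarray:
    lo, hi = C.min(axis=0), C.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    return (C - lo) / span


def _eps_efficient_mask(Cn: np.ndarray, eps: float) -> np.ndarray:
    """Mask of samples not epsilon-dominated by any other (normalized units)."""
    if eps == 0.0:
        return _non_dominated_mask(Cn)
    n = len(Cn)
    mask = np.ones(n, dtype=bool)
    for i in range(n):
        better = (Cn <= Cn[i] - eps).all(axis=1) & (Cn < Cn[i] - eps).any(axis=1)
        if better.any():
            mask[i] = False
    return mask


def epsilon_front(crit: CriterionTable, criteria=None, eps: float = 0.0) -> ParetoResult:
    """epsilon-relaxed Pareto front; eps=0 is exactly :func:`pareto_front`."""
    if eps < 0:
        raise ValueError("eps must be non-negative")
    if eps == 0.0:
        return pareto_front(crit, criteria)
    cols = list(criteria) if criteria is not None else list(crit.data.columns)
    C = crit.aligned(cols).to_numpy(dtype=float)
    mask = _eps_efficient_mask(_normalize(C), eps)
    return ParetoResult(
        indices=np.where(mask)[0],
        criteria=cols,
        eps=eps,
        orientations={c: crit.orientations[c] for c in cols},
    )


# ---------------------------------------------------------------------------
# enrichment
# ---------------------------------------------------------------------------

def enrich_front(
    designs: pd.DataFrame,
    crit: CriterionTable,
    front: ParetoResult,
    evaluate,
    n_new: int,
    seed: int | None = None,
    eps: float = 0.05,
) -> ParetoResult:
    """Enrich a front with convex combinations of nearest-neighbor efficient designs.

    For each candidate a random front member ``a`` is paired with its nearest
    neighbor ``b`` in (normalized) criterion space and a design
    ``lam*d_a + (1-lam)*d_b`` is generated, ``lam ~ U(0,1)``.  Candidates are
    re-evaluated with ``evaluate`` (a callable mapping a design DataFrame to a
    :class:`CriterionTable`) and kept only if epsilon-efficient against the
    combined original-plus-candidate set.  Retained points are flagged as
    synthetic via the returned ``enriched_*`` frames.
    """
    if len(front) < 2:
        raise ValueError("front must have at least 2 members to combine")
    rng = np.random.default_rng(seed)
    cols = front.criteria
    C = crit.aligned(cols).to_numpy(dtype=float)
    Cn = _normalize(C)
    F = front.indices
    # nearest neighbor of each front member, in criterion space
    P = Cn[F]
    d2 = ((P[:, None, :] - P[None, :, :]) ** 2).sum(-1)
    np.fill_diagonal(d2, np.inf)
    nn = d2.argmin(axis=1)
    a = rng.integers(0, len(F), size=n_new)
    lam = rng.uniform(0.0, 1.0, size=n_new)
    Da = designs.iloc[F[a]].to_numpy(dtype=float)
    Db = designs.iloc[F[nn[a]]].to_numpy(dtype=float)
    cand = pd.DataFrame(lam[:, None] * Da + (1 - lam[:, None]) * Db, columns=designs.columns)
    cand_crit = evaluate(cand)
    Cc = cand_crit.aligned(cols).to_numpy(dtype=float)
    # epsilon-efficiency of candidates against front + candidates jointly
    combined = np.vstack([C[F], Cc])
    lo, hi = combined.min(axis=0), combined.max(axis=0)
    span = np.where(hi > lo, hi - lo, 1.0)
    Zn = (combined - lo) / span
    keep = np.ones(len(Cc), dtype=bool)
    for i in range(len(Cc)):
        zi = Zn[len(F) + i]
        better = (Zn <= zi - eps).all(axis=1) & (Zn < zi - eps).any(axis=1)
        if better.any():
            keep[i] = False
    return ParetoResult(
        indices=front.indices,
        criteria=cols,
        eps=eps,
        orientations=front.orientations,
        duplicate_of=dict(front.duplicate_of),
        enriched_designs=cand.loc[keep].reset_index(drop=True),
        enriched_criteria=cand_crit.data.loc[keep].reset_index(drop=True),
    )


# ---------------------------------------------------------------------------
# behavioral classes
# ---------------------------------------------------------------------------

def behavioral_class(
    crit: CriterionTable,
    criteria,
    percentile: float = 50.0,
    exclusion: tuple[str, float] | None = None,
) -> ClassMask:
    """Percentile-cutoff class: at-or-better than the cutoff for every criterion.

    ``percentile`` is the fraction of the ensemble admitted per criterion
    (50 keeps the better half).  ``exclusion`` = (criterion, worst_fraction)
    removes only the stated worst fraction for that criterion instead of half.
    """
    if not (0 < percentile < 100):
        raise ValueError("percentile must be in (0, 100)")
    for c in list(criteria) + ([exclusion[0]] if exclusion else []):
        if c not in crit.data.columns:
            raise KeyError(f"criterion {c!r} not in table")
    mask = np.ones(len(crit), dtype=bool)
    thresholds: dict[str, float] = {}
    for c in criteria:
        vals = crit.data[c].to_numpy(dtype=float)
        if crit.orientations[c] == "min":
            cut = np.percentile(vals, percentile)
            mask &= vals <= cut
        else:
            cut = np.percentile(vals, 100 - percentile)
            mask &= vals >= cut
        thresholds[c] = float(cut)
    if exclusion is not None:
        c, frac = exclusion
        if not (0 <= frac <= 1):
            raise ValueError("exclusion fraction must be in [0, 1]")
        vals = crit.data[c].to_numpy(dtype=float)
        if crit.orientations[c] == "min":
            cut = np.percentile(vals, 100 * (1 - frac))
            mask &= vals <= cut
        else:
            cut = np.percentile(vals, 100 * frac)
            mask &= vals >= cut
        thresholds[c] = float(cut)
    return ClassMask(mask, list(criteria), percentile, thresholds, exclusion)


# ---------------------------------------------------------------------------
# composite axis
# ---------------------------------------------------------------------------

def composite_axis(
    crit: CriterionTable,
    pair,
    front: ParetoResult,
    name: str = "demand_performance",
) -> CompositeAxis:
    """Collapse a two-criterion tradeoff into one axis orthogonal to the front.

    A total-least-squares line is fitted to the front members in the
    orientation-aligned (larger-is-better) plane; the axis weights are the
    unit normal to that line, with the sign chosen so the utopian corner
    (both criteria at their best) scores highest.
    """
    c1, c2 = pair
    # larger-is-better alignment: negate minimize criteria
    A = crit.data[[c1, c2]].to_numpy(dtype=float).copy()
    for j, c in enumerate((c1, c2)):
        if crit.orientations[c] == "min":
            A[:, j] = -A[:, j]
    P = A[front.indices]
    center = P.mean(axis=0)
    Pc = P - center
    if np.allclose(Pc, 0):
        raise ValueError("degenerate front: all members identical")
    _, _, vt = np.linalg.svd(Pc, full_matrices=False)
    normal = vt[-1]
    utopia = A.max(axis=0)
    if normal @ (utopia - center) < 0:
        normal = -normal
    score = A @ normal
    return CompositeAxis(
        name=name,
        criteria=[c1, c2],
        weights=pd.Series(normal, index=[c1, c2]),
        score=score,
    )
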