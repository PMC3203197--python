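"""Expression-distance scoring and inter-atlas cell correspondence.

The expression distance between two cells is the squared Euclidean
distance between their normalized expression profiles (sum over genes and
timepoints of squared differences of means).  Being a sum of squares it is
additive across genes, which makes per-gene contributions directly
interpretable.

Correspondence is found by a local search: for each query cell, the k
spatially nearest target cells (default 30, positions scaled to unit egg
length) are candidates, and the candidate with the smallest expression
distance is the best match.  Matching is deliberately not one-to-one —
several query cells may share a best target, which is required when the
two atlases contain different numbers of cells.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .atlas import (
    Atlas,
    ExpressionProfile,
    GeneSubset,
    profile_matrix,
    shared_entry_mask,
)
from .errors import IntegrityError
from .geometry import align_atlases

#: Below this expression distance two profiles are treated as identical
#: when computing inverse-distance weights.
ZERO_DISTANCE_EPS = 1e-12


@dataclass
class MatchConfig:
    """Local-search parameters: k spatial candidates, top-m list for
    displacement/tallies, the gene subset scored, and which cohort's
    nuclear positions anchor the spatial search (default: the last)."""

    k: int = 30
    m: int = 10
    genes: GeneSubset | None = None
    cohort: int | None = None

    def __post_init__(self):
        if not 1 <= self.m <= self.k:
            raise ValueError(f"need 1 <= m <= k; got m={self.m}, k={self.k}")

    def resolve_cohort(self, atlas: Atlas) -> int:
        return self.cohort if self.cohort is not None else atlas.T


@dataclass
class MatchResult:
    """Correspondence for one query cell."""

    query_id: int
    candidate_ids: np.ndarray     # (k,) sorted by ascending expression distance
    candidate_scores: np.ndarray  # (k,) ascending
    best_id: int
    best_score: float
    nearest_id: int               # spatially nearest candidate
    nearest_score: float


@dataclass
class Matches:
    """Array-backed collection of per-query-cell match results."""

    query_ids: np.ndarray       # (nq,)
    candidate_ids: np.ndarray   # (nq, k) sorted by expression distance
    candidate_scores: np.ndarray
    best_ids: np.ndarray
    best_scores: np.ndarray
    nearest_ids: np.ndarray
    nearest_scores: np.ndarray
    config: MatchConfig = field(repr=False, default=None)

    def __len__(self) -> int:
        return len(self.query_ids)

    def __getitem__(self, i: int) -> MatchResult:
        return MatchResult(
            query_id=int(self.query_ids[i]),
            candidate_ids=self.candidate_ids[i],
            candidate_scores=self.candidate_scores[i],
            best_id=int(self.best_ids[i]),
            best_score=float(self.best_scores[i]),
            nearest_id=int(self.nearest_ids[i]),
            nearest_score=float(self.nearest_scores[i]),
        )

    def __iter__(self):
        return (self[i] for i in range(len(self)))

    def pairs(self) -> np.ndarray:
        """(nq, 2) array of (query_id, best_id)."""
        return np.column_stack([self.query_ids, self.best_ids])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "query_id": self.query_ids,
            "best_id": self.best_ids,
            "best_score": self.best_scores,
            "nearest_id": self.nearest_ids,
            "nearest_score": self.nearest_scores,
        })


# ------------------------------------------------------------------- scoring

def expression_distance(a: ExpressionProfile, b: ExpressionProfile,
                        gs: GeneSubset | None = None) -> float:
    """Squared Euclidean distance between two expression profiles over the
    subset's measured entries.  Symmetric, non-negative, zero iff equal."""
    table = distance_decomposition(a, b, gs)
    return float(table["score"].sum())


def distance_decomposition(a: ExpressionProfile, b: ExpressionProfile,
                           gs: GeneSubset | None = None) -> pd.DataFrame:
    """Per-gene contributions to the expression distance; the column sum
    equals :func:`expression_distance` exactly (additivity)."""
    if a.genes != b.genes:
        raise IntegrityError("profiles carry different gene lists")
    genes = gs.genes if gs is not None else a.genes
    unknown = [g for g in genes if g not in a.genes]
    if unknown:
        raise KeyError(f"genes {unknown} not in profile; available: {a.genes}")
    rows = []
    T = a.values.shape[1]
    for g in genes:
        gi = a.genes.index(g)
        keep = ~(a.missing[gi] | b.missing[gi])
        if gs is not None and g in gs.timepoints:
            sel = np.zeros(T, dtype=bool)
            sel[[t - 1 for t in gs.timepoints[g]]] = True
            keep &= sel
        diff = a.values[gi, keep] - b.values[gi, keep]
        rows.append({"gene": g, "score": float(np.sum(diff**2))})
    return pd.DataFrame(rows)


# ------------------------------------------------------------ spatial search

def spatial_knn(query: Atlas, target: Atlas, cfg: MatchConfig) -> np.ndarray:
    """(nq, k) target cell ids, per query cell, ordered by ascending 3D
    distance in the unit-egg-length aligned frame; ties broken by id."""
    if cfg.k > target.n_cells:
        raise ValueError(
            f"k={cfg.k} exceeds target atlas size {target.n_cells}"
        )
    t = cfg.resolve_cohort(query)
    qpos, tpos = align_atlases(query, target, t)
    tree = cKDTree(tpos)
    dist, idx = tree.query(qpos, k=cfg.k)
    if cfg.k == 1:
        dist, idx = dist[:, None], idx[:, None]
    # deterministic ordering: ascending distance, then ascending cell id
    order = np.lexsort((idx, dist), axis=1)
    return np.take_along_axis(idx, order, axis=1)


def match_all(query: Atlas, target: Atlas, cfg: MatchConfig | None = None) -> Matches:
    """Local-search correspondence for every query cell.

    Both atlases must be normalized.  Per query cell the expression
    distance to each of the k spatial candidates is computed; the best
    match is the argmin (ties resolved to the lowest cell id) and the
    spatially nearest candidate's score is recorded separately as the
    no-search baseline.
    """
    cfg = cfg or MatchConfig()
    mask = shared_entry_mask(query, target, cfg.genes)
    Xq, _ = profile_matrix(query, entry_mask=mask)
    Xt, _ = profile_matrix(target, entry_mask=mask)

    cand = spatial_knn(query, target, cfg)          # (nq, k) spatial order
    diffs = Xt[cand] - Xq[:, None, :]               # (nq, k, D)
    scores = np.einsum("ijk,ijk->ij", diffs, diffs)

    nearest_ids = cand[:, 0]
    nearest_scores = scores[np.arange(len(cand)), 0]

    # sort candidates by (score, id) for deterministic best and top-m lists
    order = np.lexsort((cand, scores), axis=1)
    cand_sorted = np.take_along_axis(cand, order, axis=1)
    scores_sorted = np.take_along_axis(scores, order, axis=1)

    return Matches(
        query_ids=np.arange(query.n_cells),
        candidate_ids=cand_sorted,
        candidate_scores=scores_sorted,
        best_ids=cand_sorted[:, 0],
        best_scores=scores_sorted[:, 0],
        nearest_ids=nearest_ids,
        nearest_scores=nearest_scores,
        config=cfg,
    )


# -------------------------------------------------------------- displacement

def displacement_field(matches: Matches, query: Atlas, target: Atlas,
                       cfg: MatchConfig | None = None) -> pd.DataFrame:
    """Displacement from each query cell to the inverse-distance-weighted
    average position of its top-m matches (weights 1/d; candidates at
    d < 1e-12 get equal weight and the rest zero).

    Positions are in the unit-egg-length aligned frame; lengths are
    reported both scaled and in µm of the query embryo.
    """
    cfg = cfg or matches.config or MatchConfig()
    t = cfg.resolve_cohort(query)
    qpos, tpos = align_atlases(query, target, t)

    top_ids = matches.candidate_ids[:, :cfg.m]
    top_d = matches.candidate_scores[:, :cfg.m]

    zero = top_d < ZERO_DISTANCE_EPS
    any_zero = zero.any(axis=1)
    with np.errstate(divide="ignore"):
        w = 1.0 / top_d
    w[any_zero] = zero[any_zero].astype(float)
    w = w / w.sum(axis=1, keepdims=True)

    endpoint = np.einsum("ij,ijk->ik", w, tpos[top_ids])
    disp = endpoint - qpos
    length = np.linalg.norm(disp, axis=1)
    return pd.DataFrame({
        "query_id": matches.query_ids,
        "disp_x": disp[:, 0],
        "disp_y": disp[:, 1],
        "disp_z": disp[:, 2],
        "disp_len_scaled": length,
        "disp_len_um": length * query.egg_length,
    })


def match_tally(matches: Matches, target: Atlas,
                cfg: MatchConfig | None = None) -> tuple[np.ndarray, float]:
    """Per-target-cell count of appearances in query cells' top-m lists,
    and the fraction of target cells matched at least once."""
    cfg = cfg or matches.config or MatchConfig()
    top_ids = matches.candidate_ids[:, :cfg.m]
    counts = np.bincount(top_ids.ravel(), minlength=target.n_cells)
    return counts, float(np.mean(counts >= 1))


def score_summary(matches: Matches, n_bins: int = 40) -> pd.DataFrame:
    """Mean/median of nearest vs best scores plus a histogram of the square
    root of the scores (the root separates values near zero in display)."""
    rows = []
    hi = max(np.sqrt(matches.nearest_scores.max()), 1e-9)
    edges = np.linspace(0.0, hi, n_bins + 1)
    for name, s in (("nearest", matches.nearest_scores), ("best", matches.best_scores)):
        hist, _ = np.histogram(np.sqrt(s), bins=edges)
        rows.append({
            "mapping": name,
            "mean": float(np.mean(s)),
            "median": float(np.median(s)),
            "hist_edges": ";".join(f"{e:.6g}" for e in edges),
            "hist_counts": ";".join(str(int(h)) for h in hist),
        })
    return pd.DataFrame(rows)
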