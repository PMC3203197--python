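"""Expression neighborhoods and cell-type proportion analysis.

The expression neighborhood N_i of a cell i is the connected component of
the surface neighbor graph, restricted to cells whose expression distance
to i is strictly below a threshold t, that contains i.  Its size measures
the local abundance of cells with i's expression profile (a proxy for cell
type at this stage).  Between species, fluorescence scales are not
comparable, so the target atlas's threshold is chosen adaptively: the mean
log size ratio R over matched cell pairs must equal the log ratio of total
nuclei counts, i.e. proportion changes are displayed relative to a null of
uniform scaling between the species.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atlas import Atlas, GeneSubset, profile_matrix, shared_entry_mask
from .errors import CalibrationError
from .matching import Matches


@dataclass
class Neighborhood:
    """Connected set of surface-adjacent expression neighbors of one cell."""

    cell_id: int
    threshold: float
    members: np.ndarray  # sorted cell ids; always contains cell_id

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass
class ExpansionRecord:
    """Neighborhood sizes and log ratio for one matched cell pair."""

    query_id: int
    target_id: int
    size_query: int
    size_target: int

    @property
    def R(self) -> float:
        return float(np.log(self.size_target / self.size_query))


@dataclass
class CalibrationResult:
    t_query: float
    t_target: float
    mean_R: float
    target_R: float
    iterations: int
    curve: list  # (t_target, mean_R) evaluations


# ------------------------------------------------------------ neighborhoods

def _component_of(i: int, in_set: np.ndarray, nbr_lists: list[np.ndarray]) -> list[int]:
    """BFS over the neighbor graph restricted to ``in_set`` membership."""
    visited = {i}
    queue = deque([i])
    while queue:
        u = queue.popleft()
        for v in nbr_lists[u]:
            v = int(v)
            if in_set[v] and v not in visited:
                visited.add(v)
                queue.append(v)
    return sorted(visited)


def expression_neighborhood(atlas: Atlas, i: int, t: float,
                            gs: GeneSubset | None = None) -> Neighborhood:
    """The focal cell's expression neighborhood at threshold ``t``:
    cells with d_ij < t (strict), connected to i on the surface graph."""
    if t <= 0:
        raise ValueError("threshold must be positive")
    X, _ = profile_matrix(atlas, gs)
    diffs = X - X[i]
    d = np.einsum("ij,ij->i", diffs, diffs)
    in_set = d < t
    in_set[i] = True  # d_ii = 0 < t always, but guard against rounding
    members = _component_of(i, in_set, atlas.neighbor_lists())
    return Neighborhood(cell_id=i, threshold=t, members=np.array(members))


def neighborhood_size_map(atlas: Atlas, t: float,
                          gs: GeneSubset | None = None) -> np.ndarray:
    """|N_i| for every focal cell i (monotone non-decreasing in t)."""
    X, _ = profile_matrix(atlas, gs)
    nbr_lists = atlas.neighbor_lists()
    return _size_map(X, np.arange(atlas.n_cells), t, nbr_lists)


def _size_map(X_all: np.ndarray, focal_ids: np.ndarray,
              t: float, nbr_lists: list[np.ndarray],
              block: int = 256) -> np.ndarray:
    """Neighborhood sizes for the focal cells ``focal_ids`` (rows of the
    atlas profile matrix ``X_all``), with blocked distance computation."""
    if t <= 0:
        raise ValueError("threshold must be positive")
    sizes = np.empty(len(focal_ids), dtype=np.int64)
    sq_all = np.einsum("ij,ij->i", X_all, X_all)
    for start in range(0, len(focal_ids), block):
        ids = focal_ids[start:start + block]
        Xf = X_all[ids]
        d = (
            sq_all[None, :]
            - 2.0 * Xf @ X_all.T
            + np.einsum("ij,ij->i", Xf, Xf)[:, None]
        )
        np.clip(d, 0.0, None, out=d)
        in_set = d < t
        for row, i in enumerate(ids):
            mask = in_set[row]
            mask[i] = True
            sizes[start + row] = len(_component_of(int(i), mask, nbr_lists))
    return sizes


# ---------------------------------------------------------------- calibration

def calibrate_threshold(
    query: Atlas,
    target: Atlas,
    matches: Matches,
    t_query: float,
    gs: GeneSubset | None = None,
    tol: float = 1e-3,
    max_iter: int = 80,
) -> CalibrationResult:
    """Adaptive threshold for the target atlas.

    Finds t_target such that the mean over matched pairs of
    R = ln(|N_j(t_target)| / |N_i(t_query)|) equals
    ln(n_target / n_query) within ``tol``, by bracketing and bisection on
    the empirically monotone mean-R curve; falls back to a fine grid scan
    between the bracket endpoints if bisection stalls on a plateau.
    """
    if t_query <= 0:
        raise ValueError("t_query must be positive")
    mask = shared_entry_mask(query, target, gs)
    Xq, _ = profile_matrix(query, entry_mask=mask)
    Xt, _ = profile_matrix(target, entry_mask=mask)
    nbr_q = query.neighbor_lists()
    nbr_t = target.neighbor_lists()

    qids = matches.query_ids
    jids = matches.best_ids
    log_sizes_q = np.log(_size_map(Xq, qids, t_query, nbr_q))
    uniq_j, inverse = np.unique(jids, return_inverse=True)

    target_R = float(np.log(target.n_cells / query.n_cells))
    curve: list[tuple[float, float]] = []
    evals = [0]

    def mean_R(t_t: float) -> float:
        evals[0] += 1
        sizes_j = _size_map(Xt, uniq_j, t_t, nbr_t)
        value = float(np.mean(np.log(sizes_j[inverse]) - log_sizes_q))
        curve.append((t_t, value))
        return value

    lo, hi = t_query / 100.0, t_query * 100.0
    g_lo = mean_R(lo) - target_R
    if abs(g_lo) <= tol:
        return CalibrationResult(t_query, lo, g_lo + target_R, target_R, evals[0], curve)
    g_hi = mean_R(hi) - target_R
    if abs(g_hi) <= tol:
        return CalibrationResult(t_query, hi, g_hi + target_R, target_R, evals[0], curve)
    if g_lo * g_hi > 0:
        raise CalibrationError(
            f"cannot bracket target mean R {target_R:.4g} within "
            f"[{lo:.4g}, {hi:.4g}]: endpoints give {g_lo + target_R:.4g}, "
            f"{g_hi + target_R:.4g}", curve=curve,
        )

    best_t, best_g = (lo, g_lo) if abs(g_lo) < abs(g_hi) else (hi, g_hi)
    for _ in range(max_iter):
        mid = np.sqrt(lo * hi)  # thresholds live on a ratio scale
        g_mid = mean_R(mid) - target_R
        if abs(g_mid) < abs(best_g):
            best_t, best_g = mid, g_mid
        if abs(g_mid) <= tol:
            return CalibrationResult(
                t_query, mid, g_mid + target_R, target_R, evals[0], curve
            )
        if g_lo * g_mid <= 0:
            hi, g_hi = mid, g_mid
        else:
            lo, g_lo = mid, g_mid
        if hi / lo < 1.0 + 1e-12:
            break

    # plateau of the (stepwise) mean-R curve: scan the remaining bracket
    for t_t in np.geomspace(lo, hi, 50):
        g = mean_R(t_t) - target_R
        if abs(g) < abs(best_g):
            best_t, best_g = t_t, g
        if abs(g) <= tol:
            break
    if abs(best_g) > tol:
        raise CalibrationError(
            f"bisection and grid scan did not reach |mean R - {target_R:.4g}| "
            f"<= {tol:g}; best residual {best_g:.4g} at t={best_t:.4g}",
            curve=curve,
        )
    return CalibrationResult(t_query, float(best_t), best_g + target_R,
                             target_R, evals[0], curve)


# -------------------------------------------------------------- expansion map

def expansion_map(
    query: Atlas,
    target: Atlas,
    matches: Matches,
    t_query: float,
    t_target: float,
    gs: GeneSubset | None = None,
) -> tuple[list[ExpansionRecord], dict]:
    """Per-pair neighborhood log size ratios at the calibrated thresholds.

    Returns the records and a summary with min/max R and the fraction of
    pairs beyond a 5-fold change in either direction.
    """
    mask = shared_entry_mask(query, target, gs)
    Xq, _ = profile_matrix(query, entry_mask=mask)
    Xt, _ = profile_matrix(target, entry_mask=mask)
    qids, jids = matches.query_ids, matches.best_ids
    sizes_q = _size_map(Xq, qids, t_query, query.neighbor_lists())
    uniq_j, inverse = np.unique(jids, return_inverse=True)
    sizes_j = _size_map(Xt, uniq_j, t_target, target.neighbor_lists())[inverse]
    records = [
        ExpansionRecord(int(q), int(j), int(sq), int(sj))
        for q, j, sq, sj in zip(qids, jids, sizes_q, sizes_j)
    ]
    R = np.log(sizes_j / sizes_q)
    summary = {
        "min_R": float(R.min()),
        "max_R": float(R.max()),
        "mean_R": float(R.mean()),
        "frac_over_5fold": float(np.mean(np.abs(R) > np.log(5.0))),
    }
    return records, summary


def expansion_frame(records: list[ExpansionRecord]) -> pd.DataFrame:
    return pd.DataFrame({
        "query_id": [r.query_id for r in records],
        "target_id": [r.target_id for r in records],
        "size_query": [r.size_query for r in records],
        "size_target": [r.size_target for r in records],
        "R": [r.R for r in records],
    })
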