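"""Welch t-tests on atlas expression summaries and density grids.

Each (gene, timepoint) entry of a cell pair's profiles is compared with a
two-sample t-test for unequal sample sizes and variances (Welch), using
the per-cell across-embryo standard deviations and replicate counts stored
in the atlases.  Per cell pair, the Bonferroni correction over all tested
entries controls the family-wise error rate; the number of significant
entries is the *t-test score*, and a pair is declared "different" when the
score is at least 1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .atlas import Atlas, GeneSubset, shared_entry_mask
from .errors import IntegrityError
from .geometry import DensityGrid

logger = logging.getLogger(__name__)


@dataclass
class TTestScore:
    """Per-pair test outcome: statistics for every tested profile entry and
    the count significant under Bonferroni at family-wise level alpha."""

    query_id: int
    target_id: int
    t: np.ndarray           # (m_tests,)
    df: np.ndarray
    p: np.ndarray
    m_tests: int
    n_significant: int
    alpha: float


def welch_test(mean1, sd1, n1, mean2, sd2, n2):
    """Welch two-sample t-test from summary statistics (vectorized).

    Returns (t, df, p) with df by Welch–Satterthwaite and two-sided p.
    Degenerate inputs (both variances zero) take p = 1 when the means are
    equal and p = 0 otherwise, by convention (logged).
    """
    mean1, sd1, n1, mean2, sd2, n2 = map(np.asarray, (mean1, sd1, n1, mean2, sd2, n2))
    if np.any(n1 < 2) or np.any(n2 < 2):
        raise ValueError("Welch test needs at least 2 replicates per group")
    if np.any(sd1 < 0) or np.any(sd2 < 0):
        raise ValueError("negative standard deviation")
    v1 = sd1**2 / n1
    v2 = sd2**2 / n2
    denom = v1 + v2
    degenerate = denom == 0
    if np.any(degenerate):
        logger.info("both variances zero in %d tests; p set by convention",
                    int(np.sum(degenerate)))
    safe = np.where(degenerate, 1.0, denom)
    t = (mean1 - mean2) / np.sqrt(safe)
    with np.errstate(invalid="ignore", divide="ignore"):
        df = denom**2 / (v1**2 / (n1 - 1) + v2**2 / (n2 - 1))
    df = np.where(degenerate, 1.0, df)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    # conventions for the degenerate cases
    eq = mean1 == mean2
    with np.errstate(invalid="ignore"):
        t_deg = np.where(eq, 0.0, np.inf * np.sign(mean1 - mean2))
    t = np.where(degenerate, t_deg, t)
    p = np.where(degenerate, np.where(eq, 1.0, 0.0), p)
    return t, df, p


def ttest_score(
    query: Atlas,
    target: Atlas,
    pairs: np.ndarray,
    gs: GeneSubset | None = None,
    alpha: float = 0.01,
) -> list[TTestScore]:
    """Bonferroni-corrected Welch tests for matched cell pairs.

    ``pairs`` is an (n_pairs, 2) array of (query_id, target_id).  Every
    entry measured in both atlases (within the subset) is tested; an entry
    is significant iff p < alpha / m_tests.
    """
    pairs = np.asarray(pairs)
    mask = shared_entry_mask(query, target, gs)
    m_tests = int(mask.sum())
    if m_tests == 0:
        raise IntegrityError("no shared measured entries to test")
    for atlas, name in ((query, "query"), (target, "target")):
        low = (atlas.expr_n < 2) & mask[None, :, :]
        if np.any(low):
            i, g, t = np.argwhere(low)[0]
            raise IntegrityError(
                f"{name} atlas has replicate count < 2 at cell {i}, "
                f"gene {atlas.genes[g]!r}, timepoint {t + 1}"
            )

    qi, ti = pairs[:, 0], pairs[:, 1]
    m1 = query.expr_mean[qi][:, mask]
    s1 = query.expr_sd[qi][:, mask]
    n1 = query.expr_n[qi][:, mask]
    m2 = target.expr_mean[ti][:, mask]
    s2 = target.expr_sd[ti][:, mask]
    n2 = target.expr_n[ti][:, mask]
    t, df, p = welch_test(m1, s1, n1, m2, s2, n2)
    sig = p < alpha / m_tests
    return [
        TTestScore(
            query_id=int(qi[r]),
            target_id=int(ti[r]),
            t=t[r],
            df=df[r],
            p=p[r],
            m_tests=m_tests,
            n_significant=int(sig[r].sum()),
            alpha=alpha,
        )
        for r in range(len(pairs))
    ]


def ttest_score_frame(scores: list[TTestScore]) -> pd.DataFrame:
    return pd.DataFrame({
        "query_id": [s.query_id for s in scores],
        "target_id": [s.target_id for s in scores],
        "n_tests": [s.m_tests for s in scores],
        "n_significant": [s.n_significant for s in scores],
        "min_p": [float(np.min(s.p)) for s in scores],
    })


def density_compare(grid_a: DensityGrid, grid_b: DensityGrid,
                    similar_p: float = 0.05) -> pd.DataFrame:
    """Node-wise Welch comparison of two density grids with per-map samples.

    Returns one row per grid node with log10 p and a ``similar`` flag where
    p >= ``similar_p`` (the non-significant mask).
    """
    if grid_a.n < 2 or grid_b.n < 2:
        raise ValueError("need at least 2 density maps per grid to test")
    sa = grid_a.samples.reshape(grid_a.n, -1)
    sb = grid_b.samples.reshape(grid_b.n, -1)
    if sa.shape[1] != sb.shape[1]:
        raise ValueError("grids have different resolutions")
    t, df, p = welch_test(
        sa.mean(axis=0), sa.std(axis=0, ddof=1), grid_a.n,
        sb.mean(axis=0), sb.std(axis=0, ddof=1), grid_b.n,
    )
    gx, ga = np.meshgrid(grid_a.axial_centers, grid_a.angle_centers, indexing="ij")
    with np.errstate(divide="ignore"):
        log10p = np.log10(p)
    return pd.DataFrame({
        "axial_bin": gx.ravel(),
        "angle_bin": ga.ravel(),
        "t": t,
        "log10_p": log10p,
        "similar": p >= similar_p,
    })
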