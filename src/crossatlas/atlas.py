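"""Atlas data model, tab-delimited I/O, normalization and gene subsetting.

An :class:`Atlas` holds one species' cellular-resolution expression atlas:
per-cell 3D nuclear positions over ``T`` temporal cohorts, a surface
triangulation expressed as an undirected neighbor graph, and per-(gene,
timepoint) expression summaries (mean, standard deviation and replicate
count across the registered embryos).

Cells are identified by dense integer ids ``0..n_cells-1``; all derived
tables reference these ids.  Gene/timepoint slices in which every cell has
a replicate count of zero form the *missing mask* (e.g. *cad* absent from
one species, *bcd* not measured at late cohorts) and are excluded from
distances and tests downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

from .errors import FormatError, IntegrityError

logger = logging.getLogger(__name__)

#: Genes excluded from whole-profile comparisons by default: the maternal
#: gradient genes, whose measurements are unreliable early (bcd) or absent
#: in one species (cad).
DEFAULT_EXCLUDED_GENES = ("bcd", "cad")


@dataclass
class CellRecord:
    """Read-only view of one cell: positions per cohort and expression summaries."""

    cell_id: int
    position: np.ndarray   # (T, 3) µm
    expr_mean: np.ndarray  # (G, T)
    expr_sd: np.ndarray    # (G, T)
    expr_n: np.ndarray     # (G, T) replicate embryo counts


@dataclass
class ExpressionProfile:
    """The G×T expression vector of one cell, with gene names and missing mask."""

    genes: list[str]
    values: np.ndarray        # (G, T) normalized means
    missing: np.ndarray       # (G, T) bool, True where no measurement exists


@dataclass
class GeneSubset:
    """A selection of genes (and optionally timepoints per gene) for scoring.

    ``timepoints`` maps a gene name to the 1-based cohort indices to keep;
    genes absent from the map use every cohort.
    """

    genes: list[str]
    timepoints: dict[str, list[int]] = field(default_factory=dict)

    def __post_init__(self):
        if not self.genes:
            raise ValueError("GeneSubset must contain at least one gene")

    @classmethod
    def default_for(cls, atlas: "Atlas") -> "GeneSubset":
        """All atlas genes except the maternal gradients bcd and cad."""
        keep = [g for g in atlas.genes if g not in DEFAULT_EXCLUDED_GENES]
        return cls(genes=keep)

    def validate(self, atlas: "Atlas") -> None:
        missing = [g for g in self.genes if g not in atlas.genes]
        if missing:
            raise KeyError(
                f"genes {missing} not in atlas; available: {atlas.genes}"
            )
        for g, tps in self.timepoints.items():
            bad = [t for t in tps if t not in atlas.timepoints]
            if bad:
                raise KeyError(f"timepoints {bad} for gene {g!r} not in atlas")

    def entry_mask(self, atlas: "Atlas") -> np.ndarray:
        """(G, T) boolean mask of entries included by this subset AND measured."""
        self.validate(atlas)
        mask = np.zeros((atlas.n_genes, atlas.T), dtype=bool)
        for g in self.genes:
            gi = atlas.genes.index(g)
            tps = self.timepoints.get(g, atlas.timepoints)
            for t in tps:
                mask[gi, t - 1] = True
        return mask & ~atlas.missing_mask


@dataclass
class Atlas:
    species_label: str
    genes: list[str]
    positions: np.ndarray   # (n_cells, T, 3) µm
    expr_mean: np.ndarray   # (n_cells, G, T)
    expr_sd: np.ndarray     # (n_cells, G, T)
    expr_n: np.ndarray      # (n_cells, G, T) int
    edges: np.ndarray       # (E, 2) int, each undirected edge once, a < b
    egg_length: float       # µm
    normalized: bool = False
    norm_scope: str = "per_timepoint"
    true_mean: np.ndarray | None = None  # synthetic ground-truth levels, if any

    # ------------------------------------------------------------------ shape
    @property
    def n_cells(self) -> int:
        return self.positions.shape[0]

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def T(self) -> int:
        return self.positions.shape[1]

    @property
    def timepoints(self) -> list[int]:
        return list(range(1, self.T + 1))

    @property
    def missing_mask(self) -> np.ndarray:
        """(G, T) bool: slices with replicate count zero for every cell."""
        return np.all(self.expr_n == 0, axis=0)

    # -------------------------------------------------------------- accessors
    def cell(self, i: int) -> CellRecord:
        return CellRecord(
            cell_id=i,
            position=self.positions[i],
            expr_mean=self.expr_mean[i],
            expr_sd=self.expr_sd[i],
            expr_n=self.expr_n[i],
        )

    def profile(self, i: int) -> ExpressionProfile:
        return ExpressionProfile(
            genes=list(self.genes),
            values=self.expr_mean[i],
            missing=self.missing_mask,
        )

    def adjacency(self) -> csr_matrix:
        """Symmetric sparse adjacency over cell ids."""
        n = self.n_cells
        a, b = self.edges[:, 0], self.edges[:, 1]
        data = np.ones(2 * len(self.edges), dtype=np.int8)
        rows = np.concatenate([a, b])
        cols = np.concatenate([b, a])
        return csr_matrix((data, (rows, cols)), shape=(n, n))

    def neighbor_lists(self) -> list[np.ndarray]:
        """Per-cell arrays of graph neighbors (for BFS-style traversals)."""
        adj = self.adjacency()
        return [adj.indices[adj.indptr[i]:adj.indptr[i + 1]] for i in range(self.n_cells)]

    # ------------------------------------------------------------- validation
    def validate(self) -> None:
        n, G, T = self.n_cells, self.n_genes, self.T
        if n == 0:
            raise IntegrityError("atlas has no cells")
        if self.expr_mean.shape != (n, G, T):
            raise IntegrityError(
                f"expr_mean shape {self.expr_mean.shape} != {(n, G, T)}"
            )
        if self.expr_sd.shape != (n, G, T) or self.expr_n.shape != (n, G, T):
            raise IntegrityError("expr_sd/expr_n shapes inconsistent with atlas")
        if not np.all(np.isfinite(self.positions)):
            raise IntegrityError("non-finite cell positions")
        if np.any(self.expr_sd < 0):
            raise IntegrityError("negative expression standard deviation")
        if np.any(self.expr_n < 0):
            raise IntegrityError("negative replicate count")
        # missing data are per (gene, timepoint) slices: a slice is either
        # fully measured or fully absent
        partial = (~np.all(self.expr_n == 0, axis=0)) & np.any(self.expr_n == 0, axis=0)
        if np.any(partial):
            g, t = np.argwhere(partial)[0]
            raise IntegrityError(
                f"replicate count zero for some but not all cells at "
                f"gene {self.genes[g]!r} timepoint {t + 1}"
            )
        self._validate_edges()

    def _validate_edges(self) -> None:
        e = self.edges
        if e.ndim != 2 or e.shape[1] != 2:
            raise IntegrityError("neighbor table must have two columns")
        if np.any(e < 0) or np.any(e >= self.n_cells):
            raise IntegrityError("neighbor edge references unknown cell id")
        if np.any(e[:, 0] == e[:, 1]):
            raise IntegrityError("self-loop in neighbor graph")
        canon = np.sort(e, axis=1)
        if len(np.unique(canon, axis=0)) != len(canon):
            raise IntegrityError("duplicate edge in neighbor graph")
        n_comp, _ = connected_components(self.adjacency(), directed=False)
        if n_comp != 1:
            raise IntegrityError(f"neighbor graph has {n_comp} components; must be connected")


# ---------------------------------------------------------------------- I/O

def _atlas_columns(genes: Sequence[str], T: int) -> list[str]:
    cols = ["cell_id"]
    for t in range(1, T + 1):
        cols += [f"x_{t}", f"y_{t}", f"z_{t}"]
    for g in genes:
        for t in range(1, T + 1):
            cols += [f"{g}_{t}_mean", f"{g}_{t}_sd", f"{g}_{t}_n"]
    return cols


def _meta_path(path) -> Path:
    return Path(str(path) + ".meta")


def read_atlas(path, neighbor_path) -> Atlas:
    """Read an atlas table, its neighbor table and its metadata sidecar.

    ``path`` is the tab-delimited atlas table; the metadata sidecar is
    expected at ``<path>.meta``.  The returned atlas has all invariants
    checked; the missing mask is inferred from all-zero replicate counts.
    """
    path = Path(path)
    meta = _read_meta(_meta_path(path))
    genes = meta["genes"]
    T = meta["T"]
    df = pd.read_csv(path, sep="\t")
    expected = _atlas_columns(genes, T)
    if list(df.columns) != expected:
        for got, want in zip(list(df.columns) + ["<missing>"], expected + ["<extra>"]):
            if got != want:
                raise FormatError(
                    f"atlas table column mismatch: expected {want!r}, found {got!r}"
                )
    n = len(df)
    if not np.array_equal(df["cell_id"].to_numpy(), np.arange(n)):
        raise FormatError("cell_id column must be dense integers starting at 0")

    positions = np.empty((n, T, 3))
    for t in range(1, T + 1):
        positions[:, t - 1, :] = df[[f"x_{t}", f"y_{t}", f"z_{t}"]].to_numpy()
    G = len(genes)
    expr_mean = np.empty((n, G, T))
    expr_sd = np.empty((n, G, T))
    expr_n = np.empty((n, G, T), dtype=np.int64)
    for gi, g in enumerate(genes):
        for t in range(1, T + 1):
            expr_mean[:, gi, t - 1] = df[f"{g}_{t}_mean"]
            expr_sd[:, gi, t - 1] = df[f"{g}_{t}_sd"]
            expr_n[:, gi, t - 1] = df[f"{g}_{t}_n"]

    edges = _read_neighbors(neighbor_path)
    atlas = Atlas(
        species_label=meta["species_label"],
        genes=genes,
        positions=positions,
        expr_mean=expr_mean,
        expr_sd=expr_sd,
        expr_n=expr_n,
        edges=edges,
        egg_length=meta["egg_length"],
        normalized=meta.get("normalized", False),
        norm_scope=meta.get("norm_scope", "per_timepoint"),
    )
    atlas.validate()
    return atlas


def _read_neighbors(neighbor_path) -> np.ndarray:
    ndf = pd.read_csv(neighbor_path, sep="\t")
    if list(ndf.columns) != ["cell_id_a", "cell_id_b"]:
        raise FormatError(
            f"neighbor table columns must be cell_id_a, cell_id_b; found {list(ndf.columns)}"
        )
    edges = ndf.to_numpy(dtype=np.int64)
    canon = np.sort(edges, axis=1)
    if len(np.unique(canon, axis=0)) != len(canon):
        raise IntegrityError("neighbor pair listed more than once (asymmetric table)")
    return canon


def _read_meta(path: Path) -> dict:
    meta = {}
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if ":" not in line:
            raise FormatError(f"metadata line without 'key: value' form: {line!r}")
        key, val = line.split(":", 1)
        meta[key.strip()] = val.strip()
    try:
        meta["genes"] = [g for g in meta["genes"].split(",") if g]
        meta["T"] = int(meta["T"])
        meta["egg_length"] = float(meta["egg_length"])
        meta["normalized"] = meta.get("normalized", "false").lower() == "true"
        meta["species_label"] = meta["species_label"]
    except KeyError as exc:
        raise FormatError(f"metadata sidecar missing required key: {exc}") from exc
    return meta


def write_atlas(atlas: Atlas, path, neighbor_path) -> None:
    """Write atlas + neighbor tables (TSV) and the metadata sidecar.

    ``read_atlas(path, neighbor_path)`` recovers an element-wise equal atlas.
    """
    atlas.validate()
    path = Path(path)
    n, T = atlas.n_cells, atlas.T
    data = {"cell_id": np.arange(n)}
    for t in range(1, T + 1):
        data[f"x_{t}"] = atlas.positions[:, t - 1, 0]
        data[f"y_{t}"] = atlas.positions[:, t - 1, 1]
        data[f"z_{t}"] = atlas.positions[:, t - 1, 2]
    for gi, g in enumerate(atlas.genes):
        for t in range(1, T + 1):
            data[f"{g}_{t}_mean"] = atlas.expr_mean[:, gi, t - 1]
            data[f"{g}_{t}_sd"] = atlas.expr_sd[:, gi, t - 1]
            data[f"{g}_{t}_n"] = atlas.expr_n[:, gi, t - 1]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False, float_format="%.10g")

    pd.DataFrame(atlas.edges, columns=["cell_id_a", "cell_id_b"]).to_csv(
        neighbor_path, sep="\t", index=False
    )
    meta_lines = [
        f"species_label: {atlas.species_label}",
        f"egg_length: {atlas.egg_length:.10g}",
        f"genes: {','.join(atlas.genes)}",
        f"T: {atlas.T}",
        f"normalized: {str(atlas.normalized).lower()}",
        f"norm_scope: {atlas.norm_scope}",
    ]
    _meta_path(path).write_text("\n".join(meta_lines) + "\n")


# -------------------------------------------------------------- normalization

def normalize_atlas(atlas: Atlas, scope: str = "per_timepoint") -> Atlas:
    """Scale expression so the maximum mean of each slice is 1.0.

    ``scope="per_timepoint"`` rescales each (gene, timepoint) slice by its
    own maximum (the scaling used for distance scoring).
    ``scope="per_gene"`` rescales each gene by the maximum over its whole
    time course, so the peak timepoint takes the value 1 (the scaling used
    for display of expression time traces).

    Standard deviations are divided by the same factor.  All-zero slices
    are left unchanged and logged.  Idempotent.
    """
    if scope not in ("per_timepoint", "per_gene"):
        raise ValueError(f"unknown normalization scope {scope!r}")
    if np.any(atlas.expr_mean < 0):
        raise IntegrityError("negative expression mean; cannot normalize")
    mean = atlas.expr_mean.copy()
    sd = atlas.expr_sd.copy()
    if scope == "per_timepoint":
        # scale (G, T): max over cells
        scale = mean.max(axis=0)
    else:
        # per-gene max over the whole time course, broadcast over T
        scale = np.broadcast_to(mean.max(axis=(0, 2))[:, None], mean.shape[1:]).copy()
    zero = scale == 0
    if np.any(zero):
        for g, t in np.argwhere(zero):
            logger.warning(
                "all-zero expression slice left unnormalized: gene %s timepoint %d",
                atlas.genes[g], t + 1,
            )
    safe = np.where(zero, 1.0, scale)
    mean = mean / safe
    sd = sd / safe
    out = replace(atlas, expr_mean=mean, expr_sd=sd, normalized=True, norm_scope=scope)
    if atlas.true_mean is not None:
        out.true_mean = atlas.true_mean / safe
    return out


def subset(atlas: Atlas, gs: GeneSubset) -> Atlas:
    """Restrict an atlas to the genes (and timepoints) of ``gs``.

    Cells and geometry are unchanged.  Per-gene timepoint restrictions are
    represented through the missing mask (replicate count set to zero).
    """
    gs.validate(atlas)
    idx = [atlas.genes.index(g) for g in gs.genes]
    mean = atlas.expr_mean[:, idx, :].copy()
    sd = atlas.expr_sd[:, idx, :].copy()
    nrep = atlas.expr_n[:, idx, :].copy()
    for j, g in enumerate(gs.genes):
        tps = gs.timepoints.get(g)
        if tps is not None:
            drop = [t - 1 for t in atlas.timepoints if t not in tps]
            mean[:, j, drop] = 0.0
            sd[:, j, drop] = 0.0
            nrep[:, j, drop] = 0
    out = replace(
        atlas,
        genes=list(gs.genes),
        expr_mean=mean,
        expr_sd=sd,
        expr_n=nrep,
    )
    if atlas.true_mean is not None:
        out.true_mean = atlas.true_mean[:, idx, :]
    return out


def profile_matrix(atlas: Atlas, gs: GeneSubset | None = None,
                   entry_mask: np.ndarray | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Flatten normalized profiles to an (n_cells, D) matrix.

    Returns the matrix and the (G, T) boolean entry mask actually used.
    Cross-atlas comparisons should pass a shared mask (see
    :func:`shared_entry_mask`) so both matrices keep the same entries.
    """
    if not atlas.normalized:
        raise IntegrityError("atlas must be normalized before profile comparison")
    if entry_mask is None:
        gs = gs or GeneSubset(genes=list(atlas.genes))
        entry_mask = gs.entry_mask(atlas)
    return atlas.expr_mean[:, entry_mask], entry_mask


def shared_entry_mask(a: Atlas, b: Atlas, gs: GeneSubset | None = None) -> np.ndarray:
    """Entry mask of (gene, timepoint) pairs measured in BOTH atlases."""
    if a.genes != b.genes or a.T != b.T:
        raise IntegrityError(
            "atlases must share gene list and cohort count for comparison; "
            f"got {a.genes}/{a.T} vs {b.genes}/{b.T}"
        )
    gs = gs or GeneSubset(genes=list(a.genes))
    return gs.entry_mask(a) & gs.entry_mask(b)
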