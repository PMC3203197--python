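"""Synthetic two-species blastoderm atlases with known ground truth.

The generator emulates the statistical structure the comparative analysis
assumes: nuclei quasi-uniformly covering an ellipsoidal blastoderm surface
(a jittered Fibonacci lattice, triangulated by its convex hull), graded
gap-gene domains and 7-stripe pair-rule patterns expressed as functions of
cylindrical position, six temporal cohorts with a small poleward-to-center
nuclear drift, and replicate-embryo measurement noise (additive truncated
Gaussian per replicate, summarized to mean/sd/count as a registered atlas
would be).

Inter-species differences are injected explicitly — per-gene AP/DV shifts,
amplitude scaling, timing offsets, different nuclei counts and egg lengths —
and the injected values are retained as ground truth so that parameter
recovery can be checked downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull

from .atlas import Atlas
from .geometry import cylindrical_projection

_GOLDEN_ANGLE = math.pi * (3.0 - math.sqrt(5.0))

#: Common slope of nuclei count vs blastoderm surface area across species
#: (nuclei per µm²); embryo-to-embryo series share this slope while each
#: species keeps its own offset, so that embryos of equal area can still
#: differ in nuclear number between species.
NUCLEI_PER_UM2_SLOPE = 0.0278


@dataclass
class SpeciesSpec:
    """Morphology and measurement parameters for one synthetic species.

    Defaults follow blastoderm-stage Drosophila: ~400 µm egg length with
    transverse radii about a quarter of it, six temporal cohorts spanning
    the hour before gastrulation, and replicate noise of 5% of each
    expression slice's maximum.
    """

    label: str = "synthetic"
    n_nuclei: int = 6000
    egg_length: float = 400.0                 # µm, AP extent
    transverse_radii: tuple[float, float] | None = None  # µm; default L/4
    T: int = 6
    n_replicates: int = 10                    # embryos per (gene, timepoint)
    noise_sd: float = 0.05                    # fraction of slice max
    drift_fraction: float = 0.02              # poleward drift, fraction of L
    jitter: float = 0.3                       # lattice jitter, fraction of spacing
    seed: int = 0

    def __post_init__(self):
        if self.n_nuclei < 4:
            raise ValueError("need at least 4 nuclei")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.n_replicates < 2:
            raise ValueError("need at least 2 replicates for t-tests")
        if self.transverse_radii is None:
            self.transverse_radii = (self.egg_length / 4, self.egg_length / 4)

    # Table-driven presets for the three species' average morphologies
    @classmethod
    def melanogaster(cls, seed: int = 0, **kw) -> "SpeciesSpec":
        return cls(label="D.mel", n_nuclei=5974, egg_length=393.8, seed=seed, **kw)

    @classmethod
    def yakuba(cls, seed: int = 1, **kw) -> "SpeciesSpec":
        return cls(label="D.yak", n_nuclei=6128, egg_length=451.8, seed=seed, **kw)

    @classmethod
    def pseudoobscura(cls, seed: int = 2, **kw) -> "SpeciesSpec":
        return cls(label="D.pse", n_nuclei=5087, egg_length=394.6, seed=seed, **kw)


@dataclass
class PatternSpec:
    """One gene's spatial expression program.

    kinds:
      ``sigmoid_gradient`` — step-like AP domain boundary at ``center``
        (``orientation`` +1 = high anterior, -1 = high posterior);
      ``exp_gradient``     — exponential decay from a pole
        (``origin`` 0 = anterior, 1 = posterior), decay length ``decay``;
      ``stripes``          — sum of Gaussian bumps at ``centers`` (egg-length
        fractions) with standard-deviation ``widths`` and relative
        ``stripe_amps``, optionally drifting by ``center_drift`` over the
        time course;
      ``terminal``         — exponential caps at one or both poles,
        length scale ``cap_width``.

    ``amplitudes`` (length T) scales the whole pattern per cohort, encoding
    expression dynamics.  ``dv_modulation`` multiplies by
    ``1 + dv_modulation * cos(angle)`` (clipped at 0) to emulate
    dorsoventral variation of nominally AP patterns.
    """

    gene: str
    kind: str
    amplitudes: tuple = (1.0,) * 6
    center: float = 0.5
    steepness: float = 0.05
    orientation: int = 1
    origin: int = 0
    decay: float = 0.2
    centers: tuple = ()
    widths: tuple = ()
    stripe_amps: tuple = ()
    center_drift: float = 0.0
    cap_width: float = 0.1
    poles: str = "both"
    dv_modulation: float = 0.0

    def __post_init__(self):
        if self.kind not in ("sigmoid_gradient", "exp_gradient", "stripes", "terminal"):
            raise ValueError(f"unknown pattern kind {self.kind!r}")
        if any(a < 0 for a in self.amplitudes):
            raise ValueError("amplitudes must be non-negative")
        if self.kind == "stripes":
            if not self.centers:
                raise ValueError("stripe pattern needs centers")
            if any(w <= 0 for w in self.widths):
                raise ValueError("stripe width must be positive")
            if any(not 0 <= c <= 1 for c in self.centers):
                raise ValueError("stripe centers must lie in [0, 1]")
            if not self.stripe_amps:
                self.stripe_amps = (1.0,) * len(self.centers)

    def evaluate(self, axial: np.ndarray, angle: np.ndarray, t: int) -> np.ndarray:
        """True expression at cohort ``t`` (1-based) for cells at
        (axial fraction, angle)."""
        s = axial
        if self.kind == "sigmoid_gradient":
            v = 1.0 / (1.0 + np.exp(self.orientation * (s - self.center) / self.steepness))
        elif self.kind == "exp_gradient":
            dist = s if self.origin == 0 else 1.0 - s
            v = np.exp(-dist / self.decay)
        elif self.kind == "stripes":
            frac = (t - 1) / max(self.T_course - 1, 1)
            v = np.zeros_like(s)
            for c, w, a in zip(self.centers, self.widths, self.stripe_amps):
                ct = c + self.center_drift * frac
                v = v + a * np.exp(-0.5 * ((s - ct) / w) ** 2)
        else:  # terminal
            v = np.zeros_like(s)
            if self.poles in ("anterior", "both"):
                v = v + np.exp(-s / self.cap_width)
            if self.poles in ("posterior", "both"):
                v = v + np.exp(-(1.0 - s) / self.cap_width)
        if self.dv_modulation:
            v = v * np.clip(1.0 + self.dv_modulation * np.cos(angle), 0.0, None)
        amp = self.amplitudes[min(t - 1, len(self.amplitudes) - 1)]
        return amp * v

    @property
    def T_course(self) -> int:
        return len(self.amplitudes)


@dataclass
class GenePerturbation:
    """Differences injected for one gene in the target species."""

    ap_shift: float = 0.0        # egg-length fraction, signed (+ = posterior)
    dv_shift: float = 0.0        # radians
    amplitude_scale: tuple | float = 1.0  # scalar or per-cohort
    timing_offset: int = 0       # cohorts (+ = pattern delayed)


@dataclass
class PerturbationSpec:
    """Per-gene perturbations; genes not listed are unperturbed."""

    per_gene: dict[str, GenePerturbation] = field(default_factory=dict)

    @classmethod
    def null(cls) -> "PerturbationSpec":
        return cls()

    @classmethod
    def uniform_ap_shift(cls, delta: float, genes: list[str]) -> "PerturbationSpec":
        return cls({g: GenePerturbation(ap_shift=delta) for g in genes})

    def get(self, gene: str) -> GenePerturbation:
        return self.per_gene.get(gene, GenePerturbation())

    def ground_truth(self, genes: list[str], T: int) -> pd.DataFrame:
        rows = []
        for g in genes:
            p = self.get(g)
            for t in range(1, T + 1):
                scale = p.amplitude_scale
                if isinstance(scale, (tuple, list)):
                    scale = scale[min(t - 1, len(scale) - 1)]
                rows.append({
                    "gene": g, "cohort": t,
                    "true_shift_axial": p.ap_shift,
                    "true_shift_angle": p.dv_shift,
                    "amplitude_scale": scale,
                    "timing_offset": p.timing_offset,
                })
        return pd.DataFrame(rows)


# ---------------------------------------------------------------- pattern set

def segmentation_network_patterns(T: int = 6) -> list[PatternSpec]:
    """A 13-gene pattern set emulating the AP segmentation network:
    maternal gradients (bcd, cad), gap domains (hb, Kr, kni, gt), terminal
    caps (tll, hkb, fkh) and 7-stripe pair-rule patterns (eve, ftz, odd, prd).
    """
    seven = tuple(np.linspace(0.33, 0.87, 7))
    ramp_up = tuple(np.linspace(0.4, 1.0, T))
    late = tuple(np.linspace(0.05, 1.0, T) ** 2)
    const = (1.0,) * T
    return [
        PatternSpec("bcd", "exp_gradient", amplitudes=const, origin=0, decay=0.2),
        PatternSpec("cad", "sigmoid_gradient", amplitudes=const,
                    center=0.45, steepness=0.1, orientation=-1),
        PatternSpec("hb", "sigmoid_gradient", amplitudes=const,
                    center=0.47, steepness=0.03, orientation=1),
        PatternSpec("Kr", "stripes", amplitudes=ramp_up,
                    centers=(0.5,), widths=(0.07,)),
        PatternSpec("kni", "stripes", amplitudes=ramp_up,
                    centers=(0.67,), widths=(0.05,)),
        PatternSpec("gt", "stripes", amplitudes=const,
                    centers=(0.2, 0.78), widths=(0.06, 0.045),
                    stripe_amps=(1.0, 0.9), dv_modulation=0.3),
        PatternSpec("tll", "terminal", amplitudes=const, poles="both", cap_width=0.08),
        PatternSpec("hkb", "terminal", amplitudes=const, poles="both", cap_width=0.04),
        PatternSpec("fkh", "terminal", amplitudes=ramp_up, poles="both", cap_width=0.06),
        PatternSpec("eve", "stripes", amplitudes=ramp_up,
                    centers=seven, widths=(0.018,) * 7,
                    stripe_amps=(0.8, 1.0, 0.9, 1.0, 0.95, 1.0, 0.85)),
        PatternSpec("ftz", "stripes", amplitudes=ramp_up,
                    centers=tuple(c + 0.038 for c in seven), widths=(0.018,) * 7),
        PatternSpec("odd", "stripes", amplitudes=ramp_up,
                    centers=tuple(c + 0.042 for c in seven), widths=(0.016,) * 7,
                    stripe_amps=(0.9,) * 7),
        PatternSpec("prd", "stripes", amplitudes=late,
                    centers=tuple(c + 0.02 for c in seven), widths=(0.02,) * 7),
    ]


def _ellipsoid_area(a: float, b: float, c: float) -> float:
    """Thomsen's approximation to the ellipsoid surface area (error < 1.1%)."""
    p = 1.6075
    return 4.0 * math.pi * ((a**p * b**p + a**p * c**p + b**p * c**p) / 3.0) ** (1.0 / p)


def embryo_series(spec: SpeciesSpec, n_embryos: int,
                  size_cv: float = 0.04, count_sd: float = 0.0,
                  seed: int | None = None) -> list[SpeciesSpec]:
    """Specs for a cohort of embryos of one species, varying in size.

    Linear dimensions are scaled by independent factors ~ Normal(1, size_cv)
    and nuclei counts follow the shared count-vs-area slope
    :data:`NUCLEI_PER_UM2_SLOPE` plus a species-specific offset anchored at
    the base spec, so counts are linear in surface area with a common slope
    across species while species of equal area can differ in count.
    """
    rng = np.random.default_rng([seed if seed is not None else spec.seed, 2])
    b, c = spec.transverse_radii
    base_area = _ellipsoid_area(spec.egg_length / 2, b, c)
    offset = spec.n_nuclei - NUCLEI_PER_UM2_SLOPE * base_area
    out = []
    for e in range(n_embryos):
        f = max(rng.normal(1.0, size_cv), 0.5)
        area = _ellipsoid_area(f * spec.egg_length / 2, f * b, f * c)
        n = int(round(
            NUCLEI_PER_UM2_SLOPE * area + offset + rng.normal(0.0, count_sd)
        ))
        out.append(replace(
            spec,
            egg_length=f * spec.egg_length,
            transverse_radii=(f * b, f * c),
            n_nuclei=max(n, 4),
            seed=int(rng.integers(2**31 - 1)),
        ))
    return out


# ------------------------------------------------------------------ geometry

def generate_geometry(spec: SpeciesSpec) -> Atlas:
    """Atlas skeleton: nuclear positions over T cohorts plus the surface
    triangulation graph; no expression.  Deterministic given ``spec.seed``.

    Nuclei sit on a jittered Fibonacci lattice over the ellipsoid surface;
    cohorts include a small poleward-to-center drift (``drift_fraction`` of
    egg length at the poles across the full time course); the neighbor
    graph is the convex-hull triangulation of the first cohort.
    """
    rng = np.random.default_rng([spec.seed, 0])
    n = spec.n_nuclei
    a = spec.egg_length / 2.0
    b, c = spec.transverse_radii

    i = np.arange(n)
    u = 1.0 - 2.0 * (i + 0.5) / n
    phi = i * _GOLDEN_ANGLE
    # jitter both lattice coordinates by a fraction of the local spacing
    u = u + rng.normal(0.0, spec.jitter * 2.0 / n, n)
    u = np.clip(u, -1.0 + 1e-9, 1.0 - 1e-9)
    phi = phi + rng.normal(0.0, spec.jitter * 0.05, n)

    positions = np.empty((n, spec.T, 3))
    for t in range(spec.T):
        s_t = t / max(spec.T - 1, 1)
        u_t = u * (1.0 - 2.0 * spec.drift_fraction * s_t)
        r_t = np.sqrt(np.clip(1.0 - u_t**2, 0.0, None))
        positions[:, t, 0] = a * u_t
        positions[:, t, 1] = b * r_t * np.cos(phi)
        positions[:, t, 2] = c * r_t * np.sin(phi)

    hull = ConvexHull(positions[:, 0, :])
    edges = set()
    for s1, s2, s3 in hull.simplices:
        for p, q in ((s1, s2), (s1, s3), (s2, s3)):
            edges.add((min(p, q), max(p, q)))
    edge_arr = np.array(sorted(edges), dtype=np.int64)

    G = 0
    atlas = Atlas(
        species_label=spec.label,
        genes=[],
        positions=positions,
        expr_mean=np.zeros((n, G, spec.T)),
        expr_sd=np.zeros((n, G, spec.T)),
        expr_n=np.zeros((n, G, spec.T), dtype=np.int64),
        edges=edge_arr,
        egg_length=spec.egg_length,
    )
    atlas.validate()
    return atlas


# ---------------------------------------------------------------- expression

def _true_levels(
    skeleton: Atlas,
    patterns: list[PatternSpec],
    perturb: PerturbationSpec,
) -> np.ndarray:
    """(n_cells, G, T) noiseless expression after perturbation."""
    n, T = skeleton.n_cells, skeleton.T
    true = np.empty((n, len(patterns), T))
    for t in range(1, T + 1):
        pc = cylindrical_projection(skeleton, t)
        for gi, pat in enumerate(patterns):
            p = perturb.get(pat.gene)
            t_eff = int(np.clip(t - p.timing_offset, 1, T))
            scale = p.amplitude_scale
            if isinstance(scale, (tuple, list)):
                scale = scale[min(t - 1, len(scale) - 1)]
            true[:, gi, t - 1] = scale * pat.evaluate(
                pc.axial - p.ap_shift, pc.angle - p.dv_shift, t_eff
            )
    return true


def _draw_replicates(true: np.ndarray, noise_sd: float, n_rep: int,
                     rng: np.random.Generator) -> np.ndarray:
    """(n_cells, G, T, n_rep) replicate draws: additive Gaussian noise with
    sd = noise_sd × slice max, truncated at zero."""
    n, G, T = true.shape
    draws = np.empty((n, G, T, n_rep))
    slice_max = true.max(axis=0)  # (G, T)
    for g in range(G):
        for t in range(T):
            sigma = noise_sd * slice_max[g, t]
            noise = rng.normal(0.0, sigma, (n, n_rep)) if sigma > 0 else 0.0
            draws[:, g, t, :] = np.clip(true[:, g, t][:, None] + noise, 0.0, None)
    return draws


def _summarize(skeleton: Atlas, patterns, true, draws, label=None) -> Atlas:
    n_rep = draws.shape[-1]
    sd = draws.std(axis=-1, ddof=1) if n_rep > 1 else np.zeros(true.shape)
    # identical replicates (noiseless slices) must give sd exactly 0
    sd[draws.max(axis=-1) == draws.min(axis=-1)] = 0.0
    atlas = replace(
        skeleton,
        species_label=label or skeleton.species_label,
        genes=[p.gene for p in patterns],
        expr_mean=draws.mean(axis=-1),
        expr_sd=sd,
        expr_n=np.full(true.shape, n_rep, dtype=np.int64),
    )
    atlas.true_mean = true
    return atlas


def generate_expression(
    skeleton: Atlas,
    patterns: list[PatternSpec],
    perturb: PerturbationSpec,
    spec: SpeciesSpec,
) -> Atlas:
    """Fill a skeleton with expression summaries drawn from the patterns.

    With ``spec.noise_sd == 0`` the means equal the true pattern exactly and
    all standard deviations are zero.  Ground truth is stored on the atlas
    as ``true_mean``.
    """
    if not patterns:
        raise ValueError("need at least one pattern")
    rng = np.random.default_rng([spec.seed, 1])
    true = _true_levels(skeleton, patterns, perturb)
    draws = _draw_replicates(true, spec.noise_sd, spec.n_replicates, rng)
    return _summarize(skeleton, patterns, true, draws)


def generate_species_atlas(
    spec: SpeciesSpec,
    patterns: list[PatternSpec] | None = None,
    perturb: PerturbationSpec | None = None,
) -> Atlas:
    """Geometry + expression in one call."""
    patterns = patterns if patterns is not None else segmentation_network_patterns(spec.T)
    perturb = perturb or PerturbationSpec.null()
    return generate_expression(generate_geometry(spec), patterns, perturb, spec)


def generate_species_pair(
    spec_a: SpeciesSpec,
    spec_b: SpeciesSpec,
    patterns: list[PatternSpec] | None = None,
    perturb_b: PerturbationSpec | None = None,
) -> tuple[Atlas, Atlas, pd.DataFrame]:
    """Two atlases sharing pattern definitions, the second perturbed.

    Returns (atlas A, atlas B, ground-truth table of the injected per-gene
    shifts and scalings).
    """
    patterns = patterns if patterns is not None else segmentation_network_patterns(spec_a.T)
    perturb_b = perturb_b or PerturbationSpec.null()
    atlas_a = generate_species_atlas(spec_a, patterns, PerturbationSpec.null())
    atlas_b = generate_species_atlas(spec_b, patterns, perturb_b)
    truth = perturb_b.ground_truth([p.gene for p in patterns], spec_b.T)
    return atlas_a, atlas_b, truth


def split_replicates(
    spec: SpeciesSpec,
    patterns: list[PatternSpec] | None = None,
    perturb: PerturbationSpec | None = None,
) -> tuple[Atlas, Atlas]:
    """Two atlases summarizing disjoint halves of the same replicate draws.

    This is the null control: the halves share geometry and ground truth
    exactly and differ only by measurement noise, so distances and test
    scores between them bracket measurement error.  Odd replicate counts
    split floor/ceil.
    """
    if spec.n_replicates < 4:
        raise ValueError("need at least 4 replicates to split into testable halves")
    patterns = patterns if patterns is not None else segmentation_network_patterns(spec.T)
    perturb = perturb or PerturbationSpec.null()
    rng = np.random.default_rng([spec.seed, 1])
    skeleton = generate_geometry(spec)
    true = _true_levels(skeleton, patterns, perturb)
    draws = _draw_replicates(true, spec.noise_sd, spec.n_replicates, rng)
    half = spec.n_replicates // 2
    a = _summarize(skeleton, patterns, true, draws[..., :half],
                   label=f"{spec.label}-half1")
    b = _summarize(skeleton, patterns, true, draws[..., half:],
                   label=f"{spec.label}-half2")
    return a, b
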