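"""Shared fixtures: small synthetic atlases and hand-built toy atlases."""

import numpy as np
import pytest

import crossatlas as ca


def toy_atlas(n=3, genes=("g1", "g2"), T=1, seed=0, edges=None):
    """Minimal hand-built atlas: cells on a line, random expression."""
    rng = np.random.default_rng(seed)
    G = len(genes)
    positions = np.zeros((n, T, 3))
    positions[:, :, 0] = np.arange(n)[:, None]
    positions[:, :, 1] = rng.normal(0, 0.01, (n, T))
    if edges is None:
        edges = np.column_stack([np.arange(n - 1), np.arange(1, n)])
    return ca.Atlas(
        species_label="toy",
        genes=list(genes),
        positions=positions,
        expr_mean=rng.uniform(0.1, 1.0, (n, G, T)),
        expr_sd=rng.uniform(0.01, 0.1, (n, G, T)),
        expr_n=np.full((n, G, T), 5, dtype=np.int64),
        edges=np.asarray(edges, dtype=np.int64),
        egg_length=float(n),
    )


@pytest.fixture(scope="session")
def small_spec():
    return ca.SpeciesSpec(label="small", n_nuclei=600, seed=11)


@pytest.fixture(scope="session")
def small_atlas(small_spec):
    return ca.generate_species_atlas(small_spec)


@pytest.fixture(scope="session")
def small_normalized(small_atlas):
    return ca.normalize_atlas(small_atlas)


@pytest.fixture(scope="session")
def null_pair():
    """Two species with different nuclei counts, no expression perturbation."""
    sa = ca.SpeciesSpec(label="A", n_nuclei=700, seed=21)
    sb = ca.SpeciesSpec(label="B", n_nuclei=600, seed=22)
    a, b, truth = ca.generate_species_pair(sa, sb)
    return ca.normalize_atlas(a), ca.normalize_atlas(b), truth


@pytest.fixture(scope="session")
def calib_pair():
    """Null pair with unequal nuclei counts, large enough that the discrete
    mean-R calibration curve has steps well below the 1e-3 tolerance."""
    sa = ca.SpeciesSpec(label="A", n_nuclei=3000, seed=121)
    sb = ca.SpeciesSpec(label="B", n_nuclei=2550, seed=122)
    a, b, _ = ca.generate_species_pair(sa, sb)
    a, b = ca.normalize_atlas(a), ca.normalize_atlas(b)
    gs = ca.GeneSubset.default_for(a)
    matches = ca.match_all(a, b, ca.MatchConfig(genes=gs))
    return a, b, gs, matches


def icosphere(subdivisions=3, radius=1.0):
    """Triangulated sphere by repeated subdivision of an icosahedron.

    Returns (vertices (n,3), edges (E,2)).  Independent geometry oracle for
    surface-area checks.
    """
    phi = (1 + np.sqrt(5)) / 2
    verts = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
    ], dtype=float)
    faces = [
        (0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
        (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
        (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
        (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1),
    ]
    verts = [v / np.linalg.norm(v) for v in verts]
    for _ in range(subdivisions):
        midpoint = {}

        def mid(i, j):
            key = (min(i, j), max(i, j))
            if key not in midpoint:
                m = verts[i] + verts[j]
                verts.append(m / np.linalg.norm(m))
                midpoint[key] = len(verts) - 1
            return midpoint[key]

        new_faces = []
        for a, b, c in faces:
            ab, bc, ca_ = mid(a, b), mid(b, c), mid(c, a)
            new_faces += [(a, ab, ca_), (b, bc, ab), (c, ca_, bc), (ab, bc, ca_)]
        faces = new_faces
    verts = np.array(verts) * radius
    edges = set()
    for a, b, c in faces:
        for p, q in ((a, b), (b, c), (a, c)):
            edges.add((min(p, q), max(p, q)))
    return verts, np.array(sorted(edges), dtype=np.int64)
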