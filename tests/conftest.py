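"""Shared fixtures: toy meshes, standard geometries, and cached phantoms."""

import numpy as np
import pytest
from scipy.spatial import Delaunay

from ecgibench.mesh import TriMesh, build_ellipsoid_mesh
from ecgibench.bench import default_geometry


@pytest.fixture(scope="session")
def icosahedron():
    return build_ellipsoid_mesh((1.0, 1.0, 1.0), 0)


@pytest.fixture(scope="session")
def sphere2():
    """Unit icosphere, subdivision level 2 (162 nodes)."""
    return build_ellipsoid_mesh((1.0, 1.0, 1.0), 2)


@pytest.fixture(scope="session")
def tiny_geometry():
    """162-node atria / 42-lead torso standard pair."""
    return default_geometry("tiny")


@pytest.fixture(scope="session")
def disk_mesh():
    """Open planar triangulated disk (boundary nodes have open fans).

    Used by singularity-point oracles: on an open patch a vortex whose
    compensating antivortex lies outside the patch yields exactly one
    detectable singularity.
    """
    pts = [(0.0, 0.0)]
    n_rings, radius = 7, 21.0
    for k in range(1, n_rings + 1):
        r = radius * k / n_rings
        m = 6 * k
        ang = 2 * np.pi * np.arange(m) / m + 0.1 * k
        pts.extend(zip(r * np.cos(ang), r * np.sin(ang)))
    pts = np.asarray(pts)
    tri = Delaunay(pts)
    faces = tri.simplices.copy()
    # enforce counter-clockwise orientation
    p = pts[faces]
    cross = ((p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
             - (p[:, 1, 1] - p[:, 0, 1]) * (p[:, 2, 0] - p[:, 0, 0]))
    flip = cross < 0
    faces[flip] = faces[flip][:, [0, 2, 1]]
    verts3 = np.c_[pts, np.zeros(len(pts))]
    return TriMesh(verts3, faces)


@pytest.fixture(scope="session")
def saf_phantom(tiny_geometry):
    """8 s noiseless SAF phantom on the tiny atria (cached per session)."""
    from ecgibench.phantom import simulate_pattern
    from ecgibench.bench import make_pattern
    atria, _ = tiny_geometry
    pattern = make_pattern("SAF", seed=0)
    field, truth = simulate_pattern(atria, pattern, 8.0, 500.0)
    return atria, pattern, field, truth
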