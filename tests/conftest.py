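"""Shared fixtures: small meshes, layouts and phantom cases.

Everything is generated programmatically; session scope keeps the heavier
forward solves shared across tests.
"""

import numpy as np
import pytest

from dcedot import meshgen, phantoms, recon
from dcedot.forward import ForwardConfig, OpticalMap, forward_measurements
from dcedot.meshgen import Mesh2D, cross2
from dcedot.workflow import ExperimentConfig, build_case


def circle_polygon(radius: float, n: int = 120) -> np.ndarray:
    th = np.linspace(0, 2 * np.pi, n, endpoint=False)
    return radius * np.stack([np.cos(th), np.sin(th)], axis=1)


def polar_mesh(radius: float = 25.0, n_rings: int = 12, n_theta: int = 48) -> Mesh2D:
    """Structured, exactly rotationally symmetric disk mesh (symmetry oracle)."""
    nodes = [(0.0, 0.0)]
    for i in range(1, n_rings + 1):
        r = radius * i / n_rings
        th = np.arange(n_theta) * 2 * np.pi / n_theta
        nodes += [(r * np.cos(t), r * np.sin(t)) for t in th]
    nodes = np.array(nodes)

    def idx(i, k):
        return 1 + (i - 1) * n_theta + (k % n_theta)

    elems = []
    for k in range(n_theta):
        elems.append((0, idx(1, k), idx(1, k + 1)))
    for i in range(1, n_rings):
        for k in range(n_theta):
            a, b = idx(i, k), idx(i, k + 1)
            c, d = idx(i + 1, k), idx(i + 1, k + 1)
            elems.append((a, c, d))
            elems.append((a, d, b))
    elems = np.array(elems)
    p = nodes[elems]
    flip = cross2(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]) < 0
    elems[flip] = elems[flip][:, [0, 2, 1]]
    outer = [idx(n_rings, k) for k in range(n_theta)]
    boundary = np.stack([outer, np.roll(outer, -1)], axis=1)
    return Mesh2D(nodes=nodes, elements=elems, boundary_edges=boundary)


@pytest.fixture(scope="session")
def fwd_cfg():
    return ForwardConfig()


@pytest.fixture(scope="session")
def small_disk():
    """~200-node disk mesh with a fan-beam layout (Jacobian-scale problems)."""
    mesh = meshgen.build_mesh(circle_polygon(20.0, 40), 3.0)
    layout = meshgen.map_optodes(mesh, np.array([0.0, 0.0]))
    return mesh, layout


@pytest.fixture(scope="session")
def disk_mesh():
    """~500-node disk mesh with layout (reconstruction-scale problems)."""
    mesh = meshgen.build_mesh(circle_polygon(25.0), 2.0)
    layout = meshgen.map_optodes(mesh, np.array([0.0, 0.0]))
    return mesh, layout


@pytest.fixture(scope="session")
def symmetric_disk():
    mesh = polar_mesh()
    layout = meshgen.map_optodes(mesh, np.array([0.0, 0.0]))
    return mesh, layout


@pytest.fixture(scope="session")
def circle_case():
    """Same-mesh, noise-free circular phantom case with labelled inclusion."""
    cfg = ExperimentConfig(shapes=("circle",), same_mesh=True,
                           amplitude_cv=0.0, phase_sd_deg=0.0, recon_edge_mm=2.0)
    return cfg, build_case(cfg, "circle")


@pytest.fixture(scope="session")
def circle_b_series(circle_case, fwd_cfg):
    """Noise-free same-mesh B-series frames plus the homogeneous fit."""
    _, case = circle_case
    maps = phantoms.make_phantom_series(case.spec, case.gen_mesh)
    frames = [forward_measurements(case.gen_mesh, m, case.gen_layout, fwd_cfg)
              for m in maps]
    homog = recon.fit_homogeneous(frames[0], case.recon_mesh, case.recon_layout, fwd_cfg)
    return case, frames, homog
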