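"""Frequency-domain diffusion forward model on linear-triangle FEM meshes.

The fluence rate Phi(r, omega) obeys

    div(D grad Phi) - (mu_a + i*omega/c_n) Phi = -q0,      D = 1/[3(mu_a + mu_s')]

with the Robin condition Phi + 2 A D dPhi/dn = 0 on the boundary, so the
measurable photon flux is phi = Phi / (2A).  A point source of unit amplitude
is placed one transport mean free path (1/mu_s') inside the boundary below
each source optode.  With the e^{+i omega t} convention the detected phase is
reported as a positive lag that grows with source-detector separation.

The weak form yields a complex symmetric system

    [ K(D) + M(mu_a + i omega/c_n) + (1/2A) B ] Phi = q

with K the D-weighted stiffness matrix, M the consistent mass matrix and B
the boundary-edge mass matrix.  Element coefficients are the mean of the
three nodal values, which keeps the Jacobian of the assembly with respect to
nodal optical properties exact and cheap (see :mod:`dcedot.recon`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.integrate import quad
from scipy.sparse.linalg import splu

from dcedot.meshgen import Mesh2D, OptodeLayout, find_element

C0_MM_PER_S = 2.99792458e11  # vacuum light speed, mm/s


def fresnel_reflectance(cos_i: float, n_in: float, n_out: float) -> float:
    """Unpolarised Fresnel reflectance for light hitting the boundary from
    inside (refractive index n_in) at incidence cosine cos_i."""
    sin_i = np.sqrt(max(0.0, 1.0 - cos_i**2))
    sin_t = n_in / n_out * sin_i
    if sin_t >= 1.0:
        return 1.0  # total internal reflection
    cos_t = np.sqrt(1.0 - sin_t**2)
    rs = (n_in * cos_i - n_out * cos_t) / (n_in * cos_i + n_out * cos_t)
    rp = (n_in * cos_t - n_out * cos_i) / (n_in * cos_t + n_out * cos_i)
    return 0.5 * (rs**2 + rp**2)


def effective_reflection(n_in: float = 1.4, n_out: float = 1.0) -> float:
    """Angle-averaged effective reflection coefficient R_eff.

    Integrates the unpolarised Fresnel reflectance against the fluence and
    current weightings; R_eff = (R_phi + R_j) / (2 - R_phi + R_j).
    """
    r_phi = quad(lambda t: 2 * np.sin(t) * np.cos(t) * fresnel_reflectance(np.cos(t), n_in, n_out), 0, np.pi / 2)[0]
    r_j = quad(lambda t: 3 * np.sin(t) * np.cos(t) ** 2 * fresnel_reflectance(np.cos(t), n_in, n_out), 0, np.pi / 2)[0]
    return (r_phi + r_j) / (2 - r_phi + r_j)


def mismatch_parameter(n_in: float = 1.4, n_out: float = 1.0) -> float:
    """Boundary mismatch parameter A = (1 + R_eff)/(1 - R_eff); ~2.95 at n=1.4."""
    r = effective_reflection(n_in, n_out)
    return (1 + r) / (1 - r)


@dataclass
class ForwardConfig:
    """Physics configuration shared by forward and inverse solvers."""

    modulation_freq: float = 100e6      # Hz
    refractive_index: float = 1.4       # interior; exterior assumed 1.0
    A: float = None                     # boundary mismatch; derived if None

    def __post_init__(self):
        if self.A is None:
            self.A = mismatch_parameter(self.refractive_index, 1.0)
        if self.A < 1:
            raise ValueError("A must be >= 1 for an index-mismatched boundary")

    @property
    def omega(self) -> float:
        return 2 * np.pi * self.modulation_freq

    @property
    def c_n(self) -> float:
        return C0_MM_PER_S / self.refractive_index


@dataclass
class OpticalMap:
    """Nodal absorption and reduced-scattering fields (mm^-1)."""

    mua: np.ndarray
    musp: np.ndarray

    def __post_init__(self):
        self.mua = np.atleast_1d(np.asarray(self.mua, dtype=float))
        self.musp = np.atleast_1d(np.asarray(self.musp, dtype=float))
        if self.mua.shape != self.musp.shape:
            raise ValueError("mua and musp must have the same shape")
        if np.any(self.mua <= 0) or np.any(self.musp <= 0):
            raise ValueError("optical properties must be positive")

    @property
    def diffusion(self) -> np.ndarray:
        """D = 1/[3(mu_a + mu_s')], mm."""
        return 1.0 / (3.0 * (self.mua + self.musp))

    @classmethod
    def homogeneous(cls, mesh: Mesh2D, mua: float, musp: float) -> "OpticalMap":
        n = mesh.n_nodes
        return cls(np.full(n, mua), np.full(n, musp))

    def copy(self) -> "OpticalMap":
        return OpticalMap(self.mua.copy(), self.musp.copy())


@dataclass
class FluenceField:
    """Complex nodal fluence for one source."""

    values: np.ndarray
    source_index: int = -1

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=complex)
        if not np.all(np.isfinite(self.values)):
            raise ValueError("fluence field contains non-finite values")


@dataclass
class MeasurementFrame:
    """One frame of boundary data: Ns x Nd amplitude and phase.

    Phase is the positive lag in radians, unwrapped along the detector index
    for each source.  The complex flux is amplitude * exp(-i * phase).
    """

    amplitude: np.ndarray
    phase: np.ndarray
    frame_time: float = 0.0

    def __post_init__(self):
        self.amplitude = np.asarray(self.amplitude, dtype=float)
        self.phase = np.asarray(self.phase, dtype=float)
        if self.amplitude.shape != self.phase.shape:
            raise ValueError("amplitude and phase shapes differ")
        if np.any(self.amplitude <= 0):
            raise ValueError("amplitudes must be positive")

    @property
    def flux(self) -> np.ndarray:
        return self.amplitude * np.exp(-1j * self.phase)

    @classmethod
    def from_flux(cls, flux: np.ndarray, frame_time: float = 0.0) -> "MeasurementFrame":
        amp = np.abs(flux)
        lag = np.unwrap(-np.angle(flux), axis=1)
        return cls(amplitude=amp, phase=lag, frame_time=frame_time)

    def to_csv(self, path: str) -> None:
        ns, nd = self.amplitude.shape
        i, j = np.meshgrid(np.arange(ns), np.arange(nd), indexing="ij")
        pd.DataFrame({
            "source_index": i.ravel(),
            "detector_index": j.ravel(),
            "amplitude": self.amplitude.ravel(),
            "phase": self.phase.ravel(),
        }).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path: str, frame_time: float = 0.0) -> "MeasurementFrame":
        df = pd.read_csv(path)
        ns = df["source_index"].max() + 1
        nd = df["detector_index"].max() + 1
        amp = np.zeros((ns, nd))
        ph = np.zeros((ns, nd))
        amp[df["source_index"], df["detector_index"]] = df["amplitude"]
        ph[df["source_index"], df["detector_index"]] = df["phase"]
        return cls(amplitude=amp, phase=ph, frame_time=frame_time)


# ---------------------------------------------------------------------------
# assembly

def element_matrices(mesh: Mesh2D):
    """Geometric element matrices.

    Returns (S0, M0, areas): per-element unit-coefficient stiffness and
    consistent mass matrices, shapes (E, 3, 3).
    """
    p = mesh.nodes[mesh.elements]  # (E, 3, 2)
    x, y = p[..., 0], p[..., 1]
    b = np.stack([y[:, 1] - y[:, 2], y[:, 2] - y[:, 0], y[:, 0] - y[:, 1]], axis=1)
    c = np.stack([x[:, 2] - x[:, 1], x[:, 0] - x[:, 2], x[:, 1] - x[:, 0]], axis=1)
    area = mesh.element_areas()
    if np.any(area <= 0):
        bad = int(np.argmin(area))
        raise ValueError(f"element {bad} has zero or negative area")
    S0 = (b[:, :, None] * b[:, None, :] + c[:, :, None] * c[:, None, :]) / (4 * area)[:, None, None]
    m = np.array([[2.0, 1, 1], [1, 2, 1], [1, 1, 2]]) / 12.0
    M0 = area[:, None, None] * m[None]
    return S0, M0, area


def boundary_matrix(mesh: Mesh2D) -> sparse.csr_matrix:
    """Unit-coefficient boundary-edge mass matrix (scaled by 1/2A at use)."""
    n = mesh.n_nodes
    a = mesh.boundary_edges[:, 0]
    b = mesh.boundary_edges[:, 1]
    ell = np.linalg.norm(mesh.nodes[b] - mesh.nodes[a], axis=1)
    rows = np.concatenate([a, b, a, b])
    cols = np.concatenate([a, b, b, a])
    vals = np.concatenate([ell / 3, ell / 3, ell / 6, ell / 6])
    return sparse.csr_matrix((vals, (rows, cols)), shape=(n, n))


class FemSystem:
    """Assembled forward operator with a reusable factorization.

    Holds the geometric element matrices so that repeated assembly on the
    same mesh (LM iterations, Jacobian products) skips the geometry work.
    """

    def __init__(self, mesh: Mesh2D, cfg: ForwardConfig = None):
        self.mesh = mesh
        self.cfg = cfg or ForwardConfig()
        self.S0, self.M0, self.areas = element_matrices(mesh)
        self.B = boundary_matrix(mesh)
        tri = mesh.elements
        self._rows = np.repeat(tri, 3, axis=1).ravel()
        self._cols = np.tile(tri, (1, 3)).ravel()
        self._matrix = None
        self._lu = None

    def element_coeffs(self, omap: OpticalMap):
        """Element-mean mu_a and D."""
        tri = self.mesh.elements
        mua_e = omap.mua[tri].mean(axis=1)
        musp_e = omap.musp[tri].mean(axis=1)
        D_e = 1.0 / (3.0 * (mua_e + musp_e))
        return mua_e, D_e

    def assemble(self, omap: OpticalMap) -> sparse.csc_matrix:
        if len(omap.mua) != self.mesh.n_nodes:
            raise ValueError("optical map does not match mesh")
        mua_e, D_e = self.element_coeffs(omap)
        kappa = mua_e + 1j * self.cfg.omega / self.cfg.c_n
        local = D_e[:, None, None] * self.S0 + kappa[:, None, None] * self.M0
        n = self.mesh.n_nodes
        A = sparse.csc_matrix((local.ravel(), (self._rows, self._cols)), shape=(n, n))
        A = A + (1.0 / (2.0 * self.cfg.A)) * self.B.astype(complex)
        self._matrix = A
        self._lu = None
        return A

    def factorize(self):
        if self._matrix is None:
            raise RuntimeError("assemble() before factorize()")
        self._lu = splu(self._matrix.tocsc())
        return self._lu

    def solve(self, rhs: np.ndarray) -> np.ndarray:
        if self._lu is None:
            self.factorize()
        return self._lu.solve(np.asarray(rhs, dtype=complex))


def assemble_system(mesh: Mesh2D, omap: OpticalMap, cfg: ForwardConfig = None) -> sparse.csc_matrix:
    """Assemble the complex symmetric FEM system matrix."""
    return FemSystem(mesh, cfg).assemble(omap)


def place_source(mesh: Mesh2D, optode_pos, musp_local: float) -> np.ndarray:
    """Unit point source one transport length inside the boundary.

    The source sits 1/mu_s' below the optode along the inward normal and is
    distributed to the enclosing element's nodes by barycentric weights.
    """
    optode_pos = np.asarray(optode_pos, dtype=float)
    bnodes = mesh.boundary_nodes()
    node = bnodes[np.argmin(np.linalg.norm(mesh.nodes[bnodes] - optode_pos, axis=1))]
    inward = -mesh.node_normal(node)
    depth = 1.0 / musp_local
    point = mesh.nodes[node] + depth * inward
    elems, bary = find_element(mesh, point)
    if elems[0] < 0:
        raise ValueError(
            f"source point {point} at depth {depth:.2f} mm falls outside the mesh; "
            "domain too thin for the transport-length placement rule")
    q = np.zeros(mesh.n_nodes)
    q[mesh.elements[elems[0]]] = bary[0]
    return q


def solve_fluence(system: FemSystem, source: np.ndarray, source_index: int = -1) -> FluenceField:
    """Solve the assembled system for one source (factorization is reused)."""
    phi = system.solve(source)
    return FluenceField(values=phi, source_index=source_index)


def boundary_flux(field: FluenceField, layout: OptodeLayout, cfg: ForwardConfig) -> np.ndarray:
    """Measured flux phi = Phi(detector node) / (2A) for each detector."""
    if layout.detector_nodes is None:
        raise ValueError("layout has no detector node indices")
    det = np.asarray(layout.detector_nodes)
    if det.max() >= len(field.values):
        raise ValueError("detector index out of range for this mesh")
    return field.values[det] / (2.0 * cfg.A)


def forward_measurements(mesh: Mesh2D, omap: OpticalMap, layout: OptodeLayout,
                         cfg: ForwardConfig = None, frame_time: float = 0.0) -> MeasurementFrame:
    """Run all sources through one factorization and collect the 8x8 data."""
    cfg = cfg or ForwardConfig()
    system = FemSystem(mesh, cfg)
    system.assemble(omap)
    system.factorize()
    flux = np.zeros((layout.n_sources, layout.n_detectors), dtype=complex)
    for i, pos in enumerate(layout.source_positions):
        node = np.argmin(np.linalg.norm(mesh.nodes - pos, axis=1))
        q = place_source(mesh, pos, omap.musp[node])
        phi = solve_fluence(system, q, i)
        flux[i] = boundary_flux(phi, layout, cfg)
    return MeasurementFrame.from_flux(flux, frame_time=frame_time)
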