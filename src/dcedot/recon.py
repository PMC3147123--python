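"""Levenberg-Marquardt image reconstruction with structural priors.

Measurements are inverted for nodal absorption (optionally also reduced
scattering) by iterating

    X_{m+1} = X_m + (J^T J + lambda R)^{-1} J^T eps,

where eps is the residual between measured and predicted data, J is the
sensitivity (Jacobian) computed with the adjoint method, and R is either the
identity or L^T L built from anatomical region labels.  The L matrix carries
1 on the diagonal, -1/Nr between nodes sharing a region of Nr nodes, and 0
across regions, so it penalises within-region variation while leaving
region-wide offsets nearly free.

Residuals are stacked in log-amplitude and phase rather than raw complex
flux: the measurement dynamic range spans decades, and the multiplicative
calibration and optode-coupling models become additive in log space.  Per-
optode coupling gains can be appended to the unknown vector (their Jacobian
columns are indicator patterns in log-amplitude space) with the reciprocal
gauge fixed by sum(log s) = sum(log d); reported gains are rescaled to zero
log-mean, so only their ratios are meaningful.

Four analysis methods are dispatched by :func:`reconstruct`:

1. 128 data (64 log-amplitude + 64 phase), unknowns mu_a and mu_s',
   identity damping.
2. 64 log-amplitude data, mu_a only; mu_s' fixed from a homogeneous fit.
3. Method 2 plus per-optode coupling unknowns.
4. Method 2 data with the L^T L region prior replacing the identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.optimize import least_squares

from dcedot.forward import (FemSystem, ForwardConfig, MeasurementFrame, OpticalMap,
                            place_source)
from dcedot.meshgen import Mesh2D, OptodeLayout

MUA_FLOOR = 1e-4    # mm^-1, keeps D finite and mu_a physical
MUSP_FLOOR = 1e-3   # mm^-1
# relative damping of the 16 coupling gains: they are few, well determined
# (indicator columns) and should absorb per-channel offsets before the image
COUPLING_DAMP = 1e-6


# ---------------------------------------------------------------------------
# data stacking and objective

def stack_frame(frame: MeasurementFrame, data: str = "logamp_phase") -> np.ndarray:
    """Stack a frame into the residual data space.

    data = "logamp_phase": [log amplitude (64); phase (64)];
    data = "logamp": log amplitude only.
    """
    la = np.log(frame.amplitude).ravel()
    if data == "logamp":
        return la
    if data == "logamp_phase":
        return np.concatenate([la, frame.phase.ravel()])
    raise ValueError(f"unknown data stacking {data!r}")


def objective(measured: MeasurementFrame, predicted: MeasurementFrame,
              data: str = "logamp_phase") -> float:
    """Sum of squared residuals over the stacked data vector."""
    a = stack_frame(measured, data)
    b = stack_frame(predicted, data)
    if a.shape != b.shape:
        raise ValueError("measured and predicted frames have different layouts")
    return float(np.sum((a - b) ** 2))


# ---------------------------------------------------------------------------
# coupling factors and calibration

@dataclass
class CouplingFactors:
    """Per-optode multiplicative gains s_i (sources) and d_j (detectors)."""

    s: np.ndarray
    d: np.ndarray

    def __post_init__(self):
        self.s = np.atleast_1d(np.asarray(self.s, dtype=float))
        self.d = np.atleast_1d(np.asarray(self.d, dtype=float))
        if np.any(self.s <= 0) or np.any(self.d <= 0):
            raise ValueError("coupling factors must be positive (multiplicative gains)")

    @classmethod
    def unity(cls, ns: int = 8, nd: int = 8) -> "CouplingFactors":
        return cls(np.ones(ns), np.ones(nd))

    def apply(self, frame: MeasurementFrame) -> MeasurementFrame:
        amp = frame.amplitude * np.outer(self.s, self.d)
        return MeasurementFrame(amplitude=amp, phase=frame.phase.copy(),
                                frame_time=frame.frame_time)

    def gauge_fixed(self) -> "CouplingFactors":
        """Rescale so that sum(log s) = sum(log d) = 0."""
        ls = np.log(self.s)
        ld = np.log(self.d)
        return CouplingFactors(np.exp(ls - ls.mean()), np.exp(ld - ld.mean()))


@dataclass
class CalibrationSet:
    """Bookkeeping for the homogeneous-phantom data calibration."""

    F_measured: np.ndarray
    F_homo_measured: np.ndarray
    F_homo_forw: np.ndarray
    F_calibrated: np.ndarray = None

    def __post_init__(self):
        if np.any(np.abs(self.F_homo_measured) == 0):
            raise ValueError("homogeneous measurement contains zero amplitude")
        if self.F_calibrated is None:
            self.F_calibrated = self.F_measured / self.F_homo_measured * self.F_homo_forw


def calibrate(measured: MeasurementFrame, homo_measured: MeasurementFrame,
              homo_forward: MeasurementFrame) -> MeasurementFrame:
    """Reference the data to the forward model via a homogeneous phantom.

    F_cal = F_measured / F_homo_measured * F_homo_forward, element-wise in
    the complex flux.  Multiplicative per-channel factors common to both
    measured frames (e.g. coupling gains) cancel exactly.
    """
    shapes = {measured.amplitude.shape, homo_measured.amplitude.shape,
              homo_forward.amplitude.shape}
    if len(shapes) != 1:
        raise ValueError("calibration frames do not share a layout")
    if np.any(homo_measured.amplitude == 0):
        raise ValueError("homogeneous measurement contains zero amplitude")
    amp = measured.amplitude / homo_measured.amplitude * homo_forward.amplitude
    phase = measured.phase - homo_measured.phase + homo_forward.phase
    return MeasurementFrame(amplitude=amp, phase=phase, frame_time=measured.frame_time)


# ---------------------------------------------------------------------------
# region prior

@dataclass
class RegionPrior:
    """Laplacian-type regularization matrix built from region labels."""

    region_labels: np.ndarray
    L: np.ndarray

    def LtL(self) -> np.ndarray:
        return self.L.T @ self.L


def build_region_L(region_labels, off_diag_sign: float = -1.0) -> RegionPrior:
    """Build the region L matrix: 1 on the diagonal, sign/Nr within a region,
    0 across regions.

    The default off-diagonal sign is negative so that L annihilates (up to
    1/Nr) vectors constant within a region: the prior penalises within-region
    variation rather than the region mean.  ``off_diag_sign=+1`` reproduces
    the alternative printed convention for comparison.
    """
    labels = np.asarray(region_labels, dtype=np.int64)
    n = len(labels)
    L = np.eye(n)
    for r in np.unique(labels):
        idx = np.flatnonzero(labels == r)
        nr = len(idx)
        if nr == 0:
            raise ValueError(f"region {r} is empty")
        if nr == 1:
            continue
        block = np.full((nr, nr), off_diag_sign / nr)
        np.fill_diagonal(block, 1.0)
        L[np.ix_(idx, idx)] = block
    return RegionPrior(region_labels=labels, L=L)


# ---------------------------------------------------------------------------
# forward operator with adjoint Jacobian

class ForwardOperator:
    """Forward predictions and adjoint sensitivities on one mesh/layout.

    Source vectors are placed once (depth 1/mu_s' below each optode, using
    ``source_musp``) and frozen, so predictions are smooth in the optical
    unknowns and the adjoint Jacobian matches finite differences of
    :meth:`predict` exactly.
    """

    def __init__(self, mesh: Mesh2D, layout: OptodeLayout, cfg: ForwardConfig = None,
                 source_musp: float = 0.6):
        self.mesh = mesh
        self.layout = layout
        self.cfg = cfg or ForwardConfig()
        self.system = FemSystem(mesh, self.cfg)
        self.sources = np.stack([
            place_source(mesh, pos, source_musp) for pos in layout.source_positions
        ], axis=1)  # (N, Ns)
        det = np.asarray(layout.detector_nodes)
        n = mesh.n_nodes
        self.det_rhs = np.zeros((n, len(det)))
        self.det_rhs[det, np.arange(len(det))] = 1.0 / (2.0 * self.cfg.A)

    def predict(self, omap: OpticalMap):
        """Solve all sources; returns (flux (Ns, Nd), Phi (N, Ns))."""
        self.system.assemble(omap)
        self.system.factorize()
        phi = self.system.solve(self.sources)
        det = np.asarray(self.layout.detector_nodes)
        flux = (phi[det, :] / (2.0 * self.cfg.A)).T  # (Ns, Nd)
        return flux, phi

    def predict_frame(self, omap: OpticalMap) -> MeasurementFrame:
        flux, _ = self.predict(omap)
        return MeasurementFrame.from_flux(flux)

    def predict_stack(self, omap: OpticalMap, data: str = "logamp_phase") -> np.ndarray:
        return stack_frame(self.predict_frame(omap), data)

    def jacobian(self, omap: OpticalMap, data: str = "logamp_phase",
                 unknowns: str = "mua"):
        """Adjoint-method Jacobian of the stacked data w.r.t. nodal unknowns.

        Returns (J, flux).  Rows follow the stacking of :func:`stack_frame`
        (pair order i*Nd + j); columns are nodal mu_a, then nodal mu_s' when
        ``unknowns='mua_musp'``.
        """
        if unknowns not in ("mua", "mua_musp"):
            raise ValueError(f"unknowns must be 'mua' or 'mua_musp', got {unknowns!r}")
        flux, phi = self.predict(omap)
        psi = self.system.solve(self.det_rhs)  # adjoint fields, (N, Nd)

        tri = self.mesh.elements
        U = phi[tri]   # (E, 3, Ns)
        V = psi[tri]   # (E, 3, Nd)
        T_stiff = np.einsum("eai,eab,ebj->eij", U, self.system.S0, V, optimize=True)
        T_mass = np.einsum("eai,eab,ebj->eij", U, self.system.M0, V, optimize=True)

        _, D_e = self.system.element_coeffs(omap)
        De2 = (D_e ** 2)[:, None, None]
        n = self.mesh.n_nodes
        ns, nd = flux.shape

        def scatter(C):
            G = np.zeros((n, ns, nd), dtype=complex)
            for a in range(3):
                np.add.at(G, tri[:, a], C)
            return G.reshape(n, ns * nd)

        # dA_e/dmu_a at any of the element's 3 nodes: (1/3) M0 - D_e^2 S0
        G_mua = scatter(-(T_mass / 3.0 - De2 * T_stiff))
        blocks = [G_mua]
        if unknowns == "mua_musp":
            blocks.append(scatter(De2 * T_stiff))
        rel = [(g / flux.ravel()[None, :]) for g in blocks]  # d(log flux)/dp

        cols = []
        for g in rel:
            if data == "logamp":
                cols.append(g.real.T)
            else:
                cols.append(np.vstack([g.real.T, -g.imag.T]))
        J = np.hstack(cols)
        return J, flux


def jacobian_adjoint(mesh: Mesh2D, omap: OpticalMap, layout: OptodeLayout,
                     cfg: ForwardConfig = None, unknowns: str = "mua",
                     data: str = "logamp_phase") -> np.ndarray:
    """Convenience wrapper building a fresh operator (sources placed with the
    boundary-mean mu_s' of the map)."""
    op = ForwardOperator(mesh, layout, cfg, source_musp=float(np.mean(omap.musp)))
    J, _ = op.jacobian(omap, data=data, unknowns=unknowns)
    return J


# ---------------------------------------------------------------------------
# Levenberg-Marquardt machinery

@dataclass
class LMState:
    """State of one Levenberg-Marquardt inversion."""

    X: np.ndarray
    J: np.ndarray = None
    epsilon: np.ndarray = None
    lambda_: float = 1.0
    iteration: int = 0
    objective_history: list = field(default_factory=list)
    R: np.ndarray = None  # regularization matrix (None = identity)


def lm_step(J: np.ndarray, eps: np.ndarray, lam: float, R: np.ndarray = None) -> np.ndarray:
    """Solve the damped normal equations (J^T J + lam R) dx = J^T eps."""
    H = J.T @ J
    if R is None:
        H = H + lam * np.eye(H.shape[0])
    else:
        H = H + lam * R
    dx = np.linalg.solve(H, J.T @ eps)
    if not np.all(np.isfinite(dx)):
        raise FloatingPointError("non-finite Levenberg-Marquardt step")
    return dx


def lm_update(state: LMState, evaluate=None, max_escalations: int = 8) -> LMState:
    """One LM update (identity damping).

    Without ``evaluate`` the damped step is taken unconditionally.  With
    ``evaluate(X) -> objective`` the step is accepted only if the objective
    decreases; otherwise lambda is multiplied by 10 and the step retried, up
    to ``max_escalations`` times.  Accepted steps halve lambda.
    """
    return _lm_update(state, state.R, evaluate, max_escalations)


def lm_update_prior(state: LMState, prior: RegionPrior, evaluate=None,
                    max_escalations: int = 8) -> LMState:
    """One LM update with L^T L damping from a region prior."""
    LtL = prior.LtL()
    if LtL.shape[0] != len(state.X):
        raise ValueError("prior dimension does not match unknown vector")
    return _lm_update(state, LtL, evaluate, max_escalations)


def _lm_update(state: LMState, R, evaluate, max_escalations: int) -> LMState:
    lam = state.lambda_
    obj0 = float(state.epsilon @ state.epsilon)
    for _ in range(max_escalations + 1):
        dx = lm_step(state.J, state.epsilon, lam, R)
        X_new = state.X + dx
        if evaluate is None:
            return replace(state, X=X_new, lambda_=lam, iteration=state.iteration + 1,
                           objective_history=state.objective_history + [obj0])
        obj_new = evaluate(X_new)
        if obj_new < obj0:
            return replace(state, X=X_new, lambda_=lam / 2.0,
                           iteration=state.iteration + 1,
                           objective_history=state.objective_history + [obj_new])
        lam *= 10.0
    # no acceptable step: keep X, report the escalated lambda
    return replace(state, lambda_=lam, iteration=state.iteration + 1,
                   objective_history=state.objective_history + [obj0])


# ---------------------------------------------------------------------------
# homogeneous fitting

def fit_homogeneous(frame: MeasurementFrame, mesh: Mesh2D, layout: OptodeLayout,
                    cfg: ForwardConfig = None, x0=(0.02, 1.0)):
    """Fit a single (mu_a, mu_s') pair to amplitude and phase data.

    Two-parameter nonlinear least squares on the stacked log-amplitude +
    phase residuals; sources are re-placed at depth 1/mu_s' for each trial
    so the fit is self-consistent.
    """
    cfg = cfg or ForwardConfig()
    y = stack_frame(frame, "logamp_phase")

    def residual(x):
        mua, musp = x
        op = ForwardOperator(mesh, layout, cfg, source_musp=musp)
        omap = OpticalMap.homogeneous(mesh, mua, musp)
        return op.predict_stack(omap, "logamp_phase") - y

    res = least_squares(residual, x0, bounds=([MUA_FLOOR, 0.05], [0.5, 5.0]),
                        xtol=1e-10, ftol=1e-12, max_nfev=100)
    if not res.success:
        raise RuntimeError(f"homogeneous fit did not converge: {res.message}; "
                           f"last iterate {res.x}")
    return float(res.x[0]), float(res.x[1])


# ---------------------------------------------------------------------------
# coupling augmentation

def coupling_columns(ns: int, nd: int) -> np.ndarray:
    """Indicator Jacobian columns of log s_i and log d_j in log-amplitude
    space: entry 1 where the data row involves that optode."""
    rows = ns * nd
    cols = np.zeros((rows, ns + nd))
    for i in range(ns):
        cols[i * nd:(i + 1) * nd, i] = 1.0
    for j in range(nd):
        cols[j::nd, ns + j] = 1.0
    return cols


def gauge_rows(n_nodal: int, ns: int, nd: int, weight: float = 1.0) -> np.ndarray:
    """One penalty row enforcing sum(log s) = sum(log d).

    The factorisation s_i * d_j is degenerate only under the reciprocal
    rescaling s -> c*s, d -> d/c; this row pins it.  The common mean is left
    free so that a global amplitude scale is absorbed by the couplings, not
    forced into the image.
    """
    g = np.zeros((1, n_nodal + ns + nd))
    g[0, n_nodal:n_nodal + ns] = weight
    g[0, n_nodal + ns:] = -weight
    return g


def augment_coupling(state: LMState, layout: OptodeLayout) -> LMState:
    """Extend an LM state (log-amplitude rows) with log-coupling unknowns.

    Appends 8 log s_i + 8 log d_j unknowns (initialised at 0), their
    indicator Jacobian columns, and the gauge row pinning the reciprocal
    rescaling degeneracy.
    """
    ns, nd = layout.n_sources, layout.n_detectors
    n_nodal = len(state.X)
    X = np.concatenate([state.X, np.zeros(ns + nd)])
    J = np.hstack([state.J, coupling_columns(ns, nd)])
    J = np.vstack([J, gauge_rows(n_nodal, ns, nd)])
    eps = np.concatenate([state.epsilon, [0.0]])
    return replace(state, X=X, J=J, epsilon=eps)


# ---------------------------------------------------------------------------
# method dispatch

@dataclass
class ReconResult:
    """Outcome of one frame inversion."""

    map: OpticalMap
    coupling: CouplingFactors = None
    history: list = field(default_factory=list)   # (iteration, lambda, objective)
    homogeneous_fit: tuple = None
    method_id: int = 0


def reconstruct(frame: MeasurementFrame, mesh: Mesh2D, layout: OptodeLayout,
                method_id: int, cfg: ForwardConfig = None, *,
                region_labels: np.ndarray = None, homogeneous_init: tuple = None,
                max_iter: int = 20, rel_tol: float = 1e-3,
                prior_off_diag_sign: float = -1.0) -> ReconResult:
    """Invert one calibrated measurement frame with one of the four methods.

    1 : 64 log-amplitude + 64 phase data; unknowns mu_a and mu_s'.
    2 : 64 log-amplitude data; mu_a only, mu_s' fixed from the homogeneous fit.
    3 : Method 2 plus per-optode coupling unknowns (gauge-fixed).
    4 : Method 2 with the L^T L region prior from ``region_labels``
        (falling back to the mesh's own labels).

    ``homogeneous_init`` short-circuits the internal homogeneous fit, e.g.
    when many frames of one phantom share the same background.
    """
    if method_id not in (1, 2, 3, 4):
        raise ValueError(f"method_id must be 1..4, got {method_id}")
    cfg = cfg or ForwardConfig()
    ns, nd = layout.n_sources, layout.n_detectors

    if homogeneous_init is None:
        mua0, musp0 = fit_homogeneous(frame, mesh, layout, cfg)
    else:
        mua0, musp0 = homogeneous_init

    data = "logamp_phase" if method_id == 1 else "logamp"
    unknowns = "mua_musp" if method_id == 1 else "mua"
    y = stack_frame(frame, data)
    n = mesh.n_nodes

    op = ForwardOperator(mesh, layout, cfg, source_musp=musp0)

    with_coupling = method_id == 3
    n_extra = ns + nd if with_coupling else 0

    R = None
    if method_id == 4:
        labels = region_labels if region_labels is not None else mesh.region_labels
        if labels is None or len(np.unique(labels)) < 2:
            raise ValueError("Method 4 requires region labels on the mesh")
        R = build_region_L(labels, prior_off_diag_sign).LtL()
    elif with_coupling:
        R = np.diag(np.concatenate([np.ones(n), np.full(ns + nd, COUPLING_DAMP)]))
    if method_id == 1:
        X = np.concatenate([np.full(n, mua0), np.full(n, musp0)])
    else:
        X = np.full(n + n_extra, mua0)
        if with_coupling:
            X[n:] = 0.0

    def to_map(X):
        if method_id == 1:
            return OpticalMap(np.maximum(X[:n], MUA_FLOOR),
                              np.maximum(X[n:2 * n], MUSP_FLOOR))
        return OpticalMap(np.maximum(X[:n], MUA_FLOOR), np.full(n, musp0))

    def residual(X):
        pred = op.predict_stack(to_map(X), data)
        if with_coupling:
            pred = pred + coupling_columns(ns, nd) @ X[n:]
            eps = np.concatenate([y - pred, [X[n + ns:].sum() - X[n:n + ns].sum()]])
        else:
            eps = y - pred
        return eps

    def evaluate(X):
        e = residual(X)
        return float(e @ e)

    history = []
    eps = residual(X)
    obj = float(eps @ eps)
    lam = None
    for it in range(max_iter):
        J, _ = op.jacobian(to_map(X), data=data, unknowns=unknowns)
        if with_coupling:
            J = np.hstack([J, coupling_columns(ns, nd)])
            J = np.vstack([J, gauge_rows(n, ns, nd)])
        if lam is None:
            lam = 10.0 * float(np.mean(np.einsum("ij,ij->j", J, J)))
        Rfull = R
        if R is not None and R.shape[0] != len(X):
            pad = np.eye(len(X))
            pad[:n, :n] = R
            Rfull = pad
        state = LMState(X=X, J=J, epsilon=eps, lambda_=lam, iteration=it, R=Rfull)

        def eval_floored(X_new):
            X_new = _apply_floors(X_new, method_id, n)
            return evaluate(X_new)

        new = _lm_update(state, Rfull, eval_floored, max_escalations=8)
        accepted = new.objective_history[-1] < obj if new.objective_history else False
        X_new = _apply_floors(new.X, method_id, n)
        lam = new.lambda_
        obj_new = new.objective_history[-1]
        history.append((it, lam, obj_new))
        if not np.any(X_new != X):
            break  # no acceptable step found
        rel_change = abs(obj - obj_new) / max(obj, 1e-300)
        X = X_new
        eps = residual(X)
        obj = float(eps @ eps)
        if rel_change < rel_tol:
            break

    coupling = None
    if with_coupling:
        coupling = CouplingFactors(np.exp(X[n:n + ns]), np.exp(X[n + ns:])).gauge_fixed()
    return ReconResult(map=to_map(X), coupling=coupling, history=history,
                       homogeneous_fit=(mua0, musp0), method_id=method_id)


def _apply_floors(X: np.ndarray, method_id: int, n: int) -> np.ndarray:
    X = X.copy()
    X[:n] = np.maximum(X[:n], MUA_FLOOR)
    if method_id == 1:
        X[n:2 * n] = np.maximum(X[n:2 * n], MUSP_FLOOR)
    return X
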