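"""Morphological microstates as smooth 2D maps of the reference circular cell.

A microstate is parametrized by K = 20 coefficients: a 2x2 affine block and
16 harmonic-polynomial enrichment coefficients (orders 2..5, cos/sin, two
displacement components). The map is

    x_i(X) = A_ij X_j + R0 * sum_m [ a_im Re((z/R0)^m) + b_im Im((z/R0)^m) ]

with z = X1 + i X2. Harmonic polynomials are smooth everywhere and give
analytic deformation gradients, so kinematics reduce to precomputed
matrix-vector products (fast enough for Monte Carlo proposals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from shapely.geometry import LinearRing

from .params import CellParameters, Environment, InvalidMicrostateError

HARMONIC_ORDERS = (2, 3, 4, 5)
N_COEFFS = 4 + 4 * len(HARMONIC_ORDERS)  # affine + (cos,sin) x 2 components

_J_MIN = 1e-8


@dataclass
class ShapeState:
    """One morphological microstate: coefficient vector plus provenance."""

    coefficients: np.ndarray
    seed: int = 0
    step: int = 0

    def __post_init__(self):
        c = np.asarray(self.coefficients, dtype=float)
        if c.shape != (N_COEFFS,):
            raise ValueError(f"coefficient vector must have length {N_COEFFS}")
        self.coefficients = c

    def to_record(self) -> dict:
        return {
            "coefficients": self.coefficients.tolist(),
            "seed": int(self.seed),
            "step": int(self.step),
        }

    @classmethod
    def from_record(cls, rec: dict) -> "ShapeState":
        return cls(np.asarray(rec["coefficients"], float),
                   int(rec.get("seed", 0)), int(rec.get("step", 0)))


@dataclass
class MechanicalFields:
    """Kinematic fields on the reference quadrature grid."""

    F: np.ndarray          # (n_pts, 2, 2) deformation gradient
    lam1: np.ndarray       # (n_pts,) larger principal stretch
    lam2: np.ndarray       # (n_pts,) smaller principal stretch
    J: np.ndarray          # (n_pts,) areal stretch
    eps: np.ndarray        # (n_pts, n_phi) nominal fibre-direction strain
    nucleus: np.ndarray    # (n_pts,) bool mask, True inside nucleus


def _barycentric_diff_matrix(x: np.ndarray) -> np.ndarray:
    """Polynomial differentiation matrix on arbitrary nodes (barycentric)."""
    n = len(x)
    dx = x[:, None] - x[None, :]
    np.fill_diagonal(dx, 1.0)
    w = 1.0 / np.prod(dx, axis=1)
    D = (w[None, :] / w[:, None]) / dx
    np.fill_diagonal(D, 0.0)
    np.fill_diagonal(D, -D.sum(axis=1))
    return D


def _periodic_diff_matrix(n: int) -> np.ndarray:
    """Spectral differentiation matrix on n uniform points over [0, 2π)."""
    D = np.zeros((n, n))
    for a in range(n):
        for b in range(n):
            if a != b:
                D[a, b] = 0.5 * (-1.0) ** (a - b) / np.tan((a - b) * np.pi / n)
    return D


class Discretization:
    """Fixed quadrature and basis tables for a given cell geometry.

    Tensor product of Gauss–Legendre radial nodes with a uniform angular
    grid over the reference disc; fibre orientations are equal bins on
    [0, π). Everything that is linear in the shape coefficients (positions,
    deformation gradients) is tabulated as design matrices once.
    """

    def __init__(self, params: CellParameters, n_r: int = 16, n_theta: int = 24,
                 n_phi: int = 16, n_boundary: int = 72):
        self.params = params
        self.n_r, self.n_theta, self.n_phi = n_r, n_theta, n_phi
        R0 = params.R0

        nodes, wts = np.polynomial.legendre.leggauss(n_r)
        self.r = 0.5 * (nodes + 1.0) * R0
        wr = 0.5 * R0 * wts
        self.theta = np.arange(n_theta) * 2.0 * np.pi / n_theta
        w_theta = 2.0 * np.pi / n_theta

        Rg, Tg = np.meshgrid(self.r, self.theta, indexing="ij")
        self.X = np.stack([(Rg * np.cos(Tg)).ravel(), (Rg * np.sin(Tg)).ravel()], axis=1)
        self.w = ((wr * self.r)[:, None] * w_theta * np.ones(n_theta)).ravel()
        self.r_flat = Rg.ravel()
        self.cos_t = np.cos(Tg).ravel()
        self.sin_t = np.sin(Tg).ravel()
        self.nucleus = self.r_flat <= params.RN
        self.n_pts = self.X.shape[0]

        # fibre orientations: midpoints of n_phi equal bins on [0, π)
        self.phi = (np.arange(n_phi) + 0.5) * np.pi / n_phi
        self.cos_p = np.cos(self.phi)
        self.sin_p = np.sin(self.phi)
        self.cc = self.cos_p ** 2
        self.cs = self.cos_p * self.sin_p
        self.ss = self.sin_p ** 2

        # boundary ring on the reference circle
        tb = np.arange(n_boundary) * 2.0 * np.pi / n_boundary
        self.Xb = np.stack([R0 * np.cos(tb), R0 * np.sin(tb)], axis=1)

        # design matrices: x = BX @ c (positions), F = F_DESIGN @ c
        self.BX = self._position_design(self.X)
        self.BXb = self._position_design(self.Xb)
        self.BF = self._gradient_design(self.X)  # (4, n_pts, K): F11,F12,F21,F22

        # differentiation matrices for the traction divergence
        self.D_r = _barycentric_diff_matrix(self.r)
        self.D_theta = _periodic_diff_matrix(n_theta)

        # spatial conservation weights over the cytoplasm
        cyto = ~self.nucleus
        self.A_cyto_ref = float(self.w[cyto].sum())
        self.area_ref = float(self.w.sum())

    # --- basis tables -----------------------------------------------------
    def _harmonics(self, X: np.ndarray):
        R0 = self.params.R0
        z = (X[:, 0] + 1j * X[:, 1]) / R0
        vals, grads = [], []
        for m in HARMONIC_ORDERS:
            zm = z ** m
            g = m * z ** (m - 1) / R0  # d/dz of (z/R0)^m times... (1/R0 from chain rule)
            # value of R0*(z/R0)^m and its gradient
            vals.append(R0 * zm)
            grads.append(R0 * g)
        return vals, grads

    def _position_design(self, X: np.ndarray) -> np.ndarray:
        """(2*n, K) matrix mapping coefficients to stacked (x1, x2)."""
        n = X.shape[0]
        B = np.zeros((2 * n, N_COEFFS))
        # affine: c0..c3 = A11, A12, A21, A22
        B[:n, 0] = X[:, 0]
        B[:n, 1] = X[:, 1]
        B[n:, 2] = X[:, 0]
        B[n:, 3] = X[:, 1]
        vals, _ = self._harmonics(X)
        k = 4
        for comp in range(2):
            rows = slice(0, n) if comp == 0 else slice(n, 2 * n)
            for v in vals:
                B[rows, k] = v.real
                B[rows, k + 1] = v.imag
                k += 2
        return B

    def _gradient_design(self, X: np.ndarray) -> np.ndarray:
        """(4, n, K) tensors giving F11, F12, F21, F22 as B @ c."""
        n = X.shape[0]
        B = np.zeros((4, n, N_COEFFS))
        B[0, :, 0] = 1.0  # F11 <- A11
        B[1, :, 1] = 1.0  # F12 <- A12
        B[2, :, 2] = 1.0  # F21 <- A21
        B[3, :, 3] = 1.0  # F22 <- A22
        _, grads = self._harmonics(X)
        k = 4
        for comp in range(2):
            i11, i12 = (0, 1) if comp == 0 else (2, 3)
            for g in grads:
                # f = Re(w): grad = (Re g, -Im g);  f = Im(w): grad = (Im g, Re g)
                B[i11, :, k] = g.real
                B[i12, :, k] = -g.imag
                B[i11, :, k + 1] = g.imag
                B[i12, :, k + 1] = g.real
                k += 2
        return B

    # --- evaluations ------------------------------------------------------
    def positions(self, c: np.ndarray) -> np.ndarray:
        xy = self.BX @ c
        n = self.n_pts
        return np.stack([xy[:n], xy[n:]], axis=1)

    def boundary(self, c: np.ndarray) -> np.ndarray:
        xy = self.BXb @ c
        n = self.Xb.shape[0]
        return np.stack([xy[:n], xy[n:]], axis=1)

    def gradient(self, c: np.ndarray) -> np.ndarray:
        comp = self.BF @ c  # (4, n_pts)
        F = np.empty((self.n_pts, 2, 2))
        F[:, 0, 0], F[:, 0, 1], F[:, 1, 0], F[:, 1, 1] = comp
        return F


def make_reference_cell(params: CellParameters, seed: int = 0) -> ShapeState:
    """Identity map: the undeformed circular cell of radius R0."""
    c = np.zeros(N_COEFFS)
    c[0] = 1.0  # A11
    c[3] = 1.0  # A22
    return ShapeState(c, seed=seed, step=0)


def evaluate_kinematics(shape: ShapeState, disc: Discretization) -> MechanicalFields:
    """Deformation gradient, principal stretches, areal stretch and the
    nominal strain along each fibre orientation, on the quadrature grid.

    Raises InvalidMicrostateError if the map is degenerate (det F <= 0
    anywhere on the grid).
    """
    c = shape.coefficients
    F11, F12, F21, F22 = disc.BF @ c
    J = F11 * F22 - F12 * F21
    if np.any(J <= _J_MIN):
        raise InvalidMicrostateError("degenerate map: det F <= 0 on the grid")
    C11 = F11 ** 2 + F21 ** 2
    C12 = F11 * F12 + F21 * F22
    C22 = F12 ** 2 + F22 ** 2
    tr = C11 + C22
    disc_rt = np.sqrt(np.maximum((C11 - C22) ** 2 + 4.0 * C12 ** 2, 0.0))
    lam1 = np.sqrt(0.5 * (tr + disc_rt))
    lam2 = J / lam1
    # stretch of the unit material vector at angle phi
    lam_phi_sq = (np.outer(C11, disc.cc) + 2.0 * np.outer(C12, disc.cs)
                  + np.outer(C22, disc.ss))
    eps = np.sqrt(np.maximum(lam_phi_sq, 0.0)) - 1.0
    F = np.empty((disc.n_pts, 2, 2))
    F[:, 0, 0], F[:, 0, 1], F[:, 1, 0], F[:, 1, 1] = F11, F12, F21, F22
    return MechanicalFields(F=F, lam1=lam1, lam2=lam2, J=J, eps=eps,
                            nucleus=disc.nucleus)


def footprint_is_simple(shape: ShapeState, disc: Discretization) -> bool:
    """True iff the deformed boundary polygon does not self-intersect."""
    b = disc.boundary(shape.coefficients)
    return bool(LinearRing(b).is_simple)


def footprint_inside_island(shape: ShapeState, env: Environment,
                            disc: Discretization, tol: float = 1e-9) -> bool:
    """True iff every boundary point of the deformed footprint lies inside
    the closed square island (side sqrt(A_p), centred at the origin)."""
    half = 0.5 * env.island_side
    b = disc.boundary(shape.coefficients)
    return bool(np.all(np.abs(b) <= half + tol))


def footprint_area_boundary(shape: ShapeState, disc: Discretization) -> float:
    """Footprint area by the boundary integral ½∮(x dy − y dx).

    The deformed boundary is a trigonometric polynomial of low order in the
    boundary angle, so the periodic trapezoid rule with a spectral derivative
    is exact to round-off.
    """
    b = disc.boundary(shape.coefficients)
    x, y = b[:, 0], b[:, 1]
    n = len(x)
    k = np.fft.rfftfreq(n, d=1.0 / n) * 1j
    dx = np.fft.irfft(k * np.fft.rfft(x), n)
    dy = np.fft.irfft(k * np.fft.rfft(y), n)
    return float(abs(0.5 * np.mean(x * dy - y * dx) * 2.0 * np.pi))


def footprint_area_quadrature(shape: ShapeState, disc: Discretization) -> float:
    """Footprint area as the integral of the areal stretch J over the disc."""
    fields = evaluate_kinematics(shape, disc)
    return float(np.sum(disc.w * fields.J))


def footprint_moments(shape: ShapeState, disc: Discretization):
    """(area, centroid, 2x2 central second-moment matrix) of the footprint,
    computed as reference-domain integrals weighted by J."""
    fields = evaluate_kinematics(shape, disc)
    x = disc.positions(shape.coefficients)
    wJ = disc.w * fields.J
    area = wJ.sum()
    cen = (wJ[:, None] * x).sum(axis=0) / area
    d = x - cen
    M = np.einsum("p,pi,pj->ij", wJ, d, d) / area
    return float(area), cen, M


def aspect_ratio(shape: ShapeState, disc: Discretization) -> float:
    """Major/minor axis ratio of the best-fit (moment-equivalent) ellipse."""
    _, _, M = footprint_moments(shape, disc)
    ev = np.linalg.eigvalsh(M)
    ev = np.maximum(ev, 1e-300)
    return float(np.sqrt(ev[1] / ev[0]))
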