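"""Normalized Gibbs free energy of a morphological microstate.

Ĝ(j) = F̂passive(j) + F̂cyto(j) + F̂sub(j), where

* F̂passive — compressible 2D Ogden strain energy of cytoplasm and nucleus,
  zero and stress-free in the undeformed circular state;
* F̂cyto — free energy of the stress-fibre cytoskeleton: a spatially uniform
  unbound protein pool in Langmuir-type chemical equilibrium with bound
  contractile fibres distributed over position and orientation;
* F̂sub — elastic energy stored in the substrate by the cell tractions,
  through a Winkler-foundation compliance (zero on rigid islands).

All energies are normalized by ``params.energy_norm``.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.optimize import brentq

from .geometry import (Discretization, MechanicalFields, ShapeState,
                       evaluate_kinematics, footprint_inside_island,
                       footprint_is_simple, make_reference_cell)
from .params import (CellParameters, ConfigurationError, Environment,
                     InvalidMicrostateError)

_PSI_CLIP = 60.0
_CONSERVATION_TOL = 1e-12


@dataclass
class CytoskeletonState:
    """Chemical-equilibrium state of the stress-fibre system.

    ``eta`` and ``n_hat`` are (n_cyto_pts, n_phi) arrays over cytoplasm
    quadrature points and fibre orientations; ``N_u`` is the uniform unbound
    fraction and ``N_b = 1 - N_u`` the bound (polymerized) fraction.
    """

    eta: np.ndarray
    n_hat: np.ndarray
    psi: np.ndarray
    N_u: float
    N_b: float
    residual: float


@dataclass
class EnergyBreakdown:
    """Energy decomposition and summary observables of one microstate."""

    F_passive: float
    F_cyto: float
    F_sub: float
    G: float
    N_b: float
    area: float            # deformed footprint area, µm²
    A_hat: float           # area / (π R0²)
    aspect_ratio: float
    T_total: float         # ∫|T| dA, kPa·µm²
    T_hat_total: float     # T_total / (σmax π R0²)
    tractions: Optional[np.ndarray] = None  # (n_pts, 2) kPa, on request


def solve_unbound_fraction(E: np.ndarray, n_hat: np.ndarray,
                           weights: np.ndarray, eta_max: float,
                           nu0: float = 0.5) -> float:
    """Root of the protein-conservation equation for the unbound fraction.

    Solves  g(ν) = ν + Σ_k w_k · η̂max · n̂_k · ν E_k / (1 + ν E_k) − 1 = 0
    for ν in (0, 1). g is strictly increasing with g(0) = −1 < 0 and
    g(1) > 0, so the root exists and is unique. Damped Newton with a
    bisection fallback; the returned root satisfies |g| < 1e-12.
    """
    E = np.asarray(E, float).ravel()
    M = np.asarray(weights, float).ravel() * eta_max * np.asarray(n_hat, float).ravel() * E

    def g_and_dg(nu):
        d = 1.0 + nu * E
        return nu + nu * np.sum(M / d) - 1.0, 1.0 + np.sum(M / d ** 2)

    nu = min(max(nu0, 1e-6), 1.0 - 1e-6)
    lo, hi = 0.0, 1.0
    for _ in range(100):
        g, dg = g_and_dg(nu)
        if abs(g) < _CONSERVATION_TOL:
            return float(nu)
        if g > 0:
            hi = min(hi, nu)
        else:
            lo = max(lo, nu)
        step = g / dg
        nu_new = nu - step
        if not (lo < nu_new < hi):
            nu_new = 0.5 * (lo + hi)
        nu = nu_new
    g, _ = g_and_dg(nu)
    if abs(g) > 1e-8:
        raise InvalidMicrostateError("protein conservation equation failed to converge")
    return float(nu)


class FreeEnergyModel:
    """Evaluator of the Gibbs free energy for one (params, environment).

    Precomputes quadrature, basis and differentiation tables, then maps a
    20-coefficient shape state to an EnergyBreakdown. Used both directly and
    as the target density of the homeostatic Monte Carlo sampler.
    """

    def __init__(self, params: CellParameters, env: Environment,
                 disc: Optional[Discretization] = None):
        self.params = params
        self.env = env
        self.disc = disc if disc is not None else Discretization(params)
        d = self.disc
        # conservation weights: spatial (normalized) x angular mean; the
        # stress-fibre system spans the whole disc (the nucleus region only
        # differs in its passive modulus), keeping all fields smooth
        self.u = (d.w / d.area_ref)[:, None] * np.full(d.n_phi, 1.0 / d.n_phi)
        self._nu_warm = 0.5
        if env.kind == "elastic_uniform":
            e_eff = min(env.E_sub, params.e_sub_cap)
            self.k_winkler = params.winkler_c * e_eff / params.R0  # kPa/µm
            # chemo-mechanical feedback: steady-state fibre tension requires
            # the adhesions to hold against a resisting substrate, so the
            # attainable tension saturates with stiffness; normalized to 1
            # at the stiffness cap so that stiff gels, glass and rigid
            # islands share the same tension capacity
            cap = params.e_sub_cap
            self.tension_factor = min(1.0, (e_eff * (cap + params.E_half))
                                      / ((e_eff + params.E_half) * cap))
        else:
            self.k_winkler = np.inf  # rigid
            self.tension_factor = 1.0

    # ------------------------------------------------------------------ #
    def passive_energy(self, fields: MechanicalFields) -> float:
        """Normalized Ogden strain energy (zero and stress-free at identity)."""
        p, d = self.params, self.disc
        if np.any(fields.lam1 <= 0) or np.any(fields.lam2 <= 0):
            raise InvalidMicrostateError("non-positive principal stretch")
        m = p.ogden_m
        mu = np.where(fields.nucleus, p.mu_nucleus, p.mu_cytoplasm)
        phi = (2.0 * mu / m ** 2) * (fields.lam1 ** m + fields.lam2 ** m - 2.0
                                     - m * np.log(fields.J)) \
            + 0.5 * p.kappa * (fields.J - 1.0) ** 2
        return float(p.t0 * np.sum(d.w * phi) / p.energy_norm)

    # ------------------------------------------------------------------ #
    def _psi(self, eps_cyto: np.ndarray, sigma_max: Optional[float] = None):
        """Normalized binding advantage Ψ and fibre tension σ (kPa)."""
        p = self.params
        s_max = p.sigma_max if sigma_max is None else sigma_max
        s_max = s_max * self.tension_factor
        sigma = s_max * np.maximum(0.0, 1.0 + p.beta * eps_cyto)
        psi = (sigma * p.omega - p.mu_b0) / p.kT_hat
        return np.clip(psi, -_PSI_CLIP, _PSI_CLIP), sigma

    def cytoskeleton_equilibrium(self, fields: MechanicalFields) -> CytoskeletonState:
        """Solve the coupled chemical equilibrium + conservation problem.

        Pointwise Langmuir closure η̂ = η̂max·ν e^Ψ/(1+ν e^Ψ) with a single
        global unknown ν = N̂u fixed by protein conservation over the
        cytoplasm.
        """
        eps = fields.eps
        psi, _ = self._psi(eps)
        E = np.exp(psi)
        n_hat = np.maximum(1.0 + eps, self.params.n_min)
        nu = solve_unbound_fraction(E, n_hat, self.u, self.params.eta_max,
                                    nu0=self._nu_warm)
        self._nu_warm = nu
        eta = self.params.eta_max * nu * E / (1.0 + nu * E)
        bound = float(np.sum(self.u * eta * n_hat))
        residual = abs(nu + bound - 1.0)
        return CytoskeletonState(eta=eta, n_hat=n_hat, psi=psi, N_u=nu,
                                 N_b=1.0 - nu, residual=residual)

    def cytoskeleton_energy(self, cyto: CytoskeletonState,
                            fields: MechanicalFields) -> float:
        """Normalized cytoskeletal free energy.

        Mixing entropy of the unbound pool plus standard free energy of the
        bound fibres minus the mechanical work of fibre tension (through Ψ);
        decreases as the polymerization level N̂b rises at fixed strain.
        """
        p = self.params
        if cyto.residual > 1e-8:
            raise InvalidMicrostateError("cytoskeleton state violates conservation")
        nu = cyto.N_u
        en = cyto.eta * cyto.n_hat
        bound_term = np.sum(self.u * en * (np.log(np.maximum(en, 1e-300) / p.eta_max)
                                           - 1.0 - cyto.psi))
        bracket = nu * (np.log(nu) - 1.0) + bound_term
        return float((p.c_cyto * bracket + p.f_cyto_offset) / p.energy_norm)

    # ------------------------------------------------------------------ #
    def _nominal_stress(self, fields: MechanicalFields,
                        cyto: CytoskeletonState) -> np.ndarray:
        """First Piola–Kirchhoff stress (passive + active fibre), kPa."""
        p, d = self.params, self.disc
        m = p.ogden_m
        mu = np.where(fields.nucleus, p.mu_nucleus, p.mu_cytoplasm)
        lam = np.stack([fields.lam1, fields.lam2], axis=1)
        J = fields.J
        dphi = (2.0 * mu[:, None] / m) * (lam ** (m - 1.0) - 1.0 / lam) \
            + (p.kappa * (J - 1.0) * J)[:, None] / lam
        s = dphi / lam  # principal 2nd PK values
        F = fields.F
        C11 = F[:, 0, 0] ** 2 + F[:, 1, 0] ** 2
        C12 = F[:, 0, 0] * F[:, 0, 1] + F[:, 1, 0] * F[:, 1, 1]
        C22 = F[:, 0, 1] ** 2 + F[:, 1, 1] ** 2
        ang = 0.5 * np.arctan2(2.0 * C12, C11 - C22)
        ca, sa = np.cos(ang), np.sin(ang)
        # S = s1 n1⊗n1 + s2 n2⊗n2, n1 = (ca, sa), n2 = (-sa, ca)
        S11 = s[:, 0] * ca ** 2 + s[:, 1] * sa ** 2
        S22 = s[:, 0] * sa ** 2 + s[:, 1] * ca ** 2
        S12 = (s[:, 0] - s[:, 1]) * ca * sa
        P = np.empty_like(F)
        P[:, 0, 0] = F[:, 0, 0] * S11 + F[:, 0, 1] * S12
        P[:, 0, 1] = F[:, 0, 0] * S12 + F[:, 0, 1] * S22
        P[:, 1, 0] = F[:, 1, 0] * S11 + F[:, 1, 1] * S12
        P[:, 1, 1] = F[:, 1, 0] * S12 + F[:, 1, 1] * S22

        # active fibre stress: tension σ(ε) along the deformed fibre direction
        _, sigma = self._psi(fields.eps)
        lam_phi = 1.0 + fields.eps
        q = cyto.eta * sigma / np.maximum(lam_phi, 1e-6)  # (n_pts, n_phi)
        w_phi = 1.0 / d.n_phi
        Acc = w_phi * q @ d.cc
        Acs = w_phi * q @ d.cs
        Ass = w_phi * q @ d.ss
        P[:, 0, 0] += F[:, 0, 0] * Acc + F[:, 0, 1] * Acs
        P[:, 0, 1] += F[:, 0, 0] * Acs + F[:, 0, 1] * Ass
        P[:, 1, 0] += F[:, 1, 0] * Acc + F[:, 1, 1] * Acs
        P[:, 1, 1] += F[:, 1, 0] * Acs + F[:, 1, 1] * Ass
        return P

    def _divergence(self, P: np.ndarray) -> np.ndarray:
        """Reference-domain divergence of the nominal stress, spectral in θ."""
        d = self.disc
        nr, nt = d.n_r, d.n_theta
        out = np.empty((d.n_pts, 2))
        inv_r = 1.0 / d.r_flat
        for i in range(2):
            div = np.zeros(d.n_pts)
            for j in range(2):
                f = P[:, i, j].reshape(nr, nt)
                dfr = (d.D_r @ f).ravel()
                dft = (f @ d.D_theta.T).ravel()
                if j == 0:
                    div += d.cos_t * dfr - d.sin_t * inv_r * dft
                else:
                    div += d.sin_t * dfr + d.cos_t * inv_r * dft
            out[:, i] = div
        return out

    def substrate_energy_and_tractions(self, shape: ShapeState,
                                       fields: MechanicalFields,
                                       cyto: CytoskeletonState):
        """Traction field T (kPa), normalized substrate energy F̂sub and the
        integrated traction ∫|T| dA.

        T = t0 · Div P with rigid-body force/torque modes projected out, so
        the net force and torque the cell exerts vanish identically. On a
        Winkler foundation the substrate displaces u = T/k and stores
        F̂sub = ∫ |T|²/(2k) dA / E_norm; a rigid island stores nothing.
        """
        p, d = self.params, self.disc
        P = self._nominal_stress(fields, cyto)
        T = p.t0 * self._divergence(P)
        # project out net force and net torque (rigid modes under weights w)
        x = d.positions(shape.coefficients)
        modes = np.zeros((3, d.n_pts, 2))
        modes[0, :, 0] = 1.0
        modes[1, :, 1] = 1.0
        modes[2, :, 0] = -x[:, 1]
        modes[2, :, 1] = x[:, 0]
        G = np.einsum("p,api,bpi->ab", d.w, modes, modes)
        b = np.einsum("p,api,pi->a", d.w, modes, T)
        alpha = np.linalg.solve(G, b)
        T = T - np.einsum("a,api->pi", alpha, modes)
        Tmag = np.hypot(T[:, 0], T[:, 1])
        T_total = float(np.sum(d.w * Tmag))
        F_sub = self.winkler_energy(Tmag)
        return T, F_sub, T_total

    def winkler_energy(self, T_mag: np.ndarray) -> float:
        """F̂sub = ∫ |T|²/(2k) dA / E_norm for a traction magnitude field on
        the quadrature grid (u = T/k on the Winkler foundation; 0 if rigid)."""
        if np.isinf(self.k_winkler):
            return 0.0
        return float(np.sum(self.disc.w * np.asarray(T_mag, float) ** 2)
                     / (2.0 * self.k_winkler) / self.params.energy_norm)

    # ------------------------------------------------------------------ #
    def gibbs(self, shape: ShapeState, store_tractions: bool = False) -> EnergyBreakdown:
        """Full energy breakdown of a microstate; raises InvalidMicrostateError
        for degenerate maps, self-intersecting footprints or island violations."""
        p, d = self.params, self.disc
        if self.env.kind == "rigid_island" and not footprint_inside_island(shape, self.env, d):
            raise InvalidMicrostateError("footprint leaves the adhesive island")
        fields = evaluate_kinematics(shape, d)
        if not footprint_is_simple(shape, d):
            raise InvalidMicrostateError("self-intersecting footprint")
        F_pass = self.passive_energy(fields)
        cyto = self.cytoskeleton_equilibrium(fields)
        F_cyto = self.cytoskeleton_energy(cyto, fields)
        T, F_sub, T_total = self.substrate_energy_and_tractions(shape, fields, cyto)

        x = d.positions(shape.coefficients)
        wJ = d.w * fields.J
        area = float(wJ.sum())
        cen = (wJ[:, None] * x).sum(axis=0) / area
        dx = x - cen
        M = np.einsum("p,pi,pj->ij", wJ, dx, dx) / area
        ev = np.maximum(np.linalg.eigvalsh(M), 1e-300)
        aspect = float(np.sqrt(ev[1] / ev[0]))
        A0 = np.pi * p.R0 ** 2
        sig_ref = p.traction_norm_kpa
        return EnergyBreakdown(
            F_passive=F_pass, F_cyto=F_cyto, F_sub=F_sub,
            G=F_pass + F_cyto + F_sub,
            N_b=cyto.N_b, area=area, A_hat=area / A0, aspect_ratio=aspect,
            T_total=T_total, T_hat_total=T_total / (sig_ref * A0),
            tractions=T if store_tractions else None,
        )


# ---------------------------------------------------------------------- #
# suspension reference state
# ---------------------------------------------------------------------- #

@dataclass
class SuspensionState:
    """Equibiaxial suspended configuration balancing fibre tension against
    passive compression."""

    lam: float
    G_S: float
    F_passive: float
    F_cyto: float
    N_b: float


def _uniform_cyto(params: CellParameters, lam: float):
    """Cytoskeleton equilibrium for a uniform equibiaxial stretch lam.

    In suspension the cell has no mature focal adhesions to react fibre
    tension against, so the tension capacity is reduced by
    ``suspension_tension_factor`` (same saturation idea as the
    substrate-stiffness feedback of the adhered state)."""
    eps = lam - 1.0
    sigma = (params.sigma_max * params.suspension_tension_factor
             * max(0.0, 1.0 + params.beta * eps))
    psi = np.clip((sigma * params.omega - params.mu_b0) / params.kT_hat,
                  -_PSI_CLIP, _PSI_CLIP)
    E = float(np.exp(psi))
    n_hat = max(1.0 + eps, params.n_min)
    nu = solve_unbound_fraction(np.array([E]), np.array([n_hat]),
                                np.array([1.0]), params.eta_max)
    eta = params.eta_max * nu * E / (1.0 + nu * E)
    en = eta * n_hat
    bracket = nu * (np.log(nu) - 1.0) + en * (np.log(en / params.eta_max) - 1.0 - psi)
    f_cyto = (params.c_cyto * bracket + params.f_cyto_offset) / params.energy_norm
    return nu, eta, sigma, float(f_cyto)


def _phi_prime(lam: float, mu: float, m: float, kappa: float) -> float:
    return (4.0 * mu / m) * (lam ** (m - 1.0) - 1.0 / lam) \
        + 2.0 * kappa * lam * (lam ** 2 - 1.0)


def _phi(lam: float, mu: float, m: float, kappa: float) -> float:
    return (2.0 * mu / m ** 2) * (2.0 * lam ** m - 2.0 - 2.0 * m * np.log(lam)) \
        + 0.5 * kappa * (lam ** 2 - 1.0) ** 2


def suspension_energy(params: CellParameters) -> SuspensionState:
    """Suspended-cell reference state and its normalized Gibbs energy G_S.

    The isolated circular cell contracts until the tensile fibre stress is
    balanced by passive compressive elastic stress; with σmax = 0 the
    suspended state is the undeformed circle. Solves the 1D radial balance
    for the equibiaxial stretch λ* and evaluates G_S = F̂passive + F̂cyto.
    """
    p = params
    A_c = np.pi * (p.R0 ** 2 - p.RN ** 2)
    A_n = np.pi * p.RN ** 2

    def balance(lam):
        _, eta, sigma, _ = _uniform_cyto(p, lam)
        passive = A_c * _phi_prime(lam, p.mu_cytoplasm, p.ogden_m, p.kappa) \
            + A_n * _phi_prime(lam, p.mu_nucleus, p.ogden_m, p.kappa)
        return passive + (A_c + A_n) * eta * sigma

    if p.sigma_max == 0.0:
        lam_star = 1.0
    else:
        lo, hi = 0.2, 1.0
        if balance(lo) >= 0 or balance(hi) <= 0:
            raise ConfigurationError("no balanced suspended radius in (0.2 R0, R0)")
        lam_star = brentq(balance, lo, hi, xtol=1e-12)

    F_pass = p.t0 * (A_c * _phi(lam_star, p.mu_cytoplasm, p.ogden_m, p.kappa)
                     + A_n * _phi(lam_star, p.mu_nucleus, p.ogden_m, p.kappa)) \
        / p.energy_norm
    nu, _, _, F_cyto = _uniform_cyto(p, lam_star)
    return SuspensionState(lam=float(lam_star), G_S=float(F_pass + F_cyto),
                           F_passive=float(F_pass), F_cyto=float(F_cyto),
                           N_b=1.0 - nu)


def with_suspension(params: CellParameters) -> CellParameters:
    """Return params with the suspended-cell energy G_S cached."""
    return params.with_(G_S=suspension_energy(params).G_S)
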