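"""Homeostatic-ensemble construction by Metropolis Monte Carlo.

The equilibrium distribution over morphological microstates is
P_eq(j) ∝ exp(−ζ Ĝ(j)), with the homeostatic temperature 1/ζ fixed by the
constraint that the ensemble-average Gibbs energy equals the suspended-cell
energy, ⟨Ĝ⟩ = G_S. For continuous shape spaces ζ is found by stochastic
root-finding (pilot chains + importance-reweighted Newton updates, bisection
fallback); for enumerable toy spaces the constraint is solved exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import logsumexp
from scipy.stats import gaussian_kde

from .energy import FreeEnergyModel, EnergyBreakdown, with_suspension
from .geometry import N_COEFFS, make_reference_cell, ShapeState
from .params import CellParameters, ConfigurationError, Environment, InvalidMicrostateError

_OBS_COLUMNS = ("G", "F_passive", "F_cyto", "F_sub", "N_b",
                "area", "A_hat", "aspect_ratio", "T_total", "T_hat")


class DiagnosticsError(RuntimeError):
    """Chain failed a health check (e.g. vanishing acceptance rate)."""


# --------------------------------------------------------------------- #
# state spaces
# --------------------------------------------------------------------- #

class DiscreteSpace:
    """Enumerable toy state space with assigned Ĝ values (oracle fixture)."""

    enumerable = True

    def __init__(self, energies: Sequence[float],
                 f_cyto: Optional[Sequence[float]] = None):
        self.G = np.asarray(energies, float)
        if self.G.size == 0:
            raise ConfigurationError("empty toy state list")
        if not np.all(np.isfinite(self.G)):
            raise ConfigurationError("toy energies must be finite")
        self.F_cyto = np.asarray(f_cyto, float) if f_cyto is not None else self.G
        self.n = self.G.size

    def initial_state(self, rng: np.random.Generator):
        return 0

    def propose(self, state: int, rng: np.random.Generator, scale: float):
        return int(rng.integers(self.n))

    def energy(self, state: int) -> float:
        return float(self.G[state])

    def record(self, state: int, step: int) -> dict:
        return {"state": state, "step": step, "G": float(self.G[state]),
                "F_cyto": float(self.F_cyto[state])}

    # exact quantities for the homeostatic constraint
    def exact_peq(self, zeta: float) -> np.ndarray:
        logw = -zeta * self.G
        return np.exp(logw - logsumexp(logw))

    def exact_mean(self, zeta: float) -> float:
        return float(np.sum(self.exact_peq(zeta) * self.G))


class ShapeSpace:
    """Continuous space of 20-coefficient shape states under a free-energy
    model; Gaussian random-walk proposals on the coefficients."""

    enumerable = False

    def __init__(self, model: FreeEnergyModel, base_scales: Optional[np.ndarray] = None):
        self.model = model
        if base_scales is None:
            base_scales = np.concatenate([np.full(4, 0.02),
                                          np.full(N_COEFFS - 4, 0.012)])
        self.base_scales = np.asarray(base_scales, float)
        self._last_breakdown: Optional[EnergyBreakdown] = None

    def initial_state(self, rng: np.random.Generator) -> np.ndarray:
        c = make_reference_cell(self.model.params).coefficients.copy()
        env = self.model.env
        if env.kind == "rigid_island":
            s = min(1.0, 0.9 * env.island_side / (2.0 * self.model.params.R0))
            c[0] = c[3] = s
        return c

    def propose(self, state: np.ndarray, rng: np.random.Generator,
                scale: float) -> np.ndarray:
        return state + rng.normal(size=N_COEFFS) * (scale * self.base_scales)

    def energy(self, state: np.ndarray) -> Optional[float]:
        try:
            bd = self.model.gibbs(ShapeState(state))
        except InvalidMicrostateError:
            self._last_breakdown = None
            return None
        self._last_breakdown = bd
        return bd.G

    def record(self, state: np.ndarray, step: int) -> dict:
        bd = self._last_breakdown
        if bd is None:  # recompute (e.g. stored current state after rejection)
            bd = self.model.gibbs(ShapeState(state))
        return {"step": step, "G": bd.G, "F_passive": bd.F_passive,
                "F_cyto": bd.F_cyto, "F_sub": bd.F_sub, "N_b": bd.N_b,
                "area": bd.area, "A_hat": bd.A_hat,
                "aspect_ratio": bd.aspect_ratio, "T_total": bd.T_total,
                "T_hat": bd.T_hat_total}


# --------------------------------------------------------------------- #
# chains
# --------------------------------------------------------------------- #

@dataclass
class Chain:
    """Thinned post-burn-in Metropolis samples plus diagnostics."""

    samples: pd.DataFrame
    states: list
    acceptance_rate: float
    scale: float
    zeta: float
    seed: int
    last_state: object = None


def metropolis_chain(space, zeta: float, n_steps: int, seed: int,
                     init=None, burn_frac: float = 0.2, thin: int = 10,
                     adapt: bool = True, scale: float = 1.0,
                     min_acceptance: float = 0.01) -> Chain:
    """Metropolis chain targeting P(j) ∝ exp(−ζ Ĝ(j)).

    Symmetric Gaussian (or uniform, for discrete spaces) proposals; invalid
    proposals are rejected. The proposal scale is adapted during burn-in to
    a 25–35% acceptance target and frozen afterwards (preserving detailed
    balance in the recorded portion). Fully reproducible from ``seed``.
    """
    if n_steps < 1:
        raise ValueError("n_steps must be >= 1")
    rng = np.random.Generator(np.random.PCG64(seed))
    state = space.initial_state(rng) if init is None else init
    G = space.energy(state)
    if G is None:
        raise ConfigurationError("initial state is invalid")
    cur_rec = space.record(state, 0)

    n_burn = int(burn_frac * n_steps)
    records, states = [], []
    accepted = 0
    window_acc, window_n = 0, 0
    for step in range(1, n_steps + 1):
        prop = space.propose(state, rng, scale)
        # draw the acceptance variate unconditionally: the chain trajectory
        # then depends only on the seed, not on branch short-cuts
        u = rng.random()
        Gp = space.energy(prop)
        if Gp is not None and u < np.exp(min(0.0, -zeta * (Gp - G))):
            state, G = prop, Gp
            cur_rec = space.record(state, step)
            accepted += 1
            window_acc += 1
        window_n += 1
        if adapt and step <= n_burn and window_n >= 100:
            acc = window_acc / window_n
            scale *= float(np.exp(1.2 * (acc - 0.30)))
            scale = float(np.clip(scale, 1e-4, 1e3))
            window_acc = window_n = 0
        if step > n_burn and (step - n_burn) % thin == 0:
            rec = dict(cur_rec)
            rec["step"] = step
            records.append(rec)
            states.append(np.copy(state) if isinstance(state, np.ndarray) else state)

    acc_rate = accepted / n_steps
    if min_acceptance > 0 and acc_rate < min_acceptance and n_steps >= 1000 \
            and getattr(space, "enumerable", False) is False:
        raise DiagnosticsError(
            f"acceptance rate {acc_rate:.4f} < {min_acceptance}: "
            "reduce the proposal scale or check the energy model")
    return Chain(samples=pd.DataFrame(records), states=states,
                 acceptance_rate=acc_rate, scale=scale, zeta=zeta,
                 seed=seed, last_state=state)


# --------------------------------------------------------------------- #
# ensemble container and statistics
# --------------------------------------------------------------------- #

@dataclass
class HomeostaticEnsemble:
    """ζ plus an ordered collection of sampled microstates (one row per
    thinned sample) representing the homeostatic distribution."""

    zeta: float
    samples: pd.DataFrame
    G_S: float
    seed: int
    diagnostics: dict = field(default_factory=dict)
    coefficients: Optional[np.ndarray] = None
    params_fingerprint: str = ""
    env_fingerprint: str = ""

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    def constraint_residual(self) -> float:
        return float(abs(self.samples["G"].mean() - self.G_S))


@dataclass
class ObservableStats:
    mean: float
    std: float
    se_mean: float
    tau: float
    n: int
    n_eff: float
    density: Callable[[np.ndarray], np.ndarray]


def integrated_autocorr_time(x: np.ndarray, c: float = 5.0) -> float:
    """Integrated autocorrelation time with Sokal's adaptive window."""
    x = np.asarray(x, float)
    n = len(x)
    if n < 4 or np.std(x) == 0:
        return 1.0
    xc = x - x.mean()
    nfft = int(2 ** np.ceil(np.log2(2 * n)))
    f = np.fft.rfft(xc, nfft)
    acf = np.fft.irfft(f * np.conj(f), nfft)[:n].real
    acf /= acf[0]
    taus = 1.0 + 2.0 * np.cumsum(acf[1:])
    for m in range(1, len(taus) + 1):
        if m >= c * taus[m - 1]:
            return float(max(taus[m - 1], 1.0))
    return float(max(taus[-1], 1.0))


def ensemble_statistics(ensemble: HomeostaticEnsemble, observable: str) -> ObservableStats:
    """Mean, standard deviation, Monte-Carlo standard error (via the
    integrated autocorrelation time) and a Gaussian KDE of an observable."""
    if observable not in ensemble.samples.columns:
        raise KeyError(f"observable {observable!r} not in ensemble table")
    x = ensemble.samples[observable].to_numpy(float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples")
    mean, std = float(x.mean()), float(x.std(ddof=1))
    tau = integrated_autocorr_time(x)
    n_eff = len(x) / tau
    se = std / np.sqrt(max(n_eff, 1.0))
    if std == 0.0:
        bw = max(abs(mean), 1.0) * 1e-9

        def density(grid, _m=mean, _bw=bw):
            grid = np.asarray(grid, float)
            return np.exp(-0.5 * ((grid - _m) / _bw) ** 2) / (_bw * np.sqrt(2 * np.pi))
    else:
        kde = gaussian_kde(x, bw_method="silverman")

        def density(grid, _k=kde):
            return _k(np.asarray(grid, float))
    return ObservableStats(mean=mean, std=std, se_mean=float(se), tau=float(tau),
                           n=len(x), n_eff=float(n_eff), density=density)


def split_rhat(x: np.ndarray) -> float:
    """Split-chain potential scale reduction factor of a scalar series."""
    x = np.asarray(x, float)
    n = len(x) // 2
    if n < 2:
        return 1.0
    halves = np.stack([x[:n], x[n:2 * n]])
    W = halves.var(axis=1, ddof=1).mean()
    B = n * halves.mean(axis=1).var(ddof=1)
    if W == 0:
        return 1.0
    return float(np.sqrt((n - 1) / n + B / (n * W)))


# --------------------------------------------------------------------- #
# homeostatic constraint: solve for ζ
# --------------------------------------------------------------------- #

def _solve_zeta_exact(space: DiscreteSpace, G_S: float, tol: float) -> float:
    G = space.G
    if np.ptp(G) == 0.0:
        if abs(G[0] - G_S) <= tol * max(1.0, abs(G_S)):
            return 1.0  # documented tie-break: constraint holds for all ζ
        raise ConfigurationError("degenerate space cannot meet the target mean")
    if G_S <= G.min():
        raise ConfigurationError("target mean below the minimum reachable Ĝ")
    if G_S >= space.exact_mean(0.0):
        raise ConfigurationError("target mean at/above the ζ→0 ensemble mean")
    lo, hi = 1e-12, 1.0
    while space.exact_mean(hi) > G_S:
        hi *= 2.0
        if hi > 1e12:
            raise ConfigurationError("failed to bracket ζ")
    return float(brentq(lambda z: space.exact_mean(z) - G_S, lo, hi, xtol=1e-12))


def solve_zeta(space, G_S: float, seed: int, tol_G: float = 0.01,
               pilot_steps: int = 3000, production_steps: int = 20000,
               thin: int = 10, zeta0: float = 1.0, max_iter: int = 12,
               return_history: bool = False):
    """Find ζ* with ⟨Ĝ⟩_{ζ*} = G_S and return (ζ*, HomeostaticEnsemble).

    Enumerable spaces are solved exactly (bisection to 1e-12). Continuous
    spaces use stochastic root-finding: pilot chains at trial ζ, importance
    reweighting to estimate d⟨Ĝ⟩/dζ = −Var(Ĝ) for Newton updates, with a
    geometric-bisection fallback on the bracketing interval. The constraint
    is re-verified on the final production chain.
    """
    tol = tol_G * max(1.0, abs(G_S))
    history = []

    if getattr(space, "enumerable", False):
        zeta = _solve_zeta_exact(space, G_S, tol_G)
        chain = metropolis_chain(space, zeta, production_steps, seed, thin=thin)
        ens = HomeostaticEnsemble(zeta=zeta, samples=chain.samples, G_S=G_S,
                                  seed=seed,
                                  diagnostics={"acceptance_rate": chain.acceptance_rate,
                                               "exact": True})
        return (zeta, ens, history) if return_history else (zeta, ens)

    rng_seeds = np.random.SeedSequence(seed).generate_state(max_iter + 2)
    zeta = float(zeta0)
    zeta_cap = 1e4
    lo, hi = None, None  # lo: mean > G_S (ζ too small); hi: mean < G_S
    state, scale = None, 1.0
    mean = var = np.nan
    no_root = False
    for it in range(max_iter):
        chain = metropolis_chain(space, zeta, pilot_steps, int(rng_seeds[it]),
                                 init=state, thin=max(2, thin // 2),
                                 scale=scale, burn_frac=0.3 if it == 0 else 0.15,
                                 min_acceptance=0.0)
        state, scale = chain.last_state, chain.scale
        g = chain.samples["G"].to_numpy()
        mean, var = float(g.mean()), float(g.var())
        se = float(g.std() * np.sqrt(integrated_autocorr_time(g) / max(len(g), 1)))
        history.append({"zeta": zeta, "mean_G": mean, "var_G": var})
        if abs(mean - G_S) <= max(0.5 * tol, se):
            break
        # only assign a bracket side when the estimate is clearly off-target,
        # and drop a stale bound if noise has made the bracket inconsistent
        if mean > G_S + se:
            lo = zeta
            if hi is not None and hi <= lo:
                hi = None
        elif mean < G_S - se:
            hi = zeta
            if lo is not None and lo >= hi:
                lo = None
        if lo is not None and hi is not None:
            # Newton within the bracket, else geometric bisection
            z_new = zeta + (mean - G_S) / var if var > 0 else None
            if z_new is None or not (min(lo, hi) < z_new < max(lo, hi)):
                z_new = float(np.sqrt(lo * hi))
            zeta = z_new
        elif lo is not None:
            step = (mean - G_S) / var if var > 0 else None
            zeta = min(zeta + step, 2.0 * zeta) if step else 2.0 * zeta
            if zeta >= zeta_cap:
                # ensemble mean cannot be brought down to G_S: the constraint
                # has no root (e.g. severe confinement pins the cell near its
                # minimum-energy state). Return the cold ensemble, flagged.
                no_root = True
                zeta = zeta_cap
                break
        else:
            zeta = max(zeta - ((G_S - mean) / var if var > 0 else 0.0), 0.5 * zeta)
        zeta = float(np.clip(zeta, 1e-8, zeta_cap))

    # production chain, with corrective updates if the constraint misses;
    # the verification tolerance cannot be tighter than the Monte-Carlo
    # standard error of the mean itself
    for attempt in range(6):
        chain = metropolis_chain(space, zeta, production_steps,
                                 int(rng_seeds[max_iter + 1]) + attempt,
                                 init=state, thin=thin, scale=scale,
                                 min_acceptance=0.0)
        g = chain.samples["G"].to_numpy()
        mean, var = float(g.mean()), float(g.var())
        tau = integrated_autocorr_time(g)
        se_mean = np.sqrt(var * tau / max(len(g), 1))
        tol_eff = max(tol, 3.0 * se_mean)
        history.append({"zeta": zeta, "mean_G": mean, "var_G": var, "production": True})
        if no_root or abs(mean - G_S) <= max(tol, 2.0 * se_mean) or var <= 1e-12:
            break
        zeta = float(np.clip(zeta + (mean - G_S) / var, 1e-8, zeta_cap))
        state = chain.last_state

    if zeta >= 0.99 * zeta_cap and mean > G_S + tol_eff:
        no_root = True  # ζ pinned at its cap with the mean still above G_S
    diagnostics = {
        "acceptance_rate": chain.acceptance_rate,
        "tau_G": tau,
        "rhat_G": split_rhat(g),
        "mean_G": mean,
        "var_G": var,
        "constraint_residual": abs(mean - G_S),
        "constraint_tol": float(tol_eff),
        "constraint_ok": bool(abs(mean - G_S) <= tol_eff) and not no_root,
        "no_root": no_root,
        "proposal_scale": chain.scale,
    }
    ens = HomeostaticEnsemble(
        zeta=zeta, samples=chain.samples, G_S=G_S, seed=seed,
        diagnostics=diagnostics,
        coefficients=np.asarray(chain.states) if chain.states and isinstance(chain.states[0], np.ndarray) else None,
    )
    return (zeta, ens, history) if return_history else (zeta, ens)


# --------------------------------------------------------------------- #
# convenience front end
# --------------------------------------------------------------------- #

def sample_homeostatic_ensemble(env: Environment, params: CellParameters,
                                seed: int, production_steps: int = 200_000,
                                pilot_steps: int = 3000, thin: int = 10,
                                tol_G: float = 0.01) -> HomeostaticEnsemble:
    """End-to-end: suspension energy → ζ solve → production ensemble."""
    if params.G_S is None:
        params = with_suspension(params)
    model = FreeEnergyModel(params, env)
    space = ShapeSpace(model)
    zeta, ens = solve_zeta(space, params.G_S, seed=seed, tol_G=tol_G,
                           pilot_steps=pilot_steps,
                           production_steps=production_steps, thin=thin)
    ens.params_fingerprint = params.fingerprint()
    ens.env_fingerprint = env.fingerprint()
    return ens
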