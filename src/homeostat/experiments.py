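"""End-to-end in-silico experiments: stiffness sweeps, adhesive-island
sweeps, media comparison and ROCK-inhibition runs.

Each experiment samples one homeostatic ensemble per condition, computes
observable statistics, calibrates lineage bands on the package's own
ensembles (calibrate-then-predict), and writes CSV tables; figures are
regenerated from the CSVs so results stay auditable.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as hio
from .energy import with_suspension
from .forecast import (CalibrationResult, ForecastResult, MediaModel,
                       calibrate_bands, forecast)
from .morphometrics import l1_density_distance
from .params import CellParameters, ConfigurationError, Environment, elastic, island
from .sampler import (DiscreteSpace, HomeostaticEnsemble,
                      ensemble_statistics, sample_homeostatic_ensemble,
                      solve_zeta)

log = logging.getLogger("homeostat")

DEFAULT_STIFFNESS_KPA = (1.0, 3.0, 10.0, 30.0, 70.0)
DEFAULT_ISLAND_AREAS_UM2 = (900.0, 1600.0, 2025.0, 2725.0, 4900.0,
                            8100.0, 11025.0, 14400.0)
ROCK_SIGMA_MAX_KPA = 231.0          # treated; untreated default is 240 kPa
ROCK_ISLAND_AREA_UM2 = 2725.0

# Approximate differentiation fractions used to calibrate lineage bands,
# digitized from the experimental trends the forecasting model was built
# against: in growth media osteoblasts peak at 30 kPa (~80%, leaving ~20%
# undifferentiated) and myoblasts at 10 kPa; in mixed media small islands
# favour adipocytes and large islands osteoblasts.
GROWTH_CALIBRATION_FRACTIONS: Dict[float, Dict[str, float]] = {
    1.0: {"osteoblast": 0.0, "myoblast": 0.0},
    3.0: {"osteoblast": 0.0, "myoblast": 0.10},
    10.0: {"osteoblast": 0.05, "myoblast": 0.80},
    30.0: {"osteoblast": 0.80, "myoblast": 0.05},
    70.0: {"osteoblast": 0.10, "myoblast": 0.0},
}
MIXED_CALIBRATION_FRACTIONS: Dict[float, Dict[str, float]] = {
    900.0: {"osteoblast": 0.05, "adipocyte": 0.65},
    2025.0: {"osteoblast": 0.35, "adipocyte": 0.45},
    2725.0: {"osteoblast": 0.50, "adipocyte": 0.35},
    8100.0: {"osteoblast": 0.65, "adipocyte": 0.10},
    14400.0: {"osteoblast": 0.70, "adipocyte": 0.05},
}


@dataclass
class ExperimentConfig:
    stiffness_kpa: Sequence[float] = DEFAULT_STIFFNESS_KPA
    island_areas_um2: Sequence[float] = DEFAULT_ISLAND_AREAS_UM2
    media: str = "growth"
    sigma_max_kpa: Optional[float] = None   # override for inhibition runs
    n_steps: int = 200_000
    pilot_steps: int = 3000
    thin: int = 10
    seed: int = 0
    outdir: Optional[str] = None

    def __post_init__(self):
        if len(self.stiffness_kpa) == 0 and len(self.island_areas_um2) == 0:
            raise ConfigurationError("empty condition list")


def condition_seeds(seed: int, n: int) -> List[int]:
    """Deterministic per-condition seeds derived from one master seed."""
    return [int(s % (2 ** 31 - 1)) for s in
            np.random.SeedSequence(seed).generate_state(n, dtype=np.uint64)]


def _params(config: ExperimentConfig) -> CellParameters:
    p = CellParameters()
    if config.sigma_max_kpa is not None:
        p = p.with_(sigma_max=config.sigma_max_kpa)
    return with_suspension(p)


def sample_conditions(envs: Mapping[object, Environment], params: CellParameters,
                      config: ExperimentConfig) -> Dict[object, HomeostaticEnsemble]:
    """Sample one homeostatic ensemble per condition (never aborts a sweep:
    non-converged ensembles are flagged in diagnostics and kept)."""
    seeds = condition_seeds(config.seed, len(envs))
    out = {}
    for (key, env), s in zip(envs.items(), seeds):
        ens = sample_homeostatic_ensemble(
            env, params, seed=s, production_steps=config.n_steps,
            pilot_steps=config.pilot_steps, thin=config.thin)
        if not ens.diagnostics.get("constraint_ok", True):
            log.warning("condition %s: homeostatic constraint residual %.3g "
                        "exceeds tolerance", key, ens.diagnostics["constraint_residual"])
        out[key] = ens
        log.info("condition %s: zeta=%.4g, <G>=%.4g (G_S=%.4g), acc=%.2f",
                 key, ens.zeta, ens.samples["G"].mean(), ens.G_S,
                 ens.diagnostics.get("acceptance_rate", float("nan")))
    return out


def moments_table(ensembles: Mapping[object, HomeostaticEnsemble]) -> Dict[object, Tuple[float, float]]:
    """(µ, σ) of F̂cyto per condition."""
    out = {}
    for k, ens in ensembles.items():
        st = ensemble_statistics(ens, "F_cyto")
        out[k] = (st.mean, st.std)
    return out


@dataclass
class SweepResult:
    ensembles: Dict[object, HomeostaticEnsemble]
    media_model: MediaModel
    calibration: Optional[CalibrationResult]
    forecasts: Dict[object, ForecastResult]
    table: pd.DataFrame


def _forecast_all(ensembles, media_model) -> Dict[object, ForecastResult]:
    return {k: forecast(ens, media_model) for k, ens in ensembles.items()}


def _summary_table(ensembles, forecasts, condition_name: str) -> pd.DataFrame:
    rows = []
    for k, ens in ensembles.items():
        fc = forecasts[k]
        row = {condition_name: k, "zeta": ens.zeta,
               "mu_Fcyto": fc.mu, "sigma_Fcyto": fc.sigma,
               "undifferentiated": fc.undifferentiated,
               "constraint_ok": ens.diagnostics.get("constraint_ok", True)}
        for obs in ("A_hat", "aspect_ratio", "T_hat", "N_b"):
            st = ensemble_statistics(ens, obs)
            row[f"mean_{obs}"] = st.mean
            q = ens.samples[obs].quantile([0.25, 0.75])
            row[f"iqr_{obs}"] = float(q.loc[0.75] - q.loc[0.25])
        for lin, p in fc.probabilities.items():
            row[f"P_{lin}"] = p
        rows.append(row)
    return pd.DataFrame(rows).sort_values(condition_name).reset_index(drop=True)


def _emit(table: pd.DataFrame, config: ExperimentConfig, stem: str,
          condition_name: str) -> None:
    if config.outdir is None:
        return
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    csv_path = outdir / f"{stem}.csv"
    table.to_csv(csv_path, index=False, float_format="%.10g")
    if len(table) < 2:
        log.info("%s: single condition, plot generation skipped", stem)
        return
    _plot_from_csv(csv_path, condition_name, outdir / f"{stem}.png")


def _plot_from_csv(csv_path: Path, condition_name: str, png_path: Path) -> None:
    """Figures always regenerate from the emitted CSV, never from memory."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = pd.read_csv(csv_path)
    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 3.5))
    for col in [c for c in df.columns if c.startswith("P_")]:
        ax1.plot(df[condition_name], df[col], "o-", label=col[2:])
    ax1.plot(df[condition_name], df["undifferentiated"], "s--", label="undifferentiated")
    ax1.set_xlabel(condition_name)
    ax1.set_ylabel("lineage fraction $P_x$")
    ax1.set_xscale("log")
    ax1.legend(fontsize=8)
    ax2.errorbar(df[condition_name], df["mu_Fcyto"], yerr=df["sigma_Fcyto"], fmt="o-")
    ax2.set_xlabel(condition_name)
    ax2.set_ylabel(r"$\hat{F}_{cyto}$ (mean $\pm$ sd)")
    ax2.set_xscale("log")
    fig.tight_layout()
    fig.savefig(png_path, dpi=120)
    plt.close(fig)


def run_stiffness_sweep(config: ExperimentConfig,
                        calibration: Optional[Mapping[float, Mapping[str, float]]] = None,
                        Nc: int = 15) -> SweepResult:
    """Ensemble + forecast per substrate stiffness in growth (or mixed) media.

    Lineage bands are calibrated on this sweep's own (µ, σ) against the
    observed differentiation fractions, then used for the forecasts.
    """
    params = _params(config)
    envs = {float(E): elastic(float(E)) for E in config.stiffness_kpa}
    ensembles = sample_conditions(envs, params, config)
    moments = moments_table(ensembles)
    if calibration is None:
        calibration = (GROWTH_CALIBRATION_FRACTIONS if config.media == "growth"
                       else MIXED_CALIBRATION_FRACTIONS)
    usable = {k: v for k, v in calibration.items() if k in moments}
    cal = calibrate_bands(moments, usable, Nc=Nc, media=config.media) \
        if len(usable) >= 2 else None
    media_model = cal.media_model if cal else MediaModel(config.media, ())
    forecasts = _forecast_all(ensembles, media_model)
    table = _summary_table(ensembles, forecasts, "stiffness_kpa")
    _emit(table, config, f"stiffness_sweep_{config.media}", "stiffness_kpa")
    return SweepResult(ensembles, media_model, cal, forecasts, table)


def run_island_sweep(config: ExperimentConfig,
                     media_model: Optional[MediaModel] = None,
                     calibration: Optional[Mapping[float, Mapping[str, float]]] = None,
                     Nc: int = 15, include_reference: bool = True) -> SweepResult:
    """Ensemble + forecast per adhesive-island area on a rigid substrate.

    Includes an unpatterned E_sub = 70 kPa reference ensemble (key
    ``"unpatterned_70kPa"``) for the spreading-convergence comparison. Bands
    come from ``media_model`` if given (calibrate-then-predict across cue
    families), else are calibrated on this sweep.
    """
    params = _params(config)
    envs: Dict[object, Environment] = {float(a): island(float(a))
                                       for a in config.island_areas_um2}
    if include_reference:
        envs["unpatterned_70kPa"] = elastic(70.0)
    ensembles = sample_conditions(envs, params, config)
    island_ens = {k: v for k, v in ensembles.items() if isinstance(k, float)}
    moments = moments_table(island_ens)
    cal = None
    if media_model is None:
        if calibration is None:
            calibration = (MIXED_CALIBRATION_FRACTIONS if config.media == "mixed"
                           else GROWTH_CALIBRATION_FRACTIONS)
        usable = {k: v for k, v in calibration.items() if k in moments}
        if len(usable) >= 2:
            cal = calibrate_bands(moments, usable, Nc=Nc, media=config.media)
            media_model = cal.media_model
        else:
            media_model = MediaModel(config.media, ())
    forecasts = _forecast_all(island_ens, media_model)
    table = _summary_table(island_ens, forecasts, "island_area_um2")
    _emit(table, config, f"island_sweep_{config.media}", "island_area_um2")
    result = SweepResult(ensembles, media_model, cal, forecasts, table)
    return result


@dataclass
class RockInhibitionResult:
    untreated: HomeostaticEnsemble
    treated: HomeostaticEnsemble
    untreated_forecast: ForecastResult
    treated_forecast: ForecastResult
    l1_distances: Dict[str, float]


def run_rock_inhibition(config: ExperimentConfig, media_model: MediaModel,
                        area_um2: float = ROCK_ISLAND_AREA_UM2,
                        sigma_max_treated: float = ROCK_SIGMA_MAX_KPA) -> RockInhibitionResult:
    """Paired untreated/ROCK-inhibitor ensembles on one adhesive island.

    The inhibitor is simulated by reducing σmax (default 240 → 231 kPa).
    Reports forecasts under ``media_model`` and the comparative L1 statistic:
    L1 distance between treated/untreated densities of each direct observable
    (Â, A_s, T̂T) versus that of F̂cyto.
    """
    env = island(area_um2)
    # paired design: both arms share one seed (common random numbers), so
    # the treated-vs-untreated contrast is not polluted by chain-to-chain
    # noise in the ζ solve
    seed = condition_seeds(config.seed, 1)[0]
    p_unt = _params(config)
    p_trt = with_suspension(CellParameters(sigma_max=sigma_max_treated))
    kw = dict(production_steps=config.n_steps, pilot_steps=config.pilot_steps,
              thin=config.thin)
    ens_u = sample_homeostatic_ensemble(env, p_unt, seed=seed, **kw)
    ens_t = sample_homeostatic_ensemble(env, p_trt, seed=seed, **kw)

    l1 = {}
    for obs in ("A_hat", "aspect_ratio", "T_hat", "F_cyto"):
        a = ens_u.samples[obs].to_numpy()
        b = ens_t.samples[obs].to_numpy()
        lo = min(a.min(), b.min())
        hi = max(a.max(), b.max())
        pad = 0.2 * (hi - lo + 1e-12)
        grid = np.linspace(lo - pad, hi + pad, 400)
        l1[obs] = l1_density_distance(a, b, grid)

    fc_u = forecast(ens_u, media_model)
    fc_t = forecast(ens_t, media_model)

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        hio.save_ensemble(ens_u, outdir / "rock_untreated.csv")
        hio.save_ensemble(ens_t, outdir / "rock_treated.csv")
        (outdir / "rock_forecasts.json").write_text(json.dumps({
            "untreated": fc_u.as_dict(), "treated": fc_t.as_dict(),
            "l1_distances": l1}, indent=2))
    return RockInhibitionResult(ens_u, ens_t, fc_u, fc_t, l1)


# --------------------------------------------------------------------- #
# toy fixtures
# --------------------------------------------------------------------- #

@dataclass
class ToyEnsembleSpec:
    """Explicit enumerable state list for oracle testing."""

    G: Sequence[float]
    F_cyto: Optional[Sequence[float]] = None
    G_S: Optional[float] = None


class ToyEnsemble:
    """Enumerable fixture exposing the same sampler/forecast surface as the
    continuous shape space, with exact P_eq available by direct summation."""

    def __init__(self, spec: ToyEnsembleSpec):
        self.space = DiscreteSpace(spec.G, f_cyto=spec.F_cyto)
        self.spec = spec

    def exact_peq(self, zeta: float) -> np.ndarray:
        return self.space.exact_peq(zeta)

    def exact_mean_G(self, zeta: float) -> float:
        return self.space.exact_mean(zeta)

    def solve(self, seed: int = 0, production_steps: int = 20000,
              tol_G: float = 0.01):
        if self.spec.G_S is None:
            raise ConfigurationError("toy spec needs a target mean G_S")
        return solve_zeta(self.space, self.spec.G_S, seed=seed, tol_G=tol_G,
                          production_steps=production_steps)


def make_toy_ensemble(spec: ToyEnsembleSpec) -> ToyEnsemble:
    return ToyEnsemble(spec)
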