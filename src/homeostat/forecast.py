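"""Lineage forecasting from the homeostatic distribution of F̂cyto.

Over the 24–48 h commitment window the cell visits Nc decorrelated
morphological microstates, so by the central limit theorem the time-averaged
cytoskeletal free energy F̄cyto is Gaussian with mean µ and variance σ²/Nc,
where (µ, σ) are the mean and standard deviation of F̂cyto over the
homeostatic ensemble. A cell commits to lineage x when F̄cyto falls in the
band F̄x ± ΔF̄x; raw band probabilities are normalized by
Z_L = max(1, Σx Px), with 1 − Σx Px/Z_L remaining undifferentiated.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import norm

from .sampler import HomeostaticEnsemble, ensemble_statistics


@dataclass(frozen=True)
class LineageBand:
    """Commitment band for one lineage: centre F̄x and half-width ΔF̄x on the
    normalized-energy scale."""

    lineage: str
    center: float
    half_width: float

    def __post_init__(self):
        if self.half_width < 0:
            raise ValueError("band half-width must be >= 0")


@dataclass(frozen=True)
class MediaModel:
    """Lineage bands and the decorrelated-microstate count Nc for one medium."""

    media: str
    bands: Tuple[LineageBand, ...]
    Nc: int = 15

    def __post_init__(self):
        if self.Nc < 1:
            raise ValueError("Nc must be >= 1")
        names = [b.lineage for b in self.bands]
        if len(set(names)) != len(names):
            raise ValueError("lineage names must be unique")

    def to_dict(self) -> dict:
        return {"media": self.media, "Nc": self.Nc,
                "bands": [{"lineage": b.lineage, "center": b.center,
                           "half_width": b.half_width} for b in self.bands]}

    @classmethod
    def from_dict(cls, d: dict) -> "MediaModel":
        return cls(media=d["media"], Nc=int(d["Nc"]),
                   bands=tuple(LineageBand(b["lineage"], float(b["center"]),
                                           float(b["half_width"]))
                               for b in d["bands"]))


@dataclass
class ForecastResult:
    """Per-lineage commitment probabilities derived from (µ, σ)."""

    media: str
    mu: float
    sigma: float
    Nc: int
    raw: Dict[str, float]
    probabilities: Dict[str, float]
    undifferentiated: float
    Z_L: float
    se: Dict[str, float] = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {"media": self.media, "mu": self.mu, "sigma": self.sigma,
                "Nc": self.Nc, "raw": self.raw,
                "probabilities": self.probabilities,
                "undifferentiated": self.undifferentiated, "Z_L": self.Z_L,
                "se": self.se}


# reference band values as printed for the source calibration; on this
# package's own energy scale the default workflow recalibrates them
# (see calibrate_bands) because the absolute normalization differs.
REFERENCE_MEDIA = {
    "growth": MediaModel("growth", (
        LineageBand("osteoblast", 2.59, 0.14),
        LineageBand("myoblast", 1.87, 0.05),
    ), Nc=15),
    "mixed": MediaModel("mixed", (
        LineageBand("osteoblast", 2.59, 0.37),
        LineageBand("adipocyte", 1.61, 0.44),
    ), Nc=15),
}


def fbar_density(mu: float, sigma: float, Nc: int) -> Callable[[np.ndarray], np.ndarray]:
    """Gaussian density of the time-averaged F̄cyto: mean µ, variance σ²/Nc."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    if Nc < 1:
        raise ValueError("Nc must be >= 1")
    s = sigma / np.sqrt(Nc)

    def pdf(x):
        return norm.pdf(np.asarray(x, float), loc=mu, scale=s)

    return pdf


def lineage_probability(mu: float, sigma: float, Nc: int, band: LineageBand) -> float:
    """Raw band probability Px = ∫ over [F̄x−ΔF̄x, F̄x+ΔF̄x] of the F̄cyto density
    (closed form via the standard normal CDF)."""
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    s = sigma / np.sqrt(Nc)
    hi = norm.cdf((band.center + band.half_width - mu) / s)
    lo = norm.cdf((band.center - band.half_width - mu) / s)
    return float(hi - lo)


def normalize(raw: Mapping[str, float]) -> Tuple[Dict[str, float], float, float]:
    """Z_L normalization: returns (normalized Px, undifferentiated, Z_L)."""
    for k, v in raw.items():
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"raw probability for {k!r} outside [0, 1]")
    total = float(sum(raw.values()))
    Z_L = max(1.0, total)
    probs = {k: v / Z_L for k, v in raw.items()}
    undiff = 1.0 - total / Z_L
    return probs, undiff, Z_L


def forecast(ensemble: HomeostaticEnsemble, media: MediaModel) -> ForecastResult:
    """Forecast lineage fractions from an ensemble's F̂cyto statistics.

    Monte-Carlo standard errors on each Px are propagated from SE(µ) and
    SE(σ) by first-order sensitivity of the closed-form band probability.
    """
    stats = ensemble_statistics(ensemble, "F_cyto")
    mu, sigma = stats.mean, stats.std
    if sigma <= 0:
        raise ValueError("degenerate F_cyto distribution (zero variance)")
    raw = {b.lineage: lineage_probability(mu, sigma, media.Nc, b)
           for b in media.bands}
    probs, undiff, Z_L = normalize(raw)

    se_mu = stats.se_mean
    se_sigma = sigma / np.sqrt(2.0 * max(stats.n_eff - 1.0, 1.0))
    se = {}
    s = sigma / np.sqrt(media.Nc)
    for b in media.bands:
        zp = (b.center + b.half_width - mu) / s
        zm = (b.center - b.half_width - mu) / s
        dP_dmu = (-norm.pdf(zp) + norm.pdf(zm)) / s
        dP_dsig = (-zp * norm.pdf(zp) + zm * norm.pdf(zm)) / sigma
        se[b.lineage] = float(np.hypot(dP_dmu * se_mu, dP_dsig * se_sigma)) / Z_L
    return ForecastResult(media=media.media, mu=mu, sigma=sigma, Nc=media.Nc,
                          raw=raw, probabilities=probs,
                          undifferentiated=undiff, Z_L=Z_L, se=se)


def forecast_from_moments(mu: float, sigma: float, media: MediaModel) -> ForecastResult:
    """Forecast directly from (µ, σ) summary statistics."""
    raw = {b.lineage: lineage_probability(mu, sigma, media.Nc, b)
           for b in media.bands}
    probs, undiff, Z_L = normalize(raw)
    return ForecastResult(media=media.media, mu=mu, sigma=sigma, Nc=media.Nc,
                          raw=raw, probabilities=probs,
                          undifferentiated=undiff, Z_L=Z_L)


def calibrate_bands(moments: Mapping[object, Tuple[float, float]],
                    observed: Mapping[object, Mapping[str, float]],
                    Nc: int, media: str = "calibrated") -> "CalibrationResult":
    """Least-squares fit of (F̄x, ΔF̄x) per lineage to observed fractions.

    ``moments`` maps condition → (µ, σ) of F̂cyto; ``observed`` maps
    condition → {lineage: fraction}. Undetected lineages at a condition are
    simply absent (lumped into non-differentiation). Each lineage needs at
    least two conditions with recorded fractions.
    """
    lineages: List[str] = sorted({lin for fr in observed.values() for lin in fr})
    bands = []
    residuals: Dict[str, float] = {}
    for lin in lineages:
        conds = [c for c in observed if lin in observed[c] and c in moments]
        if len(conds) < 2:
            raise ValueError(f"lineage {lin!r} needs >= 2 calibration conditions")
        mus = np.array([moments[c][0] for c in conds])
        sigs = np.array([moments[c][1] for c in conds])
        fr = np.array([observed[c][lin] for c in conds])

        def resid(p, mus=mus, sigs=sigs, fr=fr):
            center, half = p
            s = sigs / np.sqrt(Nc)
            px = (norm.cdf((center + half - mus) / s)
                  - norm.cdf((center - half - mus) / s))
            return px - fr

        # multi-start: the objective is multi-modal in (centre, half-width),
        # so seed the fit at the µ of every condition with a nonzero observed
        # fraction, with half-widths on the scale of the CLT-narrowed spread
        starts = []
        for i in range(len(conds)):
            if fr[i] > 0 or i == int(np.argmax(fr)):
                s_i = max(sigs[i] / np.sqrt(Nc), 1e-3)
                z = norm.ppf(0.5 * (1.0 + min(fr[i], 0.999))) if fr[i] > 0 else 1.0
                starts += [np.array([mus[i], z * s_i]),
                           np.array([mus[i], 3.0 * s_i])]
        best = None
        for x0 in starts:
            sol = least_squares(resid, x0, bounds=([-np.inf, 0.0], [np.inf, np.inf]))
            if best is None or sol.cost < best.cost:
                best = sol
        bands.append(LineageBand(lin, float(best.x[0]), float(best.x[1])))
        residuals[lin] = float(np.sqrt(np.mean(best.fun ** 2)))
    model = MediaModel(media, tuple(bands), Nc=Nc)
    return CalibrationResult(media_model=model, residuals=residuals)


@dataclass
class CalibrationResult:
    media_model: MediaModel
    residuals: Dict[str, float]
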