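"""Material, biochemical and environment parameters of the cell model.

All lengths are in µm, stresses/moduli in kPa, energies in kPa·µm³ (= fJ).
Reported free energies are dimensionless: energy / ``energy_norm``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict, replace
import hashlib
import json
from typing import Optional


class ConfigurationError(ValueError):
    """Raised for physically inconsistent parameter or environment settings."""


class InvalidMicrostateError(ValueError):
    """Raised when a morphological microstate is mechanically inadmissible
    (non-positive Jacobian, self-intersecting footprint, island violation,
    or no cytoskeletal chemical equilibrium)."""


@dataclass(frozen=True)
class CellParameters:
    """Constants of the single-cell free-energy model.

    The passive cell is a 2D compressible Ogden body: a cytoplasm disc of
    radius ``R0`` with shear-like modulus ``mu_cytoplasm`` containing a
    stiffer circular nucleus of radius ``RN`` (modulus ``mu_nucleus``).
    The active stress-fibre cytoskeleton is a Langmuir-type bound/unbound
    protein system with maximum fibre tension ``sigma_max``; its closure
    constants are documented in docs/methods.md.
    """

    # geometry
    R0: float = 20.0          # reference (elastic resting) cell radius, µm
    RN: float = 6.0           # nucleus radius, µm
    t0: float = 1.0           # cell thickness used to scale 2D energy densities, µm

    # passive 2D Ogden hyperelasticity
    mu_cytoplasm: float = 6.0   # kPa
    mu_nucleus: float = 24.0    # kPa
    ogden_m: float = 3.0        # Ogden exponent (dimensionless)
    kappa: float = 4.5          # areal bulk penalty, kPa

    # stress-fibre cytoskeleton closure
    sigma_max: float = 240.0    # maximum tensile stress of a fibre, kPa
    omega: float = 0.022        # fibre-tension binding volume factor, 1/kPa
    mu_b0: float = 2.8          # normalized standard binding enthalpy (dimensionless)
    beta: float = 2.0           # strain sensitivity of fibre tension (dimensionless)
    eta_max: float = 0.9        # saturation angular fibre concentration (dimensionless)
    n_min: float = 0.3          # floor on functional units per fibre (dimensionless)
    kT_hat: float = 1.0         # normalized biochemical temperature (dimensionless)
    E_half: float = 4.0         # substrate stiffness at half-maximal fibre tension, kPa
    suspension_tension_factor: float = 0.35  # tension capacity without mature adhesions
    c_cyto: float = 700.0       # entropic energy scale of the protein pools, fJ
    f_cyto_offset: float = 7100.0  # additive offset on the cytoskeletal free energy, fJ

    # fixed reference stress for traction normalization (T̂ = |T|/σ_ref),
    # independent of sigma_max so treated/untreated runs share one scale
    traction_norm_kpa: float = 240.0

    # substrate coupling (Winkler foundation k = winkler_c * E_sub / R0)
    winkler_c: float = 8000.0   # dimensionless foundation constant
    e_sub_cap: float = 70.0     # effective stiffness cap for glass/stiff gels, kPa

    # normalization
    energy_norm: float = 1000.0  # fJ; all reported energies divided by this

    # normalized Gibbs energy of the suspended cell (filled by suspension_energy)
    G_S: Optional[float] = None

    def __post_init__(self):
        if not (self.R0 > self.RN > 0):
            raise ConfigurationError("require R0 > RN > 0")
        if self.sigma_max < 0:
            raise ConfigurationError("sigma_max must be >= 0")
        if self.energy_norm <= 0:
            raise ConfigurationError("energy_norm must be > 0")
        if min(self.mu_cytoplasm, self.mu_nucleus, self.kappa, self.t0) <= 0:
            raise ConfigurationError("moduli and thickness must be > 0")
        if self.eta_max <= 0 or self.kT_hat <= 0:
            raise ConfigurationError("eta_max and kT_hat must be > 0")

    def with_(self, **kwargs) -> "CellParameters":
        """Return a copy with selected fields replaced."""
        return replace(self, **kwargs)

    def fingerprint(self) -> str:
        d = asdict(self)
        d.pop("G_S", None)  # derived, not an input
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass(frozen=True)
class Environment:
    """Substrate the cell adheres to.

    ``elastic_uniform``: an unpatterned linear-elastic substrate of stiffness
    ``E_sub`` (kPa), coupled through a Winkler foundation.
    ``rigid_island``: a square adhesive island of area ``A_p`` (µm²) centred
    at the origin on an effectively rigid substrate (PDMS-like); the
    footprint must stay inside the island and the substrate stores no energy.
    """

    kind: str = "elastic_uniform"
    E_sub: Optional[float] = 70.0    # kPa, elastic_uniform only
    A_p: Optional[float] = None      # µm², rigid_island only
    nu_sub: float = 0.5              # substrate Poisson ratio (reserved)

    def __post_init__(self):
        if self.kind not in ("elastic_uniform", "rigid_island"):
            raise ConfigurationError(f"unknown environment kind {self.kind!r}")
        if self.kind == "elastic_uniform":
            if self.E_sub is None or self.E_sub <= 0:
                raise ConfigurationError("elastic_uniform requires E_sub > 0")
        else:
            if self.A_p is None or self.A_p <= 0:
                raise ConfigurationError("rigid_island requires A_p > 0")

    @property
    def island_side(self) -> float:
        if self.kind != "rigid_island":
            raise ConfigurationError("island_side undefined for elastic_uniform")
        return float(self.A_p) ** 0.5

    def fingerprint(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def elastic(E_sub: float) -> Environment:
    """Unpatterned elastic substrate of stiffness ``E_sub`` kPa."""
    return Environment(kind="elastic_uniform", E_sub=E_sub)


def island(A_p: float) -> Environment:
    """Square rigid adhesive island of area ``A_p`` µm²."""
    return Environment(kind="rigid_island", E_sub=None, A_p=A_p)
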