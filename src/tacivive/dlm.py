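"""Diffusion-layer-model (DLM) particle dissolution kinetics.

The dissolution rate of a population of spherical particles follows the
Nernst-Brunner form with a finite diffusion layer,

    dM/dt = S * sum_i  n_i * 4 pi r_i (r_i + h_i) * (D / h_i) * (Cs - Cb),

where ``r_i`` is the particle radius of bin ``i``, ``n_i`` its particle count,
``D`` the aqueous diffusivity, ``Cs`` the (apparent, amorphous) solubility in
the current medium, ``Cb`` the bulk concentration and ``h_i = min(r_i, hmax)``
the effective diffusion-layer thickness.  ``S`` is the dimensionless DLM
scalar, a per-region (in vivo) or per-medium (in vitro) tuning factor that
multiplies the whole rate and absorbs everything the idealized geometry does
not capture (wetting, polymer gelation, local hydrodynamics).  The rate is
floored at zero when the bulk is at or above saturation: no precipitation is
modelled.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np

__all__ = [
    "ParticleBin",
    "FormulationModel",
    "DissolutionState",
    "dlm_rate",
    "shrink_particles",
    "radius_cm_from_mass",
    "bin_rate_factors",
]

UM_TO_CM = 1e-4
#: radius below which a bin is considered exhausted (µm)
RADIUS_CUTOFF_UM = 0.01


@dataclass(frozen=True)
class ParticleBin:
    """One size bin of the particle population: radius in µm, particle count
    (possibly fractional — counts are a continuum here)."""

    radius: float  # µm
    count: float

    def __post_init__(self) -> None:
        if self.radius < 0:
            raise ValueError("radius must be >= 0")
        if self.count < 0:
            raise ValueError("count must be >= 0")

    @property
    def mass(self) -> float:
        """Bin solid mass in mg at unit density; multiply by density (g/mL)."""
        r_cm = self.radius * UM_TO_CM
        return self.count * (4.0 / 3.0) * np.pi * r_cm**3 * 1e3  # cm³ -> mg/(g/mL)


@dataclass
class FormulationModel:
    """Drug product model for dissolution simulation.

    Parameters
    ----------
    dose : float
        Label dose, mg.
    density : float
        True density of the dispersed solid, g/mL.
    diffusivity : float
        Aqueous diffusivity of the drug, cm²/s.
    bins : list of ParticleBin
        Particle-size distribution; bin counts are scaled so the total solid
        mass equals the dose.
    solubility_by_medium : mapping
        Apparent (amorphous) solubility per dissolution medium, mg/mL.
    dlm_scalars : mapping
        DLM scalar per medium name (in vitro) and/or GI region name (in vivo).
    hmax : float
        Diffusion-layer thickness cap, µm (default 30).
    label : str
        Formulation identifier.
    """

    dose: float
    density: float = 1.3
    diffusivity: float = 5e-6
    bins: list[ParticleBin] = field(default_factory=list)
    solubility_by_medium: dict[str, float] = field(default_factory=dict)
    dlm_scalars: dict[str, float] = field(default_factory=dict)
    hmax: float = 30.0
    label: str = "formulation"

    def __post_init__(self) -> None:
        if self.dose <= 0:
            raise ValueError("dose must be > 0")
        if any(s < 0 for s in self.dlm_scalars.values()):
            raise ValueError("DLM scalars must be >= 0")

    @classmethod
    def monodisperse(
        cls,
        dose: float,
        radius_um: float = 10.0,
        density: float = 1.3,
        diffusivity: float = 5e-6,
        **kwargs,
    ) -> "FormulationModel":
        """Monodisperse population carrying the full dose (the default for a
        spray-dried ASD of unknown size distribution)."""
        r_cm = radius_um * UM_TO_CM
        particle_mass_mg = (4.0 / 3.0) * np.pi * r_cm**3 * density * 1e3
        count = dose / particle_mass_mg
        return cls(dose=dose, density=density, diffusivity=diffusivity,
                   bins=[ParticleBin(radius_um, count)], **kwargs)

    def bin_masses(self) -> np.ndarray:
        """Solid mass per bin, mg."""
        return np.array([b.mass * self.density for b in self.bins])

    def bin_counts(self) -> np.ndarray:
        return np.array([b.count for b in self.bins])

    def solid_mass(self) -> float:
        return float(self.bin_masses().sum())


@dataclass
class DissolutionState:
    """Instantaneous state of a dissolving particle population in a vessel."""

    bins: list[ParticleBin]
    dissolved: float = 0.0  # mg in solution
    bulk_conc: float = 0.0  # mg/mL

    def __post_init__(self) -> None:
        if self.dissolved < 0:
            raise ValueError("dissolved must be >= 0")
        if self.bulk_conc < 0:
            raise ValueError("bulk_conc must be >= 0")


def radius_cm_from_mass(mass_mg: np.ndarray, count: np.ndarray, density: float) -> np.ndarray:
    """Invert bin mass to particle radius (cm), elementwise.

    Bins with zero count or nonpositive mass get radius 0.
    """
    mass_mg = np.asarray(mass_mg, dtype=float)
    count = np.asarray(count, dtype=float)
    out = np.zeros_like(mass_mg)
    ok = (count > 0) & (mass_mg > 0)
    # mass [mg] -> volume [cm³]: /1e3/density
    vol = mass_mg[ok] / (1e3 * density * count[ok])
    out[ok] = np.cbrt(3.0 * vol / (4.0 * np.pi))
    return out


def bin_rate_factors(
    radius_cm: np.ndarray,
    count: np.ndarray,
    diffusivity_cm2_s: float,
    hmax_um: float,
) -> np.ndarray:
    """Per-bin geometric rate factor ``n * 4 pi r (r+h) D / h`` in mL/min.

    Multiplying by a concentration difference in mg/mL yields mg/min.
    """
    r = np.asarray(radius_cm, dtype=float)
    count = np.asarray(count, dtype=float)
    h = np.minimum(r, hmax_um * UM_TO_CM)
    D = diffusivity_cm2_s * 60.0  # cm²/min
    out = np.zeros_like(r)
    ok = (r > 0) & (h > 0) & (count > 0)
    out[ok] = count[ok] * 4.0 * np.pi * r[ok] * (r[ok] + h[ok]) * D / h[ok]
    return out


def dlm_rate(
    state: DissolutionState,
    solubility: float,
    scalar: float,
    form: FormulationModel,
) -> float:
    """Total DLM dissolution rate of the population, mg/min.

    Zero when the bulk is saturated (``Cb >= Cs``); linear in the scalar.
    """
    if scalar < 0:
        raise ValueError("DLM scalar must be >= 0")
    driving = max(solubility - state.bulk_conc, 0.0)
    if driving == 0.0 or scalar == 0.0:
        return 0.0
    radii_cm = np.array([b.radius * UM_TO_CM for b in state.bins])
    counts = np.array([b.count for b in state.bins])
    factors = bin_rate_factors(radii_cm, counts, form.diffusivity, form.hmax)
    return float(scalar * factors.sum() * driving)


def shrink_particles(
    state: DissolutionState,
    dm: float,
    form: FormulationModel,
) -> DissolutionState:
    """Remove dissolved mass ``dm`` (mg) from the population at constant count.

    ``dm`` is apportioned across bins by their instantaneous DLM rate share
    (the geometric factor; the common driving force cancels).  Bins driven
    below the radius cutoff are zeroed and their residual mass moved to
    ``dissolved`` so total mass is conserved exactly.
    """
    if dm < 0:
        raise ValueError("dm must be >= 0")
    masses = np.array([b.mass * form.density for b in state.bins])
    total_solid = masses.sum()
    if dm > total_solid * (1 + 1e-9):
        raise ValueError(f"dm={dm} mg exceeds remaining solid mass {total_solid} mg")
    dm = min(dm, total_solid)
    counts = np.array([b.count for b in state.bins])
    remaining = dm
    # water-filling: bins may be exhausted before taking their full share
    while remaining > 1e-15 * max(form.dose, 1.0):
        radii_cm = radius_cm_from_mass(masses, counts, form.density)
        factors = bin_rate_factors(radii_cm, counts, form.diffusivity, form.hmax)
        tot = factors.sum()
        if tot <= 0:
            break
        take = np.minimum(remaining * factors / tot, masses)
        masses = masses - take
        remaining -= take.sum()
    radii_um = radius_cm_from_mass(masses, counts, form.density) / UM_TO_CM
    # zero out exhausted bins, moving residual mass into solution
    extra = 0.0
    new_bins: list[ParticleBin] = []
    for m, c, r in zip(masses, counts, radii_um):
        if r < RADIUS_CUTOFF_UM:
            extra += m
            new_bins.append(ParticleBin(0.0, c))
        else:
            new_bins.append(ParticleBin(float(r), float(c)))
    dissolved = state.dissolved + dm + extra
    return DissolutionState(bins=new_bins, dissolved=dissolved, bulk_conc=state.bulk_conc)
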