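"""Nine-compartment gastrointestinal transit, dissolution, absorption and
gut-wall metabolism model.

The GI tract is discretized into Stomach, Duodenum, Jejunum I-II, Ileum I-IV
and Colon.  Solid and dissolved drug transit sequentially at first-order
regional rates; within each region solid dissolves either

* mechanistically, via the diffusion-layer model with that region's DLM
  scalar against the solubility of the biorelevant medium that mimics the
  region's luminal fluid (``dlm`` input mode), or
* empirically, by applying the release hazard of a measured in vitro
  cumulative dissolution curve, lambda(t) = d'(t) / (1 - d(t)), to all solid
  wherever it resides (``profile`` input mode).  By construction the in vivo
  cumulative release then tracks the in vitro curve exactly as long as no
  other sink (fecal loss of solid) competes.

Dissolved drug is absorbed at a flux 2*Peff/R per unit lumen volume (none
from the stomach; colonic permeability scaled down), passes a per-region
enterocyte pool with first-order CYP3A4/5 metabolic loss scaled by regional
enzyme abundance, and survivors enter the portal vein.  Everything that exits
the colon is counted as fecal loss, so the model is mass-conservative by
construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy.integrate import solve_ivp

from .dlm import FormulationModel
from .media import DEFAULT_REGION_MAP, GI_REGIONS, default_media
from .pbpk import CompoundDisposition
from .usp4 import ConfigurationError, DissolutionProfile

__all__ = [
    "GIRegion",
    "GITrajectory",
    "default_regions",
    "release_hazard",
    "simulate_gi_dlm",
    "simulate_gi_profile",
]

#: fasted-state small-intestinal residence is apportioned across the seven
#: SI compartments proportionally to the in vitro media residence durations
#: (40/40/40 min for Duodenum and Jejunum I-II, 15 min each for Ileum I-IV).
_SI_TOTAL_H = 3.32
_SI_WEIGHTS = np.array([40.0, 40.0, 40.0, 15.0, 15.0, 15.0, 15.0]) / 180.0

_DEFAULT_RESIDENCE_H = np.concatenate(([0.25], _SI_TOTAL_H * _SI_WEIGHTS, [12.0]))
_DEFAULT_VOLUME_ML = np.array([50.0, 15.0, 25.0, 20.0, 10.0, 10.0, 10.0, 10.0, 50.0])
_DEFAULT_RADIUS_CM = np.array([10.0, 1.75, 1.75, 1.75, 1.75, 1.75, 1.75, 1.75, 2.5])
_DEFAULT_CYP3A = np.array([0.0, 1.0, 1.0, 0.8, 0.6, 0.5, 0.4, 0.3, 0.1])
#: no absorption from the stomach; colonic permeability scaled down
_DEFAULT_PERM_SCALE = np.array([0.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 1.0, 0.5])


@dataclass(frozen=True)
class GIRegion:
    """One GI compartment of the absorption model."""

    name: str
    transit_rate: float      # 1/h
    fluid_volume: float      # mL
    radius: float            # cm
    solubility: float        # mg/mL (matching biorelevant medium)
    dlm_scalar: float | None = None  # None = unresolved, needs sensitivity
    cyp3a_abundance: float = 0.0     # relative units
    perm_scale: float = 1.0

    def __post_init__(self) -> None:
        if self.transit_rate <= 0:
            raise ValueError(f"{self.name}: transit_rate must be > 0")
        if self.fluid_volume <= 0:
            raise ValueError(f"{self.name}: fluid_volume must be > 0")


def default_regions(
    media_solubility: Mapping[str, float] | None = None,
    scalars_by_region: Mapping[str, float] | None = None,
    region_map: Mapping[str, tuple[str, ...]] | None = None,
) -> list[GIRegion]:
    """Standard fasted physiology with regional solubility taken from the
    biorelevant medium mapped to each region.

    ``scalars_by_region`` may leave regions unset (``None``) — those must be
    resolved (e.g. by sensitivity analysis) before a DLM-mode simulation.
    """
    media = default_media(media_solubility)
    rmap = dict(region_map or DEFAULT_REGION_MAP)
    sol_by_region: dict[str, float] = {}
    for medium_name, regions in rmap.items():
        for r in regions:
            sol_by_region[r] = media[medium_name].solubility
    scalars = dict(scalars_by_region or {})
    out = []
    for i, name in enumerate(GI_REGIONS):
        out.append(GIRegion(
            name=name,
            transit_rate=1.0 / _DEFAULT_RESIDENCE_H[i],
            fluid_volume=_DEFAULT_VOLUME_ML[i],
            radius=_DEFAULT_RADIUS_CM[i],
            solubility=sol_by_region[name],
            dlm_scalar=scalars.get(name),
            cyp3a_abundance=_DEFAULT_CYP3A[i],
            perm_scale=_DEFAULT_PERM_SCALE[i],
        ))
    return out


@dataclass
class GITrajectory:
    """GI state time course plus the portal input rate function.

    All masses in mg; times in h.  ``portal_rate`` is continuous (evaluated
    from the ODE dense output) and is what the disposition model consumes.
    """

    times: np.ndarray
    solid: np.ndarray        # (n_regions, n_times)
    dissolved: np.ndarray
    enterocyte: np.ndarray
    portal_cum: np.ndarray   # cumulative absorbed-to-portal
    gut_metabolized: np.ndarray
    fecal: np.ndarray
    dose: float
    portal_rate: Callable[[float], float]

    def total_accounted(self) -> np.ndarray:
        return (self.solid.sum(axis=0) + self.dissolved.sum(axis=0)
                + self.enterocyte.sum(axis=0) + self.portal_cum
                + self.gut_metabolized + self.fecal)

    def mass_balance_error(self) -> float:
        """Max relative deviation of accounted mass from the dose."""
        return float(np.max(np.abs(self.total_accounted() - self.dose)) / self.dose)

    def fraction_absorbed(self) -> float:
        """Fraction of dose that left the lumen across the gut wall."""
        absorbed = self.portal_cum[-1] + self.gut_metabolized[-1] + self.enterocyte.sum(axis=0)[-1]
        return float(absorbed / self.dose)


def release_hazard(
    profile: DissolutionProfile,
    lambda_max: float = 50.0,
) -> Callable[[float], float]:
    """First-order release hazard (1/h) implied by a cumulative profile.

    For the piecewise-linear cumulative fraction d(t) the hazard on each
    interval is d'/(1 - d) evaluated with the interval-midpoint survivor,
    capped at ``lambda_max``; beyond the last observation the final value is
    held.  Applying this hazard to all remaining solid reproduces d(t) in the
    absence of competing solid sinks.
    """
    t_h = np.asarray(profile.times, dtype=float) / 60.0
    d = np.clip(np.asarray(profile.cum_pct, dtype=float) / 100.0, 0.0, 1.0)
    if t_h.size < 2:
        raise ValueError("profile needs at least 2 points")
    dt = np.diff(t_h)
    dd = np.maximum(np.diff(d), 0.0)
    surv_mid = 1.0 - (d[:-1] + d[1:]) / 2.0
    with np.errstate(divide="ignore", invalid="ignore"):
        lam = np.where(surv_mid > 1e-12, dd / dt / np.maximum(surv_mid, 1e-12), lambda_max)
    lam = np.minimum(lam, lambda_max)
    # immediate-release edge: everything already dissolved at the first point
    lam0 = lambda_max if d[0] >= 0.999 else lam[0]
    edges = t_h

    def hazard(t: float) -> float:
        if t < edges[0]:
            return lam0
        i = int(np.searchsorted(edges, t, side="right")) - 1
        if i >= lam.size:
            return float(lam[-1])
        return float(lam[i])

    return hazard


def _gi_core(
    form: FormulationModel,
    regions: Sequence[GIRegion],
    compound: CompoundDisposition,
    t_grid: Sequence[float],
    scalars: np.ndarray | None,
    hazard: Callable[[float], float] | None,
    rtol: float,
    atol: float,
) -> GITrajectory:
    nr = len(regions)
    if nr != len(GI_REGIONS):
        raise ValueError(f"expected {len(GI_REGIONS)} GI regions, got {nr}")
    t_grid = np.asarray(t_grid, dtype=float)
    masses0 = form.bin_masses()
    if masses0.sum() > 0:
        masses0 = masses0 * (form.dose / masses0.sum())
    counts0 = form.bin_counts()
    nb = len(masses0)

    k = np.array([r.transit_rate for r in regions])
    vol = np.array([r.fluid_volume for r in regions])
    cs = np.array([r.solubility for r in regions])
    abund = np.array([r.cyp3a_abundance for r in regions])
    # 2*Peff/R absorption rate constant per region, 1/h
    peff_cm_h = compound.Peff * 1e-4 * 3600.0
    ka = 2.0 * peff_cm_h * np.array([r.perm_scale for r in regions]) / np.array([r.radius for r in regions])
    kmet = (compound.gut_clint_3a4 + compound.gut_clint_3a5) * abund
    kout = compound.ent_kout

    # state: M (nr*nb), N (nr*nb, fraction of initial bin count), D (nr),
    # E (nr), portal_cum, gutmet_cum, fecal_cum
    iM = slice(0, nr * nb)
    iN = slice(nr * nb, 2 * nr * nb)
    iD = slice(2 * nr * nb, 2 * nr * nb + nr)
    iE = slice(2 * nr * nb + nr, 2 * nr * nb + 2 * nr)
    n_state = 2 * nr * nb + 2 * nr + 3

    y0 = np.zeros(n_state)
    y0[:nb] = masses0          # all solid starts in the stomach
    y0[iN][:nb] = 1.0

    # fused constants for the in-line DLM rate (see dlm.bin_rate_factors)
    _vol_coef = 3.0 / (4.0 * np.pi * 1e3 * form.density)  # mg -> cm³ per count
    _hmax_cm = form.hmax * 1e-4
    _D_cm2_h = form.diffusivity * 3600.0
    _eps_mg = 1e-7  # smooths the m^(1/3) rate singularity at exhaustion

    def rhs(t, y):
        M = np.maximum(y[iM].reshape(nr, nb), 0.0)
        N = np.maximum(y[iN].reshape(nr, nb), 0.0)
        D = np.maximum(y[iD], 0.0)
        E = np.maximum(y[iE], 0.0)

        if hazard is not None:
            lam = hazard(t)
            diss = lam * M  # (nr, nb) mg/h
        else:
            driving = np.maximum(cs - D / vol, 0.0)
            counts = N * counts0[None, :]
            rad = np.cbrt(_vol_coef * M / np.maximum(counts, 1e-300))
            h = np.maximum(np.minimum(rad, _hmax_cm), 1e-12)
            fac = counts * 4.0 * np.pi * rad * (rad + h) * _D_cm2_h / h
            diss = (scalars * driving)[:, None] * fac * (M / (M + _eps_mg))

        transit_M = k[:, None] * M
        transit_N = k[:, None] * N
        transit_D = k * D

        dM = -diss - transit_M
        dM[1:] += transit_M[:-1]
        dN = -transit_N
        dN[1:] += transit_N[:-1]
        absorb = ka * D
        dD = diss.sum(axis=1) - transit_D - absorb
        dD[1:] += transit_D[:-1]
        dE = absorb - (kout + kmet) * E
        d_portal = kout * E.sum()
        d_gutmet = float((kmet * E).sum())
        d_fecal = transit_M[-1].sum() + transit_D[-1]

        dy = np.empty(n_state)
        dy[iM] = dM.ravel()
        dy[iN] = dN.ravel()
        dy[iD] = dD
        dy[iE] = dE
        dy[-3] = d_portal
        dy[-2] = d_gutmet
        dy[-1] = d_fecal
        return dy

    res = None
    for method in ("LSODA", "BDF", "Radau"):  # fallbacks for extreme scalars
        res = solve_ivp(rhs, (float(t_grid[0]), float(t_grid[-1])), y0, method=method,
                        t_eval=t_grid, dense_output=True, rtol=rtol, atol=atol)
        if res.success:
            break
    if not res.success:  # pragma: no cover
        raise RuntimeError(f"GI integration failed: {res.message}")

    Y = res.y
    sol_dense = res.sol

    def portal_rate(t: float) -> float:
        t = min(max(t, t_grid[0]), t_grid[-1])
        e = np.maximum(sol_dense(t)[iE], 0.0)
        return float(kout * e.sum())

    return GITrajectory(
        times=t_grid,
        solid=Y[iM].reshape(nr, nb, -1).sum(axis=1),
        dissolved=Y[iD],
        enterocyte=Y[iE],
        portal_cum=Y[-3],
        gut_metabolized=Y[-2],
        fecal=Y[-1],
        dose=form.dose,
        portal_rate=portal_rate,
    )


def simulate_gi_dlm(
    form: FormulationModel,
    regions: Sequence[GIRegion],
    compound: CompoundDisposition,
    t_grid: Sequence[float],
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> GITrajectory:
    """Mechanistic (DLM) input mode: per-region scalars must all be resolved
    numbers, otherwise :class:`ConfigurationError` is raised."""
    scalars = []
    for r in regions:
        if not isinstance(r.dlm_scalar, (int, float)):
            raise ConfigurationError(
                f"region {r.name!r} has unresolved DLM scalar "
                f"({r.dlm_scalar!r}); run sensitivity analysis first"
            )
        if r.dlm_scalar < 0:
            raise ConfigurationError(f"region {r.name!r}: negative DLM scalar")
        scalars.append(float(r.dlm_scalar))
    return _gi_core(form, regions, compound, t_grid, np.array(scalars), None, rtol, atol)


def simulate_gi_profile(
    profile: DissolutionProfile,
    regions: Sequence[GIRegion],
    compound: CompoundDisposition,
    t_grid: Sequence[float],
    dose: float | None = None,
    lambda_max: float = 50.0,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> GITrajectory:
    """Direct dissolution-profile input mode.

    The measured cumulative curve is converted to a release hazard applied to
    transiting solid in every region.  ``dose`` defaults to 5 mg if not given.
    """
    form = FormulationModel.monodisperse(dose=dose if dose is not None else 5.0,
                                         label=profile.label)
    hazard = release_hazard(profile, lambda_max=lambda_max)
    return _gi_core(form, regions, compound, t_grid, None, hazard, rtol, atol)
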