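"""Synthetic dissolution profiles and virtual PK studies.

No dissolution or clinical dataset is deposited with the study this package
emulates, so every analysis stage is exercised on generated data with the
statistical structure the pipeline assumes:

* cumulative dissolution curves follow a Weibull release law
  F(t) = fmax (1 - exp(-(t/td)^beta)); beta > 1 gives the sigmoidal shape of
  pH-responsive (Eudragit-S100) matrices, beta <= 1 with fmax < 100 the
  plateauing, incomplete release of ethylcellulose matrices.  Additive
  Gaussian measurement noise is made monotone again by isotonic regression,
  since real cumulative data are monotone by construction;
* virtual studies draw subject parameters log-normally (between-subject
  variability) and multiply sampled concentrations by log-normal residual
  error, then write the same CSV schema the pipeline reads.

Preset parameter values are illustrative: they are pinned only to the two
landmark behaviours of the reference and test products (about 50 % released
at the 6-h end of the run; 100 % by about 2.5 h) and to the qualitative
ordering of the eight screening formulations (intra-granular surfactant >
extra-granular release; Eudragit complete, EC incomplete).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.isotonic import IsotonicRegression

from .adam import GIRegion
from .dlm import FormulationModel
from .pbpk import CompoundDisposition
from .trial import simulate_trial
from .usp4 import DissolutionProfile

__all__ = [
    "ProfileSpec",
    "StudySpec",
    "PROFILE_PRESETS",
    "gen_profile",
    "profile_from_preset",
    "gen_virtual_study",
    "study_frame",
]


@dataclass(frozen=True)
class ProfileSpec:
    """Weibull-release profile parameters."""

    shape: str = "weibull"   # "weibull" | "plateau"
    fmax: float = 100.0      # % released asymptote
    td: float = 60.0         # time scale, min
    beta: float = 1.0        # shape exponent
    noise_sd: float = 0.0    # additive noise, % points
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0 < self.fmax <= 100):
            raise ValueError("fmax must be in (0, 100]")
        if self.td <= 0 or self.beta <= 0:
            raise ValueError("td and beta must be > 0")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")


#: named presets: the reference product, the test product, and the eight
#: screening formulations (TAC1* Eudragit-S100, TAC3* ethylcellulose;
#: E = extra-granular, I = intra-granular surfactant; TAC1I8 is the test).
PROFILE_PRESETS: dict[str, ProfileSpec] = {
    "advagraf": ProfileSpec("plateau", fmax=55.0, td=120.0, beta=0.75),
    "test": ProfileSpec("weibull", fmax=100.0, td=45.0, beta=1.6),
    "TAC1E5": ProfileSpec("weibull", fmax=90.0, td=120.0, beta=1.5),
    "TAC1E8": ProfileSpec("weibull", fmax=95.0, td=100.0, beta=1.5),
    "TAC1I8": ProfileSpec("weibull", fmax=100.0, td=45.0, beta=1.6),
    "TAC1I7": ProfileSpec("weibull", fmax=98.0, td=70.0, beta=1.5),
    "TAC3E5": ProfileSpec("plateau", fmax=45.0, td=160.0, beta=0.9),
    "TAC3E6": ProfileSpec("plateau", fmax=50.0, td=150.0, beta=0.9),
    "TAC3I5": ProfileSpec("plateau", fmax=55.0, td=130.0, beta=0.8),
    "TAC3I6": ProfileSpec("plateau", fmax=58.0, td=120.0, beta=0.8),
}


def gen_profile(
    spec: ProfileSpec,
    t_grid: Sequence[float] | None = None,
    label: str = "synthetic",
) -> DissolutionProfile:
    """Generate a cumulative dissolution profile on ``t_grid`` (default
    0-360 min, 10-min spacing), deterministic for a fixed seed."""
    if t_grid is None:
        t_grid = np.arange(0.0, 360.0 + 1e-9, 10.0)
    t = np.asarray(t_grid, dtype=float)
    f = spec.fmax * (1.0 - np.exp(-np.power(t / spec.td, spec.beta)))
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        f = f + rng.normal(0.0, spec.noise_sd, size=f.shape)
        f = IsotonicRegression(y_min=0.0, y_max=100.0).fit_transform(t, f)
    f = np.clip(f, 0.0, 100.0)
    return DissolutionProfile(times=t, cum_pct=f, label=label)


def profile_from_preset(
    name: str,
    t_grid: Sequence[float] | None = None,
    noise_sd: float | None = None,
    seed: int | None = None,
) -> DissolutionProfile:
    spec = PROFILE_PRESETS[name]
    if noise_sd is not None or seed is not None:
        spec = ProfileSpec(spec.shape, spec.fmax, spec.td, spec.beta,
                           noise_sd if noise_sd is not None else spec.noise_sd,
                           seed if seed is not None else spec.seed)
    return gen_profile(spec, t_grid, label=name)


@dataclass(frozen=True)
class StudySpec:
    """Virtual single-dose study design: 12 healthy subjects, one 5-mg dose,
    whole-blood sampling over 144 h."""

    n_subjects: int = 12
    dose: float = 5.0  # mg
    variability_cv: Mapping[str, float] = field(default_factory=lambda: {
        "CLint_3A4": 0.35, "Vc": 0.25, "Peff": 0.20, "Q_dist": 0.15,
    })
    residual_cv: float = 0.10
    seed: int = 0
    sample_times_h: tuple[float, ...] = (
        0.0, 0.5, 1.0, 1.5, 2.0, 2.5, 3.0, 3.5, 4.0, 5.0, 6.0, 8.0, 12.0,
        16.0, 24.0, 36.0, 48.0, 72.0, 96.0, 120.0, 144.0,
    )

    def __post_init__(self) -> None:
        if self.n_subjects < 1:
            raise ValueError("n_subjects must be >= 1")
        if self.dose <= 0:
            raise ValueError("dose must be > 0")
        if self.residual_cv < 0:
            raise ValueError("residual_cv must be >= 0")


def sample_with_residual(
    subjects,
    sample_times_h,
    residual_cv: float,
    seed: int,
) -> list:
    """Apply the observation process to simulated profiles: sample at the
    clinical schedule and multiply by log-normal residual error.

    The residual stream is derived from ``seed`` alone, so two simulations
    run with the same seed see identical error realizations — the common-
    random-numbers device the calibration stages rely on.
    """
    from .pbpk import PKProfile  # local import; avoids a hard dependency cycle

    rng = np.random.default_rng(np.random.SeedSequence([seed, 7]))
    times = np.asarray(sample_times_h, dtype=float)
    s = np.sqrt(np.log1p(residual_cv**2)) if residual_cv > 0 else 0.0
    out = []
    for prof in subjects:
        conc = np.interp(times, prof.times, prof.conc_blood)
        if s > 0:
            conc = conc * rng.lognormal(-0.5 * s**2, s, size=conc.shape)
        conc[times == 0.0] = 0.0
        out.append(PKProfile(times.copy(), conc, prof.subject_id))
    return out


def gen_virtual_study(
    disp: CompoundDisposition,
    regions: Sequence[GIRegion],
    spec: StudySpec,
    mode: str = "dlm",
    form: FormulationModel | None = None,
    profile: DissolutionProfile | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Simulate an observed-style study and return (data frame, ground truth).

    The frame has columns ``subject_id,time_h,conc_ng_ml``; ground truth
    records the generating scalars, disposition parameters and study design
    so parameter-recovery tests can compare against it.
    """
    trial = simulate_trial(disp, regions, spec.variability_cv,
                           n=spec.n_subjects, seed=spec.seed, mode=mode,
                           form=form, profile=profile, dose=spec.dose)
    sampled = sample_with_residual(trial.population.subjects,
                                   spec.sample_times_h, spec.residual_cv,
                                   spec.seed)
    rows = []
    for prof in sampled:
        for t, c in zip(prof.times, prof.conc_blood):
            rows.append({"subject_id": prof.subject_id, "time_h": t,
                         "conc_ng_ml": c})
    frame = pd.DataFrame(rows)
    truth = {
        "mode": mode,
        "dose_mg": spec.dose,
        "n_subjects": spec.n_subjects,
        "seed": spec.seed,
        "residual_cv": spec.residual_cv,
        "variability_cv": dict(spec.variability_cv),
        "dlm_scalars_by_region": {r.name: r.dlm_scalar for r in regions},
        "disposition": {k: getattr(disp, k) for k in (
            "Vc", "Vp", "Q_dist", "CLint_3A4", "CLint_3A5", "fu_plasma",
            "Q_h", "Peff", "bp_max", "bp_c50")},
    }
    return frame, truth


def study_frame(result_subjects) -> pd.DataFrame:
    """Long-format frame (subject_id,time_h,conc_ng_ml) from PK profiles."""
    rows = []
    for prof in result_subjects:
        for t, c in zip(prof.times, prof.conc_blood):
            rows.append({"subject_id": prof.subject_id, "time_h": t, "conc_ng_ml": c})
    return pd.DataFrame(rows)
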