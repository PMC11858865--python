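"""GI absorption model: conservation, limits, hazard identity, input modes."""

from dataclasses import replace

import numpy as np
import pytest

from tacivive.adam import (default_regions, release_hazard, simulate_gi_dlm,
                           simulate_gi_profile)
from tacivive.dlm import FormulationModel
from tacivive.metrics import compute_metrics
from tacivive.pbpk import CompoundDisposition
from tacivive.sensitivity import apply_scalars
from tacivive.synthetic import profile_from_preset
from tacivive.trial import simulate_subject
from tacivive.usp4 import ConfigurationError, DissolutionProfile

GRID = np.linspace(0.0, 144.0, 37)


def test_unresolved_scalar_is_configuration_error(form, disposition):
    regions = default_regions(scalars_by_region={"Stomach": 1.0})  # rest None
    with pytest.raises(ConfigurationError, match="sensitivity"):
        simulate_gi_dlm(form, regions, disposition, GRID)


def test_zero_permeability_all_fecal(form, regions_resolved):
    disp = replace(CompoundDisposition(), Peff=0.0)
    gi = simulate_gi_dlm(form, regions_resolved, disp, np.linspace(0, 600, 31))
    assert gi.fraction_absorbed() == pytest.approx(0.0, abs=1e-9)
    assert gi.fecal[-1] == pytest.approx(form.dose, rel=1e-3)
    assert gi.mass_balance_error() < 1e-6


def test_mass_balance_dlm_mode(form, regions_resolved, disposition):
    gi = simulate_gi_dlm(form, regions_resolved, disposition, GRID)
    assert gi.mass_balance_error() < 1e-6
    assert np.all(gi.solid >= -1e-9) and np.all(gi.dissolved >= -1e-9)


def test_release_monotone_in_scalar(form, disposition, regions_resolved):
    """Raising a region's DLM scalar never decreases in vivo release."""
    released = []
    for ileum in (0.01, 0.1, 1.0):
        regions = apply_scalars(regions_resolved, ileum, 0.5)
        gi = simulate_gi_dlm(form, regions, disposition, GRID)
        released.append(form.dose - gi.solid.sum(axis=0)[-1])
    assert released[0] <= released[1] + 1e-9 <= released[2] + 2e-9


def test_hazard_reconstructs_cumulative_curve():
    """1 - exp(-int lambda) must reproduce the cumulative fraction."""
    prof = profile_from_preset("advagraf")
    lam = release_hazard(prof)
    t_h = prof.times / 60.0
    # integrate the piecewise-constant hazard over the profile span
    from scipy.integrate import quad
    for t_end, d_expected in [(1.0, None), (3.0, None), (6.0, None)]:
        integral = quad(lam, 0, t_end, limit=200)[0]
        d = 1 - np.exp(-integral)
        d_obs = np.interp(t_end, t_h, prof.cum_pct / 100.0)
        assert d == pytest.approx(d_obs, abs=5e-3)


def test_profile_mode_tracks_in_vitro_release(regions_resolved, disposition):
    """With no competing solid sink, total in vivo release at 6 h equals the
    in vitro cumulative fraction (hazard-construction identity)."""
    prof = profile_from_preset("advagraf")
    # suppress fecal solid loss within the window: near-infinite colon residence
    regions = [replace(r, transit_rate=1e-4) if r.name == "Colon" else r
               for r in regions_resolved]
    gi = simulate_gi_profile(prof, regions, disposition, np.linspace(0, 6, 25),
                             dose=5.0)
    solid_left = gi.solid.sum(axis=0)[-1]
    released = 1 - solid_left / 5.0
    d6 = prof.cum_pct[-1] / 100.0
    assert released == pytest.approx(d6, abs=0.01)
    assert gi.mass_balance_error() < 1e-6


def test_profile_zero_release_all_fecal(regions_resolved, disposition):
    prof = DissolutionProfile(np.arange(0, 361, 10.0), np.zeros(37), "null")
    gi = simulate_gi_profile(prof, regions_resolved, disposition,
                             np.linspace(0, 600, 31), dose=5.0)
    assert gi.portal_cum[-1] == pytest.approx(0.0, abs=1e-9)
    assert gi.fecal[-1] == pytest.approx(5.0, rel=1e-3)


def test_step_profile_equals_infinite_scalar(form, regions_resolved, disposition):
    """Direct input of an instantaneous-release curve and the mechanistic mode
    with scalar -> infinity agree within 1 % on AUC and Cmax.

    The identity requires a non-saturating configuration: the hazard input has
    no solubility ceiling, whereas the mechanistic rate is always capped at
    Cs, so regional solubilities are raised far above dose/volume here."""
    regions = [replace(r, dlm_scalar=1e6, solubility=0.5) for r in regions_resolved]
    pk_dlm, _ = simulate_subject(disposition, regions, mode="dlm", form=form)
    step = DissolutionProfile(np.array([0.0, 1.0, 360.0]),
                              np.array([100.0, 100.0, 100.0]), "step")
    pk_step, _ = simulate_subject(disposition, regions, mode="profile",
                                  profile=step)
    m1, m2 = compute_metrics(pk_dlm), compute_metrics(pk_step)
    assert m2.auc_0_144 == pytest.approx(m1.auc_0_144, rel=0.01)
    assert m2.cmax == pytest.approx(m1.cmax, rel=0.01)


def test_ileum_scalar_directional_report(form, disposition, regions_resolved, capsys):
    """Report-only check of the distal sensitivity directions: the colon
    scalar should raise exposure markedly; the ileum-scalar direction depends
    on regional CYP3A settings and is reported, not asserted."""
    rows = {}
    for ileum in (0.005, 0.05, 0.5):
        pk, _ = simulate_subject(disposition, apply_scalars(regions_resolved, ileum, 0.5),
                                 mode="dlm", form=form)
        rows[ileum] = compute_metrics(pk)
    tmax = [rows[i].tmax for i in (0.005, 0.05, 0.5)]
    trend = "decreasing" if tmax[0] >= tmax[1] >= tmax[2] else "not decreasing"
    print(f"Tmax vs ileum scalar {tmax}: {trend} (report-only)")
    assert len(rows) == 3
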