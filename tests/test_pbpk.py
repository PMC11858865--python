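"""Disposition model: B:P partitioning, biexponential oracle, population."""

from dataclasses import replace

import numpy as np
import pytest

from tacivive.metrics import compute_metrics
from tacivive.pbpk import (CompoundDisposition, blood_to_plasma, simulate_pk,
                           simulate_population)


def test_blood_to_plasma_limits_and_midpoint(disposition):
    assert blood_to_plasma(0.0, disposition) == pytest.approx(disposition.bp_max)
    mid = blood_to_plasma(disposition.bp_c50, disposition)
    assert mid == pytest.approx(1 + (disposition.bp_max - 1) / 2)
    flat = replace(disposition, bp_max=1.0)
    for cp in (0.0, 1.0, 100.0):
        assert blood_to_plasma(cp, flat) == pytest.approx(1.0)
    with pytest.raises(ValueError):
        blood_to_plasma(-1.0, disposition)
    # decreasing and bounded
    grid = np.linspace(0, 100, 50)
    bp = blood_to_plasma(grid, disposition)
    assert np.all(np.diff(bp) < 0) and bp.min() >= 1.0


def test_biexponential_closed_form_oracle():
    """With linear B:P the bolus response is the textbook 2-compartment
    biexponential; the ODE solution must match within 0.1 %."""
    disp = replace(CompoundDisposition(), bp_max=1.0)
    fu = disp.fu_plasma
    clh = disp.Q_h * fu * disp.clint_total / (disp.Q_h + fu * disp.clint_total)
    k10, k12, k21 = clh / disp.Vc, disp.Q_dist / disp.Vc, disp.Q_dist / disp.Vp
    b = k10 + k12 + k21
    disc = np.sqrt(b * b - 4 * k10 * k21)
    alpha, beta = (b + disc) / 2, (b - disc) / 2
    dose = 5.0
    t = np.linspace(0.01, 144.0, 200)
    ref = (dose / disp.Vc * ((alpha - k21) * np.exp(-alpha * t)
                             - (beta - k21) * np.exp(-beta * t)) / (alpha - beta)) * 1000
    pk = simulate_pk(lambda _t: 0.0, disp, np.concatenate([[0.0], t]),
                     central_bolus=dose)
    assert np.max(np.abs(pk.conc_blood[1:] - ref) / ref) < 1e-3


def test_zero_input_zero_profile(disposition):
    pk = simulate_pk(lambda t: 0.0, disposition, np.linspace(0, 144, 50))
    assert np.allclose(pk.conc_blood, 0.0)


def test_dose_linearity_with_linear_bp():
    disp = replace(CompoundDisposition(), bp_max=1.0)
    t = np.linspace(0, 144, 80)

    def pulse(scale):
        return lambda tt: scale * (1.0 if tt < 1.0 else 0.0)

    one = simulate_pk(pulse(1.0), disp, t).conc_blood
    two = simulate_pk(pulse(2.0), disp, t).conc_blood
    assert np.allclose(two, 2 * one, rtol=1e-6, atol=1e-9)


def test_auc_monotone_in_clearance(disposition):
    t = np.linspace(0, 144, 80)
    aucs = []
    for mult in (0.5, 1.0, 2.0):
        disp = replace(disposition, CLint_3A4=disposition.CLint_3A4 * mult)
        pk = simulate_pk(lambda tt: 1.0 if tt < 2.0 else 0.0, disp, t)
        aucs.append(compute_metrics(pk).auc_0_144)
    assert aucs[0] > aucs[1] > aucs[2]


def _portal_factory(disp):
    return lambda t: 1.0 if t < 2.0 else 0.0


def test_population_zero_cv_collapses_to_mean(disposition):
    t = np.linspace(0, 144, 60)
    pop = simulate_population(_portal_factory, disposition, {"Vc": 0.0}, n=4,
                              seed=3, t_grid=t)
    for subj in pop.subjects:
        assert np.allclose(subj.conc_blood, pop.mean.conc_blood)
    assert np.allclose(pop.p5.conc_blood, pop.p95.conc_blood)


def test_population_seed_determinism(disposition):
    t = np.linspace(0, 144, 60)
    cv = {"CLint_3A4": 0.3, "Vc": 0.2}
    a = simulate_population(_portal_factory, disposition, cv, n=6, seed=11, t_grid=t)
    b = simulate_population(_portal_factory, disposition, cv, n=6, seed=11, t_grid=t)
    c = simulate_population(_portal_factory, disposition, cv, n=6, seed=12, t_grid=t)
    assert np.array_equal(a.mean.conc_blood, b.mean.conc_blood)
    assert not np.array_equal(a.mean.conc_blood, c.mean.conc_blood)


def test_population_cv_propagates_to_auc_spread(disposition):
    """Empirical AUC CV grows with the input clearance CV (seeded)."""
    t = np.linspace(0, 144, 60)

    def auc_cv(cv_in):
        pop = simulate_population(_portal_factory, disposition,
                                  {"CLint_3A4": cv_in}, n=40, seed=5, t_grid=t)
        aucs = np.array([compute_metrics(p).auc_0_144 for p in pop.subjects])
        return aucs.std(ddof=1) / aucs.mean()

    assert auc_cv(0.1) < auc_cv(0.3) < auc_cv(0.6)
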