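"""Diffusion-layer dissolution kinetics: rate law, shrinkage, conservation."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from tacivive.dlm import (DissolutionState, FormulationModel, ParticleBin,
                          dlm_rate, shrink_particles)


def _state(radius=10.0, count=1.0, bulk=0.0):
    return DissolutionState(bins=[ParticleBin(radius, count)], bulk_conc=bulk)


@pytest.fixture(scope="module")
def mono():
    return FormulationModel.monodisperse(dose=5.0)


def test_rate_zero_at_saturation_and_zero_scalar(mono):
    st8 = _state(bulk=0.05)
    assert dlm_rate(st8, solubility=0.05, scalar=1.0, form=mono) == 0.0
    assert dlm_rate(_state(), solubility=0.05, scalar=0.0, form=mono) == 0.0
    with pytest.raises(ValueError):
        dlm_rate(_state(), solubility=0.05, scalar=-1.0, form=mono)


def test_single_particle_closed_form(mono):
    # for r <= hmax the diffusion layer is the radius itself and the rate
    # collapses to scalar * 8 pi r D (Cs - Cb)
    r_um, cs, scalar = 10.0, 0.008, 0.7
    rate = dlm_rate(_state(radius=r_um, count=1.0), cs, scalar, mono)
    r_cm = r_um * 1e-4
    expected = scalar * 8 * np.pi * r_cm * (mono.diffusivity * 60) * cs
    assert rate == pytest.approx(expected, rel=1e-12)


@given(scale=st.floats(0.1, 10.0), cs=st.floats(1e-4, 0.1),
       cb_frac=st.floats(0.0, 0.99))
@settings(max_examples=50, deadline=None)
def test_rate_scalar_linearity_and_monotonicity(scale, cs, cb_frac):
    form = FormulationModel.monodisperse(dose=5.0)
    state = _state(bulk=cb_frac * cs)
    base = dlm_rate(state, cs, 1.0, form)
    assert dlm_rate(state, cs, scale, form) == pytest.approx(scale * base, rel=1e-12)
    # nondecreasing in the driving force
    richer = dlm_rate(_state(bulk=0.0), cs, 1.0, form)
    assert richer >= base


def test_rate_monotone_in_surface_area(mono):
    one = dlm_rate(_state(count=1e5), 0.008, 1.0, mono)
    two = dlm_rate(_state(count=2e5), 0.008, 1.0, mono)
    assert two == pytest.approx(2 * one, rel=1e-12)


def test_shrink_noop_and_exhaustion(mono):
    s0 = DissolutionState(bins=list(mono.bins))
    unchanged = shrink_particles(s0, 0.0, mono)
    assert unchanged.bins[0].radius == s0.bins[0].radius
    total = mono.solid_mass()
    gone = shrink_particles(s0, total, mono)
    assert gone.bins[0].radius == 0.0
    assert gone.dissolved == pytest.approx(total, rel=1e-9)
    with pytest.raises(ValueError):
        shrink_particles(s0, total * 1.01, mono)


def test_shrink_radius_cube_root_law(mono):
    # removing 87.5 % of a monodisperse bin's mass halves the radius
    s0 = DissolutionState(bins=list(mono.bins))
    total = mono.solid_mass()
    out = shrink_particles(s0, 0.875 * total, mono)
    assert out.bins[0].radius == pytest.approx(mono.bins[0].radius / 2, rel=1e-9)
    # mass conserved
    remaining = out.bins[0].mass * mono.density
    assert remaining + out.dissolved == pytest.approx(total, rel=1e-9)


def test_shrink_polydisperse_conserves_mass():
    form = FormulationModel(dose=5.0, bins=[ParticleBin(5.0, 4e6), ParticleBin(20.0, 5e4)])
    masses = form.bin_masses()
    form = FormulationModel(dose=float(masses.sum()), bins=form.bins)
    state = DissolutionState(bins=list(form.bins))
    dm = 0.4 * masses.sum()
    out = shrink_particles(state, dm, form)
    left = sum(b.mass * form.density for b in out.bins)
    assert left + out.dissolved == pytest.approx(masses.sum(), rel=1e-9)
    # smaller particles shed mass relatively faster (larger specific surface)
    frac = [out.bins[i].mass * form.density / masses[i] for i in range(2)]
    assert frac[0] < frac[1]
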