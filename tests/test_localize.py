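"""Forward model and equivalent-dipole fitting.

The forward oracle solves the same per-harmonic boundary-value problem
in exact (rational) arithmetic with sympy at double truncation order,
with Legendre terms from scipy.special — an independently coded direct
partial-sum evaluation.  A second check verifies the angular machinery
against the closed-form infinite-medium dipole potential.
"""

import numpy as np
import pytest
import sympy as sp
from scipy.special import eval_legendre, legendre_p_all

import devsource.localize as loc
from devsource.data_io import ValidationError
from devsource.localize import (
    DipoleFit,
    HeadModel,
    average_reference,
    dipole_gain,
    dipole_potential,
    fit_dipole,
    screen_ics,
)


def oracle_radial_transfer(model: HeadModel, n_terms: int) -> np.ndarray:
    """Exact-arithmetic per-order scalp transfer factors (sympy)."""
    r1, r2, r3 = [sp.Rational(r) / sp.Rational(model.radii[2]) for r in model.radii]
    s1, s2, s3 = [sp.Rational(str(c)) for c in model.conductivities]
    out = []
    for n in range(1, n_terms + 1):
        m = n + 1
        a1, a2, b2, a3, b3 = sp.symbols("a1 a2 b2 a3 b3")
        eqs = [
            sp.Eq(a1 * r1**n + r1**-m, a2 * r1**n + b2 * r1**-m),
            sp.Eq(
                s1 * (n * a1 * r1 ** (n - 1) - m * r1 ** (-m - 1)),
                s2 * (n * a2 * r1 ** (n - 1) - m * b2 * r1 ** (-m - 1)),
            ),
            sp.Eq(a2 * r2**n + b2 * r2**-m, a3 * r2**n + b3 * r2**-m),
            sp.Eq(
                s2 * (n * a2 * r2 ** (n - 1) - m * b2 * r2 ** (-m - 1)),
                s3 * (n * a3 * r2 ** (n - 1) - m * b3 * r2 ** (-m - 1)),
            ),
            sp.Eq(n * a3 * r3 ** (n - 1) - m * b3 * r3 ** (-m - 1), 0),
        ]
        sol = sp.solve(eqs, [a1, a2, b2, a3, b3], rational=True)
        out.append(float(sol[a3] * r3**n + sol[b3] * r3**-m))
    return np.array(out)


class TestForwardModel:
    def test_linearity_in_moment(self, head_model, montage68):
        pos = np.array([20.0, 10.0, 40.0])
        v1 = dipole_potential(pos, [1.0, -0.5, 2.0], head_model, montage68)
        v2 = dipole_potential(pos, [2.0, -1.0, 4.0], head_model, montage68)
        assert np.allclose(v2, 2.0 * v1)

    def test_central_dipole_antisymmetric_under_z_reflection(self, head_model, montage68):
        from devsource.data_io import Montage

        v = dipole_potential([0.0, 0.0, 1e-6], [0.0, 0.0, 1.0], head_model, montage68)
        reflected = Montage(
            list(montage68.channel_names), montage68.positions * np.array([1, 1, -1])
        )
        v_ref = dipole_potential([0.0, 0.0, 1e-6], [0.0, 0.0, 1.0], head_model, reflected)
        assert np.allclose(v, -v_ref, atol=1e-6 * np.abs(v).max())

    def test_radial_dipole_matches_exact_series_oracle(self, head_model, montage68):
        """3-shell potentials vs sympy BVP at double truncation order."""
        pos = np.array([0.0, 0.0, 60.0])
        mom = np.array([0.0, 0.0, 1.0])  # radial
        mine = dipole_potential(pos, mom, head_model, montage68)

        w = oracle_radial_transfer(head_model, 2 * head_model.n_terms)
        R = head_model.scalp_radius
        rho = 60.0 / R
        c = montage68.positions[:, 2] / np.linalg.norm(montage68.positions, axis=1)
        expected = np.zeros(len(montage68))
        for n in range(1, 2 * head_model.n_terms + 1):
            expected += (
                w[n - 1] * rho ** (n - 1) * n * eval_legendre(n, c)
            )
        expected /= 4.0 * np.pi * head_model.conductivities[0] * R**2
        assert np.linalg.norm(mine - expected) / np.linalg.norm(expected) < 1e-8

    def test_tangential_dipole_matches_exact_series_oracle(self, head_model, montage68):
        pos = np.array([0.0, 0.0, 55.0])
        mom = np.array([1.0, 0.0, 0.0])  # tangential
        mine = dipole_potential(pos, mom, head_model, montage68)

        w = oracle_radial_transfer(head_model, 2 * head_model.n_terms)
        R = head_model.scalp_radius
        rho = 55.0 / R
        e = montage68.positions / np.linalg.norm(montage68.positions, axis=1, keepdims=True)
        c = e[:, 2]
        expected = np.zeros(len(montage68))
        n_max = 2 * head_model.n_terms
        for i in range(len(montage68)):
            pn, dpn = np.asarray(legendre_p_all(n_max, c[i], diff_n=1))
            s = 0.0
            for n in range(1, n_max + 1):
                s += w[n - 1] * rho ** (n - 1) * dpn[n] * e[i, 0]
            expected[i] = s
        expected /= 4.0 * np.pi * head_model.conductivities[0] * R**2
        assert np.linalg.norm(mine - expected) / np.linalg.norm(expected) < 1e-8

    def test_angular_series_matches_infinite_medium_closed_form(
        self, head_model, montage68, monkeypatch
    ):
        """With unit radial transfer the series must reduce to the direct
        dipole formula p·(r−r0)/(4πσ|r−r0|³)."""
        model = HeadModel(n_terms=300)
        monkeypatch.setattr(
            loc, "_transfer", lambda m: np.ones(m.n_terms)
        )
        pos = np.array([10.0, -15.0, 40.0])
        mom = np.array([0.7, 1.1, -0.4])
        mine = dipole_potential(pos, mom, model, montage68)
        d = montage68.positions - pos[None, :]
        direct = (d @ mom) / (
            4.0
            * np.pi
            * head_model.conductivities[0]
            * np.linalg.norm(d, axis=1) ** 3
        )
        assert np.allclose(mine, direct, rtol=1e-6)

    def test_position_outside_brain_rejected(self, head_model, montage68):
        with pytest.raises(ValidationError):
            dipole_potential([0, 0, 85.0], [0, 0, 1.0], head_model, montage68)


class TestFitDipole:
    def test_noiseless_round_trip(self, head_model, montage68):
        target = np.array([30.0, 20.0, 50.0])
        v = dipole_potential(target, [1.0, 0.5, -0.3], head_model, montage68)
        fit = fit_dipole(v, head_model, montage68, seed=0)
        assert np.linalg.norm(fit.position - target) < 1.0
        assert fit.rv < 1e-4

    def test_negated_map_gives_same_position_negated_moment(self, head_model, montage68):
        target = np.array([10.0, -30.0, 45.0])
        v = dipole_potential(target, [0.2, 1.0, 0.4], head_model, montage68)
        f1 = fit_dipole(v, head_model, montage68, seed=0)
        f2 = fit_dipole(-v, head_model, montage68, seed=0)
        assert np.linalg.norm(f1.position - f2.position) < 0.5
        assert np.allclose(f1.moment, -f2.moment, rtol=1e-2, atol=1e-8)

    def test_rv_invariant_to_map_scaling(self, head_model, montage68):
        v = dipole_potential([25, 0, 40], [1, 0, 1.0], head_model, montage68)
        v += 0.1 * np.abs(v).max() * np.sin(np.arange(v.size))
        f1 = fit_dipole(v, head_model, montage68, seed=3)
        f2 = fit_dipole(7.5 * v, head_model, montage68, seed=3)
        assert np.isclose(f1.rv, f2.rv, rtol=1e-6)

    def test_noisy_round_trip(self, head_model, montage68, rng):
        """10 % RMS map noise: rv stays below the screen, position within
        10 mm (Monte-Carlo over seeds)."""
        target = np.array([20.0, 25.0, 45.0])
        clean = dipole_potential(target, [1.0, 0.0, 0.8], head_model, montage68)
        for k in range(20):
            noisy = clean + 0.10 * clean.std() * rng.standard_normal(clean.size)
            fit = fit_dipole(noisy, head_model, montage68, n_starts=4, seed=k)
            assert 0.0 < fit.rv < 0.15
            assert np.linalg.norm(fit.position - target) < 10.0

    def test_constant_map_rejected(self, head_model, montage68):
        with pytest.raises(ValidationError):
            fit_dipole(np.ones(68), head_model, montage68)


class TestScreening:
    def _fit(self, rv, pos=(0, 0, 0)):
        p = np.asarray(pos, dtype=float)
        return DipoleFit(p, np.ones(3), rv, bool(np.linalg.norm(p) < 80.0))

    def test_rv_threshold_boundary(self):
        fits = [self._fit(0.16), self._fit(0.15), self._fit(0.0)]
        assert screen_ics(fits) == [1, 2]

    def test_origin_dipole_with_zero_rv_retained(self):
        assert screen_ics([self._fit(0.0, (0, 0, 0))]) == [0]

    def test_outside_brain_excluded_unless_allowed(self):
        fits = [self._fit(0.01, (0, 84, -20)), self._fit(0.01, (0, 40, 20))]
        assert screen_ics(fits) == [1]
        assert screen_ics(fits, require_inside=False) == [0, 1]

    def test_synthetic_subject_screen_separates_brain_from_artifacts(
        self, head_model, montage32
    ):
        """Brain-source maps pass; ocular/myogenic maps fit outside the
        brain shell (or fit poorly) and are excluded."""
        from devsource.synth import _unshielded_map, default_sources

        fits = []
        n_brain = 0
        for spec in default_sources():
            g = dipole_gain(spec.location, head_model, montage32) @ spec.orientation
            fits.append(fit_dipole(g, head_model, montage32, seed=1))
            n_brain += 1
        for pos, mom in [
            ((0.0, 81.0, -28.0), (0.0, 0.3, 1.0)),
            ((-86.0, -12.0, -6.0), (-1.0, 0.0, 0.0)),
            ((86.0, -12.0, -6.0), (1.0, 0.0, 0.0)),
        ]:
            fits.append(
                fit_dipole(_unshielded_map(pos, mom, montage32), head_model, montage32, seed=1)
            )
        kept = screen_ics(fits)
        assert kept == list(range(n_brain))


class TestConsistencyProperties:
    def test_forward_inverse_consistency_at_high_eccentricity(self, head_model, montage68, rng):
        for _ in range(5):
            direction = rng.standard_normal(3)
            direction /= np.linalg.norm(direction)
            pos = direction * rng.uniform(0.1, 0.9) * head_model.brain_radius
            mom = rng.standard_normal(3)
            v = dipole_potential(pos, mom, head_model, montage68)
            fit = fit_dipole(v, head_model, montage68, seed=7)
            assert np.linalg.norm(fit.position - pos) < 1.0
            assert np.linalg.norm(fit.moment - mom) / np.linalg.norm(mom) < 0.01

    def test_average_reference_removes_mean(self, rng):
        x = rng.standard_normal((7, 5))
        assert np.allclose(average_reference(x).mean(axis=0), 0.0)
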