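import math

import numpy as np
import pytest
from scipy import stats

from scalemap.covariance import dataset_covariances
from scalemap.data import Instrument, ValidationError, load_trials
from scalemap.models import (
    ModelLayout,
    ModelSpec,
    ParameterState,
    PriorSpec,
    derived_mapping,
    expected_effects,
    log_likelihood,
    log_prior,
    reparameterise_reference,
)

from conftest import make_rows


def small_dataset():
    return load_trials(
        make_rows(
            [
                ("T1", 1, 100, 100, "LSAS", -12.0, 3.0, 30.0),
                ("T1", 1, 100, 100, "CGI", -0.5, 0.14, 1.2),
                ("T2", 1, 90, 95, "LSAS", -9.0, 3.5, 28.0),
                ("T2", 2, 90, 92, "LSAS", -10.0, 3.4, 28.0),
                ("T2", 1, 90, 95, "CGI", -0.4, 0.15, 1.1),
                ("T2", 2, 90, 92, "CGI", -0.45, 0.15, 1.1),
                ("T3", 1, 80, 85, "CGI", -0.6, 0.2, 1.3),
            ]
        ),
        instruments=(Instrument("LSAS"), Instrument("CGI")),
    )


def make_state(ds, spec, mu=-11.0, sigma=3.0, beta=(0.045,), phi=0.2):
    lay = ModelLayout(ds, spec)
    return lay, ParameterState(
        layout=lay, mu=mu, sigma=sigma, beta=np.array(beta), phi=phi
    )


class TestDerivedMapping:
    def test_identity_and_basic(self):
        beta = {"CGI": 0.0445, "BSPS": 0.42}
        assert derived_mapping(beta, "LSAS", "LSAS", reference="LSAS") == 1.0
        assert derived_mapping(beta, "CGI", "CGI", reference="LSAS") == 1.0
        assert derived_mapping(beta, "LSAS", "CGI", reference="LSAS") == 0.0445

    def test_transitivity_and_inverse(self):
        beta = {"a": 2.0, "b": 4.0}
        assert derived_mapping(beta, "a", "b", reference="r") == 2.0
        fwd = derived_mapping(beta, "a", "b", reference="r")
        rev = derived_mapping(beta, "b", "a", reference="r")
        assert fwd * rev == pytest.approx(1.0)

    def test_zero_mapping_is_degenerate(self):
        with pytest.raises(ValidationError, match="degenerate"):
            derived_mapping({"a": 0.0}, "a", "b", reference="r")


class TestExpectedEffects:
    def test_ratios_one_repeats_delta(self):
        ds = small_dataset()
        spec = ModelSpec(variant="ratios_one")
        lay, state = make_state(ds, spec, beta=(0.045,))
        state.delta[:] = -0.45
        t1 = ds.trials[0]
        assert np.allclose(expected_effects(state, spec, t1), [-0.45, -0.45])

    def test_fixed_mapping_scales_by_ratio(self):
        ds = small_dataset()
        spec = ModelSpec(variant="fixed_mapping")
        lay, state = make_state(ds, spec, beta=(0.0443,))
        state.delta[lay.arm_index("T1", 1)] = -11.85
        eff = expected_effects(state, spec, ds.trials[0])
        assert eff[0] == pytest.approx(-11.85)
        assert eff[1] == pytest.approx(-11.85 * 0.0443)  # about -0.525

    def test_random_mapping_with_phi_zero_equals_fixed(self):
        ds = small_dataset()
        fixed = ModelSpec(variant="fixed_mapping")
        collapsed = ModelSpec(variant="random_mapping", phi_fixed=0.0)
        _, s1 = make_state(ds, fixed)
        _, s2 = make_state(ds, collapsed)
        for t in ds.trials:
            assert np.allclose(
                expected_effects(s1, fixed, t), expected_effects(s2, collapsed, t)
            )

    def test_missing_trial_ratio_fails(self):
        ds = small_dataset()
        spec = ModelSpec(variant="random_mapping")
        lay, state = make_state(ds, spec)
        other = load_trials(
            make_rows([("T9", 1, 50, 50, "CGI", -0.5, 0.2, 1.2)])
        ).trials[0]
        with pytest.raises(ValidationError, match="no trial-specific ratio"):
            expected_effects(state, spec, other)


class TestLogPrior:
    def test_out_of_support_is_minus_inf(self):
        ds = small_dataset()
        spec = ModelSpec(variant="random_mapping")
        lay, state = make_state(ds, spec)
        bad = state.copy()
        bad.sigma = -1.0
        assert log_prior(bad, spec) == -math.inf
        bad = state.copy()
        bad.phi = 5.0  # above the uniform upper bound
        assert log_prior(bad, spec) == -math.inf

    def test_matches_independent_density_composition(self):
        """Sum of scipy densities over the hierarchy reproduces log_prior."""
        ds = small_dataset()
        spec = ModelSpec(variant="random_mapping")
        lay, state = make_state(ds, spec, mu=-10.0, sigma=2.5, beta=(0.05,), phi=0.3)
        state.delta[:] = [-9.0, -11.0, -10.5, -12.0]
        state.beta_trial[:] = [0.048, 0.051, 0.046]

        expected = (
            stats.norm.logpdf(-10.0, 0, 100)
            - math.log(50)  # sigma ~ U(0, 50)
            + stats.norm.logpdf(0.05, 0, 100)
            - math.log(2)  # phi ~ U(0, 2)
            + stats.norm.logpdf(state.delta, -10.0, 2.5).sum()
            + stats.norm.logpdf(state.beta_trial, 0.05, 0.3 * 0.05).sum()
        )
        assert log_prior(state, spec) == pytest.approx(expected, abs=1e-10)

    def test_phi_floor_keeps_density_finite(self):
        ds = small_dataset()
        spec = ModelSpec(variant="random_mapping")
        lay, state = make_state(ds, spec, phi=0.0)
        state.beta_trial[:] = state.beta[lay.trial_ratio_beta]
        assert np.isfinite(log_prior(state, spec))

    def test_prior_hyperparameters_are_live_knobs(self):
        ds = small_dataset()
        tight = ModelSpec(
            variant="fixed_mapping", priors=PriorSpec(mu_sd=1.0)
        )
        vague = ModelSpec(variant="fixed_mapping")
        _, state = make_state(ds, tight)
        delta = log_prior(state, vague) - log_prior(state, tight)
        expected = stats.norm.logpdf(state.mu, 0, 100) - stats.norm.logpdf(
            state.mu, 0, 1
        )
        assert delta == pytest.approx(expected, abs=1e-10)


class TestLogLikelihood:
    def test_perfect_fit_leaves_normalising_constant(self):
        ds = small_dataset()
        spec = ModelSpec(variant="fixed_mapping")
        lay, state = make_state(ds, spec)
        covs = dataset_covariances(ds.trials, spec.rho)
        # overwrite data with the model-expected values
        rows = []
        for t in ds.trials:
            eff = expected_effects(state, spec, t)
            i = 0
            for arm, obs in enumerate(t.observations, start=1):
                for o in obs:
                    rows.append(
                        {
                            "trial_id": t.trial_id,
                            "arm_index": arm,
                            "n_control": t.n_control,
                            "n_arm": t.n_active[arm - 1],
                            "instrument": o.instrument,
                            "mean_diff": eff[i],
                            "se": o.se,
                            "pooled_sd": o.pooled_sd,
                            "basis": o.basis,
                        }
                    )
                    i += 1
        perfect = load_trials(rows, instruments=ds.instruments)
        expected_const = sum(
            -0.5 * (c.dim * math.log(2 * math.pi) + 2 * np.log(np.diag(c.cholesky())).sum())
            for c in covs
        )
        got = log_likelihood(state, spec, perfect, covs)
        assert got == pytest.approx(expected_const, abs=1e-9)

    def test_single_observation_reduces_to_scalar_normal(self):
        ds = load_trials(make_rows([("T1", 1, 50, 50, "LSAS", -6.6, 3.21, 30.2)]))
        spec = ModelSpec(variant="fixed_mapping")
        lay = ModelLayout(ds, spec)
        state = ParameterState(layout=lay, mu=-8.0, sigma=3.0, beta=np.empty(0))
        got = log_likelihood(state, spec, ds)
        assert got == pytest.approx(stats.norm.logpdf(-6.6, -8.0, 3.21), abs=1e-12)

    def test_agrees_with_scipy_multivariate_normal(self, anxiety, rng):
        spec = ModelSpec(variant="fixed_mapping")
        lay = ModelLayout(anxiety, spec)
        covs = dataset_covariances(anxiety.trials, spec.rho)
        by_id = {c.trial_id: c for c in covs}
        for _ in range(5):
            state = ParameterState(
                layout=lay,
                mu=rng.normal(-11, 2),
                sigma=rng.uniform(1, 5),
                beta=rng.normal(0.3, 0.2, size=lay.n_beta),
                delta=rng.normal(-11, 4, size=lay.n_arms),
            )
            oracle = 0.0
            for t in anxiety.trials:
                y = [o.mean_diff for obs in t.observations for o in obs]
                oracle += stats.multivariate_normal.logpdf(
                    y, mean=expected_effects(state, spec, t), cov=by_id[t.trial_id].matrix
                )
            got = log_likelihood(state, spec, anxiety, covs)
            assert got == pytest.approx(oracle, abs=1e-8)

    def test_likelihood_invariant_under_reference_change(self, anxiety, rng):
        spec = ModelSpec(variant="fixed_mapping", reference_instrument="LSAS")
        lay = ModelLayout(anxiety, spec)
        state = ParameterState(
            layout=lay,
            mu=-11.5,
            sigma=3.0,
            beta=np.abs(rng.normal(0.4, 0.2, size=lay.n_beta)) + 0.01,
            delta=rng.normal(-11.5, 3.0, size=lay.n_arms),
        )
        spec2 = ModelSpec(variant="fixed_mapping", reference_instrument="CGI-S")
        lay2 = ModelLayout(anxiety, spec2)
        state2 = reparameterise_reference(state, "CGI-S", lay2)
        covs = dataset_covariances(anxiety.trials, spec.rho)
        assert log_likelihood(state2, spec2, anxiety, covs) == pytest.approx(
            log_likelihood(state, spec, anxiety, covs), rel=1e-12
        )

    def test_ratios_one_equals_fixed_at_unit_beta(self, anxiety_std):
        constrained = ModelSpec(variant="ratios_one", standardised=True)
        free = ModelSpec(variant="fixed_mapping", standardised=True)
        lay_c = ModelLayout(anxiety_std, constrained)
        lay_f = ModelLayout(anxiety_std, free)
        delta = np.linspace(-0.6, -0.2, lay_f.n_arms)
        s_c = ParameterState(
            layout=lay_c, mu=-0.45, sigma=0.15, beta=np.empty(0) if lay_c.n_beta == 0 else np.ones(lay_c.n_beta), delta=delta
        )
        s_f = ParameterState(
            layout=lay_f, mu=-0.45, sigma=0.15, beta=np.ones(lay_f.n_beta), delta=delta
        )
        covs = dataset_covariances(anxiety_std.trials, 0.65)
        assert log_likelihood(s_c, constrained, anxiety_std, covs) == pytest.approx(
            log_likelihood(s_f, free, anxiety_std, covs), rel=1e-12
        )

    def test_reference_only_trial_contributes_nothing_to_mappings(self):
        """A trial reporting only the reference has zero mapping gradient."""
        ds = small_dataset()
        only_ref = load_trials(
            make_rows([("T1", 1, 100, 100, "LSAS", -12.0, 3.0, 30.0)]),
            instruments=ds.instruments,
        )
        spec = ModelSpec(variant="fixed_mapping")
        lay = ModelLayout(only_ref, spec)
        state = ParameterState(layout=lay, mu=-11.0, sigma=3.0, beta=np.array([0.05]))
        base = log_likelihood(state, spec, only_ref)
        bumped = state.copy()
        bumped.beta[0] += 1e-4
        assert log_likelihood(bumped, spec, only_ref) == base


def test_spec_validation():
    with pytest.raises(ValidationError):
        ModelSpec(variant="nonsense")
    with pytest.raises(ValidationError):
        ModelSpec(phi_fixed=-0.5)
    ds = small_dataset()
    with pytest.raises(ValidationError, match="reference instrument"):
        ModelLayout(ds, ModelSpec(reference_instrument="MISSING"))
    with pytest.raises(ValidationError, match="does not match dataset"):
        ModelLayout(ds, ModelSpec(standardised=True))
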