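import math

import numpy as np
import pytest

from scalemap.covariance import dataset_covariances
from scalemap.data import Instrument, ValidationError, load_trials
from scalemap.inference import (
    MCMCConfig,
    PosteriorSamples,
    fit,
    gelman_rubin,
    residual_deviance,
    run_mcmc,
    summarise,
)
from scalemap.models import ModelLayout, ModelSpec, ParameterState, expected_effects

from conftest import make_rows
from test_models import small_dataset

SHORT = dict(n_chains=2, n_burn=400, n_keep=600, rhat_gate=None)


def test_same_seed_gives_identical_draws():
    ds = small_dataset()
    cfg = MCMCConfig(seed=7, **SHORT)
    spec = ModelSpec(variant="random_mapping")
    a = run_mcmc(spec, ds, cfg)
    b = run_mcmc(spec, ds, cfg)
    assert set(a.draws) == set(b.draws)
    for name in a.draws:
        assert np.array_equal(a.draws[name], b.draws[name])


def test_posterior_invariant_under_trial_row_order(anxiety):
    """Shuffling input rows leaves draws bit-identical (canonical ordering)."""
    df = anxiety.to_frame()
    shuffled = df.sample(frac=1.0, random_state=3)
    ds2 = load_trials(shuffled, instruments=anxiety.instruments)
    cfg = MCMCConfig(seed=11, n_chains=1, n_burn=150, n_keep=150, rhat_gate=None)
    spec = ModelSpec(variant="fixed_mapping")
    a = run_mcmc(spec, anxiety, cfg)
    b = run_mcmc(spec, ds2, cfg)
    for name in a.draws:
        assert np.array_equal(a.draws[name], b.draws[name])


def test_phi_zero_random_mapping_reduces_to_fixed():
    ds = small_dataset()
    cfg = MCMCConfig(seed=5, **SHORT)
    fixed = run_mcmc(ModelSpec(variant="fixed_mapping"), ds, cfg)
    collapsed = run_mcmc(
        ModelSpec(variant="random_mapping", phi_fixed=0.0), ds, cfg
    )
    assert set(fixed.draws) == set(collapsed.draws)
    for name in fixed.draws:
        assert np.array_equal(fixed.draws[name], collapsed.draws[name])


class TestGelmanRubin:
    def test_identical_chains_sit_at_one(self):
        # identical chains with matching halves: B = 0, so the statistic
        # equals sqrt((L-1)/L), i.e. 1 up to O(1/L)
        pattern = np.sin(np.arange(200.0))
        x = np.tile(np.concatenate([pattern, pattern]), (3, 1))
        rhat = gelman_rubin({"x": x})["x"]
        assert rhat == pytest.approx(np.sqrt(199 / 200), abs=1e-12)
        assert rhat == pytest.approx(1.0, abs=3e-3)

    def test_separated_chains_flag_divergence(self, rng):
        x = rng.normal(size=(2, 400))
        x[1] += 50.0
        assert gelman_rubin({"x": x})["x"] > 5.0

    def test_matches_arviz_split_rhat(self, rng):
        az = pytest.importorskip("arviz")
        arr = rng.normal(size=(4, 500)) + 0.3 * rng.normal(size=(4, 1))
        mine = gelman_rubin({"x": arr})["x"]
        theirs = float(az.rhat(arr, method="split"))
        assert mine == pytest.approx(theirs, abs=1e-8)

    def test_single_chain_rejected(self):
        with pytest.raises(ValidationError, match="2 chains"):
            gelman_rubin({"x": np.zeros((1, 100))})


def _craft_samples(draws):
    ds = small_dataset()
    spec = ModelSpec(variant="fixed_mapping")
    lay = ModelLayout(ds, spec)
    cfg = MCMCConfig(seed=0, n_chains=draws["mu"].shape[0], n_burn=0,
                     n_keep=draws["mu"].shape[1], rhat_gate=None)
    return PosteriorSamples(draws, lay, spec, cfg, {})


def _quantile_oracle(x, q):
    """Sorted-array linear interpolation, written independently."""
    xs = np.sort(np.asarray(x, float))
    pos = q * (xs.size - 1)
    lo = int(math.floor(pos))
    hi = min(lo + 1, xs.size - 1)
    return xs[lo] + (pos - lo) * (xs[hi] - xs[lo])


def test_summary_quantiles_match_sorted_array_oracle(rng):
    mu = rng.normal(-11, 1, size=(2, 500))
    draws = {"mu": mu, "sigma": np.abs(rng.normal(3, 1, size=(2, 500))),
             "resdev": np.full((2, 500), 88.0)}
    rep = summarise(_craft_samples(draws))
    flat = mu.reshape(-1)
    assert rep.row("mu")["median"] == pytest.approx(_quantile_oracle(flat, 0.5), abs=1e-12)
    assert rep.row("mu")["q2.5"] == pytest.approx(_quantile_oracle(flat, 0.025), abs=1e-12)
    assert rep.row("mu")["q97.5"] == pytest.approx(_quantile_oracle(flat, 0.975), abs=1e-12)
    assert rep.mean_residual_deviance == pytest.approx(88.0)


def test_degenerate_draws_have_zero_width():
    draws = {"mu": np.full((2, 100), -4.2), "sigma": np.full((2, 100), 1.5),
             "resdev": np.zeros((2, 100))}
    rep = summarise(_craft_samples(draws))
    row = rep.row("mu")
    assert row["mean"] == pytest.approx(-4.2, abs=1e-12)
    assert row["median"] == pytest.approx(-4.2, abs=1e-12)
    assert row["sd"] == pytest.approx(0.0, abs=1e-12)
    assert row["q97.5"] - row["q2.5"] == pytest.approx(0.0, abs=1e-12)
    assert residual_deviance(_craft_samples(draws)) == 0.0


def test_stored_residual_deviance_matches_recomputation():
    """Per-draw deviance recomputed from stored states equals the stored one."""
    ds = small_dataset()
    spec = ModelSpec(variant="fixed_mapping")
    cfg = MCMCConfig(seed=9, n_chains=1, n_burn=200, n_keep=50, rhat_gate=None)
    s = run_mcmc(spec, ds, cfg)
    lay = s.layout
    covs = {c.trial_id: c for c in dataset_covariances(lay.trials, spec.rho)}
    for i in range(50):
        state = ParameterState(
            layout=lay,
            mu=s.draws["mu"][0, i],
            sigma=s.draws["sigma"][0, i],
            beta=np.array([s.draws[s.beta_name(n)][0, i] for n in lay.beta_names]),
            delta=np.array(
                [s.draws[f"delta[{tid}:{a}]"][0, i] for tid, a in lay.arm_keys]
            ),
        )
        dev = 0.0
        for t in lay.trials:
            y = np.array([o.mean_diff for obs in t.observations for o in obs])
            r = y - expected_effects(state, spec, t)
            dev += float(r @ np.linalg.inv(covs[t.trial_id].matrix) @ r)
        assert s.draws["resdev"][0, i] == pytest.approx(dev, abs=1e-8)


def test_single_instrument_matches_numerical_integration(anxiety):
    """On one instrument and two-arm trials the model is plain normal-normal
    random-effects meta-analysis; a 2-D quadrature over (mu, sigma) is an
    independent oracle for the posterior."""
    rows = []
    for t in anxiety.trials:
        if len(t.n_active) != 1:
            continue
        for o in t.observations[0]:
            if o.instrument == "LSAS":
                rows.append(
                    ("T" + t.trial_id, 1, t.n_control, t.n_active[0], "LSAS",
                     o.mean_diff, o.se, o.pooled_sd)
                )
    ds = load_trials(make_rows(rows), instruments=(Instrument("LSAS"),))
    y = np.array([t.observations[0][0].mean_diff for t in ds.trials])
    se = np.array([t.observations[0][0].se for t in ds.trials])

    mu_grid = np.linspace(-25.0, 2.0, 541)
    sg_grid = np.linspace(0.02, 16.0, 500)
    M, S = np.meshgrid(mu_grid, sg_grid, indexing="ij")
    logpost = -0.5 * (M / 100.0) ** 2  # mu prior (constant terms cancel)
    for yj, sej in zip(y, se):
        v = S**2 + sej**2
        logpost += -0.5 * np.log(v) - 0.5 * (yj - M) ** 2 / v
    w = np.exp(logpost - logpost.max())
    w /= w.sum()
    mu_mean_oracle = float((w * M).sum())
    psig = w.sum(axis=0)
    sg_median_oracle = float(np.interp(0.5, np.cumsum(psig), sg_grid))

    cfg = MCMCConfig(seed=13, n_chains=2, n_burn=1500, n_keep=2500, rhat_gate=None)
    rep = summarise(run_mcmc(ModelSpec(variant="fixed_mapping"), ds, cfg))
    assert rep.row("mu")["mean"] == pytest.approx(mu_mean_oracle, abs=0.15)
    assert rep.row("sigma")["median"] == pytest.approx(sg_median_oracle, abs=0.15)


def test_convergence_gate_raises():
    ds = small_dataset()
    cfg = MCMCConfig(seed=1, n_chains=2, n_burn=300, n_keep=300, rhat_gate=0.5)
    with pytest.raises(ValidationError, match="convergence gate"):
        fit(ModelSpec(variant="fixed_mapping"), ds, cfg)


def test_samples_respect_support_and_config():
    ds = small_dataset()
    cfg = MCMCConfig(seed=3, **SHORT)
    s = run_mcmc(ModelSpec(variant="random_mapping"), ds, cfg)
    assert s.draws["mu"].shape == (2, 600)
    assert np.all(s.draws["sigma"] > 0)
    assert np.all((s.draws["phi"] >= 0) & (s.draws["phi"] <= 2))
    frame = s.to_frame()
    assert len(frame) == 1200 and "chain" in frame.columns
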