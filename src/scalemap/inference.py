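"""Posterior sampling, convergence diagnostics, and fit summaries.

The sampler is an adaptive random-walk Metropolis-within-Gibbs: each scalar
parameter (pooled effect mu, log between-trials SD, each basic mapping
ratio, log ratio CV, each per-arm random effect, each trial-specific ratio)
is updated in turn with a normal random-walk proposal.  Step sizes adapt
toward a 0.44 acceptance rate during burn-in only, so the post-burn-in
kernel satisfies detailed balance.  Chains start from overdispersed,
data-informed positions and are fully deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .covariance import TrialCovariance, dataset_covariances
from .data import TrialDataset, ValidationError
from .models import (
    ModelLayout,
    ModelSpec,
    _LOG_2PI,
    _PHI_FLOOR,
)

__all__ = [
    "MCMCConfig",
    "PosteriorSamples",
    "FitReport",
    "run_mcmc",
    "gelman_rubin",
    "residual_deviance",
    "summarise",
    "fit",
]


@dataclass(frozen=True)
class MCMCConfig:
    """Run lengths and tuning knobs.

    Defaults reproduce the reference analysis: four chains, 30 000 burn-in
    iterations discarded, 20 000 retained per chain.  Shorter runs are
    adequate for exploratory work and testing at this problem size.
    """

    n_chains: int = 4
    n_burn: int = 30000
    n_keep: int = 20000
    thin: int = 1
    seed: int = 0
    adapt_interval: int = 50
    target_accept: float = 0.44
    rhat_gate: float | None = 1.05

    def __post_init__(self) -> None:
        if self.n_chains < 1 or self.n_keep < 1 or self.n_burn < 0:
            raise ValidationError("invalid MCMC run lengths")
        if not 0.0 < self.target_accept < 1.0:
            raise ValidationError("target_accept must lie in (0, 1)")

    def to_dict(self) -> dict:
        return {
            "n_chains": self.n_chains,
            "n_burn": self.n_burn,
            "n_keep": self.n_keep,
            "thin": self.thin,
            "seed": self.seed,
            "adapt_interval": self.adapt_interval,
            "target_accept": self.target_accept,
            "rhat_gate": self.rhat_gate,
        }


class PosteriorSamples:
    """Multi-chain draws, stored per scalar parameter.

    ``draws[name]`` has shape ``(n_chains, n_kept)``.  Basic mapping ratios
    are named ``beta[REF->K]``; per-draw total residual deviance is stored
    under ``resdev``.
    """

    def __init__(
        self,
        draws: Mapping[str, np.ndarray],
        layout: ModelLayout,
        spec: ModelSpec,
        config: MCMCConfig,
        acceptance: Mapping[str, float],
    ):
        self.draws = dict(draws)
        self.layout = layout
        self.spec = spec
        self.config = config
        self.acceptance = dict(acceptance)

    @property
    def parameter_names(self) -> list[str]:
        return [k for k in self.draws if k != "resdev"]

    @property
    def n_chains(self) -> int:
        return next(iter(self.draws.values())).shape[0]

    def stacked(self, name: str) -> np.ndarray:
        """All chains concatenated into one flat sample."""
        return self.draws[name].reshape(-1)

    def beta_name(self, instrument: str) -> str:
        return f"beta[{self.layout.reference}->{instrument}]"

    def to_frame(self) -> pd.DataFrame:
        cols = {}
        for name, arr in self.draws.items():
            cols[name] = arr.reshape(-1)
        df = pd.DataFrame(cols)
        nc, nk = next(iter(self.draws.values())).shape
        df.insert(0, "chain", np.repeat(np.arange(nc), nk))
        df.insert(1, "iteration", np.tile(np.arange(nk), nc))
        return df


@dataclass
class FitReport:
    """Posterior summaries in the layout of the reference analysis.

    The pooled effect ``mu`` is conventionally read as mean (SD); spread
    parameters (sigma, betas, phi) as median (2.5%, 97.5%).  All of those
    summaries, plus split R-hat, are tabulated for every parameter.
    """

    params: pd.DataFrame
    mean_residual_deviance: float
    n_observations: int
    spec: dict
    config: dict
    max_rhat: float

    def row(self, name: str) -> pd.Series:
        return self.params.loc[name]

    def to_csv(self, path) -> None:
        self.params.to_csv(path)

    def to_dict(self) -> dict:
        return {
            "params": self.params.reset_index().to_dict(orient="records"),
            "mean_residual_deviance": self.mean_residual_deviance,
            "n_observations": self.n_observations,
            "spec": self.spec,
            "config": self.config,
            "max_rhat": self.max_rhat,
        }


class _Compiled:
    """Index structures and covariance factors for fast scalar updates."""

    def __init__(self, ds: TrialDataset, spec: ModelSpec,
                 covs: Sequence[TrialCovariance] | None = None):
        self.layout = lay = ModelLayout(ds, spec)
        self.spec = spec
        if covs is None:
            covs = dataset_covariances(lay.trials, spec.rho)
        by_id = {c.trial_id: c for c in covs}

        self.y: list[np.ndarray] = []
        self.vinv: list[np.ndarray] = []
        self.const: list[float] = []  # -0.5 * (n log 2pi + logdet)
        self.obs_arm: list[np.ndarray] = []  # global delta index per obs
        self.obs_beta: list[np.ndarray] = []  # beta index per obs, -1 = ref
        self.obs_btr: list[np.ndarray] = []  # trial-ratio index per obs, -1 = ref
        self.pos_by_arm: list[dict[int, np.ndarray]] = []
        self.pos_by_btr: list[dict[int, np.ndarray]] = []
        self.trial_of_arm = np.empty(lay.n_arms, dtype=int)
        self.trial_of_btr = np.empty(lay.n_trial_ratios, dtype=int)
        self.trials_by_beta: list[list[tuple[int, np.ndarray]]] = [
            [] for _ in range(lay.n_beta)
        ]
        self.btrs_by_beta: list[np.ndarray] = []

        for ti, t in enumerate(lay.trials):
            cov = by_id[t.trial_id]
            L = cov.cholesky()
            logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
            vinv = np.linalg.inv(cov.matrix)
            y, oa, ob, obtr = [], [], [], []
            for arm, obs in enumerate(t.observations, start=1):
                gj = lay.arm_index(t.trial_id, arm)
                self.trial_of_arm[gj] = ti
                for o in obs:
                    y.append(o.mean_diff)
                    oa.append(gj)
                    if o.instrument == lay.reference:
                        ob.append(-1)
                        obtr.append(-1)
                    else:
                        ob.append(lay.beta_index(o.instrument))
                        if spec.has_trial_ratios:
                            bj = lay.trial_ratio_index(t.trial_id, o.instrument)
                            obtr.append(bj)
                            self.trial_of_btr[bj] = ti
                        else:
                            obtr.append(-1)
            y = np.array(y)
            oa = np.array(oa, dtype=int)
            ob = np.array(ob, dtype=int)
            obtr = np.array(obtr, dtype=int)
            self.y.append(y)
            self.vinv.append(vinv)
            self.const.append(-0.5 * (y.size * _LOG_2PI + logdet))
            self.obs_arm.append(oa)
            self.obs_beta.append(ob)
            self.obs_btr.append(obtr)
            self.pos_by_arm.append(
                {gj: np.flatnonzero(oa == gj) for gj in np.unique(oa)}
            )
            self.pos_by_btr.append(
                {bj: np.flatnonzero(obtr == bj) for bj in np.unique(obtr) if bj >= 0}
            )
            for k in np.unique(ob):
                if k >= 0:
                    self.trials_by_beta[k].append((ti, np.flatnonzero(ob == k)))
        for k in range(lay.n_beta):
            self.btrs_by_beta.append(
                np.flatnonzero(lay.trial_ratio_beta == k)
            )
        self.n_trials = len(lay.trials)
        self.n_obs = int(sum(y.size for y in self.y))

    # ratio of each observation implied by the current state arrays
    def ratio_obs(self, ti: int, beta: np.ndarray, btr: np.ndarray) -> np.ndarray:
        spec = self.spec
        ob = self.obs_beta[ti]
        if spec.variant == "ratios_one":
            return np.ones(ob.size)
        if spec.has_trial_ratios:
            obtr = self.obs_btr[ti]
            out = np.ones(obtr.size)
            m = obtr >= 0
            out[m] = btr[obtr[m]]
            return out
        out = np.ones(ob.size)
        m = ob >= 0
        out[m] = beta[ob[m]]
        return out


def _quad(vinv: np.ndarray, r: np.ndarray) -> float:
    return float(r @ vinv @ r)


def _crude_inits(comp: _Compiled):
    """Data-driven centre and scale used to overdisperse starting values."""
    lay = comp.layout
    ref_effects, arm_ref = [], {}
    ratio_num = np.zeros(lay.n_beta)
    ratio_den = np.zeros(lay.n_beta)
    for ti in range(comp.n_trials):
        y = comp.y[ti]
        ob = comp.obs_beta[ti]
        oa = comp.obs_arm[ti]
        refmask = ob < 0
        for j, v in zip(oa[refmask], y[refmask]):
            arm_ref[int(j)] = float(v)
            ref_effects.append(float(v))
        for k in np.unique(ob[ob >= 0]):
            mask = ob == k
            # pair each non-reference obs with its arm's reference obs
            for pos in np.flatnonzero(mask):
                gj = int(oa[pos])
                if gj in arm_ref:
                    ratio_num[k] += y[pos]
                    ratio_den[k] += arm_ref[gj]
    m_hat = float(np.mean(ref_effects)) if ref_effects else 0.0
    s_hat = float(np.std(ref_effects)) if len(ref_effects) > 1 else 1.0
    s_hat = max(s_hat, abs(m_hat) / 4.0, 1e-3)
    r_hat = np.ones(lay.n_beta)
    ok = np.abs(ratio_den) > 1e-8
    r_hat[ok] = ratio_num[ok] / ratio_den[ok]
    r_hat[~np.isfinite(r_hat)] = 1.0
    r_hat[np.abs(r_hat) < 1e-3] = 1e-3
    return m_hat, s_hat, r_hat, arm_ref


def run_mcmc(
    spec: ModelSpec,
    ds: TrialDataset,
    cfg: MCMCConfig,
    covs: Sequence[TrialCovariance] | None = None,
) -> PosteriorSamples:
    """Draw from the posterior of ``spec`` fitted to ``ds``.

    Returns kept draws for mu, sigma, the basic mapping ratios, phi (random
    mapping), the per-arm random effects, and the per-draw total residual
    deviance.  Bit-for-bit deterministic given ``cfg.seed``.
    """
    comp = _Compiled(ds, spec, covs)
    lay = comp.layout
    pri = spec.priors
    sigma_upper = pri.resolve_sigma_upper(spec.standardised)
    free_beta = spec.has_free_ratios
    has_btr = spec.has_trial_ratios
    free_phi = spec.variant == "random_mapping" and spec.phi_fixed is None
    log_hier = spec.ratio_hierarchy == "log"
    beta_in_lik = spec.variant == "fixed_mapping" or (
        spec.variant == "random_mapping" and not has_btr
    )
    m_hat, s_hat, r_hat, arm_ref = _crude_inits(comp)

    n_blocks = (
        2
        + (lay.n_beta if free_beta else 0)
        + (1 if free_phi else 0)
        + lay.n_arms
        + (lay.n_trial_ratios if has_btr else 0)
    )
    keep_names = (
        ["mu", "sigma"]
        + ([f"beta[{lay.reference}->{n}]" for n in lay.beta_names] if free_beta else [])
        + (["phi"] if free_phi else [])
        + [f"delta[{tid}:{arm}]" for tid, arm in lay.arm_keys]
        + ["resdev"]
    )
    n_kept = cfg.n_keep // cfg.thin
    all_draws = {
        name: np.empty((cfg.n_chains, n_kept)) for name in keep_names
    }
    acc_total: dict[str, float] = {}

    def hier_logpdf(btr_vals, beta_vals, phi):
        """Hierarchical density of trial ratios given mean ratios and CV."""
        phi_eff = max(phi, _PHI_FLOOR)
        if log_hier:
            if np.any(btr_vals * beta_vals <= 0):
                return -np.inf
            s = math.sqrt(math.log1p(phi_eff**2))
            x = np.abs(btr_vals)
            m = np.log(np.abs(beta_vals)) - 0.5 * s * s
            z = (np.log(x) - m) / s
            return float(np.sum(-0.5 * z * z - math.log(s) - 0.5 * _LOG_2PI - np.log(x)))
        sd = np.maximum(phi_eff * np.abs(beta_vals), _PHI_FLOOR)
        z = (btr_vals - beta_vals) / sd
        return float(np.sum(-0.5 * z * z - np.log(sd)))

    for chain in range(cfg.n_chains):
        rng = np.random.default_rng([int(cfg.seed) & 0x7FFFFFFF, chain])

        # --- overdispersed, data-informed start ------------------------------
        mu = m_hat + (4.0 * rng.random() - 2.0) * s_hat
        sigma = float(
            np.clip(s_hat * math.exp(rng.uniform(-1.5, 1.5)), 1e-3, sigma_upper * 0.99)
        )
        beta = r_hat * np.exp(rng.uniform(-0.7, 0.7, size=lay.n_beta))
        phi = float(rng.uniform(0.02, min(1.0, pri.phi_upper))) if free_phi else (
            spec.phi_fixed if spec.phi_fixed is not None else 0.0
        )
        delta = np.array(
            [
                arm_ref.get(j, m_hat) + rng.normal(0.0, 0.5 * s_hat)
                for j in range(lay.n_arms)
            ]
        )
        btr = (
            beta[lay.trial_ratio_beta]
            * np.exp(rng.uniform(-0.2, 0.2, size=lay.n_trial_ratios))
            if has_btr
            else np.zeros(0)
        )

        # --- caches -----------------------------------------------------------
        mean_c = []
        ll = np.empty(comp.n_trials)
        for ti in range(comp.n_trials):
            ratios = comp.ratio_obs(ti, beta, btr)
            mean = ratios * delta[comp.obs_arm[ti]]
            mean_c.append(mean)
            ll[ti] = comp.const[ti] - 0.5 * _quad(comp.vinv[ti], comp.y[ti] - mean)

        step = np.full(n_blocks, 0.2)
        step[0] = 0.5 * s_hat  # mu
        # per-arm effects move on the data scale
        arm_lo = 2 + (lay.n_beta if free_beta else 0) + (1 if free_phi else 0)
        step[arm_lo : arm_lo + lay.n_arms] = 0.5 * s_hat
        acc = np.zeros(n_blocks)
        prop = np.zeros(n_blocks)

        n_iter = cfg.n_burn + cfg.n_keep
        kept = 0
        inv_mu_sd2 = 1.0 / pri.mu_sd**2
        inv_beta_sd2 = 1.0 / pri.beta_sd**2

        for it in range(n_iter):
            burning = it < cfg.n_burn

            # -- mu ------------------------------------------------------------
            b = 0
            prop[b] += 1
            mu_new = mu + step[b] * rng.standard_normal()
            d = delta - mu
            d_new = delta - mu_new
            dlp = (
                -0.5 * inv_mu_sd2 * (mu_new**2 - mu**2)
                - 0.5 * (float(d_new @ d_new) - float(d @ d)) / sigma**2
            )
            if dlp >= 0 or math.log(rng.random()) < dlp:
                mu = mu_new
                acc[b] += 1

            # -- sigma (log scale) ----------------------------------------------
            b = 1
            prop[b] += 1
            sig_new = sigma * math.exp(step[b] * rng.standard_normal())
            if sig_new < sigma_upper:
                d = delta - mu
                ssq = float(d @ d)
                # U(0, upper) prior + log-scale Jacobian (one power of sigma)
                dlp = (
                    -lay.n_arms * (math.log(sig_new) - math.log(sigma))
                    - 0.5 * ssq * (1.0 / sig_new**2 - 1.0 / sigma**2)
                    + (math.log(sig_new) - math.log(sigma))
                )
                if dlp >= 0 or math.log(rng.random()) < dlp:
                    sigma = sig_new
                    acc[b] += 1

            # -- basic mapping ratios -------------------------------------------
            if free_beta:
                for k in range(lay.n_beta):
                    b = 2 + k
                    prop[b] += 1
                    bk = beta[k]
                    bk_new = bk + step[b] * rng.standard_normal()
                    dlp = -0.5 * inv_beta_sd2 * (bk_new**2 - bk**2)
                    touched = []
                    if beta_in_lik:
                        for ti, pos in comp.trials_by_beta[k]:
                            mean = mean_c[ti].copy()
                            mean[pos] = bk_new * delta[comp.obs_arm[ti][pos]]
                            ll_new = comp.const[ti] - 0.5 * _quad(
                                comp.vinv[ti], comp.y[ti] - mean
                            )
                            dlp += ll_new - ll[ti]
                            touched.append((ti, mean, ll_new))
                    if has_btr:
                        js = comp.btrs_by_beta[k]
                        if js.size:
                            dlp += hier_logpdf(
                                btr[js], np.full(js.size, bk_new), phi
                            ) - hier_logpdf(btr[js], np.full(js.size, bk), phi)
                    if math.isfinite(dlp) and (
                        dlp >= 0 or math.log(rng.random()) < dlp
                    ):
                        beta[k] = bk_new
                        for ti, mean, ll_new in touched:
                            mean_c[ti] = mean
                            ll[ti] = ll_new
                        acc[b] += 1

            # -- phi (log scale) ------------------------------------------------
            if free_phi:
                b = 2 + lay.n_beta
                prop[b] += 1
                phi_new = phi * math.exp(step[b] * rng.standard_normal())
                if phi_new <= pri.phi_upper:
                    bmeans = beta[lay.trial_ratio_beta]
                    dlp = (
                        hier_logpdf(btr, bmeans, phi_new)
                        - hier_logpdf(btr, bmeans, phi)
                        + (math.log(phi_new) - math.log(phi))  # Jacobian
                    )
                    if math.isfinite(dlp) and (
                        dlp >= 0 or math.log(rng.random()) < dlp
                    ):
                        phi = phi_new
                        acc[b] += 1

            # -- per-arm random effects ----------------------------------------
            for j in range(lay.n_arms):
                b = arm_lo + j
                prop[b] += 1
                ti = comp.trial_of_arm[j]
                dj = delta[j]
                dj_new = dj + step[b] * rng.standard_normal()
                pos = comp.pos_by_arm[ti][j]
                mean = mean_c[ti].copy()
                ratios = comp.ratio_obs(ti, beta, btr)
                mean[pos] = ratios[pos] * dj_new
                ll_new = comp.const[ti] - 0.5 * _quad(
                    comp.vinv[ti], comp.y[ti] - mean
                )
                dlp = (
                    ll_new
                    - ll[ti]
                    - 0.5 * ((dj_new - mu) ** 2 - (dj - mu) ** 2) / sigma**2
                )
                if dlp >= 0 or math.log(rng.random()) < dlp:
                    delta[j] = dj_new
                    mean_c[ti] = mean
                    ll[ti] = ll_new
                    acc[b] += 1

            # -- trial-specific ratios -----------------------------------------
            if has_btr:
                btr_lo = arm_lo + lay.n_arms
                for j in range(lay.n_trial_ratios):
                    b = btr_lo + j
                    prop[b] += 1
                    ti = comp.trial_of_btr[j]
                    bj = btr[j]
                    bj_new = bj + step[b] * rng.standard_normal()
                    k = lay.trial_ratio_beta[j]
                    dlp = hier_logpdf(
                        np.array([bj_new]), np.array([beta[k]]), phi
                    ) - hier_logpdf(np.array([bj]), np.array([beta[k]]), phi)
                    pos = comp.pos_by_btr[ti][j]
                    mean = mean_c[ti].copy()
                    mean[pos] = bj_new * delta[comp.obs_arm[ti][pos]]
                    ll_new = comp.const[ti] - 0.5 * _quad(
                        comp.vinv[ti], comp.y[ti] - mean
                    )
                    dlp += ll_new - ll[ti]
                    if math.isfinite(dlp) and (
                        dlp >= 0 or math.log(rng.random()) < dlp
                    ):
                        btr[j] = bj_new
                        mean_c[ti] = mean
                        ll[ti] = ll_new
                        acc[b] += 1

            # -- adaptation (burn-in only) -------------------------------------
            if burning and (it + 1) % cfg.adapt_interval == 0:
                with np.errstate(invalid="ignore"):
                    rate = np.where(prop > 0, acc / np.maximum(prop, 1), 0.0)
                step *= np.exp(np.clip(rate - cfg.target_accept, -0.5, 0.5))
                step = np.clip(step, 1e-8, 1e4)
                acc[:] = 0
                prop[:] = 0

            # -- record ---------------------------------------------------------
            if not burning:
                if (it - cfg.n_burn) % cfg.thin == 0 and kept < n_kept:
                    all_draws["mu"][chain, kept] = mu
                    all_draws["sigma"][chain, kept] = sigma
                    if free_beta:
                        for k, name in enumerate(lay.beta_names):
                            all_draws[f"beta[{lay.reference}->{name}]"][
                                chain, kept
                            ] = beta[k]
                    if free_phi:
                        all_draws["phi"][chain, kept] = phi
                    for j, (tid, arm) in enumerate(lay.arm_keys):
                        all_draws[f"delta[{tid}:{arm}]"][chain, kept] = delta[j]
                    resdev = -2.0 * float(np.sum(ll - np.array(comp.const)))
                    all_draws["resdev"][chain, kept] = resdev
                    kept += 1

        # post-burn-in acceptance (steps frozen after burn-in)
        labels = _block_labels(lay, free_beta, free_phi, has_btr)
        with np.errstate(invalid="ignore"):
            rates = np.where(prop > 0, acc / np.maximum(prop, 1), np.nan)
        for name, r in zip(labels, rates):
            acc_total[f"chain{chain}:{name}"] = float(r)

        stuck = [
            labels[i]
            for i in range(n_blocks)
            if prop[i] > 0 and acc[i] == 0 and cfg.n_keep >= 200
        ]
        if stuck:
            raise ValidationError(
                f"chain {chain}: no accepted proposals after adaptation for "
                f"block(s) {stuck[:5]}"
            )

    return PosteriorSamples(
        draws=all_draws,
        layout=lay,
        spec=spec,
        config=cfg,
        acceptance=acc_total,
    )


def _block_labels(lay, free_beta, free_phi, has_btr):
    labels = ["mu", "sigma"]
    if free_beta:
        labels += [f"beta[{lay.reference}->{n}]" for n in lay.beta_names]
    if free_phi:
        labels.append("phi")
    labels += [f"delta[{tid}:{arm}]" for tid, arm in lay.arm_keys]
    if has_btr:
        labels += [f"beta_trial[{tid}:{n}]" for tid, n in lay.trial_ratio_keys]
    return labels


def gelman_rubin(samples: PosteriorSamples | Mapping[str, np.ndarray]) -> dict[str, float]:
    """Split-R-hat (Brooks–Gelman) per stored scalar parameter.

    Each chain is split in half; R-hat compares the between- to within-half
    variance.  Well-mixed chains give values near 1 (to O(1/length));
    chains stuck at different means give values well above 1.  Requires at
    least two chains.
    """
    draws = samples.draws if isinstance(samples, PosteriorSamples) else samples
    out: dict[str, float] = {}
    for name, arr in draws.items():
        if name == "resdev":
            continue
        arr = np.asarray(arr, dtype=float)
        if arr.ndim != 2 or arr.shape[0] < 2:
            raise ValidationError("gelman_rubin requires >=2 chains")
        n = arr.shape[1] // 2
        halves = np.concatenate([arr[:, :n], arr[:, n : 2 * n]], axis=0)
        m, length = halves.shape
        chain_means = halves.mean(axis=1)
        chain_vars = halves.var(axis=1, ddof=1)
        w = chain_vars.mean()
        b = length * chain_means.var(ddof=1)
        if w <= 0:
            out[name] = 1.0 if b <= 0 else np.inf
            continue
        var_plus = (length - 1) / length * w + b / length
        out[name] = float(np.sqrt(var_plus / w))
    return out


def residual_deviance(samples: PosteriorSamples) -> float:
    """Posterior mean residual deviance.

    Per draw, the sum over trials of ``(y - theta)' V^{-1} (y - theta)``;
    a well-fitting model scores about one per observation.
    """
    return float(np.mean(samples.stacked("resdev")))


def _summary_row(x: np.ndarray, rhat: float | None) -> dict:
    q = np.quantile(x, [0.025, 0.5, 0.975])
    return {
        "mean": float(np.mean(x)),
        "sd": float(np.std(x, ddof=1)),
        "median": float(q[1]),
        "q2.5": float(q[0]),
        "q97.5": float(q[2]),
        "rhat": rhat if rhat is not None else np.nan,
    }


def summarise(samples: PosteriorSamples) -> FitReport:
    """Tabulate posterior summaries and the mean residual deviance."""
    rhats = (
        gelman_rubin(samples) if samples.n_chains >= 2 else
        {k: float("nan") for k in samples.parameter_names}
    )
    rows = {}
    for name in samples.parameter_names:
        rows[name] = _summary_row(samples.stacked(name), rhats.get(name))
    params = pd.DataFrame.from_dict(rows, orient="index")
    params.index.name = "parameter"
    finite = params["rhat"].dropna()
    return FitReport(
        params=params,
        mean_residual_deviance=residual_deviance(samples),
        n_observations=_n_obs_of(samples.layout),
        spec=samples.spec.to_dict(),
        config=samples.config.to_dict(),
        max_rhat=float(finite.max()) if len(finite) else float("nan"),
    )


def _n_obs_of(layout: ModelLayout) -> int:
    return sum(t.n_observations() for t in layout.trials)


def fit(
    spec: ModelSpec,
    ds: TrialDataset,
    cfg: MCMCConfig,
) -> tuple[PosteriorSamples, FitReport]:
    """Convenience wrapper: sample, then summarise."""
    samples = run_mcmc(spec, ds, cfg)
    report = summarise(samples)
    if cfg.rhat_gate is not None and report.max_rhat > cfg.rhat_gate:
        worst = report.params["rhat"].idxmax()
        raise ValidationError(
            f"convergence gate failed: max R-hat {report.max_rhat:.3f} "
            f"({worst}) exceeds {cfg.rhat_gate}"
        )
    return samples, report
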