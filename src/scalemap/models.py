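"""Mapping-ratio synthesis models.

The treatment effect of trial *i*, active arm *a*, on the reference
instrument is a random effect ``delta[i,a] ~ N(mu, sigma^2)`` — a
conventional random-effects meta-analysis, with every active arm of a
multi-arm trial drawn from the same distribution.  Effects on any other
instrument *k* are tied to the reference effect through a multiplicative
mapping ratio:

* ``fixed_mapping``   — the ratio ``beta[1->k]`` is the same in every trial;
* ``random_mapping``  — each trial has its own ratio
  ``beta[i,1->k] ~ N(beta[1->k], (phi * |beta[1->k]|)^2)``, i.e. ratios vary
  between trials with a constant coefficient of variation ``phi``;
* ``ratios_one``      — all ratios clamped to 1 (every instrument equally
  responsive), meaningful for standardised data.

With M instruments only the M-1 *basic* ratios from the reference are free
parameters; all other pairwise ratios follow by transitivity.  The observed
mean-difference vector of each trial is multivariate normal around the
expected effects with the within-trial covariance of
:mod:`scalemap.covariance`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.linalg import solve_triangular

from .covariance import TrialCovariance, dataset_covariances
from .data import TrialDataset, TrialRecord, ValidationError, instrument_network

__all__ = [
    "VARIANTS",
    "PriorSpec",
    "ModelSpec",
    "ModelLayout",
    "ParameterState",
    "derived_mapping",
    "expected_effects",
    "log_prior",
    "log_likelihood",
]

VARIANTS = ("fixed_mapping", "random_mapping", "ratios_one")

_LOG_2PI = math.log(2.0 * math.pi)
_PHI_FLOOR = 1e-12  # guards the phi -> 0 point-mass limit of the hierarchy


@dataclass(frozen=True)
class PriorSpec:
    """Vague priors on the hyperparameters.

    ``sigma_upper`` is the upper bound of the uniform prior on the
    between-trials SD; ``None`` picks 50 on raw scales and 5 on standardised
    ones (both far above any plausible heterogeneity in the worked example).
    """

    mu_sd: float = 100.0
    beta_sd: float = 100.0
    sigma_upper: float | None = None
    phi_upper: float = 2.0

    def resolve_sigma_upper(self, standardised: bool) -> float:
        if self.sigma_upper is not None:
            return self.sigma_upper
        return 5.0 if standardised else 50.0


@dataclass(frozen=True)
class ModelSpec:
    """Which model to fit, on which scale, against which reference."""

    variant: str = "fixed_mapping"
    standardised: bool = False
    reference_instrument: str = "LSAS"
    rho: float = 0.65
    priors: PriorSpec = field(default_factory=PriorSpec)
    phi_fixed: float | None = None
    ratio_hierarchy: str = "natural"  # or "log": lognormal trial ratios

    def __post_init__(self) -> None:
        if self.variant not in VARIANTS:
            raise ValidationError(f"unknown model variant {self.variant!r}")
        if self.ratio_hierarchy not in ("natural", "log"):
            raise ValidationError("ratio_hierarchy must be 'natural' or 'log'")
        if self.phi_fixed is not None and self.phi_fixed < 0:
            raise ValidationError("phi_fixed must be >= 0")

    @property
    def has_free_ratios(self) -> bool:
        return self.variant in ("fixed_mapping", "random_mapping")

    @property
    def has_trial_ratios(self) -> bool:
        """Trial-specific ratios are sampled (collapses away at phi == 0)."""
        return self.variant == "random_mapping" and self.phi_fixed != 0

    def to_dict(self) -> dict:
        return {
            "variant": self.variant,
            "standardised": self.standardised,
            "reference_instrument": self.reference_instrument,
            "rho": self.rho,
            "phi_fixed": self.phi_fixed,
            "ratio_hierarchy": self.ratio_hierarchy,
            "priors": {
                "mu_sd": self.priors.mu_sd,
                "beta_sd": self.priors.beta_sd,
                "sigma_upper": self.priors.sigma_upper,
                "phi_upper": self.priors.phi_upper,
            },
        }

    @classmethod
    def from_dict(cls, d: Mapping) -> "ModelSpec":
        d = dict(d)
        priors = d.pop("priors", None)
        if priors is not None:
            d["priors"] = PriorSpec(**priors)
        return cls(**d)


class ModelLayout:
    """Flattened parameter indexing for a (dataset, spec) pair.

    Trials are processed in sorted ``trial_id`` order so that posteriors do
    not depend on input row order.  The layout defines:

    * ``arm_keys[j] = (trial_id, arm_index)`` — index of ``delta[j]``;
    * ``beta_names[j]`` — non-reference instruments, dataset order, index of
      ``beta[j]``;
    * ``trial_ratio_keys[j] = (trial_id, instrument)`` — index of the
      trial-specific ratio ``beta_trial[j]`` (random-mapping only; one per
      non-reference instrument actually reported by the trial, shared across
      that trial's arms).
    """

    def __init__(self, ds: TrialDataset, spec: ModelSpec):
        if spec.standardised != ds.standardised:
            raise ValidationError(
                "ModelSpec.standardised does not match dataset.standardised; "
                "standardise the dataset first (or fix the spec)"
            )
        ref = spec.reference_instrument
        if ref not in ds.instrument_names:
            raise ValidationError(f"reference instrument {ref!r} not in dataset")
        net = instrument_network(ds)
        if net.components and ref not in max(net.components, key=len):
            raise ValidationError(
                f"reference instrument {ref!r} lies outside the largest "
                "connected component of the instrument network"
            )
        modelled = net.component_of(ref) if net.components else frozenset()
        unreachable = [
            n
            for t in ds.trials
            for n in t.instruments
            if n not in modelled
        ]
        if unreachable:
            raise ValidationError(
                "instruments disconnected from the reference cannot be "
                f"modelled: {sorted(set(unreachable))}"
            )

        self.spec = spec
        self.dataset = ds
        self.reference = ref
        self.trials: tuple[TrialRecord, ...] = tuple(
            sorted(ds.trials, key=lambda t: t.trial_id)
        )
        self.beta_names: tuple[str, ...] = tuple(
            n for n in ds.instrument_names if n != ref
        )
        self._beta_index = {n: j for j, n in enumerate(self.beta_names)}

        arm_keys: list[tuple[str, int]] = []
        trial_ratio_keys: list[tuple[str, str]] = []
        for t in self.trials:
            for arm in range(1, len(t.n_active) + 1):
                arm_keys.append((t.trial_id, arm))
            if spec.has_trial_ratios:
                for name in ds.instrument_names:
                    if name != ref and name in t.instruments:
                        trial_ratio_keys.append((t.trial_id, name))
        self.arm_keys = tuple(arm_keys)
        self.trial_ratio_keys = tuple(trial_ratio_keys)
        self._arm_index = {k: j for j, k in enumerate(self.arm_keys)}
        self._trial_ratio_index = {k: j for j, k in enumerate(self.trial_ratio_keys)}
        # beta index backing each trial ratio (for the hierarchical prior)
        self.trial_ratio_beta = np.array(
            [self._beta_index[name] for _, name in self.trial_ratio_keys], dtype=int
        )

    @property
    def n_arms(self) -> int:
        return len(self.arm_keys)

    @property
    def n_beta(self) -> int:
        return len(self.beta_names)

    @property
    def n_trial_ratios(self) -> int:
        return len(self.trial_ratio_keys)

    def beta_index(self, instrument: str) -> int:
        return self._beta_index[instrument]

    def arm_index(self, trial_id: str, arm: int) -> int:
        return self._arm_index[(trial_id, arm)]

    def trial_ratio_index(self, trial_id: str, instrument: str) -> int:
        return self._trial_ratio_index[(trial_id, instrument)]


@dataclass
class ParameterState:
    """One point in parameter space, aligned to a :class:`ModelLayout`."""

    layout: ModelLayout
    mu: float
    sigma: float
    beta: np.ndarray  # (n_beta,), ratios reference -> other instruments
    phi: float = 0.0
    delta: np.ndarray = None  # (n_arms,), per active arm, reference scale
    beta_trial: np.ndarray = None  # (n_trial_ratios,), random mapping only

    def __post_init__(self) -> None:
        lay = self.layout
        self.beta = np.atleast_1d(np.asarray(self.beta, dtype=float))
        if self.beta.shape != (lay.n_beta,):
            raise ValidationError(
                f"beta has shape {self.beta.shape}, layout expects ({lay.n_beta},)"
            )
        if self.delta is None:
            self.delta = np.full(lay.n_arms, self.mu)
        self.delta = np.asarray(self.delta, dtype=float)
        if self.delta.shape != (lay.n_arms,):
            raise ValidationError("delta length does not match layout arms")
        if self.beta_trial is None:
            self.beta_trial = self.beta[lay.trial_ratio_beta].copy()
        self.beta_trial = np.asarray(self.beta_trial, dtype=float)
        if self.beta_trial.shape != (lay.n_trial_ratios,):
            raise ValidationError("beta_trial length does not match layout")

    def copy(self) -> "ParameterState":
        return ParameterState(
            layout=self.layout,
            mu=self.mu,
            sigma=self.sigma,
            beta=self.beta.copy(),
            phi=self.phi,
            delta=self.delta.copy(),
            beta_trial=self.beta_trial.copy(),
        )

    def beta_of(self, instrument: str) -> float:
        """Basic mapping ratio reference -> instrument (1 for the reference)."""
        if instrument == self.layout.reference:
            return 1.0
        return float(self.beta[self.layout.beta_index(instrument)])


def derived_mapping(
    beta_basic: Mapping[str, float], h: str, k: str, reference: str
) -> float:
    """Pairwise mapping ratio ``beta[h->k]`` from the basic parameters.

    Transitivity pins every pairwise ratio to a quotient of basic ones:
    ``beta[h->k] = beta[ref->k] / beta[ref->h]`` with ``beta[ref->ref] = 1``.
    """

    def basic(name: str) -> float:
        if name == reference:
            return 1.0
        try:
            return float(beta_basic[name])
        except KeyError:
            raise ValidationError(f"no basic mapping parameter for {name!r}") from None

    bh = basic(h)
    if bh == 0.0:
        raise ValidationError(f"degenerate mapping: beta[ref->{h}] is zero")
    return basic(k) / bh


def _trial_ratio_obs(state: ParameterState, spec: ModelSpec, t: TrialRecord):
    """Per-observation mapping ratio for one trial (layout order)."""
    lay = state.layout
    ratios = []
    for arm, obs in enumerate(t.observations, start=1):
        for o in obs:
            if spec.variant == "ratios_one" or o.instrument == lay.reference:
                ratios.append(1.0)
            elif spec.has_trial_ratios:
                try:
                    j = lay.trial_ratio_index(t.trial_id, o.instrument)
                except KeyError:
                    raise ValidationError(
                        f"no trial-specific ratio for trial {t.trial_id!r} "
                        f"instrument {o.instrument!r}"
                    ) from None
                ratios.append(float(state.beta_trial[j]))
            else:
                ratios.append(float(state.beta[lay.beta_index(o.instrument)]))
    return np.array(ratios)


def expected_effects(
    state: ParameterState, spec: ModelSpec, t: TrialRecord
) -> np.ndarray:
    """Model-expected mean differences for trial ``t``, covariance layout order.

    Entry for (arm a, instrument k) is ``ratio[k] * delta[i,a]`` where the
    ratio is 1 for the reference (and for every instrument under
    ``ratios_one``), the basic ratio under ``fixed_mapping``, and the
    trial-specific ratio under ``random_mapping``.
    """
    lay = state.layout
    ratios = _trial_ratio_obs(state, spec, t)
    deltas = []
    for arm, obs in enumerate(t.observations, start=1):
        d = state.delta[lay.arm_index(t.trial_id, arm)]
        deltas.extend([d] * len(obs))
    return ratios * np.asarray(deltas)


def _norm_logpdf(x, mean, sd):
    z = (np.asarray(x) - mean) / sd
    return -0.5 * z * z - np.log(sd) - 0.5 * _LOG_2PI


def log_prior(state: ParameterState, spec: ModelSpec) -> float:
    """Joint log density of priors and hierarchical layers.

    Returns ``-inf`` (never raises) outside the support: non-positive sigma,
    phi outside its uniform bounds.
    """
    pri = spec.priors
    sigma_upper = pri.resolve_sigma_upper(spec.standardised)
    if not 0.0 < state.sigma < sigma_upper:
        return -math.inf
    lp = float(_norm_logpdf(state.mu, 0.0, pri.mu_sd))
    lp -= math.log(sigma_upper)  # sigma ~ U(0, upper)

    if spec.has_free_ratios:
        lp += float(np.sum(_norm_logpdf(state.beta, 0.0, pri.beta_sd)))

    # random effects: one per active arm, shared distribution
    lp += float(np.sum(_norm_logpdf(state.delta, state.mu, state.sigma)))

    if spec.variant == "random_mapping":
        phi = spec.phi_fixed if spec.phi_fixed is not None else state.phi
        if spec.phi_fixed is None:
            if not 0.0 <= state.phi <= pri.phi_upper:
                return -math.inf
            lp -= math.log(pri.phi_upper)  # phi ~ U(0, upper)
        if spec.has_trial_ratios:
            lay = state.layout
            b = state.beta[lay.trial_ratio_beta]
            phi_eff = max(phi, _PHI_FLOOR)
            if spec.ratio_hierarchy == "natural":
                sd = phi_eff * np.abs(b)
                sd = np.maximum(sd, _PHI_FLOOR)
                lp += float(np.sum(_norm_logpdf(state.beta_trial, b, sd)))
            else:  # lognormal with matching CV
                if np.any(state.beta_trial * b <= 0):
                    return -math.inf
                s = math.sqrt(math.log1p(phi_eff**2))
                x = np.abs(state.beta_trial)
                m = np.log(np.abs(b)) - 0.5 * s * s
                lp += float(np.sum(_norm_logpdf(np.log(x), m, s) - np.log(x)))
    if not math.isfinite(lp):
        return -math.inf
    return lp


def log_likelihood(
    state: ParameterState,
    spec: ModelSpec,
    ds: TrialDataset,
    covs: Sequence[TrialCovariance] | None = None,
) -> float:
    """Multivariate-normal log likelihood summed over trials."""
    if covs is None:
        covs = dataset_covariances(ds.trials, spec.rho)
    by_id = {c.trial_id: c for c in covs}
    total = 0.0
    for t in ds.trials:
        cov = by_id[t.trial_id]
        y = np.array(
            [o.mean_diff for obs in t.observations for o in obs]
        )
        if cov.dim != y.size:
            raise ValidationError(
                f"trial {t.trial_id!r}: covariance dimension {cov.dim} does "
                f"not match {y.size} observations"
            )
        mean = expected_effects(state, spec, t)
        L = cov.cholesky()
        z = solve_triangular(L, y - mean, lower=True)
        logdet = 2.0 * float(np.sum(np.log(np.diag(L))))
        total += -0.5 * (y.size * _LOG_2PI + logdet + float(z @ z))
    return total


def reparameterise_reference(
    state: ParameterState, new_reference: str, new_layout: ModelLayout
) -> ParameterState:
    """Express a state relative to a different reference instrument.

    ``delta' = beta[ref->r] * delta`` and ``beta'[r->k] = beta[ref->k] /
    beta[ref->r]``; the likelihood is invariant under this change because the
    expected effects are unchanged.
    """
    b_r = state.beta_of(new_reference)
    if b_r == 0.0:
        raise ValidationError("cannot re-reference through a zero mapping")
    old_lay = state.layout
    beta_new = np.array(
        [state.beta_of(name) / b_r for name in new_layout.beta_names]
    )
    delta_new = np.array(
        [
            state.delta[old_lay.arm_index(tid, arm)] * b_r
            for tid, arm in new_layout.arm_keys
        ]
    )
    if new_layout.n_trial_ratios:
        btr_new = np.empty(new_layout.n_trial_ratios)
        for j, (tid, name) in enumerate(new_layout.trial_ratio_keys):
            try:
                old = state.beta_trial[old_lay.trial_ratio_index(tid, name)]
            except KeyError:
                old = state.beta_of(name)
            btr_new[j] = old / b_r
    else:
        btr_new = None
    return ParameterState(
        layout=new_layout,
        mu=state.mu * b_r,
        sigma=state.sigma * abs(b_r),
        beta=beta_new,
        phi=state.phi,
        delta=delta_new,
        beta_trial=btr_new,
    )
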