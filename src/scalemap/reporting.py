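"""Derived outputs: mapped effects, relative precision, sensitivity runs.

Once the posterior carries the pooled reference-scale effect ``mu``, the
heterogeneity ``sigma``, and the basic mapping ratios, the pooled effect can
be re-expressed on *any* connected instrument by transforming each draw:
``beta[ref->k] * mu`` for the effect and ``|beta[ref->k]| * sigma`` for the
between-trials SD.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Sequence

import numpy as np
import pandas as pd

from .data import Instrument, TrialDataset, ValidationError
from .inference import FitReport, MCMCConfig, PosteriorSamples, run_mcmc, summarise
from .models import ModelSpec

__all__ = [
    "map_pooled_effects",
    "relative_precision",
    "range_ratio_conversion",
    "rho_sensitivity",
]


def map_pooled_effects(samples: PosteriorSamples) -> pd.DataFrame:
    """Pooled effect and between-trials SD on every modelled instrument.

    One row per instrument: posterior mean and equal-tailed 95% CrI of the
    mapped effect, posterior median and 95% CrI of the mapped SD.  The
    reference row reproduces the raw ``mu`` / ``sigma`` summaries exactly.
    """
    lay = samples.layout
    mu = samples.stacked("mu")
    sigma = samples.stacked("sigma")
    rows = {}
    for name in lay.dataset.instrument_names:
        if name == lay.reference:
            b = np.ones_like(mu)
        else:
            key = samples.beta_name(name)
            if key not in samples.draws:
                raise ValidationError(
                    f"no mapping draws for instrument {name!r} "
                    "(was the model fitted with free ratios?)"
                )
            b = samples.stacked(key)
        eff = b * mu
        sd = np.abs(b) * sigma
        e_lo, e_hi = np.quantile(eff, [0.025, 0.975])
        s_lo, s_md, s_hi = np.quantile(sd, [0.025, 0.5, 0.975])
        rows[name] = {
            "effect_mean": float(np.mean(eff)),
            "effect_q2.5": float(e_lo),
            "effect_q97.5": float(e_hi),
            "sd_median": float(s_md),
            "sd_q2.5": float(s_lo),
            "sd_q97.5": float(s_hi),
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "instrument"
    return out


def relative_precision(reports: dict[str, FitReport] | Sequence[FitReport]) -> pd.DataFrame:
    """Signal-to-noise ratios of the pooled effect, per fitted model.

    Two ratios per model: |posterior mean of mu| over its posterior SD
    (precision of the estimate) and over the posterior median of sigma
    (effect relative to between-trials heterogeneity).  Both are invariant
    under rescaling of the measurement units.
    """
    if not isinstance(reports, dict):
        reports = {r.spec.get("variant", f"model{i}"): r for i, r in enumerate(reports)}
    rows = {}
    for label, rep in reports.items():
        mu = rep.row("mu")
        sigma = rep.row("sigma")
        if mu["sd"] <= 0:
            raise ValidationError(f"model {label!r}: zero posterior SD for mu")
        if sigma["median"] <= 0:
            raise ValidationError(f"model {label!r}: non-positive sigma median")
        rows[label] = {
            "effect_over_posterior_sd": abs(mu["mean"]) / mu["sd"],
            "effect_over_between_trial_sd": abs(mu["mean"]) / sigma["median"],
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "model"
    return out


def range_ratio_conversion(from_instrument: Instrument, to_instrument: Instrument) -> float:
    """Heuristic scale conversion by ratio of theoretical ranges.

    A crude alternative to the estimated mapping ratio: multiplying an
    effect on ``from_instrument`` by ``range(to)/range(from)`` re-expresses
    it on ``to_instrument`` assuming both scales are used proportionally.
    """
    for ins in (from_instrument, to_instrument):
        if ins.scale_range is None:
            raise ValidationError(f"instrument {ins.name!r} has no scale_range")
    return to_instrument.scale_range / from_instrument.scale_range


def rho_sensitivity(
    spec: ModelSpec,
    ds: TrialDataset,
    cfg: MCMCConfig,
    rhos: Sequence[float],
) -> pd.DataFrame:
    """Refit under alternative between-test correlations.

    One row per requested rho with the shift, relative to the baseline
    ``spec.rho``, of the mean residual deviance and of the key posterior
    summaries.  All runs reuse the baseline seed so the deltas are not
    dominated by Monte-Carlo noise.
    """
    base_samples = run_mcmc(spec, ds, cfg)
    base = summarise(base_samples)
    rows = {}
    for rho in rhos:
        if rho == spec.rho:
            rep = base
        else:
            rep = summarise(run_mcmc(replace(spec, rho=rho), ds, cfg))
        row = {
            "mean_residual_deviance": rep.mean_residual_deviance,
            "delta_resdev": rep.mean_residual_deviance - base.mean_residual_deviance,
            "mu_mean": rep.row("mu")["mean"],
            "delta_mu_mean": rep.row("mu")["mean"] - base.row("mu")["mean"],
            "sigma_median": rep.row("sigma")["median"],
            "delta_sigma_median": rep.row("sigma")["median"]
            - base.row("sigma")["median"],
        }
        if "phi" in rep.params.index:
            row["phi_median"] = rep.row("phi")["median"]
            row["delta_phi_median"] = (
                rep.row("phi")["median"] - base.row("phi")["median"]
            )
        rows[rho] = row
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "rho"
    return out
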