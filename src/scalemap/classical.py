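"""Classical variance homogeneity companions.

Trials report one pooled within-trial SD per instrument.  Bartlett's test
asks whether those SDs are compatible with a single population variance;
the pooled within-study SD is the df-weighted root mean square.  Both
operate on (sd, df) pairs, with df = total randomised patients minus the
number of arms (the df behind a pooled across-arm SD).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .data import TrialDataset, ValidationError

__all__ = [
    "VarianceSample",
    "variance_samples",
    "bartlett_test",
    "pooled_within_sd",
]


@dataclass(frozen=True)
class VarianceSample:
    """One trial's pooled SD on an instrument and its degrees of freedom."""

    trial_id: str
    sd: float
    df: int

    def __post_init__(self) -> None:
        if self.df < 1:
            raise ValidationError(f"trial {self.trial_id!r}: df must be >= 1")
        if not self.sd > 0:
            raise ValidationError(f"trial {self.trial_id!r}: sd must be positive")


def variance_samples(ds: TrialDataset, instrument: str) -> list[VarianceSample]:
    """Extract (sd, df) pairs for one instrument from a dataset.

    The pooled SD is taken once per trial (it is shared across arms); the
    df is the trial's total randomised sample size minus its arm count.
    """
    out = []
    for t in ds.trials:
        sds = {
            o.pooled_sd
            for obs in t.observations
            for o in obs
            if o.instrument == instrument and o.pooled_sd is not None
        }
        if not sds:
            continue
        if len(sds) > 1:
            raise ValidationError(
                f"trial {t.trial_id!r}: inconsistent pooled SDs for {instrument!r}"
            )
        out.append(
            VarianceSample(trial_id=t.trial_id, sd=sds.pop(), df=t.n_total - t.n_arms)
        )
    return out


def bartlett_test(samples: list[VarianceSample]) -> tuple[float, int, float]:
    """Bartlett's homogeneity-of-variance test from summary (sd, df) pairs.

    Returns (corrected chi-square statistic, k-1 degrees of freedom,
    upper-tail p-value).  The statistic is zero when all SDs coincide and
    is invariant under a common rescaling of the SDs.
    """
    if len(samples) < 2:
        raise ValidationError("bartlett_test needs at least two variance samples")
    df = np.array([s.df for s in samples], dtype=float)
    s2 = np.array([s.sd for s in samples], dtype=float) ** 2
    n = df.sum()
    k = len(samples)
    sp2 = float((df * s2).sum() / n)
    stat = n * np.log(sp2) - float((df * np.log(s2)).sum())
    correction = 1.0 + (float((1.0 / df).sum()) - 1.0 / n) / (3.0 * (k - 1))
    stat /= correction
    p = float(stats.chi2.sf(stat, k - 1))
    return float(stat), k - 1, p


def pooled_within_sd(samples: list[VarianceSample]) -> float:
    """Within-study SD pooled over trials: sqrt(sum df*sd^2 / sum df)."""
    if not samples:
        raise ValidationError("pooled_within_sd needs at least one sample")
    df = np.array([s.df for s in samples], dtype=float)
    s2 = np.array([s.sd for s in samples], dtype=float) ** 2
    return float(np.sqrt((df * s2).sum() / df.sum()))
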