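"""Within-trial covariance of the observed mean-difference vector.

Each trial contributes a vector of mean treatment differences laid out as
(arm 1 instruments..., arm 2 instruments..., ...).  Its covariance combines
two sources of dependence:

* different instruments measured on the same patients correlate with the
  assumed between-test score correlation ``rho``;
* active arms compared against the same control arm share the control-arm
  sampling error, contributing ``sd^2 / n_control`` terms.

The entries are, for observations (a, h) and (b, k):

====================  =========================================
same arm, h == k      ``se_h^2``
same arm, h != k      ``rho * se_h * se_k``
a != b, h == k        ``sd_h^2 / n_control``
a != b, h != k        ``rho * sd_h * sd_k / n_control``
====================  =========================================

where ``sd`` is the trial's pooled SD on the relevant instrument.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .data import TrialRecord, ValidationError

__all__ = ["TrialCovariance", "trial_covariance", "dataset_covariances"]


@dataclass(frozen=True)
class TrialCovariance:
    """Covariance of a trial's observation vector, plus its layout.

    ``order[j] = (arm_index, instrument)`` gives the meaning of row/column j.
    """

    trial_id: str
    order: tuple[tuple[int, str], ...]
    matrix: np.ndarray

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        if m.shape != (len(self.order), len(self.order)):
            raise ValidationError(
                f"trial {self.trial_id!r}: covariance shape {m.shape} does not "
                f"match layout of length {len(self.order)}"
            )

    @property
    def dim(self) -> int:
        return len(self.order)

    def cholesky(self) -> np.ndarray:
        try:
            return np.linalg.cholesky(self.matrix)
        except np.linalg.LinAlgError as exc:
            raise ValidationError(
                f"trial {self.trial_id!r}: covariance matrix is not positive "
                "definite (check se / pooled_sd / n_control consistency)"
            ) from exc


def trial_covariance(t: TrialRecord, rho: float) -> TrialCovariance:
    """Build the covariance matrix of trial ``t``'s observation vector.

    ``rho`` is the common correlation between scores on different instruments
    in the same patients.  Multi-arm trials require a pooled SD on every
    instrument entering a shared-control term.
    """
    if not -1.0 < rho < 1.0:
        raise ValidationError(f"rho must lie in (-1, 1), got {rho}")

    order: list[tuple[int, str]] = []
    se: list[float] = []
    sd: list[float | None] = []
    for arm, obs in enumerate(t.observations, start=1):
        for o in obs:
            order.append((arm, o.instrument))
            se.append(o.se)
            sd.append(o.pooled_sd)

    n = len(order)
    multi_arm = len(t.n_active) > 1
    if multi_arm and any(s is None for s in sd):
        missing = [order[j] for j in range(n) if sd[j] is None]
        raise ValidationError(
            f"trial {t.trial_id!r}: pooled_sd required for shared-control "
            f"covariance terms; missing at {missing}"
        )

    mat = np.empty((n, n))
    for i in range(n):
        arm_i, ins_i = order[i]
        for j in range(i, n):
            arm_j, ins_j = order[j]
            if arm_i == arm_j:
                if i == j:
                    v = se[i] ** 2
                elif ins_i == ins_j:  # unreachable for valid records
                    v = se[i] * se[j]
                else:
                    v = rho * se[i] * se[j]
            else:
                if ins_i == ins_j:
                    v = sd[i] * sd[j] / t.n_control
                else:
                    v = rho * sd[i] * sd[j] / t.n_control
            mat[i, j] = mat[j, i] = v

    cov = TrialCovariance(trial_id=t.trial_id, order=tuple(order), matrix=mat)
    cov.cholesky()  # positive-definiteness gate
    return cov


def dataset_covariances(trials, rho: float) -> list[TrialCovariance]:
    """Per-trial covariances for an iterable of trial records."""
    return [trial_covariance(t, rho) for t in trials]
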