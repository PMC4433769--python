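"""Trial-level evidence base for multi-instrument continuous outcomes.

A dataset holds one row of evidence per (trial, active arm, instrument): the
mean treatment difference versus the shared control arm, its standard error,
and the pooled within-trial SD on that instrument.  Trials may report any
subset of the instruments; mapping models are identifiable only within a
connected component of the instrument co-reporting graph.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import networkx as nx
import pandas as pd

__all__ = [
    "Instrument",
    "ObservedDifference",
    "TrialRecord",
    "TrialDataset",
    "InstrumentNetwork",
    "ValidationError",
    "load_trials",
    "load_instruments",
    "social_anxiety_dataset",
    "count_observations",
    "standardise_dataset",
    "instrument_network",
]

REQUIRED_COLUMNS = (
    "trial_id",
    "arm_index",
    "n_control",
    "n_arm",
    "instrument",
    "mean_diff",
    "se",
    "pooled_sd",
    "basis",
)

BASES = ("follow_up", "change_score", "unknown")


class ValidationError(ValueError):
    """Raised when input evidence violates a structural requirement."""


@dataclass(frozen=True)
class Instrument:
    """A rating scale: short label, theoretical range, and score direction."""

    name: str
    scale_range: float | None = None
    lower_is_better: bool = True

    def __post_init__(self) -> None:
        if self.scale_range is not None and self.scale_range <= 0:
            raise ValidationError(
                f"instrument {self.name!r}: scale_range must be positive"
            )


@dataclass(frozen=True)
class ObservedDifference:
    """One reported mean treatment difference (active minus control)."""

    instrument: str
    mean_diff: float
    se: float
    pooled_sd: float | None = None
    basis: str = "unknown"

    def __post_init__(self) -> None:
        if not self.se > 0:
            raise ValidationError(
                f"instrument {self.instrument!r}: se must be positive, got {self.se}"
            )
        if self.pooled_sd is not None and not self.pooled_sd > 0:
            raise ValidationError(
                f"instrument {self.instrument!r}: pooled_sd must be positive"
            )
        if self.basis not in BASES:
            raise ValidationError(
                f"instrument {self.instrument!r}: basis must be one of {BASES}"
            )


@dataclass(frozen=True)
class TrialRecord:
    """One randomised trial: a control arm plus >=1 active arms.

    ``observations[a]`` lists the instruments reported for active arm ``a``.
    """

    trial_id: str
    n_control: int
    n_active: tuple[int, ...]
    observations: tuple[tuple[ObservedDifference, ...], ...]

    def __post_init__(self) -> None:
        if len(self.n_active) < 1:
            raise ValidationError(f"trial {self.trial_id!r}: needs >=1 active arm")
        if len(self.observations) != len(self.n_active):
            raise ValidationError(
                f"trial {self.trial_id!r}: one observation group per active arm"
            )
        if self.n_control < 1 or any(n < 1 for n in self.n_active):
            raise ValidationError(f"trial {self.trial_id!r}: arm sizes must be >=1")
        for arm, obs in enumerate(self.observations, start=1):
            if not obs:
                raise ValidationError(
                    f"trial {self.trial_id!r} arm {arm}: empty instrument list"
                )
            names = [o.instrument for o in obs]
            if len(set(names)) != len(names):
                raise ValidationError(
                    f"trial {self.trial_id!r} arm {arm}: duplicate instrument rows"
                )

    @property
    def n_arms(self) -> int:
        """Total number of randomised arms, control included."""
        return 1 + len(self.n_active)

    @property
    def n_total(self) -> int:
        return self.n_control + sum(self.n_active)

    @property
    def instruments(self) -> tuple[str, ...]:
        seen: dict[str, None] = {}
        for obs in self.observations:
            for o in obs:
                seen.setdefault(o.instrument, None)
        return tuple(seen)

    def n_observations(self) -> int:
        return sum(len(obs) for obs in self.observations)


@dataclass(frozen=True)
class TrialDataset:
    """The full evidence base: instruments plus trial records."""

    instruments: tuple[Instrument, ...]
    trials: tuple[TrialRecord, ...]
    standardised: bool = False

    def __post_init__(self) -> None:
        names = [i.name for i in self.instruments]
        if len(set(names)) != len(names):
            raise ValidationError("duplicate instrument names in dataset")
        known = set(names)
        for t in self.trials:
            missing = set(t.instruments) - known
            if missing:
                raise ValidationError(
                    f"trial {t.trial_id!r} references unknown instruments {sorted(missing)}"
                )
        ids = [t.trial_id for t in self.trials]
        if len(set(ids)) != len(ids):
            raise ValidationError("duplicate trial_id in dataset")

    def instrument(self, name: str) -> Instrument:
        for i in self.instruments:
            if i.name == name:
                return i
        raise KeyError(name)

    @property
    def instrument_names(self) -> tuple[str, ...]:
        return tuple(i.name for i in self.instruments)

    def to_frame(self) -> pd.DataFrame:
        """Flatten to the canonical one-row-per-observation table."""
        rows = []
        for t in self.trials:
            for arm, obs in enumerate(t.observations, start=1):
                for o in obs:
                    rows.append(
                        {
                            "trial_id": t.trial_id,
                            "arm_index": arm,
                            "n_control": t.n_control,
                            "n_arm": t.n_active[arm - 1],
                            "instrument": o.instrument,
                            "mean_diff": o.mean_diff,
                            "se": o.se,
                            "pooled_sd": o.pooled_sd,
                            "basis": o.basis,
                        }
                    )
        return pd.DataFrame(rows, columns=list(REQUIRED_COLUMNS))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class InstrumentNetwork:
    """Co-reporting graph: edge (h, k) counts trials reporting both scales."""

    nodes: tuple[str, ...]
    edges: dict[tuple[str, str], int] = field(default_factory=dict)
    components: tuple[frozenset[str], ...] = ()

    @property
    def is_connected(self) -> bool:
        return len(self.components) <= 1

    def edge_count(self, h: str, k: str) -> int:
        key = (h, k) if (h, k) in self.edges else (k, h)
        return self.edges.get(key, 0)

    def component_of(self, name: str) -> frozenset[str]:
        for comp in self.components:
            if name in comp:
                return comp
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {"instrument_a": h, "instrument_b": k, "n_trials": c}
            for (h, k), c in sorted(self.edges.items())
        ]
        return pd.DataFrame(rows, columns=["instrument_a", "instrument_b", "n_trials"])


def _instrument_table() -> pd.DataFrame:
    with importlib.resources.files("scalemap.datasets").joinpath(
        "instruments.csv"
    ).open() as fh:
        return pd.read_csv(fh)


def load_instruments(source: str | Path | None = None) -> tuple[Instrument, ...]:
    """Read instrument metadata (name, theoretical range, direction).

    With no argument, returns the nine packaged social-anxiety scales.
    """
    df = pd.read_csv(source) if source is not None else _instrument_table()
    return tuple(
        Instrument(
            name=str(r["name"]),
            scale_range=float(r["scale_range"]),
            lower_is_better=bool(r["lower_is_better"]),
        )
        for _, r in df.iterrows()
    )


def load_trials(
    source: str | Path | pd.DataFrame | Iterable[dict],
    instruments: Sequence[Instrument] | None = None,
    standardised: bool = False,
) -> TrialDataset:
    """Build a validated :class:`TrialDataset` from the canonical table.

    ``source`` is a CSV path, a DataFrame, or an iterable of row dicts with
    columns ``trial_id, arm_index, n_control, n_arm, instrument, mean_diff,
    se, pooled_sd, basis``.  Rows belonging to the same trial must agree on
    ``n_control``; rows of the same arm must agree on ``n_arm``.
    """
    if isinstance(source, pd.DataFrame):
        df = source.copy()
    elif isinstance(source, (str, Path)):
        df = pd.read_csv(source)
    else:
        df = pd.DataFrame(list(source))

    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns: {missing}")
    for col in ("mean_diff", "se", "pooled_sd"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    for col in ("arm_index", "n_control", "n_arm"):
        df[col] = pd.to_numeric(df[col], downcast=None, errors="raise").astype(int)

    dup = df.duplicated(subset=["trial_id", "arm_index", "instrument"])
    if dup.any():
        bad = df.loc[dup, ["trial_id", "arm_index", "instrument"]].iloc[0]
        raise ValidationError(
            f"duplicate row for trial {bad.trial_id!r} arm {bad.arm_index} "
            f"instrument {bad.instrument!r}"
        )

    trials: list[TrialRecord] = []
    for tid, sub in df.groupby("trial_id", sort=False):
        if sub["n_control"].nunique() != 1:
            raise ValidationError(f"trial {tid!r}: inconsistent n_control")
        arm_groups = []
        n_active = []
        for arm, arm_sub in sub.groupby("arm_index", sort=True):
            if arm_sub["n_arm"].nunique() != 1:
                raise ValidationError(f"trial {tid!r} arm {arm}: inconsistent n_arm")
            n_active.append(int(arm_sub["n_arm"].iloc[0]))
            obs = tuple(
                ObservedDifference(
                    instrument=str(r["instrument"]),
                    mean_diff=float(r["mean_diff"]),
                    se=float(r["se"]),
                    pooled_sd=None if pd.isna(r["pooled_sd"]) else float(r["pooled_sd"]),
                    basis=str(r["basis"]),
                )
                for _, r in arm_sub.iterrows()
            )
            arm_groups.append(obs)
        trials.append(
            TrialRecord(
                trial_id=str(tid),
                n_control=int(sub["n_control"].iloc[0]),
                n_active=tuple(n_active),
                observations=tuple(arm_groups),
            )
        )

    if instruments is None:
        seen: dict[str, None] = {}
        for t in trials:
            for name in t.instruments:
                seen.setdefault(name, None)
        instruments = tuple(Instrument(name=n) for n in seen)

    # canonical within-arm observation order (dataset instrument order), so
    # that downstream layouts do not depend on input row order
    rank = {ins.name: j for j, ins in enumerate(instruments)}
    trials = [
        replace(
            t,
            observations=tuple(
                tuple(sorted(obs, key=lambda o: rank.get(o.instrument, len(rank))))
                for obs in t.observations
            ),
        )
        for t in trials
    ]

    return TrialDataset(
        instruments=tuple(instruments), trials=tuple(trials), standardised=standardised
    )


def social_anxiety_dataset() -> TrialDataset:
    """The packaged worked example: 22 SSRI/SNRI-vs-placebo social-anxiety
    trials reporting 88 mean differences on nine rating scales."""
    with importlib.resources.files("scalemap.datasets").joinpath(
        "social_anxiety.csv"
    ).open() as fh:
        df = pd.read_csv(fh)
    return load_trials(df, instruments=load_instruments())


def count_observations(ds: TrialDataset) -> int:
    """Total number of observed mean differences across trials, arms, scales."""
    return sum(t.n_observations() for t in ds.trials)


def standardise_dataset(ds: TrialDataset, allow_restandardise: bool = False) -> TrialDataset:
    """Divide each observation's mean difference and SE by its pooled SD.

    Produces the standardised-mean-difference (Cohen's d style) version of the
    dataset: pooled SDs become 1 and the ``standardised`` flag is set.  By
    default a second standardisation is an error.
    """
    if ds.standardised and not allow_restandardise:
        raise ValidationError("dataset is already standardised")
    new_trials = []
    for t in ds.trials:
        new_arms = []
        for arm, obs in enumerate(t.observations, start=1):
            new_obs = []
            for o in obs:
                if o.pooled_sd is None:
                    raise ValidationError(
                        f"trial {t.trial_id!r} arm {arm} instrument "
                        f"{o.instrument!r}: pooled_sd required for standardisation"
                    )
                new_obs.append(
                    replace(
                        o,
                        mean_diff=o.mean_diff / o.pooled_sd,
                        se=o.se / o.pooled_sd,
                        pooled_sd=1.0,
                    )
                )
            new_arms.append(tuple(new_obs))
        new_trials.append(replace(t, observations=tuple(new_arms)))
    return replace(ds, trials=tuple(new_trials), standardised=True)


def instrument_network(ds: TrialDataset) -> InstrumentNetwork:
    """Build the instrument co-reporting graph.

    Edge (h, k) carries the number of trials whose reported instrument set
    contains both h and k; components come from ordinary graph traversal.
    Instruments never reported appear as isolated nodes.
    """
    g = nx.Graph()
    g.add_nodes_from(ds.instrument_names)
    for t in ds.trials:
        names = t.instruments
        for i, h in enumerate(names):
            for k in names[i + 1 :]:
                if g.has_edge(h, k):
                    g[h][k]["n_trials"] += 1
                else:
                    g.add_edge(h, k, n_trials=1)
    order = {n: i for i, n in enumerate(ds.instrument_names)}
    edges = {
        tuple(sorted((h, k), key=order.get)): d["n_trials"]
        for h, k, d in g.edges(data=True)
    }
    components = tuple(
        frozenset(c)
        for c in sorted(nx.connected_components(g), key=lambda c: -len(c))
    )
    return InstrumentNetwork(
        nodes=ds.instrument_names, edges=edges, components=components
    )
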