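"""Data model and preprocessing for trial-structured population recordings.

Trial-level firing rates for serially recorded units are turned into the
normalized tensors that all downstream analyses consume: a z-scored,
optionally common-condition-subtracted trial-average tensor (units x
conditions x time), the matrix of trials per (unit, condition), and a
condition-by-variable predictor design scaled to [0, 1].
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "Condition",
    "TrialTable",
    "PopulationResponse",
    "TrialCounts",
    "ConditionDesign",
    "FilterReport",
    "NoUnitsSurviveError",
    "filter_units",
    "build_population_response",
    "build_design",
    "OFFER_DOMAIN",
]

OFFER_DOMAIN = (0, 1, 2, 4, 8)

#: Trial-level columns required in a long-format table.
LONG_COLUMNS = [
    "unit_id", "trial_id", "session_id", "offer", "choice", "singleton",
    "prev_offer", "prev_choice", "alignment", "bin_index", "rate",
]


@dataclass(frozen=True, order=True)
class Condition:
    """A behavioral condition: unique (offer, choice, singleton) combination."""

    offer: int
    choice: int
    singleton: bool = False

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        tag = "singleton " if self.singleton else ""
        return f"{tag}{self.offer}-reward {'accept' if self.choice else 'reject'}"


@dataclass
class TrialTable:
    """Aligned per-trial firing rates for a population of serially recorded units.

    Parameters
    ----------
    rates
        Array (n_units, n_trials, n_bins) of firing rates in spikes/s per
        100 ms bin.  NaN marks (unit, trial) pairs where the unit was not
        recorded (serial recordings) or was excluded.
    trials
        Trial-level labels, one row per trial: columns ``trial_id``,
        ``session_id``, ``offer``, ``choice``, ``singleton`` and optionally
        ``prev_offer``, ``prev_choice`` (NaN on a session's first trial) and
        ``reject_time`` (seconds; NaN for accepts).
    unit_ids
        Identifiers, one per row of ``rates``.
    bin_starts
        Left edge of each time bin in seconds relative to the alignment event.
        Bins are left-closed/right-open, ``bin_width`` wide, with bin edges on
        multiples of the bin width so that a boundary falls at t = 0.
    """

    rates: np.ndarray
    trials: pd.DataFrame
    unit_ids: list
    bin_starts: np.ndarray
    bin_width: float = 0.1
    alignment: str = "offer"
    excluded_conditions: list = field(default_factory=list)

    def __post_init__(self) -> None:
        self.rates = np.asarray(self.rates, dtype=float)
        self.bin_starts = np.asarray(self.bin_starts, dtype=float)
        if self.rates.ndim != 3:
            raise ValueError("rates must be (n_units, n_trials, n_bins)")
        n_units, n_trials, n_bins = self.rates.shape
        if len(self.unit_ids) != n_units:
            raise ValueError("unit_ids length mismatch")
        if len(self.trials) != n_trials:
            raise ValueError("trials length mismatch")
        if len(self.bin_starts) != n_bins:
            raise ValueError("bin_starts length mismatch")
        for col in ("offer", "choice", "singleton"):
            if col not in self.trials.columns:
                raise ValueError(f"missing condition label column {col!r}")
        bad = set(self.trials["offer"].unique()) - set(OFFER_DOMAIN)
        if bad:
            raise ValueError(f"offers outside domain {OFFER_DOMAIN}: {sorted(bad)}")
        if not self.trials["choice"].isin([0, 1]).all():
            raise ValueError("choice labels must be binary 0/1")
        with np.errstate(invalid="ignore"):
            if np.nanmin(self.rates) < 0:
                raise ValueError("rates must be non-negative")
        self.trials = self.trials.reset_index(drop=True)

    # -- shape helpers -------------------------------------------------
    @property
    def n_units(self) -> int:
        return self.rates.shape[0]

    @property
    def n_trials(self) -> int:
        return self.rates.shape[1]

    @property
    def n_bins(self) -> int:
        return self.rates.shape[2]

    def condition_of_trials(self, sort_by: str = "present") -> pd.Series:
        """Condition label per trial (NaN-labelled trials map to None)."""
        if sort_by == "present":
            off, cho = self.trials["offer"], self.trials["choice"]
            sing = self.trials["singleton"].astype(bool)
        elif sort_by == "previous":
            off, cho = self.trials["prev_offer"], self.trials["prev_choice"]
            sing = pd.Series(False, index=self.trials.index)
        else:
            raise ValueError("sort_by must be 'present' or 'previous'")
        out = []
        for o, c, s in zip(off, cho, sing):
            if pd.isna(o) or pd.isna(c):
                out.append(None)
            else:
                out.append(Condition(int(o), int(c), bool(s)))
        return pd.Series(out, index=self.trials.index)

    def conditions(self, sort_by: str = "present") -> list:
        """Sorted list of conditions present (excluding globally dropped ones)."""
        labels = self.condition_of_trials(sort_by)
        present = {c for c in labels if c is not None}
        present -= set(self.excluded_conditions)
        return sorted(present)

    def trial_counts(self, conditions: list, sort_by: str = "present") -> np.ndarray:
        """(n_units, len(conditions)) matrix of recorded-trial counts."""
        labels = self.condition_of_trials(sort_by)
        observed = ~np.isnan(self.rates).all(axis=2)  # unit x trial
        M = np.zeros((self.n_units, len(conditions)), dtype=int)
        for j, cond in enumerate(conditions):
            mask = np.asarray(labels.apply(lambda c: c == cond))
            M[:, j] = observed[:, mask].sum(axis=1)
        return M

    # -- long-format conversion ---------------------------------------
    @classmethod
    def from_long(cls, df: pd.DataFrame, bin_width: float = 0.1,
                  bin0_start: float | None = None) -> "TrialTable":
        """Build from a long-format table (one row per unit/trial/bin)."""
        missing = [c for c in LONG_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"long table missing columns: {missing}")
        unit_ids = sorted(df["unit_id"].unique())
        trial_ids = sorted(df["trial_id"].unique())
        bins = np.array(sorted(df["bin_index"].unique()))
        uidx = {u: i for i, u in enumerate(unit_ids)}
        tidx = {t: i for i, t in enumerate(trial_ids)}
        bidx = {b: i for i, b in enumerate(bins)}
        rates = np.full((len(unit_ids), len(trial_ids), len(bins)), np.nan)
        rates[df["unit_id"].map(uidx), df["trial_id"].map(tidx),
              df["bin_index"].map(bidx)] = df["rate"].to_numpy()
        label_cols = ["trial_id", "session_id", "offer", "choice", "singleton",
                      "prev_offer", "prev_choice"]
        if "reject_time" in df.columns:
            label_cols.append("reject_time")
        trials = (df[label_cols].drop_duplicates("trial_id")
                  .set_index("trial_id").loc[trial_ids].reset_index())
        alignment = str(df["alignment"].iloc[0])
        start = bins[0] * bin_width if bin0_start is None else bin0_start
        bin_starts = start + (bins - bins[0]) * bin_width
        return cls(rates, trials, unit_ids, bin_starts, bin_width, alignment)

    def to_long(self) -> pd.DataFrame:
        u, t, b = np.nonzero(~np.isnan(self.rates))
        df = pd.DataFrame({
            "unit_id": np.asarray(self.unit_ids)[u],
            "trial_id": self.trials["trial_id"].to_numpy()[t],
            "session_id": self.trials["session_id"].to_numpy()[t],
            "offer": self.trials["offer"].to_numpy()[t],
            "choice": self.trials["choice"].to_numpy()[t],
            "singleton": self.trials["singleton"].to_numpy()[t],
            "prev_offer": self.trials["prev_offer"].to_numpy()[t]
            if "prev_offer" in self.trials else np.nan,
            "prev_choice": self.trials["prev_choice"].to_numpy()[t]
            if "prev_choice" in self.trials else np.nan,
            "alignment": self.alignment,
            "bin_index": np.round(self.bin_starts[b] / self.bin_width).astype(int),
            "rate": self.rates[u, t, b],
        })
        return df


@dataclass
class TrialCounts:
    """Trials observed per unit and condition (the weighting matrix M)."""

    M: np.ndarray
    conditions: list

    def __post_init__(self) -> None:
        self.M = np.asarray(self.M)
        if (self.M < 0).any():
            raise ValueError("trial counts must be non-negative")


@dataclass
class PopulationResponse:
    """Trial-average, z-scored population response tensor.

    ``tensor`` is (N, C, T).  When ``mean_subtracted`` the per-time
    across-condition mean (the common-condition response ``cc``) has been
    removed.  ``zmean``/``zstd`` record the per-unit statistics used for
    z-scoring so bootstrap resamples can reuse them.
    """

    tensor: np.ndarray
    cc: np.ndarray
    mean_subtracted: bool
    bin_starts: np.ndarray
    bin_width: float
    alignment: str
    condition_index: list
    zmean: np.ndarray | None = None
    zstd: np.ndarray | None = None

    @property
    def n_units(self) -> int:
        return self.tensor.shape[0]

    @property
    def n_conditions(self) -> int:
        return self.tensor.shape[1]

    @property
    def n_bins(self) -> int:
        return self.tensor.shape[2]

    def unfold(self, exclude_singleton: bool = False) -> np.ndarray:
        """Reshape to the N x (T*C) matrix used for PCA and covariance."""
        tensor = self.tensor
        if exclude_singleton:
            keep = [j for j, c in enumerate(self.condition_index) if not c.singleton]
            tensor = tensor[:, keep, :]
        return tensor.reshape(self.n_units, -1)

    def condition_subset(self, conditions: list) -> np.ndarray:
        idx = [self.condition_index.index(c) for c in conditions]
        return self.tensor[:, idx, :]


@dataclass
class ConditionDesign:
    """Condition-by-variable predictor matrix, each column scaled to [0, 1]."""

    P: np.ndarray
    variables: list
    conditions: list
    scaling: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.P = np.asarray(self.P, dtype=float)
        if self.P.shape != (len(self.conditions), len(self.variables)):
            raise ValueError("design shape mismatch")
        if self.P.min() < -1e-12 or self.P.max() > 1 + 1e-12:
            raise ValueError("design columns must lie in [0, 1]")

    def column(self, variable: str) -> np.ndarray:
        return self.P[:, self.variables.index(variable)]


@dataclass
class FilterReport:
    """Record of exclusions applied by :func:`filter_units`."""

    low_trial_units: list = field(default_factory=list)
    low_variability_units: list = field(default_factory=list)
    low_condition_units: list = field(default_factory=list)
    dropped_conditions: list = field(default_factory=list)
    absent_run_trials: dict = field(default_factory=dict)


class NoUnitsSurviveError(RuntimeError):
    """Raised when filtering removes every unit."""


# ---------------------------------------------------------------------------
# filtering
# ---------------------------------------------------------------------------

def _strike_absent_runs(rates: np.ndarray, absent_rate: float, run_length: int,
                        report: FilterReport, unit_ids: list) -> np.ndarray:
    """NaN-out runs of >= run_length consecutive trials where a unit is absent."""
    rates = rates.copy()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean_rate = np.nanmean(rates, axis=2)  # unit x trial (NaN if unrecorded)
    for i in range(rates.shape[0]):
        with np.errstate(invalid="ignore"):
            absent = mean_rate[i] < absent_rate
        absent &= ~np.isnan(mean_rate[i])
        struck = []
        j = 0
        n = len(absent)
        while j < n:
            if absent[j]:
                k = j
                while k < n and absent[k]:
                    k += 1
                if k - j >= run_length:
                    rates[i, j:k, :] = np.nan
                    struck.extend(range(j, k))
                j = k
            else:
                j += 1
        if struck:
            report.absent_run_trials[unit_ids[i]] = struck
    return rates


def filter_units(
    table: TrialTable,
    min_total_trials: int = 60,
    min_trials_per_condition: int = 5,
    min_rate_sd: float = 0.5,
    absent_rate: float = 0.1,
    absent_run_length: int = 5,
    condition_coverage: float = 0.4,
) -> tuple[TrialTable, FilterReport]:
    """Apply the unit- and condition-inclusion rules.

    In order: (1) strike runs of >= 5 consecutive trials where a unit is
    absent (mean rate < 0.1 spikes/s); (2) drop units recorded on fewer than
    60 trials total; (3) drop units whose trial-average rate has s.d. < 0.5
    spikes/s across conditions and time bins; (4) drop, globally, conditions
    in which fewer than 40% of surviving units reach 5 trials; (5) drop units
    with fewer than 5 trials in any remaining included condition.  Applying
    the filter to its own output is a no-op.
    """
    report = FilterReport()
    rates = _strike_absent_runs(table.rates, absent_rate, absent_run_length,
                                report, table.unit_ids)

    observed = ~np.isnan(rates).all(axis=2)
    total = observed.sum(axis=1)
    keep = total >= min_total_trials
    report.low_trial_units = [u for u, k in zip(table.unit_ids, keep) if not k]

    # trial-average rate per (unit, condition, bin) for the variability rule
    labels = table.condition_of_trials("present")
    conds = sorted({c for c in labels if c is not None})
    sd = np.zeros(table.n_units)
    for i in range(table.n_units):
        means = []
        for cond in conds:
            mask = np.asarray(labels.apply(lambda c: c == cond)) & observed[i]
            if mask.any():
                means.append(np.nanmean(rates[i, mask, :], axis=0))
        sd[i] = np.std(np.concatenate(means)) if means else 0.0
    low_var = sd < min_rate_sd
    report.low_variability_units = [
        u for u, k, lv in zip(table.unit_ids, keep, low_var) if k and lv]
    keep &= ~low_var

    if not keep.any():
        raise NoUnitsSurviveError("no units survive filtering")

    kept_idx = np.nonzero(keep)[0]
    sub = TrialTable(rates[kept_idx], table.trials.copy(),
                     [table.unit_ids[i] for i in kept_idx],
                     table.bin_starts, table.bin_width, table.alignment,
                     list(table.excluded_conditions))

    # condition-coverage rule, on surviving units
    conds = sub.conditions("present")
    M = sub.trial_counts(conds, "present")
    frac = (M >= min_trials_per_condition).mean(axis=0)
    dropped = [c for c, f in zip(conds, frac) if f < condition_coverage]
    report.dropped_conditions = dropped
    sub.excluded_conditions = sorted(set(sub.excluded_conditions) | set(dropped))

    # re-check the per-condition trial floor on included conditions only
    included = [c for c in conds if c not in sub.excluded_conditions]
    M_inc = sub.trial_counts(included, "present")
    ok = (M_inc >= min_trials_per_condition).all(axis=1)
    report.low_condition_units = [u for u, k in zip(sub.unit_ids, ok) if not k]
    if not ok.any():
        raise NoUnitsSurviveError("no units survive the per-condition trial floor")
    if not ok.all():
        idx = np.nonzero(ok)[0]
        sub = TrialTable(sub.rates[idx], sub.trials.copy(),
                         [sub.unit_ids[i] for i in idx],
                         sub.bin_starts, sub.bin_width, sub.alignment,
                         list(sub.excluded_conditions))
    return sub, report


# ---------------------------------------------------------------------------
# trial averaging / normalization
# ---------------------------------------------------------------------------

def build_population_response(
    table: TrialTable,
    sort_by: str = "present",
    subtract_cc: bool = True,
    zmean: np.ndarray | None = None,
    zstd: np.ndarray | None = None,
) -> tuple[PopulationResponse, TrialCounts]:
    """Trial-average per condition, z-score per unit, optionally remove the
    common-condition response.

    ``zmean``/``zstd`` override the z-scoring statistics (used when
    re-normalizing bootstrap resamples with the full-data statistics).
    Previous-trial sorting groups trials by the labels of trial r-1; trials
    without previous-trial labels are ignored.
    """
    conds = table.conditions(sort_by)
    if not conds:
        raise ValueError("no conditions available under this sorting")
    labels = table.condition_of_trials(sort_by)
    observed = ~np.isnan(table.rates).all(axis=2)
    N, T = table.n_units, table.n_bins
    C = len(conds)
    tensor = np.empty((N, C, T))
    M = np.zeros((N, C), dtype=int)
    for j, cond in enumerate(conds):
        mask = np.asarray(labels.apply(lambda c: c == cond))
        M[:, j] = observed[:, mask].sum(axis=1)
        if (M[:, j] == 0).any():
            bad = [table.unit_ids[i] for i in np.nonzero(M[:, j] == 0)[0]]
            raise ValueError(
                f"condition {cond} has zero trials for units {bad}; "
                "it should have been dropped upstream")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            tensor[:, j, :] = np.nanmean(table.rates[:, mask, :], axis=1)
    if np.isnan(tensor).any():
        raise ValueError("missing bins in the trial-average tensor; drop "
                         "affected trials at the TrialTable stage")

    if zmean is None:
        zmean = tensor.reshape(N, -1).mean(axis=1)
    if zstd is None:
        zstd = tensor.reshape(N, -1).std(axis=1)
    if (np.asarray(zstd) == 0).any():
        raise ValueError("zero-variance unit cannot be z-scored; filter first")
    z = (tensor - np.asarray(zmean)[:, None, None]) / np.asarray(zstd)[:, None, None]
    cc = z.mean(axis=1)  # N x T common-condition response
    if subtract_cc:
        z = z - cc[:, None, :]
    pop = PopulationResponse(z, cc, subtract_cc, table.bin_starts,
                             table.bin_width, table.alignment, conds,
                             zmean=np.asarray(zmean), zstd=np.asarray(zstd))
    return pop, TrialCounts(M, conds)


# ---------------------------------------------------------------------------
# design matrix
# ---------------------------------------------------------------------------

_PRESENT_VARIABLES = ("benefit", "choice", "expected_reward")
_PREVIOUS_VARIABLES = ("prev_benefit", "prev_choice", "experienced_reward")


def build_design(conditions: list,
                 variables: tuple = _PRESENT_VARIABLES) -> ConditionDesign:
    """Predictor matrix over conditions, each column scaled to [0, 1].

    Benefit is the offer size {0,1,2,4,8} scaled by 1/8; choice is 0 (reject)
    or 1 (accept); expected reward is the unscaled benefit x choice product,
    rescaled by 1/8.  Previous-trial analogues use the same encodings applied
    to previous-trial labels (condition labels under previous sorting).
    Singleton conditions are not part of a design and must be excluded first.
    """
    if any(c.singleton for c in conditions):
        raise ValueError("singleton conditions are excluded from regression designs")
    offers = np.array([c.offer for c in conditions], dtype=float)
    choices = np.array([c.choice for c in conditions], dtype=float)
    max_offer = float(max(OFFER_DOMAIN))
    cols, scaling = [], {}
    for name in variables:
        base = name.removeprefix("prev_")
        if base == "benefit":
            cols.append(offers / max_offer)
            scaling[name] = {"raw_domain": list(OFFER_DOMAIN), "scale": 1 / max_offer}
        elif base == "choice":
            cols.append(choices)
            scaling[name] = {"raw_domain": [0, 1], "scale": 1.0}
        elif base in ("expected_reward", "experienced_reward"):
            cols.append(offers * choices / max_offer)
            scaling[name] = {"raw_domain": [0, max_offer], "scale": 1 / max_offer}
        else:
            raise ValueError(f"unknown variable {name!r}")
    return ConditionDesign(np.column_stack(cols), list(variables),
                           list(conditions), scaling)
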