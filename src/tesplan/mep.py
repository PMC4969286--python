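"""Motor-evoked-potential (MEP) after-effect statistics and a synthetic cohort.

Analysis chain
--------------
Each measurement block is a list of peak-to-peak MEP amplitudes (mV).
Post-stimulation blocks of 12 trials are summarized by a trimmed mean —
exactly one minimum and one maximum trial removed — while 10-trial
baseline blocks are averaged untrimmed.  Per-interval means are divided by
the session baseline mean to give after-effect ratios; the overall session
ratio is the mean over the nine post-stimulation intervals (0–30 min in
5-min steps, then 60 and 90 min).  Condition contrasts use one-tailed
paired t-tests (alternative: condition < placebo), and response-proportion
comparisons against published cohorts use exact binomial tail sums.

Synthetic cohort
----------------
``simulate_cohort`` emulates the statistical structure of a three-session
crossover (anodal / cathodal / placebo, within participant): a truncated
normal baseline amplitude, a participant-level true after-effect ratio per
condition, and multiplicative lognormal trial noise (MEP amplitudes are
positive and right-skewed).  It is a statistical stand-in — no TMS physics,
recruitment curves, or serial correlation between trials.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "POST_INTERVALS_MIN",
    "MEPBlock",
    "ParticipantSession",
    "CohortSpec",
    "TTestResult",
    "trimmed_mep_mean",
    "normalize_to_baseline",
    "paired_one_tailed_t",
    "exact_binomial_tail",
    "simulate_cohort",
    "analyze_session",
    "analyze_cohort",
]

#: Post-stimulation measurement intervals (minutes after current offset).
POST_INTERVALS_MIN = (0, 5, 10, 15, 20, 25, 30, 60, 90)
CONDITIONS = ("anodal", "cathodal", "placebo")


@dataclass
class MEPBlock:
    """One measurement block: amplitudes (mV) and a timestamp label.

    ``label`` is ``"baseline"`` or the minutes-post-stimulation value.
    Post blocks carry 12 trials, baseline blocks 10.
    """

    amplitudes_mv: np.ndarray
    label: str | int

    def __post_init__(self) -> None:
        self.amplitudes_mv = np.asarray(self.amplitudes_mv, dtype=float)
        if np.any(self.amplitudes_mv < 0):
            raise ValueError("MEP amplitudes must be non-negative")

    def summary_mv(self) -> float:
        if self.label == "baseline":
            return float(self.amplitudes_mv.mean())
        return trimmed_mep_mean(self.amplitudes_mv)


def trimmed_mep_mean(amplitudes_mv: np.ndarray) -> float:
    """Mean after removing exactly one smallest and one largest trial.

    On ties the first occurrence of the extreme value is the one removed
    (the result is the same for any choice).  Requires at least 3 trials.
    """
    a = np.asarray(amplitudes_mv, dtype=float)
    if a.size < 3:
        raise ValueError("trimmed mean needs at least 3 trials")
    keep = np.ones(a.size, dtype=bool)
    keep[int(np.argmin(a))] = False
    # first occurrence of the max among still-kept trials
    masked = np.where(keep, a, -np.inf)
    keep[int(np.argmax(masked))] = False
    return float(a[keep].mean())


@dataclass
class ParticipantSession:
    """One participant x condition session, summarized."""

    participant: int
    condition: str
    baseline_mean_mv: float
    interval_means_mv: dict[int, float]
    ratios: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.baseline_mean_mv <= 0:
            raise ValueError("baseline mean must be positive")
        if not self.ratios:
            self.ratios = {
                t: m / self.baseline_mean_mv for t, m in self.interval_means_mv.items()
            }

    @property
    def overall_ratio(self) -> float:
        return float(np.mean([self.ratios[t] for t in POST_INTERVALS_MIN]))

    def grouped_ratio(self, group: str) -> float:
        """Mean ratio over an interval grouping: "0-30" or "60-90" minutes."""
        if group == "0-30":
            keys = [t for t in POST_INTERVALS_MIN if t <= 30]
        elif group == "60-90":
            keys = [60, 90]
        else:
            raise ValueError("group must be '0-30' or '60-90'")
        return float(np.mean([self.ratios[t] for t in keys]))


def normalize_to_baseline(
    baseline_mean_mv: float, interval_means_mv: dict[int, float]
) -> dict[int, float]:
    """Per-interval MEP ratios relative to the session baseline mean."""
    if baseline_mean_mv <= 0:
        raise ValueError("baseline mean must be positive")
    return {t: m / baseline_mean_mv for t, m in interval_means_mv.items()}


@dataclass(frozen=True)
class TTestResult:
    t: float
    df: int
    p: float
    degenerate: bool = False


def paired_one_tailed_t(
    condition_ratios: np.ndarray, placebo_ratios: np.ndarray
) -> TTestResult:
    """Classical paired t-test, one-tailed for condition < placebo.

    Zero-variance differences are flagged degenerate with p forced to 0 or
    1 by the sign of the (constant) difference, 0.5 when identically zero.
    """
    x = np.asarray(condition_ratios, dtype=float)
    y = np.asarray(placebo_ratios, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 2:
        raise ValueError("need equal-length paired vectors with n >= 2")
    d = x - y
    n = d.size
    sd = d.std(ddof=1)
    if sd == 0.0:
        mean = d.mean()
        p = 0.5 if mean == 0 else (0.0 if mean < 0 else 1.0)
        t = 0.0 if mean == 0 else np.sign(mean) * np.inf
        return TTestResult(t=float(t), df=n - 1, p=p, degenerate=True)
    t = d.mean() / (sd / np.sqrt(n))
    p = float(stats.t.cdf(t, df=n - 1))
    return TTestResult(t=float(t), df=n - 1, p=p)


def exact_binomial_tail(k: int, n: int, p0: float, tail: str = "upper") -> float:
    """Exact binomial goodness-of-fit tail: P(X >= k) (or <= k) under Binomial(n, p0).

    Computed by direct summation of binomial point masses.
    """
    if not 0 <= k <= n:
        raise ValueError("k must be between 0 and n")
    if not 0 < p0 < 1:
        raise ValueError("p0 must be strictly between 0 and 1")
    if tail == "upper":
        ks = range(k, n + 1)
    elif tail == "lower":
        ks = range(0, k + 1)
    else:
        raise ValueError("tail must be 'upper' or 'lower'")
    return float(sum(comb(n, i) * p0**i * (1 - p0) ** (n - i) for i in ks))


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of the synthetic crossover cohort.

    Condition means and SDs are participant-level after-effect ratios;
    ``baseline_mean_mv``/``baseline_sd_mv`` describe the TMS baseline
    amplitude distribution (truncated above ``baseline_floor_mv``).
    ``trial_noise_sigma`` is the SD of the lognormal trial noise on the log
    scale (mean-one noise); 0.15 gives ~15% trial-to-trial variability, a
    modest but realistic spread that keeps the trimmed mean essentially
    unbiased.
    """

    n_participants: int = 12
    ratio_means: dict[str, float] = field(
        default_factory=lambda: {"cathodal": 0.79, "anodal": 0.93, "placebo": 1.10}
    )
    ratio_sds: dict[str, float] = field(
        default_factory=lambda: {"cathodal": 0.21, "anodal": 0.08, "placebo": 0.36}
    )
    baseline_mean_mv: float = 0.97
    baseline_sd_mv: float = 0.35
    baseline_floor_mv: float = 0.1
    trial_noise_sigma: float = 0.15
    n_baseline_trials: int = 10
    n_post_trials: int = 12
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2:
            raise ValueError("need at least 2 participants")
        for c in CONDITIONS:
            if self.ratio_sds[c] <= 0:
                raise ValueError("ratio SDs must be positive")
        if self.baseline_sd_mv <= 0 or self.trial_noise_sigma <= 0:
            raise ValueError("spread parameters must be positive")


def _truncated_normal(rng, mean, sd, floor, size):
    out = np.empty(size)
    todo = np.arange(size)
    while todo.size:
        draw = rng.normal(mean, sd, size=todo.size)
        ok = draw > floor
        out[todo[ok]] = draw[ok]
        todo = todo[~ok]
    return out


def _noise(rng, sigma, size):
    # lognormal with unit mean: exp(N(-sigma^2/2, sigma))
    return rng.lognormal(mean=-0.5 * sigma**2, sigma=sigma, size=size)


def simulate_cohort(spec: CohortSpec = CohortSpec()) -> pd.DataFrame:
    """Trial-level synthetic cohort as a tidy DataFrame.

    Columns: participant, condition, interval ("baseline" or minutes), trial,
    amplitude_mv.  Deterministic for a fixed ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    rows: list[tuple] = []
    n = spec.n_participants
    baselines = _truncated_normal(
        rng, spec.baseline_mean_mv, spec.baseline_sd_mv, spec.baseline_floor_mv, n
    )
    for p in range(n):
        for cond in CONDITIONS:
            true_ratio = max(
                0.05, rng.normal(spec.ratio_means[cond], spec.ratio_sds[cond])
            )
            base_amps = baselines[p] * _noise(rng, spec.trial_noise_sigma, spec.n_baseline_trials)
            for trial, amp in enumerate(base_amps):
                rows.append((p, cond, "baseline", trial, amp))
            for t in POST_INTERVALS_MIN:
                amps = (
                    baselines[p]
                    * true_ratio
                    * _noise(rng, spec.trial_noise_sigma, spec.n_post_trials)
                )
                for trial, amp in enumerate(amps):
                    rows.append((p, cond, str(t), trial, amp))
    return pd.DataFrame(
        rows, columns=["participant", "condition", "interval", "trial", "amplitude_mv"]
    )


def analyze_session(trials: pd.DataFrame) -> ParticipantSession:
    """Summarize one participant x condition trial table into a session."""
    participants = trials["participant"].unique()
    conditions = trials["condition"].unique()
    if len(participants) != 1 or len(conditions) != 1:
        raise ValueError("analyze_session expects a single participant and condition")
    base = trials.loc[trials["interval"] == "baseline", "amplitude_mv"].to_numpy()
    if base.size == 0:
        raise ValueError("session has no baseline block")
    interval_means = {}
    for t in POST_INTERVALS_MIN:
        block = trials.loc[trials["interval"] == str(t), "amplitude_mv"].to_numpy()
        if block.size == 0:
            raise ValueError(f"session is missing the {t}-minute block")
        interval_means[t] = trimmed_mep_mean(block)
    return ParticipantSession(
        participant=int(participants[0]),
        condition=str(conditions[0]),
        baseline_mean_mv=float(base.mean()),
        interval_means_mv=interval_means,
    )


def analyze_cohort(
    trials: pd.DataFrame,
    exclude_participants: tuple[int, ...] = (),
    group: str | None = None,
) -> pd.DataFrame:
    """Per-participant overall (or grouped) after-effect ratios, wide by condition.

    ``exclude_participants`` drops listed participants (e.g. sensitivity
    re-analyses); ``group`` restricts the ratio to the "0-30" or "60-90"
    minute interval grouping.
    """
    out: dict[int, dict[str, float]] = {}
    for (p, cond), tab in trials.groupby(["participant", "condition"], sort=True):
        if p in exclude_participants:
            continue
        s = analyze_session(tab)
        out.setdefault(int(p), {})[str(cond)] = (
            s.overall_ratio if group is None else s.grouped_ratio(group)
        )
    df = pd.DataFrame.from_dict(out, orient="index").sort_index()
    df.index.name = "participant"
    return df


def cohort_tests(ratios: pd.DataFrame) -> dict[str, TTestResult]:
    """One-tailed paired contrasts of each active condition against placebo."""
    return {
        cond: paired_one_tailed_t(ratios[cond].to_numpy(), ratios["placebo"].to_numpy())
        for cond in ("anodal", "cathodal")
        if cond in ratios
    }
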