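"""Post-hoc run summaries, treatment contrasts and trajectory figures.

A run is condensed into a handful of descriptive statistics: time-weighted
mean and final stock, time-weighted mean and dispersion of group effort,
total group harvest, least-squares linear trends of stock and effort, and a
count of recovery episodes (intervals of rising stock after a drawdown of
at least 10% from the running peak — the "short pause then recovery"
signature of continuous-time harvesting groups). Treatment arms are
compared by arm means and their differences; an optional seeded label
permutation supplies a p-value when asked for, since descriptive contrasts
are the default.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass
from typing import Sequence

import numpy as np

from .events import Trajectory

__all__ = [
    "RunSummary",
    "TreatmentContrast",
    "summarize",
    "compare_treatments",
    "count_recovery_episodes",
    "plot_trajectory",
]

#: Drawdown (fraction of the running peak) that must precede a rising
#: interval for it to count as a recovery episode.
DRAWDOWN_THRESHOLD = 0.10
#: Minimum total rise (fraction of the running peak) for an episode to count;
#: filters sample-to-sample noise.
MIN_RISE_FRACTION = 0.01


@dataclass(frozen=True)
class RunSummary:
    """Descriptive statistics of one simulated run."""

    mean_resource: float
    final_resource: float
    mean_group_effort: float
    effort_sd: float
    total_group_harvest: float
    recovery_episodes: int
    resource_trend: float
    effort_trend: float

    def as_dict(self) -> dict[str, float]:
        return asdict(self)


def _time_weighted_mean(t: np.ndarray, y: np.ndarray) -> float:
    if t.size == 1:
        return float(y[0])
    span = t[-1] - t[0]
    if span <= 0:
        return float(y[0])
    return float(np.trapezoid(y, t) / span)


def count_recovery_episodes(
    t: np.ndarray,
    R: np.ndarray,
    drawdown: float = DRAWDOWN_THRESHOLD,
    min_rise: float = MIN_RISE_FRACTION,
) -> int:
    """Count maximal rising intervals of the stock that start after the
    stock has fallen at least ``drawdown`` below its running peak.

    A rising run only counts when its total rise exceeds ``min_rise`` of the
    running peak at its start, so numerical ripple is ignored.
    """
    n = R.size
    if n < 3:
        return 0
    episodes = 0
    peak = R[0]
    i = 1
    while i < n:
        peak = max(peak, R[i - 1])
        if R[i - 1] <= (1.0 - drawdown) * peak and R[i] > R[i - 1]:
            start = i - 1
            while i < n and R[i] > R[i - 1]:
                i += 1
            if R[i - 1] - R[start] >= min_rise * peak:
                episodes += 1
        else:
            i += 1
    return episodes


def summarize(traj: Trajectory) -> RunSummary:
    """Condense a trajectory into the per-run summary statistics.

    Means are time-weighted over the (possibly irregular) sample grid; the
    effort dispersion is the population standard deviation of the sampled
    group effort; trends are least-squares slopes against time. A
    single-sample trajectory degenerates to sd 0 and zero trends.
    """
    t, R = traj.t, traj.R
    if t.size == 0:
        raise ValueError("empty trajectory")
    group_effort = traj.group_effort
    if t.size == 1:
        return RunSummary(
            mean_resource=float(R[0]),
            final_resource=float(R[0]),
            mean_group_effort=float(group_effort[0]),
            effort_sd=0.0,
            total_group_harvest=float(traj.group_cum_harvest[-1]),
            recovery_episodes=0,
            resource_trend=0.0,
            effort_trend=0.0,
        )
    return RunSummary(
        mean_resource=_time_weighted_mean(t, R),
        final_resource=float(R[-1]),
        mean_group_effort=_time_weighted_mean(t, group_effort),
        effort_sd=float(np.std(group_effort)),
        total_group_harvest=float(traj.group_cum_harvest[-1]),
        recovery_episodes=count_recovery_episodes(t, R),
        resource_trend=float(np.polyfit(t, R, 1)[0]),
        effort_trend=float(np.polyfit(t, group_effort, 1)[0]),
    )


_CONTRAST_STATS = ("mean_resource", "final_resource", "mean_group_effort", "effort_sd")


@dataclass(frozen=True)
class TreatmentContrast:
    """Arm-level means and their differences (arm A minus arm B)."""

    arm_a: dict[str, float]
    arm_b: dict[str, float]
    difference: dict[str, float]
    sign: dict[str, str]
    p_values: dict[str, float] | None = None


def _arm_means(summaries: Sequence[RunSummary]) -> dict[str, float]:
    return {
        stat: float(np.mean([getattr(s, stat) for s in summaries]))
        for stat in _CONTRAST_STATS
    }


def compare_treatments(
    arm_a: Sequence[RunSummary],
    arm_b: Sequence[RunSummary],
    *,
    n_permutations: int = 0,
    seed: int | None = 0,
) -> TreatmentContrast:
    """Contrast two treatment arms on the summary statistics.

    By default purely descriptive (means, differences, sign labels). With
    ``n_permutations > 0`` a two-sided label-permutation p-value is computed
    for each statistic's difference in means.
    """
    if not arm_a or not arm_b:
        raise ValueError("both arms need at least one run")
    means_a = _arm_means(arm_a)
    means_b = _arm_means(arm_b)
    diff = {k: means_a[k] - means_b[k] for k in _CONTRAST_STATS}
    sign = {k: ("A>B" if d > 0 else "A<B" if d < 0 else "A=B") for k, d in diff.items()}

    p_values = None
    if n_permutations > 0:
        rng = np.random.default_rng(seed)
        values = {
            stat: np.array(
                [getattr(s, stat) for s in arm_a] + [getattr(s, stat) for s in arm_b]
            )
            for stat in _CONTRAST_STATS
        }
        n_a = len(arm_a)
        n = n_a + len(arm_b)
        p_values = {}
        for stat, v in values.items():
            observed = abs(diff[stat])
            hits = 1  # the observed labelling counts as one permutation
            for _ in range(n_permutations):
                perm = rng.permutation(n)
                d = v[perm[:n_a]].mean() - v[perm[n_a:]].mean()
                if abs(d) >= observed - 1e-15:
                    hits += 1
            p_values[stat] = hits / (n_permutations + 1)
    return TreatmentContrast(
        arm_a=means_a, arm_b=means_b, difference=diff, sign=sign, p_values=p_values
    )


def plot_trajectory(traj: Trajectory, path: str, title: str | None = None) -> None:
    """Dual-axis time-series figure: stock (left) and group harvest rate
    (right), the client-graph layout where the two y-axes scale
    independently."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax1 = plt.subplots(figsize=(8, 4.5))
    ax1.plot(traj.t, traj.R, color="tab:orange", label="resource")
    ax1.set_xlabel("time (s)")
    ax1.set_ylabel("resource", color="tab:orange")
    ax1.tick_params(axis="y", labelcolor="tab:orange")
    ax2 = ax1.twinx()
    ax2.plot(traj.t, traj.group_harvest_rate, color="tab:blue", label="group harvest rate")
    ax2.set_ylabel("group harvest rate (1/s)", color="tab:blue")
    ax2.tick_params(axis="y", labelcolor="tab:blue")
    if title:
        ax1.set_title(title)
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)
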