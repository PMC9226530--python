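"""Per-step flexibility statistics, window SD pooling and one-way ANOVA.

Flexibility is quantified as the sample standard deviation (n-1 denominator)
of each helical parameter over the frames of a replica, per base-pair step.
SD values are pooled over the modified-site windows (one observation per
replica x window step) and substrate differences are tested by single-factor
fixed-effects ANOVA.  A static reference structure (e.g. nucleosomal DNA)
yields a spatial SD across its steps as a flexibility yardstick.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .frames import INTRA_PARAMS, STEP_PARAMS
from .sequences import SiteWindow
from .structure import AnalyzedStructure, DuplexModel, ParameterTrajectory, analyze_structure

# significance annotation convention used in reports: one star for P < 0.1,
# two for P < 0.05
STAR_THRESHOLDS = ((0.05, "**"), (0.1, "*"))


class FlexibilityError(ValueError):
    pass


@dataclass
class FlexibilityProfile:
    """Per-replica, per-position mean and SD of every helical parameter.

    table columns: replica, kind ('step' or 'bp'), index (1-based), parameter,
    mean, sd.
    """

    fragment: str
    table: pd.DataFrame
    n_replicas: int

    @classmethod
    def from_trajectories(cls, trajectories: list[ParameterTrajectory],
                          fragment: str = "") -> "FlexibilityProfile":
        parts = []
        for traj in trajectories:
            part = per_step_sd(traj)
            part.insert(0, "replica", traj.replica_id)
            parts.append(part)
        return cls(fragment, pd.concat(parts, ignore_index=True), len(trajectories))

    def sd_at(self, parameter: str, step: int, replica: int) -> float:
        t = self.table
        row = t[(t.parameter == parameter) & (t["index"] == step)
                & (t.replica == replica) & (t.kind == "step")]
        return float(row["sd"].iloc[0])


def per_step_sd(traj: ParameterTrajectory) -> pd.DataFrame:
    """Mean and sample SD over frames for every position and parameter."""
    if traj.n_frames < 2:
        raise FlexibilityError("SD undefined for a single-frame trajectory")
    parts = []
    for kind, arr, names in (("step", traj.step, STEP_PARAMS),
                             ("bp", traj.intra, INTRA_PARAMS)):
        mean = arr.mean(axis=0)          # (positions, 6)
        sd = arr.std(axis=0, ddof=1)
        n_pos = arr.shape[1]
        parts.append(pd.DataFrame({
            "kind": kind,
            "index": np.repeat(np.arange(1, n_pos + 1), 6),
            "parameter": np.tile(list(names), n_pos),
            "mean": mean.ravel(),
            "sd": sd.ravel(),
        }))
    return pd.concat(parts, ignore_index=True)


@dataclass
class WindowSdSample:
    """Pooled SD observations for one fragment and parameter.

    One value per (replica x window step); the unit of observation for the
    ANOVA.
    """

    fragment: str
    parameter: str
    values: np.ndarray
    steps: list[int] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.values)


def window_sd_samples(profiles: list[FlexibilityProfile] | dict[str, FlexibilityProfile],
                      windows: list[SiteWindow],
                      parameters: tuple[str, ...] = ("roll", "twist", "slide"),
                      pool_replicas: bool = False) -> list[WindowSdSample]:
    """Collect SD values at every window step from every replica.

    All fragments are sampled at the *same* windows so that position is not
    confounded with modification status.  With pool_replicas=True, the SD is
    first averaged over window steps within each replica (one observation per
    replica instead of replica x step).
    """
    if not windows:
        raise FlexibilityError("empty window list")
    if isinstance(profiles, dict):
        profiles = list(profiles.values())
    steps = sorted({s for w in windows for s in w.step_indices})
    out = []
    for profile in profiles:
        t = profile.table
        max_step = t.loc[t.kind == "step", "index"].max()
        if steps[-1] > max_step:
            raise FlexibilityError(
                f"window step {steps[-1]} outside profile range (1..{max_step})")
        for parameter in parameters:
            kind = "bp" if parameter in INTRA_PARAMS else "step"
            sub = t[(t.kind == kind) & (t.parameter == parameter) & t["index"].isin(steps)]
            if pool_replicas:
                values = sub.groupby("replica")["sd"].mean().to_numpy()
            else:
                values = sub.sort_values(["replica", "index"])["sd"].to_numpy()
            out.append(WindowSdSample(profile.fragment, parameter, values, steps))
    return out


@dataclass
class AnovaResult:
    """Classical one-way fixed-effects ANOVA on SD observations."""

    f_statistic: float
    df_between: int
    df_within: int
    p_value: float
    group_labels: list[str]
    group_sizes: list[int]

    @property
    def stars(self) -> str:
        for threshold, mark in STAR_THRESHOLDS:
            if self.p_value < threshold:
                return mark
        return ""

    def to_dict(self) -> dict:
        return {
            "F": self.f_statistic, "df": [self.df_between, self.df_within],
            "p": self.p_value, "groups": self.group_labels,
            "sizes": self.group_sizes, "stars": self.stars,
        }


def anova_single_factor(groups: list[WindowSdSample] | list[np.ndarray],
                        labels: list[str] | None = None) -> AnovaResult:
    """One-way ANOVA across fragment groups of SD observations."""
    if groups and isinstance(groups[0], WindowSdSample):
        labels = [g.fragment for g in groups]
        arrays = [np.asarray(g.values, float) for g in groups]
    else:
        arrays = [np.asarray(g, float) for g in groups]
        if labels is None:
            labels = [f"group{i + 1}" for i in range(len(arrays))]
    if len(arrays) < 2:
        raise FlexibilityError("ANOVA requires at least 2 groups")
    if any(len(a) < 2 for a in arrays):
        raise FlexibilityError("every ANOVA group needs at least 2 observations")
    sizes = [len(a) for a in arrays]
    df_between = len(arrays) - 1
    df_within = sum(sizes) - len(arrays)
    grand = np.concatenate(arrays)
    ssb = sum(n * (a.mean() - grand.mean()) ** 2 for n, a in zip(sizes, arrays))
    ssw = sum(((a - a.mean()) ** 2).sum() for a in arrays)
    if ssw == 0.0 and ssb == 0.0:
        warnings.warn("zero variance within and between groups; F defined as 0")
        return AnovaResult(0.0, df_between, df_within, 1.0, labels, sizes)
    f_stat, p = stats.f_oneway(*arrays)
    if not np.isfinite(f_stat):  # constant groups with nonzero between-group variance
        f_stat, p = np.inf, 0.0
    return AnovaResult(float(f_stat), df_between, df_within, float(p), labels, sizes)


def anova_report(samples: list[WindowSdSample],
                 reference: str | None = None) -> dict:
    """Joint and pairwise-vs-reference ANOVAs for every parameter.

    reference defaults to the first fragment seen (conventionally the
    unmodified control).  Returns a JSON-ready dict keyed by parameter.
    """
    by_param: dict[str, list[WindowSdSample]] = {}
    for s in samples:
        by_param.setdefault(s.parameter, []).append(s)
    report = {}
    for parameter, group in by_param.items():
        ref_label = reference if reference is not None else group[0].fragment
        entry = {"joint": anova_single_factor(group).to_dict(), "vs_reference": {}}
        ref = [g for g in group if g.fragment == ref_label]
        if ref:
            for g in group:
                if g.fragment == ref_label:
                    continue
                entry["vs_reference"][g.fragment] = anova_single_factor([ref[0], g]).to_dict()
        report[parameter] = entry
    return report


def nucleosome_reference_sd(structure: DuplexModel | AnalyzedStructure,
                            max_origin_gap: float = 10.0) -> dict[str, float]:
    """Spatial SD of each parameter across the steps/bps of one structure.

    The duplex must be continuous: consecutive base-pair origins further
    apart than max_origin_gap are reported as breakpoints.  Sample SD
    convention (n-1), matching the temporal statistics.
    """
    res = structure if isinstance(structure, AnalyzedStructure) else analyze_structure(structure)
    origins = np.array([f.origin for f in res.bp_frames])
    gaps = np.linalg.norm(np.diff(origins, axis=0), axis=1)
    breaks = [i for i, g in enumerate(gaps, start=1) if g > max_origin_gap]
    if breaks:
        raise FlexibilityError(f"duplex discontinuous at step(s) {breaks}")
    out = {}
    step_arr = np.array([p.as_array() for p in res.step])
    for j, name in enumerate(STEP_PARAMS):
        out[name] = float(step_arr[:, j].std(ddof=1)) if len(step_arr) > 1 else 0.0
    intra_arr = np.array([p.as_array() for p in res.intra])
    for j, name in enumerate(INTRA_PARAMS):
        out[name] = float(intra_arr[:, j].std(ddof=1)) if len(intra_arr) > 1 else 0.0
    return out


def violin_summary(samples: list[WindowSdSample]) -> pd.DataFrame:
    """Quartiles, mean and a kernel-density summary per group.

    Rows ordered stably by (fragment, parameter).
    """
    rows = []
    for s in sorted(samples, key=lambda s: (s.fragment, s.parameter)):
        v = np.asarray(s.values, float)
        kde_bw = float(stats.gaussian_kde(v).factor) if len(v) > 1 and v.std() > 0 else np.nan
        rows.append({
            "fragment": s.fragment, "parameter": s.parameter, "n": len(v),
            "mean": v.mean(), "sd": v.std(ddof=1) if len(v) > 1 else np.nan,
            "min": v.min(), "q1": np.quantile(v, 0.25), "median": np.quantile(v, 0.5),
            "q3": np.quantile(v, 0.75), "max": v.max(), "kde_bandwidth": kde_bw,
        })
    return pd.DataFrame(rows)


def export_violin_summaries(samples: list[WindowSdSample], out_csv: str | Path,
                            plot_path: str | Path | None = None) -> pd.DataFrame:
    """Write the violin summary table as CSV and optionally a violin plot."""
    if not samples:
        raise FlexibilityError("no samples to summarise")
    table = violin_summary(samples)
    table.to_csv(out_csv, index=False)
    if plot_path is not None:
        _violin_plot(samples, plot_path)
    return table


def _violin_plot(samples: list[WindowSdSample], path: str | Path) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    params = sorted({s.parameter for s in samples})
    fig, axes = plt.subplots(1, len(params), figsize=(4 * len(params), 4), squeeze=False)
    for ax, parameter in zip(axes[0], params):
        group = [s for s in samples if s.parameter == parameter]
        ax.violinplot([s.values for s in group], showmeans=True)
        ax.set_xticks(range(1, len(group) + 1), [s.fragment for s in group],
                      rotation=45, ha="right")
        ax.set_title(parameter)
        ax.set_ylabel("SD per replica x step")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
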