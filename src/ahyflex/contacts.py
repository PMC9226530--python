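"""Azide-DNA contact classification and conditioned parameter profiles.

Frames of an azide-carrying ensemble are sorted by whether any side chain's
terminal azide nitrogen lies within a distance threshold (default 4.5 A,
strict less-than; the boundary itself counts as no touch) of any eligible
DNA heavy atom — every atom of both strands except the querying side
chain's own atoms.  Helical-parameter distributions are then summarised
within the "any touch" and "no touch" frame classes, with a seeded random
split of the same frames as the null control.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .frames import STEP_PARAMS
from .structure import DuplexModel, DuplexTrajectory, ParameterTrajectory

DEFAULT_THRESHOLD = 4.5  # Angstrom
TERMINAL_AZIDE_ATOM = "N5C"


class ContactError(ValueError):
    pass


@dataclass(frozen=True)
class ContactRecord:
    """Minimum azide-DNA distance and touch flag for one frame and site."""

    frame: int   # 1-based
    site: int    # bp position of the modified C
    min_distance: float
    touching: bool


@dataclass
class ContactTable:
    """All contact records of one ensemble plus the per-frame any-touch flag."""

    records: pd.DataFrame     # columns: frame, site, min_distance, touching
    threshold: float

    @property
    def n_frames(self) -> int:
        return int(self.records["frame"].max())

    @property
    def sites(self) -> list[int]:
        return sorted(self.records["site"].unique())

    def any_touch(self) -> np.ndarray:
        flags = (self.records.groupby("frame")["touching"].any()
                 .reindex(range(1, self.n_frames + 1), fill_value=False))
        return flags.to_numpy()

    def to_records(self) -> list[ContactRecord]:
        return [ContactRecord(int(r.frame), int(r.site), float(r.min_distance), bool(r.touching))
                for r in self.records.itertuples()]


def classify_frames(ensemble: DuplexTrajectory, threshold: float = DEFAULT_THRESHOLD,
                    sites: list[int] | None = None) -> ContactTable:
    """Per-frame, per-site minimum azide-DNA distances from coordinates.

    Eligible DNA atoms for a site are all heavy atoms of both strands except
    that side chain's own atoms (its own base ring included).
    """
    if threshold <= 0:
        raise ContactError("threshold must be positive")
    if sites is None:
        sites = sorted(int(s) for s in set(ensemble.sidechain_site) - {0})
    if not sites:
        raise ContactError("no azide-modified sites in ensemble")
    rows = []
    for site in sites:
        tip_idx = np.flatnonzero(
            (ensemble.sidechain_site == site) & (ensemble.names == TERMINAL_AZIDE_ATOM))
        if len(tip_idx) != 1:
            raise ContactError(f"site {site}: terminal azide atom not identifiable")
        eligible = ensemble.sidechain_site != site
        tips = ensemble.coords[:, tip_idx[0], :]             # (F, 3)
        others = ensemble.coords[:, eligible, :]             # (F, M, 3)
        dists = np.linalg.norm(others - tips[:, None, :], axis=2).min(axis=1)
        rows.append(pd.DataFrame({
            "frame": np.arange(1, ensemble.n_frames + 1),
            "site": site,
            "min_distance": dists,
            "touching": dists < threshold,
        }))
    records = pd.concat(rows, ignore_index=True).sort_values(["frame", "site"],
                                                             ignore_index=True)
    return ContactTable(records, threshold)


def contacts_from_distances(distances: pd.DataFrame,
                            threshold: float = DEFAULT_THRESHOLD) -> ContactTable:
    """Contact table from a precomputed distance series.

    distances needs columns frame, site, distance (e.g. the latent-truth
    table of a fast-mode synthetic ensemble, optionally filtered to one
    replica).
    """
    if threshold <= 0:
        raise ContactError("threshold must be positive")
    if distances.empty:
        raise ContactError("empty distance table")
    records = pd.DataFrame({
        "frame": distances["frame"].to_numpy(),
        "site": distances["site"].to_numpy(),
        "min_distance": distances["distance"].to_numpy(),
    })
    records["touching"] = records["min_distance"] < threshold
    return ContactTable(records.sort_values(["frame", "site"], ignore_index=True), threshold)


def partition_counts(contacts: ContactTable) -> tuple[int, int, int]:
    """(n_any_touch, n_no_touch, n_total); the first two always sum to the
    third."""
    per_site = contacts.records.groupby("site")["frame"].count()
    if per_site.nunique() > 1 or per_site.iloc[0] != contacts.n_frames:
        raise ContactError("records do not cover every frame exactly once per site")
    flags = contacts.any_touch()
    n_any = int(flags.sum())
    return n_any, int(len(flags) - n_any), int(len(flags))


@dataclass
class ConditionedSummary:
    """Per-step parameter statistics within disjoint frame groups.

    table columns: group, step, parameter, mean, sd, n.  SD is NaN for
    single-frame groups (flagged, not silently zero).
    """

    table: pd.DataFrame
    group_sizes: dict[str, int]

    def group(self, label: str) -> pd.DataFrame:
        return self.table[self.table.group == label]

    def mean_profile(self, label: str, parameter: str) -> np.ndarray:
        sub = self.table[(self.table.group == label) & (self.table.parameter == parameter)]
        return sub.sort_values("step")["mean"].to_numpy()

    def sd_profile(self, label: str, parameter: str) -> np.ndarray:
        sub = self.table[(self.table.group == label) & (self.table.parameter == parameter)]
        return sub.sort_values("step")["sd"].to_numpy()


def _group_summary(traj: ParameterTrajectory, mask: np.ndarray, label: str,
                   parameters: tuple[str, ...]) -> pd.DataFrame:
    idx = [STEP_PARAMS.index(p) for p in parameters]
    sub = traj.step[mask][:, :, idx]               # (n, steps, k)
    n = int(mask.sum())
    mean = sub.mean(axis=0)
    sd = sub.std(axis=0, ddof=1) if n > 1 else np.full(sub.shape[1:], np.nan)
    n_steps = sub.shape[1]
    return pd.DataFrame({
        "group": label,
        "step": np.repeat(np.arange(1, n_steps + 1), len(parameters)),
        "parameter": np.tile(list(parameters), n_steps),
        "mean": mean.ravel(),
        "sd": sd.ravel(),
        "n": n,
    })


def conditioned_profiles(traj: ParameterTrajectory, any_touch: np.ndarray,
                         parameters: tuple[str, ...] = ("roll", "twist", "slide"),
                         labels: tuple[str, str] = ("any touch", "no touch"),
                         ) -> ConditionedSummary:
    """Mean/SD of the requested step parameters within the touch classes,
    at every step of the fragment."""
    any_touch = np.asarray(any_touch, dtype=bool)
    if len(any_touch) != traj.n_frames:
        raise ContactError(
            f"flag vector length {len(any_touch)} != {traj.n_frames} frames")
    if any_touch.all() or not any_touch.any():
        raise ContactError(
            "one conditioning group is empty; use a different threshold or more frames")
    parts = [_group_summary(traj, any_touch, labels[0], parameters),
             _group_summary(traj, ~any_touch, labels[1], parameters)]
    table = pd.concat(parts, ignore_index=True)
    return ConditionedSummary(table, {labels[0]: int(any_touch.sum()),
                                      labels[1]: int((~any_touch).sum())})


def random_split_control(traj: ParameterTrajectory, sizes: tuple[int, int], seed: int,
                         parameters: tuple[str, ...] = ("roll", "twist", "slide"),
                         ) -> ConditionedSummary:
    """Uniform random partition of the same frames into groups of the given
    sizes, summarised exactly like conditioned_profiles (the null control)."""
    n_a, n_b = sizes
    if n_a + n_b != traj.n_frames:
        raise ContactError(f"split sizes {sizes} do not sum to {traj.n_frames} frames")
    rng = np.random.default_rng(seed)
    mask = np.zeros(traj.n_frames, dtype=bool)
    mask[rng.choice(traj.n_frames, size=n_a, replace=False)] = True
    return conditioned_profiles(traj, mask, parameters, labels=("split A", "split B"))


def interaction_frequencies(ensemble: DuplexTrajectory,
                            threshold: float = DEFAULT_THRESHOLD,
                            sites: list[int] | None = None) -> pd.DataFrame:
    """Cumulative per-residue contact frequencies for each azide site.

    For every frame, each residue (chain, resid) with at least one eligible
    heavy atom within the threshold of the site's terminal azide N is
    counted; frequencies are fractions of frames, so multiple residues may
    be counted in one frame (cumulative, not exclusive attribution).  A
    site's own base counts (self-loop); its own side chain never does.
    """
    if sites is None:
        sites = sorted(int(s) for s in set(ensemble.sidechain_site) - {0})
    rows = []
    residue_keys = list(zip(ensemble.chains, ensemble.resids))
    unique_residues = sorted(set(residue_keys))
    res_index = np.array([unique_residues.index(k) for k in residue_keys])
    for site in sites:
        tip_idx = np.flatnonzero(
            (ensemble.sidechain_site == site) & (ensemble.names == TERMINAL_AZIDE_ATOM))
        if len(tip_idx) != 1:
            raise ContactError(f"site {site}: terminal azide atom not identifiable")
        eligible = ensemble.sidechain_site != site
        tips = ensemble.coords[:, tip_idx[0], :]
        dists = np.linalg.norm(ensemble.coords[:, eligible, :] - tips[:, None, :], axis=2)
        close = dists < threshold                     # (F, M)
        res_of_eligible = res_index[eligible]
        counts = np.zeros(len(unique_residues))
        for r in range(len(unique_residues)):
            cols = res_of_eligible == r
            if cols.any():
                counts[r] = close[:, cols].any(axis=1).mean()
        for r, freq in enumerate(counts):
            if freq > 0:
                chain, resid = unique_residues[r]
                rows.append({"site": site, "chain": chain, "resid": int(resid),
                             "frequency": float(freq)})
    return pd.DataFrame(rows, columns=["site", "chain", "resid", "frequency"])


@dataclass
class DwellStatistics:
    """Run-length statistics of consecutive touch frames."""

    run_lengths: np.ndarray
    frame_stride: float | None = None  # time per frame, arbitrary units

    @property
    def n_runs(self) -> int:
        return len(self.run_lengths)

    @property
    def mean_frames(self) -> float:
        return float(self.run_lengths.mean()) if self.n_runs else 0.0

    @property
    def median_frames(self) -> float:
        return float(np.median(self.run_lengths)) if self.n_runs else 0.0

    @property
    def mean_time(self) -> float | None:
        return None if self.frame_stride is None else self.mean_frames * self.frame_stride

    @property
    def median_time(self) -> float | None:
        return None if self.frame_stride is None else self.median_frames * self.frame_stride


def contact_dwell_statistics(any_touch: np.ndarray,
                             frame_stride: float | None = None) -> DwellStatistics:
    """Run-length encoding of the touch flag series."""
    flags = np.asarray(any_touch, dtype=bool)
    if flags.size == 0:
        return DwellStatistics(np.array([], dtype=int), frame_stride)
    edges = np.flatnonzero(np.diff(flags.astype(int)))
    starts = np.concatenate([[0], edges + 1])
    ends = np.concatenate([edges + 1, [len(flags)]])
    runs = np.array([e - s for s, e in zip(starts, ends) if flags[s]], dtype=int)
    return DwellStatistics(runs, frame_stride)
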