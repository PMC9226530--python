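"""Synthetic duplex conformational ensembles with planted effects.

The generator emulates the statistical structure that the flexibility and
contact analyses assume of an MD ensemble, without any physics: per-step
Gaussian helical-parameter fluctuations whose spread is inflated (or
reduced) at modified-site windows, and, for azide-carrying duplexes, a
latent two-state ("touch"/"no touch") Markov chain per side chain that
shifts the local roll/twist/slide means while touching.  Ground truth
(state and azide-DNA distance per frame per site) is recorded so recovery
tests can score the analysis stages against what was planted.

Fast mode emits parameter tables and distance series directly; coordinate
mode additionally builds atomic models frame by frame (synthetic fibre
geometry with the azide tail laid along the C5->terminal-N line).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .frames import INTRA_PARAMS, STEP_PARAMS, IntraBpParameters, StepParameters
from .refgeom import AHY_CHAIN
from .sequences import AnnotatedDuplex, Modification, SiteWindow, modification_windows
from .structure import DuplexTrajectory, ParameterTrajectory, rebuild_duplex

# B-DNA-like baseline levels.  Only ratios between fragments matter to the
# in-scope statistics; absolute levels are free parameters.
DEFAULT_STEP_MEANS = {"shift": 0.0, "slide": 0.0, "rise": 3.35, "tilt": 0.0, "roll": 0.0, "twist": 34.3}
DEFAULT_STEP_SDS = {"shift": 0.4, "slide": 0.4, "rise": 0.25, "tilt": 3.5, "roll": 5.5, "twist": 4.5}
DEFAULT_BP_MEANS = {"shear": 0.0, "stretch": 0.0, "stagger": 0.0, "buckle": 0.0, "propeller": -12.0, "opening": 0.0}
DEFAULT_BP_SDS = {"shear": 0.25, "stretch": 0.12, "stagger": 0.35, "buckle": 8.0, "propeller": 8.0, "opening": 4.0}

# The printed 25-bp fragment with CpG sites at top positions 8 and 16.
REFERENCE_FRAGMENT = "GCTCTCTCGAAGCAACGAGAACAGT"

TOUCH_THRESHOLD = 4.5  # Angstrom


class EnsembleConfigError(ValueError):
    """Raised on invalid generator configuration."""


@dataclass
class ContactModel:
    """Latent azide-contact model for ahy-modified sites.

    p_touch is the stationary per-site touch probability; mean_dwell_frames
    the expected run length of a touch episode.  While a site touches, the
    roll/twist/slide means at its step window gain the configured shifts and
    its azide terminal N sits at a distance drawn from touch_distance_range;
    otherwise from notouch_distance_range (both in A, straddling the 4.5 A
    classification boundary).
    """

    p_touch: float = 0.554
    mean_dwell_frames: float = 9.0
    touch_roll_shift: float = 4.0
    touch_twist_shift: float = 3.0
    touch_slide_shift: float = 0.3
    touch_distance_range: tuple[float, float] = (2.5, 4.5)
    notouch_distance_range: tuple[float, float] = (4.5, 9.0)

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_touch <= 1.0:
            raise EnsembleConfigError(f"p_touch {self.p_touch} outside [0, 1]")
        if self.mean_dwell_frames < 1:
            raise EnsembleConfigError("mean_dwell_frames must be >= 1")
        lo, hi = self.touch_distance_range
        if not 0 < lo < hi <= TOUCH_THRESHOLD:
            raise EnsembleConfigError("touch_distance_range must lie in (0, 4.5]")
        lo, hi = self.notouch_distance_range
        if not TOUCH_THRESHOLD <= lo < hi:
            raise EnsembleConfigError("notouch_distance_range must start at >= 4.5")


@dataclass
class EnsembleConfig:
    """Generative specification of a synthetic ensemble."""

    duplex: AnnotatedDuplex
    n_frames: int = 9001
    n_replicas: int = 5
    baseline_step_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_STEP_MEANS))
    baseline_step_sds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_STEP_SDS))
    baseline_bp_means: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BP_MEANS))
    baseline_bp_sds: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_BP_SDS))
    site_sd_multiplier: float = 1.0
    contact_model: ContactModel | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_frames < 1:
            raise EnsembleConfigError("n_frames must be >= 1")
        if self.n_replicas < 1:
            raise EnsembleConfigError("n_replicas must be >= 1")
        if self.site_sd_multiplier <= 0:
            raise EnsembleConfigError("site_sd_multiplier must be > 0")
        for d, ref in ((self.baseline_step_means, STEP_PARAMS), (self.baseline_step_sds, STEP_PARAMS),
                       (self.baseline_bp_means, INTRA_PARAMS), (self.baseline_bp_sds, INTRA_PARAMS)):
            unknown = set(d) - set(ref)
            if unknown:
                raise EnsembleConfigError(f"unknown parameter name(s) {sorted(unknown)}")
        if self.contact_model is not None and not self.ahy_modifications():
            raise EnsembleConfigError("contact model requested but duplex has no ahy modifications")

    @property
    def name(self) -> str:
        return self.duplex.name

    def ahy_modifications(self) -> list[Modification]:
        return [m for m in self.duplex.modifications if m.code == "ahy"]

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "duplex": {
                "top_strand": self.duplex.top_strand,
                "name": self.duplex.name,
                "modifications": [[m.position, m.strand, m.code] for m in self.duplex.modifications],
            },
            "n_frames": self.n_frames,
            "n_replicas": self.n_replicas,
            "baseline_step_means": self.baseline_step_means,
            "baseline_step_sds": self.baseline_step_sds,
            "baseline_bp_means": self.baseline_bp_means,
            "baseline_bp_sds": self.baseline_bp_sds,
            "site_sd_multiplier": self.site_sd_multiplier,
            "contact_model": None if self.contact_model is None else asdict(self.contact_model),
            "seed": self.seed,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            Path(path).write_text(text + "\n")
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "EnsembleConfig":
        if isinstance(source, Path) or not str(source).lstrip().startswith("{"):
            text = Path(source).read_text()
        else:
            text = str(source)
        payload = json.loads(text)
        dup = payload["duplex"]
        duplex = AnnotatedDuplex(
            dup["top_strand"],
            [Modification(p, s, c) for p, s, c in dup.get("modifications", [])],
            name=dup.get("name", ""),
        )
        cm = payload.get("contact_model")
        if cm is not None:
            cm = ContactModel(**{**cm, "touch_distance_range": tuple(cm["touch_distance_range"]),
                                 "notouch_distance_range": tuple(cm["notouch_distance_range"])})
        kwargs = {k: payload[k] for k in
                  ("n_frames", "n_replicas", "baseline_step_means", "baseline_step_sds",
                   "baseline_bp_means", "baseline_bp_sds", "site_sd_multiplier", "seed")
                  if k in payload}
        return cls(duplex=duplex, contact_model=cm, **kwargs)


@dataclass
class SyntheticEnsemble:
    """Generated ensemble plus the ground truth that was planted."""

    config: EnsembleConfig
    trajectories: list[ParameterTrajectory]
    latent: pd.DataFrame  # columns: replica, frame, site, touching, distance
    models: list[DuplexTrajectory] | None = None

    @property
    def n_replicas(self) -> int:
        return len(self.trajectories)

    def sites(self) -> list[int]:
        """Base-pair positions of the azide-carrying cytosines."""
        return sorted({_mod_bp(m) for m in self.config.ahy_modifications()})

    def any_touch(self, replica: int = 0) -> np.ndarray:
        """Per-frame OR over sites of the latent touch state."""
        sub = self.latent[self.latent["replica"] == replica]
        if sub.empty:
            return np.zeros(self.trajectories[replica].n_frames, dtype=bool)
        return (sub.groupby("frame")["touching"].any()
                .reindex(range(1, self.trajectories[replica].n_frames + 1), fill_value=False)
                .to_numpy())

    def write_latent_csv(self, path: str | Path) -> None:
        self.latent.to_csv(path, index=False)


def _mod_bp(mod: Modification) -> int:
    """Base-pair index of the modified cytosine itself."""
    return mod.position


def _site_window(mod: Modification, duplex: AnnotatedDuplex) -> SiteWindow:
    """The step window of the CpG a modification belongs to."""
    cpg_start = mod.position if mod.strand == "top" else mod.position - 1
    return SiteWindow(max(1, cpg_start - 1), min(duplex.length, cpg_start + 2))


def _simulate_touch_chain(rng: np.random.Generator, n: int, p: float, dwell: float) -> np.ndarray:
    """Two-state Markov chain with stationary touch probability p and mean
    touch dwell (capped below so the no-touch exit rate stays a probability;
    the stationary probability is always honoured exactly)."""
    if p <= 0.0:
        return np.zeros(n, dtype=bool)
    if p >= 1.0:
        return np.ones(n, dtype=bool)
    a = min(1.0 / dwell, (1.0 - p) / p)  # touch -> no-touch
    b = p * a / (1.0 - p)                # no-touch -> touch
    u = rng.random(n)
    state = np.empty(n, dtype=bool)
    state[0] = u[0] < p
    for t in range(1, n):
        state[t] = (not state[t - 1] and u[t] < b) or (state[t - 1] and u[t] >= a)
    return state


def generate_ensemble(config: EnsembleConfig, mode: str = "fast") -> SyntheticEnsemble:
    """Draw a synthetic ensemble from the configured generative model.

    mode="fast" emits parameter tables and latent distances only;
    mode="coordinates" additionally builds atomic models per frame whose
    analysis reproduces the planted parameters and whose azide terminal N
    honours the latent contact state geometrically.
    """
    if mode not in {"fast", "coordinates"}:
        raise ValueError(f"unknown mode {mode!r}")
    duplex = config.duplex
    length = duplex.length
    n_steps = length - 1

    step_means = np.array([DEFAULT_STEP_MEANS[p] for p in STEP_PARAMS])
    for k, v in config.baseline_step_means.items():
        step_means[STEP_PARAMS.index(k)] = v
    step_sds = np.array([DEFAULT_STEP_SDS[p] for p in STEP_PARAMS])
    for k, v in config.baseline_step_sds.items():
        step_sds[STEP_PARAMS.index(k)] = v
    bp_means = np.array([DEFAULT_BP_MEANS[p] for p in INTRA_PARAMS])
    for k, v in config.baseline_bp_means.items():
        bp_means[INTRA_PARAMS.index(k)] = v
    bp_sds = np.array([DEFAULT_BP_SDS[p] for p in INTRA_PARAMS])
    for k, v in config.baseline_bp_sds.items():
        bp_sds[INTRA_PARAMS.index(k)] = v

    # SD inflation/deflation at all modified-site windows
    sd_grid = np.tile(step_sds, (n_steps, 1))
    loose_cols = [STEP_PARAMS.index(p) for p in ("roll", "twist", "slide")]
    for window in modification_windows(duplex):
        for s in window.step_indices:
            for c in loose_cols:
                sd_grid[s - 1, c] *= config.site_sd_multiplier

    cm = config.contact_model
    ahy_mods = sorted(config.ahy_modifications())

    trajectories: list[ParameterTrajectory] = []
    latent_rows: list[pd.DataFrame] = []
    models: list[DuplexTrajectory] = [] if mode == "coordinates" else None

    children = np.random.SeedSequence(config.seed).spawn(config.n_replicas)
    for replica, child in enumerate(children):
        rng = np.random.default_rng(child)
        f = config.n_frames

        site_state: dict[int, np.ndarray] = {}
        site_dist: dict[int, np.ndarray] = {}
        if cm is not None:
            for mod in ahy_mods:
                site = _mod_bp(mod)
                state = _simulate_touch_chain(rng, f, cm.p_touch, cm.mean_dwell_frames)
                u = rng.random(f)
                lo_t, hi_t = cm.touch_distance_range
                lo_n, hi_n = cm.notouch_distance_range
                dist = np.where(state, lo_t + u * (hi_t - lo_t), lo_n + u * (hi_n - lo_n))
                site_state[site] = state
                site_dist[site] = dist

        step = rng.normal(step_means, sd_grid, size=(f, n_steps, 6))
        intra = rng.normal(bp_means, bp_sds, size=(f, length, 6))

        if cm is not None:
            shifts = {
                STEP_PARAMS.index("roll"): cm.touch_roll_shift,
                STEP_PARAMS.index("twist"): cm.touch_twist_shift,
                STEP_PARAMS.index("slide"): cm.touch_slide_shift,
            }
            for mod in ahy_mods:
                site = _mod_bp(mod)
                window = _site_window(mod, duplex)
                touching = site_state[site]
                for s in window.step_indices:
                    for col, shift in shifts.items():
                        step[touching, s - 1, col] += shift

        traj = ParameterTrajectory(step, intra, replica_id=replica, source=config.name)
        trajectories.append(traj)

        if cm is not None:
            for mod in ahy_mods:
                site = _mod_bp(mod)
                latent_rows.append(pd.DataFrame({
                    "replica": replica,
                    "frame": np.arange(1, f + 1),
                    "site": site,
                    "touching": site_state[site],
                    "distance": site_dist[site],
                }))

        if mode == "coordinates":
            models.append(_build_coordinates(config, traj, site_state, site_dist))

    if latent_rows:
        latent = pd.concat(latent_rows, ignore_index=True)
    else:
        latent = pd.DataFrame(columns=["replica", "frame", "site", "touching", "distance"])
    return SyntheticEnsemble(config, trajectories, latent, models)


def _build_coordinates(config: EnsembleConfig, traj: ParameterTrajectory,
                       site_state: dict[int, np.ndarray],
                       site_dist: dict[int, np.ndarray]) -> DuplexTrajectory:
    """Atomic models for every frame, with azide tips placed per the latent
    contact state.  The recorded latent distance is re-set to the actual
    minimum eligible-atom distance so geometry and truth always agree."""
    duplex = config.duplex
    frames = []
    for f in range(traj.n_frames):
        per_bp = [IntraBpParameters(*traj.intra[f, i], bp_index=i + 1) for i in range(traj.n_bp)]
        per_step = [StepParameters(*traj.step[f, i], step_index=i + 1) for i in range(traj.n_steps)]
        model = rebuild_duplex(duplex, per_bp, per_step)
        for mod in sorted(config.ahy_modifications()):
            site = _mod_bp(mod)
            _place_azide(model, mod, bool(site_state[site][f]), float(site_dist[site][f]))
        _settle_no_touch(model, config, {s: bool(site_state[s][f]) for s in site_state},
                         {s: float(site_dist[s][f]) for s in site_dist})
        frames.append(model)
    return DuplexTrajectory.from_models(frames)


def _site_mask(model, site: int) -> np.ndarray:
    return model.sidechain_site == site


def _eligible_mask(model, site: int) -> np.ndarray:
    """Heavy atoms of both strands excluding the querying side chain."""
    return ~_site_mask(model, site)


def _site_anchor(model, mod: Modification) -> tuple[np.ndarray, np.ndarray]:
    """(C5 position, outward direction) for a modified cytosine."""
    length = model.duplex.length
    if mod.strand == "top":
        chain, resid = "A", mod.position
    else:
        chain, resid = "B", length + 1 - mod.position
    atoms = model.residue_atoms(chain, resid)
    c5 = atoms["C5"]
    n3 = atoms["N3"]
    out = c5 - n3  # points from the pairing edge outward through the ring
    return c5, out / np.linalg.norm(out)


def _chain_atom_indices(model, site: int) -> np.ndarray:
    idx = np.flatnonzero(_site_mask(model, site))
    order = {name: k for k, (name, *_) in enumerate(AHY_CHAIN)}
    return idx[np.argsort([order[model.names[i]] for i in idx])]


def _lay_chain(model, site: int, c5: np.ndarray, tip: np.ndarray) -> None:
    """Place tail atoms along the C5->tip line (synthetic layout), tip last."""
    idx = _chain_atom_indices(model, site)
    n = len(idx)
    for k, i in enumerate(idx, start=1):
        model.coords[i] = c5 + (tip - c5) * (k / n)


def _min_distance(model, site: int, point: np.ndarray) -> float:
    mask = _eligible_mask(model, site)
    return float(np.min(np.linalg.norm(model.coords[mask] - point, axis=1)))


def _place_azide(model, mod: Modification, touching: bool, distance: float) -> None:
    site = _mod_bp(mod)
    c5, out = _site_anchor(model, mod)
    if touching:
        # nearest eligible atom of any neighbouring residue, excluding the
        # modified base's own residue atoms beyond bonding distance
        mask = _eligible_mask(model, site)
        candidates = model.coords[mask]
        dists = np.linalg.norm(candidates - c5, axis=1)
        # nearest atom more than one bond away, so the tail has somewhere to go
        target = candidates[np.argmin(np.where(dists > 2.0, dists, np.inf))]
        u = c5 + 2.0 * out - target
        u /= np.linalg.norm(u)
        tip = target + distance * u
    else:
        tip = _bisect_outward(model, site, c5, out, distance)
    _lay_chain(model, site, c5, tip)


def _bisect_outward(model, site: int, c5: np.ndarray, out: np.ndarray,
                    distance: float) -> np.ndarray:
    lo, hi = 0.0, 40.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        if _min_distance(model, site, c5 + mid * out) < distance:
            lo = mid
        else:
            hi = mid
    return c5 + hi * out


def _settle_no_touch(model, config: EnsembleConfig, states: dict[int, bool],
                     dists: dict[int, float]) -> None:
    """Re-place no-touch tips whose clearance was spoiled by later side-chain
    placements, until every latent state is geometrically consistent."""
    mods = {_mod_bp(m): m for m in config.ahy_modifications()}
    for _ in range(6):
        dirty = False
        for site, touching in states.items():
            if touching:
                continue
            idx = _chain_atom_indices(model, site)
            tip = model.coords[idx[-1]]
            if _min_distance(model, site, tip) < TOUCH_THRESHOLD:
                c5, out = _site_anchor(model, mods[site])
                _lay_chain(model, site, c5, _bisect_outward(model, site, c5, out, dists[site]))
                dirty = True
        if not dirty:
            return
    raise RuntimeError("could not settle no-touch azide placements")


# ---------------------------------------------------------------------------
# the six reference fragments

def reference_fragment_set(seed: int = 0, n_frames: int = 9001, n_replicas: int = 5,
                           ahy_multiplier: float = 1.5, mc_multiplier: float = 0.8,
                           contact_model: ContactModel | None = None,
                           ) -> dict[str, EnsembleConfig]:
    """Configurations for the six simulated 25-bp fragments.

    All share the printed top strand with CpG sites at 8 and 16.  mCx4 uses
    an SD multiplier < 1 (modestly stiffer), the ahyC fragments > 1 (more
    flexible) at their modified-site windows; azide-carrying fragments get a
    contact model.
    """
    if contact_model is None:
        contact_model = ContactModel()

    def mods(*entries: tuple[int, str, str]) -> list[Modification]:
        return [Modification(p, s, c) for p, s, c in entries]

    spec = {
        "C": ([], 1.0, False),
        "mCx4": (mods((8, "top", "m"), (9, "bottom", "m"),
                      (16, "top", "m"), (17, "bottom", "m")), mc_multiplier, False),
        "ahyCx4": (mods((8, "top", "ahy"), (9, "bottom", "ahy"),
                        (16, "top", "ahy"), (17, "bottom", "ahy")), ahy_multiplier, True),
        "ahyCx2": (mods((8, "top", "ahy"), (16, "top", "ahy")), ahy_multiplier, True),
        "ahyCx1(8)": (mods((8, "top", "ahy")), ahy_multiplier, True),
        "ahyCx1(16)": (mods((16, "top", "ahy")), ahy_multiplier, True),
    }
    out = {}
    for name, (modlist, multiplier, contacts) in spec.items():
        out[name] = EnsembleConfig(
            duplex=AnnotatedDuplex(REFERENCE_FRAGMENT, modlist, name=name),
            n_frames=n_frames,
            n_replicas=n_replicas,
            site_sd_multiplier=multiplier,
            contact_model=contact_model if contacts else None,
            seed=seed,
        )
    return out
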