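"""Base reference frames and rigid-body helical parameters.

The step decomposition follows the mid-step-triad (CEHS) construction used
by the 3DNA family of programs: the net rotation between two base-pair
frames is factored as Rz(w/2 - phi) Ry(Gamma) Rz(w/2 + phi), where w is
twist, Gamma the bend magnitude and phi the hinge phase; roll = Gamma
cos(phi), tilt = Gamma sin(phi); translations are expressed in the mid-step
triad (shift, slide, rise).  The same machinery, with (buckle, propeller,
opening) in place of (tilt, roll, twist) and (shear, stretch, stagger) in
place of (shift, slide, rise), yields the intra-base-pair parameters after
the standard axis flip of the strand-II base frame.  Every decomposition is
exactly invertible (compose_* are closed-form inverses), which the tests
exploit for round-trip checks.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .refgeom import FLIP, RING_ATOMS, standard_coords

STEP_PARAMS = ("shift", "slide", "rise", "tilt", "roll", "twist")
INTRA_PARAMS = ("shear", "stretch", "stagger", "buckle", "propeller", "opening")


class FrameError(ValueError):
    """Raised on invalid or degenerate frame geometry."""


@dataclass(frozen=True)
class BaseFrame:
    """A right-handed orthonormal reference frame.

    origin: 3-vector (A).  axes: 3x3 matrix whose *columns* are the x, y, z
    unit vectors in global coordinates.
    """

    origin: np.ndarray
    axes: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "origin", np.asarray(self.origin, float))
        object.__setattr__(self, "axes", np.asarray(self.axes, float))
        if self.origin.shape != (3,) or self.axes.shape != (3, 3):
            raise FrameError("frame requires a 3-vector origin and 3x3 axes")
        if not np.allclose(self.axes.T @ self.axes, np.eye(3), atol=1e-9):
            raise FrameError("frame axes not orthonormal")
        if np.linalg.det(self.axes) < 0:
            raise FrameError("frame axes left-handed")

    def apply(self, local: np.ndarray) -> np.ndarray:
        """Map local coordinates into the global frame."""
        return np.asarray(local, float) @ self.axes.T + self.origin

    def flipped(self) -> "BaseFrame":
        """Frame with y and z axes negated (strand-II pairing convention)."""
        return BaseFrame(self.origin, self.axes @ FLIP)

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "BaseFrame":
        return BaseFrame(rotation @ self.origin + translation, rotation @ self.axes)


IDENTITY_FRAME = BaseFrame(np.zeros(3), np.eye(3))


@dataclass(frozen=True)
class StepParameters:
    """Six rigid-body parameters between consecutive base pairs."""

    shift: float
    slide: float
    rise: float
    tilt: float
    roll: float
    twist: float
    step_index: int = 0

    def as_array(self) -> np.ndarray:
        return np.array([self.shift, self.slide, self.rise, self.tilt, self.roll, self.twist])


@dataclass(frozen=True)
class IntraBpParameters:
    """Six rigid-body parameters between the two bases of one pair."""

    shear: float
    stretch: float
    stagger: float
    buckle: float
    propeller: float
    opening: float
    bp_index: int = 0

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.shear, self.stretch, self.stagger, self.buckle, self.propeller, self.opening]
        )


def _rot_z(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, -s, 0.0], [s, c, 0.0], [0.0, 0.0, 1.0]])


def _rot_y(a: float) -> np.ndarray:
    c, s = math.cos(a), math.sin(a)
    return np.array([[c, 0.0, s], [0.0, 1.0, 0.0], [-s, 0.0, c]])


def _wrap(deg: float) -> float:
    """Wrap an angle in degrees into (-180, 180]."""
    w = (deg + 180.0) % 360.0 - 180.0
    return 180.0 if w == -180.0 else w


def _decompose(frame1: BaseFrame, frame2: BaseFrame) -> tuple[np.ndarray, BaseFrame]:
    """Six parameters (3 translations, 3 rotations in degrees) taking frame1
    to frame2, plus the mid frame.  Rotations come back in the order
    (about-x, about-y, about-z) = (tilt, roll, twist)-like."""
    a = frame1.axes.T @ frame2.axes
    cos_gamma = np.clip(a[2, 2], -1.0, 1.0)
    sin_gamma = math.hypot(a[0, 2], a[1, 2])
    gamma = math.atan2(sin_gamma, cos_gamma)
    if cos_gamma < -1.0 + 1e-9:
        raise FrameError("degenerate 180-degree rotation between frames")
    if sin_gamma < 1e-12:
        # pure twist about the shared z axis
        omega = math.atan2(a[1, 0], a[0, 0])
        phi = 0.0
        gamma = 0.0
    else:
        alpha = math.atan2(a[1, 2], a[0, 2])      # = w/2 - phi
        beta = math.atan2(a[2, 1], -a[2, 0])      # = w/2 + phi
        omega = alpha + beta
        phi = 0.5 * (beta - alpha)
        # keep twist in (-pi, pi]; a 2-pi shift of omega must be absorbed by
        # a pi shift of the hinge phase to leave the factorisation invariant
        if omega > math.pi:
            omega -= 2.0 * math.pi
            phi -= math.pi
        elif omega <= -math.pi:
            omega += 2.0 * math.pi
            phi += math.pi
    mid_rot = _rot_z(0.5 * omega - phi) @ _rot_y(0.5 * gamma) @ _rot_z(phi)
    mid = BaseFrame(0.5 * (frame1.origin + frame2.origin), frame1.axes @ mid_rot)
    disp = mid.axes.T @ (frame2.origin - frame1.origin)
    rx = math.degrees(gamma) * math.sin(phi)
    ry = math.degrees(gamma) * math.cos(phi)
    rz = _wrap(math.degrees(omega))
    return np.array([disp[0], disp[1], disp[2], rx, ry, rz]), mid


def _compose(frame1: BaseFrame, params: np.ndarray) -> tuple[BaseFrame, BaseFrame]:
    """Inverse of _decompose: frame2 (and the mid frame) from frame1 and the
    six parameters (tx, ty, tz, about-x deg, about-y deg, about-z deg)."""
    tx, ty, tz, rx, ry, rz = params
    gamma = math.radians(math.hypot(rx, ry))
    phi = math.atan2(rx, ry)
    omega = math.radians(rz)
    rot = _rot_z(0.5 * omega - phi) @ _rot_y(gamma) @ _rot_z(0.5 * omega + phi)
    mid_rot = _rot_z(0.5 * omega - phi) @ _rot_y(0.5 * gamma) @ _rot_z(phi)
    mid_axes = frame1.axes @ mid_rot
    delta = mid_axes @ np.array([tx, ty, tz])
    origin2 = frame1.origin + delta
    mid = BaseFrame(frame1.origin + 0.5 * delta, mid_axes)
    return BaseFrame(origin2, frame1.axes @ rot), mid


# ---------------------------------------------------------------------------
# frame fitting

def kabsch(moving: np.ndarray, fixed: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of `moving` onto `fixed`.

    Returns (rotation, translation, rmsd) with fixed ~ moving @ R.T + t.
    Raises FrameError if the optimal transform requires a reflection.
    """
    moving = np.asarray(moving, float)
    fixed = np.asarray(fixed, float)
    mc = moving.mean(axis=0)
    fc = fixed.mean(axis=0)
    h = (moving - mc).T @ (fixed - fc)
    u, s, vt = np.linalg.svd(h)
    d = np.linalg.det(vt.T @ u.T)
    if d < 0:
        # near-planar atom sets (base rings) leave the out-of-plane direction
        # unconstrained: the sign flip there is the standard correction, not a
        # chirality violation
        if s[-1] > 1e-4 * s[0]:
            raise FrameError("superposition requires a reflection (chirality violation)")
        u[:, -1] *= -1.0
    rot = vt.T @ u.T
    t = fc - rot @ mc
    resid = moving @ rot.T + t - fixed
    rmsd = float(np.sqrt((resid**2).sum() / len(moving)))
    return rot, t, rmsd


def fit_base_frame(base_atoms: dict[str, np.ndarray], base_identity: str) -> BaseFrame:
    """Fit the standard reference frame of a base onto observed ring atoms.

    base_atoms maps atom names to 3D coordinates; only the ring atoms of the
    base are used, so C5 substituents (mC/hmC/ahyC) do not enter the fit.
    """
    if base_identity not in RING_ATOMS:
        raise FrameError(f"unknown base identity {base_identity!r}")
    ring = RING_ATOMS[base_identity]
    missing = [a for a in ring if a not in base_atoms]
    if missing:
        raise FrameError(f"missing ring atom(s) {missing} for base {base_identity}")
    observed = np.array([base_atoms[a] for a in ring], float)
    reference = standard_coords(base_identity, ring)
    rot, t, _ = kabsch(reference, observed)
    return BaseFrame(t, rot)  # standard-frame origin is (0,0,0)


# ---------------------------------------------------------------------------
# parameter operations

def step_parameters(bp_frame_i: BaseFrame, bp_frame_j: BaseFrame,
                    step_index: int = 0) -> tuple[StepParameters, BaseFrame]:
    """Step parameters of bp j relative to bp i, plus the mid-step triad."""
    p, mid = _decompose(bp_frame_i, bp_frame_j)
    return StepParameters(p[0], p[1], p[2], p[3], p[4], p[5], step_index), mid


def compose_step(bp_frame_i: BaseFrame, params: StepParameters) -> BaseFrame:
    """Exact inverse of step_parameters: reconstruct bp frame j."""
    frame2, _ = _compose(bp_frame_i, params.as_array())
    return frame2


def pair_parameters(frame_i: BaseFrame, frame_ii: BaseFrame,
                    bp_index: int = 0) -> tuple[IntraBpParameters, BaseFrame]:
    """Intra-base-pair parameters and the base-pair (mid) frame.

    frame_i / frame_ii are the frames of the strand-I and strand-II bases;
    the strand-II frame is y/z-flipped internally per the antiparallel
    convention.  Parameters describe base I relative to the flipped base II.
    """
    p, mid = _decompose(frame_ii.flipped(), frame_i)
    return IntraBpParameters(p[0], p[1], p[2], p[3], p[4], p[5], bp_index), mid


def compose_pair(bp_frame: BaseFrame, params: IntraBpParameters) -> tuple[BaseFrame, BaseFrame]:
    """Inverse of pair_parameters: (strand-I frame, strand-II frame) from the
    base-pair frame and the six intra-bp parameters."""
    arr = params.as_array()
    # reconstruct frame_ii_flipped such that the mid of (ii_flipped -> i) is bp_frame
    tx, ty, tz, rx, ry, rz = arr
    gamma = math.radians(math.hypot(rx, ry))
    phi = math.atan2(rx, ry)
    omega = math.radians(rz)
    mid_rot = _rot_z(0.5 * omega - phi) @ _rot_y(0.5 * gamma) @ _rot_z(phi)
    axes_iif = bp_frame.axes @ np.linalg.inv(mid_rot)
    delta = bp_frame.axes @ np.array([tx, ty, tz])
    origin_iif = bp_frame.origin - 0.5 * delta
    frame_iif = BaseFrame(origin_iif, axes_iif)
    frame_i, _ = _compose(frame_iif, arr)
    return frame_i, frame_iif.flipped()
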