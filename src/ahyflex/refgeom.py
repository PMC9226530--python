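"""Reference geometry: standard bases, backbone placement, side chains.

Standard nucleobase coordinates are given in the base's own standard
reference frame (origin at the pairing centre, x toward the major groove,
y toward the strand-I backbone, z along the helix for a strand-I base),
the convention shared by modern helical-parameter software.  Frame fitting
uses ring atoms only, so 5-substituted cytosines analyse identically to C.
"""

from __future__ import annotations

import math

import numpy as np

# Atomic coordinates (x, y, z in Angstrom) of the standard bases, expressed
# in the standard base reference frame.
STANDARD_BASES: dict[str, dict[str, tuple[float, float, float]]] = {
    "A": {
        "N9": (-1.291, 4.498, 0.000),
        "C8": (0.024, 4.897, 0.000),
        "N7": (0.877, 3.902, 0.000),
        "C5": (0.071, 2.771, 0.000),
        "C6": (0.369, 1.398, 0.000),
        "N6": (1.611, 0.909, 0.000),
        "N1": (-0.668, 0.532, 0.000),
        "C2": (-1.912, 1.023, 0.000),
        "N3": (-2.320, 2.290, 0.000),
        "C4": (-1.267, 3.124, 0.000),
        "C1'": (-2.479, 5.346, 0.000),
    },
    "G": {
        "N9": (-1.289, 4.551, 0.000),
        "C8": (0.023, 4.962, 0.000),
        "N7": (0.870, 3.969, 0.000),
        "C5": (0.071, 2.833, 0.000),
        "C6": (0.424, 1.460, 0.000),
        "O6": (1.554, 0.955, 0.000),
        "N1": (-0.700, 0.641, 0.000),
        "C2": (-1.999, 1.087, 0.000),
        "N2": (-2.949, 0.139, -0.001),
        "N3": (-2.342, 2.364, 0.001),
        "C4": (-1.265, 3.177, 0.000),
        "C1'": (-2.477, 5.399, 0.000),
    },
    "C": {
        "N1": (-1.285, 4.542, 0.000),
        "C2": (-1.472, 3.158, 0.000),
        "O2": (-2.628, 2.709, 0.001),
        "N3": (-0.391, 2.344, 0.000),
        "C4": (0.837, 2.868, 0.000),
        "N4": (1.875, 2.027, 0.001),
        "C5": (1.056, 4.275, 0.000),
        "C6": (-0.023, 5.068, 0.000),
        "C1'": (-2.477, 5.402, 0.000),
    },
    "T": {
        "N1": (-1.284, 4.500, 0.000),
        "C2": (-1.462, 3.135, 0.000),
        "O2": (-2.562, 2.608, 0.000),
        "N3": (-0.298, 2.407, 0.000),
        "C4": (0.994, 2.897, 0.000),
        "O4": (1.944, 2.119, 0.000),
        "C5": (1.106, 4.338, 0.000),
        "C7": (2.466, 4.961, 0.001),
        "C6": (-0.024, 5.057, 0.000),
        "C1'": (-2.481, 5.354, 0.000),
    },
}

# Ring atoms used for frame fitting (exocyclic substituents excluded on
# purpose: C, mC, hmC and ahyC then share one fitting atom set).
RING_ATOMS: dict[str, tuple[str, ...]] = {
    "A": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "G": ("N9", "C8", "N7", "C5", "C6", "N1", "C2", "N3", "C4"),
    "C": ("N1", "C2", "N3", "C4", "C5", "C6"),
    "T": ("N1", "C2", "N3", "C4", "C5", "C6"),
}

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

# Phosphorus placement in the base-pair frame for rebuilt (fibre-style)
# duplexes: radius 9.0 A, azimuth 109 deg, in the bp plane.  Solved so an
# ideal B-DNA duplex (twist 36 deg, rise 3.4 A) reproduces canonical
# cross-strand P-P distances at the groove offsets used in groove_widths.
_P_AZIMUTH = math.radians(71.0)
P_LOCAL = np.array([9.0 * math.cos(_P_AZIMUTH), 9.0 * math.sin(_P_AZIMUTH), 0.0])
# O5' placed between P and C1', purely so rebuilt models carry the minimal
# backbone set; not used by any statistic.
O5_LOCAL = np.array([7.0 * math.cos(_P_AZIMUTH), 7.0 * math.sin(_P_AZIMUTH), 0.3])

# Groove-width convention: cross-strand P-P distance minus a van der Waals
# correction; fixed index offsets (in bp) relative to the base pair.
VDW_CORRECTION = 5.8
MAJOR_GROOVE_OFFSET = -4  # P(strand I, i) to P(strand II, i - 4)
MINOR_GROOVE_OFFSET = 3   # P(strand I, i) to P(strand II, i + 3)

# Strand-II flip: a paired base's frame has its y and z axes reversed
# relative to the shared base-pair frame (antiparallel convention).
FLIP = np.diag([1.0, -1.0, -1.0])


def standard_coords(base: str, atoms: tuple[str, ...] | None = None) -> np.ndarray:
    """(n, 3) standard-frame coordinates for the requested atoms of a base."""
    ref = STANDARD_BASES[base]
    if atoms is None:
        atoms = tuple(ref)
    return np.array([ref[a] for a in atoms], dtype=float)


# ---------------------------------------------------------------------------
# internal-coordinate chain building

def place_atom(
    a: np.ndarray, b: np.ndarray, c: np.ndarray,
    bond: float, angle_deg: float, dihedral_deg: float,
) -> np.ndarray:
    """Position a new atom D given three predecessors A-B-C, the C-D bond
    length, the B-C-D angle and the A-B-C-D dihedral.

    Collinear A-B-C (a 180 deg predecessor angle) is handled by substituting
    an arbitrary stable perpendicular reference, under which the dihedral
    only fixes an overall rotation about the chain axis.
    """
    bc = c - b
    bc /= np.linalg.norm(bc)
    ab = b - a
    n = np.cross(ab, bc)
    norm = np.linalg.norm(n)
    if norm < 1e-8:
        # predecessors collinear: pick any perpendicular to bc
        trial = np.array([1.0, 0.0, 0.0])
        if abs(bc @ trial) > 0.9:
            trial = np.array([0.0, 1.0, 0.0])
        n = np.cross(bc, trial)
        norm = np.linalg.norm(n)
    n /= norm
    m = np.cross(n, bc)
    ang = math.radians(angle_deg)
    dih = math.radians(dihedral_deg)
    d_local = np.array([
        -bond * math.cos(ang),
        bond * math.sin(ang) * math.cos(dih),
        bond * math.sin(ang) * math.sin(dih),
    ])
    frame = np.column_stack([bc, m, n])
    return c + frame @ d_local


# 6-azidohex-2-ynyl side chain off cytosine C5:
#   C5-CH2-C#C-CH2-CH2-CH2-N=N=N
# (name, bond to previous, angle at previous, dihedral).  Standard bond
# lengths: sp3 C-C 1.53, sp3-sp 1.47, C#C 1.20, C-N 1.47, azide N-N 1.24
# and 1.13 A; tetrahedral sp3 angles, linear alkyne, C-N=N 115 deg with a
# linear azide; all-anti torsions (maximally extended).
AHY_CHAIN: tuple[tuple[str, float, float, float], ...] = (
    ("C5A", 1.53, 120.0, 180.0),   # angle/dihedral at ring C5 (sp2)
    ("C5B", 1.47, 109.47, 180.0),
    ("C5C", 1.20, 180.0, 180.0),   # alkyne
    ("C5D", 1.47, 180.0, 180.0),
    ("C5E", 1.53, 109.47, 180.0),
    ("C5F", 1.53, 109.47, 180.0),
    ("N5A", 1.47, 109.47, 180.0),
    ("N5B", 1.24, 115.0, 180.0),   # azide proximal N=N
    ("N5C", 1.13, 180.0, 180.0),   # azide distal N (the terminal N atom)
)

METHYL_CHAIN: tuple[tuple[str, float, float, float], ...] = (
    ("C5M", 1.53, 120.0, 180.0),
)

SIDE_CHAINS = {"ahy": AHY_CHAIN, "m": METHYL_CHAIN, "hm": METHYL_CHAIN}
TERMINAL_ATOM = {"ahy": "N5C", "m": "C5M", "hm": "C5M"}


def build_side_chain(
    code: str,
    c5: np.ndarray | None = None,
    c4: np.ndarray | None = None,
    c6: np.ndarray | None = None,
) -> dict[str, np.ndarray]:
    """Build the side chain of a modified cytosine atom by atom.

    Anchors default to the standard cytosine frame.  Returns name -> position
    for the chain atoms (excluding C5 itself).
    """
    if code not in SIDE_CHAINS:
        raise ValueError(f"unsupported side-chain code {code!r}")
    ref = STANDARD_BASES["C"]
    if c5 is None:
        c5 = np.array(ref["C5"])
        c4 = np.array(ref["C4"])
        c6 = np.array(ref["C6"])
    chain = {}
    # predecessors for the first placement: C4-C6 midpoint trick keeps the
    # first bond in the ring plane, pointing away from the ring
    a, b, c = np.asarray(c4, float), np.asarray(c6, float), np.asarray(c5, float)
    prev3 = [a, b, c]
    for name, bond, angle, dihedral in SIDE_CHAINS[code]:
        pos = place_atom(prev3[-3], prev3[-2], prev3[-1], bond, angle, dihedral)
        chain[name] = pos
        prev3.append(pos)
    return chain


def side_chain_extension(code: str) -> float:
    """Maximum C5-to-terminal-atom distance (A) of an extended side chain.

    All sp3 torsions are anti and the alkyne/azide units are linear.  The
    torsion about the linear C-C#C-C segment is left undefined by those
    rules, so the extension maximises the C5-terminal distance over that
    free rotation (the terminal atom traces a circle about the alkyne axis,
    so the maximum is closed-form).
    """
    chain = build_side_chain(code)
    c5 = np.array(STANDARD_BASES["C"]["C5"])
    tip = chain[TERMINAL_ATOM[code]]
    if code != "ahy":
        return float(np.linalg.norm(tip - c5))
    # rotate the tail tip about the linear alkyne axis; |tip(theta) - C5|^2 is
    # sinusoidal in theta, maximised by aligning the tip's off-axis component
    # against C5's off-axis component
    axis_point = chain["C5D"]
    u = chain["C5D"] - chain["C5C"]
    u /= np.linalg.norm(u)
    rel = tip - axis_point
    along = (rel @ u) * u
    radius = np.linalg.norm(rel - along)
    v = c5 - axis_point
    v_along = (v @ u) * u
    v_perp = np.linalg.norm(v - v_along)
    # farthest point of the circle from C5
    d2 = np.linalg.norm(along - v_along) ** 2 + (radius + v_perp) ** 2
    return float(math.sqrt(d2))
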