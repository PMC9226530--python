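"""Duplex atomic models: analysis, rebuilding and multi-model PDB I/O.

A model carries both strands as chains A (top, 5'->3') and B (bottom,
5'->3' in its own numbering), so chain B residue j pairs with base pair
L+1-j.  Rebuilt models are fibre-style: full base heavy atoms, C1' and a
minimal P/O5' backbone sufficient for groove widths, plus C5 side chains
on modified cytosines.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator

import numpy as np
import pandas as pd

from . import refgeom
from .frames import (
    INTRA_PARAMS,
    STEP_PARAMS,
    BaseFrame,
    FrameError,
    IntraBpParameters,
    StepParameters,
    compose_pair,
    compose_step,
    fit_base_frame,
    pair_parameters,
    step_parameters,
)
from .refgeom import COMPLEMENT, FLIP, P_LOCAL, STANDARD_BASES, VDW_CORRECTION
from .sequences import AnnotatedDuplex

IDENTITY = BaseFrame(np.zeros(3), np.eye(3))

_RESNAME = {"A": "DA", "C": "DC", "G": "DG", "T": "DT"}
_BASE_OF_RESNAME = {v: k for k, v in _RESNAME.items()}
_BASE_OF_RESNAME.update({"A": "A", "C": "C", "G": "G", "T": "T"})  # legacy names
_SIDECHAIN_ATOMS = {name for name, *_ in refgeom.AHY_CHAIN} | {name for name, *_ in refgeom.METHYL_CHAIN}


class StructureError(ValueError):
    """Raised on unmappable or malformed duplex structures."""


@dataclass
class DuplexModel:
    """One conformation of a duplex: atom metadata plus coordinates."""

    duplex: AnnotatedDuplex
    names: np.ndarray          # atom names, shape (N,)
    chains: np.ndarray         # 'A' or 'B'
    resids: np.ndarray         # residue number within the chain (1-based)
    elements: np.ndarray
    sidechain_site: np.ndarray  # top-strand site position of the owning side chain, 0 if none
    coords: np.ndarray          # (N, 3) in Angstrom

    @property
    def n_atoms(self) -> int:
        return len(self.names)

    def bp_of_atom(self) -> np.ndarray:
        """Base-pair index of every atom (chain B numbering reversed)."""
        length = self.duplex.length
        return np.where(self.chains == "A", self.resids, length + 1 - self.resids)

    def residue_atoms(self, chain: str, resid: int) -> dict[str, np.ndarray]:
        mask = (self.chains == chain) & (self.resids == resid)
        return dict(zip(self.names[mask], self.coords[mask]))

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "DuplexModel":
        return DuplexModel(
            self.duplex, self.names, self.chains, self.resids, self.elements,
            self.sidechain_site, self.coords @ np.asarray(rotation).T + translation,
        )


@dataclass
class DuplexTrajectory:
    """Multi-frame ensemble sharing one atom layout."""

    duplex: AnnotatedDuplex
    names: np.ndarray
    chains: np.ndarray
    resids: np.ndarray
    elements: np.ndarray
    sidechain_site: np.ndarray
    coords: np.ndarray  # (F, N, 3)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    def frame(self, i: int) -> DuplexModel:
        return DuplexModel(self.duplex, self.names, self.chains, self.resids,
                           self.elements, self.sidechain_site, self.coords[i])

    def __iter__(self) -> Iterator[DuplexModel]:
        for i in range(self.n_frames):
            yield self.frame(i)

    @classmethod
    def from_models(cls, models: list[DuplexModel]) -> "DuplexTrajectory":
        first = models[0]
        for k, m in enumerate(models):
            if m.n_atoms != first.n_atoms or not np.array_equal(m.names, first.names):
                raise StructureError(f"frame {k}: atom layout differs from frame 0")
        coords = np.stack([m.coords for m in models])
        return cls(first.duplex, first.names, first.chains, first.resids,
                   first.elements, first.sidechain_site, coords)


@dataclass
class GrooveProfile:
    """Per-base-pair groove widths (P-P distance minus the 5.8 A van der
    Waals correction); NaN where a cross-strand phosphate partner is absent."""

    major: np.ndarray
    minor: np.ndarray

    def defined(self, which: str = "major") -> np.ndarray:
        return ~np.isnan(getattr(self, which))


@dataclass
class AnalyzedStructure:
    """Full helical-parameter analysis of one duplex conformation."""

    intra: list[IntraBpParameters]
    step: list[StepParameters]
    groove: GrooveProfile
    bp_frames: list[BaseFrame] = field(default_factory=list, repr=False)


@dataclass
class ParameterTrajectory:
    """Per-frame tables of step and intra-base-pair parameters.

    step has shape (frames, L-1, 6) ordered as STEP_PARAMS; intra has shape
    (frames, L, 6) ordered as INTRA_PARAMS.  Indices are 1-based in all
    exported tables.
    """

    step: np.ndarray
    intra: np.ndarray
    replica_id: int = 0
    source: str = ""

    def __post_init__(self) -> None:
        if self.step.ndim != 3 or self.intra.ndim != 3:
            raise ValueError("parameter arrays must be (frames, positions, 6)")
        if self.step.shape[0] != self.intra.shape[0]:
            raise ValueError("step/intra frame counts differ")
        if self.step.shape[0] < 1:
            raise ValueError("empty trajectory")

    @property
    def n_frames(self) -> int:
        return self.step.shape[0]

    @property
    def n_steps(self) -> int:
        return self.step.shape[1]

    @property
    def n_bp(self) -> int:
        return self.intra.shape[1]

    def step_column(self, parameter: str) -> np.ndarray:
        """(frames, L-1) values of one step parameter."""
        return self.step[:, :, STEP_PARAMS.index(parameter)]

    def to_step_frame(self) -> pd.DataFrame:
        f, s, _ = self.step.shape
        df = pd.DataFrame(self.step.reshape(f * s, 6), columns=list(STEP_PARAMS))
        df.insert(0, "index", np.tile(np.arange(1, s + 1), f))
        df.insert(0, "frame", np.repeat(np.arange(1, f + 1), s))
        return df

    def to_intra_frame(self) -> pd.DataFrame:
        f, b, _ = self.intra.shape
        df = pd.DataFrame(self.intra.reshape(f * b, 6), columns=list(INTRA_PARAMS))
        df.insert(0, "index", np.tile(np.arange(1, b + 1), f))
        df.insert(0, "frame", np.repeat(np.arange(1, f + 1), b))
        return df

    def write_csv(self, step_path: str | Path, intra_path: str | Path | None = None) -> None:
        self.to_step_frame().to_csv(step_path, index=False)
        if intra_path is not None:
            self.to_intra_frame().to_csv(intra_path, index=False)

    @classmethod
    def read_csv(cls, step_path: str | Path, intra_path: str | Path | None = None,
                 replica_id: int = 0, source: str = "") -> "ParameterTrajectory":
        sdf = pd.read_csv(step_path)
        f = sdf["frame"].max()
        s = sdf["index"].max()
        step = sdf.sort_values(["frame", "index"])[list(STEP_PARAMS)].to_numpy().reshape(f, s, 6)
        if intra_path is not None:
            idf = pd.read_csv(intra_path)
            b = idf["index"].max()
            intra = idf.sort_values(["frame", "index"])[list(INTRA_PARAMS)].to_numpy().reshape(f, b, 6)
        else:
            intra = np.zeros((f, s + 1, 6))
        return cls(step, intra, replica_id=replica_id, source=str(source))


# ---------------------------------------------------------------------------
# analysis

def _base_frames(model: DuplexModel) -> tuple[list[BaseFrame], list[BaseFrame]]:
    """Fitted strand-I and strand-II base frames for every base pair."""
    duplex = model.duplex
    length = duplex.length
    frames_i, frames_ii = [], []
    for bp in range(1, length + 1):
        top = duplex.top_strand[bp - 1]
        bottom = COMPLEMENT[top]
        atoms_a = model.residue_atoms("A", bp)
        atoms_b = model.residue_atoms("B", length + 1 - bp)
        if not atoms_a or not atoms_b:
            raise StructureError(f"base pair {bp}: missing residue in model")
        try:
            frames_i.append(fit_base_frame(atoms_a, top))
            frames_ii.append(fit_base_frame(atoms_b, bottom))
        except FrameError as exc:
            raise StructureError(f"base pair {bp}: {exc}") from exc
    return frames_i, frames_ii


def groove_widths(model: DuplexModel) -> GrooveProfile:
    """Cross-strand P-P groove widths at fixed offsets (major +4, minor -3)."""
    duplex = model.duplex
    length = duplex.length
    p_top: dict[int, np.ndarray] = {}
    p_bot: dict[int, np.ndarray] = {}
    for bp in range(1, length + 1):
        a = model.residue_atoms("A", bp)
        b = model.residue_atoms("B", length + 1 - bp)
        if "P" in a:
            p_top[bp] = a["P"]
        if "P" in b:
            p_bot[bp] = b["P"]

    major = np.full(length, np.nan)
    minor = np.full(length, np.nan)
    for bp in range(1, length + 1):
        j = bp + refgeom.MAJOR_GROOVE_OFFSET
        if bp in p_top and 1 <= j <= length and j in p_bot:
            major[bp - 1] = np.linalg.norm(p_top[bp] - p_bot[j]) - VDW_CORRECTION
        j = bp + refgeom.MINOR_GROOVE_OFFSET
        if bp in p_top and 1 <= j <= length and j in p_bot:
            minor[bp - 1] = np.linalg.norm(p_top[bp] - p_bot[j]) - VDW_CORRECTION
    if np.isnan(major).all() and np.isnan(minor).all():
        warnings.warn("duplex too short (or missing phosphates): no groove width defined")
    return GrooveProfile(major, minor)


def analyze_structure(model: DuplexModel,
                      duplex: AnnotatedDuplex | None = None) -> AnalyzedStructure:
    """Helical parameters and groove widths of one duplex conformation."""
    if duplex is not None and duplex.length != model.duplex.length:
        raise StructureError(
            f"duplex length {duplex.length} does not match model ({model.duplex.length} bp)"
        )
    frames_i, frames_ii = _base_frames(model)
    intra: list[IntraBpParameters] = []
    bp_frames: list[BaseFrame] = []
    for bp, (fi, fii) in enumerate(zip(frames_i, frames_ii), start=1):
        params, mid = pair_parameters(fi, fii, bp_index=bp)
        intra.append(params)
        bp_frames.append(mid)
    steps: list[StepParameters] = []
    for i in range(len(bp_frames) - 1):
        sp, _ = step_parameters(bp_frames[i], bp_frames[i + 1], step_index=i + 1)
        steps.append(sp)
    return AnalyzedStructure(intra, steps, groove_widths(model), bp_frames)


def analyze_trajectory(ensemble: DuplexTrajectory | Iterable[DuplexModel],
                       duplex: AnnotatedDuplex | None = None,
                       replica_id: int = 0, source: str = "") -> ParameterTrajectory:
    """Per-frame analyze_structure over an ensemble (streaming over frames)."""
    step_rows, intra_rows = [], []
    n_atoms = None
    for k, model in enumerate(ensemble):
        if n_atoms is None:
            n_atoms = model.n_atoms
        elif model.n_atoms != n_atoms:
            raise StructureError(f"frame {k}: atom count {model.n_atoms} != {n_atoms}")
        res = analyze_structure(model, duplex)
        step_rows.append(np.array([p.as_array() for p in res.step]))
        intra_rows.append(np.array([p.as_array() for p in res.intra]))
    if not step_rows:
        raise StructureError("empty ensemble")
    return ParameterTrajectory(np.stack(step_rows), np.stack(intra_rows),
                               replica_id=replica_id, source=source)


# ---------------------------------------------------------------------------
# rebuilding

def ideal_bdna_parameters(length: int, twist: float = 36.0, rise: float = 3.4,
                          ) -> tuple[list[IntraBpParameters], list[StepParameters]]:
    """Fibre B-DNA parameter set: uniform twist/rise, all else zero."""
    intra = [IntraBpParameters(0, 0, 0, 0, 0, 0, bp_index=i) for i in range(1, length + 1)]
    step = [StepParameters(0, 0, rise, 0, 0, twist, step_index=i) for i in range(1, length)]
    return intra, step


def rebuild_duplex(duplex: AnnotatedDuplex,
                   per_bp: list[IntraBpParameters],
                   per_step: list[StepParameters],
                   side_chain_dihedral: float = 180.0) -> DuplexModel:
    """Build a duplex atomic model from helical parameters.

    Bases use standard geometry placed by composing frames from the
    parameters; modified cytosines carry a C5 methyl (m/hm) or the
    6-azidohex-2-ynyl chain (ahy) with the first torsion set by
    side_chain_dihedral.  analyze_structure on the result reproduces the
    input parameters (exact inverse construction).
    """
    length = duplex.length
    if len(per_bp) != length or len(per_step) != length - 1:
        raise StructureError(
            f"expected {length} intra-bp and {length - 1} step parameter sets, "
            f"got {len(per_bp)} and {len(per_step)}"
        )
    bp_frames = [IDENTITY]
    for sp in per_step:
        bp_frames.append(compose_step(bp_frames[-1], sp))

    names, chains, resids, elements, sites, coords = [], [], [], [], [], []

    def emit(chain: str, resid: int, name: str, pos: np.ndarray, site: int = 0) -> None:
        names.append(name)
        chains.append(chain)
        resids.append(resid)
        elements.append(name.strip()[0])
        sites.append(site)
        coords.append(pos)

    for bp in range(1, length + 1):
        mid = bp_frames[bp - 1]
        frame_i, frame_ii = compose_pair(mid, per_bp[bp - 1])
        top = duplex.top_strand[bp - 1]
        bottom = COMPLEMENT[top]
        resid_b = length + 1 - bp
        # strand I (chain A); no phosphate on the 5'-terminal residue
        if bp > 1:
            emit("A", bp, "P", mid.apply(P_LOCAL))
        emit("A", bp, "O5'", mid.apply(refgeom.O5_LOCAL))
        atoms_top = {n: p for n, p in zip(STANDARD_BASES[top],
                                          frame_i.apply(refgeom.standard_coords(top)))}
        for n, p in atoms_top.items():
            emit("A", bp, n, p)
        # strand II (chain B); its 5' terminus is resid 1 = base pair L
        if resid_b > 1:
            emit("B", resid_b, "P", mid.apply(FLIP @ P_LOCAL))
        emit("B", resid_b, "O5'", mid.apply(FLIP @ refgeom.O5_LOCAL))
        atoms_bot = {n: p for n, p in zip(STANDARD_BASES[bottom],
                                          frame_ii.apply(refgeom.standard_coords(bottom)))}
        for n, p in atoms_bot.items():
            emit("B", resid_b, n, p)
        # side chains on modified cytosines
        for m in duplex.modifications:
            # a side chain is tagged with the bp index of its modified C
            if m.strand == "top" and m.position == bp:
                chain, resid, base_atoms, site = "A", bp, atoms_top, m.position
            elif m.strand == "bottom" and m.position == bp:
                chain, resid, base_atoms, site = "B", resid_b, atoms_bot, m.position
            else:
                continue
            sc = refgeom.build_side_chain(
                m.code, base_atoms["C5"], base_atoms["C4"], base_atoms["C6"])
            if side_chain_dihedral != 180.0 and m.code == "ahy":
                sc = _rotate_chain(sc, base_atoms["C5"], side_chain_dihedral)
            for n, p in sc.items():
                emit(chain, resid, n, p, site=site)

    # standard PDB layout: chain A residues ascending, then chain B ascending
    order = sorted(range(len(names)), key=lambda i: (chains[i], resids[i]))
    return DuplexModel(duplex,
                       np.array([names[i] for i in order], dtype=object),
                       np.array([chains[i] for i in order], dtype=object),
                       np.array([resids[i] for i in order], dtype=int),
                       np.array([elements[i] for i in order], dtype=object),
                       np.array([sites[i] for i in order], dtype=int),
                       np.array([coords[i] for i in order], dtype=float))


def _rotate_chain(chain: dict[str, np.ndarray], c5: np.ndarray,
                  dihedral: float) -> dict[str, np.ndarray]:
    """Rotate side-chain atoms beyond C5A about the C5-C5A bond."""
    from scipy.spatial.transform import Rotation

    axis = chain["C5A"] - c5
    axis = axis / np.linalg.norm(axis)
    rot = Rotation.from_rotvec(np.radians(dihedral - 180.0) * axis).as_matrix()
    out = {"C5A": chain["C5A"]}
    for n, p in chain.items():
        if n != "C5A":
            out[n] = (rot @ (p - chain["C5A"])) + chain["C5A"]
    return out


# ---------------------------------------------------------------------------
# multi-model PDB I/O

def write_pdb(trajectory: DuplexTrajectory | DuplexModel | list[DuplexModel],
              path: str | Path) -> None:
    """Write a (multi-)model PDB with chains A/B for the two strands."""
    if isinstance(trajectory, DuplexModel):
        trajectory = DuplexTrajectory.from_models([trajectory])
    elif isinstance(trajectory, list):
        trajectory = DuplexTrajectory.from_models(trajectory)
    duplex = trajectory.duplex
    length = duplex.length
    resname = np.empty(len(trajectory.names), dtype=object)
    for i in range(len(trajectory.names)):
        if trajectory.chains[i] == "A":
            base = duplex.top_strand[trajectory.resids[i] - 1]
        else:
            base = COMPLEMENT[duplex.top_strand[length - trajectory.resids[i]]]
        resname[i] = _RESNAME[base]
    lines: list[str] = []
    multi = trajectory.n_frames > 1
    for f in range(trajectory.n_frames):
        if multi:
            lines.append(f"MODEL     {f + 1:4d}")
        serial = 0
        for i in range(len(trajectory.names)):
            if i and trajectory.chains[i] != trajectory.chains[i - 1]:
                lines.append("TER")
            serial += 1
            name = trajectory.names[i]
            pad = f" {name:<3s}" if len(name) < 4 else name
            x, y, z = trajectory.coords[f, i]
            lines.append(
                f"ATOM  {serial:5d} {pad:<4s} {resname[i]:>3s} {trajectory.chains[i]}"
                f"{trajectory.resids[i]:4d}    {x:8.3f}{y:8.3f}{z:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {trajectory.elements[i]:>2s}"
            )
        lines.append("TER")
        if multi:
            lines.append("ENDMDL")
    lines.append("END")
    Path(path).write_text("\n".join(lines) + "\n")


def read_pdb(path: str | Path, duplex: AnnotatedDuplex | None = None,
             chain_top: str = "A", chain_bottom: str = "B") -> DuplexTrajectory:
    """Read a (multi-)model PDB into a trajectory.

    If `duplex` is omitted the top-strand sequence is inferred from chain A
    residue names; modification annotations are then inferred from side-chain
    atoms present on cytosines.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("duplex", str(path))
    models = list(structure)
    if not models:
        raise StructureError(f"{path}: no models found")

    first = models[0]
    names, chains, resids, elements, coords0 = [], [], [], [], []
    seq_a: dict[int, str] = {}
    for chain in first:
        tag = "A" if chain.id == chain_top else ("B" if chain.id == chain_bottom else None)
        if tag is None:
            continue
        for residue in chain:
            resname = residue.get_resname().strip()
            if resname not in _BASE_OF_RESNAME:
                continue
            rid = residue.id[1]
            if tag == "A":
                seq_a[rid] = _BASE_OF_RESNAME[resname]
            for atom in residue:
                if atom.element == "H":
                    continue
                names.append(atom.get_name())
                chains.append(tag)
                resids.append(rid)
                elements.append(atom.element if atom.element else atom.get_name()[0])
                coords0.append(atom.coord.astype(float))
    if not names:
        raise StructureError(f"{path}: no DNA atoms on chains {chain_top}/{chain_bottom}")

    if duplex is None:
        seq = "".join(seq_a[k] for k in sorted(seq_a))
        mods = _infer_modifications(names, chains, resids, seq)
        duplex = AnnotatedDuplex(seq, mods, name=Path(path).stem)
    if duplex.length != len(seq_a):
        raise StructureError(
            f"{path}: chain {chain_top} has {len(seq_a)} residues, duplex has {duplex.length}"
        )

    names_arr = np.array(names, dtype=object)
    chains_arr = np.array(chains, dtype=object)
    resids_arr = np.array(resids, dtype=int)
    site = np.zeros(len(names), dtype=int)
    length = duplex.length
    for i in range(len(names)):
        if names[i] in _SIDECHAIN_ATOMS:
            bp = resids[i] if chains[i] == "A" else length + 1 - resids[i]
            site[i] = bp

    all_coords = [np.array(coords0)]
    for k, model in enumerate(models[1:], start=2):
        frame_coords = []
        for chain in model:
            tag = "A" if chain.id == chain_top else ("B" if chain.id == chain_bottom else None)
            if tag is None:
                continue
            for residue in chain:
                if residue.get_resname().strip() not in _BASE_OF_RESNAME:
                    continue
                for atom in residue:
                    if atom.element == "H":
                        continue
                    frame_coords.append(atom.coord.astype(float))
        if len(frame_coords) != len(names):
            raise StructureError(f"{path}: model {k} has {len(frame_coords)} atoms, expected {len(names)}")
        all_coords.append(np.array(frame_coords))

    return DuplexTrajectory(duplex, names_arr, chains_arr, resids_arr,
                            np.array(elements, dtype=object), site, np.stack(all_coords))


def _infer_modifications(names: list[str], chains: list[str], resids: list[int],
                         seq: str) -> list:
    """Infer modification annotations from side-chain atoms in a PDB."""
    from .sequences import Modification

    length = len(seq)
    found: dict[tuple[int, str], set[str]] = {}
    for n, c, r in zip(names, chains, resids):
        if n not in _SIDECHAIN_ATOMS:
            continue
        bp = r if c == "A" else length + 1 - r
        strand = "top" if c == "A" else "bottom"
        found.setdefault((bp, strand), set()).add(n)
    mods = []
    for (pos, strand), atoms in sorted(found.items()):
        code = "ahy" if "N5C" in atoms else "m"
        mods.append(Modification(pos, strand, code))
    return mods
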