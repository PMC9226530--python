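"""Modified duplex sequences, CpG sites and analysis windows.

A duplex is represented by its top strand (5'->3') plus a list of cytosine-5
modifications.  All coordinates are 1-based and ranges are inclusive.  A
modification on the bottom strand (the C paired with a top-strand G) is
recorded against the top-strand index of that G, so a fully modified CpG at
top positions (p, p+1) carries a top-strand entry at p and a bottom-strand
entry at p+1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

MOD_CODES = frozenset({"m", "hm", "ahy"})
STRANDS = frozenset({"top", "bottom"})

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


class DuplexValidationError(ValueError):
    """Raised when a duplex annotation violates its invariants."""


@dataclass(frozen=True, order=True)
class Modification:
    """A single cytosine-5 modification.

    position is the 1-based top-strand index of the modified C (strand="top")
    or of the G whose paired bottom-strand C is modified (strand="bottom").
    code is one of {m, hm, ahy}: 5-methyl, 5-hydroxymethyl or
    5-(6-azidohex-2-ynyl) cytosine.
    """

    position: int
    strand: str
    code: str


@dataclass
class AnnotatedDuplex:
    """A duplex DNA fragment with per-position modification annotations."""

    top_strand: str
    modifications: list[Modification] = field(default_factory=list)
    name: str = ""

    def __post_init__(self) -> None:
        self.top_strand = self.top_strand.upper()
        bad = re.search(r"[^ACGT]", self.top_strand)
        if bad:
            raise DuplexValidationError(
                f"non-ACGT character {self.top_strand[bad.start()]!r} "
                f"at position {bad.start() + 1}"
            )
        if not self.top_strand:
            raise DuplexValidationError("empty sequence")
        seen: set[tuple[int, str]] = set()
        for mod in self.modifications:
            if mod.code not in MOD_CODES:
                raise DuplexValidationError(f"unknown modification code {mod.code!r}")
            if mod.strand not in STRANDS:
                raise DuplexValidationError(f"unknown strand {mod.strand!r}")
            if not 1 <= mod.position <= self.length:
                raise DuplexValidationError(
                    f"modification position {mod.position} outside [1, {self.length}]"
                )
            base = self.top_strand[mod.position - 1]
            want = "C" if mod.strand == "top" else "G"
            if base != want:
                raise DuplexValidationError(
                    f"modification at position {mod.position} ({mod.strand} strand) "
                    f"requires top-strand {want}, found {base}"
                )
            key = (mod.position, mod.strand)
            if key in seen:
                raise DuplexValidationError(f"duplicate modification at {key}")
            seen.add(key)
        self.modifications = sorted(self.modifications)

    @property
    def length(self) -> int:
        return len(self.top_strand)

    @property
    def bottom_strand(self) -> str:
        """Bottom strand written 5'->3'."""
        return self.top_strand.translate(_COMPLEMENT)[::-1]

    def base_pair(self, position: int) -> tuple[str, str]:
        """(top base, paired bottom base) at a 1-based position."""
        top = self.top_strand[position - 1]
        return top, top.translate(_COMPLEMENT)

    def modified_positions(self, codes: frozenset[str] | None = None) -> list[int]:
        """Sorted unique top-strand positions carrying a modification.

        A bottom-strand entry at p marks the C of the CpG whose G sits at top
        position p; the site it belongs to starts at p-1, which is what this
        returns so that windows centre on the CpG's top-strand C.
        """
        out = set()
        for mod in self.modifications:
            if codes is not None and mod.code not in codes:
                continue
            out.add(mod.position if mod.strand == "top" else mod.position - 1)
        return sorted(out)


@dataclass(frozen=True)
class SiteWindow:
    """Inclusive 1-based base-pair and step ranges around a modified site.

    Step i lies between base pairs i and i+1, so the step range of a bp range
    [a, b] is [a, b-1].
    """

    bp_start: int
    bp_end: int

    def __post_init__(self) -> None:
        if self.bp_start > self.bp_end or self.bp_start < 1:
            raise DuplexValidationError(f"invalid bp window [{self.bp_start}, {self.bp_end}]")

    @property
    def step_start(self) -> int:
        return self.bp_start

    @property
    def step_end(self) -> int:
        return self.bp_end - 1

    @property
    def bp_indices(self) -> list[int]:
        return list(range(self.bp_start, self.bp_end + 1))

    @property
    def step_indices(self) -> list[int]:
        return list(range(self.step_start, self.step_end + 1))


def find_cpg_sites(seq: str) -> list[int]:
    """1-based positions of the C of every CpG dinucleotide on the given strand."""
    seq = seq.upper()
    if not seq:
        raise DuplexValidationError("empty sequence")
    bad = re.search(r"[^ACGT]", seq)
    if bad:
        raise DuplexValidationError(
            f"non-ACGT character {seq[bad.start()]!r} at position {bad.start() + 1}"
        )
    return [i + 1 for i in range(len(seq) - 1) if seq[i] == "C" and seq[i + 1] == "G"]


def modification_windows(
    duplex: AnnotatedDuplex,
    flank: int = 1,
    codes: frozenset[str] | None = None,
) -> list[SiteWindow]:
    """One window per modified CpG site, +/- `flank` base pairs, merged when
    overlapping and clipped to the duplex bounds."""
    cpg = set(find_cpg_sites(duplex.top_strand))
    raw: list[tuple[int, int]] = []
    for p in duplex.modified_positions(codes):
        if p not in cpg:
            raise DuplexValidationError(
                f"modified position {p} does not start a CpG on the top strand"
            )
        raw.append((max(1, p - flank), min(duplex.length, p + 1 + flank)))
    raw.sort()
    merged: list[list[int]] = []
    for a, b in raw:
        if merged and a <= merged[-1][1] + 1:
            merged[-1][1] = max(merged[-1][1], b)
        else:
            merged.append([a, b])
    return [SiteWindow(a, b) for a, b in merged]


@dataclass
class PatternReport:
    """Result of checking a duplex against a named modification pattern."""

    pattern: str
    passed: bool
    violations: list[str] = field(default_factory=list)

    def __bool__(self) -> bool:
        return self.passed


def validate_modification_pattern(duplex: AnnotatedDuplex, pattern: str) -> PatternReport:
    """Check whether the duplex matches a substrate pattern.

    Patterns: ``unmodified`` (no modifications), ``fully_modified`` (both
    strands of every CpG), ``hemi_modified`` (exactly one strand per CpG),
    ``single`` (exactly one modification in total).  Returns a report; never
    raises on mismatch.
    """
    if pattern not in {"unmodified", "fully_modified", "hemi_modified", "single"}:
        raise ValueError(f"unknown pattern {pattern!r}")
    cpg = find_cpg_sites(duplex.top_strand)
    by_site: dict[int, set[str]] = {p: set() for p in cpg}
    stray: list[Modification] = []
    for mod in duplex.modifications:
        site = mod.position if mod.strand == "top" else mod.position - 1
        if site in by_site:
            by_site[site].add(mod.strand)
        else:
            stray.append(mod)

    violations = [f"modification {m} not at a CpG site" for m in stray]
    if pattern == "unmodified":
        if duplex.modifications:
            violations.append(f"{len(duplex.modifications)} modifications present")
    elif pattern == "single":
        if len(duplex.modifications) != 1:
            violations.append(
                f"expected exactly 1 modification, found {len(duplex.modifications)}"
            )
    elif pattern == "fully_modified":
        for p, strands in by_site.items():
            if "top" not in strands:
                violations.append(f"CpG at {p}: top-strand C unmodified")
            if "bottom" not in strands:
                violations.append(f"CpG at {p}: bottom-strand C (top index {p + 1}) unmodified")
    elif pattern == "hemi_modified":
        for p, strands in by_site.items():
            if len(strands) != 1:
                violations.append(
                    f"CpG at {p}: expected exactly one modified strand, found {len(strands)}"
                )
    return PatternReport(pattern, not violations, violations)


# ---------------------------------------------------------------------------
# file formats: FASTA top strand + tab-separated modification sidecar

def read_duplex_fasta(path: str | Path) -> AnnotatedDuplex:
    """Read the top strand from a single-record FASTA file."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 1:
        raise DuplexValidationError(f"{path}: expected exactly 1 FASTA record, found {len(records)}")
    return AnnotatedDuplex(str(records[0].seq), name=records[0].id)


def read_modifications(path: str | Path) -> list[Modification]:
    """Read a modification sidecar: ``position<TAB>strand<TAB>code``, 1-based,
    ``#`` comment lines ignored."""
    mods = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise DuplexValidationError(f"{path}:{lineno}: expected 3 tab-separated fields")
        pos, strand, code = parts
        mods.append(Modification(int(pos), strand, code))
    return mods


def write_modifications(mods: list[Modification], path: str | Path) -> None:
    lines = ["# position\tstrand\tcode"]
    lines += [f"{m.position}\t{m.strand}\t{m.code}" for m in sorted(mods)]
    Path(path).write_text("\n".join(lines) + "\n")
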