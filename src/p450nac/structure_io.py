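"""Multi-model PDB trajectory I/O, atom selection, and tabular output.

A structural ensemble — MD snapshots or a set of superposable crystal
structures — is represented as a :class:`Trajectory`: a fixed topology
(ordered atom records from the first model) plus one coordinate set per
model, in Å.  Only ATOM/HETATM/MODEL/ENDMDL records are interpreted; the
reader deliberately speaks a minimal, predictable PDB v3.3 dialect and
requires hydrogens to be present explicitly (no hydrogen building).
"""

from __future__ import annotations

import json
import logging
import math
import os
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

logger = logging.getLogger("p450nac")

__all__ = [
    "AtomRecord",
    "Trajectory",
    "AtomSelector",
    "PdbFormatError",
    "SelectorError",
    "AmbiguousSelectorError",
    "read_multimodel_pdb",
    "write_multimodel_pdb",
    "resolve_selector",
    "write_profile_tsv",
    "write_profile_json",
    "write_timeseries_tsv",
    "write_rmsf_tsv",
    "write_ranking_tsv",
    "atomic_write_text",
]


class PdbFormatError(ValueError):
    """Raised when a PDB file violates the supported dialect."""


class SelectorError(LookupError):
    """Raised when an atom selector matches no atom."""


class AmbiguousSelectorError(LookupError):
    """Raised when an atom selector matches more than one atom."""


@dataclass(frozen=True)
class AtomRecord:
    """One atom of the topology.  Coordinates live in Trajectory.frames."""

    serial: int
    name: str
    residue_name: str
    residue_id: int
    chain_id: str
    element: str
    position: tuple[float, float, float]

    def __post_init__(self) -> None:
        if not self.name:
            raise ValueError("atom name must be non-empty")
        if not all(math.isfinite(c) for c in self.position):
            raise ValueError(f"non-finite position for atom {self.name}")


@dataclass
class Trajectory:
    """Ordered topology plus ≥1 coordinate frames (Å), identical atom order."""

    topology: list[AtomRecord]
    frames: np.ndarray  # (n_frames, n_atoms, 3)

    def __post_init__(self) -> None:
        self.frames = np.asarray(self.frames, dtype=float)
        if self.frames.ndim != 3 or self.frames.shape[2] != 3:
            raise ValueError("frames must have shape (n_frames, n_atoms, 3)")
        if self.frames.shape[0] < 1:
            raise ValueError("trajectory must contain at least one frame")
        if self.frames.shape[1] != len(self.topology):
            raise ValueError(
                f"frame atom count {self.frames.shape[1]} != topology size "
                f"{len(self.topology)}"
            )

    @property
    def n_frames(self) -> int:
        return self.frames.shape[0]

    @property
    def n_atoms(self) -> int:
        return len(self.topology)


@dataclass(frozen=True)
class AtomSelector:
    """Criteria identifying a single topology atom; atom_name is mandatory."""

    atom_name: str
    chain_id: str | None = None
    residue_id: int | None = None
    residue_name: str | None = None

    def __post_init__(self) -> None:
        if not self.atom_name:
            raise ValueError("atom_name is required in a selector")

    def matches(self, atom: AtomRecord) -> bool:
        if atom.name != self.atom_name:
            return False
        if self.chain_id is not None and atom.chain_id != self.chain_id:
            return False
        if self.residue_id is not None and atom.residue_id != self.residue_id:
            return False
        if self.residue_name is not None and atom.residue_name != self.residue_name:
            return False
        return True

    def describe(self) -> str:
        parts = [f"name={self.atom_name!r}"]
        if self.chain_id is not None:
            parts.append(f"chain={self.chain_id!r}")
        if self.residue_id is not None:
            parts.append(f"resid={self.residue_id}")
        if self.residue_name is not None:
            parts.append(f"resname={self.residue_name!r}")
        return ", ".join(parts)


# ---------------------------------------------------------------------------
# PDB reading


@dataclass
class _RawAtom:
    serial: int
    name: str
    altloc: str
    residue_name: str
    chain_id: str
    residue_id: int
    xyz: tuple[float, float, float]
    occupancy: float
    element: str
    lineno: int

    @property
    def site_key(self) -> tuple:
        """Identity of the atom irrespective of altloc."""
        return (self.chain_id, self.residue_id, self.residue_name, self.name)


def _parse_atom_line(line: str, lineno: int) -> _RawAtom:
    # PDB v3.3 fixed columns (1-based): serial 7-11, name 13-16, altloc 17,
    # resname 18-20, chain 22, resseq 23-26, x/y/z 31-54, occupancy 55-60,
    # element 77-78.
    line = line.rstrip("\n")
    if len(line) < 54:
        raise PdbFormatError(f"line {lineno}: ATOM/HETATM record too short")
    try:
        serial = int(line[6:11])
    except ValueError:
        raise PdbFormatError(f"line {lineno}: unparseable atom serial") from None
    name = line[12:16].strip()
    altloc = line[16].strip()
    residue_name = line[17:20].strip()
    chain_id = line[21].strip()
    try:
        residue_id = int(line[22:26])
    except ValueError:
        raise PdbFormatError(f"line {lineno}: unparseable residue number") from None
    try:
        xyz = (float(line[30:38]), float(line[38:46]), float(line[46:54]))
    except ValueError:
        raise PdbFormatError(f"line {lineno}: unparseable coordinate field") from None
    if not all(math.isfinite(c) for c in xyz):
        raise PdbFormatError(f"line {lineno}: non-finite coordinate")
    occ_field = line[54:60].strip()
    try:
        occupancy = float(occ_field) if occ_field else 1.0
    except ValueError:
        occupancy = 1.0
    element = line[76:78].strip() if len(line) >= 78 else ""
    if not element:
        # fall back to the leading letter of the atom name
        element = "".join(c for c in name if c.isalpha())[:1].upper()
    return _RawAtom(
        serial, name, altloc, residue_name, chain_id, residue_id, xyz,
        occupancy, element, lineno,
    )


def _resolve_altlocs(atoms: list[_RawAtom]) -> list[_RawAtom]:
    """Keep one location per atom: highest occupancy, ties first-encountered."""
    chosen: dict[tuple, _RawAtom] = {}
    order: list[tuple] = []
    for atom in atoms:
        key = atom.site_key
        if key not in chosen:
            chosen[key] = atom
            order.append(key)
        elif atom.occupancy > chosen[key].occupancy:
            chosen[key] = atom
    return [chosen[key] for key in order]


def read_multimodel_pdb(path: str | os.PathLike) -> Trajectory:
    """Read a multi-model PDB file into a Trajectory (one frame per MODEL).

    The topology is taken from the first model; every later model must contain
    the same atoms in the same order (after altloc resolution).  A file with
    no MODEL records is accepted as a single-frame trajectory.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"no such PDB file: {path}")

    models: list[list[_RawAtom]] = []
    model_labels: list[str] = []
    current: list[_RawAtom] | None = None
    in_model = False
    with open(path, encoding="utf-8") as handle:
        for lineno, line in enumerate(handle, start=1):
            record = line[:6].strip()
            if record == "MODEL":
                if in_model:
                    raise PdbFormatError(
                        f"line {lineno}: nested MODEL record (missing ENDMDL)"
                    )
                in_model = True
                current = []
                label = line[6:].strip() or str(len(models) + 1)
                model_labels.append(label)
            elif record == "ENDMDL":
                if not in_model:
                    raise PdbFormatError(f"line {lineno}: ENDMDL without MODEL")
                models.append(current if current is not None else [])
                current = None
                in_model = False
            elif record in ("ATOM", "HETATM"):
                atom = _parse_atom_line(line, lineno)
                if current is None:
                    # implicit single model (no MODEL/ENDMDL delimiters)
                    current = []
                    model_labels.append("1")
                    in_model = False
                    models.append(current)
                current.append(atom)
            # every other record type is ignored by design

    if in_model:
        raise PdbFormatError(f"model {model_labels[-1]}: missing ENDMDL")
    models = [m for m in models if m]
    if not models:
        raise PdbFormatError(f"{path}: no ATOM/HETATM records found")

    resolved = [_resolve_altlocs(m) for m in models]
    first = resolved[0]
    reference_keys = [a.site_key for a in first]
    for idx, model in enumerate(resolved[1:], start=2):
        label = model_labels[idx - 1] if idx - 1 < len(model_labels) else str(idx)
        if len(model) != len(first):
            raise PdbFormatError(
                f"model {label}: {len(model)} atoms, expected {len(first)}"
            )
        keys = [a.site_key for a in model]
        if keys != reference_keys:
            raise PdbFormatError(
                f"model {label}: atom order differs from first model"
            )

    topology = [
        AtomRecord(
            serial=a.serial,
            name=a.name,
            residue_name=a.residue_name,
            residue_id=a.residue_id,
            chain_id=a.chain_id,
            element=a.element,
            position=a.xyz,
        )
        for a in first
    ]
    frames = np.array(
        [[a.xyz for a in model] for model in resolved], dtype=float
    )
    return Trajectory(topology=topology, frames=frames)


def write_multimodel_pdb(trajectory: Trajectory, path: str | os.PathLike) -> None:
    """Write a Trajectory as a MODEL/ENDMDL-delimited PDB file (3-decimal Å)."""
    lines: list[str] = []
    for f in range(trajectory.n_frames):
        lines.append(f"MODEL     {f + 1:>4d}")
        for atom, xyz in zip(trajectory.topology, trajectory.frames[f]):
            name = atom.name if len(atom.name) == 4 else f" {atom.name:<3s}"
            lines.append(
                f"HETATM{atom.serial:>5d} {name:<4.4s} {atom.residue_name:<3.3s} "
                f"{atom.chain_id or ' '}{atom.residue_id:>4d}    "
                f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}"
                f"{1.00:6.2f}{0.00:6.2f}          {atom.element:>2.2s}"
            )
        lines.append("ENDMDL")
    lines.append("END")
    atomic_write_text(path, "\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Selection


def resolve_selector(trajectory: Trajectory, selector: AtomSelector) -> int:
    """Return the unique 0-based topology index matching the selector.

    Raises SelectorError on zero matches and AmbiguousSelectorError when the
    selector is under-specified and matches several atoms.
    """
    matches = [
        i for i, atom in enumerate(trajectory.topology) if selector.matches(atom)
    ]
    if not matches:
        raise SelectorError(f"no atom matches selector ({selector.describe()})")
    if len(matches) > 1:
        listing = ", ".join(
            f"#{i} {trajectory.topology[i].name}/"
            f"{trajectory.topology[i].residue_name}{trajectory.topology[i].residue_id}"
            for i in matches
        )
        raise AmbiguousSelectorError(
            f"selector ({selector.describe()}) matches {len(matches)} atoms: {listing}"
        )
    return matches[0]


# ---------------------------------------------------------------------------
# Tabular output


def atomic_write_text(path: str | os.PathLike, text: str) -> None:
    """Write text atomically (temp file + rename) so failures leave no partial file."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fd, tmp = tempfile.mkstemp(dir=path.parent, prefix=f".{path.name}.")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="\n") as handle:
            handle.write(text)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def _profile_rows(profile) -> list:
    """Deterministic row order: descending percentage, ties lexicographic."""
    return sorted(
        profile.per_site.items(), key=lambda kv: (-kv[1].percentage, kv[0])
    )


def write_profile_tsv(profile, path: str | os.PathLike, site_map=None) -> None:
    """Serialize an accessibility profile as TSV.

    Columns: site, event_count, percentage (2 decimals), stereo_class (blank
    when no site map is supplied).
    """
    lines = ["site\tevent_count\tpercentage\tstereo_class"]
    for label, stats in _profile_rows(profile):
        stereo = ""
        if site_map is not None and label in site_map.sites:
            stereo = site_map.sites[label].stereo_class
        lines.append(
            f"{label}\t{stats.event_count}\t{stats.percentage:.2f}\t{stereo}"
        )
    atomic_write_text(path, "\n".join(lines) + "\n")


def write_profile_json(profile, path: str | os.PathLike, site_map=None) -> None:
    payload = {
        "per_site": {
            label: {
                "event_count": stats.event_count,
                "percentage": stats.percentage,
                "stereo_class": (
                    site_map.sites[label].stereo_class
                    if site_map is not None and label in site_map.sites
                    else None
                ),
            }
            for label, stats in _profile_rows(profile)
        },
        "total_events": profile.total_events,
        "total_frames": profile.total_frames,
        "frames_with_access": profile.frames_with_access,
        "denominator": profile.denominator,
    }
    atomic_write_text(path, json.dumps(payload, ensure_ascii=False, indent=2) + "\n")


def write_timeseries_tsv(records: Iterable, path: str | os.PathLike) -> None:
    """One row per (frame, site) access event: frame, site, distance, angle."""
    lines = ["frame_index\tsite\tbest_hydrogen\th_oxo_A\th_oxo_fe_deg"]
    for rec in records:
        for event in rec.events:
            lines.append(
                f"{event.frame_index}\t{event.site}\t{event.best_hydrogen}\t"
                f"{event.h_oxo:.3f}\t{event.h_oxo_fe:.2f}"
            )
    atomic_write_text(path, "\n".join(lines) + "\n")


def write_rmsf_tsv(result, path: str | os.PathLike, threshold: float = 1.0) -> None:
    """Per-residue RMSF with a flag column marking residues at or above threshold (Å)."""
    lines = ["chain\tresidue_id\trmsf_A\tflexible"]
    for chain, resid, rmsf in result.entries:
        flag = "yes" if rmsf >= threshold else "no"
        lines.append(f"{chain}\t{resid}\t{rmsf:.3f}\t{flag}")
    atomic_write_text(path, "\n".join(lines) + "\n")


def write_ranking_tsv(ranking, path: str | os.PathLike) -> None:
    lines = ["rank\tsite\taccessibility_pct\tweight\tscore"]
    for rank, entry in enumerate(ranking.entries, start=1):
        lines.append(
            f"{rank}\t{entry.site}\t{entry.accessibility_pct:.2f}\t"
            f"{entry.weight:.6g}\t{entry.score:.6g}"
        )
    atomic_write_text(path, "\n".join(lines) + "\n")
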