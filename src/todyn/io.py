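"""File formats: XYZ geometries, frequency files, Molden subset, manifests.

Formats are deliberately plain text: standard XYZ for Cartesian geometries,
a YAML-based native frequency format for normal-mode data, a read-only
subset of the Molden frequency dialect ([FREQ]/[FR-COORD]/[FR-NORM-COORD]),
and JSON run manifests that record everything needed to reproduce a run.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field

import numpy as np
import yaml

from .constants import ATOMIC_MASSES
from .wigner import NormalModeSet

__all__ = ["CartesianGeometry", "RunManifest", "read_xyz", "write_xyz",
           "read_frequency_file", "write_frequency_file", "read_molden_frequencies"]

#: Bohr→Å, Molden frequency sections are in atomic units.
_BOHR_A = 0.529177210903


@dataclass
class CartesianGeometry:
    """Element symbols with Cartesian coordinates in Å and masses in amu."""

    symbols: list
    coordinates: np.ndarray     # (natom, 3)
    comment: str = ""

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, float).reshape(-1, 3)
        if len(self.symbols) != self.coordinates.shape[0]:
            raise ValueError("one symbol per atom required")
        for s in self.symbols:
            if s not in ATOMIC_MASSES:
                raise ValueError(f"unknown element symbol {s!r}")

    @property
    def masses(self) -> np.ndarray:
        return np.array([ATOMIC_MASSES[s] for s in self.symbols])


def read_xyz(path) -> CartesianGeometry:
    """Read the first frame of a standard XYZ file."""
    with open(path) as fh:
        lines = fh.read().splitlines()
    if not lines:
        raise ValueError(f"{path}: empty file")
    try:
        natom = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ValueError(f"{path}: line 1: expected an atom count")
    if len(lines) < natom + 2:
        raise ValueError(f"{path}: truncated file ({len(lines)} lines, "
                         f"{natom} atoms declared)")
    symbols, coords = [], []
    for i, line in enumerate(lines[2:2 + natom], start=3):
        parts = line.split()
        if len(parts) < 4:
            raise ValueError(f"{path}: line {i}: malformed atom record {line!r}")
        sym = parts[0].capitalize()
        if sym not in ATOMIC_MASSES:
            raise ValueError(f"{path}: line {i}: unknown element {parts[0]!r}")
        try:
            coords.append([float(x) for x in parts[1:4]])
        except ValueError:
            raise ValueError(f"{path}: line {i}: non-numeric coordinate")
        symbols.append(sym)
    return CartesianGeometry(symbols, np.array(coords), comment=lines[1])


def write_xyz(path, geometry: CartesianGeometry, precision: int = 8) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(geometry.symbols)}\n{geometry.comment}\n")
        for s, xyz in zip(geometry.symbols, geometry.coordinates):
            fh.write(f"{s:<3s} " + " ".join(f"{x:.{precision}f}" for x in xyz) + "\n")


def write_frequency_file(path, modes: NormalModeSet) -> None:
    """Write the native YAML frequency format."""
    payload = {
        "schema": "todyn-frequencies/1",
        "coord_names": list(modes.coord_names),
        "reference": modes.reference.tolist(),
        "masses_amu": modes.masses.tolist(),
        "frequencies_cm": modes.frequencies_cm.tolist(),
        "displacements": modes.displacements.tolist(),
    }
    with open(path, "w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=False)


def read_frequency_file(path) -> NormalModeSet:
    """Read the native frequency format; imaginary modes are kept (flagged by
    their negative wavenumber) and rejected later by the Wigner sampler."""
    with open(path) as fh:
        payload = yaml.safe_load(fh)
    schema = str(payload.get("schema", ""))
    if not schema.startswith("todyn-frequencies/1"):
        raise ValueError(f"{path}: unsupported frequency schema {schema!r}")
    return NormalModeSet(
        reference=np.array(payload["reference"], float),
        masses=np.array(payload["masses_amu"], float),
        frequencies_cm=np.array(payload["frequencies_cm"], float),
        displacements=np.array(payload["displacements"], float),
        coord_names=tuple(payload.get("coord_names", ())),
    )


def read_molden_frequencies(path) -> NormalModeSet:
    """Read the [FREQ]/[FR-COORD]/[FR-NORM-COORD] sections of a Molden file.

    Coordinates are Bohr and mode vectors Cartesian displacements; the
    vectors are mass-weighted and re-orthonormalised (Gram–Schmidt via QR on
    the mass-weighted matrix keeps each mode's span while restoring the
    orthonormality the format does not guarantee after truncation).
    """
    sections: dict = {}
    current = None
    with open(path) as fh:
        for raw in fh:
            line = raw.strip()
            if not line:
                continue
            if line.startswith("["):
                current = line.split("]")[0].strip("[").upper()
                sections[current] = []
            elif current is not None:
                sections[current].append(line)
    for need in ("FREQ", "FR-COORD", "FR-NORM-COORD"):
        if need not in sections:
            raise ValueError(f"{path}: missing [{need}] section")
    freqs = np.array([float(x) for x in sections["FREQ"]])
    symbols, coords = [], []
    for line in sections["FR-COORD"]:
        parts = line.split()
        sym = parts[0].capitalize()
        if sym not in ATOMIC_MASSES:
            raise ValueError(f"{path}: unknown element {parts[0]!r} in [FR-COORD]")
        symbols.append(sym)
        coords.append([float(x) * _BOHR_A for x in parts[1:4]])
    natom = len(symbols)
    vec_rows: list = []
    block: list = []
    for line in sections["FR-NORM-COORD"]:
        if line.lower().startswith("vibration"):
            if block:
                vec_rows.append(block)
            block = []
        else:
            block.extend(float(x) * _BOHR_A for x in line.split())
    if block:
        vec_rows.append(block)
    if len(vec_rows) != freqs.size:
        raise ValueError(f"{path}: {freqs.size} frequencies but "
                         f"{len(vec_rows)} vibration blocks")
    disp = np.array(vec_rows, float).T          # (3N, nmode)
    if disp.shape[0] != 3 * natom:
        raise ValueError(f"{path}: mode vectors have {disp.shape[0]} components, "
                         f"expected {3 * natom}")
    masses3 = np.repeat([ATOMIC_MASSES[s] for s in symbols], 3)
    mw = disp * np.sqrt(masses3)[:, None]
    q, r = np.linalg.qr(mw)
    q = q * np.sign(np.diag(r))                 # keep original mode orientation
    return NormalModeSet(
        reference=np.array(coords, float).ravel(),
        masses=masses3,
        frequencies_cm=freqs,
        displacements=q,
        coord_names=tuple(f"{s}{i}_{ax}" for i, s in enumerate(symbols)
                          for ax in "xyz"),
    )


@dataclass
class RunManifest:
    """Reproducibility record written by every pipeline stage."""

    stage: str
    config: dict
    seed: int
    version: str = ""
    input_checksums: dict = field(default_factory=dict)
    trajectory_seeds: list = field(default_factory=list)
    timings_s: dict = field(default_factory=dict)
    defaults_used: dict = field(default_factory=dict)
    created: str = ""

    def add_input(self, path) -> None:
        h = hashlib.sha256()
        with open(path, "rb") as fh:
            h.update(fh.read())
        self.input_checksums[str(path)] = h.hexdigest()

    def write(self, path) -> None:
        from . import __version__

        payload = {
            "schema": "todyn-manifest/1",
            "stage": self.stage,
            "config": self.config,
            "seed": self.seed,
            "version": self.version or __version__,
            "input_checksums": self.input_checksums,
            "trajectory_seeds": self.trajectory_seeds,
            "timings_s": self.timings_s,
            "defaults_used": self.defaults_used,
            "created": self.created or time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, indent=1)

    @classmethod
    def read(cls, path) -> "RunManifest":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("schema") != "todyn-manifest/1":
            raise ValueError("unsupported manifest schema")
        return cls(stage=payload["stage"], config=payload["config"],
                   seed=payload["seed"], version=payload["version"],
                   input_checksums=payload["input_checksums"],
                   trajectory_seeds=payload["trajectory_seeds"],
                   timings_s=payload["timings_s"],
                   defaults_used=payload.get("defaults_used", {}),
                   created=payload["created"])
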