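"""Structure, conformer-frame and experiment-table I/O.

Geometry is always Cartesian and always in Angstrom.  Single structures are
read from XYZ (via MDAnalysis) or SDF V2000 (via rdkit); conformer frame sets
from multi-frame XYZ or an HDF5 container.  Experiment and solvent tables are
plain CSV.

CSV experiment schema (header mandatory, comma separated, UTF-8)::

    racemate_id,agent_id,solvents,solvent_fractions,m_frac,ee[,full_dissolution]

where ``solvents`` is a ``|``-separated list of solvent ids and
``solvent_fractions`` the matching ``|``-separated molar fractions
(must sum to 1 within 1e-6).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .elements import SUPPORTED_ELEMENTS, UnsupportedElementError, canonical_symbol

logger = logging.getLogger(__name__)

__all__ = [
    "Molecule3D",
    "SaltComplex",
    "FrameSet",
    "ExperimentRecord",
    "ParseError",
    "ValidationError",
    "StructuralError",
    "read_structure",
    "write_structure",
    "read_frames",
    "write_frames",
    "load_experiment_table",
    "write_experiment_table",
    "load_solvent_table",
    "max_possible_ee",
    "validate_record",
    "filter_records",
]


class ParseError(ValueError):
    """A file could not be parsed."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


class StructuralError(ValueError):
    """Frames or complexes are structurally inconsistent."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class Molecule3D:
    """A molecule as element symbols plus N x 3 Cartesian coordinates (Angstrom)."""

    elements: list[str]
    coords: np.ndarray
    role: str = "substrate"  # 'substrate' | 'resolving_agent'
    atom_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.elements = [canonical_symbol(e) for e in self.elements]
        for e in self.elements:
            if e not in SUPPORTED_ELEMENTS:
                raise UnsupportedElementError(
                    f"element {e!r} is not in the supported set"
                )
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValidationError("coords must be an N x 3 array")
        if len(self.elements) != len(self.coords):
            raise ValidationError("elements and coords length mismatch")
        if len(self.elements) < 1:
            raise ValidationError("molecule must contain at least one atom")
        if not np.all(np.isfinite(self.coords)):
            raise ValidationError("coordinates must be finite")
        if self.role not in ("substrate", "resolving_agent"):
            raise ValidationError(f"unknown role {self.role!r}")
        if not self.atom_ids:
            self.atom_ids = [f"{self.role[:3]}{i}" for i in range(len(self.elements))]
        if len(self.atom_ids) != len(self.elements):
            raise ValidationError("atom_ids length mismatch")

    @property
    def n_atoms(self) -> int:
        return len(self.elements)

    def with_coords(self, coords: np.ndarray) -> "Molecule3D":
        return Molecule3D(list(self.elements), coords, self.role, list(self.atom_ids))


@dataclass
class SaltComplex:
    """An acid-base complex: one substrate enantiomer posed against a resolving agent."""

    substrate: Molecule3D
    agent: Molecule3D
    handedness: str  # 'R' | 'S' of the substrate enantiomer

    def __post_init__(self) -> None:
        if self.handedness not in ("R", "S"):
            raise ValidationError(f"handedness must be 'R' or 'S', got {self.handedness!r}")
        ids = self.substrate.atom_ids + self.agent.atom_ids
        if len(set(ids)) != len(ids):
            raise ValidationError("atom identifiers must be unique across the complex")

    @property
    def elements(self) -> list[str]:
        return self.substrate.elements + self.agent.elements

    @property
    def coords(self) -> np.ndarray:
        return np.vstack([self.substrate.coords, self.agent.coords])

    @property
    def atom_ids(self) -> list[str]:
        return self.substrate.atom_ids + self.agent.atom_ids

    @property
    def n_atoms(self) -> int:
        return self.substrate.n_atoms + self.agent.n_atoms

    @property
    def n_substrate(self) -> int:
        return self.substrate.n_atoms

    def with_coords(self, coords: np.ndarray) -> "SaltComplex":
        coords = np.asarray(coords, dtype=float)
        ns = self.substrate.n_atoms
        return SaltComplex(
            self.substrate.with_coords(coords[:ns]),
            self.agent.with_coords(coords[ns:]),
            self.handedness,
        )


@dataclass
class FrameSet:
    """Conformer frames for one complex; all frames share the template's atoms."""

    complex_template: SaltComplex
    frames: list[np.ndarray]

    def __post_init__(self) -> None:
        n = self.complex_template.n_atoms
        self.frames = [np.asarray(f, dtype=float) for f in self.frames]
        for k, f in enumerate(self.frames):
            if f.shape != (n, 3):
                raise StructuralError(
                    f"frame {k} has shape {f.shape}, expected ({n}, 3)"
                )
        if len(self.frames) < 2:
            raise StructuralError(
                "a frame set needs at least 2 frames (standard deviation undefined)"
            )

    @property
    def frame_count(self) -> int:
        return len(self.frames)


@dataclass
class ExperimentRecord:
    """One resolution experiment: who, in what solvent, with what outcome."""

    racemate_id: str
    agent_id: str
    solvent_components: list[tuple[str, float]]
    m_frac: float
    ee: float
    full_dissolution: bool | None = None
    ee_imputed: bool = False  # provenance: ee forced to 0 because no solid formed

    def __post_init__(self) -> None:
        fracs = np.array([f for _, f in self.solvent_components], dtype=float)
        if len(fracs) == 0:
            raise ValidationError("at least one solvent component required")
        if np.any(fracs <= 0):
            raise ValidationError("solvent molar fractions must be positive")
        if abs(fracs.sum() - 1.0) > 1e-6:
            raise ValidationError(
                f"solvent molar fractions must sum to 1, got {fracs.sum():.6f}"
            )
        if self.m_frac == 0.0 and self.ee != 0.0:
            # no solid: enantiomeric excess undefined, stored as 0 by convention
            self.ee = 0.0
            self.ee_imputed = True
        for name, val in (("m_frac", self.m_frac), ("ee", self.ee)):
            if not 0.0 <= val <= 1.0:
                raise ValidationError(f"{name} must lie in [0, 1], got {val}")


# ---------------------------------------------------------------------------
# structure I/O
# ---------------------------------------------------------------------------

def _read_xyz_structure(path: Path) -> tuple[list[str], np.ndarray]:
    # Light pre-validation so parse errors carry a line number, then delegate
    # coordinate handling to MDAnalysis.
    lines = path.read_text().splitlines()
    if not lines:
        raise ParseError(f"{path}: line 1: empty XYZ file")
    try:
        n = int(lines[0].split()[0])
    except (ValueError, IndexError):
        raise ParseError(f"{path}: line 1: expected an atom count") from None
    if len(lines) < n + 2:
        raise ParseError(
            f"{path}: line {len(lines)}: truncated XYZ block (expected {n} atoms)"
        )
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path), format="XYZ")
        elements = [str(nm) for nm in u.atoms.names]
        coords = np.asarray(u.atoms.positions, dtype=float)
    return elements, coords


def _read_sdf_structure(path: Path) -> tuple[list[str], np.ndarray]:
    from rdkit import Chem

    supplier = Chem.SDMolSupplier(str(path), removeHs=False, sanitize=False)
    mol = next(iter(supplier), None)
    if mol is None:
        raise ParseError(f"{path}: line 4: unreadable SDF molecule block")
    conf = mol.GetConformer()
    elements = [atom.GetSymbol() for atom in mol.GetAtoms()]
    coords = np.array(
        [[conf.GetAtomPosition(i).x, conf.GetAtomPosition(i).y, conf.GetAtomPosition(i).z]
         for i in range(mol.GetNumAtoms())],
        dtype=float,
    )
    return elements, coords


def read_structure(path: str | Path, fmt: str | None = None,
                   role: str = "substrate") -> Molecule3D:
    """Read a single 3D structure from XYZ or SDF (V2000).

    ``fmt`` defaults to the file extension.  Element symbols are canonicalised;
    unknown elements raise :class:`UnsupportedElementError`.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = (fmt or path.suffix.lstrip(".")).lower()
    if fmt == "xyz":
        elements, coords = _read_xyz_structure(path)
    elif fmt in ("sdf", "mol"):
        elements, coords = _read_sdf_structure(path)
    else:
        raise ValueError(f"unsupported structure format {fmt!r}")
    return Molecule3D(elements, coords, role=role)


def write_structure(mol: Molecule3D, path: str | Path) -> None:
    """Write a structure as plain XYZ (float32-exact coordinate text)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"{mol.n_atoms}\n")
        fh.write("written by chirsep\n")
        for el, (x, y, z) in zip(mol.elements, mol.coords):
            fh.write(f"{el} {x:.9e} {y:.9e} {z:.9e}\n")


def read_frames(path: str | Path, template: SaltComplex | None = None) -> FrameSet:
    """Read a conformer frame set.

    ``.xyz`` files are multi-frame XYZ (read through MDAnalysis, float32
    precision); ``.h5``/``.hdf5`` files are the package's HDF5 container,
    which round-trips coordinates bitwise.  A template complex must be given
    for XYZ input (XYZ stores no substrate/agent split); the HDF5 container
    stores the split and element symbols itself.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        return _read_frames_h5(path)
    if template is None:
        raise ValueError("a template SaltComplex is required for XYZ frame input")
    import MDAnalysis as mda

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        u = mda.Universe(str(path), format="XYZ")
        if u.atoms.n_atoms != template.n_atoms:
            raise StructuralError(
                f"frame atom count {u.atoms.n_atoms} does not match template "
                f"({template.n_atoms})"
            )
        frames = [np.asarray(ts.positions, dtype=float) for ts in u.trajectory]
    return FrameSet(template, frames)


def write_frames(frames: FrameSet, path: str | Path) -> None:
    """Write a frame set: multi-frame XYZ for ``.xyz``, HDF5 container otherwise."""
    path = Path(path)
    if path.suffix.lower() in (".h5", ".hdf5"):
        _write_frames_h5(frames, path)
        return
    elements = frames.complex_template.elements
    with path.open("w") as fh:
        for f in frames.frames:
            fh.write(f"{len(elements)}\n")
            fh.write("frame\n")
            for el, (x, y, z) in zip(elements, f):
                fh.write(f"{el} {x:.9e} {y:.9e} {z:.9e}\n")


def _write_frames_h5(frames: FrameSet, path: Path) -> None:
    import h5py

    tpl = frames.complex_template
    with h5py.File(path, "w") as h5:
        h5.create_dataset("frames", data=np.stack(frames.frames))
        h5.attrs["n_substrate"] = tpl.n_substrate
        h5.attrs["handedness"] = tpl.handedness
        h5.create_dataset("elements", data=np.array(tpl.elements, dtype="S4"))
        h5.create_dataset("atom_ids", data=np.array(tpl.atom_ids, dtype="S16"))


def _read_frames_h5(path: Path) -> FrameSet:
    import h5py

    with h5py.File(path, "r") as h5:
        data = np.asarray(h5["frames"], dtype=float)
        ns = int(h5.attrs["n_substrate"])
        handedness = str(h5.attrs["handedness"])
        elements = [e.decode() for e in h5["elements"][...]]
        atom_ids = [a.decode() for a in h5["atom_ids"][...]]
    sub = Molecule3D(elements[:ns], data[0, :ns], "substrate", atom_ids[:ns])
    agt = Molecule3D(elements[ns:], data[0, ns:], "resolving_agent", atom_ids[ns:])
    tpl = SaltComplex(sub, agt, handedness)
    return FrameSet(tpl, [data[k] for k in range(data.shape[0])])


# ---------------------------------------------------------------------------
# experiment / solvent tables
# ---------------------------------------------------------------------------

def load_experiment_table(path: str | Path) -> list[ExperimentRecord]:
    """Load resolution experiments from CSV (schema in the module docstring)."""
    path = Path(path)
    df = pd.read_csv(path)
    if df.empty:
        logger.warning("experiment table %s is empty", path)
        return []
    required = {"racemate_id", "agent_id", "solvents", "solvent_fractions",
                "m_frac", "ee"}
    missing = required - set(df.columns)
    if missing:
        raise ParseError(f"{path}: missing columns {sorted(missing)}")
    records = []
    for idx, row in df.iterrows():
        ids = str(row["solvents"]).split("|")
        fracs = [float(f) for f in str(row["solvent_fractions"]).split("|")]
        if len(ids) != len(fracs):
            raise ValidationError(f"{path}: row {idx}: solvent id/fraction mismatch")
        fd = None
        if "full_dissolution" in df.columns and not pd.isna(row["full_dissolution"]):
            fd = bool(row["full_dissolution"])
        try:
            rec = ExperimentRecord(
                racemate_id=str(row["racemate_id"]),
                agent_id=str(row["agent_id"]),
                solvent_components=list(zip(ids, fracs)),
                m_frac=float(row["m_frac"]),
                ee=float(row["ee"]),
                full_dissolution=fd,
            )
        except ValidationError as exc:
            raise ValidationError(f"{path}: row {idx}: {exc}") from None
        records.append(rec)
    return records


def write_experiment_table(records: list[ExperimentRecord], path: str | Path) -> None:
    rows = []
    for r in records:
        rows.append({
            "racemate_id": r.racemate_id,
            "agent_id": r.agent_id,
            "solvents": "|".join(s for s, _ in r.solvent_components),
            "solvent_fractions": "|".join(repr(f) for _, f in r.solvent_components),
            "m_frac": r.m_frac,
            "ee": r.ee,
            "full_dissolution": r.full_dissolution,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def load_solvent_table(path: str | Path) -> pd.DataFrame:
    """Load solvent descriptors: one row per solvent id, numeric columns.

    Returns a DataFrame indexed by ``solvent_id``; all descriptor columns must
    be finite.
    """
    df = pd.read_csv(path)
    if "solvent_id" not in df.columns:
        raise ParseError(f"{path}: missing 'solvent_id' column")
    df = df.set_index("solvent_id")
    values = df.to_numpy(dtype=float)
    if not np.all(np.isfinite(values)):
        raise ValidationError(f"{path}: non-finite solvent descriptors")
    return df


# ---------------------------------------------------------------------------
# physical-consistency filter
# ---------------------------------------------------------------------------

def max_possible_ee(m_frac: float) -> float:
    """Largest enantiomeric excess attainable at a given solid mass fraction.

    Assumes a racemic 50:50 feed: below half the mass crystallised the solid
    can be enantiopure (max ee 1); above, the minor enantiomer must start
    appearing, giving (1 - m_frac) / m_frac.
    """
    if m_frac <= 0.5:
        return 1.0
    return (1.0 - m_frac) / m_frac


def validate_record(record: ExperimentRecord,
                    tolerance: float = 0.05) -> tuple[bool, str]:
    """Keep a record iff its ee is physically consistent with its m_frac.

    Records within ``tolerance`` (default 5%) above the maximum-possible-ee
    line are kept to allow for experimental error.
    Returns ``(keep, reason)``.
    """
    bound = max_possible_ee(record.m_frac)
    if record.ee <= bound + tolerance:
        return True, "consistent"
    return False, (
        f"ee {record.ee:.3f} exceeds max possible {bound:.3f} "
        f"(+{tolerance:.2f} band) at m_frac {record.m_frac:.3f}"
    )


def filter_records(records: list[ExperimentRecord],
                   tolerance: float = 0.05
                   ) -> tuple[list[ExperimentRecord], list[ExperimentRecord]]:
    """Apply :func:`validate_record` to a list; log kept/discarded counts."""
    kept, discarded = [], []
    for r in records:
        (kept if validate_record(r, tolerance)[0] else discarded).append(r)
    logger.info("physical-consistency filter: kept %d, discarded %d",
                len(kept), len(discarded))
    return kept, discarded
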