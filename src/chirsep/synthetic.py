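"""Synthetic inputs: toy chiral complexes, conformer ensembles and labelled
screening grids with a planted, recoverable signal.

The geometry generator builds tetrahedral stereocentres with four distinct
substituent fragments.  The S substrate is the exact mirror (x -> -x) of the
R substrate, posed against the same resolving-agent geometry, so the R and S
complexes are exact mirror images when the agent is achiral (all agent atoms
in the x = 0 plane) and genuinely diastereomeric when the agent is chiral.

Conformer ensembles stand in for molecular-dynamics snapshots: seeded
Gaussian jitter plus a small rigid agent re-orientation, with the minimum
intermolecular distance held inside a contact band.  The emulated MD protocol
(500 K warm-up over 2.5 ps at 0.25 fs, sampling every 5 ps at 0.5 fs,
Langevin thermostat, 200 snapshots, 2 Angstrom initial contact) is carried
verbatim as metadata so a real dynamics backend can be slotted in behind the
same FrameSet interface.

The screening-grid generator plants a logistic signal in compressed
diff-stream space, so recovering it exercises the entire pipeline
(featurise -> compress -> pair -> model) by construction.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.spatial.transform import Rotation

from .atom_density import featurize_frameset
from .electronic_weights import SurrogateProvider
from .structures_io import ExperimentRecord, FrameSet, Molecule3D, SaltComplex

logger = logging.getLogger(__name__)

#: substituent fragments: chains of (element, bond length to previous atom)
FRAGMENTS: dict[str, list[tuple[str, float]]] = {
    "H":    [("H", 1.09)],
    "F":    [("F", 1.35)],
    "Cl":   [("Cl", 1.77)],
    "Br":   [("Br", 1.94)],
    "OH":   [("O", 1.43), ("H", 0.96)],
    "NH2":  [("N", 1.47), ("H", 1.01)],
    "SH":   [("S", 1.81), ("H", 1.34)],
    "CH3":  [("C", 1.53), ("H", 1.09)],
    "CN":   [("C", 1.46), ("N", 1.16)],
    "CF":   [("C", 1.53), ("F", 1.35)],
    "COH":  [("C", 1.53), ("O", 1.43), ("H", 0.96)],
    "CCl":  [("C", 1.53), ("Cl", 1.77)],
    "CNC":  [("C", 1.53), ("N", 1.47), ("C", 1.47)],
    "COC":  [("C", 1.53), ("O", 1.43), ("C", 1.43)],
    "CSH":  [("C", 1.53), ("S", 1.81), ("H", 1.34)],
}

_TETRAHEDRAL = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                        dtype=float) / np.sqrt(3.0)
MIRROR = np.diag([-1.0, 1.0, 1.0])


@dataclass(frozen=True)
class ToyChiralSpec:
    """A stereocentre element plus four pairwise-distinct substituent fragments."""

    centre: str = "C"
    substituents: tuple[str, str, str, str] = ("OH", "CH3", "Cl", "COH")

    def __post_init__(self) -> None:
        if len(set(self.substituents)) != 4:
            raise ValueError("the four substituents must be pairwise distinct "
                             "(otherwise the centre is not a stereocentre)")
        for s in self.substituents:
            if s not in FRAGMENTS:
                raise ValueError(f"unknown fragment {s!r}")


@dataclass(frozen=True)
class TrajectoryProtocol:
    """The emulated dynamics protocol, stored verbatim as metadata."""

    initial_separation: float = 2.0      # Angstrom
    restraint: str = "square-well"
    warm_temperature: float = 500.0      # K
    warm_time: float = 2.5               # ps
    warm_timestep: float = 0.25          # fs
    sampling_interval: float = 5.0       # ps
    sampling_timestep: float = 0.5       # fs
    thermostat: str = "Langevin"
    n_snapshots: int = 200


@dataclass
class PlantedSignalConfig:
    """Logistic hit model planted in compressed diff-stream space."""

    base_rate: float = 0.03          # target overall hit rate
    slope: float = 2.0               # logistic slope on the standardised score
    label_noise: float = 0.01        # probability of flipping a drawn label
    low_noise_nonhit_frac: float = 0.45  # non-hits that still form solid
    solvent_coef: float = 0.3        # relative solvent contribution to the score

    def __post_init__(self) -> None:
        if not 0 < self.base_rate < 0.5:
            raise ValueError("base rate must lie in (0, 0.5)")
        if self.label_noise >= self.base_rate:
            raise ValueError("label noise must stay below the base rate, "
                             "otherwise flips dominate the planted signal")


# ---------------------------------------------------------------------------
# geometry construction
# ---------------------------------------------------------------------------

def _perpendicular(u: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0]) if abs(u[2]) < 0.9 else np.array([0.0, 1.0, 0.0])
    v = np.cross(u, ref)
    return v / np.linalg.norm(v)


def _build_fragment(origin: np.ndarray, direction: np.ndarray,
                    fragment: list[tuple[str, float]]
                    ) -> tuple[list[str], np.ndarray]:
    """Place a fragment chain along ``direction`` with a fixed 35-degree kink."""
    elements, coords = [], []
    pos = origin.copy()
    u = direction / np.linalg.norm(direction)
    for k, (el, bond) in enumerate(fragment):
        if k > 0:  # kink successive bonds so chains are not collinear
            axis = _perpendicular(u)
            u = Rotation.from_rotvec(axis * np.deg2rad(35.0)).apply(u)
        pos = pos + bond * u
        elements.append(el)
        coords.append(pos.copy())
    return elements, np.array(coords)


def build_substrate(spec: ToyChiralSpec) -> Molecule3D:
    """Tetrahedral stereocentre with the spec's four fragments (R geometry)."""
    elements = [spec.centre]
    coords = [np.zeros(3)]
    for frag_name, direction in zip(spec.substituents, _TETRAHEDRAL):
        els, xyz = _build_fragment(np.zeros(3), direction, FRAGMENTS[frag_name])
        elements.extend(els)
        coords.extend(xyz)
    return Molecule3D(elements, np.array(coords), role="substrate",
                      atom_ids=[f"sub{i}" for i in range(len(elements))])


def build_agent(spec: ToyChiralSpec | None = None,
                achiral: bool = False) -> Molecule3D:
    """A resolving agent: chiral tetrahedral by default, or a planar achiral one.

    The achiral agent lies entirely in the x = 0 plane, so it is invariant
    under the x -> -x mirror used to build the S substrate.
    """
    if achiral:
        # planar carboxylate-like fragment in the x = 0 plane
        elements = ["C", "O", "O", "C", "H", "H"]
        coords = np.array([
            [0.0, 0.00, 0.00],
            [0.0, 1.10, 0.60],
            [0.0, -1.10, 0.60],
            [0.0, 0.00, -1.52],
            [0.0, 0.93, -2.10],
            [0.0, -0.93, -2.10],
        ])
    else:
        spec = spec or ToyChiralSpec(substituents=("NH2", "COH", "CH3", "SH"))
        base = build_substrate(spec)
        elements, coords = base.elements, base.coords
    return Molecule3D(list(elements), np.array(coords), role="resolving_agent",
                      atom_ids=[f"agt{i}" for i in range(len(elements))])


def mirror_molecule(mol: Molecule3D) -> Molecule3D:
    """Reflect through the x = 0 plane (an involution)."""
    return mol.with_coords(mol.coords @ MIRROR.T)


def _min_intermolecular(sub_coords: np.ndarray, agent_coords: np.ndarray) -> float:
    return float(cdist(sub_coords, agent_coords).min())


def _pose_substrate(sub: Molecule3D, agent: Molecule3D,
                    contact: float) -> Molecule3D:
    """Translate the substrate along +x until its closest agent contact is
    ``contact`` Angstrom (bisection on the monotone far side)."""
    base = sub.coords - sub.coords.mean(axis=0)
    span = np.abs(base[:, 0]).max() + np.abs(agent.coords[:, 0]).max()
    lo, hi = 0.0, span + contact + 10.0
    for _ in range(60):
        mid = 0.5 * (lo + hi)
        d = _min_intermolecular(base + [mid, 0.0, 0.0], agent.coords)
        if d < contact:
            lo = mid
        else:
            hi = mid
    return sub.with_coords(base + [hi, 0.0, 0.0])


def make_chiral_complex(spec: ToyChiralSpec,
                        agent: Molecule3D | None = None,
                        seed: int = 0, contact: float = 2.0,
                        min_separation: float = 0.8,
                        max_retries: int = 20
                        ) -> tuple[SaltComplex, SaltComplex]:
    """Build the (R-complex, S-complex) diastereomer pair.

    The S substrate is the exact x -> -x mirror of the R substrate; the agent
    geometry is shared and the atom ordering is identical across the pair.
    If the mirrored pose collides with the agent (closest approach below
    ``min_separation``), the substrate is rotated about the x axis (which
    commutes with the mirror, preserving exactness) and re-posed.
    """
    agent = agent if agent is not None else build_agent(achiral=False)
    rng = np.random.default_rng(seed)
    sub0 = build_substrate(spec)
    for attempt in range(max_retries):
        if attempt == 0:
            sub = sub0
        else:
            rot = Rotation.from_rotvec([rng.uniform(0, 2 * np.pi), 0, 0])
            sub = sub0.with_coords(rot.apply(sub0.coords))
        posed = _pose_substrate(sub, agent, contact)
        mirrored = mirror_molecule(posed)
        ok_r = _min_intermolecular(posed.coords, agent.coords) >= min_separation
        ok_s = _min_intermolecular(mirrored.coords, agent.coords) >= min_separation
        if ok_r and ok_s:
            return (SaltComplex(posed, agent, "R"),
                    SaltComplex(mirrored, agent, "S"))
    raise RuntimeError(
        f"steric collision below {min_separation} Angstrom persisted after "
        f"{max_retries} substrate re-orientations")


# ---------------------------------------------------------------------------
# conformer ensembles
# ---------------------------------------------------------------------------

def _band_correct(coords: np.ndarray, n_sub: int,
                  band: tuple[float, float], max_iter: int = 12) -> np.ndarray:
    """Translate the substrate rigidly so the closest intermolecular contact
    stays inside ``band``.

    The shift is along the current closest-pair direction, iterated because a
    translation can change which pair is closest.  The rule is a deterministic
    function of the geometry, so it commutes with mirror reflection and keeps
    mirror-consistent frame pairs exactly mirrored.
    """
    coords = coords.copy()
    for _ in range(max_iter):
        d_mat = cdist(coords[:n_sub], coords[n_sub:])
        i, j = np.unravel_index(np.argmin(d_mat), d_mat.shape)
        d = d_mat[i, j]
        if band[0] <= d <= band[1]:
            break
        u = coords[i] - coords[n_sub + j]
        u = u / np.linalg.norm(u)
        target = band[0] if d < band[0] else band[1]
        coords[:n_sub] += (target - d) * u
    return coords


def _frame_ops(n_frames: int, n_atoms: int, n_agent: int, amplitude: float,
               rot_amplitude: float, rng) -> list[dict]:
    ops = []
    for _ in range(n_frames):
        axis = rng.normal(size=3)
        axis /= np.linalg.norm(axis)
        ops.append({
            "delta": rng.normal(scale=amplitude, size=(n_atoms, 3))
            if amplitude > 0 else np.zeros((n_atoms, 3)),
            "rotvec": axis * rng.normal(scale=rot_amplitude),
        })
    return ops


def _apply_ops(cplx: SaltComplex, ops: list[dict], band: tuple[float, float],
               mirrored: bool) -> list[np.ndarray]:
    n_sub = cplx.n_substrate
    frames = []
    for op in ops:
        delta, rotvec = op["delta"], op["rotvec"]
        if mirrored:
            delta = delta @ MIRROR.T
            rotvec = MIRROR @ -rotvec  # conjugated rotation: M R M
        coords = cplx.coords + delta
        agent = coords[n_sub:]
        centroid = agent.mean(axis=0)
        coords[n_sub:] = Rotation.from_rotvec(rotvec).apply(agent - centroid) + centroid
        frames.append(_band_correct(coords, n_sub, band))
    return frames


def jitter_ensemble(cplx: SaltComplex, n_frames: int = 16,
                    amplitude: float = 0.05, seed: int = 0,
                    band: tuple[float, float] = (1.6, 4.5),
                    rot_amplitude: float = 0.15) -> FrameSet:
    """Seeded Gaussian jitter + rigid agent rattle standing in for MD frames."""
    if amplitude < 0:
        raise ValueError("amplitude must be non-negative")
    rng = np.random.default_rng(seed)
    ops = _frame_ops(n_frames, cplx.n_atoms, cplx.agent.n_atoms,
                     amplitude, rot_amplitude if amplitude > 0 else 0.0, rng)
    return FrameSet(cplx, _apply_ops(cplx, ops, band, mirrored=False))


def jitter_pair(cplx_r: SaltComplex, cplx_s: SaltComplex, n_frames: int = 16,
                amplitude: float = 0.05, seed: int = 0,
                band: tuple[float, float] = (1.6, 4.5),
                rot_amplitude: float = 0.15) -> tuple[FrameSet, FrameSet]:
    """Mirror-consistent ensembles for a diastereomer pair.

    One set of random operations is drawn; the S member receives the x -> -x
    mirrored operations.  When the agent is achiral (mirror-invariant) every
    S frame is then the exact mirror image of the matching R frame, so the
    two trajectory representations coincide exactly -- the property that makes
    the diff stream vanish for achiral agents.
    """
    rng = np.random.default_rng(seed)
    ops = _frame_ops(n_frames, cplx_r.n_atoms, cplx_r.agent.n_atoms,
                     amplitude, rot_amplitude if amplitude > 0 else 0.0, rng)
    return (FrameSet(cplx_r, _apply_ops(cplx_r, ops, band, mirrored=False)),
            FrameSet(cplx_s, _apply_ops(cplx_s, ops, band, mirrored=True)))


# ---------------------------------------------------------------------------
# labelled screening grids
# ---------------------------------------------------------------------------

@dataclass
class SyntheticDataset:
    """A full racemate x agent x solvent screening grid with planted signal."""

    records: list[ExperimentRecord]
    complexes: dict[tuple[str, str], tuple[SaltComplex, SaltComplex]]
    framesets: dict[tuple[str, str], tuple[FrameSet, FrameSet]]
    reps: dict[tuple[str, str], tuple]  # (TrajectoryRep R, TrajectoryRep S)
    solvent_table: pd.DataFrame
    truth: dict = field(default_factory=dict)
    protocol: TrajectoryProtocol = field(default_factory=TrajectoryProtocol)


def _random_specs(n: int, rng, reserved: set[tuple[str, ...]]) -> list[ToyChiralSpec]:
    names = sorted(FRAGMENTS)
    specs = []
    while len(specs) < n:
        subs = tuple(names[i] for i in rng.choice(len(names), size=4, replace=False))
        if subs in reserved:
            continue
        reserved.add(subs)
        specs.append(ToyChiralSpec(substituents=subs))
    return specs


def _draw_outcome(hit: bool, signal: PlantedSignalConfig, rng
                  ) -> tuple[float, float, bool]:
    """(m_frac, ee, full_dissolution) consistent with the drawn label."""
    if hit:
        m_frac = rng.uniform(0.22, 0.50)
        ee = rng.uniform(0.30, 0.95)
        full = bool(rng.random() < 0.8)
    elif rng.random() < signal.low_noise_nonhit_frac:
        m_frac = rng.uniform(0.20, 0.55)
        ee = rng.uniform(0.0, 0.22)
        full = bool(rng.random() < 0.5)
    else:
        m_frac = rng.uniform(0.01, 0.19)
        ee = rng.uniform(0.0, 1.0)
        full = bool(rng.random() < 0.5)
    return m_frac, ee, full


def generate_dataset(n_racemates: int = 30, n_agents: int = 20,
                     n_solvents: int = 2,
                     signal: PlantedSignalConfig | None = None,
                     seed: int = 0, n_frames: int = 16,
                     amplitude: float = 0.05,
                     n_solvent_descriptors: int = 8) -> SyntheticDataset:
    """Generate the full grid: structures, frames, representations and labels.

    The hit probability for a (racemate, agent, solvent) cell is a logistic
    function of the mean compressed diff-stream vector of that diastereomer
    pair (plus a small solvent term); the intercept is calibrated by bisection
    so the expected hit rate matches ``signal.base_rate``.
    """
    if n_racemates < 5:
        raise ValueError("need at least 5 racemates")
    signal = signal or PlantedSignalConfig()
    rng = np.random.default_rng(seed)
    reserved: set[tuple[str, ...]] = set()
    rac_specs = _random_specs(n_racemates, rng, reserved)
    agent_specs = _random_specs(n_agents, rng, reserved)
    agents = {f"A{k:03d}": build_agent(spec) for k, spec in enumerate(agent_specs)}
    racemates = {f"R{k:03d}": spec for k, spec in enumerate(rac_specs)}

    provider = SurrogateProvider()
    complexes, framesets, reps = {}, {}, {}
    for rid, spec in racemates.items():
        for aid, agent in agents.items():
            pair_seed = int(rng.integers(2 ** 31))
            cr, cs = make_chiral_complex(spec, agent=agent, seed=pair_seed)
            fr, fs = jitter_pair(cr, cs, n_frames=n_frames,
                                 amplitude=amplitude, seed=pair_seed + 1)
            key = (rid, aid)
            complexes[key] = (cr, cs)
            framesets[key] = (fr, fs)
            reps[key] = (featurize_frameset(fr, provider, dtype=np.float32),
                         featurize_frameset(fs, provider, dtype=np.float32))

    # solvent descriptor table; the first column feeds the planted signal
    solvent_ids = [f"S{k}" for k in range(n_solvents)]
    solvent_table = pd.DataFrame(
        rng.normal(size=(n_solvents, n_solvent_descriptors)),
        index=pd.Index(solvent_ids, name="solvent_id"),
        columns=[f"desc{k}" for k in range(n_solvent_descriptors)])

    # generator-internal compression defines the planted diff-space signal
    from .pair_assembly import PCACompressor

    keys = sorted(reps)
    atom_stack = np.vstack([np.vstack([reps[k][0].values, reps[k][1].values])
                            for k in keys]).astype(float)
    oracle = PCACompressor(latent_dim=20, seed=seed).fit(atom_stack)
    diff_by_pair = {}
    for k in keys:
        z_r = oracle.encode(np.asarray(reps[k][0].values, dtype=float))
        z_s = oracle.encode(np.asarray(reps[k][1].values, dtype=float))
        diff_by_pair[k] = np.abs(z_r - z_s).mean(axis=0)

    w = rng.normal(size=20)
    if np.allclose(w, 0):
        raise ValueError("degenerate planted signal direction")
    w /= np.linalg.norm(w)
    raw = np.array([w @ diff_by_pair[k] for k in keys])
    raw_std = raw.std()
    if raw_std == 0:
        raise ValueError("planted signal is degenerate: zero variance in diff space")
    raw = (raw - raw.mean()) / raw_std
    score_by_pair = dict(zip(keys, raw))
    solv_raw = solvent_table["desc0"].to_numpy()
    solv_score = (solv_raw - solv_raw.mean()) / (solv_raw.std() or 1.0)
    solv_by_id = dict(zip(solvent_ids, solv_score))

    cells = [(rid, aid, sid) for rid in racemates for aid in agents
             for sid in solvent_ids]
    s_vals = np.array([score_by_pair[(rid, aid)]
                       + signal.solvent_coef * solv_by_id[sid]
                       for rid, aid, sid in cells])

    # calibrate the intercept so the expected post-noise hit rate matches the
    # target: a label drawn from p survives the flip channel with rate
    # p (1 - noise) + (1 - p) noise
    nz = signal.label_noise
    target_mean_p = (signal.base_rate - nz) / (1.0 - 2.0 * nz)

    def mean_rate(intercept: float) -> float:
        return float((1.0 / (1.0 + np.exp(-(signal.slope * s_vals + intercept)))).mean())

    lo, hi = -30.0, 30.0
    for _ in range(80):
        mid = 0.5 * (lo + hi)
        if mean_rate(mid) < target_mean_p:
            lo = mid
        else:
            hi = mid
    b = 0.5 * (lo + hi)
    p_cells = 1.0 / (1.0 + np.exp(-(signal.slope * s_vals + b)))

    records = []
    label_rng = np.random.default_rng(seed + 1)
    for (rid, aid, sid), p in zip(cells, p_cells):
        hit = bool(label_rng.random() < p)
        if label_rng.random() < signal.label_noise:
            hit = not hit
        m_frac, ee, full = _draw_outcome(hit, signal, label_rng)
        records.append(ExperimentRecord(
            racemate_id=rid, agent_id=aid, solvent_components=[(sid, 1.0)],
            m_frac=m_frac, ee=ee, full_dissolution=full))

    realised = float(np.mean([r.m_frac > 0.20 and r.ee > 0.25 for r in records]))
    if not (0.7 * signal.base_rate <= realised <= 1.3 * signal.base_rate):
        logger.warning("realised base rate %.4f outside +/-30%% of target %.4f",
                       realised, signal.base_rate)

    return SyntheticDataset(
        records=records, complexes=complexes, framesets=framesets, reps=reps,
        solvent_table=solvent_table,
        truth={"w": w, "intercept": b, "p_by_record": p_cells,
               "score_by_pair": score_by_pair, "cells": cells,
               "realised_base_rate": realised},
    )
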