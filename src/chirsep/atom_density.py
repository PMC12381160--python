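"""Weighted atom-density profiles and trajectory aggregation.

Every non-hydrogen atom i of an acid-base complex is described by

* ``A1(i)`` -- 7 identity features (see :mod:`chirsep.electronic_weights`);
* ``A2(i)^w(r) = sum_{j != i} w_ij G_ij(r)`` -- a two-body radial density,
  one 160-bin profile per weighting channel;
* ``A3(i)^{w,phi}(r) = sum_{j,k != i, j != k} w_ij w_ik w_jk G_ij(r) phi(theta_ijk)``
  -- a three-body profile where phi is the cosine or sine of the angle at
  the central atom i between i->j and i->k.

``G_ij`` is a normalised Gaussian of width sigma = 0.0825 Angstrom centred at
the interatomic distance d_ij, evaluated at the 160 bin centres spanning
0.7 to 8 Angstrom (endpoints included).  Neighbours beyond the 8 Angstrom
cutoff are dropped (a hard cutoff: at this Gaussian width the tail crossing
the boundary is below machine precision for the in-range bins).

Per-atom snapshot vector: 7 + 7*160 + 14*160 = 3367 entries.  A trajectory
representation concatenates the per-frame mean and (population) standard
deviation: 6734 entries per atom.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .electronic_weights import CHANNELS, LONG_RANGE_CHANNELS, SurrogateProvider
from .structures_io import FrameSet, SaltComplex, StructuralError

SIGMA = 0.0825          # Gaussian width, Angstrom
CUTOFF = 8.0            # neighbour cutoff, Angstrom
N_BINS = 160
R_MIN, R_MAX = 0.7, 8.0
SNAPSHOT_DIM = 7 + 7 * N_BINS + 14 * N_BINS  # 3367
TRAJECTORY_DIM = 2 * SNAPSHOT_DIM            # 6734


@dataclass(frozen=True)
class RadialGrid:
    """Evenly spaced radial bin centres, endpoints inclusive."""

    r_min: float = R_MIN
    r_max: float = R_MAX
    n_bins: int = N_BINS

    @property
    def centers(self) -> np.ndarray:
        return np.linspace(self.r_min, self.r_max, self.n_bins)

    @property
    def spacing(self) -> float:
        return (self.r_max - self.r_min) / (self.n_bins - 1)


DEFAULT_GRID = RadialGrid()


def gaussian(d_ij: float | np.ndarray, r: np.ndarray,
             sigma: float = SIGMA) -> np.ndarray:
    """Normalised Gaussian density centred at d_ij, evaluated at radii r (1/Angstrom)."""
    d = np.asarray(d_ij, dtype=float)
    return np.exp(-((d - r) ** 2) / (2.0 * sigma ** 2)) / (sigma * np.sqrt(2.0 * np.pi))


@dataclass
class SnapshotRep:
    """Per-atom representation of one snapshot: (n_centres, 3367)."""

    values: np.ndarray
    center_indices: np.ndarray    # indices of the centre atoms in the complex
    atom_ids: list[str]
    elements: list[str]

    def __post_init__(self) -> None:
        if self.values.shape[1] != SNAPSHOT_DIM:
            raise ValueError(f"snapshot vectors must have length {SNAPSHOT_DIM}")


@dataclass
class TrajectoryRep:
    """Mean-and-std aggregate of snapshot representations: (n_centres, 6734)."""

    values: np.ndarray
    center_indices: np.ndarray
    atom_ids: list[str]
    elements: list[str]
    frame_count: int = 0

    def __post_init__(self) -> None:
        if self.values.shape[1] != TRAJECTORY_DIM:
            raise ValueError(f"trajectory vectors must have length {TRAJECTORY_DIM}")

    @property
    def n_tokens(self) -> int:
        return self.values.shape[0]


def _neighbour_mask(dists: np.ndarray, i: int, cutoff: float,
                    unbounded: bool) -> np.ndarray:
    mask = np.ones(len(dists), dtype=bool)
    mask[i] = False
    if not unbounded:
        mask &= dists <= cutoff
    return mask


def a2_profile(i: int, coords: np.ndarray, weight_matrix: np.ndarray,
               grid: RadialGrid = DEFAULT_GRID, cutoff: float = CUTOFF,
               long_range_unbounded: bool = False) -> np.ndarray:
    """Two-body weighted density profile of atom i (160-vector)."""
    coords = np.asarray(coords, dtype=float)
    d = np.linalg.norm(coords - coords[i], axis=1)
    mask = _neighbour_mask(d, i, cutoff, long_range_unbounded)
    if not mask.any():
        return np.zeros(grid.n_bins)
    g = gaussian(d[mask][:, None], grid.centers[None, :])
    return weight_matrix[i, mask] @ g


def a3_profile(i: int, coords: np.ndarray, weight_matrix: np.ndarray,
               angle_fn: str, grid: RadialGrid = DEFAULT_GRID,
               cutoff: float = CUTOFF,
               long_range_unbounded: bool = False) -> np.ndarray:
    """Three-body weighted density profile of atom i (160-vector).

    Sums over ordered neighbour pairs (j, k), j != k, both within the cutoff;
    theta_ijk is the angle at the central atom i.  The j = k diagonal is
    excluded (the angle of an atom with itself is undefined); because the
    summand is otherwise symmetric in (j, k) apart from G using d_ij, the
    ordered sum counts each unordered pair once through each G centre.
    """
    if angle_fn not in ("cos", "sin"):
        raise ValueError("angle_fn must be 'cos' or 'sin'")
    coords = np.asarray(coords, dtype=float)
    d = np.linalg.norm(coords - coords[i], axis=1)
    mask = _neighbour_mask(d, i, cutoff, long_range_unbounded)
    nbr = np.flatnonzero(mask)
    if len(nbr) < 2:
        return np.zeros(grid.n_bins)
    vec = coords[nbr] - coords[i]
    unit = vec / np.linalg.norm(vec, axis=1, keepdims=True)
    cos_t = np.clip(unit @ unit.T, -1.0, 1.0)
    phi = cos_t if angle_fn == "cos" else np.sqrt(np.maximum(1.0 - cos_t ** 2, 0.0))
    w_i = weight_matrix[i, nbr]                 # w_ij over neighbours
    w_jk = weight_matrix[np.ix_(nbr, nbr)]      # w_jk between neighbours
    inner = w_jk * phi
    np.fill_diagonal(inner, 0.0)                # exclude j == k
    coeff = inner @ w_i                         # coeff_j = sum_k w_jk phi_jk w_ik
    g = gaussian(d[nbr][:, None], grid.centers[None, :])
    return (w_i * coeff) @ g


def snapshot_representation(cplx: SaltComplex, coords: np.ndarray | None = None,
                            provider=None, grid: RadialGrid = DEFAULT_GRID,
                            cutoff: float = CUTOFF,
                            include_h_neighbours: bool = True,
                            long_range_unbounded: bool = False) -> SnapshotRep:
    """Full per-atom representation of one snapshot.

    Centre atoms are the non-hydrogen atoms; neighbours include hydrogens by
    default (they carry charge in the q channel).  Layout per centre atom:
    A1 (7) || A2 over the 7 channels (7 x 160) || A3 over 7 channels x
    {cos, sin} (14 x 160).
    """
    provider = provider or SurrogateProvider()
    xyz = np.asarray(cplx.coords if coords is None else coords, dtype=float)
    channels = provider.weight_channels(cplx, xyz)
    a1 = provider.a1_features(cplx).values
    elements = cplx.elements
    heavy = np.array([k for k, e in enumerate(elements) if e != "H"], dtype=int)
    if len(heavy) == 0:
        raise ValueError("complex has no non-hydrogen atoms")

    if not include_h_neighbours:
        keep = heavy
        xyz = xyz[keep]
        a1 = a1[keep]
        channels = _subset_channels(channels, keep)
        centre_local = np.arange(len(keep))
        centre_global = heavy
    else:
        centre_local = heavy
        centre_global = heavy

    dists = squareform(pdist(xyz))
    centers = grid.centers
    n_bins = grid.n_bins
    zeros = np.zeros(n_bins)
    rows = np.empty((len(centre_local), SNAPSHOT_DIM))
    for row, (ic, ig) in enumerate(zip(centre_local, centre_global)):
        parts = [a1[ic if include_h_neighbours else row]]
        d_i = dists[ic]
        # the Gaussian matrix and angle factors are shared across channels;
        # with the cutoff disabled for the long-range channels two neighbour
        # sets (and caches) are needed
        caches = {}
        for unb in ({False, True} if long_range_unbounded else {False}):
            mask = _neighbour_mask(d_i, ic, cutoff, unb)
            nbr = np.flatnonzero(mask)
            cache = {"nbr": nbr}
            if len(nbr):
                cache["g"] = gaussian(d_i[nbr][:, None], centers[None, :])
            if len(nbr) >= 2:
                vec = xyz[nbr] - xyz[ic]
                unit = vec / np.linalg.norm(vec, axis=1, keepdims=True)
                cos_t = np.clip(unit @ unit.T, -1.0, 1.0)
                cache["cos"] = cos_t
                cache["sin"] = np.sqrt(np.maximum(1.0 - cos_t ** 2, 0.0))
            caches[unb] = cache

        def channel_cache(ch):
            return caches[long_range_unbounded and ch in LONG_RANGE_CHANNELS]

        for ch in CHANNELS:
            cache = channel_cache(ch)
            nbr = cache["nbr"]
            if len(nbr) == 0:
                parts.append(zeros)
                continue
            parts.append(channels.matrix(ch)[ic, nbr] @ cache["g"])
        for fn in ("cos", "sin"):  # all cosine channels, then all sine channels
            for ch in CHANNELS:
                cache = channel_cache(ch)
                nbr = cache["nbr"]
                if len(nbr) < 2:
                    parts.append(zeros)
                    continue
                w = channels.matrix(ch)
                w_i = w[ic, nbr]
                inner = w[np.ix_(nbr, nbr)] * cache[fn]
                np.fill_diagonal(inner, 0.0)
                parts.append((w_i * (inner @ w_i)) @ cache["g"])
        rows[row] = np.concatenate(parts)
    return SnapshotRep(
        values=rows,
        center_indices=np.asarray(centre_global),
        atom_ids=[cplx.atom_ids[k] for k in centre_global],
        elements=[elements[k] for k in centre_global],
    )


def _subset_channels(channels, keep):
    from .electronic_weights import WeightChannels

    return WeightChannels({c: channels.matrix(c)[np.ix_(keep, keep)]
                           for c in CHANNELS})


def aggregate_trajectory(frame_reps: list[SnapshotRep]) -> TrajectoryRep:
    """Concatenate per-atom mean and population standard deviation over frames."""
    if len(frame_reps) < 2:
        raise StructuralError("trajectory aggregation needs at least 2 frames")
    first = frame_reps[0]
    stack = np.stack([f.values for f in frame_reps])
    mean = stack.mean(axis=0)
    std = stack.std(axis=0, ddof=0)
    return TrajectoryRep(
        values=np.concatenate([mean, std], axis=1),
        center_indices=first.center_indices,
        atom_ids=first.atom_ids,
        elements=first.elements,
        frame_count=len(frame_reps),
    )


def featurize_frameset(frames: FrameSet, provider=None,
                       grid: RadialGrid = DEFAULT_GRID, cutoff: float = CUTOFF,
                       include_h_neighbours: bool = True,
                       long_range_unbounded: bool = False,
                       dtype=np.float64) -> TrajectoryRep:
    """Featurise every frame of a frame set and aggregate to a TrajectoryRep."""
    provider = provider or SurrogateProvider()
    reps = [snapshot_representation(frames.complex_template, f, provider, grid,
                                    cutoff, include_h_neighbours,
                                    long_range_unbounded)
            for f in frames.frames]
    out = aggregate_trajectory(reps)
    if dtype is not np.float64:
        out.values = out.values.astype(dtype)
    return out


# ---------------------------------------------------------------------------
# representation cache
# ---------------------------------------------------------------------------

def save_representations(path, reps: dict[str, TrajectoryRep]) -> None:
    """Store trajectory representations in an HDF5 container keyed by complex id."""
    import h5py

    with h5py.File(path, "w") as h5:
        for key, rep in reps.items():
            grp = h5.create_group(key)
            grp.create_dataset("values", data=rep.values)
            grp.create_dataset("center_indices", data=rep.center_indices)
            grp.create_dataset("atom_ids", data=np.array(rep.atom_ids, dtype="S16"))
            grp.create_dataset("elements", data=np.array(rep.elements, dtype="S4"))
            grp.attrs["frame_count"] = rep.frame_count


def load_representations(path) -> dict[str, TrajectoryRep]:
    import h5py

    out = {}
    with h5py.File(path, "r") as h5:
        for key in h5:
            grp = h5[key]
            out[key] = TrajectoryRep(
                values=np.asarray(grp["values"]),
                center_indices=np.asarray(grp["center_indices"]),
                atom_ids=[a.decode() for a in grp["atom_ids"][...]],
                elements=[e.decode() for e in grp["elements"][...]],
                frame_count=int(grp.attrs["frame_count"]),
            )
    return out
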