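"""Per-atom identity features (A1) and pairwise weighting channels.

The atom-density profiles weight each neighbour Gaussian by an electronic
pair quantity.  Seven channels make up the weighting set W:

* ``eps_sigma`` / ``eps_pi`` / ``eps_delta`` -- orbital-overlap weights,
  symmetric in (i, j), decaying exponentially with distance;
* ``q`` -- the charge product q_i * q_j (sign-indefinite, long range);
* ``p_sigma`` / ``p_pi`` / ``p_delta`` -- products of per-atom orbital
  populations (long range, distance independent).

Channel values come from a pluggable provider.  The default
:class:`SurrogateProvider` is a deterministic, self-contained electronic
model: electronegativity-equalisation partial charges, neutral valence
configurations adjusted by charge, and covalent-radius exponential overlaps.
:func:`external_provider_adapter` instead populates the channels from the
parsed output file of a semi-empirical calculation; the library never runs
external processes itself.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .elements import ElementData, element_data
from .structures_io import ParseError, SaltComplex

CHANNELS = ("eps_sigma", "eps_pi", "eps_delta", "q", "p_sigma", "p_pi", "p_delta")
#: channels whose pair weight decays with distance (overlap type)
OVERLAP_CHANNELS = ("eps_sigma", "eps_pi", "eps_delta")
#: channels that are products of per-atom scalars (distance independent)
LONG_RANGE_CHANNELS = ("q", "p_sigma", "p_pi", "p_delta")

A1_FIELDS = ("nuclear_charge", "group", "period", "partial_charge",
             "pop_s", "pop_p", "pop_d")


@dataclass
class A1Features:
    """Per-atom identity features, one 7-vector per atom.

    Columns: nuclear charge, group, period, partial charge (e) and the
    populations of the s, p and d valence orbitals.
    """

    values: np.ndarray  # (N, 7)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] != 7:
            raise ValueError("A1 features must be (N, 7)")
        if np.any(self.values[:, 0] < 1):
            raise ValueError("nuclear charge must be >= 1")
        if np.any(self.values[:, 4:] < -1e-12):
            raise ValueError("orbital populations must be >= 0")

    @property
    def n_atoms(self) -> int:
        return self.values.shape[0]


@dataclass
class WeightChannels:
    """Per-snapshot pair-weight matrices, one symmetric (N, N) matrix per channel."""

    matrices: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        if set(self.matrices) != set(CHANNELS):
            raise ValueError(f"expected exactly the channels {CHANNELS}")

    def matrix(self, channel: str) -> np.ndarray:
        try:
            return self.matrices[channel]
        except KeyError:
            raise ValueError(f"unknown weighting channel {channel!r}") from None


def pair_weight(channel: str, i: int, j: int, channels: WeightChannels) -> float:
    """The scalar weight w_ij for one channel and one atom pair (i != j)."""
    if i == j:
        raise ValueError("pair weights are defined for distinct atoms only")
    return float(channels.matrix(channel)[i, j])


# ---------------------------------------------------------------------------
# surrogate provider
# ---------------------------------------------------------------------------

def _eem_charges(rows: list[ElementData]) -> np.ndarray:
    """Electronegativity-equalisation partial charges for a neutral molecule.

    q_i = (chi_bar - chi_i) / eta_i with the common potential chi_bar fixed by
    charge neutrality; the charges sum to zero exactly.
    """
    chi = np.array([r.chi for r in rows])
    eta = np.array([r.eta for r in rows])
    chi_bar = (chi / eta).sum() / (1.0 / eta).sum()
    return (chi_bar - chi) / eta


class SurrogateProvider:
    """Deterministic self-contained electronic model for the weight channels.

    Partial charges come from electronegativity equalisation over the whole
    complex; orbital populations are the neutral valence configuration with
    the charge removed from (added to) the outermost partially filled shell;
    overlaps are ``cap_i * cap_j * exp(-(d_ij - r_cov_i - r_cov_j) / lam)``
    with per-element sigma/pi/delta capacities and decay length ``lam``
    (default 0.5 Angstrom, the covalent-overlap scale).

    Everything depends only on element identities and interatomic distances,
    so the channels are invariant under rigid rotation, translation and
    reflection of the complex.
    """

    name = "surrogate"

    def __init__(self, decay_length: float = 0.5):
        if decay_length <= 0:
            raise ValueError("decay length must be positive")
        self.decay_length = decay_length

    # -- per-complex scalars -------------------------------------------------
    def atom_scalars(self, cplx: SaltComplex) -> dict[str, np.ndarray]:
        rows = [element_data(e) for e in cplx.elements]
        q = _eem_charges(rows)
        pop_s = np.array([r.val_s for r in rows], dtype=float)
        pop_p = np.array([r.val_p for r in rows], dtype=float)
        pop_d = np.array([r.val_d for r in rows], dtype=float)
        # charge adjustment on the outermost partially-occupied shell
        for k, r in enumerate(rows):
            if r.val_p > 0:
                pop_p[k] = max(r.val_p - q[k], 0.0)
            else:
                pop_s[k] = max(r.val_s - q[k], 0.0)
        return {
            "q": q, "pop_s": pop_s, "pop_p": pop_p, "pop_d": pop_d,
            "cap_sigma": np.array([r.cap_sigma for r in rows], dtype=float),
            "cap_pi": np.array([r.cap_pi for r in rows], dtype=float),
            "cap_delta": np.array([r.cap_delta for r in rows], dtype=float),
            "r_cov": np.array([r.r_cov for r in rows], dtype=float),
            "z": np.array([r.z for r in rows], dtype=float),
            "group": np.array([r.group for r in rows], dtype=float),
            "period": np.array([r.period for r in rows], dtype=float),
        }

    def a1_features(self, cplx: SaltComplex) -> A1Features:
        s = self.atom_scalars(cplx)
        return A1Features(np.column_stack([
            s["z"], s["group"], s["period"], s["q"],
            s["pop_s"], s["pop_p"], s["pop_d"],
        ]))

    def weight_channels(self, cplx: SaltComplex,
                        coords: np.ndarray | None = None) -> WeightChannels:
        """Pair-weight matrices for one snapshot geometry."""
        s = self.atom_scalars(cplx)
        xyz = cplx.coords if coords is None else np.asarray(coords, dtype=float)
        d = squareform(pdist(xyz))
        r_sum = s["r_cov"][:, None] + s["r_cov"][None, :]
        decay = np.exp(-(d - r_sum) / self.decay_length)
        np.fill_diagonal(decay, 0.0)
        mats = {}
        for name, cap in (("eps_sigma", "cap_sigma"), ("eps_pi", "cap_pi"),
                          ("eps_delta", "cap_delta")):
            mats[name] = np.outer(s[cap], s[cap]) * decay
        for name, vec in (("q", "q"), ("p_sigma", "pop_s"),
                          ("p_pi", "pop_p"), ("p_delta", "pop_d")):
            m = np.outer(s[vec], s[vec]).astype(float)
            np.fill_diagonal(m, 0.0)
            mats[name] = m
        return WeightChannels(mats)


def compute_a1(cplx: SaltComplex, provider=None) -> A1Features:
    """A1 identity features for every atom of a complex (7 floats per atom)."""
    provider = provider or SurrogateProvider()
    return provider.a1_features(cplx)


# ---------------------------------------------------------------------------
# external (semi-empirical) adapter
# ---------------------------------------------------------------------------

class ExternalFileProvider:
    """Weight channels read from a parsed semi-empirical output file.

    The adapter is geometry-blind: the channel matrices are exactly those in
    the file, so the same matrices are returned for every snapshot.
    """

    name = "external_file"

    def __init__(self, a1: A1Features, channels: WeightChannels):
        self._a1 = a1
        self._channels = channels

    def a1_features(self, cplx: SaltComplex) -> A1Features:
        if self._a1.n_atoms != cplx.n_atoms:
            raise ValueError("external features atom count mismatch")
        return self._a1

    def weight_channels(self, cplx: SaltComplex,
                        coords: np.ndarray | None = None) -> WeightChannels:
        return self._channels


def external_provider_adapter(path: str | Path) -> ExternalFileProvider:
    """Parse a semi-empirical job output into a weight provider.

    Expected plain-text layout (a simplified transcription of the charge /
    population / bond-analysis sections of a PM7-style output; parsing
    assumptions are deliberately explicit rather than guessed from any one
    program version):

    * a block headed ``ATOMIC CHARGES AND ORBITAL POPULATIONS`` with rows
      ``index element charge pop_s pop_p pop_d``;
    * three blocks headed ``OVERLAP MATRIX SIGMA`` / ``... PI`` / ``... DELTA``
      with rows ``i j value`` (0-based indices, symmetrised on read).

    A missing block raises :class:`ParseError` naming the block.
    """
    text = Path(path).read_text().splitlines()

    def block(header: str) -> list[str]:
        try:
            start = next(k for k, ln in enumerate(text) if ln.strip() == header)
        except StopIteration:
            raise ParseError(f"{path}: missing block {header!r}") from None
        rows = []
        for ln in text[start + 1:]:
            if not ln.strip() or not ln.split()[0].lstrip("-").replace(".", "").isdigit():
                break
            rows.append(ln)
        if not rows:
            raise ParseError(f"{path}: empty block {header!r}")
        return rows

    pop_rows = block("ATOMIC CHARGES AND ORBITAL POPULATIONS")
    n = len(pop_rows)
    a1 = np.zeros((n, 7))
    for ln in pop_rows:
        parts = ln.split()
        k = int(parts[0])
        el = element_data(parts[1])
        a1[k] = [el.z, el.group, el.period, float(parts[2]),
                 float(parts[3]), float(parts[4]), float(parts[5])]

    mats: dict[str, np.ndarray] = {}
    for name, header in (("eps_sigma", "OVERLAP MATRIX SIGMA"),
                         ("eps_pi", "OVERLAP MATRIX PI"),
                         ("eps_delta", "OVERLAP MATRIX DELTA")):
        m = np.zeros((n, n))
        for ln in block(header):
            i, j, v = ln.split()[:3]
            m[int(i), int(j)] = m[int(j), int(i)] = float(v)
        np.fill_diagonal(m, 0.0)
        mats[name] = m

    q = a1[:, 3]
    for name, vec in (("q", q), ("p_sigma", a1[:, 4]),
                      ("p_pi", a1[:, 5]), ("p_delta", a1[:, 6])):
        m = np.outer(vec, vec)
        np.fill_diagonal(m, 0.0)
        mats[name] = m

    return ExternalFileProvider(A1Features(a1), WeightChannels(mats))


def get_provider(kind: str = "surrogate", **kwargs):
    """Provider factory: ``surrogate`` or ``external_file`` (needs ``path=``)."""
    if kind == "surrogate":
        return SurrogateProvider(**kwargs)
    if kind == "external_file":
        return external_provider_adapter(kwargs["path"])
    raise ValueError(f"unknown provider kind {kind!r}")
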