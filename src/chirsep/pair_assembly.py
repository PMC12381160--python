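"""Build model inputs from the two diastereomeric complexes.

The 6734-dimensional per-atom trajectory vectors are compressed to 20
dimensions (autoencoder or PCA), then combined per atom token into a mean
stream ``(z_R + z_S) / 2`` and an absolute-difference stream ``|z_R - z_S|``.
Because the underlying representation is invariant to reflections, the diff
stream vanishes identically when the two complexes are isometric (achiral
resolving agent) and is non-zero exactly when the two diastereomeric salts
genuinely differ -- this is where chirality sensitivity enters the pipeline.

Solvent mixtures are represented by the molar-fraction-weighted sum of the
pure-solvent descriptor vectors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .atom_density import TrajectoryRep
from .autodiff import Adam, Tensor

LATENT_DIM = 20


class CompressorError(ValueError):
    pass


@dataclass
class PairTensors:
    """Token streams for one diastereomer pair, plus the solvent vector."""

    atom_ids: list[str]
    elements: list[str]
    mean_stream: np.ndarray   # (T, latent)
    diff_stream: np.ndarray   # (T, latent), elementwise >= 0
    solvent: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.mean_stream.shape != self.diff_stream.shape:
            raise ValueError("mean and diff streams must have equal shape")
        if np.any(self.diff_stream < 0):
            raise ValueError("diff stream must be non-negative (absolute difference)")

    @property
    def n_tokens(self) -> int:
        return self.mean_stream.shape[0]

    def with_solvent(self, solvent: np.ndarray) -> "PairTensors":
        return PairTensors(self.atom_ids, self.elements, self.mean_stream,
                           self.diff_stream, np.asarray(solvent, dtype=float))


# ---------------------------------------------------------------------------
# compressors
# ---------------------------------------------------------------------------

class PCACompressor:
    """Standardise-then-PCA compression to ``latent_dim`` components."""

    kind = "pca"

    def __init__(self, latent_dim: int = LATENT_DIM, seed: int = 0):
        self.latent_dim = latent_dim
        self.seed = seed
        self.training_fingerprint: str | None = None
        self._scaler = None
        self._pca = None

    def fit(self, X: np.ndarray) -> "PCACompressor":
        from sklearn.decomposition import PCA
        from sklearn.preprocessing import StandardScaler

        X = _check_training_matrix(X, self.latent_dim)
        self.training_fingerprint = _fingerprint(X)
        self._scaler = StandardScaler().fit(X)
        Xs = self._scaler.transform(X)
        self._pca = PCA(n_components=self.latent_dim, svd_solver="randomized",
                        random_state=self.seed).fit(Xs)
        return self

    def encode(self, X: np.ndarray) -> np.ndarray:
        if self._pca is None:
            raise CompressorError("compressor is not fitted")
        return self._pca.transform(self._scaler.transform(np.asarray(X, dtype=float)))

    def decode(self, Z: np.ndarray) -> np.ndarray:
        return self._scaler.inverse_transform(self._pca.inverse_transform(Z))


class AutoencoderCompressor:
    """Symmetric two-hidden-layer autoencoder trained on squared reconstruction error.

    Architecture: input -> hidden -> latent -> hidden -> input with tanh hidden
    activations and linear latent/output layers, trained with Adam on
    standardised inputs.  Deterministic for a fixed seed.
    """

    kind = "autoencoder"

    def __init__(self, latent_dim: int = LATENT_DIM, hidden_dim: int = 64,
                 seed: int = 0, epochs: int = 200, batch_size: int = 256,
                 lr: float = 1e-3):
        self.latent_dim = latent_dim
        self.hidden_dim = hidden_dim
        self.seed = seed
        self.epochs = epochs
        self.batch_size = batch_size
        self.lr = lr
        self.params: dict[str, Tensor] | None = None
        self.training_fingerprint: str | None = None
        self._mu = None
        self._sd = None

    def _init_params(self, d: int) -> dict[str, Tensor]:
        rng = np.random.default_rng(self.seed)

        def glorot(n_in, n_out):
            s = np.sqrt(6.0 / (n_in + n_out))
            return Tensor(rng.uniform(-s, s, size=(n_in, n_out)), requires_grad=True)

        h, z = self.hidden_dim, self.latent_dim
        return {
            "enc1.W": glorot(d, h), "enc1.b": Tensor(np.zeros(h), requires_grad=True),
            "enc2.W": glorot(h, z), "enc2.b": Tensor(np.zeros(z), requires_grad=True),
            "dec1.W": glorot(z, h), "dec1.b": Tensor(np.zeros(h), requires_grad=True),
            "dec2.W": glorot(h, d), "dec2.b": Tensor(np.zeros(d), requires_grad=True),
        }

    def _encode_t(self, x: Tensor) -> Tensor:
        p = self.params
        return (x @ p["enc1.W"] + p["enc1.b"]).tanh() @ p["enc2.W"] + p["enc2.b"]

    def _decode_t(self, z: Tensor) -> Tensor:
        p = self.params
        return (z @ p["dec1.W"] + p["dec1.b"]).tanh() @ p["dec2.W"] + p["dec2.b"]

    def fit(self, X: np.ndarray) -> "AutoencoderCompressor":
        X = _check_training_matrix(X, self.latent_dim)
        self.training_fingerprint = _fingerprint(X)
        self._mu = X.mean(axis=0)
        sd = X.std(axis=0)
        self._sd = np.where(sd > 0, sd, 1.0)
        Xs = (X - self._mu) / self._sd
        self.params = self._init_params(X.shape[1])
        opt = Adam(self.params, lr=self.lr)
        rng = np.random.default_rng(self.seed + 1)
        n = len(Xs)
        for _ in range(self.epochs):
            order = rng.permutation(n)
            for lo in range(0, n, self.batch_size):
                idx = order[lo:lo + self.batch_size]
                xb = Tensor(Xs[idx])
                recon = self._decode_t(self._encode_t(xb))
                loss = ((recon - xb) ** 2).mean()
                opt.zero_grad()
                loss.backward()
                opt.step()
        return self

    def encode(self, X: np.ndarray) -> np.ndarray:
        if self.params is None:
            raise CompressorError("compressor is not fitted")
        Xs = (np.asarray(X, dtype=float) - self._mu) / self._sd
        return self._encode_t(Tensor(Xs)).data

    def decode(self, Z: np.ndarray) -> np.ndarray:
        return self._decode_t(Tensor(np.asarray(Z, dtype=float))).data * self._sd + self._mu


def _fingerprint(X: np.ndarray) -> str:
    """SHA-256 of the training matrix, recording what the compressor saw."""
    import hashlib

    return hashlib.sha256(np.ascontiguousarray(X).tobytes()).hexdigest()


def _check_training_matrix(X: np.ndarray, latent_dim: int) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise CompressorError("training data must be a 2-D matrix")
    if X.shape[0] < latent_dim:
        raise CompressorError(
            f"need at least latent_dim={latent_dim} training vectors, got {X.shape[0]}"
        )
    if np.all(X.std(axis=0) == 0):
        raise CompressorError("training inputs are constant; compression is degenerate")
    return X


def train_compressor(per_atom_reps: np.ndarray, latent_dim: int = LATENT_DIM,
                     kind: str = "autoencoder", seed: int = 0, **kwargs):
    """Fit a compressor on a stack of per-atom trajectory vectors.

    ``per_atom_reps`` is (n_atoms, 6734) -- typically the pooled atom vectors
    of the training split only, so the compression never sees test complexes.
    """
    if kind == "autoencoder":
        return AutoencoderCompressor(latent_dim=latent_dim, seed=seed, **kwargs).fit(per_atom_reps)
    if kind == "pca":
        return PCACompressor(latent_dim=latent_dim, seed=seed).fit(per_atom_reps)
    raise ValueError(f"unknown compressor kind {kind!r}")


# ---------------------------------------------------------------------------
# pair construction
# ---------------------------------------------------------------------------

def build_pair(rep_R: TrajectoryRep, rep_S: TrajectoryRep, compressor) -> PairTensors:
    """Mean / absolute-difference token streams from the two diastereomer reps.

    The two representations must come from mirror-substrate complexes with
    identical atom ordering.  Swapping R and S leaves the output unchanged:
    the pair input carries no enantiomer label, as the physics requires.
    """
    if rep_R.values.shape != rep_S.values.shape:
        raise ValueError("R and S representations have different atom counts")
    if rep_R.atom_ids != rep_S.atom_ids:
        raise ValueError("R and S representations have different atom orderings")
    z_r = compressor.encode(np.asarray(rep_R.values, dtype=float))
    z_s = compressor.encode(np.asarray(rep_S.values, dtype=float))
    return PairTensors(
        atom_ids=list(rep_R.atom_ids),
        elements=list(rep_R.elements),
        mean_stream=0.5 * (z_r + z_s),
        diff_stream=np.abs(z_r - z_s),
    )


def stack_atom_vectors(reps: dict, keys=None) -> np.ndarray:
    """Stack the per-atom trajectory vectors of selected (R, S) rep pairs.

    ``reps`` maps a pair key to a (TrajectoryRep, TrajectoryRep) tuple; the
    result is the compressor training matrix for those keys (training split
    only, to keep test complexes out of the compression fit).
    """
    keys = sorted(reps) if keys is None else sorted(keys)
    return np.vstack([np.vstack([np.asarray(reps[k][0].values, dtype=float),
                                 np.asarray(reps[k][1].values, dtype=float)])
                      for k in keys])


def build_pair_lookup(reps: dict, compressor) -> dict:
    """Compress every (R, S) rep pair into PairTensors keyed like ``reps``."""
    return {key: build_pair(rep_r, rep_s, compressor)
            for key, (rep_r, rep_s) in reps.items()}


def solvent_vector(components: list[tuple[str, float]],
                   solvent_table: pd.DataFrame) -> np.ndarray:
    """Molar-fraction-weighted sum of pure-solvent descriptor rows."""
    fracs = np.array([f for _, f in components], dtype=float)
    if abs(fracs.sum() - 1.0) > 1e-6:
        raise ValueError(f"solvent fractions must sum to 1, got {fracs.sum():.6f}")
    out = np.zeros(solvent_table.shape[1])
    for sid, frac in components:
        if sid not in solvent_table.index:
            raise KeyError(f"unknown solvent id {sid!r}")
        out += frac * solvent_table.loc[sid].to_numpy(dtype=float)
    return out
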