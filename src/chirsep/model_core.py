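"""Dual-stream attention network over diastereomer pair representations.

The mean and absolute-difference token streams are processed by independent
stacks of pre-norm transformer blocks (multi-head self-attention + feedforward,
no positional encoding -- the atom tokens form a set).  The processed tokens of
both streams are concatenated and pooled by a single cross-attention query
built from the embedded solvent descriptor.  A small feedforward head maps the
pooled vector to either two regression outputs (solid mass fraction and
enantiomeric excess) or a success probability.

The implementation runs on the in-package autodiff engine
(:mod:`chirsep.autodiff`); with a fixed seed and single-threaded numpy the
forward pass is bit-for-bit reproducible.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np

from .autodiff import Tensor, concatenate
from .pair_assembly import PairTensors

STREAMS = ("mean", "diff")
_NEG_INF = -1e9


@dataclass
class ModelConfig:
    input_dim: int = 20
    solvent_dim: int = 8
    token_dim: int = 64
    n_blocks: int = 2
    n_heads: int = 4
    ff_dim: int = 128
    dropout: float = 0.1
    head_kind: str = "regression"      # 'regression' | 'classification'
    n_regression_targets: int = 2
    solvent_as_token: bool = False     # alternative pooling: solvent joins the token set
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("input_dim", "solvent_dim", "token_dim", "n_blocks",
                     "n_heads", "ff_dim"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.token_dim % self.n_heads != 0:
            raise ValueError("n_heads must divide token_dim")
        if self.head_kind not in ("regression", "classification"):
            raise ValueError(f"unknown head kind {self.head_kind!r}")


@dataclass
class PredictionOutput:
    """Model outputs: stage-1 regression pair or stage-2 success probability."""

    regression: np.ndarray | None = None    # (B, n_targets)
    probability: np.ndarray | None = None   # (B,), in [0, 1]
    member_outputs: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.probability is not None:
            if np.any(self.probability < 0) or np.any(self.probability > 1):
                raise ValueError("probabilities must lie in [0, 1]")

    @property
    def spread(self) -> np.ndarray | None:
        if not self.member_outputs:
            return None
        return np.std(np.stack(self.member_outputs), axis=0)


@dataclass
class AttentionRecord:
    """Row-normalised attention matrices for one forward pass.

    ``stream_attention[stream][block]`` is (B, heads, T, T); ``cross_attention``
    is (B, heads, 1, 2T) over the concatenated token set.  ``atom_ids`` maps
    token index (within one stream) to the source atom.
    """

    stream_attention: dict[str, list[np.ndarray]]
    cross_attention: np.ndarray
    atom_ids: list[str]

    def matrix(self, stream: str, block: int, head: int,
               sample: int = 0) -> np.ndarray:
        return self.stream_attention[stream][block][sample, head]


# ---------------------------------------------------------------------------
# batching
# ---------------------------------------------------------------------------

def make_batch(pairs: list[PairTensors]) -> dict[str, np.ndarray]:
    """Pad a list of pair tensors into dense batch arrays plus a token mask."""
    if not pairs:
        raise ValueError("empty batch")
    t_max = max(p.n_tokens for p in pairs)
    f = pairs[0].mean_stream.shape[1]
    s = len(pairs[0].solvent) if pairs[0].solvent is not None else 0
    if s == 0:
        raise ValueError("pairs must carry a solvent vector (use with_solvent)")
    b = len(pairs)
    mean = np.zeros((b, t_max, f))
    diff = np.zeros((b, t_max, f))
    solvent = np.zeros((b, s))
    mask = np.zeros((b, t_max))
    for k, p in enumerate(pairs):
        t = p.n_tokens
        mean[k, :t] = p.mean_stream
        diff[k, :t] = p.diff_stream
        solvent[k] = p.solvent
        mask[k, :t] = 1.0
    return {"mean": mean, "diff": diff, "solvent": solvent, "mask": mask}


# ---------------------------------------------------------------------------
# model
# ---------------------------------------------------------------------------

class DualStreamModel:
    """The dual-stream transformer with solvent cross-attention pooling."""

    def __init__(self, config: ModelConfig,
                 params: dict[str, Tensor] | None = None):
        self.config = config
        self.params = params if params is not None else self._init_params()
        #: parameter-name prefixes excluded from training (set by swap_head)
        self.frozen_prefixes: tuple[str, ...] = ()

    # -- parameters ---------------------------------------------------------
    def _init_params(self) -> dict[str, Tensor]:
        cfg = self.config
        rng = np.random.default_rng(cfg.seed)

        def glorot(n_in, n_out):
            s = np.sqrt(6.0 / (n_in + n_out))
            return Tensor(rng.uniform(-s, s, size=(n_in, n_out)), requires_grad=True)

        def bias(n):
            return Tensor(np.zeros(n), requires_grad=True)

        d, ff = cfg.token_dim, cfg.ff_dim
        p: dict[str, Tensor] = {}
        for stream in STREAMS:
            p[f"{stream}.embed.W"] = glorot(cfg.input_dim, d)
            p[f"{stream}.embed.b"] = bias(d)
            for k in range(cfg.n_blocks):
                base = f"{stream}.block{k}"
                for w in ("Wq", "Wk", "Wv", "Wo"):
                    p[f"{base}.attn.{w}"] = glorot(d, d)
                p[f"{base}.attn.bo"] = bias(d)
                p[f"{base}.ff.W1"] = glorot(d, ff)
                p[f"{base}.ff.b1"] = bias(ff)
                p[f"{base}.ff.W2"] = glorot(ff, d)
                p[f"{base}.ff.b2"] = bias(d)
        p["pool.Wsolv"] = glorot(cfg.solvent_dim, d)
        p["pool.bsolv"] = bias(d)
        for w in ("Wk", "Wv", "Wo"):
            p[f"pool.{w}"] = glorot(d, d)
        p["pool.bo"] = bias(d)
        p.update(self._init_head(cfg, rng))
        return p

    @staticmethod
    def _init_head(cfg: ModelConfig, rng) -> dict[str, Tensor]:
        def glorot(n_in, n_out):
            s = np.sqrt(6.0 / (n_in + n_out))
            return Tensor(rng.uniform(-s, s, size=(n_in, n_out)), requires_grad=True)

        n_out = cfg.n_regression_targets if cfg.head_kind == "regression" else 1
        return {
            "head.W1": glorot(cfg.token_dim, cfg.token_dim),
            "head.b1": Tensor(np.zeros(cfg.token_dim), requires_grad=True),
            "head.W2": glorot(cfg.token_dim, n_out),
            "head.b2": Tensor(np.zeros(n_out), requires_grad=True),
        }

    def trainable_names(self) -> set[str]:
        return {name for name in self.params
                if not any(name.startswith(p) for p in self.frozen_prefixes)}

    def parameter_fingerprint(self, exclude_head: bool = False) -> str:
        """SHA-256 over the concatenated parameter bytes (sorted by name)."""
        h = hashlib.sha256()
        for name in sorted(self.params):
            if exclude_head and name.startswith("head."):
                continue
            h.update(name.encode())
            h.update(np.ascontiguousarray(self.params[name].data).tobytes())
        return h.hexdigest()

    # -- forward ------------------------------------------------------------
    def _dropout(self, x: Tensor, train: bool, rng) -> Tensor:
        p = self.config.dropout
        if not train or p <= 0:
            return x
        if rng is None:
            raise ValueError("training-mode forward needs an rng for dropout")
        keep = (rng.random(x.shape) >= p) / (1.0 - p)
        return x * Tensor(keep)

    def _mha(self, x: Tensor, prefix: str, key_mask: np.ndarray,
             query: Tensor | None = None, train: bool = False, rng=None):
        """Multi-head attention; self-attention if ``query`` is None.

        Returns (output, attention-weights ndarray (B, H, Tq, Tk)).
        """
        cfg = self.config
        p = self.params
        b, tk = x.shape[0], x.shape[1]
        h, dh = cfg.n_heads, cfg.token_dim // cfg.n_heads

        def split(z: Tensor, t: int) -> Tensor:
            return z.reshape(b, t, h, dh).swapaxes(1, 2)

        if query is None:
            q = split(x @ p[f"{prefix}.Wq"], tk)
            tq = tk
        else:
            tq = query.shape[1]
            q = split(query, tq)
        k = split(x @ p[f"{prefix}.Wk"], tk)
        v = split(x @ p[f"{prefix}.Wv"], tk)
        scores = (q @ k.swapaxes(-1, -2)) * (1.0 / np.sqrt(dh))
        add_mask = (1.0 - key_mask)[:, None, None, :] * _NEG_INF
        attn = (scores + Tensor(add_mask)).softmax(axis=-1)
        attn_d = self._dropout(attn, train, rng)
        out = (attn_d @ v).swapaxes(1, 2).reshape(b, tq, cfg.token_dim)
        out = out @ p[f"{prefix}.Wo"] + p[f"{prefix}.bo"]
        return out, attn.data

    def _forward_pooled(self, batch: dict[str, np.ndarray], train: bool = False,
                        rng=None):
        """Backbone forward up to the pooled vector.

        Returns (pooled Tensor (B, D), per-stream attention, cross attention).
        """
        cfg = self.config
        p = self.params
        mask = batch["mask"]
        stream_attn: dict[str, list[np.ndarray]] = {s: [] for s in STREAMS}

        processed = []
        for stream in STREAMS:
            x = Tensor(batch[stream]) @ p[f"{stream}.embed.W"] + p[f"{stream}.embed.b"]
            for kblk in range(cfg.n_blocks):
                base = f"{stream}.block{kblk}"
                attn_out, attn_w = self._mha(x.layer_norm(), f"{base}.attn",
                                             mask, train=train, rng=rng)
                stream_attn[stream].append(attn_w)
                x = x + self._dropout(attn_out, train, rng)
                y = x.layer_norm()
                y = (y @ p[f"{base}.ff.W1"] + p[f"{base}.ff.b1"]).relu()
                y = y @ p[f"{base}.ff.W2"] + p[f"{base}.ff.b2"]
                x = x + self._dropout(y, train, rng)
            processed.append(x)

        tokens = concatenate(processed, axis=1)            # (B, 2T, D)
        key_mask = np.concatenate([mask, mask], axis=1)    # (B, 2T)

        solv = Tensor(batch["solvent"]) @ p["pool.Wsolv"] + p["pool.bsolv"]
        b = batch["solvent"].shape[0]
        query = solv.reshape(b, 1, cfg.token_dim)
        if cfg.solvent_as_token:
            tokens = concatenate([tokens, query], axis=1)
            key_mask = np.concatenate([key_mask, np.ones((b, 1))], axis=1)
        pooled, cross_w = self._mha(tokens.layer_norm(), "pool", key_mask,
                                    query=query, train=train, rng=rng)
        return pooled.squeeze(1), stream_attn, cross_w

    def forward(self, batch: dict[str, np.ndarray], train: bool = False,
                rng=None, return_attention: bool = False
                ) -> tuple[Tensor, AttentionRecord | None]:
        """Run the network on a padded batch (see :func:`make_batch`).

        Returns the raw output tensor -- (B, n_targets) for regression,
        (B, 1) squashed probabilities for classification -- plus the
        attention record if requested.
        """
        pooled, stream_attn, cross_w = self._forward_pooled(batch, train, rng)
        out = self.head_forward(pooled)
        record = None
        if return_attention:
            record = AttentionRecord(stream_attention=stream_attn,
                                     cross_attention=cross_w,
                                     atom_ids=[])
        return out, record

    def head_forward(self, pooled: Tensor) -> Tensor:
        """Apply the readout head to a pooled representation."""
        p = self.params
        hvec = (pooled @ p["head.W1"] + p["head.b1"]).relu()
        out = hvec @ p["head.W2"] + p["head.b2"]
        if self.config.head_kind == "classification":
            out = out.sigmoid()
        return out

    def pooled_features(self, batch: dict[str, np.ndarray]) -> np.ndarray:
        """Evaluation-mode pooled vectors (B, token_dim), before the head.

        With a frozen backbone the pooled representation of a record is fixed,
        so the head can be trained on cached features.
        """
        return self._forward_pooled(batch)[0].data

    def predict(self, pairs: list[PairTensors],
                return_attention: bool = False
                ) -> tuple[PredictionOutput, AttentionRecord | None]:
        """Evaluation-mode prediction on a list of pairs."""
        batch = make_batch(pairs)
        out, record = self.forward(batch, train=False,
                                   return_attention=return_attention)
        if record is not None:
            record.atom_ids = list(pairs[0].atom_ids)
        if self.config.head_kind == "classification":
            return PredictionOutput(probability=out.data[:, 0]), record
        return PredictionOutput(regression=out.data), record

    # -- stage transitions --------------------------------------------------
    def swap_head(self, new_head_kind: str) -> "DualStreamModel":
        """Replace the readout head, freezing every other parameter.

        The non-head parameters of the returned model are the same arrays as
        this model's (bit-identical) and are marked frozen so optimisers skip
        them.
        """
        new_cfg = replace(self.config, head_kind=new_head_kind)
        rng = np.random.default_rng(self.config.seed + 104729)
        params = {name: t for name, t in self.params.items()
                  if not name.startswith("head.")}
        params.update(self._init_head(new_cfg, rng))
        model = DualStreamModel(new_cfg, params=params)
        model.frozen_prefixes = tuple(sorted(
            {name.split(".")[0] + "." for name in params
             if not name.startswith("head.")}))
        return model

    # -- persistence --------------------------------------------------------
    def save(self, path) -> None:
        import h5py
        import json

        with h5py.File(path, "w") as h5:
            h5.attrs["config"] = json.dumps(self.config.__dict__)
            h5.attrs["frozen_prefixes"] = json.dumps(list(self.frozen_prefixes))
            h5.attrs["fingerprint"] = self.parameter_fingerprint()
            grp = h5.create_group("params")
            for name, t in self.params.items():
                grp.create_dataset(name, data=t.data)

    @classmethod
    def load(cls, path) -> "DualStreamModel":
        import h5py
        import json

        with h5py.File(path, "r") as h5:
            cfg = ModelConfig(**json.loads(h5.attrs["config"]))
            params = {name: Tensor(np.asarray(h5["params"][name]), requires_grad=True)
                      for name in h5["params"]}
            frozen = tuple(json.loads(h5.attrs["frozen_prefixes"]))
        model = cls(cfg, params=params)
        model.frozen_prefixes = frozen
        return model


def ensemble_predict(models: list[DualStreamModel],
                     pairs: list[PairTensors]) -> PredictionOutput:
    """Mean probability across ensemble members; per-member outputs retained."""
    if not models:
        raise ValueError("ensemble must contain at least one model")
    member_outputs = []
    for m in models:
        out, _ = m.predict(pairs)
        vals = out.probability if out.probability is not None else out.regression
        member_outputs.append(np.asarray(vals))
    stacked = np.stack(member_outputs)
    meanv = stacked.mean(axis=0)
    if models[0].config.head_kind == "classification":
        return PredictionOutput(probability=meanv, member_outputs=member_outputs)
    return PredictionOutput(regression=meanv, member_outputs=member_outputs)
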