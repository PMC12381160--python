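"""Compare model attention with crystal-structure contacts.

Crystal neighbours are unordered heavy-atom pairs within 3.5 Angstrom in the
salt's crystal coordinates.  For every attention head the mean symmetrised
attention over neighbour pairs and over non-neighbour pairs is compared with
the uniform baseline 1/T (T tokens): a head whose neighbour ratio exceeds 1
concentrates on atom pairs that end up close in the crystal.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist, squareform

from .model_core import AttentionRecord

DEFAULT_CONTACT_CUTOFF = 3.5  # Angstrom


@dataclass
class ContactMap:
    """Unordered neighbour pairs over the token atom set."""

    pairs: set[frozenset]
    intermolecular: set[frozenset]
    cutoff: float
    atom_ids: list[str]

    def is_neighbour(self, a: str, b: str) -> bool:
        return frozenset((a, b)) in self.pairs


@dataclass
class HeadContactStats:
    stream: str
    block: int
    head: int
    mean_neighbour: float
    mean_non_neighbour: float
    neighbour_ratio: float       # vs uniform baseline 1/T
    non_neighbour_ratio: float


def find_contacts(atom_ids: list[str], coords: np.ndarray,
                  cutoff: float = DEFAULT_CONTACT_CUTOFF,
                  n_first_molecule: int | None = None) -> ContactMap:
    """All unordered atom pairs within ``cutoff`` (single asymmetric unit).

    ``atom_ids`` must match the model's token atoms (heavy atoms only);
    ``n_first_molecule`` marks the substrate/agent split for intermolecular
    flagging.
    """
    coords = np.asarray(coords, dtype=float)
    if len(atom_ids) != len(coords):
        raise ValueError("atom_ids and coords length mismatch")
    if len(set(atom_ids)) != len(atom_ids):
        dupes = sorted({a for a in atom_ids if atom_ids.count(a) > 1})
        raise ValueError(f"duplicate atom ids {dupes}")
    d = squareform(pdist(coords))
    pairs, inter = set(), set()
    n = len(atom_ids)
    for i in range(n):
        for j in range(i + 1, n):
            if d[i, j] <= cutoff:
                key = frozenset((atom_ids[i], atom_ids[j]))
                pairs.add(key)
                if n_first_molecule is not None and \
                        (i < n_first_molecule) != (j < n_first_molecule):
                    inter.add(key)
    return ContactMap(pairs=pairs, intermolecular=inter, cutoff=cutoff,
                      atom_ids=list(atom_ids))


def _symmetrise(matrix: np.ndarray) -> np.ndarray:
    return 0.5 * (matrix + matrix.T)


def _pair_class_means(sym: np.ndarray, neighbour_mask: np.ndarray
                      ) -> tuple[float, float]:
    t = sym.shape[0]
    iu = np.triu_indices(t, k=1)
    vals = sym[iu]
    nbr = neighbour_mask[iu]
    mean_nbr = float(vals[nbr].mean()) if nbr.any() else np.nan
    mean_non = float(vals[~nbr].mean()) if (~nbr).any() else np.nan
    return mean_nbr, mean_non


def head_stats(attention: AttentionRecord, contacts: ContactMap,
               sample: int = 0) -> list[HeadContactStats]:
    """Neighbour / non-neighbour mean attention per (stream, block, head).

    Attention is symmetrised as (A + A^T)/2 before pair statistics; means are
    over unordered pair classes and ratios are against the uniform baseline
    1/T.  Both streams are analysed and reported separately.
    """
    if not contacts.pairs:
        raise ValueError("empty contact set")
    atom_ids = attention.atom_ids
    unmapped = [a for a in contacts.atom_ids if a not in atom_ids]
    if unmapped:
        raise ValueError(f"contact atoms missing from tokens: {unmapped}")
    t = len(atom_ids)
    nbr_mask = np.zeros((t, t), dtype=bool)
    for i in range(t):
        for j in range(t):
            if i != j and contacts.is_neighbour(atom_ids[i], atom_ids[j]):
                nbr_mask[i, j] = True
    baseline = 1.0 / t
    stats = []
    for stream, blocks in attention.stream_attention.items():
        for b, mats in enumerate(blocks):
            n_heads = mats.shape[1]
            for h in range(n_heads):
                sym = _symmetrise(mats[sample, h, :t, :t])
                mean_nbr, mean_non = _pair_class_means(sym, nbr_mask)
                stats.append(HeadContactStats(
                    stream=stream, block=b, head=h,
                    mean_neighbour=mean_nbr, mean_non_neighbour=mean_non,
                    neighbour_ratio=mean_nbr / baseline,
                    non_neighbour_ratio=mean_non / baseline,
                ))
    return stats


def reference_atom_profile(attention: AttentionRecord, atom_id: str,
                           stream: str = "mean", block: int = -1,
                           head: int = 0, sample: int = 0
                           ) -> tuple[np.ndarray, list[int], bool]:
    """Symmetrised, renormalised attention row for one reference atom.

    Returns ``(profile, argmax_indices, tied)`` where ``argmax_indices`` has
    more than one entry (and ``tied`` is True) when the maximum is degenerate.
    """
    atom_ids = attention.atom_ids
    if atom_id not in atom_ids:
        raise ValueError(f"atom {atom_id!r} not in token set")
    idx = atom_ids.index(atom_id)
    mats = attention.stream_attention[stream]
    t = len(atom_ids)
    sym = _symmetrise(mats[block][sample, head, :t, :t])
    row = sym[idx]
    row = row / row.sum()
    top = float(row.max())
    arg = [int(k) for k in np.flatnonzero(np.isclose(row, top, rtol=0, atol=1e-12))]
    return row, arg, len(arg) > 1
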