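"""Patch grid and masking plans for 12-lead ECG records.

A 12x5000 record becomes a 12x20 grid of 1x250 patches (0.5 s each at
500 Hz), flattened lead-major: patches 0..19 are lead I, 20..39 lead II,
and so on — 240 patches per record.  Patch ``i`` of a lead covers the
half-open sample window ``[250*i, 250*(i+1))``.

Three masking strategies are supported:

``random``
    a seeded uniform shuffle hides ``round(240 * r)`` patches anywhere
    on the grid;
``per_lead``
    the same ratio applied independently inside each lead
    (``round(20 * r)`` hidden per lead);
``grid``
    a regular keep-one-in-four pattern along time (defined only for
    r = 0.75): a patch is visible iff its time index is congruent to a
    seed-chosen phase modulo 4.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

from .ecg_io import ECGRecord

N_LEADS = 12
PATCHES_PER_LEAD = 20
PATCH_LENGTH = 250
N_PATCHES = N_LEADS * PATCHES_PER_LEAD

STRATEGIES = ("random", "grid", "per_lead")


class UnsupportedMaskError(ValueError):
    """Masking configuration outside the defined strategy domain."""


@dataclass
class PatchSet:
    """240 patches of 250 samples, lead-major order."""

    patches: np.ndarray                 # (240, 250)
    n_leads: int = N_LEADS
    patches_per_lead: int = PATCHES_PER_LEAD
    patch_length: int = PATCH_LENGTH

    def __post_init__(self):
        expected = (self.n_leads * self.patches_per_lead, self.patch_length)
        if self.patches.shape != expected:
            raise ValueError(f"expected patches of shape {expected}, "
                             f"got {self.patches.shape}")


def patchify(record) -> PatchSet:
    """Split a record (or raw 12xN array) into non-overlapping patches."""
    signal = record.signal if isinstance(record, ECGRecord) else np.asarray(record)
    if signal.ndim != 2 or signal.shape[0] != N_LEADS:
        raise ValueError(f"expected a (12, n) signal, got {signal.shape}")
    if signal.shape[1] % PATCH_LENGTH != 0:
        raise ValueError(
            f"sample count {signal.shape[1]} not divisible by {PATCH_LENGTH}"
        )
    per_lead = signal.shape[1] // PATCH_LENGTH
    patches = signal.reshape(N_LEADS * per_lead, PATCH_LENGTH)
    return PatchSet(patches, patches_per_lead=per_lead)


def unpatchify(patches) -> np.ndarray:
    """Exact inverse of :func:`patchify`; bitwise roundtrip."""
    if isinstance(patches, PatchSet):
        arr = patches.patches
        per_lead = patches.patches_per_lead
    else:
        arr = np.asarray(patches)
        if arr.shape[0] % N_LEADS != 0:
            raise ValueError(f"patch count {arr.shape[0]} not a multiple of 12")
        per_lead = arr.shape[0] // N_LEADS
    if arr.shape != (N_LEADS * per_lead, PATCH_LENGTH):
        raise ValueError(f"bad patch array shape {arr.shape}")
    return arr.reshape(N_LEADS, per_lead * PATCH_LENGTH)


@dataclass
class MaskSpec:
    """A masking plan over the 240-patch grid.

    ``shuffle`` lists visible indices first, then masked ones (the order
    the encoder/decoder pipeline uses); ``restore`` is its inverse
    permutation, mapping shuffled positions back to canonical order.
    """

    ratio: float
    strategy: str
    seed: int
    visible_indices: np.ndarray
    masked_indices: np.ndarray
    shuffle: np.ndarray = field(default=None)
    restore: np.ndarray = field(default=None)

    def __post_init__(self):
        self.visible_indices = np.asarray(self.visible_indices, dtype=np.int64)
        self.masked_indices = np.asarray(self.masked_indices, dtype=np.int64)
        union = np.union1d(self.visible_indices, self.masked_indices)
        if union.size != self.visible_indices.size + self.masked_indices.size:
            raise ValueError("visible and masked sets overlap")
        if not np.array_equal(union, np.arange(N_PATCHES)):
            raise ValueError("visible and masked sets must partition 0..239")
        if self.shuffle is None:
            self.shuffle = np.concatenate([self.visible_indices,
                                           self.masked_indices])
        self.shuffle = np.asarray(self.shuffle, dtype=np.int64)
        self.restore = np.argsort(self.shuffle)

    @property
    def n_visible(self) -> int:
        return int(self.visible_indices.size)

    @property
    def n_masked(self) -> int:
        return int(self.masked_indices.size)

    def bool_mask(self) -> np.ndarray:
        """Boolean vector over 0..239, True where masked."""
        out = np.zeros(N_PATCHES, dtype=bool)
        out[self.masked_indices] = True
        return out

    def to_json(self) -> str:
        return json.dumps(
            {
                "ratio": self.ratio,
                "strategy": self.strategy,
                "seed": self.seed,
                "visible_indices": self.visible_indices.tolist(),
                "masked_indices": self.masked_indices.tolist(),
                "shuffle": self.shuffle.tolist(),
            }
        )

    @classmethod
    def from_json(cls, text: str) -> "MaskSpec":
        d = json.loads(text)
        return cls(
            ratio=d["ratio"],
            strategy=d["strategy"],
            seed=d["seed"],
            visible_indices=np.array(d["visible_indices"]),
            masked_indices=np.array(d["masked_indices"]),
            shuffle=np.array(d["shuffle"]),
        )


def make_mask(ratio: float, strategy: str = "random", seed: int = 0) -> MaskSpec:
    """Build a masking plan; deterministic per seed."""
    if not (0 <= ratio <= 1):
        raise ValueError(f"masking ratio {ratio} outside [0, 1]")
    if strategy not in STRATEGIES:
        raise UnsupportedMaskError(f"unknown strategy {strategy!r}")
    rng = np.random.default_rng(seed)

    if strategy == "random":
        perm = rng.permutation(N_PATCHES)
        n_visible = int(round(N_PATCHES * (1 - ratio)))
        visible = np.sort(perm[:n_visible])
        masked = np.sort(perm[n_visible:])
        shuffle = np.concatenate([perm[:n_visible], perm[n_visible:]])
    elif strategy == "per_lead":
        n_masked_per_lead = int(round(PATCHES_PER_LEAD * ratio))
        masked_parts = []
        for lead in range(N_LEADS):
            perm = rng.permutation(PATCHES_PER_LEAD)
            masked_parts.append(lead * PATCHES_PER_LEAD
                                + perm[:n_masked_per_lead])
        masked = np.sort(np.concatenate(masked_parts)) if masked_parts else \
            np.empty(0, dtype=np.int64)
        visible = np.setdiff1d(np.arange(N_PATCHES), masked)
        shuffle = None
    else:  # grid
        if abs(ratio - 0.75) > 1e-9:
            raise UnsupportedMaskError(
                "grid masking is defined only for ratio 0.75"
            )
        phase = int(rng.integers(0, 4))
        time_idx = np.arange(N_PATCHES) % PATCHES_PER_LEAD
        visible = np.flatnonzero(time_idx % 4 == phase)
        masked = np.flatnonzero(time_idx % 4 != phase)
        shuffle = None

    return MaskSpec(ratio=ratio, strategy=strategy, seed=seed,
                    visible_indices=visible, masked_indices=masked,
                    shuffle=shuffle)


def make_mask_batch(batch_size: int, ratio: float, strategy: str,
                    seed: int) -> np.ndarray:
    """Visible-index matrix (batch, n_visible) with a fresh mask per row.

    Only strategies with a fixed visible count across rows are batchable;
    all three qualify.  Row ``b`` uses seed ``seed + b``.
    """
    masks = [make_mask(ratio, strategy, seed + b) for b in range(batch_size)]
    return np.stack([m.visible_indices for m in masks])
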