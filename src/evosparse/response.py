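"""Response vectors and class balancing.

The response assigns +1 to sequences in the focal clade (or carrying the
trait) and −1 to the rest. Phylogenomic class sizes are usually very
unequal, so the fit is balanced either with inverse-frequency class
weights (the default), by up-sampling the minority class with replacement,
or by down-sampling the majority class.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class ResponseError(ValueError):
    pass


@dataclass
class ResponseVector:
    """Per-taxon class labels in {+1, −1} with sample weights."""

    taxa: list[str]
    y: np.ndarray
    weights: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.y = np.asarray(self.y, dtype=np.float64)
        if self.weights is None:
            self.weights = np.ones_like(self.y)
        self.weights = np.asarray(self.weights, dtype=np.float64)
        if self.y.shape != self.weights.shape or self.y.ndim != 1:
            raise ResponseError("y and weights must be 1-D and congruent")
        if len(self.taxa) != self.y.size:
            raise ResponseError("taxa and y differ in length")
        if not np.all(np.isin(self.y, (-1.0, 1.0))):
            raise ResponseError("labels must be +1 or -1")
        if np.any(self.weights < 0):
            raise ResponseError("negative sample weight")
        if not (np.any(self.y > 0) and np.any(self.y < 0)):
            raise ResponseError("both classes must be non-empty")

    @property
    def n_positive(self) -> int:
        return int(np.sum(self.y > 0))

    @property
    def n_negative(self) -> int:
        return int(np.sum(self.y < 0))


def build_response(taxa: list[str], positives: set[str]) -> ResponseVector:
    """+1 for members of ``positives``, −1 otherwise; unit weights.

    ``positives`` must be a proper non-empty subset of ``taxa``.
    """
    taxa = list(taxa)
    unknown = set(positives) - set(taxa)
    if unknown:
        raise ResponseError(f"class members not in alignment: {sorted(unknown)[:5]}")
    if not positives:
        raise ResponseError("positive class is empty")
    if set(taxa) <= set(positives):
        raise ResponseError("positive class contains every taxon")
    y = np.array([1.0 if t in positives else -1.0 for t in taxa])
    return ResponseVector(taxa=taxa, y=y)


def balance(rv: ResponseVector, mode: str = "class_weights", seed: int = 0):
    """Equalize effective class masses.

    ``class_weights`` returns a new ResponseVector with weight
    w_c = S / (2·S_c) per member of class c, so per-class weight sums are
    both S/2. ``upsample`` returns row indices where the minority class is
    drawn with replacement up to the majority size; ``downsample`` returns
    indices where the majority is subsampled without replacement down to
    the minority size. Resampling is deterministic given the seed.
    """
    pos_idx = np.flatnonzero(rv.y > 0)
    neg_idx = np.flatnonzero(rv.y < 0)
    if mode == "class_weights":
        S = rv.y.size
        w = np.where(
            rv.y > 0, S / (2.0 * pos_idx.size), S / (2.0 * neg_idx.size)
        )
        return ResponseVector(taxa=list(rv.taxa), y=rv.y.copy(), weights=w)
    rng = np.random.default_rng(seed)
    minority, majority = (
        (pos_idx, neg_idx) if pos_idx.size <= neg_idx.size else (neg_idx, pos_idx)
    )
    if mode == "upsample":
        extra = rng.choice(minority, size=majority.size, replace=True)
        return np.sort(np.concatenate([majority, extra]))
    if mode == "downsample":
        kept = rng.choice(majority, size=minority.size, replace=False)
        return np.sort(np.concatenate([minority, kept]))
    raise ValueError(f"unknown balancing mode {mode!r}")
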