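"""One-hot encoding of alignments into binary design matrices.

Each aligned position contributes as many bit-columns as the number of
distinct unambiguous states observed there (at most 4 for nucleotides, 20
for amino acids, plus one if gaps are encoded as a state). Monomorphic
bit-columns carry no information for classification and are filtered out
before fitting. Bit-columns are ordered by position ascending, then state
in fixed alphabet order, so the encoding is deterministic.

Ambiguity codes either contribute no bits (``missing``, the default) or set
the bit of each constituent state that has a column at that position
(``constituent_bits``). Gaps ('-' and '?') contribute no bits unless
``gap_as_state`` is set, in which case '-' gets its own bit-column.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .msa_io import (
    GAP_CHARS,
    Alignment,
    GroupMap,
    alphabet_states,
    ambiguity_map,
)

logger = logging.getLogger(__name__)

GAP_STATE = "-"


class EncodingError(ValueError):
    pass


@dataclass
class BitColumnMap:
    """Maps every bit-column to exactly one (position, state) pair.

    ``positions`` are 1-based alignment coordinates; ``states`` are single
    characters ('-' denotes the gap bit-column when enabled).
    """

    positions: np.ndarray  # int, shape (c,)
    states: np.ndarray  # '<U1', shape (c,)
    alphabet: str
    gap_as_state: bool = False
    ambiguity_policy: str = "missing"

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.states = np.asarray(self.states, dtype="<U1")
        if self.positions.shape != self.states.shape:
            raise EncodingError("positions and states differ in shape")

    @property
    def n_columns(self) -> int:
        return int(self.positions.size)

    def columns_for_position(self, position: int) -> np.ndarray:
        return np.flatnonzero(self.positions == position)

    def inverse(self) -> dict[int, np.ndarray]:
        """Position → indices of its bit-columns."""
        order = np.argsort(self.positions, kind="stable")
        out: dict[int, np.ndarray] = {}
        for pos in np.unique(self.positions):
            out[int(pos)] = np.flatnonzero(self.positions == pos)
        return out

    def subset(self, idx: np.ndarray) -> "BitColumnMap":
        return BitColumnMap(
            positions=self.positions[idx],
            states=self.states[idx],
            alphabet=self.alphabet,
            gap_as_state=self.gap_as_state,
            ambiguity_policy=self.ambiguity_policy,
        )


@dataclass
class OneHotMatrix:
    """S×c binary design matrix with its bit-column map."""

    X: np.ndarray  # float64, shape (S, c), entries in {0, 1}
    bitmap: BitColumnMap
    taxa: list[str]

    def __post_init__(self) -> None:
        self.X = np.ascontiguousarray(self.X, dtype=np.float64)
        if self.X.ndim != 2:
            raise EncodingError("design matrix must be 2-D")
        if self.X.shape[1] != self.bitmap.n_columns:
            raise EncodingError("matrix width does not match bit-column map")

    @property
    def n_sequences(self) -> int:
        return self.X.shape[0]

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    def subset_columns(self, idx: np.ndarray) -> "OneHotMatrix":
        idx = np.asarray(idx)
        return OneHotMatrix(
            X=self.X[:, idx], bitmap=self.bitmap.subset(idx), taxa=list(self.taxa)
        )

    def subset_rows(self, idx: np.ndarray) -> "OneHotMatrix":
        idx = np.asarray(idx)
        return OneHotMatrix(
            X=self.X[idx, :],
            bitmap=self.bitmap,
            taxa=[self.taxa[i] for i in idx],
        )


def _char_matrix(aln: Alignment) -> np.ndarray:
    return np.array([list(row) for row in aln.rows], dtype="<U1")


def one_hot_encode(
    aln: Alignment,
    gap_as_state: bool = False,
    ambiguity_policy: str = "missing",
) -> OneHotMatrix:
    """Encode an alignment as an S×c binary matrix with a bit-column map.

    One bit-column per distinct observed unambiguous state per position;
    optionally one more for the gap. No filtering is applied here — use
    :func:`filter_monomorphic` afterwards.
    """
    if ambiguity_policy not in {"missing", "constituent_bits"}:
        raise ValueError(f"unknown ambiguity policy {ambiguity_policy!r}")
    C = _char_matrix(aln)
    S, p = C.shape
    if S == 0 or p == 0:
        raise EncodingError("empty alignment")
    order = alphabet_states(aln.alphabet)
    ambig = ambiguity_map(aln.alphabet)

    cols: list[np.ndarray] = []
    positions: list[int] = []
    states: list[str] = []
    for j in range(p):
        col = C[:, j]
        present = set(col)
        observed = [s for s in order if s in present]
        block: dict[str, np.ndarray] = {
            s: (col == s).astype(np.float64) for s in observed
        }
        if gap_as_state and (present & GAP_CHARS):
            block[GAP_STATE] = np.isin(col, list(GAP_CHARS)).astype(np.float64)
        if ambiguity_policy == "constituent_bits":
            for code in present & set(ambig):
                rows = col == code
                for s in ambig[code]:
                    if s in block:
                        block[s] = np.where(rows, 1.0, block[s])
        block_order = observed + ([GAP_STATE] if GAP_STATE in block else [])
        for s in block_order:
            cols.append(block[s])
            positions.append(j + 1)
            states.append(s)

    X = (
        np.stack(cols, axis=1)
        if cols
        else np.zeros((S, 0), dtype=np.float64)
    )
    bitmap = BitColumnMap(
        positions=np.array(positions, dtype=np.int64),
        states=np.array(states, dtype="<U1"),
        alphabet=aln.alphabet,
        gap_as_state=gap_as_state,
        ambiguity_policy=ambiguity_policy,
    )
    return OneHotMatrix(X=X, bitmap=bitmap, taxa=list(aln.taxa))


def filter_monomorphic(ohm: OneHotMatrix) -> OneHotMatrix:
    """Drop bit-columns that are constant across sequences.

    Retained columns each contain at least one 0 and one 1. The number of
    removed columns is logged.
    """
    sums = ohm.X.sum(axis=0)
    S = ohm.n_sequences
    keep = np.flatnonzero((sums > 0) & (sums < S))
    removed = ohm.n_columns - keep.size
    if removed:
        logger.info(
            "filtered %d monomorphic bit-columns (%d retained)", removed, keep.size
        )
    return ohm.subset_columns(keep)


def map_groups_to_bits(
    bitmap: BitColumnMap, groups: GroupMap, allow_uncovered: bool = False
) -> list[np.ndarray]:
    """Bit-column index slice per group, in GroupMap order.

    Groups whose positions were entirely filtered out yield empty slices
    (inert groups). Retained bit-columns at positions not covered by any
    group raise unless ``allow_uncovered``; downstream fits should then be
    restricted to covered columns.
    """
    pos2group: dict[int, int] = {}
    for gi, poss in enumerate(groups.positions):
        for i in poss:
            pos2group[i] = gi
    slices: list[list[int]] = [[] for _ in groups.names]
    uncovered = 0
    for col, pos in enumerate(bitmap.positions):
        gi = pos2group.get(int(pos))
        if gi is None:
            uncovered += 1
            continue
        slices[gi].append(col)
    if uncovered and not allow_uncovered:
        raise EncodingError(
            f"{uncovered} retained bit-columns map to positions outside every "
            "group"
        )
    for gi, sl in enumerate(slices):
        if not sl:
            logger.info("group %r is inert (no retained bit-columns)",
                        groups.names[gi])
    return [np.array(sl, dtype=np.int64) for sl in slices]


def decode(ohm: OneHotMatrix) -> list[str]:
    """Reconstruct sequence rows from a full (pre-filter) encoding.

    Exact for unambiguous data; rows with no bit set at a position decode
    to '-'. Intended for round-trip checks, not production use.
    """
    inv = ohm.bitmap.inverse()
    S = ohm.n_sequences
    all_pos = sorted(inv)
    out = []
    for r in range(S):
        chars = []
        for pos in all_pos:
            cols = inv[pos]
            hot = cols[ohm.X[r, cols] == 1.0]
            chars.append(str(ohm.bitmap.states[hot[0]]) if hot.size else GAP_STATE)
        out.append("".join(chars))
    return out


def write_encoding_tsv(ohm: OneHotMatrix, groups: GroupMap | None, path) -> None:
    """Audit output: one row per bit-column (position, state, group)."""
    pos2group = groups.position_to_group() if groups is not None else {}
    with open(path, "w") as fh:
        fh.write("bit_column\tposition\tstate\tgroup\n")
        for j in range(ohm.n_columns):
            pos = int(ohm.bitmap.positions[j])
            fh.write(
                f"{j}\t{pos}\t{ohm.bitmap.states[j]}\t{pos2group.get(pos, '')}\n"
            )
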