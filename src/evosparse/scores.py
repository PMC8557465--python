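"""Sparsity scores, sequence predictions and ROC curves.

From a fitted model, the strength of association of each unit of the
alignment with the hypothesis is summarized hierarchically:

* BSS (bit sparsity score) — |β| of one bit-column;
* PSS (position sparsity score) — sum of BSS over a position's bit-columns;
* GSS (group sparsity score) — sum of PSS over a gene's positions;
* FSS (functional sparsity score) — sum of GSS over a category's genes
  (a gene in several categories contributes to each);
* HSS (hypothesis sparsity score) — sum of GSS over all genes.

Predictions: SPS is the linear predictor β0 + x·β for a one-hot-encoded
sequence; SPP = 1/(1+exp(−SPS)) is the probability of the +1 class, with
SPP ≥ 0.5 classified as +1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import auc as _sk_auc
from sklearn.metrics import roc_curve as _sk_roc_curve

from .msa_io import Alignment, GroupMap, ambiguity_map
from .encode import GAP_STATE
from .response import ResponseVector
from .sgl import ESLModel


class ScoreError(ValueError):
    pass


@dataclass
class ScoreTable:
    """Hierarchical sparsity scores from one fitted model."""

    bss: pd.Series  # index: bit-column, values |β|
    pss: pd.Series  # index: 1-based position
    gss: pd.Series  # index: group name
    hss: float
    fss: pd.Series | None = None  # index: category name, if categories given


def score_model(
    model: ESLModel,
    groups: GroupMap,
    categories: dict[str, set[str]] | None = None,
) -> ScoreTable:
    """Compute BSS/PSS/GSS/HSS (and FSS when categories are provided).

    Positions and groups without retained bit-columns score 0; every score
    is a sum of |β| values, so all are non-negative and HSS equals the
    total l1 norm of the coefficients.
    """
    if model.bitmap is None:
        raise ScoreError("model carries no bit-column map")
    if model.bitmap.n_columns != model.beta.size:
        raise ScoreError("bit-column map inconsistent with coefficients")
    bss = pd.Series(
        np.abs(model.beta),
        index=pd.RangeIndex(model.beta.size, name="bit_column"),
        name="BSS",
    )
    pos = model.bitmap.positions
    pss_nonzero = pd.Series(bss.to_numpy()).groupby(pos).sum()
    all_positions = sorted(groups.covered_positions() | set(pss_nonzero.index))
    pss = pd.Series(0.0, index=pd.Index(all_positions, name="position"), name="PSS")
    pss.loc[pss_nonzero.index] = pss_nonzero.to_numpy()
    pos2group = groups.position_to_group()
    gss = pd.Series(0.0, index=pd.Index(groups.names, name="group"), name="GSS")
    for position, value in pss.items():
        g = pos2group.get(int(position))
        if g is None:
            if value != 0.0:
                raise ScoreError(
                    f"position {position} has score but belongs to no group"
                )
            continue
        gss[g] += value
    hss = float(gss.sum())
    fss = None
    if categories:
        unknown = {
            g for members in categories.values() for g in members
        } - set(groups.names)
        if unknown:
            raise ScoreError(f"categories reference unknown groups: {sorted(unknown)}")
        fss = pd.Series(
            {cat: float(gss[list(members)].sum()) for cat, members in categories.items()},
            name="FSS",
        )
        fss.index.name = "category"
    return ScoreTable(bss=bss, pss=pss, gss=gss, hss=hss, fss=fss)


def encode_for_model(model: ESLModel, aln: Alignment) -> np.ndarray:
    """One-hot encode sequences against the model's bit-column map.

    States not represented in the map contribute 0 (unknown states carry
    no evidence either way). Ambiguity codes follow the policy the model
    was encoded with.
    """
    bitmap = model.bitmap
    if bitmap is None:
        raise ScoreError("model carries no bit-column map")
    p_needed = int(bitmap.positions.max()) if bitmap.n_columns else 0
    if aln.length < p_needed:
        raise ScoreError(
            f"alignment length {aln.length} shorter than the model's "
            f"maximum position {p_needed}"
        )
    ambig = ambiguity_map(bitmap.alphabet)
    constituent = bitmap.ambiguity_policy == "constituent_bits"
    C = np.array([list(row) for row in aln.rows], dtype="<U1")
    chars = C[:, bitmap.positions - 1]  # (S, c): character at each column's position
    X = (chars == bitmap.states[None, :]).astype(np.float64)
    gap_cols = bitmap.states == GAP_STATE
    if np.any(gap_cols):
        X[:, gap_cols] = np.maximum(X[:, gap_cols], chars[:, gap_cols] == "?")
    if constituent:
        for code, members in ambig.items():
            hit = chars == code
            if not hit.any():
                continue
            member_col = np.isin(bitmap.states, list(members))[None, :]
            X = np.maximum(X, hit & member_col)
    return X


def predict(model: ESLModel, aln: Alignment) -> pd.DataFrame:
    """Per-sequence SPS, SPP and predicted class.

    SPS = β0 + x·β with x the sequence's one-hot row on the model's
    bit-columns; SPP = 1/(1+exp(−SPS)); class +1 iff SPP ≥ 0.5.
    """
    X = encode_for_model(model, aln)
    sps = model.intercept + X @ model.beta
    spp = 1.0 / (1.0 + np.exp(-sps))
    pred = np.where(spp >= 0.5, 1, -1)
    return pd.DataFrame(
        {"taxon": aln.taxa, "SPS": sps, "SPP": spp, "predicted_class": pred}
    )


def roc(records: pd.DataFrame, y: ResponseVector) -> tuple[pd.DataFrame, float]:
    """ROC curve and AUC of SPS against true ±1 labels.

    Thresholds are placed at every distinct SPS value (ties grouped); the
    curve reports the false-positive rate against the true-positive rate
    and the AUC by the trapezoid rule.
    """
    order = {t: i for i, t in enumerate(y.taxa)}
    missing = [t for t in records["taxon"] if t not in order]
    if missing:
        raise ScoreError(f"predictions for unknown taxa: {missing[:5]}")
    truth = np.array([y.y[order[t]] for t in records["taxon"]])
    if len(set(truth)) < 2:
        raise ScoreError("ROC needs both classes present")
    scores = records["SPS"].to_numpy()
    fpr, tpr, thresholds = _sk_roc_curve(truth, scores, pos_label=1)
    curve = pd.DataFrame({"threshold": thresholds, "FPR": fpr, "TPR": tpr})
    return curve, float(_sk_auc(fpr, tpr))
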