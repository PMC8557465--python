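"""Bootstrap and permutation significance machinery.

Point estimates of GSS/PSS say nothing about their stability, so support
is assessed by refitting the whole selection-and-refit pipeline on
resampled data:

* sequence bootstrap — rows resampled with replacement *within each
  class* (class sizes preserved exactly);
* site bootstrap — alignment positions resampled with replacement, each
  sampled position carrying its gene membership along;
* permutation null — class labels assigned by a fair coin, giving the
  distribution of gene inclusion when no true signal exists.

Support of a gene (or position) is the proportion of replicate models in
which its score is positive; the spread of GSS across replicates is
summarized by its coefficient of variation (sd/mean).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .encode import OneHotMatrix
from .response import ResponseVector, balance
from .sgl import BitGroups, ESLModel, FitError, FitOptions, fit, refit_selected

logger = logging.getLogger(__name__)

MAX_FAILURE_FRACTION = 0.10


class ResamplingError(RuntimeError):
    pass


@dataclass
class BootstrapResult:
    """Per-replicate scores and their summaries."""

    reps: int  # successfully fitted replicates
    failed: int
    gss_replicates: pd.DataFrame  # reps × groups
    pss_replicates: pd.DataFrame  # reps × positions
    support_groups: pd.Series
    support_positions: pd.Series
    mean_gss: pd.Series
    sd_gss: pd.Series
    cv_gss: pd.Series  # defined only where mean > 0, else NaN


def _replicate_scores(
    Xm: np.ndarray,
    y: ResponseVector,
    groups: BitGroups,
    positions: np.ndarray,
    opts: FitOptions,
    refit_mode: str,
) -> tuple[pd.Series, pd.Series, bool]:
    """Run select→refit on one replicate; returns (GSS, PSS, converged).

    Scores are aggregated directly from |β| via the group slices and the
    supplied per-column position labels, so site-bootstrap replicates with
    duplicated columns aggregate back onto original coordinates.
    """
    model = fit(Xm, y, groups, opts, penalty="sparse_group")
    ok = model.converged
    selected = model.nonzero_groups(groups)
    if selected:
        final = refit_selected(Xm, y, groups, selected, mode=refit_mode, opts=opts)
        ok = ok and final.converged
    else:
        final = model  # all-zero model: scores are all zero
    absb = np.abs(final.beta)
    gss = pd.Series(
        {
            name: float(absb[sl].sum()) if sl.size else 0.0
            for name, sl in zip(groups.names, groups.slices)
        }
    )
    pss = pd.Series(absb).groupby(positions).sum()
    return gss, pss, ok


def bootstrap(
    X: OneHotMatrix,
    y: ResponseVector,
    groups: BitGroups,
    opts: FitOptions | None = None,
    reps: int = 100,
    mode: str = "sequence",
    seed: int = 0,
    refit_mode: str = "group_lasso",
) -> BootstrapResult:
    """Bootstrap the selection + refit pipeline; support per group/position.

    ``sequence`` mode resamples rows with replacement within each class;
    ``site`` mode resamples alignment positions with replacement (their
    bit-columns and group labels travel together). Replicates that fail to
    converge are excluded and counted; the run errors out if more than 10%
    fail. Deterministic given the seed.
    """
    if reps < 2:
        raise ResamplingError("need at least 2 bootstrap replicates")
    if mode not in ("sequence", "site"):
        raise ResamplingError(f"unknown bootstrap mode {mode!r}")
    opts = opts or FitOptions()
    rng = np.random.default_rng(seed)
    Xm = X.X
    positions = X.bitmap.positions
    pos_idx = np.flatnonzero(y.y > 0)
    neg_idx = np.flatnonzero(y.y < 0)
    all_positions = np.unique(positions)
    # position -> (bit-column indices, group index)
    col_of_pos: dict[int, np.ndarray] = {
        int(p): np.flatnonzero(positions == p) for p in all_positions
    }
    group_of_pos: dict[int, int] = {}
    for gi, sl in enumerate(groups.slices):
        for pos in np.unique(positions[sl]):
            group_of_pos[int(pos)] = gi

    gss_rows, pss_rows = [], []
    failed = 0
    for _ in range(reps):
        if mode == "sequence":
            rows = np.concatenate(
                [
                    rng.choice(pos_idx, size=pos_idx.size, replace=True),
                    rng.choice(neg_idx, size=neg_idx.size, replace=True),
                ]
            )
            y_rep = ResponseVector(
                taxa=[y.taxa[i] for i in rows], y=y.y[rows], weights=y.weights[rows]
            )
            gss, pss, ok = _replicate_scores(
                Xm[rows], y_rep, groups, positions, opts, refit_mode
            )
        else:
            sampled = rng.choice(all_positions, size=all_positions.size, replace=True)
            cols = np.concatenate([col_of_pos[int(p)] for p in sampled])
            pos_labels = positions[cols]
            slices: list[list[int]] = [[] for _ in groups.names]
            offset = 0
            for p in sampled:
                n = col_of_pos[int(p)].size
                slices[group_of_pos[int(p)]].extend(range(offset, offset + n))
                offset += n
            rep_groups = BitGroups(
                names=list(groups.names),
                slices=[np.array(s, dtype=np.int64) for s in slices],
                weights=groups.weights,
            )
            gss, pss, ok = _replicate_scores(
                Xm[:, cols], y, rep_groups, pos_labels, opts, refit_mode
            )
        if not ok:
            failed += 1
            continue
        gss_rows.append(gss)
        pss_rows.append(pss)

    if failed > MAX_FAILURE_FRACTION * reps:
        raise ResamplingError(
            f"{failed}/{reps} bootstrap replicates failed to converge"
        )
    if failed:
        logger.warning("excluded %d non-converged bootstrap replicates", failed)
    gss_df = pd.DataFrame(gss_rows).fillna(0.0)
    pss_df = pd.DataFrame(pss_rows).reindex(columns=all_positions).fillna(0.0)
    mean_gss = gss_df.mean(axis=0)
    sd_gss = gss_df.std(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        cv = sd_gss / mean_gss
    cv[mean_gss <= 0] = np.nan
    return BootstrapResult(
        reps=len(gss_rows),
        failed=failed,
        gss_replicates=gss_df.reset_index(drop=True),
        pss_replicates=pss_df.reset_index(drop=True),
        support_groups=(gss_df > 0).mean(axis=0),
        support_positions=(pss_df > 0).mean(axis=0),
        mean_gss=mean_gss,
        sd_gss=sd_gss,
        cv_gss=cv,
    )


def support_select(
    result: BootstrapResult, threshold: float = 0.95
) -> tuple[list, list]:
    """Groups and positions with support strictly greater than ``threshold``."""
    if not (0.0 < threshold <= 1.0):
        raise ResamplingError("threshold must be in (0, 1]")
    groups = list(result.support_groups[result.support_groups > threshold].index)
    positions = list(
        result.support_positions[result.support_positions > threshold].index
    )
    return groups, positions


@dataclass
class PermutationResult:
    reps: int
    inclusion_frequency: pd.Series  # per group: fraction of null models entered
    per_rep_fraction: np.ndarray  # fraction of groups entering each null model
    summary: dict  # min / median / max of per-group frequencies


def permutation_null(
    X: OneHotMatrix,
    groups: BitGroups,
    opts: FitOptions | None = None,
    reps: int = 20,
    seed: int = 0,
) -> PermutationResult:
    """Gene inclusion under random ±1 labels.

    Each replicate assigns labels by a fair coin (redrawn until both
    classes are non-empty), balances with class weights, fits the
    sparse-group model, and records which genes receive nonzero
    coefficients.
    """
    if reps < 2:
        raise ResamplingError("need at least 2 permutation replicates")
    opts = opts or FitOptions()
    rng = np.random.default_rng(seed)
    S = X.n_sequences
    counts = pd.Series(0.0, index=pd.Index(groups.names, name="group"))
    per_rep = np.zeros(reps)
    for r in range(reps):
        while True:
            yv = rng.choice([-1.0, 1.0], size=S)
            if np.any(yv > 0) and np.any(yv < 0):
                break
        rv = ResponseVector(taxa=list(X.taxa), y=yv)
        rv = balance(rv, mode="class_weights")
        try:
            model = fit(X.X, rv, groups, opts, penalty="sparse_group")
        except FitError:
            continue
        entered = model.nonzero_groups(groups)
        per_rep[r] = len(entered) / len(groups.names)
        for name in entered:
            counts[name] += 1.0
    freq = counts / reps
    return PermutationResult(
        reps=reps,
        inclusion_frequency=freq,
        per_rep_fraction=per_rep,
        summary={
            "min": float(freq.min()),
            "median": float(freq.median()),
            "max": float(freq.max()),
        },
    )
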