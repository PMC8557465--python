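"""End-to-end orchestration: select → refit → score → predict → ROC.

``analyze_branch`` reproduces the canonical analysis for one phylogenetic
partition (or trait): encode the alignment, balance the classes, fit the
sparse-group-lasso model, keep the genes with nonzero coefficients, refit
those genes with a mild group penalty for more reliable coefficients, and
derive scores, per-sequence predictions and a training ROC from the refit
model. ``scan_branches`` repeats this over every eligible internal branch
of a tree.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass

import dendropy
import numpy as np
import pandas as pd

from .encode import OneHotMatrix, filter_monomorphic, one_hot_encode
from .msa_io import Alignment, GroupMap, iter_internal_bipartitions
from .response import ResponseVector, build_response, balance
from .sgl import BitGroups, ESLModel, FitOptions, fit, lambda_max, refit_selected
from .scores import ScoreTable, predict, roc, score_model

logger = logging.getLogger(__name__)

# default regularization as a fraction of λ_max: small values retain the
# strongly associated genes while still zeroing most groups
DEFAULT_LAM1_FRACTION = 0.05
DEFAULT_LAM2_FRACTION = 0.05


class WorkflowError(ValueError):
    pass


@dataclass
class BranchResult:
    """Everything one branch analysis produces."""

    positives: set[str]
    select_model: ESLModel
    refit_model: ESLModel | None
    selected_groups: list[str]
    scores: ScoreTable | None
    predictions: pd.DataFrame | None
    roc_curve: pd.DataFrame | None
    auc: float | None
    opts: FitOptions
    empty: bool = False

    def manifest(self) -> str:
        """Run parameters and headline outputs as JSON, for provenance."""
        return json.dumps(
            {
                "options": dataclasses.asdict(self.opts),
                "n_positive": len(self.positives),
                "selected_groups": self.selected_groups,
                "empty_model": self.empty,
                "auc": self.auc,
                "hss": self.scores.hss if self.scores else 0.0,
            },
            indent=1,
        )


def prepare_design(
    aln: Alignment,
    groups: GroupMap,
    gap_as_state: bool = False,
    ambiguity_policy: str = "missing",
) -> tuple[OneHotMatrix, BitGroups]:
    """Encode, filter monomorphic bit-columns, and attach group slices.

    Positions outside every group are excluded from the design (the
    partition reader already errors on them unless dropping was allowed).
    """
    ohm = filter_monomorphic(
        one_hot_encode(aln, gap_as_state=gap_as_state, ambiguity_policy=ambiguity_policy)
    )
    covered = groups.covered_positions()
    keep = np.flatnonzero(np.isin(ohm.bitmap.positions, sorted(covered)))
    if keep.size < ohm.n_columns:
        logger.info(
            "excluding %d bit-columns at ungrouped positions",
            ohm.n_columns - keep.size,
        )
        ohm = ohm.subset_columns(keep)
    return ohm, BitGroups.from_maps(ohm.bitmap, groups)


def default_options(
    X: OneHotMatrix, y: ResponseVector, seed: int = 0
) -> FitOptions:
    """λ1 and λ2 as fixed small fractions of λ_max for this data set."""
    lmax = lambda_max(X, y)
    return FitOptions(
        lam1=DEFAULT_LAM1_FRACTION * lmax,
        lam2=DEFAULT_LAM2_FRACTION * lmax,
        seed=seed,
    )


def analyze_branch(
    aln: Alignment,
    groups: GroupMap,
    positives: set[str],
    opts: FitOptions | None = None,
    balance_mode: str = "class_weights",
    refit_mode: str = "group_lasso",
    refit_lam: float | None = None,
    categories: dict[str, set[str]] | None = None,
    gap_as_state: bool = False,
    ambiguity_policy: str = "missing",
    seed: int = 0,
) -> BranchResult:
    """One full analysis for a clade/trait bipartition.

    Returns an empty-model result (not an exception) when no group
    survives selection.
    """
    X, bit_groups = prepare_design(
        aln, groups, gap_as_state=gap_as_state, ambiguity_policy=ambiguity_policy
    )
    y_full = build_response(aln.taxa, positives)
    y = y_full
    if balance_mode == "class_weights":
        y = balance(y_full, mode="class_weights")
    elif balance_mode in ("upsample", "downsample"):
        idx = balance(y_full, mode=balance_mode, seed=seed)
        X = X.subset_rows(idx)
        y = ResponseVector(
            taxa=[y_full.taxa[i] for i in idx],
            y=y_full.y[idx],
            weights=y_full.weights[idx],
        )
    elif balance_mode != "none":
        raise WorkflowError(f"unknown balance mode {balance_mode!r}")
    if opts is None:
        opts = default_options(X, y, seed=seed)
    select_model = fit(X, y, bit_groups, opts, penalty="sparse_group")
    selected = select_model.nonzero_groups(bit_groups)
    logger.info(
        "selected %d/%d groups (λ1=%.4g, λ2=%.4g)",
        len(selected), len(bit_groups.names), opts.lam1, opts.lam2,
    )
    if not selected:
        return BranchResult(
            positives=set(positives),
            select_model=select_model,
            refit_model=None,
            selected_groups=[],
            scores=None,
            predictions=None,
            roc_curve=None,
            auc=None,
            opts=opts,
            empty=True,
        )
    refit_model = refit_selected(
        X, y, bit_groups, selected, lam_refit=refit_lam, mode=refit_mode, opts=opts
    )
    table = score_model(refit_model, groups, categories)
    preds = predict(refit_model, aln)
    curve, auc_value = roc(preds, y_full)  # evaluate on the original taxa
    return BranchResult(
        positives=set(positives),
        select_model=select_model,
        refit_model=refit_model,
        selected_groups=selected,
        scores=table,
        predictions=preds,
        roc_curve=curve,
        auc=auc_value,
        opts=opts,
    )


def scan_branches(
    aln: Alignment,
    groups: GroupMap,
    tree: dendropy.Tree,
    opts: FitOptions | None = None,
    min_class_size: int = 2,
    **kwargs,
) -> dict[frozenset, BranchResult]:
    """analyze_branch for every internal branch with both sides ≥ min size.

    Results are keyed by the frozenset of taxa below the branch. Branches
    with an undersized side are logged and skipped; no eligible branch at
    all is an error.
    """
    taxa = set(aln.taxa)
    results: dict[frozenset, BranchResult] = {}
    for node, below in iter_internal_bipartitions(tree):
        if below - taxa:
            raise WorkflowError(
                f"tree leaves missing from alignment: {sorted(below - taxa)[:5]}"
            )
        other = taxa - below
        if len(below) < min_class_size or len(other) < min_class_size:
            logger.info(
                "skipping branch with sides (%d, %d): below minimum class size %d",
                len(below), len(other), min_class_size,
            )
            continue
        results[below] = analyze_branch(aln, groups, set(below), opts=opts, **kwargs)
    if not results:
        raise WorkflowError("no eligible internal branch in the tree")
    return results
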