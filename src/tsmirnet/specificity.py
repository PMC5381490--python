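"""Tissue-specificity statistics for miRNAs and transcription factors.

Two screens live here:

* the fold-change screen for tissue-specific miRNAs — a miRNA is called in a
  tissue when its copy number there is at least ``fold_threshold`` (default
  80) times the mean copy number over the remaining tissues, with an optional
  top-2 variant for miRNAs specific to two tissues; and

* the TSPV / TSVT tissue-specificity score for TFs.  With ``f_b`` the
  fraction of a TF's total expression falling in tissue ``b``,

      TSVT_b = log2(f_b)        (per-tissue;  > -2.5 flags specificity)
      TSPV   = sum_b TSVT_b     (overall; uniform expression over 12 tissues
                                 gives the maximum, 12*log2(1/12) = -43.02)

  More negative TSPV means stronger overall tissue specificity; TSPV bins
  define four categories from "high" (< -120) to "non-tissue-specific"
  (>= -60).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .io_formats import ExpressionMatrix, SchemaError, TISSUES

logger = logging.getLogger(__name__)

#: TSPV of a perfectly uniform 12-tissue profile: 12 * log2(1/12).
UNIFORM_TSPV: float = 12.0 * float(np.log2(1.0 / 12.0))

#: TSPV category bounds (high/medium, medium/low, low/non-specific edges).
DEFAULT_CATEGORY_BOUNDS: tuple[float, float, float, float] = (-160.0, -120.0, -80.0, -60.0)

CATEGORIES = ("high", "medium", "low", "non-tissue-specific")


@dataclass(frozen=True)
class TSCall:
    """A tissue-specific miRNA call: one or two tissues plus fold changes."""

    mirna_name: str
    tissues: tuple[str, ...]
    fold_values: Mapping[str, float]

    def __post_init__(self) -> None:
        if not 1 <= len(self.tissues) <= 2:
            raise ValueError(f"{self.mirna_name}: a call names 1 or 2 tissues")


@dataclass
class SpecificityProfile:
    """TSPV / per-tissue TSVT profile of one entity, with optional category."""

    entity_id: str
    tspv: float
    tsvt: Mapping[str, float]
    category: str | None = None
    specific_tissues: frozenset[str] = field(default_factory=frozenset)


def _fold_changes(row: np.ndarray) -> np.ndarray:
    """Per-tissue fold of a value over the mean of the other tissues (inf when 0)."""
    n = row.size
    other_means = (row.sum() - row) / (n - 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        folds = np.where(
            other_means > 0,
            row / np.where(other_means > 0, other_means, 1.0),
            np.where(row > 0, np.inf, 0.0),
        )
    return folds


def screen_ts_mirnas(
    expr: ExpressionMatrix,
    fold_threshold: float = 80.0,
    max_tissues: int = 2,
) -> list[TSCall]:
    """Call tissue-specific miRNAs by the fold-change rule.

    Single-tissue rule: call miRNA m in tissue t when
    ``x_t / mean(x over the other 11 tissues) >= fold_threshold``.  When
    ``max_tissues == 2`` and no single tissue passes, the top two tissues are
    called jointly when ``min(top-2) / mean(remaining 10) >= fold_threshold``.
    At most one call is made per miRNA.  All-zero rows are skipped with a
    warning.
    """
    if fold_threshold <= 1:
        raise ValueError("fold_threshold must exceed 1")
    if max_tissues not in (1, 2):
        raise ValueError("max_tissues must be 1 or 2")
    if len(expr.tissues) != 12:
        raise SchemaError("the screen is defined over exactly 12 tissues")

    tissues = list(expr.tissues)
    calls: list[TSCall] = []
    for mirna in expr.entity_ids:
        row = expr.row(mirna)
        if not row.any():
            logger.warning("miRNA %s has zero expression everywhere; no call", mirna)
            continue
        folds = _fold_changes(row)
        best = int(np.argmax(folds))
        if folds[best] >= fold_threshold:
            calls.append(
                TSCall(mirna, (tissues[best],), {tissues[best]: float(folds[best])})
            )
            continue
        if max_tissues == 2:
            top2 = np.argsort(row, kind="stable")[-2:]
            rest = np.delete(row, top2)
            rest_mean = rest.mean()
            low = row[top2].min()
            joint = low / rest_mean if rest_mean > 0 else (np.inf if low > 0 else 0.0)
            if joint >= fold_threshold:
                pair = sorted(int(i) for i in top2)
                fold_values = {}
                for i in pair:
                    fi = row[i] / rest_mean if rest_mean > 0 else np.inf
                    fold_values[tissues[i]] = float(fi)
                calls.append(TSCall(mirna, tuple(tissues[i] for i in pair), fold_values))
    return calls


def compute_tspv(
    expr_row: Sequence[float] | np.ndarray,
    epsilon: float | None = None,
    tissues: Sequence[str] = TISSUES,
    entity_id: str = "",
) -> SpecificityProfile:
    """Compute the TSPV score and per-tissue TSVT vector for one entity.

    ``epsilon`` is a pseudocount added to every cell before forming
    expression fractions; the default is ``1e-9 *`` the row sum when any cell
    is zero (log2(0) is undefined) and 0 otherwise.  Raises ``ValueError``
    on all-zero rows.
    """
    row = np.asarray(expr_row, dtype=float)
    if row.size != len(tissues):
        raise SchemaError(f"expected {len(tissues)} tissues, got {row.size}")
    if (row < 0).any():
        raise ValueError("expression values must be non-negative")
    total = row.sum()
    if total == 0:
        raise ValueError(f"undefined profile: entity {entity_id!r} has zero total expression")
    if epsilon is None:
        epsilon = 1e-9 * total if (row == 0).any() else 0.0
    shifted = row + epsilon
    fractions = shifted / shifted.sum()
    tsvt = np.log2(fractions)
    return SpecificityProfile(
        entity_id=entity_id,
        tspv=float(tsvt.sum()),
        tsvt={t: float(v) for t, v in zip(tissues, tsvt)},
    )


def classify_tf_specificity(
    tspv: float,
    bounds: tuple[float, float, float, float] = DEFAULT_CATEGORY_BOUNDS,
) -> str:
    """Map a TSPV score to its tissue-specificity category.

    Half-open bins: high for tspv < bounds[1] (the nominal lower edge
    bounds[0] is treated as open, since lower TSPV only means stronger
    specificity), medium for [bounds[1], bounds[2]), low for
    [bounds[2], bounds[3]), non-tissue-specific at or above bounds[3].
    """
    if tspv > 0:
        raise ValueError(f"TSPV must be <= 0, got {tspv}")
    if not (bounds[0] < bounds[1] < bounds[2] < bounds[3]):
        raise ValueError("category bounds must be strictly increasing")
    if tspv < bounds[1]:
        return "high"
    if tspv < bounds[2]:
        return "medium"
    if tspv < bounds[3]:
        return "low"
    return "non-tissue-specific"


def call_tissue_specific_tf(
    profile: SpecificityProfile, tsvt_threshold: float = -2.5
) -> frozenset[str]:
    """Tissues in which the entity is specifically expressed: TSVT strictly above threshold."""
    return frozenset(t for t, v in profile.tsvt.items() if v > tsvt_threshold)


def specificity_profile(
    entity_id: str,
    expr_row: Sequence[float] | np.ndarray,
    epsilon: float | None = None,
    tsvt_threshold: float = -2.5,
    bounds: tuple[float, float, float, float] = DEFAULT_CATEGORY_BOUNDS,
    tissues: Sequence[str] = TISSUES,
) -> SpecificityProfile:
    """Full profile: TSPV + TSVT + category + per-tissue specificity calls."""
    profile = compute_tspv(expr_row, epsilon=epsilon, tissues=tissues, entity_id=entity_id)
    profile.category = classify_tf_specificity(profile.tspv, bounds)
    profile.specific_tissues = call_tissue_specific_tf(profile, tsvt_threshold)
    return profile


def profile_matrix(
    expr: ExpressionMatrix,
    epsilon: float | None = None,
    tsvt_threshold: float = -2.5,
    bounds: tuple[float, float, float, float] = DEFAULT_CATEGORY_BOUNDS,
) -> dict[str, SpecificityProfile]:
    """Profiles for every row of an expression matrix; all-zero rows are skipped."""
    profiles: dict[str, SpecificityProfile] = {}
    for entity in expr.entity_ids:
        row = expr.row(entity)
        if not row.any():
            logger.warning("entity %s has zero expression everywhere; profile skipped", entity)
            continue
        profiles[entity] = specificity_profile(
            entity, row, epsilon=epsilon, tsvt_threshold=tsvt_threshold,
            bounds=bounds, tissues=expr.tissues,
        )
    return profiles
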