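"""Fuzzy similarity relations, neighborhood granules and the rough decision.

For a normalized attribute ``b``, two samples are similar to the degree
``r_b(x, y) = 1 - |x_b - y_b|``, cut to zero once the distance exceeds
``1 - alpha``.  A subset ``B`` of attributes aggregates by the minimum
(the standard min t-norm), and the fuzzy neighborhood granule of ``x`` is
that aggregated similarity row with every entry below the radius ``alpha``
zeroed.  The granule describes which samples are (and how strongly they
are) indistinguishable from ``x`` under ``B``.

The rough decision RD replaces the crisp class indicator with a graded
membership: the share of a sample's total similarity mass (under the full
attribute set) that falls inside each decision class.  The nonstandard
soft-inclusion cardinality ``|S ∩ T|`` — the number of objects with
*nonzero* membership in S whose S-membership does not exceed their
T-membership — links granules to RD and is the counting primitive of the
uncertainty measures.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np

from .data_model import DecisionTable, ValidationError

__all__ = [
    "SimilarityMatrix",
    "GranuleSet",
    "RoughDecision",
    "attribute_similarity_stack",
    "similarity_from_stack",
    "similarity_matrix",
    "granules",
    "granules_universe",
    "rough_decision",
    "soft_card_leq",
    "granule_decision_counts",
]


@dataclasses.dataclass
class SimilarityMatrix:
    """Fuzzy similarity relation R_B over all sample pairs.

    Reflexive (unit diagonal), symmetric; every off-diagonal entry is
    either zero or at least ``alpha``.
    """

    values: np.ndarray
    attribute_subset: tuple[str, ...]
    alpha: float

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclasses.dataclass
class GranuleSet:
    """Fuzzy neighborhood granules: one fuzzy vector over U per sample.

    Row ``i`` of ``granules`` is the granule of sample ``x_i``; its
    cardinality is the count of nonzero entries (always >= 1 thanks to
    self-similarity).
    """

    granules: np.ndarray
    cardinalities: np.ndarray
    alpha: float


@dataclasses.dataclass
class RoughDecision:
    """n × r matrix of graded memberships of samples to decision classes.

    Entry (i, j) is the similarity mass of sample ``x_i`` inside class
    ``D_j`` divided by its total similarity mass, so each row sums to 1.
    """

    values: np.ndarray
    class_ids: list


def attribute_similarity_stack(
    table: DecisionTable, subset: Sequence[str] | None = None
) -> np.ndarray:
    """Raw (un-cut) per-attribute similarity matrices ``1 - |x_b - y_b|``.

    Returns an array of shape ``(len(subset), n, n)``; ``subset=None``
    means the full attribute set, in table order.  Callers that evaluate
    many attribute subsets build this once and slice it.
    """
    if not table.normalized:
        raise ValidationError("similarity requires a normalized table")
    if subset is None:
        idx = np.arange(table.n_attributes)
    else:
        idx = table.column_indices(subset)
    cols = table.values[:, idx]  # (n, k)
    diffs = np.abs(cols.T[:, :, None] - cols.T[:, None, :])  # (k, n, n)
    return 1.0 - diffs


def similarity_from_stack(stack: np.ndarray, alpha: float) -> np.ndarray:
    """Apply the radius cut per attribute, min-aggregate, and cut again.

    The cut is closed at the boundary: an entry exactly equal to ``alpha``
    survives.  The second cut on the aggregate is implied by the granule
    definition; it is algebraically redundant after the per-attribute cut
    but kept so this function matches the granule semantics verbatim.
    """
    cut = np.where(stack >= alpha, stack, 0.0)
    agg = cut.min(axis=0)
    return np.where(agg >= alpha, agg, 0.0)


def similarity_matrix(
    table: DecisionTable, subset: Sequence[str], alpha: float
) -> SimilarityMatrix:
    """Fuzzy similarity relation R_B for an attribute subset at radius alpha.

    Per attribute, ``r_b = 1 - |x_b - y_b|`` when the distance is at most
    ``1 - alpha`` and zero otherwise; subsets aggregate by the minimum and
    the final alpha cut zeroes any aggregate below the radius.
    """
    if len(subset) == 0:
        raise ValidationError(
            "empty attribute subset; use granules_universe for B = ∅"
        )
    stack = attribute_similarity_stack(table, subset)
    values = similarity_from_stack(stack, alpha)
    return SimilarityMatrix(
        values=values, attribute_subset=tuple(subset), alpha=float(alpha)
    )


def granules(sim: SimilarityMatrix) -> GranuleSet:
    """Fuzzy neighborhood granules from an (already alpha-cut) relation."""
    g = sim.values
    cards = np.count_nonzero(g, axis=1)
    return GranuleSet(granules=g, cardinalities=cards, alpha=sim.alpha)


def granules_universe(n: int) -> GranuleSet:
    """Granules of the empty attribute set: everything relates to everything.

    The empty subset induces the universal indiscernibility relation, so
    every granule is the all-ones vector with cardinality ``n``.  This
    gives the greedy search a well-defined starting entropy.
    """
    return GranuleSet(
        granules=np.ones((n, n)),
        cardinalities=np.full(n, n, dtype=np.intp),
        alpha=0.0,
    )


def rough_decision(sim_full: SimilarityMatrix, labels: np.ndarray) -> RoughDecision:
    """Rough-decision membership matrix from the full-attribute relation.

    ``RD_j(x_i)`` is the similarity mass of ``x_i`` over the members of
    class ``D_j`` divided by its mass over all of U.  The relation should
    be computed over the *full* attribute set A at the working radius
    (the radius cut is part of the similarity relation); the reduction
    holds RD fixed while candidate subsets vary.  Class columns are
    ordered by first appearance of each label.
    """
    import pandas as pd

    sim = sim_full.values
    class_ids = list(pd.unique(labels))
    if len(class_ids) < 2:
        raise ValidationError("rough decision requires at least 2 classes")
    n = sim.shape[0]
    totals = sim.sum(axis=1)  # diagonal is 1, so never zero
    rd = np.empty((n, len(class_ids)))
    for j, cid in enumerate(class_ids):
        mask = labels == cid
        rd[:, j] = sim[:, mask].sum(axis=1) / totals
    return RoughDecision(values=rd, class_ids=class_ids)


def soft_card_leq(S: np.ndarray, T: np.ndarray) -> int:
    """Soft-inclusion cardinality |S ∩ T| of two fuzzy vectors.

    Counts objects with nonzero membership in ``S`` whose membership does
    not exceed their membership in ``T``: ``|{x : 0 < S(x) <= T(x)}|``.
    Ties count; positions where ``S`` is zero never count.
    """
    S = np.asarray(S, dtype=float)
    T = np.asarray(T, dtype=float)
    if S.shape != T.shape:
        raise ValidationError("fuzzy vectors must have equal length")
    return int(np.count_nonzero((S > 0) & (S <= T)))


def granule_decision_counts(
    gset: GranuleSet, rd: RoughDecision, labels: np.ndarray
) -> np.ndarray:
    """Per-sample count |[x_i]_B^alpha ∩ RD_class(i)| (Definition-3 style).

    For each sample the granule row is compared, by soft inclusion, with
    the RD column of the sample's *own* class.  Counts may be zero when a
    sample's self-membership 1 exceeds its own RD value and no other
    sample qualifies; callers decide how to guard the logarithm.
    """
    lookup = {c: j for j, c in enumerate(rd.class_ids)}
    codes = np.array([lookup[c] for c in labels], dtype=np.intp)
    G = gset.granules
    # row i of T_mat is the RD column for x_i's class
    T_mat = rd.values[:, codes].T
    return ((G > 0) & (G <= T_mat)).sum(axis=1).astype(np.intp)
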