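"""Rough uncertainty measures: entropies over granules and significance.

The rough entropy of an attribute subset B treats each sample's granule as
a uniform event space: ``E_c(B) = (1/n) Σ_i log2 |[x_i]_B^α|``.  The joint
entropy of two subsets replaces the granule by the entrywise minimum of
the two granules.  The conditional entropy of the rough decision given B,

    E_c(RD | B) = (1/n) Σ_i log2( |[x_i]_B^α| / |[x_i]_B^α ∩ RD_i| ),

uses the soft-inclusion cardinality against the RD column of each
sample's own class; it is zero exactly when every granule is softly
included in its rough-decision column, and it decomposes as
``E_c(B) − E_c(RD, B)``.  All logarithms are base 2 (bits).

The significance of a candidate attribute is the conditional-entropy drop
it buys: ``SIG(r, red, D) = E_c(RD | red) − E_c(RD | red ∪ {r})``.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np

from .data_model import DecisionTable, ValidationError
from .fuzzy_core import (
    GranuleSet,
    RoughDecision,
    granule_decision_counts,
    granules,
    granules_universe,
    similarity_matrix,
)

__all__ = [
    "EntropyReport",
    "rough_entropy",
    "joint_entropy",
    "decision_joint_entropy",
    "conditional_entropy",
    "entropy_report",
    "conditional_entropy_for_subset",
    "significance",
    "removal_significance",
]


@dataclasses.dataclass
class EntropyReport:
    """The three RUM entropies for one attribute subset, in bits."""

    rough_entropy: float
    joint_entropy_with_decision: float
    conditional_entropy: float
    per_sample_terms: np.ndarray

    def to_dict(self) -> dict:
        return {
            "rough_entropy": self.rough_entropy,
            "joint_entropy_with_decision": self.joint_entropy_with_decision,
            "conditional_entropy": self.conditional_entropy,
            "per_sample_terms": self.per_sample_terms.tolist(),
        }


def rough_entropy(gset: GranuleSet) -> float:
    """``E_c(B) = (1/n) Σ_i log2 |[x_i]_B^α|``; non-negative."""
    return float(np.log2(gset.cardinalities).mean())


def joint_entropy(gset_b: GranuleSet, gset_c: GranuleSet) -> float:
    """Joint rough entropy of two attribute subsets.

    The intersection of two fuzzy granules is the entrywise minimum; its
    cardinality counts nonzero entries.  Self-similarity keeps every
    intersection non-empty.
    """
    if gset_b.granules.shape != gset_c.granules.shape:
        raise ValidationError("granule sets must cover the same universe")
    inter = np.minimum(gset_b.granules, gset_c.granules)
    cards = np.count_nonzero(inter, axis=1)
    return float(np.log2(cards).mean())


def _clamped_counts(
    gset: GranuleSet, rd: RoughDecision, labels: np.ndarray
) -> np.ndarray:
    counts = granule_decision_counts(gset, rd, labels)
    zeros = counts == 0
    if zeros.any():
        warnings.warn(
            f"{int(zeros.sum())} sample(s) had zero granule–decision count; "
            "clamped to 1 (as if only the sample itself counted)",
            RuntimeWarning,
            stacklevel=3,
        )
        counts = np.where(zeros, 1, counts)
    return counts


def decision_joint_entropy(
    gset: GranuleSet, rd: RoughDecision, labels: np.ndarray
) -> float:
    """``E_c(RD, B) = (1/n) Σ_i log2 |[x_i]_B^α ∩ RD_i|``.

    Uses the soft-inclusion cardinality against each sample's own RD
    column, the same counts that appear in the conditional entropy, so
    the decomposition ``E_c(RD|B) = E_c(B) − E_c(RD, B)`` holds exactly.
    """
    counts = _clamped_counts(gset, rd, labels)
    return float(np.log2(counts).mean())


def conditional_entropy(
    gset: GranuleSet, rd: RoughDecision, labels: np.ndarray
) -> float:
    """``E_c(RD | B) = (1/n) Σ_i log2(card_i / count_i)``, in bits.

    ``count_i`` is the granule–decision soft-inclusion count, clamped to a
    minimum of 1 to keep the term finite in the degenerate zero-count
    case.  Always non-negative, since a count never exceeds the granule
    cardinality.
    """
    counts = _clamped_counts(gset, rd, labels)
    return float(np.log2(gset.cardinalities / counts).mean())


def entropy_report(
    gset: GranuleSet, rd: RoughDecision, labels: np.ndarray
) -> EntropyReport:
    """All three entropies plus the per-sample log terms."""
    counts = _clamped_counts(gset, rd, labels)
    terms = np.log2(gset.cardinalities / counts)
    return EntropyReport(
        rough_entropy=rough_entropy(gset),
        joint_entropy_with_decision=float(np.log2(counts).mean()),
        conditional_entropy=float(terms.mean()),
        per_sample_terms=terms,
    )


def conditional_entropy_for_subset(
    table: DecisionTable,
    subset: Sequence[str],
    rd: RoughDecision,
    alpha: float,
) -> float:
    """``E_c(RD | B)`` for an attribute subset, with ``B = ∅`` supported.

    The empty subset uses the universal granule (all-ones, cardinality n),
    giving the greedy search a well-defined starting point.
    """
    if len(subset) == 0:
        gset = granules_universe(table.n_samples)
    else:
        gset = granules(similarity_matrix(table, subset, alpha))
    return conditional_entropy(gset, rd, table.labels)


def significance(
    candidate: str,
    current: Sequence[str],
    table: DecisionTable,
    rd: RoughDecision,
    alpha: float,
) -> float:
    """Conditional-entropy drop from adding ``candidate`` to ``current``.

    ``SIG(r, red, D) = E_c(RD | red) − E_c(RD | red ∪ {r})``.  An exact
    duplicate of an attribute already in ``current`` leaves every granule
    unchanged and scores zero.
    """
    if candidate in current:
        raise ValidationError(f"candidate {candidate!r} already in the subset")
    before = conditional_entropy_for_subset(table, current, rd, alpha)
    after = conditional_entropy_for_subset(
        table, [*current, candidate], rd, alpha
    )
    return before - after


def removal_significance(
    attribute: str,
    full: Sequence[str],
    table: DecisionTable,
    rd: RoughDecision,
    alpha: float,
) -> float:
    """Entropy rise from removing ``attribute`` from the subset ``full``.

    ``SIG(a, A, D) = E_c(RD | A − {a}) − E_c(RD | A)``; zero means the
    attribute is unnecessary given the rest.
    """
    if attribute not in full:
        raise ValidationError(f"attribute {attribute!r} not in the subset")
    rest = [a for a in full if a != attribute]
    with_a = conditional_entropy_for_subset(table, full, rd, alpha)
    without_a = conditional_entropy_for_subset(table, rest, rd, alpha)
    return without_a - with_a
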