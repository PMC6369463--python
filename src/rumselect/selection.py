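"""Greedy variable-precision attribute reduction and the (α, β) grid sweep.

The reduction starts from the empty subset and repeatedly adds the
attribute with the largest significance — the biggest drop in the
conditional entropy of the rough decision — until the variable-precision
stopping rule is met:

    E_c(RD | red) − E_c(RD | A) ≤ β.

β is a tolerance in bits: with β = 0 the reduct must match the full
attribute set's conditional entropy exactly, while a positive β tolerates
noise by accepting a slightly coarser subset.  The rough decision RD is
computed once from the full attribute set (un-cut similarity) and held
fixed while candidate subsets vary; only the granules depend on the
radius α.  Ties in significance break toward the smaller attribute index,
making the procedure fully deterministic.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np

from .data_model import DecisionTable, SelectionConfig, ValidationError
from .evaluation import EvalResult, evaluate
from .fuzzy_core import (
    GranuleSet,
    RoughDecision,
    SimilarityMatrix,
    attribute_similarity_stack,
    granules_universe,
    rough_decision,
    similarity_from_stack,
)
from .uncertainty import conditional_entropy

# below this significance an attribute buys nothing; guards non-termination
_SIG_FLOOR = 1e-12

__all__ = ["ReductStep", "ReductTrace", "SweepRow", "SweepResult", "reduce", "prune", "sweep"]


@dataclasses.dataclass
class ReductStep:
    """One greedy step: the attribute added, its significance and the
    conditional entropy of the subset after adding it (both in bits)."""

    attribute: str
    significance: float
    conditional_entropy: float


@dataclasses.dataclass
class ReductTrace:
    """Result of one greedy reduction run."""

    selected: list[str]
    per_step: list[ReductStep]
    baseline_entropy: float  # E_c(RD | A)
    empty_set_entropy: float  # E_c(RD | ∅)
    alpha: float
    beta: float
    stalled: bool = False  # no candidate had positive significance
    pruned: bool = False
    _final_entropy: float | None = None  # set after pruning

    @property
    def final_entropy(self) -> float:
        if self._final_entropy is not None:
            return self._final_entropy
        if self.per_step:
            return self.per_step[-1].conditional_entropy
        return self.empty_set_entropy

    @property
    def gap(self) -> float:
        """E_c(RD | red) − E_c(RD | A), the quantity compared with β."""
        return self.final_entropy - self.baseline_entropy

    @property
    def satisfied(self) -> bool:
        return self.gap <= self.beta

    def to_dict(self, one_based_indices: Sequence[int] | None = None) -> dict:
        out = {
            "selected": list(self.selected),
            "alpha": self.alpha,
            "beta": self.beta,
            "baseline_entropy": self.baseline_entropy,
            "empty_set_entropy": self.empty_set_entropy,
            "final_entropy": self.final_entropy,
            "gap": self.gap,
            "satisfied": self.satisfied,
            "stalled": self.stalled,
            "per_step": [
                {
                    "attribute": s.attribute,
                    "significance": s.significance,
                    "conditional_entropy": s.conditional_entropy,
                }
                for s in self.per_step
            ],
        }
        if one_based_indices is not None:
            out["selected_indices_1based"] = list(one_based_indices)
        return out


class _GranuleEngine:
    """Caches per-attribute similarity so subset entropies are cheap.

    Holds the raw (un-cut) per-attribute similarity stack and the fixed
    rough decision; evaluates E_c(RD | B) for any attribute-index subset
    expressed as a running entrywise minimum.
    """

    def __init__(self, table: DecisionTable, alpha: float):
        self.table = table
        self.alpha = float(alpha)
        self.n = table.n_samples
        self.stack = attribute_similarity_stack(table)  # (m, n, n), raw
        # RD comes from the full attribute set at the working radius: the
        # radius cut is part of the similarity relation itself, so the
        # rough decision sums run over the cut relation.
        full = similarity_from_stack(self.stack, self.alpha)
        self.rd: RoughDecision = rough_decision(
            SimilarityMatrix(full, tuple(table.attribute_ids), self.alpha),
            table.labels,
        )
        lookup = {c: j for j, c in enumerate(self.rd.class_ids)}
        codes = np.array([lookup[c] for c in table.labels], dtype=np.intp)
        self._T = self.rd.values[:, codes].T  # row i = RD column of x_i's class

    def cut_attr(self, j: int) -> np.ndarray:
        """Per-attribute similarity with the radius cut applied."""
        s = self.stack[j]
        return np.where(s >= self.alpha, s, 0.0)

    def entropy_of_min(self, agg_min: np.ndarray) -> float:
        """E_c(RD | B) where ``agg_min`` is the min of the cut per-attribute
        matrices over B (the final α cut is applied here)."""
        G = np.where(agg_min >= self.alpha, agg_min, 0.0)
        cards = np.count_nonzero(G, axis=1)
        counts = ((G > 0) & (G <= self._T)).sum(axis=1)
        counts = np.maximum(counts, 1)  # degenerate zero-count guard
        return float(np.log2(cards / counts).mean())

    def empty_entropy(self) -> float:
        gset = granules_universe(self.n)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            return conditional_entropy(gset, self.rd, self.table.labels)

    def full_entropy(self) -> float:
        return self.entropy_of_min(
            np.minimum.reduce([self.cut_attr(j) for j in range(self.stack.shape[0])])
        )


def reduce(table: DecisionTable, config: SelectionConfig) -> ReductTrace:
    """Greedy forward attribute reduction under the β stopping rule.

    Starting from the empty subset, each iteration scores every remaining
    attribute by its significance, adds the best (ties to the smallest
    index) and re-tests ``E_c(RD|red) − E_c(RD|A) ≤ β``.  If no candidate
    improves the entropy by more than a floor of 1e-12 bits before the
    rule is met, the search stops with the best-effort subset and the
    trace is flagged ``stalled``.
    """
    if not table.normalized:
        raise ValidationError("reduce requires a normalized table")
    table.validate()
    engine = _GranuleEngine(table, config.alpha)
    baseline = engine.full_entropy()
    empty = engine.empty_entropy()

    trace = ReductTrace(
        selected=[],
        per_step=[],
        baseline_entropy=baseline,
        empty_set_entropy=empty,
        alpha=config.alpha,
        beta=config.beta,
    )
    if empty - baseline <= config.beta:
        warnings.warn(
            "the stopping rule is met by the empty attribute set "
            f"(gap {empty - baseline:.4g} <= beta {config.beta:g}); "
            "no attribute selected",
            RuntimeWarning,
            stacklevel=2,
        )
        return trace

    m = table.n_attributes
    remaining = list(range(m))
    current_min = np.ones((engine.n, engine.n))
    current_entropy = empty
    while remaining:
        entropies = np.array(
            [
                engine.entropy_of_min(np.minimum(current_min, engine.cut_attr(j)))
                for j in remaining
            ]
        )
        sigs = current_entropy - entropies
        best = int(np.argmax(sigs))  # first max → smallest attribute index
        if sigs[best] <= _SIG_FLOOR:
            trace.stalled = True
            warnings.warn(
                "no remaining attribute has positive significance but the "
                f"beta criterion is unmet (gap {current_entropy - baseline:.4g} "
                f"> beta {config.beta:g}); returning best-effort subset",
                RuntimeWarning,
                stacklevel=2,
            )
            break
        j = remaining.pop(best)
        current_min = np.minimum(current_min, engine.cut_attr(j))
        current_entropy = float(entropies[best])
        trace.selected.append(table.attribute_ids[j])
        trace.per_step.append(
            ReductStep(
                attribute=table.attribute_ids[j],
                significance=float(sigs[best]),
                conditional_entropy=current_entropy,
            )
        )
        if current_entropy - baseline <= config.beta:
            break
    return trace


def prune(table: DecisionTable, trace: ReductTrace, config: SelectionConfig) -> ReductTrace:
    """Backward pass: drop attributes whose removal keeps the β criterion.

    Scans the selected attributes in reverse selection order and removes
    any whose absence still satisfies
    ``E_c(RD | red − {b}) − E_c(RD | A) ≤ β``.  Returns a new trace with
    the pruned subset (per-step history kept from the forward pass).
    """
    engine = _GranuleEngine(table, config.alpha)
    kept = list(trace.selected)
    for attr in reversed(trace.selected):
        if len(kept) <= 1:
            break
        candidate = [a for a in kept if a != attr]
        idx = table.column_indices(candidate)
        agg = np.minimum.reduce([engine.cut_attr(j) for j in idx])
        if engine.entropy_of_min(agg) - trace.baseline_entropy <= config.beta:
            kept = candidate
    if kept == trace.selected:
        return trace
    idx = table.column_indices(kept)
    agg = np.minimum.reduce([engine.cut_attr(j) for j in idx])
    final = engine.entropy_of_min(agg)
    return dataclasses.replace(trace, selected=kept, pruned=True, _final_entropy=final)


@dataclasses.dataclass
class SweepRow:
    alpha: float
    beta: float
    subset_size: int
    selected: tuple[str, ...]
    accuracy_svm: float
    accuracy_knn: float


@dataclasses.dataclass
class SweepResult:
    """All (α, β) grid rows with the reducts and their CV accuracies."""

    rows: list[SweepRow]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            [
                {
                    "alpha": r.alpha,
                    "beta": r.beta,
                    "subset_size": r.subset_size,
                    "selected": ";".join(r.selected),
                    "accuracy_svm": r.accuracy_svm,
                    "accuracy_knn": r.accuracy_knn,
                }
                for r in self.rows
            ]
        )

    def best_row(self, classifier: str = "svm") -> SweepRow:
        """Row with the highest CV accuracy; ties break toward the smaller
        subset, then grid order.  Rows with empty subsets are skipped."""
        key = {"svm": lambda r: r.accuracy_svm, "knn": lambda r: r.accuracy_knn}[classifier]
        candidates = [r for r in self.rows if r.subset_size > 0]
        if not candidates:
            raise ValidationError("no sweep row selected a non-empty subset")
        return max(candidates, key=lambda r: (key(r), -r.subset_size))


def _grid(step: float, stop: float = 0.5) -> list[float]:
    k = int(round(stop / step))
    if abs(k * step - stop) > 1e-9:
        raise ValidationError(f"grid_step {step} does not divide the range [0, {stop}]")
    return [round(i * step, 10) for i in range(k + 1)]


def sweep(
    table: DecisionTable,
    config: SelectionConfig,
    with_evaluation: bool = True,
) -> SweepResult:
    """Run reduce (and optionally CV evaluation) at every (α, β) grid point.

    The grid is ``{0, grid_step, ..., 0.5}²``.  Deterministic for a fixed
    ``rng_seed`` (the reduction itself has no randomness; the seed fixes
    the cross-validation folds).  Rows whose reduct is empty carry NaN
    accuracies.
    """
    values = _grid(config.grid_step)
    rows: list[SweepRow] = []
    acc_cache: dict[tuple[str, ...], tuple[float, float]] = {}
    for alpha in values:
        for beta in values:
            cfg = dataclasses.replace(config, alpha=alpha, beta=beta)
            with warnings.catch_warnings():
                warnings.simplefilter("ignore", RuntimeWarning)
                trace = reduce(table, cfg)
            subset = tuple(trace.selected)
            if subset and with_evaluation:
                if subset not in acc_cache:
                    res: EvalResult = evaluate(table, trace.selected, cfg)
                    acc_cache[subset] = (res.accuracy_svm, res.accuracy_knn)
                acc_svm, acc_knn = acc_cache[subset]
            else:
                acc_svm = acc_knn = float("nan")
            rows.append(
                SweepRow(
                    alpha=alpha,
                    beta=beta,
                    subset_size=len(subset),
                    selected=subset,
                    accuracy_svm=acc_svm,
                    accuracy_knn=acc_knn,
                )
            )
    return SweepResult(rows=rows)
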