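"""Synthetic decision tables with known ground truth, plus desk fixtures.

The generator plants three kinds of attributes so the selector's behavior
is fully checkable without external downloads:

* *informative* — class-conditional Gaussians whose class means are spaced
  ``effect_size`` apart (in normalized units) with within-class spread
  ``noise_sd``;
* *redundant* — exact duplicates of informative attributes, which a sound
  significance measure must never pick once the parent is in;
* *noise* — uniform on [0, 1], independent of the class.

Columns are clipped into [0, 1] and then min-max rescaled per column so
the similarity semantics stay valid.  It does not emulate gene–gene
correlation structure beyond the planted redundancy, batch effects, or
heavy-tailed expression noise — recovery results on it bound what the
selector can do under its own assumptions, not on real microarrays.

Two tiny desk fixtures used throughout the tests are also defined here:
a pair of ten-element fuzzy membership vectors, and a 5 × 5 fuzzy
similarity matrix with a two-class decision ({x1,x2,x3} vs {x4,x5}).
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .data_model import DecisionTable, ValidationError
from .fuzzy_core import SimilarityMatrix

__all__ = [
    "SyntheticSpec",
    "generate",
    "fixture_example1",
    "fixture_example2",
]


@dataclasses.dataclass(frozen=True)
class SyntheticSpec:
    """Recipe for a synthetic decision table.

    Defaults plant two informative attributes whose individual class
    separation (effect 0.6, spread 0.2, i.e. 3 sd between means) is
    deliberately imperfect: one attribute alone misclassifies a few
    percent of samples, both together are near-perfect, so the planted
    pair — not any single attribute — is the accuracy-optimal subset.
    """

    n_samples: int = 60
    n_classes: int = 2
    n_informative: int = 2
    n_redundant: int = 1
    n_noise: int = 5
    effect_size: float = 0.6
    noise_sd: float = 0.2
    rng_seed: int = 7

    def __post_init__(self) -> None:
        if self.n_informative < 1:
            raise ValidationError("at least one informative attribute is required")
        if min(self.n_redundant, self.n_noise) < 0:
            raise ValidationError("attribute counts must be non-negative")
        if self.n_classes < 2:
            raise ValidationError("at least two classes are required")
        if self.n_samples < 2 * self.n_classes:
            raise ValidationError("need at least two samples per class")
        if self.effect_size <= 0:
            raise ValidationError("effect_size must be positive")
        if self.noise_sd <= 0:
            raise ValidationError("noise_sd must be positive")

    @property
    def informative_ids(self) -> list[str]:
        return [f"inf{k + 1}" for k in range(self.n_informative)]

    @property
    def redundant_ids(self) -> list[str]:
        return [f"dup{k + 1}" for k in range(self.n_redundant)]

    @property
    def noise_ids(self) -> list[str]:
        return [f"noise{k + 1}" for k in range(self.n_noise)]

    @property
    def redundant_parents(self) -> dict[str, str]:
        """Which informative attribute each duplicate copies."""
        return {
            f"dup{k + 1}": self.informative_ids[k % self.n_informative]
            for k in range(self.n_redundant)
        }


def generate(spec: SyntheticSpec) -> DecisionTable:
    """Draw a normalized decision table from a :class:`SyntheticSpec`.

    Labels are balanced (sample counts across classes differ by at most
    one) and shuffled; informative class means are centered on 0.5 and
    spaced ``effect_size`` apart; the whole draw is reproducible from
    ``rng_seed``.
    """
    rng = np.random.default_rng(spec.rng_seed)
    n, k = spec.n_samples, spec.n_classes

    counts = [n // k + (1 if c < n % k else 0) for c in range(k)]
    codes = np.repeat(np.arange(k), counts)
    rng.shuffle(codes)
    labels = np.array([f"c{c + 1}" for c in codes], dtype=object)

    means = 0.5 + (np.arange(k) - (k - 1) / 2) * spec.effect_size
    columns: list[np.ndarray] = []
    for _ in range(spec.n_informative):
        col = rng.normal(means[codes], spec.noise_sd)
        columns.append(np.clip(col, 0.0, 1.0))
    parents = spec.redundant_parents
    for dup_id in spec.redundant_ids:
        parent_pos = spec.informative_ids.index(parents[dup_id])
        columns.append(columns[parent_pos].copy())
    for _ in range(spec.n_noise):
        columns.append(rng.uniform(0.0, 1.0, size=n))

    values = np.column_stack(columns)
    # per-column min-max rescale keeps everything exactly in [0, 1]
    mins = values.min(axis=0)
    spans = values.max(axis=0) - mins
    spans[spans == 0] = 1.0
    values = (values - mins) / spans

    table = DecisionTable(
        values=values,
        labels=labels,
        attribute_ids=spec.informative_ids + spec.redundant_ids + spec.noise_ids,
        class_ids=[f"c{c + 1}" for c in range(k)],
        normalized=True,
    )
    table.validate()
    return table


def fixture_example1() -> tuple[np.ndarray, np.ndarray]:
    """Two fuzzy membership vectors S, T over a ten-sample universe.

    The classic desk example for the soft-inclusion cardinality:
    ``|S ∩ T| = 4`` (x2, x6, x8, x9) and ``|T ∩ S| = 8``.
    """
    S = np.array([0.7, 0.4, 0.5, 0.7, 0.8, 0.3, 0.5, 0.1, 0.2, 0.6])
    T = np.array([0.5, 0.4, 0.3, 0.6, 0.4, 0.7, 0.4, 0.9, 0.2, 0.3])
    return S, T


def fixture_example2() -> tuple[SimilarityMatrix, np.ndarray]:
    """A 5 × 5 fuzzy similarity relation with a two-class decision.

    The matrix is a literal constant (it is the example's input, not
    derived from attribute values); classes are D1 = {x1, x2, x3} and
    D2 = {x4, x5}.  At radius 0 its granule cardinalities are
    (3, 5, 5, 4, 4) and the conditional entropy of the rough decision
    is 1.0118 bits.
    """
    values = np.array(
        [
            [1.00, 0.53, 0.70, 0.00, 0.00],
            [0.53, 1.00, 0.70, 0.20, 0.62],
            [0.70, 0.70, 1.00, 0.11, 0.50],
            [0.00, 0.20, 0.11, 1.00, 0.70],
            [0.00, 0.62, 0.50, 0.70, 1.00],
        ]
    )
    labels = np.array(["d1", "d1", "d1", "d2", "d2"], dtype=object)
    sim = SimilarityMatrix(values=values, attribute_subset=("A",), alpha=0.0)
    return sim, labels
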