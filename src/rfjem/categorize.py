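"""Percentile-based exposure categories anchored in the control distribution.

Exposure is skewed, so the analysis uses ordered categories rather than a
continuous term: cut-points at the 50th, 75th and 90th percentiles of the
exposure distribution among *exposed* controls define five levels —
0 = never exposed (the reference group in the primary analysis),
1 = (0, p50], 2 = (p50, p75], 3 = (p75, p90], 4 = (p90, inf).  Values equal
to a cut-point fall in the lower category.  A sensitivity variant rebases
the reference on the low-exposed group (category 1) instead.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .errors import UndefinedCutpointsError

CATEGORY_LABELS = {
    0: "unexposed",
    1: "(0, p50]",
    2: "(p50, p75]",
    3: "(p75, p90]",
    4: "(p90, inf)",
}

N_CATEGORIES = 5


@dataclass(frozen=True)
class CutpointSet:
    """Cut-points for one metric x label x method x field cell.

    Derived only from exposed controls; cases never influence cut-points.
    """

    p50: float
    p75: float
    p90: float
    n_exposed_controls: int
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.p50 <= self.p75 <= self.p90):
            raise ValueError(f"cut-points must be ordered, got {self}")

    def as_array(self) -> np.ndarray:
        return np.array([self.p50, self.p75, self.p90])


def cutpoints(control_values, probs=(0.5, 0.75, 0.9), label: str = "",
              include_zeros: bool = False) -> CutpointSet:
    """Empirical quantiles of the exposed-control exposure distribution.

    Quantiles use linear interpolation between order statistics.  By default
    only strictly positive (exposed) values enter; ``include_zeros=True`` is
    a robustness-check variant.
    """
    values = np.asarray(control_values, dtype=float)
    if not include_zeros:
        values = values[values > 0]
    if values.size == 0:
        raise UndefinedCutpointsError("no exposed controls: cut-points undefined")
    q = np.quantile(values, probs)
    return CutpointSet(p50=float(q[0]), p75=float(q[1]), p90=float(q[2]),
                       n_exposed_controls=int(values.size), label=label)


def assign_category(value: float, exposed: bool, c: CutpointSet) -> int:
    """Ordinal category of one exposure value (0 iff never exposed)."""
    if not exposed:
        return 0
    if value <= c.p50:
        return 1
    if value <= c.p75:
        return 2
    if value <= c.p90:
        return 3
    return 4


def assign_categories(values, exposed, c: CutpointSet) -> np.ndarray:
    """Vectorized :func:`assign_category`."""
    values = np.asarray(values, dtype=float)
    exposed = np.asarray(exposed, dtype=bool)
    # searchsorted with side="left": value == cutpoint stays in lower category
    cats = 1 + np.searchsorted(c.as_array(), values, side="left")
    cats[~exposed] = 0
    return cats.astype(int)


@dataclass(frozen=True)
class CategorizedExposure:
    """Category codes plus the level serving as the model reference group."""

    codes: np.ndarray
    reference: int = 0

    @property
    def non_reference_levels(self) -> list[int]:
        return [k for k in range(N_CATEGORIES) if k != self.reference]

    def indicators(self) -> np.ndarray:
        """(n, 4) indicator matrix for the non-reference levels, in order."""
        return np.column_stack(
            [(self.codes == k).astype(float) for k in self.non_reference_levels]
        )


def categorize(values, exposed, c: CutpointSet) -> CategorizedExposure:
    return CategorizedExposure(codes=assign_categories(values, exposed, c))


def rebase_reference(cats: CategorizedExposure) -> CategorizedExposure:
    """Move the reference group to the low-exposed category (level 1).

    Pure relabelling: codes are untouched, the unexposed level becomes an
    ordinary non-reference contrast.
    """
    return replace(cats, reference=1)
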