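"""Label construction and rating-consistency statistics.

Two labelling schemes map perceived-difficulty ratings onto the unit
interval that the network's sigmoid output lives in:

* **individual** — each participant's own 7-point rating ``r`` becomes
  ``(r - 1) / 6``, i.e. seven equidistant labels 0, 0.1667, ..., 1.  One
  level of workload (LoW) therefore spans 1/6 of label space, and a mean
  absolute label error ``e`` converts to ``6 e`` LoW.
* **group** — each puzzle's mean rating over all participants is min-max
  normalised, giving one (generally non-equidistant) label per puzzle
  with the easiest puzzle at 0 and the hardest at 1.

Rating consistency is summarised by Cronbach's alpha, computable with
either puzzles or participants as test items.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LabelScheme",
    "individual_label",
    "individual_label_values",
    "group_labels",
    "low_from_error",
    "cronbach_alpha",
]

#: Width of one workload level in label space under the individual scheme.
LEVEL_WIDTH = 1.0 / 6.0


@dataclass
class LabelScheme:
    """A named labelling scheme with its sorted label values."""

    scheme: str                 # "individual" or "group"
    label_values: np.ndarray    # sorted ascending, within [0, 1]

    def __post_init__(self) -> None:
        self.label_values = np.asarray(self.label_values, dtype=np.float64)
        if np.any(np.diff(self.label_values) < 0):
            raise ValueError("label values must be sorted ascending")


def individual_label(rating) -> float | np.ndarray:
    """Map a 7-point difficulty rating onto [0, 1]: ``(rating - 1) / 6``.

    Rating 1 maps to 0, rating 2 to 0.1667, ..., rating 7 to 1.
    """
    r = np.asarray(rating)
    if np.any((r < 1) | (r > 7)) or not np.issubdtype(r.dtype, np.number):
        raise ValueError("ratings must lie in 1..7")
    out = (r - 1.0) / 6.0
    return float(out) if np.isscalar(rating) else out


def individual_label_values() -> np.ndarray:
    """The seven equidistant individual-scheme label values."""
    return np.arange(7) / 6.0


def inverse_individual_label(label) -> np.ndarray:
    """Recover the integer rating from an exact individual label."""
    return np.rint(np.asarray(label) * 6.0).astype(int) + 1


def group_labels(mean_ratings) -> np.ndarray:
    """Min-max normalise per-puzzle mean ratings onto [0, 1].

    The puzzle with the lowest mean rated difficulty gets label 0, the
    highest gets 1; intermediate puzzles land proportionally (and hence
    non-equidistantly) in between.  Invariant under positive affine
    transformations of the input.
    """
    m = np.asarray(mean_ratings, dtype=np.float64)
    if m.size < 2:
        raise ValueError("group labels need at least 2 puzzles")
    lo, hi = m.min(), m.max()
    if hi == lo:
        raise ValueError("degenerate input: all mean ratings equal")
    return (m - lo) / (hi - lo)


def low_from_error(mean_abs_label_error: float) -> float:
    """Convert a mean absolute label error into levels of workload.

    One level spans 1/6 of label space, so the conversion is a factor 6
    (e.g. an error of 0.1642 is 0.985 LoW).
    """
    e = float(mean_abs_label_error)
    if e < 0:
        raise ValueError("error must be >= 0")
    return e / LEVEL_WIDTH


def cronbach_alpha(matrix, orientation: str = "puzzles-as-items") -> float:
    """Cronbach's alpha of a participants x puzzles rating matrix.

    ``alpha = k/(k-1) * (1 - sum(item variances) / var(item sums))`` with
    sample variances (n-1 denominator).  Orientation chooses the test
    items: ``"puzzles-as-items"`` treats columns as items (consistency of
    the puzzles as a difficulty instrument), ``"participants-as-items"``
    transposes first (consistency of the raters).  Rows containing NaN
    are dropped (listwise deletion).
    """
    x = np.asarray(matrix, dtype=np.float64)
    if x.ndim != 2:
        raise ValueError("rating matrix must be 2-D (participants x puzzles)")
    if orientation == "participants-as-items":
        x = x.T
    elif orientation != "puzzles-as-items":
        raise ValueError(f"unknown orientation {orientation!r}")
    x = x[~np.isnan(x).any(axis=1)]
    n, k = x.shape
    if k < 2 or n < 2:
        raise ValueError("alpha needs >= 2 items and >= 2 observations")
    total_var = x.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise ValueError("degenerate input: zero total-score variance")
    item_vars = x.var(axis=0, ddof=1)
    return float(k / (k - 1) * (1.0 - item_vars.sum() / total_var))
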