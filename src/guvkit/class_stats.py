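"""Contingency statistics for categorical nanotube/tethering outcomes.

Nanotube assemblies observed by cryo-EM fall into classes (disordered,
stacked, isolated); differences between two conditions in the proportion
falling in one class are tested with the pooled two-proportion z-test
without continuity correction, reported equivalently as a 1-df chi-square
(chi2 = z^2). The uncorrected form is deliberate: it is the dialect of the
chi-square test these class comparisons use.

Reference count tables for ezrin nanotube assemblies are included as module
data. The ezrinWT counts follow directly from the published percentages
(58% stacked, 42% isolated of N = 62); the ezrinTD stacked count is not
printed and is reconstructed as 60 - 41 - 15 = 4 from the printed 68.5%
disordered (41 tubes) and 25% isolated (15 tubes) — an inference, flagged
as such.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import sqrt
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import erfc

ASSEMBLY_CLASSES = ("disordered", "stacked", "isolated")

# ezrinTD nanotube classes, N = 60. "stacked" is reconstructed (see module
# docstring), not directly printed.
EZRIN_TD_COUNTS = {"disordered": 41, "stacked": 4, "isolated": 15}
EZRIN_TD_STACKED_INFERRED = True
# ezrinWT nanotube classes, N = 62.
EZRIN_WT_COUNTS = {"disordered": 0, "stacked": 36, "isolated": 26}


@dataclass
class ClassCounts:
    """Per-group counts over a shared set of outcome classes."""

    groups: Sequence[str]
    classes: Sequence[str]
    counts: np.ndarray  # shape (n_groups, n_classes)

    def __post_init__(self) -> None:
        c = np.asarray(self.counts, dtype=int)
        if c.shape != (len(self.groups), len(self.classes)):
            raise ValueError("counts shape must be (n_groups, n_classes)")
        if np.any(c < 0):
            raise ValueError("counts must be non-negative")
        if np.any(c.sum(axis=1) <= 0):
            raise ValueError("each group total must be > 0")
        self.counts = c

    @property
    def totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)


def two_proportion_test(x1: int, n1: int, x2: int, n2: int
                        ) -> tuple[float, float, float]:
    """Pooled two-proportion z-test, no continuity correction.

    Returns (chi2, z, p) with chi2 = z^2 on 1 df and p the two-sided normal
    tail probability. Identical proportions give z = 0, p = 1.
    """
    for x, n in ((x1, n1), (x2, n2)):
        if n <= 0:
            raise ValueError("group totals must be > 0")
        if not (0 <= x <= n):
            raise ValueError("successes must satisfy 0 <= x <= n")
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    se = sqrt(pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2))
    if se == 0:  # pooled proportion 0 or 1: no variability
        return 0.0, 0.0, 1.0
    z = (p1 - p2) / se
    # two-sided normal p; erfc stays accurate in the far tail
    p = float(erfc(abs(z) / sqrt(2.0)))
    return z * z, z, p


def percent_table(counts: ClassCounts, decimals: int = 1) -> pd.DataFrame:
    """Per-group class percentages (rows sum to 100 up to rounding)."""
    pct = 100.0 * counts.counts / counts.totals[:, None]
    return pd.DataFrame(np.round(pct, decimals), index=list(counts.groups),
                        columns=list(counts.classes))


def class_test_table(counts: ClassCounts) -> pd.DataFrame:
    """Two-group per-class comparison: z, chi2 and p for every class.

    Requires exactly two groups; each class is tested as present/absent
    between the groups with :func:`two_proportion_test`.
    """
    if len(counts.groups) != 2:
        raise ValueError("class_test_table needs exactly two groups")
    n1, n2 = counts.totals
    rows = []
    for j, cls in enumerate(counts.classes):
        chi2, z, p = two_proportion_test(
            int(counts.counts[0, j]), int(n1),
            int(counts.counts[1, j]), int(n2))
        rows.append({"class": cls, "chi2": chi2, "z": z, "p": p})
    return pd.DataFrame(rows)


def ezrin_assembly_counts() -> ClassCounts:
    """The reference ezrinTD/ezrinWT nanotube class-count table."""
    return ClassCounts(
        groups=("ezrinTD", "ezrinWT"),
        classes=ASSEMBLY_CLASSES,
        counts=np.array([
            [EZRIN_TD_COUNTS[c] for c in ASSEMBLY_CLASSES],
            [EZRIN_WT_COUNTS[c] for c in ASSEMBLY_CLASSES],
        ]),
    )
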