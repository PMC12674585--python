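"""Top-fraction clone selection and Cohen's kappa concordance.

Two rankings of the same clone universe (e.g. phenotype-based dBLUPs and
model-predicted dBLUPs) are each reduced to a "selected" set — the top 20%
by default, higher values being better for all three root-quality traits —
and agreement between the two binary classifications is summarised by the
unweighted Cohen kappa:

    kappa = (po - pe) / (1 - pe)

where po is the observed proportion of agreement (both-selected plus
neither-selected over n) and pe the agreement expected by chance from the
marginal selection rates. kappa is 1 for identical sets, 0 at chance-level
overlap, and negative below chance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError


@dataclass(frozen=True)
class ConcordanceResult:
    set_a: frozenset
    set_b: frozenset
    n_clones: int
    both_selected: int
    a_only: int
    b_only: int
    neither: int
    po: float
    pe: float
    kappa: float

    @property
    def confusion(self) -> np.ndarray:
        return np.array(
            [[self.both_selected, self.a_only], [self.b_only, self.neither]]
        )


def select_top_fraction(scores, fraction: float = 0.20) -> frozenset:
    """The ``ceil(fraction * n)`` clone ids with the largest scores.

    ``scores`` maps clone id to value (a dict or a pandas Series indexed by
    clone id). Missing scores are excluded with a warning; ties at the
    cutoff are broken by ascending clone id (stable and documented), with a
    warning when the tie actually crosses the cutoff.
    """
    series = pd.Series(scores, dtype=float)
    n_missing = int(series.isna().sum())
    if n_missing:
        warnings.warn(f"{n_missing} clone(s) with missing scores excluded")
        series = series.dropna()
    n = len(series)
    if n == 0:
        raise ConfigurationError("no clones with scores to select from")
    k = math.ceil(fraction * n)
    ordered = series.sort_index().sort_values(ascending=False, kind="stable")
    if k < n and ordered.iloc[k - 1] == ordered.iloc[k]:
        warnings.warn("tie at the selection cutoff broken by ascending clone id")
    return frozenset(ordered.index[:k])


def cohen_kappa(set_a, set_b, n_clones: int) -> ConcordanceResult:
    """Chance-corrected agreement of two selected/not-selected partitions
    of a universe of ``n_clones`` clones."""
    if n_clones <= 0:
        raise ConfigurationError("n_clones must be positive")
    a, b = frozenset(set_a), frozenset(set_b)
    if len(a | b) > n_clones:
        raise ConfigurationError("selection sets exceed the clone universe")
    both = len(a & b)
    a_only = len(a - b)
    b_only = len(b - a)
    neither = n_clones - both - a_only - b_only
    po = (both + neither) / n_clones
    pa, pb = len(a) / n_clones, len(b) / n_clones
    pe = pa * pb + (1 - pa) * (1 - pb)
    if pe == 1.0:
        kappa = 1.0 if po == 1.0 else 0.0
    else:
        kappa = (po - pe) / (1 - pe)
    return ConcordanceResult(
        set_a=a, set_b=b, n_clones=n_clones,
        both_selected=both, a_only=a_only, b_only=b_only, neither=neither,
        po=po, pe=pe, kappa=kappa,
    )


def concordance_matrix(selections: dict, n_clones: int) -> pd.DataFrame:
    """Symmetric pairwise-kappa table over named selection sets; the
    diagonal is 1 by convention."""
    names = list(selections)
    table = pd.DataFrame(np.eye(len(names)), index=names, columns=names)
    for i, a in enumerate(names):
        for j in range(i + 1, len(names)):
            b = names[j]
            k = cohen_kappa(selections[a], selections[b], n_clones).kappa
            table.iloc[i, j] = table.iloc[j, i] = k
    return table


def concordance_long_format(
    tables: dict, path=None
) -> pd.DataFrame:
    """Flatten {(trait, sample_type): kappa table} into a long-format frame
    (one row per method pair), optionally written as CSV."""
    rows = []
    for (trait, sample_type), table in tables.items():
        names = list(table.index)
        for i, a in enumerate(names):
            for j, b in enumerate(names):
                if j < i:
                    continue
                rows.append(
                    dict(trait=trait, sample_type=sample_type,
                         method_a=a, method_b=b, kappa=float(table.iloc[i, j]))
                )
    frame = pd.DataFrame(rows)
    if path is not None:
        frame.to_csv(path, index=False)
    return frame
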