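"""Closed-form "balance" model of CRE activity from binding-site counts.

For a CRE with x sites of one activator TF and y sites of a second,

    A = alpha_x * x + alpha_y * y + beta_xy * x * y
        - (gamma_x * x(x-1) + gamma_y * y(y-1)) / 2

i.e. positive, independent contributions per site, positive cooperativity
between every pair of sites for *different* TFs, and negative interactions
between every pair of sites for the *same* TF.  The model has no fit
parameters: all weights default to 1.  Because additive terms scale
linearly with site count while interaction terms scale with its square,
adding sites for one TF first raises and then lowers activity — a CRE with
many sites for a single activator is a silencer, and swapping a single
site for a different TF's site can flip it back to an enhancer.

The generalization to k TF types with counts n_i (cooperativity optional):

    A = sum_i alpha_i n_i + [coop] sum_{i<j} beta_ij n_i n_j
        - sum_i gamma_i n_i (n_i - 1) / 2
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

__all__ = [
    "BalanceWeights",
    "BalanceResult",
    "eq1_activity",
    "generalized_activity",
    "grid_simulation",
    "diversity_decomposition",
    "rank_compare",
    "genomic_site_count_predict",
    "activity_from_token_counts",
]


@dataclass
class BalanceWeights:
    """Weights for additive (alpha), heterotypic (beta), homotypic (gamma)
    contributions, keyed by TF type or unordered type pair; default 1."""

    alpha: dict = field(default_factory=dict)
    beta: dict = field(default_factory=dict)
    gamma: dict = field(default_factory=dict)

    def a(self, tf) -> float:
        return float(self.alpha.get(tf, 1.0))

    def b(self, tf1, tf2) -> float:
        return float(self.beta.get(frozenset((tf1, tf2)), self.beta.get((tf1, tf2),
                     self.beta.get((tf2, tf1), 1.0))))

    def g(self, tf) -> float:
        return float(self.gamma.get(tf, 1.0))


@dataclass
class BalanceResult:
    """Activity and its exact decomposition: A = additive + heterotypic - homotypic."""

    activity: float
    additive: float
    heterotypic: float
    homotypic: float

    def __post_init__(self):
        assert abs(self.activity - (self.additive + self.heterotypic - self.homotypic)) < 1e-9


def generalized_activity(
    counts: dict, weights: BalanceWeights | None = None, cooperativity: bool = True
) -> BalanceResult:
    """Balance-model activity for an arbitrary site-count vector.

    ``counts`` maps TF type -> non-negative site count.  With
    ``cooperativity=False`` the heterotypic beta terms are dropped,
    leaving only independent positive contributions and negative homotypic
    interactions.
    """
    if not counts:
        raise ValueError("need at least one TF type")
    weights = weights or BalanceWeights()
    for tf, n in counts.items():
        if n < 0 or int(n) != n:
            raise ValueError(f"count for {tf} must be a non-negative integer")
    additive = sum(weights.a(tf) * n for tf, n in counts.items())
    hetero = 0.0
    if cooperativity:
        for tf1, tf2 in itertools.combinations(sorted(counts), 2):
            hetero += weights.b(tf1, tf2) * counts[tf1] * counts[tf2]
    homo = sum(weights.g(tf) * n * (n - 1) / 2 for tf, n in counts.items())
    return BalanceResult(additive + hetero - homo, float(additive), float(hetero), float(homo))


def eq1_activity(x: int, y: int, weights: BalanceWeights | None = None) -> BalanceResult:
    """Two-TF balance model: A = ax*x + ay*y + bxy*x*y - [gx*x(x-1)+gy*y(y-1)]/2.

    With unit weights, (4, 0) -> -2 (four same-TF sites are repressive) and
    (3, 1) -> 4 (one swapped site turns the silencer into an enhancer).
    """
    if x < 0 or y < 0:
        raise ValueError("site counts must be non-negative")
    return generalized_activity({"x": x, "y": y}, weights, cooperativity=True)


def grid_simulation(
    max_x: int,
    max_y: int,
    weights: BalanceWeights | None = None,
    cooperativity: bool = True,
    max_total: int | None = None,
) -> pd.DataFrame:
    """Exhaustive (x, y) grid of balance-model activities.

    Returns one row per cell with the decomposition, the sign of A, and an
    ``is_max`` flag on the argmax cell.  ``max_total`` optionally restricts
    to x + y <= max_total (the up-to-four-sites grid).
    """
    if max_x < 0 or max_y < 0:
        raise ValueError("grid bounds must be >= 0")
    rows = []
    for x in range(max_x + 1):
        for y in range(max_y + 1):
            if max_total is not None and x + y > max_total:
                continue
            res = generalized_activity({"x": x, "y": y}, weights, cooperativity)
            rows.append(
                {
                    "x": x,
                    "y": y,
                    "activity": res.activity,
                    "additive": res.additive,
                    "heterotypic": res.heterotypic,
                    "homotypic": res.homotypic,
                    "sign": int(np.sign(res.activity)),
                }
            )
    grid = pd.DataFrame(rows)
    grid["is_max"] = grid["activity"] == grid["activity"].max()
    return grid


def diversity_decomposition(
    total_sites: int, weights: BalanceWeights | None = None
) -> pd.DataFrame:
    """Activity of every composition of N sites over TF types, cooperativity off.

    For each partition of ``total_sites`` (e.g. (5), (4,1), ..., (1,1,1,1,1))
    the additive total equals N while the homotypic total shrinks as the
    composition becomes more even, so diversity alone raises activity even
    without cooperativity.
    """
    if total_sites < 1:
        raise ValueError("total_sites must be >= 1")
    rows = []
    for part in _partitions(total_sites):
        counts = {f"tf{i}": n for i, n in enumerate(part)}
        res = generalized_activity(counts, weights, cooperativity=False)
        rows.append(
            {
                "composition": part,
                "diversity": len(part),
                "additive": res.additive,
                "homotypic": res.homotypic,
                "activity": res.activity,
            }
        )
    return pd.DataFrame(rows)


def _partitions(n: int, maxpart: int | None = None):
    """Integer partitions of n in decreasing-part order."""
    maxpart = n if maxpart is None else maxpart
    if n == 0:
        yield ()
        return
    for first in range(min(n, maxpart), 0, -1):
        for rest in _partitions(n - first, first):
            yield (first,) + rest


def rank_compare(predicted, measured) -> float:
    """Spearman rank correlation (average ranks for ties) of predicted vs
    measured activities; ranks are invariant to monotone transforms so
    either log or linear activities may be passed."""
    predicted = np.asarray(predicted, float)
    measured = np.asarray(measured, float)
    if len(predicted) != len(measured) or len(predicted) < 3:
        raise ValueError("need >= 3 paired values")
    if np.std(predicted) == 0 or np.std(measured) == 0:
        raise ValueError("rank correlation undefined for all-tied input")
    return float(spearmanr(predicted, measured).statistic)


def genomic_site_count_predict(
    table: pd.DataFrame,
    crx_col: str = "crx_sites",
    other_col: str = "other_sites",
    weights: BalanceWeights | None = None,
    per_type: bool = False,
    activity_col: str | None = None,
) -> pd.DataFrame:
    """Predicted balance-model activity for genomic CREs from site counts.

    By default all non-CRX sites are lumped into a single second TF type;
    ``per_type=True`` instead treats every count column other than
    ``crx_col`` as its own TF type.  If ``activity_col`` names a measured
    activity column, a grid-binned mean-activity table is attached as
    ``.attrs["binned_measured"]``.
    """
    for col in (crx_col, other_col) if not per_type else (crx_col,):
        if col not in table.columns:
            raise ValueError(f"missing column {col!r}")
    out = table.copy()
    if per_type:
        count_cols = [
            c for c in table.columns
            if c != activity_col and np.issubdtype(table[c].dtype, np.integer)
        ]
    else:
        count_cols = None
    preds = []
    for _, row in table.iterrows():
        if per_type:
            counts = {c: int(row[c]) for c in count_cols}
        else:
            counts = {"CRX": int(row[crx_col]), "other": int(row[other_col])}
        preds.append(generalized_activity(counts, weights, cooperativity=True).activity)
    out["predicted_activity"] = preds
    if activity_col is not None:
        binned = (
            out.groupby([crx_col, other_col])[activity_col].mean().reset_index()
        )
        out.attrs["binned_measured"] = binned
    return out


def activity_from_token_counts(token_string: str, tf_of_code: dict) -> float:
    """Unit-weight balance activity of one CRE given its site tokens.

    ``tf_of_code`` maps each site character to its TF type; counts are
    accumulated per TF and passed through the two-or-more-TF model with
    cooperativity on.  Used to rank-compare the balance model against
    measured library activities.
    """
    counts: dict = {}
    for ch in token_string:
        tf = tf_of_code.get(ch)
        if tf is None:
            continue  # pad / promoter characters carry no sites
        counts[tf] = counts.get(tf, 0) + 1
    if not counts:
        return 0.0
    return generalized_activity(counts, None, cooperativity=True).activity
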