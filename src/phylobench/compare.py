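"""Paired-difference comparison of methods and their components.

Comparing the raw Taxon averages of two methods wastes power: the per-OG
distances of different methods are strongly positively correlated (hard OGs
are hard for everyone).  The classic variance-reduction remedy is to take,
OG by OG, the *difference* of the two methods' distances and test whether
its mean is zero.  The mean difference equals the difference of the means,
but its standard error is far smaller.

Significance is reported on three tiers, written with the field's symbols:
``≫`` for p < 1e-6 (better than one in a million), ``>`` for p < 0.05 and
``≥`` otherwise.  Given the sample sizes this machinery targets (tens of
thousands to millions of OGs) a normal z-test on the mean difference is
used; for n < 30 a small-sample warning is attached to the result.

Component-level comparisons (e.g. one aligner versus another) pool the
per-OG differences of every *matched* method pair — pairs whose identifiers
differ only by the component token under study, so the companion components
are identical on both sides.  OGs are then counted once per matched pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "ComparisonResult",
    "ComponentComparison",
    "SMALL_SAMPLE_N",
    "paired_difference",
    "component_comparison",
    "matched_pairs",
    "rank_chain",
    "correlation",
    "split_by",
    "significance_symbol",
]

P_STRONG = 1e-6
P_WEAK = 0.05
SMALL_SAMPLE_N = 30
Z_95 = 1.96  # exact 95% half-width convention used in the output tables


def significance_symbol(p_value: float) -> str:
    if p_value < P_STRONG:
        return "≫"  # ≫
    if p_value < P_WEAK:
        return ">"
    return "≥"  # ≥


@dataclass(frozen=True)
class ComparisonResult:
    """Outcome of a paired-difference test between two methods.

    ``delta`` is the mean of the per-OG differences (a - b); negative means
    method *a* makes fewer mistakes per tree.  ``ci_half`` is the 95%
    confidence half-width ``1.96 * s / sqrt(n)``.
    """

    method_a: str
    method_b: str
    delta: float
    ci_half: float
    n: int
    p_value: float
    symbol: str
    small_sample: bool = False

    def verdict(self) -> str:
        better = self.method_a if self.delta <= 0 else self.method_b
        other = self.method_b if self.delta <= 0 else self.method_a
        if self.symbol == "≫":
            return f"{better} is strongly better than {other}"
        if self.symbol == ">":
            return f"{better} is better than {other}"
        return f"{self.method_a} and {self.method_b} are not significantly different"


def _as_aligned_diff(
    dist_a, dist_b, name_a: str, name_b: str
) -> np.ndarray:
    a = pd.Series(dist_a, dtype=float)
    b = pd.Series(dist_b, dtype=float)
    if set(a.index) != set(b.index):
        only_a = sorted(set(a.index) - set(b.index))[:5]
        only_b = sorted(set(b.index) - set(a.index))[:5]
        raise ValueError(
            f"OG sets of {name_a} and {name_b} differ "
            f"(e.g. only in first: {only_a}, only in second: {only_b})"
        )
    return (a - b.reindex(a.index)).to_numpy()


def _summarize(diff: np.ndarray, name_a: str, name_b: str) -> ComparisonResult:
    n = diff.size
    if n < 2:
        raise ValueError("paired difference needs at least 2 observations")
    delta = float(diff.mean())
    s = float(diff.std(ddof=1))
    if s == 0.0:
        p = 1.0 if delta == 0.0 else 0.0
        ci = 0.0
    else:
        se = s / np.sqrt(n)
        z = delta / se
        p = float(2.0 * stats.norm.sf(abs(z)))
        ci = float(Z_95 * se)
    small = n < SMALL_SAMPLE_N
    if small:
        warnings.warn(
            f"paired comparison {name_a} vs {name_b} has only n={n} "
            "observations; the normal approximation is unreliable",
            stacklevel=3,
        )
    return ComparisonResult(
        name_a, name_b, delta, ci, n, p, significance_symbol(p), small
    )


def paired_difference(dist_a, dist_b, name_a="A", name_b="B") -> ComparisonResult:
    """Test the mean per-OG difference of two distance vectors.

    ``dist_a`` and ``dist_b`` are mappings/Series of OG id -> distance with
    identical key sets.  Antisymmetric in its arguments: swapping them flips
    the sign of delta and keeps the p-value.
    """
    if hasattr(dist_a, "name") and getattr(dist_a, "name", None) and name_a == "A":
        name_a = str(dist_a.name)
    if hasattr(dist_b, "name") and getattr(dist_b, "name", None) and name_b == "B":
        name_b = str(dist_b.name)
    diff = _as_aligned_diff(dist_a, dist_b, name_a, name_b)
    return _summarize(diff, name_a, name_b)


def matched_pairs(
    method_ids: Sequence[str], token_a: str, token_b: str
) -> List[Tuple[str, str]]:
    """Method pairs whose ordered token lists differ only by token_a -> token_b.

    Method ids are underscore-joined component tokens; substituting
    ``token_a`` by ``token_b`` at the position where it occurs must yield
    another known method, guaranteeing identical companion components.
    """
    ids = set(method_ids)
    pairs = []
    for mid in sorted(ids):
        tokens = mid.split("_")
        if token_a not in tokens:
            continue
        partner = "_".join(token_b if t == token_a else t for t in tokens)
        if partner in ids and partner != mid:
            pairs.append((mid, partner))
    return pairs


@dataclass(frozen=True)
class ComponentComparison:
    """Pooled verdict for one component substitution plus per-pair detail."""

    token_a: str
    token_b: str
    pooled: ComparisonResult
    per_pair: Tuple[ComparisonResult, ...]


def component_comparison(
    store: pd.DataFrame, token_a: str, token_b: str
) -> ComponentComparison:
    """Compare two components over every matched method pair in a store.

    ``store`` is the per-OG distance matrix (rows: OG ids, columns: method
    ids).  The per-OG differences of all matched pairs are pooled, so an OG
    contributes once per matched pair and the pooled n is the sum of the
    per-pair counts.
    """
    pairs = matched_pairs(list(store.columns), token_a, token_b)
    if not pairs:
        raise ValueError(
            f"no method pairs match the substitution {token_a!r} -> {token_b!r}"
        )
    diffs = []
    per_pair = []
    for a, b in pairs:
        cols = store[[a, b]].dropna()
        d = (cols[a] - cols[b]).to_numpy()
        per_pair.append(_summarize(d, a, b))
        diffs.append(d)
    pooled = _summarize(np.concatenate(diffs), token_a, token_b)
    return ComponentComparison(token_a, token_b, pooled, tuple(per_pair))


def rank_chain(
    means: Dict[str, float], store: pd.DataFrame, top: Optional[int] = None
) -> str:
    """Methods sorted by mean (ascending, lower = better), annotated with the
    significance symbol of each adjacent paired comparison.

    e.g. ``"A ≫ B ≥ C"``.  ``top`` limits the chain to the best k methods.
    """
    order = sorted(means, key=lambda m: (means[m], m))
    if top is not None:
        order = order[:top]
    if not order:
        return ""
    parts = [order[0]]
    for prev, cur in zip(order, order[1:]):
        res = paired_difference(store[prev], store[cur], prev, cur)
        parts.append(res.symbol)
        parts.append(cur)
    return " ".join(parts)


def correlation(x, y, kind: str = "pearson") -> float:
    """Pearson or Spearman correlation; NaN (with a warning) if degenerate."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 3:
        raise ValueError("correlation needs two equal-length vectors, n >= 3")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        warnings.warn("correlation undefined: zero variance input", stacklevel=2)
        return float("nan")
    if kind == "pearson":
        return float(stats.pearsonr(x, y).statistic)
    if kind == "spearman":
        return float(stats.spearmanr(x, y).statistic)
    raise ValueError(f"unknown correlation kind {kind!r}")


def split_by(og_meta: pd.DataFrame, column: str, threshold: float):
    """Partition OG ids by a per-OG covariate (<= threshold vs above).

    Used to score the Taxon measure separately on small vs large trees (leaf
    count threshold) or short vs long sequences (median length threshold)
    and correlate method rankings across the two sides.  An empty side is
    legal but flagged with a warning.
    """
    if column not in og_meta.columns:
        raise KeyError(f"no per-OG column {column!r}")
    low = set(og_meta.index[og_meta[column] <= threshold])
    high = set(og_meta.index[og_meta[column] > threshold])
    if not low or not high:
        warnings.warn(
            f"split on {column!r} at {threshold} leaves one side empty",
            stacklevel=2,
        )
    return low, high
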