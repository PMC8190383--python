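"""Group-comparison layer: rank tests, correlation, feature tables.

All tests are two-sided and rank-based.  Unpaired contrasts use the
Mann-Whitney U test (exact null when the product of group sizes is at most
400 and no ties are present, otherwise the normal approximation with tie
and continuity correction); paired pre/post contrasts use the Wilcoxon
signed-rank test (zeros dropped, exact null when the effective n is at
most 25 and the absolute differences are tie-free).  Monotone association
with a continuous covariate uses the Spearman rank correlation with the
t approximation for its p-value.

Multiple-testing correction is off by default (mirroring univariate
reporting without correction); Benjamini-Hochberg is available as a flag
and the adjusted p is always at least the raw p.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_MWU_MAX_PRODUCT = 400
EXACT_WILCOXON_MAX_N = 25


class StatsError(ValueError):
    pass


@dataclass
class ComparisonRow:
    feature: str
    contrast: str
    statistic: float
    p_value: float
    direction: int  # sign of the median difference (first minus second)
    n_x: int
    n_y: int
    adjusted_p: Optional[float] = None


def _has_ties(values: np.ndarray) -> bool:
    return np.unique(values).size < values.size


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Two-sided Mann-Whitney U; returns (U of x, p)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise StatsError("empty group")
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        # degenerate: identical constants carry no ordering information
        return x.size * y.size / 2.0, 1.0
    exact = x.size * y.size <= EXACT_MWU_MAX_PRODUCT and not _has_ties(pooled)
    res = sps.mannwhitneyu(
        x, y,
        alternative="two-sided",
        method="exact" if exact else "asymptotic",
        use_continuity=True,
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def wilcoxon_signed_rank(
    before: Sequence[float], after: Sequence[float]
) -> tuple[float, float]:
    """Two-sided Wilcoxon signed-rank on paired values; zero differences
    dropped; returns (W, p)."""
    before = np.asarray(before, dtype=float)
    after = np.asarray(after, dtype=float)
    if before.shape != after.shape or before.size == 0:
        raise StatsError("paired vectors must be equal-length and non-empty")
    diff = after - before
    diff = diff[diff != 0]
    if diff.size == 0:
        raise StatsError("degenerate pairing: all differences are zero")
    exact = diff.size <= EXACT_WILCOXON_MAX_N and not _has_ties(np.abs(diff))
    res = sps.wilcoxon(
        diff,
        alternative="two-sided",
        method="exact" if exact else "approx",
        correction=not exact,
    )
    return float(res.statistic), float(min(res.pvalue, 1.0))


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation (rho, p) with the t approximation."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise StatsError("need at least 3 paired observations")
    if np.unique(x).size == 1 or np.unique(y).size == 1:
        raise StatsError("zero rank variance in input")
    res = sps.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def _bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    m = pvalues.size
    order = np.argsort(pvalues, kind="stable")
    adj = np.empty(m, dtype=float)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        idx = order[rank]
        running = min(running, pvalues[idx] * m / (rank + 1))
        adj[idx] = running
    return np.maximum(adj, pvalues)


def compare_features(
    features: pd.DataFrame,
    metadata: pd.DataFrame,
    group_col: str = "group",
    contrast: Optional[tuple[str, str]] = None,
    design: str = "unpaired",
    pair_col: str = "pair_id",
    adjust: str = "none",
    feature_names: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """One comparison row per feature between two groups.

    ``features`` is a samples x features matrix indexed by sample id;
    ``metadata`` carries ``sample_id``, the group label column, and (for
    the paired design) a pairing id.  Samples with a missing value for a
    feature are dropped pairwise from that feature's test; features
    constant across all tested samples get p = 1.  Rows are sorted by p.
    """
    if design not in ("unpaired", "paired"):
        raise StatsError(f"unknown design {design!r}")
    if adjust not in ("none", "bh"):
        raise StatsError(f"unknown adjust {adjust!r}")
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    missing = [s for s in meta.index if s not in features.index]
    if missing:
        raise StatsError(f"metadata samples absent from features: {missing}")
    labels = meta[group_col]
    if contrast is None:
        uniq = list(pd.unique(labels))
        if len(uniq) != 2:
            raise StatsError(f"need exactly 2 groups, found {uniq}")
        contrast = (str(uniq[0]), str(uniq[1]))
    a_label, b_label = contrast
    a_samples = labels.index[labels == a_label]
    b_samples = labels.index[labels == b_label]
    if len(a_samples) == 0 or len(b_samples) == 0:
        raise StatsError(f"empty group in contrast {contrast}")

    if design == "paired":
        if pair_col not in meta.columns:
            raise StatsError(f"paired design requires a {pair_col!r} column")
        a_pairs = meta.loc[a_samples, pair_col]
        b_pairs = meta.loc[b_samples, pair_col]
        orphans = sorted(set(a_pairs) ^ set(b_pairs))
        if orphans:
            raise StatsError(f"unmatched pair ids: {orphans}")
        order = sorted(set(a_pairs))
        a_samples = pd.Index([a_pairs.index[a_pairs == p][0] for p in order])
        b_samples = pd.Index([b_pairs.index[b_pairs == p][0] for p in order])

    names = list(feature_names) if feature_names is not None else list(features.columns)
    unknown = [f for f in names if f not in features.columns]
    if unknown:
        raise StatsError(f"unknown features: {unknown}")

    rows: list[ComparisonRow] = []
    for feat in names:
        xa = features.loc[a_samples, feat].to_numpy(dtype=float)
        xb = features.loc[b_samples, feat].to_numpy(dtype=float)
        if design == "paired":
            keep = ~(np.isnan(xa) | np.isnan(xb))
            xa, xb = xa[keep], xb[keep]
        else:
            xa = xa[~np.isnan(xa)]
            xb = xb[~np.isnan(xb)]
        if xa.size == 0 or xb.size == 0:
            continue
        direction = int(np.sign(np.median(xa) - np.median(xb)))
        try:
            if design == "paired":
                stat, p = wilcoxon_signed_rank(xb, xa)
            else:
                stat, p = mann_whitney_u(xa, xb)
        except StatsError:
            stat, p = float("nan"), 1.0
        rows.append(
            ComparisonRow(
                feature=feat, contrast=f"{a_label} vs {b_label}",
                statistic=stat, p_value=p, direction=direction,
                n_x=int(xa.size), n_y=int(xb.size),
            )
        )
    if not rows:
        raise StatsError("no testable features")
    out = pd.DataFrame([r.__dict__ for r in rows])
    if adjust == "bh":
        out["adjusted_p"] = _bh_adjust(out["p_value"].to_numpy())
    out = out.sort_values(["p_value", "feature"], kind="stable").reset_index(drop=True)
    return out


def correlate_features(
    features: pd.DataFrame,
    metadata: pd.DataFrame,
    covariate: str,
    feature_names: Optional[Sequence[str]] = None,
) -> pd.DataFrame:
    """Spearman correlation of every feature with a continuous covariate
    (e.g. an APLA2R titer column); one row per feature."""
    meta = metadata.set_index("sample_id") if "sample_id" in metadata.columns else metadata
    if covariate not in meta.columns:
        raise StatsError(f"covariate {covariate!r} not in metadata")
    names = list(feature_names) if feature_names is not None else list(features.columns)
    rows = []
    for feat in names:
        joined = pd.concat([features[feat], meta[covariate]], axis=1, join="inner").dropna()
        if len(joined) < 3:
            continue
        try:
            rho, p = spearman(joined.iloc[:, 0], joined.iloc[:, 1])
        except StatsError:
            continue
        rows.append(
            {"feature": feat, "covariate": covariate, "rho": rho, "p_value": p,
             "n": len(joined)}
        )
    if not rows:
        raise StatsError("no correlatable features")
    return pd.DataFrame(rows).sort_values(["p_value", "feature"], kind="stable").reset_index(drop=True)
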