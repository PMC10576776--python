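"""Penetrance, expressivity and correlation statistics of boundary phenotypes.

Somite boundaries 11-30 of each embryo side are scored 0 (intact) or 1
(defected); unscorable boundaries are NA.  An embryo with a single defected
boundary on either side counts as defected (penetrance); the number of
defected boundaries per side measures expressivity.  Whether defects are
laid down independently along the axis is probed with two Pearson
correlations: consecutive boundaries of one side (11th-29th vs 12th-30th)
and matching boundaries of the left and right sides (11th-30th).  Under
independent per-cycle failures both means sit near zero.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import fisher_exact, kruskal, mannwhitneyu, norm, rankdata

__all__ = [
    "DEFAULT_RANGE",
    "PenetranceSummary",
    "ExpressivitySummary",
    "CorrelationSummary",
    "classify_embryos",
    "defect_counts",
    "consecutive_correlation",
    "left_right_correlation",
    "per_side_consecutive",
    "per_embryo_left_right",
    "summarize_correlations",
    "expressivity_change",
    "round_half_up",
    "compare_two_groups",
    "compare_penetrance",
    "compare_many_groups",
]

log = logging.getLogger(__name__)

#: Boundary range scored in the phenotype tables (inclusive).
DEFAULT_RANGE = (11, 30)

REQUIRED_COLUMNS = ("embryo_id", "side", "boundary_index", "phenotype")


def _check_table(table: pd.DataFrame) -> None:
    if table.empty:
        raise ValueError("boundary table is empty")
    missing = [c for c in REQUIRED_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"boundary table lacks columns {missing}")
    vals = table["phenotype"].dropna().unique()
    bad = set(vals) - {0, 1, 0.0, 1.0}
    if bad:
        raise ValueError(f"phenotype codes must be 0/1/NA, got {sorted(bad)}")


def _in_range(table: pd.DataFrame, rng: tuple[int, int]) -> pd.DataFrame:
    lo, hi = rng
    return table[(table["boundary_index"] >= lo) & (table["boundary_index"] <= hi)]


@dataclass
class PenetranceSummary:
    """Per-condition penetrance: fraction of embryos with >= 1 defected
    boundary on either side within the scored range."""

    per_condition: pd.DataFrame  # condition, n_embryos, n_defected, fraction
    n_excluded: int  # embryos with no scorable boundary in range


@dataclass
class ExpressivitySummary:
    """Defected-boundary counts per (embryo, side) and their per-condition
    median/quartiles/mean."""

    per_side: pd.DataFrame  # condition, embryo_id, side, n_defected, n_scored
    per_condition: pd.DataFrame  # condition, median, q1, q3, mean, n_sides


@dataclass
class CorrelationSummary:
    """Collection of per-unit Pearson r values with the paper-style
    histogram (0.1 bins over [-1, 1], rightmost bin closed)."""

    values: np.ndarray
    n_excluded: int
    mean: float
    bin_edges: np.ndarray
    frequencies: np.ndarray


def classify_embryos(
    table: pd.DataFrame, rng: tuple[int, int] = DEFAULT_RANGE
) -> PenetranceSummary:
    """Score each embryo defected iff any boundary on either side within the
    range is defected; summarize the defected fraction per condition."""
    _check_table(table)
    sub = _in_range(table, rng)
    cond_col = sub["condition"] if "condition" in sub.columns else "all"
    sub = sub.assign(_cond=cond_col)
    n_excluded = 0
    rows = []
    for cond, grp in sub.groupby("_cond"):
        n_emb = n_def = 0
        for eid, emb in grp.groupby("embryo_id"):
            scored = emb["phenotype"].dropna()
            if scored.empty:
                log.warning("embryo %s has no scorable boundary in range; excluded", eid)
                n_excluded += 1
                continue
            n_emb += 1
            n_def += int((scored == 1).any())
        rows.append(
            {
                "condition": cond,
                "n_embryos": n_emb,
                "n_defected": n_def,
                "fraction": n_def / n_emb if n_emb else np.nan,
            }
        )
    return PenetranceSummary(pd.DataFrame(rows), n_excluded)


def defect_counts(
    table: pd.DataFrame, rng: tuple[int, int] = DEFAULT_RANGE
) -> ExpressivitySummary:
    """Count defected boundaries per embryo side (NA entries excluded and
    flagged via n_scored) and summarize per condition."""
    _check_table(table)
    sub = _in_range(table, rng)
    cond_col = sub["condition"] if "condition" in sub.columns else "all"
    sub = sub.assign(_cond=cond_col)
    per_side = (
        sub.groupby(["_cond", "embryo_id", "side"])
        .agg(
            n_defected=("phenotype", lambda s: int((s.dropna() == 1).sum())),
            n_scored=("phenotype", lambda s: int(s.notna().sum())),
        )
        .reset_index()
        .rename(columns={"_cond": "condition"})
    )
    per_cond = (
        per_side.groupby("condition")["n_defected"]
        .agg(
            median="median",
            q1=lambda s: s.quantile(0.25),
            q3=lambda s: s.quantile(0.75),
            mean="mean",
            n_sides="count",
        )
        .reset_index()
    )
    return ExpressivitySummary(per_side, per_cond)


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    """Pearson product-moment r on pairwise-complete entries; NaN (undefined)
    when either vector is constant."""
    mask = ~(np.isnan(x) | np.isnan(y))
    x, y = x[mask], y[mask]
    if len(x) < 3:
        raise ValueError("fewer than 3 complete pairs")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return np.nan
    xc, yc = x - x.mean(), y - y.mean()
    return float((xc * yc).sum() / math.sqrt((xc**2).sum() * (yc**2).sum()))


def consecutive_correlation(phenotypes: np.ndarray, max_na: int = 2) -> float:
    """Pearson r between consecutive-boundary phenotypes of one side.

    ``phenotypes`` is the ordered series over the scored range (e.g.
    boundaries 11..30); the correlation compares entries 1..n-1 against
    2..n (11th-29th vs 12th-30th for the default range) on pairwise-complete
    pairs.  Returns NaN when either lagged copy is constant (undefined).
    """
    v = np.asarray(phenotypes, dtype=float)
    if len(v) < 4:
        raise ValueError("need at least 4 boundaries (3 lagged pairs)")
    if np.isnan(v).sum() > max_na:
        raise ValueError(f"more than {max_na} unscorable boundaries")
    return _pearson(v[:-1], v[1:])


def left_right_correlation(left: np.ndarray, right: np.ndarray) -> float:
    """Pearson r between left- and right-side phenotypes at matching
    boundary indices; NaN when either side is constant."""
    left = np.asarray(left, dtype=float)
    right = np.asarray(right, dtype=float)
    if left.shape != right.shape:
        raise ValueError("left and right series must have matching length")
    return _pearson(left, right)


def _side_vectors(
    table: pd.DataFrame, rng: tuple[int, int]
) -> dict[tuple[str, str], np.ndarray]:
    lo, hi = rng
    idx = np.arange(lo, hi + 1)
    out = {}
    for (eid, side), grp in table.groupby(["embryo_id", "side"]):
        ser = grp.set_index("boundary_index")["phenotype"].reindex(idx)
        out[(eid, side)] = ser.to_numpy(dtype=float)
    return out


def per_side_consecutive(
    table: pd.DataFrame, rng: tuple[int, int] = DEFAULT_RANGE, max_na: int = 2
) -> list[float]:
    """Consecutive-boundary r for every (embryo, side) unit in the table.
    Units failing the NA budget are skipped with a log message."""
    _check_table(table)
    rs = []
    for key, vec in _side_vectors(_in_range(table, rng), rng).items():
        try:
            rs.append(consecutive_correlation(vec, max_na=max_na))
        except ValueError as e:
            log.warning("side %s skipped: %s", key, e)
    return rs


def per_embryo_left_right(
    table: pd.DataFrame, rng: tuple[int, int] = DEFAULT_RANGE
) -> list[float]:
    """Left-right r for every embryo; raises if an embryo lacks a side."""
    _check_table(table)
    vecs = _side_vectors(_in_range(table, rng), rng)
    rs = []
    for eid in sorted({e for e, _ in vecs}):
        if (eid, "L") not in vecs or (eid, "R") not in vecs:
            raise ValueError(f"embryo {eid} is missing a side")
        rs.append(left_right_correlation(vecs[(eid, "L")], vecs[(eid, "R")]))
    return rs


def summarize_correlations(values) -> CorrelationSummary:
    """Mean and 0.1-binned normalized-frequency histogram of defined r
    values; undefined (NaN) entries are excluded and counted.

    Bins are [k/10, (k+1)/10) over [-1, 1] with the rightmost bin closed so
    r = 1 is representable.
    """
    arr = np.asarray(list(values), dtype=float)
    defined = arr[~np.isnan(arr)]
    if defined.size == 0:
        raise ValueError("no defined correlation values")
    if (np.abs(defined) > 1 + 1e-12).any():
        raise ValueError("correlation values must lie in [-1, 1]")
    edges = np.round(np.arange(-10, 11) / 10.0, 10)
    counts, _ = np.histogram(defined, bins=edges)  # numpy closes the last bin
    return CorrelationSummary(
        values=defined,
        n_excluded=int(arr.size - defined.size),
        mean=float(defined.mean()),
        bin_edges=edges,
        frequencies=counts / defined.size,
    )


def round_half_up(x: float) -> int:
    """Round to the nearest integer, ties away from zero (62.5 -> 63)."""
    return int(math.copysign(math.floor(abs(x) + 0.5), x))


def expressivity_change(value_a: float, value_b: float) -> tuple[float, int]:
    """Percent change of a summary statistic from condition a to b,
    100 * (b - a) / a, returned raw and rounded half-up to integer percent."""
    if value_a == 0:
        raise ValueError("percent change is undefined for a zero baseline")
    raw = 100.0 * (value_b - value_a) / value_a
    return raw, round_half_up(raw)


def compare_two_groups(a, b) -> dict:
    """Two-sided Mann-Whitney U comparison of two observation groups."""
    a, b = np.asarray(a, dtype=float), np.asarray(b, dtype=float)
    if min(a.size, b.size) < 2:
        raise ValueError("each group needs >= 2 observations")
    stat, p = mannwhitneyu(a, b, alternative="two-sided")
    return {"test": "mann-whitney-u", "statistic": float(stat), "p_value": float(p),
            "n": [int(a.size), int(b.size)]}


def compare_penetrance(table_2x2) -> dict:
    """Two-sided Fisher exact test on a 2x2 defected/intact count table."""
    t = np.asarray(table_2x2, dtype=int)
    if t.shape != (2, 2) or (t < 0).any():
        raise ValueError("need a non-negative 2x2 count table")
    stat, p = fisher_exact(t, alternative="two-sided")
    return {"test": "fisher-exact", "odds_ratio": float(stat), "p_value": float(p),
            "n": t.sum(axis=1).tolist()}


def _dunn_pairwise(groups: dict) -> pd.DataFrame:
    """Dunn's z-tests on pooled ranks with tie correction and Bonferroni
    adjustment (the standard post hoc after Kruskal-Wallis)."""
    names = list(groups)
    pooled = np.concatenate([np.asarray(groups[g], dtype=float) for g in names])
    sizes = {g: len(groups[g]) for g in names}
    ranks = rankdata(pooled)
    n_total = len(pooled)
    mean_rank = {}
    start = 0
    for g in names:
        mean_rank[g] = ranks[start:start + sizes[g]].mean()
        start += sizes[g]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (12.0 * (n_total - 1))
    var_base = n_total * (n_total + 1) / 12.0 - tie_term
    m = len(names) * (len(names) - 1) // 2
    rows = []
    for i, gi in enumerate(names):
        for gj in names[i + 1:]:
            se = math.sqrt(var_base * (1.0 / sizes[gi] + 1.0 / sizes[gj]))
            z = (mean_rank[gi] - mean_rank[gj]) / se
            p = min(1.0, 2.0 * (1.0 - norm.cdf(abs(z))) * m)
            rows.append({"group_a": gi, "group_b": gj, "z": z, "p_adjusted": p})
    return pd.DataFrame(rows)


def compare_many_groups(groups: dict) -> dict:
    """Kruskal-Wallis across >= 3 groups with Dunn pairwise correction."""
    if len(groups) < 3:
        raise ValueError("use compare_two_groups for fewer than 3 groups")
    if any(len(v) < 2 for v in groups.values()):
        raise ValueError("each group needs >= 2 observations")
    stat, p = kruskal(*[np.asarray(v, dtype=float) for v in groups.values()])
    return {
        "test": "kruskal-wallis+dunn",
        "statistic": float(stat),
        "p_value": float(p),
        "n": {g: len(v) for g, v in groups.items()},
        "pairwise": _dunn_pairwise(groups),
    }
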