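"""Architecture-stratified analysis of localization changes.

Relates per-gene localization deltas to gene architecture: rank correlations
against each feature, distributions across pre-mRNA length bins, single- vs
multi-exon classes and arbitrary gene sets, and a length-controlled exon
analysis that asks whether exon count matters once pre-mRNA length is held
fixed.  The nonparametric machinery (Spearman rank correlation,
Mann-Whitney-Wilcoxon U with exact small-sample enumeration, and
Benjamini-Hochberg FDR adjustment) is implemented here from first
principles; tests report both raw p and BH-adjusted q within each report
section.
"""

from __future__ import annotations

import itertools
import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.stats import norm as _norm
from scipy.stats import t as _t

__all__ = [
    "spearman",
    "mann_whitney_u",
    "bh_adjust",
    "feature_correlations",
    "group_compare",
    "length_bin_analysis",
    "length_controlled_exon_analysis",
    "StratifiedReport",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = (
    "gene_length",
    "pre_mrna_length",
    "exonic_length",
    "n_exons",
    "fraction_intronic",
    "exon_density",
    "utr3_length",
)

EXACT_MWW_MAX_N = 12
EXACT_SPEARMAN_MAX_N = 8


class StatError(ValueError):
    pass


def _rank_midrank(x: np.ndarray) -> np.ndarray:
    """Ranks (1-based) with mid-ranks for ties."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x), dtype=float)
    i = 0
    sx = x[order]
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def _pearson(a: np.ndarray, b: np.ndarray) -> float:
    a = a - a.mean()
    b = b - b.mean()
    denom = math.sqrt(float(a @ a) * float(b @ b))
    if denom == 0:
        raise StatError("correlation undefined for constant input")
    return float(a @ b) / denom


def spearman(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Spearman rank correlation with mid-rank ties and two-sided p.

    p comes from exact permutation enumeration for n <= 8, otherwise from
    the t approximation ``t = rho sqrt((n-2)/(1-rho^2))``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise StatError("x and y must be equal-length vectors")
    n = len(x)
    if n < 3:
        raise StatError("need at least 3 observations")
    rx = _rank_midrank(x)
    ry = _rank_midrank(y)
    rho = _pearson(rx, ry)
    if n <= EXACT_SPEARMAN_MAX_N:
        count = total = 0
        obs = abs(rho) - 1e-12
        for perm in itertools.permutations(ry):
            total += 1
            if abs(_pearson(rx, np.array(perm))) >= obs:
                count += 1
        p = count / total
    else:
        r2 = min(rho * rho, 1.0 - 1e-15)
        tval = rho * math.sqrt((n - 2) / (1.0 - r2))
        p = 2.0 * float(_t.sf(abs(tval), df=n - 2))
    return rho, min(p, 1.0)


def _u_exact_counts(n1: int, n2: int) -> np.ndarray:
    """counts[u] = number of assignments of group-1 ranks with U statistic u.

    Classic dynamic program over distinct ranks 1..n1+n2 (no ties).
    """
    max_u = n1 * n2
    # c[k][u] = ways to pick k ranks so far with U contribution u
    c = np.zeros((n1 + 1, max_u + 1), dtype=float)
    c[0, 0] = 1.0
    for rank_pos in range(1, n1 + n2 + 1):
        # process ranks from largest to smallest to update in place safely
        for k in range(min(rank_pos, n1), 0, -1):
            # choosing this rank as the k-th smallest of group 1 adds
            # (rank_pos - k) to U (number of group-2 values below it)
            add = rank_pos - k
            c[k, add:] += c[k - 1, : max_u + 1 - add]
    return c[n1]


def mann_whitney_u(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Mann-Whitney U of x vs y with a two-sided p value.

    Exact p by enumeration when the combined sample size is <= 12 and there
    are no ties; otherwise a normal approximation with tie and continuity
    corrections.  Returns ``(U_x, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise StatError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = _rank_midrank(combined)
    r1 = ranks[:n1].sum()
    u = r1 - n1 * (n1 + 1) / 2.0

    has_ties = len(np.unique(combined)) < n1 + n2
    if n1 + n2 <= EXACT_MWW_MAX_N and not has_ties:
        counts = _u_exact_counts(n1, n2)
        total = counts.sum()
        ui = int(round(u))
        lower = counts[: ui + 1].sum() / total
        upper = counts[ui:].sum() / total
        p = min(1.0, 2.0 * min(lower, upper))
        return u, p

    mean_u = n1 * n2 / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(combined, return_counts=True)
    tie_term = float(((tie_counts**3 - tie_counts)).sum())
    var_u = n1 * n2 / 12.0 * ((n + 1) - tie_term / (n * (n - 1)))
    if var_u <= 0:
        return u, 1.0  # all observations identical
    z = (abs(u - mean_u) - 0.5) / math.sqrt(var_u)
    z = max(z, 0.0)
    p = 2.0 * float(_norm.sf(z))
    return u, min(p, 1.0)


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q values."""
    p = np.asarray(pvals, dtype=float)
    if p.ndim != 1:
        raise StatError("pvals must be a vector")
    if len(p) == 0:
        return p.copy()
    if np.isnan(p).any() or (p < 0).any() or (p > 1).any():
        raise StatError("p values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="mergesort")
    q_sorted = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(q_sorted[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


# ---------------------------------------------------------------------------
# Report sections


@dataclass
class StratifiedReport:
    """Named TSV-serializable sections of a stratified analysis."""

    sections: dict[str, pd.DataFrame] = field(default_factory=dict)

    def add(self, name: str, df: pd.DataFrame) -> None:
        self.sections[name] = df

    def to_tsv(self, outdir) -> list[str]:
        import os

        paths = []
        os.makedirs(outdir, exist_ok=True)
        for name in sorted(self.sections):
            path = os.path.join(outdir, f"{name}.tsv")
            self.sections[name].to_csv(path, sep="\t", float_format="%.6g", index=False)
            paths.append(path)
        return paths

    def summary(self) -> str:
        lines = ["Stratified report", "================="]
        for name in sorted(self.sections):
            df = self.sections[name]
            lines.append(f"[{name}] {len(df)} rows")
            if "q" in df.columns and len(df):
                sig = int((df["q"] < 0.05).sum())
                lines.append(f"  tests with q < 0.05: {sig}/{df['q'].notna().sum()}")
        return "\n".join(lines)


def _align(delta: pd.Series, other: pd.Series) -> tuple[np.ndarray, np.ndarray]:
    joined = pd.concat([delta, other], axis=1, join="inner").dropna()
    if joined.empty:
        raise StatError("no genes in common between localization table and metrics")
    return joined.iloc[:, 0].to_numpy(float), joined.iloc[:, 1].to_numpy(float)


def _delta_series(localization_table: pd.DataFrame, column: str = "delta_shrunk") -> pd.Series:
    return localization_table[column]


def feature_correlations(
    localization_table: pd.DataFrame,
    gene_metrics: pd.DataFrame,
    covariates: Mapping[str, pd.Series] | None = None,
    delta_column: str = "delta_shrunk",
) -> pd.DataFrame:
    """Spearman rho of delta vs each architecture metric (and covariates)."""
    delta = _delta_series(localization_table, delta_column)
    rows = []
    items = [(c, gene_metrics[c]) for c in FEATURE_COLUMNS if c in gene_metrics.columns]
    if covariates:
        items += list(covariates.items())
    for name, series in items:
        d, v = _align(delta, series)
        if len(d) < 3:
            continue
        rho, p = spearman(v, d)
        rows.append({"metric": name, "rho": rho, "p": p, "n": len(d)})
    if not rows:
        raise StatError("no metric had enough overlapping genes")
    return pd.DataFrame(rows)


def _summaries(delta: pd.Series, labels: pd.Series) -> pd.DataFrame:
    rows = []
    for label, vals in delta.groupby(labels):
        rows.append(
            {
                "group": label,
                "n": len(vals),
                "median": vals.median(),
                "q1": vals.quantile(0.25),
                "q3": vals.quantile(0.75),
            }
        )
    return pd.DataFrame(rows).sort_values("group", kind="mergesort").reset_index(drop=True)


def group_compare(
    localization_table: pd.DataFrame,
    groups: Mapping[str, str] | pd.Series,
    delta_column: str = "delta_shrunk",
    mode: str = "vs_background",
) -> StratifiedReport:
    """Compare delta distributions between gene groups.

    ``groups`` maps gene_id -> label.  ``mode='vs_background'`` tests each
    group against all other labelled genes (the group itself excluded from
    the background); ``mode='pairwise'`` tests every pair of groups.  BH
    adjustment spans all tests of the section.  Groups with fewer than two
    members are excluded with a warning.
    """
    delta = _delta_series(localization_table, delta_column)
    labels = pd.Series(groups).reindex(delta.index).dropna()
    delta = delta.loc[labels.index]
    sizes = labels.value_counts()
    small = sizes[sizes < 2].index.tolist()
    if small:
        warnings.warn(f"groups with < 2 members excluded: {small}")
        keep = ~labels.isin(small)
        labels, delta = labels[keep], delta[keep]
    names = sorted(labels.unique())
    if len(names) < 2:
        raise StatError("need at least two groups with >= 2 members")

    report = StratifiedReport()
    report.add("group_summaries", _summaries(delta, labels))

    rows = []
    if mode == "pairwise":
        pairs = list(itertools.combinations(names, 2))
        for a, b in pairs:
            u, p = mann_whitney_u(delta[labels == a], delta[labels == b])
            rows.append({"group_a": a, "group_b": b, "U": u, "p": p})
    elif mode == "vs_background":
        for a in names:
            u, p = mann_whitney_u(delta[labels == a], delta[labels != a])
            rows.append({"group_a": a, "group_b": "background", "U": u, "p": p})
    else:
        raise StatError(f"unknown mode {mode!r}")
    tests = pd.DataFrame(rows)
    tests["q"] = bh_adjust(tests["p"].to_numpy())
    report.add("group_tests", tests)
    return report


def length_bin_analysis(
    localization_table: pd.DataFrame,
    gene_metrics: pd.DataFrame,
    delta_column: str = "delta_shrunk",
) -> StratifiedReport:
    """Delta distributions across pre-mRNA length bins with MWW + BH tests.

    Tests each adjacent bin pair and each bin against all other genes; empty
    bins appear in the summary with n = 0 and contribute no tests.
    """
    from .annotation import LENGTH_BIN_LABELS, assign_length_bin

    delta = _delta_series(localization_table, delta_column)
    lengths = gene_metrics["pre_mrna_length"].reindex(delta.index).dropna()
    delta = delta.loc[lengths.index]
    bins = lengths.map(assign_length_bin)

    report = StratifiedReport()
    summ_rows = []
    for label in LENGTH_BIN_LABELS:
        vals = delta[bins == label]
        summ_rows.append(
            {
                "bin": label,
                "n": len(vals),
                "median": vals.median() if len(vals) else np.nan,
                "q1": vals.quantile(0.25) if len(vals) else np.nan,
                "q3": vals.quantile(0.75) if len(vals) else np.nan,
            }
        )
    report.add("length_bin_summaries", pd.DataFrame(summ_rows))

    rows = []
    occupied = [b for b in LENGTH_BIN_LABELS if (bins == b).sum() >= 2]
    for a, b in zip(occupied[:-1], occupied[1:]):
        u, p = mann_whitney_u(delta[bins == a], delta[bins == b])
        rows.append({"kind": "adjacent", "bin_a": a, "bin_b": b, "U": u, "p": p})
    if len(occupied) >= 2:
        for a in occupied:
            u, p = mann_whitney_u(delta[bins == a], delta[bins != a])
            rows.append({"kind": "vs_rest", "bin_a": a, "bin_b": "rest", "U": u, "p": p})
    tests = pd.DataFrame(rows, columns=["kind", "bin_a", "bin_b", "U", "p"])
    tests["q"] = bh_adjust(tests["p"].to_numpy()) if len(tests) else np.nan
    report.add("length_bin_tests", tests)
    return report


DEFAULT_LENGTH_WINDOWS = {"5-6 kb": (5000, 6000), "20-25 kb": (20_000, 25_000)}


def length_controlled_exon_analysis(
    localization_table: pd.DataFrame,
    gene_metrics: pd.DataFrame,
    windows: Mapping[str, tuple[float, float]] | None = None,
    delta_column: str = "delta_shrunk",
    min_group: int = 5,
) -> StratifiedReport:
    """Disentangle exon count from pre-mRNA length.

    Within each narrow length window, compares delta between genes of
    different (rounded) exon counts; across windows, compares genes of the
    same exon count.  If length — not splicing — drives the localization
    effect, within-window comparisons are null while matched between-window
    comparisons are significant.  BH spans all tests of the section.
    """
    if windows is None:
        windows = DEFAULT_LENGTH_WINDOWS
    delta = _delta_series(localization_table, delta_column)
    gm = gene_metrics.reindex(delta.index).dropna(subset=["pre_mrna_length"])
    delta = delta.loc[gm.index]

    report = StratifiedReport()
    summ_rows, test_rows = [], []
    window_groups: dict[str, dict[int, pd.Series]] = {}
    for wname, (lo, hi) in windows.items():
        in_w = (gm["pre_mrna_length"] >= lo) & (gm["pre_mrna_length"] < hi)
        sub_delta = delta[in_w]
        sub_exons = gm.loc[in_w, "rounded_exon_count"]
        groups = {
            int(k): sub_delta[sub_exons == k]
            for k in sorted(sub_exons.unique())
            if (sub_exons == k).sum() >= min_group
        }
        window_groups[wname] = groups
        for k, vals in groups.items():
            summ_rows.append(
                {
                    "window": wname,
                    "exon_count": k,
                    "n": len(vals),
                    "median": vals.median(),
                    "q1": vals.quantile(0.25),
                    "q3": vals.quantile(0.75),
                }
            )
        if len(groups) >= 2:
            for a, b in itertools.combinations(sorted(groups), 2):
                u, p = mann_whitney_u(groups[a], groups[b])
                test_rows.append(
                    {
                        "kind": "within_window",
                        "window_a": wname,
                        "window_b": wname,
                        "exon_a": a,
                        "exon_b": b,
                        "U": u,
                        "p": p,
                    }
                )

    wnames = list(windows)
    for wa, wb in itertools.combinations(wnames, 2):
        shared = sorted(set(window_groups.get(wa, {})) & set(window_groups.get(wb, {})))
        for k in shared:
            u, p = mann_whitney_u(window_groups[wa][k], window_groups[wb][k])
            test_rows.append(
                {
                    "kind": "between_window",
                    "window_a": wa,
                    "window_b": wb,
                    "exon_a": k,
                    "exon_b": k,
                    "U": u,
                    "p": p,
                }
            )
        if shared:
            # pooled matched-exon comparison: all genes whose exon count
            # occurs in both windows, compared window vs window
            pool_a = pd.concat([window_groups[wa][k] for k in shared])
            pool_b = pd.concat([window_groups[wb][k] for k in shared])
            u, p = mann_whitney_u(pool_a, pool_b)
            test_rows.append(
                {
                    "kind": "between_window_pooled",
                    "window_a": wa,
                    "window_b": wb,
                    "exon_a": -1,
                    "exon_b": -1,
                    "U": u,
                    "p": p,
                }
            )

    report.add(
        "exon_window_summaries",
        pd.DataFrame(summ_rows, columns=["window", "exon_count", "n", "median", "q1", "q3"]),
    )
    tests = pd.DataFrame(
        test_rows, columns=["kind", "window_a", "window_b", "exon_a", "exon_b", "U", "p"]
    )
    tests["q"] = bh_adjust(tests["p"].to_numpy()) if len(tests) else np.nan
    report.add("exon_window_tests", tests)
    return report
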