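"""Paired two-device statistics.

Device comparisons follow the non-parametric paired recipe standard in
method-comparison studies: a Shapiro-Wilk normality check (used only to
choose between median(IQR) and mean(SD) summaries — the paired test is
always the Wilcoxon signed-rank test), the Wilcoxon signed-rank test on
per-eye paired values, and Cliff's delta as the paired effect size,

    delta = (n_plus - n_minus) / n,

where n_plus / n_minus count pairs in which the reference device's value
is larger / smaller and ties count only in the denominator.  delta = +1
(-1) means the reference device dominates (is dominated) in every pair.

Wilcoxon conventions: zero differences are dropped, tied absolute
differences receive mid-ranks, the null distribution is enumerated exactly
(via dynamic programming over the rank-sum distribution) for n <= 25 and
approximated normally with continuity and tie corrections above.
P-values are two-sided and unadjusted (no multiplicity correction by
default; Holm adjustment is available as an option).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

EXACT_N_MAX = 25


@dataclass
class PairedSeries:
    """Aligned per-eye values from two devices for one metric."""

    metric: str
    a: np.ndarray
    b: np.ndarray

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.b = np.asarray(self.b, dtype=float)
        if self.a.shape != self.b.shape or self.a.ndim != 1:
            raise ValueError("paired series must be equal-length 1-D arrays")
        if self.a.size < 1:
            raise ValueError("need at least one pair")

    @property
    def n(self) -> int:
        return self.a.size

    @property
    def differences(self) -> np.ndarray:
        return self.a - self.b


@dataclass
class PairedComparison:
    """One metric's two-device comparison row."""

    metric: str
    plexus: str
    n: int
    median_a: float
    iqr_a: float
    median_b: float
    iqr_b: float
    mean_a: float
    sd_a: float
    mean_b: float
    sd_b: float
    display: str  # 'median_iqr' | 'mean_sd'
    p_value: float
    delta: float
    n_plus: int
    n_minus: int
    n_ties: int

    def summary(self, which: str) -> str:
        if self.display == "mean_sd":
            m = self.mean_a if which == "a" else self.mean_b
            s = self.sd_a if which == "a" else self.sd_b
            return f"{m:.4g} ({s:.4g})"
        m = self.median_a if which == "a" else self.median_b
        s = self.iqr_a if which == "a" else self.iqr_b
        return f"{m:.4g} ({s:.4g})"


def iqr(values) -> float:
    """Interquartile range with linear percentile interpolation."""
    v = np.asarray(values, dtype=float)
    return float(np.percentile(v, 75, method="linear")
                 - np.percentile(v, 25, method="linear"))


def normality_gate(values) -> tuple[bool, float]:
    """Shapiro-Wilk normality check: (p >= 0.05, p).

    Degenerate (constant) samples are treated as non-normal with p = NaN.
    Sample size must be in [3, 5000].
    """
    v = np.asarray(values, dtype=float)
    if not 3 <= v.size <= 5000:
        raise ValueError("Shapiro-Wilk requires 3 <= n <= 5000")
    if np.ptp(v) == 0:
        return False, math.nan
    w, p = sps.shapiro(v)
    return bool(p >= 0.05), float(p)


def _exact_signed_rank_p(doubled_ranks: np.ndarray, w2: float) -> float:
    """Two-sided exact p for the signed-rank statistic.

    ``doubled_ranks`` are the (mid-)ranks of |d| times two, so they are
    integers even under ties; the null distribution of the doubled
    positive-rank sum is built by dynamic programming over all 2^n sign
    assignments.
    """
    total = int(doubled_ranks.sum())
    counts = np.zeros(total + 1, dtype=float)
    counts[0] = 1.0
    for r in doubled_ranks:
        r = int(r)
        shifted = np.zeros_like(counts)
        shifted[r:] = counts[:-r] if r > 0 else counts
        counts = counts + shifted
    n_assign = counts.sum()
    w2i = int(round(w2))
    p_le = counts[: w2i + 1].sum() / n_assign
    p_ge = counts[w2i:].sum() / n_assign
    return float(min(1.0, 2.0 * min(p_le, p_ge)))


def wilcoxon_signed_rank(pairs: PairedSeries | np.ndarray, b=None) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired data.

    Accepts a :class:`PairedSeries` or two arrays.  Zero differences are
    dropped; if all differences are zero the test is vacuous and p = 1.
    Exact enumeration for n <= 25 effective pairs, else a normal
    approximation with continuity and tie corrections.
    """
    if isinstance(pairs, PairedSeries):
        d = pairs.differences
    else:
        a = np.asarray(pairs, dtype=float)
        d = a - np.asarray(b, dtype=float) if b is not None else a
    d = d[d != 0]
    n = d.size
    if n == 0:
        return 1.0
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_N_MAX:
        doubled = np.rint(2.0 * ranks).astype(int)
        return _exact_signed_rank_p(doubled, 2.0 * w_plus)
    mn = n * (n + 1) * 0.25
    se = n * (n + 1) * (2 * n + 1)
    _, tie_counts = np.unique(ranks, return_counts=True)
    repnum = tie_counts[tie_counts > 1].astype(float)
    if repnum.size:
        se -= 0.5 * (repnum * (repnum * repnum - 1)).sum()
    se = math.sqrt(se / 24.0)
    correction = 0.5 * np.sign(w_plus - mn)
    z = (w_plus - mn - correction) / se
    return float(2.0 * sps.norm.sf(abs(z)))


def cliffs_delta(pairs: PairedSeries | np.ndarray, b=None) -> tuple[float, int, int, int]:
    """Paired Cliff's delta: ((n+ - n-)/n, n_plus, n_minus, n_ties).

    Ties count in the denominator but in neither n_plus nor n_minus.
    """
    if isinstance(pairs, PairedSeries):
        d = pairs.differences
    else:
        d = np.asarray(pairs, dtype=float) - np.asarray(b, dtype=float)
    if d.size < 1:
        raise ValueError("need at least one pair")
    n_plus = int((d > 0).sum())
    n_minus = int((d < 0).sum())
    n_ties = d.size - n_plus - n_minus
    return (n_plus - n_minus) / d.size, n_plus, n_minus, n_ties


def holm_adjust(p_values) -> np.ndarray:
    """Holm step-down adjustment (optional; off by default in tables)."""
    p = np.asarray(p_values, dtype=float)
    order = np.argsort(p)
    adjusted = np.empty_like(p)
    running = 0.0
    for rank, idx in enumerate(order):
        running = max(running, (p.size - rank) * p[idx])
        adjusted[idx] = min(1.0, running)
    return adjusted


# metrics summarized as mean (SD) regardless of the normality gate; the
# fractal dimension varies too little for median/IQR to be informative
MEAN_SD_METRICS = frozenset({"fd"})


def device_comparison_table(
    records,
    metrics: list[str],
    device_a: str,
    device_b: str,
    pair_on: tuple[str, ...] = ("participant", "eye"),
    group_by: str = "plexus",
    holm: bool = False,
):
    """Build a per-metric paired comparison table from a records DataFrame.

    ``records`` must hold one row per (eye, device) with metric columns;
    eyes missing either device for a metric are excluded from that metric's
    comparison (with the exclusion count retained in ``n``).  Returns a
    DataFrame with one row per (group, metric): summaries for both devices,
    the Wilcoxon p-value, and Cliff's delta with ``device_a`` as reference.
    """
    import pandas as pd

    records = pd.DataFrame(records)
    rows = []
    groups = records[group_by].unique() if group_by in records else [None]
    for group in groups:
        sub = records[records[group_by] == group] if group is not None else records
        for metric in metrics:
            if metric not in sub.columns:
                continue
            wide = sub.pivot_table(
                index=list(pair_on), columns="device", values=metric, aggfunc="first"
            )
            if device_a not in wide.columns or device_b not in wide.columns:
                continue
            wide = wide[[device_a, device_b]].dropna()
            if wide.empty:
                continue
            a = wide[device_a].to_numpy(float)
            bvals = wide[device_b].to_numpy(float)
            series = PairedSeries(metric, a, bvals)
            try:
                normal_a, _ = normality_gate(a)
                normal_b, _ = normality_gate(bvals)
                both_normal = normal_a and normal_b
            except ValueError:
                both_normal = False
            display = "mean_sd" if (metric in MEAN_SD_METRICS or both_normal) \
                else "median_iqr"
            delta, n_plus, n_minus, n_ties = cliffs_delta(series)
            rows.append(PairedComparison(
                metric=metric, plexus=str(group), n=series.n,
                median_a=float(np.median(a)), iqr_a=iqr(a),
                median_b=float(np.median(bvals)), iqr_b=iqr(bvals),
                mean_a=float(np.mean(a)), sd_a=float(np.std(a, ddof=1)) if len(a) > 1 else math.nan,
                mean_b=float(np.mean(bvals)), sd_b=float(np.std(bvals, ddof=1)) if len(bvals) > 1 else math.nan,
                display=display, p_value=wilcoxon_signed_rank(series),
                delta=delta, n_plus=n_plus, n_minus=n_minus, n_ties=n_ties,
            ))
    table = pd.DataFrame([vars(r) for r in rows])
    if holm and not table.empty:
        table["p_holm"] = holm_adjust(table["p_value"].to_numpy())
    return table


def comparison_table_text(table, device_a: str = "A", device_b: str = "B") -> str:
    """Render a comparison table as fixed-width text."""
    lines = [
        f"{'plexus':<7}{'metric':<16}{'n':>4}  {device_a + ' summary':<22}"
        f"{device_b + ' summary':<22}{'p':>10}{'delta':>8}"
    ]
    for _, r in table.iterrows():
        comp = PairedComparison(**{k: r[k] for k in PairedComparison.__dataclass_fields__})
        lines.append(
            f"{r['plexus']:<7}{r['metric']:<16}{r['n']:>4}  "
            f"{comp.summary('a'):<22}{comp.summary('b'):<22}"
            f"{r['p_value']:>10.4g}{r['delta']:>8.2f}"
        )
    return "\n".join(lines)
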