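"""Rank-based association machinery and the correlation-matrix analyses.

Spearman's rho with mid-ranks for ties is the primary statistic; its
two-sided p-value uses the classical t approximation on n-2 degrees of
freedom for n > 9 (the convention of mainstream clinical-statistics
software) and the exact permutation null for small n. Group contrasts
use the Mann-Whitney U test, exact by enumeration for small samples and
tie-corrected normal approximation otherwise.

Matrix analyses correlate the per-course PASI change with every
biomarker-index change, in either ``rate`` or ``difference`` mode, with
pairwise deletion of censored cells: a course censored for one ratio
still contributes to every cell it has values for. No multiple-testing
correction is applied by default; a Benjamini-Hochberg option exists for
reanalysis.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .indices import FIXTURE_INDICES, build_index_change_table
from .model import CohortDataset
from .outcomes import build_pasi_table

__all__ = [
    "CorrelationResult",
    "CorrelationMatrix",
    "spearman_rho",
    "spearman_p",
    "spearman_test",
    "mann_whitney_u",
    "build_change_frames",
    "correlation_matrix",
    "subgroup_analyses",
    "export_heatmap_table",
    "plot_heatmap",
    "significance_stars",
    "benjamini_hochberg",
    "PASI_VARIABLE",
    "EXACT_N_MAX",
]

PASI_VARIABLE = "PASI"

#: Largest n for which the exact Spearman permutation null is enumerated.
EXACT_N_MAX = 9

#: The Mann-Whitney null is enumerated whenever the group sizes are small
#: enough that the exact distribution is cheap and the normal
#: approximation still shaky: n_a*n_b <= 20 or n_a+n_b <= 10.
_MWU_EXACT_PRODUCT_MAX = 20
_MWU_EXACT_TOTAL_MAX = 10

_TINY = float(np.nextafter(0, 1))


def spearman_rho(x, y) -> float:
    """Tie-aware Spearman rho: the Pearson correlation of mid-ranks."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError(f"x and y must be equal-length vectors, got {x.shape} and {y.shape}")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if np.isnan(x).any() or np.isnan(y).any():
        raise ValueError("missing values: caller must perform pairwise deletion first")
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    if np.ptp(rx) == 0 or np.ptp(ry) == 0:
        raise ValueError("rho undefined for a constant vector (zero rank variance)")
    return float(np.corrcoef(rx, ry)[0, 1])


@lru_cache(maxsize=16)
def _exact_rho_distribution(n: int) -> np.ndarray:
    """All n! Spearman rho values for untied ranks 1..n, sorted."""
    base = np.arange(1, n + 1)
    denom = n * (n * n - 1)
    out = np.empty(math.factorial(n))
    for i, perm in enumerate(itertools.permutations(range(1, n + 1))):
        d2 = int(np.sum((base - np.asarray(perm)) ** 2))
        out[i] = 1.0 - 6.0 * d2 / denom
    out.sort()
    return out


def spearman_p(rho: float, n: int, exact_n_max: int = EXACT_N_MAX) -> float:
    """Two-sided p-value for an observed Spearman rho at sample size n.

    For n > *exact_n_max*: the t approximation
    ``t = rho * sqrt((n-2)/(1-rho^2))`` on n-2 degrees of freedom.
    For small n: the exact permutation null over all n! untied rankings.
    |rho| = 1 on the t branch returns the smallest positive float rather
    than dividing by zero.
    """
    if n < 3:
        raise ValueError("p-value requires n >= 3")
    if abs(rho) > 1 + 1e-12:
        raise ValueError(f"|rho| > 1: {rho}")
    rho = float(np.clip(rho, -1.0, 1.0))
    if n <= exact_n_max:
        dist = _exact_rho_distribution(n)
        return float(np.mean(np.abs(dist) >= abs(rho) - 1e-12))
    if abs(rho) == 1.0:
        return _TINY
    t = rho * math.sqrt((n - 2) / (1.0 - rho * rho))
    return float(2.0 * stats.t.sf(abs(t), df=n - 2))


@dataclass(frozen=True)
class CorrelationResult:
    """One pairwise Spearman result."""

    var_a: str
    var_b: str
    n: int
    rho: float
    p_value: Optional[float]
    method: str  # "t_approx" | "exact_permutation" | "identity"

    @property
    def stars(self) -> str:
        return significance_stars(self.p_value)


def spearman_test(x, y, var_a: str = "x", var_b: str = "y") -> CorrelationResult:
    """rho plus its p-value, choosing the exact/approximate branch by n."""
    x = np.asarray(x, dtype=float)
    n = int(x.size)
    rho = spearman_rho(x, y)
    method = "exact_permutation" if n <= EXACT_N_MAX else "t_approx"
    return CorrelationResult(var_a, var_b, n, rho, spearman_p(rho, n), method)


def mann_whitney_u(group_a, group_b) -> tuple[float, float]:
    """Mann-Whitney U (of *group_a*) and two-sided p-value.

    Exact enumeration of all group labelings when n_a*n_b <= 20 or
    n_a+n_b <= 10 (ties handled through mid-rank U values); otherwise
    the tie-corrected normal approximation without continuity correction.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    na, nb = a.size, b.size
    pooled = np.concatenate([a, b])
    ranks = stats.rankdata(pooled)
    u_a = float(ranks[:na].sum() - na * (na + 1) / 2.0)
    if np.ptp(pooled) == 0:  # every observation tied: no evidence either way
        return u_a, 1.0
    if na * nb > _MWU_EXACT_PRODUCT_MAX and na + nb > _MWU_EXACT_TOTAL_MAX:
        _, p = stats.mannwhitneyu(
            a, b, alternative="two-sided", method="asymptotic", use_continuity=False
        )
        return u_a, float(p)
    mu = na * nb / 2.0
    dev = abs(u_a - mu)
    count = 0
    total = 0
    idx = range(na + nb)
    for comb in itertools.combinations(idx, na):
        u = float(ranks[list(comb)].sum() - na * (na + 1) / 2.0)
        count += abs(u - mu) >= dev - 1e-12
        total += 1
    return u_a, count / total


def significance_stars(p: Optional[float]) -> str:
    """Star annotation: * p<0.05, ** p<0.01, *** p<0.001."""
    if p is None:
        return ""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def benjamini_hochberg(p_values: list[float]) -> list[float]:
    """BH-adjusted q-values, preserving input order."""
    p = np.asarray(p_values, dtype=float)
    m = p.size
    order = np.argsort(p)
    q = np.empty(m)
    running = 1.0
    for rank_idx in range(m - 1, -1, -1):
        i = order[rank_idx]
        running = min(running, p[i] * m / (rank_idx + 1))
        q[i] = running
    return q.tolist()


def build_change_frames(
    ds: CohortDataset,
    indices=FIXTURE_INDICES,
    denominator_floor: Optional[float] = None,
) -> dict[str, pd.DataFrame]:
    """Wide per-course change tables, one per mode.

    Each frame has one row per biologic course with columns
    ``patient_id``, ``biologic``, ``has_psa``, ``PASI`` and one column
    per index label; censored index changes are NaN.
    """
    kwargs = {} if denominator_floor is None else {"denominator_floor": denominator_floor}
    records = build_index_change_table(ds, indices, **kwargs)
    pasi = {(p.patient_id, p.biologic): p for p in build_pasi_table(ds)}
    psa = {p.patient_id: p.has_psa for p in ds.patients}

    frames = {}
    for mode, idx_attr, pasi_attr in (
        ("rate", "reduction_rate", "rate"),
        ("difference", "difference", "difference"),
    ):
        rows: dict[tuple[str, str], dict] = {}
        for c in ds.courses:
            key = (c.patient_id, c.biologic)
            rows[key] = {
                "patient_id": c.patient_id,
                "biologic": c.biologic,
                "has_psa": psa[c.patient_id],
                PASI_VARIABLE: getattr(pasi[key], pasi_attr),
            }
        for r in records:
            val = getattr(r, idx_attr)
            rows[(r.patient_id, r.biologic)][r.index.label] = (
                np.nan if val is None else val
            )
        frames[mode] = pd.DataFrame(list(rows.values()))
    return frames


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric matrix of pairwise Spearman results for one mode."""

    mode: str  # "rate" | "difference"
    variables: tuple[str, ...]
    cells: dict[tuple[str, str], Optional[CorrelationResult]]
    subgroup: Optional[str] = None
    n_rows: int = 0
    low_n: bool = False

    def cell(self, a: str, b: str) -> Optional[CorrelationResult]:
        return self.cells[tuple(sorted((a, b)))]

    def rho(self, a: str, b: str) -> float:
        c = self.cell(a, b)
        return math.nan if c is None else c.rho

    def to_wide_frame(self, value: str = "rho") -> pd.DataFrame:
        data = {
            vb: [getattr(self.cell(va, vb), value) if self.cell(va, vb) else np.nan
                 for va in self.variables]
            for vb in self.variables
        }
        return pd.DataFrame(data, index=list(self.variables))


def correlation_matrix(
    frame: pd.DataFrame,
    mode: str,
    subgroup: Optional[str] = None,
    variables: Optional[list[str]] = None,
    min_n: int = 3,
) -> CorrelationMatrix:
    """Pairwise Spearman matrix over the variable columns of a change frame.

    Each cell uses the pairwise-complete rows for its two variables; a
    cell with fewer than *min_n* complete pairs is reported undefined
    (``None``) rather than raising.
    """
    if variables is None:
        variables = [c for c in frame.columns
                     if c not in ("patient_id", "biologic", "has_psa")]
    cells: dict[tuple[str, str], Optional[CorrelationResult]] = {}
    for va, vb in itertools.combinations_with_replacement(sorted(variables), 2):
        if va == vb:
            n = int(frame[va].notna().sum())
            cells[(va, vb)] = CorrelationResult(va, vb, n, 1.0, None, "identity")
            continue
        sub = frame[[va, vb]].dropna()
        if len(sub) < min_n:
            cells[(va, vb)] = None
            continue
        try:
            cells[(va, vb)] = spearman_test(sub[va], sub[vb], va, vb)
        except ValueError:  # constant column in this stratum
            cells[(va, vb)] = None
    return CorrelationMatrix(
        mode=mode,
        variables=tuple(variables),
        cells=cells,
        subgroup=subgroup,
        n_rows=len(frame),
        low_n=len(frame) < 4,
    )


def subgroup_analyses(
    ds: CohortDataset,
    grouping: str,
    indices=FIXTURE_INDICES,
    denominator_floor: Optional[float] = None,
) -> list[CorrelationMatrix]:
    """Per-stratum matrix pairs (rate then difference).

    ``by_biologic`` strata are the distinct biologic labels among the
    courses; ``by_disease`` yields exactly the PsO-only and PsO+PsA
    strata of the patient-level arthritis flag.
    """
    if grouping not in ("by_biologic", "by_disease"):
        raise ValueError(f"unknown grouping {grouping!r}")
    frames = build_change_frames(ds, indices, denominator_floor)
    out: list[CorrelationMatrix] = []
    if grouping == "by_biologic":
        labels = sorted({c.biologic for c in ds.courses})
        selectors = [(lab, lambda f, lab=lab: f["biologic"] == lab) for lab in labels]
    else:
        selectors = [
            ("PsO-only", lambda f: ~f["has_psa"]),
            ("PsO+PsA", lambda f: f["has_psa"]),
        ]
    for label, sel in selectors:
        for mode in ("rate", "difference"):
            f = frames[mode]
            out.append(correlation_matrix(f[sel(f)], mode, subgroup=label))
    return out


def export_heatmap_table(matrix: CorrelationMatrix) -> pd.DataFrame:
    """Plot-ready long table: one row per off-diagonal unordered pair."""
    rows = []
    for (va, vb), cell in sorted(matrix.cells.items()):
        if va == vb:
            continue
        rows.append(
            {
                "mode": matrix.mode,
                "subgroup": matrix.subgroup,
                "var_a": va,
                "var_b": vb,
                "n": None if cell is None else cell.n,
                "rho": np.nan if cell is None else cell.rho,
                "p_value": np.nan if cell is None else cell.p_value,
                "stars": "" if cell is None else cell.stars,
            }
        )
    return pd.DataFrame(rows)


def plot_heatmap(matrix: CorrelationMatrix, path) -> None:
    """Render the matrix as an annotated heatmap (rho color, p stars)."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    wide = matrix.to_wide_frame("rho")
    fig, ax = plt.subplots(figsize=(1.1 * len(wide) + 2, 1.0 * len(wide) + 1.5))
    im = ax.imshow(wide.values, vmin=-1, vmax=1, cmap="RdBu_r")
    ax.set_xticks(range(len(wide)), wide.columns, rotation=45, ha="right")
    ax.set_yticks(range(len(wide)), wide.index)
    for i, va in enumerate(matrix.variables):
        for j, vb in enumerate(matrix.variables):
            cell = matrix.cell(va, vb)
            if cell is None:
                txt = "n/a"
            else:
                txt = f"{cell.rho:.2f}{cell.stars}" if va != vb else "1.00"
            ax.text(j, i, txt, ha="center", va="center", fontsize=8)
    title = f"Spearman rho ({matrix.mode} mode)"
    if matrix.subgroup:
        title += f" — {matrix.subgroup} (n={matrix.n_rows})"
    ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
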