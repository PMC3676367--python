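"""Statistics for normalised canopy-temperature data.

Sums of squares are accumulated explicitly from the mean decomposition (not
delegated to a formula interface) so every table entry can be checked against
a brute-force oracle; distribution functions (t, F) come from scipy.

Contents: the two-way genotype x day ANOVA on per-plot NPT values, the
one-way ANOVA treating per-day genotype means as replicates, the t-based
least significant difference, a Monte-Carlo randomisation test that permutes
genotype labels independently within each day (yielding the *apparent* LSD —
the difference magnitude obtainable by chance alone), Spearman rank
correlation with average ranks, rank consistency of the temperature extremes,
occasion correlation matrices with day-mean columns, and forward-stepwise
regression of yield on temperature, maturity and height.
"""

from __future__ import annotations

import logging
import math
import warnings
from dataclasses import dataclass, field
from typing import Hashable, Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats as sps

logger = logging.getLogger(__name__)

__all__ = [
    "RandomizationResult",
    "StepwiseResult",
    "ExtremeSubsetResult",
    "anova_twoway",
    "anova_on_means",
    "lsd",
    "monte_carlo_randomization",
    "spearman_rho",
    "rank_matrix",
    "extreme_subset_rho",
    "correlation_matrix",
    "forward_stepwise",
]

ANOVA_COLUMNS = ["df", "SS", "MS", "F", "p"]


def _anova_frame(rows: dict[str, tuple]) -> pd.DataFrame:
    table = pd.DataFrame.from_dict(rows, orient="index", columns=ANOVA_COLUMNS)
    table.index.name = "source"
    return table


# ---------------------------------------------------------------------------
# ANOVA

def anova_twoway(data: pd.DataFrame, value_col: str = "value") -> pd.DataFrame:
    """Two-way genotype x day ANOVA with replication on per-plot values.

    ``data`` is tidy with columns ``genotype``, ``day``, ``replicate`` and the
    value column.  For balanced data (every genotype x day cell holding the
    same number of replicates, >= 2) the exact orthogonal decomposition is
    used; unbalanced data fall back to sequential (Type I) sums of squares in
    the order Genotype, Days, Interaction, with a logged note.  F ratios test
    each source against the error mean square.
    """
    for col in ("genotype", "day", "replicate", value_col):
        if col not in data.columns:
            raise ValueError(f"missing column {col!r}")
    genos = sorted(data["genotype"].unique())
    days = sorted(data["day"].unique())
    if len(genos) < 2 or len(days) < 2:
        raise ValueError("need at least 2 genotypes and 2 days")
    cell_counts = data.groupby(["genotype", "day"], sort=False)[value_col].size()
    if (cell_counts < 1).any() or len(cell_counts) < len(genos) * len(days):
        raise ValueError("every genotype x day cell needs at least one observation")
    if (cell_counts == 1).all():
        raise ValueError("one replicate per cell leaves no error term")

    balanced = cell_counts.nunique() == 1
    n = len(data)
    y = data[value_col].to_numpy(float)
    grand = y.mean()
    ss_total = float(((y - grand) ** 2).sum())

    if balanced:
        r = int(cell_counts.iloc[0])
        G, D = len(genos), len(days)
        mean_g = data.groupby("genotype")[value_col].mean()
        mean_d = data.groupby("day")[value_col].mean()
        mean_gd = data.groupby(["genotype", "day"])[value_col].mean()
        ss_g = D * r * float(((mean_g - grand) ** 2).sum())
        ss_d = G * r * float(((mean_d - grand) ** 2).sum())
        inter = (
            mean_gd
            - mean_g.reindex(mean_gd.index.get_level_values(0)).to_numpy()
            - mean_d.reindex(mean_gd.index.get_level_values(1)).to_numpy()
            + grand
        )
        ss_gd = r * float((inter**2).sum())
        cell_of = data.set_index(["genotype", "day"]).index
        ss_e = float(((y - mean_gd.reindex(cell_of).to_numpy()) ** 2).sum())
        df_g, df_d = G - 1, D - 1
        df_gd, df_e = df_g * df_d, G * D * (r - 1)
    else:
        logger.info("unbalanced genotype x day table: using sequential (Type I) SS")
        Xg = pd.get_dummies(data["genotype"], dtype=float).to_numpy()
        Xd = pd.get_dummies(data["day"].astype(str), dtype=float).to_numpy()
        Xgd = pd.get_dummies(
            data["genotype"].astype(str) + "|" + data["day"].astype(str), dtype=float
        ).to_numpy()
        ones = np.ones((n, 1))

        def rss_rank(X: np.ndarray) -> tuple[float, int]:
            beta, _, rank, _ = np.linalg.lstsq(X, y, rcond=None)
            return float(((y - X @ beta) ** 2).sum()), int(rank)

        rss0, rank0 = rss_rank(ones)
        rss1, rank1 = rss_rank(np.hstack([ones, Xg]))
        rss2, rank2 = rss_rank(np.hstack([ones, Xg, Xd]))
        rss3, rank3 = rss_rank(np.hstack([ones, Xg, Xd, Xgd]))
        ss_g, ss_d, ss_gd, ss_e = rss0 - rss1, rss1 - rss2, rss2 - rss3, rss3
        df_g, df_d, df_gd = rank1 - rank0, rank2 - rank1, rank3 - rank2
        df_e = n - rank3

    if df_e < 1:
        raise ValueError("no error degrees of freedom")
    ms_e = ss_e / df_e
    rows = {}
    for name, ss, df in (
        ("Genotype", ss_g, df_g), ("Days", ss_d, df_d), ("Days x Genotype", ss_gd, df_gd),
    ):
        ms = ss / df
        if ms_e > 0:
            F = ms / ms_e
        else:
            F = np.inf if ms > 0 else np.nan
        rows[name] = (df, ss, ms, F, float(sps.f.sf(F, df, df_e)))
    rows["Error"] = (df_e, ss_e, ms_e, np.nan, np.nan)
    rows["Total"] = (n - 1, ss_total, np.nan, np.nan, np.nan)
    return _anova_frame(rows)


def anova_on_means(means: pd.DataFrame) -> tuple[pd.DataFrame, float]:
    """One-way ANOVA on a genotype x day table of means, days as replicates.

    Returns the table and the percentage of total variation explained by
    genotypes (SS_between / SS_total x 100).
    """
    M = means.to_numpy(float)
    G, D = M.shape
    if D < 2:
        raise ValueError("need at least 2 days to form a within-genotype term")
    if G < 2:
        raise ValueError("need at least 2 genotypes")
    if not np.all(np.isfinite(M)):
        raise ValueError("means table must be complete")
    grand = M.mean()
    row_means = M.mean(axis=1)
    ss_b = D * float(((row_means - grand) ** 2).sum())
    ss_w = float(((M - row_means[:, None]) ** 2).sum())
    df_b, df_w = G - 1, G * (D - 1)
    ms_b, ms_w = ss_b / df_b, ss_w / df_w
    F = ms_b / ms_w if ms_w > 0 else np.inf
    rows = {
        "Genotype": (df_b, ss_b, ms_b, F, float(sps.f.sf(F, df_b, df_w))),
        "Within": (df_w, ss_w, ms_w, np.nan, np.nan),
        "Total": (G * D - 1, ss_b + ss_w, np.nan, np.nan, np.nan),
    }
    total = ss_b + ss_w
    explained = 100.0 * ss_b / total if total > 0 else 100.0
    return _anova_frame(rows), float(explained)


def lsd(ms_error: float, df_error: int, n_per_mean: int, alpha: float = 0.05) -> float:
    """t-based least significant difference for equally replicated means.

    LSD = t(1 - alpha/2, df_error) * sqrt(2 * ms_error / n_per_mean).
    """
    if ms_error <= 0:
        raise ValueError("ms_error must be > 0")
    if df_error < 1 or n_per_mean < 1:
        raise ValueError("df_error and n_per_mean must be >= 1")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    return float(sps.t.ppf(1 - alpha / 2, df_error) * math.sqrt(2 * ms_error / n_per_mean))


# ---------------------------------------------------------------------------
# Monte-Carlo randomisation

@dataclass
class RandomizationResult:
    """Null distribution of genotype differences under label permutation.

    ``apparent_lsd`` is the mean, over permutations, of the LSD computed from
    the null within-genotype mean square — the difference magnitude that
    label noise alone would produce.  ``p_value`` is the add-one permutation
    p for the observed one-way F.
    """

    n_reps: int
    seed: int
    observed_f: float
    observed_range: float
    observed_lsd: float
    apparent_lsd: float
    p_value: float
    null_ranges: np.ndarray = field(repr=False)
    null_f: np.ndarray = field(repr=False)
    null_lsds: np.ndarray = field(repr=False)

    def range_summary(self) -> dict[str, float]:
        q = np.quantile(self.null_ranges, [0.5, 0.95])
        return {
            "mean": float(self.null_ranges.mean()),
            "median": float(q[0]),
            "q95": float(q[1]),
            "max": float(self.null_ranges.max()),
        }


def _oneway_from_table(M: np.ndarray) -> tuple[float, float, float]:
    """(F, ms_within, range of row means) for a genotype x day table."""
    G, D = M.shape
    grand = M.mean()
    rm = M.mean(axis=1)
    ss_b = D * ((rm - grand) ** 2).sum()
    ss_w = ((M - rm[:, None]) ** 2).sum()
    ms_b = ss_b / (G - 1)
    ms_w = ss_w / (G * (D - 1))
    F = ms_b / ms_w if ms_w > 0 else np.inf
    return float(F), float(ms_w), float(rm.max() - rm.min())


def monte_carlo_randomization(
    means: pd.DataFrame,
    n_reps: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> RandomizationResult:
    """Permute genotype labels independently within each day.

    Each permutation shuffles every day's column of the genotype x day means
    table separately, destroying genotypic structure while preserving each
    day's multiset of values, then recomputes the genotype means, their
    range, the one-way F and the LSD from the null within-genotype MS.  The
    p-value is (1 + #{null F >= observed F}) / (n_reps + 1).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    M = np.asarray(means, dtype=float)
    if M.ndim != 2 or M.shape[0] < 2 or M.shape[1] < 2:
        raise ValueError("means must be a genotype x day table with >= 2 of each")
    G, D = M.shape
    df_w = G * (D - 1)
    t_crit = sps.t.ppf(1 - alpha / 2, df_w)

    obs_f, obs_msw, obs_range = _oneway_from_table(M)
    observed_lsd = float(t_crit * math.sqrt(2 * obs_msw / D))

    rng = np.random.default_rng(seed)
    null_f = np.empty(n_reps)
    null_ranges = np.empty(n_reps)
    null_lsds = np.empty(n_reps)
    for b in range(n_reps):
        perm = rng.permuted(M, axis=0)  # each day's column shuffled independently
        f, msw, rng_b = _oneway_from_table(perm)
        null_f[b] = f
        null_ranges[b] = rng_b
        null_lsds[b] = t_crit * math.sqrt(2 * msw / D)

    p = float((1 + (null_f >= obs_f).sum()) / (n_reps + 1))
    return RandomizationResult(
        n_reps=n_reps,
        seed=seed,
        observed_f=obs_f,
        observed_range=obs_range,
        observed_lsd=observed_lsd,
        apparent_lsd=float(null_lsds.mean()),
        p_value=p,
        null_ranges=null_ranges,
        null_f=null_f,
        null_lsds=null_lsds,
    )


# ---------------------------------------------------------------------------
# rank consistency

def spearman_rho(x: Sequence[float], y: Sequence[float]) -> float:
    """Spearman correlation: Pearson correlation of average (midrank) ranks."""
    xv = np.asarray(x, dtype=float)
    yv = np.asarray(y, dtype=float)
    if xv.shape != yv.shape or xv.ndim != 1:
        raise ValueError("x and y must be 1-D of equal length")
    if len(xv) < 3:
        raise ValueError("need at least 3 observations")
    rx = sps.rankdata(xv, method="average")
    ry = sps.rankdata(yv, method="average")
    if np.std(rx) == 0 or np.std(ry) == 0:
        raise ValueError("constant vector: rank correlation undefined")
    return float(np.corrcoef(rx, ry)[0, 1])


def rank_matrix(means_by_occasion: pd.DataFrame) -> pd.DataFrame:
    """Within-occasion ranks of genotype means (1 = coolest, average ties)."""
    return means_by_occasion.apply(lambda col: sps.rankdata(col, method="average"))


@dataclass
class ExtremeSubsetResult:
    """Rank consistency over the temperature-extreme genotypes."""

    subset: list[str]
    rho: pd.DataFrame  # pairwise Spearman between occasions on the subset
    k: int


def extreme_subset_rho(means_by_occasion: pd.DataFrame, k: int) -> ExtremeSubsetResult:
    """Spearman consistency for the k coolest and k hottest genotypes.

    Genotypes are ordered by their mean rank across occasions (boundary ties
    broken by genotype identifier); the k lowest and k highest form the
    subset, and pairwise Spearman correlations between occasions are computed
    on it.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    n = len(means_by_occasion)
    if 2 * k > n:
        raise ValueError(f"2k = {2 * k} exceeds the {n} genotypes available")
    mean_rank = rank_matrix(means_by_occasion).mean(axis=1)
    order = sorted(means_by_occasion.index, key=lambda g: (mean_rank[g], str(g)))
    subset = list(order[:k]) + list(order[-k:])
    sub = means_by_occasion.loc[subset]
    occ = list(means_by_occasion.columns)
    rho = pd.DataFrame(np.eye(len(occ)), index=occ, columns=occ)
    for i, a in enumerate(occ):
        for j in range(i + 1, len(occ)):
            r = spearman_rho(sub[a].to_numpy(), sub[occ[j]].to_numpy())
            rho.iloc[i, j] = rho.iloc[j, i] = r
    return ExtremeSubsetResult(subset=subset, rho=rho, k=k)


def correlation_matrix(
    means_by_occasion: pd.DataFrame,
    days: Mapping[Hashable, Hashable] | None = None,
) -> pd.DataFrame:
    """Pearson correlations between occasions, plus per-day mean columns.

    ``days`` maps each occasion column to its measurement day; for every day
    with more than one occasion a ``day<d>_mean`` column (the average of that
    day's occasions) is appended before the correlation matrix is formed —
    averaging repeated measures raises the correlations relative to single
    occasions.
    """
    if means_by_occasion.shape[1] < 2:
        raise ValueError("need at least 2 occasions")
    if means_by_occasion.shape[0] < 3:
        raise ValueError("need at least 3 genotypes per occasion")
    table = means_by_occasion.astype(float).copy()
    if days is not None:
        by_day: dict[Hashable, list] = {}
        for occ, day in days.items():
            if occ in table.columns:
                by_day.setdefault(day, []).append(occ)
        for day, occs in sorted(by_day.items(), key=lambda kv: str(kv[0])):
            table[f"day{day}_mean"] = means_by_occasion[occs].mean(axis=1)
    return table.corr(method="pearson")


# ---------------------------------------------------------------------------
# forward-stepwise yield regression

@dataclass
class StepwiseResult:
    """Forward-selection path with cumulative r² per entered term."""

    selected: list[str]
    cumulative_r2: list[float]
    entry_f: list[float]
    entry_p: list[float]
    full_model_r2: float
    n_obs: int

    def report(self) -> str:
        lines = ["Forward-stepwise regression", f"n = {self.n_obs} complete cases", ""]
        for term, r2, f, p in zip(self.selected, self.cumulative_r2, self.entry_f, self.entry_p):
            lines.append(
                f"  + {term:<16s} cumulative r2 = {100 * r2:5.1f}%   "
                f"partial F = {f:8.2f}   p = {p:.4g}"
            )
        if not self.selected:
            lines.append("  (no predictor met the entry criterion)")
        lines.append("")
        lines.append(f"full-model r2 (all predictors): {100 * self.full_model_r2:.1f}%")
        return "\n".join(lines)


def forward_stepwise(
    y: Sequence[float],
    predictors: pd.DataFrame,
    alpha_enter: float = 0.05,
) -> StepwiseResult:
    """Forward selection maximising r² with a partial-F entry test.

    At each step the candidate giving the largest r² increase is entered if
    its partial-F p-value is below ``alpha_enter``; candidates that add no
    rank (collinear with the current model) are skipped with a warning.
    Incomplete rows are dropped before fitting.
    """
    if predictors.shape[1] < 2:
        raise ValueError("need at least 2 candidate predictors")
    frame = predictors.astype(float).copy()
    frame.insert(0, "__y__", np.asarray(y, dtype=float))
    frame = frame.dropna()
    if len(frame) < predictors.shape[1] + 2:
        raise ValueError("too few complete cases")
    yv = frame.pop("__y__").to_numpy()
    n = len(yv)

    def fit(cols: list[str]):
        X = sm.add_constant(frame[cols].to_numpy()) if cols else np.ones((n, 1))
        return sm.OLS(yv, X).fit()

    selected: list[str] = []
    cum_r2: list[float] = []
    entry_f: list[float] = []
    entry_p: list[float] = []
    current = fit(selected)
    remaining = list(frame.columns)

    while remaining:
        best = None
        for cand in remaining:
            cols = selected + [cand]
            X = sm.add_constant(frame[cols].to_numpy())
            if np.linalg.matrix_rank(X) <= len(selected) + 1:
                warnings.warn(
                    f"predictor {cand!r} is collinear with the current model; skipped",
                    UserWarning,
                    stacklevel=2,
                )
                continue
            trial = fit(cols)
            if best is None or trial.rsquared > best[1].rsquared:
                best = (cand, trial)
        if best is None:
            break
        cand, model = best
        df_new = n - len(selected) - 2
        if df_new < 1 or model.ssr == 0:
            f_stat, p = np.inf, 0.0
        else:
            f_stat = (current.ssr - model.ssr) / (model.ssr / df_new)
            p = float(sps.f.sf(f_stat, 1, df_new))
        if p >= alpha_enter:
            break
        selected.append(cand)
        remaining.remove(cand)
        current = model
        cum_r2.append(float(model.rsquared))
        entry_f.append(float(f_stat))
        entry_p.append(p)

    full = fit(list(frame.columns)) if np.linalg.matrix_rank(
        sm.add_constant(frame.to_numpy())
    ) > 1 else current
    return StepwiseResult(
        selected=selected,
        cumulative_r2=cum_r2,
        entry_f=entry_f,
        entry_p=entry_p,
        full_model_r2=float(full.rsquared),
        n_obs=n,
    )
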