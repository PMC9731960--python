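"""Median-split group comparison of connectivity edges.

Subjects are split at the empirical median of the trait score (scores below
the median form the Low group; ties at the median go High, which is the
documented tie rule).  Every (ROI pair, band) hypothesis in a family is then
tested with a label-permutation test on the pooled-variance two-sample t
statistic, two-sided, with the add-one Monte-Carlo estimator

    p = (1 + #{ |t*| >= |t_obs| }) / (1 + n_perm)

so p is never exactly zero.  Families (intra-network and inter-network, each
pooled across all bands) are corrected separately with Benjamini-Hochberg
FDR at q = 0.05.  Flagged edges are supplemented with the Pearson
correlation between the trait score and the edge's PLV across the whole
sample.

Permutation randomness: one master seed; each edge derives its own stream
from (seed, i, j, band index), so results are independent of evaluation
order and of which other edges are in the family.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import combinations
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sst
from statsmodels.stats.multitest import multipletests

from .atlas import NetworkAtlas, classify_edge
from .connectivity import PLVMatrixSet


class StatsError(ValueError):
    pass


@dataclass
class GroupSplit:
    median: float
    low_ids: list[str]
    high_ids: list[str]

    @property
    def n_low(self) -> int:
        return len(self.low_ids)

    @property
    def n_high(self) -> int:
        return len(self.high_ids)


@dataclass
class EdgeResult:
    """One (pair, band) hypothesis with its test results."""

    edge: tuple[int, int]
    band: str
    family: str  # e.g. "DMN" or "CON-FPN"
    mean_high: float
    mean_low: float
    stat: float  # pooled-variance two-sample t, High - Low
    p_perm: float
    raw_significant: bool = False
    p_fdr_significant: bool = False
    r_mwq: float | None = None
    r_p: float | None = None


@dataclass
class ComparisonTable:
    results: list[EdgeResult]
    family_kind: str  # "intra" | "inter"

    @property
    def n_tests(self) -> int:
        return len(self.results)

    @property
    def n_significant_raw(self) -> int:
        return sum(r.raw_significant for r in self.results)

    @property
    def n_significant_fdr(self) -> int:
        return sum(r.p_fdr_significant for r in self.results)

    def significant(self) -> list[EdgeResult]:
        return [r for r in self.results if r.p_fdr_significant]


def median_split(scores: Mapping[str, float]) -> GroupSplit:
    """Split subjects at the empirical median of their trait scores."""
    if len(scores) < 4:
        raise StatsError("median split needs at least 4 subjects")
    values = np.array(list(scores.values()), dtype=float)
    if np.all(values == values[0]):
        raise StatsError("all trait scores identical; median split undefined")
    median = float(np.median(values))
    low = [s for s, v in scores.items() if v < median]
    high = [s for s, v in scores.items() if v >= median]
    if not low or not high:
        raise StatsError(
            f"median split produced groups of size {len(low)}/{len(high)}; "
            "both groups must be non-empty"
        )
    if min(len(low), len(high)) < 2:
        warnings.warn(
            "a median-split group has a single member; downstream group "
            "tests require at least 2 per group",
            stacklevel=2,
        )
    return GroupSplit(median, low, high)


def _pooled_t(mean_hi, mean_lo, ss_hi, ss_lo, n_hi: int, n_lo: int):
    """Pooled-variance t from per-group means and raw sums of squares."""
    pooled_ss = (ss_hi - n_hi * mean_hi**2) + (ss_lo - n_lo * mean_lo**2)
    pooled_ss = np.maximum(pooled_ss, 0.0)  # guard rounding
    df = n_hi + n_lo - 2
    se = np.sqrt(pooled_ss / df * (1.0 / n_hi + 1.0 / n_lo))
    diff = mean_hi - mean_lo
    with np.errstate(divide="ignore", invalid="ignore"):
        t = diff / se
        # zero pooled variance: equal means -> t = 0; unequal -> +/- inf
        t = np.where(se == 0, np.where(diff == 0, 0.0, np.inf * np.sign(diff)), t)
    return t


def permutation_edge_test(
    values_low: Sequence[float],
    values_high: Sequence[float],
    n_perm: int = 20000,
    seed: int | np.random.Generator = 0,
    exact: bool = False,
) -> tuple[float, float]:
    """Two-sided label-permutation test of a group difference on one edge.

    Returns ``(t_obs, p_perm)`` where ``t_obs`` is the pooled-variance
    two-sample t (High minus Low) on the observed labels.  With
    ``exact=True`` all distinct label assignments are enumerated and the
    p-value is the exact proportion ``#{ |t*| >= |t_obs| } / C(n, n_low)``
    (the observed split is one of them); otherwise ``n_perm`` uniformly
    random assignments are drawn and the add-one estimator is used.
    """
    lo = np.asarray(values_low, dtype=float)
    hi = np.asarray(values_high, dtype=float)
    if lo.size < 2 or hi.size < 2:
        raise StatsError("each group needs at least 2 values")
    if not (np.all(np.isfinite(lo)) and np.all(np.isfinite(hi))):
        raise StatsError("non-finite values in permutation test input")
    n_lo, n_hi = lo.size, hi.size
    pooled = np.concatenate([lo, hi])
    t_obs = float(
        _pooled_t(hi.mean(), lo.mean(), (hi**2).sum(), (lo**2).sum(), n_hi, n_lo)
    )

    sq = pooled**2
    total, total_sq = pooled.sum(), sq.sum()

    def t_for_low_indices(idx: np.ndarray) -> np.ndarray:
        sum_lo = pooled[idx].sum(axis=-1)
        ss_lo = sq[idx].sum(axis=-1)
        mean_lo = sum_lo / n_lo
        mean_hi = (total - sum_lo) / n_hi
        ss_hi = total_sq - ss_lo
        return _pooled_t(mean_hi, mean_lo, ss_hi, ss_lo, n_hi, n_lo)

    abs_obs = abs(t_obs)
    if exact:
        idx = np.array(list(combinations(range(n_lo + n_hi), n_lo)))
        t_all = t_for_low_indices(idx)
        p = float(np.mean(np.abs(t_all) >= abs_obs - 1e-12))
        return t_obs, p

    if n_perm < 100:
        warnings.warn(
            f"n_perm={n_perm} is very small; p-value resolution is poor",
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    # random label assignment = first n_lo slots of a random permutation
    order = rng.random((n_perm, n_lo + n_hi)).argsort(axis=1)
    t_star = t_for_low_indices(order[:, :n_lo])
    exceed = int(np.sum(np.abs(t_star) >= abs_obs - 1e-12))
    p = (1 + exceed) / (1 + n_perm)
    return t_obs, float(p)


def fdr_correct(p_values: Sequence[float], q: float = 0.05) -> np.ndarray:
    """Benjamini-Hochberg step-up significance flags at level q."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    if np.any((p <= 0) | (p > 1)):
        raise StatsError("p-values must lie in (0, 1]")
    return multipletests(p, alpha=q, method="fdr_bh")[0]


def _edge_values(
    plv_sets: Mapping[str, PLVMatrixSet],
    subjects: Sequence[str],
    edge: tuple[int, int],
    band: str,
) -> np.ndarray:
    out = np.empty(len(subjects))
    for k, s in enumerate(subjects):
        try:
            out[k] = plv_sets[s].matrices[band][edge[0], edge[1]]
        except KeyError:
            raise StatsError(f"missing PLV matrices for subject {s!r}") from None
    return out


def run_family_tests(
    plv_sets: Mapping[str, PLVMatrixSet],
    split: GroupSplit,
    hypotheses: Sequence[tuple[tuple[int, int], str]],
    atlas: NetworkAtlas,
    family_kind: str,
    n_perm: int = 20000,
    seed: int = 0,
    q: float = 0.05,
    alpha_raw: float = 0.05,
) -> ComparisonTable:
    """Test one hypothesis family edge-by-edge and FDR-correct it jointly.

    The family is all (pair, band) hypotheses passed in — the intra or inter
    set pooled across bands — and BH-FDR runs across the whole family.
    The raw-significance count uses an uncorrected ``alpha_raw`` threshold.
    """
    band_order: dict[str, int] = {}
    for _, band in hypotheses:
        band_order.setdefault(band, len(band_order))
    names = atlas.names
    results: list[EdgeResult] = []
    for (i, j), band in hypotheses:
        lo = _edge_values(plv_sets, split.low_ids, (i, j), band)
        hi = _edge_values(plv_sets, split.high_ids, (i, j), band)
        ss = np.random.SeedSequence(entropy=seed, spawn_key=(i, j, band_order[band]))
        t, p = permutation_edge_test(lo, hi, n_perm=n_perm, seed=np.random.default_rng(ss))
        fam = classify_edge(atlas, names[i], names[j])
        results.append(
            EdgeResult(
                edge=(i, j),
                band=band,
                family=fam.label,
                mean_high=float(hi.mean()),
                mean_low=float(lo.mean()),
                stat=t,
                p_perm=p,
                raw_significant=p < alpha_raw,
            )
        )
    flags = fdr_correct([r.p_perm for r in results], q=q)
    for r, f in zip(results, flags):
        r.p_fdr_significant = bool(f)
    return ComparisonTable(results, family_kind)


def mwq_plv_correlations(
    plv_sets: Mapping[str, PLVMatrixSet],
    scores: Mapping[str, float],
    edges: Sequence[tuple[tuple[int, int], str]],
) -> list[tuple[float | None, float | None]]:
    """Whole-sample Pearson r between trait score and each edge's PLV.

    An edge whose PLV (or the score vector) has zero variance has no defined
    correlation and is reported as missing (None, None).
    """
    subjects = list(scores.keys())
    if len(subjects) < 3:
        raise StatsError("correlation needs at least 3 subjects")
    y = np.array([scores[s] for s in subjects], dtype=float)
    out: list[tuple[float | None, float | None]] = []
    for edge, band in edges:
        x = _edge_values(plv_sets, subjects, edge, band)
        if x.std() == 0 or y.std() == 0:
            out.append((None, None))
            continue
        r, p = sst.pearsonr(x, y)
        out.append((float(r), float(p)))
    return out


def correlation_stars(p: float | None) -> str:
    """Reporting convention: * p<0.05, ** p<0.01, *** p<0.001."""
    if p is None:
        return "n/a"
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def cohens_d(x: np.ndarray, y: np.ndarray) -> float:
    """Pooled-SD standardised mean difference (magnitude)."""
    nx, ny = len(x), len(y)
    sp = np.sqrt(
        ((nx - 1) * x.var(ddof=1) + (ny - 1) * y.var(ddof=1)) / (nx + ny - 2)
    )
    if sp == 0:
        return 0.0
    return float(abs(x.mean() - y.mean()) / sp)


def demographics_compare(metadata: pd.DataFrame, split: GroupSplit) -> pd.DataFrame:
    """Group comparison of covariates: t/Cohen's d, chi-squared/r for sex.

    Continuous variables use the pooled-variance two-sample t; sex uses the
    Pearson chi-squared on the 2x2 counts (no continuity correction) with
    effect size r = sqrt(chi2 / N).
    """
    meta = metadata.set_index("subject")
    hi = meta.loc[split.high_ids]
    lo = meta.loc[split.low_ids]
    if len(hi) < 2 or len(lo) < 2:
        raise StatsError("each group needs at least 2 subjects")
    rows = []
    for var in ("age", "education", "spm_pr", "mwq_total"):
        if var not in meta.columns:
            continue
        x, y = hi[var].to_numpy(float), lo[var].to_numpy(float)
        t, p = sst.ttest_ind(x, y, equal_var=True)
        rows.append(
            {
                "variable": var,
                "high_mean": x.mean(),
                "high_sd": x.std(ddof=1),
                "low_mean": y.mean(),
                "low_sd": y.std(ddof=1),
                "stat": abs(float(t)),
                "stat_kind": "t",
                "p": float(p),
                "effect": cohens_d(x, y),
                "effect_kind": "cohen_d",
            }
        )
    if "sex" in meta.columns:
        table = np.array(
            [
                [(hi["sex"] == "M").sum(), (hi["sex"] == "F").sum()],
                [(lo["sex"] == "M").sum(), (lo["sex"] == "F").sum()],
            ]
        )
        if np.all(table.sum(axis=0) > 0):
            chi2, p, _, _ = sst.chi2_contingency(table, correction=False)
        else:
            chi2, p = 0.0, 1.0
        n = table.sum()
        rows.append(
            {
                "variable": "sex_pct_male",
                "high_mean": 100 * table[0, 0] / table[0].sum(),
                "high_sd": np.nan,
                "low_mean": 100 * table[1, 0] / table[1].sum(),
                "low_sd": np.nan,
                "stat": float(chi2),
                "stat_kind": "chi2",
                "p": float(p),
                "effect": float(np.sqrt(chi2 / n)),
                "effect_kind": "r",
            }
        )
    return pd.DataFrame(rows)
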