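"""Tiled differential-modification calling.

The genome is tiled in fixed-width non-overlapping windows (default 1000 bp),
per-sample counts are pooled within windows, and differential regions are
called two ways:

* ``call_dmr`` (mCG/mCH): per-window binomial logistic-regression
  likelihood-ratio test of modified/total counts on group membership — the
  standard replicate test for tiled bisulfite counts.  With a single binary
  covariate the GLM maximum-likelihood fits are the group-pooled proportions,
  so the statistic is computed in closed form (a two-group G-statistic against
  the pooled null), chi-square with 1 df.
* ``call_dhmr`` (hmCG): per-sample window hmC is the BS-minus-oxBS level
  difference; groups are compared by a two-sample Student t-test across
  replicates, filtered on effect size, p, and a step-up q computed within the
  comparison.

q-values use the explicit step-up formula
``q_i = min(p_i * N / rank_i, q_{i+1})`` (ascending p, ranks 1..N), which is
the Benjamini–Hochberg adjustment.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .io import SiteCalls, ValidationError

MOD_TYPES = ("mCG", "hmCG", "mCH")


def tile_genome(chrom_sizes: Mapping[str, int], width: int = 1000) -> pd.DataFrame:
    """Consecutive half-open tiles per chromosome; the final partial tile is kept."""
    if width < 1:
        raise ValidationError("tile width must be >= 1")
    rows = []
    for chrom, size in chrom_sizes.items():
        starts = np.arange(0, size, width, dtype=np.int64)
        ends = np.minimum(starts + width, size)
        rows.append(pd.DataFrame({"chrom": chrom, "start": starts, "end": ends}))
    return pd.concat(rows, ignore_index=True)


@dataclass(frozen=True)
class WindowTable:
    """Per-sample pooled counts and levels over fixed-width genomic tiles."""

    windows: pd.DataFrame  # chrom, start, end
    samples: tuple[str, ...]
    coverage: np.ndarray  # (n_windows, n_samples) int
    modified: np.ndarray  # (n_windows, n_samples) int
    width: int

    @property
    def levels(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.coverage > 0, self.modified / self.coverage, np.nan)

    def __len__(self) -> int:
        return len(self.windows)

    def sample_index(self, names: Sequence[str]) -> np.ndarray:
        return np.array([self.samples.index(n) for n in names])


def window_levels(
    calls_by_sample: Mapping[str, SiteCalls],
    windows: pd.DataFrame,
    min_samples_rule: str = "all",
    k: int = 2,
) -> WindowTable:
    """Pool per-site counts into windows for every sample and apply the coverage rule.

    ``min_samples_rule``: ``"all"`` retains windows covered in every sample
    (the DMCGR/DMCHR rule); ``"at_least_k"`` retains windows covered in at
    least ``k`` samples (the DhMCGR rule, k=2 per arm).
    """
    samples = tuple(calls_by_sample)
    contexts = {c.context for c in calls_by_sample.values()}
    if len(contexts) > 1:
        raise ValidationError(f"samples mix contexts {contexts}")
    widths = (windows["end"] - windows["start"]).to_numpy()
    width = int(widths.max()) if len(widths) else 0

    # window lookup: windows are on a fixed grid per chromosome
    win_key = {}
    for i, row in enumerate(windows.itertuples(index=False)):
        win_key[(row.chrom, row.start // max(width, 1))] = i

    n_w, n_s = len(windows), len(samples)
    cov = np.zeros((n_w, n_s), dtype=np.int64)
    mod = np.zeros((n_w, n_s), dtype=np.int64)
    for j, name in enumerate(samples):
        df = calls_by_sample[name].df
        pos0 = df["pos"].to_numpy(np.int64) - 1
        tile_idx = pos0 // max(width, 1)
        keys = list(zip(df["chrom"], tile_idx))
        rows = np.array([win_key.get(kk, -1) for kk in keys], dtype=np.int64)
        ok = rows >= 0
        np.add.at(cov[:, j], rows[ok], df["coverage"].to_numpy(np.int64)[ok])
        np.add.at(mod[:, j], rows[ok], df["modified"].to_numpy(np.int64)[ok])

    covered = cov > 0
    if min_samples_rule == "all":
        keep = covered.all(axis=1)
    elif min_samples_rule == "at_least_k":
        keep = covered.sum(axis=1) >= k
    else:
        raise ValidationError(f"unknown rule {min_samples_rule!r}")
    return WindowTable(
        windows=windows[keep].reset_index(drop=True),
        samples=samples,
        coverage=cov[keep],
        modified=mod[keep],
        width=width,
    )


def manual_q(pvals: Sequence[float] | np.ndarray) -> np.ndarray:
    """Step-up q-values: ``q_i = min(p_i * N / rank_i, q_{i+1})``.

    p-values are ranked ascending (stable sort, so tied p share the step-up
    minimum naturally); the largest rank gets ``q_N = p_N``; values are
    returned in the original order.  Identical to the Benjamini–Hochberg
    adjustment on every input.
    """
    p = np.asarray(pvals, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValidationError("p-values outside [0,1]")
    n = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * n / np.arange(1, n + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(n)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def _binomial_loglik(mod: np.ndarray, cov: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Binomial log-likelihood kernel (constants dropped), safe at p in {0,1}."""
    with np.errstate(invalid="ignore", divide="ignore"):
        a = np.where(mod > 0, mod * np.log(p), 0.0)
        b = np.where(cov - mod > 0, (cov - mod) * np.log1p(-p), 0.0)
    return a + b


def logistic_lrt(
    mod_a: np.ndarray, cov_a: np.ndarray, mod_b: np.ndarray, cov_b: np.ndarray
) -> np.ndarray:
    """Vectorised per-window LRT p-values for group effect on binomial counts.

    Inputs are group-pooled modified/total counts per window.  The statistic
    is twice the log-likelihood gain of group-specific proportions over the
    pooled proportion; reference chi-square, 1 df.
    """
    mod_a, cov_a, mod_b, cov_b = (np.asarray(x, dtype=float) for x in (mod_a, cov_a, mod_b, cov_b))
    with np.errstate(invalid="ignore", divide="ignore"):
        p_a = np.where(cov_a > 0, mod_a / cov_a, 0.0)
        p_b = np.where(cov_b > 0, mod_b / cov_b, 0.0)
        p_0 = (mod_a + mod_b) / (cov_a + cov_b)
    ll_alt = _binomial_loglik(mod_a, cov_a, p_a) + _binomial_loglik(mod_b, cov_b, p_b)
    ll_null = _binomial_loglik(mod_a, cov_a, p_0) + _binomial_loglik(mod_b, cov_b, p_0)
    stat = np.maximum(2.0 * (ll_alt - ll_null), 0.0)
    return stats.chi2.sf(stat, df=1)


def call_dmr(
    wt: WindowTable,
    groups: Mapping[str, str],
    comparison: tuple[str, str],
    min_diff_pct: float = 5.0,
    q_max: float = 0.05,
    mod_type: str = "mCG",
) -> pd.DataFrame:
    """Call differentially methylated windows between two groups from count data.

    Per window: group levels are coverage-weighted pooled proportions; the
    difference is ``level(first) - level(second)`` in percentage points;
    significance by the logistic-regression LRT; q by ``manual_q`` over all
    tested windows.  Records pass with ``|diff| >= min_diff_pct`` and
    ``q < q_max``; direction is hyper/hypo with respect to the first group.
    Windows where a group has zero total coverage are skipped (counted in the
    attrs of the result).
    """
    g_a, g_b = comparison
    samples_a = [s for s in wt.samples if groups.get(s) == g_a]
    samples_b = [s for s in wt.samples if groups.get(s) == g_b]
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValidationError("need >= 2 samples per group with count data")
    ia, ib = wt.sample_index(samples_a), wt.sample_index(samples_b)
    mod_a = wt.modified[:, ia].sum(axis=1)
    cov_a = wt.coverage[:, ia].sum(axis=1)
    mod_b = wt.modified[:, ib].sum(axis=1)
    cov_b = wt.coverage[:, ib].sum(axis=1)
    usable = (cov_a > 0) & (cov_b > 0)
    n_skipped = int((~usable).sum())

    p = np.full(len(wt), np.nan)
    p[usable] = logistic_lrt(mod_a[usable], cov_a[usable], mod_b[usable], cov_b[usable])
    with np.errstate(invalid="ignore", divide="ignore"):
        lvl_a = np.where(cov_a > 0, mod_a / cov_a, np.nan)
        lvl_b = np.where(cov_b > 0, mod_b / cov_b, np.nan)
    diff_pp = 100.0 * (lvl_a - lvl_b)
    q = np.full(len(wt), np.nan)
    q[usable] = manual_q(p[usable])

    out = wt.windows.copy()
    out["mod_type"] = mod_type
    out["comparison"] = f"{g_a}_vs_{g_b}"
    out["level_a"] = lvl_a
    out["level_b"] = lvl_b
    out["diff_pp"] = diff_pp
    out["p"] = p
    out["q"] = q
    out["direction"] = np.where(diff_pp >= 0, "hyper", "hypo")
    passed = usable & (np.abs(diff_pp) >= min_diff_pct) & (q < q_max)
    result = out[passed].reset_index(drop=True)
    result.attrs["n_tested"] = int(usable.sum())
    result.attrs["n_skipped_zero_coverage"] = n_skipped
    return result


def dhmr_window_levels(bs_wt: WindowTable, ox_wt: WindowTable) -> tuple[pd.DataFrame, np.ndarray]:
    """Intersect BS and oxBS window tables and return per-sample window hmC levels."""
    if tuple(bs_wt.samples) != tuple(ox_wt.samples):
        raise ValidationError("BS and oxBS tables must carry the same samples in the same order")
    key_bs = list(zip(bs_wt.windows["chrom"], bs_wt.windows["start"]))
    key_ox = {k: i for i, k in enumerate(zip(ox_wt.windows["chrom"], ox_wt.windows["start"]))}
    rows_bs, rows_ox = [], []
    for i, k in enumerate(key_bs):
        j = key_ox.get(k)
        if j is not None:
            rows_bs.append(i)
            rows_ox.append(j)
    windows = bs_wt.windows.iloc[rows_bs].reset_index(drop=True)
    h = bs_wt.levels[rows_bs] - ox_wt.levels[rows_ox]
    return windows, h


def dhmr_from_levels(
    windows: pd.DataFrame,
    h: np.ndarray,
    samples: Sequence[str],
    groups: Mapping[str, str],
    comparison: tuple[str, str],
    min_diff_pct: float = 5.0,
    p_max: float = 0.05,
    q_max: float = 0.05,
    welch: bool = False,
) -> pd.DataFrame:
    """DhMCGR filter chain on per-sample window hmC levels.

    Group means are unweighted replicate means; the test is a two-sample
    pooled-variance Student t (Welch optional).  q is computed by ``manual_q``
    over all windows tested within the comparison, then the three filters
    ``|diff| >= min_diff_pct``, ``p <= p_max`` and ``q <= q_max`` are applied.
    Computing q only within the effect-size-filtered windows would lose false
    discovery control (the filter selects for extreme t statistics).
    """
    g_a, g_b = comparison
    ia = np.array([i for i, s in enumerate(samples) if groups.get(s) == g_a])
    ib = np.array([i for i, s in enumerate(samples) if groups.get(s) == g_b])
    if len(ia) < 2 or len(ib) < 2:
        raise ValidationError("t-test undefined with < 2 replicates in a group")
    h_a, h_b = h[:, ia], h[:, ib]
    complete = ~np.isnan(h_a).any(axis=1) & ~np.isnan(h_b).any(axis=1)
    mean_a = h_a.mean(axis=1)
    mean_b = h_b.mean(axis=1)
    diff_pp = 100.0 * (mean_a - mean_b)
    with np.errstate(invalid="ignore", divide="ignore"):
        t_res = stats.ttest_ind(h_a, h_b, axis=1, equal_var=not welch)
    p = np.where(np.isnan(t_res.pvalue), 1.0, t_res.pvalue)
    # zero-variance identical groups: define p = 1 (no evidence)
    out = windows.copy()
    out["mod_type"] = "hmCG"
    out["comparison"] = f"{g_a}_vs_{g_b}"
    out["level_a"] = mean_a
    out["level_b"] = mean_b
    out["diff_pp"] = diff_pp
    out["p"] = p
    out["direction"] = np.where(diff_pp >= 0, "hyper", "hypo")

    q = np.full(len(out), np.nan)
    if complete.any():
        q[complete] = manual_q(p[complete])
    out["q"] = q
    passed_diff = complete & (np.abs(diff_pp) >= min_diff_pct)
    final = passed_diff & (p <= p_max) & (q <= q_max)
    result = out[final].reset_index(drop=True)
    result.attrs["n_tested"] = int(complete.sum())
    result.attrs["n_diff_filtered"] = int(passed_diff.sum())
    return result


def call_dhmr(
    bs_wt: WindowTable,
    ox_wt: WindowTable,
    groups: Mapping[str, str],
    comparison: tuple[str, str],
    min_diff_pct: float = 5.0,
    p_max: float = 0.05,
    q_max: float = 0.05,
    welch: bool = False,
) -> pd.DataFrame:
    """Call differentially hydroxymethylated windows from paired BS/oxBS tables.

    Windows are intersected between arms ("covered by both BS and oxBS"),
    per-sample hmC is the BS-minus-oxBS window level, then the DhMCGR filter
    chain of ``dhmr_from_levels`` is applied.
    """
    windows, h = dhmr_window_levels(bs_wt, ox_wt)
    return dhmr_from_levels(
        windows, h, bs_wt.samples, groups, comparison,
        min_diff_pct=min_diff_pct, p_max=p_max, q_max=q_max, welch=welch,
    )


def dmr_overlap(
    dmrs_a: pd.DataFrame,
    dmrs_b: pd.DataFrame,
    dmrs_c: pd.DataFrame,
    names: tuple[str, str, str] = ("a", "b", "c"),
) -> dict[str, dict[frozenset, int]]:
    """Three-way Venn counts of DMR windows per direction (window-identity based)."""
    frames = dict(zip(names, (dmrs_a, dmrs_b, dmrs_c)))
    # records share a tile grid iff any window key seen in two frames has the
    # same end coordinate in both
    ends: dict[tuple, int] = {}
    for df in frames.values():
        for chrom, start, end in zip(df["chrom"], df["start"], df["end"]):
            key = (chrom, int(start))
            if ends.setdefault(key, int(end)) != int(end):
                raise ValidationError(f"mismatched tile grids at {chrom}:{start}")
    out: dict[str, dict[frozenset, int]] = {}
    for direction in ("hyper", "hypo"):
        sets = {
            n: set(
                zip(
                    df.loc[df["direction"] == direction, "chrom"],
                    df.loc[df["direction"] == direction, "start"],
                )
            )
            for n, df in frames.items()
        }
        universe = set().union(*sets.values())
        counts: dict[frozenset, int] = {}
        for w in universe:
            member = frozenset(n for n, s in sets.items() if w in s)
            counts[member] = counts.get(member, 0) + 1
        out[direction] = counts
    return out


def dmr_correlation(dmrs_m: pd.DataFrame, dmrs_h: pd.DataFrame) -> tuple[float, float, int]:
    """Correlation of mC and hmC differences over shared differential windows.

    Returns (Pearson r, p, n shared windows).  In brain cell-type data the
    two modifications exchange, producing a negative correlation.
    """
    key = ["chrom", "start"]
    merged = dmrs_m[key + ["diff_pp"]].merge(
        dmrs_h[key + ["diff_pp"]], on=key, suffixes=("_m", "_h")
    )
    if len(merged) < 3:
        return np.nan, np.nan, len(merged)
    r, p = stats.pearsonr(merged["diff_pp_m"], merged["diff_pp_h"])
    return float(r), float(p), len(merged)


def write_dmr_bed(dmrs: pd.DataFrame, path: str | Path) -> None:
    """Export DMR records as BED6+ (name=mod_type:comparison, score=-log10 q)."""
    with np.errstate(divide="ignore"):
        score = -np.log10(np.maximum(dmrs["q"].to_numpy(float), 1e-300))
    out = pd.DataFrame(
        {
            "chrom": dmrs["chrom"],
            "start": dmrs["start"],
            "end": dmrs["end"],
            "name": dmrs["mod_type"].astype(str) + ":" + dmrs["comparison"].astype(str),
            "score": np.round(score, 4),
            "strand": ".",
            "diff_pp": np.round(dmrs["diff_pp"], 6),
            "p": dmrs["p"],
            "q": dmrs["q"],
            "direction": dmrs["direction"],
        }
    )
    out.to_csv(path, sep="\t", header=False, index=False)
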