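"""Resolving mC and hmC from paired assay arms.

Two chemistries share one subtraction kernel:

* BS/oxBS: the BS arm reads mC+hmC as modified, the oxBS arm reads only mC,
  so per site ``f_mC = oxBS`` and ``f_hmC = BS - oxBS``.
* EM-seq: the TET+ arm reads mC+hmC, the mock TET- arm reads only hmC, so
  ``f_hmC = TET-`` and ``f_mC = TET+ - TET-``.

In both cases the partial arm is read directly and the difference of the two
arms gives the other fraction.  Negative differences (sampling noise at low
true levels) are clamped to zero for per-site reporting, with the raw value
kept in a diagnostic column; genome-wide hmC should instead be computed from
aggregate arm levels (``genome_level_difference``), where negative site noise
cancels rather than biasing the mean upward.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import SiteCalls, UndefinedLevelError, ValidationError, genome_level, merge_intervals


@dataclass(frozen=True)
class PairedLevels:
    """Per-site mC/hmC fractions resolved from a pair of arms.

    ``df`` columns: chrom, pos, strand, coverage_total, coverage_partial,
    f_mc, f_hmc, raw_diff (the unclamped arm difference).
    ``n_dropped_total`` / ``n_dropped_partial`` count keys covered in only
    one arm or failing the coverage floor.
    """

    df: pd.DataFrame
    context: str
    n_dropped_total: int
    n_dropped_partial: int


def _paired_difference(
    total: SiteCalls,
    partial: SiteCalls,
    min_cov: int,
    clamp: bool,
) -> tuple[pd.DataFrame, int, int]:
    """Inner-join two arms on site key and compute partial level and arm difference."""
    if total.context != partial.context:
        raise ValidationError(
            f"context mismatch between arms: {total.context} vs {partial.context}"
        )
    key = ["chrom", "pos", "strand"]
    merged = total.df.merge(partial.df, on=key, how="outer", suffixes=("_total", "_partial"), indicator=True)
    cov_t = merged["coverage_total"].fillna(0).to_numpy(float)
    cov_p = merged["coverage_partial"].fillna(0).to_numpy(float)
    keep = (merged["_merge"] == "both").to_numpy() & (cov_t >= min_cov) & (cov_p >= min_cov)
    n_drop_total = int(((merged["_merge"] != "right_only") & ~keep).sum())
    n_drop_partial = int(((merged["_merge"] != "left_only") & ~keep).sum())
    sub = merged[keep]
    cov_t = sub["coverage_total"].to_numpy(float)
    cov_p = sub["coverage_partial"].to_numpy(float)
    level_t = sub["modified_total"].to_numpy(float) / cov_t
    level_p = sub["modified_partial"].to_numpy(float) / cov_p
    diff = level_t - level_p
    out = pd.DataFrame(
        {
            "chrom": sub["chrom"].to_numpy(),
            "pos": sub["pos"].to_numpy(np.int64),
            "strand": sub["strand"].to_numpy(),
            "coverage_total": cov_t.astype(np.int64),
            "coverage_partial": cov_p.astype(np.int64),
            "level_partial": level_p,
            "raw_diff": diff,
            "diff": np.clip(diff, 0.0, None) if clamp else diff,
        }
    )
    return out.reset_index(drop=True), n_drop_total, n_drop_partial


def subtract_oxbs(
    bs: SiteCalls,
    oxbs: SiteCalls,
    min_cov: int = 1,
    clamp: bool = True,
) -> PairedLevels:
    """Per-site mC/hmC by BS-minus-oxBS subtraction.

    ``f_mC`` is the oxBS level; ``f_hmC`` is the BS level minus the oxBS
    level, clamped at zero when ``clamp`` (the raw value stays in
    ``raw_diff``).  Keys below ``min_cov`` in either arm are dropped and
    counted.
    """
    df, nd_t, nd_p = _paired_difference(bs, oxbs, min_cov, clamp)
    df = df.rename(columns={"level_partial": "f_mc", "diff": "f_hmc"})
    return PairedLevels(df=df, context=bs.context, n_dropped_total=nd_t, n_dropped_partial=nd_p)


def emseq_levels(
    tet_plus: SiteCalls,
    tet_minus: SiteCalls,
    min_cov: int = 10,
    clamp: bool = True,
) -> PairedLevels:
    """Per-site mC/hmC from EM-seq TET+/TET- arms.

    The mock (TET-) arm reads hmC directly; mC is TET+ minus TET-.  The
    default coverage floor is a strand-specific minimum of 10 calls in each
    arm.
    """
    df, nd_t, nd_p = _paired_difference(tet_plus, tet_minus, min_cov, clamp)
    df = df.rename(columns={"level_partial": "f_hmc", "diff": "f_mc"})
    return PairedLevels(df=df, context=tet_plus.context, n_dropped_total=nd_t, n_dropped_partial=nd_p)


def genome_level_difference(total: SiteCalls, partial: SiteCalls, min_cov: int = 1) -> float:
    """Genome-wide arm difference from aggregate levels (unclamped).

    Computed as genome_level(total) - genome_level(partial) over the common
    keys, so negative per-site noise cancels instead of accumulating.
    """
    df, _, _ = _paired_difference(total, partial, min_cov, clamp=False)
    cov_t = df["coverage_total"].sum()
    cov_p = df["coverage_partial"].sum()
    if cov_t == 0 or cov_p == 0:
        raise UndefinedLevelError("zero total coverage in an arm")
    level_t = (df["level_partial"] + df["raw_diff"]).to_numpy() * df["coverage_total"].to_numpy()
    level_p = df["level_partial"].to_numpy() * df["coverage_partial"].to_numpy()
    return float(level_t.sum() / cov_t - level_p.sum() / cov_p)


def region_level(calls: SiteCalls, intervals: pd.DataFrame) -> pd.Series:
    """Coverage-weighted modification level per half-open interval.

    Intervals must be non-overlapping within the query set.  Intervals with
    no covered sites get NaN (missing is a value, not an error).
    """
    merged = merge_intervals(intervals)
    if len(merged) != len(intervals):
        raise ValidationError("query intervals overlap")
    out = np.full(len(intervals), np.nan)
    df = calls.df
    for i, row in enumerate(intervals.itertuples(index=False)):
        rows = df[(df["chrom"] == row.chrom) & (df["pos"] - 1 >= row.start) & (df["pos"] - 1 < row.end)]
        cov = rows["coverage"].sum()
        if cov > 0:
            out[i] = rows["modified"].sum() / cov
    return pd.Series(out, index=intervals.index, name="level")


def subsample_calls(calls: SiteCalls, fraction: float, seed: int) -> SiteCalls:
    """Binomially thin a call table, retaining each read-call with ``fraction``.

    Both modified and unmodified calls of every site are thinned
    independently, so the expected genome-wide level is preserved.
    Deterministic under ``seed``.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValidationError(f"fraction must be in (0, 1], got {fraction}")
    if fraction == 1.0:
        return calls
    rng = np.random.default_rng(seed)
    mod = calls.df["modified"].to_numpy(np.int64)
    unmod = calls.df["coverage"].to_numpy(np.int64) - mod
    kept_mod = rng.binomial(mod, fraction)
    kept_unmod = rng.binomial(unmod, fraction)
    df = calls.df.copy()
    df["modified"] = kept_mod
    df["coverage"] = kept_mod + kept_unmod
    return SiteCalls(df, calls.context)
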