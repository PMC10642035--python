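"""Reading/writing per-cytosine modification call tables and interval annotations.

The on-disk dialect is the methylKit coverage text file: a tab-separated table
with header ``chrBase chr base strand coverage freqC freqT`` where ``base`` is
the 1-based cytosine position, ``strand`` is ``F``/``R`` (``+``/``-`` also
accepted) and ``freqC`` is the percent of reads calling the base modified.
A counts variant (``chr base strand coverage modified``) is also accepted.

All interval types (BED, tiles, gene models) are 0-based half-open; call-table
positions are 1-based.  Conversion between the two conventions happens only in
the helpers of this module.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

CONTEXTS = ("CG", "CH")

SITE_COLUMNS = ["chrom", "pos", "strand", "coverage", "modified"]


class ParseError(ValueError):
    """A call table line could not be parsed."""


class ValidationError(ValueError):
    """A table violated a SiteCalls invariant."""


class UndefinedLevelError(ValueError):
    """A modification level was requested over zero total coverage."""


class EstimationError(ValueError):
    """A conversion-rate class was absent or uncovered in the spike-ins."""


class SingularSystemError(ValueError):
    """The two-arm unmixing system has (near-)zero determinant."""


def _normalise_strand(values: pd.Series) -> pd.Series:
    mapped = values.astype(str).replace({"F": "+", "R": "-"})
    bad = ~mapped.isin(["+", "-"])
    if bad.any():
        raise ValidationError(f"unknown strand value {mapped[bad].iloc[0]!r}")
    return mapped


@dataclass(frozen=True)
class SiteCalls:
    """Per-cytosine coverage and apparent-modified counts for one sample/arm.

    Parameters
    ----------
    df
        Columns ``chrom, pos, strand, coverage, modified``; ``pos`` is
        1-based.  Rows are sorted by ``(chrom, pos, strand)`` and keys are
        unique.
    context
        ``"CG"`` or ``"CH"``; uniform within a table.
    """

    df: pd.DataFrame
    context: str

    def __post_init__(self) -> None:
        if self.context not in CONTEXTS:
            raise ValidationError(f"context must be one of {CONTEXTS}, got {self.context!r}")
        df = self.df
        missing = [c for c in SITE_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"SiteCalls missing columns {missing}")
        if len(df) == 0:
            return
        if (df["modified"] < 0).any() or (df["coverage"] < 0).any():
            raise ValidationError("negative counts")
        if (df["modified"] > df["coverage"]).any():
            raise ValidationError("modified count exceeds coverage")
        keys = df[["chrom", "pos", "strand"]]
        if keys.duplicated().any():
            dup = keys[keys.duplicated()].iloc[0]
            raise ValidationError(
                f"duplicate site key {dup['chrom']}:{dup['pos']}({dup['strand']}); "
                "split counts must not be merged silently"
            )
        object.__setattr__(self, "df", df.reset_index(drop=True))

    @classmethod
    def from_arrays(
        cls,
        chrom,
        pos,
        strand,
        coverage,
        modified,
        context: str,
    ) -> "SiteCalls":
        df = pd.DataFrame(
            {
                "chrom": np.asarray(chrom, dtype=object),
                "pos": np.asarray(pos, dtype=np.int64),
                "strand": np.asarray(strand, dtype=object),
                "coverage": np.asarray(coverage, dtype=np.int64),
                "modified": np.asarray(modified, dtype=np.int64),
            }
        )
        df = df.sort_values(["chrom", "pos", "strand"], kind="stable").reset_index(drop=True)
        return cls(df, context)

    def __len__(self) -> int:
        return len(self.df)

    @property
    def levels(self) -> np.ndarray:
        """Per-site modified fraction (NaN where coverage is zero)."""
        cov = self.df["coverage"].to_numpy(float)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(cov > 0, self.df["modified"].to_numpy(float) / cov, np.nan)

    def restrict(self, chroms: Iterable[str]) -> "SiteCalls":
        chroms = set(chroms)
        return SiteCalls(self.df[self.df["chrom"].isin(chroms)].reset_index(drop=True), self.context)


def read_site_calls(path: str | Path, context: str) -> SiteCalls:
    """Read a methylKit-dialect call table (frequency or counts variant).

    Counts are reconstructed from percent columns by rounding
    ``coverage * freqC / 100`` to the nearest integer, ties half up.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", header=0, dtype=str)
    except Exception as exc:  # pragma: no cover - passthrough of pandas detail
        raise ParseError(f"{path}: {exc}") from exc
    df.columns = [c.strip() for c in df.columns]
    if "freqC" in df.columns:
        needed = ["chr", "base", "strand", "coverage", "freqC"]
    elif "modified" in df.columns:
        needed = ["chr", "base", "strand", "coverage", "modified"]
    else:
        raise ParseError(f"{path}: unrecognised header {list(df.columns)}")
    for col in needed:
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    out = pd.DataFrame()
    try:
        out["chrom"] = df["chr"].astype(str)
        out["pos"] = pd.to_numeric(df["base"], errors="raise").astype(np.int64)
        out["strand"] = _normalise_strand(df["strand"])
        out["coverage"] = pd.to_numeric(df["coverage"], errors="raise").astype(np.int64)
        if "freqC" in needed:
            freq = pd.to_numeric(df["freqC"], errors="raise").to_numpy(float)
            if np.any((freq < 0) | (freq > 100)):
                line = int(np.flatnonzero((freq < 0) | (freq > 100))[0]) + 2
                raise ValidationError(f"{path}: freqC outside [0,100] at line {line}")
            out["modified"] = np.floor(out["coverage"].to_numpy(float) * freq / 100.0 + 0.5).astype(np.int64)
        else:
            out["modified"] = pd.to_numeric(df["modified"], errors="raise").astype(np.int64)
    except (ValueError, TypeError) as exc:
        if isinstance(exc, ValidationError):
            raise
        raise ParseError(f"{path}: malformed value ({exc})") from exc
    out = out.sort_values(["chrom", "pos", "strand"], kind="stable")
    # identical duplicate rows (a table written twice) collapse; conflicting
    # duplicates are an invariant violation caught by SiteCalls itself
    out = out.drop_duplicates().reset_index(drop=True)
    return SiteCalls(out, context)


def write_site_calls(calls: SiteCalls, path: str | Path) -> None:
    """Write the methylKit frequency dialect (chrBase/chr/base/strand/coverage/freqC/freqT)."""
    df = calls.df
    cov = df["coverage"].to_numpy(float)
    with np.errstate(invalid="ignore", divide="ignore"):
        freq_c = np.where(cov > 0, 100.0 * df["modified"].to_numpy(float) / cov, 0.0)
    out = pd.DataFrame(
        {
            "chrBase": df["chrom"].astype(str) + "." + df["pos"].astype(str),
            "chr": df["chrom"],
            "base": df["pos"],
            "strand": df["strand"].replace({"+": "F", "-": "R"}),
            "coverage": df["coverage"],
            "freqC": np.round(freq_c, 6),
            "freqT": np.round(100.0 - freq_c, 6),
        }
    )
    out.to_csv(path, sep="\t", index=False)


def read_chrom_sizes(path: str | Path) -> dict[str, int]:
    """Two-column TSV of chromosome name and length."""
    df = pd.read_csv(path, sep="\t", header=None, names=["chrom", "size"])
    return dict(zip(df["chrom"].astype(str), df["size"].astype(int)))


def write_chrom_sizes(sizes: Mapping[str, int], path: str | Path) -> None:
    pd.DataFrame(sizes.items()).to_csv(path, sep="\t", header=False, index=False)


def read_bed(path: str | Path) -> pd.DataFrame:
    """BED3/BED6(+) intervals as a DataFrame with 0-based half-open coordinates."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    names = ["chrom", "start", "end", "name", "score", "strand"][: min(df.shape[1], 6)]
    names += [f"extra{i}" for i in range(df.shape[1] - len(names))]
    df.columns = names
    df["chrom"] = df["chrom"].astype(str)
    df["start"] = df["start"].astype(int)
    df["end"] = df["end"].astype(int)
    return df


def write_bed(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, sep="\t", header=False, index=False)


def destrand(calls: SiteCalls) -> SiteCalls:
    """Merge the two strands of each CpG dyad into one plus-strand record.

    Minus-strand positions map to ``pos - 1`` (the plus-strand C of the dyad).
    Only meaningful in CG context.
    """
    if calls.context != "CG":
        raise ValidationError("destranding is defined for CG context only")
    df = calls.df.copy()
    df["pos"] = np.where(df["strand"] == "-", df["pos"] - 1, df["pos"])
    grouped = df.groupby(["chrom", "pos"], as_index=False)[["coverage", "modified"]].sum()
    grouped["strand"] = "+"
    grouped = grouped[SITE_COLUMNS].sort_values(["chrom", "pos"], kind="stable")
    return SiteCalls(grouped.reset_index(drop=True), "CG")


# ---------------------------------------------------------------------------
# levels and conversion correction
# ---------------------------------------------------------------------------


def genome_level(calls: SiteCalls, weighted: bool = True) -> float:
    """Genome-wide modification level.

    Coverage-weighted by default: total modified calls over total calls.  With
    ``weighted=False`` the unweighted mean of per-site fractions is returned.
    """
    df = calls.df
    total = int(df["coverage"].sum())
    if total == 0:
        raise UndefinedLevelError("zero total coverage")
    if weighted:
        return float(df["modified"].sum()) / total
    lv = calls.levels
    return float(np.nanmean(lv))


@dataclass(frozen=True)
class ConversionRates:
    """Apparent-modification probabilities for each true base state in one arm.

    ``a_c`` is the probability an unmodified C reads as modified (1 minus the
    conversion efficiency); ``a_mc`` and ``a_hmc`` are the retention
    probabilities of mC and hmC.
    """

    arm: str
    a_c: float
    a_mc: float
    a_hmc: float

    def __post_init__(self) -> None:
        for name in ("a_c", "a_mc", "a_hmc"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValidationError(f"{name}={v} outside [0,1]")

    def apparent(self, f_mc: np.ndarray | float, f_hmc: np.ndarray | float) -> np.ndarray | float:
        """Forward model: probability a call reads modified given true fractions."""
        f_c = 1.0 - np.asarray(f_mc) - np.asarray(f_hmc)
        return f_c * self.a_c + np.asarray(f_mc) * self.a_mc + np.asarray(f_hmc) * self.a_hmc


SPIKE_STATES = ("C", "mC", "hmC")


def read_spike_truth(path: str | Path) -> pd.DataFrame:
    """Spike-in truth TSV: chrom, pos, strand, true_state."""
    df = pd.read_csv(path, sep="\t")
    if not set(df["true_state"]).issubset(SPIKE_STATES):
        raise ValidationError("unknown spike-in state")
    return df


def estimate_conversion_rates(spike_calls: SiteCalls, truth: pd.DataFrame, arm: str) -> ConversionRates:
    """Estimate arm conversion rates from spike-in control calls.

    For each true state X, ``a_X`` is the pooled apparent-modified fraction
    over spike positions with that state.
    """
    merged = spike_calls.df.merge(truth, on=["chrom", "pos", "strand"], how="inner")
    rates = {}
    for state in SPIKE_STATES:
        sub = merged[merged["true_state"] == state]
        cov = int(sub["coverage"].sum())
        if cov == 0:
            raise EstimationError(f"spike-in class {state!r} absent or uncovered for arm {arm}")
        rates[state] = float(sub["modified"].sum()) / cov
    return ConversionRates(arm=arm, a_c=rates["C"], a_mc=rates["mC"], a_hmc=rates["hmC"])


@dataclass(frozen=True)
class ModLevels:
    """A (f_C, f_mC, f_hmC) point on the simplex with clamping diagnostics."""

    f_c: float
    f_mc: float
    f_hmc: float
    scope: str = "genome"
    clamped: bool = False
    raw_f_mc: float | None = None
    raw_f_hmc: float | None = None

    def __post_init__(self) -> None:
        s = self.f_c + self.f_mc + self.f_hmc
        if not np.isclose(s, 1.0, atol=1e-9):
            raise ValidationError(f"fractions sum to {s}, not 1")
        for name in ("f_c", "f_mc", "f_hmc"):
            v = getattr(self, name)
            if not -1e-12 <= v <= 1 + 1e-12:
                raise ValidationError(f"{name}={v} outside [0,1]")


def correct_levels(
    bs_level: float,
    oxbs_level: float,
    rates_bs: ConversionRates,
    rates_oxbs: ConversionRates,
) -> ModLevels:
    """Invert the two-arm chemistry to spike-in-corrected (f_mC, f_hmC).

    Solves the linear system::

        bs   = (1 - m - h) a_C^BS + m a_mC^BS + h a_hmC^BS
        oxbs = (1 - m - h) a_C^ox + m a_mC^ox + h a_hmC^ox

    for ``(m, h)`` and clamps onto the simplex, recording whether clamping
    occurred.  With identity chemistry this reduces to ``m = oxbs``,
    ``h = bs - oxbs``.
    """
    for name, lv in (("bs_level", bs_level), ("oxbs_level", oxbs_level)):
        if not 0.0 <= lv <= 1.0:
            raise ValidationError(f"{name}={lv} outside [0,1]")
    a = np.array(
        [
            [rates_bs.a_mc - rates_bs.a_c, rates_bs.a_hmc - rates_bs.a_c],
            [rates_oxbs.a_mc - rates_oxbs.a_c, rates_oxbs.a_hmc - rates_oxbs.a_c],
        ]
    )
    b = np.array([bs_level - rates_bs.a_c, oxbs_level - rates_oxbs.a_c])
    det = np.linalg.det(a)
    if abs(det) < 1e-12:
        raise SingularSystemError("conversion-rate system is singular; arms do not separate mC from hmC")
    m_raw, h_raw = np.linalg.solve(a, b)
    m, h = float(m_raw), float(h_raw)
    clamped = False
    if m < 0 or h < 0 or m + h > 1:
        clamped = True
        m = min(max(m, 0.0), 1.0)
        h = min(max(h, 0.0), 1.0)
        if m + h > 1:
            s = m + h
            m, h = m / s, h / s
    return ModLevels(
        f_c=1.0 - m - h,
        f_mc=m,
        f_hmc=h,
        scope="genome",
        clamped=clamped,
        raw_f_mc=float(m_raw),
        raw_f_hmc=float(h_raw),
    )


# ---------------------------------------------------------------------------
# interval helpers (the single place 1-based calls meet 0-based intervals)
# ---------------------------------------------------------------------------


def merge_intervals(df: pd.DataFrame) -> pd.DataFrame:
    """Union of possibly-overlapping intervals, per chromosome, sorted."""
    parts = []
    for chrom, sub in df.groupby("chrom", sort=True):
        sub = sub.sort_values("start")
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        merged_s, merged_e = [], []
        for s, e in zip(starts, ends):
            if merged_e and s < merged_e[-1]:  # touching half-open intervals stay separate
                merged_e[-1] = max(merged_e[-1], e)
            else:
                merged_s.append(s)
                merged_e.append(e)
        parts.append(pd.DataFrame({"chrom": chrom, "start": merged_s, "end": merged_e}))
    if not parts:
        return pd.DataFrame(columns=["chrom", "start", "end"])
    return pd.concat(parts, ignore_index=True)


def sites_in_intervals(calls: SiteCalls, intervals: pd.DataFrame) -> np.ndarray:
    """Boolean mask of call rows falling inside the (merged) intervals.

    A 1-based site ``pos`` lies in half-open ``[start, end)`` iff
    ``start <= pos - 1 < end``.
    """
    merged = merge_intervals(intervals)
    mask = np.zeros(len(calls.df), dtype=bool)
    for chrom, sub in merged.groupby("chrom"):
        rows = calls.df["chrom"] == chrom
        if not rows.any():
            continue
        pos0 = calls.df.loc[rows, "pos"].to_numpy(np.int64) - 1
        starts = sub["start"].to_numpy(np.int64)
        ends = sub["end"].to_numpy(np.int64)
        idx = np.searchsorted(starts, pos0, side="right") - 1
        ok = (idx >= 0) & (pos0 < ends[np.clip(idx, 0, len(ends) - 1)])
        mask[np.flatnonzero(rows.to_numpy())[ok]] = True
    return mask
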