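"""Metagene profiles, expression-tertile stratification, and repeat summaries.

The metagene layout mirrors the standard flank/body binning: 4 kb flanks
split into 20 bins of 200 nt on each side of the gene, and the gene body
scaled to 27 equal-width bins regardless of its length, giving a fixed
67-bin profile oriented 5'->3' along the gene strand.  Bin means are
gene-averaged (each gene contributes one value per bin with data).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import stats

from .io import SiteCalls, ValidationError, sites_in_intervals

REPEAT_CLASSES = ("LINE", "SINE", "LTR", "Simple_repeat")
REGIONS = ("upstream", "body", "downstream")


# ---------------------------------------------------------------------------
# expression classes
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ExpressionClasses:
    """Gene lists split by expression: tertiles of expressed genes plus unexpressed."""

    high: tuple[str, ...]
    mid: tuple[str, ...]
    low: tuple[str, ...]
    unexpressed: tuple[str, ...]

    def tier_of(self) -> dict[str, str]:
        out = {}
        for tier in ("high", "mid", "low", "unexpressed"):
            for g in getattr(self, tier):
                out[g] = tier
        return out


def expression_classes(expr: pd.DataFrame, gene_col: str = "gene_id") -> ExpressionClasses:
    """Split genes into unexpressed plus three equal-size expression tertiles.

    Genes with zero reads in every sample are unexpressed.  The remainder are
    ranked by mean count and split into three equally sized lists; when the
    count is not divisible by 3 the extra genes go to the highest tertiles
    first ({4,3,3} for ten genes).  Ties at boundaries break by stable
    gene-id order.
    """
    if len(expr) == 0:
        raise ValidationError("empty expression table")
    counts = expr.set_index(gene_col) if gene_col in expr.columns else expr
    numeric = counts.select_dtypes("number")
    if (numeric < 0).any().any():
        raise ValidationError("negative counts")
    means = numeric.mean(axis=1)
    unexpressed = tuple(means.index[(numeric == 0).all(axis=1)])
    expressed = means.drop(list(unexpressed))
    order = np.argsort(-expressed.to_numpy(), kind="stable")
    ranked = list(expressed.index[order])
    n = len(ranked)
    base, rem = divmod(n, 3)
    n_high = base + (1 if rem >= 1 else 0)
    n_mid = base + (1 if rem >= 2 else 0)
    return ExpressionClasses(
        high=tuple(ranked[:n_high]),
        mid=tuple(ranked[n_high : n_high + n_mid]),
        low=tuple(ranked[n_high + n_mid :]),
        unexpressed=unexpressed,
    )


# ---------------------------------------------------------------------------
# metagene profiles
# ---------------------------------------------------------------------------


def _gene_bin_levels(
    df: pd.DataFrame,
    gene,
    flank: int,
    flank_bins: int,
    body_bins: int,
) -> tuple[np.ndarray, np.ndarray]:
    """Per-bin (coverage, modified) totals for one gene, 5'->3' bin order."""
    n_bins = 2 * flank_bins + body_bins
    cov = np.zeros(n_bins, dtype=np.int64)
    mod = np.zeros(n_bins, dtype=np.int64)
    bin_nt = flank // flank_bins
    start, end = gene.start, gene.end
    length = end - start
    sub = df[(df["chrom"] == gene.chrom) & (df["pos"] - 1 >= start - flank) & (df["pos"] - 1 < end + flank)]
    if len(sub) == 0:
        return cov, mod
    pos0 = sub["pos"].to_numpy(np.int64) - 1
    if gene.strand == "+":
        rel = pos0 - (start - flank)
    else:
        rel = (end + flank - 1) - pos0
    # rel in [0, flank) -> upstream flank; [flank, flank+length) -> body; rest downstream
    bins = np.empty(len(rel), dtype=np.int64)
    up = rel < flank
    body = (rel >= flank) & (rel < flank + length)
    down = rel >= flank + length
    bins[up] = rel[up] // bin_nt
    bins[body] = flank_bins + ((rel[body] - flank) * body_bins) // length
    bins[down] = flank_bins + body_bins + (rel[down] - flank - length) // bin_nt
    np.add.at(cov, bins, sub["coverage"].to_numpy(np.int64))
    np.add.at(mod, bins, sub["modified"].to_numpy(np.int64))
    return cov, mod


@dataclass(frozen=True)
class MetageneProfile:
    """Gene-averaged per-bin modification levels for a gene set.

    ``df`` has one row per bin with columns ``bin`` (1-based), ``segment``
    and one level column per sample; ``n_genes`` counts genes retained.
    """

    df: pd.DataFrame
    n_genes: int
    n_dropped: int
    gene_set: str = "all"


def metagene_profile(
    calls_by_sample: Mapping[str, SiteCalls],
    genes: pd.DataFrame,
    flank: int = 4000,
    flank_bins: int = 20,
    body_bins: int = 27,
    gene_set: str = "all",
) -> MetageneProfile:
    """Average modification in flank/body bins over a gene set, per sample.

    Genes with body length < ``body_bins`` nt are dropped (and counted).
    Per gene per bin the level is coverage-weighted over sites in the bin;
    per bin the profile is the unweighted mean over genes with data, so each
    gene contributes equally.  Minus-strand genes are reversed so bin 1 is
    always 4 kb upstream of the TSS.
    """
    if len(genes) == 0:
        raise ValidationError("empty gene list")
    keep = genes[(genes["end"] - genes["start"]) >= body_bins]
    n_dropped = len(genes) - len(keep)
    n_bins = 2 * flank_bins + body_bins
    segments = (
        ["upstream"] * flank_bins + ["body"] * body_bins + ["downstream"] * flank_bins
    )
    out = pd.DataFrame({"bin": np.arange(1, n_bins + 1), "segment": segments})
    for name, calls in calls_by_sample.items():
        sums = np.zeros(n_bins)
        counts = np.zeros(n_bins)
        for gene in keep.itertuples(index=False):
            cov, mod = _gene_bin_levels(calls.df, gene, flank, flank_bins, body_bins)
            has = cov > 0
            sums[has] += mod[has] / cov[has]
            counts[has] += 1
        with np.errstate(invalid="ignore", divide="ignore"):
            out[name] = np.where(counts > 0, sums / counts, np.nan)
    return MetageneProfile(df=out, n_genes=len(keep), n_dropped=n_dropped, gene_set=gene_set)


def write_profile(profile: MetageneProfile, path) -> None:
    """Long-format TSV export: gene_set, sample, bin, segment, level."""
    long = profile.df.melt(id_vars=["bin", "segment"], var_name="sample", value_name="level")
    long.insert(0, "gene_set", profile.gene_set)
    long.to_csv(path, sep="\t", index=False)


def region_averages(
    calls_by_sample: Mapping[str, SiteCalls],
    genes: pd.DataFrame,
    flank: int = 4000,
) -> pd.DataFrame:
    """Coverage-weighted levels for upstream(-4kb..TSS) / body / downstream(TES..+4kb).

    One row per sample per region, pooled over the union of the gene set's
    region intervals.
    """
    intervals = {r: [] for r in REGIONS}
    for g in genes.itertuples(index=False):
        if g.strand == "+":
            intervals["upstream"].append((g.chrom, max(g.start - flank, 0), g.start))
            intervals["body"].append((g.chrom, g.start, g.end))
            intervals["downstream"].append((g.chrom, g.end, g.end + flank))
        else:
            intervals["upstream"].append((g.chrom, g.end, g.end + flank))
            intervals["body"].append((g.chrom, g.start, g.end))
            intervals["downstream"].append((g.chrom, max(g.start - flank, 0), g.start))
    rows = []
    for region, ivs in intervals.items():
        ivs_df = pd.DataFrame(ivs, columns=["chrom", "start", "end"])
        for name, calls in calls_by_sample.items():
            mask = sites_in_intervals(calls, ivs_df)
            cov = int(calls.df.loc[mask, "coverage"].sum())
            level = float(calls.df.loc[mask, "modified"].sum()) / cov if cov else np.nan
            rows.append({"sample": name, "region": region, "level": level, "coverage": cov})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# group comparisons of region averages
# ---------------------------------------------------------------------------


def sidak(p: np.ndarray | float, m: int) -> np.ndarray | float:
    """Sidak family-wise correction ``1 - (1 - p)^m`` for m comparisons."""
    return 1.0 - (1.0 - np.asarray(p)) ** m


def compare_region_averages(
    df: pd.DataFrame,
    design: str,
    comparison: tuple[str, str] | None = None,
) -> pd.DataFrame:
    """Group tests on per-replicate region means.

    ``df`` columns: group, pair (replicate pairing id), region, level.

    * ``design="paired"``: per region, a paired two-tailed t-test between the
      two groups, aligned on ``pair`` (unbalanced pairing is an error).
    * ``design="multi"``: two-factor fixed-effects cell-means fit
      (group x region); per region all pairwise group contrasts are tested
      with the single pooled residual variance and Sidak-corrected over the
      whole contrast family.
    """
    if design == "paired":
        groups = sorted(df["group"].unique()) if comparison is None else list(comparison)
        if len(groups) != 2:
            raise ValidationError("paired design needs exactly two groups")
        rows = []
        for region, sub in df.groupby("region", sort=False):
            a = sub[sub["group"] == groups[0]].set_index("pair")["level"]
            b = sub[sub["group"] == groups[1]].set_index("pair")["level"]
            if not a.index.sort_values().equals(b.index.sort_values()):
                raise ValidationError(f"unbalanced pairing in region {region!r}")
            b = b.reindex(a.index)
            t, p = stats.ttest_rel(a.to_numpy(), b.to_numpy())
            if np.isnan(p):  # identical pairs: zero variance of differences
                t, p = 0.0, 1.0
            rows.append({"region": region, "group_a": groups[0], "group_b": groups[1],
                         "t": float(t), "p": float(p)})
        return pd.DataFrame(rows)

    if design != "multi":
        raise ValidationError(f"unknown design {design!r}")

    # cell-means two-way fit: pooled residual variance across all cells
    cells = df.groupby(["group", "region"])["level"]
    resid_ss = float(((df["level"] - cells.transform("mean")) ** 2).sum())
    df_resid = len(df) - df.groupby(["group", "region"]).ngroups
    if df_resid <= 0:
        raise ValidationError("no residual degrees of freedom (need replicates)")
    mse = resid_ss / df_resid
    means = cells.mean()
    ns = cells.count()
    groups = sorted(df["group"].unique())
    regions = list(df["region"].unique())
    pairs = [(a, b) for i, a in enumerate(groups) for b in groups[i + 1 :]]
    m = len(pairs) * len(regions)
    rows = []
    for region in regions:
        for a, b in pairs:
            d = means[(a, region)] - means[(b, region)]
            se = np.sqrt(mse * (1.0 / ns[(a, region)] + 1.0 / ns[(b, region)]))
            t = d / se if se > 0 else 0.0
            p = 2.0 * stats.t.sf(abs(t), df_resid)
            rows.append({"region": region, "group_a": a, "group_b": b, "diff": float(d),
                         "t": float(t), "p": float(p), "p_sidak": float(sidak(p, m))})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# repeat summaries
# ---------------------------------------------------------------------------


def repeat_summary(
    calls_by_sample: Mapping[str, SiteCalls],
    repeats: pd.DataFrame,
) -> pd.DataFrame:
    """Modification levels for whole genome / repeat / non-repeat / repeat classes.

    A site is repeat-assigned iff it overlaps any repeat interval, so the
    repeat and non-repeat site sets partition all sites.  Class rows use the
    class-specific intervals (classes may overlap each other); unknown class
    labels are grouped as ``Other`` with a warning.
    """
    repeats = repeats.rename(columns={"name": "repeat_class"}) if "name" in repeats.columns else repeats
    if "repeat_class" not in repeats.columns:
        repeats = repeats.assign(repeat_class="Other")
    unknown = set(repeats["repeat_class"]) - set(REPEAT_CLASSES)
    if unknown:
        warnings.warn(f"unknown repeat classes {sorted(unknown)} grouped as 'Other'")
        repeats = repeats.copy()
        repeats.loc[repeats["repeat_class"].isin(unknown), "repeat_class"] = "Other"
    classes = [c for c in REPEAT_CLASSES if (repeats["repeat_class"] == c).any()]
    if (repeats["repeat_class"] == "Other").any():
        classes.append("Other")
    rows = []
    for name, calls in calls_by_sample.items():
        df = calls.df
        total_cov = int(df["coverage"].sum())
        rows.append({"sample": name, "category": "whole_genome",
                     "level": df["modified"].sum() / total_cov if total_cov else np.nan})
        if len(repeats):
            in_rep = sites_in_intervals(calls, repeats[["chrom", "start", "end"]])
        else:
            in_rep = np.zeros(len(df), dtype=bool)
        for category, mask in (("repeat", in_rep), ("non_repeat", ~in_rep)):
            cov = int(df.loc[mask, "coverage"].sum())
            level = df.loc[mask, "modified"].sum() / cov if cov else np.nan
            if category == "repeat" and len(repeats) == 0:
                level = np.nan
            rows.append({"sample": name, "category": category, "level": level})
        for cls in classes:
            sub = repeats[repeats["repeat_class"] == cls]
            mask = sites_in_intervals(calls, sub[["chrom", "start", "end"]])
            cov = int(df.loc[mask, "coverage"].sum())
            rows.append({"sample": name, "category": cls,
                         "level": df.loc[mask, "modified"].sum() / cov if cov else np.nan})
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# EM-seq region tests
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class EmseqRegionResult:
    """Region-level t-test plus per-CpG Sidak-corrected contrasts."""

    region_t: float
    region_p: float
    per_cpg: pd.DataFrame | None
    note: str = ""


def emseq_region_tests(
    levels: pd.DataFrame,
    comparison: tuple[str, str],
) -> EmseqRegionResult:
    """Compare two cell types over one targeted region.

    ``levels`` columns: cell_type, replicate, pos, level (per-CpG per
    replicate).  The region test is a two-tailed unpaired t on per-replicate
    region means.  Per-CpG contrasts come from a position x cell-type
    cell-means fit with a single pooled residual variance, Sidak-corrected
    over positions; with fewer than two common positions the per-CpG test is
    skipped with a note.
    """
    a, b = comparison
    sub = levels[levels["cell_type"].isin([a, b])]
    for ct in (a, b):
        if sub[sub["cell_type"] == ct]["replicate"].nunique() < 2:
            raise ValidationError(f"need >= 2 replicates for cell type {ct!r}")
    rep_means = sub.groupby(["cell_type", "replicate"])["level"].mean()
    t, p = stats.ttest_ind(rep_means[a].to_numpy(), rep_means[b].to_numpy(), equal_var=True)
    if np.isnan(p):
        t, p = 0.0, 1.0

    # common positions covered in every replicate of both cell types
    n_reps = sub.groupby("cell_type")["replicate"].nunique()
    by_pos = sub.groupby(["pos", "cell_type"])["level"]
    counts = by_pos.count().unstack("cell_type")
    common = counts.index[(counts[a] == n_reps[a]) & (counts[b] == n_reps[b])]
    if len(common) < 2:
        return EmseqRegionResult(float(t), float(p), None, note="fewer than 2 common positions; per-CpG test skipped")
    cc = sub[sub["pos"].isin(common)]
    cell = cc.groupby(["pos", "cell_type"])["level"]
    resid_ss = float(((cc["level"] - cell.transform("mean")) ** 2).sum())
    df_resid = len(cc) - cc.groupby(["pos", "cell_type"]).ngroups
    if df_resid <= 0:
        return EmseqRegionResult(float(t), float(p), None, note="no residual degrees of freedom")
    mse = resid_ss / df_resid
    means = cell.mean()
    ns = cell.count()
    m = len(common)
    rows = []
    for pos in common:
        d = means[(pos, a)] - means[(pos, b)]
        se = np.sqrt(mse * (1.0 / ns[(pos, a)] + 1.0 / ns[(pos, b)]))
        tt = d / se if se > 0 else 0.0
        pp = 2.0 * stats.t.sf(abs(tt), df_resid)
        rows.append({"pos": pos, "diff": float(d), "t": float(tt), "p": float(pp),
                     "p_sidak": float(sidak(pp, m))})
    return EmseqRegionResult(float(t), float(p), pd.DataFrame(rows))
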