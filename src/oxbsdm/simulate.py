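"""Synthetic ground-truth genomes, modification landscapes, and sequencing arms.

The generator emulates the statistical structure of cell-type-resolved
whole-genome oxidative bisulfite data from brain tissue:

* three cell types (neuron, astrocyte, microglia) with genome-wide mCG/hmCG
  levels ordered microglia > astrocyte > neuron for mCG and the reverse for
  hmCG and mCH; whole-genome mCH defaults are 1.46 / 0.85 / 0.67 % and
  simple-repeat mCH 2.51 / 1.54 / 1.17 %;
* genic structure: a TSS-proximal dip in all modifications, promoter and
  gene-body couplings to expression tier (promoter/body mCG inverse,
  gene-body hmCG positive, and an mCH-expression inverse coupling applied to
  neurons only);
* repeat intervals (LINE/SINE/LTR/Simple_repeat) with class-level offsets;
* arm-specific conversion chemistry: each read-call is modified with
  probability ``f_C a_C + f_mC a_mC + f_hmC a_hmC`` for the arm's rates, with
  Poisson per-site coverage;
* spike-in control contigs of known C/mC/hmC state for conversion-rate
  estimation;
* per-gene expression count tables whose tier structure matches the planted
  modification couplings.

Everything is deterministic under the configured seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .dmr import tile_genome
from .io import ConversionRates, SiteCalls, ValidationError

TIERS = ("high", "mid", "low", "unexpressed")


@dataclass(frozen=True)
class CellTargets:
    """Genome-wide truth levels for one cell type (fractions, not percent)."""

    mcg: float
    hmcg: float
    mch: float
    hmch: float = 0.0
    simple_repeat_mch: float | None = None


DEFAULT_CELL_TYPES: dict[str, CellTargets] = {
    "neuron": CellTargets(mcg=0.70, hmcg=0.22, mch=0.0146, simple_repeat_mch=0.0251),
    "astrocyte": CellTargets(mcg=0.76, hmcg=0.15, mch=0.0085, simple_repeat_mch=0.0154),
    "microglia": CellTargets(mcg=0.80, hmcg=0.10, mch=0.0067, simple_repeat_mch=0.0117),
}

DEFAULT_RATES = {
    # BS converts unmodified C nearly completely; mC and hmC mostly retained
    "BS": ConversionRates("BS", a_c=0.005, a_mc=0.98, a_hmc=0.95),
    # oxidation converts hmC so only mC reads modified in the oxBS arm
    "oxBS": ConversionRates("oxBS", a_c=0.005, a_mc=0.98, a_hmc=0.05),
    # EM-seq: TET+ reads mC+hmC, the mock TET- arm reads only (protected) hmC
    "TET+": ConversionRates("TET+", a_c=0.005, a_mc=0.98, a_hmc=0.95),
    "TET-": ConversionRates("TET-", a_c=0.005, a_mc=0.005, a_hmc=0.95),
}


@dataclass(frozen=True)
class PlantedWindowSpec:
    """Planted differential windows: ``diff`` added to the first cell type."""

    mod_type: str  # mCG | hmCG | mCH
    comparison: tuple[str, str]
    diff: float  # fraction, e.g. 0.20
    n_windows: int
    base: float | None = None  # second cell type's window level; default from targets


@dataclass(frozen=True)
class SimConfig:
    seed: int = 0
    chrom_sizes: Mapping[str, int] = field(default_factory=lambda: {"chr1": 10_000_000})
    tile_width: int = 1000
    # genes
    n_genes: int = 250
    gene_min_len: int = 5_000
    gene_max_len: int = 30_000
    min_gene_gap: int = 2_000
    unexpressed_fraction: float = 0.1
    # repeats: class -> fraction of genome covered (non-overlapping placement)
    repeat_fractions: Mapping[str, float] = field(
        default_factory=lambda: {"LINE": 0.15, "SINE": 0.10, "LTR": 0.10, "Simple_repeat": 0.05}
    )
    repeat_min_len: int = 200
    repeat_max_len: int = 1_500
    # site densities (sites per bp, single strand assignment)
    cpg_density: float = 0.03
    ch_density: float = 0.10
    # truth levels
    cell_types: Mapping[str, CellTargets] = field(default_factory=lambda: dict(DEFAULT_CELL_TYPES))
    # beta concentrations: CpG methylomes are bimodal (small nu), mCH is not
    nu_cg: float = 0.8
    nu_ch: float = 60.0
    # genic effects (multipliers on the site mean)
    tss_dip_mult: float = 0.3
    tss_dip_span: tuple[int, int] = (-2000, 500)  # around TSS, strand-oriented
    promoter_span: int = 4000
    promoter_mcg_by_tier: Mapping[str, float] = field(
        default_factory=lambda: {"high": 0.5, "mid": 0.8, "low": 1.0, "unexpressed": 1.1}
    )
    body_mcg_by_tier: Mapping[str, float] = field(
        default_factory=lambda: {"high": 0.85, "mid": 1.0, "low": 1.1, "unexpressed": 1.15}
    )
    body_hmcg_by_tier: Mapping[str, float] = field(
        default_factory=lambda: {"high": 1.5, "mid": 1.0, "low": 0.7, "unexpressed": 0.5}
    )
    body_mch_by_tier: Mapping[str, float] = field(
        default_factory=lambda: {"high": 0.5, "mid": 1.0, "low": 1.6, "unexpressed": 1.2}
    )
    mch_coupled_cell_types: tuple[str, ...] = ("neuron",)
    repeat_mcg_mult: float = 1.08
    repeat_hmcg_mult: float = 0.80
    repeat_mch_mult: float = 0.95  # LINE/SINE/LTR (Simple_repeat has absolute targets)
    # planted differential windows
    planted: tuple[PlantedWindowSpec, ...] = ()
    # sequencing
    rates: Mapping[str, ConversionRates] = field(default_factory=lambda: dict(DEFAULT_RATES))
    mean_coverage: float = 2.0
    n_replicates: int = 4
    # spike-ins
    spike_sites_per_class: int = 200
    spike_coverage: float = 50.0
    # expression
    tier_means: Mapping[str, float] = field(
        default_factory=lambda: {"high": 2000.0, "mid": 200.0, "low": 20.0}
    )
    tier_lognorm_sigma: float = 0.3
    nb_size: float = 20.0

    def __post_init__(self) -> None:
        for ct, t in self.cell_types.items():
            for name in ("mcg", "hmcg", "mch", "hmch"):
                v = getattr(t, name)
                if not 0.0 <= v <= 1.0:
                    raise ValidationError(f"{ct}.{name}={v} outside [0,1]")
        if self.mean_coverage < 0:
            raise ValidationError("mean_coverage must be >= 0")


@dataclass
class Genome:
    chrom_sizes: dict[str, int]
    genes: pd.DataFrame  # gene_id, chrom, strand, start, end, exons, cds, tier_<ct>
    repeats: pd.DataFrame  # chrom, start, end, repeat_class
    tiles: pd.DataFrame
    spike_truth: pd.DataFrame  # chrom, pos, strand, true_state


@dataclass
class SyntheticTruth:
    """Ground truth: per-site simplex fractions per cell type and context."""

    genome: Genome
    sites: dict[str, pd.DataFrame]  # context -> chrom, pos, strand
    f_mc: dict[tuple[str, str], np.ndarray]  # (cell_type, context) -> per-site
    f_hmc: dict[tuple[str, str], np.ndarray]
    planted: pd.DataFrame  # chrom, start, end, mod_type, cell_a, cell_b, diff, base

    def window_truth_mean(self, cell_type: str, context: str, chrom: str, start: int, end: int,
                          which: str = "hmc") -> float:
        df = self.sites[context]
        mask = (df["chrom"] == chrom).to_numpy() & ((df["pos"] - 1 >= start) & (df["pos"] - 1 < end)).to_numpy()
        arr = self.f_hmc if which == "hmc" else self.f_mc
        return float(arr[(cell_type, context)][mask].mean())


def _place_nonoverlapping(rng: np.random.Generator, genome_len: int, lengths: np.ndarray,
                          min_gap: int) -> np.ndarray:
    """Random non-overlapping placement: shuffle, distribute slack as gaps."""
    total = int(lengths.sum()) + min_gap * (len(lengths) + 1)
    if total > genome_len:
        raise ValidationError(
            f"infeasible layout: {len(lengths)} intervals of total length {int(lengths.sum())} "
            f"do not fit in {genome_len} bp"
        )
    slack = genome_len - total
    w = rng.random(len(lengths) + 1)
    gaps = min_gap + np.floor(slack * w / w.sum()).astype(np.int64)
    starts = np.cumsum(gaps[:-1] + np.concatenate([[0], lengths[:-1]]))
    return starts


def make_genome(config: SimConfig) -> Genome:
    """Deterministic genome layout: genes, repeats, tile grid, spike-in truth."""
    rng = np.random.default_rng(config.seed)
    (chrom, size), *rest = list(config.chrom_sizes.items())
    if rest:
        raise ValidationError("one data chromosome supported per simulation")

    # genes: non-overlapping by construction
    lengths = rng.integers(config.gene_min_len, config.gene_max_len + 1, size=config.n_genes)
    starts = _place_nonoverlapping(rng, size, lengths, config.min_gene_gap)
    rows = []
    for i, (s, ln) in enumerate(zip(starts, lengths)):
        end = int(s + ln)
        strand = "+" if rng.random() < 0.5 else "-"
        n_ex = int(rng.integers(3, 9))
        w = rng.random(2 * n_ex - 1) + 0.05
        seg = np.floor(ln * np.cumsum(w) / w.sum()).astype(np.int64)
        bounds = np.concatenate([[0], seg[:-1], [ln]])
        ex_s = [int(s + bounds[j]) for j in range(0, 2 * n_ex - 1, 2)]
        ex_e = [int(s + bounds[j + 1]) for j in range(0, 2 * n_ex - 1, 2)]
        ex_s, ex_e = zip(*[(a, b) for a, b in zip(ex_s, ex_e) if b > a])
        cds_start = ex_s[0] + (ex_e[0] - ex_s[0]) // 2
        cds_end = ex_s[-1] + (ex_e[-1] - ex_s[-1]) // 2
        rows.append(
            dict(gene_id=f"gene{i:04d}", chrom=chrom, strand=strand, start=int(s), end=end,
                 exon_starts=list(ex_s), exon_ends=list(ex_e),
                 cds_start=int(cds_start), cds_end=int(cds_end))
        )
    genes = pd.DataFrame(rows)

    # expression tiers per cell type, sized exactly like the tertile split
    n = len(genes)
    n_unexp = int(round(config.unexpressed_fraction * n))
    n_exp = n - n_unexp
    base, rem = divmod(n_exp, 3)
    sizes = [base + (1 if rem >= 1 else 0), base + (1 if rem >= 2 else 0), base]
    for ct in config.cell_types:
        perm = rng.permutation(n)
        tier = np.empty(n, dtype=object)
        hi, mi, lo = perm[: sizes[0]], perm[sizes[0] : sizes[0] + sizes[1]], perm[sizes[0] + sizes[1] : n_exp]
        tier[hi], tier[mi], tier[lo] = "high", "mid", "low"
        tier[perm[n_exp:]] = "unexpressed"
        genes[f"tier_{ct}"] = tier

    # repeats: per-class budgets realised exactly by non-overlapping placement
    rep_rows = []
    all_lengths, all_classes = [], []
    for cls, frac in config.repeat_fractions.items():
        budget = frac * size
        mean_len = (config.repeat_min_len + config.repeat_max_len) / 2
        n_iv = max(int(round(budget / mean_len)), 1)
        ls = rng.integers(config.repeat_min_len, config.repeat_max_len + 1, size=n_iv)
        ls = np.floor(ls * budget / ls.sum()).astype(np.int64)
        all_lengths.append(ls[ls > 0])
        all_classes += [cls] * int((ls > 0).sum())
    lengths_r = np.concatenate(all_lengths)
    order = rng.permutation(len(lengths_r))
    lengths_r = lengths_r[order]
    classes_r = np.array(all_classes, dtype=object)[order]
    starts_r = _place_nonoverlapping(rng, size, lengths_r, min_gap=10)
    repeats = pd.DataFrame(
        {"chrom": chrom, "start": starts_r, "end": starts_r + lengths_r, "repeat_class": classes_r}
    )

    tiles = tile_genome(config.chrom_sizes, config.tile_width)

    # spike-ins: one control contig per state block
    spacing = 10
    n_spike = config.spike_sites_per_class
    pos = np.arange(1, 3 * n_spike + 1) * spacing
    states = np.repeat(["C", "mC", "hmC"], n_spike)
    spike = pd.DataFrame({"chrom": "spikein", "pos": pos, "strand": "+", "true_state": states})

    return Genome(chrom_sizes=dict(config.chrom_sizes), genes=genes, repeats=repeats,
                  tiles=tiles, spike_truth=spike)


def _interval_mask(pos0: np.ndarray, intervals: pd.DataFrame) -> np.ndarray:
    """Membership of 0-based positions in sorted non-overlapping intervals."""
    if len(intervals) == 0:
        return np.zeros(len(pos0), dtype=bool)
    iv = intervals.sort_values("start")
    starts = iv["start"].to_numpy(np.int64)
    ends = iv["end"].to_numpy(np.int64)
    idx = np.searchsorted(starts, pos0, side="right") - 1
    return (idx >= 0) & (pos0 < ends[np.clip(idx, 0, len(ends) - 1)])


def _draw_simplex(
    rng: np.random.Generator, mu_m: np.ndarray, mu_h: np.ndarray, nu: float
) -> tuple[np.ndarray, np.ndarray]:
    """Per-site Dirichlet draw of (f_C, f_mC, f_hmC) with exact means (mu_m, mu_h).

    Zero means yield exact zeros (a zero-shape gamma component), so a zero
    hmCH target produces f_hmC = 0 at every site.
    """
    mu_c = 1.0 - mu_m - mu_h
    g_m = rng.standard_gamma(nu * mu_m)
    g_h = rng.standard_gamma(nu * mu_h)
    g_c = rng.standard_gamma(nu * mu_c)
    total = g_m + g_h + g_c
    total[total == 0] = 1.0
    return g_m / total, g_h / total


def _renormalise_means(
    mu: np.ndarray, target: float, fixed: np.ndarray | None = None
) -> np.ndarray:
    """Scale free sites so the overall mean hits ``target`` (fixed sites kept)."""
    if target <= 0:
        return mu
    free = np.ones(len(mu), dtype=bool) if fixed is None else ~fixed
    want = target * len(mu) - mu[~free].sum()
    have = mu[free].sum()
    if want <= 0 or have <= 0:
        raise ValidationError("level targets incompatible with fixed-class overrides")
    out = mu.copy()
    out[free] = mu[free] * (want / have)
    return out


def make_landscape(config: SimConfig, genome: Genome) -> SyntheticTruth:
    """Draw per-site true (f_C, f_mC, f_hmC) for each cell type and context."""
    rng = np.random.default_rng(config.seed + 1)
    (chrom, size), = genome.chrom_sizes.items()

    sites: dict[str, pd.DataFrame] = {}
    for context, density in (("CG", config.cpg_density), ("CH", config.ch_density)):
        n_sites = int(round(density * size))
        pos0 = np.unique(rng.integers(0, size, size=int(n_sites * 1.1)))
        if len(pos0) > n_sites:
            pos0 = np.sort(rng.choice(pos0, size=n_sites, replace=False))
        strand = np.where(rng.random(len(pos0)) < 0.5, "+", "-")
        sites[context] = pd.DataFrame({"chrom": chrom, "pos": pos0 + 1, "strand": strand})

    # per-site multiplier fields shared across cell types, per modification kind
    gene_arrays = genome.genes
    repeats = genome.repeats
    sr = repeats[repeats["repeat_class"] == "Simple_repeat"]
    other_rep = repeats[repeats["repeat_class"] != "Simple_repeat"]

    def genic_mult(context_pos0: np.ndarray, by_tier: Mapping[str, float], tier_col: str,
                   tss_dip: bool) -> np.ndarray:
        m = np.ones(len(context_pos0))
        for g in gene_arrays.itertuples(index=False):
            tier = getattr(g, tier_col)
            body = (context_pos0 >= g.start) & (context_pos0 < g.end)
            m[body] *= by_tier[tier]
            tss = g.start if g.strand == "+" else g.end
            lo, hi = config.tss_dip_span
            if g.strand == "+":
                dip = (context_pos0 >= tss + lo) & (context_pos0 < tss + hi)
            else:
                dip = (context_pos0 >= tss - hi) & (context_pos0 < tss - lo)
            if tss_dip:
                m[dip] *= config.tss_dip_mult
            # promoter coupling, upstream of the TSS
            if g.strand == "+":
                prom = (context_pos0 >= tss - config.promoter_span) & (context_pos0 < tss)
            else:
                prom = (context_pos0 >= tss) & (context_pos0 < tss + config.promoter_span)
            if by_tier is not config.body_hmcg_by_tier:  # promoters couple for mCG/mCH only
                m[prom] *= np.sqrt(by_tier[tier])
        return m

    f_mc: dict[tuple[str, str], np.ndarray] = {}
    f_hmc: dict[tuple[str, str], np.ndarray] = {}
    for ct, targets in config.cell_types.items():
        for context in ("CG", "CH"):
            pos0 = sites[context]["pos"].to_numpy(np.int64) - 1
            in_sr = _interval_mask(pos0, sr)
            in_rep = _interval_mask(pos0, other_rep) | in_sr
            nu = config.nu_cg if context == "CG" else config.nu_ch
            tier_col = f"tier_{ct}"

            sr_fixed: np.ndarray | None = None
            if context == "CG":
                m_mult = genic_mult(pos0, config.body_mcg_by_tier, tier_col, tss_dip=True)
                m_mult *= np.where(in_rep, config.repeat_mcg_mult, 1.0)
                mu_m = targets.mcg * m_mult / m_mult.mean() if targets.mcg > 0 else np.zeros(len(pos0))
                h_mult = genic_mult(pos0, config.body_hmcg_by_tier, tier_col, tss_dip=True)
                h_mult *= np.where(in_rep, config.repeat_hmcg_mult, 1.0)
                mu_h = targets.hmcg * h_mult / h_mult.mean() if targets.hmcg > 0 else np.zeros(len(pos0))
                target_m, target_h = targets.mcg, targets.hmcg
            else:
                coupled = ct in config.mch_coupled_cell_types
                tiers = {t: (config.body_mch_by_tier[t] if coupled else 1.0) for t in TIERS}
                m_mult = genic_mult(pos0, tiers, tier_col, tss_dip=True)
                m_mult *= np.where(in_rep & ~in_sr, config.repeat_mch_mult, 1.0)
                if targets.simple_repeat_mch is not None and in_sr.any():
                    mu_m = np.empty(len(pos0))
                    mu_m[in_sr] = targets.simple_repeat_mch
                    mu_m[~in_sr] = m_mult[~in_sr]
                    sr_fixed = in_sr
                    mu_m = _renormalise_means(mu_m, targets.mch, fixed=sr_fixed)
                else:
                    mu_m = targets.mch * m_mult / m_mult.mean() if targets.mch > 0 else np.zeros(len(pos0))
                mu_h = np.full(len(pos0), targets.hmch)
                target_m, target_h = targets.mch, targets.hmch

            # cap the simplex, then restore the configured genome means; a
            # second pass reduces residual bias from re-capping
            for _ in range(2):
                hi = mu_m + mu_h > 0.995
                if hi.any():
                    s = (mu_m[hi] + mu_h[hi]) / 0.995
                    mu_m[hi] /= s
                    mu_h[hi] /= s
                if target_m > 0:
                    mu_m = _renormalise_means(mu_m, target_m, fixed=sr_fixed)
                if target_h > 0:
                    mu_h = _renormalise_means(mu_h, target_h)
            hi = mu_m + mu_h > 0.999
            if hi.any():
                s = (mu_m[hi] + mu_h[hi]) / 0.999
                mu_m[hi] /= s
                mu_h[hi] /= s
            fm, fh = _draw_simplex(rng, mu_m, mu_h, nu)
            f_mc[(ct, context)] = fm
            f_hmc[(ct, context)] = fh

    # planted windows: constant truth override on tile-grid windows
    planted_rows = []
    used_tiles: set[int] = set()
    tiles = genome.tiles
    for spec in config.planted:
        if spec.mod_type not in ("mCG", "hmCG", "mCH"):
            raise ValidationError(f"unknown planted mod_type {spec.mod_type!r}")
        context = "CG" if spec.mod_type.endswith("CG") else "CH"
        free = [i for i in range(len(tiles)) if i not in used_tiles]
        chosen = rng.choice(free, size=spec.n_windows, replace=False)
        used_tiles.update(int(i) for i in chosen)
        ct_a, ct_b = spec.comparison
        t_b = config.cell_types[ct_b]
        if spec.base is not None:
            base = spec.base
        else:
            base = {"mCG": t_b.mcg, "hmCG": t_b.hmcg, "mCH": t_b.mch}[spec.mod_type]
        arr = f_mc if spec.mod_type in ("mCG", "mCH") else f_hmc
        pos0 = sites[context]["pos"].to_numpy(np.int64) - 1
        for i in chosen:
            row = tiles.iloc[int(i)]
            in_w = (pos0 >= row.start) & (pos0 < row.end)
            arr[(ct_a, context)][in_w] = base + spec.diff
            arr[(ct_b, context)][in_w] = base
            planted_rows.append(
                dict(chrom=row.chrom, start=int(row.start), end=int(row.end),
                     mod_type=spec.mod_type, cell_a=ct_a, cell_b=ct_b,
                     diff=spec.diff, base=base)
            )
    planted = pd.DataFrame(
        planted_rows, columns=["chrom", "start", "end", "mod_type", "cell_a", "cell_b", "diff", "base"]
    )
    return SyntheticTruth(genome=genome, sites=sites, f_mc=f_mc, f_hmc=f_hmc, planted=planted)


def simulate_arm(
    truth: SyntheticTruth,
    cell_type: str,
    context: str,
    rates: ConversionRates,
    mean_coverage: float,
    seed: int,
) -> SiteCalls:
    """Forward-simulate one sequencing arm's call table from the truth.

    Per site: coverage ~ Poisson(mean), modified ~ Binomial(coverage, p) with
    ``p = f_C a_C + f_mC a_mC + f_hmC a_hmC``.  Zero-coverage sites are not
    emitted (as in real coverage files).
    """
    rng = np.random.default_rng(seed)
    df = truth.sites[context]
    fm = truth.f_mc[(cell_type, context)]
    fh = truth.f_hmc[(cell_type, context)]
    p = np.asarray(rates.apparent(fm, fh), dtype=float)
    cov = rng.poisson(mean_coverage, size=len(df))
    mod = rng.binomial(cov, np.clip(p, 0.0, 1.0))
    keep = cov > 0
    return SiteCalls.from_arrays(
        df["chrom"].to_numpy()[keep], df["pos"].to_numpy()[keep], df["strand"].to_numpy()[keep],
        cov[keep], mod[keep], context,
    )


def simulate_spike_calls(
    genome: Genome,
    rates: ConversionRates,
    coverage: float,
    seed: int,
) -> SiteCalls:
    """Simulate spike-in control calls from the known per-position states."""
    rng = np.random.default_rng(seed)
    truth = genome.spike_truth
    p = truth["true_state"].map({"C": rates.a_c, "mC": rates.a_mc, "hmC": rates.a_hmc}).to_numpy(float)
    cov = rng.poisson(coverage, size=len(truth))
    mod = rng.binomial(cov, p)
    keep = cov > 0
    return SiteCalls.from_arrays(
        truth["chrom"].to_numpy()[keep], truth["pos"].to_numpy()[keep], truth["strand"].to_numpy()[keep],
        cov[keep], mod[keep], "CG",
    )


def make_expression(
    truth: SyntheticTruth,
    config: SimConfig,
    cell_type: str,
    seed: int,
    n_replicates: int | None = None,
) -> pd.DataFrame:
    """Negative-binomial expression counts matching the planted tiers.

    Unexpressed-tier genes emit exactly zero in every replicate; expressed
    tiers get per-gene lognormal means around the tier centre and NB counts
    with dispersion ``nb_size``.
    """
    rng = np.random.default_rng(seed)
    genes = truth.genome.genes
    n_reps = n_replicates or config.n_replicates
    tiers = genes[f"tier_{cell_type}"].to_numpy()
    mean = np.zeros(len(genes))
    for tier, centre in config.tier_means.items():
        sel = tiers == tier
        mean[sel] = centre * rng.lognormal(0.0, config.tier_lognorm_sigma, size=int(sel.sum()))
    out = pd.DataFrame({"gene_id": genes["gene_id"]})
    r = config.nb_size
    for rep in range(1, n_reps + 1):
        counts = np.zeros(len(genes), dtype=np.int64)
        pos = mean > 0
        counts[pos] = rng.negative_binomial(r, r / (r + mean[pos]))
        out[f"{cell_type}_rep{rep}"] = counts
    return out


def simulate_experiment(config: SimConfig) -> dict:
    """Full forward simulation: genome, truth, arm call tables, spikes, expression.

    Returns a dict with keys ``genome``, ``truth``, ``calls`` (mapping
    (cell_type, arm, context, replicate) -> SiteCalls), ``spikes`` (mapping
    (cell_type, arm, replicate) -> SiteCalls) and ``expression`` (mapping
    cell_type -> DataFrame).
    """
    genome = make_genome(config)
    truth = make_landscape(config, genome)
    calls: dict[tuple, SiteCalls] = {}
    spikes: dict[tuple, SiteCalls] = {}
    expression: dict[str, pd.DataFrame] = {}
    base = config.seed
    for i_ct, ct in enumerate(config.cell_types):
        for i_arm, arm in enumerate(("BS", "oxBS")):
            for context in ("CG", "CH"):
                for rep in range(1, config.n_replicates + 1):
                    seed = (base + 7919 * i_ct + 911 * i_arm + 101 * rep + (13 if context == "CH" else 0)) % (2**31 - 1)
                    calls[(ct, arm, context, rep)] = simulate_arm(
                        truth, ct, context, config.rates[arm], config.mean_coverage, seed
                    )
                    if context == "CG":
                        spikes[(ct, arm, rep)] = simulate_spike_calls(
                            genome, config.rates[arm], config.spike_coverage, seed + 1
                        )
        expression[ct] = make_expression(truth, config, ct, seed=base + 37 * i_ct + 5)
    return {"genome": genome, "truth": truth, "calls": calls, "spikes": spikes, "expression": expression}
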