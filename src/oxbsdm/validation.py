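"""End-to-end simulation studies exercising the pipeline against known truth.

Each function builds a synthetic scenario with the generator, runs the
relevant pipeline operations, and returns the measured quantity.  They are
used both by the test suite and by ``scripts/acceptance.py``.

Problem sizes are desk-scale versions of the real study: a 5 Mb genome with
~150k CpG (or ~500k CH) sites stands in for the mouse genome, with coverage
and replicate numbers matching the sequencing design being emulated.
"""

from __future__ import annotations

import numpy as np

from .dmr import WindowTable, call_dmr, dhmr_from_levels, tile_genome
from .hmc import subsample_calls
from .io import ConversionRates, genome_level
from .profiles import expression_classes, region_averages, repeat_summary
from .simulate import (
    CellTargets,
    SimConfig,
    make_expression,
    make_genome,
    make_landscape,
    simulate_arm,
)

IDEAL_BS = ConversionRates("BS", a_c=0.0, a_mc=1.0, a_hmc=1.0)
IDEAL_OXBS = ConversionRates("oxBS", a_c=0.0, a_mc=1.0, a_hmc=0.0)


def _seed(base: int, k: int) -> int:
    return (base * 1_000_003 + k) % (2**31 - 1)


def coverage_thinning_error(
    seed: int,
    n_seeds: int = 100,
    genome_size: int = 5_000_000,
    site_coverage: float = 30.0,
    target_x: float = 0.001,
) -> dict:
    """Thin a full-coverage CG table down to 0.001X and measure the level error.

    A 5 Mb CG landscape (~150k sites, genome mean ~0.75, bimodal Beta site
    levels) is sequenced at 30x site coverage; the table is binomially
    thinned so that the retained total call count equals ``target_x`` times
    the genome length, and the coverage-weighted genome level is recomputed.
    Returns the per-seed absolute errors in percentage points.
    """
    config = SimConfig(
        seed=_seed(seed, 1),
        chrom_sizes={"chr1": genome_size},
        n_genes=100,
        cpg_density=0.03,
        ch_density=0.001,
        cell_types={"neuron": CellTargets(mcg=0.75, hmcg=0.0, mch=0.001, simple_repeat_mch=None)},
        mean_coverage=site_coverage,
    )
    genome = make_genome(config)
    truth = make_landscape(config, genome)
    calls = simulate_arm(truth, "neuron", "CG", IDEAL_BS, site_coverage, _seed(seed, 2))
    full_level = genome_level(calls)
    total_cov = int(calls.df["coverage"].sum())
    fraction = target_x * genome_size / total_cov
    errors = []
    for k in range(n_seeds):
        thin = subsample_calls(calls, fraction, seed=_seed(seed, 100 + k))
        errors.append(abs(genome_level(thin) - full_level) * 100.0)
    errors = np.array(errors)
    return {
        "errors_pp": errors,
        "median_pp": float(np.median(errors)),
        "frac_within_1pp": float(np.mean(errors <= 1.0)),
        "n_sites": len(calls),
        "fraction": fraction,
    }


def hmch_background(
    seed: int,
    genome_size: int = 5_000_000,
    ch_density: float = 0.10,
    mean_coverage: float = 2.0,
    n_replicates: int = 4,
    true_mch: float = 0.015,
) -> dict:
    """Genome-wide hmCH by BS-minus-oxBS when the true hmCH is zero.

    CH-context arms are simulated with the default conversion errors
    (a_C=0.005, a_mC=0.98 both arms; hmC retention 0.95 BS / 0.05 oxBS);
    the reported value is the replicate-averaged difference of the two arms'
    coverage-weighted genome levels, in percent.
    """
    config = SimConfig(
        seed=_seed(seed, 3),
        chrom_sizes={"chr1": genome_size},
        n_genes=100,
        cpg_density=0.001,
        ch_density=ch_density,
        cell_types={"neuron": CellTargets(mcg=0.75, hmcg=0.0, mch=true_mch, hmch=0.0,
                                          simple_repeat_mch=None)},
        mean_coverage=mean_coverage,
        n_replicates=n_replicates,
    )
    genome = make_genome(config)
    truth = make_landscape(config, genome)
    diffs = []
    for rep in range(n_replicates):
        bs = simulate_arm(truth, "neuron", "CH", config.rates["BS"], mean_coverage, _seed(seed, 200 + rep))
        ox = simulate_arm(truth, "neuron", "CH", config.rates["oxBS"], mean_coverage, _seed(seed, 300 + rep))
        diffs.append(genome_level(bs) - genome_level(ox))
    return {"hmch_percent": float(np.mean(diffs)) * 100.0, "n_sites": len(truth.sites["CH"])}


def neuron_mch_recovery(
    seed: int,
    genome_size: int = 5_000_000,
    ch_density: float = 0.10,
    mean_coverage: float = 2.0,
) -> dict:
    """Recover the neuron-configured whole-genome and simple-repeat mCH truths.

    The generator is configured with the neuronal truths (1.46% genome-wide
    mCH; 2.51% within Simple_repeat intervals covering ~5% of the genome);
    an oxBS CH arm is simulated with ideal conversion chemistry and the
    pipeline's genome-level and repeat-summary operations are run on it.
    """
    config = SimConfig(
        seed=_seed(seed, 4),
        chrom_sizes={"chr1": genome_size},
        n_genes=100,
        cpg_density=0.001,
        ch_density=ch_density,
        cell_types={"neuron": CellTargets(mcg=0.70, hmcg=0.22, mch=0.0146,
                                          simple_repeat_mch=0.0251)},
        mean_coverage=mean_coverage,
    )
    genome = make_genome(config)
    truth = make_landscape(config, genome)
    ox = simulate_arm(truth, "neuron", "CH", IDEAL_OXBS, mean_coverage, _seed(seed, 5))
    summary = repeat_summary({"neuron_oxBS": ox}, genome.repeats)
    whole = float(summary.loc[summary["category"] == "whole_genome", "level"].iloc[0])
    sr = float(summary.loc[summary["category"] == "Simple_repeat", "level"].iloc[0])
    return {
        "genome_mch_percent": 100.0 * genome_level(ox),
        "simple_repeat_mch_percent": 100.0 * sr,
        "whole_genome_check": 100.0 * whole,
        "n_sites": len(ox),
    }


def null_calibration(
    seed: int,
    n_reps: int = 500,
    n_windows: int = 200,
    n_per_group: int = 4,
    mean_coverage: float = 50.0,
) -> dict:
    """Fraction of windows with q < 0.05 when both groups share one distribution.

    For the count-based caller, per-window baseline levels are Beta-drawn and
    all samples of both groups are binomial around them; for the
    subtraction-based caller, per-sample window hmC is Gaussian noise around
    a shared mean.  Returns the across-rep average rejected fraction for each.
    """
    rng = np.random.default_rng(_seed(seed, 6))
    windows = tile_genome({"chr1": n_windows * 1000}, 1000)
    samples = tuple(f"s{i}" for i in range(2 * n_per_group))
    groups = {s: ("A" if i < n_per_group else "B") for i, s in enumerate(samples)}
    frac_dmr, frac_dhmr = [], []
    for _ in range(n_reps):
        p_w = rng.beta(2.0, 2.0, size=n_windows)
        cov = rng.poisson(mean_coverage, size=(n_windows, len(samples))) + 1
        mod = rng.binomial(cov, p_w[:, None])
        wt = WindowTable(windows=windows, samples=samples, coverage=cov, modified=mod, width=1000)
        res = call_dmr(wt, groups, ("A", "B"), min_diff_pct=0.0, q_max=0.05)
        frac_dmr.append(len(res) / res.attrs["n_tested"])

        h = 0.20 + rng.normal(0.0, 0.03, size=(n_windows, len(samples)))
        res_h = dhmr_from_levels(windows, h, samples, groups, ("A", "B"),
                                 min_diff_pct=0.0, p_max=1.0, q_max=0.05)
        frac_dhmr.append(len(res_h) / n_windows)
    return {
        "dmr_fraction_q05": float(np.mean(frac_dmr)),
        "dhmr_fraction_q05": float(np.mean(frac_dhmr)),
        "n_reps": n_reps,
    }


def planted_power(
    seed: int,
    n_reps: int = 100,
    n_windows: int = 1000,
    n_planted: int = 10,
    diff: float = 0.20,
    noise_sd: float = 0.03,
    n_per_group: int = 4,
    base: float = 0.15,
) -> dict:
    """Sensitivity and FDR for planted hmCG window differences.

    ``n_planted`` of ``n_windows`` windows carry a ``diff`` group difference
    in per-sample window hmC (replicate noise SD ``noise_sd``); the
    subtraction-based caller runs at the standard thresholds (>=5 pp
    difference, t-test p<=0.05, step-up q<=0.05).
    """
    rng = np.random.default_rng(_seed(seed, 7))
    windows = tile_genome({"chr1": n_windows * 1000}, 1000)
    samples = tuple(f"s{i}" for i in range(2 * n_per_group))
    groups = {s: ("A" if i < n_per_group else "B") for i, s in enumerate(samples)}
    sens, fdrs = [], []
    for _ in range(n_reps):
        h = base + rng.normal(0.0, noise_sd, size=(n_windows, len(samples)))
        planted_idx = rng.choice(n_windows, size=n_planted, replace=False)
        h[np.ix_(planted_idx, np.arange(n_per_group))] += diff
        res = dhmr_from_levels(windows, h, samples, groups, ("A", "B"),
                               min_diff_pct=5.0, p_max=0.05, q_max=0.05)
        called = set(res["start"] // 1000)
        truth_set = set(int(i) for i in planted_idx)
        tp = len(called & truth_set)
        fp = len(called - truth_set)
        sens.append(tp / n_planted)
        fdrs.append(fp / max(len(called), 1))
    return {
        "sensitivity": float(np.mean(sens)),
        "fdr": float(np.mean(fdrs)),
        "n_reps": n_reps,
    }


def expression_coupling_signs(
    seed: int,
    genome_size: int = 3_000_000,
    n_genes: int = 90,
    mean_coverage: float = 5.0,
) -> dict:
    """Recover the modification-expression tertile orderings from a full loop.

    Expression counts are generated from the planted tiers, re-classified
    with ``expression_classes``, and per-tertile region averages are computed
    from simulated BS/oxBS arms.  Returns the tertile means and whether the
    expected orderings hold: highest tertile has the lowest promoter mCG, the
    highest gene-body hmCG, and (neuron mCH coupling) the lowest gene-body
    mCH.
    """
    config = SimConfig(
        seed=_seed(seed, 8),
        chrom_sizes={"chr1": genome_size},
        n_genes=n_genes,
        gene_min_len=5_000,
        gene_max_len=20_000,
        cpg_density=0.03,
        ch_density=0.05,
        mean_coverage=mean_coverage,
        cell_types={"neuron": CellTargets(mcg=0.70, hmcg=0.22, mch=0.0146, simple_repeat_mch=None)},
    )
    genome = make_genome(config)
    truth = make_landscape(config, genome)
    expr = make_expression(truth, config, "neuron", seed=_seed(seed, 9))
    classes = expression_classes(expr)

    bs_cg = simulate_arm(truth, "neuron", "CG", IDEAL_BS, mean_coverage, _seed(seed, 10))
    ox_cg = simulate_arm(truth, "neuron", "CG", IDEAL_OXBS, mean_coverage, _seed(seed, 11))
    ox_ch = simulate_arm(truth, "neuron", "CH", IDEAL_OXBS, mean_coverage, _seed(seed, 12))

    genes = genome.genes.set_index("gene_id")
    out: dict[str, dict[str, float]] = {"promoter_mcg": {}, "body_hmcg": {}, "body_mch": {}}
    for tier in ("high", "mid", "low"):
        ids = list(getattr(classes, tier))
        sub = genes.loc[ids].reset_index()
        ra_bs = region_averages({"bs": bs_cg}, sub).set_index("region")["level"]
        ra_ox = region_averages({"ox": ox_cg}, sub).set_index("region")["level"]
        ra_ch = region_averages({"ox": ox_ch}, sub).set_index("region")["level"]
        out["promoter_mcg"][tier] = float(ra_ox["upstream"])
        out["body_hmcg"][tier] = float(ra_bs["body"] - ra_ox["body"])
        out["body_mch"][tier] = float(ra_ch["body"])
    m = out
    return {
        **m,
        "promoter_mcg_ordered": m["promoter_mcg"]["high"] < m["promoter_mcg"]["mid"] < m["promoter_mcg"]["low"],
        "body_hmcg_ordered": m["body_hmcg"]["high"] > m["body_hmcg"]["mid"] > m["body_hmcg"]["low"],
        "body_mch_ordered": m["body_mch"]["high"] < m["body_mch"]["mid"] < m["body_mch"]["low"],
    }
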