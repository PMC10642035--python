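"""Genic-feature assignment and log-odds over/under-representation.

Every genomic position resolves to exactly one label from a fixed vocabulary
(promoter tiers, UTRs, exons, introns, downstream, distal intergenic) under a
priority rule, so per-feature counts partition any region set.  Differential
regions are compared against a background region set feature-by-feature with
a manually computed log odds ratio ``ln((a*d)/(c*b))``, a Woolf
normal-approximation 95% CI, and a two-sided Fisher exact p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from intervaltree import IntervalTree
from scipy import stats

from .io import ValidationError

FEATURE_LABELS = (
    "Promoter (2-3kb)",
    "Promoter (1-2kb)",
    "Promoter (<=1kb)",
    "5' UTR",
    "1st Exon",
    "1st Intron",
    "Other Exon",
    "Other Intron",
    "3' UTR",
    "Downstream (<=300bp)",
    "Distal Intergenic",
)

# assignment priority (promoter tiers collapse into one nearest-TSS lookup)
_PRIORITY = (
    "promoter",
    "5' UTR",
    "3' UTR",
    "1st Exon",
    "Other Exon",
    "1st Intron",
    "Other Intron",
    "Downstream (<=300bp)",
)


def _parse_bed12_blocks(row) -> tuple[np.ndarray, np.ndarray]:
    sizes = np.array([int(x) for x in str(row.block_sizes).rstrip(",").split(",")])
    offsets = np.array([int(x) for x in str(row.block_starts).rstrip(",").split(",")])
    starts = row.start + offsets
    return starts, starts + sizes


@dataclass
class GenomicFeatureSet:
    """Gene models with derived, labelled feature intervals.

    ``genes`` columns: gene_id, chrom, strand, start, end (transcript span,
    0-based half-open), exon_starts, exon_ends (lists), cds_start, cds_end
    (thick region; equal values mean no CDS, so no UTR labels are derived).
    """

    genes: pd.DataFrame
    promoter_span: int = 3000
    downstream_span: int = 300
    _trees: dict = field(default_factory=dict, repr=False)

    @classmethod
    def from_bed12(cls, path: str | Path, **kwargs) -> "GenomicFeatureSet":
        raw = pd.read_csv(path, sep="\t", header=None)
        raw.columns = [
            "chrom", "start", "end", "name", "score", "strand",
            "thick_start", "thick_end", "rgb", "block_count", "block_sizes", "block_starts",
        ][: raw.shape[1]]
        rows = []
        for row in raw.itertuples(index=False):
            ex_s, ex_e = _parse_bed12_blocks(row)
            rows.append(
                {
                    "gene_id": row.name,
                    "chrom": str(row.chrom),
                    "strand": row.strand,
                    "start": int(row.start),
                    "end": int(row.end),
                    "exon_starts": list(ex_s),
                    "exon_ends": list(ex_e),
                    "cds_start": int(row.thick_start),
                    "cds_end": int(row.thick_end),
                }
            )
        return cls(pd.DataFrame(rows), **kwargs)

    def to_bed12(self, path: str | Path) -> None:
        rows = []
        for g in self.genes.itertuples(index=False):
            sizes = ",".join(str(e - s) for s, e in zip(g.exon_starts, g.exon_ends))
            offs = ",".join(str(s - g.start) for s in g.exon_starts)
            rows.append(
                [g.chrom, g.start, g.end, g.gene_id, 0, g.strand,
                 g.cds_start, g.cds_end, 0, len(g.exon_starts), sizes, offs]
            )
        pd.DataFrame(rows).to_csv(path, sep="\t", header=False, index=False)

    # -- feature interval construction ------------------------------------
    def _build(self) -> None:
        trees: dict[str, dict[str, IntervalTree]] = {lab: {} for lab in _PRIORITY}

        def add(label: str, chrom: str, start: int, end: int, payload=None) -> None:
            if end > start:
                trees[label].setdefault(chrom, IntervalTree()).addi(start, end, payload)

        for g in self.genes.itertuples(index=False):
            fwd = g.strand == "+"
            tss = g.start if fwd else g.end
            if fwd:
                add("promoter", g.chrom, max(tss - self.promoter_span, 0), tss, (tss, "+"))
                add("Downstream (<=300bp)", g.chrom, g.end, g.end + self.downstream_span)
            else:
                add("promoter", g.chrom, tss, tss + self.promoter_span, (tss, "-"))
                add("Downstream (<=300bp)", g.chrom, max(g.start - self.downstream_span, 0), g.start)

            exons = sorted(zip(g.exon_starts, g.exon_ends))
            order = exons if fwd else exons[::-1]
            for i, (s, e) in enumerate(order):
                add("1st Exon" if i == 0 else "Other Exon", g.chrom, s, e)
            introns = [(e1, s2) for (_, e1), (s2, _) in zip(exons[:-1], exons[1:])]
            intron_order = introns if fwd else introns[::-1]
            for i, (s, e) in enumerate(intron_order):
                add("1st Intron" if i == 0 else "Other Intron", g.chrom, s, e)

            if g.cds_end > g.cds_start:  # UTRs: exonic sequence outside the CDS
                for s, e in exons:
                    left_s, left_e = s, min(e, g.cds_start)
                    right_s, right_e = max(s, g.cds_end), e
                    add("5' UTR" if fwd else "3' UTR", g.chrom, left_s, left_e)
                    add("3' UTR" if fwd else "5' UTR", g.chrom, right_s, right_e)
        self._trees = trees

    def _lookup_point(self, chrom: str, point: int) -> str:
        if not self._trees:
            self._build()
        prom = self._trees["promoter"].get(chrom)
        if prom is not None:
            hits = prom[point]
            if hits:
                best = min(
                    hits,
                    key=lambda iv: (iv.data[0] - point) if iv.data[1] == "+" else (point - iv.data[0] + 1),
                )
                tss, strand = best.data
                d = (tss - point) if strand == "+" else (point - tss + 1)
                if d <= 1000:
                    return "Promoter (<=1kb)"
                if d <= 2000:
                    return "Promoter (1-2kb)"
                return "Promoter (2-3kb)"
        for label in _PRIORITY[1:]:
            tree = self._trees[label].get(chrom)
            if tree is not None and tree[point]:
                return label
        return "Distal Intergenic"

    def _lookup_span(self, chrom: str, start: int, end: int) -> str:
        if not self._trees:
            self._build()
        prom = self._trees["promoter"].get(chrom)
        if prom is not None:
            hits = prom.overlap(start, end)
            if hits:
                mid = (start + end) // 2
                best = min(hits, key=lambda iv: abs(iv.data[0] - mid))
                tss, strand = best.data
                d = (tss - mid) if strand == "+" else (mid - tss + 1)
                d = max(min(d, self.promoter_span), 1)
                if d <= 1000:
                    return "Promoter (<=1kb)"
                if d <= 2000:
                    return "Promoter (1-2kb)"
                return "Promoter (2-3kb)"
        for label in _PRIORITY[1:]:
            tree = self._trees[label].get(chrom)
            if tree is not None and tree.overlap(start, end):
                return label
        return "Distal Intergenic"

    def annotate_region(self, chrom: str, start: int, end: int, method: str = "midpoint") -> str:
        """Single feature label for an interval.

        ``midpoint`` (default) classifies the interval midpoint; ``overlap``
        assigns the highest-priority feature the interval touches.
        """
        if method == "midpoint":
            return self._lookup_point(chrom, (start + end) // 2)
        if method == "overlap":
            return self._lookup_span(chrom, start, end)
        raise ValidationError(f"unknown assignment method {method!r}")

    def annotate_regions(self, regions: pd.DataFrame, method: str = "midpoint") -> pd.Series:
        labels = [
            self.annotate_region(r.chrom, r.start, r.end, method=method)
            for r in regions.itertuples(index=False)
        ]
        return pd.Series(labels, index=regions.index, name="feature")


def woolf_ci(a: float, b: float, c: float, d: float) -> float:
    """Half-width of the Woolf 95% CI for a log odds ratio."""
    return 1.96 * np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)


def log_odds_enrichment(
    regions: pd.DataFrame,
    background: pd.DataFrame,
    features: GenomicFeatureSet,
    method: str = "midpoint",
) -> pd.DataFrame:
    """Per-feature over/under-representation of a region set vs a background.

    For each feature label: ``a`` regions in the comparison set with that
    label, ``b`` without, ``c``/``d`` the same in the background.  The log
    odds ratio is ``ln((a*d)/(c*b))`` with a Haldane–Anscombe 0.5 added to
    every cell when any of b, c, d is zero; ``a = 0`` yields status ``n.d.``
    with no estimate.  Fisher's exact two-sided p is computed on the
    uncorrected table.
    """
    if len(background) == 0:
        raise ValidationError("empty background region set")
    lab_r = features.annotate_regions(regions, method=method) if len(regions) else pd.Series(dtype=object)
    lab_b = features.annotate_regions(background, method=method)
    n_r, n_b = len(regions), len(background)
    counts_r = lab_r.value_counts()
    counts_b = lab_b.value_counts()
    rows = []
    for label in FEATURE_LABELS:
        a = int(counts_r.get(label, 0))
        b = n_r - a
        c = int(counts_b.get(label, 0))
        d = n_b - c
        if a == 0:
            rows.append(
                dict(feature=label, a=a, b=b, c=c, d=d, log_odds=np.nan,
                     ci_low=np.nan, ci_high=np.nan, p=np.nan, status="n.d.")
            )
            continue
        if min(b, c, d) == 0:
            aa, bb, cc, dd = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        else:
            aa, bb, cc, dd = float(a), float(b), float(c), float(d)
        lo = float(np.log((aa * dd) / (cc * bb)))
        hw = woolf_ci(aa, bb, cc, dd)
        _, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
        rows.append(
            dict(feature=label, a=a, b=b, c=c, d=d, log_odds=lo,
                 ci_low=lo - hw, ci_high=lo + hw, p=float(p), status="ok")
        )
    return pd.DataFrame(rows)
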