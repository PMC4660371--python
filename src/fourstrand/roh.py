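"""Runs of homozygosity (ROH) in diploid genotype panels.

A sliding-window scan in the PLINK tradition: windows of ``window_snps``
consecutive SNPs are classed as homozygous if they contain at most
``max_het_per_window`` heterozygous calls; a SNP is "in a run" if more than
5% of the windows covering it are homozygous; maximal stretches of in-run
SNPs become candidate intervals, split at physical gaps larger than
``max_gap`` and filtered by SNP support and length.  Long runs (>= a few
Mb) indicate recent consanguinity; an abundance of short runs reflects
small ancestral population size.
"""
from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
import pandas as pd

from .genodata import DIPLOID, MISSING, GenotypePanel, validate_snp_table

WINDOW_HIT_FRACTION = 0.05


@dataclasses.dataclass(frozen=True)
class RohParams:
    """Detection and binning parameters (all lengths in bp)."""

    window_snps: int = 50
    max_het_per_window: int = 1
    min_snps: int = 25
    min_length: int = 500_000
    max_gap: int = 100_000
    short_long_boundary: int = 1_600_000
    consanguinity_boundary: int = 4_000_000

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            if getattr(self, f.name) <= 0:
                raise ValueError(f"{f.name} must be positive")
        if self.min_length > self.short_long_boundary:
            raise ValueError("min_length must not exceed the short/long boundary")


def _runs_for_chrom(
    geno: np.ndarray, pos: np.ndarray, params: RohParams
) -> list[tuple[int, int, int]]:
    """(start, end, n_snps) intervals for one sample on one chromosome."""
    n = len(geno)
    w = params.window_snps
    if n < w:
        return []
    het = (geno == 1).astype(np.int32)
    chet = np.concatenate([[0], np.cumsum(het)])
    win_het = chet[w:] - chet[:-w]  # windows starting at 0..n-w
    win_pass = (win_het <= params.max_het_per_window).astype(np.int32)
    cpass = np.concatenate([[0], np.cumsum(win_pass)])
    idx = np.arange(n)
    lo = np.maximum(idx - w + 1, 0)
    hi = np.minimum(idx, n - w)
    covering = hi - lo + 1
    passing = cpass[hi + 1] - cpass[lo]
    in_run = np.zeros(n, dtype=bool)
    valid = covering > 0
    in_run[valid] = passing[valid] / covering[valid] > WINDOW_HIT_FRACTION

    intervals = []
    i = 0
    while i < n:
        if not in_run[i]:
            i += 1
            continue
        j = i
        while j + 1 < n and in_run[j + 1]:
            j += 1
        # split at large physical gaps
        seg_start = i
        for k in range(i, j):
            if pos[k + 1] - pos[k] > params.max_gap:
                intervals.append((seg_start, k))
                seg_start = k + 1
        intervals.append((seg_start, j))
        i = j + 1

    out = []
    for s, e in intervals:
        n_snps = e - s + 1
        length = int(pos[e] - pos[s] + 1)
        if n_snps >= params.min_snps and length >= params.min_length:
            out.append((int(pos[s]), int(pos[e]), n_snps))
    return out


def detect_roh(
    panel: GenotypePanel,
    snps: pd.DataFrame,
    params: RohParams | None = None,
) -> pd.DataFrame:
    """Detect ROH per sample; returns a BED-like table.

    Columns: sample, chrom, start, end, n_snps, length.  All samples must
    be diploid — heterozygosity is undefined for pseudo-haploid calls, so
    low-coverage ancients need imputed diploid genotypes upstream.
    """
    if params is None:
        params = RohParams()
    validate_snp_table(snps)
    if (panel.samples["ploidy_mode"] != DIPLOID).any():
        raise ValueError("ROH detection requires diploid samples only")
    if len(snps) != panel.n_snps:
        raise ValueError("SNP table does not match panel")
    rows = []
    chrom_groups = snps.groupby("chrom", sort=False).indices
    for si in range(panel.n_samples):
        sample = panel.samples["id"].iloc[si]
        for chrom, cidx in chrom_groups.items():
            cidx = np.asarray(cidx)
            geno = panel.dosages[si, cidx]
            pos = snps["position"].to_numpy()[cidx]
            for start, end, n_snps in _runs_for_chrom(geno, pos, params):
                rows.append(
                    {
                        "sample": sample,
                        "chrom": chrom,
                        "start": start,
                        "end": end,
                        "n_snps": n_snps,
                        "length": end - start + 1,
                    }
                )
    return pd.DataFrame(
        rows, columns=["sample", "chrom", "start", "end", "n_snps", "length"]
    )


def roh_summary(
    intervals: pd.DataFrame,
    bins: Sequence[float] | None = None,
    short_long_boundary: int = 1_600_000,
) -> pd.DataFrame:
    """Per-sample total ROH length per length bin.

    ``bins`` are ascending bin edges in bp; interval lengths are assigned
    to half-open [lo, hi) bins, with the last bin open-ended.  Adds
    ``short`` (< boundary) and ``long`` (>= boundary) totals and a grand
    total, which equals the sum over bins by construction.
    """
    if bins is None:
        bins = [0, 500_000, 1_000_000, 1_600_000, 2_000_000, 4_000_000, 8_000_000]
    bins = list(bins)
    if bins != sorted(bins):
        raise ValueError("bins must be sorted ascending")
    edges = bins + [np.inf]
    labels = [
        f"[{int(edges[i])},{'inf' if np.isinf(edges[i+1]) else int(edges[i+1])})"
        for i in range(len(bins))
    ]
    samples = sorted(intervals["sample"].unique()) if len(intervals) else []
    rows = []
    for sample in samples:
        sub = intervals[intervals["sample"] == sample]
        lengths = sub["length"].to_numpy(dtype=float)
        row: dict[str, object] = {"sample": sample}
        for i, lab in enumerate(labels):
            sel = (lengths >= edges[i]) & (lengths < edges[i + 1])
            row[lab] = float(lengths[sel].sum())
        row["short"] = float(lengths[lengths < short_long_boundary].sum())
        row["long"] = float(lengths[lengths >= short_long_boundary].sum())
        row["total"] = float(lengths.sum())
        rows.append(row)
    return pd.DataFrame(rows, columns=["sample", *labels, "short", "long", "total"])
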