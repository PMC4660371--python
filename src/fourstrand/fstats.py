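"""f2, f3, f4 and D statistics with weighted block-jackknife errors.

Population allele frequencies are estimated by allele counting: a diploid
sample contributes its dosage out of 2 chromosomes, a pseudo-haploid sample
contributes dosage/2 out of a single chromosome (its two identical alleles
are one observation, so within-individual "heterozygosity" never enters).

The unbiased per-SNP terms are

    f2(A,B):  (pA - pB)^2 - hA/(nA - 1) - hB/(nB - 1)
    f3(C;A,B): (pC - pA)(pC - pB) - hC/(nC - 1)
    f4(W,X;Y,Z): (pW - pX)(pY - pZ)           (no correction needed)

with h = p(1 - p) the sample heterozygosity and n the chromosome count;
the corrections remove the sampling variance of the estimated frequencies
so that finite panels estimate the population-level drift quantities.
D is the f4 numerator normalized by (pW + pX - 2 pW pX)(pY + pZ - 2 pY pZ),
jackknifed as a ratio.  Standard errors come from a weighted delete-one
block jackknife over genetic-map blocks, with block weights equal to the
number of contributing SNPs; statistics with |Z| > 3 are conventionally
called significant.
"""
from __future__ import annotations

import dataclasses
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genodata import DIPLOID, MISSING, PSEUDO_HAPLOID, GenotypePanel
from .syndata import PopulationFrequencies


@dataclasses.dataclass
class FreqEstimate:
    """Per-(population, SNP) allele counts and frequency estimates.

    ``a[i, j]`` counts allele1 copies among ``n[i, j]`` observed
    chromosomes; ``n`` may be ``inf`` for exact population frequencies (the
    sampling-bias corrections then vanish).  ``pseudo_haploid`` flags
    populations containing any pseudo-haploid individuals.
    """

    populations: list[str]
    a: np.ndarray
    n: np.ndarray
    pseudo_haploid: dict[str, bool]

    def __post_init__(self) -> None:
        self.a = np.asarray(self.a, dtype=float)
        self.n = np.asarray(self.n, dtype=float)
        if self.a.shape != self.n.shape:
            raise ValueError("a and n must have the same shape")

    @property
    def n_snps(self) -> int:
        return self.a.shape[1]

    @property
    def phat(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(self.n > 0, self.a / np.where(self.n > 0, self.n, 1.0), np.nan)
        inf = np.isinf(self.n)
        if inf.any():
            p[inf] = self.a[inf]
        return p

    def index(self, pop: str) -> int:
        try:
            return self.populations.index(pop)
        except ValueError:
            raise KeyError(f"unknown population {pop!r}")


@dataclasses.dataclass(frozen=True)
class FStatResult:
    label: str
    estimate: float
    se: float
    z: float
    n_snps: int
    n_blocks: int

    def significant(self, threshold: float = 3.0) -> bool:
        return abs(self.z) > threshold

    def __str__(self) -> str:  # pragma: no cover
        return (
            f"{self.label}\t{self.estimate:.6g}\t{self.se:.3g}\tZ={self.z:.2f}"
            f"\t({self.n_snps} SNPs, {self.n_blocks} blocks)"
        )


# ---------------------------------------------------------------------------
# Frequency estimation
# ---------------------------------------------------------------------------

def pop_frequencies(
    panel: GenotypePanel,
    groups: Mapping[str, Sequence[str]] | None = None,
) -> FreqEstimate:
    """Count-based allele frequency estimates per analysis population.

    ``groups`` maps analysis population names to lists of panel population
    labels (default: every panel population is its own group).  Missing
    dosages are excluded per SNP.
    """
    if groups is None:
        groups = {p: [p] for p in panel.samples["population"].unique()}
    pops = list(groups)
    a = np.zeros((len(pops), panel.n_snps))
    n = np.zeros((len(pops), panel.n_snps))
    ph_flag: dict[str, bool] = {}
    pop_labels = panel.samples["population"].to_numpy()
    ploidy = panel.samples["ploidy_mode"].to_numpy()
    for gi, (gname, members) in enumerate(groups.items()):
        member_mask = np.isin(pop_labels, list(members))
        if not member_mask.any():
            raise ValueError(f"population group {gname!r} has no samples")
        ph_flag[gname] = bool((ploidy[member_mask] == PSEUDO_HAPLOID).any())
        for si in np.where(member_mask)[0]:
            dos = panel.dosages[si].astype(float)
            ok = dos >= 0
            if ploidy[si] == PSEUDO_HAPLOID:
                a[gi, ok] += dos[ok] / 2.0
                n[gi, ok] += 1.0
            else:
                a[gi, ok] += dos[ok]
                n[gi, ok] += 2.0
    return FreqEstimate(populations=pops, a=a, n=n, pseudo_haploid=ph_flag)


def from_frequencies(
    freqs: PopulationFrequencies, populations: Sequence[str] | None = None
) -> FreqEstimate:
    """Treat simulated population frequencies as exactly known (n = inf)."""
    pops = list(populations) if populations is not None else list(freqs.populations)
    mat = np.vstack([freqs.of(p) for p in pops])
    return FreqEstimate(
        populations=pops,
        a=mat,
        n=np.full_like(mat, np.inf),
        pseudo_haploid={p: False for p in pops},
    )


# ---------------------------------------------------------------------------
# Block jackknife
# ---------------------------------------------------------------------------

def block_jackknife(
    num: np.ndarray, den: np.ndarray, weights: np.ndarray
) -> tuple[float, float]:
    """Weighted delete-one-block jackknife for a ratio of block sums.

    ``num``/``den`` are per-block sums whose ratio of totals is the
    estimate; ``weights`` are block sizes (SNP counts).  Uses the weighted
    jackknife variance for unequal block sizes, which reduces to the
    textbook formula when blocks are equal.  Returns (estimate, SE).
    """
    num = np.asarray(num, dtype=float)
    den = np.asarray(den, dtype=float)
    weights = np.asarray(weights, dtype=float)
    keep = weights > 0
    num, den, weights = num[keep], den[keep], weights[keep]
    g = len(weights)
    if g < 2:
        raise ValueError("need at least 2 non-empty blocks for a jackknife SE")
    tot_n, tot_d, tot_w = num.sum(), den.sum(), weights.sum()
    if tot_d == 0:
        raise ValueError("zero denominator in jackknife estimate")
    theta = tot_n / tot_d
    loo_den = tot_d - den
    if (loo_den == 0).any():
        raise ValueError("zero denominator in a leave-one-out estimate")
    loo = (tot_n - num) / loo_den
    h = tot_w / weights
    theta_dot = g * theta - ((1.0 - weights / tot_w) * loo).sum()
    tau = h * theta - (h - 1.0) * loo
    var = np.sum((tau - theta_dot) ** 2 / (h - 1.0)) / g
    return float(theta), float(np.sqrt(var))


def _block_sums(values: np.ndarray, blocks: np.ndarray) -> np.ndarray:
    return np.bincount(blocks, weights=values)


def _jackknifed_mean(
    terms: np.ndarray, mask: np.ndarray, blocks: np.ndarray, label: str
) -> FStatResult:
    """Jackknife the mean of per-SNP terms over ``mask``-selected SNPs."""
    if not mask.any():
        raise ValueError(f"{label}: no SNPs with complete data")
    blocks = np.asarray(blocks)
    if blocks.shape[0] != terms.shape[0]:
        raise ValueError("block assignment does not match SNP count")
    use = np.where(mask, terms, 0.0)
    counts = _block_sums(mask.astype(float), blocks)
    sums = _block_sums(use, blocks)
    est, se = block_jackknife(sums, counts, counts)
    z = est / se if se > 0 else np.inf * np.sign(est) if est != 0 else 0.0
    return FStatResult(
        label=label, estimate=est, se=se, z=float(z),
        n_snps=int(mask.sum()), n_blocks=int((counts > 0).sum()),
    )


# ---------------------------------------------------------------------------
# Per-SNP machinery
# ---------------------------------------------------------------------------

def _het_correction(freqs: FreqEstimate, i: int) -> np.ndarray:
    """Unbiased per-SNP correction h/(n-1); zero when n is infinite."""
    p = freqs.phat[i]
    n = freqs.n[i]
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = p * (1 - p) / (n - 1.0)
    corr = np.where(np.isinf(n), 0.0, corr)
    return corr


def _require_n(freqs: FreqEstimate, pops_min2: Sequence[str], pops_min1: Sequence[str]):
    mask = np.ones(freqs.n_snps, dtype=bool)
    for p in pops_min2:
        mask &= freqs.n[freqs.index(p)] >= 2
    for p in pops_min1:
        mask &= freqs.n[freqs.index(p)] >= 1
    return mask


def f2_hat(
    freqs: FreqEstimate, a: str, b: str, blocks: np.ndarray
) -> FStatResult:
    """Bias-corrected f2 = E[(pA - pB)^2] with jackknife SE."""
    i, j = freqs.index(a), freqs.index(b)
    p = freqs.phat
    mask = _require_n(freqs, [a, b], [])
    terms = (p[i] - p[j]) ** 2 - _het_correction(freqs, i) - _het_correction(freqs, j)
    return _jackknifed_mean(np.nan_to_num(terms), mask, blocks, f"f2({a},{b})")


def f3_hat(
    freqs: FreqEstimate,
    c: str,
    a: str,
    b: str,
    blocks: np.ndarray,
    inbreed_mode: bool = False,
) -> FStatResult:
    """f3(C; A, B) = E[(pC - pA)(pC - pB)] with target-heterozygosity
    correction; significantly negative values indicate C is admixed
    between A- and B-related sources.

    When the target population contains pseudo-haploid individuals the
    correction cannot rely on within-individual heterozygosity; pass
    ``inbreed_mode=True`` to estimate the target's heterozygosity from
    allele counts across haploid chromosomes (pseudo-haploid individuals
    contribute one chromosome each).  Without the flag, pseudo-haploid
    targets are rejected.
    """
    i = freqs.index(c)
    if freqs.pseudo_haploid.get(c, False) and not inbreed_mode:
        raise ValueError(
            f"f3 target {c!r} contains pseudo-haploid samples; "
            "use inbreed_mode=True (haploid-count heterozygosity)"
        )
    if np.nanmax(freqs.n[i]) < 2:
        raise ValueError(
            f"f3 target {c!r} has fewer than 2 chromosomes; the heterozygosity "
            "correction is undefined — add samples or use the population as A/B"
        )
    j, k = freqs.index(a), freqs.index(b)
    p = freqs.phat
    mask = _require_n(freqs, [c], [a, b])
    terms = (p[i] - p[j]) * (p[i] - p[k]) - _het_correction(freqs, i)
    label = f"f3({c};{a},{b})"
    return _jackknifed_mean(np.nan_to_num(terms), mask, blocks, label)


def f4_hat(
    freqs: FreqEstimate, w: str, x: str, y: str, z: str, blocks: np.ndarray
) -> FStatResult:
    """f4(W, X; Y, Z) = E[(pW - pX)(pY - pZ)]; unbiased without correction."""
    iw, ix, iy, iz = (freqs.index(s) for s in (w, x, y, z))
    p = freqs.phat
    mask = _require_n(freqs, [], [w, x, y, z])
    terms = (p[iw] - p[ix]) * (p[iy] - p[iz])
    return _jackknifed_mean(np.nan_to_num(terms), mask, blocks, f"f4({w},{x};{y},{z})")


def d_stat(
    freqs: FreqEstimate, w: str, x: str, y: str, z: str, blocks: np.ndarray
) -> FStatResult:
    """Normalized f4 (ABBA-BABA D); jackknifed as a ratio of block sums."""
    iw, ix, iy, iz = (freqs.index(s) for s in (w, x, y, z))
    p = freqs.phat
    mask = _require_n(freqs, [], [w, x, y, z])
    if not mask.any():
        raise ValueError("D statistic: no SNPs with complete data")
    num = np.nan_to_num((p[iw] - p[ix]) * (p[iy] - p[iz]))
    den = np.nan_to_num(
        (p[iw] + p[ix] - 2 * p[iw] * p[ix]) * (p[iy] + p[iz] - 2 * p[iy] * p[iz])
    )
    num = np.where(mask, num, 0.0)
    den = np.where(mask, den, 0.0)
    blocks = np.asarray(blocks)
    counts = _block_sums(mask.astype(float), blocks)
    nsum = _block_sums(num, blocks)
    dsum = _block_sums(den, blocks)
    if dsum.sum() == 0:
        raise ValueError("D statistic: zero denominator")
    est, se = block_jackknife(nsum, dsum, counts)
    z_score = est / se if se > 0 else 0.0
    return FStatResult(
        label=f"D({w},{x};{y},{z})", estimate=est, se=se, z=float(z_score),
        n_snps=int(mask.sum()), n_blocks=int((counts > 0).sum()),
    )


def f4_ratio(
    freqs: FreqEstimate,
    outgroup: str,
    x: str,
    a: str,
    b: str,
    m: str,
    blocks: np.ndarray,
) -> tuple[float, float, FStatResult]:
    """Admixture proportion alpha from the f4-ratio.

    For a target M modeled as a mixture of A-related (proportion alpha) and
    B-related sources, with X a population attached on A's lineage,

        alpha = f4(O, X; B, M) / f4(O, X; B, A).

    Returns (alpha, jackknife SE, denominator f4 result); an unreliable
    denominator (|Z| < 3) raises a warning flag in the returned result's
    consumer — callers should check ``den.significant()``.
    """
    io, ix, ia, ib, im = (freqs.index(s) for s in (outgroup, x, a, b, m))
    p = freqs.phat
    mask = _require_n(freqs, [], [outgroup, x, a, b, m])
    if not mask.any():
        raise ValueError("f4-ratio: no SNPs with complete data")
    num = np.where(mask, np.nan_to_num((p[io] - p[ix]) * (p[ib] - p[im])), 0.0)
    den = np.where(mask, np.nan_to_num((p[io] - p[ix]) * (p[ib] - p[ia])), 0.0)
    blocks = np.asarray(blocks)
    counts = _block_sums(mask.astype(float), blocks)
    nsum = _block_sums(num, blocks)
    dsum = _block_sums(den, blocks)
    alpha, se = block_jackknife(nsum, dsum, counts)
    den_res = f4_hat(freqs, outgroup, x, b, a, blocks)
    return float(alpha), float(se), den_res


def diff_z(
    terms_a: np.ndarray,
    terms_b: np.ndarray,
    mask: np.ndarray,
    blocks: np.ndarray,
) -> tuple[float, float]:
    """Jackknifed difference of two per-SNP statistics on a joint mask."""
    diff = np.where(mask, terms_a - terms_b, 0.0)
    counts = _block_sums(mask.astype(float), np.asarray(blocks))
    sums = _block_sums(diff, np.asarray(blocks))
    return block_jackknife(sums, counts, counts)


def f3_terms(
    freqs: FreqEstimate, c: str, a: str, b: str
) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP corrected f3 terms and their complete-data mask."""
    i, j, k = freqs.index(c), freqs.index(a), freqs.index(b)
    p = freqs.phat
    mask = _require_n(freqs, [c], [a, b])
    terms = (p[i] - p[j]) * (p[i] - p[k]) - _het_correction(freqs, i)
    return np.nan_to_num(terms), mask
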