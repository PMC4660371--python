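"""Genotype panels: EIGENSTRAT I/O, pseudo-haploid calling, merging, LD
pruning, jackknife block assignment and molecular sexing.

The in-memory containers are deliberately small:

* a SNP table is a :class:`pandas.DataFrame` with columns
  ``snp_id, chrom, position, genetic_pos, allele1, allele2`` — physical
  position in bp (1-based), genetic position in cM, sorted by
  (chrom, position) and strictly biallelic;
* a :class:`GenotypePanel` holds a samples-by-SNPs dosage matrix counting
  copies of ``allele1`` (0/1/2, ``-1`` for missing) plus per-sample
  metadata (id, population, ploidy mode, sex).

Pseudo-haploid samples — low-coverage ancient individuals represented by a
single randomly sampled allele duplicated into a homozygous genotype —
carry only dosages 0 and 2 (or missing).
"""
from __future__ import annotations

import dataclasses
import math
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

SNP_COLUMNS = ["snp_id", "chrom", "position", "genetic_pos", "allele1", "allele2"]

DIPLOID = "diploid"
PSEUDO_HAPLOID = "pseudo-haploid"

_ALLELE_CYCLE = [("A", "G"), ("C", "T"), ("A", "C"), ("G", "T"), ("A", "T"), ("C", "G")]


class EigenstratParseError(ValueError):
    """Raised when a geno/snp/ind triplet is malformed."""


def make_snp_table(
    n_snps: int,
    n_chromosomes: int = 30,
    chrom_length_mb: float = 100.0,
    cm_per_mb: float = 1.0,
    chrom_offset: int = 0,
) -> pd.DataFrame:
    """Evenly spaced autosomal SNPs on a uniform genetic map.

    SNPs are distributed as evenly as possible over ``n_chromosomes``
    chromosomes of ``chrom_length_mb`` Mb each; the genetic position is
    physical position times ``cm_per_mb`` (default 1 cM/Mb).
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if n_chromosomes < 2 and n_snps > 1:
        raise ValueError("need at least 2 chromosomes for jackknife blocks")
    n_chromosomes = min(n_chromosomes, n_snps) if n_snps > 1 else 1
    base = n_snps // n_chromosomes
    extra = n_snps % n_chromosomes
    rows = []
    length_bp = int(chrom_length_mb * 1e6)
    idx = 0
    for c in range(n_chromosomes):
        k = base + (1 if c < extra else 0)
        if k == 0:
            continue
        spacing = length_bp / (k + 1)
        for j in range(k):
            pos = int(round((j + 1) * spacing))
            a1, a2 = _ALLELE_CYCLE[idx % len(_ALLELE_CYCLE)]
            rows.append(
                (f"snp{idx}", str(c + 1 + chrom_offset), pos, pos / 1e6 * cm_per_mb, a1, a2)
            )
            idx += 1
    return pd.DataFrame(rows, columns=SNP_COLUMNS)


def validate_snp_table(snps: pd.DataFrame) -> None:
    missing = [c for c in SNP_COLUMNS if c not in snps.columns]
    if missing:
        raise ValueError(f"SNP table missing columns: {missing}")
    if snps["snp_id"].duplicated().any():
        raise ValueError("duplicate SNP ids")


@dataclasses.dataclass
class GenotypePanel:
    """Dosage matrix (samples x SNPs) with per-sample metadata.

    ``dosages[i, j]`` counts copies of ``allele1`` at SNP j in sample i;
    ``MISSING`` (-1) marks no-calls.  ``samples`` has columns
    ``id, population, ploidy_mode, sex``.
    """

    dosages: np.ndarray
    samples: pd.DataFrame

    def __post_init__(self) -> None:
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        if self.dosages.ndim != 2:
            raise ValueError("dosages must be 2-D (samples x SNPs)")
        if len(self.samples) != self.dosages.shape[0]:
            raise ValueError("sample metadata does not match dosage rows")
        for col in ("id", "population", "ploidy_mode"):
            if col not in self.samples.columns:
                raise ValueError(f"samples table missing column {col!r}")
        if "sex" not in self.samples.columns:
            self.samples = self.samples.assign(sex="U")
        self.samples = self.samples.reset_index(drop=True)
        ph = (self.samples["ploidy_mode"] == PSEUDO_HAPLOID).to_numpy()
        if ph.any() and (self.dosages[ph] == 1).any():
            raise ValueError("pseudo-haploid samples cannot carry heterozygous dosages")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def subset_snps(self, index: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(self.dosages[:, index], self.samples.copy())

    def subset_samples(self, mask: np.ndarray) -> "GenotypePanel":
        return GenotypePanel(self.dosages[mask], self.samples.loc[np.asarray(mask)].copy())


def concat_panels(a: GenotypePanel, b: GenotypePanel) -> GenotypePanel:
    if a.n_snps != b.n_snps:
        raise ValueError("panels have different SNP counts")
    return GenotypePanel(
        np.vstack([a.dosages, b.dosages]),
        pd.concat([a.samples, b.samples], ignore_index=True),
    )


# ---------------------------------------------------------------------------
# EIGENSTRAT I/O
# ---------------------------------------------------------------------------

def write_eigenstrat(panel: GenotypePanel, snps: pd.DataFrame, prefix: str) -> None:
    """Write geno/snp/ind files. Genetic positions are stored in Morgans."""
    validate_snp_table(snps)
    if len(snps) != panel.n_snps:
        raise ValueError("SNP table does not match panel")
    geno = panel.dosages.T.astype(np.int16)  # SNPs x samples
    chars = np.where(geno == MISSING, 9, geno).astype("U1")
    with open(f"{prefix}.geno", "w") as fh:
        for row in chars:
            fh.write("".join(row) + "\n")
    with open(f"{prefix}.snp", "w") as fh:
        for r in snps.itertuples(index=False):
            fh.write(
                f"{r.snp_id}\t{r.chrom}\t{r.genetic_pos / 100.0:.8f}\t"
                f"{int(r.position)}\t{r.allele1}\t{r.allele2}\n"
            )
    with open(f"{prefix}.ind", "w") as fh:
        for r in panel.samples.itertuples(index=False):
            ploidy_tag = "PH" if r.ploidy_mode == PSEUDO_HAPLOID else "DIP"
            fh.write(f"{r.id}\t{r.sex}\t{r.population}:{ploidy_tag}\n")


def read_eigenstrat(prefix: str) -> tuple[GenotypePanel, pd.DataFrame]:
    """Read a geno/snp/ind triplet written by :func:`write_eigenstrat`.

    Plain EIGENSTRAT files (population labels without the ``:PH``/``:DIP``
    ploidy tag) are read as diploid.
    """
    snp_rows = []
    with open(f"{prefix}.snp") as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6:
                raise EigenstratParseError(f"{prefix}.snp line {ln}: expected 6 fields")
            snp_rows.append(
                (parts[0], parts[1], int(parts[3]), float(parts[2]) * 100.0, parts[4], parts[5])
            )
    snps = pd.DataFrame(snp_rows, columns=SNP_COLUMNS)

    ind_rows = []
    with open(f"{prefix}.ind") as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 3:
                raise EigenstratParseError(f"{prefix}.ind line {ln}: expected 3 fields")
            pop = parts[2]
            ploidy = DIPLOID
            if pop.endswith(":PH"):
                pop, ploidy = pop[:-3], PSEUDO_HAPLOID
            elif pop.endswith(":DIP"):
                pop = pop[:-4]
            ind_rows.append((parts[0], pop, ploidy, parts[1]))
    samples = pd.DataFrame(ind_rows, columns=["id", "population", "ploidy_mode", "sex"])

    geno = np.empty((len(snps), len(samples)), dtype=np.int8)
    with open(f"{prefix}.geno") as fh:
        ln = 0
        for ln, line in enumerate(fh, 1):
            row = line.strip()
            if len(row) != len(samples):
                raise EigenstratParseError(
                    f"{prefix}.geno line {ln}: {len(row)} characters, expected {len(samples)}"
                )
            if ln > len(snps):
                raise EigenstratParseError(f"{prefix}.geno: more lines than SNPs")
            try:
                vals = np.frombuffer(row.encode(), dtype=np.uint8) - ord("0")
            except ValueError as exc:  # pragma: no cover
                raise EigenstratParseError(f"{prefix}.geno line {ln}: {exc}")
            if not np.isin(vals, (0, 1, 2, 9)).all():
                raise EigenstratParseError(
                    f"{prefix}.geno line {ln}: character outside {{0,1,2,9}}"
                )
            geno[ln - 1] = np.where(vals == 9, MISSING, vals)
        if ln != len(snps):
            raise EigenstratParseError(f"{prefix}.geno: {ln} lines, expected {len(snps)}")
    return GenotypePanel(geno.T, samples), snps


# ---------------------------------------------------------------------------
# Pseudo-haploid calling
# ---------------------------------------------------------------------------

def pseudo_haploid_call(
    pileup: pd.DataFrame,
    snps: pd.DataFrame,
    seed: int,
    sample_id: str = "ancient1",
    population: str = "ancient",
) -> GenotypePanel:
    """Call one pseudo-haploid sample from per-SNP base counts.

    At each SNP one base is drawn with probability equal to its frequency
    among the observed bases and duplicated into a homozygous genotype.
    Sites where any observed base falls outside the SNP's two panel alleles
    (effectively triallelic) are discarded, as are zero-depth sites.
    """
    validate_snp_table(snps)
    rng = np.random.default_rng(seed)
    counts = pileup.set_index("snp_id")[["countA", "countC", "countG", "countT"]]
    if (counts.to_numpy() < 0).any():
        raise ValueError("negative base counts in pileup")
    aligned = counts.reindex(snps["snp_id"]).fillna(0).to_numpy(dtype=float)
    base_index = {"A": 0, "C": 1, "G": 2, "T": 3}
    i1 = snps["allele1"].map(base_index).to_numpy()
    i2 = snps["allele2"].map(base_index).to_numpy()
    rows = np.arange(len(snps))
    c1 = aligned[rows, i1]
    c2 = aligned[rows, i2]
    total = aligned.sum(axis=1)
    off_target = total - c1 - c2 > 0
    depth0 = total == 0
    dosage = np.full(len(snps), MISSING, dtype=np.int8)
    ok = ~(off_target | depth0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p1 = np.where(ok, c1 / np.maximum(c1 + c2, 1), 0.0)
    draw = rng.random(len(snps)) < p1
    dosage[ok] = np.where(draw[ok], 2, 0)
    samples = pd.DataFrame(
        {"id": [sample_id], "population": [population], "ploidy_mode": [PSEUDO_HAPLOID],
         "sex": ["U"]}
    )
    return GenotypePanel(dosage[None, :], samples)


# ---------------------------------------------------------------------------
# Merging ancient and modern panels
# ---------------------------------------------------------------------------

def _is_autosomal(chrom: str) -> bool:
    try:
        return 1 <= int(chrom) <= 22
    except ValueError:
        return False


def merge_panels(
    ancient: GenotypePanel,
    ancient_snps: pd.DataFrame,
    modern: GenotypePanel,
    modern_snps: pd.DataFrame,
    min_pop_size: int = 4,
) -> tuple[GenotypePanel, pd.DataFrame, dict]:
    """Merge an ancient panel onto a modern reference panel.

    Filters, in order: intersect SNP ids; drop non-autosomal SNPs; drop
    modern populations with fewer than ``min_pop_size`` individuals; drop
    SNPs with minor allele frequency zero across the retained modern
    samples; drop SNPs whose ancient alleles do not match the modern allele
    pair (no strand flipping is attempted — ambiguous sites are removed,
    allele order swaps are recoded).  Returns the merged panel on the
    modern allele coding plus a per-filter removal report.
    """
    validate_snp_table(ancient_snps)
    validate_snp_table(modern_snps)
    report: dict[str, object] = {}

    shared = modern_snps[modern_snps["snp_id"].isin(set(ancient_snps["snp_id"]))]
    if shared.empty:
        raise ValueError("no overlapping SNPs between panels")
    report["shared_snps"] = int(len(shared))

    autosomal = shared[shared["chrom"].map(_is_autosomal)]
    report["non_autosomal_removed"] = int(len(shared) - len(autosomal))

    pop_sizes = modern.samples["population"].value_counts()
    keep_pops = set(pop_sizes[pop_sizes >= min_pop_size].index)
    dropped_pops = sorted(set(pop_sizes.index) - keep_pops)
    report["small_modern_pops_removed"] = dropped_pops
    sample_mask = modern.samples["population"].isin(keep_pops).to_numpy()
    if not sample_mask.any():
        raise ValueError("no modern populations pass the size filter")
    modern_kept = modern.subset_samples(sample_mask)

    mod_idx = autosomal.index.to_numpy()
    mdos = modern_kept.dosages[:, mod_idx].astype(float)
    mdos[mdos == MISSING] = np.nan
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(mdos, axis=0) / 2.0
    polymorphic = (freq > 0) & (freq < 1)
    report["maf_zero_removed"] = int((~polymorphic).sum())
    autosomal = autosomal[polymorphic]
    mod_idx = mod_idx[polymorphic]

    anc_lookup = ancient_snps.set_index("snp_id")
    anc_rows = anc_lookup.loc[autosomal["snp_id"]]
    same = (anc_rows["allele1"].to_numpy() == autosomal["allele1"].to_numpy()) & (
        anc_rows["allele2"].to_numpy() == autosomal["allele2"].to_numpy()
    )
    swapped = (anc_rows["allele1"].to_numpy() == autosomal["allele2"].to_numpy()) & (
        anc_rows["allele2"].to_numpy() == autosomal["allele1"].to_numpy()
    )
    compatible = same | swapped
    report["allele_mismatch_removed"] = int((~compatible).sum())
    autosomal = autosomal[compatible]
    mod_idx = mod_idx[compatible]
    same = same[compatible]

    anc_pos = {sid: i for i, sid in enumerate(ancient_snps["snp_id"])}
    anc_idx = np.array([anc_pos[s] for s in autosomal["snp_id"]], dtype=int)
    anc_dos = ancient.dosages[:, anc_idx].astype(np.int8)
    flip = ~same
    flipped = anc_dos[:, flip]
    flipped = np.where(flipped == MISSING, MISSING, 2 - flipped)
    anc_dos[:, flip] = flipped

    merged_dos = np.vstack([anc_dos, modern_kept.dosages[:, mod_idx]])
    merged_samples = pd.concat([ancient.samples, modern_kept.samples], ignore_index=True)
    merged_snps = autosomal.reset_index(drop=True)
    report["final_snps"] = int(len(merged_snps))
    report["final_samples"] = int(len(merged_samples))
    if merged_snps.empty:
        raise ValueError("no SNPs survive merging filters")
    return GenotypePanel(merged_dos, merged_samples), merged_snps, report


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------

def _pairwise_r2(dos: np.ndarray) -> np.ndarray:
    """Squared Pearson correlation over pairwise-complete samples.

    ``dos`` is SNPs x samples with MISSING for no-calls. Pairs with fewer
    than 2 complete observations or zero variance get r^2 = 0.
    """
    X = dos.astype(float)
    M = (dos != MISSING).astype(float)
    X = X * M
    n = M @ M.T
    sx = X @ M.T
    sxx = (X * X) @ M.T
    sxy = X @ X.T
    with np.errstate(invalid="ignore", divide="ignore"):
        cov = n * sxy - sx * sx.T
        varx = n * sxx - sx**2
        denom = varx * varx.T
        r2 = np.where((denom > 0) & (n >= 2), cov**2 / np.where(denom > 0, denom, 1.0), 0.0)
    np.fill_diagonal(r2, 0.0)
    return r2


def ld_prune(
    panel: GenotypePanel,
    snps: pd.DataFrame,
    window: int = 200,
    step: int = 25,
    r2_threshold: float = 0.5,
) -> list[str]:
    """Windowed greedy LD pruning (indep-pairwise style).

    Slides a window of ``window`` SNPs advanced by ``step``; within each
    window, while any pair of retained SNPs exceeds ``r2_threshold``, the
    member of the worst pair with the lower minor allele frequency is
    removed (ties: the later physical position).  Returns kept SNP ids in
    table order; the result is deterministic and sample-order invariant.
    """
    if not (window > step > 0):
        raise ValueError("require window > step > 0")
    if not (0 < r2_threshold <= 1):
        raise ValueError("r2_threshold must be in (0, 1]")
    validate_snp_table(snps)
    n = panel.n_snps
    keep = np.ones(n, dtype=bool)
    dosT = panel.dosages.T  # SNPs x samples
    dd = dosT.astype(float)
    dd[dosT == MISSING] = np.nan
    with np.errstate(invalid="ignore"):
        freq = np.nanmean(dd, axis=1) / 2.0
    maf = np.minimum(freq, 1 - freq)
    maf = np.where(np.isnan(maf), 0.0, maf)
    pos = snps["position"].to_numpy()

    # prune within chromosomes only
    for _, chrom_idx in snps.groupby("chrom", sort=False).indices.items():
        idx = np.asarray(chrom_idx)
        start = 0
        while True:
            win = idx[start : start + window]
            active = win[keep[win]]
            if len(active) >= 2:
                r2 = _pairwise_r2(dosT[active])
                local_alive = np.ones(len(active), dtype=bool)
                while True:
                    sub = r2[np.ix_(local_alive, local_alive)]
                    if sub.size == 0 or sub.max() <= r2_threshold:
                        break
                    a_idx = np.where(local_alive)[0]
                    i, j = np.unravel_index(np.argmax(sub), sub.shape)
                    gi, gj = active[a_idx[i]], active[a_idx[j]]
                    if maf[gi] < maf[gj]:
                        drop = gi
                    elif maf[gj] < maf[gi]:
                        drop = gj
                    else:
                        drop = gi if pos[gi] > pos[gj] else gj
                    keep[drop] = False
                    local_alive[a_idx[i] if drop == gi else a_idx[j]] = False
            if start + window >= len(idx):
                break
            start += step
    return snps.loc[keep, "snp_id"].tolist()


PRUNE_PROFILES = {
    "pca": dict(window=200, step=25, r2_threshold=0.2),
    "admixture": dict(window=200, step=25, r2_threshold=0.5),
}


def prune_profile(panel: GenotypePanel, snps: pd.DataFrame, profile: str) -> list[str]:
    """LD-prune with a named parameter profile ('pca' or 'admixture')."""
    try:
        params = PRUNE_PROFILES[profile]
    except KeyError:
        raise ValueError(
            f"unknown prune profile {profile!r}; available: {sorted(PRUNE_PROFILES)}"
        )
    return ld_prune(panel, snps, **params)


# ---------------------------------------------------------------------------
# Jackknife blocks
# ---------------------------------------------------------------------------

def assign_blocks(snps: pd.DataFrame, block_cm: float = 5.0) -> np.ndarray:
    """Assign each SNP to a half-open genetic-distance block.

    Blocks are windows [k*block_cm, (k+1)*block_cm) in absolute genetic
    position, restarting at every chromosome; block ids are sequential
    integers in table order.
    """
    validate_snp_table(snps)
    g = snps["genetic_pos"].to_numpy(dtype=float)
    if np.isnan(g).any():
        raise ValueError("genetic positions missing; cannot assign blocks")
    if block_cm <= 0:
        raise ValueError("block_cm must be positive")
    k = np.floor(g / block_cm).astype(np.int64)
    key = pd.MultiIndex.from_arrays([snps["chrom"], k])
    codes, _ = pd.factorize(key, sort=False)
    return codes.astype(np.int64)


# ---------------------------------------------------------------------------
# Molecular sex
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class SexCall:
    n_y: int
    n_xy: int
    ry: float
    ci95: tuple[float, float]
    call: str


def determine_sex(
    n_y: int,
    n_x: int,
    xx_threshold: float = 0.016,
    xy_threshold: float = 0.075,
) -> SexCall:
    """Sex from the fraction of sex-chromosome reads aligning to Y.

    R_y = n_Y / (n_X + n_Y) with a normal-approximation 95% CI; the call is
    XX when the interval lies entirely below ``xx_threshold``, XY when
    entirely above ``xy_threshold``, else indeterminate.
    """
    total = n_x + n_y
    if total <= 0:
        raise ValueError("no reads on sex chromosomes")
    if n_x < 0 or n_y < 0:
        raise ValueError("read counts must be non-negative")
    ry = n_y / total
    se = math.sqrt(ry * (1 - ry) / total)
    lo, hi = max(0.0, ry - 1.96 * se), min(1.0, ry + 1.96 * se)
    if hi < xx_threshold:
        call = "XX"
    elif lo > xy_threshold:
        call = "XY"
    else:
        call = "indeterminate"
    return SexCall(n_y=n_y, n_xy=total, ry=ry, ci95=(lo, hi), call=call)
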