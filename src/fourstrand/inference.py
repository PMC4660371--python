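"""Decision procedures built on f-statistics: three-topology outgroup-f3
tests, clade D-tests, outgroup-f3 affinity ranking, admixture-f3 source
scans, and method-of-moments split-time fitting.

The split-time fitter replaces a full coalescent MCMC with deterministic
least squares: observed f-statistics (with jackknife SEs) are matched
against the exact drift-moment expectations of a fixed-topology model
whose free node times are optimized.  Identifiability requires Ne and the
generation time to be fixed externally — drift only measures t / (2 Ne g).
"""
from __future__ import annotations

import dataclasses
import itertools
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from . import fstats, syndata
from .fstats import FreqEstimate, FStatResult
from .syndata import DemographyModel

Z_THRESHOLD = 3.0


# ---------------------------------------------------------------------------
# Result containers
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class TopologyVerdict:
    """Outcome of the three-topology outgroup-f3 comparison.

    ``winner`` is the pair forming the best-supported clade (the pair with
    the largest shared drift relative to the outgroup); ``decisive`` when
    every pairwise difference of f3 values between the winner and the
    alternatives exceeds |Z| > 3.
    """

    results: dict[tuple[str, str], FStatResult]
    winner: tuple[str, str]
    outsider: str
    difference_z: dict[tuple[str, str], float]
    decisive: bool

    def summary(self) -> pd.DataFrame:
        rows = [
            {
                "clade": f"({a},{b})",
                "f3": r.estimate,
                "se": r.se,
                "z": r.z,
                "winner": (a, b) == self.winner,
            }
            for (a, b), r in self.results.items()
        ]
        return pd.DataFrame(rows).sort_values("f3", ascending=False, ignore_index=True)


@dataclasses.dataclass
class ScanResult:
    """Ranked statistic table from a scan (admixture, clade or affinity)."""

    table: pd.DataFrame
    kind: str

    def significant(self) -> pd.DataFrame:
        return self.table[self.table["significant"]]


@dataclasses.dataclass
class SplitFit:
    """Fitted node times (years) from the moments-based least squares."""

    times: dict[str, float]
    residual: float
    n_obs: int
    free: list[str]
    ne: float
    gen_time: float
    identifiable: bool


@dataclasses.dataclass(frozen=True)
class ObservedStat:
    kind: str  # "f2" | "f3" | "f4"
    pops: tuple[str, ...]
    value: float
    se: float


# ---------------------------------------------------------------------------
# Topology test
# ---------------------------------------------------------------------------

def topology_test(
    freqs: FreqEstimate,
    p1: str,
    p2: str,
    p3: str,
    outgroup: str,
    blocks: np.ndarray,
) -> TopologyVerdict:
    """Which pair of three populations forms a clade against an outgroup?

    Computes the outgroup f3(outgroup; Pi, Pj) for the three pairs; the
    correct topology shows the largest shared drift between the two clade
    members.  Decisiveness requires the winner to beat both alternatives
    with a difference Z-score above 3 (difference jackknifed per SNP on the
    joint complete-data mask).
    """
    trio = (p1, p2, p3)
    if len(set(trio)) != 3:
        raise ValueError("populations P1, P2, P3 must be distinct")
    if outgroup in trio:
        raise ValueError("outgroup must not be one of the tested populations")
    pairs = [(p1, p2), (p1, p3), (p2, p3)]
    results = {
        pair: fstats.f3_hat(freqs, outgroup, pair[0], pair[1], blocks) for pair in pairs
    }
    winner = max(results, key=lambda k: results[k].estimate)
    outsider = next(p for p in trio if p not in winner)
    term_cache = {pair: fstats.f3_terms(freqs, outgroup, *pair) for pair in pairs}
    diff_zs: dict[tuple[str, str], float] = {}
    for pair in pairs:
        if pair == winner:
            continue
        ta, ma = term_cache[winner]
        tb, mb = term_cache[pair]
        est, se = fstats.diff_z(ta, tb, ma & mb, blocks)
        diff_zs[pair] = est / se if se > 0 else np.inf
    decisive = all(z > Z_THRESHOLD for z in diff_zs.values())
    return TopologyVerdict(
        results=results,
        winner=winner,
        outsider=outsider,
        difference_z=diff_zs,
        decisive=decisive,
    )


# ---------------------------------------------------------------------------
# Clade test
# ---------------------------------------------------------------------------

def clade_test(
    freqs: FreqEstimate,
    outgroup: str,
    probe_set: Sequence[str],
    a: str,
    b: str,
    blocks: np.ndarray,
) -> ScanResult:
    """Do A and B form a clade to the exclusion of every probe?

    Computes D(outgroup, probe; A, B) for each probe; a significant
    deviation (|Z| > 3) for some probe means that probe shares excess
    alleles with one clade member, rejecting treeness.
    """
    if not probe_set:
        raise ValueError("probe set must be non-empty")
    if outgroup in probe_set or outgroup in (a, b) or {a, b} & set(probe_set):
        raise ValueError("outgroup, probes and the clade pair must be distinct")
    rows = []
    for probe in probe_set:
        r = fstats.d_stat(freqs, outgroup, probe, a, b, blocks)
        rows.append(
            {
                "probe": probe,
                "statistic": r.estimate,
                "se": r.se,
                "z": r.z,
                "significant": abs(r.z) > Z_THRESHOLD,
                "n_snps": r.n_snps,
            }
        )
    table = pd.DataFrame(rows).sort_values("z", key=np.abs, ascending=False,
                                           ignore_index=True)
    return ScanResult(table=table, kind="clade")


def clade_supported(result: ScanResult) -> bool:
    return not result.table["significant"].any()


# ---------------------------------------------------------------------------
# Affinity ranking
# ---------------------------------------------------------------------------

def affinity_rank(
    freqs: FreqEstimate,
    ancient: str,
    moderns: Sequence[str],
    outgroup: str,
    blocks: np.ndarray,
) -> ScanResult:
    """Rank modern populations by shared drift with an ancient sample.

    Outgroup f3(outgroup; modern, ancient) measures the genetic history
    shared between the pair since their divergence from the outgroup;
    larger values mean closer affinity, so rows are ranked descending.
    """
    if not moderns:
        raise ValueError("need at least one modern population")
    rows = []
    for modern in moderns:
        r = fstats.f3_hat(freqs, outgroup, modern, ancient, blocks)
        rows.append(
            {
                "modern": modern,
                "statistic": r.estimate,
                "se": r.se,
                "z": r.z,
                "significant": abs(r.z) > Z_THRESHOLD,
                "n_snps": r.n_snps,
            }
        )
    table = pd.DataFrame(rows).sort_values("statistic", ascending=False,
                                           ignore_index=True)
    return ScanResult(table=table, kind="affinity")


# ---------------------------------------------------------------------------
# Admixture scan
# ---------------------------------------------------------------------------

def admixture_scan(
    freqs: FreqEstimate,
    target: str,
    candidates: Sequence[str],
    blocks: np.ndarray,
) -> ScanResult:
    """Scan source pairs for admixture into a target via f3(X, Y; target).

    A significantly negative f3 (Z < -3) means the target's allele
    frequencies are intermediate between X and Y beyond what drift allows —
    evidence of admixture; the most negative pair is the most likely
    source combination.  Uses haploid-count heterozygosity for
    pseudo-haploid targets.
    """
    candidates = list(candidates)
    if len(candidates) < 2:
        raise ValueError("need at least 2 candidate source populations")
    if target in candidates:
        raise ValueError("target must not be among the candidates")
    inbreed = freqs.pseudo_haploid.get(target, False)
    rows = []
    for x, y in itertools.combinations(candidates, 2):
        r = fstats.f3_hat(freqs, target, x, y, blocks, inbreed_mode=inbreed)
        rows.append(
            {
                "source_a": x,
                "source_b": y,
                "statistic": r.estimate,
                "se": r.se,
                "z": r.z,
                "significant": r.z < -Z_THRESHOLD,
                "n_snps": r.n_snps,
            }
        )
    table = pd.DataFrame(rows).sort_values("statistic", ignore_index=True)
    return ScanResult(table=table, kind="admixture")


# ---------------------------------------------------------------------------
# Split-time fitting
# ---------------------------------------------------------------------------

def observed_f2_suite(
    freqs: FreqEstimate, pops: Sequence[str], blocks: np.ndarray
) -> list[ObservedStat]:
    """All pairwise bias-corrected f2 statistics among ``pops``."""
    out = []
    for a, b in itertools.combinations(pops, 2):
        r = fstats.f2_hat(freqs, a, b, blocks)
        out.append(ObservedStat("f2", (a, b), r.estimate, r.se))
    return out


def fit_split_times(
    observed: Sequence[ObservedStat],
    template: DemographyModel,
    ne: float,
    gen_time: float,
    free_times: Sequence[str],
    x0: Mapping[str, float] | None = None,
) -> SplitFit:
    """Least-squares node times from observed f-statistics.

    Minimizes sum_i [(obs_i - expected_i(t)) / SE_i]^2 over the free node
    times, where expectations come from the exact drift-moment engine with
    branch durations converted to drift using the supplied Ne and
    generation time.  Times are bounded below by zero; parent-before-child
    ordering is enforced with a penalty (violating configurations clamp the
    branch duration at zero and are pushed back).  Flags the fit as
    non-identifiable when the objective is locally flat in some parameter.
    """
    observed = list(observed)
    free_times = list(free_times)
    if template.node_times is None:
        raise ValueError("template model must carry node_times")
    unknown = set(free_times) - set(template.node_times)
    if unknown:
        raise ValueError(f"free parameters not in template node times: {sorted(unknown)}")
    if len(observed) < len(free_times):
        raise ValueError(
            f"{len(free_times)} free parameters but only {len(observed)} observed "
            "statistics; the fit is under-determined"
        )
    work = template.with_node_times({})
    work.Ne = ne
    work.gen_time = gen_time

    parent = work.parent_of()

    def residuals(x: np.ndarray) -> np.ndarray:
        times = dict(zip(free_times, x))
        m = work.with_node_times(times)
        table = syndata.expected_f_moments(m)
        res = [
            (obs.value - table.expected(obs.kind, obs.pops)) / max(obs.se, 1e-12)
            for obs in observed
        ]
        # ordering penalty: child older than parent
        for e in work.edges:
            tp = m.node_times.get(e.parent, 0.0)
            tc = m.node_times.get(e.child, 0.0)
            if tc > tp:
                res.append((tc - tp) / 1000.0)
        return np.asarray(res)

    if x0 is None:
        # deterministic topology-aware start: root-most free node high, each
        # child a fraction of its parent, independent of the template's values
        depth: dict[str, int] = {work.root(): 0}
        for n in work.topological_order():
            if n in depth:
                continue
            if n in parent:
                depth[n] = depth[parent[n].parent] + 1
            else:  # admixture target
                adm = next(a for a in work.admixture if a.target == n)
                depth[n] = max(depth[adm.source_a], depth[adm.source_b]) + 1
        start = np.array([80_000.0 * (0.65 ** depth.get(n, 1)) for n in free_times])
    else:
        start = np.array([float(x0[n]) for n in free_times])

    fit = optimize.least_squares(
        residuals,
        start,
        bounds=(0.0, 300_000.0),
        x_scale=np.maximum(start, 1_000.0),
        xtol=1e-10,
        ftol=1e-12,
        gtol=1e-12,
    )
    times = dict(zip(free_times, (float(v) for v in fit.x)))
    # identifiability probe: relative objective change under 5% parameter nudge
    f_at = 0.5 * np.sum(residuals(fit.x) ** 2)
    identifiable = True
    for i in range(len(free_times)):
        x_pert = fit.x.copy()
        x_pert[i] *= 1.05
        x_pert[i] += 100.0
        f_pert = 0.5 * np.sum(residuals(x_pert) ** 2)
        if abs(f_pert - f_at) <= 1e-9 * max(1.0, abs(f_at)):
            identifiable = False
            break
    return SplitFit(
        times=times,
        residual=float(2 * f_at),
        n_obs=len(observed),
        free=free_times,
        ne=ne,
        gen_time=gen_time,
        identifiable=identifiable,
    )
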