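"""Allele-frequency simulation under population trees with drift and
admixture, plus an exact moment-propagation engine for expected
f-statistics.

The model is an admixture graph: a rooted tree of populations whose
branches carry dimensionless drift ``d`` in [0, 1), optionally augmented
with two-source admixture events.  A branch of duration ``t`` years in a
population of diploid effective size ``Ne`` maps onto drift via

    d = 1 - exp(-t / (gen_time * 2 * Ne)),

the classical diffusion loss of heterozygosity.  Along a branch allele
frequencies evolve by the Balding–Nichols transition

    p' ~ Beta(p (1 - d) / d, (1 - p)(1 - d) / d),

which preserves the mean and has Var(p' | p) = d * p(1 - p) — exactly the
first two moments the deterministic engine propagates, so simulated
f2/f3/f4 converge to the engine's closed-form expectations.

Admixed populations take frequency ``alpha * p_A + (1 - alpha) * p_B``;
because this is linear in frequencies, expected f-statistics are linear
(first moments) and bilinear (second moments) in ``alpha``.
"""
from __future__ import annotations

import copy
import dataclasses
import math
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import genodata
from .genodata import DIPLOID, MISSING, PSEUDO_HAPLOID, GenotypePanel


# ---------------------------------------------------------------------------
# Model types
# ---------------------------------------------------------------------------

@dataclasses.dataclass(frozen=True)
class AncestralFreqSpec:
    """Distribution of the root allele frequency p0."""

    dist: str = "uniform"
    params: tuple[float, ...] = (0.05, 0.95)

    def moments(self) -> tuple[float, float]:
        """Analytic (E[p0], E[p0^2])."""
        if self.dist == "uniform":
            lo, hi = self.params
            m1 = (lo + hi) / 2.0
            m2 = (lo * lo + lo * hi + hi * hi) / 3.0
            return m1, m2
        if self.dist == "beta":
            a, b = self.params
            m1 = a / (a + b)
            m2 = a * (a + 1) / ((a + b) * (a + b + 1))
            return m1, m2
        raise ValueError(f"unknown ancestral frequency distribution {self.dist!r}")

    def draw(self, rng: np.random.Generator, n: int) -> np.ndarray:
        if self.dist == "uniform":
            lo, hi = self.params
            return rng.uniform(lo, hi, size=n)
        if self.dist == "beta":
            a, b = self.params
            return rng.beta(a, b, size=n)
        raise ValueError(f"unknown ancestral frequency distribution {self.dist!r}")


@dataclasses.dataclass(frozen=True)
class Edge:
    parent: str
    child: str
    drift: float | None = None
    time_years: float | None = None


@dataclasses.dataclass(frozen=True)
class AdmixtureEvent:
    target: str
    source_a: str
    source_b: str
    alpha: float  # proportion from source_a


@dataclasses.dataclass(frozen=True)
class SamplingSpec:
    n_diploid: int = 0
    n_pseudo_haploid: int = 0


@dataclasses.dataclass
class DemographyModel:
    """Rooted population graph with drift branches and admixture events.

    Branch drift may be given directly (``Edge.drift``), as a duration
    (``Edge.time_years``), or implicitly via ``node_times`` (years before
    present per node; a branch's duration is then parent time minus child
    time).  ``sampling`` maps leaf population names to how many diploid and
    pseudo-haploid individuals to draw.
    """

    edges: list[Edge]
    admixture: list[AdmixtureEvent] = dataclasses.field(default_factory=list)
    Ne: float = 10_000.0
    gen_time: float = 29.0
    ancestral: AncestralFreqSpec = dataclasses.field(default_factory=AncestralFreqSpec)
    sampling: dict[str, SamplingSpec] = dataclasses.field(default_factory=dict)
    node_times: dict[str, float] | None = None
    name: str = ""

    # -- structure ---------------------------------------------------------
    def nodes(self) -> list[str]:
        seen: dict[str, None] = {}
        for e in self.edges:
            seen.setdefault(e.parent)
            seen.setdefault(e.child)
        for a in self.admixture:
            seen.setdefault(a.source_a)
            seen.setdefault(a.source_b)
            seen.setdefault(a.target)
        return list(seen)

    def root(self) -> str:
        children = {e.child for e in self.edges} | {a.target for a in self.admixture}
        roots = [n for n in self.nodes() if n not in children]
        if len(roots) != 1:
            raise ValueError(f"model must have exactly one root, found {roots}")
        return roots[0]

    def leaves(self) -> list[str]:
        parents = {e.parent for e in self.edges}
        srcs = {a.source_a for a in self.admixture} | {a.source_b for a in self.admixture}
        return [n for n in self.nodes() if n not in parents and n not in srcs]

    def topological_order(self) -> list[str]:
        deps: dict[str, list[str]] = {n: [] for n in self.nodes()}
        for e in self.edges:
            deps[e.child].append(e.parent)
        for a in self.admixture:
            deps[a.target].extend([a.source_a, a.source_b])
        order: list[str] = []
        state: dict[str, int] = {}

        def visit(n: str) -> None:
            if state.get(n) == 2:
                return
            if state.get(n) == 1:
                raise ValueError("demography graph contains a cycle")
            state[n] = 1
            for p in deps[n]:
                visit(p)
            state[n] = 2
            order.append(n)

        for n in self.nodes():
            visit(n)
        return order

    def parent_of(self) -> dict[str, Edge]:
        out: dict[str, Edge] = {}
        for e in self.edges:
            if e.child in out:
                raise ValueError(f"node {e.child!r} has multiple parent edges")
            out[e.child] = e
        return out

    # -- drift -------------------------------------------------------------
    def edge_drift(self, edge: Edge) -> float:
        if edge.drift is not None:
            d = float(edge.drift)
        else:
            if edge.time_years is not None:
                t = float(edge.time_years)
            elif self.node_times is not None:
                try:
                    t = float(self.node_times.get(edge.parent, 0.0)) - float(
                        self.node_times.get(edge.child, 0.0)
                    )
                except TypeError:
                    raise ValueError(f"missing node time for edge {edge.parent}->{edge.child}")
            else:
                raise ValueError(
                    f"edge {edge.parent}->{edge.child} has neither drift nor a duration"
                )
            t = max(t, 0.0)
            d = time_to_drift(t, self.Ne, self.gen_time)
        if not (0.0 <= d < 1.0):
            raise ValueError(f"drift on {edge.parent}->{edge.child} must be in [0,1), got {d}")
        return d

    def validate(self) -> None:
        self.root()
        self.topological_order()
        self.parent_of()
        targets = {a.target for a in self.admixture}
        for e in self.edges:
            if e.child in targets:
                raise ValueError(f"node {e.child!r} is both edge child and admixture target")
            self.edge_drift(e)
        for a in self.admixture:
            if not (0.0 <= a.alpha <= 1.0):
                raise ValueError(f"admixture alpha must be in [0,1], got {a.alpha}")
        unknown = set(self.sampling) - set(self.nodes())
        if unknown:
            raise ValueError(f"sampling specs for unknown populations: {sorted(unknown)}")

    def with_node_times(self, times: Mapping[str, float]) -> "DemographyModel":
        """Copy of the model with some node times replaced."""
        if self.node_times is None:
            raise ValueError("model has no node_times to update")
        new_times = dict(self.node_times)
        new_times.update(times)
        out = copy.copy(self)
        out.node_times = new_times
        return out


def time_to_drift(t: float, ne: float, gen_time: float) -> float:
    """Map a branch duration in years to dimensionless drift.

    d = 1 - exp(-t / (gen_time * 2 * Ne)); d -> 0 as t -> 0 and d -> 1 for
    branches much longer than 2*Ne generations.
    """
    if ne <= 0 or gen_time <= 0:
        raise ValueError("Ne and gen_time must be positive")
    if t < 0:
        raise ValueError("branch duration must be non-negative")
    return 1.0 - math.exp(-t / (gen_time * 2.0 * ne))


# ---------------------------------------------------------------------------
# Presets
# ---------------------------------------------------------------------------

def build_preset(name: str, basal_eurasian: bool = False) -> DemographyModel:
    """Named demographic presets.

    ``jones2015``: Upper-Palaeolithic Eurasia — an outgroup plus three
    deep Eurasian strands: western hunter-gatherers (WHG; Bichon- and
    Loschbour-like leaves), Caucasus hunter-gatherers (CHG; Kotias- and
    Satsurblia-like leaves) and early farmers (EF).  WHG split from the
    CHG/EF ancestor 45 kya; CHG and EF separated 25 kya around the Last
    Glacial Maximum; eastern hunter-gatherers (EHG) sit on the WHG side
    (20 kya); Yamnaya steppe herders are an even mixture of CHG- and
    EHG-related sources.  Modern Caucasus and modern north-European
    diploid populations descend from the CHG and WHG branches.

    ``star``: four leaves radiating from a single root with equal drift —
    a null model in which no pair shares post-root drift.

    Split times the source demography does not pin down (outgroup 100 kya,
    EHG–WHG 20 kya, within-CHG and within-WHG splits 17 kya, admixture
    source branch-off 5 kya) are package defaults, configurable per model.
    With ``basal_eurasian=True`` an extra deep lineage contributes 20% of
    EF ancestry (off by default).
    """
    if name == "jones2015":
        node_times = {
            "root": 100_000.0,
            "eurasia": 45_000.0,
            "north": 20_000.0,
            "whg_anc": 17_000.0,
            "south": 25_000.0,
            "chg_anc": 17_000.0,
            "ehg_src": 5_000.0,
            "chg_src": 5_000.0,
            "yamnaya_adm": 5_000.0,
            "Outgroup": 0.0,
            "Bichon": 0.0,
            "Loschbour": 0.0,
            "Kotias": 0.0,
            "Satsurblia": 0.0,
            "EF": 0.0,
            "EHG": 0.0,
            "Yamnaya": 0.0,
            "ModernCaucasus": 0.0,
            "ModernNorth": 0.0,
        }
        edges = [
            Edge("root", "Outgroup"),
            Edge("root", "eurasia"),
            Edge("eurasia", "north"),
            Edge("eurasia", "south"),
            Edge("north", "whg_anc"),
            Edge("north", "ehg_src"),
            Edge("whg_anc", "Bichon"),
            Edge("whg_anc", "Loschbour"),
            Edge("whg_anc", "ModernNorth"),
            Edge("ehg_src", "EHG"),
            Edge("south", "chg_anc"),
            Edge("south", "EF"),
            Edge("chg_anc", "Kotias"),
            Edge("chg_anc", "Satsurblia"),
            Edge("chg_anc", "chg_src"),
            Edge("chg_src", "ModernCaucasus"),
            Edge("yamnaya_adm", "Yamnaya"),
        ]
        admixture = [AdmixtureEvent("yamnaya_adm", "chg_src", "ehg_src", 0.5)]
        sampling = {
            "Outgroup": SamplingSpec(n_diploid=10),
            "Bichon": SamplingSpec(n_pseudo_haploid=2),
            "Loschbour": SamplingSpec(n_pseudo_haploid=2),
            "Kotias": SamplingSpec(n_pseudo_haploid=2),
            "Satsurblia": SamplingSpec(n_pseudo_haploid=2),
            "EF": SamplingSpec(n_diploid=2),
            "EHG": SamplingSpec(n_pseudo_haploid=2),
            "Yamnaya": SamplingSpec(n_pseudo_haploid=4),
            "ModernCaucasus": SamplingSpec(n_diploid=10),
            "ModernNorth": SamplingSpec(n_diploid=10),
        }
        if basal_eurasian:
            node_times["basal"] = 65_000.0
            node_times["basal_src"] = 25_000.0
            node_times["stem"] = 65_000.0
            node_times["ef_adm"] = 25_000.0
            node_times["EF"] = 0.0
            # re-route: root -> stem -> (basal, eurasia); EF = 0.8 south + 0.2 basal
            edges = [e for e in edges if not (e.parent == "root" and e.child == "eurasia")]
            edges = [e for e in edges if not (e.parent == "south" and e.child == "EF")]
            edges += [
                Edge("root", "stem"),
                Edge("stem", "eurasia"),
                Edge("stem", "basal"),
                Edge("basal", "basal_src"),
                Edge("ef_adm", "EF"),
            ]
            admixture.append(AdmixtureEvent("ef_adm", "south", "basal_src", 0.8))
        model = DemographyModel(
            edges=edges,
            admixture=admixture,
            sampling=sampling,
            node_times=node_times,
            name=name,
        )
        model.validate()
        return model
    if name == "star":
        node_times = {"root": 30_000.0, "A": 0.0, "B": 0.0, "C": 0.0, "Outgroup": 0.0}
        edges = [Edge("root", n) for n in ("A", "B", "C", "Outgroup")]
        sampling = {n: SamplingSpec(n_diploid=5) for n in ("A", "B", "C", "Outgroup")}
        model = DemographyModel(
            edges=edges, sampling=sampling, node_times=node_times, name=name
        )
        model.validate()
        return model
    raise ValueError(f"unknown preset {name!r}; available presets: ['jones2015', 'star']")


def random_model(seed: int, n_leaves: int | None = None) -> DemographyModel:
    """Small random tree (3–5 leaves, drifts 0.002–0.05) for property tests."""
    rng = np.random.default_rng(seed)
    if n_leaves is None:
        n_leaves = int(rng.integers(3, 6))
    edges: list[Edge] = []
    leaves = ["root"]
    counter = 0
    while len(leaves) < n_leaves:
        split = leaves.pop(int(rng.integers(len(leaves))))
        for _ in range(2):
            child = f"n{counter}"
            counter += 1
            edges.append(Edge(split, child, drift=float(rng.uniform(0.002, 0.05))))
            leaves.append(child)
    # relabel terminal nodes as populations P0..Pk
    terminal = {e.child for e in edges} - {e.parent for e in edges}
    mapping = {n: f"P{i}" for i, n in enumerate(sorted(terminal))}
    edges = [
        Edge(mapping.get(e.parent, e.parent), mapping.get(e.child, e.child), e.drift)
        for e in edges
    ]
    model = DemographyModel(edges=edges, name=f"random{seed}")
    model.validate()
    return model


# ---------------------------------------------------------------------------
# Moment engine
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class MomentTable:
    """Exact first and second moments of node allele frequencies.

    ``m2[i, j] = E[p_i p_j]`` taken over the ancestral frequency
    distribution and the drift process; f-statistics are linear
    combinations of these entries.
    """

    populations: list[str]
    m1: np.ndarray
    m2: np.ndarray

    def _i(self, pop: str) -> int:
        try:
            return self.populations.index(pop)
        except ValueError:
            raise KeyError(f"unknown population {pop!r}")

    def f2(self, a: str, b: str) -> float:
        i, j = self._i(a), self._i(b)
        return float(self.m2[i, i] + self.m2[j, j] - 2 * self.m2[i, j])

    def f3(self, c: str, a: str, b: str) -> float:
        i, j, k = self._i(c), self._i(a), self._i(b)
        return float(self.m2[i, i] - self.m2[i, j] - self.m2[i, k] + self.m2[j, k])

    def f4(self, w: str, x: str, y: str, z: str) -> float:
        i, j, k, l = self._i(w), self._i(x), self._i(y), self._i(z)
        return float(self.m2[i, k] - self.m2[i, l] - self.m2[j, k] + self.m2[j, l])

    def expected(self, kind: str, pops: Sequence[str]) -> float:
        if kind == "f2":
            return self.f2(*pops)
        if kind == "f3":
            return self.f3(*pops)
        if kind == "f4":
            return self.f4(*pops)
        raise ValueError(f"unknown statistic kind {kind!r}")


def expected_f_moments(model: DemographyModel) -> MomentTable:
    """Propagate E[p] and E[p p'] through the graph, exactly.

    Drift d on a branch leaves E[p] and all cross moments unchanged and
    updates the own second moment by E[p^2] <- E[p^2] + d (E[p] - E[p^2]);
    children of a split share their parent's E[p^2] as cross moment;
    admixture combines moments linearly/bilinearly in alpha.
    """
    model.validate()
    order = model.topological_order()
    idx = {n: i for i, n in enumerate(order)}
    k = len(order)
    m1 = np.zeros(k)
    m2 = np.zeros((k, k))
    parent = model.parent_of()
    adm = {a.target: a for a in model.admixture}
    e1, e2 = model.ancestral.moments()
    processed: list[int] = []
    root = model.root()
    for n in order:
        i = idx[n]
        if n == root:
            m1[i] = e1
            m2[i, i] = e2
        elif n in adm:
            a = adm[n]
            ia, ib = idx[a.source_a], idx[a.source_b]
            al = a.alpha
            m1[i] = al * m1[ia] + (1 - al) * m1[ib]
            for j in processed:
                cross = al * m2[ia, j] + (1 - al) * m2[ib, j]
                m2[i, j] = m2[j, i] = cross
            m2[i, i] = (
                al * al * m2[ia, ia]
                + 2 * al * (1 - al) * m2[ia, ib]
                + (1 - al) * (1 - al) * m2[ib, ib]
            )
        else:
            e = parent[n]
            d = model.edge_drift(e)
            ip = idx[e.parent]
            m1[i] = m1[ip]
            for j in processed:
                m2[i, j] = m2[j, i] = m2[ip, j]
            m2[i, i] = m2[ip, ip] + d * (m1[ip] - m2[ip, ip])
        processed.append(i)
    if (m2 < -1e-12).any() or (m2 > 1 + 1e-12).any():
        raise AssertionError("second moments escaped [0, 1]")
    return MomentTable(populations=order, m1=m1, m2=m2)


# ---------------------------------------------------------------------------
# Frequency simulation
# ---------------------------------------------------------------------------

@dataclasses.dataclass
class PopulationFrequencies:
    """Per-(node, SNP) allele frequencies from one simulated history."""

    populations: list[str]
    freqs: np.ndarray  # (n_pops, n_snps)

    @property
    def n_snps(self) -> int:
        return self.freqs.shape[1]

    def of(self, pop: str) -> np.ndarray:
        try:
            return self.freqs[self.populations.index(pop)]
        except ValueError:
            raise KeyError(f"unknown population {pop!r}")


def _balding_nichols(rng: np.random.Generator, p: np.ndarray, d: float) -> np.ndarray:
    """One drift step; boundaries 0 and 1 are absorbing."""
    if d == 0.0:
        return p.copy()
    out = p.copy()
    interior = (p > 0.0) & (p < 1.0)
    if interior.any():
        scale = (1.0 - d) / d
        pi = p[interior]
        out[interior] = rng.beta(pi * scale, (1.0 - pi) * scale)
    return out


def simulate_frequencies(
    model: DemographyModel, n_snps: int, seed: int
) -> PopulationFrequencies:
    """Draw allele-frequency trajectories for every node of the graph.

    Per SNP the root frequency is drawn from the ancestral distribution and
    propagated down each branch with the Balding–Nichols transition; an
    admixed node's frequency is the alpha-weighted average of its sources.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    model.validate()
    rng = np.random.default_rng(seed)
    order = model.topological_order()
    parent = model.parent_of()
    adm = {a.target: a for a in model.admixture}
    root = model.root()
    values: dict[str, np.ndarray] = {}
    for n in order:
        if n == root:
            values[n] = model.ancestral.draw(rng, n_snps)
        elif n in adm:
            a = adm[n]
            values[n] = a.alpha * values[a.source_a] + (1 - a.alpha) * values[a.source_b]
        else:
            e = parent[n]
            values[n] = _balding_nichols(rng, values[e.parent], model.edge_drift(e))
    return PopulationFrequencies(populations=order, freqs=np.vstack([values[n] for n in order]))


# ---------------------------------------------------------------------------
# Genotype sampling
# ---------------------------------------------------------------------------

def sample_genotypes(
    freqs: PopulationFrequencies,
    model: DemographyModel,
    seed: int,
    n_chromosomes: int = 30,
    chrom_length_mb: float = 100.0,
    cm_per_mb: float = 1.0,
) -> tuple[GenotypePanel, pd.DataFrame]:
    """Draw a genotype panel from population frequencies.

    Diploid individuals get dosage ~ Binomial(2, p); pseudo-haploid
    individuals get a single Bernoulli(p) allele duplicated (dosage 0 or 2).
    SNPs are laid out on a uniform genetic map so jackknife blocks exist.
    The dosage counts copies of ``allele1``, identified with the simulated
    (derived) allele of frequency p.
    """
    if not model.sampling:
        raise ValueError("model has no sampling specs")
    missing_pops = [p for p in model.sampling if p not in freqs.populations]
    if missing_pops:
        raise ValueError(f"frequencies lack sampled populations: {missing_pops}")
    rng = np.random.default_rng(seed)
    n_snps = freqs.n_snps
    snps = genodata.make_snp_table(
        n_snps, n_chromosomes=n_chromosomes, chrom_length_mb=chrom_length_mb,
        cm_per_mb=cm_per_mb,
    )
    rows = []
    meta = []
    for pop, spec in model.sampling.items():
        p = freqs.of(pop)
        for i in range(spec.n_diploid):
            rows.append(rng.binomial(2, p).astype(np.int8))
            meta.append((f"{pop}_d{i}", pop, DIPLOID, "U"))
        for i in range(spec.n_pseudo_haploid):
            rows.append((2 * rng.binomial(1, p)).astype(np.int8))
            meta.append((f"{pop}_h{i}", pop, PSEUDO_HAPLOID, "U"))
    panel = GenotypePanel(
        np.vstack(rows),
        pd.DataFrame(meta, columns=["id", "population", "ploidy_mode", "sex"]),
    )
    return panel, snps


# ---------------------------------------------------------------------------
# Pileup fixtures
# ---------------------------------------------------------------------------

def simulate_pileup(
    freqs: PopulationFrequencies,
    coverage: float,
    error_rate: float,
    seed: int,
    population: str | None = None,
    snps: pd.DataFrame | None = None,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Per-SNP base counts for one simulated ancient individual.

    Depth is Poisson(coverage); each read carries an allele of the
    individual's true diploid genotype with probability 1 - error_rate,
    otherwise a uniformly chosen other base.  Zero-depth SNPs are absent
    from the table.  Returns (pileup table, true dosage of allele1).
    """
    if coverage <= 0:
        raise ValueError("coverage must be positive")
    if not (0.0 <= error_rate < 0.25):
        raise ValueError("error_rate must be in [0, 0.25)")
    rng = np.random.default_rng(seed)
    pop = population if population is not None else freqs.populations[-1]
    p = freqs.of(pop)
    n_snps = len(p)
    if snps is None:
        snps = genodata.make_snp_table(n_snps)
    if len(snps) != n_snps:
        raise ValueError("SNP table does not match frequency matrix")
    genotype = rng.binomial(2, p)  # copies of allele1
    depth = rng.poisson(coverage, size=n_snps)
    bases = ["A", "C", "G", "T"]
    b1 = snps["allele1"].map(bases.index).to_numpy()
    b2 = snps["allele2"].map(bases.index).to_numpy()
    counts = np.zeros((n_snps, 4), dtype=np.int64)
    for j in range(n_snps):
        if depth[j] == 0:
            continue
        alleles = np.where(rng.random(depth[j]) < genotype[j] / 2.0, b1[j], b2[j])
        errs = rng.random(depth[j]) < error_rate
        if errs.any():
            shift = rng.integers(1, 4, size=int(errs.sum()))
            alleles[errs] = (alleles[errs] + shift) % 4
        counts[j] = np.bincount(alleles, minlength=4)
    present = depth > 0
    pileup = pd.DataFrame(
        {
            "snp_id": snps.loc[present, "snp_id"].to_numpy(),
            "chrom": snps.loc[present, "chrom"].to_numpy(),
            "pos": snps.loc[present, "position"].to_numpy(),
            "countA": counts[present, 0],
            "countC": counts[present, 1],
            "countG": counts[present, 2],
            "countT": counts[present, 3],
        }
    )
    return pileup, genotype


# ---------------------------------------------------------------------------
# ROH fixtures
# ---------------------------------------------------------------------------

def simulate_roh_genome(
    chrom_lengths: Sequence[int],
    het_density: float,
    planted_segments: Sequence[tuple[int, int, int]],
    error_het_rate: float,
    seed: int,
    snp_per_bp: float = 1e-4,
    sample_id: str = "roh_sample",
    population: str = "roh_pop",
) -> tuple[GenotypePanel, pd.DataFrame, list[tuple[int, int, int]]]:
    """Diploid genome with planted autozygous segments.

    SNP positions are uniform at density ``snp_per_bp``.  Outside planted
    segments a SNP is heterozygous with probability
    ``het_density / snp_per_bp`` (so heterozygotes occur at ``het_density``
    per bp); inside a segment heterozygotes occur only at the per-SNP
    ``error_het_rate``.  Segments are (chrom_index_1based, start, end) in
    bp and must be non-overlapping and within bounds.
    """
    if het_density < 0 or error_het_rate < 0:
        raise ValueError("rates must be non-negative")
    p_het = het_density / snp_per_bp
    if p_het > 1:
        raise ValueError("het_density exceeds SNP density")
    segs = sorted(planted_segments)
    by_chrom: dict[int, list[tuple[int, int]]] = {}
    for c, s, e in segs:
        if not (1 <= c <= len(chrom_lengths)):
            raise ValueError(f"segment chromosome {c} out of range")
        if not (1 <= s <= e <= chrom_lengths[c - 1]):
            raise ValueError(f"segment ({c},{s},{e}) out of chromosome bounds")
        prev = by_chrom.setdefault(c, [])
        if prev and s <= prev[-1][1]:
            raise ValueError("planted segments overlap")
        prev.append((s, e))
    rng = np.random.default_rng(seed)
    snp_rows = []
    genos = []
    for ci, length in enumerate(chrom_lengths, start=1):
        n = rng.poisson(length * snp_per_bp)
        pos = np.sort(rng.integers(1, length + 1, size=n))
        inside = np.zeros(n, dtype=bool)
        for s, e in by_chrom.get(ci, []):
            inside |= (pos >= s) & (pos <= e)
        het = np.where(
            inside,
            rng.random(n) < error_het_rate,
            rng.random(n) < p_het,
        )
        hom = 2 * rng.integers(0, 2, size=n)
        g = np.where(het, 1, hom).astype(np.int8)
        genos.append(g)
        for j, p in enumerate(pos):
            a1, a2 = genodata._ALLELE_CYCLE[j % len(genodata._ALLELE_CYCLE)]
            snp_rows.append((f"c{ci}_snp{j}", str(ci), int(p), p / 1e6, a1, a2))
    snps = pd.DataFrame(snp_rows, columns=genodata.SNP_COLUMNS)
    panel = GenotypePanel(
        np.concatenate(genos)[None, :],
        pd.DataFrame(
            {"id": [sample_id], "population": [population],
             "ploidy_mode": [DIPLOID], "sex": ["U"]}
        ),
    )
    return panel, snps, [tuple(s) for s in segs]


# ---------------------------------------------------------------------------
# Config I/O
# ---------------------------------------------------------------------------

def model_to_config(model: DemographyModel) -> dict:
    cfg: dict = {
        "name": model.name,
        "Ne": model.Ne,
        "gen_time": model.gen_time,
        "ancestral": {"dist": model.ancestral.dist, "params": list(model.ancestral.params)},
        "edges": [],
        "admixture": [
            {"target": a.target, "source_a": a.source_a, "source_b": a.source_b,
             "alpha": a.alpha}
            for a in model.admixture
        ],
        "sampling": {
            p: {"diploid": s.n_diploid, "pseudo_haploid": s.n_pseudo_haploid}
            for p, s in model.sampling.items()
        },
    }
    for e in model.edges:
        entry: dict = {"parent": e.parent, "child": e.child}
        if e.drift is not None:
            entry["drift"] = e.drift
        if e.time_years is not None:
            entry["time_years"] = e.time_years
        cfg["edges"].append(entry)
    if model.node_times is not None:
        cfg["node_times"] = dict(model.node_times)
    return cfg


def model_from_config(cfg: dict) -> DemographyModel:
    anc = cfg.get("ancestral", {})
    model = DemographyModel(
        edges=[
            Edge(e["parent"], e["child"], e.get("drift"), e.get("time_years"))
            for e in cfg["edges"]
        ],
        admixture=[
            AdmixtureEvent(a["target"], a["source_a"], a["source_b"], float(a["alpha"]))
            for a in cfg.get("admixture", [])
        ],
        Ne=float(cfg.get("Ne", 10_000.0)),
        gen_time=float(cfg.get("gen_time", 29.0)),
        ancestral=AncestralFreqSpec(
            anc.get("dist", "uniform"), tuple(anc.get("params", (0.05, 0.95)))
        ),
        sampling={
            p: SamplingSpec(int(s.get("diploid", 0)), int(s.get("pseudo_haploid", 0)))
            for p, s in cfg.get("sampling", {}).items()
        },
        node_times=cfg.get("node_times"),
        name=cfg.get("name", ""),
    )
    model.validate()
    return model


def write_model(model: DemographyModel, path: str) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_config(model), fh, sort_keys=False)


def read_model(path: str) -> DemographyModel:
    with open(path) as fh:
        return model_from_config(yaml.safe_load(fh))
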