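"""Desk-scale replay pipeline: simulate a demography, sample a panel, and
run the full analysis chain — topology test, clade tests, admixture scan,
ancestry proportion, split-time fit, PCA projection and ROH profiling —
writing intermediates and a consolidated report.
"""
from __future__ import annotations

import dataclasses
import json
import os
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import fstats, genodata, inference, projection, roh, syndata

ANALYSIS_GROUPS = {
    "Outgroup": ["Outgroup"],
    "WHG": ["Bichon", "Loschbour"],
    "CHG": ["Kotias", "Satsurblia"],
    "EF": ["EF"],
    "EHG": ["EHG"],
    "Yamnaya": ["Yamnaya"],
    "ModernCaucasus": ["ModernCaucasus"],
    "ModernNorth": ["ModernNorth"],
    "Kotias": ["Kotias"],
    "Satsurblia": ["Satsurblia"],
}

FIT_FREE_TIMES = ["root", "eurasia", "north", "whg_anc", "south", "chg_anc"]


@dataclasses.dataclass
class RunConfig:
    """Configuration for one replay run; round-trips through YAML."""

    preset: str = "jones2015"
    model_path: str | None = None
    n_snps: int = 100_000
    seed: int = 1
    out_dir: str = "replay_out"
    block_cm: float = 5.0
    run_topology: bool = True
    run_clade: bool = True
    run_scan: bool = True
    run_f4_ratio: bool = True
    run_split_fit: bool = False
    run_pca: bool = True
    run_roh: bool = True
    fit_n_snps: int = 200_000

    def to_yaml(self, path: str) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls(**data)


def _load_model(config: RunConfig) -> syndata.DemographyModel:
    if config.model_path:
        return syndata.read_model(config.model_path)
    return syndata.build_preset(config.preset)


def run_replay(config: RunConfig) -> dict[str, Any]:
    """Execute the configured stages; returns the report dict.

    The report records, per analysis, the computed tables and a boolean
    assertion where the analysis has an expected outcome under the
    simulated demography (topology winner, clade support, scan winner,
    admixture proportion consistent with one half).  ``passed`` is the
    conjunction of all assertions that ran.
    """
    os.makedirs(config.out_dir, exist_ok=True)
    model = _load_model(config)
    report: dict[str, Any] = {
        "config": dataclasses.asdict(config),
        "stages": [],
        "assertions": {},
    }

    freqs = syndata.simulate_frequencies(model, config.n_snps, config.seed)
    panel, snps = syndata.sample_genotypes(freqs, model, config.seed + 1)
    genodata.write_eigenstrat(panel, snps, os.path.join(config.out_dir, "panel"))
    report["stages"].append("simulate")

    blocks = genodata.assign_blocks(snps, config.block_cm)
    groups = {g: m for g, m in ANALYSIS_GROUPS.items()
              if set(m) <= set(panel.samples["population"])}
    fr = fstats.pop_frequencies(panel, groups)

    if config.run_topology:
        verdict = inference.topology_test(fr, "WHG", "CHG", "EF", "Outgroup", blocks)
        verdict.summary().to_csv(
            os.path.join(config.out_dir, "topology.tsv"), sep="\t", index=False
        )
        report["topology"] = {
            "winner": list(verdict.winner),
            "decisive": verdict.decisive,
        }
        report["assertions"]["topology_chg_ef_clade"] = (
            set(verdict.winner) == {"CHG", "EF"} and verdict.decisive
        )
        report["stages"].append("topology")

    if config.run_clade:
        clade = inference.clade_test(
            fr, "Outgroup", ["EF", "WHG", "EHG"], "Kotias", "Satsurblia", blocks
        )
        clade.table.to_csv(
            os.path.join(config.out_dir, "clade.tsv"), sep="\t", index=False
        )
        report["clade"] = {"supported": inference.clade_supported(clade)}
        report["assertions"]["chg_clade_supported"] = inference.clade_supported(clade)
        report["stages"].append("clade")

    if config.run_scan:
        scan = inference.admixture_scan(
            fr, "Yamnaya", ["CHG", "EHG", "WHG", "EF"], blocks
        )
        scan.table.to_csv(
            os.path.join(config.out_dir, "admixture_scan.tsv"), sep="\t", index=False
        )
        top = scan.table.iloc[0]
        winner_pair = {top["source_a"], top["source_b"]}
        report["admixture_scan"] = {
            "winner": sorted(winner_pair),
            "statistic": float(top["statistic"]),
            "z": float(top["z"]),
        }
        report["assertions"]["yamnaya_scan_chg_ehg"] = (
            winner_pair == {"CHG", "EHG"} and bool(top["significant"])
        )
        report["stages"].append("scan")

    if config.run_f4_ratio:
        alpha, se, den = fstats.f4_ratio(
            fr, "Outgroup", "Satsurblia", "Kotias", "EHG", "Yamnaya", blocks
        )
        report["f4_ratio"] = {
            "alpha": alpha,
            "se": se,
            "denominator_z": den.z,
            "reliable": den.significant(),
        }
        report["assertions"]["yamnaya_half_chg"] = abs(alpha - 0.5) <= 2 * se
        report["stages"].append("f4_ratio")

    if config.run_split_fit:
        fit_freqs = syndata.simulate_frequencies(model, config.fit_n_snps, config.seed + 7)
        fit_panel, fit_snps = syndata.sample_genotypes(fit_freqs, model, config.seed + 8)
        fit_blocks = genodata.assign_blocks(fit_snps, config.block_cm)
        fit_fr = fstats.pop_frequencies(fit_panel)
        pops = [p for p in fit_panel.samples["population"].unique()]
        observed = inference.observed_f2_suite(fit_fr, pops, fit_blocks)
        fit = inference.fit_split_times(
            observed, model, model.Ne, model.gen_time, FIT_FREE_TIMES
        )
        report["split_fit"] = {
            "times": fit.times,
            "residual": fit.residual,
            "identifiable": fit.identifiable,
        }
        report["stages"].append("split_fit")

    if config.run_pca:
        diploid = (panel.samples["ploidy_mode"] == genodata.DIPLOID).to_numpy()
        modern_panel = panel.subset_samples(diploid)
        dd = modern_panel.dosages.astype(float)
        dd[dd == genodata.MISSING] = np.nan
        freq = np.nanmean(dd, axis=0) / 2.0
        poly = (freq > 0) & (freq < 1)
        model_pca = projection.pca_fit(modern_panel.subset_snps(np.where(poly)[0]), 2)
        scores = projection.project_panel(panel.subset_snps(np.where(poly)[0]), model_pca)
        scores.to_csv(os.path.join(config.out_dir, "pca_scores.tsv"), sep="\t",
                      index=False)
        report["pca"] = {
            "variance_fraction": [float(v) for v in model_pca.variance_fraction]
        }
        report["stages"].append("pca")

    if config.run_roh:
        roh_panel, roh_snps, segs = syndata.simulate_roh_genome(
            chrom_lengths=[60_000_000, 60_000_000],
            het_density=3e-5,
            planted_segments=[(1, 10_000_000, 15_000_000), (2, 30_000_000, 33_000_000)],
            error_het_rate=0.001,
            seed=config.seed + 11,
        )
        intervals = roh.detect_roh(roh_panel, roh_snps)
        intervals.to_csv(os.path.join(config.out_dir, "roh.tsv"), sep="\t", index=False)
        summary = roh.roh_summary(intervals)
        summary.to_csv(os.path.join(config.out_dir, "roh_summary.tsv"), sep="\t",
                       index=False)
        report["roh"] = {"n_intervals": int(len(intervals))}
        report["stages"].append("roh")

    report["passed"] = all(report["assertions"].values()) if report["assertions"] else True
    with open(os.path.join(config.out_dir, "report.json"), "w") as fh:
        json.dump(report, fh, indent=2, sort_keys=True)
    return report


def make_fixtures(seed: int, out_dir: str) -> dict[str, str]:
    """Write the small fixture set used by tests and worked examples.

    A toy EIGENSTRAT panel (jones2015 at 2,000 SNPs), a pileup TSV for the
    pseudo-haploid caller, an ROH genome with one planted segment, and the
    moment-engine oracle table of expected f2 values for the preset.
    """
    os.makedirs(out_dir, exist_ok=True)
    model = syndata.build_preset("jones2015")
    freqs = syndata.simulate_frequencies(model, 2_000, seed)
    panel, snps = syndata.sample_genotypes(freqs, model, seed + 1)
    prefix = os.path.join(out_dir, "toy_panel")
    genodata.write_eigenstrat(panel, snps, prefix)

    pileup, _ = syndata.simulate_pileup(
        freqs, coverage=1.4, error_rate=0.01, seed=seed + 2,
        population="Satsurblia", snps=snps,
    )
    pileup_path = os.path.join(out_dir, "toy_pileup.tsv")
    pileup.to_csv(pileup_path, sep="\t", index=False)

    roh_panel, roh_snps, _ = syndata.simulate_roh_genome(
        chrom_lengths=[30_000_000, 30_000_000],
        het_density=3e-5,
        planted_segments=[(1, 10_000_000, 15_000_000)],
        error_het_rate=0.001,
        seed=seed + 3,
    )
    roh_prefix = os.path.join(out_dir, "toy_roh")
    genodata.write_eigenstrat(roh_panel, roh_snps, roh_prefix)

    table = syndata.expected_f_moments(model)
    leaves = sorted(model.sampling)
    rows = [
        {"pop_a": a, "pop_b": b, "expected_f2": table.f2(a, b)}
        for i, a in enumerate(leaves)
        for b in leaves[i + 1 :]
    ]
    oracle_path = os.path.join(out_dir, "expected_f2.tsv")
    pd.DataFrame(rows).to_csv(oracle_path, sep="\t", index=False)
    return {
        "panel_prefix": prefix,
        "pileup": pileup_path,
        "roh_prefix": roh_prefix,
        "oracle": oracle_path,
    }
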