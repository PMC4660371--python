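"""PCA on modern diploid panels with least-squares projection of ancient
samples (the smartpca ``lsqproject`` idea).

Each SNP column is centred by its mean dosage mu and scaled by
sqrt(p(1 - p)) with p = mu/2 — the expected binomial standard deviation per
chromosome — after which missing entries contribute zero.  Ancient samples
with missing data are placed on the fitted components by ordinary least
squares restricted to their observed SNPs, which equals the standard score
when nothing is missing.
"""
from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .genodata import DIPLOID, MISSING, GenotypePanel


@dataclasses.dataclass
class PcaModel:
    """Fitted PCA basis: per-SNP standardization plus loading vectors."""

    mean: np.ndarray          # per-SNP mean dosage
    scale: np.ndarray         # per-SNP sqrt(p(1-p))
    loadings: np.ndarray      # SNPs x components, orthonormal columns
    eigenvalues: np.ndarray   # non-increasing
    variance_fraction: np.ndarray
    scores: np.ndarray        # fitting samples x components
    sample_ids: list[str]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[1]


def _standardize(dosages: np.ndarray, mean: np.ndarray, scale: np.ndarray) -> np.ndarray:
    X = dosages.astype(float)
    missing = dosages == MISSING
    X[missing] = np.nan
    Z = (X - mean) / scale
    Z[missing] = 0.0
    return Z


def pca_fit(panel: GenotypePanel, n_components: int) -> PcaModel:
    """Principal components of a modern diploid panel.

    No outlier-removal iterations are performed.  Monomorphic SNPs (which
    would need division by zero) are rejected — filter them upstream.
    Component signs are fixed by making each component's largest-magnitude
    loading positive, so plots are reproducible across runs and platforms.
    """
    if (panel.samples["ploidy_mode"] != DIPLOID).any():
        raise ValueError("PCA fitting panel must be all diploid")
    n, s = panel.n_samples, panel.n_snps
    if not (1 <= n_components <= min(n - 1, s)):
        raise ValueError("n_components must be in [1, min(n_samples-1, n_snps)]")
    X = panel.dosages.astype(float)
    X[panel.dosages == MISSING] = np.nan
    mean = np.nanmean(X, axis=0)
    p = mean / 2.0
    scale = np.sqrt(p * (1.0 - p))
    if (scale == 0).any() or np.isnan(scale).any():
        bad = int(((scale == 0) | np.isnan(scale)).sum())
        raise ValueError(f"{bad} monomorphic or all-missing SNPs; prune before PCA")
    Z = _standardize(panel.dosages, mean, scale)
    u, sv, vt = np.linalg.svd(Z, full_matrices=False)
    k = n_components
    loadings = vt[:k].T
    eigenvalues = sv[:k] ** 2 / (n - 1)
    total_var = float((Z**2).sum()) / (n - 1)
    # sign convention: largest |loading| positive per component
    for c in range(k):
        j = np.argmax(np.abs(loadings[:, c]))
        if loadings[j, c] < 0:
            loadings[:, c] *= -1.0
    scores = Z @ loadings
    return PcaModel(
        mean=mean,
        scale=scale,
        loadings=loadings,
        eigenvalues=eigenvalues,
        variance_fraction=eigenvalues / total_var,
        scores=scores,
        sample_ids=panel.samples["id"].tolist(),
    )


def lsq_project(dosage_row: np.ndarray, model: PcaModel) -> np.ndarray:
    """Project one (possibly incomplete) genotype row onto fitted components.

    Solves min_s || L_obs s - z_obs || over the sample's non-missing SNPs,
    standardized with the model's mean and scale.  Requires at least as
    many observed SNPs as components.
    """
    dosage_row = np.asarray(dosage_row)
    if dosage_row.shape != model.mean.shape:
        raise ValueError("dosage row length does not match model SNP count")
    obs = dosage_row != MISSING
    if int(obs.sum()) < model.n_components:
        raise ValueError(
            f"only {int(obs.sum())} non-missing SNPs; need >= {model.n_components}"
        )
    z = (dosage_row[obs].astype(float) - model.mean[obs]) / model.scale[obs]
    sol, *_ = np.linalg.lstsq(model.loadings[obs], z, rcond=None)
    return sol


def project_panel(panel: GenotypePanel, model: PcaModel) -> pd.DataFrame:
    """Scores table (sample, population, PC1..PCk) for a whole panel."""
    rows = []
    for i in range(panel.n_samples):
        scores = lsq_project(panel.dosages[i], model)
        rows.append(
            [panel.samples["id"].iloc[i], panel.samples["population"].iloc[i], *scores]
        )
    cols = ["sample", "population"] + [f"PC{c+1}" for c in range(model.n_components)]
    return pd.DataFrame(rows, columns=cols)
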