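import numpy as np
import pytest

from fourstrand import fstats, genodata, pipeline, syndata


@pytest.fixture(scope="session")
def preset_model():
    return syndata.build_preset("jones2015")


@pytest.fixture(scope="session")
def preset_sim_100k(preset_model):
    """One 100k-SNP simulated panel under the jones2015 preset, shared by
    the statistic-level checks (simulation dominates their cost)."""
    freqs = syndata.simulate_frequencies(preset_model, 100_000, seed=5)
    panel, snps = syndata.sample_genotypes(freqs, preset_model, seed=6)
    blocks = genodata.assign_blocks(snps)
    groups = {g: m for g, m in pipeline.ANALYSIS_GROUPS.items()}
    fe = fstats.pop_frequencies(panel, groups)
    return {
        "model": preset_model,
        "freqs": freqs,
        "panel": panel,
        "snps": snps,
        "blocks": blocks,
        "fe": fe,
    }


@pytest.fixture(scope="session")
def small_sim(preset_model):
    """A fast 20k-SNP panel for structural (non-power) checks."""
    freqs = syndata.simulate_frequencies(preset_model, 20_000, seed=42)
    panel, snps = syndata.sample_genotypes(freqs, preset_model, seed=43)
    blocks = genodata.assign_blocks(snps)
    return {
        "freqs": freqs,
        "panel": panel,
        "snps": snps,
        "blocks": blocks,
        "fe": fstats.pop_frequencies(panel),
    }
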