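import numpy as np
import pandas as pd
import pytest

from spermclock import SimulationConfig, build_features, simulate_cohort


@pytest.fixture(scope="session")
def small_config():
    """A fast cohort: 60 samples, 20 signal regions, thin background."""
    return SimulationConfig(
        n_samples=60, n_signal_regions=20, n_hyper=2,
        n_background_probes=150, seed=11,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return simulate_cohort(small_config)


@pytest.fixture(scope="session")
def small_features(small_cohort):
    return build_features(small_cohort.betas, small_cohort.manifest,
                          small_cohort.regions, design="regional")


@pytest.fixture()
def beta_file(tmp_path):
    """Write a tiny 2-probe x 2-sample beta matrix and return its path."""
    path = tmp_path / "betas.tsv"
    path.write_text(
        "probe_id\tA\tB\n"
        "cg01\t0.1\t0.9\n"
        "cg02\t0.5\t0.5\n"
    )
    return path


def brute_force_probe_map(manifest: pd.DataFrame, regions) -> dict:
    """Exhaustive per-probe, per-region membership scan (test oracle)."""
    mapping = {r.name: [] for r in regions}
    order = {}
    for region in regions:
        hits = []
        for _, row in manifest.iterrows():
            if row["chrom"] == region.chromosome and region.start <= row["pos"] <= region.stop:
                hits.append((row["pos"], row["probe_id"]))
        mapping[region.name] = [p for _, p in sorted(hits)]
    return mapping


def brute_force_region_means(betas, mapping) -> pd.DataFrame:
    """Loop-computed per-sample mean over each region's probes (test oracle)."""
    probe_row = {p: i for i, p in enumerate(betas.probe_ids)}
    out = {}
    for region, probes in mapping.items():
        present = [p for p in probes if p in probe_row]
        if not present:
            continue
        col = []
        for j in range(len(betas.sample_ids)):
            vals = [betas.values[probe_row[p], j] for p in present]
            vals = [v for v in vals if not np.isnan(v)]
            col.append(np.mean(vals) if vals else np.nan)
        out[region] = col
    return pd.DataFrame(out, index=betas.sample_ids)
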