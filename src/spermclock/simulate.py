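"""Synthetic sperm-methylation cohorts with known ground truth.

The generator emulates the statistical structure the clock assumes: a
cohort of men aged roughly 20-45 whose sperm methylomes carry 148
age-responsive ~1 kb regions — 8 gaining and 140 losing methylation with
age — measured through a few array probes per region, plus a large
background of age-independent probes. Per-sample "biological age"
scatter (a Gaussian offset applied to every signal region), per-probe
fixed offsets and per-measurement noise control how far any predictor
can get; the truth object exposes the implied analytic accuracy floor.

Smoking is modelled as effective-age inflation (a smoker's signal
regions look ``age * (1 + s/100)`` years old), so the ground-truth age
acceleration of a smoker group is the configured percentage by
construction. Optional somatic admixture perturbs the contamination
panel loci toward the somatic state in proportion to the configured
mixing fraction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from . import io as sio
from .exceptions import InputError, ValidationError
from .io import BetaMatrix, RegionSet, Region
from .qc import default_panel, PanelLocus


@dataclass
class SimulationConfig:
    """Knobs for :func:`simulate_cohort`; defaults are the study conditions."""

    n_samples: int = 250
    age_min: float = 20.0
    age_max: float = 45.0
    age_ref: float = 20.0
    n_signal_regions: int = 148
    n_hyper: int = 8                      # regions gaining methylation with age
    probes_per_region: tuple[int, int] = (3, 8)
    baseline_hypo: tuple[float, float] = (0.55, 0.90)
    baseline_hyper: tuple[float, float] = (0.10, 0.40)
    slope_magnitude: tuple[float, float] = (0.002, 0.006)  # beta units / year
    probe_offset_sd: float = 0.02
    probe_noise_sd: float = 0.03
    bio_age_sd: float = 2.0               # years of per-sample biological scatter
    n_background_probes: int = 2000
    smoker_fraction: float = 0.0
    long_term_fraction: float = 0.0       # of smokers, labelled long_term_smoker
    smoking_effect_pct: float = 0.0
    long_term_effect_pct: float = 0.0
    contamination_fractions: tuple[float, ...] = ()
    n_blood_samples: int = 0
    include_panel: bool = True
    noise_model: str = "clip"             # 'clip' (truncated Gaussian) or 'logit'
    replicate_noise_sd: float = 0.02
    seed: int = 0

    def validate(self) -> None:
        if self.n_samples < 2:
            raise ValidationError("n_samples must be >= 2")
        if not self.age_min < self.age_max:
            raise ValidationError("age_min must be < age_max")
        if self.n_hyper > self.n_signal_regions:
            raise ValidationError(
                f"n_hyper ({self.n_hyper}) exceeds n_signal_regions "
                f"({self.n_signal_regions})"
            )
        lo, hi = self.probes_per_region
        if lo < 1 or hi < lo:
            raise ValidationError("probes_per_region must satisfy 1 <= lo <= hi")
        if not 0.0 <= self.smoker_fraction <= 1.0:
            raise ValidationError("smoker_fraction must be in [0, 1]")
        if not 0.0 <= self.long_term_fraction <= 1.0:
            raise ValidationError("long_term_fraction must be in [0, 1]")
        if any(not 0.0 <= f <= 1.0 for f in self.contamination_fractions):
            raise ValidationError("contamination fractions must be in [0, 1]")
        if len(self.contamination_fractions) + self.n_blood_samples > self.n_samples:
            raise ValidationError("more contaminated/blood samples than samples")
        if self.noise_model not in ("clip", "logit"):
            raise ValidationError("noise_model must be 'clip' or 'logit'")


@dataclass
class SimulationTruth:
    """Everything needed to recompute expected region means analytically."""

    config: SimulationConfig
    ages: pd.Series                     # chronological, years
    bio_offset: pd.Series               # years
    effective_age: pd.Series            # drives signal regions
    region_truth: pd.DataFrame          # name, direction, baseline, slope
    region_probes: dict[str, list[str]]
    probe_offsets: pd.Series            # per signal-region probe
    contamination: pd.Series            # somatic fraction per sample
    smoking_status: pd.Series

    def expected_region_means(self) -> pd.DataFrame:
        """Noise-free samples x regions means implied by the linear model."""
        eff = self.effective_age.to_numpy()[:, None]
        cols = {}
        for _, row in self.region_truth.iterrows():
            offsets = self.probe_offsets[self.region_probes[row["name"]]].to_numpy()
            mu = row["baseline"] + offsets[None, :] + row["slope"] * (
                eff - self.config.age_ref
            )
            cols[row["name"]] = np.clip(mu, 0.0, 1.0).mean(axis=1)
        return pd.DataFrame(cols, index=self.ages.index)

    def feature_noise_age_variance(self) -> float:
        """Age-equivalent variance (years^2) of probe noise through the features.

        Each region mean carries noise variance sigma^2 / m_r; combining
        regions optimally, the Fisher information about age sums to
        sum_r m_r * slope_r^2 / sigma^2.
        """
        sigma2 = self.config.probe_noise_sd ** 2
        if sigma2 == 0:
            return 0.0
        info = sum(
            len(self.region_probes[row["name"]]) * row["slope"] ** 2 / sigma2
            for _, row in self.region_truth.iterrows()
        )
        return 1.0 / info if info > 0 else np.inf

    def mae_floor(self) -> float:
        """Best attainable MAE (years): biological scatter plus feature noise."""
        sd = np.sqrt(self.config.bio_age_sd ** 2 + self.feature_noise_age_variance())
        return float(np.sqrt(2.0 / np.pi) * sd)

    def attainable_r2(self) -> float:
        """Test r-squared of an ideal predictor given the configured noise."""
        var_age = (self.config.age_max - self.config.age_min) ** 2 / 12.0
        noise = self.config.bio_age_sd ** 2 + self.feature_noise_age_variance()
        return float(var_age / (var_age + noise))


@dataclass
class SimulatedCohort:
    betas: BetaMatrix
    manifest: pd.DataFrame
    regions: RegionSet
    metadata: pd.DataFrame
    truth: SimulationTruth


def _add_noise(mu: np.ndarray, sd: float, rng: np.random.Generator,
               model: str) -> np.ndarray:
    if sd == 0.0:
        return np.clip(mu, 0.0, 1.0)
    if model == "logit":
        eps = 1e-6
        z = logit(np.clip(mu, eps, 1.0 - eps))
        # match the beta-scale sd near mu via the logistic derivative
        deriv = np.clip(mu * (1.0 - mu), 1e-3, None)
        return expit(z + rng.normal(0.0, sd, size=mu.shape) / deriv)
    return np.clip(mu + rng.normal(0.0, sd, size=mu.shape), 0.0, 1.0)


def simulate_cohort(config: SimulationConfig | None = None) -> SimulatedCohort:
    """Generate one cohort: betas, manifest, regions, metadata and truth.

    Deterministic in ``config.seed``: identical configs produce
    byte-identical outputs.
    """
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_samples
    sample_ids = [f"S{i + 1:04d}" for i in range(n)]

    ages = rng.uniform(config.age_min, config.age_max, n)
    bio = rng.normal(0.0, config.bio_age_sd, n)

    # smoking labels: a random subset of the cohort, long-term nested within
    status = np.array(["never"] * n, dtype=object)
    n_smokers = int(round(config.smoker_fraction * n))
    smoker_idx = rng.choice(n, size=n_smokers, replace=False)
    status[smoker_idx] = "smoker"
    n_long = int(round(config.long_term_fraction * n_smokers))
    if n_long:
        status[smoker_idx[:n_long]] = "long_term_smoker"
    effect = np.zeros(n)
    effect[status == "smoker"] = config.smoking_effect_pct
    effect[status == "long_term_smoker"] = config.long_term_effect_pct
    effective_age = ages * (1.0 + effect / 100.0) + bio

    # tissue labels: the last n_blood_samples are somatic positive controls
    tissue = np.array(["sperm"] * n, dtype=object)
    if config.n_blood_samples:
        tissue[-config.n_blood_samples:] = "somatic"
    is_somatic = tissue == "somatic"

    # contamination: fractions assigned to the last sperm samples before blood
    contam = np.zeros(n)
    n_contam = len(config.contamination_fractions)
    if n_contam:
        stop = n - config.n_blood_samples
        contam[stop - n_contam:stop] = config.contamination_fractions
    contam[is_somatic] = 1.0

    # signal regions on chr1, disjoint ~1 kb intervals in a synthetic namespace
    n_reg = config.n_signal_regions
    directions = np.array(
        ["hyper"] * config.n_hyper + ["hypo"] * (n_reg - config.n_hyper)
    )
    rng.shuffle(directions)
    names = [f"R{i + 1:03d}" for i in range(n_reg)]
    starts = 10_000_000 + 5_000 * np.arange(n_reg)
    regions = RegionSet([
        Region(name=names[i], chromosome="chr1", start=int(starts[i]),
               stop=int(starts[i] + 999))
        for i in range(n_reg)
    ])
    baselines = np.where(
        directions == "hypo",
        rng.uniform(*config.baseline_hypo, n_reg),
        rng.uniform(*config.baseline_hyper, n_reg),
    )
    slopes = rng.uniform(*config.slope_magnitude, n_reg)
    slopes = np.where(directions == "hypo", -slopes, slopes)

    lo, hi = config.probes_per_region
    probes_per = rng.integers(lo, hi + 1, n_reg)

    probe_ids: list[str] = []
    probe_chrom: list[str] = []
    probe_pos: list[int] = []
    region_probes: dict[str, list[str]] = {}
    rows: list[np.ndarray] = []
    offset_records: dict[str, float] = {}
    counter = 0
    age_term = effective_age - config.age_ref
    for i in range(n_reg):
        m = int(probes_per[i])
        pos = np.sort(rng.choice(np.arange(starts[i], starts[i] + 1000), size=m,
                                 replace=False))
        offsets = rng.normal(0.0, config.probe_offset_sd, m)
        pids = [f"cgSIM{counter + j:06d}" for j in range(m)]
        counter += m
        region_probes[names[i]] = pids
        for j in range(m):
            offset_records[pids[j]] = float(offsets[j])
        mu = baselines[i] + offsets[:, None] + slopes[i] * age_term[None, :]
        rows.append(_add_noise(mu, config.probe_noise_sd, rng, config.noise_model))
        probe_ids.extend(pids)
        probe_chrom.extend(["chr1"] * m)
        probe_pos.extend(int(p) for p in pos)

    # age-independent background probes, bimodal baseline, on chr3
    if config.n_background_probes:
        nb = config.n_background_probes
        high = rng.random(nb) < 0.5
        base = np.where(high, rng.beta(8, 2, nb), rng.beta(2, 8, nb))
        mu = np.repeat(base[:, None], n, axis=1)
        rows.append(_add_noise(mu, config.probe_noise_sd, rng, config.noise_model))
        probe_ids.extend(f"cgBG{j:06d}" for j in range(nb))
        probe_chrom.extend(["chr3"] * nb)
        probe_pos.extend(1_000_000 + 200 * j for j in range(nb))

    # contamination panel loci: sperm-low, somatic-high, admixture-sensitive
    if config.include_panel:
        for locus in default_panel():
            m = 5
            pos = np.linspace(locus.region.start, locus.region.stop, m).astype(int)
            sperm_mu = rng.uniform(0.02, 0.08, m)
            somatic_mu = rng.uniform(0.80, 0.92, m)
            if not locus.somatic_is_higher:
                sperm_mu, somatic_mu = somatic_mu, sperm_mu
            mu = (1.0 - contam)[None, :] * sperm_mu[:, None] \
                + contam[None, :] * somatic_mu[:, None]
            rows.append(_add_noise(mu, config.probe_noise_sd, rng, config.noise_model))
            pids = [f"cgPANEL_{locus.name}_{j}" for j in range(m)]
            probe_ids.extend(pids)
            probe_chrom.extend([locus.region.chromosome] * m)
            probe_pos.extend(int(p) for p in pos)

    values = np.vstack(rows)
    betas = BetaMatrix(probe_ids, sample_ids, values)
    manifest = pd.DataFrame(
        {"probe_id": probe_ids, "chrom": probe_chrom, "pos": probe_pos}
    )
    idx = pd.Index(sample_ids, name="sample_id")
    metadata = pd.DataFrame({
        "sample_id": sample_ids,
        "age": np.round(ages, 3),
        "smoking_status": status,
        "replicate_group": pd.NA,
        "tissue": tissue,
    })
    truth = SimulationTruth(
        config=config,
        ages=pd.Series(ages, index=idx, name="age"),
        bio_offset=pd.Series(bio, index=idx, name="bio_offset"),
        effective_age=pd.Series(effective_age, index=idx, name="effective_age"),
        region_truth=pd.DataFrame({
            "name": names, "direction": directions,
            "baseline": baselines, "slope": slopes,
        }),
        region_probes=region_probes,
        probe_offsets=pd.Series(offset_records, name="probe_offset"),
        contamination=pd.Series(contam, index=idx, name="somatic_fraction"),
        smoking_status=pd.Series(status, index=idx, name="smoking_status"),
    )
    return SimulatedCohort(betas=betas, manifest=manifest, regions=regions,
                           metadata=metadata, truth=truth)


def simulate_replicates(
    cohort: SimulatedCohort,
    n_individuals: int = 10,
    n_replicates: int = 6,
    replicate_noise_sd: float | None = None,
    seed: int | None = None,
) -> tuple[BetaMatrix, pd.DataFrame]:
    """Technical-replicate arrays for the first ``n_individuals`` samples.

    Each replicate is the individual's measured probe profile plus
    independent replicate noise (clipped to [0, 1]); ``replicate_group``
    links replicates of one individual. With zero replicate noise all
    replicates are identical.
    """
    if n_replicates < 2:
        raise InputError("need at least 2 replicates per individual")
    if n_individuals > cohort.betas.n_samples:
        raise InputError(
            f"cohort has {cohort.betas.n_samples} samples, "
            f"cannot draw {n_individuals} individuals"
        )
    config = cohort.truth.config
    if replicate_noise_sd is None:
        replicate_noise_sd = config.replicate_noise_sd
    rng = np.random.default_rng([config.seed, 7_000_001] if seed is None else seed)

    base_ids = cohort.betas.sample_ids[:n_individuals]
    base = cohort.betas.subset_samples(base_ids).values
    meta = cohort.metadata.set_index("sample_id")

    rep_ids: list[str] = []
    rep_values: list[np.ndarray] = []
    rows = []
    for j, sid in enumerate(base_ids):
        for rep in range(1, n_replicates + 1):
            col = base[:, j]
            if replicate_noise_sd > 0.0:
                col = np.clip(col + rng.normal(0.0, replicate_noise_sd, col.shape),
                              0.0, 1.0)
            rep_values.append(col)
            rep_id = f"{sid}_rep{rep}"
            rep_ids.append(rep_id)
            rows.append({
                "sample_id": rep_id,
                "age": meta.loc[sid, "age"],
                "smoking_status": meta.loc[sid, "smoking_status"],
                "replicate_group": sid,
                "tissue": meta.loc[sid, "tissue"],
            })
    betas = BetaMatrix(list(cohort.betas.probe_ids), rep_ids,
                       np.column_stack(rep_values))
    return betas, pd.DataFrame(rows)


def write_cohort(cohort: SimulatedCohort, outdir: str | Path) -> dict[str, Path]:
    """Write the cohort as the plain-text files the rest of the package reads."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "betas": outdir / "betas.tsv",
        "manifest": outdir / "manifest.csv",
        "regions_csv": outdir / "regions.csv",
        "regions_bed": outdir / "regions.bed",
        "metadata": outdir / "metadata.csv",
        "truth": outdir / "truth.json",
    }
    sio.write_beta_matrix(cohort.betas, paths["betas"])
    sio.write_probe_manifest(cohort.manifest, paths["manifest"])
    cohort.regions.write_csv(paths["regions_csv"])
    cohort.regions.write_bed(paths["regions_bed"])
    sio.write_sample_metadata(cohort.metadata, paths["metadata"])
    truth = cohort.truth
    doc = {
        "config": asdict(truth.config),
        "ages": truth.ages.round(6).to_dict(),
        "bio_offset": truth.bio_offset.round(6).to_dict(),
        "effective_age": truth.effective_age.round(6).to_dict(),
        "region_truth": truth.region_truth.to_dict(orient="records"),
        "contamination": truth.contamination[truth.contamination > 0].to_dict(),
        "mae_floor": truth.mae_floor(),
        "attainable_r2": truth.attainable_r2(),
    }
    with open(paths["truth"], "w") as fh:
        json.dump(doc, fh, indent=1, default=float)
        fh.write("\n")
    return paths
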