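"""Probe-to-region mapping and region-level feature construction.

The clock's "regional level" features are per-sample arithmetic means of
beta values over all array probes falling inside each clock region.
Alternative feature designs used when benchmarking model construction —
per-probe features restricted to clock regions ("cpg" level) and the
whole array ("entire_array") — are built here as well so all designs
share one code path.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, InputError
from .io import BetaMatrix, RegionSet

logger = logging.getLogger(__name__)

DESIGNS = ("regional", "cpg", "entire_array")


@dataclass
class RegionFeatureMatrix:
    """Sample x feature matrix of region mean betas (or probe betas).

    ``values`` is a samples x features DataFrame in [0, 1] (NaN where a
    sample has no usable probe in a region); ``probes_per_region`` counts
    the probes contributing to each retained feature.
    """

    values: pd.DataFrame
    probes_per_region: dict[str, int] = field(default_factory=dict)
    dropped_regions: dict[str, int] = field(default_factory=dict)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def region_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def write_tsv(self, path) -> None:
        self.values.to_csv(path, sep="\t", na_rep="NA", index_label="sample_id")


def _chrom_style(names) -> set[str]:
    return {"prefixed" if str(n).lower().startswith("chr") else "bare" for n in names}


def map_probes_to_regions(manifest: pd.DataFrame, regions: RegionSet) -> dict[str, list[str]]:
    """Assign probes to regions by coordinate containment.

    A probe belongs to a region when it sits on the same chromosome and
    its position lies within [start, stop] (both ends inclusive). Probes
    in overlapping regions are assigned to every region they hit. Output
    is ordered by region name, probes by position then probe ID.
    """
    if len(regions) == 0:
        return {}
    manifest_styles = _chrom_style(manifest["chrom"].unique())
    region_styles = _chrom_style({r.chromosome for r in regions})
    mapping: dict[str, list[str]] = {}
    for region in sorted(regions, key=lambda r: r.name):
        on_chrom = manifest[manifest["chrom"] == region.chromosome]
        hit = on_chrom[(on_chrom["pos"] >= region.start) & (on_chrom["pos"] <= region.stop)]
        hit = hit.sort_values(["pos", "probe_id"], kind="mergesort")
        mapping[region.name] = hit["probe_id"].tolist()
    if all(len(v) == 0 for v in mapping.values()) and manifest_styles.isdisjoint(region_styles):
        raise ConfigurationError(
            "no probe fell in any region and chromosome naming styles differ "
            f"(manifest: {sorted(manifest_styles)}, regions: {sorted(region_styles)}); "
            "harmonize names, e.g. add/strip the 'chr' prefix"
        )
    return mapping


def write_probe_region_map(mapping: dict[str, list[str]], path) -> None:
    with open(path, "w") as fh:
        fh.write("region\tprobe_id\n")
        for region, probes in mapping.items():
            for probe in probes:
                fh.write(f"{region}\t{probe}\n")


def aggregate_region_means(
    betas: BetaMatrix,
    mapping: dict[str, list[str]],
    min_probes: int = 1,
) -> RegionFeatureMatrix:
    """Compute per-sample mean beta over each region's probes.

    Missing probe values are excluded from the mean; an entry with no
    non-missing probe at all is left missing. Regions with fewer than
    ``min_probes`` probes present in the matrix are dropped globally;
    probes named in the mapping but absent from the matrix are dropped
    with a logged warning.
    """
    frame = betas.to_frame()
    probe_index = {p: i for i, p in enumerate(betas.probe_ids)}
    cols: dict[str, np.ndarray] = {}
    probes_per_region: dict[str, int] = {}
    dropped: dict[str, int] = {}
    n_absent = 0
    for region, probes in mapping.items():
        present = [p for p in probes if p in probe_index]
        n_absent += len(probes) - len(present)
        if len(present) < min_probes:
            dropped[region] = len(present)
            continue
        rows = frame.values[[probe_index[p] for p in present], :]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN slices
            cols[region] = np.nanmean(rows, axis=0)
        probes_per_region[region] = len(present)
    if n_absent:
        logger.warning("%d mapped probes absent from the beta matrix; dropped", n_absent)
    if dropped:
        logger.warning(
            "%d regions dropped with < %d probes present: %s",
            len(dropped), min_probes, sorted(dropped)[:10],
        )
    if not cols:
        raise InputError(
            f"no region retained >= {min_probes} probes; cannot build features"
        )
    values = pd.DataFrame(cols, index=pd.Index(betas.sample_ids, name="sample_id"))
    n_missing = int(values.isna().sum().sum())
    if n_missing:
        logger.warning("%d region-mean entries are missing (all probes NaN)", n_missing)
    return RegionFeatureMatrix(values=values, probes_per_region=probes_per_region,
                               dropped_regions=dropped)


def build_features(
    betas: BetaMatrix,
    manifest: pd.DataFrame,
    regions: RegionSet | None,
    design: str = "regional",
    min_probes: int = 1,
) -> RegionFeatureMatrix:
    """Build the feature matrix for one of the model designs.

    ``regional``: one mean-beta feature per region. ``cpg``: one feature
    per probe falling inside any region. ``entire_array``: one feature
    per probe on the array (regions ignored).
    """
    if design not in DESIGNS:
        raise ValueError(f"unknown design {design!r}; expected one of {DESIGNS}")
    if design == "regional":
        if regions is None:
            raise InputError("regional design requires a region set")
        mapping = map_probes_to_regions(manifest, regions)
        return aggregate_region_means(betas, mapping, min_probes=min_probes)
    if design == "cpg":
        if regions is None:
            raise InputError("cpg design requires a region set")
        mapping = map_probes_to_regions(manifest, regions)
        in_region: list[str] = []
        seen: set[str] = set()
        for probes in mapping.values():
            for p in probes:
                if p not in seen:
                    seen.add(p)
                    in_region.append(p)
        present = [p for p in in_region if p in set(betas.probe_ids)]
        if not present:
            raise InputError("no in-region probe present in the beta matrix")
        frame = betas.to_frame().loc[present].T
        frame.index.name = "sample_id"
        return RegionFeatureMatrix(values=frame,
                                   probes_per_region={p: 1 for p in present})
    # entire_array
    frame = betas.to_frame().T
    frame.index.name = "sample_id"
    return RegionFeatureMatrix(values=frame,
                               probes_per_region={p: 1 for p in betas.probe_ids})
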