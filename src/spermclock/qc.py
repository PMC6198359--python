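"""Somatic-contamination screening for sperm methylation profiles.

Sperm and somatic tissues have opposite methylation states at a handful
of discriminating loci (the imprinted DLK1 locus is the canonical
example: essentially unmethylated in pure sperm, heavily methylated in
blood and other somatic tissue). A sample whose mean beta at a majority
of panel loci deviates toward the somatic state by more than a threshold
is flagged as possibly contaminated.

The packaged default panel holds the DLK1 interval plus two loci named
``SYN_PANEL_*`` that are synthetic — they exist so simulated cohorts can
carry a multi-locus panel — and users can supply their own panel CSV.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import InputError, ValidationError
from .io import BetaMatrix, Region, RegionSet
from .regions import map_probes_to_regions

#: default expected beta ranges for the two methylation states
STATE_BOUNDS = {"low": (0.0, 0.15), "high": (0.70, 1.0)}


@dataclass(frozen=True)
class PanelLocus:
    """One sperm-vs-soma discriminating locus with expected beta ranges."""

    name: str
    region: Region
    sperm_low: float
    sperm_high: float
    somatic_low: float
    somatic_high: float

    def __post_init__(self) -> None:
        sperm = (self.sperm_low + self.sperm_high) / 2
        somatic = (self.somatic_low + self.somatic_high) / 2
        if sperm == somatic:
            raise ValidationError(
                f"panel locus {self.name}: sperm and somatic states do not differ"
            )

    @property
    def somatic_is_higher(self) -> bool:
        return (self.somatic_low + self.somatic_high) > (self.sperm_low + self.sperm_high)


def load_panel(path: str | Path) -> list[PanelLocus]:
    """Read a panel CSV (locus, chrom, start, stop, sperm_state, somatic_state)."""
    frame = pd.read_csv(path)
    required = {"locus", "chrom", "start", "stop", "sperm_state", "somatic_state"}
    if not required.issubset(frame.columns):
        raise ValidationError(f"panel file {path} must have columns {sorted(required)}")
    loci = []
    for _, row in frame.iterrows():
        for col in ("sperm_state", "somatic_state"):
            if row[col] not in STATE_BOUNDS:
                raise ValidationError(
                    f"panel locus {row['locus']}: {col} must be one of "
                    f"{sorted(STATE_BOUNDS)}, got {row[col]!r}"
                )
        sperm = STATE_BOUNDS[row["sperm_state"]]
        somatic = STATE_BOUNDS[row["somatic_state"]]
        loci.append(PanelLocus(
            name=str(row["locus"]),
            region=Region(name=str(row["locus"]), chromosome=str(row["chrom"]),
                          start=int(row["start"]), stop=int(row["stop"])),
            sperm_low=sperm[0], sperm_high=sperm[1],
            somatic_low=somatic[0], somatic_high=somatic[1],
        ))
    return loci


def default_panel() -> list[PanelLocus]:
    path = resources.files("spermclock.data").joinpath("contamination_panel.csv")
    with resources.as_file(path) as p:
        return load_panel(p)


@dataclass
class ContaminationReport:
    per_locus_means: pd.DataFrame   # samples x loci mean beta (NaN: no probes)
    flagged: pd.Series              # bool per sample
    probes_per_locus: dict[str, int]
    threshold: float

    def to_frame(self) -> pd.DataFrame:
        out = self.per_locus_means.copy()
        out["flagged"] = self.flagged
        return out

    def write_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", na_rep="NA", index_label="sample_id")


def contamination_screen(
    betas: BetaMatrix,
    manifest: pd.DataFrame,
    panel: list[PanelLocus] | None = None,
    threshold: float = 0.2,
) -> ContaminationReport:
    """Flag samples whose panel loci drift toward the somatic state.

    A locus counts against a sample when its mean beta deviates beyond
    the expected sperm range toward the somatic state by more than
    ``threshold`` (absolute beta units); a sample is flagged when a
    strict majority of loci with probe coverage count against it.
    """
    if panel is None:
        panel = default_panel()
    regions = RegionSet([locus.region for locus in panel])
    mapping = map_probes_to_regions(manifest, regions)
    covered = [locus for locus in panel if mapping.get(locus.name)]
    if not covered:
        raise InputError("no panel locus has any probe in the beta matrix")

    frame = betas.to_frame()
    probe_pos = {p: i for i, p in enumerate(betas.probe_ids)}
    means: dict[str, np.ndarray] = {}
    probes_per_locus: dict[str, int] = {}
    locus_flag = {}
    for locus in covered:
        present = [p for p in mapping[locus.name] if p in probe_pos]
        if not present:
            continue
        rows = frame.values[[probe_pos[p] for p in present], :]
        mean = np.nanmean(rows, axis=0)
        means[locus.name] = mean
        probes_per_locus[locus.name] = len(present)
        if locus.somatic_is_higher:
            locus_flag[locus.name] = mean > locus.sperm_high + threshold
        else:
            locus_flag[locus.name] = mean < locus.sperm_low - threshold
    if not means:
        raise InputError("no panel locus has any probe in the beta matrix")

    mean_frame = pd.DataFrame(means, index=pd.Index(betas.sample_ids, name="sample_id"))
    flags = pd.DataFrame(locus_flag, index=mean_frame.index)
    evaluable = mean_frame.notna().sum(axis=1)
    flagged = (flags & mean_frame.notna()).sum(axis=1) > evaluable / 2.0
    return ContaminationReport(per_locus_means=mean_frame, flagged=flagged,
                               probes_per_locus=probes_per_locus, threshold=threshold)
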