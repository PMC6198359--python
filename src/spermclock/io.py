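"""Readers, writers and domain containers for methylation-array data.

Input formats are deliberately plain text: beta matrices as TSV/CSV
(probes as rows, samples as columns), probe manifests and sample metadata
as delimited tables, genomic regions as either BED or a simple
``name,chr,start,stop`` CSV dialect. Fitted clock models are serialized
as versioned JSON documents.

Coordinate convention: all regions are stored 1-based with inclusive
endpoints. BED input (0-based, half-open) is converted on read; BED
output is converted back on write.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Iterator, Sequence

import numpy as np
import pandas as pd

from .exceptions import FormatError, ValidationError, VersionError

MISSING_TOKENS = ["", "NA", "NaN", "nan"]

SMOKING_LEVELS = ("never", "smoker", "long_term_smoker", "unknown")
TISSUE_LEVELS = ("sperm", "somatic", "unknown")


def _infer_delimiter(path: str | Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    suffix = Path(path).suffix.lower()
    return "\t" if suffix in {".tsv", ".txt", ".bed"} else ","


# ---------------------------------------------------------------------------
# Beta matrix
# ---------------------------------------------------------------------------


@dataclass
class BetaMatrix:
    """Probe x sample fraction-methylation matrix.

    ``values[i, j]`` is the beta value of probe ``probe_ids[i]`` in sample
    ``sample_ids[j]``; each non-missing entry lies in [0, 1] and missing
    measurements are ``NaN``.
    """

    probe_ids: list[str]
    sample_ids: list[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.probe_ids = [str(p) for p in self.probe_ids]
        self.sample_ids = [str(s) for s in self.sample_ids]
        self.values = np.asarray(self.values, dtype=float)
        self.validate()

    def validate(self) -> None:
        if self.values.shape != (len(self.probe_ids), len(self.sample_ids)):
            raise ValidationError(
                f"beta matrix shape {self.values.shape} does not match "
                f"{len(self.probe_ids)} probes x {len(self.sample_ids)} samples"
            )
        if len(set(self.probe_ids)) != len(self.probe_ids):
            dupes = pd.Index(self.probe_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValidationError(f"duplicate probe IDs: {dupes[:5]}")
        if len(set(self.sample_ids)) != len(self.sample_ids):
            dupes = pd.Index(self.sample_ids)
            dupes = sorted(dupes[dupes.duplicated()].unique())
            raise ValidationError(f"duplicate sample IDs: {dupes[:5]}")
        with np.errstate(invalid="ignore"):
            bad = (self.values < 0.0) | (self.values > 1.0)
        if bad.any():
            i, j = np.argwhere(bad)[0]
            raise ValidationError(
                f"beta value out of [0, 1]: probe {self.probe_ids[i]!r}, "
                f"sample {self.sample_ids[j]!r}, value {self.values[i, j]!r}"
            )

    @property
    def n_probes(self) -> int:
        return len(self.probe_ids)

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values, index=pd.Index(self.probe_ids, name="probe_id"),
            columns=self.sample_ids,
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BetaMatrix":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy(dtype=float))

    def subset_samples(self, sample_ids: Sequence[str]) -> "BetaMatrix":
        idx = {s: j for j, s in enumerate(self.sample_ids)}
        cols = [idx[s] for s in sample_ids]
        return BetaMatrix(list(self.probe_ids), list(sample_ids), self.values[:, cols])


def load_beta_matrix(path: str | Path, delimiter: str | None = None) -> BetaMatrix:
    """Read a probe x sample beta matrix from delimited text.

    First column holds probe IDs, the header row holds sample IDs. Empty
    cells and ``NA`` are read as missing (NaN), never as zero.
    """
    sep = _infer_delimiter(path, delimiter)
    try:
        frame = pd.read_csv(
            path, sep=sep, index_col=0, na_values=MISSING_TOKENS,
            keep_default_na=False, float_precision="round_trip",
        )
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse beta matrix {path}: {exc}") from exc
    if frame.shape[1] == 0:
        raise FormatError(f"beta matrix {path} has no sample columns (delimiter {sep!r}?)")
    non_numeric = [c for c in frame.columns if not pd.api.types.is_numeric_dtype(frame[c])]
    if non_numeric:
        raise FormatError(
            f"beta matrix {path}: non-numeric values in sample column(s) {non_numeric[:3]}"
        )
    return BetaMatrix.from_frame(frame)


def write_beta_matrix(betas: BetaMatrix, path: str | Path, delimiter: str | None = None) -> None:
    sep = _infer_delimiter(path, delimiter)
    betas.to_frame().to_csv(path, sep=sep, na_rep="NA")


# ---------------------------------------------------------------------------
# Probe manifest
# ---------------------------------------------------------------------------


def load_probe_manifest(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read a probe manifest (columns ``probe_id``, ``chrom``, ``pos``, 1-based)."""
    sep = _infer_delimiter(path, delimiter)
    frame = pd.read_csv(path, sep=sep)
    required = {"probe_id", "chrom", "pos"}
    if not required.issubset(frame.columns):
        raise FormatError(
            f"manifest {path} must have columns {sorted(required)}, got {list(frame.columns)}"
        )
    frame = frame[["probe_id", "chrom", "pos"]].copy()
    frame["probe_id"] = frame["probe_id"].astype(str)
    frame["chrom"] = frame["chrom"].astype(str)
    return validate_manifest(frame)


def validate_manifest(manifest: pd.DataFrame) -> pd.DataFrame:
    if manifest["probe_id"].duplicated().any():
        dupes = sorted(manifest.loc[manifest["probe_id"].duplicated(), "probe_id"].unique())
        raise ValidationError(f"duplicate probe IDs in manifest: {dupes[:5]}")
    if not pd.api.types.is_integer_dtype(manifest["pos"]):
        try:
            manifest["pos"] = manifest["pos"].astype(np.int64)
        except (ValueError, TypeError) as exc:
            raise ValidationError(f"manifest positions must be integers: {exc}") from exc
    if (manifest["pos"] < 1).any():
        raise ValidationError("manifest positions must be >= 1 (1-based coordinates)")
    return manifest


def write_probe_manifest(manifest: pd.DataFrame, path: str | Path,
                         delimiter: str | None = None) -> None:
    manifest.to_csv(path, sep=_infer_delimiter(path, delimiter), index=False)


# ---------------------------------------------------------------------------
# Regions
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Region:
    """A named genomic interval, 1-based with inclusive endpoints."""

    name: str
    chromosome: str
    start: int
    stop: int

    def __post_init__(self) -> None:
        if self.start < 1:
            raise ValidationError(f"region {self.name}: start {self.start} < 1")
        if self.start > self.stop:
            raise ValidationError(
                f"region {self.name}: start {self.start} > stop {self.stop}"
            )

    @property
    def length(self) -> int:
        return self.stop - self.start + 1


class RegionSet:
    """An ordered collection of uniquely named regions."""

    def __init__(self, regions: Iterable[Region]):
        self.regions = list(regions)
        names = [r.name for r in self.regions]
        if len(set(names)) != len(names):
            dupes = sorted(pd.Index(names)[pd.Index(names).duplicated()].unique())
            raise ValidationError(f"duplicate region names: {dupes[:5]}")
        self._by_name = {r.name: r for r in self.regions}

    def __len__(self) -> int:
        return len(self.regions)

    def __iter__(self) -> Iterator[Region]:
        return iter(self.regions)

    def __getitem__(self, name: str) -> Region:
        return self._by_name[name]

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [r.name for r in self.regions]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "name": [r.name for r in self.regions],
                "chr": [r.chromosome for r in self.regions],
                "start": [r.start for r in self.regions],
                "stop": [r.stop for r in self.regions],
            }
        )

    def write_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False)

    def write_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for r in self.regions:
                fh.write(f"{r.chromosome}\t{r.start - 1}\t{r.stop}\t{r.name}\n")


def _parse_coord(token: str, where: str) -> int:
    try:
        return int(str(token).replace(",", "").strip())
    except ValueError as exc:
        raise FormatError(f"cannot parse coordinate {token!r} in {where}") from exc


def parse_region_table(path: str | Path, dialect: str = "table1") -> RegionSet:
    """Read genomic regions from a region table.

    ``table1`` dialect: CSV with columns name, chr, start, stop; 1-based
    inclusive coordinates, commas inside numbers tolerated. ``bed``
    dialect: standard BED with at least 4 columns (chrom, start, end,
    name), 0-based half-open, converted to 1-based inclusive on read.
    """
    if dialect == "table1":
        frame = pd.read_csv(path, dtype=str, skipinitialspace=True)
        frame.columns = [c.strip().lower() for c in frame.columns]
        required = {"name", "chr", "start", "stop"}
        if not required.issubset(frame.columns):
            raise FormatError(
                f"table1 region file {path} must have columns {sorted(required)}"
            )
        regions = [
            Region(
                name=str(row["name"]).strip(),
                chromosome=str(row["chr"]).strip(),
                start=_parse_coord(row["start"], f"{path} row {i}"),
                stop=_parse_coord(row["stop"], f"{path} row {i}"),
            )
            for i, row in frame.iterrows()
        ]
        return RegionSet(regions)
    if dialect == "bed":
        regions = []
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.rstrip("\n")
                if not line or line.startswith(("track", "browser", "#")):
                    continue
                parts = line.split("\t")
                if len(parts) == 1:
                    parts = line.split()
                if len(parts) < 4:
                    raise FormatError(
                        f"BED file {path} line {i + 1}: need >= 4 columns "
                        "(chrom, start, end, name)"
                    )
                chrom, start, end, name = parts[0], parts[1], parts[2], parts[3]
                regions.append(
                    Region(
                        name=name,
                        chromosome=chrom,
                        start=_parse_coord(start, f"{path} line {i + 1}") + 1,
                        stop=_parse_coord(end, f"{path} line {i + 1}"),
                    )
                )
        return RegionSet(regions)
    raise ValueError(f"unknown region dialect {dialect!r}; expected 'table1' or 'bed'")


def load_table1_regions() -> RegionSet:
    """The packaged clock region set (50 named ~1 kb intervals)."""
    path = resources.files("spermclock.data").joinpath("table1_regions.csv")
    with resources.as_file(path) as p:
        return parse_region_table(p, dialect="table1")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------


def load_sample_metadata(path: str | Path, delimiter: str | None = None) -> pd.DataFrame:
    """Read per-sample metadata.

    Requires ``sample_id`` and ``age`` columns; ``smoking_status``,
    ``replicate_group`` and ``tissue`` are optional and default to
    ``unknown`` / absent. Extra columns are carried through untouched.
    """
    sep = _infer_delimiter(path, delimiter)
    frame = pd.read_csv(path, sep=sep, na_values=MISSING_TOKENS, keep_default_na=False)
    if "sample_id" not in frame.columns or "age" not in frame.columns:
        raise FormatError(f"metadata {path} must have 'sample_id' and 'age' columns")
    frame["sample_id"] = frame["sample_id"].astype(str)
    return validate_metadata(frame)


def validate_metadata(frame: pd.DataFrame) -> pd.DataFrame:
    frame = frame.copy()
    if frame["sample_id"].duplicated().any():
        dupes = sorted(frame.loc[frame["sample_id"].duplicated(), "sample_id"].unique())
        raise ValidationError(f"duplicate sample IDs in metadata: {dupes[:5]}")
    frame["age"] = pd.to_numeric(frame["age"], errors="raise")
    present = frame["age"].notna()
    if (frame.loc[present, "age"] <= 0).any():
        bad = frame.loc[present & (frame["age"] <= 0), "sample_id"].tolist()
        raise ValidationError(f"non-positive ages for samples {bad[:5]}")
    if "smoking_status" not in frame.columns:
        frame["smoking_status"] = "unknown"
    frame["smoking_status"] = frame["smoking_status"].fillna("unknown").astype(str)
    bad_levels = set(frame["smoking_status"]) - set(SMOKING_LEVELS)
    if bad_levels:
        raise ValidationError(
            f"unknown smoking_status values {sorted(bad_levels)}; "
            f"expected one of {SMOKING_LEVELS}"
        )
    if "tissue" not in frame.columns:
        frame["tissue"] = "unknown"
    frame["tissue"] = frame["tissue"].fillna("unknown").astype(str)
    bad_tissue = set(frame["tissue"]) - set(TISSUE_LEVELS)
    if bad_tissue:
        raise ValidationError(
            f"unknown tissue values {sorted(bad_tissue)}; expected one of {TISSUE_LEVELS}"
        )
    if "replicate_group" not in frame.columns:
        frame["replicate_group"] = pd.NA
    return frame


def write_sample_metadata(frame: pd.DataFrame, path: str | Path,
                          delimiter: str | None = None) -> None:
    frame.to_csv(path, sep=_infer_delimiter(path, delimiter), index=False, na_rep="")


# ---------------------------------------------------------------------------
# Clock model serialization
# ---------------------------------------------------------------------------

MODEL_SCHEMA_VERSION = 1


def save_model(model, path: str | Path) -> None:
    """Serialize a fitted ClockModel to a versioned JSON document.

    Floats are written with shortest round-trip representation, so a
    reloaded model reproduces predictions bit-for-bit.
    """
    doc = {
        "schema_version": MODEL_SCHEMA_VERSION,
        "region_names": list(model.region_names),
        "coefficients": [float(c) for c in model.coefficients],
        "intercept": float(model.intercept),
        "alpha": float(model.alpha),
        "lambda": float(model.lam),
        "feature_means": [float(m) for m in model.feature_means],
        "seed": model.seed,
        "provenance": dict(model.provenance),
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=1)
        fh.write("\n")


def load_model(path: str | Path):
    from .model import ClockModel  # local import to avoid a cycle

    try:
        with open(path) as fh:
            doc = json.load(fh)
    except (json.JSONDecodeError, UnicodeDecodeError) as exc:
        raise FormatError(f"cannot parse model file {path}: {exc}") from exc
    version = doc.get("schema_version")
    if version != MODEL_SCHEMA_VERSION:
        raise VersionError(
            f"model file {path} has schema_version {version!r}; "
            f"this build reads version {MODEL_SCHEMA_VERSION}"
        )
    for key in ("region_names", "coefficients", "intercept", "feature_means"):
        if key not in doc:
            raise FormatError(f"model file {path} missing field {key!r}")
    n = len(doc["region_names"])
    if len(doc["coefficients"]) != n or len(doc["feature_means"]) != n:
        raise ValidationError(
            f"model file {path}: {n} regions but {len(doc['coefficients'])} "
            f"coefficients / {len(doc['feature_means'])} feature means"
        )
    return ClockModel(
        region_names=list(doc["region_names"]),
        coefficients=np.asarray(doc["coefficients"], dtype=float),
        intercept=float(doc["intercept"]),
        alpha=float(doc.get("alpha", 0.5)),
        lam=float(doc.get("lambda", 0.0)),
        feature_means=np.asarray(doc["feature_means"], dtype=float),
        seed=doc.get("seed"),
        provenance=doc.get("provenance", {}),
    )
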