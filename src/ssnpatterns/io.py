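"""Readers and writers for the package's plain-text interchange formats.

Sequences travel as FASTA (via Biopython); abundance, metadata and taxonomy
tables as TSV with a header row.  Metadata rows carry 14 descriptive columns
plus the 10 environmental variables; missing environmental values are empty
cells.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import pandas as pd
import yaml
from Bio import SeqIO

from .core import (
    ENV_VARIABLES,
    RANKS,
    SampleMetadata,
    TaxonomyPath,
    validate_abundance,
)

__all__ = [
    "read_fasta",
    "write_fasta",
    "read_abundance",
    "write_abundance",
    "read_metadata",
    "write_metadata",
    "read_taxonomy",
    "write_taxonomy",
    "read_tables",
    "load_config",
]

_METADATA_COLUMNS = [
    "sample_id",
    "dataset",
    "region",
    "station",
    "date",
    "depth_m",
    "depth_type",
    "size_fraction",
    "latitude",
    "longitude",
] + [name for name, _ in ENV_VARIABLES]


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Read a FASTA file into ``(id, uppercased sequence)`` pairs.

    Record order is preserved.  Duplicate ids and empty sequences raise a
    format error naming the offending record.
    """
    out: list[tuple[str, str]] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: record {rec.id!r} has an empty sequence")
        if rec.id in seen:
            raise ValueError(f"{path}: duplicate record id {rec.id!r}")
        seen.add(rec.id)
        out.append((rec.id, seq))
    return out


def write_fasta(path: str | Path, entries: list[tuple[str, str]]) -> None:
    with open(path, "w") as fh:
        for rid, seq in entries:
            fh.write(f">{rid}\n{seq}\n")


def read_abundance(path: str | Path) -> pd.DataFrame:
    """Read a metabarcode-by-sample TSV (first column = metabarcode id)."""
    table = pd.read_csv(path, sep="\t", index_col=0)
    table.index = table.index.astype(str)
    table.columns = table.columns.astype(str)
    validate_abundance(table)
    return table


def write_abundance(path: str | Path, table: pd.DataFrame) -> None:
    table.to_csv(path, sep="\t", index_label="metabarcode_id")


def read_taxonomy(path: str | Path) -> dict[str, TaxonomyPath]:
    """Read a TSV with one id column followed by the eight rank columns."""
    frame = pd.read_csv(path, sep="\t", dtype=str).fillna("Unknown")
    missing = [r for r in RANKS if r not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing rank column(s) {missing}")
    id_col = frame.columns[0]
    out: dict[str, TaxonomyPath] = {}
    for _, row in frame.iterrows():
        rid = str(row[id_col])
        if rid in out:
            raise ValueError(f"{path}: duplicate taxonomy id {rid!r}")
        out[rid] = TaxonomyPath(tuple(row[r] for r in RANKS))
    return out


def write_taxonomy(path: str | Path, taxonomy: dict[str, TaxonomyPath]) -> None:
    rows = [{"metabarcode_id": rid, **tax.as_dict()} for rid, tax in taxonomy.items()]
    pd.DataFrame(rows, columns=["metabarcode_id", *RANKS]).to_csv(
        path, sep="\t", index=False
    )


def read_metadata(path: str | Path) -> list[SampleMetadata]:
    frame = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "station": str})
    missing = [c for c in _METADATA_COLUMNS[:7] if c not in frame.columns]
    if missing:
        raise ValueError(f"{path}: missing metadata column(s) {missing}")
    samples: list[SampleMetadata] = []
    seen: set[str] = set()
    env_names = [name for name, _ in ENV_VARIABLES]
    for _, row in frame.iterrows():
        sid = str(row["sample_id"])
        if sid in seen:
            raise ValueError(f"{path}: duplicate sample id {sid!r}")
        seen.add(sid)
        env = {}
        for name in env_names:
            if name in frame.columns and pd.notna(row[name]):
                env[name] = float(row[name])
        samples.append(
            SampleMetadata(
                sample_id=sid,
                dataset=str(row["dataset"]),
                region=str(row["region"]),
                station=str(row.get("station", "")),
                date=_dt.date.fromisoformat(str(row["date"])),
                depth_m=float(row["depth_m"]),
                depth_type=str(row["depth_type"]),
                size_fraction=str(row.get("size_fraction", "")),
                latitude=float(row.get("latitude", float("nan"))),
                longitude=float(row.get("longitude", float("nan"))),
                env=env,
            )
        )
    return samples


def write_metadata(path: str | Path, samples: list[SampleMetadata]) -> None:
    rows = []
    for s in samples:
        row = {
            "sample_id": s.sample_id,
            "dataset": s.dataset,
            "region": s.region,
            "station": s.station,
            "date": s.date.isoformat(),
            "depth_m": s.depth_m,
            "depth_type": s.depth_type,
            "size_fraction": s.size_fraction,
            "latitude": s.latitude,
            "longitude": s.longitude,
        }
        for name, _ in ENV_VARIABLES:
            row[name] = s.env.get(name, None)
        rows.append(row)
    pd.DataFrame(rows, columns=_METADATA_COLUMNS).to_csv(path, sep="\t", index=False)


def read_tables(
    abundance_path: str | Path,
    metadata_path: str | Path,
    taxonomy_path: str | Path,
    regions: tuple[str, ...] | None = None,
) -> tuple[pd.DataFrame, list[SampleMetadata], dict[str, TaxonomyPath]]:
    """Load and cross-validate the three tabular inputs.

    Every abundance row id must have a taxonomy entry and every column id a
    metadata row; violations raise listing the offenders.  When ``regions``
    is given, each sample's region must be in that vocabulary.
    """
    table = read_abundance(abundance_path)
    samples = read_metadata(metadata_path)
    taxonomy = read_taxonomy(taxonomy_path)

    no_tax = sorted(set(table.index) - set(taxonomy))
    if no_tax:
        raise ValueError(f"metabarcodes without taxonomy: {no_tax[:10]}")
    sample_ids = {s.sample_id for s in samples}
    no_meta = sorted(set(table.columns) - sample_ids)
    if no_meta:
        raise ValueError(f"samples without metadata: {no_meta[:10]}")
    if regions is not None:
        bad = sorted({s.region for s in samples} - set(regions))
        if bad:
            raise ValueError(f"regions outside the configured vocabulary: {bad}")
    return table, samples, taxonomy


def load_config(path: str | Path) -> dict:
    """Load a YAML run configuration (region vocabulary, thresholds, seeds)."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: configuration must be a mapping")
    return cfg
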