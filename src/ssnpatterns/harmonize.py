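"""Per-dataset homogenization filters and multi-dataset merging.

Heterogeneous metabarcoding projects are made comparable by applying the same
screens to each dataset independently — removal of multicellular taxa
(metazoans, land plants, macroalgae), of sequences with weak reference-database
support (<80% best-hit identity) and of short sequences (<=200 bp) — before
merging abundance tables on the union of samples and renormalizing.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .core import MetabarcodeRecord, normalize_samples

__all__ = [
    "DEFAULT_BLOCKLIST",
    "FilterReport",
    "DatasetInput",
    "filter_blocklist",
    "filter_identity",
    "filter_length",
    "harmonize",
]

#: Multicellular taxa screened out at any rank: metazoans, terrestrial plants
#: and the four macroalgal classes.
DEFAULT_BLOCKLIST = frozenset(
    {
        "Metazoa",
        "Streptophyta",
        "Florideophyceae",
        "Bangiophyceae",
        "Phaeophyceae",
        "Ulvophyceae",
    }
)


@dataclass
class FilterReport:
    """Per-dataset accounting of the homogenization filters.

    Removals are attributed to the first failing predicate in the order
    blocklist, identity, length; counts always sum back to the input size.
    """

    dataset: str
    removed_blocklist: int = 0
    removed_low_identity: int = 0
    removed_short: int = 0
    retained: int = 0

    @property
    def input_count(self) -> int:
        return (
            self.removed_blocklist
            + self.removed_low_identity
            + self.removed_short
            + self.retained
        )


@dataclass
class DatasetInput:
    """One dataset: its records and its metabarcode-by-sample count table."""

    name: str
    records: list[MetabarcodeRecord]
    abundance: pd.DataFrame


def _blocklisted(record: MetabarcodeRecord, blocklist: frozenset[str]) -> bool:
    return any(label in blocklist for label in record.taxonomy.ranks)


def _low_identity(
    record: MetabarcodeRecord, min_identity: float, keep_missing: bool
) -> bool:
    ident = record.best_ref_identity
    if ident is None:
        return not keep_missing
    return ident < min_identity


def filter_blocklist(
    records: list[MetabarcodeRecord],
    blocklist: frozenset[str] = DEFAULT_BLOCKLIST,
) -> tuple[list[MetabarcodeRecord], int]:
    """Drop records whose taxonomy matches the blocklist at any rank."""
    kept = [r for r in records if not _blocklisted(r, blocklist)]
    return kept, len(records) - len(kept)


def filter_identity(
    records: list[MetabarcodeRecord],
    min_identity: float = 80.0,
    keep_missing: bool = True,
) -> tuple[list[MetabarcodeRecord], int]:
    """Drop records whose best reference identity is strictly below the cutoff.

    Records without an identity value are kept by default (the screen was
    designed for inputs where identity was computed upstream).
    """
    kept = [r for r in records if not _low_identity(r, min_identity, keep_missing)]
    return kept, len(records) - len(kept)


def filter_length(
    records: list[MetabarcodeRecord], min_len: int = 200
) -> tuple[list[MetabarcodeRecord], int]:
    """Keep only sequences strictly longer than ``min_len`` bp."""
    kept = [r for r in records if len(r) > min_len]
    return kept, len(records) - len(kept)


def harmonize(
    datasets: list[DatasetInput],
    blocklist: frozenset[str] = DEFAULT_BLOCKLIST,
    min_identity: float = 80.0,
    min_len: int = 200,
    keep_missing_identity: bool = True,
) -> tuple[list[MetabarcodeRecord], pd.DataFrame, list[FilterReport]]:
    """Filter each dataset independently, then merge into one normalized table.

    Filters are applied per record in the order blocklist -> identity ->
    length, with removal attributed to the first failing predicate (the
    retained set does not depend on the order).  Metabarcode ids duplicated
    across datasets are namespaced as ``<dataset>|<id>``.  The merged table
    covers the union of samples, absent entries are zero, and every sample is
    renormalized to relative abundances.
    """
    if not datasets:
        raise ValueError("no datasets to harmonize")

    reports: list[FilterReport] = []
    retained: list[MetabarcodeRecord] = []
    tables: list[pd.DataFrame] = []
    all_ids: dict[str, int] = {}
    for ds in datasets:
        for rec in ds.records:
            all_ids[rec.id] = all_ids.get(rec.id, 0) + 1

    for ds in datasets:
        report = FilterReport(dataset=ds.name)
        kept_ids: list[str] = []
        rename: dict[str, str] = {}
        for rec in ds.records:
            if _blocklisted(rec, blocklist):
                report.removed_blocklist += 1
            elif _low_identity(rec, min_identity, keep_missing_identity):
                report.removed_low_identity += 1
            elif len(rec) <= min_len:
                report.removed_short += 1
            else:
                report.retained += 1
                if all_ids[rec.id] > 1:
                    new_id = f"{ds.name}|{rec.id}"
                    rename[rec.id] = new_id
                    rec = MetabarcodeRecord(
                        id=new_id,
                        sequence=rec.sequence,
                        dataset=rec.dataset,
                        taxonomy=rec.taxonomy,
                        short_amplicon=rec.short_amplicon,
                        best_ref_identity=rec.best_ref_identity,
                    )
                retained.append(rec)
                kept_ids.append(rec.id)
        reports.append(report)
        sub = ds.abundance.rename(index=rename)
        sub = sub.loc[sub.index.intersection(kept_ids)]
        if not sub.empty:
            tables.append(sub)

    if not tables:
        raise ValueError("all records were filtered out of every dataset")
    merged = pd.concat(tables, axis=0).fillna(0.0)
    merged = merged.groupby(level=0).sum()  # defensive; ids are unique by now
    merged = merged.loc[:, merged.sum(axis=0) > 0]
    merged = normalize_samples(merged)
    order = [r.id for r in retained if r.id in set(merged.index)]
    merged = merged.reindex(order)
    return retained, merged, reports
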