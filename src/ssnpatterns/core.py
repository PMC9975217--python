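"""Domain types and shared semantics for metabarcoding pattern analysis.

The package operates on 18S rDNA V4 metabarcodes (representative sequences of
read clusters) gathered from heterogeneous sampling projects.  This module
holds the vocabulary every other stage relies on:

* an eight-rank taxonomy path with an explicit ``"Unknown"`` sentinel and the
  distinction between *unassigned* ranks and *gaps* in the hierarchy,
* per-sample metadata including depth-layer classification,
* relative-abundance normalization of metabarcode-by-sample count tables.

Abundance tables are plain :class:`pandas.DataFrame` objects with metabarcode
ids as the index and sample ids as columns; no wrapper class is introduced.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

__all__ = [
    "RANKS",
    "UNKNOWN",
    "DEPTH_TYPES",
    "DEFAULT_REGIONS",
    "ENV_VARIABLES",
    "SEASONS",
    "TaxonomyPath",
    "MetabarcodeRecord",
    "SampleMetadata",
    "rank_status",
    "depth_layer",
    "season_of",
    "normalize_samples",
    "validate_abundance",
]

#: The eight taxonomic ranks of the PR2 reference hierarchy, most to least
#: inclusive.
RANKS = (
    "kingdom",
    "supergroup",
    "division",
    "class",
    "order",
    "family",
    "genus",
    "species",
)

#: Sentinel used for a rank without taxonomic assignment (case-sensitive).
UNKNOWN = "Unknown"

#: Depth-layer vocabulary.  SRF/DCM/MESO/BATHY are derived from depth and the
#: DCM flag; NET (vertical profile) and OTHER are accepted only as explicit
#: metadata values.
DEPTH_TYPES = ("SRF", "DCM", "MESO", "BATHY", "NET", "OTHER")

#: Default sea-region vocabulary of the integrated surveys.
DEFAULT_REGIONS = (
    "Mediterranean Sea",
    "Tropical/Subtropical Ocean",
    "English Channel",
    "Bay of Biscay",
    "North Sea",
    "Black Sea",
)

#: The ten homogenized environmental variables (name, unit).
ENV_VARIABLES = (
    ("temperature", "degC"),
    ("salinity", "PSU"),
    ("ph", "pH"),
    ("oxygen", "ml/L"),
    ("no3", "umol/L"),
    ("no2", "umol/L"),
    ("nh4", "umol/L"),
    ("po4", "umol/L"),
    ("sio4", "umol/L"),
    ("chla", "ug/L"),
)

#: Meteorological northern-hemisphere seasons, keyed by month.
SEASONS = {
    12: "DJF", 1: "DJF", 2: "DJF",
    3: "MAM", 4: "MAM", 5: "MAM",
    6: "JJA", 7: "JJA", 8: "JJA",
    9: "SON", 10: "SON", 11: "SON",
}


@dataclass(frozen=True)
class TaxonomyPath:
    """An ordered 8-rank taxonomic affiliation.

    Each rank label is either a non-empty name or the sentinel ``"Unknown"``.
    """

    ranks: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.ranks) != len(RANKS):
            raise ValueError(
                f"taxonomy path needs {len(RANKS)} ranks, got {len(self.ranks)}"
            )
        for name, label in zip(RANKS, self.ranks):
            if not label:
                raise ValueError(f"empty label at rank {name!r}")

    def __getitem__(self, rank: str) -> str:
        return self.ranks[_rank_index(rank)]

    @classmethod
    def from_mapping(cls, labels: Mapping[str, str]) -> "TaxonomyPath":
        return cls(tuple(labels.get(r, UNKNOWN) for r in RANKS))

    def as_dict(self) -> dict[str, str]:
        return dict(zip(RANKS, self.ranks))


@dataclass
class MetabarcodeRecord:
    """One metabarcode with dataset provenance and taxonomy.

    ``best_ref_identity`` is the percent identity of the best reference
    database hit (used only as a harmonization filter input; the package never
    recomputes it).  ``short_amplicon`` marks records from datasets whose
    amplicons are systematically shorter than the rest of the corpus, which
    relaxes the network coverage rule to their side only.
    """

    id: str
    sequence: str
    dataset: str
    taxonomy: TaxonomyPath
    short_amplicon: bool = False
    best_ref_identity: float | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r} has an empty sequence")
        seq = self.sequence.upper()
        if set(seq) - set("ACGTN"):
            bad = sorted(set(seq) - set("ACGTN"))
            raise ValueError(f"record {self.id!r} has non-IUPAC-core symbols {bad}")
        self.sequence = seq
        if self.best_ref_identity is not None and not (
            0.0 <= self.best_ref_identity <= 100.0
        ):
            raise ValueError(
                f"record {self.id!r}: identity {self.best_ref_identity} outside [0, 100]"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SampleMetadata:
    """Metadata for one sample: provenance, position, depth and environment."""

    sample_id: str
    dataset: str
    region: str
    station: str
    date: _dt.date
    depth_m: float
    depth_type: str
    size_fraction: str = ""
    latitude: float = float("nan")
    longitude: float = float("nan")
    env: dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.depth_m < 0:
            raise ValueError(f"sample {self.sample_id!r}: negative depth")
        if self.depth_type not in DEPTH_TYPES:
            raise ValueError(
                f"sample {self.sample_id!r}: unknown depth type {self.depth_type!r}"
            )


def _rank_index(rank: str) -> int:
    try:
        return RANKS.index(rank)
    except ValueError:
        raise KeyError(f"unknown taxonomic rank {rank!r}") from None


def rank_status(tax: TaxonomyPath, rank: str) -> str:
    """Classify one rank of a taxonomy path as assigned, unassigned or gap.

    A rank labelled ``"Unknown"`` is a *gap* when a more specific (lower) rank
    carries an assignment — the hierarchy skips a level rather than ending —
    and *unassigned* otherwise.  Ranks with any other label are *assigned*.
    """
    i = _rank_index(rank)
    if tax.ranks[i] != UNKNOWN:
        return "assigned"
    if any(label != UNKNOWN for label in tax.ranks[i + 1:]):
        return "gap"
    return "unassigned"


def depth_layer(depth_m: float, dcm_flag: bool = False) -> str:
    """Classify a sampling depth into a water-column layer.

    The deep chlorophyll maximum cannot be inferred from depth alone, so an
    explicit ``dcm_flag`` takes precedence.  Otherwise: surface at <=5 m,
    bathypelagic at >=1000 m, mesopelagic at >=200 m; depths in (5, 200)
    without a DCM flag fall into OTHER.
    """
    if depth_m < 0:
        raise ValueError(f"negative depth {depth_m}")
    if dcm_flag:
        return "DCM"
    if depth_m <= 5:
        return "SRF"
    if depth_m >= 1000:
        return "BATHY"
    if depth_m >= 200:
        return "MESO"
    return "OTHER"


def season_of(date: _dt.date) -> str:
    """Meteorological northern-hemisphere season (DJF/MAM/JJA/SON)."""
    return SEASONS[date.month]


def validate_abundance(table: pd.DataFrame) -> None:
    """Check structural invariants of a metabarcode-by-sample table."""
    if table.index.has_duplicates:
        dup = table.index[table.index.duplicated()].unique().tolist()
        raise ValueError(f"duplicate metabarcode ids: {dup}")
    if table.columns.has_duplicates:
        dup = table.columns[table.columns.duplicated()].unique().tolist()
        raise ValueError(f"duplicate sample ids: {dup}")
    values = table.to_numpy(dtype=float)
    if np.isnan(values).any():
        raise ValueError("abundance table contains missing values")
    if (values < 0).any():
        rows, cols = np.nonzero(values < 0)
        where = [(table.index[r], table.columns[c]) for r, c in zip(rows[:5], cols[:5])]
        raise ValueError(f"negative abundances at {where}")


def normalize_samples(table: pd.DataFrame) -> pd.DataFrame:
    """Convert each sample (column) to relative abundances summing to one.

    Each column is divided by its total, so values lie in [0, 1] and the zero
    pattern is preserved.  The operation is idempotent.  An all-zero sample
    has no defined composition and raises.
    """
    validate_abundance(table)
    sums = table.sum(axis=0)
    dead = sums.index[sums <= 0].tolist()
    if dead:
        raise ValueError(f"all-zero sample column(s): {dead}")
    return table.div(sums, axis=1)
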