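"""Synthetic multi-dataset metabarcoding corpus with planted ground truth.

The generator emulates the statistical structure of an integrated 18S-V4
metabarcoding corpus at desk scale: several sampling projects (two multi-depth
oceanographic surveys, one multi-region coastal project, three bimonthly
coastal time series, one of which yields systematically short amplicons),
groups of metabarcodes that are exact copies or long prefixes of a group
master sequence (guaranteeing in-group network edges at >=80% coverage),
masters engineered to share no long exact segment across groups (guaranteeing
no cross-group edges), region/depth occupancy drawn from a configurable
distribution over region combinations, multi-year bimonthly abundance series
with planted periodicities for a subset of groups, depth-structured
environmental variables, and partial taxonomic annotation with the
``"Unknown"`` sentinel.

All guarantees are constructive and re-verified at generation time, so
partition-recovery tests can assert exact equality rather than statistical
agreement.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass
from math import ceil
from pathlib import Path

import numpy as np

from .core import (
    DEFAULT_REGIONS,
    UNKNOWN,
    MetabarcodeRecord,
    SampleMetadata,
    TaxonomyPath,
    depth_layer,
)
from .harmonize import DatasetInput
from .io import write_abundance, write_fasta, write_metadata, write_taxonomy

import pandas as pd

__all__ = ["SyntheticSpec", "SyntheticTruth", "SyntheticDataset", "synthesize", "generate", "perturb"]

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

# region -> the spatial dataset that samples it
_PRIMARY_DATASET = {
    "Tropical/Subtropical Ocean": "survey_tropical",
    "Mediterranean Sea": "survey_med",
    "English Channel": "coastal_eu",
    "North Sea": "coastal_eu",
    "Black Sea": "coastal_eu",
    "Bay of Biscay": "coastal_eu",
}

#: time-series sites: name -> (region, short_amplicon dataset?)
_TS_SITES = {
    "ts_channel": ("English Channel", False),
    "ts_med_a": ("Mediterranean Sea", False),
    "ts_med_b": ("Mediterranean Sea", True),
}

# default distribution over region combinations (weights sum to 1); dominated
# by the pair Mediterranean/Tropical, with endemics, a few other pairs and
# triples, and a small ubiquitous fraction
_DEFAULT_COMBOS: list[tuple[frozenset[str], float]] = [
    (frozenset({"Tropical/Subtropical Ocean"}), 0.14),
    (frozenset({"Mediterranean Sea"}), 0.04),
    (frozenset({"English Channel"}), 0.04),
    (frozenset({"Mediterranean Sea", "Tropical/Subtropical Ocean"}), 0.40),
    (frozenset({"English Channel", "Tropical/Subtropical Ocean"}), 0.05),
    (frozenset({"Bay of Biscay", "Mediterranean Sea"}), 0.04),
    (frozenset({"Black Sea", "Mediterranean Sea"}), 0.03),
    (frozenset({"English Channel", "North Sea"}), 0.04),
    (frozenset({"Mediterranean Sea", "Tropical/Subtropical Ocean", "North Sea"}), 0.05),
    (frozenset({"Mediterranean Sea", "Tropical/Subtropical Ocean", "English Channel"}), 0.05),
    (
        frozenset(
            {"Mediterranean Sea", "Tropical/Subtropical Ocean", "English Channel", "Bay of Biscay"}
        ),
        0.04,
    ),
    (frozenset(DEFAULT_REGIONS), 0.08),
]

_GENUS_POOL = ("Amoebophrya", "Euduboscquella", "Hematodinium", "Syndinium")
_ORDER_POOL = ("Dino-Group-I", "Dino-Group-II", "Dino-Group-III", "Dino-Group-V")
_ORDER_WEIGHTS = (0.25, 0.55, 0.12, 0.08)

# surface temperature (degC) per region for the environmental model
_REGION_TEMP = {
    "Tropical/Subtropical Ocean": 26.0,
    "Mediterranean Sea": 19.0,
    "English Channel": 13.0,
    "North Sea": 11.0,
    "Black Sea": 14.0,
    "Bay of Biscay": 15.0,
}


@dataclass
class SyntheticSpec:
    """Tunable study conditions for the synthetic corpus."""

    n_groups: int = 40
    group_size_range: tuple[int, int] = (6, 10)
    n_decoys: int = 5
    decoy_size_range: tuple[int, int] = (1, 5)
    seq_len_range: tuple[int, int] = (380, 460)
    short_amplicon_len: int = 230
    regions: tuple[str, ...] = DEFAULT_REGIONS
    years: int = 8
    ts_participation: float = 0.8
    sparse_fraction: float = 0.15
    rhythmic_fraction: float = 0.1
    periods_days: tuple[float, ...] = (182.0, 365.0, 548.0)
    rhythmic_amplitude: float = 1.0
    snr: float = 2.0
    background_mean: float = 0.25
    background_sd: float = 0.12
    unassigned_genus_fraction: float = 0.85
    n_blocklisted: int = 4
    n_low_identity: int = 3
    n_short: int = 3
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_groups < 1 or self.group_size_range[0] < 6:
            raise ValueError("need >= 1 group of size >= 6")
        if self.group_size_range[0] > self.group_size_range[1]:
            raise ValueError("invalid group size range")
        if self.decoy_size_range[1] >= 6:
            raise ValueError("decoy groups must stay below the size-6 cutoff")
        if not 0 <= self.rhythmic_fraction <= 1:
            raise ValueError("rhythmic_fraction outside [0, 1]")
        if self.short_amplicon_len > self.seq_len_range[0]:
            raise ValueError("short amplicons longer than the shortest master")
        if self.snr <= 0:
            raise ValueError("snr must be positive")


@dataclass
class SyntheticTruth:
    """Planted ground truth serialized alongside the generated files."""

    partition: dict[str, list[str]]
    region_sets: dict[str, list[str]]
    rhythmic: dict[str, float]
    genus_labels: dict[str, str]
    decoy_groups: list[str]
    ts_sites: dict[str, str]

    def to_json(self) -> str:
        return json.dumps(
            {
                "partition": self.partition,
                "region_sets": {g: sorted(r) for g, r in self.region_sets.items()},
                "rhythmic": self.rhythmic,
                "genus_labels": self.genus_labels,
                "decoy_groups": self.decoy_groups,
                "ts_sites": self.ts_sites,
            },
            indent=1,
            sort_keys=True,
        )


@dataclass
class SyntheticDataset:
    """In-memory generated corpus: per-dataset inputs plus shared tables."""

    datasets: dict[str, DatasetInput]
    metadata: list[SampleMetadata]
    taxonomy: dict[str, TaxonomyPath]
    truth: SyntheticTruth


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode("ascii")


def _ts_dates(years: int) -> list[_dt.date]:
    dates = []
    for y in range(years):
        for m in range(1, 13):
            for d in (5, 20):
                dates.append(_dt.date(2012 + y, m, d))
    return dates


def _shares_kmer(kmers: dict[str, str], seq: str, k: int, owner: str) -> bool:
    """Register ``seq``'s k-mers under ``owner``; True if any k-mer is already
    owned by a different master (the cross-group exclusion check)."""
    for i in range(len(seq) - k + 1):
        sub = seq[i : i + k]
        prev = kmers.get(sub)
        if prev is not None and prev != owner:
            return True
    for i in range(len(seq) - k + 1):
        kmers[seq[i : i + k]] = owner
    return False


def synthesize(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate the corpus in memory; bit-reproducible for a fixed spec."""
    rng = np.random.default_rng(spec.seed)
    combos = [c for c, _ in _DEFAULT_COMBOS]
    weights = np.array([w for _, w in _DEFAULT_COMBOS])
    weights = weights / weights.sum()

    # --- samples & metadata -------------------------------------------------
    metadata: list[SampleMetadata] = []
    samples_by_dataset: dict[str, list[SampleMetadata]] = {}

    def add_sample(dataset, region, station, date, depth, dcm, lat, lon):
        layer = depth_layer(depth, dcm)
        sid = f"{dataset}_s{len(samples_by_dataset.get(dataset, [])):04d}"
        env = _environment(rng, region, depth, dcm, date)
        s = SampleMetadata(
            sample_id=sid, dataset=dataset, region=region, station=station,
            date=date, depth_m=depth, depth_type=layer, size_fraction="0.8-20um",
            latitude=lat, longitude=lon, env=env,
        )
        metadata.append(s)
        samples_by_dataset.setdefault(dataset, []).append(s)
        return s

    layer_depths = [(3.0, False), (45.0, True), (500.0, False), (1800.0, False)]
    for st in range(3):
        for depth, dcm in layer_depths:
            add_sample("survey_tropical", "Tropical/Subtropical Ocean", f"trop_st{st}",
                       _dt.date(2012, 7, 10 + st), depth, dcm, -10.0 - st, -25.0 + 3 * st)
    for st in range(3):
        for depth, dcm in layer_depths:
            add_sample("survey_med", "Mediterranean Sea", f"med_st{st}",
                       _dt.date(2013, 5, 4 + st), depth, dcm, 39.0 + st, 5.0 + 2 * st)
    for region, lat, lon in (
        ("English Channel", 48.7, -3.9), ("North Sea", 59.1, 10.6),
        ("Black Sea", 43.2, 28.0), ("Bay of Biscay", 43.6, -5.7),
    ):
        for depth, dcm in ((3.0, False), (45.0, True)):
            add_sample("coastal_eu", region, f"coast_{region.split()[0].lower()}",
                       _dt.date(2010, 9, 15), depth, dcm, lat, lon)
    dates = _ts_dates(spec.years)
    for site, (region, _short) in _TS_SITES.items():
        for d in dates:
            add_sample(site, region, site, d, 3.0, False, 41.0, 3.0)

    # --- groups: sequences, datasets, occupancy -----------------------------
    n_all = spec.n_groups + spec.n_decoys
    k_guard = ceil(0.8 * min(spec.short_amplicon_len, spec.seq_len_range[0]))
    kmer_owner: dict[str, str] = {}
    masters: dict[str, str] = {}
    group_ids = [f"g{i:03d}" for i in range(1, spec.n_groups + 1)]
    decoy_ids = [f"d{i:02d}" for i in range(1, spec.n_decoys + 1)]
    for gid in group_ids + decoy_ids:
        while True:
            length = int(rng.integers(spec.seq_len_range[0], spec.seq_len_range[1] + 1))
            seq = _random_seq(rng, length)
            if not _shares_kmer(kmer_owner, seq, k_guard, gid):
                masters[gid] = seq
                break

    combo_idx = rng.choice(len(combos), size=spec.n_groups, p=weights)
    region_sets = {gid: combos[ci] for gid, ci in zip(group_ids, combo_idx)}
    for did in decoy_ids:
        region_sets[did] = frozenset({spec.regions[int(rng.integers(len(spec.regions)))]})

    ts_membership: dict[str, list[str]] = {gid: [] for gid in group_ids}
    for gid in group_ids:
        for site, (region, _short) in _TS_SITES.items():
            if region in region_sets[gid] and rng.random() < spec.ts_participation:
                ts_membership[gid].append(site)

    candidates = [g for g in group_ids if ts_membership[g]]
    n_rhythmic = round(spec.rhythmic_fraction * spec.n_groups)
    rhythmic_ids = [
        str(g)
        for g in rng.choice(candidates, size=min(n_rhythmic, len(candidates)), replace=False)
    ]
    rhythmic = {
        gid: float(spec.periods_days[i % len(spec.periods_days)])
        for i, gid in enumerate(sorted(rhythmic_ids))
    }
    for gid in rhythmic:  # rhythmic groups attend every site their combo covers
        ts_membership[gid] = [
            site for site, (region, _s) in _TS_SITES.items() if region in region_sets[gid]
        ]

    # dataset assignment per group: one primary spatial dataset per region,
    # plus the time-series sites it participates in
    group_datasets: dict[str, list[str]] = {}
    for gid in group_ids + decoy_ids:
        needed = sorted({_PRIMARY_DATASET[r] for r in region_sets[gid]})
        needed += sorted(ts_membership.get(gid, []))
        group_datasets[gid] = needed

    # --- members ------------------------------------------------------------
    taxonomy: dict[str, TaxonomyPath] = {}
    genus_labels: dict[str, str] = {}
    partition: dict[str, list[str]] = {}
    records_by_dataset: dict[str, list[MetabarcodeRecord]] = {
        ds: [] for ds in samples_by_dataset
    }
    members_in_dataset: dict[tuple[str, str], list[str]] = {}

    order_choice = rng.choice(len(_ORDER_POOL), size=n_all, p=np.array(_ORDER_WEIGHTS))
    for gi, gid in enumerate(group_ids + decoy_ids):
        is_decoy = gid.startswith("d")
        lo, hi = spec.decoy_size_range if is_decoy else spec.group_size_range
        size = int(rng.integers(lo, hi + 1))
        needed = group_datasets[gid]
        size = max(size, len(needed)) if not is_decoy else size
        # datasets per member: cover every needed dataset, spread the rest
        slots = list(needed[: size]) if is_decoy else list(needed)
        while len(slots) < size:
            slots.append(needed[int(rng.integers(len(needed)))])
        if not slots:
            slots = [needed[0]]
        master = masters[gid]
        order = _ORDER_POOL[order_choice[gi]]
        assigned_genus = (
            None
            if is_decoy or rng.random() < spec.unassigned_genus_fraction
            else _GENUS_POOL[int(rng.integers(len(_GENUS_POOL)))]
        )
        genus_carrier = int(rng.integers(len(slots))) if assigned_genus else -1
        members = []
        # the first non-short slot holds a full master copy so prefixes of
        # >=80% length connect through it (they also connect pairwise)
        non_short = [i for i, ds in enumerate(slots) if not _TS_SITES.get(ds, ("", False))[1]]
        full_at = non_short[0] if non_short else 0
        for mi, ds in enumerate(slots):
            mid = f"{gid}_m{mi:02d}"
            short = _TS_SITES.get(ds, ("", False))[1]
            if short:
                seq = master[: spec.short_amplicon_len]
            elif mi == full_at or rng.random() < 0.5:
                seq = master
            else:
                cut = int(rng.integers(ceil(0.8 * len(master)), len(master) + 1))
                seq = master[:cut]
            genus = assigned_genus if mi == genus_carrier and assigned_genus else UNKNOWN
            tax = TaxonomyPath(
                ("Eukaryota", "Alveolata", "Dinoflagellata", "Syndiniales",
                 order, UNKNOWN, genus, UNKNOWN)
            )
            taxonomy[mid] = tax
            rec = MetabarcodeRecord(
                id=mid, sequence=seq, dataset=ds, taxonomy=tax,
                short_amplicon=short,
                best_ref_identity=float(np.round(rng.uniform(82, 100), 1)),
            )
            records_by_dataset[ds].append(rec)
            members_in_dataset.setdefault((gid, ds), []).append(mid)
            members.append(mid)
        partition[gid] = members
        genus_labels[gid] = assigned_genus or "unknown"

    _add_contaminants(spec, rng, records_by_dataset, taxonomy, kmer_owner, k_guard)

    # --- abundances ---------------------------------------------------------
    abundance = _abundances(
        spec, rng, samples_by_dataset, group_ids + decoy_ids, region_sets,
        group_datasets, members_in_dataset, rhythmic, records_by_dataset,
    )

    datasets = {
        ds: DatasetInput(name=ds, records=records_by_dataset[ds], abundance=abundance[ds])
        for ds in sorted(records_by_dataset)
    }
    truth = SyntheticTruth(
        partition={g: partition[g] for g in group_ids},
        region_sets={g: sorted(region_sets[g]) for g in group_ids},
        rhythmic=rhythmic,
        genus_labels=genus_labels,
        decoy_groups=[f"{d}" for d in decoy_ids],
        ts_sites={site: region for site, (region, _s) in _TS_SITES.items()},
    )
    truth.partition.update({d: partition[d] for d in decoy_ids})
    return SyntheticDataset(
        datasets=datasets, metadata=metadata, taxonomy=taxonomy, truth=truth
    )


def _environment(rng, region, depth, dcm, date) -> dict[str, float]:
    base = _REGION_TEMP[region]
    doy = date.timetuple().tm_yday
    seasonal = 4.0 * np.sin(2 * np.pi * (doy - 120) / 365.25) if depth <= 5 else 0.0
    temp = 4.0 + (base - 4.0) * np.exp(-depth / 150.0) + seasonal + rng.normal(0, 0.4)
    deep = 1.0 - np.exp(-depth / 300.0)
    return {
        "temperature": round(float(temp), 3),
        "salinity": round(float(rng.normal(35.5 + 2.5 * (region == "Mediterranean Sea") - 17 * (region == "Black Sea"), 0.2)), 3),
        "ph": round(float(8.15 - 0.25 * deep + rng.normal(0, 0.02)), 3),
        "oxygen": round(float(6.2 - 2.0 * deep + rng.normal(0, 0.15)), 3),
        "no3": round(float(max(0.0, 0.4 + 13.0 * deep + rng.normal(0, 0.4))), 3),
        "no2": round(float(max(0.0, 0.05 + 0.3 * deep + rng.normal(0, 0.02))), 3),
        "nh4": round(float(max(0.0, 0.1 + 0.2 * deep + rng.normal(0, 0.03))), 3),
        "po4": round(float(max(0.0, 0.05 + 0.8 * deep + rng.normal(0, 0.03))), 3),
        "sio4": round(float(max(0.0, 1.0 + 20.0 * deep + rng.normal(0, 0.6))), 3),
        "chla": round(float(max(0.01, (0.9 if dcm else 0.25 * np.exp(-depth / 60.0)) + rng.normal(0, 0.03))), 3),
    }


def _add_contaminants(spec, rng, records_by_dataset, taxonomy, kmer_owner, k_guard):
    """Singleton records exercising the homogenization filters."""
    def fresh_seq(owner, length):
        while True:
            seq = _random_seq(rng, length)
            if not _shares_kmer(kmer_owner, seq, min(k_guard, ceil(0.8 * length)), owner):
                return seq

    spatial = ["survey_tropical", "survey_med", "coastal_eu"]
    blocked_tax = [
        ("Eukaryota", "Opisthokonta", "Metazoa", "Arthropoda", "Crustacea", UNKNOWN, UNKNOWN, UNKNOWN),
        ("Eukaryota", "Archaeplastida", "Streptophyta", "Embryophyceae", UNKNOWN, UNKNOWN, UNKNOWN, UNKNOWN),
        ("Eukaryota", "Archaeplastida", "Rhodophyta", "Florideophyceae", UNKNOWN, UNKNOWN, UNKNOWN, UNKNOWN),
        ("Eukaryota", "Stramenopiles", "Ochrophyta", "Phaeophyceae", UNKNOWN, UNKNOWN, UNKNOWN, UNKNOWN),
    ]
    syndi = ("Eukaryota", "Alveolata", "Dinoflagellata", "Syndiniales",
             "Dino-Group-II", UNKNOWN, UNKNOWN, UNKNOWN)
    specs = (
        [("x_block", blocked_tax[i % len(blocked_tax)], 95.0, 420) for i in range(spec.n_blocklisted)]
        + [("x_lowid", syndi, float(np.round(rng.uniform(55, 79.5), 1)), 420) for _ in range(spec.n_low_identity)]
        + [("x_short", syndi, 95.0, int(rng.integers(150, 201))) for _ in range(spec.n_short)]
    )
    for i, (kind, tax, ident, length) in enumerate(specs):
        ds = spatial[i % len(spatial)]
        mid = f"{kind}{i:02d}"
        path = TaxonomyPath(tax)
        taxonomy[mid] = path
        records_by_dataset[ds].append(
            MetabarcodeRecord(
                id=mid, sequence=fresh_seq(mid, length), dataset=ds,
                taxonomy=path, best_ref_identity=ident,
            )
        )


def _abundances(
    spec, rng, samples_by_dataset, all_groups, region_sets, group_datasets,
    members_in_dataset, rhythmic, records_by_dataset,
):
    """Per-dataset metabarcode-by-sample count-like tables (pre-normalization)."""
    tables: dict[str, pd.DataFrame] = {}
    for ds, samples in samples_by_dataset.items():
        ids = [r.id for r in records_by_dataset[ds]]
        cols = [s.sample_id for s in samples]
        mat = pd.DataFrame(0.0, index=ids, columns=cols)
        is_ts = ds in _TS_SITES
        t_days = (
            np.array([(s.date - samples[0].date).days for s in samples], dtype=float)
            if is_ts
            else None
        )
        bg_mean, bg_sd = spec.background_mean, spec.background_sd
        if is_ts:
            participants = [g for g in all_groups if members_in_dataset.get((g, ds))]
            k_rhy = sum(1 for g in participants if g in rhythmic)
            sparse_flags = {
                g: (g not in rhythmic) and (rng.random() < spec.sparse_fraction)
                for g in participants
            }
            n_bg = sum(
                1 for g in participants if g not in rhythmic and not sparse_flags[g]
            )
            if k_rhy and n_bg:
                # Scale the background covariance mass so the cumulated RV of
                # Escoufier selection crosses the 75% level exactly after the
                # planted rhythmic (dominant) columns: with diagonal-dominant
                # covariance, RV(j of k) ~ sqrt(j c^2 / (k c^2 + m)), so the
                # background mass m must fall between (16/9)(k-1)-k and (7/9)k
                # rhythmic-column units.
                var_r = spec.rhythmic_amplitude**2 / 2 + (spec.rhythmic_amplitude / spec.snr) ** 2
                lo = max(0.0, (16.0 / 9.0) * (k_rhy - 1) - k_rhy)
                hi = (7.0 / 9.0) * k_rhy
                bg_sd = float(np.sqrt(var_r * np.sqrt(0.5 * (lo + hi) / n_bg)))
                bg_mean = max(spec.background_mean, 3.5 * bg_sd)
        for gid in all_groups:
            members = members_in_dataset.get((gid, ds))
            if not members:
                continue
            shares = rng.dirichlet(np.ones(len(members)) * 4.0)
            if is_ts:
                series = _ts_series(
                    spec, rng, gid, rhythmic, t_days,
                    sparse=sparse_flags.get(gid, False),
                    bg_mean=bg_mean, bg_sd=bg_sd,
                )
            else:
                eligible = np.array([s.region in region_sets[gid] for s in samples])
                values = np.where(
                    (rng.random(len(samples)) < 0.7) & eligible,
                    rng.lognormal(-2.0, 0.5, size=len(samples)),
                    0.0,
                )
                # every occupied region keeps at least one positive sample
                for region in region_sets[gid]:
                    idx = [
                        i for i, s in enumerate(samples)
                        if s.region == region and eligible[i]
                    ]
                    if idx and not (values[np.array(idx)] > 0).any():
                        values[idx[int(rng.integers(len(idx)))]] = rng.lognormal(-2.0, 0.5)
                series = values
            for mid, w in zip(members, shares):
                mat.loc[mid] += w * series
        # contaminants: sparse low abundance within their own dataset
        for rec in records_by_dataset[ds]:
            if rec.id.startswith("x_"):
                pick = rng.integers(0, len(cols), size=2)
                for c in pick:
                    mat.iloc[mat.index.get_loc(rec.id), int(c)] = rng.lognormal(-3.0, 0.3)
        # no sample may end up empty: back-fill with an eligible group
        dead = [c for c in cols if mat[c].sum() <= 0]
        for c in dead:
            region = next(s.region for s in samples if s.sample_id == c)
            donors = [
                g for g in all_groups
                if region in region_sets[g] and members_in_dataset.get((g, ds))
            ]
            if donors:
                g = donors[int(rng.integers(len(donors)))]
                mat.loc[members_in_dataset[(g, ds)][0], c] = rng.lognormal(-2.0, 0.5)
        tables[ds] = mat
    return tables


def _ts_series(spec, rng, gid, rhythmic, t_days, sparse, bg_mean, bg_sd):
    n = t_days.size
    if gid in rhythmic:
        period = rhythmic[gid]
        phase = rng.uniform(0, 2 * np.pi)
        amp = spec.rhythmic_amplitude
        x = amp * (1.0 + np.sin(2 * np.pi * t_days / period + phase))
        x = x + rng.normal(0, amp / spec.snr, size=n)
    elif sparse:
        x = np.zeros(n)
        x[rng.choice(n, size=3, replace=False)] = rng.lognormal(-2.5, 0.4, size=3)
    else:
        x = bg_mean + rng.normal(0, bg_sd, size=n)
    return np.clip(x, 0.0, None)


def generate(spec: SyntheticSpec, outdir: str | Path) -> tuple[dict[str, dict[str, Path]], SyntheticTruth]:
    """Write the corpus to ``outdir`` and return per-dataset paths and truth.

    Emits, per dataset, ``<name>.fasta``, ``<name>_abundance.tsv`` and
    ``<name>_taxonomy.tsv``; plus shared ``metadata.tsv`` and ``truth.json``.
    """
    data = synthesize(spec)
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths: dict[str, dict[str, Path]] = {}
    for name, ds in data.datasets.items():
        p = {
            "fasta": outdir / f"{name}.fasta",
            "abundance": outdir / f"{name}_abundance.tsv",
            "taxonomy": outdir / f"{name}_taxonomy.tsv",
        }
        write_fasta(p["fasta"], [(r.id, r.sequence) for r in ds.records])
        write_abundance(p["abundance"], ds.abundance)
        write_taxonomy(p["taxonomy"], {r.id: r.taxonomy for r in ds.records})
        paths[name] = p
    write_metadata(outdir / "metadata.tsv", data.metadata)
    (outdir / "truth.json").write_text(data.truth.to_json())
    paths["shared"] = {
        "metadata": outdir / "metadata.tsv",
        "truth": outdir / "truth.json",
    }
    return paths, data.truth


def perturb(
    records: list[MetabarcodeRecord],
    mutation_rate: float,
    rng: np.random.Generator | int | None = None,
) -> list[MetabarcodeRecord]:
    """Negative controls: dispersed substitutions breaking long exact runs.

    Positions are drawn at the given per-base rate, then extra substitutions
    are inserted wherever a run of unmodified bases would reach 0.8 of the
    sequence length, so a mutated copy can never satisfy the edge rule
    against its original.
    """
    if not 0.0 <= mutation_rate <= 1.0:
        raise ValueError(f"mutation rate {mutation_rate} outside [0, 1]")
    if mutation_rate == 0.0:
        return list(records)
    rng = np.random.default_rng(rng)
    out = []
    for rec in records:
        seq = np.frombuffer(rec.sequence.encode("ascii"), dtype=np.uint8).copy()
        n = seq.size
        hit = set(np.nonzero(rng.random(n) < mutation_rate)[0].tolist())
        limit = max(1, ceil(0.8 * n) - 1)  # longest allowed untouched run
        bounds = sorted(hit) + [n]
        prev = -1
        for b in bounds:
            while b - prev - 1 > limit:
                mid = prev + 1 + limit
                hit.add(mid)
                prev = mid
            prev = b
        for pos in hit:
            old = seq[pos]
            choices = _BASES[_BASES != old]
            seq[pos] = choices[rng.integers(len(choices))]
        out.append(
            MetabarcodeRecord(
                id=rec.id, sequence=seq.tobytes().decode("ascii"),
                dataset=rec.dataset, taxonomy=rec.taxonomy,
                short_amplicon=rec.short_amplicon,
                best_ref_identity=rec.best_ref_identity,
            )
        )
    return out
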