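"""End-to-end convenience layer: load a corpus, harmonize, cluster, profile.

Ties the stage modules together for scripted runs: reading a generated (or
externally prepared) per-dataset directory back into memory, and running the
harmonization -> network -> connected-component -> occurrence chain in one
call.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from . import io as pio
from .core import MetabarcodeRecord, SampleMetadata, TaxonomyPath
from .harmonize import DatasetInput, FilterReport, harmonize
from .network import ConnectedComponent, build_ssn, extract_ccs, label_ccs
from .simulate import SyntheticDataset

__all__ = ["PipelineResult", "load_generated_corpus", "run_pipeline"]

#: Datasets whose longest sequence stays below this are treated as
#: short-amplicon datasets (coverage rule applied to their side only).
SHORT_AMPLICON_MAX_LEN = 260


@dataclass
class PipelineResult:
    records: list[MetabarcodeRecord]
    table: pd.DataFrame
    reports: list[FilterReport]
    ccs: list[ConnectedComponent]
    taxonomy: dict[str, TaxonomyPath]
    metadata: list[SampleMetadata]


def load_generated_corpus(
    indir: str | Path,
) -> tuple[list[DatasetInput], list[SampleMetadata], dict[str, TaxonomyPath]]:
    """Read a directory of per-dataset files back into memory.

    Expects ``<name>.fasta``, ``<name>_abundance.tsv``, ``<name>_taxonomy.tsv``
    per dataset plus a shared ``metadata.tsv``.  A dataset whose longest
    sequence is below :data:`SHORT_AMPLICON_MAX_LEN` bp is flagged as a
    short-amplicon dataset.
    """
    indir = Path(indir)
    metadata = pio.read_metadata(indir / "metadata.tsv")
    datasets: list[DatasetInput] = []
    taxonomy: dict[str, TaxonomyPath] = {}
    for fasta in sorted(indir.glob("*.fasta")):
        name = fasta.stem
        seqs = pio.read_fasta(fasta)
        tax = pio.read_taxonomy(indir / f"{name}_taxonomy.tsv")
        table = pio.read_abundance(indir / f"{name}_abundance.tsv")
        short = bool(seqs) and max(len(s) for _, s in seqs) <= SHORT_AMPLICON_MAX_LEN
        records = [
            MetabarcodeRecord(
                id=rid, sequence=seq, dataset=name, taxonomy=tax[rid],
                short_amplicon=short,
            )
            for rid, seq in seqs
        ]
        taxonomy.update(tax)
        datasets.append(DatasetInput(name=name, records=records, abundance=table))
    if not datasets:
        raise ValueError(f"no datasets found under {indir}")
    return datasets, metadata, taxonomy


def run_pipeline(
    data: SyntheticDataset | tuple[list[DatasetInput], list[SampleMetadata], dict[str, TaxonomyPath]],
    min_cov: float = 0.8,
    min_cc_size: int = 6,
) -> PipelineResult:
    """Harmonize datasets, build the SSN and extract labelled components."""
    if isinstance(data, SyntheticDataset):
        datasets = list(data.datasets.values())
        metadata = data.metadata
        taxonomy = data.taxonomy
    else:
        datasets, metadata, taxonomy = data
    records, table, reports = harmonize(datasets)
    graph = build_ssn(records, min_cov=min_cov)
    ccs = label_ccs(extract_ccs(graph, min_size=min_cc_size), taxonomy, table)
    return PipelineResult(
        records=records, table=table, reports=reports, ccs=ccs,
        taxonomy=taxonomy, metadata=metadata,
    )
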