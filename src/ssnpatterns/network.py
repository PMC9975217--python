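"""Exact-identity sequence similarity network (SSN) and connected components.

Metabarcodes are clustered at 100% sequence identity: two records are linked
when they share a gap-free identical segment covering at least ``min_cov``
(default 0.8) of *both* sequences.  Datasets with systematically short
amplicons are the exception — when exactly one record of a pair is flagged
``short_amplicon``, the coverage rule is applied to that record only, so that
short amplicons fully contained in longer ones are not penalized.

Connected components (CCs) of this graph are the analysis units: a pragmatic
proxy for genus-level lineages that works without taxonomic assignment.
Components smaller than ``min_size`` (default 6, the number of integrated
datasets) are discarded.  When exactly one assigned genus occurs among a
component's members, that name is extrapolated to the whole component.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import ceil

import networkx as nx
import numpy as np
import pandas as pd

from .core import UNKNOWN, MetabarcodeRecord, TaxonomyPath

__all__ = [
    "SSNEdge",
    "ConnectedComponent",
    "longest_common_substring",
    "pair_edge",
    "build_ssn",
    "extract_ccs",
    "extrapolate_genus",
    "extrapolate_order",
    "label_ccs",
    "cc_abundance",
    "cc_abundance_table",
]


@dataclass(frozen=True)
class SSNEdge:
    """An undirected exact-identity link between two metabarcodes."""

    id_a: str
    id_b: str
    match_len: int
    coverage_a: float
    coverage_b: float


@dataclass
class ConnectedComponent:
    """A maximal set of metabarcodes linked at 100% identity.

    ``genus_label`` is the extrapolated genus name, ``"unknown"`` when no
    member has an assigned genus, or ``"ambiguous"`` when members disagree.
    ``order_label`` is the unique assigned order among members or
    ``"Unknown"``.
    """

    cc_id: str
    members: frozenset[str]
    genus_label: str = "unknown"
    order_label: str = UNKNOWN

    @property
    def size(self) -> int:
        return len(self.members)


def longest_common_substring(a: str, b: str) -> int:
    """Length of the longest contiguous segment shared exactly by two strings.

    Row-wise dynamic programming vectorized over the second string; zero when
    the strings share no symbol.
    """
    if not a or not b:
        raise ValueError("longest_common_substring requires non-empty strings")
    if len(a) > len(b):  # iterate over the shorter string
        a, b = b, a
    x = np.frombuffer(a.encode("ascii"), dtype=np.uint8)
    y = np.frombuffer(b.encode("ascii"), dtype=np.uint8)
    prev = np.zeros(y.size, dtype=np.int32)
    shifted = np.empty_like(prev)
    best = 0
    for c in x:
        shifted[0] = 0
        shifted[1:] = prev[:-1]
        prev = np.where(y == c, shifted + 1, 0)
        m = prev.max()
        if m > best:
            best = int(m)
    return best


def pair_edge(
    rec_a: MetabarcodeRecord,
    rec_b: MetabarcodeRecord,
    min_cov: float = 0.8,
) -> SSNEdge | None:
    """Evaluate the exact-identity edge rule for one unordered pair.

    The shared-segment length must cover at least ``min_cov`` of both
    sequences; when exactly one record is a short amplicon, only that record's
    coverage is tested.
    """
    match_len = longest_common_substring(rec_a.sequence, rec_b.sequence)
    if match_len == 0:
        return None
    cov_a = match_len / len(rec_a)
    cov_b = match_len / len(rec_b)
    if rec_a.short_amplicon != rec_b.short_amplicon:
        ok = (cov_a if rec_a.short_amplicon else cov_b) >= min_cov
    else:
        ok = cov_a >= min_cov and cov_b >= min_cov
    if not ok:
        return None
    return SSNEdge(rec_a.id, rec_b.id, match_len, cov_a, cov_b)


def _candidate_pairs(records: list[MetabarcodeRecord], min_cov: float) -> set[tuple[int, int]]:
    """Index-based prefilter: pairs that could satisfy the coverage rule.

    Any qualifying pair shares an exact segment of at least
    ``ceil(min_cov * Lmin)`` bp (Lmin = shortest sequence in the collection),
    hence shares at least one k-mer of that length.  The prefilter therefore
    never removes a true edge; it only skips pairs that cannot have one.
    """
    lmin = min(len(r) for r in records)
    k = max(1, ceil(min_cov * lmin))
    index: dict[str, list[int]] = {}
    for i, rec in enumerate(records):
        seq = rec.sequence
        if len(seq) < k:
            continue
        for start in range(len(seq) - k + 1):
            index.setdefault(seq[start : start + k], []).append(i)
    pairs: set[tuple[int, int]] = set()
    for hits in index.values():
        uniq = sorted(set(hits))
        for ai in range(len(uniq)):
            for bi in range(ai + 1, len(uniq)):
                pairs.add((uniq[ai], uniq[bi]))
    return pairs


def build_ssn(
    records: list[MetabarcodeRecord],
    min_cov: float = 0.8,
    prefilter: bool = True,
) -> nx.Graph:
    """Build the SSN over all unordered record pairs.

    Every record is a node (isolated nodes are legitimate singleton
    components).  With ``prefilter`` a shared-k-mer index restricts the pairs
    whose longest common substring is computed; the resulting edge set is
    identical to exhaustive evaluation.
    """
    if not records:
        raise ValueError("no records to build a network from")
    ids = [r.id for r in records]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate record ids in network input")
    graph = nx.Graph()
    for rec in records:
        graph.add_node(rec.id, dataset=rec.dataset, length=len(rec))
    if prefilter:
        pairs = _candidate_pairs(records, min_cov)
    else:
        pairs = {
            (i, j) for i in range(len(records)) for j in range(i + 1, len(records))
        }
    for i, j in pairs:
        edge = pair_edge(records[i], records[j], min_cov=min_cov)
        if edge is not None:
            graph.add_edge(
                edge.id_a,
                edge.id_b,
                match_len=edge.match_len,
                coverage_a=edge.coverage_a,
                coverage_b=edge.coverage_b,
            )
    return graph


def extract_ccs(graph: nx.Graph, min_size: int = 6) -> list[ConnectedComponent]:
    """Extract connected components of at least ``min_size`` nodes.

    Components are ordered (and provisionally numbered) by their
    lexicographically smallest member id, which makes extraction
    deterministic regardless of graph insertion order.
    """
    comps = [frozenset(c) for c in nx.connected_components(graph) if len(c) >= min_size]
    comps.sort(key=lambda c: min(c))
    width = max(4, len(str(len(comps))))
    return [
        ConnectedComponent(cc_id=f"cc_{i:0{width}d}", members=members)
        for i, members in enumerate(comps, start=1)
    ]


def extrapolate_genus(
    cc: ConnectedComponent, taxonomy: dict[str, TaxonomyPath]
) -> str:
    """Genus label for a component from its members' assignments.

    Exactly one assigned genus among members -> that name is extrapolated to
    all members; none -> ``"unknown"``; several -> ``"ambiguous"``.
    """
    genera = {
        taxonomy[m]["genus"] for m in cc.members if taxonomy[m]["genus"] != UNKNOWN
    }
    if not genera:
        return "unknown"
    if len(genera) == 1:
        return genera.pop()
    return "ambiguous"


def extrapolate_order(
    cc: ConnectedComponent, taxonomy: dict[str, TaxonomyPath]
) -> str:
    """Unique assigned order among members, else the ``"Unknown"`` sentinel."""
    orders = {
        taxonomy[m]["order"] for m in cc.members if taxonomy[m]["order"] != UNKNOWN
    }
    if len(orders) == 1:
        return orders.pop()
    return UNKNOWN


def label_ccs(
    ccs: list[ConnectedComponent],
    taxonomy: dict[str, TaxonomyPath],
    table: pd.DataFrame | None = None,
) -> list[ConnectedComponent]:
    """Assign genus/order labels and final ``CC_<genus>_<n>`` identifiers.

    Numbering follows descending total abundance when a table is given
    (ties, and the no-table case, fall back to the smallest member id), so
    CC_*_1 is the most abundant component.
    """
    def total(cc: ConnectedComponent) -> float:
        if table is None:
            return 0.0
        present = [m for m in cc.members if m in table.index]
        return float(table.loc[present].to_numpy().sum()) if present else 0.0

    ranked = sorted(ccs, key=lambda cc: (-total(cc), min(cc.members)))
    out = []
    for i, cc in enumerate(ranked, start=1):
        out.append(
            ConnectedComponent(
                cc_id=f"CC_{extrapolate_genus(cc, taxonomy)}_{i}",
                members=cc.members,
                genus_label=extrapolate_genus(cc, taxonomy),
                order_label=extrapolate_order(cc, taxonomy),
            )
        )
    return out


def cc_abundance(cc: ConnectedComponent, table: pd.DataFrame) -> pd.Series:
    """Per-sample abundance of a component: element-wise sum of member rows."""
    missing = sorted(set(cc.members) - set(table.index))
    if missing:
        raise KeyError(f"component {cc.cc_id}: members absent from table: {missing}")
    return table.loc[sorted(cc.members)].sum(axis=0)


def cc_abundance_table(
    ccs: list[ConnectedComponent], table: pd.DataFrame
) -> pd.DataFrame:
    """CC-by-sample abundance table (member rows summed per component).

    This is the unit at which cross-dataset comparisons are meaningful: the
    same lineage sequenced by two projects appears as distinct metabarcode
    rows but as one component.
    """
    return pd.DataFrame(
        {cc.cc_id: cc_abundance(cc, table) for cc in ccs}
    ).T
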