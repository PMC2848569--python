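"""Homology-transferred Gene Ontology vectors and functional-domain vectors.

A query protein without curated annotation can still borrow annotation from
its close homologs: proteins found by a BLAST search that pass an identity
and an expect-value threshold form its "homology set", and the union of the
GO terms annotated to those homologs becomes a sparse binary GO vector for
the query.  Similarly, significant hits against a conserved-domain database
(RPS-BLAST style) switch on components of a binary functional-domain (FunD)
vector.  Both vectors are flat indicator vectors — no GO-graph propagation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Set, Union

import pandas as pd

#: GO index space size used by the full-scale predictor (GO release 70.0).
GO_DIMENSION: int = 60020
#: Conserved-domain index space size (CDD version 2.11).
FUND_DIMENSION: int = 17402

#: Column layout of BLAST tabular output (``-outfmt 6``).
BLAST6_COLUMNS = (
    "qseqid sseqid pident length mismatch gapopen "
    "qstart qend sstart send evalue bitscore"
).split()


@dataclass(frozen=True)
class HomologySet:
    """Subject accessions that passed both homology thresholds for a query.

    May legitimately be empty: a query with no significant homolog cannot be
    expressed in the GO space and is routed to the sequence-based engine.
    """

    query_id: str
    accessions: frozenset[str]
    identity_min: float
    evalue_max: float

    def __len__(self) -> int:
        return len(self.accessions)

    @property
    def is_empty(self) -> bool:
        return not self.accessions


@dataclass(frozen=True)
class GOVector:
    """Binary indicator vector over GO-term indices (1-based)."""

    protein_id: str
    nonzero_indices: frozenset[int]
    dimension: int = GO_DIMENSION

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError("dimension must be positive")
        bad = [i for i in self.nonzero_indices if not 1 <= i <= self.dimension]
        if bad:
            raise ValueError(
                f"GO indices {sorted(bad)[:5]} outside [1, {self.dimension}]"
            )
        object.__setattr__(
            self, "nonzero_indices", frozenset(self.nonzero_indices)
        )

    @property
    def is_empty(self) -> bool:
        return not self.nonzero_indices


@dataclass(frozen=True)
class FunDVector:
    """Binary indicator vector over conserved-domain indices (1-based)."""

    protein_id: str
    nonzero_indices: frozenset[int]
    dimension: int = FUND_DIMENSION

    def __post_init__(self) -> None:
        if self.dimension < 1:
            raise ValueError("dimension must be positive")
        bad = [i for i in self.nonzero_indices if not 1 <= i <= self.dimension]
        if bad:
            raise ValueError(
                f"domain indices {sorted(bad)[:5]} outside [1, {self.dimension}]"
            )
        object.__setattr__(
            self, "nonzero_indices", frozenset(self.nonzero_indices)
        )


def read_blast_tabular(path) -> pd.DataFrame:
    """Read BLAST ``-outfmt 6`` tabular output into a hit table."""
    table = pd.read_csv(path, sep="\t", header=None, comment="#")
    table.columns = BLAST6_COLUMNS[: table.shape[1]]
    return table


def build_homology_set(
    hits: pd.DataFrame,
    query_id: str,
    identity_min: float = 60.0,
    evalue_max: float = 1e-3,
) -> HomologySet:
    """Filter a BLAST hit table down to the homology set of one query.

    Keeps subjects with ``evalue <= evalue_max`` and
    ``pident >= identity_min`` (both comparisons inclusive), excluding
    self-hits.  An empty result is a valid outcome.
    """
    if not 0.0 <= identity_min <= 100.0:
        raise ValueError("identity_min must lie in [0, 100]")
    if not evalue_max > 0:
        raise ValueError("evalue_max must be positive")
    if hits.empty:
        rows = hits
    else:
        rows = hits[
            (hits["qseqid"] == query_id)
            & (hits["sseqid"] != query_id)
            & (hits["evalue"] <= evalue_max)
            & (hits["pident"] >= identity_min)
        ]
    accessions = frozenset() if rows.empty else frozenset(rows["sseqid"])
    return HomologySet(query_id, accessions, identity_min, evalue_max)


def read_go_annotations(
    annotation_path, index_path
) -> dict[str, frozenset[int]]:
    """Load a 2-column accession→GO-term TSV plus a GO-id→index manifest.

    Returns a mapping accession → set of integer GO indices.
    """
    index = pd.read_csv(index_path, sep="\t", header=None, names=["go", "idx"])
    go_to_idx = dict(zip(index["go"], index["idx"].astype(int)))
    anno = pd.read_csv(annotation_path, sep="\t", header=None, names=["acc", "go"])
    table: dict[str, set[int]] = {}
    for acc, go in zip(anno["acc"], anno["go"]):
        if go in go_to_idx:
            table.setdefault(acc, set()).add(go_to_idx[go])
    return {acc: frozenset(idx) for acc, idx in table.items()}


def go_vector(
    hset: HomologySet,
    table: Mapping[str, Set[int]],
    dimension: int = GO_DIMENSION,
) -> GOVector:
    """Union of the GO indices annotated to the homology-set members.

    Accessions missing from the annotation table contribute nothing; an
    empty homology set yields the all-zero vector.
    """
    indices: set[int] = set()
    for acc in hset.accessions:
        indices.update(table.get(acc, ()))
    return GOVector(hset.query_id, frozenset(indices), dimension)


def is_productive(vec: GOVector, training_go_index: Set[int]) -> bool:
    """Whether the GO vector is a usable descriptor for a given training set.

    True iff the vector switches on at least one GO index that also occurs
    somewhere in the reference library — otherwise the GO space carries no
    information about the query relative to that library.
    """
    return bool(vec.nonzero_indices & set(training_go_index))


def read_domain_hits(hits_path, index_path) -> pd.DataFrame:
    """Load domain hits (protein_id, domain_id, evalue TSV) and translate
    domain ids to integer indices via the manifest."""
    index = pd.read_csv(index_path, sep="\t", header=None, names=["dom", "idx"])
    dom_to_idx = dict(zip(index["dom"], index["idx"].astype(int)))
    hits = pd.read_csv(
        hits_path, sep="\t", header=None, names=["protein_id", "dom", "evalue"]
    )
    hits["domain_index"] = hits["dom"].map(dom_to_idx)
    return hits[["protein_id", "domain_index", "evalue"]]


def fund_vector(
    hits: Union[pd.DataFrame, "list[tuple[int, float]]"],
    evalue_max: float = 1e-3,
    dimension: int = FUND_DIMENSION,
    protein_id: str = "",
) -> FunDVector:
    """Binary domain vector: component i is 1 iff some hit on domain i has
    ``evalue <= evalue_max``.  Duplicate hits are idempotent.

    Raises
    ------
    ValueError
        If a domain index falls outside ``[1, dimension]``.
    """
    if not evalue_max > 0:
        raise ValueError("evalue_max must be positive")
    if isinstance(hits, pd.DataFrame):
        pairs = zip(hits["domain_index"], hits["evalue"])
    else:
        pairs = iter(hits)
    indices: set[int] = set()
    for domain_index, evalue in pairs:
        domain_index = int(domain_index)
        if not 1 <= domain_index <= dimension:
            raise ValueError(
                f"domain index {domain_index} outside [1, {dimension}]"
            )
        if evalue <= evalue_max:
            indices.add(domain_index)
    return FunDVector(protein_id, frozenset(indices), dimension)
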