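"""Ensemble prediction engines, query routing and the multi-label decision.

Two engines fuse evidential-KNN voters:

* the GO engine — 10 members (K = 1..10) voting in the homology-transferred
  GO space; used whenever the query has a productive GO vector;
* the SEQ engine — 500 members indexed by (K = 1..10, lag ξ = 0..49), each
  voting in the combined functional-domain ⊕ pseudo-PSSM(ξ) space; used for
  queries with an empty homology set or no usable GO information.

Each member casts exactly one vote.  The vote tally is turned into a
location set by a threshold rule: every location whose vote share comes
within θ of the maximum share (and received at least one vote) is
predicted, so θ = 0 returns the argmax set and larger θ admits more
locations.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .annotations import FunDVector, GOVector, build_homology_set, go_vector, is_productive
from .config import RunConfig
from .evclassifier import ReferenceLibrary, etknn_vote, fit_gammas
from .profiles import NormalizedProfile, PSSMProfile, normalize_profile, psepssm_vector

#: Shortest sequence accepted as a whole protein rather than a fragment.
MIN_PROTEIN_LENGTH = 50

SHARE_TOL = 1e-12


class FragmentError(ValueError):
    """Raised for query sequences shorter than 50 residues."""


class MissingInputError(ValueError):
    """Raised when a required feature resource is absent."""


@dataclass(frozen=True)
class VoteTally:
    """Vote counts per location from one engine run."""

    votes: Mapping[int, int]
    n_members: int

    def __post_init__(self) -> None:
        votes = {int(k): int(v) for k, v in self.votes.items() if v}
        if any(v < 0 for v in votes.values()):
            raise ValueError("vote counts must be non-negative")
        if sum(votes.values()) != self.n_members:
            raise ValueError(
                f"votes sum to {sum(votes.values())}, expected {self.n_members}"
            )
        object.__setattr__(self, "votes", votes)


@dataclass(frozen=True)
class PredictionResult:
    """Outcome of routing one query through the ensemble."""

    protein_id: str
    engine: str  # "GO" | "SEQ"
    predicted_locations: frozenset[int]
    tally: VoteTally
    theta: float
    warnings: tuple[str, ...] = ()


def multilabel_select(tally: VoteTally, theta: float) -> frozenset[int]:
    """Locations whose vote share is within ``theta`` of the maximum share.

    Only locations with at least one vote are eligible; ``theta = 0``
    returns all tied maxima.  The comparison carries a tiny slack so exact
    rational shares are not lost to floating-point rounding.
    """
    if not 0.0 <= theta < 1.0:
        raise ValueError("theta must lie in [0, 1)")
    if tally.n_members < 1:
        raise ValueError("tally must contain at least one member")
    shares = {loc: v / tally.n_members for loc, v in tally.votes.items()}
    top = max(shares.values())
    return frozenset(
        loc for loc, s in shares.items() if s >= top - theta - SHARE_TOL
    )


def _run_members(
    query,
    library: ReferenceLibrary,
    k_values: Sequence[int],
    alpha: float,
    exponent: float,
    gammas=None,
    distances=None,
) -> list[int]:
    if gammas is None:
        gammas = fit_gammas(library)
    if distances is None:
        distances = library.distances_to(query)
    return [
        etknn_vote(query, library, k, alpha, gammas, distances, exponent)
        for k in k_values
    ]


def go_engine_predict(
    vec: GOVector,
    library: ReferenceLibrary,
    theta: float,
    config: Optional[RunConfig] = None,
    gammas=None,
    distances=None,
) -> PredictionResult:
    """GO-space engine: members K = 1..10 each cast one evidential vote."""
    config = config or RunConfig()
    if library.space_tag != "go":
        raise ValueError(
            f"GO engine requires a 'go' library, got {library.space_tag!r}"
        )
    training_index = set().union(*library.features) if library.features else set()
    if not is_productive(vec, training_index):
        raise ValueError(
            f"query {vec.protein_id!r} has no productive GO descriptor "
            "for this library"
        )
    k_values = range(config.k_min, config.k_max + 1)
    votes = _run_members(
        vec.nonzero_indices,
        library,
        list(k_values),
        config.alpha,
        config.mass_exponent,
        gammas,
        distances,
    )
    counts: dict[int, int] = {}
    for v in votes:
        counts[v] = counts.get(v, 0) + 1
    tally = VoteTally(counts, len(votes))
    return PredictionResult(
        vec.protein_id, "GO", multilabel_select(tally, theta), tally, theta
    )


def seq_engine_predict(
    fund: FunDVector,
    norm: NormalizedProfile,
    libraries: Mapping[int, ReferenceLibrary],
    theta: float,
    config: Optional[RunConfig] = None,
    gammas_by_xi: Optional[Mapping[int, Mapping[int, float]]] = None,
) -> PredictionResult:
    """Sequence-based engine over the combined FunD ⊕ PsePSSM(ξ) space.

    Members are indexed by (K, ξ); with the full K = 1..10 and ξ = 0..49
    ranges there are 500 of them.  Profiles shorter than 50 residues
    truncate the usable lag range to ξ < L and record a warning.
    """
    config = config or RunConfig()
    length = norm.length
    warnings: list[str] = []
    xi_cap = min(config.xi_max, length - 1)
    if length <= config.xi_max:
        warnings.append(
            f"profile length {length} < {config.xi_max + 1}: "
            f"lag range truncated to 0..{xi_cap}"
        )
    lags = [xi for xi in range(xi_cap + 1) if xi in libraries]
    missing = [xi for xi in range(xi_cap + 1) if xi not in libraries]
    if missing:
        warnings.append(f"no reference library for lags {missing}")
    if not lags:
        raise MissingInputError("no usable per-lag reference library")
    k_values = list(range(config.k_min, config.k_max + 1))
    counts: dict[int, int] = {}
    n_members = 0
    for xi in lags:
        library = libraries[xi]
        pse = psepssm_vector(norm, xi, config.coupling_exponent)
        gammas = gammas_by_xi.get(xi) if gammas_by_xi else None
        if config.joint_space:
            if library.space_tag != "fund+psepssm":
                raise ValueError(
                    "SEQ engine requires 'fund+psepssm' libraries, got "
                    f"{library.space_tag!r}"
                )
            query = (fund.nonzero_indices, pse.values)
            votes = _run_members(
                query, library, k_values, config.alpha,
                config.mass_exponent, gammas,
            )
        else:
            # per-space variant: members vote on the PsePSSM block alone
            votes = _run_members(
                pse.values, library, k_values, config.alpha,
                config.mass_exponent, gammas,
            )
        for v in votes:
            counts[v] = counts.get(v, 0) + 1
        n_members += len(votes)
    if not config.joint_space and -1 in libraries:
        # per-space variant: an extra bank of members votes on the domain
        # block alone (library key -1, space tag 'fund')
        votes = _run_members(
            fund.nonzero_indices, libraries[-1], k_values, config.alpha,
            config.mass_exponent,
            gammas_by_xi.get(-1) if gammas_by_xi else None,
        )
        for v in votes:
            counts[v] = counts.get(v, 0) + 1
        n_members += len(votes)
    tally = VoteTally(counts, n_members)
    return PredictionResult(
        fund.protein_id or norm.protein_id,
        "SEQ",
        multilabel_select(tally, theta),
        tally,
        theta,
        tuple(warnings),
    )


@dataclass(frozen=True)
class ProteinRecord:
    protein_id: str
    sequence: str


@dataclass
class ProteinResources:
    """Per-query raw evidence: hit tables and the evolutionary profile."""

    blast_hits: Optional[object] = None  # BLAST tabular DataFrame
    go_table: Optional[Mapping[str, frozenset[int]]] = None
    domain_hits: Optional[object] = None  # DataFrame or (index, evalue) pairs
    profile: Optional[PSSMProfile] = None


def predict(
    record: ProteinRecord,
    resources: ProteinResources,
    go_library: Optional[ReferenceLibrary],
    seq_libraries: Optional[Mapping[int, ReferenceLibrary]],
    config: Optional[RunConfig] = None,
) -> PredictionResult:
    """Route one query through the flowchart and run the matching engine.

    A productive GO vector (non-empty homology set whose transferred terms
    overlap the reference library) goes to the GO engine; anything else
    falls back to the sequence engine.  Sequences shorter than 50 residues
    are rejected as fragments.
    """
    from .annotations import fund_vector  # local import avoids cycle at module load

    config = config or RunConfig()
    if len(record.sequence) < MIN_PROTEIN_LENGTH:
        raise FragmentError(
            f"{record.protein_id}: sequence of {len(record.sequence)} residues "
            f"is shorter than {MIN_PROTEIN_LENGTH} amino acids and is deemed "
            "a fragment; supply the entire sequence"
        )
    vec = GOVector(record.protein_id, frozenset(), config.go_dimension)
    if resources.blast_hits is not None and resources.go_table is not None:
        hset = build_homology_set(
            resources.blast_hits,
            record.protein_id,
            config.identity_min,
            config.evalue_max_go,
        )
        vec = go_vector(hset, resources.go_table, config.go_dimension)
    if go_library is not None and len(go_library):
        training_index = set().union(*go_library.features)
        if is_productive(vec, training_index):
            return go_engine_predict(vec, go_library, config.theta, config)
    # SEQ route
    if resources.profile is None:
        raise MissingInputError(
            f"{record.protein_id}: a PSSM profile is required for the "
            "sequence-based engine but none was provided"
        )
    if seq_libraries is None or not seq_libraries:
        raise MissingInputError(
            f"{record.protein_id}: no sequence-space reference libraries"
        )
    if resources.domain_hits is not None:
        fund = fund_vector(
            resources.domain_hits,
            config.evalue_max_fund,
            config.fund_dimension,
            record.protein_id,
        )
    else:
        fund = FunDVector(record.protein_id, frozenset(), config.fund_dimension)
    norm = normalize_profile(resources.profile)
    return seq_engine_predict(fund, norm, seq_libraries, config.theta, config)
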