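"""Virtual-sample accounting, multi-label scoring and the jackknife test.

A protein annotated to m subcellular locations is counted as m "virtual"
(locative) samples, one per location, so a benchmark with N_m proteins of
multiplicity m holds ``sum_m m * N_m`` virtual samples.  Success rates are
reported per location over virtual samples, in two modes:

* locative — a virtual sample (p, l) scores 1 iff l is among the predicted
  locations of p;
* penalized — the credit is additionally shrunk by the Jaccard overlap
  |T ∩ P| / |T ∪ P| between the true and predicted location sets, so both
  over- and under-predictions reduce the score.

The jackknife (leave-one-protein-out) test removes ALL virtual samples of
one protein from every reference library, refits the evidential scale
parameters, predicts the withheld protein through the normal routing, and
aggregates the per-location outcomes.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence, Set

import numpy as np
from scipy.spatial.distance import cdist

from .config import RunConfig
from .ensemble import VoteTally, multilabel_select
from .evclassifier import (
    ReferenceLibrary,
    SpaceParams,
    gammas_from_distance_matrix,
    jaccard_distance,
    vote_from_distances,
)
from .profiles import NormalizedProfile, psepssm_vector

#: The 22 subcellular locations of the eukaryotic benchmark system.
EUK22_LOCATIONS: tuple[str, ...] = (
    "acrosome", "cell membrane", "cell wall", "centrosome", "chloroplast",
    "cyanelle", "cytoplasm", "cytoskeleton", "endoplasmic reticulum",
    "endosome", "extracell", "Golgi apparatus", "hydrogenosome", "lysosome",
    "melanosome", "microsome", "mitochondrion", "nucleus", "peroxisome",
    "spindle pole body", "synapse", "vacuole",
)


@dataclass
class ProteinEntry:
    """One benchmark protein with its derived feature resources."""

    protein_id: str
    sequence: str
    labels: tuple[int, ...]  # 1-based location indices, ascending
    go_indices: frozenset[int]
    fund_indices: frozenset[int]
    profile: NormalizedProfile
    has_homologs: bool = True

    def __post_init__(self) -> None:
        self.labels = tuple(sorted(set(int(l) for l in self.labels)))
        if not self.labels:
            raise ValueError(f"{self.protein_id}: at least one location required")


@dataclass
class BenchmarkDataset:
    """A labeled benchmark: proteins plus the ordered location name list."""

    proteins: list[ProteinEntry]
    location_names: tuple[str, ...]

    def __post_init__(self) -> None:
        ids = [p.protein_id for p in self.proteins]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate protein ids in benchmark")
        n_loc = len(self.location_names)
        for p in self.proteins:
            if any(not 1 <= l <= n_loc for l in p.labels):
                raise ValueError(
                    f"{p.protein_id}: labels {p.labels} outside 1..{n_loc}"
                )

    def __len__(self) -> int:
        return len(self.proteins)

    @property
    def truth(self) -> dict[str, frozenset[int]]:
        return {p.protein_id: frozenset(p.labels) for p in self.proteins}


@dataclass(frozen=True)
class VirtualCounts:
    n_distinct: int
    n_virtual: int
    multiplicity_histogram: Mapping[int, int]


def virtual_counts_from_histogram(histogram: Mapping[int, int]) -> VirtualCounts:
    """Virtual-sample total from a multiplicity histogram.

    ``histogram[m]`` is the number of proteins annotated to exactly m
    locations; the virtual total is the multiplicity-weighted sum
    ``sum_m m * N_m``.
    """
    hist = {int(m): int(n) for m, n in histogram.items() if n}
    if any(m < 1 or n < 0 for m, n in hist.items()):
        raise ValueError("histogram needs multiplicities >= 1, counts >= 0")
    n_distinct = sum(hist.values())
    n_virtual = sum(m * n for m, n in hist.items())
    return VirtualCounts(n_distinct, n_virtual, hist)


def virtual_counts(dataset: BenchmarkDataset) -> VirtualCounts:
    """Distinct / virtual sample counts of a benchmark."""
    hist = Counter(len(p.labels) for p in dataset.proteins)
    return virtual_counts_from_histogram(hist)


@dataclass
class EvaluationReport:
    """Per-location correct/total bookkeeping plus the overall rate.

    ``per_location[l] = (correct, total)`` where ``total`` is the number of
    virtual samples carrying location l and ``correct`` the (possibly
    fractional, in penalized mode) credit they earned.
    """

    per_location: dict[int, tuple[float, int]]
    scoring_mode: str
    location_names: tuple[str, ...] = ()
    warnings: tuple[str, ...] = ()

    @property
    def total_correct(self) -> float:
        return sum(c for c, _ in self.per_location.values())

    @property
    def total_samples(self) -> int:
        return sum(t for _, t in self.per_location.values())

    @property
    def overall_rate(self) -> float:
        total = self.total_samples
        return self.total_correct / total if total else 0.0

    def location_rate(self, location: int) -> float:
        correct, total = self.per_location[location]
        return correct / total if total else 0.0

    def to_table(self) -> str:
        """Render the report as TSV: location, correct, total, percent
        (two-decimal percentages)."""
        lines = ["location\tcorrect\ttotal\tpercent"]
        for loc in sorted(self.per_location):
            correct, total = self.per_location[loc]
            name = (
                self.location_names[loc - 1]
                if loc - 1 < len(self.location_names)
                else str(loc)
            )
            pct = 100.0 * correct / total if total else 0.0
            lines.append(f"{name}\t{correct:g}\t{total}\t{pct:.2f}%")
        lines.append(
            f"Total\t{self.total_correct:g}\t{self.total_samples}\t"
            f"{100.0 * self.overall_rate:.2f}%"
        )
        return "\n".join(lines) + "\n"


def overall_from_counts(counts: Mapping[object, tuple[float, float]]) -> float:
    """Overall success rate from per-location (correct, total) pairs —
    the bottom-row aggregation convention of per-location report tables."""
    total_correct = sum(c for c, _ in counts.values())
    total = sum(t for _, t in counts.values())
    if total <= 0:
        raise ValueError("total sample count must be positive")
    return total_correct / total


def score_predictions(
    truth: Mapping[str, Set[int]],
    predicted: Mapping[str, Set[int]],
    mode: str = "locative",
    locations: Optional[Iterable[int]] = None,
    location_names: tuple[str, ...] = (),
    warnings: tuple[str, ...] = (),
) -> EvaluationReport:
    """Score predicted location sets against the truth, per virtual sample.

    Raises
    ------
    ValueError
        If the two mappings do not share the same protein keys.
    """
    if mode not in ("locative", "penalized"):
        raise ValueError("mode must be 'locative' or 'penalized'")
    if set(truth) != set(predicted):
        raise ValueError("truth and prediction keys differ")
    locs = set(locations or ())
    for t in truth.values():
        locs.update(t)
    per_location = {loc: [0.0, 0] for loc in sorted(locs)}
    for pid, t_set in truth.items():
        p_set = set(predicted[pid])
        t_set = set(t_set)
        if mode == "penalized":
            union = len(t_set | p_set)
            overlap = len(t_set & p_set) / union if union else 1.0
        for loc in t_set:
            per_location[loc][1] += 1
            if loc in p_set:
                per_location[loc][0] += 1.0 if mode == "locative" else overlap
    return EvaluationReport(
        {loc: (c, t) for loc, (c, t) in per_location.items()},
        mode,
        location_names,
        warnings,
    )


# --- reference-library construction -------------------------------------

def _descending_virtual_samples(
    proteins: Sequence[ProteinEntry],
) -> list[tuple[int, int]]:
    """(protein index, label) pairs, one per virtual sample.

    Copies of a multi-location protein are stored adjacent in DESCENDING
    label order.  Combined with the documented tie-breaks (distance ties →
    ascending sample index, belief ties → smallest class), this ordering
    lets exact-tie neighborhoods of multi-location twins split their member
    votes across the true labels instead of collapsing onto the lowest one.
    """
    out = []
    for i, p in enumerate(proteins):
        for label in sorted(p.labels, reverse=True):
            out.append((i, label))
    return out


def _mean_offdiag(mat: np.ndarray) -> float:
    n = mat.shape[0]
    if n < 2:
        return 1.0
    total = mat.sum() - np.trace(mat)
    mean = total / (n * (n - 1))
    return float(mean) if mean > 1e-12 else 1.0


def psepssm_features(
    proteins: Sequence[ProteinEntry], xi: int, coupling_exponent: float = 2.0
) -> np.ndarray:
    """Stacked pseudo-PSSM vectors for a protein list at one lag."""
    return np.vstack(
        [psepssm_vector(p.profile, xi, coupling_exponent).values for p in proteins]
    )


def build_go_library(
    dataset: BenchmarkDataset,
    config: Optional[RunConfig] = None,
    exclude: Set[str] = frozenset(),
) -> ReferenceLibrary:
    """GO-space reference library over productive (non-empty GO) proteins."""
    config = config or RunConfig()
    kept = [
        p
        for p in dataset.proteins
        if p.protein_id not in exclude and p.go_indices
    ]
    samples = _descending_virtual_samples(kept)
    return ReferenceLibrary(
        [kept[i].go_indices for i, _ in samples],
        np.array([label for _, label in samples], dtype=int),
        [kept[i].protein_id for i, _ in samples],
        "go",
        config.go_dimension,
    )


def build_seq_libraries(
    dataset: BenchmarkDataset,
    config: Optional[RunConfig] = None,
    exclude: Set[str] = frozenset(),
    lags: Optional[Iterable[int]] = None,
) -> dict[int, ReferenceLibrary]:
    """Per-lag combined FunD ⊕ PsePSSM reference libraries.

    The continuous block of each lag's space is normalized by the mean
    pairwise PsePSSM distance between the included proteins.
    """
    config = config or RunConfig()
    kept = [p for p in dataset.proteins if p.protein_id not in exclude]
    if not kept:
        raise ValueError("no proteins left after exclusion")
    min_len = min(p.profile.length for p in kept)
    xi_cap = min(config.xi_max, min_len - 1)
    lags = list(lags) if lags is not None else list(range(xi_cap + 1))
    samples = _descending_virtual_samples(kept)
    labels = np.array([label for _, label in samples], dtype=int)
    sids = [kept[i].protein_id for i, _ in samples]
    libraries = {}
    for xi in lags:
        pse = psepssm_features(kept, xi, config.coupling_exponent)
        scale = _mean_offdiag(cdist(pse, pse))
        params = SpaceParams(config.space_weight, scale)
        feats = [
            (kept[i].fund_indices, pse[i]) for i, _ in samples
        ]
        libraries[xi] = ReferenceLibrary(
            feats, labels, sids, "fund+psepssm", config.fund_dimension, params
        )
    return libraries


# --- jackknife ------------------------------------------------------------

def _jaccard_matrix(sets: Sequence[frozenset]) -> np.ndarray:
    n = len(sets)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = jaccard_distance(sets[i], sets[j])
            out[i, j] = out[j, i] = d
    return out


def _fold_gammas(
    dist: np.ndarray,
    class_to_prot: Mapping[int, np.ndarray],
) -> dict[int, float]:
    """Per-class gammas from a protein-level distance matrix.

    ``class_to_prot[c]`` lists the training protein indices carrying label
    c (a protein appears at most once per class, so virtual-sample and
    protein-level same-class distances coincide).
    """
    import math

    per_class: dict[int, float] = {}
    for cls, idx in class_to_prot.items():
        if len(idx) < 2:
            per_class[cls] = math.nan
            continue
        sub = dist[np.ix_(idx, idx)].copy()
        np.fill_diagonal(sub, np.inf)
        per_class[cls] = float((sub.min(axis=1) ** 2).mean())
    valid = [v for v in per_class.values() if not math.isnan(v) and v > 0]
    global_mean = float(np.mean(valid)) if valid else 0.0
    fallback = 1.0 / global_mean if global_mean > 0 else 1.0
    return {
        cls: (1.0 / v if not math.isnan(v) and v > 0 else fallback)
        for cls, v in per_class.items()
    }


@dataclass
class JackknifeResult:
    """Predictions plus double-mode reports from a leave-one-protein-out run."""

    predictions: dict[str, frozenset[int]]
    engines: dict[str, str]
    locative: EvaluationReport
    penalized: EvaluationReport
    warnings: tuple[str, ...]

    def report(self, mode: str) -> EvaluationReport:
        if mode == "locative":
            return self.locative
        if mode == "penalized":
            return self.penalized
        raise ValueError("mode must be 'locative' or 'penalized'")


def jackknife_predict_all(
    dataset: BenchmarkDataset, config: Optional[RunConfig] = None
) -> JackknifeResult:
    """Leave-one-protein-out prediction of every benchmark protein.

    All virtual samples of the withheld protein leave every reference
    library; the evidential scale parameters are refitted on the remaining
    proteins; the query is routed to the GO engine when its transferred GO
    terms overlap the training library and to the sequence engine otherwise.

    Uses precomputed protein-level distance matrices (features of a
    protein's virtual copies are identical, so sample distances reduce to
    protein distances); the member votes themselves go through the same
    :func:`~subcell.evclassifier.vote_from_distances` path as the public
    engines.
    """
    config = config or RunConfig()
    proteins = dataset.proteins
    n = len(proteins)
    if n < 2:
        raise ValueError("jackknife requires at least 2 distinct proteins")
    k_values = list(range(config.k_min, config.k_max + 1))

    go_sets = [p.go_indices for p in proteins]
    fund_sets = [p.fund_indices for p in proteins]
    min_len = min(p.profile.length for p in proteins)
    xi_cap = min(config.xi_max, min_len - 1)

    d_go = _jaccard_matrix(go_sets)
    d_fund = _jaccard_matrix(fund_sets)
    d_pse, pse_rowsum, pse_total = {}, {}, {}
    for xi in range(xi_cap + 1):
        mat = cdist(
            psepssm_features(proteins, xi, config.coupling_exponent),
            psepssm_features(proteins, xi, config.coupling_exponent),
        )
        d_pse[xi] = mat
        pse_rowsum[xi] = mat.sum(axis=1)
        pse_total[xi] = mat.sum()

    samples = _descending_virtual_samples(proteins)
    vs_prot = np.array([i for i, _ in samples], dtype=int)
    vs_label = np.array([label for _, label in samples], dtype=int)
    go_ok = np.array([bool(s) for s in go_sets])

    term_count: Counter = Counter()
    for s in go_sets:
        term_count.update(s)
    loc_presence: Counter = Counter()
    for p in proteins:
        loc_presence.update(p.labels)

    all_classes = sorted(loc_presence)
    prot_has = {
        c: np.array([c in p.labels for p in proteins]) for c in all_classes
    }

    predictions: dict[str, frozenset[int]] = {}
    engines: dict[str, str] = {}
    warnings: list[str] = []
    w = config.space_weight

    go_vs_mask_base = go_ok[vs_prot]

    for p_idx, prot in enumerate(proteins):
        for loc in prot.labels:
            if loc_presence[loc] - 1 == 0:
                warnings.append(
                    f"{prot.protein_id}: training fold lost location {loc} "
                    "entirely"
                )
        productive = any(term_count[t] > 1 for t in go_sets[p_idx])
        train_mask_prot = np.ones(n, dtype=bool)
        train_mask_prot[p_idx] = False

        if productive:
            engines[prot.protein_id] = "GO"
            vs_mask = go_vs_mask_base & (vs_prot != p_idx)
            sel_prot = vs_prot[vs_mask]
            sel_label = vs_label[vs_mask]
            dists = d_go[p_idx, sel_prot]
            class_to_prot = {
                c: np.where(prot_has[c] & go_ok & train_mask_prot)[0]
                for c in all_classes
            }
            gammas = _fold_gammas(d_go, {
                c: idx for c, idx in class_to_prot.items() if len(idx)
            })
            counts: Counter = Counter(
                vote_from_distances(
                    dists, sel_label, k, config.alpha, gammas,
                    config.mass_exponent,
                )
                for k in k_values
            )
            tally = VoteTally(dict(counts), len(k_values))
        else:
            engines[prot.protein_id] = "SEQ"
            vs_mask = vs_prot != p_idx
            sel_prot = vs_prot[vs_mask]
            sel_label = vs_label[vs_mask]
            counts = Counter()
            n_members = 0
            class_to_prot = {
                c: np.where(prot_has[c] & train_mask_prot)[0]
                for c in all_classes
            }
            class_to_prot = {c: i for c, i in class_to_prot.items() if len(i)}
            train_idx = np.where(train_mask_prot)[0]
            for xi in range(xi_cap + 1):
                denom = (n - 1) * (n - 2)
                if denom > 0:
                    s = (
                        pse_total[xi]
                        - 2.0 * pse_rowsum[xi][p_idx]
                    ) / denom
                else:
                    s = 1.0
                if s <= 1e-12:
                    s = 1.0
                d_comb = w * d_fund + (1.0 - w) * d_pse[xi] / s
                dists = d_comb[p_idx, sel_prot]
                gammas = _fold_gammas(d_comb, class_to_prot)
                for k in k_values:
                    counts[
                        vote_from_distances(
                            dists, sel_label, k, config.alpha, gammas,
                            config.mass_exponent,
                        )
                    ] += 1
                n_members += len(k_values)
            tally = VoteTally(dict(counts), n_members)
        predictions[prot.protein_id] = multilabel_select(tally, config.theta)

    truth = dataset.truth
    locs = range(1, len(dataset.location_names) + 1)
    locative = score_predictions(
        truth, predictions, "locative", locs, dataset.location_names,
        tuple(warnings),
    )
    penalized = score_predictions(
        truth, predictions, "penalized", locs, dataset.location_names,
        tuple(warnings),
    )
    return JackknifeResult(
        predictions, engines, locative, penalized, tuple(warnings)
    )


def jackknife(
    dataset: BenchmarkDataset,
    config: Optional[RunConfig] = None,
    mode: Optional[str] = None,
) -> EvaluationReport:
    """Leave-one-protein-out evaluation report (mode from the config unless
    given explicitly)."""
    config = config or RunConfig()
    result = jackknife_predict_all(dataset, config)
    return result.report(mode or config.scoring_mode)
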