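"""Evidence-theoretic K-nearest-neighbor (ET-KNN) single-vote classifier.

Each of the K nearest reference samples contributes a basic belief
assignment: a sample of class c at distance d supports the singleton {c}
with mass ``m({c}) = alpha * exp(-gamma_c * d**q)`` (q = 2 by default) and
leaves the remainder ``1 - m({c})`` on the whole frame of discernment.
The K assignments are fused with Dempster's rule of combination and the
query is assigned to the singleton with the largest combined belief.  The
"optimized" variant tunes the per-class scale parameters gamma_c on the
reference library.

The classifier is feature-space agnostic: binary index-set spaces (GO,
functional domains) use the Jaccard distance, continuous pseudo-PSSM blocks
use the Euclidean distance, and the combined domain+evolution space mixes
the two as a convex combination of normalized per-space distances.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

MASS_TOL = 1e-9

#: Recognized feature-space tags.
SPACE_TAGS = ("go", "fund", "psepssm", "fund+psepssm")


@dataclass(frozen=True)
class SpaceParams:
    """Parameters of the combined FunD ⊕ PsePSSM space.

    ``weight`` is the convex weight on the binary (Jaccard) block;
    ``pse_scale`` normalizes the continuous block (typically the mean
    pairwise PsePSSM distance of the training library).
    """

    weight: float = 0.5
    pse_scale: float = 1.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.weight <= 1.0:
            raise ValueError("weight must lie in [0, 1]")
        if not self.pse_scale > 0:
            raise ValueError("pse_scale must be positive")


@dataclass
class ReferenceLibrary:
    """Labeled reference samples over one feature space.

    A protein annotated to m locations appears m times ("virtual samples"),
    once per location label.  ``features`` holds per-sample feature objects:
    frozensets for binary spaces, 1-D float arrays for the PsePSSM space, or
    ``(frozenset, ndarray)`` pairs for the combined space.
    """

    features: list
    labels: np.ndarray
    source_ids: list[str]
    space_tag: str
    dimension: int = 0
    params: SpaceParams = field(default_factory=SpaceParams)

    def __post_init__(self) -> None:
        if self.space_tag not in SPACE_TAGS:
            raise ValueError(f"unknown space tag {self.space_tag!r}")
        self.labels = np.asarray(self.labels, dtype=int)
        if not (len(self.features) == len(self.labels) == len(self.source_ids)):
            raise ValueError("features, labels and source_ids must align")

    def __len__(self) -> int:
        return len(self.features)

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)

    def distances_to(self, query) -> np.ndarray:
        """Distances from a query feature to every library sample."""
        if self.space_tag == "psepssm":
            mat = np.vstack(self.features)
            q = np.asarray(query, dtype=float)
            return np.sqrt(((mat - q[None, :]) ** 2).sum(axis=1))
        if self.space_tag in ("go", "fund"):
            return np.array(
                [jaccard_distance(query, f) for f in self.features]
            )
        # combined space
        qset, qvec = query
        qvec = np.asarray(qvec, dtype=float)
        mat = np.vstack([f[1] for f in self.features])
        d_pse = np.sqrt(((mat - qvec[None, :]) ** 2).sum(axis=1))
        d_bin = np.array([jaccard_distance(qset, f[0]) for f in self.features])
        w = self.params.weight
        return w * d_bin + (1.0 - w) * d_pse / self.params.pse_scale

    def pairwise_distances(self) -> np.ndarray:
        """Full sample-by-sample distance matrix (used by gamma fitting)."""
        n = len(self)
        out = np.zeros((n, n))
        for i in range(n):
            row = self.distances_to(self.features[i])
            out[i, :] = row
        return out


def jaccard_distance(a, b) -> float:
    """Jaccard distance between two index sets; 0 when both are empty."""
    a, b = set(a), set(b)
    union = len(a | b)
    if union == 0:
        return 0.0
    return 1.0 - len(a & b) / union


def space_distance(a, b, space_tag: str, params: Optional[SpaceParams] = None) -> float:
    """Distance between two feature objects in the tagged space.

    Binary spaces use the Jaccard distance on nonzero index sets, the
    PsePSSM space the Euclidean distance, and the combined space the convex
    mix ``w * d_FunD + (1 - w) * d_PsePSSM / s``.
    """
    if space_tag in ("go", "fund"):
        return jaccard_distance(a, b)
    if space_tag == "psepssm":
        a = np.asarray(a, dtype=float)
        b = np.asarray(b, dtype=float)
        if a.shape != b.shape:
            raise ValueError(f"dimension mismatch: {a.shape} vs {b.shape}")
        return float(np.sqrt(((a - b) ** 2).sum()))
    if space_tag == "fund+psepssm":
        params = params or SpaceParams()
        aset, avec = a
        bset, bvec = b
        d_pse = space_distance(avec, bvec, "psepssm")
        d_bin = jaccard_distance(aset, bset)
        return params.weight * d_bin + (1.0 - params.weight) * d_pse / params.pse_scale
    raise ValueError(f"unknown space tag {space_tag!r}")


@dataclass(frozen=True)
class MassAssignment:
    """Basic belief assignment with singleton focal sets plus the frame."""

    singleton_masses: Mapping[int, float]
    frame_mass: float

    def __post_init__(self) -> None:
        total = self.frame_mass + sum(self.singleton_masses.values())
        if self.frame_mass < -MASS_TOL or any(
            m < -MASS_TOL for m in self.singleton_masses.values()
        ):
            raise ValueError("masses must be non-negative")
        if abs(total - 1.0) > MASS_TOL:
            raise ValueError(f"masses must sum to 1, got {total}")
        object.__setattr__(
            self, "singleton_masses", dict(self.singleton_masses)
        )


def neighbor_masses(
    neighbors: Sequence[tuple[float, int]],
    alpha: float,
    gammas: Mapping[int, float],
    exponent: float = 2.0,
) -> list[MassAssignment]:
    """One belief assignment per neighbor ``(distance, class)``.

    A neighbor of class c at distance d yields
    ``m({c}) = alpha * exp(-gamma_c * d**exponent)`` and puts the rest on
    the frame.
    """
    if not neighbors:
        raise ValueError("at least one neighbor is required")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie in (0, 1)")
    out = []
    for distance, cls in neighbors:
        if not math.isfinite(distance):
            raise ValueError(f"non-finite distance {distance!r}")
        gamma = gammas[cls]
        m = alpha * math.exp(-gamma * distance**exponent)
        out.append(MassAssignment({int(cls): m}, 1.0 - m))
    return out


def combine_masses(
    masses: Sequence[MassAssignment], normalized: bool = True
) -> dict[int, float]:
    """Dempster combination of singleton-plus-frame assignments.

    Returns the combined belief (= combined mass) of each singleton class.
    With only singleton and frame focal sets, the combination has the closed
    form  ``m({c}) ∝ (1 - u_c) * U / u_c``,  ``m(Ω) ∝ U``  where
    ``u_c = Π_{k: class_k = c} (1 - m_k)`` and ``U = Π_k (1 - m_k)``.
    The operation is associative and commutative.

    Raises
    ------
    ValueError
        On total conflict (normalization constant 0), which signals
        degenerate parameters.
    """
    if not masses:
        raise ValueError("at least one mass assignment is required")
    u: dict[int, float] = {}
    for ma in masses:
        for cls, m in ma.singleton_masses.items():
            u[cls] = u.get(cls, 1.0) * (1.0 - m)
    # U = product over all assignments of (1 - m_k)
    big_u = 1.0
    for ma in masses:
        for m in ma.singleton_masses.values():
            big_u *= 1.0 - m
    unnorm = {}
    for cls, u_c in u.items():
        if u_c <= 0.0:
            # a neighbor was fully certain (m = 1): all mass collapses there
            unnorm[cls] = math.inf
        else:
            unnorm[cls] = (1.0 - u_c) * big_u / u_c
    if any(math.isinf(v) for v in unnorm.values()):
        certain = [cls for cls, v in unnorm.items() if math.isinf(v)]
        if len(certain) > 1:
            raise ValueError(
                "total conflict between fully certain assignments "
                f"for classes {sorted(certain)}"
            )
        return {cls: (1.0 if cls in certain else 0.0) for cls in unnorm}
    norm = sum(unnorm.values()) + big_u
    if not normalized:
        return unnorm
    if norm <= 0.0:
        raise ValueError(
            "degenerate combination: normalization constant is zero"
        )
    return {cls: v / norm for cls, v in unnorm.items()}


def etknn_vote(
    query,
    library: ReferenceLibrary,
    k: int,
    alpha: float = 0.95,
    gammas: Optional[Mapping[int, float]] = None,
    distances: Optional[np.ndarray] = None,
    exponent: float = 2.0,
) -> int:
    """Single evidential-KNN vote: the class with the largest combined belief
    among the K nearest reference samples.

    Ties on distance at the K boundary are broken by ascending sample index;
    ties on belief by the smallest class label.  ``distances`` may supply
    precomputed query-to-library distances (must align with the library).
    """
    if len(library) == 0:
        raise ValueError("reference library is empty")
    if not 1 <= k <= len(library):
        raise ValueError(f"k must lie in [1, {len(library)}], got {k}")
    if distances is None:
        distances = library.distances_to(query)
    if gammas is None:
        gammas = fit_gammas(library)
    return vote_from_distances(
        np.asarray(distances, dtype=float), library.labels, k, alpha, gammas,
        exponent,
    )


def vote_from_distances(
    distances: np.ndarray,
    labels: np.ndarray,
    k: int,
    alpha: float,
    gammas: Mapping[int, float],
    exponent: float = 2.0,
) -> int:
    """Evidential vote from precomputed query-to-sample distances.

    Shared by :func:`etknn_vote` and the jackknife fast path.  Distance ties
    at the K boundary resolve by ascending sample index (stable sort);
    belief ties by the smallest class label.
    """
    order = np.argsort(distances, kind="stable")[:k]
    neighbors = [(float(distances[i]), int(labels[i])) for i in order]
    beliefs = combine_masses(
        neighbor_masses(neighbors, alpha, gammas, exponent)
    )
    best = min(beliefs.items(), key=lambda kv: (-kv[1], kv[0]))
    return best[0]


def _nn_same_class_sq(dist: np.ndarray, labels: np.ndarray) -> dict[int, float]:
    """Mean squared nearest same-class neighbor distance per class.

    Classes with a single sample get ``nan``.
    """
    out: dict[int, float] = {}
    for cls in np.unique(labels):
        idx = np.where(labels == cls)[0]
        if len(idx) < 2:
            out[int(cls)] = math.nan
            continue
        sub = dist[np.ix_(idx, idx)].copy()
        np.fill_diagonal(sub, np.inf)
        out[int(cls)] = float((sub.min(axis=1) ** 2).mean())
    return out


def gammas_from_distance_matrix(
    dist: np.ndarray, labels: np.ndarray
) -> dict[int, float]:
    """Heuristic per-class scale parameters from a pairwise distance matrix.

    ``gamma_c = 1 / mean squared same-class nearest-neighbor distance``.
    Classes with fewer than 2 samples, or whose mean is 0 (duplicated
    points), fall back to the pooled global mean; if everything is
    degenerate the scale defaults to 1.
    """
    labels = np.asarray(labels, dtype=int)
    per_class = _nn_same_class_sq(dist, labels)
    valid = [v for v in per_class.values() if not math.isnan(v) and v > 0]
    global_mean = float(np.mean(valid)) if valid else 0.0
    fallback = 1.0 / global_mean if global_mean > 0 else 1.0
    gammas = {}
    for cls, mean_sq in per_class.items():
        if math.isnan(mean_sq) or mean_sq <= 0:
            gammas[cls] = fallback
        else:
            gammas[cls] = 1.0 / mean_sq
    return gammas


def fit_gammas(
    library: ReferenceLibrary,
    refine: bool = False,
    refine_k: int = 3,
    alpha: float = 0.95,
    grid: Sequence[float] = (0.25, 0.5, 1.0, 2.0, 4.0),
) -> dict[int, float]:
    """Fit the per-class evidential scale parameters on a reference library.

    The heuristic rule inverts each class's mean squared nearest same-class
    neighbor distance.  With ``refine=True`` a common scalar multiplier is
    grid-searched to minimize the leave-one-out error of the ``refine_k``-NN
    vote on the library itself.
    """
    dist = library.pairwise_distances()
    gammas = gammas_from_distance_matrix(dist, library.labels)
    if not refine or len(library) < 3:
        return gammas
    best_scale, best_err = 1.0, None
    n = len(library)
    for scale in grid:
        scaled = {c: g * scale for c, g in gammas.items()}
        errors = 0
        for i in range(n):
            mask = np.arange(n) != i
            sub = ReferenceLibrary(
                [library.features[j] for j in range(n) if mask[j]],
                library.labels[mask],
                [library.source_ids[j] for j in range(n) if mask[j]],
                library.space_tag,
                library.dimension,
                library.params,
            )
            k = min(refine_k, len(sub))
            pred = etknn_vote(
                library.features[i],
                sub,
                k,
                alpha,
                scaled,
                distances=dist[i, mask],
            )
            errors += pred != library.labels[i]
        if best_err is None or errors < best_err:
            best_err, best_scale = errors, scale
    return {c: g * best_scale for c, g in gammas.items()}


# --- serialization -------------------------------------------------------

def _encode_feature(feature, space_tag: str) -> str:
    if space_tag in ("go", "fund"):
        return ",".join(str(i) for i in sorted(feature))
    if space_tag == "psepssm":
        return ",".join(f"{v:.12g}" for v in feature)
    idx, vec = feature
    return (
        ",".join(str(i) for i in sorted(idx))
        + "|"
        + ",".join(f"{v:.12g}" for v in vec)
    )


def _decode_feature(text: str, space_tag: str):
    if space_tag in ("go", "fund"):
        return frozenset(int(t) for t in text.split(",") if t)
    if space_tag == "psepssm":
        return np.array([float(t) for t in text.split(",") if t])
    idx_part, vec_part = text.split("|")
    return (
        frozenset(int(t) for t in idx_part.split(",") if t),
        np.array([float(t) for t in vec_part.split(",") if t]),
    )


def write_library(library: ReferenceLibrary, path, manifest_path=None) -> None:
    """Serialize a reference library to TSV plus a JSON manifest recording
    the space tag, dimension, mixing parameters and fitted gammas."""
    path = str(path)
    manifest_path = str(manifest_path or path + ".manifest.json")
    with open(path, "w") as fh:
        fh.write("source_id\tlabel\tfeature\n")
        for feat, label, sid in zip(
            library.features, library.labels, library.source_ids
        ):
            fh.write(f"{sid}\t{int(label)}\t{_encode_feature(feat, library.space_tag)}\n")
    manifest = {
        "space_tag": library.space_tag,
        "dimension": library.dimension,
        "n_samples": len(library),
        "weight": library.params.weight,
        "pse_scale": library.params.pse_scale,
        "gammas": {str(c): g for c, g in fit_gammas(library).items()},
    }
    with open(manifest_path, "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def read_library(path, manifest_path=None) -> ReferenceLibrary:
    """Inverse of :func:`write_library`."""
    path = str(path)
    manifest_path = str(manifest_path or path + ".manifest.json")
    with open(manifest_path) as fh:
        manifest = json.load(fh)
    features, labels, sids = [], [], []
    with open(path) as fh:
        next(fh)
        for line in fh:
            sid, label, feat = line.rstrip("\n").split("\t")
            sids.append(sid)
            labels.append(int(label))
            features.append(_decode_feature(feat, manifest["space_tag"]))
    return ReferenceLibrary(
        features,
        np.array(labels, dtype=int),
        sids,
        manifest["space_tag"],
        manifest["dimension"],
        SpaceParams(manifest["weight"], manifest["pse_scale"]),
    )
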