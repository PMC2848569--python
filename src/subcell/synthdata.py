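"""Fully synthetic multi-label localization benchmarks.

The generator emulates the statistical structure the predictor relies on:
each subcellular location owns an exclusive block of GO terms, an exclusive
block of conserved domains and a characteristic PSSM column bias; proteins
annotated to several locations carry the union (GO/domains) or the mean
(PSSM bias) of their locations' signatures; homologs — the proteins a BLAST
search would return — are the other proteins sharing the same label set.
A configurable fraction of single-location proteins has no homolog at all,
exercising the sequence-engine routing branch.

Two structural guarantees make a noise-free benchmark exactly recoverable
by the leave-one-protein-out test (and are deliberately part of the design,
see docs/methods.md):

* label SETS are drawn first and proteins are partitioned over them so that
  every realized set has at least ``ceil(10/m) + 1`` exemplars (m = set
  size) — every withheld protein then retains at least 10 identical-
  signature virtual twins in training, enough for all K = 1..10 members;
* homolog-less proteins are sampled among single-location proteins only,
  so multi-location neighborhoods are never starved.

``noise`` in [0, 1] drives four corruption channels: annotation dropout and
spurious terms, per-entry PSSM jitter, degraded homolog identities, and —
the dominant one — homolog misassignment: with probability ``noise`` a
protein's BLAST hits point at a wrong-location family (a paralog trap) and
its domain and profile evidence blends toward that location.  At
``noise = 0`` every feature is a deterministic function of the protein's
label set.
"""

from __future__ import annotations

import itertools
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .annotations import (
    FUND_DIMENSION,
    GO_DIMENSION,
    build_homology_set,
    fund_vector,
    go_vector,
    read_blast_tabular,
    read_domain_hits,
    read_go_annotations,
)
from .config import RunConfig
from .evaluation import EUK22_LOCATIONS, BenchmarkDataset, ProteinEntry
from .profiles import (
    AMINO_ACIDS,
    PSSMProfile,
    normalize_profile,
    read_ascii_pssm,
    write_ascii_pssm,
)

#: Multiplicity proportions of the curated eukaryotic benchmark
#: (6,687 : 1,029 : 48 : 2 proteins with 1..4 locations).
BENCHMARK_MULTIPLICITY = (6687.0, 1029.0, 48.0, 2.0)

#: Minimum exemplars per realized label set so every jackknife query keeps
#: >= 10 identical-signature virtual twins for the K = 1..10 members.
def _required_exemplars(m: int, k_max: int = 10) -> int:
    return math.ceil(k_max / m) + 1


@dataclass
class SyntheticConfig:
    """Knobs of the synthetic benchmark generator (defaults = the baseline
    study conditions; see docs/methods.md for rationale)."""

    n_locations: int = 5
    n_proteins: int = 200
    multiplicity_probs: tuple[float, ...] = BENCHMARK_MULTIPLICITY
    separation: float = 6.0
    noise: float = 0.0
    go_dimension: int = GO_DIMENSION
    fund_dimension: int = FUND_DIMENSION
    terms_per_location: int = 12
    domains_per_location: int = 8
    min_len: int = 60
    max_len: int = 120
    orphan_frac: float = 0.15
    max_homologs: int = 50
    pssm_noise_scale: float = 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_locations < 2:
            raise ValueError("need at least 2 locations")
        if self.n_proteins < 2:
            raise ValueError("need at least 2 proteins")
        probs = np.asarray(self.multiplicity_probs, dtype=float)
        if probs.ndim != 1 or len(probs) < 1 or (probs < 0).any() or probs.sum() <= 0:
            raise ValueError("multiplicity_probs must be non-negative with a positive sum")
        if len(probs) > min(4, self.n_locations):
            probs = probs[: min(4, self.n_locations)]
        self.multiplicity_probs = tuple(probs / probs.sum())
        if not self.min_len <= self.max_len:
            raise ValueError("min_len must not exceed max_len")
        if not 0.0 <= self.noise <= 1.0:
            raise ValueError("noise must lie in [0, 1]")
        if self.separation < 0:
            raise ValueError("separation must be non-negative")
        if not 0.0 <= self.orphan_frac <= 1.0:
            raise ValueError("orphan_frac must lie in [0, 1]")
        if self.n_locations > len(EUK22_LOCATIONS):
            raise ValueError(
                f"at most {len(EUK22_LOCATIONS)} named locations supported"
            )

    @property
    def location_names(self) -> tuple[str, ...]:
        return EUK22_LOCATIONS[: self.n_locations]


def _apportion(n: int, probs: tuple[float, ...]) -> list[int]:
    """Largest-remainder apportionment of n items over probability weights."""
    raw = [n * p for p in probs]
    counts = [int(x) for x in raw]
    remainder = n - sum(counts)
    order = sorted(
        range(len(probs)), key=lambda i: (raw[i] - counts[i], -i), reverse=True
    )
    for i in order[:remainder]:
        counts[i] += 1
    return counts


def sample_label_sets(config: SyntheticConfig, rng: np.random.Generator) -> list[tuple[int, ...]]:
    """Assign each protein a sorted tuple of 1-based location labels.

    Multiplicity counts follow ``multiplicity_probs`` (largest-remainder
    apportionment).  Distinct label sets are drawn first and proteins are
    partitioned over them so each realized set keeps at least
    ``ceil(10/m) + 1`` exemplars; multiplicity classes too small to honor
    that floor are folded into the single-location class.
    """
    counts = _apportion(config.n_proteins, config.multiplicity_probs)
    counts += [0] * (4 - len(counts))
    for m in (2, 3, 4):
        need = _required_exemplars(m)
        if 0 < counts[m - 1] < need:
            counts[0] += counts[m - 1]
            counts[m - 1] = 0

    assignments: list[tuple[int, ...]] = []
    # single-location sets: every location is represented
    singles = [(l,) for l in range(1, config.n_locations + 1)]
    for i in range(counts[0]):
        assignments.append(singles[i % len(singles)])
    # multi-location sets
    for m in (2, 3, 4):
        n_m = counts[m - 1]
        if n_m == 0:
            continue
        n_sets = max(1, n_m // _required_exemplars(m))
        combos = list(itertools.combinations(range(1, config.n_locations + 1), m))
        n_sets = min(n_sets, len(combos))
        chosen = [combos[i] for i in rng.choice(len(combos), n_sets, replace=False)]
        for i in range(n_m):
            assignments.append(chosen[i % n_sets])
    order = rng.permutation(len(assignments))
    return [assignments[i] for i in order]


@dataclass
class _Signatures:
    go_terms: np.ndarray      # (n_locations, terms_per_location) 1-based
    domains: np.ndarray       # (n_locations, domains_per_location) 1-based
    pssm_bias: np.ndarray     # (n_locations, 20)


def _draw_signatures(config: SyntheticConfig, rng: np.random.Generator) -> _Signatures:
    n_go = config.n_locations * config.terms_per_location
    n_dom = config.n_locations * config.domains_per_location
    go = rng.choice(config.go_dimension, size=n_go, replace=False) + 1
    dom = rng.choice(config.fund_dimension, size=n_dom, replace=False) + 1
    bias = rng.normal(0.0, 1.0, size=(config.n_locations, 20))
    return _Signatures(
        go.reshape(config.n_locations, -1),
        dom.reshape(config.n_locations, -1),
        bias,
    )


def _set_go_signature(sig: _Signatures, labels: tuple[int, ...]) -> frozenset[int]:
    return frozenset(int(t) for l in labels for t in sig.go_terms[l - 1])


def _set_domain_signature(sig: _Signatures, labels: tuple[int, ...]) -> frozenset[int]:
    return frozenset(int(d) for l in labels for d in sig.domains[l - 1])


def _set_pssm_bias(sig: _Signatures, labels: tuple[int, ...]) -> np.ndarray:
    return sig.pssm_bias[[l - 1 for l in labels], :].mean(axis=0)


def make_pssm_scores(
    length: int,
    bias: np.ndarray,
    rng: np.random.Generator,
    separation: float = 6.0,
    noise: float = 0.0,
    noise_scale: float = 3.0,
) -> np.ndarray:
    """Integer PSSM score matrix: a location-specific column bias plus
    noise-scaled jitter, rounded to integers.  At ``noise = 0`` every row
    equals the rounded bias, so columns are constant along the chain."""
    base = np.broadcast_to(
        separation * np.asarray(bias, dtype=float), (length, 20)
    ).copy()
    if noise > 0:
        base += noise_scale * noise * rng.normal(size=(length, 20))
    return np.rint(base).astype(int)


def make_pssm_fixture(
    sequence: str,
    location_signature: np.ndarray,
    seed: int,
    separation: float = 6.0,
    noise: float = 0.0,
    protein_id: str = "fixture",
) -> str:
    """ASCII PSSM text for a sequence with a given 20-column bias signature.

    The emitted text round-trips exactly through the ASCII PSSM reader.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    rng = np.random.default_rng(seed)
    scores = make_pssm_scores(
        len(sequence), location_signature, rng, separation, noise
    )
    return write_ascii_pssm(PSSMProfile(protein_id, sequence, scores))


def _perturb_indices(
    base: frozenset[int],
    noise: float,
    dimension: int,
    rng: np.random.Generator,
) -> frozenset[int]:
    """Drop each index with probability ``noise`` and add a binomial number
    of spurious uniform indices."""
    if noise <= 0:
        return base
    kept = {i for i in sorted(base) if rng.random() >= noise}
    n_spur = rng.binomial(len(base), noise)
    if n_spur:
        kept.update(int(i) for i in rng.integers(1, dimension + 1, n_spur))
    return frozenset(kept)


def make_benchmark(
    config: SyntheticConfig,
    out_dir=None,
    run_config: RunConfig | None = None,
) -> BenchmarkDataset:
    """Generate a synthetic benchmark; optionally write it as fixture files.

    Deterministic given ``config.seed``: repeated calls produce identical
    datasets and byte-identical files.  Features of the returned dataset
    (GO vectors, domain vectors, normalized profiles) are derived through
    the same public operations a real pipeline would use on the files.
    """
    run_config = run_config or RunConfig(
        go_dimension=config.go_dimension, fund_dimension=config.fund_dimension
    )
    rng = np.random.default_rng(config.seed)
    label_sets = sample_label_sets(config, rng)
    n = len(label_sets)
    sig = _draw_signatures(config, rng)
    ids = [f"SYN{i + 1:05d}" for i in range(n)]

    lengths = rng.integers(config.min_len, config.max_len + 1, size=n)
    aa = np.array(list(AMINO_ACIDS))
    sequences = ["".join(rng.choice(aa, size=int(L))) for L in lengths]

    orphan = np.zeros(n, dtype=bool)
    for i, labels in enumerate(label_sets):
        if len(labels) == 1:
            orphan[i] = rng.random() < config.orphan_frac

    # homolog misassignment: with probability `noise` a protein's search
    # hits land in a wrong-location family and its domain/profile evidence
    # blends toward that location
    confound_loc = np.zeros(n, dtype=int)  # 0 = clean
    for i, labels in enumerate(label_sets):
        if config.noise > 0 and rng.random() < config.noise:
            wrong = [
                l for l in range(1, config.n_locations + 1) if l not in labels
            ]
            if wrong:
                confound_loc[i] = int(rng.choice(wrong))

    # raw evidence per protein -------------------------------------------
    profiles: list[PSSMProfile] = []
    gaf: dict[str, frozenset[int]] = {}
    domain_rows: list[tuple[str, int, float]] = []
    for i, labels in enumerate(label_sets):
        bias = _set_pssm_bias(sig, labels)
        dom_sig = set(_set_domain_signature(sig, labels))
        w_loc = int(confound_loc[i])
        if w_loc:
            bias = 0.5 * bias + 0.5 * sig.pssm_bias[w_loc - 1]
            dom_sig = {d for d in sorted(dom_sig) if rng.random() < 0.5}
            dom_sig.update(int(d) for d in sig.domains[w_loc - 1])
        scores = make_pssm_scores(
            int(lengths[i]),
            bias,
            rng,
            config.separation,
            config.noise,
            config.pssm_noise_scale,
        )
        profiles.append(PSSMProfile(ids[i], sequences[i], scores))
        gaf[ids[i]] = _perturb_indices(
            _set_go_signature(sig, labels), config.noise, config.go_dimension, rng
        )
        for d in sorted(
            _perturb_indices(
                frozenset(dom_sig),
                config.noise,
                config.fund_dimension,
                rng,
            )
        ):
            domain_rows.append((ids[i], d, 1e-8))

    # homolog hit table ---------------------------------------------------
    by_set: dict[tuple[int, ...], list[int]] = {}
    for i, labels in enumerate(label_sets):
        by_set.setdefault(labels, []).append(i)
    by_location: dict[int, list[int]] = {}
    for i, labels in enumerate(label_sets):
        for l in labels:
            by_location.setdefault(l, []).append(i)
    blast_rows: list[tuple] = []
    for i, labels in enumerate(label_sets):
        if orphan[i]:
            continue
        w_loc = int(confound_loc[i])
        if w_loc:
            pool = by_set.get((w_loc,), by_location.get(w_loc, []))
            twins = [j for j in pool if j != i][: config.max_homologs]
        else:
            twins = [j for j in by_set[labels] if j != i][: config.max_homologs]
        for j in twins:
            if config.noise > 0 and rng.random() < config.noise:
                continue
            pident = 90.0 - 35.0 * config.noise * rng.random()
            blast_rows.append(
                (ids[i], ids[j], round(pident, 2), 100, 5, 0, 1, 100, 1, 100,
                 1e-30, 250.0)
            )
        if config.noise > 0:
            n_spur = rng.binomial(max(len(twins), 1), config.noise)
            for j in rng.integers(0, n, n_spur):
                if int(j) == i:
                    continue
                blast_rows.append(
                    (ids[i], ids[int(j)], 75.0, 80, 10, 1, 1, 80, 1, 80,
                     1e-10, 180.0)
                )
    blast = pd.DataFrame(
        blast_rows,
        columns=(
            "qseqid sseqid pident length mismatch gapopen "
            "qstart qend sstart send evalue bitscore"
        ).split(),
    )

    # derived features through the public operations ----------------------
    proteins: list[ProteinEntry] = []
    dom_by_protein: dict[str, list[tuple[int, float]]] = {}
    for pid, d, ev in domain_rows:
        dom_by_protein.setdefault(pid, []).append((d, ev))
    for i, labels in enumerate(label_sets):
        hset = build_homology_set(
            blast, ids[i], run_config.identity_min, run_config.evalue_max_go
        )
        gvec = go_vector(hset, gaf, config.go_dimension)
        fvec = fund_vector(
            dom_by_protein.get(ids[i], []),
            run_config.evalue_max_fund,
            config.fund_dimension,
            ids[i],
        )
        proteins.append(
            ProteinEntry(
                protein_id=ids[i],
                sequence=sequences[i],
                labels=labels,
                go_indices=gvec.nonzero_indices,
                fund_indices=fvec.nonzero_indices,
                profile=normalize_profile(profiles[i]),
                has_homologs=not hset.is_empty,
            )
        )
    dataset = BenchmarkDataset(proteins, config.location_names)

    if out_dir is not None:
        _write_fixture_dir(
            Path(out_dir), config, dataset, profiles, gaf, domain_rows, blast
        )
    return dataset


def _write_fixture_dir(
    out_dir: Path,
    config: SyntheticConfig,
    dataset: BenchmarkDataset,
    profiles: list[PSSMProfile],
    gaf: dict[str, frozenset[int]],
    domain_rows: list[tuple[str, int, float]],
    blast: pd.DataFrame,
) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    (out_dir / "pssm").mkdir(exist_ok=True)
    records = [
        SeqRecord(Seq(p.sequence), id=p.protein_id, description="")
        for p in dataset.proteins
    ]
    SeqIO.write(records, str(out_dir / "proteins.fasta"), "fasta")
    with open(out_dir / "labels.tsv", "w") as fh:
        for p in dataset.proteins:
            names = ";".join(dataset.location_names[l - 1] for l in p.labels)
            fh.write(f"{p.protein_id}\t{names}\n")
    for prof in profiles:
        (out_dir / "pssm" / f"{prof.protein_id}.pssm").write_text(
            write_ascii_pssm(prof)
        )
    blast.to_csv(
        out_dir / "blast_hits.tsv", sep="\t", header=False, index=False,
        float_format="%.6g",
    )
    go_indices = sorted({t for terms in gaf.values() for t in terms})
    with open(out_dir / "go_index.tsv", "w") as fh:
        for t in go_indices:
            fh.write(f"GO:{t:07d}\t{t}\n")
    with open(out_dir / "go_annotations.tsv", "w") as fh:
        for pid in sorted(gaf):
            for t in sorted(gaf[pid]):
                fh.write(f"{pid}\tGO:{t:07d}\n")
    dom_indices = sorted({d for _, d, _ in domain_rows})
    with open(out_dir / "domain_index.tsv", "w") as fh:
        for d in dom_indices:
            fh.write(f"cd{d:05d}\t{d}\n")
    with open(out_dir / "domain_hits.tsv", "w") as fh:
        for pid, d, ev in domain_rows:
            fh.write(f"{pid}\tcd{d:05d}\t{ev:.3g}\n")
    manifest = {
        "format": "subcell-benchmark/1",
        "config": asdict(config),
        "locations": list(dataset.location_names),
        "n_proteins": len(dataset),
        "files": {
            "fasta": "proteins.fasta",
            "labels": "labels.tsv",
            "pssm_dir": "pssm",
            "blast_hits": "blast_hits.tsv",
            "go_annotations": "go_annotations.tsv",
            "go_index": "go_index.tsv",
            "domain_hits": "domain_hits.tsv",
            "domain_index": "domain_index.tsv",
        },
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
        fh.write("\n")


def load_benchmark(
    bench_dir, run_config: RunConfig | None = None
) -> BenchmarkDataset:
    """Rebuild a BenchmarkDataset from a fixture directory written by
    :func:`make_benchmark`, deriving all features from the files."""
    bench_dir = Path(bench_dir)
    with open(bench_dir / "manifest.json") as fh:
        manifest = json.load(fh)
    cfg = manifest["config"]
    run_config = run_config or RunConfig(
        go_dimension=cfg["go_dimension"], fund_dimension=cfg["fund_dimension"]
    )
    locations = tuple(manifest["locations"])
    name_to_idx = {name: i + 1 for i, name in enumerate(locations)}
    files = manifest["files"]

    sequences = {
        rec.id: str(rec.seq)
        for rec in SeqIO.parse(str(bench_dir / files["fasta"]), "fasta")
    }
    labels: dict[str, tuple[int, ...]] = {}
    with open(bench_dir / files["labels"]) as fh:
        for line in fh:
            pid, names = line.rstrip("\n").split("\t")
            labels[pid] = tuple(
                sorted(name_to_idx[nm] for nm in names.split(";"))
            )
    blast_path = bench_dir / files["blast_hits"]
    if blast_path.stat().st_size > 0:
        blast = read_blast_tabular(blast_path)
    else:
        blast = pd.DataFrame(
            columns="qseqid sseqid pident evalue".split()
        )
    gaf = read_go_annotations(
        bench_dir / files["go_annotations"], bench_dir / files["go_index"]
    )
    dom = read_domain_hits(
        bench_dir / files["domain_hits"], bench_dir / files["domain_index"]
    )
    proteins = []
    for pid in sorted(sequences):
        hset = build_homology_set(
            blast, pid, run_config.identity_min, run_config.evalue_max_go
        )
        gvec = go_vector(hset, gaf, cfg["go_dimension"])
        sub = dom[dom["protein_id"] == pid]
        fvec = fund_vector(
            sub, run_config.evalue_max_fund, cfg["fund_dimension"], pid
        )
        with open(bench_dir / files["pssm_dir"] / f"{pid}.pssm") as fh:
            prof = read_ascii_pssm(fh, pid)
        proteins.append(
            ProteinEntry(
                protein_id=pid,
                sequence=sequences[pid],
                labels=labels[pid],
                go_indices=gvec.nonzero_indices,
                fund_indices=fvec.nonzero_indices,
                profile=normalize_profile(prof),
                has_homologs=not hset.is_empty,
            )
        )
    return BenchmarkDataset(proteins, locations)
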