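"""Position-specific scoring matrix (PSSM) profiles and pseudo-PSSM features.

A PSI-BLAST profile assigns every residue position of a protein a row of 20
log-odds substitution scores, one per amino acid type.  Because proteins have
different lengths, the raw ``L x 20`` matrix cannot be fed directly to a
fixed-dimension classifier.  The pseudo-PSSM descriptor solves this by
reducing the (row-standardized) matrix to

* 20 per-amino-acid mean scores, and
* 20 lag-``xi`` correlation factors
  ``G_j(xi) = (1/(L-xi)) * sum_i (E_ij - E_{i+xi,j})**2``

so that some sequence-order information survives the averaging.  ``xi`` must
satisfy ``0 <= xi < min(50, L)``; at ``xi = 0`` the descriptor degenerates to
the plain 20 mean scores.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Iterable, Sequence, TextIO, Union

import numpy as np

#: Canonical amino acid ordering: alphabetical by single-letter code.
AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"

#: Largest lag permitted in the pseudo-PSSM descriptor (lags run 0..49).
MAX_LAG: int = 49


class PSSMParseError(ValueError):
    """Raised when an ASCII PSSM file cannot be parsed."""


@dataclass(frozen=True)
class PSSMProfile:
    """Raw integer log-odds profile for one protein.

    ``raw_scores`` has one row per residue of ``sequence`` and exactly 20
    columns ordered as :data:`AMINO_ACIDS`.
    """

    protein_id: str
    sequence: str
    raw_scores: np.ndarray
    alphabet: str = field(default=AMINO_ACIDS)

    def __post_init__(self) -> None:
        scores = np.asarray(self.raw_scores)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise ValueError(
                f"raw_scores must be L x 20, got shape {scores.shape}"
            )
        if scores.shape[0] != len(self.sequence):
            raise ValueError(
                f"{scores.shape[0]} score rows for a sequence of length "
                f"{len(self.sequence)}"
            )
        if len(self.sequence) < 1:
            raise ValueError("sequence must contain at least one residue")
        if self.alphabet != AMINO_ACIDS:
            raise ValueError("alphabet ordering is fixed to " + AMINO_ACIDS)
        object.__setattr__(self, "raw_scores", scores)

    @property
    def length(self) -> int:
        return len(self.sequence)


@dataclass(frozen=True)
class NormalizedProfile:
    """Row-standardized profile: each row has mean 0 and (population) SD 1.

    Rows whose 20 raw scores are all identical carry no preference between
    amino acid types and standardize to the all-zero row.
    """

    protein_id: str
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        if values.ndim != 2 or values.shape[1] != 20:
            raise ValueError(f"values must be L x 20, got shape {values.shape}")
        object.__setattr__(self, "values", values)

    @property
    def length(self) -> int:
        return int(self.values.shape[0])


@dataclass(frozen=True)
class PsePSSMVector:
    """Pseudo-PSSM descriptor: 20 means, then 20 lag-``xi`` correlation factors.

    Length 20 when ``xi == 0``, 40 when ``xi >= 1``.
    """

    protein_id: str
    xi: int
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        expected = 20 if self.xi == 0 else 40
        if values.shape != (expected,):
            raise ValueError(
                f"xi={self.xi} requires {expected} values, got {values.shape}"
            )
        if not 0 <= self.xi <= MAX_LAG:
            raise ValueError(f"xi must lie in [0, {MAX_LAG}], got {self.xi}")
        object.__setattr__(self, "values", values)


def _coerce_stream(source: Union[str, TextIO]) -> TextIO:
    if isinstance(source, str):
        return io.StringIO(source)
    return source


def read_ascii_pssm(source: Union[str, TextIO], protein_id: str = "") -> PSSMProfile:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file.

    Accepts a text stream or the file content as a string.  Only the residue
    letter column and the first 20 integer columns (the log-odds block) are
    read; the trailing percentage block and summary statistics are ignored.

    Raises
    ------
    PSSMParseError
        If a profile row does not contain 20 parsable integers, or if the
        file contains no profile rows at all.
    """
    stream = _coerce_stream(source)
    residues: list[str] = []
    rows: list[list[int]] = []
    for lineno, line in enumerate(stream, start=1):
        tokens = line.split()
        if len(tokens) < 2:
            continue
        try:
            int(tokens[0])
        except ValueError:
            continue  # header, amino-acid legend or trailing statistics
        if len(tokens[1]) != 1 or not tokens[1].isalpha():
            continue
        try:
            scores = [int(tok) for tok in tokens[2:22]]
        except ValueError:
            raise PSSMParseError(
                f"line {lineno}: log-odds block is not 20 integers"
            ) from None
        if len(scores) != 20:
            raise PSSMParseError(
                f"line {lineno}: expected 20 log-odds columns, found {len(scores)}"
            )
        residues.append(tokens[1])
        rows.append(scores)
    if not rows:
        raise PSSMParseError("no profile rows found (empty PSSM body)")
    return PSSMProfile(
        protein_id=protein_id,
        sequence="".join(residues),
        raw_scores=np.array(rows, dtype=int),
    )


def write_ascii_pssm(profile: PSSMProfile) -> str:
    """Render a profile in the PSI-BLAST ASCII dialect read by
    :func:`read_ascii_pssm` (round-trips the integer matrix exactly)."""
    lines = [
        "",
        "Last position-specific scoring matrix computed",
        "            " + "   ".join(AMINO_ACIDS),
    ]
    for i, (residue, row) in enumerate(zip(profile.sequence, profile.raw_scores), 1):
        cells = " ".join(f"{int(v):4d}" for v in row)
        lines.append(f"{i:5d} {residue} {cells}")
    lines.append("")
    return "\n".join(lines)


def normalize_profile(profile: PSSMProfile) -> NormalizedProfile:
    """Standardize each profile row to zero mean and unit population SD.

    The conversion is idempotent and invariant to per-row affine rescaling
    of the raw scores with positive slope.  Zero-variance rows map to zero.
    """
    raw = profile.raw_scores.astype(float)
    mean = raw.mean(axis=1, keepdims=True)
    std = raw.std(axis=1, keepdims=True)  # population SD (ddof=0)
    centered = raw - mean
    out = np.divide(centered, std, out=np.zeros_like(centered), where=std > 0)
    return NormalizedProfile(protein_id=profile.protein_id, values=out)


def mean_profile_scores(norm: NormalizedProfile) -> np.ndarray:
    """Column means of the standardized profile: the average evolutionary
    score of the chain mutating into each of the 20 amino acid types."""
    return norm.values.mean(axis=0)


def psepssm_vector(
    norm: NormalizedProfile, xi: int, coupling_exponent: float = 2.0
) -> PsePSSMVector:
    """Build the pseudo-PSSM descriptor at lag ``xi``.

    ``coupling_exponent`` sets the power applied to the score differences in
    the correlation factor (2 = squared-difference coupling, the default).

    Raises
    ------
    ValueError
        If ``xi >= min(50, L)`` (the lag must leave a positive number of
        coupled position pairs, and may never reach 50).
    """
    length = norm.length
    if xi < 0:
        raise ValueError(f"lag must be non-negative, got {xi}")
    if xi > MAX_LAG:
        raise ValueError(f"lag must be smaller than 50, got {xi}")
    if xi >= length:
        raise ValueError(
            f"lag must be smaller than the profile length L={length}, got {xi}"
        )
    means = mean_profile_scores(norm)
    if xi == 0:
        return PsePSSMVector(norm.protein_id, 0, means)
    diffs = norm.values[:-xi, :] - norm.values[xi:, :]
    corr = np.mean(np.abs(diffs) ** coupling_exponent, axis=0)
    return PsePSSMVector(norm.protein_id, xi, np.concatenate([means, corr]))


def featurize_table(
    profiles: Iterable[PSSMProfile], xi: int, coupling_exponent: float = 2.0
) -> "list[tuple[str, int, np.ndarray]]":
    """Pseudo-PSSM features for a batch of profiles at one lag."""
    out = []
    for prof in profiles:
        vec = psepssm_vector(normalize_profile(prof), xi, coupling_exponent)
        out.append((prof.protein_id, xi, vec.values))
    return out


def write_feature_tsv(
    rows: Sequence[tuple[str, int, np.ndarray]], handle: TextIO
) -> None:
    """Write ``featurize_table`` output as TSV: protein_id, xi, then the 20
    (lag 0) or 40 (lag >= 1) feature columns."""
    if not rows:
        raise ValueError("no feature rows to write")
    width = len(rows[0][2])
    if any(len(values) != width for _, _, values in rows):
        raise ValueError("all rows must share one feature width")
    header = ["protein_id", "xi"] + [f"f{j + 1:02d}" for j in range(width)]
    handle.write("\t".join(header) + "\n")
    for pid, xi, values in rows:
        cells = [pid, str(xi)] + [f"{v:.10g}" for v in values]
        handle.write("\t".join(cells) + "\n")
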