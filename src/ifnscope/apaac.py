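"""Amphiphilic pseudo amino acid composition (APAAC) features.

A protein of length L is represented by a 20+2λ vector: the 20 residue
frequencies, followed by 2λ sequence-correlation factors that interleave
hydrophobicity (odd tiers) and hydrophilicity (even tiers) lag products.
Tier j uses lag k = ⌈j/2⌉, so tiers (2k−1, 2k) carry the lag-k
hydrophobicity and hydrophilicity correlations respectively.  Both scales
are Z-score normalised over the 20 standard residues before use.

All components share the denominator Σf + w·Στ, so every valid vector sums
to exactly 1 — a useful algebraic invariant that the tests exploit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import (
    AlphabetError,
    DegenerateDenominatorError,
    DegenerateScaleError,
    SequenceTooShortError,
)

#: canonical ordering of the 20 standard residues (alphabetical one-letter)
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_INDEX = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: Tanford (1962) hydrophobicity scale
TANFORD_HYDROPHOBICITY: dict[str, float] = {
    "A": 0.62, "C": 0.29, "D": -0.90, "E": -0.74, "F": 1.19,
    "G": 0.48, "H": -0.40, "I": 1.38, "K": -1.50, "L": 1.06,
    "M": 0.64, "N": -0.78, "P": 0.12, "Q": -0.85, "R": -2.53,
    "S": -0.18, "T": -0.05, "V": 1.08, "W": 0.81, "Y": 0.26,
}

#: Hopp & Woods (1981) hydrophilicity scale
HOPP_WOODS_HYDROPHILICITY: dict[str, float] = {
    "A": -0.5, "C": -1.0, "D": 3.0, "E": 3.0, "F": -2.5,
    "G": 0.0, "H": -0.5, "I": -1.8, "K": 3.0, "L": -1.8,
    "M": -1.3, "N": 0.2, "P": 0.0, "Q": 0.2, "R": 3.0,
    "S": 0.3, "T": -0.4, "V": -1.5, "W": -3.4, "Y": -2.3,
}


def _scale_array(scale: Mapping[str, float]) -> np.ndarray:
    missing = set(AMINO_ACIDS) - set(scale)
    extra = set(scale) - set(AMINO_ACIDS)
    if missing or extra:
        raise ValueError(f"scale must cover exactly the 20 standard residues (missing={missing}, extra={extra})")
    return np.array([float(scale[aa]) for aa in AMINO_ACIDS])


def normalize_scale(raw: Mapping[str, float]) -> dict[str, float]:
    """Z-score a 20-residue property scale (population standard deviation).

    The divisor is 20 (population form); the result has mean 0 and standard
    deviation 1 exactly, and normalising twice is a fixed point.
    """
    values = _scale_array(raw)
    if not np.all(np.isfinite(values)):
        raise ValueError("scale values must be finite")
    sd = values.std()  # population (ddof=0)
    if sd == 0:
        raise DegenerateScaleError("scale has zero variance")
    normalized = (values - values.mean()) / sd
    return dict(zip(AMINO_ACIDS, normalized.tolist()))


@dataclass
class ApaacParams:
    """Feature-extraction parameters.

    lam (λ) is the number of correlation lags (default 30); weight (w)
    balances composition against correlation terms (default 0.05).
    """

    lam: int = 30
    weight: float = 0.05
    hydrophobicity_scale: Mapping[str, float] = field(
        default_factory=lambda: dict(TANFORD_HYDROPHOBICITY)
    )
    hydrophilicity_scale: Mapping[str, float] = field(
        default_factory=lambda: dict(HOPP_WOODS_HYDROPHILICITY)
    )

    def __post_init__(self) -> None:
        if self.lam < 1:
            raise ValueError("lambda must be >= 1")
        if self.weight <= 0:
            raise ValueError("weight must be > 0")
        self._phobi = _scale_array(normalize_scale(self.hydrophobicity_scale))
        self._phili = _scale_array(normalize_scale(self.hydrophilicity_scale))

    @property
    def dimension(self) -> int:
        return 20 + 2 * self.lam

    def to_dict(self) -> dict:
        return {
            "lambda": self.lam,
            "weight": self.weight,
            "hydrophobicity_scale": dict(self.hydrophobicity_scale),
            "hydrophilicity_scale": dict(self.hydrophilicity_scale),
        }


def _encode(sequence: str) -> np.ndarray:
    sequence = sequence.upper()
    idx = np.empty(len(sequence), dtype=np.intp)
    for pos, aa in enumerate(sequence):
        try:
            idx[pos] = _AA_INDEX[aa]
        except KeyError:
            raise AlphabetError(
                f"non-standard residue {aa!r} at position {pos + 1}"
            ) from None
    if len(idx) == 0:
        raise SequenceTooShortError("empty sequence")
    return idx


def residue_frequencies(sequence: str) -> np.ndarray:
    """Normalised occurrence frequencies f_i = count_i / L over the 20 residues."""
    idx = _encode(sequence)
    return np.bincount(idx, minlength=20) / len(idx)


def correlation_factor(sequence: str, j: int, params: ApaacParams) -> float:
    """The j-tier amphiphilic correlation factor τ_j.

    τ_j averages lag-k products of normalised hydrophobicity values (odd j)
    or hydrophilicity values (even j) over the sequence, with k = ⌈j/2⌉.
    """
    if not 1 <= j <= 2 * params.lam:
        raise ValueError(f"tier index {j} outside 1..{2 * params.lam}")
    idx = _encode(sequence)
    k = (j + 1) // 2
    if len(idx) <= k:
        raise SequenceTooShortError(
            f"length {len(idx)} <= lag {k}; tier {j} undefined"
        )
    scale = params._phobi if j % 2 == 1 else params._phili
    values = scale[idx]
    return float(np.mean(values[:-k] * values[k:]))


def apaac_vector(sequence: str, params: ApaacParams | None = None) -> np.ndarray:
    """The 20+2λ APAAC feature vector of one protein.

    Requires L ≥ λ+1 so that every tier up to lag λ is computable.
    """
    params = params or ApaacParams()
    idx = _encode(sequence)
    length = len(idx)
    if length < params.lam + 1:
        raise SequenceTooShortError(
            f"length {length} < lambda+1 = {params.lam + 1}; "
            "use a smaller lambda for short sequences"
        )
    freqs = np.bincount(idx, minlength=20) / length
    phobi = params._phobi[idx]
    phili = params._phili[idx]
    taus = np.empty(2 * params.lam)
    for k in range(1, params.lam + 1):
        taus[2 * k - 2] = np.mean(phobi[:-k] * phobi[k:])
        taus[2 * k - 1] = np.mean(phili[:-k] * phili[k:])
    denominator = freqs.sum() + params.weight * taus.sum()
    if abs(denominator) < 1e-8:
        raise DegenerateDenominatorError(
            f"normalizing denominator {denominator:.3e} is numerically zero"
        )
    return np.concatenate([freqs, params.weight * taus]) / denominator


def featurize(
    sequences: Mapping[str, str],
    params: ApaacParams | None = None,
    skip_invalid: bool = False,
) -> pd.DataFrame:
    """APAAC feature matrix for a batch of sequences (rows = sequence ids).

    With ``skip_invalid`` sequences that are too short or contain
    non-standard residues (B/J/O/U/X/Z) are dropped instead of raising.
    """
    params = params or ApaacParams()
    rows, ids, skipped = [], [], []
    for seq_id, seq in sequences.items():
        try:
            rows.append(apaac_vector(seq, params))
            ids.append(seq_id)
        except (AlphabetError, SequenceTooShortError):
            if not skip_invalid:
                raise
            skipped.append(seq_id)
    columns = [f"v{u}" for u in range(1, params.dimension + 1)]
    frame = pd.DataFrame(np.array(rows).reshape(len(rows), params.dimension), index=ids, columns=columns)
    frame.attrs["skipped"] = skipped
    return frame


def write_features(frame: pd.DataFrame, out_tsv: str, params: ApaacParams) -> None:
    """Write the feature matrix as TSV with a sidecar JSON of parameters."""
    frame.to_csv(out_tsv, sep="\t", index_label="id")
    sidecar = {
        "lambda": params.lam,
        "weight": params.weight,
        "hydrophobicity_scale": "Tanford (1962)" if dict(params.hydrophobicity_scale) == TANFORD_HYDROPHOBICITY else "custom",
        "hydrophilicity_scale": "Hopp-Woods (1981)" if dict(params.hydrophilicity_scale) == HOPP_WOODS_HYDROPHILICITY else "custom",
        "dimension": params.dimension,
    }
    with open(f"{out_tsv}.params.json", "w") as handle:
        json.dump(sidecar, handle, indent=2)
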