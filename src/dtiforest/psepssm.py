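"""PsePSSM: fixed-length protein descriptors from a position-specific score matrix.

Each profile row is first z-scored across its 20 amino-acid columns (population
variance, 1/20), so the descriptor is invariant to any uniform affine rescaling
of the raw scores. The descriptor then concatenates the 20 column means with,
for each lag 1..lag_max, the 20 mean squared lag-differences down the sequence:

    mean block      m_j = (1/L) sum_i e_ij
    lag-l block     p_j(l) = (1/(L-l)) sum_{i=1..L-l} (e_ij - e_{i+l,j})^2

giving a 20*(lag_max+1)-dimensional vector that keeps some sequence-order
information on top of the average evolutionary profile.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .pssm import PSSM

_DEGENERATE_TOL = 1e-12


@dataclass(frozen=True)
class NormalizedPSSM:
    """Row-wise z-scored profile; degenerate (constant) rows are all zero."""

    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "values", values)
        if values.ndim != 2 or values.shape[1] != 20:
            raise ValueError(f"normalized PSSM must be L x 20, got {values.shape}")


@dataclass(frozen=True)
class PsePSSMDescriptor:
    """A 20*(lag_max+1)-vector: [mean block | lag-1 block | ... | lag-Λ block]."""

    protein_id: str
    lag_max: int
    vector: np.ndarray

    def __post_init__(self) -> None:
        vector = np.asarray(self.vector, dtype=float)
        object.__setattr__(self, "vector", vector)
        if self.lag_max < 0:
            raise ValueError("lag_max must be >= 0")
        expected = 20 * (self.lag_max + 1)
        if vector.shape != (expected,):
            raise ValueError(
                f"descriptor length {vector.shape} != 20*(lag_max+1) = {expected}"
            )
        if not np.isfinite(vector).all():
            raise ValueError("descriptor entries must be finite")


def normalize_pssm(pssm: PSSM) -> NormalizedPSSM:
    """Z-score each profile row over its 20 columns with population (1/20)
    variance; rows with zero variance map to all zeros."""
    scores = pssm.scores
    mu = scores.mean(axis=1, keepdims=True)
    sd = scores.std(axis=1, keepdims=True)  # population: divides by 20
    centered = scores - mu
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(sd > _DEGENERATE_TOL, centered / sd, 0.0)
    return NormalizedPSSM(values=out)


def mean_descriptor(norm: NormalizedPSSM) -> np.ndarray:
    """Column means of the normalized profile: the composition-style block."""
    return norm.values.mean(axis=0)


def pseudo_components(norm: NormalizedPSSM, lag: int) -> np.ndarray:
    """Mean squared lag-``lag`` differences per column; non-negative.

    Raises ``ValueError`` when the lag reaches the sequence length (the
    averaging denominator L - lag would not be positive).
    """
    if lag < 1:
        raise ValueError("lag must be >= 1")
    L = norm.values.shape[0]
    if lag >= L:
        raise ValueError(f"lag exceeds sequence length: lag={lag}, L={L}")
    diff = norm.values[:-lag] - norm.values[lag:]
    return (diff ** 2).mean(axis=0)


def psepssm_descriptor(pssm: PSSM, lag_max: int = 10) -> PsePSSMDescriptor:
    """Build the full PsePSSM descriptor of a profile.

    Parameters
    ----------
    pssm : PSSM
        The protein's profile; its length L must exceed ``lag_max``.
    lag_max : int
        Largest sequence-order lag Λ; the descriptor has 20*(Λ+1) entries.
        Λ=0 reduces to the 20 column means.
    """
    if lag_max < 0:
        raise ValueError("lag_max must be >= 0")
    if pssm.length <= lag_max:
        raise ValueError(
            f"protein {pssm.protein_id!r} has length {pssm.length} <= lag_max={lag_max}"
        )
    norm = normalize_pssm(pssm)
    blocks = [mean_descriptor(norm)]
    blocks += [pseudo_components(norm, lag) for lag in range(1, lag_max + 1)]
    return PsePSSMDescriptor(
        protein_id=pssm.protein_id, lag_max=lag_max, vector=np.concatenate(blocks)
    )


def write_descriptor_table(descriptors: dict[str, PsePSSMDescriptor],
                           path: str | Path) -> None:
    """Write descriptors as TSV: one row per protein, header records Λ."""
    path = Path(path)
    if not descriptors:
        raise ValueError("no descriptors to write")
    lags = {d.lag_max for d in descriptors.values()}
    if len(lags) != 1:
        raise ValueError(f"mixed lag_max values in one table: {sorted(lags)}")
    lag_max = lags.pop()
    width = 20 * (lag_max + 1)
    with open(path, "w") as fh:
        fh.write(f"# lag_max={lag_max}\n")
        cols = "\t".join(f"v{i}" for i in range(width))
        fh.write(f"protein_id\t{cols}\n")
        for pid, desc in descriptors.items():
            vals = "\t".join(repr(float(v)) for v in desc.vector)
            fh.write(f"{pid}\t{vals}\n")


def read_descriptor_table(path: str | Path) -> dict[str, PsePSSMDescriptor]:
    """Read a descriptor TSV written by :func:`write_descriptor_table`."""
    path = Path(path)
    with open(path) as fh:
        first = fh.readline().strip()
        if not first.startswith("# lag_max="):
            raise ValueError(f"{path}: missing '# lag_max=' header")
        lag_max = int(first.split("=", 1)[1])
        fh.readline()  # column header
        out: dict[str, PsePSSMDescriptor] = {}
        for line in fh:
            if not line.strip():
                continue
            parts = line.rstrip("\n").split("\t")
            pid, values = parts[0], np.array(parts[1:], dtype=float)
            out[pid] = PsePSSMDescriptor(protein_id=pid, lag_max=lag_max, vector=values)
    return out
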