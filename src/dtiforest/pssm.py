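"""Position-specific score matrices: parsing, fabrication, and the PSI-BLAST wrapper.

A PSSM is the L x 20 profile a protein sequence acquires after iterative
database search: row i holds the log-odds score of residue position i mutating
into each of the 20 standard amino acids. Profiles are read from the ASCII
files PSI-BLAST emits with ``-out_ascii_pssm``; for fully offline work,
:func:`fallback_profile` fabricates a deterministic substitution-matrix
profile from the bare sequence.
"""

from __future__ import annotations

import logging
import shutil
import subprocess
import tempfile
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio.Align import substitution_matrices

logger = logging.getLogger(__name__)

#: Canonical amino-acid column order: the order PSI-BLAST prints profile columns.
AA_ORDER = "ARNDCQEGHILKMFPSTWYV"
_AA_SET = frozenset(AA_ORDER)
_AA_INDEX = {aa: i for i, aa in enumerate(AA_ORDER)}


class PSSMParseError(ValueError):
    """Raised when a profile file does not follow the ASCII PSSM layout."""


class ExternalToolError(RuntimeError):
    """Raised when the external PSI-BLAST executable is unavailable or fails."""


@dataclass(frozen=True)
class PSSM:
    """An L x 20 position-specific score matrix with its amino-acid sequence.

    Parameters
    ----------
    protein_id : str
        Identifier of the protein the profile belongs to.
    sequence : str
        Amino-acid sequence of length L, standard 20-letter alphabet.
    scores : numpy.ndarray
        (L, 20) array of log-odds scores, columns ordered by ``column_order``.
    column_order : str
        The 20-letter amino-acid alphabet labelling the columns; every PSSM
        in a run uses the same canonical order.
    """

    protein_id: str
    sequence: str
    scores: np.ndarray
    column_order: str = AA_ORDER

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        if scores.ndim != 2 or scores.shape[1] != 20:
            raise ValueError(
                f"PSSM scores must be L x 20, got shape {scores.shape}"
            )
        if scores.shape[0] < 1:
            raise ValueError("PSSM must have at least one row")
        if len(self.sequence) != scores.shape[0]:
            raise ValueError(
                f"sequence length {len(self.sequence)} != score rows {scores.shape[0]}"
            )
        if sorted(self.column_order) != sorted(AA_ORDER):
            raise ValueError(
                "column_order must be a permutation of the 20 standard amino acids"
            )
        if not np.isfinite(scores).all():
            raise ValueError("PSSM scores must be finite")

    @property
    def length(self) -> int:
        return self.scores.shape[0]


def _is_aa_header(tokens: list[str]) -> bool:
    return len(tokens) >= 20 and all(t in _AA_SET for t in tokens[:20])


def read_pssm_ascii(path: str | Path, protein_id: str | None = None,
                    use_percentages: bool = False) -> PSSM:
    """Parse a PSI-BLAST ``-out_ascii_pssm`` file.

    The file carries, per residue, a position index, the residue letter,
    20 log-odds columns and 20 weighted-percentage columns (plus trailing
    per-row statistics). By default the log-odds block feeds the profile;
    ``use_percentages=True`` selects the percentage block instead.

    Raises
    ------
    PSSMParseError
        On a missing header/rows, a row with a number of score columns other
        than 40, or non-numeric score cells — always naming the line number.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"PSSM file not found: {path}")
    if protein_id is None:
        protein_id = path.stem

    header_order: str | None = None
    residues: list[str] = []
    rows: list[list[float]] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            tokens = line.split()
            if not tokens:
                continue
            if header_order is None and _is_aa_header(tokens):
                header_order = "".join(tokens[:20])
                continue
            if not tokens[0].lstrip("-").isdigit():
                continue  # leading commentary / trailing statistics
            if len(tokens) < 2 or tokens[1] not in _AA_SET:
                if len(tokens) >= 2 and len(tokens[1]) == 1 and tokens[1].isalpha():
                    raise PSSMParseError(
                        f"line {lineno}: non-standard residue {tokens[1]!r}"
                    )
                continue
            cells = tokens[2:]
            # trailing information-content / weight statistics are floats with
            # a dot; score columns are plain integers in both PSI-BLAST blocks
            score_cells = [c for c in cells if "." not in c]
            if len(score_cells) != 40:
                raise PSSMParseError(
                    f"line {lineno}: expected 40 score columns, found {len(score_cells)}"
                )
            try:
                values = [float(c) for c in score_cells]
            except ValueError as exc:
                raise PSSMParseError(f"line {lineno}: non-numeric score cell ({exc})")
            residues.append(tokens[1])
            block = values[20:40] if use_percentages else values[:20]
            rows.append(block)

    if not rows:
        raise PSSMParseError(f"{path}: no PSSM rows found")

    scores = np.asarray(rows, dtype=float)
    if header_order is not None and header_order != AA_ORDER:
        perm = [header_order.index(aa) for aa in AA_ORDER]
        scores = scores[:, perm]
    return PSSM(protein_id=protein_id, sequence="".join(residues), scores=scores)


def write_pssm_ascii(pssm: PSSM, path: str | Path) -> None:
    """Write a PSSM in the PSI-BLAST ASCII layout (log-odds block duplicated
    into the percentage block so the row shape round-trips exactly)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("\n")
        fh.write("Last position-specific scoring matrix computed\n")
        letters = " ".join(pssm.column_order)
        fh.write(f"           {letters}  {letters}\n")
        for i, (aa, row) in enumerate(zip(pssm.sequence, pssm.scores), start=1):
            cells = " ".join(f"{int(v)}" if float(v).is_integer() else f"{v}"
                             for v in row)
            fh.write(f"{i:5d} {aa}  {cells}  {cells}  0.00 0.00\n")


def fallback_profile(sequence: str, protein_id: str = "protein") -> PSSM:
    """Deterministic substitution-matrix profile for a bare sequence.

    Row i is the BLOSUM62 score row of residue i, reordered to the canonical
    column order. A pure function of the sequence: no database, no external
    binary, identical input gives identical output.

    Raises
    ------
    ValueError
        If the sequence is empty or contains a non-standard residue
        (B, Z, X, U, ``*`` ...), naming the offending position.
    """
    if not sequence:
        raise ValueError("sequence must be non-empty")
    for pos, aa in enumerate(sequence):
        if aa not in _AA_SET:
            raise ValueError(
                f"non-standard residue {aa!r} at position {pos} in {protein_id!r}"
            )
    blosum = substitution_matrices.load("BLOSUM62")
    rows = np.empty((len(sequence), 20), dtype=float)
    for i, aa in enumerate(sequence):
        rows[i] = [blosum[aa, bb] for bb in AA_ORDER]
    return PSSM(protein_id=protein_id, sequence=sequence, scores=rows)


def run_psiblast(sequence: str, database: str | Path,
                 evalue: float = 0.001, iterations: int = 3,
                 protein_id: str = "query",
                 executable: str = "psiblast") -> PSSM:
    """Run PSI-BLAST on a sequence and parse the resulting ASCII PSSM.

    Defaults follow the profile-construction convention for broad, highly
    homologous hits: e-value 0.001, 3 iterations. The external tool is
    optional — if the executable is missing the call degrades to a clear
    :class:`ExternalToolError`, never a crash or partial files.
    """
    if shutil.which(executable) is None:
        raise ExternalToolError(
            f"external tool unavailable: {executable!r} not found on PATH"
        )
    logger.info("psiblast run: evalue=%g iterations=%d db=%s", evalue, iterations, database)
    with tempfile.TemporaryDirectory(prefix="psiblast_") as tmp:
        tmp = Path(tmp)
        query = tmp / "query.fasta"
        query.write_text(f">{protein_id}\n{sequence}\n")
        out_pssm = tmp / "profile.pssm"
        cmd = [
            executable,
            "-query", str(query),
            "-db", str(database),
            "-evalue", str(evalue),
            "-num_iterations", str(iterations),
            "-out_ascii_pssm", str(out_pssm),
        ]
        proc = subprocess.run(cmd, capture_output=True, text=True)
        if proc.returncode != 0:
            raise ExternalToolError(
                f"psiblast exited with status {proc.returncode}: {proc.stderr.strip()}"
            )
        if not out_pssm.exists():
            raise ExternalToolError("psiblast produced no ASCII PSSM output")
        try:
            return read_pssm_ascii(out_pssm, protein_id=protein_id)
        except PSSMParseError as exc:
            raise ExternalToolError(f"psiblast output unparseable: {exc}")
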