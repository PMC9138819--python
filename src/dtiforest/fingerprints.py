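"""881-bit drug substructure fingerprints.

A drug is encoded by presence/absence of the 881 substructure keys of the
PubChem subgraph dictionary (the CACTVS subgraph-key property). Fingerprints
are consumed, not computed: the package parses them from a two-column TSV in
either a plain 0/1-string dialect or the PubChem base64 dialect (4-byte
big-endian bit-length prefix, then packed bits, MSB-first within bytes).
"""

from __future__ import annotations

import base64
from dataclasses import dataclass
from pathlib import Path

import numpy as np

#: Size of the PubChem substructure-key dictionary.
N_FINGERPRINT_BITS = 881


class FingerprintError(ValueError):
    """Raised for malformed fingerprint strings or tables."""


@dataclass(frozen=True)
class Fingerprint:
    """An 881-bit binary substructure vector keyed by drug id (0-based keys)."""

    drug_id: str
    bits: np.ndarray

    def __post_init__(self) -> None:
        bits = np.asarray(self.bits, dtype=np.uint8)
        object.__setattr__(self, "bits", bits)
        if bits.shape != (N_FINGERPRINT_BITS,):
            raise FingerprintError(
                f"fingerprint for {self.drug_id!r} has length {bits.size}, "
                f"expected {N_FINGERPRINT_BITS}"
            )
        if not np.isin(bits, (0, 1)).all():
            raise FingerprintError(f"fingerprint for {self.drug_id!r} has non-binary entries")

    @property
    def popcount(self) -> int:
        return int(self.bits.sum())


def encode_pubchem_base64(bits: np.ndarray) -> str:
    """Encode a bit vector in the PubChem base64 dialect: a 4-byte big-endian
    bit-length prefix followed by the bits packed MSB-first within bytes."""
    bits = np.asarray(bits, dtype=np.uint8)
    prefix = len(bits).to_bytes(4, "big")
    packed = np.packbits(bits, bitorder="big").tobytes()
    return base64.b64encode(prefix + packed).decode("ascii")


def decode_pubchem_base64(text: str) -> np.ndarray:
    """Decode the PubChem base64 dialect; the length prefix must read 881."""
    try:
        raw = base64.b64decode(text, validate=True)
    except Exception as exc:
        raise FingerprintError(f"invalid base64 fingerprint: {exc}")
    if len(raw) < 4:
        raise FingerprintError("base64 fingerprint shorter than its length prefix")
    nbits = int.from_bytes(raw[:4], "big")
    if nbits != N_FINGERPRINT_BITS:
        raise FingerprintError(
            f"decoded bit-length prefix {nbits} != {N_FINGERPRINT_BITS}"
        )
    body = np.frombuffer(raw[4:], dtype=np.uint8)
    bits = np.unpackbits(body, bitorder="big")
    if bits.size < nbits:
        raise FingerprintError("base64 fingerprint body shorter than declared length")
    return bits[:nbits].astype(np.uint8)


def _parse_plain01(text: str) -> np.ndarray:
    if len(text) != N_FINGERPRINT_BITS:
        raise FingerprintError(
            f"fingerprint string length {len(text)} != {N_FINGERPRINT_BITS}"
        )
    if set(text) - {"0", "1"}:
        raise FingerprintError("fingerprint string contains characters other than 0/1")
    return np.frombuffer(text.encode("ascii"), dtype=np.uint8) - ord("0")


def parse_fingerprint_table(path: str | Path,
                            dialect: str = "plain01") -> dict[str, Fingerprint]:
    """Parse a TSV of (drug_id, fingerprint) rows into Fingerprint objects.

    ``dialect`` is ``"plain01"`` (an 881-character 0/1 string) or
    ``"pubchem_base64"``. Duplicate drug ids are rejected.
    """
    if dialect not in ("plain01", "pubchem_base64"):
        raise ValueError(f"unknown fingerprint dialect {dialect!r}")
    path = Path(path)
    out: dict[str, Fingerprint] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2:
                raise FingerprintError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            drug_id, text = parts
            if drug_id in out:
                raise FingerprintError(f"{path}:{lineno}: duplicate drug_id {drug_id!r}")
            try:
                bits = (_parse_plain01(text) if dialect == "plain01"
                        else decode_pubchem_base64(text))
            except FingerprintError as exc:
                raise FingerprintError(f"{path}:{lineno}: {exc}")
            out[drug_id] = Fingerprint(drug_id=drug_id, bits=bits)
    if not out:
        raise FingerprintError(f"{path}: no fingerprint rows found")
    return out


def write_fingerprint_table(fingerprints: dict[str, Fingerprint],
                            path: str | Path, dialect: str = "plain01") -> None:
    """Write fingerprints as a two-column TSV in the chosen dialect."""
    path = Path(path)
    with open(path, "w") as fh:
        for drug_id, fp in fingerprints.items():
            if dialect == "plain01":
                text = "".join("1" if b else "0" for b in fp.bits)
            elif dialect == "pubchem_base64":
                text = encode_pubchem_base64(fp.bits)
            else:
                raise ValueError(f"unknown fingerprint dialect {dialect!r}")
            fh.write(f"{drug_id}\t{text}\n")


def fingerprint_to_features(fp: Fingerprint) -> np.ndarray:
    """Cast the bits to a real vector in dictionary order, no scaling."""
    return fp.bits.astype(float)
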