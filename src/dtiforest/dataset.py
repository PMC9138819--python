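"""Balanced labeled pair datasets from a bipartite drug-target network.

Known interactions form the positive class; the negative class is drawn
uniformly without replacement from the unlabeled (drug, target) pair space,
by default in equal number to the positives so the dataset is balanced.
Each pair's feature row fuses the drug's 881 fingerprint bits with the
target's PsePSSM descriptor (drug block first).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .fingerprints import Fingerprint, fingerprint_to_features
from .psepssm import PsePSSMDescriptor

logger = logging.getLogger(__name__)

Pair = tuple[str, str]


@dataclass(frozen=True)
class InteractionNetwork:
    """A bipartite interaction network: drugs, targets, and positive pairs.

    Drug and target orders are first-appearance orders from the input;
    ``positives`` preserves input order with duplicates removed.
    """

    drugs: tuple[str, ...]
    targets: tuple[str, ...]
    positives: tuple[Pair, ...]

    def __post_init__(self) -> None:
        drug_set, target_set = set(self.drugs), set(self.targets)
        seen = set()
        for d, t in self.positives:
            if d not in drug_set:
                raise ValueError(f"positive pair references unknown drug {d!r}")
            if t not in target_set:
                raise ValueError(f"positive pair references unknown target {t!r}")
            if (d, t) in seen:
                raise ValueError(f"duplicate positive pair {(d, t)!r}")
            seen.add((d, t))

    @property
    def positive_set(self) -> frozenset[Pair]:
        return frozenset(self.positives)

    def unknown_pairs(self) -> list[Pair]:
        """All (drug, target) pairs not in the positive set, in drug-major order."""
        pos = self.positive_set
        return [(d, t) for d in self.drugs for t in self.targets if (d, t) not in pos]


def read_network(path: str | Path) -> InteractionNetwork:
    """Read a TSV of positive (drug_id, target_id) pairs.

    Duplicate rows are deduplicated with a logged warning; rows without two
    columns raise; an empty file raises.
    """
    path = Path(path)
    drugs: list[str] = []
    targets: list[str] = []
    positives: list[Pair] = []
    seen: set[Pair] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 2 or not parts[0] or not parts[1]:
                raise ValueError(
                    f"{path}:{lineno}: expected 2 tab-separated columns, got {len(parts)}"
                )
            d, t = parts
            if (d, t) in seen:
                logger.warning("%s:%d: duplicate pair (%s, %s) ignored", path, lineno, d, t)
                continue
            seen.add((d, t))
            if d not in drugs:
                drugs.append(d)
            if t not in targets:
                targets.append(t)
            positives.append((d, t))
    if not positives:
        raise ValueError(f"{path}: no interaction rows found")
    return InteractionNetwork(tuple(drugs), tuple(targets), tuple(positives))


def expand_entities(net: InteractionNetwork, drugs, targets) -> InteractionNetwork:
    """Extend the network with featurized entities that have no known
    interaction yet, so they participate in negative sampling and ranking."""
    extra_drugs = tuple(d for d in sorted(drugs) if d not in set(net.drugs))
    extra_targets = tuple(t for t in sorted(targets) if t not in set(net.targets))
    return InteractionNetwork(
        drugs=net.drugs + extra_drugs,
        targets=net.targets + extra_targets,
        positives=net.positives,
    )


def write_network(net: InteractionNetwork, path: str | Path) -> None:
    with open(path, "w") as fh:
        for d, t in net.positives:
            fh.write(f"{d}\t{t}\n")


def sample_negatives(net: InteractionNetwork, n: int | None = None,
                     seed: int = 0) -> list[Pair]:
    """Draw ``n`` distinct non-interacting pairs uniformly without replacement.

    ``n`` defaults to the number of positives, giving a balanced dataset.
    The draw is disjoint from the positives and reproducible under the seed.
    """
    if n is None:
        n = len(net.positives)
    candidates = net.unknown_pairs()
    if n > len(candidates):
        raise ValueError(
            f"requested {n} negatives but only {len(candidates)} "
            "non-interacting pairs exist"
        )
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(candidates), size=n, replace=False)
    return [candidates[i] for i in idx]


def assemble_matrix(net: InteractionNetwork, negatives: list[Pair],
                    fingerprints: dict[str, Fingerprint],
                    descriptors: dict[str, PsePSSMDescriptor],
                    ) -> tuple[np.ndarray, np.ndarray, list[Pair]]:
    """Build the fused feature matrix for positives followed by negatives.

    Row layout: all positives in network order, then the negatives in sample
    order. Feature layout: [fingerprint bits (881) | PsePSSM vector]. Any
    entity missing a feature map entry is reported in one aggregated error.
    """
    pairs = list(net.positives) + list(negatives)
    missing_drugs = sorted({d for d, _ in pairs if d not in fingerprints})
    missing_targets = sorted({t for _, t in pairs if t not in descriptors})
    if missing_drugs or missing_targets:
        parts = []
        if missing_drugs:
            parts.append(f"missing fingerprints for drugs: {', '.join(missing_drugs)}")
        if missing_targets:
            parts.append(f"missing descriptors for targets: {', '.join(missing_targets)}")
        raise KeyError("; ".join(parts))

    drug_vecs = {d: fingerprint_to_features(fp) for d, fp in fingerprints.items()}
    target_vecs = {t: desc.vector for t, desc in descriptors.items()}
    X = np.array([np.concatenate([drug_vecs[d], target_vecs[t]]) for d, t in pairs])
    y = np.array([1] * len(net.positives) + [0] * len(negatives), dtype=int)
    return X, y, pairs


def export_dataset(X: np.ndarray, y: np.ndarray, pairs: list[Pair],
                   path: str | Path, lag_max: int, seed: int) -> None:
    """Write the dataset as a feature TSV with a label column, plus a JSON
    sidecar recording Λ, the sampling seed, and the fusion order."""
    path = Path(path)
    with open(path, "w") as fh:
        cols = "\t".join(f"f{i}" for i in range(X.shape[1]))
        fh.write(f"drug_id\ttarget_id\tlabel\t{cols}\n")
        for (d, t), label, row in zip(pairs, y, X):
            vals = "\t".join(repr(float(v)) for v in row)
            fh.write(f"{d}\t{t}\t{int(label)}\t{vals}\n")
    sidecar = path.with_suffix(path.suffix + ".json")
    meta = {
        "lag_max": lag_max,
        "seed": seed,
        "fusion_order": ["fingerprint", "psepssm"],
        "n_samples": int(len(y)),
        "n_features": int(X.shape[1]),
        "n_positives": int(y.sum()),
    }
    sidecar.write_text(json.dumps(meta, indent=2) + "\n")
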