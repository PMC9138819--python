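import numpy as np
import pytest

from dtiforest import PSSM, Fingerprint, fallback_profile


@pytest.fixture
def tiny_pssm_file(tmp_path):
    """A 3-residue ASCII PSSM in the PSI-BLAST layout (canonical column order)."""
    from dtiforest import AA_ORDER

    letters = " ".join(AA_ORDER)
    rng = np.random.default_rng(11)
    scores = rng.integers(-5, 8, size=(3, 20))
    lines = ["", "Last position-specific scoring matrix computed",
             f"           {letters}  {letters}"]
    for i, (aa, row) in enumerate(zip("MKL", scores), start=1):
        cells = " ".join(str(v) for v in row)
        pct = " ".join("0" for _ in range(20))
        lines.append(f"{i:5d} {aa}  {cells}  {pct}  0.36 0.09")
    path = tmp_path / "tiny.pssm"
    path.write_text("\n".join(lines) + "\n")
    return path, scores


@pytest.fixture
def toy_network_file(tmp_path):
    """A 5x5 bipartite network TSV with 6 positive pairs."""
    rows = [("d1", "t1"), ("d1", "t2"), ("d2", "t3"), ("d3", "t1"),
            ("d4", "t4"), ("d5", "t5")]
    path = tmp_path / "net.tsv"
    path.write_text("".join(f"{d}\t{t}\n" for d, t in rows))
    return path, rows


def planted_dataset(n_samples=150, n_features=40, n_informative=8, seed=0):
    """Small linearly separable-ish binary dataset for classifier tests."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n_samples, n_features))
    w = np.zeros(n_features)
    w[rng.choice(n_features, size=n_informative, replace=False)] = \
        rng.standard_normal(n_informative)
    score = X @ w
    y = (score > np.median(score)).astype(int)
    return X, y


@pytest.fixture
def small_classification_data():
    return planted_dataset()


@pytest.fixture
def small_entities():
    """Three drugs with fingerprints and three targets with descriptors (Λ=2)."""
    from dtiforest import psepssm_descriptor, synth_fingerprint

    fingerprints = {
        f"d{i}": synth_fingerprint(0.1, seed=100 + i, drug_id=f"d{i}")
        for i in range(1, 4)
    }
    descriptors = {}
    for i, seq in enumerate(["MKLVAAGW", "TTWYVPAC", "GHILKMFR"], start=1):
        pssm = fallback_profile(seq, protein_id=f"t{i}")
        descriptors[f"t{i}"] = psepssm_descriptor(pssm, lag_max=2)
    return fingerprints, descriptors
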