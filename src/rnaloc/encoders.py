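"""Sequence and per-base feature encodings.

Two fixed-length composition vectors describe a whole sequence:

* **k-mer** — relative frequencies of all length-k substrings over {A,C,G,U}
  for k = 1..5, concatenated: 4 + 16 + 64 + 256 + 1024 = 1364 dimensions.
* **CKSNAP** — composition of k-spaced nucleic acid pairs: for each gap
  k = 0..5, the 16 relative frequencies of ordered base pairs (s_i, s_{i+k+1}),
  concatenated: 16 x 6 = 96 dimensions.

Each k-block (and each gap-block) is normalized by the number of counted
windows, so within-block entries sum to 1 for sequences long enough to contain
at least one window. Windows containing N are excluded from both numerator and
denominator. Feature order within a block is lexicographic with A < C < G < U.

Per-base node features for the structure-graph branch are 10-dimensional:
one-hot over (A, C, G, U, N), the NCP chemical-property triple, the EIIP
scalar, and ANF — the accumulated frequency of base s_i within the prefix
s[1..i].
"""

from __future__ import annotations

import itertools
import logging

import numpy as np

logger = logging.getLogger(__name__)

BASES = "ACGU"
KMER_K_VALUES = (1, 2, 3, 4, 5)
CKSNAP_GAP_VALUES = (0, 1, 2, 3, 4, 5)
KMER_DIM = sum(4**k for k in KMER_K_VALUES)  # 1364
CKSNAP_DIM = 16 * len(CKSNAP_GAP_VALUES)  # 96
NODE_FEATURE_DIM = 10

# Nucleotide chemical properties: (ring structure, hydrogen bond, functional group)
NCP = {
    "A": (1.0, 1.0, 1.0),
    "C": (0.0, 1.0, 0.0),
    "G": (1.0, 0.0, 0.0),
    "U": (0.0, 0.0, 1.0),
    "N": (0.0, 0.0, 0.0),
}
# Electron-ion interaction pseudopotentials
EIIP = {"A": 0.1260, "C": 0.1340, "G": 0.0806, "U": 0.1335, "N": 0.0}

_BASE_INDEX = {b: i for i, b in enumerate(BASES)}


def _kmer_index(kmer: str) -> int | None:
    """Lexicographic rank of a k-mer over ACGU, or None if it contains N."""
    idx = 0
    for c in kmer:
        b = _BASE_INDEX.get(c)
        if b is None:
            return None
        idx = idx * 4 + b
    return idx


def kmer_frequencies(seq: str, k_values: tuple[int, ...] = KMER_K_VALUES) -> np.ndarray:
    """Concatenated relative k-mer frequencies for each k in `k_values`.

    Windows containing N are skipped (excluded from the denominator). A block
    whose k exceeds the sequence length, or for which no window is countable,
    is all zeros (logged).
    """
    out_blocks = []
    L = len(seq)
    for k in sorted(k_values):
        counts = np.zeros(4**k)
        n_windows = 0
        for i in range(L - k + 1):
            idx = _kmer_index(seq[i : i + k])
            if idx is None:
                continue
            counts[idx] += 1
            n_windows += 1
        if n_windows == 0:
            logger.warning("no countable %d-mer window in sequence of length %d", k, L)
        else:
            counts /= n_windows
        out_blocks.append(counts)
    return np.concatenate(out_blocks)


def cksnap_frequencies(
    seq: str, gap_values: tuple[int, ...] = CKSNAP_GAP_VALUES
) -> np.ndarray:
    """Concatenated k-spaced pair frequencies for each gap in `gap_values`.

    For gap k the counted pairs are (s_i, s_{i+k+1}); each 16-entry block is
    normalized by its number of counted (N-free) pairs.
    """
    out_blocks = []
    L = len(seq)
    for gap in sorted(gap_values):
        counts = np.zeros(16)
        n_pairs = 0
        for i in range(L - gap - 1):
            a = _BASE_INDEX.get(seq[i])
            b = _BASE_INDEX.get(seq[i + gap + 1])
            if a is None or b is None:
                continue
            counts[a * 4 + b] += 1
            n_pairs += 1
        if n_pairs == 0:
            logger.warning("no countable pair at gap %d in sequence of length %d", gap, L)
        else:
            counts /= n_pairs
        out_blocks.append(counts)
    return np.concatenate(out_blocks)


def node_feature_matrix(seq: str) -> np.ndarray:
    """Per-base feature matrix of shape (L, 10).

    Row i is the concatenation of: one-hot over (A, C, G, U, N); the NCP
    triple; the EIIP scalar; and ANF(i) = count of base s_i within s[0..i]
    divided by i+1. N contributes a zero NCP/EIIP and occupies one-hot slot 5;
    ANF is computed over the literal character.
    """
    L = len(seq)
    X = np.zeros((L, NODE_FEATURE_DIM))
    prefix_counts: dict[str, int] = {}
    alphabet_index = {b: i for i, b in enumerate("ACGUN")}
    for i, c in enumerate(seq):
        X[i, alphabet_index[c]] = 1.0
        X[i, 5:8] = NCP[c]
        X[i, 8] = EIIP[c]
        prefix_counts[c] = prefix_counts.get(c, 0) + 1
        X[i, 9] = prefix_counts[c] / (i + 1)
    return X


def kmer_names(k_values: tuple[int, ...] = KMER_K_VALUES) -> list[str]:
    """Column names for the k-mer vector, in emission order."""
    names = []
    for k in sorted(k_values):
        names.extend("".join(p) for p in itertools.product(BASES, repeat=k))
    return names


def cksnap_names(gap_values: tuple[int, ...] = CKSNAP_GAP_VALUES) -> list[str]:
    """Column names for the CKSNAP vector, in emission order."""
    names = []
    for gap in sorted(gap_values):
        names.extend(f"{a}{'x' * gap}{b}" for a in BASES for b in BASES)
    return names
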