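"""Composition features: k-mer frequencies and the kmerscore log-odds statistic.

A sequence S = s1 s2 ... sn of length n has n-k+1 overlapping k-mer
windows. Its k-mer frequency vector has one entry per word in
lexicographic order over (A, C, G, T):

    kmer(i) = count of word i among the windows / (n - k + 1)

The kmerscore summarizes the composition bias of a sequence relative to
class-mean k-mer profiles M_pos and M_neg fitted on training data:

    kmerscore = (1 / (n - k + 1)) * sum_i log( M_neg(h_i) / M_pos(h_i) )

with h_i the k-mer starting at position i and the natural log. Higher
values mean the composition looks more negative-class-like. Since every
window of the same word contributes the same term, the sum equals the
frequency-weighted dot product of the sequence's own k-mer vector with
log(M_neg / M_pos); that equivalent form is computed here.

The fixed 90-dim feature vector is k-mer frequencies for k = 1, 2, 3
(4 + 16 + 64 = 84 entries, each block lexicographic) followed by the
kmerscore for k = 1..6 (6 entries).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from itertools import product
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .io import Dataset, SequenceRecord

ALPHABET = "ACGT"
DEFAULT_K_RANGE = (1, 2, 3, 4, 5, 6)
DEFAULT_PSEUDOCOUNT = 1e-6
KMER_KS = (1, 2, 3)  # frequency blocks in the feature vector
SCORE_KS = (1, 2, 3, 4, 5, 6)  # kmerscore entries
N_FEATURES = sum(4**k for k in KMER_KS) + len(SCORE_KS)  # 84 + 6 = 90
MIN_FEATURIZE_LENGTH = max(SCORE_KS)

_BASE_INDEX = np.full(128, -1, dtype=np.int64)
for _i, _b in enumerate(ALPHABET):
    _BASE_INDEX[ord(_b)] = _i


def kmer_names(k: int) -> list[str]:
    """Lexicographic k-mer words over (A, C, G, T)."""
    return ["".join(p) for p in product(ALPHABET, repeat=k)]


def feature_names() -> list[str]:
    """Column names of the 90-dim feature vector."""
    names = [f"k{k}_{w}" for k in KMER_KS for w in kmer_names(k)]
    names += [f"kmerscore_k{k}" for k in SCORE_KS]
    return names


def _encode(seq: str) -> np.ndarray:
    codes = _BASE_INDEX[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (codes < 0).any():
        raise ValueError("sequence contains characters outside A/C/G/T")
    return codes


def _window_codes(codes: np.ndarray, k: int) -> np.ndarray:
    """Base-4 integer code of each overlapping k-mer window."""
    n = codes.size
    out = np.zeros(n - k + 1, dtype=np.int64)
    for j in range(k):
        out = out * 4 + codes[j : n - k + 1 + j]
    return out


def kmer_counts(seq: str, k: int) -> np.ndarray:
    """Overlapping-window k-mer counts (length 4**k, lexicographic)."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if len(seq) < k:
        raise ValueError(f"sequence of length {len(seq)} is shorter than k={k}")
    return np.bincount(_window_codes(_encode(seq), k), minlength=4**k).astype(np.float64)


def kmer_frequencies(record: SequenceRecord | str, k: int) -> np.ndarray:
    """k-mer frequency vector of one sequence (entries sum to 1 for n >= k).

    Accepts a :class:`SequenceRecord` or a plain sequence string.
    """
    seq = record.seq if isinstance(record, SequenceRecord) else record
    if len(seq) < k:
        rid = record.id if isinstance(record, SequenceRecord) else "<str>"
        raise ValueError(f"record {rid!r}: length {len(seq)} < k={k}")
    counts = kmer_counts(seq, k)
    return counts / (len(seq) - k + 1)


@dataclass
class ClassMeanProfile:
    """Per-k mean k-mer profiles of the positive and negative training classes.

    ``m_pos[k]`` / ``m_neg[k]`` are the arithmetic means of the per-sequence
    k-mer frequency vectors, smoothed by adding ``pseudocount`` to every
    entry and renormalizing so entries are strictly positive (the
    kmerscore log-ratio is otherwise undefined for words absent from one
    class). Natural log is used throughout.
    """

    k_range: tuple[int, ...]
    pseudocount: float
    m_pos: dict[int, np.ndarray] = field(default_factory=dict)
    m_neg: dict[int, np.ndarray] = field(default_factory=dict)

    def log_ratio(self, k: int) -> np.ndarray:
        """log(M_neg / M_pos) per k-mer word."""
        if k not in self.m_pos:
            raise KeyError(f"k={k} not in profile k_range {self.k_range}")
        pos, neg = self.m_pos[k], self.m_neg[k]
        if (pos <= 0).any() or (neg <= 0).any():
            raise ValueError(
                "profile contains zero entries; refit with a positive pseudocount"
            )
        return np.log(neg) - np.log(pos)

    def swapped(self) -> "ClassMeanProfile":
        """Profile with the class roles exchanged (negates every kmerscore)."""
        return ClassMeanProfile(
            k_range=self.k_range,
            pseudocount=self.pseudocount,
            m_pos={k: v.copy() for k, v in self.m_neg.items()},
            m_neg={k: v.copy() for k, v in self.m_pos.items()},
        )

    def to_dict(self) -> dict:
        return {
            "k_range": list(self.k_range),
            "pseudocount": self.pseudocount,
            "m_pos": {str(k): v.tolist() for k, v in self.m_pos.items()},
            "m_neg": {str(k): v.tolist() for k, v in self.m_neg.items()},
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ClassMeanProfile":
        return cls(
            k_range=tuple(d["k_range"]),
            pseudocount=float(d["pseudocount"]),
            m_pos={int(k): np.asarray(v, dtype=np.float64) for k, v in d["m_pos"].items()},
            m_neg={int(k): np.asarray(v, dtype=np.float64) for k, v in d["m_neg"].items()},
        )

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict()))

    @classmethod
    def load(cls, path: str | Path) -> "ClassMeanProfile":
        return cls.from_dict(json.loads(Path(path).read_text()))


def _mean_kmer_vector(data: Dataset, k: int) -> np.ndarray:
    # id-sorted summation: the mean is bit-identical under record permutation
    recs = sorted(data.records, key=lambda r: r.id)
    vecs = np.stack([kmer_frequencies(rec, k) for rec in recs])
    return vecs.mean(axis=0)


def fit_class_means(
    pos: Dataset,
    neg: Dataset,
    k_range: Sequence[int] = DEFAULT_K_RANGE,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> ClassMeanProfile:
    """Fit M_pos / M_neg on training data.

    The caller is responsible for passing TRAINING data only: class means
    computed on sequences later used for evaluation leak test information
    into the kmerscore features.
    """
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be non-empty to fit class means")
    if pseudocount < 0:
        raise ValueError("pseudocount must be >= 0")
    kmax = max(k_range)
    short = [r.id for d in (pos, neg) for r in d if len(r) < kmax]
    if short:
        raise ValueError(
            f"sequences shorter than max k={kmax}: {short[:5]}"
            + ("..." if len(short) > 5 else "")
        )
    profile = ClassMeanProfile(k_range=tuple(k_range), pseudocount=float(pseudocount))
    for k in k_range:
        mp = _mean_kmer_vector(pos, k) + pseudocount
        mn = _mean_kmer_vector(neg, k) + pseudocount
        profile.m_pos[k] = mp / mp.sum()
        profile.m_neg[k] = mn / mn.sum()
    return profile


def kmerscore(record: SequenceRecord | str, profile: ClassMeanProfile, k: int) -> float:
    """Mean per-window log(M_neg/M_pos) of one sequence (natural log)."""
    freqs = kmer_frequencies(record, k)
    return float(freqs @ profile.log_ratio(k))


def featurize(record: SequenceRecord | str, profile: ClassMeanProfile) -> np.ndarray:
    """Assemble the fixed 90-dim feature vector of one sequence.

    Layout: 1-mer (4), 2-mer (16), 3-mer (64) frequencies, then kmerscore
    for k = 1..6. Sequences shorter than 6 nt are rejected.
    """
    seq = record.seq if isinstance(record, SequenceRecord) else record
    if len(seq) < MIN_FEATURIZE_LENGTH:
        rid = record.id if isinstance(record, SequenceRecord) else "<str>"
        raise ValueError(
            f"record {rid!r}: length {len(seq)} < minimum featurizable "
            f"length {MIN_FEATURIZE_LENGTH}"
        )
    parts = [kmer_frequencies(seq, k) for k in KMER_KS]
    parts.append(np.array([kmerscore(seq, profile, k) for k in SCORE_KS]))
    vec = np.concatenate(parts)
    assert vec.size == N_FEATURES
    return vec


def featurize_dataset(data: Dataset, profile: ClassMeanProfile) -> np.ndarray:
    """Feature matrix with one row per record, aligned to record order."""
    if len(data) == 0:
        return np.empty((0, N_FEATURES), dtype=np.float64)
    rows = []
    for rec in data:
        try:
            rows.append(featurize(rec, profile))
        except ValueError as exc:
            raise ValueError(f"featurization failed for record {rec.id!r}: {exc}") from exc
    return np.stack(rows)


def export_feature_matrix(
    data: Dataset, profile: ClassMeanProfile, path: str | Path
) -> None:
    """Write the feature matrix as TSV with named columns and an id column."""
    import pandas as pd

    X = featurize_dataset(data, profile)
    df = pd.DataFrame(X, columns=feature_names())
    df.insert(0, "id", data.ids)
    df.to_csv(path, sep="\t", index=False)
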