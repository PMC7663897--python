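"""Synthetic sequence datasets with the compositional structure the models exploit.

The generator emulates the compositional layout of the triplex training
data: positives come from two subtypes in roughly a 2.5:1 ratio — a
CG-rich majority subtype ("strong", mirroring triplex-peak-derived
lncRNAs) and an AT-rich minority subtype ("weak", mirroring the
experimentally reported triplex lncRNAs, whose composition resembles the
negatives) — while the negative class is AT-rich. The weak subtype sits
at a controllable effect size ``delta`` between the negative (delta=0)
and strong (delta=1) compositions. Class imbalance defaults mirror the
two model roles: about 1:68 for the lncRNA model and 1:5 for the
DNA-site model.

Sequences are i.i.d. draws from per-class base probabilities, with
lengths uniform over a configurable range. Positives are grouped into
"genes": each gene has an archetype sequence and 1-5 point-mutated
variants, giving leave-gene-out splits and redundancy filtering
realistic within-gene similarity. An optional planted motif lets tests
probe what the 3-mer features capture beyond single-base bias.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .io import (
    Dataset,
    NEGATIVE,
    POSITIVE,
    SequenceRecord,
    SUBTYPE_STRONG,
    SUBTYPE_WEAK,
    write_fasta,
)

ALPHABET = np.array(list("ACGT"))

#: CG-rich composition of the strong positive subtype.
STRONG_PROBS = (0.15, 0.35, 0.35, 0.15)
#: AT-rich composition of the negative class.
NEG_PROBS = (0.35, 0.15, 0.15, 0.35)


@dataclass(frozen=True)
class CompositionSpec:
    """I.i.d. base-composition model for one sequence class."""

    name: str
    base_probs: tuple[float, float, float, float]
    length_range: tuple[int, int]
    motif: Optional[str] = None
    motif_rate: float = 0.0

    def __post_init__(self) -> None:
        p = np.asarray(self.base_probs, dtype=np.float64)
        if abs(p.sum() - 1.0) > 1e-12 or (p < 0).any():
            raise ValueError(f"{self.name}: base_probs must be a probability 4-vector")
        lo, hi = self.length_range
        if lo < 1 or lo > hi:
            raise ValueError(f"{self.name}: invalid length_range {self.length_range}")
        if self.motif is not None:
            bad = set(self.motif) - set("ACGT")
            if bad:
                raise ValueError(f"{self.name}: motif characters {sorted(bad)} invalid")
            for b in set(self.motif):
                if p["ACGT".index(b)] == 0.0:
                    raise ValueError(
                        f"{self.name}: motif contains base {b!r} with zero probability"
                    )
            if not 0.0 <= self.motif_rate <= 1.0:
                raise ValueError(f"{self.name}: motif_rate must lie in [0, 1]")


def interpolate_probs(
    neg: tuple[float, ...], strong: tuple[float, ...], delta: float
) -> tuple[float, float, float, float]:
    """Composition at effect size delta between negative (0) and strong (1)."""
    p = (1.0 - delta) * np.asarray(neg) + delta * np.asarray(strong)
    return tuple(p.tolist())


@dataclass(frozen=True)
class SyntheticDesign:
    """Full design of one synthetic study: specs, counts, gene structure."""

    pos_strong: CompositionSpec
    pos_weak: CompositionSpec
    neg: CompositionSpec
    n_pos_strong: int
    n_pos_weak: int
    n_neg: int
    seed: int = 0
    variants_per_gene: tuple[int, int] = (1, 5)
    mutation_rate: float = 0.02

    def __post_init__(self) -> None:
        if min(self.n_pos_strong, self.n_pos_weak, self.n_neg) < 0:
            raise ValueError("counts must be >= 0")
        lo, hi = self.variants_per_gene
        if lo < 1 or lo > hi:
            raise ValueError("variants_per_gene must satisfy 1 <= lo <= hi")
        if not 0.0 <= self.mutation_rate < 1.0:
            raise ValueError("mutation_rate must lie in [0, 1)")

    @classmethod
    def lncrna_mode(cls, seed: int = 0, n_pos_strong: int = 50, n_pos_weak: int = 20,
                    imbalance: int = 68, delta: float = 0.3,
                    length_range: tuple[int, int] = (200, 2000)) -> "SyntheticDesign":
        """Transcript-scale design: subtype ratio ~2.5:1, imbalance ~1:68."""
        n_pos = n_pos_strong + n_pos_weak
        return cls(
            pos_strong=CompositionSpec("pos_strong", STRONG_PROBS, length_range),
            pos_weak=CompositionSpec(
                "pos_weak", interpolate_probs(NEG_PROBS, STRONG_PROBS, delta),
                length_range),
            neg=CompositionSpec("neg", NEG_PROBS, length_range),
            n_pos_strong=n_pos_strong, n_pos_weak=n_pos_weak,
            n_neg=imbalance * n_pos, seed=seed,
        )

    @classmethod
    def dna_site_mode(cls, seed: int = 0, n_pos: int = 200, imbalance: int = 5,
                      length_range: tuple[int, int] = (60, 400)) -> "SyntheticDesign":
        """DNA-site-scale design: single positive composition, imbalance ~1:5."""
        return cls(
            pos_strong=CompositionSpec("pos_strong", STRONG_PROBS, length_range),
            pos_weak=CompositionSpec(
                "pos_weak", interpolate_probs(NEG_PROBS, STRONG_PROBS, 0.3),
                length_range),
            neg=CompositionSpec("neg", NEG_PROBS, length_range),
            n_pos_strong=n_pos, n_pos_weak=0, n_neg=imbalance * n_pos, seed=seed,
        )


def _draw_sequence(spec: CompositionSpec, length: int,
                   rng: np.random.Generator) -> str:
    seq = rng.choice(ALPHABET, size=length, p=spec.base_probs)
    if spec.motif and rng.random() < spec.motif_rate and length >= len(spec.motif):
        start = rng.integers(0, length - len(spec.motif) + 1)
        seq[start : start + len(spec.motif)] = list(spec.motif)
    return "".join(seq)


def _mutate(seq: str, rate: float, rng: np.random.Generator) -> str:
    arr = np.array(list(seq))
    hits = np.where(rng.random(arr.size) < rate)[0]
    for i in hits:
        choices = [b for b in "ACGT" if b != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _gene_blocks(
    spec: CompositionSpec, n: int, prefix: str, subtype: Optional[str],
    design: SyntheticDesign, rng: np.random.Generator,
) -> list[SequenceRecord]:
    """Generate n records grouped into genes of point-mutated variants."""
    records: list[SequenceRecord] = []
    gene_idx = 0
    lo, hi = design.variants_per_gene
    while len(records) < n:
        gene_idx += 1
        gene = f"{prefix}G{gene_idx:04d}"
        n_var = int(rng.integers(lo, hi + 1))
        length = int(rng.integers(spec.length_range[0], spec.length_range[1] + 1))
        archetype = _draw_sequence(spec, length, rng)
        for v in range(min(n_var, n - len(records))):
            seq = archetype if v == 0 else _mutate(archetype, design.mutation_rate, rng)
            records.append(SequenceRecord(
                id=f"{gene}.v{v + 1}", seq=seq, gene=gene,
                subtype=subtype, label=POSITIVE,
            ))
    return records


def generate(design: SyntheticDesign) -> tuple[Dataset, Dataset]:
    """Generate (positives, negatives) per the design; deterministic by seed."""
    rng = np.random.default_rng(design.seed)
    pos_records = _gene_blocks(design.pos_strong, design.n_pos_strong, "STR",
                               SUBTYPE_STRONG, design, rng)
    pos_records += _gene_blocks(design.pos_weak, design.n_pos_weak, "WEA",
                                SUBTYPE_WEAK, design, rng)
    neg_records = []
    for i in range(design.n_neg):
        length = int(rng.integers(design.neg.length_range[0],
                                  design.neg.length_range[1] + 1))
        neg_records.append(SequenceRecord(
            id=f"NEG{i + 1:06d}", seq=_draw_sequence(design.neg, length, rng),
            label=NEGATIVE,
        ))
    return Dataset(pos_records, name="pos"), Dataset(neg_records, name="neg")


def composition_report(*datasets: Dataset) -> pd.DataFrame:
    """Mean single-base frequencies per class/subtype across datasets."""
    groups: dict[tuple[str, str], list[np.ndarray]] = {}
    from .features import kmer_frequencies

    for data in datasets:
        if len(data) == 0:
            warnings.warn(f"dataset {data.name!r} is empty; no composition row",
                          stacklevel=2)
            continue
        for rec in data:
            key = (rec.label or "unlabeled", rec.subtype or "-")
            groups.setdefault(key, []).append(kmer_frequencies(rec, 1))
    rows = []
    for (label, subtype), vecs in sorted(groups.items()):
        mean = np.mean(vecs, axis=0)
        rows.append({"label": label, "subtype": subtype, "n": len(vecs),
                     "A": mean[0], "C": mean[1], "G": mean[2], "T": mean[3]})
    return pd.DataFrame(rows)


def write_dataset(pos: Dataset, neg: Dataset, out_dir: str | Path) -> None:
    """Write pos.fasta, neg.fasta and a manifest.tsv (id, label, subtype, gene)."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    write_fasta(pos, out / "pos.fasta")
    write_fasta(neg, out / "neg.fasta")
    with (out / "manifest.tsv").open("w") as fh:
        fh.write("id\tlabel\tsubtype\tgene\n")
        for data in (pos, neg):
            for r in data:
                fh.write(f"{r.id}\t{r.label or ''}\t{r.subtype or ''}\t{r.gene or ''}\n")
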