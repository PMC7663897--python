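"""Imbalance handling and data splitting.

The training protocol for heavily imbalanced triplex data rests on three
pieces implemented here:

* **negative down-sampling** — negatives are randomly reduced to the size
  of the (augmented) positive training set, per training run;
* **weighted bagging** — the positive training set is enlarged by a fixed
  multiplier (default 3x) via bootstrap, with a fixed fraction of the
  draws (default 1/3) restricted to the minority ``weak`` positive
  subtype so the model cannot ignore it;
* **splits** — stratified k-fold (per-class round-robin after a seeded
  shuffle), leave-gene-out (all transcript variants of one gene held
  out), and an approximate greedy redundancy filter in the spirit of
  CD-HIT clustering (not bit-compatible with CD-HIT: it clusters on
  k-mer cosine similarity rather than alignment identity).

Every stochastic operation takes an explicit seed, canonicalizes record
order by id before sampling, and is bit-reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Optional

import numpy as np

from .features import kmer_counts
from .io import Dataset, SequenceRecord, SUBTYPE_WEAK


@dataclass(frozen=True)
class BaggingConfig:
    """Weighted-bagging settings.

    ``multiplier`` scales the positive training set; ``weak_fraction`` of
    the bootstrap draws come exclusively from the weak-subtype pool, the
    rest from all positives.
    """

    multiplier: int = 3
    weak_fraction: float = 1.0 / 3.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.multiplier < 1:
            raise ValueError("multiplier must be >= 1")
        if not 0.0 <= self.weak_fraction <= 1.0:
            raise ValueError("weak_fraction must lie in [0, 1]")


def _sorted_records(data: Dataset) -> list[SequenceRecord]:
    return sorted(data.records, key=lambda r: r.id)


def downsample_negatives(neg: Dataset, target_n: int, seed: int) -> Dataset:
    """Uniform sample without replacement of ``target_n`` records."""
    if target_n > len(neg):
        raise ValueError(f"target_n={target_n} exceeds dataset size {len(neg)}")
    if target_n < 0:
        raise ValueError("target_n must be >= 0")
    recs = _sorted_records(neg)
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(recs), size=target_n, replace=False)
    chosen = {recs[i].id for i in idx}
    return Dataset([r for r in neg if r.id in chosen], name=neg.name)


def weighted_bagging(pos: Dataset, cfg: BaggingConfig) -> Dataset:
    """Bootstrap-augment positives, over-weighting the weak subtype.

    Output size is exactly ``multiplier * len(pos)``:
    ``round((1 - weak_fraction) * multiplier * len(pos))`` draws with
    replacement from all positives, the remainder from the weak subtype
    only. Bagged records get a ``__bagN`` suffix to keep ids unique.
    """
    if len(pos) == 0:
        raise ValueError("positive dataset is empty")
    total = cfg.multiplier * len(pos)
    n_all = round((1.0 - cfg.weak_fraction) * total)
    n_weak = total - n_all
    all_recs = _sorted_records(pos)
    weak_recs = [r for r in all_recs if r.subtype == SUBTYPE_WEAK]
    if n_weak > 0 and not weak_recs:
        raise ValueError(
            "weak_fraction > 0 but no record has subtype='weak'; "
            "tag the minority positive subtype or set weak_fraction=0"
        )
    rng = np.random.default_rng(cfg.seed)
    draws = [all_recs[i] for i in rng.integers(0, len(all_recs), size=n_all)]
    if n_weak:
        draws += [weak_recs[i] for i in rng.integers(0, len(weak_recs), size=n_weak)]
    counts: dict[str, int] = {}
    out = []
    for rec in draws:
        n_seen = counts.get(rec.id, 0)
        counts[rec.id] = n_seen + 1
        out.append(replace(rec, id=f"{rec.id}__bag{n_seen}"))
    return Dataset(out, name=f"{pos.name}_bagged")


@dataclass
class SplitPlan:
    """Stratified fold assignment for cross-validation."""

    n_folds: int
    fold_assignments: dict[str, int]
    seed: int

    def fold_ids(self, fold: int) -> list[str]:
        return [rid for rid, f in self.fold_assignments.items() if f == fold]

    def split(self, data: Dataset, fold: int) -> tuple[Dataset, Dataset]:
        """(train, test) datasets for one held-out fold."""
        test_ids = set(self.fold_ids(fold))
        train = Dataset([r for r in data if r.id in self.fold_assignments and r.id not in test_ids],
                        name=f"{data.name}_train{fold}")
        test = Dataset([r for r in data if r.id in test_ids], name=f"{data.name}_test{fold}")
        return train, test

    def to_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("record_id\tfold\n")
            for rid in sorted(self.fold_assignments):
                fh.write(f"{rid}\t{self.fold_assignments[rid]}\n")


def stratified_kfold(data: Dataset, n_folds: int, seed: int) -> SplitPlan:
    """Per-class round-robin fold assignment after a seeded shuffle.

    Fold sizes per class differ by at most one. Every labeled record is
    assigned exactly one fold.
    """
    data.require_labels()
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    by_class: dict[str, list[str]] = {}
    for rec in data:
        by_class.setdefault(rec.label, []).append(rec.id)
    for label, ids in by_class.items():
        if len(ids) < n_folds:
            raise ValueError(
                f"class {label!r} has {len(ids)} records, fewer than n_folds={n_folds}"
            )
    rng = np.random.default_rng(seed)
    assignments: dict[str, int] = {}
    for label in sorted(by_class):
        ids = sorted(by_class[label])
        rng.shuffle(ids)
        for i, rid in enumerate(ids):
            assignments[rid] = i % n_folds
    return SplitPlan(n_folds=n_folds, fold_assignments=assignments, seed=seed)


def leave_gene_out_split(pos: Dataset, gene: str) -> tuple[Dataset, Dataset]:
    """Hold out every transcript variant of one gene as the test set."""
    genes = {r.gene for r in pos if r.gene is not None}
    if gene not in genes:
        raise ValueError(f"gene {gene!r} not found; available genes: {sorted(genes)}")
    test = Dataset([r for r in pos if r.gene == gene], name=f"{pos.name}_{gene}")
    train = Dataset([r for r in pos if r.gene != gene], name=f"{pos.name}_not_{gene}")
    return train, test


def greedy_redundancy_filter(
    data: Dataset, threshold: float, word_k: int = 4
) -> Dataset:
    """Approximate redundancy removal by greedy incremental clustering.

    Records are visited in decreasing length (id as tie-break); a record
    joins the first existing cluster whose representative has word_k-mer
    cosine similarity >= ``threshold``, else founds a new cluster. The
    representatives are returned. Deterministic and invariant to the
    input order. The identity thresholds used for CD-HIT-style filtering
    (0.9, 0.8) map directly onto the cosine cutoff.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must lie in (0, 1]")
    if len(data) == 0:
        raise ValueError("dataset is empty")
    order = sorted(data.records, key=lambda r: (-len(r), r.id))
    reps: list[SequenceRecord] = []
    rep_vecs: list[np.ndarray] = []
    for rec in order:
        if len(rec) < word_k:
            vec = np.zeros(4**word_k)
        else:
            vec = kmer_counts(rec.seq, word_k)
            vec = vec / np.linalg.norm(vec)
        absorbed = False
        for rv in rep_vecs:
            if float(vec @ rv) >= threshold:
                absorbed = True
                break
        if not absorbed:
            reps.append(rec)
            rep_vecs.append(vec)
    return Dataset(reps, name=f"{data.name}_nr{threshold:g}")


def write_manifest(data: Dataset, path: str | Path) -> None:
    """Audit TSV of a sampled/bagged dataset (id, label, subtype, gene, length)."""
    with Path(path).open("w") as fh:
        fh.write("id\tlabel\tsubtype\tgene\tlength\n")
        for r in data:
            fh.write(
                f"{r.id}\t{r.label or ''}\t{r.subtype or ''}\t{r.gene or ''}\t{len(r)}\n"
            )
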