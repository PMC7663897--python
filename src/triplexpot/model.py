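"""Model/Results interface tying the pipeline together.

:class:`TriplexPotentialModel` is constructed from labeled positive and
negative sequence datasets (or FASTA files) and owns the configuration
of the full training protocol — featurization, weighted bagging,
negative down-sampling, and the convolutional classifier. ``fit()``
returns a :class:`TriplexFitResults` carrying the trained classifier,
its training-sample diagnostics and a ``summary()`` table;
``cross_validate()`` and ``leave_gene_out()`` run the evaluation
protocols and return results objects of their own.

Typical use::

    design = SyntheticDesign.lncrna_mode(seed=1)
    pos, neg = generate(design)
    model = TriplexPotentialModel(pos, neg, role="lncRNA")
    cv = model.cross_validate(n_folds=5, seed=1)
    print(cv.summary())
    res = model.fit(seed=1)
    probs = res.predict_proba(new_sequences)
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__ as _version
from .cnn import (
    CNNConfig,
    ROLE_DNA_SITE,
    ROLE_LNCRNA,
    TrainedModel,
    classify as _classify,
    load_model,
    predict_proba as _predict_proba,
    save_model,
)
from .evaluation import (
    CVResult,
    MetricsReport,
    _stage_seeds,
    _train_fold,
    evaluate_scores,
    run_cross_validation,
    run_leave_gene_out,
)
from .features import DEFAULT_K_RANGE, DEFAULT_PSEUDOCOUNT, featurize_dataset
from .io import Dataset, NEGATIVE, POSITIVE, SUBTYPE_WEAK, read_fasta
from .sampling import BaggingConfig


@dataclass
class LeaveGeneOutResult:
    """Repeated leave-gene-out evaluations for one held-out gene."""

    gene: str
    reports: list[MetricsReport]

    @property
    def mean_auroc(self) -> Optional[float]:
        vals = [r.auroc for r in self.reports if r.auroc is not None]
        return float(np.mean(vals)) if vals else None

    def summary(self) -> pd.DataFrame:
        df = pd.DataFrame([r.to_dict() for r in self.reports],
                          index=[f"rep{i}" for i in range(len(self.reports))])
        return df


class TriplexPotentialModel:
    """Triplex-forming-potential classifier over nucleotide sequences.

    Parameters
    ----------
    pos, neg : Dataset
        Positive and negative sequence sets. Positive records may carry
        ``subtype`` tags ("strong"/"weak") used by weighted bagging and
        ``gene`` labels used by leave-gene-out validation.
    role : {"lncRNA", "dna_site"}
        Which of the two model roles is being trained. The lncRNA role
        defaults to weighted bagging (when weak-subtype records exist);
        the DNA-site role defaults to plain down-sampling.
    bagging : BaggingConfig, None, or "auto"
        Positive-augmentation settings; "auto" resolves per the role.
    cnn : CNNConfig
        Architecture and training hyperparameters.
    """

    def __init__(
        self,
        pos: Dataset,
        neg: Dataset,
        role: str = ROLE_LNCRNA,
        bagging: BaggingConfig | None | str = "auto",
        cnn: CNNConfig = CNNConfig(),
        k_range: Sequence[int] = DEFAULT_K_RANGE,
        pseudocount: float = DEFAULT_PSEUDOCOUNT,
        threshold: float = 0.5,
    ):
        if role not in (ROLE_LNCRNA, ROLE_DNA_SITE):
            raise ValueError(f"unknown role {role!r}")
        self.pos = pos.with_label(POSITIVE)
        self.neg = neg.with_label(NEGATIVE)
        if bagging == "auto":
            has_weak = any(r.subtype == SUBTYPE_WEAK for r in self.pos)
            bagging = BaggingConfig() if (role == ROLE_LNCRNA and has_weak) else None
        self.bagging = bagging
        self.role = role
        self.cnn = cnn
        self.k_range = tuple(k_range)
        self.pseudocount = pseudocount
        self.threshold = threshold

    @classmethod
    def from_fasta(
        cls,
        pos_path: str | Path,
        neg_path: str | Path,
        drop_n: bool = True,
        **kwargs,
    ) -> "TriplexPotentialModel":
        """Build from positive/negative FASTA files (N-records dropped)."""
        pos = read_fasta(pos_path, label=POSITIVE, drop_n=drop_n)
        neg = read_fasta(neg_path, label=NEGATIVE, drop_n=drop_n)
        return cls(pos, neg, **kwargs)

    def fit(self, seed: int = 0) -> "TriplexFitResults":
        """Run the full training protocol on all data and return results."""
        trained, profile = _train_fold(
            self.pos, self.neg, self.bagging, self.cnn,
            _stage_seeds(seed, 0), self.k_range, self.pseudocount,
        )
        trained.threshold = self.threshold
        trained.model_role = self.role
        # diagnostics on the (balanced) data the network actually saw are
        # optimistic; report instead on the full imbalanced input
        full = Dataset(self.pos.records + self.neg.records, name="train_all")
        scores = trained.predict_proba_matrix(featurize_dataset(full, profile))
        y = np.concatenate([np.ones(len(self.pos)), np.zeros(len(self.neg))])
        report = evaluate_scores(y, scores, self.threshold)
        return TriplexFitResults(model=trained, train_report=report,
                                 seed=seed, parent=self)

    def cross_validate(self, n_folds: int = 5, seed: int = 0) -> CVResult:
        """Stratified k-fold CV of the full protocol (test folds untouched)."""
        return run_cross_validation(
            self.pos, self.neg, n_folds=n_folds, bagging=self.bagging,
            cnn=self.cnn, seed=seed, k_range=self.k_range,
            pseudocount=self.pseudocount, threshold=self.threshold,
        )

    def leave_gene_out(self, gene: str, reps: int = 5,
                       seed: int = 0) -> LeaveGeneOutResult:
        """Hold out all variants of ``gene``; repeat with fresh negatives."""
        reports = run_leave_gene_out(
            self.pos, self.neg, gene, reps=reps, bagging=self.bagging,
            cnn=self.cnn, seed=seed, k_range=self.k_range,
            pseudocount=self.pseudocount, threshold=self.threshold,
        )
        return LeaveGeneOutResult(gene=gene, reports=reports)


@dataclass
class TriplexFitResults:
    """Fitted classifier plus diagnostics; supports prediction and persistence."""

    model: TrainedModel
    train_report: MetricsReport
    seed: int
    parent: Optional[TriplexPotentialModel] = field(default=None, repr=False)

    def predict_proba(self, data: Dataset) -> np.ndarray:
        return _predict_proba(self.model, data)

    def classify(self, data: Dataset) -> np.ndarray:
        return _classify(self.model, data)

    def save(self, directory: str | Path) -> None:
        save_model(self.model, directory)

    @classmethod
    def load(cls, directory: str | Path) -> "TriplexFitResults":
        """Load a saved model directory (training diagnostics not persisted)."""
        model = load_model(directory)
        empty = MetricsReport(
            counts=None, acc=None, sn=None, sp=None, hm=None, f1=None,
            pre=None, auroc=None, auprc=None,
        )
        return cls(model=model, train_report=empty, seed=-1)

    def summary(self) -> str:
        m = self.model
        cfg = m.config
        r = self.train_report
        lines = [
            "Triplex-forming potential model",
            "=" * 47,
            f"{'role':<24}{m.model_role}",
            f"{'toolkit version':<24}{_version}",
            f"{'seed':<24}{self.seed}",
            f"{'decision threshold':<24}{m.threshold}",
            f"{'conv layers':<24}{cfg.n_conv_layers}",
            f"{'filters':<24}{cfg.filters_per_layer}",
            f"{'kernels':<24}{cfg.kernel_sizes}",
            f"{'final map length':<24}{cfg.stage_lengths()[-1]}",
            f"{'epochs':<24}{cfg.epochs}",
            "-" * 47,
        ]
        if r.counts is not None:
            lines.append("Training-set diagnostics (full imbalance):")
            for name in ("acc", "sn", "sp", "hm", "f1", "auroc", "auprc"):
                val = getattr(r, name)
                lines.append(f"{name:<24}{val:.4f}" if val is not None
                             else f"{name:<24}undefined")
        return "\n".join(lines)
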