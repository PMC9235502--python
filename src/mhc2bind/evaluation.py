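"""Evaluation metrics and protocol drivers.

Per-allele AUC (binder threshold: IC50 < 500 nM, i.e. normalized affinity
strictly above 0.426) and Pearson correlation, macro-averaged over alleles;
an exact two-tailed binomial sign test for paired method comparison over
alleles; 5-fold cross-validation and leave-one-molecule-out (LOMO)
protocol drivers; and 9-mer redundancy statistics between CV folds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import roc_auc_score

from .core import predict_affinity
from .data import AffinityRecord, AlleleRegistry, CORE_LENGTH, transform_ic50
from .model import ModelConfig
from .training import Ensemble, TrainConfig, train_ensemble

#: Normalized-affinity binder threshold: the transform of 500 nM.
BINDER_THRESHOLD = transform_ic50(500.0)


def binarize(affinity) -> np.ndarray | bool:
    """Binder iff normalized affinity strictly exceeds the 500 nM threshold.

    The transform is decreasing, so IC50 < 500 nM maps to affinity above the
    threshold; a value exactly at the threshold is a non-binder.
    """
    affinity = np.asarray(affinity, dtype=float)
    out = affinity > BINDER_THRESHOLD
    return bool(out) if out.ndim == 0 else out


def auc(scores, labels) -> float | None:
    """ROC AUC (rank-based, ties half-credit); None if one class is absent."""
    labels = np.asarray(labels, dtype=bool)
    if labels.all() or not labels.any():
        return None
    return float(roc_auc_score(labels, np.asarray(scores, dtype=float)))


def pcc(pred, target) -> float | None:
    """Pearson correlation; None for degenerate (constant or n < 2) input."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if len(pred) < 2 or np.ptp(pred) == 0 or np.ptp(target) == 0:
        return None
    return float(stats.pearsonr(pred, target).statistic)


def binomial_win_test(wins: int, n: int) -> float:
    """Exact two-tailed sign test p-value under Binomial(n, 1/2).

    ``p = min(1, 2 * min(P(X <= wins), P(X >= wins)))`` with exact tail sums.
    """
    if not 0 <= wins <= n or n < 1:
        raise ValueError("need 0 <= wins <= n and n >= 1")
    lower = stats.binom.cdf(wins, n, 0.5)
    upper = stats.binom.sf(wins - 1, n, 0.5)
    return float(min(1.0, 2.0 * min(lower, upper)))


@dataclass
class AlleleMetrics:
    allele_name: str
    n_records: int
    n_binders: int
    auc: float | None
    pcc: float | None


@dataclass
class ProtocolReport:
    """Per-allele metrics with macro averages over alleles where defined."""

    per_allele: list[AlleleMetrics]
    macro_auc: float | None
    macro_pcc: float | None
    micro_auc: float | None
    n_alleles_auc: int
    n_alleles_excluded: int
    wins: int | None = None
    losses: int | None = None
    p_value: float | None = None

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                dict(allele=m.allele_name, n=m.n_records, n_binders=m.n_binders,
                     auc=m.auc, pcc=m.pcc)
                for m in self.per_allele
            ]
        )


def summarize_by_allele(
    records: Sequence[AffinityRecord],
    predictions: np.ndarray,
) -> ProtocolReport:
    """Per-allele AUC/PCC of predictions against record targets.

    Alleles with a single label class have undefined AUC and are excluded
    from the macro average (the exclusion count is reported).
    """
    predictions = np.asarray(predictions, dtype=float)
    targets = np.array([r.affinity for r in records])
    labels = binarize(targets)
    alleles = np.array([r.allele_name for r in records])
    per: list[AlleleMetrics] = []
    for name in sorted(set(alleles)):
        sel = alleles == name
        per.append(AlleleMetrics(
            allele_name=name,
            n_records=int(sel.sum()),
            n_binders=int(labels[sel].sum()),
            auc=auc(predictions[sel], labels[sel]),
            pcc=pcc(predictions[sel], targets[sel]),
        ))
    aucs = [m.auc for m in per if m.auc is not None]
    pccs = [m.pcc for m in per if m.pcc is not None]
    return ProtocolReport(
        per_allele=per,
        macro_auc=float(np.mean(aucs)) if aucs else None,
        macro_pcc=float(np.mean(pccs)) if pccs else None,
        micro_auc=auc(predictions, labels),
        n_alleles_auc=len(aucs),
        n_alleles_excluded=len(per) - len(aucs),
    )


def compare_methods(
    report_a: ProtocolReport, report_b: ProtocolReport
) -> tuple[int, int, float]:
    """Win/loss counts of method A over B on shared alleles + sign-test p.

    Ties are excluded from wins and losses but counted in n (a tie is not a
    win for either side).
    """
    b_auc = {m.allele_name: m.auc for m in report_b.per_allele}
    wins = losses = n = 0
    for m in report_a.per_allele:
        other = b_auc.get(m.allele_name)
        if m.auc is None or other is None:
            continue
        n += 1
        if m.auc > other:
            wins += 1
        elif m.auc < other:
            losses += 1
    if n == 0:
        raise ValueError("no alleles with defined AUC in both reports")
    return wins, losses, binomial_win_test(wins, n)


def _predict_records(records, ensemble, registry):
    preds = np.empty(len(records))
    by_allele: dict[str, list[int]] = {}
    for i, r in enumerate(records):
        by_allele.setdefault(r.allele_name, []).append(i)
    for name, idx in by_allele.items():
        peptides = [records[i].peptide for i in idx]
        preds[np.array(idx)] = predict_affinity(peptides, name, ensemble, registry)
    return preds


def run_cv(
    records: Sequence[AffinityRecord],
    registry: AlleleRegistry,
    model_config: ModelConfig,
    train_config: TrainConfig,
) -> ProtocolReport:
    """K-fold cross-validation using the fold labels carried by the records.

    For each fold an ensemble is trained on the remaining folds and scores
    the held-out fold; per-allele metrics are computed on the pooled
    out-of-fold predictions, so every record is scored exactly once.
    """
    if any(r.fold is None for r in records):
        raise ValueError("all records need fold labels; no silent random split")
    folds = sorted({r.fold for r in records})
    if len(folds) < 2:
        raise ValueError("cross-validation needs at least two folds")
    predictions = np.full(len(records), np.nan)
    for f in folds:
        train_recs = [r for r in records if r.fold != f]
        test_idx = [i for i, r in enumerate(records) if r.fold == f]
        ensemble = train_ensemble(train_recs, registry, model_config, train_config)
        test_recs = [records[i] for i in test_idx]
        predictions[np.array(test_idx)] = _predict_records(test_recs, ensemble, registry)
    assert not np.isnan(predictions).any(), "out-of-fold pool must cover every record"
    return summarize_by_allele(records, predictions)


def lomo_eligible_alleles(
    records: Sequence[AffinityRecord],
    min_records: int = 40,
    min_binders: int = 3,
    strict_greater: bool = True,
) -> list[str]:
    """Alleles with more than ``min_records`` data points and at least
    ``min_binders`` binders (boundary on the record count configurable)."""
    out = []
    for name in sorted({r.allele_name for r in records}):
        recs = [r for r in records if r.allele_name == name]
        n_bind = sum(bool(binarize(r.affinity)) for r in recs)
        enough = len(recs) > min_records if strict_greater else len(recs) >= min_records
        if enough and n_bind >= min_binders:
            out.append(name)
    return out


def run_lomo(
    records: Sequence[AffinityRecord],
    registry: AlleleRegistry,
    model_config: ModelConfig,
    train_config: TrainConfig,
    min_records: int = 40,
    min_binders: int = 3,
    strict_greater: bool = True,
    mode: str = "cv",
    alleles: Sequence[str] | None = None,
) -> ProtocolReport:
    """Leave-one-molecule-out evaluation of pan-specific generalization.

    For each eligible target allele, models never see any of its records at
    training time. ``mode='cv'`` follows the fold structure (for each fold,
    train on the other folds minus the target allele, test on the target
    allele's records in that fold); ``mode='holdout'`` trains once on all
    records of the other alleles and tests on all target records.
    """
    if mode not in ("cv", "holdout"):
        raise ValueError(f"unknown LOMO mode {mode!r}")
    if len({r.allele_name for r in records}) < 2:
        raise ValueError("LOMO needs at least two alleles")
    targets = alleles if alleles is not None else lomo_eligible_alleles(
        records, min_records, min_binders, strict_greater
    )
    if not targets:
        raise ValueError("no allele passes the LOMO eligibility filter")
    all_rows: list[AffinityRecord] = []
    all_preds: list[np.ndarray] = []
    for name in targets:
        target_recs = [r for r in records if r.allele_name == name]
        other_recs = [r for r in records if r.allele_name != name]
        assert all(r.allele_name != name for r in other_recs)
        if mode == "holdout":
            ensemble = train_ensemble(other_recs, registry, model_config, train_config)
            preds = _predict_records(target_recs, ensemble, registry)
            all_rows.extend(target_recs)
            all_preds.append(preds)
        else:
            if any(r.fold is None for r in records):
                raise ValueError("LOMO in cv mode requires fold labels")
            for f in sorted({r.fold for r in records}):
                test_recs = [r for r in target_recs if r.fold == f]
                if not test_recs:
                    continue
                train_recs = [r for r in other_recs if r.fold != f]
                ensemble = train_ensemble(train_recs, registry, model_config, train_config)
                all_rows.extend(test_recs)
                all_preds.append(_predict_records(test_recs, ensemble, registry))
    return summarize_by_allele(all_rows, np.concatenate(all_preds))


# ---------------------------------------------------------------------------
# redundancy statistics


@dataclass
class RedundancyStats:
    outer_p: float | None
    inner_p: float | None

    @property
    def ratio(self) -> float | None:
        if self.outer_p in (None, 0.0) or self.inner_p is None:
            return None
        return self.inner_p / self.outer_p


def _kmers(peptide: str, k: int) -> set[str]:
    return {peptide[i : i + k] for i in range(len(peptide) - k + 1)}


def redundancy_stats(
    peptides_with_folds: Sequence[tuple[str, int]],
    k: int = CORE_LENGTH,
) -> RedundancyStats:
    """Probability that two distinct peptides share an exact k-mer.

    ``outer_p`` is over pairs in different folds, ``inner_p`` over pairs in
    the same fold. Computed exactly through a k-mer inverted index over
    distinct peptide sequences (duplicates collapse to their first fold).
    A category with no pairs yields None.
    """
    seen: dict[str, int] = {}
    for pep, fold in peptides_with_folds:
        seen.setdefault(pep, fold)
    peptides = list(seen)
    folds = np.array([seen[p] for p in peptides])
    n = len(peptides)
    index: dict[str, list[int]] = {}
    for i, pep in enumerate(peptides):
        for kmer in _kmers(pep, k):
            index.setdefault(kmer, []).append(i)
    sharing: set[tuple[int, int]] = set()
    for idxs in index.values():
        if len(idxs) < 2:
            continue
        for a in range(len(idxs)):
            for b in range(a + 1, len(idxs)):
                sharing.add((idxs[a], idxs[b]))
    fold_counts = np.bincount(folds - folds.min())
    total_pairs = n * (n - 1) // 2
    inner_pairs = int(sum(c * (c - 1) // 2 for c in fold_counts))
    outer_pairs = total_pairs - inner_pairs
    inner_share = sum(1 for a, b in sharing if folds[a] == folds[b])
    outer_share = len(sharing) - inner_share
    return RedundancyStats(
        outer_p=outer_share / outer_pairs if outer_pairs else None,
        inner_p=inner_share / inner_pairs if inner_pairs else None,
    )


# ---------------------------------------------------------------------------
# ablation harness


def run_kernel_ablation(
    records: Sequence[AffinityRecord],
    registry: AlleleRegistry,
    base_model_config: ModelConfig,
    train_config: TrainConfig,
    single_sizes: Sequence[int] = (9, 11, 13, 15),
) -> pd.DataFrame:
    """Compare single-kernel-size models against the multi-size default.

    Runs cross-validation once per configuration: each single size gets all
    of the default channel budget; the final row is the unmodified
    multi-size configuration. Returns a table of macro AUC/PCC per variant.
    """
    total = base_model_config.n_channels
    rows = []
    variants: list[tuple[str, ModelConfig]] = []
    for m in single_sizes:
        cfg = ModelConfig(**{**base_model_config.to_dict(),
                             "kernel_sizes": (m,), "kernels_per_size": (total,)})
        variants.append((f"single_{m}", cfg))
    variants.append(("multi", base_model_config))
    for name, cfg in variants:
        report = run_cv(records, registry, cfg, train_config)
        rows.append(dict(variant=name, kernel_sizes=str(cfg.kernel_sizes),
                         macro_auc=report.macro_auc, macro_pcc=report.macro_pcc))
    return pd.DataFrame(rows)
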