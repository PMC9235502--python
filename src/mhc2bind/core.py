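"""Ensemble prediction, binding-core calling, motifs and pocket weights.

Binding-core calling removes the max-pool: the output layer is applied to
every candidate 9-mer row, giving one sigmoid score per core start; the
highest-scoring 9-mer is reported as the binding core. Motifs are extracted
by scoring a large random peptide sample, keeping the top fraction of
predicted binders, calling their cores and summarizing them as a position
frequency matrix with per-position information content. Pocket importance
sums the absolute binding-interaction kernel weights that map to each of
the nine groove pockets.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .alphabet import CANONICAL_AA, DEFAULT_ALPHABET
from .data import AffinityRecord, AlleleRegistry, CORE_LENGTH, encode_pair
from .model import forward_batch, pack_batch
from .training import Ensemble


def _predict_members(peptides, allele, ensemble, registry, batch_size=256):
    """Per-member pooled scores, shape (T, n_peptides)."""
    records = [AffinityRecord(p, allele, 0.0) for p in peptides]
    pairs = [encode_pair(r, registry) for r in records]
    out = np.empty((ensemble.size, len(pairs)))
    for start in range(0, len(pairs), batch_size):
        chunk = pairs[start : start + batch_size]
        pep, pse, lengths, _ = pack_batch(chunk)
        for t, params in enumerate(ensemble.members):
            z, _, _ = forward_batch(params, ensemble.config, pep, pse, lengths)
            out[t, start : start + len(chunk)] = z
    return out


def predict_affinity(
    peptides: Sequence[str],
    allele: str,
    ensemble: Ensemble,
    registry: AlleleRegistry,
    batch_size: int = 256,
) -> np.ndarray:
    """Ensemble-averaged affinity scores in (0, 1), one per input peptide."""
    return _predict_members(peptides, allele, ensemble, registry, batch_size).mean(axis=0)


@dataclass
class CorePrediction:
    """Per-start binding-core scores for one peptide (1-based starts)."""

    peptide: str
    allele_name: str
    scores: np.ndarray  # length L - 8, scores[i] for start i + 1
    best_start: int  # 1-based
    core_sequence: str

    @property
    def start_positions(self) -> np.ndarray:
        return np.arange(1, len(self.scores) + 1)


def predict_core(
    peptide: str,
    allele: str,
    ensemble: Ensemble,
    registry: AlleleRegistry,
) -> CorePrediction:
    """Call the binding core: average per-start scores over members, argmax.

    Ties break toward the smallest start position.
    """
    preds = predict_cores([peptide], allele, ensemble, registry)
    return preds[0]


def predict_cores(
    peptides: Sequence[str],
    allele: str,
    ensemble: Ensemble,
    registry: AlleleRegistry,
    batch_size: int = 256,
) -> list[CorePrediction]:
    """Vectorized :func:`predict_core` over a peptide list."""
    records = [AffinityRecord(p, allele, 0.0) for p in peptides]
    pairs = [encode_pair(r, registry) for r in records]
    results: list[CorePrediction] = []
    for start in range(0, len(pairs), batch_size):
        chunk = pairs[start : start + batch_size]
        peps = peptides[start : start + batch_size]
        pep, pse, lengths, _ = pack_batch(chunk)
        acc = None
        for params in ensemble.members:
            _, core_scores, rows_mask = forward_batch(params, ensemble.config, pep, pse, lengths)
            cs = np.where(rows_mask > 0, core_scores, 0.0)
            acc = cs if acc is None else acc + cs
        acc /= ensemble.size
        for i, p in enumerate(peps):
            n_rows = len(p) - CORE_LENGTH + 1
            scores = acc[i, :n_rows]
            best = int(np.argmax(scores))  # argmax takes the first maximum
            results.append(CorePrediction(
                peptide=p, allele_name=allele, scores=scores,
                best_start=best + 1, core_sequence=p[best : best + CORE_LENGTH],
            ))
    return results


@dataclass
class MotifSummary:
    """Position frequency matrix over predicted binding cores.

    ``pfm`` is 9 x 20 (rows: pocket positions, columns: canonical residues
    in alphabetical order); each row sums to 1. ``information`` is the
    per-position information content log2(20) - H(p) in bits.
    """

    pfm: np.ndarray
    information: np.ndarray
    n_peptides: int
    alphabet_order: str = CANONICAL_AA

    def to_frame(self):
        import pandas as pd

        df = pd.DataFrame(self.pfm, columns=list(self.alphabet_order),
                          index=[f"P{i}" for i in range(1, CORE_LENGTH + 1)])
        df["information_bits"] = self.information
        return df


@dataclass
class PeptideBackground:
    """Random-peptide background: residue frequencies and a length range."""

    residue_freqs: np.ndarray | None = None  # (20,), uniform if None
    length_range: tuple[int, int] = (12, 21)

    def sample(self, n: int, rng: np.random.Generator) -> list[str]:
        freqs = self.residue_freqs
        if freqs is None:
            freqs = np.full(20, 1.0 / 20)
        freqs = np.asarray(freqs, dtype=float)
        freqs = freqs / freqs.sum()
        lo, hi = self.length_range
        lengths = rng.integers(lo, hi + 1, size=n)
        letters = np.array(list(CANONICAL_AA))
        return [
            "".join(letters[rng.choice(20, size=L, p=freqs)]) for L in lengths
        ]


def pfm_from_cores(cores: Sequence[str]) -> MotifSummary:
    """Build a PFM and information content from called 9-mer cores."""
    if not cores:
        raise ValueError("no cores to summarize")
    counts = np.zeros((CORE_LENGTH, 20))
    for core in cores:
        ids = DEFAULT_ALPHABET.encode(core)
        for pos, t in enumerate(ids):
            if t < 20:  # unknown tokens do not contribute to the motif
                counts[pos, t] += 1
    pfm = counts / counts.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        plogp = np.where(pfm > 0, pfm * np.log2(pfm), 0.0)
    info = np.log2(20) + plogp.sum(axis=1)
    return MotifSummary(pfm=pfm, information=info, n_peptides=len(cores))


def extract_motif(
    allele: str,
    ensemble: Ensemble,
    registry: AlleleRegistry,
    n_random: int = 100_000,
    top_frac: float = 0.01,
    background: PeptideBackground | None = None,
    seed: int = 0,
) -> MotifSummary:
    """Motif of an allele from the top fraction of scored random peptides.

    Samples ``n_random`` background peptides, scores them with the ensemble,
    keeps the ceil(top_frac * n) highest-scoring ones, calls their binding
    cores and summarizes the cores as a PFM.
    """
    if background is None:
        background = PeptideBackground()
    rng = np.random.default_rng(seed)
    peptides = background.sample(n_random, rng)
    scores = predict_affinity(peptides, allele, ensemble, registry)
    n_top = int(np.ceil(top_frac * n_random))
    if n_top < 1:
        raise ValueError("top fraction selects no peptides")
    top_idx = np.argsort(-scores, kind="stable")[:n_top]
    top_peptides = [peptides[i] for i in top_idx]
    cores = [cp.core_sequence for cp in predict_cores(top_peptides, allele, ensemble, registry)]
    return pfm_from_cores(cores)


@dataclass
class PocketImportance:
    """Mean/sd over ensemble members of summed absolute kernel weights.

    One entry per groove pocket 1..9. For kernel sizes above 9 only the
    central nine kernel rows map to pockets; the flanking rows are summed
    separately as ``pfr_mean`` (peptide-flanking-region weight).
    """

    mean: np.ndarray  # (9,)
    sd: np.ndarray  # (9,)
    pfr_mean: float
    pfr_sd: float


def pocket_importance(ensemble: Ensemble) -> PocketImportance:
    """Sum |W| per binding-core position over all kernels, mean/sd across members."""
    config = ensemble.config
    per_member = np.zeros((ensemble.size, CORE_LENGTH))
    per_member_pfr = np.zeros(ensemble.size)
    for t, params in enumerate(ensemble.members):
        for m in config.kernel_sizes:
            W = np.abs(params[f"conv{m}_W"])  # (h, m, 34)
            a = (m - CORE_LENGTH) // 2
            per_member[t] += W[:, a : a + CORE_LENGTH, :].sum(axis=(0, 2))
            if a:
                per_member_pfr[t] += W[:, :a, :].sum() + W[:, a + CORE_LENGTH :, :].sum()
    return PocketImportance(
        mean=per_member.mean(axis=0),
        sd=per_member.std(axis=0),
        pfr_mean=float(per_member_pfr.mean()),
        pfr_sd=float(per_member_pfr.std()),
    )


def write_core_predictions(path, predictions: Sequence[CorePrediction]) -> None:
    """TSV: peptide, allele, best_start, core, best score, per-start scores."""
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("peptide\tallele\tbest_start\tcore\tscore\tper_start_scores\n")
        for cp in predictions:
            per = ",".join(format(s, ".6g") for s in cp.scores)
            fh.write(
                f"{cp.peptide}\t{cp.allele_name}\t{cp.best_start}\t{cp.core_sequence}"
                f"\t{cp.scores[cp.best_start - 1]:.6g}\t{per}\n"
            )


def write_motif(path, motif: MotifSummary) -> None:
    """PFM as TSV (9 rows x 20 residue columns) plus an information column."""
    motif.to_frame().to_csv(path, sep="\t", float_format="%.6g")


def render_logo(motif: MotifSummary, ax=None):
    """Render a simple sequence logo: letters stacked to information height."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 3))
    for pos in range(CORE_LENGTH):
        heights = motif.pfm[pos] * motif.information[pos]
        order = np.argsort(heights)
        y = 0.0
        for j in order:
            h = heights[j]
            if h <= 1e-3:
                continue
            ax.text(pos + 1, y + h / 2, motif.alphabet_order[j],
                    ha="center", va="center", fontsize=6 + 10 * h / np.log2(20))
            y += h
    ax.set_xlim(0.5, CORE_LENGTH + 0.5)
    ax.set_ylim(0, np.log2(20))
    ax.set_xlabel("binding-core position (pocket)")
    ax.set_ylabel("information (bits)")
    ax.set_xticks(range(1, CORE_LENGTH + 1))
    return ax
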