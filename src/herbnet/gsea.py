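"""Gene Set Enrichment Analysis from first principles.

Three steps: (1) rank all genes by a two-group differential metric
(signal-to-noise by default); (2) walk the ranked list computing the
weighted Kolmogorov-Smirnov running sum — member genes ("hits")
increment by |metric|^p normalized over hits, non-members decrement by
1/(N - N_hits) — whose maximum-magnitude deviation is the enrichment
score ES; (3) build a null by permuting the phenotype labels, giving a
nominal p per set, a signed normalized score NES = ES / mean |null ES of
matching sign|, and an FDR q from the pooled null-NES distribution.

Positive ES means coordinate up-regulation in the first group of the
matrix's ``group_order``.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import DomainError, ValidationError
from .enrichment import GeneSetCollection
from .expression import ExpressionMatrix
from .network import normalize_symbol

METRICS = ("signal_to_noise", "t_stat", "log_fc")

#: GSEA's variance floor: per-group SD is floored at 0.2 x |group mean|
#: (0.2 when the mean is zero) so flat genes cannot dominate the ranking.
SD_FLOOR_FRACTION = 0.2


@dataclass(frozen=True)
class RankedList:
    """Genes ordered best-to-worst with their metric values.

    Order is non-increasing in the metric; ties are broken by gene
    symbol so runs are reproducible.
    """

    genes: tuple[str, ...]
    scores: np.ndarray

    def __post_init__(self) -> None:
        if len(self.genes) != len(self.scores):
            raise ValidationError("genes and scores differ in length")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError("duplicate genes in ranked list")
        if not np.isfinite(self.scores).all():
            raise ValidationError("metric values must be finite")
        d = np.diff(self.scores)
        if (d > 1e-12).any():
            raise ValidationError("scores must be non-increasing")

    def __len__(self) -> int:
        return len(self.genes)


def _floored_sd(x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Group means and floored SDs along the sample axis."""
    m = x.mean(axis=-1)
    s = x.std(axis=-1, ddof=1)
    floor = SD_FLOOR_FRACTION * np.abs(m)
    floor = np.where(floor == 0, SD_FLOOR_FRACTION, floor)
    return m, np.maximum(s, floor)


def _metric_values(
    x1: np.ndarray, x2: np.ndarray, metric: str
) -> np.ndarray:
    """Per-gene two-group metric; positive = up in group 1."""
    if metric == "log_fc":
        return x1.mean(axis=-1) - x2.mean(axis=-1)
    m1, s1 = _floored_sd(x1)
    m2, s2 = _floored_sd(x2)
    if metric == "signal_to_noise":
        return (m1 - m2) / (s1 + s2)
    if metric == "t_stat":
        n1, n2 = x1.shape[-1], x2.shape[-1]
        return (m1 - m2) / np.sqrt(s1**2 / n1 + s2**2 / n2)
    raise ValueError(f"unknown metric {metric!r}; expected one of {METRICS}")


def rank_genes(mat: ExpressionMatrix, metric: str = "signal_to_noise") -> RankedList:
    """Rank all genes of a two-group matrix by the chosen metric."""
    x1, x2 = mat.split()
    if metric in ("signal_to_noise", "t_stat") and (x1.shape[1] < 2 or x2.shape[1] < 2):
        raise DomainError(f"metric {metric!r} needs >= 2 samples per group")
    scores = _metric_values(x1, x2, metric)
    genes = np.array([normalize_symbol(g) for g in mat.genes])
    order = np.lexsort((genes, -scores))
    return RankedList(genes=tuple(genes[order]), scores=scores[order])


def enrichment_score(
    ranked: RankedList, members: Iterable[str], weight_p: float = 1.0
) -> tuple[float, np.ndarray]:
    """Weighted KS running sum of a gene set over a ranked list.

    Returns (ES, running-sum profile).  ES is the signed
    maximum-magnitude deviation of the profile from zero.  Requires at
    least one member present in the list and at least one non-member
    (otherwise the miss decrement is undefined).
    """
    mset = frozenset(normalize_symbol(g) for g in members)
    hit = np.fromiter((g in mset for g in ranked.genes), dtype=bool, count=len(ranked))
    n_hit = int(hit.sum())
    n = len(ranked)
    if n_hit == 0:
        raise DomainError("no gene-set member present in the ranked list")
    if n_hit == n:
        raise DomainError("gene set covers the entire ranked list")
    w = np.abs(ranked.scores) ** weight_p
    hit_w = np.where(hit, w, 0.0)
    denom = hit_w.sum()
    if denom == 0.0:  # all hits carry zero metric: fall back to equal weights
        hit_w = hit.astype(float)
        denom = float(n_hit)
    running = np.cumsum(hit_w / denom - (~hit) / (n - n_hit))
    es = float(running[int(np.argmax(np.abs(running)))])
    return es, running


@dataclass(frozen=True)
class GseaResult:
    """Tabular GSEA output plus the permutation bookkeeping."""

    table: pd.DataFrame  # term_id, size, es, nes, p_nominal, fdr_q
    n_perm: int
    exhaustive: bool
    seed: int
    metric: str
    weight_p: float


def _perm_metrics(
    x: np.ndarray, group1: np.ndarray, metric: str
) -> np.ndarray:
    """Metric matrix (genes x permutations) for boolean group-1 indicators."""
    k1 = int(group1[0].sum())
    k2 = group1.shape[1] - k1
    p = group1.T.astype(float)  # samples x perms
    q = 1.0 - p
    m1 = x @ p / k1
    m2 = x @ q / k2
    if metric == "log_fc":
        return m1 - m2
    sq = x**2
    v1 = (sq @ p / k1 - m1**2) * (k1 / (k1 - 1))
    v2 = (sq @ q / k2 - m2**2) * (k2 / (k2 - 1))
    s1 = np.sqrt(np.clip(v1, 0.0, None))
    s2 = np.sqrt(np.clip(v2, 0.0, None))
    f1 = np.where(np.abs(m1) == 0, SD_FLOOR_FRACTION, SD_FLOOR_FRACTION * np.abs(m1))
    f2 = np.where(np.abs(m2) == 0, SD_FLOOR_FRACTION, SD_FLOOR_FRACTION * np.abs(m2))
    s1 = np.maximum(s1, f1)
    s2 = np.maximum(s2, f2)
    if metric == "signal_to_noise":
        return (m1 - m2) / (s1 + s2)
    return (m1 - m2) / np.sqrt(s1**2 / k1 + s2**2 / k2)


def _batch_es(
    metric_mat: np.ndarray, mask: np.ndarray, weight_p: float
) -> np.ndarray:
    """ES for one gene set across every column (permutation) of metric_mat.

    Rows of ``metric_mat`` must be in gene-symbol order so the stable
    argsort reproduces the symbol tie-break of :func:`rank_genes`.
    """
    n_genes, n_perm = metric_mat.shape
    order = np.argsort(-metric_mat, axis=0, kind="stable")
    w = np.abs(metric_mat) ** weight_p
    w_ranked = np.take_along_axis(w, order, axis=0)
    hit = mask[order]
    n_hit = int(mask.sum())
    hw = np.where(hit, w_ranked, 0.0)
    denom = hw.sum(axis=0)
    zero = denom == 0.0
    if zero.any():
        hw[:, zero] = hit[:, zero].astype(float)
        denom = np.where(zero, float(n_hit), denom)
    steps = hw / denom - (~hit) / (n_genes - n_hit)
    running = np.cumsum(steps, axis=0)
    idx = np.argmax(np.abs(running), axis=0)
    return running[idx, np.arange(n_perm)]


def _permutation_labels(
    n_samples: int, k1: int, n_perm: int, rng: np.random.Generator
) -> tuple[np.ndarray, bool]:
    """Boolean (perms x samples) group-1 indicators for the phenotype null.

    When fewer distinct labelings exist than requested, all distinct
    labelings are enumerated instead (exhaustive null).
    """
    total = math.comb(n_samples, k1)
    if total <= n_perm:
        out = np.zeros((total, n_samples), dtype=bool)
        for i, combo in enumerate(itertools.combinations(range(n_samples), k1)):
            out[i, list(combo)] = True
        return out, True
    out = np.zeros((n_perm, n_samples), dtype=bool)
    base = np.zeros(n_samples, dtype=bool)
    base[:k1] = True
    for i in range(n_perm):
        out[i] = rng.permutation(base)
    return out, False


def gsea_run(
    mat: ExpressionMatrix,
    collection: GeneSetCollection,
    n_perm: int = 1000,
    seed: int = 0,
    metric: str = "signal_to_noise",
    weight_p: float = 1.0,
    min_size: int = 3,
) -> GseaResult:
    """Full GSEA over a collection with a phenotype-permutation null.

    Nominal p uses the (b+1)/(k+1) pseudo-count over null ES of matching
    sign; NES normalizes ES by the mean |null ES| of matching sign; the
    FDR q compares each NES against the pooled, per-set-normalized null
    NES distribution (positive and negative sides handled separately).
    Results are sorted by |NES| descending.  Deterministic for a fixed
    (inputs, seed).
    """
    if n_perm < 10:
        raise DomainError("n_perm must be >= 10")
    if metric not in METRICS:
        raise ValueError(f"unknown metric {metric!r}")
    rng = np.random.default_rng(seed)

    # rows in symbol order so stable sorts tie-break identically everywhere
    genes = np.array([normalize_symbol(g) for g in mat.genes])
    sym_order = np.argsort(genes)
    genes = genes[sym_order]
    a, b = mat.group_order
    sample_cols = list(mat.values.columns)
    x = mat.values.to_numpy(dtype=float)[sym_order]
    obs_group1 = np.array([mat.groups[c] == a for c in sample_cols])
    k1 = int(obs_group1.sum())

    gene_index = {g: i for i, g in enumerate(genes)}
    masks: dict[str, np.ndarray] = {}
    for term in sorted(collection.sets):
        idx = [gene_index[g] for g in collection.sets[term] if g in gene_index]
        if len(idx) < min_size or len(idx) >= len(genes):
            continue
        mask = np.zeros(len(genes), dtype=bool)
        mask[idx] = True
        masks[term] = mask
    if not masks:
        raise ValidationError("no gene set overlaps the matrix at the required size")

    perm_labels, exhaustive = _permutation_labels(len(sample_cols), k1, n_perm, rng)
    n_used = perm_labels.shape[0]
    obs_metric = _perm_metrics(x, obs_group1[None, :], metric)[:, 0]
    null_metric = _perm_metrics(x, perm_labels, metric)

    rows = []
    pooled_null_nes: list[np.ndarray] = []
    obs_records: list[tuple[str, int, float, float]] = []
    for term, mask in masks.items():
        es = float(_batch_es(obs_metric[:, None], mask, weight_p)[0])
        null = _batch_es(null_metric, mask, weight_p)
        same = null >= 0 if es >= 0 else null < 0
        k = int(same.sum())
        hits = int((np.abs(null[same]) >= abs(es)).sum())
        p_nom = (hits + 1) / (k + 1)
        pos = null[null >= 0]
        neg = null[null < 0]
        mean_pos = pos.mean() if pos.size else np.nan
        mean_neg = np.abs(neg).mean() if neg.size else np.nan
        nes = es / mean_pos if es >= 0 else es / mean_neg
        nes = float(nes) if np.isfinite(nes) else float("nan")
        null_nes = np.concatenate(
            [
                pos / mean_pos if pos.size else pos,
                neg / mean_neg if neg.size else neg,
            ]
        )
        pooled_null_nes.append(null_nes)
        obs_records.append((term, int(mask.sum()), es, nes))
        rows.append({"term_id": term, "size": int(mask.sum()), "es": es, "nes": nes, "p_nominal": p_nom})

    pool = np.concatenate(pooled_null_nes)
    obs_nes = np.array([r[3] for r in obs_records])
    fdr = []
    for _, _, es, nes in obs_records:
        if not np.isfinite(nes):
            fdr.append(float("nan"))
            continue
        if nes >= 0:
            null_side = pool[pool >= 0]
            obs_side = obs_nes[np.isfinite(obs_nes) & (obs_nes >= 0)]
            num = (null_side >= nes).mean() if null_side.size else 0.0
            den = (obs_side >= nes).mean() if obs_side.size else 1.0
        else:
            null_side = pool[pool < 0]
            obs_side = obs_nes[np.isfinite(obs_nes) & (obs_nes < 0)]
            num = (null_side <= nes).mean() if null_side.size else 0.0
            den = (obs_side <= nes).mean() if obs_side.size else 1.0
        fdr.append(float(min(1.0, num / den)) if den > 0 else float("nan"))

    table = pd.DataFrame(rows)
    table["fdr_q"] = fdr
    table["n_perm"] = n_used
    table["seed"] = seed
    table = (
        table.assign(_abs=table["nes"].abs())
        .sort_values(["_abs", "term_id"], ascending=[False, True])
        .drop(columns="_abs")
        .reset_index(drop=True)
    )
    return GseaResult(
        table=table,
        n_perm=n_used,
        exhaustive=exhaustive,
        seed=seed,
        metric=metric,
        weight_p=weight_p,
    )
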