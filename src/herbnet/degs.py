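"""Disease-gene filtering, differential expression and three-set intersection.

Three gene sets feed the candidate-target intersection:

* A — disease-database genes passing a relevance-score filter
  (GeneCards-style; score strictly greater than 5 by default),
* B — differentially expressed genes (DEGs) between two sample groups,
  called at raw P < 0.05 by default,
* C — the targets of the herb network.

The DEG test defaults to Welch's t.  A moderated-t option (empirical-Bayes
shrinkage of gene-wise variances toward a common prior, the procedure
behind limma/GEO2R) is provided because public two-group microarray
contrasts are usually run that way; the choice is a flag.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import special, stats
from statsmodels.stats.multitest import multipletests

from .errors import FormatError, ValidationError
from .expression import ExpressionMatrix
from .network import normalize_symbol

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Disease genes

def load_disease_genes(path: str | Path) -> pd.DataFrame:
    """Read a 2-column (gene, score) TSV; duplicates keep the max score."""
    df = pd.read_csv(path, sep="\t")
    cols = {c.strip().lower(): c for c in df.columns}
    gene_col = cols.get("gene") or cols.get("symbol")
    score_col = cols.get("relevance_score") or cols.get("score")
    if gene_col is None or score_col is None:
        raise FormatError(f"{Path(path).name}: need 'gene' and 'score' columns")
    df = df.rename(columns={gene_col: "gene", score_col: "relevance_score"})
    df["gene"] = df["gene"].map(normalize_symbol)
    df["relevance_score"] = pd.to_numeric(df["relevance_score"], errors="raise")
    if (df["relevance_score"] < 0).any():
        bad = df.index[df["relevance_score"] < 0][0]
        raise ValidationError(f"negative relevance score at data row {bad + 1}")
    n_dup = df["gene"].duplicated().sum()
    if n_dup:
        logger.info("load_disease_genes: collapsing %d duplicate gene rows (max score kept)", n_dup)
        df = df.groupby("gene", as_index=False)["relevance_score"].max()
    return df[["gene", "relevance_score"]]


def filter_disease_genes(
    records: pd.DataFrame | Iterable[tuple[str, float]],
    score_min: float = 5.0,
    strict: bool = True,
) -> frozenset[str]:
    """Genes whose relevance score exceeds ``score_min``.

    ``strict=True`` keeps score > score_min (a score of exactly 5 is
    excluded under the default); ``strict=False`` keeps score >= score_min.
    """
    if isinstance(records, pd.DataFrame):
        pairs = records[["gene", "relevance_score"]].itertuples(index=False)
    else:
        pairs = records
    if strict:
        return frozenset(normalize_symbol(g) for g, s in pairs if s > score_min)
    return frozenset(normalize_symbol(g) for g, s in pairs if s >= score_min)


# ---------------------------------------------------------------------------
# Differential expression

@dataclass(frozen=True)
class DegResult:
    """Per-gene statistics and the significant gene set."""

    table: pd.DataFrame  # gene, log2fc, t, p, p_adj, degenerate
    significant: frozenset[str]
    alpha: float
    method: str
    use_adjusted: bool


def _squeeze_variances(s2: np.ndarray, df: float) -> tuple[np.ndarray, float, float]:
    """Empirical-Bayes shrinkage of gene variances (scaled inverse-chi-square prior).

    Moment estimation on log variances: with z = log s^2,
    E[z] = log(s0^2) + digamma(df/2) - log(df/2) + [digamma(d0/2) - log(d0/2)] terms,
    Var[z] = trigamma(df/2) + trigamma(d0/2).  d0 solves
    trigamma(d0/2) = var(e) - trigamma(df/2) by Newton on the inverse trigamma.
    Returns (posterior variances, d0, s0^2); d0 = inf collapses to s0^2.
    """
    ok = s2 > 0
    if ok.sum() < 2:
        return s2.copy(), 0.0, float(np.median(s2))
    z = np.log(s2[ok])
    e = z - special.digamma(df / 2.0) + np.log(df / 2.0)
    emean = float(e.mean())
    evar = float(e.var(ddof=1))
    target = evar - float(special.polygamma(1, df / 2.0))
    if target <= 0:
        # no excess dispersion over chi-square sampling noise: variances are
        # exchangeable and the prior dominates completely
        d0 = np.inf
        s02 = float(s2.mean())
        post = np.full_like(s2, s02)
        return post, d0, s02
    # invert trigamma by Newton (monotone decreasing, good start 1/target)
    x = 0.5 + 1.0 / target
    for _ in range(50):
        tri = float(special.polygamma(1, x))
        step = tri * (1.0 - tri / target) / float(special.polygamma(2, x))
        x += step
        if abs(step) < 1e-10 * x:
            break
    d0 = 2.0 * x
    s02 = float(np.exp(emean + special.digamma(x) - np.log(x)))
    post = (d0 * s02 + df * s2) / (d0 + df)
    return post, d0, s02


def call_degs(
    mat: ExpressionMatrix,
    alpha: float = 0.05,
    method: str = "welch_t",
    use_adjusted: bool = False,
    probe_map: Mapping[str, str] | None = None,
) -> DegResult:
    """Two-sided per-gene test of the group mean difference.

    ``log2fc`` is group2 minus group1 mean (groups in ``mat.group_order``).
    The significant set is {gene : p < alpha} on raw p by default, or on
    BH-adjusted p with ``use_adjusted=True``.  Genes with zero variance in
    both groups are flagged degenerate and assigned p = 1 rather than
    raising.  When ``probe_map`` maps row identifiers (probes) to gene
    symbols, the smallest-p row per gene is kept after testing.
    """
    if method not in ("welch_t", "moderated_t"):
        raise ValueError(f"unknown method {method!r}")
    x1, x2 = mat.split()
    n1, n2 = x1.shape[1], x2.shape[1]
    m1, m2 = x1.mean(axis=1), x2.mean(axis=1)
    v1, v2 = x1.var(axis=1, ddof=1), x2.var(axis=1, ddof=1)
    log2fc = m2 - m1
    degenerate = (v1 == 0) & (v2 == 0)

    if method == "welch_t":
        with np.errstate(divide="ignore", invalid="ignore"):
            se2 = v1 / n1 + v2 / n2
            t = (m2 - m1) / np.sqrt(se2)
            dfw = se2**2 / ((v1 / n1) ** 2 / (n1 - 1) + (v2 / n2) ** 2 / (n2 - 1))
        p = 2.0 * stats.t.sf(np.abs(t), dfw)
    else:
        dfp = n1 + n2 - 2
        s2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / dfp
        s2_post, d0, _ = _squeeze_variances(s2, dfp)
        u = np.sqrt(1.0 / n1 + 1.0 / n2)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (m2 - m1) / (u * np.sqrt(s2_post))
        df_tot = dfp + d0
        if np.isinf(df_tot):
            p = 2.0 * stats.norm.sf(np.abs(t))
        else:
            p = 2.0 * stats.t.sf(np.abs(t), df_tot)

    t = np.where(degenerate, 0.0, t)
    p = np.where(degenerate, 1.0, p)
    p = np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)

    table = pd.DataFrame(
        {
            "gene": [normalize_symbol(g) for g in mat.genes],
            "log2fc": log2fc,
            "t": t,
            "p": p,
            "degenerate": degenerate,
        }
    )
    if probe_map is not None:
        table["gene"] = [
            normalize_symbol(probe_map.get(g, g)) for g in mat.genes
        ]
        before = len(table)
        table = (
            table.sort_values(["gene", "p"]).drop_duplicates("gene", keep="first")
        )
        if len(table) < before:
            logger.info("call_degs: collapsed %d probe rows onto genes (min p kept)", before - len(table))
    table["p_adj"] = multipletests(table["p"].to_numpy(), method="fdr_bh")[1]
    table = table.sort_values(
        ["p", "log2fc", "gene"],
        ascending=[True, False, True],
        key=lambda s: s.abs() if s.name == "log2fc" else s,
    ).reset_index(drop=True)
    crit = table["p_adj"] if use_adjusted else table["p"]
    significant = frozenset(table.loc[crit < alpha, "gene"])
    return DegResult(
        table=table[["gene", "log2fc", "t", "p", "p_adj", "degenerate"]],
        significant=significant,
        alpha=alpha,
        method=method,
        use_adjusted=use_adjusted,
    )


# ---------------------------------------------------------------------------
# Three-set (Venn) intersection

_REGION_KEYS = ("A", "B", "C", "AB", "AC", "BC", "ABC")


@dataclass(frozen=True)
class VennResult:
    """All seven exclusive regions of a 3-set Venn diagram.

    Region keys name the sets an element belongs to and *only* those:
    ``"A"`` is A-only, ``"AB"`` is (A ∩ B) \\ C, ``"ABC"`` the triple
    intersection — the candidate-target list.
    """

    A: frozenset[str]
    B: frozenset[str]
    C: frozenset[str]
    regions: Mapping[str, frozenset[str]] = field(default_factory=dict)

    @property
    def triple(self) -> frozenset[str]:
        return self.regions["ABC"]

    def region_sizes(self) -> dict[str, int]:
        return {k: len(self.regions[k]) for k in _REGION_KEYS}

    def union_size(self) -> int:
        return sum(len(v) for v in self.regions.values())


def intersect_three(
    A: Iterable[str], B: Iterable[str], C: Iterable[str]
) -> VennResult:
    """Exclusive-region decomposition of three gene sets.

    Symbols are normalized (uppercased, stripped) so sets from different
    sources agree on identity.
    """
    sa = frozenset(normalize_symbol(g) for g in A)
    sb = frozenset(normalize_symbol(g) for g in B)
    sc = frozenset(normalize_symbol(g) for g in C)
    regions = {
        "A": sa - sb - sc,
        "B": sb - sa - sc,
        "C": sc - sa - sb,
        "AB": (sa & sb) - sc,
        "AC": (sa & sc) - sb,
        "BC": (sb & sc) - sa,
        "ABC": sa & sb & sc,
    }
    return VennResult(A=sa, B=sb, C=sc, regions=regions)
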