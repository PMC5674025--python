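"""Hypergeometric over-representation analysis with BH-FDR.

For a query gene list drawn from a background of N annotated genes, a
term with M member genes in the background, and m query hits in the
term, the enrichment P-value is the upper tail of the hypergeometric
distribution,

    P = P(X >= m) = 1 - sum_{i=0}^{m-1} C(M, i) C(N-M, n-i) / C(N, n),

i.e. the probability of at least the observed overlap when n query genes
are drawn without replacement.  P-values are corrected across all tested
terms by Benjamini-Hochberg, with significance at FDR <= 0.05 (inclusive).

Two backgrounds are supported for the same query — the full annotated
universe and a focused subset (here, the disease ∩ DEG intersection) —
and a consistency table records where each term is significant.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, FormatError, ValidationError
from .network import normalize_symbol

logger = logging.getLogger(__name__)

RESULT_COLUMNS = ["term_id", "term_name", "N", "n", "M", "m", "p", "fdr", "significant", "background_mode"]


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets (GMT-style): term_id -> unique member symbols."""

    sets: Mapping[str, frozenset[str]]
    descriptions: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for term, members in self.sets.items():
            if not members:
                raise ValidationError(f"term {term!r} has no members")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)

    @property
    def universe(self) -> frozenset[str]:
        """Union of all member genes — the annotated universe."""
        out: set[str] = set()
        for members in self.sets.values():
            out |= members
        return frozenset(out)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a tab-separated GMT file (term, description, members...)."""
    sets: dict[str, frozenset[str]] = {}
    desc: dict[str, str] = {}
    for ln_no, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise FormatError(f"{Path(path).name} line {ln_no}: GMT needs >= 3 fields")
        term, description, *members = parts
        if term in sets:
            raise ValidationError(f"duplicate term_id {term!r} at line {ln_no}")
        sets[term] = frozenset(normalize_symbol(g) for g in members if g.strip())
        desc[term] = description
    return GeneSetCollection(sets=sets, descriptions=desc)


def write_gmt(collection: GeneSetCollection, path: str | Path) -> Path:
    path = Path(path)
    lines = []
    for term in sorted(collection.sets):
        members = "\t".join(sorted(collection.sets[term]))
        lines.append(f"{term}\t{collection.descriptions.get(term, '')}\t{members}")
    path.write_text("\n".join(lines) + "\n")
    return path


def hypergeom_upper_tail(N: int, n: int, M: int, m: int) -> float:
    """P(X >= m) for X ~ Hypergeometric(N population, M successes, n draws).

    Computed via the survival function (numerically stable log-space
    evaluation); m = 0 returns exactly 1 (the empty sum).
    """
    for name, v in (("N", N), ("n", n), ("M", M), ("m", m)):
        if int(v) != v or v < 0:
            raise DomainError(f"{name} must be a non-negative integer, got {v!r}")
    if M > N:
        raise DomainError(f"M <= N violated (M={M}, N={N})")
    if n > N:
        raise DomainError(f"n <= N violated (n={n}, N={N})")
    if m > min(n, M):
        raise DomainError(f"m <= min(n, M) violated (m={m}, n={n}, M={M})")
    if m == 0:
        return 1.0
    return float(stats.hypergeom.sf(m - 1, N, M, n))


def enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    background: Iterable[str],
    fdr_threshold: float = 0.05,
    min_term_size: int = 3,
    include_zero_overlap: bool = False,
    background_mode: str = "all_genes",
) -> pd.DataFrame:
    """Over-representation of ``query`` against every term of ``collection``.

    The universe is background ∩ annotated genes (genes appearing in at
    least one term); query genes outside it are dropped with a logged
    count.  Terms are tested when their in-universe size M >=
    ``min_term_size`` and (by default) at least one query gene hits them.
    BH runs across all tested terms; ``significant`` means fdr <=
    ``fdr_threshold``.  Rows are sorted by p (ties by term_id).
    """
    bg = frozenset(normalize_symbol(g) for g in background)
    if not bg:
        raise ValidationError("empty background")
    universe = bg & collection.universe
    if not universe:
        raise ValidationError("background shares no gene with the collection")
    q_raw = frozenset(normalize_symbol(g) for g in query)
    q = q_raw & universe
    dropped = len(q_raw) - len(q)
    if dropped:
        logger.info("enrich: dropped %d query genes outside the annotated background", dropped)
    if not q:
        warnings.warn("enrich: query empty after background intersection", stacklevel=2)
        return pd.DataFrame(columns=RESULT_COLUMNS)

    N, n = len(universe), len(q)
    rows = []
    for term in sorted(collection.sets):
        members = collection.sets[term] & universe
        M = len(members)
        m = len(q & members)
        if M < min_term_size:
            continue
        if m == 0 and not include_zero_overlap:
            continue
        rows.append(
            {
                "term_id": term,
                "term_name": collection.descriptions.get(term, ""),
                "N": N,
                "n": n,
                "M": M,
                "m": m,
                "p": hypergeom_upper_tail(N, n, M, m),
            }
        )
    if not rows:
        return pd.DataFrame(columns=RESULT_COLUMNS)
    df = pd.DataFrame(rows)
    df["fdr"] = multipletests(df["p"].to_numpy(), method="fdr_bh")[1]
    df["significant"] = df["fdr"] <= fdr_threshold
    df["background_mode"] = background_mode
    return df.sort_values(["p", "term_id"]).reset_index(drop=True)[RESULT_COLUMNS]


@dataclass(frozen=True)
class DualEnrichment:
    """Paired ORA runs under the full and focused backgrounds."""

    all_genes: pd.DataFrame
    intersection_ab: pd.DataFrame
    consistency: pd.DataFrame  # term_id, sig_all, sig_ab, status


def dual_background_enrich(
    query: Iterable[str],
    collection: GeneSetCollection,
    bg_all: Iterable[str],
    bg_ab: Iterable[str],
    fdr_threshold: float = 0.05,
    min_term_size: int = 3,
    include_zero_overlap: bool = False,
) -> DualEnrichment:
    """Run :func:`enrich` under both backgrounds and cross-tabulate.

    ``bg_ab`` must be a subset of ``bg_all``.  The consistency table
    flags each term significant-in-both / all_only / ab_only / neither;
    no ordering between the two runs' p-values is asserted or implied.
    """
    bga = frozenset(normalize_symbol(g) for g in bg_all)
    bgb = frozenset(normalize_symbol(g) for g in bg_ab)
    if not bgb <= bga:
        raise ValidationError("focused background is not a subset of the full background")
    res_a = enrich(
        query, collection, bga, fdr_threshold, min_term_size,
        include_zero_overlap=include_zero_overlap, background_mode="all_genes",
    )
    res_b = enrich(
        query, collection, bgb, fdr_threshold, min_term_size,
        include_zero_overlap=include_zero_overlap, background_mode="intersection_AB",
    )
    sig_a = dict(zip(res_a["term_id"], res_a["significant"]))
    sig_b = dict(zip(res_b["term_id"], res_b["significant"]))
    terms = sorted(set(sig_a) | set(sig_b))
    rows = []
    for t in terms:
        a, b = bool(sig_a.get(t, False)), bool(sig_b.get(t, False))
        status = {
            (True, True): "both",
            (True, False): "all_only",
            (False, True): "ab_only",
            (False, False): "neither",
        }[(a, b)]
        rows.append({"term_id": t, "sig_all": a, "sig_ab": b, "status": status})
    consistency = pd.DataFrame(rows, columns=["term_id", "sig_all", "sig_ab", "status"])
    return DualEnrichment(all_genes=res_a, intersection_ab=res_b, consistency=consistency)
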