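"""Seeded generators for every input the pipeline consumes.

Each generator is a pure function of its parameters and a seed, and
returns the generated artifact together with a *truth* record stating
exactly what was planted (which rows pass screening, which targets are
shared by how many herbs, which genes are differentially expressed,
which term is enriched, which genes form the three-way overlap), so
every stage of the pipeline can be tested for exact recovery without
any external download.

A master seed fans out to independent per-generator streams through
``numpy`` SeedSequence spawn keys, so changing one generator's draws
never perturbs another's.  Gene symbols are synthetic (``G000001`` ...)
to make accidental dependence on real annotations impossible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .degs import filter_disease_genes
from .enrichment import GeneSetCollection, write_gmt
from .errors import DomainError
from .expression import ExpressionMatrix
from .ingredients import IngredientRecord
from .network import write_target_map

#: Fixed spawn keys: one independent random stream per generator.
_STREAMS = {
    "herbs": 1,
    "targets": 2,
    "expression": 3,
    "genesets": 4,
    "disease": 5,
    "study": 6,
}


def stream_rng(seed: int, stream: str) -> np.random.Generator:
    """Independent generator for one named sub-stream of a master seed."""
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(_STREAMS[stream],)))


def gene_symbols(n: int, prefix: str = "G") -> list[str]:
    return [f"{prefix}{i:06d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# Herb-ingredient property tables

@dataclass(frozen=True)
class HerbTableTruth:
    retained: frozenset[tuple[str, str]]  # (herb_id, ingredient_id) passing
    params: Mapping[str, object] = field(default_factory=dict)


def gen_herb_table(
    n_herbs: int = 10,
    n_ingredients_per_herb: int = 10,
    frac_passing: float = 0.5,
    seed: int = 0,
    exempt_herbs: Sequence[str] = (),
    per_herb_counts: Sequence[int] | None = None,
    ensure_herb_retained: bool = False,
) -> tuple[list[IngredientRecord], HerbTableTruth]:
    """Ingredient table with OB/DL values straddling the screening thresholds.

    Each row passes with probability ``frac_passing``; passing rows draw
    OB ~ U(30, 100) and DL ~ U(0.18, 1), failing rows miss at least one
    criterion (OB ~ U(0, 30) and/or DL ~ U(0, 0.18)), so the expected
    retained fraction equals ``frac_passing`` exactly.  Rows of exempt
    herbs are always retained.  ``per_herb_counts`` overrides the uniform
    ingredients-per-herb count; ``ensure_herb_retained`` redraws one row
    per herb as passing if a herb would otherwise retain nothing.
    """
    if n_herbs < 1:
        raise DomainError("n_herbs must be >= 1")
    if not 0.0 <= frac_passing <= 1.0:
        raise DomainError("frac_passing must be in [0, 1]")
    counts = list(per_herb_counts) if per_herb_counts is not None else [n_ingredients_per_herb] * n_herbs
    if len(counts) != n_herbs:
        raise DomainError("per_herb_counts length must equal n_herbs")
    rng = stream_rng(seed, "herbs")
    exempt = frozenset(exempt_herbs)
    records: list[IngredientRecord] = []
    retained: set[tuple[str, str]] = set()
    for h in range(n_herbs):
        herb = f"H{h + 1:02d}"
        herb_rows: list[int] = []
        for j in range(counts[h]):
            ing = f"{herb}_C{j + 1:03d}"
            passes = bool(rng.random() < frac_passing)
            ob, dl = _draw_properties(rng, passes)
            rec = IngredientRecord(herb, ing, ing, ob, dl, exempt=herb in exempt)
            herb_rows.append(len(records))
            records.append(rec)
            if passes or rec.exempt:
                retained.add((herb, ing))
        if ensure_herb_retained and not any(
            (records[i].herb_id, records[i].ingredient_id) in retained for i in herb_rows
        ):
            i = herb_rows[0]
            ob, dl = _draw_properties(rng, True)
            rec = records[i]
            records[i] = IngredientRecord(rec.herb_id, rec.ingredient_id, rec.ingredient_name, ob, dl, rec.exempt)
            retained.add((rec.herb_id, rec.ingredient_id))
    truth = HerbTableTruth(
        retained=frozenset(retained),
        params={
            "n_herbs": n_herbs,
            "counts": counts,
            "frac_passing": frac_passing,
            "exempt_herbs": sorted(exempt),
            "seed": seed,
        },
    )
    return records, truth


def _draw_properties(rng: np.random.Generator, passes: bool) -> tuple[float, float]:
    if passes:
        return float(rng.uniform(30.0, 100.0)), float(rng.uniform(0.18, 1.0))
    mode = rng.integers(3)  # which criterion fails: OB, DL, or both
    ob = float(rng.uniform(0.0, 30.0)) if mode in (0, 2) else float(rng.uniform(30.0, 100.0))
    dl = float(rng.uniform(0.0, 0.18)) if mode in (1, 2) else float(rng.uniform(0.18, 1.0))
    return ob, dl


# ---------------------------------------------------------------------------
# Ingredient -> target maps with a planted sharing histogram

@dataclass(frozen=True)
class TargetMapTruth:
    herb_targets: Mapping[str, frozenset[str]]
    expected_histogram: Mapping[int, int]
    target_universe: frozenset[str]
    params: Mapping[str, object] = field(default_factory=dict)


def gen_target_map(
    retained: Sequence[IngredientRecord],
    universe_size: int,
    sharing_profile: Mapping[int, int],
    seed: int = 0,
    symbols: Sequence[str] | None = None,
) -> tuple[dict[str, frozenset[str]], TargetMapTruth]:
    """Target map whose herb-target projection has a planted histogram.

    For every (herb-count k, target-count c) in ``sharing_profile``,
    exactly c targets are wired to exactly k distinct herbs (one random
    retained ingredient per herb), so the exact-mode shared-target
    histogram reproduces the profile bin-for-bin.  Leftover universe
    targets get herb-degree 1; a profile that itself plants bin 1 is
    accepted only when its counts sum to ``universe_size``.
    """
    herbs = sorted({r.herb_id for r in retained})
    if not herbs:
        raise DomainError("no retained ingredients to attach targets to")
    by_herb: dict[str, list[str]] = {h: [] for h in herbs}
    for r in retained:
        by_herb[r.herb_id].append(r.ingredient_id)
    planted_total = sum(sharing_profile.values())
    if planted_total > universe_size:
        raise DomainError("sharing profile plants more targets than the universe holds")
    for k in sharing_profile:
        if not 1 <= k <= len(herbs):
            raise DomainError(f"profile requests herb-count {k} but only {len(herbs)} herbs exist")
    if 1 in sharing_profile and planted_total != universe_size:
        raise DomainError(
            "a profile planting bin 1 must cover the whole universe "
            "(leftover targets also get herb-degree 1)"
        )
    syms = list(symbols) if symbols is not None else gene_symbols(universe_size, "T")
    if len(syms) != universe_size:
        raise DomainError("symbols length must equal universe_size")

    rng = stream_rng(seed, "targets")
    tmap: dict[str, set[str]] = {}
    herb_targets: dict[str, set[str]] = {h: set() for h in herbs}
    cursor = 0
    for k in sorted(sharing_profile, reverse=True):
        for _ in range(sharing_profile[k]):
            sym = syms[cursor]
            cursor += 1
            chosen = rng.choice(len(herbs), size=k, replace=False)
            for hi in chosen:
                herb = herbs[hi]
                ing = by_herb[herb][int(rng.integers(len(by_herb[herb])))]
                tmap.setdefault(ing, set()).add(sym)
                herb_targets[herb].add(sym)
    for sym in syms[cursor:]:
        herb = herbs[int(rng.integers(len(herbs)))]
        ing = by_herb[herb][int(rng.integers(len(by_herb[herb])))]
        tmap.setdefault(ing, set()).add(sym)
        herb_targets[herb].add(sym)

    # every retained ingredient must reach >= 1 target; re-using a target the
    # herb already owns leaves every herb-degree (and the histogram) unchanged
    for herb in herbs:
        pool = sorted(herb_targets[herb])
        for ing in by_herb[herb]:
            if ing not in tmap:
                if not pool:
                    raise DomainError(
                        f"herb {herb!r} received no targets; enlarge the universe or profile"
                    )
                tmap[ing] = {pool[int(rng.integers(len(pool)))]}

    expected = dict(sharing_profile)
    remainder = universe_size - planted_total
    if remainder:
        expected[1] = expected.get(1, 0) + remainder
    truth = TargetMapTruth(
        herb_targets={h: frozenset(t) for h, t in herb_targets.items()},
        expected_histogram={k: expected[k] for k in sorted(expected)},
        target_universe=frozenset(syms),
        params={"universe_size": universe_size, "sharing_profile": dict(sharing_profile), "seed": seed},
    )
    return {i: frozenset(t) for i, t in tmap.items()}, truth


# ---------------------------------------------------------------------------
# Two-group expression with planted differential expression

@dataclass(frozen=True)
class ExpressionTruth:
    de_effects: Mapping[str, float]  # gene -> signed shift in group-2 means
    params: Mapping[str, object] = field(default_factory=dict)

    @property
    def de_genes(self) -> frozenset[str]:
        return frozenset(self.de_effects)


def gen_expression(
    n_genes: int = 2000,
    n_per_group: int = 10,
    n_de: int = 100,
    effect_sd_units: float = 2.0,
    seed: int = 0,
    symbols: Sequence[str] | None = None,
    de_genes: Sequence[str] | None = None,
    de_directions: Mapping[str, int] | None = None,
    group_labels: tuple[str, str] = ("normal", "tumor"),
) -> tuple[ExpressionMatrix, ExpressionTruth]:
    """Two-group log2 matrix with planted mean shifts.

    Baseline values are N(8, 1) i.i.d. (within-group SD 1), so a planted
    gene's group-2 mean is shifted by ``effect_sd_units`` within-group
    standard deviations.  Directions default to a random +/-1 per gene.
    """
    if n_per_group < 3:
        raise DomainError("n_per_group must be >= 3")
    if de_genes is None and n_de > n_genes:
        raise DomainError("n_de cannot exceed n_genes")
    rng = stream_rng(seed, "expression")
    syms = list(symbols) if symbols is not None else gene_symbols(n_genes)
    if len(syms) != n_genes:
        raise DomainError("symbols length must equal n_genes")
    if de_genes is None:
        idx = rng.choice(n_genes, size=n_de, replace=False)
        de_genes = [syms[i] for i in sorted(idx)]
    missing = set(de_genes) - set(syms)
    if missing:
        raise DomainError(f"planted DE genes not in the gene universe: {sorted(missing)[:5]}")

    g1, g2 = group_labels
    cols = [f"{g1}_{i + 1}" for i in range(n_per_group)] + [f"{g2}_{i + 1}" for i in range(n_per_group)]
    values = rng.normal(8.0, 1.0, size=(n_genes, 2 * n_per_group))
    pos = {g: i for i, g in enumerate(syms)}
    effects: dict[str, float] = {}
    for g in de_genes:
        direction = int(de_directions[g]) if de_directions is not None else int(rng.choice([-1, 1]))
        shift = effect_sd_units * 1.0 * direction
        values[pos[g], n_per_group:] += shift
        effects[g] = shift
    mat = ExpressionMatrix(
        values=pd.DataFrame(values, index=syms, columns=cols),
        groups=pd.Series([g1] * n_per_group + [g2] * n_per_group, index=cols),
        group_order=group_labels,
    )
    truth = ExpressionTruth(
        de_effects=effects,
        params={
            "n_genes": n_genes,
            "n_per_group": n_per_group,
            "effect_sd_units": effect_sd_units,
            "seed": seed,
        },
    )
    return mat, truth


# ---------------------------------------------------------------------------
# Gene-set collections with one planted term

@dataclass(frozen=True)
class GeneSetTruth:
    planted_term_id: str | None
    planted_members: frozenset[str]
    params: Mapping[str, object] = field(default_factory=dict)


def gen_gene_sets(
    universe: Sequence[str],
    n_terms: int = 50,
    term_size_range: tuple[int, int] = (10, 50),
    planted_term_members: Sequence[str] | None = None,
    seed: int = 0,
    planted_term_id: str = "SET_PLANTED",
    exclude_from_random: Sequence[str] = (),
) -> tuple[GeneSetCollection, GeneSetTruth]:
    """Random gene sets sampled from the universe plus one planted term.

    ``exclude_from_random`` removes genes from the random terms' sampling
    pool (the planted term is unaffected).  When the excluded genes are
    the ones carrying planted signal, the planted term is the *unique*
    truly-enriched set — the property the truth record asserts.
    """
    lo, hi = term_size_range
    pool = [g for g in universe if g not in set(exclude_from_random)]
    if not 1 <= lo <= hi <= len(pool):
        raise DomainError("term sizes infeasible for the random-member pool")
    rng = stream_rng(seed, "genesets")
    sets: dict[str, frozenset[str]] = {}
    desc: dict[str, str] = {}
    for i in range(n_terms):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(len(pool), size=size, replace=False)
        term = f"SET{i + 1:04d}"
        sets[term] = frozenset(pool[j] for j in members)
        desc[term] = f"random set {i + 1}"
    planted = frozenset()
    if planted_term_members is not None:
        planted = frozenset(planted_term_members)
        missing = planted - set(universe)
        if missing:
            raise DomainError(f"planted members outside the universe: {sorted(missing)[:5]}")
        sets[planted_term_id] = planted
        desc[planted_term_id] = "planted enriched term"
    truth = GeneSetTruth(
        planted_term_id=planted_term_id if planted_term_members is not None else None,
        planted_members=planted,
        params={"n_terms": n_terms, "term_size_range": term_size_range, "seed": seed},
    )
    return GeneSetCollection(sets=sets, descriptions=desc), truth


# ---------------------------------------------------------------------------
# Full study bundle

@dataclass(frozen=True)
class SyntheticTruth:
    """Everything planted into a full-study bundle."""

    retained: frozenset[tuple[str, str]]
    herb_targets: Mapping[str, frozenset[str]]
    expected_histogram: Mapping[int, int]
    de_effects: Mapping[str, float]
    overlap: frozenset[str]  # planted disease ∩ DEG ∩ target set
    disease_genes: frozenset[str]  # genes passing the score filter
    planted_term_id: str
    planted_members: frozenset[str]
    params: Mapping[str, object] = field(default_factory=dict)
    seed: int = 0


@dataclass(frozen=True)
class StudyBundle:
    """All pipeline inputs for one synthetic study."""

    herb_table: list[IngredientRecord]
    target_map: Mapping[str, frozenset[str]]
    disease: pd.DataFrame  # gene, relevance_score
    expression: ExpressionMatrix
    gene_sets: GeneSetCollection
    truth: SyntheticTruth


def gen_full_study(
    seed: int = 0,
    n_herbs: int = 10,
    n_ingredients_per_herb: int = 12,
    frac_passing: float = 0.6,
    target_universe_size: int = 400,
    sharing_profile: Mapping[int, int] | None = None,
    overlap_size: int = 81,
    n_genes: int = 2000,
    n_per_group: int = 10,
    effect_sd_units: float = 5.0,
    n_extra_de: int = 100,
    n_disease_extra: int = 300,
    n_disease_low: int = 200,
    n_terms: int = 30,
    term_size_range: tuple[int, int] = (20, 60),
) -> StudyBundle:
    """A miniature end-to-end study with a planted candidate-gene overlap.

    Construction guarantees the pipeline's triple intersection: the
    disease genes passing the score filter meet the network-target
    universe exactly in the planted overlap set, whose genes carry
    strong (default 5 within-group SD) expression shifts in group 2, so
    screening → network → DEG calling → intersection recovers the
    overlap exactly.  The planted gene-set term equals the overlap set,
    making it the expected winner of both over-representation runs and
    of GSEA.
    """
    if sharing_profile is None:
        sharing_profile = {9: 2, 8: 9, 7: 23, 6: 30, 5: 65, 4: 69}
    if overlap_size > target_universe_size:
        raise DomainError("overlap cannot exceed the target universe")
    rng = stream_rng(seed, "study")
    universe = gene_symbols(n_genes)

    records, herb_truth = gen_herb_table(
        n_herbs=n_herbs,
        n_ingredients_per_herb=n_ingredients_per_herb,
        frac_passing=frac_passing,
        seed=seed,
        ensure_herb_retained=True,
    )
    retained = [r for r in records if (r.herb_id, r.ingredient_id) in herb_truth.retained]

    target_syms = [universe[i] for i in sorted(rng.choice(n_genes, size=target_universe_size, replace=False))]
    tmap, tmap_truth = gen_target_map(
        retained, target_universe_size, sharing_profile, seed=seed, symbols=target_syms
    )
    target_set = set(target_syms)

    overlap = sorted(rng.choice(target_syms, size=overlap_size, replace=False))
    non_targets = [g for g in universe if g not in target_set]
    extra_idx = rng.choice(len(non_targets), size=n_disease_extra + n_disease_low, replace=False)
    extra_high = [non_targets[i] for i in extra_idx[:n_disease_extra]]
    low = [non_targets[i] for i in extra_idx[n_disease_extra:]]
    drng = stream_rng(seed, "disease")
    disease = pd.DataFrame(
        {
            "gene": overlap + extra_high + low,
            "relevance_score": np.concatenate(
                [
                    5.0 + drng.exponential(20.0, size=len(overlap) + len(extra_high)),
                    drng.uniform(0.0, 5.0, size=len(low)),
                ]
            ),
        }
    ).sample(frac=1.0, random_state=int(drng.integers(2**31))).reset_index(drop=True)
    disease_high = filter_disease_genes(disease, score_min=5.0, strict=True)

    de_pool = [g for g in non_targets if g not in disease_high]
    extra_de = [de_pool[i] for i in sorted(rng.choice(len(de_pool), size=n_extra_de, replace=False))]
    de_genes = overlap + extra_de
    de_directions = {g: 1 for g in overlap}
    de_directions.update({g: int(d) for g, d in zip(extra_de, rng.choice([-1, 1], size=len(extra_de)))})
    expression, expr_truth = gen_expression(
        n_genes=n_genes,
        n_per_group=n_per_group,
        n_de=len(de_genes),
        effect_sd_units=effect_sd_units,
        seed=seed,
        symbols=universe,
        de_genes=de_genes,
        de_directions=de_directions,
    )

    # random terms avoid all DE genes so the planted term is the unique
    # truly-enriched set, as the truth record asserts
    gene_sets, gs_truth = gen_gene_sets(
        universe,
        n_terms=n_terms,
        term_size_range=term_size_range,
        planted_term_members=overlap,
        seed=seed,
        exclude_from_random=de_genes,
    )

    truth = SyntheticTruth(
        retained=herb_truth.retained,
        herb_targets=tmap_truth.herb_targets,
        expected_histogram=tmap_truth.expected_histogram,
        de_effects=expr_truth.de_effects,
        overlap=frozenset(overlap),
        disease_genes=disease_high,
        planted_term_id=gs_truth.planted_term_id or "SET_PLANTED",
        planted_members=gs_truth.planted_members,
        params={
            "n_herbs": n_herbs,
            "n_ingredients_per_herb": n_ingredients_per_herb,
            "frac_passing": frac_passing,
            "target_universe_size": target_universe_size,
            "sharing_profile": dict(sharing_profile),
            "overlap_size": overlap_size,
            "n_genes": n_genes,
            "n_per_group": n_per_group,
            "effect_sd_units": effect_sd_units,
        },
        seed=seed,
    )
    return StudyBundle(
        herb_table=records,
        target_map=tmap,
        disease=disease,
        expression=expression,
        gene_sets=gene_sets,
        truth=truth,
    )


def write_bundle(bundle: StudyBundle, outdir: str | Path) -> Path:
    """Write a study bundle to a directory in the pipeline's native formats."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(
        [
            {
                "herb_id": r.herb_id,
                "ingredient_id": r.ingredient_id,
                "ingredient_name": r.ingredient_name,
                "ob": r.ob,
                "dl": r.dl,
            }
            for r in bundle.herb_table
        ]
    ).to_csv(outdir / "herb_table.tsv", sep="\t", index=False)
    write_target_map(bundle.target_map, outdir / "target_map.tsv")
    bundle.disease.to_csv(outdir / "disease_genes.tsv", sep="\t", index=False)
    bundle.expression.to_tsv(outdir / "expression.tsv")
    bundle.expression.to_cls(outdir / "groups.cls")
    write_gmt(bundle.gene_sets, outdir / "gene_sets.gmt")
    truth = asdict(bundle.truth)
    truth["retained"] = sorted(list(t) for t in bundle.truth.retained)
    truth["herb_targets"] = {h: sorted(s) for h, s in bundle.truth.herb_targets.items()}
    truth["overlap"] = sorted(bundle.truth.overlap)
    truth["disease_genes"] = sorted(bundle.truth.disease_genes)
    truth["planted_members"] = sorted(bundle.truth.planted_members)
    truth["de_effects"] = dict(bundle.truth.de_effects)
    truth["expected_histogram"] = {str(k): v for k, v in bundle.truth.expected_histogram.items()}
    (outdir / "truth.json").write_text(json.dumps(truth, indent=2, sort_keys=True))
    return outdir
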