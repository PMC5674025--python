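"""Herb-ingredient-target tripartite networks.

The network links each herb to its retained chemical ingredients and each
ingredient to its predicted protein/gene targets.  Projecting out the
ingredient layer gives per-herb target sets; a target's *herb-degree* is
the number of distinct herbs whose ingredients reach it, the basis of the
shared-target histogram.

The graph is stored as plain typed adjacency sets; networkx is used only
for GraphML interchange.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import FormatError, ValidationError
from .ingredients import IngredientRecord

logger = logging.getLogger(__name__)


def normalize_symbol(sym: str) -> str:
    """Uppercase and strip a gene symbol; reject embedded whitespace."""
    s = str(sym).strip().upper()
    if not s or any(c.isspace() for c in s):
        raise ValidationError(f"invalid gene symbol {sym!r}")
    return s


def normalize_target_map(tmap: Mapping[str, set[str] | Sequence[str]]) -> dict[str, frozenset[str]]:
    """Validate an ingredient->targets map: symbols normalized, sets non-empty."""
    out: dict[str, frozenset[str]] = {}
    for ing, targets in tmap.items():
        syms = frozenset(normalize_symbol(t) for t in targets)
        if not syms:
            raise ValidationError(f"ingredient {ing!r} has an empty target set")
        out[str(ing)] = syms
    return out


@dataclass(frozen=True)
class TripartiteNetwork:
    """Typed herb/ingredient/target graph with layer-respecting edges."""

    herbs: frozenset[str]
    ingredients: frozenset[str]
    targets: frozenset[str]
    herb_ingredient: frozenset[tuple[str, str]]
    ingredient_target: frozenset[tuple[str, str]]

    def __post_init__(self) -> None:
        for h, i in self.herb_ingredient:
            if h not in self.herbs or i not in self.ingredients:
                raise ValidationError(f"dangling herb-ingredient edge ({h!r}, {i!r})")
        for i, t in self.ingredient_target:
            if i not in self.ingredients or t not in self.targets:
                raise ValidationError(f"dangling ingredient-target edge ({i!r}, {t!r})")
        linked = {i for _, i in self.herb_ingredient} | {i for i, _ in self.ingredient_target}
        isolated = self.ingredients - linked
        if isolated:
            raise ValidationError(f"isolated ingredient nodes: {sorted(isolated)[:5]}")

    @property
    def n_nodes(self) -> int:
        return len(self.herbs) + len(self.ingredients) + len(self.targets)

    @property
    def n_edges(self) -> int:
        return len(self.herb_ingredient) + len(self.ingredient_target)


@dataclass(frozen=True)
class HerbTargetProjection:
    """Per-herb target sets and per-target herb-degrees."""

    herb_targets: Mapping[str, frozenset[str]]
    target_herb_degree: Mapping[str, int]

    @property
    def target_universe(self) -> frozenset[str]:
        return frozenset(self.target_herb_degree)


@dataclass(frozen=True)
class NetworkSummary:
    n_ingredients: int
    n_targets: int
    per_herb: Mapping[str, tuple[int, int]] = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        rows = [
            {"herb_id": h, "n_ingredients": a, "n_targets": b}
            for h, (a, b) in sorted(self.per_herb.items())
        ]
        rows.append(
            {
                "herb_id": "TOTAL(unique)",
                "n_ingredients": self.n_ingredients,
                "n_targets": self.n_targets,
            }
        )
        return pd.DataFrame(rows)


def build_network(
    retained: Sequence[IngredientRecord],
    tmap: Mapping[str, set[str] | Sequence[str]],
) -> TripartiteNetwork:
    """Assemble the tripartite network from screened ingredients and a target map.

    Ingredients with no entry in ``tmap`` are dropped with a logged count;
    an empty ``retained`` list is an error ("nothing to build").
    """
    if not retained:
        raise ValidationError("nothing to build: empty retained ingredient list")
    tmap_n = normalize_target_map(tmap)

    herbs: set[str] = set()
    ingredients: set[str] = set()
    targets: set[str] = set()
    hi_edges: set[tuple[str, str]] = set()
    it_edges: set[tuple[str, str]] = set()
    dropped = 0
    for rec in retained:
        tset = tmap_n.get(rec.ingredient_id)
        if tset is None:
            dropped += 1
            continue
        herbs.add(rec.herb_id)
        ingredients.add(rec.ingredient_id)
        hi_edges.add((rec.herb_id, rec.ingredient_id))
        for t in tset:
            targets.add(t)
            it_edges.add((rec.ingredient_id, t))
    if dropped:
        logger.warning("build_network: %d retained ingredient rows had no target map entry", dropped)
    if not ingredients:
        raise ValidationError("nothing to build: no retained ingredient has targets")
    return TripartiteNetwork(
        herbs=frozenset(herbs),
        ingredients=frozenset(ingredients),
        targets=frozenset(targets),
        herb_ingredient=frozenset(hi_edges),
        ingredient_target=frozenset(it_edges),
    )


def project_herb_targets(net: TripartiteNetwork) -> HerbTargetProjection:
    """Project out the ingredient layer: herb -> set of reachable targets."""
    ing_targets: dict[str, set[str]] = {}
    for i, t in net.ingredient_target:
        ing_targets.setdefault(i, set()).add(t)
    herb_targets: dict[str, frozenset[str]] = {}
    for h in net.herbs:
        tset: set[str] = set()
        for hh, i in net.herb_ingredient:
            if hh == h:
                tset |= ing_targets.get(i, set())
        herb_targets[h] = frozenset(tset)
    degree: Counter[str] = Counter()
    for tset in herb_targets.values():
        degree.update(tset)
    return HerbTargetProjection(herb_targets=herb_targets, target_herb_degree=dict(degree))


def count_summary(net: TripartiteNetwork) -> NetworkSummary:
    """Unique ingredient/target totals plus per-herb counts.

    Per-herb counts are distinct entities reachable from that herb;
    totals deduplicate across herbs, so entities shared by several herbs
    are counted once network-wide.
    """
    proj = project_herb_targets(net)
    herb_ings: dict[str, set[str]] = {h: set() for h in net.herbs}
    for h, i in net.herb_ingredient:
        herb_ings[h].add(i)
    per_herb = {
        h: (len(herb_ings[h]), len(proj.herb_targets[h])) for h in net.herbs
    }
    return NetworkSummary(
        n_ingredients=len(net.ingredients),
        n_targets=len(net.targets),
        per_herb=per_herb,
    )


def common_target_histogram(
    proj: HerbTargetProjection, mode: str = "exact"
) -> dict[int, int]:
    """Herb-count -> number of targets hit by that many herbs.

    In ``exact`` mode bin n counts targets with herb-degree exactly n and
    the bins sum to the size of the target universe; ``at_least`` gives
    the cumulative tail.
    """
    if mode not in ("exact", "at_least"):
        raise ValueError(f"mode must be 'exact' or 'at_least', got {mode!r}")
    exact: Counter[int] = Counter(proj.target_herb_degree.values())
    if mode == "exact":
        return dict(sorted(exact.items()))
    out: dict[int, int] = {}
    for k in sorted(exact):
        out[k] = sum(v for kk, v in exact.items() if kk >= k)
    return out


# ---------------------------------------------------------------------------
# Cytoscape-compatible export

_SIF_RELATIONS = {"herb_ingredient": "contains", "ingredient_target": "targets"}


def _sorted_edges(net: TripartiteNetwork) -> list[tuple[str, str, str]]:
    edges = [("contains", h, i) for h, i in net.herb_ingredient]
    edges += [("targets", i, t) for i, t in net.ingredient_target]
    # lexicographic on (source, relation, target) keeps files diff-stable
    return sorted((s, rel, t) for rel, s, t in edges)


def export_network(net: TripartiteNetwork, fmt: str, path: str | Path) -> Path:
    """Write the network as SIF, GraphML or edge-list TSV.

    SIF relation labels are ``contains`` (herb->ingredient) and
    ``targets`` (ingredient->target); GraphML carries a ``node_type``
    attribute; the TSV round-trips through :func:`read_edge_tsv`.
    """
    path = Path(path)
    if fmt == "sif":
        lines = [f"{s}\t{rel}\t{t}" for s, rel, t in _sorted_edges(net)]
        path.write_text("\n".join(lines) + ("\n" if lines else ""))
    elif fmt == "tsv":
        lines = ["source\trelation\ttarget"]
        lines += [f"{s}\t{rel}\t{t}" for s, rel, t in _sorted_edges(net)]
        path.write_text("\n".join(lines) + "\n")
    elif fmt == "graphml":
        import networkx as nx

        g = nx.DiGraph()
        for h in sorted(net.herbs):
            g.add_node(h, node_type="herb")
        for i in sorted(net.ingredients):
            g.add_node(i, node_type="ingredient")
        for t in sorted(net.targets):
            g.add_node(t, node_type="target")
        for s, rel, t in _sorted_edges(net):
            g.add_edge(s, t, relation=rel)
        nx.write_graphml(g, path)
    else:
        raise FormatError(f"unknown export format {fmt!r}; expected sif|graphml|tsv")
    return path


def write_target_map(tmap: Mapping[str, set[str] | Sequence[str]], path: str | Path) -> Path:
    """Write an ingredient->target map as a two-column TSV."""
    path = Path(path)
    lines = ["ingredient_id\ttarget"]
    for ing in sorted(tmap):
        for t in sorted(tmap[ing]):
            lines.append(f"{ing}\t{t}")
    path.write_text("\n".join(lines) + "\n")
    return path


def read_target_map(path: str | Path) -> dict[str, frozenset[str]]:
    """Read a two-column (ingredient_id, target) TSV into a target map."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    cols = [c.strip().lower() for c in df.columns]
    if cols[:2] != ["ingredient_id", "target"]:
        raise FormatError(f"{Path(path).name}: expected columns ingredient_id/target")
    raw: dict[str, set[str]] = {}
    for ing, t in df.itertuples(index=False):
        raw.setdefault(str(ing), set()).add(str(t))
    return normalize_target_map(raw)


def read_edge_tsv(path: str | Path) -> TripartiteNetwork:
    """Rebuild a network from the edge-list TSV written by :func:`export_network`."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != ["source", "relation", "target"]:
        raise FormatError(f"{Path(path).name}: expected columns source/relation/target")
    herbs: set[str] = set()
    ingredients: set[str] = set()
    targets: set[str] = set()
    hi: set[tuple[str, str]] = set()
    it: set[tuple[str, str]] = set()
    for s, rel, t in df.itertuples(index=False):
        if rel == "contains":
            herbs.add(s)
            ingredients.add(t)
            hi.add((s, t))
        elif rel == "targets":
            ingredients.add(s)
            targets.add(t)
            it.add((s, t))
        else:
            raise FormatError(f"unknown relation {rel!r}")
    return TripartiteNetwork(
        herbs=frozenset(herbs),
        ingredients=frozenset(ingredients),
        targets=frozenset(targets),
        herb_ingredient=frozenset(hi),
        ingredient_target=frozenset(it),
    )
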