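"""ADME screening of herb ingredients.

Ingredient tables carry two TCMSP-style properties per compound: oral
bioavailability (OB, percent scale: 30 means 30%) and drug-likeness
(DL, unitless in [0, 1]).  An ingredient is retained when it meets both
thresholds, OB >= ob_min and DL >= dl_min (inclusive), unless its herb is
on the exemption list — used for mineral/animal-derived herbs whose
constituents are inorganic and score low on DL by construction, so the
drug-likeness heuristic does not apply to them.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .errors import FormatError, ValidationError

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("herb_id", "ingredient_id", "ingredient_name", "ob", "dl")

#: Column-name aliases accepted on input (case-insensitive).
_ALIASES = {
    "herb": "herb_id",
    "herb_id": "herb_id",
    "ingredient": "ingredient_id",
    "ingredient_id": "ingredient_id",
    "ingredient_name": "ingredient_name",
    "name": "ingredient_name",
    "ob": "ob",
    "dl": "dl",
}


@dataclass(frozen=True)
class IngredientRecord:
    """One herb-ingredient row with its screening properties."""

    herb_id: str
    ingredient_id: str
    ingredient_name: str
    ob: float  # oral bioavailability, percent, >= 0
    dl: float  # drug-likeness, unitless in [0, 1]
    exempt: bool = False

    def __post_init__(self) -> None:
        if self.ob < 0:
            raise ValidationError(
                f"ingredient {self.ingredient_id!r}: OB must be >= 0, got {self.ob}"
            )
        if not 0.0 <= self.dl <= 1.0:
            raise ValidationError(
                f"ingredient {self.ingredient_id!r}: DL must be in [0, 1], got {self.dl}"
            )


@dataclass(frozen=True)
class ScreenConfig:
    """Retention thresholds and the herb exemption list.

    Defaults follow the TCMSP screening convention: OB >= 30 (percent)
    and DL >= 0.18, with the oyster-shell herb ML exempt from both.
    """

    ob_min: float = 30.0
    dl_min: float = 0.18
    exempt_herbs: frozenset[str] = field(default_factory=lambda: frozenset({"ML"}))

    def __post_init__(self) -> None:
        if self.ob_min < 0 or self.dl_min < 0:
            raise ValidationError("thresholds must be non-negative")
        object.__setattr__(self, "exempt_herbs", frozenset(self.exempt_herbs))


def load_ingredient_table(
    path: str | Path,
    dialect: str | None = None,
    config: ScreenConfig | None = None,
) -> list[IngredientRecord]:
    """Read a TSV/CSV ingredient table into validated records.

    The header must contain herb, ingredient, ob and dl columns
    (case-insensitive; ``herb``/``herb_id`` etc. are accepted).  Malformed
    numeric cells and invariant violations are reported with their
    1-based data row number.  Duplicate (herb_id, ingredient_id) pairs are
    rejected — provenance tables are expected to be clean.

    If ``config`` is given, exemption flags are set from its
    ``exempt_herbs`` at load time.
    """
    path = Path(path)
    if dialect is None:
        dialect = "csv" if path.suffix.lower() == ".csv" else "tsv"
    if dialect not in ("tsv", "csv"):
        raise FormatError(f"unknown dialect {dialect!r}; expected 'tsv' or 'csv'")
    sep = "\t" if dialect == "tsv" else ","
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)

    rename = {}
    for col in df.columns:
        key = col.strip().lower()
        if key in _ALIASES:
            rename[col] = _ALIASES[key]
    df = df.rename(columns=rename)
    missing = {"herb_id", "ingredient_id", "ob", "dl"} - set(df.columns)
    if missing:
        raise FormatError(
            f"{path.name}: missing required column(s): {', '.join(sorted(missing))}"
        )
    if "ingredient_name" not in df.columns:
        df["ingredient_name"] = df["ingredient_id"]

    exempt_herbs = config.exempt_herbs if config is not None else frozenset()
    records: list[IngredientRecord] = []
    seen: set[tuple[str, str]] = set()
    for i, row in enumerate(df.itertuples(index=False), start=1):
        herb = str(getattr(row, "herb_id")).strip()
        ing = str(getattr(row, "ingredient_id")).strip()
        try:
            ob = float(getattr(row, "ob"))
            dl = float(getattr(row, "dl"))
        except (TypeError, ValueError) as exc:
            raise ValidationError(
                f"{path.name} row {i}: malformed numeric cell "
                f"(ob={getattr(row, 'ob')!r}, dl={getattr(row, 'dl')!r})"
            ) from exc
        key = (herb, ing)
        if key in seen:
            raise ValidationError(
                f"{path.name} row {i}: duplicate (herb_id, ingredient_id) pair {key!r}"
            )
        seen.add(key)
        try:
            rec = IngredientRecord(
                herb_id=herb,
                ingredient_id=ing,
                ingredient_name=str(getattr(row, "ingredient_name")),
                ob=ob,
                dl=dl,
                exempt=herb in exempt_herbs,
            )
        except ValidationError as exc:
            raise ValidationError(f"{path.name} row {i}: {exc}") from exc
        records.append(rec)
    return records


def apply_exemptions(
    records: Iterable[IngredientRecord], cfg: ScreenConfig
) -> list[IngredientRecord]:
    """Return records with ``exempt`` set from ``cfg.exempt_herbs``."""
    return [replace(r, exempt=r.herb_id in cfg.exempt_herbs) for r in records]


def screen_ingredients(
    records: Sequence[IngredientRecord], cfg: ScreenConfig | None = None
) -> list[IngredientRecord]:
    """Apply the OB/DL retention rule.

    A record is retained iff (ob >= ob_min and dl >= dl_min) or it is
    exempt.  Input order is preserved.  An empty input yields an empty
    output with a warning rather than an error.
    """
    cfg = cfg or ScreenConfig()
    if not records:
        warnings.warn("screen_ingredients: empty input", stacklevel=2)
        return []
    return [
        r
        for r in records
        if r.exempt or (r.ob >= cfg.ob_min and r.dl >= cfg.dl_min)
    ]


def screening_report(
    records: Sequence[IngredientRecord], cfg: ScreenConfig | None = None
) -> pd.DataFrame:
    """Per-herb retained/dropped counts for the screening step."""
    cfg = cfg or ScreenConfig()
    retained_keys = {
        (r.herb_id, r.ingredient_id) for r in screen_ingredients(records, cfg)
    }
    rows: dict[str, dict[str, int]] = {}
    for r in records:
        d = rows.setdefault(r.herb_id, {"retained": 0, "dropped": 0})
        if (r.herb_id, r.ingredient_id) in retained_keys:
            d["retained"] += 1
        else:
            d["dropped"] += 1
    report = (
        pd.DataFrame.from_dict(rows, orient="index")
        .rename_axis("herb_id")
        .sort_index()
        .reset_index()
    )
    if report.empty:
        report = pd.DataFrame(columns=["herb_id", "retained", "dropped"])
    report["total"] = report.get("retained", 0) + report.get("dropped", 0)
    return report
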