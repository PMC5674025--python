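"""Two-group log2 expression matrices with GSEA-style TSV/CLS IO."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import FormatError, ValidationError


@dataclass(frozen=True)
class ExpressionMatrix:
    """Genes x samples matrix of finite log2 values plus a two-group labelling.

    ``values`` is indexed by gene identifier (rows) and sample name
    (columns); ``groups`` maps each sample to one of exactly two labels,
    each with at least two samples.  ``group_order`` fixes which label is
    "group 1" for signed statistics (defaults to first appearance).
    """

    values: pd.DataFrame
    groups: pd.Series
    group_order: tuple[str, str] = ()

    def __post_init__(self) -> None:
        v, g = self.values, self.groups
        if not v.index.is_unique:
            raise ValidationError("duplicate gene identifiers in expression matrix")
        if v.index.isna().any() or (v.index.astype(str).str.len() == 0).any():
            raise ValidationError("missing gene identifiers")
        if not np.isfinite(v.to_numpy(dtype=float)).all():
            raise ValidationError("expression values must be finite")
        if set(g.index) != set(v.columns):
            raise ValidationError("group labels do not match sample names")
        labels = list(dict.fromkeys(g[c] for c in v.columns))
        if len(labels) != 2:
            raise ValidationError(f"exactly two groups required, got {labels}")
        counts = g.value_counts()
        if (counts < 2).any():
            raise ValidationError("each group needs >= 2 samples")
        order = self.group_order or tuple(labels)
        if set(order) != set(labels):
            raise ValidationError("group_order does not match group labels")
        object.__setattr__(self, "group_order", tuple(order))

    @property
    def genes(self) -> list[str]:
        return list(self.values.index)

    def split(self) -> tuple[np.ndarray, np.ndarray]:
        """Value arrays of (group1, group2) in ``group_order``."""
        a, b = self.group_order
        cols_a = [c for c in self.values.columns if self.groups[c] == a]
        cols_b = [c for c in self.values.columns if self.groups[c] == b]
        return (
            self.values[cols_a].to_numpy(dtype=float),
            self.values[cols_b].to_numpy(dtype=float),
        )

    # -- IO -----------------------------------------------------------------

    def to_tsv(self, path: str | Path) -> None:
        self.values.rename_axis("gene").to_csv(path, sep="\t")

    def to_cls(self, path: str | Path) -> None:
        """Write sample labels in the GSEA CLS phenotype format."""
        a, b = self.group_order
        labels = [self.groups[c] for c in self.values.columns]
        lines = [
            f"{len(labels)} 2 1",
            f"# {a} {b}",
            " ".join(labels),
        ]
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_tsv(cls, matrix_path: str | Path, cls_path: str | Path) -> "ExpressionMatrix":
        df = pd.read_csv(matrix_path, sep="\t", index_col=0)
        order, labels = read_cls(cls_path)
        if len(labels) != df.shape[1]:
            raise FormatError(
                f"CLS lists {len(labels)} samples but matrix has {df.shape[1]} columns"
            )
        groups = pd.Series(labels, index=df.columns)
        return cls(values=df, groups=groups, group_order=order)


def read_cls(path: str | Path) -> tuple[tuple[str, str], list[str]]:
    """Parse a CLS phenotype file; returns (group order, per-sample labels)."""
    lines = [ln.strip() for ln in Path(path).read_text().splitlines() if ln.strip()]
    if len(lines) < 3 or not lines[1].startswith("#"):
        raise FormatError(f"{Path(path).name}: not a CLS file")
    names = lines[1].lstrip("#").split()
    if len(names) != 2:
        raise FormatError("CLS must declare exactly two classes")
    raw = lines[2].split()
    # CLS permits either class names or 0/1 indices on the label line
    labels = [names[int(tok)] if tok in ("0", "1") else tok for tok in raw]
    return (names[0], names[1]), labels
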