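"""Shared in-memory containers for expression, regulons, and results.

The package passes gene-by-sample matrices around as a light wrapper over a
pandas DataFrame carrying a normalization tag (``raw_counts``, ``log2cpm``,
``zscaled`` or ``activity``) and a species label. Differential-expression
results and merged cross-species tables are plain DataFrames with documented
column contracts (see :mod:`carsx.diffexpr` and :mod:`carsx.xspecies`).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np
import pandas as pd

NORMALIZATIONS = ("raw_counts", "log2cpm", "zscaled", "activity")


@dataclass
class ExpressionMatrix:
    """Gene x sample expression values with provenance tags.

    Parameters
    ----------
    values : DataFrame
        Rows are genes, columns are samples. Index and columns must be unique.
    normalization : str
        One of ``raw_counts``, ``log2cpm``, ``zscaled``, ``activity``.
    species : str
        Free-text species label (e.g. ``"human"``, ``"mouse"``).
    """

    values: pd.DataFrame
    normalization: str = "log2cpm"
    species: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.values, pd.DataFrame):
            self.values = pd.DataFrame(self.values)
        if self.normalization not in NORMALIZATIONS:
            raise ValueError(
                f"normalization must be one of {NORMALIZATIONS}, "
                f"got {self.normalization!r}"
            )
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise ValueError(f"duplicate gene IDs: {dups[:5]}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise ValueError(f"duplicate sample IDs: {dups[:5]}")
        if self.normalization != "raw_counts":
            arr = self.values.to_numpy(dtype=float)
            if not np.isfinite(arr).all():
                raise ValueError("non-finite values in normalized expression matrix")

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def samples(self) -> pd.Index:
        return self.values.columns

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def subset_genes(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        missing = [g for g in genes if g not in self.values.index]
        if missing:
            raise KeyError(f"genes not present in matrix: {missing}")
        return ExpressionMatrix(self.values.loc[genes], self.normalization, self.species)


@dataclass
class Regulon:
    """A driver gene and its signed, MI-weighted target set."""

    driver: str
    targets: pd.DataFrame = field(default_factory=lambda: pd.DataFrame(
        columns=["target", "mi", "sign"]))

    def __post_init__(self) -> None:
        t = pd.DataFrame(self.targets)
        if len(t):
            if (t["target"] == self.driver).any():
                raise ValueError(f"regulon of {self.driver} contains the driver itself")
            if t["target"].duplicated().any():
                raise ValueError(f"duplicate targets in regulon of {self.driver}")
            if (t["mi"] < 0).any():
                raise ValueError("MI weights must be nonnegative")
            if not t["sign"].isin([-1, 1]).all():
                raise ValueError("target signs must be -1 or +1")
        self.targets = t.reset_index(drop=True)

    @property
    def positive_targets(self) -> list[str]:
        return self.targets.loc[self.targets["sign"] > 0, "target"].tolist()

    @property
    def negative_targets(self) -> list[str]:
        return self.targets.loc[self.targets["sign"] < 0, "target"].tolist()

    def __len__(self) -> int:
        return len(self.targets)


@dataclass
class Interactome:
    """A set of regulons plus the inference parameters that produced them."""

    regulons: dict[str, Regulon]
    params: dict = field(default_factory=dict)

    @property
    def n_nodes(self) -> int:
        nodes = set(self.regulons)
        for r in self.regulons.values():
            nodes.update(r.targets["target"])
        return len(nodes)

    @property
    def n_edges(self) -> int:
        return sum(len(r) for r in self.regulons.values())

    def to_frame(self) -> pd.DataFrame:
        """Edge table with columns source/target/mi/spearman/sign/support."""
        rows = []
        for driver, reg in self.regulons.items():
            for _, row in reg.targets.iterrows():
                rows.append({
                    "source": driver,
                    "target": row["target"],
                    "mi": row["mi"],
                    "spearman": row.get("spearman", np.nan),
                    "sign": int(row["sign"]),
                    "support": int(row.get("support", 0)),
                })
        return pd.DataFrame(rows, columns=["source", "target", "mi", "spearman",
                                           "sign", "support"])

    @classmethod
    def from_frame(cls, edges: pd.DataFrame, params: dict | None = None) -> "Interactome":
        regs = {}
        for driver, grp in edges.groupby("source", sort=True):
            t = grp.rename(columns={})[["target", "mi", "sign"]].copy()
            if "spearman" in grp:
                t["spearman"] = grp["spearman"].to_numpy()
            if "support" in grp:
                t["support"] = grp["support"].to_numpy()
            regs[str(driver)] = Regulon(str(driver), t)
        return cls(regs, params or {})


@dataclass
class GeneSet:
    """A named gene set, optionally sign-partitioned (regulon-style)."""

    name: str
    members: list[str]
    description: str = ""

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError(f"gene set {self.name!r} is empty")
        seen, uniq = set(), []
        for m in self.members:
            if m not in seen:
                seen.add(m)
                uniq.append(m)
        self.members = uniq

    def __len__(self) -> int:
        return len(self.members)
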