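"""Domain types and on-disk formats shared by all pipeline stages.

The pipeline works on a gene x sample matrix of linear-scale normalized
intensities paired with a sample design table (group in {control, uv},
week in {1, 2, 4, 6, 8}, replicate), plus gene sets in GMT and plain-text
gene lists.  Gene identifiers are opaque, case-sensitive strings: no
symbol/alias resolution is ever attempted.

Loaders validate rather than repair — a missing value, a negative
intensity or an unknown sample id is an error naming the offending row,
never something to impute silently.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

VALID_WEEKS: tuple[int, ...] = (1, 2, 4, 6, 8)
VALID_GROUPS: tuple[str, ...] = ("control", "uv")


class FormatError(ValueError):
    """Raised when an on-disk file or in-memory object violates a contract."""


# ---------------------------------------------------------------------------
# sample design
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SampleDesign:
    """Sample annotation: group, exposure week and replicate per sample.

    Invariants checked at construction: unique sample ids, weeks restricted
    to the study grid {1, 2, 4, 6, 8}, at least two replicates per present
    (group, week) cell (needed for variance estimation), and the presence
    of the week-1 control reference group.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "group", "week", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise FormatError(f"design table missing columns: {sorted(missing)}")
        t = self.table
        if t["sample_id"].duplicated().any():
            dup = t.loc[t["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise FormatError(f"duplicate sample id in design: {dup!r}")
        bad_group = ~t["group"].isin(VALID_GROUPS)
        if bad_group.any():
            row = t[bad_group].iloc[0]
            raise FormatError(
                f"sample {row['sample_id']!r}: unknown group {row['group']!r}"
            )
        bad_week = ~t["week"].isin(VALID_WEEKS)
        if bad_week.any():
            row = t[bad_week].iloc[0]
            raise FormatError(
                f"sample {row['sample_id']!r}: week {row['week']!r} not in {VALID_WEEKS}"
            )
        if (t["replicate"] < 1).any():
            row = t[t["replicate"] < 1].iloc[0]
            raise FormatError(f"sample {row['sample_id']!r}: replicate must be >= 1")
        sizes = t.groupby(["group", "week"]).size()
        small = sizes[sizes < 2]
        if not small.empty:
            g, w = small.index[0]
            raise FormatError(
                f"group ({g}, week {w}) has {small.iloc[0]} replicate(s); need >= 2"
            )
        if ("control", 1) not in sizes.index:
            raise FormatError("design must contain control samples at week 1")
        object.__setattr__(self, "table", t.reset_index(drop=True))

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples(self, group: str, week: int | None = None) -> list[str]:
        """Sample ids for a (group[, week]) cell, in design order."""
        mask = self.table["group"] == group
        if week is not None:
            mask &= self.table["week"] == week
        return list(self.table.loc[mask, "sample_id"])

    def uv_weeks(self) -> list[int]:
        return sorted(self.table.loc[self.table["group"] == "uv", "week"].unique())

    def has_control_week8(self) -> bool:
        return bool(self.samples("control", 8))


# ---------------------------------------------------------------------------
# expression matrix
# ---------------------------------------------------------------------------


@dataclass
class ExpressionMatrix:
    """Genes x samples matrix of non-negative linear-scale intensities.

    ``data`` is indexed by gene id with one column per sample id; the bound
    ``design`` lists exactly the same samples.
    """

    data: pd.DataFrame
    design: SampleDesign

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise FormatError(f"duplicate gene id: {dup!r}")
        extra = set(self.data.columns) - set(self.design.sample_ids)
        if extra:
            raise FormatError(f"sample not in design: {sorted(extra)[0]!r}")
        absent = set(self.design.sample_ids) - set(self.data.columns)
        if absent:
            raise FormatError(f"sample not in matrix: {sorted(absent)[0]!r}")
        if self.data.isna().any().any():
            gene = self.data.index[self.data.isna().any(axis=1)][0]
            raise FormatError(f"missing value for gene {gene!r}; no imputation is done")
        vals = self.data.to_numpy()
        if (vals < 0).any():
            gi, si = np.argwhere(vals < 0)[0]
            raise FormatError(
                f"negative intensity for gene {self.data.index[gi]!r} "
                f"in sample {self.data.columns[si]!r}"
            )
        # canonical column order = design order
        self.data = self.data[self.design.sample_ids]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    def subset(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = list(genes)
        return ExpressionMatrix(self.data.loc[genes].copy(), self.design)

    def group_mean(self, group: str, week: int) -> pd.Series:
        cols = self.design.samples(group, week)
        if not cols:
            raise FormatError(f"no samples for ({group}, week {week})")
        return self.data[cols].mean(axis=1)


# ---------------------------------------------------------------------------
# gene sets
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise FormatError(f"gene set {self.name!r} is empty")
        # collapse duplicates, keep first-seen order
        seen: dict[str, None] = dict.fromkeys(self.members)
        object.__setattr__(self, "members", tuple(seen))


@dataclass(frozen=True)
class GeneSetCollection:
    sets: tuple[GeneSet, ...]

    def __post_init__(self) -> None:
        names = [s.name for s in self.sets]
        dup = {n for n in names if names.count(n) > 1}
        if dup:
            raise FormatError(f"duplicate gene-set name: {sorted(dup)[0]!r}")

    def __iter__(self):
        return iter(self.sets)

    def __len__(self) -> int:
        return len(self.sets)

    def __getitem__(self, name: str) -> GeneSet:
        for s in self.sets:
            if s.name == name:
                return s
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.sets]


# ---------------------------------------------------------------------------
# readers / writers
# ---------------------------------------------------------------------------


def read_design(path: str | Path) -> SampleDesign:
    t = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "group": str})
    return SampleDesign(t)


def read_expression(path: str | Path, design_path: str | Path) -> ExpressionMatrix:
    """Load an expression TSV (first column gene ids, header = sample ids)
    together with its design table; the two are validated against each other."""
    design = read_design(design_path)
    data = pd.read_csv(path, sep="\t", index_col=0)
    data.index = data.index.astype(str)
    return ExpressionMatrix(data, design)


def write_expression(matrix: ExpressionMatrix, path: str | Path,
                     design_path: str | Path | None = None) -> None:
    df = matrix.data.copy()
    df.index.name = "gene_id"
    df.to_csv(path, sep="\t")
    if design_path is not None:
        matrix.design.table.to_csv(design_path, sep="\t", index=False)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: name TAB description TAB member TAB member..."""
    sets: list[GeneSet] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line has <3 fields")
            sets.append(GeneSet(fields[0], fields[1], tuple(fields[2:])))
    return GeneSetCollection(tuple(sets))


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


def read_gene_list(path: str | Path) -> list[str]:
    """Plain-text gene list, one id per line; blank lines skipped."""
    with open(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def write_gene_list(genes: Sequence[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for g in genes:
            fh.write(f"{g}\n")


def write_ranked_list(ranking: pd.DataFrame, path: str | Path) -> None:
    """Persist a ranked gene list (columns gene_id, score, rank) as TSV."""
    ranking.to_csv(path, sep="\t", index=False)


def read_ranked_list(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    return df


def write_edge_list(network, tau: float, sif_path: str | Path,
                    tsv_path: str | Path | None = None,
                    absolute: bool = False) -> int:
    """Export the edges of the adjacency at threshold ``tau``.

    SIF dialect: one line per undirected edge ``geneA co geneB``, each
    unordered pair written once, lexicographically smaller id first.  The
    optional TSV variant carries the Pearson r as a third column (with a
    header line).  Returns the number of edges written.
    """
    if not (0 < tau < 1):
        raise ValueError("tau must be in (0, 1)")
    adj = network.binarize(tau, absolute=absolute)
    ids = network.gene_ids
    iu, ju = np.triu_indices(len(ids), k=1)
    mask = adj[iu, ju]
    pairs = []
    for i, j in zip(iu[mask], ju[mask]):
        a, b = ids[i], ids[j]
        if b < a:
            a, b = b, a
        pairs.append((a, b, network.weights[i, j]))
    pairs.sort()
    with open(sif_path, "w") as fh:
        for a, b, _ in pairs:
            fh.write(f"{a} co {b}\n")
    if tsv_path is not None:
        with open(tsv_path, "w") as fh:
            fh.write("gene_a\tgene_b\tr\n")
            for a, b, r in pairs:
                fh.write(f"{a}\t{b}\t{r!r}\n")
    return len(pairs)


def write_network(network, path: str | Path) -> None:
    """Persist a weighted network as a flat TSV: header of gene ids, then one
    row per gene i holding the lower triangle r(i, 0..i-1), full precision."""
    with open(path, "w") as fh:
        fh.write("\t".join(network.gene_ids) + "\n")
        for i in range(len(network.gene_ids)):
            row = network.weights[i, :i]
            fh.write("\t".join(repr(float(v)) for v in row) + "\n")


def read_network(path: str | Path):
    from .coexpression import WeightedNetwork

    with open(path) as fh:
        ids = fh.readline().rstrip("\n").split("\t")
        m = len(ids)
        W = np.eye(m)
        for i in range(m):
            line = fh.readline().rstrip("\n")
            vals = [float(v) for v in line.split("\t")] if line else []
            if len(vals) != i:
                raise FormatError(f"network row {i} has {len(vals)} values, expected {i}")
            W[i, :i] = vals
            W[:i, i] = vals
    return WeightedNetwork(ids, W)
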