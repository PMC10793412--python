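"""Readers, writers and in-memory containers for the pipeline's formats.

Formats: GMT gene-set collections, bulk expression TSV (genes in rows,
first column ``gene``, samples in columns) with a sample-metadata TSV,
MatrixMarket or dense-TSV single-cell count matrices with gene/barcode/
label sidecar files, and a YAML configuration file of pipeline
thresholds.

Gene identifiers are treated as case-sensitive symbols throughout; no
alias or ID-mapping layer is provided.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import anndata as ad
import numpy as np
import pandas as pd
import scipy.io
import scipy.sparse
import yaml

__all__ = [
    "GeneSetCollection",
    "GlycogeneTable",
    "ExpressionMatrix",
    "read_gmt",
    "write_gmt",
    "read_expression",
    "write_expression",
    "read_single_cell",
    "write_single_cell",
    "load_config",
    "DEFAULT_CONFIG",
]

#: Pipeline-wide defaults (overridable through a YAML config file).
DEFAULT_CONFIG: dict = {
    "fdr": 0.05,
    "top_n": 30,
    "tom_percentile": 90.0,
    "n_perm": 999,
    "gsea_perm": 1000,
    "restart_prob": 0.7,
    "soft_power": 8.0,
    "seed": 0,
}


# ---------------------------------------------------------------------------
# Gene sets


@dataclass(frozen=True)
class GeneSet:
    """A named gene set with a free-text description."""

    name: str
    description: str
    members: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.members) == 0:
            raise ValueError(f"gene set {self.name!r} has no members")
        if len(set(self.members)) != len(self.members):
            raise ValueError(f"gene set {self.name!r} has duplicate members")

    def __len__(self) -> int:
        return len(self.members)

    def __contains__(self, gene: str) -> bool:
        return gene in set(self.members)


class GeneSetCollection:
    """An ordered collection of uniquely named gene sets (GMT-backed).

    Member order within a set is preserved from the source; preranked
    GSEA and the synthetic generators rely on deterministic ordering.
    """

    def __init__(self, sets: Iterable[GeneSet] = ()) -> None:
        self._sets: dict[str, GeneSet] = {}
        for s in sets:
            self.add(s)

    def add(self, gene_set: GeneSet) -> None:
        if gene_set.name in self._sets:
            raise ValueError(f"duplicate gene set name: {gene_set.name!r}")
        self._sets[gene_set.name] = gene_set

    @property
    def names(self) -> list[str]:
        return list(self._sets)

    def __len__(self) -> int:
        return len(self._sets)

    def __iter__(self):
        return iter(self._sets.values())

    def __contains__(self, name: str) -> bool:
        return name in self._sets

    def __getitem__(self, name: str) -> GeneSet:
        return self._sets[name]

    def members(self, name: str) -> tuple[str, ...]:
        return self._sets[name].members

    def subset(self, names: Sequence[str]) -> "GeneSetCollection":
        """A new collection restricted to ``names`` (order of ``names``)."""
        return GeneSetCollection(self._sets[n] for n in names)

    def all_genes(self) -> list[str]:
        """Union of members over all sets, first-occurrence order."""
        seen: dict[str, None] = {}
        for s in self:
            for g in s.members:
                seen.setdefault(g)
        return list(seen)

    def __repr__(self) -> str:  # pragma: no cover
        return f"GeneSetCollection({len(self)} sets)"


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Parse a GMT file: one set per line, ``name<TAB>description<TAB>genes...``.

    Duplicate members within a line are dropped, keeping the first
    occurrence. Lines with fewer than three tab-separated fields raise a
    parse error naming the line; duplicate set names raise.
    """
    collection = GeneSetCollection()
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n").rstrip("\r")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno}: expected >=3 tab-separated fields, "
                    f"got {len(fields)}"
                )
            name, description = fields[0], fields[1]
            members: dict[str, None] = {}
            for g in fields[2:]:
                if g:
                    members.setdefault(g)
            collection.add(GeneSet(name, description, tuple(members)))
    return collection


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.members]) + "\n")


# ---------------------------------------------------------------------------
# Glycogene annotation


@dataclass
class GlycogeneTable:
    """Annotation of glycogenes: glycosylation pathway and synthesis step.

    ``df`` columns: ``gene``, ``pathway``, ``step``, ``pathway_specific``.
    Gene symbols are unique and every row carries a non-empty pathway
    label (the 16 canonical glycosylation pathways in real data).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"gene", "pathway"}
        missing = required - set(self.df.columns)
        if missing:
            raise ValueError(f"glycogene table missing columns: {sorted(missing)}")
        if self.df["gene"].duplicated().any():
            dups = self.df["gene"][self.df["gene"].duplicated()].tolist()
            raise ValueError(f"duplicate glycogene symbols: {dups}")
        if (self.df["pathway"].astype(str).str.strip() == "").any():
            raise ValueError("empty glycosylation pathway label")

    @property
    def genes(self) -> list[str]:
        return self.df["gene"].tolist()

    def by_pathway(self) -> dict[str, list[str]]:
        """Glycogene lists grouped by glycosylation pathway label."""
        return {
            pw: sub["gene"].tolist()
            for pw, sub in self.df.groupby("pathway", sort=True)
        }

    @classmethod
    def read_tsv(cls, path: str | Path) -> "GlycogeneTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def write_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Bulk expression


@dataclass
class ExpressionMatrix:
    """Genes x samples expression values with per-sample metadata.

    ``values``: DataFrame indexed by gene symbol, columns are sample ids.
    ``samples``: DataFrame indexed by sample id with columns ``cohort``,
    ``region`` and ``condition`` (``case``/``control``). Values are
    assumed to be on a log scale for the meta-analysis stage.
    """

    values: pd.DataFrame
    samples: pd.DataFrame
    metadata_columns = ("cohort", "region", "condition")

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            dups = self.values.index[self.values.index.duplicated()].tolist()
            raise ValueError(f"duplicate gene ids: {dups[:5]}")
        if self.values.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        vals = self.values.to_numpy()
        if vals.size and not np.isfinite(vals.astype(float)).all():
            i, j = np.argwhere(~np.isfinite(vals.astype(float)))[0]
            raise ValueError(
                f"non-finite expression value at gene {self.values.index[i]!r}, "
                f"sample {self.values.columns[j]!r}"
            )
        missing = [c for c in self.metadata_columns if c not in self.samples.columns]
        if missing:
            raise ValueError(f"sample metadata missing columns: {missing}")
        absent = [s for s in self.values.columns if s not in self.samples.index]
        if absent:
            raise ValueError(f"samples absent from metadata: {absent}")
        # keep metadata aligned to the matrix column order
        self.samples = self.samples.loc[self.values.columns]

    @property
    def genes(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    def strata(self) -> list[tuple[str, str]]:
        """Distinct (cohort, region) pairs, in order of first appearance."""
        seen: dict[tuple[str, str], None] = {}
        for _, row in self.samples.iterrows():
            seen.setdefault((row["cohort"], row["region"]))
        return list(seen)

    def subset_stratum(self, cohort: str, region: str) -> "ExpressionMatrix":
        mask = (self.samples["cohort"] == cohort) & (self.samples["region"] == region)
        cols = self.samples.index[mask]
        return ExpressionMatrix(self.values[cols], self.samples.loc[cols].copy())

    def condition_arms(self) -> tuple[pd.Index, pd.Index]:
        """(case sample ids, control sample ids)."""
        case = self.samples.index[self.samples["condition"] == "case"]
        ctrl = self.samples.index[self.samples["condition"] == "control"]
        return case, ctrl


def read_expression(path: str | Path, metadata_path: str | Path) -> ExpressionMatrix:
    """Read a genes-in-rows expression TSV plus its sample-metadata TSV.

    The matrix TSV has a ``gene`` first column and one column per sample;
    the metadata TSV is keyed by a ``sample`` column. Non-numeric or
    missing cells and samples absent from the metadata are errors.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = np.argwhere(numeric.isna().to_numpy())
    if bad.size:
        i, j = bad[0]
        raise ValueError(
            f"{path}: non-numeric or missing value at gene {df.index[i]!r}, "
            f"sample {df.columns[j]!r}"
        )
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    if "sample" not in meta.columns:
        raise ValueError(f"{metadata_path}: metadata requires a 'sample' column")
    meta = meta.set_index("sample")
    return ExpressionMatrix(numeric.astype(float), meta)


def write_expression(
    expr: ExpressionMatrix, path: str | Path, metadata_path: str | Path
) -> None:
    out = expr.values.copy()
    out.index.name = "gene"
    out.to_csv(path, sep="\t")
    meta = expr.samples.copy()
    meta.index.name = "sample"
    meta.to_csv(metadata_path, sep="\t")


# ---------------------------------------------------------------------------
# Single cell

#: Single-cell data travel as :class:`anndata.AnnData`: ``X`` holds raw
#: counts (cells x genes), ``obs`` carries ``cell_type`` and ``condition``
#: labels, and normalization adds a ``lognorm`` layer.
SingleCellDataset = ad.AnnData


def read_single_cell(
    matrix_path: str | Path,
    genes_path: str | Path,
    barcodes_path: str | Path,
    labels_path: str | Path,
) -> SingleCellDataset:
    """Load a count matrix with gene/barcode lists and per-cell labels.

    ``matrix_path`` may be MatrixMarket (``.mtx``, genes in rows and
    cells in columns, 1-based per the standard) or a dense TSV laid out
    like the bulk format (genes in rows, barcodes as columns). The
    labels TSV is keyed by ``barcode`` and must provide ``cell_type``
    and ``condition`` for every barcode.
    """
    genes = pd.read_csv(genes_path, sep="\t", header=None)[0].astype(str).tolist()
    barcodes = pd.read_csv(barcodes_path, sep="\t", header=None)[0].astype(str).tolist()

    matrix_path = Path(matrix_path)
    if matrix_path.suffix == ".mtx":
        m = scipy.io.mmread(matrix_path)  # genes x cells
        counts = scipy.sparse.csr_matrix(m.T)
        n_cells, n_genes = counts.shape
    else:
        dense = pd.read_csv(matrix_path, sep="\t", index_col=0)
        counts = scipy.sparse.csr_matrix(dense.to_numpy().T)
        n_cells, n_genes = counts.shape
        if dense.index.tolist() != genes or dense.columns.tolist() != barcodes:
            raise ValueError(
                f"{matrix_path}: dense matrix gene/barcode headers disagree with "
                "the sidecar lists"
            )
    if n_genes != len(genes):
        raise ValueError(
            f"gene list length {len(genes)} != matrix gene dimension {n_genes}"
        )
    if n_cells != len(barcodes):
        raise ValueError(
            f"barcode list length {len(barcodes)} != matrix cell dimension {n_cells}"
        )

    data = counts.data
    if data.size and (data < 0).any():
        raise ValueError("negative counts in matrix")
    if data.size and np.any(data != np.round(data)):
        raise ValueError("fractional counts in matrix")

    labels = pd.read_csv(labels_path, sep="\t", dtype=str)
    for col in ("barcode", "cell_type", "condition"):
        if col not in labels.columns:
            raise ValueError(f"{labels_path}: labels require a {col!r} column")
    labels = labels.set_index("barcode")
    missing = [b for b in barcodes if b not in labels.index]
    if missing:
        raise ValueError(f"barcodes missing from labels: {missing[:5]}")

    obs = labels.loc[barcodes, ["cell_type", "condition"]].copy()
    obs.index.name = None
    adata = ad.AnnData(
        X=counts.astype(np.float64),
        obs=obs,
        var=pd.DataFrame(index=pd.Index(genes, name=None)),
    )
    return adata


def write_single_cell(adata: SingleCellDataset, out_dir: str | Path) -> None:
    """Write counts as ``matrix.mtx`` (genes x cells) plus sidecar TSVs."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    counts = scipy.sparse.coo_matrix(adata.X).T  # genes x cells
    scipy.io.mmwrite(str(out / "matrix.mtx"), counts)
    pd.Series(adata.var_names).to_csv(
        out / "genes.tsv", sep="\t", index=False, header=False
    )
    pd.Series(adata.obs_names).to_csv(
        out / "barcodes.tsv", sep="\t", index=False, header=False
    )
    labels = adata.obs[["cell_type", "condition"]].copy()
    labels.index.name = "barcode"
    labels.to_csv(out / "labels.tsv", sep="\t")


# ---------------------------------------------------------------------------
# Config


def load_config(path: str | Path | None = None) -> dict:
    """Pipeline thresholds: defaults overlaid with a YAML file if given."""
    config = dict(DEFAULT_CONFIG)
    if path is not None:
        with open(path) as fh:
            user = yaml.safe_load(fh) or {}
        unknown = set(user) - set(config)
        if unknown:
            warnings.warn(f"unknown config keys ignored: {sorted(unknown)}")
        config.update({k: v for k, v in user.items() if k in config})
    return config
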