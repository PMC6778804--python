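"""Readers and writers for on-disk artifacts.

Formats
-------
* counts: tab-separated text, first column ``gene``, one column per sample
  (non-negative expected counts; floats allowed — probabilistic quantifiers
  emit fractional expected counts).
* sample sheet: tab-separated with columns ``sample_id``, ``tissue``,
  ``timepoint``, ``replicate``.
* bootstraps: HDF5, one 2-D ``genes x B`` dataset per sample id, row order
  matching the counts file; gene ids stored once under ``genes``.
* gene sets: two-column tab-separated (term, gene), with an optional
  term-name sidecar (term, name[, namespace]).
* category table: tab-separated ``gene, cat_20SS, cat_52hpf, cat_72hpf, flow``.

All readers validate before constructing; invalid files raise ``ValueError``
and no partially-valid object escapes.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd

from .design import CONDITIONS, TIMEPOINTS, TISSUES


@dataclass
class SampleSheet:
    """Sample metadata: one row per (tissue, timepoint, replicate)."""

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"sample_id", "tissue", "timepoint", "replicate"}
        missing = required - set(self.table.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns {sorted(missing)}")
        t = self.table
        for _, row in t.iterrows():
            if row["tissue"] not in TISSUES:
                raise ValueError(f"unknown tissue {row['tissue']!r}")
            if row["timepoint"] not in TIMEPOINTS:
                raise ValueError(f"unknown timepoint {row['timepoint']!r}")
            if (row["tissue"], row["timepoint"]) not in CONDITIONS:
                raise ValueError(
                    f"invalid condition ({row['tissue']}, {row['timepoint']}): "
                    "periderm/basal/nonskin2 do not exist at 20SS"
                )
            if int(row["replicate"]) < 1:
                raise ValueError("replicate index must be a positive integer")
        if t["sample_id"].duplicated().any():
            dup = t["sample_id"][t["sample_id"].duplicated()].iloc[0]
            raise ValueError(f"duplicate sample id {dup!r}")
        key = t[["tissue", "timepoint", "replicate"]].apply(tuple, axis=1)
        if key.duplicated().any():
            raise ValueError("duplicate (tissue, timepoint, replicate) entry")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table["sample_id"])

    def samples_for(self, tissue: str, timepoint: str) -> list[str]:
        t = self.table
        sel = (t["tissue"] == tissue) & (t["timepoint"] == timepoint)
        return list(t.loc[sel, "sample_id"])

    def conditions(self) -> list[tuple[str, str]]:
        seen = []
        for _, row in self.table.iterrows():
            c = (row["tissue"], row["timepoint"])
            if c not in seen:
                seen.append(c)
        return seen


@dataclass
class CountMatrix:
    """Genes x samples matrix of non-negative expected counts."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.duplicated().any():
            dup = self.data.index[self.data.index.duplicated()][0]
            raise ValueError(f"duplicate gene id {dup!r}")
        values = self.data.to_numpy()
        if not np.issubdtype(values.dtype, np.number):
            raise ValueError("count matrix contains non-numeric values")
        if not np.isfinite(values).all():
            raise ValueError("count matrix contains non-finite values")
        if (values < 0).any():
            raise ValueError("count matrix contains negative values")

    @property
    def genes(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)


@dataclass
class BootstrapTensor:
    """Per-sample genes x B bootstrap count matrices (technical replicates)."""

    genes: list[str]
    matrices: dict[str, np.ndarray]

    def __post_init__(self) -> None:
        n_boot = None
        for sid, mat in self.matrices.items():
            if mat.ndim != 2 or mat.shape[0] != len(self.genes):
                raise ValueError(
                    f"bootstrap matrix for {sid!r} has {mat.shape[0]} rows, "
                    f"expected {len(self.genes)} genes"
                )
            if n_boot is None:
                n_boot = mat.shape[1]
            elif mat.shape[1] != n_boot:
                raise ValueError(
                    f"bootstrap count mismatch: {sid!r} has B={mat.shape[1]}, "
                    f"expected B={n_boot}"
                )
            if (mat < 0).any():
                raise ValueError(f"negative bootstrap counts for {sid!r}")
        if n_boot is not None and n_boot < 2:
            raise ValueError("need at least B=2 bootstraps")

    @property
    def n_bootstraps(self) -> int:
        return next(iter(self.matrices.values())).shape[1]

    @property
    def sample_ids(self) -> list[str]:
        return list(self.matrices)


@dataclass
class GeneSetTable:
    """Mapping term id -> member gene ids, with optional names/namespaces.

    ``propagated`` records whether memberships were pre-propagated to
    ancestor terms upstream; the enrichment code accepts either.
    """

    sets: dict[str, set[str]]
    names: dict[str, str] = field(default_factory=dict)
    namespaces: dict[str, str] = field(default_factory=dict)
    propagated: bool | None = None

    def validate_universe(self, universe: set[str]) -> None:
        for term, members in self.sets.items():
            extra = members - universe
            if extra:
                raise ValueError(
                    f"term {term!r} has members outside the universe, "
                    f"e.g. {sorted(extra)[0]!r}"
                )


# ---------------------------------------------------------------------------
# counts


def read_counts(path, tx2gene: dict[str, str] | None = None) -> CountMatrix:
    """Read a tab-separated count matrix.

    When ``tx2gene`` is given the file is treated as transcript-level and
    rows are aggregated to genes as arithmetic sums of their isoforms.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    for j, col in enumerate(df.columns):
        if not np.issubdtype(df[col].dtype, np.number):
            bad = df[col].apply(
                lambda v: not isinstance(v, (int, float, np.number))
                or isinstance(v, bool)
            )
            # locate first offending cell for the error message
            i = int(np.argmax(pd.to_numeric(df[col], errors="coerce").isna()))
            raise ValueError(
                f"non-numeric value in column {col!r}, row {df.index[i]!r}"
            )
    if df.index.duplicated().any():
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"duplicate gene id {dup!r} in {path}")
    if tx2gene is not None:
        missing = [t for t in df.index if t not in tx2gene]
        if missing:
            raise ValueError(f"transcript {missing[0]!r} missing from tx2gene map")
        df = df.groupby(df.index.map(tx2gene.get)).sum()
        df.index.name = "gene"
    return CountMatrix(df)


def write_counts(matrix: CountMatrix, path) -> None:
    df = matrix.data.copy()
    df.index.name = "gene"
    df.to_csv(path, sep="\t", float_format="%.10g")


# ---------------------------------------------------------------------------
# sample sheet


def read_sample_sheet(path) -> SampleSheet:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str})
    return SampleSheet(df)


def write_sample_sheet(sheet: SampleSheet, path) -> None:
    sheet.table.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# bootstraps (HDF5: one dataset per sample + a "genes" string dataset)


def write_bootstraps(tensor: BootstrapTensor, path) -> None:
    with h5py.File(path, "w") as h5:
        h5.create_dataset(
            "genes", data=np.array(tensor.genes, dtype=h5py.string_dtype())
        )
        grp = h5.create_group("samples")
        for sid, mat in tensor.matrices.items():
            grp.create_dataset(sid, data=mat, compression="gzip", compression_opts=1)


def read_bootstraps(path) -> BootstrapTensor:
    with h5py.File(path, "r") as h5:
        genes = [g.decode() if isinstance(g, bytes) else g for g in h5["genes"][:]]
        matrices = {sid: ds[:] for sid, ds in h5["samples"].items()}
    return BootstrapTensor(genes=genes, matrices=matrices)


# ---------------------------------------------------------------------------
# gene sets


def read_gene_sets(
    path, names_path=None, propagated: bool | None = None
) -> GeneSetTable:
    df = pd.read_csv(path, sep="\t", header=None, names=["term", "gene"], dtype=str)
    sets: dict[str, set[str]] = {}
    for term, sub in df.groupby("term"):
        sets[term] = set(sub["gene"])
    names: dict[str, str] = {}
    namespaces: dict[str, str] = {}
    if names_path is not None:
        nd = pd.read_csv(names_path, sep="\t", header=None, dtype=str)
        for _, row in nd.iterrows():
            names[row[0]] = row[1]
            if len(row) > 2 and isinstance(row[2], str):
                namespaces[row[0]] = row[2]
    return GeneSetTable(sets=sets, names=names, namespaces=namespaces,
                        propagated=propagated)


# ---------------------------------------------------------------------------
# category/flow tables

CATEGORY_COLUMNS = ["gene", "cat_20SS", "cat_52hpf", "cat_72hpf", "flow"]


def write_category_table(calls: pd.DataFrame, path) -> None:
    """Write per-gene category calls.

    ``calls`` is indexed by gene with columns ``cat_20SS``, ``cat_52hpf``,
    ``cat_72hpf`` and ``flow``.
    """
    out = calls.reset_index()
    out.columns = CATEGORY_COLUMNS
    out.to_csv(path, sep="\t", index=False)


def read_category_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns) != CATEGORY_COLUMNS:
        raise ValueError(f"category table must have columns {CATEGORY_COLUMNS}")
    df = df.set_index("gene")
    recomposed = df["cat_20SS"] + df["cat_52hpf"] + df["cat_72hpf"]
    if not (recomposed == df["flow"]).all():
        bad = df.index[recomposed != df["flow"]][0]
        raise ValueError(f"flow string inconsistent with categories for {bad!r}")
    return df


# ---------------------------------------------------------------------------
# cross-file referential integrity


def validate_dataset(
    counts: CountMatrix, boots: BootstrapTensor | None, sheet: SampleSheet
) -> None:
    """Check counts / bootstraps / sample sheet against each other."""
    sheet_ids = set(sheet.sample_ids)
    missing = [s for s in counts.sample_ids if s not in sheet_ids]
    if missing:
        raise ValueError(f"sample {missing[0]!r} in counts but not in sample sheet")
    if boots is not None:
        if boots.genes != counts.genes:
            raise ValueError("bootstrap tensor gene order does not match counts")
        extra = [s for s in boots.sample_ids if s not in sheet_ids]
        if extra:
            raise ValueError(
                f"sample {extra[0]!r} in bootstrap tensor but not in sample sheet"
            )
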