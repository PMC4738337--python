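"""Readers, writers and in-memory containers for expression data.

All matrices are log2-scale, genes in rows, samples in columns — the common
array-export layout. Gene identifiers are opaque strings; no probe/symbol
translation happens here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

ANNOTATION_COLUMNS = ("sample_id", "species", "group", "role")
ROLES = ("tumour", "reference")


@dataclass
class ExpressionMatrix:
    """A log2 expression matrix for one species.

    Parameters
    ----------
    values : pandas.DataFrame
        Genes in rows (index = gene identifiers), samples in columns.
        Must be fully numeric with no missing entries.
    species : str
        Species label, e.g. ``"mouse"`` or ``"human"``.
    """

    values: pd.DataFrame
    species: str

    def __post_init__(self) -> None:
        idx = self.values.index
        cols = self.values.columns
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValueError(f"duplicate gene identifier: {dup!r}")
        if cols.has_duplicates:
            dup = cols[cols.duplicated()][0]
            raise ValueError(f"duplicate sample identifier: {dup!r}")
        if self.values.size == 0:
            raise ValueError("empty expression matrix")
        if not np.issubdtype(np.asarray(self.values).dtype, np.number):
            raise ValueError("expression matrix must be numeric")
        if self.values.isna().any().any():
            r, c = np.argwhere(self.values.isna().to_numpy())[0]
            raise ValueError(
                f"missing value at gene {idx[r]!r} (row {r + 1}), "
                f"sample {cols[c]!r} (column {c + 1})"
            )

    @property
    def gene_ids(self) -> pd.Index:
        return self.values.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.columns

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def subset_genes(self, gene_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[gene_ids], self.species)

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[:, list(sample_ids)], self.species)


def load_expression_matrix(
    path, species: str, drop_missing: bool = False
) -> ExpressionMatrix:
    """Load a tab-delimited genes × samples matrix.

    First column holds gene identifiers, the header row sample identifiers.
    Non-numeric or missing cells are rejected with their coordinates unless
    ``drop_missing`` is set, in which case offending gene rows are dropped
    (never imputed).
    """
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"{path}: empty expression matrix")
    if df.index.has_duplicates:
        dup = df.index[df.index.duplicated()][0]
        raise ValueError(f"{path}: duplicate gene identifier: {dup!r}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna().to_numpy()
    if bad.any():
        if drop_missing:
            n_before = numeric.shape[0]
            numeric = numeric.loc[~bad.any(axis=1)]
            logger.warning(
                "%s: dropped %d gene(s) with missing/non-numeric values",
                path, n_before - numeric.shape[0],
            )
            if numeric.shape[0] == 0:
                raise ValueError(f"{path}: no genes left after dropping missing rows")
        else:
            r, c = np.argwhere(bad)[0]
            raise ValueError(
                f"{path}: non-numeric or missing value {df.iat[r, c]!r} at "
                f"gene {df.index[r]!r} (row {r + 1}), "
                f"sample {df.columns[c]!r} (column {c + 1})"
            )
    numeric.index.name = "gene_id"
    return ExpressionMatrix(numeric.astype(float), species)


def write_expression_matrix(matrix: ExpressionMatrix, path) -> None:
    out = matrix.values.copy()
    out.index.name = "gene_id"
    out.to_csv(path, sep="\t")


def load_sample_annotation(path) -> pd.DataFrame:
    """Load the sample annotation table (sample_id, species, group, role)."""
    ann = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in ANNOTATION_COLUMNS if c not in ann.columns]
    if missing:
        raise ValueError(f"{path}: annotation is missing column(s) {missing}")
    ann["role"] = ann["role"].str.replace("tumor", "tumour")
    bad_roles = sorted(set(ann["role"]) - set(ROLES))
    if bad_roles:
        raise ValueError(f"{path}: unknown role(s) {bad_roles}; expected {ROLES}")
    if ann["sample_id"].duplicated().any():
        dup = ann.loc[ann["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValueError(f"{path}: duplicate sample_id {dup!r}")
    return ann


def write_sample_annotation(ann: pd.DataFrame, path) -> None:
    ann.to_csv(path, sep="\t", index=False)


def validate_annotation(ann: pd.DataFrame, matrices) -> None:
    """Check every annotated sample exists in exactly one matrix of its species."""
    for _, row in ann.iterrows():
        hits = [
            m for m in matrices
            if m.species == row["species"] and row["sample_id"] in m.sample_ids
        ]
        if len(hits) != 1:
            raise ValueError(
                f"sample {row['sample_id']!r} (species {row['species']!r}) found in "
                f"{len(hits)} matrices; expected exactly 1"
            )


@dataclass
class OrthologMap:
    """Cross-species gene pairing, reducible to a 1:1 core.

    ``pairs`` is a DataFrame with columns ``gene_a`` and ``gene_b``.
    """

    pairs: pd.DataFrame
    provenance: str = ""
    _is_1to1: bool = field(default=False, repr=False)

    def __post_init__(self) -> None:
        if list(self.pairs.columns) != ["gene_a", "gene_b"]:
            self.pairs = self.pairs.rename(
                columns=dict(zip(self.pairs.columns, ["gene_a", "gene_b"]))
            )

    def __len__(self) -> int:
        return len(self.pairs)

    @property
    def n_1to1(self) -> int:
        return len(to_1to1(self).pairs)


def load_ortholog_map(path, provenance: str = "") -> OrthologMap:
    """Load a two-column tab-delimited ortholog table, one pair per line.

    Duplicate pairs are collapsed; malformed lines are rejected with their
    line number; an empty file yields an empty map with a warning.
    """
    rows = []
    with open(path, encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) != 2:
                raise ValueError(
                    f"{path}:{lineno}: expected exactly 2 tab-separated fields, "
                    f"got {len(fields)}"
                )
            rows.append(fields)
    if not rows:
        logger.warning("%s: empty ortholog map", path)
        pairs = pd.DataFrame(columns=["gene_a", "gene_b"])
    else:
        pairs = pd.DataFrame(rows, columns=["gene_a", "gene_b"]).drop_duplicates(
            ignore_index=True
        )
    return OrthologMap(pairs, provenance=provenance or str(path))


def write_ortholog_map(omap: OrthologMap, path) -> None:
    omap.pairs.to_csv(path, sep="\t", index=False, header=False)


def to_1to1(omap: OrthologMap, policy: str = "drop_all") -> OrthologMap:
    """Reduce an ortholog map to a 1:1 core.

    policy="drop_all" (default) removes every pair touching a gene that appears
    in more than one pair on either side — the conservative standard for
    cross-species expression comparison. policy="first" keeps the first-listed
    pair for each gene instead. Both are deterministic and idempotent.
    """
    pairs = omap.pairs.drop_duplicates(ignore_index=True)
    if policy == "drop_all":
        mult_a = pairs["gene_a"].duplicated(keep=False)
        mult_b = pairs["gene_b"].duplicated(keep=False)
        kept = pairs.loc[~(mult_a | mult_b)].reset_index(drop=True)
    elif policy == "first":
        seen_a: set = set()
        seen_b: set = set()
        keep = []
        for i, (a, b) in enumerate(zip(pairs["gene_a"], pairs["gene_b"])):
            if a not in seen_a and b not in seen_b:
                keep.append(i)
                seen_a.add(a)
                seen_b.add(b)
        kept = pairs.iloc[keep].reset_index(drop=True)
    else:
        raise ValueError(f"unknown 1:1 policy {policy!r}")
    return OrthologMap(kept, provenance=omap.provenance, _is_1to1=True)
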