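"""Compositional analysis of taxa-by-sample count tables.

The table is an integer count matrix (taxa as rows, samples as columns)
produced upstream by a read classifier; this module handles the standard
downstream steps: removal of host and low-abundance taxa, average
genome-size normalisation to relative abundances, rarefaction to a common
depth, Jaccard dissimilarities for ordination, plus extraction of reads
assigned to a marker genus for the genus-restricted classification
workflow.

Tables are plain pandas DataFrames indexed by taxon id; an optional
semicolon-delimited lineage string per taxon supports descendant
matching during read extraction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

from .fastq import ReadRecord

__all__ = [
    "TaxaTable",
    "read_taxa_table",
    "read_genome_sizes",
    "read_assignments",
    "filter_taxa",
    "normalize_genome_size",
    "rarefy",
    "jaccard_distance_matrix",
    "extract_taxon_reads",
    "genus_sample_gate",
]

HOST_TAXON_ID = 9606  # Homo sapiens


@dataclass
class TaxaTable:
    """Counts (taxa x samples) with optional per-taxon lineage strings."""

    counts: pd.DataFrame
    lineage: pd.Series | None = None

    def __post_init__(self) -> None:
        if self.counts.index.duplicated().any():
            raise ValueError("duplicate taxon ids")
        if self.counts.columns.duplicated().any():
            raise ValueError("duplicate sample ids")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("negative counts")

    def to_tsv(self, path: Union[str, Path]) -> None:
        out = self.counts.copy()
        out.insert(0, "taxon_id", out.index)
        if self.lineage is not None:
            out.insert(1, "lineage", self.lineage.reindex(out.index))
        out.to_csv(path, sep="\t", index=False)


def read_taxa_table(path: Union[str, Path]) -> TaxaTable:
    """Read a TSV with first column ``taxon_id``, optional ``lineage``."""
    df = pd.read_csv(path, sep="\t")
    df = df.set_index("taxon_id")
    lineage = None
    if "lineage" in df.columns:
        lineage = df.pop("lineage").astype(str)
    return TaxaTable(df.astype(np.int64), lineage)


def read_genome_sizes(path: Union[str, Path]) -> pd.Series:
    """Read a two-column TSV ``taxon_id, size_bp`` into a Series."""
    df = pd.read_csv(path, sep="\t")
    sizes = df.set_index("taxon_id")["size_bp"].astype(float)
    if (sizes <= 0).any():
        raise ValueError("genome sizes must be positive")
    return sizes


def read_assignments(path: Union[str, Path]) -> dict[str, int]:
    """Read a two-column TSV ``read_id, taxon_id`` into a mapping."""
    df = pd.read_csv(path, sep="\t")
    if df["read_id"].duplicated().any():
        raise ValueError("duplicate read ids in assignment table")
    return dict(zip(df["read_id"].astype(str), df["taxon_id"].astype(int)))


def filter_taxa(
    counts: pd.DataFrame,
    exclude_taxa: Iterable[int] = (HOST_TAXON_ID,),
    min_total: int = 10,
) -> pd.DataFrame:
    """Drop listed taxa and taxa with < min_total reads summed over samples."""
    out = counts.drop(index=[t for t in exclude_taxa if t in counts.index])
    return out[out.sum(axis=1) >= min_total]


def normalize_genome_size(
    counts: pd.DataFrame, sizes: Mapping[int, float] | pd.Series
) -> pd.DataFrame:
    """Genome-size-corrected relative abundances.

    Each count is divided by that taxon's average genome size and the
    sample column renormalised to sum to 1; longer genomes shed
    proportionally more reads, so raw counts overstate their abundance.
    Taxa without a size entry are dropped before normalisation.
    """
    sizes = pd.Series(sizes, dtype=float)
    known = counts.index.intersection(sizes.index)
    out = counts.loc[known].div(sizes.loc[known], axis=0)
    totals = out.sum(axis=0)
    empty = totals[totals == 0].index.tolist()
    if empty:
        warnings.warn(f"samples with no sized taxa left: {empty}")
        totals = totals.replace(0, np.nan)
    return out.div(totals, axis=1).fillna(0.0)


def rarefy(
    counts: pd.DataFrame, depth: int | None = None, seed: int = 0
) -> pd.DataFrame:
    """Subsample each sample to *depth* reads without replacement.

    Defaults to the lowest sample depth.  Samples whose total is below
    the requested depth are excluded with a warning.  The draw is
    multivariate hypergeometric, so every output column sums to exactly
    *depth*.
    """
    totals = counts.sum(axis=0)
    if depth is None:
        depth = int(totals.min())
    if depth <= 0:
        raise ValueError("rarefaction depth must be positive")
    shallow = totals[totals < depth].index.tolist()
    if shallow:
        warnings.warn(f"samples below rarefaction depth {depth} excluded: {shallow}")
    keep = [c for c in counts.columns if c not in set(shallow)]
    rng = np.random.default_rng(seed)
    out = {}
    for col in keep:
        col_counts = counts[col].to_numpy(dtype=np.int64)
        if col_counts.sum() == depth:
            out[col] = col_counts
        else:
            out[col] = rng.multivariate_hypergeometric(col_counts, depth, method="marginals")
    return pd.DataFrame(out, index=counts.index)


def jaccard_distance_matrix(
    counts: pd.DataFrame, mode: str = "binary"
) -> pd.DataFrame:
    """Pairwise Jaccard dissimilarities between sample columns.

    ``binary`` (default): 1 - |A & B| / |A | B| on presence/absence —
    the textbook Jaccard.  ``quantitative``: 2b/(1+b) with b the
    Bray-Curtis dissimilarity — the abundance-weighted variant used by
    community-ecology software.
    """
    X = counts.to_numpy(dtype=float).T  # samples x taxa
    if mode == "binary":
        present = X > 0
        d = pdist(present, metric="jaccard")
    elif mode == "quantitative":
        b = pdist(X, metric="braycurtis")
        d = 2 * b / (1 + b)
    else:
        raise ValueError(f"unknown Jaccard mode {mode!r}")
    return pd.DataFrame(
        squareform(d), index=counts.columns, columns=counts.columns
    )


def _lineage_tokens(lineage: str) -> list[str]:
    return [tok.strip() for tok in str(lineage).split(";")]


def extract_taxon_reads(
    reads: Iterable[ReadRecord],
    assignment: Mapping[str, int],
    taxon_id: int,
    include_descendants: bool = False,
    lineages: Mapping[int, str] | pd.Series | None = None,
) -> list[ReadRecord]:
    """Reads assigned to *taxon_id* (or its descendants), in input order.

    Unassigned reads are treated as unclassified and never match.
    Descendant matching requires semicolon-delimited lineage strings: a
    taxon descends from the target when the target id appears among its
    lineage tokens.
    """
    matching: set[int] = {int(taxon_id)}
    if include_descendants and lineages is not None:
        target = str(taxon_id)
        for tid, lin in (
            lineages.items() if not isinstance(lineages, pd.Series) else lineages.items()
        ):
            if target in _lineage_tokens(lin):
                matching.add(int(tid))
    out = [
        r
        for r in reads
        if r.read_id in assignment and int(assignment[r.read_id]) in matching
    ]
    if not out:
        warnings.warn(f"no reads assigned to taxon {taxon_id}")
    return out


def genus_sample_gate(
    genus_read_counts: Mapping[str, int], min_reads: int = 100_000
) -> tuple[list[str], list[str]]:
    """Partition samples by marker-genus read count.

    Samples with fewer than *min_reads* marker-genus reads are excluded
    (the boundary count itself passes).  Raises when nothing survives.
    """
    included = [s for s, c in genus_read_counts.items() if c >= min_reads]
    excluded = [s for s, c in genus_read_counts.items() if c < min_reads]
    if not included:
        raise ValueError(
            f"all {len(excluded)} samples fall below the {min_reads}-read marker-genus gate"
        )
    return included, excluded
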