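"""Readers and writers for the pipeline's on-disk formats.

Canonical formats are plain TSV (community table, metadata, distance
matrices — human-diffable at the ~1,300-taxon scale this targets) and
single-tree Newick with branch lengths.  All writers emit full double
precision so write → read round-trips are lossless.
"""

from __future__ import annotations

import logging
import warnings

import dendropy
import numpy as np
import pandas as pd

from .containers import CommunityTable
from .errors import ConsistencyError, FormatError, ValidationError
from .trees import prune_to_taxa, tip_labels

log = logging.getLogger(__name__)

METADATA_NUMERIC = (
    "depth_m", "lat", "lon", "temperature", "salinity", "oxygen",
    "nitrate", "phosphate", "chlorophyll_a",
)


def read_community_table(path, samples_as_rows: bool = True) -> CommunityTable:
    """Read a TSV abundance table (header = taxon IDs, first column = sample IDs).

    Set ``samples_as_rows=False`` for a transposed file; orientation is
    never guessed.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    if not samples_as_rows:
        df = df.T
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    for col in df.columns:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = bad.idxmax()
            raise FormatError(
                f"non-numeric cell at sample {row!r}, taxon {col!r}: {df.loc[row, col]!r}")
        if coerced.isna().any():
            row = coerced.isna().idxmax()
            raise FormatError(f"missing value at sample {row!r}, taxon {col!r}")
        if (coerced < 0).any():
            row = (coerced < 0).idxmax()
            raise FormatError(
                f"negative count at sample {row!r}, taxon {col!r}: {coerced[row]}")
        df[col] = coerced
    try:
        return CommunityTable(data=df)
    except ValidationError as exc:
        raise FormatError(str(exc)) from exc


def write_community_table(table: CommunityTable, path) -> None:
    df = table.data
    df.to_csv(path, sep="\t", index_label="sample_id",
              float_format=None)  # full precision


def read_newick_tree(path) -> dendropy.Tree:
    """Read a single rooted Newick tree with branch lengths.

    Zero-length branches are permitted with a warning; polytomies are
    permitted; a missing branch length on any non-root edge is a format
    error.
    """
    try:
        tree = dendropy.Tree.get(path=str(path), schema="newick",
                                 preserve_underscores=True)
    except Exception as exc:  # dendropy raises several parse error types
        raise FormatError(f"could not parse Newick file {path}: {exc}") from exc
    tips = tip_labels(tree)
    if len(tips) != len(set(tips)):
        raise FormatError("duplicate tip labels in tree")
    if len(tips) == 1:
        warnings.warn("tree has a single tip; distances are degenerate", stacklevel=2)
    zero_edges = 0
    for node in tree.preorder_node_iter():
        if node.parent_node is None:
            continue
        if node.edge.length is None:
            label = node.taxon.label if node.is_leaf() and node.taxon else "<internal>"
            raise FormatError(f"missing branch length on edge above {label}")
        if node.edge.length == 0:
            zero_edges += 1
    if zero_edges:
        warnings.warn(f"{zero_edges} zero-length branch(es) in tree", stacklevel=2)
    return tree


def write_newick_tree(tree: dendropy.Tree, path) -> None:
    tree.write(path=str(path), schema="newick", suppress_rooting=True,
               unquoted_underscores=True)


def read_sample_metadata(path) -> pd.DataFrame:
    """Read the sample metadata TSV (required: sample ID column + depth_m).

    Missing environmental values are preserved as NaN — never coerced to
    zero.  Latitude/longitude bounds and ID uniqueness are enforced.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    df.index = df.index.astype(str)
    if df.index.has_duplicates:
        dupes = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"duplicate sample IDs in metadata: {dupes}")
    if "depth_m" not in df.columns:
        raise FormatError("metadata is missing required column 'depth_m'")
    for col in METADATA_NUMERIC:
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    if (df["depth_m"] <= 0).any():
        bad = df.index[df["depth_m"] <= 0].tolist()
        raise ValidationError(f"nonpositive depth_m for samples: {bad}")
    if "lat" in df.columns and (df["lat"].dropna().abs() > 90).any():
        raise ValidationError("latitude outside [-90, 90]")
    if "lon" in df.columns and (df["lon"].dropna().abs() > 180).any():
        raise ValidationError("longitude outside [-180, 180]")
    return df


def write_sample_metadata(meta: pd.DataFrame, path) -> None:
    meta.to_csv(path, sep="\t", index_label="sample_id")


def write_distance_matrix(dm: pd.DataFrame, path) -> None:
    dm.to_csv(path, sep="\t", index_label="sample_id")


def read_distance_matrix(path) -> pd.DataFrame:
    dm = pd.read_csv(path, sep="\t", index_col=0)
    dm.index = dm.index.astype(str)
    dm.columns = dm.columns.astype(str)
    return dm


def align_inputs(
    table: CommunityTable,
    tree: dendropy.Tree | None,
    meta: pd.DataFrame | None,
) -> tuple[CommunityTable, dendropy.Tree | None, pd.DataFrame | None]:
    """Restrict table/tree/metadata to their shared samples and taxa.

    The table keeps samples present in the metadata and taxa present in
    the tree; the tree is pruned to the table's taxa; orderings follow the
    table.  Every dropped sample or taxon is logged.  Idempotent.
    """
    df = table.data
    samples = list(df.index)
    if meta is not None:
        kept = [s for s in samples if s in meta.index]
        dropped = sorted(set(samples) - set(kept))
        if not kept:
            raise ConsistencyError("no samples shared between table and metadata")
        if dropped:
            log.info("align_inputs: dropping %d sample(s) absent from metadata: %s",
                     len(dropped), dropped)
        samples = kept
        meta = meta.loc[samples]

    taxa = list(df.columns)
    if tree is not None:
        tips = set(tip_labels(tree))
        kept_taxa = [t for t in taxa if t in tips]
        if not kept_taxa:
            raise ConsistencyError("no taxa shared between table and tree")
        dropped_taxa = sorted(set(taxa) - set(kept_taxa))
        extra_tips = sorted(tips - set(kept_taxa))
        if dropped_taxa:
            dropped_reads = float(df[dropped_taxa].to_numpy().sum())
            log.info("align_inputs: dropping %d taxa absent from tree "
                     "(%g reads): %s", len(dropped_taxa), dropped_reads, dropped_taxa[:10])
        if extra_tips:
            log.info("align_inputs: pruning %d tree tip(s) absent from table: %s",
                     len(extra_tips), extra_tips[:10])
            tree = prune_to_taxa(tree, kept_taxa)
        taxa = kept_taxa

    sub = df.loc[samples, taxa]
    rowsums = sub.to_numpy().sum(axis=1)
    empty = sub.index[rowsums == 0].tolist()
    if empty:
        log.info("align_inputs: dropping %d now-empty sample(s): %s", len(empty), empty)
        sub = sub.loc[rowsums > 0]
        if meta is not None:
            meta = meta.loc[sub.index]
    if sub.shape[0] == 0:
        raise ConsistencyError("alignment left no non-empty samples")
    aligned = CommunityTable(data=sub.copy(), standardized=table.standardized,
                             provenance=dict(table.provenance, aligned=True))
    return aligned, tree, meta


def read_functional_lookup(path) -> dict[str, str]:
    """Read a two-column TSV mapping taxonomy token → trophic group."""
    df = pd.read_csv(path, sep="\t", header=0)
    if df.shape[1] < 2:
        raise FormatError("functional lookup needs two columns: token, group")
    tokens = df.iloc[:, 0].astype(str)
    groups = df.iloc[:, 1].astype(str).str.lower()
    if tokens.duplicated().any():
        raise ValidationError(
            f"duplicate lookup tokens: {tokens[tokens.duplicated()].tolist()}")
    allowed = {"autotroph", "mixotroph", "parasite", "osmotroph",
               "phagotroph", "heterotroph", "unknown"}
    bad = set(groups) - allowed
    if bad:
        raise ValidationError(f"unknown trophic groups: {sorted(bad)}")
    return dict(zip(tokens, groups))
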