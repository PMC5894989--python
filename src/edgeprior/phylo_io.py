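"""Reading, validating and pruning the three input artefacts.

Trees arrive as Newick (single- or multi-tree, one per line) or as Nexus
TREES blocks (translate tables honoured); taxonomy and Red List tables as
comma- or tab-delimited text with a header row.  Before any ED computation a
tree is pruned to the species a taxonomic authority recognises as valid and
extant; pruning collapses degree-2 nodes (summing the two incident edge
lengths) so every retained leaf keeps its root-to-leaf path length.

Leaf labels are matched against taxonomy species names exactly after
trimming whitespace, trying both the underscore and the space form of each
name (the Newick convention writes spaces as underscores).
"""

from __future__ import annotations

import io
import os
from pathlib import Path

import dendropy
import pandas as pd

from .exceptions import SchemaError, TreeError

RED_LIST_CATEGORIES = ("LC", "NT", "VU", "EN", "CR", "EW", "EX", "DD", "NE")

TAXONOMY_COLUMNS = ("species", "genus", "family", "clade")
TAXONOMY_FLAGS = ("is_valid", "is_extinct")

_TRUE = {"true", "t", "1", "yes", "y"}
_FALSE = {"false", "f", "0", "no", "n"}


def _as_text(source) -> str:
    """Accept a path, file handle, or raw tree text and return text."""
    if hasattr(source, "read"):
        return source.read()
    if isinstance(source, Path):
        return source.read_text()
    s = str(source)
    looks_like_data = s.lstrip().startswith(("(", "#NEXUS", "#nexus"))
    if not looks_like_data and os.path.exists(s):
        return Path(s).read_text()
    if looks_like_data:
        return s
    raise TreeError(f"no such file and not Newick/Nexus text: {s[:80]!r}")


def read_newick(source) -> dendropy.TreeList:
    """Parse one or more rooted trees from a path, handle, or string.

    Newline-separated Newick and Nexus TREES blocks are both accepted;
    polytomies and unlabelled internal nodes are preserved.  Raises
    :class:`TreeError` naming the tree index and position on malformed input
    and on negative branch lengths.
    """
    text = _as_text(source).strip()
    if not text:
        raise TreeError("empty tree source")
    schema = "nexus" if text.upper().startswith("#NEXUS") else "newick"
    try:
        trees = dendropy.TreeList.get(
            data=text, schema=schema, suppress_internal_node_taxa=True
        )
    except Exception as exc:  # dendropy raises several parse error types
        line = getattr(exc, "line_num", None)
        col = getattr(exc, "col_num", None)
        where = f" (line {line}, column {col})" if line is not None else ""
        raise TreeError(f"malformed {schema} input{where}: {exc}") from exc
    if len(trees) == 0:
        raise TreeError("no trees found in source")
    for i, tree in enumerate(trees):
        tree.is_rooted = True
        for edge in tree.preorder_edge_iter():
            if edge.length is not None and edge.length < 0:
                raise TreeError(
                    f"tree {i}: negative branch length {edge.length}"
                )
    return trees


def write_newick(trees, path) -> None:
    """Write a tree or TreeList as Newick, one tree per line."""
    if isinstance(trees, dendropy.Tree):
        trees = [trees]
    with open(path, "w") as fh:
        for tree in trees:
            fh.write(
                tree.as_string(
                    schema="newick", suppress_rooting=True
                ).strip()
                + "\n"
            )


def _name_variants(name: str) -> tuple[str, str]:
    name = name.strip()
    return name.replace("_", " "), name.replace(" ", "_")


def match_leaves(tree: dendropy.Tree, names) -> tuple[dict, set]:
    """Map tree leaf labels onto ``names`` (exact after normalisation).

    Returns ``(label -> canonical name, unmatched labels)``.
    """
    lookup: dict[str, str] = {}
    for nm in names:
        for v in _name_variants(str(nm)):
            lookup[v] = str(nm)
    matched: dict[str, str] = {}
    unmatched: set[str] = set()
    for leaf in tree.leaf_node_iter():
        lab = (leaf.taxon.label if leaf.taxon else leaf.label) or ""
        hit = None
        for v in _name_variants(lab):
            if v in lookup:
                hit = lookup[v]
                break
        if hit is None:
            unmatched.add(lab)
        else:
            matched[lab] = hit
    return matched, unmatched


def prune_to_labels(tree: dendropy.Tree, keep_labels) -> dendropy.Tree:
    """Copy of ``tree`` restricted to ``keep_labels``; degree-2 nodes are
    collapsed with their edge lengths summed, so every retained leaf keeps
    its root-to-leaf path length (a stem above the retained crown becomes a
    root edge)."""
    keep = set(keep_labels)
    if len(keep) < 2:
        raise TreeError("pruning would leave fewer than 2 leaves")
    pruned = tree.extract_tree_with_taxa_labels(labels=keep)
    pruned.is_rooted = True
    if len(pruned.leaf_nodes()) != len(keep):
        missing = keep - {l.taxon.label for l in pruned.leaf_node_iter()}
        raise TreeError(f"labels not found in tree: {sorted(missing)}")
    return pruned


def prune_to_recognised(
    tree: dendropy.Tree, taxonomy: pd.DataFrame
) -> dendropy.Tree:
    """Remove leaves that the taxonomy does not recognise as valid, extant
    species, collapsing degree-2 nodes.  Unmatched leaf labels are treated as
    unrecognised (no synonym guessing); the caller can inspect them via
    :func:`match_leaves`."""
    recognised = set(
        taxonomy.loc[
            taxonomy["is_valid"] & ~taxonomy["is_extinct"], "species"
        ]
    )
    matched, _ = match_leaves(tree, recognised)
    if len(matched) == len(tree.leaf_nodes()):
        return tree.clone(depth=1)
    return prune_to_labels(tree, matched.keys())


def _read_delimited(source) -> pd.DataFrame:
    if hasattr(source, "read"):
        source = io.StringIO(source.read())
    df = pd.read_csv(source, sep=None, engine="python", dtype=str)
    df.columns = [str(c).strip().lower() for c in df.columns]
    return df


def _parse_flag(series: pd.Series, column: str, default: bool) -> pd.Series:
    def one(v):
        if v is None or (isinstance(v, float) and pd.isna(v)) or str(v).strip() == "":
            return default
        s = str(v).strip().lower()
        if s in _TRUE:
            return True
        if s in _FALSE:
            return False
        raise SchemaError(f"unrecognised boolean {v!r} in column {column}")

    return series.map(one)


def read_taxonomy(source) -> pd.DataFrame:
    """Species -> genus -> family -> clade table with validity/extinct flags.

    Missing flag columns default to valid=True, extinct=False.  Duplicate
    species rows and empty names raise :class:`SchemaError`.
    """
    df = _read_delimited(source)
    missing = [c for c in TAXONOMY_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"taxonomy missing mandatory column(s): {missing}")
    for col in TAXONOMY_COLUMNS:
        df[col] = df[col].astype(str).str.strip()
        if (df[col] == "") .any() or df[col].isin(("nan", "None")).any():
            raise SchemaError(f"empty value in taxonomy column {col!r}")
    dup = df["species"][df["species"].duplicated()]
    if not dup.empty:
        raise SchemaError(f"duplicate species in taxonomy: {sorted(set(dup))}")
    for gcol, pcol in (("genus", "family"), ("family", "clade")):
        parents = df.groupby(gcol)[pcol].nunique()
        bad = parents[parents > 1]
        if not bad.empty:
            raise SchemaError(
                f"{gcol} mapped to multiple {pcol} values: {sorted(bad.index)}"
            )
    for flag, default in zip(TAXONOMY_FLAGS, (True, False)):
        df[flag] = (
            _parse_flag(df[flag], flag, default)
            if flag in df.columns
            else default
        )
    return df[list(TAXONOMY_COLUMNS) + list(TAXONOMY_FLAGS)].reset_index(
        drop=True
    )


def read_redlist(source) -> pd.DataFrame:
    """Species -> IUCN Red List category table.

    Categories are normalised case-insensitively to the nine-value IUCN set;
    anything else raises :class:`SchemaError` naming the offending row.
    """
    df = _read_delimited(source)
    for col in ("species", "category"):
        if col not in df.columns:
            raise SchemaError(f"red list table missing column {col!r}")
    df["species"] = df["species"].astype(str).str.strip()
    df["category"] = df["category"].astype(str).str.strip().str.upper()
    dup = df["species"][df["species"].duplicated()]
    if not dup.empty:
        raise SchemaError(f"duplicate species in red list: {sorted(set(dup))}")
    bad = ~df["category"].isin(RED_LIST_CATEGORIES)
    if bad.any():
        row = int(df.index[bad][0])
        raise SchemaError(
            f"unknown Red List category {df.loc[row, 'category']!r} "
            f"at row {row} (species {df.loc[row, 'species']!r})"
        )
    return df[["species", "category"]].reset_index(drop=True)


def write_table(df: pd.DataFrame, path, float_format: str | None = None) -> None:
    """All tabular outputs are plain comma-delimited text."""
    df.to_csv(path, index=False, float_format=float_format)
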