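"""Readers and writers for the tab-delimited formats the pipeline consumes.

Supported inputs: classic QIIME-1-style OTU tables ("#OTU ID" header
tolerated, either orientation), two-column taxonomy TSV with
semicolon-separated rank-prefixed lineages (SILVA/Greengenes style),
sample-metadata TSV, and single-tree newick files (read through
scikit-bio).  All result tables are written as TSV with >= 10
significant digits so read(write(x)) round-trips within 1e-9.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import skbio

from .containers import (
    RANKS,
    RANK_PREFIXES,
    CohortMetadata,
    FormatError,
    OtuTable,
    TaxonomyMap,
    ValidationError,
)

__all__ = [
    "read_otu_table",
    "write_otu_table",
    "read_taxonomy",
    "write_taxonomy",
    "read_metadata",
    "write_metadata",
    "read_newick",
    "write_newick",
    "write_result_table",
    "read_result_table",
    "write_run_manifest",
]


def read_otu_table(
    path: str | Path,
    orientation: str = "samples_as_rows",
    relative: bool = False,
) -> OtuTable:
    """Read a tab-delimited OTU table.

    ``orientation`` must be ``samples_as_rows`` or ``otus_as_rows``; it is
    never guessed (square-ish tables are ambiguous).  A leading
    ``#OTU ID`` header cell is tolerated.  Both orientations of the same
    data yield an identical canonical samples-x-OTUs table.
    """
    if orientation not in ("samples_as_rows", "otus_as_rows"):
        raise ValueError(
            "orientation must be 'samples_as_rows' or 'otus_as_rows', "
            f"got {orientation!r}"
        )
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0, comment=None)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse OTU table {path}: {exc}") from exc
    frame.index = frame.index.astype(str)
    frame.index.name = None
    if orientation == "otus_as_rows":
        frame = frame.T
    body = frame.apply(pd.to_numeric, errors="coerce")
    if body.isna().any().any():
        bad = body.columns[body.isna().any()].tolist()[:5]
        raise FormatError(f"non-numeric cell(s) in OTU table column(s) {bad}")
    return OtuTable(body, relative=relative)


def write_otu_table(
    table: OtuTable, path: str | Path, orientation: str = "samples_as_rows"
) -> Path:
    frame = table.counts if orientation == "samples_as_rows" else table.counts.T
    frame = frame.copy()
    frame.index.name = "#OTU ID" if orientation == "otus_as_rows" else "sample_id"
    path = Path(path)
    frame.to_csv(path, sep="\t", float_format="%.10g")
    return path


def _parse_lineage(raw: str, otu_id: str) -> dict[str, str]:
    if not raw or not raw.strip():
        raise FormatError(f"empty lineage for OTU {otu_id!r}")
    named: dict[str, str] = {}
    fields = [f.strip() for f in raw.strip().strip(";").split(";")]
    positional_rank = 0
    for fld in fields:
        if not fld:
            positional_rank += 1
            continue
        if "__" in fld:
            prefix, _, name = fld.partition("__")
            rank = RANK_PREFIXES.get(prefix.strip().lower())
            if rank is None:
                raise FormatError(
                    f"unknown rank prefix {prefix!r} in lineage of OTU {otu_id!r}"
                )
            positional_rank = RANKS.index(rank) + 1
        else:
            if positional_rank >= len(RANKS):
                break
            rank = RANKS[positional_rank]
            name = fld
            positional_rank += 1
        if name:
            named[rank] = name
    if not named:
        raise FormatError(f"no named ranks in lineage {raw!r} of OTU {otu_id!r}")
    # Fill gaps and the unclassified tail from the deepest named ancestor.
    lineage: dict[str, str] = {}
    parent: str | None = None
    for rank in RANKS:
        name = named.get(rank)
        if name:
            lineage[rank] = name
            parent = name
        else:
            if parent is None:
                raise FormatError(
                    f"lineage of OTU {otu_id!r} does not start at domain: {raw!r}"
                )
            base = parent[: -len("_unclassified")] if parent.endswith("_unclassified") else parent
            lineage[rank] = f"{base}_unclassified"
            parent = lineage[rank]
    return lineage


def read_taxonomy(path: str | Path) -> TaxonomyMap:
    """Read a two-column TSV of OTU id and semicolon-separated lineage."""
    try:
        frame = pd.read_csv(path, sep="\t", header=None, dtype=str, comment="#")
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse taxonomy {path}: {exc}") from exc
    if frame.shape[1] < 2:
        raise FormatError("taxonomy file must have two tab-separated columns")
    rows = {}
    for otu_id, raw in zip(frame.iloc[:, 0], frame.iloc[:, 1]):
        rows[str(otu_id)] = _parse_lineage("" if pd.isna(raw) else str(raw), str(otu_id))
    return TaxonomyMap(pd.DataFrame.from_dict(rows, orient="index"))


def write_taxonomy(tax: TaxonomyMap, path: str | Path) -> Path:
    path = Path(path)
    prefix = {"domain": "d", "phylum": "p", "class": "c", "order": "o",
              "family": "f", "genus": "g"}
    with open(path, "w") as fh:
        for otu_id, row in tax.lineages.iterrows():
            lineage = ";".join(f"{prefix[r]}__{row[r]}" for r in RANKS)
            fh.write(f"{otu_id}\t{lineage}\n")
    return path


def read_metadata(path: str | Path) -> CohortMetadata:
    """Read the sample-metadata TSV (sample id, group, cohort, sledai, ...)."""
    try:
        frame = pd.read_csv(path, sep="\t", index_col=0)
    except (pd.errors.ParserError, pd.errors.EmptyDataError) as exc:
        raise FormatError(f"cannot parse metadata {path}: {exc}") from exc
    frame.index = frame.index.astype(str)
    return CohortMetadata(frame)


def write_metadata(meta: CohortMetadata, path: str | Path) -> Path:
    path = Path(path)
    frame = meta.frame.copy()
    frame.index.name = "sample_id"
    frame.to_csv(path, sep="\t", float_format="%.10g")
    return path


def read_newick(path: str | Path) -> skbio.TreeNode:
    """Read a single rooted newick tree; absent branch lengths become 0."""
    try:
        tree = skbio.TreeNode.read(str(path), format="newick")
    except Exception as exc:  # skbio raises several parser error types
        raise FormatError(f"cannot parse newick tree {path}: {exc}") from exc
    names = [tip.name for tip in tree.tips()]
    if len(names) != len(set(names)):
        dups = sorted({n for n in names if names.count(n) > 1})
        raise ValidationError(f"duplicate leaf label(s) in tree: {dups}")
    for node in tree.traverse():
        if node.length is None:
            node.length = 0.0
        elif node.length < 0:
            raise ValidationError(f"negative branch length at node {node.name!r}")
    return tree


def write_newick(tree: skbio.TreeNode, path: str | Path) -> Path:
    path = Path(path)
    tree.write(str(path), format="newick")
    return path


def write_result_table(result: pd.DataFrame | Mapping, path: str | Path) -> Path:
    """Write any named-column tabular result as TSV, >= 10 significant digits."""
    if isinstance(result, Mapping):
        result = pd.DataFrame(result)
    if not isinstance(result, pd.DataFrame):
        raise TypeError("result must be a DataFrame or a mapping of named columns")
    for col in result.columns:
        if result[col].map(lambda v: isinstance(v, (list, dict, tuple, set))).any():
            raise ValueError(f"cannot flatten nested values in column {col!r}")
    path = Path(path)
    result.to_csv(path, sep="\t", float_format="%.12g")
    return path


def read_result_table(path: str | Path, index_col: int | None = 0) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=index_col)


def write_run_manifest(path: str | Path, seed: int | None, params: Mapping) -> Path:
    """JSON provenance record: seed, resolved parameters, library versions."""
    import sklearn
    import scipy

    manifest = {
        "seed": seed,
        "params": dict(params),
        "versions": {
            "python": platform.python_version(),
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "scipy": scipy.__version__,
            "scikit-learn": sklearn.__version__,
            "scikit-bio": skbio.__version__,
        },
    }
    path = Path(path)
    path.write_text(json.dumps(manifest, indent=2, default=str) + "\n")
    return path
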