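"""Readers and writers for the external formats the pipeline touches.

Supported dialects
------------------
* MaxQuant ``proteinGroups.txt`` (TSV; one row per protein group, intensity
  columns per fraction, ``Reverse`` / ``Potential contaminant`` / ``Only
  identified by site`` flag columns).
* MaxQuant ``Phospho (STY)Sites.txt`` (TSV; one row per site).
* CORUM ``coreComplexes.txt``-like tables (semicolon-delimited subunit list).
* EcoCyc ``protcplxs.col``-like tables (members spread over GENE columns).
* GMT annotation sets, 2-column ortholog maps, 2-3 column edge lists, and a
  generic elution-matrix TSV used for round-tripping simulator output.

All identifiers are whitespace-trimmed with case preserved. Missing
intensities are encoded as an empty cell or ``NA`` on write and parse back to
``NaN``; a literal ``0`` parses as numeric zero (the preprocess step decides
whether zeros mean "not quantified" for a given dialect).
"""

from __future__ import annotations

import logging
from pathlib import Path
from typing import Optional, Union

import numpy as np
import pandas as pd

from .errors import ConfigError, FormatError
from .types import (
    AnnotationSet,
    ComplexCatalog,
    EdgeList,
    ElutionMatrix,
    OrthologMap,
    make_pair,
)

logger = logging.getLogger("cfnet.io")

PathLike = Union[str, Path]

PROTEIN_GROUPS_ID_COLUMNS = ("Majority protein IDs", "Protein IDs", "Protein group IDs", "id")
FLAG_COLUMNS = {
    "reverse": "Reverse",
    "contaminant": "Potential contaminant",
    "only_by_site": "Only identified by site",
}

__all__ = [
    "read_protein_groups",
    "read_phospho_sites",
    "write_phospho_sites",
    "read_complexes",
    "read_gmt",
    "read_ortholog_map",
    "read_edge_list",
    "write_edge_list",
    "read_elution_matrix",
    "write_elution_matrix",
]


def _read_tsv(path: PathLike) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, comment=None)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas message passthrough
        raise FormatError(f"{path}: not parseable as TSV: {exc}") from exc


def _parse_intensity(cell: str, row: int, column: str, path: PathLike) -> float:
    cell = cell.strip()
    if cell == "" or cell.upper() in ("NA", "NAN"):
        return np.nan
    try:
        value = float(cell)
    except ValueError as exc:
        raise FormatError(
            f"{path}: non-numeric intensity {cell!r} at row {row}, column {column!r}"
        ) from exc
    return value


def read_protein_groups(
    path: PathLike,
    intensity_column_prefix: str = "Intensity ",
    experiment_id: Optional[str] = None,
    species: str = "",
) -> tuple[ElutionMatrix, pd.DataFrame]:
    """Read a MaxQuant ``proteinGroups.txt``-dialect table.

    Returns the raw elution matrix (one row per protein group; *no* filtering
    is applied here) together with a boolean flag frame (columns ``reverse``,
    ``contaminant``, ``only_by_site``) aligned to the matrix rows, for
    consumption by :mod:`cfnet.preprocess`.

    Fraction order is the column order of the file. Empty intensity cells are
    missing; zeros are kept as numeric zeros (see
    :func:`cfnet.preprocess.zeros_to_missing`).
    """
    df = _read_tsv(path)
    id_col = next((c for c in PROTEIN_GROUPS_ID_COLUMNS if c in df.columns), None)
    if id_col is None:
        raise FormatError(
            f"{path}: no protein-groups identifier column "
            f"(looked for {PROTEIN_GROUPS_ID_COLUMNS})"
        )
    intensity_cols = [c for c in df.columns if c.startswith(intensity_column_prefix)]
    # Plain "Intensity" (summed over fractions) is not a fraction column.
    intensity_cols = [c for c in intensity_cols if c.strip() != intensity_column_prefix.strip()]
    if not intensity_cols:
        raise FormatError(
            f"{path}: no intensity columns with prefix {intensity_column_prefix!r}"
        )

    proteins = [v.strip() for v in df[id_col]]
    values = np.empty((len(df), len(intensity_cols)), dtype=float)
    for j, col in enumerate(intensity_cols):
        for i, cell in enumerate(df[col]):
            values[i, j] = _parse_intensity(cell, i, col, path)

    flags = pd.DataFrame(index=range(len(df)))
    for key, col in FLAG_COLUMNS.items():
        if col in df.columns:
            flags[key] = df[col].str.strip() == "+"
        else:
            logger.warning("%s: flag column %r absent; treating all rows as unflagged", path, col)
            flags[key] = False
    flags.index = pd.Index(proteins, name="protein")

    matrix = ElutionMatrix(
        experiment_id=experiment_id or Path(path).stem,
        species=species,
        proteins=proteins,
        intensities=values,
    )
    return matrix, flags


def read_phospho_sites(path: PathLike, intensity_column_prefix: str = "Intensity ") -> pd.DataFrame:
    """Read a MaxQuant ``Phospho (STY)Sites.txt``-dialect table.

    Returns the raw table as a typed DataFrame with columns ``protein``,
    ``position``, ``residue``, ``localization_prob``, ``delta_score``, the
    boolean flags ``reverse`` / ``contaminant``, and float columns
    ``intensity_1..n`` (NaN = missing). Site filtering lives in
    :func:`cfnet.phospho.filter_sites`.
    """
    df = _read_tsv(path)
    required = {"Protein": "protein", "Position": "position", "Amino acid": "residue"}
    for col in required:
        if col not in df.columns:
            raise FormatError(f"{path}: required column {col!r} missing")
    out = pd.DataFrame({new: df[old].str.strip() for old, new in required.items()})
    try:
        out["position"] = out["position"].astype(int)
    except ValueError as exc:
        raise FormatError(f"{path}: non-integer site position") from exc
    for col, new in (("Localization prob", "localization_prob"), ("Delta score", "delta_score")):
        if col in df.columns:
            out[new] = [_parse_intensity(v, i, col, path) for i, v in enumerate(df[col])]
        else:
            out[new] = np.nan
    for key in ("reverse", "contaminant"):
        col = FLAG_COLUMNS[key]
        if col in df.columns:
            out[key] = df[col].str.strip() == "+"
        else:
            logger.warning("%s: flag column %r absent; nothing flagged", path, col)
            out[key] = False
    intensity_cols = [
        c
        for c in df.columns
        if c.startswith(intensity_column_prefix) and c.strip() != intensity_column_prefix.strip()
    ]
    for j, col in enumerate(intensity_cols, start=1):
        out[f"intensity_{j}"] = [_parse_intensity(v, i, col, path) for i, v in enumerate(df[col])]
    return out


def write_phospho_sites(table: pd.DataFrame, path: PathLike) -> None:
    """Write a typed site table back out in the MaxQuant-like dialect.

    Inverse of :func:`read_phospho_sites`: boolean flags become ``+``/empty,
    missing intensities become empty cells.
    """
    intensity_cols = sorted(
        (c for c in table.columns if c.startswith("intensity_")),
        key=lambda c: int(c.split("_")[1]),
    )
    out = pd.DataFrame(
        {
            "Protein": table["protein"],
            "Position": table["position"],
            "Amino acid": table["residue"],
            "Localization prob": table["localization_prob"],
            "Delta score": table["delta_score"],
            "Reverse": np.where(table["reverse"], "+", ""),
            "Potential contaminant": np.where(table["contaminant"], "+", ""),
        }
    )
    for j, col in enumerate(intensity_cols, start=1):
        out[f"Intensity F{j}"] = table[col]
    out.to_csv(path, sep="\t", index=False, na_rep="")


# ---------------------------------------------------------------------------
# Complex catalogs
# ---------------------------------------------------------------------------


def _dedupe_complexes(raw: dict[str, set[str]], source: str) -> ComplexCatalog:
    """Drop <2-member complexes and redundant (identical member set) entries."""
    n_small = 0
    seen: dict[frozenset[str], str] = {}
    kept: dict[str, frozenset[str]] = {}
    for cid in sorted(raw):
        members = frozenset(m for m in (x.strip() for x in raw[cid]) if m)
        if len(members) < 2:
            n_small += 1
            continue
        if members in seen:
            logger.info("complex %r redundant with %r; dropped", cid, seen[members])
            continue
        seen[members] = cid
        kept[cid] = members
    if n_small:
        logger.info("dropped %d complexes with fewer than 2 members", n_small)
    return ComplexCatalog(complexes=dict(kept), source=source)


def read_complexes(path: PathLike, dialect: str = "corum_like") -> ComplexCatalog:
    """Read a protein-complex catalog.

    ``corum_like``: a TSV with a complex-id column (``ComplexID`` or the first
    column) and a semicolon-delimited subunit column (first column whose name
    starts with ``subunits``, preferring gene names, else a ``Members``
    column).

    ``ecocyc_like``: a TSV whose member identifiers are spread over every
    column containing ``GENE`` in its name (``protcplxs.col`` layout); lines
    starting with ``#`` are comments.

    Complexes with fewer than two members are dropped and redundant entries
    (identical member sets) removed, with counts logged.
    """
    if dialect == "corum_like":
        df = _read_tsv(path)
        id_col = "ComplexID" if "ComplexID" in df.columns else df.columns[0]
        subunit_cols = [c for c in df.columns if c.lower().startswith("subunits")]
        gene_cols = [c for c in subunit_cols if "gene" in c.lower()]
        if gene_cols:
            sub_col = gene_cols[0]
        elif subunit_cols:
            sub_col = subunit_cols[0]
        elif "Members" in df.columns:
            sub_col = "Members"
        else:
            raise FormatError(f"{path}: no subunit column found (corum_like dialect)")
        raw: dict[str, set[str]] = {}
        for _, row in df.iterrows():
            cid = str(row[id_col]).strip()
            members = {m.strip() for m in str(row[sub_col]).split(";") if m.strip()}
            raw.setdefault(cid, set()).update(members)
        return _dedupe_complexes(raw, source="corum_like")

    if dialect == "ecocyc_like":
        lines = Path(path).read_text().splitlines()
        lines = [ln for ln in lines if ln.strip() and not ln.startswith("#")]
        if not lines:
            raise FormatError(f"{path}: empty ecocyc_like file")
        header = lines[0].split("\t")
        member_idx = [i for i, c in enumerate(header) if "GENE" in c.upper()]
        if not member_idx:
            raise FormatError(f"{path}: no GENE member columns found (ecocyc_like dialect)")
        raw = {}
        for ln in lines[1:]:
            fields = ln.split("\t")
            cid = fields[0].strip()
            members = {fields[i].strip() for i in member_idx if i < len(fields) and fields[i].strip()}
            raw.setdefault(cid, set()).update(members)
        return _dedupe_complexes(raw, source="ecocyc_like")

    raise ConfigError(f"unknown complex-catalog dialect: {dialect!r}")


# ---------------------------------------------------------------------------
# GMT / ortholog maps / edge lists
# ---------------------------------------------------------------------------


def read_gmt(path: PathLike) -> AnnotationSet:
    """Read a GMT file: ``term<TAB>description<TAB>member...`` per line."""
    terms: dict[str, frozenset[str]] = {}
    names: dict[str, str] = {}
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) < 3:
            raise FormatError(f"{path}:{lineno}: GMT line needs term, description, >=1 member")
        term, desc, members = fields[0], fields[1], [m for m in fields[2:] if m]
        if not members:
            raise FormatError(f"{path}:{lineno}: term {term!r} has no members")
        terms[term] = frozenset(members)
        names[term] = desc
    return AnnotationSet(terms=terms, names=names)


def write_gmt(annotations: AnnotationSet, path: PathLike) -> None:
    with open(path, "w") as fh:
        for term in sorted(annotations.terms):
            desc = annotations.names.get(term, "")
            members = "\t".join(sorted(annotations.terms[term]))
            fh.write(f"{term}\t{desc}\t{members}\n")


def read_ortholog_map(path: PathLike, policy: str = "one_to_one_only") -> OrthologMap:
    """Read a 2-column source->target TSV.

    Under ``one_to_one_only`` every source or target identifier occurring in
    more than one row is dropped entirely (the map must be injective both
    ways); dropped-row counts are logged.
    """
    sources: list[str] = []
    targets: list[str] = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected 2 tab-separated columns")
        sources.append(fields[0].strip())
        targets.append(fields[1].strip())
    src_counts = pd.Series(sources).value_counts()
    tgt_counts = pd.Series(targets).value_counts()
    pairs: dict[str, str] = {}
    dropped = 0
    for s, t in zip(sources, targets):
        if src_counts[s] > 1 or tgt_counts[t] > 1:
            dropped += 1
            continue
        pairs[s] = t
    if dropped:
        logger.info("%s: dropped %d non-one-to-one ortholog rows", path, dropped)
    return OrthologMap(pairs=pairs, policy=policy)


def read_edge_list(path: PathLike) -> EdgeList:
    """Read a 2-3 column TSV of edges; pairs are alphabetized on read."""
    edges: list[tuple[str, str]] = []
    scores: dict[tuple[str, str], float] = {}
    has_scores = False
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip() or line.startswith("#"):
            continue
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) < 2:
            raise FormatError(f"{path}:{lineno}: expected >=2 tab-separated columns")
        pair = make_pair(fields[0], fields[1])
        edges.append(pair)
        if len(fields) >= 3:
            has_scores = True
            try:
                scores[pair] = float(fields[2])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: non-numeric score {fields[2]!r}") from exc
    return EdgeList(edges=edges, scores=scores if has_scores else None)


def write_edge_list(network: EdgeList, path: PathLike) -> None:
    with open(path, "w") as fh:
        for a, b in sorted(network.edges):
            if network.scores is not None:
                fh.write(f"{a}\t{b}\t{network.scores[(a, b)]:.10g}\n")
            else:
                fh.write(f"{a}\t{b}\n")


# ---------------------------------------------------------------------------
# Generic elution-matrix TSV (simulator output / cleaned matrices)
# ---------------------------------------------------------------------------


def write_elution_matrix(matrix: ElutionMatrix, path: PathLike, missing: str = "NA") -> None:
    """Write a matrix as ``protein<TAB>F1..Fn`` with NA for missing values."""
    with open(path, "w") as fh:
        cols = "\t".join(f"F{i}" for i in matrix.fractions)
        fh.write(f"protein\t{cols}\n")
        for name, row in zip(matrix.proteins, matrix.intensities):
            cells = "\t".join(missing if np.isnan(v) else f"{v:.10g}" for v in row)
            fh.write(f"{name}\t{cells}\n")


def read_elution_matrix(
    path: PathLike, experiment_id: Optional[str] = None, species: str = ""
) -> ElutionMatrix:
    """Read the generic elution-matrix TSV written by :func:`write_elution_matrix`."""
    df = _read_tsv(path)
    if "protein" not in df.columns:
        raise FormatError(f"{path}: missing 'protein' identifier column")
    frac_cols = [c for c in df.columns if c != "protein"]
    if not frac_cols:
        raise FormatError(f"{path}: no fraction columns")
    values = np.empty((len(df), len(frac_cols)), dtype=float)
    for j, col in enumerate(frac_cols):
        for i, cell in enumerate(df[col]):
            values[i, j] = _parse_intensity(cell, i, col, path)
    return ElutionMatrix(
        experiment_id=experiment_id or Path(path).stem,
        species=species,
        proteins=[p.strip() for p in df["protein"]],
        intensities=values,
    )
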