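"""Readers, writers and row-level filters for the standard file dialects.

Protein-group tables follow the MaxQuant ``proteinGroups.txt`` dialect:
tab-separated, one row per protein group, per-channel columns named
``Reporter intensity corrected <channel> <plex>``, and "+"-flag columns
``Reverse``, ``Potential contaminant`` and ``Only identified by site``.
Zero or blank intensity cells are stored as missing (NaN): reporter-ion
zeros are absent measurements, and treating them as numeric zero would
produce -inf at the log2 step.

The channel design table is a TSV with columns sample_id, plex, channel,
role (experimental | pooled_reference), sex (M | F | none) and treatment
(control | nicotine | none).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .containers import (CHANNEL_COLUMNS, EdgeTable, GeneSetCollection,
                         IntensityMatrix, validate_channels)
from .errors import DesignError, FormatError

log = logging.getLogger(__name__)

COL_PROTEIN = "Protein IDs"
COL_GENE = "Gene names"
COL_REVERSE = "Reverse"
COL_CONTAMINANT = "Potential contaminant"
COL_ONLY_SITE = "Only identified by site"

_FLAG_MAP = {
    COL_REVERSE: "is_reverse",
    COL_CONTAMINANT: "is_contaminant",
    COL_ONLY_SITE: "only_identified_by_site",
}


def reporter_column(channel: int, plex) -> str:
    return f"Reporter intensity corrected {channel} {plex}"


def read_design(path) -> pd.DataFrame:
    design = pd.read_csv(path, sep="\t", dtype=str)
    required = ["sample_id", *CHANNEL_COLUMNS]
    missing = [c for c in required if c not in design.columns]
    if missing:
        raise FormatError(f"design table missing required column(s): {missing}")
    design = design.set_index("sample_id")
    design["channel"] = design["channel"].astype(int)
    validate_channels(design)
    return design


def read_protein_groups(path, design_path) -> IntensityMatrix:
    """Load a protein-group TSV against its channel design.

    Returns a raw-scale :class:`IntensityMatrix`. Flags are parsed with the
    MaxQuant convention ("+" means flagged). The first listed gene name of a
    group is used as its symbol; the choice is recorded in ``meta``.
    """
    design = read_design(design_path)
    table = pd.read_csv(path, sep="\t", dtype=str)

    if COL_PROTEIN not in table.columns:
        raise FormatError(f"protein-group table missing required column: {COL_PROTEIN!r}")
    for sid, row in design.iterrows():
        col = reporter_column(row["channel"], row["plex"])
        if col not in table.columns:
            raise FormatError(f"protein-group table missing required column: {col!r}")
    # channel-count consistency: reporter columns present per plex must match design
    prefix = "Reporter intensity corrected "
    for plex in dict.fromkeys(design["plex"]):
        in_table = [c for c in table.columns
                    if c.startswith(prefix) and c.rsplit(" ", 1)[-1] == str(plex)]
        n_design = int((design["plex"] == plex).sum())
        if len(in_table) != n_design:
            raise DesignError(
                f"plex {plex!r}: {len(in_table)} reporter columns in table but "
                f"{n_design} channels in design")

    protein_ids = table[COL_PROTEIN].astype(str)
    if protein_ids.isna().any() or (protein_ids == "").any():
        raise FormatError("empty protein id")
    if protein_ids.duplicated().any():
        raise FormatError("duplicate protein ids in table")

    records = pd.DataFrame(index=pd.Index(protein_ids, name="protein_id"))
    genes = table.get(COL_GENE, pd.Series("", index=table.index)).fillna("")
    records["gene_name"] = [g.split(";")[0].strip() for g in genes.astype(str)]
    for col, field in _FLAG_MAP.items():
        if col in table.columns:
            records[field] = (table[col].fillna("") == "+").to_numpy()
        else:
            records[field] = False

    values = pd.DataFrame(index=records.index)
    for sid, row in design.iterrows():
        col = reporter_column(row["channel"], row["plex"])
        v = pd.to_numeric(table[col], errors="coerce").to_numpy(dtype=float)
        v[v == 0.0] = np.nan  # zero reporter intensity = missing
        if np.nanmin(v, initial=np.inf) < 0:
            raise FormatError(f"negative intensity in column {col!r}")
        values[sid] = v

    m = IntensityMatrix(values, records, design, scale="raw")
    m.meta["gene_symbol_rule"] = "first listed gene name per protein group"
    return m


def write_protein_groups(matrix: IntensityMatrix, path, design_path=None) -> None:
    """Write the MaxQuant-dialect TSV (round-trips with read_protein_groups)."""
    out = pd.DataFrame()
    out[COL_PROTEIN] = matrix.values.index
    out[COL_GENE] = matrix.records["gene_name"].to_numpy()
    for sid, row in matrix.channels.iterrows():
        col = reporter_column(row["channel"], row["plex"])
        v = matrix.values[sid].to_numpy(dtype=float)
        out[col] = ["" if np.isnan(x) else np.format_float_positional(x, trim="0")
                    for x in v]
    for col, fieldname in _FLAG_MAP.items():
        out[col] = np.where(matrix.records[fieldname].to_numpy(), "+", "")
    out.to_csv(path, sep="\t", index=False)
    if design_path is not None:
        write_design(matrix.channels, design_path)


def write_design(channels: pd.DataFrame, path) -> None:
    channels.rename_axis("sample_id").reset_index().to_csv(path, sep="\t", index=False)


def filter_rows(matrix: IntensityMatrix) -> IntensityMatrix:
    """Remove flagged rows, then rows with any missing value.

    Mirrors the pre-statistics filtering convention for protein-group tables:
    decoy ("reverse"), contaminant and only-identified-by-site groups are
    removed, and a protein must be quantified in every channel of the table
    to survive. Survivor order and values are untouched; drop counts are
    recorded in ``meta``. An empty result is a warning, not an error.
    """
    r = matrix.records
    flagged = (r["is_reverse"] | r["is_contaminant"] | r["only_identified_by_site"])
    keep = matrix.values.index[~flagged]
    n_flagged = int(flagged.sum())
    vals = matrix.values.loc[keep]
    has_missing = vals.isna().any(axis=1)
    keep = keep[~has_missing.to_numpy()]
    n_missing = int(has_missing.sum())
    out = matrix.subset_rows(keep)
    out.meta["n_dropped_flagged"] = n_flagged
    out.meta["n_dropped_missing"] = n_missing
    if out.n_proteins == 0:
        log.warning("filter_rows: no proteins survive filtering")
    return out


def read_gmt(path) -> GeneSetCollection:
    """Read a GMT file (name, description, tab-separated members)."""
    sets, descriptions = {}, {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}: line {lineno}: GMT line needs >=3 fields")
            name, desc, *members = fields
            members = [m for m in members if m.strip()]
            if not members:
                raise FormatError(f"{path}: line {lineno}: gene set {name!r} has no members")
            sets[name] = members
            descriptions[name] = desc
    return GeneSetCollection(sets, descriptions)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for name, members in collection:
            desc = collection.descriptions.get(name, "")
            fh.write("\t".join([name, desc, *sorted(members)]) + "\n")


def read_edge_table(path, score_scale: str = "unit") -> EdgeTable:
    """Read a TSV edge list (a, b, score).

    ``score_scale`` declares the score range: ``unit`` for [0, 1] or
    ``string_0_1000`` for the STRING-export 0..1000 integer combined score
    (divided by 1000 on load). Self-loops are dropped; duplicate undirected
    edges keep the maximum score.
    """
    if score_scale not in ("unit", "string_0_1000"):
        raise FormatError(f"unknown score_scale: {score_scale!r}")
    raw = pd.read_csv(path, sep="\t", header=None, dtype=str, comment=None)
    if raw.shape[1] < 3:
        raise FormatError("edge table needs at least 3 tab-separated columns")
    # tolerate a single header line (non-numeric score cell)
    first_score = pd.to_numeric(raw.iloc[0, 2], errors="coerce")
    if pd.isna(first_score):
        raw = raw.iloc[1:]
    a = raw.iloc[:, 0].astype(str)
    b = raw.iloc[:, 1].astype(str)
    score = pd.to_numeric(raw.iloc[:, 2], errors="coerce")
    if score.isna().any():
        raise FormatError("non-numeric combined score in edge table")
    hi = 1000.0 if score_scale == "string_0_1000" else 1.0
    if ((score < 0) | (score > hi)).any():
        raise FormatError(f"combined score outside declared range [0, {hi:g}]")
    if score_scale == "string_0_1000":
        score = score / 1000.0
    frame = pd.DataFrame({"protein_a": a, "protein_b": b, "combined_score": score})
    frame = frame[frame["protein_a"] != frame["protein_b"]]
    swap = frame["protein_a"] > frame["protein_b"]
    lo = np.where(swap, frame["protein_b"], frame["protein_a"])
    hi_ = np.where(swap, frame["protein_a"], frame["protein_b"])
    frame = frame.assign(protein_a=lo, protein_b=hi_)
    frame = (frame.groupby(["protein_a", "protein_b"], as_index=False)["combined_score"]
             .max())
    return EdgeTable(frame.reset_index(drop=True))


def write_edge_table(edges: EdgeTable, path) -> None:
    edges.frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
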