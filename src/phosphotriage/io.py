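"""Tabular input/output for phosphosite screens.

All pipeline stages exchange a single wide, tab-delimited table keyed by
``site_id``.  One row is one localized phosphorylation event carrying its
sequence context (a 15-mer window centred on the phosphoacceptor), optional
SILAC log2 ratios per experiment/orientation, and optional TMT reporter
intensities for the ten genotype x time-point conditions.

Rows that violate the site invariants (window length, centre residue,
position, localization probability) are never silently dropped: readers
return them in a rejects table with a per-row reason.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

WINDOW_LENGTH = 15
CENTER_INDEX = 7  # 0-based index of the phosphoacceptor (1-based char 8)
PAD = "_"
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
PHOSPHOACCEPTORS = ("S", "T", "Y")

EXPERIMENTS = (1, 2, 3)
GENOTYPES = ("WT", "DKO")
TIMEPOINTS = ("0", "10", "30", "60", "RF")
#: Fixed condition order used everywhere correlation over the 10 conditions
#: is computed: WT time course first, then DKO.
TMT_CONDITIONS = tuple(f"{g}_{t}" for g in GENOTYPES for t in TIMEPOINTS)

SITE_COLUMNS = (
    "site_id",
    "gene",
    "protein",
    "residue",
    "position",
    "window",
    "localization_prob",
)


def silac_col(experiment: int, kind: str) -> str:
    """Column name for a SILAC measurement; kind is 'fwd', 'rev' or 'ctrl'."""
    if experiment not in EXPERIMENTS:
        raise ValueError(f"unknown experiment {experiment!r}")
    if kind not in ("fwd", "rev", "ctrl"):
        raise ValueError(f"unknown SILAC measurement kind {kind!r}")
    return f"silac_exp{experiment}_{kind}"


def tmt_col(condition: str) -> str:
    if condition not in TMT_CONDITIONS:
        raise ValueError(f"unknown TMT condition {condition!r}")
    return f"tmt_{condition}"


SILAC_COLUMNS = tuple(
    silac_col(e, k) for e in EXPERIMENTS for k in ("fwd", "rev", "ctrl")
)
TMT_COLUMNS = tuple(tmt_col(c) for c in TMT_CONDITIONS)
CANONICAL_ORDER = SITE_COLUMNS + SILAC_COLUMNS + TMT_COLUMNS


class MissingColumnError(ValueError):
    """A mandatory column is absent from an input table."""


@dataclass
class SiteTable:
    """Validated phosphosite table plus the rows that failed validation."""

    sites: pd.DataFrame
    rejects: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:  # pragma: no cover - trivial
        return len(self.sites)


def make_site_id(gene: str, residue: str, position: int) -> str:
    return f"{gene}_{residue}{position}"


def _to_float(value) -> float:
    # python float() round-trips repr exactly; pandas' fast parser does not
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return math.nan
    try:
        return float(value)
    except (TypeError, ValueError):
        return math.nan


def _coerce_numeric(df: pd.DataFrame, columns: Iterable[str]) -> None:
    for col in columns:
        if col in df.columns:
            df[col] = df[col].map(_to_float)


def read_phosphosite_table(
    path: str | Path,
    dialect: Mapping[str, str] | None = None,
    collapse_duplicates: bool = True,
) -> SiteTable:
    """Read a tab-delimited phosphosite table.

    Parameters
    ----------
    path:
        Tab-delimited file with a header row.
    dialect:
        Optional mapping ``canonical column -> column name in the file``
        so that externally produced exports (e.g. search-engine site
        tables) parse without renaming on disk.
    collapse_duplicates:
        Collapse multiplicity variants of one site -- rows sharing
        (gene, position, residue) -- to the best-localized record.

    Returns a :class:`SiteTable`; rows violating site invariants land in
    ``rejects`` with a ``reject_reason`` column.  A missing mandatory
    column raises :class:`MissingColumnError` naming the column.
    """
    df = pd.read_csv(path, sep="\t", dtype=str, comment=None, float_precision="round_trip")
    if dialect:
        df = df.rename(columns={v: k for k, v in dialect.items()})

    mandatory = ("gene", "residue", "position", "window", "localization_prob")
    for col in mandatory:
        if col not in df.columns:
            raise MissingColumnError(f"mandatory column {col!r} not found")

    df = df.copy()
    _coerce_numeric(df, ("position", "localization_prob"))
    _coerce_numeric(df, SILAC_COLUMNS)
    _coerce_numeric(df, TMT_COLUMNS)
    return validate_sites(df, collapse_duplicates=collapse_duplicates)


def validate_sites(df: pd.DataFrame, collapse_duplicates: bool = True) -> SiteTable:
    """Apply the site invariants row-wise, splitting valid rows from rejects."""
    df = df.copy()
    window = df["window"].fillna("").astype(str)
    residue = df["residue"].fillna("").astype(str)

    reasons = pd.Series([""] * len(df), index=df.index, dtype=object)

    def flag(mask: pd.Series, reason: str) -> None:
        fresh = mask & (reasons == "")
        reasons[fresh] = reason

    flag(~residue.isin(PHOSPHOACCEPTORS), "residue not in {S,T,Y}")
    flag(window.str.len() != WINDOW_LENGTH, "window length")
    center = window.str.slice(CENTER_INDEX, CENTER_INDEX + 1)
    flag((window.str.len() == WINDOW_LENGTH) & (center != residue), "window center mismatch")
    flag(df["position"].isna() | (df["position"] < 1), "position")
    flag(
        df["localization_prob"].isna()
        | (df["localization_prob"] < 0)
        | (df["localization_prob"] > 1),
        "localization_prob out of [0,1]",
    )

    bad = reasons != ""
    rejects = df.loc[bad].copy()
    rejects["reject_reason"] = reasons[bad]
    sites = df.loc[~bad].copy()
    sites["position"] = sites["position"].astype(int)
    sites["localization_prob"] = sites["localization_prob"].astype(float)

    if "protein" not in sites.columns:
        sites["protein"] = sites["gene"]
    if "site_id" not in sites.columns or sites["site_id"].isna().any():
        sites["site_id"] = [
            make_site_id(g, r, p)
            for g, r, p in zip(sites["gene"], sites["residue"], sites["position"])
        ]

    if collapse_duplicates:
        sites = sites.sort_values(
            ["gene", "position", "residue", "localization_prob", "site_id"],
            ascending=[True, True, True, False, True],
            kind="mergesort",
        )
        sites = sites.drop_duplicates(subset=["gene", "position", "residue"], keep="first")
        sites = sites.sort_index()

    dup = sites["site_id"].duplicated()
    if dup.any():
        raise ValueError(
            "duplicate site_id after validation: "
            + ", ".join(sites.loc[dup, "site_id"].head(5))
        )
    return SiteTable(sites=sites.reset_index(drop=True), rejects=rejects.reset_index(drop=True))


def apply_localization_filter(sites: pd.DataFrame, min_prob: float) -> pd.DataFrame:
    """Retain sites with localization probability >= ``min_prob``."""
    if not 0.0 <= min_prob <= 1.0:
        raise ValueError(f"min_prob must be in [0,1], got {min_prob}")
    return sites.loc[sites["localization_prob"] >= min_prob].reset_index(drop=True)


def write_results(records: pd.DataFrame, path: str | Path) -> None:
    """Write a results table: deterministic column order, UTF-8, tab-delimited.

    Known canonical columns come first in canonical order; any extra
    columns follow in their existing order.  Writing then re-reading then
    re-writing is byte-identical for valid tables.
    """
    known = [c for c in CANONICAL_ORDER if c in records.columns]
    extra = [c for c in records.columns if c not in known]
    out = records[known + extra]
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    out.to_csv(path, sep="\t", index=False, lineterminator="\n", encoding="utf-8")


def read_results(path: str | Path) -> pd.DataFrame:
    """Read a table written by :func:`write_results` without re-validating."""
    return pd.read_csv(path, sep="\t", float_precision="round_trip")


# ---------------------------------------------------------------------------
# Edge lists and ortholog window pairs


def read_edge_list(path: str | Path) -> nx.Graph:
    """Two tab-separated symbol columns; '#' comment lines ignored.

    Symbols are uppercase-normalized; self-loops dropped.
    """
    graph = nx.Graph()
    with open(path, encoding="utf-8") as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise ValueError(f"edge line needs two columns: {line!r}")
            a, b = parts[0].strip().upper(), parts[1].strip().upper()
            if a == b:
                continue
            graph.add_edge(a, b)
    return graph


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("# protein_a\tprotein_b\n")
        for a, b in sorted(tuple(sorted(e)) for e in graph.edges()):
            fh.write(f"{a}\t{b}\n")


def read_ortholog_table(path: str | Path) -> pd.DataFrame:
    """Ortholog window pairs: site_id, window_mouse, window_human."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("site_id", "window_mouse", "window_human"):
        if col not in df.columns:
            raise MissingColumnError(f"ortholog table missing column {col!r}")
    return df


# ---------------------------------------------------------------------------
# Optional FASTA-derived windows


def window_from_sequence(sequence: str, position: int) -> str:
    """±7-residue window around a 1-based position, '_'-padded at termini."""
    if position < 1 or position > len(sequence):
        raise ValueError(f"position {position} outside sequence of length {len(sequence)}")
    idx = position - 1
    left = sequence[max(0, idx - 7) : idx]
    right = sequence[idx + 1 : idx + 8]
    return PAD * (7 - len(left)) + left + sequence[idx] + right + PAD * (7 - len(right))


def windows_from_fasta(
    fasta_path: str | Path, sites: pd.DataFrame, id_column: str = "protein"
) -> pd.Series:
    """Derive windows from a FASTA of protein sequences.

    Used when the input table lacks a window column; sequences are looked
    up by the accession in ``id_column``.
    """
    from Bio import SeqIO

    seqs = {rec.id: str(rec.seq) for rec in SeqIO.parse(str(fasta_path), "fasta")}
    out = []
    for acc, pos in zip(sites[id_column], sites["position"]):
        if acc not in seqs:
            out.append(math.nan)
        else:
            out.append(window_from_sequence(seqs[acc], int(pos)))
    return pd.Series(out, index=sites.index, name="window")
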