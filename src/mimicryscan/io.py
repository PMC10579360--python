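"""Readers and writers for the file formats the pipeline touches.

Proteins travel as FASTA; epitope catalogs, HLA binding predictions, ELISA
optical densities, reactive-antigen lists and hit reports are UTF-8
delimited tables with a header row (tab-separated by default, comma for
``.csv`` paths). Epitope-catalog column names vary between export dialects,
so :func:`read_epitope_table` takes a user-supplied column map with
sensible defaults.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
from Bio import SeqIO

from .types import (
    BindingRecord,
    ELISAMeasurement,
    Epitope,
    FormatError,
    ProteinSequence,
)

__all__ = [
    "read_fasta",
    "read_epitope_table",
    "read_binding_table",
    "read_elisa_table",
    "read_reactive_list",
    "write_reactive_list",
    "write_hits_report",
    "read_hits_report",
    "DEFAULT_EPITOPE_COLUMNS",
]

#: Default column map for epitope catalogs, modeled on a typical linear-
#: epitope export (one row per epitope, semicolon-separated multi-values).
DEFAULT_EPITOPE_COLUMNS: Mapping[str, str] = {
    "epitope_id": "epitope_id",
    "sequence": "sequence",
    "parent_antigen": "parent_antigen",
    "antigen_accession": "antigen_accession",
    "diseases": "diseases",
    "assay_classes": "assay_classes",
    "outcome": "outcome",
}

_POSITIVE = {"positive", "pos", "1", "true", "yes", "y"}


def _sep(path: str | Path) -> str:
    return "," if str(path).endswith(".csv") else "\t"


def read_fasta(path: str | Path) -> list[ProteinSequence]:
    """Read protein sequences from a FASTA file, in file order.

    Residues are upper-cased and validated against the accepted alphabet;
    an illegal character raises :class:`FormatError` naming the record.
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FormatError(f"{path}: no FASTA records found")
    out = []
    for rec in records:
        out.append(
            ProteinSequence(
                id=rec.id, residues=str(rec.seq), name=rec.description
            )
        )
    return out


def _split_multi(value) -> frozenset[str]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return frozenset()
    parts = str(value).replace(",", ";").split(";")
    return frozenset(p.strip() for p in parts if p.strip())


def read_epitope_table(
    path: str | Path,
    column_map: Mapping[str, str] | None = None,
) -> list[Epitope]:
    """Read an epitope catalog from a delimited table.

    Only rows with a positive assay outcome are retained, and duplicate
    (sequence, parent antigen) rows are collapsed with their disease and
    assay tags merged. ``column_map`` maps the logical field names
    (``sequence``, ``parent_antigen``, ``diseases``, ...) to the table's
    column headers; missing mapped columns raise :class:`FormatError`
    (``antigen_accession``, ``assay_classes`` and ``epitope_id`` are
    optional).
    """
    cmap = dict(DEFAULT_EPITOPE_COLUMNS)
    if column_map:
        cmap.update(column_map)
    df = pd.read_csv(path, sep=_sep(path), dtype=str)
    required = ("sequence", "parent_antigen", "diseases", "outcome")
    for field in required:
        if cmap[field] not in df.columns:
            raise FormatError(
                f"{path}: mapped column {cmap[field]!r} for field "
                f"{field!r} not found (have: {', '.join(df.columns)})"
            )
    merged: dict[tuple[str, str], Epitope] = {}
    for idx, row in df.iterrows():
        outcome = str(row[cmap["outcome"]]).strip().lower()
        if outcome not in _POSITIVE:
            continue
        seq = row[cmap["sequence"]]
        if not isinstance(seq, str) or not seq.strip():
            raise FormatError(f"{path}: line {idx + 2}: empty sequence cell")
        seq = seq.strip().upper()
        antigen = str(row[cmap["parent_antigen"]]).strip()
        acc_col = cmap.get("antigen_accession")
        accession = None
        if acc_col and acc_col in df.columns:
            v = row[acc_col]
            if isinstance(v, str) and v.strip():
                accession = v.strip()
        id_col = cmap.get("epitope_id")
        eid = (
            str(row[id_col]).strip()
            if id_col and id_col in df.columns and isinstance(row[id_col], str)
            else f"E{idx + 1:06d}"
        )
        diseases = _split_multi(row[cmap["diseases"]])
        assays_col = cmap.get("assay_classes")
        assays = (
            _split_multi(row[assays_col])
            if assays_col and assays_col in df.columns
            else frozenset()
        )
        key = (seq, antigen)
        if key in merged:
            prev = merged[key]
            merged[key] = Epitope(
                epitope_id=prev.epitope_id,
                sequence=seq,
                parent_antigen=antigen,
                antigen_accession=prev.antigen_accession or accession,
                diseases=prev.diseases | diseases,
                assay_classes=prev.assay_classes | assays,
                positive=True,
            )
        else:
            merged[key] = Epitope(
                epitope_id=eid,
                sequence=seq,
                parent_antigen=antigen,
                antigen_accession=accession,
                diseases=diseases,
                assay_classes=assays,
                positive=True,
            )
    return list(merged.values())


def _parse_float(value, path, line, column) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise FormatError(
            f"{path}: line {line}: malformed numeric value {value!r} "
            f"in column {column!r}"
        )


def read_binding_table(path: str | Path) -> list[BindingRecord]:
    """Read peptide-HLA binding predictions (IC50 in nM) from a table.

    Expected columns: ``peptide``, ``allele``, ``hla_class`` (I or II),
    ``ic50_nM`` and optionally ``percentile_rank``.
    """
    df = pd.read_csv(path, sep=_sep(path), dtype=str)
    for col in ("peptide", "allele", "hla_class", "ic50_nM"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    out = []
    for idx, row in df.iterrows():
        line = idx + 2
        rank = None
        if "percentile_rank" in df.columns:
            v = row["percentile_rank"]
            if isinstance(v, str) and v.strip():
                rank = _parse_float(v, path, line, "percentile_rank")
        out.append(
            BindingRecord(
                peptide=str(row["peptide"]).strip().upper(),
                allele=str(row["allele"]).strip(),
                hla_class=str(row["hla_class"]).strip(),
                ic50_nM=_parse_float(row["ic50_nM"], path, line, "ic50_nM"),
                percentile_rank=rank,
            )
        )
    return out


def read_elisa_table(path: str | Path) -> list[ELISAMeasurement]:
    """Read ELISA optical densities from a table.

    Expected columns: ``antigen``, ``antibody`` and one or more OD columns
    named ``od1``, ``od2``, ... (blank cells allowed past the first).
    """
    df = pd.read_csv(path, sep=_sep(path), dtype=str)
    od_cols = [c for c in df.columns if c.lower().startswith("od")]
    if "antigen" not in df.columns or "antibody" not in df.columns or not od_cols:
        raise FormatError(
            f"{path}: expected columns 'antigen', 'antibody' and 'od1', 'od2', ..."
        )
    out = []
    for idx, row in df.iterrows():
        line = idx + 2
        ods = []
        for c in od_cols:
            v = row[c]
            if v is None or (isinstance(v, float) and math.isnan(v)):
                continue
            if isinstance(v, str) and not v.strip():
                continue
            ods.append(_parse_float(v, path, line, c))
        out.append(
            ELISAMeasurement(
                antigen=str(row["antigen"]).strip(),
                antibody=str(row["antibody"]).strip().lower(),
                ods=tuple(ods),
            )
        )
    return out


def read_reactive_list(path: str | Path) -> set[str]:
    """Read a reactive-antigen list: a table with an ``antigen`` column."""
    df = pd.read_csv(path, sep=_sep(path), dtype=str)
    if "antigen" not in df.columns:
        raise FormatError(f"{path}: missing column 'antigen'")
    return {str(a).strip() for a in df["antigen"] if isinstance(a, str) and a.strip()}


def write_reactive_list(antigens: Iterable[str], path: str | Path) -> None:
    """Write a reactive-antigen list consumable by the screening stage."""
    df = pd.DataFrame({"antigen": sorted(antigens)})
    df.to_csv(path, sep=_sep(path), index=False)


#: Column order of the hit report (the six-pair table layout: human
#: sequence, column count, identity, similarity, target sequence, diseases,
#: plus provenance and filter evidence).
HIT_REPORT_COLUMNS = [
    "epitope_id",
    "parent_antigen",
    "antigen_accession",
    "diseases",
    "human",
    "ln",
    "identity",
    "similarity",
    "mtg",
    "score",
    "q_start",
    "q_end",
    "t_start",
    "t_end",
    "hla1_best_ic50",
    "hla2_best_ic50",
    "cross_reactive",
]


def write_hits_report(hits: Sequence, path: str | Path) -> None:
    """Write one row per mimicry hit in the six-pair table layout.

    An empty hit list yields a header-only file. The report round-trips
    through :func:`read_hits_report`.
    """
    rows = []
    for h in hits:
        a = h.alignment
        rows.append(
            {
                "epitope_id": h.epitope.epitope_id,
                "parent_antigen": h.epitope.parent_antigen,
                "antigen_accession": h.epitope.antigen_accession or "",
                "diseases": ";".join(sorted(h.epitope.diseases)),
                "human": a.aligned_query,
                "ln": a.length,
                "identity": a.n_identity,
                "similarity": a.n_similarity,
                "mtg": a.aligned_target,
                "score": a.score,
                "q_start": a.q_start,
                "q_end": a.q_end,
                "t_start": a.t_start,
                "t_end": a.t_end,
                "hla1_best_ic50": h.best_ic50("I"),
                "hla2_best_ic50": h.best_ic50("II"),
                "cross_reactive": h.cross_reactive,
            }
        )
    df = pd.DataFrame(rows, columns=HIT_REPORT_COLUMNS)
    df.to_csv(path, sep=_sep(path), index=False)


def read_hits_report(path: str | Path) -> pd.DataFrame:
    """Read a hit report back as a DataFrame (columns as written)."""
    df = pd.read_csv(path, sep=_sep(path))
    missing = [c for c in HIT_REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing hit-report columns {missing}")
    return df
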