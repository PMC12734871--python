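"""Reading and writing Compound-Discoverer-style feature tables and ontologies.

Vendor exports vary in column naming, so parsing goes through a small
*dialect*: a mapping from internal field names to column headers.  A default
dialect matching the field list of a CD 3.3 compound export is shipped.
Database-hit evidence may arrive either as one boolean column per source or
as a single delimited list column; both are supported.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

__all__ = [
    "DB_SOURCES",
    "FeatureRecord",
    "Ontology",
    "Dialect",
    "DEFAULT_DIALECT",
    "read_feature_table",
    "write_feature_table",
    "read_ontology",
    "write_ontology",
]

#: The five annotation sources consulted by the screening workflow.
DB_SOURCES = ("mzCloud", "mzVault", "Metabolika", "ChemSpider", "MassList")

_ION_MODES = {"positive", "negative"}


@dataclass(frozen=True)
class FeatureRecord:
    """One detected LC-MS feature with its annotation metadata.

    Masses are in Da, retention time in minutes, peak area in (unitless)
    instrument counts.  ``db_hits`` is the subset of :data:`DB_SOURCES` in
    which the feature found a full or partial match.
    """

    compound_name: str | None
    formula: str | None
    ion_mode: str
    precursor_mz: float
    calc_mw: float
    rt: float
    peak_area: float
    db_hits: frozenset[str] = frozenset()
    has_ms2: bool = False
    msi_level: int = 4
    species: str = ""
    replicate_id: str = ""

    def __post_init__(self) -> None:
        if self.ion_mode not in _ION_MODES:
            raise ValueError(f"ion_mode must be one of {_ION_MODES}, got {self.ion_mode!r}")
        if not self.precursor_mz > 0:
            raise ValueError(f"precursor_mz must be positive, got {self.precursor_mz}")
        if self.rt < 0:
            raise ValueError(f"rt must be nonnegative, got {self.rt}")
        if self.peak_area < 0:
            raise ValueError(f"peak_area must be nonnegative, got {self.peak_area}")
        if self.msi_level not in (1, 2, 3, 4):
            raise ValueError(f"msi_level must be in 1..4, got {self.msi_level}")
        unknown = set(self.db_hits) - set(DB_SOURCES)
        if unknown:
            raise ValueError(f"unknown db sources: {sorted(unknown)}")
        object.__setattr__(self, "db_hits", frozenset(self.db_hits))

    def with_msi_level(self, level: int) -> "FeatureRecord":
        return replace(self, msi_level=level)


class OntologyError(ValueError):
    """Raised when a hierarchy file violates the tree constraint."""


@dataclass(frozen=True)
class Ontology:
    """Three-level natural-product hierarchy: pathway -> superclass -> class.

    Each class has exactly one superclass parent and each superclass exactly
    one pathway parent, i.e. the hierarchy is a forest rooted at pathways.
    """

    pathways: frozenset[str] = frozenset()
    superclass_parent: Mapping[str, str] = field(default_factory=dict)
    class_parent: Mapping[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for sc, pw in self.superclass_parent.items():
            if pw not in self.pathways:
                raise OntologyError(f"superclass {sc!r} points at unknown pathway {pw!r}")
        for cl, sc in self.class_parent.items():
            if sc not in self.superclass_parent:
                raise OntologyError(f"class {cl!r} points at unknown superclass {sc!r}")

    @property
    def superclasses(self) -> frozenset[str]:
        return frozenset(self.superclass_parent)

    @property
    def classes(self) -> frozenset[str]:
        return frozenset(self.class_parent)

    def pathway_of_class(self, cls: str) -> str:
        return self.superclass_parent[self.class_parent[cls]]

    def is_consistent(self, pathway: str, superclass: str, cls: str) -> bool:
        """True iff the three labels form a parent chain in this hierarchy."""
        return (
            self.class_parent.get(cls) == superclass
            and self.superclass_parent.get(superclass) == pathway
        )


@dataclass(frozen=True)
class Dialect:
    """Mapping from internal field names to table column headers.

    ``db_hit_columns`` maps each source to a boolean-ish column; when it is
    empty, ``db_hits_column`` names a single column holding a ``;``-delimited
    source list.  ``ion_mode_values`` translates vendor polarity strings.
    """

    columns: Mapping[str, str]
    db_hit_columns: Mapping[str, str] = field(default_factory=dict)
    db_hits_column: str | None = "Annot. Source"
    ion_mode_values: Mapping[str, str] = field(default_factory=dict)
    delimiter: str = ","

    def ion_mode(self, raw: str) -> str:
        raw = raw.strip()
        mapped = self.ion_mode_values.get(raw, raw).lower()
        if mapped in ("+", "pos", "positive", "esi+", "esi pos"):
            return "positive"
        if mapped in ("-", "neg", "negative", "esi-", "esi−", "esi neg"):
            return "negative"
        raise ValueError(f"unrecognized ion mode value {raw!r}")


#: Headers reconstructed from the CD 3.3 compound-export field list.
DEFAULT_DIALECT = Dialect(
    columns={
        "compound_name": "Name",
        "formula": "Formula",
        "ion_mode": "Ion Mode",
        "precursor_mz": "m/z",
        "calc_mw": "Calc. MW",
        "rt": "RT [min]",
        "peak_area": "Area (Max.)",
        "has_ms2": "MS2",
        "msi_level": "MSI Level",
        "species": "Species",
        "replicate_id": "Replicate",
    },
    db_hits_column="Annot. Source",
)

_MANDATORY = ("ion_mode", "precursor_mz", "calc_mw", "rt", "peak_area")
_TRUE_STRINGS = {"1", "true", "yes", "y", "ddms2", "checked"}


class TableFormatError(ValueError):
    """Raised for a malformed feature table (missing column, bad cell)."""


def _parse_bool(raw: str) -> bool:
    return raw.strip().lower() in _TRUE_STRINGS


def read_feature_table(
    path: str | Path, dialect: Dialect = DEFAULT_DIALECT
) -> list[FeatureRecord]:
    """Parse a delimited feature table into :class:`FeatureRecord` objects.

    Raises :class:`TableFormatError` naming the column if a mandatory mapped
    column is missing, or naming the (1-based) data row on an unparseable
    numeric cell.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=dialect.delimiter)
        header = reader.fieldnames or []
        for fld in _MANDATORY:
            col = dialect.columns.get(fld)
            if col is None or col not in header:
                raise TableFormatError(
                    f"mandatory column {col!r} (field {fld!r}) missing from {path.name}"
                )
        records: list[FeatureRecord] = []
        for idx, row in enumerate(reader, start=1):
            records.append(_row_to_record(row, idx, dialect))
    return records


def _row_to_record(row: Mapping[str, str], idx: int, dialect: Dialect) -> FeatureRecord:
    cols = dialect.columns

    def cell(fld: str) -> str | None:
        col = cols.get(fld)
        if col is None or col not in row:
            return None
        val = row[col]
        return val if val is not None and val.strip() != "" else None

    def num(fld: str) -> float:
        raw = cell(fld)
        try:
            return float(raw)  # type: ignore[arg-type]
        except (TypeError, ValueError):
            raise TableFormatError(
                f"row {idx}: cannot parse {fld!r} value {raw!r} as a number"
            ) from None

    hits: set[str] = set()
    if dialect.db_hit_columns:
        for source, col in dialect.db_hit_columns.items():
            if col in row and _parse_bool(row[col] or ""):
                hits.add(source)
    elif dialect.db_hits_column and dialect.db_hits_column in row:
        raw = row[dialect.db_hits_column] or ""
        hits = {tok.strip() for tok in raw.split(";") if tok.strip()}

    msi_raw = cell("msi_level")
    ms2_raw = cell("has_ms2")
    return FeatureRecord(
        compound_name=cell("compound_name"),
        formula=cell("formula"),
        ion_mode=dialect.ion_mode(cell("ion_mode") or ""),
        precursor_mz=num("precursor_mz"),
        calc_mw=num("calc_mw"),
        rt=num("rt"),
        peak_area=num("peak_area"),
        db_hits=frozenset(hits),
        has_ms2=_parse_bool(ms2_raw or ""),
        msi_level=int(msi_raw) if msi_raw else 4,
        species=cell("species") or "",
        replicate_id=cell("replicate_id") or "",
    )


def write_feature_table(
    records: Iterable[FeatureRecord],
    path: str | Path,
    dialect: Dialect = DEFAULT_DIALECT,
) -> None:
    """Write records as delimited text readable by :func:`read_feature_table`.

    Numeric fields are rendered with ``repr`` so a read-back round-trips
    exactly; booleans as ``True``/``False``; db hits as a ``;`` list.
    """
    cols = dialect.columns
    header = [cols[f] for f in cols]
    if not dialect.db_hit_columns and dialect.db_hits_column:
        header.append(dialect.db_hits_column)
    elif dialect.db_hit_columns:
        header.extend(dialect.db_hit_columns.values())
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=dialect.delimiter)
        writer.writerow(header)
        for rec in records:
            row = []
            for fld in cols:
                val = getattr(rec, fld)
                if isinstance(val, float):
                    row.append(repr(val))
                elif val is None:
                    row.append("")
                else:
                    row.append(str(val))
            if not dialect.db_hit_columns and dialect.db_hits_column:
                row.append(";".join(s for s in DB_SOURCES if s in rec.db_hits))
            elif dialect.db_hit_columns:
                row.extend(
                    "True" if src in rec.db_hits else "False"
                    for src in dialect.db_hit_columns
                )
            writer.writerow(row)


def read_ontology(path: str | Path) -> Ontology:
    """Load a (pathway, superclass, class) triple file into an :class:`Ontology`.

    Triples may repeat; conflicts (a class or superclass claiming two distinct
    parents) raise :class:`OntologyError` listing the offender.
    """
    pathways: set[str] = set()
    sc_parent: dict[str, str] = {}
    cl_parent: dict[str, str] = {}
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        rows = [r for r in reader if r and any(c.strip() for c in r)]
    if rows and [c.strip().lower() for c in rows[0][:3]] == ["pathway", "superclass", "class"]:
        rows = rows[1:]
    for row in rows:
        if len(row) < 3:
            raise OntologyError(f"expected 3 columns, got {row!r}")
        pw, sc, cl = (c.strip() for c in row[:3])
        pathways.add(pw)
        if sc in sc_parent and sc_parent[sc] != pw:
            raise OntologyError(
                f"superclass {sc!r} has two parents: {sc_parent[sc]!r} and {pw!r}"
            )
        sc_parent[sc] = pw
        if cl:
            if cl in cl_parent and cl_parent[cl] != sc:
                raise OntologyError(
                    f"class {cl!r} has two parents: {cl_parent[cl]!r} and {sc!r}"
                )
            cl_parent[cl] = sc
    return Ontology(frozenset(pathways), sc_parent, cl_parent)


def write_ontology(ontology: Ontology, path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["pathway", "superclass", "class"])
        seen_sc = set()
        for cl in sorted(ontology.class_parent):
            sc = ontology.class_parent[cl]
            seen_sc.add(sc)
            writer.writerow([ontology.superclass_parent[sc], sc, cl])
        for sc in sorted(ontology.superclass_parent):
            if sc not in seen_sc:
                writer.writerow([ontology.superclass_parent[sc], sc, ""])
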