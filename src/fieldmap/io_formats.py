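"""Readers, writers and validated in-memory containers for all tabular formats.

Every file is tab-separated UTF-8 with a header row, decimal point, no
thousands separators.  Numeric output is written at 6 significant digits and
round-trips bit-exactly at that precision.

The 96 trinucleotide motifs follow the COSMIC convention: substitution-major
order (C>A, C>G, C>T, T>A, T>C, T>G), then the 5' base in A,C,G,T order, then
the 3' base in A,C,G,T order.  A motif is written ``5'[REF>ALT]3'``, e.g.
``A[C>T]G``.
"""

from __future__ import annotations

import json
import hashlib
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "GRADES",
    "GROUPS",
    "GRADE_TO_GROUP",
    "SUBSTITUTIONS",
    "MOTIFS_96",
    "MUTATION_TYPES",
    "parse_context",
    "FieldMap",
    "MutationTable",
    "OmicsMatrix",
    "SignatureCatalog",
    "read_field_map",
    "read_mutation_table",
    "read_gmt",
    "read_signature_catalog",
    "read_matrix",
    "write_field_map",
    "write_mutation_table",
    "write_matrix",
    "write_signature_catalog",
    "write_gmt",
    "write_results",
    "write_manifest",
]


class FormatError(ValueError):
    """Raised when an input file violates the format contract."""


GRADES = ("NU", "LGIN", "HGIN", "UC")
GROUPS = ("NU_LGIN", "HGIN", "UC")
GRADE_TO_GROUP = {"NU": "NU_LGIN", "LGIN": "NU_LGIN", "HGIN": "HGIN", "UC": "UC"}

SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")
MUTATION_TYPES = ("SNV", "INS", "DEL")
_BASES = ("A", "C", "G", "T")

#: canonical 96-motif ordering, substitution-major then 5' then 3' base
MOTIFS_96 = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in _BASES
    for three in _BASES
)
MOTIF_INDEX = {m: i for i, m in enumerate(MOTIFS_96)}

_FLOAT_FMT = "%.6g"


def parse_context(context: str) -> tuple[str, str]:
    """Split a trinucleotide motif into (substitution class, motif).

    >>> parse_context("A[C>T]G")
    ('C>T', 'A[C>T]G')
    """
    if context not in MOTIF_INDEX:
        raise FormatError(
            f"invalid trinucleotide context {context!r}; expected e.g. 'A[C>T]G' "
            "with a pyrimidine-normalized substitution"
        )
    return context[2:5], context


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FieldMap:
    """Spatial grid of mucosal fields with histology grades.

    ``table`` is indexed by ``field_id`` with columns ``row``, ``col``,
    ``grade`` and the derived 3-level ``group`` (NU and LGIN pool to NU_LGIN).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        t = self.table
        required = {"row", "col", "grade"}
        if missing := required - set(t.columns):
            raise FormatError(f"field map missing columns: {sorted(missing)}")
        if t.index.duplicated().any():
            dupes = sorted(t.index[t.index.duplicated()].unique())
            raise FormatError(f"duplicate field_id values: {dupes}")
        bad = sorted(set(t["grade"]) - set(GRADES))
        if bad:
            raise FormatError(
                f"unknown histology grade(s) {bad}; allowed values are {list(GRADES)}"
            )
        coords = list(zip(t["row"], t["col"]))
        if len(set(coords)) != len(coords):
            raise FormatError("duplicate grid coordinates in field map")
        if "group" not in t.columns:
            t["group"] = t["grade"].map(GRADE_TO_GROUP)
        elif not (t["group"] == t["grade"].map(GRADE_TO_GROUP)).all():
            raise FormatError("group column inconsistent with grade mapping")

    @property
    def field_ids(self) -> list[str]:
        return list(self.table.index)

    @property
    def n_fields(self) -> int:
        return len(self.table)

    def fields_in_group(self, group: str) -> list[str]:
        if group not in GROUPS:
            raise ValueError(f"unknown group {group!r}; expected one of {list(GROUPS)}")
        return list(self.table.index[self.table["group"] == group])

    def group_of(self) -> pd.Series:
        return self.table["group"]


@dataclass(frozen=True)
class MutationTable:
    """Per-mutation annotations plus a mutation x field VAF matrix.

    ``meta`` is indexed by ``mutation_id`` with columns ``gene``, ``locus``,
    ``mtype``, ``substitution``, ``context``, ``silent``.  ``vaf`` shares the
    index and has one column per field, in FieldMap order.  Absent
    mutation/field pairs are 0, not NA.
    """

    meta: pd.DataFrame
    vaf: pd.DataFrame
    vaf_scale: str = "fraction"  # 'fraction' or 'percent' as read from disk

    def __post_init__(self) -> None:
        if not self.meta.index.equals(self.vaf.index):
            raise FormatError("meta and vaf indices disagree")
        if self.meta.index.duplicated().any():
            raise FormatError("duplicate mutation_id values")
        vals = self.vaf.to_numpy(dtype=float)
        if np.isnan(vals).any():
            raise FormatError("VAF matrix contains NA; absent cells must be 0")
        if (vals < 0).any() or (vals > 1).any():
            raise FormatError("VAF values must lie in [0, 1]")
        bad_type = set(self.meta["mtype"]) - set(MUTATION_TYPES)
        if bad_type:
            raise FormatError(f"unknown mutation type(s): {sorted(bad_type)}")
        snv = self.meta["mtype"] == "SNV"
        ctx = self.meta.loc[snv, "context"]
        bad_ctx = sorted(set(ctx) - set(MOTIFS_96))
        if bad_ctx:
            raise FormatError(f"invalid SNV context(s): {bad_ctx[:5]}")
        sub = self.meta.loc[snv, "substitution"]
        if not (sub == ctx.str.slice(2, 5)).all():
            raise FormatError("substitution column inconsistent with context")
        indel_ctx = self.meta.loc[~snv, "context"]
        if not ((indel_ctx == "") | (indel_ctx == ".")).all():
            raise FormatError("INS/DEL rows must not carry a trinucleotide context")

    @property
    def mutation_ids(self) -> list[str]:
        return list(self.meta.index)

    @property
    def n_mutations(self) -> int:
        return len(self.meta)

    def presence(self, threshold: float = 0.01) -> pd.DataFrame:
        """Boolean mutation x field presence matrix (VAF >= threshold)."""
        return self.vaf >= threshold

    def subset(self, ids: Sequence[str]) -> "MutationTable":
        ids = list(ids)
        return MutationTable(self.meta.loc[ids], self.vaf.loc[ids], self.vaf_scale)


@dataclass(frozen=True)
class OmicsMatrix:
    """Analyte x sample log-scale abundance matrix with designated controls.

    Missing values (NaN) are allowed — proteomic and metabolomic platforms do
    not quantify every analyte in every sample.
    """

    values: pd.DataFrame
    control_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise FormatError("duplicate analyte ids")
        missing = set(self.control_ids) - set(self.values.columns)
        if missing:
            raise FormatError(f"control sample(s) not in matrix: {sorted(missing)}")
        if len(self.control_ids) < 1:
            raise FormatError("at least one control sample is required")
        object.__setattr__(self, "control_ids", tuple(self.control_ids))

    @property
    def analyte_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def map_sample_ids(self) -> list[str]:
        ctrl = set(self.control_ids)
        return [c for c in self.values.columns if c not in ctrl]

    def controls(self) -> pd.DataFrame:
        return self.values[list(self.control_ids)]

    def map_samples(self) -> pd.DataFrame:
        return self.values[self.map_sample_ids]


@dataclass(frozen=True)
class SignatureCatalog:
    """96-context x K reference signature matrix; columns sum to 1."""

    matrix: pd.DataFrame

    def __post_init__(self) -> None:
        m = self.matrix
        if list(m.index) != list(MOTIFS_96):
            if set(m.index) != set(MOTIFS_96):
                raise FormatError("catalog rows must be the 96 canonical motifs")
            object.__setattr__(self, "matrix", m.loc[list(MOTIFS_96)])
            m = self.matrix
        vals = m.to_numpy(dtype=float)
        if (vals < 0).any():
            raise FormatError("catalog entries must be non-negative")
        sums = vals.sum(axis=0)
        if np.any(np.abs(sums - 1.0) > 1e-6):
            bad = [f"{c}={s:.4f}" for c, s in zip(m.columns, sums) if abs(s - 1) > 1e-6]
            raise FormatError(f"catalog columns must sum to 1 (+/-1e-6): {bad}")

    @property
    def signature_names(self) -> list[str]:
        return list(self.matrix.columns)

    @property
    def n_signatures(self) -> int:
        return self.matrix.shape[1]


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------


def _read_tsv(path: str | Path, **kw) -> pd.DataFrame:
    try:
        return pd.read_csv(path, sep="\t", **kw)
    except FileNotFoundError:
        raise
    except Exception as exc:  # malformed file
        raise FormatError(f"cannot parse {path}: {exc}") from exc


def read_field_map(path: str | Path) -> FieldMap:
    """Read a field map TSV with header ``field_id, row, col, grade``."""
    df = _read_tsv(path, dtype={"field_id": str, "grade": str})
    required = {"field_id", "row", "col", "grade"}
    if missing := required - set(df.columns):
        raise FormatError(f"{path}: field map missing columns {sorted(missing)}")
    df = df.set_index("field_id")
    df["row"] = df["row"].astype(int)
    df["col"] = df["col"].astype(int)
    return FieldMap(df[["row", "col", "grade"]].copy())


_MUT_META_COLS = ["gene", "locus", "mtype", "substitution", "context", "silent"]


def read_mutation_table(path: str | Path, field_map: FieldMap) -> MutationTable:
    """Read a MAF-like mutation TSV; VAF columns are named by field_id.

    Fields missing from the file are filled with VAF 0; columns are aligned to
    the FieldMap order regardless of file order.  Tables whose VAFs are
    written as percentages (any value > 1) are auto-detected and rescaled to
    fractions; the choice is recorded on the returned table.
    """
    df = _read_tsv(path, dtype={"mutation_id": str})
    if "mutation_id" not in df.columns:
        raise FormatError(f"{path}: missing mutation_id column")
    df = df.set_index("mutation_id")
    known = set(_MUT_META_COLS)
    vaf_cols = [c for c in df.columns if c not in known]
    unknown = set(vaf_cols) - set(field_map.field_ids)
    if unknown:
        raise FormatError(
            f"{path}: VAF column(s) {sorted(unknown)} do not match any field_id"
        )
    meta = pd.DataFrame(index=df.index)
    meta["gene"] = df.get("gene", pd.Series("", index=df.index)).fillna("")
    if "locus" in df.columns:
        meta["locus"] = df["locus"].fillna(df.index.to_series())
    else:
        meta["locus"] = df.index.to_series()
    meta["mtype"] = df.get("mtype", pd.Series("SNV", index=df.index))
    meta["context"] = df.get("context", pd.Series(".", index=df.index)).fillna(".")
    meta["substitution"] = ""
    snv = meta["mtype"] == "SNV"
    # substitution class is parsed from the context for SNVs
    meta.loc[snv, "substitution"] = [
        parse_context(c)[0] for c in meta.loc[snv, "context"]
    ]
    meta.loc[~snv, "substitution"] = ""
    meta.loc[~snv, "context"] = "."
    if "silent" in df.columns:
        meta["silent"] = df["silent"].astype(bool)
    else:
        meta["silent"] = False

    vaf = pd.DataFrame(0.0, index=df.index, columns=field_map.field_ids)
    present = df[vaf_cols].apply(pd.to_numeric, errors="coerce").fillna(0.0)
    vaf_scale = "fraction"
    vals = present.to_numpy(dtype=float)
    if (vals < 0).any():
        raise FormatError(f"{path}: negative VAF values")
    vmax = vals.max(initial=0.0)
    if vmax > 100:
        raise FormatError(f"{path}: VAF values outside [0, 1] (and [0, 100])")
    if vmax > 2:  # unambiguous percent table (some VAF above 2%)
        present = present / 100.0
        vaf_scale = "percent"
    elif vmax > 1:
        raise FormatError(
            f"{path}: VAF {vmax:g} outside [0, 1] but too small to be an "
            "unambiguous percentage table"
        )
    vaf[present.columns] = present
    return MutationTable(meta[_MUT_META_COLS], vaf, vaf_scale=vaf_scale)


def read_gmt(path: str | Path) -> dict[str, list[str]]:
    """Read gene sets in the standard GMT dialect (name, description, members).

    Empty sets are retained (with a warning) so set names stay addressable.
    """
    import warnings

    sets: dict[str, list[str]] = {}
    with open(path, encoding="utf-8") as fh:
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) < 2:
                raise FormatError(f"{path}:{ln}: GMT line needs name and description")
            name = parts[0]
            members = [g for g in parts[2:] if g]
            if not members:
                warnings.warn(f"{path}:{ln}: gene set {name!r} is empty; retained")
            sets[name] = members
    return sets


def read_signature_catalog(path: str | Path) -> SignatureCatalog:
    df = _read_tsv(path, index_col=0)
    return SignatureCatalog(df.astype(float))


def read_matrix(path: str | Path, controls: Sequence[str]) -> OmicsMatrix:
    """Read an analyte x sample abundance matrix (analytes in rows)."""
    df = _read_tsv(path, index_col=0)
    return OmicsMatrix(df.astype(float), tuple(controls))


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------


def write_field_map(field_map: FieldMap, path: str | Path) -> None:
    out = field_map.table[["row", "col", "grade"]].copy()
    out.index.name = "field_id"
    out.to_csv(path, sep="\t")


def write_mutation_table(table: MutationTable, path: str | Path) -> None:
    out = pd.concat([table.meta[_MUT_META_COLS], table.vaf], axis=1)
    out.index.name = "mutation_id"
    out.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def write_matrix(matrix: OmicsMatrix, path: str | Path) -> None:
    out = matrix.values.copy()
    out.index.name = "analyte_id"
    out.to_csv(path, sep="\t", float_format=_FLOAT_FMT)


def write_signature_catalog(catalog: SignatureCatalog, path: str | Path) -> None:
    out = catalog.matrix.copy()
    out.index.name = "context"
    # full precision: column sums must re-validate to 1 +/- 1e-6 on read
    out.to_csv(path, sep="\t", float_format="%.10g")


def write_gmt(sets: Mapping[str, Iterable[str]], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for name, members in sets.items():
            fh.write("\t".join([name, "na", *members]) + "\n")


def write_results(out_dir: str | Path, objects: Mapping[str, object]) -> list[Path]:
    """Write result tables into ``out_dir`` with stable column order.

    DataFrames/Series go to ``<name>.tsv``; dicts to ``<name>.json``; domain
    containers use their dedicated writers.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    for name, obj in objects.items():
        if isinstance(obj, FieldMap):
            p = out_dir / f"{name}.tsv"
            write_field_map(obj, p)
        elif isinstance(obj, MutationTable):
            p = out_dir / f"{name}.tsv"
            write_mutation_table(obj, p)
        elif isinstance(obj, OmicsMatrix):
            p = out_dir / f"{name}.tsv"
            write_matrix(obj, p)
        elif isinstance(obj, SignatureCatalog):
            p = out_dir / f"{name}.tsv"
            write_signature_catalog(obj, p)
        elif isinstance(obj, pd.Series):
            p = out_dir / f"{name}.tsv"
            obj.to_frame().to_csv(p, sep="\t", float_format=_FLOAT_FMT)
        elif isinstance(obj, pd.DataFrame):
            p = out_dir / f"{name}.tsv"
            obj.to_csv(p, sep="\t", float_format=_FLOAT_FMT)
        elif isinstance(obj, str):
            p = out_dir / name
            p.write_text(obj, encoding="utf-8")
        else:
            p = out_dir / f"{name}.json"
            p.write_text(json.dumps(obj, indent=2, default=str), encoding="utf-8")
        written.append(p)
    return written


def file_checksum(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(
    out_dir: str | Path,
    parameters: Mapping[str, object],
    seed: int | None,
    files: Iterable[str | Path] = (),
) -> Path:
    """Write the JSON run manifest (parameters, seed, versions, checksums)."""
    import scipy
    import sys

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "parameters": dict(parameters),
        "seed": seed,
        "versions": {
            "python": sys.version.split()[0],
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "checksums": {str(Path(f).name): file_checksum(f) for f in files},
    }
    p = out_dir / "manifest.json"
    p.write_text(json.dumps(manifest, indent=2, sort_keys=True), encoding="utf-8")
    return p
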