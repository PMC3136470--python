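"""Tabular I/O and the shared data model.

All pipeline tables are UTF-8, tab-delimited, one header line, "." decimal
separator. Lines starting with ``#`` are comment headers (pipeline version,
seed, parameters) and are ignored on read.

Sites are two labeled arms ``A`` and ``B`` throughout; field-site names such
as "EPR" or "Guaymas" are display labels only.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError

SITES = ("A", "B")

#: Controlled vocabulary for pathway tags in the protein catalog.
PATHWAY_VOCABULARY = frozenset(
    {
        "nitrogen",
        "sulfur_oxidation",
        "thiosulfate_oxidation",
        "rTCA",
        "CBB",
        "transport",
        "energy_storage",
        "hemoglobin",
    }
)

#: Common decoy accession prefixes mapped onto the explicit boolean flag.
DECOY_PREFIXES = ("rev_", "DECOY_", "REV_", "decoy_")

PSM_COLUMNS = (
    "spectrum_id",
    "peptide",
    "accession",
    "site",
    "replicate",
    "score",
    "mass_error_ppm",
    "is_decoy",
)

CATALOG_COLUMNS = ("accession", "origin", "cog", "pathways", "housekeeping", "description")

TRACE_COLUMNS = (
    "vessel_id",
    "substrate",
    "time_h",
    "c_in_uM",
    "c_out_uM",
    "flow_L_h",
    "wet_weight_g",
    "is_control",
)


@dataclass(frozen=True)
class PSMRecord:
    """One peptide-spectrum match with identification metadata."""

    spectrum_id: str
    peptide: str
    accession: str
    site: str
    replicate: int
    score: float
    mass_error_ppm: float
    is_decoy: bool = False

    def __post_init__(self):
        if not self.peptide:
            raise ValidationError("peptide must be non-empty")
        if self.replicate < 1:
            raise ValidationError("replicate must be >= 1")


def _parse_bool(value, line: int | None = None) -> bool:
    s = str(value).strip().lower()
    if s in {"true", "1", "t", "yes"}:
        return True
    if s in {"false", "0", "f", "no"}:
        return False
    raise ParseError(f"cannot parse boolean value {value!r}", line)


def _format_bool(value: bool) -> str:
    return "true" if value else "false"


def _read_table(path, required: tuple[str, ...]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str, comment="#", keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}")
    return df


def _write_table(df: pd.DataFrame, path, comment: str | None = None) -> None:
    buf = io.StringIO()
    if comment:
        for line in comment.splitlines():
            buf.write(f"# {line}\n")
    df.to_csv(buf, sep="\t", index=False)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        fh.write(buf.getvalue())


# ---------------------------------------------------------------------------
# PSM tables


def read_psm_table(path) -> pd.DataFrame:
    """Read a PSM table into a validated DataFrame (one row per PSM).

    Row order is preserved and no row is ever silently dropped: any
    malformed row raises :class:`ParseError` naming its 1-based line number
    (counting the header as line 1; comment lines are not counted).

    Use :func:`psm_records` for a list of :class:`PSMRecord` objects.
    """
    raw = _read_table(path, PSM_COLUMNS)
    n = len(raw)
    out = pd.DataFrame(index=raw.index)
    out["spectrum_id"] = raw["spectrum_id"]
    out["peptide"] = raw["peptide"]
    out["accession"] = raw["accession"]
    out["site"] = raw["site"]

    def _numeric(col: str, caster, dtype):
        values = np.empty(n, dtype=dtype)
        for i, v in enumerate(raw[col].to_numpy()):
            try:
                values[i] = caster(v)
            except (TypeError, ValueError):
                raise ParseError(f"non-numeric {col} value {v!r}", i + 2) from None
        return values

    out["replicate"] = _numeric("replicate", int, np.int64)
    out["score"] = _numeric("score", float, np.float64)
    out["mass_error_ppm"] = _numeric("mass_error_ppm", float, np.float64)
    out["is_decoy"] = [_parse_bool(v, i + 2) for i, v in enumerate(raw["is_decoy"].to_numpy())]
    if (out["replicate"] < 1).any():
        bad = int(out.index[out["replicate"] < 1][0]) + 2
        raise ParseError("replicate must be >= 1", bad)
    if (out["peptide"] == "").any():
        bad = int(out.index[out["peptide"] == ""][0]) + 2
        raise ParseError("peptide must be non-empty", bad)
    return out


def write_psm_table(psms: pd.DataFrame, path, comment: str | None = None) -> None:
    df = psms.loc[:, list(PSM_COLUMNS)].copy()
    df["is_decoy"] = df["is_decoy"].map(_format_bool)
    _write_table(df, path, comment)


def psm_records(psms: pd.DataFrame) -> list[PSMRecord]:
    """Convert a PSM DataFrame into a list of :class:`PSMRecord`."""
    return [PSMRecord(**rec) for rec in psms.loc[:, list(PSM_COLUMNS)].to_dict("records")]


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records], columns=list(PSM_COLUMNS))


def apply_decoy_prefixes(psms: pd.DataFrame, prefixes=DECOY_PREFIXES) -> pd.DataFrame:
    """Loader shim: fold common decoy accession prefixes into ``is_decoy``.

    Accessions beginning with any of *prefixes* have the prefix stripped and
    the flag set. Rows already flagged are left alone.
    """
    out = psms.copy()
    acc = out["accession"].astype(str)
    for p in prefixes:
        hit = acc.str.startswith(p)
        out.loc[hit, "is_decoy"] = True
        acc = acc.where(~hit, acc.str.slice(len(p)))
    out["accession"] = acc
    return out


# ---------------------------------------------------------------------------
# Protein catalog


@dataclass
class ProteinCatalog:
    """Per-accession annotation: origin, COG letter, pathway tags, housekeeping.

    Backed by a DataFrame indexed by accession with columns ``origin``
    (host|symbiont), ``cog`` (single letter or "unassigned"), ``pathways``
    (frozenset of controlled-vocabulary tags), ``housekeeping`` (bool) and
    ``description``.
    """

    frame: pd.DataFrame
    vocabulary: frozenset = field(default=PATHWAY_VOCABULARY)

    def __post_init__(self):
        if self.frame.index.has_duplicates:
            dups = sorted(self.frame.index[self.frame.index.duplicated()].unique())
            raise ValidationError(f"duplicate accessions in catalog: {dups}")
        bad_origin = set(self.frame["origin"]) - {"host", "symbiont"}
        if bad_origin:
            raise ValidationError(f"unknown origin value(s): {sorted(bad_origin)}")
        for acc, tags in self.frame["pathways"].items():
            unknown = set(tags) - self.vocabulary
            if unknown:
                raise ValidationError(
                    f"accession {acc}: pathway tag(s) {sorted(unknown)} not in vocabulary"
                )

    def __len__(self) -> int:
        return len(self.frame)

    def __contains__(self, accession) -> bool:
        return accession in self.frame.index

    @property
    def accessions(self) -> pd.Index:
        return self.frame.index

    def origin(self, accession: str) -> str:
        return self.frame.at[accession, "origin"]

    def origins(self) -> pd.Series:
        return self.frame["origin"]

    def cog(self, accession: str) -> str:
        return self.frame.at[accession, "cog"]

    def housekeeping_accessions(self) -> list[str]:
        return list(self.frame.index[self.frame["housekeeping"]])

    def with_pathway(self, tag: str) -> list[str]:
        if tag not in self.vocabulary:
            raise ValidationError(f"pathway tag {tag!r} not in vocabulary")
        return [a for a, tags in self.frame["pathways"].items() if tag in tags]


def read_protein_catalog(path, vocabulary=PATHWAY_VOCABULARY) -> ProteinCatalog:
    """Read a protein catalog TSV, rejecting duplicates and unknown tags."""
    raw = _read_table(path, CATALOG_COLUMNS)
    frame = pd.DataFrame(
        {
            "origin": raw["origin"].to_numpy(),
            "cog": raw["cog"].to_numpy(),
            "pathways": [
                frozenset(t for t in p.split(";") if t) for p in raw["pathways"].to_numpy()
            ],
            "housekeeping": [_parse_bool(v, i + 2) for i, v in enumerate(raw["housekeeping"])],
            "description": raw["description"].to_numpy(),
        },
        index=pd.Index(raw["accession"], name="accession"),
    )
    return ProteinCatalog(frame, frozenset(vocabulary))


def write_protein_catalog(catalog: ProteinCatalog, path, comment: str | None = None) -> None:
    df = catalog.frame.reset_index()
    df["pathways"] = df["pathways"].map(lambda tags: ";".join(sorted(tags)))
    df["housekeeping"] = df["housekeeping"].map(_format_bool)
    _write_table(df.loc[:, list(CATALOG_COLUMNS)], path, comment)


# ---------------------------------------------------------------------------
# Count matrix


@dataclass
class CountMatrix:
    """Protein x (site, replicate) spectral counts.

    ``counts``: wide DataFrame, rows are accessions, columns a MultiIndex of
    (site, replicate). ``unique_peptides``: accessions x sites. ``mask``:
    boolean, same shape as counts; True marks a replicate value masked as an
    outlier. ``unannotated``: accessions counted but absent from the catalog.
    """

    counts: pd.DataFrame
    unique_peptides: pd.DataFrame
    mask: pd.DataFrame | None = None
    unannotated: frozenset = frozenset()

    def __post_init__(self):
        if self.mask is None:
            self.mask = pd.DataFrame(
                False, index=self.counts.index, columns=self.counts.columns
            )
        if len(self.counts) and (self.counts.to_numpy() < 0).any():
            raise ValidationError("counts must be nonnegative")
        self.counts.index.name = "accession"
        self.unique_peptides.index.name = "accession"
        self.unique_peptides.columns.name = "site"

    @property
    def sites(self) -> tuple:
        return tuple(dict.fromkeys(self.counts.columns.get_level_values(0)))

    @property
    def n_replicates(self) -> dict:
        out: dict = {}
        for site in self.sites:
            out[site] = len(self.counts[site].columns)
        return out

    @property
    def accessions(self) -> pd.Index:
        return self.counts.index

    def subset(self, accessions) -> "CountMatrix":
        idx = self.counts.index.intersection(pd.Index(accessions), sort=False)
        return CountMatrix(
            self.counts.loc[idx],
            self.unique_peptides.loc[idx],
            self.mask.loc[idx],
            frozenset(a for a in self.unannotated if a in idx),
        )

    def total_psms(self) -> int:
        return int(self.counts.to_numpy().sum())


def count_matrix_from_tidy(tidy: pd.DataFrame, n_replicates: dict | None = None) -> CountMatrix:
    """Build a :class:`CountMatrix` from tidy rows.

    Expected columns: accession, site, replicate, count, unique_peptides.
    Missing (accession, site, replicate) cells become zero counts.
    """
    sites = sorted(tidy["site"].unique())
    if n_replicates is None:
        n_replicates = {s: int(tidy.loc[tidy["site"] == s, "replicate"].max()) for s in sites}
    cols = pd.MultiIndex.from_tuples(
        [(s, r) for s in sites for r in range(1, n_replicates[s] + 1)],
        names=["site", "replicate"],
    )
    counts = (
        tidy.pivot_table(
            index="accession", columns=["site", "replicate"], values="count", aggfunc="sum"
        )
        .reindex(columns=cols)
        .fillna(0)
        .astype(np.int64)
    )
    uniq = (
        tidy.pivot_table(
            index="accession", columns="site", values="unique_peptides", aggfunc="max"
        )
        .reindex(columns=list(sites), index=counts.index)
        .fillna(0)
        .astype(np.int64)
    )
    counts.index.name = "accession"
    return CountMatrix(counts, uniq)


def count_matrix_to_tidy(matrix: CountMatrix) -> pd.DataFrame:
    rows = []
    for acc in matrix.accessions:
        for site, rep in matrix.counts.columns:
            rows.append(
                {
                    "accession": acc,
                    "site": site,
                    "replicate": rep,
                    "count": int(matrix.counts.at[acc, (site, rep)]),
                    "unique_peptides": int(matrix.unique_peptides.at[acc, site]),
                }
            )
    return pd.DataFrame(rows, columns=["accession", "site", "replicate", "count", "unique_peptides"])


def write_count_matrix(matrix: CountMatrix, path, comment: str | None = None) -> None:
    _write_table(count_matrix_to_tidy(matrix), path, comment)


def read_count_matrix(path) -> CountMatrix:
    tidy = _read_table(path, ("accession", "site", "replicate", "count", "unique_peptides"))
    for col in ("replicate", "count", "unique_peptides"):
        tidy[col] = tidy[col].astype(np.int64)
    return count_matrix_from_tidy(tidy)


# ---------------------------------------------------------------------------
# Respirometry traces (long format; the trace object lives in .respirometry)


def read_trace_table(path) -> pd.DataFrame:
    raw = _read_table(path, TRACE_COLUMNS)
    out = raw.copy()
    for col in ("time_h", "c_in_uM", "c_out_uM", "flow_L_h", "wet_weight_g"):
        try:
            out[col] = out[col].astype(np.float64)
        except ValueError as exc:
            raise ParseError(f"non-numeric value in column {col}: {exc}") from None
    out["is_control"] = [_parse_bool(v, i + 2) for i, v in enumerate(raw["is_control"])]
    return out


def write_trace_table(traces: pd.DataFrame, path, comment: str | None = None) -> None:
    df = traces.loc[:, list(TRACE_COLUMNS)].copy()
    df["is_control"] = df["is_control"].map(_format_bool)
    _write_table(df, path, comment)
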