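"""Aggregate qualified proteins into comparative summaries.

Abundance here always means the per-site sum of normalized, zero-floored
spectral counts over unmasked replicates (the ``abundance_A``/``abundance_B``
columns of the qualified table). Symbiont percentages are computed against
the symbiont-scope total only, so host protein load at one site cannot
distort symbiont comparisons; host hemoglobin is evaluated against host
proteins, and total host against the combined proteome.
"""

from __future__ import annotations

import importlib.resources
import warnings

import pandas as pd

from .errors import ValidationError
from .psm_io import PATHWAY_VOCABULARY, ProteinCatalog

DIRECTIONS = ("upregulated_in_A", "upregulated_in_B")


def _qualified(table: pd.DataFrame) -> pd.DataFrame:
    return table.loc[table["qualified"]]


def _scope_accessions(table: pd.DataFrame, catalog: ProteinCatalog, scope: str) -> pd.Index:
    q = _qualified(table)
    if scope == "combined":
        return q.index
    if scope not in ("host", "symbiont"):
        raise ValidationError(f"unknown scope {scope!r}")
    origins = catalog.origins().reindex(q.index)
    return q.index[origins == scope]


def proteome_fractions(
    table: pd.DataFrame, catalog: ProteinCatalog, scope: str = "symbiont"
) -> pd.DataFrame:
    """Per-protein percent of the scope's total abundance, per site.

    Returns a DataFrame indexed by accession with columns abundance_A,
    abundance_B, percent_A, percent_B. Percents within the scope sum to 100
    per site.
    """
    accs = _scope_accessions(table, catalog, scope)
    if len(accs) == 0:
        raise ValidationError(f"scope {scope!r} contains no qualified proteins")
    sub = table.loc[accs, ["abundance_A", "abundance_B"]].astype(float)
    out = sub.copy()
    for site in ("A", "B"):
        total = sub[f"abundance_{site}"].sum()
        out[f"percent_{site}"] = 100.0 * sub[f"abundance_{site}"] / total
    return out


def host_fraction(table: pd.DataFrame, catalog: ProteinCatalog) -> dict:
    """Percent of the combined proteome abundance that is host, per site."""
    q = _qualified(table)
    origins = catalog.origins().reindex(q.index)
    out = {}
    for site in ("A", "B"):
        total = q[f"abundance_{site}"].sum()
        if total <= 0:
            raise ValidationError("combined scope has zero abundance")
        host = q.loc[(origins == "host").to_numpy(), f"abundance_{site}"].sum()
        out[site] = 100.0 * host / total
    return out


def load_pathway_map(path=None) -> dict[str, frozenset]:
    """Load a pathway map TSV (columns: pathway, tag) into {name: tags}.

    Without *path*, the packaged default map is used. Tags must belong to
    the catalog's controlled vocabulary.
    """
    if path is None:
        ref = importlib.resources.files("symbioquant").joinpath("data/pathway_map.tsv")
        with importlib.resources.as_file(ref) as p:
            df = pd.read_csv(p, sep="\t", comment="#")
    else:
        df = pd.read_csv(path, sep="\t", comment="#")
    for col in ("pathway", "tag"):
        if col not in df.columns:
            raise ValidationError(f"pathway map missing column {col!r}")
    out: dict[str, frozenset] = {}
    for name, grp in df.groupby("pathway", sort=True):
        tags = frozenset(grp["tag"])
        unknown = tags - PATHWAY_VOCABULARY
        if unknown:
            raise ValidationError(f"pathway {name!r}: unknown tag(s) {sorted(unknown)}")
        out[name] = tags
    return out


def pathway_abundance(
    table: pd.DataFrame,
    catalog: ProteinCatalog,
    pathway_map: dict[str, frozenset] | None = None,
    scope: str = "symbiont",
) -> pd.DataFrame:
    """Summed abundance, percent of scope, and A/B fold ratio per pathway.

    Pathways with no qualified member proteins get ``present = False`` and
    NaN statistics rather than a zero division. ``floor_limited`` marks
    fold ratios computed against a site where every member was absent
    before the zero floor.
    """
    pathway_map = pathway_map or load_pathway_map()
    scope_accs = _scope_accessions(table, catalog, scope)
    totals = {s: float(table.loc[scope_accs, f"abundance_{s}"].sum()) for s in ("A", "B")}
    member_tags = catalog.frame["pathways"]
    rows = []
    for name in sorted(pathway_map):
        tags = pathway_map[name]
        members = [
            a
            for a in scope_accs
            if a in member_tags.index and member_tags[a] & tags
        ]
        if not members:
            rows.append(
                {
                    "pathway": name,
                    "present": False,
                    "n_proteins": 0,
                    "abundance_A": float("nan"),
                    "abundance_B": float("nan"),
                    "percent_A": float("nan"),
                    "percent_B": float("nan"),
                    "fold_ratio": float("nan"),
                    "floor_limited": False,
                }
            )
            continue
        sub = table.loc[members]
        ab_a = float(sub["abundance_A"].sum())
        ab_b = float(sub["abundance_B"].sum())
        rows.append(
            {
                "pathway": name,
                "present": True,
                "n_proteins": len(members),
                "abundance_A": ab_a,
                "abundance_B": ab_b,
                "percent_A": 100.0 * ab_a / totals["A"],
                "percent_B": 100.0 * ab_b / totals["B"],
                "fold_ratio": ab_a / ab_b,
                "floor_limited": bool(sub["absent_A"].all() or sub["absent_B"].all()),
            }
        )
    return pd.DataFrame(rows).set_index("pathway")


def cog_composition(
    table: pd.DataFrame, catalog: ProteinCatalog, direction_threshold: float = 0.0
) -> pd.DataFrame:
    """COG-category percent composition of up-regulated proteins per direction.

    Proteins with log2 ratio magnitude strictly above the threshold are
    split by sign into the two directions; each protein counts once per
    category regardless of its peptide count. Percents within a direction
    sum to 100 when any protein passes.
    """
    q = _qualified(table)
    cogs = catalog.frame["cog"].reindex(q.index).fillna("unassigned")
    ratio = q["log2_ratio"].astype(float)
    rows = []
    for direction, sel in (
        ("upregulated_in_A", ratio > direction_threshold),
        ("upregulated_in_B", ratio < -direction_threshold),
    ):
        chosen = cogs[sel.to_numpy()]
        n_dir = len(chosen)
        if n_dir == 0:
            continue
        counts = chosen.value_counts().sort_index()
        for cog, n in counts.items():
            rows.append(
                {
                    "direction": direction,
                    "cog": cog,
                    "n_proteins": int(n),
                    "percent_composition": 100.0 * n / n_dir,
                }
            )
    return pd.DataFrame(rows, columns=["direction", "cog", "n_proteins", "percent_composition"])


def top_n(table: pd.DataFrame, catalog: ProteinCatalog, n: int = 25) -> dict[str, pd.DataFrame]:
    """Top-*n* proteins per site by absolute abundance, with origin flags.

    Ties break by accession lexicographic order so rankings are
    rerun-identical. ``shared`` marks proteins present in both site lists;
    ``host_origin`` marks catalog host proteins. If *n* exceeds the table
    size the full ranking is returned with a warning.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    q = _qualified(table)
    if n > len(q):
        warnings.warn(
            f"requested top {n} but only {len(q)} qualified proteins; returning all",
            stacklevel=2,
        )
    ranked = {}
    for site in ("A", "B"):
        s = (
            q[[f"abundance_{site}"]]
            .rename(columns={f"abundance_{site}": "abundance"})
            .reset_index()
            .sort_values(["abundance", "accession"], ascending=[False, True], kind="mergesort")
            .head(n)
            .reset_index(drop=True)
        )
        s.index = pd.RangeIndex(1, len(s) + 1, name="rank")
        ranked[site] = s
    shared = set(ranked["A"]["accession"]) & set(ranked["B"]["accession"])
    origins = catalog.origins()
    for site in ("A", "B"):
        df = ranked[site]
        df["shared"] = df["accession"].isin(shared)
        df["host_origin"] = df["accession"].map(
            lambda a: a in origins.index and origins[a] == "host"
        )
    return ranked
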