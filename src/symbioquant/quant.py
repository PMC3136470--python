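"""Protein qualification and differential representation.

The quantification contract, applied to a spectral-count matrix with two
site arms and replicate columns, in this order:

1. presence filter — a protein must have a nonzero count in every replicate
   (of both sites by default, configurable to either site);
2. unique-peptide filter — at least ``min_unique`` (default 3) distinct
   peptides must support the protein at one site or the other;
3. outlier masking — replicate counts farther than ``k`` (default 2)
   population standard deviations from their (protein, site) mean are
   masked, in a single non-iterated pass;
4. total-count normalization — the non-reference arm is rescaled by the
   ratio of unmasked site totals (reference / other);
5. zero floor — exact zeros among the normalized values become ``floor``
   (default 0.2) so ratios stay finite;
6. log2 ratio — per protein, log2 of the site-A mean over the site-B mean
   of unmasked, floored replicate values.

Note that with 4 replicates per (protein, site) group the maximum possible
population z-score is sqrt(3) < 2, so step 3 cannot mask anything at the
default design; it becomes active for larger replicate counts or a smaller
``k``. See docs/methods.md.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ValidationError
from .psm_io import CountMatrix, ProteinCatalog

EXCLUSION_REASONS = ("missing_replicate", "too_few_unique_peptides", "none")


@dataclass
class QuantConfig:
    """Tunable parameters of the qualification pipeline."""

    presence_scope: str = "both"  # "both" | "either"
    min_unique: int = 3
    outlier_k: float = 2.0
    zero_floor: float = 0.2
    reference_site: str = "A"

    def validate(self) -> None:
        if self.presence_scope not in ("both", "either"):
            raise ValidationError(f"presence_scope must be 'both' or 'either', got {self.presence_scope!r}")
        if self.min_unique < 1:
            raise ValidationError("min_unique must be >= 1")
        if self.zero_floor <= 0:
            raise ValidationError("zero_floor must be positive")


@dataclass
class NormalizationReport:
    """Record of the total-count normalization step."""

    factor: float
    reference_site: str
    scaled_site: str
    total_reference: float
    total_scaled: float


@dataclass
class HousekeepingReport:
    """Advisory check that constitutive proteins center near log2 ratio 0."""

    ratios: pd.Series
    mean: float
    sd: float
    verdict: str  # PASS | FAIL | INDETERMINATE


@dataclass
class QualifyResult:
    """Per-protein table plus bookkeeping from :func:`qualify`.

    ``table`` is indexed by accession with columns: qualified, reason,
    mean_A, mean_B, log2_ratio, abundance_A, abundance_B, absent_A,
    absent_B, n_masked. Means/ratios are NaN for unqualified rows.
    """

    table: pd.DataFrame
    normalization: NormalizationReport | None
    exclusions: dict = field(default_factory=dict)
    n_identified: int = 0
    n_qualified: int = 0


def filter_replicate_presence(matrix: CountMatrix, scope: str = "both"):
    """Keep proteins identified (count > 0) in every replicate.

    *scope* "both" requires full presence at both sites; "either" at at
    least one site. Returns the retained sub-matrix and the excluded
    accession list (reason: missing_replicate).
    """
    if scope not in ("both", "either"):
        raise ValidationError(f"unknown presence scope {scope!r}")
    present = pd.DataFrame(
        {site: (matrix.counts[site] > 0).all(axis=1) for site in matrix.sites}
    )
    keep = present.all(axis=1) if scope == "both" else present.any(axis=1)
    excluded = list(matrix.accessions[~keep])
    return matrix.subset(matrix.accessions[keep]), excluded


def filter_unique_peptides(matrix: CountMatrix, min_unique: int = 3):
    """Keep proteins supported by >= *min_unique* distinct peptides at some site."""
    if min_unique < 1:
        raise ValidationError("min_unique must be >= 1")
    keep = matrix.unique_peptides.max(axis=1) >= min_unique
    excluded = list(matrix.accessions[~keep])
    return matrix.subset(matrix.accessions[keep]), excluded


def mask_outliers(matrix: CountMatrix, k: float = 2.0):
    """Mask replicate counts outside k population SDs of their (protein, site) mean.

    Statistics are computed over all replicate values of the group in a
    single pass (the rule is therefore idempotent). Proteins left with
    fewer than 2 unmasked values at a site are reported as flagged, not
    excluded. Groups with zero SD mask nothing.
    """
    mask = matrix.mask.copy()
    flagged: list = []
    for site in matrix.sites:
        vals = matrix.counts[site].to_numpy(dtype=float)
        mean = vals.mean(axis=1, keepdims=True)
        sd = vals.std(axis=1, keepdims=True)  # population sd (ddof=0)
        out = (np.abs(vals - mean) > k * sd) & (sd > 0)
        for j, col in enumerate(matrix.counts[site].columns):
            mask[(site, col)] = mask[(site, col)].to_numpy() | out[:, j]
        n_unmasked = (~mask[site].to_numpy()).sum(axis=1)
        flagged.extend(matrix.accessions[n_unmasked < 2])
    return (
        CountMatrix(matrix.counts, matrix.unique_peptides, mask, matrix.unannotated),
        sorted(set(flagged)),
    )


def normalize_total(matrix: CountMatrix, reference_site: str = "A"):
    """Rescale the non-reference arm by the ratio of unmasked site totals.

    factor = total(reference) / total(other); every count of the other site
    is multiplied by the factor, so the scaled arm's unmasked total equals
    the reference arm's. Returns (normalized float DataFrame, report).
    """
    sites = matrix.sites
    if reference_site not in sites:
        raise ValidationError(f"reference site {reference_site!r} not among sites {sites}")
    (other,) = [s for s in sites if s != reference_site]
    unmasked = matrix.counts.where(~matrix.mask, 0)
    total_ref = float(unmasked[reference_site].to_numpy().sum())
    total_other = float(unmasked[other].to_numpy().sum())
    if total_ref <= 0 or total_other <= 0:
        raise ValidationError("both site totals must be positive for normalization")
    factor = total_ref / total_other
    norm = matrix.counts.astype(float).copy()
    for col in norm[other].columns:
        norm[(other, col)] *= factor
    report = NormalizationReport(
        factor=factor,
        reference_site=reference_site,
        scaled_site=other,
        total_reference=total_ref,
        total_scaled=total_other * factor,
    )
    return norm, report


def replace_zeros(values, floor: float = 0.2):
    """Replace exact zeros with *floor*; positive values pass through."""
    if floor <= 0:
        raise ValidationError("floor must be positive")
    arr = np.asarray(values, dtype=float) if not hasattr(values, "where") else values
    if (np.asarray(arr, dtype=float) < 0).any():
        raise ValidationError("counts cannot be negative")
    if hasattr(values, "where"):
        return values.where(values != 0, floor)
    return np.where(arr == 0, floor, arr)


def log2_ratios(norm: pd.DataFrame, mask: pd.DataFrame, sites) -> pd.DataFrame:
    """Per-protein site means (over unmasked values) and their log2 ratio.

    Expects normalized, zero-floored values; the ratio is log2(mean of the
    first site over mean of the second) and is antisymmetric under swapping
    the two sites.
    """
    site_a, site_b = sites
    if (norm.to_numpy() <= 0).any():
        raise ValidationError("log2_ratios expects strictly positive (zero-floored) values")
    masked = norm.where(~mask)
    mean_a = masked[site_a].mean(axis=1)
    mean_b = masked[site_b].mean(axis=1)
    return pd.DataFrame(
        {
            "mean_A": mean_a,
            "mean_B": mean_b,
            "log2_ratio": np.log2(mean_a / mean_b),
        }
    )


def housekeeping_check(
    table: pd.DataFrame,
    catalog: ProteinCatalog,
    tol_mean: float = 0.5,
    tol_sd: float = 1.0,
) -> HousekeepingReport:
    """Advisory normalization sanity check on constitutive proteins.

    Reports each qualified housekeeping protein's log2 ratio, their mean
    and sample SD; PASS iff |mean| <= tol_mean and sd <= tol_sd. Never
    fails the pipeline.
    """
    hk = [a for a in catalog.housekeeping_accessions() if a in table.index and table.at[a, "qualified"]]
    if not hk:
        warnings.warn("no qualified housekeeping proteins; verdict INDETERMINATE", stacklevel=2)
        return HousekeepingReport(pd.Series(dtype=float), float("nan"), float("nan"), "INDETERMINATE")
    ratios = table.loc[hk, "log2_ratio"].astype(float)
    mean = float(ratios.mean())
    sd = float(ratios.std(ddof=1)) if len(ratios) > 1 else 0.0
    verdict = "PASS" if (abs(mean) <= tol_mean and sd <= tol_sd) else "FAIL"
    return HousekeepingReport(ratios, mean, sd, verdict)


def qualify(
    matrix: CountMatrix,
    catalog: ProteinCatalog | None = None,
    config: QuantConfig | None = None,
) -> QualifyResult:
    """Run the full qualification pipeline on a count matrix.

    Composes presence filter -> unique-peptide filter -> outlier masking ->
    total-count normalization -> zero floor -> log2 ratios, in that order,
    and accounts for every identified protein: identified = qualified +
    sum of exclusions.
    """
    config = config or QuantConfig()
    config.validate()
    n_identified = len(matrix.accessions)
    columns = [
        "qualified",
        "reason",
        "mean_A",
        "mean_B",
        "log2_ratio",
        "abundance_A",
        "abundance_B",
        "absent_A",
        "absent_B",
        "n_masked",
    ]
    if n_identified == 0:
        empty = pd.DataFrame(columns=columns)
        empty.index.name = "accession"
        return QualifyResult(empty, None, {"missing_replicate": [], "too_few_unique_peptides": []}, 0, 0)

    m1, excl_presence = filter_replicate_presence(matrix, config.presence_scope)
    m2, excl_unique = filter_unique_peptides(m1, config.min_unique)
    if len(m2.accessions) == 0:
        table = pd.DataFrame(index=matrix.accessions, columns=columns)
        table["qualified"] = False
        table["reason"] = "none"
        table.loc[excl_presence, "reason"] = "missing_replicate"
        table.loc[excl_unique, "reason"] = "too_few_unique_peptides"
        for col in ("absent_A", "absent_B"):
            table[col] = False
        table["n_masked"] = 0
        table.index.name = "accession"
        exclusions = {
            "missing_replicate": excl_presence,
            "too_few_unique_peptides": excl_unique,
        }
        res = QualifyResult(table, None, exclusions, n_identified, 0)
        res.flagged_low_replicates = []
        return res
    m3, flagged = mask_outliers(m2, config.outlier_k)
    norm, report = normalize_total(m3, config.reference_site)
    floored = replace_zeros(norm, config.zero_floor)
    sites = m3.sites
    stats = log2_ratios(floored, m3.mask, sites)

    site_a, site_b = sites
    unmasked_floored = floored.where(~m3.mask)
    stats["abundance_A"] = unmasked_floored[site_a].sum(axis=1)
    stats["abundance_B"] = unmasked_floored[site_b].sum(axis=1)
    raw_unmasked = m3.counts.where(~m3.mask)
    stats["absent_A"] = (raw_unmasked[site_a].fillna(0) == 0).all(axis=1)
    stats["absent_B"] = (raw_unmasked[site_b].fillna(0) == 0).all(axis=1)
    stats["n_masked"] = m3.mask.sum(axis=1)
    stats["qualified"] = True
    stats["reason"] = "none"

    table = stats.reindex(matrix.accessions)
    table["qualified"] = table["qualified"].eq(True)
    for col in ("absent_A", "absent_B"):
        table[col] = table[col].eq(True)
    table["n_masked"] = table["n_masked"].fillna(0).astype(int)
    table.loc[excl_presence, "reason"] = "missing_replicate"
    table.loc[excl_unique, "reason"] = "too_few_unique_peptides"
    table["reason"] = table["reason"].fillna("none")
    table = table.loc[:, columns]
    table.index.name = "accession"

    exclusions = {
        "missing_replicate": excl_presence,
        "too_few_unique_peptides": excl_unique,
    }
    result = QualifyResult(
        table=table,
        normalization=report,
        exclusions=exclusions,
        n_identified=n_identified,
        n_qualified=int(table["qualified"].sum()),
    )
    assert result.n_identified == result.n_qualified + sum(len(v) for v in exclusions.values())
    result.flagged_low_replicates = flagged
    return result


def write_qualified_table(result: QualifyResult, path, comment: str | None = None) -> None:
    from .psm_io import _write_table

    df = result.table.reset_index()
    for col in ("qualified", "absent_A", "absent_B"):
        df[col] = df[col].map(lambda v: "true" if v else "false")
    _write_table(df, path, comment)


def read_qualified_table(path) -> pd.DataFrame:
    from .psm_io import _read_table

    df = _read_table(
        path,
        (
            "accession",
            "qualified",
            "reason",
            "mean_A",
            "mean_B",
            "log2_ratio",
            "abundance_A",
            "abundance_B",
            "absent_A",
            "absent_B",
            "n_masked",
        ),
    )
    df = df.set_index("accession")
    for col in ("mean_A", "mean_B", "log2_ratio", "abundance_A", "abundance_B"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["n_masked"] = pd.to_numeric(df["n_masked"], errors="coerce").fillna(0).astype(int)
    for col in ("qualified", "absent_A", "absent_B"):
        df[col] = df[col].str.lower().isin(["true", "1", "t", "yes"])
    return df
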