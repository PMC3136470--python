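"""PSM-level acceptance and spectral-count enumeration.

Two acceptance gates precede quantification: a precursor mass-error cutoff
(default |error| < 3.0 ppm) and a score threshold chosen to bound the
estimated false discovery rate (default ~1%) by the target-decoy strategy:
for a candidate score threshold t, FDR(t) is estimated as the number of
decoy PSMs scoring >= t divided by the number of target PSMs scoring >= t
(no +1 correction, no q-value monotonization). The chosen threshold accepts
the maximal number of targets among all thresholds satisfying the bound;
ties at the threshold score are always included before the bound is checked.

Accepted target PSMs are then enumerated into a protein x (site, replicate)
spectral-count matrix; unique peptides are distinct plain peptide strings
per (protein, site), ignoring modifications.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ValidationError
from .psm_io import CountMatrix, ProteinCatalog


@dataclass
class FdrResult:
    """Outcome of target-decoy score thresholding."""

    score_threshold: float
    accepted: pd.DataFrame
    achieved_fdr: float
    n_targets_accepted: int
    n_decoys_at_threshold: int

    @property
    def attainable(self) -> bool:
        return not math.isnan(self.achieved_fdr)


def filter_mass_error(psms: pd.DataFrame, max_ppm: float = 3.0) -> pd.DataFrame:
    """Retain PSMs with |mass_error_ppm| strictly below *max_ppm*.

    The cut is strict and applied to the absolute value; order is preserved.
    """
    if max_ppm <= 0:
        raise ValidationError("max_ppm must be positive")
    return psms.loc[psms["mass_error_ppm"].abs() < max_ppm]


def fdr_threshold(psms: pd.DataFrame, target_fdr: float = 0.01) -> FdrResult:
    """Choose the score threshold attaining the requested decoy-estimated FDR.

    Scans every observed score as a candidate threshold; among thresholds t
    with (#decoys >= t) / (#targets >= t) <= target_fdr, the one accepting
    the most targets wins; acceptance ties resolve to the largest (most
    conservative) such threshold, which admits the identical target set with
    the fewest decoys. If no threshold is feasible the result is empty with
    achieved_fdr = NaN.
    """
    if not (0 < target_fdr < 1):
        raise ValidationError("target_fdr must lie in (0, 1)")
    is_decoy = psms["is_decoy"].to_numpy(dtype=bool)
    if not (~is_decoy).any():
        raise ValidationError("no target PSMs to accept (all records are decoys)")
    scores = psms["score"].to_numpy(dtype=float)

    order = np.argsort(-scores, kind="stable")
    s_sorted = scores[order]
    d_sorted = is_decoy[order]
    # cumulative counts at each candidate threshold = last index of each tie group
    cum_decoys = np.cumsum(d_sorted)
    cum_targets = np.cumsum(~d_sorted)
    # last position of each distinct score (ties included before the bound check)
    is_group_end = np.ones(len(s_sorted), dtype=bool)
    is_group_end[:-1] = s_sorted[:-1] != s_sorted[1:]
    ends = np.flatnonzero(is_group_end)
    t_candidates = s_sorted[ends]
    n_decoys = cum_decoys[ends]
    n_targets = cum_targets[ends]

    with np.errstate(divide="ignore", invalid="ignore"):
        fdr = np.where(n_targets > 0, n_decoys / np.maximum(n_targets, 1), np.inf)
    feasible = fdr <= target_fdr
    if not feasible.any():
        empty = psms.iloc[0:0]
        return FdrResult(math.inf, empty, math.nan, 0, 0)
    # candidates are ordered by decreasing threshold and targets accepted is
    # nondecreasing along the scan; among feasible candidates accepting the
    # maximal number of targets, report the largest (most conservative)
    # threshold — it admits the same target set with the fewest decoys
    feas_idx = np.flatnonzero(feasible)
    max_acc = n_targets[feas_idx].max()
    best = feas_idx[n_targets[feas_idx] == max_acc][0]
    threshold = float(t_candidates[best])
    accepted = psms.loc[(~is_decoy) & (scores >= threshold)]
    return FdrResult(
        score_threshold=threshold,
        accepted=accepted,
        achieved_fdr=float(fdr[best]),
        n_targets_accepted=int(n_targets[best]),
        n_decoys_at_threshold=int(n_decoys[best]),
    )


def fdr_threshold_stratified(
    psms: pd.DataFrame, target_fdr: float = 0.01, scope: str = "run"
) -> tuple[pd.DataFrame, dict]:
    """Apply :func:`fdr_threshold` per (site, replicate) run or to the dataset.

    Returns the concatenated accepted target PSMs (original order preserved)
    and a dict of per-stratum :class:`FdrResult`.
    """
    if scope == "dataset":
        res = fdr_threshold(psms, target_fdr)
        return res.accepted, {"dataset": res}
    if scope != "run":
        raise ValidationError(f"unknown FDR scope {scope!r}")
    results: dict = {}
    keep = np.zeros(len(psms), dtype=bool)
    pos = pd.Series(np.arange(len(psms)), index=psms.index)
    for (site, rep), group in psms.groupby(["site", "replicate"], sort=True):
        res = fdr_threshold(group, target_fdr)
        results[(site, int(rep))] = res
        keep[pos.loc[res.accepted.index].to_numpy()] = True
    return psms.loc[keep], results


def count_spectra(
    psms: pd.DataFrame,
    catalog: ProteinCatalog | None = None,
    n_replicates: dict | None = None,
) -> CountMatrix:
    """Enumerate accepted PSMs into spectral counts.

    counts(accession, site, replicate) is the number of PSMs with that key;
    unique_peptides(accession, site) is the number of distinct peptide
    strings across the site's replicates. Accessions absent from *catalog*
    are counted but flagged unannotated. Input must be decoy-free.
    """
    if psms["is_decoy"].any():
        raise ValidationError("count_spectra expects decoy-free input; run fdr_threshold first")
    sites = sorted(psms["site"].unique())
    if n_replicates is None:
        n_replicates = {
            s: int(psms.loc[psms["site"] == s, "replicate"].max()) for s in sites
        }
    cols = pd.MultiIndex.from_tuples(
        [(s, r) for s in sites for r in range(1, n_replicates[s] + 1)],
        names=["site", "replicate"],
    )
    grouped = psms.groupby(["accession", "site", "replicate"]).size()
    counts = grouped.unstack(["site", "replicate"]).reindex(columns=cols).fillna(0).astype(np.int64)
    counts = counts.sort_index()
    counts.index.name = "accession"
    uniq = (
        psms.groupby(["accession", "site"])["peptide"]
        .nunique()
        .unstack("site")
        .reindex(index=counts.index, columns=list(sites))
        .fillna(0)
        .astype(np.int64)
    )
    unannotated = frozenset(
        a for a in counts.index if catalog is not None and a not in catalog
    )
    return CountMatrix(counts, uniq, unannotated=unannotated)
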