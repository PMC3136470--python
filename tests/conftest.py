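"""Shared fixtures and independent brute-force oracles.

The oracles here are deliberately naive (plain Python loops, no numpy
vectorization) so they stay independent of the implementation paths they
check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from symbioquant.psm_io import CountMatrix, ProteinCatalog


# ---------------------------------------------------------------------------
# Oracles


def brute_fdr_scan(scores, is_decoy, target_fdr):
    """Exhaustive threshold scan over every observed score.

    Among feasible thresholds accepting the most targets, the largest
    threshold wins. Returns (threshold, n_accepted, achieved_fdr) or None
    if no threshold is feasible.
    """
    candidates = sorted(set(scores))
    best = None
    for t in candidates:
        n_d = sum(1 for s, d in zip(scores, is_decoy) if d and s >= t)
        n_t = sum(1 for s, d in zip(scores, is_decoy) if not d and s >= t)
        if n_t == 0:
            continue
        if n_d / n_t <= target_fdr:
            if best is None or n_t > best[1] or (n_t == best[1] and t > best[0]):
                best = (t, n_t, n_d / n_t)
    return best


def scan_fdr_linear(scores, is_decoy, target_fdr):
    """Pure-python exhaustive scan in one sorted pass (for large instances).

    Same convention as brute_fdr_scan: maximal target acceptance, then the
    largest threshold. Returns (threshold, n_accepted, achieved_fdr) | None.
    """
    pairs = sorted(zip(scores, is_decoy), key=lambda p: -p[0])
    best = None
    n_t = n_d = 0
    i = 0
    n = len(pairs)
    while i < n:
        t = pairs[i][0]
        while i < n and pairs[i][0] == t:  # swallow the tie group
            if pairs[i][1]:
                n_d += 1
            else:
                n_t += 1
            i += 1
        if n_t > 0 and n_d / n_t <= target_fdr:
            if best is None or n_t > best[1]:
                best = (t, n_t, n_d / n_t)
    return best


def brute_qualified_set(counts, unique_peptides, n_replicates, scope, min_unique, k):
    """Re-implementation of the presence + unique-peptide + outlier rules.

    counts: {(acc, site, rep): int}; unique_peptides: {(acc, site): int}.
    Returns the set of qualified accessions (the outlier rule masks values
    but never disqualifies, so it does not affect membership; it is
    re-derived here for mask comparison via brute_outlier_mask).
    """
    accs = sorted({a for (a, _, _) in counts})
    sites = sorted({s for (_, s, _) in counts})
    qualified = set()
    for a in accs:
        present = {}
        for s in sites:
            present[s] = all(
                counts.get((a, s, r), 0) > 0 for r in range(1, n_replicates + 1)
            )
        ok_presence = all(present.values()) if scope == "both" else any(present.values())
        ok_unique = max(unique_peptides.get((a, s), 0) for s in sites) >= min_unique
        if ok_presence and ok_unique:
            qualified.add(a)
    return qualified


def brute_outlier_mask(values, k):
    """Per-group 2-SD rule: population sd over all values, single pass."""
    n = len(values)
    mean = sum(values) / n
    var = sum((v - mean) ** 2 for v in values) / n
    sd = math.sqrt(var)
    if sd == 0:
        return [False] * n
    return [abs(v - mean) > k * sd for v in values]


def make_count_matrix(counts_dict, unique_dict, sites=("A", "B"), n_replicates=4):
    """CountMatrix from {(acc, site, rep): count} / {(acc, site): uniq}."""
    accs = sorted({a for (a, _, _) in counts_dict})
    cols = pd.MultiIndex.from_tuples(
        [(s, r) for s in sites for r in range(1, n_replicates + 1)],
        names=["site", "replicate"],
    )
    counts = pd.DataFrame(
        [[counts_dict.get((a, s, r), 0) for s, r in cols] for a in accs],
        index=pd.Index(accs, name="accession"),
        columns=cols,
        dtype=np.int64,
    )
    uniq = pd.DataFrame(
        {s: [unique_dict.get((a, s), 0) for a in accs] for s in sites},
        index=counts.index,
        dtype=np.int64,
    )
    return CountMatrix(counts, uniq)


def random_count_matrix(rng, n_proteins=None, n_replicates=None):
    """Random CountMatrix instance with zeros and varied unique peptides."""
    n = n_proteins or int(rng.integers(5, 40))
    reps = n_replicates or int(rng.integers(3, 6))
    counts, uniq = {}, {}
    for i in range(n):
        a = f"P{i:04d}"
        for s in ("A", "B"):
            uniq[(a, s)] = int(rng.integers(0, 8))
            for r in range(1, reps + 1):
                c = int(rng.integers(0, 60))
                if rng.random() < 0.15:
                    c = 0
                counts[(a, s, r)] = c
    return make_count_matrix(counts, uniq, n_replicates=reps), counts, uniq, reps


def swap_sites(matrix: CountMatrix) -> CountMatrix:
    """Relabel site arms A<->B."""
    mapping = {"A": "B", "B": "A"}
    counts = matrix.counts.copy()
    counts.columns = pd.MultiIndex.from_tuples(
        [(mapping[s], r) for s, r in counts.columns], names=["site", "replicate"]
    )
    counts = counts.sort_index(axis=1)
    uniq = matrix.unique_peptides.rename(columns=mapping).sort_index(axis=1)
    return CountMatrix(counts, uniq)


def simple_catalog(accessions, origins=None, cogs=None, housekeeping=(), pathways=None):
    frame = pd.DataFrame(
        {
            "origin": [
                (origins or {}).get(a, "symbiont") for a in accessions
            ],
            "cog": [(cogs or {}).get(a, "C") for a in accessions],
            "pathways": [frozenset((pathways or {}).get(a, ())) for a in accessions],
            "housekeeping": [a in housekeeping for a in accessions],
            "description": ["" for _ in accessions],
        },
        index=pd.Index(list(accessions), name="accession"),
    )
    return ProteinCatalog(frame)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def small_psm_frame():
    """Nine target + three decoy PSMs over 2 sites x 2 replicates."""
    rows = []
    i = 0
    for site in ("A", "B"):
        for rep in (1, 2):
            for pep, acc in (("PEPTIDEA", "P1"), ("PEPTIDEB", "P1"), ("PEPSEQC", "P2")):
                if site == "B" and rep == 2 and acc == "P2":
                    continue  # leave one cell empty
                rows.append(
                    {
                        "spectrum_id": f"s{i}",
                        "peptide": pep,
                        "accession": acc,
                        "site": site,
                        "replicate": rep,
                        "score": 9.0 + 0.1 * i,
                        "mass_error_ppm": 0.5,
                        "is_decoy": False,
                    }
                )
                i += 1
    for j in range(3):
        rows.append(
            {
                "spectrum_id": f"d{j}",
                "peptide": "DECOYPEP",
                "accession": f"X{j}",
                "site": "A",
                "replicate": 1,
                "score": 3.0 + j * 0.1,
                "mass_error_ppm": 0.6,
                "is_decoy": True,
            }
        )
    return pd.DataFrame(rows)
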