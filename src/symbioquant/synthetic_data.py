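"""Seeded generators for every input the pipeline consumes.

The PSM generator emulates a two-site, quadruplicate spectral-counting
design: latent per-protein counts are negative binomial (the field norm
for overdispersed spectral counts) with a planted log2 fold change split
symmetrically between the sites (half the effect up at A, half down at B)
so total-count normalization stays well-posed. Low-abundance replicate
dropout, multiplicative single-replicate outlier spikes, a host/symbiont
catalog mixture with housekeeping proteins pinned at fold change 0, and a
location-scale target/decoy score model complete the picture. Every latent
value is recorded so downstream estimates can be scored without
re-simulation.

The respirometry generator produces flow-through vessel traces whose
outflow obeys the steady-state mass balance for a planted uptake rate,
perturbed by multiplicative measurement noise, plus empty control vessels
with optional drift.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ValidationError
from .psm_io import (
    PATHWAY_VOCABULARY,
    PSM_COLUMNS,
    CountMatrix,
    ProteinCatalog,
    write_protein_catalog,
    write_psm_table,
    write_trace_table,
    _write_table,
)
from .respirometry import RespirometryTrace

AA = "ACDEFGHIKLMNPQRSTVWY"
COG_LETTERS = list("CEFGHIJKLMNOPTU")
SYMBIONT_TAGS = (
    "nitrogen",
    "sulfur_oxidation",
    "thiosulfate_oxidation",
    "rTCA",
    "CBB",
    "transport",
    "energy_storage",
)


@dataclass
class SimulationConfig:
    """Study-design parameters for the PSM dataset generator.

    Defaults emulate the quadruplicate two-site design the pipeline is
    built for: 500 proteins, 4+4 replicates, negative-binomial counts with
    dispersion 0.2 and base means 30-300, ~40% of proteins differential
    with N(0, 1) log2 fold changes, 10 housekeeping proteins at fold
    change 0 and base mean 50, mild mean-dependent dropout, and rare 5x
    single-replicate outlier spikes.
    """

    n_proteins: int = 500
    host_fraction: float = 0.25
    n_replicates: int = 4
    base_mean_low: float = 30.0
    base_mean_high: float = 300.0
    dispersion: float = 0.2  # NB: var = m + dispersion * m^2; 0 => deterministic
    fraction_differential: float = 0.4
    fc_sd: float = 1.0
    n_housekeeping: int = 10
    housekeeping_mean: float = 50.0
    dropout_rate: float = 0.1  # p_drop = rate * exp(-mean / dropout_mean_scale)
    dropout_mean_scale: float = 30.0
    outlier_rate: float = 0.02  # per (protein, site): one replicate spiked
    outlier_magnitude: float = 5.0
    site_depth: dict = field(default_factory=lambda: {"A": 1.0, "B": 1.0})
    peptide_pool_min: int = 3
    peptide_pool_max: int = 12
    low_peptide_fraction: float = 0.1  # proteins with a 1-2 peptide pool
    target_score_mean: float = 8.0
    target_score_sd: float = 1.0
    decoy_score_mean: float = 4.0
    decoy_score_sd: float = 1.0
    decoy_fraction: float = 0.1  # decoy PSMs relative to target PSMs
    mass_error_sd: float = 1.2  # ppm; a small tail falls beyond the 3 ppm gate
    enriched_pathway: str | None = None  # plant a pathway-wide fold change
    enrichment_fold: float = 1.0  # A/B fold applied to members of enriched_pathway
    expand_psms: bool = True
    seed: int = 0

    def validate(self) -> None:
        probs = {
            "host_fraction": self.host_fraction,
            "fraction_differential": self.fraction_differential,
            "dropout_rate": self.dropout_rate,
            "outlier_rate": self.outlier_rate,
            "low_peptide_fraction": self.low_peptide_fraction,
        }
        for name, p in probs.items():
            if not (0 <= p <= 1):
                raise ValidationError(f"{name} must lie in [0, 1], got {p}")
        if self.n_proteins < 1 or self.n_replicates < 1:
            raise ValidationError("n_proteins and n_replicates must be >= 1")
        if self.base_mean_low <= 0 or self.base_mean_high < self.base_mean_low:
            raise ValidationError("base mean range must satisfy 0 < low <= high")
        if self.dispersion < 0:
            raise ValidationError("dispersion must be >= 0")
        if self.enriched_pathway is not None:
            if self.enriched_pathway not in PATHWAY_VOCABULARY:
                raise ValidationError(f"unknown pathway {self.enriched_pathway!r}")
            if self.enrichment_fold <= 0:
                raise ValidationError("enrichment_fold must be positive")
        for site, d in self.site_depth.items():
            if d <= 0:
                raise ValidationError(f"site_depth[{site!r}] must be positive")


@dataclass
class SimulatedDataset:
    """Generator output plus the latent truth needed to score the pipeline."""

    psms: pd.DataFrame
    catalog: ProteinCatalog
    protein_truth: pd.DataFrame  # accession-indexed latent protein parameters
    count_truth: pd.DataFrame  # tidy (accession, site, replicate, count)
    config: SimulationConfig

    def site_psm_totals(self) -> dict:
        """Target PSM totals per site, from the latent count bookkeeping."""
        return self.count_truth.groupby("site")["count"].sum().to_dict()

    def truth_count_matrix(self) -> CountMatrix:
        """CountMatrix of the latent counts (bypasses PSM expansion).

        unique_peptides is the deterministic bound min(pool size, largest
        replicate count at the site).
        """
        cols = pd.MultiIndex.from_tuples(
            [(s, r) for s in ("A", "B") for r in range(1, self.config.n_replicates + 1)],
            names=["site", "replicate"],
        )
        counts = (
            self.count_truth.pivot_table(
                index="accession", columns=["site", "replicate"], values="count"
            )
            .reindex(columns=cols)
            .fillna(0)
            .astype(np.int64)
            .sort_index()
        )
        pools = self.protein_truth["pool_size"].reindex(counts.index)
        uniq = pd.DataFrame(index=counts.index)
        for s in ("A", "B"):
            uniq[s] = np.minimum(pools, counts[s].max(axis=1)).astype(np.int64)
        counts.index.name = "accession"
        return CountMatrix(counts, uniq)

    def write(self, outdir, comment: str | None = None) -> dict:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        paths = {
            "psm": outdir / "psm.tsv",
            "catalog": outdir / "catalog.tsv",
            "truth_proteins": outdir / "truth_proteins.tsv",
            "truth_counts": outdir / "truth_counts.tsv",
        }
        write_psm_table(self.psms, paths["psm"], comment)
        write_protein_catalog(self.catalog, paths["catalog"], comment)
        _write_table(self.protein_truth.reset_index(), paths["truth_proteins"], comment)
        _write_table(self.count_truth, paths["truth_counts"], comment)
        return paths


def _random_peptide(rng: np.random.Generator) -> str:
    length = int(rng.integers(8, 16))
    return "".join(rng.choice(list(AA), size=length))


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    if dispersion == 0:
        return np.round(mean).astype(np.int64)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam).astype(np.int64)


def gen_psm_dataset(config: SimulationConfig | None = None) -> SimulatedDataset:
    """Generate a PSM table, protein catalog and latent truth tables."""
    config = config or SimulationConfig()
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    accs = np.array([f"P{i:05d}" for i in range(1, n + 1)])

    n_host = int(round(config.host_fraction * n))
    origin = np.where(rng.permutation(n) < n_host, "host", "symbiont")
    symbiont_idx = np.flatnonzero(origin == "symbiont")

    base_mean = np.exp(
        rng.uniform(np.log(config.base_mean_low), np.log(config.base_mean_high), size=n)
    )
    is_diff = rng.random(n) < config.fraction_differential
    log2_fc = np.where(is_diff, rng.normal(0.0, config.fc_sd, size=n), 0.0)

    housekeeping = np.zeros(n, dtype=bool)
    n_hk = min(config.n_housekeeping, symbiont_idx.size)
    hk_idx = rng.choice(symbiont_idx, size=n_hk, replace=False)
    housekeeping[hk_idx] = True
    log2_fc[hk_idx] = 0.0
    base_mean[hk_idx] = config.housekeeping_mean

    # catalog annotation
    cogs = np.where(
        origin == "symbiont", rng.choice(COG_LETTERS, size=n), "unassigned"
    )
    pathways = [frozenset() for _ in range(n)]
    for i in symbiont_idx:
        if housekeeping[i]:
            continue
        if rng.random() < 0.25:
            pathways[i] = frozenset({str(rng.choice(SYMBIONT_TAGS))})
    if config.enriched_pathway is not None:
        planted_fc = float(np.log2(config.enrichment_fold))
        for i in range(n):
            if config.enriched_pathway in pathways[i]:
                log2_fc[i] = planted_fc

    pool_size = rng.integers(config.peptide_pool_min, config.peptide_pool_max + 1, size=n)
    low = rng.random(n) < config.low_peptide_fraction
    pool_size[low] = rng.integers(1, 3, size=int(low.sum()))

    # latent counts: mean split symmetrically between sites, per-site depth
    sites = ("A", "B")
    reps = range(1, config.n_replicates + 1)
    mean_site = {
        "A": base_mean * 2 ** (log2_fc / 2) * config.site_depth.get("A", 1.0),
        "B": base_mean * 2 ** (-log2_fc / 2) * config.site_depth.get("B", 1.0),
    }
    count_rows = []
    counts = {}
    for s in sites:
        for r in reps:
            c = _nb_counts(rng, mean_site[s], config.dispersion)
            if config.dropout_rate > 0:
                p_drop = config.dropout_rate * np.exp(-mean_site[s] / config.dropout_mean_scale)
                c = np.where(rng.random(n) < p_drop, 0, c)
            counts[(s, r)] = c
        if config.outlier_rate > 0:
            spiked = rng.random(n) < config.outlier_rate
            which_rep = rng.integers(1, config.n_replicates + 1, size=n)
            for r in reps:
                sel = spiked & (which_rep == r)
                counts[(s, r)] = np.where(
                    sel, np.round(counts[(s, r)] * config.outlier_magnitude), counts[(s, r)]
                ).astype(np.int64)
    for s in sites:
        for r in reps:
            for i in range(n):
                count_rows.append((accs[i], s, r, int(counts[(s, r)][i])))
    count_truth = pd.DataFrame(count_rows, columns=["accession", "site", "replicate", "count"])

    protein_truth = pd.DataFrame(
        {
            "origin": origin,
            "cog": cogs,
            "housekeeping": housekeeping,
            "base_mean": base_mean,
            "log2_fc": log2_fc,
            "pool_size": pool_size,
            "mean_A": mean_site["A"],
            "mean_B": mean_site["B"],
        },
        index=pd.Index(accs, name="accession"),
    )

    catalog_frame = pd.DataFrame(
        {
            "origin": origin,
            "cog": cogs,
            "pathways": pathways,
            "housekeeping": housekeeping,
            "description": [f"simulated protein {a}" for a in accs],
        },
        index=pd.Index(accs, name="accession"),
    )
    catalog = ProteinCatalog(catalog_frame)

    if config.expand_psms:
        pools = [
            [_random_peptide(rng) for _ in range(int(pool_size[i]))] for i in range(n)
        ]
        rec_acc, rec_pep, rec_site, rec_rep = [], [], [], []
        for s in sites:
            for r in reps:
                c = counts[(s, r)]
                for i in np.flatnonzero(c > 0):
                    k = int(c[i])
                    idx = rng.integers(0, pool_size[i], size=k)
                    rec_acc.extend([accs[i]] * k)
                    rec_pep.extend(pools[i][j] for j in idx)
                    rec_site.extend([s] * k)
                    rec_rep.extend([r] * k)
        n_target = len(rec_acc)
        n_decoy = int(round(config.decoy_fraction * n_target))
        dec_site = rng.choice(sites, size=n_decoy)
        dec_rep = rng.integers(1, config.n_replicates + 1, size=n_decoy)
        psms = pd.DataFrame(
            {
                "spectrum_id": "",
                "peptide": rec_pep + [_random_peptide(rng) for _ in range(n_decoy)],
                "accession": rec_acc + [f"DEC{i:06d}" for i in range(n_decoy)],
                "site": rec_site + list(dec_site),
                "replicate": np.concatenate(
                    [np.asarray(rec_rep, dtype=np.int64), dec_rep.astype(np.int64)]
                ),
                "score": np.concatenate(
                    [
                        rng.normal(config.target_score_mean, config.target_score_sd, n_target),
                        rng.normal(config.decoy_score_mean, config.decoy_score_sd, n_decoy),
                    ]
                ),
                "mass_error_ppm": rng.normal(0.0, config.mass_error_sd, n_target + n_decoy),
                "is_decoy": [False] * n_target + [True] * n_decoy,
            },
            columns=list(PSM_COLUMNS),
        )
        psms = psms.iloc[rng.permutation(len(psms))].reset_index(drop=True)
        psms["spectrum_id"] = [f"scan{i:07d}" for i in range(len(psms))]
    else:
        psms = pd.DataFrame(columns=list(PSM_COLUMNS))

    return SimulatedDataset(psms, catalog, protein_truth, count_truth, config)


# ---------------------------------------------------------------------------
# Respirometry traces


def gen_respirometry_trace(
    rate_true: float,
    noise: float = 0.05,
    n_points: int = 50,
    seed: int = 0,
    c_in: float = 40.0,
    flow: float = 1.0,
    wet_weight: float = 10.0,
    duration_h: float = 10.0,
    substrate: str = "nitrate",
    vessel_id: str = "V1",
    is_control: bool = False,
    drift: float = 0.0,
) -> tuple[RespirometryTrace, dict]:
    """One flow-through trace with a planted uptake rate.

    Clean outflow is c_in - rate * weight / flow (controls: c_in plus a
    linear drift); multiplicative Gaussian noise of relative SD *noise* is
    applied to the outflow. Returns the trace and a truth dict.
    """
    if not np.isfinite(rate_true):
        raise ValidationError("rate_true must be finite")
    if n_points < 3:
        raise ValidationError("need n_points >= 3")
    rng = np.random.default_rng(seed)
    times = np.linspace(0.0, duration_h, n_points)
    if is_control:
        clean = c_in * (1.0 + drift * times / max(duration_h, 1e-12))
    else:
        clean = np.full(n_points, c_in - rate_true * wet_weight / flow)
    if (clean < 0).any():
        raise ValidationError(
            "parameters imply negative outflow concentration; lower rate_true or raise c_in"
        )
    c_out = np.clip(clean * (1.0 + noise * rng.standard_normal(n_points)), 0.0, None)
    trace = RespirometryTrace(
        vessel_id=vessel_id,
        substrate=substrate,
        times=times,
        c_in=np.full(n_points, c_in),
        c_out=c_out,
        flow=flow,
        wet_weight=wet_weight if not is_control else 0.0,
        is_control=is_control,
    )
    truth = {
        "vessel_id": vessel_id,
        "rate_true": 0.0 if is_control else rate_true,
        "noise": noise,
        "seed": seed,
    }
    return trace, truth


def gen_slope_experiment(
    slope: float,
    ambients=(10.0, 20.0, 30.0, 40.0),
    noise: float = 0.10,
    n_points: int = 50,
    seed: int = 0,
    flow: float = 1.0,
    wet_weight: float = 10.0,
    substrate: str = "ammonium",
    vessel_prefix: str = "V",
) -> tuple[list[RespirometryTrace], dict]:
    """Traces across ambient concentrations with rate = slope * ambient.

    The inflow is set so the clean chamber (outflow) concentration equals
    each target ambient value, i.e. c_in = ambient + rate * weight / flow.
    """
    traces = []
    truth = {"slope_true": slope, "ambients": list(ambients)}
    for j, amb in enumerate(ambients):
        rate = slope * amb
        trace, _ = gen_respirometry_trace(
            rate_true=rate,
            noise=noise,
            n_points=n_points,
            seed=seed * 1009 + j,
            c_in=amb + rate * wet_weight / flow,
            flow=flow,
            wet_weight=wet_weight,
            substrate=substrate,
            vessel_id=f"{vessel_prefix}{j + 1}",
        )
        traces.append(trace)
    return traces, truth


def traces_to_table(traces) -> pd.DataFrame:
    rows = []
    for t in traces:
        for i in range(len(t.times)):
            rows.append(
                {
                    "vessel_id": t.vessel_id,
                    "substrate": t.substrate,
                    "time_h": t.times[i],
                    "c_in_uM": t.c_in[i],
                    "c_out_uM": t.c_out[i],
                    "flow_L_h": t.flow,
                    "wet_weight_g": t.wet_weight,
                    "is_control": t.is_control,
                }
            )
    return pd.DataFrame(rows)


def write_traces(traces, path, comment: str | None = None) -> None:
    write_trace_table(traces_to_table(traces), path, comment)


def config_from_dict(d: dict) -> SimulationConfig:
    known = {f for f in SimulationConfig.__dataclass_fields__}
    unknown = set(d) - known
    if unknown:
        raise ValidationError(f"unknown simulation config field(s): {sorted(unknown)}")
    return SimulationConfig(**d)


def config_to_dict(config: SimulationConfig) -> dict:
    return asdict(config)
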