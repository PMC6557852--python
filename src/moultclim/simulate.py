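"""Synthetic museum-specimen datasets with the structure the analysis assumes.

The generator emulates all pipeline inputs: an ultrametric pure-birth
phylogeny, phylogenetically correlated per-species regression coefficients,
a two-source temperature-anomaly series centred on the 1951–1980 reference
window, species tract-area tables, and per-feather specimen records whose
moulted areas are Gamma draws around an identity-link mean

    µ = intercept + slope·GMTA(year) + sex_effect·male + interaction·male·GMTA(year).

Each drawn area is realised into 0/1 feather scores deterministically: tracts
fill in moult-priority order, feathers within a tract in label order, until
the drawn area is exhausted — so scoring a generated record recovers the
drawn area up to less than one feather's area.

Default magnitudes mirror the study conditions: 19 species sampled over
1805–2016 (per-species data start years 1805–1864), roughly 200 specimens per
species, an anomaly series rising about 2.0 °C over the period, and moulted
areas around 1100 mm² against wing+tail totals near 6000 mm².
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import dendropy
import numpy as np
import pandas as pd

from .gmta import (
    SOURCE_INSTRUMENTAL,
    SOURCE_RECONSTRUCTED,
    GmtaSeries,
)
from .pgls import brownian_vcv, apply_lambda, tip_labels, tree_to_newick
from .scoring import (
    FeatherTractLayout,
    MoultRecord,
    TractAreaTable,
    default_layout,
)

logger = logging.getLogger("moultclim.simulate")


class SimulationError(ValueError):
    """Raised for infeasible generator configurations."""


#: species-independent baseline tract areas (mm²), scaled per species by a
#: lognormal body-size factor; roughly a mid-sized passerine wing+tail
BASE_TRACT_AREAS = {
    "LC": 300.0, "MC": 400.0, "GC": 800.0, "CC": 50.0, "AL": 150.0,
    "PC": 300.0, "P": 1500.0, "S": 900.0, "T": 350.0, "R": 1200.0,
}

_INSTRUMENTAL_FROM = 1880


@dataclasses.dataclass
class SyntheticConfig:
    """Generator settings; the defaults define the emulated study conditions."""

    n_species: int = 19
    n_specimens: int = 200
    year_start: int = 1805
    year_end: int = 2016
    reference_window: tuple[int, int] = (1951, 1980)
    data_start_range: tuple[int, int] = (1805, 1864)
    intercept_mean: float = 1100.0
    intercept_sd: float = 150.0
    gmta_slope_mean: float = 150.0
    gmta_slope_sd: float = 50.0
    sex_effect: float = 100.0
    interaction_mean: float = 0.0
    interaction_sd: float = 25.0
    ornamentation_slope: float = -150.0
    lambda_true: float = 0.5
    gamma_shape: float = 25.0
    dichromatic_fraction: float = 10.0 / 19.0
    gmta_rise: float = 2.0
    gmta_noise_sd: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_species < 2:
            raise SimulationError("need at least 2 species")
        if not (0.0 <= self.lambda_true <= 1.0):
            raise SimulationError("lambda_true must lie in [0, 1]")
        if self.gamma_shape <= 0:
            raise SimulationError("gamma_shape must be positive")
        for name in ("intercept_sd", "gmta_slope_sd", "interaction_sd", "gmta_noise_sd"):
            if getattr(self, name) < 0:
                raise SimulationError(f"{name} must be non-negative")
        lo, hi = self.reference_window
        if not (self.year_start <= lo <= hi <= self.year_end):
            raise SimulationError("reference window must lie within the year span")
        if not (0.0 <= self.dichromatic_fraction <= 1.0):
            raise SimulationError("dichromatic_fraction must lie in [0, 1]")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["reference_window"] = list(self.reference_window)
        d["data_start_range"] = list(self.data_start_range)
        return d


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------

def simulate_tree(n_tips: int, seed: int) -> dendropy.Tree:
    """Pure-birth (Yule) tree with unit speciation rate: exponential waiting
    times between splits, a uniformly chosen lineage splitting each time.
    Ultrametric by construction and deterministic per seed; tips are labelled
    sp01, sp02, ... in traversal order."""
    if n_tips < 2:
        raise SimulationError("a tree needs at least 2 tips")
    rng = np.random.default_rng(seed)
    tree = dendropy.Tree()
    root = tree.seed_node
    pending: dict = {root.new_child(): 0.0, root.new_child(): 0.0}
    while len(pending) < n_tips:
        k = len(pending)
        wait = rng.exponential(1.0 / k)
        for node in pending:
            pending[node] += wait
        chosen = list(pending)[int(rng.integers(k))]
        chosen.edge.length = pending.pop(chosen)
        pending[chosen.new_child()] = 0.0
        pending[chosen.new_child()] = 0.0
    tail = rng.exponential(1.0 / n_tips)
    for node, length in pending.items():
        node.edge.length = length + tail
    root.edge.length = 0.0
    ns = tree.taxon_namespace
    for i, leaf in enumerate(tree.leaf_node_iter()):
        leaf.taxon = ns.new_taxon(f"sp{i + 1:02d}")
    return tree


# ---------------------------------------------------------------------------
# GMTA
# ---------------------------------------------------------------------------

def simulate_gmta(
    years: tuple[int, int] = (1805, 2016),
    rise: float = 2.0,
    noise_sd: float = 0.05,
    seed: int = 0,
    reference_window: tuple[int, int] = (1951, 1980),
) -> GmtaSeries:
    """Accelerating (quadratic-in-time) warming trend plus white noise,
    centred so the mean over the reference window is exactly zero.  Years
    before 1880 are tagged as reconstructed, later ones as instrumental."""
    y0, y1 = years
    if y1 - y0 < 1:
        raise SimulationError("GMTA span must cover at least 2 years")
    lo, hi = reference_window
    if not (y0 <= lo <= hi <= y1):
        raise SimulationError("reference window must lie within the simulated span")
    rng = np.random.default_rng(seed)
    yr = np.arange(y0, y1 + 1)
    t = (yr - y0) / (y1 - y0)
    values = rise * t**2 + rng.normal(0.0, noise_sd, size=len(yr))
    ref = (yr >= lo) & (yr <= hi)
    values = values - values[ref].mean()
    sources = np.where(yr >= _INSTRUMENTAL_FROM, SOURCE_INSTRUMENTAL, SOURCE_RECONSTRUCTED)
    return GmtaSeries(years=yr, anomalies=values, sources=sources.astype(object))


# ---------------------------------------------------------------------------
# Species-level parameters
# ---------------------------------------------------------------------------

def _structured_noise(L: np.ndarray, sd: float, rng: np.random.Generator) -> np.ndarray:
    return sd * (L @ rng.standard_normal(L.shape[0]))


def simulate_species_coefficients(
    tree: dendropy.Tree,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Per-species true coefficients and metadata.

    Intercept, GMTA slope and the interaction's residual noise are drawn from
    multivariate normals whose covariance is sd²·Ṽ(λ_true), where Ṽ is the
    Brownian correlation matrix of the tree (unit diagonal), so λ_true sets
    the phylogenetic signal of the species effects.  In dichromatic species
    the GMTA×sex interaction is ornamentation_slope × (male − female
    ornamentation difference) plus that structured noise.
    """
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    species = tip_labels(tree)
    n = len(species)
    C = brownian_vcv(tree, species)
    corr = C / np.mean(np.diag(C))
    np.fill_diagonal(corr, 1.0)
    V = apply_lambda(corr, config.lambda_true)
    L = np.linalg.cholesky(V + 1e-10 * np.eye(n))

    intercept = config.intercept_mean + _structured_noise(L, config.intercept_sd, rng)
    slope = config.gmta_slope_mean + _structured_noise(L, config.gmta_slope_sd, rng)

    n_dichromatic = int(round(config.dichromatic_fraction * n))
    dichromatic = np.zeros(n, dtype=bool)
    dichromatic[rng.permutation(n)[:n_dichromatic]] = True

    ornament_male = rng.uniform(1.0, 3.0, size=n)
    orn_diff = np.where(dichromatic, rng.uniform(0.1, 1.5, size=n), 0.0)
    ornament_female = ornament_male - orn_diff

    interaction = (
        config.interaction_mean
        + config.ornamentation_slope * orn_diff
        + _structured_noise(L, config.interaction_sd, rng)
    )
    interaction = np.where(dichromatic, interaction, 0.0)
    sex_effect = np.where(dichromatic, config.sex_effect, 0.0)

    # fixed group sizes (≈12/19 short-distance, ≈15/19 pre-migration moult,
    # at least 2 per class) assigned to a random species subset
    n_long = max(2, int(round(7.0 / 19.0 * n)))
    long_idx = rng.permutation(n)[:n_long]
    migration_km = rng.uniform(300.0, 1800.0, size=n)
    migration_km[long_idx] = rng.uniform(3000.0, 6000.0, size=n_long)
    n_post = max(2, int(round(4.0 / 19.0 * n)))
    post_idx = rng.permutation(n)[:n_post]
    strategy = np.array(["pre"] * n, dtype=object)
    strategy[post_idx] = "post"

    start_lo, start_hi = config.data_start_range
    start_year = rng.integers(start_lo, start_hi + 1, size=n)

    return pd.DataFrame(
        {
            "intercept": intercept,
            "gmta_slope": slope,
            "sex_effect": sex_effect,
            "interaction": interaction,
            "dichromatic": dichromatic,
            "ornament_male": ornament_male,
            "ornament_female": ornament_female,
            "migration_km": migration_km,
            "moult_strategy": strategy,
            "start_year": start_year,
        },
        index=pd.Index(species, name="species_id"),
    )


def simulate_tract_areas(
    species: list[str], rng: np.random.Generator, layout: FeatherTractLayout | None = None
) -> TractAreaTable:
    """Species tract areas: the baseline table scaled by a per-species
    lognormal body-size factor (σ = 0.15)."""
    layout = layout or default_layout()
    areas = {}
    for sp in species:
        factor = float(rng.lognormal(0.0, 0.15))
        for tract in layout.tracts:
            areas[(sp, tract.name)] = BASE_TRACT_AREAS[tract.name] * factor
    return TractAreaTable(areas)


# ---------------------------------------------------------------------------
# Specimens
# ---------------------------------------------------------------------------

def allocate_area(
    area: float,
    species_id: str,
    areas: TractAreaTable,
    layout: FeatherTractLayout,
) -> tuple[dict[str, int | None], float, float]:
    """Realise a moulted area into feather scores by the layout's priority
    order: proportion tracts absorb exactly, discrete tracts fill whole
    feathers in label order; allocation stops at the first unaffordable
    feather, so the quantisation error is below one feather's area."""
    remaining = float(area)
    scores: dict[str, int | None] = {label: 0 for label in layout.discrete_labels}
    lc = mc = 0.0
    for tract in layout.by_priority:
        tract_area = areas.area(species_id, tract.name)
        if tract.is_proportion:
            take = min(remaining, tract_area)
            prop = take / tract_area
            if tract.name == "LC":
                lc = prop
            else:
                mc = prop
            remaining -= take
        else:
            per_feather = tract_area / tract.n_feathers
            stopped = False
            for label in tract.labels:
                if remaining >= per_feather - 1e-9:
                    scores[label] = 1
                    remaining = max(remaining - per_feather, 0.0)
                else:
                    stopped = True
                    break
            if stopped:
                break
    return scores, lc, mc


def simulate_specimens(
    coefficients: pd.DataFrame,
    gmta: GmtaSeries,
    areas: TractAreaTable,
    layout: FeatherTractLayout,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> list[MoultRecord]:
    """Draw per-specimen moulted areas from the identity-link Gamma model and
    realise them into per-feather records."""
    rng = rng if rng is not None else np.random.default_rng(config.seed)
    records: list[MoultRecord] = []
    n_capped = 0
    for species in coefficients.index:
        row = coefficients.loc[species]
        start = int(row["start_year"])
        years = np.arange(start, config.year_end + 1)
        anomalies = np.array([gmta.anomaly_for_year(y) for y in years])
        g_lo, g_hi = float(anomalies.min()), float(anomalies.max())
        dichromatic = bool(row["dichromatic"])
        for male in (0.0, 1.0) if dichromatic else (0.0,):
            for g in (g_lo, g_hi):
                mu = (
                    row["intercept"]
                    + row["gmta_slope"] * g
                    + row["sex_effect"] * male
                    + row["interaction"] * male * g
                )
                if mu <= 0:
                    raise SimulationError(
                        f"{species}: implied mean {mu:.1f} mm² ≤ 0 at anomaly {g:.2f} "
                        f"(male={int(male)}); choose a larger intercept or weaker slopes"
                    )
        total = areas.total_area(species, layout)
        for j in range(config.n_specimens):
            year = int(rng.integers(start, config.year_end + 1))
            g = gmta.anomaly_for_year(year)
            if dichromatic:
                male = float(rng.integers(2))
                sex = "male" if male else "female"
            else:
                male, sex = 0.0, "unknown"
            mu = (
                row["intercept"]
                + row["gmta_slope"] * g
                + row["sex_effect"] * male
                + row["interaction"] * male * g
            )
            drawn = float(rng.gamma(config.gamma_shape, mu / config.gamma_shape))
            if drawn > total:
                drawn = total
                n_capped += 1
            scores, lc, mc = allocate_area(drawn, species, areas, layout)
            records.append(
                MoultRecord(
                    specimen_id=f"{species}-{j:04d}",
                    species_id=species,
                    collection_year=year,
                    sex=sex,
                    feather_scores=scores,
                    lc_proportion=lc,
                    mc_proportion=mc,
                )
            )
    if n_capped:
        logger.info("capped %d drawn areas at the species total", n_capped)
    return records


# ---------------------------------------------------------------------------
# Whole datasets
# ---------------------------------------------------------------------------

METADATA_COLUMNS = (
    "dichromatic", "ornament_male", "ornament_female",
    "migration_km", "moult_strategy", "start_year",
)


@dataclasses.dataclass
class SyntheticDataset:
    """A complete generated input bundle plus the generating truth."""

    config: SyntheticConfig
    tree: dendropy.Tree
    coefficients: pd.DataFrame  # includes the true parameters
    areas: TractAreaTable
    gmta: GmtaSeries
    records: list[MoultRecord]
    layout: FeatherTractLayout

    @property
    def metadata(self) -> pd.DataFrame:
        return self.coefficients[list(METADATA_COLUMNS)].copy()


def simulate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a full dataset; fully determined by the config (incl. seed)."""
    ss = np.random.SeedSequence(config.seed)
    s_tree, s_gmta, s_coef, s_spec, s_area = ss.spawn(5)
    layout = default_layout()
    tree = simulate_tree(config.n_species, seed=int(s_tree.generate_state(1)[0] % 2**31))
    series = simulate_gmta(
        years=(config.year_start, config.year_end),
        rise=config.gmta_rise,
        noise_sd=config.gmta_noise_sd,
        seed=int(s_gmta.generate_state(1)[0] % 2**31),
        reference_window=config.reference_window,
    )
    coefficients = simulate_species_coefficients(tree, config, rng=np.random.default_rng(s_coef))
    areas = simulate_tract_areas(list(coefficients.index), np.random.default_rng(s_area), layout)
    records = simulate_specimens(
        coefficients, series, areas, layout, config, rng=np.random.default_rng(s_spec)
    )
    return SyntheticDataset(
        config=config, tree=tree, coefficients=coefficients, areas=areas,
        gmta=series, records=records, layout=layout,
    )


def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, Path]:
    """Write the dataset in the same dialects the pipeline reads, plus a
    manifest recording the config, and the true coefficients for reference."""
    from .scoring import write_specimen_csv  # local to avoid re-export confusion

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "specimens": outdir / "specimens.csv",
        "areas": outdir / "tract_areas.csv",
        "gmta_instrumental": outdir / "gmta_instrumental.csv",
        "metadata": outdir / "species_metadata.csv",
        "tree": outdir / "tree.nwk",
        "truth": outdir / "true_coefficients.csv",
        "manifest": outdir / "dataset_manifest.json",
    }
    write_specimen_csv(dataset.records, paths["specimens"], dataset.layout)
    dataset.areas.to_frame().to_csv(paths["areas"], index=False, float_format="%.10g")
    frame = dataset.gmta.to_frame(include_source=False)
    instr = frame[dataset.gmta.years >= _INSTRUMENTAL_FROM]
    recon = frame[dataset.gmta.years < _INSTRUMENTAL_FROM]
    instr.to_csv(paths["gmta_instrumental"], index=False, float_format="%.12g")
    if not recon.empty:
        paths["gmta_reconstruction"] = outdir / "gmta_reconstruction.csv"
        recon.to_csv(paths["gmta_reconstruction"], index=False, float_format="%.12g")
    dataset.metadata.to_csv(paths["metadata"], float_format="%.10g")
    with open(paths["tree"], "w") as fh:
        fh.write(tree_to_newick(dataset.tree))
    dataset.coefficients.to_csv(paths["truth"], float_format="%.12g")
    with open(paths["manifest"], "w") as fh:
        json.dump(
            {"config": dataset.config.to_dict(), "n_records": len(dataset.records)},
            fh, indent=2, sort_keys=True,
        )
        fh.write("\n")
    return paths
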