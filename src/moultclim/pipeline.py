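"""End-to-end orchestration: scoring → covariate join → per-species model
selection → cross-species comparative stage.

``run_full_analysis`` reads the five inputs (specimen table, tract areas, one
or two anomaly series, species metadata, Newick tree), and writes five
outputs into the run directory: the per-specimen extent table, the annual
moult-index series, the per-species AICc selection table, the comparative
PGLS reports (migration-distance contrast, moult-strategy contrast,
ornamentation regression) and a run manifest.  Identical config + inputs
produce byte-identical outputs; every output table carries the manifest hash
in a leading comment line.  Any stage failure removes partial outputs and
raises a stage-named error.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import pandas as pd

from . import __version__
from .glm import per_species_analysis, selection_table, SelectionResult
from .gmta import composite_series, load_gmta_table, GmtaSeries
from .pgls import group_contrast, ornamentation_regression, read_tree
from .scoring import (
    TractAreaTable,
    annual_moult_index,
    default_layout,
    read_specimen_csv,
    score_records,
)

logger = logging.getLogger("moultclim.pipeline")

STAGES = ("validate", "load", "score", "index", "glm", "pgls", "write")


class PipelineError(RuntimeError):
    """A stage failure; ``stage`` names the stage that failed."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclasses.dataclass
class RunConfig:
    """Validated run settings (paths and analysis choices)."""

    specimens: str
    areas: str
    gmta_instrumental: str
    metadata: str
    tree: str
    outdir: str
    gmta_reconstruction: str | None = None
    response: str = "area"  # or "relative_extent"
    covariate: str = "gmta"  # or "year"
    delta_aicc_threshold: float = 2.0
    lambda_mode: str | float = "ML"
    min_specimens: int = 30
    migration_split_km: float = 2000.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.delta_aicc_threshold <= 0:
            raise PipelineError("validate", "delta_aicc_threshold must be positive")
        if self.response not in ("area", "relative_extent"):
            raise PipelineError("validate", f"unknown response {self.response!r}")
        if self.covariate not in ("gmta", "year"):
            raise PipelineError("validate", f"unknown covariate {self.covariate!r}")

    def input_paths(self) -> dict[str, str]:
        paths = {
            "specimens": self.specimens,
            "areas": self.areas,
            "gmta_instrumental": self.gmta_instrumental,
            "metadata": self.metadata,
            "tree": self.tree,
        }
        if self.gmta_reconstruction:
            paths["gmta_reconstruction"] = self.gmta_reconstruction
        return paths

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["lambda_mode"] = self.lambda_mode if isinstance(self.lambda_mode, str) else float(self.lambda_mode)
        return d


def load_run_config(path) -> RunConfig:
    """Read a flat key:value config file (YAML mapping of scalars)."""
    import yaml

    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise PipelineError("validate", f"{path}: config must be a flat key-value mapping")
    fields = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - fields
    if unknown:
        raise PipelineError("validate", f"{path}: unknown config keys {sorted(unknown)}")
    return RunConfig(**raw)


def _config_hash(config: RunConfig) -> str:
    payload = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def _write_table(frame: pd.DataFrame, path: Path, manifest_hash: str) -> None:
    with open(path, "w") as fh:
        fh.write(f"# manifest_hash={manifest_hash}\n")
        frame.to_csv(fh, index=False, float_format="%.12g")


def _gmta_coefficient(result: SelectionResult) -> float | None:
    """Per-species GMTA response for the comparative stage: the selected
    model's GMTA coefficient, else the lowest-AICc GMTA-containing candidate's."""
    fit = result.selected_fit
    if fit is not None and "gmta" in fit.coefficients:
        return fit.coefficients["gmta"]
    gmta_fits = [f for f in result.fits if "gmta" in f.coefficients]
    if not gmta_fits:
        return None
    best = min(gmta_fits, key=lambda f: f.aicc)
    return best.coefficients["gmta"]


def run_full_analysis(config: RunConfig) -> dict:
    """Run the whole pipeline; returns output paths and in-memory results."""
    t0 = time.perf_counter()
    created: list[Path] = []
    stage = "validate"
    try:
        for name, p in config.input_paths().items():
            if not Path(p).is_file():
                raise PipelineError(stage, f"input {name!r} not found: {p}")
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        manifest_hash = _config_hash(config)

        stage = "load"
        layout = default_layout()
        records = read_specimen_csv(config.specimens, layout)
        areas = TractAreaTable.from_csv(config.areas)
        instrumental = load_gmta_table(config.gmta_instrumental, "instrumental")
        if config.gmta_reconstruction:
            reconstruction = load_gmta_table(config.gmta_reconstruction, "reconstructed")
            gmta: GmtaSeries = composite_series(instrumental, reconstruction)
        else:
            gmta = instrumental
        metadata = pd.read_csv(config.metadata, comment="#").set_index("species_id")
        tree = read_tree(config.tree)
        areas.check_complete({r.species_id for r in records}, layout)
        logger.info("loaded %d records, %d species", len(records), metadata.shape[0])

        stage = "score"
        extent = score_records(records, areas, layout)
        extent_path = outdir / "specimen_extent.csv"
        _write_table(extent, extent_path, manifest_hash)
        created.append(extent_path)

        stage = "index"
        index = annual_moult_index(records, areas, layout)
        index_path = outdir / "moult_index.csv"
        _write_table(index.table, index_path, manifest_hash)
        created.append(index_path)

        stage = "glm"
        results = per_species_analysis(
            records, areas, layout, gmta, metadata,
            response=config.response, covariate=config.covariate,
            threshold=config.delta_aicc_threshold, on_zero="drop",
        )
        sel_table = selection_table(results)
        selection_path = outdir / "model_selection.csv"
        _write_table(sel_table, selection_path, manifest_hash)
        created.append(selection_path)

        stage = "pgls"
        counts = extent.groupby("species_id").size()
        eligible = sorted(
            sp for sp in results
            if counts.get(sp, 0) >= config.min_specimens
        )
        excluded = sorted(set(results) - set(eligible))
        if excluded:
            logger.warning(
                "excluding %d species with < %d specimens from the comparative "
                "stage: %s", len(excluded), config.min_specimens, excluded,
            )
        gmta_coef = pd.Series(
            {sp: _gmta_coefficient(results[sp]) for sp in eligible}, name="gmta_coefficient"
        ).dropna()
        migration_groups = pd.Series(
            {
                sp: "short" if metadata.loc[sp, "migration_km"] < config.migration_split_km else "long"
                for sp in gmta_coef.index
            }
        )
        strategy_groups = metadata.loc[gmta_coef.index, "moult_strategy"]
        migration_fit = group_contrast(gmta_coef, migration_groups, tree, config.lambda_mode)
        strategy_fit = group_contrast(gmta_coef, strategy_groups, tree, config.lambda_mode)
        dichromatic = [
            sp for sp in eligible
            if bool(metadata.loc[sp, "dichromatic"])
            and any(f.spec.has_interaction for f in results[sp].fits)
        ]
        interaction = pd.Series(
            {
                sp: results[sp].fit_for("gmta+sex+gmta:sex").coefficients["gmta:sex"]
                for sp in dichromatic
            },
            name="interaction",
        )
        ornament_fit = ornamentation_regression(
            interaction,
            metadata["ornament_male"],
            metadata["ornament_female"],
            tree,
            config.lambda_mode,
        )
        pgls_report = {
            "manifest_hash": manifest_hash,
            "migration_distance_contrast": migration_fit.to_dict(),
            "moult_strategy_contrast": strategy_fit.to_dict(),
            "ornamentation_regression": ornament_fit.to_dict(),
            "n_species_comparative": len(gmta_coef),
            "n_species_dichromatic": len(dichromatic),
        }
        pgls_path = outdir / "pgls_fits.json"
        with open(pgls_path, "w") as fh:
            json.dump(pgls_report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        created.append(pgls_path)

        stage = "write"
        manifest = {
            "config": config.to_dict(),
            "config_hash": manifest_hash,
            "package_version": __version__,
            "outputs": sorted(p.name for p in created) + ["run_manifest.json"],
            "n_records": len(records),
            "n_species_analysed": len(results),
        }
        manifest_path = outdir / "run_manifest.json"
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
        created.append(manifest_path)
    except PipelineError:
        _cleanup(created)
        raise
    except Exception as exc:
        _cleanup(created)
        raise PipelineError(stage, str(exc)) from exc
    logger.info("pipeline finished in %.1f s", time.perf_counter() - t0)
    return {
        "extent": extent_path,
        "index": index_path,
        "selection": selection_path,
        "pgls": pgls_path,
        "manifest": manifest_path,
        "results": results,
        "pgls_report": pgls_report,
        "manifest_hash": manifest_hash,
    }


def _cleanup(created: list[Path]) -> None:
    for p in created:
        try:
            p.unlink()
        except OSError:  # pragma: no cover
            pass
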