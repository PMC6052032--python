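"""End-to-end orchestration: spectra -> JND + SVM, behaviour -> GLMM fits.

``run_all`` sequences the whole analysis from either real input files
(reflectance CSV, behaviour CSVs) or, when paths are omitted, from the
seeded synthetic generators, and assembles one JSON results document.  Every
output embeds the hash of the configuration that produced it; a rerun with
the same configuration and seed is byte-identical.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import count_models, conspicuity, spectra as spectra_mod, svm_discrimination
from .exceptions import ConfigError, FlorisightError
from .photoreceptor import default_phenotypes, load_phenotypes
from .rnl import Illuminant
from .synthgen import BehaviorScenario, SpectraScenario, generate_behavior, generate_spectra

log = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Fully serialisable description of one analysis run."""

    seed: int = 0
    out_dir: str | None = None
    # spectral inputs (None -> synthetic scenario)
    spectra_path: str | None = None
    dialect: dict = field(default_factory=dict)
    spectra_scenario: dict = field(default_factory=dict)
    # behavioural inputs (None -> synthetic scenario)
    scans_path: str | None = None
    flpv_path: str | None = None
    roster_path: str | None = None
    hours_path: str | None = None
    behavior_scenario: dict = field(default_factory=dict)
    # model configuration
    phenotype_registry: str | None = None
    illuminant_path: str | None = None
    step: float = 1.0
    svm: dict = field(default_factory=dict)
    glmm: dict = field(default_factory=dict)
    # stage selection
    spectra_only: bool = False
    behavior_only: bool = False

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        extra = set(doc) - known
        if extra:
            raise ConfigError(f"unknown config keys: {sorted(extra)}")
        return cls(**doc)

    def hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def _load_or_generate_spectra(cfg: RunConfig):
    if cfg.spectra_path is not None:
        raw = spectra_mod.read_spectra(cfg.spectra_path, cfg.dialect)
    else:
        sc = SpectraScenario(**cfg.spectra_scenario)
        raw = generate_spectra(sc, seed=cfg.seed)
    processed = raw.map(
        lambda s: spectra_mod.clip_nonnegative(
            spectra_mod.resample(spectra_mod.dark_correct(s), step=cfg.step)
        )
    )
    processed.provenance = list(raw.provenance)
    processed.note(f"dark-corrected and resampled to {cfg.step} nm")
    flowers = processed.select(item_kind="flower")
    leaves = processed.select(item_kind="leaf")
    return flowers, leaves


def _load_or_generate_behavior(cfg: RunConfig):
    paths = (cfg.scans_path, cfg.flpv_path, cfg.roster_path, cfg.hours_path)
    if any(p is not None for p in paths):
        if any(p is None for p in paths):
            raise ConfigError(
                "behavioural input needs all of scans/flpv/roster/hours paths"
            )
        return {
            "scans": pd.read_csv(cfg.scans_path),
            "flpv": pd.read_csv(cfg.flpv_path),
            "roster": pd.read_csv(cfg.roster_path),
            "hours": pd.read_csv(cfg.hours_path),
        }
    sc = BehaviorScenario(**cfg.behavior_scenario)
    return generate_behavior(sc, seed=cfg.seed)


def run_all(cfg: RunConfig) -> dict:
    """Run every stage and return (and optionally write) the report bundle.

    The bundle maps section names to pandas frames / dicts:
    ``jnd_table``, ``conspicuity``, ``svm_report``, ``glmm`` and a flat
    ``results`` document mirroring the analysis structure.  With
    ``cfg.out_dir`` set, CSV/JSON files are written there.
    """
    if cfg.spectra_only and cfg.behavior_only:
        raise ConfigError("spectra_only and behavior_only are mutually exclusive")
    phenotypes = (
        load_phenotypes(cfg.phenotype_registry)
        if cfg.phenotype_registry
        else default_phenotypes()
    )
    bundle: dict = {"config_hash": cfg.hash()}
    results: dict = {"config_hash": cfg.hash(), "seed": cfg.seed}
    stage = "setup"
    try:
        if not cfg.behavior_only:
            stage = "spectra"
            flowers, leaves = _load_or_generate_spectra(cfg)
            flower_means = spectra_mod.average_replicates(flowers)
            background = spectra_mod.mean_background(leaves)
            illuminant = (
                Illuminant.from_csv(cfg.illuminant_path, grid=background.wavelengths)
                if cfg.illuminant_path
                else Illuminant.flat(background.wavelengths)
            )

            stage = "jnd"
            table = conspicuity.jnd_table(
                flower_means, background, phenotypes, illuminant
            )
            summary = conspicuity.detectability_summary(table)
            advantage = conspicuity.advantage_summary(table)
            bundle["jnd_table"] = table
            bundle["conspicuity"] = summary
            bundle["advantage"] = advantage
            results["jnd"] = {
                "mean_delta_s_by_class": summary.mean_delta_s,
                "not_detectable_any_dichromat": summary.not_detectable_any_dichromat,
                "marginal_any_dichromat": summary.marginal_any_dichromat,
                "n_parts": summary.n_parts,
                "n_species": summary.n_species,
                "advantage": advantage.to_dict(orient="records"),
            }

            stage = "svm"
            svm_cfg = svm_discrimination.SVMConfig(**cfg.svm)
            report = svm_discrimination.discrimination_report(
                flowers, leaves, phenotypes, config=svm_cfg, illuminant=illuminant
            )
            bundle["svm_report"] = report
            results["svm"] = {
                "majority_correct_rate": report.groupby(
                    ["phenotype_class", "include_lightness"]
                )["majority_correct"]
                .mean()
                .reset_index()
                .to_dict(orient="records")
            }

        if not cfg.spectra_only:
            stage = "behaviour"
            data = _load_or_generate_behavior(cfg)
            glmm_kwargs = dict(cfg.glmm)
            scan_fit = count_models.scan_model(data["scans"], **glmm_kwargs)
            counts = count_models.small_patch_filter(
                data["flpv"], roster=data["roster"]
            )
            flpv_fit = count_models.flpv_model(counts, data["roster"], data["hours"])
            bundle["glmm"] = {"scan": scan_fit, "flpv": flpv_fit}
            results["glmm"] = {
                "scan": scan_fit.to_dict(),
                "flpv": flpv_fit.to_dict(),
                "n_small_patch_visits": counts.attrs.get("n_retained_visits"),
                "n_small_patch_species": counts.attrs.get("n_species_retained"),
            }
    except FlorisightError as exc:
        exc.stage = stage
        exc.partial = sorted(bundle)
        raise

    bundle["results"] = results
    if cfg.out_dir:
        _write_bundle(bundle, cfg)
    return bundle


def _write_bundle(bundle: dict, cfg: RunConfig) -> None:
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    if "jnd_table" in bundle:
        bundle["jnd_table"].to_csv(out / "jnd_table.csv", index=False)
        with open(out / "conspicuity_summary.json", "w") as fh:
            json.dump(
                {
                    "config_hash": cfg.hash(),
                    **bundle["conspicuity"].to_dict(),
                    "advantage": bundle["advantage"].to_dict(orient="records"),
                },
                fh, indent=2, sort_keys=True, default=str,
            )
    if "svm_report" in bundle:
        bundle["svm_report"].to_csv(out / "svm_report.csv", index=False)
    if "glmm" in bundle:
        with open(out / "glmm_fits.json", "w") as fh:
            json.dump(
                {k: v.to_dict() for k, v in bundle["glmm"].items()},
                fh, indent=2, sort_keys=True,
            )
    with open(out / "results.json", "w") as fh:
        json.dump(bundle["results"], fh, indent=2, sort_keys=True, default=str)
    log.info("wrote report bundle to %s (config %s)", out, cfg.hash())
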