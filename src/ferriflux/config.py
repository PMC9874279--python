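"""Structured-text (YAML) configuration loading and writing.

Configurations are nested key/value files with units embedded in the key
names, so that a value can never silently change meaning.  Unknown keys
are rejected with an error naming the offending key.  The two calibrated
site fixtures of the package (``monterey_canyon``, ``santa_barbara_basin``)
ship as packaged YAML files and load through the same path.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import yaml

from .isotopes import DEFAULT_EPS, IsotopeParams
from .reactions import FeOxideClasses, KineticParams, SorptionParams
from .scenarios import ScenarioConfig
from .transport import PorosityProfile, TransportParams


class ConfigError(ValueError):
    pass


SITE_FIXTURES = ("monterey_canyon", "santa_barbara_basin")


def _check_keys(section: dict, allowed, where: str) -> None:
    unknown = set(section) - set(allowed)
    if unknown:
        raise ConfigError(
            f"unknown key(s) {sorted(unknown)} in section {where!r}")


def _build_kinetics(section: dict) -> KineticParams:
    allowed = {f.name for f in dataclasses.fields(KineticParams)}
    _check_keys(section, allowed, "kinetics")
    kwargs = dict(section)
    if "sorption" in kwargs:
        sub = kwargs.pop("sorption")
        _check_keys(sub, {f.name for f in dataclasses.fields(SorptionParams)},
                    "kinetics.sorption")
        kwargs["sorption"] = SorptionParams(**sub)
    if "oxide_classes" in kwargs:
        sub = kwargs.pop("oxide_classes")
        _check_keys(sub, {"half_life", "partition"}, "kinetics.oxide_classes")
        kwargs["oxide_classes"] = FeOxideClasses(**sub)
    if "poc_fractions" in kwargs:
        kwargs["poc_fractions"] = tuple(kwargs["poc_fractions"])
    if "poc_decay" in kwargs:
        kwargs["poc_decay"] = tuple(kwargs["poc_decay"])
    return KineticParams(**kwargs)


_TOP_KEYS = {
    "name", "variant", "domain_depth_cm", "n_cells", "grid_grading",
    "porosity", "burial_velocity_cm_kyr", "temperature_degC", "salinity",
    "bottom_water_umol_cm3", "deposition", "bioturbation", "kinetics",
    "eps_eff_permil",
}

_DEPOSITION_KEYS = {
    "poc_mmol_m2_d", "feooh_total_umol_m2_d", "feooh_delta56_permil",
    "fes_umol_m2_d", "fes_delta56_permil",
    "fes2_umol_m2_d", "fes2_delta56_permil", "mno2_umol_m2_d",
}

_BIOTURBATION_KEYS = {
    "biodiffusion_cm2_yr", "mixing_depth_cm", "irrigation_yr",
    "irrigation_attenuation_cm", "irrigation_scaling",
    "diffusivity_overrides_cm2_yr",
}


def config_from_dict(raw: dict) -> ScenarioConfig:
    _check_keys(raw, _TOP_KEYS, "<top level>")

    por = raw.get("porosity", {})
    _check_keys(por, {"phi_surface", "phi_deep", "attenuation_depth_cm"},
                "porosity")
    porosity = PorosityProfile(
        por.get("phi_surface", 0.95),
        por.get("phi_deep", 0.82),
        por.get("attenuation_depth_cm", 3.6),
    )

    temp = raw.get("temperature_degC", 10.0)
    sal = raw.get("salinity", 34.2)
    bio = raw.get("bioturbation", {})
    _check_keys(bio, _BIOTURBATION_KEYS, "bioturbation")
    transport = TransportParams(
        biodiffusion_coeff=bio.get("biodiffusion_cm2_yr", 0.0),
        mixing_depth=bio.get("mixing_depth_cm", 10.0),
        irrigation_coeff=bio.get("irrigation_yr", 0.0),
        irrigation_attenuation=bio.get("irrigation_attenuation_cm", 3.0),
        temperature=temp,
        salinity=sal,
        irrigation_scaling=dict(bio.get("irrigation_scaling",
                                        {"Fe2": 0.2, "HS": 0.5})),
        diffusivity_overrides=dict(bio.get("diffusivity_overrides_cm2_yr", {})),
    )

    dep = raw.get("deposition", {})
    _check_keys(dep, _DEPOSITION_KEYS, "deposition")

    eps = dict(DEFAULT_EPS)
    eps.update(raw.get("eps_eff_permil", {}))
    unknown_eps = set(eps) - set(DEFAULT_EPS)
    if unknown_eps:
        raise ConfigError(f"unknown eps_eff_permil key(s) {sorted(unknown_eps)}")

    return ScenarioConfig(
        name=raw.get("name", "custom"),
        variant=raw.get("variant", "idealized"),
        domain_depth=raw.get("domain_depth_cm", 150.0),
        n_cells=int(raw.get("n_cells", 200)),
        grid_grading=raw.get("grid_grading", 6.0),
        porosity=porosity,
        burial_velocity=raw.get("burial_velocity_cm_kyr", 60.0),
        temperature=temp,
        salinity=sal,
        bottom_water=dict(raw.get("bottom_water_umol_cm3", {})),
        j_poc=dep.get("poc_mmol_m2_d", 10.0),
        j_feooh_total=dep.get("feooh_total_umol_m2_d", 1110.0),
        delta_feooh=dep.get("feooh_delta56_permil", 0.0),
        j_fes=dep.get("fes_umol_m2_d", 0.0),
        delta_fes=dep.get("fes_delta56_permil", 0.0),
        j_fes2=dep.get("fes2_umol_m2_d", 0.0),
        delta_fes2=dep.get("fes2_delta56_permil", 0.0),
        j_mno2=dep.get("mno2_umol_m2_d", 2.0),
        transport=transport,
        kinetics=_build_kinetics(raw.get("kinetics", {})),
        isotopes=IsotopeParams(eps_eff=eps),
    )


def config_to_dict(cfg: ScenarioConfig) -> dict:
    """Serialize a configuration back to the structured-text schema."""
    kin = dataclasses.asdict(cfg.kinetics)
    kin["sorption"] = dataclasses.asdict(cfg.kinetics.sorption)
    kin["oxide_classes"] = {
        "half_life": dict(cfg.kinetics.oxide_classes.half_life),
        "partition": dict(cfg.kinetics.oxide_classes.partition),
    }
    kin["poc_fractions"] = list(cfg.kinetics.poc_fractions)
    kin["poc_decay"] = list(cfg.kinetics.poc_decay)
    tp = cfg.transport
    return {
        "name": cfg.name,
        "variant": cfg.variant,
        "domain_depth_cm": cfg.domain_depth,
        "n_cells": cfg.n_cells,
        "grid_grading": cfg.grid_grading,
        "porosity": {
            "phi_surface": cfg.porosity.phi_surface,
            "phi_deep": cfg.porosity.phi_deep,
            "attenuation_depth_cm": cfg.porosity.attenuation_depth,
        },
        "burial_velocity_cm_kyr": cfg.burial_velocity,
        "temperature_degC": cfg.temperature,
        "salinity": cfg.salinity,
        "bottom_water_umol_cm3": dict(cfg.bottom_water),
        "deposition": {
            "poc_mmol_m2_d": cfg.j_poc,
            "feooh_total_umol_m2_d": cfg.j_feooh_total,
            "feooh_delta56_permil": cfg.delta_feooh,
            "fes_umol_m2_d": cfg.j_fes,
            "fes_delta56_permil": cfg.delta_fes,
            "fes2_umol_m2_d": cfg.j_fes2,
            "fes2_delta56_permil": cfg.delta_fes2,
            "mno2_umol_m2_d": cfg.j_mno2,
        },
        "bioturbation": {
            "biodiffusion_cm2_yr": tp.biodiffusion_coeff,
            "mixing_depth_cm": tp.mixing_depth,
            "irrigation_yr": tp.irrigation_coeff,
            "irrigation_attenuation_cm": tp.irrigation_attenuation,
            "irrigation_scaling": dict(tp.irrigation_scaling),
            "diffusivity_overrides_cm2_yr": dict(tp.diffusivity_overrides),
        },
        "kinetics": kin,
        "eps_eff_permil": dict(cfg.isotopes.eps_eff),
    }


def load_config(path) -> ScenarioConfig:
    """Load and validate a scenario configuration from a YAML file."""
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ConfigError(f"{path}: expected a mapping at the top level")
    return config_from_dict(raw)


def dump_config(cfg: ScenarioConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(cfg), fh, sort_keys=False)


def site_fixture(name: str) -> ScenarioConfig:
    """Load one of the packaged calibrated site configurations."""
    if name not in SITE_FIXTURES:
        raise ConfigError(f"unknown site fixture {name!r}; "
                          f"available: {SITE_FIXTURES}")
    ref = resources.files("ferriflux").joinpath(f"configs/{name}.yaml")
    with resources.as_file(ref) as path:
        return load_config(Path(path))
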