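"""Simulation configuration: defaults, validation and seed fan-out."""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields

import numpy as np

from .cna_engine import EventModelParams
from .exceptions import ConfigError, ParameterError
from .lineage import PopulationParams
from .profiles import ErrorModelParams
from .reads import CoverageModel

__all__ = ["SimulationConfig", "validate_config", "module_rng", "module_seed"]

MODES = ("cnp", "reads", "both")

# fixed tags so adding one output stage never perturbs another stage's draws
SEED_TAGS = {
    "reference": 1,
    "tree": 2,
    "subclones": 3,
    "events": 4,
    "noise": 5,
    "haplotypes": 6,
    "reads": 7,
}


@dataclass(frozen=True)
class SimulationConfig:
    """Full parameter surface of one simulation run."""

    # population
    num_cells: int = 100
    growth_rate: float = 1.0
    sweeps: tuple[tuple[float, float], ...] = ()
    normal_cells: int = 0
    pseudo_normal_cells: int = 0
    subclones: int = 0
    subclone_min_size: int = 2
    root_stem_length: float = 1.0
    random_outgroup_spacing: bool = False
    # genome / template
    reference: str | None = None
    arm_table: str | None = None
    num_chromosomes: int = 2
    chrom_length: int = 5_000_000
    arm_fraction: float = 0.4
    gc_content: float = 0.41
    region_size: int = 1_000
    bin_size: int = 1_000_000
    # event model
    focal_rate: float = 2.0
    mean_focal_length: float = 1000.0
    min_focal_length: int = 100
    p_gain: float = 0.5
    p_cnloh: float = 0.1
    p_mag: float = 0.5
    founder_event_mean: float = 5.0
    subclone_event_mean: float = 2.0
    p_arm: float = 0.5
    p_chrom_gain: float = 0.5
    wgd: bool = False
    pseudo_normal_event_mean: float = 3.0
    events_per_edge: int | None = None
    # error model
    boundary_prob: float = 0.5
    boundary_geom_p: float = 0.5
    jitter_sd: float = 0.15
    # sequencing
    coverage: float = 0.1
    window_size: int = 100_000
    read_length: int = 100
    insert_mean: float = 350.0
    insert_sd: float = 50.0
    base_error_rate: float = 0.002
    coverage_sd: float = 0.2
    autocorr: float = 0.5
    snp_rate: float = 0.001
    # run control
    mode: str = "cnp"
    out_dir: str = "sccnsim_out"
    seed: int = 0

    # -- derived module parameter objects ---------------------------------
    def population_params(self, tree_seed: int) -> PopulationParams:
        return PopulationParams(
            n=self.num_cells,
            growth_rate=self.growth_rate,
            sweeps=self.sweeps,
            normal_count=self.normal_cells,
            pseudo_normal_count=self.pseudo_normal_cells,
            seed=tree_seed,
        )

    def event_params(self) -> EventModelParams:
        return EventModelParams(
            focal_rate=self.focal_rate,
            mean_focal_length=self.mean_focal_length,
            min_focal_length=self.min_focal_length,
            p_gain=self.p_gain,
            p_cnloh=self.p_cnloh,
            p_mag=self.p_mag,
            founder_event_mean=self.founder_event_mean,
            subclone_event_mean=self.subclone_event_mean,
            p_arm=self.p_arm,
            p_chrom_gain=self.p_chrom_gain,
            wgd=self.wgd,
            pseudo_normal_event_mean=self.pseudo_normal_event_mean,
            events_per_edge=self.events_per_edge,
        )

    def error_params(self) -> ErrorModelParams:
        return ErrorModelParams(
            boundary_prob=self.boundary_prob,
            boundary_geom_p=self.boundary_geom_p,
            jitter_sd=self.jitter_sd,
        )

    def coverage_model(self) -> CoverageModel:
        return CoverageModel(
            coverage=self.coverage,
            window_size=self.window_size,
            read_length=self.read_length,
            insert_mean=self.insert_mean,
            insert_sd=self.insert_sd,
            base_error_rate=self.base_error_rate,
            coverage_sd=self.coverage_sd,
            autocorr=self.autocorr,
        )

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sweeps"] = [list(s) for s in self.sweeps]
        return d


def module_rng(master_seed: int, module: str) -> np.random.Generator:
    """Independent stream per pipeline stage, derived from the master seed."""
    return np.random.default_rng(
        np.random.SeedSequence(master_seed, spawn_key=(SEED_TAGS[module],))
    )


def module_seed(master_seed: int, module: str) -> int:
    """Small integer seed (for libraries that take one) derived per stage."""
    ss = np.random.SeedSequence(master_seed, spawn_key=(SEED_TAGS[module],))
    return int(ss.generate_state(1)[0] % (2**31 - 1))


_FIELD_TYPES = {f.name: f for f in fields(SimulationConfig)}

_INT_FIELDS = {
    "num_cells", "normal_cells", "pseudo_normal_cells", "subclones",
    "subclone_min_size", "num_chromosomes", "chrom_length", "region_size",
    "bin_size", "min_focal_length", "window_size", "read_length", "seed",
    "events_per_edge",
}
_FLOAT_FIELDS = {
    "growth_rate", "root_stem_length", "arm_fraction", "gc_content",
    "focal_rate", "mean_focal_length", "p_gain", "p_cnloh", "p_mag",
    "founder_event_mean", "subclone_event_mean", "p_arm", "p_chrom_gain",
    "pseudo_normal_event_mean", "boundary_prob", "boundary_geom_p",
    "jitter_sd", "coverage", "insert_mean", "insert_sd", "base_error_rate",
    "coverage_sd", "autocorr", "snp_rate",
}
_BOOL_FIELDS = {"wgd", "random_outgroup_spacing"}
_STR_FIELDS = {"reference", "arm_table", "mode", "out_dir"}


def _coerce_sweeps(value, errors):
    out = []
    try:
        for item in value:
            if isinstance(item, str):
                time_s, severity_s = item.split(":")
                out.append((float(time_s), float(severity_s)))
            else:
                time, severity = item
                out.append((float(time), float(severity)))
    except (TypeError, ValueError):
        errors.append(f"sweeps: expected (time, severity) pairs, got {value!r}")
        return ()
    return tuple(out)


def validate_config(raw: dict | None = None) -> SimulationConfig:
    """Type/range-check every field, fill defaults, reject unknown keys.

    All problems are reported together in one :class:`ConfigError`.
    """
    raw = dict(raw or {})
    errors: list[str] = []
    values: dict = {}
    for key in list(raw):
        if key not in _FIELD_TYPES:
            errors.append(f"unknown configuration key: {key}")
            raw.pop(key)
    for key, value in raw.items():
        if value is None:
            if key in ("reference", "arm_table", "events_per_edge"):
                values[key] = None
            continue
        try:
            if key == "sweeps":
                values[key] = _coerce_sweeps(value, errors)
            elif key in _BOOL_FIELDS:
                if not isinstance(value, bool):
                    raise ValueError
                values[key] = value
            elif key in _INT_FIELDS:
                if isinstance(value, bool) or int(value) != float(value):
                    raise ValueError
                values[key] = int(value)
            elif key in _FLOAT_FIELDS:
                values[key] = float(value)
            elif key in _STR_FIELDS:
                values[key] = str(value)
        except (TypeError, ValueError):
            errors.append(f"{key}: cannot interpret {value!r}")
    config = SimulationConfig(**{**values})
    # range checks via the module parameter classes plus cross-field rules
    try:
        config.population_params(0)
    except ParameterError as exc:
        errors.append(str(exc))
    try:
        config.event_params()
    except ParameterError as exc:
        errors.append(str(exc))
    try:
        config.error_params()
    except ParameterError as exc:
        errors.append(str(exc))
    try:
        config.coverage_model()
    except ParameterError as exc:
        errors.append(str(exc))
    if config.mode not in MODES:
        errors.append(f"mode must be one of {MODES}, got {config.mode!r}")
    if config.region_size < 1 or config.bin_size < 1:
        errors.append("region_size and bin_size must be positive")
    elif config.bin_size % config.region_size != 0:
        errors.append(
            f"bin_size ({config.bin_size}) must be an integer multiple of "
            f"region_size ({config.region_size})"
        )
    if config.reference is not None and config.arm_table is None:
        errors.append("a reference FASTA requires an arm_table")
    if config.mode in ("reads", "both") and config.reference is None \
            and config.arm_table is not None:
        errors.append(
            "mode=reads needs a FASTA: give --reference or omit --arm-table "
            "to use a synthetic reference"
        )
    if not 0 < config.arm_fraction < 1:
        errors.append("arm_fraction must be in (0, 1)")
    if not 0 <= config.gc_content <= 1:
        errors.append("gc_content must be in [0, 1]")
    if not 0 <= config.snp_rate <= 0.1:
        errors.append("snp_rate must be in [0, 0.1]")
    if config.subclone_min_size < 1:
        errors.append("subclone_min_size must be >= 1")
    if config.subclones < 0:
        errors.append("subclones must be >= 0")
    if config.root_stem_length <= 0:
        errors.append("root_stem_length must be > 0")
    if config.num_chromosomes < 1 or config.chrom_length < 2:
        errors.append("num_chromosomes must be >= 1 and chrom_length >= 2")
    if errors:
        raise ConfigError(errors)
    return config
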