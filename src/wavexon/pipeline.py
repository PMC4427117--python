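"""The end-to-end detection pipeline and its declarative configuration.

Chain per sequence: EIIP mapping -> period-3 band-pass -> Coiflet-5 level-2
DWT -> detail-band energy profile -> adaptive denoise -> per-sequence max
normalization -> threshold calling. Each sequence's profile is normalized by
its own maximum, so thresholds are comparable across genes.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from typing import Any, Optional

import yaml

from .caller import CallerSpec, call_regions
from .errors import ConfigError, ValidationError
from .mapping import EiipTable, map_eiip
from .transform import (
    BandpassSpec,
    DenoiseSpec,
    adaptive_denoise,
    bandpass_period3,
    dwt_decompose,
    energy_profile,
    normalize_profile,
)
from .types import DnaSequence, GenomicIntervals, NumericSignal, WaveletDecomposition

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class TransformSpec:
    """Wavelet stage parameters (wavelet, depth, boundary handling, energy source)."""

    wavelet: str = "coif5"
    levels: int = 2
    boundary_mode: str = "symmetric"
    energy_source: str = "detail_levels"
    smooth_window: int = 9

    def __post_init__(self) -> None:
        if self.levels < 1:
            raise ConfigError("levels must be >= 1")
        if self.smooth_window < 1:
            raise ConfigError("smooth_window must be positive")


@dataclass(frozen=True)
class PipelineConfig:
    """Fully resolved parameters for one run; every field has a default."""

    eiip: EiipTable = field(default_factory=EiipTable)
    n_policy: str = "mean"
    bandpass: BandpassSpec = field(default_factory=BandpassSpec)
    transform: TransformSpec = field(default_factory=TransformSpec)
    denoise: DenoiseSpec = field(default_factory=DenoiseSpec)
    caller: CallerSpec = field(default_factory=CallerSpec)

    def to_dict(self) -> dict[str, Any]:
        return {
            "eiip": dict(self.eiip.values),
            "n_policy": self.n_policy,
            "bandpass": dataclasses.asdict(self.bandpass),
            "transform": dataclasses.asdict(self.transform),
            "denoise": dataclasses.asdict(self.denoise),
            "caller": dataclasses.asdict(self.caller),
        }


def _build(cls, section: dict[str, Any], name: str):
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(section) - fields
    if unknown:
        raise ConfigError(f"config section {name!r}: unknown keys {sorted(unknown)}")
    try:
        return cls(**section)
    except (ValidationError, TypeError) as exc:
        raise ConfigError(f"config section {name!r}: {exc}") from exc


def config_from_dict(data: dict[str, Any]) -> PipelineConfig:
    """Build a validated config from a nested dict; unknown keys are rejected."""
    known = {"eiip", "n_policy", "bandpass", "transform", "denoise", "caller"}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown top-level config keys {sorted(unknown)}")
    kwargs: dict[str, Any] = {}
    if "eiip" in data:
        table = data["eiip"]
        if not isinstance(table, dict):
            raise ConfigError("config section 'eiip' must map the four bases to floats")
        try:
            kwargs["eiip"] = EiipTable({k.upper(): float(v) for k, v in table.items()})
        except (ValidationError, ValueError) as exc:
            raise ConfigError(f"config section 'eiip': {exc}") from exc
    if "n_policy" in data:
        if data["n_policy"] not in ("mean", "error"):
            raise ConfigError(f"unknown n_policy {data['n_policy']!r}")
        kwargs["n_policy"] = data["n_policy"]
    for key, cls in (
        ("bandpass", BandpassSpec),
        ("transform", TransformSpec),
        ("denoise", DenoiseSpec),
        ("caller", CallerSpec),
    ):
        if key in data:
            kwargs[key] = _build(cls, dict(data[key]), key)
    return PipelineConfig(**kwargs)


def load_config(path: Optional[str]) -> PipelineConfig:
    """Load a YAML config file, or the defaults when ``path`` is None."""
    if path is None:
        return PipelineConfig()
    try:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    except yaml.YAMLError as exc:
        raise ConfigError(f"cannot parse config {path}: {exc}") from exc
    if data is None:
        return PipelineConfig()
    if not isinstance(data, dict):
        raise ConfigError(f"config {path} must be a YAML mapping")
    return config_from_dict(data)


def dump_config(config: PipelineConfig, path: str) -> None:
    """Write the fully resolved configuration as YAML (run provenance)."""
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)


@dataclass
class PipelineResult:
    """All intermediate stages for one sequence, for inspection and plotting."""

    sequence_id: str
    eiip: NumericSignal
    bandpassed: NumericSignal
    decomposition: WaveletDecomposition
    energy: NumericSignal
    denoised: NumericSignal
    normalized: NumericSignal
    regions: GenomicIntervals


def run_pipeline(seq: DnaSequence, config: Optional[PipelineConfig] = None) -> PipelineResult:
    """Run the full detection chain on one sequence."""
    if config is None:
        config = PipelineConfig()
    eiip = map_eiip(seq, config.eiip, n_policy=config.n_policy)
    band = bandpass_period3(eiip, config.bandpass)
    decomp = dwt_decompose(
        band,
        wavelet_name=config.transform.wavelet,
        levels=config.transform.levels,
        boundary_mode=config.transform.boundary_mode,
    )
    energy = energy_profile(
        decomp,
        source=config.transform.energy_source,
        smooth_window=config.transform.smooth_window,
    )
    denoised = adaptive_denoise(energy, config.denoise)
    normalized = normalize_profile(denoised)
    regions = call_regions(normalized, config.caller)
    log.info(
        "sequence %r: length %d, %d region(s) called at threshold %.2f",
        seq.id, len(seq), len(regions), config.caller.threshold,
    )
    return PipelineResult(
        sequence_id=seq.id,
        eiip=eiip,
        bandpassed=band,
        decomposition=decomp,
        energy=energy,
        denoised=denoised,
        normalized=normalized,
        regions=regions,
    )
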