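"""Run configuration: YAML parsing, seed bookkeeping, and config hashing.

A run config collects a beam section, detector/readout sections and an
analysis section into one resolvable object. Every stochastic pipeline output
records the seed and a SHA-256 hash of the fully resolved configuration so a
run can be reproduced exactly.
"""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .beam import BeamSpec
from .detectors import DetectorSpec, ReadoutModel
from .errors import ProtonDosimError
from .presets import beam_preset, detector_preset

__all__ = ["RunConfig", "load_config", "config_hash"]


@dataclass(frozen=True)
class AnalysisConfig:
    depth_step: float = 0.25
    lateral_step: float = 0.25
    pullback_step: float = 2.0
    flatness_tol: float = 0.02
    n_primaries: int = 100_000


@dataclass(frozen=True)
class RunConfig:
    beam: BeamSpec
    scan_detector: DetectorSpec
    reference_detector: DetectorSpec
    readout: ReadoutModel
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    seed: int = 0
    output_dir: str = "runs"

    def resolved(self) -> dict:
        """Full configuration as plain data (for hashing and provenance)."""
        return {
            "beam": dataclasses.asdict(self.beam),
            "scan_detector": dataclasses.asdict(self.scan_detector),
            "reference_detector": dataclasses.asdict(self.reference_detector),
            "readout": dataclasses.asdict(self.readout),
            "analysis": dataclasses.asdict(self.analysis),
            "seed": self.seed,
        }


def config_hash(cfg: RunConfig) -> str:
    blob = json.dumps(cfg.resolved(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


def _build_beam(section) -> BeamSpec:
    if isinstance(section, str):
        return beam_preset(section)
    if isinstance(section, dict):
        if "preset" in section:
            base = dataclasses.asdict(beam_preset(section.pop("preset")))
            base.update(section)
            section = base
        return BeamSpec(**section)
    raise ProtonDosimError("beam section must be a preset name or a mapping")


def _build_detector(section, default: str) -> DetectorSpec:
    if section is None:
        return detector_preset(default)
    if isinstance(section, str):
        return detector_preset(section)
    if isinstance(section, dict):
        return DetectorSpec(**section)
    raise ProtonDosimError("detector section must be a preset name or a mapping")


def load_config(path: str | Path) -> RunConfig:
    """Load a YAML run configuration.

    Sections: ``beam`` (preset name or field mapping, a ``preset`` key may be
    combined with overrides), ``scan_detector``/``reference_detector`` (preset
    names or mappings), ``readout`` (field mapping), ``analysis``, ``seed``,
    ``output_dir``.
    """
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ProtonDosimError(f"{path}: config must be a YAML mapping")
    try:
        beam = _build_beam(raw.get("beam", "127MeV-Mod30-20mm"))
        scan_det = _build_detector(raw.get("scan_detector"), "PR60020")
        ref_det = _build_detector(raw.get("reference_detector"), "MarkusN23343")
        readout = ReadoutModel(**raw.get("readout", {}))
        analysis = AnalysisConfig(**raw.get("analysis", {}))
    except TypeError as exc:
        raise ProtonDosimError(f"{path}: {exc}") from exc
    return RunConfig(
        beam=beam,
        scan_detector=scan_det,
        reference_detector=ref_det,
        readout=readout,
        analysis=analysis,
        seed=int(raw.get("seed", 0)),
        output_dir=str(raw.get("output_dir", "runs")),
    )
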