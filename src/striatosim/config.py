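"""Validated parameter models and config-file I/O.

All quantities use a fixed unit convention: lengths in micrometers (µm),
times in seconds, firing rates in Hz, concentrations in nM except where a
field name says otherwise (``vmax_total`` and ``km`` are in µM as is
conventional for striatal uptake kinetics).

Configs are plain TOML files whose section names mirror the model classes
(``[firing]``, ``[lattice]``, ``[kinetics]``, ``[receptors]``,
``[transduction]``, ``[experiment]``).  Unknown keys are rejected so typos
fail loudly.
"""
from __future__ import annotations

import math
from pathlib import Path
from typing import Literal, Optional, Tuple

from pydantic import BaseModel, ConfigDict, Field, ValidationError, model_validator

__all__ = [
    "ConfigError",
    "FiringConfig",
    "Lattice",
    "AutoreceptorParams",
    "KineticParams",
    "AmphetamineSpec",
    "InterventionSpec",
    "ReceptorParams",
    "TransductionConfig",
    "ExperimentConfig",
    "RunConfig",
    "load_config",
    "dump_config",
]

# Avogadro's number (1/mol); used to convert release quanta to concentration.
N_AVOGADRO = 6.02214076e23


class ConfigError(ValueError):
    """Raised for invalid parameter values or malformed config files."""


class _Model(BaseModel):
    model_config = ConfigDict(extra="forbid", validate_assignment=True)


class FiringConfig(_Model):
    """Dopamine-neuron firing-pattern parameters.

    The phasic pattern superimposes synchronized burst epochs (``burst_rate``
    for ``burst_duration``) and silent pause epochs (``pause_duration``) on a
    tonic background, balanced so the long-run mean rate stays at
    ``mean_rate``.
    """

    mean_rate: float = Field(4.0, ge=0.0, description="mean firing rate (Hz)")
    burst_rate: float = Field(20.0, gt=0.0, description="within-burst rate (Hz)")
    burst_duration: float = Field(0.3, gt=0.0, description="burst epoch length (s)")
    pause_duration: float = Field(1.2, gt=0.0, description="pause epoch length (s)")
    event_rate: float = Field(0.25, ge=0.0, description="burst/pause event frequency (1/s)")
    synchrony: bool = True
    mode: Literal["tonic", "phasic"] = "tonic"

    @model_validator(mode="after")
    def _check(self) -> "FiringConfig":
        if self.mode == "phasic" and self.burst_rate <= self.mean_rate:
            raise ValueError("burst_rate must exceed mean_rate for phasic firing")
        return self

    @property
    def pause_event_rate(self) -> float:
        """Pause-event frequency satisfying the rate-balance identity.

        (burst_rate - mean_rate) * burst_duration * f_burst
            = mean_rate * pause_duration * f_pause
        """
        if self.mean_rate == 0:
            return 0.0
        excess = (self.burst_rate - self.mean_rate) * self.burst_duration
        return self.event_rate * excess / (self.mean_rate * self.pause_duration)

    @property
    def balanced_pairs(self) -> bool:
        """True when one burst and one pause cancel spike-for-spike."""
        excess = (self.burst_rate - self.mean_rate) * self.burst_duration
        deficit = self.mean_rate * self.pause_duration
        return math.isclose(excess, deficit, rel_tol=1e-9, abs_tol=1e-12)


class Lattice(_Model):
    """Periodic cubic lattice holding terminals and the dopamine field."""

    extent: Tuple[float, float, float] = (60.0, 60.0, 60.0)
    voxel_size: float = Field(2.0, gt=0.0)
    boundary: Literal["periodic", "fixed"] = "periodic"

    @model_validator(mode="after")
    def _check(self) -> "Lattice":
        for e in self.extent:
            if e <= 0:
                raise ValueError("extent must be positive")
            n = e / self.voxel_size
            if abs(n - round(n)) > 1e-9:
                raise ValueError(
                    f"extent {e} not divisible by voxel_size {self.voxel_size}"
                )
        return self

    @property
    def shape(self) -> Tuple[int, int, int]:
        return tuple(int(round(e / self.voxel_size)) for e in self.extent)

    @property
    def n_voxels(self) -> int:
        nx, ny, nz = self.shape
        return nx * ny * nz

    @property
    def volume(self) -> float:
        """Total lattice volume (µm³)."""
        return self.extent[0] * self.extent[1] * self.extent[2]

    @property
    def voxel_volume(self) -> float:
        """Single-voxel volume (µm³)."""
        return self.voxel_size ** 3


class AutoreceptorParams(_Model):
    """Presynaptic D2-like autoreceptor feedback on release probability.

    Release probability is multiplied by
    ``1 - max_suppression * C^h / (C^h + ec50^h)`` with C the local
    extracellular dopamine at the terminal's voxel.
    """

    enabled: bool = True
    ec50: float = Field(40.0, gt=0.0, description="half-suppression concentration (nM)")
    hill: float = Field(2.0, gt=0.0)
    max_suppression: float = Field(0.5, ge=0.0, le=1.0)
    tau: float = Field(0.3, ge=0.0, description="activation time constant (s); feedback senses a low-pass of local DA, so it lags sub-second bursts. 0 = instantaneous")


class KineticParams(_Model):
    """Release, diffusion, uptake and clearance parameters.

    Defaults are standard striatal values: effective diffusion coefficient
    D_eff = 763/1.54² ≈ 322 µm²/s (tortuosity-corrected), extracellular
    volume fraction 0.21, Vmax = 4 µM/s at intact terminal density,
    Km = 0.2 µM, 3000 molecules per vesicle, release probability 0.06 per
    spike per terminal.  ``k_ns`` (nonspecific clearance) defaults to
    D_eff/λ² with λ = 70 µm, which places the diffusion screening length of
    denervated voids such that a 500 µm void retains ~20% of the outside
    tonic level at its center.
    """

    d_eff: float = Field(322.0, gt=0.0, description="effective diffusion coeff (µm²/s)")
    alpha: float = Field(0.21, gt=0.0, le=1.0, description="extracellular volume fraction")
    vmax_total: float = Field(4.0, ge=0.0, description="max uptake rate at intact density (µM/s)")
    km: float = Field(0.2, gt=0.0, description="uptake Michaelis constant (µM)")
    quantum: float = Field(3000.0, ge=0.0, description="molecules per release event")
    p_release: float = Field(0.06, ge=0.0, le=1.0, description="release probability per spike per terminal")
    k_ns: float = Field(322.0 / 70.0 ** 2, ge=0.0, description="nonspecific clearance rate (1/s)")
    release_sigma: float = Field(2.0, ge=0.0, description="Gaussian deposition width of a quantum (µm); 0 = single voxel")
    efflux_rate: float = Field(0.0, ge=0.0, description="amphetamine efflux (molecules/s per terminal)")
    autoreceptor: AutoreceptorParams = Field(default_factory=AutoreceptorParams)

    @property
    def vmax_nM(self) -> float:
        return self.vmax_total * 1e3

    @property
    def km_nM(self) -> float:
        return self.km * 1e3

    def quantum_conc(self, voxel_volume_um3: float) -> float:
        """Concentration increment (nM) of one quantum released into one voxel.

        The quantum dissolves in the voxel's extracellular water volume
        (voxel volume × alpha).
        """
        vol_l = voxel_volume_um3 * 1e-15 * self.alpha
        return self.quantum / (N_AVOGADRO * vol_l) * 1e9

    def molecule_conc(self, voxel_volume_um3: float) -> float:
        """Concentration (nM) of a single molecule in one voxel's ECS."""
        vol_l = voxel_volume_um3 * 1e-15 * self.alpha
        return 1.0 / (N_AVOGADRO * vol_l) * 1e9


class AmphetamineSpec(_Model):
    """High-dose amphetamine: vesicular depletion, transporter reversal."""

    efflux_rate: float = Field(250.0, ge=0.0, description="DA efflux (molecules/s per terminal)")
    vesicular_quench: float = Field(1.0, ge=0.0, le=1.0)
    uptake_block: float = Field(30.0, ge=1.0, description="effective Km multiplier (transporter reversal)")


class InterventionSpec(_Model):
    """Pharmacological interventions expressed as parameter transforms."""

    ldopa_quantum_scale: float = Field(1.0, ge=1.0)
    uptake_km_scale: float = Field(1.0, ge=1.0)
    amphetamine: Optional[AmphetamineSpec] = None


class ReceptorParams(_Model):
    """Postsynaptic binding parameters: high-affinity D2, low-affinity D1."""

    ec50_d1: float = Field(300.0, gt=0.0, description="D1 half-occupancy (nM)")
    ec50_d2: float = Field(10.0, gt=0.0, description="D2 half-occupancy (nM)")
    hill: float = Field(1.0, gt=0.0)
    k_on: Optional[float] = Field(None, gt=0.0, description="binding rate (1/(nM·s))")
    k_off: Optional[float] = Field(None, gt=0.0, description="unbinding rate (1/s)")

    @model_validator(mode="after")
    def _check(self) -> "ReceptorParams":
        if self.ec50_d2 >= self.ec50_d1:
            raise ValueError("ec50_d2 must be below ec50_d1 (D2 is the high-affinity receptor)")
        if (self.k_on is None) != (self.k_off is None):
            raise ValueError("k_on and k_off must be set together for kinetic mode")
        return self


class TransductionConfig(_Model):
    """Threshold/gain transduction criteria.

    ``aberrant_criterion`` and ``aberrant_threshold`` operationalize
    "persistent activation by baseline fluctuations": the aberrant index is
    the fraction of tonic-firing time a pathway's response exceeds
    ``aberrant_criterion`` × the intact *event-evoked* reference (the mean
    response during bursts for D1, during pauses for D2 — the epochs that
    carry each pathway's functional signal).  Compensation counts as broken
    down at a denervation level when the index *exceeds the seed-matched
    intact index* by more than ``aberrant_threshold`` (the excess form pairs
    out shared baseline statistics), or when the phasic/tonic contrast falls
    below ``contrast_lost``.  All three were calibrated once against the
    compensated-D2 breakdown landing in the 70±10% denervation band (see
    docs/methods.md) and then frozen.
    """

    aberrant_criterion: float = Field(0.2, gt=0.0)
    aberrant_threshold: float = Field(0.035, gt=0.0, le=1.0)
    contrast_lost: float = Field(0.2, ge=0.0, le=1.0)
    gain_cap: float = Field(100.0, gt=0.0)
    min_reference: float = Field(30.0, gt=0.0, description="min tonic reference length (s)")
    burn_in: float = Field(2.0, ge=0.0, description="discarded transient (s)")


class ExperimentConfig(_Model):
    """Problem sizes and sweep plan for the in-silico experiments."""

    n_neurons: int = Field(100, ge=1, description="DA neurons innervating the volume when intact; ~100-200 arbors overlap any striatal point")
    duration: float = Field(64.0, gt=0.0, description="total run length (s); tonic then phasic halves")
    dt: float = Field(1e-3, gt=0.0)
    terminal_density: float = Field(0.1, ge=0.0, description="intact terminal density (1/µm³)")
    n_probes: int = Field(4, ge=1)
    levels: Tuple[float, ...] = (0.0, 0.25, 0.5, 0.7, 0.75, 0.85, 0.9, 0.97)
    n_seeds: int = Field(5, ge=1)


class RunConfig(_Model):
    """Top-level run configuration (one TOML file)."""

    firing: FiringConfig = Field(default_factory=FiringConfig)
    lattice: Lattice = Field(default_factory=Lattice)
    kinetics: KineticParams = Field(default_factory=KineticParams)
    receptors: ReceptorParams = Field(default_factory=ReceptorParams)
    transduction: TransductionConfig = Field(default_factory=TransductionConfig)
    experiment: ExperimentConfig = Field(default_factory=ExperimentConfig)
    master_seed: int = 0
    output_dir: str = "."


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a TOML run configuration.

    An empty file yields all documented defaults.  Unknown keys and
    invariant violations raise :class:`ConfigError` naming the offending key.
    """
    import tomllib

    p = Path(path)
    if not p.exists():
        raise ConfigError(f"config file not found: {p}")
    try:
        data = tomllib.loads(p.read_text())
    except tomllib.TOMLDecodeError as e:
        raise ConfigError(f"malformed config {p}: {e}") from e
    try:
        return RunConfig(**data)
    except ValidationError as e:
        keys = ", ".join(
            ".".join(str(x) for x in err["loc"]) or "<root>" for err in e.errors()
        )
        raise ConfigError(f"invalid config {p}: bad key(s) {keys}\n{e}") from e


def _toml_value(v) -> str:
    if isinstance(v, bool):
        return "true" if v else "false"
    if isinstance(v, (int, float)):
        return repr(v)
    if isinstance(v, str):
        return f'"{v}"'
    if isinstance(v, (list, tuple)):
        return "[" + ", ".join(_toml_value(x) for x in v) + "]"
    raise TypeError(f"cannot serialize {type(v)}")


def dump_config(cfg: RunConfig) -> str:
    """Serialize a config to normalized TOML (stable key order)."""
    lines: list[str] = []
    top = cfg.model_dump()
    for key in ("master_seed", "output_dir"):
        lines.append(f"{key} = {_toml_value(top[key])}")
    for section in ("firing", "lattice", "kinetics", "receptors", "transduction", "experiment"):
        data = top[section]
        lines.append("")
        lines.append(f"[{section}]")
        for k, v in data.items():
            if isinstance(v, dict):
                continue
            if v is None:
                continue
            lines.append(f"{k} = {_toml_value(v)}")
        for k, v in data.items():
            if isinstance(v, dict):
                lines.append("")
                lines.append(f"[{section}.{k}]")
                for kk, vv in v.items():
                    if vv is not None:
                        lines.append(f"{kk} = {_toml_value(vv)}")
    return "\n".join(lines) + "\n"
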