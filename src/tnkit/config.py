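"""Configuration objects for simulation and pipeline runs.

All randomness in the package flows from the mandatory ``seed`` field; no
function draws from global numpy state.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Sequence


class ConfigurationError(ValueError):
    """Raised when a configuration violates its invariants."""


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic two-population motility simulation.

    The defaults describe a fibronectin-coated 2D imaging chamber holding
    motile CD8+ T cells and NK cells: a 400 um square arena imaged for 100
    frames at 30 s intervals, T cells migrating at ~0.15 um/s and slowing
    ~10-fold during scripted NK contacts.

    Parameters
    ----------
    seed : int
        Seed for the single random generator driving the simulation.
    n_t, n_nk : int
        Number of T and NK cells.
    arena_size : float
        Side length of the square arena, um.
    n_frames : int
        Number of time-lapse frames (default 100).
    frame_interval : float
        Seconds between frames.
    base_speed_t, base_speed_nk : float
        Free-migration speed per cell type, um/s.
    deceleration_factors : float or sequence of float
        Multiplier applied to a T cell's speed during its scripted contact
        window; scalar applies to all T cells, a sequence gives one factor
        per T cell. Must lie in (0, 1].
    contact_radius : float
        Centre-to-centre distance (um) at or below which two cells are in
        contact.
    noise_sd_frac : float
        Standard deviation of Gaussian step-speed noise, as a fraction of
        the current speed.
    transfer_pixels : int
        Number of donor-channel pixels painted inside the recipient mask
        per frame of a transfer event.
    pixel_size : float
        um per pixel for rendering.
    cell_radius_um : float
        Rendered cell radius, um. Kept below contact_radius / 2 so that
        touching cells' disks remain disjoint.
    """

    seed: int
    n_t: int = 20
    n_nk: int = 20
    arena_size: float = 400.0
    n_frames: int = 100
    frame_interval: float = 30.0
    base_speed_t: float = 0.15
    base_speed_nk: float = 0.10
    deceleration_factors: float | Sequence[float] = 0.1
    contact_radius: float = 10.0
    noise_sd_frac: float = 0.1
    transfer_pixels: int = 50
    pixel_size: float = 0.5
    cell_radius_um: float = 4.0

    def __post_init__(self) -> None:
        if self.n_frames < 3:
            raise ConfigurationError("n_frames must be >= 3")
        for name in ("arena_size", "frame_interval", "base_speed_t",
                     "base_speed_nk", "contact_radius", "pixel_size",
                     "cell_radius_um"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.contact_radius >= self.arena_size:
            raise ConfigurationError("contact_radius must be < arena_size")
        if self.n_t < 0 or self.n_nk < 0:
            raise ConfigurationError("cell counts must be non-negative")
        if self.noise_sd_frac < 0:
            raise ConfigurationError("noise_sd_frac must be >= 0")
        if self.transfer_pixels < 0:
            raise ConfigurationError("transfer_pixels must be >= 0")
        for f in self.factor_list():
            if not 0 < f <= 1:
                raise ConfigurationError(
                    "deceleration factors must lie in (0, 1]")

    def factor_list(self) -> list[float]:
        """Per-T-cell deceleration factors, broadcasting a scalar."""
        if isinstance(self.deceleration_factors, (int, float)):
            return [float(self.deceleration_factors)] * self.n_t
        factors = [float(f) for f in self.deceleration_factors]
        if len(factors) != self.n_t:
            raise ConfigurationError(
                f"expected {self.n_t} deceleration factors, got {len(factors)}")
        return factors


@dataclass(frozen=True)
class PipelineConfig:
    """Analysis-side constants, with the study's fixed defaults.

    proximity_threshold_px (250) and hist_bin_px (10) are the published
    close/distant classification constants; lr_thresholds are the TPM
    screening cut-offs.
    """

    pixel_size: float = 0.5
    frame_interval: float = 30.0
    epsilon: float = 1e-6
    contact_distance: float = 10.0
    min_contact_frames: int = 2
    proximity_threshold_px: float = 250.0
    hist_bin_px: float = 10.0
    velocity_mode: str = "path"
    sdi_bin_width: float = 3600.0
    lr_thresholds: tuple[float, ...] = (2.0, 10.0)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("pixel_size", "frame_interval", "epsilon",
                     "contact_distance", "proximity_threshold_px",
                     "hist_bin_px", "sdi_bin_width"):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.min_contact_frames < 1:
            raise ConfigurationError("min_contact_frames must be >= 1")
        if self.velocity_mode not in ("path", "net"):
            raise ConfigurationError("velocity_mode must be 'path' or 'net'")
        if any(t <= 0 for t in self.lr_thresholds):
            raise ConfigurationError("lr_thresholds must be > 0")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        d["lr_thresholds"] = list(self.lr_thresholds)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        d["lr_thresholds"] = tuple(d["lr_thresholds"])
        return cls(**d)
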