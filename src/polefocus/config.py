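"""Configuration objects for the synthetic-microscopy generator.

All lengths are micrometers, times are seconds unless a field name says
minutes, intensities are arbitrary camera units.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass, field
from typing import Optional

import yaml

PATTERNS = ("non-Dyn", "Dyn-1P", "Dyn-OP", "UC")

#: Per-pattern cluster phenotype: fraction of the fluorophore budget in the
#: cluster (phi) and Gaussian spot width (sigma, um).  Bigger clusters are
#: brighter and wider, matching the inverse size/mobility trend the
#: classifier must resolve.
DEFAULT_PATTERN_CLUSTERS = {
    "non-Dyn": {"phi": 0.60, "sigma": 0.20},
    "Dyn-1P": {"phi": 0.40, "sigma": 0.15},
    "Dyn-OP": {"phi": 0.25, "sigma": 0.10},
}


class ConfigurationError(ValueError):
    """Raised when a simulation configuration violates its invariants."""


class GeometryError(ValueError):
    """Raised when cells cannot be placed inside the requested image."""


@dataclass
class FrapSettings:
    """Parameters of a photobleaching experiment on one polar cluster.

    ``recovery_asymptote`` and ``exchange_rate`` parameterize the normalized
    recovery curve A*(1 - exp(-k*t)), in percent of the bleached-away signal,
    exactly as the analysis pipeline reports it.  The renderer inverts the
    pipeline's normalization so the measured curve matches this analytic
    ground truth.  ``synthesis_asymptote`` is the additive contribution of
    newly synthesized molecules; translation-inhibited (chloramphenicol)
    stacks are generated with it set to zero.
    """

    bleach_frame: int = 2
    bleach_efficiency: float = 0.9
    exchange_rate: float = 0.005          # k, 1/s
    recovery_asymptote: float = 4.2096    # exchange component A_ex, %
    synthesis_asymptote: float = 2.1048   # de novo synthesis component, %
    n_postbleach_frames: int = 61         # 10 s grid -> 0..600 s inclusive

    @property
    def total_asymptote(self) -> float:
        return self.recovery_asymptote + self.synthesis_asymptote

    def analytic_recovery(self, t_s):
        """Normalized recovery (%) at time(s) ``t_s`` after the bleach."""
        import numpy as np

        t = np.asarray(t_s, dtype=float)
        return self.total_asymptote * (1.0 - np.exp(-self.exchange_rate * t))

    @classmethod
    def for_endpoint(
        cls,
        endpoint_pct: float,
        k: float = 0.005,
        t_end: float = 600.0,
        synthesis_fraction: float = 1.0 / 3.0,
        **kwargs,
    ) -> "FrapSettings":
        """Build settings whose analytic recovery at ``t_end`` equals
        ``endpoint_pct``, with ``synthesis_fraction`` of the recovered signal
        attributed to de novo synthesis."""
        total = endpoint_pct / (1.0 - math.exp(-k * t_end))
        return cls(
            exchange_rate=k,
            recovery_asymptote=total * (1.0 - synthesis_fraction),
            synthesis_asymptote=total * synthesis_fraction,
            **kwargs,
        )

    def validate(self) -> None:
        if not (0.0 < self.bleach_efficiency <= 1.0):
            raise ConfigurationError(
                f"bleach_efficiency must be in (0, 1], got {self.bleach_efficiency}"
            )
        if self.exchange_rate < 0:
            raise ConfigurationError("exchange_rate must be nonnegative")
        if self.bleach_frame < 1:
            raise ConfigurationError("bleach_frame must leave >= 1 prebleach frame")


@dataclass
class SimulationConfig:
    """Every generative parameter of the synthetic world.

    The defaults describe an exponentially growing *E. coli* population imaged
    at 0.1 um/px with one-minute frames over ten minutes — the canonical
    pattern-classification protocol.
    """

    # --- optics / sampling -------------------------------------------------
    pixel_size: float = 0.1               # um per pixel
    frame_interval: float = 60.0          # s
    n_frames: int = 11
    image_shape: Optional[tuple] = None   # (rows, cols) px; None -> auto grid

    # --- cell geometry and growth -----------------------------------------
    n_cells: int = 100
    cell_length_range: tuple = (2.5, 4.0)  # um at t0
    cell_width: float = 1.0                # um
    growth_rate: float = 0.02              # um/min
    division_length: float = 5.0           # um
    allow_division: bool = False

    # --- fluorophore budget and cluster phenotype --------------------------
    total_intensity_mean: float = 5000.0
    total_intensity_cv: float = 0.2
    cluster_fraction_range: tuple = (0.1, 0.7)
    cluster_sigma: float = 0.15            # um, default spot width
    pattern_clusters: dict = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PATTERN_CLUSTERS.items()}
    )

    # --- cluster motion ----------------------------------------------------
    speed_coefficient: float = 0.02        # v0, um/s at the reference area
    speed_exponent: float = 1.0            # alpha; speed = v0*(A_ref/A)^alpha
    reference_area: float = 0.2            # A_ref, um^2
    speed_noise_cv: float = 0.15           # lognormal per-cell speed scatter
    motility_suppressed: bool = False      # DNP mode: residual 0.05*v0, size-free
    speed_area_rank_corr: Optional[float] = None  # copula mode for Fig 1E-style runs
    area_lognorm: tuple = (math.log(0.2), 0.5)    # (mu, sigma) of ln(area um^2)
    speed_lognorm: tuple = (math.log(0.015), 0.6)  # (mu, sigma) of ln(speed um/s)

    # --- population composition and kinetics --------------------------------
    pattern_weights: tuple = (0.09, 0.43, 0.11, 0.37)  # non-Dyn, Dyn-1P, Dyn-OP, UC
    nucleation_rate: float = 0.008         # lambda, events/min per clusterless cell
    formation_duration: float = 3.0        # min, ramp of the cluster fraction
    dispersal_rate: float = 0.02           # fraction of cluster lost per min
    inherit_single_prob: float = 0.72      # P(exactly one daughter gets the cluster)
    nucleate_after_division: bool = True
    pole_zone_fraction: float = 0.25

    # --- quiescence-exit (overnight) populations ----------------------------
    qx_class_weights: tuple = (0.13, 0.64, 0.23)   # no-cluster, small, big
    qx_phi_small: float = 0.18
    qx_phi_big: float = 0.70
    qx_disperse_prob: float = 35.0 / 64.0  # among small-cluster cells
    qx_reform: bool = True
    #: when set to (lo, hi), quiescence-exit cells get a continuous uniform
    #: cluster-fraction spectrum instead of the three discrete classes —
    #: the layout of the reporter-correlation scatter experiments
    qx_phi_continuous: Optional[tuple] = None

    # --- image formation -----------------------------------------------------
    background_level: float = 5.0
    read_noise_sd: float = 0.3
    phase_amplitude: float = 100.0

    # --- reporter channel ----------------------------------------------------
    reporter_rank_corr: Optional[float] = None
    reporter_mean: float = 500.0
    reporter_cv: float = 0.2

    # --- FRAP ----------------------------------------------------------------
    frap: Optional[FrapSettings] = None

    seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # ------------------------------------------------------------------
    def validate(self) -> None:
        w = self.pattern_weights
        if len(w) != 4 or abs(sum(w) - 1.0) > 1e-9 or any(x < 0 for x in w):
            raise ConfigurationError(
                f"pattern_weights must be 4 nonnegative values summing to 1, got {w}"
            )
        lo, hi = self.cluster_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ConfigurationError(
                f"cluster_fraction_range must lie inside [0, 1], got {self.cluster_fraction_range}"
            )
        if self.reporter_rank_corr is not None and abs(self.reporter_rank_corr) > 1.0:
            raise ConfigurationError(
                f"reporter_rank_corr must be in [-1, 1], got {self.reporter_rank_corr}"
            )
        if self.speed_area_rank_corr is not None and abs(self.speed_area_rank_corr) > 1.0:
            raise ConfigurationError("speed_area_rank_corr must be in [-1, 1]")
        for name in (
            "pixel_size", "frame_interval", "cell_width", "division_length",
            "total_intensity_mean", "cluster_sigma", "reference_area",
        ):
            if getattr(self, name) <= 0:
                raise ConfigurationError(f"{name} must be positive")
        for name in (
            "growth_rate", "nucleation_rate", "dispersal_rate", "background_level",
            "read_noise_sd", "speed_coefficient", "total_intensity_cv",
            "speed_noise_cv", "formation_duration",
        ):
            if getattr(self, name) < 0:
                raise ConfigurationError(f"{name} must be nonnegative")
        if not (0.0 <= self.inherit_single_prob <= 1.0):
            raise ConfigurationError("inherit_single_prob must be a probability")
        if not (0.0 < self.pole_zone_fraction < 0.5):
            raise ConfigurationError("pole_zone_fraction must be in (0, 0.5)")
        if self.n_frames < 1:
            raise ConfigurationError("n_frames must be >= 1")
        qw = self.qx_class_weights
        if len(qw) != 3 or abs(sum(qw) - 1.0) > 1e-9 or any(x < 0 for x in qw):
            raise ConfigurationError("qx_class_weights must be 3 weights summing to 1")
        if self.frap is not None:
            self.frap.validate()
            if self.frap.bleach_frame >= self.n_frames:
                raise ConfigurationError("frap.bleach_frame must lie within the stack")

    # ------------------------------------------------------------------
    def replace(self, **kwargs) -> "SimulationConfig":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        if d.get("frap") is not None and not isinstance(d["frap"], FrapSettings):
            d["frap"] = FrapSettings(**d["frap"])
        for key in ("cell_length_range", "cluster_fraction_range", "pattern_weights",
                    "qx_class_weights", "area_lognorm", "speed_lognorm", "image_shape"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path) -> "SimulationConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))
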