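"""Synthetic 2DES data generator.

Builds :class:`~twodes.core.Dataset2DES` stacks with the statistical structure
the downstream analysis assumes: multi-exponential population kinetics encoded
as 2D decay-associated spectra, a diagonally elongated lineshape whose
excitation-emission correlation decays with population time (spectral
diffusion), damped vibrational beats localized on a spatial profile, and
additive Gaussian noise.

Four named presets encode the chlorophyll-b study conditions at room
temperature and 77 K, so every analysis stage has a known recovery target:

``rt_kinetic``
    Bi-exponential kinetics (150 fs + 3 ps) with the room-temperature 2D-DAS
    morphologies: a Q_y(0,0) diagonal peak at 15,390 cm^-1, a below-diagonal
    vibronic cross peak at (16,000, 15,250) cm^-1, a negative excited-state
    absorption at (15,410, 14,350) cm^-1, and nine vibrational beat modes
    between 200 and 1260 cm^-1.
``k77_kinetic``
    Same structure at 77 K: 60 fs fast constant, negative fast-DAS features
    at emission ~15,000 cm^-1 (vibrational energy redistribution), and beat
    modes below 700 cm^-1 quenched to one fifth of their RT amplitude.
``rt_lineshape`` / ``k77_lineshape``
    A single diagonal peak whose correlation rho(t2) decays with a 150 fs
    spectral-diffusion constant at RT but stays frozen at 77 K.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict
from typing import Literal, Sequence

import numpy as np

from .core import C_CM_PER_FS, Dataset2DES, FrequencyAxis, Map2D, TimeAxis
from .exceptions import DomainError

#: Default noise seed for reproducible fixtures.
DEFAULT_SEED = 2836

OFFSET = "offset"


@dataclass(frozen=True)
class Gaussian2DFeature:
    """Bivariate-Gaussian feature on the (excitation, emission) plane.

    ``rho`` is the excitation-emission correlation; a positive value
    elongates the feature along the diagonal.  ``amplitude`` is the signed
    peak value at the center.
    """

    center: tuple[float, float]
    sigma1: float
    sigma3: float
    rho: float = 0.0
    amplitude: float = 1.0

    def __post_init__(self):
        if not (self.sigma1 > 0 and self.sigma3 > 0):
            raise DomainError("feature widths must be positive")
        if not abs(self.rho) < 1:
            raise DomainError("|rho| must be < 1")


@dataclass(frozen=True)
class KineticComponent:
    """One exponential component of the population kinetics.

    ``tau`` is the decay constant in fs, or the sentinel ``"offset"`` for a
    non-decaying contribution.  ``features`` compose its 2D-DAS.
    """

    tau: float | str
    features: tuple[Gaussian2DFeature, ...]

    def __post_init__(self):
        if self.tau != OFFSET and not (isinstance(self.tau, (int, float)) and self.tau > 0):
            raise DomainError("tau must be positive or the sentinel 'offset'")
        object.__setattr__(self, "features", tuple(self.features))


@dataclass(frozen=True)
class LineshapeModel:
    """Single-peak lineshape with decaying excitation-emission correlation.

    ``rho(t2) = rho_inf + (rho0 - rho_inf) * exp(-t2 / tau_sd)`` and the
    overall amplitude decays as ``exp(-t2 / tau_amp)``.
    """

    center: tuple[float, float]
    sigma1: float
    sigma3: float
    rho0: float
    rho_inf: float
    tau_sd: float
    tau_amp: float

    def __post_init__(self):
        if not (0 <= self.rho_inf <= self.rho0 < 1):
            raise DomainError("require 0 <= rho_inf <= rho0 < 1")
        if not (self.tau_sd > 0 and self.tau_amp > 0):
            raise DomainError("time constants must be positive")
        if not (self.sigma1 > 0 and self.sigma3 > 0):
            raise DomainError("widths must be positive")

    def rho(self, t2: np.ndarray | float) -> np.ndarray | float:
        return self.rho_inf + (self.rho0 - self.rho_inf) * np.exp(-np.asarray(t2) / self.tau_sd)


@dataclass(frozen=True)
class BeatMode:
    """Damped vibrational coherence at wavenumber ``nu`` (cm^-1).

    The oscillation ``amplitude`` is a fraction of the dataset maximum and is
    spatially localized by ``profile``.
    """

    nu: float
    amplitude: float
    damping: float
    phase: float = 0.0
    profile: Gaussian2DFeature | None = None

    def __post_init__(self):
        if not self.nu > 0:
            raise DomainError("mode wavenumber must be positive")
        if not self.damping > 0:
            raise DomainError("damping time must be positive")
        if self.amplitude < 0:
            raise DomainError("beat amplitude must be >= 0")


@dataclass(frozen=True)
class NoiseSpec:
    """Additive i.i.d. Gaussian noise, s.d. = ``sigma_rel`` x dataset max."""

    sigma_rel: float = 0.01
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        if self.sigma_rel < 0:
            raise DomainError("sigma_rel must be >= 0")


@dataclass(frozen=True)
class Preset:
    """Full parameter bundle from which a synthetic dataset is built."""

    name: str
    grid: tuple[float, float, int, float, float]  # (w_min, w_max, n_w, t2_max, dt2)
    mode: Literal["kinetic", "lineshape"]
    components: tuple[KineticComponent, ...] = ()
    lineshape: LineshapeModel | None = None
    beats: tuple[BeatMode, ...] = ()
    noise: NoiseSpec = field(default_factory=NoiseSpec)
    temperature: str = ""

    def __post_init__(self):
        if self.mode == "kinetic":
            if not self.components or self.lineshape is not None:
                raise DomainError("kinetic preset must define components only")
        elif self.mode == "lineshape":
            if self.lineshape is None or self.components:
                raise DomainError("lineshape preset must define a lineshape only")
        else:
            raise DomainError(f"unknown preset mode {self.mode!r}")
        object.__setattr__(self, "components", tuple(self.components))
        object.__setattr__(self, "beats", tuple(self.beats))

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "Preset":
        d = dict(d)
        d["grid"] = tuple(d["grid"])
        d["components"] = tuple(
            KineticComponent(
                tau=c["tau"],
                features=tuple(_feature_from_dict(f) for f in c["features"]),
            )
            for c in d.get("components", ())
        )
        ls = d.get("lineshape")
        if ls is not None:
            ls = dict(ls)
            ls["center"] = tuple(ls["center"])
            d["lineshape"] = LineshapeModel(**ls)
        d["beats"] = tuple(
            BeatMode(
                nu=b["nu"],
                amplitude=b["amplitude"],
                damping=b["damping"],
                phase=b.get("phase", 0.0),
                profile=_feature_from_dict(b["profile"]) if b.get("profile") else None,
            )
            for b in d.get("beats", ())
        )
        d["noise"] = NoiseSpec(**d["noise"]) if d.get("noise") else NoiseSpec()
        return cls(**d)


def _feature_from_dict(f: dict) -> Gaussian2DFeature:
    f = dict(f)
    f["center"] = tuple(f["center"])
    return Gaussian2DFeature(**f)


# ---------------------------------------------------------------------------
# generation primitives


def make_grid(
    w_min: float, w_max: float, n_w: int, t2_max: float, dt2: float
) -> tuple[FrequencyAxis, FrequencyAxis, TimeAxis]:
    """Identical excitation/emission axes plus the t2 axis 0, dt2, ... <= t2_max."""
    if not w_max > w_min:
        raise DomainError("need w_max > w_min")
    if n_w < 8:
        raise DomainError("need at least 8 frequency points")
    if not dt2 > 0:
        raise DomainError("dt2 must be positive")
    w = np.linspace(w_min, w_max, n_w)
    n_t = int(math.floor(t2_max / dt2 + 1e-9)) + 1
    t = np.arange(max(n_t, 1)) * dt2
    return FrequencyAxis(w), FrequencyAxis(w.copy()), TimeAxis(t)


def render_feature(
    f: Gaussian2DFeature, excitation: FrequencyAxis, emission: FrequencyAxis
) -> Map2D:
    """Render a bivariate Gaussian on the grid; peak value equals ``amplitude``."""
    u = (excitation.values[:, None] - f.center[0]) / f.sigma1
    v = (emission.values[None, :] - f.center[1]) / f.sigma3
    z = (u * u - 2.0 * f.rho * u * v + v * v) / (1.0 - f.rho**2)
    return Map2D(excitation, emission, f.amplitude * np.exp(-0.5 * z))


def _render_sum(features: Sequence[Gaussian2DFeature], exc, emi) -> np.ndarray:
    out = np.zeros((len(exc), len(emi)))
    for f in features:
        out += render_feature(f, exc, emi).amplitude
    return out


def generate_kinetic(p: Preset) -> Dataset2DES:
    """Build a dataset from exponential components: sum_k DAS_k exp(-t2/tau_k)
    (+ offset), then apply beats and noise if the preset configures them."""
    if p.mode != "kinetic":
        raise DomainError("preset is not kinetic")
    exc, emi, time = make_grid(*p.grid)
    t = time.values
    cube = np.zeros((len(exc), len(emi), len(time)))
    for comp in p.components:
        das = _render_sum(comp.features, exc, emi)
        decay = np.ones_like(t) if comp.tau == OFFSET else np.exp(-t / comp.tau)
        cube += das[:, :, None] * decay[None, None, :]
    ds = Dataset2DES(
        exc, emi, time, cube,
        meta={"preset": p.name, "temperature": p.temperature,
              "seed": p.noise.seed, "generator": "kinetic"},
    )
    if p.beats:
        ds = add_beats(ds, p.beats)
    if p.noise.sigma_rel > 0:
        ds = add_noise(ds, p.noise)
    return ds


def generate_lineshape(p: Preset) -> Dataset2DES:
    """Build a spectral-diffusion dataset: one Gaussian peak per t2 slice with
    correlation rho(t2) and overall amplitude exp(-t2/tau_amp)."""
    if p.mode != "lineshape":
        raise DomainError("preset is not lineshape")
    ls = p.lineshape
    exc, emi, time = make_grid(*p.grid)
    cube = np.empty((len(exc), len(emi), len(time)))
    for k, t2 in enumerate(time.values):
        f = Gaussian2DFeature(
            center=ls.center, sigma1=ls.sigma1, sigma3=ls.sigma3,
            rho=float(ls.rho(t2)), amplitude=math.exp(-t2 / ls.tau_amp),
        )
        cube[:, :, k] = render_feature(f, exc, emi).amplitude
    ds = Dataset2DES(
        exc, emi, time, cube,
        meta={"preset": p.name, "temperature": p.temperature,
              "seed": p.noise.seed, "generator": "lineshape"},
    )
    if p.beats:
        ds = add_beats(ds, p.beats)
    if p.noise.sigma_rel > 0:
        ds = add_noise(ds, p.noise)
    return ds


def generate(p: Preset) -> Dataset2DES:
    """Dispatch on the preset mode."""
    return generate_kinetic(p) if p.mode == "kinetic" else generate_lineshape(p)


def add_beats(ds: Dataset2DES, modes: Sequence[BeatMode]) -> Dataset2DES:
    """Superimpose damped cosine oscillations on a dataset.

    Each mode adds ``amplitude * max|cube| * profile(w1, w3) *
    cos(2 pi c nu t2 + phase) * exp(-t2 / damping)``.  Modes above the t2
    Nyquist frequency are rejected.
    """
    out = ds.copy()
    if not modes:
        return out
    t = ds.time.values
    nyquist = 1.0 / (2.0 * ds.time.step * C_CM_PER_FS)
    scale = ds.max_abs
    for m in modes:
        if m.nu > nyquist:
            raise DomainError(
                f"beat mode {m.nu} cm^-1 exceeds the Nyquist frequency {nyquist:.1f}"
            )
        profile = (
            np.ones((len(ds.excitation), len(ds.emission)))
            if m.profile is None
            else render_feature(m.profile, ds.excitation, ds.emission).amplitude
        )
        osc = np.cos(2.0 * np.pi * C_CM_PER_FS * m.nu * t + m.phase) * np.exp(-t / m.damping)
        out.cube += m.amplitude * scale * profile[:, :, None] * osc[None, None, :]
    return out


def add_noise(ds: Dataset2DES, ns: NoiseSpec) -> Dataset2DES:
    """Add i.i.d. Gaussian noise (s.d. = sigma_rel x max|cube|), seeded."""
    out = ds.copy()
    if ns.sigma_rel == 0:
        return out
    rng = np.random.default_rng(ns.seed)
    out.cube += rng.standard_normal(ds.cube.shape) * (ns.sigma_rel * ds.max_abs)
    out.meta["seed"] = ns.seed
    return out


# ---------------------------------------------------------------------------
# presets

#: Common frequency/time grid: Q-band window, 96 points; t2 0-1000 fs step 7.5 fs.
DEFAULT_GRID = (13_800.0, 17_600.0, 96, 1000.0, 7.5)

#: The nine vibrational beat modes (cm^-1) observed in the coherence spectra.
BEAT_MODES_CM1 = (200.0, 296.0, 380.0, 450.0, 530.0, 770.0, 926.0, 1120.0, 1260.0)

_BEAT_DAMPING_FS = 600.0
_SLOW_TAU_FS = 3000.0  # stands in for the ">1 ps" component

#: Deterministic, pairwise-decorrelated beat phases (golden-ratio sequence).
#: Distinct vibrational coherences carry unrelated phases; an all-in-phase
#: choice would synthesize a coherent packet at t2 ~ 0 whose slowly decaying
#: envelope masquerades as an extra kinetic component and corrupts the
#: multi-exponential recovery targets the presets exist to provide.
_GOLDEN = 2.0 * math.pi * (math.sqrt(5.0) - 1.0) / 2.0


def _beat_phase(index: int) -> float:
    return float(((index + 1) * _GOLDEN) % (2.0 * math.pi))


def _rt_kinetic(noise: NoiseSpec) -> Preset:
    fast = KineticComponent(
        tau=150.0,
        features=(
            Gaussian2DFeature((15_390.0, 15_390.0), 260.0, 260.0, 0.7, 1.0),
            Gaussian2DFeature((15_150.0, 15_700.0), 200.0, 200.0, 0.0, -0.4),
            Gaussian2DFeature((15_700.0, 15_150.0), 200.0, 200.0, 0.0, -0.4),
        ),
    )
    # Diagonal width 240 cm^-1: narrow enough that the vibronic cross peak at
    # (16,000, 15,250) survives as a distinct local feature below the diagonal.
    slow_diag = Gaussian2DFeature((15_390.0, 15_390.0), 240.0, 240.0, 0.5, 1.0)
    slow = KineticComponent(
        tau=_SLOW_TAU_FS,
        features=(
            slow_diag,
            Gaussian2DFeature((16_000.0, 15_250.0), 220.0, 220.0, 0.0, 0.35),
            Gaussian2DFeature((15_410.0, 14_350.0), 250.0, 250.0, 0.0, -0.30),
        ),
    )
    # Coherences ride on the full GSB/SE diagonal band, which is broader than
    # the long-lived DAS peak rendered above.
    beat_profile = Gaussian2DFeature((15_390.0, 15_390.0), 300.0, 300.0, 0.5, 1.0)
    beats = tuple(
        BeatMode(nu=nu, amplitude=0.03, damping=_BEAT_DAMPING_FS,
                 phase=_beat_phase(m), profile=beat_profile)
        for m, nu in enumerate(BEAT_MODES_CM1)
    )
    return Preset("rt_kinetic", DEFAULT_GRID, "kinetic",
                  components=(fast, slow), beats=beats, noise=noise, temperature="RT")


def _k77_kinetic(noise: NoiseSpec) -> Preset:
    fast = KineticComponent(
        tau=60.0,
        features=(
            Gaussian2DFeature((15_580.0, 15_580.0), 200.0, 200.0, 0.85, 1.0),
            Gaussian2DFeature((16_000.0, 15_000.0), 200.0, 200.0, 0.0, -0.5),
            Gaussian2DFeature((17_000.0, 15_000.0), 200.0, 200.0, 0.0, -0.5),
        ),
    )
    slow_diag = Gaussian2DFeature((15_450.0, 15_450.0), 220.0, 220.0, 0.85, 1.0)
    slow = KineticComponent(
        tau=_SLOW_TAU_FS,
        features=(
            slow_diag,
            Gaussian2DFeature((15_990.0, 15_300.0), 180.0, 180.0, 0.0, 0.3),
            Gaussian2DFeature((16_400.0, 15_300.0), 180.0, 180.0, 0.0, 0.3),
        ),
    )
    beat_profile = Gaussian2DFeature((15_450.0, 15_450.0), 300.0, 300.0, 0.5, 1.0)
    beats = tuple(
        BeatMode(
            nu=nu,
            amplitude=0.006 if nu < 700.0 else 0.03,  # low modes quenched at 77 K
            damping=_BEAT_DAMPING_FS,
            phase=_beat_phase(m),
            profile=beat_profile,
        )
        for m, nu in enumerate(BEAT_MODES_CM1)
    )
    return Preset("k77_kinetic", DEFAULT_GRID, "kinetic",
                  components=(fast, slow), beats=beats, noise=noise, temperature="77K")


def _rt_lineshape(noise: NoiseSpec) -> Preset:
    ls = LineshapeModel(
        center=(15_390.0, 15_390.0), sigma1=300.0, sigma3=300.0,
        rho0=0.85, rho_inf=0.05, tau_sd=150.0, tau_amp=_SLOW_TAU_FS,
    )
    return Preset("rt_lineshape", DEFAULT_GRID, "lineshape",
                  lineshape=ls, noise=noise, temperature="RT")


def _k77_lineshape(noise: NoiseSpec) -> Preset:
    ls = LineshapeModel(
        center=(15_390.0, 15_390.0), sigma1=300.0, sigma3=300.0,
        rho0=0.85, rho_inf=0.85, tau_sd=150.0, tau_amp=_SLOW_TAU_FS,
    )
    return Preset("k77_lineshape", DEFAULT_GRID, "lineshape",
                  lineshape=ls, noise=noise, temperature="77K")


_PRESETS = {
    "rt_kinetic": _rt_kinetic,
    "k77_kinetic": _k77_kinetic,
    "rt_lineshape": _rt_lineshape,
    "k77_lineshape": _k77_lineshape,
}

PRESET_NAMES = tuple(sorted(_PRESETS))


def get_preset(name: str, seed: int | None = None, sigma_rel: float | None = None) -> Preset:
    """Return a named preset; optional overrides for the noise seed and level."""
    if name not in _PRESETS:
        raise DomainError(
            f"unknown preset {name!r}; valid names: {', '.join(PRESET_NAMES)}"
        )
    noise = NoiseSpec(
        sigma_rel=0.01 if sigma_rel is None else sigma_rel,
        seed=DEFAULT_SEED if seed is None else seed,
    )
    return _PRESETS[name](noise)
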