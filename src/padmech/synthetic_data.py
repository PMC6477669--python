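"""Synthetic test-machine data with the statistical structure the analysis assumes.

The generator plays the role of the materials testing machine: it emits
(time, displacement, force) records in machine format.  Monotonic records
ramp the piston at a nominal displacement rate and evaluate the Yeoh plant
forward; cyclic records build triangular load–unload cycles whose unloading
force branch is the loading branch scaled pointwise by (1 − q), so each
cycle's analytic energy dissipation ratio equals the prescribed q exactly.
Load-cell noise is Gaussian on force only (the displacement encoder is
treated as exact), parameterized as a fraction of the peak force, and
clipped at zero.

Default protocol values follow the surrogate test setup: 40 mm × 18 mm
cylindrical specimens, 9 mm maximum displacement, 1.96 mm/s displacement
rate, five cycles, optional 40 N load cap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core_mechanics import (
    DEFAULT_GEOMETRY,
    CompressionRecord,
    SpecimenGeometry,
)
from .surrogate_selection import LabeledCurve
from .yeoh_model import YeohParameters, uniaxial_stress

__all__ = [
    "GeneratorSpec",
    "generate_compression_record",
    "generate_hysteresis_record",
    "generate_cohort",
]


@dataclass(frozen=True)
class GeneratorSpec:
    """Everything needed to synthesize one machine record.

    ``force_noise_sd`` is the Gaussian noise standard deviation as a
    fraction of the noise-free peak force; ``dissipation`` is the target
    energy dissipation ratio q of cyclic records; ``load_cap`` optionally
    truncates a monotonic record at the first sample exceeding the cap
    (the test machine's force limit).
    """

    params: YeohParameters
    geometry: SpecimenGeometry = DEFAULT_GEOMETRY
    displacement_rate: float = 1.96  # mm/s
    max_displacement: float = 9.0  # mm
    sampling_rate: float = 100.0  # Hz
    force_noise_sd: float = 0.0
    n_cycles: int = 5
    dissipation: float = 0.22
    seed: int = 0
    load_cap: float | None = None
    label: str = ""

    def __post_init__(self) -> None:
        if not (self.max_displacement < self.geometry.height):
            raise ValueError(
                f"max displacement {self.max_displacement:g} mm must be below "
                f"specimen height {self.geometry.height:g} mm"
            )
        if not (0.0 <= self.dissipation < 1.0):
            raise ValueError(f"dissipation q must be in [0, 1), got {self.dissipation}")
        if not (self.sampling_rate > 0):
            raise ValueError("sampling rate must be > 0")
        if not (self.displacement_rate > 0):
            raise ValueError("displacement rate must be > 0")
        if self.force_noise_sd < 0:
            raise ValueError("force noise sd must be >= 0")
        if self.n_cycles < 1:
            raise ValueError("n_cycles must be >= 1")


def _ramp(spec: GeneratorSpec) -> tuple[np.ndarray, np.ndarray]:
    """Displacement ramp 0 → max at the nominal rate, endpoint included."""
    duration = spec.max_displacement / spec.displacement_rate
    n = max(int(round(duration * spec.sampling_rate)), 1)
    t = np.linspace(0.0, duration, n + 1)
    d = spec.displacement_rate * t
    d[-1] = spec.max_displacement  # exact endpoint
    return t, d


def _plant_force(spec: GeneratorSpec, displacement: np.ndarray) -> np.ndarray:
    lam = 1.0 - displacement / spec.geometry.height
    sigma = uniaxial_stress(lam, spec.params)
    return np.abs(sigma) * spec.geometry.cross_section_area


def _add_noise(
    force: np.ndarray, spec: GeneratorSpec, rng: np.random.Generator
) -> np.ndarray:
    if spec.force_noise_sd == 0.0:
        return force
    sd = spec.force_noise_sd * float(np.max(force))
    return np.clip(force + rng.normal(0.0, sd, size=force.shape), 0.0, None)


def generate_compression_record(spec: GeneratorSpec) -> CompressionRecord:
    """One monotonic compression ramp evaluated through the Yeoh plant."""
    rng = np.random.default_rng(spec.seed)
    t, d = _ramp(spec)
    f = _add_noise(_plant_force(spec, d), spec, rng)
    if spec.load_cap is not None:
        over = np.nonzero(f > spec.load_cap)[0]
        if len(over) and over[0] >= 2:
            t, d, f = t[: over[0]], d[: over[0]], f[: over[0]]
    return CompressionRecord(
        time=t,
        displacement=d,
        force=f,
        displacement_rate=spec.displacement_rate,
        geometry=spec.geometry,
        label=spec.label or spec.params.label,
    )


def generate_hysteresis_record(spec: GeneratorSpec) -> CompressionRecord:
    """Triangular load–unload cycles with prescribed dissipation q.

    The unloading force equals (1 − q) times the loading force at the same
    displacement.  The turning point is emitted twice — once at the loading
    force and once at the dropped unloading force — so the trapezoid-rule
    EDR of each segmented cycle equals q exactly (the duplicated sample
    spans zero displacement width and adds no area).
    """
    q = spec.dissipation
    rng = np.random.default_rng(spec.seed)
    t_up, d_up = _ramp(spec)
    f_up = _plant_force(spec, d_up)
    dt = t_up[1] - t_up[0] if len(t_up) > 1 else 1.0 / spec.sampling_rate

    times, disps, forces = [], [], []
    t0 = 0.0
    for _ in range(spec.n_cycles):
        # loading branch, including the peak
        times.append(t0 + t_up)
        disps.append(d_up)
        forces.append(f_up)
        t_peak = t0 + t_up[-1]
        # duplicated peak with the force drop, then the descending branch
        times.append(t_peak + np.concatenate(([0.0], dt + t_up[:-1])))
        disps.append(np.concatenate(([d_up[-1]], d_up[-2::-1])))
        forces.append((1.0 - q) * np.concatenate(([f_up[-1]], f_up[-2::-1])))
        t0 = t_peak + dt * len(t_up[:-1]) + dt
    t = np.concatenate(times)
    d = np.concatenate(disps)
    f = _add_noise(np.concatenate(forces), spec, rng)
    return CompressionRecord(
        time=t,
        displacement=d,
        force=f,
        displacement_rate=spec.displacement_rate,
        geometry=spec.geometry,
        label=spec.label or spec.params.label,
    )


def generate_cohort(
    composition_params: dict[str, YeohParameters],
    reference_params: dict[str, YeohParameters],
    variability_sd: float = 0.0,
    n_specimens: int = 3,
    seed: int = 0,
    geometry: SpecimenGeometry = DEFAULT_GEOMETRY,
    max_strain: float = 0.45,
    n_points: int = 50,
) -> tuple[list[LabeledCurve], dict[str, LabeledCurve]]:
    """Labeled force–strain curves for a candidate cohort plus references.

    Each composition is realized ``n_specimens`` times with lognormal
    multiplicative specimen-to-specimen variability on (c1, c2, c3)
    (keeps coefficients positive); references are noise-free group plants.
    Candidate labels are ``"<composition>#<specimen>"``.

    Returns
    -------
    (candidates, references)
        Candidates as a flat list of :class:`LabeledCurve`; references as a
        mapping group name → curve.
    """
    if not composition_params or not reference_params:
        raise ValueError("composition and reference parameter maps must be nonempty")
    if variability_sd < 0:
        raise ValueError("variability sd must be >= 0")
    rng = np.random.default_rng(seed)
    strain = np.linspace(0.0, max_strain, n_points)
    area = geometry.cross_section_area

    def curve(label: str, params: YeohParameters) -> LabeledCurve:
        lam = 1.0 - strain
        lam[0] = 1.0
        force = np.abs(uniaxial_stress(np.clip(lam, 1e-6, None), params)) * area
        return LabeledCurve(label=label, strain=strain, force=force)

    candidates: list[LabeledCurve] = []
    for name, params in composition_params.items():
        for k in range(n_specimens):
            mult = np.exp(rng.normal(0.0, variability_sd, size=3)) if variability_sd else np.ones(3)
            jittered = YeohParameters(
                params.c1 * mult[0], params.c2 * mult[1], params.c3 * mult[2]
            )
            candidates.append(curve(f"{name}#{k}", jittered))
    references = {g: curve(g, p) for g, p in reference_params.items()}
    return candidates, references
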