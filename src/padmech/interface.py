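"""Config handling, machine-CSV I/O, and the end-to-end pipeline.

Machine records travel as comma-separated UTF-8 CSV with a mandatory header
``time_s,displacement_mm,force_N`` (the column names assert the units).
Run configuration is a YAML document with ``geometry``, ``protocol``,
``analysis`` and ``seed`` blocks; all randomness flows from the single root
seed, split per stage with :class:`numpy.random.SeedSequence` in a fixed
order (generation first, then per-record noise streams).
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core_mechanics import (
    CompressionRecord,
    SpecimenGeometry,
    to_stress_stretch,
)
from .cyclic_analysis import (
    energy_dissipation_ratio,
    repeatability_check,
    segment_cycles,
)
from .fitting import FIT_R2_THRESHOLD, FitResult, classify_fit, fit_yeoh
from .surrogate_selection import (
    DEFAULT_N_GRID,
    SELECTION_THRESHOLD,
    SelectionReport,
    select_surrogates,
)
from .synthetic_data import (
    GeneratorSpec,
    generate_cohort,
    generate_compression_record,
    generate_hysteresis_record,
)
from .yeoh_model import YeohParameters, load_reference_parameters

logger = logging.getLogger("padmech")

REQUIRED_COLUMNS = ("time_s", "displacement_mm", "force_N")

__all__ = [
    "RunConfig",
    "read_record_csv",
    "write_record_csv",
    "run_pipeline",
    "ReportBundle",
]


@dataclass(frozen=True)
class RunConfig:
    """Geometry, protocol and analysis settings for one run."""

    diameter_mm: float = 40.0
    height_mm: float = 18.0
    rate_mm_per_s: float = 1.96
    max_displacement_mm: float = 9.0
    max_load_N: float = 40.0
    n_cycles: int = 5
    skip_cycles: int = 0
    threshold_select: float = SELECTION_THRESHOLD
    threshold_fit: float = FIT_R2_THRESHOLD
    n_grid: int = DEFAULT_N_GRID
    repeatability_tolerance: float = 0.10
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("threshold_select", "threshold_fit"):
            v = getattr(self, name)
            if not (0.0 < v <= 1.0):
                raise ValueError(f"{name} must lie in (0, 1], got {v}")
        if self.n_grid < 2:
            raise ValueError(f"n_grid must be >= 2, got {self.n_grid}")

    @property
    def geometry(self) -> SpecimenGeometry:
        return SpecimenGeometry(diameter=self.diameter_mm, height=self.height_mm)

    # -- YAML round trip ----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return {
            "geometry": {k: d.pop(k) for k in ("diameter_mm", "height_mm")},
            "protocol": {
                k: d.pop(k)
                for k in (
                    "rate_mm_per_s",
                    "max_displacement_mm",
                    "max_load_N",
                    "n_cycles",
                    "skip_cycles",
                )
            },
            "analysis": {
                k: d.pop(k)
                for k in (
                    "threshold_select",
                    "threshold_fit",
                    "n_grid",
                    "repeatability_tolerance",
                )
            },
            "seed": d.pop("seed"),
        }

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        flat: dict = {}
        for block in ("geometry", "protocol", "analysis"):
            flat.update(data.get(block, {}))
        if "seed" in data:
            flat["seed"] = data["seed"]
        return cls(**flat)

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def content_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]


def read_record_csv(path: str | Path, config: RunConfig) -> CompressionRecord:
    """Read one machine record CSV, validating schema and time ordering."""
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required column(s) {missing}")
    t = df["time_s"].to_numpy(float)
    if np.any(np.diff(t) < 0):
        raise ValueError(f"{path}: time_s must be monotone nondecreasing")
    return CompressionRecord(
        time=t,
        displacement=df["displacement_mm"].to_numpy(float),
        force=df["force_N"].to_numpy(float),
        displacement_rate=config.rate_mm_per_s,
        geometry=config.geometry,
        label=Path(path).stem,
    )


def write_record_csv(record: CompressionRecord, path: str | Path) -> None:
    pd.DataFrame(
        {
            "time_s": record.time,
            "displacement_mm": record.displacement,
            "force_N": record.force,
        }
    ).to_csv(path, index=False, lineterminator="\n")


@dataclass(frozen=True)
class ReportBundle:
    """Everything one pipeline run produces."""

    config: RunConfig
    config_hash: str
    fits: dict[str, FitResult]
    edr_table: pd.DataFrame
    repeatability_passed: bool
    selection: SelectionReport
    summary_markdown: str


def _split_seeds(root_seed: int, n: int) -> list[int]:
    """Stage seeds derived from the root via SeedSequence spawning."""
    return [int(s.generate_state(1)[0] % (2**31)) for s in np.random.SeedSequence(root_seed).spawn(n)]


def run_pipeline(
    config: RunConfig,
    records: list[CompressionRecord] | None = None,
    parameter_sets: dict[str, YeohParameters] | None = None,
) -> ReportBundle:
    """Run the three analyses end to end: per-rate fits, cyclic EDR, selection.

    Inputs are either machine records (``records``) or a map of named Yeoh
    parameter sets from which synthetic inputs are generated
    (``parameter_sets``; defaults to the packaged per-rate reference sets).
    Every artifact is reproducible from (config, seed).
    """
    if records is not None and len(records) == 0:
        raise ValueError("empty record list")
    if parameter_sets is None:
        parameter_sets = load_reference_parameters()

    seeds = _split_seeds(config.seed, 3)
    logger.info("pipeline start: config=%s seeds=%s", config.content_hash(), seeds)

    # --- per-rate hyperelastic fits ---------------------------------------
    fits: dict[str, FitResult] = {}
    if records is None:
        for name, params in parameter_sets.items():
            rate = params.rate_mm_per_s or config.rate_mm_per_s
            spec = GeneratorSpec(
                params=params,
                geometry=config.geometry,
                displacement_rate=rate,
                max_displacement=config.max_displacement_mm,
                # sampling tracks the ramp so high-rate tests keep 50 samples
                sampling_rate=50.0 * rate / config.max_displacement_mm,
                seed=seeds[0],
                label=name,
            )
            curve = to_stress_stretch(generate_compression_record(spec))
            fits[name] = fit_yeoh(curve)
            logger.info("fit %s: R²=%.6f", name, fits[name].r_squared)
    else:
        for rec in records:
            curve = to_stress_stretch(rec)
            fits[rec.label] = fit_yeoh(curve)
            logger.info("fit %s: R²=%.6f", rec.label, fits[rec.label].r_squared)

    # --- cyclic EDR and repeatability -------------------------------------
    cyclic_params = next(iter(parameter_sets.values()))
    cyc_spec = GeneratorSpec(
        params=cyclic_params,
        geometry=config.geometry,
        displacement_rate=config.rate_mm_per_s,
        max_displacement=config.max_displacement_mm,
        n_cycles=config.n_cycles,
        seed=seeds[1],
    )
    cyclic_record = (
        generate_hysteresis_record(cyc_spec) if records is None else records[0]
    )
    loops = segment_cycles(cyclic_record)[config.skip_cycles :]
    rows = []
    for loop in loops:
        if loop.loading_only:
            continue
        res = energy_dissipation_ratio(loop)
        rows.append(
            {
                "cycle": loop.cycle_index,
                "edr": res.edr,
                "loading_area_Nmm": res.loading_area,
                "hysteresis_area_Nmm": res.hysteresis_area,
                "peak_force_N": loop.peak_force,
            }
        )
    edr_table = pd.DataFrame(rows)
    repeat = (
        repeatability_check(loops, config.repeatability_tolerance)
        if len(loops) >= 2
        else None
    )
    logger.info("EDR mean=%.4f over %d cycles", edr_table["edr"].mean(), len(rows))

    # --- surrogate selection ----------------------------------------------
    candidates, references = generate_cohort(
        composition_params=parameter_sets,
        reference_params=parameter_sets,
        seed=seeds[2],
        geometry=config.geometry,
        n_specimens=1,
    )
    selection = select_surrogates(
        candidates, references, config.threshold_select, config.n_grid
    )

    summary = _summary_markdown(config, fits, edr_table, repeat, selection)
    return ReportBundle(
        config=config,
        config_hash=config.content_hash(),
        fits=fits,
        edr_table=edr_table,
        repeatability_passed=bool(repeat.passed) if repeat else False,
        selection=selection,
        summary_markdown=summary,
    )


def _summary_markdown(config, fits, edr_table, repeat, selection) -> str:
    lines = [
        "# padmech run summary",
        "",
        f"config hash: `{config.content_hash()}`",
        "",
        "## Yeoh fits",
        "",
        "| set | c1 (MPa) | c2 (MPa) | c3 (MPa) | R² | accurate |",
        "|---|---|---|---|---|---|",
    ]
    for name, fr in fits.items():
        lines.append(
            f"| {name} | {fr.params.c1:.4f} | {fr.params.c2:.4f} | "
            f"{fr.params.c3:.4f} | {fr.r_squared:.4f} | "
            f"{classify_fit(fr, config.threshold_fit)} |"
        )
    lines += ["", "## Cyclic analysis", ""]
    if len(edr_table):
        lines.append(f"mean EDR: {edr_table['edr'].mean():.4f}")
    if repeat is not None:
        lines.append(f"repeatability (±{repeat.tolerance:.0%} of max load): "
                     f"{'pass' if repeat.passed else 'fail'}")
    lines += ["", "## Selection", ""]
    for group, best in selection.best.items():
        lines.append(
            f"- {group}: best = {best}, admitted = {selection.admitted[group]}"
        )
    return "\n".join(lines) + "\n"
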