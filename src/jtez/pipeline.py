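"""End-to-end orchestration: phantom -> recording -> reconstruction ->
phase scan -> theziograms -> markers -> diagnostics.

Every stage's outputs land in the run directory together with a manifest
(config, seeds, config hash); rerunning with the same config reproduces
all numeric outputs bit-identically.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io
from .diagnostics import classify_loo, se_sp_ac
from .interferometry import RecoveredField, demodulate, rephase, synthesize
from .markers import marker_table
from .phantom import CohortSpec, Sample, make_cohort
from .phase_scan import DEFAULT_PLANES, PhaseSection, layered_field
from .theziography import PARAMETERS, theziogram_maps

log = logging.getLogger("jtez")

__all__ = ["RunConfig", "run_pipeline", "reconstruct_sample", "sample_maps"]


@dataclass(frozen=True)
class RunConfig:
    """One pipeline run: phantom cohort settings plus method knobs."""

    grid: tuple[int, int] = (128, 128)
    n_per_group: int = 26
    seed: int = 0
    carrier: tuple[float, float] = (0.2, 0.2)
    window_halfwidth: float = 0.1
    apodize: bool = True
    noise_sd: float = 0.0
    bit_depth: int | None = 16
    phase_planes: tuple[float, ...] = DEFAULT_PLANES
    scan_mode: str = "cumulative"
    phase_window: float = math.pi / 16.0
    method: str = "exact"
    inversion_convention: str = "eq10_11"
    clip_arccos: bool = False
    z2_is_variance: bool = False
    raw_kurtosis: bool = False
    save_images: bool = False
    out_dir: str = "jtez_run"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["grid"] = list(self.grid)
        d["carrier"] = list(self.carrier)
        d["phase_planes"] = list(self.phase_planes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        kw = dict(d)
        for key in ("grid", "carrier", "phase_planes"):
            if key in kw:
                kw[key] = tuple(kw[key])
        if kw.get("bit_depth") == 0:
            kw["bit_depth"] = None
        return cls(**kw)

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(io.read_toml(path))

    def save(self, path: str | Path) -> None:
        d = self.to_dict()
        if d.get("bit_depth") is None:
            d["bit_depth"] = 0  # TOML has no null
        io.write_toml(path, d)

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def reconstruct_sample(sample: Sample, config: RunConfig, out_dir: Path | None = None) -> RecoveredField:
    """Record the four interference channels of one sample and demodulate."""
    igs = synthesize(
        sample.jones,
        carrier=config.carrier,
        noise_sd=config.noise_sd,
        bit_depth=config.bit_depth,
        seed=sample.seed,
    )
    if out_dir is not None and config.save_images:
        for (s, omega), im in igs.images.items():
            io.write_tiff(out_dir / io.interferogram_name(sample.sample_id, s, omega), im)
    rec = demodulate(igs, window_halfwidth=config.window_halfwidth, apodize=config.apodize)
    return rephase(rec)


def sample_maps(rec: RecoveredField, config: RunConfig) -> dict[tuple[str, str | float], "object"]:
    """Integral + per-phase-plane theziograms of one recovered field."""
    maps: dict[tuple[str, str | float], object] = {}
    integral = theziogram_maps(
        rec, method=config.method, convention=config.inversion_convention, clip_arccos=config.clip_arccos
    )
    for name in PARAMETERS:
        maps[(name, "integral")] = integral[name]
    for phi_k in config.phase_planes:
        section = PhaseSection(phi_k=phi_k, delta_phi=config.phase_window, mode=config.scan_mode)
        gated = layered_field(rec, section)
        tz = theziogram_maps(
            gated, method=config.method, convention=config.inversion_convention, clip_arccos=config.clip_arccos
        )
        for name in PARAMETERS:
            maps[(name, float(phi_k))] = tz[name]
        log.info("phase plane %.4g: K=%d, dropped=%.3f", phi_k, tz["LB"].k, tz["LB"].dropped_fraction)
    return maps


def run_pipeline(config: RunConfig, out_dir: str | Path | None = None) -> Path:
    """Run the whole pipeline on a synthetic cohort; returns the run directory.

    Writes ``markers.csv`` (per sample x parameter x phase plane),
    ``diagnosis.json`` (confusion counts, Se/Sp/Ac, grade for every marker),
    and ``manifest.json``.
    """
    out = Path(out_dir if out_dir is not None else config.out_dir)
    out.mkdir(parents=True, exist_ok=True)

    cohort = CohortSpec.default(grid=config.grid, n_per_group=config.n_per_group, seed=config.seed)
    samples = make_cohort(cohort)
    log.info("cohort: %d samples per group on %sx%s grid", config.n_per_group, *config.grid)

    records = []
    for sample in samples:
        rec = reconstruct_sample(sample, config, out_dir=out)
        maps = sample_maps(rec, config)
        records.append((sample.sample_id, sample.group, maps))

    table = marker_table(records, z2_is_variance=config.z2_is_variance, raw_kurtosis=config.raw_kurtosis)
    io.write_markers_csv(out / "markers.csv", table)

    diagnosis = []
    planes = ["integral"] + [str(float(p)) for p in config.phase_planes]
    for parameter in PARAMETERS:
        for plane in planes:
            sub = table[(table.parameter == parameter) & (table.phase_plane == plane)]
            for z in ("Z1", "Z2", "Z3", "Z4"):
                ctrl = sub[sub.group == "healthy"][z].to_numpy(float)
                expe = sub[sub.group == "pathology"][z].to_numpy(float)
                if ctrl.size < 2 or expe.size < 2 or not (np.all(np.isfinite(ctrl)) and np.all(np.isfinite(expe))):
                    continue
                marker_id = f"{z}:{parameter}:{plane}"
                counts = classify_loo(ctrl, expe, marker_id=marker_id)
                res = se_sp_ac(counts, marker_id=marker_id)
                diagnosis.append(
                    {
                        "marker_id": marker_id,
                        "counts": dataclasses.asdict(counts),
                        "se": res.se,
                        "sp": res.sp,
                        "ac": res.ac,
                        "grade": res.grade,
                    }
                )
    io.write_json(out / "diagnosis.json", diagnosis)

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "n_samples": len(samples),
        "sample_seeds": {s.sample_id: s.seed for s in samples},
        "parameters": list(PARAMETERS),
        "phase_planes": planes,
        "outputs": ["markers.csv", "diagnosis.json"],
    }
    io.write_json(out / "manifest.json", manifest)
    return out
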