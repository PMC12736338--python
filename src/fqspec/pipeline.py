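"""End-to-end workflow: generate -> cut -> solve -> excite -> spectrum -> shift.

Mirrors the five-step solution-spectra protocol: sample solute-water
configurations, cut each to a droplet, solve the polarizable embedding
for every snapshot, obtain per-snapshot stick spectra, broaden and
ensemble-average them, and read off the band maximum and the
vacuo-to-water solvatochromic shift.  Every stage writes its artifacts
into its own workspace subdirectory and the run is summarised in a JSON
manifest (band energies, shift, timings, seeds, content hashes) so that
a rerun with the same config is reproducible bit for bit.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import fileio
from .core import (
    ForceFieldVariant,
    PARAMETER_SETS,
    interaction_energy,
    solute_point_source,
    solve_embedding,
    water_topology,
)
from .spectra import (
    DEFAULT_FWHM,
    DEFAULT_GRID,
    SpectrumCurve,
    band_maximum,
    band_width,
    convolve_gaussian,
    ensemble_average,
    solvatochromic_shift,
)
from .synthetic import (
    GeneratorConfig,
    MockExcitationModel,
    generate_snapshots,
    mock_excitations,
)
from .trajectory import Snapshot, spherical_cut

__all__ = ["PipelineConfig", "run_pipeline", "compare_variants",
           "load_config", "save_config"]

log = logging.getLogger("fqspec.pipeline")


@dataclass
class PipelineConfig:
    """Complete study configuration for one pipeline run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    excitation: MockExcitationModel = field(default_factory=MockExcitationModel)
    variant: ForceFieldVariant = ForceFieldVariant.FQ
    parameter_set: str | dict = "toy"
    kernel_form: str = "ohno"
    fwhm: float = DEFAULT_FWHM
    grid: tuple[float, float, float] = DEFAULT_GRID
    cut_radius: float | None = None
    normalize: bool = False
    seed: int = 0

    def __post_init__(self):
        if isinstance(self.variant, str):
            self.variant = ForceFieldVariant(self.variant)
        # one top-level seed drives both stochastic stages
        self.generator.seed = self.seed
        self.excitation.seed = self.seed

    @property
    def radius(self) -> float:
        return self.cut_radius if self.cut_radius is not None \
            else self.generator.droplet_radius

    def first_band_window(self) -> tuple[float, float]:
        """Energy window isolating the lowest band of the mock model."""
        lo = self.grid[0]
        if self.excitation.n_states > 1:
            hi = self.excitation.e0 + 0.5 * self.excitation.state_offsets[0]
        else:
            hi = self.grid[1]
        return (lo, hi)


def _plain(obj):
    """Recursively convert numpy scalars/arrays and tuples for YAML."""
    if isinstance(obj, dict):
        return {k: _plain(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_plain(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    return obj


def _to_dict(cfg: PipelineConfig) -> dict:
    d = dataclasses.asdict(cfg)
    d["variant"] = cfg.variant.value
    d["generator"]["solute"] = [
        [list(map(float, p)), float(c), str(lab)] for p, c, lab in cfg.generator.solute
    ]
    return _plain(d)


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(_to_dict(cfg), sort_keys=False))


def load_config(path: str | Path) -> PipelineConfig:
    d = yaml.safe_load(Path(path).read_text())
    gen = d.pop("generator", {})
    gen["solute"] = [(tuple(p), c, lab) for p, c, lab in gen.get("solute", [])] \
        or list(GeneratorConfig().solute)
    exc = d.pop("excitation", {})
    for key in ("probe_point", "probe_axis", "state_offsets"):
        if key in exc:
            exc[key] = tuple(exc[key])
    grid = tuple(d.pop("grid", list(DEFAULT_GRID)))
    return PipelineConfig(
        generator=GeneratorConfig(**gen),
        excitation=MockExcitationModel(**exc),
        grid=grid,
        **d,
    )


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _solve_snapshot(snapshot: Snapshot, cfg: PipelineConfig):
    params = (
        PARAMETER_SETS[cfg.parameter_set]
        if isinstance(cfg.parameter_set, str)
        else cfg.parameter_set
    )
    topo = water_topology(snapshot.solvent_coords, params, cfg.variant)
    source = solute_point_source(
        [(p, c) for p, c, _ in _solute_rows(cfg, snapshot)], topo
    )
    sol = solve_embedding(topo, cfg.variant, source, cfg.kernel_form)
    return topo, source, sol


def _solute_rows(cfg: PipelineConfig, snapshot: Snapshot):
    charges = cfg.generator.solute_charges
    return [
        (snapshot.solute_coords[k], charges[k], cfg.generator.solute_labels[k])
        for k in range(len(charges))
    ]


def run_pipeline(cfg: PipelineConfig, workspace: str | Path) -> dict:
    """Execute all stages, write per-stage artifacts, return the report.

    Workspace layout: generate/, cut/, solve/, excite/, spectrum/, shift/
    with a manifest.json at the root.  Any stage failure is re-raised
    annotated with the stage name (and snapshot id where applicable).
    """
    ws = Path(workspace)
    ws.mkdir(parents=True, exist_ok=True)
    report: dict = {"seed": cfg.seed, "variant": cfg.variant.value,
                    "stages": {}, "files": {}}
    timings: dict[str, float] = {}

    def stage(name: str):
        d = ws / name
        d.mkdir(exist_ok=True)
        return d

    save_config(cfg, ws / "config.yaml")

    # --- generate -----------------------------------------------------
    t0 = time.perf_counter()
    try:
        snapshots = generate_snapshots(cfg.generator)
    except Exception as exc:
        raise RuntimeError(f"stage 'generate' failed: {exc}") from exc
    gen_dir = stage("generate")
    fileio.write_snapshots_xyz(snapshots, gen_dir / "snapshots.xyz")
    timings["generate"] = time.perf_counter() - t0
    log.info("generated %d snapshots (%d waters each)",
             len(snapshots), snapshots[0].n_waters)

    # --- cut ----------------------------------------------------------
    t0 = time.perf_counter()
    cut_dir = stage("cut")
    cut_snaps = []
    for snap in snapshots:
        try:
            cut = spherical_cut(snap, center=(0.0, 0.0, 0.0), radius=cfg.radius)
        except Exception as exc:
            raise RuntimeError(
                f"stage 'cut' failed on snapshot {snap.snapshot_id}: {exc}"
            ) from exc
        cut_snaps.append(cut)
        fileio.write_snapshot_pdb(cut, cut_dir / f"snapshot_{snap.snapshot_id:04d}.pdb")
    timings["cut"] = time.perf_counter() - t0

    # --- solve + excite ----------------------------------------------
    solve_dir = stage("solve")
    excite_dir = stage("excite")
    sticks = []
    energies = []
    t_solve = t_excite = 0.0
    for snap in cut_snaps:
        t0 = time.perf_counter()
        try:
            topo, source, sol = _solve_snapshot(snap, cfg)
        except Exception as exc:
            raise RuntimeError(
                f"stage 'solve' failed on snapshot {snap.snapshot_id}: {exc}"
            ) from exc
        log.debug("snapshot %d: solver residual %.2e", snap.snapshot_id, sol.residual)
        fileio.write_solution_csv(
            sol, topo, solve_dir / f"solution_{snap.snapshot_id:04d}.csv"
        )
        energies.append(interaction_energy(sol, source, cfg.variant))
        t_solve += time.perf_counter() - t0

        t0 = time.perf_counter()
        try:
            st = mock_excitations(snap, sol, cfg.excitation)
        except Exception as exc:
            raise RuntimeError(
                f"stage 'excite' failed on snapshot {snap.snapshot_id}: {exc}"
            ) from exc
        sticks.append(st)
        fileio.write_sticks_csv(
            [st], excite_dir / f"sticks_{snap.snapshot_id:04d}.csv"
        )
        t_excite += time.perf_counter() - t0
        log.info("snapshot %d done (E1 = %.3f eV)",
                 snap.snapshot_id, st.first_energy())
    timings["solve"] = t_solve
    timings["excite"] = t_excite
    fileio.write_json(
        {"interaction_energy_au": energies}, solve_dir / "energies.json"
    )

    # --- spectrum -----------------------------------------------------
    t0 = time.perf_counter()
    spec_dir = stage("spectrum")
    curves = [convolve_gaussian(s, cfg.fwhm, cfg.grid) for s in sticks]
    avg = ensemble_average(curves)
    if cfg.normalize and avg.intensity.max() > 0:
        avg = SpectrumCurve(avg.energies, avg.intensity / avg.intensity.max(),
                            avg.fwhm, avg.n_snapshots)
    fileio.write_sticks_csv(sticks, spec_dir / "all_sticks.csv")
    fileio.write_curve_csv(avg, spec_dir / "average.csv")
    timings["spectrum"] = time.perf_counter() - t0

    # --- shift --------------------------------------------------------
    shift_dir = stage("shift")
    window = cfg.first_band_window()
    e_solv = band_maximum(avg, window)
    shift = solvatochromic_shift(cfg.excitation.e0, e_solv)
    width = band_width(sticks)
    shift_report = {
        "e_vac_eV": shift.e_vac,
        "e_solv_eV": shift.e_solv,
        "delta_e_eV": shift.delta_e,
        "band_window_eV": list(window),
        "band_width_eV": width,
    }
    fileio.write_json(shift_report, shift_dir / "shift.json")

    report["stages"] = timings
    report.update(shift_report)
    report["n_snapshots"] = len(sticks)
    report["n_waters"] = cut_snaps[0].n_waters
    report["mean_interaction_energy_au"] = float(np.mean(energies))
    report["files"] = {
        str(p.relative_to(ws)): _sha256(p)
        for p in sorted(ws.rglob("*"))
        if p.is_file() and p.suffix in {".csv", ".json", ".xyz", ".pdb", ".yaml"}
    }
    fileio.write_json(report, ws / "manifest.json")
    return report


def compare_variants(
    configs: list[PipelineConfig], workspace: str | Path
) -> pd.DataFrame:
    """Run several variants on identical snapshots and tabulate the results.

    All configs must share the generator settings (same seed and snapshot
    count) so that the comparison isolates the solvent model.  Returns a
    table of variant, shift, band maximum and inhomogeneous band width,
    also written to ``comparison.csv``.
    """
    if not configs:
        raise ValueError("need at least one config")
    ref = configs[0].generator
    for c in configs[1:]:
        if (c.generator.seed != ref.seed
                or c.generator.n_snapshots != ref.n_snapshots):
            raise ValueError("configs must share the generator seed and snapshots")
    ws = Path(workspace)
    rows = []
    for k, cfg in enumerate(configs):
        rep = run_pipeline(cfg, ws / f"run_{k}_{cfg.variant.value}")
        rows.append(
            {
                "variant": cfg.variant.value,
                "parameter_set": (cfg.parameter_set
                                  if isinstance(cfg.parameter_set, str)
                                  else "custom"),
                "delta_e_eV": rep["delta_e_eV"],
                "band_max_eV": rep["e_solv_eV"],
                "band_width_eV": rep["band_width_eV"],
            }
        )
    table = pd.DataFrame(rows)
    table.to_csv(ws / "comparison.csv", index=False)
    return table
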