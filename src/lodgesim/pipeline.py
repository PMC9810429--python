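"""Seeded end-to-end runs: synth -> materials -> sweep -> render -> phenotype -> stats.

Each stage is a plain function writing text artifacts (CSV/JSON, PNG frames
for the render stage) into the run directory; :func:`run_pipeline` chains
them and writes a manifest with per-stage seeds, timings and SHA-256
checksums of every file, so identical configs and seeds produce identical
runs.  Stage seeds are derived from the master seed by a counter scheme, so
any stage can be re-run independently.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import units
from .micromech import build_crop_cards, card_to_dict
from .morphotypes import (
    CULTIVARS,
    crop_template,
    generate_morphology,
    generate_trial,
    morphology_to_dict,
    render_silhouette,
    trials_to_dataframe,
)
from .phenotypes import (
    EdgeProfile,
    bending_angle,
    fit_power_law,
    force_from_loadcell,
    lodging_resistance,
)
from .stats import fit_nested_anova, lsd_separation, pearson_matrix
from .stemfe import (
    NonConvergence,
    build_stem_model,
    extend_profile,
    limiting_wind_speed,
    simulate_load_unload,
)
from .windload import WindCase, build_loadset

__all__ = ["RunConfig", "run_pipeline", "stage_seed"]


@dataclass
class RunConfig:
    """Configuration of an end-to-end run."""

    seed: int = 1
    crops: tuple[str, ...] = ("oat", "wheat")
    threshold: float = 0.3
    grid_m_s: float = 0.5
    v_max_m_s: float = 16.0
    mesh_density: int = 8
    blocks: int = 3
    phenotype_speed_m_s: float = 8.0
    render_seconds: tuple[float, ...] = (25.0, 80.0, 135.0)
    out_dir: str = "runs/demo"
    render: bool = True

    def __post_init__(self) -> None:
        if not 0.0 < self.threshold < 1.0:
            raise ValueError("threshold must lie in (0, 1)")
        for crop in self.crops:
            crop_template(crop)  # validates the label

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        import yaml

        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("crops", "render_seconds"):
            if key in raw:
                raw[key] = tuple(raw[key])
        return cls(**raw)

    def to_yaml(self, path) -> None:
        import yaml

        d = dataclasses.asdict(self)
        d["crops"] = list(d["crops"])
        d["render_seconds"] = list(d["render_seconds"])
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=True)


def stage_seed(master: int, counter: int) -> int:
    """Per-stage seed derived from the master seed by a counter scheme."""
    return int((master * 100003 + counter * 7919 + 12345) % (2**31 - 1))


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _mean_plant(crop: str):
    return generate_morphology(crop_template(crop).replace(cv=0.0), 1, 0)[0]


# ---------------------------------------------------------------------------
# Stages
# ---------------------------------------------------------------------------

def stage_synth(config: RunConfig, out: Path, seed: int) -> list[Path]:
    records = generate_trial(
        {c: list(CULTIVARS[c]) for c in config.crops}, blocks=config.blocks, seed=seed
    )
    df = trials_to_dataframe(records)
    trials_csv = out / "trials.csv"
    df.to_csv(trials_csv, index=False)
    plants = {c: [morphology_to_dict(p) for p in
                  generate_morphology(c, n=config.blocks * 4, seed=seed + i)]
              for i, c in enumerate(config.crops)}
    morph_json = out / "morphologies.json"
    morph_json.write_text(json.dumps(plants, indent=1))
    return [trials_csv, morph_json]


def stage_materials(config: RunConfig, out: Path) -> list[Path]:
    paths = []
    for crop in config.crops:
        pith, shell = build_crop_cards(crop)
        for card in (pith, shell):
            p = out / f"material_card_{crop}_{card.region}.json"
            p.write_text(json.dumps(card_to_dict(card), indent=1))
            paths.append(p)
    return paths


def stage_sweep(config: RunConfig, out: Path) -> tuple[list[Path], dict]:
    paths, speeds = [], {}
    for crop in config.crops:
        pith, shell = build_crop_cards(crop)
        plant = _mean_plant(crop)
        res = limiting_wind_speed(
            plant, pith, shell, threshold=config.threshold, grid=config.grid_m_s,
            v_max=config.v_max_m_s, mesh_density=config.mesh_density,
        )
        curve_csv = out / f"sweep_{crop}.csv"
        np.savetxt(
            curve_csv, res.curve, delimiter=",", header="v_m_s,residual_ratio",
            comments="", fmt="%.6g",
        )
        paths.append(curve_csv)
        speeds[crop] = res.v_limit_m_s if res.reached else None
    sp = out / "limiting_speeds.json"
    sp.write_text(json.dumps({"threshold": config.threshold, "speeds_m_s": speeds},
                             indent=1))
    paths.append(sp)
    return paths, speeds


def stage_simulate(config: RunConfig, out: Path, speeds: dict) -> list[Path]:
    paths = []
    for crop in config.crops:
        v = speeds.get(crop) or config.phenotype_speed_m_s
        pith, shell = build_crop_cards(crop)
        plant = _mean_plant(crop)
        case = WindCase.from_m_s(v)
        model = build_stem_model(
            plant, pith, shell, mesh_density=config.mesh_density,
            loadset=build_loadset(plant, case),
        )
        res = simulate_load_unload(model, case)
        prof_csv = out / f"profiles_{crop}.csv"
        loaded, unloaded = res.deformed_profiles["loaded"], res.deformed_profiles["unloaded"]
        np.savetxt(
            prof_csv,
            np.column_stack([loaded, unloaded]),
            delimiter=",", comments="", fmt="%.6g",
            header="x_loaded,y_loaded,x_unloaded,y_unloaded",
        )
        summary = out / f"sim_{crop}.json"
        summary.write_text(json.dumps({
            "crop": crop, "v_m_s": v, "u_max_mm": res.u_max, "u_res_mm": res.u_res,
            "residual_ratio": res.u_res / res.u_max if res.u_max > 0 else 0.0,
            "energy": res.energy,
        }, indent=1))
        paths += [prof_csv, summary]
    return paths


def _simulated_full_profile(crop: str, plant, v_m_s: float, mesh_density: int):
    """Deformed full-plant centerline: modeled part + rigid upper extension."""
    pith, shell = build_crop_cards(crop)
    case = WindCase.from_m_s(v_m_s)
    model = build_stem_model(
        plant, pith, shell, mesh_density=mesh_density, loadset=build_loadset(plant, case)
    )
    res = simulate_load_unload(model, case, record_profiles=True)
    prof = res.deformed_profiles["loaded"]
    upper = plant.total_height - model.length
    return extend_profile(prof, upper), res


def _loading_profile(crop: str, plant, v_m_s: float, mesh_density: int):
    """Deformed full-plant centerline at peak load (no unloading step).

    Speeds beyond the collapse point fall back by halving until the loading
    branch converges — a rendered frame needs *a* deformed state, and past
    collapse the quasi-static model has none.
    """
    from .stemfe import solve_quasistatic

    pith, shell = build_crop_cards(crop)
    v = v_m_s
    for _ in range(6):
        case = WindCase.from_m_s(v)
        model = build_stem_model(
            plant, pith, shell, mesh_density=mesh_density,
            loadset=build_loadset(plant, case),
        )
        schedule = [(0.0, 0.0), (1.0, 0.0)] + [(1.0, lw) for lw in
                                               np.linspace(0.2, 1.0, 5)]
        try:
            d, _, _ = solve_quasistatic(model, schedule)
        except NonConvergence:
            v *= 0.5
            continue
        X = np.column_stack([np.zeros(model.n_nodes), model.node_y])
        prof = X + d.reshape(-1, 3)[:, :2]
        return extend_profile(prof, plant.total_height - model.length)
    raise NonConvergence(f"no renderable state near {v_m_s} m/s for {crop}")


def stage_render(config: RunConfig, out: Path, seed: int) -> list[Path]:
    import imageio.v3 as iio

    paths = []
    for crop in config.crops:
        plant = _mean_plant(crop)
        frames_meta = []
        for k, t in enumerate(config.render_seconds):
            from .windload import wind_protocol

            v = max(wind_protocol(t), 0.5)
            centerline = _loading_profile(crop, plant, v, config.mesh_density)
            # fit the field of view to the deformed centerline
            s_px, margin = 3.0, 16
            x_mm, y_mm = centerline[:, 0], centerline[:, 1]
            a_row = int(np.ceil(max(y_mm.max(), 0) / s_px)) + margin
            a_col = int(np.ceil(max(-x_mm.min(), 0) / s_px)) + margin
            h_px = a_row + int(np.ceil(max(-y_mm.min(), 0) / s_px)) + margin
            w_px = a_col + int(np.ceil(max(x_mm.max(), 0) / s_px)) + margin
            frame = render_silhouette(
                centerline, image_size=(h_px + 1, w_px + 1), mm_per_pixel=s_px,
                noise_sd=0.5, seed=stage_seed(seed, k), stem_width_mm=9.0,
                anchor_rc=(a_row, a_col), timestamp=t,
            )
            png = out / f"frame_{crop}_{int(t):03d}s.png"
            iio.imwrite(png, (frame.image * 255).astype(np.uint8))
            frames_meta.append({"file": png.name, **frame.sidecar()})
            paths.append(png)
        sidecar = out / f"frames_{crop}.json"
        sidecar.write_text(json.dumps(frames_meta, indent=1))
        paths.append(sidecar)
    return paths


def stage_phenotype(config: RunConfig, out: Path, seed: int) -> list[Path]:
    """Per-record bending phenotypes from per-plant simulations.

    Each trial record gets its own sampled morphology and a bending
    simulation at the phenotype speed; theta, (c, d) and CL_r come from the
    power-law fit of the deformed full-plant centerline (the fast geometric
    path — the imaging path is exercised by the render stage and its tests).
    """
    records = generate_trial(
        {c: list(CULTIVARS[c]) for c in config.crops}, blocks=config.blocks, seed=seed
    )
    rows = []
    for i, rec in enumerate(records):
        tpl = crop_template(rec.crop)
        plant = generate_morphology(tpl, 1, seed=stage_seed(seed, 100 + i))[0]
        try:
            centerline, res = _simulated_full_profile(
                rec.crop, plant, config.phenotype_speed_m_s, config.mesh_density
            )
        except NonConvergence:
            continue
        profile = EdgeProfile(points=centerline)
        fit = fit_power_law(profile)
        h = plant.total_height
        theta = bending_angle(fit, h)
        f_s = units.un_from_n(rec.plant_strength_n)
        f_w = force_from_loadcell(f_s, theta, h, fit=fit)
        cl_r, cl_def = lodging_resistance(fit, h)
        rows.append({
            "crop": rec.crop, "cultivar": rec.cultivar, "block": rec.block,
            "heading_days": rec.heading_days,
            "plant_strength_n": rec.plant_strength_n,
            "height_cm": rec.height_cm, "biomass_g": rec.biomass_g,
            "theta_deg": theta, "c": fit.c, "d": fit.d,
            "cl_r": cl_r, "cl_r_definition": cl_def,
            "f_w_n": units.n_from_un(f_w),
            "u_res_mm": res.u_res, "u_max_mm": res.u_max,
        })
    import pandas as pd

    df = pd.DataFrame(rows)
    path = out / "phenotypes.csv"
    df.to_csv(path, index=False)
    return [path]


def stage_stats(config: RunConfig, out: Path) -> list[Path]:
    import pandas as pd

    df = pd.read_csv(out / "phenotypes.csv")
    paths = []
    tables = {}
    for response in ("theta_deg", "d", "cl_r", "plant_strength_n"):
        res = fit_nested_anova(df, response)
        tables[response] = res.anova_table
        sep = lsd_separation(res)
        p = out / f"anova_{response}.csv"
        res.anova_table.to_csv(p)
        paths.append(p)
        p2 = out / f"lsd_{response}.csv"
        sep.to_csv(p2)
        paths.append(p2)
    cult = df.groupby("cultivar").mean(numeric_only=True).reset_index()
    variables = ["theta_deg", "d", "cl_r", "plant_strength_n", "height_cm", "biomass_g"]
    r, stars = pearson_matrix(cult, variables)
    p3 = out / "correlations.csv"
    r.round(4).to_csv(p3)
    p4 = out / "correlation_stars.csv"
    stars.to_csv(p4)
    paths += [p3, p4]
    return paths


# ---------------------------------------------------------------------------
# Orchestration
# ---------------------------------------------------------------------------

def run_pipeline(config: RunConfig) -> dict:
    """Run every stage; return (and write) the run manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": dataclasses.asdict(config),
        "stages": {},
        "files": {},
    }
    written: list[Path] = []

    def run_stage(name, fn, *args):
        t0 = time.perf_counter()
        try:
            result = fn(*args)
        except Exception as exc:
            manifest["stages"][name] = {"status": "failed", "error": str(exc)}
            (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
            raise RuntimeError(
                f"pipeline stage {name!r} failed: {exc}; last valid artifacts: "
                f"{[p.name for p in written[-3:]]}"
            ) from exc
        dt = time.perf_counter() - t0
        paths = result[0] if isinstance(result, tuple) else result
        written.extend(paths)
        manifest["stages"][name] = {
            "status": "ok", "seconds": round(dt, 3),
            "files": [p.name for p in paths],
        }
        return result

    s = config.seed
    run_stage("synth", stage_synth, config, out, stage_seed(s, 1))
    run_stage("materials", stage_materials, config, out)
    _, speeds = run_stage("sweep", stage_sweep, config, out)
    manifest["limiting_speeds_m_s"] = speeds
    run_stage("simulate", stage_simulate, config, out, speeds)
    if config.render:
        run_stage("render", stage_render, config, out, stage_seed(s, 2))
    run_stage("phenotype", stage_phenotype, config, out, stage_seed(s, 1))
    run_stage("stats", stage_stats, config, out)

    for p in written:
        manifest["files"][p.name] = _sha256(p)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest
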