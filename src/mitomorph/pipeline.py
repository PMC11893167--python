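"""Run the full analysis — classify, cluster, patches, polysomes — over many
tomograms from one configuration, and aggregate study-level statistics.

Statistics are per-tomogram first (one interval maximum, one overlap
fraction, one histogram peak per tomogram and class), then compared across
tomograms with Mann-Whitney U tests; particles are never pooled across
tomograms.  Every threshold in force, every seed, and a manifest of
completed stages are recorded next to the outputs, and the summary JSON is
byte-reproducible for a fixed seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import clustering, patches as patches_mod, polysomes as poly_mod
from .config import RunConfig
from .context import compute_context, summarize_classes
from .geometry import BodyFrameOffsets
from .io import particle_positions, read_particles, read_surface, write_context_records
from .synthetic import decorate_particles, make_mitochondrion

logger = logging.getLogger(__name__)

NM = 10.0


def _load_tomogram(entry: dict, run: RunConfig, seed: int):
    """One tomogram's (particles, omm, imm) from files or the synthetic generator."""
    if "particles_star" in entry:
        particles = read_particles(entry["particles_star"], entry.get("pixel_size", 1.0))
        omm = read_surface(entry["omm_stl"], entry.get("omm_sidecar"),
                           surface_id="OMM", tomogram_id=entry["tomogram_id"])
        imm = read_surface(entry["imm_stl"], entry.get("imm_sidecar"),
                           surface_id="IMM", tomogram_id=entry["tomogram_id"])
        return particles, omm, imm
    scene = dict(entry.get("scene", {}))
    omm, imm, _ = make_mitochondrion(
        radius=scene.get("radius", 3000.0),
        spacing=scene.get("spacing", 135.0),
        n_cj_wells=scene.get("n_cj_wells", 3),
        subdivisions=scene.get("subdivisions", 5),
        seed=seed,
    )
    particles, _ = decorate_particles(
        omm,
        n=scene.get("n_particles", 300),
        import_fraction=scene.get("import_fraction", 0.4),
        mode=scene.get("mode", "csr"),
        cluster_scale=scene.get("cluster_scale", 35.0),
        tomogram_id=entry["tomogram_id"],
        seed=seed + 1,
    )
    return particles, omm, imm


def run_all(config, out_dir=None) -> dict:
    """Execute all stages per tomogram and write the report bundle.

    ``config`` is a dict or a path to a JSON file with keys:

    ``run``        RunConfig fields (all optional);
    ``tomograms``  list of per-tomogram entries — either file inputs
                   (``particles_star``/``pixel_size``/``omm_stl``/``imm_stl``)
                   or a ``scene`` block for the synthetic generator;
    ``seed``       master seed (overrides run.seed).

    Returns the summary dict; when ``out_dir`` (or config["out_dir"]) is set,
    writes per-tomogram CSVs, the summary JSON, a stage manifest and a log of
    thresholds in force.
    """
    if not isinstance(config, dict):
        config = json.loads(Path(config).read_text())
    run = RunConfig(**config.get("run", {}))
    seed = int(config.get("seed", run.seed))
    offsets = BodyFrameOffsets.default()
    out = Path(out_dir or config.get("out_dir", ".")) if (out_dir or config.get("out_dir")) else None
    if out:
        out.mkdir(parents=True, exist_ok=True)

    manifest = []
    per_tomo = []
    kcurve_frames = []
    chains_tables = []

    for t_idx, entry in enumerate(config["tomograms"]):
        tomo_id = entry.get("tomogram_id", f"tomo_{t_idx:03d}")
        entry = {**entry, "tomogram_id": tomo_id}
        t_seed = seed + 1000 * (t_idx + 1)
        particles, omm, imm = _load_tomogram(entry, run, t_seed)

        # --- stage 1: classification
        records = compute_context(particles, omm, offsets, run)
        summary = summarize_classes(records)
        if out:
            write_context_records(records, out / f"{tomo_id}_context.csv")
        manifest.append(f"{tomo_id}:classify")

        imp = records["orientation_class"] == "import_oriented"
        non = records["orientation_class"] == "proximal_non_import"
        pos = particle_positions(particles)

        # --- stage 2: clustering per class
        interval = {}
        for label, mask in (("import", imp), ("non_import", non)):
            if mask.sum() >= 2:
                curve = clustering.compute_k_curve(
                    pos[mask.to_numpy()], omm, run, seed=t_seed + 7,
                    standoff=135.0, tomogram_id=tomo_id, class_label=label,
                )
                kcurve_frames.append(curve)
                interval[label] = clustering.interval_max_at(curve, 30.0, 40.0)
            else:
                interval[label] = float("nan")
        manifest.append(f"{tomo_id}:cluster")

        # --- stages 3-4: patches, crista overlap, OMM-IMM distances
        seeds = records.loc[imp, "nearest_triangle_id"].to_numpy()
        obs = patches_mod.build_patches(seeds, omm, run.patch_radius)
        field = patches_mod.intermembrane_distance(omm, imm, method="nearest-point")
        hists = patches_mod.patch_distance_histograms(field, obs, run.histogram_bins)
        peaks = {
            "co_translation": hists["patch"]["peak"],
            "non_co_translation": hists["complement"]["peak"],
            "all_membrane": hists["all"]["peak"],
            "randomized": float("nan"),
        }
        overlaps = {"import": float("nan"), "non_import": float("nan"),
                    "randomized": float("nan")}
        crista = patches_mod.crista_associated_omm(omm, imm, run)
        overlaps["import"] = patches_mod.overlap_fraction(obs, crista, omm)
        non_seeds = records.loc[non, "nearest_triangle_id"].to_numpy()
        if non_seeds.size:
            non_obs = patches_mod.build_patches(non_seeds, omm, run.patch_radius)
            overlaps["non_import"] = patches_mod.overlap_fraction(non_obs, crista, omm)
        if len(obs.seed_ids):
            rand = patches_mod.randomize_patches(obs, omm, seed=t_seed + 13)
            rhists = patches_mod.patch_distance_histograms(field, rand, run.histogram_bins)
            peaks["randomized"] = rhists["patch"]["peak"]
            overlaps["randomized"] = patches_mod.overlap_fraction(rand, crista, omm)
        manifest.append(f"{tomo_id}:patches")

        # --- stage 5: polysomes among import-oriented particles
        chains = poly_mod.detect_chains(particles[imp.to_numpy()].reset_index(drop=True),
                                        offsets, run)
        table, chain_summary = poly_mod.chain_report(chains)
        table["tomogram_id"] = tomo_id
        chains_tables.append(table)
        manifest.append(f"{tomo_id}:polysomes")

        per_tomo.append({
            "tomogram_id": tomo_id,
            "classes": summary,
            "interval_max_30_40": interval,
            "peaks": peaks,
            "overlap_fractions": overlaps,
            "polysomes": chain_summary,
        })

    # --- study-level aggregation
    def collect(key, sub):
        vals = [t[key][sub] for t in per_tomo]
        return [v for v in vals if np.isfinite(v)]

    def mw(a, b):
        if len(a) >= 1 and len(b) >= 1:
            r = clustering.mann_whitney_u(a, b)
            return {"U": r["U"], "p_two_sided": r["p_two_sided"]}
        return None

    study = {
        "n_tomograms": len(per_tomo),
        "pooled_classes": {
            c: int(sum(t["classes"]["counts"][c] for t in per_tomo))
            for c in ("import_oriented", "proximal_non_import", "background")
        },
        "interval_max_import_vs_non": mw(collect("interval_max_30_40", "import"),
                                         collect("interval_max_30_40", "non_import")),
        "peaks_co_vs_non": mw(collect("peaks", "co_translation"),
                              collect("peaks", "non_co_translation")),
        "peaks_randomized_vs_all": mw(collect("peaks", "randomized"),
                                      collect("peaks", "all_membrane")),
        "overlap_import_vs_non": mw(collect("overlap_fractions", "import"),
                                    collect("overlap_fractions", "non_import")),
        "overlap_import_vs_randomized": mw(collect("overlap_fractions", "import"),
                                           collect("overlap_fractions", "randomized")),
    }
    n_imp = study["pooled_classes"]["import_oriented"]
    n_near = n_imp + study["pooled_classes"]["proximal_non_import"]
    study["pooled_import_fraction"] = (n_imp / n_near) if n_near else None

    all_chains = pd.concat(chains_tables, ignore_index=True) if chains_tables else pd.DataFrame()
    study["polysomes"] = {
        "n_chains": int(len(all_chains)),
        "end_to_end_range": (
            [float(all_chains["end_to_end"].min()), float(all_chains["end_to_end"].max())]
            if len(all_chains) else None
        ),
    }

    report = {
        "config": {"run": asdict(run), "seed": seed},
        "per_tomogram": per_tomo,
        "study": study,
    }
    if out:
        (out / "summary.json").write_text(json.dumps(report, indent=2, sort_keys=True,
                                                     default=_json_safe) + "\n")
        (out / "manifest.txt").write_text("\n".join(manifest) + "\n")
        if kcurve_frames:
            pd.concat(kcurve_frames, ignore_index=True).to_csv(out / "k_curves.csv", index=False)
        if len(all_chains):
            all_chains.to_csv(out / "polysome_chains.csv", index=False)
        (out / "thresholds.log").write_text(
            "\n".join(f"{k} = {v}" for k, v in asdict(run).items()) + "\n")
    return report


def _json_safe(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    raise TypeError(f"not JSON serializable: {type(obj)}")
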