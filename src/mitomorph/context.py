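"""Stage 1: membrane context of each ribosome, and its orientation class.

For every particle the stage records the center-to-OMM distance, the nearest
OMM triangle, the angles between each rotated body axis and that triangle's
normal, and the distance from the peptide exit tunnel to the OMM.  A particle
is *import-oriented* when the exit tunnel is within the exit cutoff (95 A
default) of the membrane, *proximal-non-import* when only its center is
within the proximity cutoff (250 A), and *background* otherwise.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import RunConfig
from .geometry import BodyFrameOffsets, euler_to_matrix
from .io import particle_angles, particle_positions
from .surfaces import TriangleSurface, nearest_triangle

logger = logging.getLogger(__name__)

CLASSES = ("import_oriented", "proximal_non_import", "background")


def compute_context(
    particles: pd.DataFrame,
    omm: TriangleSurface,
    offsets: BodyFrameOffsets | None = None,
    cfg: RunConfig | None = None,
) -> pd.DataFrame:
    """Per-ribosome context records against an OMM surface.

    Returns a DataFrame with columns ``particle_id, center_to_omm, angle_x,
    angle_y, angle_z, nearest_triangle_id, exit_to_omm, orientation_class``
    (plus ``tomogram_id`` and ``truth_label`` passed through when present).
    """
    offsets = offsets or BodyFrameOffsets.default()
    cfg = cfg or RunConfig()
    if len(particles) == 0:
        return pd.DataFrame(columns=[
            "particle_id", "center_to_omm", "angle_x", "angle_y", "angle_z",
            "nearest_triangle_id", "exit_to_omm", "orientation_class",
        ])

    centers = particle_positions(particles)
    angles = particle_angles(particles)

    span = omm.vertices.max(axis=0) - omm.vertices.min(axis=0)
    if np.min(np.linalg.norm(centers - omm.centroids.mean(axis=0), axis=1)) > 10 * np.linalg.norm(span):
        logger.warning("all particles are >10x the mesh bounding box away; frame mismatch?")

    ids, center_dist = nearest_triangle(centers, omm)
    normals = omm.normals[ids]

    R = euler_to_matrix(angles)  # (n, 3, 3); columns are rotated body axes
    body_axis_angles = {}
    for k, name in enumerate(("angle_x", "angle_y", "angle_z")):
        dot = np.abs(np.einsum("ni,ni->n", R[:, :, k], normals))
        body_axis_angles[name] = np.degrees(np.arccos(np.clip(dot, 0.0, 1.0)))

    exit_points = centers + np.einsum("nij,j->ni", R, offsets.exit_tunnel)
    _, exit_dist = nearest_triangle(exit_points, omm)

    cls = np.where(
        exit_dist <= cfg.exit_cutoff,
        "import_oriented",
        np.where(center_dist <= cfg.proximity_cutoff, "proximal_non_import", "background"),
    )

    out = pd.DataFrame(
        {
            "particle_id": np.arange(len(particles)),
            "center_to_omm": center_dist,
            **body_axis_angles,
            "nearest_triangle_id": ids,
            "exit_to_omm": exit_dist,
            "orientation_class": cls,
        }
    )
    for passthrough in ("tomogram_id", "truth_label"):
        if passthrough in particles.columns:
            out[passthrough] = particles[passthrough].to_numpy()
    return out


def summarize_classes(records: pd.DataFrame) -> dict:
    """Class counts and the import fraction among membrane-proximal particles.

    The import fraction is n_import / (n_import + n_proximal_non_import);
    ``None`` (undefined) when that denominator is zero.
    """
    counts = {c: int((records["orientation_class"] == c).sum()) for c in CLASSES}
    denom = counts["import_oriented"] + counts["proximal_non_import"]
    frac = counts["import_oriented"] / denom if denom else None
    return {"counts": counts, "import_fraction": frac, "n_total": int(len(records))}


def import_fraction_percent(n_import: int, n_near: int) -> float:
    """Printed-style percentage of import-oriented among near-membrane ribosomes."""
    if n_near <= 0:
        raise ValueError("n_near must be positive")
    return 100.0 * n_import / n_near


def estimate_import_fraction(records: pd.DataFrame, chance_rate: float) -> float:
    """Chance-corrected planted-fraction estimate.

    A randomly oriented membrane-proximal particle passes the exit rule with
    probability ``chance_rate`` (see ``synthetic.chance_import_rate``), so the
    raw import rate at planted fraction f has expectation
    f + (1 - f) * chance_rate; this inverts that relation, clipped to [0, 1].
    """
    if not 0 <= chance_rate < 1:
        raise ValueError("chance_rate must be in [0, 1)")
    summary = summarize_classes(records)
    if summary["import_fraction"] is None:
        return float("nan")
    return float(np.clip((summary["import_fraction"] - chance_rate) / (1 - chance_rate), 0.0, 1.0))


def sweep_exit_cutoff(records: pd.DataFrame, cutoffs, proximity_cutoff: float = 250.0) -> pd.DataFrame:
    """Class counts as a function of the exit cutoff (0-120 A exploration).

    Reclassifies the recorded distances at each cutoff so the visual
    calibration of the import threshold can be reproduced numerically.
    """
    rows = []
    for c in cutoffs:
        imp = records["exit_to_omm"] <= c
        prox = ~imp & (records["center_to_omm"] <= proximity_cutoff)
        rows.append({
            "exit_cutoff": float(c),
            "import_oriented": int(imp.sum()),
            "proximal_non_import": int(prox.sum()),
            "background": int((~imp & ~prox).sum()),
        })
    return pd.DataFrame(rows)
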