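"""Stage 5: polysome chain detection among import-oriented ribosomes.

Two ribosomes are candidate mRNA neighbors when (1) their centers are within
30 nm and (2) the 3' mRNA entry of one sits next to the 5' mRNA exit of the
other (entry-to-exit distance below the adjacency cutoff, 60 A default — the
published criterion was applied by eye and prints no number).  Because an
mRNA threads singly through each ribosome, every particle gets at most one
inbound and one outbound link, resolved greedily by smallest adjacency
distance; chains are the maximal simple paths of two or more members.

A chain is ordered 5'->3': the head's 5' mRNA exit and the tail's 3' mRNA
entry are the free ends, and the end-to-end distance is the straight line
between them.  The path length additionally follows the zig-zag through
every intra-ribosome span and inter-ribosome gap, so end_to_end <=
path_length always.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .config import RunConfig
from .geometry import BodyFrameOffsets, euler_to_matrix
from .io import particle_angles, particle_positions

logger = logging.getLogger(__name__)

NM = 10.0


def _site_positions(particles: pd.DataFrame, offsets: BodyFrameOffsets):
    centers = particle_positions(particles)
    R = euler_to_matrix(particle_angles(particles))
    entry = centers + np.einsum("nij,j->ni", R, offsets.mrna_entry)
    exit_ = centers + np.einsum("nij,j->ni", R, offsets.mrna_exit)
    return centers, entry, exit_


def detect_chains(
    particles: pd.DataFrame,
    offsets: BodyFrameOffsets | None = None,
    cfg: RunConfig | None = None,
) -> list[dict]:
    """Detect putative polysome chains among (import-oriented) particles.

    Returns a list of chains, each a dict with ``members`` (particle row
    indexes ordered 5'->3'), ``end_to_end`` and ``path_length`` in A.
    Deterministic: ties cannot survive the strict ordering by (distance,
    source id, target id).
    """
    offsets = offsets or BodyFrameOffsets.default()
    cfg = cfg or RunConfig()
    n = len(particles)
    if n < 2:
        return []
    centers, entry, exit_ = _site_positions(particles, offsets)

    neighbor_cut = cfg.polysome_neighbor * NM
    # candidate links i -> j: entry_i adjacent to exit_j
    diff_c = np.linalg.norm(centers[:, None] - centers[None, :], axis=2)
    adj = np.linalg.norm(entry[:, None] - exit_[None, :], axis=2)
    cand = (diff_c <= neighbor_cut) & (adj <= cfg.adjacency_cutoff)
    np.fill_diagonal(cand, False)

    links = sorted(
        ((adj[i, j], i, j) for i, j in zip(*np.nonzero(cand))),
        key=lambda t: (t[0], t[1], t[2]),
    )
    out_link: dict[int, int] = {}
    in_link: dict[int, int] = {}
    link_dist: dict[tuple[int, int], float] = {}
    for d, i, j in links:
        if i in out_link or j in in_link:
            continue
        out_link[i] = j
        in_link[j] = i
        link_dist[(i, j)] = d

    # break cycles at their weakest (largest-distance) link
    visited: set[int] = set()
    for start in sorted(out_link):
        if start in visited:
            continue
        path = []
        node = start
        on_path: set[int] = set()
        while node in out_link and node not in on_path and node not in visited:
            on_path.add(node)
            path.append(node)
            node = out_link[node]
        if node in on_path:  # found a cycle
            cyc = path[path.index(node):] + [node]
            worst = max(zip(cyc[:-1], cyc[1:]), key=lambda e: link_dist[e])
            logger.info("breaking polysome cycle at link %s (%.1f A)", worst, link_dist[worst])
            del in_link[worst[1]]
            del out_link[worst[0]]
        visited |= on_path

    heads = [i for i in out_link if i not in in_link]
    chains = []
    for head in sorted(heads):
        members = [head]
        node = head
        while node in out_link:
            node = out_link[node]
            members.append(node)
        if len(members) < 2:
            continue
        # 5' free end: exit of the head; 3' free end: entry of the tail
        end_to_end = float(np.linalg.norm(exit_[members[0]] - entry[members[-1]]))
        spans = sum(float(np.linalg.norm(entry[m] - exit_[m])) for m in members)
        gaps = sum(
            float(np.linalg.norm(entry[a] - exit_[b]))
            for a, b in zip(members[:-1], members[1:])
        )
        chains.append({
            "members": members,
            "end_to_end": end_to_end,
            "path_length": spans + gaps,
            "tomogram_id": str(particles["tomogram_id"].iloc[head])
            if "tomogram_id" in particles.columns else "tomo",
        })
    return chains


def chain_report(chains: list[dict]) -> tuple[pd.DataFrame, dict]:
    """Tabulate chains and summarize end-to-end distances.

    Returns ``(table, summary)``; the summary's min/max/median are NaN
    (flagged undefined) for an empty chain list.
    """
    rows = [
        {
            "chain_id": k,
            "length": len(c["members"]),
            "end_to_end": c["end_to_end"],
            "path_length": c["path_length"],
            "tomogram_id": c.get("tomogram_id", "tomo"),
            "members": ";".join(str(m) for m in c["members"]),
        }
        for k, c in enumerate(chains)
    ]
    table = pd.DataFrame(rows, columns=[
        "chain_id", "length", "end_to_end", "path_length", "tomogram_id", "members",
    ])
    if len(table):
        e = table["end_to_end"]
        summary = {"n_chains": int(len(table)),
                   "end_to_end_min": float(e.min()),
                   "end_to_end_max": float(e.max()),
                   "end_to_end_median": float(e.median())}
    else:
        summary = {"n_chains": 0, "end_to_end_min": float("nan"),
                   "end_to_end_max": float("nan"), "end_to_end_median": float("nan")}
    return table, summary
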