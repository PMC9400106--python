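"""End-to-end orchestration: bank -> rotated feature table -> clusters.

The rotation stage recomputes every type's populations in all local
coordinate systems of its group, producing one feature row per
(atom type, frame) — the analogue of blowing a bank of N types up to the
sum over groups of (types x frames) rotated entries.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

from .bank import AtomTypeEntry
from .clustering import (FEATURE_COLUMNS, ClusteringConfig,
                         assignments_frame, cluster_report,
                         multilevel_cluster, plm_column)
from .frames import (enumerate_frames, parse_frame_name, realize_frame,
                     recompute_type_in_frames, rotate_plm, rotate_plm_sd,
                     FrameError)
from .harmonics import lm_indices

logger = logging.getLogger(__name__)

ROTATED_LMAX = 3


def census(entries) -> pd.DataFrame:
    """Per-group tally: atom types, coordinate systems, and their product
    (the number of rotated entries the group contributes)."""
    counts: dict[str, int] = {}
    for e in entries:
        counts[e.topology.group_label] = counts.get(
            e.topology.group_label, 0) + 1
    rows = []
    for group in sorted(counts):
        n_frames = len(enumerate_frames(group))
        rows.append({"group": group, "n_types": counts[group],
                     "n_frames": n_frames,
                     "total": counts[group] * n_frames})
    df = pd.DataFrame(rows)
    df.attrs["grand_total"] = int(df["total"].sum()) if rows else 0
    return df


def _row(entry: AtomTypeEntry, frame, mean_p_lm, inconsistent, max_sd):
    row = {
        "entry": entry.name,
        "frame": frame.name,
        "family": frame.family,
        "element": entry.topology.central_element,
        "group": entry.topology.group_label,
        "kappa": entry.params.kappa,
        "p_val": entry.params.p_val,
        "kappa_prime": entry.params.kappa_prime,
        "inconsistent": bool(inconsistent),
        "max_plm_sd": float(max_sd),
    }
    for l, m in lm_indices(ROTATED_LMAX):
        if l > 0:
            row[plm_column(l, m)] = float(mean_p_lm.get((l, m), 0.0))
    return row


def rotate_bank(entries, members_by_name: dict) -> pd.DataFrame:
    """Recompute every entry in all frames of its group from member atoms.

    kappa, Pval and kappa' are frame-invariant and copied through; the Plm
    means and sample sds are recomputed per frame, and the inconsistent flag
    is set per row when any Plm sd exceeds 0.05 e.
    """
    rows = []
    for entry in entries:
        frames = enumerate_frames(entry.topology.group_label)
        stats = recompute_type_in_frames(members_by_name[entry.name], frames,
                                         lmax=ROTATED_LMAX)
        for frame in frames:
            if frame.name not in stats:
                logger.warning("entry %s: frame %s unrealizable; row skipped",
                               entry.name, frame.name)
                continue
            st = stats[frame.name]
            rows.append(_row(entry, frame, st.mean_p_lm, st.inconsistent,
                             max(st.sd_p_lm.values(), default=0.0)))
    return pd.DataFrame(rows)


def rotate_bank_idealized(entries) -> pd.DataFrame:
    """Frame recomputation directly from stored bank parameters.

    Without member atoms the stored mean populations are rotated on the
    idealized geometry of each group (sds propagated through the squared
    rotation blocks); this is the fallback path for an external bank file.
    """
    from .synthetic import ideal_geometry
    rows = []
    for entry in entries:
        group = entry.topology.group_label
        geo = ideal_geometry(group, _default_hybridization(group))
        positions = {lab: 1.5 * b for lab, b in zip("abcdef", geo.bonds)}
        distant = list(geo.distants) or None
        source = parse_frame_name(entry.frame)
        m0 = realize_frame(source, np.zeros(3), positions, distant).rotation
        for frame in enumerate_frames(group):
            try:
                m1 = realize_frame(frame, np.zeros(3), positions,
                                   distant).rotation
            except FrameError as exc:
                logger.warning("entry %s: frame %s unrealizable (%s)",
                               entry.name, frame.name, exc)
                continue
            rel = m1 @ m0.T
            mean = rotate_plm(entry.params.p_lm, rel, ROTATED_LMAX)
            sd = rotate_plm_sd(entry.params.sd_p_lm, rel, ROTATED_LMAX)
            max_sd = max(sd.values(), default=0.0)
            rows.append(_row(entry, frame, mean, max_sd > 0.05, max_sd))
    return pd.DataFrame(rows)


def _default_hybridization(group: str) -> str:
    return {"1x": "sp1", "1p": "sp2", "2x": "sp1", "2p": "sp3",
            "3p": "sp2", "3n": "sp3", "4n": "sp3", "6n": "sp3"}[group]


def cluster_rotated(table: pd.DataFrame, config: ClusteringConfig):
    """Multi-level clustering of a rotated feature table.

    Returns (labels, eps log, assignments table, per-cluster report).
    """
    missing = [c for c in FEATURE_COLUMNS if c not in table.columns]
    if missing:
        raise ValueError(f"rotated table lacks feature columns {missing}")
    labels, eps_log = multilevel_cluster(table, config)
    assignments = assignments_frame(table, labels, eps_log)
    report = cluster_report(table, labels)
    return labels, eps_log, assignments, report


def labels_by_entry(table: pd.DataFrame, labels) -> dict[str, dict[str, str]]:
    """entry name -> {frame name -> label path} for tree overlays."""
    out: dict[str, dict[str, str]] = {}
    for (_, row), lab in zip(table.iterrows(), labels):
        out.setdefault(row["entry"], {})[row["frame"]] = str(lab)
    return out


def cluster_sizes(labels) -> dict[str, int]:
    sizes: dict[str, int] = {}
    for lab in labels:
        key = str(lab)
        sizes[key] = sizes.get(key, 0) + 1
    return sizes
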