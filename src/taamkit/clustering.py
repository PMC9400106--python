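"""Multi-level DBSCAN of multipole parameters.

Each row of the feature matrix is one (atom type, local coordinate system)
entry described by 18 dimensions: kappa, Pval, kappa' and the fifteen
dipole-to-octupole populations.  Hexadecapoles are supported by the model
but never enter the clustering features.

Distances can be computed on the original parameters or after a subtraction
(kappa-1, kappa'-1, Pval minus the formal valence-electron count) and/or a
column-wise L2 normalization.  The Eps radius is taken from a replayable
schedule or estimated by the knee of the sorted k-nearest-neighbor distance
curve.  Clusters whose *original-scale* Plm sample standard deviations
exceed 0.05 e are re-clustered with a fresh (smaller) Eps, down to four
levels by default; labels accumulate into underscore-joined paths with the
DBSCAN noise sentinel -1 terminating a path.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cluster import DBSCAN
from sklearn.neighbors import NearestNeighbors

from .bank import VALENCE_ELECTRONS
from .harmonics import lm_indices

logger = logging.getLogger(__name__)

#: clustering acts on dipoles..octupoles only
FEATURE_LMAX = 3


def plm_column(l: int, m: int) -> str:
    return f"P{l}{m}"


PLM_COLUMNS = [plm_column(l, m) for l, m in lm_indices(FEATURE_LMAX) if l > 0]
FEATURE_COLUMNS = ["kappa", "p_val", "kappa_prime"] + PLM_COLUMNS

TRANSFORM_MODES = ("original", "subtract", "normalize", "subtract_normalize")


class ClusteringError(ValueError):
    pass


class DegenerateEpsError(ClusteringError):
    """k-distance curve carries no information (too few distinct points)."""


@dataclass(frozen=True)
class ClusterLabelPath:
    """Underscore-joined multi-level cluster label, e.g. ``10_0_16_3``;
    the outlier sentinel -1 terminates a path."""

    levels: tuple[int, ...]

    def __post_init__(self):
        if not self.levels:
            raise ClusteringError("empty label path")
        for lab in self.levels[:-1]:
            if lab == -1:
                raise ClusteringError("-1 may only terminate a path")

    def __str__(self) -> str:
        return "_".join(str(v) for v in self.levels)

    @property
    def is_outlier(self) -> bool:
        return self.levels[-1] == -1

    @classmethod
    def parse(cls, text: str) -> "ClusterLabelPath":
        try:
            return cls(tuple(int(t) for t in text.split("_")))
        except ValueError as exc:
            raise ClusteringError(f"bad label path {text!r}") from exc


@dataclass
class ClusteringConfig:
    min_pts: int = 2
    eps: float | None = None                 # manual level-1 Eps
    max_levels: int = 4
    sd_threshold: float = 0.05               # electrons, Plm columns only
    eps_schedule: dict[str, float] = field(default_factory=dict)
    transform: str = "original"
    scale: float = 1.0

    def validate(self) -> None:
        if self.min_pts < 1:
            raise ClusteringError("min_pts must be >= 1")
        if self.eps is not None and self.eps <= 0:
            raise ClusteringError("manual eps must be positive")
        if self.max_levels < 1:
            raise ClusteringError("max_levels must be >= 1")
        if self.transform not in TRANSFORM_MODES:
            raise ClusteringError(f"unknown transform {self.transform!r}")


def transform(matrix: pd.DataFrame, mode: str, elements=None,
              scale: float = 1.0) -> pd.DataFrame:
    """Apply the subtraction and/or L2-normalization transforms.

    Subtraction: kappa -> kappa-1, kappa' -> kappa'-1, Pval -> Pval minus the
    formal valence-electron count of the row's element; Plm unchanged.
    Normalization: each column divided by its L2 norm over all rows.  Modes
    compose (subtract first); a uniform scale factor is applied last.
    """
    if mode not in TRANSFORM_MODES:
        raise ClusteringError(f"unknown transform mode {mode!r}")
    out = matrix[FEATURE_COLUMNS].astype(float).copy()
    if mode in ("subtract", "subtract_normalize"):
        if elements is None:
            if "element" not in matrix.columns:
                raise ClusteringError(
                    "subtraction needs the element of every row")
            elements = matrix["element"]
        z_val = np.array([VALENCE_ELECTRONS[e] for e in elements], float)
        out["kappa"] = out["kappa"] - 1.0
        out["kappa_prime"] = out["kappa_prime"] - 1.0
        out["p_val"] = out["p_val"] - z_val
    if mode in ("normalize", "subtract_normalize"):
        norms = np.sqrt((out.to_numpy() ** 2).sum(axis=0))
        for i, col in enumerate(out.columns):
            if norms[i] == 0.0:
                logger.warning("column %s has zero norm; left unscaled", col)
            else:
                out[col] = out[col] / norms[i]
    if scale != 1.0:
        out = out * scale
    out.attrs["transform"] = mode
    out.attrs["scale"] = scale
    return out


def estimate_eps(matrix, k: int) -> float:
    """Knee-method Eps: the value of the ascending k-nearest-neighbor
    distance curve at maximum perpendicular distance from its chord.

    Exact-duplicate rows are removed first, so indistinguishable rotations
    cannot flatten the curve to zero.
    """
    x = np.asarray(matrix, dtype=float)
    if x.ndim != 2:
        x = np.atleast_2d(x)
    x = np.unique(x, axis=0)
    if len(x) <= k:
        raise DegenerateEpsError(
            f"need at least k+1={k + 1} distinct points, have {len(x)}")
    nn = NearestNeighbors(n_neighbors=k + 1).fit(x)
    dist, _ = nn.kneighbors(x)
    curve = np.sort(dist[:, k])
    if curve[-1] <= 0.0:
        raise DegenerateEpsError("all k-distances are zero")
    n = len(curve)
    if n == 1 or curve[-1] == curve[0]:
        return float(curve[-1])
    # perpendicular distance of each curve point to the first-to-last chord
    t = np.arange(n, dtype=float)
    chord = np.array([n - 1.0, curve[-1] - curve[0]])
    chord /= np.linalg.norm(chord)
    rel = np.stack([t, curve - curve[0]], axis=1)
    perp = np.abs(rel[:, 0] * chord[1] - rel[:, 1] * chord[0])
    return float(curve[int(np.argmax(perp))])


def dbscan(matrix, eps: float, min_pts: int) -> np.ndarray:
    """Euclidean DBSCAN with labels renumbered by order of first member row
    (noise = -1), so the labeling is deterministic for a given row order."""
    if eps <= 0:
        raise ClusteringError("eps must be positive")
    raw = DBSCAN(eps=eps, min_samples=min_pts).fit_predict(
        np.asarray(matrix, dtype=float))
    remap: dict[int, int] = {}
    out = np.empty_like(raw)
    for i, lab in enumerate(raw):
        if lab == -1:
            out[i] = -1
            continue
        if lab not in remap:
            remap[lab] = len(remap)
        out[i] = remap[lab]
    return out


@dataclass
class EpsLogRecord:
    path: str          # "" for the top level
    eps: float
    source: str        # knee | manual | schedule
    n_rows: int


def _plm_sd_exceeds(original: pd.DataFrame, rows: np.ndarray,
                    threshold: float) -> bool:
    sub = original.iloc[rows][PLM_COLUMNS].to_numpy()
    if len(sub) < 2:
        return False
    return bool((sub.std(axis=0, ddof=1) > threshold).any())


def multilevel_cluster(matrix: pd.DataFrame, config: ClusteringConfig
                       ) -> tuple[list[ClusterLabelPath], list[EpsLogRecord]]:
    """Run the multi-level DBSCAN protocol.

    ``matrix`` holds the original-scale features (plus an ``element`` column
    when the subtraction transform is requested).  Level 1 clusters all
    rows; a cluster is re-clustered at the next level iff some Plm column's
    sample sd within it exceeds ``sd_threshold`` on the original scale
    (kappa, Pval, kappa' never trigger subdivision).  Outliers are excluded
    from subdivision; recursion stops at ``max_levels``.
    """
    config.validate()
    feats = transform(matrix, config.transform, scale=config.scale)
    x = feats.to_numpy()
    n = len(x)
    paths: list[tuple[int, ...] | None] = [None] * n
    eps_log: list[EpsLogRecord] = []

    def choose_eps(rows: np.ndarray, path: tuple[int, ...]) -> tuple[float, str]:
        key = "_".join(map(str, path))
        if key in config.eps_schedule:
            return float(config.eps_schedule[key]), "schedule"
        if not path and config.eps is not None:
            return float(config.eps), "manual"
        return estimate_eps(x[rows], config.min_pts), "knee"

    def run(rows: np.ndarray, path: tuple[int, ...], level: int) -> None:
        try:
            eps, source = choose_eps(rows, path)
        except DegenerateEpsError:
            if not path:
                raise
            logger.warning("knee estimation degenerate for cluster %s; "
                           "left undivided", "_".join(map(str, path)))
            for r in rows:
                paths[r] = path
            return
        eps_log.append(EpsLogRecord("_".join(map(str, path)), eps, source,
                                    len(rows)))
        labels = dbscan(x[rows], eps, config.min_pts)
        for lab in sorted(set(labels)):
            sub = rows[labels == lab]
            sub_path = path + (int(lab),)
            if lab == -1:
                for r in sub:
                    paths[r] = sub_path
                continue
            needs_split = _plm_sd_exceeds(matrix, sub, config.sd_threshold)
            if needs_split and len(sub) <= 1:
                logger.warning("cluster %s has one row; cannot subdivide",
                               "_".join(map(str, sub_path)))
                needs_split = False
            if needs_split and level < config.max_levels:
                run(sub, sub_path, level + 1)
            else:
                for r in sub:
                    paths[r] = sub_path

    run(np.arange(n), (), 1)
    return [ClusterLabelPath(tuple(p)) for p in paths], eps_log


def cluster_report(matrix: pd.DataFrame,
                   labels: list[ClusterLabelPath]) -> pd.DataFrame:
    """Per-cluster summary: size, mean and sample sd of all 18 features,
    dominant multipoles (largest |mean Plm|, with sign), the point group
    detected on the mean Plm vector, and the inconsistency fraction."""
    from .symmetry import detect_symmetry
    if len(labels) != len(matrix):
        raise ClusteringError("labels do not cover the feature rows")
    rows = []
    by_path: dict[str, list[int]] = {}
    for i, path in enumerate(labels):
        by_path.setdefault(str(path), []).append(i)
    for path in sorted(by_path):
        idx = by_path[path]
        sub = matrix.iloc[idx]
        feats = sub[FEATURE_COLUMNS].to_numpy()
        mean = feats.mean(axis=0)
        sd = (feats.std(axis=0, ddof=1) if len(idx) > 1
              else np.zeros(len(FEATURE_COLUMNS)))
        plm_mean = {lm: float(sub[plm_column(*lm)].mean())
                    for lm in lm_indices(FEATURE_LMAX) if lm[0] > 0}
        dominant = max(plm_mean, key=lambda lm: abs(plm_mean[lm]))
        record = {
            "cluster": path,
            "n": len(idx),
            "outlier": path.split("_")[-1] == "-1",
            "dominant_multipole": plm_column(*dominant),
            "dominant_value": plm_mean[dominant],
            "point_group": detect_symmetry(plm_mean),
            "max_plm_sd": float(
                sd[len(FEATURE_COLUMNS) - len(PLM_COLUMNS):].max()),
        }
        if "inconsistent" in sub.columns:
            record["inconsistent_fraction"] = float(
                sub["inconsistent"].mean())
        for col, m, s in zip(FEATURE_COLUMNS, mean, sd):
            record[f"mean_{col}"] = m
            record[f"sd_{col}"] = s
        rows.append(record)
    return pd.DataFrame(rows)


def assignments_frame(matrix: pd.DataFrame, labels, eps_log) -> pd.DataFrame:
    """Assignment table: identifying columns plus label path and the Eps
    used at every level along the path."""
    eps_by_path = {rec.path: rec.eps for rec in eps_log}
    ident = [c for c in ("entry", "frame", "family", "element", "group")
             if c in matrix.columns]
    out = matrix[ident].copy() if ident else pd.DataFrame(index=matrix.index)
    out["label"] = [str(p) for p in labels]
    out["eps_path"] = [
        "|".join(f"{eps_by_path[prefix]:.6g}"
                 for prefix in _prefixes(p) if prefix in eps_by_path)
        for p in labels]
    return out


def _prefixes(path: ClusterLabelPath):
    yield ""
    for i in range(1, len(path.levels)):
        yield "_".join(map(str, path.levels[:i]))
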