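"""Clonal dynamics between primary tumors and xenografts from paired MAFs.

Each variant carries a mutant allele frequency (MAF) in the primary tumor
and in the xenograft.  Variants are classified by their MAF dynamics
(shared / enriched / depleted at a 2x fold-change boundary, or private to one
sample when below detection in the other), clustered into clones in
(MAF_primary, MAF_xeno) space, and counted into per-model non-silent
mutation burdens.  Under the heterozygous-diploid convention a clone at
cellular frequency f produces MAFs near f/2, so clone frequencies are read
off as twice the per-coordinate cluster medians.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from scipy.stats import ttest_rel
from sklearn.metrics import silhouette_score

VARIANT_COLUMNS = ["model_id", "chrom", "pos", "ref", "alt", "gene",
                   "effect_class", "maf_primary", "maf_xeno",
                   "depth_primary", "depth_xeno"]

DYNAMICS_CLASSES = ("shared", "enriched", "depleted",
                    "primary_private", "xeno_private")

DEFAULT_DETECT_MAF = 0.02
DEFAULT_MIN_READS = 3


@dataclass
class CloneTrack:
    clone_id: int
    freq_primary: float
    freq_xeno: float
    members: list[int]  # row indices into the variant table


def _detected(maf: np.ndarray, depth: np.ndarray, detect_maf: float,
              min_reads: int) -> np.ndarray:
    reads = np.rint(maf * depth)
    return (maf >= detect_maf) & (reads >= min_reads)


def classify_dynamics(variants: pd.DataFrame,
                      detect_maf: float = DEFAULT_DETECT_MAF,
                      fold: float = 2.0,
                      min_reads: int = DEFAULT_MIN_READS) -> pd.Series:
    """Classify each variant's primary-to-xenograft MAF dynamics.

    A variant detected in only one sample is private to that sample; for
    variants detected in both, the MAF ratio xeno/primary above ``fold`` is
    ``enriched``, below ``1/fold`` ``depleted``, otherwise ``shared`` (the
    boundary ratio itself counts as shared).  Variants below detection on
    both sides are uninformative: they are returned as NaN with a warning and
    should be dropped upstream.
    """
    if not 0 < detect_maf < 0.5:
        raise ValueError("detect_maf must lie in (0, 0.5)")
    if fold <= 1:
        raise ValueError("fold must exceed 1")
    mp = variants["maf_primary"].to_numpy(dtype=float)
    mx = variants["maf_xeno"].to_numpy(dtype=float)
    if np.any((mp < 0) | (mp > 1) | (mx < 0) | (mx > 1)):
        raise ValueError("MAFs must lie in [0, 1]")
    det_p = _detected(mp, variants["depth_primary"].to_numpy(dtype=float),
                      detect_maf, min_reads)
    det_x = _detected(mx, variants["depth_xeno"].to_numpy(dtype=float),
                      detect_maf, min_reads)
    out = np.full(len(variants), None, dtype=object)
    out[det_p & ~det_x] = "primary_private"
    out[det_x & ~det_p] = "xeno_private"
    both = det_p & det_x
    with np.errstate(divide="ignore"):
        ratio = np.where(both, mx / np.where(mp > 0, mp, np.nan), np.nan)
    out[both & (ratio > fold)] = "enriched"
    out[both & (ratio < 1 / fold)] = "depleted"
    out[both & (ratio <= fold) & (ratio >= 1 / fold)] = "shared"
    n_uninformative = int((~det_p & ~det_x).sum())
    if n_uninformative:
        warnings.warn(f"{n_uninformative} variant(s) below detection in both "
                      "samples were left unclassified", stacklevel=2)
    return pd.Series(out, index=variants.index, name="dynamics_class")


def _pam(points: np.ndarray, k: int, max_iter: int = 100) -> np.ndarray:
    """Deterministic k-medoids (PAM): greedy BUILD then SWAP to convergence."""
    d = cdist(points, points)
    n = len(points)
    medoids = [int(np.argmin(d.sum(axis=1)))]
    while len(medoids) < k:
        current = d[:, medoids].min(axis=1)
        gains = np.array([np.maximum(current - d[:, j], 0).sum()
                          if j not in medoids else -1.0 for j in range(n)])
        medoids.append(int(np.argmax(gains)))
    medoids = sorted(medoids)
    for _ in range(max_iter):
        cost = d[:, medoids].min(axis=1).sum()
        best = (cost, None)
        for mi, m in enumerate(medoids):
            for j in range(n):
                if j in medoids:
                    continue
                trial = medoids[:mi] + [j] + medoids[mi + 1:]
                c = d[:, trial].min(axis=1).sum()
                if c < best[0] - 1e-12:
                    best = (c, (mi, j))
        if best[1] is None:
            break
        mi, j = best[1]
        medoids[mi] = j
        medoids = sorted(medoids)
    return np.argmin(d[:, medoids], axis=1)


def cluster_clones(variants: pd.DataFrame, k_max: int = 6,
                   min_silhouette: float = 0.5,
                   tight_tol: float = 0.03) -> list[CloneTrack]:
    """Partition variants into clones in (MAF_primary, MAF_xeno) space.

    k-medoids (PAM, deterministic) is run for k = 2..k_max and the k with the
    best mean silhouette is kept; a single clone is returned when the points
    are essentially coincident (spread below ``tight_tol``) or no split
    reaches ``min_silhouette``.  Clone frequencies are twice the
    per-coordinate medians of member MAFs, capped at 1 (heterozygous-diploid
    convention).
    """
    if k_max < 1:
        raise ValueError("k_max must be at least 1")
    if len(variants) < 3:
        raise ValueError("need at least 3 variants to cluster")
    pts = variants[["maf_primary", "maf_xeno"]].to_numpy(dtype=float)
    spread = np.abs(pts - np.median(pts, axis=0)).max()
    labels = np.zeros(len(pts), dtype=int)
    if spread > tight_tol and k_max >= 2:
        best_score, best_labels = -np.inf, None
        for k in range(2, min(k_max, len(pts) - 1) + 1):
            lab = _pam(pts, k)
            if len(np.unique(lab)) < 2:
                continue
            score = silhouette_score(pts, lab)
            if score > best_score:
                best_score, best_labels = score, lab
        if best_labels is not None and best_score >= min_silhouette:
            labels = best_labels
    tracks = []
    for clone_id in np.unique(labels):
        idx = np.flatnonzero(labels == clone_id)
        med = np.median(pts[idx], axis=0)
        tracks.append(CloneTrack(
            clone_id=int(clone_id),
            freq_primary=float(min(2 * med[0], 1.0)),
            freq_xeno=float(min(2 * med[1], 1.0)),
            members=[int(variants.index[i]) for i in idx]))
    tracks.sort(key=lambda t: -(t.freq_primary + t.freq_xeno))
    for new_id, t in enumerate(tracks):
        t.clone_id = new_id
    return tracks


def clone_table(tracks: list[CloneTrack]) -> pd.DataFrame:
    """Fish-plot-ready clone frequency table (clone x {primary, xeno})."""
    return pd.DataFrame(
        [{"clone_id": t.clone_id, "freq_primary": t.freq_primary,
          "freq_xeno": t.freq_xeno, "n_variants": len(t.members)}
         for t in tracks]).set_index("clone_id")


def nonsilent_burden(variants: pd.DataFrame,
                     detect_maf: float = DEFAULT_DETECT_MAF,
                     min_reads: int = DEFAULT_MIN_READS) -> pd.DataFrame:
    """Per-model count of non-silent variants detected on each side."""
    ns = variants[variants["effect_class"] == "non-silent"]
    rows = []
    for model_id, sub in ns.groupby("model_id", sort=True):
        det_p = _detected(sub["maf_primary"].to_numpy(dtype=float),
                          sub["depth_primary"].to_numpy(dtype=float),
                          detect_maf, min_reads)
        det_x = _detected(sub["maf_xeno"].to_numpy(dtype=float),
                          sub["depth_xeno"].to_numpy(dtype=float),
                          detect_maf, min_reads)
        rows.append({"model_id": model_id, "n_primary": int(det_p.sum()),
                     "n_xeno": int(det_x.sum())})
    if not rows:
        return pd.DataFrame(columns=["n_primary", "n_xeno"],
                            index=pd.Index([], name="model_id"))
    return pd.DataFrame(rows).set_index("model_id")


def cohort_burden_summary(burden: pd.DataFrame) -> dict:
    """Cohort median/IQR of non-silent burden per side plus a paired t-test."""
    out = {}
    for side in ("primary", "xeno"):
        counts = burden[f"n_{side}"]
        q1, med, q3 = counts.quantile([0.25, 0.5, 0.75])
        out[side] = {"median": float(med), "iqr": (float(q1), float(q3))}
    if len(burden) >= 2:
        t, p = ttest_rel(burden["n_primary"], burden["n_xeno"])
        out["paired_t"] = {"t": float(t), "p": float(p)}
    return out
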