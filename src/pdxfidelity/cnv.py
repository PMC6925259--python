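"""Copy-number inference from methylation-array total hybridization signal.

The log-scale total intensity of each probe carries copy-number information
once technical covariates are removed.  The pipeline is:

1. ``adjust_signal`` — regress out GC content and probe-type effects with a
   piecewise-constant (regression-tree style) fit and keep the residuals;
2. ``segment_cbs`` — circular binary segmentation: recursively find the arc
   of probes maximising the circular two-sample t statistic against the rest
   of the segment, accepting splits whose permutation p-value falls below
   ``alpha``;
3. ``recenter`` — subtract the probe-weighted median of segment means so a
   predominantly diploid genome sits at zero;
4. ``call_states`` — segments with mean < -0.2 are losses, > +0.2 gains,
   otherwise neutral (strict inequalities; exactly +/-0.2 stays neutral).

``shared_cn_fraction`` compares two per-probe state profiles from a paired
primary tumor and xenograft.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

LOSS, NEUTRAL, GAIN = -1, 0, 1
STATE_NAMES = {LOSS: "loss", NEUTRAL: "neutral", GAIN: "gain"}

SIGNAL_COLUMNS = ["probe_id", "chrom", "pos", "total_signal", "gc", "probe_type"]


@dataclass
class SegmentProfile:
    """Segmentation of one or more chromosomes into constant-mean segments.

    ``segments`` has columns chrom, start, end (0-based half-open probe
    indices within the chromosome), n_probes, mean and, after
    :func:`call_states`, state.  Segments partition each chromosome's probes
    without overlap.
    """

    segments: pd.DataFrame

    def __post_init__(self) -> None:
        for chrom, sub in self.segments.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            if (sub["end"].to_numpy()[:-1] != sub["start"].to_numpy()[1:]).any():
                raise ValueError(f"segments on {chrom} do not partition probes")
            if int(sub["start"].iloc[0]) != 0:
                raise ValueError(f"first segment on {chrom} does not start at 0")

    def probe_means(self) -> dict[str, np.ndarray]:
        """Expand segment means back to per-probe vectors, per chromosome."""
        out = {}
        for chrom, sub in self.segments.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            out[chrom] = np.repeat(sub["mean"].to_numpy(),
                                   sub["n_probes"].to_numpy())
        return out

    def probe_states(self) -> dict[str, np.ndarray]:
        out = {}
        for chrom, sub in self.segments.groupby("chrom", sort=False):
            sub = sub.sort_values("start")
            out[chrom] = np.repeat(sub["state"].to_numpy(),
                                   sub["n_probes"].to_numpy())
        return out


def adjust_signal(track: pd.DataFrame, n_gc_bins: int = 10) -> np.ndarray:
    """Residuals of a piecewise-constant regression of signal on (gc, probe_type).

    GC content is binned into ``n_gc_bins`` quantile bins crossed with probe
    type; the cell mean is subtracted from every probe, which is exactly a
    depth-limited regression tree with axis-aligned splits on the two
    covariates.  Falls back to overall mean-centering (with a warning) when
    the covariates are constant.
    """
    signal = track["total_signal"].to_numpy(dtype=float)
    gc = track["gc"].to_numpy(dtype=float)
    if np.any((gc < 0) | (gc > 1)):
        raise ValueError("gc fractions must lie in [0, 1]")
    if np.unique(gc).size < 2 and track["probe_type"].nunique() < 2:
        warnings.warn("constant GC and probe type: adjustment reduces to "
                      "mean-centering", stacklevel=2)
        return signal - signal.mean()
    # quantile bins keep cells populated even for skewed GC distributions;
    # with few distinct GC values, stratify by exact value instead
    if np.unique(gc).size <= n_gc_bins:
        gc_bin = pd.factorize(gc)[0]
    else:
        gc_bin = pd.qcut(gc, q=n_gc_bins, duplicates="drop", labels=False)
    cells = pd.DataFrame({"signal": signal, "gc_bin": gc_bin,
                          "ptype": track["probe_type"].to_numpy()})
    fitted = cells.groupby(["gc_bin", "ptype"])["signal"].transform("mean")
    return signal - fitted.to_numpy()


def _max_circular_t(values: np.ndarray, min_width: int
                    ) -> tuple[float, int, int]:
    """Maximum |t| over all arcs [i, j) vs. their complement within one segment.

    Uses pooled-variance two-sample t.  Arcs with fewer than ``min_width``
    probes on either side are excluded.  Returns (|t|, i, j); (0, 0, n) when
    no admissible arc exists or the segment is constant.
    """
    x = np.asarray(values, dtype=float)
    n = x.size
    if n < 2 * min_width:
        return 0.0, 0, n
    cs = np.concatenate(([0.0], np.cumsum(x)))
    cs2 = np.concatenate(([0.0], np.cumsum(x * x)))
    total, total2 = cs[-1], cs2[-1]
    i_idx, j_idx = np.triu_indices(n + 1, k=min_width)
    m = (j_idx - i_idx).astype(float)
    keep = (m >= min_width) & (n - m >= min_width)
    if not keep.any():
        return 0.0, 0, n
    i_idx, j_idx, m = i_idx[keep], j_idx[keep], m[keep]
    s_in = cs[j_idx] - cs[i_idx]
    ss_in = cs2[j_idx] - cs2[i_idx]
    m_out = n - m
    mean_in = s_in / m
    mean_out = (total - s_in) / m_out
    ss_within = (ss_in - m * mean_in**2) + (total2 - ss_in - m_out * mean_out**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        pooled = ss_within / (n - 2)
        t = (mean_in - mean_out) / np.sqrt(pooled * (1 / m + 1 / m_out))
    diff = mean_in - mean_out
    t = np.abs(t)
    # noiseless change: zero within-arc variance with distinct means -> inf
    t[np.isnan(t) & (np.abs(diff) > 0)] = np.inf
    t[~np.isfinite(t) & (np.abs(diff) == 0)] = 0.0
    best = int(np.argmax(t))
    return float(t[best]), int(i_idx[best]), int(j_idx[best])


def _perm_pvalue(values: np.ndarray, observed_t: float, n_perm: int,
                 min_width: int, rng: np.random.Generator) -> float:
    """Permutation p-value for the max circular t statistic."""
    if observed_t == 0.0:
        return 1.0
    exceed = 0
    x = np.asarray(values, dtype=float)
    for _ in range(n_perm):
        t, _, _ = _max_circular_t(rng.permutation(x), min_width)
        if t >= observed_t:
            exceed += 1
    return (1 + exceed) / (1 + n_perm)


def segment_cbs(values: np.ndarray, alpha: float = 0.01, n_perm: int = 1000,
                seed: int = 0, min_width: int = 2, chrom: str = "chr1"
                ) -> SegmentProfile:
    """Circular binary segmentation of one chromosome's adjusted signal.

    Recursively splits segments at the arc maximising the circular two-sample
    t statistic whenever the permutation p-value of that statistic is below
    ``alpha``.  Deterministic for a fixed seed.
    """
    if n_perm < 100:
        raise ValueError("n_perm must be at least 100")
    if not 0 < alpha < 1:
        raise ValueError("alpha must lie in (0, 1)")
    x = np.asarray(values, dtype=float)
    if x.size < 4:
        raise ValueError("need at least 4 probes per chromosome")
    rng = np.random.default_rng(seed)
    boundaries = {0, x.size}

    def recurse(lo: int, hi: int) -> None:
        seg = x[lo:hi]
        t, i, j = _max_circular_t(seg, min_width)
        if t == 0.0:
            return
        p = _perm_pvalue(seg, t, n_perm, min_width, rng)
        if p >= alpha:
            return
        cuts = sorted({lo, lo + i, lo + j, hi})
        boundaries.update(cuts)
        for a, b in zip(cuts[:-1], cuts[1:]):
            recurse(a, b)

    recurse(0, x.size)
    cuts = sorted(boundaries)
    rows = [{"chrom": chrom, "start": a, "end": b, "n_probes": b - a,
             "mean": float(x[a:b].mean())}
            for a, b in zip(cuts[:-1], cuts[1:])]
    return SegmentProfile(pd.DataFrame(rows))


def segment_genome(track: pd.DataFrame, alpha: float = 0.01,
                   n_perm: int = 1000, seed: int = 0, min_width: int = 2,
                   adjusted: np.ndarray | None = None) -> SegmentProfile:
    """Adjust and segment every chromosome of a signal track."""
    if adjusted is None:
        adjusted = adjust_signal(track)
    frames = []
    for k, (chrom, idx) in enumerate(
            track.groupby("chrom", sort=False).indices.items()):
        sub = adjusted[idx]
        prof = segment_cbs(sub, alpha=alpha, n_perm=n_perm,
                           seed=seed + k, min_width=min_width, chrom=chrom)
        frames.append(prof.segments)
    return SegmentProfile(pd.concat(frames, ignore_index=True))


def _weighted_median(values: np.ndarray, weights: np.ndarray) -> float:
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order].astype(float)
    cw = np.cumsum(w)
    half = cw[-1] / 2.0
    return float(v[np.searchsorted(cw, half)])


def recenter(profile: SegmentProfile) -> SegmentProfile:
    """Subtract the probe-weighted median of segment means from every segment.

    Probe weighting realises median-centering "at the probe-set level": a
    segment's influence on the centre is proportional to the number of probes
    it spans.  Idempotent.
    """
    seg = profile.segments.copy()
    if seg.empty:
        raise ValueError("profile has no segments")
    shift = _weighted_median(seg["mean"].to_numpy(),
                             seg["n_probes"].to_numpy())
    seg["mean"] = seg["mean"] - shift
    return SegmentProfile(seg)


def call_states(profile: SegmentProfile, threshold: float = 0.2
                ) -> SegmentProfile:
    """Assign loss/neutral/gain per segment from recentered means."""
    seg = profile.segments.copy()
    means = seg["mean"].to_numpy()
    states = np.where(means < -threshold, LOSS,
                      np.where(means > threshold, GAIN, NEUTRAL))
    seg["state"] = states
    return SegmentProfile(seg)


def shared_cn_fraction(profile_a: SegmentProfile, profile_b: SegmentProfile
                       ) -> tuple[float, dict[str, np.ndarray]]:
    """Probe-weighted fraction of identical CN state between two profiles.

    The differential map gives, per probe, ``state_b - state_a`` clipped to
    {-1, 0, +1}: -1 marks loss in the second profile relative to the first,
    +1 relative gain.  Swapping arguments flips the sign of the map.
    """
    states_a = profile_a.probe_states()
    states_b = profile_b.probe_states()
    chroms = [c for c in states_a if c in states_b]
    if not chroms:
        raise ValueError("profiles share no chromosomes")
    same = 0
    total = 0
    diff_map: dict[str, np.ndarray] = {}
    for chrom in chroms:
        a, b = states_a[chrom], states_b[chrom]
        if a.size != b.size:
            raise ValueError(f"probe grids differ on {chrom}")
        same += int((a == b).sum())
        total += a.size
        diff_map[chrom] = np.clip(b - a, -1, 1)
    return same / total, diff_map
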