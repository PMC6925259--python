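"""Synthetic paired primary-tumor / xenograft cohorts with known ground truth.

Every downstream stage of the package (methylation retention, copy-number
segmentation, clonal dynamics, growth-response classification, transcriptome
similarity) has a generator here that plants the parameter the stage is
supposed to recover.  Defaults emulate the structure of a 39-45 model Wilms
tumor PDX cohort: per-pair methylation retention near the observed cohort
median (0.8678), clone frequencies spanning maintained / expanding / lost /
graft-private subclones, exponential tumor growth with enrollment at
0.2-0.5 cm3 and weekly measurement to day 84 or 2.5 cm3, and a blastemal
gene-set expression shift in the xenografts.

All draws come from a single integer seed; a fixed seed reproduces the
cohort bit-identically.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .methylation import BetaMatrix
from .response import GrowthCurve, StudyArm
from .transcriptome import ExpressionMatrix

_BIN_EDGES = (0.0, 1 / 3, 2 / 3, 1.0)


@dataclass
class ArmSpec:
    """Growth-study arm: exponential growth with a multiplicative kill term."""

    baseline_doubling_days: float = 7.0
    treatment_kill_rate: float = 0.0  # per day; 0 = control
    n_mice: int = 8
    measurement_days: tuple = tuple(range(0, 85, 7))

    def __post_init__(self) -> None:
        if self.baseline_doubling_days <= 0:
            raise ValueError("doubling time must be positive")
        if self.treatment_kill_rate < 0:
            raise ValueError("kill rate must be non-negative")
        if self.n_mice < 2:
            raise ValueError("need at least 2 mice per arm")
        days = np.asarray(self.measurement_days, dtype=float)
        if days.size == 0:
            raise ValueError("measurement_days must be non-empty")
        if days[0] != 0 or np.any(np.diff(days) <= 0):
            raise ValueError("measurement_days must start at 0 and increase")


# default arms: a control, a strongly effective drug (net regression), and a
# weakly effective drug (slight growth delay only)
DEFAULT_GROWTH_SPEC = {
    "control": ArmSpec(),
    "V": ArmSpec(treatment_kill_rate=0.25),
    "A": ArmSpec(treatment_kill_rate=0.03),
}

DEFAULT_CLONE_TABLE = (
    (1.0, 1.0, 30),   # maintained major clone
    (0.2, 0.8, 25),   # minor subclone expanding in the graft
    (0.4, 0.0, 20),   # primary clone lost on engraftment
    (0.0, 0.5, 15),   # xenograft-specific clone
)


@dataclass
class CohortSpec:
    """Ground-truth parameters for one simulated paired cohort."""

    n_models: int = 39
    n_probes: int = 20_000
    n_variants_per_model: int = 90
    n_genes: int = 4_000
    retention_rate_target: float = 0.8678
    clone_table: tuple = DEFAULT_CLONE_TABLE
    sequencing_depth: int = 500
    cn_events: tuple = (("chr1", 300, 400, 0.4),)
    cn_noise_sd: float = 0.1
    growth_spec: dict = field(default_factory=lambda: dict(DEFAULT_GROWTH_SPEC))
    blastema_shift: float = 1.0
    n_blastemal_genes: int = 100
    n_low_fidelity: int = 0
    low_fidelity_noise_sd: float = 1.5
    expression_noise_sd: float = 0.2
    growth_noise_sd: float = 0.05
    detection_floor_cm3: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.retention_rate_target <= 1:
            raise ValueError("retention_rate_target must lie in [0, 1]")
        for fp, fx, nv in self.clone_table:
            if not (0 <= fp <= 1 and 0 <= fx <= 1):
                raise ValueError("clone frequencies must lie in [0, 1]")
            if nv < 1:
                raise ValueError("each clone needs at least 1 variant")

    def rng(self, stream=0) -> np.random.Generator:
        streams = stream if isinstance(stream, tuple) else (stream,)
        return np.random.default_rng((self.seed,) + streams)


def _sample_in_bin(rng: np.random.Generator, centre: np.ndarray,
                   bin_idx: np.ndarray, sd: float = 0.05) -> np.ndarray:
    """Truncated-normal draw around ``centre`` confined to each probe's bin."""
    lo = np.take(_BIN_EDGES, bin_idx)
    hi = np.take(_BIN_EDGES, bin_idx + 1)
    eps = 1e-9
    draw = rng.normal(centre, sd)
    return np.clip(draw, lo, np.where(hi == 1.0, 1.0, hi - eps))


def _uniform_in_other_bin(rng: np.random.Generator,
                          bin_idx: np.ndarray) -> np.ndarray:
    """Uniform draw from one of the two bins the probe is *not* in."""
    shift = rng.integers(1, 3, size=bin_idx.shape)
    other = (bin_idx + shift) % 3
    lo = np.take(_BIN_EDGES, other)
    hi = np.take(_BIN_EDGES, other + 1)
    return lo + rng.uniform(0, 1, size=bin_idx.shape) * (hi - lo - 1e-9)


def simulate_beta_pair(spec: CohortSpec) -> BetaMatrix:
    """Paired beta matrices with a planted per-probe retention rate.

    For each model, a fraction ``retention_rate_target`` of probes keeps its
    tri-state bin in the xenograft (drawn near the primary value inside the
    bin); the rest jump to a different bin, so the planted rate is exactly
    the expected tri-state retention a downstream analysis should recover.
    """
    if spec.n_probes < 100:
        raise ValueError("need at least 100 probes")
    rng = spec.rng(1)
    probe_ids = [f"cg{i:07d}" for i in range(spec.n_probes)]
    baseline = rng.uniform(0.02, 0.98, size=spec.n_probes)
    cols, pairing = {}, []
    for m in range(spec.n_models):
        model = f"SIM-{m:02d}"
        # per-model deviation dominates the shared baseline so each tumor
        # has a recognisable global methylation identity, as on real arrays
        primary = np.clip(baseline + rng.normal(0, 0.2, size=spec.n_probes),
                          0, 1)
        pbin = np.minimum(np.searchsorted(_BIN_EDGES, primary,
                                          side="right") - 1, 2)
        retained = rng.uniform(size=spec.n_probes) < spec.retention_rate_target
        xeno = np.where(
            retained,
            _sample_in_bin(rng, primary, pbin),
            _uniform_in_other_bin(rng, pbin))
        cols[f"{model}-PT"] = primary
        cols[f"{model}-X"] = xeno
        pairing.append({"sample_id": f"{model}-PT", "model_id": model,
                        "tissue": "primary"})
        pairing.append({"sample_id": f"{model}-X", "model_id": model,
                        "tissue": "xenograft"})
    values = pd.DataFrame(cols, index=pd.Index(probe_ids, name="probe_id"))
    return BetaMatrix(values=values, pairing=pd.DataFrame(pairing))


def simulate_variant_pair_table(spec: CohortSpec,
                                model_id: str = "SIM-00") -> pd.DataFrame:
    """Variant MAF table for one model from the planted clone structure.

    Each clone contributes its stated number of variants; the observed MAF
    is a binomial draw at the sequencing depth around clone frequency / 2
    (heterozygous-diploid convention).
    """
    if not spec.clone_table:
        raise ValueError("clone_table must be non-empty")
    rng = spec.rng(2)
    rows = []
    vid = 0
    for clone_idx, (fp, fx, nv) in enumerate(spec.clone_table):
        for _ in range(nv):
            dp = spec.sequencing_depth
            maf_p = rng.binomial(dp, fp / 2) / dp
            maf_x = rng.binomial(dp, fx / 2) / dp
            rows.append({
                "model_id": model_id, "chrom": f"chr{rng.integers(1, 23)}",
                "pos": int(rng.integers(1, 2_000_000)),
                "ref": "A", "alt": "T", "gene": f"GENE{vid}",
                "effect_class": "non-silent" if rng.uniform() < 0.6
                                else "silent",
                "maf_primary": maf_p, "maf_xeno": maf_x,
                "depth_primary": dp, "depth_xeno": dp,
                "true_clone": clone_idx,
            })
            vid += 1
    return pd.DataFrame(rows)


def simulate_burden_cohort(n_models: int = 35, lam_primary: float = 7.0,
                           lam_xeno: float = 5.0, depth: int = 300,
                           seed: int = 0) -> pd.DataFrame:
    """Non-silent variant tables for a cohort with planted per-side burdens.

    Per model the number of detected non-silent variants on each side is a
    Poisson draw (defaults centred on the burdens typical of Wilms tumor:
    around 7 in primaries, 5 in xenografts); detected variants get clonal
    MAFs, absent ones MAF 0.
    """
    rng = np.random.default_rng((seed, 3))
    rows = []
    for m in range(n_models):
        n_p = rng.poisson(lam_primary)
        n_x = rng.poisson(lam_xeno)
        n_shared = rng.binomial(min(n_p, n_x), 0.7)
        total = n_p + n_x - n_shared
        for v in range(total):
            in_p = v < n_p
            in_x = v < n_shared or v >= n_p
            rows.append({
                "model_id": f"SIM-{m:02d}", "chrom": "chr1",
                "pos": int(rng.integers(1, 2_000_000)), "ref": "C",
                "alt": "G", "gene": f"GENE{v}", "effect_class": "non-silent",
                "maf_primary": rng.uniform(0.15, 0.5) if in_p else 0.0,
                "maf_xeno": rng.uniform(0.15, 0.5) if in_x else 0.0,
                "depth_primary": depth, "depth_xeno": depth,
            })
    return pd.DataFrame(rows)


def simulate_signal_track(spec: CohortSpec, n_probes: int = 600,
                          events: tuple | None = None,
                          stream: int = 4) -> pd.DataFrame:
    """Methylation-array total-signal track with GC wave and planted segments.

    The signal is a smooth GC-driven component plus a probe-type offset plus
    the planted copy-number shifts plus Gaussian noise, so the adjustment
    step must remove the first two while the segmentation recovers the
    third.
    """
    rng = spec.rng(stream)
    events = spec.cn_events if events is None else events
    gc = rng.uniform(0.3, 0.7, size=n_probes)
    ptype = rng.choice(["I", "II"], size=n_probes, p=[0.3, 0.7])
    signal = (0.6 * np.sin(2 * np.pi * gc)           # GC wave
              + np.where(ptype == "I", 0.15, -0.05)  # probe-type offset
              + rng.normal(0, spec.cn_noise_sd, size=n_probes))
    chrom = np.array(["chr1"] * n_probes)
    for _ev_chrom, start, end, shift in events:
        if end > n_probes:
            raise ValueError("planted event exceeds probe count")
        signal[start:end] += shift
    return pd.DataFrame({
        "probe_id": [f"cn{i:06d}" for i in range(n_probes)],
        "chrom": chrom, "pos": np.arange(1, n_probes + 1) * 1000,
        "total_signal": signal, "gc": gc, "probe_type": ptype,
    })


def simulate_growth_study(spec: CohortSpec, arm: str,
                          model_id: str = "SIM-00",
                          v0: float | None = None) -> StudyArm:
    """Growth curves for one arm: exponential growth minus treatment kill.

    Day-0 volume is uniform on [0.2, 0.5] cm3 (the enrollment window) unless
    ``v0`` pins it.  Volume follows V0 * exp((log2/doubling - kill) * t)
    with multiplicative lognormal measurement noise; readings below the
    detection floor record as 0, and the series stops at the first reading
    of 2.5 cm3 or more, or at the last scheduled measurement day.
    """
    if arm not in spec.growth_spec:
        raise ValueError(f"unknown arm {arm!r}")
    arm_spec = spec.growth_spec[arm]
    rng = spec.rng((5, zlib.crc32(arm.encode()) % 2**16))
    growth = np.log(2) / arm_spec.baseline_doubling_days
    net = growth - arm_spec.treatment_kill_rate
    days = np.asarray(arm_spec.measurement_days, dtype=float)
    curves = []
    for i in range(arm_spec.n_mice):
        start = rng.uniform(0.2, 0.5) if v0 is None else v0
        noise = np.exp(rng.normal(0, spec.growth_noise_sd, size=days.size))
        noise[0] = 1.0
        vols = start * np.exp(net * days) * noise
        vols[vols < spec.detection_floor_cm3] = 0.0
        capped = np.flatnonzero(vols >= 2.5)
        keep = days.size if capped.size == 0 else capped[0] + 1
        curves.append(GrowthCurve(mouse_id=f"{model_id}-{arm}-{i}",
                                  model_id=model_id, arm=arm,
                                  days=days[:keep], volumes=vols[:keep]))
    return StudyArm(curves=curves)


def simulate_expression_pair(spec: CohortSpec
                             ) -> tuple[ExpressionMatrix, list[str]]:
    """Paired log2-expression profiles with a blastemal gene-set shift.

    Xenograft profiles equal their primary plus noise plus
    ``blastema_shift`` added to the blastemal gene set.  The first
    ``n_low_fidelity`` models additionally receive heavy independent noise
    in the xenograft, making them the planted low-similarity pairs.
    """
    if spec.n_genes < 200:
        raise ValueError("need at least 200 genes")
    if spec.n_blastemal_genes < 1:
        raise ValueError("blastemal gene set must be non-empty")
    rng = spec.rng(6)
    genes = [f"G{i:05d}" for i in range(spec.n_genes)]
    blastemal = genes[:spec.n_blastemal_genes]
    base = rng.normal(4.0, 2.0, size=spec.n_genes)
    shift_vec = np.zeros(spec.n_genes)
    shift_vec[:spec.n_blastemal_genes] = spec.blastema_shift
    cols, pairing = {}, []
    for m in range(spec.n_models):
        model = f"SIM-{m:02d}"
        primary = base + rng.normal(0, 0.8, size=spec.n_genes) \
            + rng.normal(0, spec.expression_noise_sd, size=spec.n_genes)
        xeno = primary + shift_vec \
            + rng.normal(0, spec.expression_noise_sd, size=spec.n_genes)
        if m < spec.n_low_fidelity:
            xeno = xeno + rng.normal(0, spec.low_fidelity_noise_sd,
                                     size=spec.n_genes)
        cols[f"{model}-PT"] = primary
        cols[f"{model}-X"] = xeno
        pairing.append({"sample_id": f"{model}-PT", "model_id": model,
                        "tissue": "primary"})
        pairing.append({"sample_id": f"{model}-X", "model_id": model,
                        "tissue": "xenograft"})
    values = pd.DataFrame(cols, index=pd.Index(genes, name="gene_id"))
    matrix = ExpressionMatrix(values=values, pairing=pd.DataFrame(pairing))
    return matrix, blastemal


def expression_to_fpkm(matrix: ExpressionMatrix) -> pd.DataFrame:
    """Invert the log2(FPKM + 0.01) transform for writing raw-scale files."""
    return np.maximum(2.0 ** matrix.values - 0.01, 0.0)
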