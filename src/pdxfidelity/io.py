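"""Readers and writers for the plain-text formats the pipeline exchanges.

Dialects: beta matrices and FPKM matrices are TSV with the probe/gene id in
the first column; pairing manifests, growth curves, STR profiles and
annotations are CSV; segment calls are written BED-like (0-based half-open
probe intervals, stated in the header).  Gene sets use GMT.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .clones import VARIANT_COLUMNS
from .cnv import STATE_NAMES, SegmentProfile
from .methylation import BetaMatrix
from .response import GrowthCurve, StudyArm
from .transcriptome import ExpressionMatrix


def read_beta_matrix(beta_path, pairs_path) -> BetaMatrix:
    values = pd.read_csv(beta_path, sep="\t", index_col=0)
    pairing = pd.read_csv(pairs_path)
    return BetaMatrix(values=values, pairing=pairing)


def write_beta_matrix(matrix: BetaMatrix, beta_path, pairs_path) -> None:
    matrix.values.to_csv(beta_path, sep="\t")
    matrix.pairing.to_csv(pairs_path, index=False)


def read_signal_track(path) -> pd.DataFrame:
    track = pd.read_csv(path, sep="\t")
    required = {"probe_id", "chrom", "pos", "total_signal", "gc", "probe_type"}
    missing = required - set(track.columns)
    if missing:
        raise ValueError(f"signal track missing columns: {sorted(missing)}")
    return track


def write_segments(profile: SegmentProfile, path) -> None:
    seg = profile.segments.copy()
    if "state" in seg.columns:
        seg["state"] = seg["state"].map(STATE_NAMES)
    with open(path, "w") as fh:
        fh.write("# 0-based half-open probe-index intervals\n")
        seg.to_csv(fh, sep="\t", index=False)


def read_variants(path) -> pd.DataFrame:
    variants = pd.read_csv(path, sep="\t")
    missing = set(VARIANT_COLUMNS) - set(variants.columns)
    if missing:
        raise ValueError(f"variant table missing columns: {sorted(missing)}")
    return variants


def write_variants(variants: pd.DataFrame, path) -> None:
    variants.to_csv(path, sep="\t", index=False)


def read_growth_curves(path, diameter_units: bool = False
                       ) -> dict[tuple[str, str], StudyArm]:
    """Growth CSV -> {(model_id, arm): StudyArm}.

    Columns: model_id, arm, mouse_id, day, volume_cm3 (or diameter_mm with
    ``diameter_units=True``, converted via the spherical formula).
    """
    from .response import volume_from_diameter

    df = pd.read_csv(path)
    if diameter_units:
        df["volume_cm3"] = [volume_from_diameter(d / 10.0)
                            for d in df["diameter_mm"]]
    arms: dict[tuple[str, str], StudyArm] = {}
    for (model, arm), sub in df.groupby(["model_id", "arm"]):
        curves = []
        for mouse, ms in sub.groupby("mouse_id"):
            ms = ms.sort_values("day")
            curves.append(GrowthCurve(
                mouse_id=str(mouse), model_id=str(model), arm=str(arm),
                days=ms["day"].to_numpy(dtype=float),
                volumes=ms["volume_cm3"].to_numpy(dtype=float)))
        arms[(str(model), str(arm))] = StudyArm(curves=curves)
    return arms


def write_growth_curves(arms: dict[tuple[str, str], StudyArm], path) -> None:
    rows = []
    for (model, arm), study in arms.items():
        for curve in study.curves:
            for day, vol in zip(curve.days, curve.volumes):
                rows.append({"model_id": model, "arm": arm,
                             "mouse_id": curve.mouse_id, "day": day,
                             "volume_cm3": vol})
    pd.DataFrame(rows).to_csv(path, index=False)


def read_expression(fpkm_path, pairs_path) -> tuple[pd.DataFrame, pd.DataFrame]:
    fpkm = pd.read_csv(fpkm_path, sep="\t", index_col=0)
    pairing = pd.read_csv(pairs_path)
    return fpkm, pairing


def write_expression_matrix(matrix: ExpressionMatrix, values_path,
                            pairs_path) -> None:
    matrix.values.to_csv(values_path, sep="\t")
    matrix.pairing.to_csv(pairs_path, index=False)


def read_str_profiles(path) -> dict[str, dict[str, set]]:
    """STR CSV (sample, locus, allele1, allele2) -> per-sample profiles."""
    df = pd.read_csv(path, dtype=str)
    profiles: dict[str, dict[str, set]] = {}
    for _, row in df.iterrows():
        alleles = {a for a in (row.get("allele1"), row.get("allele2"))
                   if isinstance(a, str) and a}
        profiles.setdefault(row["sample"], {})[row["locus"]] = alleles
    return profiles


def ensure_dir(path) -> Path:
    p = Path(path)
    p.mkdir(parents=True, exist_ok=True)
    return p
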