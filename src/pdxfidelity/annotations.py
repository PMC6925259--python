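"""Per-model cohort annotations: concordance, 11p15 status, STR identity,
and blastema-enrichment statistics.

The package ships a synthetic 45-model annotation table
(``data/cohort_annotations_synthetic.csv``) whose cohort-level marginals —
histologic concordance, 11p15 category counts, copy-number-alteration
prevalences — are fixed by construction; per-model placements without named
evidence are synthetic.  All statistics here recompute counts and
percentages from whatever table they are given.

11p15 status is decided by a fixed cascade over copy ratio, microsatellite
zygosity, and imprinting-center methylation indices:

1. copy ratio below the loss threshold       -> hemizygous loss
2. copy ratio above the gain threshold       -> paternal gain
3. copy-neutral, all informative markers homozygous -> uniparental disomy
4. copy-neutral, heterozygosity retained, IC1 biallelically methylated -> LOI
5. otherwise                                 -> normal
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

FEATURES = ["TP53", "WT1", "CTNNB1", "SIX1_2", "DROSHA", "DGCR8", "MYCN",
            "gain_1q", "loh_16q", "loh_1p", "loh_17p"]

STATUS_11P15 = ("UPD", "hemizygous_loss", "LOI", "paternal_gain", "normal")

MICROSATELLITE_MARKERS = ("D11S1363", "D11S922", "D11S4046", "HUMTH01",
                          "D11S988")

STR_LOCI = ("D3S1358", "TH01", "D21S11", "D18S51", "Penta_E", "D5S818",
            "D13S317", "D7S820", "D16S539", "CSF1PO", "Penta_D", "vWA",
            "D8S1179", "TPOX", "FGA", "AMEL")


@dataclass
class Thresholds11p15:
    """Decision thresholds for the 11p15 cascade (copy ratio 1.0 = diploid)."""

    copy_loss: float = 0.8
    copy_gain: float = 1.2
    ic1_biallelic: float = 0.75


def load_cohort_annotations() -> pd.DataFrame:
    """The bundled synthetic 45-model annotation table."""
    path = importlib.resources.files("pdxfidelity.data") \
        .joinpath("cohort_annotations_synthetic.csv")
    with importlib.resources.as_file(path) as p:
        return pd.read_csv(p, comment="#")


def _pct(count: int, n: int) -> float:
    return round(100.0 * count / n, 1)


def concordance_stats(table: pd.DataFrame) -> dict:
    """Cohort counts and percentages from a per-model annotation table.

    Covers histologic concordance, 11p15 category proportions, per-feature
    prevalence in the xenografts, combined 1p+16q LOH, and per-feature
    primary/xenograft pair concordance over evaluable pairs.  Percentages
    are reported to one decimal.
    """
    if table.empty:
        raise ValueError("annotation table is empty")
    n = len(table)
    out: dict = {"n_models": n}
    conc = int(table["histology_concordant"].sum())
    out["histologic_concordance"] = {"count": conc, "n": n, "pct": _pct(conc, n)}
    out["status_11p15"] = {
        status: {"count": int(c), "pct": _pct(int(c), n)}
        for status, c in table["status_11p15"].value_counts().items()}
    prevalence = {}
    for feat in FEATURES:
        col = f"{feat}_xeno"
        if col in table.columns:
            c = int(pd.to_numeric(table[col], errors="coerce").fillna(0).sum())
            prevalence[feat] = {"count": c, "pct": _pct(c, n)}
    out["xenograft_prevalence"] = prevalence
    if {"loh_1p_xeno", "loh_16q_xeno"}.issubset(table.columns):
        both = int(((table["loh_1p_xeno"] == 1)
                    & (table["loh_16q_xeno"] == 1)).sum())
        out["combined_1p_16q_loh"] = {"count": both, "pct": _pct(both, n)}
    pair_conc = {}
    for feat in FEATURES:
        xc, pc = f"{feat}_xeno", f"{feat}_primary"
        if xc in table.columns and pc in table.columns:
            prim = pd.to_numeric(table[pc], errors="coerce")
            evaluable = prim.notna()
            if evaluable.any():
                match = (table.loc[evaluable, xc] == prim[evaluable]).mean()
                pair_conc[feat] = {"n_evaluable": int(evaluable.sum()),
                                   "concordance": round(float(match), 3)}
    out["feature_pair_concordance"] = pair_conc
    return out


def classify_11p15(copy_ratio: float, ic1_index: float, ic2_index: float,
                   markers: dict[str, str],
                   thresholds: Thresholds11p15 | None = None) -> str:
    """11p15 status from copy ratio, imprinting indices, and microsatellites.

    ``markers`` maps marker name to 'het' / 'hom' / 'uninformative'.  Returns
    one of the five categories, or 'indeterminate' when the ratio is
    copy-neutral and no marker is informative.
    """
    th = thresholds or Thresholds11p15()
    if not 0 <= ic1_index <= 1 or not 0 <= ic2_index <= 1:
        raise ValueError("methylation indices must lie in [0, 1]")
    bad = set(markers.values()) - {"het", "hom", "uninformative"}
    if bad:
        raise ValueError(f"unknown marker calls: {sorted(bad)}")
    if copy_ratio < th.copy_loss:
        return "hemizygous_loss"
    if copy_ratio > th.copy_gain:
        return "paternal_gain"
    informative = [v for v in markers.values() if v != "uninformative"]
    if not informative:
        return "indeterminate"
    if all(v == "hom" for v in informative):
        return "UPD"
    if ic1_index > th.ic1_biallelic:
        return "LOI"
    return "normal"


@dataclass
class STRMatchReport:
    n_loci: int
    n_identical: int
    n_loss_tolerated: int
    mismatched_loci: list[str] = field(default_factory=list)
    loss_tolerated_loci: list[str] = field(default_factory=list)

    @property
    def fraction_identical(self) -> float:
        return self.n_identical / self.n_loci

    @property
    def verdict(self) -> str:
        return "match" if not self.mismatched_loci else "mismatch"


def str_match(primary: dict[str, set], xenograft: dict[str, set],
              min_loci: int = 8) -> STRMatchReport:
    """Compare STR allele profiles between a primary tumor and its xenograft.

    A locus matches when the allele sets are equal, or when the xenograft
    set is a strict subset of the primary's (allele loss in the graft, which
    is tolerated but counted separately).  The verdict is 'match' when every
    shared locus is identical or loss-tolerated.
    """
    shared = sorted(set(primary) & set(xenograft))
    if len(shared) < min_loci:
        raise ValueError(f"only {len(shared)} shared typed loci; "
                         f"need at least {min_loci}")
    identical = loss = 0
    mism, lost = [], []
    for locus in shared:
        a, b = set(primary[locus]), set(xenograft[locus])
        if not a or not b or len(a) > 2 or len(b) > 2:
            raise ValueError(f"locus {locus} must carry 1-2 alleles")
        if a == b:
            identical += 1
        elif b < a:
            loss += 1
            lost.append(locus)
        else:
            mism.append(locus)
    return STRMatchReport(n_loci=len(shared), n_identical=identical,
                          n_loss_tolerated=loss, mismatched_loci=mism,
                          loss_tolerated_loci=lost)


def blastema_enrichment(table: pd.DataFrame) -> dict:
    """Paired xenograft-minus-primary percent-blastema statistics.

    Returns the mean difference, its 95% CI, and the paired two-tailed
    t-test p-value over models with both percentages present.
    """
    sub = table.dropna(subset=["pct_blastema_primary", "pct_blastema_xeno"])
    if len(sub) < 2:
        raise ValueError("need at least 2 models with paired blastema values")
    diff = (sub["pct_blastema_xeno"] - sub["pct_blastema_primary"]) \
        .to_numpy(dtype=float)
    n = len(diff)
    mean = diff.mean()
    se = diff.std(ddof=1) / np.sqrt(n)
    tcrit = stats.t.ppf(0.975, n - 1)
    t, p = stats.ttest_rel(sub["pct_blastema_xeno"],
                           sub["pct_blastema_primary"])
    return {"n_pairs": n, "mean_difference": float(mean),
            "ci95": (float(mean - tcrit * se), float(mean + tcrit * se)),
            "t": float(t), "p": float(p)}


def passage_trajectory(table: pd.DataFrame, n_passages: int = 5) -> pd.DataFrame:
    """Per-passage percent-blastema difference versus the primary tumor.

    Uses models with a ``pct_blastema_passages`` list (semicolon-separated,
    passage 1 first).  Returns per-passage mean difference and paired
    t-test p over those models.
    """
    sub = table[table["pct_blastema_passages"].notna()
                & (table["pct_blastema_passages"] != "")]
    if len(sub) < 2:
        raise ValueError("passage analysis needs at least 2 models")
    traj = np.array([[float(v) for v in s.split(";")][:n_passages]
                     for s in sub["pct_blastema_passages"]])
    prim = sub["pct_blastema_primary"].to_numpy(dtype=float)
    rows = []
    for p_idx in range(traj.shape[1]):
        t, p = stats.ttest_rel(traj[:, p_idx], prim)
        rows.append({"passage": p_idx + 1,
                     "mean_difference": float((traj[:, p_idx] - prim).mean()),
                     "t": float(t), "p": float(p)})
    return pd.DataFrame(rows).set_index("passage")
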