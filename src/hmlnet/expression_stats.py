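"""Statistics for the expression-validation phase.

Covers relative quantification of qPCR data by the 2^(-ddCT) model
(normalized to a reference assay, calibrated to the control-group mean),
one-way ANOVA across diet/exercise groups with Welch pairwise post-hoc
tests, Pearson correlation between paired mRNA and lncRNA expression,
ROC/AUC discrimination with a bootstrap confidence interval, the HOMA-IR
insulin-resistance index, and trapezoidal area under glucose/insulin
tolerance-test curves.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .enrichment import adjust_bh

logger = logging.getLogger(__name__)

GROUPS = ("Ctrl", "HF-Sed", "HF-Exe", "Diabetic")
DEFAULT_REFERENCE = "18SrRNA"


class CTTable:
    """Grouped qPCR cycle-threshold measurements, long format.

    Wraps a DataFrame with columns (sample, group, target, ct); each sample
    belongs to exactly one group and the reference assay must be present
    among the targets.  Missing wells are simply absent rows.
    """

    COLUMNS = ("sample", "group", "target", "ct")

    def __init__(self, data: pd.DataFrame):
        missing = set(self.COLUMNS) - set(data.columns)
        if missing:
            raise ValueError(f"CT table missing columns {sorted(missing)}")
        df = data.loc[:, list(self.COLUMNS)].copy()
        df["ct"] = df["ct"].astype(float)
        if not np.isfinite(df["ct"]).all():
            raise ValueError("CT table contains non-finite ct values")
        groups_per_sample = df.groupby("sample")["group"].nunique()
        conflicted = groups_per_sample[groups_per_sample > 1]
        if len(conflicted):
            raise ValueError(
                f"samples with conflicting group labels: {list(conflicted.index)}"
            )
        self.df = df

    @property
    def targets(self) -> list[str]:
        return sorted(self.df["target"].unique())

    @property
    def groups(self) -> list[str]:
        return sorted(self.df["group"].unique())

    @classmethod
    def from_tsv(cls, path: str | Path) -> "CTTable":
        return cls(pd.read_csv(path, sep="\t"))

    def to_tsv(self, path: str | Path) -> None:
        self.df.to_csv(path, sep="\t", index=False, float_format="%.6g")


def ddct(
    table: CTTable,
    reference: str = DEFAULT_REFERENCE,
    calibrator_group: str = "Ctrl",
) -> pd.DataFrame:
    """Relative expression by the 2^(-ddCT) method.

    Per sample and target: dCT = CT_target - CT_reference; ddCT = dCT minus
    the mean dCT of the calibrator group for that target (group-mean
    calibration — animals are not paired across groups); fold = 2^(-ddCT).
    Samples missing either CT are skipped with a logged count.

    Returns a tidy frame (sample, group, target, delta_ct, delta_delta_ct,
    fold).
    """
    df = table.df
    if reference not in set(df["target"]):
        raise ValueError(f"reference assay {reference!r} absent from CT table")
    ref = (
        df[df["target"] == reference]
        .set_index("sample")["ct"]
        .rename("ref_ct")
    )
    tgt = df[df["target"] != reference].copy()
    n_before = len(tgt)
    tgt = tgt.join(ref, on="sample")
    tgt = tgt.dropna(subset=["ref_ct"])
    n_skipped = n_before - len(tgt)
    if n_skipped:
        logger.info("ddct: skipped %d wells lacking a reference CT", n_skipped)
    tgt["delta_ct"] = tgt["ct"] - tgt["ref_ct"]
    out = []
    for target, sub in tgt.groupby("target", sort=True):
        calib = sub.loc[sub["group"] == calibrator_group, "delta_ct"]
        if calib.empty:
            raise ValueError(
                f"calibrator group {calibrator_group!r} has no samples for "
                f"target {target!r}"
            )
        sub = sub.copy()
        sub["delta_delta_ct"] = sub["delta_ct"] - calib.mean()
        sub["fold"] = 2.0 ** (-sub["delta_delta_ct"])
        out.append(sub)
    result = pd.concat(out, ignore_index=True)
    return result[
        ["sample", "group", "target", "delta_ct", "delta_delta_ct", "fold"]
    ].sort_values(["target", "group", "sample"], ignore_index=True)


class AnovaResult(NamedTuple):
    F: float
    p: float
    group_means: dict[str, float]
    group_sems: dict[str, float]


def group_anova(values: Mapping[str, Sequence[float]]) -> AnovaResult:
    """One-way fixed-effects ANOVA with per-group mean +/- SEM.

    Degenerate case: when every observation is identical (zero between- and
    within-group variance) F is reported as 0 with p = 1 and a warning,
    rather than NaN.
    """
    groups = {g: np.asarray(v, dtype=float) for g, v in values.items()}
    if len(groups) < 2:
        raise ValueError("ANOVA needs >= 2 groups")
    for g, arr in groups.items():
        if arr.size < 2:
            raise ValueError(f"group {g!r} has fewer than 2 values")
        if not np.isfinite(arr).all():
            raise ValueError(f"group {g!r} contains non-finite values")
    means = {g: float(a.mean()) for g, a in groups.items()}
    sems = {g: float(a.std(ddof=1) / math.sqrt(a.size)) for g, a in groups.items()}
    all_vals = np.concatenate(list(groups.values()))
    if np.ptp(all_vals) == 0:
        logger.warning("group_anova: zero variance everywhere; reporting p = 1")
        return AnovaResult(F=0.0, p=1.0, group_means=means, group_sems=sems)
    F, p = stats.f_oneway(*groups.values())
    return AnovaResult(F=float(F), p=float(p), group_means=means, group_sems=sems)


def pairwise_welch(
    values: Mapping[str, Sequence[float]], adjust: bool = True
) -> pd.DataFrame:
    """Pairwise Welch t-tests between groups, BH-adjusted by default.

    The post-hoc used for the letter-coded group contrasts; the omnibus
    ANOVA is run separately.
    """
    groups = sorted(values)
    rows = []
    for i, a in enumerate(groups):
        for b in groups[i + 1 :]:
            t, p = stats.ttest_ind(values[a], values[b], equal_var=False)
            rows.append({"group_a": a, "group_b": b, "t": float(t), "p": float(p)})
    df = pd.DataFrame(rows)
    if adjust and len(df):
        df["p_adjusted"] = adjust_bh(df["p"].tolist())
    return df


class PearsonResult(NamedTuple):
    r: float
    p: float
    n: int


def pearson(x: Sequence[float], y: Sequence[float]) -> PearsonResult:
    """Sample Pearson correlation with the two-sided t-transform p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 3:
        raise ValueError(f"Pearson correlation needs n >= 3, got n = {x.size}")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero variance in x or y")
    res = stats.pearsonr(x, y)
    return PearsonResult(r=float(res.statistic), p=float(res.pvalue), n=int(x.size))


class RocResult(NamedTuple):
    auc: float
    ci_low: float
    ci_high: float


def _auc_rank(scores: np.ndarray, labels: np.ndarray) -> float:
    """Mann-Whitney AUC: P(score_pos > score_neg) + 0.5 P(tie)."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    ranks = stats.rankdata(np.concatenate([pos, neg]))
    rank_sum_pos = ranks[: pos.size].sum()
    u = rank_sum_pos - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def roc_auc(
    scores: Sequence[float],
    labels: Sequence[int],
    n_boot: int = 2000,
    seed: int = 0,
) -> RocResult:
    """ROC AUC (rank-sum form, ties counted half) with a percentile
    bootstrap 95% CI over stratified resamples."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if scores.shape != labels.shape:
        raise ValueError("scores and labels must have equal length")
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    n_pos = int((labels == 1).sum())
    n_neg = int((labels == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    auc = _auc_rank(scores, labels)
    rng = np.random.default_rng(seed)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    boot = np.empty(n_boot)
    for i in range(n_boot):
        bp = rng.choice(pos, size=n_pos, replace=True)
        bn = rng.choice(neg, size=n_neg, replace=True)
        boot[i] = _auc_rank(
            np.concatenate([bp, bn]),
            np.concatenate([np.ones(n_pos, int), np.zeros(n_neg, int)]),
        )
    lo, hi = np.percentile(boot, [2.5, 97.5])
    return RocResult(auc=auc, ci_low=float(lo), ci_high=float(hi))


def homa_ir(fasting_insulin_uU_ml: float, fasting_glucose_mg_dl: float) -> float:
    """HOMA-IR = insulin (uU/mL) x fasting glucose (mg/dL) / 405."""
    if fasting_insulin_uU_ml <= 0 or fasting_glucose_mg_dl <= 0:
        raise ValueError("insulin and glucose must be positive")
    return fasting_insulin_uU_ml * fasting_glucose_mg_dl / 405.0


def insulin_ng_to_uU(insulin_ng_ml: float, factor: float = 25.0) -> float:
    """Convert insulin ng/mL to uU/mL (1 ng/mL = 25 uU/mL by default).

    Kept separate from :func:`homa_ir` so the unit conversion — which
    depends on the insulin standard used — is always an explicit step.
    """
    if insulin_ng_ml <= 0:
        raise ValueError("insulin must be positive")
    return insulin_ng_ml * factor


def tolerance_auc(
    timeseries: Iterable[tuple[float, float]],
    incremental: bool = False,
) -> float:
    """Trapezoidal area under a tolerance-test glucose curve (mg/dL * min).

    With ``incremental`` the baseline (time-0 value) is subtracted first,
    giving area above baseline.
    """
    pts = list(timeseries)
    if len(pts) < 2:
        raise ValueError("need >= 2 time points")
    minutes = np.array([t for t, _ in pts], dtype=float)
    glucose = np.array([g for _, g in pts], dtype=float)
    if not np.all(np.diff(minutes) > 0):
        raise ValueError("minutes must be strictly increasing")
    if incremental:
        glucose = glucose - glucose[0]
    return float(np.trapezoid(glucose, minutes))


@dataclass(frozen=True)
class PhenotypePanel:
    """Fasting glucose/insulin and a tolerance-test time course for one animal."""

    sample_id: str
    fasting_glucose: float  # mg/dL
    fasting_insulin: float  # uU/mL
    timeseries: tuple[tuple[float, float], ...] = ()

    def __post_init__(self) -> None:
        if self.fasting_glucose <= 0 or self.fasting_insulin <= 0:
            raise ValueError(
                f"{self.sample_id}: fasting values must be positive"
            )
        minutes = [t for t, _ in self.timeseries]
        if any(b <= a for a, b in zip(minutes, minutes[1:])):
            raise ValueError(f"{self.sample_id}: minutes not strictly increasing")

    @property
    def homa_ir(self) -> float:
        return homa_ir(self.fasting_insulin, self.fasting_glucose)


def read_phenotypes(path: str | Path) -> list[PhenotypePanel]:
    """Read a phenotype TSV: sample, group, fasting_glucose, fasting_insulin,
    glucose_0, glucose_30, ... columns give the time course."""
    df = pd.read_csv(path, sep="\t")
    time_cols = sorted(
        (c for c in df.columns if c.startswith("glucose_")),
        key=lambda c: float(c.split("_", 1)[1]),
    )
    panels = []
    for row in df.to_dict("records"):
        ts = tuple(
            (float(c.split("_", 1)[1]), float(row[c]))
            for c in time_cols
            if not pd.isna(row[c])
        )
        panels.append(
            PhenotypePanel(
                sample_id=str(row["sample"]),
                fasting_glucose=float(row["fasting_glucose"]),
                fasting_insulin=float(row["fasting_insulin"]),
                timeseries=ts,
            )
        )
    return panels
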