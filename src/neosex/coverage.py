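"""Coverage-based detection of W-gametolog loss.

In a ZW female, a gene whose W copy has been deleted is hemizygous: female
DNA coverage drops to half the male level. After normalizing per-sample
coverage by total library size, transcripts where female coverage is below
70% of male coverage are flagged as W-absent and removed from gametolog
analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

W_ABSENT_THRESHOLD = 0.7


@dataclass
class CoverageRecord:
    transcript_id: str
    female_mean: float
    male_mean: float
    fm_ratio: float
    w_absent: bool


def library_size_factors(totals: pd.Series) -> pd.Series:
    """Per-sample multipliers: largest library / sample library.

    The sample with the most aligned reads gets factor 1.0; smaller
    libraries are scaled up.
    """
    totals = totals.astype(float)
    if (totals <= 0).any():
        bad = totals.index[totals <= 0].tolist()
        raise ValueError(f"non-positive library totals for samples: {bad}")
    return totals.max() / totals


def transcript_coverage(
    counts: pd.DataFrame,
    factors: pd.Series,
    sexes: dict[str, str],
    threshold: float = W_ABSENT_THRESHOLD,
) -> pd.DataFrame:
    """Normalized per-transcript coverage with female/male ratio.

    ``counts`` is long format with columns sample, exon_id, transcript_id,
    count, exon_length. Per-exon depth is factor x count / exon_length;
    the transcript value is the unweighted mean over its exons; sex means
    average over samples of each sex. Returns one row per transcript with
    female_mean, male_mean, fm_ratio and the w_absent flag
    (fm_ratio < threshold, strict).
    """
    required = {"sample", "exon_id", "transcript_id", "count", "exon_length"}
    if not required.issubset(counts.columns):
        raise ValueError(f"coverage table must have columns {sorted(required)}")
    df = counts.copy()
    unknown = set(df["sample"]) - set(factors.index)
    if unknown:
        raise ValueError(f"samples without library factors: {sorted(unknown)}")
    df["depth"] = df["count"] / df["exon_length"] * df["sample"].map(factors)

    # unweighted mean over exons, per transcript and sample
    per_tx = (
        df.groupby(["transcript_id", "sample"], sort=True)["depth"]
        .mean()
        .reset_index()
    )
    if per_tx.groupby("transcript_id")["sample"].count().eq(0).any():
        raise ValueError("transcript with zero exons")
    per_tx["sex"] = per_tx["sample"].map(sexes)
    if per_tx["sex"].isna().any():
        bad = per_tx.loc[per_tx["sex"].isna(), "sample"].unique().tolist()
        raise ValueError(f"samples without sex labels: {bad}")
    sex_means = (
        per_tx.groupby(["transcript_id", "sex"])["depth"].mean().unstack("sex")
    )
    out = pd.DataFrame(
        {
            "transcript_id": sex_means.index,
            "female_mean": sex_means.get("F"),
            "male_mean": sex_means.get("M"),
        }
    ).reset_index(drop=True)
    out["fm_ratio"] = out["female_mean"] / out["male_mean"]
    out["w_absent"] = out["fm_ratio"] < threshold
    return out


def filter_w_absent(
    records: pd.DataFrame, threshold: float = W_ABSENT_THRESHOLD
) -> tuple[list[str], list[str]]:
    """Split transcript ids into (retained, removed) by the coverage rule.

    Removal is strict: fm_ratio < threshold. A ratio exactly at the
    threshold is retained.
    """
    if records.empty:
        return [], []
    removed = records.loc[records["fm_ratio"] < threshold, "transcript_id"]
    retained = records.loc[records["fm_ratio"] >= threshold, "transcript_id"]
    return retained.tolist(), removed.tolist()


def write_coverage_report(records: pd.DataFrame, path: str | Path) -> None:
    records.to_csv(path, sep="\t", index=False, float_format="%.6g")
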