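"""Relative quantification of qPCR Ct tables by the ddCt method.

Workflow: collapse technical replicates (with explicit non-detect policy),
screen candidate reference genes for inter-sample stability, then compute
per-sample fold changes 2^(-ddCt) against a calibrator group. Amplification
efficiency is fixed at 2 (no efficiency correction).

Ct tables are long-format pandas DataFrames with columns
``sample_id, line, treatment, dpi, gene, tech_rep, ct, nondetect``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ConfigurationError, DegenerateInputError

__all__ = [
    "CT_CYCLE_LIMIT",
    "ReferenceScreenResult",
    "FoldChangeResult",
    "read_ct_table",
    "validate_ct_table",
    "collapse_technical",
    "screen_reference",
    "delta_delta_ct",
]

CT_CYCLE_LIMIT = 40.0  # reactions run 40 amplification cycles
REQUIRED_COLUMNS = ("sample_id", "gene", "tech_rep", "ct", "nondetect")
GROUP_COLUMNS = ("line", "treatment", "dpi")


@dataclass
class ReferenceScreenResult:
    """Stability verdicts for candidate reference genes."""

    per_gene: pd.DataFrame  # gene, inter_sample_ct_range, fold_scale_range, verdict
    threshold_fold: float

    def verdict(self, gene: str) -> str:
        row = self.per_gene[self.per_gene["gene"] == gene]
        if row.empty:
            raise KeyError(f"gene {gene!r} was not screened")
        return str(row["verdict"].iloc[0])

    def suitable(self) -> list[str]:
        return list(self.per_gene.loc[self.per_gene["verdict"] == "suitable", "gene"])


@dataclass
class FoldChangeResult:
    """Per-sample ddCt fold changes for one target gene."""

    target_gene: str
    reference_gene: str
    calibrator: dict
    per_sample: pd.DataFrame  # sample_id, group cols, delta_ct, delta_delta_ct, fold_change, flags

    def fold(self, sample_id: str) -> float:
        row = self.per_sample[self.per_sample["sample_id"] == sample_id]
        if row.empty:
            raise KeyError(f"sample {sample_id!r} not in result")
        return float(row["fold_change"].iloc[0])


def read_ct_table(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    return validate_ct_table(df)


def validate_ct_table(df: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ConfigurationError(f"Ct table missing columns: {missing}")
    df = df.copy()
    df["nondetect"] = df["nondetect"].astype(bool)
    detected = df.loc[~df["nondetect"], "ct"]
    if detected.isna().any():
        raise ConfigurationError("detected rows must carry a Ct value")
    if ((detected <= 0) | (detected > CT_CYCLE_LIMIT)).any():
        raise ConfigurationError(f"Ct values must lie in (0, {CT_CYCLE_LIMIT}]")
    for col in GROUP_COLUMNS:
        if col not in df.columns:
            df[col] = "" if col != "dpi" else 0
    return df


def collapse_technical(df: pd.DataFrame, policy: str = "impute_limit") -> pd.DataFrame:
    """Mean Ct of detected technical replicates per (sample, gene).

    All-non-detect groups are imputed at the cycle limit (``impute_limit``)
    or excluded (``drop``); either way the ``all_nondetect`` flag is set and
    partial non-detects set ``nondetect_dropped``. Never silent.
    """
    if policy not in ("impute_limit", "drop"):
        raise ConfigurationError(f"unknown non-detect policy {policy!r}")
    df = validate_ct_table(df)
    group_cols = ["sample_id"] + [c for c in GROUP_COLUMNS if c in df.columns] + ["gene"]
    out_rows = []
    for keys, sub in df.groupby(group_cols, sort=False):
        detected = sub.loc[~sub["nondetect"], "ct"]
        rec = dict(zip(group_cols, keys))
        rec["n_technical"] = len(sub)
        rec["nondetect_dropped"] = bool(sub["nondetect"].any()) and len(detected) > 0
        rec["all_nondetect"] = len(detected) == 0
        if len(detected) > 0:
            rec["ct"] = float(detected.mean())
        elif policy == "impute_limit":
            rec["ct"] = CT_CYCLE_LIMIT
        else:
            continue
        out_rows.append(rec)
    return pd.DataFrame(out_rows)


def screen_reference(
    df: pd.DataFrame,
    candidate_genes: list[str],
    threshold_fold: float = 2.0,
) -> ReferenceScreenResult:
    """Rate candidate reference genes by inter-sample Ct stability.

    For each candidate, the range of per-sample mean Cts is converted to a
    fold scale 2^range; genes exceeding ``threshold_fold`` are unsuitable.
    Raises if no candidate passes.
    """
    collapsed = collapse_technical(df, policy="impute_limit")
    rows = []
    samples = set(collapsed["sample_id"])
    for gene in candidate_genes:
        sub = collapsed[collapsed["gene"] == gene]
        if set(sub["sample_id"]) != samples:
            raise ConfigurationError(
                f"candidate {gene!r} not measured in every sample"
            )
        ct_range = float(sub["ct"].max() - sub["ct"].min())
        fold_scale = float(2.0**ct_range)
        rows.append(
            {
                "gene": gene,
                "inter_sample_ct_range": ct_range,
                "fold_scale_range": fold_scale,
                "verdict": "unsuitable" if fold_scale > threshold_fold else "suitable",
            }
        )
    result = ReferenceScreenResult(
        per_gene=pd.DataFrame(rows), threshold_fold=threshold_fold
    )
    if not result.suitable():
        raise DegenerateInputError(
            "no suitable reference gene among candidates "
            f"{candidate_genes} at threshold {threshold_fold}"
        )
    return result


def _match_calibrator(collapsed: pd.DataFrame, calibrator: dict) -> pd.Series:
    mask = pd.Series(True, index=collapsed.index)
    for key, value in calibrator.items():
        if key not in collapsed.columns:
            raise ConfigurationError(f"calibrator key {key!r} not a table column")
        col = collapsed[key]
        if key == "dpi":
            mask &= col.astype(int) == int(value)
        else:
            mask &= col.astype(str) == str(value)
    return mask


def delta_delta_ct(
    df: pd.DataFrame,
    target_gene: str,
    reference_gene: str,
    calibrator: dict,
    nondetect_policy: str = "impute_limit",
) -> FoldChangeResult:
    """Livak ddCt fold change of ``target_gene`` against a calibrator group.

    Per sample: dCt = Ct_target - Ct_reference; ddCt = dCt minus the
    arithmetic mean dCt over calibrator samples; fold = 2^(-ddCt). One record
    per sample (per retina in the source design).
    """
    collapsed = collapse_technical(df, policy=nondetect_policy)
    genes = set(collapsed["gene"])
    for g in (target_gene, reference_gene):
        if g not in genes:
            raise ConfigurationError(f"gene {g!r} not in table")

    wide = collapsed.pivot_table(
        index=["sample_id"] + [c for c in GROUP_COLUMNS if c in collapsed.columns],
        columns="gene",
        values="ct",
        aggfunc="first",
    ).reset_index()
    flags = (
        collapsed[collapsed["gene"] == target_gene]
        .set_index("sample_id")[["nondetect_dropped", "all_nondetect"]]
        .to_dict("index")
    )
    if wide[reference_gene].isna().any():
        raise ConfigurationError(f"reference gene {reference_gene!r} missing in some sample")

    wide = wide[wide[target_gene].notna()].copy()
    wide["delta_ct"] = wide[target_gene] - wide[reference_gene]

    cal_mask = _match_calibrator(wide, calibrator)
    cal = wide[cal_mask]
    if cal.empty:
        raise ConfigurationError(f"calibrator selector {calibrator} matches no sample")
    cal_flags = [flags.get(s, {}) for s in cal["sample_id"]]
    if cal_flags and all(f.get("all_nondetect", False) for f in cal_flags):
        raise DegenerateInputError(
            f"calibrator group {calibrator} is entirely non-detect for {target_gene!r}"
        )
    cal_mean = float(cal["delta_ct"].mean())
    wide["delta_delta_ct"] = wide["delta_ct"] - cal_mean
    wide["fold_change"] = 2.0 ** (-wide["delta_delta_ct"])
    wide["is_calibrator"] = cal_mask
    wide["nondetect_dropped"] = [
        flags.get(s, {}).get("nondetect_dropped", False) for s in wide["sample_id"]
    ]
    wide["all_nondetect"] = [
        flags.get(s, {}).get("all_nondetect", False) for s in wide["sample_id"]
    ]

    cols = (
        ["sample_id"]
        + [c for c in GROUP_COLUMNS if c in wide.columns]
        + [
            "delta_ct",
            "delta_delta_ct",
            "fold_change",
            "is_calibrator",
            "nondetect_dropped",
            "all_nondetect",
        ]
    )
    return FoldChangeResult(
        target_gene=target_gene,
        reference_gene=reference_gene,
        calibrator=dict(calibrator),
        per_sample=wide[cols].reset_index(drop=True),
    )
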