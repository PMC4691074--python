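"""qPCR relative quantification by the comparative 2^-ddCt method.

dCt = Ct(target) - Ct(reference gene); ddCt = mean dCt(sample) - mean
dCt(calibrator); fold change rq = 2^-ddCt (amplification efficiency fixed at
2.0). Significance is a two-sided t-test on replicate dCt values against the
calibrator replicates — Welch by default, pooled-variance optionally. Calls
require both the fold threshold and p < alpha. A BH-FDR column is reported
for transparency but never drives calls, matching per-gene star annotation
practice.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core_io import CtTable

__all__ = [
    "delta_ct",
    "relative_quantification",
    "analyze",
    "log2_report",
]


def delta_ct(ct_target: float, ct_reference: float) -> float:
    """Normalize target Ct to the reference gene: dCt = Ct_t - Ct_ref."""
    return ct_target - ct_reference


def relative_quantification(sample_dct: float, calibrator_dct: float) -> tuple[float, float]:
    """(ddCt, fold change 2^-ddCt) of a sample relative to the calibrator."""
    ddct = sample_dct - calibrator_dct
    return ddct, 2.0 ** (-ddct)


def _stars(p: float) -> str:
    if not np.isfinite(p):
        return ""
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def _sample_key(condition: str, timepoint: str) -> str:
    return f"{condition}:{timepoint}"


def analyze(
    ct: CtTable,
    calibrator: str | dict[str, str],
    fold_threshold: float = 2.0,
    alpha: float = 0.05,
    test: str = "welch",
) -> pd.DataFrame:
    """Relative expression for every (gene, condition, timepoint) cell.

    ``calibrator`` is a sample key "condition:timepoint" (e.g. "CK:0h"),
    or a gene -> key mapping for per-gene calibrators. Output columns:
    gene, condition, timepoint, n, delta_ct, ddct, rq, log2_rq, p_value,
    p_bh, call (up/down/ns/na), stars. With a single replicate per cell the
    fold change is still reported but p, call, and stars are unavailable.
    """
    if test not in ("welch", "pooled"):
        raise ValueError(f"unknown test {test!r}")
    df = ct.data.copy()
    df["dct"] = df["ct_target"].astype(float) - df["ct_reference"].astype(float)
    df["key"] = [_sample_key(c, t) for c, t in zip(df["condition"], df["timepoint"])]

    rows = []
    for gene, gdf in df.groupby("gene", sort=True):
        cal_key = calibrator[gene] if isinstance(calibrator, dict) else calibrator
        cal = gdf.loc[gdf["key"] == cal_key, "dct"].to_numpy()
        if cal.size == 0:
            raise ValueError(f"{gene}: calibrator sample {cal_key!r} not found")
        cal_mean = float(cal.mean())
        for (cond, tp), cell in gdf.groupby(["condition", "timepoint"], sort=True):
            x = cell["dct"].to_numpy()
            ddct, rq = relative_quantification(float(x.mean()), cal_mean)
            if x.size >= 2 and cal.size >= 2:
                if _sample_key(cond, tp) == cal_key:
                    p = 1.0
                else:
                    res = stats.ttest_ind(x, cal, equal_var=(test == "pooled"))
                    p = float(res.pvalue)
                    if not np.isfinite(p):  # zero variance in both groups
                        p = 1.0 if np.isclose(x.mean(), cal.mean()) else 0.0
                if p < alpha and rq >= fold_threshold:
                    call = "up"
                elif p < alpha and rq <= 1.0 / fold_threshold:
                    call = "down"
                else:
                    call = "ns"
            else:
                p, call = np.nan, "na"
            rows.append(
                {
                    "gene": gene,
                    "condition": cond,
                    "timepoint": tp,
                    "n": int(x.size),
                    "delta_ct": float(x.mean()),
                    "ddct": ddct,
                    "rq": rq,
                    "log2_rq": -ddct,
                    "p_value": p,
                    "call": call,
                    "stars": _stars(p) if call != "na" else "",
                }
            )
    out = pd.DataFrame(rows)
    tested = out["p_value"].notna()
    out["p_bh"] = np.nan
    if tested.any():
        out.loc[tested, "p_bh"] = multipletests(out.loc[tested, "p_value"], method="fdr_bh")[1]
    return out


def log2_report(rq_values: pd.Series | np.ndarray, dynamic_range: float = 100.0) -> pd.DataFrame:
    """log2-transform fold changes; flag values spanning a wide dynamic range.

    Genes whose fold change magnitude exceeds ``dynamic_range`` (or falls
    below its reciprocal) are flagged for log-scale display.
    """
    rq = np.asarray(rq_values, dtype=float)
    if (rq <= 0).any():
        raise ValueError("fold changes must be > 0")
    return pd.DataFrame(
        {
            "rq": rq,
            "log2_rq": np.log2(rq),
            "log_display": (rq > dynamic_range) | (rq < 1.0 / dynamic_range),
        }
    )
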