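"""Relative mRNA quantification from qPCR Ct tables (dCt / ddCt).

Implements the classical relative-quantification methods with amplification
efficiency fixed at 2: the dCt method (abundance relative to an untreated
baseline sample) and the ddCt method (additionally cross-normalized to a
non-decaying reference gene such as RPLP0), plus Welch t-tests for condition
contrasts on log2 abundances. Replicates are averaged in Ct (log) space before
exponentiation; SDs are propagated to the fold scale by the first-order delta
method, sd(value) = ln2 * value * sd(Ct).
"""

from __future__ import annotations

import logging
import math

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)

LN2 = math.log(2.0)
_REQUIRED = ["gene", "condition", "time", "replicate", "ct"]


def _check_table(table: pd.DataFrame) -> None:
    missing = set(_REQUIRED) - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing columns: {sorted(missing)}")
    if not np.isfinite(table["ct"]).all() or (table["ct"] <= 0).any():
        raise ValueError("Ct values must be finite and > 0")


def _collapse(table: pd.DataFrame) -> pd.DataFrame:
    """Replicate mean/sd/n of Ct per (gene, condition, time)."""
    g = table.groupby(["gene", "condition", "time"], sort=True)["ct"]
    out = g.agg(ct_mean="mean", ct_sd="std", n="count").reset_index()
    out["ct_sd"] = out["ct_sd"].fillna(0.0)
    return out


def relative_abundance_dct(table: pd.DataFrame, baseline_time: float = 0.0,
                           collapse_replicates: bool = True) -> pd.DataFrame:
    """Abundance relative to the baseline sample by the dCt method.

    value = 2^-(Ct_sample - Ct_baseline), per (gene, condition, time); the
    baseline (default the untreated t = 0 sample of the same condition) maps to
    1 by construction. With ``collapse_replicates=False`` per-replicate values
    are returned (for downstream t-tests), baselined against the replicate-mean
    baseline Ct.
    """
    _check_table(table)
    stats = _collapse(table)
    base = stats[stats["time"] == baseline_time].set_index(["gene", "condition"])["ct_mean"]
    if base.empty:
        raise ValueError(f"no baseline samples at time {baseline_time}")
    missing = set(zip(stats["gene"], stats["condition"])) - set(base.index)
    if missing:
        raise ValueError(f"baseline missing for: {sorted(missing)}")
    if collapse_replicates:
        dct = stats["ct_mean"].to_numpy() - base.loc[
            list(zip(stats["gene"], stats["condition"]))].to_numpy()
        value = 2.0 ** (-dct)
        return pd.DataFrame({
            "gene": stats["gene"], "condition": stats["condition"], "time": stats["time"],
            "value": value, "sd": LN2 * value * stats["ct_sd"].to_numpy(), "n": stats["n"],
        })
    rows = table.copy()
    rows["value"] = 2.0 ** -(rows["ct"].to_numpy()
                             - base.loc[list(zip(rows["gene"], rows["condition"]))].to_numpy())
    return rows[["gene", "condition", "time", "replicate", "value"]]


def relative_abundance_ddct(table: pd.DataFrame, reference_gene: str,
                            baseline_time: float = 0.0,
                            collapse_replicates: bool = True) -> pd.DataFrame:
    """Abundance by the ddCt method with reference-gene cross-normalization.

    value = 2^-[(Ct_g - Ct_ref)_sample - (Ct_g - Ct_ref)_baseline]. Exactly
    invariant to any per-sample Ct offset (plate effects), since the offset
    cancels in Ct_g - Ct_ref.
    """
    _check_table(table)
    if reference_gene not in set(table["gene"]):
        raise ValueError(f"reference gene {reference_gene!r} not in table")
    stats = _collapse(table)
    ref = stats[stats["gene"] == reference_gene].set_index(["condition", "time"])["ct_mean"]
    samples = set(zip(stats["condition"], stats["time"]))
    if samples - set(ref.index):
        raise ValueError(f"reference gene missing in samples: {sorted(samples - set(ref.index))}")
    targets = stats[stats["gene"] != reference_gene].copy()
    targets["dct"] = targets["ct_mean"].to_numpy() - ref.loc[
        list(zip(targets["condition"], targets["time"]))].to_numpy()
    base = targets[targets["time"] == baseline_time].set_index(["gene", "condition"])["dct"]
    if base.empty:
        raise ValueError(f"no baseline samples at time {baseline_time}")
    missing = set(zip(targets["gene"], targets["condition"])) - set(base.index)
    if missing:
        raise ValueError(f"baseline missing for: {sorted(missing)}")
    if collapse_replicates:
        ddct = targets["dct"].to_numpy() - base.loc[
            list(zip(targets["gene"], targets["condition"]))].to_numpy()
        value = 2.0 ** (-ddct)
        return pd.DataFrame({
            "gene": targets["gene"], "condition": targets["condition"], "time": targets["time"],
            "value": value, "sd": LN2 * value * targets["ct_sd"].to_numpy(), "n": targets["n"],
        })
    # per replicate: pair the target replicate with the reference replicate of
    # the same sample (fall back to the sample-mean reference Ct if unpaired)
    ref_rep = table[table["gene"] == reference_gene].set_index(
        ["condition", "time", "replicate"])["ct"]
    rows = table[table["gene"] != reference_gene].copy()
    keys = list(zip(rows["condition"], rows["time"], rows["replicate"]))
    ref_vals = np.array([
        ref_rep.get(k, ref.get(k[:2], np.nan)) for k in keys
    ])
    rows["dct"] = rows["ct"].to_numpy() - ref_vals
    rows["value"] = 2.0 ** -(rows["dct"].to_numpy()
                             - base.loc[list(zip(rows["gene"], rows["condition"]))].to_numpy())
    return rows[["gene", "condition", "time", "replicate", "value"]]


def _stars(p: float) -> str:
    if not math.isfinite(p):
        return ""
    if p < 0.005:
        return "**"
    if p < 0.05:
        return "*"
    return ""


def condition_contrast(abundances: pd.DataFrame, groups: tuple[str, str],
                       group_col: str = "condition") -> pd.DataFrame:
    """Welch two-sample t-test on log2 abundances per (gene, time).

    ``abundances`` must carry per-replicate values (see
    ``collapse_replicates=False``). Effect = mean log2 difference
    (groups[1] - groups[0]); stars: * p < 0.05, ** p < 0.005. Groups with a
    single replicate yield p = NaN with a warning.
    """
    if "value" not in abundances.columns:
        raise ValueError("abundances must have a 'value' column")
    if (abundances["value"] <= 0).any():
        raise ValueError("abundances must be positive")
    rows = []
    for (gene, t), grp in abundances.groupby(["gene", "time"], sort=True):
        a = np.log2(grp.loc[grp[group_col] == groups[0], "value"].to_numpy())
        b = np.log2(grp.loc[grp[group_col] == groups[1], "value"].to_numpy())
        if len(a) == 0 or len(b) == 0:
            continue
        effect = float(b.mean() - a.mean())
        if len(a) < 2 or len(b) < 2:
            logger.warning("single replicate for (%s, %s); p-value undefined", gene, t)
            p = float("nan")
        elif np.ptp(a) == 0 and np.ptp(b) == 0:
            p = 1.0 if effect == 0 else 0.0
        else:
            p = float(sps.ttest_ind(b, a, equal_var=False).pvalue)
        rows.append({"gene": gene, "time": t, "log2_effect": effect, "p_value": p,
                     "stars": _stars(p), "n_a": len(a), "n_b": len(b)})
    return pd.DataFrame(rows)


def fit_half_life(abundance: pd.DataFrame) -> pd.DataFrame:
    """Log-linear fit of relative abundance vs time -> decay rate and half-life.

    Expects collapsed abundances (gene, condition, time, value); fits
    ln(value) = -lambda * t per (gene, condition) by OLS.
    """
    rows = []
    for (gene, cond), grp in abundance.groupby(["gene", "condition"], sort=True):
        t = grp["time"].to_numpy(dtype=float)
        y = np.log(grp["value"].to_numpy(dtype=float))
        if len(t) < 2:
            continue
        slope = float(np.polyfit(t, y, 1)[0])
        lam = -slope
        rows.append({"gene": gene, "condition": cond, "decay_rate": lam,
                     "half_life": LN2 / lam if lam > 0 else float("inf")})
    return pd.DataFrame(rows)
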