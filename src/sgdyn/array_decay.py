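"""Array-based bulk mRNA-decay analysis.

Pipeline for ActD-chase expression matrices: keep probes reliably detected in
all untreated samples (detection p < 0.001), subtract a per-sample background,
quantile-normalize, regress non-log intensity on time per transcript and
condition (the decay "slope"), correlate slopes between conditions (Pearson),
and classify knockdown/control log2 ratios under stress vs no stress into the
2-fold scatter classes (green / red / blue / none).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats as sps

from .synthetic import ExpressionMatrix

logger = logging.getLogger(__name__)


def _untreated_samples(matrix: ExpressionMatrix) -> list[str]:
    meta = matrix.sample_meta
    sel = meta["time"] == 0
    if "stress" in meta.columns:
        sel = sel & ~meta["stress"].astype(bool)
    samples = meta.index[sel].tolist()
    if not samples:
        raise ValueError("no untreated samples (time == 0) in metadata")
    return samples


def filter_reliable(matrix: ExpressionMatrix, alpha: float = 0.001,
                    rule: str = "pvalue") -> list[str]:
    """Transcripts reliably detected in ALL untreated samples.

    ``rule='pvalue'``: detection p < alpha in every untreated sample.
    ``rule='present_call'``: detection_p interpreted as a present(1)/absent(0)
    call matrix; a transcript must be present in all untreated samples.
    """
    untreated = _untreated_samples(matrix)
    p = matrix.detection_p[untreated]
    if rule == "pvalue":
        keep = (p < alpha).all(axis=1)
    elif rule == "present_call":
        keep = (p > 0).all(axis=1)
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return matrix.intensities.index[keep].tolist()


def background_correct(matrix: ExpressionMatrix, quantile: float = 0.05,
                       epsilon: float = 1e-6) -> tuple[ExpressionMatrix, pd.Series]:
    """Subtract a per-sample background (default: the 5th percentile), floor at
    a small positive epsilon; returns the corrected matrix and the offsets."""
    offsets = matrix.intensities.quantile(quantile, axis=0)
    corrected = (matrix.intensities - offsets).clip(lower=epsilon)
    degenerate = matrix.intensities.nunique(axis=0) == 1
    if degenerate.any():
        logger.warning("all-equal samples after correction: %s",
                       list(matrix.intensities.columns[degenerate]))
    return ExpressionMatrix(corrected, matrix.detection_p.copy(),
                            matrix.sample_meta.copy()), offsets


def quantile_normalize(matrix: ExpressionMatrix | pd.DataFrame
                       ) -> ExpressionMatrix | pd.DataFrame:
    """Force every sample onto the cross-sample mean quantile distribution.

    Each sample's sorted vector becomes the column-wise mean of all sorted
    vectors; ties receive the mean of their would-be quantiles (average ranks,
    linearly interpolated). Row and column counts are preserved.
    """
    df = matrix.intensities if isinstance(matrix, ExpressionMatrix) else matrix
    if df.shape[1] < 2:
        raise ValueError("quantile normalization needs >= 2 samples")
    values = df.to_numpy(dtype=float)
    sorted_means = np.sort(values, axis=0).mean(axis=1)
    ranks = pd.DataFrame(values).rank(method="average").to_numpy()
    grid = np.arange(1, values.shape[0] + 1, dtype=float)
    out = np.empty_like(values)
    for j in range(values.shape[1]):
        out[:, j] = np.interp(ranks[:, j], grid, sorted_means)
    normed = pd.DataFrame(out, index=df.index, columns=df.columns)
    if isinstance(matrix, ExpressionMatrix):
        return ExpressionMatrix(normed, matrix.detection_p.copy(), matrix.sample_meta.copy())
    return normed


def decay_slopes(matrix: ExpressionMatrix, transcripts: list[str] | None = None,
                 on_replicate_means: bool = True) -> pd.DataFrame:
    """OLS decay slope of non-log intensity vs time (minutes), per transcript
    and condition.

    By default replicates are averaged per time point before the fit; with
    ``on_replicate_means=False`` every replicate sample enters the regression.
    Returns a tidy frame (transcript, condition, slope, intercept, r_squared,
    n_times). Requires >= 3 time points per condition.
    """
    intens = matrix.intensities if transcripts is None else matrix.intensities.loc[transcripts]
    meta = matrix.sample_meta
    rows = []
    for cond, cmeta in meta.groupby("condition", sort=True):
        times = np.sort(cmeta["time"].unique())
        if len(times) < 3:
            raise ValueError(f"condition {cond!r} has {len(times)} time points; need >= 3")
        if on_replicate_means:
            y = np.column_stack([
                intens[cmeta.index[cmeta["time"] == t]].mean(axis=1).to_numpy()
                for t in times
            ])
            t_vec = times.astype(float)
        else:
            cols = cmeta.index.tolist()
            y = intens[cols].to_numpy(dtype=float)
            t_vec = cmeta.loc[cols, "time"].to_numpy(dtype=float)
        tc = t_vec - t_vec.mean()
        denom = float(tc @ tc)
        ym = y.mean(axis=1, keepdims=True)
        slope = (y - ym) @ tc / denom
        intercept = ym[:, 0] - slope * t_vec.mean()
        pred = intercept[:, None] + np.outer(slope, t_vec)
        ss_res = ((y - pred) ** 2).sum(axis=1)
        ss_tot = ((y - ym) ** 2).sum(axis=1)
        with np.errstate(invalid="ignore", divide="ignore"):
            r2 = np.where(ss_tot > 0, 1.0 - ss_res / ss_tot, 0.0)
        for i, tr in enumerate(intens.index):
            rows.append((tr, cond, slope[i], intercept[i], r2[i], len(times)))
    return pd.DataFrame(rows, columns=["transcript", "condition", "slope",
                                       "intercept", "r_squared", "n_times"])


def slope_correlation(slopes_a: pd.Series | pd.DataFrame, slopes_b: pd.Series | pd.DataFrame
                      ) -> tuple[float, pd.DataFrame]:
    """Pearson r between two per-transcript slope vectors on shared transcripts.

    Accepts Series indexed by transcript (or tidy decay_slopes frames filtered
    to one condition each, using their 'transcript'/'slope' columns). Returns
    (r, paired table); r is NaN with a warning when either vector has zero
    variance.
    """
    def as_series(s):
        if isinstance(s, pd.DataFrame):
            return s.set_index("transcript")["slope"]
        return s
    a, b = as_series(slopes_a), as_series(slopes_b)
    shared = a.index.intersection(b.index)
    if len(shared) < 3:
        raise ValueError("need >= 3 shared transcripts")
    paired = pd.DataFrame({"slope_a": a.loc[shared], "slope_b": b.loc[shared]})
    if paired["slope_a"].nunique() == 1 or paired["slope_b"].nunique() == 1:
        logger.warning("zero variance in a slope vector; correlation undefined")
        return float("nan"), paired
    r = float(sps.pearsonr(paired["slope_a"], paired["slope_b"]).statistic)
    return r, paired


def classify_fold_change(matrix: ExpressionMatrix, knockdown: str = "siSG",
                         control: str = "siC", mode: str = "chebyshev",
                         fold_threshold: float = 1.0, unchanged_threshold: float = 1.0
                         ) -> tuple[pd.DataFrame, dict[str, int], dict[str, int]]:
    """Classify knockdown/control log2 ratios under stress vs no stress.

    (x, y) = (log2 knockdown/control without stress, same with stress), on
    replicate-mean intensities. Classes (mutually exclusive, red/blue take
    precedence over green):

    * red   — y <= -fold_threshold and |x| < unchanged_threshold (selectively
      down during stress);
    * blue  — y >= +fold_threshold and |x| < unchanged_threshold (selectively
      up during stress);
    * green — at least 2-fold from the origin in any direction
      (``mode='chebyshev'``: max(|x|, |y|) >= fold_threshold;
      ``mode='euclidean'``: sqrt(x^2 + y^2) >= fold_threshold);
    * none  — otherwise.

    Returns (records, class counts, quadrant counts of >=2-fold transcripts).
    Transcripts with a nonpositive group mean are excluded with a warning.
    """
    meta = matrix.sample_meta
    if "stress" not in meta.columns:
        raise ValueError("sample_meta must have a boolean 'stress' column")
    means = {}
    for cond in (control, knockdown):
        for stressed in (False, True):
            cols = meta.index[(meta["condition"] == cond)
                              & (meta["stress"].astype(bool) == stressed)]
            if len(cols) == 0:
                raise ValueError(f"no samples for condition={cond!r}, stress={stressed}")
            means[(cond, stressed)] = matrix.intensities[cols].mean(axis=1)
    ok = pd.concat(means.values(), axis=1).gt(0).all(axis=1)
    if (~ok).any():
        logger.warning("%d transcripts excluded (nonpositive group mean)", int((~ok).sum()))
    x = np.log2(means[(knockdown, False)][ok] / means[(control, False)][ok])
    y = np.log2(means[(knockdown, True)][ok] / means[(control, True)][ok])
    records = pd.DataFrame({"transcript": x.index, "log2_ratio_nostress": x.to_numpy(),
                            "log2_ratio_stress": y.to_numpy()})
    xv, yv = records["log2_ratio_nostress"].to_numpy(), records["log2_ratio_stress"].to_numpy()
    if mode == "chebyshev":
        two_fold = np.maximum(np.abs(xv), np.abs(yv)) >= fold_threshold
    elif mode == "euclidean":
        two_fold = np.hypot(xv, yv) >= fold_threshold
    else:
        raise ValueError(f"unknown mode {mode!r}")
    red = (yv <= -fold_threshold) & (np.abs(xv) < unchanged_threshold)
    blue = (yv >= fold_threshold) & (np.abs(xv) < unchanged_threshold)
    cls = np.where(red, "red", np.where(blue, "blue", np.where(two_fold, "green", "none")))
    records["class"] = cls
    class_counts = {c: int((cls == c).sum()) for c in ("green", "red", "blue", "none")}
    quadrant = {"I": 0, "II": 0, "III": 0, "IV": 0}
    for xi, yi, tf in zip(xv, yv, two_fold):
        if not tf:
            continue
        if xi >= 0 and yi >= 0:
            quadrant["I"] += 1
        elif xi < 0 and yi >= 0:
            quadrant["II"] += 1
        elif xi < 0 and yi < 0:
            quadrant["III"] += 1
        else:
            quadrant["IV"] += 1
    return records, class_counts, quadrant
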