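"""File I/O: TIFF images/masks, trace CSVs, expression matrices.

Images travel as multi-page TIFF (one page per channel) with the label mask as
a separate 16-bit TIFF; traces and tables as headered CSV. Floats are written
at fixed precision so reruns are byte-identical.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .synthetic import ExchangeTrace, ExpressionMatrix, GranuleField

FLOAT_FORMAT = "%.10g"


def write_csv(df: pd.DataFrame, path: str | Path, index: bool = False) -> None:
    df.to_csv(path, index=index, float_format=FLOAT_FORMAT)


def save_field(field: GranuleField, image_path: str | Path, mask_path: str | Path,
               truth_path: str | Path | None = None) -> None:
    tifffile.imwrite(image_path, np.asarray(field.image, dtype=np.float32))
    tifffile.imwrite(mask_path, np.asarray(field.cell_mask, dtype=np.uint16))
    if truth_path is not None and field.truth is not None:
        write_csv(field.truth, truth_path)


def load_field(image_path: str | Path, mask_path: str | Path,
               metadata: dict | None = None) -> GranuleField:
    image = tifffile.imread(image_path).astype(float)
    if image.ndim == 3:     # multi-channel stack: use the first page
        image = image[0]
    mask = tifffile.imread(mask_path).astype(np.uint16)
    return GranuleField(image=image, cell_mask=mask, metadata=metadata or {})


def save_trace(trace: ExchangeTrace, path: str | Path) -> None:
    df = pd.DataFrame({"time_s": trace.times, "roi": trace.roi_intensity})
    if trace.reference_intensity is not None:
        df["reference"] = trace.reference_intensity
    df["channel"] = trace.channel
    write_csv(df, path)


def load_trace(path: str | Path, kind: str = "frap", n_pre: int | None = None
               ) -> ExchangeTrace:
    """Read a trace CSV (columns time_s, roi[, reference, channel]).

    ``n_pre`` defaults to the number of rows with negative time.
    """
    df = pd.read_csv(path)
    times = df["time_s"].to_numpy(dtype=float)
    if n_pre is None:
        n_pre = int((times < 0).sum())
    ref = df["reference"].to_numpy(dtype=float) if "reference" in df.columns else None
    channel = str(df["channel"].iloc[0]) if "channel" in df.columns else "green"
    return ExchangeTrace(times=times, roi_intensity=df["roi"].to_numpy(dtype=float),
                         reference_intensity=ref, n_pre=n_pre, kind=kind, channel=channel)


def save_matrix(matrix: ExpressionMatrix, prefix: str | Path) -> None:
    prefix = Path(prefix)
    matrix.intensities.to_csv(prefix.with_suffix(".intensities.csv"), float_format=FLOAT_FORMAT)
    matrix.detection_p.to_csv(prefix.with_suffix(".detection_p.csv"), float_format=FLOAT_FORMAT)
    matrix.sample_meta.to_csv(prefix.with_suffix(".samples.csv"), float_format=FLOAT_FORMAT)


def load_matrix(intensities: str | Path, detection_p: str | Path,
                samples: str | Path) -> ExpressionMatrix:
    return ExpressionMatrix(
        intensities=pd.read_csv(intensities, index_col=0),
        detection_p=pd.read_csv(detection_p, index_col=0),
        sample_meta=pd.read_csv(samples, index_col=0),
    )
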