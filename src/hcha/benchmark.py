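"""Published per-patient benchmark figures for the five enhancement methods.

The reference comparison study evaluated 211 brain MR slices (256x256) from
ten patients; only the per-patient mean PSNR and mean average gradient were
published, together with their unweighted grand averages.  They are kept
here as data so the aggregation rule (:func:`hcha.metrics.grand_average`)
can be checked against the printed summary rows, and so reports can be laid
out the same way.
"""

from __future__ import annotations

import csv
import io

from hcha.metrics import grand_average

__all__ = [
    "METHODS",
    "PATIENTS",
    "N_IMAGES",
    "PSNR_BY_METHOD",
    "GRADIENT_BY_METHOD",
    "grand_averages",
    "to_csv",
]

METHODS = ("he", "opening", "closing", "clahe", "hcha")
PATIENTS = tuple(range(1, 11))
N_IMAGES = (19, 22, 20, 22, 26, 30, 15, 18, 17, 22)

#: Per-patient mean PSNR (dB) of original-versus-enhanced, one row per method.
PSNR_BY_METHOD: dict[str, tuple[float, ...]] = {
    "he": (18.09, 23.30, 19.00, 16.71, 11.47, 10.69, 21.05, 12.38, 15.26, 13.14),
    "opening": (20.46, 19.21, 17.32, 19.42, 21.11, 20.01, 18.62, 20.54, 20.18, 21.76),
    "closing": (19.75, 19.45, 17.37, 19.03, 19.22, 18.49, 18.45, 19.31, 19.36, 20.57),
    "clahe": (17.35, 18.09, 18.11, 16.68, 17.59, 18.17, 17.36, 15.00, 18.15, 17.11),
    "hcha": (19.39, 18.67, 19.18, 19.52, 21.35, 22.19, 19.54, 20.97, 19.69, 21.27),
}

#: Per-patient mean average gradient of the enhanced images.
GRADIENT_BY_METHOD: dict[str, tuple[float, ...]] = {
    "he": (22.51, 28.31, 24.27, 26.97, 26.36, 30.92, 25.70, 28.36, 23.52, 21.84),
    "opening": (9.78, 8.91, 11.42, 10.50, 10.28, 10.42, 10.61, 8.86, 11.04, 9.05),
    "closing": (8.89, 9.42, 10.27, 9.66, 7.32, 6.84, 10.04, 7.44, 9.02, 7.62),
    "clahe": (28.81, 37.93, 30.76, 35.47, 26.76, 28.11, 35.37, 33.22, 29.21, 26.99),
    "hcha": (19.48, 24.55, 27.34, 21.17, 16.47, 18.50, 25.37, 17.12, 21.90, 16.18),
}

#: Published grand-average summary rows (2-decimal display precision).
PUBLISHED_PSNR_AVERAGES = {
    "he": 16.11,
    "opening": 19.86,
    "closing": 19.10,
    "clahe": 17.36,
    "hcha": 20.18,
}
PUBLISHED_GRADIENT_AVERAGES = {
    "he": 25.88,
    "opening": 10.09,
    "closing": 8.65,
    "clahe": 31.26,
    "hcha": 20.81,
}


def grand_averages(table: dict[str, tuple[float, ...]]) -> dict[str, float]:
    """Unweighted grand average per method column (unrounded)."""
    return {method: grand_average(values) for method, values in table.items()}


def to_csv() -> str:
    """Serialize the benchmark as RFC-4180 rows:
    ``patient,n_images,method,psnr,avg_gradient``."""
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\r\n")
    writer.writerow(["patient", "n_images", "method", "psnr", "avg_gradient"])
    for idx, patient in enumerate(PATIENTS):
        for method in METHODS:
            writer.writerow(
                [
                    patient,
                    N_IMAGES[idx],
                    method,
                    f"{PSNR_BY_METHOD[method][idx]:.2f}",
                    f"{GRADIENT_BY_METHOD[method][idx]:.2f}",
                ]
            )
    return buf.getvalue()
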