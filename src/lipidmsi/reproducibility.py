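"""Coefficient-of-variation reproducibility metrics for master-list masses.

Three flavors are computed from section mean-spectrum intensities:

* whole-dataset CV: per mass, the section intensities of each measurement
  day are first averaged over the biological samples, and the CV is taken
  across the resulting day-level means (one CV per mass, three day values);
* interday CV: CV across the three technical replicates of one biological
  sample measured on different days;
* intraday CV: the same with three sections measured on the same day.

Each report carries the per-mass CVs plus their mean and SD over masses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import MSIDataset
from .peaklist import MasterPeakList, cv
from .preprocess import roi_mean_spectrum

__all__ = [
    "CVReport",
    "section_mass_intensities",
    "whole_dataset_cv",
    "intraday_cv",
    "interday_cv",
]


@dataclass
class CVReport:
    per_mz_cv: dict[float, float]
    cv_avg: float
    cv_sd: float
    mode: str
    n_imputed_zero: int = 0

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"mz": list(self.per_mz_cv), "cv_percent": list(self.per_mz_cv.values())}
        )


def section_mass_intensities(
    dataset: MSIDataset,
    mzs: Sequence[float],
    regions: tuple[str, ...] = ("tumor", "necrosis"),
    halfwidth_da: float = 0.25,
) -> np.ndarray:
    """Mean-spectrum intensity of each mass over the on-tissue ROI pixels.

    The intensity of a mass is the maximum of the ROI mean spectrum within
    +/- ``halfwidth_da`` of the query m/z (absorbing calibration drift).
    """
    labels = dataset.pixel_labels()
    sel = np.isin(labels, regions)
    if not np.any(sel):
        raise ValueError(f"no pixels labeled {regions} in {dataset.meta.section_id}")
    mean_spec = dataset.intensities[sel].mean(axis=0)
    out = np.zeros(len(mzs))
    for j, mz in enumerate(mzs):
        lo, hi = np.searchsorted(dataset.mz_axis, [mz - halfwidth_da, mz + halfwidth_da])
        if hi > lo:
            out[j] = mean_spec[lo:hi].max()
    return out


def _report(per_mass: Mapping[float, float], mode: str, n_imputed: int) -> CVReport:
    vals = np.array([v for v in per_mass.values() if np.isfinite(v)])
    return CVReport(
        per_mz_cv=dict(per_mass),
        cv_avg=float(vals.mean()) if vals.size else float("nan"),
        cv_sd=float(vals.std(ddof=1)) if vals.size > 1 else 0.0,
        mode=mode,
        n_imputed_zero=n_imputed,
    )


def whole_dataset_cv(
    sections: Sequence[MSIDataset], master: MasterPeakList | Sequence[float]
) -> CVReport:
    """Whole-dataset CV over measurement days.

    For mass m and day d, I(m, d) is the mean over the biological samples
    of the section mean-spectrum intensity of that day; the per-mass CV is
    taken across the day-level means.  Masses absent from a section enter
    as zero intensity and are counted in ``n_imputed_zero``.
    """
    mzs = list(master.mz) if isinstance(master, MasterPeakList) else list(master)
    days = sorted({ds.meta.tech_rep for ds in sections})
    if len(days) < 2:
        raise ValueError("whole-dataset CV needs sections from at least two days")
    n_imputed = 0
    day_means = np.zeros((len(days), len(mzs)))
    for i, d in enumerate(days):
        rows = []
        for ds in sections:
            if ds.meta.tech_rep != d:
                continue
            inten = section_mass_intensities(ds, mzs)
            n_imputed += int(np.sum(inten == 0))
            rows.append(inten)
        day_means[i] = np.mean(rows, axis=0)
    per_mass = {mz: cv(day_means[:, j]) for j, mz in enumerate(mzs)}
    return _report(per_mass, "whole_dataset", n_imputed)


def _triplet_cv(
    sections: Sequence[MSIDataset], master: MasterPeakList | Sequence[float], mode: str
) -> CVReport:
    if len(sections) != 3:
        raise ValueError(f"{mode} CV requires exactly 3 sections, got {len(sections)}")
    if len({ds.meta.bio_sample for ds in sections}) != 1:
        raise ValueError("replicate CV requires sections of one biological sample")
    mzs = list(master.mz) if isinstance(master, MasterPeakList) else list(master)
    mat = np.vstack([section_mass_intensities(ds, mzs) for ds in sections])
    n_imputed = int(np.sum(mat == 0))
    per_mass = {mz: cv(mat[:, j]) for j, mz in enumerate(mzs)}
    return _report(per_mass, mode, n_imputed)


def interday_cv(
    sections: Sequence[MSIDataset], master: MasterPeakList | Sequence[float]
) -> CVReport:
    """CV across three technical replicates measured on different days."""
    if len({ds.meta.tech_rep for ds in sections}) != len(sections):
        raise ValueError("interday CV requires sections from distinct days")
    return _triplet_cv(sections, master, "interday")


def intraday_cv(
    sections: Sequence[MSIDataset], master: MasterPeakList | Sequence[float]
) -> CVReport:
    """CV across three sections measured on the same day."""
    return _triplet_cv(sections, master, "intraday")
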