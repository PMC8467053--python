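"""Data model and file I/O for mass spectrometry imaging datasets.

The central container is :class:`MSIDataset`: one tissue section worth of
pixel spectra together with section metadata (biological sample, technical
replicate / measurement day, treatment arm) and a region-of-interest mask
(tumor / necrosis / off-tissue / excluded).

Supported formats: imzML 1.1 (continuous and processed mode, via pyimzML),
ROI masks as CSV (columns ``x,y,label``), section metadata as YAML, and
tab-separated tables for all derived results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "REGION_LABELS",
    "ARMS",
    "PixelSpectrum",
    "SectionMeta",
    "ROIMask",
    "MSIDataset",
    "read_imzml",
    "write_imzml",
    "read_roi_mask",
    "write_roi_mask",
    "read_section_meta",
    "write_section_meta",
    "write_peaklist_tsv",
    "read_peaklist_tsv",
]

#: Closed set of per-pixel annotation labels.
REGION_LABELS = ("tumor", "necrosis", "off_tissue", "excluded")

#: Treatment arms of the study design.
ARMS = ("treated", "control")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


@dataclass
class PixelSpectrum:
    """A single pixel spectrum on a strictly increasing m/z axis."""

    coords: tuple[int, int]
    mz: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        self.mz = np.asarray(self.mz, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.mz.shape != self.intensity.shape:
            raise ValueError("mz and intensity must have the same length")
        if self.mz.size > 1 and not np.all(np.diff(self.mz) > 0):
            raise FormatError("m/z axis must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")


@dataclass(frozen=True)
class SectionMeta:
    """Metadata of one tissue section.

    ``tech_rep`` numbers the technical replicate and equals the measurement
    day in the study design (adjacent sections of one block are measured on
    different days).
    """

    section_id: str
    bio_sample: str
    tech_rep: int
    arm: str

    def __post_init__(self) -> None:
        if self.arm not in ARMS:
            raise ValueError(f"arm must be one of {ARMS}, got {self.arm!r}")
        if not isinstance(self.tech_rep, (int, np.integer)) or self.tech_rep < 1:
            raise ValueError("tech_rep must be a positive integer")


class ROIMask:
    """Mapping from grid coordinates ``(x, y)`` to a region label."""

    def __init__(self, labels: Mapping[tuple[int, int], str] | None = None):
        self._labels: dict[tuple[int, int], str] = {}
        if labels:
            for xy, lab in labels.items():
                self[xy] = lab

    def __setitem__(self, xy: tuple[int, int], label: str) -> None:
        if label not in REGION_LABELS:
            raise FormatError(
                f"unknown ROI label {label!r} at pixel {tuple(xy)}; "
                f"allowed: {REGION_LABELS}"
            )
        self._labels[(int(xy[0]), int(xy[1]))] = label

    def __getitem__(self, xy: tuple[int, int]) -> str:
        return self._labels.get((int(xy[0]), int(xy[1])), "excluded")

    def __len__(self) -> int:
        return len(self._labels)

    def items(self):
        return self._labels.items()

    def labels_for(self, coords: np.ndarray) -> np.ndarray:
        """Label array aligned with an ``(n, 2)`` coordinate array."""
        return np.array([self[(x, y)] for x, y in coords], dtype=object)


class MSIDataset:
    """One section of MSI data.

    Continuous-mode data share a single m/z axis: ``mz_axis`` has shape
    ``(m,)`` and ``intensities`` shape ``(n_pixels, m)``.  Processed-mode
    data carry one (mz, intensity) pair per pixel in ``spectra``.
    """

    def __init__(
        self,
        coords: np.ndarray,
        meta: SectionMeta,
        mz_axis: np.ndarray | None = None,
        intensities: np.ndarray | None = None,
        spectra: Sequence[PixelSpectrum] | None = None,
        roi: ROIMask | None = None,
    ):
        self.coords = np.asarray(coords, dtype=int).reshape(-1, 2)
        self.meta = meta
        self.roi = roi if roi is not None else ROIMask()
        self.flags: dict = {}
        if mz_axis is not None:
            self.mode = "continuous"
            self.mz_axis = np.asarray(mz_axis, dtype=float)
            if self.mz_axis.size > 1 and not np.all(np.diff(self.mz_axis) > 0):
                raise FormatError("m/z axis must be strictly increasing")
            self.intensities = np.asarray(intensities)
            if self.intensities.shape != (len(self.coords), self.mz_axis.size):
                raise ValueError("intensities must be (n_pixels, n_bins)")
            self.spectra = None
        elif spectra is not None:
            self.mode = "processed"
            self.spectra = list(spectra)
            if len(self.spectra) != len(self.coords):
                raise ValueError("one spectrum per coordinate required")
            self.mz_axis = None
            self.intensities = None
        else:
            raise ValueError("either (mz_axis, intensities) or spectra required")

    @property
    def n_pixels(self) -> int:
        return len(self.coords)

    def pixel_labels(self) -> np.ndarray:
        return self.roi.labels_for(self.coords)

    def tic(self) -> np.ndarray:
        """Total ion count per pixel."""
        if self.mode == "continuous":
            return self.intensities.sum(axis=1)
        return np.array([s.intensity.sum() for s in self.spectra])

    def iter_spectra(self) -> Iterable[PixelSpectrum]:
        if self.mode == "continuous":
            for xy, row in zip(self.coords, self.intensities):
                yield PixelSpectrum(tuple(xy), self.mz_axis, np.asarray(row, dtype=float))
        else:
            yield from self.spectra

    def copy(self) -> "MSIDataset":
        if self.mode == "continuous":
            out = MSIDataset(
                self.coords.copy(), self.meta, mz_axis=self.mz_axis.copy(),
                intensities=self.intensities.copy(), roi=self.roi,
            )
        else:
            out = MSIDataset(
                self.coords.copy(), self.meta,
                spectra=[PixelSpectrum(s.coords, s.mz.copy(), s.intensity.copy())
                         for s in self.spectra],
                roi=self.roi,
            )
        out.flags = dict(self.flags)
        return out

    def bin_to_axis(self, mz_axis: np.ndarray) -> "MSIDataset":
        """Bin processed-mode spectra onto a uniform axis (nearest bin, summed).

        Continuous-mode datasets are returned unchanged if the axis matches.
        """
        mz_axis = np.asarray(mz_axis, dtype=float)
        if self.mode == "continuous":
            if self.mz_axis.size == mz_axis.size and np.allclose(self.mz_axis, mz_axis):
                return self
            raise ValueError("continuous dataset is already on a different axis")
        step = np.median(np.diff(mz_axis))
        mat = np.zeros((self.n_pixels, mz_axis.size), dtype=np.float32)
        for i, s in enumerate(self.spectra):
            idx = np.rint((s.mz - mz_axis[0]) / step).astype(int)
            ok = (idx >= 0) & (idx < mz_axis.size)
            np.add.at(mat[i], idx[ok], s.intensity[ok])
        out = MSIDataset(self.coords.copy(), self.meta, mz_axis=mz_axis,
                         intensities=mat, roi=self.roi)
        out.flags = dict(self.flags)
        return out


# ---------------------------------------------------------------------------
# imzML
# ---------------------------------------------------------------------------

def read_imzml(path: str | Path, meta: SectionMeta | None = None) -> MSIDataset:
    """Read an imzML/ibd file pair into an :class:`MSIDataset`.

    imzML coordinates are 1-based; they are mapped onto the package's
    0-based grid convention (x = column, y = row).  If ``meta`` is not
    given, a placeholder section metadata record is attached.
    """
    from pyimzml.ImzMLParser import ImzMLParser

    path = Path(path)
    ibd = path.with_suffix(".ibd")
    if not ibd.exists():
        raise FileNotFoundError(f"missing binary data file {ibd}")
    parser = ImzMLParser(str(path))
    mode = "processed"
    try:
        fdesc = parser.metadata.file_description
        if "continuous" in getattr(fdesc, "param_by_name", {}):
            mode = "continuous"
    except AttributeError:  # fall back to comparing lengths
        if len(set(parser.mzLengths)) == 1:
            mode = "continuous"

    coords = np.array([(x - 1, y - 1) for x, y, _z in parser.coordinates], dtype=int)
    spectra = []
    for i, xy in enumerate(coords):
        mz, inten = parser.getspectrum(i)
        mz = np.asarray(mz, dtype=float)
        if mz.size > 1 and np.any(np.diff(mz) <= 0):
            raise FormatError(f"non-monotone m/z axis in spectrum {i}")
        spectra.append(PixelSpectrum(tuple(xy), mz, np.asarray(inten, dtype=float)))
    if meta is None:
        meta = SectionMeta(path.stem, path.stem, 1, "control")

    if mode == "continuous" and spectra:
        axis = spectra[0].mz
        mat = np.vstack([s.intensity for s in spectra]).astype(np.float32)
        return MSIDataset(coords, meta, mz_axis=axis, intensities=mat)
    return MSIDataset(coords, meta, spectra=spectra)


def write_imzml(dataset: MSIDataset, path: str | Path) -> None:
    """Write a dataset as imzML (continuous or processed matching its mode)."""
    from pyimzml.ImzMLWriter import ImzMLWriter

    mode = dataset.mode
    with ImzMLWriter(str(path), mode=mode) as writer:
        for s in dataset.iter_spectra():
            x, y = s.coords
            writer.addSpectrum(s.mz, s.intensity, (int(x) + 1, int(y) + 1, 1))


# ---------------------------------------------------------------------------
# ROI masks and metadata
# ---------------------------------------------------------------------------

def read_roi_mask(path: str | Path, dataset: MSIDataset | None = None) -> ROIMask:
    """Read a CSV ROI mask (columns ``x,y,label``).

    Labels outside the closed set raise :class:`FormatError` naming the
    offending row.  Pixels absent from the CSV default to ``excluded``.
    When ``dataset`` is given the mask is attached to it.
    """
    df = pd.read_csv(path)
    required = {"x", "y", "label"}
    if not required.issubset(df.columns):
        raise FormatError(f"ROI mask must have columns {sorted(required)}")
    mask = ROIMask()
    for i, row in enumerate(df.itertuples(index=False)):
        if row.label not in REGION_LABELS:
            raise FormatError(
                f"unknown ROI label {row.label!r} in row {i} of {path}"
            )
        mask[(int(row.x), int(row.y))] = str(row.label)
    if dataset is not None:
        dataset.roi = mask
    return mask


def write_roi_mask(mask: ROIMask, path: str | Path) -> None:
    rows = [(x, y, lab) for (x, y), lab in sorted(mask.items())]
    pd.DataFrame(rows, columns=["x", "y", "label"]).to_csv(path, index=False)


def read_section_meta(path: str | Path) -> SectionMeta:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    return SectionMeta(
        section_id=str(d["section_id"]),
        bio_sample=str(d["bio_sample"]),
        tech_rep=int(d["tech_rep"]),
        arm=str(d["arm"]),
    )


def write_section_meta(meta: SectionMeta, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "section_id": meta.section_id,
                "bio_sample": meta.bio_sample,
                "tech_rep": int(meta.tech_rep),
                "arm": meta.arm,
            },
            fh,
        )


# ---------------------------------------------------------------------------
# Master peak list TSV
# ---------------------------------------------------------------------------

def write_peaklist_tsv(master, path: str | Path) -> None:
    """Write a master peak list as TSV ('.' decimal, UTF-8, 6 decimals).

    Columns: m/z, source lists, contributing biological samples,
    per-sample mean intensities, overall mean intensity and whole-dataset
    CV.  An empty list produces a header-only file with a warning.
    """
    if len(master.entries) == 0:
        warnings.warn("writing header-only TSV for empty master peak list")
    samples = sorted({s for e in master.entries for s in e.sample_intensity})
    cols = ["mz", "sources", "bio_samples", "mean_intensity", "cv_percent"] + [
        f"intensity_{s}" for s in samples
    ]
    rows = []
    for e in master.entries:
        row = {
            "mz": round(float(e.mz), 6),
            "sources": ",".join(sorted(e.sources)),
            "bio_samples": ",".join(sorted(e.bio_samples)),
            "mean_intensity": round(float(e.mean_intensity), 6),
            "cv_percent": "" if e.cv_percent is None else round(float(e.cv_percent), 6),
        }
        for s in samples:
            v = e.sample_intensity.get(s)
            row[f"intensity_{s}"] = "" if v is None else round(float(v), 6)
        rows.append(row)
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False, encoding="utf-8")


def read_peaklist_tsv(path: str | Path):
    """Read a master peak list written by :func:`write_peaklist_tsv`."""
    from .peaklist import MasterEntry, MasterPeakList

    df = pd.read_csv(path, sep="\t", encoding="utf-8", comment="#")
    entries = []
    int_cols = [c for c in df.columns if c.startswith("intensity_")]
    for row in df.itertuples(index=False):
        d = row._asdict()
        sample_intensity = {}
        for c in int_cols:
            v = d[c]
            if pd.notna(v) and v != "":
                sample_intensity[c[len("intensity_"):]] = float(v)
        cv = d.get("cv_percent")
        entries.append(
            MasterEntry(
                mz=float(d["mz"]),
                sources=frozenset(str(d["sources"]).split(",")) if pd.notna(d["sources"]) else frozenset(),
                bio_samples=tuple(str(d["bio_samples"]).split(",")) if pd.notna(d["bio_samples"]) else (),
                sample_intensity=sample_intensity,
                mean_intensity=float(d["mean_intensity"]),
                cv_percent=None if pd.isna(cv) or cv == "" else float(cv),
            )
        )
    return MasterPeakList(entries=entries)
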