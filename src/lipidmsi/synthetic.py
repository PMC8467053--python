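"""Ground-truthed synthetic MSI study generator.

Emulates the study design this pipeline targets: 8 biological xenograft
samples (4 treated with a glutaminase inhibitor, 4 control), 3 technical
replicate sections each, measured on different days, positive-mode spectra
on a uniform m/z 500-1300 axis.  Each section carries a contiguous
necrosis blob inside a tumor region with an off-tissue border; lipid peaks
are rendered as Gaussians (FWHM 0.3 Da) with

* planted tumor/necrosis and treated/control log2 fold changes,
* lognormal day-level (lipid x day, shared across samples), section-level
  (intraday), and biological-sample-level intensity factors,
* spatially autocorrelated lognormal pixel noise (Gaussian-filtered white
  noise),
* +1 isotopologue peaks at a configurable intensity ratio,
* matrix-derived peaks strongly elevated off-tissue,
* a per-section mass-calibration shift (uniform within +/- the configured
  ppm), and a Gaussian detector noise floor.

The default truth masses are the 26 masses of the bundled reference master
list, with two high-abundance structural lipids dominating the TIC as in
real MALDI lipid spectra.  Everything is reproducible bit-for-bit from the
seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

from .core_io import MSIDataset, ROIMask, SectionMeta, write_imzml, write_roi_mask, write_section_meta
from . import reference

__all__ = ["GeneratorConfig", "GroundTruth", "generate_study", "truth_confusion", "write_study"]

# default planted effects (log2 units), keyed by truth mass
_DEFAULT_TN = {740.6: 1.0, 766.6: 1.0, 768.6: 1.0, 788.6: 1.0, 790.6: 1.0,
               812.6: 1.0, 639.5: -0.8, 683.5: -0.8}
_DEFAULT_ARM = {768.6: 0.5, 790.6: 0.5, 812.6: 0.5, 604.7: -1.1}
# two structural lipids carry most of the TIC so that TIC normalization
# perturbs planted fold changes only marginally
_STRUCTURAL_BASE = {576.7: 1500.0, 826.6: 1200.0}
_DEFAULT_MATRIX_MZ = (546.10, 620.15, 698.20, 875.25)


@dataclass
class GeneratorConfig:
    n_bio: int = 8
    n_treated: int = 4
    n_tech: int = 3
    grid: tuple[int, int] = (40, 40)
    mz_min: float = 500.0
    mz_max: float = 1300.0
    mz_step: float = 0.1
    true_mzs: tuple[float, ...] | None = None  # default: reference master list
    matrix_mzs: tuple[float, ...] = _DEFAULT_MATRIX_MZ
    tumor_fraction: float = 0.35
    necrosis_fraction: float = 0.20
    off_tissue_fraction: float = 0.25
    planted_tn_log2fc: dict = field(default_factory=lambda: dict(_DEFAULT_TN))
    planted_arm_log2fc: dict = field(default_factory=lambda: dict(_DEFAULT_ARM))
    base_intensity_range: tuple[float, float] = (10.0, 40.0)
    pixel_noise_cv: float = 0.5
    day_effect_cv: float = 0.20
    intraday_cv: float = 0.12
    bio_effect_cv: float = 0.15
    section_mass_shift_ppm: float = 100.0
    isotope_ratio: float = 0.4
    spatial_corr_length: float = 3.0
    peak_fwhm: float = 0.3
    noise_floor: float = 0.05
    matrix_boost: float = 12.0
    n_intraday: int = 0  # extra same-day sections of the first sample
    seed: int = 0

    def __post_init__(self) -> None:
        if self.tumor_fraction + self.necrosis_fraction + self.off_tissue_fraction > 1:
            raise ValueError("region fractions must sum to at most 1")
        if self.section_mass_shift_ppm < 0:
            raise ValueError("mass shift must be non-negative")

    @property
    def mz_axis(self) -> np.ndarray:
        n = int(round((self.mz_max - self.mz_min) / self.mz_step)) + 1
        return self.mz_min + self.mz_step * np.arange(n)


@dataclass
class GroundTruth:
    """Per-feature truth of a generated study."""

    features: pd.DataFrame  # mz, base, tn_log2fc, arm_log2fc, is_matrix, isotope_of

    @property
    def true_mzs(self) -> np.ndarray:
        """Masses a perfect master list should contain (monoisotopic lipids)."""
        f = self.features
        return f.loc[(~f.is_matrix) & f.isotope_of.isna(), "mz"].to_numpy()

    @property
    def matrix_mzs(self) -> np.ndarray:
        return self.features.loc[self.features.is_matrix, "mz"].to_numpy()

    @property
    def tumor_up_mzs(self) -> np.ndarray:
        f = self.features
        sel = (~f.is_matrix) & f.isotope_of.isna() & (f.tn_log2fc > 0)
        return f.loc[sel, "mz"].to_numpy()

    @property
    def necrosis_up_mzs(self) -> np.ndarray:
        f = self.features
        sel = (~f.is_matrix) & f.isotope_of.isna() & (f.tn_log2fc < 0)
        return f.loc[sel, "mz"].to_numpy()


def _lognormal_factors(rng: np.random.Generator, cv: float, size) -> np.ndarray:
    """Unit-mean lognormal factors with the given coefficient of variation."""
    if cv <= 0:
        return np.ones(size)
    sigma2 = np.log1p(cv**2)
    return rng.lognormal(mean=-sigma2 / 2.0, sigma=np.sqrt(sigma2), size=size)


def _correlated_field(rng: np.random.Generator, shape, corr_length: float, cv: float) -> np.ndarray:
    """Unit-mean lognormal random field with Gaussian spatial correlation."""
    white = rng.standard_normal(shape)
    if corr_length > 0:
        sm = ndimage.gaussian_filter(white, sigma=corr_length, mode="wrap")
        sd = sm.std()
        sm = sm / sd if sd > 0 else sm
    else:
        sm = white
    sigma2 = np.log1p(cv**2)
    return np.exp(np.sqrt(sigma2) * sm - sigma2 / 2.0)


def _section_mask(cfg: GeneratorConfig, rng: np.random.Generator) -> np.ndarray:
    """Label grid: contiguous necrosis blob, surrounding tumor, off-tissue ring."""
    W, H = cfg.grid
    ring = max(1, int(round((1 - np.sqrt(1 - cfg.off_tissue_fraction)) * min(W, H) / 2)))
    xx, yy = np.meshgrid(np.arange(W), np.arange(H), indexing="xy")
    labels = np.full((H, W), "excluded", dtype=object)
    off = (xx < ring) | (xx >= W - ring) | (yy < ring) | (yy >= H - ring)
    labels[off] = "off_tissue"
    cx = W / 2 + rng.uniform(-0.12, 0.12) * W
    cy = H / 2 + rng.uniform(-0.12, 0.12) * H
    r = np.sqrt(cfg.necrosis_fraction * W * H / np.pi)
    d = np.sqrt((xx - cx) ** 2 + (yy - cy) ** 2)
    nec = (~off) & (d <= r)
    labels[nec] = "necrosis"
    # tumor: interior pixels nearest the necrotic core, up to the target count
    buffer = (~off) & (~nec) & (d <= r + 1.0)  # mixed margin stays excluded
    cand = np.flatnonzero((~off) & (~nec) & (~buffer))
    order = cand[np.argsort(d.ravel()[cand], kind="stable")]
    n_tumor = min(int(round(cfg.tumor_fraction * W * H)), order.size)
    labels.ravel()[order[:n_tumor]] = "tumor"
    return labels


def _truth(cfg: GeneratorConfig) -> tuple[pd.DataFrame, GroundTruth]:
    if cfg.true_mzs is not None:
        lipid_mz = np.asarray(cfg.true_mzs, dtype=float)
    else:
        lipid_mz = reference.master_list()["mz"].to_numpy(dtype=float)
    lo, hi = cfg.base_intensity_range
    # deterministic, ratio-bounded base intensities cycling through the range
    pattern = np.array([0.0, 0.45, 0.9, 0.25, 0.7, 0.1, 0.55, 1.0])
    base = lo + (hi - lo) * pattern[np.arange(lipid_mz.size) % pattern.size]
    for mz, b in _STRUCTURAL_BASE.items():
        hit = np.isclose(lipid_mz, mz)
        if cfg.true_mzs is None and hit.any():
            base[hit] = b
    rows = []
    for mz, b in zip(lipid_mz, base):
        rows.append(
            {"mz": float(mz), "base": float(b),
             "tn_log2fc": float(cfg.planted_tn_log2fc.get(round(mz, 1), 0.0)),
             "arm_log2fc": float(cfg.planted_arm_log2fc.get(round(mz, 1), 0.0)),
             "is_matrix": False, "isotope_of": np.nan}
        )
    if cfg.isotope_ratio > 0:
        for mz, b in zip(lipid_mz, base):
            rows.append(
                {"mz": float(mz) + 1.00335, "base": float(b) * cfg.isotope_ratio,
                 "tn_log2fc": float(cfg.planted_tn_log2fc.get(round(mz, 1), 0.0)),
                 "arm_log2fc": float(cfg.planted_arm_log2fc.get(round(mz, 1), 0.0)),
                 "is_matrix": False, "isotope_of": float(mz)}
            )
    for mz in cfg.matrix_mzs:
        rows.append({"mz": float(mz), "base": 15.0, "tn_log2fc": 0.0,
                     "arm_log2fc": 0.0, "is_matrix": True, "isotope_of": np.nan})
    feats = pd.DataFrame(rows)
    return feats, GroundTruth(features=feats)


def _render_section(
    cfg: GeneratorConfig,
    feats: pd.DataFrame,
    meta: SectionMeta,
    day_f: np.ndarray,
    bio_f: np.ndarray,
    rng: np.random.Generator,
) -> MSIDataset:
    W, H = cfg.grid
    labels_grid = _section_mask(cfg, rng)
    labels = labels_grid.ravel()
    xx, yy = np.meshgrid(np.arange(W), np.arange(H), indexing="xy")
    coords = np.column_stack([xx.ravel(), yy.ravel()])
    n_px = coords.shape[0]
    axis = cfg.mz_axis
    shift_ppm = rng.uniform(-cfg.section_mass_shift_ppm, cfg.section_mass_shift_ppm)
    intra_f = _lognormal_factors(rng, cfg.intraday_cv, len(feats))

    is_tumor = labels == "tumor"
    is_nec = labels == "necrosis"
    is_off = labels == "off_tissue"
    on_tissue = ~is_off
    treated = meta.arm == "treated"

    sigma = cfg.peak_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    mat = np.zeros((n_px, axis.size), dtype=np.float32)
    for j, f in enumerate(feats.itertuples(index=False)):
        field2d = _correlated_field(rng, (H, W), cfg.spatial_corr_length, cfg.pixel_noise_cv)
        noise = field2d.ravel()
        amp = np.zeros(n_px)
        if f.is_matrix:
            amp[:] = f.base
            amp[is_off] *= cfg.matrix_boost
            amp *= day_f[j] * intra_f[j] * noise
        else:
            level = np.zeros(n_px)
            level[is_tumor] = 2.0 ** f.tn_log2fc
            level[is_nec] = 1.0
            # mixed (excluded) tissue: halfway between the two compartments
            level[on_tissue & ~is_tumor & ~is_nec] = 2.0 ** (f.tn_log2fc / 2.0)
            amp = f.base * level
            if treated:
                amp *= 2.0 ** f.arm_log2fc
            amp *= day_f[j] * bio_f[j] * intra_f[j] * noise
        center = f.mz * (1.0 + shift_ppm / 1e6)
        lo = np.searchsorted(axis, center - 4 * sigma)
        hi = np.searchsorted(axis, center + 4 * sigma)
        if hi <= lo:
            continue
        prof = np.exp(-0.5 * ((axis[lo:hi] - center) / sigma) ** 2)
        mat[:, lo:hi] += np.outer(amp, prof).astype(np.float32)
    if cfg.noise_floor > 0:
        mat += rng.normal(0.0, cfg.noise_floor, size=mat.shape).astype(np.float32)
        np.clip(mat, 0.0, None, out=mat)

    roi = ROIMask({(int(x), int(y)): lab for (x, y), lab in zip(coords, labels)})
    ds = MSIDataset(coords, meta, mz_axis=axis, intensities=mat, roi=roi)
    ds.flags["mass_shift_ppm"] = float(shift_ppm)
    return ds


def generate_study(
    cfg: GeneratorConfig | None = None, seed: int | None = None
) -> tuple[list[MSIDataset], GroundTruth]:
    """Generate the full synthetic study.

    Returns one dataset per section (``n_bio * n_tech``, plus
    ``n_intraday`` extra same-day sections of the first sample when
    configured) and the generator ground truth.  Identical
    ``(cfg, seed)`` produce bit-identical data.
    """
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    feats, truth = _truth(cfg)
    n_feat = len(feats)

    day_f = _lognormal_factors(rng, cfg.day_effect_cv, (cfg.n_tech, n_feat))
    bio_f = _lognormal_factors(rng, cfg.bio_effect_cv, (cfg.n_bio, n_feat))
    # isotopes inherit their parent's day and sample factors
    parent_idx = {round(mz, 5): i for i, mz in enumerate(feats.mz) if np.isnan(feats.isotope_of[i])}
    for i, iso in enumerate(feats.isotope_of):
        if not np.isnan(iso):
            p = parent_idx[round(iso, 5)]
            day_f[:, i] = day_f[:, p]
            bio_f[:, i] = bio_f[:, p]

    sections: list[MSIDataset] = []
    samples = [f"T{i+1}" for i in range(cfg.n_treated)] + [
        f"C{i+1}" for i in range(cfg.n_bio - cfg.n_treated)
    ]
    for s_idx, sample in enumerate(samples):
        arm = "treated" if s_idx < cfg.n_treated else "control"
        for rep in range(1, cfg.n_tech + 1):
            meta = SectionMeta(f"{sample}_r{rep}", sample, rep, arm)
            sections.append(
                _render_section(cfg, feats, meta, day_f[rep - 1], bio_f[s_idx], rng)
            )
    for k in range(cfg.n_intraday):
        # same-day repeats of the first sample: day factors of day 1
        meta = SectionMeta(f"{samples[0]}_intra{k+1}", samples[0], 1, "treated" if cfg.n_treated else "control")
        ds = _render_section(cfg, feats, meta, day_f[0], bio_f[0], rng)
        ds.flags["intraday"] = True
        sections.append(ds)
    return sections, truth


def truth_confusion(
    called_mzs: Sequence[float],
    truth: GroundTruth | Sequence[float],
    ppm: float = 220.0,
) -> dict:
    """Confusion counts of called masses against the generator truth.

    A call matches a true mass within ``ppm``; each true mass can absorb
    several calls (they would fall in one ppm cluster).  Returns TP, FP,
    FN, recall and precision.
    """
    true_mzs = truth.true_mzs if isinstance(truth, GroundTruth) else np.asarray(truth, float)
    called = np.asarray(list(called_mzs), dtype=float)
    matched_true = set()
    fp = 0
    for mz in called:
        if true_mzs.size:
            d = np.abs(true_mzs - mz) / true_mzs * 1e6
            j = int(np.argmin(d))
            if d[j] <= ppm:
                matched_true.add(j)
                continue
        fp += 1
    tp = len(matched_true)
    fn = len(true_mzs) - tp
    return {
        "TP": tp,
        "FP": fp,
        "FN": fn,
        "recall": tp / len(true_mzs) if len(true_mzs) else float("nan"),
        "precision": tp / (tp + fp) if (tp + fp) else float("nan"),
    }


def write_study(
    sections: Sequence[MSIDataset], truth: GroundTruth, out_dir: str | Path
) -> None:
    """Write a generated study as imzML + ROI CSV + metadata YAML + truth TSV."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for ds in sections:
        stem = out / ds.meta.section_id
        write_imzml(ds, stem.with_suffix(".imzML"))
        write_roi_mask(ds.roi, stem.with_suffix(".roi.csv"))
        write_section_meta(ds.meta, stem.with_suffix(".meta.yaml"))
    truth.features.to_csv(out / "truth.tsv", sep="\t", index=False)
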