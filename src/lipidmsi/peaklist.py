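"""Master peak list construction.

The reproducibility filter chain works per biological sample and then
across samples:

1. peaks picked from ROI mean spectra are clustered across the three
   technical replicates by a 220 ppm tolerance (single-linkage gap
   clustering over the pooled sorted m/z values);
2. a mass is *common* when every technical replicate contributes a member;
3. common masses pass an intensity-CV gate (CV < 45 %), and masses present
   in both tumor and necrosis additionally feed a log2 fold-change
   consistency gate (CV of the per-replicate log2FC < 60 %);
4. matrix-derived peaks (higher off-tissue, ROC AUC > 0.9) and +1 isotope
   peaks (mass delta 1.00335 Da below a stronger retained peak) are removed;
5. masses present in at least two biological samples with TIC-normalized
   mean intensity > 1 enter the master peak list.

All gates are pure filters (output is a subset of the input) and
idempotent.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .core_io import MSIDataset
from .preprocess import PeakList, pixel_mass_intensities

__all__ = [
    "FilterConfig",
    "MassCluster",
    "ReplicatedPeak",
    "CandidateMass",
    "MasterEntry",
    "MasterPeakList",
    "merge_by_ppm",
    "common_across_tech_reps",
    "cv",
    "cv_gate",
    "log2fc_consistency_gate",
    "rank_auc",
    "matrix_peak_filter",
    "isotope_filter",
    "build_master_list",
]

ISOTOPE_DELTA = 1.00335  # Da, mass difference of a +1 (13C) isotopologue


@dataclass
class FilterConfig:
    """Thresholds of the master-peak-list filter chain.

    ``ppm_window`` is the mass tolerance used for all clustering and
    matching; ``cv_region_max`` / ``cv_log2fc_max`` are the strict upper
    CV bounds (percent); matrix peaks are removed above ``matrix_auc_min``
    AUC (off-tissue vs on-tissue); the final master-list gates are
    ``min_bio_reps`` contributing biological samples (inclusive) and mean
    TIC-normalized intensity strictly above ``min_mean_intensity``.
    ``min_detection_freq`` automates the manual low-quality-signal check:
    masses detected in fewer than this fraction of contributing ROI pixels
    are dropped.
    """

    ppm_window: float = 220.0
    cv_region_max: float = 45.0
    cv_log2fc_max: float = 60.0
    matrix_auc_min: float = 0.9
    min_bio_reps: int = 2
    min_mean_intensity: float = 1.0
    isotope_delta: float = ISOTOPE_DELTA
    isotope_tol_ppm: float = 220.0
    min_detection_freq: float = 0.01

    def __post_init__(self) -> None:
        for name in (
            "ppm_window", "cv_region_max", "cv_log2fc_max", "matrix_auc_min",
            "min_bio_reps", "min_mean_intensity", "isotope_delta",
            "isotope_tol_ppm",
        ):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class MassCluster:
    """A ppm-merged mass group across replicate peak lists."""

    rep_mz: float
    members: list[tuple[str, str, float, float]]  # (replicate_id, region, mz, intensity)
    span_ppm: float

    @property
    def replicates(self) -> set[str]:
        return {m[0] for m in self.members}


@dataclass
class ReplicatedPeak:
    """A mass with one intensity per technical replicate."""

    mz: float
    intensities: dict[str, float]

    @property
    def mean_intensity(self) -> float:
        return float(np.mean(list(self.intensities.values())))


@dataclass(frozen=True)
class CandidateMass:
    """A per-biological-sample master-list candidate."""

    mz: float
    intensity: float
    sources: frozenset  # subset of {"tumor", "necrosis", "log2fc"}


@dataclass
class MasterEntry:
    mz: float
    sources: frozenset
    bio_samples: tuple
    sample_intensity: dict
    mean_intensity: float
    cv_percent: float | None = None


@dataclass
class MasterPeakList:
    entries: list[MasterEntry] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.entries)

    @property
    def mz(self) -> np.ndarray:
        return np.array([e.mz for e in self.entries])


# ---------------------------------------------------------------------------
# clustering and gates
# ---------------------------------------------------------------------------

def merge_by_ppm(
    peaklists: Sequence[PeakList], ppm_window: float = 220.0
) -> list[MassCluster]:
    """Single-linkage gap clustering of pooled peaks by ppm tolerance.

    All peaks are pooled and sorted by m/z; a new cluster starts whenever
    the gap to the previous mass exceeds ``ppm_window`` relative to the
    smaller mass.  Deterministic and independent of input list order.
    The representative m/z is the intensity-weighted mean of the members.
    """
    pooled = []
    for pl in peaklists:
        for p in pl.peaks:
            pooled.append((p.mz, pl.section_id, pl.region, p.intensity))
    pooled.sort()
    clusters: list[MassCluster] = []
    current: list[tuple] = []

    def _close(members: list[tuple]) -> MassCluster:
        mzs = np.array([m[0] for m in members])
        ints = np.array([m[3] for m in members])
        rep = float(np.average(mzs, weights=ints)) if ints.sum() > 0 else float(mzs.mean())
        span = float((mzs.max() - mzs.min()) / mzs.min() * 1e6) if mzs.min() > 0 else 0.0
        return MassCluster(
            rep_mz=rep,
            members=[(sid, reg, mz, inten) for mz, sid, reg, inten in members],
            span_ppm=span,
        )

    for item in pooled:
        if current and (item[0] - current[-1][0]) / current[-1][0] * 1e6 > ppm_window:
            clusters.append(_close(current))
            current = []
        current.append(item)
    if current:
        clusters.append(_close(current))
    return clusters


def common_across_tech_reps(
    clusters: Iterable[MassCluster],
    replicate_ids: Sequence[str],
    region: str | None = None,
) -> list[ReplicatedPeak]:
    """Keep clusters detected in *every* technical replicate.

    ``replicate_ids`` names the technical replicates (section ids) a
    cluster must cover.  The per-replicate intensity is the member
    intensity, taking the maximum if a replicate contributed several
    members to one cluster.
    """
    required = set(replicate_ids)
    out = []
    for c in clusters:
        members = [m for m in c.members if region is None or m[1] == region]
        by_rep: dict[str, float] = {}
        for sid, _reg, _mz, inten in members:
            by_rep[sid] = max(by_rep.get(sid, 0.0), inten)
        if required.issubset(by_rep.keys()):
            out.append(ReplicatedPeak(mz=c.rep_mz, intensities={r: by_rep[r] for r in replicate_ids}))
    return out


def cv(values: Sequence[float]) -> float:
    """Coefficient of variation in percent: 100 * sample SD / |mean|.

    Uses the n-1 denominator.  Returns NaN when the mean is zero (the CV
    is undefined there); callers treat NaN as a failed gate.
    """
    arr = np.asarray(values, dtype=float)
    if arr.size < 2:
        raise ValueError("CV requires at least two values")
    m = arr.mean()
    if m == 0:
        return float("nan")
    return float(100.0 * arr.std(ddof=1) / abs(m))


def cv_gate(peaks: Sequence[ReplicatedPeak], max_cv: float = 45.0) -> list[ReplicatedPeak]:
    """Keep masses whose across-replicate intensity CV is strictly below ``max_cv``."""
    out = []
    for p in peaks:
        c = cv(list(p.intensities.values()))
        if np.isfinite(c) and c < max_cv:
            out.append(p)
    return out


def log2fc_consistency_gate(
    tumor: Sequence[ReplicatedPeak],
    necrosis: Sequence[ReplicatedPeak],
    max_cv: float = 60.0,
    ppm_window: float = 220.0,
) -> list[ReplicatedPeak]:
    """Keep masses with a consistent tumor/necrosis log2 fold change.

    Tumor and necrosis masses are paired within ``ppm_window``; for each
    technical replicate r the fold change is log2(I_tumor,r / I_necrosis,r),
    and the mass is kept when the CV of the per-replicate fold changes is
    strictly below ``max_cv``.  Masses missing (or zero) in necrosis in any
    replicate are excluded.  Returned peaks carry the mean of the tumor and
    necrosis intensity per replicate.
    """
    nec_sorted = sorted(necrosis, key=lambda p: p.mz)
    nec_mz = np.array([p.mz for p in nec_sorted])
    out = []
    for tp in tumor:
        if nec_mz.size == 0:
            break
        j = int(np.argmin(np.abs(nec_mz - tp.mz)))
        npk = nec_sorted[j]
        if abs(npk.mz - tp.mz) / min(npk.mz, tp.mz) * 1e6 > ppm_window:
            continue
        reps = sorted(tp.intensities)
        if sorted(npk.intensities) != reps:
            continue
        if any(npk.intensities[r] <= 0 for r in reps):
            continue
        fcs = [np.log2(tp.intensities[r] / npk.intensities[r]) for r in reps]
        c = cv(fcs)
        if np.isfinite(c) and c < max_cv:
            out.append(
                ReplicatedPeak(
                    mz=tp.mz,
                    intensities={
                        r: 0.5 * (tp.intensities[r] + npk.intensities[r]) for r in reps
                    },
                )
            )
    return out


def rank_auc(positives: np.ndarray, negatives: np.ndarray) -> float:
    """ROC AUC by the rank (Mann-Whitney) statistic, ties counted 1/2."""
    from scipy.stats import rankdata

    pos = np.asarray(positives, dtype=float)
    neg = np.asarray(negatives, dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both groups must be non-empty")
    ranks = rankdata(np.concatenate([pos, neg]))
    u = ranks[: pos.size].sum() - pos.size * (pos.size + 1) / 2.0
    return float(u / (pos.size * neg.size))


def matrix_peak_filter(
    datasets: MSIDataset | Sequence[MSIDataset],
    candidates: Sequence[float],
    auc_min: float = 0.9,
    halfwidth_da: float = 0.25,
) -> tuple[list[float], list[float], dict[float, float]]:
    """Split candidate masses into tissue peaks and matrix peaks.

    For every candidate m/z the per-pixel intensities of the on-tissue
    (tumor + necrosis) and off-tissue pixels, pooled over the given
    sections, are compared by ROC AUC with off-tissue as the positive
    class.  A mass is removed iff AUC > ``auc_min`` (strict) and its mean
    off-tissue intensity exceeds the on-tissue mean.  Returns
    ``(kept, removed, auc_by_mz)``.  Without off-tissue pixels the filter
    is skipped with a warning.
    """
    if isinstance(datasets, MSIDataset):
        datasets = [datasets]
    candidates = list(candidates)
    if not candidates:
        return [], [], {}
    on, off = [], []
    for ds in datasets:
        labels = ds.pixel_labels()
        mat = pixel_mass_intensities(ds, candidates, halfwidth_da=halfwidth_da)
        on.append(mat[(labels == "tumor") | (labels == "necrosis")])
        off.append(mat[labels == "off_tissue"])
    on_mat = np.vstack(on) if on else np.empty((0, len(candidates)))
    off_mat = np.vstack(off) if off else np.empty((0, len(candidates)))
    if off_mat.shape[0] == 0:
        warnings.warn("no off-tissue pixels; matrix peak filter skipped")
        return candidates, [], {}
    kept, removed, aucs = [], [], {}
    for j, mz in enumerate(candidates):
        auc = rank_auc(off_mat[:, j], on_mat[:, j])
        aucs[mz] = auc
        if auc > auc_min and off_mat[:, j].mean() > on_mat[:, j].mean():
            removed.append(mz)
        else:
            kept.append(mz)
    return kept, removed, aucs


def isotope_filter(
    peaks: Sequence[tuple[float, float]],
    delta: float = ISOTOPE_DELTA,
    tol_ppm: float = 220.0,
) -> list[tuple[float, float]]:
    """Remove +1 isotope peaks from a ``(mz, intensity)`` sequence.

    Scanning in ascending m/z, a peak is flagged as an isotope and removed
    when a *retained* peak sits one isotope spacing below it (within
    ``tol_ppm``) with strictly greater intensity; monoisotopic peaks are
    therefore always retained, and a larger peak one spacing above a
    smaller one is treated as a chance overlap and kept.
    """
    ordered = sorted(peaks)
    retained: list[tuple[float, float]] = []
    for mz, inten in ordered:
        is_iso = False
        for rmz, rint in reversed(retained):
            if mz - rmz > delta * 1.01 + mz * tol_ppm / 1e6:
                break
            if abs((mz - rmz) - delta) <= mz * tol_ppm / 1e6 and rint > inten:
                is_iso = True
                break
        if not is_iso:
            retained.append((mz, inten))
    return retained


def build_master_list(
    per_sample: Mapping[str, Sequence[CandidateMass]],
    cfg: FilterConfig | None = None,
) -> MasterPeakList:
    """Assemble the master peak list from per-biological-sample candidates.

    Candidates of all samples are pooled and clustered by ``ppm_window``;
    a cluster enters the master list when at least ``min_bio_reps``
    distinct biological samples contribute and the mean of the per-sample
    intensities is strictly above ``min_mean_intensity``.  A final isotope
    re-check runs on the assembled list.  Entries are ordered by m/z and
    the result is invariant under permutation of the input samples.
    """
    cfg = cfg or FilterConfig()
    pooled = []
    for sample in sorted(per_sample):
        for cand in per_sample[sample]:
            pooled.append((cand.mz, sample, cand.intensity, cand.sources))
    pooled.sort()

    entries: list[MasterEntry] = []
    current: list[tuple] = []

    def _close(group: list[tuple]) -> None:
        samples = sorted({g[1] for g in group})
        if len(samples) < cfg.min_bio_reps:
            return
        sample_int: dict[str, float] = {}
        for _mz, s, inten, _src in group:
            sample_int[s] = max(sample_int.get(s, 0.0), inten)
        mean_int = float(np.mean(list(sample_int.values())))
        if not mean_int > cfg.min_mean_intensity:
            return
        mzs = np.array([g[0] for g in group])
        ints = np.array([g[2] for g in group])
        rep = float(np.average(mzs, weights=ints)) if ints.sum() > 0 else float(mzs.mean())
        sources = frozenset().union(*[g[3] for g in group])
        entries.append(
            MasterEntry(
                mz=rep,
                sources=sources,
                bio_samples=tuple(samples),
                sample_intensity=sample_int,
                mean_intensity=mean_int,
            )
        )

    for item in pooled:
        if current and (item[0] - current[-1][0]) / current[-1][0] * 1e6 > cfg.ppm_window:
            _close(current)
            current = []
        current.append(item)
    if current:
        _close(current)

    # final isotope re-check on the assembled list
    kept = isotope_filter(
        [(e.mz, e.mean_intensity) for e in entries],
        delta=cfg.isotope_delta,
        tol_ppm=cfg.isotope_tol_ppm,
    )
    kept_mz = {mz for mz, _ in kept}
    entries = [e for e in entries if e.mz in kept_mz]
    entries.sort(key=lambda e: e.mz)
    return MasterPeakList(entries=entries)
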