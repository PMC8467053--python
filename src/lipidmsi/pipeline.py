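"""End-to-end orchestration of the analysis stages.

Stage order: TIC normalization -> per-biological-sample reproducibility
filtering (common masses across technical replicates, CV gates, matrix and
isotope removal) -> cross-sample master peak list -> CV reproducibility
reports -> tumor/necrosis iterative mixed-model testing -> treated/control
marker discovery -> accurate-mass annotation.

Randomness is controlled by one master seed fanned out per (stage,
technical replicate) through ``numpy``'s sequence seeding, so results are
reproducible and independent of execution order.
"""

from __future__ import annotations

import warnings
from collections import defaultdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .core_io import MSIDataset
from .preprocess import (
    PickingParams,
    pick_peaks,
    pixel_mass_intensities,
    roi_mean_spectrum,
    tic_normalize,
)
from .peaklist import (
    CandidateMass,
    FilterConfig,
    MasterPeakList,
    build_master_list,
    common_across_tech_reps,
    cv_gate,
    isotope_filter,
    log2fc_consistency_gate,
    matrix_peak_filter,
    merge_by_ppm,
)
from .reproducibility import whole_dataset_cv
from .group_stats import (
    LMMConfig,
    TreatmentConfig,
    call_significant,
    call_treatment_markers,
    iterative_lmm,
    pca_scores,
    treatment_analysis,
)
from .reproducibility import section_mass_intensities

__all__ = [
    "normalize_study",
    "masterlist_pipeline",
    "tumor_necrosis_pipeline",
    "treatment_pipeline",
]

_STAGE_LMM = 1
_STAGE_TREATMENT = 2


def normalize_study(sections: Sequence[MSIDataset]) -> list[MSIDataset]:
    """TIC-normalize every section (see :func:`tic_normalize`)."""
    return [tic_normalize(ds) for ds in sections]


def _main_sections(sections: Sequence[MSIDataset]) -> list[MSIDataset]:
    """Sections of the main replicate design (drops extra intraday repeats)."""
    return [ds for ds in sections if not ds.flags.get("intraday")]


def _by_sample(sections: Sequence[MSIDataset]) -> dict[str, list[MSIDataset]]:
    out: dict[str, list[MSIDataset]] = defaultdict(list)
    for ds in sections:
        out[ds.meta.bio_sample].append(ds)
    return {k: sorted(v, key=lambda d: d.meta.tech_rep) for k, v in out.items()}


def _dedup_candidates(
    cands: list[CandidateMass], ppm_window: float
) -> list[CandidateMass]:
    """ppm-cluster candidates of one sample, merging duplicate sources."""
    cands = sorted(cands, key=lambda c: c.mz)
    out: list[CandidateMass] = []
    group: list[CandidateMass] = []

    def _close(g: list[CandidateMass]) -> CandidateMass:
        mzs = np.array([c.mz for c in g])
        ints = np.array([c.intensity for c in g])
        rep = float(np.average(mzs, weights=ints)) if ints.sum() > 0 else float(mzs.mean())
        return CandidateMass(
            mz=rep,
            intensity=float(ints.mean()),
            sources=frozenset().union(*[c.sources for c in g]),
        )

    for c in cands:
        if group and (c.mz - group[-1].mz) / group[-1].mz * 1e6 > ppm_window:
            out.append(_close(group))
            group = []
        group.append(c)
    if group:
        out.append(_close(group))
    return out


def sample_candidates(
    sample_sections: Sequence[MSIDataset],
    cfg: FilterConfig,
    picking: PickingParams,
    audit: dict | None = None,
) -> list[CandidateMass]:
    """Reproducibility-filtered candidate masses of one biological sample.

    Implements the per-sample filter chain: common masses across the
    technical replicates per region, CV gates, tumor/necrosis log2FC
    consistency, matrix-peak removal (off- vs on-tissue ROC), isotope
    removal, and the minimum pixel detection-frequency check.
    """
    rep_ids = [ds.meta.section_id for ds in sample_sections]
    common = {}
    for region in ("tumor", "necrosis"):
        pls = []
        for ds in sample_sections:
            mz, spec = roi_mean_spectrum(ds, region)
            pls.append(
                pick_peaks(mz, spec, picking, section_id=ds.meta.section_id, region=region)
            )
        clusters = merge_by_ppm(pls, cfg.ppm_window)
        common[region] = common_across_tech_reps(clusters, rep_ids, region)

    cands: list[CandidateMass] = []
    for region in ("tumor", "necrosis"):
        for p in cv_gate(common[region], cfg.cv_region_max):
            cands.append(CandidateMass(p.mz, p.mean_intensity, frozenset({region})))
    for p in log2fc_consistency_gate(
        common["tumor"], common["necrosis"], cfg.cv_log2fc_max, cfg.ppm_window
    ):
        cands.append(CandidateMass(p.mz, p.mean_intensity, frozenset({"log2fc"})))
    cands = _dedup_candidates(cands, cfg.ppm_window)

    kept_mz, removed_mz, _aucs = matrix_peak_filter(
        sample_sections, [c.mz for c in cands], cfg.matrix_auc_min
    )
    kept_set = set(kept_mz)
    cands = [c for c in cands if c.mz in kept_set]

    iso_kept = isotope_filter(
        [(c.mz, c.intensity) for c in cands],
        delta=cfg.isotope_delta,
        tol_ppm=cfg.isotope_tol_ppm,
    )
    iso_set = {mz for mz, _ in iso_kept}
    iso_removed = [c.mz for c in cands if c.mz not in iso_set]
    cands = [c for c in cands if c.mz in iso_set]

    # automated stand-in for the manual low-quality-signal inspection
    lowq_removed = []
    if cands and cfg.min_detection_freq > 0:
        det = []
        for ds in sample_sections:
            labels = ds.pixel_labels()
            sel = (labels == "tumor") | (labels == "necrosis")
            mat = pixel_mass_intensities(ds, [c.mz for c in cands])[sel]
            det.append(mat > picking.abs_int_min)
        freq = np.vstack(det).mean(axis=0)
        lowq_removed = [c.mz for c, f in zip(cands, freq) if f < cfg.min_detection_freq]
        cands = [c for c, f in zip(cands, freq) if f >= cfg.min_detection_freq]

    if audit is not None:
        audit["matrix_removed"] = removed_mz
        audit["isotope_removed"] = iso_removed
        audit["low_quality_removed"] = lowq_removed
    return cands


def masterlist_pipeline(
    sections: Sequence[MSIDataset],
    cfg: FilterConfig | None = None,
    picking: PickingParams | None = None,
    normalized: bool = False,
) -> tuple[MasterPeakList, dict]:
    """Build the master peak list from all sections of a study.

    Returns the list plus an audit dict recording what each filter removed.
    ``normalized=True`` skips TIC normalization (inputs already scaled).
    """
    cfg = cfg or FilterConfig()
    picking = picking or PickingParams()
    sections = list(sections)
    if not normalized:
        sections = normalize_study(sections)
    main = _main_sections(sections)
    audit: dict = {"per_sample": {}}
    per_sample: dict[str, list[CandidateMass]] = {}
    for sample, s_sections in sorted(_by_sample(main).items()):
        s_audit: dict = {}
        per_sample[sample] = sample_candidates(s_sections, cfg, picking, s_audit)
        audit["per_sample"][sample] = s_audit

    master = build_master_list(per_sample, cfg)

    # final cross-study matrix re-check
    if len(master.entries):
        kept, removed, _ = matrix_peak_filter(main, list(master.mz), cfg.matrix_auc_min)
        audit["final_matrix_removed"] = removed
        keep = set(kept)
        master = MasterPeakList([e for e in master.entries if e.mz in keep])

    if len(master.entries):
        try:
            report = whole_dataset_cv(main, master)
            for e in master.entries:
                e.cv_percent = report.per_mz_cv.get(e.mz)
        except ValueError:
            warnings.warn("whole-dataset CV skipped (sections from a single day)")
    return master, audit


def tumor_necrosis_pipeline(
    sections: Sequence[MSIDataset],
    mzs: Sequence[float],
    cfg: LMMConfig | None = None,
) -> tuple[dict, pd.DataFrame]:
    """Iterative subsampled LMM per technical replicate plus combined calls.

    Sections lacking either region are excluded with a warning and the
    per-replicate analysis proceeds with the remaining samples.
    """
    cfg = cfg or LMMConfig()
    main = _main_sections(sections)
    by_rep: dict[int, list[MSIDataset]] = defaultdict(list)
    for ds in main:
        labels = ds.pixel_labels()
        if not (np.any(labels == "tumor") and np.any(labels == "necrosis")):
            warnings.warn(f"excluding section {ds.meta.section_id}: missing a region")
            continue
        by_rep[ds.meta.tech_rep].append(ds)
    results_by_rep = {}
    for rep, rep_sections in sorted(by_rep.items()):
        rng = np.random.default_rng([cfg.seed, _STAGE_LMM, rep])
        results_by_rep[rep] = iterative_lmm(rep_sections, mzs, cfg, rng)
    calls = call_significant(results_by_rep, cfg)
    return results_by_rep, calls


def treatment_pipeline(
    sections: Sequence[MSIDataset],
    mzs: Sequence[float],
    cfg: TreatmentConfig | None = None,
) -> tuple[dict, pd.DataFrame, dict]:
    """Treated-vs-control markers plus PCA of tumor mean spectra."""
    cfg = cfg or TreatmentConfig()
    main = _main_sections(sections)
    rng = np.random.default_rng([cfg.seed, _STAGE_TREATMENT])
    analysis = treatment_analysis(main, mzs, cfg, rng)
    markers = call_treatment_markers(analysis, cfg)

    X = np.vstack([section_mass_intensities(ds, mzs, regions=("tumor",)) for ds in main])
    scores, loadings, evr = pca_scores(X)
    pca = {
        "scores": scores,
        "loadings": loadings,
        "explained_variance_ratio": evr,
        "sections": [ds.meta.section_id for ds in main],
        "arms": [ds.meta.arm for ds in main],
    }
    return analysis, markers, pca
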