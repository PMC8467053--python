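"""Group comparisons: iterative subsampled mixed-model testing of tumor
versus necrosis, and treated-versus-control marker discovery.

MSI pixel spectra are strongly spatially autocorrelated, so naive
pixel-level tests are anti-conservative.  The tumor/necrosis comparison
therefore fits, per technical replicate, a linear mixed model

    intensity = b0 + b1 * 1[tumor] + u_sample + eps,   u ~ N(0, s_b^2)

with the biological sample as random intercept, on 1 % randomly selected
pixels, repeated 100 times; reported log2 fold changes and
Benjamini-Hochberg adjusted p-values are averages over the iterations.
The mixed model is fit by profiled restricted maximum likelihood (a 1-D
search over the variance ratio with closed-form GLS updates), which makes
the 100-fold iteration cheap; a singular fit (s_b -> 0) degenerates to
ordinary least squares and is flagged.

Treated-versus-control markers combine a Wilcoxon rank-sum test on section
mean intensities, pixel-level ROC AUC on equally sized spectrum subsets
(n = 15,000), and PCA of the section mean spectra.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

from .core_io import MSIDataset
from .peaklist import rank_auc
from .preprocess import pixel_mass_intensities
from .reproducibility import section_mass_intensities

__all__ = [
    "LMMConfig",
    "LMMResult",
    "TreatmentConfig",
    "subsample_pixels",
    "fit_lmm",
    "bh_adjust",
    "iterative_lmm",
    "call_significant",
    "wilcoxon_rank_sum",
    "pixel_roc_auc",
    "treatment_analysis",
    "call_treatment_markers",
    "pca_scores",
]


@dataclass
class LMMConfig:
    fraction: float = 0.01
    iterations: int = 100
    lfc_min: float = 0.5
    p_max: float = 0.05
    min_sig_tech_reps: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.fraction <= 1:
            raise ValueError("fraction must be in (0, 1]")
        if self.iterations < 1:
            raise ValueError("iterations must be >= 1")


@dataclass
class LMMResult:
    mz: float
    tech_rep: int
    mean_log2fc: float
    log2fc_range: tuple[float, float]
    mean_adj_p: float
    p_range: tuple[float, float]
    n_skipped: int = 0
    ols_fallback_frac: float = 0.0


@dataclass
class TreatmentConfig:
    wilcoxon_p_max: float = 0.05
    wilcoxon_min_tech_reps: int = 2
    auc_min: float = 0.7
    auc_min_tech_reps: int = 2
    auc_min_bio_reps: int = 3
    roc_subset_n: int = 15000
    seed: int = 0


# ---------------------------------------------------------------------------
# random-intercept REML fit
# ---------------------------------------------------------------------------

def _group_stats(X: np.ndarray, y: np.ndarray, groups: np.ndarray):
    """Per-group sums needed for closed-form GLS with a random intercept."""
    uniq, inv = np.unique(groups, return_inverse=True)
    k = uniq.size
    n_i = np.bincount(inv, minlength=k).astype(float)
    Sx = np.zeros((k, X.shape[1]))
    Sy = np.zeros(k)
    for j in range(X.shape[1]):
        Sx[:, j] = np.bincount(inv, weights=X[:, j], minlength=k)
    Sy = np.bincount(inv, weights=y, minlength=k)
    return n_i, Sx, Sy


def fit_lmm(
    y: np.ndarray, region: np.ndarray, groups: np.ndarray
) -> tuple[float, float, bool]:
    """Fit intensity ~ region with a random intercept per group (REML).

    ``region`` is a binary indicator (1 = tumor).  Returns
    ``(beta_region, wald_p, ols_fallback)``; the fallback flag is set when
    the between-group variance estimate collapses to zero (the GLS fit then
    equals ordinary least squares) or only one group is present.
    """
    y = np.asarray(y, dtype=float)
    x = np.asarray(region, dtype=float)
    groups = np.asarray(groups)
    if x.min() == x.max():
        raise ValueError("both region levels must be present")
    X = np.column_stack([np.ones_like(x), x])
    n, p = X.shape
    uniq = np.unique(groups)
    n_i, Sx, Sy = _group_stats(X, y, groups)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = y @ y

    def crit(log_psi: float) -> float:
        return _reml_crit(np.exp(log_psi))[0]

    def _reml_crit(psi: float):
        c = psi / (1.0 + psi * n_i)  # shrinkage weight per group
        A = XtX - (Sx * c[:, None]).T @ Sx
        b = Xty - Sx.T @ (c * Sy)
        q_y = yty - np.sum(c * Sy**2)
        try:
            beta = np.linalg.solve(A, b)
        except np.linalg.LinAlgError:
            return np.inf, None, None, None
        rss = q_y - 2 * beta @ b + beta @ A @ beta
        rss = max(rss, 1e-300)
        sigma2 = rss / (n - p)
        sign, logdet_A = np.linalg.slogdet(A)
        if sign <= 0:
            return np.inf, None, None, None
        val = (n - p) * np.log(sigma2) + np.sum(np.log1p(psi * n_i)) + logdet_A
        return val, beta, sigma2, A

    ols_fallback = uniq.size < 2
    psi_hat = 0.0
    if not ols_fallback:
        res = optimize.minimize_scalar(
            crit, bounds=(np.log(1e-8), np.log(1e6)), method="bounded",
            options={"xatol": 1e-6},
        )
        psi_hat = float(np.exp(res.x))
        if _reml_crit(0.0 if psi_hat < 1e-7 else psi_hat)[0] > _reml_crit(1e-12)[0]:
            psi_hat = 0.0
        if psi_hat < 1e-7:
            psi_hat = 0.0
            ols_fallback = True
    _val, beta, sigma2, A = _reml_crit(psi_hat)
    cov = sigma2 * np.linalg.inv(A)
    se = float(np.sqrt(cov[1, 1]))
    z = beta[1] / se if se > 0 else np.inf
    pval = float(2 * stats.norm.sf(abs(z)))
    return float(beta[1]), pval, ols_fallback


def bh_adjust(pvals: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values."""
    return multipletests(np.asarray(pvals, dtype=float), method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# iterative subsampled LMM
# ---------------------------------------------------------------------------

def subsample_pixels(
    strata: Mapping[str, np.ndarray], fraction: float, rng: np.random.Generator
) -> dict[str, np.ndarray]:
    """Uniform subsample without replacement, stratified per section-region.

    Each stratum contributes ``max(1, round(fraction * N))`` pixels.
    """
    out = {}
    for key, idx in strata.items():
        idx = np.asarray(idx)
        if idx.size == 0:
            raise ValueError(f"empty stratum {key!r}")
        k = max(1, int(round(fraction * idx.size)))
        out[key] = rng.choice(idx, size=k, replace=False)
    return out


def iterative_lmm(
    sections: Sequence[MSIDataset],
    mzs: Sequence[float],
    cfg: LMMConfig | None = None,
    rng: np.random.Generator | None = None,
) -> list[LMMResult]:
    """Iterative fraction-based LMM for one technical replicate.

    ``sections`` are the sections of one technical replicate (one per
    biological sample).  Per iteration, ``fraction`` of the tumor and
    necrosis pixels of every section is drawn; for each mass the log2 fold
    change is computed from the pooled drawn-pixel means and the LMM Wald
    p-value from :func:`fit_lmm` with the biological sample as grouping;
    p-values are BH-adjusted across masses within the iteration.  Reported
    values are means (and ranges) over iterations.  Iterations in which a
    region mean is zero for a mass skip that mass's fold change and are
    counted in ``n_skipped``.
    """
    cfg = cfg or LMMConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    tech_reps = {ds.meta.tech_rep for ds in sections}
    if len(tech_reps) != 1:
        raise ValueError("iterative_lmm expects sections of one technical replicate")
    tech_rep = tech_reps.pop()

    # per section: label indices and pixel intensity matrix at the masses
    per_section = []
    for ds in sections:
        labels = ds.pixel_labels()
        t_idx = np.flatnonzero(labels == "tumor")
        n_idx = np.flatnonzero(labels == "necrosis")
        if t_idx.size == 0 or n_idx.size == 0:
            raise ValueError(
                f"section {ds.meta.section_id} lacks tumor or necrosis pixels"
            )
        mat = pixel_mass_intensities(ds, mzs)
        per_section.append((ds.meta.bio_sample, t_idx, n_idx, mat))
    if len({s[0] for s in per_section}) < 2:
        warnings.warn("fewer than two biological samples; random effect is degenerate")

    n_mz = len(mzs)
    fc_acc = [[] for _ in range(n_mz)]
    p_acc = [[] for _ in range(n_mz)]
    skipped = np.zeros(n_mz, dtype=int)
    ols_count = np.zeros(n_mz, dtype=int)

    for _it in range(cfg.iterations):
        ys, xs, gs = [], [], []
        for sample, t_idx, n_idx, mat in per_section:
            sub = subsample_pixels(
                {"tumor": t_idx, "necrosis": n_idx}, cfg.fraction, rng
            )
            for reg, idx in (("tumor", sub["tumor"]), ("necrosis", sub["necrosis"])):
                ys.append(mat[idx])
                xs.append(np.full(idx.size, 1.0 if reg == "tumor" else 0.0))
                gs.append(np.full(idx.size, sample, dtype=object))
        Y = np.vstack(ys)  # (n_drawn, n_mz)
        x = np.concatenate(xs)
        g = np.concatenate(gs)
        t_mask = x == 1.0

        raw_p = np.ones(n_mz)
        for j in range(n_mz):
            mt = Y[t_mask, j].mean()
            mn = Y[~t_mask, j].mean()
            if mt > 0 and mn > 0:
                fc_acc[j].append(np.log2(mt / mn))
            else:
                skipped[j] += 1
            _beta, pval, ols = fit_lmm(Y[:, j], x, g)
            raw_p[j] = pval
            if ols:
                ols_count[j] += 1
        adj = bh_adjust(raw_p)
        for j in range(n_mz):
            p_acc[j].append(adj[j])

    results = []
    for j, mz in enumerate(mzs):
        fcs = np.array(fc_acc[j]) if fc_acc[j] else np.array([np.nan])
        ps = np.array(p_acc[j])
        results.append(
            LMMResult(
                mz=float(mz),
                tech_rep=int(tech_rep),
                mean_log2fc=float(np.nanmean(fcs)),
                log2fc_range=(float(np.nanmin(fcs)), float(np.nanmax(fcs))),
                mean_adj_p=float(ps.mean()),
                p_range=(float(ps.min()), float(ps.max())),
                n_skipped=int(skipped[j]),
                ols_fallback_frac=float(ols_count[j] / cfg.iterations),
            )
        )
    return results


def call_significant(
    results_by_rep: Mapping[int, Sequence[LMMResult]],
    cfg: LMMConfig | None = None,
) -> pd.DataFrame:
    """Combine per-technical-replicate LMM results into per-mass verdicts.

    A mass is significant when |mean log2FC| > ``lfc_min`` and mean
    adjusted p < ``p_max`` in at least ``min_sig_tech_reps`` replicates
    with a consistent fold-change sign; the direction is tumor-up for a
    positive fold change.  Qualifying replicates with conflicting signs
    leave the mass uncalled and flagged.
    """
    cfg = cfg or LMMConfig()
    if len(results_by_rep) < 2:
        raise ValueError("needs results from at least two technical replicates")
    by_mass: dict[float, list[LMMResult]] = {}
    for _rep, results in sorted(results_by_rep.items()):
        for r in results:
            by_mass.setdefault(r.mz, []).append(r)
    rows = []
    for mz, rs in sorted(by_mass.items()):
        qual = [
            r for r in rs
            if abs(r.mean_log2fc) > cfg.lfc_min and r.mean_adj_p < cfg.p_max
        ]
        signs = {np.sign(r.mean_log2fc) for r in qual}
        conflict = len(signs) > 1
        significant = len(qual) >= cfg.min_sig_tech_reps and not conflict
        direction = ""
        if significant:
            direction = "tumor_up" if qual[0].mean_log2fc > 0 else "necrosis_up"
        rows.append(
            {
                "mz": mz,
                "n_tech_reps": len(rs),
                "n_significant_reps": len(qual),
                "mean_log2fc": float(np.mean([r.mean_log2fc for r in rs])),
                "mean_adj_p": float(np.mean([r.mean_adj_p for r in rs])),
                "significant": significant,
                "direction": direction,
                "sign_conflict": conflict,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# treated vs control
# ---------------------------------------------------------------------------

def wilcoxon_rank_sum(group_a: Sequence[float], group_b: Sequence[float]) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact for n <= 10 per group without ties, normal approximation with
    tie correction otherwise; fully tied data return p = 1.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("each group needs at least 3 values")
    pooled = np.concatenate([a, b])
    if np.all(pooled == pooled[0]):
        return 1.0
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (a.size <= 10 and b.size <= 10 and not has_ties) else "asymptotic"
    return float(stats.mannwhitneyu(a, b, alternative="two-sided", method=method).pvalue)


def pixel_roc_auc(
    treated: np.ndarray,
    control: np.ndarray,
    subset_n: int = 15000,
    rng: np.random.Generator | None = None,
) -> float:
    """ROC AUC on equally sized pixel subsets, treated as positive class.

    Each group is subsampled without replacement to ``subset_n`` pixels;
    smaller groups are used in full (with a warning).
    """
    rng = rng if rng is not None else np.random.default_rng(0)
    treated = np.asarray(treated, dtype=float)
    control = np.asarray(control, dtype=float)
    if treated.size == 0 or control.size == 0:
        raise ValueError("both groups must be non-empty")
    if treated.size < subset_n or control.size < subset_n:
        warnings.warn("group smaller than subset_n; using all pixels")
    t = treated if treated.size <= subset_n else rng.choice(treated, subset_n, replace=False)
    c = control if control.size <= subset_n else rng.choice(control, subset_n, replace=False)
    return rank_auc(t, c)


def treatment_analysis(
    sections: Sequence[MSIDataset],
    mzs: Sequence[float],
    cfg: TreatmentConfig | None = None,
    rng: np.random.Generator | None = None,
) -> dict:
    """Per-replicate Wilcoxon p-values, arm log2FC, and per-sample AUCs.

    Wilcoxon compares the tumor-ROI mean intensities of the treated
    sections against the control sections within each technical replicate.
    The log2 fold change is log2(mean treated / mean control) over section
    means, so positive values mean elevated in the treated arm.  The AUC of
    biological sample s in technical replicate r contrasts s's tumor pixels
    (own arm as positive class) against all opposite-arm tumor pixels of
    the same replicate, on equally sized subsets.
    """
    cfg = cfg or TreatmentConfig()
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)
    mzs = list(mzs)
    tech_reps = sorted({ds.meta.tech_rep for ds in sections})

    wilcox_p: dict[int, np.ndarray] = {}
    log2fc_by_rep: dict[int, np.ndarray] = {}
    auc: dict[tuple[str, int], np.ndarray] = {}
    arm_of: dict[str, str] = {}

    for rep in tech_reps:
        rep_sections = [ds for ds in sections if ds.meta.tech_rep == rep]
        means = {"treated": [], "control": []}
        pixels: dict[str, list[np.ndarray]] = {"treated": [], "control": []}
        per_sample_pixels: dict[str, np.ndarray] = {}
        for ds in rep_sections:
            arm_of[ds.meta.bio_sample] = ds.meta.arm
            inten = section_mass_intensities(ds, mzs, regions=("tumor",))
            means[ds.meta.arm].append(inten)
            labels = ds.pixel_labels()
            mat = pixel_mass_intensities(ds, mzs)[labels == "tumor"]
            pixels[ds.meta.arm].append(mat)
            per_sample_pixels[ds.meta.bio_sample] = mat
        if len(means["treated"]) < 3 or len(means["control"]) < 3:
            warnings.warn(
                f"tech rep {rep}: fewer than 3 sections per arm; "
                "Wilcoxon skipped, criteria denominators adjusted"
            )
        else:
            tr = np.vstack(means["treated"])
            ct = np.vstack(means["control"])
            pvals = np.ones(len(mzs))
            for j in range(len(mzs)):
                pvals[j] = wilcoxon_rank_sum(tr[:, j], ct[:, j])
            wilcox_p[rep] = pvals
        if means["treated"] and means["control"]:
            tr_m = np.vstack(means["treated"]).mean(axis=0)
            ct_m = np.vstack(means["control"]).mean(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                log2fc_by_rep[rep] = np.log2(tr_m / ct_m)
        arm_pool = {k: np.vstack(v) for k, v in pixels.items() if v}
        for sample, mat in per_sample_pixels.items():
            own = arm_of[sample]
            other = "control" if own == "treated" else "treated"
            if other not in arm_pool:
                continue
            aucs = np.zeros(len(mzs))
            for j in range(len(mzs)):
                aucs[j] = pixel_roc_auc(
                    mat[:, j], arm_pool[other][:, j], cfg.roc_subset_n, rng
                )
            auc[(sample, rep)] = aucs
    return {
        "mzs": mzs,
        "tech_reps": tech_reps,
        "wilcoxon_p": wilcox_p,
        "log2fc": log2fc_by_rep,
        "auc": auc,
        "arm_of": arm_of,
    }


def call_treatment_markers(
    analysis: dict, cfg: TreatmentConfig | None = None
) -> pd.DataFrame:
    """Apply the multi-replicate treatment-marker criteria.

    Wilcoxon criterion: p < ``wilcoxon_p_max`` in at least
    ``wilcoxon_min_tech_reps`` of the available technical replicates.
    AUC criterion: a biological sample passes in a replicate when its
    own-arm-positive AUC is >= ``auc_min``; a sample qualifies when it
    passes in at least ``auc_min_tech_reps`` of its available replicates,
    and the criterion holds when at least ``auc_min_bio_reps`` samples of
    one arm qualify.  Denominators shrink to the replicates actually
    available (sections may be excluded upstream).  The reported AUC is
    the mean over the qualifying sample-replicate AUCs; the direction
    comes from the sign of the arm log2FC (positive = treated-up).
    """
    cfg = cfg or TreatmentConfig()
    mzs = analysis["mzs"]
    wilcox = analysis["wilcoxon_p"]
    aucs = analysis["auc"]
    arm_of = analysis["arm_of"]
    n_reps = len(analysis["tech_reps"])
    samples = sorted(arm_of)
    rows = []
    for j, mz in enumerate(mzs):
        pvals = [wilcox[r][j] for r in wilcox]
        n_sig = sum(p < cfg.wilcoxon_p_max for p in pvals)
        wilcoxon_ok = bool(pvals) and n_sig >= min(cfg.wilcoxon_min_tech_reps, len(pvals))
        mean_fc = float(np.nanmean([analysis["log2fc"][r][j] for r in analysis["log2fc"]]))

        qualifying_aucs = []
        passing_by_arm = {"treated": 0, "control": 0}
        n_by_arm = {"treated": 0, "control": 0}
        for s in samples:
            reps_avail = [r for (ss, r) in aucs if ss == s]
            if not reps_avail:
                continue
            n_by_arm[arm_of[s]] += 1
            vals = [aucs[(s, r)][j] for r in reps_avail]
            n_pass = sum(v >= cfg.auc_min for v in vals)
            need = min(cfg.auc_min_tech_reps, len(reps_avail))
            if n_pass >= need:
                passing_by_arm[arm_of[s]] += 1
                qualifying_aucs.extend(v for v in vals if v >= cfg.auc_min)
        auc_ok = any(
            passing_by_arm[a] >= min(cfg.auc_min_bio_reps, max(n_by_arm[a], 1))
            for a in ("treated", "control")
            if n_by_arm[a] > 0
        )
        rows.append(
            {
                "mz": float(mz),
                "mean_wilcoxon_p": float(np.mean(pvals)) if pvals else float("nan"),
                "n_wilcoxon_sig_reps": int(n_sig),
                "wilcoxon_ok": bool(wilcoxon_ok),
                "mean_log2fc": mean_fc,
                "auc": float(np.mean(qualifying_aucs)) if qualifying_aucs else float("nan"),
                "auc_ok": bool(auc_ok),
                "marker": bool(wilcoxon_ok and auc_ok),
                "direction": "treated_up" if mean_fc > 0 else "control_up",
            }
        )
    return pd.DataFrame(rows)


def pca_scores(
    X: np.ndarray, n_components: int = 2
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """PCA of a (sections x masses) matrix by SVD of the centered data.

    Returns ``(scores, loadings, explained_variance_ratio)``.  Constant
    columns are dropped with a warning.  Sign convention: within each
    component the largest-magnitude loading is positive.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] < 3:
        raise ValueError("PCA needs at least 3 sections")
    keep = X.std(axis=0) > 0
    if not np.all(keep):
        warnings.warn(f"dropping {int(np.sum(~keep))} constant column(s)")
        X = X[:, keep]
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    n_components = min(n_components, S.size)
    evr = S**2 / np.sum(S**2)
    scores = U[:, :n_components] * S[:n_components]
    loadings = Vt[:n_components]
    for k in range(n_components):
        imax = np.argmax(np.abs(loadings[k]))
        if loadings[k, imax] < 0:
            loadings[k] = -loadings[k]
            scores[:, k] = -scores[:, k]
    return scores, loadings, evr[:n_components]
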