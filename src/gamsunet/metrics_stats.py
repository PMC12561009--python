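"""Evaluation metrics, slice filtering, volumetry and nonparametric tests.

Covers the full evaluation protocol: per-slice Dice / SSIM / confusion
metrics, the exact-0/1 slice-exclusion rule, whole-brain volumetry with
resize correction, volume regression agreement, and the Wilcoxon
signed-rank / Kruskal-Wallis / Shapiro-Wilk test battery used to compare
segmentation models.

The Wilcoxon and Kruskal-Wallis statistics are computed from their rank
formulas here (with exact sign-enumeration for small Wilcoxon samples);
Shapiro-Wilk delegates to scipy's vetted implementation.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, replace

import numpy as np
from scipy import stats as sp_stats
from scipy.signal import fftconvolve


# ---------------------------------------------------------------------------
# per-slice metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsRecord:
    subject_id: str
    slice_index: int
    dice: float
    ssim: float
    tp: int
    fp: int
    fn: int
    tn: int
    included: bool = True


@dataclass
class VolumeEstimate:
    subject_id: str
    predicted_mm3: float
    reference_mm3: float

    def __post_init__(self):
        if self.predicted_mm3 < 0 or self.reference_mm3 < 0:
            raise ValueError("volumes must be non-negative")


@dataclass
class StatReport:
    wilcoxon_p: dict[str, float]
    kruskal_H: float
    kruskal_p: float
    shapiro_p: float


def _check_binary_pair(pred, gt):
    pred = np.asarray(pred)
    gt = np.asarray(gt)
    if pred.shape != gt.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {gt.shape}")
    return pred.astype(bool), gt.astype(bool)


def dice(pred_mask, gt_mask) -> float:
    """Dice overlap 2|P&G| / (|P|+|G|); defined as 1.0 for two empty masks."""
    p, g = _check_binary_pair(pred_mask, gt_mask)
    denom = p.sum() + g.sum()
    if denom == 0:
        return 1.0
    return float(2.0 * np.logical_and(p, g).sum() / denom)


def confusion_metrics(pred_mask, gt_mask) -> tuple[float, float, float]:
    """(accuracy, precision, recall); undefined ratios come back as NaN."""
    p, g = _check_binary_pair(pred_mask, gt_mask)
    tp = int(np.logical_and(p, g).sum())
    fp = int(np.logical_and(p, ~g).sum())
    fn = int(np.logical_and(~p, g).sum())
    tn = int(np.logical_and(~p, ~g).sum())
    accuracy = (tp + tn) / (tp + fp + fn + tn)
    precision = tp / (tp + fp) if tp + fp else float("nan")
    recall = tp / (tp + fn) if tp + fn else float("nan")
    return accuracy, precision, recall


_SSIM_WIN = 11
_SSIM_SIGMA = 1.5
_SSIM_K1 = 0.01
_SSIM_K2 = 0.03


def _gaussian_kernel2d(win: int, sigma: float) -> np.ndarray:
    r = np.arange(win) - (win - 1) / 2.0
    k1 = np.exp(-(r**2) / (2 * sigma**2))
    k = np.outer(k1, k1)
    return k / k.sum()


def ssim(pred, gt, data_range: float = 1.0) -> float:
    """Mean local structural similarity (Wang et al. 2004 settings).

    11x11 Gaussian window, sigma 1.5, K1=0.01, K2=0.03; only windows fully
    inside the image contribute (valid-mode convolution), matching the
    reference description.  Inputs are expected scaled to ``data_range``
    (binarized masks use range 1).
    """
    a = np.asarray(pred, dtype=np.float64)
    b = np.asarray(gt, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("ssim expects two 2D arrays of identical shape")
    if min(a.shape) < _SSIM_WIN:
        raise ValueError(f"image smaller than the {_SSIM_WIN}x{_SSIM_WIN} SSIM window")
    w = _gaussian_kernel2d(_SSIM_WIN, _SSIM_SIGMA)
    mu_a = fftconvolve(a, w, mode="valid")
    mu_b = fftconvolve(b, w, mode="valid")
    saa = fftconvolve(a * a, w, mode="valid") - mu_a**2
    sbb = fftconvolve(b * b, w, mode="valid") - mu_b**2
    sab = fftconvolve(a * b, w, mode="valid") - mu_a * mu_b
    c1 = (_SSIM_K1 * data_range) ** 2
    c2 = (_SSIM_K2 * data_range) ** 2
    num = (2 * mu_a * mu_b + c1) * (2 * sab + c2)
    den = (mu_a**2 + mu_b**2 + c1) * (saa + sbb + c2)
    return float(np.mean(num / den))


def slice_record(pred_mask, gt_mask, subject_id: str = "", slice_index: int = 0) -> MetricsRecord:
    """Bundle Dice, SSIM and confusion counts for one slice."""
    p, g = _check_binary_pair(pred_mask, gt_mask)
    rec = MetricsRecord(
        subject_id=subject_id,
        slice_index=slice_index,
        dice=dice(p, g),
        ssim=ssim(p.astype(np.float64), g.astype(np.float64)),
        tp=int(np.logical_and(p, g).sum()),
        fp=int(np.logical_and(p, ~g).sum()),
        fn=int(np.logical_and(~p, g).sum()),
        tn=int(np.logical_and(~p, ~g).sum()),
    )
    return rec


def filter_slices(records: list[MetricsRecord]) -> list[MetricsRecord]:
    """Exclude slices whose Dice or SSIM is exactly 0 or exactly 1.

    These are the empty / non-informative slices at the top and bottom of
    a volume; the comparison is literal equality, no epsilon window.
    """
    out = []
    for r in records:
        degenerate = r.dice in (0.0, 1.0) or r.ssim in (0.0, 1.0)
        out.append(replace(r, included=not degenerate))
    return out


# ---------------------------------------------------------------------------
# volumetry
# ---------------------------------------------------------------------------

def whole_brain_volume(mask, orig_dims: tuple[int, int],
                       orig_spacing: tuple[float, float, float]) -> float:
    """Nonzero-voxel volume in mm^3, corrected for the in-plane resize.

    A mask predicted on a T x T grid that originated from a Dx x Dy slice
    with spacing (sx, sy, sz) has per-pixel area (sx*Dx/T) * (sy*Dy/T),
    so physical volume is invariant to the resize.
    """
    labels = mask.labels if hasattr(mask, "labels") else np.asarray(mask)
    if labels.ndim != 3:
        raise ValueError("expected a 3D mask grid")
    if orig_dims is None or orig_spacing is None:
        raise ValueError("volumetry requires orig_dims and orig_spacing provenance")
    tx, ty = labels.shape[:2]
    dx, dy = orig_dims
    sx, sy, sz = orig_spacing
    voxel_mm3 = (sx * dx / tx) * (sy * dy / ty) * sz
    return float(np.count_nonzero(labels) * voxel_mm3)


def volume_regression(estimates: list[VolumeEstimate]) -> float:
    """R^2 of the OLS regression of predicted volume on reference volume."""
    if len(estimates) < 2:
        raise ValueError("need at least two volume estimates")
    ref = np.array([e.reference_mm3 for e in estimates], dtype=np.float64)
    pred = np.array([e.predicted_mm3 for e in estimates], dtype=np.float64)
    if np.ptp(ref) == 0:
        raise ValueError("reference volumes are constant; regression undefined")
    res = sp_stats.linregress(ref, pred)
    return float(res.rvalue**2)


# ---------------------------------------------------------------------------
# nonparametric tests
# ---------------------------------------------------------------------------

_WILCOXON_EXACT_N = 12


def wilcoxon_signed_rank(x, y) -> float:
    """Two-sided Wilcoxon signed-rank p-value for paired samples.

    Zero differences are discarded (classic Wilcoxon). For n <= 12
    retained pairs the null distribution of W+ is enumerated over all 2^n
    sign assignments (valid under ties); larger samples use the
    continuity-corrected normal approximation with tie-corrected variance.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.shape != y.shape or x.ndim != 1 or x.size < 5:
        raise ValueError("need paired 1D samples of equal length >= 5")
    d = x - y
    d = d[d != 0]
    n = d.size
    if n == 0:
        raise ValueError("all paired differences are zero")
    ranks = sp_stats.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= _WILCOXON_EXACT_N:
        signs = np.array(list(itertools.product((0.0, 1.0), repeat=n)))
        w_all = signs @ ranks
        p_ge = np.mean(w_all >= w_plus - 1e-12)
        p_le = np.mean(w_all <= w_plus + 1e-12)
        return float(min(1.0, 2.0 * min(p_ge, p_le)))
    mean = n * (n + 1) / 4.0
    _, counts = np.unique(ranks, return_counts=True)
    tie_term = float(((counts**3 - counts)).sum()) / 48.0
    var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term
    # continuity-corrected two-sided normal approximation
    z = (abs(w_plus - mean) - 0.5) / math.sqrt(var)
    return float(min(1.0, 2.0 * sp_stats.norm.sf(max(z, 0.0))))


def kruskal_wallis(groups: list[np.ndarray]) -> tuple[float, float]:
    """Tie-corrected Kruskal-Wallis H and its chi-squared p-value."""
    groups = [np.asarray(g, dtype=np.float64) for g in groups]
    if len(groups) < 2 or any(g.size == 0 for g in groups):
        raise ValueError("need >= 2 non-empty groups")
    pooled = np.concatenate(groups)
    n_total = pooled.size
    if np.ptp(pooled) == 0:
        raise ValueError("all observations identical; ranks are degenerate")
    ranks = sp_stats.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start:start + g.size]
        h += r.sum() ** 2 / g.size
        start += g.size
    h = 12.0 / (n_total * (n_total + 1)) * h - 3.0 * (n_total + 1)
    _, counts = np.unique(pooled, return_counts=True)
    correction = 1.0 - ((counts**3 - counts).sum()) / (n_total**3 - n_total)
    h /= correction
    p = float(sp_stats.chi2.sf(h, len(groups) - 1))
    return float(h), p


def shapiro_wilk(x) -> float:
    """Shapiro-Wilk normality p-value (delegated to scipy)."""
    x = np.asarray(x, dtype=np.float64)
    if x.ndim != 1 or x.size < 3:
        raise ValueError("Shapiro-Wilk needs a 1D sample with n >= 3")
    return float(sp_stats.shapiro(x).pvalue)


def compare_models(dice_by_model: dict[str, np.ndarray], reference: str) -> StatReport:
    """Assemble the full statistical report against a reference model.

    Pairwise Wilcoxon tests of the reference against every other model,
    a Kruskal-Wallis test over all models, and Shapiro-Wilk normality of
    the reference model's scores.
    """
    if reference not in dice_by_model:
        raise ValueError(f"reference model {reference!r} missing")
    ref_scores = np.asarray(dice_by_model[reference], dtype=np.float64)
    wilcoxon_p = {
        name: wilcoxon_signed_rank(ref_scores, np.asarray(scores, dtype=np.float64))
        for name, scores in dice_by_model.items() if name != reference
    }
    h, p = kruskal_wallis([np.asarray(v) for v in dice_by_model.values()])
    return StatReport(
        wilcoxon_p=wilcoxon_p,
        kruskal_H=h,
        kruskal_p=p,
        shapiro_p=shapiro_wilk(ref_scores),
    )
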