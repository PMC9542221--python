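"""Image-quality and agreement metrics.

MSE / SSIM / PSNR are evaluated inside the smallest axis-aligned box that
contains the image foreground, intersected with the acquired image's own
pixel domain.  Agreement between paired probability outputs is quantified
with the identity-regression R^2 and the two-way absolute-agreement,
single-measurement intra-class correlation coefficient (ICC(2,1)).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from skimage.metrics import structural_similarity

__all__ = [
    "EvaluationDomain",
    "foreground_box",
    "mse_metric",
    "psnr_metric",
    "ssim_metric",
    "icc_agreement",
    "r2_identity",
    "summarize_cohort",
]


class DomainError(ValueError):
    pass


@dataclass(frozen=True)
class EvaluationDomain:
    """Bounding box (lower inclusive, upper exclusive per axis) plus mask."""

    lower: tuple[int, ...]
    upper: tuple[int, ...]
    mask: np.ndarray | None = None  # restricted domain inside the box, box-shaped

    def slices(self) -> tuple[slice, ...]:
        return tuple(slice(lo, up) for lo, up in zip(self.lower, self.upper))

    def crop(self, volume: np.ndarray) -> np.ndarray:
        return volume[self.slices()]


def foreground_box(*volumes: np.ndarray, domain_mask: np.ndarray | None = None) -> EvaluationDomain:
    """Smallest box containing the union foreground of the given volumes.

    The optional ``domain_mask`` (e.g. the acquired image's pixel domain)
    is intersected with the box and carried along for metric evaluation.
    """
    if not volumes:
        raise DomainError("no volumes given")
    fg = np.zeros(volumes[0].shape, bool)
    for v in volumes:
        if v.shape != fg.shape:
            raise DomainError("volumes do not share one grid")
        fg |= v != 0
    if not fg.any():
        raise DomainError("all-zero volume has no foreground box")
    idx = np.nonzero(fg)
    lower = tuple(int(i.min()) for i in idx)
    upper = tuple(int(i.max()) + 1 for i in idx)
    mask = None
    if domain_mask is not None:
        box = tuple(slice(lo, up) for lo, up in zip(lower, upper))
        mask = np.asarray(domain_mask, bool)[box]
        if not mask.any():
            raise DomainError("domain mask empty inside the foreground box")
    return EvaluationDomain(lower, upper, mask)


def _cropped(a: np.ndarray, b: np.ndarray, domain: EvaluationDomain):
    if a.shape != b.shape:
        raise DomainError("images do not share one grid")
    ca, cb = domain.crop(a), domain.crop(b)
    if domain.mask is not None:
        return ca[domain.mask], cb[domain.mask], ca, cb
    return ca.ravel(), cb.ravel(), ca, cb


def mse_metric(a: np.ndarray, b: np.ndarray, domain: EvaluationDomain) -> float:
    va, vb, _, _ = _cropped(a, b, domain)
    return float(np.mean((va - vb) ** 2))


def psnr_metric(a: np.ndarray, b: np.ndarray, domain: EvaluationDomain,
                data_range: float | None = None) -> float:
    """PSNR = 10 log10(L^2 / MSE); L defaults to max |a| over the domain.

    Identical images have zero MSE and report ``inf`` (flagged sentinel).
    """
    mse = mse_metric(a, b, domain)
    va, _, _, _ = _cropped(a, b, domain)
    lrange = float(np.abs(va).max()) if data_range is None else float(data_range)
    if mse == 0.0:
        return float("inf")
    return float(10.0 * np.log10(lrange**2 / mse))


def ssim_metric(a: np.ndarray, b: np.ndarray, domain: EvaluationDomain,
                data_range: float | None = None) -> float:
    """Mean SSIM over the foreground box (Gaussian-weighted standard form).

    Computed slice-wise on the last axis for 3-D inputs and averaged;
    stabilizers K1=0.01, K2=0.03 as in the canonical definition.
    """
    _, _, ca, cb = _cropped(a, b, domain)
    if data_range is None:
        rng = float(np.abs(ca).max())
        data_range = rng if rng > 0 else 1.0
    kw = dict(gaussian_weights=True, sigma=1.5, use_sample_covariance=False,
              K1=0.01, K2=0.03, data_range=data_range)
    if ca.ndim == 2:
        return float(structural_similarity(ca, cb, **kw))
    win = min(11, (min(ca.shape[:2]) // 2) * 2 - 1)
    if win < 3:
        raise DomainError("foreground box too small for SSIM")
    vals = [
        structural_similarity(ca[..., k], cb[..., k], win_size=win, **kw)
        for k in range(ca.shape[-1])
    ]
    return float(np.mean(vals))


def icc_agreement(pairs: np.ndarray) -> float:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    ``pairs`` is (n, 2): n targets rated by two methods.  Computed from the
    two-way ANOVA decomposition:

        ICC = (MS_R - MS_E) / (MS_R + MS_E + 2/n * (MS_C - MS_E))

    with MS_R rows (targets), MS_C columns (methods), MS_E residual.
    """
    x = np.asarray(pairs, float)
    if x.ndim != 2 or x.shape[1] != 2:
        raise DomainError("pairs must be an (n, 2) array")
    n, k = x.shape
    if n < 3:
        raise DomainError("ICC needs at least 3 pairs")
    grand = x.mean()
    row_means = x.mean(axis=1)
    col_means = x.mean(axis=0)
    ss_rows = k * np.sum((row_means - grand) ** 2)
    ss_cols = n * np.sum((col_means - grand) ** 2)
    ss_tot = np.sum((x - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))
    denom = ms_r + (k - 1) * ms_e + (k / n) * (ms_c - ms_e)
    if denom == 0:
        raise DomainError("zero total variance; ICC undefined")
    return float((ms_r - ms_e) / denom)


def r2_identity(x: np.ndarray, y: np.ndarray) -> float:
    """R^2 of y against the identity line y = x.

    R^2 = 1 - sum (y - x)^2 / sum (y - mean(y))^2; equals 1 iff y == x for
    non-constant y, and may be negative for strong deviation.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape:
        raise DomainError("x and y must have equal length")
    ss_tot = np.sum((y - y.mean()) ** 2)
    if ss_tot == 0:
        raise DomainError("constant y; identity R^2 undefined")
    return float(1.0 - np.sum((y - x) ** 2) / ss_tot)


def summarize_cohort(per_subject_metrics: dict[str, np.ndarray]) -> dict[str, dict[str, float]]:
    """Mean and (n-1)-denominator std per metric across subjects."""
    out: dict[str, dict[str, float]] = {}
    for name, vals in per_subject_metrics.items():
        v = np.asarray(vals, float)
        std = float(v.std(ddof=1)) if v.size > 1 else 0.0
        out[name] = {"mean": float(v.mean()), "std": std, "n": int(v.size)}
    return out
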