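"""Closed-form MR signal models for spin-echo and inversion-recovery spin-echo.

Any weighted contrast (T1w, T2w, FLAIR, post-contrast T1w) is an ideal,
noiseless function of the three relaxometry maps (T1, T2, PD) and the
acquisition parameters (TE, TR, TI).  These forward models drive both the
phantom simulator and the non-trainable physics layer of the synthesis
network, and the MAE-based synthesis loss is defined here as well.

Units: relaxation times and sequence timings in milliseconds; PD in
arbitrary units (the phantom generator scales PD to [0, 1]).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "AcquisitionParams",
    "RelaxometryMaps",
    "WeightedImage",
    "CONTRAST_LABELS",
    "default_protocol",
    "simulate_spin_echo",
    "simulate_ir_se",
    "simulate_contrast",
    "mae_image",
    "synthesis_loss",
]

CONTRAST_LABELS = ("T1w", "T2w", "FLAIR", "T1w_c")

_TINY = 1e-30  # guards divisions at background voxels where maps are 0


class ParameterError(ValueError):
    """Invalid acquisition parameters."""


class GridError(ValueError):
    """Volumes do not share a common grid shape."""


class DomainError(ValueError):
    """Empty evaluation domain."""


class ConfigError(KeyError):
    """Unknown contrast label or missing protocol entry."""


@dataclass(frozen=True)
class AcquisitionParams:
    """Sequence family and timing parameters of one weighted acquisition.

    ``sequence`` is ``"SE"`` (spin echo) or ``"IR_SE"`` (inversion-recovery
    spin echo); ``ti`` is required iff the sequence is IR_SE.
    """

    sequence: str
    te: float
    tr: float
    ti: float | None = None

    def __post_init__(self) -> None:
        if self.sequence not in ("SE", "IR_SE"):
            raise ParameterError(f"unknown sequence {self.sequence!r}")
        if not (self.te > 0 and self.tr > 0):
            raise ParameterError("TE and TR must be positive")
        if self.te >= self.tr:
            raise ParameterError("TE must be smaller than TR")
        if self.sequence == "IR_SE":
            if self.ti is None:
                raise ParameterError("IR_SE requires an inversion time TI")
            if not (0 < self.ti < self.tr):
                raise ParameterError("TI must lie in (0, TR)")


@dataclass
class RelaxometryMaps:
    """Voxel-wise T1/T2/PD parameter volumes plus a foreground mask.

    Background voxels (mask False) are exactly zero in all three maps;
    on the foreground T1 >= T2 > 0 holds (physical constraint).
    """

    t1: np.ndarray
    t2: np.ndarray
    pd: np.ndarray
    foreground_mask: np.ndarray

    def __post_init__(self) -> None:
        shapes = {self.t1.shape, self.t2.shape, self.pd.shape, self.foreground_mask.shape}
        if len(shapes) != 1:
            raise GridError(f"maps do not share one grid shape: {shapes}")
        self.foreground_mask = self.foreground_mask.astype(bool)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.t1.shape

    def validate(self) -> None:
        m = self.foreground_mask
        if not (np.all(self.t1[m] > 0) and np.all(self.t2[m] > 0)):
            raise ParameterError("T1 and T2 must be strictly positive on the foreground")
        if not np.all(self.t1[m] >= self.t2[m]):
            raise ParameterError("T1 >= T2 violated on the foreground")
        bg = ~m
        if bg.any() and not (
            np.all(self.t1[bg] == 0) and np.all(self.t2[bg] == 0) and np.all(self.pd[bg] == 0)
        ):
            raise ParameterError("background voxels must be exactly zero")


@dataclass
class WeightedImage:
    """A simulated or synthesized weighted contrast volume (or slice)."""

    intensities: np.ndarray
    contrast: str
    params: AcquisitionParams
    mask: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.mask is None:
            self.mask = self.intensities != 0
        self.mask = self.mask.astype(bool)
        if self.mask.shape != self.intensities.shape:
            raise GridError("mask and intensities shapes differ")


def _se_signal(t1, t2, pd, te, tr):
    """S = PD * (1 - exp(-TR/T1)) * exp(-TE/T2), evaluated where maps > 0."""
    t1s = np.where(t1 > 0, t1, _TINY)
    t2s = np.where(t2 > 0, t2, _TINY)
    s = pd * (1.0 - np.exp(-tr / t1s)) * np.exp(-te / t2s)
    return np.where((t1 > 0) & (t2 > 0), s, 0.0)


def _ir_se_signal(t1, t2, pd, te, tr, ti):
    """Magnitude IR-SE: S = PD * |1 - 2 exp(-TI/T1) + exp(-TR/T1)| * exp(-TE/T2)."""
    t1s = np.where(t1 > 0, t1, _TINY)
    t2s = np.where(t2 > 0, t2, _TINY)
    recovery = 1.0 - 2.0 * np.exp(-ti / t1s) + np.exp(-tr / t1s)
    s = pd * np.abs(recovery) * np.exp(-te / t2s)
    return np.where((t1 > 0) & (t2 > 0), s, 0.0)


def simulate_spin_echo(maps: RelaxometryMaps, params: AcquisitionParams,
                       contrast: str = "T1w") -> WeightedImage:
    """Ideal spin-echo forward model.

    Monotonically increasing in TR, decreasing in TE, and linear in PD.
    """
    if params.sequence != "SE":
        raise ParameterError("simulate_spin_echo requires an SE parameter set")
    s = _se_signal(maps.t1, maps.t2, maps.pd, params.te, params.tr)
    s = np.where(maps.foreground_mask, s, 0.0)
    return WeightedImage(s, contrast, params, maps.foreground_mask)


def simulate_ir_se(maps: RelaxometryMaps, params: AcquisitionParams,
                   contrast: str = "FLAIR") -> WeightedImage:
    """Ideal inversion-recovery spin-echo with magnitude reconstruction.

    Signal is nulled for tissue whose T1 satisfies the inversion null
    condition (TI = T1 ln 2 at long TR), which is how FLAIR suppresses CSF.
    """
    if params.sequence != "IR_SE":
        raise ParameterError("simulate_ir_se requires an IR_SE parameter set")
    s = _ir_se_signal(maps.t1, maps.t2, maps.pd, params.te, params.tr, params.ti)
    s = np.where(maps.foreground_mask, s, 0.0)
    return WeightedImage(s, contrast, params, maps.foreground_mask)


def default_protocol() -> dict[str, AcquisitionParams]:
    """Per-contrast acquisition parameters (ms) for the simulated protocol.

    Classic 1.5 T presets: short-TE/TR SE for T1w and post-contrast T1w,
    long-TE/TR SE for T2w, and a long-TI IR-SE for FLAIR (TI 2200 ms).
    """
    return {
        "T1w": AcquisitionParams("SE", te=10.0, tr=500.0),
        "T2w": AcquisitionParams("SE", te=100.0, tr=8000.0),
        "FLAIR": AcquisitionParams("IR_SE", te=140.0, tr=9000.0, ti=2200.0),
        "T1w_c": AcquisitionParams("SE", te=10.0, tr=500.0),
    }


def simulate_contrast(maps: RelaxometryMaps, contrast_label: str,
                      protocol_config: Mapping[str, AcquisitionParams]) -> WeightedImage:
    """Dispatch a contrast label to the matching closed-form model."""
    if contrast_label not in protocol_config:
        raise ConfigError(f"protocol config has no entry for {contrast_label!r}")
    params = protocol_config[contrast_label]
    if params.sequence == "IR_SE":
        return simulate_ir_se(maps, params, contrast=contrast_label)
    return simulate_spin_echo(maps, params, contrast=contrast_label)


def mae_image(acquired: WeightedImage | np.ndarray,
              synthesized: WeightedImage | np.ndarray,
              domain_mask: np.ndarray | None = None) -> float:
    """Mean absolute error over the pixel domain of the acquired image.

    MAE(m, m_syn) = (1/|chi|) * sum_{x in chi} |m(x) - m_syn(x)|.
    """
    a = acquired.intensities if isinstance(acquired, WeightedImage) else np.asarray(acquired)
    b = synthesized.intensities if isinstance(synthesized, WeightedImage) else np.asarray(synthesized)
    if a.shape != b.shape:
        raise GridError("images do not share one grid")
    if domain_mask is None:
        domain_mask = acquired.mask if isinstance(acquired, WeightedImage) else np.ones(a.shape, bool)
    domain_mask = np.asarray(domain_mask, bool)
    if domain_mask.shape != a.shape:
        raise GridError("domain mask shape differs from the images")
    n = int(domain_mask.sum())
    if n == 0:
        raise DomainError("empty evaluation domain")
    return float(np.abs(a[domain_mask] - b[domain_mask]).sum() / n)


def synthesis_loss(batch_acquired: Sequence, batch_synth: Sequence,
                   domain_masks: Sequence[np.ndarray] | None = None) -> float:
    """Average MAE over a batch of (acquired, synthesized) image pairs.

    L_syn = (1/M) * sum_k MAE(m_k, m_syn^k), with M the number of images
    entering the average.  Reduces to ``mae_image`` for M = 1.
    """
    if len(batch_acquired) != len(batch_synth):
        raise DomainError("batches must have equal length")
    m = len(batch_acquired)
    if m == 0:
        raise DomainError("empty batch")
    if domain_masks is None:
        domain_masks = [None] * m
    return float(np.mean([
        mae_image(a, s, dm) for a, s, dm in zip(batch_acquired, batch_synth, domain_masks)
    ]))
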