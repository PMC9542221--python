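"""Self-supervised contrast synthesis via relaxometry-map prediction.

Two weighted contrasts (e.g. T1w and T2w) enter two convolutional
encoders whose latent features are fused with a pixel-wise max; three
decoders emit T1, T2 and PD map slices, and a non-trainable physics layer
converts the predicted maps into weighted intensities through the ideal
spin-echo / IR-SE equations.  Training minimizes the average MAE between
acquired and physics-synthesized images, so no map ground truth is ever
seen: supervision comes from the acquired weighted images alone.

The network is 2-D slice-wise (axial slices are batch elements); volumes
are reassembled at inference.  All computation runs on the package's
NumPy autodiff engine and is deterministic given the config seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace as dc_replace
from typing import Sequence

import numpy as np
from sklearn.base import BaseEstimator

from . import _autograd as ag
from .physics import AcquisitionParams, RelaxometryMaps, WeightedImage, simulate_contrast
from .phantom import SubjectRecord
from .radiomics import normalize_by_reference

__all__ = [
    "SynthNetConfig",
    "SelfSupervisedSynthesizer",
    "build_network",
    "fuse_latents",
    "physics_layer",
    "train_self_supervised",
    "predict_maps",
    "leave_one_out_synthesize",
    "loo_splits",
]

MAP_NAMES = ("t1", "t2", "pd")

# FLAIR is synthesized from (T1w, T2w), T2w from (T1w, FLAIR)
SYNTH_INPUTS = {"FLAIR": ("T1w", "T2w"), "T2w": ("T1w", "FLAIR")}


@dataclass(frozen=True)
class SynthNetConfig:
    """Configuration of the synthesis network and its training protocol."""

    input_contrasts: tuple[str, str] = ("T1w", "T2w")
    target_contrast: str = "FLAIR"
    base_width: int = 16
    depth: int = 1                     # number of pooling levels
    learning_rate: float = 1e-4
    batch_size: int = 32
    max_epochs: int = 40
    early_stop_patience: int = 10
    seed: int = 0
    val_fraction: float = 0.2
    # physical output ranges (scaled sigmoid per map), ms / ms / a.u.
    map_ranges: dict = field(default_factory=lambda: {
        "t1": (50.0, 5000.0), "t2": (10.0, 2500.0), "pd": (0.0, 1.2)})
    # contrasts entering the loss; None = inputs + target, each through its
    # own physics layer (identifies the maps); may be set to the target only
    loss_contrasts: tuple[str, ...] | None = None
    min_slice_foreground: int = 16
    # >1: probe several inits briefly, continue the best by validation loss
    n_init_candidates: int = 1
    # 1 turns the network into a voxel-wise map inverter (no spatial
    # context, hence no texture smoothing); 3 is the standard conv net
    kernel_size: int = 3
    # train on every n-th axial slice: subject diversity matters more than
    # slice count, so striding trades epochs for cohort breadth
    slice_stride: int = 1
    # supervise on reference-normalized images (the space the radiomic
    # features are computed in); PD is then identified only up to the
    # subject's white-matter gain
    normalize_targets: bool = False
    # validation domain for early stopping / init selection: "foreground"
    # or "lesion" (whole-tumor voxels; the region downstream radiomics
    # reads, so model selection is sensitive to lesion fidelity)
    val_region: str = "foreground"

    def __post_init__(self) -> None:
        if self.target_contrast in self.input_contrasts:
            raise ValueError("target contrast must not be an input contrast")

    def resolved_loss_contrasts(self) -> tuple[str, ...]:
        if self.loss_contrasts is not None:
            return tuple(self.loss_contrasts)
        return (*self.input_contrasts, self.target_contrast)


# --------------------------------------------------------------------------
# network topology
# --------------------------------------------------------------------------

class _ConvBlock:
    """conv(k) -> ReLU -> conv(k) -> ReLU."""

    def __init__(self, rng, c_in, c_out, k=3):
        self.w1 = _he(rng, (c_out, c_in, k, k))
        self.b1 = ag.Tensor(np.zeros(c_out), requires_grad=True)
        self.w2 = _he(rng, (c_out, c_out, k, k))
        self.b2 = ag.Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x):
        return ag.relu(ag.conv2d(ag.relu(ag.conv2d(x, self.w1, self.b1)),
                                 self.w2, self.b2))

    def params(self):
        return [self.w1, self.b1, self.w2, self.b2]


def _he(rng, shape):
    fan_in = int(np.prod(shape[1:]))
    return ag.Tensor(rng.standard_normal(shape) * np.sqrt(2.0 / fan_in),
                     requires_grad=True)


def fuse_latents(a: ag.Tensor, b: ag.Tensor) -> ag.Tensor:
    """Pixel-wise max fusion of two latent tensors."""
    return ag.maximum(a, b)


class SynthNetwork:
    """Dual-encoder / max-fusion / triple-decoder map-prediction network."""

    def __init__(self, config: SynthNetConfig):
        self.config = config
        rng = np.random.default_rng(config.seed)
        w, d = config.base_width, config.depth
        widths = [w * 2**l for l in range(d)]
        bott = w * 2**d

        k = config.kernel_size

        def encoder():
            blocks = []
            c_in = 1
            for wl in widths:
                blocks.append(_ConvBlock(rng, c_in, wl, k))
                c_in = wl
            return blocks, _ConvBlock(rng, c_in, bott, k)

        self.enc_a, self.bott_a = encoder()
        self.enc_b, self.bott_b = encoder()

        # decoder level = 1x1 channel reduction, upsample, concat skip, block
        self.decoders = {}
        self.heads = {}
        for name in MAP_NAMES:
            levels = []
            c_in = bott
            for wl in reversed(widths):
                reduce = (_he(rng, (wl, c_in, 1, 1)),
                          ag.Tensor(np.zeros(wl), requires_grad=True))
                levels.append((reduce, _ConvBlock(rng, 2 * wl, wl, k)))
                c_in = wl
            if d == 0:
                levels.append((None, _ConvBlock(rng, bott, w, k)))
                c_in = w
            self.decoders[name] = levels
            self.heads[name] = (_he(rng, (1, c_in, 1, 1)),
                                ag.Tensor(np.zeros(1), requires_grad=True))

    def parameters(self) -> list[ag.Tensor]:
        ps: list[ag.Tensor] = []
        for blocks, bott in ((self.enc_a, self.bott_a), (self.enc_b, self.bott_b)):
            for b in blocks:
                ps += b.params()
            ps += bott.params()
        for name in MAP_NAMES:
            for reduce, block in self.decoders[name]:
                if reduce is not None:
                    ps += list(reduce)
                ps += block.params()
            wh, bh = self.heads[name]
            ps += [wh, bh]
        return ps

    @property
    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def _encode(self, x, blocks, bott):
        feats = []
        h = x
        for blk in blocks:
            h = blk(h)
            feats.append(h)
            h = ag.maxpool2(h)
        return feats, bott(h)

    def forward(self, x_a: ag.Tensor, x_b: ag.Tensor) -> dict[str, ag.Tensor]:
        """Two (N,1,H,W) input slices -> dict of (N,1,H,W) map slices."""
        feats_a, h_a = self._encode(x_a, self.enc_a, self.bott_a)
        feats_b, h_b = self._encode(x_b, self.enc_b, self.bott_b)
        fused = fuse_latents(h_a, h_b)
        fused_feats = [fuse_latents(fa, fb) for fa, fb in zip(feats_a, feats_b)]

        out = {}
        for name in MAP_NAMES:
            h = fused
            levels = self.decoders[name]
            if self.config.depth == 0:
                h = levels[0][1](h)
            else:
                for (reduce, block), skip in zip(levels, reversed(fused_feats)):
                    h = ag.upsample2(ag.conv2d(h, *reduce))
                    h = ag.concat([h, skip], axis=1)
                    h = block(h)
            wh, bh = self.heads[name]
            out[name] = self._activate(name, ag.conv2d(h, wh, bh))
        return out

    def _activate(self, name: str, z: ag.Tensor) -> ag.Tensor:
        """Scaled sigmoid onto the physical range; T1/T2 use a log-spaced
        sigmoid (relaxation times span orders of magnitude), PD a linear one."""
        lo, hi = self.config.map_ranges[name]
        if name in ("t1", "t2"):
            return float(lo) * ag.exp(float(np.log(hi / lo)) * ag.sigmoid(z))
        return lo + (hi - lo) * ag.sigmoid(z)

    def state(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.parameters()]

    def load_state(self, state: list[np.ndarray]) -> None:
        for p, s in zip(self.parameters(), state):
            p.data[...] = s


def build_network(config: SynthNetConfig) -> SynthNetwork:
    return SynthNetwork(config)


# --------------------------------------------------------------------------
# physics layer
# --------------------------------------------------------------------------

def physics_layer(predicted_maps: dict, params: AcquisitionParams,
                  mask: np.ndarray) -> ag.Tensor:
    """Ideal signal equations applied to predicted map tensors.

    Contributes no trainable parameters and is differentiable in the maps.
    Background voxels (mask False) are zeroed; T1/T2 are guarded there so
    the reciprocal stays finite.  With ground-truth maps this reproduces
    the forward simulator exactly on the foreground (shared equations).
    """
    t1, t2, pd = (predicted_maps[k] for k in MAP_NAMES)
    if not isinstance(t1, ag.Tensor):
        t1, t2, pd = ag.Tensor(t1), ag.Tensor(t2), ag.Tensor(pd)
    guard = ag.Tensor((~np.asarray(mask, bool)).astype(float))
    t1g = t1 + guard
    t2g = t2 + guard
    e_te = ag.exp((-params.te) * ag.reciprocal(t2g))
    if params.sequence == "SE":
        rec = 1.0 - ag.exp((-params.tr) * ag.reciprocal(t1g))
    elif params.sequence == "IR_SE":
        rec = ag.absolute(1.0 - 2.0 * ag.exp((-params.ti) * ag.reciprocal(t1g))
                          + ag.exp((-params.tr) * ag.reciprocal(t1g)))
    else:  # pragma: no cover
        raise ValueError(f"unknown sequence {params.sequence!r}")
    return pd * rec * e_te * ag.Tensor(np.asarray(mask, float))


# --------------------------------------------------------------------------
# data plumbing
# --------------------------------------------------------------------------

def _normalized_input(record: SubjectRecord, contrast: str) -> np.ndarray:
    img = normalize_by_reference(record.weighted[contrast],
                                 record.label_mask("WM"),
                                 record.hemisphere_of_tumor)
    return img.intensities


def _subject_slices(record: SubjectRecord, config: SynthNetConfig):
    """Per-subject axial slices: inputs (normalized), loss targets (native
    or normalized per ``config.normalize_targets``), plus the validation
    domain mask for each slice."""
    in_a = _normalized_input(record, config.input_contrasts[0])
    in_b = _normalized_input(record, config.input_contrasts[1])
    mask = record.maps.foreground_mask
    if config.val_region == "lesion":
        lesion = record.wt_mask
        vmask = lesion if lesion.any() else mask
    else:
        vmask = mask
    if config.normalize_targets:
        targets = {c: _normalized_input(record, c)
                   for c in config.resolved_loss_contrasts()}
    else:
        targets = {c: record.weighted[c].intensities
                   for c in config.resolved_loss_contrasts()}
    out = []
    for k in range(0, mask.shape[-1], config.slice_stride):
        m = mask[..., k]
        if m.sum() < config.min_slice_foreground:
            continue
        out.append((in_a[..., k], in_b[..., k], m,
                    {c: t[..., k] for c, t in targets.items()},
                    vmask[..., k]))
    return out


def _loss_params(records: Sequence[SubjectRecord],
                 contrasts: Sequence[str]) -> dict[str, AcquisitionParams]:
    params = {c: records[0].weighted[c].params for c in contrasts}
    for r in records:
        for c in contrasts:
            if r.weighted[c].params != params[c]:
                raise ValueError("acquisition parameters differ across subjects")
    return params


def _batch_loss(net: SynthNetwork, params_by_contrast, xa, xb, masks, targets,
                with_grad: bool = True) -> ag.Tensor:
    """Eq-style loss: mean over images of per-image masked MAE."""
    n = xa.shape[0]
    pred = net.forward(ag.Tensor(xa[:, None]), ag.Tensor(xb[:, None]))
    contrasts = list(targets.keys())
    m_images = n * len(contrasts)
    total = None
    for c in contrasts:
        synth = physics_layer(pred, params_by_contrast[c], masks[:, None])
        # per-image weights 1/(M * |chi_k|)
        area = masks.reshape(n, -1).sum(axis=1).astype(float)
        w = masks[:, None] / area[:, None, None, None] / m_images
        term = (ag.absolute(synth - ag.Tensor(targets[c][:, None])) * ag.Tensor(w)).sum()
        total = term if total is None else total + term
    return total


# --------------------------------------------------------------------------
# estimator
# --------------------------------------------------------------------------

class SelfSupervisedSynthesizer(BaseEstimator):
    """Fit the synthesis network on a cohort of subject records.

    Parameters mirror :class:`SynthNetConfig`.  After ``fit``:

    ``network_``          trained network (best early-stopping weights)
    ``history_``          per-epoch train / validation loss
    ``params_by_contrast_``  acquisition parameters used by the physics layer
    """

    def __init__(self, input_contrasts=("T1w", "T2w"), target_contrast="FLAIR",
                 base_width=16, depth=1, learning_rate=1e-4, batch_size=32,
                 max_epochs=40, early_stop_patience=10, seed=0, val_fraction=0.2,
                 loss_contrasts=None, n_init_candidates=1, kernel_size=3, slice_stride=1,
                 normalize_targets=False, val_region="foreground"):
        self.input_contrasts = input_contrasts
        self.target_contrast = target_contrast
        self.base_width = base_width
        self.depth = depth
        self.learning_rate = learning_rate
        self.batch_size = batch_size
        self.max_epochs = max_epochs
        self.early_stop_patience = early_stop_patience
        self.seed = seed
        self.val_fraction = val_fraction
        self.loss_contrasts = loss_contrasts
        self.n_init_candidates = n_init_candidates
        self.kernel_size = kernel_size
        self.slice_stride = slice_stride
        self.normalize_targets = normalize_targets
        self.val_region = val_region

    def _config(self) -> SynthNetConfig:
        return SynthNetConfig(
            input_contrasts=tuple(self.input_contrasts),
            target_contrast=self.target_contrast,
            base_width=self.base_width, depth=self.depth,
            learning_rate=self.learning_rate, batch_size=self.batch_size,
            max_epochs=self.max_epochs, early_stop_patience=self.early_stop_patience,
            seed=self.seed, val_fraction=self.val_fraction,
            loss_contrasts=self.loss_contrasts,
            n_init_candidates=self.n_init_candidates,
            kernel_size=self.kernel_size,
            slice_stride=self.slice_stride,
            normalize_targets=self.normalize_targets,
            val_region=self.val_region,
        )

    def fit(self, records: Sequence[SubjectRecord],
            validation_records: Sequence[SubjectRecord] | None = None,
            init_state: list | None = None):
        """Train on ``records``; ``init_state`` warm-starts the weights
        (e.g. from a model pretrained on a disjoint cohort)."""
        config = self._config()
        rng = np.random.default_rng(config.seed)
        records = list(records)
        if validation_records is None:
            if len(records) < 2:
                raise ValueError("need at least 2 subjects (train + validation)")
            idx = rng.permutation(len(records))
            n_val = max(1, int(round(config.val_fraction * len(records))))
            val_ids = set(int(i) for i in idx[:n_val])
            validation_records = [records[i] for i in sorted(val_ids)]
            records = [records[i] for i in range(len(records)) if i not in val_ids]
        if not records:
            raise ValueError("empty training split")

        contrasts = config.resolved_loss_contrasts()
        self.params_by_contrast_ = _loss_params(list(records) + list(validation_records),
                                                contrasts)

        def stack(recs, use_val_mask=False):
            sl = [s for r in recs for s in _subject_slices(r, config)]
            if use_val_mask:   # validation domain (possibly lesion-restricted)
                sl = [s for s in sl if s[4].sum() >= 4]
            xa = np.stack([s[0] for s in sl])
            xb = np.stack([s[1] for s in sl])
            mk = np.stack([s[4] if use_val_mask else s[2] for s in sl])
            tg = {c: np.stack([s[3][c] for s in sl]) for c in contrasts}
            return xa, xb, mk, tg

        xa, xb, mk, tg = stack(records)
        vxa, vxb, vmk, vtg = stack(validation_records, use_val_mask=True)
        n = xa.shape[0]

        def val_loss(net):
            vlosses = []
            for lo in range(0, vxa.shape[0], config.batch_size):
                s = slice(lo, lo + config.batch_size)
                vlosses.append((float(_batch_loss(
                    net, self.params_by_contrast_, vxa[s], vxb[s], vmk[s],
                    {c: vtg[c][s] for c in contrasts}).data), vxa[s].shape[0]))
            return float(sum(v * k for v, k in vlosses) / sum(k for _, k in vlosses))

        def run_epochs(net, opt, rng, n_epochs, history, tracker):
            best_val, best_state, since_best = tracker
            for _ in range(n_epochs):
                order = rng.permutation(n)
                ep_loss, nb = 0.0, 0
                for lo in range(0, n, config.batch_size):
                    sel = order[lo:lo + config.batch_size]
                    loss = _batch_loss(net, self.params_by_contrast_,
                                       xa[sel], xb[sel], mk[sel],
                                       {c: tg[c][sel] for c in contrasts})
                    opt.zero_grad()
                    loss.backward()
                    opt.step()
                    ep_loss += float(loss.data)
                    nb += 1
                val = val_loss(net)
                history["train"].append(ep_loss / max(nb, 1))
                history["val"].append(val)
                if val < best_val - 1e-12:
                    best_val, best_state, since_best = val, net.state(), 0
                else:
                    since_best += 1
                    if since_best >= config.early_stop_patience:
                        break
            return best_val, best_state, since_best

        # optional restarts: probe a few inits briefly, continue the one
        # with the lowest validation loss (small nets are init-sensitive)
        n_init = max(1, int(self.n_init_candidates)) if init_state is None else 1
        probe = (min(config.max_epochs, max(1, config.max_epochs // 3))
                 if n_init > 1 else config.max_epochs)

        candidates = []
        for i in range(n_init):
            cand_cfg = dc_replace(config, seed=config.seed + 137 * i)
            net = build_network(cand_cfg)
            if init_state is not None:
                net.load_state(init_state)
            opt = ag.Adam(net.parameters(), lr=config.learning_rate)
            crng = np.random.default_rng(cand_cfg.seed + 1)
            history = {"train": [], "val": []}
            tracker = run_epochs(net, opt, crng, probe, history,
                                 (np.inf, net.state(), 0))
            candidates.append((tracker[0], i, net, opt, crng, history, tracker))
        best = min(candidates, key=lambda c: c[0])
        _, _, net, opt, crng, history, tracker = best
        if probe < config.max_epochs:
            tracker = run_epochs(net, opt, crng, config.max_epochs - probe,
                                 history, tracker)
        best_val, best_state, _ = tracker
        net.load_state(best_state)
        self.network_ = net
        self.history_ = history
        self.best_val_loss_ = best_val
        self.config_ = config
        return self

    def predict_maps(self, record: SubjectRecord) -> RelaxometryMaps:
        """Slice-wise map inference reassembled into a volume.

        Outputs are clipped to the configured physical ranges, the T1 >= T2
        constraint is enforced, and background voxels are zeroed.
        """
        config = self.config_
        in_a = _normalized_input(record, config.input_contrasts[0])
        in_b = _normalized_input(record, config.input_contrasts[1])
        mask = record.maps.foreground_mask
        vol = {k: np.zeros(mask.shape) for k in MAP_NAMES}
        ks = range(mask.shape[-1])
        xa = np.stack([in_a[..., k] for k in ks])[:, None]
        xb = np.stack([in_b[..., k] for k in ks])[:, None]
        pred = self.network_.forward(ag.Tensor(xa), ag.Tensor(xb))
        for name in MAP_NAMES:
            arr = pred[name].data[:, 0]
            for i, k in enumerate(ks):
                vol[name][..., k] = arr[i]
        t1, t2, pd = vol["t1"], vol["t2"], vol["pd"]
        t2 = np.minimum(t2, t1)
        for a in (t1, t2, pd):
            a[~mask] = 0.0
        return RelaxometryMaps(t1, t2, pd, mask)

    def synthesize(self, record: SubjectRecord) -> WeightedImage:
        """Predict maps, then run the target contrast's forward model."""
        maps = self.predict_maps(record)
        protocol = {self.config_.target_contrast:
                    self.params_by_contrast_.get(self.config_.target_contrast,
                                                 record.weighted[self.config_.target_contrast].params)}
        return simulate_contrast(maps, self.config_.target_contrast, protocol)


def train_self_supervised(cohort: Sequence[SubjectRecord],
                          config: SynthNetConfig) -> SelfSupervisedSynthesizer:
    return _estimator_from_config(config).fit(cohort)


def predict_maps(model: SelfSupervisedSynthesizer, record: SubjectRecord) -> RelaxometryMaps:
    return model.predict_maps(record)


def loo_splits(subject_ids: Sequence[str], val_fraction: float = 0.2,
               seed: int = 0) -> list[dict]:
    """Leave-one-out folds: one test subject, ~80/20 train/validation rest.

    For 24 subjects each fold holds 18 train / 5 validation / 1 test.
    """
    ids = list(subject_ids)
    if len(ids) < 4:
        raise ValueError("leave-one-out needs at least 4 subjects")
    rng = np.random.default_rng(seed)
    folds = []
    for k, test_id in enumerate(ids):
        rest = [i for i in ids if i != test_id]
        order = rng.permutation(len(rest))
        n_train = int(round((1.0 - val_fraction) * len(rest)))
        train = [rest[i] for i in order[:n_train]]
        val = [rest[i] for i in order[n_train:]]
        folds.append({"test": test_id, "train": train, "val": val})
    return folds


def _estimator_from_config(config: SynthNetConfig) -> SelfSupervisedSynthesizer:
    return SelfSupervisedSynthesizer(
        input_contrasts=config.input_contrasts,
        target_contrast=config.target_contrast,
        base_width=config.base_width, depth=config.depth,
        learning_rate=config.learning_rate, batch_size=config.batch_size,
        max_epochs=config.max_epochs,
        early_stop_patience=config.early_stop_patience,
        seed=config.seed, val_fraction=config.val_fraction,
        loss_contrasts=config.loss_contrasts,
        n_init_candidates=config.n_init_candidates,
        kernel_size=config.kernel_size,
        slice_stride=config.slice_stride,
        normalize_targets=config.normalize_targets,
        val_region=config.val_region)


def leave_one_out_synthesize(cohort: Sequence[SubjectRecord],
                             config: SynthNetConfig,
                             pretrain_records: Sequence[SubjectRecord] | None = None,
                             pretrain_epochs: int | None = None,
                             pretrain_lr: float | None = None):
    """One model per held-out subject; its volume comes from its own fold only.

    ``pretrain_records`` (a cohort disjoint from ``cohort``; checked by id)
    warm-starts every fold from one shared pretrained state, so the short
    per-fold trainings differ only through their fold data.  Returns
    (synthesized: dict subject_id -> WeightedImage, folds).
    """
    by_id = {r.subject_id: r for r in cohort}
    folds = loo_splits(list(by_id), config.val_fraction, config.seed)

    init_state = None
    if pretrain_records is not None:
        overlap = {r.subject_id for r in pretrain_records} & set(by_id)
        if overlap:
            raise ValueError(f"pretraining cohort overlaps the LOO cohort: {overlap}")
        pre_epochs = pretrain_epochs or config.max_epochs
        pre_cfg = dc_replace(config,
                             max_epochs=pre_epochs,
                             learning_rate=pretrain_lr or config.learning_rate,
                             # the fold configs carry a tiny fine-tune
                             # patience; pretraining needs its own horizon
                             early_stop_patience=max(10, pre_epochs // 3))
        pre = _estimator_from_config(pre_cfg)
        pre.fit(pretrain_records)
        init_state = pre.network_.state()

    synthesized: dict[str, WeightedImage] = {}
    for fold in folds:
        # same init / batch-schedule seed in every fold: fold models then
        # differ only through their training data, not through init noise
        est = _estimator_from_config(dc_replace(config, seed=config.seed))
        est.fit([by_id[i] for i in fold["train"]],
                validation_records=[by_id[i] for i in fold["val"]],
                init_state=init_state)
        synthesized[fold["test"]] = est.synthesize(by_id[fold["test"]])
    return synthesized, folds
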