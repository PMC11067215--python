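"""Deep-radiomics feature extraction.

A masked tumour volume is turned into one fixed-length feature vector by
running every axial slice that intersects the ROI through the convolutional
prefix of a VGG16 network and summarising each feature-map channel with six
statistics: mean, median, standard deviation, 5th and 95th percentiles and
(non-excess) kurtosis.  Activations of a channel are pooled across slices
before the statistics are computed, so the vector length does not depend on
tumour size.

The conv stack is the standard VGG16 architecture prefix — 3x3 kernels,
stride 1, same-padding, ReLU, with 2x2/stride-2 max-pooling between blocks —
evaluated directly with NumPy (im2col + matrix multiply).  Filters are
either He-initialised from a seed (the default: the statistical pipeline is
weight-agnostic and needs no checkpoint) or loaded from an .npz checkpoint
holding ImageNet VGG16 weights (keys ``w0, b0, w1, b1, ...`` with kernels
shaped (out, in, 3, 3)).

Vector layout is modality-major, then layer (0 = the raw masked input),
then channel, then statistic, with the subject's age optionally appended as
the final element.
"""

from __future__ import annotations

import dataclasses
from typing import Sequence

import numpy as np
from scipy import stats as sps

from .volio import (
    DegenerateInputError,
    ROIMask,
    SubjectRecord,
    Volume,
    apply_mask_and_crop,
    mask_bounding_box,
)

STATISTIC_NAMES = ("mean", "median", "sd", "p5", "p95", "kurtosis")

# VGG16 conv plan: channel width per conv layer, and the set of conv indices
# (1-based) preceded by a 2x2 max-pool.  Five layers cover blocks 1-2 plus
# the first conv of block 3, enough for the layer sweep.
VGG16_CONV_CHANNELS = (64, 64, 128, 128, 256)
_POOL_BEFORE = {3, 5}  # pool on entering block 2 (conv2_1) and block 3 (conv3_1)

MIN_SLICE_SIDE = 8  # receptive-field floor for a slice entering the stack


@dataclasses.dataclass(frozen=True)
class ConvStackConfig:
    """Configuration of the convolutional feature extractor.

    ``layer_channel_counts`` lists the channel width of layer 0 (the input,
    always 1) and of each conv layer; ``n_layers_used`` is the number of conv
    layers whose feature maps contribute statistics (0 = input only).
    """

    layer_channel_counts: tuple[int, ...] = (1, 64, 64, 128, 128)
    n_layers_used: int = 3
    weights_source: str = "seeded-random"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.layer_channel_counts[0] != 1:
            raise ValueError("layer 0 is the single-channel input")
        conv = self.layer_channel_counts[1:]
        if conv != VGG16_CONV_CHANNELS[: len(conv)]:
            raise ValueError(
                f"channel counts {conv} are not a VGG16 prefix "
                f"{VGG16_CONV_CHANNELS[:len(conv)]}"
            )
        if not 0 <= self.n_layers_used <= len(conv):
            raise ValueError(
                f"n_layers_used={self.n_layers_used} outside 0..{len(conv)}"
            )

    @property
    def n_conv_layers(self) -> int:
        return len(self.layer_channel_counts) - 1

    def with_layers(self, n_layers_used: int) -> "ConvStackConfig":
        counts = self.layer_channel_counts
        if n_layers_used > self.n_conv_layers:
            counts = (1,) + VGG16_CONV_CHANNELS[:n_layers_used]
        return dataclasses.replace(
            self, layer_channel_counts=counts, n_layers_used=n_layers_used
        )


# ---------------------------------------------------------------------------
# Weights


def _he_weights(cfg: ConvStackConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    rng = np.random.default_rng(cfg.seed)
    params = []
    c_in = 1
    for c_out in cfg.layer_channel_counts[1:]:
        std = np.sqrt(2.0 / (9.0 * c_in))
        w = rng.normal(0.0, std, size=(c_out, c_in, 3, 3)).astype(np.float32)
        b = np.zeros(c_out, dtype=np.float32)
        params.append((w, b))
        c_in = c_out
    return params


def _checkpoint_weights(path: str, n_layers: int) -> list[tuple[np.ndarray, np.ndarray]]:
    with np.load(path) as npz:
        params = []
        for i in range(n_layers):
            w = np.asarray(npz[f"w{i}"], dtype=np.float32)
            b = np.asarray(npz[f"b{i}"], dtype=np.float32)
            if w.ndim != 4 or w.shape[2:] != (3, 3):
                raise ValueError(f"checkpoint kernel w{i} must be (out, in, 3, 3)")
            params.append((w, b))
    return params


_WEIGHT_CACHE: dict[ConvStackConfig, list[tuple[np.ndarray, np.ndarray]]] = {}


def _load_weights(cfg: ConvStackConfig) -> list[tuple[np.ndarray, np.ndarray]]:
    if cfg not in _WEIGHT_CACHE:
        if cfg.weights_source == "seeded-random":
            _WEIGHT_CACHE[cfg] = _he_weights(cfg)
        elif cfg.weights_source.startswith("checkpoint:"):
            _WEIGHT_CACHE[cfg] = _checkpoint_weights(
                cfg.weights_source.split(":", 1)[1], cfg.n_conv_layers
            )
        else:
            raise ValueError(f"unknown weights_source {cfg.weights_source!r}")
    return _WEIGHT_CACHE[cfg]


# ---------------------------------------------------------------------------
# Forward pass


def _conv2d_same(x: np.ndarray, w: np.ndarray, b: np.ndarray) -> np.ndarray:
    """3x3 conv, stride 1, same-padding: x (C,H,W), w (O,C,3,3) -> (O,H,W)."""
    c, h, wd = x.shape
    xp = np.pad(x, ((0, 0), (1, 1), (1, 1)))
    win = np.lib.stride_tricks.sliding_window_view(xp, (3, 3), axis=(1, 2))
    # (C,H,W,3,3) -> (H*W, C*9)
    cols = win.transpose(1, 2, 0, 3, 4).reshape(h * wd, c * 9)
    out = cols @ w.reshape(w.shape[0], -1).T + b
    return out.reshape(h, wd, w.shape[0]).transpose(2, 0, 1)


def _maxpool2(x: np.ndarray) -> np.ndarray:
    """2x2 max-pool, stride 2, ceil-mode (odd edges padded with -inf)."""
    c, h, w = x.shape
    h2, w2 = -(-h // 2), -(-w // 2)
    xp = np.full((c, h2 * 2, w2 * 2), -np.inf, dtype=x.dtype)
    xp[:, :h, :w] = x
    return xp.reshape(c, h2, 2, w2, 2).max(axis=(2, 4))


def conv_forward(slice2d: np.ndarray, cfg: ConvStackConfig) -> list[np.ndarray]:
    """Run one 2D slice through the conv stack.

    Returns the input itself (as a (1,H,W) stack, layer 0) followed by the
    ReLU activation stack of each conv layer up to ``cfg.n_layers_used``.
    """
    x = np.asarray(slice2d, dtype=np.float32)
    if x.ndim != 2:
        raise ValueError(f"expected a 2D slice, got shape {x.shape}")
    if min(x.shape) < MIN_SLICE_SIDE:
        raise ValueError(
            f"slice {x.shape} below the {MIN_SLICE_SIDE}x{MIN_SLICE_SIDE} floor"
        )
    params = _load_weights(cfg)
    acts = [x[np.newaxis]]
    cur = x[np.newaxis]
    for i in range(cfg.n_layers_used):
        w, b = params[i]
        if (i + 1) in _POOL_BEFORE:
            cur = _maxpool2(cur)
        if w.shape[1] == 3 and cur.shape[0] == 1:
            cur = np.repeat(cur, 3, axis=0)  # grayscale -> RGB for checkpoints
        cur = np.maximum(_conv2d_same(cur, w, b), 0.0)
        acts.append(cur)
    return acts


# ---------------------------------------------------------------------------
# Statistics


@dataclasses.dataclass
class ChannelStats:
    """Six summary statistics of one feature-map channel."""

    mean: float
    median: float
    sd: float
    p5: float
    p95: float
    kurtosis: float
    degenerate: bool = False

    def as_tuple(self) -> tuple[float, ...]:
        return (self.mean, self.median, self.sd, self.p5, self.p95, self.kurtosis)


def channel_statistics(values: np.ndarray) -> ChannelStats:
    """Mean, median, sample sd, linearly interpolated 5th/95th percentiles
    and non-excess kurtosis (normal -> 3) of a multiset of activations.

    A zero-variance multiset is degenerate: its kurtosis is reported as 0
    and the degeneracy flag is set.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise DegenerateInputError("cannot summarise an empty activation set")
    mean = float(v.mean())
    median = float(np.median(v))
    sd = float(v.std(ddof=1)) if v.size > 1 else 0.0
    p5, p95 = (float(p) for p in np.percentile(v, [5, 95], method="linear"))
    if sd == 0.0 or np.ptp(v) == 0.0:
        return ChannelStats(mean, median, sd, p5, p95, 0.0, degenerate=True)
    kurt = float(sps.kurtosis(v, fisher=False, bias=True))
    return ChannelStats(mean, median, sd, p5, p95, kurt)


# ---------------------------------------------------------------------------
# Subject-level extraction


@dataclasses.dataclass
class FeatureVector:
    """Ordered feature values with a (modality, layer, channel, statistic)
    schema entry per element; the demographic element is tagged
    ("age", -1, -1, "age")."""

    values: np.ndarray
    schema: list[tuple[str, int, int, str]]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.size != len(self.schema):
            raise ValueError("schema length must equal value length")

    def __len__(self) -> int:
        return self.values.size

    @property
    def feature_names(self) -> list[str]:
        return [
            f"{m}_L{l}_c{c}_{s}" if l >= 0 else "age"
            for m, l, c, s in self.schema
        ]


def feature_length(
    n_modalities: int, cfg: ConvStackConfig, include_age: bool = False
) -> int:
    """Closed-form vector length: M * 6 * sum of channel counts over the
    included layers, plus one for age."""
    if n_modalities < 1:
        raise ValueError("need at least one modality")
    total = sum(cfg.layer_channel_counts[: cfg.n_layers_used + 1])
    return n_modalities * len(STATISTIC_NAMES) * total + (1 if include_age else 0)


def _roi_slices(rec: SubjectRecord, modality: str, margin_vox: int):
    """Cropped masked volume and the axial slice indices intersecting the ROI."""
    vol = rec.volumes[modality]
    cropped = apply_mask_and_crop(vol, rec.mask, margin_vox)
    box = mask_bounding_box(rec.mask, margin_vox)
    mask_crop = rec.mask.data[box]
    z_idx = np.where(mask_crop.any(axis=(0, 1)))[0]
    return cropped, z_idx


def extract_subject_features(
    rec: SubjectRecord,
    modalities: Sequence[str],
    cfg: ConvStackConfig,
    include_age: bool = False,
    margin_vox: int = 8,
) -> FeatureVector:
    """Extract the deep-radiomics feature vector for one subject.

    Per modality the tumour is masked and cropped (with boundary margin),
    every axial slice intersecting the ROI is pushed through the conv stack,
    activations are pooled per channel across slices, and six statistics per
    channel per layer are concatenated in (modality, layer, channel,
    statistic) order.  Age, when requested, is appended raw as the final
    element (columns are standardised downstream by the classifier).
    """
    missing = [m for m in modalities if m not in rec.volumes]
    if missing:
        raise KeyError(f"subject {rec.subject_id} lacks modalities {missing}")
    if rec.mask.n_voxels == 0:
        raise DegenerateInputError(f"subject {rec.subject_id} has an empty ROI")

    values: list[float] = []
    schema: list[tuple[str, int, int, str]] = []
    for m in modalities:
        cropped, z_idx = _roi_slices(rec, m, margin_vox)
        # pooled[l][c] accumulates channel c's activations across slices
        pooled: list[list[list[np.ndarray]]] = [
            [[] for _ in range(cfg.layer_channel_counts[l])]
            for l in range(cfg.n_layers_used + 1)
        ]
        for z in z_idx:
            acts = conv_forward(cropped.data[:, :, z], cfg)
            for l, stack in enumerate(acts):
                for c in range(stack.shape[0]):
                    pooled[l][c].append(stack[c].ravel())
        for l in range(cfg.n_layers_used + 1):
            for c in range(cfg.layer_channel_counts[l]):
                st = channel_statistics(np.concatenate(pooled[l][c]))
                values.extend(st.as_tuple())
                schema.extend((m, l, c, s) for s in STATISTIC_NAMES)
    if include_age:
        values.append(float(rec.age))
        schema.append(("age", -1, -1, "age"))
    return FeatureVector(np.array(values), schema)


def extract_cohort_features(
    cohort: Sequence[SubjectRecord],
    modalities: Sequence[str],
    cfg: ConvStackConfig,
    include_age: bool = False,
    margin_vox: int = 8,
) -> tuple[np.ndarray, np.ndarray, list[str], list[tuple[str, int, int, str]]]:
    """Feature matrix X (subjects x features), labels y (1 = mutant),
    subject ids, and the shared schema for a whole cohort."""
    rows, y, ids = [], [], []
    schema = None
    for rec in cohort:
        fv = extract_subject_features(rec, modalities, cfg, include_age, margin_vox)
        if schema is None:
            schema = fv.schema
        rows.append(fv.values)
        y.append(rec.y)
        ids.append(rec.subject_id)
    return np.vstack(rows), np.array(y), ids, schema


# ---------------------------------------------------------------------------
# Feature-map visualisation


def render_feature_heatmaps(
    rec: SubjectRecord,
    cfg: ConvStackConfig,
    layer: int,
    k: int = 4,
    seed: int = 0,
    modality: str | None = None,
    out_dir=None,
) -> list[np.ndarray]:
    """Min-max-scaled heatmaps of k randomly chosen channels of one layer.

    The representative slice is the axial slice with the largest ROI area.
    Constant maps scale to uniform zero (degenerate).  When ``out_dir`` is
    given each map is also written as a PNG.
    """
    if not 0 <= layer <= cfg.n_layers_used:
        raise ValueError(f"layer {layer} outside 0..{cfg.n_layers_used}")
    n_ch = cfg.layer_channel_counts[layer]
    if k > n_ch:
        raise ValueError(f"k={k} exceeds the {n_ch} channels of layer {layer}")
    if modality is None:
        modality = next(iter(rec.volumes))
    cropped, z_idx = _roi_slices(rec, modality, margin_vox=8)
    areas = rec.mask.data.sum(axis=(0, 1))
    z_best = int(np.argmax(areas)) - int(mask_bounding_box(rec.mask, 8)[2].start)
    acts = conv_forward(cropped.data[:, :, z_best], cfg)[layer]
    rng = np.random.default_rng(seed)
    channels = rng.choice(n_ch, size=k, replace=False)
    maps = []
    for c in channels:
        fmap = acts[c].astype(float)
        lo, hi = fmap.min(), fmap.max()
        maps.append((fmap - lo) / (hi - lo) if hi > lo else np.zeros_like(fmap))
    if out_dir is not None:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
        from pathlib import Path

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for c, m in zip(channels, maps):
            plt.imsave(out / f"{rec.subject_id}_{modality}_L{layer}_c{c}.png", m,
                       cmap="inferno", vmin=0, vmax=1)
    return maps
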