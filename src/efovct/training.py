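"""Estimator training: corpus synthesis, DSSIM loss, optimization loop.

Training pairs are produced exactly the way inference inputs are: a
random body-like slice (exceeding the sFoV, inside the bore) is
rasterized on the 800 mm ground-truth grid, forward-projected with the
scanner geometry on the bore-wide detector, truncated to the physical
detector, and reconstructed with the slope-matched linear x cos^2
convolution-only extrapolation; the pair is (that reconstruction,
ground truth), both area-averaged to the 256^2 network grid.  The
corpus is unlimited in principle; desk-scale runs use hundreds of pairs
where a production-scale system would use tens of thousands.

The loss is structural dissimilarity DSSIM = (1 - SSIM)/2 with the
standard constants (k1=0.01, k2=0.03, Gaussian window sigma=1.5
truncated at 3.5 sigma, i.e. 11 pixels, sample statistics by filtering).
Both the value and its analytic gradient with respect to the first image
are computed from the Gaussian-filtered moment maps.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.ndimage import gaussian_filter

from .containers import CTImage, Sinogram
from .deepfov import (
    HU_MAX,
    HU_MIN,
    NETWORK_FOV_MM,
    NETWORK_MATRIX,
    Estimator,
    downsample_image,
    prepare_network_input,
)
from .geometry import ScanGeometry, default_geometry
from .phantom import PhantomSpec, random_body_spec
from .projection import forward_project, truncate
from .unet import Adam, UNet

__all__ = [
    "dssim",
    "dssim_grad",
    "TrainingConfig",
    "TrainingPair",
    "generate_training_pair",
    "generate_training_corpus",
    "TrainedEstimator",
    "train_estimator",
]

log = logging.getLogger(__name__)

_SSIM_SIGMA = 1.5
_SSIM_TRUNCATE = 3.5
_K1, _K2 = 0.01, 0.03


def _ssim_maps(a: np.ndarray, b: np.ndarray, data_range: float):
    c1 = (_K1 * data_range) ** 2
    c2 = (_K2 * data_range) ** 2
    filt = lambda z: gaussian_filter(z, _SSIM_SIGMA, truncate=_SSIM_TRUNCATE)
    mua, mub = filt(a), filt(b)
    saa = filt(a * a) - mua * mua
    sbb = filt(b * b) - mub * mub
    sab = filt(a * b) - mua * mub
    a1 = 2 * mua * mub + c1
    a2 = 2 * sab + c2
    b1 = mua * mua + mub * mub + c1
    b2 = saa + sbb + c2
    s = (a1 * a2) / (b1 * b2)
    return s, (mua, mub, a1, a2, b1, b2)


def _crop_pad() -> int:
    return int(_SSIM_TRUNCATE * _SSIM_SIGMA + 0.5)


def dssim(a: np.ndarray, b: np.ndarray, data_range: float = 1.0) -> float:
    """Structural dissimilarity (1 - SSIM)/2, mean over the image.

    Matches the standard windowed SSIM (Gaussian weights, sigma 1.5,
    11-pixel support, population statistics); the border of half a window
    is excluded from the average.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    s, _ = _ssim_maps(a, b, data_range)
    pad = _crop_pad()
    return float((1.0 - s[pad:-pad, pad:-pad].mean()) / 2.0)


def dssim_grad(a: np.ndarray, b: np.ndarray, data_range: float = 1.0) -> tuple[float, np.ndarray]:
    """DSSIM and its gradient with respect to ``a``.

    The SSIM map S depends on ``a`` through the filtered moments
    mu_a = G*a, sigma_aa = G*(a^2) - mu_a^2, sigma_ab = G*(ab) - mu_a mu_b;
    the chain rule turns the pointwise partials into adjoint Gaussian
    filterings (the Gaussian is symmetric, so the adjoint is the filter
    itself).
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("shape mismatch")
    s, (mua, mub, a1, a2, b1, b2) = _ssim_maps(a, b, data_range)
    pad = _crop_pad()
    interior = np.zeros_like(s)
    interior[pad:-pad, pad:-pad] = 1.0
    n = interior.sum()
    loss = float((1.0 - (s * interior).sum() / n) / 2.0)
    # dL/dS on the cropped mean
    gs = -interior / (2.0 * n)
    # pointwise partials of S
    ds_dmua = 2.0 * (mub * a2 * b1 - mua * a1 * a2) / (b1 * b1 * b2)
    ds_dsaa = -s / b2
    ds_dsab = 2.0 * a1 / (b1 * b2)
    filt = lambda z: gaussian_filter(z, _SSIM_SIGMA, truncate=_SSIM_TRUNCATE)
    term_mu = filt(gs * (ds_dmua - 2.0 * mua * ds_dsaa - mub * ds_dsab))
    term_sq = filt(gs * ds_dsaa)
    term_x = filt(gs * ds_dsab)
    grad = term_mu + 2.0 * a * term_sq + b * term_x
    return loss, grad


# ----------------------------------------------------------------------
@dataclass
class TrainingPair:
    input_image: CTImage  # 256^2 linear x cos^2 conv-only reconstruction
    target_image: CTImage  # 256^2 downsampled ground truth
    spec: PhantomSpec  # analytic ground truth of the slice
    index: int


@dataclass
class TrainingConfig:
    n_pairs: int = 500
    seed: int = 0
    n_angles: int = 360
    raster_matrix: int = 512
    input_recon_matrix: int = 512
    depth: int = 3
    base_channels: int = 8
    leaky_slope: float = 0.01
    stem_pool: int = 2
    learning_rate: float = 1e-3
    batch_size: int = 4
    epochs: int = 30
    validation_fraction: float = 0.2
    checkpoint_path: str | None = None

    def __post_init__(self) -> None:
        if self.n_pairs < 8:
            raise ValueError("n_pairs must be >= 8")
        if not (0.0 < self.validation_fraction <= 0.5):
            raise ValueError("validation_fraction must be in (0, 0.5]")


def _pair_rng(seed: int, index: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(index,)))


def generate_training_pair(
    config: TrainingConfig, index: int, geometry: ScanGeometry | None = None
) -> TrainingPair:
    """One reproducible (input, ground truth) pair: same (seed, index)
    always yields a bit-identical pair."""
    geo = geometry or default_geometry(config.n_angles)
    rng = _pair_rng(config.seed, index)
    spec = random_body_spec(rng)
    gt, _ = spec.rasterize(NETWORK_FOV_MM / config.raster_matrix, config.raster_matrix)
    wide, _ = geo.widened_to(geo.bore_radius_mm)
    sino = truncate(forward_project(gt, wide))
    net_in = prepare_network_input(sino, recon_matrix=config.input_recon_matrix)
    target = downsample_image(gt, config.raster_matrix // NETWORK_MATRIX)
    return TrainingPair(net_in, target, spec, index)


def generate_training_corpus(
    config: TrainingConfig, geometry: ScanGeometry | None = None, progress: bool = False
) -> list[TrainingPair]:
    pairs = []
    for i in range(config.n_pairs):
        pairs.append(generate_training_pair(config, i, geometry))
        if progress and (i + 1) % 25 == 0:
            log.info("generated %d/%d pairs", i + 1, config.n_pairs)
    return pairs


# ----------------------------------------------------------------------
def _normalize(hu: np.ndarray) -> np.ndarray:
    return (np.clip(hu, HU_MIN, HU_MAX) - HU_MIN) / (HU_MAX - HU_MIN)


def _denormalize(x: np.ndarray) -> np.ndarray:
    return np.clip(x, 0.0, 1.0) * (HU_MAX - HU_MIN) + HU_MIN


class TrainedEstimator(Estimator):
    """U-Net estimator operating on HU images normalized to [0, 1]."""

    kind = "trained"

    def __init__(self, net: UNet):
        self.net = net

    def __call__(self, image: CTImage) -> CTImage:
        self._validate_grid(image)
        x = _normalize(image.values)[:, None]  # (N, 1, H, W)
        y = self.net.forward(x)[:, 0]
        return CTImage(
            _denormalize(y), image.pixel_spacing_mm, image.slice_thickness_mm, image.origin
        )

    def save(self, path: str | Path, config: TrainingConfig | None = None) -> None:
        path = Path(path)
        np.savez(path, **self.net.state_dict())
        meta = {
            "matrix": NETWORK_MATRIX,
            "fov_mm": NETWORK_FOV_MM,
            "hu_range": [HU_MIN, HU_MAX],
            "depth": self.net.depth,
            "base_channels": self.net.base,
            "leaky_slope": self.net.slope,
            "stem_pool": self.net.stem_pool,
        }
        if config is not None:
            meta["training_config"] = {
                k: v for k, v in vars(config).items() if not k.startswith("_")
            }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, path: str | Path) -> "TrainedEstimator":
        path = Path(path)
        meta = json.loads(path.with_suffix(".json").read_text())
        net = UNet(
            meta["depth"],
            meta["base_channels"],
            meta["leaky_slope"],
            stem_pool=meta.get("stem_pool", 1),
        )
        with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as data:
            net.load_state_dict(dict(data))
        return cls(net)


@dataclass
class TrainingLog:
    train_dssim: list = field(default_factory=list)
    val_dssim: list = field(default_factory=list)
    untrained_val_dssim: float = float("nan")
    best_epoch: int = -1
    best_val_dssim: float = float("inf")


def _mean_val_dssim(net: UNet, val_x: np.ndarray, val_y: np.ndarray) -> float:
    losses = []
    for i in range(val_x.shape[0]):
        pred = net.forward(val_x[i : i + 1])
        losses.append(dssim(pred[0, 0], val_y[i, 0]))
    return float(np.mean(losses))


def train_estimator(
    corpus: list[TrainingPair], config: TrainingConfig
) -> tuple[TrainedEstimator, TrainingLog]:
    """Train the U-Net with Adam on the DSSIM loss.

    The last ``validation_fraction`` of the corpus is held out; the
    checkpoint with the best validation DSSIM is returned.  Divergence
    (non-finite loss) aborts with the log so far.
    """
    if not corpus:
        raise ValueError("empty corpus")
    x = np.stack([_normalize(p.input_image.values[0]) for p in corpus])[:, None]
    y = np.stack([_normalize(p.target_image.values[0]) for p in corpus])[:, None]
    n_val = max(1, int(round(config.validation_fraction * len(corpus))))
    train_x, val_x = x[:-n_val], x[-n_val:]
    train_y, val_y = y[:-n_val], y[-n_val:]

    net = UNet(
        config.depth,
        config.base_channels,
        config.leaky_slope,
        seed=config.seed,
        stem_pool=config.stem_pool,
    )
    opt = Adam(net, lr=config.learning_rate)
    rng = np.random.default_rng(config.seed + 1)
    logrec = TrainingLog()
    logrec.untrained_val_dssim = _mean_val_dssim(net, val_x, val_y)

    best_state = {k: v.copy() for k, v in net.state_dict().items()}
    n_train = train_x.shape[0]
    for epoch in range(config.epochs):
        order = rng.permutation(n_train)
        epoch_losses = []
        for start in range(0, n_train, config.batch_size):
            idx = order[start : start + config.batch_size]
            xb, yb = train_x[idx], train_y[idx]
            pred = net.forward(xb)
            grads = np.empty_like(pred)
            batch_loss = 0.0
            for k in range(pred.shape[0]):
                loss_k, g_k = dssim_grad(pred[k, 0], yb[k, 0])
                grads[k, 0] = g_k
                batch_loss += loss_k
            batch_loss /= pred.shape[0]
            if not np.isfinite(batch_loss):
                log.error("training diverged at epoch %d", epoch)
                raise FloatingPointError("non-finite training loss")
            net.backward(grads / pred.shape[0])
            opt.step()
            epoch_losses.append(batch_loss)
        val_loss = _mean_val_dssim(net, val_x, val_y)
        logrec.train_dssim.append(float(np.mean(epoch_losses)))
        logrec.val_dssim.append(val_loss)
        if val_loss < logrec.best_val_dssim:
            logrec.best_val_dssim = val_loss
            logrec.best_epoch = epoch
            best_state = {k: v.copy() for k, v in net.state_dict().items()}
        log.info(
            "epoch %d: train DSSIM %.5f, val DSSIM %.5f", epoch, logrec.train_dssim[-1], val_loss
        )
    net.load_state_dict(best_state)
    est = TrainedEstimator(net)
    if config.checkpoint_path:
        est.save(config.checkpoint_path, config)
    return est, logrec
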