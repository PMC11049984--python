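"""Conditional-GAN single-mesh contour tracer (image-to-image translation).

The tracer learns to translate a fluorescence patch centred on one PNN
mesh into the contour-mask image of that mesh.  A U-Net generator G maps
the normalised input patch x to a candidate mask G(x); a PatchGAN
discriminator D judges (x, mask) pairs fragment-by-fragment.  Training
minimises the canonical conditional-GAN objective

    L = E[log D(x, y)] + E[log(1 - D(x, G(x)))] + lambda_l1 * E[|G(x) - y|]

with the non-saturating generator form of the adversarial term, Adam
(lr 2e-4, beta1 0.5) and lambda_l1 = 100, so the L1 reconstruction term
carries most of the signal while the discriminator sharpens texture.

The public surface follows the fitted-model convention:
``Pix2PixTracer(train_set).fit(config)`` returns a :class:`Pix2PixResults`
holding the trained parameters, per-epoch losses, snapshots and
prediction/evaluation methods.  Thin functional wrappers
(:func:`build_models`, :func:`train`, :func:`predict_mask`) expose the
same steps.
"""

from __future__ import annotations

import io
import json
import zlib
from dataclasses import asdict, dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .dataset import SyntheticDataset
from .nn import Adam, PatchGAN, UNet
from .nn.models import receptive_field as _rf


class TrainingDivergedError(RuntimeError):
    """A loss went non-finite; the state before the bad epoch is attached."""

    def __init__(self, msg: str, last_good: "ModelState"):
        super().__init__(msg)
        self.last_good = last_good


@dataclass(frozen=True)
class GeneratorSpec:
    """U-Net generator architecture: ``depth`` resolution halvings with
    channel counts ``base_channels * 2**level`` capped at ``channel_cap``;
    skip connections are always on; 1-channel input/output in [-1, 1]."""

    depth: int = 5
    base_channels: int = 32
    channel_cap: int = 64
    in_channels: int = 1
    out_channels: int = 1


@dataclass(frozen=True)
class DiscriminatorSpec:
    """PatchGAN architecture: ``n_layers`` stride-2 convolutions (doubling
    channels, capped), one stride-1 convolution, then the logit map."""

    n_layers: int = 3
    base_channels: int = 32
    channel_cap: int = 256

    @property
    def receptive_field(self) -> int:
        """Analytic fragment diameter in input pixels."""
        ks = [(4, 2)] * self.n_layers + [(4, 1)]
        return _rf(ks)


@dataclass(frozen=True)
class TrainConfig:
    """Training hyper-parameters (canonical Pix2Pix recipe as defaults)."""

    epochs: int = 30
    batch_size: int = 8
    learning_rate: float = 2e-4
    adam_beta1: float = 0.5
    lambda_l1: float = 100.0
    patch_size: int = 128
    seed: int = 0
    snapshot_epochs: tuple[int, ...] = ()
    intensity_max: float = 65535.0

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ValueError("epochs must be >= 1")
        if self.lambda_l1 < 0:
            raise ValueError("lambda_l1 must be >= 0")


@dataclass
class ModelState:
    """Generator/discriminator parameters plus everything needed to resume
    or exactly reproduce inference."""

    generator: UNet
    discriminator: PatchGAN
    gen_spec: GeneratorSpec
    disc_spec: DiscriminatorSpec
    patch_size: int
    seed: int
    epoch: int = 0
    train_config: Optional[TrainConfig] = None
    gen_opt: Optional[Adam] = None
    disc_opt: Optional[Adam] = None

    def checksum(self) -> int:
        crc = 0
        for name in sorted(self.generator.named_params()):
            crc = zlib.crc32(self.generator.named_params()[name].tobytes(), crc)
        for name in sorted(self.discriminator.named_params()):
            crc = zlib.crc32(self.discriminator.named_params()[name].tobytes(), crc)
        return crc


def build_models(
    gen: GeneratorSpec = GeneratorSpec(),
    disc: DiscriminatorSpec = DiscriminatorSpec(),
    patch_size: int = 128,
    seed: int = 0,
) -> ModelState:
    """Deterministically initialise generator and discriminator.

    Raises
    ------
    ValueError
        If ``patch_size`` is not divisible by ``2**depth`` or collapses
        the bottleneck below 2 px, or the discriminator's receptive field
        is not smaller than the patch.
    """
    if patch_size % 2**gen.depth or patch_size // 2**gen.depth < 2:
        raise ValueError(
            f"patch_size {patch_size} incompatible with depth {gen.depth}: "
            f"needs divisibility by 2**depth with a >= 2 px bottleneck"
        )
    if disc.receptive_field >= patch_size:
        raise ValueError(
            f"discriminator receptive field {disc.receptive_field} must be "
            f"smaller than patch_size {patch_size}"
        )
    rng = np.random.default_rng(seed)
    g = UNet(
        in_ch=gen.in_channels, out_ch=gen.out_channels, depth=gen.depth,
        base_channels=gen.base_channels, channel_cap=gen.channel_cap, rng=rng,
    )
    d = PatchGAN(
        in_ch=gen.in_channels + gen.out_channels, base_channels=disc.base_channels,
        n_layers=disc.n_layers, channel_cap=disc.channel_cap, rng=rng,
    )
    return ModelState(
        generator=g, discriminator=d, gen_spec=gen, disc_spec=disc,
        patch_size=patch_size, seed=seed,
    )


def _sigmoid(z: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * z))


def _bce_with_logits(z: np.ndarray, target: float) -> float:
    # softplus(z) - t*z, numerically stable
    return float(np.mean(np.logaddexp(0.0, z) - target * z))


def _normalize_images(images: np.ndarray, intensity_max: float) -> np.ndarray:
    return (images.astype(np.float32) / intensity_max) * 2.0 - 1.0


def _sample_arrays(dataset: SyntheticDataset, intensity_max: float):
    """Stack a dataset into normalised (x, y) arrays in [-1, 1].

    3-plane stacks keep the in-focus plane as the network input.
    """
    xs, ys = [], []
    for s in dataset.samples:
        img = s.image
        if img.ndim == 3:  # (3, H, W) stack: feed the in-focus plane
            img = img[img.shape[0] // 2]
        xs.append(img)
        ys.append(s.target)
    x = _normalize_images(np.stack(xs)[:, None], intensity_max)
    y = np.stack(ys)[:, None].astype(np.float32) * 2.0 - 1.0
    return x, y


def train(
    model: ModelState,
    train_set: SyntheticDataset,
    config: TrainConfig,
    eval_set: Optional[SyntheticDataset] = None,
) -> tuple[ModelState, pd.DataFrame, dict]:
    """Run the adversarial training loop.

    Alternates are folded into one pass per batch: the generator forward
    runs once, and discriminator/generator gradients are taken from the
    shared forward before a simultaneous Adam step for both networks.
    Returns ``(model, loss_history, snapshots)`` where ``loss_history``
    has one row per epoch (generator adversarial loss, generator L1 loss,
    discriminator loss, and test-set L1 when ``eval_set`` is given) and
    ``snapshots`` maps snapshot epochs to generator outputs on a probe set
    fixed before training.

    Raises
    ------
    TrainingDivergedError
        On a non-finite loss; the state from the last completed epoch is
        attached to the exception.
    """
    if len(train_set) == 0:
        raise ValueError("empty training set")
    g, d = model.generator, model.discriminator
    in_ch = model.gen_spec.in_channels
    rng = np.random.default_rng(config.seed)
    x_all, y_all = _sample_arrays(train_set, config.intensity_max)
    if x_all.shape[-1] != model.patch_size:
        raise ValueError(
            f"dataset patch size {x_all.shape[-1]} != model patch size {model.patch_size}"
        )
    x_eval = y_eval = None
    if eval_set is not None and len(eval_set):
        x_eval, y_eval = _sample_arrays(eval_set, config.intensity_max)

    # probe set for learning-progress snapshots, fixed before training
    probe_ix = rng.choice(len(train_set), size=min(4, len(train_set)), replace=False)
    snapshots: dict[int, np.ndarray] = {}

    if model.gen_opt is None:
        model.gen_opt = Adam(g.named_params(), lr=config.learning_rate, beta1=config.adam_beta1)
        model.disc_opt = Adam(d.named_params(), lr=config.learning_rate, beta1=config.adam_beta1)
    gen_opt, disc_opt = model.gen_opt, model.disc_opt

    n = len(train_set)
    history = []
    last_good = _clone_params(model)
    for epoch in range(1, config.epochs + 1):
        order = rng.permutation(n)
        sums = np.zeros(3)
        seen = 0
        for start in range(0, n, config.batch_size):
            ix = order[start : start + config.batch_size]
            xb, yb = x_all[ix], y_all[ix]
            g.zero_grad()
            d.zero_grad()

            fake = g.forward(xb)
            zf = d.forward(np.concatenate([xb, fake], axis=1))
            # generator adversarial gradient (non-saturating): data grad only
            dz_gen = (_sigmoid(zf) - 1.0) / zf.size
            dfake_adv = d.backward(dz_gen, accumulate=False)[:, in_ch:]
            # discriminator loss, fake half
            d.backward(0.5 * _sigmoid(zf) / zf.size, accumulate=True)
            # discriminator loss, real half
            zr = d.forward(np.concatenate([xb, yb], axis=1))
            d.backward(0.5 * (_sigmoid(zr) - 1.0) / zr.size, accumulate=True)

            l1 = np.mean(np.abs(fake - yb))
            dfake = config.lambda_l1 * np.sign(fake - yb) / fake.size + dfake_adv
            g.backward(dfake.astype(np.float32), accumulate=True)

            disc_opt.step(d.named_grads())
            gen_opt.step(g.named_grads())

            g_adv = _bce_with_logits(zf, 1.0)
            d_loss = 0.5 * (_bce_with_logits(zr, 1.0) + _bce_with_logits(zf, 0.0))
            sums += np.array([g_adv, l1, d_loss]) * len(ix)
            seen += len(ix)

        row = {
            "epoch": model.epoch + epoch,
            "gen_adv_loss": sums[0] / seen,
            "gen_l1_loss": sums[1] / seen,
            "disc_loss": sums[2] / seen,
        }
        if not all(np.isfinite(v) for v in row.values()):
            _restore_params(model, last_good)
            raise TrainingDivergedError(
                f"non-finite loss at epoch {row['epoch']}", model
            )
        if x_eval is not None:
            row["test_l1"] = _batched_l1(g, x_eval, y_eval, config.batch_size)
        history.append(row)
        last_good = _clone_params(model)
        if (model.epoch + epoch) in config.snapshot_epochs:
            out = g.forward(x_all[probe_ix])
            snapshots[model.epoch + epoch] = (out + 1.0) / 2.0

    model.epoch += config.epochs
    model.train_config = config
    return model, pd.DataFrame(history), snapshots


def _batched_l1(g: UNet, x: np.ndarray, y: np.ndarray, batch: int) -> float:
    tot = 0.0
    for s in range(0, len(x), batch):
        out = g.forward(x[s : s + batch])
        tot += float(np.abs(out - y[s : s + batch]).sum())
    return tot / y.size


def _clone_params(model: ModelState) -> dict:
    return {
        "g": {k: v.copy() for k, v in model.generator.named_params().items()},
        "d": {k: v.copy() for k, v in model.discriminator.named_params().items()},
    }


def _restore_params(model: ModelState, saved: dict) -> None:
    for k, v in model.generator.named_params().items():
        v[...] = saved["g"][k]
    for k, v in model.discriminator.named_params().items():
        v[...] = saved["d"][k]


def predict_mask(model: ModelState, patch: np.ndarray,
                 intensity_max: Optional[float] = None) -> np.ndarray:
    """Translate one patch (or a batch) into a [0, 1] contour-mask image.

    Deterministic for a fixed ModelState.  Raises on a spatial-shape
    mismatch with the configured patch size.
    """
    if intensity_max is None:
        intensity_max = model.train_config.intensity_max if model.train_config else 65535.0
    arr = np.asarray(patch)
    squeeze = arr.ndim == 2
    if arr.ndim == 2:
        arr = arr[None, None]
    elif arr.ndim == 3:
        arr = arr[:, None]
    if arr.shape[-2:] != (model.patch_size, model.patch_size):
        raise ValueError(f"patch shape {arr.shape[-2:]} != model patch size {model.patch_size}")
    x = _normalize_images(arr, intensity_max)
    out = (model.generator.forward(x) + 1.0) / 2.0
    out = np.clip(out[:, 0], 0.0, 1.0)
    return out[0] if squeeze else out


# ---------------------------------------------------------------------------
# serialization: single-file .npz with an embedded JSON header

def save_model(model: ModelState, path) -> None:
    arrays = {f"g.{k}": v for k, v in model.generator.named_params().items()}
    arrays.update({f"d.{k}": v for k, v in model.discriminator.named_params().items()})
    if model.gen_opt is not None:
        arrays.update({f"gopt.{k}": v for k, v in model.gen_opt.state_dict().items()})
        arrays.update({f"dopt.{k}": v for k, v in model.disc_opt.state_dict().items()})
    header = {
        "schema": 1,
        "gen_spec": asdict(model.gen_spec),
        "disc_spec": asdict(model.disc_spec),
        "patch_size": model.patch_size,
        "seed": model.seed,
        "epoch": model.epoch,
        "train_config": asdict(model.train_config) if model.train_config else None,
        "has_opt": model.gen_opt is not None,
    }
    arrays["header"] = np.frombuffer(json.dumps(header).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_model(path) -> ModelState:
    with np.load(path) as z:
        arrays = {k: z[k] for k in z.files}
    header = json.loads(bytes(arrays.pop("header")).decode())
    gen_spec = GeneratorSpec(**header["gen_spec"])
    disc_spec = DiscriminatorSpec(**header["disc_spec"])
    model = build_models(gen_spec, disc_spec, header["patch_size"], header["seed"])
    model.epoch = header["epoch"]
    if header["train_config"]:
        tc = dict(header["train_config"])
        tc["snapshot_epochs"] = tuple(tc.get("snapshot_epochs", ()))
        model.train_config = TrainConfig(**tc)
    for k, v in model.generator.named_params().items():
        v[...] = arrays[f"g.{k}"]
    for k, v in model.discriminator.named_params().items():
        v[...] = arrays[f"d.{k}"]
    if header["has_opt"]:
        cfg = model.train_config or TrainConfig()
        model.gen_opt = Adam(model.generator.named_params(), lr=cfg.learning_rate,
                             beta1=cfg.adam_beta1)
        model.disc_opt = Adam(model.discriminator.named_params(), lr=cfg.learning_rate,
                              beta1=cfg.adam_beta1)
        model.gen_opt.load_state_dict({k[5:]: v for k, v in arrays.items() if k.startswith("gopt.")})
        model.disc_opt.load_state_dict({k[5:]: v for k, v in arrays.items() if k.startswith("dopt.")})
    return model


# ---------------------------------------------------------------------------
# fitted-model front end

class Pix2PixTracer:
    """The Model-1 tracer as a fittable model object.

    Parameters
    ----------
    train_set, eval_set
        Paired patch corpora (:class:`~pnnmesh.dataset.SyntheticDataset`
        or anything with the same sample interface).
    gen_spec, disc_spec
        Architecture specifications.
    """

    def __init__(
        self,
        train_set: SyntheticDataset,
        eval_set: Optional[SyntheticDataset] = None,
        gen_spec: GeneratorSpec = GeneratorSpec(),
        disc_spec: DiscriminatorSpec = DiscriminatorSpec(),
    ):
        self.train_set = train_set
        self.eval_set = eval_set
        self.gen_spec = gen_spec
        self.disc_spec = disc_spec

    def fit(self, config: TrainConfig = TrainConfig()) -> "Pix2PixResults":
        model = build_models(
            self.gen_spec, self.disc_spec, patch_size=self.train_set.patch_size,
            seed=config.seed,
        )
        model, history, snapshots = train(model, self.train_set, config, eval_set=self.eval_set)
        return Pix2PixResults(model, history, snapshots, tracer=self)


class Pix2PixResults:
    """Trained tracer: parameters, loss history, snapshots, prediction."""

    def __init__(self, model_state: ModelState, loss_history: pd.DataFrame,
                 snapshots: Optional[dict] = None, tracer: Optional[Pix2PixTracer] = None):
        self.model_state = model_state
        self.loss_history = loss_history
        self.snapshots = snapshots or {}
        self.tracer = tracer

    def predict_mask(self, patch: np.ndarray) -> np.ndarray:
        return predict_mask(self.model_state, patch)

    def evaluate(self, test_set: SyntheticDataset, **kw):
        from .evaluate import evaluate_on_set

        return evaluate_on_set(self.model_state, test_set, **kw)

    def save(self, path) -> None:
        save_model(self.model_state, path)

    @classmethod
    def load(cls, path) -> "Pix2PixResults":
        return cls(load_model(path), pd.DataFrame())

    def summary(self) -> str:
        m = self.model_state
        buf = io.StringIO()
        buf.write("Pix2Pix mesh tracer (Model 1)\n")
        buf.write("=" * 46 + "\n")
        buf.write(f"generator      U-Net depth {m.gen_spec.depth}, base {m.gen_spec.base_channels}, cap {m.gen_spec.channel_cap}\n")
        buf.write(f"discriminator  PatchGAN, fragment diameter {m.disc_spec.receptive_field} px\n")
        buf.write(f"patch size     {m.patch_size} px, epochs trained {m.epoch}\n")
        if len(self.loss_history):
            last = self.loss_history.iloc[-1]
            buf.write(f"final losses   G_adv {last['gen_adv_loss']:.4f}  "
                      f"G_L1 {last['gen_l1_loss']:.4f}  D {last['disc_loss']:.4f}\n")
            if "test_l1" in self.loss_history:
                buf.write(f"test L1        epoch 1: {self.loss_history['test_l1'].iloc[0]:.4f}"
                          f" -> final: {last['test_l1']:.4f}\n")
        return buf.getvalue()
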