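"""The three networks of the joint calibration/classification framework.

* **Calibrator** ``C`` — maps a feature vector to a latent code of the
  same width.  Its first layer is batch normalization (standardizing each
  measurement batch against its own statistics during training), followed
  by two affine layers interleaved with two leaky rectifiers; every hidden
  width equals the input dimensionality, so the latent space is not
  compressed.
* **Reconstructors** ``R1``/``R2`` — one decoder per measurement batch,
  three affine layers with two leaky rectifiers, all widths equal to the
  input dimensionality.  They map latent codes back to the raw feature
  space so that the latent code retains the full sample content.
* **Discriminator** ``D`` — the label classifier on the latent space:
  five affine layers narrowing 128 → 64 → 32 → 16 → 1 with four leaky
  rectifiers and a terminal sigmoid, i.e. a binary classifier.

All parameters live in plain NumPy arrays; a checkpoint is a single zip
archive of ``.npy`` tensors plus a JSON manifest, auditable without any
deep-learning framework.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field

import numpy as np

from .nn import Adam, BatchNorm1d, LeakyReLU, Linear, Sequential, Sigmoid

__all__ = [
    "ModelState", "init_model", "calibrate", "reconstruct", "discriminate",
    "architecture", "save_checkpoint", "load_checkpoint",
    "DISCRIMINATOR_HIDDEN_WIDTHS",
]

#: widths of the discriminator's affine layers after the input layer
DISCRIMINATOR_HIDDEN_WIDTHS = (128, 64, 32, 16, 1)

CHECKPOINT_FORMAT = 1


@dataclass
class ModelState:
    """Trained (or freshly initialized) parameters of all four stacks."""

    calibrator: Sequential
    reconstructor_1: Sequential
    reconstructor_2: Sequential
    discriminator: Sequential
    input_dim: int
    seed: int
    negative_slope: float = 0.01
    init_scheme: str = "kaiming_uniform"
    extra: dict = field(default_factory=dict)

    def stacks(self) -> list[Sequential]:
        return [self.calibrator, self.reconstructor_1,
                self.reconstructor_2, self.discriminator]


def _calibrator(d: int, slope: float, rng) -> Sequential:
    return Sequential([
        BatchNorm1d(d),
        Linear(d, d, rng), LeakyReLU(slope),
        Linear(d, d, rng), LeakyReLU(slope),
    ])


def _reconstructor(d: int, slope: float, rng) -> Sequential:
    return Sequential([
        Linear(d, d, rng), LeakyReLU(slope),
        Linear(d, d, rng), LeakyReLU(slope),
        Linear(d, d, rng),
    ])


def _discriminator(d: int, slope: float, rng) -> Sequential:
    widths = (d,) + DISCRIMINATOR_HIDDEN_WIDTHS
    layers = []
    for i in range(len(widths) - 1):
        layers.append(Linear(widths[i], widths[i + 1], rng))
        if i < len(widths) - 2:
            layers.append(LeakyReLU(slope))
    layers.append(Sigmoid())
    return Sequential(layers)


def init_model(input_dim: int, seed: int, init_scheme: str = "kaiming_uniform",
               negative_slope: float = 0.01) -> ModelState:
    """Build a fresh, deterministic model for ``input_dim`` features.

    The same (input_dim, seed, init_scheme) always yields bitwise-identical
    parameters.  All affine layers share the same initialization strategy
    (uniform Kaiming fan-in scaling).
    """
    if input_dim < 1:
        raise ValueError("input_dim must be >= 1")
    if init_scheme != "kaiming_uniform":
        raise ValueError(f"unknown init_scheme: {init_scheme!r}")
    rng = np.random.default_rng(seed)
    return ModelState(
        calibrator=_calibrator(input_dim, negative_slope, rng),
        reconstructor_1=_reconstructor(input_dim, negative_slope, rng),
        reconstructor_2=_reconstructor(input_dim, negative_slope, rng),
        discriminator=_discriminator(input_dim, negative_slope, rng),
        input_dim=int(input_dim), seed=int(seed),
        negative_slope=float(negative_slope), init_scheme=init_scheme,
    )


def _check_width(model: ModelState, X: np.ndarray) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] != model.input_dim:
        raise ValueError(
            f"expected a 2-D array with {model.input_dim} columns, got shape {X.shape}")
    return X


def calibrate(model: ModelState, X: np.ndarray, batch_stats: bool = False) -> np.ndarray:
    """Latent codes ``Z = C(X)`` in evaluation mode (no running-stat updates).

    ``batch_stats=True`` standardizes against the statistics of ``X`` itself
    (transductive calibration of a whole measurement batch, matching the
    training-time treatment); ``False`` uses the frozen running statistics.
    """
    X = _check_width(model, X)
    Z, _ = model.calibrator.forward(X, training=False, batch_stats=batch_stats)
    return Z


def reconstruct(model: ModelState, Z: np.ndarray, which_batch: int) -> np.ndarray:
    """Decode latent codes with the reconstructor of the given batch (1 or 2)."""
    Z = _check_width(model, Z)
    if which_batch == 1:
        stack = model.reconstructor_1
    elif which_batch == 2:
        stack = model.reconstructor_2
    else:
        raise ValueError(f"which_batch must be 1 or 2, got {which_batch}")
    Xp, _ = stack.forward(Z, training=False)
    return Xp


def discriminate(model: ModelState, Z: np.ndarray) -> np.ndarray:
    """Per-sample class-1 probabilities ``D(Z)``, each strictly in (0, 1)."""
    Z = _check_width(model, Z)
    p, _ = model.discriminator.forward(Z, training=False)
    return p.ravel()


def architecture(model: ModelState) -> dict:
    """Layer-by-layer description of all four stacks (for audit/tests)."""
    return {
        "input_dim": model.input_dim,
        "calibrator": model.calibrator.specs(),
        "reconstructor_1": model.reconstructor_1.specs(),
        "reconstructor_2": model.reconstructor_2.specs(),
        "discriminator": model.discriminator.specs(),
    }


# ---------------------------------------------------------------------------
# checkpoint archive

def _stack_name(i: int) -> str:
    return ["calibrator", "reconstructor_1", "reconstructor_2", "discriminator"][i]


def save_checkpoint(model: ModelState, path) -> None:
    manifest = {
        "format": CHECKPOINT_FORMAT,
        "input_dim": model.input_dim,
        "seed": model.seed,
        "negative_slope": model.negative_slope,
        "init_scheme": model.init_scheme,
        "architecture": architecture(model),
        "tensors": [],
    }
    entries: list[tuple[str, np.ndarray]] = []

    def add(name: str, arr: np.ndarray):
        manifest["tensors"].append({"name": name, "shape": list(arr.shape)})
        entries.append((name, arr))

    for s, stack in enumerate(model.stacks()):
        for i, layer in enumerate(stack.layers):
            for pname, arr in layer.params.items():
                add(f"{_stack_name(s)}/{i}/{pname}", arr)
            if isinstance(layer, BatchNorm1d):
                add(f"{_stack_name(s)}/{i}/running_mean", layer.running_mean)
                add(f"{_stack_name(s)}/{i}/running_var", layer.running_var)

    with zipfile.ZipFile(path, "w", zipfile.ZIP_DEFLATED) as zf:
        zf.writestr("manifest.json", json.dumps(manifest, indent=2, sort_keys=True))
        for name, arr in entries:
            buf = io.BytesIO()
            np.save(buf, np.ascontiguousarray(arr))
            zf.writestr(name + ".npy", buf.getvalue())


def load_checkpoint(path) -> ModelState:
    with zipfile.ZipFile(path) as zf:
        manifest = json.loads(zf.read("manifest.json"))
        if manifest.get("format") != CHECKPOINT_FORMAT:
            raise ValueError("unrecognized checkpoint format")
        model = init_model(manifest["input_dim"], manifest["seed"],
                           manifest["init_scheme"], manifest["negative_slope"])
        for s, stack in enumerate(model.stacks()):
            for i, layer in enumerate(stack.layers):
                for pname in layer.params:
                    name = f"{_stack_name(s)}/{i}/{pname}.npy"
                    layer.params[pname] = np.load(io.BytesIO(zf.read(name)))
                if isinstance(layer, BatchNorm1d):
                    layer.running_mean = np.load(
                        io.BytesIO(zf.read(f"{_stack_name(s)}/{i}/running_mean.npy")))
                    layer.running_var = np.load(
                        io.BytesIO(zf.read(f"{_stack_name(s)}/{i}/running_var.npy")))
    return model
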