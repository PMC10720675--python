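"""Segmentation model definitions: U-Net, attention U-Net, multiscale U-Net.

All three are symmetric encoder-decoder fully convolutional networks
producing a per-pixel foreground probability at input resolution:

* ``unet`` — standard double-conv blocks with skip connections;
* ``atten_unet`` — additive attention gates on every skip connection;
* ``ms_unet`` — encoder blocks use parallel atrous (dilated) branches
  whose outputs are concatenated and fused 1x1, so each block combines
  the fields of view of several magnifications in one pass.
"""

from __future__ import annotations

import io
import json
import zipfile
from dataclasses import dataclass, field, asdict

import numpy as np

from . import nn

VARIANTS = ("unet", "atten_unet", "ms_unet")
STRUCTURES = ("gc", "sinus")


@dataclass
class SegModelSpec:
    """Architecture hyperparameters for one binary segmentation model.

    ``scales`` are the downsample factors the multiscale variant fuses
    (1, 2, 4 corresponding to x10, x5, x2.5 fields of view);
    ``dilation_rates`` default to the scales themselves.
    """

    variant: str = "ms_unet"
    structure: str = "gc"
    input_magnification: str = "x10"
    scales: tuple = (1, 2, 4)
    base_channels: int = 16
    depth: int = 5
    dilation_rates: tuple | None = None
    seed: int = 0

    def __post_init__(self):
        if self.variant not in VARIANTS:
            raise ValueError(f"unknown variant {self.variant!r}")
        if self.structure not in STRUCTURES:
            raise ValueError(f"unknown structure {self.structure!r}")
        if self.depth < 2:
            raise ValueError("depth must be >= 2")
        self.scales = tuple(int(s) for s in self.scales)
        if self.dilation_rates is None:
            self.dilation_rates = self.scales
        self.dilation_rates = tuple(int(r) for r in self.dilation_rates)
        if self.variant == "ms_unet":
            if len(self.scales) < 2:
                raise ValueError("ms_unet requires at least 2 scales")
            if len(self.dilation_rates) != len(self.scales):
                raise ValueError("dilation_rates length must equal number of scales")


class UNet:
    """Encoder-decoder segmentation network built from the nn engine.

    ``depth`` counts encoder blocks (the last acts as the bottleneck);
    input height and width must be divisible by ``2**(depth-1)``.
    """

    def __init__(self, spec: SegModelSpec):
        self.spec = spec
        rng = np.random.default_rng(spec.seed)
        d, c0 = spec.depth, spec.base_channels
        chans = [c0 * 2 ** i for i in range(d)]
        self.enc = []
        c_in = 3
        for i in range(d):
            if spec.variant == "ms_unet":
                blk = nn.MultiScaleConv(c_in, chans[i], spec.dilation_rates, rng)
            else:
                blk = nn.DoubleConv(c_in, chans[i], rng)
            self.enc.append(blk)
            c_in = chans[i]
        self.pools = [nn.MaxPool2() for _ in range(d - 1)]
        self.ups = []
        self.upconv = []
        self.gates = []
        self.dec = []
        for i in range(d - 2, -1, -1):
            self.ups.append(nn.Upsample2())
            self.upconv.append(nn.Conv2d(chans[i + 1], chans[i], 3, rng))
            if spec.variant == "atten_unet":
                self.gates.append(nn.AttentionGate(chans[i], chans[i], max(chans[i] // 2, 1), rng))
            else:
                self.gates.append(None)
            self.dec.append(nn.DoubleConv(chans[i] * 2, chans[i], rng))
        self.final = nn.Conv2d(chans[0], 1, 1, rng)
        self._relu_up = [nn.ReLU() for _ in self.upconv]
        self._cache = None

    # ---- parameter plumbing -------------------------------------------------
    def params(self):
        ps = []
        for blk in self.enc:
            ps += blk.params()
        for conv in self.upconv:
            ps += conv.params()
        for g in self.gates:
            if g is not None:
                ps += g.params()
        for blk in self.dec:
            ps += blk.params()
        return ps + self.final.params()

    def _check_input(self, x):
        if x.ndim != 4 or x.shape[1] != 3:
            raise ValueError("expected NCHW input with 3 channels")
        div = 2 ** (self.spec.depth - 1)
        if x.shape[2] % div or x.shape[3] % div:
            raise ValueError(
                f"input size {x.shape[2]}x{x.shape[3]} not divisible by {div} "
                f"(depth {self.spec.depth})")

    # ---- forward / backward -------------------------------------------------
    def forward(self, x: np.ndarray) -> np.ndarray:
        """Return logits with the same height/width as the input."""
        self._check_input(x)
        skips = []
        h = x
        for i, blk in enumerate(self.enc):
            h = blk.forward(h)
            if i < len(self.pools):
                skips.append(h)
                h = self.pools[i].forward(h)
        self._gated = []
        for j in range(len(self.dec)):
            h = self._relu_up[j].forward(self.upconv[j].forward(self.ups[j].forward(h)))
            skip = skips[-(j + 1)]
            if self.gates[j] is not None:
                skip = self.gates[j].forward(skip, h)
            h = self.dec[j].forward(np.concatenate([skip, h], axis=1))
        return self.final.forward(h)

    def backward(self, gy: np.ndarray) -> None:
        g = self.final.backward(gy)
        gskips = [None] * len(self.dec)
        for j in range(len(self.dec) - 1, -1, -1):
            g = self.dec[j].backward(g)
            c = g.shape[1] // 2
            gskip, g = g[:, :c], g[:, c:]
            if self.gates[j] is not None:
                gskip, gg = self.gates[j].backward(gskip)
                g = g + gg
            gskips[j] = gskip
            g = self.ups[j].backward(self.upconv[j].backward(self._relu_up[j].backward(g)))
        for i in range(len(self.enc) - 1, -1, -1):
            if i < len(self.pools):
                g = self.pools[i].backward(g)
                g = g + gskips[len(self.dec) - 1 - i]
            g = self.enc[i].backward(g)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Per-pixel probabilities in [0, 1] for a NCHW float batch."""
        logits = self.forward(np.asarray(x, dtype=np.float64))
        from .nn import _sigmoid
        return _sigmoid(logits)[:, 0]

    # ---- serialization ------------------------------------------------------
    def state(self) -> list[np.ndarray]:
        return [p.v.copy() for p in self.params()]

    def load_state(self, state) -> None:
        for p, v in zip(self.params(), state):
            p.v[...] = v


def build_model(spec: SegModelSpec) -> UNet:
    """Instantiate a variant from its spec with seeded initialization."""
    return UNet(spec)


def save_checkpoint(path, model: UNet, train_config=None, history=None) -> None:
    """Self-describing checkpoint: spec + optional train config + weights."""
    meta = {"spec": asdict(model.spec)}
    if train_config is not None:
        meta["train_config"] = train_config if isinstance(train_config, dict) else asdict(train_config)
    if history is not None:
        meta["history"] = history
    with zipfile.ZipFile(path, "w") as zf:
        zf.writestr("meta.json", json.dumps(meta, default=_json_default))
        buf = io.BytesIO()
        np.savez(buf, *[p.v for p in model.params()])
        zf.writestr("weights.npz", buf.getvalue())


def load_checkpoint(path) -> tuple[UNet, dict]:
    with zipfile.ZipFile(path) as zf:
        meta = json.loads(zf.read("meta.json"))
        spec = SegModelSpec(**{k: tuple(v) if isinstance(v, list) else v
                               for k, v in meta["spec"].items()})
        model = UNet(spec)
        with zf.open("weights.npz") as f:
            data = np.load(io.BytesIO(f.read()))
            model.load_state([data[k] for k in data.files])
    return model, meta


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
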