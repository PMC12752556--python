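"""17-way cell classification with a large-kernel-attention network, plus the
dual-model agreement gate.

The network follows the visual-attention design that combines convolutional
locality with long-range context: each block computes an attention map through
a depthwise convolution, a depthwise *dilated* convolution and a pointwise
convolution, and gates its input multiplicatively with that map. A light
convolutional feed-forward sub-block follows; both sub-blocks are residual.

The agreement gate re-tests the papillary-carcinoma and benign-follicular
classes (C1-C3, C6-C8) against the independent morphology-GBT call: only cells
on which both models agree (at the role level by default) keep their class;
the rest are rejected and excluded from slide-level statistics.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .nn import (AdamW, BatchNorm2d, Conv2d, DepthwiseConv2d, GELU,
                 GlobalAvgPool, Linear, Module, cosine_lr, softmax,
                 softmax_cross_entropy)
from .schema import (CLASS_IDS, DEFAULT_SCHEMA, GATED_CLASSES, REJECTED,
                     ClassSchema)

__all__ = ["CellNetConfig", "CellTrainConfig", "CellNet", "CellCall",
           "TINY_CELL", "build_cell_net", "train_cell_net",
           "classify_patches", "agreement_gate"]


class ConfigurationError(ValueError):
    pass


class DataError(ValueError):
    pass


@dataclass(frozen=True)
class CellNetConfig:
    stage_depths: tuple = (2, 2)
    stage_widths: tuple = (16, 32)
    lka_kernel: int = 5
    lka_dilated_kernel: int = 7
    lka_dilation: int = 3
    input_size: int = 224
    num_classes: int = 17

    def __post_init__(self):
        if self.input_size < 32:
            raise ConfigurationError("input crop size must be >= 32")
        if self.num_classes != len(CLASS_IDS):
            raise ConfigurationError("num_classes is fixed at the schema size")
        if len(self.stage_depths) != len(self.stage_widths):
            raise ConfigurationError("stage depths/widths mismatch")


TINY_CELL = CellNetConfig(input_size=64)


class _LKA:
    """Large-kernel attention: DW conv -> DW dilated conv -> PW conv; the
    result gates the input multiplicatively. ``identity_gate`` is a test hook
    replacing the attention map with ones."""

    def __init__(self, c, cfg: CellNetConfig, rng):
        self.dw = DepthwiseConv2d(c, cfg.lka_kernel, rng=rng)
        self.dwd = DepthwiseConv2d(c, cfg.lka_dilated_kernel,
                                   dilation=cfg.lka_dilation, rng=rng)
        self.pw = Conv2d(c, c, 1, rng=rng)
        self.identity_gate = False

    def forward(self, u):
        if self.identity_gate:
            self._u, self._a = u, None
            return u.copy()
        a = self.pw.forward(self.dwd.forward(self.dw.forward(u)))
        self._u, self._a = u, a
        return a * u

    def backward(self, dy):
        if self.identity_gate:
            return dy
        da = self._u * dy
        du_gate = self.dw.backward(self.dwd.backward(self.pw.backward(da)))
        return self._a * dy + du_gate

    def modules(self):
        return [self.dw, self.dwd, self.pw]


class _Block:
    """Residual attention sub-block + residual convolutional FFN."""

    def __init__(self, c, cfg, rng):
        self.bn1 = BatchNorm2d(c)
        self.proj1 = Conv2d(c, c, 1, rng=rng)
        self.act1 = GELU()
        self.lka = _LKA(c, cfg, rng)
        self.proj2 = Conv2d(c, c, 1, rng=rng)
        self.bn2 = BatchNorm2d(c)
        self.fc1 = Conv2d(c, 2 * c, 1, rng=rng)
        self.act2 = GELU()
        self.fc2 = Conv2d(2 * c, c, 1, rng=rng)

    def forward(self, x):
        h = self.proj2.forward(self.lka.forward(
            self.act1.forward(self.proj1.forward(self.bn1.forward(x)))))
        x = x + h
        h2 = self.fc2.forward(self.act2.forward(
            self.fc1.forward(self.bn2.forward(x))))
        return x + h2

    def backward(self, dy):
        d2 = self.bn2.backward(self.fc1.backward(
            self.act2.backward(self.fc2.backward(dy))))
        dy = dy + d2
        d1 = self.bn1.backward(self.proj1.backward(self.act1.backward(
            self.lka.backward(self.proj2.backward(dy)))))
        return dy + d1

    def modules(self):
        return [self.bn1, self.proj1, self.act1, *self.lka.modules(),
                self.proj2, self.bn2, self.fc1, self.act2, self.fc2]


class CellNet:
    def __init__(self, config: CellNetConfig, init_seed: int = 0):
        self.config = config
        rng = np.random.default_rng(init_seed)
        w = config.stage_widths
        self.embed = Conv2d(3, w[0], 4, stride=4, padding=0, rng=rng)
        self.embed_bn = BatchNorm2d(w[0])
        self.stages, self.downs = [], []
        for si, (depth, width) in enumerate(zip(config.stage_depths, w)):
            if si > 0:
                self.downs.append((Conv2d(w[si - 1], width, 3, stride=2,
                                          padding=1, rng=rng),
                                   BatchNorm2d(width)))
            self.stages.append([_Block(width, config, rng)
                                for _ in range(depth)])
        self.pool = GlobalAvgPool()
        self.head = Linear(w[-1], config.num_classes, rng=rng)

    def modules(self):
        mods = [self.embed, self.embed_bn]
        for si, stage in enumerate(self.stages):
            if si > 0:
                mods.extend(self.downs[si - 1])
            for b in stage:
                mods.extend(b.modules())
        mods.extend([self.pool, self.head])
        return mods

    def n_params(self):
        return sum(m.n_params() for m in self.modules() if isinstance(m, Module))

    def train(self):
        for m in self.modules():
            m.train()

    def eval(self):
        for m in self.modules():
            m.eval()

    def set_identity_gate(self, flag: bool):
        for stage in self.stages:
            for b in stage:
                b.lka.identity_gate = flag

    def forward(self, x):
        h = self.embed_bn.forward(self.embed.forward(x))
        for si, stage in enumerate(self.stages):
            if si > 0:
                conv, bn = self.downs[si - 1]
                h = bn.forward(conv.forward(h))
            for b in stage:
                h = b.forward(h)
        return self.head.forward(self.pool.forward(h))

    def backward(self, dlogits):
        dh = self.pool.backward(self.head.backward(dlogits))
        for si in range(len(self.stages) - 1, -1, -1):
            for b in reversed(self.stages[si]):
                dh = b.backward(dh)
            if si > 0:
                conv, bn = self.downs[si - 1]
                dh = conv.backward(bn.backward(dh))
        return self.embed.backward(self.embed_bn.backward(dh))

    def logits(self, crops: np.ndarray) -> np.ndarray:
        """Eval-mode logits for a batch of uint8 RGB crops (center-cropped to
        the configured input size when larger)."""
        self.eval()
        x = _prep(crops, self.config.input_size)
        return self.forward(x)


def _prep(crops, size):
    if crops.ndim == 3:
        crops = crops[None]
    h, w = crops.shape[1:3]
    if h < size or w < size:
        raise ValueError(f"crops {h}x{w} smaller than input size {size}")
    dy, dx = (h - size) // 2, (w - size) // 2
    crops = crops[:, dy:dy + size, dx:dx + size]
    return (crops.astype(np.float32) / 255.0).transpose(0, 3, 1, 2)


def build_cell_net(config: CellNetConfig, init_seed: int = 0) -> CellNet:
    return CellNet(config, init_seed=init_seed)


@dataclass(frozen=True)
class CellTrainConfig:
    lr: float = 1e-3            # cosine-annealed
    weight_decay: float = 0.05
    epochs: int = 40
    batch_size: int = 32
    seed: int = 0
    augment: bool = True
    jitter: float = 0.06        # multiplicative colour jitter amplitude


def _augment_batch(batch, size, rng, jitter):
    """Flip / rotate / colour-jitter, then random crop to the input size."""
    out = np.empty((batch.shape[0], size, size, 3), dtype=np.float32)
    for i, img in enumerate(batch):
        x = img
        if rng.random() < 0.5:
            x = x[:, ::-1]
        if rng.random() < 0.5:
            x = x[::-1]
        k = int(rng.integers(0, 4))
        if k:
            x = np.rot90(x, k)
        g = 1.0 + rng.uniform(-jitter, jitter, size=3)
        x = np.clip(x.astype(np.float32) * g, 0, 255)
        h, w = x.shape[:2]
        oy = int(rng.integers(0, h - size + 1))
        ox = int(rng.integers(0, w - size + 1))
        out[i] = x[oy:oy + size, ox:ox + size]
    return (out / 255.0).transpose(0, 3, 1, 2)


def train_cell_net(model: CellNet, crops, labels,
                   hyper: CellTrainConfig | None = None):
    """Train on labelled crops (labels are class ids like 'C4').

    AdamW with decoupled weight decay and a cosine-annealed learning rate;
    deterministic given ``hyper.seed``. Returns ``(model, loss trace)``.
    """
    hyper = hyper or CellTrainConfig()
    crops = np.asarray(crops)
    yi = np.array([CLASS_IDS.index(l) for l in labels])
    if len(set(yi.tolist())) < 2:
        raise DataError("need at least 2 classes present")
    rng = np.random.default_rng(hyper.seed)
    opt = AdamW(model.modules(), lr=hyper.lr, weight_decay=hyper.weight_decay)
    n = len(crops)
    size = model.config.input_size
    spe = int(np.ceil(n / hyper.batch_size))
    total = hyper.epochs * spe
    trace, step = [], 0
    model.train()
    for _ in range(hyper.epochs):
        order = rng.permutation(n)
        losses = []
        for b in range(spe):
            idx = order[b * hyper.batch_size:(b + 1) * hyper.batch_size]
            if hyper.augment:
                x = _augment_batch(crops[idx], size, rng, hyper.jitter)
            else:
                x = _prep(crops[idx], size)
            logits = model.forward(x)
            loss, dlog = softmax_cross_entropy(logits, yi[idx])
            opt.zero_grad()
            model.backward(dlog)
            opt.step(lr=cosine_lr(hyper.lr, step, total))
            step += 1
            losses.append(loss)
        trace.append(float(np.mean(losses)))
    model.eval()
    return model, trace


def classify_patches(crops, model: CellNet, batch_size: int = 64):
    """Softmax probabilities and argmax class for each crop.

    Returns a list of ``(prob_vector, net_class)``; ties break to the lowest
    class index. An empty crop list yields an empty result.
    """
    crops = np.asarray(crops)
    if crops.size == 0:
        return []
    if crops.ndim == 3:
        crops = crops[None]
    out = []
    for b in range(0, len(crops), batch_size):
        logits = model.logits(crops[b:b + batch_size])
        probs = softmax(logits)
        for p in probs:
            out.append((p, CLASS_IDS[int(np.argmax(p))]))
    return out


# ---------------------------------------------------------------------------
# dual-model agreement gate

@dataclass
class CellCall:
    detection_id: int
    prob_vector: np.ndarray          # 17 probabilities, sums to 1
    net_class: str
    morpho_class: str | None = None  # class id or role name from the GBT
    agreed: bool | None = None
    final_class: str | None = None


def agreement_gate(calls, schema: ClassSchema = DEFAULT_SCHEMA,
                   exact_id: bool = False):
    """Apply the dual-model re-test to C1-C3 / C6-C8 calls.

    Agreement is evaluated at the role level by default (the morphology GBT
    may be trained on the 9-role reduction; its call may be a class id or a
    role name); ``exact_id=True`` demands identical class ids. The gate never
    changes a class — it only rejects; classes outside the gated set pass
    through unconditionally. Idempotent.
    """
    out = []
    for call in calls:
        c = CellCall(detection_id=call.detection_id,
                     prob_vector=call.prob_vector, net_class=call.net_class,
                     morpho_class=call.morpho_class)
        if call.net_class in GATED_CLASSES and call.final_class != REJECTED:
            mc = call.morpho_class
            if exact_id:
                c.agreed = (mc == call.net_class)
            else:
                mrole = schema.role(mc) if mc in schema.class_ids else mc
                c.agreed = (mrole == schema.role(call.net_class))
            c.final_class = call.net_class if c.agreed else REJECTED
        elif call.final_class == REJECTED:
            c.agreed, c.final_class = False, REJECTED
        else:
            c.final_class = call.net_class
        out.append(c)
    return out
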