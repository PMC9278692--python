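"""Cycle-consistent unpaired CBCT<->CT translation model.

Two fully convolutional generators (G_cbct2ct, G_ct2cbct) and two patch
discriminators (D_ct, D_cbct) are trained jointly on unpaired 2D axial
patches with a five-term objective:

======  ==============================================  =======
term    purpose                                         weight
======  ==============================================  =======
cycle   G'(G(x)) ~ x, content preservation              10.0
adv     least-squares adversarial realism               1.0
grad    preserve edge structure between input/output    1.0
idem    a generator leaves its own domain unchanged     1.0
tv      total-variation smoothness of outputs           1.0
======  ==============================================  =======

Each generator encodes with strided convolutions, transforms through
residual blocks (default 3) and decodes with transposed convolutions back to
the input size; the network output is added to its input (residual
formulation), so a freshly initialized generator is the identity map.
Discriminators emit a patch-level real/fake score map whose receptive field
is smaller than the training patch.

The model object follows the fit/results pattern: build a
:class:`CycleGan` from slice data (or :meth:`CycleGan.from_manifest`), call
:meth:`~CycleGan.fit`, and use the returned :class:`CycleGanResults` for
inference, the loss history, and checkpointing.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .grid import ImageVolume
from .nn import Tensor, avg_pool2d, conv2d, conv2d_transpose, instance_norm

__all__ = [
    "GeneratorSpec", "DiscriminatorSpec", "LossWeights", "TrainConfig",
    "loss_cycle", "loss_adv", "loss_grad", "loss_idem", "loss_tv",
    "total_objective", "preprocess_slice", "augmented_count",
    "CycleGan", "CycleGanResults", "load_results",
]

AIR_HU = -1000.0


# ---------------------------------------------------------------------------
# Specs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GeneratorSpec:
    base_filters: int = 8
    n_res_blocks: int = 3
    depth: int = 1  # number of stride-2 encoder stages

    def __post_init__(self):
        if self.n_res_blocks < 1:
            raise ValueError("need at least one residual block")
        if self.depth < 0:
            raise ValueError("depth must be >= 0")


@dataclass(frozen=True)
class DiscriminatorSpec:
    """Patch discriminator: score map over pooled, gain-amplified input.

    CBCT artifacts at desk scale are fractions of a percent of the
    normalized HU range, so the discriminator front end average-pools the
    patch (suppressing per-voxel noise, widening the effective receptive
    field toward the low-frequency cupping/bias signatures) and applies a
    fixed affine input transform ``gain * (x - offset)`` to bring the
    differences to unit scale.  Neither step is learned.
    """

    base_filters: int = 8
    depth: int = 2            # stride-2 stages before the score-map head
    kernel: int = 3
    pool: int = 4             # fixed front-end average pooling
    input_gain: float = 16.0
    input_offset: float = -0.75  # ~mean normalized HU of an abdominal slice

    def receptive_field(self) -> int:
        rf, jump = self.kernel, 1
        for _ in range(self.depth):
            jump *= 2
            rf += (self.kernel - 1) * jump
        return rf * self.pool


@dataclass(frozen=True)
class LossWeights:
    cycle: float = 10.0
    adv: float = 1.0
    grad: float = 1.0
    idem: float = 1.0
    tv: float = 1.0

    def __post_init__(self):
        for f in dataclasses.fields(self):
            if getattr(self, f.name) < 0:
                raise ValueError(f"loss weight {f.name} must be >= 0")

    def as_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class TrainConfig:
    epochs: int = 25
    batch_size: int = 4
    patch_size: int = 64
    crops_per_slice: int = 1
    work_size: tuple[int, int] = (64, 64)  # free-air crop target (rows, cols)
    hu_window: tuple[float, float] = (-1000.0, 3000.0)
    optimizer: str = "adam"  # or "sgd"
    lr: float = 2e-3
    disc_lr: float | None = 1e-2  # None -> same as lr
    seed: int = 0
    checkpoint_every: int = 0  # epochs; 0 = final only

    def __post_init__(self):
        lo, hi = self.hu_window
        if not hi > lo:
            raise ValueError("HU window min must be < max")
        if self.patch_size > min(self.work_size):
            raise ValueError("crop size must be <= the working slice size")


# ---------------------------------------------------------------------------
# Layers and networks
# ---------------------------------------------------------------------------

class _Conv:
    def __init__(self, cin, cout, k, stride, pad, rng, zero_init=False):
        scale = 0.0 if zero_init else 0.02
        self.w = Tensor((scale * rng.standard_normal((cout, cin, k, k))
                         ).astype(np.float32), requires_grad=True)
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)
        self.stride, self.pad = stride, pad

    def __call__(self, x):
        return conv2d(x, self.w, self.b, stride=self.stride, pad=self.pad)

    def params(self):
        return [self.w, self.b]


class _ConvT:
    def __init__(self, cin, cout, k, rng):
        self.w = Tensor((0.02 * rng.standard_normal((cin, cout, k, k))
                         ).astype(np.float32), requires_grad=True)
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def __call__(self, x):
        return conv2d_transpose(x, self.w, self.b, stride=2, pad=1,
                                output_padding=1)

    def params(self):
        return [self.w, self.b]


class _InstanceNorm:
    eps = 1e-5

    def __init__(self, c):
        self.g = Tensor(np.ones((1, c, 1, 1), dtype=np.float32),
                        requires_grad=True)
        self.beta = Tensor(np.zeros((1, c, 1, 1), dtype=np.float32),
                           requires_grad=True)

    def __call__(self, x):
        return instance_norm(x, self.g, self.beta, self.eps)

    def params(self):
        return [self.g, self.beta]


class Generator:
    """Residual encoder / res-blocks / decoder generator."""

    def __init__(self, spec: GeneratorSpec, rng: np.random.Generator):
        f = spec.base_filters
        self.spec = spec
        self.layers: list = []
        self.head = _Conv(1, f, 3, 1, 1, rng)
        self.head_n = _InstanceNorm(f)
        self.down, self.down_n = [], []
        c = f
        for _ in range(spec.depth):
            self.down.append(_Conv(c, 2 * c, 3, 2, 1, rng))
            self.down_n.append(_InstanceNorm(2 * c))
            c *= 2
        self.res = []
        for _ in range(spec.n_res_blocks):
            self.res.append((_Conv(c, c, 3, 1, 1, rng), _InstanceNorm(c),
                             _Conv(c, c, 3, 1, 1, rng), _InstanceNorm(c)))
        self.up, self.up_n = [], []
        for _ in range(spec.depth):
            self.up.append(_ConvT(c, c // 2, 3, rng))
            self.up_n.append(_InstanceNorm(c // 2))
            c //= 2
        self.tail = _Conv(c, 1, 3, 1, 1, rng, zero_init=True)

    def __call__(self, x: Tensor) -> Tensor:
        h = self.head_n(self.head(x)).relu()
        for cv, nrm in zip(self.down, self.down_n):
            h = nrm(cv(h)).relu()
        for c1, n1, c2, n2 in self.res:
            h = h + n2(c2(n1(c1(h)).relu()))
        for cv, nrm in zip(self.up, self.up_n):
            h = nrm(cv(h)).relu()
        return x + self.tail(h)

    def modules(self):
        mods = [self.head, self.head_n, *self.down, *self.down_n, self.tail,
                *self.up, *self.up_n]
        for block in self.res:
            mods.extend(block)
        return mods

    def params(self):
        return [p for m in self.modules() for p in m.params()]


class Discriminator:
    """PatchGAN discriminator: real/fake score map, no global pooling."""

    def __init__(self, spec: DiscriminatorSpec, rng: np.random.Generator):
        f = spec.base_filters
        k = spec.kernel
        self.spec = spec
        self.blocks = [(_Conv(1, f, k, 2, k // 2, rng), None)]
        c = f
        for _ in range(spec.depth - 1):
            self.blocks.append((_Conv(c, 2 * c, k, 2, k // 2, rng), None))
            c *= 2
        self.headc = _Conv(c, 1, k, 1, k // 2, rng)

    def __call__(self, x: Tensor) -> Tensor:
        h = avg_pool2d(x, self.spec.pool)
        h = (h + (-self.spec.input_offset)) * self.spec.input_gain
        for cv, nrm in self.blocks:
            h = cv(h)
            if nrm is not None:
                h = nrm(h)
            h = h.leaky_relu(0.2)
        return self.headc(h)

    def params(self):
        ps = []
        for cv, nrm in self.blocks:
            ps.extend(cv.params())
            if nrm is not None:
                ps.extend(nrm.params())
        ps.extend(self.headc.params())
        return ps


class _Adam:
    def __init__(self, params, lr, betas=(0.5, 0.999), eps=1e-8):
        self.params = params
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * p.grad
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * p.grad**2
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


class _SGD:
    def __init__(self, params, lr):
        self.params, self.lr = params, lr

    def step(self):
        for p in self.params:
            if p.grad is not None:
                p.data -= self.lr * p.grad

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def _make_opt(kind: str, params, lr):
    if kind == "adam":
        return _Adam(params, lr)
    if kind == "sgd":
        return _SGD(params, lr)
    raise ValueError(f"unknown optimizer {kind!r}")


# ---------------------------------------------------------------------------
# Loss functions
# ---------------------------------------------------------------------------

def _T(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=float))


def _ret(val: Tensor, *inputs):
    return val if any(isinstance(i, Tensor) for i in inputs) else val.item()


def loss_cycle(x, x_cyclic):
    """Mean absolute difference between an image and its cyclic reconstruction."""
    xt, ct = _T(x), _T(x_cyclic)
    if xt.shape != ct.shape:
        raise ValueError(f"shape mismatch: {xt.shape} vs {ct.shape}")
    return _ret((xt - ct).abs().mean(), x, x_cyclic)


def loss_adv(score_fake, score_real=None, role: str = "generator"):
    """Least-squares adversarial objective on discriminator score maps.

    Generator role: mean((fake - 1)^2) — fooled when fakes score 1.
    Discriminator role: mean((real - 1)^2) + mean(fake^2).
    """
    fk = _T(score_fake)
    if role == "generator":
        return _ret(((fk - 1.0) ** 2).mean(), score_fake)
    if role == "discriminator":
        if score_real is None:
            raise ValueError("discriminator role needs real scores")
        rl = _T(score_real)
        return _ret(((rl - 1.0) ** 2).mean() + (fk**2).mean(),
                    score_fake, score_real)
    raise ValueError(f"role must be generator|discriminator, got {role!r}")


def _axis_grad_mag(t: Tensor, axis: int) -> Tensor:
    if axis == -2:
        return (t[..., 1:, :] - t[..., :-1, :]).abs()
    return (t[..., :, 1:] - t[..., :, :-1]).abs()


def loss_grad(inp, out):
    """Edge-preservation loss: |grad-magnitude(input) - grad-magnitude(output)|.

    Row and column finite differences are compared separately and averaged,
    so a constant offset between input and output costs nothing.
    """
    it, ot = _T(inp), _T(out)
    if it.shape != ot.shape:
        raise ValueError(f"shape mismatch: {it.shape} vs {ot.shape}")
    r = (_axis_grad_mag(it, -2) - _axis_grad_mag(ot, -2)).abs().mean()
    c = (_axis_grad_mag(it, -1) - _axis_grad_mag(ot, -1)).abs().mean()
    return _ret(0.5 * (r + c), inp, out)


def loss_idem(g, y):
    """Idempotency: a generator applied to its own target domain is identity."""
    yt = _T(y)
    gy = g(yt) if callable(g) else _T(g)
    return _ret((gy - yt).abs().mean(), y)


def loss_tv(out):
    """Mean anisotropic total variation, normalized by pixel count."""
    ot = _T(out)
    n = float(np.prod(ot.shape))
    tv = _axis_grad_mag(ot, -2).sum() + _axis_grad_mag(ot, -1).sum()
    return _ret(tv * (1.0 / n), out)


def total_objective(terms: dict, weights: LossWeights = LossWeights()):
    """Weighted sum of the five per-term losses; returns (total, breakdown)."""
    w = weights.as_dict()
    breakdown = {}
    total = None
    for name in ("cycle", "adv", "grad", "idem", "tv"):
        term = terms.get(name, 0.0)
        contrib = _T(term) * w[name]
        breakdown[name] = contrib if isinstance(term, Tensor) else float(contrib.item())
        total = contrib if total is None else total + contrib
    if not any(isinstance(v, Tensor) for v in terms.values()):
        return float(total.item()), breakdown
    return total, breakdown


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def _normalize(sl: np.ndarray, window) -> np.ndarray:
    lo, hi = window
    clipped = np.clip(sl.astype(float), lo, hi)
    return 2.0 * (clipped - lo) / (hi - lo) - 1.0


def _denormalize(sl: np.ndarray, window) -> np.ndarray:
    lo, hi = window
    return (sl + 1.0) / 2.0 * (hi - lo) + lo


def _crop_free_air(sl: np.ndarray, work_size, air_threshold=-990.0) -> np.ndarray:
    """Centre a work_size window on the non-air content, clipped to bounds."""
    h, w = sl.shape
    th, tw = min(work_size[0], h), min(work_size[1], w)
    content = np.argwhere(sl > air_threshold)
    if content.size:
        cy, cx = content.mean(axis=0)
    else:
        cy, cx = (h - 1) / 2.0, (w - 1) / 2.0
    y0 = int(np.clip(round(cy - th / 2.0), 0, h - th))
    x0 = int(np.clip(round(cx - tw / 2.0), 0, w - tw))
    return sl[y0:y0 + th, x0:x0 + tw]


def preprocess_slice(sl: np.ndarray, cfg: TrainConfig,
                     rng: np.random.Generator | None = None) -> list[np.ndarray]:
    """Working-size crop, HU windowing to [-1, 1], random patch sampling.

    Returns ``cfg.crops_per_slice`` patches of ``cfg.patch_size`` square;
    deterministic when an explicitly seeded ``rng`` is supplied.
    """
    sl = np.asarray(sl, dtype=float)
    if sl.ndim != 2:
        raise ValueError("expected a 2D slice")
    if min(sl.shape) < cfg.patch_size:
        raise ValueError(f"slice {sl.shape} smaller than the "
                         f"{cfg.patch_size}-pixel crop size")
    rng = rng or np.random.default_rng(cfg.seed)
    work = _crop_free_air(sl, cfg.work_size)
    norm = _normalize(work, cfg.hu_window)
    h, w = norm.shape
    p = cfg.patch_size
    patches = []
    for _ in range(cfg.crops_per_slice):
        y0 = rng.integers(0, h - p + 1)
        x0 = rng.integers(0, w - p + 1)
        patches.append(norm[y0:y0 + p, x0:x0 + p].copy())
    return patches


def augmented_count(n_slices: int, cfg: TrainConfig) -> int:
    """Training samples after random-crop augmentation."""
    return int(n_slices) * cfg.crops_per_slice


# ---------------------------------------------------------------------------
# Model / Results
# ---------------------------------------------------------------------------

def _collect_state(gens_discs: dict) -> dict[str, np.ndarray]:
    state = {}
    for prefix, net in gens_discs.items():
        for i, p in enumerate(net.params()):
            state[f"{prefix}_{i}"] = p.data.copy()
    return state


def _load_state(gens_discs: dict, state: dict) -> None:
    for prefix, net in gens_discs.items():
        for i, p in enumerate(net.params()):
            key = f"{prefix}_{i}"
            if key not in state:
                raise ValueError(f"checkpoint missing parameter {key}")
            if state[key].shape != p.data.shape:
                raise ValueError(f"checkpoint/{key} shape mismatch: "
                                 f"{state[key].shape} vs {p.data.shape}")
            p.data = np.asarray(state[key], dtype=np.float32).copy()


class CycleGan:
    """Unpaired translation model built from CBCT and CT slice collections.

    Parameters
    ----------
    cbct_slices, ct_slices : sequences of 2D HU arrays
        Unpaired axial training slices from the two domains.
    """

    def __init__(self, cbct_slices, ct_slices,
                 gen_spec: GeneratorSpec = GeneratorSpec(),
                 disc_spec: DiscriminatorSpec = DiscriminatorSpec(),
                 weights: LossWeights = LossWeights(),
                 config: TrainConfig = TrainConfig()):
        if not len(cbct_slices) or not len(ct_slices):
            raise ValueError("both domains need at least one training slice")
        self.cbct_slices = [np.asarray(s, dtype=float) for s in cbct_slices]
        self.ct_slices = [np.asarray(s, dtype=float) for s in ct_slices]
        self.gen_spec, self.disc_spec = gen_spec, disc_spec
        self.weights, self.config = weights, config
        rng = np.random.default_rng(np.random.SeedSequence(config.seed))
        self.g_cbct2ct = Generator(gen_spec, rng)
        self.g_ct2cbct = Generator(gen_spec, rng)
        self.d_ct = Discriminator(disc_spec, rng)
        self.d_cbct = Discriminator(disc_spec, rng)

    @classmethod
    def from_manifest(cls, manifest, root=None, min_tissue_fraction=0.05, **kw):
        """Build the model from a generated-dataset manifest (dict or path)."""
        from . import io as sct_io

        if isinstance(manifest, (str, Path)):
            with open(manifest) as fh:
                mdict = json.load(fh)
            root = root or Path(manifest).parent
        else:
            mdict = manifest
            root = Path(root or mdict.get("root", "."))
        cbct, ct = [], []
        for sub in mdict["subjects"]:
            if sub["split"] != "train":
                continue
            ct_vol = sct_io.read_volume(Path(root) / sub["ct"])
            cbct_vol = sct_io.read_volume(Path(root) / sub["cbct"])
            for vol, dest in ((ct_vol, ct), (cbct_vol, cbct)):
                for sl in vol.data:
                    if (sl > -990).mean() >= min_tissue_fraction:
                        dest.append(sl)
        if not ct or not cbct:
            raise ValueError("manifest has no usable training slices")
        return cls(cbct, ct, **kw)

    def _nets(self) -> dict:
        return {"g_cbct2ct": self.g_cbct2ct, "g_ct2cbct": self.g_ct2cbct,
                "d_ct": self.d_ct, "d_cbct": self.d_cbct}

    def _epoch_patches(self, slices, epoch: int, stream: int) -> np.ndarray:
        cfg = self.config
        ss = np.random.SeedSequence(cfg.seed, spawn_key=(epoch, stream))
        rng = np.random.default_rng(ss)
        patches = []
        for sl in slices:
            patches.extend(preprocess_slice(sl, cfg, rng))
        arr = np.stack(patches)[:, None, :, :].astype(np.float32)  # (n,1,h,w)
        rng.shuffle(arr, axis=0)
        return arr

    def fit(self, verbose: bool = False, checkpoint_dir=None) -> "CycleGanResults":
        """Alternate discriminator/generator updates over unpaired patches.

        Deterministic given the config seed.  Raises ``RuntimeError`` with the
        failing epoch if any loss turns non-finite.
        """
        cfg, w = self.config, self.weights
        g_params = self.g_cbct2ct.params() + self.g_ct2cbct.params()
        d_params = self.d_ct.params() + self.d_cbct.params()
        opt_g = _make_opt(cfg.optimizer, g_params, cfg.lr)
        opt_d = _make_opt(cfg.optimizer, d_params,
                          cfg.lr if cfg.disc_lr is None else cfg.disc_lr)

        history = []
        for epoch in range(cfg.epochs):
            a_all = self._epoch_patches(self.cbct_slices, epoch, 0)
            b_all = self._epoch_patches(self.ct_slices, epoch, 1)
            n_batches = max(min(len(a_all), len(b_all)) // cfg.batch_size, 1)
            sums = {k: 0.0 for k in ("cycle", "adv", "grad", "idem", "tv",
                                     "d_loss", "total")}
            for it in range(n_batches):
                sl_ = slice(it * cfg.batch_size, (it + 1) * cfg.batch_size)
                a = Tensor(a_all[sl_])
                b = Tensor(b_all[sl_])

                # --- discriminators (fakes detached) ---
                fake_b = self.g_cbct2ct(a).detach()
                fake_a = self.g_ct2cbct(b).detach()
                d_loss = (loss_adv(self.d_ct(fake_b), self.d_ct(b),
                                   role="discriminator")
                          + loss_adv(self.d_cbct(fake_a), self.d_cbct(a),
                                     role="discriminator"))
                opt_d.zero_grad()
                d_loss.backward()
                opt_d.step()

                # --- generators ---
                fake_b = self.g_cbct2ct(a)
                rec_a = self.g_ct2cbct(fake_b)
                fake_a = self.g_ct2cbct(b)
                rec_b = self.g_cbct2ct(fake_a)
                terms = {
                    "cycle": loss_cycle(a, rec_a) + loss_cycle(b, rec_b),
                    "adv": (loss_adv(self.d_ct(fake_b), role="generator")
                            + loss_adv(self.d_cbct(fake_a), role="generator")),
                    "grad": loss_grad(a, fake_b) + loss_grad(b, fake_a),
                    "idem": (loss_idem(self.g_cbct2ct, b)
                             + loss_idem(self.g_ct2cbct, a)),
                    "tv": loss_tv(fake_b) + loss_tv(fake_a),
                }
                g_loss, _ = total_objective(terms, w)
                opt_g.zero_grad()
                g_loss.backward()
                opt_g.step()

                vals = {k: float(t.item()) for k, t in terms.items()}
                vals["d_loss"] = float(d_loss.item())
                vals["total"] = float(g_loss.item())
                if not all(np.isfinite(v) for v in vals.values()):
                    raise RuntimeError(
                        f"non-finite loss at epoch {epoch}, iteration {it}: {vals}"
                    )
                for k, v in vals.items():
                    sums[k] += v
            row = {"epoch": epoch}
            row.update({k: v / n_batches for k, v in sums.items()})
            history.append(row)
            if verbose:
                print(f"epoch {epoch:3d}  total {row['total']:.4f}  "
                      f"d {row['d_loss']:.4f}")
            if (checkpoint_dir and cfg.checkpoint_every
                    and (epoch + 1) % cfg.checkpoint_every == 0):
                self._save_checkpoint(Path(checkpoint_dir)
                                      / f"epoch_{epoch + 1:04d}.npz")
        return CycleGanResults(self, pd.DataFrame(history))

    # -- persistence --------------------------------------------------------

    def _config_blob(self) -> dict:
        return {
            "gen_spec": dataclasses.asdict(self.gen_spec),
            "disc_spec": dataclasses.asdict(self.disc_spec),
            "weights": dataclasses.asdict(self.weights),
            "config": dataclasses.asdict(self.config),
        }

    def _save_checkpoint(self, path, history: pd.DataFrame | None = None) -> None:
        from .io import config_hash

        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        blob = self._config_blob()
        extra = {"__config__": np.frombuffer(
            json.dumps({**blob, "config_hash": config_hash(blob)}).encode(),
            dtype=np.uint8)}
        np.savez(path, **_collect_state(self._nets()), **extra)
        if history is not None:
            history.to_csv(path.with_suffix(".csv"), index=False)


@dataclass
class CycleGanResults:
    """Fitted translation model: weights, training history, inference."""

    model: CycleGan
    history: pd.DataFrame

    # -- inference ----------------------------------------------------------

    def _generator(self, direction: str) -> Generator:
        if direction in ("cbct2ct", "cbct->ct"):
            return self.model.g_cbct2ct
        if direction in ("ct2cbct", "ct->cbct"):
            return self.model.g_ct2cbct
        raise ValueError(f"unknown translation direction {direction!r}; "
                         "expected 'cbct2ct' or 'ct2cbct'")

    def translate_slice(self, sl: np.ndarray, direction: str = "cbct2ct") -> np.ndarray:
        """Translate one full axial HU slice (fully convolutional inference)."""
        cfg = self.model.config
        g = self._generator(direction)
        norm = _normalize(np.asarray(sl, dtype=float), cfg.hu_window)
        h, w = norm.shape
        mult = 2 ** self.model.gen_spec.depth
        ph = (-h) % mult
        pw = (-w) % mult
        padded = np.pad(norm, [(0, ph), (0, pw)], mode="edge")
        out = g(Tensor(padded[None, None].astype(np.float32))
                ).data[0, 0, :h, :w].astype(float)
        lo, hi = cfg.hu_window
        return np.clip(_denormalize(out, cfg.hu_window), lo, hi)

    def translate_volume(self, vol: ImageVolume, direction: str = "cbct2ct") -> ImageVolume:
        """Slice-wise translation of a whole volume; metadata preserved.

        Output HU values are clipped to the training window.
        """
        out = np.stack([self.translate_slice(sl, direction) for sl in vol.data])
        return vol.with_data(out)

    # -- reporting ----------------------------------------------------------

    def summary(self) -> str:
        m = self.model
        last = self.history.iloc[-1] if len(self.history) else None
        lines = [
            "Cycle-consistent CBCT<->CT translation model",
            "=" * 52,
            f"generators          : base {m.gen_spec.base_filters} filters, "
            f"{m.gen_spec.n_res_blocks} residual blocks, depth {m.gen_spec.depth}",
            f"discriminators      : base {m.disc_spec.base_filters} filters, "
            f"receptive field {m.disc_spec.receptive_field()} px",
            f"loss weights        : {m.weights.as_dict()}",
            f"patch / window      : {m.config.patch_size} px, "
            f"HU {m.config.hu_window}",
            f"optimizer           : {m.config.optimizer} (lr={m.config.lr})",
            f"training slices     : {len(m.cbct_slices)} CBCT / "
            f"{len(m.ct_slices)} CT",
            f"epochs completed    : {len(self.history)}",
        ]
        if last is not None:
            lines.append(
                "final losses        : "
                + ", ".join(f"{k}={last[k]:.4f}"
                            for k in ("cycle", "adv", "grad", "idem", "tv",
                                      "d_loss")))
        return "\n".join(lines)

    def save(self, path) -> None:
        self.model._save_checkpoint(path, self.history)


def load_results(path) -> CycleGanResults:
    """Restore a :class:`CycleGanResults` from a saved checkpoint."""
    path = Path(path)
    with np.load(path) as npz:
        blob = json.loads(bytes(npz["__config__"]).decode())
        state = {k: npz[k] for k in npz.files if k != "__config__"}
    model = CycleGan(
        [np.zeros((8, 8))], [np.zeros((8, 8))],  # placeholder training data
        gen_spec=GeneratorSpec(**blob["gen_spec"]),
        disc_spec=DiscriminatorSpec(**blob["disc_spec"]),
        weights=LossWeights(**blob["weights"]),
        config=TrainConfig(
            **{k: tuple(v) if isinstance(v, list) else v
               for k, v in blob["config"].items()}),
    )
    _load_state(model._nets(), state)
    hist_path = path.with_suffix(".csv")
    history = pd.read_csv(hist_path) if hist_path.exists() else pd.DataFrame()
    return CycleGanResults(model, history)
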