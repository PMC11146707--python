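"""Build runnable MSDC / residual blocks and whole detection networks.

A block applies shared pre-activation (batchnorm then ReLU), runs each
dilated branch convolution in parallel, concatenates branch outputs on the
channel axis, and adds a shortcut (identity when shapes match, pointwise
projection otherwise).  A network is a contiguous-kernel stem convolution,
``n_blocks`` identical blocks (temporal halving at the scheduled indices),
a final batchnorm/ReLU, global average pooling over time, and a linear
head — so the same weights score any admissible input length.

``norm`` / ``activation`` / ``padding`` toggles exist for static analysis:
with normalization and activation disabled the block is linear in its
input, which lets perturbation probes recover the exact receptive field.
"""

from __future__ import annotations

import numpy as np

from . import nn
from .specs import BlockSpec, NetworkSpec, SpecError


class MSDCBlock(nn.Layer):
    """One multi-branch block: pre-activation, parallel dilated convs, concat, shortcut."""

    def __init__(
        self,
        spec: BlockSpec,
        in_channels: int,
        stride: int = 1,
        rng: np.random.Generator | None = None,
        norm: bool = True,
        activation: bool = True,
        padding: str = "same",
        dtype=np.float32,
    ):
        if in_channels < 1:
            raise SpecError("in_channels must be >= 1")
        rng = rng if rng is not None else np.random.default_rng()
        self.spec = spec
        self.in_channels = in_channels
        self.out_channels = spec.out_channels
        self.stride = stride
        self.padding = padding
        self.bn = nn.BatchNorm1d(in_channels, dtype=dtype) if norm else None
        self.act = nn.ReLU() if activation else None
        self.branches = [
            nn.Conv1d(
                in_channels,
                b.filters,
                b.kernel_size,
                stride=stride * b.stride,
                dilation=b.tap_stride,
                padding=padding,
                rng=rng,
                dtype=dtype,
            )
            for b in spec.branches
        ]
        self.skip = spec.skip
        needs_projection = self.skip and (
            self.out_channels != in_channels or stride != 1 or padding == "valid"
        )
        self.proj = (
            nn.Conv1d(in_channels, self.out_channels, 1, stride=stride,
                      padding="same" if padding == "same" else "valid",
                      rng=rng, dtype=dtype)
            if needs_projection
            else None
        )
        self._cache = None

    def parameters(self) -> list[nn.Param]:
        params = []
        if self.bn is not None:
            params += self.bn.parameters()
        for c in self.branches:
            params += c.parameters()
        if self.proj is not None:
            params += self.proj.parameters()
        return params

    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        h = x
        if self.bn is not None:
            h = self.bn.forward(h, training)
        if self.act is not None:
            h = self.act.forward(h, training)
        ys = [c.forward(h, training) for c in self.branches]
        lengths = [y.shape[2] for y in ys]
        L_out = min(lengths)
        ys = [y[:, :, :L_out] for y in ys]  # left-aligned trim ('valid' mode only)
        y = np.concatenate(ys, axis=1)
        sc_len = None
        if self.skip:
            if self.proj is not None:
                sc = self.proj.forward(x, training)
                sc_len = sc.shape[2]
                y = y + sc[:, :, :L_out]
            else:
                y = y + x[:, :, :L_out]
        if training:
            self._cache = (x.shape, lengths, L_out, sc_len)
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x_shape, lengths, L_out, sc_len = self._cache
        dx = np.zeros(x_shape, dtype=dy.dtype)
        if self.skip:
            if self.proj is not None:
                dsc = dy
                if sc_len != L_out:
                    dsc = np.zeros(dy.shape[:2] + (sc_len,), dtype=dy.dtype)
                    dsc[:, :, :L_out] = dy
                dx += self.proj.backward(dsc)
            else:
                dx[:, :, :L_out] += dy
        dh = None
        ofs = 0
        for conv, L_b in zip(self.branches, lengths):
            f = conv.out_channels
            dyb = dy[:, ofs : ofs + f]
            if L_b != L_out:
                padded = np.zeros((dy.shape[0], f, L_b), dtype=dy.dtype)
                padded[:, :, :L_out] = dyb
                dyb = padded
            g = conv.backward(dyb)
            dh = g if dh is None else dh + g
            ofs += f
        if self.act is not None:
            dh = self.act.backward(dh)
        if self.bn is not None:
            dh = self.bn.backward(dh)
        self._cache = None
        return dx + dh


def build_block(
    block: BlockSpec,
    in_channels: int,
    stride: int = 1,
    seed: int | None = None,
    rng: np.random.Generator | None = None,
    norm: bool = True,
    activation: bool = True,
    padding: str = "same",
    dtype=np.float32,
) -> MSDCBlock:
    """Construct one runnable block from its declarative spec."""
    if rng is None:
        rng = np.random.default_rng(seed)
    return MSDCBlock(
        block, in_channels, stride=stride, rng=rng,
        norm=norm, activation=activation, padding=padding, dtype=dtype,
    )


class Network:
    """Stem conv -> stacked blocks -> batchnorm/ReLU -> global pooling -> linear head."""

    def __init__(self, spec: NetworkSpec, seed: int = 0, dtype=np.float32):
        rng = np.random.default_rng(seed)
        self.spec = spec
        self.seed = seed
        self.stem = nn.Conv1d(1, spec.stem_filters, spec.stem_kernel,
                              stride=spec.stem_stride, rng=rng, dtype=dtype)
        schedule = set(spec.downsample_schedule)
        self.blocks: list[MSDCBlock] = []
        ch = spec.stem_filters
        for i in range(spec.n_blocks):
            blk = MSDCBlock(
                spec.block, ch, stride=2 if i in schedule else 1, rng=rng, dtype=dtype
            )
            self.blocks.append(blk)
            ch = blk.out_channels
        self.head_bn = nn.BatchNorm1d(ch, dtype=dtype)
        self.head_act = nn.ReLU()
        self.pool = nn.GlobalAvgPool()
        self.fc = nn.Linear(ch, spec.n_classes, rng=rng, dtype=dtype)

    # -- forward / backward ------------------------------------------------
    def forward(self, x: np.ndarray, training: bool = True) -> np.ndarray:
        """(batch, 1, length) -> (batch, n_classes) raw scores."""
        h = self.stem.forward(x, training)
        for blk in self.blocks:
            h = blk.forward(h, training)
        h = self.head_bn.forward(h, training)
        h = self.head_act.forward(h, training)
        h = self.pool.forward(h, training)
        return self.fc.forward(h, training)

    def backward(self, dlogits: np.ndarray) -> None:
        g = self.fc.backward(dlogits)
        g = self.pool.backward(g)
        g = self.head_act.backward(g)
        g = self.head_bn.backward(g)
        for blk in reversed(self.blocks):
            g = blk.backward(g)
        self.stem.backward(g)

    def predict(self, x: np.ndarray) -> np.ndarray:
        """Argmax class indices in inference mode (running batchnorm stats)."""
        return np.argmax(self.forward(x, training=False), axis=1)

    # -- introspection -----------------------------------------------------
    def _layers(self) -> list[nn.Layer]:
        out: list[nn.Layer] = [self.stem]
        out.extend(self.blocks)
        out.extend([self.head_bn, self.fc])
        return out

    def parameters(self) -> list[nn.Param]:
        params: list[nn.Param] = []
        for layer in self._layers():
            params += layer.parameters()
        return params

    def parameter_count(self) -> int:
        return nn.parameter_count(self.parameters())

    def _batchnorms(self) -> list[nn.BatchNorm1d]:
        bns = [b.bn for b in self.blocks if b.bn is not None]
        return bns + [self.head_bn]

    # -- checkpoints -------------------------------------------------------
    def save(self, path) -> None:
        """Single-file checkpoint: weights plus the network spec as embedded JSON."""
        arrays = {f"p{i}": p.value for i, p in enumerate(self.parameters())}
        for i, bn in enumerate(self._batchnorms()):
            arrays[f"rm{i}"] = bn.running_mean
            arrays[f"rv{i}"] = bn.running_var
        arrays["spec_json"] = np.frombuffer(self.spec.as_json().encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "Network":
        with np.load(path) as data:
            spec = NetworkSpec.from_json(bytes(data["spec_json"]).decode())
            net = cls(spec)
            for i, p in enumerate(net.parameters()):
                p.value = data[f"p{i}"].copy()
                p.grad = np.zeros_like(p.value)
            for i, bn in enumerate(net._batchnorms()):
                bn.running_mean = data[f"rm{i}"].copy()
                bn.running_var = data[f"rv{i}"].copy()
        return net

    def state_copy(self) -> dict:
        state = {f"p{i}": p.value.copy() for i, p in enumerate(self.parameters())}
        for i, bn in enumerate(self._batchnorms()):
            state[f"rm{i}"] = bn.running_mean.copy()
            state[f"rv{i}"] = bn.running_var.copy()
        return state

    def load_state(self, state: dict) -> None:
        for i, p in enumerate(self.parameters()):
            p.value[...] = state[f"p{i}"]
        for i, bn in enumerate(self._batchnorms()):
            bn.running_mean[...] = state[f"rm{i}"]
            bn.running_var[...] = state[f"rv{i}"]


def build_network(spec: NetworkSpec, seed: int = 0, dtype=np.float32) -> Network:
    """Construct a seeded, runnable detection network from its spec."""
    return Network(spec, seed=seed, dtype=dtype)


def full_param_count_of_blocks(net: Network) -> int:
    """Analyzer-side full-convention conv parameter count summed over blocks.

    Counts ``in_channels * k * f + f`` per branch for every block in the
    network, which must equal the engine's own enumeration of the branch
    conv parameters (the parity is asserted in the test suite).
    """
    from .specs import block_param_count

    total = 0
    for blk in net.blocks:
        total += block_param_count(blk.spec, "full", in_channels=blk.in_channels)
    return total
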