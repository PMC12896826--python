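"""Neural-network layers, loss and optimizer built on the autodiff core."""

from __future__ import annotations

import numpy as np

from .autodiff import Tensor, im2col1d

__all__ = [
    "Module",
    "Linear",
    "Conv1d",
    "BatchNorm1d",
    "Adam",
    "softmax",
    "softmax_cross_entropy",
]


class Module:
    """Tiny parameter container: named Tensors plus named submodules."""

    def __init__(self):
        self._params: dict[str, Tensor] = {}
        self._modules: dict[str, Module] = {}
        self.training = True

    def __setattr__(self, name, value):
        if isinstance(value, Tensor) and value.requires_grad:
            self.__dict__.setdefault("_params", {})[name] = value
        elif isinstance(value, Module):
            self.__dict__.setdefault("_modules", {})[name] = value
        object.__setattr__(self, name, value)

    def named_parameters(self, prefix: str = ""):
        for k, p in self._params.items():
            yield prefix + k, p
        for k, m in self._modules.items():
            yield from m.named_parameters(prefix + k + ".")

    def parameters(self):
        for _, p in self.named_parameters():
            yield p

    def zero_grad(self):
        for p in self.parameters():
            p.zero_grad()

    def train(self, mode: bool = True):
        self.training = mode
        for m in self._modules.values():
            m.train(mode)
        return self

    def eval(self):
        return self.train(False)

    def state_dict(self, prefix: str = "") -> dict[str, np.ndarray]:
        out = {prefix + k: p.data.copy() for k, p in self._params.items()}
        out.update({prefix + k: v.copy() for k, v in self._buffers().items()})
        for k, m in self._modules.items():
            out.update(m.state_dict(prefix + k + "."))
        return out

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = dict(self.named_parameters())
        for k, v in state.items():
            if k in params:
                params[k].data = np.array(v, dtype=params[k].data.dtype)
            else:
                mod, attr = self._locate_buffer(k)
                old = getattr(mod, attr)
                setattr(mod, attr, np.array(v, dtype=old.dtype))

    def _buffers(self) -> dict[str, np.ndarray]:
        return {}

    def _locate_buffer(self, dotted: str):
        mod = self
        parts = dotted.split(".")
        for p in parts[:-1]:
            mod = mod._modules[p]
        if parts[-1] not in mod._buffers():
            raise KeyError(f"unknown state entry {dotted!r}")
        return mod, parts[-1]


def _fan_in_uniform(rng: np.random.Generator, shape, fan_in: int,
                    dtype=np.float64) -> Tensor:
    bound = 1.0 / np.sqrt(max(1, fan_in))
    w = rng.uniform(-bound, bound, size=shape).astype(dtype)
    return Tensor(w, requires_grad=True)


class Linear(Module):
    def __init__(self, in_features: int, out_features: int,
                 rng: np.random.Generator, bias: bool = True,
                 dtype=np.float64):
        super().__init__()
        self.in_features, self.out_features = in_features, out_features
        self.weight = _fan_in_uniform(rng, (out_features, in_features), in_features, dtype)
        self.bias = _fan_in_uniform(rng, (out_features,), in_features, dtype) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight.transpose()
        return y + self.bias if self.bias is not None else y


class Conv1d(Module):
    """1-D convolution, stride 1, zero 'same' padding (length-preserving)."""

    def __init__(self, in_channels: int, out_channels: int, kernel: int,
                 rng: np.random.Generator, bias: bool = True,
                 dtype=np.float64):
        super().__init__()
        self.in_channels, self.out_channels, self.kernel = in_channels, out_channels, kernel
        fan_in = in_channels * kernel
        self.weight = _fan_in_uniform(rng, (out_channels, in_channels, kernel), fan_in, dtype)
        self.bias = _fan_in_uniform(rng, (out_channels,), fan_in, dtype) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        out_c = self.weight.shape[0]
        cols = im2col1d(x, self.kernel)                      # (N, L, C*k)
        w = self.weight.reshape(out_c, -1).transpose()       # (C*k, out)
        y = cols @ w                                         # (N, L, out)
        if self.bias is not None:
            y = y + self.bias
        return y.transpose(0, 2, 1)                          # (N, out, L)


class BatchNorm1d(Module):
    """Batch normalization over (N, C, L) or (N, C) activations."""

    def __init__(self, channels: int, momentum: float = 0.1, eps: float = 1e-5,
                 dtype=np.float64):
        super().__init__()
        self.channels, self.momentum, self.eps = channels, momentum, eps
        self.gamma = Tensor(np.ones(channels, dtype=dtype), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, dtype=dtype), requires_grad=True)
        self.running_mean = np.zeros(channels, dtype=dtype)
        self.running_var = np.ones(channels, dtype=dtype)

    def _buffers(self):
        return {"running_mean": self.running_mean, "running_var": self.running_var}

    def __call__(self, x: Tensor) -> Tensor:
        spatial = x.ndim == 3
        axes = (0, 2) if spatial else (0,)
        shape = (1, self.channels, 1) if spatial else (1, self.channels)
        gamma, beta = self.gamma, self.beta
        if not self.training:
            # inference: a plain affine map using the running statistics
            w = (gamma.data / np.sqrt(self.running_var + self.eps)).reshape(shape)
            b = (beta.data - self.running_mean * w.reshape(-1)).reshape(shape)
            return x * Tensor(w) + Tensor(b)

        m = x.data.mean(axis=axes, keepdims=True)
        v = x.data.var(axis=axes, keepdims=True)
        mom = self.momentum
        self.running_mean = (1 - mom) * self.running_mean + mom * m.reshape(-1)
        self.running_var = (1 - mom) * self.running_var + mom * v.reshape(-1)
        inv = 1.0 / np.sqrt(v + self.eps)
        xhat = (x.data - m) * inv
        out = xhat * gamma.data.reshape(shape) + beta.data.reshape(shape)
        n = x.data.size // self.channels

        def bw(g):
            beta._accum(g.sum(axis=axes))
            gamma._accum((g * xhat).sum(axis=axes))
            if x.requires_grad:
                gs = g * gamma.data.reshape(shape)
                gm = gs.mean(axis=axes, keepdims=True)
                gx = (gs * xhat).mean(axis=axes, keepdims=True)
                x._accum(inv * (gs - gm - xhat * gx))

        return Tensor._from_op(out, (x, gamma, beta), bw)


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, labels: np.ndarray) -> Tensor:
    """Mean cross-entropy with a fused softmax gradient."""
    labels = np.asarray(labels, dtype=int)
    p = softmax(logits.data)
    n = labels.shape[0]
    nll = -np.log(np.maximum(p[np.arange(n), labels], 1e-30)).mean()

    def bw(g):
        grad = p.copy()
        grad[np.arange(n), labels] -= 1.0
        logits._accum(g * grad / n)

    return Tensor._from_op(np.array(nll), (logits,), bw)


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.betas, self.eps = lr, betas, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.zero_grad()

    def step(self):
        self.t += 1
        b1, b2 = self.betas
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
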