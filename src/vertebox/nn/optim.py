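"""AdamW optimizer (decoupled weight decay)."""

from __future__ import annotations

import numpy as np

from .tensor import Parameter

__all__ = ["AdamW"]


class AdamW:
    """Adam with decoupled weight decay.

    Update per parameter p with gradient g:
        m <- b1*m + (1-b1)*g         v <- b2*v + (1-b2)*g^2
        p <- p - lr*( m_hat / (sqrt(v_hat)+eps) + weight_decay*p )
    """

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.01):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.betas
        c1 = 1 - b1 ** self.t
        c2 = 1 - b2 ** self.t
        for p, m, v in zip(self.params, self.m, self.v):
            if p.grad is None:
                continue
            g = p.grad
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            denom = np.sqrt(v / c2) + self.eps
            p.data -= self.lr * ((m / c1) / denom + self.weight_decay * p.data)

    # -- checkpointing ---------------------------------------------------------

    def state_dict(self) -> dict:
        state = {"t": np.asarray(self.t)}
        for i, (m, v) in enumerate(zip(self.m, self.v)):
            state[f"m{i}"] = m.copy()
            state[f"v{i}"] = v.copy()
        return state

    def load_state_dict(self, state: dict) -> None:
        self.t = int(state["t"])
        self.m = [np.array(state[f"m{i}"]) for i in range(len(self.params))]
        self.v = [np.array(state[f"v{i}"]) for i in range(len(self.params))]
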