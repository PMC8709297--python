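"""Dense and LSTM layers on top of the autodiff engine."""

from __future__ import annotations

import numpy as np

from .autodiff import Parameter, Tensor


class Dense:
    """Affine layer y = x W + b with Glorot-uniform init."""

    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        limit = np.sqrt(6.0 / (n_in + n_out))
        self.W = Parameter(rng.uniform(-limit, limit, size=(n_in, n_out)))
        self.b = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]


class LSTMCell:
    """Standard LSTM cell; gate order [input, forget, cell, output].

    Forget-gate bias initialized to 1 so early training does not erase
    state — the usual stabilization for short corpora.
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_hidden = n_hidden
        limit = np.sqrt(6.0 / (n_in + 4 * n_hidden))
        self.Wx = Parameter(rng.uniform(-limit, limit, size=(n_in, 4 * n_hidden)))
        limit = np.sqrt(6.0 / (n_hidden + 4 * n_hidden))
        self.Wh = Parameter(rng.uniform(-limit, limit, size=(n_hidden, 4 * n_hidden)))
        b = np.zeros(4 * n_hidden)
        b[n_hidden : 2 * n_hidden] = 1.0
        self.b = Parameter(b)

    def step(self, x: Tensor, h: Tensor, c: Tensor) -> tuple[Tensor, Tensor]:
        H = self.n_hidden
        gates = x @ self.Wx + h @ self.Wh + self.b
        i = gates[:, 0:H].sigmoid()
        f = gates[:, H : 2 * H].sigmoid()
        g = gates[:, 2 * H : 3 * H].tanh()
        o = gates[:, 3 * H : 4 * H].sigmoid()
        c_new = f * c + i * g
        h_new = o * c_new.tanh()
        return h_new, c_new

    def parameters(self) -> list[Parameter]:
        return [self.Wx, self.Wh, self.b]


class LSTMStack:
    """Sequentially stacked LSTM cells run over a (T x B x D) input sequence."""

    def __init__(self, n_in: int, n_hidden: int, n_cells: int, rng: np.random.Generator):
        self.cells = [
            LSTMCell(n_in if k == 0 else n_hidden, n_hidden, rng)
            for k in range(n_cells)
        ]
        self.n_hidden = n_hidden

    def init_states(self, batch: int) -> list[tuple[Tensor, Tensor]]:
        zeros = lambda: Tensor(np.zeros((batch, self.n_hidden)))
        return [(zeros(), zeros()) for _ in self.cells]

    def step(
        self, x: Tensor, states: list[tuple[Tensor, Tensor]]
    ) -> tuple[Tensor, list[tuple[Tensor, Tensor]]]:
        """One time step through the whole stack; returns the top hidden
        state and the updated per-cell states."""
        new_states: list[tuple[Tensor, Tensor]] = []
        inp = x
        for cell, (h, c) in zip(self.cells, states):
            h, c = cell.step(inp, h, c)
            new_states.append((h, c))
            inp = h
        return inp, new_states

    def run(self, xs: list[Tensor], batch: int) -> list[Tensor]:
        """Run over a list of T tensors of shape (B x D); returns the top
        cell's hidden state at every time step."""
        states = self.init_states(batch)
        outputs: list[Tensor] = []
        for x in xs:
            out, states = self.step(x, states)
            outputs.append(out)
        return outputs

    def step_numpy(
        self, x: np.ndarray, states: list[tuple[np.ndarray, np.ndarray]]
    ) -> tuple[np.ndarray, list[tuple[np.ndarray, np.ndarray]]]:
        """Gradient-free forward step on raw arrays (inference-time)."""
        new_states = []
        inp = x
        for cell, (h, c) in zip(self.cells, states):
            H = cell.n_hidden
            gates = inp @ cell.Wx.data + h @ cell.Wh.data + cell.b.data
            i = 1.0 / (1.0 + np.exp(-gates[:, 0:H]))
            f = 1.0 / (1.0 + np.exp(-gates[:, H : 2 * H]))
            g = np.tanh(gates[:, 2 * H : 3 * H])
            o = 1.0 / (1.0 + np.exp(-gates[:, 3 * H : 4 * H]))
            c = f * c + i * g
            h = o * np.tanh(c)
            new_states.append((h, c))
            inp = h
        return inp, new_states

    def parameters(self) -> list[Parameter]:
        return [p for cell in self.cells for p in cell.parameters()]
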