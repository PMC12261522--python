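"""Minimal dense-network machinery for the Wasserstein GAN.

Implements exactly what the surrogate needs and nothing more: fully
connected ReLU networks with a linear output layer, reverse-mode
gradients, the input-gradient of a scalar-output network, the
parameter-gradient of the WGAN gradient penalty, and Adam.

The gradient-penalty term needs a second-order derivative (the penalty
depends on the critic's input gradient).  For ReLU networks this
"double backprop" has a closed form: with the ReLU activation masks
held fixed — exact almost everywhere, since ReLU is piecewise linear —
the input gradient g_i of sample i is a product of masked weight
matrices, so d(penalty)/dW is obtained from one extra masked forward
pass with the penalty's gradient w.r.t. g as input.  See
:meth:`DenseNet.gradient_penalty_grads`.
"""

from __future__ import annotations

import numpy as np

__all__ = ["DenseNet", "Adam"]


class DenseNet:
    """Fully connected network, ReLU hidden layers, linear output.

    Parameters are a list of ``(W, b)`` pairs with ``W`` of shape
    (n_out, n_in).  All math is float32 unless the parameters say
    otherwise.
    """

    def __init__(self, sizes, rng=None, dtype=np.float32):
        self.sizes = list(sizes)
        self.dtype = dtype
        self.params = []
        if rng is not None:
            for n_in, n_out in zip(sizes[:-1], sizes[1:]):
                # He initialization for ReLU nets
                w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_out, n_in)).astype(dtype)
                b = np.zeros(n_out, dtype=dtype)
                self.params.append((w, b))

    @property
    def n_layers(self) -> int:
        return len(self.params)

    def forward(self, x, return_cache=False):
        """Forward pass.  ``x`` is (n, d_in); returns (n, d_out)."""
        x = np.asarray(x, dtype=self.dtype)
        h = x
        pre = []  # pre-activations per layer
        acts = [x]  # inputs to each layer
        L = self.n_layers
        for l, (w, b) in enumerate(self.params):
            a = h @ w.T + b
            pre.append(a)
            h = np.maximum(a, 0.0) if l < L - 1 else a
            if l < L - 1:
                acts.append(h)
        if return_cache:
            return h, (acts, pre)
        return h

    def backward(self, cache, grad_out):
        """Gradients of sum(grad_out * output) w.r.t. params and input.

        Returns ``(param_grads, grad_input)`` with param_grads a list of
        (dW, db) matching :attr:`params`.
        """
        acts, pre = cache
        L = self.n_layers
        g = np.asarray(grad_out, dtype=self.dtype)
        param_grads = [None] * L
        for l in range(L - 1, -1, -1):
            w, _ = self.params[l]
            if l < L - 1:
                g = g * (pre[l] > 0)
            dw = g.T @ acts[l]
            db = g.sum(axis=0)
            param_grads[l] = (dw, db)
            g = g @ w
        return param_grads, g

    def input_gradient(self, cache):
        """Per-sample gradient of a scalar output w.r.t. the input.

        Only valid for networks with a single output unit.  Returns the
        (n, d_in) gradient matrix and the list of backward signals s_l
        (reused by :meth:`gradient_penalty_grads`).
        """
        acts, pre = cache
        n = pre[-1].shape[0]
        L = self.n_layers
        s_list = [None] * L
        g = np.ones((n, 1), dtype=self.dtype)
        for l in range(L - 1, -1, -1):
            w, _ = self.params[l]
            if l < L - 1:
                g = g * (pre[l] > 0)
            s_list[l] = g
            g = g @ w
        return g, s_list

    def gradient_penalty_grads(self, cache, s_list, r):
        """Parameter gradients of a scalar that is linear in the input gradient.

        Given ``r`` (n, d_in) = d(scalar)/d(input-gradient), computes
        d(scalar)/dW_l for every layer with the ReLU masks frozen.  The
        per-sample input gradient is g_i^T = W_1^T D_1 ... W_L^T with
        D_l the ReLU masks, so sum_i r_i . g_i re-traverses the same
        masked linear chain forward:  t_0 = r,
        t_l = (t_{l-1} W_l^T) * D_l, and d/dW_l = s_l^T t_{l-1} with the
        s_l already produced by :meth:`input_gradient`.  Bias gradients
        are zero (the input gradient does not depend on biases given the
        masks).
        """
        acts, pre = cache
        L = self.n_layers
        t = np.asarray(r, dtype=self.dtype)
        grads = [None] * L
        for l in range(L):
            w, b = self.params[l]
            grads[l] = (s_list[l].T @ t, np.zeros_like(b))
            if l < L - 1:
                t = (t @ w.T) * (pre[l] > 0)
        return grads

    def copy_params(self):
        return [(w.copy(), b.copy()) for w, b in self.params]

    def set_params(self, params):
        self.params = [(np.asarray(w, dtype=self.dtype), np.asarray(b, dtype=self.dtype)) for w, b in params]


class Adam:
    """Adam optimizer over a DenseNet's parameter list."""

    def __init__(self, net: DenseNet, lr=5e-5, beta1=0.5, beta2=0.9, eps=1e-8):
        self.net = net
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = [(np.zeros_like(w), np.zeros_like(b)) for w, b in net.params]
        self.v = [(np.zeros_like(w), np.zeros_like(b)) for w, b in net.params]

    def step(self, grads):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1**self.t
        bc2 = 1.0 - b2**self.t
        new_params = []
        for (w, b), (gw, gb), (mw, mb), (vw, vb) in zip(self.net.params, grads, self.m, self.v):
            mw *= b1
            mw += (1 - b1) * gw
            mb *= b1
            mb += (1 - b1) * gb
            vw *= b2
            vw += (1 - b2) * gw * gw
            vb *= b2
            vb += (1 - b2) * gb * gb
            w = w - self.lr * (mw / bc1) / (np.sqrt(vw / bc2) + self.eps)
            b = b - self.lr * (mb / bc1) / (np.sqrt(vb / bc2) + self.eps)
            new_params.append((w, b))
        self.net.params = new_params
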