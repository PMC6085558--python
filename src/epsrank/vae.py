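"""A variational autoencoder for expression features, in pure NumPy.

Encoder and decoder are symmetric ReLU multilayer perceptrons.  The
encoder ends in two linear heads producing the posterior mean mu and,
through a softplus, the posterior scale sigma of a diagonal Gaussian
q(z|x) = N(mu, diag(sigma^2)).  Reconstruction uses a Gaussian likelihood
(mean squared error) on the transformed features, and training minimizes

    (1/n) * [ 0.5 * ||x_hat - x||^2  +  kl_weight * KL(q(z|x) || N(0, I)) ]

by reparameterized gradients (z = mu + sigma * eps) with the Adam
optimizer.  Gradients are derived and implemented by hand; a
finite-difference check in the test suite guards the implementation.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np

PAPER_WIDTHS = (30_000, 15_000, 10_000, 2_000, 500, 2_000, 10_000, 15_000, 30_000)
DESK_HIDDEN = (256, 64, 16, 64, 256)


@dataclass
class VAEArchitecture:
    """Symmetric layer widths, input ... bottleneck ... output.

    The middle width is the latent dimension.  The ``paper`` preset is the
    9-layer, 30,000-unit-input architecture; the ``desk`` preset is
    (input, 256, 64, 16, 64, 256, input) and is the default at
    interactive scale.
    """

    layer_widths: tuple[int, ...]
    activation: str = "relu"
    preset: str = "custom"

    def __post_init__(self) -> None:
        w = tuple(int(x) for x in self.layer_widths)
        if len(w) < 3 or len(w) % 2 == 0:
            raise ValueError("layer widths must be an odd-length list of >= 3")
        if any(x < 1 for x in w):
            raise ValueError("layer widths must be positive")
        if w != w[::-1]:
            raise ValueError("layer widths must be symmetric about the bottleneck")
        if self.activation != "relu":
            raise ValueError("only relu hidden activation is supported")
        self.layer_widths = w

    @property
    def n_layers(self) -> int:
        return len(self.layer_widths)

    @property
    def latent_dim(self) -> int:
        return self.layer_widths[len(self.layer_widths) // 2]

    @property
    def input_dim(self) -> int:
        return self.layer_widths[0]

    @classmethod
    def paper(cls) -> "VAEArchitecture":
        return cls(PAPER_WIDTHS, preset="paper")

    @classmethod
    def desk(cls, input_dim: int) -> "VAEArchitecture":
        return cls((input_dim, *DESK_HIDDEN, input_dim), preset="desk")


@dataclass
class LatentRepresentation:
    """Posterior parameters and one sampled point per sample."""

    sample_ids: list[str]
    mu: np.ndarray  # (n, latent_dim)
    sigma: np.ndarray
    z: np.ndarray
    labels: np.ndarray  # 1 = case, 0 = control

    def __post_init__(self) -> None:
        if not (self.mu.shape == self.sigma.shape == self.z.shape):
            raise ValueError("mu, sigma, z must share a shape")
        if np.any(self.sigma <= 0):
            raise ValueError("sigma must be strictly positive")


def reparameterize(mu: np.ndarray, sigma: np.ndarray, eps: np.ndarray) -> np.ndarray:
    """z = mu + sigma * eps; collapses to mu as sigma -> 0."""
    return mu + sigma * eps


def kl_standard_normal(mu: np.ndarray, sigma: np.ndarray) -> float:
    """KL(N(mu, diag(sigma^2)) || N(0, I)), summed over dimensions,
    averaged over samples."""
    per = 0.5 * (mu**2 + sigma**2 - 1.0 - 2.0 * np.log(sigma))
    return float(per.sum(axis=-1).mean())


SIGMA_FLOOR = 1e-8  # keeps log sigma finite when softplus underflows


def _softplus(x: np.ndarray) -> np.ndarray:
    return np.logaddexp(0.0, x)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


class VAE:
    """Weights plus forward/backward passes; see the module docstring."""

    def __init__(self, arch: VAEArchitecture, seed: int = 0, dtype=np.float32):
        self.arch = arch
        self.dtype = dtype
        self.feature_names: list[str] | None = None
        mid = arch.n_layers // 2
        widths = arch.layer_widths
        rng = np.random.default_rng(seed)

        def init(n_in: int, n_out: int) -> tuple[np.ndarray, np.ndarray]:
            w = rng.normal(0.0, np.sqrt(2.0 / n_in), size=(n_in, n_out)).astype(dtype)
            return w, np.zeros(n_out, dtype=dtype)

        # encoder trunk: input -> last hidden before the bottleneck
        self.enc = [init(widths[i], widths[i + 1]) for i in range(mid - 1)]
        self.w_mu = init(widths[mid - 1], widths[mid])
        self.w_sigma = init(widths[mid - 1], widths[mid])
        # decoder: bottleneck -> output (last layer linear)
        self.dec = [init(widths[i], widths[i + 1]) for i in range(mid, arch.n_layers - 1)]

    # --- parameter bookkeeping -------------------------------------------
    def parameters(self) -> list[np.ndarray]:
        params: list[np.ndarray] = []
        for w, b in [*self.enc, self.w_mu, self.w_sigma, *self.dec]:
            params.extend((w, b))
        return params

    # --- forward passes ---------------------------------------------------
    def encode(self, X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        h = np.asarray(X, dtype=self.dtype)
        for w, b in self.enc:
            h = np.maximum(h @ w + b, 0.0)
        mu = h @ self.w_mu[0] + self.w_mu[1]
        sigma = _softplus(h @ self.w_sigma[0] + self.w_sigma[1]) + SIGMA_FLOOR
        return mu.astype(float), sigma.astype(float)

    def decode(self, Z: np.ndarray) -> np.ndarray:
        h = np.asarray(Z, dtype=self.dtype)
        for i, (w, b) in enumerate(self.dec):
            h = h @ w + b
            if i < len(self.dec) - 1:
                h = np.maximum(h, 0.0)
        return h.astype(float)

    # --- loss and gradients ----------------------------------------------
    def loss_and_grads(
        self, X: np.ndarray, eps: np.ndarray, kl_weight: float
    ) -> tuple[float, float, list[np.ndarray]]:
        """Return (reconstruction loss, KL, gradients aligned with
        :meth:`parameters`), all averaged per sample."""
        X = np.asarray(X, dtype=self.dtype)
        n = X.shape[0]

        # encoder forward, caching pre-activations
        h = X
        enc_acts = [h]
        for w, b in self.enc:
            h = np.maximum(h @ w + b, 0.0)
            enc_acts.append(h)
        s_pre = h @ self.w_sigma[0] + self.w_sigma[1]
        mu = h @ self.w_mu[0] + self.w_mu[1]
        sigma = _softplus(s_pre) + SIGMA_FLOOR
        z = mu + sigma * eps.astype(self.dtype)

        # decoder forward
        g = z
        dec_acts = [g]
        for i, (w, b) in enumerate(self.dec):
            g = g @ w + b
            if i < len(self.dec) - 1:
                g = np.maximum(g, 0.0)
            dec_acts.append(g)
        x_hat = g

        diff = x_hat - X
        recon = float(0.5 * np.sum(diff.astype(np.float64) ** 2) / n)
        kl = kl_standard_normal(mu.astype(np.float64), sigma.astype(np.float64))
        if not (np.isfinite(recon) and np.isfinite(kl)):
            raise FloatingPointError(
                f"non-finite VAE loss (recon={recon}, kl={kl}); "
                "reduce the learning rate or check the input scaling"
            )

        # backward through the decoder
        grads_dec: list[tuple[np.ndarray, np.ndarray]] = [None] * len(self.dec)  # type: ignore
        delta = diff / n
        for i in range(len(self.dec) - 1, -1, -1):
            w, _ = self.dec[i]
            a_in = dec_acts[i]
            grads_dec[i] = (a_in.T @ delta, delta.sum(axis=0))
            delta = delta @ w.T
            if i > 0:
                delta = delta * (dec_acts[i] > 0)
        dz = delta

        # backward into the two heads
        kw = kl_weight / n
        dmu = dz + kw * mu
        dsigma = dz * eps.astype(self.dtype) + kw * (sigma - 1.0 / sigma)
        ds_pre = dsigma * _sigmoid(s_pre)
        h_last = enc_acts[-1]
        g_mu = (h_last.T @ dmu, dmu.sum(axis=0))
        g_sigma = (h_last.T @ ds_pre, ds_pre.sum(axis=0))

        # backward through the encoder trunk
        delta = dmu @ self.w_mu[0].T + ds_pre @ self.w_sigma[0].T
        grads_enc: list[tuple[np.ndarray, np.ndarray]] = [None] * len(self.enc)  # type: ignore
        for i in range(len(self.enc) - 1, -1, -1):
            delta = delta * (enc_acts[i + 1] > 0)
            grads_enc[i] = (enc_acts[i].T @ delta, delta.sum(axis=0))
            delta = delta @ self.enc[i][0].T

        flat: list[np.ndarray] = []
        for w, b in [*grads_enc, g_mu, g_sigma, *grads_dec]:
            flat.extend((w, b))
        return recon, kl, flat

    # --- persistence ------------------------------------------------------
    def save(self, path) -> None:
        arrays = {f"p{i}": p for i, p in enumerate(self.parameters())}
        header = {
            "layer_widths": list(self.arch.layer_widths),
            "preset": self.arch.preset,
            "feature_names": self.feature_names,
        }
        np.savez(path, __header__=json.dumps(header), **arrays)

    @classmethod
    def load(cls, path) -> "VAE":
        data = np.load(path, allow_pickle=False)
        header = json.loads(str(data["__header__"]))
        arch = VAEArchitecture(tuple(header["layer_widths"]), preset=header["preset"])
        model = cls(arch, seed=0)
        for i, p in enumerate(model.parameters()):
            p[...] = data[f"p{i}"]
        model.feature_names = header["feature_names"]
        return model


@dataclass
class TrainingHistory:
    reconstruction: list[float] = field(default_factory=list)
    kl: list[float] = field(default_factory=list)

    def to_tsv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("epoch\treconstruction\tkl\n")
            for e, (r, k) in enumerate(zip(self.reconstruction, self.kl), start=1):
                fh.write(f"{e}\t{r:.8g}\t{k:.8g}\n")


class _Adam:
    def __init__(self, params: list[np.ndarray], lr: float):
        self.params = params
        self.lr = lr
        self.m = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.v = [np.zeros_like(p, dtype=np.float64) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1, b2, eps = 0.9, 0.999, 1e-8
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            g = g.astype(np.float64)
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            p -= (self.lr * (m / corr1) / (np.sqrt(v / corr2) + eps)).astype(p.dtype)


def train_vae(
    X: np.ndarray,
    arch: VAEArchitecture,
    epochs: int = 200,
    kl_weight: float = 1.0,
    seed: int = 0,
    batch_size: int = 64,
    learning_rate: float = 1e-3,
    feature_names: list[str] | None = None,
) -> tuple[VAE, TrainingHistory]:
    """Train on a samples x features block; returns the model and the
    per-epoch reconstruction / KL history.

    The KL weight warms up linearly over the first 10% of epochs, which
    prevents posterior collapse on small data.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[0] < 2:
        raise ValueError("X must be a (samples, features) block with >= 2 samples")
    if X.shape[1] != arch.input_dim:
        raise ValueError(
            f"architecture expects {arch.input_dim} features, got {X.shape[1]}"
        )
    rng = np.random.default_rng(seed)
    model = VAE(arch, seed=int(rng.integers(2**31 - 1)))
    model.feature_names = list(feature_names) if feature_names is not None else None
    opt = _Adam(model.parameters(), lr=learning_rate)
    history = TrainingHistory()
    n = X.shape[0]
    latent = arch.latent_dim
    warmup = max(1, int(np.ceil(0.1 * epochs)))
    for epoch in range(epochs):
        weight = kl_weight * min(1.0, (epoch + 1) / warmup)
        order = rng.permutation(n)
        recon_sum = kl_sum = 0.0
        n_batches = 0
        for start in range(0, n, batch_size):
            idx = order[start : start + batch_size]
            eps = rng.standard_normal((len(idx), latent))
            recon, kl, grads = model.loss_and_grads(X[idx], eps, weight)
            opt.step(grads)
            recon_sum += recon
            kl_sum += kl
            n_batches += 1
        history.reconstruction.append(recon_sum / n_batches)
        history.kl.append(kl_sum / n_batches)
    return model, history


def embed(
    model: VAE,
    X: np.ndarray,
    sample_ids: list[str],
    labels: np.ndarray,
    seed: int = 0,
) -> LatentRepresentation:
    """Posterior mu/sigma (deterministic) plus one sampled z per sample."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != model.arch.input_dim:
        raise ValueError(
            f"model expects {model.arch.input_dim} features, got {X.shape[1]}"
        )
    mu, sigma = model.encode(X)
    eps = np.random.default_rng(seed).standard_normal(mu.shape)
    z = reparameterize(mu, sigma, eps)
    return LatentRepresentation(
        sample_ids=list(sample_ids),
        mu=mu,
        sigma=sigma,
        z=z,
        labels=np.asarray(labels, dtype=int),
    )
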