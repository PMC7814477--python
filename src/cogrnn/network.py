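"""Continuous-time rate recurrent network: dynamics, initializers, constraints.

The recurrent state ``x`` of ``n_rec`` units follows the stochastic rate
equation

    tau dx = (-x + W_rec r + b_rec + W_in u) dt + sqrt(2 tau) sigma_rec dxi
    r = f(x)
    z = W_out r + b_out

with ``u`` the task input, ``r`` the firing rate through the transfer
function ``f`` (rectified linear by default) and ``z`` the readout.
Integration uses first-order Euler-Maruyama: with ``alpha = dt / tau``,

    x[t+1] = (1 - alpha) x[t]
             + alpha (W_rec r[t] + b_rec + W_in u[t])
             + sqrt(2 alpha) sigma_rec xi[t],      xi[t] ~ N(0, I).

Biological structure enters through a :class:`MaskSet` that maps the raw
trainable parameters of a :class:`WeightSet` to *effective* weights:
connectivity masks zero forbidden synapses, trainability masks freeze
synapses, and Dale's principle is enforced by reparameterization —
``W_eff = conn * |W_raw| * sign(presynaptic unit)`` — so each unit's
outgoing weights keep a single sign at every training iteration.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "NetworkSpec",
    "WeightSet",
    "MaskSet",
    "transfer",
    "transfer_deriv",
    "dale_sign_vector",
    "init_spectral_gaussian",
    "init_alpha_identity",
    "default_initializer",
    "make_structured_masks",
    "effective_weights",
    "step",
    "forward",
]


# ---------------------------------------------------------------------------
# Transfer functions
# ---------------------------------------------------------------------------

def _relu(x):
    return np.maximum(x, 0.0)


def _relu_deriv(x):
    # subgradient at 0 taken as 0
    return (x > 0.0).astype(float)


def _tanh_deriv(x):
    return 1.0 - np.tanh(x) ** 2


def _sigmoid(x):
    return 0.5 * (1.0 + np.tanh(0.5 * x))


def _sigmoid_deriv(x):
    s = _sigmoid(x)
    return s * (1.0 - s)


_TRANSFERS = {
    "relu": (_relu, _relu_deriv),
    "tanh": (np.tanh, _tanh_deriv),
    "sigmoid": (_sigmoid, _sigmoid_deriv),
}


def transfer(x, kind: str = "relu"):
    """Elementwise state-to-rate nonlinearity ``r = f(x)``."""
    try:
        return _TRANSFERS[kind][0](np.asarray(x, dtype=float))
    except KeyError:
        raise ValueError(f"unknown transfer function {kind!r}; "
                         f"choose from {sorted(_TRANSFERS)}") from None


def transfer_deriv(x, kind: str = "relu"):
    """Elementwise derivative ``f'(x)`` (subgradients at kinks are 0)."""
    try:
        return _TRANSFERS[kind][1](np.asarray(x, dtype=float))
    except KeyError:
        raise ValueError(f"unknown transfer function {kind!r}; "
                         f"choose from {sorted(_TRANSFERS)}") from None


# ---------------------------------------------------------------------------
# Specifications and parameter containers
# ---------------------------------------------------------------------------

@dataclass
class NetworkSpec:
    """Architecture and dynamics hyperparameters.

    Parameters
    ----------
    n_in, n_rec, n_out
        Input, recurrent, and output channel counts.
    dt
        Integration time step in ms.
    tau
        Intrinsic unit timescale in ms; ``alpha = dt / tau`` must lie in
        (0, 1] for the Euler update to be a contraction of the leak term.
    sigma_rec
        Scale of the private white noise injected into each unit's state.
    transfer
        Name of the rate nonlinearity: ``relu`` (default), ``tanh`` or
        ``sigmoid``.
    dales_ratio
        If set, the fraction of excitatory units under Dale's principle
        (the first ``ceil(dales_ratio * n_rec)`` units excite, the rest
        inhibit).  ``None`` leaves weights unsigned.
    """

    n_in: int
    n_rec: int = 50
    n_out: int = 2
    dt: float = 10.0
    tau: float = 100.0
    sigma_rec: float = 0.05
    transfer: str = "relu"
    dales_ratio: float | None = None

    def __post_init__(self):
        for name in ("n_in", "n_rec", "n_out"):
            if int(getattr(self, name)) < 1:
                raise ValueError(f"{name} must be a positive integer")
            setattr(self, name, int(getattr(self, name)))
        if not 0.0 < self.dt <= self.tau:
            raise ValueError("require 0 < dt <= tau so alpha = dt/tau is in (0, 1]")
        if self.sigma_rec < 0:
            raise ValueError("sigma_rec must be nonnegative")
        if self.transfer not in _TRANSFERS:
            raise ValueError(f"unknown transfer {self.transfer!r}")
        if self.dales_ratio is not None and not 0.0 < self.dales_ratio < 1.0:
            raise ValueError("dales_ratio must lie in (0, 1)")

    @property
    def alpha(self) -> float:
        return self.dt / self.tau

    def to_dict(self) -> dict:
        return {
            "n_in": self.n_in, "n_rec": self.n_rec, "n_out": self.n_out,
            "dt": self.dt, "tau": self.tau, "sigma_rec": self.sigma_rec,
            "transfer": self.transfer, "dales_ratio": self.dales_ratio,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkSpec":
        return cls(**d)


_WEIGHT_FIELDS = ("W_in_raw", "W_rec_raw", "W_out_raw", "b_rec", "b_out", "x0")


@dataclass
class WeightSet:
    """Raw trainable parameters (before masks/Dale reparameterization)."""

    W_in_raw: np.ndarray
    W_rec_raw: np.ndarray
    W_out_raw: np.ndarray
    b_rec: np.ndarray
    b_out: np.ndarray
    x0: np.ndarray

    def __post_init__(self):
        for name in _WEIGHT_FIELDS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite entries")
            setattr(self, name, arr)
        n_rec = self.W_rec_raw.shape[0]
        if self.W_rec_raw.shape != (n_rec, n_rec):
            raise ValueError("W_rec_raw must be square")
        if self.W_in_raw.shape[0] != n_rec or self.W_out_raw.shape[1] != n_rec:
            raise ValueError("W_in_raw/W_out_raw shapes inconsistent with n_rec")
        if self.b_rec.shape != (n_rec,) or self.x0.shape != (n_rec,):
            raise ValueError("b_rec/x0 must be length n_rec vectors")
        if self.b_out.shape != (self.W_out_raw.shape[0],):
            raise ValueError("b_out length must match W_out_raw rows")

    def copy(self) -> "WeightSet":
        return WeightSet(**{k: getattr(self, k).copy() for k in _WEIGHT_FIELDS})

    def as_dict(self) -> dict:
        return {k: getattr(self, k) for k in _WEIGHT_FIELDS}


_MASK_FIELDS = ("conn_in", "conn_rec", "conn_out",
                "train_in", "train_rec", "train_out",
                "train_b_rec", "train_b_out")


@dataclass
class MaskSet:
    """Connectivity masks (1 = synapse allowed), trainability masks
    (1 = plastic) and, optionally, the Dale sign of each recurrent unit."""

    conn_in: np.ndarray
    conn_rec: np.ndarray
    conn_out: np.ndarray
    train_in: np.ndarray
    train_rec: np.ndarray
    train_out: np.ndarray
    train_b_rec: np.ndarray
    train_b_out: np.ndarray
    dale_signs: np.ndarray | None = None

    def __post_init__(self):
        for name in _MASK_FIELDS:
            arr = np.asarray(getattr(self, name), dtype=float)
            if not np.all(np.isin(arr, (0.0, 1.0))):
                raise ValueError(f"{name} must be binary")
            setattr(self, name, arr)
        if self.dale_signs is not None:
            s = np.asarray(self.dale_signs, dtype=float)
            if not np.all(np.isin(s, (-1.0, 1.0))):
                raise ValueError("dale_signs entries must be +1 or -1")
            if s.shape != (self.conn_rec.shape[0],):
                raise ValueError("dale_signs must be a length-n_rec vector")
            self.dale_signs = s

    @classmethod
    def all_to_all(cls, spec: NetworkSpec) -> "MaskSet":
        n_in, n_rec, n_out = spec.n_in, spec.n_rec, spec.n_out
        signs = None
        if spec.dales_ratio is not None:
            signs = dale_sign_vector(n_rec, spec.dales_ratio)
        return cls(
            conn_in=np.ones((n_rec, n_in)),
            conn_rec=np.ones((n_rec, n_rec)),
            conn_out=np.ones((n_out, n_rec)),
            train_in=np.ones((n_rec, n_in)),
            train_rec=np.ones((n_rec, n_rec)),
            train_out=np.ones((n_out, n_rec)),
            train_b_rec=np.ones(n_rec),
            train_b_out=np.ones(n_out),
            dale_signs=signs,
        )

    def copy(self) -> "MaskSet":
        return MaskSet(
            **{k: getattr(self, k).copy() for k in _MASK_FIELDS},
            dale_signs=None if self.dale_signs is None else self.dale_signs.copy(),
        )


def dale_sign_vector(n_rec: int, dales_ratio: float) -> np.ndarray:
    """Sign of each unit's outgoing synapses: the first
    ``ceil(dales_ratio * n_rec)`` units are excitatory (+1), the rest
    inhibitory (-1)."""
    n_exc = math.ceil(dales_ratio * n_rec)
    signs = -np.ones(n_rec)
    signs[:n_exc] = 1.0
    return signs


# ---------------------------------------------------------------------------
# Initializers
# ---------------------------------------------------------------------------

def init_spectral_gaussian(n_rec: int, radius: float = 1.1,
                           rng: np.random.Generator | None = None) -> np.ndarray:
    """Gaussian recurrent matrix rescaled to a fixed spectral radius.

    Entries are drawn i.i.d. N(0, 1/n_rec) and the whole matrix is scaled
    so its largest absolute eigenvalue equals ``radius`` (1.1 by default,
    slightly supercritical, which keeps activity alive at the start of
    training).
    """
    if n_rec < 1:
        raise ValueError("n_rec must be >= 1")
    if radius <= 0:
        raise ValueError("radius must be positive")
    rng = np.random.default_rng(rng)
    W = rng.standard_normal((n_rec, n_rec)) / math.sqrt(n_rec)
    rho = np.max(np.abs(np.linalg.eigvals(W)))
    if rho == 0.0:
        raise ValueError("degenerate draw: zero spectral radius")
    return W * (radius / rho)


def init_alpha_identity(n_rec: int, alpha: float) -> np.ndarray:
    """Identity recurrent initialization scaled by ``alpha``."""
    if n_rec < 1:
        raise ValueError("n_rec must be >= 1")
    return float(alpha) * np.eye(n_rec)


def default_initializer(spec: NetworkSpec,
                        rng: np.random.Generator | None = None,
                        radius: float = 1.1) -> tuple[WeightSet, MaskSet]:
    """Default weight/mask initialization.

    Recurrent weights come from :func:`init_spectral_gaussian`; input and
    output weights are i.i.d. Gaussian with standard deviation
    ``1/sqrt(fan_in)``; all biases and the initial state are zero; the
    connectivity and trainability masks are all-to-all / all-plastic; Dale
    signs follow ``spec.dales_ratio`` when present.
    """
    rng = np.random.default_rng(rng)
    w = WeightSet(
        W_in_raw=rng.standard_normal((spec.n_rec, spec.n_in)) / math.sqrt(spec.n_in),
        W_rec_raw=init_spectral_gaussian(spec.n_rec, radius=radius, rng=rng),
        W_out_raw=rng.standard_normal((spec.n_out, spec.n_rec)) / math.sqrt(spec.n_rec),
        b_rec=np.zeros(spec.n_rec),
        b_out=np.zeros(spec.n_out),
        x0=np.zeros(spec.n_rec),
    )
    return w, MaskSet.all_to_all(spec)


# ---------------------------------------------------------------------------
# Structured connectivity recipes
# ---------------------------------------------------------------------------

def make_structured_masks(kind: str, masks: MaskSet, *,
                          region_sizes: tuple[int, int] | None = None,
                          p_inter: float | None = None,
                          rng: np.random.Generator | None = None) -> MaskSet:
    """Return a copy of ``masks`` with one structural constraint applied.

    kinds
    -----
    ``no_autapse``
        Forbid self-connections (zero the diagonal of ``conn_rec``).
    ``two_region``
        Two densely connected populations of sizes ``region_sizes`` with
        Bernoulli(``p_inter``) connections between them (``rng`` required
        when ``0 < p_inter < 1``).
    ``dale_fixed_ei``
        Freeze every synapse joining units of opposite Dale sign
        (E<->I fixed, E->E and I->I plastic); requires ``dale_signs``.
    """
    out = masks.copy()
    n_rec = out.conn_rec.shape[0]
    if kind == "no_autapse":
        np.fill_diagonal(out.conn_rec, 0.0)
    elif kind == "two_region":
        if region_sizes is None or p_inter is None:
            raise ValueError("two_region requires region_sizes and p_inter")
        n1, n2 = region_sizes
        if n1 + n2 != n_rec:
            raise ValueError(f"region sizes {region_sizes} do not sum to n_rec={n_rec}")
        if not 0.0 <= p_inter <= 1.0:
            raise ValueError("p_inter must lie in [0, 1]")
        conn = np.ones((n_rec, n_rec))
        if p_inter < 1.0:
            rng = np.random.default_rng(rng)
            inter12 = (rng.random((n1, n2)) < p_inter).astype(float)
            inter21 = (rng.random((n2, n1)) < p_inter).astype(float)
            conn[:n1, n1:] = inter12
            conn[n1:, :n1] = inter21
        out.conn_rec = out.conn_rec * conn
    elif kind == "dale_fixed_ei":
        if out.dale_signs is None:
            raise ValueError("dale_fixed_ei requires dale_signs on the mask set")
        s = out.dale_signs
        opposite = (s[:, None] * s[None, :]) < 0  # entry (i, j): post i, pre j
        out.train_rec = out.train_rec * np.where(opposite, 0.0, 1.0)
    else:
        raise ValueError(f"unknown structured-mask kind {kind!r}")
    return out


# ---------------------------------------------------------------------------
# Effective weights and dynamics
# ---------------------------------------------------------------------------

def effective_weights(w: WeightSet, m: MaskSet):
    """Map raw parameters to the weights the dynamics actually use.

    Without Dale signs the effective weight is ``conn * raw``.  With Dale
    signs, recurrent and output weights become ``conn * |raw| * s_j`` where
    ``s_j`` is the sign of presynaptic unit ``j`` (the column index under
    ``z = W r``), so each unit's outgoing synapses share one sign exactly.
    Input weights are never sign-constrained.
    """
    W_in = m.conn_in * w.W_in_raw
    if m.dale_signs is None:
        W_rec = m.conn_rec * w.W_rec_raw
        W_out = m.conn_out * w.W_out_raw
    else:
        s = m.dale_signs[None, :]
        W_rec = m.conn_rec * np.abs(w.W_rec_raw) * s
        W_out = m.conn_out * np.abs(w.W_out_raw) * s
    return W_in, W_rec, W_out


def step(x_t: np.ndarray, u_t: np.ndarray, w: WeightSet, m: MaskSet,
         spec: NetworkSpec, noise: np.ndarray) -> np.ndarray:
    """One Euler-Maruyama update of the recurrent state.

    ``noise`` is a standard-normal draw of the same trailing shape as the
    state; it is injected (rather than drawn internally) so callers control
    the noise stream exactly.
    """
    W_in, W_rec, _ = effective_weights(w, m)
    a = spec.alpha
    r = transfer(x_t, spec.transfer)
    x_next = ((1.0 - a) * np.asarray(x_t, dtype=float)
              + a * (r @ W_rec.T + w.b_rec + np.asarray(u_t, dtype=float) @ W_in.T)
              + math.sqrt(2.0 * a) * spec.sigma_rec * np.asarray(noise, dtype=float))
    if not np.all(np.isfinite(x_next)):
        raise FloatingPointError("recurrent state diverged (non-finite entries)")
    return x_next


def forward(batch_inputs: np.ndarray, w: WeightSet, m: MaskSet,
            spec: NetworkSpec, rng: np.random.Generator | None = None,
            noise: np.ndarray | None = None):
    """Unroll the dynamics over a batch of input time series.

    Parameters
    ----------
    batch_inputs
        ``(B, T, n_in)`` array (a single ``(T, n_in)`` trial is promoted).
    rng, noise
        Either a generator from which one ``(B, T, n_rec)`` standard-normal
        noise tensor is drawn, or that tensor itself (takes precedence).
        With ``sigma_rec == 0`` and no rng the pass is deterministic.

    Returns
    -------
    states, rates, outputs
        ``(B, T, n_rec)``, ``(B, T, n_rec)`` and ``(B, T, n_out)`` arrays;
        row ``t`` holds the state after input row ``t`` has been applied.
    """
    inputs = np.asarray(batch_inputs, dtype=float)
    single = inputs.ndim == 2
    if single:
        inputs = inputs[None]
    B, T, n_in = inputs.shape
    if n_in != spec.n_in:
        raise ValueError(f"inputs have {n_in} channels, spec.n_in={spec.n_in}")
    if noise is None:
        if rng is not None:
            noise = rng.standard_normal((B, T, spec.n_rec))
        else:
            noise = np.zeros((B, T, spec.n_rec))
    else:
        noise = np.asarray(noise, dtype=float)
        if single and noise.ndim == 2:
            noise = noise[None]
        if noise.shape != (B, T, spec.n_rec):
            raise ValueError("noise tensor shape mismatch")

    W_in, W_rec, W_out = effective_weights(w, m)
    a = spec.alpha
    noise_scale = math.sqrt(2.0 * a) * spec.sigma_rec
    f = _TRANSFERS[spec.transfer][0]

    states = np.empty((B, T, spec.n_rec))
    rates = np.empty((B, T, spec.n_rec))
    x = np.broadcast_to(w.x0, (B, spec.n_rec)).copy()
    r = f(x)
    for t in range(T):
        x = ((1.0 - a) * x + a * (r @ W_rec.T + w.b_rec + inputs[:, t] @ W_in.T)
             + noise_scale * noise[:, t])
        r = f(x)
        states[:, t] = x
        rates[:, t] = r
    if not np.all(np.isfinite(states)):
        raise FloatingPointError("recurrent state diverged (non-finite entries)")
    outputs = rates @ W_out.T + w.b_out
    if single:
        return states[0], rates[0], outputs[0]
    return states, rates, outputs
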