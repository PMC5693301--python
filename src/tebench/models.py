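"""Generative network models for the preprocessing benchmark.

Three small directed networks of coupled stochastic difference equations
produce trial-based ensembles with known ground-truth coupling:

``kus``
    A linear five-channel cascade driven by a surrogate EEG-like signal
    (1/f-type background plus a ~10 Hz rhythm).  Interaction delays of 4
    and 8 samples.
``clmm``
    A coupled logistic-map network: three branches of four channels each
    plus a common sink, with the logistic map iterated once, twice or
    three times as the coupling function (progressively stronger
    nonlinearity).  Delays of 2, 4, 6 and 8 samples.
``csem``
    A coupled sigmoid-equations network of four channels (plus one pure
    noise channel), emulating threshold-like single-unit coupling.
    Delays of 4, 6 and 8 samples.

Every driven channel receives *internal* (dynamic) Gaussian noise that
enters the recursion, and every channel receives *external* (measurement)
Gaussian noise after the dynamics have been computed.  Both are scaled so
that their variance is ``noise_fraction`` (default one quarter) of the
variance of the network's noise-free input channel.
"""

from __future__ import annotations

import dataclasses
import math
from typing import Mapping, Sequence

import numpy as np

__all__ = [
    "ModelSpec",
    "CouplingGraph",
    "TrialEnsemble",
    "generate_surrogate_input",
    "logistic_map",
    "sigmoid_transfer",
    "simulate_kus",
    "simulate_clmm",
    "simulate_csem",
    "simulate",
    "BURN_IN",
]

_MODEL_NAMES = ("kus", "clmm", "csem")

#: Extra samples simulated before each trial and discarded, so that the
#: recursion has forgotten its zero initial condition (longest delay chain
#: in any model is 18 samples).
BURN_IN = 32


@dataclasses.dataclass(frozen=True)
class ModelSpec:
    """Configuration of one simulated study condition.

    Parameters
    ----------
    model_name:
        One of ``kus``, ``clmm``, ``csem``.
    fs:
        Sampling rate in Hz.
    n_samples:
        Samples per trial (after burn-in removal).
    n_trials, n_datasets:
        Trials per dataset and independent datasets per condition.
    gamma:
        Coupling factor applied to every source term.
    noise_fraction:
        Ratio of injected noise variance to the reference variance of the
        noise-free input channel (internal and external noise separately).
    alpha_logistic:
        Logistic-map parameter (weakly chaotic at the default 3.576).
    a_sigmoid:
        Steepness of the sigmoid coupling function.
    strict_literal_noise:
        If True, scale noise by ``noise_fraction * sigma**2`` directly
        (amplitude, not variance, interpretation); off by default.
    """

    model_name: str
    fs: float = 1250.0
    n_samples: int = 3000
    n_trials: int = 20
    n_datasets: int = 100
    gamma: float = 0.4
    noise_fraction: float = 0.25
    alpha_logistic: float = 3.576
    a_sigmoid: float = 6.0
    rng_seed: int = 0
    strict_literal_noise: bool = False

    def __post_init__(self) -> None:
        if self.model_name not in _MODEL_NAMES:
            raise ValueError(f"unknown model_name {self.model_name!r}")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.n_samples < 1:
            raise ValueError("n_samples must be >= 1")
        if self.n_trials < 1 or self.n_datasets < 1:
            raise ValueError("n_trials and n_datasets must be >= 1")
        if self.noise_fraction < 0:
            raise ValueError("noise_fraction must be >= 0")
        if self.gamma <= 0:
            raise ValueError("gamma must be > 0")

    def noise_scale(self, sigma_ref: float) -> float:
        """Noise amplitude multiplier for a given reference std ``sigma_ref``."""
        if self.strict_literal_noise:
            return self.noise_fraction * sigma_ref**2
        return math.sqrt(self.noise_fraction) * sigma_ref


@dataclasses.dataclass(frozen=True)
class CouplingGraph:
    """Ground-truth directed coupling structure of a simulated network.

    ``direct_edges`` are (source, target, delay_samples, weight) tuples.
    Indirect pairs are ordered pairs connected only through a directed
    path of length >= 2; unconnected pairs are all remaining ordered
    pairs of distinct nodes.  The three sets partition the ordered pairs.
    """

    nodes: tuple[str, ...]
    direct_edges: tuple[tuple[str, str, int, float], ...]

    def __post_init__(self) -> None:
        for src, tgt, delay, _w in self.direct_edges:
            if src not in self.nodes or tgt not in self.nodes:
                raise ValueError(f"edge endpoint not in nodes: {src}->{tgt}")
            if delay < 1:
                raise ValueError("all coupling delays must be >= 1 sample")

    def direct_pairs(self) -> tuple[tuple[str, str], ...]:
        return tuple((s, t) for s, t, _d, _w in self.direct_edges)

    def _reachable(self) -> dict[str, set[str]]:
        adj: dict[str, set[str]] = {n: set() for n in self.nodes}
        for s, t, _d, _w in self.direct_edges:
            adj[s].add(t)
        reach: dict[str, set[str]] = {}
        for start in self.nodes:
            seen: set[str] = set()
            stack = list(adj[start])
            while stack:
                n = stack.pop()
                if n not in seen:
                    seen.add(n)
                    stack.extend(adj[n])
            reach[start] = seen
        return reach

    def indirect_pairs(self) -> tuple[tuple[str, str], ...]:
        direct = set(self.direct_pairs())
        reach = self._reachable()
        out = []
        for s in self.nodes:
            for t in self.nodes:
                if s != t and (s, t) not in direct and t in reach[s]:
                    out.append((s, t))
        return tuple(out)

    def unconnected_pairs(self) -> tuple[tuple[str, str], ...]:
        taken = set(self.direct_pairs()) | set(self.indirect_pairs())
        return tuple(
            (s, t)
            for s in self.nodes
            for t in self.nodes
            if s != t and (s, t) not in taken
        )

    def delay_of(self, source: str, target: str) -> int:
        for s, t, d, _w in self.direct_edges:
            if (s, t) == (source, target):
                return d
        raise KeyError(f"no direct edge {source}->{target}")


@dataclasses.dataclass
class TrialEnsemble:
    """Trial-resolved multichannel time series, the currency between stages.

    ``values`` is indexed ``(dataset, trial, channel, time)``.  The
    ``provenance`` list records the simulation and every preprocessing
    transform subsequently applied.
    """

    values: np.ndarray
    fs: float
    channels: tuple[str, ...]
    provenance: list[dict] = dataclasses.field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 4:
            raise ValueError("values must be (dataset, trial, channel, time)")
        if self.values.shape[2] != len(self.channels):
            raise ValueError("channel axis does not match channel labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("ensemble contains non-finite values")

    @property
    def n_datasets(self) -> int:
        return self.values.shape[0]

    @property
    def n_trials(self) -> int:
        return self.values.shape[1]

    @property
    def n_samples(self) -> int:
        return self.values.shape[3]

    def channel_index(self, label: str) -> int:
        return self.channels.index(label)

    def with_values(self, values: np.ndarray, fs: float | None = None,
                    step: dict | None = None) -> "TrialEnsemble":
        """Copy with new data and an appended provenance step."""
        prov = list(self.provenance)
        if step is not None:
            prov.append(step)
        return TrialEnsemble(values=values, fs=self.fs if fs is None else fs,
                             channels=self.channels, provenance=prov)


# ---------------------------------------------------------------------------
# building blocks


def generate_surrogate_input(n_samples: int, fs: float, seed,
                             peak_hz: float = 10.0, peak_width_hz: float = 1.0,
                             knee_hz: float = 3.0,
                             background_power: float = 0.75) -> np.ndarray:
    """Surrogate EEG-like driving signal.

    Sum of a 1/f-type background (amplitude ~ 1/f above ``knee_hz``, flat
    below) and a narrowband ~``peak_hz`` oscillation, mixed at a 3:1
    background:peak power ratio by default, normalized to zero mean and
    unit variance.  Deterministic per seed.
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if fs <= 0:
        raise ValueError("fs must be positive")
    rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n_samples, 1.0 / fs)
    bg_amp = np.zeros_like(freqs)
    bg_amp[1:] = 1.0 / np.maximum(freqs[1:], knee_hz)
    pk_amp = np.exp(-0.5 * ((freqs - peak_hz) / peak_width_hz) ** 2)
    pk_amp[0] = 0.0

    def _synth(amp: np.ndarray) -> np.ndarray:
        phases = rng.uniform(0.0, 2.0 * np.pi, amp.shape)
        spec = amp * np.exp(1j * phases)
        spec[0] = 0.0
        if n_samples % 2 == 0:
            spec[-1] = spec[-1].real
        x = np.fft.irfft(spec, n_samples)
        sd = x.std()
        return x / sd if sd > 0 else x

    x = (math.sqrt(background_power) * _synth(bg_amp)
         + math.sqrt(1.0 - background_power) * _synth(pk_amp))
    x -= x.mean()
    x /= x.std()
    return x


def logistic_map(x, alpha: float, n_iter: int = 1):
    """``n_iter``-fold composition of the logistic map f(x) = alpha*x*(1-x).

    Defined on [0, 1]; stays in [0, 1] for 0 < alpha <= 4.
    """
    x = np.asarray(x, dtype=float)
    if np.any(x < 0) or np.any(x > 1):
        raise ValueError("logistic map input must lie in [0, 1]")
    if not 0 < alpha <= 4:
        raise ValueError("alpha must be in (0, 4]")
    if n_iter < 1:
        raise ValueError("n_iter must be >= 1")
    y = x
    for _ in range(n_iter):
        y = alpha * y * (1.0 - y)
    return y if y.ndim else float(y)


def sigmoid_transfer(x, a: float = 6.0):
    """Sigmoid coupling function 2/(1+exp(-a*x)) - 1, ranging over (-1, 1).

    Equals tanh(a*x/2); the inflection point at zero crudely mimics a
    neuron's firing threshold.
    """
    y = np.tanh(0.5 * a * np.asarray(x, dtype=float))
    return y if y.ndim else float(y)


def _lag(x: np.ndarray, delay: int) -> np.ndarray:
    """x delayed by ``delay`` samples, zero-padded at the start."""
    out = np.zeros_like(x)
    if delay < x.shape[-1]:
        out[..., delay:] = x[..., : x.shape[-1] - delay]
    return out


def _minmax01(x: np.ndarray) -> np.ndarray:
    lo, hi = x.min(), x.max()
    if hi == lo:
        raise ValueError("cannot min-max normalize a constant series")
    return (x - lo) / (hi - lo)


def _dataset_rngs(spec: ModelSpec) -> list[np.random.Generator]:
    ss = np.random.SeedSequence(spec.rng_seed)
    return [np.random.default_rng(c) for c in ss.spawn(spec.n_datasets)]


# ---------------------------------------------------------------------------
# models


def simulate_kus(spec: ModelSpec,
                 input_signal: np.ndarray | None = None
                 ) -> tuple[TrialEnsemble, CouplingGraph]:
    """Linear five-channel cascade driven by a surrogate EEG signal.

    X1 = d + internal noise; X2 = gamma*X1(t-4); X3 = gamma*X2(t-4);
    X4 = gamma*X2(t-8); X5 = pure noise.  External noise is added to all
    channels after the dynamics.  The driving signal ``d`` is shared by
    all trials of a dataset; noise is fresh per trial.

    ``input_signal``, if given, must cover ``n_samples + BURN_IN`` samples
    and is reused for every dataset.
    """
    if spec.model_name != "kus":
        raise ValueError("spec.model_name must be 'kus'")
    L = spec.n_samples + BURN_IN
    if input_signal is not None:
        input_signal = np.asarray(input_signal, dtype=float)
        if input_signal.shape[-1] < L:
            raise ValueError(
                f"input_signal must have at least n_samples + {BURN_IN} samples")
    g = spec.gamma
    out = np.empty((spec.n_datasets, spec.n_trials, 5, spec.n_samples))
    for i_ds, rng in enumerate(_dataset_rngs(spec)):
        if input_signal is None:
            d = generate_surrogate_input(L, spec.fs, rng)
        else:
            d = input_signal[:L]
        sigma_ref = d.std()
        V = spec.noise_scale(sigma_ref)
        for i_tr in range(spec.n_trials):
            eta = V * rng.standard_normal((5, L))
            x1 = d + eta[0]
            x2 = g * _lag(x1, 4) + eta[1]
            x3 = g * _lag(x2, 4) + eta[2]
            x4 = g * _lag(x2, 8) + eta[3]
            x5 = eta[4]
            X = np.stack([x1, x2, x3, x4, x5])
            X = X + V * rng.standard_normal((5, L))
            out[i_ds, i_tr] = X[:, BURN_IN:]
    graph = CouplingGraph(
        nodes=("X1", "X2", "X3", "X4", "X5"),
        direct_edges=(("X1", "X2", 4, g), ("X2", "X3", 4, g),
                      ("X2", "X4", 8, g)),
    )
    ens = TrialEnsemble(out, spec.fs, graph.nodes,
                        [{"op": "simulate", "model": "kus",
                          "seed": spec.rng_seed, "fs": spec.fs}])
    return ens, graph


def simulate_clmm(spec: ModelSpec,
                  inputs: Mapping[int, np.ndarray] | None = None
                  ) -> tuple[TrialEnsemble, CouplingGraph]:
    """Coupled logistic-map network: 13 channels in three branches.

    Branch m (= 1, 2, 3) has a white-noise input channel Xns_m (min-max
    normalized to [0, 1]) and channels Xm2 (input lagged 6), Xm3 (Xm2
    lagged 8) and Xm4 (Xm2 lagged 6 plus Xm3 lagged 4), with the logistic
    map iterated m times as the coupling function.  A common channel Xi
    receives the three branches' Xm2 at lags 2, 6 and 8.  Every driven
    channel is rescaled by (s*gamma + V), s = number of inputs, so values
    stay in [0, 1]; noise is drawn Gaussian and min-max normalized to
    [0, 1] before scaling.

    ``inputs`` optionally overrides the branch input series (keyed 1-3,
    values in [0, 1], length >= n_samples + BURN_IN); used for controlled
    experiments.
    """
    if spec.model_name != "clmm":
        raise ValueError("spec.model_name must be 'clmm'")
    L = spec.n_samples + BURN_IN
    g = spec.gamma
    alpha = spec.alpha_logistic

    def f(x: np.ndarray, m: int) -> np.ndarray:
        y = np.clip(x, 0.0, 1.0)  # guard against float round-off at the ends
        for _ in range(m):
            y = alpha * y * (1.0 - y)
        return y

    node_list: list[str] = []
    for m in (1, 2, 3):
        node_list += [f"Xns{m}", f"X{m}2", f"X{m}3", f"X{m}4"]
    node_list.append("Xi")
    nodes = tuple(node_list)

    out = np.empty((spec.n_datasets, spec.n_trials, 13, spec.n_samples))
    for i_ds, rng in enumerate(_dataset_rngs(spec)):
        for i_tr in range(spec.n_trials):
            inp = {}
            for m in (1, 2, 3):
                if inputs is not None and m in inputs:
                    arr = np.asarray(inputs[m], dtype=float)
                    if arr.shape[-1] < L:
                        raise ValueError("override input too short")
                    inp[m] = arr[:L]
                else:
                    inp[m] = _minmax01(rng.standard_normal(L))
            sigma_ref = inp[1].std()
            target_std = spec.noise_scale(sigma_ref)

            def noise() -> tuple[np.ndarray, float]:
                if target_std == 0.0:
                    return np.zeros(L), 0.0
                z = _minmax01(rng.standard_normal(L))
                scale = target_std / z.std()
                return z * scale, scale

            chans: dict[str, np.ndarray] = {}
            x2 = {}
            for m in (1, 2, 3):
                chans[f"Xns{m}"] = inp[m]
                n2, V2 = noise()
                x2[m] = (g * f(_lag(inp[m], 6), m) + n2) / (g + V2 if g + V2 > 0 else 1.0)
                chans[f"X{m}2"] = x2[m]
                n3, V3 = noise()
                x3 = (g * f(_lag(x2[m], 8), m) + n3) / (g + V3 if g + V3 > 0 else 1.0)
                chans[f"X{m}3"] = x3
                n4, V4 = noise()
                chans[f"X{m}4"] = (g * (f(_lag(x2[m], 6), m) + f(_lag(x3, 4), m))
                                   + n4) / (2 * g + V4)
            ni, Vi = noise()
            chans["Xi"] = (g * (f(_lag(x2[1], 2), 1) + f(_lag(x2[2], 6), 2)
                                + f(_lag(x2[3], 8), 3)) + ni) / (3 * g + Vi)
            X = np.stack([chans[n] for n in nodes])
            if target_std > 0.0:
                for c in range(13):
                    e, _ = noise()
                    X[c] = X[c] + e
            out[i_ds, i_tr] = np.clip(X[:, BURN_IN:], 0.0, 1.0)

    delays_to_i = {1: 2, 2: 6, 3: 8}
    edges = []
    for m in (1, 2, 3):
        edges += [
            (f"Xns{m}", f"X{m}2", 6, g),
            (f"X{m}2", f"X{m}3", 8, g),
            (f"X{m}2", f"X{m}4", 6, g),
            (f"X{m}3", f"X{m}4", 4, g),
            (f"X{m}2", "Xi", delays_to_i[m], g),
        ]
    graph = CouplingGraph(nodes=nodes, direct_edges=tuple(edges))
    ens = TrialEnsemble(out, spec.fs, nodes,
                        [{"op": "simulate", "model": "clmm",
                          "seed": spec.rng_seed, "fs": spec.fs}])
    return ens, graph


def simulate_csem(spec: ModelSpec) -> tuple[TrialEnsemble, CouplingGraph]:
    """Coupled sigmoid-equations network.

    X1 = white noise; X2 = f(gamma*X1(t-6)); X3 = f(gamma*X2(t-8));
    X4 = f(gamma*(X2(t-6) + X3(t-4))), with f the sigmoid transfer
    function.  Internal noise enters each driven channel per step,
    external noise is added to every channel after the full simulation.

    A fifth, independent pure-noise channel X5 is a synthetic addition
    (the four coupled equations leave the network without a null channel;
    X5 mirrors the linear model's noise channel and carries no coupling).
    """
    if spec.model_name != "csem":
        raise ValueError("spec.model_name must be 'csem'")
    L = spec.n_samples + BURN_IN
    g, a = spec.gamma, spec.a_sigmoid
    out = np.empty((spec.n_datasets, spec.n_trials, 5, spec.n_samples))
    for i_ds, rng in enumerate(_dataset_rngs(spec)):
        for i_tr in range(spec.n_trials):
            x1 = rng.standard_normal(L)
            sigma_ref = x1.std()
            V = spec.noise_scale(sigma_ref)
            x2 = sigmoid_transfer(g * _lag(x1, 6), a) + V * rng.standard_normal(L)
            x3 = sigmoid_transfer(g * _lag(x2, 8), a) + V * rng.standard_normal(L)
            x4 = (sigmoid_transfer(g * (_lag(x2, 6) + _lag(x3, 4)), a)
                  + V * rng.standard_normal(L))
            x5 = V * rng.standard_normal(L)
            X = np.stack([x1, x2, x3, x4, x5])
            X = X + V * rng.standard_normal((5, L))
            out[i_ds, i_tr] = X[:, BURN_IN:]
    graph = CouplingGraph(
        nodes=("X1", "X2", "X3", "X4", "X5"),
        direct_edges=(("X1", "X2", 6, g), ("X2", "X3", 8, g),
                      ("X2", "X4", 6, g), ("X3", "X4", 4, g)),
    )
    ens = TrialEnsemble(out, spec.fs, graph.nodes,
                        [{"op": "simulate", "model": "csem",
                          "seed": spec.rng_seed, "fs": spec.fs}])
    return ens, graph


def simulate(spec: ModelSpec, **kwargs) -> tuple[TrialEnsemble, CouplingGraph]:
    """Dispatch to the simulator named by ``spec.model_name``."""
    return {
        "kus": simulate_kus,
        "clmm": simulate_clmm,
        "csem": simulate_csem,
    }[spec.model_name](spec, **kwargs)
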