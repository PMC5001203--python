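"""Synthetic MBDCap-seq promoter/background count generation.

The generator mirrors the benchmark design for the DM test: per-promoter
NB signal with (mean, dispersion) pairs resampled from a parameter pool,
a designated fraction of promoters differentially methylated at a fixed
fold change, and background counts built per 100 bp window from the
hybrid noise model

    B_inc = M * Normal(mu, sigma),   mu ~ Poisson(lambda + NF),

truncated at zero and rounded (counts must be non-negative integers).
M = 10 and sigma = 3 by default; the noise factor NF in {0, 7, 20}
spans low, intermediate and high background dispersion. Each promoter
owns 40 windows whose summed counts form its background B, and the
observed promoter count is X = S + B.

The default parameter pool is a synthetic stand-in emulating the scale
of promoter-level NB estimates from real prostate MBDCap-seq libraries
(log-normal means around ~400 reads per 4 kb promoter, log-normal
dispersions around 0.2); see ``default_signal_params``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .counts import CountMatrix

__all__ = [
    "SignalParamPool",
    "NoiseScenario",
    "ScenarioConfig",
    "SimulatedDataset",
    "default_signal_params",
    "build_param_pool",
    "simulate_signal",
    "simulate_window_noise",
    "assemble_dataset",
    "simulate_dataset",
]

#: internal seed fixing the synthetic parameter-table fixture
_FIXTURE_SEED = 20160818


@dataclass
class SignalParamPool:
    """Per-promoter NB (mean, dispersion) pairs sampled with replacement."""

    means: np.ndarray
    dispersions: np.ndarray

    def __post_init__(self) -> None:
        self.means = np.asarray(self.means, dtype=float)
        self.dispersions = np.asarray(self.dispersions, dtype=float)
        if np.any(self.means <= 0) or np.any(self.dispersions <= 0):
            raise ValueError("means and dispersions must be positive")

    def __len__(self) -> int:
        return len(self.means)


@dataclass
class NoiseScenario:
    """Hybrid background-noise model parameters for 100 bp windows."""

    multiplier: float = 10.0  # M
    sigma: float = 3.0
    noise_factor: float = 0.0  # NF in {0, 7, 20}
    lambda_mean: float = 0.5  # mean of the exponential law for per-window rates
    distribution: str = "poisson"  # rate model for mu: poisson | normal | uniform

    def __post_init__(self) -> None:
        if self.multiplier <= 0 or self.sigma < 0 or self.noise_factor < 0:
            raise ValueError("require M > 0, sigma >= 0, NF >= 0")


@dataclass
class ScenarioConfig:
    """One cell of the benchmark grid."""

    n_promoters: int = 5000
    replicates: int = 3  # per group
    dm_fraction: float = 0.10
    fold_change: float = 2.0
    noise: NoiseScenario = field(default_factory=NoiseScenario)
    windows_per_promoter: int = 40
    signal_distribution: str = "nb"  # nb | normal
    shared_background_draws: bool = True

    def __post_init__(self) -> None:
        if not 0 <= self.dm_fraction <= 1:
            raise ValueError("dm_fraction must lie in [0, 1]")
        if self.fold_change < 1:
            raise ValueError("fold_change must be >= 1")

    def with_noise(self, **kw) -> "ScenarioConfig":
        return replace(self, noise=replace(self.noise, **kw))


@dataclass
class SimulatedDataset:
    """Observed counts plus generating truth for one simulated experiment."""

    promoter_counts: CountMatrix  # X = S + B
    background_counts: CountMatrix  # per-promoter window sums as observed
    window_counts: pd.DataFrame  # per-window draws (windows x samples)
    signal: pd.DataFrame  # true S
    is_dm: pd.Series
    true_fold: pd.Series  # group-B/group-A mean ratio per promoter
    true_mean: pd.Series  # generating signal mean (group A scale)
    config: ScenarioConfig


def default_signal_params(n: int = 6000, seed: int = _FIXTURE_SEED) -> pd.DataFrame:
    """Synthetic promoter-level NB parameter table (mean, dispersion).

    A deterministic stand-in for parameter estimates from a real
    prostate MBDCap-seq library, which are not shipped. The mean scale
    follows typical library arithmetic — ~40M mapped reads per sample
    with roughly a third captured inside the ~33k promoter regions
    gives ~400 reads per promoter — so means are log-normal with
    median 400 and a long right tail; dispersions are log-normal
    centered at 0.2 with the heavy upper tail promoter-level estimates
    show.
    """
    rng = np.random.default_rng(seed)
    means = rng.lognormal(mean=np.log(400.0), sigma=0.8, size=n)
    dispersions = rng.lognormal(mean=np.log(0.20), sigma=0.6, size=n)
    return pd.DataFrame({"mean": means, "dispersion": dispersions})


def build_param_pool(
    table: pd.DataFrame | None = None,
    n: int = 5000,
    seed: int | np.random.Generator = 0,
    min_mean: float = 10.0,
    dispersion_quantile: float = 0.90,
) -> SignalParamPool:
    """Resample a parameter pool after the exclusion rules.

    Promoters with low counts (mean below ``min_mean``) and the top 10%
    of dispersions are discarded; ``n`` rows are then drawn with
    replacement under the seed.
    """
    if table is None:
        table = default_signal_params()
    if len(table) < 100:
        raise ValueError("parameter table must have at least 100 rows")
    rng = np.random.default_rng(seed)
    cutoff = table["dispersion"].quantile(dispersion_quantile)
    kept = table[(table["mean"] >= min_mean) & (table["dispersion"] < cutoff)]
    if kept.empty:
        raise ValueError("exclusion rules removed every promoter")
    idx = rng.integers(0, len(kept), size=n)
    sel = kept.iloc[idx]
    return SignalParamPool(sel["mean"].to_numpy(), sel["dispersion"].to_numpy())


def _nb_draw(rng, mean, dispersion, size):
    """NB draws parameterized by mean and dispersion (var = mu + phi mu^2)."""
    r = 1.0 / dispersion
    p = r / (r + mean)
    return rng.negative_binomial(np.broadcast_to(r, size), np.broadcast_to(p, size))


def simulate_signal(
    pool: SignalParamPool,
    config: ScenarioConfig,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Simulate true signal counts for both groups.

    Returns ``(S, is_dm, fold)`` where S has shape
    (n_promoters, 2 * replicates) with group A in the first
    ``replicates`` columns, ``is_dm`` marks promoters whose group-B mean
    was shifted, and ``fold`` is the applied group-B/group-A mean ratio
    (direction randomized per promoter). ``fold_change == 1`` labels no
    promoter as DM.
    """
    n, m = config.n_promoters, config.replicates
    mean_a = pool.means[:n] if len(pool) >= n else np.resize(pool.means, n)
    disp = pool.dispersions[:n] if len(pool) >= n else np.resize(pool.dispersions, n)
    is_dm = np.zeros(n, dtype=bool)
    fold = np.ones(n)
    if config.dm_fraction > 0 and config.fold_change > 1:
        n_dm = int(round(config.dm_fraction * n))
        chosen = rng.choice(n, size=n_dm, replace=False)
        up = rng.random(n_dm) < 0.5
        fold[chosen] = np.where(up, config.fold_change, 1.0 / config.fold_change)
        is_dm[chosen] = True
    mean_b = mean_a * fold
    if config.signal_distribution == "nb":
        s_a = _nb_draw(rng, mean_a[:, None], disp[:, None], (n, m))
        s_b = _nb_draw(rng, mean_b[:, None], disp[:, None], (n, m))
    elif config.signal_distribution == "normal":
        sd_a = np.sqrt(mean_a + disp * mean_a**2)
        sd_b = np.sqrt(mean_b + disp * mean_b**2)
        s_a = np.rint(np.clip(rng.normal(mean_a[:, None], sd_a[:, None], (n, m)), 0, None))
        s_b = np.rint(np.clip(rng.normal(mean_b[:, None], sd_b[:, None], (n, m)), 0, None))
    else:
        raise ValueError(f"unknown signal distribution {config.signal_distribution!r}")
    s = np.concatenate([s_a, s_b], axis=1).astype(np.int64)
    return s, is_dm, fold


def simulate_window_noise(
    scenario: NoiseScenario,
    n_windows: int,
    m: int,
    rng: np.random.Generator,
    lam: np.ndarray | None = None,
) -> np.ndarray:
    """Per-window background counts from the hybrid noise model.

    For each window and replicate: draw the rate mu ~ Poisson(lambda + NF)
    (or from a normal / uniform law for the robustness variants), then
    B_inc = M * Normal(mu, sigma), truncated at 0 and rounded to the
    nearest integer. ``lam`` gives per-window base rates; by default they
    are drawn once from an exponential law with mean ``lambda_mean``.
    """
    if lam is None:
        lam = rng.exponential(scale=scenario.lambda_mean, size=n_windows)
    lam = np.asarray(lam, dtype=float)
    rate = lam[:, None] + scenario.noise_factor
    shape = (n_windows, m)
    if scenario.distribution == "poisson":
        mu = rng.poisson(np.broadcast_to(rate, shape))
    elif scenario.distribution == "normal":
        mu = np.clip(rng.normal(rate, np.sqrt(np.maximum(rate, 1e-12)), shape), 0, None)
    elif scenario.distribution == "uniform":
        mu = rng.uniform(0.0, 2.0 * np.broadcast_to(rate, shape))
    else:
        raise ValueError(f"unknown noise distribution {scenario.distribution!r}")
    values = scenario.multiplier * rng.normal(mu, scenario.sigma, shape)
    return np.rint(np.clip(values, 0.0, None)).astype(np.int64)


def assemble_dataset(
    signal: np.ndarray,
    window_noise: np.ndarray,
    is_dm: np.ndarray,
    fold: np.ndarray,
    true_mean: np.ndarray,
    config: ScenarioConfig,
    rng: np.random.Generator | None = None,
) -> SimulatedDataset:
    """Combine signal and window noise into an observed dataset.

    Each promoter owns ``windows_per_promoter`` consecutive windows;
    its background B is their column sum and the observed count is
    X = S + B. By default the DM algorithm observes the very window
    draws that compose the truth; with
    ``config.shared_background_draws = False`` an independent set of
    draws (same rates) is exposed instead, which requires ``rng``.
    """
    n, total_reps = signal.shape
    w = config.windows_per_promoter
    if window_noise.shape != (n * w, total_reps):
        raise ValueError("window_noise shape does not match promoters x windows")
    b_prom = window_noise.reshape(n, w, total_reps).sum(axis=1)
    x = signal + b_prom

    m = total_reps // 2
    samples = [f"A{j + 1}" for j in range(m)] + [f"B{j + 1}" for j in range(m)]
    conditions = pd.Series(["A"] * m + ["B"] * m, index=samples)
    promoters = pd.Index([f"prom_{i}" for i in range(n)], name="id")
    window_ids = pd.Index(
        [f"prom_{i}:w{j}" for i in range(n) for j in range(w)], name="id"
    )

    if config.shared_background_draws:
        observed_windows = window_noise
    else:
        if rng is None:
            raise ValueError("independent observation draws require an rng")
        observed_windows = simulate_window_noise(
            config.noise, n * w, total_reps, rng
        )
    b_obs = observed_windows.reshape(n, w, total_reps).sum(axis=1)

    return SimulatedDataset(
        promoter_counts=CountMatrix(
            pd.DataFrame(x, index=promoters, columns=samples), conditions
        ),
        background_counts=CountMatrix(
            pd.DataFrame(b_obs, index=promoters, columns=samples), conditions
        ),
        window_counts=pd.DataFrame(observed_windows, index=window_ids, columns=samples),
        signal=pd.DataFrame(signal, index=promoters, columns=samples),
        is_dm=pd.Series(is_dm, index=promoters, name="is_dm"),
        true_fold=pd.Series(fold, index=promoters, name="fold"),
        true_mean=pd.Series(true_mean, index=promoters, name="true_mean"),
        config=config,
    )


def simulate_dataset(
    config: ScenarioConfig,
    seed: int | np.random.SeedSequence | np.random.Generator,
    pool: SignalParamPool | None = None,
) -> SimulatedDataset:
    """End-to-end generation of one simulated experiment.

    Identical (config, seed) pairs produce bit-identical datasets.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    if pool is None:
        pool = build_param_pool(n=config.n_promoters, seed=rng)
    signal, is_dm, fold = simulate_signal(pool, config, rng)
    n_windows = config.n_promoters * config.windows_per_promoter
    noise = simulate_window_noise(
        config.noise, n_windows, 2 * config.replicates, rng
    )
    true_mean = pool.means[: config.n_promoters]
    return assemble_dataset(signal, noise, is_dm, fold, true_mean, config, rng)
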