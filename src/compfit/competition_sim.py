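"""Forward simulator of the pairwise competition protocol.

Each transfer cycle is modelled at the resolution of the fitted model: a
deterministic selection step p' = p*w / (p*w + 1 - p), then a binomial
bottleneck of ~1000-2000 L1-L2 larvae founding the next plate.  Genomic DNA
is sampled at the measurement generations (every odd generation in the
protocol) and read out through the ddPCR droplet simulator.  Defaults match
the study conditions: p0 = 0.5 (ten L4 founders per strain), seven transfers
at one generation each, bottleneck 1500, measurements at generations
1, 3, 5, 7, ddPCR at occupancy 0.1 with 15000 accepted droplets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import ddpcr
from .selection_model import (
    AlleleTrajectory,
    FitConfig,
    FitnessEstimate,
    UnfittableTrajectoryError,
    fit_relative_fitness,
)


@dataclass(frozen=True)
class CompetitionConfig:
    """Ground truth and protocol parameters for one simulated experiment."""

    p0: float = 0.5
    w_true: float = 1.3
    n_transfers: int = 7
    bottleneck_n: int = 1500
    measurement_generations: tuple = (1, 3, 5, 7)
    droplet_occupancy: float = 0.1
    droplets_total: int = 15000
    n_replicates: int = 4
    seed: int = 0
    drift: bool = True  # False -> infinite-bottleneck limit (no sampling)
    measurement_noise: bool = True  # False -> exact frequencies reported
    pair_label: str = "simulated competition"

    def __post_init__(self):
        if not (0.0 <= self.p0 <= 1.0):
            raise ValueError("p0 must lie in [0, 1]")
        if self.w_true <= 0:
            raise ValueError("w_true must be positive")
        if self.n_transfers < 1:
            raise ValueError("n_transfers must be >= 1")
        if self.bottleneck_n < 2:
            raise ValueError("bottleneck_n must be >= 2")
        gens = tuple(int(g) for g in self.measurement_generations)
        object.__setattr__(self, "measurement_generations", gens)
        if not gens or any(g < 1 or g > self.n_transfers for g in gens):
            raise ValueError(
                "measurement_generations must be a non-empty subset of "
                f"1..{self.n_transfers}"
            )
        if self.droplet_occupancy <= 0:
            raise ValueError("droplet_occupancy must be positive")
        if self.droplets_total < 1:
            raise ValueError("droplets_total must be positive")
        if self.n_replicates < 1:
            raise ValueError("n_replicates must be >= 1")


def simulate_competition(config: CompetitionConfig, rng=None):
    """Simulate all replicates of one competition experiment.

    Returns ``(trajectories, latent)`` where ``trajectories`` is a list of
    :class:`AlleleTrajectory` (one per replicate, measured proportions) and
    ``latent`` a dict replicate_id -> array of true post-bottleneck
    frequencies at generations 1..n_transfers.  Fixation is absorbing.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    trajectories, latent = [], {}
    for r in range(config.n_replicates):
        rep_id = f"rep{r + 1}"
        freqs = _simulate_one_replicate(config, rng)
        latent[rep_id] = freqs
        measured = []
        for g in config.measurement_generations:
            p_true = freqs[g - 1]
            if config.measurement_noise:
                counts = ddpcr.simulate_droplet_readout(
                    p_true, config.droplet_occupancy, config.droplets_total,
                    rng=rng,
                )
                try:
                    p_obs = ddpcr.proportion_from_counts(counts)
                except ValueError:  # no positive droplets at all (tiny p & N)
                    p_obs = p_true
            else:
                p_obs = p_true
            measured.append(p_obs)
        trajectories.append(
            AlleleTrajectory(
                pair_label=config.pair_label,
                replicate_id=rep_id,
                generations=config.measurement_generations,
                proportions=tuple(measured),
            )
        )
    return trajectories, latent


def _simulate_one_replicate(config: CompetitionConfig, rng):
    p = config.p0
    w = config.w_true
    freqs = np.empty(config.n_transfers)
    for g in range(config.n_transfers):
        if p in (0.0, 1.0):  # absorbing
            freqs[g:] = p
            return freqs
        p = p * w / (p * w + (1.0 - p))
        if config.drift:
            p = rng.binomial(config.bottleneck_n, p) / config.bottleneck_n
        freqs[g] = p
    return freqs


@dataclass(frozen=True)
class RecoverySummary:
    """Monte-Carlo summary of how well the fit recovers a known s_true."""

    s_true: float
    n_experiments: int
    mean_s_hat: float
    bias: float
    rmse: float
    ci_coverage: float
    n_failed_fits: int
    s_hats: tuple = field(default=(), repr=False)


def parameter_recovery_experiment(config: CompetitionConfig,
                                  n_experiments: int,
                                  fit_config: FitConfig | None = None,
                                  rng=None) -> RecoverySummary:
    """Repeatedly simulate + fit, and report bias, RMSE and CI coverage of s."""
    if n_experiments < 50:
        raise ValueError("n_experiments must be >= 50")
    if fit_config is None:
        fit_config = FitConfig()
    if rng is None:
        rng = np.random.default_rng(config.seed)
    s_true = config.w_true - 1.0
    s_hats, covered, failed = [], 0, 0
    n_ci = 0
    for _ in range(n_experiments):
        trajectories, _ = simulate_competition(config, rng=rng)
        try:
            est = fit_relative_fitness(trajectories, fit_config)
        except UnfittableTrajectoryError:
            failed += 1
            continue
        s_hats.append(est.s_hat)
        if est.ci_low is not None:
            n_ci += 1
            if est.ci_low <= s_true <= est.ci_high:
                covered += 1
    s_arr = np.asarray(s_hats)
    return RecoverySummary(
        s_true=s_true,
        n_experiments=n_experiments,
        mean_s_hat=float(s_arr.mean()) if len(s_arr) else float("nan"),
        bias=float(s_arr.mean() - s_true) if len(s_arr) else float("nan"),
        rmse=float(np.sqrt(np.mean((s_arr - s_true) ** 2))) if len(s_arr)
        else float("nan"),
        ci_coverage=covered / n_ci if n_ci else float("nan"),
        n_failed_fits=failed,
        s_hats=tuple(float(s) for s in s_arr),
    )


def generate_source_data_table(config: CompetitionConfig, path):
    """Write one simulated experiment as a trajectory CSV and return it.

    The layout (pair_label, replicate_id, generation, proportion; one row
    per measurement) mirrors the published competition source-data tables
    and round-trips losslessly through :func:`compfit.io.read_trajectories`.
    """
    from .io import write_trajectories

    trajectories, _ = simulate_competition(config)
    write_trajectories(trajectories, path, seed=config.seed)
    return trajectories


def with_overrides(config: CompetitionConfig, **kwargs) -> CompetitionConfig:
    """Return a copy of ``config`` with the given fields replaced."""
    return replace(config, **kwargs)
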