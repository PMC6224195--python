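"""Droplet digital PCR: counts -> allele proportions, plus a droplet simulator.

A ddPCR reaction partitions the template into ~10^4 droplets; a droplet is
positive in a channel if it received at least one template of that allele.
The raw count-ratio estimator

    p_hat = n_pos_A / (n_pos_A + n_pos_a)

is the one used for the competition trajectories.  It is unbiased only at
low occupancy (mean templates per droplet << 1): at high occupancy,
positivity saturates and compresses the ratio toward 1/2.  The standard
Poisson occupancy correction, lambda_c = -ln(1 - n_pos_c / n_total), is
provided as the consistent alternative at any occupancy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np


class SaturatedChannelError(ValueError):
    """A channel with every droplet positive has unbounded concentration."""


@dataclass(frozen=True)
class DropletCounts:
    """Positive-droplet counts from one duplex ddPCR reaction.

    A droplet containing templates of both alleles is positive in both
    channels, so n_pos_A + n_pos_a may exceed n_total.
    """

    n_pos_A: int
    n_pos_a: int
    n_total: int
    channel_labels: tuple = ("A", "a")

    def __post_init__(self):
        if self.n_total <= 0:
            raise ValueError("n_total must be positive")
        if self.n_pos_A < 0 or self.n_pos_a < 0:
            raise ValueError("positive-droplet counts must be non-negative")
        if self.n_pos_A > self.n_total or self.n_pos_a > self.n_total:
            raise ValueError("positive droplets cannot exceed total droplets")


def proportion_from_counts(counts: DropletCounts) -> float:
    """Raw count-ratio proportion n_pos_A / (n_pos_A + n_pos_a)."""
    denom = counts.n_pos_A + counts.n_pos_a
    if denom == 0:
        raise ValueError("no positive droplets in either channel; "
                         "proportion undefined")
    return counts.n_pos_A / denom


def poisson_corrected_proportion(counts: DropletCounts) -> float:
    """Occupancy-corrected proportion lambda_A / (lambda_A + lambda_a).

    lambda_c = -ln(1 - n_pos_c / n_total) estimates the mean number of
    templates of allele c per droplet; the ratio of concentrations is a
    consistent estimate of the allele proportion at any occupancy.
    """
    if counts.n_pos_A == counts.n_total or counts.n_pos_a == counts.n_total:
        raise SaturatedChannelError(
            "a channel with all droplets positive cannot be quantified"
        )
    lam_A = -math.log1p(-counts.n_pos_A / counts.n_total)
    lam_a = -math.log1p(-counts.n_pos_a / counts.n_total)
    if lam_A + lam_a == 0.0:
        raise ValueError("no positive droplets in either channel; "
                         "proportion undefined")
    return lam_A / (lam_A + lam_a)


def simulate_droplet_readout(true_p, mean_templates_per_droplet, n_total,
                             rng=None) -> DropletCounts:
    """Simulate one duplex ddPCR readout.

    Each droplet receives Poisson(mean_templates_per_droplet) templates, each
    independently allele A with probability ``true_p``.  By Poisson thinning
    the per-droplet template counts of the two alleles are independent
    Poissons with means lambda*p and lambda*(1-p), so channel positivity is
    independent across channels and the counts are exactly

        n_pos_c ~ Binomial(n_total, 1 - exp(-lambda * p_c)).

    ``rng`` is an integer seed or a numpy Generator.
    """
    if not (0.0 <= true_p <= 1.0):
        raise ValueError("true_p must lie in [0, 1]")
    if mean_templates_per_droplet <= 0:
        raise ValueError("mean_templates_per_droplet must be positive")
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    rng = np.random.default_rng(rng)
    lam = mean_templates_per_droplet
    prob_A = -math.expm1(-lam * true_p)
    prob_a = -math.expm1(-lam * (1.0 - true_p))
    n_pos_A = int(rng.binomial(n_total, prob_A))
    n_pos_a = int(rng.binomial(n_total, prob_a))
    return DropletCounts(n_pos_A=n_pos_A, n_pos_a=n_pos_a, n_total=n_total)
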