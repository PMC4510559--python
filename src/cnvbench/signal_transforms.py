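"""SNP-array signal transforms: the theta transform, B-allele fraction and
log-2 ratio.

SNP arrays measure two channel intensities per marker, one per allele
(``R_A``, ``R_B``).  The theta transform maps the channel ratio onto [0, 1];
the B-allele fraction (BAF) rescales theta by piecewise-linear interpolation
between the genotype-cluster medians (theta_AA, theta_AB, theta_BB) so that
the three canonical genotypes land at 0, 0.5 and 1.  The log-2 ratio (LRR)
compares total observed intensity to its expectation and is negative under
deletions, positive under duplications.

Note on orientation: the transform is written here as
``2/pi * arctan(R_A / R_B)``, which *increases* with the A-allele signal,
while BAF interpolation requires theta to increase from the AA to the BB
cluster.  The two conventions are mutually inconsistent; the ``orientation``
flag makes the choice explicit (``"a_over_b"``, the default as written, or
``"b_over_a"``, the convention under which theta_AA < theta_BB naturally
holds) rather than silently correcting either.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ChannelIntensities",
    "GenotypeClusterMedians",
    "theta",
    "baf",
    "log2_ratio",
]


@dataclass(frozen=True)
class ChannelIntensities:
    """Raw two-channel signal intensities for one marker (arbitrary units)."""

    R_A: float
    R_B: float

    def __post_init__(self) -> None:
        if self.R_A < 0 or self.R_B < 0:
            raise ValueError("channel intensities must be non-negative")
        if self.R_A == 0 and self.R_B == 0:
            raise ValueError("both channel intensities are zero")


@dataclass(frozen=True)
class GenotypeClusterMedians:
    """Per-marker median theta of the three canonical genotype clusters."""

    theta_AA: float
    theta_AB: float
    theta_BB: float

    def __post_init__(self) -> None:
        if not (self.theta_AA < self.theta_AB < self.theta_BB):
            raise ValueError(
                "cluster medians must satisfy theta_AA < theta_AB < theta_BB, got "
                f"({self.theta_AA}, {self.theta_AB}, {self.theta_BB})"
            )


def theta(
    ch: ChannelIntensities | tuple[float, float],
    orientation: str = "a_over_b",
):
    """Theta transform 2/pi * arctan of the channel ratio, in [0, 1].

    ``orientation`` selects the numerator channel: ``"a_over_b"`` computes
    2/pi*arctan(R_A/R_B), ``"b_over_a"`` computes 2/pi*arctan(R_B/R_A).  A
    zero denominator is handled by the arctan limit (theta -> 1); both
    channels zero is an error (raised by ChannelIntensities).
    """
    if not isinstance(ch, ChannelIntensities):
        ch = ChannelIntensities(*ch)
    if orientation == "a_over_b":
        num, den = ch.R_A, ch.R_B
    elif orientation == "b_over_a":
        num, den = ch.R_B, ch.R_A
    else:
        raise ValueError(f"orientation must be 'a_over_b' or 'b_over_a', got {orientation!r}")
    # arctan2 realizes the arctan(num/den) limit num>0, den=0 -> pi/2 exactly
    return float(2.0 / np.pi * np.arctan2(num, den))


def baf(theta_obs, clusters: GenotypeClusterMedians):
    """B-allele fraction by piecewise-linear interpolation of theta.

    0 below the AA cluster; linear 0 -> 0.5 on [theta_AA, theta_AB]; linear
    0.5 -> 1 on [theta_AB, theta_BB]; 1 above the BB cluster.  The cluster
    medians themselves map to exactly 0, 0.5 and 1, and the function is
    continuous and monotone non-decreasing.  Accepts scalars or arrays.
    """
    xp = [clusters.theta_AA, clusters.theta_AB, clusters.theta_BB]
    result = np.interp(theta_obs, xp, [0.0, 0.5, 1.0])
    if np.isscalar(theta_obs):
        return float(result)
    return result


def log2_ratio(R_obs, R_exp):
    """Log-2 ratio of observed vs expected total intensity.

    Returns log2(R_obs) - log2(R_exp); inputs must be strictly positive.
    Accepts scalars or arrays.
    """
    R_obs_arr = np.asarray(R_obs, dtype=float)
    R_exp_arr = np.asarray(R_exp, dtype=float)
    if np.any(R_obs_arr <= 0) or np.any(R_exp_arr <= 0):
        raise ValueError("log2_ratio requires strictly positive intensities")
    result = np.log2(R_obs_arr) - np.log2(R_exp_arr)
    if np.isscalar(R_obs) and np.isscalar(R_exp):
        return float(result)
    return result
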