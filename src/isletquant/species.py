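"""Species islet-size profiles and the diameter distribution they imply.

Profiles carry the published diameter range and mean ± sd for isolated islets
of each species.  The generator models diameters as a lognormal matched by
moments to (mean_d, sd_d) — right-skewed with positive support, consistent
with preparations in which a few large islets dominate the volume — truncated
to the reported range.
"""

from __future__ import annotations

import importlib.resources
import math
from dataclasses import dataclass
from functools import lru_cache
from typing import Optional

import numpy as np
import yaml
from scipy import integrate, stats


class ProfileError(ValueError):
    """A species profile cannot support the requested operation."""


@dataclass(frozen=True)
class SpeciesProfile:
    """Published islet-size summary for one species (lengths in μm)."""

    species: str
    d_min: Optional[float]
    d_max: Optional[float]
    mean_d: Optional[float]
    sd_d: Optional[float]

    def __post_init__(self) -> None:
        if self.d_min is not None and self.d_max is not None and not self.d_min < self.d_max:
            raise ValueError(f"{self.species}: require d_min < d_max")
        if self.sd_d is not None and not self.sd_d > 0:
            raise ValueError(f"{self.species}: sd_d must be > 0")

    def sampling_range(self) -> tuple[float, float]:
        """Truncation range for sampling; falls back to mean ± 6 sd if unreported."""
        if self.mean_d is None or self.sd_d is None:
            raise ProfileError(
                f"{self.species}: no mean/sd on record; supply them explicitly to sample"
            )
        lo = self.d_min if self.d_min is not None else max(1.0, self.mean_d - 6 * self.sd_d)
        hi = self.d_max if self.d_max is not None else self.mean_d + 6 * self.sd_d
        if not lo < self.mean_d < hi:
            raise ProfileError(f"{self.species}: mean_d must lie inside the range")
        return lo, hi


def lognormal_params(mean: float, sd: float) -> tuple[float, float]:
    """(μ, σ) of the lognormal with the given arithmetic mean and sd."""
    sigma2 = math.log1p((sd / mean) ** 2)
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def diameter_distribution(profile: SpeciesProfile):
    """Frozen scipy lognormal matched by moments to the profile (untruncated).

    Raises :class:`ProfileError` if the truncation range would discard most of
    the distribution's mass (sd too large for the reported range).
    """
    lo, hi = profile.sampling_range()
    mu, sigma = lognormal_params(profile.mean_d, profile.sd_d)
    dist = stats.lognorm(s=sigma, scale=math.exp(mu))
    mass = dist.cdf(hi) - dist.cdf(lo)
    if mass < 0.5:
        raise ProfileError(
            f"{profile.species}: sd_d={profile.sd_d} keeps only {mass:.0%} of mass "
            f"inside [{lo}, {hi}] — infeasible moment match"
        )
    return dist


def truncated_moment(profile: SpeciesProfile, p: float) -> float:
    """E[d^p] under the profile's truncated lognormal (numerical quadrature)."""
    lo, hi = profile.sampling_range()
    dist = diameter_distribution(profile)
    mass = dist.cdf(hi) - dist.cdf(lo)
    val, _ = integrate.quad(lambda d: d**p * dist.pdf(d), lo, hi, limit=200)
    return val / mass


def sample_diameters(profile: SpeciesProfile, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n diameters from the truncated lognormal by rejection."""
    lo, hi = profile.sampling_range()
    dist = diameter_distribution(profile)
    out = np.empty(0)
    while out.size < n:
        draw = dist.rvs(size=max(n, 2 * (n - out.size)), random_state=rng)
        out = np.concatenate([out, draw[(draw >= lo) & (draw <= hi)]])
    return out[:n]


@lru_cache(maxsize=1)
def species_registry() -> dict[str, SpeciesProfile]:
    """Profiles shipped with the package, keyed by species label."""
    text = (
        importlib.resources.files("isletquant").joinpath("data/species.yaml").read_text()
    )
    raw = yaml.safe_load(text)
    return {
        name: SpeciesProfile(species=name, **fields) for name, fields in raw.items()
    }


def get_profile(species: str) -> SpeciesProfile:
    reg = species_registry()
    try:
        return reg[species]
    except KeyError:
        raise KeyError(
            f"unknown species {species!r}; known: {', '.join(sorted(reg))}"
        ) from None
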