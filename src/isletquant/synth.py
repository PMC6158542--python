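"""Ground-truth islet prep generator with the documented measurement flaws.

This module produces synthetic preparations whose every true quantity is
known — diameters, ellipsoid axes, projected outline area/perimeter,
dissociated cell counts, purity — so that the counting procedures in the rest
of the package can be tested against an exact oracle.  Three documented
sources of error are modelled explicitly:

* **Shape**: islets are triaxial ellipsoids, axis ratios drawn around
  b/a = 0.82 and c/a = 0.70, and their 2-D projections carry boundary
  roughness calibrated so mean circularity is 0.801 for small islets
  (< 125 μm) and 0.740 for large ones.
* **Technician binning bias**: a technician model mis-assigns islets one
  50 μm bin up or down; at its default calibration the expected batch IEQ
  shift is zero, so roughly half of replicate counts overestimate the truth —
  the behaviour documented across clinical counting sites.
* **Settling-biased aliquots**: islets settle quickly, so a pipetted aliquot
  over-samples large islets; sampling weight ∝ d^bias, bias 0 = uniform.

Diameters are lognormal, matched by moments to the species profile and
truncated to its range.  A single seed drives everything; each stochastic
stage derives its own child stream, so preps are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from functools import lru_cache
from typing import Optional, Sequence

import numpy as np
from scipy import optimize, special, stats

from .cellnum import CalibrationCurve, DissociationRecord, default_curve
from .ieq import EXCLUDED, BinningScheme, assign_bin
from .morphometry import IsletBatch, IsletRecord, IsletShape
from .species import SpeciesProfile, get_profile, sample_diameters

# ---------------------------------------------------------------------------
# projected-ellipse geometry

_MIN_RATIO = 0.05


def ellipse_perimeter(a: float, b: float) -> float:
    """Exact perimeter of an ellipse with full axes a >= b (elliptic integral)."""
    if not (a >= b > 0):
        raise ValueError("require a >= b > 0")
    m = 1.0 - (b / a) ** 2
    return 2.0 * a * special.ellipe(m)


def ellipse_circularity(q) -> np.ndarray | float:
    """Circularity 4πA/P² of an ellipse with axis ratio q = b/a in (0, 1]."""
    q = np.asarray(q, dtype=float)
    m = 1.0 - q**2
    peri = 2.0 * special.ellipe(m)  # per unit full major axis
    out = 4.0 * math.pi * (math.pi * q / 4.0) / peri**2
    return out if out.shape else float(out)


# ---------------------------------------------------------------------------
# shape model and its roughness calibration

_GH_NODES, _GH_WEIGHTS = np.polynomial.hermite.hermgauss(64)


def _gh_expect(f, mean: float, sd: float) -> float:
    """E[f(X)] for X ~ N(mean, sd) by Gauss–Hermite quadrature."""
    x = mean + math.sqrt(2.0) * sd * _GH_NODES
    return float(np.sum(_GH_WEIGHTS * f(x)) / math.sqrt(math.pi))


def _roughness_factor_expectation(m: float) -> float:
    """E[(1 + m·|ε|)⁻²] for ε ~ N(0,1): mean circularity attenuation."""
    x = math.sqrt(2.0) * _GH_NODES
    return float(np.sum(_GH_WEIGHTS * (1.0 + m * np.abs(x)) ** -2) / math.sqrt(math.pi))


@dataclass(frozen=True)
class ShapeModel:
    """Ellipsoid axis-ratio and projected-roughness model.

    Axis ratios b/a and c/a are independent normals (clipped to
    (0.05, 1]); the larger of the two draws becomes b/a so that a ≥ b ≥ c.
    Projected outlines are the (a, b) ellipse with a multiplicative
    perimeter roughness 1 + m·|ε|, ε ~ N(0,1); the magnitude m is solved
    numerically per size class so the expected mean circularity hits the
    class target.
    """

    mean_ba: float = 0.82
    mean_ca: float = 0.70
    ratio_sd: float = 0.05
    circ_small: float = 0.801
    circ_large: float = 0.740
    size_cutoff: float = 125.0

    def __post_init__(self) -> None:
        for name, v in [("mean_ba", self.mean_ba), ("mean_ca", self.mean_ca)]:
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        for name, v in [("circ_small", self.circ_small), ("circ_large", self.circ_large)]:
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1], got {v}")
        if not self.ratio_sd >= 0:
            raise ValueError("ratio_sd must be >= 0")

    def expected_ellipse_circularity(self) -> float:
        """E[circularity] of the projected ellipse before roughness."""
        return _expected_ellipse_circ(self.mean_ba, self.mean_ca, self.ratio_sd)

    def roughness_magnitude(self, size_class: str) -> float:
        """Perimeter roughness magnitude m calibrated for 'small' or 'large'."""
        target = {"small": self.circ_small, "large": self.circ_large}[size_class]
        return _solve_roughness(self.mean_ba, self.mean_ca, self.ratio_sd, target)


@lru_cache(maxsize=None)
def _expected_ellipse_circ(mean_ba: float, mean_ca: float, ratio_sd: float) -> float:
    if ratio_sd == 0:
        return ellipse_circularity(np.clip(max(mean_ba, mean_ca), _MIN_RATIO, 1.0))
    # 2-D quadrature over the two ratio draws; projection ratio is the max.
    xb = mean_ba + math.sqrt(2.0) * ratio_sd * _GH_NODES
    xc = mean_ca + math.sqrt(2.0) * ratio_sd * _GH_NODES
    q = np.clip(np.maximum(xb[:, None], xc[None, :]), _MIN_RATIO, 1.0)
    w = _GH_WEIGHTS[:, None] * _GH_WEIGHTS[None, :]
    return float(np.sum(w * ellipse_circularity(q)) / math.pi)


@lru_cache(maxsize=None)
def _solve_roughness(mean_ba: float, mean_ca: float, ratio_sd: float, target: float) -> float:
    base = _expected_ellipse_circ(mean_ba, mean_ca, ratio_sd)
    if target > base:
        raise ValueError(
            f"target circularity {target} exceeds smooth-ellipse mean {base:.3f}"
        )
    if math.isclose(target, base):
        return 0.0
    return float(
        optimize.brentq(
            lambda m: base * _roughness_factor_expectation(m) - target, 0.0, 50.0
        )
    )


def sample_shapes(
    diameters: np.ndarray, model: ShapeModel, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Draw axes and projected outline for each diameter.

    Returns (a, b, c, area, perimeter).  The representative diameter is the
    arithmetic mean of the three axes, so a = 3d/(1 + b/a + c/a).  Projected
    area is the exact (a, b)-ellipse area; the perimeter carries the
    calibrated boundary roughness for the islet's size class.
    """
    d = np.asarray(diameters, dtype=float)
    n = d.size
    rb = np.clip(rng.normal(model.mean_ba, model.ratio_sd, n), _MIN_RATIO, 1.0)
    rc = np.clip(rng.normal(model.mean_ca, model.ratio_sd, n), _MIN_RATIO, 1.0)
    r1 = np.maximum(rb, rc)  # b/a
    r2 = np.minimum(rb, rc)  # c/a
    a = 3.0 * d / (1.0 + r1 + r2)
    b = a * r1
    c = a * r2

    area = math.pi * a * b / 4.0
    peri_smooth = 2.0 * a * special.ellipe(1.0 - r1**2)
    m = np.where(
        d < model.size_cutoff,
        model.roughness_magnitude("small"),
        model.roughness_magnitude("large"),
    )
    rough = 1.0 + m * np.abs(rng.standard_normal(n))
    return a, b, c, area, peri_smooth * rough


# ---------------------------------------------------------------------------
# ground-truth preparation

@dataclass(frozen=True)
class GroundTruthPrep:
    """A synthetic prep with every per-islet truth known."""

    species: str
    diameters: np.ndarray
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    areas: np.ndarray
    perimeters: np.ndarray
    cells: np.ndarray
    purity: float
    seed: Optional[int] = None

    @property
    def n(self) -> int:
        return int(self.diameters.size)

    @property
    def circularities(self) -> np.ndarray:
        return np.minimum(1.0, 4.0 * math.pi * self.areas / self.perimeters**2)

    def to_batch(self) -> IsletBatch:
        records = [
            IsletRecord(
                id=f"islet{i}",
                diameter=float(self.diameters[i]),
                shape=IsletShape(float(self.a[i]), float(self.b[i]), float(self.c[i])),
                area=float(self.areas[i]),
                perimeter=float(self.perimeters[i]),
                cell_count=int(self.cells[i]),
            )
            for i in range(self.n)
        ]
        return IsletBatch(records=records, species=self.species)

    def subset(self, idx: np.ndarray) -> "GroundTruthPrep":
        return replace(
            self,
            diameters=self.diameters[idx],
            a=self.a[idx],
            b=self.b[idx],
            c=self.c[idx],
            areas=self.areas[idx],
            perimeters=self.perimeters[idx],
            cells=self.cells[idx],
        )


def sample_prep(
    profile: SpeciesProfile | str,
    n: int,
    shape: ShapeModel = ShapeModel(),
    curve: Optional[CalibrationCurve] = None,
    purity: float = 1.0,
    seed: Optional[int] = None,
) -> GroundTruthPrep:
    """Generate a ground-truth prep of ``n`` islets for one species.

    Dissociated cell counts are Poisson with mean given by the calibration
    curve (default: the species default curve if one exists, else the rat
    curve).  All randomness derives from ``seed`` via independent child
    streams per stage, so identical seeds give identical preps.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if not 0 < purity <= 1:
        raise ValueError(f"purity must be in (0, 1], got {purity}")
    if isinstance(profile, str):
        profile = get_profile(profile)
    if curve is None:
        try:
            curve = default_curve(profile.species)
        except KeyError:
            curve = default_curve("rat")

    ss = np.random.SeedSequence(seed)
    rng_d, rng_shape, rng_cells = (np.random.default_rng(s) for s in ss.spawn(3))
    d = sample_diameters(profile, n, rng_d)
    a, b, c, area, peri = sample_shapes(d, shape, rng_shape)
    cells = rng_cells.poisson(np.asarray(curve.expected_cells(d), dtype=float))
    return GroundTruthPrep(
        species=profile.species,
        diameters=d,
        a=a,
        b=b,
        c=c,
        areas=area,
        perimeters=peri,
        cells=cells,
        purity=purity,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# technician mis-binning

@dataclass(frozen=True)
class TechnicianModel:
    """Per-islet probability of assigning the next-larger or -smaller bin."""

    p_upbin: float = 0.0
    p_downbin: float = 0.0
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.p_upbin < 0 or self.p_downbin < 0 or self.p_upbin + self.p_downbin > 1:
            raise ValueError("require p_upbin, p_downbin >= 0 and p_upbin + p_downbin <= 1")


def _bin_shift_deltas(
    diameters: Sequence[float], scheme: BinningScheme
) -> tuple[float, float]:
    """Total IEQ gain if every islet shifted one bin up, and loss if down."""
    labels = scheme.labels()
    factors = [scheme.factor(lab) for lab in labels]
    index = {lab: i for i, lab in enumerate(labels)}
    gain = loss = 0.0
    for d in diameters:
        lab = assign_bin(float(d), scheme)
        if lab == EXCLUDED:
            continue
        k = index[lab]
        if k + 1 < len(labels):
            gain += factors[k + 1] - factors[k]
        if k - 1 >= 0:
            loss += factors[k] - factors[k - 1]
    return gain, loss


def calibrate_technician(
    prep: GroundTruthPrep,
    scheme: BinningScheme = BinningScheme(),
    total_misbin: float = 0.4,
    seed: Optional[int] = None,
) -> TechnicianModel:
    """Default technician calibration: zero expected batch IEQ shift.

    The total mis-binning rate is split between up and down so that the
    expected IEQ change of a replicate count is zero; because a replicate's
    IEQ error is then a near-symmetric sum of many small per-islet shifts,
    about half of replicate counts overestimate the truth.
    """
    if not 0 < total_misbin <= 1:
        raise ValueError("total_misbin must be in (0, 1]")
    gain, loss = _bin_shift_deltas(prep.diameters, scheme)
    if gain + loss == 0:
        p_up = total_misbin / 2.0
    else:
        p_up = total_misbin * loss / (gain + loss)
    return TechnicianModel(p_upbin=p_up, p_downbin=total_misbin - p_up, seed=seed)


def simulate_technician_binning(
    prep: GroundTruthPrep,
    scheme: BinningScheme = BinningScheme(),
    tech: TechnicianModel = TechnicianModel(),
    rng: Optional[np.random.Generator] = None,
) -> list[str]:
    """Per-islet bin labels after simulated technician mis-assignment.

    Each islet's true bin is moved one bin up with probability ``p_upbin``
    and one down with ``p_downbin``; shifts past the lowest or top bin leave
    the islet where it is.  Excluded islets stay excluded.
    """
    if rng is None:
        rng = np.random.default_rng(tech.seed)
    labels = scheme.labels()
    index = {lab: i for i, lab in enumerate(labels)}
    u = rng.random(prep.n)
    out: list[str] = []
    for i, d in enumerate(prep.diameters):
        lab = assign_bin(float(d), scheme)
        if lab == EXCLUDED:
            out.append(lab)
            continue
        k = index[lab]
        if u[i] < tech.p_upbin:
            k = min(k + 1, len(labels) - 1)
        elif u[i] < tech.p_upbin + tech.p_downbin:
            k = max(k - 1, 0)
        out.append(labels[k])
    return out


# ---------------------------------------------------------------------------
# settling-biased aliquot sampling

def simulate_aliquot(
    prep: GroundTruthPrep,
    fraction: float,
    settling_bias: float = 0.0,
    seed: Optional[int] = None,
) -> GroundTruthPrep:
    """Sample an aliquot without replacement, weight ∝ diameter^settling_bias.

    ``settling_bias = 0`` is unbiased pipetting; positive values over-sample
    large (fast-settling) islets.  Implemented as Gumbel-perturbed weighted
    order sampling, equivalent to drawing islets one at a time with
    probability proportional to weight.
    """
    if not 0 < fraction < 1:
        raise ValueError(f"fraction must be in (0, 1), got {fraction}")
    rng = np.random.default_rng(seed)
    k = max(1, round(fraction * prep.n))
    logw = settling_bias * np.log(prep.diameters)
    keys = logw + rng.gumbel(size=prep.n)
    idx = np.sort(np.argpartition(-keys, k - 1)[:k])
    return prep.subset(idx)


# ---------------------------------------------------------------------------
# simulated dissociation experiment

def dissociation_experiment(
    prep: GroundTruthPrep,
    scheme: BinningScheme = BinningScheme(),
    tech: Optional[TechnicianModel] = None,
    rng: Optional[np.random.Generator] = None,
) -> list[DissociationRecord]:
    """Pair each islet's true cell count with its (possibly mis-)binned diameter.

    The binned diameter is the assigned bin's midpoint.  Islets excluded by
    the scheme are dropped, as they were from the bench procedure.
    """
    if tech is None:
        labels = [assign_bin(float(d), scheme) for d in prep.diameters]
    else:
        labels = simulate_technician_binning(prep, scheme, tech, rng=rng)
    midpoints = {lab: (lo + hi) / 2.0 for lab, lo, hi in scheme.intervals()}
    out = []
    for i, lab in enumerate(labels):
        if lab == EXCLUDED:
            continue
        out.append(
            DissociationRecord(
                islet_id=f"islet{i}",
                diameter=float(prep.diameters[i]),
                cells=int(prep.cells[i]),
                binned_diameter=midpoints[lab],
            )
        )
    return out
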