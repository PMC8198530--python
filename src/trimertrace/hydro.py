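"""Scalar hydrodynamics and size-distribution statistics.

Stokes-Einstein conversions between translational diffusion coefficient and
hydrodynamic radius, the equivalent hydrated-sphere diameter of a protein of
given molecular weight, particle dispersity and Gaussian fits of DLS-style
size distributions, and the mass-action trimer-monomer equilibrium.

Unit conventions: SI for the hydrodynamic quantities (m^2/s, K, Pa*s, m),
nanometres for particle diameters, molar for concentrations. Temperatures in
Celsius are converted as K = degC + 273.15.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq, curve_fit

from trimertrace.errors import ValidationError

logger = logging.getLogger(__name__)

#: Boltzmann constant, J/K (2019 SI exact value).
K_B = 1.380649e-23
#: Avogadro constant, 1/mol (2019 SI exact value).
N_A = 6.02214076e23


def celsius_to_kelvin(t_celsius: float) -> float:
    return t_celsius + 273.15


@dataclass(frozen=True)
class HydroParams:
    """Inputs of the Stokes-Einstein relation D = k_B T / (6 pi eta R_H).

    Attributes
    ----------
    d_diff : translational diffusion coefficient, m^2/s
    temperature : absolute temperature, K
    viscosity : solvent dynamic viscosity, Pa*s (never looked up silently;
        the caller supplies the value appropriate for the temperature)
    """

    d_diff: float
    temperature: float
    viscosity: float

    def __post_init__(self):
        for name in ("d_diff", "temperature", "viscosity"):
            value = getattr(self, name)
            if not np.isfinite(value) or value <= 0:
                raise ValidationError(
                    f"{name} must be positive and finite, got {value!r}", field=name
                )


def hydrodynamic_radius(params: HydroParams) -> float:
    """Hydrodynamic radius in metres from the Stokes-Einstein relation.

    R_H is the radius of the sphere with the same translational diffusion
    coefficient as the particle: R_H = k_B T / (6 pi eta D).
    """
    return K_B * params.temperature / (6.0 * np.pi * params.viscosity * params.d_diff)


def diffusion_from_radius(r_h: float, temperature: float, viscosity: float) -> float:
    """Inverse of :func:`hydrodynamic_radius`: D from R_H (metres)."""
    if r_h <= 0:
        raise ValidationError("r_h must be positive", field="r_h")
    params = HydroParams(d_diff=1.0, temperature=temperature, viscosity=viscosity)
    return K_B * params.temperature / (6.0 * np.pi * params.viscosity * r_h)


def equivalent_sphere_diameter(
    molecular_weight: float,
    partial_specific_volume: float = 0.73,
    hydration: float = 0.35,
) -> float:
    """Diameter (nm) of the hydrated sphere equivalent to a protein of given mass.

    The hydrated volume per gram is v_bar + delta * v_w with v_w = 1 cm^3/g
    for the bound water; the sphere of that volume for one molecule of
    ``molecular_weight`` Da has diameter

        d = 2 * (3 M (v_bar + delta) / (4 pi N_A))^(1/3).

    Defaults v_bar = 0.73 cm^3/g and delta = 0.35 g water / g protein are the
    textbook values for globular proteins.
    """
    if molecular_weight <= 0:
        raise ValidationError("molecular_weight must be positive", field="molecular_weight")
    if partial_specific_volume <= 0:
        raise ValidationError(
            "partial_specific_volume must be positive", field="partial_specific_volume"
        )
    if hydration < 0:
        raise ValidationError("hydration must be non-negative", field="hydration")
    v_w = 1.0  # cm^3/g, specific volume of bound water
    volume_cm3 = molecular_weight * (partial_specific_volume + hydration * v_w) / N_A
    radius_cm = (3.0 * volume_cm3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    return 2.0 * radius_cm * 1e7  # cm -> nm


class SizeDistribution:
    """A DLS-style particle size distribution: diameter bins with percent weights.

    ``frequencies`` follow the percent convention: they sum to 100, and the
    moment formulas divide by 100 accordingly. Distributions whose weights sum
    to 100 within 0.5 are accepted as-is; anything else positive is
    renormalized with a logged warning.
    """

    def __init__(self, diameters_nm, frequencies):
        diameters = np.asarray(diameters_nm, dtype=float)
        freqs = np.asarray(frequencies, dtype=float)
        if diameters.ndim != 1 or diameters.shape != freqs.shape:
            raise ValidationError(
                "diameters and frequencies must be 1-D arrays of equal length",
                field="frequencies",
            )
        if diameters.size == 0:
            raise ValidationError("distribution is empty", field="diameters_nm")
        if np.any(np.diff(diameters) <= 0):
            raise ValidationError(
                "diameters must be strictly increasing", field="diameters_nm"
            )
        if np.any(freqs < 0):
            raise ValidationError("frequencies must be non-negative", field="frequencies")
        total = freqs.sum()
        if total <= 0:
            raise ValidationError("frequencies sum to zero", field="frequencies")
        if abs(total - 100.0) > 0.5:
            logger.warning(
                "frequencies sum to %.3f, renormalizing to the percent convention", total
            )
            freqs = freqs * (100.0 / total)
        self.diameters_nm = diameters
        self.frequencies = freqs

    @property
    def mean_diameter(self) -> float:
        """<D> = sum_i D_i q(i) / 100, nm."""
        return float(np.sum(self.diameters_nm * self.frequencies) / 100.0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"diameter_nm": self.diameters_nm, "percent": self.frequencies}
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "SizeDistribution":
        df = pd.read_csv(path, sep=None, engine="python")
        if df.shape[1] < 2:
            raise ValidationError("expected two columns: diameter_nm, percent")
        return cls(df.iloc[:, 0].to_numpy(), df.iloc[:, 1].to_numpy())


def particle_dispersity(dist: SizeDistribution) -> float:
    """Heterogeneity index of a size distribution.

    dispersity = sum_i (D_i - <D>)^2 q(i)/100 / <D>^2 -- the variance of the
    distribution normalized by the squared mean diameter, by analogy with the
    mass dispersity of polymer science. Zero for a monodisperse sample; scale
    invariant under a common rescaling of all diameters.
    """
    mean = dist.mean_diameter
    if mean == 0:
        raise ValidationError("mean diameter is zero", field="diameters_nm")
    variance = float(
        np.sum((dist.diameters_nm - mean) ** 2 * dist.frequencies) / 100.0
    )
    return variance / mean**2


@dataclass(frozen=True)
class GaussianFitResult:
    mean: float  # nm
    sigma: float  # nm
    variance: float  # nm^2
    amplitude: float  # percent at the mode
    residual: float  # root-mean-square fit residual, percent units


def gaussian_fit(dist: SizeDistribution) -> GaussianFitResult:
    """Least-squares Gaussian profile fit to a size histogram.

    Fits a * exp(-(D - mu)^2 / (2 sigma^2)) to the (diameter, percent) pairs
    and reports the fitted mean and variance, the conventional way DLS mean
    diameters and widths are quoted.
    """
    nonzero = int(np.count_nonzero(dist.frequencies))
    if nonzero < 4:
        raise ValidationError(
            "need at least 4 bins with nonzero frequency for a Gaussian fit; "
            "for near-degenerate histograms use particle_dispersity instead",
            field="frequencies",
        )
    d, q = dist.diameters_nm, dist.frequencies
    # moment-based starting point
    mu0 = dist.mean_diameter
    var0 = max(float(np.sum((d - mu0) ** 2 * q) / 100.0), 1e-6)
    p0 = (float(q.max()), mu0, np.sqrt(var0))

    def profile(x, a, mu, sigma):
        return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))

    popt, _ = curve_fit(profile, d, q, p0=p0, maxfev=20000)
    a, mu, sigma = popt
    sigma = abs(float(sigma))
    resid = float(np.sqrt(np.mean((profile(d, *popt) - q) ** 2)))
    return GaussianFitResult(
        mean=float(mu), sigma=sigma, variance=sigma**2, amplitude=float(a), residual=resid
    )


@dataclass(frozen=True)
class EquilibriumResult:
    k_d: float  # M^2, dissociation constant of 3M <-> T written as [M]^3/[T]
    total_monomer: float  # M, total protein expressed as monomer equivalents
    free_monomer: float  # M
    trimer: float  # M (molar concentration of trimer particles)
    trimer_fraction: float  # mass fraction of monomer units bound in trimers


def trimer_fraction(k_d: float, total_monomer: float) -> EquilibriumResult:
    """Fraction of protein mass in trimers for the single-step 3M <-> T model.

    Mass action with K_d = [M]^3 / [T] (units M^2) and the mass balance
    [M] + 3[T] = c gives [M]^3 = K_d (c - [M]) / 3, solved for the free
    monomer concentration by bracketed root finding on [0, c]. The returned
    fraction is 3[T]/c, i.e. the mass (monomer-unit) fraction in trimers.
    The fraction is strictly decreasing in K_d and increasing in c.
    """
    if k_d <= 0:
        raise ValidationError("k_d must be positive", field="k_d")
    if total_monomer <= 0:
        raise ValidationError("total_monomer must be positive", field="total_monomer")
    c = total_monomer

    def f(m):
        return m**3 - k_d * (c - m) / 3.0

    # f(0) = -K_d c / 3 < 0, f(c) = c^3 > 0: a root is bracketed
    m = brentq(f, 0.0, c, xtol=1e-300, rtol=8.9e-16, maxiter=200)
    trimer = (c - m) / 3.0
    return EquilibriumResult(
        k_d=k_d,
        total_monomer=c,
        free_monomer=m,
        trimer=trimer,
        trimer_fraction=(c - m) / c,
    )
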