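"""Bonded-parameter extraction from atomistic bond/angle distributions.

Coarse-grained bonded terms are harmonic in bond length,

    V_bond(R) = 1/2 K_bond (R - R_bond)^2 ,

and cosine-harmonic in the angle,

    V_angle(theta) = 1/2 K_angle (cos theta - cos theta_0)^2 .

At temperature T the Boltzmann-weighted probability of a multi-state degree
of freedom is a sum of Gaussian components,

    P(x) = sum_i A_i exp(-V_i(x) / k_B T) ,

each with variance k_B T / K_i in the coordinate where the potential is
harmonic (bond length R for bonds, cos theta for angles).  The pipeline here
fits up to three such components to an observed distribution, weights them by
their analytic areas w_i = S_i / sum S_i, drops negligible components
(K_i < 1 in native units, w_i < 0.1%), and reduces the mixture to one
single-peak parameter set via

    equilibrium = sum_i w_i x0_i ,    1/K = sum_i w_i / K_i

(weighted harmonic mean of the force constants).  Angle fitting happens in
cos-space, where the Boltzmann form is exactly Gaussian; equilibrium angles
are averaged in degrees after back-conversion.

``k_B`` follows the MD-engine convention of being the gas constant
R = 8.314 J mol^-1 K^-1, so force constants come out in kJ/mol units.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Optional, Sequence, Union

import numpy as np
from scipy.optimize import curve_fit

from .polymer_graph import AngleType, BondType, PolymerGraph

__all__ = [
    "KB",
    "DEFAULT_TEMPERATURE",
    "DistributionSample",
    "GaussianPeak",
    "BondedParam",
    "ParamTable",
    "fit_peaks",
    "peak_weights",
    "reduce_peaks",
    "sample_synthetic_distribution",
    "evaluate_potential",
    "make_peaks",
    "default_param_table",
    "FitError",
]

#: Gas constant in kJ mol^-1 K^-1 (the MD convention for k_B).
KB = 8.314e-3
DEFAULT_TEMPERATURE = 298.15


class FitError(RuntimeError):
    """Multi-peak fit failed; carries the best residual seen."""

    def __init__(self, message: str, best_residual: float | None = None):
        super().__init__(message)
        self.best_residual = best_residual


@dataclass
class DistributionSample:
    """A series of observed bond lengths (nm) or angles (degrees)."""

    kind: str  # "bond" | "angle"
    values: np.ndarray
    temperature: float = DEFAULT_TEMPERATURE

    def __post_init__(self) -> None:
        if self.kind not in ("bond", "angle"):
            raise ValueError(f"kind must be 'bond' or 'angle', got {self.kind!r}")
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1 or self.values.size == 0:
            raise ValueError("values must be a non-empty 1-d series")
        if self.kind == "bond" and np.any(self.values <= 0):
            raise ValueError("bond lengths must be positive")
        if self.kind == "angle" and (
            np.any(self.values <= 0) or np.any(self.values > 180.0)
        ):
            raise ValueError("angles must lie in (0, 180] degrees")

    @property
    def fit_values(self) -> np.ndarray:
        """Values in the coordinate where the potential is harmonic."""
        if self.kind == "bond":
            return self.values
        return np.cos(np.radians(self.values))


@dataclass
class GaussianPeak:
    """One Boltzmann-weighted Gaussian component of a bonded distribution.

    ``mean``/``sigma`` live in fit space (nm for bonds, cos theta for
    angles); ``equilibrium`` is in native units (nm or degrees) and
    ``force_constant`` in kJ mol^-1 nm^-2 (bond) or kJ mol^-1 (angle).
    """

    kind: str
    amplitude: float
    mean: float
    sigma: float
    force_constant: float
    temperature: float = DEFAULT_TEMPERATURE
    area: float = field(default=0.0)
    weight: float = field(default=0.0)

    def __post_init__(self) -> None:
        if self.kind not in ("bond", "angle"):
            raise ValueError("kind must be 'bond' or 'angle'")
        if self.area == 0.0:
            self.area = abs(self.amplitude) * abs(self.sigma) * math.sqrt(2 * math.pi)

    @property
    def equilibrium(self) -> float:
        if self.kind == "bond":
            return self.mean
        return math.degrees(math.acos(min(1.0, max(-1.0, self.mean))))


@dataclass
class BondedParam:
    """Single-peak bonded parameter consumed by topology writers.

    ``equilibrium`` in nm (bond) or degrees (angle); ``force_constant`` in
    kJ mol^-1 nm^-2 (bond) or kJ mol^-1 (angle).
    """

    type: Optional[Union[BondType, AngleType]]
    kind: str
    equilibrium: float
    force_constant: float
    peaks: tuple[GaussianPeak, ...] = ()

    def __post_init__(self) -> None:
        if self.kind not in ("bond", "angle"):
            raise ValueError("kind must be 'bond' or 'angle'")
        if self.force_constant <= 0:
            raise ValueError("force constant must be positive")
        if self.kind == "bond" and self.equilibrium <= 0:
            raise ValueError("bond equilibrium must be positive")
        if self.kind == "angle" and not (0.0 < self.equilibrium <= 180.0):
            raise ValueError("angle equilibrium must lie in (0, 180] degrees")


class ParamTable:
    """Bonded parameters keyed by bond/angle type.

    Lookup must be total for every type present in a graph the table claims
    to cover; :meth:`covers` verifies that before a writer runs.
    """

    def __init__(self, params: Iterable[BondedParam] = ()):
        self._map: dict[Union[BondType, AngleType], BondedParam] = {}
        for p in params:
            self.add(p)

    def add(self, param: BondedParam) -> None:
        if param.type is None:
            raise ValueError("ParamTable entries need a bond/angle type")
        if param.type in self._map:
            raise ValueError(f"duplicate parameter for {param.type}")
        self._map[param.type] = param

    def __len__(self) -> int:
        return len(self._map)

    def __iter__(self):
        return iter(
            sorted(self._map.values(), key=lambda p: (p.kind, str(p.type)))
        )

    def __contains__(self, t) -> bool:
        return t in self._map

    def get(self, t) -> BondedParam:
        try:
            return self._map[t]
        except KeyError:
            raise KeyError(f"no bonded parameter for type {t}") from None

    def bond(self, a, b) -> BondedParam:
        return self.get(BondType(a, b))

    def angle(self, flank_a, center, flank_b) -> BondedParam:
        return self.get(AngleType(flank_a, center, flank_b))

    def covers(self, graph: PolymerGraph) -> None:
        """Raise KeyError naming the first missing type for ``graph``."""
        for bt in sorted(set(graph.bond_types()), key=str):
            self.get(bt)
        for at in sorted(set(graph.angle_types()), key=str):
            self.get(at)


# ----------------------------------------------------------------------
# fitting


def _gaussian_mixture(x: np.ndarray, *params: float) -> np.ndarray:
    y = np.zeros_like(x)
    for i in range(0, len(params), 3):
        a, mu, sig = params[i : i + 3]
        y = y + a * np.exp(-((x - mu) ** 2) / (2.0 * sig**2))
    return y


def _initial_centers(centers: np.ndarray, density: np.ndarray, k: int) -> list[np.ndarray]:
    """Candidate centre sets: histogram local maxima first, quantiles second."""
    inits = []
    # local maxima of a lightly smoothed histogram, tallest first
    kernel = np.array([0.25, 0.5, 0.25])
    smooth = np.convolve(density, kernel, mode="same")
    interior = np.arange(1, len(smooth) - 1)
    is_max = (smooth[interior] >= smooth[interior - 1]) & (
        smooth[interior] >= smooth[interior + 1]
    )
    maxima = interior[is_max]
    maxima = maxima[np.argsort(smooth[maxima])[::-1]]
    if len(maxima) >= k:
        inits.append(np.sort(centers[maxima[:k]]))
    # quantile fallback
    cdf = np.cumsum(density)
    cdf = cdf / cdf[-1]
    qs = (np.arange(k) + 0.5) / k
    inits.append(np.interp(qs, cdf, centers))
    return inits


def fit_peaks(
    sample: DistributionSample,
    max_peaks: int = 3,
    bins: Union[int, str, None] = None,
) -> list[GaussianPeak]:
    """Fit a 1-3 component Gaussian mixture to a bonded distribution.

    The observed values are histogrammed (Freedman-Diaconis by default,
    density-normalized) in the harmonic coordinate — bond length for bonds,
    cos theta for angles — and a sum of Gaussians is fitted by nonlinear
    least squares with multi-start initialization.  The component count in
    ``1..max_peaks`` is chosen by a BIC-style corrected residual score so
    single-mode distributions are not force-split.  Peaks are returned sorted
    by equilibrium value with analytic-area weights attached.
    """
    if max_peaks not in (1, 2, 3):
        raise ValueError("max_peaks must be 1, 2 or 3")
    x = sample.fit_values
    if x.size < 500:
        raise ValueError("need at least 500 observations to fit")
    if np.ptp(x) == 0 or np.std(x) == 0:
        raise FitError("zero-variance distribution: nothing to fit")

    if bins is None:
        bins = "fd"
    density, edges = np.histogram(x, bins=bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    if len(centers) < 8:
        density, edges = np.histogram(x, bins=16, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
    n_bins = len(centers)
    spread = np.std(x)

    best: tuple[float, np.ndarray] | None = None
    best_residual = None
    for k in range(1, max_peaks + 1):
        fit_for_k = None
        for init_centers in _initial_centers(centers, density, k):
            p0, lo, hi = [], [], []
            for mu in init_centers:
                p0 += [float(density.max()), float(mu), float(spread / k)]
                lo += [0.0, float(centers[0] - spread), 1e-9]
                hi += [np.inf, float(centers[-1] + spread), float(4 * np.ptp(x) + 1e-9)]
            try:
                popt, _ = curve_fit(
                    _gaussian_mixture,
                    centers,
                    density,
                    p0=p0,
                    bounds=(lo, hi),
                    maxfev=20000,
                )
            except (RuntimeError, ValueError):
                continue
            rss = float(np.sum((_gaussian_mixture(centers, *popt) - density) ** 2))
            if fit_for_k is None or rss < fit_for_k[0]:
                fit_for_k = (rss, popt)
        if fit_for_k is None:
            continue
        rss, popt = fit_for_k
        best_residual = rss if best_residual is None else min(best_residual, rss)
        # BIC-style corrected score on the binned residuals
        score = n_bins * math.log(max(rss, 1e-300) / n_bins) + 3 * k * math.log(n_bins)
        if best is None or score < best[0]:
            best = (score, popt)

    if best is None:
        raise FitError(
            "peak fit did not converge for any component count",
            best_residual=best_residual,
        )

    popt = best[1]
    peaks = []
    for i in range(0, len(popt), 3):
        a, mu, sig = popt[i : i + 3]
        sig = abs(float(sig))
        k_force = KB * sample.temperature / sig**2
        peaks.append(
            GaussianPeak(
                kind=sample.kind,
                amplitude=float(a),
                mean=float(mu),
                sigma=sig,
                force_constant=k_force,
                temperature=sample.temperature,
            )
        )
    w = peak_weights(peaks)
    for p, wi in zip(peaks, w):
        p.weight = float(wi)
    peaks.sort(key=lambda p: p.equilibrium)
    return peaks


def peak_weights(peaks: Sequence[GaussianPeak]) -> np.ndarray:
    """Area weights w_i = S_i / sum S_i with S_i = A_i sigma_i sqrt(2 pi)."""
    if len(peaks) == 0:
        raise ValueError("no peaks")
    areas = np.array([p.area for p in peaks], dtype=float)
    if np.any(areas < 0):
        raise ValueError("negative peak area")
    total = areas.sum()
    if total <= 0:
        raise ValueError("all peak areas are zero: weights undefined")
    return areas / total


def reduce_peaks(
    peaks: Sequence[GaussianPeak],
    k_min: float = 1.0,
    w_min: float = 0.001,
    type: Optional[Union[BondType, AngleType]] = None,
) -> BondedParam:
    """Reduce a multi-peak fit to one single-peak bonded parameter.

    Components with force constant below ``k_min`` (native units) or weight
    below ``w_min`` are excluded — they barely affect the fit quality but
    would dominate the harmonic mean — and the surviving weights are
    renormalized.  The equilibrium is the weighted mean of the per-peak
    equilibria (degrees for angles, after back-conversion from cos-space) and
    the force constant the weighted harmonic mean 1/K = sum w_i / K_i.
    """
    if len(peaks) == 0:
        raise ValueError("no peaks to reduce")
    kind = peaks[0].kind
    if any(p.kind != kind for p in peaks):
        raise ValueError("mixed bond/angle peaks")
    w = peak_weights(peaks)
    kept = [
        (p, wi)
        for p, wi in zip(peaks, w)
        if p.force_constant >= k_min and wi >= w_min
    ]
    if not kept:
        raise FitError(
            "all peaks excluded by the K/weight filters: "
            "distribution is not parametrizable"
        )
    ws = np.array([wi for _, wi in kept])
    ws = ws / ws.sum()
    eq = float(sum(wi * p.equilibrium for (p, _), wi in zip(kept, ws)))
    k_red = float(1.0 / sum(wi / p.force_constant for (p, _), wi in zip(kept, ws)))
    retained = tuple(
        replace(p, weight=float(wi)) for (p, _), wi in zip(kept, ws)
    )
    return BondedParam(
        type=type,
        kind=kind,
        equilibrium=eq,
        force_constant=k_red,
        peaks=retained,
    )


# ----------------------------------------------------------------------
# synthetic distributions


def make_peaks(
    kind: str,
    components: Sequence[tuple[float, float, float]],
    temperature: float = DEFAULT_TEMPERATURE,
) -> list[GaussianPeak]:
    """Build GaussianPeak components from (equilibrium, K, weight) triples.

    Equilibria are native-unit (nm or degrees); sigma is derived from the
    Boltzmann relation sigma^2 = k_B T / K in the harmonic coordinate.
    """
    peaks = []
    for eq, k_force, weight in components:
        if k_force <= 0:
            raise ValueError("force constant must be positive")
        sigma = math.sqrt(KB * temperature / k_force)
        mean = eq if kind == "bond" else math.cos(math.radians(eq))
        amplitude = weight / (sigma * math.sqrt(2 * math.pi))
        peaks.append(
            GaussianPeak(
                kind=kind,
                amplitude=amplitude,
                mean=mean,
                sigma=sigma,
                force_constant=k_force,
                temperature=temperature,
                weight=weight,
            )
        )
    return peaks


def sample_synthetic_distribution(
    peaks: Sequence[GaussianPeak],
    n: int,
    seed: int,
    temperature: float | None = None,
) -> DistributionSample:
    """Draw a synthetic bonded distribution from a Gaussian mixture.

    Components are chosen by weight, then values are drawn from the
    component Gaussian in the harmonic coordinate.  Angle draws are rejection
    sampled into the physical cos-range [-1, 1], which is exactly the
    Boltzmann distribution restricted to real angles.  Deterministic for a
    given seed.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if len(peaks) == 0:
        raise ValueError("no peaks")
    kind = peaks[0].kind
    temp = temperature if temperature is not None else peaks[0].temperature
    rng = np.random.default_rng(seed)
    w = peak_weights(peaks)
    idx = rng.choice(len(peaks), size=n, p=w)
    means = np.array([p.mean for p in peaks])
    sigmas = np.array([p.sigma for p in peaks])
    draws = rng.normal(means[idx], sigmas[idx])
    if kind == "bond":
        bad = draws <= 0
    else:
        bad = (draws < -1.0) | (draws > 1.0)
    while np.any(bad):
        redraw = rng.normal(means[idx[bad]], sigmas[idx[bad]])
        draws[bad] = redraw
        if kind == "bond":
            bad = draws <= 0
        else:
            bad = (draws < -1.0) | (draws > 1.0)
    if kind == "angle":
        values = np.degrees(np.arccos(draws))
    else:
        values = draws
    return DistributionSample(kind=kind, values=values, temperature=temp)


def evaluate_potential(param: BondedParam, x) -> Union[float, np.ndarray]:
    """Bonded energy in kJ/mol at bond length x (nm) or angle x (degrees)."""
    x = np.asarray(x, dtype=float)
    if param.kind == "bond":
        v = 0.5 * param.force_constant * (x - param.equilibrium) ** 2
    else:
        v = (
            0.5
            * param.force_constant
            * (np.cos(np.radians(x)) - math.cos(math.radians(param.equilibrium)))
            ** 2
        )
    return float(v) if v.ndim == 0 else v


def default_param_table(include_complete_molecules: bool = True) -> ParamTable:
    """Placeholder bonded-parameter table covering every PEI bond/angle type.

    These values are synthetic round-number placeholders so that generated
    topologies are syntactically complete; they are NOT fitted parameters.
    Regenerate authoritative values from atomistic distributions with
    :func:`fit_peaks`/:func:`reduce_peaks`.
    """
    from .polymer_graph import enumerate_angle_types, enumerate_bond_types

    table = ParamTable()
    for bt in sorted(
        enumerate_bond_types(allow_complete_molecules=include_complete_molecules),
        key=str,
    ):
        table.add(
            BondedParam(type=bt, kind="bond", equilibrium=0.33, force_constant=8000.0)
        )
    for at in sorted(
        enumerate_angle_types(allow_complete_molecules=include_complete_molecules),
        key=str,
    ):
        table.add(
            BondedParam(type=at, kind="angle", equilibrium=130.0, force_constant=50.0)
        )
    return table
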