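"""Gaussian characterisation of property distributions and spectra.

Each metastable pattern holds structurally similar conformers, so a
property such as the vertical S1 excitation energy is approximately
normal within a pattern (low bias) while varying strongly between
patterns (high variance).  Distributions are summarised as Gaussian fits
(mu, sigma), intervals as mu +/- z sigma — z = 2.58 covers 99% of the
probability mass — and emission spectra as Gaussian-broadened sums over
snapshot energies.

The default fit is method-of-moments with the population (1/n) standard
deviation, so that pooling per-pattern moments weighted by member count
reproduces the global moments exactly; a histogram least-squares mode is
available for fitting binned data.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

logger = logging.getLogger(__name__)

__all__ = [
    "GaussianFit",
    "Spectrum",
    "fit_gaussian",
    "per_pattern_stats",
    "gaussian_coverage",
    "coverage_interval",
    "emission_spectrum",
    "stats_to_frame",
]


@dataclass(frozen=True)
class GaussianFit:
    """Normal summary of a sample: mean, standard deviation, count."""

    mu: float
    sigma: float
    n: int

    def __post_init__(self) -> None:
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")
        if self.n < 1:
            raise ValueError("n must be >= 1")


@dataclass
class Spectrum:
    """Broadened line spectrum on a regular energy grid."""

    grid: np.ndarray        # eV, strictly increasing
    intensity: np.ndarray   # >= 0, per grid point
    broadening_fwhm: float  # eV


def fit_gaussian(samples, method: str = "moments", bins: int = 50) -> GaussianFit:
    """Fit a Gaussian to samples.

    ``method="moments"`` (default): sample mean and population standard
    deviation.  ``method="histogram"``: least-squares fit of a Gaussian
    density to a normalised histogram, moment-initialised.
    """
    x = np.asarray(samples, dtype=float).ravel()
    if x.size == 0:
        raise ValueError("empty sample")
    if not np.all(np.isfinite(x)):
        raise ValueError("non-finite sample values")
    mu = float(np.mean(x))
    sigma = float(np.std(x))  # population (ddof=0)
    if method == "moments":
        return GaussianFit(mu=mu, sigma=sigma, n=x.size)
    if method != "histogram":
        raise ValueError(f"unknown method {method!r}")
    if sigma == 0.0 or x.size < 5:
        return GaussianFit(mu=mu, sigma=sigma, n=x.size)
    dens, edges = np.histogram(x, bins=bins, density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])

    def model(e, m, s):
        return stats.norm.pdf(e, loc=m, scale=abs(s))

    try:
        popt, _ = optimize.curve_fit(model, centers, dens, p0=[mu, sigma])
        return GaussianFit(mu=float(popt[0]), sigma=float(abs(popt[1])), n=x.size)
    except RuntimeError:
        logger.warning("histogram fit did not converge; falling back to moments")
        return GaussianFit(mu=mu, sigma=sigma, n=x.size)


def per_pattern_stats(
    labels: np.ndarray,
    properties: Mapping[str, np.ndarray] | pd.DataFrame,
    method: str = "moments",
) -> dict[int, dict[str, GaussianFit]]:
    """One Gaussian fit per (pattern, property).

    ``properties`` maps property name to a per-frame array aligned with
    ``labels``; NaN entries are treated as missing.  Per-atom charges are
    passed as one property per atom (e.g. ``charge_1``).  Patterns with
    no finite values for a property are omitted with a warning.
    """
    lab = np.asarray(labels, dtype=int)
    if isinstance(properties, pd.DataFrame):
        properties = {c: properties[c].to_numpy() for c in properties.columns}
    out: dict[int, dict[str, GaussianFit]] = {}
    for name, vals in properties.items():
        v = np.asarray(vals, dtype=float)
        if v.shape[0] != lab.shape[0]:
            raise ValueError(
                f"property {name!r}: {v.shape[0]} values vs {lab.shape[0]} labels"
            )
        for pat in np.unique(lab):
            sel = v[lab == pat]
            sel = sel[np.isfinite(sel)]
            if sel.size == 0:
                logger.warning(
                    "pattern %d: no finite values for %r; fit omitted", pat, name
                )
                continue
            out.setdefault(int(pat), {})[name] = fit_gaussian(sel, method=method)
    return out


def gaussian_coverage(z: float) -> float:
    """Probability mass of a standard normal within [-z, z]: Phi(z)-Phi(-z)."""
    if z < 0:
        raise ValueError("z must be >= 0")
    return float(stats.norm.cdf(z) - stats.norm.cdf(-z))


def coverage_interval(fit: GaussianFit, z: float = 2.58) -> tuple[float, float]:
    """Symmetric interval (mu - z sigma, mu + z sigma) in property units."""
    return (fit.mu - z * fit.sigma, fit.mu + z * fit.sigma)


def emission_spectrum(
    energies: Sequence[float],
    broadening_fwhm: float = 0.2,
    grid_step: float | None = None,
) -> Spectrum:
    """Gaussian-broadened emission spectrum from snapshot energies.

    Each snapshot contributes a unit-area Gaussian of the given FWHM at
    its emission energy (no oscillator-strength weighting), so the
    integral of the spectrum equals the snapshot count.  The grid spans
    all energies +/- 3 broadening widths; default step is FWHM/20.
    """
    e = np.asarray(energies, dtype=float).ravel()
    if e.size == 0:
        raise ValueError("no energies")
    if not np.all(np.isfinite(e)):
        raise ValueError("non-finite energies")
    if broadening_fwhm <= 0:
        raise ValueError("broadening_fwhm must be positive")
    sigma = broadening_fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    step = grid_step if grid_step is not None else broadening_fwhm / 20.0
    lo = e.min() - 3.0 * broadening_fwhm
    hi = e.max() + 3.0 * broadening_fwhm
    grid = np.arange(lo, hi + step, step)
    # (n_grid,) sum over unit-area Gaussians
    z = (grid[:, None] - e[None, :]) / sigma
    intensity = np.sum(
        np.exp(-0.5 * z**2) / (sigma * np.sqrt(2.0 * np.pi)), axis=1
    )
    return Spectrum(grid=grid, intensity=intensity, broadening_fwhm=broadening_fwhm)


def stats_to_frame(
    fits: Mapping[int, Mapping[str, GaussianFit]]
) -> pd.DataFrame:
    """Flatten per-pattern fits to a (pattern, property, mu, sigma, n) table."""
    rows = [
        {"pattern": pat, "property": name,
         "mu": f.mu, "sigma": f.sigma, "n": f.n}
        for pat, props in sorted(fits.items())
        for name, f in props.items()
    ]
    return pd.DataFrame(rows, columns=["pattern", "property", "mu", "sigma", "n"])
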