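"""Per-patient up-regulated gene calling from paired tumor/control profiles.

For each patient the control expression vector is subtracted from the paired
tumor vector, gene by gene (RSEM units; negative values are retained).  The
frequency distribution of these differentials is dominated by a roughly
Gaussian bulk of unchanged genes with a right tail of genuinely up-regulated
ones.  The bulk is modelled by least-squares fitting a Gaussian curve to the
log10(y+1)-transformed relative bin frequencies; its upper one-tail cut at
significance alpha,

    threshold = mu + sigma * z(1 - alpha),

defines the up-regulation call: genes whose differential strictly exceeds
the threshold.  With alpha = 0.05 (the default), z(0.95) = 1.6449.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .errors import DegenerateDistributionError, FitError, ValidationError
from .io import IdMap, PatientPair

logger = logging.getLogger(__name__)

__all__ = [
    "DifferentialProfile",
    "FrequencyHistogram",
    "GaussianFit",
    "UpregulatedSet",
    "differential_profile",
    "build_histogram",
    "fit_gaussian_threshold",
    "select_upregulated",
]


@dataclass(frozen=True)
class DifferentialProfile:
    """Tumor-minus-control differential expression over the gene universe."""

    patient_id: str
    diffs: pd.Series = field(repr=False)

    def __post_init__(self) -> None:
        if not np.isfinite(self.diffs.to_numpy(dtype=float)).all():
            raise ValidationError("differential values must be finite")


@dataclass(frozen=True)
class FrequencyHistogram:
    """Relative-frequency histogram of one patient's differentials.

    ``transformed`` holds y' = log10(y + 1) of each relative frequency y;
    empty bins therefore transform to exactly 0.  The raw differential
    values are kept for fit initialisation and the quantile fallback.
    """

    bin_centers: np.ndarray
    rel_freq: np.ndarray
    transformed: np.ndarray
    raw_values: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if np.any(np.diff(self.bin_centers) <= 0):
            raise ValidationError("bin centers must be strictly increasing")
        if abs(self.rel_freq.sum() - 1.0) > 1e-9:
            raise ValidationError("relative frequencies must sum to 1")


@dataclass(frozen=True)
class GaussianFit:
    """Fitted Gaussian bulk and the derived one-tail threshold.

    When the optimiser fails, ``converged`` is False and ``threshold``
    falls back to the empirical (1 - alpha) quantile of the raw
    differentials; mu/sigma/amplitude are NaN in that case.
    """

    mu: float
    sigma: float
    amplitude: float
    threshold: float
    alpha: float
    converged: bool


@dataclass(frozen=True)
class UpregulatedSet:
    """Genes called up-regulated for one patient, plus mapped accessions."""

    patient_id: str
    genes: frozenset[str]
    proteins: frozenset[str]
    n_unmapped: int = 0


def differential_profile(pair: PatientPair) -> DifferentialProfile:
    """diffs[g] = tumor[g] - control[g] over the shared gene universe."""
    if list(pair.tumor.index) != list(pair.control.index):
        raise ValidationError(
            f"patient {pair.patient_id}: tumor and control gene universes differ"
        )
    diffs = pair.tumor.astype(float) - pair.control.astype(float)
    return DifferentialProfile(patient_id=pair.patient_id, diffs=diffs)


def build_histogram(profile: DifferentialProfile, n_bins: int = 100) -> FrequencyHistogram:
    """Equal-width relative-frequency histogram spanning [min, max]."""
    if n_bins < 10:
        raise ValidationError("n_bins must be >= 10")
    values = profile.diffs.to_numpy(dtype=float)
    if np.ptp(values) == 0:
        raise DegenerateDistributionError(
            f"patient {profile.patient_id}: all differential values identical"
        )
    counts, edges = np.histogram(values, bins=n_bins)
    rel = counts / counts.sum()
    centers = 0.5 * (edges[:-1] + edges[1:])
    return FrequencyHistogram(
        bin_centers=centers,
        rel_freq=rel,
        transformed=np.log10(rel + 1.0),
        raw_values=values,
    )


def _gaussian(x: np.ndarray, amplitude: float, mu: float, sigma: float) -> np.ndarray:
    return amplitude * np.exp(-0.5 * ((x - mu) / sigma) ** 2)


def fit_gaussian_threshold(hist: FrequencyHistogram, alpha: float = 0.05) -> GaussianFit:
    """Fit the Gaussian bulk and derive the upper one-tail threshold.

    The curve A*exp(-(x-mu)^2 / (2 sigma^2)) is least-squares fitted to
    (bin centers, transformed frequencies); the threshold is expressed back
    on the differential-expression axis as mu + sigma*z(1-alpha), i.e. the
    point above which the fitted bulk leaves alpha of its mass.
    """
    if not 0.0 < alpha < 0.5:
        raise ValidationError(f"alpha must lie in (0, 0.5), got {alpha}")
    if int(np.count_nonzero(hist.rel_freq)) < 4:
        raise FitError("fewer than 4 non-empty bins; cannot fit a Gaussian bulk")

    z = float(stats.norm.ppf(1.0 - alpha))
    q1, q3 = np.percentile(hist.raw_values, [25, 75])
    p0 = (
        float(hist.transformed.max()),                      # amplitude
        float(hist.bin_centers[np.argmax(hist.transformed)]),  # mode center
        max((q3 - q1) / 2.0, np.finfo(float).eps),          # half the IQR
    )
    try:
        popt, _ = optimize.curve_fit(
            _gaussian,
            hist.bin_centers,
            hist.transformed,
            p0=p0,
            maxfev=10_000,
            xtol=1e-8,
            ftol=1e-8,
        )
        amplitude, mu, sigma = float(popt[0]), float(popt[1]), abs(float(popt[2]))
        if not (np.isfinite(mu) and np.isfinite(sigma) and sigma > 0):
            raise RuntimeError("non-finite fit")
    except RuntimeError:
        fallback = float(np.quantile(hist.raw_values, 1.0 - alpha))
        logger.warning(
            "Gaussian fit did not converge; using empirical %.0f%% quantile %.4g",
            100 * (1 - alpha),
            fallback,
        )
        return GaussianFit(
            mu=float("nan"),
            sigma=float("nan"),
            amplitude=float("nan"),
            threshold=fallback,
            alpha=alpha,
            converged=False,
        )
    return GaussianFit(
        mu=mu,
        sigma=sigma,
        amplitude=amplitude,
        threshold=mu + sigma * z,
        alpha=alpha,
        converged=True,
    )


def select_upregulated(
    profile: DifferentialProfile, fit: GaussianFit, idmap: IdMap
) -> UpregulatedSet:
    """Genes strictly above the threshold, mapped to protein accessions.

    Genes with no symbol->accession entry stay in ``genes`` but contribute
    no protein; their count is logged and reported on the result.
    """
    mask = profile.diffs.to_numpy(dtype=float) > fit.threshold
    genes = frozenset(profile.diffs.index[mask])
    proteins = {idmap.entries[g] for g in genes if g in idmap.entries}
    n_unmapped = len(genes) - len([g for g in genes if g in idmap.entries])
    if n_unmapped:
        logger.info(
            "patient %s: %d up-regulated gene(s) had no protein mapping",
            profile.patient_id,
            n_unmapped,
        )
    return UpregulatedSet(
        patient_id=profile.patient_id,
        genes=genes,
        proteins=frozenset(proteins),
        n_unmapped=n_unmapped,
    )
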