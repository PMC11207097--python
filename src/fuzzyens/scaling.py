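"""Polymer scaling analysis: R(s) curves, Flory exponent, θ-point, p(dee) fit.

The central quantities:

* the inter-residue distance curve R(s): the distance between residues i and
  j, averaged over all conformations and all pairs with the same sequence
  separation s = |i - j| within a chosen domain.  The per-pair distance is
  either the minimum bead–bead distance (the literal contact-map convention)
  or the backbone-bead distance; the average is either arithmetic or RMS.
  Ideal-chain closed forms hold exactly for RMS backbone distances, so that
  is the mode used for parameter-recovery checks.
* the Flory fit R(s) = b s^nu, with the Kuhn length b fixed (0.55 nm, the
  standard IDP value) or free.  nu ≈ 1/3 for a collapsed globule, 1/2 at the
  θ-point, ≈ 0.59 in good solvent.
* the θ-scan: given fitted nu at several solvent-quality control values, a
  monotone smooth curve is interpolated and its crossing with nu = 1/2
  located — the θ-point of the scan.
* the Gaussian-chain end-to-end distance density

      p(d) = 4 d^2 exp[-(d / xi)^2] / (sqrt(pi) xi^3),

  least-squares fitted to a normalised histogram of end-to-end distances;
  the Pearson R^2 between histogram and fit quantifies how Gaussian-chain-
  like the ensemble is (ideal chains give R^2 > 0.98; collapsed or swollen
  chains fall below).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from scipy.interpolate import PchipInterpolator

from ._distances import residue_min_distances
from .ensemble import Ensemble
from .errors import FitError
from .geometry import metrics_series

DEFAULT_KUHN_LENGTH = 0.55  # nm, standard IDP value


# ---------------------------------------------------------------------------
# scaling curve
# ---------------------------------------------------------------------------


@dataclass
class ScalingCurve:
    """Mean inter-residue distance vs sequence separation for one domain."""

    s: np.ndarray
    r: np.ndarray  # nm
    mode: str  # "mean" | "rms"
    distance: str  # "min-bead" | "backbone"
    domain: str | None = None


def scaling_curve(
    ensemble: Ensemble,
    domain: str | None = None,
    mode: str = "mean",
    distance: str = "min-bead",
    molecule: int = 0,
    frame_chunk: int = 2000,
) -> ScalingCurve:
    """R(s) averaged over frames and same-separation residue pairs.

    ``domain`` restricts the analysis to a named residue interval of the
    topology (e.g. the disordered tail); by default all residues of the
    molecule are used.
    """
    if mode not in ("mean", "rms"):
        raise ValueError("mode must be 'mean' or 'rms'")
    if distance not in ("min-bead", "backbone"):
        raise ValueError("distance must be 'min-bead' or 'backbone'")
    top = ensemble.topology
    mol = top.molecules[molecule]
    if domain is None:
        res_idx = np.arange(1, mol.n_residues + 1)
    else:
        res_idx = top.domain_residues(domain)
    n = res_idx.size
    if n < 3:
        raise ValueError("domain must contain at least 3 residues")

    seps = np.arange(1, n)
    if distance == "backbone":
        bb = ensemble.backbone_xyz(molecule)[:, res_idx - 1, :]  # (N, n, 3)
        sums = np.zeros(n - 1)
        counts = np.zeros(n - 1)
        for start in range(0, bb.shape[0], frame_chunk):
            chunk = bb[start : start + frame_chunk]
            for s in seps:
                d2 = np.sum((chunk[:, s:, :] - chunk[:, :-s, :]) ** 2, axis=2)
                if mode == "rms":
                    sums[s - 1] += d2.sum()
                else:
                    sums[s - 1] += np.sqrt(d2).sum()
                counts[s - 1] += d2.size
    else:
        sums = np.zeros(n - 1)
        counts = np.zeros(n - 1)
        xyz = ensemble.molecule_xyz(molecule)
        sel = res_idx - 1
        for k in range(ensemble.n_frames):
            d = residue_min_distances(xyz[k], mol)[np.ix_(sel, sel)]
            for s in seps:
                vals = np.diagonal(d, offset=s)
                if mode == "rms":
                    sums[s - 1] += np.sum(vals**2)
                else:
                    sums[s - 1] += vals.sum()
                counts[s - 1] += vals.size
    means = sums / counts
    r = np.sqrt(means) if mode == "rms" else means
    return ScalingCurve(s=seps, r=r, mode=mode, distance=distance, domain=domain)


# ---------------------------------------------------------------------------
# Flory fit
# ---------------------------------------------------------------------------


@dataclass
class FloryFit:
    """Result of fitting R(s) = b s^nu."""

    b: float  # nm
    nu: float
    residual: float  # RMS residual of the fit, nm
    b_fixed: bool
    s_min: int


def fit_flory(
    curve: ScalingCurve,
    b_fixed: float | None = DEFAULT_KUHN_LENGTH,
    s_min: int = 2,
) -> FloryFit:
    """Nonlinear least squares of b * s^nu to a scaling curve.

    ``b_fixed`` pins the Kuhn length (pass ``None`` to fit b as well);
    ``s_min`` drops the smallest separations, whose distances are set by
    bonded geometry rather than chain statistics.
    """
    sel = curve.s >= s_min
    s, r = curve.s[sel].astype(float), curve.r[sel]
    if s.size < 5:
        raise FitError("need at least 5 separation points for the Flory fit")
    try:
        if b_fixed is None:
            popt, _ = optimize.curve_fit(
                lambda x, b, nu: b * x**nu, s, r, p0=(DEFAULT_KUHN_LENGTH, 0.5)
            )
            b, nu = popt
        else:
            popt, _ = optimize.curve_fit(
                lambda x, nu: b_fixed * x**nu, s, r, p0=(0.5,)
            )
            b, nu = b_fixed, popt[0]
    except RuntimeError as exc:
        raise FitError(f"Flory fit did not converge: {exc}") from exc
    if not 0 < nu < 1:
        raise FitError(f"fitted nu={nu:.3f} outside (0, 1); data not scaling-like")
    resid = float(np.sqrt(np.mean((r - b * s**nu) ** 2)))
    return FloryFit(b=float(b), nu=float(nu), residual=resid, b_fixed=b_fixed is not None, s_min=s_min)


# ---------------------------------------------------------------------------
# θ-scan
# ---------------------------------------------------------------------------


@dataclass
class ThetaScan:
    """A nu(control) scan, its monotone smooth and the nu = 1/2 crossing."""

    control: np.ndarray
    nu: np.ndarray
    theta: float | None  # control value where nu = 1/2, None if not bracketed
    message: str = ""
    _interp: PchipInterpolator | None = field(default=None, repr=False)

    def smooth(self, x: np.ndarray) -> np.ndarray:
        """Evaluate the monotone smoothed nu(control) curve."""
        if self._interp is None:
            raise FitError("scan has no smooth curve")
        return self._interp(np.asarray(x, dtype=float))


def theta_scan(points) -> ThetaScan:
    """Locate the θ-point of a nu(control) scan.

    ``points`` is a sequence of (control, nu) pairs (at least 3).  A
    shape-preserving monotone cubic (PCHIP) is put through the points — if
    the raw nu values are not monotone in the control value they are first
    projected onto the best monotone sequence (pool-adjacent-violators) —
    and the root of nu = 1/2 is found by bisection.  When 1/2 is not
    bracketed by the scan, ``theta`` is ``None``.
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need at least 3 (control, nu) points")
    order = np.argsort(pts[:, 0])
    x, y = pts[order, 0], pts[order, 1]
    if np.unique(x).size != x.size:
        raise ValueError("control values must be distinct")
    y_mono = _monotone_projection(y)
    interp = PchipInterpolator(x, y_mono)
    f = lambda t: interp(t) - 0.5
    lo, hi = x[0], x[-1]
    if f(lo) * f(hi) > 0:
        return ThetaScan(
            control=x, nu=y, theta=None, message="no crossing: nu = 1/2 not bracketed",
            _interp=interp,
        )
    theta = float(optimize.brentq(f, lo, hi, xtol=1e-10))
    return ThetaScan(control=x, nu=y, theta=theta, _interp=interp)


def _monotone_projection(y: np.ndarray) -> np.ndarray:
    """Project onto the closest monotone sequence (increasing or decreasing),
    via pool-adjacent-violators; returns y unchanged if already monotone."""
    dy = np.diff(y)
    if (dy >= 0).all() or (dy <= 0).all():
        return y
    inc = _pava(y)
    dec = -_pava(-y)
    return inc if np.sum((inc - y) ** 2) <= np.sum((dec - y) ** 2) else dec


def _pava(y: np.ndarray) -> np.ndarray:
    """Pool-adjacent-violators for an increasing fit (equal weights)."""
    y = y.astype(float)
    n = y.size
    blocks = [[i] for i in range(n)]
    i = 0
    while i < len(blocks) - 1:
        a, b = blocks[i], blocks[i + 1]
        ma = np.mean(y[a])
        mb = np.mean(y[b])
        if ma > mb:
            blocks[i] = a + b
            del blocks[i + 1]
            i = max(i - 1, 0)
        else:
            i += 1
    out = np.empty(n)
    for blk in blocks:
        out[blk] = np.mean(y[blk])
    return out


# ---------------------------------------------------------------------------
# Gaussian-chain end-to-end fit
# ---------------------------------------------------------------------------


def gaussian_dee_pdf(d: np.ndarray, xi: float) -> np.ndarray:
    """Gaussian-chain end-to-end distance density with scale ``xi`` (nm)."""
    d = np.asarray(d, dtype=float)
    return 4.0 * d**2 * np.exp(-((d / xi) ** 2)) / (np.sqrt(np.pi) * xi**3)


def gaussian_dee_cdf(d: np.ndarray, xi: float) -> np.ndarray:
    """Analytic CDF of the Gaussian-chain end-to-end distance density."""
    d = np.asarray(d, dtype=float)
    t = d / xi
    return stats.chi.cdf(t * np.sqrt(2.0), df=3)


@dataclass
class GaussianChainFit:
    """Scale parameter and goodness of fit of the p(dee) histogram fit."""

    xi: float  # nm
    r2: float  # Pearson correlation^2 between histogram and fit
    bin_centers: np.ndarray = field(repr=False)
    hist_density: np.ndarray = field(repr=False)
    fit_density: np.ndarray = field(repr=False)


def fit_gaussian_dee_histogram(
    centers: np.ndarray, density: np.ndarray, xi0: float | None = None
) -> GaussianChainFit:
    """Fit the Gaussian-chain density to precomputed histogram densities."""
    centers = np.asarray(centers, dtype=float)
    density = np.asarray(density, dtype=float)
    if np.count_nonzero(density) < 2:
        raise FitError("degenerate histogram: fewer than 2 nonempty bins")
    if xi0 is None:
        # moment-based start from the histogram: E[d] = 2 xi / sqrt(pi)
        widths = np.gradient(centers)
        xi0 = float(np.sum(centers * density * widths) * np.sqrt(np.pi) / 2.0)
    try:
        popt, _ = optimize.curve_fit(gaussian_dee_pdf, centers, density, p0=(xi0,))
    except RuntimeError as exc:
        raise FitError(f"p(dee) fit did not converge: {exc}") from exc
    xi = float(abs(popt[0]))
    fit = gaussian_dee_pdf(centers, xi)
    r = np.corrcoef(density, fit)[0, 1]
    return GaussianChainFit(
        xi=xi, r2=float(r**2), bin_centers=centers, hist_density=density, fit_density=fit
    )


def fit_gaussian_dee(samples: np.ndarray, bins: int = 50) -> GaussianChainFit:
    """Fit the Gaussian-chain density to a histogram of end-to-end distances.

    The histogram uses ``bins`` equal-width bins on [0, max sample]
    (zero-count bins included); the density is least-squares fitted for xi
    and R^2 is the squared Pearson correlation between histogram densities
    and fitted densities at the bin centers.
    """
    d = np.asarray(samples, dtype=float).ravel()
    if d.size < 100:
        raise ValueError("need at least 100 samples for a stable histogram fit")
    if (d < 0).any():
        raise ValueError("end-to-end distances must be non-negative")
    density, edges = np.histogram(d, bins=bins, range=(0.0, d.max()), density=True)
    centers = 0.5 * (edges[:-1] + edges[1:])
    return fit_gaussian_dee_histogram(
        centers, density, xi0=d.mean() * np.sqrt(np.pi) / 2.0
    )


def fit_gaussian_dee_ensemble(
    ensemble: Ensemble, molecule: int = 0, bins: int = 50
) -> GaussianChainFit:
    """Convenience: p(dee) fit on the end-to-end series of an ensemble."""
    return fit_gaussian_dee(metrics_series(ensemble, molecule).dee, bins=bins)
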