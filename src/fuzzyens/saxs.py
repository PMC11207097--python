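"""Coarse-grained SAXS: Debye profiles, ensemble averaging, chi-square fitting.

The scattering of a rigid set of beads is the orientation-averaged Debye sum

    I(q) = sum_u sum_v f_u f_v sin(q r_uv) / (q r_uv),

with per-bead form factors ``f`` (default 1, i.e. identical beads; electron
counts can be passed to emulate contrast weighting).  The q -> 0 limit is
(sum f)^2 and is handled exactly through the normalised sinc.

An ensemble profile is the per-q arithmetic mean of the per-structure
profiles.  Comparison against a reference curve uses the reduced

    chi^2(a, b) = (1/n) sum_i [I_ref(q_i) - a I_model(q_i) - b]^2 / sigma_i^2

minimised in closed form over the scale a and offset b (weighted linear
regression), the standard figure of merit for ensemble-vs-experiment SAXS
agreement.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import pdist

from .ensemble import ConformationFrame, Ensemble
from .errors import FormatError


@dataclass
class ScatteringProfile:
    """An I(q) curve on a strictly increasing q grid (q in nm^-1)."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.q.shape != self.intensity.shape or self.q.ndim != 1:
            raise FormatError("q and intensity must be 1-D arrays of equal length")
        if self.q.size == 0:
            raise FormatError("profile must contain at least one point")
        if not (np.diff(self.q) > 0).all():
            raise FormatError("q must be strictly increasing")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float)
            if self.sigma.shape != self.q.shape:
                raise FormatError("sigma must match the q grid")
            if (self.sigma < 0).any():
                raise FormatError("sigma must be non-negative")

    @property
    def n_points(self) -> int:
        return self.q.size


@dataclass
class Chi2Fit:
    """Result of the (a, b) scale/offset fit: global WLS minimiser."""

    scale: float
    offset: float
    chi2: float
    n_points: int


def debye_profile(
    frame: ConformationFrame,
    q_grid: np.ndarray,
    molecule: int | None = 0,
    form_factors: np.ndarray | None = None,
) -> ScatteringProfile:
    """Debye scattering profile of one conformation.

    ``molecule=None`` uses all beads in the frame.  ``np.sinc`` evaluates
    sin(x)/x stably through x=0, so the I(0) = (sum f)^2 limit is exact.
    """
    q = np.asarray(q_grid, dtype=float)
    if (q < 0).any():
        raise ValueError("q values must be non-negative")
    coords = frame.coords if molecule is None else frame.molecule_coords(molecule)
    n = coords.shape[0]
    f = np.ones(n) if form_factors is None else np.asarray(form_factors, dtype=float)
    if f.shape != (n,):
        raise ValueError(f"form_factors must have shape ({n},)")
    if n == 1:
        return ScatteringProfile(q=q, intensity=np.full_like(q, f[0] ** 2))
    r = pdist(coords)  # condensed upper triangle
    iu, ju = np.triu_indices(n, k=1)
    ff = f[iu] * f[ju]
    # I(q) = sum f^2 + 2 sum_{u<v} f_u f_v sinc(q r)
    sinc = np.sinc(np.outer(q, r) / np.pi)
    intensity = np.sum(f**2) + 2.0 * sinc @ ff
    return ScatteringProfile(q=q, intensity=intensity)


def ensemble_profile(profiles: list[ScatteringProfile]) -> ScatteringProfile:
    """Per-q arithmetic mean of per-structure profiles (identical q grids)."""
    if not profiles:
        raise ValueError("need at least one profile")
    q0 = profiles[0].q
    for p in profiles[1:]:
        if p.q.shape != q0.shape or not np.allclose(p.q, q0):
            raise ValueError("profiles must share an identical q grid")
    mean_int = np.mean([p.intensity for p in profiles], axis=0)
    return ScatteringProfile(q=q0, intensity=mean_int)


def ensemble_debye_profile(
    ensemble: Ensemble,
    q_grid: np.ndarray,
    molecule: int | None = 0,
    form_factors: np.ndarray | None = None,
) -> ScatteringProfile:
    """Ensemble-averaged Debye profile, I_sim(q) = (1/N) sum_k I_k(q)."""
    q = np.asarray(q_grid, dtype=float)
    total = np.zeros_like(q)
    for frame in ensemble:
        total += debye_profile(frame, q, molecule=molecule, form_factors=form_factors).intensity
    return ScatteringProfile(q=q, intensity=total / ensemble.n_frames)


def chi2_fit(reference: ScatteringProfile, model: ScatteringProfile) -> Chi2Fit:
    """Fit scale and offset of a model profile against a reference curve.

    The model is linearly interpolated onto the reference q grid; (a, b)
    minimising the reduced chi-square are obtained in closed form from the
    weighted normal equations.
    """
    if reference.sigma is None or not (reference.sigma > 0).all():
        raise ValueError("reference profile must carry positive sigma values")
    y = reference.intensity
    m = np.interp(reference.q, model.q, model.intensity)
    w = 1.0 / reference.sigma**2
    sw = w.sum()
    mw = (w * m).sum() / sw
    yw = (w * y).sum() / sw
    var_m = (w * (m - mw) ** 2).sum()
    if var_m == 0:
        raise ValueError("model profile is constant on the reference grid; scale undefined")
    a = (w * (m - mw) * (y - yw)).sum() / var_m
    b = yw - a * mw
    n = reference.n_points
    chi2 = float(np.sum(w * (y - a * m - b) ** 2) / n)
    return Chi2Fit(scale=float(a), offset=float(b), chi2=chi2, n_points=n)


def debye_function(x: np.ndarray) -> np.ndarray:
    """Gaussian-chain (Debye) form factor D(x) = 2 (exp(-x) + x - 1) / x^2.

    ``x = q^2 <Rg^2>``.  The x -> 0 limit is 1.
    """
    x = np.asarray(x, dtype=float)
    out = np.ones_like(x)
    nz = x > 1e-8
    out[nz] = 2.0 * (np.expm1(-x[nz]) + x[nz]) / x[nz] ** 2
    return out
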