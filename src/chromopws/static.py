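"""Static PWS: spectral interference forward model and packing-scaling maps.

Chromatin within packing domains behaves as a mass-fractal polymer,
``M ∝ r**D`` with packing scaling ``D`` between the solvated-coil limit
(5/3) and the space-filling limit (3). The refractive-index (RI)
fluctuations of such a medium have a power-law autocorrelation
``B(r) ∝ (r / l_min)**(D - 3)`` over the domain length scales
``l_min <= r <= l_max``. PWS probes this statistic interferometrically: the
standard deviation of the backscattered spectrum over wavelength (the Σ map)
grows monotonically with ``D``, because media with larger ``D`` put more
fluctuation power at the low spatial frequencies the instrument samples.

The estimator here is deliberately self-calibrated: `PackingScalingEstimator`
builds a Σ(D) curve from the package's own forward model (isotonic-
regularized so it is monotone by construction) and inverts measured Σ maps
through it. What the closed loop certifies is parameter recovery under the
model's stated assumptions, which is also the property the comparative
bleb-versus-body conclusions rely on.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator
from sklearn.isotonic import IsotonicRegression

from .optics import OpticsConfig

__all__ = [
    "ChromatinMedium",
    "SpectralCube",
    "SigmaDCalibration",
    "DAMap",
    "PackingScalingEstimator",
    "sample_ri_profile",
    "simulate_interference_spectrum",
    "spectral_sigma_map",
    "build_sigma_to_d_calibration",
    "estimate_da_map",
    "nuclear_average_d",
]

D_PHYSICAL_RANGE = (5.0 / 3.0, 3.0)
D_CLIP_RANGE = (1.0, 3.5)


@dataclass(frozen=True)
class ChromatinMedium:
    """Statistical description of a chromatin medium inside one pixel column.

    Attributes
    ----------
    D : float
        Packing scaling (mass-fractal dimension), physical range (5/3, 3].
    l_min, l_max : float
        Inner and outer correlation scales of the power-law regime, nm.
    phi_cvc : float
        Mean chromatin volume concentration (volume fraction).
    sigma_n : float
        RMS refractive-index fluctuation.
    thickness : float
        Axial extent of the probed column, µm.
    n_layers : int
        Number of axial samples of the RI profile.
    n_speckle : int
        Independent transverse coherence cells integrated by one camera
        pixel (intensity-averaged); the default 9 corresponds to an effective
        pixel about three lateral coherence widths across.
    """

    D: float
    l_min: float = 10.0
    l_max: float = 1000.0
    phi_cvc: float = 0.35
    sigma_n: float = 0.05
    thickness: float = 2.0
    n_layers: int = 256
    n_speckle: int = 9

    def __post_init__(self) -> None:
        if not (D_CLIP_RANGE[0] <= self.D <= D_CLIP_RANGE[1]):
            raise ValueError(f"D={self.D} outside supported range {D_CLIP_RANGE}")
        if not (0 < self.l_min < self.l_max):
            raise ValueError("require 0 < l_min < l_max")
        if self.sigma_n < 0:
            raise ValueError("sigma_n must be >= 0")
        if self.n_layers < 8:
            raise ValueError("n_layers must be >= 8")

    @property
    def dz_nm(self) -> float:
        return self.thickness * 1000.0 / self.n_layers


@dataclass
class SpectralCube:
    """Backscattered interference intensities over (y, x, lambda)."""

    intensity: np.ndarray
    lambda_grid: np.ndarray
    reference: np.ndarray | None = None
    pixel_size: float = 0.15  # µm

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.lambda_grid = np.asarray(self.lambda_grid, dtype=float)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be (y, x, lambda)")
        if self.intensity.shape[-1] != self.lambda_grid.size:
            raise ValueError("lambda axis length must match lambda_grid")
        if np.any(self.intensity < 0):
            raise ValueError("intensities must be non-negative")
        if self.reference is not None:
            self.reference = np.asarray(self.reference, dtype=float)
            if self.reference.shape != self.intensity.shape[:2]:
                raise ValueError("reference image shape mismatch")

    @property
    def shape(self):
        return self.intensity.shape


@dataclass
class SigmaDCalibration:
    """Monotone Σ(D) curve sampled by the forward model."""

    d_grid: np.ndarray
    sigma_grid: np.ndarray
    n_replicates: int
    rng_seed: int

    def __post_init__(self) -> None:
        self.d_grid = np.asarray(self.d_grid, dtype=float)
        self.sigma_grid = np.asarray(self.sigma_grid, dtype=float)
        if self.d_grid.size < 2:
            raise ValueError("calibration needs at least 2 D points")
        if np.any(np.diff(self.sigma_grid) < 0):
            raise ValueError("sigma_grid must be monotone non-decreasing")


@dataclass
class DAMap:
    """Per-pixel local packing scaling with validity bookkeeping."""

    d_a: np.ndarray
    valid_mask: np.ndarray
    d_n: dict = field(default_factory=dict)


# ---------------------------------------------------------------------------
# forward model
# ---------------------------------------------------------------------------

def _target_acf(medium: ChromatinMedium) -> np.ndarray:
    """Circulant target autocorrelation of the axial RI profile, B(r)."""
    n = medium.n_layers
    j = np.arange(n)
    r = np.minimum(j, n - j) * medium.dz_nm  # circular lag distance, nm
    b = np.empty(n)
    inside = r <= medium.l_max
    r_eff = np.maximum(r, medium.l_min)
    b[inside] = (r_eff[inside] / medium.l_min) ** (medium.D - 3.0)
    b[~inside] = 0.0
    return b * medium.sigma_n**2


def sample_ri_profile(medium: ChromatinMedium, rng_seed, n_profiles: int = 1
                      ) -> np.ndarray:
    """Draw zero-mean Gaussian axial RI profiles with power-law correlation.

    Uses circulant spectral synthesis: eigenvalues of the circulant target
    covariance are clipped at zero and white complex noise is colored by
    their square root. The realized variance is rescaled to ``sigma_n**2``
    exactly (the clipping perturbs it slightly).

    Returns an array of shape ``(n_profiles, n_layers)`` (squeezed to 1-D
    when ``n_profiles == 1``).
    """
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator) else rng_seed
    n = medium.n_layers
    if medium.sigma_n == 0.0:
        out = np.zeros((n_profiles, n))
        return out[0] if n_profiles == 1 else out
    b = _target_acf(medium)
    lam = np.fft.fft(b).real
    lam = np.clip(lam, 0.0, None)
    b0_eff = lam.sum() / n  # realized variance after clipping
    scale = medium.sigma_n / np.sqrt(b0_eff)
    w = (rng.standard_normal((n_profiles, n))
         + 1j * rng.standard_normal((n_profiles, n))) / np.sqrt(2.0)
    x = np.sqrt(2.0) * np.real(
        np.fft.fft(np.sqrt(lam)[None, :] * w, axis=1)) / np.sqrt(n)
    x *= scale
    return x[0] if n_profiles == 1 else x


def _sample_coherent_profile(medium: ChromatinMedium, rng,
                             n_profiles: int) -> np.ndarray:
    """Axial profile of the medium averaged over the lateral coherence area.

    A single transect of the isotropic 3-D medium has the medium's own
    autocorrelation ``r**(D-3)`` (that is `sample_ri_profile`). The
    interferometric signal, however, integrates the field laterally over the
    coherence area, and for axial frequencies above the inverse coherence
    width the averaged line inherits the 3-D spectral law: its axial power
    spectrum goes as ``q**(-D)`` over the band ``[2 pi / l_max, 2 pi / l_min]``.
    This is the representation the forward model propagates; its variance is
    normalized to ``sigma_n**2`` (the lateral-averaging reduction factor is
    absorbed into the scalar instrument calibration).
    """
    n = medium.n_layers
    if medium.sigma_n == 0.0:
        return np.zeros((n_profiles, n))
    k_idx = np.arange(n)
    q = 2.0 * np.pi * np.minimum(k_idx, n - k_idx) / (n * medium.dz_nm)
    band = (q >= 2.0 * np.pi / medium.l_max) & (q <= 2.0 * np.pi / medium.l_min)

    def c3(d):
        # amplitude of the 3-D spectral law q**(-d) holding the 3-D medium
        # variance fixed: sigma^2 = const * integral q^2 * q^(-d) dq over band
        q_lo, q_hi = 2.0 * np.pi / medium.l_max, 2.0 * np.pi / medium.l_min
        if abs(d - 3.0) < 1e-9:
            return 1.0 / np.log(q_hi / q_lo)
        return (3.0 - d) / (q_hi ** (3.0 - d) - q_lo ** (3.0 - d))

    lam = np.zeros(n)
    lam[band] = c3(medium.D) * q[band] ** (-medium.D)
    # D-independent overall scale: realized 1-D variance equals sigma_n^2 at
    # the reference scaling D = 2.5 (the lateral-averaging constant folded in)
    ref = np.zeros(n)
    ref[band] = c3(2.5) * q[band] ** (-2.5)
    lam *= medium.sigma_n**2 * n / ref.sum()
    w = (rng.standard_normal((n_profiles, n))
         + 1j * rng.standard_normal((n_profiles, n))) / np.sqrt(2.0)
    x = np.sqrt(2.0) * np.real(
        np.fft.fft(np.sqrt(lam)[None, :] * w, axis=1)) / np.sqrt(n)
    return x


def _phase_matrix(medium: ChromatinMedium, cfg: OpticsConfig) -> np.ndarray:
    """Complex propagation factors exp(i 2 k(lambda) n_1 z_j), (n_lambda, n_layers)."""
    z = (np.arange(medium.n_layers) + 0.5) * medium.dz_nm  # nm
    k_lam = 2.0 * np.pi / cfg.lambda_grid  # nm^-1
    return np.exp(1j * 2.0 * k_lam[:, None] * cfg.n_1 * z[None, :])


def _coupling(medium: ChromatinMedium, cfg: OpticsConfig) -> float:
    # scalar NA weighting of the scattered-field amplitude; normalized per
    # layer so the total scattered power is insensitive to the sampling n_layers
    return (cfg.na_i / cfg.na_c) / np.sqrt(medium.n_layers)


def simulate_interference_spectrum(medium: ChromatinMedium,
                                   cfg: OpticsConfig | None = None,
                                   rng_seed=0,
                                   n_spectra: int = 1) -> np.ndarray:
    """Forward-model backscattered interference spectra I(lambda).

    One-dimensional Born/phase-sum approximation: the reference field
    ``sqrt(Gamma)`` interferes with the sum of layer reflections
    ``a * delta_n_j * exp(i 2 k(lambda) n_1 z_j)`` where ``a`` is a scalar
    NA-dependent coupling and ``delta_n_j`` is the coherence-area-averaged
    axial RI profile (see `_sample_coherent_profile`). Deterministic given
    the seed.

    Returns shape ``(n_spectra, n_lambda)`` (1-D when ``n_spectra == 1``).
    """
    cfg = cfg or OpticsConfig()
    rng = np.random.default_rng(rng_seed) if not isinstance(
        rng_seed, np.random.Generator) else rng_seed
    m = max(1, int(medium.n_speckle))
    profiles = _sample_coherent_profile(medium, rng, n_profiles=n_spectra * m)
    e = _phase_matrix(medium, cfg)  # (n_lambda, n_layers)
    a = _coupling(medium, cfg)
    r_ref = np.sqrt(cfg.gamma)
    s = a * (profiles @ e.T)  # (n_spectra * m, n_lambda)
    intensity = np.abs(r_ref + s) ** 2
    # camera pixel integrates intensity over m transverse coherence cells
    intensity = intensity.reshape(n_spectra, m, -1).mean(axis=1)
    return intensity[0] if n_spectra == 1 else intensity


# ---------------------------------------------------------------------------
# Σ map
# ---------------------------------------------------------------------------

def spectral_sigma_map(cube: SpectralCube) -> np.ndarray:
    """Per-pixel standard deviation of the spectrum over wavelength (the Σ map).

    The spectrum is divided by the reference image when one is supplied (the
    calibrated-units path); pixels with a non-positive reference are masked to
    NaN rather than propagated. Sample (n-1) convention.
    """
    if cube.lambda_grid.size < 3:
        raise ValueError("need at least 3 wavelengths for a spectral SD")
    spec = cube.intensity
    if cube.reference is not None:
        ref = cube.reference
        bad = ~(ref > 0)
        safe = np.where(bad, 1.0, ref)
        spec = spec / safe[..., None]
        sigma = spec.std(axis=-1, ddof=1)
        sigma[bad] = np.nan
        return sigma
    return spec.std(axis=-1, ddof=1)


# ---------------------------------------------------------------------------
# Σ → D estimator
# ---------------------------------------------------------------------------

def _edge_slope(sigma_grid, d_grid, side: str) -> float:
    """Slope dD/dΣ of the first non-degenerate segment at either grid edge."""
    n = sigma_grid.size
    if side == "lo":
        idx = range(1, n)
        s0, d0 = sigma_grid[0], d_grid[0]
    else:
        idx = range(n - 2, -1, -1)
        s0, d0 = sigma_grid[-1], d_grid[-1]
    for j in idx:
        if sigma_grid[j] != s0:
            return (d_grid[j] - d0) / (sigma_grid[j] - s0)
    return 0.0

class PackingScalingEstimator(BaseEstimator):
    """Self-calibrated inversion of Σ maps into local packing-scaling maps.

    ``fit`` runs the forward model over ``d_grid`` (``n_replicates``
    single-pixel spectra per D), records the mean Σ per D, and regularizes
    the curve with isotonic regression (ties broken toward lower D).
    ``predict`` inverts a Σ map by piecewise-linear interpolation; pixels
    outside the calibrated Σ range are clipped to the range edges and cleared
    in ``valid_mask``.

    Parameters
    ----------
    cfg : OpticsConfig, optional
    d_grid : array-like
        Packing-scaling sample points, within [1.7, 3.2].
    n_replicates : int
        Forward-model realizations per D (>= 100).
    medium_kwargs : dict, optional
        Overrides for the nominal `ChromatinMedium` used in calibration.
    random_state : int
        Seed for the calibration draws; stored for reproducibility.

    Attributes
    ----------
    calibration_ : SigmaDCalibration
    """

    def __init__(self, cfg=None, d_grid=None, n_replicates=200,
                 medium_kwargs=None, random_state=0):
        self.cfg = cfg
        self.d_grid = d_grid
        self.n_replicates = n_replicates
        self.medium_kwargs = medium_kwargs
        self.random_state = random_state

    def fit(self, X=None, y=None) -> "PackingScalingEstimator":
        cfg = self.cfg or OpticsConfig()
        d_grid = np.asarray(
            self.d_grid if self.d_grid is not None
            else np.linspace(1.7, 3.2, 16), dtype=float)
        if d_grid.size < 2:
            raise ValueError("d_grid must have at least 2 points to interpolate")
        if d_grid.min() < 1.7 - 1e-9 or d_grid.max() > 3.2 + 1e-9:
            raise ValueError("d_grid must lie within [1.7, 3.2]")
        if self.n_replicates < 100:
            raise ValueError("n_replicates must be >= 100")
        kw = dict(self.medium_kwargs or {})
        raw = np.empty(d_grid.size)
        for i, d in enumerate(d_grid):
            medium = ChromatinMedium(D=float(d), **kw)
            # one deterministic sub-seed per D point
            spectra = simulate_interference_spectrum(
                medium, cfg, rng_seed=np.random.default_rng(
                    [int(self.random_state), i]),
                n_spectra=int(self.n_replicates))
            raw[i] = spectra.std(axis=-1, ddof=1).mean()
        iso = IsotonicRegression(increasing=True)
        sigma = iso.fit_transform(d_grid, raw)
        self.calibration_ = SigmaDCalibration(
            d_grid=d_grid, sigma_grid=sigma,
            n_replicates=int(self.n_replicates),
            rng_seed=int(self.random_state))
        return self

    def predict(self, sigma_map, regions: dict | None = None) -> DAMap:
        """Invert a Σ map (array or `SpectralCube`) into a `DAMap`.

        ``regions`` maps label names to boolean masks; each gets its mean
        packing scaling in ``d_n``.
        """
        cal = self.calibration_
        if isinstance(sigma_map, SpectralCube):
            sigma_map = spectral_sigma_map(sigma_map)
        sigma_map = np.asarray(sigma_map, dtype=float)
        if sigma_map.size == 0:
            raise ValueError("empty sigma map")
        lo, hi = cal.sigma_grid[0], cal.sigma_grid[-1]
        finite = np.isfinite(sigma_map)
        in_range = finite & (sigma_map >= lo) & (sigma_map <= hi)
        # piecewise-linear inverse; ties in the isotonic fit resolve to the
        # lowest D of the flat run via the left-continuous interp convention.
        # Out-of-range Σ extrapolates with the edge-segment slopes (then hard
        # clips) rather than saturating at the end knots: saturation would
        # one-sidedly truncate pixel noise near the calibration edges and
        # bias regional means.
        s = np.where(finite, sigma_map, lo)
        d_a = np.interp(s, cal.sigma_grid, cal.d_grid)
        sg, dg = cal.sigma_grid, cal.d_grid
        lo_slope = _edge_slope(sg, dg, "lo")
        hi_slope = _edge_slope(sg, dg, "hi")
        below, above = s < lo, s > hi
        d_a[below] = dg[0] + (s[below] - lo) * lo_slope
        d_a[above] = dg[-1] + (s[above] - hi) * hi_slope
        d_a = np.clip(d_a, *D_CLIP_RANGE)
        d_a[~finite] = np.nan
        damap = DAMap(d_a=d_a, valid_mask=in_range)
        if regions:
            for name, mask in regions.items():
                damap.d_n[name] = nuclear_average_d(damap, mask)
        return damap

    def fit_predict(self, sigma_map, regions=None) -> DAMap:
        return self.fit().predict(sigma_map, regions=regions)


def build_sigma_to_d_calibration(cfg=None, d_grid=None, n_replicates=200,
                                 rng_seed=0, medium_kwargs=None
                                 ) -> SigmaDCalibration:
    """Functional wrapper over `PackingScalingEstimator.fit`."""
    est = PackingScalingEstimator(cfg=cfg, d_grid=d_grid,
                                  n_replicates=n_replicates,
                                  medium_kwargs=medium_kwargs,
                                  random_state=rng_seed)
    return est.fit().calibration_


def estimate_da_map(sigma_map, cal: SigmaDCalibration,
                    regions: dict | None = None) -> DAMap:
    """Functional wrapper: invert a Σ map through an existing calibration."""
    est = PackingScalingEstimator()
    est.calibration_ = cal
    return est.predict(sigma_map, regions=regions)


def nuclear_average_d(da_map: DAMap, region, include_clipped: bool = True
                      ) -> float:
    """Mean packing scaling over the region (the D_n scalar).

    Out-of-calibration pixels enter the mean at their clipped value by
    default; dropping them (``include_clipped=False``) truncates the noise
    distribution asymmetrically near the calibration edges and biases
    regional means, so the flags in ``valid_mask`` are reported but clipped
    pixels are kept. Non-finite pixels (masked reference) are always
    excluded.
    """
    region = np.asarray(region, dtype=bool)
    sel = region & np.isfinite(da_map.d_a)
    if not include_clipped:
        sel &= da_map.valid_mask
    if not sel.any():
        raise ValueError("region does not overlap any valid pixels")
    return float(da_map.d_a[sel].mean())
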