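"""Optical constants and closed-form physics shared by all estimators.

The package models live-cell interferometric (PWS) measurements of chromatin.
Three closed forms are used everywhere:

* the Fresnel intensity reflectance at a refractive-index (RI) mismatch,
  ``R = ((n_a - n_b) / (n_a + n_b))**2``;
* the Gladstone–Dale relation linking RI to dry-mass concentration,
  ``n(phi) = n_water + alpha_gd * rho_0 * phi`` where ``phi`` is the chromatin
  volume concentration (CVC, a volume fraction in [0, 1]);
* the mean-reflectance → CVC calibration obtained by composing the two.

`OpticsConfig` collects every instrument and physics constant so that the
forward models (synthetic generators) and the inverse estimators share a single
normative parameter set.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields, replace

import numpy as np

__all__ = [
    "OpticsConfig",
    "CvcCalibration",
    "ReflectanceCvcModel",
    "fresnel_reflectance",
    "ri_from_cvc",
    "cvc_from_ri",
    "build_cvc_calibration",
    "cvc_from_reflectance",
    "fmm_prefactor",
]


def _default_lambda_grid() -> np.ndarray:
    # 500-700 nm at 2-nm steps: 101 samples
    return np.arange(500.0, 702.0, 2.0)


@dataclass(frozen=True)
class OpticsConfig:
    """Instrument and physics constants of the dual-PWS system.

    Parameters
    ----------
    n_m : float
        Refractive index of a nucleosome (dimensionless).
    n_1 : float
        Refractive index of the nucleus.
    n_i : float
        Refractive index of the immersion oil.
    rho_0 : float
        Dry density of a nucleosome, g/cm^3.
    k : float
        Scalar wavenumber of the illumination light, 1/cm.
    gamma_fresnel : float or None
        Fresnel intensity coefficient for normal incidence. When ``None`` it
        is derived as ``fresnel_reflectance(n_i, n_1)`` (oil/nucleus
        interface); pass a value to override.
    na_c, na_i : float
        Numerical apertures of collection and illumination.
    lambda_grid : ndarray
        Spectral acquisition wavelengths, nm (default 500-700 nm, 2-nm step).
    lambda_dyn : float
        Single wavelength used for dynamics acquisition, nm.
    frame_interval : float
        Dynamics frame interval, s.
    n_water : float
        Refractive index of water (Gladstone-Dale intercept).
    alpha_gd : float
        Gladstone-Dale specific refractive increment, cm^3/g.
    """

    n_m: float = 1.43
    n_1: float = 1.37
    n_i: float = 1.518
    rho_0: float = 0.55
    k: float = 1.57e5
    gamma_fresnel: float | None = None
    na_c: float = 1.49
    na_i: float = 0.52
    lambda_grid: np.ndarray = field(default_factory=_default_lambda_grid)
    lambda_dyn: float = 550.0
    frame_interval: float = 0.050
    n_water: float = 1.334
    alpha_gd: float = 0.18

    def __post_init__(self) -> None:
        for name in ("n_m", "n_1", "n_i", "n_water"):
            if getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must exceed 1 (got {getattr(self, name)})")
        if not (0.0 < self.na_i < self.na_c):
            raise ValueError("require 0 < na_i < na_c")
        if self.rho_0 <= 0 or self.frame_interval <= 0:
            raise ValueError("rho_0 and frame_interval must be positive")
        lam = np.asarray(self.lambda_grid, dtype=float)
        if lam.ndim != 1 or lam.size < 2 or np.any(np.diff(lam) <= 0):
            raise ValueError("lambda_grid must be 1-D and strictly increasing")
        object.__setattr__(self, "lambda_grid", lam)

    @property
    def gamma(self) -> float:
        """Fresnel intensity coefficient: override or oil/nucleus reflectance."""
        if self.gamma_fresnel is not None:
            return float(self.gamma_fresnel)
        return fresnel_reflectance(self.n_i, self.n_1)

    def to_dict(self) -> dict:
        out = {}
        for f in fields(self):
            v = getattr(self, f.name)
            out[f.name] = v.tolist() if isinstance(v, np.ndarray) else v
        return out

    @classmethod
    def from_dict(cls, d: dict) -> "OpticsConfig":
        d = dict(d)
        if "lambda_grid" in d and d["lambda_grid"] is not None:
            d["lambda_grid"] = np.asarray(d["lambda_grid"], dtype=float)
        else:
            d.pop("lambda_grid", None)
        return cls(**d)

    def replace(self, **kw) -> "OpticsConfig":
        return replace(self, **kw)


def fresnel_reflectance(n_a: float, n_b: float):
    """Intensity reflectance at a normal-incidence RI mismatch interface.

    ``R = ((n_a - n_b) / (n_a + n_b))**2``; symmetric in its arguments and
    zero for matched media. Accepts scalars or arrays.
    """
    n_a = np.asarray(n_a, dtype=float)
    n_b = np.asarray(n_b, dtype=float)
    if np.any(n_a <= 0) or np.any(n_b <= 0):
        raise ValueError("refractive indices must be positive")
    r = ((n_a - n_b) / (n_a + n_b)) ** 2
    return float(r) if r.ndim == 0 else r


def ri_from_cvc(phi, cfg: OpticsConfig | None = None):
    """Gladstone-Dale RI of chromatin-occupied medium at volume fraction phi.

    ``n = n_water + alpha_gd * rho_0 * phi``, affine and strictly increasing.
    """
    cfg = cfg or OpticsConfig()
    phi = np.asarray(phi, dtype=float)
    if np.any(phi < 0) or np.any(phi > 1):
        raise ValueError("CVC phi must lie in [0, 1]")
    n = cfg.n_water + cfg.alpha_gd * cfg.rho_0 * phi
    return float(n) if n.ndim == 0 else n


def cvc_from_ri(n, cfg: OpticsConfig | None = None):
    """Inverse Gladstone-Dale: volume fraction from refractive index."""
    cfg = cfg or OpticsConfig()
    n = np.asarray(n, dtype=float)
    phi = (n - cfg.n_water) / (cfg.alpha_gd * cfg.rho_0)
    return float(phi) if phi.ndim == 0 else phi


@dataclass
class CvcCalibration:
    """Monotone map R(phi) from chromatin volume concentration to reflectance.

    Attributes
    ----------
    phi_grid : ndarray
        CVC sample points in [0, 1].
    r_grid : ndarray
        Mean reflectance at each phi; strictly monotone.
    fit_coeffs : ndarray or None
        Polynomial coefficients (highest power first) reproducing r_grid.
        ``None`` for user-supplied grids, which are interpolated piecewise-
        linearly instead.
    provenance : str
        ``"fresnel-analytic"`` or ``"user-supplied"``.
    """

    phi_grid: np.ndarray
    r_grid: np.ndarray
    fit_coeffs: np.ndarray | None
    provenance: str = "fresnel-analytic"

    def __post_init__(self) -> None:
        self.phi_grid = np.asarray(self.phi_grid, dtype=float)
        self.r_grid = np.asarray(self.r_grid, dtype=float)
        if self.phi_grid.size == 0:
            raise ValueError("empty calibration")
        if np.any(self.phi_grid < 0) or np.any(self.phi_grid > 1):
            raise ValueError("phi_grid must lie within [0, 1]")
        d = np.diff(self.r_grid)
        if not (np.all(d > 0) or np.all(d < 0)):
            raise ValueError("r_grid must be strictly monotone over phi_grid")

    def reflectance(self, phi):
        """Evaluate the fitted (or interpolated) R(phi)."""
        phi = np.asarray(phi, dtype=float)
        if self.fit_coeffs is None:
            return np.interp(phi, self.phi_grid, self.r_grid)
        return np.polyval(self.fit_coeffs, phi)


class ReflectanceCvcModel:
    """Calibration model mapping mean reflectance to chromatin volume
    concentration, in the fit/transform idiom.

    ``fit`` builds the analytic calibration on a phi grid: the Gladstone-Dale
    RI of the chromatin-occupied medium composed with the Fresnel reflectance
    of that medium against its aqueous surround, so R(0) = 0 and R is strictly
    increasing in phi. ``transform`` inverts reflectance values back to CVC.

    Parameters
    ----------
    cfg : OpticsConfig, optional
    degree : int
        Degree of the polynomial fitted to R(phi). The composed map is
        ``(a phi)^2 / (2 n_water + a phi)^2`` with ``a = alpha_gd * rho_0``;
        a zero-intercept polynomial in phi^2..phi^degree reproduces it to
        better than 1e-6 relative for degree >= 6.
    """

    def __init__(self, cfg: OpticsConfig | None = None, degree: int = 8):
        self.cfg = cfg
        self.degree = degree

    def get_params(self, deep: bool = True) -> dict:
        return {"cfg": self.cfg, "degree": self.degree}

    def set_params(self, **params) -> "ReflectanceCvcModel":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"unknown parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, phi_grid=None, r_grid=None) -> "ReflectanceCvcModel":
        """Build the R(phi) calibration.

        With ``r_grid=None`` the analytic Fresnel∘Gladstone-Dale composition
        is used; a user-supplied r_grid (e.g. from an external electromagnetic
        fit) must be strictly monotone.
        """
        cfg = self.cfg or OpticsConfig()
        if phi_grid is None:
            phi_grid = np.linspace(0.0, 1.0, 21)
        phi_grid = np.asarray(phi_grid, dtype=float)
        if phi_grid.size < 5 or phi_grid.min() > 0.0 or phi_grid.max() < 1.0:
            raise ValueError("phi_grid needs >= 5 points spanning [0, 1]")
        if r_grid is None:
            n_phi = ri_from_cvc(phi_grid, cfg)
            r_grid = fresnel_reflectance(cfg.n_water, n_phi)
            # zero-intercept basis phi^2..phi^degree: the composed map has an
            # exact phi^2 factor, keeping relative error bounded as phi -> 0
            powers = np.arange(2, self.degree + 1)
            basis = phi_grid[:, None] ** powers[None, :]
            sol, *_ = np.linalg.lstsq(basis, r_grid, rcond=None)
            coeffs = np.zeros(self.degree + 1)
            coeffs[: powers.size] = sol[::-1]  # highest power first
            fitted = np.polyval(coeffs, phi_grid)
            nonzero = r_grid > 0
            rel = np.max(np.abs(fitted[nonzero] - r_grid[nonzero]) / r_grid[nonzero])
            if rel > 1e-6 or abs(np.polyval(coeffs, 0.0)) > 1e-12:
                raise ValueError(
                    f"polynomial of degree {self.degree} does not reproduce "
                    f"r_grid (max relative error {rel:.2e}); increase degree"
                )
            cal = CvcCalibration(phi_grid, r_grid, coeffs, "fresnel-analytic")
        else:
            r_grid = np.asarray(r_grid, dtype=float)
            cal = CvcCalibration(phi_grid, r_grid, None, "user-supplied")
        self.calibration_ = cal
        return self

    def transform(self, r_mean, return_flags: bool = False):
        """Invert mean reflectance to CVC on the calibration range.

        Values outside the calibrated reflectance range are clipped to 0 or 1
        and flagged when ``return_flags`` is true.
        """
        cal = self.calibration_
        r = np.atleast_1d(np.asarray(r_mean, dtype=float))
        lo, hi = cal.r_grid.min(), cal.r_grid.max()
        out_of_range = (r < lo) | (r > hi)
        # dense inverse via monotone interpolation of the fitted curve
        phi_dense = np.linspace(0.0, 1.0, 2001)
        r_dense = cal.reflectance(phi_dense)
        order = np.argsort(r_dense)
        phi = np.interp(np.clip(r, lo, hi), r_dense[order], phi_dense[order])
        phi = np.clip(phi, 0.0, 1.0)
        phi[r < lo] = 0.0
        phi[r > hi] = 1.0
        if np.isscalar(r_mean) or np.ndim(r_mean) == 0:
            phi, out_of_range = float(phi[0]), bool(out_of_range[0])
        if return_flags:
            return phi, out_of_range
        return phi

    def fit_transform(self, r_mean, **fit_kw):
        return self.fit(**fit_kw).transform(r_mean)


def build_cvc_calibration(cfg: OpticsConfig | None = None, phi_grid=None,
                          r_grid=None) -> CvcCalibration:
    """Functional wrapper: build the reflectance↔CVC calibration."""
    model = ReflectanceCvcModel(cfg=cfg)
    return model.fit(phi_grid=phi_grid, r_grid=r_grid).calibration_


def cvc_from_reflectance(r_mean, cal: CvcCalibration, return_flags: bool = False):
    """Functional wrapper: unique phi with R(phi) = r_mean, clipped + flagged."""
    model = ReflectanceCvcModel()
    model.calibration_ = cal
    return model.transform(r_mean, return_flags=return_flags)


def fmm_prefactor(cfg: OpticsConfig) -> float:
    """Normalization constant A relating temporal-interference variance to
    fractional moving mass: ``Var_t[I/I0] = A * m_f`` with ``m_f`` in grams.

    The pre-factor is the package's normative constant, derived from a scalar
    scattering model of the instrument: a coherently moving macromolecular
    cluster of dry mass ``m`` perturbs the collected field by an amplitude

        s(m) = k^3 * NA_c * alpha_gd * m / (2 pi^2)

    (Rayleigh amplitude of the excess polarizability ``alpha_gd * m`` focused
    over a diffraction-limited waist set by ``NA_c``). Summing independent
    clusters inside the coherence volume — lateral radius
    ``w = 0.61 * lambda / NA_c``, depth ``L = n_1 * lambda / NA_i^2``,
    dry mass ``M = rho_0 * pi w^2 L`` — and normalizing the interference term
    by the reference intensity Gamma gives a variance exactly linear in the
    moving-mass product ``m_c * phi_mobile``:

        A = 2 * rho_0 * pi * w^2 * L * s(1 g)^2 / Gamma      [1/g]

    A pure function of (rho_0, alpha_gd, k, n_1, Gamma, NA_c, NA_i); the
    synthetic generator and the estimator both use this single definition, so
    swapping in an externally supplied constant is a one-line config change.
    """
    lam_cm = 2.0 * math.pi / cfg.k
    w = 0.61 * lam_cm / cfg.na_c
    depth = cfg.n_1 * lam_cm / cfg.na_i**2
    v_coh = math.pi * w * w * depth
    s1 = cfg.k**3 * cfg.na_c * cfg.alpha_gd / (2.0 * math.pi**2)
    return 2.0 * cfg.rho_0 * v_coh * s1 * s1 / cfg.gamma
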