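"""Dynamic PWS: temporal-interference estimators.

A single-wavelength (550 nm) image stream I(x, y, t) at 50-ms frames carries
two statistics of chromatin motion inside each diffraction-limited volume:

* the **fractional moving mass** (FMM), in grams — the product of the mass of
  the typical coherently moving macromolecular cluster and the mobile volume
  fraction. It is read out from the temporal variance of the reference-
  normalized intensity, ``FMM = Var_t[I / I0] / A``, where the pre-factor
  ``A`` (`chromopws.optics.fmm_prefactor`) collects the instrument and
  physics constants;
* the **effective diffusion coefficient** D_e, in µm²/s — from the decay
  rate of the temporal autocorrelation, ``D_e = 1 / (4 k_med² tau_d)`` with
  ``k_med = 2 pi n_1 / lambda`` (dynamic-light-scattering backscatter
  convention) and ``tau_d`` the single-exponential decay time.

The slow envelope of the same signal tracks relative chromatin volume
concentration (CVC): mean intensity is inversely proportional to local
macromolecular density, so region traces are inverted and min-max scaled to
[0, 1], summarized by fourth-order polynomial trends, cell ensembles with
standard errors, and per-cell bleb-to-body ratios.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .optics import OpticsConfig, fmm_prefactor

__all__ = [
    "TemporalCube",
    "DynamicsMaps",
    "CvcTrace",
    "MovingMassEstimator",
    "DiffusionEstimator",
    "fractional_moving_mass",
    "effective_diffusion",
    "relative_cvc_trace",
    "fit_polynomial_trend",
    "ensemble_cvc",
    "bleb_body_cvc_ratio",
    "medium_wavenumber",
    "tau_from_diffusion",
    "diffusion_from_tau",
    "DE_MEASURABLE_BAND",
]

# instrument-resolvable effective-diffusion band, µm^2/s
DE_MEASURABLE_BAND = (3.5e-5, 0.065)


@dataclass
class TemporalCube:
    """Single-wavelength intensity stream over (y, x, t) with reference image."""

    intensity: np.ndarray
    i0: np.ndarray
    frame_interval: float = 0.050
    lambda_dyn: float = 550.0
    pixel_size: float = 0.15

    def __post_init__(self) -> None:
        self.intensity = np.asarray(self.intensity, dtype=float)
        self.i0 = np.asarray(self.i0, dtype=float)
        if self.intensity.ndim != 3:
            raise ValueError("intensity must be (y, x, t)")
        if self.intensity.shape[-1] < 10:
            raise ValueError("need at least 10 frames")
        if self.i0.shape != self.intensity.shape[:2]:
            raise ValueError("i0 shape mismatch")
        if self.frame_interval <= 0:
            raise ValueError("frame_interval must be positive")

    @property
    def n_frames(self) -> int:
        return self.intensity.shape[-1]

    @property
    def t(self) -> np.ndarray:
        return np.arange(self.n_frames) * self.frame_interval

    def normalized(self) -> tuple[np.ndarray, np.ndarray]:
        """I / I0 with a mask of analyzable pixels (i0 > 0)."""
        good = self.i0 > 0
        safe = np.where(good, self.i0, 1.0)
        return self.intensity / safe[..., None], good


@dataclass
class DynamicsMaps:
    """Per-pixel dynamics read-outs with region-aggregated summaries."""

    fmm: np.ndarray | None = None            # grams
    d_e: np.ndarray | None = None            # µm^2/s
    cvc_mean: np.ndarray | None = None
    valid_mask: np.ndarray | None = None
    below_floor: np.ndarray | None = None    # no measurable ACF decay
    region_summaries: dict = field(default_factory=dict)


@dataclass
class CvcTrace:
    """Relative chromatin-volume-concentration trace for one region."""

    t: np.ndarray
    raw: np.ndarray
    cvc_rel: np.ndarray
    poly_coeffs: np.ndarray | None = None
    trend: np.ndarray | None = None
    region_label: str = "body"
    cell_id: str = ""
    flat_trace: bool = False

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.raw = np.asarray(self.raw, dtype=float)
        self.cvc_rel = np.asarray(self.cvc_rel, dtype=float)
        if len(self.t) != len(self.raw):
            raise ValueError("t and raw must have equal length")


def medium_wavenumber(cfg: OpticsConfig) -> float:
    """k_med = 2 pi n_1 / lambda_dyn, in 1/µm."""
    return 2.0 * np.pi * cfg.n_1 / (cfg.lambda_dyn * 1e-3)


def tau_from_diffusion(d_e: float, cfg: OpticsConfig) -> float:
    """Autocorrelation decay time tau_d (s) for a given D_e (µm²/s)."""
    return 1.0 / (4.0 * medium_wavenumber(cfg) ** 2 * d_e)


def diffusion_from_tau(tau_d, cfg: OpticsConfig):
    """D_e (µm²/s) from decay time tau_d (s)."""
    return 1.0 / (4.0 * medium_wavenumber(cfg) ** 2 * np.asarray(tau_d, float))


class MovingMassEstimator(BaseEstimator):
    """Fractional moving mass from temporal-interference variance.

    Stateless transformer: ``transform`` maps a `TemporalCube` to a per-pixel
    FMM map in grams, ``Var_t[I/I0] / A(cfg)`` with the package's normative
    pre-factor. Pixels with non-positive reference are masked (NaN).

    Parameters
    ----------
    cfg : OpticsConfig, optional
    detrend : bool
        Subtract the fourth-order polynomial trend from each pixel trace
        before taking the variance. Default off: the raw normalized trace is
        the normative input, matching the forward generator.
    """

    def __init__(self, cfg=None, detrend: bool = False):
        self.cfg = cfg
        self.detrend = detrend

    def fit(self, X=None, y=None):
        return self

    def transform(self, cube: TemporalCube) -> DynamicsMaps:
        cfg = self.cfg or OpticsConfig()
        norm, good = cube.normalized()
        if self.detrend:
            t = cube.t
            coeffs = np.polynomial.polynomial.polyfit(
                t, norm.reshape(-1, cube.n_frames).T, deg=4)
            trend = np.polynomial.polynomial.polyval(t, coeffs)
            norm = norm - trend.reshape(norm.shape)
        var = norm.var(axis=-1, ddof=1)
        fmm = var / fmm_prefactor(cfg)
        fmm[~good] = np.nan
        return DynamicsMaps(fmm=fmm, valid_mask=good)

    def fit_transform(self, cube: TemporalCube, y=None) -> DynamicsMaps:
        return self.fit().transform(cube)


class DiffusionEstimator(BaseEstimator):
    """Effective diffusion from the temporal-autocorrelation decay rate.

    Per pixel, the normalized autocorrelation C(tau) of the mean-subtracted
    trace is fitted with ``exp(-tau / tau_d)`` by unweighted least squares on
    the log, and ``D_e = 1 / (4 k_med^2 tau_d)``. The fit covers the initial
    decay only: contiguous positive lags within the first quarter of the
    record with ``C >= acf_floor`` (default 0.2). Beyond that point the
    finite-record autocorrelation estimate is dominated by its negative
    mean-subtraction bias, which steepens the apparent decay; restricting to
    the early lags keeps the decay-time estimate unbiased to a few per cent.
    The lag-``tau`` autocovariance is unbiased by ``n / (n - tau)``.

    Pixels whose ACF shows no decay (constant trace, or no positive-lag
    support) are flagged below-floor and reported NaN. Estimates are clipped
    to the instrument's measurable band with flags. Region summaries are
    fitted on the region-averaged ACF, which suppresses the per-pixel lag
    noise the transverse-error caveat warns about.
    """

    def __init__(self, cfg=None, max_lag_fraction: float = 0.25,
                 acf_floor: float = 0.2):
        self.cfg = cfg
        self.max_lag_fraction = max_lag_fraction
        self.acf_floor = acf_floor

    def fit(self, X=None, y=None):
        return self

    @staticmethod
    def _acf(traces: np.ndarray, n_lags: int,
             subtract_mean: bool = True) -> np.ndarray:
        """Sample ACF via FFT, normalized to C(0) = 1; traces (n, t).

        ``subtract_mean=False`` is used when the deterministic part has
        already been removed (ensemble detrending), avoiding the negative
        finite-record bias of per-trace mean subtraction.
        """
        if subtract_mean:
            x = traces - traces.mean(axis=-1, keepdims=True)
        else:
            x = traces
        n = x.shape[-1]
        nfft = int(2 ** np.ceil(np.log2(2 * n)))
        f = np.fft.rfft(x, nfft, axis=-1)
        acov = np.fft.irfft(f * np.conj(f), nfft, axis=-1)[..., : n_lags + 1]
        acov *= n / (n - np.arange(n_lags + 1, dtype=float))
        c0 = acov[..., :1].copy()
        c0[c0 <= 0] = np.nan
        return acov / c0

    def _fit_tau(self, acf_row: np.ndarray, dt: float,
                 n_frames: int | None = None) -> float:
        """Decay time from one ACF (lags 1..L); NaN when no decay is seen.

        With ``n_frames`` given, the per-trace mean-subtraction bias of the
        sample ACF — approximately a uniform shift of
        ``-(1 + rho) / ((1 - rho) n)`` — is removed by fixed-point
        iteration before the log-linear fit.
        """
        c = np.asarray(acf_row[1:], dtype=float)

        def fit(cvals: np.ndarray) -> float:
            usable = cvals > max(0.0, self.acf_floor)
            if not usable.any() or not usable[0]:
                return np.nan
            stop = int(np.argmin(usable)) if not usable.all() else usable.size
            lags = np.arange(1, stop + 1) * dt
            logc = np.log(cvals[:stop])
            if logc.size < 2:
                return -lags[0] / logc[0] if logc[0] < 0 else np.nan
            slope = np.polyfit(lags, logc, 1)[0]
            return -1.0 / slope if slope < 0 else np.nan

        tau = fit(c)
        if n_frames is None or not np.isfinite(tau):
            return tau
        # decay times beyond the record length are not identifiable
        tau_cap = n_frames * dt
        tau = min(tau, tau_cap)
        for _ in range(5):
            rho = np.exp(-dt / tau)
            bias = (1.0 + rho) / ((1.0 - rho) * n_frames)
            if bias >= 0.25:  # correction unreliable; stop here
                return tau
            corrected = c * (1.0 - bias) + bias
            new_tau = fit(corrected)
            if not np.isfinite(new_tau):
                return tau
            new_tau = min(new_tau, tau_cap)
            if abs(new_tau - tau) < 1e-4 * tau:
                return new_tau
            tau = new_tau
        return tau

    def transform(self, cube: TemporalCube, regions: dict | None = None
                  ) -> DynamicsMaps:
        cfg = self.cfg or OpticsConfig()
        if cube.n_frames < 20:
            raise ValueError("need at least 20 frames for a decay fit")
        norm, good = cube.normalized()
        n_lags = max(2, int(cube.n_frames * self.max_lag_fraction))
        flat = np.ptp(norm, axis=-1) == 0
        traces = norm.reshape(-1, cube.n_frames)
        acf = self._acf(traces, n_lags).reshape(
            norm.shape[0], norm.shape[1], -1)
        tau = np.full(norm.shape[:2], np.nan)
        it = np.ndindex(norm.shape[:2])
        for idx in it:
            if good[idx] and not flat[idx] and np.isfinite(acf[idx][0]):
                tau[idx] = self._fit_tau(acf[idx], cube.frame_interval,
                                         n_frames=cube.n_frames)
        d_e = np.full_like(tau, np.nan)
        ok = np.isfinite(tau) & (tau > 0)
        d_e[ok] = diffusion_from_tau(tau[ok], cfg)
        below_floor = ~ok
        lo, hi = DE_MEASURABLE_BAND
        out_of_band = ok & ((d_e < lo) | (d_e > hi))
        d_e[ok] = np.clip(d_e[ok], lo, hi)
        maps = DynamicsMaps(d_e=d_e, valid_mask=good & ok & ~out_of_band,
                            below_floor=below_floor)
        if regions:
            for name, mask in regions.items():
                sel = np.asarray(mask, bool) & good & ~flat
                if not sel.any():
                    maps.region_summaries[name] = {"d_e": np.nan, "n": 0}
                    continue
                # ensemble detrending: the pixel-mean at each frame removes
                # the shared deterministic drift without the per-trace
                # mean-subtraction bias (needs >= a few pixels)
                region_traces = norm[sel]
                if region_traces.shape[0] >= 8:
                    resid = region_traces - region_traces.mean(
                        axis=0, keepdims=True)
                    mean_acf = np.nanmean(self._acf(
                        resid, n_lags, subtract_mean=False), axis=0)
                    tau_r = self._fit_tau(mean_acf, cube.frame_interval)
                else:
                    mean_acf = np.nanmean(acf[sel], axis=0)
                    tau_r = self._fit_tau(mean_acf, cube.frame_interval,
                                          n_frames=cube.n_frames)
                de_r = (float(diffusion_from_tau(tau_r, cfg))
                        if np.isfinite(tau_r) and tau_r > 0 else np.nan)
                maps.region_summaries[name] = {
                    "d_e": de_r, "tau_d": float(tau_r), "n": int(sel.sum())}
        return maps

    def fit_transform(self, cube: TemporalCube, regions=None) -> DynamicsMaps:
        return self.fit().transform(cube, regions=regions)


def fractional_moving_mass(cube: TemporalCube, cfg: OpticsConfig | None = None,
                           detrend: bool = False) -> np.ndarray:
    """Per-pixel fractional moving mass map in grams."""
    return MovingMassEstimator(cfg=cfg, detrend=detrend).transform(cube).fmm


def effective_diffusion(cube: TemporalCube, cfg: OpticsConfig | None = None,
                        regions: dict | None = None) -> DynamicsMaps:
    """Per-pixel effective diffusion map (µm²/s) with flags and summaries."""
    return DiffusionEstimator(cfg=cfg).transform(cube, regions=regions)


# ---------------------------------------------------------------------------
# relative CVC workflow
# ---------------------------------------------------------------------------

def relative_cvc_trace(cube: TemporalCube, region, region_label: str = "body",
                       cell_id: str = "") -> CvcTrace:
    """Region-mean relative CVC trace, inverted and min-max scaled to [0, 1].

    The raw trace is the region mean of ``(I(t) - I0) / I0``. Mean intensity
    is inversely proportional to local macromolecular concentration, so the
    trace is inverted through ``1 / (1 + raw) = I0 / I`` (strictly decreasing
    in intensity, and finite for positive intensities) before min-max
    scaling. A flat trace yields the all-0.5 degenerate output with
    ``flat_trace`` set.
    """
    region = np.asarray(region, dtype=bool)
    norm, good = cube.normalized()
    sel = region & good
    if not sel.any():
        raise ValueError("region contains no analyzable pixels")
    raw = norm[sel].mean(axis=0) - 1.0
    inv = 1.0 / (1.0 + raw)
    lo, hi = inv.min(), inv.max()
    if hi == lo:
        cvc = np.full_like(inv, 0.5)
        flat = True
    else:
        cvc = (inv - lo) / (hi - lo)
        flat = False
    return CvcTrace(t=cube.t, raw=raw, cvc_rel=cvc,
                    region_label=region_label, cell_id=cell_id,
                    flat_trace=flat)


def fit_polynomial_trend(trace: CvcTrace, order: int = 4) -> CvcTrace:
    """Least-squares polynomial trend of the relative CVC trace.

    Stores coefficients (numpy ``polyfit`` convention, highest power first)
    and the fitted curve on the trace; the high-frequency residual
    ``cvc_rel - trend`` stays available for moving-mass cross-checks.
    """
    if len(trace.t) <= order + 1:
        raise ValueError("trace shorter than polynomial order + 2")
    coeffs = np.polyfit(trace.t, trace.cvc_rel, deg=order)
    trace.poly_coeffs = coeffs
    trace.trend = np.polyval(coeffs, trace.t)
    return trace


def ensemble_cvc(traces: list[CvcTrace], order: int = 4,
                 n_grid: int | None = None) -> dict:
    """Pointwise mean trend ± s.e.m. across cells on a common time grid.

    Traces are fitted (if needed) and their trends linearly resampled onto
    the intersection time span. A single trace returns its mean with
    ``sem=None`` and the undefined flag set.
    """
    if not traces:
        raise ValueError("no traces supplied")
    for tr in traces:
        if tr.trend is None:
            fit_polynomial_trend(tr, order=order)
    t0 = max(tr.t[0] for tr in traces)
    t1 = min(tr.t[-1] for tr in traces)
    if t1 <= t0:
        raise ValueError("traces do not share a common time span")
    m = n_grid or min(len(tr.t) for tr in traces)
    grid = np.linspace(t0, t1, m)
    stack = np.vstack([np.interp(grid, tr.t, tr.trend) for tr in traces])
    mean = stack.mean(axis=0)
    if len(traces) < 2:
        return {"t": grid, "mean": mean, "sem": None, "n": 1,
                "sem_undefined": True}
    sem = stack.std(axis=0, ddof=1) / np.sqrt(len(traces))
    return {"t": grid, "mean": mean, "sem": sem, "n": len(traces),
            "sem_undefined": False}


def bleb_body_cvc_ratio(summaries: list[dict]) -> dict:
    """Per-cell bleb-to-body ratio of mean relative CVC.

    ``summaries`` rows carry ``cell_id``, ``region`` ("body" | "bleb") and
    ``cvc_mean``. Cells lacking either region, or with a zero body mean, are
    excluded and listed under ``excluded``.
    """
    by_cell: dict[str, dict] = {}
    for row in summaries:
        by_cell.setdefault(str(row["cell_id"]), {})[row["region"]] = float(
            row["cvc_mean"])
    ratios, cells, excluded = [], [], []
    for cell_id, regs in sorted(by_cell.items()):
        if "body" not in regs or "bleb" not in regs:
            excluded.append((cell_id, "unpaired"))
            continue
        if regs["body"] == 0:
            excluded.append((cell_id, "zero body mean"))
            continue
        ratios.append(regs["bleb"] / regs["body"])
        cells.append(cell_id)
    return {"cell_id": cells, "ratio": np.asarray(ratios), "excluded": excluded}
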