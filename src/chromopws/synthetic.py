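"""Ground-truth generators for every modality the pipeline analyzes.

The study's raw data are live-cell microscopy streams that cannot be
redistributed; this module generates synthetic stand-ins with the exact
statistical structure the estimators assume, so the full pipeline is
verifiable by parameter recovery:

* nucleus + bleb geometries (`make_scene`): elliptical nuclear body, a
  circular bleb connected through a neck (a herniation still connected to
  the body), optionally a detached micronucleus;
* spectral cubes (`synth_spectral_cube`): per-pixel interference spectra
  from the static forward model at each region's packing scaling D;
* temporal cubes (`synth_temporal_cube`): per-pixel discrete
  Ornstein-Uhlenbeck (AR(1)) traces whose stationary variance encodes the
  fractional moving mass through the shared pre-factor A(cfg) and whose
  exponential autocorrelation encodes the effective diffusion, plus a slow
  per-region density drift for the relative-CVC workflow;
* localization tables (`synth_localizations`): nanodomain point clouds
  (uniform-disk domains with localization noise) over uniform background.

Every generator is a pure function of (spec, seed). The packaged
"paper-like" scenario bundle encodes the study's qualitative contrasts:
blebs carry lower packing scaling and moving mass but higher mobility than
the nuclear body; lamin-depletion blebs sit above enzyme-inhibition blebs
in D and moving mass; HDAC inhibition raises body density while suppressing
the bleb-to-body density ratio; bleb nanodomains are smaller than body
nanodomains.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .dynamic import DE_MEASURABLE_BAND, TemporalCube, tau_from_diffusion
from .optics import OpticsConfig, fmm_prefactor
from .static import ChromatinMedium, SpectralCube, simulate_interference_spectrum

__all__ = [
    "RegionScene",
    "ScenarioSpec",
    "make_scene",
    "synth_spectral_cube",
    "synth_temporal_cube",
    "synth_localizations",
    "paper_like_scenarios",
]


@dataclass
class RegionScene:
    """Labeled nucleus/bleb geometry.

    ``label_image``: 0 background, 1 nuclear body, >= 2 blebs (4-connected to
    the body through a neck), negative codes for detached micronuclei.
    """

    label_image: np.ndarray
    pairing: dict = field(default_factory=dict)  # bleb label -> body label
    pixel_size: float = 0.15                     # µm
    params: dict = field(default_factory=dict)

    @property
    def body_mask(self) -> np.ndarray:
        return self.label_image == 1

    @property
    def bleb_mask(self) -> np.ndarray:
        return self.label_image >= 2

    def region_masks(self) -> dict:
        masks = {"body": self.body_mask}
        if self.bleb_mask.any():
            masks["bleb"] = self.bleb_mask
        return masks


@dataclass(frozen=True)
class ScenarioSpec:
    """Ground truth for one synthetic condition.

    Packing scaling D per region, fractional moving mass (grams), effective
    diffusion (µm²/s, inside the measurable band), slow density-drift
    amplitudes for the CVC workflow (fractional intensity depression),
    nanodomain geometry for the localization generator, and scene geometry.
    """

    condition: str = "control"
    # static
    d_body: float = 2.6
    d_bleb: float = 2.3
    # dynamics
    fmm_body: float = 3.0e-19
    fmm_bleb: float = 1.76e-19
    de_body: float = 4.0e-3
    de_bleb: float = 5.09e-3
    # relative CVC (fractional intensity depression levels, body/bleb)
    cvc_body: float = 0.10
    cvc_bleb: float = 0.12
    cvc_ramp: float = 0.3          # fractional slow ramp of the level over the record
    # SMLM nanodomains
    domain_radius_body: float = 120.0   # nm
    domain_radius_bleb: float = 50.0
    domain_count_body: int = 120
    domain_count_bleb: int = 40
    domain_occupancy: int = 30
    background_events: int = 150
    loc_uncertainty_nm: float = 25.0
    # geometry
    shape: tuple = (64, 64)
    pixel_size: float = 0.15       # µm
    nucleus_axes: tuple = (22.0, 16.0)   # semi-axes, px (x, y)
    bleb_radius_px: float = 6.0
    neck_width_px: float = 3.0
    with_bleb: bool = True
    with_micronucleus: bool = False
    micronucleus_radius_px: float = 4.0
    # acquisition
    n_frames: int = 300
    n_cells: int = 1

    def __post_init__(self) -> None:
        for name in ("de_body", "de_bleb", "domain_radius_body",
                     "domain_radius_bleb", "loc_uncertainty_nm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.fmm_body < 0 or self.fmm_bleb < 0:
            raise ValueError("moving mass must be non-negative")
        lo, hi = DE_MEASURABLE_BAND
        for name in ("de_body", "de_bleb"):
            v = getattr(self, name)
            if not (lo <= v <= hi):
                raise ValueError(
                    f"{name}={v} outside the measurable band {DE_MEASURABLE_BAND}")

    def truth(self) -> dict:
        """Sidecar ground truth, sufficient to score every estimator."""
        return {
            "condition": self.condition,
            "d": {"body": self.d_body, "bleb": self.d_bleb},
            "fmm_g": {"body": self.fmm_body, "bleb": self.fmm_bleb},
            "de_um2_s": {"body": self.de_body, "bleb": self.de_bleb},
            "cvc_level": {"body": self.cvc_body, "bleb": self.cvc_bleb},
            "domain_radius_nm": {"body": self.domain_radius_body,
                                 "bleb": self.domain_radius_bleb},
            "domain_count": {"body": self.domain_count_body,
                             "bleb": self.domain_count_bleb},
        }


def _as_rng(rng_seed) -> np.random.Generator:
    if isinstance(rng_seed, np.random.Generator):
        return rng_seed
    return np.random.default_rng(rng_seed)


def make_scene(spec: ScenarioSpec, rng_seed=0) -> RegionScene:
    """Build the labeled nucleus(+bleb)(+micronucleus) geometry.

    The bleb is a circle attached to the elliptical body through a
    rectangular neck; connectivity is verified on the finished mask, and a
    protrusion that ends up 4-disconnected (e.g. ``neck_width_px=0``) is
    relabeled as a micronucleus, so the emitted labels always agree with the
    mask's true topology.
    """
    rng = _as_rng(rng_seed)
    ny, nx = spec.shape
    ax, ay = spec.nucleus_axes
    if spec.with_bleb and spec.bleb_radius_px >= min(ax, ay):
        raise ValueError("bleb radius must be smaller than the nucleus minor axis")
    # small seed-driven jitter of the nucleus center keeps scenes distinct
    cy = ny / 2 + rng.uniform(-1.5, 1.5)
    cx = nx / 2 - spec.bleb_radius_px + rng.uniform(-1.5, 1.5)
    yy, xx = np.mgrid[0:ny, 0:nx]
    label = np.zeros((ny, nx), dtype=int)
    body = ((xx - cx) / ax) ** 2 + ((yy - cy) / ay) ** 2 <= 1.0
    label[body] = 1
    if spec.with_bleb:
        r = spec.bleb_radius_px
        gap = 1.0 if spec.neck_width_px > 0 else 2.0
        bx = cx + ax + r + gap
        bleb = (xx - bx) ** 2 + (yy - cy) ** 2 <= r**2
        label[bleb & ~body] = 2
        if spec.neck_width_px > 0:
            half = spec.neck_width_px / 2.0
            neck = ((np.abs(yy - cy) <= half)
                    & (xx >= cx + ax - 1) & (xx <= bx))
            label[neck & ~body] = 2
    if spec.with_micronucleus:
        r = spec.micronucleus_radius_px
        mx, my = nx * 0.12, ny * 0.15
        micro = (xx - mx) ** 2 + (yy - my) ** 2 <= r**2
        # guarantee 4-disconnection from the body: keep a 1-px margin
        margin = ndimage.binary_dilation(
            label != 0, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        micro &= ~margin
        if not micro.any():
            raise ValueError("no room for a detached micronucleus")
        label[micro] = -1
    # verify topology: any label-2 component not 4-connected to the body
    # becomes a micronucleus
    pairing = {}
    if spec.with_bleb:
        comp, n_comp = ndimage.label(label == 2,
                                     structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]])
        for c in range(1, n_comp + 1):
            m = comp == c
            touch = ndimage.binary_dilation(
                m, structure=[[0, 1, 0], [1, 1, 1], [0, 1, 0]]) & (label == 1)
            if touch.any():
                pairing[2] = 1
            else:
                label[m] = -2
    return RegionScene(label_image=label, pairing=pairing,
                       pixel_size=spec.pixel_size,
                       params={"condition": spec.condition,
                               "nucleus_axes": spec.nucleus_axes,
                               "bleb_radius_px": spec.bleb_radius_px,
                               "neck_width_px": spec.neck_width_px})


def synth_spectral_cube(scene: RegionScene, spec: ScenarioSpec,
                        cfg: OpticsConfig | None = None, rng_seed=0,
                        medium_kwargs: dict | None = None
                        ) -> tuple[SpectralCube, dict]:
    """Spectral cube with per-region packing scaling.

    Body pixels draw spectra from the forward model at ``d_body``, bleb
    pixels at ``d_bleb``; background and micronucleus pixels carry the
    flat reference spectrum (no medium). Ground truth rides along as a
    sidecar dict.
    """
    cfg = cfg or OpticsConfig()
    rng = _as_rng(rng_seed)
    label = scene.label_image
    ny, nx = label.shape
    n_lam = cfg.lambda_grid.size
    intensity = np.full((ny, nx, n_lam), cfg.gamma)
    kw = dict(medium_kwargs or {})
    region_d = {"body": (label == 1, spec.d_body),
                "bleb": (label >= 2, spec.d_bleb)}
    for name, (mask, d) in region_d.items():
        n_pix = int(mask.sum())
        if n_pix == 0:
            continue
        if d is None:
            raise ValueError(f"region {name!r} has no assigned D")
        medium = ChromatinMedium(D=float(d), **kw)
        spectra = simulate_interference_spectrum(medium, cfg, rng_seed=rng,
                                                 n_spectra=n_pix)
        intensity[mask] = spectra
    reference = np.ones((ny, nx))
    cube = SpectralCube(intensity=intensity, lambda_grid=cfg.lambda_grid,
                        reference=reference, pixel_size=scene.pixel_size)
    return cube, spec.truth()


def synth_temporal_cube(scene: RegionScene, spec: ScenarioSpec,
                        cfg: OpticsConfig | None = None, rng_seed=0
                        ) -> tuple[TemporalCube, dict]:
    """Temporal cube: per-pixel AR(1) fluctuations plus slow density drift.

    For each region the pixel trace is ``I0 * (1 + g(t) + drift(t))`` where
    ``g`` is a stationary AR(1) (exact discrete Ornstein-Uhlenbeck) process
    with variance ``A(cfg) * fmm_true`` and lag autocorrelation
    ``exp(-tau / tau_d)``, ``tau_d = 1 / (4 k_med^2 d_e_true)``; ``drift``
    is the region's slow fractional intensity depression
    ``-level * (1 + ramp * s(t))`` with ``s`` a linear 0→1 ramp, encoding
    relative chromatin volume concentration. Background pixels are constant.
    """
    cfg = cfg or OpticsConfig()
    rng = _as_rng(rng_seed)
    label = scene.label_image
    ny, nx = label.shape
    nt = spec.n_frames
    dt = cfg.frame_interval
    a_pref = fmm_prefactor(cfg)
    i0 = np.full((ny, nx), 1000.0)
    intensity = np.ones((ny, nx, nt))
    s_ramp = np.linspace(0.0, 1.0, nt)
    regions = {
        "body": (label == 1, spec.fmm_body, spec.de_body, spec.cvc_body),
        "bleb": (label >= 2, spec.fmm_bleb, spec.de_bleb, spec.cvc_bleb),
    }
    for name, (mask, fmm, d_e, level) in regions.items():
        n_pix = int(mask.sum())
        if n_pix == 0:
            continue
        var = a_pref * fmm
        if var > 0:
            tau_d = tau_from_diffusion(d_e, cfg)
            rho = np.exp(-dt / tau_d)
            g = np.empty((n_pix, nt))
            g[:, 0] = rng.standard_normal(n_pix)
            innov = rng.standard_normal((n_pix, nt - 1)) * np.sqrt(1 - rho**2)
            for t in range(1, nt):
                g[:, t] = rho * g[:, t - 1] + innov[:, t - 1]
            g *= np.sqrt(var)
        else:
            g = np.zeros((n_pix, nt))
        drift = -level * (1.0 + spec.cvc_ramp * s_ramp)
        intensity[mask] = 1.0 + g + drift[None, :]
    # detected intensity cannot go negative; rare deep excursions are floored
    np.maximum(intensity, 0.02, out=intensity)
    cube = TemporalCube(intensity=intensity * i0[..., None], i0=i0,
                        frame_interval=dt, lambda_dyn=cfg.lambda_dyn,
                        pixel_size=scene.pixel_size)
    truth = spec.truth()
    truth["fmm_variance"] = {k: a_pref * v
                             for k, v in truth["fmm_g"].items()}
    return cube, truth


def synth_localizations(scene: RegionScene, spec: ScenarioSpec, rng_seed=0
                        ) -> tuple[pd.DataFrame, dict]:
    """Nanodomain localization table over the scene, nm coordinates.

    Domain centers are uniform over the region's pixels; each domain emits
    events uniform in a disk of the region's domain radius, plus Gaussian
    localization noise with the event's uncertainty. The event count per
    domain scales with domain area (``domain_occupancy`` is the count at the
    50-nm reference radius), i.e. the labeling surface density is constant —
    without this, large domains fall below the clustering density threshold
    and fragment. Uniform background events cover the full field.
    Ground-truth domain membership is recorded in the ``truth_domain``
    column (-1 background).
    """
    rng = _as_rng(rng_seed)
    label = scene.label_image
    ny, nx = label.shape
    px_nm = scene.pixel_size * 1000.0
    rows_x, rows_y, unc, dom_id, reg = [], [], [], [], []
    next_dom = 0
    for name, mask, count, radius in (
            ("body", label == 1, spec.domain_count_body,
             spec.domain_radius_body),
            ("bleb", label >= 2, spec.domain_count_bleb,
             spec.domain_radius_bleb)):
        idx = np.flatnonzero(mask.ravel())
        if idx.size == 0:
            continue
        area_nm2 = idx.size * px_nm**2
        if count * np.pi * radius**2 > 0.5 * area_nm2:
            raise ValueError(
                f"{count} domains of radius {radius} nm infeasible for the "
                f"{name} region area")
        choice = rng.choice(idx, size=count, replace=True)
        ci = choice // nx
        cj = choice % nx
        centers = np.column_stack([
            (cj + rng.uniform(0, 1, count)) * px_nm,
            (ci + rng.uniform(0, 1, count)) * px_nm])
        n_per_domain = max(10, int(round(spec.domain_occupancy
                                         * (radius / 50.0) ** 2)))
        for c in range(count):
            n_ev = n_per_domain
            theta = rng.uniform(0, 2 * np.pi, n_ev)
            rad = radius * np.sqrt(rng.uniform(0, 1, n_ev))
            u = np.clip(rng.normal(spec.loc_uncertainty_nm,
                                   spec.loc_uncertainty_nm / 5.0, n_ev),
                        5.0, None)
            x = centers[c, 0] + rad * np.cos(theta) + rng.normal(0, u)
            y = centers[c, 1] + rad * np.sin(theta) + rng.normal(0, u)
            rows_x.append(x)
            rows_y.append(y)
            unc.append(u)
            dom_id.append(np.full(n_ev, next_dom))
            reg.append([name] * n_ev)
            next_dom += 1
    # uniform background over the field of view
    nb = spec.background_events
    if nb:
        rows_x.append(rng.uniform(0, nx * px_nm, nb))
        rows_y.append(rng.uniform(0, ny * px_nm, nb))
        unc.append(np.clip(rng.normal(spec.loc_uncertainty_nm,
                                      spec.loc_uncertainty_nm / 5.0, nb),
                           5.0, None))
        dom_id.append(np.full(nb, -1))
        reg.append(["background"] * nb)
    x = np.concatenate(rows_x)
    n = x.size
    locs = pd.DataFrame({
        "x": x,
        "y": np.concatenate(rows_y),
        "uncertainty": np.concatenate(unc),
        "frame": rng.integers(1, 10000, n),
        "truth_domain": np.concatenate(dom_id).astype(int),
        "truth_region": np.concatenate([np.asarray(r) for r in reg]),
    })
    # shuffle so input order carries no structure
    locs = locs.sample(frac=1.0, random_state=int(rng.integers(2**31))
                       ).reset_index(drop=True)
    return locs, spec.truth()


def paper_like_scenarios() -> dict[str, ScenarioSpec]:
    """The packaged three-condition scenario bundle.

    Encodes the study's qualitative sign structure (effect directions, not
    live-cell magnitudes): every condition has bleb D and moving mass below
    the body and bleb mobility above it; the lamin-depleted condition raises
    body D and moving mass and carries the largest bleb D / moving mass;
    HDAC inhibition lowers D everywhere, fragments nanodomains (smallest
    radii), raises body density, and suppresses the bleb-to-body density
    ratio. Bleb moving-mass magnitudes sit in the observed ~2e-19 g band;
    effective diffusions in the few-1e-3 µm²/s range.
    """
    control = ScenarioSpec(
        condition="control",
        d_body=2.60, d_bleb=2.30,
        fmm_body=3.0e-19, fmm_bleb=1.76e-19,
        de_body=4.0e-3, de_bleb=5.09e-3,
        cvc_body=0.10, cvc_bleb=0.12,
        domain_radius_body=120.0, domain_radius_bleb=50.0)
    lamin = replace(
        control, condition="lamin_depleted",
        d_body=2.75, d_bleb=2.45,
        fmm_body=3.6e-19, fmm_bleb=2.26e-19,
        de_body=3.8e-3, de_bleb=4.35e-3,
        cvc_body=0.10, cvc_bleb=0.11,
        domain_radius_body=150.0, domain_radius_bleb=60.0)
    hdac = replace(
        control, condition="hdac_inhibited",
        d_body=2.35, d_bleb=2.10,
        fmm_body=2.4e-19, fmm_bleb=1.4e-19,
        de_body=4.1e-3, de_bleb=4.34e-3,
        cvc_body=0.16, cvc_bleb=0.10,
        domain_radius_body=80.0, domain_radius_bleb=40.0)
    return {"control": control, "lamin_depleted": lamin,
            "hdac_inhibited": hdac}
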