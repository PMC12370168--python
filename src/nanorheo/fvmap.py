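"""Force-volume processing: pixel grids of force curves into parameter maps.

A force volume is a grid of force-distance curves plus topography. This
module generates synthetic phantom volumes for end-to-end validation,
batch-inverts them into E0 / gamma / height maps with either the trained
regressor or the classical least-squares fit, and renders the combined
height+modulus compositional image.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field

import numpy as np
from matplotlib.colors import hsv_to_rgb

from .basis import BSplineBasis
from .contact import (
    PLRMaterial,
    ProbeCellGeometry,
    ForceCurve,
    simulate_force_curve,
)
from .dataset import preprocess_curve
from .fit import fit_curve
from .profiles import IndentationProfile, make_triangular

#: quality-map codes; 0 means the pixel was inverted successfully.
QUALITY_OK = 0.0
QUALITY_PREPROCESS_FAILED = 1.0
QUALITY_INFERENCE_FAILED = 2.0

#: RGB no-data color used for masked pixels in rendered overlays.
NO_DATA_RGB = (1.0, 0.0, 1.0)

#: maximum allowed r_max/h; deeper setpoints are clamped with a warning count.
RHO_CLAMP = 0.98


@dataclass(frozen=True)
class PhantomSpec:
    """Synthetic cell phantom: height dome plus E0/gamma composition fields.

    The height field is a dome on a thin margin; the modulus field is a
    uniform background with a softer nucleus patch and stiffer filament-like
    ridges. Regions are defined in fractional coordinates of the grid.
    """

    nx: int = 32
    ny: int = 32
    h_margin: float = 1.0e-6
    h_peak: float = 7.0e-6
    E0_background: float = 5_000.0
    E0_nucleus: float = 1_500.0
    E0_ridge: float = 20_000.0
    gamma_background: float = 0.30
    gamma_nucleus: float = 0.20
    nucleus_center: tuple[float, float] = (0.5, 0.5)
    nucleus_radius: float = 0.22
    n_ridges: int = 3
    ridge_width: float = 0.03
    I_max: float = 0.75e-6
    t_tot: float = 0.2
    theta: float = math.radians(25.0)
    kind: str = "dome"  # "uniform" | "two-region" | "dome"

    def __post_init__(self) -> None:
        if self.nx <= 0 or self.ny <= 0:
            raise ValueError("grid dims must be positive")
        if self.kind not in ("uniform", "two-region", "dome"):
            raise ValueError(f"unknown phantom kind {self.kind!r}")


def build_fields(spec: PhantomSpec) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Ground-truth (E0, gamma, height) fields of a phantom, shape (ny, nx)."""
    yy, xx = np.meshgrid(
        (np.arange(spec.ny) + 0.5) / spec.ny,
        (np.arange(spec.nx) + 0.5) / spec.nx,
        indexing="ij",
    )
    if spec.kind == "uniform":
        E0 = np.full((spec.ny, spec.nx), spec.E0_background)
        gamma = np.full((spec.ny, spec.nx), spec.gamma_background)
        h = np.full((spec.ny, spec.nx), spec.h_peak)
        return E0, gamma, h

    cy, cx = spec.nucleus_center
    r2 = (xx - cx) ** 2 + (yy - cy) ** 2
    nucleus = r2 <= spec.nucleus_radius**2

    if spec.kind == "two-region":
        E0 = np.where(nucleus, spec.E0_nucleus, spec.E0_background)
        gamma = np.where(nucleus, spec.gamma_nucleus, spec.gamma_background)
        h = np.full((spec.ny, spec.nx), spec.h_peak)
        return E0, gamma, h

    # dome: raised-cosine height from margin to peak
    rim = np.sqrt(r2) / 0.5
    dome = 0.5 * (1.0 + np.cos(np.pi * np.clip(rim, 0.0, 1.0)))
    h = spec.h_margin + (spec.h_peak - spec.h_margin) * dome
    E0 = np.where(nucleus, spec.E0_nucleus, spec.E0_background)
    gamma = np.where(nucleus, spec.gamma_nucleus, spec.gamma_background)
    for k in range(spec.n_ridges):
        ang = np.pi * (k + 0.7) / max(spec.n_ridges, 1)
        d = np.abs(
            (xx - cx) * math.sin(ang) - (yy - cy) * math.cos(ang)
        )
        ridge = (d < spec.ridge_width) & ~nucleus & (rim < 0.9)
        E0 = np.where(ridge, spec.E0_ridge, E0)
    return E0, gamma, h


@dataclass
class ForceVolume:
    """Pixel grid of force curves sharing one acquisition protocol."""

    t: np.ndarray  # (ny, nx, nt) seconds
    F: np.ndarray  # (ny, nx, nt) newtons
    I: np.ndarray  # (ny, nx, nt) meters
    height: np.ndarray  # (ny, nx) meters
    I_max: np.ndarray  # (ny, nx) meters, per-pixel (may be clamped)
    t_tot: float
    theta: float
    p: float  # approach fraction of the triangular protocol
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        ny, nx = self.height.shape
        if ny <= 0 or nx <= 0:
            raise ValueError("grid dims must be positive")
        if self.t.shape[:2] != (ny, nx) or self.F.shape != self.t.shape:
            raise ValueError("array dims inconsistent")
        if np.any(self.height <= 0):
            raise ValueError("per-pixel height must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return self.height.shape

    def curve(self, iy: int, ix: int) -> ForceCurve:
        """Materialize the ForceCurve of one pixel."""
        t = self.t[iy, ix]
        F = self.F[iy, ix]
        I = self.I[iy, ix]
        i_peak = int(np.argmax(I))
        v = np.gradient(I, t)
        F_bar = float(np.trapezoid(F, t) / self.t_tot)
        v_bar = float(np.trapezoid(np.abs(v), t) / self.t_tot)
        return ForceCurve(
            t=t,
            F=F,
            I=I,
            v=v,
            t_max=float(t[i_peak]),
            t_tot=self.t_tot,
            I_max=float(self.I_max[iy, ix]),
            F_bar=F_bar,
            v_bar=v_bar,
            meta={"pixel": (iy, ix), "theta": self.theta},
        )

    def profile(self, iy: int, ix: int, basis: BSplineBasis | None = None
                ) -> IndentationProfile:
        """Indentation profile of one pixel's triangular protocol."""
        I_max = float(self.I_max[iy, ix])
        v_app = I_max / (self.p * self.t_tot)
        v_ret = I_max / ((1.0 - self.p) * self.t_tot)
        return make_triangular(I_max, v_app, v_ret, basis)

    def geometry(self, iy: int, ix: int) -> ProbeCellGeometry:
        return ProbeCellGeometry(theta=self.theta, h=float(self.height[iy, ix]))


def synth_force_volume(
    spec: PhantomSpec,
    seed: int,
    n_points: int = 301,
) -> tuple[ForceVolume, dict]:
    """Simulate one force curve per phantom pixel.

    Curves are stored on the simulation time grid itself (identical for all
    pixels of the shared triangular protocol), so downstream per-pixel fits
    see the data at full fidelity. Returns the volume and a ground-truth
    dict with the true E0/gamma/height fields plus the count of pixels
    whose indentation was clamped to keep r_max/h <= RHO_CLAMP.
    Deterministic for a given spec and seed (the seed is recorded for
    provenance; the triangular protocol itself is deterministic).
    """
    E0_true, gamma_true, h_true = build_fields(spec)
    ny, nx = E0_true.shape
    tan_t = math.tan(spec.theta)
    I_max_req = np.full((ny, nx), spec.I_max)
    I_max_cap = RHO_CLAMP * h_true / tan_t
    I_max = np.minimum(I_max_req, I_max_cap)
    n_clamped = int(np.sum(I_max < I_max_req))

    p = 0.5
    t = np.zeros((ny, nx, n_points))
    F = np.zeros((ny, nx, n_points))
    I = np.zeros((ny, nx, n_points))
    cache: dict[tuple, tuple[np.ndarray, np.ndarray, np.ndarray]] = {}
    for iy in range(ny):
        for ix in range(nx):
            key = (
                round(float(E0_true[iy, ix]), 9),
                round(float(gamma_true[iy, ix]), 9),
                round(float(I_max[iy, ix]), 15),
                round(float(h_true[iy, ix]), 15),
            )
            if key not in cache:
                im = float(I_max[iy, ix])
                prof = make_triangular(
                    im, im / (p * spec.t_tot), im / ((1 - p) * spec.t_tot)
                )
                mat = PLRMaterial(
                    E0=float(E0_true[iy, ix]), gamma=float(gamma_true[iy, ix])
                )
                geom = ProbeCellGeometry(theta=spec.theta, h=float(h_true[iy, ix]))
                curve = simulate_force_curve(prof, mat, geom, n_points)
                cache[key] = (curve.t, curve.F, curve.I)
            ti, Fi, Ii = cache[key]
            t[iy, ix] = ti
            F[iy, ix] = Fi
            I[iy, ix] = Ii

    fv = ForceVolume(
        t=t,
        F=F,
        I=I,
        height=h_true,
        I_max=I_max,
        t_tot=spec.t_tot,
        theta=spec.theta,
        p=p,
        meta={"seed": seed, "phantom_kind": spec.kind, "n_clamped": n_clamped},
    )
    truth = {
        "E0": E0_true,
        "gamma": gamma_true,
        "height": h_true,
        "n_clamped": n_clamped,
    }
    return fv, truth


@dataclass
class NanomechMap:
    """Per-pixel inversion result of a force volume."""

    E0: np.ndarray  # Pa, NaN where masked
    gamma: np.ndarray  # dimensionless, NaN where masked
    height: np.ndarray  # m
    quality: np.ndarray  # failure codes, QUALITY_OK where fine
    provenance: dict = field(default_factory=dict)
    timings: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        shapes = {a.shape for a in (self.E0, self.gamma, self.height, self.quality)}
        if len(shapes) != 1:
            raise ValueError("all maps must share dims")
        if not np.all(np.isfinite(self.quality)):
            raise ValueError("quality map must be finite")

    @property
    def mask(self) -> np.ndarray:
        """True where the pixel failed and is excluded from statistics."""
        return self.quality != QUALITY_OK

    def summary(self) -> dict:
        ok = ~self.mask
        return {
            "n_pixels": int(self.quality.size),
            "n_masked": int(self.mask.sum()),
            "E0_median_pa": float(np.median(self.E0[ok])) if ok.any() else float("nan"),
            "gamma_median": float(np.median(self.gamma[ok])) if ok.any() else float("nan"),
        }


def process_force_volume(
    fv: ForceVolume,
    engine: str = "sml",
    model=None,
    basis: BSplineBasis | None = None,
    pixel_order: np.ndarray | None = None,
    progress=None,
) -> NanomechMap:
    """Invert every pixel of a force volume into (E0, gamma).

    engine "sml" uses a trained NestedRegressor (`model` required); engine
    "fit" runs the classical per-curve least squares. Per-pixel failures
    mask the pixel with a failure code instead of aborting. The result is
    independent of pixel visit order; `pixel_order` (flat indices) only
    controls the processing sequence.
    """
    if engine not in ("sml", "fit"):
        raise ValueError(f"unknown engine {engine!r}")
    if engine == "sml" and model is None:
        raise ValueError("engine 'sml' requires a trained model")
    ny, nx = fv.shape
    if ny * nx == 0:
        raise ValueError("empty volume")
    basis = basis or BSplineBasis()

    E0 = np.full((ny, nx), np.nan)
    gamma = np.full((ny, nx), np.nan)
    quality = np.full((ny, nx), QUALITY_OK)
    t_pre = 0.0
    t_inf = 0.0
    t_start = time.time()

    order = np.arange(ny * nx) if pixel_order is None else np.asarray(pixel_order)
    # identical protocols share one profile/feature template per I_max
    prof_cache: dict[float, IndentationProfile] = {}
    for count, flat in enumerate(order):
        iy, ix = divmod(int(flat), nx)
        try:
            tp = time.time()
            im = float(fv.I_max[iy, ix])
            if im not in prof_cache:
                prof_cache[im] = fv.profile(iy, ix, basis)
            profile = prof_cache[im]
            curve = fv.curve(iy, ix)
            geom = fv.geometry(iy, ix)
            t_pre += time.time() - tp
        except Exception:
            quality[iy, ix] = QUALITY_PREPROCESS_FAILED
            continue
        try:
            ti = time.time()
            if engine == "sml":
                fvec = preprocess_curve(curve, profile, basis, geom)
                g_hat, _, e0_hat = model.predict(fvec)
            else:
                res = fit_curve(curve, profile, geom)
                g_hat, e0_hat = res.gamma_hat, res.E0_hat
            t_inf += time.time() - ti
            E0[iy, ix] = e0_hat
            gamma[iy, ix] = g_hat
        except Exception:
            quality[iy, ix] = QUALITY_INFERENCE_FAILED
        if progress and (count + 1) % 256 == 0:
            progress(count + 1, len(order))

    total = time.time() - t_start
    timings = {
        "loading_s": 0.0,
        "preprocessing_s": t_pre,
        "parameter_inference_s": t_inf,
        "other_s": max(total - t_pre - t_inf, 0.0),
        "total_s": total,
    }
    provenance = {
        "engine": engine,
        "model": getattr(model, "train_meta", {}).get("schema", None)
        if model is not None
        else None,
    }
    return NanomechMap(
        E0=E0,
        gamma=gamma,
        height=fv.height.copy(),
        quality=quality,
        provenance=provenance,
        timings=timings,
    )


def encode_channels(
    nmap: NanomechMap,
    e0_range: tuple[float, float] | None = None,
    h_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Quantize the overlay channels to uint8: [log-E0, height, flag].

    Channel 0 is normalized log10(E0) (the hue source), channel 1 is
    normalized height (the luminance source), channel 2 flags masked
    pixels with 255. This is the stored form of the compositional map;
    decode_compositional inverts it within one quantization step.
    """
    ok = ~nmap.mask
    if e0_range is None:
        vals = nmap.E0[ok]
        e0_range = (float(vals.min()), float(vals.max())) if vals.size else (1.0, 10.0)
    if h_range is None:
        h_range = (float(nmap.height.min()), float(nmap.height.max()))

    def norm(x, lo, hi):
        if hi <= lo:
            return np.full(np.asarray(x).shape, 0.5)
        return np.clip((np.asarray(x, dtype=float) - lo) / (hi - lo), 0.0, 1.0)

    hue_n = norm(np.log10(np.where(ok, nmap.E0, e0_range[0])),
                 math.log10(e0_range[0]), math.log10(e0_range[1]))
    val_n = norm(nmap.height, h_range[0], h_range[1])
    out = np.zeros(nmap.E0.shape + (3,), dtype=np.uint8)
    out[..., 0] = np.round(hue_n * 255.0)
    out[..., 1] = np.round(val_n * 255.0)
    out[..., 2] = np.where(nmap.mask, 255, 0)
    return out


def decode_compositional(
    channels: np.ndarray,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Recover (normalized log-E0, normalized height, mask) from channels.

    Inverse of encode_channels up to uint8 quantization (1/255).
    """
    arr = np.asarray(channels, dtype=float)
    return arr[..., 0] / 255.0, arr[..., 1] / 255.0, channels[..., 2] == 255


def compositional_map(
    nmap: NanomechMap,
    e0_range: tuple[float, float] | None = None,
    h_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Render the combined topography+modulus overlay as uint8 RGB.

    log10(E0) maps to hue (blue soft -> red stiff over 2/3 of the wheel)
    and height maps to luminance (HSV value); saturation is fixed at 1.
    Masked pixels get the designated no-data color. Deterministic.
    """
    channels = encode_channels(nmap, e0_range, h_range)
    hue_n = channels[..., 0] / 255.0
    val_n = channels[..., 1] / 255.0
    hsv = np.stack(
        [(2.0 / 3.0) * (1.0 - hue_n), np.ones_like(hue_n), val_n], axis=-1
    )
    rgb = hsv_to_rgb(hsv)
    rgb[nmap.mask] = NO_DATA_RGB
    return np.round(rgb * 255.0).astype(np.uint8)
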