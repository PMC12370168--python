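"""Synthetic training corpus for the nanorheology regressor.

Each sample is one simulated force-distance curve with known labels
(E0, gamma, r_max/h, f_bar). Sampling follows the study conditions: gamma
and the bottom-effect parameter r_max/h uniform on their admissible ranges,
E0 log-uniform over the soft-to-stiff mammalian-cell range 0.1-100 kPa, and
a mixture of triangular, capped-sinusoidal and random-spline indentation
profiles. All regressor inputs are dimensionless, so the dimensional scales
(E0, I_max, t_tot) influence only the label bookkeeping and the closed-form
modulus recovery.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field

import h5py
import numpy as np
import pandas as pd

from . import contact
from .basis import BSplineBasis, fit_bspline
from .contact import (
    ForceCurve,
    PLRMaterial,
    ProbeCellGeometry,
    dimensionless_force,
    simulate_force_curve,
)
from .profiles import (
    IndentationProfile,
    ProfileGenerationError,
    make_capped_sinusoid,
    make_triangular,
    random_profile,
)

SCHEMA_VERSION = "1.0.0"

PROFILE_KINDS = ("triangular", "capped_sinusoid", "bspline")


@dataclass(frozen=True)
class DatasetConfig:
    """Sampling ranges and preprocessing layout of the synthetic corpus.

    Defaults are the study conditions: gamma ~ U(0, gamma_max),
    r_max/h ~ U(0, 1), E0 log-uniform over 0.1-100 kPa, equal thirds of the
    three profile families, cone semiangle 25 deg, reference time 1 s.
    Dimensional scales span typical force-spectroscopy settings
    (sub-micron to few-micron indentations at 1-100 um/s, i.e. curve
    durations of order 0.05-5 s).
    """

    n: int = 100_000
    gamma_range: tuple[float, float] = (0.0, contact.GAMMA_MAX)
    rho_range: tuple[float, float] = (1e-3, 1.0)
    E0_range_pa: tuple[float, float] = (100.0, 100_000.0)
    I_max_range_m: tuple[float, float] = (0.3e-6, 3.5e-6)
    t_tot_range_s: tuple[float, float] = (0.05, 5.0)
    theta_rad: float = math.radians(25.0)
    t0_s: float = 1.0
    profile_fractions: tuple[float, float, float] = (1 / 3, 1 / 3, 1 / 3)
    p_range: tuple[float, float] = (0.3, 0.7)
    n_force_samples: int = 100
    n_knots: int = 40
    spline_degree: int = 3
    n_grid: int = 301
    noise_sd: float = 0.0
    split_seed: int = 0
    val_fraction: float = 0.1

    def basis(self) -> BSplineBasis:
        return BSplineBasis(n_knots=self.n_knots, degree=self.spline_degree)

    def validate(self) -> None:
        g0, g1 = self.gamma_range
        if not (0.0 <= g0 < g1 <= contact.GAMMA_MAX):
            raise ValueError("invalid gamma range")
        r0, r1 = self.rho_range
        if not (0.0 <= r0 < r1 <= 1.0):
            raise ValueError("invalid rho range")
        if self.E0_range_pa[0] <= 0 or self.E0_range_pa[1] <= self.E0_range_pa[0]:
            raise ValueError("invalid E0 range")
        if abs(sum(self.profile_fractions) - 1.0) > 1e-9:
            raise ValueError("profile fractions must sum to 1")


@dataclass
class FeatureVector:
    """Raw (unstandardized) regressor inputs for one curve.

    force: mean-normalized force resampled on n uniform time points
    (mean = 1 by construction); i_coeffs / v_coeffs: spline expansion of the
    dimensionless indentation and velocity; rho: bottom-effect strength
    r_max/h. The scales tuple carries what the closed-form modulus recovery
    needs (F_bar, t_tot, I_max, v_bar, theta).
    """

    force: np.ndarray
    i_coeffs: np.ndarray
    v_coeffs: np.ndarray
    rho: float
    F_bar: float
    t_tot: float
    I_max: float
    v_bar: float
    theta: float


@dataclass
class NormalizationStats:
    """Dataset-level standardization statistics.

    The force block is normalized as one group (single mean/std across all
    curves and time channels); spline coefficients are standardized per
    coefficient.
    """

    force_mean: float
    force_std: float
    i_mean: np.ndarray
    i_std: np.ndarray
    v_mean: np.ndarray
    v_std: np.ndarray
    rho_mean: float
    rho_std: float

    @classmethod
    def from_arrays(
        cls, force: np.ndarray, ci: np.ndarray, cv: np.ndarray, rho: np.ndarray
    ) -> "NormalizationStats":
        def _std(x: np.ndarray, axis=None) -> np.ndarray:
            s = x.std(axis=axis)
            return np.where(s > 1e-12, s, 1.0) if np.ndim(s) else (
                s if s > 1e-12 else 1.0
            )

        return cls(
            force_mean=float(force.mean()),
            force_std=float(_std(force)),
            i_mean=ci.mean(axis=0),
            i_std=np.asarray(_std(ci, axis=0)),
            v_mean=cv.mean(axis=0),
            v_std=np.asarray(_std(cv, axis=0)),
            rho_mean=float(rho.mean()),
            rho_std=float(_std(rho)),
        )


@dataclass
class Dataset:
    """Feature arrays, label table and provenance of one synthetic corpus."""

    force: np.ndarray  # (n, n_force_samples) mean-normalized
    i_coeffs: np.ndarray  # (n, n_basis)
    v_coeffs: np.ndarray  # (n, n_basis)
    rho: np.ndarray  # (n,)
    labels: pd.DataFrame
    stats: NormalizationStats
    config: DatasetConfig
    n_rejected: int = 0

    def __len__(self) -> int:
        return len(self.rho)

    def split_indices(self) -> tuple[np.ndarray, np.ndarray]:
        """Deterministic train/validation split by seed-derived shuffle."""
        rng = np.random.default_rng(self.config.split_seed)
        order = rng.permutation(len(self))
        n_val = int(round(self.config.val_fraction * len(self)))
        return np.sort(order[n_val:]), np.sort(order[:n_val])

    # -- persistence --------------------------------------------------
    def save(self, path: str) -> None:
        with h5py.File(path, "w") as f:
            f.attrs["schema_version"] = SCHEMA_VERSION
            f.attrs["kind"] = "nanorheo-dataset"
            f.attrs["config"] = json.dumps(asdict(self.config))
            f.attrs["n_rejected"] = self.n_rejected
            f.create_dataset("force", data=self.force)
            f.create_dataset("i_coeffs", data=self.i_coeffs)
            f.create_dataset("v_coeffs", data=self.v_coeffs)
            f.create_dataset("rho", data=self.rho)
            lab = f.create_group("labels")
            lab.attrs["columns"] = json.dumps(list(self.labels.columns))
            for col in self.labels.columns:
                data = self.labels[col].to_numpy()
                if data.dtype == object:
                    data = data.astype("S")
                lab.create_dataset(col, data=data)
            st = f.create_group("stats")
            for k, v in asdict(self.stats).items():
                st.create_dataset(k, data=v)

    @classmethod
    def load(cls, path: str) -> "Dataset":
        with h5py.File(path, "r") as f:
            major = str(f.attrs["schema_version"]).split(".")[0]
            if major != SCHEMA_VERSION.split(".")[0]:
                raise ValueError(
                    f"unsupported dataset schema {f.attrs['schema_version']}"
                )
            config = DatasetConfig(**_config_kwargs(json.loads(f.attrs["config"])))
            cols = {}
            order = json.loads(f["labels"].attrs["columns"])
            for col in order:
                data = f["labels"][col][()]
                if data.dtype.kind == "S":
                    data = data.astype(str)
                cols[col] = data
            stats = NormalizationStats(
                **{k: f["stats"][k][()] for k in f["stats"]}
            )
            return cls(
                force=f["force"][()],
                i_coeffs=f["i_coeffs"][()],
                v_coeffs=f["v_coeffs"][()],
                rho=f["rho"][()],
                labels=pd.DataFrame(cols),
                stats=stats,
                config=config,
                n_rejected=int(f.attrs["n_rejected"]),
            )


def _config_kwargs(d: dict) -> dict:
    return {
        k: tuple(v) if isinstance(v, list) else v for k, v in d.items()
    }


def sample_parameters(
    n: int, seed: int, config: DatasetConfig | None = None
) -> pd.DataFrame:
    """Draw n label rows: gamma, r_max/h, E0, profile kind and scales.

    gamma and r_max/h are uniform on their ranges, E0 is log-uniform
    (equal relative coverage of the three decades), t_tot log-uniform,
    I_max uniform; the cell thickness follows as h = tan(theta) I_max / rho.
    Deterministic given the seed.
    """
    if n <= 0:
        raise ValueError("n must be positive")
    config = config or DatasetConfig()
    config.validate()
    rng = np.random.default_rng(seed)
    gamma = rng.uniform(*config.gamma_range, size=n)
    rho = rng.uniform(*config.rho_range, size=n)
    E0 = np.exp(
        rng.uniform(
            math.log(config.E0_range_pa[0]),
            math.log(config.E0_range_pa[1]),
            size=n,
        )
    )
    I_max = rng.uniform(*config.I_max_range_m, size=n)
    t_tot = np.exp(
        rng.uniform(
            math.log(config.t_tot_range_s[0]),
            math.log(config.t_tot_range_s[1]),
            size=n,
        )
    )
    kind_idx = rng.choice(3, size=n, p=config.profile_fractions)
    p = rng.uniform(*config.p_range, size=n)
    p[kind_idx == 1] = 0.5
    profile_seed = rng.integers(0, 2**31 - 1, size=n)
    h = np.tan(config.theta_rad) * I_max / rho
    return pd.DataFrame(
        {
            "gamma": gamma,
            "rmax_over_h": rho,
            "E0": E0,
            "I_max": I_max,
            "t_tot": t_tot,
            "h": h,
            "profile_kind": np.array(PROFILE_KINDS)[kind_idx],
            "p": p,
            "profile_seed": profile_seed,
        }
    )


def _build_profile(
    row: pd.Series, config: DatasetConfig, basis: BSplineBasis
) -> IndentationProfile:
    kind = row["profile_kind"]
    if kind == "triangular":
        p = float(row["p"])
        v_app = float(row["I_max"]) / (p * float(row["t_tot"]))
        v_ret = float(row["I_max"]) / ((1.0 - p) * float(row["t_tot"]))
        return make_triangular(float(row["I_max"]), v_app, v_ret, basis)
    if kind == "capped_sinusoid":
        return make_capped_sinusoid(
            float(row["I_max"]), 2.0 * float(row["t_tot"]), basis
        )
    return random_profile(
        int(row["profile_seed"]),
        basis,
        p_range=config.p_range,
        I_max=float(row["I_max"]),
        t_tot=float(row["t_tot"]),
    )


def preprocess_curve(
    curve: ForceCurve,
    profile: IndentationProfile,
    basis: BSplineBasis,
    geometry: ProbeCellGeometry,
    n_force_samples: int = 100,
) -> FeatureVector:
    """Turn one curve into raw regressor inputs.

    The force is linearly resampled on n uniform time points and divided by
    its mean; the dimensionless indentation and velocity are projected onto
    the spline basis. Dataset-level standardization is applied later, by
    the model, from its own stored statistics.
    """
    s_out = np.linspace(0.0, 1.0, n_force_samples)
    f = np.interp(s_out * curve.t_tot, curve.t, curve.F)
    m = f.mean()
    if m <= 0:
        raise ValueError("curve has non-positive mean force")
    sd = np.linspace(0.0, 1.0, max(4 * basis.n_basis, 201))
    ci, _ = fit_bspline(sd, profile.i(sd), basis)
    cv, _ = fit_bspline(sd, profile.di(sd), basis)
    return FeatureVector(
        force=f / m,
        i_coeffs=ci,
        v_coeffs=cv,
        rho=geometry.rmax_over_h(curve.I_max),
        F_bar=curve.F_bar,
        t_tot=curve.t_tot,
        I_max=curve.I_max,
        v_bar=curve.v_bar,
        theta=geometry.theta,
    )


def build_dataset(
    n: int,
    seed: int,
    config: DatasetConfig | None = None,
    progress: bool = False,
) -> Dataset:
    """Generate the full synthetic corpus: a pure function of (n, seed, config).

    Simulation happens in dimensionless form (the dimensionless force f(s)
    depends only on gamma, the profile shape, and r_max/h); the dimensional
    mean force follows exactly from the scale identity, so the label round
    trip through recover_modulus is exact by construction. Degenerate draws
    (non-positive mean force, profile-generation failures) are rejected and
    resampled; their count is reported on the dataset.
    """
    config = config or DatasetConfig()
    config.validate()
    basis = config.basis()
    rng = np.random.default_rng(seed)
    s_out = np.linspace(0.0, 1.0, config.n_force_samples)
    sd = np.linspace(0.0, 1.0, max(4 * basis.n_basis, 201))
    tan_t = math.tan(config.theta_rad)

    force = np.empty((n, config.n_force_samples))
    i_coeffs = np.empty((n, basis.n_basis))
    v_coeffs = np.empty((n, basis.n_basis))
    rho_arr = np.empty(n)
    label_rows = []
    n_rejected = 0
    made = 0
    while made < n:
        batch = sample_parameters(
            max(n - made, 1), int(rng.integers(0, 2**31 - 1)), config
        )
        for _, row in batch.iterrows():
            if made >= n:
                break
            try:
                profile = _build_profile(row, config, basis)
                geometry = ProbeCellGeometry.from_table(
                    config.theta_rad, float(row["h"])
                )
                df = dimensionless_force(
                    profile, float(row["gamma"]), geometry, config.n_grid
                )
            except (ProfileGenerationError, ValueError):
                n_rejected += 1
                continue
            if df.f_bar <= 0:
                n_rejected += 1
                continue
            f100 = np.interp(s_out, df.s, df.f)
            if config.noise_sd > 0:
                f100 = f100 + config.noise_sd * f100.mean() * rng.standard_normal(
                    config.n_force_samples
                )
            m = f100.mean()
            if m <= 0:
                n_rejected += 1
                continue
            force[made] = f100 / m
            ci, _ = fit_bspline(sd, profile.i(sd), basis)
            cv, _ = fit_bspline(sd, profile.di(sd), basis)
            i_coeffs[made] = ci
            v_coeffs[made] = cv
            rho = geometry.rmax_over_h(profile.I_max)
            rho_arr[made] = rho
            # dimensional scale identity: F_bar = E0 tanT Imax^2 (t/t0)^-g w fbar
            scale = (
                float(row["E0"])
                * tan_t
                * profile.I_max**2
                * (profile.t_tot / config.t0_s) ** (-float(row["gamma"]))
                * df.w
            )
            label_rows.append(
                {
                    "E0": float(row["E0"]),
                    "gamma": float(row["gamma"]),
                    "rmax_over_h": rho,
                    "f_bar": df.f_bar,
                    "F_bar": scale * df.f_bar,
                    "t_tot": profile.t_tot,
                    "I_max": profile.I_max,
                    "v_bar": profile.I_max * df.w / profile.t_tot,
                    "theta": config.theta_rad,
                    "h": float(row["h"]),
                    "profile_kind": row["profile_kind"],
                    "profile_seed": int(row["profile_seed"]),
                    "p": profile.p,
                }
            )
            made += 1
            if progress and made % 2000 == 0:
                print(f"  built {made}/{n} curves", flush=True)

    labels = pd.DataFrame(label_rows)
    stats = NormalizationStats.from_arrays(force, i_coeffs, v_coeffs, rho_arr)
    return Dataset(
        force=force,
        i_coeffs=i_coeffs,
        v_coeffs=v_coeffs,
        rho=rho_arr,
        labels=labels,
        stats=stats,
        config=config,
        n_rejected=n_rejected,
    )
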