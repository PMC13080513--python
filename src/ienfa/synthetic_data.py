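"""Seeded generators for biopsy-like images and subject-level cohorts.

Two generators make every downstream stage testable without real data:

``simulate_image``
    A two-channel fluorescence-like image: an undulating epidermis band with
    rete ridges and an excluded stratum corneum, crossed by thin curvilinear
    nerve fibres rising from a dermal plexus, over noisy background — with
    pixel-level ground truth recorded before noise.

``simulate_cohort``
    Subject-level biomarker tables with the group/age/sex structure of a
    small-fibre-neuropathy case–control study.  Control biomarkers are
    normal with explicit age and sex effects; neuropathy biomarkers are
    zero-inflated truncated normals (severely denervated subjects cluster at
    zero).  All metrics of a subject load on one latent innervation variable
    so that cross-metric correlations emerge naturally.

Both generators draw every random quantity from a single seed.
"""

from __future__ import annotations

import functools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from scipy import stats as sps
from scipy.optimize import root
from skimage.morphology import disk

from .image_model import CalibratedImage, PolygonROI, rasterize_roi
from .morphometry import MIN_PARTICLE_AREA_UM2, extract_particles

__all__ = [
    "CalibrationError",
    "TABLE2_TARGETS",
    "STD_AGE_BETA",
    "SEX_MALE_EFFECT",
    "BIOMARKER_COLUMNS",
    "COHORT_COLUMNS",
    "CohortSimParams",
    "simulate_cohort",
    "simulate_rater_readings",
    "ratings_matrix",
    "ImageSimParams",
    "FibreRecord",
    "GroundTruth",
    "simulate_image",
    "true_fibre_count",
]


class CalibrationError(ValueError):
    pass


# Target (control mean, control SD, neuropathy mean, neuropathy SD) for each
# biomarker.  IENFd in fibres/mm; IENFa/A on the x100 scale; IENFa/P in
# µm²/µm.
TABLE2_TARGETS: dict[str, tuple[float, float, float, float]] = {
    "ienfd": (7.83, 2.94, 1.58, 1.98),
    "ienfa_a_aa": (1.02, 0.49, 0.35, 0.39),
    "ienfa_a_cf": (0.91, 0.48, 0.32, 0.32),
    "ienfa_a_ed": (2.11, 1.18, 0.61, 0.62),
    "ienfa_p_aa": (0.32, 0.15, 0.10, 0.11),
    "ienfa_p_cf": (0.29, 0.15, 0.09, 0.09),
    "ienfa_p_ed": (0.67, 0.36, 0.18, 0.20),
}

# Standardized age coefficients in controls: strong for length-based
# metrics, more modest for area-based ones.  Raw slopes are derived from
# these and the control SDs, except IENFd whose raw slope is set directly.
STD_AGE_BETA: dict[str, float] = {
    "ienfd": -0.46,
    "ienfa_a_aa": -0.27,
    "ienfa_a_cf": -0.27,
    "ienfa_a_ed": -0.27,
    "ienfa_p_aa": -0.40,
    "ienfa_p_cf": -0.40,
    "ienfa_p_ed": -0.40,
}

#: Raw age slope of IENFd in controls (fibres/mm per year).
IENFD_AGE_SLOPE = -0.105

# Male-sex coefficients (females higher); only IENFd and the CF area metric
# are sex-dependent.
SEX_MALE_EFFECT: dict[str, float] = {
    "ienfd": -1.45,
    "ienfa_a_cf": -0.24,
}

BIOMARKER_COLUMNS = tuple(TABLE2_TARGETS)
COHORT_COLUMNS = (
    "subject_id",
    "group",
    "age",
    "sex",
    *BIOMARKER_COLUMNS,
    "sural_snap_uv",
    "tibial_cmap_mv",
)


@dataclass
class CohortSimParams:
    """Study conditions of the simulated case–control cohort.

    Group sizes, age distributions (truncated normal) and sex proportions
    follow the reference study; biomarker targets are per-group means/SDs.
    ``latent_rho`` is the loading of every biomarker on the shared latent
    innervation variable; ``zero_inflation`` is the point mass at zero of
    the neuropathy biomarker distributions.
    """

    n_neuropathy: int = 48
    n_control: int = 63
    age_neuropathy: tuple[float, float] = (59.3, 12.5)
    age_control: tuple[float, float] = (56.8, 13.0)
    age_range: tuple[float, float] = (20.0, 85.0)
    male_frac_neuropathy: float = 31 / 48
    male_frac_control: float = 40 / 63
    latent_rho: float = 0.92
    zero_inflation: float = 0.30
    targets: dict[str, tuple[float, float, float, float]] = field(
        default_factory=lambda: dict(TABLE2_TARGETS)
    )
    age_slopes: dict[str, float] | None = None
    sex_effects: dict[str, float] | None = None
    nominal_age_sd: float = 13.0
    snap_rho: float = 0.72
    include_ncs: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_neuropathy < 2 or self.n_control < 2:
            raise CalibrationError("group sizes must be >= 2")
        if not 0.0 <= self.zero_inflation < 1.0:
            raise CalibrationError("zero_inflation must lie in [0, 1)")
        if not 0.0 <= self.latent_rho < 1.0:
            raise CalibrationError("latent_rho must lie in [0, 1)")
        for m, (cm, cs, nm, ns) in self.targets.items():
            if cs < 0 or ns < 0:
                raise CalibrationError(f"negative SD target for {m}")
        if self.age_slopes is None:
            self.age_slopes = {
                m: (
                    IENFD_AGE_SLOPE
                    if m == "ienfd"
                    else STD_AGE_BETA[m] * self.targets[m][1] / self.nominal_age_sd
                )
                for m in self.targets
            }
        if self.sex_effects is None:
            self.sex_effects = {
                m: SEX_MALE_EFFECT.get(m, 0.0) for m in self.targets
            }


@functools.lru_cache(maxsize=256)
def _truncnorm_from_moments(mean: float, sd: float) -> tuple[float, float]:
    """Underlying (loc, scale) of a normal truncated at 0 with given moments.

    Feasible for coefficients of variation below 1 (the truncated normal
    family spans CV 0..1 as loc runs from +inf to -inf).
    """
    if mean <= 0 or sd <= 0:
        raise CalibrationError("truncated-normal moments need mean, sd > 0")
    cv = sd / mean
    if cv >= 0.999:
        raise CalibrationError(
            f"CV {cv:.3f} too large for a zero-truncated normal"
        )

    def residual(v: np.ndarray) -> list[float]:
        mu, logs = v
        s = np.exp(logs)
        a = -mu / s
        return [
            sps.truncnorm.mean(a, np.inf, loc=mu, scale=s) - mean,
            sps.truncnorm.std(a, np.inf, loc=mu, scale=s) - sd,
        ]

    x0 = np.array([mean if cv < 0.7 else 0.05 * sd, np.log(sd)])
    sol = root(residual, x0, method="hybr")
    if not sol.success or max(abs(r) for r in residual(sol.x)) > 1e-8 * max(mean, sd):
        raise CalibrationError(
            f"truncated-normal moment matching failed for mean={mean}, sd={sd}"
        )
    return float(sol.x[0]), float(np.exp(sol.x[1]))


def _zi_truncnorm_values(
    mean: float, sd: float, pi: float, v: np.ndarray
) -> np.ndarray:
    """Zero-inflated truncated normal via inverse-CDF of uniforms ``v``.

    ``v`` uniform on [0, 1]; values below ``pi`` map to the zero mass, the
    rest to a zero-truncated normal whose parameters are moment-matched so
    the mixture has exactly the requested mean and SD.
    """
    if sd == 0:
        return np.full_like(v, mean)
    m1 = mean / (1.0 - pi)
    ex2 = (sd**2 + mean**2) / (1.0 - pi)
    s1_sq = ex2 - m1**2
    if s1_sq <= 0:
        raise CalibrationError(
            f"zero inflation {pi} infeasible for mean={mean}, sd={sd}"
        )
    loc, scale = _truncnorm_from_moments(m1, float(np.sqrt(s1_sq)))
    a = -loc / scale
    out = np.zeros_like(v)
    nz = v >= pi
    out[nz] = sps.truncnorm.ppf(
        (v[nz] - pi) / (1.0 - pi), a, np.inf, loc=loc, scale=scale
    )
    return out


def _draw_ages(
    rng: np.random.Generator, n: int, mean: float, sd: float, lo: float, hi: float
) -> tuple[np.ndarray, float, float]:
    a, b = (lo - mean) / sd, (hi - mean) / sd
    dist = sps.truncnorm(a, b, loc=mean, scale=sd)
    ages = dist.ppf(rng.uniform(size=n))
    return ages, float(dist.mean()), float(dist.std())


def _simulate_group(
    rng: np.random.Generator, params: CohortSimParams, group: str, n: int
) -> pd.DataFrame:
    neuro = group == "neuropathy"
    age_mean, age_sd = params.age_neuropathy if neuro else params.age_control
    male_frac = params.male_frac_neuropathy if neuro else params.male_frac_control
    lo, hi = params.age_range
    ages, mu_age, sd_age = _draw_ages(rng, n, age_mean, age_sd, lo, hi)
    male = rng.uniform(size=n) < male_frac
    latent = rng.standard_normal(n)
    rho = params.latent_rho
    rows: dict[str, np.ndarray] = {}
    for m, (cm, cs, nm, ns) in params.targets.items():
        eps = rng.standard_normal(n)
        z = rho * latent + np.sqrt(1.0 - rho**2) * eps
        if neuro:
            rows[m] = _zi_truncnorm_values(nm, ns, params.zero_inflation, sps.norm.cdf(z))
        else:
            slope = params.age_slopes[m]
            beta_sex = params.sex_effects[m]
            resid_var = (
                cs**2
                - (slope * sd_age) ** 2
                - beta_sex**2 * male_frac * (1.0 - male_frac)
            )
            if resid_var < 0:
                raise CalibrationError(
                    f"effects exceed the target variance of {m} in controls"
                )
            values = (
                cm
                + slope * (ages - mu_age)
                + beta_sex * (male.astype(float) - male_frac)
                + np.sqrt(resid_var) * z
            )
            rows[m] = np.maximum(values, 0.0)
    df = pd.DataFrame(
        {
            "group": group,
            "age": ages,
            "sex": np.where(male, "M", "F"),
            **rows,
        }
    )
    if params.include_ncs:
        # Nerve-conduction amplitudes: noisy increasing transforms of the
        # latent so that moderate (r ~ 0.4-0.6) correlations emerge in the
        # neuropathy group.  Control norms are ordinary healthy values.
        r = params.snap_rho
        for col, (nm, ns), (cm2, cs2) in (
            ("sural_snap_uv", (7.5, 5.5), (18.0, 6.0)),
            ("tibial_cmap_mv", (11.2, 5.3), (16.0, 4.0)),
        ):
            eps = rng.standard_normal(n)
            if neuro:
                z = r * latent + np.sqrt(1.0 - r**2) * eps
                df[col] = np.maximum(nm + ns * z, 0.0)
            else:
                z = 0.3 * latent + np.sqrt(1.0 - 0.3**2) * eps
                df[col] = np.maximum(cm2 + cs2 * z, 0.0)
    else:
        df["sural_snap_uv"] = np.nan
        df["tibial_cmap_mv"] = np.nan
    return df


def simulate_cohort(
    params: CohortSimParams | None = None, seed: int | None = None
) -> pd.DataFrame:
    """Simulate a full case–control cohort as a tidy subject table.

    Returns a DataFrame with one row per subject and the columns of
    :data:`COHORT_COLUMNS`.  Deterministic given the seed (``seed`` argument
    overrides ``params.seed``).
    """
    params = params or CohortSimParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    neuro = _simulate_group(rng, params, "neuropathy", params.n_neuropathy)
    ctrl = _simulate_group(rng, params, "control", params.n_control)
    df = pd.concat([neuro, ctrl], ignore_index=True)
    df.insert(0, "subject_id", [f"S{i + 1:03d}" for i in range(len(df))])
    return df[list(COHORT_COLUMNS)]


def simulate_rater_readings(
    cohort: pd.DataFrame,
    biomarker: str = "ienfa_a_aa",
    n_raters: int = 2,
    bias_sd: float = 0.05,
    noise_sd: float = 0.05,
    n_repeats: int = 1,
    seed: int = 0,
) -> pd.DataFrame:
    """Ratings = true biomarker + per-rater bias + measurement noise.

    ``n_repeats > 1`` yields repeated measurements per rater for intra-rater
    designs.  Tidy output: ``subject_id, rater, repeat, value``.
    """
    if n_raters < 2:
        raise CalibrationError("need at least two raters")
    if bias_sd < 0 or noise_sd < 0:
        raise CalibrationError("rater bias/noise SDs must be non-negative")
    if biomarker not in cohort.columns:
        raise CalibrationError(f"cohort has no column {biomarker!r}")
    rng = np.random.default_rng(seed)
    biases = rng.normal(0.0, bias_sd, size=n_raters) if bias_sd > 0 else np.zeros(n_raters)
    truth = cohort[biomarker].to_numpy()
    records = []
    for r in range(n_raters):
        for k in range(n_repeats):
            noise = (
                rng.normal(0.0, noise_sd, size=len(truth))
                if noise_sd > 0
                else np.zeros(len(truth))
            )
            records.append(
                pd.DataFrame(
                    {
                        "subject_id": cohort["subject_id"].to_numpy(),
                        "rater": r + 1,
                        "repeat": k + 1,
                        "value": truth + biases[r] + noise,
                    }
                )
            )
    return pd.concat(records, ignore_index=True)


def ratings_matrix(ratings: pd.DataFrame, repeat: int = 1) -> np.ndarray:
    """Pivot tidy ratings of one repeat into an (n_subjects, n_raters) array."""
    sub = ratings[ratings["repeat"] == repeat]
    wide = sub.pivot(index="subject_id", columns="rater", values="value")
    if wide.isna().any().any():
        raise CalibrationError("ratings table is incomplete")
    return wide.to_numpy()


# ---------------------------------------------------------------------------
# Image generator


@dataclass
class ImageSimParams:
    """Geometry, optics and fibre statistics of the simulated section.

    Default calibration is 0.5 µm/px: fine enough to resolve 1.5 µm fibres
    and to keep the 0.40 µm² particle filter meaningful (one pixel is
    0.25 µm²).  The epidermis is a band between an upper border (below the
    excluded stratum corneum) and an undulating dermal–epidermal junction
    with rete ridges; fibres random-walk upward from the dermal plexus
    across the junction.
    """

    shape: tuple[int, int] = (300, 600)
    scale_um_per_px: float = 0.5
    epidermis_thickness_um: float = 60.0
    rete_amplitude_um: float = 12.0
    rete_wavelength_um: float = 90.0
    stratum_corneum_um: float = 15.0
    surface_depth_um: float = 25.0
    fibres_per_mm: float = 8.0
    fibre_width_um: float = 1.5
    branching_prob: float = 0.2
    snr: float = 10.0
    background_blob_density: float = 2e-4
    junction_gap_px: int = 5
    plexus: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "scale_um_per_px",
            "epidermis_thickness_um",
            "rete_wavelength_um",
            "stratum_corneum_um",
            "surface_depth_um",
            "fibre_width_um",
            "snr",
        ):
            if getattr(self, name) <= 0:
                raise CalibrationError(f"{name} must be positive")
        if self.fibres_per_mm < 0 or self.rete_amplitude_um < 0:
            raise CalibrationError("rates and amplitudes must be non-negative")


@dataclass(frozen=True)
class FibreRecord:
    """One fibre trajectory: dermal parent, crossing flag, branch flag."""

    parent_id: int
    crossed: bool
    branch_in_epidermis: bool


@dataclass(frozen=True)
class GroundTruth:
    """Pixel-level truth recorded before noise was added.

    ``true_ienfa_um2`` applies the same gating as the quantification
    pipeline (epidermis intersection, periphery exclusion, minimum particle
    area); ``true_ienfa_raw_um2`` is the plain intraepidermal fibre area.
    """

    fibre_mask: np.ndarray
    epidermis_polygon: PolygonROI
    fibre_records: tuple[FibreRecord, ...]
    n_fibres_crossing: int
    true_ienfa_um2: float
    true_ienfa_raw_um2: float
    scale: float


def true_fibre_count(truth: GroundTruth) -> int:
    """Fibres crossing the junction, counting intraepidermal branches once.

    Trajectories sharing a dermal parent (a branch point inside the
    epidermis) count as a single fibre; distinct dermal parents count
    separately.
    """
    return len({r.parent_id for r in truth.fibre_records if r.crossed})


def _walk_fibre(
    rng: np.random.Generator,
    x0: int,
    y0: float,
    top: np.ndarray,
    junction: np.ndarray,
    target_frac: float,
    x_lo: int,
    x_hi: int,
) -> list[tuple[int, int]]:
    """Upward random walk from the dermis into the epidermis band."""
    x, y = int(x0), int(round(y0))
    path = []
    for _ in range(10000):
        path.append((y, x))
        stop_y = junction[x] - target_frac * (junction[x] - top[x])
        if y <= stop_y:
            break
        y -= 1
        x = int(np.clip(x + rng.choice((-1, 0, 1), p=(0.25, 0.5, 0.25)), x_lo, x_hi))
    return path


def simulate_image(
    params: ImageSimParams | None = None, seed: int | None = None
) -> tuple[CalibratedImage, GroundTruth]:
    """Render a two-channel section image and its ground truth.

    The intraepidermal fibre segment is rendered detached from the dermal
    plexus by ``junction_gap_px`` (the faint basement-membrane crossing
    point is typically below resolution), so intraepidermal particles do
    not touch the lower boundary of the epidermis mask.
    """
    params = params or ImageSimParams()
    rng = np.random.default_rng(params.seed if seed is None else seed)
    h, w = params.shape
    s = params.scale_um_per_px
    margin = 4

    x = np.arange(w, dtype=float)
    phase = rng.uniform(0, 2 * np.pi)
    sc_top = params.surface_depth_um / s + 1.5 * np.sin(2 * np.pi * x / (w / 1.5) + phase)
    top = sc_top + params.stratum_corneum_um / s
    ridge = (params.rete_amplitude_um / s) * np.sin(
        2 * np.pi * x * s / params.rete_wavelength_um + rng.uniform(0, 2 * np.pi)
    )
    rough = ndi.gaussian_filter1d(rng.standard_normal(w), 12.0) * 4.0
    junction = top + params.epidermis_thickness_um / s + ridge + rough
    if junction.max() > h - margin - 20 or top.min() < margin + 1:
        raise CalibrationError("epidermis geometry does not fit the image")

    yy = np.arange(h, dtype=float)[:, None]
    epi_band = (yy >= top[None, :]) & (yy < junction[None, :])
    sc_band = (yy >= sc_top[None, :]) & (yy < top[None, :])
    dermis = yy >= junction[None, :]
    epidermis_ch = np.full((h, w), 0.05)
    epidermis_ch[sc_band] = 0.25
    epidermis_ch[epi_band] = 0.75
    epidermis_ch[dermis] = 0.12
    epidermis_ch += rng.normal(0, 0.03, size=(h, w))

    # fibre geometry
    width_px = params.fibre_width_um / s
    if width_px < 1.0:
        warnings.warn(
            f"fibre width {params.fibre_width_um} µm is below one pixel at "
            f"{s} µm/px; clamping to 1 px",
            stacklevel=2,
        )
        width_px = 1.0
    dil_radius = int(round((width_px - 1) / 2))

    dx = np.gradient(junction)
    junction_len_um = float(np.sum(np.sqrt(1.0 + dx[margin : w - margin] ** 2)) * s)
    n_fibres = int(round(params.fibres_per_mm * junction_len_um / 1000.0))

    gap = params.junction_gap_px
    fibre_mask = np.zeros((h, w), dtype=bool)
    records: list[FibreRecord] = []
    x_lo, x_hi = margin + 2, w - margin - 3
    for parent in range(n_fibres):
        x0 = int(rng.integers(x_lo + 3, x_hi - 3))
        walks = [
            (
                _walk_fibre(
                    rng, x0, junction[x0] + 8, top, junction,
                    rng.uniform(0.55, 0.9), x_lo, x_hi,
                ),
                False,
            )
        ]
        # optional single branch inside the epidermis
        branched = False
        if rng.uniform() < params.branching_prob:
            intraepi = [
                (y, cx)
                for y, cx in walks[0][0]
                if top[cx] < y < junction[cx] - gap - 2
            ]
            if intraepi:
                by, bx = intraepi[rng.integers(len(intraepi))]
                walks.append(
                    (
                        _walk_fibre(
                            rng, bx, by, top, junction,
                            rng.uniform(0.7, 0.95), x_lo, x_hi,
                        ),
                        True,
                    )
                )
                branched = True
        for path, is_branch in walks:
            rendered = False
            for y, cx in path:
                if top[cx] <= y <= junction[cx] - gap:
                    fibre_mask[y, cx] = True
                    rendered = True
            records.append(
                FibreRecord(
                    parent_id=parent,
                    crossed=rendered,
                    branch_in_epidermis=is_branch and branched,
                )
            )
    if dil_radius > 0:
        fibre_mask = ndi.binary_dilation(fibre_mask, structure=disk(dil_radius))

    nerve_ch = np.full((h, w), 0.08)
    if params.plexus:
        plexus_mask = np.zeros((h, w), dtype=bool)
        for k in range(2):
            offset = 5 + 5 * k
            py = np.round(
                junction + offset + 2.0 * np.sin(2 * np.pi * x / 150.0 + k)
            ).astype(int)
            ok = (py >= 0) & (py < h)
            plexus_mask[py[ok], np.arange(w)[ok]] = True
        plexus_mask = ndi.binary_dilation(plexus_mask, structure=disk(1))
        nerve_ch[plexus_mask] = 0.55
    nerve_ch[fibre_mask] = 0.85

    n_blobs = rng.poisson(params.background_blob_density * h * w)
    if n_blobs:
        blob_layer = np.zeros((h, w))
        by = rng.integers(0, h, size=n_blobs)
        bx = rng.integers(0, w, size=n_blobs)
        blob_layer[by, bx] = rng.uniform(0.5, 1.2, size=n_blobs)
        nerve_ch += 0.9 * ndi.gaussian_filter(blob_layer, 1.2)

    nerve_ch = ndi.gaussian_filter(nerve_ch, 0.6)  # optical blur
    noise_sd = 0.77 / params.snr  # signal amplitude over background
    nerve_ch = np.clip(nerve_ch + rng.normal(0, noise_sd, size=(h, w)), 0.0, 1.0)
    epidermis_ch = np.clip(epidermis_ch, 0.0, 1.0)

    xs = np.arange(margin, w - margin + 1, 4)
    if xs[-1] != w - margin:
        xs = np.append(xs, w - margin)
    verts = [(float(cx), float(top[cx])) for cx in xs]
    verts += [(float(cx), float(junction[cx])) for cx in xs[::-1]]
    polygon = PolygonROI(np.asarray(verts))
    epi_roi = rasterize_roi(polygon, (h, w), s)

    raw_area = float((fibre_mask & epi_roi.mask).sum()) * s**2
    gated = extract_particles(
        fibre_mask, epi_roi, s, min_area_um2=MIN_PARTICLE_AREA_UM2
    ).ienfa_um2
    truth = GroundTruth(
        fibre_mask=fibre_mask,
        epidermis_polygon=polygon,
        fibre_records=tuple(records),
        n_fibres_crossing=len({r.parent_id for r in records if r.crossed}),
        true_ienfa_um2=gated,
        true_ienfa_raw_um2=raw_area,
        scale=s,
    )
    image = CalibratedImage(nerve=nerve_ch, epidermis=epidermis_ch, scale=s)
    return image, truth
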