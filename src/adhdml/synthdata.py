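"""Synthetic multi-site cohort generator.

Generates phenotype tables, band-limited ROI time series, small 4D voxel
blocks and morphometric feature tables with the statistical structure the
downstream classification pipeline assumes: site-specific diagnosis and
subtype mixes, a gender gap in ADHD prevalence, site-varying age and IQ
distributions with lower IQ in ADHD, class-dependent covariance on a
planted set of connectivity edges, and a class effect on the regional
homogeneity of a planted voxel block.

The default multi-site template (:func:`adhd200_template`) reproduces the
published ADHD-200 training-set composition by site, diagnosis and gender,
so prevalence statistics computed from a generated cohort match the
published training-set demographics exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ConfigError",
    "SiteSpec",
    "CohortConfig",
    "adhd200_template",
    "generate_phenotypes",
    "generate_timeseries",
    "generate_morphometry",
    "generate_voxels",
    "generate_cohort",
    "cortical_feature_names",
    "noncortical_feature_names",
    "morphometry_feature_names",
    "DX_LEVELS",
    "ADHD_SUBTYPES",
]


class ConfigError(ValueError):
    """Raised for invalid cohort configurations."""


DX_LEVELS = ("TD", "ADHD-C", "ADHD-H", "ADHD-I")
ADHD_SUBTYPES = ("ADHD-C", "ADHD-H", "ADHD-I")

# Desikan-Killiany cortical parcellation (34 regions per hemisphere) and the
# nine per-region surface measures reported by standard surface reconstruction.
CORTICAL_REGIONS = (
    "bankssts", "caudalanteriorcingulate", "caudalmiddlefrontal", "cuneus",
    "entorhinal", "fusiform", "inferiorparietal", "inferiortemporal",
    "isthmuscingulate", "lateraloccipital", "lateralorbitofrontal", "lingual",
    "medialorbitofrontal", "middletemporal", "parahippocampal", "paracentral",
    "parsopercularis", "parsorbitalis", "parstriangularis", "pericalcarine",
    "postcentral", "posteriorcingulate", "precentral", "precuneus",
    "rostralanteriorcingulate", "rostralmiddlefrontal", "superiorfrontal",
    "superiorparietal", "superiortemporal", "supramarginal", "temporalpole",
    "transversetemporal", "frontalpole", "insula",
)
CORTICAL_MEASURES = (
    "NumVert", "SurfArea", "GrayVol", "ThickAvg", "ThickStd",
    "MeanCurv", "GausCurv", "FoldInd", "CurvInd",
)
# 45 non-cortical segmentation entities (subcortical gray, white matter,
# ventricles, hypointensities, corpus callosum) with three volume/intensity
# measures each.
NONCORTICAL_REGIONS = (
    "Left-Lateral-Ventricle", "Left-Inf-Lat-Vent",
    "Left-Cerebellum-White-Matter", "Left-Cerebellum-Cortex",
    "Left-Thalamus-Proper", "Left-Caudate", "Left-Putamen", "Left-Pallidum",
    "3rd-Ventricle", "4th-Ventricle", "Brain-Stem", "Left-Hippocampus",
    "Left-Amygdala", "CSF", "Left-Accumbens-area", "Left-VentralDC",
    "Left-vessel", "Left-choroid-plexus", "Right-Lateral-Ventricle",
    "Right-Inf-Lat-Vent", "Right-Cerebellum-White-Matter",
    "Right-Cerebellum-Cortex", "Right-Thalamus-Proper", "Right-Caudate",
    "Right-Putamen", "Right-Pallidum", "Right-Hippocampus", "Right-Amygdala",
    "Right-Accumbens-area", "Right-VentralDC", "Right-vessel",
    "Right-choroid-plexus", "5th-Ventricle", "WM-hypointensities",
    "Left-WM-hypointensities", "Right-WM-hypointensities",
    "non-WM-hypointensities", "Left-non-WM-hypointensities",
    "Right-non-WM-hypointensities", "Optic-Chiasm", "CC_Posterior",
    "CC_Mid_Posterior", "CC_Central", "CC_Mid_Anterior", "CC_Anterior",
)
NONCORTICAL_MEASURES = ("Volume_mm3", "normMean", "normStdDev")


def cortical_feature_names() -> list[str]:
    """9 measures x 34 regions x 2 hemispheres = 612 cortical feature names."""
    return [
        f"{hemi}_{region}_{measure}"
        for hemi in ("lh", "rh")
        for region in CORTICAL_REGIONS
        for measure in CORTICAL_MEASURES
    ]


def noncortical_feature_names() -> list[str]:
    """3 measures x 45 segmentation entities = 135 non-cortical names."""
    return [
        f"{region}_{measure}"
        for region in NONCORTICAL_REGIONS
        for measure in NONCORTICAL_MEASURES
    ]


def morphometry_feature_names() -> list[str]:
    """All 747 morphometric feature names, cortical first."""
    return cortical_feature_names() + noncortical_feature_names()


@dataclass(frozen=True)
class SiteSpec:
    """Per-site subject counts: typically developing and ADHD subtypes."""

    name: str
    n_td: int
    n_adhd_c: int = 0
    n_adhd_h: int = 0
    n_adhd_i: int = 0

    def counts(self) -> dict[str, int]:
        return {
            "TD": self.n_td,
            "ADHD-C": self.n_adhd_c,
            "ADHD-H": self.n_adhd_h,
            "ADHD-I": self.n_adhd_i,
        }


@dataclass
class CohortConfig:
    """Generative parameters for a multi-site synthetic cohort.

    Parameters
    ----------
    sites:
        Subject counts per site and diagnosis.
    age_range_by_site:
        Uniform age range (years) per site; ``default_age_range`` is used for
        sites not listed.
    iq_mean_by_site:
        Mean full-scale IQ of TD subjects per site (sd fixed at 15 points).
    iq_adhd_shift:
        Additive IQ shift (points) applied to ADHD subjects; the default of
        -9 points reflects the reported population-level deficit.
    iq_missing_sites:
        Sites whose IQ column is generated entirely missing (whole-site
        missingness only).
    female_fraction_by_class:
        Fraction of female subjects per 2-class group, emulating the lower
        ADHD prevalence among girls; ``female_counts`` overrides it with
        exact per-(site, dx) female counts.
    T, TR, R:
        Time points, repetition time (seconds) and ROI count of the
        generated ROI time series.
    band:
        Retained frequency band in Hz, matching the standard resting-state
        band-pass of 0.009-0.08 Hz.
    planted_edges:
        ``(i, j, d)`` triples: ROI pairs whose population Fisher-z
        correlation differs by ``d`` (z units) between ADHD and TD.
    planted_base_z:
        Fisher-z correlation of planted edges in the TD population.
    voxel_grid, voxel_block:
        Shape of the 4D voxel data and the planted block (three ``(lo, hi)``
        index ranges) carrying the class effect on regional homogeneity.
    voxel_shared_base, voxel_shared_effect:
        Shared-signal variance fraction inside the planted block for TD
        subjects and its increase in ADHD (raising Kendall's W).
    morph_effect:
        ``(column, d)`` pairs: morphometric columns with a standardized
        class difference of ``d``.
    seed:
        Master seed; identical config + seed gives bit-identical output.
    """

    sites: list[SiteSpec]
    age_range_by_site: dict[str, tuple[float, float]] = field(default_factory=dict)
    default_age_range: tuple[float, float] = (8.0, 17.0)
    iq_mean_by_site: dict[str, float] = field(default_factory=dict)
    default_iq_mean: float = 110.0
    iq_sd: float = 15.0
    iq_adhd_shift: float = -9.0
    iq_missing_sites: tuple[str, ...] = ()
    female_fraction_by_class: dict[str, float] = field(
        default_factory=lambda: {"TD": 0.45, "ADHD": 0.20}
    )
    female_counts: dict[tuple[str, str], int] | None = None
    T: int = 176
    TR: float = 2.0
    R: int = 10
    band: tuple[float, float] = (0.009, 0.08)
    planted_edges: list[tuple[int, int, float]] = field(default_factory=list)
    planted_base_z: float = 0.2
    voxel_grid: tuple[int, int, int] = (5, 5, 5)
    voxel_block: tuple[tuple[int, int], tuple[int, int], tuple[int, int]] = (
        (1, 4), (1, 4), (1, 4),
    )
    voxel_shared_base: float = 0.2
    voxel_shared_effect: float = 0.0
    morph_effect: list[tuple[str, float]] = field(default_factory=list)
    seed: int = 0

    def validate(self) -> None:
        if not self.sites:
            raise ConfigError("at least one site is required")
        for s in self.sites:
            for dx, n in s.counts().items():
                if n < 0:
                    raise ConfigError(f"negative count for {s.name}/{dx}")
        if self.T < 8:
            raise ConfigError("T must be >= 8")
        if self.R < 2:
            raise ConfigError("R must be >= 2")
        if self.TR <= 0:
            raise ConfigError("TR must be positive")
        lo, hi = self.band
        if not (0 <= lo < hi <= 0.5 / self.TR + 1e-12):
            raise ConfigError("band must satisfy 0 <= low < high <= Nyquist")
        for i, j, d in self.planted_edges:
            if not np.isfinite(d):
                raise ConfigError("planted edge effect size must be finite")
            if not (0 <= i < self.R and 0 <= j < self.R and i != j):
                raise ConfigError(f"invalid planted edge ({i}, {j})")
        for col, d in self.morph_effect:
            if not np.isfinite(d):
                raise ConfigError(f"non-finite morphometric effect on {col}")
        if not (0 <= self.voxel_shared_base <= 1):
            raise ConfigError("voxel_shared_base must be in [0, 1]")
        if not (0 <= self.voxel_shared_base + self.voxel_shared_effect <= 1):
            raise ConfigError("voxel shared fraction must stay in [0, 1]")


# Published ADHD-200 training-set composition: subject counts by site and
# diagnosis, and female counts by site and diagnosis for the five sites with
# ADHD subjects (the TD-only sites' gender split is not published; an even
# split is used there).
_ADHD200_COUNTS: list[tuple[str, int, int, int, int]] = [
    # (site, TD, ADHD-C, ADHD-H, ADHD-I)
    ("Peking", 116, 29, 0, 49),
    ("KKI", 61, 16, 1, 5),
    ("NI", 23, 18, 6, 1),
    ("NYU", 99, 77, 2, 44),
    ("OHSU", 42, 23, 2, 12),
    ("Pitt", 89, 0, 0, 0),
    ("WashU", 61, 0, 0, 0),
]
_ADHD200_FEMALE: dict[tuple[str, str], int] = {
    ("Peking", "TD"): 45, ("Peking", "ADHD-C"): 0, ("Peking", "ADHD-I"): 7,
    ("KKI", "TD"): 27, ("KKI", "ADHD-C"): 9, ("KKI", "ADHD-I"): 1,
    ("NI", "TD"): 12, ("NI", "ADHD-C"): 4, ("NI", "ADHD-I"): 0,
    ("NYU", "TD"): 52, ("NYU", "ADHD-C"): 12, ("NYU", "ADHD-I"): 15,
    ("OHSU", "TD"): 24, ("OHSU", "ADHD-C"): 4, ("OHSU", "ADHD-I"): 6,
    ("Pitt", "TD"): 44, ("WashU", "TD"): 30,
}


def adhd200_template(seed: int = 0, **overrides) -> CohortConfig:
    """Cohort config reproducing the ADHD-200 training-set composition.

    Exact subject counts by site, diagnosis (four levels) and gender; the NI
    site is generated with missing IQ; keyword overrides adjust any other
    generative parameter.
    """
    sites = [SiteSpec(name, td, c, h, i) for name, td, c, h, i in _ADHD200_COUNTS]
    cfg = CohortConfig(
        sites=sites,
        age_range_by_site={
            "Peking": (8.0, 17.0), "KKI": (8.0, 13.0), "NI": (11.0, 22.0),
            "NYU": (7.0, 18.0), "OHSU": (7.0, 12.0), "Pitt": (10.0, 20.0),
            "WashU": (7.0, 22.0),
        },
        iq_mean_by_site={
            "Peking": 115.0, "KKI": 110.0, "NYU": 110.0, "OHSU": 115.0,
            "Pitt": 110.0, "WashU": 115.0,
        },
        iq_missing_sites=("NI",),
        female_counts=dict(_ADHD200_FEMALE),
        seed=seed,
    )
    for key, value in overrides.items():
        if not hasattr(cfg, key):
            raise ConfigError(f"unknown config field {key!r}")
        setattr(cfg, key, value)
    cfg.validate()
    return cfg


def _stream_rng(seed: int, *path: int) -> np.random.Generator:
    return np.random.default_rng([seed, *path])


def generate_phenotypes(config: CohortConfig) -> pd.DataFrame:
    """Generate the phenotype table for a configured cohort.

    Returns a DataFrame with columns ``subject_id, site, dx, age, gender,
    iq, handedness``; class/site/gender counts match the config exactly, IQ
    is shifted by ``iq_adhd_shift`` in ADHD and entirely missing at the
    configured sites.
    """
    config.validate()
    rng = _stream_rng(config.seed, 1)
    rows = []
    sub = 0
    for site in config.sites:
        lo_age, hi_age = config.age_range_by_site.get(
            site.name, config.default_age_range
        )
        iq_mean = config.iq_mean_by_site.get(site.name, config.default_iq_mean)
        for dx, n in site.counts().items():
            n_female = _n_female(config, site.name, dx, n)
            for k in range(n):
                sub += 1
                age = rng.uniform(lo_age, hi_age)
                iq = rng.normal(iq_mean, config.iq_sd)
                if dx != "TD":
                    iq += config.iq_adhd_shift
                if site.name in config.iq_missing_sites:
                    iq = np.nan
                rows.append(
                    {
                        "subject_id": f"sub-{sub:04d}",
                        "site": site.name,
                        "dx": dx,
                        "age": round(age, 2),
                        "gender": "F" if k < n_female else "M",
                        "iq": np.nan if np.isnan(iq) else round(iq, 1),
                        "handedness": "R" if rng.uniform() < 0.9 else "L",
                    }
                )
    return pd.DataFrame(rows)


def _n_female(config: CohortConfig, site: str, dx: str, n: int) -> int:
    if config.female_counts is not None:
        return min(n, config.female_counts.get((site, dx), 0))
    group = "TD" if dx == "TD" else "ADHD"
    frac = config.female_fraction_by_class.get(group, 0.5)
    return int(round(n * frac))


# ---------------------------------------------------------------------------
# Band-limited time series


def _band_mask(T: int, TR: float, band: tuple[float, float]) -> np.ndarray:
    freqs = np.fft.rfftfreq(T, d=TR)
    lo, hi = band
    return (freqs >= lo) & (freqs <= hi)


def _bandlimited_noise(
    T: int, n_series: int, TR: float, band: tuple[float, float],
    rng: np.random.Generator,
) -> np.ndarray:
    """T x n matrix of independent, unit-variance, band-limited Gaussians.

    White Gaussian noise is masked in the frequency domain (spectral mass
    outside the band removed exactly) and rescaled by the analytic variance
    factor so each column has unit population variance.
    """
    mask = _band_mask(T, TR, band)
    if not mask.any():
        raise ConfigError("frequency band contains no DFT bins for this T, TR")
    white = rng.standard_normal((T, n_series))
    spec = np.fft.rfft(white, axis=0)
    spec[~mask, :] = 0.0
    # two-sided count of retained bins: interior rfft bins represent two
    # conjugate DFT bins each, DC and (even-T) Nyquist represent one
    weights = np.full(mask.size, 2.0)
    weights[0] = 1.0
    if T % 2 == 0:
        weights[-1] = 1.0
    m = float(weights[mask].sum())
    x = np.fft.irfft(spec, n=T, axis=0)
    return x * np.sqrt(T / m)


def generate_timeseries(
    cov: np.ndarray,
    T: int,
    TR: float = 2.0,
    band: tuple[float, float] = (0.009, 0.08),
    seed: int | np.random.Generator = 0,
) -> np.ndarray:
    """Sample a T x R band-limited Gaussian series with target covariance.

    The population covariance of the returned series equals ``cov``; the
    sample covariance converges to it as T grows. Spectral mass outside
    ``band`` is removed exactly (frequency-domain masking before covariance
    coloring).

    Raises
    ------
    ConfigError
        If ``cov`` is not symmetric positive-definite or the band is invalid.
    """
    cov = np.asarray(cov, dtype=float)
    if cov.ndim != 2 or cov.shape[0] != cov.shape[1]:
        raise ConfigError("cov must be square")
    if not np.allclose(cov, cov.T, atol=1e-10):
        raise ConfigError("cov must be symmetric")
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ConfigError("cov must be positive-definite") from exc
    if T < 8:
        raise ConfigError("T must be >= 8")
    lo, hi = band
    if not (0 <= lo < hi <= 0.5 / TR + 1e-12):
        raise ConfigError("band must satisfy 0 <= low < high <= Nyquist")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    noise = _bandlimited_noise(T, cov.shape[0], TR, band, rng)
    return noise @ L.T


def class_covariance(config: CohortConfig, dx: str) -> np.ndarray:
    """Population ROI covariance for a diagnostic class.

    Identity, except that planted edges carry correlation
    ``tanh(planted_base_z)`` in TD and ``tanh(planted_base_z + d)`` in ADHD.
    """
    cov = np.eye(config.R)
    for i, j, d in config.planted_edges:
        z = config.planted_base_z + (d if dx != "TD" else 0.0)
        r = np.tanh(z)
        cov[i, j] = cov[j, i] = r
    try:
        np.linalg.cholesky(cov)
    except np.linalg.LinAlgError as exc:
        raise ConfigError("planted edges yield a non-PD covariance") from exc
    return cov


# ---------------------------------------------------------------------------
# Morphometry


def generate_morphometry(
    config: CohortConfig, phenotypes: pd.DataFrame | None = None
) -> pd.DataFrame:
    """Generate the 747-column morphometric table for a cohort.

    Columns are standardized surrogate features (population sd 1); columns
    listed in ``config.morph_effect`` carry an additive class difference of
    ``d`` standard deviations (ADHD minus TD). Indexed by subject_id.
    """
    config.validate()
    if phenotypes is None:
        phenotypes = generate_phenotypes(config)
    names = morphometry_feature_names()
    name_to_col = {n: k for k, n in enumerate(names)}
    for col, _ in config.morph_effect:
        if col not in name_to_col:
            raise ConfigError(f"unknown morphometric column {col!r}")
    rng = _stream_rng(config.seed, 2)
    X = rng.standard_normal((len(phenotypes), len(names)))
    is_adhd = (phenotypes["dx"] != "TD").to_numpy()
    for col, d in config.morph_effect:
        X[is_adhd, name_to_col[col]] += d
    return pd.DataFrame(X, index=phenotypes["subject_id"].to_numpy(), columns=names)


# ---------------------------------------------------------------------------
# Voxel blocks


def generate_voxels(
    config: CohortConfig, phenotypes: pd.DataFrame | None = None
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    """Generate per-subject 4D voxel time series and a binary mask.

    Voxels carry independent band-limited noise except inside the planted
    block, where a fraction of the variance (``voxel_shared_base``, plus
    ``voxel_shared_effect`` in ADHD) comes from a signal shared across the
    block — raising within-neighborhood concordance (Kendall's W) for ADHD.

    Returns
    -------
    data, mask:
        ``data[subject_id]`` is an ``(nx, ny, nz, T)`` array; ``mask`` is the
        all-ones ``(nx, ny, nz)`` analysis mask.
    """
    config.validate()
    if phenotypes is None:
        phenotypes = generate_phenotypes(config)
    nx, ny, nz = config.voxel_grid
    (x0, x1), (y0, y1), (z0, z1) = config.voxel_block
    if not (0 <= x0 < x1 <= nx and 0 <= y0 < y1 <= ny and 0 <= z0 < z1 <= nz):
        raise ConfigError("voxel_block must lie inside voxel_grid")
    n_vox = nx * ny * nz
    mask = np.ones((nx, ny, nz), dtype=np.uint8)
    block = np.zeros((nx, ny, nz), dtype=bool)
    block[x0:x1, y0:y1, z0:z1] = True
    block_flat = block.reshape(-1)

    data: dict[str, np.ndarray] = {}
    for k, row in enumerate(phenotypes.itertuples(index=False)):
        rng = _stream_rng(config.seed, 3, k)
        noise = _bandlimited_noise(config.T, n_vox, config.TR, config.band, rng)
        shared = _bandlimited_noise(config.T, 1, config.TR, config.band, rng)[:, 0]
        a = config.voxel_shared_base
        if row.dx != "TD":
            a += config.voxel_shared_effect
        vox = noise
        vox[:, block_flat] = (
            np.sqrt(1 - a) * vox[:, block_flat]
            + np.sqrt(a) * shared[:, None]
        )
        data[row.subject_id] = np.moveaxis(
            vox.reshape(config.T, nx, ny, nz), 0, -1
        )
    return data, mask


# ---------------------------------------------------------------------------
# Full cohort


def generate_cohort(
    config: CohortConfig, with_voxels: bool = True
) -> tuple[pd.DataFrame, dict[str, pd.DataFrame], dict[str, np.ndarray] | None, pd.DataFrame]:
    """Generate a full synthetic cohort.

    Returns ``(phenotypes, roi_timeseries, voxel_data, morphometry)`` where
    ``roi_timeseries[subject_id]`` is a T x R DataFrame with ROI-name
    columns. Deterministic given ``config.seed``; voxel generation can be
    switched off for speed when only ROI-level features are needed.
    """
    config.validate()
    pheno = generate_phenotypes(config)
    roi_names = [f"roi{r:03d}" for r in range(config.R)]
    cov_by_dx = {dx: class_covariance(config, dx) for dx in DX_LEVELS}
    series: dict[str, pd.DataFrame] = {}
    for k, row in enumerate(pheno.itertuples(index=False)):
        rng = _stream_rng(config.seed, 4, k)
        ts = generate_timeseries(
            cov_by_dx[row.dx], config.T, config.TR, config.band, seed=rng
        )
        series[row.subject_id] = pd.DataFrame(ts, columns=roi_names)
    voxels = generate_voxels(config, pheno)[0] if with_voxels else None
    morph = generate_morphometry(config, pheno)
    return pheno, series, voxels, morph
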