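"""Body-size spectrum analysis for terrestrial mammal assemblages.

The package estimates the shape of species body-mass distributions at
local (species list of one locality) and continental (whole fauna) scales
and compares them.  For each assemblage it computes:

* the diversity/size slope -- an OLS log-log regression of species density
  (species count per gram of mass-class width) on mass-class midpoint,
  with log2 size classes built under three boundary-rounding conventions
  and averaged, so that the classic log-binning biases (growing bin width,
  arbitrary bin phase) do not distort the exponent;
* g1 sample skewness on raw masses and on log2-transformed masses;
* the half-sample mode (robust modal body size) on both scales;
* median mass, richness and the percentage of species lighter than 100 g.

A comparative layer tests slopes against the fractal-niche prediction of
-2/3, contrasts continents (Kruskal-Wallis + pairwise Mood median tests
with compact-letter display), computes richness-controlled slope
residuals, and rank (Spearman) semi-partial correlations of each shape
parameter on median size, richness and continent.

Because the empirical locality lists are not redistributable, the module
also ships a seeded synthetic-assemblage generator: right-skewed
continental mass pools with per-species occupancy increasing with body
mass (larger species range more widely), which reproduces the qualitative
local-versus-continental contrasts of real mammal faunas, and truncated
power-law ("fractal") pools for estimator-recovery experiments.

The file is organised in pipeline order:

1. configuration, logging, errors
2. synthetic assemblage generation
3. per-assemblage spectrum estimators
4. comparative statistics
5. readers/writers and the end-to-end pipeline
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import yaml
from scipy import stats
from scipy.special import expit

__all__ = [
    # configuration / errors
    "FRACTAL_SLOPE_MASS", "configure_logging",
    "SizeSpectraError", "ConfigurationError", "DegenerateConfigurationError",
    "DegenerateOccupancyError", "InsufficientBinsError",
    "UndefinedSkewnessError", "CollinearityError", "InputError",
    # synthetic data
    "PoolConfig", "SpeciesPool", "AssemblageTable",
    "generate_continent_pool", "generate_fractal_pool",
    "sample_localities", "simulate_study",
    "default_study_config", "turnover_protocol_config",
    # estimators
    "MassSample", "BinnedSpectrum", "SchemeFit", "SlopeEstimate",
    "ShapeSummary", "SCHEMES", "log2_class_assign", "bin_spectrum",
    "fit_loglog_slope", "estimate_slope", "g1_skewness", "half_sample_mode",
    "shape_summary", "summarize_assemblages",
    "fractal_expected_increase", "mass_slope_to_length_slope",
    # comparative statistics
    "TestResult", "PosthocLetters", "SemiPartialResult",
    "one_sample_t", "kruskal_wallis", "median_posthoc",
    "spearman_semipartial", "richness_residual_slopes", "scale_contrast",
    "compare_report", "SHAPE_PARAMETERS",
    # io / pipeline
    "StudyConfig", "read_assemblages", "write_assemblages", "run_pipeline",
]

__version__ = "0.1.0"

# ---------------------------------------------------------------------------
# 1. configuration, logging, errors
# ---------------------------------------------------------------------------

#: Fractal-niche prediction for the diversity/size slope on body mass
#: (equivalently -2 on body length under isometry).
FRACTAL_SLOPE_MASS = -2.0 / 3.0

#: The three log2 class-boundary rounding conventions that are averaged.
SCHEMES = ("lower", "upper", "half")

#: Shape parameters reported per assemblage and contrasted across scales.
SHAPE_PARAMETERS = (
    "slope", "skew_linear", "skew_log2",
    "mode_linear_g", "mode_log2_g", "median_g", "pct_under_100g",
)

SUMMARY_COLUMNS = (
    "label", "continent", "scale", "richness", "slope",
    "skew_linear", "skew_log2", "mode_linear_g", "mode_log2_g",
    "median_g", "pct_under_100g",
)

logger = logging.getLogger("sizespectra")


def configure_logging(level: str | int = "INFO",
                      logfile: str | Path | None = None) -> None:
    """Attach console (and optionally file) handlers to the package logger."""
    logger.setLevel(level if isinstance(level, int) else level.upper())
    logger.handlers.clear()
    fmt = logging.Formatter("%(asctime)s %(levelname)s %(name)s: %(message)s")
    handler = logging.StreamHandler()
    handler.setFormatter(fmt)
    logger.addHandler(handler)
    if logfile is not None:
        fh = logging.FileHandler(logfile, mode="w", encoding="utf-8")
        fh.setFormatter(fmt)
        logger.addHandler(fh)


class SizeSpectraError(Exception):
    """Base class of all package errors."""


class ConfigurationError(SizeSpectraError):
    """A configuration value violates its declared constraints."""


class DegenerateConfigurationError(ConfigurationError):
    """A configuration is formally valid but numerically unusable."""


class DegenerateOccupancyError(SizeSpectraError):
    """Occupancy probabilities too low to populate a locality."""


class InsufficientBinsError(SizeSpectraError):
    """Fewer occupied size classes than the regression minimum."""

    def __init__(self, scheme: str, n_bins: int, minimum: int = 3):
        self.scheme = scheme
        self.n_bins = n_bins
        self.minimum = minimum
        super().__init__(
            f"scheme '{scheme}': {n_bins} occupied size class(es), "
            f"need at least {minimum} for a log-log regression"
        )


class UndefinedSkewnessError(SizeSpectraError):
    """g1 undefined: fewer than three values or zero variance."""


class CollinearityError(SizeSpectraError):
    """Rank-deficient predictor set in the semi-partial correlation."""


class InputError(SizeSpectraError):
    """Malformed input file or table."""


def _seedseq(seed) -> np.random.SeedSequence:
    if isinstance(seed, np.random.SeedSequence):
        return seed
    return np.random.SeedSequence(seed)


# ---------------------------------------------------------------------------
# 2. synthetic assemblage generation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PoolConfig:
    """Generative settings of one synthetic continental species pool.

    Log2 body masses are drawn from a skew-normal distribution (location,
    scale and shape on the log2-gram scale; shape 0 reduces to a normal),
    truncated to ``[mass_floor_g, mass_ceiling_g]`` by resampling.  Each
    species' probability of occurring at any one locality is
    ``logistic(occupancy_intercept + occupancy_mass_coef * log2(mass))``;
    a positive coefficient encodes the macroecological premise that larger
    species occupy more localities, which is the turnover mechanism that
    separates continental from local distribution shape.
    """

    continent_label: str
    n_species: int = 2000
    log2_mass_location: float = 5.0
    log2_mass_scale: float = 4.0
    log2_mass_skew: float = 3.0
    mass_floor_g: float = 1.5
    mass_ceiling_g: float = 1.0e7
    occupancy_intercept: float = -10.6
    occupancy_mass_coef: float = 1.0
    n_localities: int = 30

    def validate(self) -> None:
        if not self.continent_label:
            raise ConfigurationError("continent_label must be non-empty")
        if self.n_species < 10:
            raise ConfigurationError(
                f"n_species must be >= 10, got {self.n_species}")
        if not self.log2_mass_scale > 0:
            raise ConfigurationError(
                f"log2_mass_scale must be positive, got {self.log2_mass_scale}")
        if not (0 < self.mass_floor_g < self.mass_ceiling_g):
            raise ConfigurationError(
                "need 0 < mass_floor_g < mass_ceiling_g, got "
                f"{self.mass_floor_g} / {self.mass_ceiling_g}")
        if self.n_localities < 1:
            raise ConfigurationError(
                f"n_localities must be >= 1, got {self.n_localities}")

    _FIELDS = ("continent_label", "n_species", "log2_mass_location",
               "log2_mass_scale", "log2_mass_skew", "mass_floor_g",
               "mass_ceiling_g", "occupancy_intercept",
               "occupancy_mass_coef", "n_localities")

    @classmethod
    def from_dict(cls, d: Mapping) -> "PoolConfig":
        unknown = set(d) - set(cls._FIELDS)
        if unknown:
            raise ConfigurationError(
                f"unknown pool config key(s): {sorted(unknown)}")
        cfg = cls(**d)
        cfg.validate()
        return cfg


@dataclass
class SpeciesPool:
    """A synthetic continental fauna: masses plus occupancy probabilities."""

    species_ids: list[str]
    masses_g: np.ndarray
    occupancy_p: np.ndarray
    continent_label: str
    config: PoolConfig | None = None

    def validate(self) -> None:
        n = len(self.species_ids)
        if not (len(self.masses_g) == len(self.occupancy_p) == n):
            raise ConfigurationError("pool field lengths differ")
        if np.any(~(self.masses_g > 0)):
            raise ConfigurationError("pool masses must be positive")
        if np.any(self.occupancy_p <= 0) or np.any(self.occupancy_p >= 1):
            raise ConfigurationError("occupancy_p must lie in (0, 1)")
        if self.config is not None and self.config.occupancy_mass_coef > 0:
            order = np.argsort(self.masses_g)
            if np.any(np.diff(self.occupancy_p[order]) < -1e-12):
                raise ConfigurationError(
                    "occupancy_p not non-decreasing in mass")

    def mass_sample(self) -> "MassSample":
        return MassSample(masses_g=np.asarray(self.masses_g, float),
                          label=self.continent_label,
                          scale_tag="continental",
                          continent=self.continent_label)


@dataclass
class AssemblageTable:
    """Long-format locality x species presences plus a species-mass lookup.

    ``table`` has columns ``locality_id, continent, species_id``; ``masses``
    maps species_id to body mass in grams.
    """

    table: pd.DataFrame
    masses: pd.Series

    def validate(self) -> None:
        required = {"locality_id", "continent", "species_id"}
        missing = required - set(self.table.columns)
        if missing:
            raise InputError(f"assemblage table missing column(s) {sorted(missing)}")
        if self.table.empty:
            raise InputError("assemblage table is empty")
        dup = self.table.duplicated(["locality_id", "species_id"])
        if dup.any():
            raise InputError(
                f"{int(dup.sum())} duplicate (locality_id, species_id) pair(s)")
        unknown = set(self.table["species_id"]) - set(self.masses.index)
        if unknown:
            raise InputError(
                f"{len(unknown)} species without a mass entry, e.g. "
                f"{sorted(unknown)[:3]}")
        if self.masses.index.has_duplicates:
            raise InputError("duplicate species_id in the mass lookup")
        if np.any(~(self.masses.to_numpy(float) > 0)):
            raise InputError("all masses must be positive")

    def locality_ids(self) -> list[str]:
        key = self.table[["continent", "locality_id"]].drop_duplicates()
        key = key.sort_values(["continent", "locality_id"])
        return list(key["locality_id"])

    def continent_of(self, locality_id: str) -> str:
        rows = self.table.loc[self.table["locality_id"] == locality_id,
                              "continent"]
        if rows.empty:
            raise InputError(f"unknown locality_id {locality_id!r}")
        return str(rows.iloc[0])

    def mass_sample(self, locality_id: str) -> "MassSample":
        species = self.table.loc[self.table["locality_id"] == locality_id,
                                 "species_id"]
        if species.empty:
            raise InputError(f"unknown locality_id {locality_id!r}")
        masses = self.masses.loc[species].to_numpy(float)
        return MassSample(masses_g=masses, label=locality_id,
                          scale_tag="local",
                          continent=self.continent_of(locality_id))

    def continental_sample(self, continent: str) -> "MassSample":
        """Union of species over all localities of one continent."""
        species = self.table.loc[self.table["continent"] == continent,
                                 "species_id"].unique()
        if species.size == 0:
            raise InputError(f"unknown continent {continent!r}")
        masses = self.masses.loc[species].to_numpy(float)
        return MassSample(masses_g=masses, label=continent,
                          scale_tag="continental", continent=continent)

    def write(self, locality_csv: str | Path, mass_csv: str | Path) -> None:
        out = self.table[["locality_id", "continent", "species_id"]]
        out = out.sort_values(["continent", "locality_id", "species_id"])
        out.to_csv(locality_csv, index=False)
        mass = self.masses.rename("mass_g").rename_axis("species_id")
        mass.sort_index().to_csv(mass_csv)


def generate_continent_pool(config: PoolConfig, seed) -> SpeciesPool:
    """Draw one continental species pool from its generative settings.

    Masses come from a truncated skew-normal on the log2-gram scale
    (resampled until ``n_species`` draws fall inside the floor/ceiling);
    occupancy probabilities follow the logistic mass link.  The same
    (config, seed) pair always yields a bit-identical pool.
    """
    config.validate()
    rng = np.random.default_rng(seed)
    lo = np.log2(config.mass_floor_g)
    hi = np.log2(config.mass_ceiling_g)
    kept: list[np.ndarray] = []
    n_kept = n_drawn = 0
    batch = max(config.n_species, 1000)
    while n_kept < config.n_species:
        draw = stats.skewnorm.rvs(
            config.log2_mass_skew, loc=config.log2_mass_location,
            scale=config.log2_mass_scale, size=batch, random_state=rng)
        acc = draw[(draw >= lo) & (draw <= hi)]
        kept.append(acc)
        n_kept += acc.size
        n_drawn += draw.size
        if n_drawn >= 10 * batch and n_kept / n_drawn < 0.01:
            raise DegenerateConfigurationError(
                f"truncation acceptance {n_kept / n_drawn:.2%} < 1% for "
                f"pool {config.continent_label!r}")
    log2_masses = np.concatenate(kept)[:config.n_species]
    masses = 2.0 ** log2_masses
    occupancy = expit(config.occupancy_intercept
                      + config.occupancy_mass_coef * log2_masses)
    occupancy = np.clip(occupancy, 1e-12, 1 - 1e-12)
    ids = [f"{config.continent_label}_S{i:05d}"
           for i in range(config.n_species)]
    pool = SpeciesPool(ids, masses, occupancy, config.continent_label, config)
    pool.validate()
    return pool


def generate_fractal_pool(n: int, m_min_g: float, m_max_g: float,
                          exponent: float, seed) -> np.ndarray:
    """Masses from the truncated power-law density s(m) ∝ m**exponent.

    Inverse-CDF sampling on [m_min_g, m_max_g].  The exponent -1
    (log-uniform) integrates to a logarithm and is not supported.
    """
    if n < 10:
        raise ConfigurationError(f"n must be >= 10, got {n}")
    if not (0 < m_min_g < m_max_g):
        raise ConfigurationError(
            f"need 0 < m_min_g < m_max_g, got {m_min_g} / {m_max_g}")
    if exponent == -1:
        raise ConfigurationError(
            "exponent -1 (log-uniform) is not supported")
    rng = np.random.default_rng(seed)
    u = rng.random(n)
    b = exponent + 1.0
    lo, hi = m_min_g ** b, m_max_g ** b
    return (lo + u * (hi - lo)) ** (1.0 / b)


_MAX_LOCALITY_REDRAWS = 100
_MIN_LOCALITY_RICHNESS = 5


def sample_localities(pool: SpeciesPool, seed) -> AssemblageTable:
    """Assemble the pool's localities by independent Bernoulli occupancy.

    Each locality gets its own child random stream (derived from ``seed``),
    so a pool can be partially re-sampled reproducibly.  Localities with
    fewer than five species are redrawn; a locality that fails
    ``_MAX_LOCALITY_REDRAWS`` consecutive draws aborts the sampling.
    """
    pool.validate()
    if pool.config is None:
        raise ConfigurationError("pool carries no config (n_localities unknown)")
    n_loc = pool.config.n_localities
    children = _seedseq(seed).spawn(n_loc)
    ids = np.asarray(pool.species_ids)
    frames = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        for _ in range(_MAX_LOCALITY_REDRAWS):
            present = rng.random(ids.size) < pool.occupancy_p
            if int(present.sum()) >= _MIN_LOCALITY_RICHNESS:
                break
        else:
            raise DegenerateOccupancyError(
                f"locality {i + 1} of pool {pool.continent_label!r} stayed "
                f"below {_MIN_LOCALITY_RICHNESS} species after "
                f"{_MAX_LOCALITY_REDRAWS} redraws")
        locality = f"{pool.continent_label}_L{i + 1:03d}"
        frames.append(pd.DataFrame({
            "locality_id": locality,
            "continent": pool.continent_label,
            "species_id": ids[present],
        }))
    table = pd.concat(frames, ignore_index=True)
    masses = pd.Series(pool.masses_g, index=pool.species_ids, name="mass_g")
    at = AssemblageTable(table, masses)
    at.validate()
    return at


def simulate_study(configs: Sequence[PoolConfig],
                   seed) -> tuple[list[SpeciesPool], AssemblageTable]:
    """Generate per-continent pools and the concatenated locality table.

    Child seeds for each continent's pool and locality draws are spawned
    deterministically from the master seed.
    """
    if not 1 <= len(configs) <= 5:
        raise ConfigurationError(
            f"need between 1 and 5 pool configs, got {len(configs)}")
    labels = [c.continent_label for c in configs]
    if len(set(labels)) != len(labels):
        raise ConfigurationError(f"duplicate continent_label in {labels}")
    children = _seedseq(seed).spawn(2 * len(configs))
    pools: list[SpeciesPool] = []
    tables: list[AssemblageTable] = []
    for i, cfg in enumerate(configs):
        pool = generate_continent_pool(cfg, children[2 * i])
        pools.append(pool)
        tables.append(sample_localities(pool, children[2 * i + 1]))
    table = pd.concat([t.table for t in tables], ignore_index=True)
    masses = pd.concat([t.masses for t in tables])
    at = AssemblageTable(table, masses)
    at.validate()
    return pools, at


def turnover_protocol_config(continent_label: str = "SIM",
                             n_localities: int = 30) -> PoolConfig:
    """The size-dependent-occupancy study condition used throughout.

    Occupancy coefficient +1 per log2 gram with the intercept calibrated
    so the pool-wide mean occupancy is about 0.2, over a right-skewed
    mass pool spanning ~2 g to 10 t.
    """
    return PoolConfig(continent_label=continent_label, n_species=2000,
                      log2_mass_location=5.0, log2_mass_scale=4.0,
                      log2_mass_skew=3.0, mass_floor_g=1.5,
                      mass_ceiling_g=1.0e7, occupancy_intercept=-10.6,
                      occupancy_mass_coef=1.0, n_localities=n_localities)


# ---------------------------------------------------------------------------
# 3. per-assemblage spectrum estimators
# ---------------------------------------------------------------------------

@dataclass
class MassSample:
    """Body masses (grams) of one assemblage, the atomic analysis unit."""

    masses_g: np.ndarray
    label: str
    scale_tag: str = "local"      # "local" or "continental"
    continent: str = ""

    def __post_init__(self):
        self.masses_g = np.asarray(self.masses_g, float)
        if self.masses_g.size < 1:
            raise InputError(f"sample {self.label!r} is empty")
        if np.any(~(self.masses_g > 0)):
            raise InputError(f"sample {self.label!r} has non-positive masses")
        if self.scale_tag not in ("local", "continental"):
            raise ConfigurationError(
                f"scale_tag must be 'local' or 'continental', got "
                f"{self.scale_tag!r}")


def log2_class_assign(masses_g, scheme: str) -> np.ndarray:
    """Integer log2 size-class index of each species under one scheme.

    The class index is the species' log2 mass rounded down ("lower"),
    up ("upper") or half-up ("half"); species sharing a rounded value
    share a class.  All three schemes tile the mass axis with
    width-doubling classes whose boundaries sit one rounding step apart,
    which is what lets averaging the three fitted slopes cancel the
    boundary-phase bias.
    """
    m = np.asarray(masses_g, float)
    if m.size == 0:
        raise InputError("no masses to assign")
    if np.any(~(m > 0)):
        raise InputError("masses must be positive")
    x = np.log2(m)
    if scheme == "lower":
        k = np.floor(x)
    elif scheme == "upper":
        k = np.ceil(x)
    elif scheme == "half":
        k = np.floor(x + 0.5)      # round-half-up
    else:
        raise ConfigurationError(f"unknown scheme {scheme!r}")
    return k.astype(np.int64)


def _class_edges(k: np.ndarray, scheme: str) -> tuple[np.ndarray, np.ndarray]:
    """Linear-gram edges of class index k under one scheme."""
    k = np.asarray(k, float)
    if scheme == "lower":      # x in [k, k+1)
        return 2.0 ** k, 2.0 ** (k + 1)
    if scheme == "upper":      # x in (k-1, k]
        return 2.0 ** (k - 1), 2.0 ** k
    if scheme == "half":       # x in [k-1/2, k+1/2)
        return 2.0 ** (k - 0.5), 2.0 ** (k + 0.5)
    raise ConfigurationError(f"unknown scheme {scheme!r}")


@dataclass
class BinnedSpectrum:
    """Occupied log2 size classes of one sample under one scheme.

    ``density`` is species count divided by the class's *linear* width in
    grams, the correction that removes the spurious excess of species in
    wider (larger-mass) log classes.  Empty classes are never stored.
    """

    scheme: str
    class_index: np.ndarray
    lower_edge_g: np.ndarray
    upper_edge_g: np.ndarray
    linear_width_g: np.ndarray
    midpoint_g: np.ndarray
    count: np.ndarray
    density: np.ndarray

    @property
    def n_classes(self) -> int:
        return int(self.class_index.size)

    @property
    def richness(self) -> int:
        return int(self.count.sum())


def bin_spectrum(masses_g, scheme: str) -> BinnedSpectrum:
    """Count species per occupied log2 class and width-correct the counts."""
    k = log2_class_assign(masses_g, scheme)
    classes, counts = np.unique(k, return_counts=True)
    lower, upper = _class_edges(classes, scheme)
    width = upper - lower
    midpoint = (lower + upper) / 2.0
    return BinnedSpectrum(
        scheme=scheme, class_index=classes, lower_edge_g=lower,
        upper_edge_g=upper, linear_width_g=width, midpoint_g=midpoint,
        count=counts, density=counts / width)


def fit_loglog_slope(spectrum: BinnedSpectrum,
                     min_bins: int = 3) -> tuple[float, float, float]:
    """OLS of log10(density) on log10(midpoint) over occupied classes.

    Returns (slope, intercept, r_squared).  The slope is invariant to the
    logarithm base; base 10 is used for both axes.  Fewer than
    ``min_bins`` occupied classes raises :class:`InsufficientBinsError`.
    """
    if spectrum.n_classes < min_bins:
        raise InsufficientBinsError(spectrum.scheme, spectrum.n_classes,
                                    min_bins)
    fit = stats.linregress(np.log10(spectrum.midpoint_g),
                           np.log10(spectrum.density))
    return float(fit.slope), float(fit.intercept), float(fit.rvalue ** 2)


@dataclass(frozen=True)
class SchemeFit:
    scheme: str
    slope: float
    intercept: float
    r_squared: float
    n_bins: int


@dataclass(frozen=True)
class SlopeEstimate:
    """Per-scheme log-log fits and their unweighted average slope."""

    fits: tuple[SchemeFit, ...]

    @property
    def slope(self) -> float:
        return float(np.mean([f.slope for f in self.fits]))

    def per_scheme(self) -> dict[str, float]:
        return {f.scheme: f.slope for f in self.fits}


def estimate_slope(masses_g, schemes: Sequence[str] = SCHEMES,
                   min_bins: int = 3) -> SlopeEstimate:
    """The assemblage diversity/size slope, averaged over rounding schemes.

    Every scheme must yield at least ``min_bins`` occupied classes; if any
    fails the whole estimate fails, because the average over all schemes
    is what cancels the rounding bias.
    """
    if not schemes:
        raise ConfigurationError("at least one rounding scheme required")
    fits = []
    for scheme in schemes:
        spectrum = bin_spectrum(masses_g, scheme)
        slope, intercept, r2 = fit_loglog_slope(spectrum, min_bins=min_bins)
        fits.append(SchemeFit(scheme, slope, intercept, r2,
                              spectrum.n_classes))
    return SlopeEstimate(tuple(fits))


def g1_skewness(values) -> float:
    """Bias-adjusted third-moment sample skewness.

    g1 = n * sum((x - mean)^3) / ((n - 1) * (n - 2) * s^3) with s the
    (n - 1)-denominator standard deviation; positive values mean a tail
    toward large values.  Undefined below n = 3 or at zero variance.
    """
    x = np.asarray(values, float)
    if x.size < 3:
        raise UndefinedSkewnessError(f"need n >= 3, got n = {x.size}")
    if np.std(x, ddof=1) == 0:
        raise UndefinedSkewnessError("zero variance")
    return float(stats.skew(x, bias=False))


def half_sample_mode(values) -> float:
    """Robust mode: recursively narrow to the tightest half of the sample.

    Sort; while n > 3 keep the contiguous window of ceil(n/2) values with
    the smallest range (ties broken to the leftmost window).  Base cases:
    one value -> itself; two -> their mean; three -> mean of the closest
    pair, or of all three if the gaps tie.
    """
    x = np.sort(np.asarray(values, float))
    if x.size == 0:
        raise InputError("empty sample has no mode")
    while x.size > 3:
        h = (x.size + 1) // 2
        ranges = x[h - 1:] - x[:x.size - h + 1]
        i = int(np.argmin(ranges))       # argmin returns the leftmost tie
        x = x[i:i + h]
    if x.size == 1:
        return float(x[0])
    if x.size == 2:
        return float(x.mean())
    d1, d2 = x[1] - x[0], x[2] - x[1]
    if d1 < d2:
        return float((x[0] + x[1]) / 2.0)
    if d2 < d1:
        return float((x[1] + x[2]) / 2.0)
    return float(x.mean())


@dataclass
class ShapeSummary:
    """All distribution parameters of one assemblage.

    Component failures (e.g. too few size classes for a slope, undefined
    skewness) leave the field ``None`` and record the reason in
    ``errors`` instead of aborting a batch.
    """

    label: str
    continent: str
    scale_tag: str
    richness: int
    slope: float | None
    skew_linear: float | None
    skew_log2: float | None
    mode_linear_g: float | None
    mode_log2_g: float | None
    median_g: float | None
    pct_under_100g: float | None
    errors: dict = field(default_factory=dict)

    def to_row(self) -> dict:
        return {
            "label": self.label, "continent": self.continent,
            "scale": self.scale_tag, "richness": self.richness,
            "slope": self.slope, "skew_linear": self.skew_linear,
            "skew_log2": self.skew_log2, "mode_linear_g": self.mode_linear_g,
            "mode_log2_g": self.mode_log2_g, "median_g": self.median_g,
            "pct_under_100g": self.pct_under_100g,
        }


def shape_summary(sample: MassSample, schemes: Sequence[str] = SCHEMES,
                  min_bins: int = 3) -> ShapeSummary:
    """Compute every shape parameter of one assemblage."""
    m = sample.masses_g
    log2m = np.log2(m)
    errors: dict[str, str] = {}

    slope = skew_linear = skew_log2 = None
    try:
        slope = estimate_slope(m, schemes=schemes, min_bins=min_bins).slope
    except SizeSpectraError as exc:
        errors["slope"] = str(exc)
    try:
        skew_linear = g1_skewness(m)
    except UndefinedSkewnessError as exc:
        errors["skew_linear"] = str(exc)
    try:
        skew_log2 = g1_skewness(log2m)
    except UndefinedSkewnessError as exc:
        errors["skew_log2"] = str(exc)

    return ShapeSummary(
        label=sample.label, continent=sample.continent,
        scale_tag=sample.scale_tag, richness=int(m.size), slope=slope,
        skew_linear=skew_linear, skew_log2=skew_log2,
        mode_linear_g=half_sample_mode(m),
        mode_log2_g=float(2.0 ** half_sample_mode(log2m)),
        median_g=float(np.median(m)),
        pct_under_100g=float(100.0 * np.mean(m < 100.0)),
        errors=errors)


def summarize_assemblages(assemblages: AssemblageTable,
                          pools: Sequence[SpeciesPool] | None = None,
                          schemes: Sequence[str] = SCHEMES,
                          min_bins: int = 3) -> pd.DataFrame:
    """One ShapeSummary row per continent and per locality.

    Continental samples come from the species pools when given (simulated
    studies); otherwise from the union of species over each continent's
    localities -- a lower bound on the true continental fauna, flagged in
    the log.
    """
    assemblages.validate()
    rows = []
    continents = sorted(assemblages.table["continent"].unique())
    if pools is not None:
        by_label = {p.continent_label: p for p in pools}
        missing = set(continents) - set(by_label)
        if missing:
            raise ConfigurationError(
                f"no pool for continent(s) {sorted(missing)}")
        continental = [by_label[c].mass_sample() for c in continents]
    else:
        logger.info("no species pools given: continental assemblages are "
                    "unions of locality lists (lower bounds on the fauna)")
        continental = [assemblages.continental_sample(c) for c in continents]
    for sample in continental:
        rows.append(shape_summary(sample, schemes, min_bins).to_row())
    for locality in assemblages.locality_ids():
        sample = assemblages.mass_sample(locality)
        rows.append(shape_summary(sample, schemes, min_bins).to_row())
    df = pd.DataFrame(rows, columns=list(SUMMARY_COLUMNS))
    order = df["scale"].map({"continental": 0, "local": 1})
    df = df.assign(_o=order).sort_values(["continent", "_o", "label"])
    return df.drop(columns="_o").reset_index(drop=True)


def fractal_expected_increase(slope: float) -> float:
    """Percent increase in species number per halving of body mass.

    A log-log density slope b (b <= 0) means species density scales as
    m**b, so halving mass multiplies diversity by 2**|b|; the increase is
    (2**|b| - 1) * 100 percent.
    """
    if slope > 0:
        raise ConfigurationError(
            "conversion defined for diversity non-increasing with size "
            f"(slope <= 0), got {slope}")
    return float((2.0 ** abs(slope) - 1.0) * 100.0)


def mass_slope_to_length_slope(slope_mass: float) -> float:
    """Mass-axis slope re-expressed on body length under isometry.

    With mass proportional to length cubed, a density exponent b on mass
    corresponds to 3b on length (e.g. -2/3 on mass is -2 on length).
    """
    if not np.isfinite(slope_mass):
        raise ConfigurationError(f"slope must be finite, got {slope_mass}")
    return float(3.0 * slope_mass)


# ---------------------------------------------------------------------------
# 4. comparative statistics
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TestResult:
    test_name: str
    statistic: float
    p_value: float
    df: float | None = None
    group_sizes: tuple[int, ...] | None = None

    def to_dict(self) -> dict:
        d = {"test": self.test_name, "statistic": self.statistic,
             "p_value": self.p_value}
        if self.df is not None:
            d["df"] = self.df
        if self.group_sizes is not None:
            d["group_sizes"] = list(self.group_sizes)
        return d


def one_sample_t(values, mu0: float = FRACTAL_SLOPE_MASS) -> TestResult:
    """Two-sided one-sample t test of the mean against ``mu0``.

    The default null is the fractal-niche slope prediction of -2/3.
    """
    x = np.asarray(values, float)
    if x.size < 2:
        raise ConfigurationError(f"need n >= 2, got n = {x.size}")
    if np.std(x, ddof=1) == 0:
        raise ConfigurationError("zero variance: t statistic undefined")
    res = stats.ttest_1samp(x, popmean=mu0)
    return TestResult("one-sample t", float(res.statistic),
                      float(res.pvalue), df=float(x.size - 1))


def _as_groups(groups) -> tuple[list[str], list[np.ndarray]]:
    if isinstance(groups, Mapping):
        labels = list(groups)
        arrays = [np.asarray(groups[k], float) for k in labels]
    else:
        arrays = [np.asarray(g, float) for g in groups]
        labels = [f"group{i + 1}" for i in range(len(arrays))]
    return labels, arrays


def kruskal_wallis(groups) -> TestResult:
    """Rank-based Kruskal-Wallis H with tie correction, chi-square p.

    Completely tied data (every value identical) carries no rank
    information and is reported as H = 0, p = 1.
    """
    labels, arrays = _as_groups(groups)
    if len(arrays) < 2:
        raise ConfigurationError("need at least 2 groups")
    for lab, g in zip(labels, arrays):
        if g.size < 2:
            raise ConfigurationError(f"group {lab!r} has n < 2")
    pooled = np.concatenate(arrays)
    sizes = tuple(int(g.size) for g in arrays)
    if np.all(pooled == pooled[0]):
        return TestResult("Kruskal-Wallis", 0.0, 1.0,
                          df=float(len(arrays) - 1), group_sizes=sizes)
    h, p = stats.kruskal(*arrays)
    return TestResult("Kruskal-Wallis", float(h), float(p),
                      df=float(len(arrays) - 1), group_sizes=sizes)


def _pairwise_median_p(a: np.ndarray, b: np.ndarray) -> float:
    """Mood's median test p for one pair, exact-test fallback when the
    above/below table degenerates (e.g. a group equal to the pooled
    median)."""
    try:
        res = stats.median_test(a, b, ties="below", correction=True)
        return float(res.pvalue)
    except ValueError:
        med = np.median(np.concatenate([a, b]))
        table = np.array([[int(np.sum(a > med)), int(np.sum(b > med))],
                          [int(np.sum(a <= med)), int(np.sum(b <= med))]])
        _, p = stats.fisher_exact(table)
        return float(p)


@dataclass
class PosthocLetters:
    """Compact-letter display over pairwise Mood median tests.

    Two groups share a letter exactly when their pairwise test is
    non-significant at ``alpha``.
    """

    letters: dict[str, str]
    pairwise_p: dict[tuple[str, str], float]
    alpha: float

    def to_dict(self) -> dict:
        return {"alpha": self.alpha, "letters": dict(self.letters),
                "pairwise_p": {f"{a}|{b}": p
                               for (a, b), p in self.pairwise_p.items()}}


def median_posthoc(groups, alpha: float = 0.05,
                   bonferroni: bool = False) -> PosthocLetters:
    """Pairwise Mood median tests with a compact-letter display.

    Letters come from the maximal cliques of the non-significance graph,
    ordered by descending group median, so sharing a letter is exactly
    pairwise non-significance.  ``bonferroni`` multiplies each pairwise p
    by the number of pairs (off by default).
    """
    labels, arrays = _as_groups(groups)
    if len(arrays) < 2:
        raise ConfigurationError("need at least 2 groups")
    by = dict(zip(labels, arrays))
    pairs = list(itertools.combinations(labels, 2))
    pvals: dict[tuple[str, str], float] = {}
    for a, b in pairs:
        p = _pairwise_median_p(by[a], by[b])
        if bonferroni:
            p = min(1.0, p * len(pairs))
        pvals[(a, b)] = p

    nonsig = {(a, b) for (a, b), p in pvals.items() if p >= alpha}

    def adjacent(a: str, b: str) -> bool:
        return (a, b) in nonsig or (b, a) in nonsig

    # groups ordered by descending median, as contrast tables print them
    order = sorted(labels, key=lambda g: -np.median(by[g]))
    cliques = []
    for r in range(len(order), 0, -1):
        for subset in itertools.combinations(order, r):
            if any(set(subset) <= set(c) for c in cliques):
                continue
            if all(adjacent(a, b)
                   for a, b in itertools.combinations(subset, 2)):
                cliques.append(subset)
    cliques.sort(key=lambda c: min(order.index(g) for g in c))
    letters = {g: "" for g in labels}
    for letter, clique in zip("abcdefghijklmnopqrstuvwxyz", cliques):
        for g in clique:
            letters[g] += letter
    letters = {g: "".join(sorted(s)) for g, s in letters.items()}
    return PosthocLetters(letters, pvals, alpha)


@dataclass
class SemiPartialResult:
    """Rank semi-partial correlations of one response on each predictor."""

    response: str
    predictors: tuple[str, ...]
    estimates: dict[str, dict[str, float]]   # predictor -> {r, p_value}
    n: int

    def to_dict(self) -> dict:
        return {"response": self.response, "n": self.n,
                "predictors": {k: dict(v) for k, v in self.estimates.items()}}


def _numeric_codes(col: pd.Series) -> pd.Series:
    """Fixed integer coding (1..k, alphabetical) for a categorical column."""
    if pd.api.types.is_numeric_dtype(col):
        return col.astype(float)
    codes = {lab: i + 1 for i, lab in enumerate(sorted(col.unique()))}
    return col.map(codes).astype(float)


def spearman_semipartial(data: pd.DataFrame, response: str,
                         predictors: Sequence[str]) -> SemiPartialResult:
    """Spearman semi-partial correlation of a response with each predictor.

    All columns are rank-transformed (average ranks; a categorical column
    is first coded 1..k in alphabetical label order).  The semi-partial
    for predictor j is the Pearson correlation, on ranks, between the
    response and the residual of predictor j regressed (OLS with
    intercept) on the remaining predictors; that isolates the part of
    predictor j orthogonal to the others while leaving the response
    intact.  p-values use the t approximation with df = n - k - 1.
    """
    predictors = tuple(predictors)
    cols = [response, *predictors]
    df = data[cols].dropna()
    n, k = len(df), len(predictors)
    if n < k + 3:
        raise ConfigurationError(
            f"need at least {k + 3} complete cases, got {n}")
    ranks = {c: stats.rankdata(_numeric_codes(df[c]).to_numpy())
             for c in cols}
    y = ranks[response]
    dof = n - k - 1
    estimates: dict[str, dict[str, float]] = {}
    for pred in predictors:
        xj = ranks[pred]
        others = [ranks[p] for p in predictors if p != pred]
        design = np.column_stack([np.ones(n), *others])
        coef, _, rank, _ = np.linalg.lstsq(design, xj, rcond=None)
        if rank < design.shape[1]:
            raise CollinearityError(
                f"predictors regressed for {pred!r} are rank deficient")
        resid = xj - design @ coef
        if not np.any(np.abs(resid) > 1e-9 * max(1.0, np.abs(xj).max())):
            raise CollinearityError(
                f"predictor {pred!r} fully explained by the others")
        r = float(np.corrcoef(y, resid)[0, 1])
        r = float(np.clip(r, -1.0, 1.0))
        if abs(r) >= 1.0 - 1e-15:
            p = 0.0
        else:
            t = r * np.sqrt(dof / (1.0 - r * r))
            p = float(2.0 * stats.t.sf(abs(t), dof))
        estimates[pred] = {"r": r, "p_value": p}
    return SemiPartialResult(response, predictors, estimates, n)


def richness_residual_slopes(summaries: pd.DataFrame) -> pd.Series:
    """Slope residuals after removing the linear effect of richness.

    OLS of slope on richness across assemblages; the residuals isolate
    how steep each assemblage is for its diversity, the quantity compared
    across continents.
    """
    sub = summaries.dropna(subset=["slope", "richness"])
    if len(sub) < 3:
        raise ConfigurationError(
            f"need at least 3 assemblages with a slope, got {len(sub)}")
    richness = sub["richness"].to_numpy(float)
    if np.std(richness) == 0:
        raise ConfigurationError("zero richness variance")
    fit = stats.linregress(richness, sub["slope"].to_numpy(float))
    resid = sub["slope"].to_numpy(float) - (fit.intercept
                                            + fit.slope * richness)
    return pd.Series(resid, index=sub["label"].to_numpy(), name="residual")


_P_FLAG_LEVELS = ((0.001, "***"), (0.01, "**"))


def _p_flag(p: float) -> str:
    for level, flag in _P_FLAG_LEVELS:
        if p < level:
            return flag
    return "ns"


def scale_contrast(continental_summaries: pd.DataFrame,
                   locality_summaries: pd.DataFrame) -> pd.DataFrame:
    """Continental versus locality mean (± SD) for every shape parameter.

    One row per parameter with a two-sample Mann-Whitney p-value and a
    significance flag at the 0.01 / 0.001 levels.
    """
    if len(continental_summaries) < 2 or len(locality_summaries) < 3:
        raise ConfigurationError(
            "need >= 2 continental and >= 3 locality summaries")
    rows = []
    for param in SHAPE_PARAMETERS:
        a = continental_summaries[param].dropna().to_numpy(float)
        b = locality_summaries[param].dropna().to_numpy(float)
        pooled = np.concatenate([a, b])
        if a.size == 0 or b.size == 0:
            p = np.nan
        elif np.all(pooled == pooled[0]):
            p = 1.0
        else:
            p = float(stats.mannwhitneyu(a, b,
                                         alternative="two-sided").pvalue)
        rows.append({
            "parameter": param,
            "continental_mean": float(np.mean(a)) if a.size else np.nan,
            "continental_sd": float(np.std(a, ddof=1)) if a.size > 1
            else np.nan,
            "locality_mean": float(np.mean(b)) if b.size else np.nan,
            "locality_sd": float(np.std(b, ddof=1)) if b.size > 1
            else np.nan,
            "p_value": p,
            "flag": _p_flag(p) if np.isfinite(p) else "",
        })
    return pd.DataFrame(rows)


_RANKED_PARAMETERS = ("slope", "skew_linear", "skew_log2",
                      "mode_linear_g", "mode_log2_g")


def compare_report(summaries: pd.DataFrame, alpha: float = 0.05,
                   mu0: float = FRACTAL_SLOPE_MASS
                   ) -> tuple[dict, pd.Series | None]:
    """The full inferential report over one summary table.

    Sections: slope tests against the fractal prediction; the
    continental-versus-local contrast table; per-parameter continental
    rankings (Kruskal-Wallis + median post-hoc letters); rank
    semi-partial correlations of each parameter on median size, richness
    and continent; and the richness-controlled slope-residual contrast.
    Returns (report dict, per-locality residual series or None).
    """
    loc = summaries[summaries["scale"] == "local"]
    cont = summaries[summaries["scale"] == "continental"]
    report: dict = {"n_localities": int(len(loc)),
                    "n_continents": int(len(cont)),
                    "alpha": alpha, "mu0": mu0}

    slope_tests = {}
    loc_slopes = loc["slope"].dropna().to_numpy(float)
    if loc_slopes.size >= 2 and np.std(loc_slopes, ddof=1) > 0:
        slope_tests["localities_vs_fractal"] = one_sample_t(
            loc_slopes, mu0).to_dict()
    cont_slopes = cont["slope"].dropna().to_numpy(float)
    if cont_slopes.size >= 2 and np.std(cont_slopes, ddof=1) > 0:
        slope_tests["continents_vs_fractal"] = one_sample_t(
            cont_slopes, mu0).to_dict()
    report["slope_vs_fractal"] = slope_tests

    if len(cont) >= 2 and len(loc) >= 3:
        report["scale_contrast"] = scale_contrast(cont, loc).to_dict(
            orient="records")

    continents = sorted(loc["continent"].unique())
    rankings: dict = {}
    if len(continents) >= 2:
        for param in _RANKED_PARAMETERS:
            groups = {c: loc.loc[loc["continent"] == c, param]
                      .dropna().to_numpy(float) for c in continents}
            groups = {c: g for c, g in groups.items() if g.size >= 2}
            if len(groups) < 2:
                continue
            kw = kruskal_wallis(groups)
            letters = median_posthoc(groups, alpha=alpha)
            rankings[param] = {
                "kruskal_wallis": kw.to_dict(),
                "letters": letters.to_dict(),
                "group_medians": {c: float(np.median(g))
                                  for c, g in groups.items()},
            }
    report["continental_rankings"] = rankings

    semipartial: dict = {}
    predictors = ["median_g", "richness", "continent"]
    if len(continents) < 2:
        predictors = ["median_g", "richness"]
    for param in _RANKED_PARAMETERS:
        try:
            res = spearman_semipartial(loc, param, predictors)
        except (ConfigurationError, CollinearityError) as exc:
            logger.warning("semi-partial for %s skipped: %s", param, exc)
            continue
        semipartial[param] = res.to_dict()
    report["semipartial"] = semipartial

    residuals = None
    try:
        residuals = richness_residual_slopes(loc)
    except ConfigurationError as exc:
        logger.warning("richness residuals skipped: %s", exc)
    if residuals is not None and len(continents) >= 2:
        by_cont = {
            c: residuals.loc[residuals.index.isin(
                loc.loc[loc["continent"] == c, "label"])].to_numpy(float)
            for c in continents}
        by_cont = {c: g for c, g in by_cont.items() if g.size >= 2}
        if len(by_cont) >= 2:
            report["richness_residuals"] = {
                "kruskal_wallis": kruskal_wallis(by_cont).to_dict(),
                "letters": median_posthoc(by_cont, alpha=alpha).to_dict(),
                "group_medians": {c: float(np.median(g))
                                  for c, g in by_cont.items()},
            }
    return report, residuals


# ---------------------------------------------------------------------------
# 5. readers/writers and the end-to-end pipeline
# ---------------------------------------------------------------------------

def read_assemblages(locality_csv: str | Path,
                     mass_csv: str | Path) -> AssemblageTable:
    """Read and validate a locality table plus its species-mass lookup.

    Rows whose species lack a mass entry are dropped with a logged count;
    duplicate (locality, species) rows are collapsed with a warning.
    Missing columns, empty files and non-positive or non-numeric masses
    raise :class:`InputError` naming the offending rows (1-based data
    row numbers).
    """
    try:
        loc = pd.read_csv(locality_csv, dtype=str)
    except pd.errors.EmptyDataError:
        raise InputError(f"{locality_csv}: empty file") from None
    missing = {"locality_id", "continent", "species_id"} - set(loc.columns)
    if missing:
        raise InputError(f"{locality_csv}: missing column(s) {sorted(missing)}")
    if loc.empty:
        raise InputError(f"{locality_csv}: no data rows")

    try:
        mass = pd.read_csv(mass_csv, dtype={"species_id": str})
    except pd.errors.EmptyDataError:
        raise InputError(f"{mass_csv}: empty file") from None
    missing = {"species_id", "mass_g"} - set(mass.columns)
    if missing:
        raise InputError(f"{mass_csv}: missing column(s) {sorted(missing)}")
    if mass.empty:
        raise InputError(f"{mass_csv}: no data rows")
    mass_values = pd.to_numeric(mass["mass_g"], errors="coerce")
    bad = mass.index[mass_values.isna()] + 1
    if len(bad):
        raise InputError(
            f"{mass_csv}: non-numeric mass at data row(s) {list(bad[:10])}")
    bad = mass.index[mass_values <= 0] + 1
    if len(bad):
        raise InputError(
            f"{mass_csv}: non-positive mass at data row(s) {list(bad[:10])}")
    masses = pd.Series(mass_values.to_numpy(float),
                       index=mass["species_id"], name="mass_g")
    if masses.index.has_duplicates:
        per_species = masses.groupby(level=0).nunique()
        conflicting = per_species[per_species > 1]
        if len(conflicting):
            raise InputError(
                f"{mass_csv}: conflicting masses for species "
                f"{list(conflicting.index[:5])}")
        n_dup = int(masses.index.duplicated().sum())
        logger.warning("%s: %d duplicate mass row(s) collapsed",
                       mass_csv, n_dup)
        masses = masses[~masses.index.duplicated()]

    n_before = len(loc)
    loc = loc.drop_duplicates(["locality_id", "species_id"])
    n_dup = n_before - len(loc)
    if n_dup:
        logger.warning("%s: %d duplicate (locality, species) row(s) "
                       "collapsed", locality_csv, n_dup)
    known = loc["species_id"].isin(masses.index)
    n_unknown = int((~known).sum())
    if n_unknown:
        logger.warning("%s: %d row(s) with species missing from the mass "
                       "file dropped", locality_csv, n_unknown)
        loc = loc[known]
    if loc.empty:
        raise InputError(
            f"{locality_csv}: no rows left after dropping unknown species")
    at = AssemblageTable(loc.reset_index(drop=True), masses)
    at.validate()
    return at


def write_assemblages(assemblages: AssemblageTable, locality_csv: str | Path,
                      mass_csv: str | Path) -> None:
    assemblages.write(locality_csv, mass_csv)


@dataclass
class StudyConfig:
    """Everything one pipeline run needs: pools, estimator and test options."""

    pools: list[PoolConfig]
    seed: int = 0
    out_dir: str = "results"
    schemes: tuple[str, ...] = SCHEMES
    min_bins: int = 3
    alpha: float = 0.05
    mu0: float = FRACTAL_SLOPE_MASS

    _FIELDS = ("pools", "seed", "out_dir", "schemes", "min_bins",
               "alpha", "mu0")

    def validate(self) -> None:
        if not self.pools:
            raise ConfigurationError("at least one pool config required")
        labels = [p.continent_label for p in self.pools]
        if len(set(labels)) != len(labels):
            raise ConfigurationError(f"duplicate continent_label in {labels}")
        for p in self.pools:
            p.validate()
        unknown = set(self.schemes) - set(SCHEMES)
        if not self.schemes or unknown:
            raise ConfigurationError(
                f"schemes must be a non-empty subset of {SCHEMES}")
        if self.min_bins < 3:
            raise ConfigurationError("min_bins must be >= 3")
        if not 0 < self.alpha < 1:
            raise ConfigurationError("alpha must lie in (0, 1)")

    @classmethod
    def from_dict(cls, d: Mapping) -> "StudyConfig":
        unknown = set(d) - set(cls._FIELDS)
        if unknown:
            raise ConfigurationError(
                f"unknown study config key(s): {sorted(unknown)}")
        if "pools" not in d:
            raise ConfigurationError("study config needs a 'pools' list")
        pools = [PoolConfig.from_dict(p) for p in d["pools"]]
        kwargs = {k: d[k] for k in d if k != "pools"}
        if "schemes" in kwargs:
            kwargs["schemes"] = tuple(kwargs["schemes"])
        cfg = cls(pools=pools, **kwargs)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path: str | Path) -> "StudyConfig":
        with open(path, "r", encoding="utf-8") as fh:
            d = yaml.safe_load(fh)
        if not isinstance(d, Mapping):
            raise ConfigurationError(f"{path}: not a mapping")
        return cls.from_dict(d)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["schemes"] = list(self.schemes)
        return d

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)


def default_study_config(seed: int = 0,
                         out_dir: str = "results") -> StudyConfig:
    """The bundled three-continent study design (93 localities).

    Pools differ the way the real faunas do: the Afrotropical pool is the
    richest and reaches the largest masses, the Nearctic has many small
    species, and the Neotropical pool is "compressed" -- poorer in both
    very small insectivores and megafauna, spanning fewer octaves of
    mass.  Occupancy intercepts are calibrated so each pool's mean
    occupancy is about 0.2.
    """
    pools = [
        PoolConfig("AFR", n_species=2200, log2_mass_location=4.5,
                   log2_mass_scale=4.2, log2_mass_skew=3.0,
                   mass_floor_g=1.5, mass_ceiling_g=1.0e7,
                   occupancy_intercept=-10.3, occupancy_mass_coef=1.0,
                   n_localities=30),
        PoolConfig("NAM", n_species=1700, log2_mass_location=5.5,
                   log2_mass_scale=4.0, log2_mass_skew=3.0,
                   mass_floor_g=1.5, mass_ceiling_g=8.0e6,
                   occupancy_intercept=-11.1, occupancy_mass_coef=1.0,
                   n_localities=35),
        PoolConfig("SAM", n_species=1500, log2_mass_location=6.0,
                   log2_mass_scale=3.2, log2_mass_skew=2.5,
                   mass_floor_g=3.0, mass_ceiling_g=1.2e6,
                   occupancy_intercept=-10.65, occupancy_mass_coef=1.0,
                   n_localities=28),
    ]
    return StudyConfig(pools=pools, seed=seed, out_dir=out_dir)


def _jsonify(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def run_pipeline(config: StudyConfig) -> dict[str, Path]:
    """simulate -> summarize -> compare, writing every artifact to disk.

    Outputs in ``config.out_dir``: the resolved config, assemblage and
    mass CSVs, the per-assemblage summary CSV, the JSON comparison
    report, the residual CSV and a run log.  Identical config + seed
    yields byte-identical numeric outputs.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {name: out / fname for name, fname in (
        ("config", "config.yaml"), ("assemblages", "assemblages.csv"),
        ("masses", "masses.csv"), ("summaries", "summaries.csv"),
        ("report", "report.json"), ("residuals", "residuals.csv"),
        ("log", "run.log"))}
    configure_logging(logger.level or "INFO", logfile=paths["log"])
    logger.info("sizespectra %s: pipeline start, seed=%d, %d pool(s)",
                __version__, config.seed, len(config.pools))

    config.to_yaml(paths["config"])
    pools, assemblages = simulate_study(config.pools, config.seed)
    assemblages.write(paths["assemblages"], paths["masses"])
    logger.info("simulated %d localities, %d presence rows",
                len(assemblages.locality_ids()), len(assemblages.table))

    summaries = summarize_assemblages(assemblages, pools=pools,
                                      schemes=config.schemes,
                                      min_bins=config.min_bins)
    summaries.to_csv(paths["summaries"], index=False)
    logger.info("summarized %d assemblages", len(summaries))

    report, residuals = compare_report(summaries, alpha=config.alpha,
                                       mu0=config.mu0)
    with open(paths["report"], "w", encoding="utf-8") as fh:
        json.dump(report, fh, indent=2, default=_jsonify)
        fh.write("\n")
    if residuals is not None:
        residuals.rename_axis("label").to_csv(paths["residuals"])
    else:
        paths.pop("residuals")
    logger.info("pipeline done: %s", out)
    return paths
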