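"""Synthetic ENM exposure-table generator.

The generator emulates the statistical structure of the modelling
dataset the pipeline assumes: a panel of metal-oxide nanomaterials, a
geometric concentration series per ENM anchored at ~100 % viability at
the lowest dose, and a deterministic dose-response surface

``viability = 100 + u * (b_PEG·PEG + b_Fe3O4·Fe3O4 + b_Fe·Fe-doping
+ b_PMAA·PMAA + b_Cl·Cl-doping) + b_ratio * (c - c0)/d + noise``

where ``u = log10(c / c0)`` is the dose in decades above the series
anchor ``c0``, ``c`` the concentration (µg/mL) and ``d`` the diameter
(nm). Effect signs follow the feature–viability correlations the
modelling is expected to recover: PEG coating, Fe3O4 core and Fe doping
protective (positive); the PMAA × concentration interaction, Cl doping
and the concentration/diameter ratio cytotoxic (negative).

Noise is Gaussian. By default each ENM's noise vector is moment-matched
(exactly zero mean, exactly ``noise_sd`` population SD, orthogonal to
that ENM's deterministic dose profile), so the marginal mean and SD of
any union of whole ENM series are fixed by design rather than by luck
of the seed; the draws remain i.i.d. Gaussian up to this per-series
projection. Effect sizes and noise SD are calibrated so the study-scale
roster (:func:`study_config`) reproduces a marginal viability
distribution with mean 96 % and SD 23 % on the sub-200-nm rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np

from .data import ENMDataset, ENMRecord, NO_COATING, NO_DOPING
from .errors import ConfigError

#: Concentration series (µg/mL) used when no per-ENM series is given.
DEFAULT_GRID = (0.01, 1.56, 3.13, 6.25, 12.5, 25.0)


@dataclass(frozen=True)
class EffectTable:
    """Ground-truth signed coefficients of the generator's dose-response.

    Units: viability percent per decade of dose for the interaction
    terms; percent per (µg/mL)/nm for the concentration/diameter ratio.
    """

    peg_coating: float
    fe3o4_core: float
    fe_doping: float
    pmaa_concentration: float
    cl_doping: float
    concentration_over_diameter: float

    #: Descriptor-matrix column carrying each effect.
    FEATURE_COLUMNS = {
        "peg_coating": "coat_PEG",
        "fe3o4_core": "core_Fe3O4",
        "fe_doping": "dop_Fe (4%)",
        "pmaa_concentration": "Concentration_ug_mL*coat_PMAA",
        "cl_doping": "dop_Cl (3%)",
        "concentration_over_diameter": "Concentration_ug_mL/Diameter_nm",
    }

    def as_dict(self) -> dict[str, float]:
        return {k: float(getattr(self, k)) for k in self.FEATURE_COLUMNS}

    def signs(self) -> dict[str, int]:
        return {k: int(np.sign(v)) for k, v in self.as_dict().items()}

    def feature_signs(self) -> dict[str, int]:
        """Expected sign of each effect keyed by descriptor column name."""
        return {self.FEATURE_COLUMNS[k]: s for k, s in self.signs().items() if s != 0}


# Calibrated defaults: see docs/methods.md for the calibration procedure.
DEFAULT_EFFECTS = EffectTable(
    peg_coating=9.518,
    fe3o4_core=3.807,
    fe_doping=5.076,
    pmaa_concentration=-16.9,
    cl_doping=-10.563,
    concentration_over_diameter=-1.584,
)

DEFAULT_NOISE_SD = 7.0


@dataclass(frozen=True)
class ENMDesign:
    """Fixed attributes of one generated ENM and its dose series."""

    enm_id: str
    core: str
    doping: str
    coating: str
    diameter: float
    doses: tuple[float, ...]


@dataclass(frozen=True)
class CategoryPools:
    """Allowed composition labels and their sampling weights."""

    cores: Mapping[str, float] = field(
        default_factory=lambda: {
            "ZnO": 3, "Ag": 2, "SiO2": 2, "Fe3O4": 2, "CuO": 1, "TiO2": 1,
        }
    )
    dopings: Mapping[str, float] = field(
        default_factory=lambda: {
            NO_DOPING: 7, "Na (1.5%)": 1, "Fe (4%)": 2, "Cl (3%)": 1,
        }
    )
    coatings: Mapping[str, float] = field(
        default_factory=lambda: {
            NO_COATING: 4, "PMAA": 2, "PEG": 2, "sodium citrate": 3,
        }
    )

    def validate(self) -> None:
        for name, pool in (("cores", self.cores), ("dopings", self.dopings),
                           ("coatings", self.coatings)):
            if not pool:
                raise ConfigError(f"empty category pool: {name}")
            if any(w < 0 for w in pool.values()) or sum(pool.values()) <= 0:
                raise ConfigError(f"invalid sampling weights in pool {name}")


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything that defines one synthetic exposure table."""

    n_enms: int = 11
    concentration_grid: tuple[float, ...] = DEFAULT_GRID
    category_pools: CategoryPools = field(default_factory=CategoryPools)
    diameter_range: tuple[float, float] = (4.0, 200.0)
    effect_sizes: EffectTable = DEFAULT_EFFECTS
    noise_sd: float = DEFAULT_NOISE_SD
    hormesis: bool = False
    seed: int = 0
    #: Explicit ENM panel; overrides random sampling when given.
    roster: tuple[ENMDesign, ...] | None = None
    #: Moment-match each ENM's noise vector (see module docstring).
    match_noise_moments: bool = True

    def validate(self) -> None:
        if self.noise_sd < 0:
            raise ConfigError("noise_sd must be >= 0")
        if self.roster is None:
            if self.n_enms < 1:
                raise ConfigError("n_enms must be >= 1")
            if any(c < 0 for c in self.concentration_grid):
                raise ConfigError("doses must be >= 0")
            if len(set(self.concentration_grid)) != len(self.concentration_grid):
                raise ConfigError("concentration_grid has duplicate doses")
            lo, hi = self.diameter_range
            if not (0 < lo < hi):
                raise ConfigError("diameter_range must satisfy 0 < low < high")
            self.category_pools.validate()


def ground_truth_effects(config: GeneratorConfig) -> EffectTable:
    """The exact coefficients :func:`generate_dataset` uses for ``config``."""
    return config.effect_sizes


def _sample(rng: np.random.Generator, pool: Mapping[str, float]) -> str:
    labels = list(pool)
    w = np.array([pool[k] for k in labels], dtype=float)
    return labels[rng.choice(len(labels), p=w / w.sum())]


def _sample_roster(config: GeneratorConfig, rng: np.random.Generator) -> tuple[ENMDesign, ...]:
    designs = []
    lo, hi = config.diameter_range
    for i in range(config.n_enms):
        core = _sample(rng, config.category_pools.cores)
        doping = _sample(rng, config.category_pools.dopings)
        coating = _sample(rng, config.category_pools.coatings)
        diameter = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        designs.append(
            ENMDesign(
                enm_id=f"ENM-{i + 1:02d}",
                core=core,
                doping=doping,
                coating=coating,
                diameter=round(diameter, 2),
                doses=tuple(sorted(config.concentration_grid)),
            )
        )
    return tuple(designs)


def _hormesis_bump(u: np.ndarray) -> np.ndarray:
    # Low-dose stimulation peaking around u ~ 2.2 decades, followed by a
    # crash over the last half decade (cf. a ZnO-style 120 % -> 47 % flip).
    return 12.0 * np.exp(-((u - 2.2) ** 2) / 0.5) - 40.0 * np.clip(u - 2.8, 0.0, None)


def deterministic_viability(design: ENMDesign, effects: EffectTable,
                            hormesis: bool = False) -> np.ndarray:
    """Noise-free viability profile of one ENM over its dose series."""
    c = np.asarray(design.doses, dtype=float)
    c0 = c.min()
    with np.errstate(divide="ignore"):
        u = np.where(c > 0, np.log10(np.where(c > 0, c, 1.0) / max(c0, 1e-12)), 0.0)
    slope = (
        effects.peg_coating * (design.coating == "PEG")
        + effects.fe3o4_core * (design.core == "Fe3O4")
        + effects.fe_doping * design.doping.startswith("Fe")
        + effects.pmaa_concentration * (design.coating == "PMAA")
        + effects.cl_doping * design.doping.startswith("Cl")
    )
    v = 100.0 + slope * u + effects.concentration_over_diameter * (c - c0) / design.diameter
    if hormesis:
        v = v + _hormesis_bump(u)
    return v


def _matched_noise(rng: np.random.Generator, det: np.ndarray, sd: float) -> np.ndarray:
    """Gaussian noise with exact zero mean / exact SD, orthogonal to det."""
    n = det.size
    z = rng.standard_normal(n)
    if sd == 0:
        return np.zeros(n)
    if n < 3:
        return z * sd
    z = z - z.mean()
    dev = det - det.mean()
    norm2 = float(dev @ dev)
    if norm2 > 0:
        z = z - (z @ dev) / norm2 * dev
    zsd = z.std()  # population SD
    if zsd == 0:
        return np.zeros(n)
    return z / zsd * sd


def generate_dataset(config: GeneratorConfig) -> ENMDataset:
    """Draw one synthetic exposure table.

    Draw order (one ``numpy`` Generator seeded with ``config.seed``):
    per ENM in roster order, first the categorical attributes and
    diameter (random rosters only), then one noise vector per ENM in
    roster order. Identical config + seed gives an identical dataset.
    Viability is truncated below at 0.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    roster = config.roster if config.roster is not None else _sample_roster(config, rng)
    records: list[ENMRecord] = []
    for design in roster:
        det = deterministic_viability(design, config.effect_sizes, config.hormesis)
        if config.match_noise_moments:
            noise = _matched_noise(rng, det, config.noise_sd)
        else:
            noise = rng.standard_normal(det.size) * config.noise_sd
        v = np.clip(det + noise, 0.0, None)
        for dose, viab in zip(design.doses, v):
            records.append(
                ENMRecord(
                    enm_id=design.enm_id,
                    core=design.core,
                    doping=design.doping,
                    coating=design.coating,
                    diameter=design.diameter,
                    concentration=float(dose),
                    viability=float(viab),
                )
            )
    tag = f"generator(seed={config.seed}, n_enms={len(roster)})"
    return ENMDataset(records=tuple(records), provenance=tag)


# ---------------------------------------------------------------------------
# Study-scale roster

def _series(n: int, lo: float = 0.01, hi: float = 25.0) -> tuple[float, ...]:
    """Geometric dose ladder with ``n`` distinct doses from ``lo`` to ``hi``."""
    return tuple(float(f"{c:.6g}") for c in np.geomspace(lo, hi, n))


def study_roster() -> tuple[ENMDesign, ...]:
    """Fixed 16-ENM panel emulating the study's exposure table.

    11 ENMs under 200 nm carrying 333 observations (the modelling set
    after the diameter filter) and 5 coarse ENMs (>= 200 nm) carrying 44
    observations, 377 in total.
    """
    small = [
        ("ZnO", NO_DOPING, NO_COATING, 68.9, 31),
        ("ZnO", "Na (1.5%)", NO_COATING, 5.5, 30),
        ("ZnO", "Cl (3%)", NO_COATING, 25.0, 30),
        ("Ag", NO_DOPING, "PMAA", 12.0, 31),
        ("Ag", NO_DOPING, "sodium citrate", 18.0, 30),
        ("SiO2", "Fe (4%)", NO_COATING, 40.0, 30),
        ("SiO2", NO_DOPING, "PMAA", 95.0, 30),
        ("Fe3O4", NO_DOPING, "PEG", 45.0, 31),
        ("Fe3O4", NO_DOPING, "PEG", 80.0, 30),
        ("CuO", NO_DOPING, "PMAA", 60.0, 30),
        ("TiO2", "Fe (4%)", "sodium citrate", 110.0, 30),
    ]
    large = [
        ("TiO2", NO_DOPING, NO_COATING, 250.0, 9),
        ("SiO2", NO_DOPING, "sodium citrate", 320.0, 9),
        ("ZnO", NO_DOPING, NO_COATING, 480.0, 9),
        ("Al2O3", NO_DOPING, NO_COATING, 650.0, 9),
        ("CeO2", NO_DOPING, "sodium citrate", 900.0, 8),
    ]
    designs = []
    for i, (core, dop, coat, d, n) in enumerate(small + large, start=1):
        designs.append(
            ENMDesign(
                enm_id=f"ENM-{i:02d}", core=core, doping=dop, coating=coat,
                diameter=d, doses=_series(n),
            )
        )
    return tuple(designs)


def study_config(seed: int = 0, **overrides) -> GeneratorConfig:
    """Generator configuration reproducing the study-scale table."""
    return GeneratorConfig(roster=study_roster(), seed=seed, **overrides)
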