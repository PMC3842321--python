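"""Synthetic tissue-like spectra and cohorts for the genotyping pipeline.

The study's tissue data are not deposited, so this module generates cohorts
whose per-group metabolite concentrations match published medians and ranges.
Concentrations are drawn from a median-matched scaled Beta law on the stated
[min, max] support; spectra are rendered as sums of Lorentzian multiplets on
a uniform ppm grid plus i.i.d. Gaussian noise.  A lactate-only calibration
standard of known amount is rendered under the same conditions.

Tissue spectra deliberately contain no lactate and no lipid signals (their
absence is a sample-quality marker), so the lactate reference window is
signal-free in every tissue spectrum.
"""

from __future__ import annotations

import dataclasses
from importlib import resources
from pathlib import Path

import numpy as np
import yaml
from scipy.optimize import brentq
from scipy.special import comb
from scipy.stats import beta as beta_dist

from pgl_metabotyper.spectra import (
    DEFAULT_SPECTROMETER_MHZ,
    LACTATE_REFERENCE_REGION,
    CalibrationStandard,
    Spectrum1D,
)


class ResolutionError(ValueError):
    """The requested ppm grid is too coarse to resolve the rendered lines."""


# ---------------------------------------------------------------------------
# spectral signatures


@dataclasses.dataclass(frozen=True)
class SpectralLine:
    """One resonance: center, area per molecule (protons), multiplicity, J."""

    center_ppm: float
    relative_area: float
    multiplicity: int = 1
    j_hz: float = 0.0

    def __post_init__(self) -> None:
        if not 0.0 <= self.center_ppm <= 10.0:
            raise ValueError(f"center_ppm {self.center_ppm} outside [0, 10]")
        if not self.relative_area > 0:
            raise ValueError("relative_area must be > 0")
        if self.multiplicity < 1:
            raise ValueError("multiplicity must be >= 1")


@dataclasses.dataclass(frozen=True)
class MetaboliteSignature:
    name: str
    lines: tuple[SpectralLine, ...]

    @property
    def total_protons(self) -> float:
        return sum(line.relative_area for line in self.lines)


def _sig(name: str, *lines: tuple) -> MetaboliteSignature:
    return MetaboliteSignature(name, tuple(SpectralLine(*ln) for ln in lines))


#: rendering conventions for each species; window-determining centers follow
#: standard assignment tables, satellite lines are generator conventions.
DEFAULT_SIGNATURES: dict[str, MetaboliteSignature] = {
    "succinate": _sig("succinate", (2.41, 4, 1, 0.0)),
    "glutamate": _sig("glutamate", (2.35, 2, 2, 7.0), (2.08, 2, 2, 7.0)),
    "glutathione": _sig(
        "glutathione", (2.95, 2, 2, 7.0), (2.16, 2, 2, 7.0), (2.55, 2, 2, 7.0)
    ),
    "atp_adp_amp": _sig(
        "atp_adp_amp", (6.09, 1, 2, 5.5), (8.27, 1, 1, 0.0), (8.45, 1, 1, 0.0)
    ),
    "epinephrine": _sig(
        "epinephrine",
        (2.75, 3, 1, 0.0),  # N-CH3 singlet
        (6.91, 1, 1, 0.0),  # aromatic H5
        (6.86, 1, 1, 0.0),
        (6.97, 1, 1, 0.0),
    ),
    "norepinephrine": _sig(
        "norepinephrine", (6.91, 1, 1, 0.0), (6.86, 1, 1, 0.0), (6.97, 1, 1, 0.0)
    ),
    "dopamine": _sig(
        "dopamine",
        (2.85, 2, 3, 7.3),
        (3.22, 2, 3, 7.3),
        (6.91, 1, 1, 0.0),
        (6.87, 1, 1, 0.0),
    ),
    "lactate": _sig("lactate", (1.33, 3, 2, 6.9), (4.11, 1, 4, 6.9)),
}


# ---------------------------------------------------------------------------
# concentration law


def draw_concentration(
    median: float,
    minimum: float,
    maximum: float,
    rng: np.random.Generator,
    size: int | None = None,
) -> float | np.ndarray:
    """Draw from a scaled Beta on [minimum, maximum] with the given median.

    The Beta shape alpha is fixed at 2; beta is solved numerically so the
    distribution median matches ``median``.  A degenerate range returns the
    constant.
    """
    if not minimum <= median <= maximum:
        raise ValueError(f"median {median} outside [{minimum}, {maximum}]")
    span = maximum - minimum
    if span == 0:
        return float(median) if size is None else np.full(size, float(median))
    m = (median - minimum) / span
    m = min(max(m, 1e-6), 1 - 1e-6)  # guard medians at the support edge
    b = _solve_beta_shape(m)
    draw = rng.beta(2.0, b, size=size)
    return minimum + span * draw


_BETA_CACHE: dict[float, float] = {}


def _solve_beta_shape(target_median: float) -> float:
    """Solve beta so that Beta(2, beta) has the target median on [0, 1]."""
    b = _BETA_CACHE.get(target_median)
    if b is None:
        b = brentq(
            lambda bb: beta_dist.ppf(0.5, 2.0, bb) - target_median, 1e-6, 1e6, xtol=1e-12
        )
        _BETA_CACHE[target_median] = b
    return b


# ---------------------------------------------------------------------------
# rendering


@dataclasses.dataclass(frozen=True)
class GridSpec:
    """Uniform ppm grid for rendered spectra."""

    ppm_min: float = 0.5
    ppm_max: float = 9.0
    step: float = 0.0005

    def __post_init__(self) -> None:
        if not self.ppm_min < self.ppm_max:
            raise ValueError("ppm_min must be < ppm_max")
        if self.step <= 0:
            raise ValueError("step must be > 0")
        if self.step > 0.002:
            raise ResolutionError(
                f"grid step {self.step} ppm too coarse (must be <= 0.002 ppm)"
            )

    def build(self) -> np.ndarray:
        n = int(round((self.ppm_max - self.ppm_min) / self.step)) + 1
        return np.linspace(self.ppm_min, self.ppm_max, n)


@dataclasses.dataclass
class GroundTruth:
    """True per-sample concentrations used to render one spectrum."""

    sample_id: str
    group: str
    weight_mg: float
    concentrations: dict[str, float]  # nmol/mg per metabolite

    def __post_init__(self) -> None:
        for name, value in self.concentrations.items():
            if value < 0:
                raise ValueError(f"{self.sample_id}: negative concentration for {name}")
        if not self.weight_mg > 0:
            raise ValueError("weight_mg must be > 0")


def _lorentzian(x: np.ndarray, center: float, area: float, fwhm_ppm: float) -> np.ndarray:
    gamma = fwhm_ppm / 2.0
    return area * gamma / (np.pi * ((x - center) ** 2 + gamma**2))


def _multiplet_comb(line: SpectralLine, mhz: float) -> list[tuple[float, float]]:
    """Binomial-weighted (center, weight) comb for a first-order multiplet."""
    k = line.multiplicity
    if k == 1:
        return [(line.center_ppm, 1.0)]
    split = line.j_hz / mhz  # J in ppm
    total = 2.0 ** (k - 1)
    comb_lines = []
    for i in range(k):
        offset = (i - (k - 1) / 2.0) * split
        comb_lines.append((line.center_ppm + offset, comb(k - 1, i) / total))
    return comb_lines


def render_amounts(
    amounts_nmol: dict[str, float],
    signatures: dict[str, MetaboliteSignature] | None = None,
    grid: GridSpec | None = None,
    noise_sd: float = 0.0,
    linewidth_hz: float = 1.5,
    rng: np.random.Generator | None = None,
    spectrometer_mhz: float = DEFAULT_SPECTROMETER_MHZ,
) -> tuple[np.ndarray, np.ndarray]:
    """Render absolute amounts (nmol) into (ppm ascending, intensity) arrays.

    Each spectral line is an area-normalized Lorentzian scaled by
    ``amount * relative_area * binomial_weight``; the spectrum therefore
    integrates (up to grid truncation) to total nmol of rendered protons.
    """
    signatures = DEFAULT_SIGNATURES if signatures is None else signatures
    grid = GridSpec() if grid is None else grid
    if not linewidth_hz > 0:
        raise ValueError("linewidth_hz must be > 0")
    x = grid.build()
    y = np.zeros_like(x)
    fwhm_ppm = linewidth_hz / spectrometer_mhz
    for name in sorted(amounts_nmol):
        amount = amounts_nmol[name]
        if amount == 0:
            continue
        if amount < 0:
            raise ValueError(f"negative amount for {name}")
        sig = signatures[name]
        for line in sig.lines:
            for center, weight in _multiplet_comb(line, spectrometer_mhz):
                y += _lorentzian(x, center, amount * line.relative_area * weight, fwhm_ppm)
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if noise_sd > 0:
        if rng is None:
            rng = np.random.default_rng()
        y = y + rng.normal(0.0, noise_sd, size=y.size)
    return x, y


def render_spectrum(
    truth: GroundTruth,
    signatures: dict[str, MetaboliteSignature] | None = None,
    grid: GridSpec | None = None,
    noise_sd: float = 0.0,
    linewidth_hz: float = 1.5,
    seed: int | np.random.Generator | None = None,
    spectrometer_mhz: float = DEFAULT_SPECTROMETER_MHZ,
) -> Spectrum1D:
    """Render a tissue spectrum from true concentrations (nmol/mg)."""
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    amounts = {
        name: conc * truth.weight_mg for name, conc in truth.concentrations.items()
    }
    x, y = render_amounts(
        amounts,
        signatures=signatures,
        grid=grid,
        noise_sd=noise_sd,
        linewidth_hz=linewidth_hz,
        rng=rng,
        spectrometer_mhz=spectrometer_mhz,
    )
    return Spectrum1D(
        sample_id=truth.sample_id,
        ppm=x,
        intensity=y,
        weight_mg=truth.weight_mg,
        group_label=truth.group,
        spectrometer_mhz=spectrometer_mhz,
    )


def make_reference_standard(
    amount_nmol: float = 19.3,
    grid: GridSpec | None = None,
    noise_sd: float = 0.0,
    linewidth_hz: float = 1.5,
    seed: int | np.random.Generator | None = None,
    spectrometer_mhz: float = DEFAULT_SPECTROMETER_MHZ,
) -> CalibrationStandard:
    """Render the lactate calibration standard scanned under matched conditions."""
    if amount_nmol < 0:
        raise ValueError("amount_nmol must be >= 0")
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    amounts = {"lactate": float(amount_nmol)} if amount_nmol > 0 else {}
    x, y = render_amounts(
        amounts,
        grid=grid,
        noise_sd=noise_sd,
        linewidth_hz=linewidth_hz,
        rng=rng,
        spectrometer_mhz=spectrometer_mhz,
    )
    spectrum = Spectrum1D(
        sample_id="lactate_reference",
        ppm=x,
        intensity=y,
        weight_mg=None,
        group_label="reference",
        spectrometer_mhz=spectrometer_mhz,
    )
    return CalibrationStandard(
        spectrum=spectrum,
        amount_nmol=float(amount_nmol),
        reference_region=LACTATE_REFERENCE_REGION,
    )


# ---------------------------------------------------------------------------
# cohort specification


@dataclasses.dataclass(frozen=True)
class ConcDist:
    """Median / min / max of one metabolite's concentration in one group."""

    median: float
    minimum: float
    maximum: float

    def __post_init__(self) -> None:
        if not self.minimum <= self.median <= self.maximum:
            raise ValueError(
                f"median {self.median} outside [{self.minimum}, {self.maximum}]"
            )


@dataclasses.dataclass(frozen=True)
class EpinephrineSpec:
    """Bernoulli presence plus concentration law when present."""

    prevalence: float = 0.0
    dist: ConcDist | None = None

    def __post_init__(self) -> None:
        if not 0.0 <= self.prevalence <= 1.0:
            raise ValueError("prevalence must lie in [0, 1]")
        if self.prevalence > 0 and self.dist is None:
            raise ValueError("a nonzero prevalence needs a concentration law")


@dataclasses.dataclass(frozen=True)
class GroupSpec:
    n: int
    metabolites: dict[str, ConcDist]
    epinephrine: EpinephrineSpec = EpinephrineSpec()
    dopamine: ConcDist | None = None  # absent by default

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ValueError("group size must be >= 0")


@dataclasses.dataclass(frozen=True)
class CohortSpec:
    """Everything needed to simulate a cohort reproducibly."""

    groups: dict[str, GroupSpec]
    noise_sd: float = 0.5
    linewidth_hz: float = 1.5
    grid: GridSpec = dataclasses.field(default_factory=GridSpec)
    weight_min_mg: float = 15.0
    weight_max_mg: float = 20.0
    reference_amount_nmol: float = 19.3
    spectrometer_mhz: float = DEFAULT_SPECTROMETER_MHZ
    seed: int = 0

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if not self.linewidth_hz > 0:
            raise ValueError("linewidth_hz must be > 0")
        if not 0 < self.weight_min_mg <= self.weight_max_mg:
            raise ValueError("invalid tissue weight bounds")
        if sum(g.n for g in self.groups.values()) < 1:
            raise ValueError("cohort must contain at least one sample")

    @classmethod
    def from_dict(cls, data: dict) -> "CohortSpec":
        groups = {}
        for name, g in data["groups"].items():
            mets = {
                met: ConcDist(v["median"], v["min"], v["max"])
                for met, v in g.get("metabolites", {}).items()
            }
            epi_cfg = g.get("epinephrine", {})
            prevalence = float(epi_cfg.get("prevalence", 0.0))
            dist = None
            if prevalence > 0:
                dist = ConcDist(epi_cfg["median"], epi_cfg["min"], epi_cfg["max"])
            groups[name] = GroupSpec(
                n=int(g["n"]), metabolites=mets, epinephrine=EpinephrineSpec(prevalence, dist)
            )
        grid_cfg = data.get("grid", {})
        grid = GridSpec(
            ppm_min=float(grid_cfg.get("ppm_min", 0.5)),
            ppm_max=float(grid_cfg.get("ppm_max", 9.0)),
            step=float(grid_cfg.get("step", 0.0005)),
        )
        weight_cfg = data.get("weight_mg", {})
        return cls(
            groups=groups,
            noise_sd=float(data.get("noise_sd", 0.5)),
            linewidth_hz=float(data.get("linewidth_hz", 1.5)),
            grid=grid,
            weight_min_mg=float(weight_cfg.get("min", 15.0)),
            weight_max_mg=float(weight_cfg.get("max", 20.0)),
            reference_amount_nmol=float(
                data.get("reference", {}).get("amount_nmol", 19.3)
            ),
            spectrometer_mhz=float(data.get("spectrometer_mhz", DEFAULT_SPECTROMETER_MHZ)),
            seed=int(data.get("seed", 0)),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "CohortSpec":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))

    @classmethod
    def default(cls, seed: int | None = None, **overrides) -> "CohortSpec":
        """The shipped defaults: 10 sporadic / 12 SDHx / 6 VHL cohort."""
        ref = resources.files("pgl_metabotyper").joinpath("data/default_cohort.yaml")
        spec = cls.from_dict(yaml.safe_load(ref.read_text()))
        changes = dict(overrides)
        if seed is not None:
            changes["seed"] = int(seed)
        return dataclasses.replace(spec, **changes) if changes else spec


def simulate_cohort(
    spec: CohortSpec, seed: int | None = None
) -> tuple[list[Spectrum1D], list[GroundTruth], CalibrationStandard]:
    """Simulate one spectrum per sample plus the calibration standard.

    Fully deterministic given ``(spec, seed)``; ``seed`` overrides
    ``spec.seed`` when given.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    truths: list[GroundTruth] = []
    for group in sorted(spec.groups):
        gspec = spec.groups[group]
        for i in range(gspec.n):
            weight = float(rng.uniform(spec.weight_min_mg, spec.weight_max_mg))
            concs: dict[str, float] = {}
            for met in sorted(gspec.metabolites):
                dist = gspec.metabolites[met]
                concs[met] = float(
                    draw_concentration(dist.median, dist.minimum, dist.maximum, rng)
                )
            epi = gspec.epinephrine
            present = epi.prevalence > 0 and rng.random() < epi.prevalence
            if present:
                d = epi.dist
                concs["epinephrine"] = float(
                    draw_concentration(d.median, d.minimum, d.maximum, rng)
                )
            else:
                concs["epinephrine"] = 0.0
            if gspec.dopamine is not None:
                d = gspec.dopamine
                concs["dopamine"] = float(
                    draw_concentration(d.median, d.minimum, d.maximum, rng)
                )
            truths.append(
                GroundTruth(
                    sample_id=f"{group}_{i + 1:02d}",
                    group=group,
                    weight_mg=weight,
                    concentrations=concs,
                )
            )
    spectra = [
        render_spectrum(
            truth,
            grid=spec.grid,
            noise_sd=spec.noise_sd,
            linewidth_hz=spec.linewidth_hz,
            seed=rng,
            spectrometer_mhz=spec.spectrometer_mhz,
        )
        for truth in truths
    ]
    standard = make_reference_standard(
        amount_nmol=spec.reference_amount_nmol,
        grid=spec.grid,
        noise_sd=spec.noise_sd,
        linewidth_hz=spec.linewidth_hz,
        seed=rng,
        spectrometer_mhz=spec.spectrometer_mhz,
    )
    return spectra, truths, standard
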