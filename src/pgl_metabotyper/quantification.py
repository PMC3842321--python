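"""Absolute metabolite quantification by spectral region integration.

Concentrations are obtained PULCON-style: each window's trapezoidal integral
is divided by the contributing proton count, by a calibration factor derived
from a lactate standard of known amount, and by the sample weight, yielding
nmol/mg.  Norepinephrine is obtained by subtracting epinephrine (N-methyl
window) from the epinephrine+norepinephrine total (aromatic H5 window);
dopamine is only screened for via its triplet positions.

Normalization of the chemometric feature matrix to the total spectral
integral (1-8.65 ppm) is exposed as an optional scaling mode; the
concentration path itself is the absolute calibrated one, since only that
can yield nmol/mg.
"""

from __future__ import annotations

import dataclasses
import warnings
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from pgl_metabotyper.spectra import (
    CalibrationStandard,
    RegionDef,
    RegionCoverageError,
    Spectrum1D,
    SpectrumError,
    slice_region,
)

#: fixed column order of the chemometric feature matrix
PANEL_FEATURES = ("succinate", "glutathione", "glutamate", "atp_adp_amp")


class CalibrationError(ValueError):
    """The reference integral is non-positive."""


@dataclasses.dataclass(frozen=True)
class MetabolitePanel:
    """The fixed quantitation windows plus ancillary regions.

    ``regions`` holds one window per quantified species; the aromatic H5
    window measures epinephrine + norepinephrine jointly.  ``noise_regions``
    are candidate signal-free windows used for the detection limit, tried in
    order.
    """

    regions: dict[str, RegionDef]
    aromatic_region: RegionDef
    dopamine_check_ppm: tuple[float, float] = (2.85, 3.22)
    dopamine_check_halfwidth: float = 0.02
    total_integral_region: RegionDef = RegionDef("total", 1.0, 8.65, 1)
    noise_regions: tuple[tuple[float, float], ...] = ((9.5, 10.0), (0.5, 0.7))

    @classmethod
    def default(cls) -> "MetabolitePanel":
        return cls(
            regions={
                "succinate": RegionDef("succinate", 2.39, 2.43, 4),
                "glutathione": RegionDef("glutathione", 2.93, 2.98, 2),
                "glutamate": RegionDef("glutamate", 2.32, 2.38, 2),
                "atp_adp_amp": RegionDef("atp_adp_amp", 6.07, 6.11, 1),
                "epinephrine": RegionDef("epinephrine_nch3", 2.73, 2.77, 3),
            },
            aromatic_region=RegionDef("catechol_aromatic_h5", 6.89, 6.93, 1),
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "MetabolitePanel":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        base = cls.default()
        regions = dict(base.regions)
        for name, cfg in data.get("regions", {}).items():
            regions[name] = RegionDef(
                cfg.get("name", name),
                float(cfg["ppm_low"]),
                float(cfg["ppm_high"]),
                int(cfg["n_protons"]),
            )
        aromatic = base.aromatic_region
        if "aromatic_region" in data:
            cfg = data["aromatic_region"]
            aromatic = RegionDef(
                cfg.get("name", "catechol_aromatic_h5"),
                float(cfg["ppm_low"]),
                float(cfg["ppm_high"]),
                int(cfg["n_protons"]),
            )
        return cls(regions=regions, aromatic_region=aromatic)


@dataclasses.dataclass(frozen=True)
class CalibrationFactor:
    """Integrated area per proton per nmol, from the external standard."""

    area_per_proton_per_nmol: float

    def __post_init__(self) -> None:
        if not self.area_per_proton_per_nmol > 0:
            raise CalibrationError("calibration factor must be > 0")


def integrate(s: Spectrum1D, r: RegionDef, baseline: str = "none") -> float:
    """Trapezoidal integral of intensity over the closed window of ``r``.

    With ``baseline='linear'`` the chord joining the window's endpoint
    intensities is subtracted first.
    """
    ppm, intensity = slice_region(s, r)
    # slice preserves storage order (descending); integrate on ascending axis
    x = ppm[::-1]
    y = intensity[::-1]
    if baseline == "linear":
        chord = y[0] + (y[-1] - y[0]) * (x - x[0]) / (x[-1] - x[0])
        y = y - chord
    elif baseline != "none":
        raise ValueError(f"unknown baseline mode {baseline!r}")
    return float(np.trapezoid(y, x))


def calibrate(standard: CalibrationStandard, baseline: str = "none") -> CalibrationFactor:
    """Derive the area-per-proton-per-nmol factor from the lactate standard."""
    area = integrate(standard.spectrum, standard.reference_region, baseline=baseline)
    if not area > 0:
        raise CalibrationError(f"non-positive reference integral: {area}")
    if not standard.amount_nmol > 0:
        raise CalibrationError("standard amount must be > 0 to calibrate")
    factor = area / (standard.reference_region.n_protons * standard.amount_nmol)
    return CalibrationFactor(factor)


def estimate_noise_sd(s: Spectrum1D, panel: MetabolitePanel | None = None) -> float:
    """Per-point noise SD from a signal-free window, with a MAD fallback.

    Tries the configured noise windows in order; if none is covered by the
    spectrum, falls back to the median absolute deviation of the flattest
    decile of short spectrum blocks.
    """
    panel = MetabolitePanel.default() if panel is None else panel
    for lo, hi in panel.noise_regions:
        region = RegionDef("noise", lo, hi, 1)
        try:
            _, intensity = slice_region(s, region)
        except RegionCoverageError:
            continue
        if intensity.size >= 16:
            return float(np.std(intensity - np.median(intensity)))
    # fallback: MAD of the flattest decile of 64-point blocks
    n_block = 64
    n = s.intensity.size // n_block
    if n < 2:
        return float(1.4826 * np.median(np.abs(s.intensity - np.median(s.intensity))))
    blocks = s.intensity[: n * n_block].reshape(n, n_block)
    mads = 1.4826 * np.median(np.abs(blocks - np.median(blocks, axis=1, keepdims=True)), axis=1)
    decile = max(1, n // 10)
    return float(np.median(np.sort(mads)[:decile]))


def detect_limit(
    s: Spectrum1D,
    r: RegionDef,
    panel: MetabolitePanel | None = None,
    baseline: str = "none",
    k: float = 3.0,
) -> bool:
    """True iff the background-corrected window area exceeds ``k`` sigma.

    The local background (e.g. the tail of a large resonance nearby) is
    estimated as the mean of the median intensities in two flanking bands,
    half a window wide each, and subtracted as ``background x width``.  The
    detection SD combines the trapezoidal noise-integral SD
    (``noise_sd * dx * sqrt(n)``) with the background-estimate variance.
    """
    noise_sd = estimate_noise_sd(s, panel)
    ppm, _ = slice_region(s, r)
    n = ppm.size
    width = r.width
    dx = abs(ppm[0] - ppm[-1]) / (n - 1)
    area = integrate(s, r, baseline=baseline)
    sigma_area = noise_sd * dx * np.sqrt(max(n - 1.5, 0.5))
    sigma_bg = 0.0
    flank = width / 2.0
    left = (s.ppm >= r.ppm_low - flank) & (s.ppm < r.ppm_low)
    right = (s.ppm > r.ppm_high) & (s.ppm <= r.ppm_high + flank)
    if left.sum() >= 5 and right.sum() >= 5:
        background = 0.5 * (
            float(np.median(s.intensity[left])) + float(np.median(s.intensity[right]))
        )
        area -= background * width
        # var of a median of n noisy points is ~ (pi/2) sigma^2 / n
        sigma_bg = (
            width
            * noise_sd
            * 0.5
            * np.sqrt(np.pi / 2.0 * (1.0 / left.sum() + 1.0 / right.sum()))
        )
    return bool(area > k * np.hypot(sigma_area, sigma_bg))


def quantify_amount(
    s: Spectrum1D, r: RegionDef, f: CalibrationFactor, baseline: str = "none"
) -> float:
    """Absolute amount (nmol) in the window, without weight normalization."""
    return integrate(s, r, baseline=baseline) / (r.n_protons * f.area_per_proton_per_nmol)


def quantify_metabolite(
    s: Spectrum1D,
    r: RegionDef,
    f: CalibrationFactor,
    panel: MetabolitePanel | None = None,
    baseline: str = "none",
) -> tuple[float, bool]:
    """Concentration in nmol/mg plus a below-detection flag.

    Below-detection windows are reported as ``(0.0, True)``.
    """
    if s.weight_mg is None:
        raise SpectrumError(f"spectrum {s.sample_id!r} lacks weight_mg")
    if not detect_limit(s, r, panel=panel, baseline=baseline):
        return 0.0, True
    conc = quantify_amount(s, r, f, baseline=baseline) / s.weight_mg
    return max(conc, 0.0), False


def quantify_catecholamines(
    s: Spectrum1D,
    panel: MetabolitePanel,
    f: CalibrationFactor,
    baseline: str = "none",
) -> tuple[float, bool, float, bool, bool]:
    """Quantify epinephrine and norepinephrine; screen for dopamine.

    Returns ``(epinephrine, epi_below, norepinephrine, ne_below, dopamine_flag)``.
    Norepinephrine is the aromatic-window total minus epinephrine, clipped
    at zero; the dopamine flag requires detectable signal at both triplet
    positions (2.85 and 3.22 ppm by default).
    """
    epi, epi_below = quantify_metabolite(
        s, panel.regions["epinephrine"], f, panel=panel, baseline=baseline
    )
    total, total_below = quantify_metabolite(
        s, panel.aromatic_region, f, panel=panel, baseline=baseline
    )
    norepi = total - epi
    if norepi < 0:
        warnings.warn(
            f"{s.sample_id}: epinephrine exceeds the aromatic total "
            f"({epi:.3g} > {total:.3g}); norepinephrine clipped to 0",
            stacklevel=2,
        )
        norepi = 0.0
    hw = panel.dopamine_check_halfwidth
    dopamine_flag = all(
        detect_limit(
            s, RegionDef(f"dopamine_{c}", c - hw, c + hw, 1), panel=panel, baseline=baseline
        )
        for c in panel.dopamine_check_ppm
    )
    return epi, epi_below, norepi, total_below, dopamine_flag


@dataclasses.dataclass
class QuantResult:
    """Per-cohort quantification output."""

    table: pd.DataFrame  # one row per sample, all six species + flags
    feature_matrix: "FeatureMatrix"
    failures: list[tuple[str, str]]  # (sample_id, error message)


@dataclasses.dataclass
class FeatureMatrix:
    """Samples x features concentration matrix for the chemometric layer."""

    X: np.ndarray
    feature_names: list[str]
    sample_ids: list[str]
    y: np.ndarray  # class labels, dtype object/str

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.y = np.asarray(self.y)
        if self.X.ndim != 2:
            raise ValueError("X must be 2-D")
        if self.X.shape[0] != len(self.sample_ids) or self.X.shape[0] != self.y.size:
            raise ValueError("inconsistent sample dimension")
        if self.X.shape[1] != len(self.feature_names):
            raise ValueError("inconsistent feature dimension")
        if np.isnan(self.X).any():
            raise ValueError("feature matrix contains missing values")

    def subset_classes(self, classes: list[str]) -> "FeatureMatrix":
        mask = np.isin(self.y, classes)
        return FeatureMatrix(
            X=self.X[mask],
            feature_names=list(self.feature_names),
            sample_ids=[sid for sid, m in zip(self.sample_ids, mask) if m],
            y=self.y[mask],
        )


def quantify_cohort(
    spectra: list[Spectrum1D],
    standard: CalibrationStandard,
    panel: MetabolitePanel | None = None,
    baseline: str = "none",
    feature_scaling: str = "absolute",
) -> QuantResult:
    """Quantify a cohort and assemble the 4-metabolite feature matrix.

    ``feature_scaling='total_integral'`` divides each sample's feature row by
    its total spectral integral over 1-8.65 ppm (alternative chemometric
    scaling; concentrations in the table stay absolute).
    Per-sample failures are collected and reported, not raised.
    """
    panel = MetabolitePanel.default() if panel is None else panel
    f = calibrate(standard, baseline=baseline)
    rows = []
    failures: list[tuple[str, str]] = []
    for s in spectra:
        try:
            row: dict[str, object] = {
                "sample_id": s.sample_id,
                "group": s.group_label,
                "weight_mg": s.weight_mg,
            }
            flags = []
            for met in PANEL_FEATURES:
                conc, below = quantify_metabolite(
                    s, panel.regions[met], f, panel=panel, baseline=baseline
                )
                row[met] = conc
                if below:
                    flags.append(met)
            epi, epi_below, norepi, ne_below, dopa = quantify_catecholamines(
                s, panel, f, baseline=baseline
            )
            row["epinephrine"] = epi
            row["norepinephrine"] = norepi
            row["dopamine_flag"] = dopa
            if epi_below:
                flags.append("epinephrine")
            if ne_below:
                flags.append("norepinephrine")
            row["flags"] = ";".join(flags)
            if feature_scaling == "total_integral":
                row["_total_integral"] = integrate(
                    s, panel.total_integral_region, baseline=baseline
                )
            rows.append(row)
        except (SpectrumError, ValueError) as exc:
            failures.append((s.sample_id, str(exc)))
    columns = [
        "sample_id",
        "group",
        "weight_mg",
        *PANEL_FEATURES,
        "epinephrine",
        "norepinephrine",
        "dopamine_flag",
        "flags",
    ]
    if not rows:
        table = pd.DataFrame(columns=columns)
        fm = FeatureMatrix(
            X=np.empty((0, len(PANEL_FEATURES))),
            feature_names=list(PANEL_FEATURES),
            sample_ids=[],
            y=np.array([], dtype=object),
        )
        return QuantResult(table=table, feature_matrix=fm, failures=failures)
    table = pd.DataFrame(rows)
    X = table[list(PANEL_FEATURES)].to_numpy(dtype=float)
    if feature_scaling == "total_integral":
        totals = table.pop("_total_integral").to_numpy(dtype=float)
        X = X / totals[:, None]
    elif feature_scaling != "absolute":
        raise ValueError(f"unknown feature_scaling {feature_scaling!r}")
    fm = FeatureMatrix(
        X=X,
        feature_names=list(PANEL_FEATURES),
        sample_ids=table["sample_id"].tolist(),
        y=table["group"].to_numpy(),
    )
    return QuantResult(table=table[columns], feature_matrix=fm, failures=failures)
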