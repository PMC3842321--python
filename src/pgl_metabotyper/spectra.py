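"""Domain types and file I/O for processed 1D proton NMR spectra.

A :class:`Spectrum1D` is a frequency-domain, phased, baseline-corrected
spectrum given as a ppm axis plus intensities, with the tissue weight and
group label needed downstream.  Two plain-text dialects are supported:

* a TSV dialect with ``#key=value`` metadata headers (the canonical fixture
  format of this repository), and
* a minimal, uncompressed JCAMP-DX reader/writer restricted to the
  ``##XYDATA=(X++(Y..Y))`` form.

Spectra are stored with the ppm axis descending (NMR display convention);
constructors and readers normalize ascending input.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np

#: group labels that denote tissue samples (as opposed to standard solutions)
TISSUE_GROUPS = ("SDHx", "VHL", "sporadic")

#: default proton frequency of the acquiring spectrometer, MHz
DEFAULT_SPECTROMETER_MHZ = 500.13


class SpectrumError(ValueError):
    """Invalid spectrum or region data."""


class SpectrumParseError(SpectrumError):
    """A spectrum file could not be parsed; the message names the line."""


class RegionCoverageError(SpectrumError):
    """An integration window falls outside the spectrum's ppm range."""


@dataclasses.dataclass
class Spectrum1D:
    """A processed 1D spectrum.

    Parameters
    ----------
    sample_id : str
        Identifier of the sample.
    ppm : array_like
        Chemical shift axis; must be strictly monotone with >= 2 points.
        Stored descending regardless of input order.
    intensity : array_like
        Real intensities, same length as ``ppm`` (arbitrary units).
    weight_mg : float, optional
        Tissue mass in mg; absent for standard solutions.
    group_label : str, optional
        One of ``sporadic | SDHx | VHL | reference``.
    spectrometer_mhz : float
        Proton frequency in MHz (default 500.13).
    """

    sample_id: str
    ppm: np.ndarray
    intensity: np.ndarray
    weight_mg: float | None = None
    group_label: str | None = None
    spectrometer_mhz: float = DEFAULT_SPECTROMETER_MHZ

    def __post_init__(self) -> None:
        ppm = np.asarray(self.ppm, dtype=float)
        intensity = np.asarray(self.intensity, dtype=float)
        if ppm.ndim != 1 or intensity.ndim != 1:
            raise SpectrumError("ppm and intensity must be 1-D arrays")
        if ppm.size != intensity.size:
            raise SpectrumError(
                f"ppm and intensity length mismatch: {ppm.size} vs {intensity.size}"
            )
        if ppm.size < 2:
            raise SpectrumError("a spectrum needs at least 2 points")
        steps = np.diff(ppm)
        if np.all(steps > 0):  # ascending input -> normalize to descending
            ppm = ppm[::-1].copy()
            intensity = intensity[::-1].copy()
        elif not np.all(steps < 0):
            raise SpectrumError("ppm axis must be strictly monotone")
        self.ppm = ppm
        self.intensity = intensity
        if self.weight_mg is not None:
            self.weight_mg = float(self.weight_mg)
            if not self.weight_mg > 0:
                raise SpectrumError(f"weight_mg must be > 0, got {self.weight_mg}")
        self.spectrometer_mhz = float(self.spectrometer_mhz)
        if not self.spectrometer_mhz > 0:
            raise SpectrumError("spectrometer_mhz must be > 0")

    @property
    def ppm_min(self) -> float:
        return float(self.ppm[-1])

    @property
    def ppm_max(self) -> float:
        return float(self.ppm[0])

    def equals(self, other: "Spectrum1D", rtol: float = 0.0, atol: float = 0.0) -> bool:
        """Field-for-field equality, exact by default."""
        return (
            self.sample_id == other.sample_id
            and self.group_label == other.group_label
            and self.weight_mg == other.weight_mg
            and self.spectrometer_mhz == other.spectrometer_mhz
            and self.ppm.size == other.ppm.size
            and np.allclose(self.ppm, other.ppm, rtol=rtol, atol=atol)
            and np.allclose(self.intensity, other.intensity, rtol=rtol, atol=atol)
        )


@dataclasses.dataclass(frozen=True)
class RegionDef:
    """A named ppm integration window with its contributing proton count."""

    name: str
    ppm_low: float
    ppm_high: float
    n_protons: int

    def __post_init__(self) -> None:
        if not self.ppm_low < self.ppm_high:
            raise SpectrumError(
                f"region {self.name!r}: ppm_low must be < ppm_high "
                f"({self.ppm_low} >= {self.ppm_high})"
            )
        if int(self.n_protons) != self.n_protons or self.n_protons < 1:
            raise SpectrumError(f"region {self.name!r}: n_protons must be a positive integer")

    @property
    def width(self) -> float:
        return self.ppm_high - self.ppm_low

    @property
    def center(self) -> float:
        return 0.5 * (self.ppm_low + self.ppm_high)


#: reference window around the lactate methyl doublet used for calibration
LACTATE_REFERENCE_REGION = RegionDef("lactate_ch3", 1.31, 1.35, 3)


@dataclasses.dataclass
class CalibrationStandard:
    """A lactate standard of known amount scanned under matched conditions."""

    spectrum: Spectrum1D
    amount_nmol: float = 19.3
    reference_region: RegionDef = LACTATE_REFERENCE_REGION

    def __post_init__(self) -> None:
        # zero is tolerated so a blank standard can be represented; calibrate()
        # rejects it when the factor is actually computed
        if self.amount_nmol < 0:
            raise SpectrumError("amount_nmol must be >= 0")
        r = self.reference_region
        if r.ppm_low < self.spectrum.ppm_min or r.ppm_high > self.spectrum.ppm_max:
            raise SpectrumError(
                f"reference region [{r.ppm_low}, {r.ppm_high}] outside the "
                f"standard's range [{self.spectrum.ppm_min}, {self.spectrum.ppm_max}]"
            )


def slice_region(s: Spectrum1D, r: RegionDef) -> tuple[np.ndarray, np.ndarray]:
    """Return the (ppm, intensity) points inside the closed window of ``r``.

    Raises
    ------
    RegionCoverageError
        If fewer than 2 spectrum points fall inside the window.
    """
    mask = (s.ppm >= r.ppm_low) & (s.ppm <= r.ppm_high)
    if int(mask.sum()) < 2:
        raise RegionCoverageError(
            f"region {r.name!r} [{r.ppm_low}, {r.ppm_high}] covers "
            f"{int(mask.sum())} point(s) of spectrum {s.sample_id!r} "
            f"(range [{s.ppm_min}, {s.ppm_max}])"
        )
    return s.ppm[mask], s.intensity[mask]


# ---------------------------------------------------------------------------
# file I/O


def _infer_format(path: Path) -> str:
    suffix = path.suffix.lower()
    if suffix in (".tsv", ".txt"):
        return "tsv"
    if suffix in (".jdx", ".dx", ".jcamp"):
        return "jcamp"
    raise SpectrumError(f"cannot infer format from suffix {suffix!r}; pass format=")


def read_spectrum(path: str | Path, format: str | None = None) -> Spectrum1D:
    """Read a spectrum from ``path`` in the ``tsv`` or ``jcamp`` dialect."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "tsv":
        return _read_tsv(path)
    if fmt == "jcamp":
        return _read_jcamp(path)
    raise SpectrumError(f"unknown format {fmt!r}")


def write_spectrum(s: Spectrum1D, path: str | Path, format: str | None = None) -> None:
    """Write ``s`` so that :func:`read_spectrum` round-trips it losslessly."""
    path = Path(path)
    fmt = format or _infer_format(path)
    if fmt == "tsv":
        _write_tsv(s, path)
    elif fmt == "jcamp":
        _write_jcamp(s, path)
    else:
        raise SpectrumError(f"unknown format {fmt!r}")


def _require_weight(meta_weight: float | None, group: str | None, where: str) -> None:
    if meta_weight is None and group in TISSUE_GROUPS:
        raise SpectrumError(f"{where}: tissue spectrum (group {group!r}) lacks weight_mg")


def _read_tsv(path: Path) -> Spectrum1D:
    meta: dict[str, str] = {}
    ppm: list[float] = []
    intensity: list[float] = []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line.lstrip("#").strip()
                if "=" not in body:
                    raise SpectrumParseError(f"{path}, line {lineno}: malformed header {line!r}")
                key, _, value = body.partition("=")
                meta[key.strip()] = value.strip()
                continue
            fields = line.split("\t")
            if len(fields) == 1:  # tolerate space-separated data rows
                fields = line.split()
            if len(fields) != 2:
                raise SpectrumParseError(
                    f"{path}, line {lineno}: expected 2 columns, got {len(fields)}"
                )
            try:
                ppm.append(float(fields[0]))
                intensity.append(float(fields[1]))
            except ValueError as exc:
                raise SpectrumParseError(f"{path}, line {lineno}: {exc}") from None
    if "sample_id" not in meta:
        raise SpectrumParseError(f"{path}: missing #sample_id= header")
    weight = float(meta["weight_mg"]) if "weight_mg" in meta else None
    group = meta.get("group") or None
    _require_weight(weight, group, str(path))
    return Spectrum1D(
        sample_id=meta["sample_id"],
        ppm=np.array(ppm),
        intensity=np.array(intensity),
        weight_mg=weight,
        group_label=group,
        spectrometer_mhz=float(meta.get("spectrometer_mhz", DEFAULT_SPECTROMETER_MHZ)),
    )


def _write_tsv(s: Spectrum1D, path: Path) -> None:
    lines = [f"#sample_id={s.sample_id}"]
    if s.weight_mg is not None:
        lines.append(f"#weight_mg={s.weight_mg!r}")
    if s.group_label is not None:
        lines.append(f"#group={s.group_label}")
    lines.append(f"#spectrometer_mhz={s.spectrometer_mhz!r}")
    for x, y in zip(s.ppm, s.intensity):
        lines.append(f"{x:.17g}\t{y:.17g}")
    path.write_text("\n".join(lines) + "\n")


def _read_jcamp(path: Path) -> Spectrum1D:
    """Minimal JCAMP-DX reader: uncompressed ``##XYDATA=(X++(Y..Y))`` only."""
    labels: dict[str, str] = {}
    xs: list[float] = []
    ys: list[float] = []
    in_data = False
    firstx = lastx = None
    npoints = None
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("$$"):
                continue
            if line.startswith("##"):
                key, _, value = line[2:].partition("=")
                key = key.strip().upper()
                value = value.strip()
                if key == "END":
                    break
                if key == "XYDATA":
                    if "(X++(Y..Y))" not in value.replace(" ", ""):
                        raise SpectrumParseError(
                            f"{path}, line {lineno}: unsupported XYDATA form {value!r}"
                        )
                    firstx = float(labels.get("FIRSTX", "nan"))
                    lastx = float(labels.get("LASTX", "nan"))
                    npoints = int(float(labels.get("NPOINTS", "0")))
                    in_data = True
                    continue
                labels[key] = value
                continue
            if not in_data:
                continue
            try:
                fields = [float(tok) for tok in line.replace(",", " ").split()]
            except ValueError as exc:
                raise SpectrumParseError(f"{path}, line {lineno}: {exc}") from None
            if len(fields) < 2:
                raise SpectrumParseError(f"{path}, line {lineno}: expected X then Y value(s)")
            x0, yvals = fields[0], fields[1:]
            if len(yvals) == 1:
                xs.append(x0)
                ys.append(yvals[0])
            else:
                # multiple Ys per line: X positions implied by the global grid
                if npoints is None or npoints < 2 or not np.isfinite([firstx, lastx]).all():
                    raise SpectrumParseError(
                        f"{path}, line {lineno}: multi-Y lines need FIRSTX/LASTX/NPOINTS"
                    )
                dx = (lastx - firstx) / (npoints - 1)
                for i, y in enumerate(yvals):
                    xs.append(x0 + i * dx)
                    ys.append(y)
    if not xs:
        raise SpectrumParseError(f"{path}: no XYDATA block found")
    if labels.get("XUNITS", "PPM").upper() != "PPM":
        raise SpectrumParseError(f"{path}: XUNITS must be PPM, got {labels.get('XUNITS')!r}")
    weight = float(labels["$WEIGHT_MG"]) if "$WEIGHT_MG" in labels else None
    group = labels.get("$GROUP") or None
    _require_weight(weight, group, str(path))
    return Spectrum1D(
        sample_id=labels.get("TITLE", path.stem),
        ppm=np.array(xs),
        intensity=np.array(ys),
        weight_mg=weight,
        group_label=group,
        spectrometer_mhz=float(labels.get("$SPECTROMETER_MHZ", DEFAULT_SPECTROMETER_MHZ)),
    )


def _write_jcamp(s: Spectrum1D, path: Path) -> None:
    lines = [
        f"##TITLE={s.sample_id}",
        "##JCAMP-DX=4.24",
        "##DATA TYPE=NMR SPECTRUM",
        "##XUNITS=PPM",
        "##YUNITS=ARBITRARY UNITS",
    ]
    if s.weight_mg is not None:
        lines.append(f"##$WEIGHT_MG={s.weight_mg!r}")
    if s.group_label is not None:
        lines.append(f"##$GROUP={s.group_label}")
    lines.append(f"##$SPECTROMETER_MHZ={s.spectrometer_mhz!r}")
    lines.append(f"##NPOINTS={s.ppm.size}")
    lines.append(f"##FIRSTX={s.ppm[0]:.17g}")
    lines.append(f"##LASTX={s.ppm[-1]:.17g}")
    lines.append("##XYDATA=(X++(Y..Y))")
    # one (X, Y) pair per line keeps the round trip exact on any grid
    for x, y in zip(s.ppm, s.intensity):
        lines.append(f"{x:.17g} {y:.17g}")
    lines.append("##END=")
    path.write_text("\n".join(lines) + "\n")
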