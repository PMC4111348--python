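"""Reading, validating and resampling Raman spectra, and loading paired
Raman/wet-chemistry tables.

Two spectrum dialects are supported: plain two-column wavenumber/intensity
text (whitespace or comma delimited, ``#`` comments) and a restricted
JCAMP-DX subset (uncompressed AFFN ``(X++(Y..Y))`` and ``(XY..XY)`` data
tables with XFACTOR/YFACTOR scaling).  Paired chemistry tables are delimited
text with a fixed header; the archaeological reference cohort (31 complete
records plus 10 partial ones) ships with the package as CSV fixtures.
"""

from __future__ import annotations

import io
import re
from dataclasses import dataclass, replace
from importlib import resources
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

__all__ = [
    "RamanSpectrum",
    "PairedDataset",
    "SpectrumParseError",
    "SpectrumValidationError",
    "SpectrumRangeError",
    "TableValidationError",
    "read_spectrum",
    "write_spectrum",
    "resample",
    "load_paired_table",
    "load_table1",
    "load_table2",
    "load_combined",
]

#: Wavenumber range (cm^-1) a spectrum must cover for ratio analysis: the
#: phosphate nu2 window starts at 300 and the C-H stretch window ends at 3060.
RATIO_RANGE = (300.0, 3060.0)

#: Valid archaeological phase labels in paired tables.
PHASES = ("Neolithic", "Bronze", "Iron")

#: Tokens treated as missing values in delimited chemistry tables.
MISSING_TOKENS = ("", "-", "NA", "NaN", "nan")

#: Duplicate wavenumbers closer than this (cm^-1) are merged by mean intensity.
DUPLICATE_TOL = 1e-9

TABLE_COLUMNS = [
    "sample_id",
    "burial_no",
    "phase",
    "pct_n",
    "pct_c",
    "cn_atomic",
    "pct_collagen",
    "raman_ratio",
]


class SpectrumParseError(ValueError):
    """A spectrum file could not be parsed under the requested dialect."""


class SpectrumValidationError(ValueError):
    """A parsed spectrum violates a structural invariant."""


class SpectrumRangeError(ValueError):
    """A requested wavenumber grid or window lies outside the spectrum."""


class TableValidationError(ValueError):
    """A paired chemistry table violates a structural invariant."""


@dataclass(frozen=True)
class RamanSpectrum:
    """One replicate Raman scan on a strictly increasing wavenumber grid.

    Parameters
    ----------
    sample_id
        Identifier of the bone sample the scan belongs to.
    replicate_index
        1-based replicate number (three replicate scans per sample are the
        usual acquisition protocol).
    wavenumbers
        Raman shift grid in cm^-1, strictly increasing.
    intensities
        Detector counts, same length as ``wavenumbers``.
    source
        Optional provenance string (file path or generator tag).
    """

    sample_id: str
    replicate_index: int
    wavenumbers: np.ndarray
    intensities: np.ndarray
    source: str = ""

    def __post_init__(self) -> None:
        w = np.asarray(self.wavenumbers, dtype=float)
        y = np.asarray(self.intensities, dtype=float)
        if w.ndim != 1 or y.ndim != 1 or w.size != y.size:
            raise SpectrumValidationError(
                "wavenumbers and intensities must be 1-D of equal length"
            )
        if w.size >= 2 and not np.all(np.diff(w) > 0):
            raise SpectrumValidationError("wavenumbers must be strictly increasing")
        if self.replicate_index < 1:
            raise SpectrumValidationError("replicate_index must be >= 1")
        object.__setattr__(self, "wavenumbers", w)
        object.__setattr__(self, "intensities", y)

    def __len__(self) -> int:
        return int(self.wavenumbers.size)

    @property
    def wavenumber_range(self) -> tuple[float, float]:
        return float(self.wavenumbers[0]), float(self.wavenumbers[-1])

    @property
    def covers_ratio_range(self) -> bool:
        """Whether the scan spans the windows needed for the organic-phosphate
        ratio (at least 300-3060 cm^-1).  Spectra that do not are unusable for
        ratio analysis and should be flagged by callers."""
        lo, hi = self.wavenumber_range
        return lo <= RATIO_RANGE[0] and hi >= RATIO_RANGE[1]

    def with_values(
        self, wavenumbers: np.ndarray, intensities: np.ndarray
    ) -> "RamanSpectrum":
        return replace(self, wavenumbers=wavenumbers, intensities=intensities)


@dataclass(frozen=True)
class PairedDataset:
    """Joined Raman-ratio and wet-chemistry records (the reference-table shape).

    ``records`` is a DataFrame with columns ``sample_id`` (unique),
    ``burial_no``, ``phase`` (Neolithic/Bronze/Iron), ``pct_n``, ``pct_c``,
    ``cn_atomic``, ``pct_collagen`` and ``raman_ratio``; missing measurements
    are NaN, never zero.
    """

    records: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.records
        missing = [c for c in TABLE_COLUMNS if c not in df.columns]
        if missing:
            raise TableValidationError(f"missing required columns: {missing}")
        if df["sample_id"].duplicated().any():
            dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
            raise TableValidationError(f"duplicate sample_id values: {dupes}")
        bad_phase = set(df["phase"].dropna()) - set(PHASES)
        if bad_phase:
            raise TableValidationError(f"unknown phase labels: {sorted(bad_phase)}")
        for col in ("pct_n", "pct_c", "pct_collagen", "raman_ratio"):
            vals = df[col].dropna()
            if (vals < 0).any():
                raise TableValidationError(f"negative values in column {col!r}")
        present = df["pct_collagen"].dropna()
        if (present <= 0).any():
            raise TableValidationError("pct_collagen must be > 0 when present")

    def __len__(self) -> int:
        return len(self.records)

    def complete_cases(self) -> pd.DataFrame:
        """Records with ratio, %N, %C and %collagen all present."""
        need = ["raman_ratio", "pct_n", "pct_c", "pct_collagen"]
        return self.records.dropna(subset=need).reset_index(drop=True)


# ---------------------------------------------------------------------------
# spectrum reading / writing
# ---------------------------------------------------------------------------

_FILENAME_RE = re.compile(r"(?P<sid>.+?)[_\-]rep(?P<rep>\d+)$")


def _metadata_from_path(path: Path) -> tuple[str, int]:
    m = _FILENAME_RE.match(path.stem)
    if m:
        return m.group("sid"), int(m.group("rep"))
    return path.stem, 1


def _sort_and_merge(w: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Sort ascending; merge wavenumbers within DUPLICATE_TOL by mean intensity."""
    order = np.argsort(w, kind="stable")
    w, y = w[order], y[order]
    if w.size < 2:
        return w, y
    keep_w: list[float] = []
    keep_y: list[float] = []
    i = 0
    while i < w.size:
        j = i + 1
        while j < w.size and w[j] - w[i] <= DUPLICATE_TOL:
            j += 1
        keep_w.append(float(np.mean(w[i:j])))
        keep_y.append(float(np.mean(y[i:j])))
        i = j
    return np.asarray(keep_w), np.asarray(keep_y)


def _parse_two_column(text: str, name: str) -> tuple[np.ndarray, np.ndarray, dict]:
    meta: dict[str, str] = {}
    xs: list[float] = []
    ys: list[float] = []
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.strip()
        if not line:
            continue
        if line.startswith("#"):
            m = re.match(r"#\s*(\w+)\s*[:=]\s*(.+)$", line)
            if m:
                meta[m.group(1).lower()] = m.group(2).strip()
            continue
        parts = re.split(r"[,\s]+", line)
        if len(parts) < 2:
            raise SpectrumParseError(f"{name}: line {lineno}: expected two columns")
        try:
            xs.append(float(parts[0]))
            ys.append(float(parts[1]))
        except ValueError as exc:
            raise SpectrumParseError(f"{name}: line {lineno}: {exc}") from None
    if not xs:
        raise SpectrumParseError(f"{name}: no data rows found")
    return np.asarray(xs), np.asarray(ys), meta


def _parse_jcamp(text: str, name: str) -> tuple[np.ndarray, np.ndarray, dict]:
    """Minimal JCAMP-DX: ##LDR headers, AFFN (X++(Y..Y)) or (XY..XY) tables."""
    ldrs: dict[str, str] = {}
    data_lines: list[tuple[str, int, str]] = []  # (table kind, lineno, text)
    mode = None  # None | "xydata" | "xypoints"
    for lineno, raw in enumerate(text.splitlines(), start=1):
        line = raw.split("$$")[0].rstrip()  # strip JCAMP comments
        if not line.strip():
            continue
        if line.startswith("##"):
            key, _, value = line[2:].partition("=")
            key = key.strip().upper().replace(" ", "")
            value = value.strip()
            if key == "XYDATA":
                mode = "xydata"
            elif key == "XYPOINTS":
                mode = "xypoints"
            elif key == "END":
                mode = None
            else:
                mode = None
                ldrs[key] = value
        elif mode is not None:
            data_lines.append((mode, lineno, line))
        # lines before any LDR are ignored
    if not data_lines:
        raise SpectrumParseError(f"{name}: no XYDATA/XYPOINTS table found")

    xfac = float(ldrs.get("XFACTOR", 1.0))
    yfac = float(ldrs.get("YFACTOR", 1.0))
    xs: list[float] = []
    ys: list[float] = []
    for table_kind, lineno, line in data_lines:
        try:
            nums = [float(t) for t in re.split(r"[,\s;]+", line.strip()) if t]
        except ValueError as exc:
            raise SpectrumParseError(f"{name}: line {lineno}: {exc}") from None
        if not nums:
            continue
        if table_kind == "xypoints":
            if len(nums) % 2:
                raise SpectrumParseError(
                    f"{name}: line {lineno}: odd value count in XY pairs"
                )
            xs.extend(nums[0::2])
            ys.extend(nums[1::2])
        else:  # (X++(Y..Y)): first number is X of the first Y on the line
            x0 = nums[0]
            yvals = nums[1:]
            if not yvals:
                raise SpectrumParseError(f"{name}: line {lineno}: X with no Y values")
            if "DELTAX" in ldrs:
                dx = float(ldrs["DELTAX"])
            elif "FIRSTX" in ldrs and "LASTX" in ldrs and "NPOINTS" in ldrs:
                npts = int(float(ldrs["NPOINTS"]))
                dx = (float(ldrs["LASTX"]) - float(ldrs["FIRSTX"])) / max(npts - 1, 1)
            else:
                raise SpectrumParseError(
                    f"{name}: cannot infer DELTAX for (X++(Y..Y)) table"
                )
            xs.extend(x0 + dx * np.arange(len(yvals)))
            ys.extend(yvals)
    if not xs:
        raise SpectrumParseError(f"{name}: empty data table")
    x = np.asarray(xs, dtype=float) * xfac
    y = np.asarray(ys, dtype=float) * yfac
    meta = {k.lower(): v for k, v in ldrs.items()}
    if "TITLE" in ldrs:
        meta["sample_id"] = ldrs["TITLE"]
    return x, y, meta


def read_spectrum(path, dialect: str = "two_column") -> RamanSpectrum:
    """Read one replicate spectrum from ``path``.

    Parameters
    ----------
    path
        File to read.
    dialect
        ``"two_column"`` (wavenumber intensity per line, ``#`` comments) or
        ``"jcamp"`` (restricted JCAMP-DX subset).

    Returns
    -------
    RamanSpectrum
        With a strictly ascending grid; descending input is reversed and
        near-duplicate wavenumbers are merged by mean intensity.  Sample id
        and replicate index come from ``# sample_id:`` / ``# replicate:``
        header comments (or ##TITLE= for JCAMP), falling back to a
        ``<id>_rep<k>`` filename convention.
    """
    path = Path(path)
    text = path.read_text()
    if dialect == "two_column":
        w, y, meta = _parse_two_column(text, path.name)
    elif dialect == "jcamp":
        w, y, meta = _parse_jcamp(text, path.name)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")
    w, y = _sort_and_merge(w, y)
    if w.size >= 2 and not np.all(np.diff(w) > 0):
        raise SpectrumValidationError(f"{path.name}: non-monotone grid after sort")
    sid, rep = _metadata_from_path(path)
    sid = str(meta.get("sample_id", sid))
    rep = int(meta.get("replicate", meta.get("replicate_index", rep)))
    return RamanSpectrum(
        sample_id=sid,
        replicate_index=rep,
        wavenumbers=w,
        intensities=y,
        source=str(path),
    )


def write_spectrum(spectrum: RamanSpectrum, path, dialect: str = "two_column") -> None:
    """Write a spectrum in one of the supported dialects (round-trip safe)."""
    path = Path(path)
    if dialect == "two_column":
        buf = io.StringIO()
        buf.write(f"# sample_id: {spectrum.sample_id}\n")
        buf.write(f"# replicate: {spectrum.replicate_index}\n")
        for w, y in zip(spectrum.wavenumbers, spectrum.intensities):
            buf.write(f"{w:.6f} {y:.8g}\n")
        path.write_text(buf.getvalue())
    elif dialect == "jcamp":
        buf = io.StringIO()
        buf.write(f"##TITLE={spectrum.sample_id}\n")
        buf.write("##JCAMP-DX=4.24\n##DATA TYPE=RAMAN SPECTRUM\n")
        buf.write("##XUNITS=1/CM\n##YUNITS=ARBITRARY UNITS\n")
        buf.write("##XFACTOR=1.0\n##YFACTOR=1.0\n")
        buf.write(f"##FIRSTX={spectrum.wavenumbers[0]:.6f}\n")
        buf.write(f"##LASTX={spectrum.wavenumbers[-1]:.6f}\n")
        buf.write(f"##NPOINTS={len(spectrum)}\n")
        buf.write("##XYPOINTS=(XY..XY)\n")
        for w, y in zip(spectrum.wavenumbers, spectrum.intensities):
            buf.write(f"{w:.6f} {y:.8g}\n")
        buf.write("##END=\n")
        path.write_text(buf.getvalue())
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


def resample(spectrum: RamanSpectrum, grid: Iterable[float]) -> RamanSpectrum:
    """Linearly interpolate a spectrum onto a new wavenumber grid.

    The grid must lie within the spectrum's range; no extrapolation is done.
    """
    grid = np.asarray(list(grid) if not isinstance(grid, np.ndarray) else grid,
                      dtype=float)
    lo, hi = spectrum.wavenumber_range
    if grid.size == 0:
        raise SpectrumRangeError("empty resampling grid")
    if grid.min() < lo or grid.max() > hi:
        raise SpectrumRangeError(
            f"grid [{grid.min()}, {grid.max()}] outside spectrum range [{lo}, {hi}]"
        )
    y = np.interp(grid, spectrum.wavenumbers, spectrum.intensities)
    return spectrum.with_values(grid, y)


# ---------------------------------------------------------------------------
# paired chemistry tables
# ---------------------------------------------------------------------------

def load_paired_table(path) -> PairedDataset:
    """Load a delimited Raman/chemistry table into a :class:`PairedDataset`.

    Accepts comma- or tab-delimited text with the required header columns;
    empty cells and ``-`` are missing values (never coerced to zero).
    """
    path = Path(path)
    df = pd.read_csv(
        path,
        sep=None,
        engine="python",
        na_values=list(MISSING_TOKENS),
        keep_default_na=True,
        skip_blank_lines=True,
    )
    df.columns = [str(c).strip() for c in df.columns]
    missing = [c for c in TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise TableValidationError(f"{path.name}: missing columns {missing}")
    df = df[TABLE_COLUMNS].copy()
    df["sample_id"] = df["sample_id"].astype(str).str.strip()
    df["phase"] = df["phase"].astype("string").str.strip()
    for col in ("pct_n", "pct_c", "cn_atomic", "pct_collagen", "raman_ratio"):
        df[col] = pd.to_numeric(df[col], errors="raise")
    return PairedDataset(records=df.reset_index(drop=True))


def _fixture_path(name: str):
    return resources.files("ramanbone.data") / name


def load_table1() -> PairedDataset:
    """The packaged 31-sample complete reference table."""
    with resources.as_file(_fixture_path("table1.csv")) as p:
        return load_paired_table(p)


def load_table2() -> PairedDataset:
    """The packaged 10-sample partial table (low-nitrogen / fluorescence-failed
    samples; missing cells are printed as ``-`` in the source)."""
    with resources.as_file(_fixture_path("table2.csv")) as p:
        return load_paired_table(p)


def load_combined() -> PairedDataset:
    """Both packaged tables concatenated (41 samples)."""
    df = pd.concat(
        [load_table1().records, load_table2().records], ignore_index=True
    )
    return PairedDataset(records=df)
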