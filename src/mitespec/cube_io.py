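"""Wavelength-grid arithmetic and ENVI hyperspectral cube I/O.

A hyperspectral snapshot is a 3-D reflectance array (rows, cols, bands)
with an attached uniform wavelength grid.  Cubes are exchanged on disk in
the ENVI dialect: a plain-text ``.hdr`` file next to a raw binary data
file.  We write band-sequential (BSQ), 32-bit little-endian float with a
``wavelength`` list in nm, and read all three standard interleaves
(BSQ, BIL, BIP).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

__all__ = [
    "WavelengthGrid",
    "HyperCube",
    "make_grid",
    "nearest_band",
    "read_envi",
    "write_envi",
]

# ENVI numeric "data type" codes -> numpy dtypes (unsigned/else per the format)
_ENVI_DTYPES = {
    1: np.uint8,
    2: np.int16,
    3: np.int32,
    4: np.float32,
    5: np.float64,
    12: np.uint16,
    13: np.uint32,
    14: np.int64,
}
_DTYPE_CODES = {np.dtype(v): k for k, v in _ENVI_DTYPES.items()}


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform band-center grid: ``centers[i] = start_nm + i * step_nm``."""

    start_nm: float
    step_nm: float
    n_bands: int

    def __post_init__(self) -> None:
        if self.n_bands < 1:
            raise ValueError("grid needs at least one band")
        if self.step_nm <= 0:
            raise ValueError("step_nm must be positive")

    @property
    def centers(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_bands)

    @property
    def stop_nm(self) -> float:
        return self.start_nm + self.step_nm * (self.n_bands - 1)

    def __len__(self) -> int:
        return self.n_bands


def make_grid(start_nm: float, stop_nm: float, step_nm: float) -> WavelengthGrid:
    """Build a uniform grid whose endpoints are commensurate with the step.

    Raises ``ValueError`` when ``stop_nm - start_nm`` is not an integer
    multiple of ``step_nm`` (to within 1e-9 relative tolerance).
    """
    if step_nm <= 0:
        raise ValueError("step_nm must be positive")
    if stop_nm < start_nm:
        raise ValueError("stop_nm must be >= start_nm")
    span = stop_nm - start_nm
    n_steps = span / step_nm
    if abs(n_steps - round(n_steps)) > 1e-9 * max(1.0, abs(n_steps)):
        raise ValueError(
            f"grid endpoints not commensurate with step: "
            f"({start_nm}, {stop_nm}) nm is not a whole number of {step_nm} nm steps"
        )
    return WavelengthGrid(float(start_nm), float(step_nm), int(round(n_steps)) + 1)


def nearest_band(grid: WavelengthGrid, target_nm: float) -> int:
    """Index of the band center closest to ``target_nm``.

    Exact ties between two neighbouring centers resolve to the lower
    index; targets outside the grid clamp to the first or last band.
    """
    pos = (target_nm - grid.start_nm) / grid.step_nm
    lo = int(np.floor(pos))
    lo = max(0, min(lo, grid.n_bands - 1))
    hi = min(lo + 1, grid.n_bands - 1)
    centers = grid.centers
    # ties (equal distance) go to the lower index
    if abs(target_nm - centers[hi]) < abs(target_nm - centers[lo]):
        return hi
    return lo


@dataclass
class HyperCube:
    """Reflectance cube with shape (height, width, n_bands).

    Values are dimensionless reflectances, finite and non-negative; they
    are stored as float32, matching the on-disk dialect, so that the
    in-memory and ENVI round-trip representations are bit-identical.
    """

    values: np.ndarray
    grid: WavelengthGrid = field(repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float32)
        if self.values.ndim != 3:
            raise ValueError("cube values must be 3-D (height, width, bands)")
        if self.values.shape[2] != self.grid.n_bands:
            raise ValueError(
                f"cube has {self.values.shape[2]} bands but grid declares "
                f"{self.grid.n_bands}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("cube values must be finite")
        if self.values.min() < 0:
            raise ValueError("cube values must be non-negative")

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    def band(self, target_nm: float) -> np.ndarray:
        """Single-band image at the grid center nearest ``target_nm``."""
        return self.values[:, :, nearest_band(self.grid, target_nm)]


# ---------------------------------------------------------------------------
# ENVI header parsing/writing


def _parse_header(text: str) -> dict[str, str]:
    if not text.lstrip().lower().startswith("envi"):
        raise ValueError("not an ENVI header (missing 'ENVI' magic line)")
    fields: dict[str, str] = {}
    body = text.lstrip()[4:]
    i = 0
    lines = body.splitlines()
    while i < len(lines):
        line = lines[i].strip()
        i += 1
        if not line or "=" not in line:
            continue
        key, _, value = line.partition("=")
        value = value.strip()
        if value.startswith("{"):
            # brace-delimited value, possibly spanning lines
            while "}" not in value and i < len(lines):
                value += " " + lines[i].strip()
                i += 1
            value = value.strip("{} ")
        fields[key.strip().lower()] = value
    return fields


def _data_path_for(header_path: Path) -> Path:
    stem = header_path.with_suffix("") if header_path.suffix == ".hdr" else header_path
    for cand in (stem, stem.with_suffix(".img"), stem.with_suffix(".raw"),
                 stem.with_suffix(".dat")):
        if cand.exists() and cand != header_path:
            return cand
    raise FileNotFoundError(f"no data file found next to {header_path}")


def read_envi(header_path: str | Path) -> HyperCube:
    """Read an ENVI header/data pair into a :class:`HyperCube`.

    Supports BSQ, BIL and BIP interleaves and the common numeric data
    types; the header's ``wavelength`` list populates the grid and must
    match the declared band count.
    """
    header_path = Path(header_path)
    fields = _parse_header(header_path.read_text())

    samples = int(fields["samples"])
    lines = int(fields["lines"])
    bands = int(fields["bands"])
    dtype_code = int(fields["data type"])
    if dtype_code not in _ENVI_DTYPES:
        raise ValueError(f"unsupported ENVI data type code {dtype_code}")
    dtype = np.dtype(_ENVI_DTYPES[dtype_code])
    if int(fields.get("byte order", "0")) == 1:
        dtype = dtype.newbyteorder(">")
    interleave = fields.get("interleave", "bsq").strip().lower()

    if "wavelength" not in fields:
        raise ValueError("ENVI header lacks a wavelength list")
    wavelengths = np.array(
        [float(w) for w in fields["wavelength"].split(",") if w.strip()]
    )
    if wavelengths.size != bands:
        raise ValueError(
            f"header declares {bands} bands but lists {wavelengths.size} wavelengths"
        )
    steps = np.diff(wavelengths)
    if wavelengths.size > 1:
        if steps.min() <= 0 or not np.allclose(steps, steps[0], rtol=0, atol=1e-6):
            raise ValueError("wavelength list is not a uniform increasing grid")
        step = float(steps[0])
    else:
        step = 1.0
    grid = WavelengthGrid(float(wavelengths[0]), step, bands)

    raw = np.fromfile(_data_path_for(header_path), dtype=dtype)
    expected = samples * lines * bands
    if raw.size != expected:
        raise ValueError(
            f"data file holds {raw.size} values, expected {expected}"
        )
    if interleave == "bsq":
        cube = raw.reshape(bands, lines, samples).transpose(1, 2, 0)
    elif interleave == "bil":
        cube = raw.reshape(lines, bands, samples).transpose(0, 2, 1)
    elif interleave == "bip":
        cube = raw.reshape(lines, samples, bands)
    else:
        raise ValueError(f"unknown interleave {interleave!r}")
    return HyperCube(np.ascontiguousarray(cube, dtype=np.float32), grid)


def write_envi(cube: HyperCube, header_path: str | Path) -> tuple[Path, Path]:
    """Write ``cube`` as a BSQ float32 little-endian header/data pair.

    Returns the (header, data) paths; the data file sits next to the
    header with an ``.img`` suffix.
    """
    header_path = Path(header_path)
    if header_path.suffix != ".hdr":
        header_path = header_path.with_suffix(".hdr")
    data_path = header_path.with_suffix(".img")

    wl = ", ".join(f"{c:.1f}" for c in cube.grid.centers)
    header = (
        "ENVI\n"
        "description = {mitespec hyperspectral cube}\n"
        f"samples = {cube.width}\n"
        f"lines = {cube.height}\n"
        f"bands = {cube.grid.n_bands}\n"
        "header offset = 0\n"
        "file type = ENVI Standard\n"
        "data type = 4\n"
        "interleave = bsq\n"
        "byte order = 0\n"
        "wavelength units = nm\n"
        f"wavelength = {{{wl}}}\n"
    )
    header_path.write_text(header)
    bsq = np.ascontiguousarray(cube.values.transpose(2, 0, 1), dtype="<f4")
    bsq.tofile(data_path)
    return header_path, data_path
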