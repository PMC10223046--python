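"""Reading, writing and subsetting labeled reflectance spectra.

The canonical on-disk format is a CSV with header
``sample_id,product_class,physical_state,R350,R351,...,R2500`` -- one row per
spectrum, reflectance values aligned to a fixed wavelength grid.  Gzipped
files are handled transparently by extension.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

FROZEN = "frozen"
THAWED = "thawed"
PHYSICAL_STATES = (FROZEN, THAWED)

META_COLUMNS = ("sample_id", "product_class", "physical_state")


class SpectraFormatError(ValueError):
    """Raised when an input file does not match the expected tabular layout."""


@dataclass(frozen=True)
class WavelengthGrid:
    """Uniform wavelength grid in nanometres, endpoints inclusive."""

    start_nm: float = 350.0
    end_nm: float = 2500.0
    step_nm: float = 1.0

    def __post_init__(self) -> None:
        if not self.start_nm < self.end_nm:
            raise ValueError(f"start_nm ({self.start_nm}) must be < end_nm ({self.end_nm})")
        if self.step_nm <= 0:
            raise ValueError(f"step_nm must be positive, got {self.step_nm}")
        span = self.end_nm - self.start_nm
        n_steps = span / self.step_nm
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError(
                f"grid span {span} nm is not divisible by step {self.step_nm} nm"
            )

    @property
    def n_points(self) -> int:
        return int(round((self.end_nm - self.start_nm) / self.step_nm)) + 1

    def wavelengths(self) -> np.ndarray:
        return self.start_nm + self.step_nm * np.arange(self.n_points, dtype=float)

    def column_names(self) -> list[str]:
        return [f"R{w:g}" for w in self.wavelengths()]


#: 350-2500 nm at 1 nm resolution -> 2151 variables per spectrum.
CANONICAL_GRID = WavelengthGrid(350.0, 2500.0, 1.0)


@dataclass(frozen=True)
class SampleMeta:
    """Per-spectrum metadata: sample identity, product class, physical state.

    ``product_class`` is the binary product label (1 = Pennette72,
    0 = Mezze Penne); ``physical_state`` is ``"frozen"`` or ``"thawed"``.
    """

    sample_id: str
    product_class: int
    physical_state: str

    def __post_init__(self) -> None:
        if self.product_class not in (0, 1):
            raise ValueError(f"product_class must be 0 or 1, got {self.product_class!r}")
        if self.physical_state not in PHYSICAL_STATES:
            raise ValueError(
                f"physical_state must be one of {PHYSICAL_STATES}, got {self.physical_state!r}"
            )


@dataclass
class Spectrum:
    """A single reflectance spectrum plus its metadata."""

    meta: SampleMeta
    reflectance: np.ndarray

    def __post_init__(self) -> None:
        self.reflectance = np.asarray(self.reflectance, dtype=float)
        if self.reflectance.ndim != 1:
            raise ValueError("reflectance must be a 1-D vector")
        if not np.all(np.isfinite(self.reflectance)):
            raise ValueError("reflectance contains non-finite values")


@dataclass
class SpectraDataset:
    """An ordered collection of spectra sharing one wavelength grid."""

    grid: WavelengthGrid
    spectra: list[Spectrum] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.grid.n_points
        for i, s in enumerate(self.spectra):
            if s.reflectance.shape[0] != n:
                raise ValueError(
                    f"spectrum {i}: length {s.reflectance.shape[0]} != grid points {n}"
                )

    def __len__(self) -> int:
        return len(self.spectra)

    def __iter__(self):
        return iter(self.spectra)

    @property
    def X(self) -> np.ndarray:
        """Data matrix, one row per spectrum (n x m)."""
        if not self.spectra:
            return np.empty((0, self.grid.n_points))
        return np.stack([s.reflectance for s in self.spectra])

    @property
    def labels(self) -> np.ndarray:
        return np.array([s.meta.product_class for s in self.spectra], dtype=int)

    @property
    def states(self) -> np.ndarray:
        return np.array([s.meta.physical_state for s in self.spectra])

    def meta_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": [s.meta.sample_id for s in self.spectra],
                "product_class": self.labels,
                "physical_state": self.states,
            }
        )

    def select(self, indices: Iterable[int]) -> "SpectraDataset":
        return SpectraDataset(self.grid, [self.spectra[i] for i in indices])

    def allclose(self, other: "SpectraDataset", atol: float = 0.0) -> bool:
        if self.grid != other.grid or len(self) != len(other):
            return False
        for a, b in zip(self.spectra, other.spectra):
            if a.meta != b.meta:
                return False
            if not np.allclose(a.reflectance, b.reflectance, atol=atol, rtol=1e-5):
                return False
        return True


def infer_grid(path: str | Path) -> WavelengthGrid:
    """Reconstruct the wavelength grid from a file's R<wavelength> header."""
    header = pd.read_csv(Path(path), nrows=0, compression="infer")
    waves = [float(c[1:]) for c in header.columns if c.startswith("R")]
    if len(waves) < 2:
        raise SpectraFormatError(f"{path}: cannot infer a grid from the header")
    return WavelengthGrid(waves[0], waves[-1], (waves[-1] - waves[0]) / (len(waves) - 1))


def read_dataset(path: str | Path, grid: WavelengthGrid | None = CANONICAL_GRID) -> SpectraDataset:
    """Read a labeled spectra table, validating each row against ``grid``.

    When ``grid`` is None it is inferred from the header's R<wavelength>
    columns.

    Raises
    ------
    SpectraFormatError
        On a wrong column count, non-numeric reflectance, or an unknown
        physical-state token.
    FileNotFoundError
        If ``path`` does not exist.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if grid is None:
        grid = infer_grid(path)
    df = pd.read_csv(path, dtype={"sample_id": str}, compression="infer")
    expected = len(META_COLUMNS) + grid.n_points
    if df.shape[1] != expected:
        raise SpectraFormatError(
            f"{path}: expected {expected} columns "
            f"({len(META_COLUMNS)} metadata + {grid.n_points} reflectance), found {df.shape[1]}"
        )
    missing = [c for c in META_COLUMNS if c not in df.columns]
    if missing:
        raise SpectraFormatError(f"{path}: missing metadata columns {missing}")
    value_cols = [c for c in df.columns if c not in META_COLUMNS]
    values = df[value_cols].to_numpy()
    if not np.issubdtype(values.dtype, np.number):
        for i in range(len(df)):
            row = pd.to_numeric(df[value_cols].iloc[i], errors="coerce")
            if row.isna().any():
                raise SpectraFormatError(f"{path}: non-numeric reflectance in data row {i}")
        values = values.astype(float)
    spectra = []
    for i in range(len(df)):
        state = df["physical_state"].iloc[i]
        if state not in PHYSICAL_STATES:
            raise SpectraFormatError(
                f"{path}: row {i}: unknown physical_state {state!r} "
                f"(expected one of {PHYSICAL_STATES})"
            )
        meta = SampleMeta(
            sample_id=str(df["sample_id"].iloc[i]),
            product_class=int(df["product_class"].iloc[i]),
            physical_state=state,
        )
        spectra.append(Spectrum(meta, values[i].astype(float)))
    return SpectraDataset(grid, spectra)


def write_dataset(ds: SpectraDataset, path: str | Path) -> Path:
    """Write a dataset to CSV; byte-deterministic for a fixed dataset.

    Floats are serialized at 6 significant digits.  Raises ``ValueError`` for
    an empty dataset (no file is created).
    """
    if len(ds) == 0:
        raise ValueError("refusing to write an empty dataset")
    path = Path(path)
    df = ds.meta_frame()
    values = pd.DataFrame(ds.X, columns=ds.grid.column_names())
    out = pd.concat([df, values], axis=1)
    out.to_csv(path, index=False, float_format="%.6g", lineterminator="\n")
    return path


def subset_by_state(ds: SpectraDataset, state: str) -> SpectraDataset:
    """All spectra in the given physical state, original order preserved."""
    if state not in PHYSICAL_STATES:
        raise ValueError(f"state must be one of {PHYSICAL_STATES}, got {state!r}")
    return SpectraDataset(ds.grid, [s for s in ds.spectra if s.meta.physical_state == state])
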