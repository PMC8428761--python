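"""Domain model and serialization for bilateral wrist S-parameter cohorts.

A cohort is a set of subjects, each carrying demographics (age, BMI, wrist
circumferences) and four 201-point complex S-parameter spectra recorded by a
network analyzer: the transmission coefficient S21 and the reflection
coefficient S11 for each wrist, sampled on a common linear frequency grid
from 300 kHz to 2 GHz. Only S21 is consumed by the downstream classifier;
S11 is carried so that cohort files are structurally complete instrument
exports.

Two interchange dialects are supported:

``packed_csv``
    One long-format UTF-8 CSV, one row per (subject, arm, channel,
    frequency point), magnitude stored linear and phase in degrees (the
    network-analyzer convention). This is the canonical format.
``touchstone_dir``
    A directory of 2-port Touchstone v1 files (``<subject>_<arm>.s2p``,
    ``# HZ S MA R 50`` dialect) plus one JSON demographics sidecar per
    subject — a convenience for real instrument exports.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "GROUP1",
    "GROUP2",
    "UNKNOWN",
    "GROUPS",
    "CHANNELS",
    "ARMS",
    "CohortError",
    "FrequencyGrid",
    "Spectrum",
    "SubjectRecord",
    "Cohort",
    "mag_phase_to_complex",
    "complex_to_mag_phase",
    "read_cohort",
    "write_cohort",
]

GROUP1 = "group1_osteo"
GROUP2 = "group2_healthy"
UNKNOWN = "unknown"
GROUPS = (GROUP1, GROUP2, UNKNOWN)

CHANNELS = ("S21", "S11")
ARMS = ("left", "right")

DEFAULT_F_START_HZ = 3.0e5
DEFAULT_F_STOP_HZ = 2.0e9
DEFAULT_N_POINTS = 201

_CSV_COLUMNS = [
    "subject_id",
    "group",
    "age",
    "bmi",
    "circumference_left",
    "circumference_right",
    "arm",
    "channel",
    "freq_hz",
    "mag_linear",
    "phase_deg",
]


class CohortError(ValueError):
    """Structured validation or I/O error for cohort data."""


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FrequencyGrid:
    """A strictly increasing grid of measurement frequencies in Hz."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        if pts.ndim != 1 or pts.size < 2:
            raise CohortError("frequency grid must be a 1-D array of >= 2 points")
        if not np.all(np.diff(pts) > 0):
            raise CohortError("frequency grid must be strictly increasing")
        object.__setattr__(self, "points", pts)

    @property
    def n_points(self) -> int:
        return int(self.points.size)

    @classmethod
    def default(
        cls,
        start_hz: float = DEFAULT_F_START_HZ,
        stop_hz: float = DEFAULT_F_STOP_HZ,
        n_points: int = DEFAULT_N_POINTS,
    ) -> "FrequencyGrid":
        """Linear 201-point grid over 300 kHz – 2 GHz (instrument default)."""
        return cls(np.linspace(start_hz, stop_hz, n_points))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, FrequencyGrid):
            return NotImplemented
        return self.points.shape == other.points.shape and bool(
            np.allclose(self.points, other.points, rtol=1e-12, atol=0.0)
        )

    def __hash__(self) -> int:  # frozen dataclass with an array field
        return hash((self.points.size, float(self.points[0]), float(self.points[-1])))


@dataclass
class Spectrum:
    """A complex S-parameter series on a frequency grid.

    Values are dimensionless linear S-parameters. Passive transmission
    implies |S| <= 1; a violation triggers a warning, not a rejection,
    since calibration artefacts in real exports can exceed unity slightly.
    """

    grid: FrequencyGrid
    values: np.ndarray
    channel: str
    arm: str

    def __post_init__(self) -> None:
        vals = np.asarray(self.values, dtype=complex)
        if vals.ndim != 1 or vals.size != self.grid.n_points:
            raise CohortError(
                f"spectrum has {vals.size} values for a {self.grid.n_points}-point grid"
            )
        if not np.all(np.isfinite(vals)):
            raise CohortError("spectrum contains non-finite values")
        if self.channel not in CHANNELS:
            raise CohortError(f"unknown channel {self.channel!r}; expected one of {CHANNELS}")
        if self.arm not in ARMS:
            raise CohortError(f"unknown arm {self.arm!r}; expected one of {ARMS}")
        if np.max(np.abs(vals)) > 1.0 + 1e-9:
            warnings.warn(
                f"{self.channel}/{self.arm} spectrum exceeds unit magnitude "
                f"(max |S| = {np.max(np.abs(vals)):.4g}); not physical for a passive network",
                stacklevel=2,
            )
        self.values = vals


@dataclass
class SubjectRecord:
    """One subject: demographics, group label, and all four spectra."""

    subject_id: str
    group: str
    age: float
    bmi: float
    circumference_left: float
    circumference_right: float
    spectra: Mapping[tuple[str, str], Spectrum]

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise CohortError(
                f"subject {self.subject_id!r}: unknown group {self.group!r}"
            )
        for name, val in (
            ("age", self.age),
            ("bmi", self.bmi),
            ("circumference_left", self.circumference_left),
            ("circumference_right", self.circumference_right),
        ):
            if not (math.isfinite(val) and val > 0):
                raise CohortError(f"subject {self.subject_id!r}: {name} must be positive")
        expected = {(c, a) for c in CHANNELS for a in ARMS}
        have = set(self.spectra.keys())
        if have != expected:
            missing = sorted(expected - have)
            extra = sorted(have - expected)
            raise CohortError(
                f"subject {self.subject_id!r}: spectra mismatch"
                + (f"; missing {missing}" if missing else "")
                + (f"; unexpected {extra}" if extra else "")
            )
        for (channel, arm), spec in self.spectra.items():
            if (spec.channel, spec.arm) != (channel, arm):
                raise CohortError(
                    f"subject {self.subject_id!r}: spectrum stored under {(channel, arm)} "
                    f"is tagged {(spec.channel, spec.arm)}"
                )

    def spectrum(self, channel: str, arm: str) -> Spectrum:
        return self.spectra[(channel, arm)]

    def circumference(self, arm: str) -> float:
        if arm == "left":
            return self.circumference_left
        if arm == "right":
            return self.circumference_right
        raise CohortError(f"unknown arm {arm!r}")


@dataclass
class Cohort:
    """An ordered collection of subjects with unique ids."""

    subjects: list[SubjectRecord]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise CohortError(f"duplicate subject ids: {dupes}")

    def __len__(self) -> int:
        return len(self.subjects)

    def __iter__(self) -> Iterator[SubjectRecord]:
        return iter(self.subjects)

    def labels(self) -> dict[str, str]:
        return {s.subject_id: s.group for s in self.subjects}


# ---------------------------------------------------------------------------
# Magnitude/phase conversion
# ---------------------------------------------------------------------------


def mag_phase_to_complex(magnitude, phase_deg):
    """Combine linear magnitude and phase in degrees into complex values.

    Returns ``magnitude * exp(1j * radians(phase_deg))``. Phase may be any
    real number (it wraps naturally); magnitude must be non-negative.
    """
    mag = np.asarray(magnitude, dtype=float)
    if np.any(mag < 0):
        raise CohortError("magnitude must be non-negative")
    out = mag * np.exp(1j * np.deg2rad(np.asarray(phase_deg, dtype=float)))
    return complex(out) if out.ndim == 0 else out


def complex_to_mag_phase(values):
    """Decompose complex values into (linear magnitude, phase in degrees).

    Phase is wrapped to (-180, 180], matching network-analyzer exports.
    """
    vals = np.asarray(values, dtype=complex)
    return np.abs(vals), np.rad2deg(np.angle(vals))


# ---------------------------------------------------------------------------
# Packed CSV dialect
# ---------------------------------------------------------------------------


def _cohort_to_frame(cohort: Cohort) -> pd.DataFrame:
    rows: dict[str, list] = {c: [] for c in _CSV_COLUMNS}
    for s in cohort:
        for (channel, arm), spec in sorted(s.spectra.items()):
            mag, phase = complex_to_mag_phase(spec.values)
            n = spec.grid.n_points
            rows["subject_id"].extend([s.subject_id] * n)
            rows["group"].extend([s.group] * n)
            rows["age"].extend([s.age] * n)
            rows["bmi"].extend([s.bmi] * n)
            rows["circumference_left"].extend([s.circumference_left] * n)
            rows["circumference_right"].extend([s.circumference_right] * n)
            rows["arm"].extend([arm] * n)
            rows["channel"].extend([channel] * n)
            rows["freq_hz"].extend(spec.grid.points.tolist())
            rows["mag_linear"].extend(mag.tolist())
            rows["phase_deg"].extend(phase.tolist())
    return pd.DataFrame(rows, columns=_CSV_COLUMNS)


def _subject_from_group(subject_id: str, sdf: pd.DataFrame, n_points: int | None) -> SubjectRecord:
    meta = sdf.iloc[0]
    spectra: dict[tuple[str, str], Spectrum] = {}
    for (channel, arm), block in sdf.groupby(["channel", "arm"], sort=True):
        block = block.sort_values("freq_hz")
        if n_points is not None and len(block) != n_points:
            raise CohortError(
                f"subject {subject_id!r}: {channel}/{arm} has {len(block)} points, "
                f"expected {n_points} (pass n_points=None to accept)"
            )
        grid = FrequencyGrid(block["freq_hz"].to_numpy())
        values = mag_phase_to_complex(
            block["mag_linear"].to_numpy(), block["phase_deg"].to_numpy()
        )
        spectra[(str(channel), str(arm))] = Spectrum(grid, values, str(channel), str(arm))
    missing = sorted({(c, a) for c in CHANNELS for a in ARMS} - set(spectra))
    if missing:
        raise CohortError(f"subject {subject_id!r}: missing spectra for {missing}")
    return SubjectRecord(
        subject_id=subject_id,
        group=str(meta["group"]),
        age=float(meta["age"]),
        bmi=float(meta["bmi"]),
        circumference_left=float(meta["circumference_left"]),
        circumference_right=float(meta["circumference_right"]),
        spectra=spectra,
    )


def _read_packed_csv(path: Path, n_points: int | None) -> Cohort:
    df = pd.read_csv(path)
    missing_cols = [c for c in _CSV_COLUMNS if c not in df.columns]
    if missing_cols:
        raise CohortError(f"{path}: missing columns {missing_cols}")
    subjects = []
    for subject_id, sdf in df.groupby("subject_id", sort=False):
        subjects.append(_subject_from_group(str(subject_id), sdf, n_points))
    return Cohort(subjects=subjects, provenance=f"loaded from {path.name}")


def _write_packed_csv(cohort: Cohort, path: Path) -> None:
    # repr-precision floats so a write/read round trip is lossless to ~1e-16
    _cohort_to_frame(cohort).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Touchstone v1 dialect
# ---------------------------------------------------------------------------

_TOUCHSTONE_HEADER = "# HZ S MA R 50"


def _write_touchstone_dir(cohort: Cohort, path: Path) -> None:
    path.mkdir(parents=True, exist_ok=True)
    for s in cohort:
        meta = {
            "subject_id": s.subject_id,
            "group": s.group,
            "age": s.age,
            "bmi": s.bmi,
            "circumference_left": s.circumference_left,
            "circumference_right": s.circumference_right,
        }
        (path / f"{s.subject_id}.json").write_text(json.dumps(meta, indent=1) + "\n")
        for arm in ARMS:
            s11 = s.spectrum("S11", arm)
            s21 = s.spectrum("S21", arm)
            if s11.grid != s21.grid:
                raise CohortError(
                    f"subject {s.subject_id!r}/{arm}: S11 and S21 grids differ"
                )
            m11, p11 = complex_to_mag_phase(s11.values)
            m21, p21 = complex_to_mag_phase(s21.values)
            lines = [
                f"! subject={s.subject_id} arm={arm}",
                _TOUCHSTONE_HEADER,
            ]
            # 2-port row order: f S11 S21 S12 S22; reciprocity assumed S12=S21
            for i, f in enumerate(s11.grid.points):
                lines.append(
                    f"{f:.10g} {m11[i]:.12g} {p11[i]:.12g} {m21[i]:.12g} {p21[i]:.12g} "
                    f"{m21[i]:.12g} {p21[i]:.12g} {m11[i]:.12g} {p11[i]:.12g}"
                )
            (path / f"{s.subject_id}_{arm}.s2p").write_text("\n".join(lines) + "\n")


def _parse_s2p(path: Path) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Parse a 2-port Touchstone v1 file in the `# HZ S MA R 50` dialect.

    Returns (freq_hz, s11, s21) with complex S-parameters.
    """
    freq, s11, s21 = [], [], []
    saw_header = False
    for raw in path.read_text().splitlines():
        line = raw.split("!", 1)[0].strip()
        if not line:
            continue
        if line.startswith("#"):
            tokens = line.upper().split()
            if tokens[:4] != ["#", "HZ", "S", "MA"]:
                raise CohortError(
                    f"{path.name}: unsupported Touchstone option line {line!r}; "
                    f"only '{_TOUCHSTONE_HEADER}' is supported"
                )
            saw_header = True
            continue
        parts = [float(t) for t in line.split()]
        if len(parts) != 9:
            raise CohortError(f"{path.name}: expected 9 columns per data row, got {len(parts)}")
        freq.append(parts[0])
        s11.append(mag_phase_to_complex(parts[1], parts[2]))
        s21.append(mag_phase_to_complex(parts[3], parts[4]))
    if not saw_header:
        raise CohortError(f"{path.name}: missing Touchstone option line")
    return np.asarray(freq), np.asarray(s11), np.asarray(s21)


def _read_touchstone_dir(path: Path, n_points: int | None) -> Cohort:
    sidecars = sorted(path.glob("*.json"))
    subjects = []
    for sidecar in sidecars:
        meta = json.loads(sidecar.read_text())
        sid = str(meta["subject_id"])
        spectra: dict[tuple[str, str], Spectrum] = {}
        for arm in ARMS:
            s2p = path / f"{sid}_{arm}.s2p"
            if not s2p.exists():
                raise CohortError(f"subject {sid!r}: missing Touchstone file for arm {arm!r}")
            freq, s11, s21 = _parse_s2p(s2p)
            if n_points is not None and freq.size != n_points:
                raise CohortError(
                    f"subject {sid!r}/{arm}: {freq.size} points, expected {n_points} "
                    f"(pass n_points=None to accept)"
                )
            grid = FrequencyGrid(freq)
            spectra[("S11", arm)] = Spectrum(grid, s11, "S11", arm)
            spectra[("S21", arm)] = Spectrum(grid, s21, "S21", arm)
        subjects.append(
            SubjectRecord(
                subject_id=sid,
                group=str(meta["group"]),
                age=float(meta["age"]),
                bmi=float(meta["bmi"]),
                circumference_left=float(meta["circumference_left"]),
                circumference_right=float(meta["circumference_right"]),
                spectra=spectra,
            )
        )
    return Cohort(subjects=subjects, provenance=f"loaded from {path.name}/")


# ---------------------------------------------------------------------------
# Public I/O surface
# ---------------------------------------------------------------------------


def read_cohort(path, dialect: str = "packed_csv", n_points: int | None = DEFAULT_N_POINTS) -> Cohort:
    """Load a cohort from disk.

    Parameters
    ----------
    path
        CSV file (``packed_csv``) or directory (``touchstone_dir``).
    dialect
        ``"packed_csv"`` or ``"touchstone_dir"``.
    n_points
        Expected points per spectrum (default 201); ``None`` disables the
        check and accepts any grid length.
    """
    path = Path(path)
    if not path.exists():
        raise CohortError(f"cohort path does not exist: {path}")
    if dialect == "packed_csv":
        return _read_packed_csv(path, n_points)
    if dialect == "touchstone_dir":
        return _read_touchstone_dir(path, n_points)
    raise CohortError(f"unknown dialect {dialect!r}")


def write_cohort(cohort: Cohort, path, dialect: str = "packed_csv") -> None:
    """Write a cohort to disk; ``read_cohort`` inverts it to numeric tolerance."""
    path = Path(path)
    if dialect == "packed_csv":
        _write_packed_csv(cohort, path)
    elif dialect == "touchstone_dir":
        _write_touchstone_dir(cohort, path)
    else:
        raise CohortError(f"unknown dialect {dialect!r}")
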