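"""Domain containers and CSV input/output for recordings and profile tables.

A *recording* is one uniformly sampled channel — either electrical potential
in millivolts or temperature in degrees Celsius — optionally tagged with the
alphabet character that was projected onto the proteinoid sample while the
trace was logged.  A *profile table* holds, for each of the 26 characters,
seven-number summaries (quartiles, mean, extremes, standard deviation) of the
detected spike amplitudes (mV) and inter-spike periods (s).

CSV dialect: comma separator, dot decimal, optional ``# key: value`` metadata
lines before an optional single header row.  Time is always in seconds; the
caller declares the channel kind (no unit auto-detection).
"""

from __future__ import annotations

import math
import string
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

__all__ = [
    "POTENTIAL_MV",
    "TEMPERATURE_C",
    "CHANNEL_KINDS",
    "LABELS",
    "Recording",
    "StatsSummary",
    "CharacterProfile",
    "ProfileTable",
    "read_recording",
    "write_recording",
    "load_profile_table",
]

POTENTIAL_MV = "potential_mV"
TEMPERATURE_C = "temperature_C"
CHANNEL_KINDS = (POTENTIAL_MV, TEMPERATURE_C)

#: the 26 uppercase class labels, in alphabetical order
LABELS = tuple(string.ascii_uppercase)

_SPACING_RTOL = 1e-6


@dataclass
class Recording:
    """One uniformly sampled channel with an optional stimulus label.

    Parameters
    ----------
    times : array of float
        Sample times in seconds, strictly increasing, uniformly spaced
        within a relative tolerance of 1e-6.
    values : array of float
        Channel values (mV or °C), finite, same length as ``times``.
    channel_kind : str
        ``"potential_mV"`` or ``"temperature_C"``.
    label : str, optional
        Single character A–Z identifying the projected stimulus.
    sampling_interval : float, optional
        Seconds between samples; inferred as the median spacing if omitted.
    """

    times: np.ndarray
    values: np.ndarray
    channel_kind: str = POTENTIAL_MV
    label: Optional[str] = None
    sampling_interval: Optional[float] = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.channel_kind not in CHANNEL_KINDS:
            raise ValueError(
                f"channel_kind must be one of {CHANNEL_KINDS}, got {self.channel_kind!r}"
            )
        if self.label is not None and self.label not in LABELS:
            raise ValueError(f"label must be a single character A-Z, got {self.label!r}")
        if self.times.ndim != 1 or self.values.ndim != 1:
            raise ValueError("times and values must be one-dimensional")
        if len(self.times) != len(self.values):
            raise ValueError(
                f"length mismatch: {len(self.times)} times vs {len(self.values)} values"
            )
        if not np.all(np.isfinite(self.times)) or not np.all(np.isfinite(self.values)):
            raise ValueError("times and values must be finite")
        if len(self.times) >= 2:
            spacing = np.diff(self.times)
            bad = np.nonzero(spacing <= 0)[0]
            if bad.size:
                raise ValueError(f"non-monotone time at row {bad[0] + 2}")
            if self.sampling_interval is None:
                self.sampling_interval = float(np.median(spacing))
            dt = self.sampling_interval
            if not np.allclose(spacing, dt, rtol=_SPACING_RTOL, atol=_SPACING_RTOL * dt):
                worst = int(np.argmax(np.abs(spacing - dt)))
                raise ValueError(
                    f"non-uniform sampling near row {worst + 2}: spacing "
                    f"{spacing[worst]:g} vs inferred interval {dt:g}"
                )
        elif self.sampling_interval is None:
            self.sampling_interval = math.nan

    def __len__(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> float:
        """Time span covered by the recording, in seconds (0 if < 2 samples)."""
        return float(self.times[-1] - self.times[0]) if len(self) >= 2 else 0.0

    def value_column(self) -> str:
        return self.channel_kind


@dataclass(frozen=True)
class StatsSummary:
    """Seven-number summary of a sample (units of the summarized quantity)."""

    q1: float
    q2: float
    q3: float
    mean: float
    max: float
    min: float
    sd: float
    n: Optional[int] = None

    def check(self, strict: bool = True, name: str = "summary") -> list[str]:
        """Return invariant violations; raise if ``strict`` and any exist."""
        problems = []
        if not (self.min <= self.q1 <= self.q2 <= self.q3 <= self.max):
            problems.append(
                f"{name}: ordering min <= q1 <= q2 <= q3 <= max violated "
                f"({self.min}, {self.q1}, {self.q2}, {self.q3}, {self.max})"
            )
        if not (self.min <= self.mean <= self.max):
            problems.append(f"{name}: mean {self.mean} outside [{self.min}, {self.max}]")
        if self.sd < 0:
            problems.append(f"{name}: negative sd {self.sd}")
        if strict and problems:
            raise ValueError("; ".join(problems))
        return problems


@dataclass(frozen=True)
class CharacterProfile:
    """Amplitude (mV) and inter-spike-period (s) summaries for one character."""

    label: str
    amplitude: StatsSummary
    period: StatsSummary


_AMP_COLS = ["amp_q1", "amp_q2", "amp_q3", "amp_mean", "amp_max", "amp_min", "amp_sd"]
_PER_COLS = ["per_q1", "per_q2", "per_q3", "per_mean", "per_max", "per_min", "per_sd"]
PROFILE_COLUMNS = ["label"] + _AMP_COLS + _PER_COLS


@dataclass
class ProfileTable:
    """Ordered collection of 26 per-character profiles, labels A–Z."""

    profiles: list[CharacterProfile] = field(default_factory=list)

    def __post_init__(self) -> None:
        labels = [p.label for p in self.profiles]
        missing = [lab for lab in LABELS if lab not in labels]
        if missing:
            raise ValueError("missing profile: " + ", ".join(missing))
        extra = [lab for lab in labels if lab not in LABELS]
        if extra or len(labels) != 26:
            raise ValueError(f"expected exactly the 26 labels A-Z, got {labels}")
        self.profiles = sorted(self.profiles, key=lambda p: p.label)

    def __iter__(self):
        return iter(self.profiles)

    def __getitem__(self, label: str) -> CharacterProfile:
        return self.profiles[LABELS.index(label)]

    @property
    def labels(self) -> tuple[str, ...]:
        return LABELS

    def amplitude_means(self) -> np.ndarray:
        """Mean spike amplitude per character (mV), alphabetical order."""
        return np.array([p.amplitude.mean for p in self.profiles])

    def period_means(self) -> np.ndarray:
        """Mean inter-spike period per character (s), alphabetical order."""
        return np.array([p.period.mean for p in self.profiles])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for p in self.profiles:
            a, q = p.amplitude, p.period
            rows.append(
                [p.label, a.q1, a.q2, a.q3, a.mean, a.max, a.min, a.sd,
                 q.q1, q.q2, q.q3, q.mean, q.max, q.min, q.sd]
            )
        return pd.DataFrame(rows, columns=PROFILE_COLUMNS)


def _summary_from_row(row: pd.Series, cols: list[str]) -> StatsSummary:
    q1, q2, q3, mean, mx, mn, sd = (float(row[c]) for c in cols)
    return StatsSummary(q1=q1, q2=q2, q3=q3, mean=mean, max=mx, min=mn, sd=sd)


def _read_metadata(path: Path) -> dict[str, str]:
    meta: dict[str, str] = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            body = line.lstrip("#").strip()
            if ":" in body:
                key, _, val = body.partition(":")
                meta[key.strip()] = val.strip()
    return meta


def read_recording(
    path,
    channel_kind: Optional[str] = None,
    label: Optional[str] = None,
) -> Recording:
    """Read a two-column (time_s, value) CSV into a validated :class:`Recording`.

    ``# key: value`` comment lines may carry ``label`` and ``channel_kind``
    metadata (as written by :func:`write_recording`); explicit arguments
    override them.  A single header row is detected automatically.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    meta = _read_metadata(path)
    if channel_kind is None:
        channel_kind = meta.get("channel_kind", POTENTIAL_MV)
    if label is None:
        label = meta.get("label") or None

    # detect an optional single header row before parsing, so numeric columns
    # are read directly with the exact (round-trip) float parser
    first_line = None
    with open(path) as fh:
        for line in fh:
            if line.startswith("#") or not line.strip():
                continue
            first_line = line
            break
    if first_line is None:
        raise ValueError(f"empty recording file: {path}")

    def _is_number(tok: str) -> bool:
        try:
            float(tok)
            return True
        except ValueError:
            return False

    has_header = not all(_is_number(tok) for tok in first_line.strip().split(","))
    try:
        df = pd.read_csv(
            path, comment="#", header=0 if has_header else None,
            skip_blank_lines=True, float_precision="round_trip",
        )
    except pd.errors.EmptyDataError:
        raise ValueError(f"empty recording file: {path}") from None
    if df.shape[1] < 2:
        raise ValueError(f"{path}: expected two columns (time, value), got {df.shape[1]}")
    df = df.iloc[:, :2]
    if df.empty:
        return Recording(np.empty(0), np.empty(0), channel_kind, label)
    for c in range(2):
        col = df.iloc[:, c]
        if col.dtype == object:
            coerced = pd.to_numeric(col, errors="coerce")
            bad = np.nonzero((coerced.isna() & col.notna()).to_numpy())[0]
            if bad.size:
                r = int(bad[0])
                raise ValueError(
                    f"{path}: non-numeric cell {col.iloc[r]!r} at data row "
                    f"{r + 1}, column {c + 1}"
                )
    return Recording(
        df.iloc[:, 0].to_numpy(float),
        df.iloc[:, 1].to_numpy(float),
        channel_kind,
        label,
    )


def write_recording(recording: Recording, path) -> None:
    """Write a recording as CSV at full float64 precision (17 significant digits).

    Metadata (channel kind and, if set, the stimulus label) goes into leading
    ``# key: value`` comment lines so a read→write round trip is lossless.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# channel_kind: {recording.channel_kind}\n")
        if recording.label is not None:
            fh.write(f"# label: {recording.label}\n")
        fh.write(f"time_s,{recording.value_column()}\n")
        for t, v in zip(recording.times, recording.values):
            fh.write(f"{t:.17g},{v:.17g}\n")


def load_profile_table(path=None, strict: Optional[bool] = None) -> ProfileTable:
    """Load a per-character profile table.

    With ``path=None`` the packaged reference table is returned.  That table
    transcribes the published per-character spike statistics verbatim, and the
    published period summary for 'H' contains a quartile inversion (Q3 < Q2);
    the packaged load therefore skips strict ordering validation by default,
    while custom tables are validated strictly unless ``strict=False``.
    """
    if path is None:
        if strict is None:
            strict = False
        src = resources.files("proteospike").joinpath("data/profile_table.csv")
        with resources.as_file(src) as p:
            df = pd.read_csv(p, comment="#")
    else:
        if strict is None:
            strict = True
        df = pd.read_csv(path, comment="#")

    missing_cols = [c for c in PROFILE_COLUMNS if c not in df.columns]
    if missing_cols:
        raise ValueError("profile table missing columns: " + ", ".join(missing_cols))

    profiles = []
    problems: list[str] = []
    for _, row in df.iterrows():
        lab = str(row["label"]).strip()
        amp = _summary_from_row(row, _AMP_COLS)
        per = _summary_from_row(row, _PER_COLS)
        problems += amp.check(strict=False, name=f"row {lab} amplitude")
        problems += per.check(strict=False, name=f"row {lab} period")
        profiles.append(CharacterProfile(lab, amp, per))
    if strict and problems:
        raise ValueError("; ".join(problems))
    return ProfileTable(profiles)
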