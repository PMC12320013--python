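"""Data interchange and envelope preparation.

Slow instantaneous causal effects live in the *energies* of oscillatory
signals, not the raw oscillations.  The preparation path therefore takes
the modulus of the analytic signal (Hilbert transform) per channel to get
the amplitude envelope, and downsamples the envelope to a low rate (the
energies change slowly) before any causal estimation.

Tables travel as delimited text (CSV/TSV) with a header of unique column
names; the sampling rate rides along in a small JSON sidecar.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence, Union

import numpy as np
import pandas as pd
from scipy.signal import hilbert, resample_poly


@dataclass(frozen=True)
class TimeSeriesTable:
    """A named multivariate time series sampled at a fixed rate."""

    values: np.ndarray
    sampling_rate_hz: float = 1.0
    names: Optional[tuple] = None

    def __post_init__(self):
        v = np.asarray(self.values, dtype=float)
        if v.ndim == 1:
            v = v[:, None]
        if v.ndim != 2:
            raise ValueError("values must be 2-D (time x variables)")
        if not np.all(np.isfinite(v)):
            raise ValueError("values contain non-finite entries")
        if not self.sampling_rate_hz > 0:
            raise ValueError("sampling_rate_hz must be positive")
        names = self.names
        if names is None:
            names = tuple(f"v{k + 1}" for k in range(v.shape[1]))
        else:
            names = tuple(str(n) for n in names)
            if len(names) != v.shape[1]:
                raise ValueError("names length must match the number of columns")
            if len(set(names)) != len(names):
                raise ValueError("column names must be unique")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "names", names)

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_variables(self) -> int:
        return self.values.shape[1]

    def column(self, key: Union[str, int]) -> np.ndarray:
        """Select one column by name or integer index."""
        if isinstance(key, str):
            if key not in self.names:
                raise KeyError(f"no column named {key!r}")
            return self.values[:, self.names.index(key)]
        return self.values[:, int(key)]


def amplitude_envelope(
    table: TimeSeriesTable, trim_edge_fraction: float = 0.0
) -> TimeSeriesTable:
    """Per-column amplitude envelope: modulus of the analytic signal.

    The analytic signal is unreliable near the recording edges; setting
    ``trim_edge_fraction`` (e.g. 0.02) drops that fraction of samples at
    each end.  The sampling rate is unchanged.
    """
    if table.n_samples < 8:
        raise ValueError("need at least 8 samples for the analytic signal")
    if not 0.0 <= trim_edge_fraction < 0.5:
        raise ValueError("trim_edge_fraction must be in [0, 0.5)")
    env = np.abs(hilbert(table.values, axis=0))
    if trim_edge_fraction > 0.0:
        k = int(math.floor(trim_edge_fraction * table.n_samples))
        if k > 0:
            env = env[k:-k]
    return TimeSeriesTable(env, table.sampling_rate_hz, table.names)


def resample(table: TimeSeriesTable, target_hz: float) -> TimeSeriesTable:
    """Anti-aliased (polyphase) downsampling to ``target_hz``.

    Output length is floor(n * target / source).  Upsampling is not
    supported: envelopes are only ever taken to lower rates.
    """
    if not target_hz > 0:
        raise ValueError("target_hz must be positive")
    if target_hz > table.sampling_rate_hz:
        raise ValueError("upsampling is not supported")
    if math.isclose(target_hz, table.sampling_rate_hz):
        return TimeSeriesTable(table.values.copy(), table.sampling_rate_hz, table.names)
    ratio = Fraction(target_hz) / Fraction(table.sampling_rate_hz)
    ratio = ratio.limit_denominator(10**6)
    out = resample_poly(
        table.values, ratio.numerator, ratio.denominator, axis=0, padtype="line"
    )
    n_out = int(math.floor(table.n_samples * target_hz / table.sampling_rate_hz))
    return TimeSeriesTable(out[:n_out], target_hz, table.names)


def _sidecar_path(path: Union[str, Path]) -> Path:
    return Path(str(path) + ".meta.json")


def read_table(
    path: Union[str, Path],
    sampling_rate_hz: Optional[float] = None,
    header: bool = True,
    sep: Optional[str] = None,
) -> TimeSeriesTable:
    """Read a delimited numeric matrix (rows = time, columns = variables).

    With ``header=False`` column names are autogenerated as v1..vp.  If no
    sampling rate is given, a ``<path>.meta.json`` sidecar is consulted;
    otherwise 1 Hz is assumed.
    """
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    if header:
        with open(path) as fh:
            raw_names = [c.strip() for c in fh.readline().rstrip("\n").split(sep)]
        if len(set(raw_names)) != len(raw_names):
            raise ValueError(f"duplicate column names in {path}")
    try:
        df = pd.read_csv(path, sep=sep, header=0 if header else None)
    except pd.errors.ParserError as exc:
        raise ValueError(f"malformed table {path}: {exc}") from exc
    names = [str(c) for c in df.columns] if header else None
    try:
        values = df.to_numpy(dtype=float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"non-numeric cells in {path}: {exc}") from exc
    if sampling_rate_hz is None:
        sidecar = _sidecar_path(path)
        if sidecar.exists():
            sampling_rate_hz = json.loads(sidecar.read_text())["sampling_rate_hz"]
        else:
            sampling_rate_hz = 1.0
    return TimeSeriesTable(values, sampling_rate_hz, names)


def write_table(
    table: TimeSeriesTable, path: Union[str, Path], sep: Optional[str] = None
) -> None:
    """Write a table as delimited text plus a sampling-rate sidecar."""
    path = Path(path)
    if sep is None:
        sep = "\t" if path.suffix.lower() in (".tsv", ".tab") else ","
    df = pd.DataFrame(table.values, columns=list(table.names))
    df.to_csv(path, sep=sep, index=False, float_format="%.12g")
    _sidecar_path(path).write_text(
        json.dumps({"sampling_rate_hz": table.sampling_rate_hz})
    )


def load_subject_dir(
    directory: Union[str, Path], pattern: str = "*.csv"
) -> Sequence:
    """Load every matching file in a directory as one subject each."""
    from .consistency import SubjectData

    directory = Path(directory)
    files = sorted(directory.glob(pattern))
    if not files:
        raise FileNotFoundError(f"no files matching {pattern!r} in {directory}")
    return [
        SubjectData(subject_id=f.stem, series=read_table(f).values) for f in files
    ]
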