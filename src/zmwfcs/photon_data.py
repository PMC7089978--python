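"""Data model and I/O for time-tagged photon streams.

The raw currency of the pipeline is the TTTR (time-tagged time-resolved)
photon record: a coarse arrival time counted in laser sync periods
(*macrotime*), the delay since the last excitation pulse in picoseconds
(*microtime*) and a detector channel id.  Two on-disk representations are
supported: a minimal Photon-HDF5 layout and a greppable columnar text
dialect used for fixtures.  Binned intensity traces, TCSPC histograms and
instrument response functions (IRFs) round out the containers consumed by
the correlator and the lifetime fitter.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np

__all__ = [
    "TTTRTrace",
    "IntensityTrace",
    "TCSPCHistogram",
    "IRFModel",
    "read_photon_file",
    "write_photon_file",
    "bin_intensity",
    "build_tcspc_histogram",
    "read_histogram_csv",
    "write_histogram_csv",
]

PS_PER_S = 1e12

#: Default TCSPC channel width (ps): finer than both instrument response
#: widths used here (38 ps and 110 ps FWHM) while keeping histograms small.
DEFAULT_CHANNEL_WIDTH_PS = 16.0


class PhotonDataError(ValueError):
    """Malformed or inconsistent photon data."""


@dataclass
class TTTRTrace:
    """Ordered photon records from a pulsed-excitation measurement.

    Parameters
    ----------
    macrotimes:
        Arrival times as integer sync-pulse counts (non-decreasing).  Kept
        as integers so a 60 s acquisition accumulates no float drift.
    microtimes:
        Delay after the sync pulse, integer picoseconds in
        ``[0, sync_period_ps)``.
    channels:
        Small-integer detector ids.
    sync_rate:
        Laser repetition rate in Hz (40 MHz -> 25 ns sync period).
    duration:
        Acquisition length in seconds.  Defaults to the end of the last
        sync period containing a photon.
    metadata:
        Free-form condition labels (dye, passivation, concentration ...).
    """

    macrotimes: np.ndarray
    microtimes: np.ndarray
    channels: np.ndarray
    sync_rate: float = 40e6
    duration: float | None = None
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.macrotimes = np.asarray(self.macrotimes, dtype=np.int64)
        self.microtimes = np.asarray(self.microtimes, dtype=np.int64)
        self.channels = np.asarray(self.channels, dtype=np.int16)
        if not (len(self.macrotimes) == len(self.microtimes) == len(self.channels)):
            raise PhotonDataError("macrotimes, microtimes and channels differ in length")
        if self.sync_rate <= 0:
            raise PhotonDataError("sync_rate must be positive")
        if self.duration is None:
            if self.n_photons:
                self.duration = float(self.macrotimes[-1] + 1) / self.sync_rate
            else:
                self.duration = 0.0
        self.validate()

    # -- properties -----------------------------------------------------
    @property
    def n_photons(self) -> int:
        return int(len(self.macrotimes))

    @property
    def sync_period_ps(self) -> float:
        return PS_PER_S / self.sync_rate

    @property
    def arrival_times(self) -> np.ndarray:
        """Photon arrival times in seconds (macrotime resolution)."""
        return self.macrotimes / self.sync_rate

    # -- validation -----------------------------------------------------
    def validate(self) -> None:
        if self.n_photons == 0:
            return
        d = np.diff(self.macrotimes)
        if np.any(d < 0):
            i = int(np.argmax(d < 0)) + 1
            raise PhotonDataError(
                f"macrotimes not non-decreasing at record {i} "
                f"({self.macrotimes[i]} after {self.macrotimes[i - 1]})"
            )
        period = self.sync_period_ps
        bad = (self.microtimes < 0) | (self.microtimes >= period)
        if np.any(bad):
            i = int(np.argmax(bad))
            raise PhotonDataError(
                f"microtime out of [0, {period:g}) ps at record {i}: {self.microtimes[i]}"
            )
        if self.duration * self.sync_rate < self.macrotimes[-1]:
            raise PhotonDataError("duration shorter than the last photon's macrotime")


@dataclass
class IntensityTrace:
    """Uniformly binned photon counts."""

    bin_width: float  # s
    counts: np.ndarray
    origin_time: float = 0.0  # s

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.bin_width <= 0:
            raise PhotonDataError("bin_width must be positive")
        if np.any(self.counts < 0):
            raise PhotonDataError("negative counts")

    @property
    def n_bins(self) -> int:
        return int(len(self.counts))

    @property
    def total_counts(self) -> int:
        return int(self.counts.sum())

    @property
    def mean_rate(self) -> float:
        """Mean count rate in counts/s."""
        if self.n_bins == 0:
            return 0.0
        return self.total_counts / (self.n_bins * self.bin_width)

    @property
    def times(self) -> np.ndarray:
        return self.origin_time + self.bin_width * np.arange(self.n_bins)


@dataclass
class TCSPCHistogram:
    """Histogram of microtimes over one sync period."""

    channel_width: float  # ps
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.channel_width <= 0:
            raise PhotonDataError("channel_width must be positive")
        if np.any(self.counts < 0):
            raise PhotonDataError("negative counts")

    @property
    def n_channels(self) -> int:
        return int(len(self.counts))

    @property
    def total_photons(self) -> int:
        return int(self.counts.sum())

    @property
    def channel_starts(self) -> np.ndarray:
        """Left edge of each channel in ps."""
        return self.channel_width * np.arange(self.n_channels)

    @property
    def channel_centers(self) -> np.ndarray:
        return self.channel_starts + 0.5 * self.channel_width


@dataclass
class IRFModel:
    """Instrument response function: measured histogram or parametric Gaussian.

    Exactly one representation is active.  ``discretize`` renders either to
    a unit-sum kernel on a TCSPC channel grid spanning the sync period.
    """

    histogram: TCSPCHistogram | None = None
    fwhm_ps: float | None = None
    center_ps: float = 0.0

    def __post_init__(self) -> None:
        if (self.histogram is None) == (self.fwhm_ps is None):
            raise PhotonDataError("specify exactly one of histogram or fwhm_ps")
        if self.fwhm_ps is not None and self.fwhm_ps <= 0:
            raise PhotonDataError("fwhm_ps must be positive")

    @property
    def sigma_ps(self) -> float:
        if self.fwhm_ps is None:
            raise PhotonDataError("not a parametric IRF")
        return self.fwhm_ps / (2.0 * math.sqrt(2.0 * math.log(2.0)))

    def discretize(self, channel_width: float, n_channels: int) -> np.ndarray:
        """Unit-normalized IRF on ``n_channels`` channels of ``channel_width`` ps.

        The Gaussian form is wrapped periodically over the sync window so
        the kernel always sums to 1 regardless of its center.
        """
        if self.histogram is not None:
            h = self.histogram
            if h.n_channels == n_channels and math.isclose(h.channel_width, channel_width):
                k = h.counts.astype(float)
            else:  # resample by interpolation of the cumulative counts
                edges_src = h.channel_width * np.arange(h.n_channels + 1)
                cum = np.concatenate([[0.0], np.cumsum(h.counts.astype(float))])
                edges_dst = channel_width * np.arange(n_channels + 1)
                k = np.diff(np.interp(edges_dst, edges_src, cum, left=0.0, right=cum[-1]))
            s = k.sum()
            if s <= 0:
                raise PhotonDataError("IRF histogram has no counts")
            return k / s
        span = channel_width * n_channels
        if self.sigma_ps < 0.1 * channel_width:
            # effectively a delta kernel: split mass across the two
            # channels straddling the center
            k = np.zeros(n_channels)
            pos = (self.center_ps % span) / channel_width
            i = int(np.floor(pos))
            frac = pos - i
            k[i % n_channels] = 1.0 - frac
            k[(i + 1) % n_channels] = frac
            return k
        t = channel_width * (np.arange(n_channels) + 0.5)
        k = np.zeros(n_channels)
        # wrap +-4 periods; the Gaussian tail decays fast on a 25 ns window
        for w in range(-4, 5):
            k += np.exp(-0.5 * ((t - self.center_ps + w * span) / self.sigma_ps) ** 2)
        return k / k.sum()


# ----------------------------------------------------------------------
# Operations
# ----------------------------------------------------------------------

def bin_intensity(trace: TTTRTrace, bin_width: float) -> IntensityTrace:
    """Bin photon arrivals into a uniform intensity trace.

    A photon with arrival time t lands in bin ``floor(t / bin_width)``
    (half-open intervals, boundary photons go right).  Total counts are
    conserved.
    """
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    if trace.n_photons == 0:
        return IntensityTrace(bin_width=bin_width, counts=np.zeros(0, dtype=np.int64))
    # integer arithmetic on sync counts avoids float edge cases
    bin_sync = bin_width * trace.sync_rate
    idx = np.floor(trace.macrotimes / bin_sync).astype(np.int64)
    n_bins = max(int(idx[-1]) + 1, int(np.ceil(trace.duration / bin_width)))
    counts = np.bincount(idx, minlength=n_bins)
    return IntensityTrace(bin_width=bin_width, counts=counts)


def build_tcspc_histogram(
    trace: TTTRTrace, channel_width: float = DEFAULT_CHANNEL_WIDTH_PS
) -> TCSPCHistogram:
    """Histogram microtimes on a channel grid covering one sync period."""
    if channel_width <= 0:
        raise ValueError("channel_width must be positive")
    n_channels = int(math.ceil(trace.sync_period_ps / channel_width))
    if trace.n_photons == 0:
        return TCSPCHistogram(channel_width=channel_width, counts=np.zeros(n_channels, np.int64))
    idx = (trace.microtimes // int(round(channel_width))
           if float(channel_width).is_integer()
           else np.floor(trace.microtimes / channel_width).astype(np.int64))
    counts = np.bincount(idx.astype(np.int64), minlength=n_channels)
    return TCSPCHistogram(channel_width=channel_width, counts=counts)


# ----------------------------------------------------------------------
# Columnar text dialect
# ----------------------------------------------------------------------
# header:  # sync_rate_hz=40000000
#          # duration_s=60.0
#          # metadata={"dye": "Atto647N"}
# records: macrotime<TAB>microtime_ps<TAB>channel

def _write_text(trace: TTTRTrace, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write(f"# sync_rate_hz={trace.sync_rate:.10g}\n")
        fh.write(f"# duration_s={trace.duration:.10g}\n")
        if trace.metadata:
            fh.write(f"# metadata={json.dumps(trace.metadata)}\n")
        for mt, ut, ch in zip(trace.macrotimes, trace.microtimes, trace.channels):
            fh.write(f"{mt}\t{ut}\t{ch}\n")


def _read_text(path: Path) -> TTTRTrace:
    sync_rate = 40e6
    duration = None
    metadata: dict = {}
    mac, mic, cha = [], [], []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("sync_rate_hz="):
                    sync_rate = float(body.split("=", 1)[1])
                elif body.startswith("duration_s="):
                    duration = float(body.split("=", 1)[1])
                elif body.startswith("metadata="):
                    metadata = json.loads(body.split("=", 1)[1])
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise PhotonDataError(f"{path}: malformed record at line {lineno}: {line!r}")
            try:
                mac.append(int(parts[0]))
                mic.append(int(parts[1]))
                cha.append(int(parts[2]))
            except ValueError as exc:
                raise PhotonDataError(
                    f"{path}: non-integer field at line {lineno}: {line!r}"
                ) from exc
    return TTTRTrace(
        macrotimes=np.array(mac, np.int64),
        microtimes=np.array(mic, np.int64),
        channels=np.array(cha, np.int16),
        sync_rate=sync_rate,
        duration=duration,
        metadata=metadata,
    )


# ----------------------------------------------------------------------
# Photon-HDF5 (minimal layout)
# ----------------------------------------------------------------------

def _write_hdf5(trace: TTTRTrace, path: Path) -> None:
    with h5py.File(path, "w") as f:
        f.create_dataset("acquisition_duration", data=float(trace.duration))
        pd = f.create_group("photon_data")
        pd.create_dataset("timestamps", data=trace.macrotimes)
        pd.create_dataset("nanotimes", data=trace.microtimes)
        pd.create_dataset("detectors", data=trace.channels)
        ts = pd.create_group("timestamps_specs")
        ts.create_dataset("timestamps_unit", data=1.0 / trace.sync_rate)
        ns = pd.create_group("nanotimes_specs")
        ns.create_dataset("tcspc_unit", data=1e-12)
        if trace.metadata:
            f.create_dataset("user/metadata", data=json.dumps(trace.metadata))


def _read_hdf5(path: Path) -> TTTRTrace:
    with h5py.File(path, "r") as f:
        try:
            pd = f["photon_data"]
            mac = pd["timestamps"][()]
            unit = float(pd["timestamps_specs/timestamps_unit"][()])
            mic = pd["nanotimes"][()] if "nanotimes" in pd else np.zeros(len(mac), np.int64)
            cha = pd["detectors"][()] if "detectors" in pd else np.zeros(len(mac), np.int16)
        except KeyError as exc:
            raise PhotonDataError(f"{path}: not a recognized Photon-HDF5 layout: {exc}") from exc
        if "nanotimes_specs/tcspc_unit" in pd:
            mic = np.asarray(mic) * (float(pd["nanotimes_specs/tcspc_unit"][()]) * 1e12)
            mic = np.rint(mic).astype(np.int64)
        duration = float(f["acquisition_duration"][()]) if "acquisition_duration" in f else None
        meta = json.loads(f["user/metadata"][()]) if "user/metadata" in f else {}
    return TTTRTrace(
        macrotimes=np.asarray(mac, np.int64),
        microtimes=np.asarray(mic, np.int64),
        channels=np.asarray(cha, np.int16),
        sync_rate=1.0 / unit,
        duration=duration,
        metadata=meta,
    )


def read_photon_file(path: str | Path, format_hint: str | None = None) -> TTTRTrace:
    """Read a photon stream from Photon-HDF5 or the columnar text dialect.

    The format is taken from ``format_hint`` ("hdf5" | "text") or inferred
    from the file extension (.h5/.hdf5 vs anything else).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = format_hint or ("hdf5" if path.suffix.lower() in {".h5", ".hdf5"} else "text")
    if fmt == "hdf5":
        return _read_hdf5(path)
    if fmt == "text":
        return _read_text(path)
    raise ValueError(f"unknown format {fmt!r}")


def write_photon_file(trace: TTTRTrace, path: str | Path, format_hint: str | None = None) -> None:
    """Write a photon stream (format chosen as in :func:`read_photon_file`)."""
    path = Path(path)
    fmt = format_hint or ("hdf5" if path.suffix.lower() in {".h5", ".hdf5"} else "text")
    if fmt == "hdf5":
        _write_hdf5(trace, path)
    elif fmt == "text":
        _write_text(trace, path)
    else:
        raise ValueError(f"unknown format {fmt!r}")


# ----------------------------------------------------------------------
# 2-column CSV for TCSPC histograms / measured IRFs
# ----------------------------------------------------------------------

def write_histogram_csv(hist: TCSPCHistogram, path: str | Path) -> None:
    arr = np.column_stack([hist.channel_starts, hist.counts])
    np.savetxt(path, arr, fmt="%.6g,%d", header="channel_start_ps,counts", comments="")


def read_histogram_csv(path: str | Path) -> TCSPCHistogram:
    arr = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if arr.shape[1] != 2:
        raise PhotonDataError(f"{path}: expected 2 columns (channel_start_ps, counts)")
    starts = arr[:, 0]
    if len(starts) < 2:
        raise PhotonDataError(f"{path}: need at least 2 channels")
    width = float(starts[1] - starts[0])
    return TCSPCHistogram(channel_width=width, counts=arr[:, 1].astype(np.int64))
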