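"""Readers and writers for the package's plain-text and binary formats.

All tabular data travel as CSV with a header row; series-level metadata
(F0, concentration unit, lipid concentration) is stored in leading
``# key=value`` comment lines so a titration file is self-contained.
Photon streams have two mirrored encodings: a two-column CSV
(macro_time_s, micro_time_ns) and a packed little-endian binary with an
8-byte magic header for large streams.
"""
from __future__ import annotations

import struct
from pathlib import Path

import numpy as np
import pandas as pd

from .exceptions import ValidationError
from .types import (CorrelationCurve, PhotonStream, PolarizedReading,
                    Spectrum, TitrationSeries)

STREAM_MAGIC = b"FLBPHT01"


def _write_with_meta(path, df: pd.DataFrame, meta: dict) -> None:
    with open(path, "w") as fh:
        for k, v in meta.items():
            if v is not None:
                fh.write(f"# {k}={v}\n")
        df.to_csv(fh, index=False)


def _read_meta(path) -> dict:
    meta = {}
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            k, _, v = line[1:].strip().partition("=")
            meta[k.strip()] = v.strip()
    return meta


def write_titration_csv(path, series: TitrationSeries) -> None:
    df = pd.DataFrame({"quencher_conc": series.quencher_conc, "F": series.F})
    if series.replicate_id is not None:
        df["replicate_id"] = series.replicate_id
    _write_with_meta(path, df, {"F0": series.F0, "unit": series.unit,
                                "lip_conc": series.lip_conc})


def read_titration_csv(path) -> TitrationSeries:
    meta = _read_meta(path)
    if "F0" not in meta:
        raise ValidationError(f"{path}: missing '# F0=' metadata line")
    df = pd.read_csv(path, comment="#")
    lip = meta.get("lip_conc")
    return TitrationSeries(
        df["quencher_conc"].to_numpy(), df["F"].to_numpy(),
        F0=float(meta["F0"]), unit=meta.get("unit", "uM"),
        replicate_id=df["replicate_id"].to_numpy() if "replicate_id" in df else None,
        lip_conc=float(lip) if lip not in (None, "", "None") else None)


def write_polarized_csv(path, readings: list[PolarizedReading]) -> None:
    pd.DataFrame({"I_par": [r.I_par for r in readings],
                  "I_perp": [r.I_perp for r in readings],
                  "G": [r.G for r in readings]}).to_csv(path, index=False)


def read_polarized_csv(path) -> list[PolarizedReading]:
    df = pd.read_csv(path, comment="#")
    return [PolarizedReading(row.I_par, row.I_perp, row.G)
            for row in df.itertuples()]


def write_spectrum_csv(path, spectrum: Spectrum) -> None:
    _write_with_meta(path, pd.DataFrame({"wavenumber": spectrum.wavenumber,
                                         "absorbance": spectrum.absorbance}),
                     {"label": spectrum.label or None})


def read_spectrum_csv(path) -> Spectrum:
    meta = _read_meta(path)
    df = pd.read_csv(path, comment="#")
    cols = list(df.columns)
    return Spectrum(df[cols[0]].to_numpy(), df[cols[1]].to_numpy(),
                    label=meta.get("label", ""))


def write_correlation_csv(path, curve: CorrelationCurve) -> None:
    df = pd.DataFrame({"lag_s": curve.lags, "G": curve.G})
    if curve.stderr is not None:
        df["stderr"] = curve.stderr
    df.to_csv(path, index=False)


def read_correlation_csv(path) -> CorrelationCurve:
    df = pd.read_csv(path, comment="#")
    return CorrelationCurve(df["lag_s"].to_numpy(), df["G"].to_numpy(),
                            df["stderr"].to_numpy() if "stderr" in df else None)


def write_photon_csv(path, stream: PhotonStream) -> None:
    meta = {k: stream.meta[k] for k in ("duration", "pulse_period_ns")
            if k in stream.meta}
    _write_with_meta(path, pd.DataFrame({"macro_time_s": stream.macro_times,
                                         "micro_time_ns": stream.micro_times}),
                     meta)


def read_photon_csv(path) -> PhotonStream:
    meta = _read_meta(path)
    df = pd.read_csv(path, comment="#")
    parsed = {k: float(v) for k, v in meta.items()}
    return PhotonStream(df["macro_time_s"].to_numpy(),
                        df["micro_time_ns"].to_numpy(), parsed)


def write_photon_binary(path, stream: PhotonStream) -> None:
    """Packed stream: magic, n (uint64), duration + pulse period (f64),
    then n macro-times and n micro-times as little-endian float64."""
    n = len(stream)
    with open(path, "wb") as fh:
        fh.write(STREAM_MAGIC)
        fh.write(struct.pack("<Qdd", n, stream.duration,
                             float(stream.meta.get("pulse_period_ns", 0.0))))
        fh.write(stream.macro_times.astype("<f8").tobytes())
        fh.write(stream.micro_times.astype("<f8").tobytes())


def read_photon_binary(path) -> PhotonStream:
    with open(path, "rb") as fh:
        magic = fh.read(8)
        if magic != STREAM_MAGIC:
            raise ValidationError(f"{path}: bad magic {magic!r}")
        n, duration, period = struct.unpack("<Qdd", fh.read(24))
        macro = np.frombuffer(fh.read(8 * n), dtype="<f8")
        micro = np.frombuffer(fh.read(8 * n), dtype="<f8")
    meta = {"duration": duration}
    if period > 0:
        meta["pulse_period_ns"] = period
    return PhotonStream(macro.copy(), micro.copy(), meta)


def read_photon_stream(path) -> PhotonStream:
    """Dispatch on the magic header: binary if present, else CSV."""
    path = Path(path)
    with open(path, "rb") as fh:
        if fh.read(8) == STREAM_MAGIC:
            return read_photon_binary(path)
    return read_photon_csv(path)
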