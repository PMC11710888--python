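"""Readers and writers for raw recordings, truth sidecars and result tables.

The canonical raw format is long-format delimited text with columns
(time_s, channel_id, wavelength_nm, intensity) and a ``# sampling_rate_hz``
header line, chosen for transparency and human-readable fixtures.  A thin
read-only adapter accepts the continuous-wave subset of SNIRF (HDF5) files.
Readers validate and reject malformed input; they never repair it.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .montage import Montage, Schedule
from .recording import RawRecording
from .simulate import HRFParams, SimTruth

__all__ = [
    "write_raw",
    "read_raw",
    "read_snirf_subset",
    "write_results",
    "write_truth",
    "read_truth",
]

_TIME_TOL_S = 1e-6


def write_raw(raw: RawRecording, path) -> None:
    """Write a recording as long-format TSV with a sampling-rate header."""
    t = raw.time_s
    cids = raw.montage.channel_ids
    wls = raw.montage.wavelengths_nm
    with open(path, "w") as fh:
        fh.write(f"# sampling_rate_hz: {raw.sampling_rate_hz:.6f}\n")
        fh.write("time_s\tchannel_id\twavelength_nm\tintensity\n")
        for c, cid in enumerate(cids):
            for w, wl in enumerate(wls):
                col = raw.intensity[:, c, w]
                for i in range(raw.n_samples):
                    fh.write(f"{t[i]:.4f}\t{cid}\t{wl:g}\t{col[i]:.9g}\n")


def read_raw(path, montage: Montage, schedule: Schedule) -> RawRecording:
    """Read the long-format raw file back into a RawRecording.

    Validates that every montage channel has both wavelengths, that each
    channel/wavelength series sits on a uniform time grid, and that all
    intensities are positive.
    """
    with open(path) as fh:
        first = fh.readline()
        if not first.startswith("# sampling_rate_hz:"):
            raise ValueError(f"{path}: missing '# sampling_rate_hz' header")
        fs = float(first.split(":", 1)[1])
        df = pd.read_csv(fh, sep="\t")
    required = {"time_s", "channel_id", "wavelength_nm", "intensity"}
    if not required.issubset(df.columns):
        raise ValueError(f"{path}: missing columns {sorted(required - set(df.columns))}")

    file_chans = set(df["channel_id"].unique())
    unknown = file_chans - set(montage.channel_ids)
    if unknown:
        raise ValueError(f"{path}: channels {sorted(unknown)} not in montage")

    wls = tuple(montage.wavelengths_nm)
    n = None
    cube = None
    for c, cid in enumerate(montage.channel_ids):
        for w, wl in enumerate(wls):
            sub = df[(df["channel_id"] == cid) & (np.isclose(df["wavelength_nm"], wl))]
            if sub.empty:
                raise ValueError(f"{path}: channel Ch{cid} missing wavelength {wl:g} nm")
            sub = sub.sort_values("time_s")
            tt = sub["time_s"].to_numpy()
            if n is None:
                n = len(tt)
                cube = np.empty((n, montage.n_channels, 2))
            elif len(tt) != n:
                raise ValueError(f"{path}: channel Ch{cid} has inconsistent sample count")
            expected = np.arange(n) / fs
            if np.max(np.abs(tt - expected)) > _TIME_TOL_S:
                raise ValueError(f"{path}: non-uniform time grid on channel Ch{cid}")
            vals = sub["intensity"].to_numpy(dtype=float)
            if np.any(vals <= 0) or np.any(~np.isfinite(vals)):
                raise ValueError(f"{path}: nonpositive intensity on channel Ch{cid}")
            cube[:, c, w] = vals
    return RawRecording(
        intensity=cube,
        sampling_rate_hz=fs,
        schedule=schedule,
        montage=montage.with_sampling_rate(fs),
    )


def read_snirf_subset(path, montage: Montage, schedule: Schedule) -> RawRecording:
    """Read the continuous-wave intensity subset of a SNIRF (HDF5) file.

    Supports a single /nirs/data1 block with dataType 1 (CW amplitude) and
    exactly two wavelengths on a uniform time grid; anything else is
    rejected loudly.
    """
    try:
        fh = h5py.File(path, "r")
    except OSError as exc:
        raise ValueError(f"{path}: not a readable HDF5/SNIRF file") from exc
    with fh:
        if "nirs" not in fh:
            raise ValueError(f"{path}: no /nirs group (not SNIRF)")
        nirs = fh["nirs"]
        if "data1" not in nirs:
            raise ValueError(f"{path}: no /nirs/data1 data block")
        data = nirs["data1"]
        probe = nirs["probe"]
        wls = np.asarray(probe["wavelengths"][()], dtype=float).ravel()
        if wls.size != 2:
            raise ValueError("exactly 2 wavelengths supported")
        ts = np.asarray(data["dataTimeSeries"][()], dtype=float)
        time = np.asarray(data["time"][()], dtype=float).ravel()
        if time.size < 2:
            raise ValueError(f"{path}: empty time vector")
        dt = np.diff(time)
        if np.max(np.abs(dt - dt[0])) > _TIME_TOL_S:
            raise ValueError(f"{path}: non-uniform time grid")
        fs = 1.0 / dt[0]

        # measurementList entries map columns to (source, detector, wavelength)
        cols = []
        k = 1
        while f"measurementList{k}" in data:
            ml = data[f"measurementList{k}"]
            dtype = int(np.asarray(ml["dataType"][()]))
            if dtype != 1:
                raise ValueError(f"{path}: measurement {k} dataType {dtype} is not CW amplitude")
            cols.append(
                (
                    int(np.asarray(ml["sourceIndex"][()])),
                    int(np.asarray(ml["detectorIndex"][()])),
                    int(np.asarray(ml["wavelengthIndex"][()])),
                )
            )
            k += 1
        if not cols:
            raise ValueError(f"{path}: no measurementList entries")
        if ts.shape != (time.size, len(cols)):
            raise ValueError(f"{path}: dataTimeSeries shape does not match time/measurements")

        pair_to_chan = {(c.source_id, c.detector_id): i for i, c in enumerate(montage.channels)}
        cube = np.full((time.size, montage.n_channels, 2), np.nan)
        for j, (src, det, wli) in enumerate(cols):
            if (src, det) not in pair_to_chan:
                raise ValueError(f"{path}: source {src}/detector {det} not in montage")
            cube[:, pair_to_chan[(src, det)], wli - 1] = ts[:, j]
        if np.isnan(cube).any():
            missing = [montage.channel_ids[i] for i in np.unique(np.where(np.isnan(cube))[1])]
            raise ValueError(f"{path}: missing wavelength data for channels {missing}")
    return RawRecording(
        intensity=cube,
        sampling_rate_hz=fs,
        schedule=schedule,
        montage=montage.with_sampling_rate(fs),
    )


# ---------------------------------------------------------------------------
# results tables
# ---------------------------------------------------------------------------

def _fmt(x) -> str:
    if x is None or (isinstance(x, float) and np.isnan(x)):
        return "NA"
    if isinstance(x, (bool, np.bool_)):
        return str(bool(x))
    if isinstance(x, (int, np.integer)):
        return str(int(x))
    if isinstance(x, float):
        return f"{x:.6g}"
    return str(x)


def _write_table(df: pd.DataFrame, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("\t".join(df.columns) + "\n")
        for _, row in df.iterrows():
            fh.write("\t".join(_fmt(v) for v in row) + "\n")


def write_results(
    out_dir,
    montage: Montage,
    group_table: pd.DataFrame,
    channel_stats: pd.DataFrame,
    pairwise_stats: pd.DataFrame | None = None,
    qc_table: pd.DataFrame | None = None,
) -> dict[str, Path]:
    """Write the group summary, test statistics and QC report as TSV.

    The group summary has one row per channel with its region label and
    ``mean +/- SD`` cells per condition (NA where a channel was rejected
    for every subject); floats are at 6 significant digits and output is
    deterministic for identical inputs.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    rows = []
    conditions = sorted({c.rsplit("_", 1)[0] for c in group_table.columns if c.endswith("_mean")})
    for _, r in group_table.sort_values("channel_id").iterrows():
        cid = int(r["channel_id"])
        row = {"channel": montage.channel(cid).label}
        for cond in conditions:
            mean, sd = r.get(f"{cond}_mean"), r.get(f"{cond}_sd")
            if mean is None or (isinstance(mean, float) and np.isnan(mean)):
                cell = "NA"
            else:
                cell = f"{mean:.6g} +/- {sd:.6g}" if sd == sd else f"{mean:.6g} +/- NA"
                if bool(r.get(f"{cond}_significant", False)):
                    cell += " *"
            row[cond] = cell
        rows.append(row)
    summary_path = out_dir / "group_summary.tsv"
    _write_table(pd.DataFrame(rows), summary_path)
    written["group_summary"] = summary_path

    stats_path = out_dir / "channel_stats.tsv"
    _write_table(channel_stats, stats_path)
    written["channel_stats"] = stats_path

    if pairwise_stats is not None:
        pw_path = out_dir / "pairwise_stats.tsv"
        _write_table(pairwise_stats, pw_path)
        written["pairwise_stats"] = pw_path

    if qc_table is not None:
        qc_path = out_dir / "qc_report.tsv"
        _write_table(qc_table, qc_path)
        written["qc_report"] = qc_path
    return written


# ---------------------------------------------------------------------------
# ground-truth sidecar
# ---------------------------------------------------------------------------

def write_truth(truth: SimTruth, path) -> None:
    doc = {
        "active_map": {k: sorted(v) for k, v in truth.active_map.items()},
        "hbo_amplitude_um": truth.hbo_amplitude_um,
        "hbr_ratio": truth.hbr_ratio,
        "hrf": {
            "peak_delay_s": truth.hrf.peak_delay_s,
            "undershoot_delay_s": truth.hrf.undershoot_delay_s,
            "undershoot_ratio": truth.hrf.undershoot_ratio,
            "dispersion_s": truth.hrf.dispersion_s,
        },
        "seed": truth.seed,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_truth(path) -> SimTruth:
    with open(path) as fh:
        doc = json.load(fh)
    return SimTruth(
        active_map={k: frozenset(v) for k, v in doc["active_map"].items()},
        hbo_amplitude_um=doc["hbo_amplitude_um"],
        hbr_ratio=doc["hbr_ratio"],
        hrf=HRFParams(**doc["hrf"]),
        seed=doc["seed"],
    )
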