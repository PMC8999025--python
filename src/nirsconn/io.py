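"""Readers and writers: TSV channel x time series, connectivity TSV,
SNIRF-style HDF5 intensity recordings, BrainNet-Viewer exports, cohort
manifests.

All text output uses a fixed ``%.10g`` float format so that a run with a
fixed seed is byte-reproducible.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np

from .connectivity import BinaryNetwork, ConnectivityMatrix
from .errors import DataError
from .preprocess import HbTimeSeries, RawIntensityRecording
from .synthetic import SyntheticCohort

FLOAT_FMT = "%.10g"


def _labels(n: int) -> list[str]:
    return [f"CH{i:02d}" for i in range(1, n + 1)]


# ---------------------------------------------------------------------------
# Hb TSV
# ---------------------------------------------------------------------------

def write_hb_tsv(hb: HbTimeSeries, path) -> None:
    """Channel x time TSV; metadata in '#'-prefixed header lines."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write(f"# fs_hz={hb.fs_hz!r}\n")
        fh.write(f"# chromophore={hb.chromophore}\n")
        fh.write(f"# subject_id={hb.subject_id}\n")
        fh.write(f"# session={hb.session}\n")
        for label, row in zip(_labels(hb.n_channels), hb.values):
            fh.write(label + "\t" + "\t".join(FLOAT_FMT % v for v in row) + "\n")


def read_hb_tsv(path) -> HbTimeSeries:
    path = Path(path)
    if not path.exists():
        raise DataError(f"missing file: {path}")
    meta = {"fs_hz": "7.4074", "chromophore": "oxy", "subject_id": "", "session": "pre"}
    rows = []
    with path.open() as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
                continue
            parts = line.split("\t")
            rows.append([float(v) for v in parts[1:]])
    if not rows:
        raise DataError(f"no channel rows in {path}")
    return HbTimeSeries(np.array(rows), fs_hz=float(meta["fs_hz"]),
                        chromophore=meta["chromophore"],  # type: ignore[arg-type]
                        subject_id=meta["subject_id"], session=meta["session"])


# ---------------------------------------------------------------------------
# connectivity TSV
# ---------------------------------------------------------------------------

def write_cor_tsv(mat: ConnectivityMatrix, path) -> None:
    path = Path(path)
    labels = _labels(mat.n_channels)
    with path.open("w") as fh:
        fh.write("\t" + "\t".join(labels) + "\n")
        for label, row in zip(labels, mat.values):
            fh.write(label + "\t" + "\t".join(FLOAT_FMT % v for v in row) + "\n")


def read_cor_tsv(path, subject_id: str = "", session: str = "") -> ConnectivityMatrix:
    path = Path(path)
    if not path.exists():
        raise DataError(f"missing file: {path}")
    rows = []
    with path.open() as fh:
        header = fh.readline()
        if not header.startswith("\t"):
            raise DataError(f"malformed connectivity TSV header in {path}")
        for line in fh:
            parts = line.rstrip("\n").split("\t")
            if len(parts) < 2:
                continue
            rows.append([float(v) for v in parts[1:]])
    values = np.array(rows)
    # re-symmetrize: text round-trip keeps ~1e-10 but the container wants exact
    values = (values + values.T) / 2.0
    np.fill_diagonal(values, 1.0)
    return ConnectivityMatrix(values, subject_id=subject_id, session=session)


# ---------------------------------------------------------------------------
# SNIRF-style HDF5 intensity recordings
# ---------------------------------------------------------------------------

def write_snirf(rec: RawIntensityRecording, path) -> None:
    """Minimal SNIRF-layout HDF5: /nirs/data1/dataTimeSeries is time x
    (channel*wavelength), with a measurementList per column."""
    path = Path(path)
    nch, nwl, nt = rec.intensities.shape
    data = rec.intensities.reshape(nch * nwl, nt).T  # time x measurement
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        d1 = nirs.create_group("data1")
        d1.create_dataset("dataTimeSeries", data=data)
        d1.create_dataset("time", data=np.arange(nt) / rec.fs_hz)
        for m in range(nch * nwl):
            ml = d1.create_group(f"measurementList{m + 1}")
            ml.create_dataset("sourceIndex", data=m // nwl + 1)
            ml.create_dataset("detectorIndex", data=m // nwl + 1)
            ml.create_dataset("wavelengthIndex", data=m % nwl + 1)
        probe = nirs.create_group("probe")
        probe.create_dataset("wavelengths", data=np.array(rec.wavelengths_nm, dtype=float))
        meta = nirs.create_group("metaDataTags")
        meta.create_dataset("SubjectID", data=rec.subject_id)
        meta.create_dataset("Session", data=rec.session)
        if rec.baseline_intensity is not None:
            meta.create_dataset("BaselineIntensity", data=rec.baseline_intensity)


def read_snirf(path) -> RawIntensityRecording:
    path = Path(path)
    if not path.exists():
        raise DataError(f"missing file: {path}")
    with h5py.File(path, "r") as f:
        d1 = f["nirs/data1"]
        data = np.asarray(d1["dataTimeSeries"])  # time x measurement
        time = np.asarray(d1["time"])
        wavelengths = tuple(int(w) for w in np.asarray(f["nirs/probe/wavelengths"]))
        meta = f["nirs/metaDataTags"]
        subject_id = meta["SubjectID"][()].decode() if "SubjectID" in meta else ""
        session = meta["Session"][()].decode() if "Session" in meta else "pre"
        baseline = np.asarray(meta["BaselineIntensity"]) if "BaselineIntensity" in meta else None
    nwl = len(wavelengths)
    nt, nm = data.shape
    nch = nm // nwl
    fs = 1.0 / np.median(np.diff(time)) if nt > 1 else 1.0
    intensities = data.T.reshape(nch, nwl, nt)
    return RawIntensityRecording(intensities, fs_hz=float(fs), wavelengths_nm=wavelengths,
                                 subject_id=subject_id, session=session,
                                 baseline_intensity=baseline)


# ---------------------------------------------------------------------------
# BrainNet-Viewer exports
# ---------------------------------------------------------------------------

def write_brainnet_edge(matrix_or_net, path) -> None:
    """BrainNet-Viewer .edge format: whitespace-separated square matrix."""
    if isinstance(matrix_or_net, BinaryNetwork):
        values = matrix_or_net.adjacency
    elif isinstance(matrix_or_net, ConnectivityMatrix):
        values = matrix_or_net.values
    else:
        values = np.asarray(matrix_or_net)
    with open(path, "w") as fh:
        for row in values:
            fh.write("\t".join(FLOAT_FMT % v for v in row) + "\n")


# ---------------------------------------------------------------------------
# cohort manifest
# ---------------------------------------------------------------------------

def write_cohort_tsv(cohort: SyntheticCohort, outdir) -> Path:
    """Write every recording as Hb TSV plus a JSON manifest; returns manifest path."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    entries = []
    for i, (pre, post) in enumerate(cohort.subjects):
        sid = pre.subject_id or f"{cohort.group_label}-{i + 1:02d}"
        files = {}
        for sess, hb in (("pre", pre), ("post", post)):
            fname = f"{sid}_{sess}_hb.tsv"
            write_hb_tsv(hb, outdir / fname)
            files[sess] = fname
        entries.append({"subject_id": sid, "files": files})
    manifest = {
        "group_label": cohort.group_label,
        "n_subjects": cohort.n_subjects,
        "fs_hz": cohort.fs_hz,
        "duration_s": cohort.duration_s,
        "seed": cohort.seed,
        "subjects": entries,
    }
    mpath = outdir / f"cohort_{cohort.group_label}.json"
    with mpath.open("w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return mpath


def read_cohort_tsv(manifest_path) -> tuple[str, list[tuple[HbTimeSeries, HbTimeSeries]]]:
    """Read back a cohort written by write_cohort_tsv: (group_label, subjects)."""
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise DataError(f"missing file: {manifest_path}")
    with manifest_path.open() as fh:
        manifest = json.load(fh)
    root = manifest_path.parent
    subjects = []
    for entry in manifest["subjects"]:
        pre = read_hb_tsv(root / entry["files"]["pre"])
        post = read_hb_tsv(root / entry["files"]["post"])
        subjects.append((pre, post))
    return manifest["group_label"], subjects
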