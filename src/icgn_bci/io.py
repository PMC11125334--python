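"""Readers and writers: delimited text with JSON sidecar, a minimal SNIRF
(HDF5) subset, labeled datasets, model parameter archives and histories."""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .cells import CellParameters
from .preprocessing import AbsorbanceSeries, HemoglobinSeries, LabeledDataset

__all__ = [
    "write_hemoglobin_csv",
    "read_hemoglobin_csv",
    "write_labeled_csv",
    "read_labeled_csv",
    "write_snirf",
    "read_snirf",
    "save_cell_parameters",
    "load_cell_parameters",
]


def write_hemoglobin_csv(hemo: HemoglobinSeries, path: str | Path) -> None:
    """CSV with hbo/hbr columns per channel plus a ``<stem>.json`` sidecar (fs, channels)."""
    path = Path(path)
    cols = {}
    for i, ch in enumerate(hemo.channel_names):
        cols[f"hbo_{ch}"] = hemo.hbo[:, i]
    for i, ch in enumerate(hemo.channel_names):
        cols[f"hbr_{ch}"] = hemo.hbr[:, i]
    pd.DataFrame(cols).to_csv(path, index=False)
    meta = {"fs": hemo.fs, "channels": list(hemo.channel_names), "units": "uM"}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_hemoglobin_csv(path: str | Path) -> HemoglobinSeries:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    df = pd.read_csv(path)
    chans = meta["channels"]
    hbo = df[[f"hbo_{c}" for c in chans]].to_numpy()
    hbr = df[[f"hbr_{c}" for c in chans]].to_numpy()
    return HemoglobinSeries(hbo=hbo, hbr=hbr, fs=float(meta["fs"]), channel_names=list(chans))


def write_labeled_csv(labeled: LabeledDataset, path: str | Path) -> None:
    path = Path(path)
    df = pd.DataFrame(labeled.features, columns=[f"f{i}" for i in range(labeled.features.shape[1])])
    df.insert(0, "label", labeled.labels)
    df.insert(1, "trial", labeled.trial_ids)
    df.to_csv(path, index=False)
    meta = {"fs": labeled.fs, "class_names": labeled.class_names}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_labeled_csv(path: str | Path) -> LabeledDataset:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    df = pd.read_csv(path)
    feats = df[[c for c in df.columns if c.startswith("f")]].to_numpy()
    return LabeledDataset(
        features=feats,
        labels=df["label"].to_numpy(dtype=int),
        trial_ids=df["trial"].to_numpy(dtype=int),
        class_names=list(meta["class_names"]),
        fs=float(meta["fs"]),
    )


def write_snirf(series: AbsorbanceSeries | HemoglobinSeries, path: str | Path) -> None:
    """Minimal SNIRF layout: /nirs/data1 with dataTimeSeries, time and a measurement list.

    Absorbance is stored as optical-density change (dataType 99999, label
    "dOD"); hemoglobin as processed concentrations ("HbO"/"HbR").
    """
    path = Path(path)
    with h5py.File(path, "w") as f:
        f.create_dataset("formatVersion", data="1.0")
        nirs = f.create_group("nirs")
        data = nirs.create_group("data1")
        if isinstance(series, AbsorbanceSeries):
            T, C, _ = series.delta_od.shape
            mat = series.delta_od.reshape(T, 2 * C, order="F")  # wavelength-major blocks
            labels = ["dOD"] * (2 * C)
            wl_index = [1] * C + [2] * C
            probe = nirs.create_group("probe")
            probe.create_dataset("wavelengths", data=np.asarray(series.wavelengths))
            data.attrs["kind"] = "absorbance"
            data.attrs["source_detector_distance_cm"] = series.source_detector_distance_cm
            data.attrs["dpf"] = series.dpf
        else:
            T, C = series.hbo.shape
            mat = np.concatenate([series.hbo, series.hbr], axis=1)
            labels = ["HbO"] * C + ["HbR"] * C
            wl_index = [0] * (2 * C)
            data.attrs["kind"] = "hemoglobin"
        data.create_dataset("dataTimeSeries", data=mat)
        data.create_dataset("time", data=np.arange(T) / series.fs)
        for m in range(2 * C):
            ml = data.create_group(f"measurementList{m + 1}")
            ml.create_dataset("sourceIndex", data=m % C + 1)
            ml.create_dataset("detectorIndex", data=m % C + 1)
            ml.create_dataset("dataType", data=99999)
            ml.create_dataset("dataTypeLabel", data=labels[m])
            ml.create_dataset("wavelengthIndex", data=wl_index[m])
        nirs.create_group("metaDataTags").create_dataset(
            "channel_names", data=[c.encode() for c in series.channel_names]
        )


def read_snirf(path: str | Path) -> AbsorbanceSeries | HemoglobinSeries:
    with h5py.File(path, "r") as f:
        data = f["nirs/data1"]
        mat = np.asarray(data["dataTimeSeries"])
        time = np.asarray(data["time"])
        fs = 1.0 / float(np.median(np.diff(time)))
        chan = [c.decode() for c in np.asarray(f["nirs/metaDataTags/channel_names"])]
        C = len(chan)
        if data.attrs["kind"] == "hemoglobin":
            return HemoglobinSeries(
                hbo=mat[:, :C], hbr=mat[:, C:], fs=fs, channel_names=chan
            )
        wavelengths = tuple(np.asarray(f["nirs/probe/wavelengths"]))
        dod = mat.reshape(mat.shape[0], C, 2, order="F")
        return AbsorbanceSeries(
            delta_od=dod,
            fs=fs,
            wavelengths=(float(wavelengths[0]), float(wavelengths[1])),
            source_detector_distance_cm=float(data.attrs["source_detector_distance_cm"]),
            dpf=float(data.attrs["dpf"]),
            channel_names=chan,
        )


def save_cell_parameters(params: CellParameters, path: str | Path) -> None:
    """Named-array archive (NPZ) with the canonical weight names (wxi, whi, wci, bi, ...)."""
    meta = dict(
        cell_kind=params.cell_kind,
        input_dim=params.input_dim,
        hidden_dim=params.hidden_dim,
        share_candidate_with_forget=int(params.share_candidate_with_forget),
        share_output_context_with_forget=int(params.share_output_context_with_forget),
        candidate_uses_cell_context=int(params.candidate_uses_cell_context),
    )
    np.savez(
        path,
        __meta__=json.dumps(meta),
        **params.named_arrays(),
    )


def load_cell_parameters(path: str | Path) -> CellParameters:
    with np.load(path, allow_pickle=False) as z:
        meta = json.loads(str(z["__meta__"]))
        arrays = {k: z[k] for k in z.files if k != "__meta__"}
    from .cells import init_cell_parameters

    params = init_cell_parameters(
        meta["cell_kind"],
        meta["input_dim"],
        meta["hidden_dim"],
        "zeros",
        seed=0,
        share_candidate_with_forget=bool(meta["share_candidate_with_forget"]),
        share_output_context_with_forget=bool(meta["share_output_context_with_forget"]),
        candidate_uses_cell_context=bool(meta["candidate_uses_cell_context"]),
    )
    for name, arr in arrays.items():
        getattr(params, name)[...] = arr
    return params
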