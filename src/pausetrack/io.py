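"""File I/O: WAV audio, TSV word boundaries, HDF5 EEG containers, EDF/BDF.

WAV files are written as 32-bit float PCM.  The word-boundary table is a TSV
with columns ``word_index, onset_s, offset_s, token``; a token containing an
apostrophe (a contraction) is a single word and therefore a single row.
"""

from __future__ import annotations

from pathlib import Path
from typing import List, Sequence, Tuple

import h5py
import numpy as np
import pandas as pd
from scipy.io import wavfile

from .datatypes import AnnotatedAudio, EEGRecording

WORD_COLUMNS = ["word_index", "onset_s", "offset_s", "token"]


def write_wav(path, samples: np.ndarray, fs: float) -> None:
    wavfile.write(str(path), int(round(fs)), np.asarray(samples, dtype=np.float32))


def read_wav(path) -> Tuple[np.ndarray, float]:
    fs, data = wavfile.read(str(path))
    data = np.asarray(data)
    if data.dtype.kind == "i":  # integer PCM -> dimensionless
        data = data / float(np.iinfo(data.dtype).max)
    if data.ndim == 2:  # average stereo to mono
        data = data.mean(axis=1)
    return data.astype(float), float(fs)


def write_word_boundaries(path, boundaries: Sequence[Tuple[float, float]],
                          tokens: Sequence[str] | None = None) -> None:
    if tokens is None:
        tokens = [f"w{i:04d}" for i in range(len(boundaries))]
    df = pd.DataFrame({
        "word_index": np.arange(len(boundaries)),
        "onset_s": [b[0] for b in boundaries],
        "offset_s": [b[1] for b in boundaries],
        "token": list(tokens),
    })
    df.to_csv(path, sep="\t", index=False, float_format="%.9g")


def read_word_boundaries(path) -> List[Tuple[float, float]]:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("onset_s", "offset_s") if c not in df.columns]
    if missing:
        raise ValueError(f"word-boundary table {path} lacks columns {missing}")
    return list(zip(df["onset_s"].astype(float), df["offset_s"].astype(float)))


def read_annotated_audio(wav_path, words_path, condition_label: str = "other"
                         ) -> AnnotatedAudio:
    samples, fs = read_wav(wav_path)
    boundaries = read_word_boundaries(words_path)
    return AnnotatedAudio(samples=samples, fs=fs, word_boundaries=boundaries,
                          condition_label=condition_label)


def write_eeg_h5(path, eeg: EEGRecording) -> None:
    with h5py.File(path, "w") as fh:
        dset = fh.create_dataset("data", data=eeg.data)
        dset.attrs["fs"] = eeg.fs
        dset.attrs["channel_names"] = [str(c) for c in eeg.channel_names]
        dset.attrs["subject_id"] = eeg.subject_id
        dset.attrs["segment_id"] = eeg.segment_id
        dset.attrs["condition_label"] = eeg.condition_label
        dset.attrs["band"] = eeg.band


def read_eeg_h5(path) -> EEGRecording:
    with h5py.File(path, "r") as fh:
        dset = fh["data"]
        return EEGRecording(
            data=dset[()],
            fs=float(dset.attrs["fs"]),
            channel_names=[str(c) for c in dset.attrs["channel_names"]],
            subject_id=str(dset.attrs["subject_id"]),
            segment_id=int(dset.attrs["segment_id"]),
            condition_label=str(dset.attrs["condition_label"]),
            band=str(dset.attrs["band"]),
        )


def read_eeg_edf(path, subject_id: str = "S00", segment_id: int = 0,
                 condition_label: str = "other") -> EEGRecording:
    """Read an EDF/BDF recording via MNE (data returned in volts by MNE; we
    convert to microvolts)."""
    import mne

    path = Path(path)
    if path.suffix.lower() == ".bdf":
        raw = mne.io.read_raw_bdf(path, preload=True, verbose="error")
    else:
        raw = mne.io.read_raw_edf(path, preload=True, verbose="error")
    return EEGRecording(data=raw.get_data() * 1e6, fs=float(raw.info["sfreq"]),
                        channel_names=list(raw.ch_names), subject_id=subject_id,
                        segment_id=segment_id, condition_label=condition_label)
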