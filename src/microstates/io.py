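"""Plain-text serialization of recordings and label sequences.

Recordings are written as a delimited channels x samples matrix with a JSON
sidecar carrying the sampling rate, montage and identity metadata; label
sequences as a three-column CSV (sample, label, fit_r).  All files use '.'
decimals and UTF-8 so outputs compare bit-exactly across runs.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .clustering import TemplateSet
from .fitting import LabelSequence
from .maps import Montage, Recording

__all__ = ["save_recording", "load_recording", "save_label_sequence", "load_label_sequence"]


def save_recording(rec: Recording, prefix: str | Path) -> None:
    """Write ``<prefix>.csv`` (channels x samples) and ``<prefix>.json``."""
    prefix = Path(prefix)
    np.savetxt(prefix.with_suffix(".csv"), rec.data, delimiter=",", fmt="%.10g")
    meta = {
        "srate": rec.srate,
        "subject_id": rec.subject_id,
        "session_id": rec.session_id,
        "day_id": rec.day_id,
        "channel_names": list(rec.montage.channel_names),
        "positions": rec.montage.positions.tolist(),
    }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def load_recording(prefix: str | Path) -> Recording:
    prefix = Path(prefix)
    meta = json.loads(prefix.with_suffix(".json").read_text())
    data = np.loadtxt(prefix.with_suffix(".csv"), delimiter=",", ndmin=2)
    montage = Montage(tuple(meta["channel_names"]), np.asarray(meta["positions"]))
    return Recording(data, meta["srate"], montage, subject_id=meta["subject_id"],
                     session_id=meta["session_id"], day_id=meta["day_id"])


def save_label_sequence(seq: LabelSequence, path: str | Path) -> None:
    pd.DataFrame({
        "sample": np.arange(seq.n_samples),
        "label": seq.labels,
        "fit_r": seq.fit_r,
    }).to_csv(path, index=False)


def load_label_sequence(path: str | Path, srate: float, templates: TemplateSet) -> LabelSequence:
    df = pd.read_csv(path)
    return LabelSequence(df["label"].to_numpy(int), df["fit_r"].to_numpy(float),
                        srate, templates)
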