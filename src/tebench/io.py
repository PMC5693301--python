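"""Persistence of trial ensembles and result tables.

Ensembles go to HDF5 (values plus fs/channels/provenance attributes);
per-trial CSV export is provided for inspection.
"""

from __future__ import annotations

import json
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .models import TrialEnsemble

__all__ = ["save_ensemble", "load_ensemble", "export_trials_csv"]


def save_ensemble(path, ensemble: TrialEnsemble) -> None:
    with h5py.File(path, "w") as f:
        dset = f.create_dataset("values", data=ensemble.values,
                                compression="gzip", compression_opts=4)
        dset.attrs["fs"] = ensemble.fs
        dset.attrs["channels"] = json.dumps(list(ensemble.channels))
        dset.attrs["provenance"] = json.dumps(ensemble.provenance)


def load_ensemble(path) -> TrialEnsemble:
    with h5py.File(path, "r") as f:
        dset = f["values"]
        return TrialEnsemble(
            values=np.asarray(dset),
            fs=float(dset.attrs["fs"]),
            channels=tuple(json.loads(dset.attrs["channels"])),
            provenance=json.loads(dset.attrs["provenance"]),
        )


def export_trials_csv(directory, ensemble: TrialEnsemble,
                      dataset: int = 0) -> list[Path]:
    """Write one CSV per trial of one dataset (columns = channels)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i_tr in range(ensemble.n_trials):
        df = pd.DataFrame(ensemble.values[dataset, i_tr].T,
                          columns=list(ensemble.channels))
        p = directory / f"dataset{dataset:03d}_trial{i_tr:03d}.csv"
        df.to_csv(p, index_label="sample")
        paths.append(p)
    return paths
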