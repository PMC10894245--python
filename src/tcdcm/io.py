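"""Persistence: HDF5 containers for spectra and inversion results, delimited
text exchange formats, YAML configuration."""

from __future__ import annotations

import numpy as np

from .model import N_POP, N_STATE_PER_POP, POPULATIONS
from .spectral import SpectralData

__all__ = [
    "save_spectra",
    "load_spectra",
    "spectra_to_text",
    "spectra_from_text",
    "save_inversion",
    "load_posterior_csv",
    "save_trajectory",
    "load_config",
    "save_config",
]


def save_spectra(path, spectra) -> None:
    """Write SpectralData objects to HDF5, layout
    /subjects/<id>/<condition>/{freqs, csd_real, csd_imag}.

    ``spectra`` is an iterable of SpectralData (subject/condition metadata
    required) or a {subject: {condition: SpectralData}} mapping.
    """
    import h5py
    if isinstance(spectra, dict):
        items = [s for conds in spectra.values() for s in conds.values()]
    else:
        items = list(spectra)
    with h5py.File(path, "w") as f:
        for sd in items:
            if sd.subject is None or sd.condition is None:
                raise ValueError("subject and condition metadata required")
            g = f.require_group(f"subjects/{sd.subject}/{sd.condition}")
            g.create_dataset("freqs", data=sd.freqs)
            g.create_dataset("csd_real", data=sd.S.real)
            g.create_dataset("csd_imag", data=sd.S.imag)


def load_spectra(path) -> dict:
    """Inverse of save_spectra: {subject: {condition: SpectralData}}."""
    import h5py
    out: dict = {}
    with h5py.File(path, "r") as f:
        for subject, conds in f["subjects"].items():
            out[subject] = {}
            for cond, g in conds.items():
                out[subject][cond] = SpectralData(
                    freqs=g["freqs"][()],
                    S=g["csd_real"][()] + 1j * g["csd_imag"][()],
                    subject=subject, condition=cond)
    return out


def spectra_to_text(path, sd: SpectralData) -> None:
    """Delimited-text exchange format: frequency plus re/im of the four
    matrix entries per row."""
    cols = [sd.freqs]
    for i in range(2):
        for j in range(2):
            cols += [sd.S[:, i, j].real, sd.S[:, i, j].imag]
    header = "freq_hz " + " ".join(
        f"re_S{i}{j} im_S{i}{j}" for i in range(2) for j in range(2))
    np.savetxt(path, np.column_stack(cols), header=header)


def spectra_from_text(path, subject=None, condition=None) -> SpectralData:
    arr = np.atleast_2d(np.loadtxt(path))
    freqs = arr[:, 0]
    S = np.empty((freqs.size, 2, 2), complex)
    k = 1
    for i in range(2):
        for j in range(2):
            S[:, i, j] = arr[:, k] + 1j * arr[:, k + 1]
            k += 2
    return SpectralData(freqs=freqs, S=S, subject=subject, condition=condition)


def save_inversion(path, result, csv_path=None) -> None:
    """Persist an InversionResult to HDF5 (and optionally a flat CSV of
    posterior means per parameter name)."""
    import h5py
    with h5py.File(path, "w") as f:
        f.create_dataset("mu", data=result.mu)
        f.create_dataset("Sigma", data=result.Sigma)
        f.create_dataset("F_trace", data=result.F_trace)
        f.create_dataset("weights", data=result.weights)
        f.create_dataset("predicted_freqs", data=result.predicted.freqs)
        f.create_dataset("predicted_real", data=result.predicted.S.real)
        f.create_dataset("predicted_imag", data=result.predicted.S.imag)
        f.attrs["h"] = result.h
        f.attrs["variance_explained"] = result.variance_explained
        f.attrs["converged"] = result.converged
        f.attrs["n_iter"] = result.n_iter
        f.attrs["config_hash"] = result.config_hash
        f.attrs["names"] = ",".join(result.names)
    if csv_path is not None:
        result.posterior_table().to_csv(csv_path, index=False)


def load_posterior_csv(path) -> dict:
    import pandas as pd
    df = pd.read_csv(path)
    return dict(zip(df["parameter"], df["posterior_mean"]))


def save_trajectory(path, t, traj, node_names=("frontal", "parietal")) -> None:
    """Export a state trajectory as delimited text (time, node, population, V)."""
    n_flat = traj.shape[1] // N_STATE_PER_POP
    stride = max(1, len(t) // traj.shape[0])
    with open(path, "w") as fh:
        fh.write("time_ms\tnode\tpopulation\tV_mV\n")
        for row, x in enumerate(traj):
            tt = t[min(row * stride, len(t) - 1)]
            for q in range(n_flat):
                node = node_names[q // N_POP]
                pop = POPULATIONS[q % N_POP]
                fh.write(f"{tt:.3f}\t{node}\t{pop}\t"
                         f"{x[q * N_STATE_PER_POP]:.6f}\n")


def load_config(path) -> dict:
    import yaml
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def save_config(path, cfg: dict) -> None:
    import yaml
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
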