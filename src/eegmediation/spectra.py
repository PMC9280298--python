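"""Scalp spectral pipeline for epoched resting EEG.

Average-reference re-referencing, cross-periodogram estimation with
Bartlett (epoch) averaging, log-power transformation with a global scale
factor correction, and projection of cross-spectral matrices through a
caller-supplied linear inverse operator.

Conventions
-----------
The one-sided PSD is normalized so that summing a channel's PSD over the
full non-negative DFT grid (DC through Nyquist) equals the epoch's mean
squared amplitude (Parseval).  A pure cosine of amplitude A at an
on-grid frequency therefore carries power A**2 / 2 in its bin.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

#: international 10/20 labels in the montage order used throughout
CHANNELS_1020 = (
    "Fp1", "Fp2", "F3", "F4", "C3", "C4", "P3", "P4", "O1", "O2",
    "F7", "F8", "T3", "T4", "T5", "T6", "Fz", "Cz", "Pz",
)

#: classical frequency bands, half-open [low, high) in Hz
BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.5),
    "beta": (12.5, 20.0),
}


@dataclass
class EpochSet:
    """Epoched multichannel EEG: ``data`` is (epochs, channels, samples) in µV."""

    data: np.ndarray
    fs: float
    channel_labels: list[str]
    subject_id: str | None = None
    visit: str | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValueError(f"data must be (epochs, channels, samples), "
                             f"got shape {self.data.shape}")
        if self.fs <= 0:
            raise ValueError(f"fs must be > 0, got {self.fs}")
        if len(self.channel_labels) != self.data.shape[1]:
            raise ValueError("channel_labels length does not match data")

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def n_samples(self) -> int:
        return self.data.shape[2]


@dataclass
class CrossSpectra:
    """Per-frequency Hermitian cross-spectral matrices.

    ``matrices`` has shape (n_freqs, C, C); the diagonal is the one-sided
    PSD (real, non-negative).
    """

    frequencies: np.ndarray
    matrices: np.ndarray
    n_epochs_averaged: int
    channel_labels: list[str]

    def psd(self) -> np.ndarray:
        """(channels, freqs) real power spectral density."""
        return np.real(np.einsum("fcc->fc", self.matrices)).T


@dataclass
class LogSpectra:
    """Log10 power, rows = channels or sources, cols = frequency bins."""

    values: np.ndarray
    frequencies: np.ndarray
    row_labels: list[str]
    gsf: float | None = None
    units: str = "log10 power"


def default_grid(fs: float = 200.0, n_samples: int = 512,
                 k_min: int = 2, k_max: int = 50) -> np.ndarray:
    """Analysis grid k*(fs/T), k = 2..50: 49 bins, 0.78125–19.53125 Hz."""
    df = fs / n_samples
    return np.arange(k_min, k_max + 1) * df


def average_reference(epochs: EpochSet) -> EpochSet:
    """Re-reference to the average montage (zero channel mean per sample)."""
    if epochs.n_channels < 2:
        raise ValueError("average reference undefined for a single channel")
    data = epochs.data - epochs.data.mean(axis=1, keepdims=True)
    return EpochSet(data=data, fs=epochs.fs,
                    channel_labels=list(epochs.channel_labels),
                    subject_id=epochs.subject_id, visit=epochs.visit)


def _grid_to_bins(grid: np.ndarray, fs: float, T: int) -> np.ndarray:
    df = fs / T
    ks = []
    for f in np.atleast_1d(grid):
        k = round(f / df)
        if abs(f - k * df) > 1e-6 * df or not (0 <= k <= T // 2):
            k_near = int(np.clip(round(f / df), 0, T // 2))
            raise ValueError(
                f"frequency {f} Hz is not representable on the DFT grid "
                f"(resolution {df} Hz); nearest representable bin is "
                f"{k_near * df} Hz")
        ks.append(k)
    return np.asarray(ks, dtype=int)


def bartlett_cross_spectra(epochs: EpochSet,
                           grid: np.ndarray | None = None) -> CrossSpectra:
    """Average cross-periodograms over epochs (Bartlett's method).

    With ``grid=None`` all non-negative DFT bins (DC..Nyquist) are
    returned, so the PSD sums to the mean squared amplitude exactly.
    """
    if epochs.n_epochs < 1:
        raise ValueError("need at least one epoch")
    T = epochs.n_samples
    fs = epochs.fs
    if grid is None:
        ks = np.arange(T // 2 + 1)
    else:
        ks = _grid_to_bins(np.asarray(grid, dtype=float), fs, T)
    F = np.fft.rfft(epochs.data, axis=-1)[:, :, ks]     # (E, C, K)
    S = np.einsum("eck,edk->kcd", F, F.conj()) / epochs.n_epochs
    # one-sided normalization: interior bins count twice (conjugate pair)
    w = np.full(len(ks), 2.0 / T ** 2)
    w[ks == 0] = 1.0 / T ** 2
    if T % 2 == 0:
        w[ks == T // 2] = 1.0 / T ** 2
    S *= w[:, None, None]
    S = 0.5 * (S + np.conj(np.transpose(S, (0, 2, 1))))  # enforce Hermitian
    freqs = ks * fs / T
    return CrossSpectra(frequencies=freqs, matrices=S,
                        n_epochs_averaged=epochs.n_epochs,
                        channel_labels=list(epochs.channel_labels))


def _safe_log10(power: np.ndarray) -> np.ndarray:
    """log10 after flooring at 1e-12 x the matrix maximum (keeps log finite)."""
    mx = np.max(power)
    if mx <= 0:
        raise ValueError("all-zero power matrix; log spectra undefined")
    return np.log10(np.maximum(power, 1e-12 * mx))


def scalp_log_spectra(cross: CrossSpectra) -> LogSpectra:
    """Channel-level log10 PSD from cross-spectra."""
    psd = np.maximum(cross.psd(), 0.0)
    return LogSpectra(values=_safe_log10(psd),
                      frequencies=cross.frequencies,
                      row_labels=list(cross.channel_labels))


def global_scale_factor(logspec: LogSpectra) -> LogSpectra:
    """Remove the subject-level global scale factor.

    The factor accounts for non-neural power scaling (skull thickness,
    impedance, gain); in the log domain it is the grand mean over all
    rows and bins, so subtracting it divides power by its geometric mean
    and the stored ``gsf`` allows exact inversion.
    """
    vals = np.asarray(logspec.values, dtype=float)
    if vals.size == 0:
        raise ValueError("empty log-spectra matrix")
    if not np.all(np.isfinite(vals)):
        raise ValueError("log spectra must be finite")
    gsf = float(vals.mean())
    return LogSpectra(values=vals - gsf, frequencies=logspec.frequencies,
                      row_labels=list(logspec.row_labels), gsf=gsf,
                      units=logspec.units)


def apply_inverse(cross: CrossSpectra, operator: np.ndarray) -> LogSpectra:
    """Project cross-spectra through a linear inverse operator K.

    Source PSD at frequency f is ``diag(K S(f) K^T)`` — a quadratic form
    on a Hermitian PSD matrix, hence real and non-negative — followed by
    the floored log10 transform.  ``operator`` is (sources, channels).
    """
    K = np.asarray(operator, dtype=float)
    if K.ndim != 2 or K.shape[1] != len(cross.channel_labels):
        raise ValueError(
            f"operator shape {K.shape} incompatible with "
            f"{len(cross.channel_labels)} channels")
    src = np.einsum("sc,fcd,sd->sf", K, cross.matrices, K).real
    src = np.maximum(src, 0.0)
    labels = [f"src-{i:04d}" for i in range(K.shape[0])]
    return LogSpectra(values=_safe_log10(src), frequencies=cross.frequencies,
                      row_labels=labels)


def band_summaries(logspec: LogSpectra,
                   bands: dict[str, tuple[float, float]] = BANDS) -> dict[str, np.ndarray]:
    """Mean log power per classical band, half-open [low, high)."""
    out = {}
    f = np.asarray(logspec.frequencies)
    for name, (lo, hi) in bands.items():
        mask = (f >= lo) & (f < hi)
        if mask.any():
            out[name] = logspec.values[:, mask].mean(axis=1)
    return out


# ---------------------------------------------------------------------------
# container I/O: matrix file + JSON sidecar per subject-visit
# ---------------------------------------------------------------------------

def save_epochs(epochs: EpochSet, path: str | Path) -> None:
    """Write epochs as <path>.npy with a JSON sidecar <path>.json."""
    path = Path(path)
    np.save(path.with_suffix(".npy"), epochs.data)
    sidecar = {
        "fs": epochs.fs,
        "channel_labels": list(epochs.channel_labels),
        "epoch_length": epochs.n_samples,
        "n_epochs": epochs.n_epochs,
        "subject_id": epochs.subject_id,
        "visit": epochs.visit,
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_epochs(path: str | Path) -> EpochSet:
    path = Path(path)
    npy, sidecar_path = path.with_suffix(".npy"), path.with_suffix(".json")
    if not npy.exists():
        raise FileNotFoundError(f"epoch matrix not found: {npy}")
    with open(sidecar_path) as fh:
        meta = json.load(fh)
    return EpochSet(data=np.load(npy), fs=meta["fs"],
                    channel_labels=meta["channel_labels"],
                    subject_id=meta.get("subject_id"), visit=meta.get("visit"))


def save_log_spectra(logspec: LogSpectra, path: str | Path) -> None:
    path = Path(path)
    np.savetxt(path.with_suffix(".tsv"), logspec.values, delimiter="\t")
    sidecar = {
        "frequencies_hz": list(map(float, logspec.frequencies)),
        "n_rows": int(logspec.values.shape[0]),
        "units": logspec.units,
        "gsf": logspec.gsf,
        "row_labels": list(logspec.row_labels),
    }
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)


def load_log_spectra(path: str | Path) -> LogSpectra:
    path = Path(path)
    vals = np.loadtxt(path.with_suffix(".tsv"), delimiter="\t", ndmin=2)
    with open(path.with_suffix(".json")) as fh:
        meta = json.load(fh)
    return LogSpectra(values=vals,
                      frequencies=np.asarray(meta["frequencies_hz"]),
                      row_labels=meta["row_labels"], gsf=meta.get("gsf"),
                      units=meta.get("units", "log10 power"))
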