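"""Synthetic trial cohorts with known mediation ground truth.

Emulates the statistical structure of a small two-arm repeated-measures
drug trial: two groups of Parkinson's patients, two visits (baseline and
six-month follow-up), a dose variable that is nonzero only at follow-up
for the treated arm, and one latent mediator (a quantitative-EEG factor)
plus one latent outcome (a cognitive factor).  The mediator latent
projects into a high-dimensional log source-spectra block; the outcome
latent projects into six cognitive test scores.  Because the generative
coefficients are known, the true split of the dose effect into a
mediated and a direct component is available in closed form, so every
downstream stage (whitening CCA, mixed models, mediation) can be tested
for recovery of a known truth.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .spectra import EpochSet, CHANNELS_1020

#: canonical order of the cognitive scores (matches the cohort CSV header)
COG_SCORES = ("DRS", "MMSE", "FAB", "Sequency", "Memory", "Recognition")

#: exact cohort CSV header
COHORT_COLUMNS = (
    "subject_id", "group", "visit", "dose",
    "age_trial", "education", "severity",
) + COG_SCORES

VISITS = ("baseline", "month6")

#: default loadings of the cognitive latent on the six scores,
#: order DRS, MMSE, FAB, Sequency, Memory, Recognition
DEFAULT_LOAD_COG = (0.26, 0.22, 0.24, 0.22, 0.20, 0.21)

#: package-wide default seed for simulations
DEFAULT_SEED = 1234


def default_qeeg_loadings(n_sources: int = 200, n_freqs: int = 49,
                          rms: float = 0.1) -> np.ndarray:
    """Deterministic spectral loading pattern for the mediator latent.

    A smooth mixed-sign pattern (a contrast across sources, modulated over
    frequency) with overall root-mean-square ``rms``.  Mixed signs mirror
    the fact that an EEG latent factor is typically a contrast of log
    power between regions/bands rather than a global power increase.
    """
    s = np.arange(n_sources)
    f = np.arange(n_freqs)
    # sign alternates smoothly over sources; two frequency bumps of
    # opposite polarity keep the pattern broad-band but structured
    spatial = np.cos(2 * np.pi * s / max(n_sources, 2) * 3.0) + 0.5
    bump1 = np.exp(-0.5 * ((f - 10) / 6.0) ** 2)
    bump2 = np.exp(-0.5 * ((f - 35) / 8.0) ** 2)
    load = np.outer(spatial, bump1 - 0.8 * bump2)
    load *= rms / np.sqrt(np.mean(load ** 2))
    return load


@dataclass(frozen=True)
class TruthParams:
    """Generative coefficients for a synthetic cohort.

    ``a`` is the dose -> mediator-latent path (per unit dose), ``b`` the
    mediator -> outcome path and ``c_prime`` the direct dose -> outcome
    path.  Defaults are calibrated to the fitted coefficients of the
    motivating trial analysis so that the true proportion mediated is
    a*b/(a*b + c') = 0.659 for a unit dose contrast.
    """

    a: float = 0.496
    b: float = 3.840
    c_prime: float = 0.987
    #: (education, severity, age_trial) effects on the mediator latent
    conf_mediator: tuple[float, float, float] = (0.066, 0.232, -0.023)
    #: (education, severity, age_trial) direct effects on the outcome latent
    conf_outcome: tuple[float, float, float] = (0.067, 0.670, -0.044)
    sd_subject: float = 0.5
    sd_resid_m: float = 0.5
    sd_resid_y: float = 0.5
    load_cog: tuple[float, ...] = DEFAULT_LOAD_COG
    load_qeeg: np.ndarray | None = None   # (n_sources, n_freqs); None -> default pattern
    n_sources: int = 200
    n_freqs: int = 49
    sd_obs_cog: float = 0.2
    sd_obs_qeeg: float = 0.5
    n_treated: int = 15
    n_placebo: int = 10
    dose_value: float = 1.0

    def validate(self) -> None:
        for name in ("sd_subject", "sd_resid_m", "sd_resid_y",
                     "sd_obs_cog", "sd_obs_qeeg"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0, got {getattr(self, name)}")
        if self.n_treated < 2 or self.n_placebo < 2:
            raise ValueError(
                f"group sizes must be >= 2, got n_treated={self.n_treated}, "
                f"n_placebo={self.n_placebo}")
        if len(self.load_cog) != len(COG_SCORES):
            raise ValueError("load_cog must have six entries")
        if self.dose_value == 0:
            raise ValueError("dose_value must be nonzero (treated contrast)")

    def qeeg_loadings(self) -> np.ndarray:
        if self.load_qeeg is not None:
            load = np.asarray(self.load_qeeg, dtype=float)
            if load.shape != (self.n_sources, self.n_freqs):
                raise ValueError(
                    f"load_qeeg shape {load.shape} != "
                    f"({self.n_sources}, {self.n_freqs})")
            return load
        return default_qeeg_loadings(self.n_sources, self.n_freqs)

    def true_proportion_mediated(self, delta: float | None = None) -> float:
        """Closed-form proportion mediated a*b*d / (a*b*d + c'*d)."""
        d = self.dose_value if delta is None else delta
        acme = self.a * self.b * d
        total = acme + self.c_prime * d
        if total == 0:
            raise ValueError("total effect is zero; proportion undefined")
        return acme / total

    def replace(self, **kw) -> "TruthParams":
        return replace(self, **kw)


@dataclass
class SyntheticBundle:
    """A generated cohort plus its latent ground truth."""

    cohort: pd.DataFrame              # COHORT_COLUMNS, 2 rows per subject
    spectra: np.ndarray               # (n_rows, n_sources, n_freqs) log10 power
    latents_true: pd.DataFrame        # subject_id, visit, mediator, outcome
    truth: TruthParams
    seed: int

    def spectra_matrix(self) -> np.ndarray:
        """Vectorized spectra block, one row per subject-visit.

        Column j maps to source j // n_freqs, frequency bin j % n_freqs.
        """
        n = self.spectra.shape[0]
        return self.spectra.reshape(n, -1)

    def geometry(self) -> pd.DataFrame:
        """Source / frequency-bin index for each vectorized spectra column."""
        src = np.repeat(np.arange(self.truth.n_sources), self.truth.n_freqs)
        frq = np.tile(np.arange(self.truth.n_freqs), self.truth.n_sources)
        return pd.DataFrame({"source": src, "freq_bin": frq})


def generate_cohort(truth: TruthParams, seed: int,
                    with_spectra: bool = True) -> SyntheticBundle:
    """Generate a full synthetic trial bundle.

    Latent structure per subject i, visit v::

        mediator = a*dose + conf_m . (edu, sev, age) + u_m[i] + e_m
        outcome  = b*mediator + c'*dose + conf_y . (edu, sev, age) + u_y[i] + e_y

    with independent subject intercepts u_m, u_y ~ N(0, sd_subject^2) and
    visit-level residuals.  Observed cognitive scores are
    ``load_cog * outcome + noise``; observed spectra rows are
    ``load_qeeg * mediator + noise``.  Identical ``(truth, seed)`` pairs
    reproduce the bundle bit-exactly; spectra noise is drawn last, so
    the cohort and latents do not depend on the spectra dimensions and
    ``with_spectra=False`` produces the same cohort without the (large)
    spectra block.
    """
    truth.validate()
    rng = np.random.default_rng(seed)

    n_sub = truth.n_treated + truth.n_placebo
    n_rows = 2 * n_sub
    groups = np.array(["treated"] * truth.n_treated + ["placebo"] * truth.n_placebo)
    subject_ids = np.array([f"sub-{i + 1:03d}" for i in range(n_sub)])

    age = rng.uniform(40.0, 70.0, n_sub)
    education = rng.uniform(6.0, 20.0, n_sub)
    severity = rng.choice([1, 2], size=n_sub, p=[0.2, 0.8]).astype(int)
    u_m = rng.normal(0.0, truth.sd_subject, n_sub)
    u_y = rng.normal(0.0, truth.sd_subject, n_sub)
    e_m = rng.normal(0.0, truth.sd_resid_m, n_rows)
    e_y = rng.normal(0.0, truth.sd_resid_y, n_rows)
    score_noise = rng.normal(0.0, truth.sd_obs_cog, (n_rows, len(COG_SCORES)))

    # row layout: subject-major, visit order (baseline, month6)
    sub_idx = np.repeat(np.arange(n_sub), 2)
    visit = np.tile(np.array(VISITS), n_sub)
    dose = np.where((visit == "month6") & (groups[sub_idx] == "treated"),
                    truth.dose_value, 0.0)
    cm, cy = truth.conf_mediator, truth.conf_outcome
    conf_m = (cm[0] * education + cm[1] * severity + cm[2] * age)[sub_idx]
    conf_y = (cy[0] * education + cy[1] * severity + cy[2] * age)[sub_idx]
    mediator = truth.a * dose + conf_m + u_m[sub_idx] + e_m
    outcome = (truth.b * mediator + truth.c_prime * dose + conf_y
               + u_y[sub_idx] + e_y)
    scores = np.outer(outcome, np.asarray(truth.load_cog)) + score_noise

    if with_spectra:
        load_q = truth.qeeg_loadings().reshape(-1)
        spectra = (np.outer(mediator, load_q)
                   + rng.normal(0.0, truth.sd_obs_qeeg, (n_rows, load_q.size)))
        spectra = spectra.reshape(n_rows, truth.n_sources, truth.n_freqs)
    else:
        spectra = np.empty((n_rows, 0, 0))

    cohort = pd.DataFrame({
        "subject_id": subject_ids[sub_idx], "group": groups[sub_idx],
        "visit": visit, "dose": dose, "age_trial": age[sub_idx],
        "education": education[sub_idx], "severity": severity[sub_idx],
    })
    for j, name in enumerate(COG_SCORES):
        cohort[name] = scores[:, j]
    latents = pd.DataFrame({
        "subject_id": cohort["subject_id"], "visit": cohort["visit"],
        "mediator": mediator, "outcome": outcome,
    })
    return SyntheticBundle(cohort=cohort, spectra=spectra,
                           latents_true=latents, truth=truth, seed=seed)


# ---------------------------------------------------------------------------
# raw-EEG emulation so the spectral pipeline can be exercised end to end
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RecordingSpec:
    """Shape of an emulated resting EEG recording session.

    Defaults mirror a 19-channel 10/20 montage digitized at 200 Hz with
    24 artifact-free epochs of 512 samples (2.56 s).  ``targets`` lists
    (channel label, frequency Hz) pairs at which a sinusoid is injected
    whose amplitude grows monotonically with the mediator latent:

        amplitude = base_amplitude * exp(gain * latent)

    so the expected epoch power at a target bin is
    ``base_amplitude**2 * exp(2*gain*latent) / 2`` on top of the flat
    white-noise floor.  Target frequencies must sit on the DFT grid
    fs / n_samples for the mapping to be exactly computable.
    """

    channel_labels: tuple[str, ...] = CHANNELS_1020
    n_epochs: int = 24
    n_samples: int = 512
    fs: float = 200.0
    noise_sd: float = 1.0
    targets: tuple[tuple[str, float], ...] = (
        ("O1", 10.15625), ("O2", 10.15625), ("Pz", 6.25))
    base_amplitude: float = 2.0
    gain: float = 0.35

    def expected_peak_power(self, latent: float) -> float:
        """Expected sinusoid power A^2/2 at a target bin for this latent."""
        amp = self.base_amplitude * np.exp(self.gain * latent)
        return amp ** 2 / 2.0


def generate_eeg_epochs(mediator_latent: float, spec: RecordingSpec,
                        seed: int) -> EpochSet:
    """Emulate an epoched EEG recording driven by the mediator latent."""
    if spec.fs <= 0:
        raise ValueError(f"fs must be > 0, got {spec.fs}")
    T = spec.n_samples
    if T & (T - 1) != 0:
        warnings.warn(
            f"n_samples={T} is not a power of two; the FFT is still defined "
            "but slower", stacklevel=2)
    rng = np.random.default_rng(seed)
    C = len(spec.channel_labels)
    data = rng.normal(0.0, spec.noise_sd, (spec.n_epochs, C, T))
    t = np.arange(T) / spec.fs
    amp = spec.base_amplitude * np.exp(spec.gain * mediator_latent)
    for label, f0 in spec.targets:
        ch = spec.channel_labels.index(label)
        phases = rng.uniform(0, 2 * np.pi, spec.n_epochs)
        data[:, ch, :] += amp * np.cos(2 * np.pi * f0 * t[None, :] + phases[:, None])
    return EpochSet(data=data, fs=spec.fs, channel_labels=list(spec.channel_labels))


# ---------------------------------------------------------------------------
# plain-text I/O
# ---------------------------------------------------------------------------

def write_cohort_csv(cohort: pd.DataFrame, path: str | Path) -> None:
    missing = [c for c in COHORT_COLUMNS if c not in cohort.columns]
    if missing:
        raise ValueError(f"cohort is missing columns {missing}")
    cohort.to_csv(path, index=False, columns=list(COHORT_COLUMNS))


def read_cohort_csv(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"cohort file not found: {path}")
    return pd.read_csv(path)


def write_spectra_dir(bundle: SyntheticBundle, out_dir: str | Path) -> list[Path]:
    """One delimited matrix (sources x bins) per subject-visit + JSON sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written = []
    sidecar = {
        "n_sources": bundle.truth.n_sources,
        "n_freqs": bundle.truth.n_freqs,
        "units": "log10 power",
    }
    for r, (_, row) in enumerate(bundle.cohort.iterrows()):
        stem = f"{row['subject_id']}_{row['visit']}_spectra"
        mat_path = out / f"{stem}.tsv"
        np.savetxt(mat_path, bundle.spectra[r], delimiter="\t")
        with open(out / f"{stem}.json", "w") as fh:
            json.dump({**sidecar, "subject_id": row["subject_id"],
                       "visit": row["visit"]}, fh, indent=1)
        written.append(mat_path)
    return written


def read_spectra_dir(spectra_dir: str | Path,
                     cohort: pd.DataFrame) -> np.ndarray:
    """Read per subject-visit spectra files aligned to the cohort rows."""
    spectra_dir = Path(spectra_dir)
    mats = []
    for _, row in cohort.iterrows():
        path = spectra_dir / f"{row['subject_id']}_{row['visit']}_spectra.tsv"
        if not path.exists():
            raise FileNotFoundError(f"spectra file not found: {path}")
        mats.append(np.loadtxt(path, delimiter="\t", ndmin=2))
    return np.stack(mats)
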