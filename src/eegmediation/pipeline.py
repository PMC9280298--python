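"""End-to-end orchestration of the trial analysis.

Stages: screen -> spectra (global scale factor) -> latent CCA ->
mixed models (mediator and outcome) -> mediation decomposition ->
power simulation.  Each stage writes a plain-text table analog of the
published result tables plus a JSON manifest with the configuration,
its hash, and the seeds used, so a run is reproducible bit-for-bit for
the deterministic stages.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cca import DataBlockPair, fit_cca_whitening, loading_summaries, transform
from .lmm import ModelSpec, fit_random_intercept, wald_table
from .mediation import (MediationResult, quasi_bayesian_mediation,
                        simulate_power)
from .stats import baseline_table, screen_cognitive_variables
from .synthetic import (COG_SCORES, DEFAULT_SEED, SyntheticBundle, TruthParams,
                        generate_cohort, read_cohort_csv, read_spectra_dir,
                        write_cohort_csv)

log = logging.getLogger("eegmediation.pipeline")

CONFOUNDERS = ("severity", "education", "age_trial")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name and offending input."""


@dataclass
class PipelineConfig:
    """Fully serializable run configuration (hashable for provenance)."""

    # inputs: either simulate=True or paths to cohort CSV (+ spectra dir)
    simulate: bool = True
    cohort_csv: str | None = None
    spectra_dir: str | None = None
    out_dir: str = "results"
    seed: int = DEFAULT_SEED
    # synthetic-cohort overrides (names match TruthParams fields)
    truth: dict = field(default_factory=dict)
    # CCA options
    cca_lambda_x: float | None = None
    cca_lambda_y: float | None = None
    # LMM options
    lmm_method: str = "REML"
    p_value_mode: str = "wald-z"
    # mediation options
    mediation_n_sims: int = 1000
    treat: tuple[float, float] = (0.0, 1.0)
    # power options
    power_n_sims: int = 100
    power_alpha: float = 0.05
    # screening options
    screening_q: float = 0.05
    screening_rule: str = "treated"

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["treat"] = list(d["treat"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if "treat" in d:
            d["treat"] = tuple(d["treat"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()

    def truth_params(self) -> TruthParams:
        kw = dict(self.truth)
        if "load_qeeg" in kw and kw["load_qeeg"] is not None:
            kw["load_qeeg"] = np.asarray(kw["load_qeeg"], dtype=float)
        if "load_cog" in kw:
            kw["load_cog"] = tuple(kw["load_cog"])
        return TruthParams(**kw)


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kw):
            log.info("stage %s: start", name)
            try:
                return fn(*args, **kw)
            except PipelineError:
                raise
            except Exception as exc:
                raise PipelineError(f"stage '{name}' failed: {exc}") from exc
        return wrapper
    return deco


@dataclass
class PipelineReport:
    out_dir: Path
    scores: pd.DataFrame
    mediator_table: pd.DataFrame
    outcome_table: pd.DataFrame
    mediation: MediationResult
    power: pd.DataFrame
    manifest: dict


def _mediation_table(res: MediationResult) -> pd.DataFrame:
    rows = []
    for label, eff in (("Mediation effect", res.acme),
                       ("Direct effect", res.ade),
                       ("Total effect", res.total),
                       ("Proportion mediated", res.prop_mediated)):
        rows.append({"": label, "Estimate": eff.point,
                     "95% CI lower": eff.ci_low, "95% CI upper": eff.ci_high,
                     "P-value": eff.p_label(res.n_sims)})
    return pd.DataFrame(rows)


def run_full_pipeline(config: PipelineConfig) -> PipelineReport:
    """Execute the full analysis and write all table analogs + manifest."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    outputs: list[dict] = []

    def write_csv(df: pd.DataFrame, name: str, stage: str) -> None:
        path = out / name
        df.to_csv(path, index=False)
        outputs.append({"file": name, "stage": stage})

    # ---- load or simulate -------------------------------------------------
    @_stage("input")
    def load_inputs():
        if config.simulate:
            bundle = generate_cohort(config.truth_params(), config.seed)
            write_cohort_csv(bundle.cohort, out / "cohort.csv")
            outputs.append({"file": "cohort.csv", "stage": "input"})
            return bundle.cohort, bundle.spectra_matrix(), bundle.geometry()
        cohort = read_cohort_csv(config.cohort_csv)
        if config.spectra_dir is None:
            raise FileNotFoundError("spectra_dir is required when not simulating")
        spectra = read_spectra_dir(config.spectra_dir, cohort)
        n, s, f = spectra.shape
        geometry = pd.DataFrame({
            "source": np.repeat(np.arange(s), f),
            "freq_bin": np.tile(np.arange(f), s)})
        return cohort, spectra.reshape(n, -1), geometry

    cohort, X, geometry = load_inputs()

    # ---- baseline table + screening --------------------------------------
    @_stage("screen")
    def screen():
        write_csv(baseline_table(cohort), "baseline_table.csv", "screen")
        res = screen_cognitive_variables(cohort, list(COG_SCORES),
                                         q=config.screening_q,
                                         rule=config.screening_rule)
        write_csv(res.table, "screening.csv", "screen")
        return res

    screen()

    # ---- spectra normalization (global scale factor per row) -------------
    @_stage("spectra")
    def normalize():
        gsf = X.mean(axis=1, keepdims=True)
        return X - gsf

    Xn = normalize()

    # ---- latent CCA -------------------------------------------------------
    @_stage("latent")
    def latent():
        pair = DataBlockPair(
            X=Xn, Y=cohort[list(COG_SCORES)].to_numpy(dtype=float),
            row_keys=list(zip(cohort["subject_id"], cohort["visit"])),
            y_names=list(COG_SCORES))
        model = fit_cca_whitening(pair, lambda_x=config.cca_lambda_x,
                                  lambda_y=config.cca_lambda_y)
        model.to_json(out / "whitening_model.json")
        outputs.append({"file": "whitening_model.json", "stage": "latent"})
        scores = transform(model, pair).scores
        summ = loading_summaries(model, geometry)
        write_csv(summ.cog_loadings.rename_axis("Cognitive variables")
                  .reset_index(), "cog_loadings.csv", "latent")
        write_csv(summ.freq_minmax, "qeeg_loading_freq_minmax.csv", "latent")
        merged = cohort.merge(scores, on=["subject_id", "visit"])
        write_csv(merged, "scores.csv", "latent")
        return merged

    data = latent()

    # ---- mixed models -----------------------------------------------------
    @_stage("models")
    def models():
        med_spec = ModelSpec(response="qEEG1",
                             fixed_effects=("dose",) + CONFOUNDERS,
                             method=config.lmm_method,
                             p_value_mode=config.p_value_mode)
        out_spec = ModelSpec(response="Cog1",
                             fixed_effects=("qEEG1", "dose") + CONFOUNDERS,
                             method=config.lmm_method,
                             p_value_mode=config.p_value_mode)
        fit_m = fit_random_intercept(med_spec, data)
        fit_y = fit_random_intercept(out_spec, data)
        write_csv(wald_table(fit_m), "mediator_model.csv", "models")
        write_csv(wald_table(fit_y), "outcome_model.csv", "models")
        return fit_m, fit_y

    fit_m, fit_y = models()

    # ---- mediation --------------------------------------------------------
    @_stage("mediate")
    def mediate():
        res = quasi_bayesian_mediation(
            fit_m, fit_y, treat=config.treat,
            n_sims=config.mediation_n_sims, seed=config.seed,
            dose_term="dose", mediator_term="qEEG1")
        write_csv(_mediation_table(res), "mediation.csv", "mediate")
        return res

    med = mediate()

    # ---- power ------------------------------------------------------------
    @_stage("power")
    def power():
        rows = []
        for fit, coef in ((fit_m, "dose"), (fit_y, "qEEG1"), (fit_y, "dose")):
            r = simulate_power(fit, coef, alpha=config.power_alpha,
                               n_sims=config.power_n_sims,
                               seed=config.seed)
            rows.append({"model": fit.spec.response, "coefficient": coef,
                         "power_pct": r.power, "ci_low_pct": r.ci[0],
                         "ci_high_pct": r.ci[1], "successes": r.successes,
                         "trials": r.trials, "n_failed": r.n_failed})
        df = pd.DataFrame(rows)
        write_csv(df, "power.csv", "power")
        return df

    power_df = power()

    manifest = {
        "package": "eegmediation",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "outputs": outputs,
        # timestamp is provenance only; it is not part of the hash
        "created": time.strftime("%Y-%m-%dT%H:%M:%S"),
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)

    return PipelineReport(out_dir=out, scores=data,
                          mediator_table=wald_table(fit_m),
                          outcome_table=wald_table(fit_y),
                          mediation=med, power=power_df, manifest=manifest)
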