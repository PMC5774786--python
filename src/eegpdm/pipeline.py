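"""End-to-end train / apply workflows.

``run_train`` fits the whole chain on a labelled cohort: preprocessing,
per-epoch Laguerre-Volterra kernel estimation, per-input global PDM
extraction, per-epoch ANF fits, linear gains and the two-feature Fisher
discriminant.  ``run_apply`` evaluates new epochs against frozen artifacts
(the global PDM bases and the trained discriminant are never refit on test
data), so train/test leakage is structurally impossible.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .anf import fit_anfs, pdm_outputs, select_cross_terms
from .biomarkers import (
    ClassifierResult,
    classify,
    gain_table,
    state_contrast_test,
    train_linear_discriminator,
)
from .laguerre_volterra import fit_volterra, laguerre_basis
from .pdm import GlobalPDMBasis, assemble_Q, extract_global_pdms
from .preprocess import PreprocessConfig, preprocess_series
from .synthetic import EpochTriplet

logger = logging.getLogger("eegpdm")

__all__ = ["PipelineConfig", "TrainedArtifacts", "run_train", "run_apply"]


@dataclass
class PipelineConfig:
    """All pipeline parameters; round-trips losslessly through JSON."""

    # preprocessing; `preprocess=False` skips conditioning for epochs that
    # are already filtered/detrended (e.g. simulator output)
    preprocess: bool = True
    cutoff_hz: float = 40.0
    filter_order: int = 2
    grubbs_alpha: float = 0.05
    detrend_kind: str = "linear"
    zero_phase: bool = False
    # kernel expansion / PDM extraction
    alpha: float = 0.7
    L: int = 6
    M: int = 64
    H: int = 5
    order: int = 3
    # cross-term screen
    cross_term_level: float = 0.99
    n_surrogates: int = 200
    screen_cross_terms: bool = True
    # biomarker
    feature_pair: tuple = (("input2", 2), ("input2", 4))
    # reproducibility
    seed: int = 0

    def preprocess_config(self) -> PreprocessConfig:
        return PreprocessConfig(
            cutoff_hz=self.cutoff_hz,
            filter_order=self.filter_order,
            grubbs_alpha=self.grubbs_alpha,
            detrend_kind=self.detrend_kind,
            zero_phase=self.zero_phase,
        )

    def to_json(self) -> str:
        d = asdict(self)
        d["feature_pair"] = [list(f) for f in self.feature_pair]
        return json.dumps(d, indent=2)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        d["feature_pair"] = tuple(
            (str(a), int(b)) for a, b in d.get("feature_pair", [])
        ) or cls.feature_pair
        return cls(**d)


@dataclass
class TrainedArtifacts:
    """Everything ``run_apply`` needs, serializable to a directory of text files."""

    config: PipelineConfig
    basis1: GlobalPDMBasis
    basis2: GlobalPDMBasis
    gains: pd.DataFrame = field(repr=False)
    classifier: ClassifierResult = None
    contrast_pvalues: dict = field(default_factory=dict)

    def save(self, directory: Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "config.json").write_text(self.config.to_json())
        (directory / "pdm_basis_input1.json").write_text(self.basis1.to_json())
        (directory / "pdm_basis_input2.json").write_text(self.basis2.to_json())
        self.gains.to_csv(directory / "gains.tsv", sep="\t", index=False)
        (directory / "classifier.json").write_text(self.classifier.to_json())
        (directory / "contrast_pvalues.json").write_text(
            json.dumps(self.contrast_pvalues)
        )

    @classmethod
    def load(cls, directory: Path) -> "TrainedArtifacts":
        directory = Path(directory)
        return cls(
            config=PipelineConfig.from_json((directory / "config.json").read_text()),
            basis1=GlobalPDMBasis.from_json(
                (directory / "pdm_basis_input1.json").read_text()
            ),
            basis2=GlobalPDMBasis.from_json(
                (directory / "pdm_basis_input2.json").read_text()
            ),
            gains=pd.read_csv(directory / "gains.tsv", sep="\t"),
            classifier=ClassifierResult.from_json(
                (directory / "classifier.json").read_text()
            ),
            contrast_pvalues=json.loads(
                (directory / "contrast_pvalues.json").read_text()
            ),
        )


def _preprocess_epoch(ep: EpochTriplet, cfg: PreprocessConfig) -> EpochTriplet:
    x1, _ = preprocess_series(ep.input1, ep.fs, cfg)
    x2, _ = preprocess_series(ep.input2, ep.fs, cfg)
    y, _ = preprocess_series(ep.output, ep.fs, cfg)
    return EpochTriplet(
        input1=x1, input2=x2, output=y,
        fs=ep.fs, subject_id=ep.subject_id, state=ep.state,
    )


def _stage(name: str, t0: float) -> float:
    t1 = time.perf_counter()
    logger.info("stage %s done in %.2fs", name, t1 - t0)
    return t1


def _fit_anf_stage(epochs, config, basis1, basis2):
    """Per-epoch PDM outputs, cross-term screen, ANF fit, gains."""
    anf_models, u_pairs = [], []
    for k, ep in enumerate(epochs):
        u1 = pdm_outputs(basis1, ep.input1)
        u2 = pdm_outputs(basis2, ep.input2)
        cross = (
            select_cross_terms(
                u1, u2, ep.output,
                level=config.cross_term_level,
                n_surrogates=config.n_surrogates,
                seed=config.seed + 1000 + k,
            )
            if config.screen_cross_terms
            else []
        )
        anf_models.append(fit_anfs(u1, u2, cross, ep.output, config.order))
        u_pairs.append((u1, u2))
    gains = gain_table(
        anf_models,
        u_pairs,
        [ep.subject_id for ep in epochs],
        [ep.state for ep in epochs],
    )
    return anf_models, gains


def _feature_matrix(gains: pd.DataFrame, feature_pair) -> tuple[np.ndarray, np.ndarray, list]:
    wide = gains.pivot_table(
        index=["subject_id", "state"], columns=["input", "branch"], values="gain"
    )
    cols = [(inp, br) for inp, br in feature_pair]
    X = wide[cols].to_numpy()
    labels = np.array([s == "ictal" for _, s in wide.index])
    return X, labels, list(wide.index)


def run_train(config: PipelineConfig, cohort: list[EpochTriplet]) -> TrainedArtifacts:
    """Train the full pipeline on a two-state cohort of epoch triplets."""
    states = {ep.state for ep in cohort}
    if states != {"ictal", "interictal"}:
        raise ValueError(
            f"training cohort must contain both states, found {sorted(states)}"
        )
    t0 = time.perf_counter()
    if config.preprocess:
        pcfg = config.preprocess_config()
        epochs = [_preprocess_epoch(ep, pcfg) for ep in cohort]
    else:
        epochs = list(cohort)
    t0 = _stage("preprocess", t0)

    basis = laguerre_basis(config.alpha, config.L, config.M)
    models = [fit_volterra(ep.input1, ep.input2, ep.output, basis) for ep in epochs]
    t0 = _stage("kernel-estimation", t0)

    state_list = [ep.state for ep in epochs]
    basis1 = extract_global_pdms(
        assemble_Q(models, "input1", [float(ep.input1.std()) for ep in epochs],
                   state_list),
        config.H, input_label="input1", fs=epochs[0].fs,
    )
    basis2 = extract_global_pdms(
        assemble_Q(models, "input2", [float(ep.input2.std()) for ep in epochs],
                   state_list),
        config.H, input_label="input2", fs=epochs[0].fs,
    )
    t0 = _stage("pdm-extraction", t0)

    _, gains = _fit_anf_stage(epochs, config, basis1, basis2)
    t0 = _stage("anf-fit", t0)

    X, labels, _ = _feature_matrix(gains, config.feature_pair)
    clf = train_linear_discriminator(X, labels, feature_pair=config.feature_pair)

    pvals = {}
    for (inp, br), grp in gains.groupby(["input", "branch"]):
        wide = grp.pivot_table(index="subject_id", columns="state", values="gain")
        if {"ictal", "interictal"} <= set(wide.columns):
            pvals[f"{inp}_b{br}"] = state_contrast_test(
                wide["ictal"].to_numpy(), wide["interictal"].to_numpy(), "paired"
            )
    _stage("biomarkers", t0)
    return TrainedArtifacts(
        config=config, basis1=basis1, basis2=basis2,
        gains=gains, classifier=clf, contrast_pvalues=pvals,
    )


def run_apply(
    artifacts: TrainedArtifacts, epochs: list[EpochTriplet]
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Evaluate new epochs with frozen PDM bases and discriminant.

    Returns the gain table and a per-epoch classification frame (with
    confusion-ready true labels when epochs carry a known state).
    """
    config = artifacts.config
    if not epochs:
        return pd.DataFrame(), pd.DataFrame()
    for ep in epochs:
        if ep.fs != artifacts.basis1.fs:
            raise ValueError(
                f"epoch fs {ep.fs} differs from trained basis fs {artifacts.basis1.fs}"
            )
    if config.preprocess:
        pcfg = config.preprocess_config()
        pre = [_preprocess_epoch(ep, pcfg) for ep in epochs]
    else:
        pre = list(epochs)
    _, gains = _fit_anf_stage(pre, config, artifacts.basis1, artifacts.basis2)
    X, labels, index = _feature_matrix(gains, config.feature_pair)
    pred = classify(artifacts.classifier, X)
    frame = pd.DataFrame(
        {
            "subject_id": [sid for sid, _ in index],
            "state": [st for _, st in index],
            "predicted_ictal": pred,
        }
    )
    return gains, frame
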