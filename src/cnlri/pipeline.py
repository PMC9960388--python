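"""Two-stage workflow: descriptor model -> pseudo-labels -> CNL model.

Stage one fits a descriptor-based (QSRR) retention-index regressor on
the compounds with experimental r_i values, refits it on its 40 most
important descriptors and derives a leverage applicability domain from
the refit training design. Stage two uses that model to pseudo-label a
large spectral corpus (only compounds inside the applicability domain
receive a label), combines a majority share of the pseudo-labeled
corpus with a minority share of the experimental compounds, and trains
a CNL (cumulative-neutral-loss) regressor on the combined set. The
withheld experimental compounds — never seen by the CNL model under
either provenance — give the most honest performance estimate; the
held-out corpus share measures fidelity to the pseudo-labeler.

Splits at the CNL stage are compound-grouped by default: all spectra of
one compound fall on the same side, so duplicate spectra can never leak
a test compound into training.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd

from .cnl import CNLFeatureMatrix, CNLGrid, build_feature_matrix
from .descriptors import CurationReport, DescriptorTable, apply_curation, stability_filter
from .domain import ADModel, fit_ad, in_domain
from .model import (
    CNL_PRESET,
    DESCRIPTOR_PRESET,
    EvalReport,
    GBTConfig,
    SplitSpec,
    TrainedModel,
    evaluate,
    predict,
    refit_top_features,
    save_model,
    stratified_split,
    train,
)
from .spectra import Spectrum

logger = logging.getLogger(__name__)

__all__ = [
    "RIRecord",
    "AssemblyPlan",
    "AssembledSets",
    "TwoStageConfig",
    "TwoStageResult",
    "PipelineError",
    "pseudo_label",
    "assemble_cnl_training",
    "run_two_stage",
]


@dataclass(frozen=True)
class RIRecord:
    """One retention-index observation with provenance.

    Experimental records are measured values; predicted records are
    pseudo-labels from the descriptor model. An experimental record is
    never overwritten by a predicted value.
    """

    compound_id: str
    r_i: float
    provenance: Literal["experimental", "predicted"]
    spectrum_id: str | None = None
    leverage: float | None = None

    def __post_init__(self) -> None:
        if self.provenance not in ("experimental", "predicted"):
            raise ValueError(f"unknown provenance {self.provenance!r}")
        if not np.isfinite(self.r_i):
            raise ValueError("r_i must be finite")


@dataclass(frozen=True)
class AssemblyPlan:
    """Fractions of corpus and experimental entries that enter CNL training."""

    corpus_train_fraction: float = 0.85
    experimental_train_fraction: float = 0.30
    seed: int = 0
    group_by_compound: bool = True

    def __post_init__(self) -> None:
        for f in (self.corpus_train_fraction, self.experimental_train_fraction):
            if not (0 < f < 1):
                raise ValueError("fractions must lie in (0, 1)")


@dataclass
class AssembledSets:
    """Spectrum-level training and test sets for the CNL model."""

    train: list[RIRecord]
    corpus_test: list[RIRecord]
    experimental_test: list[RIRecord]
    dropped: list[RIRecord] = field(default_factory=list)


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def pseudo_label(
    desc_model: TrainedModel,
    ad: ADModel,
    descriptors: DescriptorTable,
) -> tuple[list[RIRecord], list[tuple[str, float]]]:
    """Predict r_i for a curated descriptor table, gated by the AD.

    Returns predicted :class:`RIRecord`s for in-domain compounds and a
    ``(compound_id, leverage)`` list for the rejected out-of-domain
    rows. The descriptor table must already be curated with the
    report that trained ``desc_model``.
    """
    missing = [c for c in desc_model.feature_names if c not in descriptors.frame.columns]
    if missing:
        raise ValueError(f"descriptor table lacks model feature(s): {missing}")
    frame = descriptors.frame[desc_model.feature_names]
    inside, lev = in_domain(frame.to_numpy(dtype=float), ad)
    records: list[RIRecord] = []
    rejected: list[tuple[str, float]] = []
    if inside.any():
        preds = predict(desc_model, frame.iloc[np.flatnonzero(inside)])
        for cid, h, p in zip(frame.index[inside], lev[inside], preds):
            records.append(
                RIRecord(str(cid), float(p), "predicted", leverage=float(h))
            )
    for cid, h in zip(frame.index[~inside], lev[~inside]):
        rejected.append((str(cid), float(h)))
    logger.info(
        "pseudo-labeling: %d in-domain, %d out-of-domain", len(records), len(rejected)
    )
    return records, rejected


def _grouped_split(
    records: list[RIRecord],
    spectra_by_compound: dict[str, list[str]],
    fraction: float,
    seed: int,
    group_by_compound: bool,
    class_edges: tuple[float, ...],
) -> tuple[list[RIRecord], list[RIRecord], list[RIRecord]]:
    """Stratified split of compound records expanded to spectrum entries."""
    with_spec = [r for r in records if spectra_by_compound.get(r.compound_id)]
    dropped = [r for r in records if not spectra_by_compound.get(r.compound_id)]

    def expand(rs: Sequence[RIRecord]) -> list[RIRecord]:
        return [
            replace(r, spectrum_id=sid)
            for r in rs
            for sid in spectra_by_compound[r.compound_id]
        ]

    spec = SplitSpec(class_edges=class_edges, train_fraction=fraction, seed=seed)
    if group_by_compound:
        y = np.array([r.r_i for r in with_spec])
        tr, te = stratified_split(y, spec) if len(with_spec) else ([], [])
        train_recs = expand([with_spec[i] for i in tr])
        test_recs = expand([with_spec[i] for i in te])
    else:
        entries = expand(with_spec)
        y = np.array([r.r_i for r in entries])
        tr, te = stratified_split(y, spec) if entries else ([], [])
        train_recs = [entries[i] for i in tr]
        test_recs = [entries[i] for i in te]
    return train_recs, test_recs, dropped


def assemble_cnl_training(
    corpus_records: Sequence[RIRecord],
    experimental_records: Sequence[RIRecord],
    plan: AssemblyPlan,
    spectra: Sequence[Spectrum],
    class_edges: tuple[float, ...] = SplitSpec().class_edges,
) -> AssembledSets:
    """Combine pseudo-labeled corpus and experimental entries for training.

    The training set takes ``corpus_train_fraction`` of the corpus and
    ``experimental_train_fraction`` of the experimental records, both
    stratified over the r_i classes; every record expands to one entry
    per spectrum of its compound. The withheld experimental test set
    contains only compounds wholly absent from training. Records whose
    compound has no spectrum are dropped and listed.
    """
    by_compound: dict[str, list[str]] = {}
    for s in spectra:
        if s.compound_id is not None:
            by_compound.setdefault(s.compound_id, []).append(s.spectrum_id)

    overlap = {r.compound_id for r in corpus_records} & {
        r.compound_id for r in experimental_records
    }
    if overlap:
        raise ValueError(f"compounds present in both corpus and experimental: {sorted(overlap)}")

    c_train, c_test, c_drop = _grouped_split(
        list(corpus_records), by_compound, plan.corpus_train_fraction,
        plan.seed, plan.group_by_compound, class_edges,
    )
    e_train, e_test, e_drop = _grouped_split(
        list(experimental_records), by_compound, plan.experimental_train_fraction,
        plan.seed + 1, plan.group_by_compound, class_edges,
    )
    if not c_test or not e_test:
        logger.warning("near-empty test set(s): corpus=%d experimental=%d", len(c_test), len(e_test))
    sets = AssembledSets(
        train=c_train + e_train,
        corpus_test=c_test,
        experimental_test=e_test,
        dropped=c_drop + e_drop,
    )
    if sets.dropped:
        logger.warning("%d record(s) without spectra dropped", len(sets.dropped))
    return sets


@dataclass(frozen=True)
class TwoStageConfig:
    """All knobs of one end-to-end run; one seed drives every stage."""

    seed: int = 0
    descriptor_train_fraction: float = 0.85
    validation_fraction: float = 0.15
    corpus_train_fraction: float = 0.85
    experimental_train_fraction: float = 0.30
    stability_threshold: float = 0.01
    top_k_descriptors: int = 40
    ad_percentile: float = 95.0
    cnl_ad_ridge: float = 1e-8
    descriptor_config: GBTConfig = DESCRIPTOR_PRESET
    cnl_config: GBTConfig = CNL_PRESET
    group_by_compound: bool = True
    class_edges: tuple[float, ...] = SplitSpec().class_edges

    def stage_seed(self, k: int) -> int:
        return (self.seed * 10007 + k) % (2**31 - 1)


@dataclass
class TwoStageResult:
    curation_report: CurationReport
    descriptor_model_full: TrainedModel
    descriptor_model: TrainedModel
    descriptor_ad: ADModel
    descriptor_reports: dict[str, EvalReport]
    pseudo_labels: list[RIRecord]
    out_of_domain: list[tuple[str, float]]
    assembled: AssembledSets
    cnl_model: TrainedModel
    cnl_ad: ADModel
    cnl_reports: dict[str, EvalReport]
    manifest: dict

    def persist(self, out_dir: str | Path) -> None:
        """Write models, reports and the run manifest under a directory."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.curation_report.to_json(out / "curation_report.json")
        save_model(self.descriptor_model, out / "descriptor_model.joblib")
        save_model(self.cnl_model, out / "cnl_model.joblib")
        reports = {
            "descriptor": {k: v.as_dict() for k, v in self.descriptor_reports.items()},
            "cnl": {k: v.as_dict() for k, v in self.cnl_reports.items()},
            "ad": {
                "descriptor_h_star": self.descriptor_ad.h_star,
                "cnl_h_star": self.cnl_ad.h_star,
            },
        }
        (out / "reports.json").write_text(json.dumps(reports, indent=2))
        pd.DataFrame(
            [
                {"compound_id": r.compound_id, "r_i": r.r_i, "leverage": r.leverage}
                for r in self.pseudo_labels
            ]
        ).to_csv(out / "pseudo_labels.csv", index=False)
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=2))


def _carve_validation(
    records: list[RIRecord], fraction: float, seed: int, class_edges: tuple[float, ...]
) -> tuple[list[RIRecord], list[RIRecord]]:
    """Split train entries into fit/validation, compound-grouped."""
    compounds: dict[str, float] = {}
    for r in records:
        compounds.setdefault(r.compound_id, r.r_i)
    cids = list(compounds)
    y = np.array([compounds[c] for c in cids])
    spec = SplitSpec(class_edges=class_edges, train_fraction=1 - fraction, seed=seed)
    fit_i, val_i = stratified_split(y, spec)
    fit_c = {cids[i] for i in fit_i}
    return [r for r in records if r.compound_id in fit_c], [
        r for r in records if r.compound_id not in fit_c
    ]


def run_two_stage(
    replicate_descriptors: Sequence[DescriptorTable],
    corpus_descriptors: DescriptorTable,
    labels: pd.DataFrame,
    spectra: Sequence[Spectrum],
    config: TwoStageConfig = TwoStageConfig(),
    grid: CNLGrid | None = None,
    out_dir: str | Path | None = None,
) -> TwoStageResult:
    """Run the full two-stage workflow from raw inputs to both models.

    Parameters
    ----------
    replicate_descriptors:
        Replicated descriptor tables (>= 2) of the experimentally
        measured compounds; drives curation and the descriptor model.
    corpus_descriptors:
        Single descriptor table of the unlabeled spectral corpus.
    labels:
        Experimental r_i values, columns ``compound_id`` and ``r_i``.
    spectra:
        MS/MS spectra of both experimental and corpus compounds.

    The run is reproducible from ``config.seed``; pass ``out_dir`` to
    persist every intermediate (curation report, pseudo-labels, models,
    metrics, manifest).
    """
    grid = grid or CNLGrid()
    manifest: dict = {"seed": config.seed}

    def stage(name):
        def deco(fn):
            try:
                return fn()
            except Exception as exc:
                raise PipelineError(name, exc) from exc

        return deco

    # --- stage 1: curation -------------------------------------------------
    @stage("curation")
    def curation() -> CurationReport:
        return stability_filter(replicate_descriptors, threshold=config.stability_threshold)

    report = curation
    manifest["descriptors_kept"] = len(report.kept)
    manifest["descriptors_dropped_unstable"] = len(report.dropped_unstable)

    @stage("descriptor-matrix")
    def desc_matrix() -> tuple[pd.DataFrame, np.ndarray]:
        curated = [apply_curation(t, report).frame for t in replicate_descriptors]
        X = sum(curated[1:], curated[0]) / len(curated)  # replicate mean
        lab = labels.set_index("compound_id")["r_i"].astype(float)
        common = [c for c in X.index if c in lab.index]
        if not common:
            raise ValueError("no overlap between descriptor compounds and labels")
        return X.loc[common], lab.loc[common].to_numpy()

    X_exp, y_exp = desc_matrix

    # --- stage 2: descriptor model -----------------------------------------
    @stage("descriptor-model")
    def desc_model() -> tuple:
        spec = SplitSpec(
            class_edges=config.class_edges,
            train_fraction=config.descriptor_train_fraction,
            seed=config.stage_seed(1),
        )
        tr, te = stratified_split(y_exp, spec)
        fit_spec = SplitSpec(
            class_edges=config.class_edges,
            train_fraction=1 - config.validation_fraction,
            seed=config.stage_seed(2),
        )
        fit_i, val_i = stratified_split(y_exp[tr], fit_spec)
        fit_rows, val_rows = tr[fit_i], tr[val_i]
        cfg = config.descriptor_config.with_seed(config.stage_seed(3))
        full = train(
            X_exp.iloc[fit_rows], y_exp[fit_rows], cfg,
            validation=(X_exp.iloc[val_rows], y_exp[val_rows]),
        )
        top_k = min(config.top_k_descriptors, len(full.feature_names))
        refit = refit_top_features(
            full, X_exp.iloc[fit_rows], y_exp[fit_rows], top_k=top_k,
            validation=(X_exp.iloc[val_rows], y_exp[val_rows]),
        )
        reports = {
            "train": evaluate(predict(refit, X_exp.iloc[tr]), y_exp[tr]),
            "test": evaluate(predict(refit, X_exp.iloc[te]), y_exp[te]),
        }
        return full, refit, tr, te, reports

    full_model, refit_model, desc_train_rows, desc_test_rows, desc_reports = desc_model
    manifest["descriptor_train_n"] = int(len(desc_train_rows))
    manifest["descriptor_test_n"] = int(len(desc_test_rows))

    @stage("descriptor-ad")
    def desc_ad() -> ADModel:
        X = X_exp.iloc[desc_train_rows][refit_model.feature_names].to_numpy(dtype=float)
        return fit_ad(X, refit_model.feature_names, percentile=config.ad_percentile)

    ad_desc = desc_ad

    # --- stage 3: pseudo-labeling ------------------------------------------
    @stage("pseudo-labeling")
    def do_pseudo() -> tuple:
        curated_corpus = apply_curation(corpus_descriptors, report)
        return pseudo_label(refit_model, ad_desc, curated_corpus)

    corpus_records, ood = do_pseudo
    manifest["pseudo_labeled"] = len(corpus_records)
    manifest["out_of_domain"] = len(ood)

    # --- stage 4: CNL featurization and assembly ---------------------------
    @stage("cnl-featurization")
    def featurize() -> CNLFeatureMatrix:
        return build_feature_matrix(spectra, grid, skip_invalid=True)

    matrix = featurize
    manifest["spectra_featurized"] = matrix.n_rows
    manifest["spectra_rejected"] = len(matrix.rejected)

    @stage("assembly")
    def assemble() -> AssembledSets:
        exp_records = [
            RIRecord(str(row.compound_id), float(row.r_i), "experimental")
            for row in labels.itertuples()
        ]
        plan = AssemblyPlan(
            corpus_train_fraction=config.corpus_train_fraction,
            experimental_train_fraction=config.experimental_train_fraction,
            seed=config.stage_seed(4),
            group_by_compound=config.group_by_compound,
        )
        return assemble_cnl_training(
            corpus_records, exp_records, plan, spectra, class_edges=config.class_edges
        )

    sets = assemble
    manifest["cnl_train_n"] = len(sets.train)
    manifest["cnl_corpus_test_n"] = len(sets.corpus_test)
    manifest["cnl_experimental_test_n"] = len(sets.experimental_test)
    manifest["records_without_spectra"] = len(sets.dropped)

    # --- stage 5: CNL model -------------------------------------------------
    @stage("cnl-model")
    def cnl_model_stage() -> tuple:
        frame_all = matrix.to_model_frame()  # bins occupied anywhere; selection below
        train_ids = [r.spectrum_id for r in sets.train]
        # restrict model columns to bins observed in the training rows only
        train_frame = frame_all.loc[train_ids]
        bin_cols = [c for c in train_frame.columns if c.startswith("cnl_")]
        keep = [c for c in bin_cols if (train_frame[c] == 1).any()]
        cols = keep + [c for c in train_frame.columns if not c.startswith("cnl_")]
        fit_recs, val_recs = _carve_validation(
            sets.train, config.validation_fraction, config.stage_seed(5), config.class_edges
        )
        cfg = config.cnl_config.with_seed(config.stage_seed(6))

        def xy(recs: list[RIRecord]) -> tuple[pd.DataFrame, np.ndarray]:
            ids = [r.spectrum_id for r in recs]
            return frame_all.loc[ids, cols], np.array([r.r_i for r in recs])

        model = train(*xy(fit_recs), cfg, validation=xy(val_recs))
        reports = {}
        for name, recs in (
            ("train", sets.train),
            ("corpus_test", sets.corpus_test),
            ("experimental_test", sets.experimental_test),
        ):
            X, y = xy(recs)
            reports[name] = evaluate(predict(model, X), y)
        return model, reports, xy

    cnl_model, cnl_reports, xy = cnl_model_stage
    manifest["cnl_used_features"] = len(cnl_model.used_features)

    @stage("cnl-ad")
    def cnl_ad_stage() -> ADModel:
        X_train, _ = xy(sets.train)
        X_used = X_train[cnl_model.used_features].to_numpy(dtype=float)
        return fit_ad(
            X_used, cnl_model.used_features,
            percentile=config.ad_percentile, ridge=config.cnl_ad_ridge,
        )

    ad_cnl = cnl_ad_stage

    result = TwoStageResult(
        curation_report=report,
        descriptor_model_full=full_model,
        descriptor_model=refit_model,
        descriptor_ad=ad_desc,
        descriptor_reports=desc_reports,
        pseudo_labels=corpus_records,
        out_of_domain=ood,
        assembled=sets,
        cnl_model=cnl_model,
        cnl_ad=ad_cnl,
        cnl_reports=cnl_reports,
        manifest=manifest,
    )
    if out_dir is not None:
        result.persist(out_dir)
    return result
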