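"""Per-band end-to-end orchestration, summary tables and run manifests.

``run_band`` executes the whole funnel for one band — univariate screen,
unsupervised structure at the all-edges and significant-edges stages,
participant split, CV-SVM-rRF-FS on the training set, final SVM, permutation
test, external ROC/AUC, PLS-DA/VIP verification, and the selected-edges
structure stage — and optionally writes every stage output as CSV/JSON plus
a checksummed manifest. ``aggregate_tables`` folds band reports into the
two summary tables (per-band significant/selected counts with directions;
the consensus edge list as region pairs) and an evaluation summary.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .dataset import ConnectomeDataset
from .pipeline import (
    EvaluationResult,
    FeatureSelectionResult,
    FinalModel,
    PermutationResult,
    PipelineConfig,
    SplitSpec,
    cv_svm_rrf_fs,
    evaluate_test,
    filtered_training_space,
    permutation_test,
    stratified_split,
    train_final_svm,
)
from .plsda import PLSDAResult, VIP_THRESHOLD, fit_plsda, plsda_cv_performance, vip_scores
from .structure import ClusteringReport, PCAReport, hierarchical_clusters, pca_report
from .univariate import (
    BandSummary,
    UnivariateResult,
    edge_ttest,
    filter_significant,
    summarize_bands,
)

__all__ = ["BandReport", "RunManifest", "run_band", "aggregate_tables", "write_band_report"]


@dataclass
class RunManifest:
    """What produced which outputs: seeds, config hash, checksums."""

    seed: int
    band: str
    config: dict
    config_hash: str
    package_version: str
    started: str
    outputs: dict[str, str] = field(default_factory=dict)  # path -> sha256

    def record(self, path: Path) -> None:
        self.outputs[path.name] = hashlib.sha256(path.read_bytes()).hexdigest()

    def write(self, path: Path) -> None:
        path.write_text(json.dumps(self.__dict__, indent=1, default=str))

    def verify(self, directory: Path) -> bool:
        for name, digest in self.outputs.items():
            f = directory / name
            if not f.exists():
                return False
            if hashlib.sha256(f.read_bytes()).hexdigest() != digest:
                return False
        return True


@dataclass
class BandReport:
    """Everything the pipeline produces for one frequency band."""

    band: str
    univariate: UnivariateResult
    clustering_all: ClusteringReport
    clustering_significant: ClusteringReport | None
    pca_all: PCAReport
    pca_significant: PCAReport | None
    pca_selected: PCAReport | None
    split: SplitSpec
    feature_selection: FeatureSelectionResult | None
    model: FinalModel
    permutation: PermutationResult | None
    evaluation: EvaluationResult
    plsda: PLSDAResult | None
    vip: np.ndarray | None
    plsda_cv_accuracy: float | None

    @property
    def no_signal(self) -> bool:
        return self.model.no_signal


def _config_hash(config: PipelineConfig) -> str:
    return hashlib.sha256(json.dumps(config.to_dict(), sort_keys=True).encode()).hexdigest()[:16]


def run_band(
    dataset: ConnectomeDataset,
    config: PipelineConfig | None = None,
    seed: int = 0,
    out_dir=None,
) -> BandReport:
    """Run the full discovery funnel on one band's dataset.

    All randomness derives from ``seed`` via documented per-stage labels, so
    two runs with the same seed, config and input are identical.
    """
    config = config or PipelineConfig()
    # descriptive arm (full sample): univariate table + structure stages
    uni = edge_ttest(dataset, alpha=config.alpha, fdr=config.fdr)
    clus_all = hierarchical_clusters(dataset, cluster_edges=False)
    pca_all = pca_report(dataset, stage="all_edges")
    sig_ds = filter_significant(dataset, uni)
    clus_sig = pca_sig = None
    if sig_ds.n_edges >= 2:
        clus_sig = hierarchical_clusters(sig_ds)
        pca_sig = pca_report(sig_ds, stage="significant")
    # leakage-safe arm: split first, then everything on the training set
    split = stratified_split(dataset, config.test_fraction, seed)
    train_space = filtered_training_space(dataset, split, config)
    fs = None
    if train_space.n_edges >= 2:
        fs = cv_svm_rrf_fs(train_space, config, seed=seed)
        consensus = fs.consensus_edges
    else:
        consensus = np.array([], dtype=int)
    train = dataset.select_subjects(split.train_ids)
    test = dataset.select_subjects(split.test_ids)
    model = train_final_svm(train, consensus, config, seed=seed)
    perm = None
    if not model.no_signal:
        perm = permutation_test(train, model, config, seed=seed)
    evaluation = evaluate_test(model, test)
    plsda_model = vip = plsda_acc = None
    if not model.no_signal and len(consensus) >= 1:
        sel = train.select_edges(consensus)
        a = min(2, min(sel.n_subjects - 1, sel.n_edges))
        plsda_model = fit_plsda(sel.X, sel.labels, n_components=a)
        vip = vip_scores(plsda_model)
        plsda_acc, _ = plsda_cv_performance(
            sel.X, sel.labels, n_components=a, k_folds=config.k_folds, seed=seed
        )
    pca_sel = None
    if len(consensus) >= 2:
        sel_full = dataset.select_edges(consensus)
        pca_sel = pca_report(sel_full, stage="selected")
    report = BandReport(
        band=dataset.band,
        univariate=uni,
        clustering_all=clus_all,
        clustering_significant=clus_sig,
        pca_all=pca_all,
        pca_significant=pca_sig,
        pca_selected=pca_sel,
        split=split,
        feature_selection=fs,
        model=model,
        permutation=perm,
        evaluation=evaluation,
        plsda=plsda_model,
        vip=vip,
        plsda_cv_accuracy=plsda_acc,
    )
    if out_dir is not None:
        write_band_report(report, dataset, config, seed, Path(out_dir))
    return report


def consensus_table(report: BandReport, edge_index) -> pd.DataFrame:
    """Consensus edges as (band, region_1, region_2) rows."""
    rows = []
    for e in report.model.consensus_edges:
        i, j = edge_index.edge_regions(int(e))
        rows.append(
            {
                "band": report.band,
                "region_1": edge_index.region_names[i],
                "region_2": edge_index.region_names[j],
            }
        )
    return pd.DataFrame(rows, columns=["band", "region_1", "region_2"])


def evaluation_summary(report: BandReport) -> dict:
    return {
        "band": report.band,
        "n_consensus_edges": int(len(report.model.consensus_edges)),
        "cv_mean": report.model.cv_mean,
        "cv_sd": report.model.cv_sd,
        "n_support_vectors": report.model.n_support_vectors,
        "svm_C": report.model.c,
        "svm_gamma": report.model.gamma,
        "permutation_p": None if report.permutation is None else report.permutation.p_value,
        "auc": report.evaluation.auc,
        "plsda_cv_accuracy": report.plsda_cv_accuracy,
        "no_signal": report.no_signal,
    }


def write_band_report(
    report: BandReport,
    dataset: ConnectomeDataset,
    config: PipelineConfig,
    seed: int,
    out_dir: Path,
) -> RunManifest:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(
        seed=seed,
        band=report.band,
        config=config.to_dict(),
        config_hash=_config_hash(config),
        package_version=__version__,
        started=time.strftime("%Y-%m-%dT%H:%M:%S"),
    )
    idx = dataset.edge_index
    paths = {}
    paths["univariate.csv"] = report.univariate.to_frame(idx)
    paths["consensus_edges.csv"] = consensus_table(report, idx)
    if report.feature_selection is not None:
        paths["selection_frequency.csv"] = pd.DataFrame(
            sorted(report.feature_selection.selection_frequency.items()),
            columns=["edge_id", "n_folds_selected"],
        )
    paths["roc.csv"] = pd.DataFrame(report.evaluation.roc, columns=["fpr", "tpr"])
    if report.vip is not None:
        paths["vip.csv"] = pd.DataFrame(
            {
                "edge_id": report.model.consensus_edges,
                "edge": [idx.edge_label(int(e)) for e in report.model.consensus_edges],
                "vip": report.vip,
                "important": report.vip >= VIP_THRESHOLD,
            }
        )
    for stage, rep in (
        ("all_edges", report.pca_all),
        ("significant", report.pca_significant),
        ("selected", report.pca_selected),
    ):
        if rep is not None:
            paths[f"pca_{stage}.csv"] = rep.scores
    for name, df in paths.items():
        f = out_dir / name
        df.to_csv(f, index=name.startswith("pca_"))
        manifest.record(f)
    ev = out_dir / "evaluation.json"
    ev.write_text(json.dumps(evaluation_summary(report), indent=1))
    manifest.record(ev)
    manifest.write(out_dir / "manifest.json")
    return manifest


def aggregate_tables(reports, edge_index) -> dict[str, pd.DataFrame]:
    """Fold band reports into the study-style summary tables.

    ``summary``: one row per band with significant and selected edge counts,
    each split by direction — the selected edges' directions are read off
    the corresponding univariate result. ``consensus``: (band, region_1,
    region_2) rows. ``evaluation``: per-band model metrics.
    """
    reports = list(reports)
    if not reports:
        raise ValueError("no band reports to aggregate")
    band_summary: BandSummary = summarize_bands([r.univariate for r in reports])
    rows = []
    for r, (_, uni_row) in zip(reports, band_summary.table.iterrows()):
        dirs = dict(zip(r.univariate.edge_ids.tolist(), r.univariate.direction.tolist()))
        sel = [dirs.get(int(e), "increase") for e in r.model.consensus_edges]
        rows.append(
            {
                "band": r.band,
                "n_significant": uni_row["n_significant"],
                "sig_increase": uni_row["n_increase"],
                "sig_decrease": uni_row["n_decrease"],
                "n_selected": len(r.model.consensus_edges),
                "sel_increase": sum(d == "increase" for d in sel),
                "sel_decrease": sum(d == "decrease" for d in sel),
            }
        )
    summary = pd.DataFrame(rows)
    consensus = pd.concat(
        [consensus_table(r, edge_index) for r in reports], ignore_index=True
    )
    evaluation = pd.DataFrame([evaluation_summary(r) for r in reports])
    meta = pd.DataFrame(
        [
            {
                "mean_significant": band_summary.mean_significant,
                "sd_significant": band_summary.sd_significant,
            }
        ]
    )
    return {
        "summary": summary,
        "consensus": consensus,
        "evaluation": evaluation,
        "significant_mean_sd": meta,
    }
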