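"""End-to-end orchestration: community prep -> chemistry -> selection -> stats -> network.

A single YAML-loadable :class:`RunConfig` drives everything; every
stochastic stage takes its own named seed and all seeds, versions and
method decisions (IndVal variant, NN importance method, distance
metric) are recorded in a JSON run manifest, which suffices to re-run
the identical analysis.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, chem, community, io, network
from .feature_select import ConsensusSelector, make_group_labels
from .stats import anosim, distance_matrix, doc_class_correlations, pca_biplot, permanova
from .synthetic import SyntheticConfig, generate_dataset

__all__ = ["RunConfig", "run_pipeline", "load_config"]

log = logging.getLogger("doclinker")


@dataclass
class RunConfig:
    """Everything one analysis run needs.

    Either ``synthetic`` is set (generate the study in-memory) or the
    input paths must point at existing files.
    """

    output_dir: str = "doclinker_run"
    synthetic: SyntheticConfig | None = None
    otu_table_bacteria: str | None = None
    otu_table_fungi: str | None = None
    taxonomy_bacteria: str | None = None
    taxonomy_fungi: str | None = None
    fticr_dir: str | None = None
    doc_table: str | None = None
    boundary_table: str | None = None
    rarefaction_depth_bacteria: int = 1023
    rarefaction_depth_fungi: int = 2032
    cohort_quantiles: tuple[float, float] = (0.5, 0.5)
    n_perm: int = 999
    alpha: float = 0.05
    rf_n_iter: int = 50
    nn_search: int = 10
    distance_metric: str = "jaccard"
    indval_sqrt: bool = True
    nn_importance_method: str = "connection_weight"
    focus_class: str = "protein"
    seeds: dict = field(
        default_factory=lambda: {"rarefaction": 1, "selection": 2, "permutation": 3}
    )

    def validate(self) -> None:
        if self.synthetic is None:
            required = {
                "otu_table_bacteria": self.otu_table_bacteria,
                "taxonomy_bacteria": self.taxonomy_bacteria,
                "fticr_dir": self.fticr_dir,
                "doc_table": self.doc_table,
            }
            missing = [k for k, v in required.items() if v is None]
            if missing:
                raise ValueError(f"non-synthetic run needs inputs: {missing}")
            absent = [k for k, v in required.items() if v is not None and not Path(v).exists()]
            for opt in ("otu_table_fungi", "taxonomy_fungi", "boundary_table"):
                v = getattr(self, opt)
                if v is not None and not Path(v).exists():
                    absent.append(opt)
            if absent:
                raise FileNotFoundError(f"input path(s) do not exist: {absent}")


def load_config(path) -> RunConfig:
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if "synthetic" in raw and raw["synthetic"] is not None:
        raw["synthetic"] = SyntheticConfig(**raw["synthetic"])
    if "cohort_quantiles" in raw:
        raw["cohort_quantiles"] = tuple(raw["cohort_quantiles"])
    return RunConfig(**raw)


def _load_inputs(config: RunConfig):
    if config.synthetic is not None:
        study = generate_dataset(config.synthetic)
        return (
            study.doc,
            study.bacteria_counts,
            study.fungi_counts,
            study.bacteria_taxonomy,
            study.fungi_taxonomy,
            study.fticr_samples,
        )
    doc = io.read_doc_csv(config.doc_table)
    bacteria = io.read_otu_tsv(config.otu_table_bacteria)
    tax_b = io.read_taxonomy_tsv(config.taxonomy_bacteria)
    fungi = io.read_otu_tsv(config.otu_table_fungi) if config.otu_table_fungi else None
    tax_f = io.read_taxonomy_tsv(config.taxonomy_fungi) if config.taxonomy_fungi else None
    samples = io.read_fticr_dir(config.fticr_dir)
    return doc, bacteria, fungi, tax_b, tax_f, samples


def _community_stage(counts, taxonomy, depth, seed, outdir, label):
    filtered, annotated = community.filter_by_confidence(counts, taxonomy)
    rare = community.rarefy(filtered, depth, seed)
    io.write_otu_tsv(rare, outdir / f"{label}_rarefied.tsv")
    io.write_taxonomy_tsv(annotated, outdir / f"{label}_taxonomy_annotated.tsv")
    return rare, annotated


def _effective_label(annotated: pd.DataFrame, otu: str) -> str:
    row = annotated.loc[otu]
    eff = row.get("effective_rank")
    if eff is None or (isinstance(eff, float) and pd.isna(eff)):
        return str(otu)
    return f"{row[eff]}"


def run_pipeline(config: RunConfig, output_dir: str | None = None) -> dict:
    """Execute all stages; returns the run manifest (also written to disk).

    Any stage failure is re-raised with the stage name; partial outputs
    stay on disk next to a FAILED marker naming the stage.
    """
    config.validate()
    outdir = Path(output_dir or config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = dict(config.seeds)
    manifest = {
        "doclinker_version": __version__,
        "seeds": seeds,
        "decisions": {
            "indval_variant": "sqrt(A*B)" if config.indval_sqrt else "A*B",
            "nn_importance_method": config.nn_importance_method,
            "distance_metric": config.distance_metric,
            "cohort_quantiles": list(config.cohort_quantiles),
            "alpha": config.alpha,
            "n_perm": config.n_perm,
        },
        "synthetic": dataclasses.asdict(config.synthetic) if config.synthetic else None,
        "stages": [],
    }
    stage = "load_inputs"
    try:
        doc, bacteria, fungi, tax_b, tax_f, fticr_samples = _load_inputs(config)
        if config.synthetic is not None:
            io.write_doc_csv(doc, outdir / "doc.csv")
        manifest["stages"].append(stage)

        stage = "community"
        rare_b, annot_b = _community_stage(
            bacteria, tax_b, config.rarefaction_depth_bacteria, seeds["rarefaction"], outdir, "bacteria"
        )
        rare_f = annot_f = None
        if fungi is not None and tax_f is not None:
            rare_f, annot_f = _community_stage(
                fungi, tax_f, config.rarefaction_depth_fungi, seeds["rarefaction"] + 1, outdir, "fungi"
            )
        manifest["stages"].append(stage)

        stage = "fticr_chem"
        boundaries = (
            io.read_boundaries(config.boundary_table) if config.boundary_table else chem.DEFAULT_BOUNDARIES
        )
        raw_profiles = chem.profile_matrix(fticr_samples, boundaries)
        normalized = chem.normalize_profiles(raw_profiles)
        transformed = chem.transform_profiles(normalized)
        raw_profiles.to_csv(outdir / "class_counts_raw.csv")
        normalized.to_csv(outdir / "class_counts_lignin_normalized.csv")
        transformed.to_csv(outdir / "class_profiles_transformed.csv")
        manifest["stages"].append(stage)

        # align everything on the samples surviving every stage
        common = [s for s in doc.index if s in rare_b.index and s in normalized.index]
        if rare_f is not None:
            common = [s for s in common if s in rare_f.index]
        doc_c = doc.loc[common]

        stage = "feature_select"
        tables = {"bacteria": (rare_b, annot_b)}
        if rare_f is not None:
            tables["fungi"] = (rare_f, annot_f)
        selectors: dict[str, ConsensusSelector] = {}
        for label, (rare, annot) in tables.items():
            sel = ConsensusSelector(
                rf_n_iter=config.rf_n_iter,
                nn_search=config.nn_search,
                n_perm=config.n_perm,
                alpha=config.alpha,
                cohort_quantiles=config.cohort_quantiles,
                sqrt_form=config.indval_sqrt,
                random_state=seeds["selection"],
            )
            sel.fit(rare.loc[common], doc_c)
            scores = sel.scores_.copy()
            scores.insert(0, "taxon_label", [_effective_label(annot, o) for o in scores.index])
            scores.to_csv(outdir / f"{label}_feature_scores.tsv", sep="\t")
            selectors[label] = sel
        manifest["stages"].append(stage)

        stage = "assoc_stats"
        corr = doc_class_correlations(normalized.loc[common], doc_c)
        corr.to_csv(outdir / "doc_class_correlations.tsv", sep="\t")
        presence = _peak_presence(fticr_samples, common)
        d = distance_matrix(presence.to_numpy(), metric=config.distance_metric)
        groups = make_group_labels(doc_c, config.cohort_quantiles)
        perm = permanova(d, groups, n_perm=config.n_perm, seed=seeds["permutation"])
        ano = anosim(d, groups, n_perm=config.n_perm, seed=seeds["permutation"] + 1)
        pd.DataFrame(d, index=common, columns=common).to_csv(outdir / "distance_matrix.tsv", sep="\t")
        scores_m, loadings, var_frac = pca_biplot(transformed.loc[common].to_numpy())
        pd.DataFrame(
            scores_m[:, :2], index=common, columns=["PC1", "PC2"]
        ).to_csv(outdir / "pca_scores.csv")
        pd.DataFrame(
            loadings[:, :2], index=transformed.columns, columns=["PC1", "PC2"]
        ).to_csv(outdir / "pca_loadings.csv")
        stats_payload = {
            "permanova": dataclasses.asdict(perm),
            "anosim": dataclasses.asdict(ano),
            "pca_variance_fractions": [float(v) for v in var_frac],
        }
        (outdir / "cohort_tests.json").write_text(json.dumps(stats_payload, indent=2))
        manifest["stages"].append(stage)

        stage = "network"
        consensus_taxa = pd.concat(
            [tables[label][0].loc[common, selectors[label].selected_] for label in selectors],
            axis=1,
        )
        edges = network.build_edges(consensus_taxa, normalized.loc[common], doc_c, alpha=config.alpha)
        network.write_sif(edges, outdir / "network.sif")
        network.write_edge_attributes(edges, outdir / "network_edges.tsv")
        groups_all = pd.concat(
            [selectors[label].scores_["indval_group"] for label in selectors]
        )
        try:
            verdicts = network.consistency_check(
                edges, groups_all.loc[list(consensus_taxa.columns)], focus_class=config.focus_class
            )
        except ValueError as exc:
            log.warning("consistency check skipped: %s", exc)
            verdicts = pd.DataFrame()
        verdicts.to_csv(outdir / "consistency.tsv", sep="\t", index=False)
        manifest["stages"].append(stage)

        manifest["summary"] = {
            "n_samples": len(common),
            "permanova_f": perm.f_stat,
            "permanova_r2": perm.r2,
            "permanova_p": perm.p,
            "anosim_r": ano.r_stat,
            "anosim_p": ano.p,
            "consensus_taxa": {k: list(v.selected_) for k, v in selectors.items()},
            "consistency_fraction": (
                float(verdicts["consistent"].mean()) if len(verdicts) else None
            ),
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        return manifest
    except Exception as exc:
        (outdir / "FAILED").write_text(f"stage: {stage}\nerror: {exc}\n")
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _peak_presence(fticr_samples, sample_ids) -> pd.DataFrame:
    """Samples x formulas presence/absence matrix over merged peak lists."""
    keys_per_sample = {}
    universe: dict[tuple, int] = {}
    for s in fticr_samples:
        if s.sample_id not in sample_ids:
            continue
        merged = s.merged_formulas()
        keys = [tuple(r) for r in merged.to_numpy()]
        keys_per_sample[s.sample_id] = keys
        for k in keys:
            universe.setdefault(k, len(universe))
    mat = np.zeros((len(sample_ids), len(universe)), dtype=np.int8)
    for i, sid in enumerate(sample_ids):
        for k in keys_per_sample.get(sid, ()):
            mat[i, universe[k]] = 1
    return pd.DataFrame(mat, index=list(sample_ids))
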