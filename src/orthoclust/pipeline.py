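"""End-to-end orchestration: filter → three clusterings → signatures →
AGDEX → centroid correlation, as one configured, seeded, logged run.

The three subgrouping methods are reported side by side with a pairwise
adjusted-Rand concordance table; no fused partition is invented. All outputs
are plain TSV/JSON; the manifest records parameters, seed, warnings and a
sha256 per output file (no timestamps, so identical runs hash identically).
"""

from __future__ import annotations

import hashlib
import json
import logging
import warnings as _warnings
from dataclasses import dataclass, asdict, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from sklearn.metrics import adjusted_rand_score

from . import __version__
from .io import (
    ExpressionMatrix,
    load_expression_matrix,
    load_ortholog_map,
    load_sample_annotation,
    to_1to1,
    validate_annotation,
    write_expression_matrix,
)
from .filtering import apply_filters
from .cluster import (
    average_linkage_cut,
    consensus_cluster,
    pearson_distance,
    NmfSubgrouper,
)
from .diffexp import group_signatures
from .cross_species import agdex_matrix, centroid_correlation

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    matrix_a: str = ""
    matrix_b: str = ""
    annotation: str = ""
    orthologs: str = ""
    reference_a: str = ""           # annotation group holding species-A reference tissue
    reference_b: str = ""
    output_dir: str = "orthoclust_out"
    background: float = 1.2
    riqr: float = 0.75
    riqr_formula: str = "symmetric"
    k_min: int = 2
    k_max: int = 7
    resamplings: int = 1000
    p_item: float = 0.8
    nmf_runs: int = 30
    nmf_max_iter: int = 300
    nmf_clip_at_zero: bool = False
    alpha: float = 0.05
    min_fc: float = 1.2
    adjust: bool = True
    n_perm: int = 1000
    zscore_centroids: bool = False
    group_source: str = "consensus"  # or "annotation"
    ortholog_policy: str = "drop_all"
    seed: int = 0


_REQUIRED_PATHS = ("matrix_a", "matrix_b", "annotation", "orthologs")


def validate_config(source):
    """Resolve a config mapping or YAML/JSON path into a PipelineConfig.

    Returns (config, errors); config is None when errors is non-empty.
    Collects every violation instead of stopping at the first.
    """
    if isinstance(source, (str, Path)):
        with open(source, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
    elif isinstance(source, PipelineConfig):
        raw = asdict(source)
    else:
        raw = dict(source)
    errors = []
    known = set(PipelineConfig.__dataclass_fields__)
    for key in raw:
        if key not in known:
            errors.append(f"unknown config key {key!r}")
    cfg = PipelineConfig(**{k: v for k, v in raw.items() if k in known})
    for name in _REQUIRED_PATHS:
        val = getattr(cfg, name)
        if not val:
            errors.append(f"{name} is required")
        elif not Path(val).exists():
            errors.append(f"{name}: path {val!r} does not exist")
    if not cfg.reference_a or not cfg.reference_b:
        errors.append("reference_a and reference_b (reference group names) are required")
    if not 0 < cfg.alpha <= 1:
        errors.append("alpha must lie in (0,1]")
    if not 0 < cfg.p_item <= 1:
        errors.append("p_item must lie in (0,1]")
    if cfg.k_min < 2 or cfg.k_max < cfg.k_min:
        errors.append("need 2 <= k_min <= k_max")
    if cfg.resamplings < 1 or cfg.nmf_runs < 1 or cfg.n_perm < 1:
        errors.append("resamplings, nmf_runs and n_perm must be >= 1")
    if cfg.background < 0 or cfg.riqr < 0 or cfg.min_fc < 0:
        errors.append("thresholds must be non-negative")
    if cfg.group_source not in ("consensus", "annotation"):
        errors.append("group_source must be 'consensus' or 'annotation'")
    return (None, errors) if errors else (cfg, [])


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index)


def run_pipeline(config) -> dict:
    """Run the full analysis; returns the manifest (also written to disk)."""
    if not isinstance(config, PipelineConfig):
        config, errors = validate_config(config)
        if errors:
            raise ValueError("invalid configuration: " + "; ".join(errors))
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "orthoclust",
        "version": __version__,
        "parameters": asdict(config),
        "seed": config.seed,
        "stages": {},
        "warnings": [],
        "valid": False,
    }
    caught: list = []

    def _finish_stage(name, outputs):
        manifest["stages"][name] = {
            "outputs": {p.name: _sha256(p) for p in outputs}
        }

    stage = "load"
    try:
        ann = load_sample_annotation(config.annotation)
        omap = to_1to1(load_ortholog_map(config.orthologs), policy=config.ortholog_policy)
        species = {}
        matrices = {}
        for key, path in (("a", config.matrix_a), ("b", config.matrix_b)):
            probe = pd.read_csv(path, sep="\t", index_col=0, nrows=1)
            sp = ann.loc[ann["sample_id"].isin(probe.columns), "species"].unique()
            if len(sp) != 1:
                raise ValueError(
                    f"matrix_{key} samples map to {len(sp)} species in the annotation"
                )
            species[key] = sp[0]
            matrices[key] = load_expression_matrix(path, sp[0])
        validate_annotation(ann, list(matrices.values()))
        _finish_stage(stage, [])

        results: dict = {}
        for key in ("a", "b"):
            sp = species[key]
            rng_seed = int(config.seed) + (0 if key == "a" else 500)
            mat = matrices[key]
            sp_ann = ann[ann["species"] == sp]
            tumour = [s for s in mat.sample_ids if
                      s in set(sp_ann.loc[sp_ann["role"] == "tumour", "sample_id"])]

            # filters are computed on the tumour cohort — the samples the
            # clustering will partition; reference tissues enter later stages
            stage = f"filter[{sp}]"
            with _warnings.catch_warnings(record=True) as wlist:
                _warnings.simplefilter("always")
                tum, report = apply_filters(
                    mat.subset_samples(tumour), config.background, config.riqr,
                    riqr_formula=config.riqr_formula,
                )
            caught.extend(str(w.message) for w in wlist)
            f_rep = out / f"filter_report_{sp}.tsv"
            f_mat = out / f"filtered_{sp}.tsv"
            _write_tsv(report, f_rep)
            write_expression_matrix(tum, f_mat)
            _finish_stage(stage, [f_rep, f_mat])

            stage = f"consensus[{sp}]"
            with _warnings.catch_warnings(record=True) as wlist:
                _warnings.simplefilter("always")
                cons = consensus_cluster(
                    tum,
                    k_range=range(config.k_min, config.k_max + 1),
                    n_resamples=config.resamplings,
                    p_item=config.p_item,
                    seed=rng_seed,
                )
            caught.extend(str(w.message) for w in wlist)
            cons_files = []
            for k, M in cons.consensus_matrices.items():
                p = out / f"consensus_{sp}_k{k}.tsv"
                _write_tsv(pd.DataFrame(M, index=tum.sample_ids, columns=tum.sample_ids), p)
                cons_files.append(p)
            lab_c = out / f"labels_consensus_{sp}.tsv"
            _write_tsv(cons.labels.rename("cluster").to_frame(), lab_c)
            _finish_stage(stage, cons_files + [lab_c])

            stage = f"nmf[{sp}]"
            nmf = NmfSubgrouper(
                k_range=range(config.k_min, config.k_max + 1),
                n_runs=config.nmf_runs,
                max_iter=config.nmf_max_iter,
                clip_negative=config.nmf_clip_at_zero,
                random_state=rng_seed,
            ).fit(tum.values.to_numpy(dtype=float).T)
            lab_n = out / f"labels_nmf_{sp}.tsv"
            _write_tsv(
                pd.DataFrame({"cluster": nmf.labels_}, index=tum.sample_ids), lab_n
            )
            _finish_stage(stage, [lab_n])

            stage = f"hierarchical[{sp}]"
            hier = average_linkage_cut(pearson_distance(tum), cons.selected_k)
            lab_h = out / f"labels_hier_{sp}.tsv"
            _write_tsv(hier.to_frame(), lab_h)
            _finish_stage(stage, [lab_h])

            results[key] = {
                "species": sp,
                "tumour_matrix": tum,
                "tumour_samples": tumour,
                "consensus": cons,
                "nmf": nmf,
                "hier": hier,
                "annotation": sp_ann,
            }

        stage = "model_selection"
        rows = []
        for key in ("a", "b"):
            r = results[key]
            for k in sorted(r["consensus"].pac):
                rows.append(
                    (r["species"], k, r["consensus"].pac[k], r["nmf"].cophenetic_[k])
                )
        sel = pd.DataFrame(rows, columns=["species", "k", "pac", "cophenetic"])
        p_sel = out / "model_selection.tsv"
        _write_tsv(sel, p_sel, index=False)
        _finish_stage(stage, [p_sel])

        stage = "concordance"
        rows = []
        for key in ("a", "b"):
            r = results[key]
            parts = {
                "consensus": np.asarray(r["consensus"].labels),
                "nmf": np.asarray(r["nmf"].labels_),
                "hierarchical": np.asarray(r["hier"]),
            }
            names = list(parts)
            for i, m1 in enumerate(names):
                for m2 in names[i + 1:]:
                    rows.append(
                        (r["species"], m1, m2,
                         adjusted_rand_score(parts[m1], parts[m2]))
                    )
        conc = pd.DataFrame(rows, columns=["species", "method_1", "method_2", "ari"])
        p_conc = out / "concordance.tsv"
        _write_tsv(conc, p_conc, index=False)
        _finish_stage(stage, [p_conc])

        # group memberships used for signatures and AGDEX
        groupings = {}
        for key in ("a", "b"):
            r = results[key]
            if config.group_source == "consensus":
                lab = r["consensus"].labels
                groups = {
                    f"{r['species']}_c{int(c) + 1}": list(lab.index[lab == c])
                    for c in sorted(lab.unique())
                }
            else:
                sp_ann = r["annotation"]
                tum_ann = sp_ann[sp_ann["role"] == "tumour"]
                groups = {
                    g: list(sub["sample_id"])
                    for g, sub in tum_ann.groupby("group", sort=True)
                }
            groupings[key] = groups

        stage = "signatures"
        sig_rows = []
        for key in ("a", "b"):
            r = results[key]
            labels = {
                s: g for g, samples in groupings[key].items() for s in samples
            }
            usable = {g: v for g, v in groupings[key].items() if len(v) >= 2}
            if len(usable) >= 2:
                labels = {s: g for g, v in usable.items() for s in v}
                sigs = group_signatures(
                    r["tumour_matrix"], labels,
                    alpha=config.alpha, min_fc=config.min_fc, adjust=config.adjust,
                )
                for g, genes in sigs.signatures.items():
                    for gene in genes:
                        sig_rows.append((r["species"], g, gene))
            else:
                manifest["warnings"].append(
                    f"signatures skipped for {r['species']}: fewer than 2 usable groups"
                )
        sig_df = pd.DataFrame(sig_rows, columns=["species", "group", "gene_id"])
        p_sig = out / "signatures.tsv"
        _write_tsv(sig_df, p_sig, index=False)
        _finish_stage(stage, [p_sig])

        stage = "agdex"
        ref_samples = {}
        for key, ref_group in (("a", config.reference_a), ("b", config.reference_b)):
            sp_ann = results[key]["annotation"]
            refs = list(sp_ann.loc[sp_ann["group"] == ref_group, "sample_id"])
            if not refs:
                raise ValueError(
                    f"reference group {ref_group!r} has no samples in the annotation"
                )
            ref_samples[key] = refs
        # AGDEX runs on all ortholog genes (differential vectors need the
        # full gene universe, not the clustering gene set)
        scores, pvals, _ = agdex_matrix(
            matrices["a"], groupings["a"], ref_samples["a"],
            matrices["b"], groupings["b"], ref_samples["b"],
            omap, n_perm=config.n_perm, seed=config.seed,
        )
        p_ag = out / "agdex.tsv"
        p_agp = out / "agdex_p.tsv"
        _write_tsv(scores, p_ag)
        _write_tsv(pvals, p_agp)
        _finish_stage(stage, [p_ag, p_agp])

        stage = "centroid_correlation"
        corr_files = []
        for key in ("a", "b"):
            r = results[key]
            sp_ann = r["annotation"]
            ref_groups = sorted(
                set(sp_ann.loc[sp_ann["role"] == "reference", "group"])
                - {config.reference_a, config.reference_b}
            )
            if not ref_groups:
                manifest["warnings"].append(
                    f"centroid correlation skipped for {r['species']}: "
                    "no reference sets beyond the differential-vector reference"
                )
                continue
            ref_sets = {
                g: list(sp_ann.loc[sp_ann["group"] == g, "sample_id"])
                for g in ref_groups
            }
            # full (unfiltered) matrix supplies reference samples; gene
            # universe restricted to the expressed-and-variable genes
            corr = centroid_correlation(
                r["tumour_matrix"], groupings[key],
                matrices[key], ref_sets,
                gene_ids=r["tumour_matrix"].gene_ids,
                zscore=config.zscore_centroids,
            )
            p_corr = out / f"correlations_{r['species']}.tsv"
            _write_tsv(corr, p_corr)
            corr_files.append(p_corr)
        _finish_stage(stage, corr_files)

        manifest["selected_k"] = {
            results[k]["species"]: {
                "consensus_pac": results[k]["consensus"].selected_k,
                "nmf_cophenetic": results[k]["nmf"].best_k_,
            }
            for k in ("a", "b")
        }
        manifest["warnings"].extend(sorted(set(caught)))
        manifest["valid"] = True
    except Exception as exc:
        manifest["failed_stage"] = stage
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
        raise RuntimeError(f"pipeline stage {stage!r} failed: {exc}") from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
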