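"""End-to-end orchestration: simulate or ingest, filter, prune, select,
validate, expand, annotate, heatmap, F4 — driven by one YAML config, with a
machine-readable run report.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .boost import ModelSpec, ResampledBoostSelector
from .datatypes import GenotypeMatrix
from .expand import expand
from .f4 import build_quartets, f4, population_frequencies
from .genes import annotate_variants, candidate_genes, genotype_heatmap_order, read_gff3
from .prune import ld_prune, pairwise_r2
from .simulate import SimConfig, simulate_study, write_fixture
from .validate import accuracy_distribution, cv52_ttest, majority_baseline
from .vcfio import (
    DEFAULT_HARD_FILTERS,
    hard_filter,
    read_phenotype_table,
    read_population_map,
    read_vcf,
)

logger = logging.getLogger(__name__)

__all__ = ["run", "truth_recovery_metrics"]


def truth_recovery_metrics(
    selected_ids: list[str],
    matrix: GenotypeMatrix,
    causal_ids: list[str],
    r2_proxy: float = 0.8,
) -> dict:
    """Recall/precision of a selected set against planted causal variants.

    A causal variant counts as recovered if it is selected itself or if some
    selected variant is an r² > ``r2_proxy`` proxy of it; selected variants
    that are neither causal nor proxies count as false selections.
    """
    index = {v: i for i, v in enumerate(matrix.variant_ids)}
    causal_present = [c for c in causal_ids if c in index]
    selected = [s for s in selected_ids if s in index]
    recovered = set()
    proxy_of_causal = set()
    for c in causal_present:
        if c in selected:
            recovered.add(c)
        for s in selected:
            if s == c:
                continue
            if pairwise_r2(matrix.dosage[:, index[c]], matrix.dosage[:, index[s]]) > r2_proxy:
                recovered.add(c)
                proxy_of_causal.add(s)
    false = [s for s in selected if s not in set(causal_present) | proxy_of_causal]
    recall = len(recovered) / len(causal_present) if causal_present else float("nan")
    precision = (
        (len(selected) - len(false)) / len(selected) if selected else float("nan")
    )
    return {
        "n_causal": len(causal_present),
        "n_selected": len(selected),
        "n_recovered": len(recovered),
        "n_false": len(false),
        "recall": recall,
        "precision": precision,
        "false_ids": false,
    }


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        with open(config) as fh:
            return yaml.safe_load(fh)
    return dict(config)


def run(config, out_dir: str | Path | None = None) -> dict:
    """Execute the configured stages in order and return the run report.

    ``config`` is a YAML path or a dict with optional sections ``simulate``
    (or ``input`` with vcf/phenotypes/populations/gff3/truth paths),
    ``filter``, ``prune``, ``select``, ``validate``, ``expand``,
    ``annotate``, ``f4`` and ``out_dir``. Stage outputs and ``report.json``
    are written under ``out_dir``; the report is also returned.
    """
    cfg = _load_config(config)
    if "simulate" not in cfg and "input" not in cfg:
        raise ValueError("config needs a 'simulate' or 'input' section")
    out = Path(out_dir or cfg.get("out_dir", "traitboost_run"))
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"version": __version__, "config": cfg, "stages": {}}

    truth = None
    gff_path = None
    if "simulate" in cfg:
        sim_cfg = SimConfig(**cfg.get("simulate") or {})
        matrix, traits, truth = simulate_study(sim_cfg)
        paths = write_fixture(matrix, traits, truth, sim_cfg, out / "fixture")
        gff_path = paths["gff3"]
        matrix = read_vcf(paths["vcf"])  # run the real ingestion path
        traits = read_phenotype_table(paths["phenotypes"])
        popmap = read_population_map(paths["populations"])
    elif "input" in cfg:
        paths = cfg["input"]
        matrix = read_vcf(paths["vcf"])
        traits = read_phenotype_table(paths["phenotypes"])
        popmap = (
            read_population_map(paths["populations"])
            if "populations" in paths
            else None
        )
        gff_path = paths.get("gff3")
        if "truth" in paths:
            truth_doc = json.loads(Path(paths["truth"]).read_text())
            truth = truth_doc
    else:
        raise ValueError("config needs a 'simulate' or 'input' section")
    causal_ids = (
        truth.causal_variant_ids
        if truth is not None and hasattr(truth, "causal_variant_ids")
        else (truth or {}).get("causal_variant_ids", [])
        if truth is not None
        else []
    )
    report["stages"]["input"] = {
        "n_samples": matrix.n_samples,
        "n_variants": matrix.n_variants,
        "traits": list(traits.columns),
    }

    filter_cfg = cfg.get("filter", {})
    expressions = filter_cfg.get("expressions", list(DEFAULT_HARD_FILTERS))
    kept = hard_filter(matrix.variants, expressions)
    matrix_f = matrix.subset_variants(list(kept["variant_id"]))
    report["stages"]["filter"] = {
        "n_in": matrix.n_variants,
        "n_out": matrix_f.n_variants,
        "expressions": list(expressions),
    }

    prune_cfg = cfg.get("prune", {})
    pruned_ids = ld_prune(
        matrix_f,
        window=prune_cfg.get("window", 50),
        step=prune_cfg.get("step", 10),
        r2_max=prune_cfg.get("r2_max", 0.1),
    )
    matrix_p = matrix_f.subset_variants(pruned_ids)
    report["stages"]["prune"] = {
        "n_in": matrix_f.n_variants,
        "n_out": matrix_p.n_variants,
    }

    sel_cfg = cfg.get("select", {})
    seed = int(sel_cfg.get("seed", 0))
    report["traits"] = {}
    all_selected: dict[str, list[str]] = {}
    for trait_name in traits.columns:
        labels = traits[trait_name].dropna()
        samples = [s for s in matrix_p.samples if s in labels.index]
        sub = matrix_p.subset_samples(samples)
        y = labels.loc[samples].to_numpy(dtype=int)
        spec_kwargs = sel_cfg.get("model_spec")
        selector = ResampledBoostSelector(
            model_spec=ModelSpec(**spec_kwargs) if spec_kwargs else None,
            n_fits=int(sel_cfg.get("n_fits", 100)),
            threshold=int(sel_cfg.get("threshold", 20)),
            tune_budget=int(sel_cfg.get("tune_budget", 0)),
            random_state=seed,
            feature_names=sub.variant_ids,
        )
        selector.fit(sub.dosage, y)
        selection = selector.selection_
        selection.to_tsv(out / f"selection_{trait_name}.tsv")
        selected_ids = selection.selected_ids
        all_selected[trait_name] = selected_ids
        trait_report = {
            "n_selected": len(selected_ids),
            "accuracy": accuracy_distribution(selector.fit_records_),
        }

        val_cfg = cfg.get("validate", {})
        if val_cfg.get("enabled", True):
            cv = cv52_ttest(
                sub.dosage,
                y,
                selector.model_spec_.make_classifier(random_state=seed),
                majority_baseline(),
                seed=int(val_cfg.get("seed", seed)),
            )
            trait_report["cv52"] = {
                "t": cv.t_statistic,
                "p": cv.p_value,
                "significant": cv.significant,
            }

        exp_cfg = cfg.get("expand", {})
        hits = expand(
            selected_ids,
            matrix_f,
            r_min=float(exp_cfg.get("r_min", 0.97)),
            absolute=bool(exp_cfg.get("absolute", False)),
        )
        hits.to_csv(out / f"expansion_{trait_name}.tsv", sep="\t", index=False)
        expanded_ids = selected_ids + [
            v for v in hits["companion_variant_id"].unique() if v not in selected_ids
        ]
        trait_report["n_expanded"] = len(expanded_ids)

        if gff_path is not None:
            ann_cfg = cfg.get("annotate", {})
            genes = read_gff3(gff_path)
            ann = annotate_variants(
                matrix_f.variants[matrix_f.variants["variant_id"].isin(expanded_ids)],
                genes,
                window=int(ann_cfg.get("window", 5000)),
            )
            ann.to_csv(out / f"annotation_{trait_name}.tsv", sep="\t", index=False)
            cand = candidate_genes(ann)
            cand.to_csv(out / f"candidate_genes_{trait_name}.tsv", sep="\t", index=False)
            trait_report["n_candidate_genes"] = len(cand)
            if causal_ids:
                causal_ann = annotate_variants(
                    matrix.variants[matrix.variants["variant_id"].isin(causal_ids)],
                    genes,
                    window=int(ann_cfg.get("window", 5000)),
                )
                truth_genes = set(causal_ann["gene_id"].dropna())
                found = truth_genes & set(cand["gene_id"])
                trait_report["gene_recall"] = (
                    len(found) / len(truth_genes) if truth_genes else float("nan")
                )

        if selected_ids and len(samples) >= 2:
            order = genotype_heatmap_order(
                sub.subset_variants(selected_ids).to_heatmap_coding(), y
            )
            trait_report["heatmap"] = {
                "row_order": order["row_order"].tolist(),
                "col_order": order["col_order"].tolist(),
            }

        if causal_ids:
            trait_report["truth_recovery"] = {
                k: v
                for k, v in truth_recovery_metrics(
                    selected_ids, matrix_f, causal_ids
                ).items()
                if k != "false_ids"
            }
        report["traits"][trait_name] = trait_report

    f4_cfg = cfg.get("f4")
    if f4_cfg and popmap:
        pf = population_frequencies(
            matrix_p, popmap, block_size=int(f4_cfg.get("block_size", 500))
        )
        quartets = build_quartets(
            pf.populations,
            f4_cfg["outgroup"],
            [tuple(t) for t in f4_cfg.get("hypotheses", [])],
        )
        rows = [f4(pf, q).as_row() for q in quartets]
        f4_table = pd.DataFrame(rows)
        f4_table.to_csv(out / "f4.tsv", sep="\t", index=False)
        report["f4"] = rows

    (out / "report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
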