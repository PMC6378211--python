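"""End-to-end pipeline: CV filter -> co-expression modules -> time profiles
-> ceRNA network -> enrichment, with a run manifest.

The candidate RNAs handed to the network stage are the intersection-shared
DELs/DEMs that are associated with reperfusion injury — members of a
trait-significant co-expression module (p < alpha) OR assigned to a
significant time profile. The union rule is the default; an intersection
rule is selectable and the choice is recorded in the manifest.
"""
from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cerna_network import (
    assemble_cerna,
    coexpressed_pairs,
    extract_gene_module,
    node_trait_profile,
)
from .coexpression import (
    detect_modules,
    make_trait,
    module_eigengene,
    module_trait_association,
    select_power,
    topological_overlap,
    adjacency_matrix,
)
from .enrichment import enrichment_table, hypergeom_enrich
from .io_formats import (
    ExpressionMatrix,
    ValidationError,
    read_annotations,
    read_expression,
    read_pairs,
    write_network,
    write_pairs,
)
from .timecourse_profiles import (
    assign_genes,
    enumerate_profiles,
    gene_time_series,
    profile_significance,
    select_representatives,
)
from .variability_filter import intersect_patients, sample_correlation_qc, screen_by_cv

logger = logging.getLogger("cerna_ti")

EXIT_OK = 0
EXIT_VALIDATION = 2
EXIT_STAGE_FAILURE = 3


class StageError(RuntimeError):
    """A pipeline stage failed; carries the stage name and an error code."""

    def __init__(self, stage: str, message: str):
        super().__init__(f"[stage={stage}] {message}")
        self.stage = stage
        self.code = EXIT_STAGE_FAILURE


@dataclass
class PipelineConfig:
    """All stage parameters plus input paths, loadable from YAML."""

    expression: str
    sample_meta: str
    pairs: str
    annotations: str
    out_dir: str = "cerna_run"
    cv_threshold: float = 0.6
    trait_encoding: str = "binary"
    target_r2: float = 0.9
    min_module_size: int = 20
    cut_height: float = 0.95
    module_alpha: float = 0.05
    profile_c: int = 1
    profile_m: int = 50
    n_permutations: int = 1000
    profile_alpha: float = 0.05
    min_abs_r: float = 0.9
    alpha: float = 0.05
    association_rule: str = "union"  # "union" | "intersection"
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(raw) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValidationError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**raw)

    def validate(self) -> None:
        for p in (self.expression, self.sample_meta, self.pairs, self.annotations):
            if not Path(p).exists():
                raise ValidationError(f"input file not found: {p}")
        if self.cv_threshold < 0 or not 0 < self.target_r2 <= 1:
            raise ValidationError("cv_threshold must be >= 0 and target_r2 in (0, 1]")
        if self.association_rule not in ("union", "intersection"):
            raise ValidationError("association_rule must be 'union' or 'intersection'")


def _sha256(path: str | Path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = True) -> None:
    df.to_csv(path, sep="\t", index=index, float_format="%.10g")


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute every stage in order, writing stage outputs and a manifest.

    Returns the run directory. On stage failure a :class:`StageError` is
    raised and partial outputs are retained.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "tool": "cerna-ti",
        "version": __version__,
        "parameters": asdict(config),
        "input_checksums": {
            name: _sha256(getattr(config, name))
            for name in ("expression", "sample_meta", "pairs", "annotations")
        },
        "set_sizes": {},
    }
    sizes = manifest["set_sizes"]

    def stage(name):
        logger.info("=== stage: %s ===", name)

    try:
        stage("load")
        expr = read_expression(config.expression, config.sample_meta)
        pairs = read_pairs(config.pairs)
        annot = read_annotations(config.annotations)
        trait = make_trait(expr.sample_meta.loc[expr.samples],
                           config.trait_encoding)
        sizes["genes"] = len(expr.gene_ids)
        sizes["samples"] = len(expr.samples)
        sizes["pairs"] = len(pairs)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("load", str(exc)) from exc

    try:
        stage("filter")
        qc = sample_correlation_qc(expr)
        _write_tsv(qc, out / "sample_r2.tsv")
        report = screen_by_cv(expr, config.cv_threshold)
        for p, cv in report.cv.items():
            _write_tsv(cv.rename("cv").to_frame(), out / f"cv_{p}.tsv")
        dels, dems = intersect_patients(report)
        shared = sorted(dels | dems)
        (out / "shared_DELs.txt").write_text("\n".join(sorted(dels)) + "\n")
        (out / "shared_DEMs.txt").write_text("\n".join(sorted(dems)) + "\n")
        sizes["shared_DELs"] = len(dels)
        sizes["shared_DEMs"] = len(dems)
        shared_expr = expr.subset_genes(shared) if shared else None
        if len(shared) < 10:
            logger.warning("only %d shared genes survive the CV screen; "
                           "module detection will be skipped", len(shared))
    except StageError:
        raise
    except Exception as exc:
        raise StageError("filter", str(exc)) from exc

    try:
        stage("modules")
        if len(shared) >= 10:
            scan = select_power(shared_expr, config.target_r2)
            _write_tsv(scan.as_frame(), out / "power_scan.tsv", index=False)
            sizes["selected_power"] = scan.selected
            adj = adjacency_matrix(shared_expr, scan.selected)
            tom = topological_overlap(adj)
            modules, unassigned = detect_modules(
                tom, config.min_module_size, config.cut_height
            )
            for m in modules:
                module_eigengene(shared_expr, m)
            modules = module_trait_association(modules, trait) if modules else []
        else:
            modules, unassigned = [], shared
        membership = pd.DataFrame(
            [(m.label, g) for m in modules for g in m.members]
            + [("unassigned", g) for g in unassigned],
            columns=["module", "gene"],
        )
        _write_tsv(membership, out / "module_membership.tsv", index=False)
        _write_tsv(pd.DataFrame(
            [{"module": m.label, "size": len(m.members),
              "explained_variance": m.explained_variance,
              "trait_r": m.trait_correlation, "trait_p": m.trait_p}
             for m in modules]), out / "module_trait.tsv", index=False)
        sizes["modules"] = len(modules)
        module_sig_genes = {
            g for m in modules if m.trait_p < config.module_alpha
            for g in m.members
        }
        sizes["module_significant_genes"] = len(module_sig_genes)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("modules", str(exc)) from exc

    try:
        stage("profiles")
        if shared_expr is not None:
            T = len(shared_expr.time_points)
            profiles = enumerate_profiles(T=T, c=config.profile_c)
            reps = select_representatives(profiles, config.profile_m)
            series = gene_time_series(shared_expr)
            assignments = assign_genes(series, reps)
            sig = profile_significance(series, reps,
                                       n_permutations=config.n_permutations,
                                       seed=config.seed)
            _write_tsv(sig.table, out / "profile_table.tsv")
            _write_tsv(assignments.rename("profile_id").to_frame(),
                       out / "profile_assignments.tsv")
            sig_profiles = set(sig.significant(config.profile_alpha))
            profile_sig_genes = set(
                assignments.index[assignments.isin(sig_profiles)]
            )
        else:
            sig_profiles, profile_sig_genes = set(), set()
        sizes["significant_profiles"] = len(sig_profiles)
        sizes["profile_significant_genes"] = len(profile_sig_genes)
    except StageError:
        raise
    except Exception as exc:
        raise StageError("profiles", str(exc)) from exc

    try:
        stage("network")
        if config.association_rule == "union":
            associated = module_sig_genes | profile_sig_genes
        else:
            associated = module_sig_genes & profile_sig_genes
        sizes["iri_associated_rnas"] = len(associated)
        (out / "iri_associated.txt").write_text(
            "\n".join(sorted(associated)) + ("\n" if associated else "")
        )
        if associated:
            assoc_expr = expr.subset_genes(sorted(associated))
            kept = coexpressed_pairs(assoc_expr, pairs, config.min_abs_r)
        else:
            kept = []
        _write_tsv(pd.DataFrame(
            [{"lncRNA": p.lncrna, "mRNA": p.mrna, "r": p.r,
              "direction": p.direction} for p in kept]),
            out / "coexpressed_pairs.tsv", index=False)
        net = assemble_cerna(kept, pairs)
        net.validate()
        write_network(net, out / "cerna_network.sif", "SIF")
        write_network(net, out / "cerna_network.graphml", "GraphML")
        write_network(net, out / "cerna_network_edges.tsv", "TSV")
        _write_tsv(pd.DataFrame(
            [(t.lncrna, t.mirna, t.mrna) for t in net.triplets],
            columns=["lncRNA", "miRNA", "mRNA"]),
            out / "cerna_triplets.tsv", index=False)
        counts = pd.DataFrame(
            [{"kind": "node", "type": k, "count": v}
             for k, v in net.node_counts().items()]
            + [{"kind": "edge", "type": k, "count": v}
               for k, v in net.edge_counts().items()])
        _write_tsv(counts, out / "network_counts.tsv", index=False)
        sizes["coexpressed_pairs"] = len(kept)
        sizes["cerna_nodes"] = net.n_nodes
        sizes["cerna_edges"] = net.n_edges
        sizes["cerna_triplets"] = len(net.triplets)
        profile_tab = node_trait_profile(expr, net, trait)
        _write_tsv(profile_tab, out / "node_trait_profiles.tsv")
    except StageError:
        raise
    except Exception as exc:
        raise StageError("network", str(exc)) from exc

    try:
        stage("enrichment")
        net_mrnas = {g for g, b in net.nodes.items() if b == "mRNA"}
        universe = {
            g for g in expr.gene_ids
            if any(g in members for _, members in annot.terms.values())
        }
        results = []
        focus: set[str] = set()
        if net_mrnas & universe:
            restricted = annot.restrict_universe(universe)
            results = hypergeom_enrich(net_mrnas & universe, restricted,
                                       alpha=config.alpha)
            top_sig = [r for r in results if r.p < config.alpha]
            if top_sig:
                best = top_sig[0]
                _, members = annot.terms[best.term_id]
                focus = net_mrnas & members
        _write_tsv(enrichment_table(results), out / "enrichment.tsv", index=False)
        sizes["significant_terms"] = sum(r.p < config.alpha for r in results)
        if focus:
            sub = extract_gene_module(net, focus)
            write_network(sub, out / "functional_submodule.sif", "SIF")
            sizes["submodule_nodes"] = sub.n_nodes
            sizes["submodule_edges"] = sub.n_edges
    except StageError:
        raise
    except Exception as exc:
        raise StageError("enrichment", str(exc)) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    logger.info("run complete: %s", json.dumps(sizes))
    return out
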